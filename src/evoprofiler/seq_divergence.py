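"""Pairwise dN/dS per OG by Nei-Gojobori (1986) counting.

Unweighted pathway averaging with Jukes-Cantor correction; a desk-scale
substitute for codon-model maximum likelihood. Parsed external M0 values take
precedence in the pipeline when supplied.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

STANDARD_CODE = {}
_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            STANDARD_CODE[_b1 + _b2 + _b3] = _AA[16 * _i + 4 * _j + _k]

_NUCS = "ACGT"


@dataclass
class CodonPairCounts:
    """NG86 site and difference counts for one sequence pair."""

    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    n_codons: int

    @property
    def pS(self) -> float:
        return self.Sd / self.S_sites if self.S_sites > 0 else np.nan

    @property
    def pN(self) -> float:
        return self.Nd / self.N_sites if self.N_sites > 0 else np.nan

    @property
    def dS(self) -> float:
        return jukes_cantor(self.pS)

    @property
    def dN(self) -> float:
        return jukes_cantor(self.pN)


def jukes_cantor(p: float) -> float:
    """JC69-corrected distance; NaN when p >= 3/4 (undefined)."""
    if np.isnan(p) or p >= 0.75:
        return np.nan
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def synonymous_site_count(codon: str, code: dict = STANDARD_CODE) -> float:
    """Sum over positions of the fraction of single-nt changes that are
    synonymous; changes producing stop codons are dropped from the
    denominator."""
    aa = code[codon]
    if aa == "*":
        raise ValueError(f"stop codon {codon!r} has no site counts")
    total = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for nt in _NUCS:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if code[alt] == "*":
                continue
            valid += 1
            if code[alt] == aa:
                syn += 1
        if valid:
            total += syn / valid
    return total


def pathway_differences(c1: str, c2: str, code: dict = STANDARD_CODE) -> tuple:
    """(Sd, Nd) for one codon pair, averaged over all substitution orders.

    Pathways with stop-codon intermediates are excluded; in the (rare) case
    that every pathway is blocked, all pathways are used with steps into or
    out of stops counted as nonsynonymous.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order, allow_stops):
        cur = c1
        sd = nd = 0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if code[nxt] == "*" and nxt != c2 and not allow_stops:
                return None
            if code[cur] == code[nxt] and code[cur] != "*":
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    results = [walk(order, False) for order in permutations(diff_pos)]
    results = [r for r in results if r is not None]
    if not results:
        results = [walk(order, True) for order in permutations(diff_pos)]
    sd = float(np.mean([r[0] for r in results]))
    nd = float(np.mean([r[1] for r in results]))
    return sd, nd


_TABLE_CACHE: dict = {}


def _ng86_tables(code: dict):
    key = id(code)
    if key not in _TABLE_CACHE:
        sense = [c for c, aa in code.items() if aa != "*"]
        sites = {c: synonymous_site_count(c, code) for c in sense}
        diffs = {}
        for c1 in sense:
            for c2 in sense:
                diffs[(c1, c2)] = pathway_differences(c1, c2, code)
        _TABLE_CACHE[key] = (set(sense), sites, diffs)
    return _TABLE_CACHE[key]


def ng86_pair(seq_a: str, seq_b: str, code: dict = STANDARD_CODE) -> CodonPairCounts:
    """NG86 counts for an aligned codon sequence pair.

    Codons containing gaps/N, or that are stop codons, in either sequence are
    skipped pairwise. Site counts are averaged over the two sequences.
    """
    seq_a = seq_a.upper()
    seq_b = seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be equal length")
    if len(seq_a) % 3 != 0:
        raise ValueError("sequence length must be divisible by 3")
    sense, site_tab, diff_tab = _ng86_tables(code)
    s_sites = 0.0
    sd = nd = 0.0
    n_codons = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3], seq_b[i:i + 3]
        if ca not in sense or cb not in sense:
            continue
        n_codons += 1
        s_sites += 0.5 * (site_tab[ca] + site_tab[cb])
        dsd, dnd = diff_tab[(ca, cb)]
        sd += dsd
        nd += dnd
    return CodonPairCounts(
        S_sites=s_sites,
        N_sites=3.0 * n_codons - s_sites,
        Sd=sd,
        Nd=nd,
        n_codons=n_codons,
    )


def og_divergence(alignment, code: dict = STANDARD_CODE) -> tuple:
    """(PDS, PDN, SEL) for one OG alignment: means of pairwise dS and dN.

    Each mean covers the pairs where that distance is defined (JC correction
    can saturate one but not the other). SEL = PDN/PDS; NaN when PDS is 0 or
    undefined.
    """
    if len(alignment) < 2:
        raise ValueError("need >= 2 sequences")
    ds_vals, dn_vals = [], []
    for i in range(len(alignment)):
        for j in range(i + 1, len(alignment)):
            pc = ng86_pair(alignment[i][1], alignment[j][1], code)
            if pc.n_codons == 0:
                continue
            if not np.isnan(pc.dS):
                ds_vals.append(pc.dS)
            if not np.isnan(pc.dN):
                dn_vals.append(pc.dN)
    pds = float(np.mean(ds_vals)) if ds_vals else np.nan
    pdn = float(np.mean(dn_vals)) if dn_vals else np.nan
    sel = pdn / pds if (ds_vals and dn_vals and pds > 0) else np.nan
    return pds, pdn, sel


def compute_divergence_table(alignments: dict, code: dict = STANDARD_CODE):
    """Per-OG (PDS, PDN, SEL) DataFrame from a CodonAlignmentSet mapping."""
    import pandas as pd

    rows = {}
    for og in sorted(alignments):
        pds, pdn, sel = og_divergence(alignments[og], code)
        rows[og] = {"PDS": pds, "PDN": pdn, "SEL": sel}
    return pd.DataFrame.from_dict(rows, orient="index")[["PDS", "PDN", "SEL"]]
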