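# evoprofiler

Evolutionary feature profiling of gene families. The package computes 18
per-orthologous-group (OG) evolutionary metrics, aggregates them into
per-family profiles with delta-vs-rest statistics and significance tests,
clusters family profiles with multiscale-bootstrap support (AU/BP) and a
subtree co-occurrence similarity, and quantifies pairwise family expression
similarity on a clustered expression map with permutation nulls — all
exercisable end-to-end on seeded synthetic data.

## Metrics

| Group | Metrics |
|---|---|
| Taxonomic spread / copy number | AGE, UNI, DUP, ACN, CNV |
| Copy-number turnover (Wagner parsimony or parsed reports) | EXP, CON, STA |
| Genomic organization / protein divergence | SYN, EVR |
| Codon divergence (NG86 or parsed PAML M0) | PDS, PDN, SEL |
| Population variation | NSP, NSD, SSD |
| Whole-genome alignment tracks | WGA, PHC |

## CLI

```bash
# generate a complete synthetic input bundle with ground truth
evoprofiler simulate bundle --seed 1 --out-dir sim/

# per-OG metrics
evoprofiler metrics og --orthology sim/orthology.tsv --tree sim/species_tree.nwk \
    --orders sim/gene_orders.tsv --identities sim/identities.tsv --out og.tsv
evoprofiler metrics turnover --orthology sim/orthology.tsv --tree sim/species_tree.nwk --out turnover.tsv
evoprofiler metrics dnds --alignments sim/alignments/ --out dnds.tsv
evoprofiler metrics sites --orthology sim/orthology.tsv --tree sim/species_tree.nwk \
    --snps sim/snps.tsv --genes sim/genes.gff3 --wga sim/wga.bedgraph \
    --phastcons sim/phastcons.bedgraph --focal-species sp01 --out sites.tsv

# family profiles, clustering, expression similarity
evoprofiler profile --og-metrics og.tsv --catalog sim/catalog.tsv \
    --orthology sim/orthology.tsv --stat mean --n-perm 10000 --seed 1 --out profile.tsv
evoprofiler cluster --profile family_matrix.tsv --n-per-scale 1000 --seed 1 --out-dir cluster/
evoprofiler exprmap --map sim/expression_map.tsv --catalog sim/catalog.tsv \
    --resolution supercell --n-perm 10000 --seed 1 --out coexpr.tsv
evoprofiler exprmodules --expr expr_matrix.tsv --n-modules 8 --out partition.tsv
evoprofiler compare --evo cluster/family_similarity.tsv --expr coexpr.tsv --out pairs.tsv

# everything from one JSON config
evoprofiler run --config config.json
```

All tabular outputs are TSV with headers; dendrograms are newick with
`[&au=..,bp=..]` node comments; similarity graphs export to DOT/GraphML.
Repeat runs with the same seed are byte-identical.

## Layout

- `src/evoprofiler/data_model_io/` — domain types and readers/writers
  (newick, orthology/catalog/order/SNP/map TSVs, FASTA, GFF3, bedGraph,
  turnover reports, codon-model summaries)
- `src/evoprofiler/og_metrics.py` — AGE/UNI/DUP/ACN/CNV/SYN/EVR
- `src/evoprofiler/turnover.py` — Sankoff parsimony, EXP/CON/STA
- `src/evoprofiler/seq_divergence.py` — NG86 dN/dS with pathway averaging
- `src/evoprofiler/site_metrics.py` — NSP/NSD/SSD and CDS track averaging
- `src/evoprofiler/family_profiling.py` — family deltas, scaling, rank-sum +
  permutation significance
- `src/evoprofiler/profile_clustering.py` — scaling, 4 distances × 4
  linkages, multiscale-bootstrap AU, subtree co-occurrence, PCA
- `src/evoprofiler/expression_similarity.py` — cell/supercell/module
  co-occurrence, permutation tests, evolutionary-vs-expression pairing
- `src/evoprofiler/synthetic_data.py` — seeded simulators for every input,
  plus the packaged immune gene catalog fixture
- `src/evoprofiler/pipeline.py`, `cli.py` — orchestration and `evoprofiler`
  entry point
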