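# dieltk

Comparative analysis of daily (diel) rhythmic gene expression across
distantly related photosynthetic species — microalgae to land plants —
where classical one-to-one orthology and shared array platforms both
break down.

Transcriptomes sampled every 3–4 h over 48–72 h under light:dark cycles
raise four linked questions that this package answers end to end:

1. **Which genes correspond between species?**  The *Multiple
   Bidirectional Best Hit* (MBBH) algorithm generalises reciprocal-best-
   hit orthology to gene families: for each protein the *N* (default 20)
   best global Needleman–Wunsch hits in the other proteome are kept,
   reciprocity within the top-*N* lists is required, pairs that share no
   annotated protein domain are removed, and proteins left unmatched can
   still pair through an exact domain-architecture match (same domains,
   same order, same count).
2. **Which genes are rhythmic?**  A nonparametric phase-scanning
   umbrella rank test: observations folded at the 24 h period are
   compared with the Mack–Wolfe umbrella statistic for every candidate
   peak phase, and the best phase's one-sided normal p-value is
   Bonferroni-corrected by the number of phases.  Genes with p < α
   (default 1%) are called rhythmic, characterised by the peak and
   trough ZT of their folded mean profile, and assigned to one of
   16 diel clusters — the (peak, trough) pair of the four 6 h intervals
   Dawn [ZT21, 3), Day [3, 9), Dusk [9, 15), Night [15, 21).
3. **How is the rhythmic transcriptome organised?**  A co-expression
   network joins rhythmic genes whose hourly 24 h profiles have Pearson
   r > 0.95, with scale-free (log–log degree regression) and small-world
   (clustering vs 10⁴ matched preferential-attachment graphs)
   diagnostics.
4. **Are rhythmic patterns conserved?**  Orthologous pairs that agree in
   diel pattern (same cluster, or profile r > 0.98) are *expresologues*;
   whole clusters are scored with the permutation **Zsummary** composite
   (median of two density Z-scores, median of two connectivity Z-scores,
   averaged) with the standard thresholds — < 2 no conservation, 2–10
   moderate, > 10 high.  Fisher-exact GO and hypergeometric pathway
   enrichment with Benjamini–Hochberg control round out the workflow.

A seeded synthetic-data module generates proteomes with controlled
family structure and diel expression with a controllable rhythmic
fraction, so the entire pipeline is testable without any external
download.

## Worked example

```python
from dieltk.synthetic import DielSpec, make_diel_expression
from dieltk.rhythmicity import run_rhythm_analysis, merge_by_peak
from dieltk.network import build_network, mean_clustering

spec = DielSpec(n_genes=200, rhythmic_fraction=0.6, noise_sd=0.5, seed=42)
matrix, truth = make_diel_expression(spec)

res = run_rhythm_analysis(matrix, alpha=0.01)
print("rhythmic:", int(res.rhythmic.sum()), "of", len(res))

labels = {g: (r.cluster_peak, r.cluster_trough)
          for g, r in res[res.rhythmic].iterrows()}
print({k: len(v) for k, v in merge_by_peak(labels).items()})

net = build_network(matrix, list(res.index[res.rhythmic]), threshold=0.95)
print("network:", net.n_nodes, "nodes,", net.n_edges, "edges")
print("mean clustering: %.3f" % mean_clustering(net))
```

prints

```
rhythmic: 121 of 200
{'Dawn': 14, 'Day': 38, 'Dusk': 21, 'Night': 48}
network: 121 nodes, 556 edges
mean clustering: 0.726
```

121 of the 200 simulated genes pass the 1% rhythm test (120 of the 120
truly rhythmic genes plus one false positive, consistent with the
nominal level), the rhythmic genes distribute over the four merged
peak-interval clusters according to their simulated phases, and the
r > 0.95 network connects genes of similar phase into a densely
clustered (0.726) graph.

## Command line

Every stage is also a `dieltk` subcommand:

```sh
dieltk simulate expression --n-genes 200 --seed 42 -o sim
dieltk rhythm  --expr sim_expr.tsv --meta sim_meta.tsv -o rhythm.tsv
dieltk mbbh    --fasta-a a.fasta --fasta-b b.fasta \
               --domains-a a_dom.tsv --domains-b b_dom.tsv -n 20 -o ortho.tsv
dieltk network --expr sim_expr.tsv --meta sim_meta.tsv --rhythm rhythm.tsv \
               --threshold 0.95 --nrandom 10000 --seed 1 -o net/
dieltk pipeline --config config.yaml -o run/     # the full comparison
```

`dieltk pipeline` consumes a YAML config naming the two species' FASTA,
domain, expression and annotation files, runs every stage with seeds
derived from one run seed, and writes a machine-readable
`manifest.json`; re-running with the same config reproduces every
output byte for byte.

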