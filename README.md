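# netmap

From differential CSF proteomics to perturbed pathway modules.

After traumatic spinal cord injury, the severity of the lesion (complete,
AIS A, versus incomplete, AIS C/D) shapes which molecular pathways are
perturbed during the secondary-injury phase. One way to map those pathways
from cerebrospinal fluid is a four-stage pipeline, which this package
implements as a tested, reusable library with a thin CLI:

1. **DIGE screening** (`netmap.dige`). On each two-dye difference gel a
   complete-injury CSF sample runs against an incomplete-injury sample
   (Cy5/Cy3, reverse-labelled on half of the gels). Spot-volume ratios are
   re-oriented to complete/incomplete, averaged as a geometric mean, and
   reported as signed folds (r if r ≥ 1, else −1/r). A spot is differential
   when |fold| ≥ 1.5, at least 3 of 7 gels agree on the direction, and a
   two-sided one-sample t-test of the log2 ratios against 0 gives p < 0.1.
2. **Seed-expanded network construction** (`netmap.ppin`). The identified
   proteins are seeds; the network is the induced subgraph of a background
   interactome on the seeds plus their first interaction partners. Seeds
   without listed partners are dropped (with a report); an alias map handles
   symbols the interactome spells differently.
3. **Modularization** (`netmap.modularity`). Girvan–Newman divisive
   clustering: repeatedly remove a highest edge-betweenness edge
   (betweenness recomputed after every removal) and keep the intermediate
   partition maximizing modularity
   `Q = Σ_c [ e_c/m − (d_c/2m)² ]`.
   A greedy agglomerative (CNM) alternative and an exhaustive-search oracle
   (≤ 10 nodes) are included.
4. **Enrichment** (`netmap.enrichment`). Each module is a query set; for a
   term carried by K of N universe genes with k hits among n query genes,
   `Hyp = P(X ≥ k)` under the hypergeometric distribution, corrected per
   module by Benjamini–Hochberg FDR to `Hyp*`, significant at `Hyp* < 0.001`.

`netmap.synthetic` generates every input with planted ground truth
(stochastic-block-model graphs, Bernoulli gene-set annotations, lognormal
DIGE ratio tables with dye swaps, cohort tables), and `netmap.datasets`
bundles the transcribed clinical and differential-spot reference tables.

## Worked example

```python
import netmap as nm
from netmap import datasets

early = nm.summarize_group(datasets.early_cohort())
print(early)
# GroupSummary(n=14, mean_age=33.3, sd_age=11.7, mean_dpi=4.07,
#              grade_counts={'A': 7, 'C': 5, 'D': 2})

table = datasets.differential_fold_table()
folds = dict(zip(table.spot_id, table.early_fold))
spots = nm.differential_spots_from_folds(folds)        # |fold| >= 1.5
proteins = nm.map_spots_to_proteins(spots, datasets.differential_spot_map())
print(len(spots), len(proteins), proteins)
# 10 8 ['ALB', 'APOH', 'AZGP1', 'GTF3C5', 'HP', 'IGHG2', 'IGHG4', 'TF']
```

The 14-patient early group has mean age 33.3 ± 11.7 years and mean sampling
time 4.07 days post injury; the 1.5-fold screen over the differential-spot
table leaves 10 spots that collapse (isoform spots merged, comigrating spots
expanded) to 8 unique proteins.

On synthetic data with planted structure:

```python
inter, truth = nm.gen_planted_partition([25, 25, 25, 25], 0.3, 0.01, rng_seed=11)
part = nm.girvan_newman(inter.to_graph())
print(part.n_modules, round(part.modularity_q, 3))
# 4 0.652   — the four planted modules, recovered exactly (ARI = 1.0)
```

The same stages are available from the shell:

```
netmap simulate partition --sizes 25,25,25,25 --p-in 0.3 --p-out 0.01 --seed 11
netmap build --seeds seeds.txt --interactome interactome.tsv --out ppin.graphml
netmap modules --network ppin.graphml --method gn --out modules.tsv
netmap enrich --modules modules.tsv --gmt terms.gmt --out enrichment.tsv
```

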