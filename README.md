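# drynet

Multi-omics analysis of progressive drought stress: differential
screening of transcripts and metabolites, temporal clustering of
metabolite profiles, and bottom-up inference of a **multi-layer
hierarchical gene regulatory network (ML-hGRN)** linking transcription
factors, pathway genes and metabolites.

The package is aimed at plant systems biologists who have gene-level
expression matrices and widely-targeted LC-MS metabolite tables from a
stress time course and want to go from raw tables to a layered,
Cytoscape-ready regulatory network — with every statistical step
auditable and every algorithm testable against simulated data with
planted ground truth.

## What it computes

**Differential screens.** Genes are screened per stress timepoint
against the day-0 control with a simplified NB Wald test
(median-of-ratios size factors, shared method-of-moments dispersion)
and called at |log2FC| ≥ 1 with BH FDR < 0.05. Metabolites are
KNN-imputed, filtered at pooled-QC CV < 0.5, modelled by OPLS-DA, and
called at VIP > 1 with fold change ≥ 2 or ≤ 0.5. Venn-style
shared/exclusive sets identify features responding at every timepoint.

**Temporal clustering.** Metabolite profiles (replicate means per
timepoint, z-scored) are clustered by K-means (default k = 8).

**The ML-hGRN (the core).** For every pathway gene, a recursive random
forest ranks candidate TFs: importances are computed, the least
important fraction eliminated, and the forest re-fit until one TF
remains (`bottom-to-up weighted random forest`, BWERF). Each TF's
importances over the iterations it survived are averaged per gene and
summed across the pathway into a score; a two-component Gaussian
mixture on the scores separates regulatory TFs from background, and the
TFs with posterior ≥ 0.5 for the high component form the layer directly
above the pathway genes. The selected layer becomes the new target set
and the procedure stacks further layers. Gene–metabolite edges are
added by Pearson correlation (|r| ≥ 0.8, BH FDR < 0.05).

See `docs/methods.md` for model details, parameter defaults and the
simulators' scope.

## Worked example

Simulate a drought-like dataset with a planted two-layer hierarchy
(40 pathway genes, 10 true layer-1 TFs, 8 layer-2 TFs, 32 decoy TFs,
6 timepoints × 3 replicates) and rebuild the network:

```python
import warnings
from drynet import synthetic, grn

expr, truth = synthetic.simulate_hierarchy_expression(
    n_pathway_genes=40, n_layer1_tfs=10, n_layer2_tfs=8, n_decoys=32,
    timepoints=6, replicates=3, seed=1,
)
tfs = sorted(truth.layer_assignments) + sorted(truth.decoy_tfs)
net = grn.build_hierarchy(
    expr, candidate_tfs=tfs, pathway_genes=truth.pathway_genes,
    n_layers=2, drop_fraction=0.3, n_trees=100, seed=1,
)
true_l1 = truth.tfs_in_layer(1)
sel = set(net.layers[0])
print("layer sizes:", [len(l) for l in net.layers])
print("layer-1 recall:", len(sel & true_l1) / len(true_l1))
print("layer-1 precision:", round(len(sel & true_l1) / len(sel), 3))
print(grn.network_summary(net))
```

```
layer sizes: [8, 8]
layer-1 recall: 0.6
layer-1 precision: 0.75
{'n_layers': 2, 'tfs_per_layer': [8, 8], 'n_tfs': 16,
 'n_functional_genes': 40, 'n_tf_edges': 144, 'n_metabolite_edges': 0,
 'n_metabolites': 0}
```

Six of the eight TFs placed in layer 1 are true layer-1 regulators
(6/10 recalled on this seed; averaged over ten simulated datasets the
build typically reaches recall ~0.75 and precision ~0.55-0.65, with the
exact figures depending on the seed set — the hard contaminant is
layer-2 TFs, whose signal genuinely reaches the pathway genes through
their layer-1 children).  The same stages run from the shell:

```bash
drynet simulate --out-dir data --seed 1
drynet grn --expression data/expression.tsv --metadata data/expression_metadata.csv \
       --tf-list data/tf_list.txt --pathway-genes data/pathway_genes.txt \
       --n-trees 100 --drop-fraction 0.3 --out results
drynet run-all --config config.yaml --out results   # full pipeline
```

Outputs are plain TSV/CSV tables, SIF + GraphML networks and a JSON run
manifest; re-running a config reproduces byte-identical tables.

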