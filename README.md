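# ipf — integrative phenotyping for multi-omics subtype discovery

Cohort studies of complex disease increasingly pair a deeply phenotyped
clinical table (continuous, ordinal, binary and categorical variables)
with molecular profiles such as mRNA and miRNA expression.  `ipf` is for
researchers who want to ask: *do these data sources agree on a partition
of the patients into subtypes, and what does each subtype look like?*

## Method

For omics sources `X^(m)` (features × samples, m = 1..M) sharing a cohort
`J`, the pipeline:

1. filters non-expressed / non-informative features and standardizes each
   source;
2. concatenates all features and computes a type-aware feature
   dissimilarity `D = (1 − R)/2`, where `R` mixes Pearson, Spearman,
   point-biserial, phi and Cramér's V according to the variable types of
   each pair (pairwise-complete, so missing values need no imputation);
3. embeds all features in 2D by non-metric MDS, so correlated features
   co-locate;
4. smooths each patient's intensities over the embedding with a thin-plate
   regression spline, giving a profile vector
   `c_j^(m) = { f̂_j^(m)(s/n, t/n) }` on the `(n+1)²` unit-square grid —
   the *feature topology plot* (FTP) of that patient;
5. clusters patients with PAM on `D_{jj'}^(m) = 1 − cor(c_j^(m), c_{j'}^(m))`,
   choosing K by a gap statistic;
6. cross-tabulates the per-source clusterings, merges sources whose
   solutions agree (small off-diagonal mass after optimal cluster
   matching), and repeats agglomeratively; disagreeing sources are
   reported side by side;
7. selects cluster-associated biomarkers by one-way ANOVA with Bonferroni
   control, groups them into co-expression modules (PAM on `1 − cor`, with
   a sign flip for inhibitory miRNAs), and summarises clinical variables
   per cluster with Kruskal–Wallis tests.

A fitted clustering transfers to a new cohort by freezing the embedding
and assigning each new patient to its nearest training medoid — the
discovery → prediction → validation scheme.

See `docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

Simulate a cohort of 90 patients with three latent subtypes measured by a
mixed-type clinical table plus mRNA- and miRNA-like sources (3% missing
cells), then fit:

```python
import ipf
from ipf.config import RunConfig

mix = {"binary": 0.3, "ordinal": 0.2, "categorical": 0.1}
spec = ipf.SimSpec(
    n_samples=90, k_true=3, effect_size=3.0, noise_fraction=0.4,
    missing_rate=0.03,
    omics_specs=[
        ipf.OmicsSpec(n_features=40, var_type_mix=mix, name="clinical"),
        ipf.OmicsSpec(n_features=50, name="mRNA"),
        ipf.OmicsSpec(n_features=30, name="miRNA"),
    ],
    seed=5,
)
sim = ipf.simulate(spec)

model = ipf.IntegrativePhenotyping(
    sim.datasets, RunConfig(grid_n=12, k_max=5, gap_B=10, seed=5)
)
results = model.fit()
print(results.summary())
print("ARI vs truth:",
      ipf.ari(results.labels().reindex(sim.true_labels.index), sim.true_labels))
```

prints

```
Integrative phenotyping results
============================================================
samples: 90   embedding stress: 0.2017
sources after merging: clinical+mRNA+miRNA
  merged: clinical + mRNA -> clinical+mRNA
  merged: clinical+mRNA + miRNA -> clinical+mRNA+miRNA
------------------------------------------------------------
clinical+mRNA+miRNA: K = 3  cluster sizes  1: 30, 2: 30, 3: 30

ARI vs truth: 1.0
```

All three sources are driven by the same latent partition, so the
workflow merges them pairwise (two merges for three sources) and the
pooled clustering recovers the planted subtypes exactly (adjusted Rand
index 1.0 against the simulated truth).  When the sources *disagree* —
two omics generated from independent partitions — no merge happens and
the remaining pair is reported with its cross-tabulation:

```
omics2   1   2   3
omics1
1        9   8  13
2       12   9   9
3        9  13   8
off-diagonal 52/90 (57.8%), ARI -0.004 -> heterogeneous
```

`results.plot_panel()` renders this comparison with the cluster-averaged
feature topology plots along both margins; `results.predict(new_dataset)`
labels a held-out cohort on the frozen embedding.

A thin CLI wraps the same machinery:

```bash
ipf simulate --mode homogeneous --seed 1 --out sim/
ipf run --data sim/omics1.tsv --data sim/omics2.tsv --out fit/
ipf compare fit/labels_omics1+omics2.tsv sim/true_labels.tsv
```

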