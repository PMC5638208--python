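# regulead

Regulon-based inference of drug-induced protein-activity changes from
perturbational gene-expression signatures.

## The problem

Most small molecules change the *activity* of their target proteins, not
their expression, so differential expression of the target gene itself is a
poor readout of compound action — and many high-value targets (transcription
factors above all) cannot be assayed biochemically at scale.  `regulead`
treats each regulatory protein's **regulon** — its set of direct and indirect
transcriptional targets, annotated with a signed **mode of regulation** (MoR)
and an interaction-confidence weight — as a multiplexed endogenous reporter:
if a compound inhibits a regulator, the regulator's activated targets fall
and its repressed targets rise in the perturbation signature.

The package is for computational biologists doing network-based drug
characterization: turning compound screens (CMAP/LINCS-style perturbational
profiling, or in-vivo pre/post-treatment contrasts) into differential
target-protein-activity (DTPA) matrices, scoring compound bioactivity and
network reliability, and prioritizing or validating candidate inhibitors.

## The statistic

A signature of per-gene differential statistics (signed z scale) is
rank-transformed into a signed quantile score and a magnitude quantile score

$$t_2(g) = \Phi^{-1}\!\left(\frac{r_g}{n+1}\right), \qquad
  t_1(g) = \Phi^{-1}\!\left(\frac12 + \frac{r'_g}{2(n+1)}\right),$$

where $r_g$ ranks the signed statistic and $r'_g$ its absolute value.  A
regulon's **3-tail enrichment score** is the weighted mean over its targets

$$\mathrm{ES} = \sum_i w_i\,\bigl[\,m_i\,t_2(i) + (1-|m_i|)\,t_1(i)\,\bigr],
  \qquad \textstyle\sum_i w_i = 1,$$

so confidently signed targets ($m_i = \pm 1$) contribute through the
two-tail score and sign-unknown targets ($m_i = 0$) through the one-tail
magnitude score.  ES is standardized into a **normalized enrichment score**
(NES, a z-score) either analytically ($\mathrm{ES}/\sqrt{\sum w_i^2}$) or —
recommended — against an empirical null of ES values recomputed on
random-sample-split null signatures, which also absorbs biological
between-replicate variability.  Activity matrices inferred from several
regulatory networks (ARACNE mutual-information regulons, STRING protein
links, ChEA TF target sets, gene-knock-down response sets) are integrated per
cell by the self-weighted average $\sum_k s_k|s_k| / \sum_k |s_k|$.

Downstream analytics include the **IRS** (interactome-reliability / compound
bioactivity score: the capped sum of $-\log_{10} p$ over FDR-significant
activity changes), weighted-KS gene-set enrichment with a permutation null,
modulator/target enrichment evaluation, symmetrized signature similarity,
gold-standard construction by correlating compound signatures with
gene-silencing signatures, and reciprocal enrichment validation.  A
synthetic-data module generates ground-truth networks and perturbation
cohorts so the whole pipeline is testable without external data.

## Worked example

```python
from regulead import (make_network, simulate_cohort, simulate_perturbation_experiment,
                      generate_null_set, infer_activity_matrix, irs_score,
                      recovery_metrics)

net = make_network(n_regulators=50, targets_per_regulator=30, n_genes=1500, seed=7)
cohort = simulate_cohort(net, n_samples=200, noise_sd=1.0, seed=8)
nulls = generate_null_set(cohort, n=300, group_size=10, seed=9)

perts = {"cmpd01": {"R01": -2.5},   # inhibits regulator R01
         "cmpd02": {"R02": 2.0},    # activates regulator R02
         "dmso_like": {}}           # inert control
expr, sigs, truth = simulate_perturbation_experiment(net, perts, n_reps=10,
                                                     noise_sd=1.0, seed=7)
matrix = infer_activity_matrix(list(sigs.values()), net, nulls=nulls)
print(matrix.nes.round(2).loc[["R01", "R02"]])
for c in matrix.perturbations:
    print(c, "IRS", round(irs_score(matrix.pvalue[c].dropna().to_numpy()), 1))
print(recovery_metrics(matrix, truth)["rank_of_true"])
```

prints

```
     cmpd01  cmpd02  dmso_like
R01   -3.65   -1.54      -0.13
R02   -0.31    4.43      -0.50
cmpd01 IRS 3.6
cmpd02 IRS 5.0
dmso_like IRS 0.0
{'cmpd01': {'R01': 1}, 'cmpd02': {'R02': 1}}
```

The inhibited regulator R01 gets the most negative NES under its compound
(and rank 1 by |NES|), the activated R02 the most positive; the inert
compound changes no protein activity significantly, so its bioactivity
(IRS) is 0.

The same pipeline is available from the shell:

```bash
regulead simulate --n-regulators 50 --targets-per-regulator 30 \
    --n-genes 1500 --n-perturbed 4 --seed 7 --out-dir run/
regulead infer --signatures run/signatures.tsv --regulons run/regulons.tsv \
    --out run/activity.tsv
regulead irs --activity run/activity.tsv --out run/irs.tsv
```

The sklearn-style estimator behind `infer_activity_matrix` is
`regulead.RegulonActivity` (fit on null signatures, `transform` to a
samples x regulators NES array); it composes with sklearn pipelines and
`clone`/`get_params`.

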