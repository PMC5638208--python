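# Methods

## Model and assumptions

`regulead` infers differential protein activity from the differential
expression of each regulator's transcriptional targets.  The underlying
assumption is purely enrichment-shaped: if a regulator's activity rises, its
positively regulated targets concentrate near the top of the perturbation
signature and its repressed targets near the bottom; targets whose direction
of regulation is unknown still concentrate at the extremes in magnitude.
Nothing about transcriptional kinetics, binding, or dosage is modelled; the
regulon is an empirical reporter panel.

A regulon carries, per target, a mode of regulation `mode` in [-1, 1]
(sign = activation/repression, magnitude = confidence in the sign, 0 =
unknown) and a non-negative confidence `weight`.  How these are populated
depends on the evidence source:

| source | targets | mode | weight |
|---|---|---|---|
| ARACNE adjacency | MI-supported edges | Spearman correlation of regulator vs target expression | MI, max-normalized per regulon |
| STRING-style links | partners with combined score > 0.7 (strict) | 0 | combined score (0-1000 scores auto-rescaled) |
| ChEA/GMT TF sets | union over records per TF | Spearman vs expression if given, else 0 | 1 |
| knock-down signatures | genes with \|z\| >= 3 in the silencing contrast, capped at 400 by \|z\| | -sign(z) | \|z\|, max-normalized |

Spearman correlation is the mode estimator because it is robust to monotone
nonlinearity; zero-variance genes get mode 0.  Weights are max-normalized
only where the raw quantity (MI, |z|) has no absolute scale; STRING scores
and ChEA's uniform weights are kept as-is.  Regulons with fewer than
`min_targets` (default 10) targets are dropped at construction, and cells
with fewer than `min_targets` targets present in a signature are *absent*
from activity matrices rather than zero — "untestable" and "no change" are
different statements.

## The 3-tail statistic and its calibration

Signatures live on a single internal currency: signed z (positive = up in
treatment), obtained from Welch t-tests via z = sign(diff) * Phi^-1(1 - p/2)
(capped at |z| = 12), from per-gene scaling, or from Stouffer combination
z* = sum(z_i)/sqrt(k).  The rank transform maps a signature to
t2 = Phi^-1(r/(n+1)) on signed ranks and t1 = Phi^-1(1/2 + r'/(2(n+1))) on
magnitude ranks (average ranks on ties); the enrichment score is the weighted
mean `ES = sum_i w_i [m_i t2_i + (1-|m_i|) t1_i]` with weights renormalized
to sum to 1 over the targets present.

Two calibrations produce NES:

- **analytic**: `NES = ES / sqrt(sum w_i^2)`, exact when the transformed
  scores are iid standard normal.  Two caveats, both documented rather than
  patched: (i) t1 has positive mean (~0.80), so regulons with many
  sign-unknown targets acquire a positive NES offset; (ii) replicate
  experiments with real (or simulated) between-sample biological
  variability violate the iid assumption — a regulator's latent activity
  varies between arms, which coherently shifts its whole regulon and
  inflates |NES| of unperturbed regulators.
- **empirical** (recommended): the regulon's ES is recomputed on a set of
  null signatures (random disjoint two-group splits of a baseline cohort,
  default 1000) and NES is the z-score of the observed ES against that
  per-regulon null.  Because the nulls are built from the same kind of
  contrast as the signatures, both caveats above cancel.  The p-value is the
  two-sided normal tail of the standardized score rather than the raw
  empirical rank: with 1000 nulls a rank p floors at 1e-3, too coarse for
  FDR across thousands of regulators.

Choosing the null split size close to the experiment's replicate count makes
the null carry the same replicate-level variability as the signatures.

The shadow-regulon (pleiotropy) correction is a simplified, conservative
stand-in for a full pleiotropy index: for each perturbation and each pair of
significant regulators sharing >= `overlap_min` (10) targets, each
regulator's NES is recomputed analytically on its unique targets; a
regulator whose unique-target NES loses significance while its partner's
persists (or, on ties, is at least as extreme — this is what makes two
identical regulons shrink symmetrically) is pulled toward the unique-target
value with weight `penalty/(penalty + n_shared)` (penalty = 20), clamped so
the sign never flips.  It only ever reduces |NES|.

Cross-network integration uses the self-weighted average
`s* = sum_k s_k |s_k| / sum_k |s_k|` over the networks where a cell exists
(0 if all contributions are 0), which keeps |s*| <= max_k |s_k| and lets
strong evidence dominate without letting one network veto another.

## Downstream analytics

- **BH-FDR** is the standard step-up procedure (statsmodels backend).
- **IRS** = sum of min(-log10 p, cap) over cells passing BH FDR < 0.05,
  cap = 20.  This is identical to the area under the significant-count curve
  N(t) = #{i: -log10 p_i >= t} integrated over t in [0, cap], which is why a
  degraded network or signature — fewer and weaker significant calls —
  lowers it monotonically.  `relative_irs` rescales a set of scores by their
  maximum for cross-network comparison.
- **KS enrichment** is the classical weighted running-sum ES (weight
  exponent 1 by default; exponent 0 gives the rank-only statistic invariant
  to monotone transforms).  The null redraws same-size random sets
  (gene-label permutation; signatures are single-column, so phenotype
  permutation does not exist here).  p is the one-sided permutation tail
  toward the top of the ranking with add-one smoothing, hence uniform under
  random sets and floored at 1/(n_perm+1); NES = Phi^-1(1 - p).  The probit
  form is deliberate: the weighted-KS ES null is strongly right-skewed for
  small sets, so a mean/sd z-score would leave maximally enriched sets below
  conventional z thresholds; the probit of the tail is an exact z-scale
  standardization under which NES > 1.96 and p < 0.025 coincide.  Its
  resolution saturates at Phi^-1(1 - 1/(n_perm+1)) (3.09 for 1000
  permutations) — raise n_perm if finer tail resolution is needed.
- **Modulator / target evaluation** ranks perturbations by a target's NES
  (ascending for inhibitors) or regulators by a perturbation's NES and tests
  the annotated set with the KS machinery; the same call applies unchanged
  to expression-based rankings for activity-vs-expression comparisons.
- **Signature similarity** scores each signature's top and bottom 5% feature
  sets on the other's ranking: `dis_ab = [ES(U_a on b) - ES(D_a on b)]/2`,
  `similarity = (dis_ab + dis_ba)/2`, symmetric and in [-1, 1]; distance for
  clustering is 1 - similarity.  Potency-profile similarity is Spearman rho
  over shared cell lines (>= 3).
- **Gold standard**: compounds are ranked per silenced gene by Pearson r of
  their signature to the silencing signature; the significant set keeps
  r > 0 with two-sided correlation-test p < 0.05 (t approximation, n-2 df).
  Only the positive tail can be called — inhibitor semantics — so random
  signatures yield ~p_cut/2 significant fraction.  **Reciprocal validation**
  ranks compounds by ascending inferred activity of the gene and tests the
  gold-standard set; a gene is recovered when enrichment NES > 1.96.  Note
  that a singleton gold-standard set cannot exceed that threshold under the
  permutation null (a one-hit KS ES is roughly uniform); genes need >= 2
  significant compounds to be meaningfully testable.

## Synthetic ground truth

The generator is linear-Gaussian, the simplest structure matching the
enrichment assumption — explicitly not a biological claim.  Per sample,
each regulator has latent activity a ~ N(0,1); a signed target responds as
`mode * weight * a`, a mode-0 target as `weight * (|a| - sqrt(2/pi))`
(centered magnitude coupling, so the one-tail component of the statistic
carries real signal), every gene gets N(0, noise_sd^2) noise, and regulator
genes express their own activity plus noise so correlation-based mode
recovery is testable.  Compound perturbations add a signed strength to the
named regulators' latent activities in the treated arm; each perturbation
gets its own control arm, and signatures are Welch contrasts.  Shadow
structure is available through paired regulators sharing a chosen fraction
of targets; all other regulons are disjoint, which makes planted-truth
bookkeeping exact.  Because the signature z is p-derived, unperturbed genes
are standard normal at any replicate count; more replicates raise the
perturbed targets' |z|, not lower the background's.

What the generator does *not* emulate: correlated technical noise, batch
effects, probe-level artifacts, regulon overlap patterns of real
transcriptional programs, or autoregulatory loops (the mechanism behind the
~10% direction flips seen on real data).  Passing benchmarks therefore
demonstrate the statistical machinery is correct and well calibrated under
its own assumptions, not that real-data performance follows.

## Benchmark designs and problem sizes

All benchmarks live in `regulead.benchmark`, keyed by a single seed; sizes
were chosen once as realistic-but-small study conditions.

- **Recovery**: 100 regulators x 50 targets (5000-gene pool), 10
  single-target compounds at strength +/-2, noise 1, 10 replicates per arm;
  analytic calibration on the true network.  Measured: mean AUROC of |NES|
  for perturbed-vs-unperturbed regulators (Mann-Whitney-equivalent) and sign
  agreement among detections, over 10 seeds.
- **Null calibration**: 50 x 20 network inside a 2000-gene iid Gaussian
  matrix (200 samples); 1000 calibration nulls, 4000 independent test draws
  (more test draws only sharpen the measurement — the binding precision is
  the 1000-null calibration error, whose per-regulon sd is ~0.032).
  Measured: per-regulon NES mean/sd and type-I error at |NES| > 1.96.
- **IRS vs randomization**: 10 compounds with graded strengths +/-(1..3) so
  the pooled IRS falls smoothly across rewiring fractions
  {0, .25, .5, .75, 1} instead of saturating at the -log10 p cap; rewiring
  is by double-edge swaps that preserve every in/out degree exactly, with
  attempt budget ceil(3 * fraction * |E|) and the realized rewired fraction
  reported.
- **Shuffle curve**: one compound perturbing 30 regulators with log-spaced
  strengths 0.3-4 (alternating signs), 20 replicates, so the FDR-significant
  count decays gradually and strictly over shuffle fractions {0..1}.
- **Reciprocal validation**: 50 x 30 network; 20 silenced genes x 3
  inhibiting compounds (strength -U(2,3)) plus 20 inert compounds; silencing
  assays at strength -3; the gold standard is rebuilt from signature
  correlations and compared against a size-matched randomized control.

## Numerical and interface choices

- Welch t (not a moderated/shrunken variance) keeps the pipeline
  self-contained; zero-variance-both-groups genes get 0 (equal means) or
  +/- z_cap = 12.
- Probe collapse keeps the probe with the largest MAD per gene,
  lexicographically smallest probe id on ties.
- Replicate reproducibility: a sample's score is its mean Pearson
  correlation to replicates; the background is its correlations to all
  non-replicate samples; keep iff z > 5.  Singleton groups are flagged
  unscorable rather than scored.
- Duplicate network edges keep the maximum MI (logged); self-loops are
  removed; all gene identifiers are opaque case-sensitive strings.
- Regulon TSV serialization uses 12 significant digits and is lossless at
  that precision; every CLI output carries a manifest reference (config
  echo, version, input checksums, seeds).
- All stochastic steps take explicit seeds; identical seeds give
  bit-identical outputs.

## Known limitations

- The analytic null is anti-conservative for regulons with sign-unknown
  targets and for replicate designs with biological variability; use
  empirical calibration for inference-grade p-values.
- The pleiotropy correction is a heuristic shadow filter, not a fitted
  pleiotropy model; with `penalty = 20` it is mild for heavily overlapping
  pairs.
- KS-enrichment NES resolution is bounded by the permutation count.
- The KD-regulon z >= 3 inclusion threshold and the reproducibility
  background definition are package choices where the upstream conventions
  are not standardized; both are exposed as parameters.
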