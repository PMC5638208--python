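"""Ground-truth generators for end-to-end pipeline benchmarks.

A linear-Gaussian generative model matching the regulon-enrichment
assumption: each regulator has a latent activity per sample; a target with a
signed mode responds linearly (mode * weight * activity), a target with
unknown mode (mode 0) responds through the centered magnitude of the
activity, so the one-tail component of the 3-tail statistic carries signal;
every gene gets iid Gaussian noise.  Regulator genes express their own
activity plus noise so that correlation-based mode recovery is testable.
Compound perturbations shift chosen regulators' latent activities by a signed
strength; signatures are Welch-t contrasts of treated vs control replicates.

None of this is a biological claim — it is the simplest structure under
which recovery, calibration and degradation benchmarks have known truth.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from ._utils import ValidationError
from .interactomes import Interactome, Regulon
from .signatures import ExpressionMatrix, GeneSignature, two_group_signature

__all__ = [
    "SyntheticTruth",
    "make_network",
    "simulate_cohort",
    "simulate_perturbation_experiment",
    "recovery_metrics",
]

_ABS_CENTER = math.sqrt(2.0 / math.pi)  # E|Z| for Z ~ N(0,1)


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated perturbation experiment."""

    interactome: Interactome
    latent_activities: pd.DataFrame  # samples x regulators
    perturbations: dict[str, dict[str, float]]
    noise_sd: float = 1.0
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = set(self.interactome.regulons)
        for pert, shifts in self.perturbations.items():
            unknown = set(shifts) - known
            if unknown:
                raise ValidationError(
                    f"perturbation {pert!r} names unknown regulators {sorted(unknown)}"
                )
            if not all(np.isfinite(list(shifts.values()) or [0.0])):
                raise ValidationError(f"perturbation {pert!r}: non-finite strength")


def make_network(
    n_regulators: int = 100,
    targets_per_regulator: int = 50,
    n_genes: int = 5000,
    overlap: float = 0.0,
    mode_mix: tuple[float, float, float] = (0.45, 0.35, 0.2),
    seed: int = 0,
    name: str = "synthetic",
) -> Interactome:
    """Sparse ground-truth network with signed modes and confidence weights.

    Regulators are paired as shadow partners; a fraction ``overlap`` of each
    partner's targets is shared within the pair, the rest are private and
    disjoint across the whole network.  Modes are drawn from ``mode_mix`` =
    (p_activating, p_repressing, p_unknown) with values +1 / -1 / 0; weights
    are Uniform(0.5, 1) max-normalized per regulon.
    """
    if not 0.0 <= overlap < 1.0:
        raise ValidationError("overlap must be in [0, 1)")
    if abs(sum(mode_mix) - 1.0) > 1e-9 or any(p < 0 for p in mode_mix):
        raise ValidationError("mode_mix must be non-negative and sum to 1")
    t = targets_per_regulator
    shared = int(round(overlap * t))
    n_pairs, leftover = divmod(n_regulators, 2)
    needed = n_pairs * (2 * t - shared) + leftover * t
    if needed > n_genes:
        raise ValidationError(
            f"infeasible: {n_regulators} regulons x {t} targets with overlap "
            f"{overlap} need {needed} distinct target genes, pool has {n_genes}"
        )
    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    pool = [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]
    pool = list(np.array(pool)[rng.permutation(n_genes)])
    rwidth = len(str(n_regulators))
    regulator_ids = [f"R{i:0{rwidth}d}" for i in range(1, n_regulators + 1)]

    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        out = pool[cursor: cursor + k]
        cursor += k
        return out

    assignments: dict[str, list[str]] = {}
    for p in range(n_pairs):
        common = take(shared)
        assignments[regulator_ids[2 * p]] = common + take(t - shared)
        assignments[regulator_ids[2 * p + 1]] = common + take(t - shared)
    if leftover:
        assignments[regulator_ids[-1]] = take(t)

    regulons: dict[str, Regulon] = {}
    for rid in regulator_ids:
        targets = assignments[rid]
        modes = rng.choice([1.0, -1.0, 0.0], size=t, p=list(mode_mix))
        weights = rng.uniform(0.5, 1.0, size=t)
        weights = weights / weights.max()
        table = pd.DataFrame({"mode": modes, "weight": weights},
                             index=pd.Index(targets, name="target"))
        regulons[rid] = Regulon(regulator=rid, table=table, source="synthetic")
    return Interactome(name=name, regulons=regulons, context="synthetic",
                       source="synthetic",
                       meta={"seed": seed, "overlap": overlap, "mode_mix": mode_mix})


def _gene_order(interactome: Interactome) -> tuple[list[str], list[str]]:
    regulators = list(interactome.regulons)
    targets = sorted({t for r in interactome.regulons.values() for t in r.table.index})
    return regulators, targets


def _expression_from_activities(
    interactome: Interactome,
    activities: pd.DataFrame,  # samples x regulators
    noise_sd: float,
    rng: np.random.Generator,
) -> ExpressionMatrix:
    regulators, targets = _gene_order(interactome)
    a = activities[regulators].to_numpy(float)  # samples x R
    tpos = {g: i for i, g in enumerate(targets)}
    w_signed = np.zeros((len(regulators), len(targets)))
    w_abs = np.zeros_like(w_signed)
    for ri, rid in enumerate(regulators):
        table = interactome.regulons[rid].table
        for tgt, mode, weight in zip(table.index, table["mode"], table["weight"]):
            if mode != 0:
                w_signed[ri, tpos[tgt]] += mode * weight
            else:
                w_abs[ri, tpos[tgt]] += weight
    x_targets = a @ w_signed + (np.abs(a) - _ABS_CENTER) @ w_abs
    x_regs = a.copy()
    x = np.concatenate([x_regs, x_targets], axis=1)  # samples x genes
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=x.shape)
    genes = regulators + targets
    data = pd.DataFrame(x.T, index=genes, columns=activities.index)
    return ExpressionMatrix(data=data)


def simulate_cohort(
    interactome: Interactome,
    n_samples: int = 200,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Baseline cohort driven by iid standard-normal latent activities."""
    if n_samples < 3:
        raise ValidationError("need >= 3 samples")
    rng = np.random.default_rng(seed)
    regulators = list(interactome.regulons)
    swidth = len(str(n_samples))
    samples = [f"S{i:0{swidth}d}" for i in range(1, n_samples + 1)]
    activities = pd.DataFrame(
        rng.standard_normal((n_samples, len(regulators))),
        index=samples, columns=regulators,
    )
    return _expression_from_activities(interactome, activities, noise_sd, rng)


def simulate_perturbation_experiment(
    interactome: Interactome,
    perturbations: Mapping[str, Mapping[str, float]],
    n_reps: int = 10,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, dict[str, GeneSignature], SyntheticTruth]:
    """Treated-vs-control perturbation profiling with known regulator shifts.

    Each perturbation gets its own control and treated arms of ``n_reps``
    samples; treated samples shift the named regulators' latent activities by
    the given signed strengths.  Signatures are Welch-t contrasts (treated vs
    control) on the signed z scale.  Returns the combined expression matrix
    with arm metadata, one signature per perturbation, and the recorded truth.
    """
    if n_reps < 2:
        raise ValidationError("need >= 2 replicates per arm")
    rng = np.random.default_rng(seed)
    regulators = list(interactome.regulons)
    pert_ids = sorted(perturbations)
    known = set(regulators)
    for pert in pert_ids:
        unknown = set(perturbations[pert]) - known
        if unknown:
            raise ValidationError(
                f"perturbation {pert!r} names unknown regulators {sorted(unknown)}")

    sample_ids: list[str] = []
    meta_rows = []
    blocks = []
    for pert in pert_ids:
        shifts = dict(perturbations[pert])
        base = rng.standard_normal((2 * n_reps, len(regulators)))
        a = pd.DataFrame(base, columns=regulators)
        for reg, strength in shifts.items():
            a.loc[: n_reps - 1, reg] += strength  # first n_reps rows treated
        ids = ([f"{pert}.t{i + 1}" for i in range(n_reps)]
               + [f"{pert}.c{i + 1}" for i in range(n_reps)])
        a.index = ids
        sample_ids.extend(ids)
        blocks.append(a)
        for i, sid in enumerate(ids):
            arm = "treated" if i < n_reps else "control"
            meta_rows.append((sid, pert, f"{pert}:{arm}", "plate1", arm))
    activities = pd.concat(blocks, axis=0)
    expr = _expression_from_activities(interactome, activities, noise_sd, rng)
    metadata = pd.DataFrame(
        meta_rows,
        columns=["sample", "perturbation", "replicate_group", "plate", "arm"],
    ).set_index("sample")
    expr = ExpressionMatrix(data=expr.data, metadata=metadata)

    signatures = {}
    for pert in pert_ids:
        treated = [s for s in sample_ids if s.startswith(f"{pert}.t")]
        control = [s for s in sample_ids if s.startswith(f"{pert}.c")]
        signatures[pert] = two_group_signature(expr.data, treated, control, label=pert)
    truth = SyntheticTruth(
        interactome=interactome,
        latent_activities=activities,
        perturbations={p: dict(perturbations[p]) for p in pert_ids},
        noise_sd=noise_sd,
        seed=seed,
        meta={"n_reps": n_reps},
    )
    return expr, signatures, truth


def recovery_metrics(
    activity,
    truth: SyntheticTruth,
    detect_cut: float = 1.96,
) -> dict:
    """How well an activity matrix recovers the planted perturbations.

    Per perturbation: AUROC of |NES| for perturbed-vs-unperturbed regulators
    (equivalent to the Mann-Whitney statistic).  Sign agreement is the
    fraction of detected perturbed regulators (|NES| >= ``detect_cut``,
    nonzero strength) whose NES sign matches the strength sign.
    ``rank_of_true`` gives, per perturbation, each perturbed regulator's rank
    by |NES| (1 = most extreme).
    """
    nes = activity.nes if hasattr(activity, "nes") else activity
    tested = set(nes.index)
    aurocs = {}
    rank_of_true: dict[str, dict[str, int]] = {}
    agree = detected = 0
    overlap_found = False
    for pert, shifts in truth.perturbations.items():
        if pert not in nes.columns:
            continue
        col = nes[pert].dropna()
        positives = set(shifts) & set(col.index)
        if positives:
            overlap_found = True
        if not positives or len(positives) == len(col):
            continue
        y = np.array([r in positives for r in col.index], dtype=int)
        aurocs[pert] = float(roc_auc_score(y, col.abs().to_numpy()))
        ranks = col.abs().rank(ascending=False, method="min")
        rank_of_true[pert] = {r: int(ranks[r]) for r in sorted(positives)}
        for reg, strength in shifts.items():
            if strength == 0 or reg not in col.index:
                continue
            if abs(col[reg]) >= detect_cut:
                detected += 1
                agree += int(np.sign(col[reg]) == np.sign(strength))
    if not overlap_found:
        raise ValidationError("no overlap between perturbed and inferred regulators")
    return {
        "auroc": float(np.mean(list(aurocs.values()))) if aurocs else float("nan"),
        "auroc_per_perturbation": aurocs,
        "sign_agreement": agree / detected if detected else float("nan"),
        "n_detected": detected,
        "rank_of_true": rank_of_true,
    }
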