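"""End-to-end synthetic benchmarks exercising the whole pipeline.

Each function builds its own ground truth, runs the inference path a user
would run, and measures a property with a known expected behaviour:
perturbation recovery (AUROC / sign agreement), empirical-null calibration
(per-regulon NES moments, pipeline type-I error), IRS decay under
degree-preserving network randomization, FDR-significant-count decay under
signature shuffling, and reciprocal gold-standard validation.  Problem sizes
are fixed here so that runs are reproducible from a single seed.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import child_seed
from .activity import RegulonActivity, infer_activity_matrix
from .interactomes import randomize_interactome
from .scoring import bh_fdr, build_gold_standard, irs_score, reciprocal_validation
from .signatures import (ExpressionMatrix, degrade_signature, generate_null_set,
                         signatures_to_frame)
from .synthetic import (SyntheticTruth, make_network, recovery_metrics,
                        simulate_perturbation_experiment)

__all__ = [
    "run_recovery",
    "run_irs_randomization",
    "run_shuffle_curve",
    "run_null_calibration",
    "run_reciprocal",
    "run_all",
]


def _single_target_perturbations(regulators, strengths) -> dict:
    return {f"cmpd{i + 1:02d}": {reg: float(s)}
            for i, (reg, s) in enumerate(zip(regulators, strengths))}


def run_recovery(
    seed: int,
    n_regulators: int = 100,
    targets_per_regulator: int = 50,
    n_genes: int = 5000,
    n_perturbed: int = 10,
    strength: float = 2.0,
    noise_sd: float = 1.0,
    n_reps: int = 10,
) -> dict:
    """Recovery benchmark: n_perturbed single-target compounds at +/-strength."""
    net = make_network(n_regulators, targets_per_regulator, n_genes,
                       seed=child_seed(seed, 1))
    rng = np.random.default_rng(child_seed(seed, 2))
    perturbed = list(rng.choice(net.regulators, size=n_perturbed, replace=False))
    strengths = [strength if i % 2 == 0 else -strength for i in range(n_perturbed)]
    perts = _single_target_perturbations(perturbed, strengths)
    _, sigs, truth = simulate_perturbation_experiment(
        net, perts, n_reps=n_reps, noise_sd=noise_sd, seed=child_seed(seed, 3))
    matrix = infer_activity_matrix(list(sigs.values()), net)
    metrics = recovery_metrics(matrix, truth)
    return {"auroc": metrics["auroc"],
            "sign_agreement": metrics["sign_agreement"],
            "n_detected": metrics["n_detected"],
            "n_perturbations": n_perturbed}


def run_irs_randomization(
    seed: int,
    fractions: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0),
    n_regulators: int = 100,
    targets_per_regulator: int = 50,
    n_genes: int = 5000,
    n_compounds: int = 10,
    noise_sd: float = 1.0,
    n_reps: int = 10,
) -> dict:
    """IRS as a function of degree-preserving network randomization.

    Compounds carry graded strengths (+/- 1..3) so that the pooled IRS
    degrades smoothly instead of saturating at the -log10 p cap.
    """
    net = make_network(n_regulators, targets_per_regulator, n_genes,
                       seed=child_seed(seed, 11))
    rng = np.random.default_rng(child_seed(seed, 12))
    perturbed = list(rng.choice(net.regulators, size=n_compounds, replace=False))
    magnitudes = np.linspace(1.0, 3.0, n_compounds)
    strengths = [m if i % 2 == 0 else -m for i, m in enumerate(magnitudes)]
    perts = _single_target_perturbations(perturbed, strengths)
    _, sigs, _ = simulate_perturbation_experiment(
        net, perts, n_reps=n_reps, noise_sd=noise_sd, seed=child_seed(seed, 13))
    signatures = list(sigs.values())
    irs = {}
    for i, frac in enumerate(fractions):
        degraded = randomize_interactome(net, frac, seed=child_seed(seed, 20 + i))
        matrix = infer_activity_matrix(signatures, degraded)
        pooled = matrix.pvalue.to_numpy().ravel()
        irs[frac] = irs_score(pooled[~np.isnan(pooled)])
    values = [irs[f] for f in fractions]
    rho = float(stats.spearmanr(list(fractions), values).statistic)
    return {"irs": irs, "spearman_rho": rho,
            "strictly_decreasing": all(a > b for a, b in zip(values, values[1:]))}


def run_shuffle_curve(
    seed: int,
    fractions: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
    n_regulators: int = 100,
    targets_per_regulator: int = 50,
    n_genes: int = 5000,
    n_perturbed: int = 30,
    noise_sd: float = 1.0,
    n_reps: int = 20,
    fdr_cut: float = 0.05,
) -> dict:
    """FDR-significant regulator count as signature shuffling increases.

    One broadly bioactive compound perturbs ``n_perturbed`` regulators with
    log-spaced strengths 0.3-4 (alternating signs), so the significant count
    falls gradually as larger shuffle fractions erase the signal.
    """
    net = make_network(n_regulators, targets_per_regulator, n_genes,
                       seed=child_seed(seed, 31))
    rng = np.random.default_rng(child_seed(seed, 32))
    perturbed = list(rng.choice(net.regulators, size=n_perturbed, replace=False))
    magnitudes = np.geomspace(0.3, 4.0, n_perturbed)
    shifts = {reg: (m if i % 2 == 0 else -m)
              for i, (reg, m) in enumerate(zip(perturbed, magnitudes))}
    _, sigs, _ = simulate_perturbation_experiment(
        net, {"compound": shifts}, n_reps=n_reps, noise_sd=noise_sd,
        seed=child_seed(seed, 33))
    signature = sigs["compound"]
    counts = {}
    for i, frac in enumerate(fractions):
        noisy = degrade_signature(signature, "shuffle_fraction", frac,
                                  seed=child_seed(seed, 40 + i))
        matrix = infer_activity_matrix([noisy], net)
        p = matrix.pvalue.iloc[:, 0].dropna()
        counts[frac] = int((bh_fdr(p.to_numpy()) < fdr_cut).sum())
    values = [counts[f] for f in fractions]
    rho = float(stats.spearmanr(list(fractions), values).statistic)
    return {"counts": counts, "spearman_rho": rho,
            "strictly_decreasing": all(a > b for a, b in zip(values, values[1:]))}


def run_null_calibration(
    seed: int,
    n_genes: int = 2000,
    n_samples: int = 200,
    n_regulators: int = 50,
    targets_per_regulator: int = 20,
    n_nulls: int = 1000,
    n_test: int = 4000,
    group_size: int = 100,
) -> dict:
    """Empirical-null calibration on pure-noise signatures.

    Null and test signatures are random two-group contrasts of an iid
    Gaussian expression matrix; empirical calibration should leave per-regulon
    NES with mean ~0, sd ~1 and a pipeline type-I error of ~0.05 at
    |NES| > 1.96.
    """
    net = make_network(n_regulators, targets_per_regulator,
                       n_genes=n_regulators * targets_per_regulator,
                       seed=child_seed(seed, 51))
    universe = sorted(net.gene_universe)
    filler = [f"F{i:05d}" for i in range(1, max(0, n_genes - len(universe)) + 1)]
    genes = universe + filler
    rng = np.random.default_rng(child_seed(seed, 52))
    matrix = ExpressionMatrix(data=pd.DataFrame(
        rng.standard_normal((len(genes), n_samples)),
        index=genes,
        columns=[f"S{i:04d}" for i in range(1, n_samples + 1)],
    ))
    nulls = generate_null_set(matrix, n=n_nulls, group_size=group_size,
                              seed=child_seed(seed, 53))
    tests = generate_null_set(matrix, n=n_test, group_size=group_size,
                              seed=child_seed(seed, 54))
    est = RegulonActivity(interactome=net, calibration="empirical")
    est.fit(nulls.to_frame().T)
    nes = est.transform(signatures_to_frame(tests.signatures).T)  # test x regulators
    per_mean = nes.mean(axis=0)
    per_sd = nes.std(axis=0, ddof=1)
    type1 = float(np.mean(np.abs(nes) > 1.96))
    return {
        "nes_mean": per_mean,
        "nes_sd": per_sd,
        "nes_mean_absmax": float(np.abs(per_mean).max()),
        "nes_sd_min": float(per_sd.min()),
        "nes_sd_max": float(per_sd.max()),
        "type1_error": type1,
        "n_regulators": len(est.regulators_),
        "n_test": n_test,
    }


def run_reciprocal(
    seed: int,
    n_regulators: int = 50,
    targets_per_regulator: int = 30,
    n_target_genes: int = 20,
    compounds_per_gene: int = 3,
    n_inert: int = 20,
    noise_sd: float = 1.0,
    n_reps: int = 10,
    n_perm: int = 1000,
) -> dict:
    """End-to-end reciprocal validation on compound / silencing pairs.

    ``n_target_genes`` regulators each get ``compounds_per_gene`` inhibiting
    compounds plus one silencing assay; ``n_inert`` compounds do nothing.  The
    gold standard is rebuilt from signature correlations and checked by
    reciprocal enrichment against the inferred activity matrix; a
    randomized gold standard gives the null recovery rate.
    """
    net = make_network(n_regulators, targets_per_regulator,
                       n_genes=n_regulators * targets_per_regulator,
                       seed=child_seed(seed, 61))
    rng = np.random.default_rng(child_seed(seed, 62))
    genes = list(rng.choice(net.regulators, size=n_target_genes, replace=False))

    compound_perts: dict[str, dict[str, float]] = {}
    for gi, gene in enumerate(genes):
        for c in range(compounds_per_gene):
            compound_perts[f"cmpd_{gene}_{c + 1}"] = {
                gene: -float(rng.uniform(2.0, 3.0))}
    for i in range(n_inert):
        compound_perts[f"inert{i + 1:02d}"] = {}
    _, compound_sigs, truth = simulate_perturbation_experiment(
        net, compound_perts, n_reps=n_reps, noise_sd=noise_sd,
        seed=child_seed(seed, 63))

    silencing_perts = {f"sh_{g}": {g: -3.0} for g in genes}
    _, silencing_raw, _ = simulate_perturbation_experiment(
        net, silencing_perts, n_reps=n_reps, noise_sd=noise_sd,
        seed=child_seed(seed, 64))
    silencing_sigs = {g: silencing_raw[f"sh_{g}"] for g in genes}

    gsd = build_gold_standard(compound_sigs, silencing_sigs)
    matrix = infer_activity_matrix(list(compound_sigs.values()), net)
    _, summary = reciprocal_validation(matrix, gsd, n_perm=n_perm,
                                       seed=child_seed(seed, 65))

    # null: same-size random compound sets per gene
    null_tables = {}
    all_compounds = sorted(compound_perts)
    for gene in genes:
        k = max(1, len(gsd.significant(gene)))
        chosen = set(rng.choice(all_compounds, size=k, replace=False))
        frame = gsd.tables[gene].copy()
        frame["significant"] = [c in chosen for c in frame.index]
        null_tables[gene] = frame
    null_gsd = type(gsd)(tables=null_tables, p_cut=gsd.p_cut)
    _, null_summary = reciprocal_validation(matrix, null_gsd, n_perm=n_perm,
                                            seed=child_seed(seed, 66))
    return {
        "recovered_fraction": summary["fraction"],
        "testable": summary["testable"],
        "null_recovered_fraction": null_summary["fraction"],
        "null_testable": null_summary["testable"],
    }


def run_all(seed: int, n_seeds: int = 10) -> dict:
    """Full benchmark suite; multi-seed metrics average over ``n_seeds``."""
    rec = [run_recovery(child_seed(seed, 100 + i)) for i in range(n_seeds)]
    irs = [run_irs_randomization(child_seed(seed, 200 + i)) for i in range(n_seeds)]
    shuffle = run_shuffle_curve(child_seed(seed, 300))
    calib = run_null_calibration(child_seed(seed, 400))
    recip = run_reciprocal(child_seed(seed, 500))
    return {
        "recovery_auroc": float(np.mean([r["auroc"] for r in rec])),
        "recovery_sign_agreement": float(np.mean([r["sign_agreement"] for r in rec])),
        "irs_randomization_spearman": float(np.mean([r["spearman_rho"] for r in irs])),
        "irs_decreasing_seed_fraction": float(np.mean(
            [r["strictly_decreasing"] for r in irs])),
        "shuffle_count_spearman": shuffle["spearman_rho"],
        "shuffle_counts": shuffle["counts"],
        "type1_error": calib["type1_error"],
        "nes_mean_absmax": calib["nes_mean_absmax"],
        "nes_sd_min": calib["nes_sd_min"],
        "nes_sd_max": calib["nes_sd_max"],
        "reciprocal_recovered_fraction": recip["recovered_fraction"],
        "reciprocal_null_fraction": recip["null_recovered_fraction"],
        "n_seeds": n_seeds,
    }
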