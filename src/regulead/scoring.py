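"""Downstream analytics over activity matrices and signatures.

Covers multiple-testing control (Benjamini-Hochberg), the interactome
reliability / compound bioactivity score (IRS), classical weighted
Kolmogorov-Smirnov gene-set enrichment with a gene-label permutation null,
modulator/target enrichment evaluation (DTPA vs DTGE style), symmetrized
signature similarity from mutual top/bottom-set enrichment, gold-standard
construction by correlating compound signatures with gene-silencing
signatures, and reciprocal enrichment validation of inferred inhibitors.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._utils import ValidationError, logger
from .signatures import GeneSignature

__all__ = [
    "EnrichmentResult",
    "GoldStandard",
    "bh_fdr",
    "irs_score",
    "relative_irs",
    "gene_set_es",
    "ks_gsea",
    "evaluate_modulators",
    "evaluate_targets",
    "drug_signature_similarity",
    "sensitivity_correlation",
    "build_gold_standard",
    "reciprocal_validation",
    "top_pair_overlap",
]


@dataclass
class EnrichmentResult:
    """KS enrichment of a set in a ranking, with a permutation null."""

    es: float
    nes: float
    p: float
    leading_edge: list[str] = field(default_factory=list)
    n_permutations: int = 0
    seed: int = 0


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-equivariant, monotone in p)."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def irs_score(
    pvalues: Sequence[float],
    fdr_cut: float = 0.05,
    cap: float = 20.0,
) -> float:
    """Interactome Reliability Score: aggregate significance of inferred cells.

    Restricting to cells passing BH FDR < ``fdr_cut``, IRS is the sum of
    min(-log10 p, cap) — equivalently the area under the significant-count
    curve N(t) = #{i : -log10 p_i >= t} integrated over t in [0, cap].  Used
    both as a network-quality and a compound-bioactivity metric: degraded
    networks or signatures yield fewer significant protein-activity changes
    and hence lower IRS.
    """
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return 0.0
    q = bh_fdr(p)
    passing = p[q < fdr_cut]
    if passing.size == 0:
        return 0.0
    return float(np.sum(np.minimum(-np.log10(passing), cap)))


def relative_irs(scores: Mapping[str, float]) -> dict[str, float]:
    """IRS in relative units: each score divided by the largest score."""
    top = max(scores.values())
    if top <= 0:
        return {k: 0.0 for k in scores}
    return {k: v / top for k, v in scores.items()}


# ---------------------------------------------------------------------------
# Weighted-KS gene-set enrichment
# ---------------------------------------------------------------------------

def _es_from_positions(pos: np.ndarray, weights: np.ndarray, n: int
                       ) -> tuple[float, int]:
    """Signed maximum deviation of the weighted KS running sum.

    ``pos`` are sorted 0-based hit positions in a ranking of length ``n``;
    ``weights`` are the hit increments (already |v|^exponent at those
    positions).  Returns (ES, peak position).
    """
    k = len(pos)
    if k == n:
        return 0.0, 0
    total = weights.sum()
    hit = np.cumsum(weights) / (total if total > 0 else 1.0)
    if total == 0:  # all-zero statistics in the set: uniform increments
        hit = np.arange(1, k + 1) / k
    miss_after = (pos + 1 - np.arange(1, k + 1)) / (n - k)
    miss_before = (pos - np.arange(k)) / (n - k)
    d_pos = hit - miss_after
    d_neg = np.concatenate(([0.0], hit[:-1])) - miss_before
    i_pos = int(np.argmax(d_pos))
    i_neg = int(np.argmin(d_neg))
    if d_pos[i_pos] >= -d_neg[i_neg]:
        return float(d_pos[i_pos]), i_pos
    return float(d_neg[i_neg]), i_neg


def _ranked_series(ranked) -> pd.Series:
    values = ranked.values if isinstance(ranked, GeneSignature) else pd.Series(ranked)
    order = sorted(values.index, key=lambda g: (-values[g], str(g)))
    return values.loc[order]


def gene_set_es(
    gene_set: set,
    ranked,
    weight_exponent: float = 1.0,
) -> float:
    """Raw weighted-KS enrichment score of a gene set in a ranking.

    ``ranked`` is a :class:`GeneSignature` or Series; genes are sorted by
    descending value (ties broken by id for determinism).  Positive ES means
    the set concentrates at the top of the ranking.
    """
    series = _ranked_series(ranked)
    n = len(series)
    members = np.fromiter((g in gene_set for g in series.index), bool, count=n)
    pos = np.where(members)[0]
    if pos.size == 0:
        raise ValidationError("gene set has empty intersection with the ranking")
    weights = np.abs(series.to_numpy(float)[pos]) ** weight_exponent
    es, _ = _es_from_positions(pos, weights, n)
    return es


def ks_gsea(
    gene_set: set,
    ranked,
    weight_exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Weighted-KS enrichment with a same-size random-set permutation null.

    ES is the signed maximum deviation of the classical running sum; the null
    redraws the set positions uniformly (gene-label permutation — signatures
    here are single-column, so phenotype permutation is unavailable).  p is
    the one-sided permutation tail toward the top of the ranking,
    (1 + #{null >= es}) / (n_perm + 1), uniform under random sets and floored
    at 1/(n_perm + 1).  NES is the probit of that tail, Phi^-1(1 - p): a
    z-scale standardization against the null under which NES > 1.96
    corresponds to p < 0.025 (the weighted-KS ES itself is too skewed for a
    mean/sd z-score to carry normal-tail semantics).  NES saturates at
    +/- Phi^-1(1 - 1/(n_perm + 1)) by construction.
    """
    series = _ranked_series(ranked)
    n = len(series)
    if float(series.iloc[0]) == float(series.iloc[-1]):
        raise ValidationError("ranking statistic is constant")
    members = np.fromiter((g in gene_set for g in series.index), bool, count=n)
    pos = np.where(members)[0]
    k = pos.size
    if k == 0:
        raise ValidationError("gene set has empty intersection with the ranking")
    absv = np.abs(series.to_numpy(float)) ** weight_exponent
    es, peak = _es_from_positions(pos, absv[pos], n)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        rpos = np.sort(rng.choice(n, size=k, replace=False))
        null[i], _ = _es_from_positions(rpos, absv[rpos], n)
    p = (1 + int(np.sum(null >= es))) / (n_perm + 1)
    nes = float(stats.norm.isf(np.clip(p, 1 / (n_perm + 1), n_perm / (n_perm + 1))))

    if es >= 0:
        leading = [g for g, hit in zip(series.index[: peak + 1], members[: peak + 1]) if hit]
    else:
        leading = [g for g, hit in zip(series.index[pos[peak]:], members[pos[peak]:]) if hit]
    return EnrichmentResult(es=float(es), nes=float(nes), p=float(p),
                            leading_edge=leading, n_permutations=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# Modulator / target evaluation
# ---------------------------------------------------------------------------

def _nes_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, pd.DataFrame):
        return matrix
    return matrix.nes


def evaluate_modulators(
    matrix,
    target: str,
    known_modulators: set,
    direction: str = "inhibitor",
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Are known modulators enriched among extreme inferred-activity compounds?

    Ranks all perturbations by the target's NES (ascending for inhibitors, so
    the strongest predicted inhibitors sit at the top of the ranking) and runs
    :func:`ks_gsea` of the modulator set on that ranking.  The same machinery
    applies unchanged to expression-based rankings for DTGE comparison.
    """
    nes = _nes_frame(matrix)
    if target not in nes.index:
        raise ValidationError(f"target {target!r} not tested in the matrix")
    if direction not in ("inhibitor", "activator"):
        raise ValidationError(f"unknown direction {direction!r}")
    row = nes.loc[target].dropna()
    present = known_modulators & set(row.index)
    if not present:
        raise ValidationError("no known modulator among tested perturbations")
    ranking = -row if direction == "inhibitor" else row
    return ks_gsea(present, ranking, n_perm=n_perm, seed=seed)


def evaluate_targets(
    matrix,
    perturbation: str,
    known_targets: set,
    direction: str = "inhibitor",
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Mirror image of :func:`evaluate_modulators` along the regulator axis."""
    nes = _nes_frame(matrix)
    if perturbation not in nes.columns:
        raise ValidationError(f"perturbation {perturbation!r} not in the matrix")
    if direction not in ("inhibitor", "activator"):
        raise ValidationError(f"unknown direction {direction!r}")
    col = nes[perturbation].dropna()
    present = known_targets & set(col.index)
    if not present:
        raise ValidationError("no known target among tested regulators")
    ranking = -col if direction == "inhibitor" else col
    return ks_gsea(present, ranking, n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# Signature similarity / distance
# ---------------------------------------------------------------------------

def drug_signature_similarity(
    a,
    b,
    top_frac: float = 0.05,
    weight_exponent: float = 1.0,
) -> tuple[float, float, float]:
    """Symmetrized mutual top/bottom-set enrichment between two signatures.

    Takes the ``top_frac`` most up- and down-regulated features of each
    signature and scores their KS enrichment on the other's ranking:
    dis_ab = [ES(U_a on b) - ES(D_a on b)] / 2, similarity = (dis_ab +
    dis_ba) / 2, in [-1, 1]; distance for clustering is 1 - similarity.
    Symmetric by construction.
    """
    sa = a.values if isinstance(a, GeneSignature) else pd.Series(a)
    sb = b.values if isinstance(b, GeneSignature) else pd.Series(b)
    shared = sa.index.intersection(sb.index)
    if len(shared) < 100:
        raise ValidationError("signatures share fewer than 100 features")
    if not 0 < top_frac <= 0.25:
        raise ValidationError("top_frac must be in (0, 0.25]")
    sa, sb = sa.loc[shared], sb.loc[shared]
    if sa.nunique() == 1 or sb.nunique() == 1:
        raise ValidationError("constant signature")
    k = max(1, int(round(top_frac * len(shared))))

    def dis(x: pd.Series, y: pd.Series) -> float:
        order = sorted(x.index, key=lambda g: (-x[g], str(g)))
        up = set(order[:k])
        down = set(order[-k:])
        return (gene_set_es(up, y, weight_exponent)
                - gene_set_es(down, y, weight_exponent)) / 2.0

    dis_ab = dis(sa, sb)
    dis_ba = dis(sb, sa)
    return (dis_ab + dis_ba) / 2.0, dis_ab, dis_ba


def sensitivity_correlation(a: pd.Series, b: pd.Series) -> float:
    """Spearman rho of two potency profiles over shared cell lines (>= 3)."""
    shared = a.dropna().index.intersection(b.dropna().index)
    if len(shared) < 3:
        raise ValidationError("fewer than 3 shared cell lines")
    rho, _ = stats.spearmanr(a.loc[shared], b.loc[shared])
    return float(rho)


# ---------------------------------------------------------------------------
# Gold standard and reciprocal validation
# ---------------------------------------------------------------------------

@dataclass
class GoldStandard:
    """Per target gene: compounds ranked by correlation to its silencing
    signature, with one-sided (positive-tail) correlation p-values."""

    tables: dict[str, pd.DataFrame]  # gene -> frame indexed by compound: r, p, significant
    p_cut: float = 0.05

    @property
    def genes(self) -> list[str]:
        return list(self.tables)

    def significant(self, gene: str) -> set:
        t = self.tables[gene]
        return set(t.index[t["significant"]])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gene, t in self.tables.items():
            for rank, (compound, row) in enumerate(t.iterrows(), start=1):
                rows.append((gene, compound, rank, row["r"], row["p"],
                             bool(row["significant"])))
        return pd.DataFrame(rows, columns=["gene", "compound", "rank", "r", "p",
                                           "significant"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")


def build_gold_standard(
    compound_sigs: Mapping[str, GeneSignature],
    silencing_sigs: Mapping[str, GeneSignature],
    p_cut: float = 0.05,
) -> GoldStandard:
    """Match compounds to silenced genes by Pearson correlation of signatures.

    Per silenced gene, compounds are ranked by descending Pearson r of their
    signature with the silencing signature; the significant set keeps
    compounds with r > 0 and two-sided correlation-test p < ``p_cut``, so
    only the positive tail can be called (inhibitor semantics: a compound
    mimicking the silencing profile inhibits the gene) and random signatures
    yield a significant fraction of about p_cut / 2.  Zero-variance
    signatures are excluded with a warning.
    """
    def usable(sigs: Mapping[str, GeneSignature]) -> dict[str, pd.Series]:
        out = {}
        for name in sorted(sigs):
            v = sigs[name].values
            if v.std() == 0:
                logger.warning("signature %r has zero variance, excluded", name)
                continue
            out[name] = v
        return out

    compounds = usable(compound_sigs)
    silencings = usable(silencing_sigs)
    if not compounds or not silencings:
        raise ValidationError("no usable signatures")
    universe = None
    for v in list(compounds.values()) + list(silencings.values()):
        universe = v.index if universe is None else universe.intersection(v.index)
    if len(universe) < 3:
        raise ValidationError("shared gene universe too small")
    c_mat = np.column_stack([compounds[c].loc[universe] for c in compounds])
    s_mat = np.column_stack([silencings[g].loc[universe] for g in silencings])

    def standardize(m: np.ndarray) -> np.ndarray:
        m = m - m.mean(axis=0)
        return m / np.sqrt((m**2).sum(axis=0))

    n = len(universe)
    r = standardize(c_mat).T @ standardize(s_mat)  # compounds x genes
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)  # two-sided; r > 0 filter below
    tables = {}
    c_names = list(compounds)
    for j, gene in enumerate(silencings):
        frame = pd.DataFrame({"r": r[:, j], "p": p[:, j]}, index=c_names)
        frame["significant"] = (frame["r"] > 0) & (frame["p"] < p_cut)
        frame = frame.loc[sorted(c_names, key=lambda c: (-frame.at[c, "r"], c))]
        tables[gene] = frame
    return GoldStandard(tables=tables, p_cut=p_cut)


def reciprocal_validation(
    matrix,
    gsd: GoldStandard,
    nes_cut: float = 1.96,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Reciprocal enrichment of gold-standard inhibitors in inferred rankings.

    Per gold-standard gene present among the matrix regulators, compounds are
    ranked by ascending inferred activity change of that gene (strongest
    predicted inhibitor first) and the gene's significant gold-standard
    compound set is tested by :func:`ks_gsea`; the gene counts as recovered
    iff enrichment NES > ``nes_cut``.  Genes with an empty significant set are
    untestable.  Returns (per-gene frame, summary counts).
    """
    nes = _nes_frame(matrix)
    testable_genes = [g for g in gsd.genes if g in nes.index]
    if not testable_genes:
        raise ValidationError("no overlap between gold-standard genes and regulators")
    rows = []
    recovered = testable = untestable = 0
    for i, gene in enumerate(testable_genes):
        sig_set = gsd.significant(gene)
        row = nes.loc[gene].dropna()
        sig_set &= set(row.index)
        if not sig_set:
            untestable += 1
            continue
        res = ks_gsea(sig_set, -row, n_perm=n_perm,
                      seed=(seed + 1009 * i) % (2**31 - 1))
        hit = res.nes > nes_cut
        testable += 1
        recovered += int(hit)
        rows.append((gene, len(sig_set), res.es, res.nes, res.p, hit))
    per_gene = pd.DataFrame(rows, columns=["gene", "n_significant", "es", "nes",
                                           "p", "recovered"])
    summary = {
        "recovered": recovered,
        "testable": testable,
        "untestable": untestable,
        "fraction": recovered / testable if testable else float("nan"),
    }
    return per_gene, summary


def top_pair_overlap(
    scores_a: pd.Series,
    scores_b: pd.Series,
    top_frac: float = 0.025,
) -> dict:
    """Fisher's exact test of top-fraction overlap between two pair rankings.

    Thin utility over a 2x2 contingency test: both Series are indexed by the
    same items (e.g. compound pairs); membership in each top ``top_frac`` set
    forms the table.
    """
    shared = scores_a.index.intersection(scores_b.index)
    if len(shared) < 4:
        raise ValidationError("need >= 4 shared items")
    k = max(1, int(round(top_frac * len(shared))))
    top_a = set(scores_a.loc[shared].nlargest(k).index)
    top_b = set(scores_b.loc[shared].nlargest(k).index)
    both = len(top_a & top_b)
    table = [[both, len(top_a) - both],
             [len(top_b) - both, len(shared) - len(top_a) - len(top_b) + both]]
    odds, p = stats.fisher_exact(table, alternative="greater")
    return {"overlap": both, "top_n": k, "odds_ratio": float(odds), "p": float(p)}
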