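"""Three-tail weighted regulon enrichment and protein-activity inference.

The core statistic: a gene-expression signature is rank-transformed into a
signed quantile score t2 = Phi^-1(r / (n+1)) (r = rank of the signed
statistic) and a magnitude quantile score t1 = Phi^-1(0.5 + r' / (2(n+1)))
(r' = rank of the absolute statistic).  A regulon's enrichment score is the
weighted mean over its targets present in the signature,

    ES = sum_i w_i * [ mode_i * t2_i + (1 - |mode_i|) * t1_i ],

with weights renormalized to sum to 1, so that targets with a confident sign
contribute through the two-tail score and sign-unknown targets through the
one-tail magnitude score.  ES is calibrated into a normalized enrichment
score (NES, z-scale) either analytically (ES / sqrt(sum w_i^2), exact when
transformed scores are iid standard normal) or against an empirical null of
ES values recomputed on random-split null signatures, which is the
recommended path for inference.

The estimator :class:`RegulonActivity` packages this as a sklearn-style
transformer: ``fit`` aligns the regulons with the gene universe (and, for
empirical calibration, learns per-regulon null ES moments from the null
signatures passed as X); ``transform`` maps a samples x genes matrix of
signatures to a samples x regulators matrix of NES.  ``infer`` returns the
full :class:`ActivityMatrix` (ES, NES, p, target counts) and optionally
applies the shadow-regulon (pleiotropy) correction.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from ._utils import ValidationError, logger
from .interactomes import Interactome
from .signatures import GeneSignature, NullSignatureSet, signatures_to_frame

__all__ = [
    "TransformedSignature",
    "ActivityMatrix",
    "IntegratedActivityMatrix",
    "RegulonActivity",
    "rank_transform",
    "regulon_es",
    "nes_analytic",
    "nes_empirical",
    "pleiotropy_adjust",
    "infer_activity_matrix",
    "integrate_networks",
]


@dataclass
class TransformedSignature:
    """Signed (t2) and magnitude (t1) quantile scores of one signature."""

    t2: pd.Series
    t1: pd.Series
    label: str = ""


def _transform_columns(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized rank transform of a genes x signatures array."""
    n = values.shape[0]
    r2 = stats.rankdata(values, axis=0, method="average")
    t2 = stats.norm.ppf(r2 / (n + 1))
    r1 = stats.rankdata(np.abs(values), axis=0, method="average")
    t1 = stats.norm.ppf(0.5 + r1 / (2 * (n + 1)))
    return t2, t1


def rank_transform(signature: GeneSignature) -> TransformedSignature:
    """Probit rank transform of a signature into (t2, t1) scores.

    Monotone: a larger statistic gives a larger t2 and a larger absolute
    statistic a larger t1; ties take average ranks.  An all-equal signature is
    rank-degenerate and rejected.
    """
    v = signature.values.to_numpy(float)
    if len(v) < 100:
        logger.warning("signature %r has %d genes; rank scores are coarse below 100",
                       signature.label, len(v))
    if np.min(v) == np.max(v):
        raise ValidationError(f"signature {signature.label!r} is constant; "
                              "ranks are degenerate")
    t2, t1 = _transform_columns(v[:, None])
    idx = signature.values.index
    return TransformedSignature(t2=pd.Series(t2[:, 0], index=idx),
                                t1=pd.Series(t1[:, 0], index=idx),
                                label=signature.label)


def regulon_es(
    transformed: TransformedSignature,
    regulon,
    min_targets: int = 10,
) -> tuple[float, int]:
    """Weighted 3-tail enrichment score of one regulon in one signature.

    Weights are renormalized to sum to 1 over the targets present in the
    signature, making ES a weighted mean.  Raises when fewer than
    ``min_targets`` targets are present (the cell is untestable, not zero).
    """
    table = regulon.table
    present = table.index.intersection(transformed.t2.index)
    if len(present) < min_targets:
        raise ValidationError(
            f"regulon {regulon.regulator!r}: only {len(present)} targets in "
            f"signature (< {min_targets})"
        )
    sub = table.loc[present]
    w = sub["weight"].to_numpy(float)
    if w.sum() <= 0:
        raise ValidationError(f"regulon {regulon.regulator!r}: zero total weight")
    w = w / w.sum()
    m = sub["mode"].to_numpy(float)
    t2 = transformed.t2.loc[present].to_numpy(float)
    t1 = transformed.t1.loc[present].to_numpy(float)
    es = float(np.sum(w * (m * t2 + (1.0 - np.abs(m)) * t1)))
    return es, int(len(present))


def nes_analytic(es: float, weights: np.ndarray) -> tuple[float, float]:
    """Analytic calibration: NES = ES / sqrt(sum w_i^2), two-sided normal p.

    Exact under the null that the transformed target scores are iid standard
    normal; for regulons with many sign-unknown targets the magnitude score's
    positive mean makes this anti-conservative — prefer the empirical null.
    """
    w = np.asarray(weights, float)
    if np.any(w < 0) or not np.isclose(w.sum(), 1.0, atol=1e-8):
        raise ValidationError("weights must be non-negative and sum to 1")
    nes = es / np.sqrt(np.sum(w**2))
    p = 2.0 * stats.norm.sf(abs(nes))
    return float(nes), float(max(p, np.nextafter(0, 1)))


def nes_empirical(
    es: float,
    regulon,
    transformed_nulls: Sequence[TransformedSignature] | NullSignatureSet,
    min_targets: int = 10,
) -> tuple[float, float]:
    """Empirical calibration against a null-signature set.

    The regulon's ES is recomputed on every null signature; NES is the
    z-score of the observed ES against that null distribution, with a
    two-sided normal-tail p (the normal approximation on the standardized
    score avoids the 1/n_null p-value floor of raw empirical ranks).
    """
    if isinstance(transformed_nulls, NullSignatureSet):
        transformed_nulls = [rank_transform(s) for s in transformed_nulls.signatures]
    if len(transformed_nulls) < 100:
        logger.warning("only %d null signatures; >= 100 recommended",
                       len(transformed_nulls))
    null_es = np.array(
        [regulon_es(t, regulon, min_targets=min_targets)[0] for t in transformed_nulls]
    )
    sd = null_es.std(ddof=1)
    if sd == 0:
        raise ValidationError("null ES distribution has zero variance")
    nes = (es - null_es.mean()) / sd
    p = 2.0 * stats.norm.sf(abs(nes))
    return float(nes), float(max(p, np.nextafter(0, 1)))


@dataclass
class ActivityMatrix:
    """Regulators x perturbations grid of (ES, NES, p) from one interactome."""

    es: pd.DataFrame
    nes: pd.DataFrame
    pvalue: pd.DataFrame
    n_targets: pd.Series
    network: str = ""
    context: str = ""

    @property
    def regulators(self) -> list[str]:
        return list(self.nes.index)

    @property
    def perturbations(self) -> list[str]:
        return list(self.nes.columns)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for reg in self.nes.index:
            for pert in self.nes.columns:
                nes = self.nes.at[reg, pert]
                if pd.isna(nes):
                    continue
                rows.append((reg, pert, self.network, self.es.at[reg, pert], nes,
                             self.pvalue.at[reg, pert], int(self.n_targets[reg])))
        return pd.DataFrame(rows, columns=["regulator", "perturbation", "network",
                                           "es", "nes", "p", "n_targets"])

    def write_long(self, path: str | Path) -> None:
        self.to_long().to_csv(path, sep="\t", index=False, float_format="%.12g")

    def write_nes(self, path: str | Path) -> None:
        self.nes.to_csv(path, sep="\t", index_label="regulator",
                        float_format="%.12g")

    @classmethod
    def read_long(cls, path: str | Path) -> "ActivityMatrix":
        frame = pd.read_csv(path, sep="\t", comment="#")
        need = {"regulator", "perturbation", "es", "nes", "p", "n_targets"}
        if not need.issubset(frame.columns):
            raise ValidationError(f"{path}: missing columns {need - set(frame.columns)}")
        network = str(frame["network"].iloc[0]) if "network" in frame and len(frame) else ""
        es = frame.pivot(index="regulator", columns="perturbation", values="es")
        nes = frame.pivot(index="regulator", columns="perturbation", values="nes")
        p = frame.pivot(index="regulator", columns="perturbation", values="p")
        n_targets = frame.groupby("regulator")["n_targets"].first()
        return cls(es=es, nes=nes, pvalue=p, n_targets=n_targets, network=network)


@dataclass
class IntegratedActivityMatrix:
    """Regulators x perturbations NES integrated across interactomes."""

    nes: pd.DataFrame
    networks: pd.DataFrame  # comma-joined contributing-network labels per cell
    sources: list[str] = field(default_factory=list)

    @property
    def regulators(self) -> list[str]:
        return list(self.nes.index)

    @property
    def perturbations(self) -> list[str]:
        return list(self.nes.columns)

    def write_nes(self, path: str | Path) -> None:
        self.nes.to_csv(path, sep="\t", index_label="regulator",
                        float_format="%.12g")


class RegulonActivity(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer from gene signatures to regulator NES.

    Parameters
    ----------
    interactome : Interactome
        Regulons to read out.
    min_targets : int, default 10
        Minimum regulon targets that must be present in the gene universe for
        a regulator to be testable; untestable cells are absent (NaN), not 0.
    calibration : {'analytic', 'empirical'}, default 'analytic'
        How ES is standardized into NES.  With ``'empirical'``, ``fit`` must
        receive null signatures (samples x genes) as X and learns per-regulon
        null ES moments from them; ``transform`` may then be applied to any
        matrix over the same genes.  With ``'analytic'`` fitting only aligns
        the gene universe.
    pleiotropy : bool, default False
        Apply the shadow-regulon correction in :meth:`infer`.
    overlap_min, penalty, sig_cut
        Shadow-correction parameters, see :func:`pleiotropy_adjust`.
    genes : sequence of str, optional
        Gene identifiers for plain-array X; ignored when X is a DataFrame.

    Attributes
    ----------
    regulators_ : list of str
        Testable regulators (columns of the transform output).
    null_mean_, null_sd_ : ndarray
        Per-regulon null ES moments (empirical calibration only).
    """

    def __init__(
        self,
        interactome: Interactome | None = None,
        min_targets: int = 10,
        calibration: str = "analytic",
        pleiotropy: bool = False,
        overlap_min: int = 10,
        penalty: float = 20.0,
        sig_cut: float = 1.96,
        genes: Sequence[str] | None = None,
    ):
        self.interactome = interactome
        self.min_targets = min_targets
        self.calibration = calibration
        self.pleiotropy = pleiotropy
        self.overlap_min = overlap_min
        self.penalty = penalty
        self.sig_cut = sig_cut
        self.genes = genes

    # -- helpers ----------------------------------------------------------

    def _resolve_genes(self, X) -> tuple[np.ndarray, list[str]]:
        if isinstance(X, pd.DataFrame):
            return X.to_numpy(float), [str(c) for c in X.columns]
        X = np.asarray(X, float)
        if self.genes is None:
            raise ValidationError("plain-array X requires the 'genes' parameter")
        if X.ndim != 2 or X.shape[1] != len(self.genes):
            raise ValidationError("X must be 2-d samples x genes matching 'genes'")
        return X, [str(g) for g in self.genes]

    def fit(self, X, y=None):
        if self.interactome is None or not self.interactome.regulons:
            raise ValidationError("a non-empty interactome is required")
        if self.calibration not in ("analytic", "empirical"):
            raise ValidationError(f"unknown calibration {self.calibration!r}")
        values, genes = self._resolve_genes(X)
        if values.shape[0] < 1:
            raise ValidationError("X must contain at least one signature")
        self.n_features_in_ = len(genes)
        self.feature_names_in_ = np.asarray(genes, dtype=object)
        pos = {g: i for i, g in enumerate(genes)}

        self.regulators_: list[str] = []
        self._idx: list[np.ndarray] = []
        self._w: list[np.ndarray] = []
        self._m: list[np.ndarray] = []
        dropped = 0
        for rid in self.interactome.regulons:
            table = self.interactome.regulons[rid].table
            hit = [(pos[t], mo, we) for t, mo, we in
                   zip(table.index, table["mode"], table["weight"]) if t in pos]
            if len(hit) < self.min_targets:
                dropped += 1
                continue
            idx = np.array([h[0] for h in hit])
            m = np.array([h[1] for h in hit])
            w = np.array([h[2] for h in hit])
            if w.sum() <= 0:
                dropped += 1
                continue
            self.regulators_.append(rid)
            self._idx.append(idx)
            self._m.append(m)
            self._w.append(w / w.sum())
        if dropped:
            logger.info("%d regulators untestable (< %d targets in universe)",
                        dropped, self.min_targets)
        if not self.regulators_:
            raise ValidationError("no regulator has enough targets in the universe")

        if self.calibration == "empirical":
            if values.shape[0] < 100:
                logger.warning("empirical calibration fit on %d null signatures; "
                               ">= 100 recommended", values.shape[0])
            null_es = self._es_matrix(values)  # n_nulls x n_regulators
            self.null_mean_ = null_es.mean(axis=0)
            self.null_sd_ = null_es.std(axis=0, ddof=1)
            if np.any(self.null_sd_ == 0):
                raise ValidationError("null ES distribution has zero variance for "
                                      "some regulators")
        return self

    def _es_matrix(self, values: np.ndarray) -> np.ndarray:
        """ES for every (signature, regulator); values is samples x genes."""
        t2, t1 = _transform_columns(values.T)  # genes x samples
        out = np.empty((values.shape[0], len(self.regulators_)))
        for k, (idx, m, w) in enumerate(zip(self._idx, self._m, self._w)):
            scores = m[:, None] * t2[idx] + (1.0 - np.abs(m))[:, None] * t1[idx]
            out[:, k] = w @ scores
        return out

    def transform(self, X) -> np.ndarray:
        """NES for every (signature, regulator) as a samples x regulators array."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "regulators_")
        values, genes = self._resolve_genes(X)
        if genes != list(self.feature_names_in_):
            raise ValidationError("X gene identifiers differ from those seen in fit")
        es = self._es_matrix(values)
        if self.calibration == "empirical":
            return (es - self.null_mean_) / self.null_sd_
        denom = np.array([np.sqrt(np.sum(w**2)) for w in self._w])
        return es / denom

    def get_feature_names_out(self, input_features=None):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "regulators_")
        return np.asarray(self.regulators_, dtype=object)

    def infer(self, X, labels: Sequence[str] | None = None) -> ActivityMatrix:
        """Full inference: regulators x perturbations ActivityMatrix.

        X is samples x genes (rows are perturbation signatures).  Applies the
        shadow-regulon correction when ``pleiotropy=True``.
        """
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "regulators_")
        values, genes = self._resolve_genes(X)
        if labels is None:
            labels = [str(i) for i in X.index] if isinstance(X, pd.DataFrame) \
                else [f"sig{i}" for i in range(values.shape[0])]
        es = self._es_matrix(values)
        nes = self.transform(X)
        p = np.maximum(2.0 * stats.norm.sf(np.abs(nes)), np.nextafter(0, 1))
        n_targets = pd.Series([len(i) for i in self._idx], index=self.regulators_)
        matrix = ActivityMatrix(
            es=pd.DataFrame(es.T, index=self.regulators_, columns=labels),
            nes=pd.DataFrame(nes.T, index=self.regulators_, columns=labels),
            pvalue=pd.DataFrame(p.T, index=self.regulators_, columns=labels),
            n_targets=n_targets,
            network=self.interactome.name,
            context=self.interactome.context,
        )
        if self.pleiotropy:
            t2, t1 = _transform_columns(values.T)
            matrix = pleiotropy_adjust(
                matrix, self.interactome,
                transformed={"t2": pd.DataFrame(t2, index=genes, columns=labels),
                             "t1": pd.DataFrame(t1, index=genes, columns=labels)},
                overlap_min=self.overlap_min, penalty=self.penalty,
                sig_cut=self.sig_cut, min_targets=self.min_targets,
            )
        return matrix


def pleiotropy_adjust(
    matrix: ActivityMatrix,
    interactome: Interactome,
    transformed: dict,
    overlap_min: int = 10,
    penalty: float = 20.0,
    sig_cut: float = 1.96,
    min_targets: int = 10,
) -> ActivityMatrix:
    """Shadow-regulon correction of an activity matrix.

    For each perturbation and ordered pair of significant regulators (|NES| >=
    ``sig_cut``) sharing >= ``overlap_min`` targets, each regulator's NES is
    recomputed analytically on its unique (non-shared) targets; an empty or
    too-small unique set counts as NES 0.  A regulator whose unique-target NES
    loses significance while the partner's persists (or is at least as
    extreme) is shrunk toward its unique-target NES with weight
    penalty / (penalty + n_shared); the adjustment never flips the sign (it is
    clamped at 0).  ``transformed`` carries the t2/t1 frames (genes x
    perturbations) the matrix was computed from.

    This is a simplified shadow correction standing in for a full pleiotropy
    index; it only ever reduces |NES|.
    """
    t2f: pd.DataFrame = transformed["t2"]
    t1f: pd.DataFrame = transformed["t1"]
    regs = [r for r in matrix.regulators if r in interactome.regulons]
    target_sets = {r: set(interactome.regulons[r].table.index) for r in regs}

    def unique_nes(reg: str, other: str, pert: str) -> float:
        shared = target_sets[reg] & target_sets[other]
        table = interactome.regulons[reg].table
        keep = [t for t in table.index if t not in shared and t in t2f.index]
        if len(keep) < min_targets:
            return 0.0
        sub = table.loc[keep]
        w = sub["weight"].to_numpy(float)
        w = w / w.sum()
        m = sub["mode"].to_numpy(float)
        es = float(np.sum(w * (m * t2f.loc[keep, pert].to_numpy()
                               + (1 - np.abs(m)) * t1f.loc[keep, pert].to_numpy())))
        return es / float(np.sqrt(np.sum(w**2)))

    nes = matrix.nes.copy()
    pval = matrix.pvalue.copy()
    pairs = [
        (a, b, len(target_sets[a] & target_sets[b]))
        for i, a in enumerate(regs) for b in regs[i + 1:]
        if len(target_sets[a] & target_sets[b]) >= overlap_min
    ]
    for pert in matrix.perturbations:
        col = matrix.nes[pert]
        significant = {r for r in regs
                       if pd.notna(col[r]) and abs(col[r]) >= sig_cut}
        proposals: dict[str, float] = {}
        for a, b, n_shared in pairs:
            if a not in significant or b not in significant:
                continue
            u_a = unique_nes(a, b, pert)
            u_b = unique_nes(b, a, pert)
            shrink_w = penalty / (penalty + n_shared)
            for loser, u_loser, u_other in ((a, u_a, u_b), (b, u_b, u_a)):
                if abs(u_loser) >= sig_cut:
                    continue
                if abs(u_other) < sig_cut and abs(u_other) < abs(u_loser):
                    continue
                orig = float(col[loser])
                new = shrink_w * u_loser + (1 - shrink_w) * orig
                if orig != 0 and np.sign(new) != np.sign(orig):
                    new = 0.0
                prev = proposals.get(loser)
                if prev is None or abs(new) < abs(prev):
                    proposals[loser] = new
        for reg, new in proposals.items():
            nes.at[reg, pert] = new
            pval.at[reg, pert] = max(2.0 * stats.norm.sf(abs(new)),
                                     np.nextafter(0, 1))
    return ActivityMatrix(es=matrix.es, nes=nes, pvalue=pval,
                          n_targets=matrix.n_targets,
                          network=matrix.network, context=matrix.context)


def infer_activity_matrix(
    signatures: Sequence[GeneSignature],
    interactome: Interactome,
    nulls: NullSignatureSet | Sequence[GeneSignature] | None = None,
    min_targets: int = 10,
    pleiotropy: bool = False,
    **kwargs,
) -> ActivityMatrix:
    """One-call inference: signatures + interactome (-> empirical nulls) -> NES.

    Empirical calibration is used when ``nulls`` is supplied, analytic
    otherwise.  Thin wrapper over :class:`RegulonActivity`.
    """
    if not interactome.regulons:
        raise ValidationError("empty interactome")
    frame = signatures_to_frame(list(signatures))  # genes x perturbations
    est = RegulonActivity(
        interactome=interactome,
        min_targets=min_targets,
        calibration="empirical" if nulls is not None else "analytic",
        pleiotropy=pleiotropy,
        **kwargs,
    )
    if nulls is not None:
        null_sigs = nulls.signatures if isinstance(nulls, NullSignatureSet) else list(nulls)
        null_frame = signatures_to_frame(null_sigs).reindex(frame.index)
        if null_frame.isna().any().any():
            raise ValidationError("null signatures do not cover the signature universe")
        est.fit(null_frame.T)
    else:
        est.fit(frame.T)
    return est.infer(frame.T, labels=[str(c) for c in frame.columns])


def integrate_networks(
    matrices: Sequence[ActivityMatrix],
) -> IntegratedActivityMatrix:
    """Integrate NES across interactomes by self-weighted averaging.

    Per cell, s* = sum_k s_k |s_k| / sum_k |s_k| over the networks where the
    cell exists; if every contributing s_k is 0 then s* = 0.  The bound
    |s*| <= max_k |s_k| holds by construction.  Contributing networks are
    recorded per cell.
    """
    if not matrices:
        raise ValidationError("integrate_networks needs >= 1 matrix")
    regulators = sorted(set().union(*[m.nes.index for m in matrices]))
    perturbations: list[str] = []
    for m in matrices:
        for c in m.nes.columns:
            if c not in perturbations:
                perturbations.append(c)
    stack = np.full((len(matrices), len(regulators), len(perturbations)), np.nan)
    for k, m in enumerate(matrices):
        stack[k] = m.nes.reindex(index=regulators, columns=perturbations).to_numpy()
    present = ~np.isnan(stack)
    absv = np.where(present, np.abs(stack), 0.0)
    num = np.nansum(stack * absv, axis=0)
    den = absv.sum(axis=0)
    any_present = present.any(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        integrated = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    integrated = np.where(any_present, integrated, np.nan)
    labels = [m.network or f"net{k}" for k, m in enumerate(matrices)]
    nets = np.empty((len(regulators), len(perturbations)), dtype=object)
    for i in range(len(regulators)):
        for j in range(len(perturbations)):
            nets[i, j] = ",".join(labels[k] for k in range(len(matrices))
                                  if present[k, i, j])
    return IntegratedActivityMatrix(
        nes=pd.DataFrame(integrated, index=regulators, columns=perturbations),
        networks=pd.DataFrame(nets, index=regulators, columns=perturbations),
        sources=labels,
    )
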