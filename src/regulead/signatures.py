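"""Perturbational gene-expression signatures and their preprocessing.

A signature is a per-gene differential statistic on the signed z-score scale
(positive = up in treatment).  This module builds them from expression
matrices (single-sample scaling or two-group Welch tests), combines replicate
signatures (Stouffer), generates null-signature sets by random sample splits,
applies knock-down efficiency and replicate-reproducibility filters, and
degrades signatures controllably for robustness benchmarks.

The one internal currency is the signed z; p-values are recovered from it as
two-sided normal tails wherever a filter needs them.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import ValidationError, logger

PROVENANCES = ("single_sample_z", "two_group_t", "stouffer", "synthetic")

__all__ = [
    "ExpressionMatrix",
    "GeneSignature",
    "NullSignatureSet",
    "collapse_probes",
    "single_sample_zscores",
    "two_group_signature",
    "generate_null_set",
    "stouffer_combine",
    "kd_efficiency_check",
    "replicate_reproducibility",
    "degrade_signature",
    "signatures_to_frame",
    "frame_to_signatures",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values plus optional sample metadata.

    ``data`` rows are gene identifiers, columns sample identifiers.
    ``metadata`` (optional) is indexed by sample with columns such as
    ``perturbation``, ``replicate_group`` and ``plate``.
    """

    data: pd.DataFrame
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate gene identifiers")
        if self.data.columns.has_duplicates:
            raise ValidationError("duplicate sample identifiers")
        if self.data.isna().any().any():
            raise ValidationError("missing values in expression matrix "
                                  "(load with impute_missing=True or clean upstream)")
        if self.metadata is not None:
            missing = [s for s in self.data.columns if s not in self.metadata.index]
            if missing:
                raise ValidationError(f"samples without metadata: {missing[:5]}")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @classmethod
    def read_tsv(
        cls,
        path: str | Path,
        metadata: str | Path | None = None,
        impute_missing: bool = False,
    ) -> "ExpressionMatrix":
        """Read a genes x samples TSV (first column gene id, header sample ids)."""
        data = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        if data.isna().any().any():
            if not impute_missing:
                raise ValidationError(f"{path}: missing values (set impute_missing=True "
                                      "to fill row medians)")
            n = int(data.isna().sum().sum())
            data = data.apply(lambda row: row.fillna(row.median()), axis=1)
            logger.warning("%s: imputed %d missing values with row medians", path, n)
        meta = None
        if metadata is not None:
            meta = pd.read_csv(metadata, sep="\t", index_col=0, comment="#")
        return cls(data=data.astype(float), metadata=meta)

    def write_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t")


@dataclass
class GeneSignature:
    """Per-gene differential statistic (signed z scale) for one perturbation."""

    values: pd.Series
    label: str = ""
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValidationError(f"signature {self.label!r}: duplicate gene ids")
        if not np.all(np.isfinite(self.values.to_numpy(float))):
            raise ValidationError(f"signature {self.label!r}: non-finite values")
        if self.provenance not in PROVENANCES:
            raise ValidationError(f"unknown provenance {self.provenance!r}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def __len__(self) -> int:
        return len(self.values)

    @classmethod
    def read_tsv(cls, path: str | Path, label: str | None = None) -> "GeneSignature":
        frame = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        return cls(values=frame.iloc[:, 0].astype(float),
                   label=label or Path(path).stem)

    def write_tsv(self, path: str | Path) -> None:
        self.values.rename("statistic").to_csv(path, sep="\t", index_label="gene")


@dataclass
class NullSignatureSet:
    """Signatures from random sample splits, used as an empirical null."""

    signatures: list[GeneSignature]
    seed: int
    scheme: str = "two_group_random_split"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 100:
            logger.warning("null set has %d signatures; >= 100 recommended for "
                           "inference use", self.n)

    @property
    def n(self) -> int:
        return len(self.signatures)

    def to_frame(self) -> pd.DataFrame:
        return signatures_to_frame(self.signatures)


def signatures_to_frame(signatures: Sequence[GeneSignature]) -> pd.DataFrame:
    """Stack signatures sharing a gene universe into a genes x labels frame."""
    if not signatures:
        raise ValidationError("no signatures given")
    universe = signatures[0].values.index
    cols = {}
    for i, sig in enumerate(signatures):
        if not sig.values.index.equals(universe):
            if set(sig.values.index) != set(universe):
                raise ValidationError("signatures do not share a gene universe")
        cols[sig.label or f"sig{i}"] = sig.values.reindex(universe)
    return pd.DataFrame(cols, index=universe)


def frame_to_signatures(frame: pd.DataFrame, provenance: str = "synthetic"):
    return [GeneSignature(values=frame[c], label=str(c), provenance=provenance)
            for c in frame.columns]


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def collapse_probes(
    matrix: ExpressionMatrix, probe_to_gene: Mapping[str, str]
) -> ExpressionMatrix:
    """Collapse probe rows to one row per gene by maximum MAD across samples.

    Ties are broken by the lexicographically smallest probe id; unmapped
    probes are dropped with the count logged.
    """
    mapped = [p for p in matrix.data.index if p in probe_to_gene]
    dropped = matrix.n_genes - len(mapped)
    if dropped:
        logger.warning("collapse_probes: %d unmapped probes dropped", dropped)
    if not mapped:
        raise ValidationError("no probes map to genes")
    sub = matrix.data.loc[mapped]
    mad = stats.median_abs_deviation(sub.to_numpy(float), axis=1, scale=1.0)
    pick = (
        pd.DataFrame({"probe": mapped,
                      "gene": [probe_to_gene[p] for p in mapped],
                      "mad": mad})
        .sort_values(["gene", "mad", "probe"], ascending=[True, False, True])
        .groupby("gene", sort=True)
        .head(1)
    )
    collapsed = sub.loc[pick["probe"]].copy()
    collapsed.index = pick["gene"].to_numpy()
    return ExpressionMatrix(data=collapsed, metadata=matrix.metadata)


def single_sample_zscores(
    matrix: ExpressionMatrix, group_by: str | None = None
) -> list[GeneSignature]:
    """Scale each gene to z-scores across samples, one signature per sample.

    With ``group_by`` (a metadata column, e.g. a plate label), scaling is done
    independently within each group, so a sample's value depends only on its
    group.  Zero-variance genes are set to 0 with a warning; groups of fewer
    than 3 samples are an error.
    """
    if group_by is not None:
        if matrix.metadata is None or group_by not in matrix.metadata.columns:
            raise ValidationError(f"metadata column {group_by!r} required for grouping")
        groups = matrix.metadata.loc[matrix.samples, group_by]
        grouping = {g: list(idx) for g, idx in groups.groupby(groups).groups.items()}
    else:
        grouping = {"all": matrix.samples}

    out: dict[str, pd.Series] = {}
    for gname, samples in grouping.items():
        if len(samples) < 3:
            raise ValidationError(f"scaling group {gname!r} has {len(samples)} "
                                  "samples; >= 3 required")
        block = matrix.data[samples].to_numpy(float)
        mean = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=1, keepdims=True)
        flat = (sd == 0).ravel()
        if flat.any():
            logger.warning("group %r: %d zero-variance genes set to 0", gname,
                           int(flat.sum()))
        z = np.where(sd == 0, 0.0, (block - mean) / np.where(sd == 0, 1.0, sd))
        for k, s in enumerate(samples):
            out[s] = pd.Series(z[:, k], index=matrix.data.index)
    return [GeneSignature(values=out[s], label=str(s), provenance="single_sample_z")
            for s in matrix.samples]


def two_group_signature(
    matrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    z_cap: float = 12.0,
    label: str = "",
) -> GeneSignature:
    """Welch t-test signature of group A vs group B on the signed z scale.

    Per gene the two-sided Welch p is mapped to z = sign(meanA - meanB) *
    Phi^-1(1 - p/2); positive means up in group A.  Genes with zero variance
    in both groups get statistic 0 when means are equal, else +/- ``z_cap``.
    """
    data = matrix.data if hasattr(matrix, "data") else matrix
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("each group needs >= 2 samples")
    if set(group_a) & set(group_b):
        raise ValidationError("groups must be disjoint")
    a = data[group_a].to_numpy(float)
    b = data[group_b].to_numpy(float)
    diff = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
        z = np.sign(diff) * stats.norm.isf(np.minimum(p, 1.0) / 2.0)
    degenerate = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    z = np.where(degenerate, np.where(diff == 0, 0.0, np.sign(diff) * z_cap), z)
    clipped = np.abs(z) > z_cap
    if clipped.any():
        logger.warning("%d statistics clamped to |z| = %g", int(clipped.sum()), z_cap)
    z = np.clip(np.nan_to_num(z, nan=0.0), -z_cap, z_cap)
    return GeneSignature(values=pd.Series(z, index=data.index), label=label,
                         provenance="two_group_t")


def generate_null_set(
    matrix,
    n: int = 1000,
    group_size: int | None = None,
    seed: int = 0,
    z_cap: float = 12.0,
) -> NullSignatureSet:
    """Null signatures from ``n`` random disjoint sample splits.

    Each draw compares ``group_size`` randomly selected samples with another
    disjoint random group of the same size via :func:`two_group_signature`.
    ``group_size`` defaults to min(100, n_samples // 2).
    """
    data = matrix.data if hasattr(matrix, "data") else matrix
    samples = list(data.columns)
    if group_size is None:
        group_size = min(100, len(samples) // 2)
    if 2 * group_size > len(samples) or group_size < 2:
        raise ValidationError(
            f"cannot draw two disjoint groups of {group_size} from "
            f"{len(samples)} samples"
        )
    rng = np.random.default_rng(seed)
    sigs = []
    for k in range(n):
        perm = rng.permutation(len(samples))
        a = [samples[i] for i in perm[:group_size]]
        b = [samples[i] for i in perm[group_size: 2 * group_size]]
        sigs.append(two_group_signature(data, a, b, z_cap=z_cap, label=f"null{k}"))
    return NullSignatureSet(
        signatures=sigs, seed=seed,
        scheme=f"two_group_random_split(group_size={group_size})",
    )


def stouffer_combine(signatures: Sequence[GeneSignature], label: str = "") -> GeneSignature:
    """Stouffer integration: z* = sum(z_i) / sqrt(k) per gene.

    Genes absent from some signatures are combined over the k signatures that
    contain them.
    """
    if not signatures:
        raise ValidationError("stouffer_combine needs >= 1 signature")
    frames = pd.concat([s.values for s in signatures], axis=1, join="outer")
    k = frames.notna().sum(axis=1)
    combined = frames.sum(axis=1, skipna=True) / np.sqrt(k)
    combined = combined[k > 0]
    return GeneSignature(values=combined, label=label or "stouffer",
                         provenance="stouffer")


def kd_efficiency_check(
    signature: GeneSignature, silenced_gene: str, p_max: float = 0.1
) -> bool:
    """True iff the silenced gene went down with two-sided p < ``p_max``."""
    if silenced_gene not in signature.values.index:
        raise ValidationError(f"silenced gene {silenced_gene!r} not in signature")
    z = float(signature.values[silenced_gene])
    p = 2.0 * stats.norm.sf(abs(z))
    return bool(p < p_max and z < 0)


def replicate_reproducibility(
    matrix,
    replicate_groups: Mapping[str, str] | str,
    z_keep: float = 5.0,
) -> pd.DataFrame:
    """Score each sample by correlation to its replicates vs the background.

    A sample's score is the mean Pearson correlation of its profile to its
    replicate samples; the background is its correlations to all non-replicate
    samples, giving z = (score - mean_bg) / sd_bg.  Samples are kept iff
    z > ``z_keep``; singleton groups are flagged unscorable.

    ``replicate_groups`` is either a sample -> group mapping or the name of a
    metadata column.  Returns a frame indexed by sample with columns
    ``group, score, z, keep, scorable``.
    """
    data = matrix.data if hasattr(matrix, "data") else matrix
    if isinstance(replicate_groups, str):
        meta = getattr(matrix, "metadata", None)
        if meta is None or replicate_groups not in meta.columns:
            raise ValidationError(f"metadata column {replicate_groups!r} not found")
        groups = {s: meta.at[s, replicate_groups] for s in data.columns}
    else:
        groups = dict(replicate_groups)
    samples = list(data.columns)
    corr = np.corrcoef(data.to_numpy(float), rowvar=False)
    rows = []
    for i, s in enumerate(samples):
        mates = [j for j, t in enumerate(samples) if j != i and groups.get(t) == groups.get(s)]
        others = [j for j, t in enumerate(samples) if j != i and groups.get(t) != groups.get(s)]
        if not mates:
            rows.append((s, groups.get(s), np.nan, np.nan, False, False))
            continue
        score = float(np.mean(corr[i, mates]))
        bg = corr[i, others]
        sd = float(np.std(bg, ddof=1)) if len(bg) > 1 else np.nan
        z = (score - float(np.mean(bg))) / sd if sd and np.isfinite(sd) and sd > 0 else np.inf
        rows.append((s, groups.get(s), score, z, bool(z > z_keep), True))
    return pd.DataFrame(rows, columns=["sample", "group", "score", "z", "keep",
                                       "scorable"]).set_index("sample")


def degrade_signature(
    signature: GeneSignature,
    mode: str,
    amount: float,
    seed: int = 0,
) -> GeneSignature:
    """Degrade a signature for robustness benchmarks.

    ``mode='shuffle_fraction'`` permutes the values of a random ``amount``
    fraction of genes among themselves; ``mode='gaussian_sd_fraction'`` adds
    N(0, (amount * sd(signature))^2) noise to every gene.  Deterministic given
    ``seed``; ``amount=0`` is the identity in both modes.
    """
    if mode not in ("shuffle_fraction", "gaussian_sd_fraction"):
        raise ValidationError(f"unknown degradation mode {mode!r}")
    if amount < 0 or (mode == "shuffle_fraction" and amount > 1):
        raise ValidationError(f"invalid amount {amount} for mode {mode!r}")
    rng = np.random.default_rng(seed)
    values = signature.values.to_numpy(float).copy()
    n = len(values)
    if mode == "shuffle_fraction":
        k = int(round(amount * n))
        if k >= 2:
            idx = rng.choice(n, size=k, replace=False)
            values[idx] = values[idx[rng.permutation(k)]]
    else:
        if amount > 0:
            values = values + rng.normal(0.0, amount * values.std(), size=n)
    return GeneSignature(
        values=pd.Series(values, index=signature.values.index),
        label=f"{signature.label}|{mode}={amount:g}",
        provenance=signature.provenance,
    )
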