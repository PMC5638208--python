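"""Regulatory networks as regulons: construction, I/O and randomization.

A *regulon* is the set of transcriptional targets of one regulatory protein,
annotated per target with a signed mode of regulation (MoR: sign = activation
vs repression, magnitude = confidence in the sign, 0 = direction unknown) and
a non-negative interaction-confidence weight.  An *interactome* is a named
collection of regulons from one evidence source: mutual-information networks
(ARACNE output), scored protein-link tables (STRING style), TF->target gene
sets (ChEA/GMT style), or knock-down differential signatures.

Regulons are the multiplexed reporters that the activity module reads out;
everything here is plumbing to get them from the four source dialects into a
single validated in-memory form, plus degree-preserving randomization used to
degrade networks controllably in benchmarks.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._utils import ParseError, ValidationError, logger

SOURCES = ("aracne", "chea", "string", "kd", "synthetic")

__all__ = [
    "Regulon",
    "Interactome",
    "read_aracne_adjacency",
    "regulons_from_edges",
    "read_string_links",
    "read_chea_sets",
    "kd_regulons",
    "randomize_interactome",
    "write_regulons",
    "read_regulons",
]


@dataclass
class Regulon:
    """One regulator's targets with per-target mode and weight.

    Parameters
    ----------
    regulator : str
        Gene identifier of the regulatory protein (opaque, case sensitive).
    table : pandas.DataFrame
        Indexed by target id, with float columns ``mode`` (in [-1, 1]) and
        ``weight`` (>= 0).
    source : str
        One of ``aracne | chea | string | kd | synthetic``.
    """

    regulator: str
    table: pd.DataFrame
    source: str = "synthetic"

    def __post_init__(self) -> None:
        t = self.table
        if t.empty:
            raise ValidationError(f"regulon {self.regulator!r} is empty")
        if not {"mode", "weight"}.issubset(t.columns):
            raise ValidationError(
                f"regulon {self.regulator!r}: table needs 'mode' and 'weight' columns"
            )
        if t.index.has_duplicates:
            raise ValidationError(f"regulon {self.regulator!r}: duplicate targets")
        if self.regulator in t.index:
            raise ValidationError(
                f"regulon {self.regulator!r}: regulator is its own target"
            )
        mode = t["mode"].to_numpy(float)
        weight = t["weight"].to_numpy(float)
        if not np.all(np.isfinite(mode)) or np.any(np.abs(mode) > 1 + 1e-12):
            raise ValidationError(f"regulon {self.regulator!r}: mode outside [-1, 1]")
        if not np.all(np.isfinite(weight)) or np.any(weight < 0):
            raise ValidationError(f"regulon {self.regulator!r}: negative weight")
        if self.source not in SOURCES:
            raise ValidationError(f"unknown source {self.source!r}")

    @property
    def targets(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)

    def equals(self, other: "Regulon", rtol: float = 1e-11) -> bool:
        if self.regulator != other.regulator or set(self.targets) != set(other.targets):
            return False
        a = self.table.sort_index()
        b = other.table.loc[a.index]
        return bool(
            np.allclose(a["mode"], b["mode"], rtol=rtol, atol=1e-12)
            and np.allclose(a["weight"], b["weight"], rtol=rtol, atol=1e-12)
        )


@dataclass
class Interactome:
    """A named collection of regulons from one source/context."""

    name: str
    regulons: dict[str, Regulon]
    context: str = ""
    source: str = "synthetic"
    meta: dict = field(default_factory=dict)

    @property
    def regulators(self) -> list[str]:
        return list(self.regulons)

    @property
    def gene_universe(self) -> set[str]:
        universe: set[str] = set(self.regulons)
        for reg in self.regulons.values():
            universe.update(reg.table.index)
        return universe

    @property
    def n_interactions(self) -> int:
        return sum(len(r) for r in self.regulons.values())

    def summary(self) -> dict:
        """Regulator / target / interaction counts, Table-1 style."""
        targets: set[str] = set()
        for reg in self.regulons.values():
            targets.update(reg.table.index)
        return {
            "name": self.name,
            "context": self.context,
            "regulators": len(self.regulons),
            "targets": len(targets),
            "interactions": self.n_interactions,
        }

    def to_frame(self) -> pd.DataFrame:
        """Long-form (regulator, target, mode, weight) table, sorted."""
        rows = []
        for rid in sorted(self.regulons):
            t = self.regulons[rid].table
            rows.append(
                pd.DataFrame(
                    {
                        "regulator": rid,
                        "target": t.index,
                        "mode": t["mode"].to_numpy(),
                        "weight": t["weight"].to_numpy(),
                    }
                )
            )
        if not rows:
            return pd.DataFrame(columns=["regulator", "target", "mode", "weight"])
        out = pd.concat(rows, ignore_index=True)
        return out.sort_values(["regulator", "target"], ignore_index=True)

    def equals(self, other: "Interactome") -> bool:
        if set(self.regulons) != set(other.regulons):
            return False
        return all(self.regulons[r].equals(other.regulons[r]) for r in self.regulons)


def _regulon_from_arrays(regulator, targets, modes, weights, source) -> Regulon:
    table = pd.DataFrame(
        {"mode": np.asarray(modes, float), "weight": np.asarray(weights, float)},
        index=pd.Index(targets, name="target"),
    )
    return Regulon(regulator=regulator, table=table, source=source)


# ---------------------------------------------------------------------------
# ARACNE output
# ---------------------------------------------------------------------------

def read_aracne_adjacency(
    path: str | Path, dialect: str = "adj"
) -> list[tuple[str, str, float]]:
    """Read ARACNE output as an edge list of (regulator, target, MI).

    ``dialect='adj'`` is the classic adjacency format, one regulator per line
    followed by alternating target / mutual-information fields (``>`` comment
    lines are skipped).  ``dialect='three_column'`` is a flat TSV with
    regulator, target, MI per line (a non-numeric first data line is treated
    as a header).  Duplicate (regulator, target) pairs keep the maximum MI
    with a warning; negative MI is rejected.
    """
    if dialect not in ("adj", "three_column"):
        raise ValidationError(f"unknown dialect {dialect!r}")
    best: dict[tuple[str, str], float] = {}
    order: list[tuple[str, str]] = []
    duplicates = 0

    def add(reg: str, tgt: str, mi: float, lineno: int) -> None:
        nonlocal duplicates
        if mi < 0:
            raise ValidationError(f"{path}:{lineno}: negative MI {mi}")
        key = (reg, tgt)
        if key in best:
            duplicates += 1
            best[key] = max(best[key], mi)
        else:
            best[key] = mi
            order.append(key)

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(">"):
                continue
            fields = line.split("\t")
            if dialect == "adj":
                if len(fields) < 3 or len(fields) % 2 == 0:
                    raise ParseError(
                        f"{path}:{lineno}: expected regulator followed by "
                        f"target/MI pairs, got {len(fields)} fields"
                    )
                reg = fields[0]
                for k in range(1, len(fields), 2):
                    try:
                        mi = float(fields[k + 1])
                    except ValueError as exc:
                        raise ParseError(
                            f"{path}:{lineno}: MI field {fields[k + 1]!r} "
                            "is not a number"
                        ) from exc
                    add(reg, fields[k], mi, lineno)
            else:
                if len(fields) != 3:
                    raise ParseError(
                        f"{path}:{lineno}: expected 3 columns, got {len(fields)}"
                    )
                try:
                    mi = float(fields[2])
                except ValueError as exc:
                    if lineno == 1:
                        continue  # header row
                    raise ParseError(
                        f"{path}:{lineno}: MI field {fields[2]!r} is not a number"
                    ) from exc
                add(fields[0], fields[1], mi, lineno)
    if duplicates:
        logger.warning("%s: %d duplicate edges collapsed (kept max MI)", path, duplicates)
    if not best:
        logger.warning("%s: no edges parsed", path)
    return [(r, t, best[(r, t)]) for r, t in order]


def _spearman_modes(expression, regulators: list[str], targets: list[str]) -> np.ndarray:
    """Spearman correlation (mode estimate) per (regulator, target) pair.

    Both lists are parallel edge arrays.  Zero-variance genes yield mode 0.
    """
    data = expression.data if hasattr(expression, "data") else expression
    ranks = data.rank(axis=1).to_numpy(float)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norm = np.sqrt((ranks**2).sum(axis=1))
    flat = np.where(norm == 0)[0]
    if flat.size:
        logger.warning("%d zero-variance genes: mode set to 0", flat.size)
    safe = np.where(norm == 0, 1.0, norm)
    unit = ranks / safe[:, None]
    unit[flat] = 0.0
    pos = {g: i for i, g in enumerate(data.index)}
    ridx = np.array([pos[r] for r in regulators])
    tidx = np.array([pos[t] for t in targets])
    modes = np.einsum("ij,ij->i", unit[ridx], unit[tidx])
    return np.clip(modes, -1.0, 1.0)


def regulons_from_edges(
    edges: Iterable[tuple[str, str, float]],
    expression,
    min_targets: int = 10,
    name: str = "aracne",
    context: str = "",
    source: str = "aracne",
) -> Interactome:
    """Build an interactome from (regulator, target, MI) edges.

    The mode of regulation is estimated as the Spearman rank correlation of
    regulator and target expression across samples (clipped to [-1, 1]); the
    weight is MI max-normalized within each regulon.  Edges whose regulator or
    target is missing from the expression matrix are skipped with a warning;
    self-loops are removed; regulons with fewer than ``min_targets`` targets
    are dropped with a warning.
    """
    data = expression.data if hasattr(expression, "data") else expression
    if data.shape[1] < 3:
        raise ValidationError("mode estimation needs >= 3 samples")
    genes = set(data.index)
    kept: list[tuple[str, str, float]] = []
    skipped = self_loops = 0
    for reg, tgt, mi in edges:
        if reg == tgt:
            self_loops += 1
            continue
        if reg not in genes or tgt not in genes:
            skipped += 1
            continue
        kept.append((reg, tgt, float(mi)))
    if skipped:
        logger.warning("%d edges skipped: gene absent from expression matrix", skipped)
    if self_loops:
        logger.warning("%d self-loop edges removed", self_loops)
    if not kept:
        return Interactome(name=name, regulons={}, context=context, source=source)

    regs = [e[0] for e in kept]
    tgts = [e[1] for e in kept]
    modes = _spearman_modes(data, regs, tgts)
    frame = pd.DataFrame({"regulator": regs, "target": tgts, "mode": modes,
                          "mi": [e[2] for e in kept]})
    regulons: dict[str, Regulon] = {}
    dropped = 0
    for rid, grp in frame.groupby("regulator", sort=True):
        if len(grp) < min_targets:
            dropped += 1
            continue
        max_mi = grp["mi"].max()
        weight = grp["mi"] / max_mi if max_mi > 0 else np.ones(len(grp))
        regulons[rid] = _regulon_from_arrays(
            rid, grp["target"].tolist(), grp["mode"].to_numpy(), weight.to_numpy(), source
        )
    if dropped:
        logger.warning("%d regulons dropped: fewer than %d targets", dropped, min_targets)
    return Interactome(name=name, regulons=regulons, context=context, source=source)


# ---------------------------------------------------------------------------
# STRING-style protein links
# ---------------------------------------------------------------------------

def read_string_links(
    path: str | Path,
    min_score: float = 0.7,
    name: str = "string",
    context: str = "",
) -> Interactome:
    """Read a scored protein-link table into undirected 'regulons'.

    Each link with combined score strictly greater than ``min_score`` makes
    both endpoints a member of the other's regulon, with mode 0 (direction
    unknown) and weight equal to the score.  Scores on a 0-1000 scale are
    auto-detected (any value > 1) and divided by 1000.
    """
    try:
        table = pd.read_csv(path, sep=r"\s+")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: could not parse link table: {exc}") from exc
    if table.shape[1] < 3:
        raise ParseError(f"{path}: expected >= 3 columns (protein1 protein2 score)")
    # tolerate headerless files: a numeric-looking header means no header row
    try:
        float(table.columns[2])
        table = pd.read_csv(path, sep=r"\s+", header=None)
    except ValueError:
        pass
    p1 = table.iloc[:, 0].astype(str)
    p2 = table.iloc[:, 1].astype(str)
    score = pd.to_numeric(table.iloc[:, 2], errors="raise").astype(float)
    if (score > 1).any():
        score = score / 1000.0
    if ((score < 0) | (score > 1)).any():
        raise ValidationError(f"{path}: scores outside [0, 1] after rescaling")
    keep = score > min_score
    members: dict[str, dict[str, float]] = {}
    for a, b, s in zip(p1[keep], p2[keep], score[keep]):
        if a == b:
            continue
        members.setdefault(a, {})[b] = max(s, members.get(a, {}).get(b, 0.0))
        members.setdefault(b, {})[a] = max(s, members.get(b, {}).get(a, 0.0))
    regulons = {
        rid: _regulon_from_arrays(
            rid,
            sorted(tgts),
            np.zeros(len(tgts)),
            np.array([tgts[t] for t in sorted(tgts)]),
            "string",
        )
        for rid, tgts in sorted(members.items())
    }
    return Interactome(name=name, regulons=regulons, context=context, source="string")


# ---------------------------------------------------------------------------
# ChEA-style GMT gene sets
# ---------------------------------------------------------------------------

def read_chea_sets(
    path: str | Path,
    expression=None,
    name: str = "chea",
    context: str = "",
) -> Interactome:
    """Read GMT records (TF, description, targets...) into regulons.

    Multiple records for the same TF are merged by target union (logged).
    All weights are 1; modes are the Spearman correlation against the
    expression matrix when one is provided, else 0.
    """
    sets: dict[str, set[str]] = {}
    merged = empty = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected TF, description, targets")
            tf, targets = fields[0], [t for t in fields[2:] if t]
            if not targets:
                empty += 1
                logger.warning("%s:%d: record for %s has no targets, skipped", path, lineno, tf)
                continue
            if tf in sets:
                merged += 1
            sets.setdefault(tf, set()).update(t for t in targets if t != tf)
    if merged:
        logger.info("%s: %d duplicate TF records merged by union", path, merged)

    regulons: dict[str, Regulon] = {}
    expr_genes: set[str] = set()
    data = None
    if expression is not None:
        data = expression.data if hasattr(expression, "data") else expression
        expr_genes = set(data.index)
    for tf in sorted(sets):
        targets = sorted(sets[tf])
        modes = np.zeros(len(targets))
        if data is not None and tf in expr_genes:
            present = [t for t in targets if t in expr_genes]
            if present:
                est = _spearman_modes(data, [tf] * len(present), present)
                lookup = dict(zip(present, est))
                modes = np.array([lookup.get(t, 0.0) for t in targets])
        regulons[tf] = _regulon_from_arrays(tf, targets, modes, np.ones(len(targets)), "chea")
    return Interactome(name=name, regulons=regulons, context=context, source="chea")


# ---------------------------------------------------------------------------
# Knock-down derived regulons
# ---------------------------------------------------------------------------

def kd_regulons(
    kd_signatures: Mapping[str, "object"],
    z_min: float = 3.0,
    max_targets: int = 400,
    min_targets: int = 10,
    name: str = "kd",
    context: str = "",
) -> Interactome:
    """Build regulons from gene knock-down differential signatures.

    For silenced gene g, the regulon is the genes responding with |z| >=
    ``z_min`` in the knock-down signature of g (excluding g itself), capped at
    ``max_targets`` by |z|.  A gene whose expression falls when g is silenced
    is positively regulated by g, so mode = -sign(z); weight = |z|
    max-normalized.  Regulons with fewer than ``min_targets`` surviving
    targets are dropped with a warning.
    """
    regulons: dict[str, Regulon] = {}
    dropped = 0
    for gene in sorted(kd_signatures):
        sig = kd_signatures[gene]
        values = sig.values if hasattr(sig, "values") and isinstance(
            getattr(sig, "values"), pd.Series
        ) else pd.Series(sig)
        z = values.drop(index=gene, errors="ignore")
        z = z[z.abs() >= z_min]
        if len(z) > max_targets:
            order = sorted(z.index, key=lambda t: (-abs(z[t]), t))[:max_targets]
            z = z.loc[order]
        if len(z) < min_targets:
            dropped += 1
            continue
        absz = z.abs()
        regulons[gene] = _regulon_from_arrays(
            gene,
            list(z.index),
            (-np.sign(z.to_numpy())),
            (absz / absz.max()).to_numpy(),
            "kd",
        )
    if dropped:
        logger.warning("%d knock-down regulons dropped: fewer than %d targets",
                       dropped, min_targets)
    return Interactome(name=name, regulons=regulons, context=context, source="kd")


# ---------------------------------------------------------------------------
# Degree-preserving randomization
# ---------------------------------------------------------------------------

def randomize_interactome(
    interactome: Interactome, fraction: float, seed: int
) -> Interactome:
    """Rewire ~``fraction`` of edges by repeated double-edge swaps.

    Every regulator's out-degree and every target's in-degree is preserved
    exactly; modes and weights travel with the regulator-side stub; no
    duplicate edges or self-loops are introduced.  Deterministic given
    ``seed``.  The realized rewired fraction is stored in
    ``result.meta['realized_fraction']``.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValidationError(f"fraction must be in [0, 1], got {fraction}")
    regs: list[str] = []
    tgts: list[str] = []
    modes: list[float] = []
    weights: list[float] = []
    for rid in sorted(interactome.regulons):
        t = interactome.regulons[rid].table
        regs.extend([rid] * len(t))
        tgts.extend(t.index)
        modes.extend(t["mode"].tolist())
        weights.extend(t["weight"].tolist())
    n_edges = len(regs)
    original = set(zip(regs, tgts))
    edge_set = set(original)

    rng = np.random.default_rng(seed)
    target_rewired = round(fraction * n_edges)
    max_attempts = math.ceil(3 * fraction * n_edges)
    realized = 0
    attempts = 0
    while attempts < max_attempts and realized < target_rewired and n_edges > 1:
        attempts += 1
        i, j = rng.integers(0, n_edges, size=2)
        if i == j or regs[i] == regs[j]:
            continue
        new_i = (regs[i], tgts[j])
        new_j = (regs[j], tgts[i])
        if tgts[j] == regs[i] or tgts[i] == regs[j]:
            continue
        if new_i in edge_set or new_j in edge_set:
            continue
        before = ((regs[i], tgts[i]) in original) + ((regs[j], tgts[j]) in original)
        edge_set.discard((regs[i], tgts[i]))
        edge_set.discard((regs[j], tgts[j]))
        edge_set.add(new_i)
        edge_set.add(new_j)
        tgts[i], tgts[j] = tgts[j], tgts[i]
        after = (new_i in original) + (new_j in original)
        realized += before - after

    by_reg: dict[str, list[int]] = {}
    for idx, rid in enumerate(regs):
        by_reg.setdefault(rid, []).append(idx)
    regulons = {
        rid: _regulon_from_arrays(
            rid,
            [tgts[k] for k in idxs],
            [modes[k] for k in idxs],
            [weights[k] for k in idxs],
            interactome.source,
        )
        for rid, idxs in by_reg.items()
    }
    realized_fraction = realized / n_edges if n_edges else 0.0
    logger.info(
        "randomize_interactome: requested %.2f, realized %.3f (%d/%d edges)",
        fraction, realized_fraction, realized, n_edges,
    )
    return Interactome(
        name=f"{interactome.name}",
        regulons=regulons,
        context=interactome.context,
        source=interactome.source,
        meta={**interactome.meta, "realized_fraction": realized_fraction,
              "requested_fraction": fraction, "seed": seed},
    )


# ---------------------------------------------------------------------------
# Native serialization
# ---------------------------------------------------------------------------

def write_regulons(interactome: Interactome, path: str | Path) -> None:
    """Write a 4-column TSV (regulator, target, mode, weight) with metadata
    header comments.  Lossless at 12 significant digits."""
    frame = interactome.to_frame()
    with open(path, "w") as fh:
        fh.write(f"# name={interactome.name}\n")
        fh.write(f"# context={interactome.context}\n")
        fh.write(f"# source={interactome.source}\n")
        fh.write("regulator\ttarget\tmode\tweight\n")
        for row in frame.itertuples(index=False):
            fh.write(f"{row.regulator}\t{row.target}\t{row.mode:.12g}\t{row.weight:.12g}\n")


def read_regulons(path: str | Path) -> Interactome:
    """Read the native 4-column regulon TSV written by :func:`write_regulons`."""
    meta = {"name": str(Path(path).stem), "context": "", "source": "synthetic"}
    rows: list[tuple[str, str, float, float]] = []
    header_seen = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, value = body.split("=", 1)
                    if key.strip() in meta:
                        meta[key.strip()] = value.strip()
                continue
            fields = line.split("\t")
            if not header_seen:
                header_seen = True
                if fields[:4] != ["regulator", "target", "mode", "weight"]:
                    raise ParseError(
                        f"{path}:{lineno}: expected header "
                        "'regulator\\ttarget\\tmode\\tweight'"
                    )
                continue
            if len(fields) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            try:
                rows.append((fields[0], fields[1], float(fields[2]), float(fields[3])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric mode/weight") from exc
    if not header_seen:
        raise ParseError(f"{path}: missing column header")
    if not rows:
        logger.warning("%s: no regulon rows, returning empty interactome", path)
        return Interactome(name=meta["name"], regulons={}, context=meta["context"],
                           source=meta["source"])
    frame = pd.DataFrame(rows, columns=["regulator", "target", "mode", "weight"])
    regulons = {
        rid: _regulon_from_arrays(
            rid, grp["target"].tolist(), grp["mode"].to_numpy(),
            grp["weight"].to_numpy(), meta["source"],
        )
        for rid, grp in frame.groupby("regulator", sort=True)
    }
    return Interactome(name=meta["name"], regulons=regulons,
                       context=meta["context"], source=meta["source"])
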