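"""Co-migration fidelity: how consistently two species share timing modules.

The yearly partitions are stacked into an affiliation matrix (species rows,
year columns, cell = that year's module label, missing where a species was
filtered out).  Fidelity between two species is the normalized mutual
information (NMI) of their year-indexed label vectors over the years both
were present,

    nmi = 2 I(a; b) / (H(a) + H(b)),

which is 1 when the two affiliation histories determine each other and 0
when they are independent.  Species are then grouped by complete-linkage
("farthest neighbour") hierarchical clustering on the distance 1 − nmi,
cutting the dendrogram at 0.5 (minimum 50% similarity within a cluster).

Caveat: NMI compares label vectors up to relabelling, so two species that
systematically occupy *different* modules in lock-step also score high —
it measures affiliation-history predictability, not co-membership frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .community import ModulePartition

__all__ = [
    "nmi",
    "affiliation_matrix",
    "fidelity_matrix",
    "FidelityResult",
    "cluster_species",
    "linkage_to_newick",
]

log = logging.getLogger(__name__)


def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / labels.size
    return float(-(p * np.log(p)).sum())


def nmi(labels_a, labels_b) -> float:
    """Normalized mutual information between two label vectors, in [0, 1].

    Uses natural logarithms (the base cancels) and the arithmetic-mean
    normalization ``2 I / (H_a + H_b)``.  Zero-entropy conventions: both
    vectors constant → 1 (identical up to relabelling); exactly one constant
    → 0 (a constant explains nothing about a varying partner).
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-D of equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 positions to compare labellings")
    h_a, h_b = _entropy(a), _entropy(b)
    if h_a == 0.0 and h_b == 0.0:
        return 1.0
    if h_a == 0.0 or h_b == 0.0:
        return 0.0
    ua, ca = np.unique(a, return_inverse=True)
    ub, cb = np.unique(b, return_inverse=True)
    joint = np.bincount(
        ca * ub.size + cb, minlength=ua.size * ub.size
    ).reshape(ua.size, ub.size).astype(float)
    p = joint / n
    pa = p.sum(axis=1, keepdims=True)
    pb = p.sum(axis=0, keepdims=True)
    nz = p > 0
    info = float((p[nz] * np.log(p[nz] / (pa @ pb)[nz])).sum())
    value = 2.0 * info / (h_a + h_b)
    return float(min(max(value, 0.0), 1.0))


def affiliation_matrix(
    partitions: list[ModulePartition], species: list[str] | None = None
) -> pd.DataFrame:
    """Species x year matrix of module labels (nullable Int64, NA = absent).

    Labels are meaningful only within a column: module 0 of one year has no
    relation to module 0 of another.
    """
    if not partitions:
        raise ValueError("no partitions supplied")
    years = [p.year for p in partitions]
    if len(set(years)) != len(years):
        raise ValueError("duplicate years among partitions")
    if species is None:
        species = sorted({sp for p in partitions for sp in p.assignment})
    affil = pd.DataFrame(index=list(species), columns=years, dtype="Int64")
    for p in sorted(partitions, key=lambda p: p.year):
        for sp, label in p.assignment.items():
            if sp in affil.index:
                affil.loc[sp, p.year] = label
    return affil.sort_index()


@dataclass(frozen=True)
class FidelityResult:
    """Pairwise NMI fidelity with the per-pair year support."""

    values: pd.DataFrame    # species x species NMI; NaN where support < min_years
    n_years: pd.DataFrame   # per-pair overlapping non-missing years
    min_years: int
    excluded_species: tuple[str, ...]

    @property
    def species(self) -> list[str]:
        return list(self.values.index)

    def write_csv(self, path: str | Path) -> None:
        self.values.to_csv(path)

    def pair_value(self, a: str, b: str) -> float:
        return float(self.values.loc[a, b])


def fidelity_matrix(affil: pd.DataFrame, min_years: int = 8) -> FidelityResult:
    """All pairwise NMI values between affiliation rows.

    Each pair is evaluated over its own overlap of non-missing years
    (pairwise-complete); pairs with fewer than ``min_years`` common years are
    left NaN, and species with fewer than ``min_years`` non-missing entries
    overall are excluded up front (logged).  The diagonal is 1 by definition.
    """
    support = affil.notna().sum(axis=1)
    eligible = affil.index[support >= min_years]
    excluded = tuple(affil.index[support < min_years])
    if excluded:
        log.info(
            "species excluded from fidelity (< %d years in modules): %s",
            min_years, list(excluded),
        )
    if len(eligible) < 2:
        raise ValueError("need at least 2 species with enough years in modules")
    sub = affil.loc[eligible]
    s = len(eligible)
    vals = np.eye(s)
    years_n = np.zeros((s, s), dtype=int)
    present = sub.notna().to_numpy()
    labels = sub.to_numpy(dtype=object)
    np.fill_diagonal(years_n, present.sum(axis=1))
    for i in range(s):
        for j in range(i + 1, s):
            both = present[i] & present[j]
            k = int(both.sum())
            years_n[i, j] = years_n[j, i] = k
            if k < min_years:
                vals[i, j] = vals[j, i] = np.nan
                log.warning(
                    "pair (%s, %s): only %d common years (< %d); fidelity missing",
                    eligible[i], eligible[j], k, min_years,
                )
                continue
            v = nmi(labels[i, both].astype(int), labels[j, both].astype(int))
            vals[i, j] = vals[j, i] = v
    frame = pd.DataFrame(vals, index=list(eligible), columns=list(eligible))
    counts = pd.DataFrame(years_n, index=list(eligible), columns=list(eligible))
    return FidelityResult(frame, counts, min_years, excluded)


def cluster_species(
    fid: FidelityResult | pd.DataFrame, cut_height: float = 0.5
) -> tuple[pd.Series, np.ndarray]:
    """Complete-linkage clustering of species on the distance ``1 - nmi``.

    Species involved in any undefined (NaN) pair are dropped with a warning.
    The dendrogram is cut at ``cut_height`` (default 0.5, i.e. clusters keep
    at least 50% pairwise-linkage similarity).  Species are processed in
    lexicographic order so merge tie-breaking is deterministic.  Returns the
    cluster labels (1-based, relabelled in order of first appearance) and the
    scipy linkage matrix of the clustered species.
    """
    values = fid.values if isinstance(fid, FidelityResult) else fid
    values = values.sort_index().sort_index(axis=1)
    incomplete = values.isna().any(axis=1) | values.isna().any(axis=0)
    if incomplete.any():
        log.warning(
            "species dropped from clustering (undefined fidelity pairs): %s",
            list(values.index[incomplete]),
        )
        values = values.loc[~incomplete, ~incomplete]
    if len(values) < 2:
        raise ValueError("need at least 2 species with complete fidelity")
    dist = 1.0 - values.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = hierarchy.linkage(squareform(dist, checks=False), method="complete")
    flat = hierarchy.fcluster(z, t=cut_height, criterion="distance")
    # stable relabelling: cluster ids in order of first species appearance
    seen: dict[int, int] = {}
    labels = []
    for c in flat:
        if c not in seen:
            seen[c] = len(seen) + 1
        labels.append(seen[c])
    return pd.Series(labels, index=values.index, name="cluster"), z


def linkage_to_newick(z: np.ndarray, leaf_names: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(z)

    def _fmt(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{leaf_names[node.id].replace(' ', '_')}:{length:.6g}"
        left = _fmt(node.left, node.dist)
        right = _fmt(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return _fmt(tree, tree.dist) + ";"
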