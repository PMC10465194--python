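"""Distance-matrix PERMANOVA for trait-based partitioning of fidelity.

Similarity (NMI) is converted to the distance ``d = 1 - nmi`` and
partitioned among categorical factors — wintering area, foraging niche —
with the permutational multivariate analysis of variance: Gower-center the
squared distances, project onto dummy-coded factor designs, and compare the
observed pseudo-F per term against its distribution under joint row/column
permutations of the distance matrix.  Sums of squares are sequential
(each term adjusted for those before it), matching the conventional
by-terms decomposition of the two-factor analysis.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .network import holm_adjust

__all__ = [
    "gower_center",
    "permanova",
    "pairwise_permanova",
    "PermanovaResult",
    "drop_singleton_levels",
]

log = logging.getLogger(__name__)


def gower_center(d: np.ndarray) -> np.ndarray:
    """Gower's double-centered matrix ``G = C (-D∘D/2) C``.

    ``C = I - J/n`` is the centering matrix; the trace of ``G`` equals the
    total sum of squares ``(1/n) * sum_{i<j} d_ij^2``.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    n = d.shape[0]
    a = -0.5 * d**2
    c = np.eye(n) - np.ones((n, n)) / n
    return c @ a @ c


def _dummy(codes: np.ndarray, n_levels: int) -> np.ndarray:
    out = np.zeros((codes.size, n_levels))
    out[np.arange(codes.size), codes] = 1.0
    return out


def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x.T @ x) @ x.T


@dataclass(frozen=True)
class PermanovaResult:
    """Sequential PERMANOVA table for one distance matrix."""

    table: pd.DataFrame  # rows: terms, Residual, Total; cols: df, SS, R2, F, p
    n_perm: int
    seed: int | None
    n: int

    def term(self, name: str) -> pd.Series:
        return self.table.loc[name]

    def to_dict(self) -> dict:
        out = {}
        for name, row in self.table.iterrows():
            out[name] = {
                k: (None if pd.isna(v) else float(v)) for k, v in row.items()
            }
        out["n_perm"] = self.n_perm
        out["n"] = self.n
        return out

    def write_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index_label="term")


def _term_stats(
    g: np.ndarray, hats: list[np.ndarray], dfs: list[int], df_res: int
) -> tuple[np.ndarray, float, np.ndarray]:
    """Sequential SS per term, residual SS and per-term pseudo-F for one G.

    Numerically tiny sums of squares (relative to the total) are clamped to
    zero so a perfectly separated design yields F = inf for a real term and
    F = nan (not a spurious value) for a null term over a zero residual.
    """
    ss_total = float(np.trace(g))
    cum = [float(np.sum(h * g)) for h in hats]  # tr(H G)
    ss_terms = np.diff([0.0] + cum)
    ss_res = ss_total - cum[-1]
    tol = 1e-12 * max(ss_total, 1.0)
    ss_terms[np.abs(ss_terms) < tol] = 0.0
    if abs(ss_res) < tol:
        ss_res = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_terms / np.asarray(dfs)) / (ss_res / df_res)
    return ss_terms, ss_res, f


def permanova(
    d: pd.DataFrame | np.ndarray,
    traits: pd.DataFrame | None = None,
    terms: tuple[str, ...] = ("wintering_area", "foraging_niche"),
    n_perm: int = 9999,
    seed: int | None = 0,
    grouping: dict[str, np.ndarray] | None = None,
    exact: bool = False,
) -> PermanovaResult:
    """Sequential (by-terms) PERMANOVA of a distance matrix on factors.

    Parameters
    ----------
    d:
        Symmetric distance matrix; a DataFrame is aligned to ``traits`` by
        its index.
    traits:
        Factor table indexed like ``d`` (e.g. the species-trait table).
    terms:
        Ordered factor names; each term's sum of squares is adjusted for the
        terms before it.
    n_perm, seed:
        Monte-Carlo permutations and RNG seed; p-values use the
        ``(exceedances + 1) / (n_perm + 1)`` convention.
    grouping:
        Alternative to ``traits``: mapping term → level array (already
        aligned with ``d``).
    exact:
        Enumerate all ``n!`` permutations instead of sampling (small n only);
        p-values are then exact proportions without the +1 convention.
    """
    if isinstance(d, pd.DataFrame):
        labels = list(d.index)
        if traits is not None:
            missing = [s for s in labels if s not in traits.index]
            if missing:
                raise ValueError(f"traits missing for: {missing}")
        dmat = d.to_numpy(dtype=float)
    else:
        labels = None
        dmat = np.asarray(d, dtype=float)
    n = dmat.shape[0]

    factors: dict[str, np.ndarray] = {}
    for term in terms:
        if grouping is not None:
            lv = np.asarray(grouping[term])
        elif traits is not None:
            lv = traits.loc[labels, term].to_numpy()
        else:
            raise ValueError("supply either traits or grouping")
        factors[term] = lv
        counts = pd.Series(lv).value_counts()
        if (counts < 2).any():
            small = list(counts.index[counts < 2])
            raise ValueError(
                f"factor {term!r} has singleton level(s) {small}; drop them "
                "first (see drop_singleton_levels)"
            )

    g = gower_center(dmat)
    # cumulative dummy-coded designs with intercept
    design = np.ones((n, 1))
    hats: list[np.ndarray] = []
    dfs: list[int] = []
    rank_prev = 1
    for term in terms:
        levels, codes = np.unique(factors[term], return_inverse=True)
        design = np.hstack([design, _dummy(codes, len(levels))])
        rank = np.linalg.matrix_rank(design)
        df_t = len(levels) - 1
        if rank - rank_prev < df_t:
            raise ValueError(f"factor {term!r} is aliased with earlier terms")
        rank_prev = rank
        dfs.append(df_t)
        hats.append(_hat(design))
    df_res = n - 1 - sum(dfs)
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    ss_terms, ss_res, f_obs = _term_stats(g, hats, dfs, df_res)
    ss_total = float(np.trace(g))

    if exact:
        if n > 8:
            raise ValueError("exact enumeration is limited to n <= 8")
        perms = list(itertools.permutations(range(n)))
        exceed = np.zeros(len(terms))
        for perm in perms:
            pg = g[np.ix_(perm, perm)]
            _, _, f_p = _term_stats(pg, hats, dfs, df_res)
            exceed += f_p >= f_obs - 1e-12
        pvals = exceed / math.factorial(n)
        n_used = len(perms)
    else:
        rng = np.random.default_rng(seed)
        exceed = np.zeros(len(terms))
        for _ in range(n_perm):
            perm = rng.permutation(n)
            pg = g[np.ix_(perm, perm)]
            _, _, f_p = _term_stats(pg, hats, dfs, df_res)
            exceed += f_p >= f_obs - 1e-12
        pvals = (exceed + 1.0) / (n_perm + 1.0)
        n_used = n_perm
    pvals = np.where(np.isnan(f_obs), np.nan, pvals)

    def _r2(ss: float) -> float:
        return float(np.clip(ss / ss_total, 0.0, 1.0)) if ss_total > 0 else 0.0

    rows = []
    for i, term in enumerate(terms):
        rows.append(
            (term, dfs[i], ss_terms[i], _r2(ss_terms[i]), f_obs[i], pvals[i])
        )
    rows.append(("Residual", df_res, ss_res, _r2(ss_res), np.nan, np.nan))
    rows.append(("Total", n - 1, ss_total, 1.0, np.nan, np.nan))
    table = pd.DataFrame(
        rows, columns=["term", "df", "SS", "R2", "F", "p"]
    ).set_index("term")
    return PermanovaResult(table=table, n_perm=n_used, seed=seed, n=n)


def drop_singleton_levels(
    traits: pd.DataFrame, factor: str, species: list[str] | None = None
) -> list[str]:
    """Species whose level of ``factor`` has at least two members.

    Mirrors the exclusion of single-species categories from the trait
    analysis; the dropped species are logged.
    """
    sub = traits if species is None else traits.loc[species]
    counts = sub[factor].value_counts()
    singleton_levels = set(counts.index[counts < 2])
    if singleton_levels:
        dropped = list(sub.index[sub[factor].isin(singleton_levels)])
        log.info(
            "factor %r: singleton level(s) %s excluded (species %s)",
            factor, sorted(singleton_levels), dropped,
        )
    return list(sub.index[~sub[factor].isin(singleton_levels)])


def pairwise_permanova(
    d: pd.DataFrame,
    traits: pd.DataFrame,
    factor: str,
    pairs: list[tuple[str, str]] | None = None,
    n_perm: int = 9999,
    seed: int | None = 0,
) -> pd.DataFrame:
    """One-factor PERMANOVA restricted to each pair of factor levels.

    Levels with fewer than two species are skipped with a warning; p-values
    are Holm-adjusted across the tested pairs.  Returns a table with columns
    ``level_a, level_b, n, F, p_raw, p_adj``.
    """
    lv = traits.loc[d.index, factor]
    counts = lv.value_counts()
    usable = [l for l in counts.index if counts[l] >= 2]
    skipped = [l for l in counts.index if counts[l] < 2]
    if pairs is None:
        pairs = list(itertools.combinations(sorted(usable), 2))
    rows = []
    kept_pairs = []
    for a, b in pairs:
        if a in skipped or b in skipped or a not in counts or b not in counts:
            log.warning(
                "pairwise contrast (%s, %s) skipped: singleton or unknown level",
                a, b,
            )
            continue
        members = list(lv.index[lv.isin([a, b])])
        sub = d.loc[members, members]
        res = permanova(
            sub, traits, terms=(factor,), n_perm=n_perm, seed=seed
        )
        rows.append(
            (a, b, len(members), res.term(factor)["F"], res.term(factor)["p"])
        )
        kept_pairs.append((a, b))
    out = pd.DataFrame(rows, columns=["level_a", "level_b", "n", "F", "p_raw"])
    out["p_adj"] = holm_adjust(out["p_raw"].to_numpy()) if len(out) else []
    return out
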