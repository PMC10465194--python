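"""Yearly temporal co-occurrence networks from lag-1 Spearman correlations.

For one season, every ordered species pair *(a, b)* is scored by the Spearman
rank correlation between the abundance of *a* on day *t* and of *b* on day
*t − 1* — species *b* leading *a* by one day.  Low-abundance species (season
total below the 25th percentile) are removed first; the family of raw
p-values of all ordered pairs tested within the year is adjusted by the
step-down Bonferroni–Holm procedure; an undirected, unweighted link is placed
whenever a direction exceeds the correlation threshold (default ``r > 0.5``)
at adjusted significance (default ``p < 0.05``).

Missing-effort days drop out pairwise: a lag pair is used only when both day
*t* and day *t − 1* had trapping effort.  Zero counts participate in the
ranking as ties — a day without captures is informative about co-occurrence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import SeasonCounts

__all__ = [
    "CoocNetwork",
    "filter_low_abundance",
    "spearman_lag1",
    "holm_adjust",
    "fdr_adjust",
    "build_network",
]

log = logging.getLogger(__name__)

SYMMETRIZATIONS = ("or", "and", "max")


class EmptyNetworkError(ValueError):
    """All species filtered out, or too few left to build a network."""


def filter_low_abundance(
    counts: SeasonCounts,
    q: float = 0.25,
    reference_totals: np.ndarray | None = None,
) -> list[str]:
    """Species whose season total reaches the ``q``-quantile threshold.

    The threshold is the linear-interpolation quantile of the reference total
    distribution — by default this season's own species totals; pass pooled
    totals from all years via ``reference_totals`` to use a global threshold.
    Species never captured in the season (total zero) are always dropped:
    their series is constant and carries no rank signal.
    """
    if counts.n_species < 4:
        raise ValueError("need at least 4 species to apply the abundance filter")
    totals = counts.totals
    ref = totals if reference_totals is None else np.asarray(reference_totals, float)
    threshold = float(np.quantile(ref, q))
    retained = [
        sp
        for sp, tot in zip(counts.species, totals)
        if tot >= threshold and tot > 0
    ]
    if not retained:
        raise EmptyNetworkError(f"empty network: all species filtered in {counts.year}")
    return retained


def spearman_lag1(
    a: np.ndarray,
    b: np.ndarray,
    valid: np.ndarray | None = None,
    min_pairs: int = 10,
) -> tuple[float, float]:
    """Lag-1 Spearman correlation of ``a`` at *t* against ``b`` at *t − 1*.

    ``valid`` marks days with trapping effort; a lag pair needs both of its
    days valid.  Returns ``(rho, p)`` with the two-sided t-approximation
    p-value; ``(nan, nan)`` when either aligned series is constant (rank
    correlation undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and share the same day grid")
    if valid is None:
        valid = np.ones(a.shape, dtype=bool)
    pair_ok = valid[1:] & valid[:-1]
    x = a[1:][pair_ok]
    y = b[:-1][pair_ok]
    if x.size < min_pairs:
        raise ValueError(
            f"only {x.size} valid lag pairs; need at least {min_pairs}"
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (float("nan"), float("nan"))
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def holm_adjust(p_values) -> np.ndarray:
    """Step-down Bonferroni–Holm adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (q-value-style FDR alternative)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class CoocNetwork:
    """Per-year undirected co-occurrence network with its correlation audit.

    ``rho[i, j]`` is the lag-1 Spearman correlation of species ``i`` at *t*
    with species ``j`` at *t − 1* (``j`` leading ``i``); ``p_raw`` / ``p_adj``
    match element-wise.  Diagonals and untestable pairs are NaN.  ``edges``
    are unordered retained-species index pairs satisfying the link rule.
    """

    year: int
    species: tuple[str, ...]
    rho: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    edges: frozenset[frozenset[int]]
    r_min: float = 0.5
    alpha: float = 0.05
    symmetrization: str = "or"

    @property
    def n_nodes(self) -> int:
        return len(self.species)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_list(self) -> list[tuple[str, str]]:
        pairs = sorted(tuple(sorted(e)) for e in self.edges)
        return [(self.species[i], self.species[j]) for i, j in pairs]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(year=self.year)
        g.add_nodes_from(self.species)
        g.add_edges_from(self.edge_list())
        return g

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def write_edgelist(self, path: str | Path) -> None:
        pd.DataFrame(
            [(self.year, a, b) for a, b in self.edge_list()],
            columns=["year", "species_a", "species_b"],
        ).to_csv(path, index=False)

    def audit_table(self) -> pd.DataFrame:
        """Long-form record of every tested ordered pair."""
        rows = []
        n = self.n_nodes
        for i in range(n):
            for j in range(n):
                if i == j or np.isnan(self.p_raw[i, j]):
                    continue
                passed = (
                    self.rho[i, j] > self.r_min and self.p_adj[i, j] < self.alpha
                )
                rows.append(
                    (
                        self.species[i],
                        self.species[j],
                        f"{self.species[j]} -> {self.species[i]}",
                        self.rho[i, j],
                        self.p_raw[i, j],
                        self.p_adj[i, j],
                        passed,
                    )
                )
        return pd.DataFrame(
            rows,
            columns=[
                "species_current",
                "species_leading",
                "direction",
                "rho",
                "p_raw",
                "p_adj",
                "passed",
            ],
        )

    def write_audit(self, path: str | Path) -> None:
        self.audit_table().to_csv(path, index=False)


def _rank_rows(m: np.ndarray) -> np.ndarray:
    return stats.rankdata(m, axis=1)


def build_network(
    counts: SeasonCounts,
    r_min: float = 0.5,
    alpha: float = 0.05,
    q: float = 0.25,
    symmetrization: str = "or",
    min_pairs: int = 10,
    reference_totals: np.ndarray | None = None,
    adjust: str = "holm",
    missing_policy: str = "drop",
) -> CoocNetwork:
    """Infer one year's co-occurrence network.

    Computes the full directed lag-1 rank-correlation matrix over the
    retained species, Holm-adjusts the family of all tested ordered pairs of
    the year (``adjust="fdr"`` switches to Benjamini–Hochberg), then places
    undirected links: with the default ``"or"`` rule an edge appears if either
    direction has ``rho > r_min`` and adjusted ``p < alpha``; ``"and"``
    requires both; ``"max"`` tests only the direction with the larger rho.

    ``missing_policy`` controls missing-effort days: ``"drop"`` (default)
    removes every lag pair touching a closed-nets day, ``"zero"`` keeps them
    as zero counts (treating closed nets as absence).
    """
    if symmetrization not in SYMMETRIZATIONS:
        raise ValueError(f"symmetrization must be one of {SYMMETRIZATIONS}")
    retained = filter_low_abundance(counts, q=q, reference_totals=reference_totals)
    if len(retained) < 3:
        raise EmptyNetworkError(
            f"{counts.year}: only {len(retained)} species retained; need >= 3"
        )
    if missing_policy not in ("drop", "zero"):
        raise ValueError("missing_policy must be 'drop' or 'zero'")
    idx = [counts.species.index(sp) for sp in retained]
    mat = counts.counts[idx].astype(float)
    valid = (
        counts.effort_mask
        if missing_policy == "drop"
        else np.ones(counts.n_days, dtype=bool)
    )
    pair_ok = valid[1:] & valid[:-1]
    n_pairs = int(pair_ok.sum())
    if n_pairs < min_pairs:
        raise ValueError(
            f"{counts.year}: only {n_pairs} valid lag day-pairs; need {min_pairs}"
        )
    cur = mat[:, 1:][:, pair_ok]   # species value on day t
    lag = mat[:, :-1][:, pair_ok]  # species value on day t-1

    r_cur = _rank_rows(cur)
    r_lag = _rank_rows(lag)

    def _standardize(r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mean = r.mean(axis=1, keepdims=True)
        sd = r.std(axis=1, keepdims=True)
        const = sd[:, 0] == 0
        sd[const] = 1.0
        return (r - mean) / sd, const

    z_cur, const_cur = _standardize(r_cur)
    z_lag, const_lag = _standardize(r_lag)
    if const_cur.any():
        log.info(
            "%s: constant series excluded from correlation: %s",
            counts.year,
            [retained[i] for i in np.flatnonzero(const_cur)],
        )

    s = len(retained)
    rho = (z_cur @ z_lag.T) / n_pairs  # rho[i, j]: j leads i
    rho = np.clip(rho, -1.0, 1.0)
    undef = const_cur[:, None] | const_lag[None, :]
    rho[undef] = np.nan
    np.fill_diagonal(rho, np.nan)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n_pairs - 2) / (1.0 - rho**2))
    p_raw = 2.0 * stats.t.sf(np.abs(t), df=n_pairs - 2)
    p_raw[np.isinf(t)] = 0.0  # |rho| == 1
    p_raw[np.isnan(rho)] = np.nan

    tested = ~np.isnan(p_raw)
    p_adj = np.full_like(p_raw, np.nan)
    adjust_fn = {"holm": holm_adjust, "fdr": fdr_adjust}[adjust]
    if tested.any():
        p_adj[tested] = adjust_fn(p_raw[tested])

    with np.errstate(invalid="ignore"):
        passed = (rho > r_min) & (p_adj < alpha) & tested
    edges: set[frozenset[int]] = set()
    for i in range(s):
        for j in range(i + 1, s):
            if symmetrization == "or":
                hit = passed[i, j] or passed[j, i]
            elif symmetrization == "and":
                hit = passed[i, j] and passed[j, i]
            else:  # max-rho direction only
                both = [rho[i, j], rho[j, i]]
                if np.all(np.isnan(both)):
                    hit = False
                else:
                    d = int(np.nanargmax(both))
                    hit = passed[i, j] if d == 0 else passed[j, i]
            if hit:
                edges.add(frozenset((i, j)))

    return CoocNetwork(
        year=counts.year,
        species=tuple(retained),
        rho=rho,
        p_raw=p_raw,
        p_adj=p_adj,
        edges=frozenset(edges),
        r_min=r_min,
        alpha=alpha,
        symmetrization=symmetrization,
    )
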