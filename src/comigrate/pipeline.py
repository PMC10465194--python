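"""Config-driven orchestration of the full co-migration analysis.

Stages — simulate (optional) → per-year network inference → Louvain
partitions → modularity trend → fidelity matrix and clustering → PERMANOVA —
communicate through plain CSV/JSON artifacts in a run directory, so each
stage can also be run standalone from the command line.  A single global
seed derives independent per-stage seeds by stage-name hashing, making every
stage and the final JSON report reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import io
from .community import ModulePartition, louvain
from .fidelity import (
    FidelityResult,
    affiliation_matrix,
    cluster_species,
    fidelity_matrix,
    linkage_to_newick,
    nmi,
)
from .network import SYMMETRIZATIONS, CoocNetwork, EmptyNetworkError, build_network
from .permanova import drop_singleton_levels, pairwise_permanova
from .permanova import permanova as _permanova
from .simulate import SimScenario, default_scenario
from .simulate import simulate as _simulate
from .trend import TrendResult, analyze_trend

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "stage_seed"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending unit."""


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed derived from the global seed by stage-name hashing."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    """All knobs of one analysis run; round-trips through YAML."""

    outdir: str = "run"
    seed: int = 1
    # inputs
    simulate: bool = True
    scenario: str | None = None
    counts: str | None = None
    traits: str | None = None
    layout: str = "long"
    # network inference
    filter_q: float = 0.25
    quantile_reference: str = "per_year"  # or "pooled"
    r_min: float = 0.5
    alpha: float = 0.05
    symmetrization: str = "or"
    adjust: str = "holm"
    missing_policy: str = "drop"
    min_pairs: int = 10
    # community detection
    louvain_restarts: int = 20
    # trend
    sma_max_order: int | None = None
    trend_mode: str = "raw"
    # fidelity
    min_years: int = 8
    cut_height: float = 0.5
    # group partitioning
    permanova_terms: tuple[str, ...] = ("wintering_area", "foraging_niche")
    n_perm: int = 9999
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.permanova_terms = tuple(self.permanova_terms)
        if not 0.0 <= self.filter_q < 1.0:
            raise ValueError("filter_q must be in [0, 1)")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        if self.symmetrization not in SYMMETRIZATIONS:
            raise ValueError(f"symmetrization must be one of {SYMMETRIZATIONS}")
        if self.missing_policy not in ("drop", "zero"):
            raise ValueError("missing_policy must be 'drop' or 'zero'")
        if self.quantile_reference not in ("per_year", "pooled"):
            raise ValueError("quantile_reference must be 'per_year' or 'pooled'")
        if self.trend_mode not in ("raw", "smoothed"):
            raise ValueError("trend_mode must be 'raw' or 'smoothed'")
        if not 0.0 <= self.cut_height <= 1.0:
            raise ValueError("cut_height must be in [0, 1]")
        if not self.simulate and self.counts is None:
            raise ValueError("provide counts or set simulate=True")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {**dataclasses.asdict(self),
                 "permanova_terms": list(self.permanova_terms)},
                sort_keys=True,
            )
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _round_floats(obj, sig: int = 12):
    """Recursively normalize floats to 12 significant digits for stable JSON."""
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}") if np.isfinite(obj) else None
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), sig)
    return obj


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(_round_floats(obj), indent=2, sort_keys=True) + "\n"
    )


def _outdir(cfg: RunConfig) -> Path:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"missing upstream artifact {path.name}; run the {producer!r} "
            f"subcommand (or stage) first"
        )
    return path


# --------------------------------------------------------------------------
# stages


def run_simulate(cfg: RunConfig) -> list[io.SeasonCounts]:
    """Generate the synthetic scenario and write its artifacts.

    Uses the scenario file named by ``cfg.scenario`` when given, otherwise
    the default study-scale scenario seeded from the global seed.  The
    scenario actually used is echoed to ``scenario.yaml``.
    """
    out = _outdir(cfg)
    if cfg.scenario:
        scenario = SimScenario.load(cfg.scenario)
    else:
        scenario = default_scenario(stage_seed(cfg.seed, "simulate"))
    seasons, truth = _simulate(scenario)
    scenario.save(out / "scenario.yaml")
    io.write_counts(seasons, out / "counts.csv", layout=cfg.layout)
    io.load_ponza_traits().to_csv(out / "traits.csv")
    pd.DataFrame(
        sorted(truth.items()), columns=["species", "group"]
    ).to_csv(out / "ground_truth.csv", index=False)
    return seasons


def _load_inputs(cfg: RunConfig) -> tuple[list[io.SeasonCounts], pd.DataFrame]:
    out = _outdir(cfg)
    counts_path = Path(cfg.counts) if cfg.counts else _require(
        out / "counts.csv", "simulate"
    )
    seasons = io.read_counts(counts_path, layout=cfg.layout)
    traits_path = Path(cfg.traits) if cfg.traits else out / "traits.csv"
    all_species = sorted({sp for sc in seasons for sp in sc.species})
    traits = (
        io.read_species_meta(traits_path, required_species=all_species)
        if traits_path.exists()
        else None
    )
    return seasons, traits


def run_infer(cfg: RunConfig) -> list[CoocNetwork]:
    """Build one co-occurrence network per year and write graph artifacts."""
    out = _outdir(cfg)
    seasons, _ = _load_inputs(cfg)
    ref = None
    if cfg.quantile_reference == "pooled":
        ref = np.concatenate([sc.totals for sc in seasons])
    nets = []
    (out / "networks").mkdir(exist_ok=True)
    for sc in seasons:
        try:
            net = build_network(
                sc,
                r_min=cfg.r_min,
                alpha=cfg.alpha,
                q=cfg.filter_q,
                symmetrization=cfg.symmetrization,
                min_pairs=cfg.min_pairs,
                reference_totals=ref,
                adjust=cfg.adjust,
                missing_policy=cfg.missing_policy,
            )
            if net.n_edges == 0:
                raise EmptyNetworkError(f"empty network: year {sc.year}")
        except Exception as e:
            raise PipelineError(f"network stage failed for year {sc.year}: {e}") from e
        net.write_graphml(out / "networks" / f"network_{sc.year}.graphml")
        net.write_edgelist(out / "networks" / f"edges_{sc.year}.csv")
        net.write_audit(out / "networks" / f"audit_{sc.year}.csv")
        nets.append(net)
    return nets


def _read_networks(out: Path) -> list[tuple[int, list, list]]:
    ndir = _require(out / "networks", "infer")
    items = []
    for path in sorted(ndir.glob("network_*.graphml")):
        g = nx.read_graphml(path)
        year = int(path.stem.split("_")[1])
        items.append((year, sorted(g.nodes), sorted(map(tuple, map(sorted, g.edges)))))
    if not items:
        raise PipelineError("no networks found; run the 'infer' subcommand first")
    return items


def run_modularity(cfg: RunConfig) -> list[ModulePartition]:
    """Louvain-partition every yearly network; write partition tables."""
    out = _outdir(cfg)
    parts = []
    for year, nodes, edges in _read_networks(out):
        try:
            part = louvain(
                (nodes, edges),
                seed=stage_seed(cfg.seed, f"louvain:{year}"),
                restarts=cfg.louvain_restarts,
                year=year,
            )
        except Exception as e:
            raise PipelineError(
                f"modularity stage failed for year {year}: {e}"
            ) from e
        parts.append(part)
    long = pd.concat(
        [p.to_frame().assign(year=p.year) for p in parts], ignore_index=True
    )[["year", "species", "module"]]
    long.to_csv(out / "partitions.csv", index=False)
    pd.DataFrame(
        {
            "year": [p.year for p in parts],
            "Q": [p.Q for p in parts],
            "n_modules": [p.n_modules for p in parts],
            "is_strongly_modular": [p.is_strongly_modular for p in parts],
        }
    ).to_csv(out / "modularity.csv", index=False)
    return parts


def run_trend(cfg: RunConfig) -> TrendResult:
    """Trend-test the yearly modularity series."""
    out = _outdir(cfg)
    mod = pd.read_csv(_require(out / "modularity.csv", "modularity"))
    try:
        result = analyze_trend(
            mod["year"], mod["Q"], max_order=cfg.sma_max_order, mode=cfg.trend_mode
        )
    except Exception as e:
        raise PipelineError(f"trend stage failed: {e}") from e
    write_json(result.to_dict(), out / "trend.json")
    result.write_smoothed_csv(out / "smoothed.csv")
    return result


def run_fidelity(cfg: RunConfig) -> tuple[FidelityResult, pd.Series]:
    """Affiliation matrix → pairwise NMI → complete-linkage clusters."""
    out = _outdir(cfg)
    parts_df = pd.read_csv(_require(out / "partitions.csv", "modularity"))
    parts = [
        ModulePartition(
            year=int(year),
            assignment=dict(zip(block["species"], block["module"].astype(int))),
            Q=float("nan"),
            n_modules=block["module"].nunique(),
            seed=cfg.seed,
            restarts=cfg.louvain_restarts,
        )
        for year, block in parts_df.groupby("year")
    ]
    try:
        affil = affiliation_matrix(parts)
        fid = fidelity_matrix(affil, min_years=cfg.min_years)
        clusters, linkage = cluster_species(fid, cut_height=cfg.cut_height)
    except Exception as e:
        raise PipelineError(f"fidelity stage failed: {e}") from e
    affil.to_csv(out / "affiliation.csv")
    fid.write_csv(out / "fidelity.csv")
    clusters.rename_axis("species").reset_index().to_csv(
        out / "clusters.csv", index=False
    )
    (out / "dendrogram.nwk").write_text(
        linkage_to_newick(linkage, list(clusters.index)) + "\n"
    )
    return fid, clusters


def run_permanova(cfg: RunConfig) -> dict:
    """Partition fidelity distances by the trait factors."""
    out = _outdir(cfg)
    fid = pd.read_csv(_require(out / "fidelity.csv", "fidelity"), index_col=0)
    traits_path = Path(cfg.traits) if cfg.traits else _require(
        out / "traits.csv", "simulate"
    )
    traits = io.read_species_meta(traits_path)
    complete = fid.index[~fid.isna().any(axis=1)]
    d_arr = (1.0 - fid.loc[complete, complete]).to_numpy(dtype=float)
    np.fill_diagonal(d_arr, 0.0)
    dist = pd.DataFrame(d_arr, index=complete, columns=complete)

    try:
        keep = list(complete)
        for term in cfg.permanova_terms:
            keep = drop_singleton_levels(traits, term, keep)
        overall = _permanova(
            dist.loc[keep, keep],
            traits,
            terms=cfg.permanova_terms,
            n_perm=cfg.n_perm,
            seed=stage_seed(cfg.seed, "permanova"),
        )
        pairwise = {}
        for term in cfg.permanova_terms:
            pairwise[term] = pairwise_permanova(
                dist,
                traits,
                term,
                n_perm=cfg.n_perm,
                seed=stage_seed(cfg.seed, f"permanova:{term}"),
            )
    except Exception as e:
        raise PipelineError(f"permanova stage failed: {e}") from e

    overall.write_csv(out / "permanova.csv")
    for term, table in pairwise.items():
        table.to_csv(out / f"pairwise_{term}.csv", index=False)
    result = {"overall": overall.to_dict(), "pairwise": {
        term: table.to_dict(orient="records") for term, table in pairwise.items()
    }}
    write_json(result, out / "permanova.json")
    return result


def _group_mean_nmi(fid: FidelityResult, groups: pd.Series) -> dict:
    """Mean off-diagonal NMI among species sharing each group label."""
    out = {}
    vals = fid.values
    for level in sorted(groups.dropna().unique()):
        members = [s for s in vals.index if groups.get(s) == level]
        if len(members) < 2:
            continue
        block = vals.loc[members, members].to_numpy(dtype=float)
        iu = np.triu_indices(len(members), k=1)
        pair_vals = block[iu]
        pair_vals = pair_vals[~np.isnan(pair_vals)]
        if pair_vals.size:
            out[str(level)] = float(pair_vals.mean())
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage in order and write the headline JSON report."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = _outdir(cfg)
    cfg.to_yaml(out / "config.yaml")
    log.info(
        "analysis choices: quantile_reference=%s symmetrization=%s adjust=%s "
        "trend_mode=%s min_years=%d",
        cfg.quantile_reference, cfg.symmetrization, cfg.adjust,
        cfg.trend_mode, cfg.min_years,
    )
    if cfg.simulate:
        run_simulate(cfg)
    nets = run_infer(cfg)
    parts = run_modularity(cfg)
    tr = run_trend(cfg)
    fid, clusters = run_fidelity(cfg)
    perm = run_permanova(cfg)

    traits_path = Path(cfg.traits) if cfg.traits else out / "traits.csv"
    traits = io.read_species_meta(traits_path) if traits_path.exists() else None

    report: dict = {
        "config": {**dataclasses.asdict(cfg),
                   "permanova_terms": list(cfg.permanova_terms)},
        "years": {
            str(p.year): {
                "Q": p.Q,
                "n_modules": p.n_modules,
                "is_strongly_modular": p.is_strongly_modular,
                "n_nodes": n.n_nodes,
                "n_edges": n.n_edges,
            }
            for p, n in zip(parts, nets)
        },
        "modularity": {
            "mean_Q": float(np.mean([p.Q for p in parts])),
            "sd_Q": float(np.std([p.Q for p in parts], ddof=1)),
            "min_Q": float(np.min([p.Q for p in parts])),
            "max_Q": float(np.max([p.Q for p in parts])),
            "share_strongly_modular": float(
                np.mean([p.is_strongly_modular for p in parts])
            ),
        },
        "trend": tr.to_dict(),
        "fidelity": {
            "n_species": len(fid.species),
            "n_clusters": int(clusters.nunique()),
            "mean_nmi": float(
                np.nanmean(
                    fid.values.to_numpy()[
                        np.triu_indices(len(fid.species), k=1)
                    ]
                )
            ),
        },
        "permanova": perm,
    }
    if traits is not None:
        report["fidelity"]["mean_nmi_by_wintering_area"] = _group_mean_nmi(
            fid, traits["wintering_area"]
        )
        report["fidelity"]["mean_nmi_by_foraging_niche"] = _group_mean_nmi(
            fid, traits["foraging_niche"]
        )
    truth_path = out / "ground_truth.csv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path).set_index("species")["group"]
        common = [s for s in clusters.index if s in truth.index]
        if len(common) >= 2:
            report["recovery"] = {
                "n_clustered": len(common),
                "nmi_vs_planted": nmi(
                    clusters.loc[common].to_numpy(),
                    truth.loc[common].to_numpy(),
                ),
            }
    write_json(report, out / "report.json")
    manifest = sorted(
        str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()
        and p.name != "manifest.json"
    )
    write_json({"files": manifest}, out / "manifest.json")
    return report
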