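"""End-to-end orchestration: record tables → site models → scenario grid.

``run_estimation`` reads the five delimited record tables, estimates every
component (fate profiles, germination rates, binned kernels, escape
curves), and assembles one validated recruitment model per site.
``run_scenarios`` feeds the intact-site model through the disperser-loss ×
predator-scenario grid and renders the results as delimited text, JSON and
a figure.  All report numbers are operation outputs; the report layer only
rounds (RS to 2 decimals, deltas to 1).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

from . import escape as escape_mod
from . import estimators, kernels, scenarios
from .estimators import SeedFateProfile
from .model_core import (
    SPAT_OUT,
    UNDISPERSED,
    DistanceKernel,
    SeedFatePathway,
    SiteRecruitmentModel,
    model_to_dict,
    recruitment_success,
)
from .synthetic_data import defecated_treatment

__all__ = [
    "PipelineConfig",
    "EstimationResult",
    "run_estimation",
    "run_scenarios",
    "default_config",
    "load_config",
    "save_config",
]

logger = logging.getLogger("seedfate")


@dataclass
class PipelineConfig:
    """Everything a reproducible pipeline run needs, serializable to YAML."""

    tables: dict[str, str]  # focal/germination/distances/survival[/cameras] paths
    sites: list[str]
    intact_site: str
    loss_order: list[str]  # largest- to smallest-bodied disperser
    predator_curve_sites: dict[str, str]  # scenario name -> site whose curve applies
    compensation_sources: dict[str, str]  # "+"-joined lost dispersers -> source site
    germination_treatments: dict[str, str] = field(default_factory=dict)
    pool_germination_across_sites: bool = True
    bin_width_m: float = 5.0
    n_boot: int = 1000
    rng_seed: int = 0
    outdir: str = "seedfate-out"

    def treatment_for(self, disperser: str) -> str:
        return self.germination_treatments.get(disperser, defecated_treatment(disperser))


@dataclass
class EstimationResult:
    """Per-site models plus the intermediate component estimates."""

    models: dict[str, SiteRecruitmentModel]
    profiles: dict[str, SeedFateProfile]
    germination: dict[str, estimators.GerminationEstimate]
    kernels: dict[str, DistanceKernel]
    escape_curves: dict[str, object]


def default_config(data_dir: str, outdir: str = "seedfate-out", rng_seed: int = 0) -> PipelineConfig:
    """Configuration matching the default synthetic dataset layout."""
    return PipelineConfig(
        tables={
            name: os.path.join(data_dir, f"{name}.tsv")
            for name in ("focal", "germination", "distances", "survival", "cameras")
        },
        sites=["intact", "moderate", "defaunated"],
        intact_site="intact",
        loss_order=["muriqui", "howler", "jacutinga"],
        predator_curve_sites={
            # the disperser-intact site is the most predator-defaunated one,
            # so the "complete predators" curve comes from the moderate site
            "complete": "moderate",
            "no_peccaries": "defaunated",
            "no_peccaries_no_agoutis": "intact",
        },
        compensation_sources={
            "muriqui": "moderate",
            "muriqui+howler": "defaunated",
        },
        rng_seed=rng_seed,
        outdir=outdir,
    )


def load_config(path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return PipelineConfig(**doc)


def save_config(config: PipelineConfig, path) -> None:
    from dataclasses import asdict

    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


def run_estimation(config: PipelineConfig) -> EstimationResult:
    """Estimate all components and assemble one recruitment model per site.

    Any schema violation in an input table aborts with a row-level
    diagnostic from the reader; a missing survival distance class or a
    disperser with no distance sample aborts with the offending name.
    """
    focal = estimators.read_focal_table(config.tables["focal"])
    germ = estimators.read_germination_table(config.tables["germination"])
    dist = kernels.read_distance_table(config.tables["distances"])
    surv = escape_mod.read_survival_table(config.tables["survival"])
    logger.info(
        "read %d focal, %d germination, %d survival records; %d distance samples",
        len(focal), len(germ), len(surv), len(dist),
    )

    profiles = {s: estimators.seed_fate_profile(focal, s) for s in config.sites}
    curves = {s: escape_mod.escape_curve(surv, s, years="pooled") for s in config.sites}
    binned = {
        d: kernels.bin_distances(sample, config.bin_width_m) for d, sample in dist.items()
    }

    germ_site = None if config.pool_germination_across_sites else None
    germination: dict[str, estimators.GerminationEstimate] = {}
    for treatment in sorted({t.treatment for t in germ}):
        germination[treatment] = estimators.germination_rate(germ, treatment, germ_site)

    models: dict[str, SiteRecruitmentModel] = {}
    for site in config.sites:
        profile = profiles[site]
        pathways = []
        for disperser, p_s in profile.swallowed_by.items():
            if disperser not in binned:
                raise ValueError(
                    f"no dispersal-distance sample for disperser {disperser!r}"
                )
            treatment = config.treatment_for(disperser)
            if treatment not in germination:
                raise ValueError(
                    f"no germination trials for treatment {treatment!r} "
                    f"(disperser {disperser!r})"
                )
            pathways.append(
                SeedFatePathway(
                    label=disperser,
                    removal_fraction=p_s,
                    germination_prob=germination[treatment].rate,
                    kernel=binned[disperser],
                )
            )
        pathways.append(
            SeedFatePathway(
                label=SPAT_OUT,
                removal_fraction=profile.spat_out,
                germination_prob=germination["without_pulp"].rate,
                kernel=DistanceKernel.degenerate(config.bin_width_m),
            )
        )
        pathways.append(
            SeedFatePathway(
                label=UNDISPERSED,
                removal_fraction=profile.undispersed,
                germination_prob=germination["with_pulp"].rate,
                kernel=DistanceKernel.degenerate(config.bin_width_m),
            )
        )
        models[site] = SiteRecruitmentModel(
            site=site, pathways=tuple(pathways), escape=curves[site]
        )
        logger.info("assembled model for site %s (%d pathways)", site, len(pathways))
    return EstimationResult(
        models=models,
        profiles=profiles,
        germination=germination,
        kernels=binned,
        escape_curves=curves,
    )


def _compensation_profiles(
    config: PipelineConfig, profiles: Mapping[str, SeedFateProfile]
) -> dict[frozenset, SeedFateProfile]:
    out: dict[frozenset, SeedFateProfile] = {}
    for lost_key, source_site in config.compensation_sources.items():
        lost = frozenset(lost_key.split("+"))
        out[lost] = profiles[source_site]
    return out


def run_scenarios(
    estimation: EstimationResult,
    config: PipelineConfig,
    outdir: str | None = None,
    make_plot: bool = True,
) -> scenarios.ScenarioGridResult:
    """Run the scenario grid on the intact-site model and render outputs."""
    base = estimation.models[config.intact_site]
    curves = {
        sc: estimation.escape_curves[site]
        for sc, site in config.predator_curve_sites.items()
    }
    comp = _compensation_profiles(config, estimation.profiles)
    grid = scenarios.scenario_grid(base, config.loss_order, curves, comp)

    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        frame = grid.to_frame()
        frame["rs_percent"] = frame["rs_percent"].round(2)
        for col in (
            "delta_vs_full_assemblage_percent",
            "delta_vs_reference_scenario_percent",
        ):
            frame[col] = frame[col].round(1)
        frame.to_csv(os.path.join(outdir, "scenario_grid.tsv"), sep="\t", index=False)
        with open(os.path.join(outdir, "scenario_grid.json"), "w", encoding="utf-8") as fh:
            json.dump(frame.to_dict(orient="records"), fh, indent=2)
        for site, model in estimation.models.items():
            with open(
                os.path.join(outdir, f"model_{site}.yaml"), "w", encoding="utf-8"
            ) as fh:
                yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)
        if make_plot:
            plot_scenario_grid(grid, os.path.join(outdir, "scenario_grid.png"))
    return grid


def plot_scenario_grid(grid: scenarios.ScenarioGridResult, path: str) -> None:
    """Dot plot of RS over the disperser-loss × predator-scenario surface."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = grid.to_frame()
    scenario_names = list(dict.fromkeys(frame["predator_scenario"]))
    loss_steps = list(dict.fromkeys(frame["dispersers_lost"]))
    fig, ax = plt.subplots(figsize=(8, 4.5))
    for comp, color in ((False, "0.7"), (True, "0.25")):
        sub = frame[frame["compensation"] == comp]
        x = [loss_steps.index(v) for v in sub["dispersers_lost"]]
        y = [scenario_names.index(v) for v in sub["predator_scenario"]]
        ax.scatter(
            x,
            y,
            s=sub["rs_percent"] * 60 + 10,
            c=color,
            alpha=0.8,
            label="with compensation" if comp else "without compensation",
        )
        for xi, yi, rs in zip(x, y, sub["rs_percent"]):
            ax.annotate(
                f"{rs:.1f}", (xi, yi), textcoords="offset points",
                xytext=(8, 6 if comp else -10), fontsize=7,
            )
    ax.set_xticks(range(len(loss_steps)), [s or "full" for s in loss_steps], rotation=20)
    ax.set_yticks(range(len(scenario_names)), scenario_names)
    ax.set_xlabel("seed dispersers lost (cumulative)")
    ax.set_ylabel("seed-predator scenario")
    ax.set_title("Expected recruitment success (%) under defaunation scenarios")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def recruitment_table(estimation: EstimationResult) -> "pd.DataFrame":
    """Per-site RS and per-pathway contributions, rounded for reporting."""
    import pandas as pd

    rows = []
    for site, model in estimation.models.items():
        result = recruitment_success(model)
        shares = result.shares if result.rs_percent > 0 else {}
        for label, contrib in result.pathway_contributions.items():
            rows.append(
                {
                    "site": site,
                    "pathway": label,
                    "rs_percent": round(result.rs_percent, 2),
                    "contribution_percent": round(contrib, 4),
                    "share": round(shares.get(label, float("nan")), 4),
                }
            )
    return pd.DataFrame(rows)
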