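"""Escape curves: distance-dependent one-year survival of dispersed seeds.

The field experiment places seed stations at 5, 15, 30 and 50 m from
parent trees and records how many seeds are alive as seedlings after one
year.  Distance-dependent mortality near the parent (seed predators,
pathogens) is the Janzen-Connell escape mechanism: survival tends to rise
with distance where the seed-predator community is intact.

The module estimates design-based survival probabilities T_m per distance
class (pooled binomial fractions), tests the distance trend with a
log-link count regression, and maps continuous dispersal distances onto
the experimental classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .model_core import DEFAULT_CLASS_MAP, ClassMap, EscapeCurve

__all__ = [
    "DESIGN_DISTANCES",
    "SurvivalRecord",
    "TrendTestResult",
    "MissingDistanceClassError",
    "DegenerateFitError",
    "escape_curve",
    "distance_trend_test",
    "distance_class",
    "read_survival_table",
]

#: The experimental distances (m) of the survival design.
DESIGN_DISTANCES: tuple[float, ...] = (5.0, 15.0, 30.0, 50.0)


class MissingDistanceClassError(ValueError):
    """A distance class has no data for the requested selection."""


class DegenerateFitError(ValueError):
    """The trend regression cannot be fitted (e.g. no survivors at all)."""


@dataclass(frozen=True)
class SurvivalRecord:
    """Seeds placed and surviving at one station (site, year, tree, distance)."""

    site: str
    year: int
    tree_id: str
    distance_m: float
    n_placed: int
    n_surviving: int

    def __post_init__(self) -> None:
        if self.distance_m not in DESIGN_DISTANCES:
            raise ValueError(
                f"distance_m must be one of {DESIGN_DISTANCES}, got {self.distance_m}"
            )
        if not (0 <= self.n_surviving <= self.n_placed):
            raise ValueError(
                f"n_surviving {self.n_surviving} outside [0, n_placed={self.n_placed}]"
            )


@dataclass(frozen=True)
class TrendTestResult:
    """Log-link distance-trend test on one-year survival counts."""

    slope: float  # log-scale survival change per metre
    z_statistic: float
    p_value: float
    n: int  # total seeds placed in the records used


def escape_curve(
    records: Iterable[SurvivalRecord],
    site: str,
    years: Sequence[int] | str = "pooled",
) -> EscapeCurve:
    """Design-based escape curve T_m = pooled surviving / pooled placed.

    ``years="pooled"`` pools all years (the default used by the recruitment
    model); a sequence restricts to those years.  A distance class with no
    data is an error — never an imputation.
    """
    year_set = None if years == "pooled" else {int(y) for y in years}
    placed = {d: 0 for d in DESIGN_DISTANCES}
    surv = {d: 0 for d in DESIGN_DISTANCES}
    used_years: set[int] = set()
    for r in records:
        if r.site != site:
            continue
        if year_set is not None and r.year not in year_set:
            continue
        placed[r.distance_m] += r.n_placed
        surv[r.distance_m] += r.n_surviving
        used_years.add(r.year)
    empty = [d for d in DESIGN_DISTANCES if placed[d] == 0]
    if empty:
        raise MissingDistanceClassError(
            f"no seeds placed at distance class(es) {empty} m for site {site!r}"
        )
    return EscapeCurve(
        site=site,
        survival=tuple(surv[d] / placed[d] for d in DESIGN_DISTANCES),
        distances_m=DESIGN_DISTANCES,
        years=tuple(sorted(used_years)),
    )


def distance_trend_test(
    records: Iterable[SurvivalRecord],
    site: str,
    year: int | str = "pooled",
) -> TrendTestResult:
    """Test the effect of distance to the parent on one-year survival.

    Fits a Poisson regression of surviving counts on distance with a
    log link, a ``log(n_placed)`` offset and tree indicator adjustments
    (fixed effects), and reports the distance slope with its Wald z and
    two-sided p-value.  Survival is a proportion, so the Poisson working
    variance is conservative; the slope is the log-scale change in
    survival per metre.
    """
    rows = [
        r
        for r in records
        if r.site == site
        and (year == "pooled" or r.year == int(year))
        and r.n_placed > 0
    ]
    if len({r.distance_m for r in rows}) < 2:
        raise MissingDistanceClassError(
            "trend test needs data at >= 2 distance classes"
        )
    y = np.array([r.n_surviving for r in rows], dtype=float)
    if y.sum() == 0:
        raise DegenerateFitError("no surviving seeds: distance slope is unidentified")
    dist = np.array([r.distance_m for r in rows])
    offset = np.log(np.array([r.n_placed for r in rows], dtype=float))
    trees = sorted({r.tree_id for r in rows})
    X = np.column_stack([np.ones(len(rows)), dist])
    names = ["const", "distance_m"]
    if len(trees) > 1:
        for t in trees[1:]:
            X = np.column_stack([X, [1.0 if r.tree_id == t else 0.0 for r in rows]])
            names.append(f"tree[{t}]")
    model = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset)
    try:
        fit = model.fit()
    except Exception as exc:  # pragma: no cover - statsmodels failure modes vary
        raise DegenerateFitError(f"log-link trend fit failed: {exc}") from exc
    slope_idx = names.index("distance_m")
    slope = float(fit.params[slope_idx])
    se = float(fit.bse[slope_idx])
    if not np.isfinite(se) or se == 0:
        raise DegenerateFitError("distance slope standard error is degenerate")
    z = slope / se
    from scipy.stats import norm

    return TrendTestResult(
        slope=slope,
        z_statistic=float(z),
        p_value=float(2.0 * norm.sf(abs(z))),
        n=int(sum(r.n_placed for r in rows)),
    )


def distance_class(distance_m: float, class_map: ClassMap = DEFAULT_CLASS_MAP) -> int:
    """1-based experimental class (1..4) nearest to a continuous distance.

    Boundaries sit halfway between stations (10, 22.5, 40 m); distances
    beyond 50 m clamp to class 4.  Total, idempotent and monotone.
    """
    if distance_m < 0:
        raise ValueError(f"negative distance {distance_m!r}")
    return class_map.class_index(distance_m) + 1


_SURV_COLS = ["site", "year", "tree_id", "distance_m", "n_placed", "n_surviving"]


def read_survival_table(path) -> list[SurvivalRecord]:
    df = pd.read_csv(path, sep=None, engine="python", encoding="utf-8")
    missing = [c for c in _SURV_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return [
        SurvivalRecord(
            site=str(r.site),
            year=int(r.year),
            tree_id=str(r.tree_id),
            distance_m=float(r.distance_m),
            n_placed=int(r.n_placed),
            n_surviving=int(r.n_surviving),
        )
        for r in df.itertuples()
    ]
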