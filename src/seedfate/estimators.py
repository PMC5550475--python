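"""Estimation of removal and germination components from field records.

Three record types feed the quantity/quality decomposition of seed
dispersal effectiveness:

* focal observations of fruiting trees → seed-fate profiles (fraction of
  the crop swallowed per disperser, spat out, or left undispersed);
* germination trials in a randomized complete block design (5 seeds × 10
  blocks per treatment in the field protocol) → germination probabilities
  per seed treatment, with a design-based one-way randomized-block ANOVA;
* camera-trap records → visitation rates per 100 trap-days, used as a raw
  relative-abundance index for terrestrial seed predators.

Fate fractions pool raw counts across trees and sessions (effort-weighted),
because the recruitment equation needs crop-level probabilities, not
per-tree averages.  Fruits dropped under the crown are merged into the
"undispersed" fate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FocalRecord",
    "SeedFateProfile",
    "GerminationTrial",
    "GerminationEstimate",
    "CameraRecord",
    "AnovaResult",
    "EmptyDataError",
    "DesignError",
    "seed_fate_profile",
    "removal_probability",
    "germination_rate",
    "randomized_block_anova",
    "visitation_rate",
    "read_focal_table",
    "read_germination_table",
    "read_camera_table",
]


class EmptyDataError(ValueError):
    """No usable records for the requested selection."""


class DesignError(ValueError):
    """The block × treatment layout is unbalanced or incomplete."""


@dataclass(frozen=True)
class FocalRecord:
    """One focal-observation session's fruit-handling tallies for one actor."""

    site: str
    tree_id: str
    session_hours: float
    actor: str  # disperser name, or "none" for unhandled fruits
    n_swallowed: int = 0
    n_spat: int = 0
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if min(self.n_swallowed, self.n_spat, self.n_dropped) < 0:
            raise ValueError("fruit counts must be non-negative")
        if self.actor == "none" and self.n_swallowed > 0:
            raise ValueError('actor "none" cannot swallow fruits')


@dataclass(frozen=True)
class SeedFateProfile:
    """Crop-level seed-fate fractions for one site; sums to 1."""

    site: str
    swallowed_by: Mapping[str, float]
    spat_out: float
    undispersed: float

    def __post_init__(self) -> None:
        vals = list(self.swallowed_by.values()) + [self.spat_out, self.undispersed]
        if any(not (0.0 <= v <= 1.0) for v in vals):
            raise ValueError("fate fractions must lie in [0, 1]")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError(f"fate fractions sum to {sum(vals)!r}, expected 1")
        object.__setattr__(self, "swallowed_by", dict(self.swallowed_by))

    @property
    def swallowed_total(self) -> float:
        """Fraction of the crop dispersed away from the parent tree."""
        return float(sum(self.swallowed_by.values()))


@dataclass(frozen=True)
class GerminationTrial:
    """One block's outcome for one seed treatment."""

    site: str
    treatment: str  # "defecated-by-<disperser>", "with_pulp" or "without_pulp"
    block_id: str
    n_sown: int
    n_germinated: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_germinated <= self.n_sown):
            raise ValueError(
                f"n_germinated {self.n_germinated} outside [0, n_sown={self.n_sown}]"
            )


@dataclass(frozen=True)
class GerminationEstimate:
    """Pooled germination probability with per-block dispersion."""

    treatment: str
    rate: float  # pooled n_germinated / pooled n_sown
    block_mean: float  # mean germinated count per block (bar-plot convention)
    block_sd: float  # SD of per-block germinated counts (n-1 denominator)
    n_blocks: int


@dataclass(frozen=True)
class CameraRecord:
    site: str
    station_id: str
    trap_days: float
    species: str
    n_visits: int

    def __post_init__(self) -> None:
        if self.trap_days <= 0:
            raise ValueError("trap_days must be positive")
        if self.n_visits < 0:
            raise ValueError("n_visits must be non-negative")


@dataclass(frozen=True)
class AnovaResult:
    """One-way randomized-block ANOVA summary."""

    f_statistic: float
    df_treatment: int
    df_error: int
    p_value: float
    treatment_means: Mapping[str, float]
    ss_treatment: float = 0.0
    ss_block: float = 0.0
    ss_error: float = 0.0


def seed_fate_profile(records: Iterable[FocalRecord], site: str) -> SeedFateProfile:
    """Pooled seed-fate fractions for a site from focal-observation records.

    Counts are pooled over all sessions and trees; the denominator is the
    total number of fruits handled.  Dispersers are those observed
    swallowing at least one fruit.
    """
    swallowed: dict[str, int] = {}
    spat = dropped = 0
    for r in records:
        if r.site != site:
            continue
        if r.n_swallowed > 0:
            swallowed[r.actor] = swallowed.get(r.actor, 0) + r.n_swallowed
        spat += r.n_spat
        dropped += r.n_dropped
    total = sum(swallowed.values()) + spat + dropped
    if total == 0:
        raise EmptyDataError(f"no fruits handled in records for site {site!r}")
    return SeedFateProfile(
        site=site,
        swallowed_by={k: v / total for k, v in swallowed.items()},
        spat_out=spat / total,
        undispersed=dropped / total,
    )


def removal_probability(profile: SeedFateProfile, disperser: str) -> float:
    """P_s for one disperser; 0 if it was never observed swallowing."""
    return float(profile.swallowed_by.get(disperser, 0.0))


def germination_rate(
    trials: Iterable[GerminationTrial],
    treatment: str,
    site: str | None = None,
) -> GerminationEstimate:
    """Pooled germination probability for one seed treatment.

    Pools germinated over sown seeds across blocks (and across sites unless
    ``site`` restricts); also reports the per-block mean count and SD, the
    convention of germination bar plots.
    """
    selected = [
        t
        for t in trials
        if t.treatment == treatment and (site is None or t.site == site)
    ]
    if not selected:
        known = sorted({t.treatment for t in trials})
        raise EmptyDataError(
            f"no trials for treatment {treatment!r}"
            + (f" at site {site!r}" if site else "")
            + f"; known treatments: {known}"
        )
    germ = np.array([t.n_germinated for t in selected], dtype=float)
    sown = np.array([t.n_sown for t in selected], dtype=float)
    return GerminationEstimate(
        treatment=treatment,
        rate=float(germ.sum() / sown.sum()),
        block_mean=float(germ.mean()),
        block_sd=float(germ.std(ddof=1)) if len(selected) > 1 else 0.0,
        n_blocks=len(selected),
    )


def randomized_block_anova(
    trials: Iterable[GerminationTrial],
    treatments: Sequence[str] | None = None,
    site: str | None = None,
) -> AnovaResult:
    """One-way ANOVA for a randomized complete block design.

    Operates on the per-block germinated counts treated as continuous
    responses.  The total sum of squares is partitioned into block,
    treatment and residual components;
    ``F = MS_treatment / MS_residual`` with ``(t-1, (t-1)(b-1))`` degrees of
    freedom.  The layout must be complete and balanced (exactly one trial
    per block × treatment cell); anything else is a design error, never
    silently dropped.
    """
    selected = [t for t in trials if site is None or t.site == site]
    if treatments is not None:
        selected = [t for t in selected if t.treatment in set(treatments)]
        treat_levels = list(treatments)
    else:
        treat_levels = sorted({t.treatment for t in selected})
    blocks = sorted({t.block_id for t in selected})
    t_n, b_n = len(treat_levels), len(blocks)
    if t_n < 2 or b_n < 2:
        raise DesignError(
            f"need >= 2 treatments and >= 2 blocks, got {t_n} and {b_n}"
        )
    cells: dict[tuple[str, str], float] = {}
    for t in selected:
        key = (t.treatment, t.block_id)
        if key in cells:
            raise DesignError(f"duplicate cell for treatment/block {key}")
        cells[key] = float(t.n_germinated)
    missing = [
        (tr, bl) for tr in treat_levels for bl in blocks if (tr, bl) not in cells
    ]
    if missing:
        raise DesignError(f"incomplete layout; missing cells: {missing[:5]}")

    y = np.array([[cells[(tr, bl)] for bl in blocks] for tr in treat_levels])
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    ss_treat = float(b_n * ((y.mean(axis=1) - grand) ** 2).sum())
    ss_block = float(t_n * ((y.mean(axis=0) - grand) ** 2).sum())
    ss_error = ss_total - ss_treat - ss_block
    df_t, df_e = t_n - 1, (t_n - 1) * (b_n - 1)
    ms_error = ss_error / df_e
    if ms_error <= 0:
        # zero residual variance: F is 0 when treatments are identical, else infinite
        f_stat = 0.0 if ss_treat <= 1e-12 else float("inf")
    else:
        f_stat = (ss_treat / df_t) / ms_error
    p_value = float(stats.f.sf(f_stat, df_t, df_e)) if np.isfinite(f_stat) else 0.0
    return AnovaResult(
        f_statistic=float(f_stat),
        df_treatment=df_t,
        df_error=df_e,
        p_value=p_value,
        treatment_means={tr: float(m) for tr, m in zip(treat_levels, y.mean(axis=1))},
        ss_treatment=ss_treat,
        ss_block=ss_block,
        ss_error=max(ss_error, 0.0),
    )


def visitation_rate(
    records: Iterable[CameraRecord],
    species_group: str | Iterable[str],
    site: str,
) -> float:
    """Visits per 100 trap-days for a species or group of species at a site.

    Effort is the summed trap-days over all stations that targeted the
    site, regardless of which species each record reports, so a station
    with zero visits of the focal group still contributes effort.
    """
    group = {species_group} if isinstance(species_group, str) else set(species_group)
    site_records = [r for r in records if r.site == site]
    # effort is per station, counted once even if several species share it
    effort = sum(
        {(r.station_id): r.trap_days for r in site_records}.values()
    )
    if effort <= 0:
        raise EmptyDataError(f"zero camera-trap effort at site {site!r}")
    visits = sum(r.n_visits for r in site_records if r.species in group)
    return 100.0 * visits / effort


# ---------------------------------------------------------------------------
# delimited-text readers (tab- or comma-separated, header row required, UTF-8)

_FOCAL_COLS = ["site", "tree_id", "session_hours", "actor", "n_swallowed", "n_spat", "n_dropped"]
_GERM_COLS = ["site", "treatment", "block_id", "n_sown", "n_germinated"]
_CAMERA_COLS = ["site", "station_id", "trap_days", "species", "n_visits"]


def _read_table(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", encoding="utf-8")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def read_focal_table(path) -> list[FocalRecord]:
    df = _read_table(path, _FOCAL_COLS)
    return [
        FocalRecord(
            site=str(r.site),
            tree_id=str(r.tree_id),
            session_hours=float(r.session_hours),
            actor=str(r.actor),
            n_swallowed=int(r.n_swallowed),
            n_spat=int(r.n_spat),
            n_dropped=int(r.n_dropped),
        )
        for r in df.itertuples()
    ]


def read_germination_table(path) -> list[GerminationTrial]:
    df = _read_table(path, _GERM_COLS)
    return [
        GerminationTrial(
            site=str(r.site),
            treatment=str(r.treatment),
            block_id=str(r.block_id),
            n_sown=int(r.n_sown),
            n_germinated=int(r.n_germinated),
        )
        for r in df.itertuples()
    ]


def read_camera_table(path) -> list[CameraRecord]:
    df = _read_table(path, _CAMERA_COLS)
    return [
        CameraRecord(
            site=str(r.site),
            station_id=str(r.station_id),
            trap_days=float(r.trap_days),
            species=str(r.species),
            n_visits=int(r.n_visits),
        )
        for r in df.itertuples()
    ]
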