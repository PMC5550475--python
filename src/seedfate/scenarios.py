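"""Defaunation scenario engine: sequential disperser loss × predator loss.

Starting from the intact community's recruitment model, the engine removes
seed dispersers cumulatively (largest- to smallest-bodied), with or
without compensatory rewiring of the remaining frugivores, and crosses
each disperser set with alternative seed-predator communities implemented
as escape-curve substitution:

* ``complete``                 — all large seed predators present;
* ``no_peccaries``             — peccaries lost;
* ``no_peccaries_no_agoutis``  — peccaries and agoutis lost (small
  granivorous rodents released, flattening the escape curve).

Without compensation, a removed disperser's share of the crop simply falls
undispersed under the crown (with pulp).  With compensation, the whole
removal profile is replaced by one observed in a real community that lacks
the lost disperser(s); germination and kernels of the remaining dispersers
keep their intact-site values — only removal fractions are rewired.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .estimators import SeedFateProfile
from .model_core import (
    SPAT_OUT,
    UNDISPERSED,
    EscapeCurve,
    SeedFatePathway,
    SiteRecruitmentModel,
    recruitment_success,
)

__all__ = [
    "PREDATOR_SCENARIOS",
    "CompensationError",
    "ScenarioCell",
    "ScenarioGridResult",
    "remove_disperser",
    "apply_predator_scenario",
    "relative_change",
    "scenario_grid",
]

#: Predator-community scenarios, from most to least intact.
PREDATOR_SCENARIOS = ("complete", "no_peccaries", "no_peccaries_no_agoutis")


class CompensationError(ValueError):
    """A compensation profile is inconsistent with the removed disperser(s)."""


def remove_disperser(
    model: SiteRecruitmentModel,
    disperser: str,
    compensation_profile: SeedFateProfile | None = None,
) -> SiteRecruitmentModel:
    """Simulate the local extinction of one seed disperser.

    Without compensation the extinct pathway's removal fraction is zeroed
    and reallocated to the "undispersed" pathway (the fruits fall with
    pulp); everything else is untouched.  With compensation, every
    pathway's removal fraction is replaced by the value observed in
    ``compensation_profile`` — a fate profile from a community lacking the
    disperser — so the remaining frugivores' quantity components are
    rewired while their quality components (germination, kernels) keep
    their original values.  Removing an absent disperser is a no-op.
    """
    labels = [p.label for p in model.pathways]
    if disperser not in labels:
        return model
    if compensation_profile is None:
        removed_mass = model.pathway(disperser).removal_fraction
        new = []
        for p in model.pathways:
            if p.label == disperser:
                new.append(replace(p, removal_fraction=0.0))
            elif p.label == UNDISPERSED:
                new.append(replace(p, removal_fraction=p.removal_fraction + removed_mass))
            else:
                new.append(p)
        return model.with_pathways(new)

    if disperser in compensation_profile.swallowed_by:
        raise CompensationError(
            f"compensation profile still contains the removed disperser {disperser!r}"
        )
    extra = set(compensation_profile.swallowed_by) - set(labels)
    if extra:
        raise CompensationError(
            f"compensation profile names dispersers absent from the model: {sorted(extra)}"
        )
    new = []
    for p in model.pathways:
        if p.label == SPAT_OUT:
            frac = compensation_profile.spat_out
        elif p.label == UNDISPERSED:
            frac = compensation_profile.undispersed
        else:
            frac = compensation_profile.swallowed_by.get(p.label, 0.0)
        new.append(replace(p, removal_fraction=frac))
    return model.with_pathways(new)


def apply_predator_scenario(
    model: SiteRecruitmentModel, curve: EscapeCurve
) -> SiteRecruitmentModel:
    """Substitute the escape curve of another predator community; pathways untouched."""
    return replace(model, escape=curve)


def relative_change(rs: float, rs_reference: float) -> float:
    """Signed percent change of RS relative to a reference RS."""
    if rs_reference <= 0:
        raise ZeroDivisionError("reference recruitment success must be positive")
    return 100.0 * (rs - rs_reference) / rs_reference


@dataclass(frozen=True)
class ScenarioCell:
    """One grid cell: a disperser set × predator scenario × compensation state."""

    dispersers_present: tuple[str, ...]
    dispersers_lost: tuple[str, ...]
    predator_scenario: str
    compensation: bool
    compensation_available: bool
    rs_percent: float
    delta_vs_full_assemblage_percent: float  # vs complete-predator, all-disperser cell
    delta_vs_reference_scenario_percent: float  # vs own scenario's all-disperser cell


@dataclass(frozen=True)
class ScenarioGridResult:
    """The full disperser-loss × predator-scenario × compensation surface."""

    cells: tuple[ScenarioCell, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dispersers_present": ["+".join(c.dispersers_present) or "none" for c in self.cells],
                "dispersers_lost": ["+".join(c.dispersers_lost) or "none" for c in self.cells],
                "predator_scenario": [c.predator_scenario for c in self.cells],
                "compensation": [c.compensation for c in self.cells],
                "compensation_available": [c.compensation_available for c in self.cells],
                "rs_percent": [c.rs_percent for c in self.cells],
                "delta_vs_full_assemblage_percent": [
                    c.delta_vs_full_assemblage_percent for c in self.cells
                ],
                "delta_vs_reference_scenario_percent": [
                    c.delta_vs_reference_scenario_percent for c in self.cells
                ],
            }
        )

    def cell(
        self,
        dispersers_lost: Sequence[str],
        predator_scenario: str,
        compensation: bool,
    ) -> ScenarioCell:
        key = tuple(dispersers_lost)
        for c in self.cells:
            if (
                c.dispersers_lost == key
                and c.predator_scenario == predator_scenario
                and c.compensation == compensation
            ):
                return c
        raise KeyError((key, predator_scenario, compensation))


def _lose(
    base: SiteRecruitmentModel,
    lost: Sequence[str],
    profile: SeedFateProfile | None,
) -> SiteRecruitmentModel:
    """Remove dispersers cumulatively; with a profile, rewire at the last step."""
    model = base
    for d in lost:
        model = remove_disperser(model, d, compensation_profile=None)
    if profile is not None:
        # compensation replaces the whole removal profile at once; removing
        # first then rewiring is equivalent and keeps the pathway set stable
        for d in lost:
            if d in profile.swallowed_by:
                raise CompensationError(
                    f"compensation profile contains removed disperser {d!r}"
                )
        model = remove_disperser(model, lost[-1], compensation_profile=profile) if lost else model
    return model


def scenario_grid(
    base: SiteRecruitmentModel,
    loss_order: Sequence[str],
    predator_curves: Mapping[str, EscapeCurve],
    compensation_profiles: Mapping[frozenset, SeedFateProfile] | None = None,
) -> ScenarioGridResult:
    """Enumerate cumulative disperser losses × predator scenarios × compensation.

    ``loss_order`` lists dispersers from first lost (largest-bodied) to
    last.  ``predator_curves`` maps each scenario name to the escape curve
    it substitutes.  ``compensation_profiles`` maps a frozenset of lost
    dispersers to the observed fate profile of a community lacking them; a
    loss step with no source profile appears as an uncompensated cell
    flagged ``compensation_available=False``.  Every cell's RS comes from
    :func:`seedfate.model_core.recruitment_success` on the cell's fully
    constructed model — no shortcut arithmetic.
    """
    missing = [d for d in loss_order if d not in base.dispersers]
    if missing:
        raise ValueError(f"loss_order names dispersers absent from the model: {missing}")
    compensation_profiles = compensation_profiles or {}
    scenarios = list(predator_curves)

    # baseline RS per predator scenario (full assemblage)
    baseline_rs = {
        sc: recruitment_success(apply_predator_scenario(base, predator_curves[sc])).rs_percent
        for sc in scenarios
    }
    ref_full = baseline_rs[scenarios[0]]

    cells: list[ScenarioCell] = []
    for k in range(len(loss_order) + 1):
        lost = tuple(loss_order[:k])
        present = tuple(d for d in base.dispersers if d not in lost)
        comp_states: list[tuple[bool, SeedFateProfile | None, bool]] = [(False, None, True)]
        if k > 0:
            profile = compensation_profiles.get(frozenset(lost))
            # no observed source community: fall back to the uncompensated
            # model but flag the cell so consumers can tell
            comp_states.append((True, profile, profile is not None))
        for compensation, profile, available in comp_states:
            model = _lose(base, lost, profile if compensation else None)
            for sc in scenarios:
                rs = recruitment_success(
                    apply_predator_scenario(model, predator_curves[sc])
                ).rs_percent
                cells.append(
                    ScenarioCell(
                        dispersers_present=present,
                        dispersers_lost=lost,
                        predator_scenario=sc,
                        compensation=compensation,
                        compensation_available=available,
                        rs_percent=rs,
                        delta_vs_full_assemblage_percent=relative_change(rs, ref_full),
                        delta_vs_reference_scenario_percent=relative_change(
                            rs, baseline_rs[sc]
                        ),
                    )
                )
    return ScenarioGridResult(cells=tuple(cells))
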