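"""Recruitment-success model for a large-seeded, animal-dispersed tree.

Recruitment success (RS) is the percentage of one year's seed crop that
yields seedlings alive at one year.  Each seed follows exactly one *fate
pathway*: swallowed by a disperser ``s`` (endozoochory), spat out with the
pulp removed, or undispersed under the parent crown.  A pathway contributes

    RS_s = 100 * P_s * G_s * sum_m D_sm * T_m

where ``P_s`` is the fraction of the crop entering the pathway, ``G_s`` the
germination probability of seeds handled that way, ``D_sm`` the probability
that a seed of pathway ``s`` lands in distance class ``m``, and ``T_m`` the
one-year survival at that distance from the parent (the escape curve of the
Janzen-Connell mechanism).  Total RS is the sum over pathways.

The module houses the domain types (:class:`SeedFatePathway`,
:class:`DistanceKernel`, :class:`EscapeCurve`, :class:`SiteRecruitmentModel`,
:class:`RecruitmentResult`), the analytic computation, a per-seed
Monte-Carlo oracle used for testing, and lossless YAML/JSON serialization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "SPAT_OUT",
    "UNDISPERSED",
    "ClassMap",
    "DEFAULT_CLASS_MAP",
    "DistanceKernel",
    "EscapeCurve",
    "SeedFatePathway",
    "SiteRecruitmentModel",
    "RecruitmentResult",
    "ModelValidationError",
    "KernelClassError",
    "UndefinedSharesError",
    "pathway_contribution",
    "recruitment_success",
    "contribution_shares",
    "monte_carlo_oracle",
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
]

#: Reserved pathway labels for the two non-dispersed fates.
SPAT_OUT = "spat_out"
UNDISPERSED = "undispersed"

_SUM_TOL = 1e-9


class ModelValidationError(ValueError):
    """An invariant of a model component is violated."""


class KernelClassError(ValueError):
    """A kernel bin cannot be mapped onto the escape-curve distance classes."""


class UndefinedSharesError(ZeroDivisionError):
    """Per-pathway shares are requested for a model with zero recruitment."""


@dataclass(frozen=True)
class DistanceKernel:
    """Binned dispersal-distance distribution D_sm.

    Bins are half-open ``[edge[i], edge[i+1])`` of uniform width (5 m by
    convention) starting at 0; ``probs`` is the probability mass per bin.
    ``sample_size`` records how many dispersal events underlie the kernel
    (0 for analytic or degenerate kernels).
    """

    bin_edges: tuple[float, ...]
    probs: tuple[float, ...]
    sample_size: int = 0

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        probs = np.asarray(self.probs, dtype=float)
        if edges.ndim != 1 or edges.size != probs.size + 1:
            raise ModelValidationError(
                f"need len(bin_edges) == len(probs) + 1, got {edges.size} and {probs.size}"
            )
        if np.any(np.diff(edges) <= 0):
            raise ModelValidationError("bin_edges must be strictly increasing")
        if np.any(probs < 0):
            raise ModelValidationError("kernel probabilities must be non-negative")
        if abs(probs.sum() - 1.0) > _SUM_TOL:
            raise ModelValidationError(
                f"kernel probabilities sum to {probs.sum()!r}, expected 1 ± {_SUM_TOL}"
            )
        object.__setattr__(self, "bin_edges", tuple(float(e) for e in edges))
        object.__setattr__(self, "probs", tuple(float(p) for p in probs))

    @property
    def midpoints(self) -> np.ndarray:
        edges = np.asarray(self.bin_edges)
        return (edges[:-1] + edges[1:]) / 2.0

    @staticmethod
    def degenerate(bin_width: float = 5.0) -> "DistanceKernel":
        """All mass in the first distance bin ``[0, bin_width)``.

        Used for the two non-dispersed pathways, whose seeds stay under or
        next to the parent crown.
        """
        return DistanceKernel(bin_edges=(0.0, bin_width), probs=(1.0,), sample_size=0)


@dataclass(frozen=True)
class EscapeCurve:
    """One-year seed/seedling survival T_m at the experimental distances.

    The field design places seeds at four distances from the parent
    (5, 15, 30 and 50 m); ``survival`` holds one probability per class.
    """

    site: str
    survival: tuple[float, float, float, float]
    distances_m: tuple[float, ...] = (5.0, 15.0, 30.0, 50.0)
    years: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.survival) != len(self.distances_m):
            raise ModelValidationError(
                "exactly one survival value per distance class required"
            )
        if any(not (0.0 <= t <= 1.0) for t in self.survival):
            raise ModelValidationError("survival values must lie in [0, 1]")
        object.__setattr__(self, "survival", tuple(float(t) for t in self.survival))
        object.__setattr__(
            self, "distances_m", tuple(float(d) for d in self.distances_m)
        )
        object.__setattr__(self, "years", tuple(int(y) for y in self.years))


@dataclass(frozen=True)
class ClassMap:
    """Rule mapping a continuous distance onto an escape-curve class.

    A distance belongs to the experimental class whose station is nearest;
    the default boundaries (10, 22.5, 40 m) are the midpoints between the
    4 stations at 5/15/30/50 m.  Distances beyond the last boundary clamp
    to the last class, so long-distance dispersal confers no modelled
    benefit past the experiment's range.
    """

    boundaries: tuple[float, ...] = (10.0, 22.5, 40.0)

    def class_index(self, distance_m: float) -> int:
        """0-based class index for a distance; negative distances are errors."""
        if distance_m < 0:
            raise KernelClassError(f"negative distance {distance_m!r}")
        return int(np.searchsorted(self.boundaries, distance_m, side="right"))

    def aggregate(self, kernel: DistanceKernel, n_classes: int) -> np.ndarray:
        """Collapse kernel bin mass into the escape-curve classes."""
        out = np.zeros(n_classes)
        for mid, p, lo in zip(kernel.midpoints, kernel.probs, kernel.bin_edges):
            idx = self.class_index(float(mid))
            if idx >= n_classes:
                raise KernelClassError(
                    f"bin starting at {lo} m maps to class {idx + 1}, "
                    f"but the escape curve has only {n_classes} classes"
                )
            out[idx] += p
        return out


DEFAULT_CLASS_MAP = ClassMap()


@dataclass(frozen=True)
class SeedFatePathway:
    """One exclusive route a seed can take, with its P, G and kernel."""

    label: str
    removal_fraction: float
    germination_prob: float
    kernel: DistanceKernel

    def __post_init__(self) -> None:
        if not (0.0 <= self.removal_fraction <= 1.0):
            raise ModelValidationError(
                f"removal_fraction {self.removal_fraction!r} outside [0, 1] "
                f"for pathway {self.label!r}"
            )
        if not (0.0 <= self.germination_prob <= 1.0):
            raise ModelValidationError(
                f"germination_prob {self.germination_prob!r} outside [0, 1] "
                f"for pathway {self.label!r}"
            )


@dataclass(frozen=True)
class SiteRecruitmentModel:
    """A site's full pathway set plus its escape curve.

    The pathways must cover the whole crop: every seed has exactly one
    fate, so removal fractions sum to 1.
    """

    site: str
    pathways: tuple[SeedFatePathway, ...]
    escape: EscapeCurve
    class_map: ClassMap = DEFAULT_CLASS_MAP

    def __post_init__(self) -> None:
        object.__setattr__(self, "pathways", tuple(self.pathways))
        labels = [p.label for p in self.pathways]
        if len(set(labels)) != len(labels):
            raise ModelValidationError(f"duplicate pathway labels: {labels}")
        total = sum(p.removal_fraction for p in self.pathways)
        if abs(total - 1.0) > _SUM_TOL:
            raise ModelValidationError(
                f"removal fractions sum to {total!r}, expected 1 ± {_SUM_TOL} "
                "(every seed must have exactly one fate)"
            )

    @property
    def n_distance_classes(self) -> int:
        return len(self.escape.distances_m)

    @property
    def dispersers(self) -> tuple[str, ...]:
        """Pathway labels that are actual dispersers (not reserved fates)."""
        return tuple(
            p.label for p in self.pathways if p.label not in (SPAT_OUT, UNDISPERSED)
        )

    def pathway(self, label: str) -> SeedFatePathway:
        for p in self.pathways:
            if p.label == label:
                return p
        raise KeyError(label)

    def with_pathways(self, pathways: Iterable[SeedFatePathway]) -> "SiteRecruitmentModel":
        return replace(self, pathways=tuple(pathways))


@dataclass(frozen=True)
class RecruitmentResult:
    """RS in percent plus per-pathway contribution accounting."""

    rs_percent: float
    pathway_contributions: Mapping[str, float]

    def __post_init__(self) -> None:
        total = sum(self.pathway_contributions.values())
        if abs(total - self.rs_percent) > 1e-9:
            raise ModelValidationError(
                f"rs_percent {self.rs_percent} != sum of contributions {total}"
            )

    @property
    def shares(self) -> dict[str, float]:
        return contribution_shares(self)


def pathway_contribution(
    pathway: SeedFatePathway,
    escape: EscapeCurve,
    class_map: ClassMap = DEFAULT_CLASS_MAP,
) -> float:
    """Percent contribution of one pathway: 100 * P * G * Σ_m D_m T_m.

    Kernel bin mass is aggregated into the escape curve's distance classes
    (nearest-station rule) before multiplying by survival.
    """
    d_by_class = class_map.aggregate(pathway.kernel, len(escape.distances_m))
    survival = np.asarray(escape.survival)
    return float(
        100.0
        * pathway.removal_fraction
        * pathway.germination_prob
        * np.dot(d_by_class, survival)
    )


def recruitment_success(model: SiteRecruitmentModel) -> RecruitmentResult:
    """Analytic recruitment success of a site model, with contributions."""
    contributions = {
        p.label: pathway_contribution(p, model.escape, model.class_map)
        for p in model.pathways
    }
    return RecruitmentResult(
        rs_percent=float(sum(contributions.values())),
        pathway_contributions=contributions,
    )


def contribution_shares(result: RecruitmentResult) -> dict[str, float]:
    """Fraction of total RS carried by each pathway; sums to 1.

    Raises :class:`UndefinedSharesError` when RS is zero — shares are then
    undefined, not silently zero.
    """
    if result.rs_percent <= 0.0:
        raise UndefinedSharesError(
            "per-pathway shares are undefined when recruitment success is 0"
        )
    return {
        label: c / result.rs_percent
        for label, c in result.pathway_contributions.items()
    }


def monte_carlo_oracle(
    model: SiteRecruitmentModel,
    n_seeds: int,
    rng_seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Brute-force per-seed simulation of the recruitment equation.

    Every seed draws a fate pathway (categorical on removal fractions),
    germinates with probability G, lands in a kernel bin, and survives with
    the escape-curve probability of that bin's distance class.  Returns the
    estimated RS in percent and its binomial standard error (percent).
    Exists as an independent test oracle for the analytic computation.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    fractions = np.array([p.removal_fraction for p in model.pathways])
    counts = rng.multinomial(n_seeds, fractions / fractions.sum())
    survival = np.asarray(model.escape.survival)
    n_recruited = 0
    for pathway, n_path in zip(model.pathways, counts):
        if n_path == 0:
            continue
        germinated = int(rng.binomial(n_path, pathway.germination_prob))
        if germinated == 0:
            continue
        bins = rng.choice(
            len(pathway.kernel.probs), size=germinated, p=np.asarray(pathway.kernel.probs)
        )
        mids = pathway.kernel.midpoints[bins]
        classes = np.array([model.class_map.class_index(m) for m in mids])
        n_recruited += int(rng.binomial(1, survival[classes]).sum())
    p_hat = n_recruited / n_seeds
    se = float(np.sqrt(p_hat * (1.0 - p_hat) / n_seeds))
    return 100.0 * p_hat, 100.0 * se


# ---------------------------------------------------------------------------
# serialization


def model_to_dict(model: SiteRecruitmentModel) -> dict:
    return {
        "site": model.site,
        "class_boundaries": list(model.class_map.boundaries),
        "pathways": [
            {
                "label": p.label,
                "removal_fraction": p.removal_fraction,
                "germination_prob": p.germination_prob,
                "kernel": {
                    "bin_edges": list(p.kernel.bin_edges),
                    "probs": list(p.kernel.probs),
                    "sample_size": p.kernel.sample_size,
                },
            }
            for p in model.pathways
        ],
        "escape": {
            "site": model.escape.site,
            "years": list(model.escape.years),
            "distances_m": list(model.escape.distances_m),
            "survival": list(model.escape.survival),
        },
    }


def model_from_dict(doc: Mapping) -> SiteRecruitmentModel:
    esc = doc["escape"]
    return SiteRecruitmentModel(
        site=doc["site"],
        pathways=tuple(
            SeedFatePathway(
                label=p["label"],
                removal_fraction=p["removal_fraction"],
                germination_prob=p["germination_prob"],
                kernel=DistanceKernel(
                    bin_edges=tuple(p["kernel"]["bin_edges"]),
                    probs=tuple(p["kernel"]["probs"]),
                    sample_size=int(p["kernel"].get("sample_size", 0)),
                ),
            )
            for p in doc["pathways"]
        ),
        escape=EscapeCurve(
            site=esc["site"],
            survival=tuple(esc["survival"]),
            distances_m=tuple(esc.get("distances_m", (5.0, 15.0, 30.0, 50.0))),
            years=tuple(esc.get("years", ())),
        ),
        class_map=ClassMap(tuple(doc.get("class_boundaries", (10.0, 22.5, 40.0)))),
    )


def save_model(model: SiteRecruitmentModel, path) -> None:
    path = str(path)
    doc = model_to_dict(model)
    with open(path, "w", encoding="utf-8") as fh:
        if path.endswith(".json"):
            json.dump(doc, fh, indent=2)
        else:
            yaml.safe_dump(doc, fh, sort_keys=False)


def load_model(path) -> SiteRecruitmentModel:
    path = str(path)
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh) if path.endswith(".json") else yaml.safe_load(fh)
    return model_from_dict(doc)
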