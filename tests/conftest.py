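import numpy as np
import pytest

from seedfate.model_core import (
    SPAT_OUT,
    UNDISPERSED,
    DistanceKernel,
    EscapeCurve,
    SeedFatePathway,
    SiteRecruitmentModel,
)


def random_model(rng: np.random.Generator, n_dispersers: int | None = None) -> SiteRecruitmentModel:
    """A random but valid site model: used by property and oracle tests."""
    if n_dispersers is None:
        n_dispersers = int(rng.integers(1, 4))
    labels = [f"disp{i}" for i in range(n_dispersers)] + [SPAT_OUT, UNDISPERSED]
    fractions = rng.dirichlet(np.ones(len(labels)))
    pathways = []
    for label, frac in zip(labels, fractions):
        if label in (SPAT_OUT, UNDISPERSED):
            kernel = DistanceKernel.degenerate()
        else:
            n_bins = int(rng.integers(2, 15))
            probs = rng.dirichlet(np.ones(n_bins))
            kernel = DistanceKernel(
                bin_edges=tuple(np.arange(n_bins + 1) * 5.0),
                probs=tuple(probs),
                sample_size=0,
            )
        pathways.append(
            SeedFatePathway(
                label=label,
                removal_fraction=float(frac),
                germination_prob=float(rng.uniform()),
                kernel=kernel,
            )
        )
    escape = EscapeCurve(site="random", survival=tuple(rng.uniform(size=4)))
    return SiteRecruitmentModel(site="random", pathways=tuple(pathways), escape=escape)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


@pytest.fixture
def flat_escape() -> EscapeCurve:
    return EscapeCurve(site="toy", survival=(1.0, 1.0, 1.0, 1.0))


@pytest.fixture
def toy_model() -> SiteRecruitmentModel:
    """Two dispersers with analytically trivial kernels, for hand arithmetic."""
    k_near = DistanceKernel(bin_edges=(0.0, 5.0), probs=(1.0,))  # class 1
    k_far = DistanceKernel(
        bin_edges=(0.0, 5.0, 10.0, 15.0, 20.0), probs=(0.0, 0.0, 0.5, 0.5)
    )  # midpoints 12.5, 17.5 -> both class 2
    pathways = (
        SeedFatePathway("A", 0.5, 0.8, k_near),
        SeedFatePathway("B", 0.3, 0.5, k_far),
        SeedFatePathway(SPAT_OUT, 0.05, 0.4, DistanceKernel.degenerate()),
        SeedFatePathway(UNDISPERSED, 0.15, 0.2, DistanceKernel.degenerate()),
    )
    escape = EscapeCurve(site="toy", survival=(0.25, 0.5, 0.75, 1.0))
    return SiteRecruitmentModel(site="toy", pathways=pathways, escape=escape)
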