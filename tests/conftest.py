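import numpy as np
import pytest

import lvmass as lv


@pytest.fixture(scope="session")
def table2_shell() -> lv.ShellSpec:
    """One representative phantom calibrated to the cohort means:
    true mass 132 g, LVIDd 4.8 cm (b = 2.4), wall 0.97 cm, d = 1.0 cm."""
    return lv.shell_for_mass(132.0, 2.4, 0.97, 1.0)


@pytest.fixture(scope="session")
def clean_study(table2_shell) -> lv.SyntheticStudy:
    """Noiseless rendering of the representative phantom."""
    return lv.synthesize_study(table2_shell, lv.TracingNoise.none(),
                               np.random.default_rng(0), n_points=720)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)


def semicircle_contour(r: float, n: int = 361, view: str = "AP4CH",
                       boundary: str = "endocardium") -> lv.PlanarContour:
    """Semicircular cavity of radius r: base chord on the x-axis from
    (-r, 0) to (r, 0), dome in y > 0."""
    theta = np.linspace(np.pi, 0.0, n)
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    return lv.PlanarContour(pts, view=view, boundary=boundary,
                            base_indices=(0, n - 1))


def half_ellipse_contour(a: float, b: float, n: int = 361,
                         view: str = "AP4CH") -> lv.PlanarContour:
    """Half ellipse with base chord (-b, 0)..(b, 0) and apex at (0, a)."""
    theta = np.linspace(np.pi, 0.0, n)
    pts = np.column_stack([b * np.cos(theta), a * np.sin(theta)])
    return lv.PlanarContour(pts, view=view, boundary="endocardium",
                            base_indices=(0, n - 1))
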