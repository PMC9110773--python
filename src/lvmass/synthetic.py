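"""Synthetic left-ventricular phantoms with analytic ground truth.

The phantom family is a truncated prolate spheroid shell with a uniform
wall: the endocardium is a spheroid with apical semi-axis ``a`` and short
semi-axes ``b_x``, ``b_y`` (equal for a solid of revolution), cut by the
mitral (base) plane at height ``d`` above the widest cross-section; the
epicardium is the concentric spheroid with every semi-axis enlarged by the
wall thickness ``t``, cut by the same plane.  The myocardial shell volume
is closed-form,

    V = pi [ (bx+t)(by+t) F(a+t) - bx by F(a) ],
    F(x) = (2/3) x + d - d^3 / (3 x^2),

so every phantom carries an exact ground-truth mass (rho * V) and the
truncated-ellipsoid method is an exact oracle on noiseless renderings.

Rendered measurements emulate a reading session: view contours are
polygonised profiles/ellipses, and the tracing-noise model applies
smoothed multiplicative radial jitter (a reader's hand wanders coherently,
not point-by-point), systematic border biases (parasternal wall-thickness
over-read; apical epicardial drop-out), correlated endo/epi fields within
one image, landmark jitter at the mitral annulus, and caliper noise on the
linear measures.  What the model does and does not capture is documented
in docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .errors import CalibrationError, ContourError, GeometryError
from .geometry import LinearMeasures, PlanarContour, PsaxTracing, BiplaneTracing
from .io import StudyMeasurements


# ---------------------------------------------------------------------------
# shell geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShellSpec:
    """Truncated prolate-spheroid LV shell with uniform wall (lengths cm).

    ``b_endo`` gives a circular cross-section; alternatively ``b_x`` and
    ``b_y`` give an elliptical one (non-revolution stress-test geometry).
    """

    a_apex: float
    t_wall: float
    d_base: float = 1.0
    b_endo: Optional[float] = None
    b_x: Optional[float] = None
    b_y: Optional[float] = None
    density: float = 1.05

    def __post_init__(self) -> None:
        if self.b_endo is None and (self.b_x is None or self.b_y is None):
            raise GeometryError("give b_endo, or both b_x and b_y")
        if self.b_endo is not None and (self.b_x is not None or self.b_y is not None):
            raise GeometryError("give either b_endo or (b_x, b_y), not both")
        for name in ("a_apex", "t_wall", "density"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        if self.bx <= 0 or self.by <= 0:
            raise GeometryError("short semi-axes must be positive")
        if not 0 <= self.d_base <= self.a_apex:
            raise GeometryError(
                f"d_base={self.d_base} must lie in [0, a_apex={self.a_apex}]")

    @property
    def bx(self) -> float:
        return self.b_endo if self.b_endo is not None else self.b_x

    @property
    def by(self) -> float:
        return self.b_endo if self.b_endo is not None else self.b_y


def _axial_factor(a: float, d: float) -> float:
    return (2.0 / 3.0) * a + d - d**3 / (3.0 * a**2)


def true_endo_volume(shell: ShellSpec) -> float:
    """Analytic endocardial (cavity) volume in ml."""
    return float(math.pi * shell.bx * shell.by * _axial_factor(shell.a_apex, shell.d_base))


def true_myocardial_volume(shell: ShellSpec) -> float:
    """Closed-form myocardial shell volume in ml."""
    a, t, d = shell.a_apex, shell.t_wall, shell.d_base
    outer = (shell.bx + t) * (shell.by + t) * _axial_factor(a + t, d)
    inner = shell.bx * shell.by * _axial_factor(a, d)
    return float(math.pi * (outer - inner))


def true_mass(shell: ShellSpec) -> float:
    """Ground-truth mass in grams: density * shell volume."""
    return shell.density * true_myocardial_volume(shell)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _apical_profile(a: float, b: float, d: float, n_points: int) -> np.ndarray:
    """Profile polygon of a truncated spheroid through the long axis.

    The base plane is y = d, the apex is (0, -a); vertex 0 and the last
    vertex are the base endpoints and the polygon closes along the base
    chord.  The apex vertex is sampled exactly.
    """
    psi_b = math.acos(-d / a)
    m = max(n_points // 2, 8)
    psi_right = np.linspace(psi_b, 0.0, m)
    psi_left = np.linspace(0.0, psi_b, m)[1:]
    x = np.concatenate([b * np.sin(psi_right), -b * np.sin(psi_left)])
    y = np.concatenate([-a * np.cos(psi_right), -a * np.cos(psi_left)])
    return np.column_stack([x, y])


def render_contours(shell: ShellSpec, view: str,
                    n_points: int = 360) -> dict[str, PlanarContour]:
    """Noiseless endo- and epicardial contours of ``shell`` in one view.

    AP4CH/AP2CH are the orthogonal long-axis planes (short semi-axes b_x
    and b_y respectively) with base landmarks at the truncation plane;
    PSAX is the pair of concentric ellipses at the widest cross-section.
    """
    if n_points < 16:
        raise GeometryError(f"n_points must be >= 16, got {n_points}")
    a, t, d = shell.a_apex, shell.t_wall, shell.d_base
    if view in ("AP4CH", "AP2CH"):
        b = shell.bx if view == "AP4CH" else shell.by
        out = {}
        for boundary, (aa, bb) in (("endocardium", (a, b)),
                                   ("epicardium", (a + t, b + t))):
            pts = _apical_profile(aa, bb, d, n_points)
            out[boundary] = PlanarContour(pts, view=view, boundary=boundary,
                                          base_indices=(0, len(pts) - 1))
        return out
    if view == "PSAX":
        theta = np.linspace(0.0, 2.0 * math.pi, n_points, endpoint=False)
        out = {}
        for boundary, (bx, by) in (("endocardium", (shell.bx, shell.by)),
                                   ("epicardium", (shell.bx + t, shell.by + t))):
            pts = np.column_stack([bx * np.cos(theta), by * np.sin(theta)])
            out[boundary] = PlanarContour(pts, view="PSAX", boundary=boundary)
        return out
    raise GeometryError(f"cannot render view {view!r}")


def derive_linear_measures(shell: ShellSpec,
                           noise: Optional["TracingNoise"] = None,
                           rng: Optional[np.random.Generator] = None) -> LinearMeasures:
    """1D caliper measures of the shell: IVSd = PWTd = t_wall and LVIDd =
    2 * b (geometric mean for elliptical sections), with caliper noise and
    the systematic wall-thickness over-read when a noise model is given."""
    t = shell.t_wall
    lvidd = 2.0 * math.sqrt(shell.bx * shell.by)
    if noise is None:
        return LinearMeasures(ivsd=t, lvidd=lvidd, pwtd=t)
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    sd = noise.caliper_sd
    return LinearMeasures(
        ivsd=t + noise.thickness_bias + sd * rng.standard_normal(),
        lvidd=lvidd + sd * rng.standard_normal(),
        pwtd=t + noise.thickness_bias + sd * rng.standard_normal())


# ---------------------------------------------------------------------------
# tracing-noise model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TracingNoise:
    """Manual-tracing variability model.

    point_jitter_sd
        SD of the smoothed multiplicative radial jitter, as a fraction of
        the local radius.
    smooth_frac
        Correlation length of the jitter field as a fraction of the
        contour (a reader's deviation is coherent over a border stretch).
    thickness_bias
        Systematic over-read of the wall (cm): outward shift of the PSAX
        epicardium and inflation of the linear wall calipers.
    apical_epi_bias
        Systematic radial shift (cm) of the apical epicardial border
        (negative: drop-out/under-tracing in the apical windows).
    landmark_jitter_sd
        Isotropic jitter (cm) of the two mitral-annulus landmarks.
    caliper_sd
        Noise (cm) of each 1D linear measure.
    endo_epi_corr
        Correlation of the jitter fields of the endo- and epicardial
        tracings of the same image (concentric tracings on one frame).
    seed
        Default seed when no generator is passed.
    """

    point_jitter_sd: float = 0.024
    smooth_frac: float = 0.25
    thickness_bias: float = 0.05
    apical_epi_bias: float = -0.05
    landmark_jitter_sd: float = 0.08
    caliper_sd: float = 0.045
    endo_epi_corr: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("point_jitter_sd", "smooth_frac", "landmark_jitter_sd", "caliper_sd"):
            if getattr(self, name) < 0:
                raise GeometryError(f"{name} must be >= 0")
        if not 0.0 <= self.endo_epi_corr <= 1.0:
            raise GeometryError("endo_epi_corr must lie in [0, 1]")

    @classmethod
    def none(cls) -> "TracingNoise":
        """Noise-free model (systematic biases included off as well)."""
        return cls(point_jitter_sd=0.0, smooth_frac=0.25, thickness_bias=0.0,
                   apical_epi_bias=0.0, landmark_jitter_sd=0.0, caliper_sd=0.0)


def _smooth_field(n: int, smooth_frac: float, rng: np.random.Generator) -> np.ndarray:
    """Circularly smoothed unit-variance Gaussian field over n vertices."""
    g = rng.standard_normal(n)
    ell = max(smooth_frac * n, 1e-9)
    k = np.arange(n)
    offs = np.minimum(k, n - k).astype(float)
    kernel = np.exp(-0.5 * (offs / ell)**2)
    kernel /= np.linalg.norm(kernel)  # unit marginal variance after convolution
    return np.real(np.fft.ifft(np.fft.fft(g) * np.fft.fft(kernel)))


def add_noise(contour: PlanarContour, noise: TracingNoise,
              rng: Optional[np.random.Generator] = None,
              radial_bias: float = 0.0,
              shared_field: Optional[np.ndarray] = None,
              max_retries: int = 5) -> PlanarContour:
    """Noised copy of a traced contour.

    Radii about the centroid are first shifted by ``radial_bias`` (cm,
    systematic) and then multiplied by ``1 + point_jitter_sd * field`` with
    a smoothed unit-variance field; base landmarks (if any) receive
    additional isotropic jitter.  ``shared_field`` mixes in a common field
    with weight ``sqrt(endo_epi_corr)`` to correlate endo/epi tracings of
    the same image.  Retries with a fresh field if the noised polygon
    self-intersects, then raises :class:`ContourError`.
    """
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    pts = contour.points
    centroid = pts.mean(axis=0)
    rel = pts - centroid
    radii = np.linalg.norm(rel, axis=1)
    unit = rel / np.where(radii > 0, radii, 1.0)[:, None]
    n = len(pts)

    last_err: Optional[Exception] = None
    for attempt in range(max_retries):
        # pathological draws are retried with progressively heavier
        # smoothing, which preserves the model and guarantees simplicity
        smooth = noise.smooth_frac * (1.5 ** max(attempt - 1, 0))
        own = _smooth_field(n, smooth, rng)
        if shared_field is not None and noise.endo_epi_corr > 0:
            c = noise.endo_epi_corr
            fld = math.sqrt(c) * shared_field + math.sqrt(1.0 - c) * own
        else:
            fld = own
        new_r = (radii + radial_bias) * (1.0 + noise.point_jitter_sd * fld)
        new_pts = centroid + unit * new_r[:, None]
        if contour.base_indices is not None and noise.landmark_jitter_sd > 0:
            # taper each landmark displacement into its neighbourhood so a
            # large annulus jitter cannot fold the border onto itself
            tau = max(n / 36.0, 2.0)
            k = np.arange(n, dtype=float)
            for idx in contour.base_indices:
                delta = noise.landmark_jitter_sd * rng.standard_normal(2)
                dist = np.minimum(np.abs(k - idx), n - np.abs(k - idx))
                new_pts += np.exp(-0.5 * (dist / tau)**2)[:, None] * delta[None, :]
        try:
            return replace(contour, points=new_pts)
        except ContourError as err:  # self-intersection after jitter: retry
            last_err = err
    raise ContourError(f"noise created a self-intersecting contour: {last_err}")


# ---------------------------------------------------------------------------
# studies and cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticStudy:
    """One phantom subject: the shell, its noised measurements, the
    noiseless measurements, and the analytic truth."""

    study_id: str
    shell: ShellSpec
    contours: StudyMeasurements
    clean: StudyMeasurements
    true_mass: float
    true_edv: float


@dataclass(frozen=True)
class CohortSpec:
    """Cohort sampling targets (population means/SDs) plus the noise model.

    Defaults are calibrated to the porcine necropsy cohort: mass
    132 +/- 11 g, LVIDd 4.8 +/- 0.3 cm, PSAX wall 0.97 +/- 0.08 cm,
    n = 34.  Parameter draws are truncated at +/- 3 SD.
    """

    n: int = 34
    mass_mean: float = 132.0
    mass_sd: float = 11.0
    lvidd_mean: float = 4.8
    lvidd_sd: float = 0.3
    wall_mean: float = 0.97
    wall_sd: float = 0.08
    d_base_mean: float = 1.0
    d_base_sd: float = 0.1
    noise: TracingNoise = field(default_factory=TracingNoise)
    seed: int = 0
    n_points: int = 360

    def __post_init__(self) -> None:
        if self.n < 3:
            raise GeometryError(f"cohort needs n >= 3, got {self.n}")
        for name in ("mass_sd", "lvidd_sd", "wall_sd", "d_base_sd"):
            if getattr(self, name) < 0:
                raise GeometryError(f"{name} must be >= 0")


def _trunc_normal(mean: float, sd: float, rng: np.random.Generator,
                  nmax: float = 3.0) -> float:
    if sd == 0:
        return mean
    while True:
        z = rng.standard_normal()
        if abs(z) <= nmax:
            return mean + sd * z


def shell_for_mass(mass: float, b: float, t: float, d: float,
                   density: float = 1.05) -> ShellSpec:
    """Solve the apical semi-axis so the shell's true mass equals ``mass``.

    The shell volume is strictly increasing in ``a``; raises
    :class:`CalibrationError` when no anatomically plausible solution
    exists (a in [d, 40] cm)."""
    lo, hi = max(d, 0.5), 40.0

    def f(a: float) -> float:
        return true_mass(ShellSpec(a_apex=a, t_wall=t, d_base=d, b_endo=b,
                                   density=density)) - mass

    if f(lo) > 0 or f(hi) < 0:
        raise CalibrationError(
            f"target mass {mass:.1f} g unreachable with b={b:.2f}, t={t:.2f}, d={d:.2f}")
    a = brentq(f, lo, hi, xtol=1e-10)
    return ShellSpec(a_apex=float(a), t_wall=t, d_base=d, b_endo=b, density=density)


def _noised_measurements(shell: ShellSpec, noise: TracingNoise,
                         rng: np.random.Generator, study_id: str,
                         n_points: int) -> tuple[StudyMeasurements, StudyMeasurements]:
    """(noised, clean) measurement sets for one shell."""
    views = {v: render_contours(shell, v, n_points) for v in ("AP4CH", "AP2CH", "PSAX")}

    def noisy(view: str, boundary: str, shared: Optional[np.ndarray]) -> PlanarContour:
        bias = 0.0
        if boundary == "epicardium":
            bias = noise.thickness_bias if view == "PSAX" else noise.apical_epi_bias
        return add_noise(views[view][boundary], noise, rng,
                         radial_bias=bias, shared_field=shared)

    contours = {}
    for view in ("AP4CH", "AP2CH", "PSAX"):
        shared = _smooth_field(len(views[view]["endocardium"].points),
                               noise.smooth_frac, rng)
        contours[(view, "endocardium")] = noisy(view, "endocardium", shared)
        contours[(view, "epicardium")] = noisy(view, "epicardium", shared)

    biplane = BiplaneTracing(
        ap4ch_endo=contours[("AP4CH", "endocardium")],
        ap2ch_endo=contours[("AP2CH", "endocardium")],
        ap4ch_epi=contours[("AP4CH", "epicardium")],
        ap2ch_epi=contours[("AP2CH", "epicardium")])
    psax = PsaxTracing(endo=contours[("PSAX", "endocardium")],
                       epi=contours[("PSAX", "epicardium")])
    linear = derive_linear_measures(shell, noise, rng)
    noised = StudyMeasurements(study_id=study_id, biplane=biplane, psax=psax,
                               linear=linear)

    clean = StudyMeasurements(
        study_id=study_id,
        biplane=BiplaneTracing(
            ap4ch_endo=views["AP4CH"]["endocardium"],
            ap2ch_endo=views["AP2CH"]["endocardium"],
            ap4ch_epi=views["AP4CH"]["epicardium"],
            ap2ch_epi=views["AP2CH"]["epicardium"]),
        psax=PsaxTracing(endo=views["PSAX"]["endocardium"],
                         epi=views["PSAX"]["epicardium"]),
        linear=derive_linear_measures(shell))
    return noised, clean


def synthesize_study(shell: ShellSpec, noise: TracingNoise,
                     rng: np.random.Generator, study_id: str = "phantom",
                     n_points: int = 360) -> SyntheticStudy:
    """Render one shell into a full synthetic study."""
    noised, clean = _noised_measurements(shell, noise, rng, study_id, n_points)
    return SyntheticStudy(study_id=study_id, shell=shell, contours=noised,
                          clean=clean, true_mass=true_mass(shell),
                          true_edv=true_endo_volume(shell))


def simulate_cohort(spec: CohortSpec) -> list[SyntheticStudy]:
    """Simulate a cohort of phantom subjects.

    Shape parameters are drawn from truncated normals calibrated to the
    cohort targets; the apical semi-axis is solved per subject so each
    subject's true mass equals its drawn target exactly.  Deterministic
    under ``spec.seed``.
    """
    root = np.random.SeedSequence(spec.seed)
    streams = [np.random.default_rng(s) for s in root.spawn(spec.n)]
    studies = []
    for i, rng in enumerate(streams):
        mass = _trunc_normal(spec.mass_mean, spec.mass_sd, rng)
        b = _trunc_normal(spec.lvidd_mean, spec.lvidd_sd, rng) / 2.0
        t = _trunc_normal(spec.wall_mean, spec.wall_sd, rng)
        d = max(_trunc_normal(spec.d_base_mean, spec.d_base_sd, rng), 0.2)
        shell = shell_for_mass(mass, b, t, d)
        studies.append(synthesize_study(shell, spec.noise, rng,
                                        study_id=f"pig{i + 1:03d}",
                                        n_points=spec.n_points))
    return studies


def simulate_readers(study: SyntheticStudy, reader_scale_sd: float = 0.015,
                     noise: Optional[TracingNoise] = None,
                     rng: Optional[np.random.Generator] = None,
                     ) -> tuple[StudyMeasurements, StudyMeasurements]:
    """Two independent readings of the same underlying shell.

    Each reading is a fresh noised tracing set; the second reading applies
    an additional per-reader multiplicative scale (calibration error) drawn
    with SD ``reader_scale_sd``.  Feeds the intra-/inter-reader analysis.
    """
    noise = noise if noise is not None else TracingNoise()
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    r1, _ = _noised_measurements(study.shell, noise, rng,
                                 study.study_id, len(study.clean.psax.endo.points))
    r2, _ = _noised_measurements(study.shell, noise, rng,
                                 study.study_id, len(study.clean.psax.endo.points))
    scale = 1.0 + reader_scale_sd * rng.standard_normal()
    r2 = _scale_measurements(r2, scale)
    return r1, r2


def _scale_measurements(m: StudyMeasurements, k: float) -> StudyMeasurements:
    bi = m.biplane
    biplane = BiplaneTracing(
        ap4ch_endo=bi.ap4ch_endo.scaled(k), ap2ch_endo=bi.ap2ch_endo.scaled(k),
        ap4ch_epi=bi.ap4ch_epi.scaled(k) if bi.ap4ch_epi is not None else None,
        ap2ch_epi=bi.ap2ch_epi.scaled(k) if bi.ap2ch_epi is not None else None)
    psax = PsaxTracing(endo=m.psax.endo.scaled(k), epi=m.psax.epi.scaled(k))
    lm = m.linear
    linear = LinearMeasures(ivsd=lm.ivsd * k, lvidd=lm.lvidd * k, pwtd=lm.pwtd * k,
                            lvids=lm.lvids * k if lm.lvids is not None else None)
    return StudyMeasurements(study_id=m.study_id, phase=m.phase, biplane=biplane,
                             psax=psax, linear=linear, metadata=dict(m.metadata))
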