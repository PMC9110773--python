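"""The five echocardiographic left-ventricular mass methods.

Masses are myocardial volume (ml) times myocardial density (default
1.05 g/ml).

==================  ======  ===========================================
method              inputs  model
==================  ======  ===========================================
devereux            1D      ASE-corrected cube formula from IVSd, LVIDd,
                            PWTd
area_length         2D      PSAX areas + apical long-axis length
truncated_ellipsoid 2D      prolate spheroid truncated at the mitral
                            plane; PSAX areas + apical axis split (a, d)
biplane_endo_epi    2D      biplane disks on both endo- and epicardial
                            apical tracings; mass = rho (V_epi - V_endo)
novel               2D      biplane disks on the endocardium only; the
                            PSAX mean wall thickness t is added to every
                            disk to reconstruct the epicardial volume
==================  ======  ===========================================

The novel method's disk expansion widens each disk diameter by 2t (wall on
both margins) and extends the long axis apically by t (the base is the
mitral plane, where no myocardium is added).  How the extended axis is
re-discretised is not uniquely determined by the construction, so it sits
behind ``MethodConfig.apex_extension``:

``extend`` (default)
    The epicardial axis L + t is cut into the same number of slabs; each
    slab samples the endocardial chord at its own absolute depth (zero
    beyond the endocardial apex, where the disk contains wall only) and
    widens it by 2t.  On truncated-spheroid shells this reconstruction is
    accurate to a few percent (see docs/methods.md for the measured band).
``none``
    Diameters widened by 2t on the unchanged axis L (no apical cap).
``stretch``
    The endocardial diameters (widened by 2t) are reused on slabs of
    height (L + t)/N, i.e. the profile is stretched axially; this
    over-adds wall laterally and is kept for comparison only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .errors import GeometryError, TracingError
from .geometry import (
    BiplaneTracing,
    DiskStack,
    LinearMeasures,
    LongAxis,
    PsaxTracing,
    biplane_disk_volume,
    biplane_stack,
    disk_diameters,
    long_axis,
    mean_wall_thickness_from_areas,
)

METHODS = ("devereux", "area_length", "truncated_ellipsoid", "biplane_endo_epi", "novel")

APEX_RULES = ("extend", "none", "stretch")

#: PSAX input: either a traced pair or explicit (A1, A2) areas in cm^2.
PsaxLike = Union[PsaxTracing, tuple]


@dataclass(frozen=True)
class MethodConfig:
    """Shared method configuration.

    density : g/ml, default 1.05 (guideline myocardial density).
    n_disks : disk count for the biplane methods, default 20.
    apex_extension : disk-expansion rule of the novel method (see module
        docstring).
    devereux_corrected : use the ASE-corrected cube formula
        ``0.8 * 1.04 * [...] + 0.6`` (the only variant implemented; the flag
        documents the convention).
    """

    density: float = 1.05
    n_disks: int = 20
    apex_extension: str = "extend"
    devereux_corrected: bool = True

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise GeometryError(f"density must be positive, got {self.density}")
        if self.n_disks < 1:
            raise GeometryError(f"n_disks must be >= 1, got {self.n_disks}")
        if self.apex_extension not in APEX_RULES:
            raise GeometryError(
                f"apex_extension must be one of {APEX_RULES}, got {self.apex_extension!r}")


@dataclass(frozen=True)
class LVMassResult:
    """Mass in grams for one method plus its named intermediate quantities
    (wall thickness t, areas, axis length, endo/epi volumes, myocardial
    volume — whichever apply)."""

    method: str
    mass: Optional[float]
    intermediates: dict = field(default_factory=dict)
    feasible: bool = True

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise GeometryError(f"unknown method {self.method!r}")
        if self.feasible:
            if self.mass is None or self.mass < 0:
                raise GeometryError(f"feasible result requires mass >= 0, got {self.mass}")


def _psax_areas(psax: PsaxLike) -> tuple[float, float]:
    if isinstance(psax, PsaxTracing):
        return psax.a1, psax.a2
    a1, a2 = psax
    return float(a1), float(a2)


# ---------------------------------------------------------------------------
# the five methods
# ---------------------------------------------------------------------------

def devereux_mass(lm: LinearMeasures, cfg: MethodConfig = MethodConfig()) -> LVMassResult:
    """ASE-corrected Devereux cube-formula mass (g) from linear measures:

        mass = 0.8 * 1.04 * [(IVSd + LVIDd + PWTd)^3 - LVIDd^3] + 0.6
    """
    s = lm.ivsd + lm.lvidd + lm.pwtd
    mass = 0.8 * 1.04 * (s**3 - lm.lvidd**3) + 0.6
    return LVMassResult("devereux", float(mass),
                        {"ivsd_cm": lm.ivsd, "lvidd_cm": lm.lvidd, "pwtd_cm": lm.pwtd})


def area_length_mass(psax: PsaxLike, l: float,
                     cfg: MethodConfig = MethodConfig()) -> LVMassResult:
    """Area-Length mass (g) from the PSAX areas and the apical long-axis
    length L:

        t = sqrt(A1/pi) - sqrt(A2/pi)
        mass = rho * (5/6) * [A1 (L + t) - A2 L]
    """
    if l <= 0:
        raise GeometryError(f"long-axis length must be positive, got {l}")
    a1, a2 = _psax_areas(psax)
    if not a1 >= a2 > 0:
        raise TracingError(f"inverted PSAX areas: A1={a1:.4g}, A2={a2:.4g}")
    t = 0.0 if a1 == a2 else mean_wall_thickness_from_areas(a1, a2)
    vol = (5.0 / 6.0) * (a1 * (l + t) - a2 * l)
    return LVMassResult("area_length", float(cfg.density * vol),
                        {"t_cm": t, "a1_cm2": a1, "a2_cm2": a2, "l_cm": l,
                         "myocardial_volume_ml": vol})


def _te_cavity_factor(a: float, d: float) -> float:
    """Axial factor of the truncated prolate spheroid: the volume enclosed
    between the apex (semi-axis a) and the mitral plane d above the widest
    cross-section is pi b^2 * [(2/3) a + d - d^3 / (3 a^2)]."""
    return (2.0 / 3.0) * a + d - d**3 / (3.0 * a**2)


def truncated_ellipsoid_mass(psax: PsaxLike, a: float, d: float,
                             cfg: MethodConfig = MethodConfig()) -> LVMassResult:
    """Truncated-ellipsoid mass (g).

    ``a`` is the apical semi-axis (widest-chord plane to apex), ``d`` the
    basal truncation (widest-chord plane to base); ``b = sqrt(A2/pi)`` and
    ``t`` come from the PSAX areas.  The myocardial shell is the difference
    of two concentric truncated spheroids sharing the mitral plane:

        mass = rho pi { (b+t)^2 [(2/3)(a+t) + d - d^3/(3(a+t)^2)]
                        - b^2   [(2/3) a    + d - d^3/(3 a^2)] }
    """
    if a <= 0:
        raise GeometryError(f"apical semi-axis must be positive, got {a}")
    if d < 0 or d > a:
        raise GeometryError(f"basal truncation d={d} outside [0, a={a}]")
    a1, a2 = _psax_areas(psax)
    if not a1 >= a2 > 0:
        raise TracingError(f"inverted PSAX areas: A1={a1:.4g}, A2={a2:.4g}")
    b = float(np.sqrt(a2 / np.pi))
    t = 0.0 if a1 == a2 else mean_wall_thickness_from_areas(a1, a2)
    vol = np.pi * ((b + t)**2 * _te_cavity_factor(a + t, d)
                   - b**2 * _te_cavity_factor(a, d))
    return LVMassResult("truncated_ellipsoid", float(cfg.density * vol),
                        {"t_cm": t, "b_cm": b, "a_cm": a, "d_cm": d,
                         "a1_cm2": a1, "a2_cm2": a2, "myocardial_volume_ml": float(vol)})


def biplane_endo_epi_mass(tr: BiplaneTracing,
                          cfg: MethodConfig = MethodConfig()) -> LVMassResult:
    """Mass (g) from separate endo- and epicardial biplane disk volumes:
    ``mass = rho (V_epi - V_endo)``."""
    if not tr.has_epicardium:
        raise TracingError("biplane endo/epi method requires epicardial tracings in both views")
    endo = biplane_stack(tr.ap4ch_endo, tr.ap2ch_endo, cfg.n_disks)
    epi = _epicardial_stack(tr, cfg.n_disks)
    v_endo = biplane_disk_volume(endo)
    v_epi = biplane_disk_volume(epi)
    if v_epi <= v_endo:
        raise TracingError(
            f"epicardial volume ({v_epi:.2f} ml) does not exceed endocardial "
            f"volume ({v_endo:.2f} ml)")
    vol = v_epi - v_endo
    return LVMassResult("biplane_endo_epi", float(cfg.density * vol),
                        {"edv_endo_ml": v_endo, "edv_epi_ml": v_epi,
                         "myocardial_volume_ml": vol})


def _epicardial_stack(tr: BiplaneTracing, n_disks: int) -> DiskStack:
    """Disk stack of the epicardial pair.  Epicardial contours may lack base
    landmarks; the endocardial base midpoint then anchors the axis (same
    mitral plane) with the apex at the farthest epicardial vertex."""
    stacks = []
    for epi, endo in ((tr.ap4ch_epi, tr.ap4ch_endo), (tr.ap2ch_epi, tr.ap2ch_endo)):
        if epi.base_indices is not None:
            stacks.append(long_axis(epi))
        else:
            base_mid = long_axis(endo).base_mid
            dist = np.linalg.norm(epi.points - base_mid, axis=1)
            k = int(np.argmax(dist))
            stacks.append(LongAxis(base_mid=base_mid, apex=epi.points[k],
                                   length=float(dist[k])))
    ax4, ax2 = stacks
    length = max(ax4.length, ax2.length)
    fr = (np.arange(n_disks) + 0.5) / n_disks
    da = disk_diameters(tr.ap4ch_epi, ax4, n_disks, fractions=fr)
    db = disk_diameters(tr.ap2ch_epi, ax2, n_disks, fractions=fr)
    return DiskStack(diam_a=da, diam_b=db, disk_height=length / n_disks,
                     n_disks=n_disks, long_axis_length=length)


def expand_endo_stack(ap4ch_endo, ap2ch_endo, t: float, n_disks: int,
                      rule: str) -> tuple[DiskStack, DiskStack]:
    """Endocardial disk stack plus its disk-expansion epicardial
    reconstruction (see module docstring for the rules).

    Returns ``(endo_stack, epi_stack)``.  Exposed so the disk-expansion
    geometry can be inspected and so epicardial contours matching the rule
    can be constructed for consistency checks.
    """
    if rule not in APEX_RULES:
        raise GeometryError(f"unknown apex_extension rule {rule!r}")
    ax4, ax2 = long_axis(ap4ch_endo), long_axis(ap2ch_endo)
    length = max(ax4.length, ax2.length)
    fr = (np.arange(n_disks) + 0.5) / n_disks
    da = disk_diameters(ap4ch_endo, ax4, n_disks, fractions=fr)
    db = disk_diameters(ap2ch_endo, ax2, n_disks, fractions=fr)
    endo = DiskStack(diam_a=da, diam_b=db, disk_height=length / n_disks,
                     n_disks=n_disks, long_axis_length=length)

    if rule == "none":
        epi = DiskStack(diam_a=da + 2 * t, diam_b=db + 2 * t,
                        disk_height=length / n_disks, n_disks=n_disks,
                        long_axis_length=length)
    elif rule == "stretch":
        epi = DiskStack(diam_a=da + 2 * t, diam_b=db + 2 * t,
                        disk_height=(length + t) / n_disks, n_disks=n_disks,
                        long_axis_length=length + t)
    else:  # "extend": re-slab the lengthened axis; wall-only disks past the apex
        l_epi = length + t
        fr_epi = (np.arange(n_disks) + 0.5) / n_disks
        # depth of each epi slab midpoint expressed as a fraction of the
        # endocardial axis; chords vanish beyond the endocardial apex
        fr_on_endo = fr_epi * l_epi / length
        inside = fr_on_endo <= 1.0
        ca = np.zeros(n_disks)
        cb = np.zeros(n_disks)
        if np.any(inside):
            ca[inside] = disk_diameters(ap4ch_endo, ax4, int(inside.sum()),
                                        fractions=fr_on_endo[inside])
            cb[inside] = disk_diameters(ap2ch_endo, ax2, int(inside.sum()),
                                        fractions=fr_on_endo[inside])
        epi = DiskStack(diam_a=ca + 2 * t, diam_b=cb + 2 * t,
                        disk_height=l_epi / n_disks, n_disks=n_disks,
                        long_axis_length=l_epi)
    return endo, epi


def novel_mass(tr: BiplaneTracing, psax: PsaxLike,
               cfg: MethodConfig = MethodConfig()) -> LVMassResult:
    """Novel disk-expansion mass (g).

    The PSAX mean wall thickness ``t`` is added to every disk of the
    endocardial biplane stack (diameters + 2t, axis lengthened apically by
    t per ``cfg.apex_extension``); the reconstructed epicardial volume
    EDV_EPI minus EDV_ENDO times density is the mass.  No epicardial apical
    tracing is required.
    """
    a1, a2 = _psax_areas(psax)
    t = mean_wall_thickness_from_areas(a1, a2)  # raises unless A1 > A2 > 0
    endo, epi = expand_endo_stack(tr.ap4ch_endo, tr.ap2ch_endo, t,
                                  cfg.n_disks, cfg.apex_extension)
    edv_endo = biplane_disk_volume(endo)
    edv_epi = biplane_disk_volume(epi)
    vol = edv_epi - edv_endo
    return LVMassResult("novel", float(cfg.density * vol),
                        {"t_cm": t, "a1_cm2": a1, "a2_cm2": a2,
                         "l_cm": endo.long_axis_length,
                         "edv_endo_ml": edv_endo, "edv_epi_ml": edv_epi,
                         "myocardial_volume_ml": vol})


# ---------------------------------------------------------------------------
# per-study dispatch
# ---------------------------------------------------------------------------

def apical_axis_split(contour, n_scan: int = 200) -> tuple[float, float, float]:
    """Split the apical long axis at the widest-chord plane.

    Returns ``(l, a, d)``: total axis length, widest-plane-to-apex distance
    ``a`` and widest-plane-to-base distance ``d``, the geometric inputs of
    the truncated-ellipsoid and area-length methods.
    """
    ax = long_axis(contour)
    fr = (np.arange(n_scan) + 0.5) / n_scan
    widths = disk_diameters(contour, ax, n_scan, fractions=fr)
    k = int(np.argmax(widths))
    d = float(fr[k] * ax.length)
    return ax.length, ax.length - d, d


def quantify_all(study, cfg: MethodConfig = MethodConfig()) -> list[LVMassResult]:
    """All five mass methods on one study; methods whose inputs are missing
    are reported with ``feasible=False`` rather than raised."""
    results: list[LVMassResult] = []

    def infeasible(name: str, why: str) -> LVMassResult:
        return LVMassResult(name, None, {"reason": why}, feasible=False)

    # devereux
    if study.linear is not None:
        results.append(devereux_mass(study.linear, cfg))
    else:
        results.append(infeasible("devereux", "no linear measures"))

    psax = study.psax
    bi = study.biplane
    ap4 = bi.ap4ch_endo if bi is not None else None

    # area-length & truncated ellipsoid: PSAX + AP4CH endocardium
    if psax is not None and ap4 is not None:
        l, a, d = apical_axis_split(ap4)
        results.append(area_length_mass(psax, l, cfg))
        results.append(truncated_ellipsoid_mass(psax, a, d, cfg))
    else:
        why = "needs PSAX tracing and AP4CH endocardium"
        results.append(infeasible("area_length", why))
        results.append(infeasible("truncated_ellipsoid", why))

    # biplane endo/epi
    if bi is not None and bi.has_epicardium:
        results.append(biplane_endo_epi_mass(bi, cfg))
    else:
        results.append(infeasible("biplane_endo_epi", "needs epicardial apical tracings"))

    # novel
    if bi is not None and psax is not None:
        results.append(novel_mass(bi, psax, cfg))
    else:
        results.append(infeasible("novel", "needs endocardial biplane and PSAX tracings"))

    return results
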