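"""Independent brute-force oracles used by the test suite.

Everything here is written as explicit loops over the defining sums —
deliberately naive and independent of both lvmass and the scipy shortcuts
it uses, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import special


def brute_mean(xs) -> float:
    s = 0.0
    for x in xs:
        s += x
    return s / len(xs)


def brute_sd(xs) -> float:
    m = brute_mean(xs)
    s = 0.0
    for x in xs:
        s += (x - m) ** 2
    return math.sqrt(s / (len(xs) - 1))


def brute_bias_loa(pred, ref) -> tuple[float, float, float]:
    d = [p - r for p, r in zip(pred, ref)]
    sd = brute_sd(d)
    return brute_mean(d), 1.96 * sd, sd


def brute_cv(pred, ref) -> float:
    return 100.0 * brute_bias_loa(pred, ref)[2] / brute_mean(ref)


def brute_ols(x, y) -> tuple[float, float]:
    """Normal-equations slope and intercept of y on x."""
    n = len(x)
    sx = sy = sxx = sxy = 0.0
    for xi, yi in zip(x, y):
        sx += xi
        sy += yi
        sxx += xi * xi
        sxy += xi * yi
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    return slope, (sy - slope * sx) / n


def brute_see(pred, ref) -> float:
    slope, intercept = brute_ols(ref, pred)
    rss = 0.0
    for xi, yi in zip(ref, pred):
        rss += (yi - (slope * xi + intercept)) ** 2
    return math.sqrt(rss / (len(pred) - 2))


def _t_sf(t: float, df: int) -> float:
    """Survival function of Student's t via the incomplete beta function."""
    x = df / (df + t * t)
    p = 0.5 * special.betainc(df / 2.0, 0.5, x)
    return p if t >= 0 else 1.0 - p


def brute_pearson(pred, ref) -> tuple[float, float]:
    n = len(pred)
    mp, mr = brute_mean(pred), brute_mean(ref)
    num = dp = dr = 0.0
    for p, r in zip(pred, ref):
        num += (p - mp) * (r - mr)
        dp += (p - mp) ** 2
        dr += (r - mr) ** 2
    rho = num / math.sqrt(dp * dr)
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return rho, 2.0 * _t_sf(abs(t), n - 2)


def brute_paired_t(pred, ref) -> float:
    d = [p - r for p, r in zip(pred, ref)]
    n = len(d)
    t = brute_mean(d) / (brute_sd(d) / math.sqrt(n))
    return 2.0 * _t_sf(abs(t), n - 1)


def brute_prop_bias(pred, ref) -> tuple[float, float]:
    d = [p - r for p, r in zip(pred, ref)]
    n = len(d)
    slope, intercept = brute_ols(ref, d)
    rss = 0.0
    for xi, yi in zip(ref, d):
        rss += (yi - (slope * xi + intercept)) ** 2
    mr = brute_mean(ref)
    sxx = 0.0
    for xi in ref:
        sxx += (xi - mr) ** 2
    se = math.sqrt(rss / (n - 2) / sxx)
    return slope, 2.0 * _t_sf(abs(slope / se), n - 2)


# ---------------------------------------------------------------------------
# geometric oracles
# ---------------------------------------------------------------------------

def shell_volume_quadrature(a, t, d, bx, by=None, n=200_000) -> float:
    """Truncated-spheroid shell volume by 1D quadrature of the annular
    cross-section area along the long axis (midpoint rule, fine grid)."""
    by = bx if by is None else by
    a_o, bx_o, by_o = a + t, bx + t, by + t
    z = np.linspace(-a_o, d, n + 1)
    zm = 0.5 * (z[:-1] + z[1:])
    outer = np.pi * bx_o * by_o * np.clip(1 - zm**2 / a_o**2, 0, None)
    inner = np.pi * bx * by * np.clip(1 - zm**2 / a**2, 0, None)
    return float(np.sum(outer - inner) * (z[1] - z[0]))


def novel_reconstruction_analytic(a, b, t, d, n_disks=20, rule="extend",
                                  density=1.05) -> float:
    """Disk-expansion mass computed from analytic spheroid chords — the
    same expansion rule as the implementation but independent of the
    polygon/chord-scanning machinery."""
    L = a + d

    def chord(depth_from_base):
        z = d - depth_from_base
        return 2 * b * math.sqrt(max(1 - z * z / (a * a), 0.0))

    fr = [(i + 0.5) / n_disks for i in range(n_disks)]
    c = [chord(f * L) for f in fr]
    edv = math.pi / 4 * sum(ci * ci for ci in c) * (L / n_disks)
    if rule == "none":
        epi = math.pi / 4 * sum((ci + 2 * t) ** 2 for ci in c) * (L / n_disks)
    elif rule == "stretch":
        epi = math.pi / 4 * sum((ci + 2 * t) ** 2 for ci in c) * ((L + t) / n_disks)
    else:
        le = L + t
        ce = [chord(f * le) if f * le <= L else 0.0 for f in fr]
        epi = math.pi / 4 * sum((ci + 2 * t) ** 2 for ci in ce) * (le / n_disks)
    return density * (epi - edv)
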