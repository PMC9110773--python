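"""Method-agreement statistics against a reference standard.

The protocol treats the reference (necropsy mass, or a baseline reading)
as the true value rather than as a second method: differences are
``predicted - reference``, positive differences mean overestimation, and
both the coefficient of variation and the per-subject percentage
differences are scaled by the reference.

Quantities per method
---------------------
bias, LOA      mean difference and 95% limits of agreement
               (bias +/- 1.96 * SD of the differences)
CV             100 * SD(differences) / mean(reference), percent
SEE            residual SD of the OLS regression of predicted on
               reference, sqrt(RSS / (n - 2))
Pearson r, p   product-moment correlation, two-sided p
paired t       two-sided paired t-test of predicted vs reference
proportional   OLS slope of difference on reference with its two-sided p;
bias           no proportional bias is declared when p >= alpha (0.05)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import AnalysisError

LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class PairedSeries:
    """Per-subject predicted vs reference masses in grams.

    Subjects with any missing value must be excluded before construction
    (complete-case analysis, as for the feasibility subgroup).
    """

    subject_ids: tuple
    predicted: np.ndarray
    reference: np.ndarray

    def __post_init__(self) -> None:
        ids = tuple(self.subject_ids)
        p = np.asarray(self.predicted, dtype=float)
        r = np.asarray(self.reference, dtype=float)
        if not (len(ids) == len(p) == len(r)):
            raise AnalysisError(
                f"length mismatch: {len(ids)} ids, {len(p)} predicted, {len(r)} reference")
        if len(ids) < 3:
            raise AnalysisError(f"need >= 3 paired subjects, got {len(ids)}")
        if not (np.all(np.isfinite(p)) and np.all(np.isfinite(r))):
            raise AnalysisError("paired series contains missing/non-finite values")
        if np.any(p <= 0) or np.any(r <= 0):
            raise AnalysisError("masses must be positive")
        object.__setattr__(self, "subject_ids", ids)
        object.__setattr__(self, "predicted", p)
        object.__setattr__(self, "reference", r)

    @property
    def n(self) -> int:
        return len(self.subject_ids)

    @property
    def differences(self) -> np.ndarray:
        """Per-subject predicted - reference (g); positive = overestimation."""
        return self.predicted - self.reference


@dataclass(frozen=True)
class AgreementSummary:
    """Full agreement panel for one method versus the reference."""

    n: int
    bias: float
    sd_diff: float
    loa_half_width: float
    cv_pct: float
    see: float
    pearson_r: float
    pearson_p: float
    paired_t_p: float
    prop_bias_slope: float
    prop_bias_p: float


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def bias_loa(s: PairedSeries) -> tuple[float, float, float]:
    """(bias, LOA half-width, SD of differences), all in grams.

    bias = mean(predicted - reference); LOA half-width = 1.96 * sample SD
    (n - 1 denominator) of the differences.
    """
    d = s.differences
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return bias, LOA_MULTIPLIER * sd, sd


def cv_percent(s: PairedSeries) -> float:
    """Coefficient of variation: 100 * SD(differences) / mean(reference)."""
    mref = float(np.mean(s.reference))
    if mref == 0.0:
        raise AnalysisError("mean reference is zero; CV undefined")
    _, _, sd = bias_loa(s)
    return 100.0 * sd / mref


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Slope, intercept and residuals of y on x (least squares)."""
    if np.ptp(x) == 0.0:
        raise AnalysisError("constant independent variable; regression degenerate")
    coef, *_ = np.linalg.lstsq(np.column_stack([x, np.ones_like(x)]), y, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    return slope, intercept, y - (slope * x + intercept)


def see(s: PairedSeries) -> float:
    """Standard error of the estimate (g): residual SD of the regression of
    predicted on reference, sqrt(sum resid^2 / (n - 2))."""
    _, _, resid = _ols(s.reference, s.predicted)
    return float(np.sqrt(np.sum(resid**2) / (s.n - 2)))


def pearson(s: PairedSeries) -> tuple[float, float]:
    """Pearson product-moment correlation and its two-sided p."""
    if np.ptp(s.predicted) == 0.0 or np.ptp(s.reference) == 0.0:
        raise AnalysisError("constant series; correlation undefined")
    r, p = stats.pearsonr(s.predicted, s.reference)
    return float(r), float(p)


def paired_t(s: PairedSeries) -> float:
    """Two-sided paired t-test p-value of predicted vs reference.

    Zero-variance differences with zero mean return p = 1 by convention.
    """
    d = s.differences
    if np.ptp(d) == 0.0:
        if d[0] == 0.0:
            return 1.0
        raise AnalysisError("constant non-zero differences; t statistic undefined")
    _, p = stats.ttest_rel(s.predicted, s.reference)
    return float(p)


def proportional_bias(s: PairedSeries) -> tuple[float, float]:
    """OLS slope of (predicted - reference) on reference, with the
    two-sided t-test p-value of the slope."""
    x, y = s.reference, s.differences
    slope, _, resid = _ols(x, y)
    n = s.n
    sxx = float(np.sum((x - x.mean())**2))
    mse = float(np.sum(resid**2)) / (n - 2)
    if mse == 0.0:
        # perfect linear dependence: p -> 0 for non-zero slope, 1 otherwise
        return slope, 0.0 if slope != 0.0 else 1.0
    t_stat = slope / np.sqrt(mse / sxx)
    p = 2.0 * stats.t.sf(abs(t_stat), n - 2)
    return slope, float(p)


def percent_differences(s: PairedSeries) -> np.ndarray:
    """Per-subject percentage difference, 100 (predicted - reference) /
    reference; positive = overestimation."""
    return 100.0 * s.differences / s.reference


def summarize(s: PairedSeries) -> AgreementSummary:
    """Full agreement panel for one method."""
    bias, loa, sd = bias_loa(s)
    r, rp = pearson(s)
    slope, sp = proportional_bias(s)
    return AgreementSummary(
        n=s.n, bias=bias, sd_diff=sd, loa_half_width=loa,
        cv_pct=cv_percent(s), see=see(s), pearson_r=r, pearson_p=rp,
        paired_t_p=paired_t(s), prop_bias_slope=slope, prop_bias_p=sp)


# ---------------------------------------------------------------------------
# per-subject accuracy ranking
# ---------------------------------------------------------------------------

def rank_accuracy(methods: Mapping[str, PairedSeries],
                  complete_cases_only: bool = True) -> dict:
    """Count, per method, for how many subjects it was the most and the
    least accurate (smallest / largest absolute percentage difference).

    Ties split the credit equally (0.5 each for a two-way tie), so counts
    always sum to the number of subjects.  With ``complete_cases_only``
    (default) only subjects present in every series are ranked.
    """
    if not methods:
        raise AnalysisError("no method series supplied")
    id_sets = [set(s.subject_ids) for s in methods.values()]
    common = set.intersection(*id_sets)
    if complete_cases_only:
        subjects = sorted(common)
    else:
        subjects = sorted(set.union(*id_sets))
    if not subjects:
        raise AnalysisError("no subjects shared across the method series")

    abs_pct: dict[str, dict] = {}
    for name, s in methods.items():
        pct = percent_differences(s)
        abs_pct[name] = dict(zip(s.subject_ids, np.abs(pct)))

    most = {m: 0.0 for m in methods}
    least = {m: 0.0 for m in methods}
    n_ranked = 0
    for subj in subjects:
        vals = {m: abs_pct[m][subj] for m in methods if subj in abs_pct[m]}
        if len(vals) < 2:
            continue
        n_ranked += 1
        lo = min(vals.values())
        hi = max(vals.values())
        winners = [m for m, v in vals.items() if v == lo]
        losers = [m for m, v in vals.items() if v == hi]
        for m in winners:
            most[m] += 1.0 / len(winners)
        for m in losers:
            least[m] += 1.0 / len(losers)

    def with_pct(counts: dict) -> dict:
        return {m: {"count": c, "pct": 100.0 * c / n_ranked if n_ranked else np.nan}
                for m, c in counts.items()}

    return {"n_subjects": n_ranked, "most_accurate": with_pct(most),
            "least_accurate": with_pct(least)}


# ---------------------------------------------------------------------------
# reader variability
# ---------------------------------------------------------------------------

def reader_variability(baseline_ids: Sequence, baseline: Sequence[float],
                       repeat_ids: Sequence, repeat: Sequence[float]) -> dict:
    """Intra-/inter-reader reproducibility of one method.

    Differences are repeat - baseline (positive bias = overestimation by
    the repeat reading); CV is scaled by the mean of the baseline reading
    and SEE comes from the regression of repeat on baseline.
    """
    if tuple(baseline_ids) != tuple(repeat_ids):
        raise AnalysisError("baseline and repeat readings cover different subjects")
    s = PairedSeries(tuple(baseline_ids), np.asarray(repeat, float),
                     np.asarray(baseline, float))
    bias, loa, sd = bias_loa(s)
    return {"n": s.n, "bias": bias, "loa_half_width": loa, "sd_diff": sd,
            "cv_pct": cv_percent(s), "see": see(s)}


# ---------------------------------------------------------------------------
# plotting
# ---------------------------------------------------------------------------

def bland_altman_plot(s: PairedSeries, ax=None, label: Optional[str] = None):
    """Difference-versus-reference agreement plot.

    Differences (predicted - reference) are plotted against the reference
    with the bias line, the 95% limits of agreement and the
    proportional-bias regression line.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    bias, loa, _ = bias_loa(s)
    slope, _, resid = _ols(s.reference, s.differences)
    intercept = float(np.mean(s.differences) - slope * np.mean(s.reference))
    x = s.reference
    ax.scatter(x, s.differences, s=18, color="tab:blue", zorder=3)
    ax.axhline(0.0, color="black", lw=0.8, ls=":")
    ax.axhline(bias, color="black", lw=1.2)
    ax.axhline(bias + loa, color="tab:red", lw=1.0)
    ax.axhline(bias - loa, color="tab:red", lw=1.0)
    xx = np.linspace(x.min(), x.max(), 50)
    ax.plot(xx, slope * xx + intercept, color="black", lw=0.8)
    ax.set_xlabel("reference LVM (g)")
    ax.set_ylabel("difference (g)")
    if label:
        ax.set_title(label)
    return ax
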