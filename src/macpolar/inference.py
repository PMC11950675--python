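"""Hypothesis tests and dose-response IC50 extraction.

Small two-group comparisons use an exact Mann-Whitney U test: for pooled
sizes n + m <= 12 every C(n+m, n) group assignment is enumerated on the
midranks, and the two-sided p is the doubled smaller tail probability
capped at 1 (conventions differ between software packages; this one is
fixed and tested against brute force).  Larger samples fall back to the
tie-corrected normal approximation.

IC50 is read off the dose-response curve the way it is read off a plot:
average the replicate viabilities per dose, find the first adjacent dose
pair whose means bracket 50% of the untreated control, and interpolate
linearly on log10(dose).  Curves that never cross 50% are reported as
censored at the dose range edge rather than extrapolated.  An optional
four-parameter-logistic fit is provided for synthetic-recovery checks.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import DegenerateDataError, ValidationError

EXACT_SIZE_CAP = 12  # enumerate all assignments up to this pooled size


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p: float
    n_per_group: tuple[int, ...]
    exact: bool
    zero_variance: bool = False


def _u_statistic(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2)


def mann_whitney(a, b, *, exact_cap: int = EXACT_SIZE_CAP) -> TestResult:
    """Two-sided Mann-Whitney U test with midrank tie handling.

    Exact by full enumeration when len(a)+len(b) <= ``exact_cap``; otherwise
    the tie-corrected normal approximation (continuity-corrected).
    The reported statistic is U of the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        raise ValidationError("mann_whitney needs two non-empty groups")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks
    u_obs = _u_statistic(ranks[:n], n)
    if n + m <= exact_cap:
        lo = hi = 0
        total = 0
        eps = 1e-9
        for comb in itertools.combinations(range(n + m), n):
            u = _u_statistic(ranks[list(comb)], n)
            total += 1
            if u <= u_obs + eps:
                lo += 1
            if u >= u_obs - eps:
                hi += 1
        p = min(1.0, 2.0 * min(lo, hi) / total)
        return TestResult("mann-whitney (exact enumeration)", u_obs, p, (n, m), True)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return TestResult("mann-whitney (normal approximation)", float(res.statistic),
                      float(res.pvalue), (n, m), False)


def anova_oneway(groups: list, *, labels: list[str] | None = None) -> TestResult:
    """One-way ANOVA F test across >= 2 groups of n >= 2 each.

    All groups identical and constant is reported as p = 1 with the
    zero-variance flag rather than a NaN.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(len(g) < 2 for g in arrs):
        raise ValidationError("anova needs >= 2 groups with n >= 2 each")
    sizes = tuple(len(g) for g in arrs)
    pooled = np.concatenate(arrs)
    if np.ptp(pooled) == 0:
        return TestResult("one-way anova", 0.0, 1.0, sizes, False, zero_variance=True)
    f, p = stats.f_oneway(*arrs)
    return TestResult("one-way anova", float(f), float(p), sizes, False)


def posthoc_vs_control(groups: dict, control: str) -> dict:
    """Pairwise two-sample t tests of each group against the named control,
    Holm-adjusted across the comparisons."""
    from statsmodels.stats.multitest import multipletests

    if control not in groups:
        raise ValidationError(f"control group {control!r} not among {sorted(groups)}")
    ctrl = np.asarray(groups[control], dtype=float)
    names = [g for g in groups if g != control]
    if not names:
        raise ValidationError("no treatment groups to compare against control")
    raw = []
    stats_ = []
    for g in names:
        t, p = stats.ttest_ind(np.asarray(groups[g], dtype=float), ctrl)
        raw.append(float(p) if math.isfinite(p) else 1.0)
        stats_.append(float(t))
    reject, adj, _, _ = multipletests(raw, method="holm")
    return {g: {"t": s, "p_raw": p, "p_holm": float(q), "significant": bool(rej)}
            for g, s, p, q, rej in zip(names, stats_, raw, adj, reject)}


def chi_square(table, *, yates: bool = False) -> TestResult:
    """Pearson chi-square test of independence on a two-way count table."""
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or min(tab.shape) < 2:
        raise ValidationError("chi_square needs at least a 2x2 table")
    if (tab < 0).any() or not np.allclose(tab, np.round(tab)):
        raise ValidationError("chi_square needs non-negative integer counts")
    if (tab.sum(axis=1) == 0).any() or (tab.sum(axis=0) == 0).any():
        raise DegenerateDataError("contingency table has an all-zero row or column")
    res = stats.chi2_contingency(tab, correction=yates)
    name = "chi-square" + (" (Yates)" if yates else "")
    return TestResult(name, float(res.statistic), float(res.pvalue),
                      tuple(int(s) for s in tab.sum(axis=1)), False)


def bh_adjust(pvalues, alpha: float = 0.10) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted q-values and rejections at
    q <= alpha."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


# ---------------------------------------------------------------------------
# dose-response


@dataclass
class DoseResponseCurve:
    """Doses (µM, strictly increasing, > 0) and replicate viability
    responses per dose, as % of the untreated control."""

    doses: np.ndarray
    responses: np.ndarray  # shape (n_doses, n_replicates) or (n_doses,)

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.atleast_2d(np.asarray(self.responses, dtype=float))
        if self.responses.shape[0] != self.doses.size:
            self.responses = self.responses.T
        if self.doses.size < 2:
            raise ValidationError("dose-response needs >= 2 dose levels")
        if (self.doses <= 0).any() or (np.diff(self.doses) <= 0).any():
            raise ValidationError("doses must be positive and strictly increasing")
        if not np.isfinite(self.responses).all():
            raise ValidationError("non-finite responses")

    def mean_responses(self) -> np.ndarray:
        return self.responses.mean(axis=1)


@dataclass(frozen=True)
class IC50Result:
    value: float | None          # µM; None when censored
    censored: str | None = None  # ">100" / "<0.01" style bound, or None
    multiple_crossings: bool = False
    level: float = 50.0

    @property
    def is_censored(self) -> bool:
        return self.censored is not None


def ic50_interpolate(curve: DoseResponseCurve, *, level: float = 50.0) -> IC50Result:
    """IC50 by log-linear interpolation of per-dose mean responses.

    The first adjacent dose pair whose means bracket ``level`` defines the
    crossing; exact hits return the measured dose.  A curve entirely above
    the level is censored '>max dose'; entirely below, '<min dose'.
    Additional crossings are flagged but the first is used.
    """
    means = curve.mean_responses()
    doses = curve.doses
    crossings = []
    for i in range(len(doses) - 1):
        a, b = means[i] - level, means[i + 1] - level
        if a == 0:
            crossings.append(float(doses[i]))
        elif a * b < 0:
            f = a / (a - b)  # fraction of the log-interval to the crossing
            logd = np.log10(doses[i]) + f * (np.log10(doses[i + 1]) - np.log10(doses[i]))
            crossings.append(float(10 ** logd))
    if means[-1] == level:
        crossings.append(float(doses[-1]))
    if not crossings:
        if (means > level).all():
            return IC50Result(None, censored=f">{doses[-1]:g}", level=level)
        return IC50Result(None, censored=f"<{doses[0]:g}", level=level)
    return IC50Result(crossings[0], multiple_crossings=len(crossings) > 1, level=level)


def four_pl(dose, ic50, hill=1.0, top=100.0, bottom=0.0):
    """Four-parameter logistic viability model (decreasing in dose)."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / ic50) ** hill)


def fit_4pl(curve: DoseResponseCurve) -> dict:
    """Least-squares 4PL fit (top/bottom fixed at 100/0); used for
    synthetic-recovery cross-checks of the interpolation estimate."""
    means = curve.mean_responses()
    lo = float(curve.doses[0])
    hi = float(curve.doses[-1])
    p0 = (float(np.sqrt(lo * hi)), 1.0)
    popt, _ = optimize.curve_fit(
        lambda d, ic50, h: four_pl(d, ic50, h),
        curve.doses, means, p0=p0,
        bounds=([lo / 1e3, 0.1], [hi * 1e3, 10.0]), maxfev=10000)
    return {"ic50": float(popt[0]), "hill": float(popt[1])}
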