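"""Diagnostic-performance statistics for continuous screening indices.

The ROC machinery (operating points, rank-based AUC with DeLong variance,
Youden-optimal cutoff, paired AUC comparison) is implemented here directly,
since threshold conventions and tie handling are the substance of the
analysis.  The positivity convention throughout is ``score >= threshold``:
high index values indicate metabolic risk.

Generic hypothesis tests (Spearman, Wilcoxon rank-sum, chi-square,
Kolmogorov-Smirnov/Lilliefors) delegate to scipy/statsmodels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, DomainError

__all__ = [
    "ScoredCohort",
    "ValueCI",
    "DiagnosticReport",
    "roc_points",
    "auc_rank",
    "youden_cutoff",
    "confusion_metrics",
    "wald_ci",
    "clopper_pearson_ci",
    "delong_compare",
    "evaluate_index",
    "prevalence_percent",
    "spearman_rho",
    "rank_sum_test",
    "chi2_2x2",
    "ks_normality",
    "tukey_outliers",
    "cutoff_trend",
]

_Z975 = stats.norm.ppf(0.975)


@dataclass
class ScoredCohort:
    """Parallel per-subject arrays: index value, MetS label, and optionally
    sex ('F'/'M') and age in years."""

    score: np.ndarray
    label: np.ndarray
    sex: Optional[np.ndarray] = None
    age: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=float)
        self.label = np.asarray(self.label).astype(bool)
        if self.score.shape != self.label.shape or self.score.ndim != 1:
            raise DegenerateInputError("score and label must be equal-length 1-D")
        for name in ("sex", "age"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v)
                if v.shape != self.score.shape:
                    raise DegenerateInputError(f"{name} length mismatch")
                setattr(self, name, v)
        if np.any(~np.isfinite(self.score)):
            raise DomainError("score", "scores must be finite")

    @property
    def n(self) -> int:
        return self.score.size

    @property
    def n_pos(self) -> int:
        return int(self.label.sum())

    @property
    def n_neg(self) -> int:
        return int((~self.label).sum())

    def require_both_classes(self) -> None:
        if self.n_pos == 0 or self.n_neg == 0:
            raise DegenerateInputError(
                f"ROC analysis needs both classes (got {self.n_pos} positives, "
                f"{self.n_neg} negatives)"
            )


@dataclass(frozen=True)
class ValueCI:
    value: float
    lo: float
    hi: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.value, self.lo, self.hi)


def roc_points(cohort: ScoredCohort) -> list[tuple[float, float, float]]:
    """Empirical ROC operating points as (threshold, sensitivity, 1-specificity).

    One point per distinct observed score (positive iff score >= threshold),
    bracketed by the trivial (+inf, 0, 0) and (-inf, 1, 1) endpoints.
    Both coordinates are nondecreasing as the threshold decreases.
    """
    cohort.require_both_classes()
    pos = np.sort(cohort.score[cohort.label])
    neg = np.sort(cohort.score[~cohort.label])
    points = [(math.inf, 0.0, 0.0)]
    for t in np.unique(cohort.score)[::-1]:
        sens = 1.0 - np.searchsorted(pos, t, side="left") / pos.size
        fpr = 1.0 - np.searchsorted(neg, t, side="left") / neg.size
        points.append((float(t), float(sens), float(fpr)))
    points.append((-math.inf, 1.0, 1.0))
    return points


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(label: np.ndarray, scores: np.ndarray):
    """DeLong structural components for k paired score vectors.

    Returns (aucs[k], cov[k, k]) where ``cov`` estimates the covariance
    matrix of the AUC estimators.
    """
    pos = scores[:, label]
    neg = scores[:, ~label]
    m, n = pos.shape[1], neg.shape[1]
    k = scores.shape[0]
    v01 = np.empty((k, m))
    v10 = np.empty((k, n))
    aucs = np.empty(k)
    for r in range(k):
        tx = _midrank(pos[r])
        ty = _midrank(neg[r])
        tz = _midrank(np.concatenate([pos[r], neg[r]]))
        aucs[r] = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        v01[r] = (tz[:m] - tx) / n
        v10[r] = 1.0 - (tz[m:] - ty) / m
    def _cov(v: np.ndarray) -> np.ndarray:
        if v.shape[1] < 2:  # a single-member class contributes no variance
            return np.zeros((k, k))
        return np.atleast_2d(np.cov(v))

    cov = _cov(v01) / m + _cov(v10) / n
    return aucs, cov


def auc_rank(cohort: ScoredCohort) -> ValueCI:
    """AUC as the Mann-Whitney concordance probability, with a DeLong 95% CI.

    AUC = (concordant pairs + 0.5 * tied pairs) / (n_pos * n_neg), computed
    via midranks; the CI is the normal interval with the DeLong variance,
    clipped to [0, 1].
    """
    cohort.require_both_classes()
    aucs, cov = _delong_components(cohort.label, cohort.score[None, :])
    auc = float(aucs[0])
    se = math.sqrt(max(cov[0, 0], 0.0))
    return ValueCI(auc, max(auc - _Z975 * se, 0.0), min(auc + _Z975 * se, 1.0))


def youden_cutoff(cohort: ScoredCohort) -> tuple[float, float]:
    """Threshold maximising J = sensitivity + specificity - 1.

    The scan is over all distinct observed scores (positivity at
    score >= threshold); ties in J are broken toward the lower threshold,
    the higher-sensitivity screening choice.
    """
    cohort.require_both_classes()
    pos = np.sort(cohort.score[cohort.label])
    neg = np.sort(cohort.score[~cohort.label])
    thresholds = np.unique(cohort.score)  # ascending
    sens = 1.0 - np.searchsorted(pos, thresholds, side="left") / pos.size
    spec = np.searchsorted(neg, thresholds, side="left") / neg.size
    j = sens + spec - 1.0
    # ties (incl. float noise) break toward the lower threshold
    best = int(np.flatnonzero(j >= j.max() - 1e-12)[0])
    return float(thresholds[best]), float(j[best])


def wald_ci(p: float, n: int) -> tuple[float, float]:
    """Normal-approximation 95% CI for a proportion, clipped to [0, 1]."""
    if n <= 0:
        raise DegenerateInputError("Wald interval undefined for n = 0")
    if not (0.0 <= p <= 1.0):
        raise DomainError("p", f"proportion must lie in [0, 1], got {p!r}")
    half = _Z975 * math.sqrt(p * (1.0 - p) / n)
    return (max(p - half, 0.0), min(p + half, 1.0))


def clopper_pearson_ci(k: int, n: int) -> tuple[float, float]:
    """Exact (Clopper-Pearson) 95% CI for k successes in n trials."""
    if n <= 0:
        raise DegenerateInputError("interval undefined for n = 0")
    lo = 0.0 if k == 0 else float(stats.beta.ppf(0.025, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(0.975, k + 1, n - k))
    return (lo, hi)


def _proportion_ci(k: int, n: int, method: str) -> ValueCI:
    p = k / n
    if method == "wald":
        lo, hi = wald_ci(p, n)
    elif method == "cp":
        lo, hi = clopper_pearson_ci(k, n)
    else:
        raise DomainError("ci", f"unknown CI method {method!r} (use 'wald' or 'cp')")
    return ValueCI(p, lo, hi)


def _ratio_log_ci(value: float, terms: Sequence[float]) -> ValueCI:
    """95% CI for a likelihood ratio via the log method; ``terms`` are the
    1/count contributions to the log-variance."""
    if value == 0.0 or not math.isfinite(value):
        return ValueCI(value, value, value)
    se = math.sqrt(sum(terms))
    return ValueCI(value, value * math.exp(-_Z975 * se), value * math.exp(_Z975 * se))


def confusion_metrics(tp: int, fn: int, fp: int, tn: int,
                      *, ci: str = "wald") -> dict[str, Optional[ValueCI]]:
    """Sensitivity, specificity, PPV, NPV, PLR, NLR with 95% CIs.

    Metrics whose defining margin is zero come back as ``None`` (explicitly
    undefined) rather than NaN.  ``ci`` selects Wald (default) or exact
    Clopper-Pearson ('cp') intervals for the four proportions; likelihood
    ratios always use the log method.
    """
    for name, v in (("tp", tp), ("fn", fn), ("fp", fp), ("tn", tn)):
        if v < 0 or v != int(v):
            raise DomainError(name, f"counts must be nonnegative integers, got {v!r}")
    out: dict[str, Optional[ValueCI]] = {}
    n_pos, n_neg = tp + fn, tn + fp
    out["sens"] = _proportion_ci(tp, n_pos, ci) if n_pos else None
    out["spec"] = _proportion_ci(tn, n_neg, ci) if n_neg else None
    out["ppv"] = _proportion_ci(tp, tp + fp, ci) if tp + fp else None
    out["npv"] = _proportion_ci(tn, tn + fn, ci) if tn + fn else None
    sens = out["sens"].value if out["sens"] else None
    spec = out["spec"].value if out["spec"] else None
    if sens is not None and spec is not None and spec < 1.0:
        plr = sens / (1.0 - spec)
        terms = [1.0 / tp - 1.0 / n_pos if tp else math.inf, 1.0 / fp - 1.0 / n_neg]
        out["plr"] = _ratio_log_ci(plr, terms) if tp and fp else ValueCI(plr, plr, plr)
    else:
        out["plr"] = None
    if sens is not None and spec is not None and spec > 0.0:
        nlr = (1.0 - sens) / spec
        out["nlr"] = (_ratio_log_ci(nlr, [1.0 / fn - 1.0 / n_pos, 1.0 / tn - 1.0 / n_neg])
                      if fn and tn else ValueCI(nlr, nlr, nlr))
    else:
        out["nlr"] = None
    return out


def prevalence_percent(positives: int, total: int) -> float:
    """Group prevalence as a percentage (e.g. 24/124 -> 19.35...)."""
    if total <= 0:
        raise DegenerateInputError("prevalence undefined for an empty group")
    if positives < 0 or positives > total:
        raise DomainError("positives", "must satisfy 0 <= positives <= total")
    return 100.0 * positives / total


def delong_compare(cohort: ScoredCohort, score_a: np.ndarray,
                   score_b: np.ndarray) -> tuple[float, float, float]:
    """DeLong paired test for the difference of two correlated AUCs.

    Both scores must be measured on the same subjects (``cohort.label``).
    Returns (auc_a, auc_b, two-sided p).
    """
    score_a = np.asarray(score_a, dtype=float)
    score_b = np.asarray(score_b, dtype=float)
    if score_a.shape != cohort.label.shape or score_b.shape != cohort.label.shape:
        raise DegenerateInputError("paired scores must match the cohort length")
    cohort.require_both_classes()
    aucs, cov = _delong_components(cohort.label, np.vstack([score_a, score_b]))
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    diff = aucs[0] - aucs[1]
    if var_diff <= 0:
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / math.sqrt(var_diff)
        p = 2.0 * float(stats.norm.sf(abs(z)))
    return float(aucs[0]), float(aucs[1]), p


@dataclass
class DiagnosticReport:
    """Full evaluation of one index against the MetS label."""

    index: str
    n: int
    n_pos: int
    auc: ValueCI
    cutoff: float
    youden: float
    metrics: dict[str, Optional[ValueCI]]
    counts: dict[str, int]
    roc: list[tuple[float, float, float]] = field(repr=False)


def evaluate_index(cohort: ScoredCohort, *, index: str = "score",
                   ci: str = "wald") -> DiagnosticReport:
    """ROC, AUC, Youden-optimal cutoff and confusion metrics at that cutoff."""
    cohort.require_both_classes()
    cutoff, j = youden_cutoff(cohort)
    pred = cohort.score >= cutoff
    tp = int(np.sum(pred & cohort.label))
    fn = int(np.sum(~pred & cohort.label))
    fp = int(np.sum(pred & ~cohort.label))
    tn = int(np.sum(~pred & ~cohort.label))
    return DiagnosticReport(
        index=index,
        n=cohort.n,
        n_pos=cohort.n_pos,
        auc=auc_rank(cohort),
        cutoff=cutoff,
        youden=j,
        metrics=confusion_metrics(tp, fn, fp, tn, ci=ci),
        counts={"tp": tp, "fn": fn, "fp": fp, "tn": tn},
        roc=roc_points(cohort),
    )


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p (t approximation)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DegenerateInputError("spearman needs paired vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateInputError("spearman undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def rank_sum_test(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses exact enumeration for combined samples of at most 12 without ties,
    otherwise the tie-corrected normal approximation.  Returns (U of the
    first group, p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DegenerateInputError("rank-sum test needs two nonempty groups")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(a.size * b.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size + b.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=(method == "asymptotic"))
    return float(res.statistic), float(res.pvalue)


def chi2_2x2(a: int, b: int, c: int, d: int, correction: str) -> tuple[float, float]:
    """Chi-square test on the 2x2 table [[a, b], [c, d]], df = 1.

    ``correction`` must be given explicitly: 'none' for the plain Pearson
    statistic or 'yates' for the continuity-corrected one — published 2x2
    p-values are reproducible only when the convention is known, so there is
    no silent default.
    """
    if correction not in ("none", "yates"):
        raise DomainError("correction", f"must be 'none' or 'yates', got {correction!r}")
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if v < 0:
            raise DomainError(name, "counts must be nonnegative")
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise DegenerateInputError("chi-square undefined with a zero margin")
    delta = abs(a * d - b * c)
    if correction == "yates":
        delta = max(delta - n / 2.0, 0.0)
    chi2 = n * delta * delta / (r1 * r2 * c1 * c2)
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def ks_normality(x: Sequence[float], *, lilliefors: bool = True) -> tuple[float, float]:
    """Kolmogorov-Smirnov normality test with moment-estimated parameters.

    With ``lilliefors=True`` (default) the p-value accounts for the
    estimated mean/SD (Lilliefors correction, via statsmodels' simulated
    tables); with ``False`` the naive KS p against the fitted normal is
    returned (anti-conservative, for comparison only).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 5:
        raise DegenerateInputError("normality test needs n >= 5")
    if np.all(x == x[0]):
        raise DegenerateInputError("normality test undefined for a constant vector")
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as sm_lilliefors
        d, p = sm_lilliefors(x, dist="norm", pvalmethod="table")
        return float(d), float(p)
    d, p = stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    return float(d), float(p)


def tukey_outliers(x: Sequence[float]) -> np.ndarray:
    """Box-plot outlier flags: outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR]."""
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise DegenerateInputError("box-plot screen needs n >= 4")
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    return (x < q1 - 1.5 * iqr) | (x > q3 + 1.5 * iqr)


def cutoff_trend(cohort: ScoredCohort, sex: Optional[str] = None, *,
                 window: float = 4.0, min_n: int = 10,
                 grid: Optional[Sequence[float]] = None
                 ) -> list[tuple[float, Optional[float]]]:
    """Age-resolved Youden cutoffs from a sliding window.

    For each grid age, the Youden-optimal threshold is recomputed among
    subjects of the given sex whose age lies within +/- window/2 of the grid
    point.  Windows with fewer than ``min_n`` subjects or a single outcome
    class yield ``None``.  The default grid is whole years spanning the
    (sex-restricted) cohort.
    """
    if cohort.age is None:
        raise DegenerateInputError("cutoff_trend needs per-subject ages")
    mask = np.ones(cohort.n, dtype=bool)
    if sex is not None:
        if cohort.sex is None:
            raise DegenerateInputError("cutoff_trend by sex needs per-subject sex")
        mask &= np.asarray(cohort.sex) == sex
    if not mask.any():
        raise DegenerateInputError("no subjects match the requested stratum")
    ages = np.asarray(cohort.age, dtype=float)
    if grid is None:
        lo, hi = ages[mask].min(), ages[mask].max()
        grid = np.arange(math.ceil(lo), math.floor(hi) + 1)
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise DegenerateInputError("empty age grid")
    half = window / 2.0
    out: list[tuple[float, Optional[float]]] = []
    for g in grid:
        sel = mask & (np.abs(ages - g) <= half)
        sub_label = cohort.label[sel]
        if sel.sum() < min_n or sub_label.all() or not sub_label.any():
            out.append((float(g), None))
            continue
        t, _ = youden_cutoff(ScoredCohort(cohort.score[sel], sub_label))
        out.append((float(g), t))
    return out
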