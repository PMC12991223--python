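"""Visual grading characteristics: curves, AUC, binormal fit, effect size.

VGC analysis compares the ordinal image-quality rating distributions of a
*test* protocol against a *reference* protocol, exactly as ROC analysis
compares rating distributions of abnormal against normal cases.  The VGC
curve plots, for each rating threshold, the proportion of test-protocol
ratings at or above the threshold (y) against the same proportion for the
reference protocol (x).  The area under the curve, AUC_VGC, is the
figure of merit: 0.5 means equal rated quality, above 0.5 means the test
protocol was rated better.

The empirical AUC is the tie-corrected two-sample U-statistic

    AUC = [ #{t > r} + 0.5 * #{t = r} ] / (n_t * n_r)

which coincides exactly with the trapezoidal area under the empirical VGC
curve.  A smooth alternative is the binormal model, in which the two
protocols' latent qualities are normal with possibly different means and
variances; on probit-transformed VGC axes the curve is the straight line
y = Phi(a + b * Phi^-1(x)) and AUC = Phi(a / sqrt(1 + b^2)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .ratings import RatingPanel

__all__ = [
    "VGCCurve",
    "VGCResult",
    "BinormalFit",
    "BinormalFitError",
    "empirical_auc",
    "vgc_curve",
    "per_observer_auc",
    "average_auc",
    "effect_size",
    "fit_binormal",
]


# ---------------------------------------------------------------------------
# category-count helpers
# ---------------------------------------------------------------------------

def _as_counts(ratings, n_categories: int) -> np.ndarray:
    """Category counts (length K) of an ordinal rating multiset."""
    r = np.asarray(ratings)
    if r.size == 0:
        raise ValueError("rating multiset must be non-empty")
    if not np.issubdtype(r.dtype, np.integer):
        ri = r.astype(int)
        if not np.array_equal(ri, r):
            raise ValueError("ratings must be integers")
        r = ri
    if r.min() < 1 or r.max() > n_categories:
        raise ValueError(
            f"rating outside [1, {n_categories}]: {int(r.min() if r.min() < 1 else r.max())}"
        )
    return np.bincount(r, minlength=n_categories + 1)[1:]


def auc_from_counts(test_counts: np.ndarray, ref_counts: np.ndarray) -> float:
    """Tie-corrected U-statistic AUC from per-category counts.

    O(K): for each category the number of reference ratings strictly below
    gets full weight, ties get half weight.
    """
    t = np.asarray(test_counts, dtype=float)
    r = np.asarray(ref_counts, dtype=float)
    n_t, n_r = t.sum(), r.sum()
    below = np.concatenate(([0.0], np.cumsum(r)[:-1]))
    return float((t * (below + 0.5 * r)).sum() / (n_t * n_r))


# ---------------------------------------------------------------------------
# empirical AUC and the VGC curve
# ---------------------------------------------------------------------------

def empirical_auc(test_ratings, ref_ratings, n_categories: int | None = None) -> float:
    """Tie-corrected nonparametric AUC_VGC of test vs reference ratings.

    Values above 0.5 mean the test protocol was rated higher.  Equal to the
    trapezoidal area under :func:`vgc_curve` built from the same data.
    """
    t = np.asarray(test_ratings)
    r = np.asarray(ref_ratings)
    if t.size == 0 or r.size == 0:
        raise ValueError("rating multisets must be non-empty")
    k = n_categories or int(max(t.max(), r.max()))
    return auc_from_counts(_as_counts(t, k), _as_counts(r, k))


@dataclass(frozen=True)
class VGCCurve:
    """Operating points of a VGC curve, from (0, 0) to (1, 1).

    ``x`` holds cumulative proportions of reference-protocol ratings at or
    above each threshold, ``y`` the same for the test protocol; the
    threshold sweeps from above the top category down to 1, giving K + 1
    points on a K-category scale.
    """

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        x, y = np.asarray(self.x, float), np.asarray(self.y, float)
        if x.shape != y.shape or x.ndim != 1 or x.size < 2:
            raise ValueError("curve needs matching 1-d x and y with >= 2 points")
        if not (x[0] == 0 and y[0] == 0 and x[-1] == 1 and y[-1] == 1):
            raise ValueError("curve must run from (0,0) to (1,1)")
        if (np.diff(x) < 0).any() or (np.diff(y) < 0).any():
            raise ValueError("operating points must be non-decreasing")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.x.tolist(), self.y.tolist()))

    def area(self) -> float:
        """Trapezoidal area under the curve."""
        return float(np.trapezoid(self.y, self.x))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"x": self.x, "y": self.y})


def vgc_curve(test_ratings, ref_ratings, n_categories: int) -> VGCCurve:
    """Empirical VGC curve from two rating multisets on a K-category scale."""
    tc = _as_counts(test_ratings, n_categories)
    rc = _as_counts(ref_ratings, n_categories)
    # P(rating >= k) for k = K, K-1, ..., 1, prefixed by the empty threshold
    x = np.concatenate(([0.0], np.cumsum(rc[::-1]) / rc.sum()))
    y = np.concatenate(([0.0], np.cumsum(tc[::-1]) / tc.sum()))
    x[-1] = 1.0
    y[-1] = 1.0
    return VGCCurve(x, y)


# ---------------------------------------------------------------------------
# observer-level analysis
# ---------------------------------------------------------------------------

def per_observer_auc(
    panel: RatingPanel,
    test: str,
    ref: str,
    criteria=None,
) -> dict[str, float]:
    """One AUC_VGC per observer for a test-vs-reference protocol comparison.

    Ratings are never compared across observers: each observer's ratings for
    all (case, criterion) cells within ``criteria`` are pooled into that
    observer's test and reference multisets, and the tie-corrected AUC is
    computed per observer.  Pooling keeps each ordinal rating as one
    observation; criteria are not averaged within a case first.
    """
    if test not in panel.protocols:
        raise KeyError(f"unknown protocol {test!r}")
    if ref not in panel.protocols:
        raise KeyError(f"unknown protocol {ref!r}")
    if criteria is None:
        criteria = panel.criteria
    criteria = list(criteria)
    if not criteria:
        raise ValueError("criteria must be non-empty")
    unknown = set(criteria) - set(panel.criteria)
    if unknown:
        raise KeyError(f"unknown criteria: {sorted(unknown)}")

    out: dict[str, float] = {}
    for obs in panel.observers:
        t = panel.ratings(observer=obs, protocol=test, criteria=criteria)
        r = panel.ratings(observer=obs, protocol=ref, criteria=criteria)
        out[obs] = empirical_auc(t, r, panel.n_categories)
    return out


def average_auc(per_observer: dict[str, float]) -> float:
    """Final AUC_VGC: the arithmetic mean of the per-observer AUCs."""
    if not per_observer:
        raise ValueError("per-observer AUC map must be non-empty")
    return float(np.mean(list(per_observer.values())))


def effect_size(auc: float) -> float:
    """Absolute difference between an AUC_VGC and the null value 0.5."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError(f"AUC must lie in [0, 1], got {auc}")
    return abs(auc - 0.5)


# ---------------------------------------------------------------------------
# result container (filled by the resampling module)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VGCResult:
    """One protocol comparison for one criterion class."""

    reference_protocol: str
    test_protocol: str
    criterion_class: str
    auc: float
    ci_low: float
    ci_high: float
    p_value: float
    effect_size: float
    per_observer_auc: dict[str, float]
    n_boot: int

    def __post_init__(self):
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low must not exceed ci_high")
        if abs(self.effect_size - abs(self.auc - 0.5)) > 1e-12:
            raise ValueError("effect_size must equal |auc - 0.5|")

    def to_dict(self) -> dict:
        return {
            "reference_protocol": self.reference_protocol,
            "test_protocol": self.test_protocol,
            "criterion_class": self.criterion_class,
            "auc": self.auc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "effect_size": self.effect_size,
            "per_observer_auc": dict(sorted(self.per_observer_auc.items())),
            "n_boot": self.n_boot,
        }


# ---------------------------------------------------------------------------
# binormal model
# ---------------------------------------------------------------------------

class BinormalFitError(RuntimeError):
    """Binormal fit failed (degenerate data or non-convergence)."""


@dataclass(frozen=True)
class BinormalFit:
    """Maximum-likelihood binormal fit to two ordinal rating samples.

    ``a`` is the latent mean separation and ``b`` the latent SD ratio on the
    probit-curve parameterisation y = Phi(a + b * Phi^-1(x)); thresholds are
    shared between the two arms and strictly increasing.
    """

    a: float
    b: float
    thresholds: np.ndarray
    auc_binormal: float
    log_likelihood: float

    def __post_init__(self):
        thr = np.asarray(self.thresholds, float)
        if (np.diff(thr) <= 0).any():
            raise ValueError("thresholds must be strictly increasing")
        if self.b <= 0:
            raise ValueError("b must be positive")
        object.__setattr__(self, "thresholds", thr)

    def curve(self, n_points: int = 101) -> VGCCurve:
        """The smooth binormal VGC curve evaluated on a probit grid."""
        z = np.linspace(-6, 6, n_points - 2)
        x = np.concatenate(([0.0], stats.norm.cdf(z), [1.0]))
        y = np.concatenate(([0.0], stats.norm.cdf(self.a + self.b * z), [1.0]))
        return VGCCurve(x, y)


def _binormal_negll(params, t_counts, r_counts, k):
    a, log_b = params[0], params[1]
    t1, log_d = params[2], params[3:]
    b = np.exp(log_b)
    thr = np.concatenate(([t1], t1 + np.cumsum(np.exp(log_d))))
    mu, sigma = a / b, 1.0 / b
    edges = np.concatenate(([-np.inf], thr, [np.inf]))
    p_ref = np.diff(stats.norm.cdf(edges))
    p_test = np.diff(stats.norm.cdf((edges - mu) / sigma))
    p_ref = np.clip(p_ref, 1e-300, None)
    p_test = np.clip(p_test, 1e-300, None)
    return -(r_counts @ np.log(p_ref) + t_counts @ np.log(p_test))


def fit_binormal(test_ratings, ref_ratings, n_categories: int) -> BinormalFit:
    """Fit the binormal latent model to two ordinal rating multisets.

    The reference latent quality is standard normal, the test latent is
    normal with mean a/b and SD 1/b, and both arms are discretised through
    the same K-1 strictly increasing thresholds.  The multinomial likelihood
    is maximised jointly over (a, b, thresholds), initialised from the
    empirical cumulative proportions via the probit transform.

    Raises
    ------
    BinormalFitError
        If either arm puts all its mass in one category (the model is not
        identifiable) or the optimiser fails to converge.
    """
    k = n_categories
    t_counts = _as_counts(np.asarray(test_ratings), k).astype(float)
    r_counts = _as_counts(np.asarray(ref_ratings), k).astype(float)
    if (t_counts > 0).sum() < 2 or (r_counts > 0).sum() < 2:
        raise BinormalFitError(
            "each arm must span at least two categories for the binormal model"
        )

    # initialisation: thresholds from the pooled empirical CDF, (a, b) from a
    # least-squares line through the probit-transformed operating points
    pooled = t_counts + r_counts
    cum = np.cumsum(pooled)[:-1] / pooled.sum()
    thr0 = stats.norm.ppf(np.clip(cum, 1e-4, 1 - 1e-4))
    thr0 = np.maximum.accumulate(thr0 + 1e-6 * np.arange(k - 1))
    eps = 0.5 / max(t_counts.sum(), r_counts.sum())
    x = np.clip(1 - np.cumsum(r_counts)[:-1] / r_counts.sum(), eps, 1 - eps)
    y = np.clip(1 - np.cumsum(t_counts)[:-1] / t_counts.sum(), eps, 1 - eps)
    zx, zy = stats.norm.ppf(x), stats.norm.ppf(y)
    if zx.size >= 2 and np.ptp(zx) > 0:
        b0 = float(np.polyfit(zx, zy, 1)[0])
        b0 = min(max(b0, 0.2), 5.0)
    else:
        b0 = 1.0
    a0 = float(np.mean(zy - b0 * zx))

    d0 = np.diff(thr0)
    x0 = np.concatenate(([a0, np.log(b0), thr0[0]], np.log(np.maximum(d0, 1e-3))))
    res = optimize.minimize(
        _binormal_negll,
        x0,
        args=(t_counts, r_counts, k),
        method="Nelder-Mead",
        options={"maxiter": 20000, "fatol": 1e-8, "xatol": 1e-8},
    )
    if not res.success:
        raise BinormalFitError(f"binormal fit did not converge: {res.message}")
    a, b = float(res.x[0]), float(np.exp(res.x[1]))
    thr = np.concatenate(([res.x[2]], res.x[2] + np.cumsum(np.exp(res.x[3:]))))
    auc = float(stats.norm.cdf(a / np.sqrt(1.0 + b * b)))
    return BinormalFit(
        a=a,
        b=b,
        thresholds=thr,
        auc_binormal=auc,
        log_likelihood=float(-res.fun),
    )
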