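"""Contrast tests for independent samples (between-subjects designs).

The contrast estimate is ``L = sum_i lambda_i * xbar_i``.  Its standard error
uses the pooled within-group variance (the ANOVA mean squared error), and
``t = L / se`` is referred to a central t distribution with ``N - K`` degrees
of freedom.  The companion F table carries ``SS_contrast = L^2 / sum(lam^2/n)``
on one degree of freedom, so ``F = t^2`` identically.

Three correlation-style effect sizes accompany the test:

``r_alerting``
    Pearson correlation between the K contrast weights and the K observed
    group means — the group-level fit of the predicted pattern.
``r_effectsize``
    ``sign(L) * sqrt(SS_contrast / SS_total)``: the correlation between
    individual observations and the contrast weights; its square is the share
    of *total* variance the contrast explains.  Requires individual-level
    data (for ``SS_total``) and is therefore ``None`` when the test is run
    from group summaries alone.
``r_contrast``
    ``sign(t) * sqrt(t^2 / (t^2 + df))``: the partial correlation tied to the
    t statistic, the quantity fed to correlation-based power analysis.

``|r_effectsize| <= |r_alerting|`` always: the group-level correlation is an
upper bound for the individual-level one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    AlignmentError,
    InsufficientDataError,
    ZeroVarianceError,
)
from .weights import ContrastWeights, lambda_diff

__all__ = [
    "GroupSummaries",
    "BetweenResult",
    "contrast_estimate",
    "pooled_within_variance",
    "between_contrast_test",
    "between_effect_sizes",
    "compare_hypotheses_between",
    "critical_t",
]

MseMethod = Literal["df_weighted", "unweighted"]


@dataclass(frozen=True)
class GroupSummaries:
    """Sufficient statistics per condition: mean, variance (ddof=1), size."""

    labels: tuple[str, ...]
    means: tuple[float, ...]
    variances: tuple[float, ...]
    ns: tuple[int, ...]
    k: int = field(init=False)
    n_total: int = field(init=False)

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels)
        means = np.asarray(self.means, dtype=float)
        variances = np.asarray(self.variances, dtype=float)
        ns = np.asarray(self.ns, dtype=int)
        if not (len(labels) == means.size == variances.size == ns.size):
            raise ValueError("labels, means, variances, ns differ in length")
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate condition labels: {labels}")
        if len(labels) < 2:
            raise ValueError("need at least two conditions")
        if np.any(ns < 2):
            raise InsufficientDataError(
                "every group needs n >= 2 to estimate its variance"
            )
        if not np.all(np.isfinite(means)) or not np.all(np.isfinite(variances)):
            raise ValueError("means and variances must be finite")
        if np.any(variances < 0):
            raise ValueError("variances must be non-negative")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "means", tuple(float(v) for v in means))
        object.__setattr__(self, "variances", tuple(float(v) for v in variances))
        object.__setattr__(self, "ns", tuple(int(v) for v in ns))
        object.__setattr__(self, "k", len(labels))
        object.__setattr__(self, "n_total", int(ns.sum()))

    @classmethod
    def from_long(
        cls,
        data: pd.DataFrame,
        condition: str = "condition",
        dv: str = "dv",
    ) -> "GroupSummaries":
        """Summarize a long-format table (one row per observation).

        Condition order follows first appearance in the data, not sort order.
        """
        if condition not in data.columns or dv not in data.columns:
            raise AlignmentError(
                f"columns {condition!r} and {dv!r} must exist; "
                f"found {list(data.columns)}"
            )
        labels = tuple(pd.unique(data[condition]).astype(str))
        g = data.groupby(condition, sort=False)[dv]
        means = g.mean()
        variances = g.var(ddof=1)
        ns = g.size()
        return cls(
            labels,
            tuple(float(means[l]) for l in labels),
            tuple(float(variances[l]) for l in labels),
            tuple(int(ns[l]) for l in labels),
        )


@dataclass(frozen=True)
class BetweenResult:
    """Full output of a between-subjects contrast test.

    ``ss_contrast`` sits on one degree of freedom, so ``ms_contrast`` equals
    it and ``f == t**2``.  ``p_one_tailed`` is the upper-tail probability at
    the observed t (directional test: positive t supports the stated
    pattern); ``p_f`` is the non-directional F-table p value.
    """

    weights: ContrastWeights
    l_estimate: float
    sigma2_within: float
    se: float
    df: int
    t: float
    p_one_tailed: float
    p_two_tailed: float
    ss_contrast: float
    ms_contrast: float
    f: float
    p_f: float
    r_alerting: float
    r_contrast: float
    r_effectsize: Optional[float]
    mse_method: MseMethod
    favored: Optional[ContrastWeights] = None
    rival: Optional[ContrastWeights] = None

    def to_dict(self) -> dict:
        d = {
            "design": "between",
            "weights": self.weights.as_mapping(),
            "L": self.l_estimate,
            "sigma2_within": self.sigma2_within,
            "se": self.se,
            "df": self.df,
            "t": self.t,
            "p_one_tailed": self.p_one_tailed,
            "p_two_tailed": self.p_two_tailed,
            "SS_contrast": self.ss_contrast,
            "MS_contrast": self.ms_contrast,
            "F": self.f,
            "p_F": self.p_f,
            "r_alerting": self.r_alerting,
            "r_contrast": self.r_contrast,
            "r_effectsize": self.r_effectsize,
            "mse_method": self.mse_method,
        }
        if self.favored is not None:
            d["favored"] = self.favored.as_mapping()
        if self.rival is not None:
            d["rival"] = self.rival.as_mapping()
        return d


def contrast_estimate(
    means: Sequence[float], w: ContrastWeights
) -> float:
    """Weighted sum of condition means, ``L = sum(lambda_i * mean_i)``.

    ``means`` must already be aligned to ``w.labels`` (use
    :meth:`ContrastWeights.aligned_to` when starting from labelled data).
    """
    means = np.asarray(means, dtype=float)
    if means.size != w.k:
        raise AlignmentError(
            f"{means.size} means supplied for {w.k} weights"
        )
    return float(w.values @ means)


def pooled_within_variance(
    summaries: GroupSummaries, method: MseMethod = "df_weighted"
) -> float:
    """Pooled within-group variance (the contrast test's error term).

    ``df_weighted`` is the classical ANOVA mean squared error,
    ``sum((n_i - 1) s_i^2) / (N - K)``; ``unweighted`` is the plain mean of
    the group variances.  The two coincide for balanced designs.
    """
    v = np.asarray(summaries.variances)
    n = np.asarray(summaries.ns)
    if method == "unweighted":
        return float(v.mean())
    if method == "df_weighted":
        return float(((n - 1) * v).sum() / (summaries.n_total - summaries.k))
    raise ValueError(f"unknown MSE method {method!r}")


def _r_alerting(lam: np.ndarray, means: np.ndarray) -> float:
    mc = means - means.mean()
    denom = np.sqrt((lam @ lam) * (mc @ mc))
    if denom == 0:
        return 0.0
    return float((lam @ mc) / denom)


def between_contrast_test(
    data: Union[pd.DataFrame, GroupSummaries],
    w: ContrastWeights,
    mse_method: MseMethod = "df_weighted",
    condition: str = "condition",
    dv: str = "dv",
) -> BetweenResult:
    """Run the contrast t test (and F table) for independent samples.

    Accepts either a long-format table (one row per observation) or
    :class:`GroupSummaries`.  Weights are re-aligned to the data's condition
    labels; a mismatch raises :class:`~contrastkit.errors.AlignmentError`.
    ``r_effectsize`` needs the total sum of squares and is only filled in
    when individual-level data are supplied.

    Raises
    ------
    ZeroVarianceError
        If the pooled within-group variance is zero.
    """
    ss_total: Optional[float] = None
    if isinstance(data, pd.DataFrame):
        ss_total = float(
            ((data[dv] - data[dv].mean()) ** 2).sum()
        ) if dv in data.columns else None
        summaries = GroupSummaries.from_long(data, condition=condition, dv=dv)
    else:
        summaries = data

    w = w.aligned_to(summaries.labels)
    lam = w.values
    means = np.asarray(summaries.means)
    ns = np.asarray(summaries.ns)

    l_est = contrast_estimate(means, w)
    mse = pooled_within_variance(summaries, mse_method)
    if mse == 0:
        raise ZeroVarianceError("pooled within-group variance is zero")
    lam2_over_n = float((lam**2 / ns).sum())
    se = float(np.sqrt(mse * lam2_over_n))
    df = summaries.n_total - summaries.k
    t = l_est / se
    p_one = float(stats.t.sf(t, df))
    p_two = float(2 * stats.t.sf(abs(t), df))

    ss_contrast = l_est**2 / lam2_over_n
    f = ss_contrast / mse
    p_f = float(stats.f.sf(f, 1, df))

    r_alert = _r_alerting(lam, means)
    r_con = float(np.sign(t) * np.sqrt(t**2 / (t**2 + df)))
    r_eff: Optional[float] = None
    if ss_total is not None:
        if ss_total == 0:
            raise ZeroVarianceError("dependent variable is constant")
        r_eff = float(np.sign(l_est) * np.sqrt(ss_contrast / ss_total))

    return BetweenResult(
        weights=w,
        l_estimate=l_est,
        sigma2_within=mse,
        se=se,
        df=df,
        t=float(t),
        p_one_tailed=p_one,
        p_two_tailed=p_two,
        ss_contrast=float(ss_contrast),
        ms_contrast=float(ss_contrast),
        f=float(f),
        p_f=p_f,
        r_alerting=r_alert,
        r_contrast=r_con,
        r_effectsize=r_eff,
        mse_method=mse_method,
    )


def between_effect_sizes(
    data: Union[pd.DataFrame, GroupSummaries],
    w: ContrastWeights,
    mse_method: MseMethod = "df_weighted",
    condition: str = "condition",
    dv: str = "dv",
) -> tuple[Optional[float], float, float]:
    """Return ``(r_effectsize, r_alerting, r_contrast)`` for a contrast.

    ``r_effectsize`` is ``None`` when only group summaries are available.
    """
    res = between_contrast_test(
        data, w, mse_method=mse_method, condition=condition, dv=dv
    )
    return res.r_effectsize, res.r_alerting, res.r_contrast


def compare_hypotheses_between(
    data: Union[pd.DataFrame, GroupSummaries],
    favored: ContrastWeights,
    rival: ContrastWeights,
    mse_method: MseMethod = "df_weighted",
    condition: str = "condition",
    dv: str = "dv",
) -> BetweenResult:
    """Competing-contrast test: does the favored pattern fit better?

    Tests the difference of the two standardized weight vectors.  A
    significantly positive t means the favored predicted mean pattern
    covaries more strongly with the observed means than the rival does;
    swapping the two hypotheses negates L and t exactly.
    """
    diff = lambda_diff(favored, rival)
    res = between_contrast_test(
        data, diff, mse_method=mse_method, condition=condition, dv=dv
    )
    return BetweenResult(
        **{**res.__dict__, "favored": favored, "rival": rival}
    )


def critical_t(df: int, alpha: float = 0.05, tails: str = "one") -> float:
    """Critical value of the central t distribution.

    One-tailed: the ``1 - alpha`` quantile; two-tailed: ``1 - alpha/2``.
    """
    if tails == "one":
        return float(stats.t.ppf(1 - alpha, df))
    if tails == "two":
        return float(stats.t.ppf(1 - alpha / 2, df))
    raise ValueError(f"tails must be 'one' or 'two', got {tails!r}")
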