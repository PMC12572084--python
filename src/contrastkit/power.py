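"""Power and sample-size solvers for contrast analysis.

Two recipes, matching how the two designs are planned in practice:

* **Between-subjects** — the contrast's partial correlation ``r_contrast``
  is treated as the effect size of a test of zero correlation.  Power uses
  the Fisher-z approximation with a small-sample bias correction: with
  ``z_r = atanh(r) + r/(2(n-1))`` and a critical correlation ``r_c`` derived
  from the central-t quantile at ``df = n - 2``, the one-tailed power is
  ``Phi((z_r - atanh(r_c)) * sqrt(n - 3))``.  The solved n is then rounded
  up to a multiple of K so conditions stay balanced.

* **Within-subjects** — ``g_contrast`` is a Cohen's-d estimate for the mean
  per-subject contrast score, so power is that of a one-sample (paired) t
  test: ``P(T' > t_crit)`` with T' noncentral t, ``df = n - 1``,
  noncentrality ``d * sqrt(n)``.

If only ``r_effectsize`` is known, use it in place of ``r_contrast``: it is a
lower bound (equality when ``r_alerting = 1``), so the resulting plan is
conservative.

Sample-size searches are integer-only: bracket doubling followed by
bisection, relying on power being strictly increasing in n.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy import stats

from .errors import DomainError, SolverError

__all__ = [
    "PowerSpec",
    "PowerResult",
    "power_correlation",
    "power_paired_t",
    "required_n_between",
    "required_n_within",
]

Tails = Literal["one", "two"]

_N_CAP = 10_000_000


@dataclass(frozen=True)
class PowerSpec:
    """Inputs to a sample-size solve.

    ``effect`` is r_contrast in (0, 1) for a between design, Cohen's d > 0
    for a within design.  ``k`` (between only) balances the solved total
    across conditions.
    """

    effect: float
    design: Literal["between", "within"]
    alpha: float = 0.05
    target_power: float = 0.80
    tails: Tails = "one"
    k: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise DomainError("alpha must be in (0, 1)")
        if not 0 < self.target_power < 1:
            raise DomainError("target power must be in (0, 1)")
        if self.tails not in ("one", "two"):
            raise DomainError("tails must be 'one' or 'two'")
        if self.design == "between":
            if not 0 < self.effect < 1:
                raise DomainError("r must be in (0, 1) for a between design")
            if self.k is not None and self.k < 2:
                raise DomainError("k must be at least 2")
        elif self.design == "within":
            if self.effect <= 0:
                raise DomainError("d must be positive for a within design")
        else:
            raise DomainError("design must be 'between' or 'within'")


@dataclass(frozen=True)
class PowerResult:
    """A solved sample size together with the power it achieves."""

    spec: PowerSpec
    n_total: int
    achieved_power: float
    n_per_condition: Optional[int] = None
    n_raw: Optional[int] = None  # before the per-condition ceiling

    def to_dict(self) -> dict:
        return {
            "design": self.spec.design,
            "effect": self.spec.effect,
            "alpha": self.spec.alpha,
            "tails": self.spec.tails,
            "target_power": self.spec.target_power,
            "n_total": self.n_total,
            "n_per_condition": self.n_per_condition,
            "n_raw": self.n_raw,
            "achieved_power": self.achieved_power,
        }


def power_correlation(
    n: int, r: float, alpha: float = 0.05, tails: Tails = "one"
) -> float:
    """Power of the test of zero correlation at sample size ``n``.

    Bias-corrected Fisher-z approximation; the critical correlation comes
    from the central-t quantile at ``df = n - 2``.  Two-tailed power sums
    both rejection regions at level ``alpha/2``.
    """
    if n < 4:
        raise DomainError("correlation power needs n >= 4")
    if not 0 <= r < 1:
        raise DomainError("r must be in [0, 1)")
    df = n - 2
    a = alpha if tails == "one" else alpha / 2
    tc = stats.t.ppf(1 - a, df)
    rc = tc / np.sqrt(tc**2 + df)
    zc = np.arctanh(rc)
    zr = np.arctanh(r) + r / (2 * (n - 1))
    s = np.sqrt(n - 3)
    power = stats.norm.cdf((zr - zc) * s)
    if tails == "two":
        power += stats.norm.cdf((-zr - zc) * s)
    return float(power)


def power_paired_t(
    n: int, d: float, alpha: float = 0.05, tails: Tails = "one"
) -> float:
    """Power of a paired (one-sample) t test at ``n`` pairs, effect ``d``.

    Exact under normality: noncentral t with ``df = n - 1`` and
    noncentrality ``d * sqrt(n)``.
    """
    if n < 2:
        raise DomainError("paired-t power needs n >= 2")
    if d < 0:
        raise DomainError("d must be non-negative")
    df = n - 1
    ncp = d * np.sqrt(n)
    a = alpha if tails == "one" else alpha / 2
    tc = stats.t.ppf(1 - a, df)
    power = stats.nct.sf(tc, df, ncp)
    if tails == "two":
        power += stats.nct.cdf(-tc, df, ncp)
    return float(power)


def _solve_min_n(power_fn, n_min: int, target: float) -> int:
    """Smallest integer n with power_fn(n) >= target (power increasing in n)."""
    lo = n_min
    if power_fn(lo) >= target:
        return lo
    hi = lo
    while power_fn(hi) < target:
        hi *= 2
        if hi > _N_CAP:
            raise SolverError(
                f"target power not reachable below n = {_N_CAP:,}"
            )
    # invariant: power(lo) < target <= power(hi)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_fn(mid) >= target:
            hi = mid
        else:
            lo = mid
    return hi


def required_n_between(spec: PowerSpec) -> PowerResult:
    """Solve total N for a between-subjects contrast via correlation power.

    The raw solution is rounded up to the nearest multiple of ``spec.k``
    (when given) so every condition gets the same number of participants.
    """
    if spec.design != "between":
        raise DomainError("spec.design must be 'between'")
    n_raw = _solve_min_n(
        lambda n: power_correlation(n, spec.effect, spec.alpha, spec.tails),
        4,
        spec.target_power,
    )
    if spec.k:
        per = -(-n_raw // spec.k)  # ceil division
        n_total = per * spec.k
    else:
        per = None
        n_total = n_raw
    return PowerResult(
        spec=spec,
        n_total=n_total,
        n_per_condition=per,
        n_raw=n_raw,
        achieved_power=power_correlation(
            n_total, spec.effect, spec.alpha, spec.tails
        ),
    )


def required_n_within(spec: PowerSpec) -> PowerResult:
    """Solve the number of subjects for a within-subjects contrast."""
    if spec.design != "within":
        raise DomainError("spec.design must be 'within'")
    n = _solve_min_n(
        lambda n: power_paired_t(n, spec.effect, spec.alpha, spec.tails),
        2,
        spec.target_power,
    )
    return PowerResult(
        spec=spec,
        n_total=n,
        n_raw=n,
        achieved_power=power_paired_t(n, spec.effect, spec.alpha, spec.tails),
    )
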