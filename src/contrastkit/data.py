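"""Bundled worked-example data and a synthetic long-format generator.

Two small fixtures make every statistic in the package testable offline:

``maraver_summaries``
    Group summaries from a three-condition false-memory experiment
    (encoding instructions *imagine* / *memorize* / *pay attention*;
    DV = proportion of correctly completed sentences; n = 40 per group).

``akan_toy``
    A four-participant excerpt from a three-condition testing-effect
    experiment (*testing* / *restudying* / *control*; DV = number of
    correctly selected contexts), used to demonstrate the within-subjects
    L-score arithmetic by hand.

The synthetic generator draws homoscedastic normal data — the implicit model
of the contrast F/t machinery.  Between designs are independent groups;
within designs use compound symmetry: a shared subject intercept with
variance ``rho * sd**2`` plus residuals with variance ``(1 - rho) * sd**2``,
giving every condition variance ``sd**2`` and every pair of conditions
correlation ``rho``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence, Union

import numpy as np
import pandas as pd

from .between import GroupSummaries
from .errors import DomainError
from .within import WithinMatrix

__all__ = [
    "SyntheticSpec",
    "moment_matched_sample",
    "generate",
    "load_fixture",
    "FIXTURES",
]

_MARAVER = dict(
    labels=("imagine", "memorize", "pay attention"),
    means=(0.414, 0.200, 0.250),
    variances=(0.025, 0.012, 0.015),
    ns=(40, 40, 40),
)

_AKAN_TOY = dict(
    subject_ids=(1, 2, 3, 4),
    condition_labels=("testing", "restudying", "control"),
    values=((1, 5, 3), (1, 4, 3), (3, 2, 1), (4, 7, 5)),
)

FIXTURES = ("maraver_summaries", "akan_toy")


def load_fixture(name: str) -> Union[GroupSummaries, WithinMatrix]:
    """Return a bundled worked-example dataset by name.

    ``maraver_summaries`` -> :class:`GroupSummaries` (between-subjects);
    ``akan_toy`` -> :class:`WithinMatrix` (within-subjects).
    """
    if name == "maraver_summaries":
        return GroupSummaries(**_MARAVER)
    if name == "akan_toy":
        return WithinMatrix(**_AKAN_TOY)
    raise KeyError(
        f"unknown fixture {name!r}; available: {', '.join(FIXTURES)}"
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic K-condition normal dataset.

    ``icc_rho`` applies only to within designs: the common correlation
    between any two repeated measurements of the same subject.
    """

    labels: tuple[str, ...]
    condition_means: tuple[float, ...]
    within_group_sd: float
    n_per_group: int
    design: Literal["between", "within"]
    seed: int
    icc_rho: float = 0.0

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.condition_means):
            raise DomainError("labels and condition_means differ in length")
        if len(self.labels) < 2:
            raise DomainError("need at least two conditions")
        if self.within_group_sd <= 0:
            raise DomainError("within_group_sd must be positive")
        if self.n_per_group < 2:
            raise DomainError("n_per_group must be at least 2")
        if self.design not in ("between", "within"):
            raise DomainError("design must be 'between' or 'within'")
        if not 0 <= self.icc_rho < 1:
            raise DomainError("icc_rho must be in [0, 1)")
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        object.__setattr__(
            self,
            "condition_means",
            tuple(float(v) for v in self.condition_means),
        )


def moment_matched_sample(
    mean: float, variance: float, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw n values whose *sample* mean and variance (ddof=1) are exact.

    A standard normal draw is affinely rescaled to hit the target moments to
    machine precision — useful for reconstructing a group from published
    summary statistics.  ``variance == 0`` returns n copies of the mean.
    """
    if variance < 0:
        raise DomainError("variance must be non-negative")
    if n < 2 and variance > 0:
        raise DomainError("n >= 2 required to realize a non-zero variance")
    if variance == 0:
        return np.full(n, float(mean))
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    while True:
        z = rng.standard_normal(n)
        if z.std(ddof=1) > 0:
            break
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + np.sqrt(variance) * z


def generate(spec: SyntheticSpec) -> pd.DataFrame:
    """Generate a long-format dataset (columns ``id``, ``condition``, ``dv``).

    Between: independent ``N(mu_i, sd^2)`` groups, one subject per row.
    Within: each subject gets all conditions with compound-symmetry
    covariance.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    k = len(spec.labels)
    n = spec.n_per_group
    sd = spec.within_group_sd
    if spec.design == "between":
        frames = []
        for i, (label, mu) in enumerate(zip(spec.labels, spec.condition_means)):
            dv = mu + sd * rng.standard_normal(n)
            frames.append(
                pd.DataFrame(
                    {
                        "id": [f"s{i * n + j + 1}" for j in range(n)],
                        "condition": label,
                        "dv": dv,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    rho = spec.icc_rho
    intercepts = np.sqrt(rho) * sd * rng.standard_normal(n)
    resid = np.sqrt(1 - rho) * sd * rng.standard_normal((n, k))
    mat = np.asarray(spec.condition_means) + intercepts[:, None] + resid
    rows = {
        "id": np.repeat([f"s{j + 1}" for j in range(n)], k),
        "condition": np.tile(spec.labels, n),
        "dv": mat.ravel(),
    }
    return pd.DataFrame(rows)
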