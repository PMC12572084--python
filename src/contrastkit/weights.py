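"""Contrast-weight vectors: construction, validation, standardization.

A contrast encodes a directional hypothesis about K condition means as a
weight vector lambda that sums to zero.  Weights here are always bound to
condition *labels*, never to positions: every analysis entry point re-aligns
weights to the data by label and raises :class:`~contrastkit.errors.AlignmentError`
on mismatch, so a re-sorted input file can never silently permute a hypothesis.

Two rival hypotheses are compared through the difference of their
*standardized* vectors (each divided by its root-mean-square), which puts both
on the same scale before subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import DegenerateContrastError, DegeneratePatternError, WeightError

__all__ = [
    "ContrastWeights",
    "PredictedPattern",
    "validate_weights",
    "weights_from_pattern",
    "standardize_weights",
    "lambda_diff",
    "helmert_set",
]

#: relative tolerance on the zero-sum requirement
ZERO_SUM_RTOL = 1e-8
#: ||difference vector|| below this (times K) means the rivals coincide
DEGENERATE_NORM_TOL = 1e-10


@dataclass(frozen=True)
class ContrastWeights:
    """A validated contrast-weight vector bound to condition labels.

    Parameters
    ----------
    labels
        Ordered, unique condition labels.
    lam
        One real weight per label; the weights must sum to zero (within a
        relative tolerance of ``1e-8``) and not all be zero.

    Attributes
    ----------
    k : int
        Number of conditions.
    s_lambda : float
        Root-mean-square of the weights, ``sqrt(sum(lam**2) / k)`` — the
        population-form standard deviation used for standardization.
    """

    labels: tuple[str, ...]
    lam: tuple[float, ...]
    k: int = field(init=False)
    s_lambda: float = field(init=False)

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels)
        lam = np.asarray(self.lam, dtype=float)
        if lam.ndim != 1:
            raise WeightError("weights must be a one-dimensional sequence")
        if len(labels) != lam.size:
            raise WeightError(
                f"{len(labels)} labels but {lam.size} weights"
            )
        if len(set(labels)) != len(labels):
            raise WeightError(f"duplicate condition labels: {labels}")
        if lam.size < 2:
            raise WeightError("a contrast needs at least two conditions")
        if not np.all(np.isfinite(lam)):
            raise WeightError("weights must be finite")
        if np.all(lam == 0):
            raise WeightError("all weights are zero; no contrast is defined")
        tol = ZERO_SUM_RTOL * max(1.0, float(np.max(np.abs(lam))))
        if abs(lam.sum()) > tol:
            raise WeightError(
                f"contrast weights must sum to zero, got sum={lam.sum():g} "
                f"(tolerance {tol:g}); weights are rejected rather than "
                "auto-centered"
            )
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "lam", tuple(float(v) for v in lam))
        object.__setattr__(self, "k", lam.size)
        object.__setattr__(self, "s_lambda", float(np.sqrt(np.mean(lam**2))))

    @property
    def values(self) -> np.ndarray:
        """Weights as a float array (copy)."""
        return np.asarray(self.lam, dtype=float)

    def as_mapping(self) -> dict[str, float]:
        return dict(zip(self.labels, self.lam))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "ContrastWeights":
        return cls(tuple(mapping.keys()), tuple(mapping.values()))

    def aligned_to(self, labels: Sequence[str]) -> "ContrastWeights":
        """Reorder the weights to ``labels``; error if the label sets differ."""
        from .errors import AlignmentError

        target = tuple(str(x) for x in labels)
        if set(target) != set(self.labels) or len(target) != len(self.labels):
            raise AlignmentError(
                f"weight labels {sorted(self.labels)} do not match data "
                f"labels {sorted(set(target))}"
            )
        m = self.as_mapping()
        return ContrastWeights(target, tuple(m[x] for x in target))

    def standardized(self) -> "ContrastWeights":
        """Divide by the root-mean-square so the output has RMS 1."""
        return ContrastWeights(
            self.labels, tuple(v / self.s_lambda for v in self.lam)
        )

    def scaled(self, c: float) -> "ContrastWeights":
        if c == 0:
            raise WeightError("scale factor must be non-zero")
        return ContrastWeights(self.labels, tuple(c * v for v in self.lam))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        pairs = ", ".join(f"{l}={v:g}" for l, v in zip(self.labels, self.lam))
        return f"ContrastWeights({pairs})"


@dataclass(frozen=True)
class PredictedPattern:
    """Hypothesized condition means in arbitrary units.

    Only the *relative* pattern matters; the grand mean is subtracted when the
    pattern is converted to contrast weights.
    """

    labels: tuple[str, ...]
    means: tuple[float, ...]

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels)
        means = np.asarray(self.means, dtype=float)
        if len(labels) != means.size:
            raise WeightError("labels and means differ in length")
        if not np.all(np.isfinite(means)):
            raise WeightError("predicted means must be finite")
        if np.ptp(means) == 0:
            raise DegeneratePatternError(
                "all predicted means are equal; no contrast exists"
            )
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "means", tuple(float(v) for v in means))


def validate_weights(
    labels: Sequence[str], lam: Sequence[float]
) -> ContrastWeights:
    """Validate a raw weight vector without rescaling it.

    Raises
    ------
    WeightError
        If the weights do not sum to zero, are all zero, or labels repeat.
    """
    return ContrastWeights(tuple(labels), tuple(lam))


def weights_from_pattern(
    pattern: PredictedPattern, scale: float = 1.0
) -> ContrastWeights:
    """Derive contrast weights from a predicted mean pattern.

    Subtracts the grand mean of the pattern (which makes the weights sum to
    zero exactly) and optionally multiplies by ``scale`` for convenient
    round numbers.
    """
    if scale <= 0:
        raise WeightError("scale must be positive")
    means = np.asarray(pattern.means, dtype=float)
    lam = scale * (means - means.mean())
    # centering is exact in theory; clean up the last bit of float error
    lam = lam - lam.sum() / lam.size
    return ContrastWeights(pattern.labels, tuple(lam))


def standardize_weights(w: ContrastWeights) -> ContrastWeights:
    """Divide the weights by their root-mean-square (divide-by-K form)."""
    return w.standardized()


def lambda_diff(
    favored: ContrastWeights, rival: ContrastWeights
) -> ContrastWeights:
    """Difference of the standardized favored and rival contrast vectors.

    The result is itself a contrast vector: a positive test of it means the
    favored predicted pattern covaries more strongly with the observed means
    than the rival pattern does.

    Raises
    ------
    DegenerateContrastError
        If the two hypotheses are proportional (identical once standardized),
        leaving a zero vector that cannot be tested.
    AlignmentError
        If the two vectors are bound to different label sets.
    """
    rival = rival.aligned_to(favored.labels)
    diff = favored.standardized().values - rival.standardized().values
    if np.linalg.norm(diff) < DEGENERATE_NORM_TOL * favored.k:
        raise DegenerateContrastError(
            "favored and rival contrasts are identical after standardization"
        )
    diff = diff - diff.sum() / diff.size
    return ContrastWeights(favored.labels, tuple(diff))


def helmert_set(labels: Sequence[str]) -> list[ContrastWeights]:
    """Build the K-1 orthogonal Helmert contrasts for the given conditions.

    Vector ``m`` contrasts level ``m`` against the mean of all later levels,
    so the set exhausts the K-1 between-group degrees of freedom.
    """
    labels = tuple(str(x) for x in labels)
    k = len(labels)
    if k < 2:
        raise WeightError("a Helmert set needs at least two conditions")
    out = []
    for m in range(k - 1):
        lam = np.zeros(k)
        lam[m] = 1.0
        lam[m + 1 :] = -1.0 / (k - m - 1)
        out.append(ContrastWeights(labels, tuple(lam)))
    return out
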