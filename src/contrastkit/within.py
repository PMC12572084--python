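"""Contrast tests for dependent samples (within-subjects designs).

Each subject contributes a single score ``L_i = sum_j lambda_j * x_ij``
across the J repeated conditions.  Because the weights sum to zero, any
subject-level constant (a subject's overall level) cancels out of ``L_i``, so
the between-subject correlation structure is absorbed without modelling it.
The test is then a one-sample t test of the ``L_i`` against zero on ``N - 1``
degrees of freedom.

Effect sizes: ``r_contrast = sign(t) * sqrt(t^2/(t^2+df))`` as in the
between-subjects case, and ``g_contrast = Lbar / s_L``, the standardized mean
of the per-subject contrast scores.  ``g_contrast`` is scale-invariant in the
weights and estimates Cohen's d for the contrast in the population, which is
what the paired-t power solver consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    AlignmentError,
    InsufficientDataError,
    MissingCellError,
    ZeroVarianceError,
)
from .weights import ContrastWeights, lambda_diff

__all__ = [
    "WithinMatrix",
    "WithinResult",
    "per_subject_L",
    "within_contrast_test",
    "compare_hypotheses_within",
]


@dataclass(frozen=True)
class WithinMatrix:
    """Complete subjects-by-conditions table of the dependent variable."""

    subject_ids: tuple
    condition_labels: tuple[str, ...]
    values: tuple  # N rows of J floats

    def __post_init__(self) -> None:
        subjects = tuple(self.subject_ids)
        labels = tuple(str(x) for x in self.condition_labels)
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValueError("values must be a 2-D subjects x conditions table")
        n, j = vals.shape
        if n != len(subjects):
            raise ValueError(f"{len(subjects)} subject ids for {n} rows")
        if j != len(labels):
            raise ValueError(f"{len(labels)} condition labels for {j} columns")
        if len(set(subjects)) != len(subjects):
            raise ValueError("duplicate subject ids")
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate condition labels")
        if n < 2 or j < 2:
            raise InsufficientDataError(
                "need at least two subjects and two conditions"
            )
        if np.isnan(vals).any():
            raise MissingCellError(
                "matrix contains missing cells; drop or complete them first"
            )
        object.__setattr__(self, "subject_ids", subjects)
        object.__setattr__(self, "condition_labels", labels)
        object.__setattr__(
            self, "values", tuple(tuple(float(v) for v in row) for row in vals)
        )

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_conditions(self) -> int:
        return len(self.condition_labels)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    @classmethod
    def from_long(
        cls,
        data: pd.DataFrame,
        id: str = "id",
        condition: str = "condition",
        dv: str = "dv",
        drop_incomplete: bool = False,
    ) -> "WithinMatrix":
        """Pivot a long table (one row per subject x condition) to wide.

        Subjects with missing conditions raise
        :class:`~contrastkit.errors.MissingCellError` unless
        ``drop_incomplete`` is set, in which case they are removed with a
        warning (which silently reduces N and hence df — hence the default).
        Duplicate (subject, condition) cells are always an error.
        """
        for col in (id, condition, dv):
            if col not in data.columns:
                raise AlignmentError(
                    f"column {col!r} not in data; found {list(data.columns)}"
                )
        if data.duplicated([id, condition]).any():
            raise ValueError(
                "duplicate (subject, condition) cells; aggregate them first"
            )
        labels = tuple(pd.unique(data[condition]).astype(str))
        subjects = tuple(pd.unique(data[id]))
        wide = data.pivot(index=id, columns=condition, values=dv)
        wide = wide.reindex(index=subjects, columns=labels)
        incomplete = wide.isna().any(axis=1)
        if incomplete.any():
            if not drop_incomplete:
                raise MissingCellError(
                    f"{int(incomplete.sum())} subject(s) lack one or more "
                    "conditions; pass drop_incomplete=True to remove them"
                )
            warnings.warn(
                f"dropping {int(incomplete.sum())} incomplete subject(s); "
                f"N reduced to {int((~incomplete).sum())}",
                stacklevel=2,
            )
            wide = wide.loc[~incomplete]
        return cls(tuple(wide.index), labels, tuple(map(tuple, wide.to_numpy())))


@dataclass(frozen=True)
class WithinResult:
    """Output of a within-subjects contrast test."""

    weights: ContrastWeights
    l_scores: tuple[float, ...]
    l_bar: float
    sigma2_l: float
    se: float
    df: int
    t: float
    p_one_tailed: float
    p_two_tailed: float
    g_contrast: float
    r_contrast: float
    favored: Optional[ContrastWeights] = None
    rival: Optional[ContrastWeights] = None

    def to_dict(self) -> dict:
        d = {
            "design": "within",
            "weights": self.weights.as_mapping(),
            "L": self.l_bar,
            "sigma2_L": self.sigma2_l,
            "se": self.se,
            "df": self.df,
            "t": self.t,
            "p_one_tailed": self.p_one_tailed,
            "p_two_tailed": self.p_two_tailed,
            "g_contrast": self.g_contrast,
            "r_contrast": self.r_contrast,
        }
        if self.favored is not None:
            d["favored"] = self.favored.as_mapping()
        if self.rival is not None:
            d["rival"] = self.rival.as_mapping()
        return d


def per_subject_L(row: Sequence[float], w: ContrastWeights) -> float:
    """One subject's contrast score, ``L_i = sum_j lambda_j x_ij``.

    ``row`` must be aligned to ``w.labels``.
    """
    row = np.asarray(row, dtype=float)
    if row.size != w.k:
        raise AlignmentError(f"{row.size} values supplied for {w.k} weights")
    if np.isnan(row).any():
        raise MissingCellError("missing value in subject row")
    return float(w.values @ row)


def within_contrast_test(m: WithinMatrix, w: ContrastWeights) -> WithinResult:
    """One-sample t test of the per-subject contrast scores against zero.

    ``sigma2_L`` uses the n-1 sample-variance denominator; df = N - 1.
    The one-tailed p value is the upper-tail probability at the observed t.

    Raises
    ------
    ZeroVarianceError
        If all subjects have the same contrast score.
    """
    w = w.aligned_to(m.condition_labels)
    n = m.n_subjects
    scores = m.array @ w.values
    l_bar = float(scores.mean())
    sigma2_l = float(scores.var(ddof=1))
    if sigma2_l == 0:
        raise ZeroVarianceError(
            "all per-subject contrast scores are equal; t is undefined"
        )
    se = float(np.sqrt(sigma2_l / n))
    df = n - 1
    t = l_bar / se
    return WithinResult(
        weights=w,
        l_scores=tuple(float(v) for v in scores),
        l_bar=l_bar,
        sigma2_l=sigma2_l,
        se=se,
        df=df,
        t=float(t),
        p_one_tailed=float(stats.t.sf(t, df)),
        p_two_tailed=float(2 * stats.t.sf(abs(t), df)),
        g_contrast=float(l_bar / np.sqrt(sigma2_l)),
        r_contrast=float(np.sign(t) * np.sqrt(t**2 / (t**2 + df))),
    )


def compare_hypotheses_within(
    m: WithinMatrix,
    favored: ContrastWeights,
    rival: ContrastWeights,
) -> WithinResult:
    """Competing-contrast test for repeated measures.

    Runs the within-subjects test on the difference of the standardized
    favored and rival weight vectors; positive t supports the favored
    pattern.
    """
    diff = lambda_diff(favored, rival)
    res = within_contrast_test(m, diff)
    return WithinResult(**{**res.__dict__, "favored": favored, "rival": rival})
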