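"""Reading delimited inputs and parsing weight specifications.

Input tables are plain delimited text (comma or tab, autodetected).  Two
layouts are understood:

* ``long`` — one row per observation, columns for (optionally) subject id,
  condition label, and the numeric DV;
* ``summaries`` — one row per condition with columns
  ``condition, mean, variance, n``.

Weights arrive as ``"label=weight"`` pairs (``"imagine=1,memorize=-0.5"``),
as a bare comma-separated list (applied to the conditions in data order), or
as a two-column delimited file of (label, weight).
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .between import GroupSummaries
from .errors import AlignmentError
from .weights import ContrastWeights

__all__ = [
    "read_table",
    "read_summaries",
    "parse_weights",
    "file_digest",
]


def read_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a delimited text file, autodetecting comma/tab/semicolon."""
    return pd.read_csv(path, sep=None, engine="python")


def read_summaries(
    path: Union[str, Path],
    condition: str = "condition",
) -> GroupSummaries:
    """Read a per-condition summaries file (condition, mean, variance, n)."""
    df = read_table(path)
    required = {condition, "mean", "variance", "n"}
    if not required.issubset(df.columns):
        raise AlignmentError(
            f"summaries file needs columns {sorted(required)}; "
            f"found {list(df.columns)}"
        )
    return GroupSummaries(
        tuple(df[condition].astype(str)),
        tuple(df["mean"].astype(float)),
        tuple(df["variance"].astype(float)),
        tuple(df["n"].astype(int)),
    )


def parse_weights(
    text: str, labels: Optional[Sequence[str]] = None
) -> ContrastWeights:
    """Parse a weight specification string into :class:`ContrastWeights`.

    ``"a=1,b=-0.5,c=-0.5"`` binds weights to labels explicitly; a bare list
    ``"1,-0.5,-0.5"`` requires ``labels`` (the conditions in data order).  A
    path to a two-column delimited file (label, weight) is also accepted.
    """
    text = text.strip()
    p = Path(text)
    if p.is_file():
        df = read_table(p)
        if df.shape[1] < 2:
            raise AlignmentError(
                f"weight file {p} needs two columns (label, weight)"
            )
        return ContrastWeights(
            tuple(df.iloc[:, 0].astype(str)),
            tuple(df.iloc[:, 1].astype(float)),
        )
    parts = [s.strip() for s in text.split(",") if s.strip()]
    if all("=" in s for s in parts):
        pairs = [s.split("=", 1) for s in parts]
        return ContrastWeights(
            tuple(k.strip() for k, _ in pairs),
            tuple(float(v) for _, v in pairs),
        )
    values = tuple(float(s) for s in parts)
    if labels is None:
        labels = tuple(f"c{i + 1}" for i in range(len(values)))
    if len(labels) != len(values):
        raise AlignmentError(
            f"{len(values)} weights supplied for {len(labels)} conditions"
        )
    return ContrastWeights(tuple(labels), values)


def file_digest(path: Union[str, Path]) -> str:
    """SHA-256 digest of an input file, for run logging."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]
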