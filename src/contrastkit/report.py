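"""Plain-text report rendering.

Display rounding follows the conventions of hand-worked contrast analyses:
weights and t statistics at 2 decimals, contrast estimates and variances at
3.  Machine (JSON) output always carries full precision; rendering a report
never mutates the result objects.
"""

from __future__ import annotations

from .between import BetweenResult
from .weights import ContrastWeights
from .within import WithinResult

__all__ = ["format_weights", "format_between", "format_within"]


def _fmt(x, nd):
    return f"{x:.{nd}f}"


def format_weights(w: ContrastWeights, title: str = "Contrast weights") -> str:
    lines = [title, "-" * len(title)]
    width = max(len(l) for l in w.labels)
    for label, v in zip(w.labels, w.lam):
        lines.append(f"  {label:<{width}}  {v:6.2f}")
    return "\n".join(lines)


def _p_str(p: float) -> str:
    return "<.001" if p < 0.001 else f"{p:.3f}"


def format_between(res: BetweenResult) -> str:
    """Render the weights table, t-table, F-table and effect sizes."""
    blocks = []
    if res.favored is not None and res.rival is not None:
        blocks.append(format_weights(res.favored, "Favored hypothesis"))
        blocks.append(format_weights(res.rival, "Rival hypothesis"))
        blocks.append(
            format_weights(res.weights, "Difference contrast (standardized)")
        )
    else:
        blocks.append(format_weights(res.weights))

    blocks.append(
        "\n".join(
            [
                "t-table (directional)",
                "---------------------",
                f"  L     {_fmt(res.l_estimate, 3)}",
                f"  SE    {_fmt(res.se, 3)}",
                f"  df    {res.df}",
                f"  t     {_fmt(res.t, 2)}",
                f"  p     {_p_str(res.p_one_tailed)}  (one-tailed)",
            ]
        )
    )
    blocks.append(
        "\n".join(
            [
                "F-table (non-directional)",
                "-------------------------",
                f"  SS    {_fmt(res.ss_contrast, 3)}",
                f"  df    1",
                f"  MS    {_fmt(res.ms_contrast, 3)}",
                f"  F     {_fmt(res.f, 2)}",
                f"  p     {_p_str(res.p_f)}",
            ]
        )
    )
    eff = [
        "Effect sizes",
        "------------",
        f"  r_alerting    {_fmt(res.r_alerting, 3)}",
        f"  r_contrast    {_fmt(res.r_contrast, 3)}",
    ]
    if res.r_effectsize is not None:
        eff.insert(2, f"  r_effectsize  {_fmt(res.r_effectsize, 3)}")
    blocks.append("\n".join(eff))
    return "\n\n".join(blocks)


def format_within(res: WithinResult) -> str:
    """Render the within-subjects contrast report."""
    blocks = []
    if res.favored is not None and res.rival is not None:
        blocks.append(format_weights(res.favored, "Favored hypothesis"))
        blocks.append(format_weights(res.rival, "Rival hypothesis"))
        blocks.append(
            format_weights(res.weights, "Difference contrast (standardized)")
        )
    else:
        blocks.append(format_weights(res.weights))
    blocks.append(
        "\n".join(
            [
                "t-table (directional)",
                "---------------------",
                f"  L     {_fmt(res.l_bar, 3)}",
                f"  SE    {_fmt(res.se, 3)}",
                f"  df    {res.df}",
                f"  t     {_fmt(res.t, 2)}",
                f"  p     {_p_str(res.p_one_tailed)}  (one-tailed)",
            ]
        )
    )
    blocks.append(
        "\n".join(
            [
                "Effect sizes",
                "------------",
                f"  r_contrast  {_fmt(res.r_contrast, 3)}",
                f"  g_contrast  {_fmt(res.g_contrast, 3)}",
            ]
        )
    )
    return "\n\n".join(blocks)
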