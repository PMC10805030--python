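"""Bookkeeping percentages used in pipeline logs and reports."""

from __future__ import annotations


def percent(numerator: float, denominator: float, decimals: int = 2) -> float:
    """100 * numerator / denominator rounded to ``decimals`` places."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round(100.0 * numerator / denominator, decimals)


def selection_percent(n_selected: int, n_passing_qc: int) -> float:
    """Share of QC-passing features selected by the sparse model, as a
    percentage rounded to two decimals (e.g. 14 of 237 -> 5.91)."""
    return percent(n_selected, n_passing_qc, decimals=2)


def format_percent(numerator: float, denominator: float, decimals: int = 2) -> str:
    value = percent(numerator, denominator, decimals)
    return f"{value:.{decimals}f}%"
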