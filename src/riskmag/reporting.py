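"""Report arithmetic: the small derived quantities the summary tables print.

These helpers are used by the report renderer so that every printed number
(events prevented per 1000 treated, per-arm event percentages, exclusion
fractions, estimated-minus-observed differences) comes from one audited place.
"""

from __future__ import annotations


def events_prevented_per_1000(risk_difference: float) -> float:
    """Events prevented per 1000 treated implied by an absolute risk
    difference (negative RD = benefit): -RD * 1000."""
    return round(-risk_difference * 1000)


def event_percent(events: int, n: int) -> float:
    """Event percentage 100*events/n to one decimal, as printed in the
    per-tertile outcome tables."""
    if n <= 0:
        raise ValueError("n must be positive")
    return round(100.0 * events / n, 1)


def estimated_minus_observed(estimated_rd: float, observed_rd: float) -> float:
    """Difference between model-estimated and KM-observed risk differences,
    to three decimals."""
    return round(estimated_rd - observed_rd, 3)


def exclusion_percent(excluded: int, randomized: int) -> float:
    """Percentage of randomized subjects excluded, to one decimal."""
    if randomized <= 0:
        raise ValueError("randomized must be positive")
    return round(100.0 * excluded / randomized, 1)


def cohort_total(n_intensive: int, n_standard: int) -> int:
    """Analytic cohort size from per-arm counts."""
    if n_intensive < 0 or n_standard < 0:
        raise ValueError("arm counts must be nonnegative")
    return n_intensive + n_standard
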