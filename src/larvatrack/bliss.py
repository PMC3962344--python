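"""Bliss Independence analysis of combination pretreatments.

Under Bliss Independence two non-interacting drugs combine multiplicatively:
if a drug alone attenuates the nicotine response by the fraction D and
varenicline alone by V, the expected remaining response is

    E = 1 − (D + V − D·V) = (1 − D)(1 − V),

i.e. the product of the monotherapy percent responses.  A measured
combination response below the expectation is greater-than-additive
(synergy-consistent), above it less-than-additive, and within a small
percentage-point band, additive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .assay_stats import ConditionSummary
from .errors import AnalysisError, InputError

__all__ = [
    "BlissResult",
    "bliss_expected",
    "classify_interaction",
    "bliss_from_summaries",
    "GREATER",
    "ADDITIVE",
    "LESS",
]

GREATER = "greater_than_additive"
ADDITIVE = "additive"
LESS = "less_than_additive"

#: Width of the additive band, in percentage points of the untreated response.
DEFAULT_TOLERANCE_PP = 2.0


@dataclass(frozen=True)
class BlissResult:
    drug_label: str
    D: float
    V: float
    expected_percent: float
    measured_percent: float
    interaction: str
    tolerance_pp: float

    @property
    def margin_pp(self) -> float:
        """Measured minus expected, percentage points (negative = stronger than additive)."""
        return self.measured_percent - self.expected_percent


def bliss_expected(D: float, V: float) -> float:
    """Expected remaining fraction of the untreated response: E = 1 − (D + V − D·V)."""
    if not (0.0 <= D <= 1.0 and 0.0 <= V <= 1.0):
        raise AnalysisError(f"attenuation fractions must be in [0,1], got D={D}, V={V}")
    return 1.0 - (D + V - D * V)


def classify_interaction(
    measured_percent: float,
    expected_percent: float,
    tolerance_pp: float = DEFAULT_TOLERANCE_PP,
) -> str:
    """Label the combination response relative to the Bliss expectation."""
    if tolerance_pp < 0:
        raise InputError(f"tolerance_pp must be >= 0, got {tolerance_pp}")
    if measured_percent < 0 or expected_percent < 0:
        raise InputError("percent responses must be non-negative")
    if measured_percent < expected_percent - tolerance_pp:
        return GREATER
    if abs(measured_percent - expected_percent) <= tolerance_pp:
        return ADDITIVE
    return LESS


def _attenuation_from_percent(percent: float, who: str) -> float:
    D = 1.0 - percent / 100.0
    if D < 0.0:
        warnings.warn(
            f"{who}: monotherapy percent {percent:.1f} > 100 (potentiation); "
            "attenuation clamped to 0 for the Bliss model",
            stacklevel=3,
        )
        return 0.0
    return min(D, 1.0)


def bliss_from_summaries(
    drug_mono: ConditionSummary,
    varenicline_mono: ConditionSummary,
    combo: ConditionSummary,
    tolerance_pp: float = DEFAULT_TOLERANCE_PP,
) -> BlissResult:
    """Bliss result from three condition summaries normalized to the same stimulus-only arm."""
    for s, who in (
        (drug_mono, "drug monotherapy"),
        (varenicline_mono, "varenicline monotherapy"),
        (combo, "combination"),
    ):
        if s.percent_of_stimulus is None:
            raise InputError(f"{who} summary has no percent_of_stimulus")
    D = _attenuation_from_percent(drug_mono.percent_of_stimulus, "drug monotherapy")
    V = _attenuation_from_percent(varenicline_mono.percent_of_stimulus, "varenicline monotherapy")
    expected = 100.0 * bliss_expected(D, V)
    measured = combo.percent_of_stimulus
    return BlissResult(
        drug_label=drug_mono.condition_label,
        D=D,
        V=V,
        expected_percent=expected,
        measured_percent=measured,
        interaction=classify_interaction(measured, expected, tolerance_pp),
        tolerance_pp=tolerance_pp,
    )
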