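"""Condition summaries, significance testing, drug categorization, and dosing arithmetic.

The screening readout is the cumulative distance traveled in an analysis
window after stimulus administration (0–4 min for nicotine and the oil
controls, 30–40 min for ethanol), averaged across replicate dishes and
expressed as a percentage of the stimulus-only response.  Significance is a
two-sided two-sample t-test at alpha = 0.05 with the replicate dish as the
unit of analysis; the pooled-variance (Student) flavor is the default, with
Welch available.

Drugs are classified into four screening categories:
(i) no attenuation, no toxicity; (ii) no attenuation but toxicity evidence
(drug absorbed); (iii) attenuation of the nicotine response and of at least
one peripheral oil control (sedation/impairment suspected); (iv) attenuation
of the nicotine response only — the screen's hits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, ConfigError, InputError
from .tracking import DishSeries

__all__ = [
    "AssayDesign",
    "ConditionSummary",
    "DrugCategory",
    "two_sided_t_test",
    "summarize_condition",
    "classify_drug",
    "final_concentration",
    "dose_response_table",
]

#: Default analysis windows (seconds relative to stimulus administration).
NICOTINE_WINDOW_S = (0.0, 240.0)
ETHANOL_WINDOW_S = (1800.0, 2400.0)
BASELINE_WINDOW_S = (-120.0, 0.0)


@dataclass
class AssayDesign:
    """Windows, stimulus identity and test level for one locomotor assay."""

    stimulus: str = "nicotine"
    stimulus_label: str = "stimulus-only"
    stimulus_time_s: float = 0.0
    baseline_window_s: tuple[float, float] = BASELINE_WINDOW_S
    analysis_window_s: tuple[float, float] = NICOTINE_WINDOW_S
    alpha: float = 0.05
    equal_var: bool = True  # Student's pooled-variance t-test; False = Welch
    baseline_subtract: bool = False

    def __post_init__(self) -> None:
        b0, b1 = self.baseline_window_s
        a0, a1 = self.analysis_window_s
        if not (b0 < b1 and a0 < a1):
            raise ConfigError("assay windows must be non-empty intervals")
        if a0 < 0:
            raise ConfigError("analysis window must start at or after the stimulus")
        if b1 > a0:
            raise ConfigError("baseline and analysis windows overlap")
        if not (0 < self.alpha < 1):
            raise ConfigError(f"alpha must be in (0,1), got {self.alpha}")


@dataclass
class ConditionSummary:
    condition_label: str
    n_replicates: int
    mean_cumulative_px: float
    se_cumulative_px: float
    percent_of_stimulus: float
    t_stat: float | None = None
    df: float | None = None
    p_value: float | None = None
    replicate_cumulative_px: list[float] = field(default_factory=list)
    baseline_mean_px: float | None = None


@dataclass(frozen=True)
class DrugCategory:
    """Screening category with the evidence that produced it."""

    label: str  # one of "i", "ii", "iii", "iv"
    nicotine_attenuated: bool
    control_attenuated: bool
    toxicity_observed: bool
    potentiation: bool = False
    provisional: bool = False


def two_sided_t_test(
    a: Sequence[float], b: Sequence[float], equal_var: bool = True
) -> tuple[float, float, float]:
    """Two-sided two-sample t-test; returns (t, df, p).

    Zero pooled variance is handled deterministically: equal means give
    p = 1, unequal means give p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InputError("t-test requires at least 2 observations per group")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise InputError("t-test inputs must be finite")
    df = (len(a) + len(b) - 2) if equal_var else _welch_df(a, b)
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(df), 1.0
        return float("inf") if a.mean() > b.mean() else float("-inf"), float(df), 0.0
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


def _welch_df(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    if va + vb == 0:
        return float(len(a) + len(b) - 2)
    return (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))


def _replicate_cumulatives(
    series: Sequence[DishSeries], design: AssayDesign, label: str
) -> list[float]:
    reps = [s for s in series if s.condition_label == label]
    vals = []
    for s in reps:
        c = s.cumulative(design.analysis_window_s, origin_s=design.stimulus_time_s)
        if design.baseline_subtract:
            b0, b1 = design.baseline_window_s
            a0, a1 = design.analysis_window_s
            base = s.cumulative(design.baseline_window_s, origin_s=design.stimulus_time_s)
            c -= base * (a1 - a0) / (b1 - b0)  # baseline rate scaled to window length
        vals.append(c)
    return vals


def summarize_condition(
    series: Sequence[DishSeries],
    design: AssayDesign,
    condition_label: str,
) -> ConditionSummary:
    """Windowed cumulative distance per replicate, normalized to the stimulus-only mean.

    ``series`` must include the replicates of both ``condition_label`` and the
    design's stimulus-only label.  percent_of_stimulus is 100 × the ratio of
    replicate means; the t-test compares replicate cumulative distances of the
    condition against stimulus-only.
    """
    cond = _replicate_cumulatives(series, design, condition_label)
    stim = _replicate_cumulatives(series, design, design.stimulus_label)
    if not cond:
        raise InputError(f"no replicate series for condition {condition_label!r}")
    if not stim:
        raise InputError(f"no replicate series for stimulus-only {design.stimulus_label!r}")
    stim_mean = float(np.mean(stim))
    if stim_mean == 0.0:
        raise AnalysisError("stimulus-only mean cumulative distance is zero; cannot normalize")
    mean = float(np.mean(cond))
    se = float(np.std(cond, ddof=1) / np.sqrt(len(cond))) if len(cond) > 1 else 0.0
    percent = 100.0 * mean / stim_mean

    t = df = p = None
    if condition_label == design.stimulus_label or cond == stim:
        pass  # comparing the stimulus-only replicates against themselves is degenerate
    elif len(cond) < 2 or len(stim) < 2:
        warnings.warn(
            f"condition {condition_label!r}: <2 replicates, p-value not computed",
            stacklevel=2,
        )
    else:
        t, df, p = two_sided_t_test(cond, stim, equal_var=design.equal_var)

    baseline = None
    if design.baseline_window_s is not None:
        per_rep = [
            s.cumulative(design.baseline_window_s, origin_s=design.stimulus_time_s)
            for s in series
            if s.condition_label == condition_label
        ]
        baseline = float(np.mean(per_rep)) if per_rep else None
    return ConditionSummary(
        condition_label=condition_label,
        n_replicates=len(cond),
        mean_cumulative_px=mean,
        se_cumulative_px=se,
        percent_of_stimulus=percent,
        t_stat=t,
        df=df,
        p_value=p,
        replicate_cumulative_px=list(map(float, cond)),
        baseline_mean_px=baseline,
    )


def _attenuated(summary: ConditionSummary | None, alpha: float) -> bool:
    if summary is None or summary.p_value is None:
        return False
    return summary.p_value < alpha and summary.percent_of_stimulus < 100.0


def _potentiated(summary: ConditionSummary | None, alpha: float) -> bool:
    if summary is None or summary.p_value is None:
        return False
    return summary.p_value < alpha and summary.percent_of_stimulus > 100.0


def classify_drug(
    nicotine: ConditionSummary,
    cinnamon: ConditionSummary | None = None,
    mustard: ConditionSummary | None = None,
    toxicity_observed: bool = False,
    alpha: float = 0.05,
) -> DrugCategory:
    """Assign the screening category (i)–(iv) from assay summaries.

    Attenuation requires both significance (p < alpha) and percent < 100;
    significant potentiation is flagged separately and never counts as
    attenuation.  A nicotine-attenuating drug with no oil-control data is
    returned as provisional category (iv) with a warning.
    """
    if nicotine.p_value is None:
        raise InputError("nicotine summary must carry a p-value for classification")
    nic_att = _attenuated(nicotine, alpha)
    ctrl_att = _attenuated(cinnamon, alpha) or _attenuated(mustard, alpha)
    potent = any(_potentiated(s, alpha) for s in (nicotine, cinnamon, mustard))
    provisional = False
    if nic_att:
        if cinnamon is None and mustard is None:
            warnings.warn(
                "nicotine attenuation without oil-control data: provisional category iv",
                stacklevel=2,
            )
            provisional = True
        label = "iii" if ctrl_att else "iv"
    else:
        label = "ii" if toxicity_observed else "i"
    return DrugCategory(
        label=label,
        nicotine_attenuated=nic_att,
        control_attenuated=ctrl_att,
        toxicity_observed=toxicity_observed,
        potentiation=potent,
        provisional=provisional,
    )


def final_concentration(stock_conc: float, added_volume: float, total_volume: float) -> float:
    """Bath concentration after adding ``added_volume`` of stock into ``total_volume``.

    E.g. 500 μl of 400 μM stock into 10 ml of dish water gives 20 μM.
    """
    if added_volume <= 0 or total_volume <= 0:
        raise InputError("volumes must be positive")
    if added_volume > total_volume:
        raise InputError("added volume cannot exceed the total volume")
    return stock_conc * added_volume / total_volume


def dose_response_table(
    summaries: Sequence[tuple[float, ConditionSummary]],
) -> tuple[pd.DataFrame, float, bool]:
    """Order summaries by dose; report the peak dose and an inverted-U flag.

    The inverted-U flag is true iff the mean cumulative distances rise to a
    single interior maximum (non-strict: plateaus allowed) and fall after it.
    Returns (table, peak_dose, is_inverted_u).
    """
    if len(summaries) < 3:
        raise InputError("dose-response needs at least 3 doses")
    doses = [d for d, _ in summaries]
    if len(set(doses)) != len(doses):
        raise InputError(f"duplicate doses: {sorted(doses)}")
    ordered = sorted(summaries, key=lambda t: t[0])
    means = np.array([s.mean_cumulative_px for _, s in ordered])
    table = pd.DataFrame(
        {
            "dose": [d for d, _ in ordered],
            "condition": [s.condition_label for _, s in ordered],
            "n": [s.n_replicates for _, s in ordered],
            "mean_cumulative_px": means,
            "se_cumulative_px": [s.se_cumulative_px for _, s in ordered],
            "percent_of_stimulus": [s.percent_of_stimulus for _, s in ordered],
        }
    )
    peak_idx = int(np.argmax(means))
    peak_dose = float(table["dose"].iloc[peak_idx])
    at_max = np.flatnonzero(means == means.max())
    interior = at_max.min() > 0 and at_max.max() < len(means) - 1
    contiguous = np.all(np.diff(at_max) == 1)
    rising = np.all(np.diff(means[: at_max.min() + 1]) >= 0)
    falling = np.all(np.diff(means[at_max.max() :]) <= 0)
    is_inverted_u = bool(interior and contiguous and rising and falling)
    return table, peak_dose, is_inverted_u


def summaries_to_frame(summaries: Sequence[ConditionSummary]) -> pd.DataFrame:
    """Flatten condition summaries for CSV export."""
    return pd.DataFrame(
        [
            {
                "condition": s.condition_label,
                "n": s.n_replicates,
                "mean_cumulative_px": s.mean_cumulative_px,
                "se_cumulative_px": s.se_cumulative_px,
                "percent_of_stimulus": s.percent_of_stimulus,
                "t_stat": s.t_stat,
                "df": s.df,
                "p_value": s.p_value,
            }
            for s in summaries
        ]
    )
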