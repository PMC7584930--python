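"""Two-sided unstratified log-rank (Mantel-Haenszel) test.

This is the significance engine behind every fragility iteration, so it is
implemented directly on numpy arrays. At each distinct event time ``t`` with
``d_t`` events among ``n_t`` subjects at risk (``n1_t`` of them in the
experimental arm) the test accumulates

    O - E = sum_t ( d1_t - d_t * n1_t / n_t )
    V     = sum_t d_t * (n1_t / n_t) * (1 - n1_t / n_t) * (n_t - d_t) / (n_t - 1)

and refers ``(O - E)^2 / V`` to a chi-square distribution with one degree of
freedom. Subjects censored at ``t`` are still at risk for events at exactly
``t`` (the standard convention); all events tied at one time are handled in a
single risk-set step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from sifi.survival_data import SurvivalDataset


@dataclass(frozen=True)
class LogRankResult:
    """Outcome of the unstratified two-sample log-rank test.

    ``observed`` and ``expected`` refer to the experimental arm;
    ``direction`` is the sign of (observed - expected), i.e. +1 when the
    experimental arm has more events than expected under the null.
    ``degenerate`` marks datasets with no events, for which the test is
    vacuous (statistic 0, p 1).
    """

    statistic: float
    p_value: float
    observed: float
    expected: float
    direction: int
    degenerate: bool = False


def logrank_arrays(
    time: np.ndarray, event: np.ndarray, experimental: np.ndarray
) -> LogRankResult:
    """Log-rank test on raw arrays (time, event flag, experimental-arm flag).

    Exists as a separate entry point so iterative algorithms can avoid
    rebuilding dataset objects; :func:`logrank_test` is the dataset-level
    wrapper.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    experimental = np.asarray(experimental, dtype=bool)
    if experimental.all() or (~experimental).all():
        raise ValueError("log-rank test requires both arms non-empty")

    if not event.any():
        return LogRankResult(0.0, 1.0, 0.0, 0.0, 0, degenerate=True)

    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    e_sorted = event[order]
    x_sorted = experimental[order]

    event_times = np.unique(t_sorted[e_sorted])
    # at risk at t: subjects with observed time >= t
    n_total = len(t_sorted)
    # counts of subjects leaving before each event time via searchsorted
    idx = np.searchsorted(t_sorted, event_times, side="left")
    n_at_risk = n_total - idx
    cum_exp = np.concatenate(([0], np.cumsum(x_sorted)))
    n1_at_risk = x_sorted.sum() - cum_exp[idx]

    # events at exactly each event time, overall and in the experimental arm
    d_total = np.zeros(len(event_times))
    d1 = np.zeros(len(event_times))
    ev_t = t_sorted[e_sorted]
    ev_x = x_sorted[e_sorted]
    pos = np.searchsorted(event_times, ev_t)
    np.add.at(d_total, pos, 1.0)
    np.add.at(d1, pos, ev_x.astype(float))

    n = n_at_risk.astype(float)
    n1 = n1_at_risk.astype(float)
    frac = n1 / n
    o_minus_e = float(np.sum(d1 - d_total * frac))
    with np.errstate(divide="ignore", invalid="ignore"):
        var_terms = d_total * frac * (1.0 - frac) * (n - d_total) / (n - 1.0)
    var_terms = np.where(n > 1.0, var_terms, 0.0)  # 0/0 -> 0 when n_t == 1
    variance = float(np.sum(var_terms))

    observed = float(np.sum(d1))
    expected = float(np.sum(d_total * frac))

    if variance <= 0.0:
        if abs(o_minus_e) > 1e-9:
            raise ArithmeticError(
                "log-rank variance is zero while O - E is "
                f"{o_minus_e:.3g}; inconsistent risk-set accounting"
            )
        return LogRankResult(
            0.0, 1.0, observed, expected, 0, degenerate=True
        )

    statistic = o_minus_e**2 / variance
    p_value = float(stats.chi2.sf(statistic, df=1))
    direction = int(np.sign(o_minus_e))
    return LogRankResult(statistic, p_value, observed, expected, direction)


def logrank_test(dataset: SurvivalDataset) -> LogRankResult:
    """Two-sided unstratified log-rank test on a two-arm dataset."""
    dataset.validate_two_arm()
    time, event, experimental = dataset.to_arrays()
    return logrank_arrays(time, event, experimental)
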