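"""Comparator fragility measure based on artificial average patients.

Johnson-style fragility for survival data: artificial patients with an
event at the mean exposure time of all original subjects are appended to
the experimental arm, one at a time, until the two-sided log-rank test is
no longer significant. The measure is only defined when the original
comparison is significant; for non-significant comparisons the value is
reported as missing rather than raised, matching its inability to express
negative fragility.

The mean exposure time is the arithmetic mean of the observed times of all
subjects in both arms, events and censored alike, computed once from the
original data and never updated as artificial patients accumulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from sifi.logrank import logrank_test
from sifi.survival_data import EXPERIMENTAL, SurvivalDataset, SurvivalRecord


@dataclass
class JohnsonResult:
    """Fragility count, the mean exposure used, and the p trajectory.

    ``value`` is None for comparisons that start non-significant.
    ``p_trajectory[0]`` is the original p value; subsequent entries follow
    each appended artificial patient.
    """

    value: int | None
    mean_exposure: float
    p_trajectory: list[float] = field(default_factory=list)
    exhausted: bool = False


def johnson_fragility(
    dataset: SurvivalDataset,
    alpha: float = 0.05,
    max_iterations: int | None = None,
) -> JohnsonResult:
    """Append mean-exposure event patients to the experimental arm until p >= alpha.

    ``max_iterations`` defaults to ten times the original subject count;
    exceeding it sets ``exhausted`` instead of raising so batch summaries
    can proceed.
    """
    dataset.validate_two_arm()
    mean_exposure = sum(r.time for r in dataset.records) / len(dataset)
    p0 = logrank_test(dataset).p_value
    trajectory = [p0]
    if p0 >= alpha:
        return JohnsonResult(
            value=None, mean_exposure=mean_exposure, p_trajectory=trajectory
        )

    cap = max_iterations if max_iterations is not None else 10 * len(dataset)
    work = dataset.copy()
    artificial = SurvivalRecord(mean_exposure, True, EXPERIMENTAL)
    for k in range(1, cap + 1):
        work.records.append(artificial)
        p = logrank_test(work).p_value
        trajectory.append(p)
        if p >= alpha:
            return JohnsonResult(
                value=k, mean_exposure=mean_exposure, p_trajectory=trajectory
            )
    return JohnsonResult(
        value=cap,
        mean_exposure=mean_exposure,
        p_trajectory=trajectory,
        exhausted=True,
    )
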