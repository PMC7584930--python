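"""The survival-inferred fragility index (SIFI).

The SIFI of a two-arm survival comparison is the minimum number of moves of
extreme subjects between arms that carries the two-sided log-rank p value
across the significance threshold alpha. A comparison that starts
significant (p < alpha) receives a positive value: extreme subjects are
moved in the direction that erodes the experimental arm's apparent
advantage until p >= alpha. A comparison that starts non-significant
receives a negative value: the mirror-image moves are applied until
p < alpha. The magnitude is the iteration count at the first crossing.

Four variants are provided:

``flip_best``
    Reassign the best survivor (longest follow-up, event or censored) of
    the experimental arm to the control arm. This is the default and, on
    published trials, typically the smallest-magnitude variant.
``flip_worst``
    Reassign the worst survivor (earliest event) of the control arm to the
    experimental arm, degrading the experimental arm's relative standing.
``clone_best``
    Append a copy of the experimental arm's best survivor to the control
    arm (the original is retained).
``clone_worst``
    Append a copy of the control arm's worst survivor to the experimental
    arm.

For negative (non-significant) comparisons the donor and recipient arms of
each variant are swapped so each variant moves the comparison toward
significance. Each iteration re-selects the extreme subject on the
already-modified data, so the procedure is fully deterministic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from sifi.logrank import logrank_test
from sifi.survival_data import (
    CONTROL,
    EXPERIMENTAL,
    DataValidationError,
    SurvivalDataset,
    SurvivalRecord,
    other_arm,
    relabel,
)


class Variant(str, enum.Enum):
    """The four SIFI move rules."""

    FLIP_BEST = "flip_best"
    FLIP_WORST = "flip_worst"
    CLONE_BEST = "clone_best"
    CLONE_WORST = "clone_worst"

    @property
    def is_clone(self) -> bool:
        return self in (Variant.CLONE_BEST, Variant.CLONE_WORST)

    @property
    def uses_best(self) -> bool:
        return self in (Variant.FLIP_BEST, Variant.CLONE_BEST)


@dataclass(frozen=True)
class SIFIConfig:
    """Settings for one SIFI computation.

    alpha
        Two-sided significance threshold; "significant" means p < alpha
        strictly, so significance is lost at the first p >= alpha.
    variant
        Which move rule to apply (see module docstring).
    max_iterations
        Cap on the number of moves; defaults to the total subject count.
    literal_directions
        When True, ``flip_worst`` moves the worst survivor of the
        experimental arm to the control arm for positive comparisons
        (mirrored when negative) instead of the default control-to-
        experimental direction. The default direction is the one that
        pushes the test toward the stopping threshold.
    """

    alpha: float = 0.05
    variant: Variant = Variant.FLIP_BEST
    max_iterations: int | None = None
    literal_directions: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.max_iterations is not None and self.max_iterations < 1:
            raise ValueError("max_iterations must be a positive integer")


@dataclass
class SIFIResult:
    """A signed fragility value with its p-value trajectory.

    ``value`` is +k when the initially significant comparison first loses
    significance after k moves, and -k when the initially non-significant
    comparison first gains it. ``p_trajectory[0]`` is the p value of the
    unmodified data and ``p_trajectory[i]`` the p value after i moves, so a
    completed run has ``len(p_trajectory) == abs(value) + 1``. ``exhausted``
    flags runs that ran out of eligible donors or hit the iteration cap
    before crossing; only then may ``value`` be 0 (no move was possible).
    """

    value: int
    variant: Variant
    p_initial: float
    p_trajectory: list[float] = field(default_factory=list)
    exhausted: bool = False

    @property
    def p_final(self) -> float:
        return self.p_trajectory[-1]


def best_survivor_index(dataset: SurvivalDataset, arm: str) -> int:
    """Index of the arm's subject with the longest follow-up time.

    The best survivor is defined by follow-up time alone, whether the
    record ends in an event or in censoring. Ties at the maximum time are
    broken in favour of censored records (a censored subject at t is at
    least as good a survivor as one who died at t), then by the lowest
    original record position.
    """
    best = -1
    for i in dataset.arm_indices(arm):
        r = dataset.records[i]
        if best < 0:
            best = i
            continue
        b = dataset.records[best]
        if r.time > b.time or (r.time == b.time and not r.event and b.event):
            best = i
    if best < 0:
        raise DataValidationError(f"arm {arm!r} is empty; no best survivor")
    return best


def worst_survivor_index(dataset: SurvivalDataset, arm: str) -> int:
    """Index of the arm's earliest event (not merely earliest time).

    Censored records are never worst survivors; an arm with no events has
    no worst survivor and raises.
    """
    worst = -1
    for i in dataset.arm_indices(arm):
        r = dataset.records[i]
        if not r.event:
            continue
        if worst < 0 or r.time < dataset.records[worst].time:
            worst = i
    if worst < 0:
        raise DataValidationError(
            f"arm {arm!r} has no events; worst survivor undefined"
        )
    return worst


def _donor_arm(variant: Variant, positive: bool, literal: bool) -> str:
    """Arm the moved/cloned subject is selected from.

    For positive comparisons (significance to be lost): best-survivor
    variants draw from the experimental arm, worst-survivor variants from
    the control arm — each move worsens the experimental arm's relative
    performance. ``literal`` switches flip_worst to draw from the
    experimental arm instead. Negative comparisons mirror everything.
    """
    if variant.uses_best:
        donor = EXPERIMENTAL
    elif variant is Variant.FLIP_WORST and literal:
        donor = EXPERIMENTAL
    else:
        donor = CONTROL
    return donor if positive else other_arm(donor)


def _select(dataset: SurvivalDataset, variant: Variant, donor: str,
            skip: set[int]) -> int | None:
    """Pick the donor-arm extreme subject, ignoring indices in ``skip``."""
    candidates = [
        i for i in dataset.arm_indices(donor) if i not in skip
    ]
    if not candidates:
        return None
    sub = SurvivalDataset(records=dataset.records)  # shared list, same indices
    best: int | None = None
    if variant.uses_best:
        for i in candidates:
            r = sub.records[i]
            if best is None:
                best = i
                continue
            b = sub.records[best]
            if r.time > b.time or (
                r.time == b.time and not r.event and b.event
            ):
                best = i
    else:
        for i in candidates:
            r = sub.records[i]
            if not r.event:
                continue
            if best is None or r.time < sub.records[best].time:
                best = i
    return best


def apply_move(
    dataset: SurvivalDataset,
    variant: Variant,
    donor: str,
    skip: set[int],
) -> bool:
    """Apply one move in place. Returns False when no eligible donor exists.

    Flip variants relabel the selected record; clone variants append a
    copy to the opposite arm, retain the original, and add the original's
    index to ``skip`` so no subject is cloned twice.
    """
    if not variant.is_clone and len(dataset.arm_indices(donor)) <= 1:
        # flipping the donor arm's last subject would leave it empty and
        # the comparison untestable; report exhaustion instead
        return False
    idx = _select(dataset, variant, donor, skip)
    if idx is None:
        return False
    record: SurvivalRecord = dataset.records[idx]
    recipient = other_arm(donor)
    if variant.is_clone:
        dataset.records.append(relabel(record, recipient))
        skip.add(idx)
    else:
        dataset.records[idx] = relabel(record, recipient)
    return True


def compute_sifi(
    dataset: SurvivalDataset, config: SIFIConfig | None = None
) -> SIFIResult:
    """Compute the SIFI of a two-arm dataset under one variant.

    The input dataset is not modified. See the module docstring for the
    semantics of the four variants and of the sign.
    """
    cfg = config or SIFIConfig()
    dataset.validate_two_arm()
    work = dataset.copy()
    p0 = logrank_test(work).p_value
    positive = p0 < cfg.alpha
    sign = 1 if positive else -1

    def crossed(p: float) -> bool:
        return (p >= cfg.alpha) if positive else (p < cfg.alpha)

    donor = _donor_arm(cfg.variant, positive, cfg.literal_directions)
    cap = cfg.max_iterations or len(dataset)
    trajectory = [p0]
    skip: set[int] = set()

    k = 0
    while k < cap:
        if not apply_move(work, cfg.variant, donor, skip):
            return SIFIResult(
                value=sign * k,
                variant=cfg.variant,
                p_initial=p0,
                p_trajectory=trajectory,
                exhausted=True,
            )
        k += 1
        p = logrank_test(work).p_value
        trajectory.append(p)
        if crossed(p):
            return SIFIResult(
                value=sign * k,
                variant=cfg.variant,
                p_initial=p0,
                p_trajectory=trajectory,
            )
    return SIFIResult(
        value=sign * k,
        variant=cfg.variant,
        p_initial=p0,
        p_trajectory=trajectory,
        exhausted=True,
    )


def sifi_all_variants(
    dataset: SurvivalDataset,
    alpha: float = 0.05,
    max_iterations: int | None = None,
) -> dict[Variant, SIFIResult]:
    """Compute all four SIFI variants independently from the same dataset."""
    return {
        v: compute_sifi(
            dataset,
            SIFIConfig(alpha=alpha, variant=v, max_iterations=max_iterations),
        )
        for v in Variant
    }
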