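"""Reconstruct individual patient data from digitized Kaplan-Meier curves.

Published survival figures show a step curve per arm plus a number-at-risk
table at a handful of checkpoint times. Given those two ingredients this
module inverts the KM estimator: within each inter-checkpoint interval it
solves iteratively for the event and censoring counts that reproduce both
the digitized survival drops and the next checkpoint's at-risk count (the
inversion scheme introduced by Guyot and co-workers). Censoring within an
interval is spread uniformly across it unless a total-event anchor pins it
down. The output is one record per inferred subject, together with the
discrepancy between the published at-risk counts and the counts implied by
the reconstruction — the same diagnostic used to judge reconstruction
quality for published trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sifi.survival_data import (
    ARMS,
    DataValidationError,
    SurvivalDataset,
    SurvivalRecord,
)

logger = logging.getLogger(__name__)

_MAX_ADJUST = 60  # iterations of censor-count adjustment per interval


@dataclass(frozen=True)
class KMCurve:
    """Digitized step-curve coordinates, one (time, survival) series per arm."""

    arms: dict[str, tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        for arm, (t, s) in self.arms.items():
            t = np.asarray(t, dtype=float)
            s = np.asarray(s, dtype=float)
            if len(t) != len(s) or len(t) < 2:
                raise DataValidationError(
                    f"arm {arm!r}: need >= 2 matched (time, survival) points"
                )
            if np.any(np.diff(t) < 0):
                raise DataValidationError(f"arm {arm!r}: times must be nondecreasing")
            if np.any(s < -1e-9) or np.any(s > 1 + 1e-9):
                raise DataValidationError(f"arm {arm!r}: survival outside [0, 1]")
            if np.any(np.diff(s) > 1e-8):
                raise DataValidationError(f"arm {arm!r}: survival must not rise")
            self.arms[arm] = (t, np.clip(s, 0.0, 1.0))

    @classmethod
    def read_csv(cls, path: str) -> "KMCurve":
        """Read a ``arm,time,survival`` CSV (one row per digitized point)."""
        df = pd.read_csv(path)
        for col in ("arm", "time", "survival"):
            if col not in df.columns:
                raise DataValidationError(f"{path}: missing column {col!r}")
        arms = {
            str(arm): (
                grp["time"].to_numpy(float),
                grp["survival"].to_numpy(float),
            )
            for arm, grp in df.groupby("arm", sort=False)
        }
        return cls(arms=arms)


@dataclass(frozen=True)
class AtRiskTable:
    """Checkpoint times and published number-at-risk counts per arm."""

    arms: dict[str, tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        for arm, (t, n) in self.arms.items():
            t = np.asarray(t, dtype=float)
            n = np.asarray(n)
            if len(t) != len(n) or len(t) < 2:
                raise DataValidationError(
                    f"arm {arm!r}: need >= 2 at-risk checkpoints"
                )
            if np.any(n < 0) or np.any(n != np.floor(n)):
                raise DataValidationError(
                    f"arm {arm!r}: at-risk counts must be nonnegative integers"
                )
            if np.any(np.diff(t) <= 0):
                raise DataValidationError(f"arm {arm!r}: checkpoint times must increase")
            if np.any(np.diff(n) > 0):
                raise DataValidationError(f"arm {arm!r}: at-risk counts must not rise")
            self.arms[arm] = (t, n.astype(int))

    @classmethod
    def read_csv(cls, path: str) -> "AtRiskTable":
        """Read a ``arm,time,n_risk`` CSV."""
        df = pd.read_csv(path)
        for col in ("arm", "time", "n_risk"):
            if col not in df.columns:
                raise DataValidationError(f"{path}: missing column {col!r}")
        arms = {
            str(arm): (
                grp["time"].to_numpy(float),
                grp["n_risk"].to_numpy(int),
            )
            for arm, grp in df.groupby("arm", sort=False)
        }
        return cls(arms=arms)


@dataclass
class ReconstructionReport:
    """Reconstructed IPD plus the at-risk agreement diagnostic.

    ``atrisk_discrepancy`` maps each arm to per-checkpoint (time,
    |published - reproduced|) pairs; ``median_discrepancy`` and
    ``iqr_discrepancy`` summarize the nonzero entries (NaN when every
    checkpoint agrees exactly).
    """

    dataset: SurvivalDataset
    atrisk_discrepancy: dict[str, list[tuple[float, int]]]
    median_discrepancy: float
    iqr_discrepancy: tuple[float, float]
    warnings: list[str] = field(default_factory=list)

    def all_discrepancies(self) -> list[int]:
        return [d for pairs in self.atrisk_discrepancy.values() for _, d in pairs]


def _prepend_origin(t: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if t[0] != 0.0 or s[0] != 1.0:
        if s[0] > 1.0 - 1e-9 and t[0] > 0.0:
            t = np.concatenate(([0.0], t))
            s = np.concatenate(([1.0], s))
        elif t[0] != 0.0 or abs(s[0] - 1.0) > 1e-9:
            raise DataValidationError(
                "curve must start at survival 1 (time 0); "
                f"got S({t[0]}) = {s[0]}"
            )
    return t, s


def _place_censors(n_cens: int, start: float, end: float) -> np.ndarray:
    """Censor times spread uniformly over the open interval (start, end)."""
    if n_cens <= 0:
        return np.empty(0)
    j = np.arange(1, n_cens + 1, dtype=float)
    return start + j * (end - start) / (n_cens + 1)


def _interval_pass(
    t: np.ndarray,
    s: np.ndarray,
    lo: int,
    hi: int,
    n_start: float,
    km_start: float,
    cen_times: np.ndarray,
    interval_end: float,
    is_first: bool,
) -> tuple[np.ndarray, float, float]:
    """One forward pass over clicks lo..hi: infer events per click.

    Returns (events per click, n remaining after the interval, KM value at
    the last event so far). ``km_start`` is the running KM product at the
    last event before this interval.
    """
    d = np.zeros(hi - lo + 1, dtype=int)
    # censorings binned by click slot: slot j spans [t[lo+j], t[lo+j+1])
    # within the interval; times before the first click join slot 0
    cen_per_slot = np.zeros(hi - lo + 1, dtype=int)
    if len(cen_times):
        slots = np.searchsorted(t[lo : hi + 1], cen_times, side="right") - 1
        slots = np.clip(slots, 0, hi - lo)
        np.add.at(cen_per_slot, slots, 1)

    n_hat = n_start
    km_last = km_start
    for j, k in enumerate(range(lo, hi + 1)):
        if is_first and k == 0:
            d[j] = 0
        elif n_hat > 0 and km_last > 0:
            d[j] = int(round(n_hat * (1.0 - s[k] / km_last)))
            d[j] = max(0, min(d[j], int(round(n_hat))))
            if d[j] > 0:
                km_last = km_last * (1.0 - d[j] / n_hat)
        else:
            d[j] = 0
        n_hat = n_hat - d[j] - cen_per_slot[j]
    return d, n_hat, km_last


def _reconstruct_arm(
    t: np.ndarray,
    s: np.ndarray,
    trisk: np.ndarray,
    nrisk: np.ndarray,
    total_events: int | None,
    warnings_out: list[str],
    arm_name: str,
) -> list[tuple[float, bool]]:
    """Guyot-class inversion of one arm. Returns (time, event) tuples."""
    t, s = _prepend_origin(np.asarray(t, float), np.asarray(s, float))
    K = len(t)
    I = len(trisk)
    if trisk[0] != 0.0:
        raise DataValidationError(
            f"arm {arm_name!r}: first at-risk checkpoint must be at time 0"
        )
    # click-index bounds per interval
    lower = np.searchsorted(t, trisk, side="left")
    upper = np.empty(I, dtype=int)
    upper[:-1] = np.searchsorted(t, trisk[1:], side="left") - 1
    upper[-1] = K - 1

    events: list[float] = []
    censors: list[float] = []
    n_carry = float(nrisk[0])
    km_carry = 1.0
    total_cens_so_far = 0

    for i in range(I - 1):
        lo, hi = int(lower[i]), int(upper[i])
        target = int(nrisk[i + 1])
        interval_end = float(trisk[i + 1])
        if hi < lo:
            # no digitized clicks inside the interval: all attrition between
            # the checkpoints must be censoring
            n_cens = max(0, int(round(n_carry)) - target)
            censors.extend(_place_censors(n_cens, trisk[i], interval_end))
            total_cens_so_far += n_cens
            n_carry -= n_cens
            continue
        s_lo = s[lo]
        s_next = s[int(lower[i + 1])] if lower[i + 1] < K else s[-1]
        n_cens = int(round(n_carry * s_next / s_lo)) - target if s_lo > 0 else 0
        best = None  # (abs gap, n_cens, d, n_end, km_end, cen_times)
        for _ in range(_MAX_ADJUST):
            n_cens = max(0, n_cens)
            cen_times = _place_censors(n_cens, trisk[i], interval_end)
            d, n_end, km_end = _interval_pass(
                t, s, lo, hi, n_carry, km_carry, cen_times, interval_end,
                is_first=(i == 0),
            )
            gap = n_end - target
            if best is None or abs(gap) < best[0]:
                best = (abs(gap), n_cens, d, n_end, km_end, cen_times)
            if gap == 0 or (gap < 0 and n_cens == 0):
                break
            n_cens += int(gap)
        else:
            warnings_out.append(
                f"arm {arm_name!r}: interval {i} did not settle; "
                "best-fit allocation used"
            )
        _, n_cens, d, n_end, km_end, cen_times = best
        for j, k in enumerate(range(lo, hi + 1)):
            events.extend([t[k]] * int(d[j]))
        censors.extend(cen_times)
        total_cens_so_far += n_cens
        n_carry = n_end
        km_carry = km_end

    # last interval: no at-risk anchor beyond its start. Without a
    # total-event anchor, censoring is assumed to continue at the average
    # rate observed over the preceding follow-up.
    lo, hi = int(lower[-1]), int(upper[-1])
    span_prev = trisk[-1] - trisk[0]
    t_end = max(t[-1], trisk[-1])
    if hi >= lo:
        if span_prev > 0:
            n_cens = int(round(total_cens_so_far * (t_end - trisk[-1]) / span_prev))
        else:
            n_cens = 0
        n_cens = int(min(max(n_cens, 0), n_carry))
        for _ in range(_MAX_ADJUST):
            cen_times = _place_censors(n_cens, trisk[-1], t_end)
            d, n_end, km_end = _interval_pass(
                t, s, lo, hi, n_carry, km_carry, cen_times, t_end,
                is_first=(I == 1),
            )
            if total_events is None:
                break
            gap = (len(events) + int(d.sum())) - total_events
            if gap == 0 or (gap > 0 and n_cens >= int(n_carry)) or (
                gap < 0 and n_cens == 0
            ):
                break
            n_cens = int(min(max(n_cens + gap, 0), n_carry))
        else:
            warnings_out.append(
                f"arm {arm_name!r}: could not match total event count"
            )
        for j, k in enumerate(range(lo, hi + 1)):
            events.extend([t[k]] * int(d[j]))
        censors.extend(cen_times)
        n_carry = n_end

    # subjects still at risk after the last click are censored there
    if n_carry > 0:
        censors.extend([float(t_end)] * int(round(n_carry)))

    return [(float(x), True) for x in events] + [
        (float(x), False) for x in censors
    ]


def reconstruct_ipd(
    curve: KMCurve,
    at_risk: AtRiskTable,
    total_events: dict[str, int] | None = None,
) -> ReconstructionReport:
    """Invert digitized KM curves plus at-risk tables into per-subject data.

    ``total_events`` optionally anchors the last (un-anchored) interval of
    each arm with the published per-arm event count. Arms are matched by
    label between ``curve`` and ``at_risk``; labels must be the canonical
    ``experimental`` / ``control`` pair.
    """
    if set(curve.arms) != set(at_risk.arms):
        raise DataValidationError(
            f"curve arms {sorted(curve.arms)} != at-risk arms {sorted(at_risk.arms)}"
        )
    if not set(curve.arms) <= set(ARMS):
        raise DataValidationError(
            f"arm labels must be {ARMS}, got {sorted(curve.arms)}"
        )

    warnings_out: list[str] = []
    records: list[SurvivalRecord] = []
    discrepancy: dict[str, list[tuple[float, int]]] = {}
    for arm in curve.arms:
        t, s = curve.arms[arm]
        trisk, nrisk = at_risk.arms[arm]
        tot = total_events.get(arm) if total_events else None
        pairs = _reconstruct_arm(t, s, trisk, nrisk, tot, warnings_out, arm)
        pairs.sort(key=lambda p: (p[0], p[1]))
        records.extend(SurvivalRecord(tm, ev, arm) for tm, ev in pairs)
        times = np.array([p[0] for p in pairs])
        reproduced = [(float(ct), int(np.sum(times >= ct))) for ct in trisk]
        discrepancy[arm] = [
            (float(ct), int(abs(int(nr) - rep)))
            for (ct, rep), nr in zip(reproduced, nrisk)
        ]

    nonzero = [d for pairs in discrepancy.values() for _, d in pairs if d > 0]
    if nonzero:
        med = float(np.median(nonzero))
        iqr = (
            float(np.percentile(nonzero, 25)),
            float(np.percentile(nonzero, 75)),
        )
    else:
        med, iqr = float("nan"), (float("nan"), float("nan"))

    for w in warnings_out:
        logger.warning("%s", w)

    return ReconstructionReport(
        dataset=SurvivalDataset(records=records, label="reconstructed"),
        atrisk_discrepancy=discrepancy,
        median_discrepancy=med,
        iqr_discrepancy=iqr,
        warnings=warnings_out,
    )


def km_step_function(
    dataset: SurvivalDataset, arm: str, grid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Kaplan-Meier survival estimate for one arm, optionally on a grid.

    Returns (times, survival). With ``grid`` given, the step function is
    evaluated at those times; otherwise the native step times (prefixed
    with time 0) are returned. Used by the round-trip tests that digitize
    a simulated trial and reconstruct it.
    """
    from lifelines import KaplanMeierFitter

    idx = dataset.arm_indices(arm)
    if not idx:
        raise DataValidationError(f"arm {arm!r} is empty")
    times = np.array([dataset.records[i].time for i in idx])
    events = np.array([dataset.records[i].event for i in idx])
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    if grid is not None:
        grid = np.asarray(grid, dtype=float)
        surv = kmf.survival_function_at_times(grid).to_numpy()
        return grid, surv
    sf = kmf.survival_function_
    return sf.index.to_numpy(float), sf.iloc[:, 0].to_numpy(float)
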