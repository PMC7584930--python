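"""Domain types for two-arm time-to-event data and delimited-text I/O.

A :class:`SurvivalDataset` is the container every other module consumes:
one record per subject, holding the observed follow-up time, whether the
record ends in an event (death) or censoring, and the assigned arm.
Arms are canonicalised to the labels ``"experimental"`` and ``"control"``;
:class:`ColumnMap` maps trial-specific file labels onto them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EXPERIMENTAL = "experimental"
CONTROL = "control"
ARMS = (EXPERIMENTAL, CONTROL)

_TRUTHY = {"1", "true", "t", "yes"}
_FALSY = {"0", "false", "f", "no"}


class DataFormatError(ValueError):
    """A file does not have the expected columns or value formats."""


class DataValidationError(ValueError):
    """Parsed data violates a domain invariant (e.g. negative time)."""


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject: follow-up time, event indicator, and arm.

    ``event`` is ``True`` when the record ends in an observed event and
    ``False`` when the subject was censored. ``time`` is in the time unit
    of the source data (months for the published trials).
    """

    time: float
    event: bool
    arm: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time < 0:
            raise DataValidationError(
                f"follow-up time must be finite and >= 0, got {self.time!r}"
            )
        if self.arm not in ARMS:
            raise DataValidationError(
                f"arm must be one of {ARMS}, got {self.arm!r}"
            )


@dataclass
class SurvivalDataset:
    """Ordered collection of :class:`SurvivalRecord` for a two-arm trial.

    Record order is part of the state: deterministic tie-breaking in the
    fragility algorithms refers to original record positions.
    """

    records: list[SurvivalRecord] = field(default_factory=list)
    label: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SurvivalRecord]:
        return iter(self.records)

    @classmethod
    def from_arrays(
        cls,
        time: Sequence[float],
        event: Sequence[bool],
        arm: Sequence[str],
        label: str = "",
    ) -> "SurvivalDataset":
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=bool)
        arm = np.asarray(arm, dtype=object)
        if not (len(time) == len(event) == len(arm)):
            raise DataValidationError("time, event and arm must have equal length")
        records = [
            SurvivalRecord(float(t), bool(e), str(a))
            for t, e, a in zip(time, event, arm)
        ]
        return cls(records=records, label=label)

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (time, event, is_experimental) numpy arrays."""
        n = len(self.records)
        time = np.empty(n, dtype=float)
        event = np.empty(n, dtype=bool)
        exp = np.empty(n, dtype=bool)
        for i, r in enumerate(self.records):
            time[i] = r.time
            event[i] = r.event
            exp[i] = r.arm == EXPERIMENTAL
        return time, event, exp

    def arm_indices(self, arm: str) -> list[int]:
        if arm not in ARMS:
            raise DataValidationError(f"unknown arm {arm!r}")
        return [i for i, r in enumerate(self.records) if r.arm == arm]

    def arm_size(self, arm: str) -> int:
        return len(self.arm_indices(arm))

    def n_events(self, arm: str | None = None) -> int:
        return sum(
            1
            for r in self.records
            if r.event and (arm is None or r.arm == arm)
        )

    def max_time(self) -> float:
        if not self.records:
            raise DataValidationError("empty dataset has no maximum time")
        return max(r.time for r in self.records)

    def copy(self) -> "SurvivalDataset":
        # records are frozen, a shallow list copy suffices
        return SurvivalDataset(records=list(self.records), label=self.label)

    def validate_two_arm(self) -> None:
        """Raise unless both arms are non-empty (required for testing)."""
        for arm in ARMS:
            if self.arm_size(arm) == 0:
                raise DataValidationError(
                    f"arm {arm!r} is empty; two-arm operations need both arms"
                )


@dataclass(frozen=True)
class ColumnMap:
    """How to read an IPD file: column names and arm-label mapping.

    ``experimental_label`` names the arm value mapped to the experimental
    arm; every other (single) distinct value maps to control. Leave it as
    the default when the file already uses ``experimental``/``control``.
    """

    time: str = "time"
    event: str = "event"
    arm: str = "arm"
    experimental_label: str = EXPERIMENTAL
    control_label: str | None = None


def _parse_event(value: object, row: int) -> bool:
    text = str(value).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise DataFormatError(
        f"row {row}: cannot parse event indicator {value!r} "
        "(expected 0/1/true/false)"
    )


def read_ipd(path: str, column_map: ColumnMap | None = None) -> SurvivalDataset:
    """Read a delimited IPD file into a :class:`SurvivalDataset`.

    The file must be CSV with a header containing the time, event and arm
    columns named in ``column_map`` (defaults ``time,event,arm``). Rows are
    numbered from 1 (excluding the header) in error messages.
    """
    cmap = column_map or ColumnMap()
    df = pd.read_csv(path, float_precision="round_trip")
    for col in (cmap.time, cmap.event, cmap.arm):
        if col not in df.columns:
            raise DataFormatError(
                f"{path}: missing required column {col!r} "
                f"(found {list(df.columns)})"
            )

    raw_arms = df[cmap.arm].astype(str).str.strip()
    labels = sorted(raw_arms.unique())
    if len(labels) > 2:
        raise DataFormatError(
            f"{path}: more than two arm labels found: {labels}; "
            "two-arm data required"
        )
    mapping: dict[str, str] = {}
    if cmap.experimental_label in labels:
        mapping[cmap.experimental_label] = EXPERIMENTAL
        others = [l for l in labels if l != cmap.experimental_label]
    elif set(labels) <= {EXPERIMENTAL, CONTROL}:
        mapping = {l: l for l in labels}
        others = []
    else:
        raise DataFormatError(
            f"{path}: experimental arm label {cmap.experimental_label!r} "
            f"not found among {labels}; configure ColumnMap"
        )
    if others:
        if cmap.control_label is not None and cmap.control_label != others[0]:
            raise DataFormatError(
                f"{path}: control label {cmap.control_label!r} does not "
                f"match remaining arm label {others[0]!r}"
            )
        mapping[others[0]] = CONTROL

    times = pd.to_numeric(df[cmap.time], errors="coerce")
    bad_time = [
        i + 1
        for i, t in enumerate(times)
        if not np.isfinite(t) or t < 0
    ]
    if bad_time:
        raise DataValidationError(
            f"{path}: non-finite or negative times in rows {bad_time}"
        )

    records = []
    for i, (t, e, a) in enumerate(zip(times, df[cmap.event], raw_arms)):
        records.append(
            SurvivalRecord(float(t), _parse_event(e, i + 1), mapping[a])
        )
    return SurvivalDataset(records=records, label=str(path))


def write_ipd(dataset: SurvivalDataset, path: str) -> None:
    """Write a dataset as CSV ``time,event,arm`` at full float precision."""
    for arm in ARMS:
        if dataset.arm_size(arm) == 0:
            logger.warning("writing dataset with empty %s arm to %s", arm, path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("time,event,arm\n")
        for r in dataset.records:
            fh.write(f"{r.time!r},{int(r.event)},{r.arm}\n")


def relabel(record: SurvivalRecord, arm: str) -> SurvivalRecord:
    """Return a copy of ``record`` assigned to ``arm``."""
    return replace(record, arm=arm)


def other_arm(arm: str) -> str:
    if arm == EXPERIMENTAL:
        return CONTROL
    if arm == CONTROL:
        return EXPERIMENTAL
    raise DataValidationError(f"unknown arm {arm!r}")
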