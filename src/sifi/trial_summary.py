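"""Aggregate fragility results across a table of published trials.

The package ships a transcription of the published per-trial table for 45
phase-3 immune-checkpoint-inhibitor trials (49 two-arm comparisons: four
trials contributed two comparisons each). :func:`summarize` reproduces the
aggregate statistics reported over that table — medians and interquartile
ranges of sample size and SIFI, the share of significant comparisons, the
count of comparisons whose fragility is under 1% of the sample size, the
SIFI/log-p correlation, and per-drug-class trial counts.

Quantiles use linear interpolation between order statistics (numpy's
default), the convention under which the table's printed medians and IQRs
are recovered exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from sifi.logrank import logrank_test
from sifi.sifi_core import SIFIConfig, SIFIResult, Variant, compute_sifi
from sifi.survival_data import DataValidationError, SurvivalDataset

DRUG_CLASSES = ("anti-CTLA-4", "anti-PD-1", "anti-PD-L1", "combination")


@dataclass(frozen=True)
class TrialRow:
    """One published comparison: trial, class, n, HR, printed p, SIFI.

    ``p_is_bound`` marks p values printed as upper bounds ("<.0001"); for
    those rows ``p`` stores the bound itself and the row is excluded from
    the p-value correlation.
    """

    trial: str
    drug_class: str
    n: int
    hr: float
    p: float
    sifi: int
    p_is_bound: bool = False
    tumor: str = ""
    year: int = 0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise DataValidationError(f"{self.trial}: sample size must be > 0")
        if self.sifi == 0:
            raise DataValidationError(f"{self.trial}: SIFI is never 0")
        if self.drug_class not in DRUG_CLASSES:
            raise DataValidationError(
                f"{self.trial}: unknown drug class {self.drug_class!r}"
            )
        if not self.p_is_bound and (
            (self.p < 0.05) != (self.sifi > 0)
        ):
            raise DataValidationError(
                f"{self.trial}: SIFI sign inconsistent with p = {self.p}"
            )


@dataclass
class SummaryReport:
    """Aggregates over a trial table; quantiles are (q25, q50, q75)."""

    n_rows: int
    median_sifi: float
    iqr_sifi: tuple[float, float]
    median_abs_sifi: float
    iqr_abs_sifi: tuple[float, float]
    median_n: float
    iqr_n: tuple[float, float]
    n_significant: int
    pct_significant: float
    count_below_1pct: int
    correlation_log_p: float
    class_counts: dict[str, int]


def load_table1() -> list[TrialRow]:
    """Load the packaged 49-row transcription of the published trial table."""
    with resources.files("sifi.data").joinpath("table1.csv").open("r") as fh:
        df = pd.read_csv(fh)
    return [
        TrialRow(
            trial=r.trial,
            drug_class=r.drug_class,
            tumor=r.tumor,
            year=int(r.year),
            n=int(r.n),
            hr=float(r.hr),
            p=float(r.p),
            p_is_bound=bool(r.p_is_bound),
            sifi=int(r.sifi),
        )
        for r in df.itertuples()
    ]


def _quantiles(values: np.ndarray) -> tuple[float, tuple[float, float]]:
    med = float(np.percentile(values, 50))
    return med, (float(np.percentile(values, 25)), float(np.percentile(values, 75)))


def summarize(table: list[TrialRow]) -> SummaryReport:
    """Compute the printed aggregate statistics over a trial table.

    A bound row ("<x") counts as significant when the bound is <= .05.
    ``count_below_1pct`` uses the strict inequality |SIFI| < 0.01 n.
    The Pearson correlation is between SIFI and log10(p) over rows with an
    exactly printed p value.
    """
    if not table:
        raise DataValidationError("cannot summarize an empty trial table")
    sifi = np.array([r.sifi for r in table], dtype=float)
    n = np.array([r.n for r in table], dtype=float)

    median_sifi, iqr_sifi = _quantiles(sifi)
    median_abs, iqr_abs = _quantiles(np.abs(sifi))
    median_n, iqr_n = _quantiles(n)

    significant = [
        (r.p <= 0.05) if r.p_is_bound else (r.p < 0.05) for r in table
    ]
    n_sig = int(sum(significant))
    below = int(sum(abs(r.sifi) < 0.01 * r.n for r in table))

    exact = [(r.sifi, np.log10(r.p)) for r in table if not r.p_is_bound]
    if len(exact) >= 2:
        xs, ys = zip(*exact)
        corr = float(stats.pearsonr(xs, ys).statistic)
    else:
        corr = float("nan")

    counts = {
        cls: len({r.trial for r in table if r.drug_class == cls})
        for cls in DRUG_CLASSES
    }

    return SummaryReport(
        n_rows=len(table),
        median_sifi=median_sifi,
        iqr_sifi=iqr_sifi,
        median_abs_sifi=median_abs,
        iqr_abs_sifi=iqr_abs,
        median_n=median_n,
        iqr_n=iqr_n,
        n_significant=n_sig,
        pct_significant=100.0 * n_sig / len(table),
        count_below_1pct=below,
        correlation_log_p=corr,
        class_counts=counts,
    )


def censored_in_first_ventile(dataset: SurvivalDataset, arm: str) -> int:
    """Subjects of ``arm`` censored within the first 1/20th of follow-up.

    The follow-up span is the maximum observed time over both arms; the
    boundary is inclusive. Comparing this count with the SIFI shows how
    often the fragility is smaller than the early censoring alone.
    """
    if not dataset.records:
        return 0
    boundary = dataset.max_time() / 20.0
    return sum(
        1
        for i in dataset.arm_indices(arm)
        if not dataset.records[i].event
        and dataset.records[i].time <= boundary
    )


@dataclass
class FollowupComparison:
    """flip_best SIFI of the same trial at two follow-up depths."""

    early: SIFIResult
    late: SIFIResult

    @property
    def difference(self) -> int:
        return self.late.value - self.early.value


def compare_followups(
    early: SurvivalDataset, late: SurvivalDataset, alpha: float = 0.05
) -> FollowupComparison:
    """flip_best SIFI for an early and a later data cut of one trial."""
    cfg = SIFIConfig(alpha=alpha, variant=Variant.FLIP_BEST)
    return FollowupComparison(
        early=compute_sifi(early, cfg), late=compute_sifi(late, cfg)
    )


def table_to_frame(table: list[TrialRow]) -> pd.DataFrame:
    """Trial rows as a DataFrame (for export or plotting)."""
    return pd.DataFrame(
        {
            "trial": [r.trial for r in table],
            "drug_class": [r.drug_class for r in table],
            "tumor": [r.tumor for r in table],
            "year": [r.year for r in table],
            "n": [r.n for r in table],
            "hr": [r.hr for r in table],
            "p": [r.p for r in table],
            "p_is_bound": [r.p_is_bound for r in table],
            "sifi": [r.sifi for r in table],
        }
    )


__all__ = [
    "TrialRow",
    "SummaryReport",
    "FollowupComparison",
    "load_table1",
    "summarize",
    "censored_in_first_ventile",
    "compare_followups",
    "table_to_frame",
    "logrank_test",
]
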