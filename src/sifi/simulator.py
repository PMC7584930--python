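"""Weibull two-arm trial simulator and factorial grid runner.

Trials are generated from an accelerated-failure-time Weibull model: for a
subject with arm indicator x (1 = experimental), the latent event time is

    T = exp(-(beta0_event + beta * x)) * E ** (1 / anc_event),  E ~ Exp(1)

i.e. Weibull with shape ``anc_event`` and scale ``exp(-(beta0_event +
beta*x))``, while the latent censoring time is an independent Weibull with
shape ``anc_cens`` and scale ``exp(-beta0_cens)``. The observed time is
min(T, C) with an event iff T <= C. Under this parameterization the model
is proportional-hazards with log hazard ratio ``anc_event * beta``, so the
default grid (beta from -1 to 0.2, shape 1.5) spans theoretical hazard
ratios from about 0.22 to 1.35.

The reference study design is a full factorial over cohort size (100-1200
by 100), censoring shape (2, 4, 6, 8, 10) and effect size (-1 to 0.2 by
0.05) with 10 replicates per cell: 1500 cells, 15 000 simulated trials.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from sifi.logrank import logrank_test
from sifi.sifi_core import SIFIConfig, compute_sifi
from sifi.survival_data import CONTROL, EXPERIMENTAL, SurvivalDataset

logger = logging.getLogger(__name__)

PAPER_COHORT_SIZES: tuple[int, ...] = tuple(range(100, 1300, 100))
PAPER_ANC_CENS: tuple[float, ...] = (2.0, 4.0, 6.0, 8.0, 10.0)
PAPER_BETAS: tuple[float, ...] = tuple(
    round(-1.0 + 0.05 * i, 2) for i in range(25)
)
PAPER_REPS_PER_CELL: int = 10


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of one simulated two-arm trial.

    n is the total cohort size with exact 1:1 allocation (must be even).
    ``beta`` shifts the experimental arm's log time-scale; negative values
    favour the experimental arm (hazard ratio exp(anc_event * beta) < 1).
    ``max_followup`` optionally censors administratively at a fixed time.
    """

    n: int
    beta: float
    seed: int
    anc_event: float = 1.5
    anc_cens: float = 2.0
    beta0_event: float = 2.0
    beta0_cens: float = 2.01
    max_followup: float | None = None

    def __post_init__(self) -> None:
        if self.n < 2 or self.n % 2:
            raise ValueError(f"n must be even and >= 2, got {self.n}")
        if self.anc_event <= 0 or self.anc_cens <= 0:
            raise ValueError("Weibull shape (ancillary) parameters must be > 0")


@dataclass(frozen=True)
class SimResultRow:
    """Outcome of one simulated trial within a grid run."""

    params: SimulationParams
    replicate: int
    hr: float
    pct_censored: float
    p: float
    sifi: int
    exhausted: bool = False


def simulate_dataset(params: SimulationParams) -> SurvivalDataset:
    """Generate one two-arm trial; deterministic given ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    n = params.n
    x = np.zeros(n)
    x[: n // 2] = 1.0  # first half experimental
    scale_event = np.exp(-(params.beta0_event + params.beta * x))
    t_event = scale_event * rng.exponential(size=n) ** (1.0 / params.anc_event)
    scale_cens = np.exp(-params.beta0_cens)
    t_cens = scale_cens * rng.exponential(size=n) ** (1.0 / params.anc_cens)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    if params.max_followup is not None:
        over = time > params.max_followup
        time = np.where(over, params.max_followup, time)
        event = event & ~over
    arm = np.where(x == 1.0, EXPERIMENTAL, CONTROL)
    return SurvivalDataset.from_arrays(
        time, event, arm, label=f"sim(seed={params.seed})"
    )


def cell_seed(base_seed: int, n: int, anc_cens: float, beta: float,
              replicate: int) -> int:
    """Stable per-trial seed so any grid subset reproduces independently."""
    key = f"{base_seed}|{n}|{anc_cens:.6g}|{beta:.6g}|{replicate}"
    digest = hashlib.blake2b(key.encode(), digest_size=8).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def estimate_hr(dataset: SurvivalDataset) -> float:
    """Cox proportional-hazards HR (experimental vs control), Efron ties.

    Returns NaN when the fit is degenerate (no events, or complete
    separation preventing convergence).
    """
    from lifelines import CoxPHFitter

    time, event, exp_arm = dataset.to_arrays()
    if not event.any():
        return float("nan")
    df = pd.DataFrame(
        {"time": time, "event": event.astype(int), "arm": exp_arm.astype(float)}
    )
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except Exception:  # convergence failure on extreme cells
        return float("nan")
    return float(np.exp(cph.params_["arm"]))


def run_grid(
    ns: tuple[int, ...] = PAPER_COHORT_SIZES,
    anc_cens_values: tuple[float, ...] = PAPER_ANC_CENS,
    betas: tuple[float, ...] = PAPER_BETAS,
    reps_per_cell: int = PAPER_REPS_PER_CELL,
    base_seed: int = 0,
    alpha: float = 0.05,
    base_params: SimulationParams | None = None,
    with_sifi: bool = True,
    with_hr: bool = True,
) -> list[SimResultRow]:
    """Run a factorial simulation grid; one row per (n, anc_cens, beta, rep).

    Per-row seeds derive deterministically from ``base_seed`` and the cell
    coordinates, so identical inputs give bit-identical output and any
    sub-grid reproduces rows of the full grid. Degenerate trials with zero
    events are retained with p = 1 and a NaN hazard ratio.
    """
    if reps_per_cell < 1:
        raise ValueError("reps_per_cell must be >= 1")
    template = base_params or SimulationParams(n=2, beta=0.0, seed=0)
    rows: list[SimResultRow] = []
    for n, anc_cens, beta in itertools.product(ns, anc_cens_values, betas):
        for rep in range(reps_per_cell):
            seed = cell_seed(base_seed, n, anc_cens, beta, rep)
            params = replace(
                template, n=n, anc_cens=anc_cens, beta=beta, seed=seed
            )
            ds = simulate_dataset(params)
            lr = logrank_test(ds)
            p = lr.p_value
            hr = estimate_hr(ds) if with_hr else float("nan")
            pct_cens = 100.0 * (len(ds) - ds.n_events()) / len(ds)
            if with_sifi:
                res = compute_sifi(ds, SIFIConfig(alpha=alpha))
                sifi_value, exhausted = res.value, res.exhausted
            else:
                sifi_value, exhausted = 0, False
            rows.append(
                SimResultRow(
                    params=params,
                    replicate=rep,
                    hr=hr,
                    pct_censored=pct_cens,
                    p=p,
                    sifi=sifi_value,
                    exhausted=exhausted,
                )
            )
    return rows


def results_to_frame(rows: list[SimResultRow]) -> pd.DataFrame:
    """Flatten grid rows into a DataFrame (one column per scalar)."""
    return pd.DataFrame(
        {
            "n": [r.params.n for r in rows],
            "anc_event": [r.params.anc_event for r in rows],
            "anc_cens": [r.params.anc_cens for r in rows],
            "beta": [r.params.beta for r in rows],
            "replicate": [r.replicate for r in rows],
            "seed": [r.params.seed for r in rows],
            "hr": [r.hr for r in rows],
            "pct_censored": [r.pct_censored for r in rows],
            "p": [r.p for r in rows],
            "sifi": [r.sifi for r in rows],
            "exhausted": [r.exhausted for r in rows],
        }
    )


def paper_grid() -> list[tuple[int, float, float, int]]:
    """Enumerate the reference study's full design: (n, anc_cens, beta, rep).

    12 cohort sizes x 5 censoring shapes x 25 effect sizes x 10 replicates
    = 15 000 simulated trials.
    """
    return [
        (n, anc_cens, beta, rep)
        for n, anc_cens, beta in itertools.product(
            PAPER_COHORT_SIZES, PAPER_ANC_CENS, PAPER_BETAS
        )
        for rep in range(PAPER_REPS_PER_CELL)
    ]
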