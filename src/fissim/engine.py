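"""Single simulations to irreversible fission, and batch parameter sweeps.

A simulation iterates days: each individual gets its daily movement
opportunity (:func:`fissim.movement.assign_day`); on days when the whole
group forages split across both areas, a temporary fission rewires the
grooming network (:func:`fissim.network.transfer_update`) and the
irreversible-fission criterion is tested on the post-update network.  The
run stops on the first day the criterion holds; otherwise it is censored
at ``max_days`` (default 900 days, past which field groups that have not
split are not expected to).

The study grid couples a mimetic coefficient ``C`` with intrinsic
probabilities ``lambda1 = lambda2`` so that the Nutrition/Sociality ratio
``R = (lambda1 + lambda2) / (C * 100)`` spans 0.11-9, crossed with
transfer percentages 10-100% and group sizes 10 and 20.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernel
from .errors import ConfigurationError, SimulationError, UndefinedRatioError
from .movement import DEFAULT_ROUND_LIMIT, Condition, assign_day, draw_preferences
from .network import (
    DayAssignment,
    SocialNetwork,
    check_irreversible,
    init_egalitarian,
    transfer_update,
)

#: default censoring horizon in days
MAX_DAYS = 900

#: irreversible-fission definition: within-subgroup social time threshold (%)
#: and the minimum subgroup size below which a split is a mere dispersion
FISSION_THRESHOLD = 95.0
MIN_SUBGROUP = 4

#: field-plausible window for an irreversible fission, in days
VIABLE_WINDOW = (90, 900)

#: (mimetic coefficient, lambda) pairs of the study design; lambda1 = lambda2
STUDY_LAMBDA_PAIRS: tuple[tuple[float, float], ...] = (
    (0.001, 0.45),
    (0.002, 0.40),
    (0.003, 0.35),
    (0.004, 0.30),
    (0.005, 0.25),
    (0.006, 0.20),
    (0.007, 0.15),
    (0.008, 0.10),
    (0.009, 0.05),
)

#: transfer percentages of the study design
STUDY_TRANSFERS: tuple[int, ...] = tuple(range(10, 101, 10))

#: group sizes of the study design
STUDY_GROUP_SIZES: tuple[int, ...] = (10, 20)

#: columns of the tidy batch table, in canonical order
BATCH_COLUMNS = (
    "n", "C", "lambda1", "lambda2", "transfer",
    "ratio", "replicate", "seed", "days", "censored",
)


def nutrition_sociality_ratio(cond: Condition) -> float:
    """Nutrition/Sociality ratio ``R = (lambda1 + lambda2) / (C * 100)``.

    High values mean movement is driven by nutritional need, low values by
    social cohesion.  Undefined for ``C = 0``.  The full-precision value is
    returned; round to 2 decimals only for display.
    """
    if cond.C <= 0.0:
        raise UndefinedRatioError(
            "the Nutrition/Sociality ratio is undefined for C = 0"
        )
    return (cond.lambda1 + cond.lambda2) / (cond.C * 100.0)


def study_conditions(
    n_values: Sequence[int] = STUDY_GROUP_SIZES,
    transfers: Sequence[float] = STUDY_TRANSFERS,
    lambda_pairs: Sequence[tuple[float, float]] = STUDY_LAMBDA_PAIRS,
) -> list[Condition]:
    """The full study grid: group sizes x ratio rows x transfer levels."""
    return [
        Condition(n=int(n), C=C, lambda1=lam, lambda2=lam, transfer=float(T))
        for n in n_values
        for (C, lam) in lambda_pairs
        for T in transfers
    ]


@dataclass(frozen=True)
class SimulationConfig:
    """Settings for a single run."""

    cond: Condition
    seed: int
    max_days: int = MAX_DAYS
    record_trace: bool = False
    threshold: float = FISSION_THRESHOLD
    min_subgroup: int = MIN_SUBGROUP
    stop_on_fission: bool = True
    day_mode: str = "single_pass"
    backend: str = "numba"

    def __post_init__(self) -> None:
        if self.max_days < 1:
            raise ConfigurationError(f"max_days must be >= 1, got {self.max_days!r}")
        if self.backend not in ("numba", "python"):
            raise ConfigurationError(f"unknown backend {self.backend!r}")
        if self.day_mode not in ("single_pass", "until_empty"):
            raise ConfigurationError(f"unknown day_mode {self.day_mode!r}")


_PREF_CODES = {"homogeneous": _kernel.PREF_HOMOGENEOUS, "uniform": _kernel.PREF_UNIFORM}
_MODE_CODES = {
    "single_pass": _kernel.MODE_SINGLE_PASS,
    "until_empty": _kernel.MODE_UNTIL_EMPTY,
}


@dataclass(frozen=True)
class TraceRecord:
    """One day of a recorded run (state after that day's network update)."""

    day: int
    assignment: DayAssignment
    temporary_fission: bool
    within_subgroup_sums: np.ndarray


@dataclass(frozen=True)
class SimulationResult:
    """Outcome of one run.

    ``days_to_fission`` is the first day whose post-update network meets
    the irreversible-fission criterion; for censored runs it equals
    ``max_days`` with ``censored=True``.  ``final_partition`` is the
    fission-day split (None when censored).
    """

    cond: Condition
    seed: int
    days_to_fission: int
    censored: bool
    final_network: SocialNetwork
    final_partition: DayAssignment | None
    ratio: float
    trace: tuple[TraceRecord, ...] | None = None

    @property
    def viable(self) -> bool:
        """Whether the event falls in the field-plausible 90-900 day window."""
        lo, hi = VIABLE_WINDOW
        return (not self.censored) and lo <= self.days_to_fission <= hi


def run_simulation(cfg: SimulationConfig) -> SimulationResult:
    """Run one simulation to irreversible fission or censoring.

    Deterministic for a given config: the same seed always reproduces the
    same result (per backend; the two backends use different random
    streams).
    """
    cond = cfg.cond
    if cfg.backend == "python":
        return _run_python(cfg)
    ratio = _safe_ratio(cond)
    W = init_egalitarian(cond.n).weights
    trace_arr = (
        np.zeros((cfg.max_days, cond.n), dtype=np.int8)
        if cfg.record_trace
        else np.zeros((0, 0), dtype=np.int8)
    )
    day, status = _kernel.run_days(
        W, cond.C, cond.lambda1, cond.lambda2, cond.transfer / 100.0,
        cfg.max_days, cfg.threshold, cfg.min_subgroup, int(cfg.seed),
        cfg.stop_on_fission, _PREF_CODES[cond.preference], cond.redraw_daily,
        _MODE_CODES[cfg.day_mode], DEFAULT_ROUND_LIMIT, trace_arr,
    )
    if status == _kernel.STATUS_ROUND_LIMIT:
        raise SimulationError(
            f"day {day} did not complete within {DEFAULT_ROUND_LIMIT} rounds "
            f"under {cond!r}"
        )
    censored = status == _kernel.STATUS_CENSORED
    net = SocialNetwork(W, validate=False, copy=False)
    trace = _replay_trace(cond, trace_arr[:day]) if cfg.record_trace else None
    partition = None
    if not censored:
        if cfg.record_trace:
            partition = trace[-1].assignment
        else:
            # the kernel does not return the last day's areas; recover them
            # by re-running with trace recording (same seed, same stream)
            rerun = run_simulation(
                SimulationConfig(
                    cond=cond, seed=cfg.seed, max_days=cfg.max_days,
                    record_trace=True, threshold=cfg.threshold,
                    min_subgroup=cfg.min_subgroup,
                    stop_on_fission=cfg.stop_on_fission,
                    day_mode=cfg.day_mode, backend="numba",
                )
            )
            partition = rerun.final_partition
    return SimulationResult(
        cond=cond, seed=int(cfg.seed), days_to_fission=int(day),
        censored=censored, final_network=net, final_partition=partition,
        ratio=ratio, trace=trace,
    )


def _run_python(cfg: SimulationConfig) -> SimulationResult:
    """Reference day loop built from the public module operations."""
    cond = cfg.cond
    rng = np.random.default_rng(cfg.seed)
    net = init_egalitarian(cond.n)
    lambdas = draw_preferences(cond, rng)
    trace: list[TraceRecord] = []
    last_assign: DayAssignment | None = None
    event_day: int | None = None
    for day in range(1, cfg.max_days + 1):
        if cond.redraw_daily:
            lambdas = draw_preferences(cond, rng)
        assign = assign_day(net, cond, rng, lambdas=lambdas, mode=cfg.day_mode)
        if assign.is_temporary_fission:
            net = transfer_update(net, assign, cond.transfer)
        if cfg.record_trace:
            trace.append(TraceRecord(
                day=day, assignment=assign,
                temporary_fission=assign.is_temporary_fission,
                within_subgroup_sums=net.within_subgroup_sums(assign),
            ))
        if (
            cfg.stop_on_fission
            and assign.is_temporary_fission
            and check_irreversible(net, assign, cfg.threshold, cfg.min_subgroup)
        ):
            event_day = day
            last_assign = assign
            break
    censored = event_day is None
    return SimulationResult(
        cond=cond, seed=int(cfg.seed),
        days_to_fission=cfg.max_days if censored else event_day,
        censored=censored, final_network=net,
        final_partition=last_assign, ratio=_safe_ratio(cond),
        trace=tuple(trace) if cfg.record_trace else None,
    )


def _replay_trace(cond: Condition, day_areas: np.ndarray) -> tuple[TraceRecord, ...]:
    """Rebuild per-day records by replaying recorded assignments through the
    reference network operations (deterministic given the assignments)."""
    net = init_egalitarian(cond.n)
    records = []
    for d in range(day_areas.shape[0]):
        assign = DayAssignment(day_areas[d])
        if assign.is_temporary_fission:
            net = transfer_update(net, assign, cond.transfer)
        records.append(TraceRecord(
            day=d + 1, assignment=assign,
            temporary_fission=assign.is_temporary_fission,
            within_subgroup_sums=net.within_subgroup_sums(assign),
        ))
    return tuple(records)


def _safe_ratio(cond: Condition) -> float:
    return float("nan") if cond.C <= 0.0 else nutrition_sociality_ratio(cond)


def replicate_seed(base_seed: int, condition_index: int, replicate: int) -> int:
    """Stable per-replicate seed below 2**31, derived from the batch base
    seed and the (condition, replicate) coordinates."""
    ss = np.random.SeedSequence([int(base_seed), int(condition_index), int(replicate)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


@dataclass
class BatchResult:
    """Tidy table of simulation outcomes over a grid x replicates sweep.

    One row per (condition, replicate) with columns
    ``n, C, lambda1, lambda2, transfer, ratio, replicate, seed, days,
    censored``; the substrate for every statistical analysis.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in BATCH_COLUMNS if c not in self.table.columns]
        if missing:
            raise ConfigurationError(f"batch table is missing columns {missing}")
        self.table = self.table.loc[:, list(BATCH_COLUMNS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def event_days(self) -> pd.Series:
        """Days-to-fission of the replicates that actually fissioned."""
        return self.table.loc[~self.table["censored"], "days"]

    def with_viability(self) -> pd.DataFrame:
        """Copy of the table with a ``viable`` flag for events inside the
        field-plausible 90-900 day window."""
        lo, hi = VIABLE_WINDOW
        out = self.table.copy()
        out["viable"] = (~out["censored"]) & out["days"].between(lo, hi)
        return out

    @staticmethod
    def concat(batches: Sequence["BatchResult"]) -> "BatchResult":
        return BatchResult(pd.concat([b.table for b in batches], ignore_index=True))


def run_batch(
    grid: Sequence[Condition],
    reps: int,
    base_seed: int,
    *,
    max_days: int = MAX_DAYS,
    threshold: float = FISSION_THRESHOLD,
    min_subgroup: int = MIN_SUBGROUP,
    day_mode: str = "single_pass",
    progress: bool = False,
) -> BatchResult:
    """Run ``reps`` seeded replicates of every condition in ``grid``.

    Replicate ``r`` of the ``c``-th condition uses
    ``replicate_seed(base_seed, c, r)``, so the batch is reproducible from
    ``base_seed`` alone and any single replicate can be replayed in
    isolation.
    """
    if len(grid) == 0:
        raise ConfigurationError("empty condition grid")
    if reps < 1:
        raise ConfigurationError(f"reps must be >= 1, got {reps!r}")
    iterator = enumerate(grid)
    if progress:
        from tqdm import tqdm  # local import: progress is interactive sugar

        iterator = tqdm(list(iterator), desc="conditions")
    no_trace = np.zeros((0, 0), dtype=np.int8)
    rows = []
    for c_idx, cond in iterator:
        ratio = _safe_ratio(cond)
        q = cond.transfer / 100.0
        for rep in range(reps):
            seed = replicate_seed(base_seed, c_idx, rep)
            W = init_egalitarian(cond.n).weights
            day, status = _kernel.run_days(
                W, cond.C, cond.lambda1, cond.lambda2, q,
                max_days, threshold, min_subgroup, seed,
                True, _PREF_CODES[cond.preference], cond.redraw_daily,
                _MODE_CODES[day_mode], DEFAULT_ROUND_LIMIT, no_trace,
            )
            if status == _kernel.STATUS_ROUND_LIMIT:
                raise SimulationError(
                    f"replicate {rep} of {cond!r} stalled on day {day}"
                )
            rows.append((
                cond.n, cond.C, cond.lambda1, cond.lambda2, cond.transfer,
                ratio, rep, seed, day, status == _kernel.STATUS_CENSORED,
            ))
    table = pd.DataFrame(rows, columns=list(BATCH_COLUMNS))
    return BatchResult(table)
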