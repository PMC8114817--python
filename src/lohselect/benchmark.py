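"""Random-instance generation and the candidate-overshoot experiment.

The sweep commits s + s' candidate sums to find the k smallest, so the
ratio (s + s') / k measures how far the method overshoots the target.
:func:`overshoot_experiment` measures that ratio on uniform random
integer instances over a grid of (n, k) configurations; the standard
grid (:func:`table1_configs`) spans n in {1000, 2000, 4000} with k from
n/4 up to 4n at rank alpha = 2.

Per-phase wall-clock timings are recorded for information only; they are
hardware-dependent and never asserted.
"""

from __future__ import annotations

import csv
import time
from dataclasses import dataclass, field
from statistics import mean
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .linear_select import partition_by_rank
from .loh import lohify
from .topk import inflate_candidates, phase1_sweep, phase2_collect

__all__ = [
    "BenchConfig",
    "BenchRecord",
    "random_instance",
    "table1_configs",
    "overshoot_experiment",
    "write_records_csv",
]

DEFAULT_VALUE_HIGH = 2**20  # ties rare at n <= 4000


@dataclass(frozen=True)
class BenchConfig:
    """One benchmark condition: vector length n, selection size k, rank alpha."""

    n: int
    k: int
    alpha: float = 2.0
    value_low: int = 0
    value_high: int = DEFAULT_VALUE_HIGH

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1 (got {self.n})")
        if not 1 <= self.k <= self.n * self.n:
            raise ValueError(f"k must be in [1, n^2] (got {self.k})")
        if self.value_low >= self.value_high:
            raise ValueError("value_low must be < value_high")


@dataclass
class BenchRecord:
    """One repetition: overshoot counters plus informational timings."""

    config: BenchConfig
    rep: int
    seed: int
    s: int
    s_prime: int
    ratio: float = field(init=False)
    t_phase0: float = 0.0
    t_phase123: float = 0.0

    def __post_init__(self) -> None:
        self.ratio = (self.s + self.s_prime) / self.config.k


def random_instance(
    n: int,
    seed: int,
    low: int = 0,
    high: int = DEFAULT_VALUE_HIGH,
) -> Tuple[List[int], List[int]]:
    """Two length-n vectors of i.i.d. uniform integers in [low, high)."""
    if n < 1:
        raise ValueError(f"n must be >= 1 (got {n})")
    if low >= high:
        raise ValueError(f"need low < high (got [{low}, {high}))")
    rng = np.random.default_rng(seed)
    X = rng.integers(low, high, size=n).tolist()
    Y = rng.integers(low, high, size=n).tolist()
    return X, Y


def table1_configs(alpha: float = 2.0) -> List[BenchConfig]:
    """The standard 15-configuration grid: n in {1000, 2000, 4000}, k = n/4 .. 4n."""
    grid = [
        (1000, 250), (1000, 500), (1000, 1000), (1000, 2000), (1000, 4000),
        (2000, 500), (2000, 1000), (2000, 2000), (2000, 4000), (2000, 8000),
        (4000, 1000), (4000, 2000), (4000, 4000), (4000, 8000), (4000, 16000),
    ]
    return [BenchConfig(n=n, k=k, alpha=alpha) for n, k in grid]


def _run_once(config: BenchConfig, rep: int, seed: int) -> BenchRecord:
    X, Y = random_instance(config.n, seed, config.value_low, config.value_high)
    t0 = time.perf_counter()
    loh_x = lohify(X, config.alpha)
    loh_y = lohify(Y, config.alpha)
    t1 = time.perf_counter()
    trace, frontier = phase1_sweep(loh_x, loh_y, config.k)
    phase2_collect(trace, frontier, loh_x, loh_y)
    candidates = inflate_candidates(loh_x, loh_y, trace.q)
    partition_by_rank(candidates, config.k)
    t2 = time.perf_counter()
    return BenchRecord(
        config=config,
        rep=rep,
        seed=seed,
        s=trace.s,
        s_prime=trace.s_prime,
        t_phase0=t1 - t0,
        t_phase123=t2 - t1,
    )


def overshoot_experiment(
    configs: Sequence[BenchConfig],
    reps: int = 10,
    seed: int = 0,
    csv_path: Optional[str] = None,
) -> Tuple[List[BenchRecord], float]:
    """Run every config x rep on fresh random instances; return records
    and the grand mean overshoot ratio (mean over configs of per-config
    mean (s + s') / k).

    Per-rep seeds are spawned from `seed` via a NumPy ``SeedSequence``,
    so runs are reproducible and instances independent.
    """
    if not configs:
        raise ValueError("configs must be nonempty")
    if reps < 1:
        raise ValueError(f"reps must be >= 1 (got {reps})")
    child_seeds = [
        int(s) & 0x7FFFFFFF
        for s in np.random.SeedSequence(seed).generate_state(len(configs) * reps)
    ]
    records: List[BenchRecord] = []
    per_config_means: List[float] = []
    for c_idx, config in enumerate(configs):
        ratios = []
        for rep in range(reps):
            record = _run_once(config, rep, child_seeds[c_idx * reps + rep])
            records.append(record)
            ratios.append(record.ratio)
        per_config_means.append(mean(ratios))
    grand_mean = mean(per_config_means)
    if csv_path is not None:
        write_records_csv(records, csv_path)
    return records, grand_mean


def write_records_csv(records: Sequence[BenchRecord], path: str) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(
            ["n", "k", "alpha", "rep", "seed", "s", "s_prime", "ratio",
             "t_phase0", "t_phase123"]
        )
        for r in records:
            writer.writerow(
                [r.config.n, r.config.k, r.config.alpha, r.rep, r.seed,
                 r.s, r.s_prime, f"{r.ratio:.6f}",
                 f"{r.t_phase0:.6f}", f"{r.t_phase123:.6f}"]
            )
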