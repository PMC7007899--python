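"""Cycle-resampling bootstrap confidence bounds.

Cycles (not subjects) are the resampling unit: each bootstrap replicate
draws ``n`` cycles with replacement from the pooled ``n``-cycle set,
recomputes the statistic (mean sway trace, FRF, coherence, ...), and the
confidence limits are read off element-wise from the sorted replicates
using the index rule

    low = round(n_boot (1 - ci) / 2),   high = round(n_boot (1 + ci) / 2)

(1-based in the ascending sort), i.e. the 10th and 390th of 400 replicates
for a 95% interval.  No simultaneous-band correction is applied; limits
are per scalar output element.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .frf import CycleSet

__all__ = ["BootstrapConfig", "BootstrapResult", "ci_indices", "bootstrap_statistic"]


@dataclass(frozen=True)
class BootstrapConfig:
    n_boot: int = 400
    ci_level: float = 0.95
    seed: int | None = None
    by_subject: bool = False  # optional subject-level resampling, off by default

    def __post_init__(self) -> None:
        if self.n_boot < 40:
            raise ValueError("n_boot must be >= 40")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")


@dataclass
class BootstrapResult:
    point: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_boot: int
    ci_level: float


def ci_indices(n_boot: int, ci_level: float) -> tuple[int, int]:
    """1-based (low, high) indices into the ascending sorted replicate list."""
    tail = n_boot * (1.0 - ci_level) / 2.0
    if tail < 1.0:
        raise ValueError(
            f"too few replicates: n_boot x (1 - ci_level)/2 = {tail:.2f} < 1"
        )
    low = int(np.round(tail))
    high = int(np.round(n_boot * (1.0 + ci_level) / 2.0))
    return low, high


def bootstrap_statistic(
    cs: CycleSet,
    statistic: Callable[[CycleSet], np.ndarray],
    cfg: BootstrapConfig,
) -> BootstrapResult:
    """Bootstrap a CycleSet statistic; deterministic given ``cfg.seed``.

    ``statistic`` must map a CycleSet to a finite-dimensional array; limits
    are computed per element with the paper-style sorted-index rule.
    """
    n = cs.n_cycles
    if n == 0:
        raise ValueError("empty cycle pool")
    low, high = ci_indices(cfg.n_boot, cfg.ci_level)
    rng = np.random.default_rng(cfg.seed)
    point = np.asarray(statistic(cs), dtype=float)
    reps = np.empty((cfg.n_boot,) + point.shape)
    if cfg.by_subject:
        subjects = [p[0] for p in cs.provenance]
        if len(subjects) != n:
            raise ValueError("subject-level resampling requires provenance")
        uniq = sorted(set(subjects))
        rows_by_subj = {s: np.flatnonzero([x == s for x in subjects]) for s in uniq}
        for b in range(cfg.n_boot):
            pick = rng.integers(0, len(uniq), len(uniq))
            idx = np.concatenate([rows_by_subj[uniq[i]] for i in pick])
            reps[b] = statistic(cs.take(idx))
    else:
        for b in range(cfg.n_boot):
            idx = rng.integers(0, n, n)
            reps[b] = statistic(cs.take(idx))
    reps.sort(axis=0)
    return BootstrapResult(
        point=point,
        ci_low=reps[low - 1],
        ci_high=reps[high - 1],
        n_boot=cfg.n_boot,
        ci_level=cfg.ci_level,
    )
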