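"""Timing comparison of the implicit and explicit null-model surfaces.

The implicit general isobole equation needs a root solve per grid cell,
while the explicit mean surface is a handful of closed-form evaluations; the
explicit formulation is therefore much faster on full checkerboards.  This
module measures that gap: median wall time over repeated full-grid
evaluations for each model and their ratio.  Absolute times and the ratio are
hardware-dependent and are reported, never asserted.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dose_response import CurvePair
from .null_models import SolverConfig, SurfaceModel, surface

__all__ = ["BenchReport", "bench"]


@dataclass(frozen=True)
class BenchReport:
    """Median seconds per full-grid evaluation for each model."""

    median_gi_s: float
    median_mean_s: float
    reps: int
    grid_shape: tuple[int, int]

    @property
    def ratio(self) -> float:
        """median(implicit) / median(explicit): how much slower GI is."""
        return self.median_gi_s / self.median_mean_s

    def to_dict(self) -> dict:
        return {
            "median_gi_s": self.median_gi_s,
            "median_mean_s": self.median_mean_s,
            "ratio_gi_over_mean": self.ratio,
            "reps": self.reps,
            "grid_shape": list(self.grid_shape),
        }


def bench(
    pair: CurvePair,
    doses1: Sequence[float],
    doses2: Sequence[float],
    reps: int = 100,
    solver: SolverConfig | None = None,
) -> BenchReport:
    """Time full-grid evaluation of the GI and explicit-mean surfaces."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    solver = solver or SolverConfig()
    gi = SurfaceModel("gi", pair, solver)
    mean = SurfaceModel("mean", pair, solver)

    def timed(model: SurfaceModel) -> float:
        times = np.empty(reps)
        for k in range(reps):
            t0 = time.perf_counter()
            surface(model, doses1, doses2)
            times[k] = time.perf_counter() - t0
        return float(np.median(times))

    t_mean = timed(mean)
    t_gi = timed(gi)
    return BenchReport(
        median_gi_s=t_gi,
        median_mean_s=t_mean,
        reps=reps,
        grid_shape=(len(doses1), len(doses2)),
    )
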