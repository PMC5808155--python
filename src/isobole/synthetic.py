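"""Synthetic curve pairs, dose designs and noisy checkerboard records.

Two screening designs are emulated:

* ``dilution6`` — a 6x6 matrix per compound pair: a top dose diluted 4-fold
  four times, with the sixth dose being zero (the layout of large one-to-all
  cancer compound screens; default top doses 2.5 and 125, in the micromolar
  range such screens use).
* ``linear8`` — an 8x8 factorial design with doses linearly increasing from
  0 up to a per-compound maximum (the layout of anti-fungal growth screens).

Records are simulated by evaluating a chosen null-model surface ("truth") on
the design grid and adding i.i.d. Gaussian measurement noise.  Responses are
not clipped to [0, 1], matching raw-viability readouts.  Curve-pair scenarios
mirror the canonical illustration settings: ``lacc`` (curves differing only
in EC50, so the consistency condition holds), ``slopes`` (different slopes),
``max_effect`` (different asymptotes) and ``both``.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .dose_response import CurvePair, HillCurve
from .null_models import SolverConfig, SurfaceModel, surface

__all__ = [
    "DoseDesign",
    "Record",
    "SCENARIOS",
    "make_pair",
    "simulate_record",
    "simulate_population",
]

SCENARIOS = ("lacc", "slopes", "max_effect", "both")

# Canonical illustration parameter sets (shared y0 = 1).
_FIXTURES = {
    "lacc": ((1.0, 0.0, 1.0, 2.0), (1.0, 0.0, 2.0, 2.0)),
    "slopes": ((1.0, 0.0, 1.0, 1.0), (1.0, 0.0, 1.0, 2.0)),
    "max_effect": ((1.0, 0.3, 1.0, 1.0), (1.0, 0.0, 1.0, 1.0)),
    "both": ((1.0, 0.3, 1.0, 1.0), (1.0, 0.0, 1.0, 2.0)),
}


@dataclass(frozen=True)
class DoseDesign:
    """Ascending dose grids (starting at exactly 0) for the two compounds."""

    doses1: tuple[float, ...]
    doses2: tuple[float, ...]
    design_name: str = "custom"

    def __post_init__(self) -> None:
        for d in (self.doses1, self.doses2):
            arr = np.asarray(d, dtype=float)
            if arr.size < 1 or arr[0] != 0.0:
                raise ValueError("dose grid must start at exactly 0")
            if np.any(np.diff(arr) <= 0):
                raise ValueError("doses must be strictly increasing")

    @classmethod
    def dilution6(cls, d_max1: float = 2.5, d_max2: float = 125.0) -> "DoseDesign":
        """6 doses per axis: top dose, four 4-fold dilutions, and zero."""

        def axis(d_max: float) -> tuple[float, ...]:
            return (0.0,) + tuple(d_max / 4.0 ** k for k in range(4, -1, -1))

        return cls(axis(d_max1), axis(d_max2), "dilution6")

    @classmethod
    def linear8(cls, d_max1: float = 1.0, d_max2: float = 1.0) -> "DoseDesign":
        """8 doses per axis, evenly spaced from 0 to the top dose."""
        return cls(
            tuple(np.linspace(0.0, d_max1, 8)),
            tuple(np.linspace(0.0, d_max2, 8)),
            "linear8",
        )

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.doses1), len(self.doses2))


@dataclass
class Record:
    """One compound-pair x cell-line measurement set.

    ``responses[i, j]`` is the measured (or simulated) response at
    ``(doses1[i], doses2[j])``; NaN marks missing cells.  Row 0 and column 0
    are the conditional (single-compound) series.  ``truth`` carries the
    generating model's provenance for simulated records.
    """

    id: str
    design: DoseDesign
    responses: np.ndarray
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.shape != self.design.shape:
            raise ValueError(
                f"responses shape {self.responses.shape} does not match "
                f"design shape {self.design.shape}"
            )

    def conditionals(self) -> tuple[np.ndarray, np.ndarray]:
        """(dose, response) arrays for the two single-compound series."""
        d1 = np.asarray(self.design.doses1)
        d2 = np.asarray(self.design.doses2)
        cond1 = np.column_stack([d1, self.responses[:, 0]])
        cond2 = np.column_stack([d2, self.responses[0, :]])
        return cond1, cond2


def _draw_curve(rng: np.random.Generator, y_inf: float, s: float) -> HillCurve:
    e = float(np.exp(rng.uniform(np.log(0.25), np.log(4.0))))
    return HillCurve(y0=1.0, y_inf=y_inf, e=e, s=s)


def make_pair(
    scenario: str,
    rng: np.random.Generator | int | None = None,
) -> CurvePair:
    """Draw (or look up) a curve pair for the given LACC scenario.

    With ``rng=None`` the canonical fixed parameter set of the scenario is
    returned.  Otherwise parameters are drawn randomly — EC50 log-uniform on
    [0.25, 4], slope uniform on [0.5, 4], asymptote uniform on [0, 0.4] —
    with the scenario's (in)equalities enforced: equal means exactly equal,
    unequal means separated by a margin (0.2 in slope, 0.1 in asymptote).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}, got {scenario!r}")
    if rng is None:
        (p1, p2) = _FIXTURES[scenario]
        return CurvePair(HillCurve(*p1), HillCurve(*p2))
    rng = np.random.default_rng(rng)

    slopes_differ = scenario in ("slopes", "both")
    yinf_differ = scenario in ("max_effect", "both")

    s1 = float(rng.uniform(0.5, 4.0))
    if slopes_differ:
        s2 = float(rng.uniform(0.5, 4.0))
        while abs(s1 - s2) < 0.2:
            s2 = float(rng.uniform(0.5, 4.0))
    else:
        s2 = s1
    y1 = float(rng.uniform(0.0, 0.4))
    if yinf_differ:
        y2 = float(rng.uniform(0.0, 0.4))
        while abs(y1 - y2) < 0.1:
            y2 = float(rng.uniform(0.0, 0.4))
    else:
        y2 = y1
    return CurvePair(_draw_curve(rng, y1, s1), _draw_curve(rng, y2, s2))


def simulate_record(
    pair: CurvePair,
    design: DoseDesign,
    truth_kind: str = "gi",
    noise_sd: float = 0.02,
    seed: int | None = None,
    record_id: str = "synthetic",
    solver: SolverConfig | None = None,
) -> Record:
    """Forward-simulate one checkerboard record.

    The truth surface is the named null model evaluated on the design grid;
    additive homoscedastic Gaussian noise of standard deviation ``noise_sd``
    (response units) is applied.  Deterministic given the seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    model = SurfaceModel(truth_kind, pair, solver or SolverConfig())
    clean = surface(model, design.doses1, design.doses2)
    rng = np.random.default_rng(seed)
    noisy = clean + rng.normal(0.0, noise_sd, size=clean.shape) if noise_sd > 0 else clean
    truth = {
        "kind": truth_kind,
        "pair": pair.to_dict(),
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return Record(id=record_id, design=design, responses=noisy, truth=truth)


def simulate_population(
    n_records: int,
    scenario: str = "both",
    truth_kind: str = "gi",
    noise_sd: float = 0.02,
    seed: int | None = None,
    design: DoseDesign | None = None,
) -> list[Record]:
    """Simulate ``n_records`` independent records.

    Per-record seeds are spawned deterministically from the master seed via
    ``np.random.SeedSequence(seed).spawn``; each record gets an independent
    curve pair (drawn for ``scenario``) and independent noise.

    With ``design=None`` each record gets an 8x8 linear grid scaled to its
    own pair, dosing up to four times each compound's EC50 — emulating
    protocols that choose per-compound top doses near the maximal-effect
    dose, and keeping the conditional curves identifiable from the record
    itself.  Pass a fixed :class:`DoseDesign` (e.g. ``dilution6``) to emulate
    a screen with one dose range for every compound.
    """
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_records)
    records = []
    for k, child in enumerate(children):
        rng = np.random.default_rng(child)
        pair = make_pair(scenario, rng)
        des = design or DoseDesign.linear8(4 * pair.curve1.e, 4 * pair.curve2.e)
        noise_seed = int(rng.integers(0, 2**31 - 1))
        records.append(
            simulate_record(
                pair,
                des,
                truth_kind=truth_kind,
                noise_sd=noise_sd,
                seed=noise_seed,
                record_id=f"rec{k:04d}",
            )
        )
    return records
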