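"""Effect-equivalent doses and the Loewe Additivity Consistency Condition.

Loewe additivity rests on dose equivalence: the dose of compound 1 that
matches the effect of dose ``x2`` of compound 2 is

    x1_equiv(x2) = f1^{-1}(f2(x2)),

and symmetrically for ``x2_equiv``.  The *Loewe Additivity Consistency
Condition* (LACC) requires that substituting either compound by the other's
equivalent dose yields the same surface, i.e. f_{2->1} = f_{1->2} everywhere.
For monotone curves this holds iff a dose and its equivalent are proportional
(x1_equiv = c * x2); for Hill curves that means the two conditional curves may
differ only in EC50 — equal y0, y_inf and slope.  The diagnostics here check
that parameter criterion and measure the residual asymmetry
|f_{2->1} - f_{1->2}| on a dose grid, at the level of a single curve pair and,
via paired Wilcoxon signed-rank tests on (s1, s2) and (y_inf,1, y_inf,2),
across a population of fitted records.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import wilcoxon

from .dose_response import CurvePair, FitResult, hill_inverse, hill_response

__all__ = [
    "LaccReport",
    "PopulationLaccTest",
    "equivalent_dose_1",
    "equivalent_dose_2",
    "check_lacc",
    "population_lacc_test",
]

#: Relative parameter tolerance under which two Hill curves are treated as
#: differing only in EC50 (the LACC is an exact condition; floats need slack).
PARAM_RTOL = 1e-6


def equivalent_dose_1(pair: CurvePair, x2) -> float | np.ndarray:
    """Dose of compound 1 with the same effect as dose ``x2`` of compound 2.

    Returns the ``np.inf`` sentinel where compound 1 cannot reach the effect
    (f2(x2) below compound 1's maximal-effect asymptote).
    """
    y = hill_response(pair.curve2, x2)
    return hill_inverse(pair.curve1, y)


def equivalent_dose_2(pair: CurvePair, x1) -> float | np.ndarray:
    """Mirror of :func:`equivalent_dose_1` with the compounds swapped."""
    y = hill_response(pair.curve1, x1)
    return hill_inverse(pair.curve2, y)


@dataclass(frozen=True)
class LaccReport:
    """Diagnostics for the LACC on one curve pair.

    ``proportional`` is the Hill-specific parameter test (equal slopes and
    asymptotes up to ``PARAM_RTOL``); ``c_hat = e1/e2`` estimates the
    proportionality constant between equivalent doses, a dimensionless number
    only when both dose axes share units (``unit_caveat`` records this).
    ``max_asymmetry`` is max |f_{2->1} - f_{1->2}| over the evaluation grid,
    in response units.
    """

    proportional: bool
    c_hat: float
    max_asymmetry: float
    grid_spec: tuple[tuple[float, ...], tuple[float, ...]]
    unit_caveat: str = (
        "c_hat is e1/e2 in the raw dose units of each axis; it is "
        "dimensionless only if both axes share units"
    )

    def to_dict(self) -> dict:
        return {
            "proportional": self.proportional,
            "c_hat": self.c_hat,
            "max_asymmetry": self.max_asymmetry,
            "unit_caveat": self.unit_caveat,
        }


def check_lacc(
    pair: CurvePair,
    doses1: Sequence[float],
    doses2: Sequence[float],
    param_rtol: float = PARAM_RTOL,
) -> LaccReport:
    """Test the LACC for a Hill-curve pair on an evaluation grid.

    For Hill curves the LACC holds iff only the EC50s differ; shared ``y0``
    is guaranteed by the pair, so the test reduces to slopes and maximal
    effects.  The asymmetry surface is evaluated on the grid as the testable
    surrogate for the "for all doses" condition.
    """
    from .null_models import explicit_1to2, explicit_2to1

    d1 = np.asarray(doses1, dtype=float)
    d2 = np.asarray(doses2, dtype=float)
    if d1.size == 0 or d2.size == 0:
        raise ValueError("evaluation grid must be non-empty")
    c1, c2 = pair.curve1, pair.curve2
    span = c1.y0 - min(c1.y_inf, c2.y_inf)
    proportional = (
        abs(c1.s - c2.s) <= param_rtol * abs(c1.s)
        and abs(c1.y_inf - c2.y_inf) <= param_rtol * span
    )
    g1, g2 = np.meshgrid(d1, d2, indexing="ij")
    a = explicit_2to1(pair, g1, g2)
    b = explicit_1to2(pair, g1, g2)
    return LaccReport(
        proportional=bool(proportional),
        c_hat=c1.e / c2.e,
        max_asymmetry=float(np.max(np.abs(a - b))),
        grid_spec=(tuple(d1.tolist()), tuple(d2.tolist())),
    )


@dataclass(frozen=True)
class PopulationLaccTest:
    """Paired Wilcoxon signed-rank tests for the LACC across records.

    ``p_slope`` tests equality of the two fitted slopes per record;
    ``p_yinf`` the same for the maximal effects.  Small p-values indicate
    systematic LACC violation across the population.
    """

    p_slope: float
    p_yinf: float
    n_records: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "p_slope": self.p_slope,
            "p_yinf": self.p_yinf,
            "n_records": self.n_records,
            "degenerate": self.degenerate,
        }


def _paired_wilcoxon(a: np.ndarray, b: np.ndarray, alternative: str) -> tuple[float, bool]:
    diffs = a - b
    if np.all(diffs == 0):
        return 1.0, True  # no evidence either way; flagged degenerate
    res = wilcoxon(a, b, alternative=alternative, zero_method="wilcox")
    return float(res.pvalue), False


def population_lacc_test(
    fits: Iterable[FitResult],
    alternative: str = "two-sided",
) -> PopulationLaccTest:
    """Wilcoxon signed-rank tests on (s1, s2) and (y_inf1, y_inf2) pairs.

    Excluded fits and fits without a usable pair are dropped.  Zero
    differences are removed by the standard signed-rank convention; if all
    differences are zero the p-value is 1 by convention and the result is
    flagged degenerate.
    """
    pairs = [f.pair for f in fits if not f.excluded and f.pair is not None]
    if len(pairs) < 1:
        raise ValueError("no usable (non-excluded) fits")
    s1 = np.array([p.curve1.s for p in pairs])
    s2 = np.array([p.curve2.s for p in pairs])
    y1 = np.array([p.curve1.y_inf for p in pairs])
    y2 = np.array([p.curve2.y_inf for p in pairs])
    p_s, deg_s = _paired_wilcoxon(s1, s2, alternative)
    p_y, deg_y = _paired_wilcoxon(y1, y2, alternative)
    return PopulationLaccTest(
        p_slope=p_s,
        p_yinf=p_y,
        n_records=len(pairs),
        degenerate=deg_s or deg_y,
    )
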