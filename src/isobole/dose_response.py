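"""Four-parameter log-logistic (Hill) dose-response curves.

The conditional response of a cell population to a single compound is modelled
with the four-parameter log-logistic curve

    f(x) = y_inf + (y0 - y_inf) / (1 + (x / e)**s),

where ``y0`` is the response at zero dose, ``y_inf`` the asymptotic response
at infinite dose (the maximal effect), ``e`` the dose reaching half-maximal
effect (EC50) and ``s`` the steepness.  A positive ``s`` with ``y0 > y_inf``
gives the monotonically decreasing, inhibitory orientation used throughout
this package (responses are viability/growth fractions, effect is the inverse
of response).

All null-reference surfaces are built on a :class:`CurvePair`: the two
conditional curves of one record, constrained to share the zero-dose response
``y0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "HillCurve",
    "CurvePair",
    "FitResult",
    "hill_response",
    "hill_inverse",
    "fit_pair",
]

# Multistart slope grid for fitting; covers shallow to steep sigmoids, plus a
# negative start so increasing (pathological) series can be represented and
# caught by the slope-exclusion rule rather than mangled into a poor
# decreasing fit.
_S_STARTS = (0.5, 1.0, 2.0, 4.0, -1.0)


@dataclass(frozen=True)
class HillCurve:
    """One conditional dose-response curve.

    Parameters
    ----------
    y0 : float
        Response at zero dose (dimensionless fraction).
    y_inf : float
        Asymptotic response at infinite dose.  ``y0 > y_inf`` for the
        inhibitory orientation assumed here.
    e : float
        Half-maximal-effect dose, in the dose units of the record's axis.
        Must be positive.
    s : float
        Slope; positive for a monotonically decreasing curve.
    """

    y0: float
    y_inf: float
    e: float
    s: float

    def __post_init__(self) -> None:
        if not (self.e > 0):
            raise ValueError(f"EC50 must be positive, got e={self.e}")
        if not (self.s > 0):
            raise ValueError(f"slope must be positive, got s={self.s}")
        if not (self.y0 > self.y_inf):
            raise ValueError(
                f"inhibitory orientation requires y0 > y_inf, got "
                f"y0={self.y0}, y_inf={self.y_inf}"
            )

    def response(self, x):
        return hill_response(self, x)

    def inverse(self, y):
        return hill_inverse(self, y)

    def to_dict(self) -> dict:
        return {"y0": self.y0, "y_inf": self.y_inf, "e": self.e, "s": self.s}

    @classmethod
    def from_dict(cls, d: dict) -> "HillCurve":
        return cls(y0=d["y0"], y_inf=d["y_inf"], e=d["e"], s=d["s"])


def hill_response(curve: HillCurve, x):
    """Evaluate the Hill curve at dose(s) ``x``.

    ``x`` may be a scalar or array of non-negative doses; ``np.inf`` is
    accepted as a sentinel and maps to ``y_inf``.  ``(x/e)**s`` at ``x = 0``
    is defined as 0, so ``f(0) == y0`` exactly.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(np.isnan(x)):
        raise ValueError("doses must be non-negative and not NaN")
    with np.errstate(over="ignore"):
        ratio = np.where(x > 0, (x / curve.e) ** curve.s, 0.0)
    out = curve.y_inf + (curve.y0 - curve.y_inf) / (1.0 + ratio)
    # x = +inf gives ratio = inf, 1/(1+inf) = 0 -> y_inf already; keep exact.
    out = np.where(np.isinf(x), curve.y_inf, out)
    return float(out) if out.ndim == 0 else out


def hill_inverse(curve: HillCurve, y):
    """Dose at which the curve attains response ``y`` (closed form).

    Returns 0 at ``y == y0`` and the ``np.inf`` sentinel for ``y <= y_inf``
    (the effect is unreachable at any finite dose).  Raises for ``y > y0``,
    where the dose would be negative.
    """
    y = np.asarray(y, dtype=float)
    slack = 1e-12 * (curve.y0 - curve.y_inf)  # float round-off near y0
    if np.any(y > curve.y0 + slack) or np.any(np.isnan(y)):
        raise ValueError(
            f"response above y0={curve.y0} has no non-negative dose"
        )
    y = np.minimum(y, curve.y0)
    span_hi = curve.y0 - y
    span_lo = y - curve.y_inf
    with np.errstate(divide="ignore", over="ignore"):
        out = np.where(
            span_lo > 0,
            curve.e * np.where(span_lo > 0, span_hi / np.maximum(span_lo, 1e-300), 1.0)
            ** (1.0 / curve.s),
            np.inf,
        )
    out = np.where(y == curve.y0, 0.0, out)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CurvePair:
    """The two conditional curves of one record, sharing ``y0``.

    Dose units of the two axes may differ (the pair never converts between
    them); derived quantities such as EC50 ratios then carry a unit caveat.
    """

    curve1: HillCurve
    curve2: HillCurve

    def __post_init__(self) -> None:
        if not np.isclose(self.curve1.y0, self.curve2.y0, rtol=0, atol=1e-12):
            raise ValueError(
                "conditional curves must share the zero-dose response y0"
            )

    @property
    def y0(self) -> float:
        return self.curve1.y0

    def swapped(self) -> "CurvePair":
        return CurvePair(curve1=self.curve2, curve2=self.curve1)

    def to_dict(self) -> dict:
        return {
            "compound_1": self.curve1.to_dict(),
            "compound_2": self.curve2.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CurvePair":
        return cls(
            curve1=HillCurve.from_dict(d["compound_1"]),
            curve2=HillCurve.from_dict(d["compound_2"]),
        )


@dataclass
class FitResult:
    """Outcome of fitting one record's conditional responses.

    ``excluded`` is set iff a fitted slope or EC50 is non-positive (the
    record-filtering rule); other pathologies (e.g. y_inf above y0) are
    reported in ``flags`` but do not exclude the record.
    """

    pair: CurvePair | None
    converged: bool
    loss: float
    excluded: bool
    reason: str = ""
    flags: tuple[str, ...] = ()
    params: dict = field(default_factory=dict)


def _unpack(theta: np.ndarray) -> tuple[float, float, float, float, float, float, float]:
    y0, yinf1, log_e1, s1, yinf2, log_e2, s2 = theta
    # keep e representable when the optimiser wanders far along log10(e)
    e1 = 10.0 ** float(np.clip(log_e1, -150, 150))
    e2 = 10.0 ** float(np.clip(log_e2, -150, 150))
    return y0, yinf1, e1, s1, yinf2, e2, s2


def _curve_eval(x: np.ndarray, y0: float, y_inf: float, e: float, s: float) -> np.ndarray:
    # raw evaluation valid for any sign of s / y ordering, used inside the fit
    out = np.full_like(x, y0, dtype=float)
    pos = x > 0
    with np.errstate(over="ignore"):
        t = np.exp(np.clip(s * np.log(x[pos] / e), -700, 700))
    out[pos] = y_inf + (y0 - y_inf) / (1.0 + t)
    return out


def _e_starts(dose: np.ndarray, resp: np.ndarray, y0_guess: float) -> list[float]:
    """Data-driven EC50 starting value, within the observed dose range.

    The dose at which the series crosses halfway between the zero-dose
    response and its lowest response; falls back to the geometric mean of the
    positive doses when the series never declines.
    """
    pos = dose > 0
    d = dose[pos]
    if d.size == 0:
        return [1.0]
    lo, hi = float(d.min()), float(d.max())
    target = 0.5 * (y0_guess + float(np.min(resp)))
    order = np.argsort(dose)
    r_sorted, d_sorted = resp[order], dose[order]
    cross = np.interp(-target, -r_sorted, d_sorted)  # resp decreasing in dose
    if np.isfinite(cross) and cross > 0:
        return [float(np.clip(cross, lo, hi))]
    return [float(np.exp(np.mean(np.log(d))))]


def fit_pair(
    cond1: Sequence[tuple[float, float]] | np.ndarray,
    cond2: Sequence[tuple[float, float]] | np.ndarray,
) -> FitResult:
    """Fit both conditional series jointly with a shared ``y0``.

    Seven free parameters (shared ``y0``; ``y_inf``, ``e``, ``s`` per curve)
    are estimated by unweighted least squares over the concatenated residuals
    of both series.  EC50s are optimised as ``log10(e)`` for conditioning.
    A deterministic multistart grid (data-driven ``e`` starts within the
    observed dose range, ``s`` in {0.5, 1, 2, 4}) guards against local minima;
    the best sum of squared residuals wins, ties broken by grid order.

    A fit with a non-positive slope or EC50 on either curve is marked
    ``excluded`` (records with negative slopes or negative EC50 values are
    filtered out of downstream analyses).
    """
    c1 = np.asarray(cond1, dtype=float)
    c2 = np.asarray(cond2, dtype=float)
    for c, name in ((c1, "cond1"), (c2, "cond2")):
        if c.ndim != 2 or c.shape[1] != 2 or c.shape[0] < 4:
            raise ValueError(f"{name}: need >= 4 (dose, response) points")
        if not np.all(np.isfinite(c)):
            raise ValueError(f"{name}: doses and responses must be finite")
        if np.any(c[:, 0] < 0):
            raise ValueError(f"{name}: doses must be non-negative")
    if c1.shape[0] + c2.shape[0] < 7:
        raise ValueError("fewer data points than free parameters")

    d1, r1 = c1[:, 0], c1[:, 1]
    d2, r2 = c2[:, 0], c2[:, 1]

    zero_resp = np.concatenate([r1[d1 == 0], r2[d2 == 0]])
    y0_start = float(zero_resp.mean()) if zero_resp.size else float(
        np.concatenate([r1, r2]).max()
    )

    def resid(theta: np.ndarray) -> np.ndarray:
        y0, yinf1, e1, s1, yinf2, e2, s2 = _unpack(theta)
        return np.concatenate(
            [
                _curve_eval(d1, y0, yinf1, e1, s1) - r1,
                _curve_eval(d2, y0, yinf2, e2, s2) - r2,
            ]
        )

    _LN10 = np.log(10.0)

    def _jac_block(x: np.ndarray, y0: float, y_inf: float, e: float, s: float):
        """Columns d/d(y0, y_inf, log10 e, s) of one curve's residuals."""
        t = np.zeros_like(x)
        lnxe = np.zeros_like(x)
        pos = x > 0
        lnxe[pos] = np.log(x[pos] / e)
        with np.errstate(over="ignore"):
            t[pos] = np.exp(np.clip(s * lnxe[pos], -700, 700))
        u = 1.0 / (1.0 + t)
        span_u2t = (y0 - y_inf) * u * u * t
        return u, 1.0 - u, span_u2t * s * _LN10, -span_u2t * lnxe

    def jac(theta: np.ndarray) -> np.ndarray:
        y0, yinf1, e1, s1, yinf2, e2, s2 = _unpack(theta)
        n1, n2 = d1.size, d2.size
        J = np.zeros((n1 + n2, 7))
        dy0, dyinf, dle, ds = _jac_block(d1, y0, yinf1, e1, s1)
        J[:n1, 0], J[:n1, 1], J[:n1, 2], J[:n1, 3] = dy0, dyinf, dle, ds
        dy0, dyinf, dle, ds = _jac_block(d2, y0, yinf2, e2, s2)
        J[n1:, 0], J[n1:, 4], J[n1:, 5], J[n1:, 6] = dy0, dyinf, dle, ds
        return J

    yinf1_start = float(r1.min())
    yinf2_start = float(r2.min())
    e1_starts = _e_starts(d1, r1, y0_start)
    e2_starts = _e_starts(d2, r2, y0_start)

    best = None
    for s0 in _S_STARTS:
        for e1_0, e2_0 in zip(
            e1_starts + [e1_starts[-1]] * (len(e2_starts) - len(e1_starts)),
            e2_starts + [e2_starts[-1]] * (len(e1_starts) - len(e2_starts)),
        ):
            theta0 = np.array(
                [y0_start, yinf1_start, np.log10(e1_0), s0,
                 yinf2_start, np.log10(e2_0), s0]
            )
            try:
                sol = least_squares(resid, theta0, jac=jac, method="lm",
                                    xtol=1e-9, ftol=1e-9, max_nfev=60)
            except Exception:
                continue
            loss = float(np.sum(sol.fun ** 2))
            if best is None or loss < best[0] - 1e-15:
                best = (loss, sol)

    if best is None:
        return FitResult(pair=None, converged=False, loss=np.inf,
                         excluded=False, reason="all multistarts failed")

    loss, sol = best
    y0, yinf1, e1, s1, yinf2, e2, s2 = _unpack(sol.x)
    params = {
        "y0": y0,
        "curve1": {"y0": y0, "y_inf": yinf1, "e": e1, "s": s1},
        "curve2": {"y0": y0, "y_inf": yinf2, "e": e2, "s": s2},
    }

    reasons = []
    if s1 <= 0 or s2 <= 0:
        reasons.append("non-positive slope")
    if e1 <= 0 or e2 <= 0:
        reasons.append("non-positive EC50")
    excluded = bool(reasons)

    flags = []
    if yinf1 >= y0 or yinf2 >= y0:
        flags.append("y_inf >= y0 (non-inhibitory orientation)")

    pair = None
    if not excluded and not flags:
        pair = CurvePair(
            curve1=HillCurve(y0=y0, y_inf=yinf1, e=e1, s=s1),
            curve2=HillCurve(y0=y0, y_inf=yinf2, e=e2, s=s2),
        )
    return FitResult(
        pair=pair,
        converged=bool(sol.success),
        loss=loss,
        excluded=excluded,
        reason="; ".join(reasons),
        flags=tuple(flags),
        params=params,
    )
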