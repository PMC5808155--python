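"""Loewe-additivity null reference surfaces for two-compound checkerboards.

Four models predict the no-interaction response at a dose combination
``(x1, x2)`` from the two conditional Hill curves:

* ``gi`` — the implicit *general isobole equation*: the response ``y`` solving

      x1 / f1^{-1}(y)  +  x2 / f2^{-1}(y)  =  1,

  found here by bracketed bisection (the left side is monotone in ``y``).
* ``2to1`` — the explicit surface f1(x1 + f1^{-1}(f2(x2))): dose ``x2`` is
  replaced by its compound-1 equivalent.
* ``1to2`` — the mirror image f2(f2^{-1}(f1(x1)) + x2).
* ``mean`` / ``geomean`` — the symmetric *explicit mean equation*: the
  arithmetic (default) or geometric mean of the two explicit surfaces.

When the LACC holds (curves differ only in EC50) all four coincide and the
isoboles are parallel straight lines; when it is violated they diverge, the
general isobole equation keeping straight (but non-parallel) isoboles while
the explicit surfaces curve.

Unequal maximal effects are handled by the standard fallbacks: where an
effect of one compound is unreachable by the other (f2(x2) below compound 1's
asymptote), the general isobole equation and f_{2->1} both degrade to
f2(x2), and symmetrically.  The explicit mean remains the average of the two
explicit surfaces with those fallbacks embedded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage import measure

from .dose_response import CurvePair, hill_response

__all__ = [
    "SolverConfig",
    "SurfaceModel",
    "SolverError",
    "MODEL_KINDS",
    "general_isobole",
    "explicit_2to1",
    "explicit_1to2",
    "explicit_mean",
    "surface",
    "isoboles",
    "max_chord_deviation",
]

MODEL_KINDS = ("gi", "2to1", "1to2", "mean", "geomean")


class SolverError(RuntimeError):
    """Root finder failed to converge; carries the last bracket."""

    def __init__(self, msg: str, bracket: tuple[float, float]):
        super().__init__(f"{msg} (last bracket {bracket})")
        self.bracket = bracket


@dataclass(frozen=True)
class SolverConfig:
    """Settings for the general-isobole bisection.

    ``y_tol`` is the absolute response tolerance at which bisection stops;
    ``bracket_pad`` is the relative padding keeping the bracket strictly
    inside (max asymptote, y0), where the dose inverses blow up.
    """

    y_tol: float = 1e-9
    max_iter: int = 200
    bracket_pad: float = 1e-12

    def __post_init__(self) -> None:
        if not (self.y_tol > 0):
            raise ValueError("y_tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


def general_isobole(
    pair: CurvePair, x1: float, x2: float, cfg: SolverConfig | None = None
) -> float:
    """Response of the implicit general isobole equation at ``(x1, x2)``.

    Scalar doses only; the equation is solved afresh per dose combination by
    bisection on g(y) = x1/f1^{-1}(y) + x2/f2^{-1}(y) - 1, which is strictly
    increasing in ``y`` for decreasing curves.  On the axes the conditional
    responses are returned exactly.  Where one compound's effect is
    unreachable by the other, the corresponding term is dropped, giving
    f_GI = f2(x2) (or f1(x1)).
    """
    if cfg is None:
        cfg = SolverConfig()
    x1 = float(x1)
    x2 = float(x2)
    if x1 < 0 or x2 < 0:
        raise ValueError("doses must be non-negative")
    c1, c2 = pair.curve1, pair.curve2
    if x1 == 0 and x2 == 0:
        return pair.y0
    if x2 == 0:
        return float(hill_response(c1, x1))
    if x1 == 0:
        return float(hill_response(c2, x2))

    y0 = pair.y0
    y_floor = max(c1.y_inf, c2.y_inf)
    span = y0 - y_floor
    eps = cfg.bracket_pad * span
    y_1 = float(hill_response(c1, x1))
    y_2 = float(hill_response(c2, x2))
    # effect unreachable by the other compound: drop that term (ties included,
    # to keep the remaining inverse bounded)
    if y_2 <= c1.y_inf + eps:
        return y_2
    if y_1 <= c2.y_inf + eps:
        return y_1

    # plain-math closed-form inverses: this solve runs once per grid cell,
    # so scalar arithmetic beats numpy dispatch by an order of magnitude
    e1, s1_inv, yi1 = c1.e, 1.0 / c1.s, c1.y_inf
    e2, s2_inv, yi2 = c2.e, 1.0 / c2.s, c2.y_inf

    def g(y: float) -> float:
        inv1 = e1 * ((y0 - y) / (y - yi1)) ** s1_inv
        inv2 = e2 * ((y0 - y) / (y - yi2)) ** s2_inv
        return x1 / inv1 + x2 / inv2 - 1.0

    lo = y_floor + eps
    hi = y0 - eps
    if g(lo) >= 0.0:
        # root is within eps of the floor; the padded bracket excludes it
        return lo
    for _ in range(cfg.max_iter):
        if hi - lo <= cfg.y_tol:
            return 0.5 * (lo + hi)
        mid = 0.5 * (lo + hi)
        if g(mid) >= 0.0:
            hi = mid
        else:
            lo = mid
    raise SolverError("general isobole bisection did not converge", (lo, hi))


def _resp(curve, x: np.ndarray) -> np.ndarray:
    # lean Hill evaluation for validated non-negative dose arrays
    with np.errstate(over="ignore"):
        ratio = np.where(x > 0, (x / curve.e) ** curve.s, 0.0)
    return curve.y_inf + (curve.y0 - curve.y_inf) / (1.0 + ratio)


def explicit_2to1(pair: CurvePair, x1, x2):
    """Explicit surface f1(x1 + x1_equiv(x2)); vectorised over dose arrays.

    Where the effect of ``x2`` is unreachable by compound 1 (infinite
    equivalent dose) the surface equals f2(x2).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if np.any(x1 < 0) or np.any(x2 < 0):
        raise ValueError("doses must be non-negative")
    c1 = pair.curve1
    y2 = _resp(pair.curve2, x2)
    # closed-form equivalent dose; reachable iff y2 above compound 1's asymptote
    span_lo = y2 - c1.y_inf
    reachable = span_lo > 0
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        xeq = c1.e * np.where(
            reachable, (pair.y0 - y2) / np.where(reachable, span_lo, 1.0), 0.0
        ) ** (1.0 / c1.s)
    out = np.where(reachable, _resp(c1, x1 + np.where(reachable, xeq, 0.0)), y2)
    return float(out) if out.ndim == 0 else out


def explicit_1to2(pair: CurvePair, x1, x2):
    """Explicit surface f2(f2^{-1}(f1(x1)) + x2); mirror of f_{2->1}.

    Where the effect of ``x1`` is unreachable by compound 2 the surface
    equals f1(x1).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if np.any(x1 < 0) or np.any(x2 < 0):
        raise ValueError("doses must be non-negative")
    c2 = pair.curve2
    y1 = _resp(pair.curve1, x1)
    span_lo = y1 - c2.y_inf
    reachable = span_lo > 0
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        xeq = c2.e * np.where(
            reachable, (pair.y0 - y1) / np.where(reachable, span_lo, 1.0), 0.0
        ) ** (1.0 / c2.s)
    out = np.where(reachable, _resp(c2, np.where(reachable, xeq, 0.0) + x2), y1)
    return float(out) if out.ndim == 0 else out


def explicit_mean(pair: CurvePair, x1, x2, variant: str = "arithmetic"):
    """Symmetric explicit mean of the two equivalent-dose surfaces.

    ``variant='arithmetic'`` (default) averages f_{2->1} and f_{1->2};
    ``'geometric'`` takes the square root of their product with responses
    floored at 0 first (fitted curves may dip below zero).  Both variants,
    with the unreachable-effect fallbacks already embedded in the explicit
    surfaces, reproduce the unequal-maximal-effect form
    (f2(x2) + f2(f2^{-1}(f1(x1)) + x2)) / 2 automatically.
    """
    a = explicit_2to1(pair, x1, x2)
    b = explicit_1to2(pair, x1, x2)
    if variant == "arithmetic":
        out = 0.5 * (np.asarray(a) + np.asarray(b))
    elif variant == "geometric":
        out = np.sqrt(np.maximum(a, 0.0) * np.maximum(b, 0.0))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SurfaceModel:
    """A named null-model evaluator bound to a curve pair.

    ``kind`` is one of ``gi``, ``2to1``, ``1to2``, ``mean``, ``geomean``;
    the solver settings are used by the implicit ``gi`` model only.
    """

    kind: str
    pair: CurvePair
    solver: SolverConfig = field(default_factory=SolverConfig)

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"kind must be one of {MODEL_KINDS}, got {self.kind!r}")

    def evaluate(self, x1, x2):
        """Predicted no-interaction response at dose combination(s)."""
        if self.kind == "gi":
            x1a = np.asarray(x1, dtype=float)
            x2a = np.asarray(x2, dtype=float)
            if x1a.ndim == 0 and x2a.ndim == 0:
                return general_isobole(self.pair, float(x1a), float(x2a), self.solver)
            x1b, x2b = np.broadcast_arrays(x1a, x2a)
            out = np.empty(x1b.shape, dtype=float)
            it = np.nditer(x1b, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                out[idx] = general_isobole(
                    self.pair, float(x1b[idx]), float(x2b[idx]), self.solver
                )
            return out
        if self.kind == "2to1":
            return explicit_2to1(self.pair, x1, x2)
        if self.kind == "1to2":
            return explicit_1to2(self.pair, x1, x2)
        if self.kind == "mean":
            return explicit_mean(self.pair, x1, x2, "arithmetic")
        return explicit_mean(self.pair, x1, x2, "geometric")


def surface(
    model: SurfaceModel,
    doses1: Sequence[float],
    doses2: Sequence[float],
) -> np.ndarray:
    """Evaluate the model on a checkerboard: M[i, j] at (doses1[i], doses2[j]).

    Row 0 / column 0 (zero doses, if present) reproduce the conditional
    curves.  Solver failures are re-raised with the offending cell index.
    """
    d1 = np.asarray(doses1, dtype=float)
    d2 = np.asarray(doses2, dtype=float)
    if d1.size < 1 or d2.size < 1:
        raise ValueError("dose grids must be non-empty")
    if np.any(np.diff(d1) < 0) or np.any(np.diff(d2) < 0):
        raise ValueError("dose grids must be sorted ascending")
    if model.kind == "gi":
        out = np.empty((d1.size, d2.size), dtype=float)
        for i, a in enumerate(d1):
            for j, b in enumerate(d2):
                try:
                    out[i, j] = general_isobole(model.pair, a, b, model.solver)
                except SolverError as err:
                    raise SolverError(
                        f"cell ({i}, {j}) at doses ({a}, {b}): {err}", err.bracket
                    ) from err
        return out
    g1, g2 = np.meshgrid(d1, d2, indexing="ij")
    return np.asarray(model.evaluate(g1, g2))


def isoboles(
    model: SurfaceModel,
    levels: Sequence[float],
    doses1: Sequence[float],
    doses2: Sequence[float],
) -> dict[float, list[np.ndarray]]:
    """Extract iso-effect contours of the model surface.

    Marching squares on the checkerboard matrix, with grid indices mapped
    back to dose coordinates by linear interpolation.  Returns, per level, a
    list of polylines as (n, 2) arrays of (x1, x2) points; a level outside
    the reachable response range yields an empty list.
    """
    d1 = np.asarray(doses1, dtype=float)
    d2 = np.asarray(doses2, dtype=float)
    mat = surface(model, d1, d2)
    out: dict[float, list[np.ndarray]] = {}
    for level in levels:
        segs = []
        if mat.min() < level < mat.max():
            for cont in measure.find_contours(mat, level):
                x1 = np.interp(cont[:, 0], np.arange(d1.size), d1)
                x2 = np.interp(cont[:, 1], np.arange(d2.size), d2)
                segs.append(np.column_stack([x1, x2]))
        out[float(level)] = segs
    return out


def max_chord_deviation(polyline: np.ndarray) -> float:
    """Maximum perpendicular deviation of a polyline from its straight chord,
    as a fraction of the chord length.  Used to quantify isobole straightness.
    """
    p = np.asarray(polyline, dtype=float)
    if p.shape[0] < 3:
        return 0.0
    a, b = p[0], p[-1]
    chord = b - a
    length = float(np.hypot(*chord))
    if length == 0:
        return float(np.max(np.hypot(*(p - a).T)))
    # perpendicular distance via the 2D cross product
    rel = p - a
    dev = np.abs(chord[0] * rel[:, 1] - chord[1] * rel[:, 0]) / length
    return float(np.max(dev)) / length
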