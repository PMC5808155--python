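"""Residual-based comparison of null models against measured checkerboards.

For record *j* with measured responses y_{i,j} and model predictions
ŷ_{i,j}, the per-record summaries are

    bias_j = (1/N) Σ_i (ŷ_{i,j} − y_{i,j})
    mse_j  = (1/N) Σ_i (ŷ_{i,j} − y_{i,j})²

over the N non-excluded cells.  Positive bias means the model over-predicts
the response (under-predicts the effect).  All finite measured cells —
including the conditional row/column — enter the residual set by default.

Model comparison refits each record's conditionals, builds two null surfaces
(by default the implicit general isobole equation and the explicit mean), and
applies a one-sided paired Wilcoxon signed-rank test with the alternative
that the implicit model's mean squared errors are greater.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import wilcoxon

from .dose_response import FitResult, fit_pair
from .null_models import SolverConfig, SurfaceModel, surface
from .synthetic import Record

__all__ = [
    "OutlierRule",
    "EvaluationResult",
    "ModelComparison",
    "residuals",
    "evaluate",
    "compare_models",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OutlierRule:
    """Robust residual-outlier exclusion.

    Off by default (appropriate for synthetic data with known noise).  When
    enabled, cells whose absolute residual exceeds ``mad_factor`` times the
    median absolute deviation of the record's residuals under the evaluated
    model are excluded.  This rule is this package's own choice of a robust
    screen; studies on real screens typically apply some such filter.
    """

    enabled: bool = False
    mad_factor: float = 5.0


@dataclass(frozen=True)
class EvaluationResult:
    """Per-record residual summary for one model."""

    record_id: str
    model_kind: str
    bias: float
    mse: float
    n_points: int
    n_outliers: int


@dataclass(frozen=True)
class ModelComparison:
    """Paired per-record (mse, bias) for two models plus the Wilcoxon test.

    ``p_mse`` is the one-sided signed-rank p-value for the alternative that
    the first model's mse values are greater than the second's (zeros
    dropped); degenerate when all paired differences vanish.
    """

    model_a: str
    model_b: str
    mse_pairs: tuple[tuple[float, float], ...]
    bias_pairs: tuple[tuple[float, float], ...]
    p_mse: float
    n: int
    degenerate: bool = False
    dropped: tuple[str, ...] = ()


def residuals(record: Record, model: SurfaceModel, combination_only: bool = False):
    """Per-cell residuals (predicted − observed) for one record.

    Returns (dose_pairs, residuals) arrays over the finite measured cells;
    ``combination_only`` drops the conditional (any-zero-dose) cells.
    """
    obs = record.responses
    if obs.size == 0 or not np.any(np.isfinite(obs)):
        raise ValueError("record has no finite measured responses")
    pred = surface(model, record.design.doses1, record.design.doses2)
    d1 = np.asarray(record.design.doses1)
    d2 = np.asarray(record.design.doses2)
    g1, g2 = np.meshgrid(d1, d2, indexing="ij")
    keep = np.isfinite(obs)
    if combination_only:
        keep &= (g1 > 0) & (g2 > 0)
    res = (pred - obs)[keep]
    pairs = np.column_stack([g1[keep], g2[keep]])
    return pairs, res


def evaluate(
    record: Record,
    model: SurfaceModel,
    outlier_rule: OutlierRule | None = None,
    combination_only: bool = False,
) -> EvaluationResult:
    """Bias and mean squared error of one model on one record."""
    _, res = residuals(record, model, combination_only=combination_only)
    n_total = res.size
    if outlier_rule is not None and outlier_rule.enabled and n_total > 2:
        mad = np.median(np.abs(res - np.median(res)))
        if mad > 0:
            keep = np.abs(res) <= outlier_rule.mad_factor * mad
            res = res[keep]
    if res.size == 0:
        raise ValueError("all residuals excluded as outliers")
    return EvaluationResult(
        record_id=record.id,
        model_kind=model.kind,
        bias=float(np.mean(res)),
        mse=float(np.mean(res**2)),
        n_points=int(res.size),
        n_outliers=int(n_total - res.size),
    )


def compare_models(
    records: list[Record],
    fits: list[FitResult] | None = None,
    model_a: str = "gi",
    model_b: str = "mean",
    alternative: str = "greater",
    solver: SolverConfig | None = None,
    outlier_rule: OutlierRule | None = None,
) -> ModelComparison:
    """Paired bias/MSE comparison of two null models across records.

    Each record's conditional series are fitted (unless precomputed fits are
    supplied); excluded fits and records on which a surface solver fails are
    dropped with a logged reason.  The signed-rank test is one-sided by
    default with the alternative "model_a's mse greater".
    """
    if not records:
        raise ValueError("no records supplied")
    if fits is None:
        fits = []
        for rec in records:
            cond1, cond2 = rec.conditionals()
            fits.append(fit_pair(cond1, cond2))
    if len(fits) != len(records):
        raise ValueError("fits and records length mismatch")

    solver = solver or SolverConfig()
    mse_pairs, bias_pairs, dropped = [], [], []
    for rec, fit in zip(records, fits):
        if fit.excluded or fit.pair is None:
            dropped.append(f"{rec.id}: fit excluded ({fit.reason or 'no pair'})")
            continue
        try:
            ev_a = evaluate(rec, SurfaceModel(model_a, fit.pair, solver), outlier_rule)
            ev_b = evaluate(rec, SurfaceModel(model_b, fit.pair, solver), outlier_rule)
        except Exception as err:  # solver failure on one record is not fatal
            dropped.append(f"{rec.id}: {err}")
            log.warning("record %s dropped: %s", rec.id, err)
            continue
        mse_pairs.append((ev_a.mse, ev_b.mse))
        bias_pairs.append((ev_a.bias, ev_b.bias))

    if len(mse_pairs) < 6:
        raise ValueError(
            f"need >= 6 usable records for the paired test, got {len(mse_pairs)}"
        )
    a = np.array([m[0] for m in mse_pairs])
    b = np.array([m[1] for m in mse_pairs])
    # mse differences within what the GI solver tolerance alone can induce
    # carry no information about the models; treat them as ties
    solver_scale = 2.0 * solver.y_tol * (np.sqrt(max(a.max(), b.max())) + solver.y_tol)
    if np.max(np.abs(a - b)) <= solver_scale:
        p, degenerate = 1.0, True
    else:
        res = wilcoxon(a, b, alternative=alternative, zero_method="wilcox")
        p, degenerate = float(res.pvalue), False
    return ModelComparison(
        model_a=model_a,
        model_b=model_b,
        mse_pairs=tuple(mse_pairs),
        bias_pairs=tuple(bias_pairs),
        p_mse=p,
        n=len(mse_pairs),
        degenerate=degenerate,
        dropped=tuple(dropped),
    )
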