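"""Readers and writers for records, Hill parameters and result tables.

Two CSV dialects for checkerboard records:

* ``long`` — columns ``dose_1,dose_2,response``, one row per cell; missing
  cells simply absent.
* ``matrix`` — first row holds the compound-2 doses, first column the
  compound-1 doses, cell (0, 0) blank; empty cells mark missing data.

Doses are serialised ascending regardless of input order.  Floats are written
with 9 significant digits so output is deterministic and diff-stable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dose_response import CurvePair
from .evaluation import EvaluationResult, ModelComparison, OutlierRule
from .null_models import SolverConfig
from .synthetic import DoseDesign, Record

__all__ = [
    "RunConfig",
    "read_record",
    "write_record",
    "read_pair_json",
    "write_pair_json",
    "write_results_csv",
    "write_comparison_json",
    "write_isoboles_csv",
    "write_matrix_csv",
]

_FMT = "%.9g"


def _fmt(x: float) -> str:
    return _FMT % x


@dataclass(frozen=True)
class RunConfig:
    """Bundled solver/evaluation/design defaults; JSON round-trips losslessly."""

    solver: SolverConfig = field(default_factory=SolverConfig)
    outlier_rule: OutlierRule = field(default_factory=OutlierRule)
    design_name: str = "dilution6"
    d_max1: float = 2.5
    d_max2: float = 125.0
    noise_sd: float = 0.02
    seed: int | None = None
    verbosity: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["solver"] = SolverConfig(**d["solver"])
        d["outlier_rule"] = OutlierRule(**d["outlier_rule"])
        return cls(**d)


def read_record(path: str | Path, dialect: str = "long", record_id: str | None = None) -> Record:
    """Read a checkerboard record from CSV (``long`` or ``matrix`` dialect)."""
    path = Path(path)
    rid = record_id or path.stem
    if dialect == "long":
        df = pd.read_csv(path)
        required = {"dose_1", "dose_2", "response"}
        if not required.issubset(df.columns):
            raise ValueError(f"long dialect needs columns {sorted(required)}")
        if np.any(df["dose_1"] < 0) or np.any(df["dose_2"] < 0):
            raise ValueError("negative dose in record file")
        if df.duplicated(subset=["dose_1", "dose_2"]).any():
            raise ValueError("duplicate dose pair in record file")
        d1 = np.unique(df["dose_1"].to_numpy(dtype=float))
        d2 = np.unique(df["dose_2"].to_numpy(dtype=float))
        mat = np.full((d1.size, d2.size), np.nan)
        i = np.searchsorted(d1, df["dose_1"].to_numpy(dtype=float))
        j = np.searchsorted(d2, df["dose_2"].to_numpy(dtype=float))
        mat[i, j] = df["response"].to_numpy(dtype=float)
    elif dialect == "matrix":
        rows = [r for r in path.read_text().splitlines() if r.strip()]
        widths = {r.count(",") for r in rows}
        if len(widths) != 1:
            raise ValueError("matrix dialect requires a rectangular grid")
        df = pd.read_csv(path, header=None, skip_blank_lines=False)
        arr = df.to_numpy(dtype=float)  # raises on non-numeric junk
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("matrix dialect needs a dose header row and column")
        d2 = arr[0, 1:]
        d1 = arr[1:, 0]
        if np.any(d1 < 0) or np.any(d2 < 0) or np.any(np.isnan(d1)) or np.any(np.isnan(d2)):
            raise ValueError("matrix dialect dose headers must be non-negative numbers")
        mat = arr[1:, 1:]
        order1, order2 = np.argsort(d1), np.argsort(d2)
        d1, d2 = d1[order1], d2[order2]
        mat = mat[np.ix_(order1, order2)]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    design = DoseDesign(tuple(d1), tuple(d2), "custom")
    return Record(id=rid, design=design, responses=mat)


def write_record(record: Record, path: str | Path, dialect: str = "long") -> None:
    """Write a record to CSV; missing (NaN) cells are omitted / left blank."""
    path = Path(path)
    d1 = np.asarray(record.design.doses1)
    d2 = np.asarray(record.design.doses2)
    if dialect == "long":
        lines = ["dose_1,dose_2,response"]
        for i, a in enumerate(d1):
            for j, b in enumerate(d2):
                v = record.responses[i, j]
                if np.isfinite(v):
                    lines.append(f"{_fmt(a)},{_fmt(b)},{_fmt(v)}")
        path.write_text("\n".join(lines) + "\n")
    elif dialect == "matrix":
        lines = ["," + ",".join(_fmt(b) for b in d2)]
        for i, a in enumerate(d1):
            cells = [
                _fmt(record.responses[i, j]) if np.isfinite(record.responses[i, j]) else ""
                for j in range(d2.size)
            ]
            lines.append(_fmt(a) + "," + ",".join(cells))
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def write_pair_json(pair: CurvePair, path: str | Path, meta: dict | None = None) -> None:
    d = pair.to_dict()
    if meta:
        d["meta"] = meta
    Path(path).write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")


def read_pair_json(path: str | Path) -> CurvePair:
    return CurvePair.from_dict(json.loads(Path(path).read_text()))


def write_matrix_csv(mat: np.ndarray, doses1, doses2, path: str | Path) -> None:
    """Surface matrix with dose header row and column (matrix dialect)."""
    rec = Record(
        id="surface",
        design=DoseDesign(tuple(doses1), tuple(doses2), "custom"),
        responses=mat,
    )
    write_record(rec, path, dialect="matrix")


def write_results_csv(results: list[EvaluationResult], path: str | Path) -> None:
    lines = ["record_id,model,bias,mse,n_points,n_outliers"]
    for r in results:
        lines.append(
            f"{r.record_id},{r.model_kind},{_fmt(r.bias)},{_fmt(r.mse)},"
            f"{r.n_points},{r.n_outliers}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_comparison_json(cmp: ModelComparison, path: str | Path) -> None:
    d = {
        "model_a": cmp.model_a,
        "model_b": cmp.model_b,
        "p_mse": cmp.p_mse,
        "n": cmp.n,
        "degenerate": cmp.degenerate,
        "dropped": list(cmp.dropped),
        "mse_pairs": [list(p) for p in cmp.mse_pairs],
        "bias_pairs": [list(p) for p in cmp.bias_pairs],
    }
    Path(path).write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")


def write_isoboles_csv(contours: dict[float, list[np.ndarray]], path: str | Path) -> None:
    """Contour polylines as rows of (level, segment_id, x1, x2)."""
    lines = ["level,segment_id,x1,x2"]
    for level in sorted(contours):
        for seg_id, seg in enumerate(contours[level]):
            for x1, x2 in seg:
                lines.append(f"{_fmt(level)},{seg_id},{_fmt(x1)},{_fmt(x2)}")
    Path(path).write_text("\n".join(lines) + "\n")
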