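"""File formats: trial-matrix CSV (tidy and wide), curve TSV, JSON reports.

CSV dialect: comma-separated, UTF-8, header required, dot decimal.  The tidy
layout is one row per (subject, trial) with columns
``subject_id,trial_index,amplitude_mv`` (1-based trial index, amplitudes in
mV); the wide layout is one row per subject with columns
``subject_id,trial_1..trial_n``.

Curve files are two-column tab-separated ``n<TAB>value`` with a single
leading ``#`` parameter line.  Reports are JSON with a fixed schema
(``tool_version, subcommand, params, results, warnings``) in which every
parameter that produced a number is echoed, so each report is reproducible
from its own contents.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import IO, Any

import pandas as pd

from . import __version__
from .estimate import TrialMatrix
from .planner import DomainError
from .simulate import ErrorCurve

__all__ = [
    "read_trials_csv",
    "write_trials_csv",
    "write_curve_tsv",
    "read_curve_tsv",
    "make_report",
    "write_report",
    "percent",
]


def read_trials_csv(path: str | Path | IO[str], layout: str = "tidy") -> TrialMatrix:
    """Read a trial matrix from CSV in the ``tidy`` or ``wide`` layout."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pandas raises several parser error types
        raise DomainError(f"unparseable CSV: {exc}") from exc
    if layout == "tidy":
        return TrialMatrix.from_tidy(df)
    if layout == "wide":
        return TrialMatrix.from_wide(df)
    raise DomainError(f"unknown layout {layout!r}; use 'tidy' or 'wide'")


def write_trials_csv(data: TrialMatrix, path: str | Path | IO[str],
                     layout: str = "tidy") -> None:
    """Write a trial matrix as CSV; byte-stable for a given matrix."""
    if layout == "tidy":
        df = data.to_tidy()
    elif layout == "wide":
        n_max = int(data.trial_counts.max())
        rows = []
        for sid, t in zip(data.subjects, data.trials):
            row: dict[str, Any] = {"subject_id": sid}
            row.update({f"trial_{i + 1}": t[i] if i < t.size else None
                        for i in range(n_max)})
            rows.append(row)
        df = pd.DataFrame(rows)
    else:
        raise DomainError(f"unknown layout {layout!r}; use 'tidy' or 'wide'")
    df.to_csv(path, index=False)


def write_curve_tsv(curve: ErrorCurve, path: str | Path | IO[str],
                    params: dict[str, Any] | None = None,
                    value_name: str = "value") -> None:
    """Write ``n<TAB>value`` rows with one leading ``#`` parameter line."""
    header = "# " + json.dumps(params or {}, sort_keys=True)
    lines = [header, f"n\t{value_name}"]
    lines += [f"{int(n)}\t{v:.10g}" for n, v in zip(curve.n_trials, curve.values)]
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)  # type: ignore[union-attr]
    else:
        Path(path).write_text(text, encoding="utf-8")


def read_curve_tsv(path: str | Path) -> ErrorCurve:
    df = pd.read_csv(path, sep="\t", comment="#")
    return ErrorCurve(n_trials=df.iloc[:, 0].to_numpy(),
                      values=df.iloc[:, 1].to_numpy(dtype=float))


def percent(x: float) -> str:
    """One-decimal percent string, the convention used in report tables."""
    if math.isinf(x):
        return "inf"
    return f"{100 * x:.1f}%"


def _jsonable(obj: Any) -> Any:
    """Make params/results JSON-safe; inf is encoded as the string 'inf'."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float):
        if math.isinf(obj):
            return "inf" if obj > 0 else "-inf"
        return obj
    if hasattr(obj, "item"):  # numpy scalar
        return _jsonable(obj.item())
    return obj


def make_report(subcommand: str, params: dict[str, Any],
                results: dict[str, Any],
                warnings: list[str] | None = None) -> dict[str, Any]:
    return {
        "tool_version": __version__,
        "subcommand": subcommand,
        "params": _jsonable(params),
        "results": _jsonable(results),
        "warnings": list(warnings or []),
    }


def write_report(report: dict[str, Any], path: str | Path | IO[str] | None) -> str:
    """Serialize a report; write to ``path`` when given, return the JSON text."""
    text = json.dumps(report, indent=2, sort_keys=False) + "\n"
    if path is None:
        return text
    if hasattr(path, "write"):
        path.write(text)  # type: ignore[union-attr]
    else:
        Path(path).write_text(text, encoding="utf-8")
    return text
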