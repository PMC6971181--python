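"""Deterministic report writing.

Three artifacts per run: ``per_case.csv`` (one row per case),
``cohort_summary.json`` and ``centroid_cloud.csv``. Floats are formatted
at 6 significant digits and column order is fixed, so re-running on the
same inputs yields byte-identical files.
"""

from __future__ import annotations

import csv
import json
import os

import pandas as pd

from .errors import LggspatError
from .summary import CohortSummary

__all__ = ["write_reports", "format_float"]


def format_float(x: object) -> object:
    if x is None:
        return ""
    if isinstance(x, float):
        if x != x:  # NaN
            return ""
        return f"{x:.6g}"
    return x


def _write_csv(df: pd.DataFrame, path: str) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(df.columns.tolist())
        for row in df.itertuples(index=False):
            writer.writerow([format_float(v) for v in row])


def _round_floats(obj):
    if isinstance(obj, float):
        return float(f"{obj:.6g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v) for v in obj]
    return obj


def write_reports(
    per_case: pd.DataFrame,
    summary: CohortSummary,
    centroid_cloud: pd.DataFrame,
    out_dir: str | os.PathLike,
) -> dict[str, str]:
    """Write all three report files; returns {name: path}."""
    if len(per_case) == 0:
        raise LggspatError("refusing to write reports for an empty result set")
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "per_case": os.path.join(out_dir, "per_case.csv"),
        "cohort_summary": os.path.join(out_dir, "cohort_summary.json"),
        "centroid_cloud": os.path.join(out_dir, "centroid_cloud.csv"),
    }
    _write_csv(per_case, paths["per_case"])
    with open(paths["cohort_summary"], "w", encoding="utf-8") as fh:
        json.dump(_round_floats(summary.to_dict()), fh, indent=2)
        fh.write("\n")
    _write_csv(centroid_cloud, paths["centroid_cloud"])
    return paths
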