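"""Cohort-level aggregation: descriptive statistics and subgroup patterns.

Produces the three table shapes a transformation-pattern study reports:
median (Q1-Q3) volumes, category tallies (clinical local/distant/combined,
overlay within, multifocal, small residual), and local/within proportions
per molecular and treatment subgroup. Only descriptive statistics — the
analysis is pattern description, not inference.

All functions consume the flat per-case table produced by
:func:`per_case_table`, which is also what gets written to ``per_case.csv``
— so summaries can be recomputed from a previous run's export without
reloading any masks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cases import Histology, PatientCase
from .centroid import CentroidOffset
from .classify import COMBINED, DISTANT, LOCAL, NOT_EVALUABLE, WITHIN, SpatialClassification

__all__ = ["CohortSummary", "per_case_table", "describe_cohort",
           "count_categories", "summarize_patterns", "build_summary"]

PER_CASE_COLUMNS = [
    "case_id", "histology", "prior_resection", "prior_chemo", "prior_rt",
    "has_preoperative", "clinical_category", "n_foci", "multifocal",
    "focus_distances_mm", "overlay_category", "overlap_ml",
    "transformation_volume_ml", "pre_transformation_volume_ml",
    "preoperative_volume_ml", "residual_lt_threshold",
    "u_x", "u_y", "u_z", "distance_ratio", "inside_cube", "multifocal_caveat",
]

SUBGROUP_ROWS = [
    ("oligodendroglioma", lambda r: r["histology"] == Histology.OLIGODENDROGLIOMA.value),
    ("astro_idh_mut", lambda r: r["histology"] == Histology.ASTRO_IDH_MUT.value),
    ("astro_idh_wt", lambda r: r["histology"] == Histology.ASTRO_IDH_WT.value),
    ("chemo_prior", lambda r: bool(r["prior_chemo"])),
    ("rt_prior", lambda r: bool(r["prior_rt"])),
    ("no_resection_prior", lambda r: not bool(r["prior_resection"])),
    ("resection_prior", lambda r: bool(r["prior_resection"])),
]


def _pct(num: int, den: int) -> int | None:
    """Percent rounded half-up to the nearest integer, None for 0/0."""
    if den == 0:
        return None
    return int(math.floor(100.0 * num / den + 0.5))


def _fraction_str(num: int, den: int) -> str:
    pct = _pct(num, den)
    return f"{num}/{den} ({'–' if pct is None else pct})"


@dataclass(frozen=True)
class CohortSummary:
    """Aggregated cohort output: descriptive, counts and subgroup blocks."""

    descriptive: list[dict]
    counts: list[dict]
    subgroup_patterns: list[dict]
    n_cases: int

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "n_cases": self.n_cases,
            "descriptive": self.descriptive,
            "counts": self.counts,
            "subgroup_patterns": self.subgroup_patterns,
        }


def per_case_table(
    records: list[tuple[PatientCase, SpatialClassification, CentroidOffset | None]],
) -> pd.DataFrame:
    """Flatten (case, classification, offset) triples into one row per case."""
    rows = []
    for case, cls, offset in records:
        rows.append({
            "case_id": case.case_id,
            "histology": case.histology.value,
            "prior_resection": bool(case.prior_resection),
            "prior_chemo": bool(case.prior_chemo),
            "prior_rt": bool(case.prior_rt),
            "has_preoperative": case.has_preoperative,
            "clinical_category": cls.clinical_category,
            "n_foci": cls.n_foci,
            "multifocal": cls.multifocal,
            "focus_distances_mm": ";".join(f"{d:.6g}" for d in cls.focus_distances_mm),
            "overlay_category": cls.overlay_category,
            "overlap_ml": cls.overlap_ml,
            "transformation_volume_ml": cls.transformation_volume_ml,
            "pre_transformation_volume_ml": cls.pre_transformation_volume_ml,
            "preoperative_volume_ml": cls.preoperative_volume_ml,
            "residual_lt_threshold": cls.residual_lt_threshold,
            "u_x": offset.u[0] if offset is not None else np.nan,
            "u_y": offset.u[1] if offset is not None else np.nan,
            "u_z": offset.u[2] if offset is not None else np.nan,
            "distance_ratio": offset.distance_ratio if offset is not None else np.nan,
            "inside_cube": offset.inside_cube if offset is not None else None,
            "multifocal_caveat": offset.multifocal_caveat if offset is not None else None,
        })
    return pd.DataFrame(rows, columns=PER_CASE_COLUMNS)


_DESCRIPTIVE_METRICS = [
    ("preoperative_volume_ml", "preoperative tumor volume (ml)"),
    ("pre_transformation_volume_ml", "pre-transformation tumor volume (ml)"),
    ("transformation_volume_ml", "transformation volume (ml)"),
]


def describe_cohort(per_case: pd.DataFrame) -> list[dict]:
    """Median (Q1-Q3) volume rows; n counts only cases with the mask present.

    Quartiles use linear interpolation between order statistics (the
    common scientific-software default).
    """
    out = []
    for column, name in _DESCRIPTIVE_METRICS:
        values = pd.to_numeric(per_case[column], errors="coerce").dropna().to_numpy()
        row: dict = {"metric": name, "n": int(values.size)}
        if values.size:
            q1, med, q3 = np.percentile(values, [25, 50, 75])
            row.update(median=float(med), q1=float(q1), q3=float(q3))
        else:
            row.update(median=None, q1=None, q3=None)
        out.append(row)
    return out


def count_categories(per_case: pd.DataFrame) -> list[dict]:
    """Category tallies with explicit denominators.

    The three clinical categories are mutually exclusive; the overlay
    denominator counts only evaluable cases (a preoperative mask was
    available for the chosen reference).
    """
    n = len(per_case)
    clinical = per_case["clinical_category"]
    overlay = per_case["overlay_category"]
    evaluable = int((overlay != NOT_EVALUABLE).sum())
    rows = [
        ("clinical_local", int((clinical == LOCAL).sum()), n),
        ("clinical_distant", int((clinical == DISTANT).sum()), n),
        ("clinical_combined", int((clinical == COMBINED).sum()), n),
        ("overlay_within", int((overlay == WITHIN).sum()), evaluable),
        ("multifocal", int(per_case["multifocal"].astype(bool).sum()), n),
        ("residual_lt_threshold", int(per_case["residual_lt_threshold"].astype(bool).sum()), n),
    ]
    return [
        {"metric": name, "numerator": num, "denominator": den, "percent": _pct(num, den)}
        for name, num, den in rows
    ]


def summarize_patterns(per_case: pd.DataFrame) -> list[dict]:
    """Subgroup rows x {clinical local, overlay within} proportion columns.

    Rows are not mutually exclusive: a case contributes to its histology
    row and to every treatment row that applies. The overlay denominator
    per row counts only evaluable cases in that subgroup.
    """
    out = []
    for name, predicate in SUBGROUP_ROWS:
        sub = per_case[per_case.apply(predicate, axis=1)] if len(per_case) else per_case
        n_clin = len(sub)
        local_n = int((sub["clinical_category"] == LOCAL).sum()) if n_clin else 0
        evaluable = sub[sub["overlay_category"] != NOT_EVALUABLE] if n_clin else sub
        n_model = len(evaluable)
        within_n = int((evaluable["overlay_category"] == WITHIN).sum()) if n_model else 0
        out.append({
            "subgroup": name,
            "clinical_local_n": local_n,
            "clinical_local_den": n_clin,
            "clinical_local": _fraction_str(local_n, n_clin),
            "overlay_within_n": within_n,
            "overlay_within_den": n_model,
            "overlay_within": _fraction_str(within_n, n_model),
        })
    return out


def build_summary(per_case: pd.DataFrame) -> CohortSummary:
    """Full cohort summary from the per-case table."""
    if len(per_case) == 0:
        raise ValueError("cannot summarize an empty cohort")
    return CohortSummary(
        descriptive=describe_cohort(per_case),
        counts=count_categories(per_case),
        subgroup_patterns=summarize_patterns(per_case),
        n_cases=len(per_case),
    )
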