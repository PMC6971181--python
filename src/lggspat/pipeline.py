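"""End-to-end orchestration: classify a cohort and aggregate results."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cases import AnalysisConfig, PatientCase
from .centroid import CentroidOffset, cohort_centroid_cloud, normalized_offset
from .classify import SpatialClassification, classify_case
from .summary import CohortSummary, build_summary, per_case_table

__all__ = ["CohortResult", "analyze_case", "analyze_cohort"]


@dataclass(frozen=True)
class CohortResult:
    """Everything one analysis run produces."""

    records: list[tuple[PatientCase, SpatialClassification, CentroidOffset | None]]
    per_case: pd.DataFrame
    summary: CohortSummary
    centroid_cloud: pd.DataFrame


def analyze_case(
    case: PatientCase, config: AnalysisConfig | None = None
) -> tuple[SpatialClassification, CentroidOffset | None]:
    """Classify one case; compute its unit-cube offset when a preoperative mask exists."""
    config = config or AnalysisConfig()
    classification = classify_case(case, config)
    offset = None
    if case.has_preoperative:
        offset = normalized_offset(
            case.preoperative, case.transformation, multifocal_caveat=classification.multifocal
        )
    return classification, offset


def analyze_cohort(cases: list[PatientCase], config: AnalysisConfig | None = None) -> CohortResult:
    """Run both spatial models over a cohort and build all summary tables."""
    config = config or AnalysisConfig()
    records = []
    for case in cases:
        classification, offset = analyze_case(case, config)
        records.append((case, classification, offset))
    per_case = per_case_table(records)
    return CohortResult(
        records=records,
        per_case=per_case,
        summary=build_summary(per_case),
        centroid_cloud=cohort_centroid_cloud(records),
    )
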