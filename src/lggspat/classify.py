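"""Spatial classification of malignant transformation.

Two complementary models are implemented:

* the **clinical rule**: every transformation focus strictly closer than
  2 cm (configurable) to the T2/FLAIR tumor on the pre-transformation scan
  is *local*, foci clearly separated are *distant*, and a patient with
  both kinds has a *combined* transformation;
* the **overlay model**: a transformation is *within* the reference tumor
  volume (preoperative by default) when the registered masks intersect.
  Any overlap counts, so a clinically combined case with one overlapping
  focus is still "within" — overlap takes precedence.

Additionally the transformation mask is split into connected foci to
assess multifocality, and small pre-transformation residual volumes are
flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cases import AnalysisConfig, PatientCase
from .errors import DegenerateInputError, EmptyMaskError, LggspatError
from .geometry import (
    connected_components,
    distance_field_mm,
    mask_volume_ml,
    overlap_volume_ml,
)
from .volume import LabelVolume

__all__ = [
    "FocusResult",
    "SpatialClassification",
    "classify_clinical",
    "classify_overlay",
    "count_foci",
    "residual_volume_flag",
    "classify_case",
]

LOCAL = "local"
DISTANT = "distant"
COMBINED = "combined"
WITHIN = "within"
OUTSIDE = "outside"
NOT_EVALUABLE = "not_evaluable"


@dataclass(frozen=True)
class FocusResult:
    """One transformation focus: its size rank, volume and distance label."""

    focus_index: int
    volume_ml: float
    min_distance_mm: float
    label: str  # LOCAL or DISTANT


@dataclass(frozen=True)
class SpatialClassification:
    """Full per-case spatial result of both models."""

    case_id: str
    clinical_category: str  # LOCAL / DISTANT / COMBINED
    foci: tuple[FocusResult, ...]
    n_foci: int
    multifocal: bool
    overlay_category: str  # WITHIN / OUTSIDE / NOT_EVALUABLE
    overlap_ml: float
    transformation_volume_ml: float
    pre_transformation_volume_ml: float
    preoperative_volume_ml: float | None
    residual_lt_threshold: bool
    focus_distances_mm: tuple[float, ...] = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "focus_distances_mm", tuple(f.min_distance_mm for f in self.foci)
        )


def _surviving_foci(transformation: LabelVolume, config: AnalysisConfig):
    """Connected foci at or above the component volume floor, largest first."""
    comps = connected_components(transformation, config.connectivity)
    kept = [i for i in range(1, comps.n + 1) if comps.sizes_ml[i - 1] >= config.min_component_ml]
    return comps, kept


def classify_clinical(
    transformation: LabelVolume,
    pre_transformation: LabelVolume,
    config: AnalysisConfig | None = None,
) -> tuple[str, list[FocusResult]]:
    """Apply the < 2 cm rule per focus against the pre-transformation tumor.

    The transformation mask is split into connected components; components
    below ``config.min_component_ml`` are discarded as noise. Each
    surviving focus is *local* iff its minimum surface distance to the
    pre-transformation mask is strictly below ``config.local_threshold_mm``
    (a focus at exactly the threshold is distant). The case category is
    local/distant when all foci agree and combined otherwise.
    """
    config = config or AnalysisConfig()
    if transformation.is_empty or pre_transformation.is_empty:
        raise EmptyMaskError("clinical classification requires non-empty masks")
    comps, kept = _surviving_foci(transformation, config)
    if not kept:
        raise DegenerateInputError(
            f"all {comps.n} transformation component(s) are below the "
            f"{config.min_component_ml} ml size floor"
        )
    dist = distance_field_mm(pre_transformation)
    foci: list[FocusResult] = []
    for rank, i in enumerate(kept, start=1):
        d = float(dist[comps.labels == i].min())
        foci.append(
            FocusResult(
                focus_index=rank,
                volume_ml=float(comps.sizes_ml[i - 1]),
                min_distance_mm=d,
                label=LOCAL if d < config.local_threshold_mm else DISTANT,
            )
        )
    labels = {f.label for f in foci}
    category = labels.pop() if len(labels) == 1 else COMBINED
    return category, foci


def classify_overlay(
    transformation: LabelVolume,
    reference: LabelVolume | None,
    config: AnalysisConfig | None = None,
) -> tuple[str, float]:
    """Overlay model: "within" iff the masks share >= min_overlap_voxels.

    Returns ``(category, overlap_ml)``; ``not_evaluable`` when the
    reference mask is absent.
    """
    config = config or AnalysisConfig()
    if reference is None:
        return NOT_EVALUABLE, 0.0
    overlap = overlap_volume_ml(transformation, reference)
    n_overlap = round(overlap * 1000.0 / transformation.voxel_volume_mm3)
    category = WITHIN if n_overlap >= config.min_overlap_voxels else OUTSIDE
    return category, overlap


def count_foci(
    transformation: LabelVolume, config: AnalysisConfig | None = None
) -> tuple[int, bool]:
    """Number of connected foci at/above the size floor, and multifocality."""
    config = config or AnalysisConfig()
    _, kept = _surviving_foci(transformation, config)
    return len(kept), len(kept) >= 2


def residual_volume_flag(
    pre_transformation: LabelVolume, config: AnalysisConfig | None = None
) -> bool:
    """True iff the pre-transformation tumor is strictly below the residual cutoff."""
    config = config or AnalysisConfig()
    return mask_volume_ml(pre_transformation) < config.residual_threshold_ml


def classify_case(case: PatientCase, config: AnalysisConfig | None = None) -> SpatialClassification:
    """Run both spatial models plus multifocality and volume metrics on a case."""
    config = config or AnalysisConfig()
    try:
        clinical_category, foci = classify_clinical(
            case.transformation, case.pre_transformation, config
        )
        reference = (
            case.preoperative
            if config.overlay_reference == "preoperative"
            else case.pre_transformation
        )
        overlay_category, overlap = classify_overlay(case.transformation, reference, config)
    except LggspatError as exc:
        raise type(exc)(f"case {case.case_id}: {exc}") from exc
    n_foci = len(foci)
    return SpatialClassification(
        case_id=case.case_id,
        clinical_category=clinical_category,
        foci=tuple(foci),
        n_foci=n_foci,
        multifocal=n_foci >= 2,
        overlay_category=overlay_category,
        overlap_ml=overlap,
        transformation_volume_ml=mask_volume_ml(case.transformation),
        pre_transformation_volume_ml=mask_volume_ml(case.pre_transformation),
        preoperative_volume_ml=(
            mask_volume_ml(case.preoperative) if case.preoperative is not None else None
        ),
        residual_lt_threshold=residual_volume_flag(case.pre_transformation, config),
    )
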