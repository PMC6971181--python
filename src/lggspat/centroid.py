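"""Normalized centroid displacement: the "unitary cube" model.

The preoperative tumor is abstracted as a unit cube: the cube center is
the tumor centroid and the cube faces are the extremes of the tumor's
world-axis bounding box. The transformation centroid is then expressed in
these normalized coordinates,

    u_i = (cT_i - cP_i) / h_i,

where cT and cP are the world centroids of the transformation and
preoperative masks and h_i is the preoperative bounding-box half-extent on
world axis i (floored at half a voxel to keep single-slice tumors finite).
``u = 0`` means transformation at the tumor center; ``|u_i| = 1`` means at
the border of the tumor's extent on that axis.

The scalar ``distance_ratio`` is the Euclidean norm of ``u``; whether the
point lies inside the cube is judged by the max-norm. For multifocal
transformations the whole-mask centroid is used and a caveat flag is set,
since a centroid of disjoint foci can land in tissue containing no tumor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cases import PatientCase
from .classify import DISTANT, SpatialClassification
from .errors import EmptyMaskError
from .geometry import bounding_box_world, mask_centroid_world, world_axis_spacing
from .volume import LabelVolume

__all__ = ["CentroidOffset", "normalized_offset", "cohort_centroid_cloud"]


@dataclass(frozen=True)
class CentroidOffset:
    """Normalized transformation-centroid displacement in the unit cube."""

    u: np.ndarray  # per world-axis, dimensionless
    distance_ratio: float
    inside_cube: bool
    multifocal_caveat: bool = False


def normalized_offset(
    preoperative: LabelVolume,
    transformation: LabelVolume,
    multifocal_caveat: bool = False,
) -> CentroidOffset:
    """Place the transformation centroid in the preoperative unit cube."""
    if preoperative.is_empty:
        raise EmptyMaskError("normalized offset requires a non-empty preoperative mask")
    if transformation.is_empty:
        raise EmptyMaskError("normalized offset requires a non-empty transformation mask")
    c_pre = mask_centroid_world(preoperative)
    c_tra = mask_centroid_world(transformation)
    half = bounding_box_world(preoperative).half_extent
    floor = world_axis_spacing(preoperative) / 2.0
    h = np.maximum(half, floor)
    u = (c_tra - c_pre) / h
    return CentroidOffset(
        u=u,
        distance_ratio=float(np.linalg.norm(u)),
        inside_cube=bool(np.max(np.abs(u)) <= 1.0),
        multifocal_caveat=multifocal_caveat,
    )


def cohort_centroid_cloud(
    records: list[tuple[PatientCase, SpatialClassification, CentroidOffset | None]],
    subgroup_key: str = "histology",
) -> pd.DataFrame:
    """Assemble the cohort point cloud for plotting/export.

    Includes only cases that have a preoperative mask (hence an offset) and
    whose clinical category is not distant — distant transformations are
    unrelated to the preoperative tumor's geometry and are excluded from
    this model. Combined cases stay in. Ordered by case_id.
    """
    rows = []
    for case, cls, offset in records:
        if offset is None or cls.clinical_category == DISTANT:
            continue
        subgroup = getattr(case, subgroup_key)
        rows.append(
            {
                "case_id": case.case_id,
                "subgroup": getattr(subgroup, "value", subgroup),
                "u_x": offset.u[0],
                "u_y": offset.u[1],
                "u_z": offset.u[2],
                "distance_ratio": offset.distance_ratio,
                "inside_cube": offset.inside_cube,
                "multifocal_caveat": offset.multifocal_caveat,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "case_id",
            "subgroup",
            "u_x",
            "u_y",
            "u_z",
            "distance_ratio",
            "inside_cube",
            "multifocal_caveat",
        ],
    )
    return df.sort_values("case_id", kind="stable").reset_index(drop=True)
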