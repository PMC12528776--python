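"""Volume biomarkers from a labelled airway decomposition.

Each class volume is expressed as a percentage of total lung volume:
terminal (STermAV), small (SSmallAV), medium (SMedAV), their sum
(STotalAV, trachea excluded) and the small+terminal composite (SPAV).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .decomposition import MEDIUM, SMALL, TERMINAL, SegmentLabelVolume
from .errors import DegenerateDataError, EmptyMaskError
from .grid import BinaryMask, same_grid

#: one covariate unit in survival models = 0.1 percentage points
MODEL_UNIT_PERCENT = 0.1


@dataclasses.dataclass(frozen=True)
class BiomarkerSet:
    """Airway class volumes as percent of total lung volume (plus raw mL)."""

    STermAV: float
    SSmallAV: float
    SMedAV: float
    STotalAV: float
    SPAV: float
    terminal_ml: float
    small_ml: float
    medium_ml: float
    total_ml: float
    lung_ml: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def percents(self) -> dict:
        return {
            k: getattr(self, k)
            for k in ("STermAV", "SSmallAV", "SMedAV", "STotalAV", "SPAV")
        }


def segment_volumes(labels: SegmentLabelVolume, lung: BinaryMask) -> BiomarkerSet:
    """Compute the biomarker set from labels and the lung mask."""
    same_grid(labels, lung)
    if lung.count == 0:
        raise EmptyMaskError("lung mask is empty; cannot normalise volumes")
    vv_ml = labels.grid.voxel_volume_mm3 / 1000.0
    lung_ml = lung.count * vv_ml
    term = int((labels.labels == TERMINAL).sum()) * vv_ml
    small = int((labels.labels == SMALL).sum()) * vv_ml
    med = int((labels.labels == MEDIUM).sum()) * vv_ml
    total = term + small + med
    pct = 100.0 / lung_ml
    return BiomarkerSet(
        STermAV=term * pct,
        SSmallAV=small * pct,
        SMedAV=med * pct,
        STotalAV=total * pct,
        SPAV=(term + small) * pct,
        terminal_ml=term,
        small_ml=small,
        medium_ml=med,
        total_ml=total,
        lung_ml=lung_ml,
    )


def to_model_units(markers: BiomarkerSet) -> dict[str, float]:
    """Scale percents so one covariate unit equals 0.1 percentage points."""
    return {k: v / MODEL_UNIT_PERCENT for k, v in markers.percents().items()}


def tertile_groups(values) -> tuple[np.ndarray, dict[str, int]]:
    """Split a biomarker vector into low/medium/high tertile groups.

    Cut points are the empirical 1/3 and 2/3 quantiles; values tied with a
    cut point all fall into the lower group.  Returns the per-sample group
    labels and the group sizes.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("expected a 1D vector of biomarker values")
    if len(np.unique(values)) < 3:
        raise DegenerateDataError(
            "need at least 3 distinct values to form tertile groups"
        )
    q1, q2 = np.quantile(values, [1.0 / 3.0, 2.0 / 3.0])
    groups = np.where(values <= q1, "low", np.where(values <= q2, "medium", "high"))
    sizes = {g: int((groups == g).sum()) for g in ("low", "medium", "high")}
    return groups, sizes
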