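"""Preprocessing tail of the perfusion pipeline.

Input scans are assumed already aligned to a common space.  The steps
implemented here, in their fixed order, are:

1. isotropic Gaussian smoothing (default 8 mm FWHM);
2. global scaling of each image to an in-mask median of 1,000, removing
   inter-subject differences in global perfusion;
3. optional averaging of scans within a subject/session/condition;
4. assembly of the samples x voxels feature matrix over the brain mask.

The median is taken over in-mask voxels by default (background zeros
would otherwise dominate a whole-volume median); ``median_in_mask=False``
switches to the whole-volume median.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import ndimage

from .synthetic import FWHM_TO_SIGMA, ScanRecord
from .volume import Volume

__all__ = [
    "FeatureMatrix",
    "gaussian_smooth",
    "scale_global_median",
    "average_scans",
    "build_feature_matrix",
    "preprocess_volume",
    "preprocess_records",
    "aggregate_records",
]


def gaussian_smooth(v: Volume, fwhm_mm: float) -> Volume:
    """Separable Gaussian smoothing with a physical FWHM.

    The per-axis sigma in voxels is ``(fwhm_mm / voxel_size) / (2 sqrt(2
    ln 2))``.  Reflective boundaries preserve constant images.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm_mm must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return v.copy_with(v.data.copy())
    sigmas = [(fwhm_mm / vs) * FWHM_TO_SIGMA for vs in v.voxel_size_mm]
    return v.copy_with(ndimage.gaussian_filter(v.data, sigmas, mode="reflect"))


def scale_global_median(
    v: Volume,
    mask: np.ndarray,
    target: float = 1000.0,
    median_in_mask: bool = True,
) -> Volume:
    """Scale a volume so its (in-mask) median equals ``target``."""
    if mask.shape != v.data.shape:
        raise ValueError(f"mask shape {mask.shape} does not match volume {v.data.shape}")
    med = float(np.median(v.data[mask.astype(bool)] if median_in_mask else v.data))
    if not med > 0:
        raise ValueError(
            f"global median must be positive to scale (got {med}); degenerate or empty image"
        )
    return v.copy_with(v.data * (target / med))


def average_scans(volumes: Sequence[Volume]) -> Volume:
    """Voxelwise arithmetic mean of same-grid volumes."""
    if len(volumes) == 0:
        raise ValueError("cannot average an empty list of volumes")
    first = volumes[0]
    for v in volumes[1:]:
        if v.data.shape != first.data.shape:
            raise ValueError(f"grid mismatch: {v.data.shape} vs {first.data.shape}")
    return first.copy_with(np.mean([v.data for v in volumes], axis=0))


@dataclass
class FeatureMatrix:
    """Samples x in-mask-voxels matrix with aligned labels and subjects.

    ``voxel_index`` maps column ``j`` to the 3-D coordinate of its voxel;
    columns follow the deterministic C-order linear scan of the mask.
    Labels are +1 (postsurgery) / -1 (comparison state).
    """

    X: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    voxel_index: np.ndarray
    grid_shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)

    def __post_init__(self) -> None:
        if not (self.X.shape[0] == len(self.labels) == len(self.subject_ids)):
            raise ValueError("X rows, labels and subject_ids must have equal length")
        if self.X.shape[1] != self.voxel_index.shape[0]:
            raise ValueError("X columns must match voxel_index length")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.X.shape[1]

    def to_volume(self, values: np.ndarray, background: float = np.nan) -> np.ndarray:
        """Scatter a per-voxel vector back onto the 3-D grid."""
        out = np.full(self.grid_shape, background, dtype=np.float64)
        out[tuple(self.voxel_index.T)] = values
        return out


def build_feature_matrix(
    records: Sequence[ScanRecord],
    mask: np.ndarray,
    label_map: dict[str, int],
    allow_unmapped: bool = False,
) -> FeatureMatrix:
    """Extract in-mask voxel values of each record into matrix rows.

    ``label_map`` assigns each condition to +1 or -1; records whose
    condition is missing from the map are an error unless
    ``allow_unmapped`` is set, in which case they are skipped.
    """
    mask = mask.astype(bool)
    voxel_index = np.argwhere(mask)  # C-order scan of the mask
    flat = mask.ravel()
    rows, labels, subjects = [], [], []
    for rec in records:
        if rec.condition not in label_map:
            if allow_unmapped:
                continue
            raise ValueError(
                f"record {rec.subject_id}/{rec.session_code} has unmapped condition "
                f"{rec.condition!r}"
            )
        if rec.volume.data.shape != mask.shape:
            raise ValueError(
                f"volume grid {rec.volume.data.shape} does not match mask {mask.shape}"
            )
        lab = int(label_map[rec.condition])
        if lab not in (-1, 1):
            raise ValueError(f"label_map values must be +1/-1, got {lab}")
        rows.append(rec.volume.data.ravel()[flat])
        labels.append(lab)
        subjects.append(rec.subject_id)
    if not rows:
        raise ValueError("no records matched the label map")
    return FeatureMatrix(
        X=np.asarray(rows, dtype=np.float64),
        labels=np.asarray(labels, dtype=np.int64),
        subject_ids=np.asarray(subjects, dtype=object),
        voxel_index=voxel_index,
        grid_shape=tuple(mask.shape),
        voxel_size_mm=records[0].volume.voxel_size_mm,
    )


def preprocess_volume(
    v: Volume,
    mask: np.ndarray,
    fwhm_mm: float = 8.0,
    target_median: float = 1000.0,
    median_in_mask: bool = True,
) -> Volume:
    """Smooth, then median-scale, one volume (the fixed pipeline order)."""
    return scale_global_median(
        gaussian_smooth(v, fwhm_mm), mask, target=target_median, median_in_mask=median_in_mask
    )


def preprocess_records(
    records: Sequence[ScanRecord],
    mask: np.ndarray,
    fwhm_mm: float = 8.0,
    target_median: float = 1000.0,
    median_in_mask: bool = True,
    smooth: Callable[[Volume, float], Volume] | None = None,
    scale: Callable[..., Volume] | None = None,
) -> list[ScanRecord]:
    """Apply smoothing then median scaling to every scan, preserving labels.

    The two stages are injectable for testing; the orchestration order
    (smooth -> scale) is fixed here and nowhere else.
    """
    smooth = smooth or gaussian_smooth
    scale = scale or scale_global_median
    out = []
    for rec in records:
        vol = smooth(rec.volume, fwhm_mm)
        vol = scale(vol, mask, target=target_median, median_in_mask=median_in_mask)
        out.append(
            ScanRecord(
                subject_id=rec.subject_id,
                session_code=rec.session_code,
                condition=rec.condition,
                side=rec.side,
                acquisition_index=rec.acquisition_index,
                volume=vol,
                vas_pain=rec.vas_pain,
                vas_alertness=rec.vas_alertness,
            )
        )
    return out


def aggregate_records(
    records: Sequence[ScanRecord],
    by: str = "session",
) -> list[ScanRecord]:
    """Average scans into one record per group.

    ``by='session'`` groups by (subject, session); ``by='condition'``
    groups by (subject, condition), pooling all sessions of the same
    state into a single sample per subject.  Group order follows first
    appearance in the input; VAS values are averaged alongside the
    images.  A merged group spanning both surgery sides reports side
    'none'.
    """
    if by not in ("session", "condition"):
        raise ValueError(f"unknown aggregation {by!r}")
    groups: dict[tuple, list[ScanRecord]] = {}
    for rec in records:
        key = (
            (rec.subject_id, rec.session_code)
            if by == "session"
            else (rec.subject_id, rec.condition)
        )
        groups.setdefault(key, []).append(rec)
    out = []
    for key, grp in groups.items():
        grp_sorted = sorted(grp, key=lambda r: (r.session_code, r.acquisition_index))
        first = grp_sorted[0]
        sides = {g.side for g in grp}
        out.append(
            ScanRecord(
                subject_id=first.subject_id,
                session_code=first.session_code if by == "session" else "+".join(
                    sorted({g.session_code for g in grp})
                ),
                condition=first.condition,
                side=sides.pop() if len(sides) == 1 else "none",
                acquisition_index=1,
                volume=average_scans([g.volume for g in grp_sorted]),
                vas_pain=float(np.mean([g.vas_pain for g in grp])),
                vas_alertness=float(np.mean([g.vas_alertness for g in grp])),
            )
        )
    return out
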