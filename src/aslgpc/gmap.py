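"""Discriminative pattern maps ("g-maps") from a trained classifier.

The trained GP classifier operates in the dual, but the direction of
maximal class difference lives in voxel space: projecting the posterior
latent mean back through the training data gives the posterior-mean
image

    g = X_c^T K^{-1} mu,

where X_c are the centred training features, K the (jittered) training
kernel and mu the EP posterior mean of the latent values.  The score at
each voxel measures that voxel's relative contribution to the class
difference *in the context of the whole pattern*; maps are exported
unthresholded.

Sign convention: by default the map is exported so that *negative*
coefficients favour the +1 (postsurgical) class — matching the display
convention of the original pattern figures — and the convention used is
always recorded in the output metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import linalg

from .gpc import GPModel
from .preprocess import FeatureMatrix
from .volume import Volume, save_volume

__all__ = ["GMap", "compute_gmap", "save_gmap"]

SIGN_CONVENTIONS = ("negative_favors_positive_class", "positive_favors_positive_class")


@dataclass
class GMap:
    """Unthresholded voxelwise coefficient map on the mask grid.

    ``data`` holds the coefficient at every in-mask voxel and NaN outside
    the mask (never silently zero-filled); ``sign_convention`` records
    which sign favours the +1 class.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    sign_convention: str
    log_signal: float
    log_bias: float

    @property
    def in_mask(self) -> np.ndarray:
        return ~np.isnan(self.data)


def compute_gmap(
    m: GPModel,
    fm: FeatureMatrix,
    sign_convention: str = "negative_favors_positive_class",
) -> GMap:
    """Project the EP posterior mean into voxel space.

    Dual coefficients ``a = K^{-1} mu`` are obtained by a Cholesky solve
    on the jittered training kernel; the voxel map is ``g = X_c^T a``
    scattered onto the grid through ``fm.voxel_index``.
    """
    if sign_convention not in SIGN_CONVENTIONS:
        raise ValueError(f"sign_convention must be one of {SIGN_CONVENTIONS}")
    if m.X_centered.shape[1] != fm.n_voxels:
        raise ValueError(
            f"model was trained on {m.X_centered.shape[1]} voxels but the feature "
            f"matrix has {fm.n_voxels}"
        )
    K = m.ep_state.K  # already jittered by ep_inference
    try:
        cho = linalg.cho_factor(K, lower=True)
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError(
            f"training kernel is singular even after jitter: {exc}"
        ) from exc
    a = linalg.cho_solve(cho, m.ep_state.mu)
    g = m.X_centered.T @ a
    if sign_convention == "negative_favors_positive_class":
        g = -g
    grid = fm.to_volume(g, background=np.nan)
    return GMap(
        data=grid,
        voxel_size_mm=tuple(fm.voxel_size_mm),
        sign_convention=sign_convention,
        log_signal=m.hyperparams.log_signal,
        log_bias=m.hyperparams.log_bias,
    )


def save_gmap(
    gmap: GMap,
    path: str | Path,
    voxel_size_mm: tuple[float, float, float] | None = None,
    extra_metadata: dict | None = None,
) -> Path:
    """Write the map as NIfTI-1 (NaN background) plus a JSON sidecar."""
    path = Path(path)
    vs = voxel_size_mm or gmap.voxel_size_mm
    vol = Volume(data=gmap.data, voxel_size_mm=vs)
    save_volume(vol, path)
    meta = {
        "sign_convention": gmap.sign_convention,
        "background": "NaN",
        "thresholded": False,
        "log_signal": gmap.log_signal,
        "log_bias": gmap.log_bias,
    }
    if extra_metadata:
        meta.update(extra_metadata)
    sidecar = path.with_suffix("").with_suffix("") if path.suffix == ".gz" else path
    sidecar = Path(str(sidecar).removesuffix(".nii") + ".json")
    sidecar.write_text(json.dumps(meta, indent=2))
    return path
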