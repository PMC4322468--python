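"""Synthetic ASL cohort generator.

The decoding pipeline was designed for a repeated-measures postsurgical
pain study: each subject is scanned across five sessions — a presurgical
baseline before each of two extractions (left and right lower third
molar), a postsurgical session after each, and a pain-free follow-up —
with six ASL perfusion scans per session and a VAS pain/alertness rating
before every scan.  No such perfusion dataset is publicly deposited, so
this module generates seeded cohorts with the statistical structure that
analysis assumes:

* a spatially distributed postsurgical rCBF *increase* in deep-brain and
  cingulate/insular territories and a *decrease* in occipito-parietal
  cortex, encoded as a sum-of-Gaussian-blobs pattern template;
* multiplicative inter-subject variability of global perfusion (the
  reason the pipeline scales every image to a median of 1,000);
* additive white per-voxel scan noise (spatial correlation enters later,
  through the smoothing step of the preprocessing pipeline);
* VAS pain scores whose postsurgical-minus-presurgical group mean
  differences default to 52.41 (left) and 50.779 (right) on the 0-100
  scale, and VAS alertness with no session effect.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import Volume, ellipsoid_mask, load_volume, save_volume

__all__ = [
    "BlobSpec",
    "CohortSpec",
    "ScanRecord",
    "DEFAULT_SESSIONS",
    "default_pattern_blobs",
    "generate_pattern_template",
    "simulate_cohort",
    "write_dataset",
    "read_dataset",
    "pattern_cnr",
    "effect_scale_for_cnr",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Session layout of the repeated-measures design: two presurgical
#: baselines, one postsurgical session per extraction side, and a
#: pain-free follow-up.  The k-th postsurgery session of a subject is
#: assigned that subject's k-th extraction side (the left/right order is
#: pseudorandomized per subject, balanced across the group).
DEFAULT_SESSIONS: tuple[tuple[str, str], ...] = (
    ("S2", "presurgery"),
    ("S3", "postsurgery"),
    ("S4", "presurgery"),
    ("S5", "postsurgery"),
    ("S6", "followup"),
)


@dataclass(frozen=True)
class BlobSpec:
    """One isotropic Gaussian bump of the discriminative pattern.

    ``amplitude`` is the signed peak rCBF offset (scaled CBF units) at the
    blob centre; positive amplitudes mark regions with *higher* perfusion
    in the postsurgical state, negative ones the reverse.
    """

    center: tuple[float, float, float]
    fwhm_mm: float
    amplitude: float

    def validate(self, grid_shape: tuple[int, int, int]) -> None:
        if not self.fwhm_mm > 0:
            raise ValueError(f"blob fwhm_mm must be > 0, got {self.fwhm_mm}")
        if len(self.center) != 3:
            raise ValueError(f"blob center must have 3 coordinates, got {self.center}")
        for c, n in zip(self.center, grid_shape):
            if not (0 <= c <= n - 1):
                raise ValueError(
                    f"blob center {self.center} lies outside the grid of shape {grid_shape}"
                )


def default_pattern_blobs(
    grid_shape: tuple[int, int, int] = (24, 32, 24),
) -> list[BlobSpec]:
    """Default discriminative pattern, placed at grid fractions.

    Approximates, at stand-in anatomy, bilateral thalamus, anterior and
    posterior insula and anterior cingulate (perfusion increase after
    surgery) against occipital and posterior parietal cortex (decrease).
    Axes are (x = left-right, y = posterior-anterior, z = inferior-superior).
    """
    nx, ny, nz = grid_shape

    def at(fx: float, fy: float, fz: float) -> tuple[float, float, float]:
        return (round(fx * (nx - 1)), round(fy * (ny - 1)), round(fz * (nz - 1)))

    return [
        # thalamus, bilateral
        BlobSpec(at(0.40, 0.48, 0.48), fwhm_mm=9.0, amplitude=1.0),
        BlobSpec(at(0.60, 0.48, 0.48), fwhm_mm=9.0, amplitude=1.0),
        # anterior insula, bilateral
        BlobSpec(at(0.24, 0.62, 0.44), fwhm_mm=9.0, amplitude=0.8),
        BlobSpec(at(0.76, 0.62, 0.44), fwhm_mm=9.0, amplitude=0.8),
        # posterior insula, bilateral
        BlobSpec(at(0.24, 0.40, 0.44), fwhm_mm=9.0, amplitude=0.7),
        BlobSpec(at(0.76, 0.40, 0.44), fwhm_mm=9.0, amplitude=0.7),
        # anterior cingulate, midline
        BlobSpec(at(0.50, 0.70, 0.56), fwhm_mm=10.0, amplitude=0.9),
        # occipital, midline posterior
        BlobSpec(at(0.50, 0.12, 0.44), fwhm_mm=12.0, amplitude=-0.8),
        # posterior parietal, bilateral
        BlobSpec(at(0.35, 0.22, 0.68), fwhm_mm=10.0, amplitude=-0.7),
        BlobSpec(at(0.65, 0.22, 0.68), fwhm_mm=10.0, amplitude=-0.7),
    ]


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort.

    Defaults reproduce the study design being emulated: 20 subjects, five
    scanning sessions each (two presurgical, one postsurgical per
    extraction side, one follow-up), six ASL scans per session, on a
    desk-scale 24x32x24 grid at 3 mm isotropic resolution.  ``baseline_cbf``
    is in ml/100g/min-like units; VAS parameters are on the 0-100 scale,
    with the postsurgical pain deltas set to the emulated group mean
    differences (52.41 left, 50.779 right).
    """

    n_subjects: int = 20
    n_scans_per_session: int = 6
    sessions: tuple[tuple[str, str], ...] = DEFAULT_SESSIONS
    grid_shape: tuple[int, int, int] = (24, 32, 24)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    baseline_cbf: float = 60.0
    subject_global_sd: float = 0.15
    scan_noise_sd: float = 10.0
    effect_scale: float = 1.65  # session-average pattern CNR ~1.5 (see pattern_cnr)
    blobs: list[BlobSpec] | None = None
    vas_pain_presurgery_mean: float = 15.0
    vas_pain_post_left_delta: float = 52.41
    vas_pain_post_right_delta: float = 50.779
    vas_alert_mean: float = 65.0
    vas_sd: float = 7.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        self.sessions = tuple((str(c), str(k)) for c, k in self.sessions)
        if self.n_subjects < 1 or self.n_scans_per_session < 1:
            raise ValueError("n_subjects and n_scans_per_session must be >= 1")
        if any(n < 1 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be positive, got {self.grid_shape}")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"voxel_size_mm must be positive, got {self.voxel_size_mm}")
        if min(self.subject_global_sd, self.scan_noise_sd, self.vas_sd) < 0:
            raise ValueError("standard deviations must be >= 0")
        for name in ("vas_pain_post_left_delta", "vas_pain_post_right_delta"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        valid = {"presurgery", "postsurgery", "followup"}
        for code, cond in self.sessions:
            if cond not in valid:
                raise ValueError(f"session {code!r} has unknown condition {cond!r}")

    def pattern_blobs(self) -> list[BlobSpec]:
        return list(self.blobs) if self.blobs is not None else default_pattern_blobs(self.grid_shape)


@dataclass
class ScanRecord:
    """One ASL scan with its labels: the sampling unit of the analysis."""

    subject_id: str
    session_code: str
    condition: str  # presurgery | postsurgery | followup
    side: str  # left | right | none
    acquisition_index: int  # 1-based scan order within the session
    volume: Volume
    vas_pain: float
    vas_alertness: float


def generate_pattern_template(
    grid_shape: tuple[int, int, int],
    voxel_size_mm: tuple[float, float, float],
    blobs: list[BlobSpec],
) -> Volume:
    """Voxelwise sum of isotropic Gaussian bumps.

    Each blob contributes ``amplitude * exp(-r_mm^2 / (2 sigma_mm^2))``
    with ``sigma_mm = fwhm_mm / (2 sqrt(2 ln 2))`` and ``r_mm`` the
    physical distance to the blob centre, so the peak value at an on-grid
    centre is exactly the blob amplitude.
    """
    grid_shape = tuple(int(n) for n in grid_shape)
    template = np.zeros(grid_shape, dtype=np.float64)
    coords = [np.arange(n, dtype=np.float64) * v for n, v in zip(grid_shape, voxel_size_mm)]
    for blob in blobs:
        blob.validate(grid_shape)
        sigma = blob.fwhm_mm * FWHM_TO_SIGMA
        d2 = sum(
            ((coords[a] - blob.center[a] * voxel_size_mm[a]) ** 2)[
                tuple(slice(None) if b == a else None for b in range(3))
            ]
            for a in range(3)
        )
        template += blob.amplitude * np.exp(-d2 / (2.0 * sigma**2))
    return Volume(data=template, voxel_size_mm=voxel_size_mm)


def _side_orders(n_subjects: int, rng: np.random.Generator) -> list[tuple[str, str]]:
    """Per-subject extraction order, balanced and pseudorandomized."""
    n_left_first = (n_subjects + 1) // 2
    orders = [("left", "right")] * n_left_first + [("right", "left")] * (n_subjects - n_left_first)
    perm = rng.permutation(n_subjects)
    return [orders[i] for i in perm]


def simulate_cohort(spec: CohortSpec) -> list[ScanRecord]:
    """Draw a full synthetic cohort, reproducibly from ``spec.seed``.

    Per scan the volume is
    ``baseline_cbf * subject_global_factor + 1{postsurgery} * effect_scale *
    template + noise`` where the subject global factor is lognormal(0,
    subject_global_sd) fixed per subject and the noise is i.i.d. Gaussian
    per voxel and scan.  VAS pain is Gaussian around the presurgery mean
    plus the side-specific delta in the postsurgical condition, clipped to
    [0, 100]; alertness has no condition effect.
    """
    rng = np.random.default_rng(spec.seed)
    template = generate_pattern_template(spec.grid_shape, spec.voxel_size_mm, spec.pattern_blobs())
    effect = spec.effect_scale * template.data

    sides = _side_orders(spec.n_subjects, rng)
    global_factors = np.exp(rng.normal(0.0, spec.subject_global_sd, size=spec.n_subjects))

    deltas = {"left": spec.vas_pain_post_left_delta, "right": spec.vas_pain_post_right_delta}
    width = len(str(spec.n_subjects))
    records: list[ScanRecord] = []
    for s in range(spec.n_subjects):
        subject_id = f"sub-{s + 1:0{width}d}"
        baseline = spec.baseline_cbf * global_factors[s]
        post_seen = 0
        for code, condition in spec.sessions:
            if condition == "postsurgery":
                side = sides[s][post_seen]
                post_seen += 1
            else:
                side = "none"
            pain_mean = spec.vas_pain_presurgery_mean
            if condition == "postsurgery":
                pain_mean += deltas[side]
            for k in range(1, spec.n_scans_per_session + 1):
                noise = rng.normal(0.0, spec.scan_noise_sd, size=spec.grid_shape)
                data = baseline + noise
                if condition == "postsurgery":
                    data = data + effect
                vas_pain = float(np.clip(rng.normal(pain_mean, spec.vas_sd), 0.0, 100.0))
                vas_alert = float(np.clip(rng.normal(spec.vas_alert_mean, spec.vas_sd), 0.0, 100.0))
                records.append(
                    ScanRecord(
                        subject_id=subject_id,
                        session_code=code,
                        condition=condition,
                        side=side,
                        acquisition_index=k,
                        volume=Volume(data=data, voxel_size_mm=spec.voxel_size_mm),
                        vas_pain=vas_pain,
                        vas_alertness=vas_alert,
                    )
                )
    return records


# ---------------------------------------------------------------------------
# on-disk dataset
# ---------------------------------------------------------------------------

_META_COLUMNS = [
    "subject_id",
    "session_code",
    "condition",
    "side",
    "acquisition_index",
    "filename",
    "vas_pain",
    "vas_alertness",
]


def write_dataset(records: list[ScanRecord], mask: np.ndarray, out_dir: str | Path) -> pd.DataFrame:
    """Write one NIfTI per scan, the brain mask, and a CSV metadata table.

    Returns the manifest DataFrame (also stored as ``participants.csv``).
    """
    if not records:
        raise ValueError("cannot write an empty record list")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    grid = records[0].volume.shape
    if tuple(mask.shape) != tuple(grid):
        raise ValueError(f"mask shape {mask.shape} does not match scan grid {grid}")

    rows = []
    for rec in records:
        fname = (
            f"{rec.subject_id}_{rec.session_code}_scan-{rec.acquisition_index:02d}.nii"
        )
        save_volume(rec.volume, out_dir / fname)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "session_code": rec.session_code,
                "condition": rec.condition,
                "side": rec.side,
                "acquisition_index": rec.acquisition_index,
                "filename": fname,
                "vas_pain": rec.vas_pain,
                "vas_alertness": rec.vas_alertness,
            }
        )
    mask_vol = Volume(mask.astype(np.float64), records[0].volume.voxel_size_mm, records[0].volume.affine)
    save_volume(mask_vol, out_dir / "mask.nii")
    manifest = pd.DataFrame(rows, columns=_META_COLUMNS)
    manifest.to_csv(out_dir / "participants.csv", index=False)
    return manifest


def read_dataset(in_dir: str | Path) -> tuple[list[ScanRecord], np.ndarray]:
    """Reconstruct (records, mask) from a directory written by write_dataset."""
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "participants.csv")
    records = []
    for row in manifest.itertuples(index=False):
        records.append(
            ScanRecord(
                subject_id=str(row.subject_id),
                session_code=str(row.session_code),
                condition=str(row.condition),
                side=str(row.side),
                acquisition_index=int(row.acquisition_index),
                volume=load_volume(in_dir / str(row.filename)),
                vas_pain=float(row.vas_pain),
                vas_alertness=float(row.vas_alertness),
            )
        )
    mask = load_volume(in_dir / "mask.nii").data > 0.5
    return records, mask


# ---------------------------------------------------------------------------
# effect-size calibration
# ---------------------------------------------------------------------------

def _white_noise_sd_factor(fwhm_mm: float, voxel_size_mm: tuple[float, float, float]) -> float:
    """SD attenuation of white noise under separable Gaussian smoothing.

    Computed from the discrete impulse response actually used by the
    smoothing step (sqrt of the sum of squared kernel taps, per axis).
    """
    if fwhm_mm == 0:
        return 1.0
    factor = 1.0
    for v in voxel_size_mm:
        sigma_vox = (fwhm_mm / v) * FWHM_TO_SIGMA
        radius = max(int(np.ceil(6 * sigma_vox)), 1)
        impulse = np.zeros(2 * radius + 1)
        impulse[radius] = 1.0
        taps = ndimage.gaussian_filter1d(impulse, sigma_vox, mode="constant")
        factor *= float(np.sqrt(np.sum(taps**2)))
    return factor


def pattern_cnr(
    spec: CohortSpec,
    fwhm_mm: float = 8.0,
    target_median: float = 1000.0,
) -> float:
    """Contrast-to-noise ratio of the session-averaged, preprocessed effect.

    Contrast: the peak absolute value of the smoothed pattern template
    times ``effect_scale``, expressed in median-1000 units for a nominal
    subject (global factor 1).  Noise: the per-voxel SD of smoothed scan
    noise after averaging the session's ``n_scans_per_session`` scans, in
    the same units.  Linear in ``effect_scale``; used to calibrate the
    generator rather than tuned per experiment.
    """
    template = generate_pattern_template(spec.grid_shape, spec.voxel_size_mm, spec.pattern_blobs())
    sigmas = [(fwhm_mm / v) * FWHM_TO_SIGMA for v in spec.voxel_size_mm]
    smoothed = ndimage.gaussian_filter(template.data, sigmas, mode="reflect")
    scale_units = target_median / spec.baseline_cbf
    signal = spec.effect_scale * float(np.max(np.abs(smoothed))) * scale_units
    noise = (
        spec.scan_noise_sd
        * _white_noise_sd_factor(fwhm_mm, spec.voxel_size_mm)
        * scale_units
        / np.sqrt(spec.n_scans_per_session)
    )
    return signal / noise


def effect_scale_for_cnr(spec: CohortSpec, target_cnr: float, **kwargs: float) -> float:
    """Effect scale giving the requested session-average pattern CNR."""
    from dataclasses import replace

    unit = replace(spec, effect_scale=1.0)
    return target_cnr / pattern_cnr(unit, **kwargs)
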