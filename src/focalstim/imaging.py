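"""dF/F activity maps and best-fit-ellipse response-shape descriptors.

A recording holds 5 s of pre-stimulus and 5 s of during-stimulus frames at
10 frames/s.  The baseline image is the mean of frames 2–3 s after recording
onset, the stimulation image the mean of frames 2–3 s after stimulus onset.
The activity measure is dF/F = (stim - baseline) / baseline pixelwise, and
pixels with dF/F > 0.15 form the active mask (the 15% threshold removes
typical fluorescence noise).

The response shape is the moment-based best-fit (equivalent) ellipse to the
active pixel set, treated as one point set: activation area is the ellipse
area pi*p*q in µm², and eccentricity sqrt(1 - (q/p)^2) equals the
focal-distance-to-major-axis ratio (0 a circle, 1 a line segment).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

DFF_THRESHOLD = 0.15
BASELINE_WINDOW_S = (2.0, 3.0)   # after recording onset
STIM_WINDOW_S = (2.0, 3.0)       # after stimulus onset
SPARSE_ACTIVITY_FLOOR_PX = 5     # below this, "no meaningful activity"


@dataclass
class ActivityMap:
    """Pixelwise dF/F image with its supra-threshold active mask."""

    dff: np.ndarray
    active_mask: np.ndarray
    threshold: float = DFF_THRESHOLD
    n_invalid_baseline: int = 0

    def __post_init__(self):
        assert self.dff.shape == self.active_mask.shape


@dataclass
class ResponseShape:
    """Best-fit-ellipse descriptors of one activity map.

    area is the fitted ellipse area in µm²; area_normalized is filled in
    downstream once the region's running maximum area is known.  An empty or
    sparse mask carries the (0, 0) sentinels; class assignment uses
    n_active_pixels, not the sentinels.
    """

    area: float                       # µm²
    eccentricity: float               # in [0, 1]
    n_active_pixels: int
    center: tuple[float, float]       # (row, col) px
    semi_major: float                 # px
    semi_minor: float                 # px
    orientation: float                # deg, major-axis angle from +x toward +y
    area_normalized: float = np.nan   # set by surrogate.prepare_training_set


def _window_frames(frame_rate: float, offset_s: float, window_s: tuple[float, float]) -> slice:
    # half-open [start, stop) frame window
    start = int(round((offset_s + window_s[0]) * frame_rate))
    stop = int(round((offset_s + window_s[1]) * frame_rate))
    return slice(start, stop)


def compute_activity_map(rec, threshold: float = DFF_THRESHOLD) -> ActivityMap:
    """Compute the dF/F map and active mask of one recording.

    ``rec`` is a :class:`focalstim.synthetic.FluorescenceRecording` (or any
    object with ``frames``, ``frame_rate`` and ``pre_stim_duration``).
    Pixels whose baseline is not strictly positive cannot carry a dF/F value;
    they are set inactive and counted in ``n_invalid_baseline`` with a
    warning.
    """
    frames = np.asarray(rec.frames, dtype=float)
    fr = float(rec.frame_rate)
    base_sl = _window_frames(fr, 0.0, BASELINE_WINDOW_S)
    stim_sl = _window_frames(fr, float(rec.pre_stim_duration), STIM_WINDOW_S)
    if stim_sl.stop > frames.shape[0]:
        raise ValueError(
            f"recording has {frames.shape[0]} frames; needs {stim_sl.stop} to "
            "cover both averaging windows"
        )
    baseline = frames[base_sl].mean(axis=0)
    stim = frames[stim_sl].mean(axis=0)

    valid = baseline > 0
    n_invalid = int((~valid).sum())
    if n_invalid:
        warnings.warn(f"{n_invalid} pixels with non-positive baseline masked out")
    dff = np.zeros_like(baseline)
    np.divide(stim - baseline, baseline, out=dff, where=valid)
    mask = (dff > threshold) & valid
    return ActivityMap(dff=dff, active_mask=mask, threshold=threshold,
                       n_invalid_baseline=n_invalid)


def _moment_ellipse(rows: np.ndarray, cols: np.ndarray):
    """Equivalent ellipse of a pixel point set from second central moments.

    Follows the image-moments convention: a solid ellipse with semi-axes
    (p, q) has eigenvalues (p²/4, q²/4) of its normalized covariance, so the
    fitted semi-axes are 2*sqrt(eigenvalue).  A half-pixel variance is added
    per axis so single pixels and 1-px-wide bars have finite extent.
    """
    n = rows.size
    cy, cx = rows.mean(), cols.mean()
    dy, dx = rows - cy, cols - cx
    # +1/12 per axis: variance of the unit pixel footprint
    myy = dy @ dy / n + 1.0 / 12.0
    mxx = dx @ dx / n + 1.0 / 12.0
    mxy = dx @ dy / n
    cov = np.array([[mxx, mxy], [mxy, myy]])
    evals, evecs = np.linalg.eigh(cov)
    q = 2.0 * np.sqrt(max(evals[0], 0.0))   # semi-minor
    p = 2.0 * np.sqrt(max(evals[1], 0.0))   # semi-major
    vx, vy = evecs[:, 1]
    orientation = float(np.degrees(np.arctan2(vy, vx)) % 180.0)
    return (cy, cx), p, q, orientation


def fit_response_shape(amap: ActivityMap, pixel_size: float) -> ResponseShape:
    """Fit the best-fit ellipse to the active pixels of one activity map.

    Parameters
    ----------
    amap : ActivityMap
    pixel_size : float
        µm per pixel (isotropic).

    Returns
    -------
    ResponseShape
        area = pi * p * q * pixel_size², eccentricity = sqrt(1 - (q/p)²).
        An empty mask yields area 0 and eccentricity 0 (class-0 pathway).
    """
    rows, cols = np.nonzero(amap.active_mask)
    n = rows.size
    if n == 0:
        return ResponseShape(area=0.0, eccentricity=0.0, n_active_pixels=0,
                             center=(np.nan, np.nan), semi_major=0.0,
                             semi_minor=0.0, orientation=0.0)
    center, p, q, orientation = _moment_ellipse(rows.astype(float), cols.astype(float))
    area = float(np.pi * p * q * pixel_size ** 2)
    ecc = float(np.sqrt(max(0.0, 1.0 - (q / p) ** 2))) if p > 0 else 0.0
    return ResponseShape(area=area, eccentricity=ecc, n_active_pixels=int(n),
                         center=center, semi_major=float(p), semi_minor=float(q),
                         orientation=orientation)


def downsample_map(dff: np.ndarray, side: int = 64) -> np.ndarray:
    """Block-mean downsample a square dF/F image to ``side`` x ``side``.

    Classifier input images are fixed-size; recordings rendered at other
    resolutions are reduced by averaging whole blocks (image side must be a
    multiple of ``side``).
    """
    h, w = dff.shape
    if h == side and w == side:
        return dff.astype(float)
    if h % side or w % side:
        raise ValueError(f"cannot block-average {dff.shape} to {side}x{side}")
    fh, fw = h // side, w // side
    return dff.reshape(side, fh, side, fw).mean(axis=(1, 3))
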