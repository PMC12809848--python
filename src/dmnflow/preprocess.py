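"""Motion quantification, subject exclusion, nuisance regression and filtering.

Framewise displacement follows the Jenkinson RMS formulation over an 80-mm
sphere (the FSL convention); subjects exceeding a mean-FD threshold are
excluded. Nuisance regression uses the Friston 24-parameter motion expansion
plus white-matter and CSF signals. Temporal filtering is a zero-phase
forward-backward Butterworth (order 4); spatial smoothing is a separable
Gaussian parameterized by FWHM in millimetres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "FDSeries",
    "framewise_displacement_jenkinson",
    "apply_motion_exclusion",
    "expand_confounds_24",
    "residualize",
    "clean_voxel_timeseries",
    "clean_component_timecourse",
    "gaussian_smooth",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class FDSeries:
    fd: np.ndarray  # per-volume framewise displacement, mm; fd[0] == 0
    mean_fd: float


def _rigid_matrix(params: np.ndarray) -> np.ndarray:
    """4x4 rigid transform from (tx, ty, tz, rx, ry, rz), rotations in radians.

    Rotation composed as R = Rx @ Ry @ Rz (applied right-to-left), the usual
    realignment convention.
    """
    tx, ty, tz, rx, ry, rz = params
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    M = np.eye(4)
    M[:3, :3] = Rx @ Ry @ Rz
    M[:3, 3] = (tx, ty, tz)
    return M


def framewise_displacement_jenkinson(
    motion: np.ndarray, radius_mm: float = 80.0
) -> FDSeries:
    """Jenkinson FD: RMS displacement over a sphere between consecutive volumes.

    For the relative transform ``[A | t] = M_t M_{t-1}^{-1} - I``,

        FD_t = sqrt( (r^2 / 5) * trace(A^T A) + t^T t ).

    The first volume's FD is defined as 0; ``mean_fd`` averages t >= 1.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be (n_volumes, 6)")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 volumes")
    if not np.isfinite(motion).all():
        raise ValueError("motion parameters must be finite")

    mats = [_rigid_matrix(p) for p in motion]
    fd = np.zeros(len(mats))
    for t in range(1, len(mats)):
        delta = mats[t] @ np.linalg.inv(mats[t - 1]) - np.eye(4)
        A = delta[:3, :3]
        trans = delta[:3, 3]
        fd[t] = np.sqrt(radius_mm**2 / 5.0 * np.trace(A.T @ A) + trans @ trans)
    return FDSeries(fd=fd, mean_fd=float(fd[1:].mean()))


def apply_motion_exclusion(
    mean_fd_by_subject: dict[str, float], threshold: float = 0.2
) -> tuple[list[str], list[dict]]:
    """Drop subjects whose mean FD strictly exceeds ``threshold`` (mm).

    Returns (retained subject ids, exclusion log). A subject at exactly the
    threshold is retained. Raises if nobody survives.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    retained, log = [], []
    for sid, mfd in mean_fd_by_subject.items():
        keep = mfd <= threshold
        log.append({"subject_id": sid, "mean_fd": float(mfd), "retained": bool(keep)})
        if keep:
            retained.append(sid)
    if not retained:
        raise RuntimeError("all subjects excluded by the motion criterion")
    return retained, log


def expand_confounds_24(motion: np.ndarray) -> np.ndarray:
    """Friston-24 expansion: 6 params, backward differences, and both squared."""
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be (n_volumes, 6)")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 volumes")
    diff = np.vstack([np.zeros(6), np.diff(motion, axis=0)])
    return np.hstack([motion, diff, motion**2, diff**2])


def residualize(data: np.ndarray, design: np.ndarray | None) -> np.ndarray:
    """Regress out ``design`` (plus an intercept) from each column of ``data``.

    data: (T, n_series). Rank-deficient designs are handled by least squares
    with a warning (equivalent to dropping collinear columns).
    """
    T = data.shape[0]
    if design is None or design.size == 0:
        X = np.ones((T, 1))
    else:
        design = np.asarray(design, dtype=float)
        if design.shape[0] != T:
            raise ValueError("design rows must equal number of time points")
        X = np.column_stack([np.ones(T), design])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            warnings.warn("collinear confound columns; using minimum-norm fit", stacklevel=2)
    beta, *_ = np.linalg.lstsq(X, data, rcond=None)
    return data - X @ beta


def _butter_sos(band_hz, fs: float, btype: str):
    nyq = fs / 2.0
    if btype == "bandpass":
        low, high = band_hz
        if not 0 <= low < high < nyq:
            raise ValueError(f"band {band_hz} invalid for Nyquist {nyq:.4g} Hz")
        if low <= 0:
            return signal.butter(4, high / nyq, btype="lowpass", output="sos")
        return signal.butter(4, [low / nyq, high / nyq], btype="bandpass", output="sos")
    high = float(band_hz)
    if not 0 < high < nyq:
        raise ValueError(f"cutoff {high} invalid for Nyquist {nyq:.4g} Hz")
    return signal.butter(4, high / nyq, btype="lowpass", output="sos")


def clean_voxel_timeseries(
    image: np.ndarray,
    tr_s: float,
    design: np.ndarray | None = None,
    band_hz: tuple[float, float] = (0.01, 0.1),
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Voxel-wise cleaning: detrend -> confound regression -> band-pass.

    ``image`` is (x, y, z, t); the confound ``design`` is (t, p), typically the
    24 motion parameters plus WM and CSF columns. Filtering is zero-phase
    (filtfilt) Butterworth order 4 in ``band_hz``.
    """
    if image.ndim != 4:
        raise ValueError("image must be 4D (x, y, z, t)")
    shape = image.shape
    T = shape[-1]
    data = image.reshape(-1, T)
    if mask is not None:
        idx = np.flatnonzero(mask.reshape(-1))
        work = data[idx].T.astype(float)  # (T, V)
    else:
        idx = None
        work = data.T.astype(float)

    work = signal.detrend(work, axis=0, type="linear")
    # keep the linear trend in the confound regression so a voxel lying in
    # the design span is removed exactly even after detrending
    trend = np.arange(T, dtype=float)
    trend -= trend.mean()
    if design is None or np.size(design) == 0:
        aug = trend[:, None]
    else:
        aug = np.column_stack([trend, np.asarray(design, dtype=float)])
    work = residualize(work, aug)
    sos = _butter_sos(band_hz, 1.0 / tr_s, "bandpass")
    work = signal.sosfiltfilt(sos, work, axis=0)

    out = np.zeros_like(data, dtype=float)
    if idx is None:
        out = work.T
    else:
        out[idx] = work.T
    return out.reshape(shape)


def despike_robust(x: np.ndarray, z_max: float = 3.5) -> np.ndarray:
    """Clip samples beyond ``z_max`` robust SDs (median/MAD) to the boundary."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    robust_sd = 1.4826 * mad
    if robust_sd == 0:
        return x.copy()
    lo, hi = med - z_max * robust_sd, med + z_max * robust_sd
    return np.clip(x, lo, hi)


def clean_component_timecourse(
    tc: np.ndarray,
    tr_s: float,
    design: np.ndarray | None = None,
    high_cutoff_hz: float = 0.15,
) -> np.ndarray:
    """Network time-course cleaning: detrend, despike, low-pass, confound regression.

    The despike step is a robust-z clip (median/MAD, |z| > 3.5 clipped to the
    boundary); the low-pass is a zero-phase Butterworth order 4 at
    ``high_cutoff_hz``. The confound design (24 motion + WM + CSF) is
    regressed out last.
    """
    tc = np.asarray(tc, dtype=float)
    if tc.ndim != 1 or tc.size < 32:
        raise ValueError("time course must be 1D with >= 32 samples")
    if np.ptp(tc) == 0:
        raise ValueError("constant time course (entropy undefined downstream)")
    x = signal.detrend(tc, type="linear")
    x = despike_robust(x)
    sos = _butter_sos(high_cutoff_hz, 1.0 / tr_s, "lowpass")
    x = signal.sosfiltfilt(sos, x)
    x = residualize(x[:, None], design)[:, 0]
    return x


def gaussian_smooth(
    image: np.ndarray, fwhm_mm: float, voxel_size_mm: float | tuple[float, float, float]
) -> np.ndarray:
    """Separable Gaussian smoothing with FWHM given in millimetres.

    Works on 3D maps or 4D series (smoothing spatial axes only). Anisotropic
    voxels are handled per axis; ``fwhm_mm=0`` returns the input unchanged.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return image
    vox = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    sigma_vox = (fwhm_mm * FWHM_TO_SIGMA) / vox
    if image.ndim == 3:
        return ndimage.gaussian_filter(image.astype(float), sigma=sigma_vox)
    if image.ndim == 4:
        return ndimage.gaussian_filter(image.astype(float), sigma=(*sigma_vox, 0.0))
    raise ValueError("image must be 3D or 4D")
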