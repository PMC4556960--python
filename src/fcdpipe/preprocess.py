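"""Per-subject BOLD time-series conditioning and motion quality control.

Fixed pipeline order: discard initial volumes -> linear detrend -> temporal
bandpass (0.01-0.08 Hz) -> nuisance regression (6 motion parameters, CSF
mean, white-matter mean, and optionally the global mean).  Each step returns
a new :class:`~fcdpipe.images.BoldImage` with provenance appended; voxels
outside the brain mask are never touched.
"""

from __future__ import annotations

import numpy as np

from .images import BoldImage, FcdPipeError, MotionTrace

#: Rotation-to-displacement radius (mm) for framewise displacement.
FD_ROTATION_RADIUS_MM = 50.0


def _masked_series(bold: BoldImage) -> np.ndarray:
    """(n_in_mask, t) view-copy of the in-mask voxel time series."""
    return bold.data[bold.brain_mask]


def _scatter(bold: BoldImage, series: np.ndarray, step: str) -> BoldImage:
    out = bold.data.copy()
    out[bold.brain_mask] = series
    return bold.with_data(out, step)


def discard_initial_volumes(bold: BoldImage, n: int = 10) -> BoldImage:
    """Drop the first ``n`` volumes (scanner equilibration)."""
    if n < 0:
        raise FcdPipeError("n must be >= 0")
    if n >= bold.n_volumes:
        raise FcdPipeError(f"cannot discard {n} of {bold.n_volumes} volumes")
    return bold.with_data(bold.data[..., n:], f"discard_initial_volumes(n={n})")


def detrend_linear(bold: BoldImage) -> BoldImage:
    """Remove the least-squares line (intercept + slope) from every in-mask
    voxel series; the result has zero mean and zero linear trend."""
    t = bold.n_volumes
    if t < 3:
        raise FcdPipeError("detrending needs at least 3 time points")
    x = _masked_series(bold)
    design = np.column_stack([np.ones(t), np.arange(t, dtype=float)])
    beta, *_ = np.linalg.lstsq(design, x.T, rcond=None)
    resid = x - (design @ beta).T
    return _scatter(bold, resid, "detrend_linear")


def bandpass_filter(bold: BoldImage, low_hz: float = 0.01, high_hz: float = 0.08) -> BoldImage:
    """Frequency-domain ideal (boxcar) bandpass on the discrete Fourier
    transform: bins with low_hz <= f <= high_hz pass unchanged, all others
    (including DC when low_hz > 0) are zeroed.  Output length unchanged."""
    nyquist = 0.5 / bold.tr_s
    if not 0 <= low_hz < high_hz:
        raise FcdPipeError("need 0 <= low_hz < high_hz")
    if high_hz > nyquist + 1e-12:
        raise FcdPipeError(f"high_hz {high_hz} exceeds Nyquist {nyquist:.4f} Hz")
    t = bold.n_volumes
    x = _masked_series(bold)
    freqs = np.fft.rfftfreq(t, d=bold.tr_s)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    if low_hz > 0:
        keep &= freqs > 0
    spec = np.fft.rfft(x, axis=-1)
    spec[:, ~keep] = 0
    y = np.fft.irfft(spec, n=t, axis=-1)
    return _scatter(bold, y, f"bandpass_filter({low_hz}-{high_hz}Hz)")


def regress_nuisance(
    bold: BoldImage,
    motion: MotionTrace,
    csf_mask: np.ndarray,
    wm_mask: np.ndarray,
    use_global: bool = True,
) -> BoldImage:
    """OLS-remove nuisance signals from every in-mask voxel series.

    Regressors: intercept, the 6 motion parameters, the CSF-mask mean, the
    white-matter-mask mean, and (by default) the whole-brain mean, all taken
    from the current (post-bandpass) data.  Residuals are orthogonal to
    every regressor.  Global-signal regression is controversial; disable it
    with ``use_global=False``.
    """
    t = bold.n_volumes
    if len(motion) != t:
        raise FcdPipeError(f"motion trace length {len(motion)} != {t} volumes")
    names = ["intercept", "trans_x", "trans_y", "trans_z",
             "rot_x", "rot_y", "rot_z"]
    cols = [np.ones(t)] + list(motion.as_array().T)
    for name, mask in (("csf_mean", csf_mask), ("wm_mean", wm_mask)):
        mask = np.asarray(mask, bool)
        if mask.shape != bold.shape:
            raise FcdPipeError(f"{name} mask shape mismatch")
        if not mask.any():
            raise FcdPipeError(f"{name} mask is empty")
        cols.append(bold.data[mask].mean(axis=0))
        names.append(name)
    if use_global:
        cols.append(_masked_series(bold).mean(axis=0))
        names.append("global_mean")
    design = np.column_stack(cols)

    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify columns whose removal restores full rank
        collinear = []
        for j in range(design.shape[1]):
            rest = np.delete(design, j, axis=1)
            if np.linalg.matrix_rank(rest) == rank:
                collinear.append(names[j])
        raise FcdPipeError(
            f"nuisance design is rank deficient; collinear columns: {collinear}"
        )
    x = _masked_series(bold)
    beta, *_ = np.linalg.lstsq(design, x.T, rcond=None)
    resid = x - (design @ beta).T
    return _scatter(
        bold, resid,
        f"regress_nuisance(motion+csf+wm{'+global' if use_global else ''})",
    )


def run_preprocessing(
    bold: BoldImage,
    motion: MotionTrace,
    csf_mask: np.ndarray,
    wm_mask: np.ndarray,
    n_discard: int = 10,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    use_global: bool = True,
) -> BoldImage:
    """The full conditioning chain in its fixed order."""
    out = discard_initial_volumes(bold, n_discard)
    trimmed = motion.drop_initial(n_discard) if n_discard else motion
    out = detrend_linear(out)
    out = bandpass_filter(out, low_hz, high_hz)
    out = regress_nuisance(out, trimmed, csf_mask, wm_mask, use_global=use_global)
    return out


# --------------------------------------------------------------------------
# motion quality control

def motion_excluded(
    trace: MotionTrace, max_trans_mm: float = 1.0, max_rot_deg: float = 1.0
) -> bool:
    """True iff any |translation| strictly exceeds ``max_trans_mm`` or any
    |rotation| strictly exceeds ``max_rot_deg`` (exclusion rule)."""
    return bool(
        (np.abs(trace.translations_mm) > max_trans_mm).any()
        or (np.abs(trace.rotations_deg) > max_rot_deg).any()
    )


def framewise_displacement(trace: MotionTrace) -> np.ndarray:
    """Per-volume framewise displacement: sum of absolute backward
    differences of the six parameters, rotations converted from degrees to
    arc length on a 50 mm sphere.  The first volume has FD = 0."""
    trans = np.abs(np.diff(trace.translations_mm, axis=0)).sum(axis=1)
    rot_rad = np.deg2rad(np.diff(trace.rotations_deg, axis=0))
    rot = (np.abs(rot_rad) * FD_ROTATION_RADIUS_MM).sum(axis=1)
    return np.concatenate([[0.0], trans + rot])


def count_motion_spikes(trace: MotionTrace, fd_threshold_mm: float = 0.5) -> int:
    """Number of volumes whose framewise displacement exceeds the threshold."""
    if fd_threshold_mm <= 0:
        raise FcdPipeError("fd_threshold_mm must be positive")
    return int((framewise_displacement(trace) > fd_threshold_mm).sum())
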