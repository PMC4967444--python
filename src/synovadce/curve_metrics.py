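"""Semi-quantitative enhancement parameters computed directly from the signal curve.

Per voxel three quantities are derived from the dynamic signal S_0..S_{n-1}
relative to the pre-contrast baseline S0:

* RER     — maximum relative enhancement rate: the steepest consecutive-frame
            slope of S(t)/S0, per minute.
* RE_max  — maximum of S_i / S0 over all frames.
* RE_late — mean of the last four frames divided by S0,
            (S_{n-1} + S_{n-2} + S_{n-3} + S_{n-4}) / (4 S0).

All three are ratios of signal to signal and are invariant to rescaling the
curve by a positive constant.  "Relative to the initial intensity" is taken
as S/S0 (not (S - S0)/S0): a non-enhancing voxel has RE_max = RE_late = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .protocols import AcquisitionProtocol

__all__ = [
    "SignalTimeSeries",
    "EnhancementParams",
    "baseline_signal",
    "re_late",
    "re_max",
    "rer",
    "enhancement_maps",
]


@dataclass(frozen=True)
class SignalTimeSeries:
    """One voxel's dynamic signal with its acquisition protocol."""

    signal: np.ndarray
    protocol: AcquisitionProtocol

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "signal", sig)
        if sig.ndim != 1 or sig.size != self.protocol.n_frames:
            raise ValueError("signal length must equal protocol.n_frames")

    def frame_times(self) -> np.ndarray:
        return self.protocol.frame_times()


@dataclass(frozen=True)
class EnhancementParams:
    """Voxel-level semi-quantitative parameter triple."""

    rer: float       # min^-1
    re_max: float    # dimensionless
    re_late: float   # dimensionless


def baseline_signal(series: SignalTimeSeries) -> float:
    """Pre-contrast baseline S0: mean of the frames before contrast arrival.

    Averaging the 3 (standard) or 2 (LTR) pre-contrast frames reduces noise
    relative to using the first frame alone.  A non-positive or non-finite
    result marks the voxel non-evaluable (handled by the caller).
    """
    n_pre = series.protocol.precontrast_frames
    if n_pre < 1:
        raise ValueError("protocol has no pre-contrast frames")
    return float(np.mean(series.signal[:n_pre]))


def re_late(series: SignalTimeSeries, s0: float) -> float:
    """Late relative enhancement: mean of the last four frames over S0."""
    if series.signal.size < 4:
        raise ValueError("re_late needs at least 4 frames")
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    return float(np.mean(series.signal[-4:]) / s0)


def re_max(series: SignalTimeSeries, s0: float) -> float:
    """Maximum relative enhancement: max of S_i / S0 over all frames."""
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    return float(np.max(series.signal) / s0)


def rer(series: SignalTimeSeries, s0: float) -> float:
    """Maximum relative enhancement rate, min^-1.

    Max over consecutive frame pairs of (S_{i+1} - S_i) / (dt_i * S0) with dt
    in minutes; no smoothing.  May be negative for a monotone-decreasing
    curve.
    """
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    if series.signal.size < 2:
        raise ValueError("rer needs at least 2 frames")
    dt_min = np.diff(series.frame_times()) / 60.0
    slopes = np.diff(series.signal) / (dt_min * s0)
    return float(np.max(slopes))


def enhancement_maps(curves: np.ndarray, protocol: AcquisitionProtocol) -> dict[str, np.ndarray]:
    """Vectorised enhancement parameters for a stack of voxel curves.

    Parameters
    ----------
    curves
        Array of shape ``(n_voxels, n_frames)``.
    protocol
        Shared acquisition protocol.

    Returns
    -------
    dict with arrays ``s0``, ``rer``, ``re_max``, ``re_late`` of length
    ``n_voxels`` and a boolean ``evaluable`` mask.  Non-evaluable voxels
    (S0 <= 0 or non-finite signal) carry NaN in the parameter arrays.
    """
    curves = np.asarray(curves, dtype=float)
    if curves.ndim != 2 or curves.shape[1] != protocol.n_frames:
        raise ValueError("curves must be (n_voxels, n_frames)")
    n_pre = protocol.precontrast_frames
    s0 = curves[:, :n_pre].mean(axis=1)
    finite = np.all(np.isfinite(curves), axis=1)
    evaluable = finite & (s0 > 0)

    with np.errstate(invalid="ignore", divide="ignore"):
        remax = curves.max(axis=1) / s0
        relate = curves[:, -4:].mean(axis=1) / s0
        dt_min = np.diff(protocol.frame_times()) / 60.0
        slopes = np.diff(curves, axis=1) / (dt_min[None, :] * s0[:, None])
        rer_ = slopes.max(axis=1)

    for arr in (remax, relate, rer_, s0):
        arr[~evaluable] = np.nan
    return {"s0": s0, "rer": rer_, "re_max": remax, "re_late": relate, "evaluable": evaluable}


def voxelwise_maps(volume4d, mask, protocol: AcquisitionProtocol,
                   aif=None, gain: float | None = None,
                   fit_vp: bool = True) -> dict[str, np.ndarray]:
    """All five voxelwise parameters over an ROI of a 4-D dynamic volume.

    Parameters
    ----------
    volume4d
        Dynamic data of shape ``(nx, ny, nz, n_frames)``.
    mask
        :class:`~synovadce.roi.ROIMask` on the same spatial grid.
    aif, gain
        When given, each evaluable voxel is additionally fitted with the
        extended Tofts model (``ktrans``, ``ve``, ``vp`` maps).

    Returns per-voxel 1-D arrays keyed ``s0, rer, re_max, re_late`` (and
    ``ktrans, ve, vp, converged`` when fitting), the ``evaluable`` mask and
    the in-mask ``indices``, all in mask-index order.  Non-evaluable voxels
    (S0 <= 0 or non-finite curve) carry NaN and are logged.
    """
    from . import kinetics

    volume4d = np.asarray(volume4d, dtype=float)
    if volume4d.ndim != 4 or volume4d.shape[-1] != protocol.n_frames:
        raise ValueError("volume4d must be (nx, ny, nz, n_frames)")
    if volume4d.shape[:3] != mask.data.shape:
        raise ValueError("mask and volume grids differ")
    idx = mask.indices()
    if idx.shape[0] == 0:
        raise ValueError("empty mask")
    curves = volume4d[idx[:, 0], idx[:, 1], idx[:, 2], :]
    out = enhancement_maps(curves, protocol)
    out["indices"] = idx
    n_bad = int((~out["evaluable"]).sum())
    if n_bad:
        import logging
        logging.getLogger(__name__).info("voxelwise_maps: %d of %d voxels non-evaluable",
                                         n_bad, idx.shape[0])
    if aif is not None:
        if gain is None:
            gain = kinetics.DEFAULT_GAIN
        n = idx.shape[0]
        ktrans = np.full(n, np.nan)
        ve = np.full(n, np.nan)
        vp = np.full(n, np.nan)
        converged = np.zeros(n, dtype=bool)
        for i in range(n):
            if not out["evaluable"][i]:
                continue
            fit = kinetics.fit_extended_tofts(curves[i], out["s0"][i], aif, protocol,
                                              gain=gain, fit_vp=fit_vp)
            ktrans[i], ve[i], vp[i] = fit.params.ktrans, fit.params.ve, fit.params.vp
            converged[i] = fit.converged
        out.update({"ktrans": ktrans, "ve": ve, "vp": vp, "converged": converged})
    return out
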