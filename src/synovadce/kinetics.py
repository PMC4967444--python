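"""Extended Tofts tracer kinetics: forward model, population AIF, voxel fitting.

The extended Tofts model describes tissue contrast concentration as

    C_t(t) = v_p * C_p(t) + Ktrans * int_0^t C_p(tau) exp(-(Ktrans/v_e)(t - tau)) dtau

where ``C_p`` is the arterial plasma concentration (the AIF), ``Ktrans``
(min^-1) the volume transfer coefficient, ``v_e`` the fractional
extravascular extracellular space and ``v_p`` the fractional plasma volume.
Signal is related to concentration by the linear convention
``S = S0 * (1 + gain * C_t)``; fitting therefore operates on relative
enhancement divided by a configured gain, which fixes the concentration
scale up to that convention (no T1 mapping is attempted).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .protocols import AcquisitionProtocol

__all__ = [
    "AIF",
    "ToftsParams",
    "ConcentrationCurve",
    "FitResult",
    "DEFAULT_GAIN",
    "DEFAULT_BOUNDS",
    "extended_tofts_forward",
    "average_population_aif",
    "fit_extended_tofts",
]

#: Signal change per unit concentration in the linear signal model.  Shared
#: convention between the synthetic forward simulation and the fitting code;
#: absolute Ktrans values are only comparable within a fixed gain.
DEFAULT_GAIN = 0.45

#: Box bounds for the fit, (lower, upper) per parameter in the order
#: (ktrans [min^-1], ve, vp).  Generous physiological range.
DEFAULT_BOUNDS = ((0.0, 1e-3, 0.0), (5.0, 1.0, 0.5))

#: Multi-start initialisation grid (3 x 3 x 2) guarding against local minima.
DEFAULT_INIT_GRID = (
    (0.01, 0.08, 0.5),  # ktrans starts, min^-1
    (0.1, 0.3, 0.6),    # ve starts
    (0.0, 0.05),        # vp starts
)


@dataclass(frozen=True)
class AIF:
    """Arterial input function: plasma concentration sampled on a time grid.

    ``times_s`` is monotone increasing in seconds; ``cp`` is the plasma
    concentration in the configured concentration units (mM for synthetic
    data) and must be non-negative.
    """

    times_s: np.ndarray
    cp: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times_s, dtype=float)
        cp = np.asarray(self.cp, dtype=float)
        object.__setattr__(self, "times_s", times)
        object.__setattr__(self, "cp", cp)
        if times.ndim != 1 or cp.shape != times.shape:
            raise ValueError("times_s and cp must be 1-D arrays of equal length")
        if times.size < 2 or np.any(np.diff(times) <= 0):
            raise ValueError("times_s must be monotone increasing with >= 2 samples")
        if np.any(~np.isfinite(cp)) or np.any(cp < -1e-12):
            raise ValueError("cp must be finite and non-negative")

    def to_table(self, path: str | Path) -> None:
        """Write as 2-column delimited text (time_s, cp)."""
        np.savetxt(path, np.column_stack([self.times_s, self.cp]),
                   header="time_s cp", comments="# ")

    @classmethod
    def from_table(cls, path: str | Path) -> "AIF":
        data = np.loadtxt(path)
        return cls(times_s=data[:, 0], cp=data[:, 1])


@dataclass(frozen=True)
class ToftsParams:
    """Extended Tofts parameter triple (ktrans in min^-1, ve and vp fractions)."""

    ktrans: float
    ve: float
    vp: float = 0.0

    def __post_init__(self) -> None:
        if self.ktrans < 0:
            raise ValueError("ktrans must be >= 0")
        if not (0 < self.ve <= 1):
            raise ValueError("ve must be in (0, 1]")
        if not (0 <= self.vp <= 1):
            raise ValueError("vp must be in [0, 1]")


@dataclass(frozen=True)
class ConcentrationCurve:
    """Tissue concentration C_t sampled at ``times_min`` (minutes)."""

    times_min: np.ndarray
    ct: np.ndarray


@dataclass(frozen=True)
class FitResult:
    params: ToftsParams
    residual_ss: float
    converged: bool
    n_iterations: int


def _exp_convolve(times_s: np.ndarray, cp: np.ndarray, kep_per_s: float) -> np.ndarray:
    """Trapezoidal evaluation of int_0^t cp(tau) exp(-kep (t - tau)) dtau.

    Uses the O(n) recursion I_j = e^{-k dt} I_{j-1} + dt/2 (cp_j + e^{-k dt} cp_{j-1}),
    exact trapezoid for the damped integrand on each sub-interval; valid for
    non-uniform grids.
    """
    out = np.zeros_like(cp)
    dts = np.diff(times_s)
    decays = np.exp(-kep_per_s * dts)
    for j in range(1, cp.size):
        out[j] = decays[j - 1] * out[j - 1] + 0.5 * dts[j - 1] * (cp[j] + decays[j - 1] * cp[j - 1])
    return out


def extended_tofts_forward(params: ToftsParams, aif: AIF, times_s: Sequence[float] | np.ndarray) -> ConcentrationCurve:
    """Evaluate the extended Tofts model at ``times_s`` (seconds).

    The convolution is computed on the AIF's dense grid by the trapezoidal
    rule (quadrature error O(dt^2)) and linearly interpolated to the
    requested sample times, which must lie within the AIF's support.
    """
    times_s = np.asarray(times_s, dtype=float)
    if times_s.size and (times_s.min() < aif.times_s[0] - 1e-9 or times_s.max() > aif.times_s[-1] + 1e-9):
        raise ValueError("requested times fall outside the AIF time support")
    if times_s.size > 1 and np.any(np.diff(times_s) <= 0):
        raise ValueError("times must be monotone increasing")

    ktrans_per_s = params.ktrans / 60.0
    kep_per_s = ktrans_per_s / params.ve if params.ktrans > 0 else 0.0
    if params.ktrans > 0:
        integral = _exp_convolve(aif.times_s, aif.cp, kep_per_s)
    else:
        integral = np.zeros_like(aif.cp)
    ct_dense = params.vp * aif.cp + ktrans_per_s * integral
    ct = np.interp(times_s, aif.times_s, ct_dense)
    return ConcentrationCurve(times_min=times_s / 60.0, ct=ct)


def average_population_aif(subject_aifs: Sequence[AIF]) -> AIF:
    """Pointwise arithmetic mean of per-subject AIFs on a common time grid.

    All inputs must share the grid exactly; mismatched grids are an error
    (no silent resampling).
    """
    if len(subject_aifs) == 0:
        raise ValueError("need at least one AIF")
    ref = subject_aifs[0].times_s
    for a in subject_aifs[1:]:
        if a.times_s.shape != ref.shape or not np.array_equal(a.times_s, ref):
            raise ValueError("AIF time grids do not match; resample explicitly before averaging")
    cp = np.mean([a.cp for a in subject_aifs], axis=0)
    return AIF(times_s=ref.copy(), cp=cp)


def _lower_corner(bounds) -> ToftsParams:
    lo = bounds[0]
    return ToftsParams(ktrans=lo[0], ve=max(lo[1], 1e-3), vp=lo[2])


def fit_extended_tofts(
    signal: np.ndarray,
    s0: float,
    aif: AIF,
    protocol: AcquisitionProtocol,
    gain: float = DEFAULT_GAIN,
    bounds=DEFAULT_BOUNDS,
    init_grid=DEFAULT_INIT_GRID,
    fit_vp: bool = True,
) -> FitResult:
    """Bounded nonlinear least-squares fit of the extended Tofts model to one voxel.

    The signal is converted to concentration via ``(S/s0 - 1) / gain`` and
    fitted against :func:`extended_tofts_forward` at the protocol frame
    times with a fixed multi-start grid (deterministic: same curve in, same
    fit out).  With ``fit_vp=False`` the plasma term is pinned to zero and
    the classic two-parameter Tofts fit is performed.

    A non-finite or non-enhancing-degenerate series (``s0 <= 0`` or any
    non-finite sample) is not fitted: the result carries the bounds' lower
    corner and ``converged=False``.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size != protocol.n_frames:
        raise ValueError("series length does not match protocol.n_frames")
    if s0 <= 0 or not np.isfinite(s0) or np.any(~np.isfinite(signal)):
        return FitResult(params=_lower_corner(bounds), residual_ss=np.inf, converged=False, n_iterations=0)
    if gain <= 0:
        raise ValueError("gain must be positive")

    times_s = protocol.frame_times()
    ct_obs = (signal / s0 - 1.0) / gain

    lo, hi = (np.asarray(b, dtype=float) for b in bounds)

    def residuals(theta: np.ndarray) -> np.ndarray:
        vp = theta[2] if fit_vp else 0.0
        p = ToftsParams(ktrans=theta[0], ve=max(theta[1], 1e-6), vp=vp)
        return extended_tofts_forward(p, aif, times_s).ct - ct_obs

    best = None
    best_nfev = 0
    for k0 in init_grid[0]:
        for v0 in init_grid[1]:
            for p0 in (init_grid[2] if fit_vp else (0.0,)):
                x0 = np.clip([k0, v0, p0], lo, hi)
                sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                                    xtol=1e-8, ftol=1e-8, gtol=1e-8, max_nfev=200 * 4)
                if best is None or sol.cost < best.cost:
                    best = sol
                    best_nfev = sol.nfev
    assert best is not None
    theta = best.x
    params = ToftsParams(ktrans=float(theta[0]), ve=float(max(theta[1], 1e-6)),
                         vp=float(theta[2] if fit_vp else 0.0))
    return FitResult(params=params, residual_ss=float(2.0 * best.cost),
                     converged=bool(best.success), n_iterations=int(best_nfev))
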