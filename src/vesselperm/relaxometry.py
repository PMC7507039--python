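"""Variable-flip-angle T1 mapping from spoiled gradient-echo (SPGR) data.

The SPGR steady-state signal at flip angle ``a`` and repetition time TR is

    S = M0 * sin(a) * (1 - E1) / (1 - E1 * cos(a)),   E1 = exp(-TR / T1).

Acquiring the same voxel at several flip angles lets T1 and M0 be
estimated. The default estimator is the standard linearization: plotting
S/sin(a) against S/tan(a) gives a line with slope E1 and intercept
M0*(1 - E1), so an ordinary least-squares line fit per voxel yields both
parameters in closed form. An optional nonlinear refinement is available
for cross-checks.

No B1 / flip-angle-error correction is applied; see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .data import VFASeries

__all__ = ["spgr_signal", "spgr_inverse_r1", "VFAT1Model", "T1MapResults", "fit_t1_vfa"]

# QC thresholds for the per-voxel linearized fit
_MIN_SIGNAL_FRAC = 1e-6  # mean voxel signal below this fraction of the series max -> reject
_SLOPE_EPS = 1e-6  # E1 estimates outside (eps, 1 - eps) -> reject


def spgr_signal(m0, t1_ms, alpha_deg, tr_s):
    """SPGR steady-state signal.

    Parameters
    ----------
    m0 : array_like
        Equilibrium signal (arbitrary units).
    t1_ms : array_like
        Longitudinal relaxation time in milliseconds; must be positive.
    alpha_deg : array_like
        Flip angle in degrees, in (0, 90].
    tr_s : float
        Repetition time in seconds; must be positive.

    Returns
    -------
    ndarray or float
        Signal in the units of ``m0``. Inputs broadcast.
    """
    t1_ms = np.asarray(t1_ms, dtype=float)
    alpha_deg = np.asarray(alpha_deg, dtype=float)
    if np.any(t1_ms <= 0):
        raise ValueError("t1_ms must be positive")
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    if np.any(alpha_deg <= 0) or np.any(alpha_deg > 90):
        raise ValueError("alpha_deg must lie in (0, 90]")
    a = np.deg2rad(alpha_deg)
    e1 = np.exp(-tr_s / (t1_ms / 1000.0))
    return m0 * np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a))


def spgr_signal_from_r1(m0, r1_per_s, alpha_deg, tr_s):
    """SPGR signal parameterized by the relaxation rate R1 = 1/T1 (1/s)."""
    r1_per_s = np.asarray(r1_per_s, dtype=float)
    a = np.deg2rad(np.asarray(alpha_deg, dtype=float))
    e1 = np.exp(-tr_s * r1_per_s)
    return m0 * np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a))


def spgr_inverse_r1(signal, m0, alpha_deg, tr_s):
    """Invert the SPGR closed form for R1 (1/s) given M0 and flip angle.

    Signals at or beyond the saturation bound ``M0*sin(a)`` (where the
    closed form is no longer invertible) and non-positive signals that
    would imply E1 >= 1 return NaN.
    """
    signal = np.asarray(signal, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    a = np.deg2rad(np.asarray(alpha_deg, dtype=float))
    sin_a, cos_a = np.sin(a), np.cos(a)
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = (m0 * sin_a - signal) / (m0 * sin_a - signal * cos_a)
        bad = ~np.isfinite(e1) | (e1 <= 0.0) | (e1 >= 1.0)
        r1 = -np.log(np.where(bad, 0.5, e1)) / tr_s
    return np.where(bad, np.nan, r1)


@dataclass
class T1MapResults:
    """Per-voxel T1/M0 estimates from a :class:`VFAT1Model` fit.

    Attributes
    ----------
    t1_ms : ndarray
        Fitted T1 in milliseconds (NaN where ``fit_ok`` is False).
    m0 : ndarray
        Fitted equilibrium signal (NaN where ``fit_ok`` is False).
    fit_ok : ndarray of bool
        True where the fit passed quality control.
    method : str
        'linear' or 'nls'.
    """

    t1_ms: np.ndarray
    m0: np.ndarray
    fit_ok: np.ndarray
    method: str
    model: "VFAT1Model"

    @property
    def n_rejected(self) -> int:
        return int(np.size(self.fit_ok) - np.count_nonzero(self.fit_ok))

    def summary(self) -> str:
        ok = self.fit_ok.astype(bool)
        lines = [
            "VFA T1 mapping results",
            "======================",
            f"method:        {self.method}",
            f"voxels:        {ok.size}",
            f"fit ok:        {int(ok.sum())}",
            f"rejected:      {self.n_rejected}",
        ]
        if ok.any():
            lines += [
                f"T1 median:     {np.nanmedian(self.t1_ms[ok]):.1f} ms",
                f"T1 IQR:        {np.nanpercentile(self.t1_ms[ok], 25):.1f}"
                f"-{np.nanpercentile(self.t1_ms[ok], 75):.1f} ms",
                f"M0 median:     {np.nanmedian(self.m0[ok]):.3g}",
            ]
        return "\n".join(lines)


class VFAT1Model:
    """T1/M0 estimation model for a variable-flip-angle SPGR series.

    Parameters
    ----------
    series : VFASeries
        Signals with shape (..., n_flip_angles).

    Examples
    --------
    >>> sig = spgr_signal(100.0, 1000.0, np.array([2, 5, 10, 15, 20, 25, 30.]), 0.0032)
    >>> res = VFAT1Model(VFASeries(sig, [2, 5, 10, 15, 20, 25, 30], 0.0032)).fit()
    >>> float(res.t1_ms)  # doctest: +ELLIPSIS
    1000.0...
    """

    def __init__(self, series: VFASeries):
        self.series = series

    def fit(self, method: str = "linear") -> T1MapResults:
        """Fit T1 and M0 per voxel.

        ``method='linear'`` uses the closed-form linearized regression of
        S/sin(a) on S/tan(a); ``method='nls'`` refines the linear estimate
        with bounded nonlinear least squares (slow, loops over voxels —
        intended for validation on small inputs).
        """
        if method not in ("linear", "nls"):
            raise ValueError(f"unknown method {method!r}")
        s = self.series.signal
        spatial = s.shape[:-1]
        flat = s.reshape(-1, s.shape[-1])
        t1, m0, ok = _fit_linear(flat, self.series.flip_angles, self.series.tr)
        if method == "nls":
            t1, m0, ok = _refine_nls(flat, self.series.flip_angles, self.series.tr, t1, m0, ok)
        return T1MapResults(
            t1_ms=t1.reshape(spatial),
            m0=m0.reshape(spatial),
            fit_ok=ok.reshape(spatial),
            method=method,
            model=self,
        )


def _fit_linear(flat: np.ndarray, angles_deg: np.ndarray, tr_s: float):
    a = np.deg2rad(angles_deg)
    y = flat / np.sin(a)
    x = flat / np.tan(a)
    xm = x.mean(axis=1, keepdims=True)
    ym = y.mean(axis=1, keepdims=True)
    sxx = ((x - xm) ** 2).sum(axis=1)
    sxy = ((x - xm) * (y - ym)).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
        intercept = ym[:, 0] - slope * xm[:, 0]
        max_sig = np.max(np.abs(flat)) or 1.0
        ok = (
            np.isfinite(slope)
            & (slope > _SLOPE_EPS)
            & (slope < 1.0 - _SLOPE_EPS)
            & (np.abs(flat).mean(axis=1) >= _MIN_SIGNAL_FRAC * max_sig)
        )
        t1 = np.where(ok, -tr_s / np.log(np.where(ok, slope, 0.5)) * 1000.0, np.nan)
        m0 = np.where(ok, intercept / (1.0 - np.where(ok, slope, 0.5)), np.nan)
    ok = ok & np.isfinite(t1) & (t1 > 0) & np.isfinite(m0) & (m0 > 0)
    t1[~ok] = np.nan
    m0[~ok] = np.nan
    return t1, m0, ok


def _refine_nls(flat, angles_deg, tr_s, t1_init, m0_init, ok):
    t1 = t1_init.copy()
    m0 = m0_init.copy()
    for i in np.flatnonzero(ok):

        def resid(p, sig=flat[i]):
            return spgr_signal(p[0], p[1], angles_deg, tr_s) - sig

        sol = least_squares(
            resid,
            x0=[m0_init[i], t1_init[i]],
            bounds=([0.0, 1.0], [np.inf, 20000.0]),
            method="trf",
        )
        m0[i], t1[i] = sol.x
    return t1, m0, ok


def fit_t1_vfa(series: VFASeries, method: str = "linear") -> T1MapResults:
    """Functional wrapper: ``VFAT1Model(series).fit(method)``."""
    return VFAT1Model(series).fit(method=method)
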