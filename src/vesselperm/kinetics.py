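"""Tracer-kinetic modelling: signal-to-concentration conversion, input
functions, and the extended Tofts model.

The extended Tofts model describes a tissue voxel as a plasma compartment
(volume fraction Vp) exchanging contrast agent with the extravascular
extracellular space (volume fraction Ve) at transfer constant Ktrans:

    Ct(t) = Vp * Cp(t) + Ktrans * int_0^t Cp(u) * exp(-kep * (t - u)) du,

with kep = Ktrans / Ve. Ktrans and kep are reported in 1/min; time arrays
are kept in seconds everywhere and converted to minutes only inside the
kinetic computations, so the unit boundary is explicit.

Fitting uses the linear least-squares reformulation

    Ct(t) = b1 * int_0^t Cp du  -  b2 * int_0^t Ct du  +  b3 * Cp(t)

with b2 = kep, b3 = Vp and b1 = Ktrans + kep * Vp, solved per voxel in
closed form; a bounded nonlinear least-squares fit of the same model is
available as an independent cross-check. All quadrature is trapezoidal on
the acquisition grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import least_squares

from .data import AIF, ConcentrationSeries, DynamicSeries
from .protocol import ScanProtocol
from .relaxometry import T1MapResults, spgr_inverse_r1

__all__ = [
    "signal_to_concentration",
    "extract_aif",
    "population_aif",
    "AIFParams",
    "tofts_forward",
    "ExtendedToftsModel",
    "ToftsResults",
    "fit_extended_tofts_linear",
    "fit_extended_tofts_nls",
    "roi_ktrans_stats",
    "ROIStats",
]

KTRANS_MAX = 5.0  # 1/min, upper bound for the nonlinear fit


# ---------------------------------------------------------------------------
# signal -> concentration
# ---------------------------------------------------------------------------

def signal_to_concentration(
    dyn: DynamicSeries,
    maps: T1MapResults,
    protocol: ScanProtocol | None = None,
    baseline: str = "t1map",
) -> tuple[ConcentrationSeries, dict]:
    """Convert a dynamic SPGR series to contrast concentration (mM).

    Per voxel and frame the SPGR closed form is inverted for R1(t) given
    the pre-contrast M0 map, then

        C(t) = (R1(t) - R1(0)) / r1,

    where r1 is the contrast agent's longitudinal relaxivity. ``baseline``
    selects where R1(0) comes from: ``'t1map'`` uses 1/T1 from the VFA fit
    (the T1-mapping block is acquired before injection), ``'signal'``
    re-estimates it per voxel from the mean R1 of the first ``n_baseline``
    frames, which cancels any static T1-map error.

    Voxels whose T1 fit was rejected yield all-NaN curves; frames whose
    signal exceeds the SPGR saturation bound (non-invertible) yield NaN
    and are counted in the returned QC dict.

    Returns
    -------
    (ConcentrationSeries, dict)
        Concentration and a QC log with keys ``n_voxels``, ``n_rejected_t1``,
        ``n_saturated_samples``.
    """
    if baseline not in ("t1map", "signal"):
        raise ValueError(f"unknown baseline mode {baseline!r}")
    protocol = protocol or dyn.protocol
    if maps.t1_ms.shape != dyn.spatial_shape:
        raise ValueError("T1 maps and dynamic series must share voxel geometry")
    if protocol.n_baseline >= protocol.n_dynamics:
        raise ValueError("n_baseline must be smaller than the number of frames")

    sig = dyn.signal.reshape(-1, dyn.signal.shape[-1])
    m0 = maps.m0.reshape(-1)
    t1 = maps.t1_ms.reshape(-1)
    ok = maps.fit_ok.reshape(-1).astype(bool)

    r1_t = np.full_like(sig, np.nan)
    r1_t[ok] = spgr_inverse_r1(
        sig[ok], m0[ok, None], protocol.flip_angle_dynamic, protocol.tr
    )
    n_sat = int(np.isnan(r1_t[ok]).sum())

    if baseline == "t1map":
        r1_0 = np.where(ok, 1000.0 / t1, np.nan)[:, None]
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            r1_0 = np.nanmean(r1_t[:, : protocol.n_baseline], axis=1, keepdims=True)

    conc = (r1_t - r1_0) / protocol.relaxivity_r1
    qc = {
        "n_voxels": sig.shape[0],
        "n_rejected_t1": int((~ok).sum()),
        "n_saturated_samples": n_sat,
    }
    series = ConcentrationSeries(
        conc.reshape(dyn.signal.shape), dyn.times, affine=dyn.affine
    )
    return series, qc


# ---------------------------------------------------------------------------
# input functions
# ---------------------------------------------------------------------------

def extract_aif(
    conc: ConcentrationSeries,
    sinus_mask: np.ndarray,
    hematocrit: float,
) -> tuple[AIF, int]:
    """Extract a plasma input function from a venous-sinus ROI.

    The blood concentration curve is the mean over mask voxels (voxels with
    any missing frame are excluded); division by (1 - hematocrit) converts
    whole-blood to plasma concentration. Small negative excursions from
    noise are clipped to zero.

    Returns the AIF and the number of usable voxels.
    """
    sinus_mask = np.asarray(sinus_mask, dtype=bool)
    if sinus_mask.shape != conc.spatial_shape:
        raise ValueError("sinus mask must share the concentration grid")
    if not sinus_mask.any():
        raise ValueError("sinus mask is empty")
    if not 0.0 <= hematocrit < 1.0:
        raise ValueError("hematocrit must lie in [0, 1)")
    curves = conc.conc[sinus_mask]
    usable = ~np.isnan(curves).any(axis=-1)
    n_usable = int(usable.sum())
    if n_usable == 0:
        raise ValueError("all sinus-mask voxels have missing concentration")
    blood = curves[usable].mean(axis=0)
    cp = np.clip(blood / (1.0 - hematocrit), 0.0, None)
    return AIF(conc.times, cp), n_usable


@dataclass(frozen=True)
class AIFParams:
    """Parameters of the population plasma input function.

    The curve is a gamma-variate first-pass bolus plus a bi-exponential
    washout with a fast rise, all zero before ``bolus_arrival_s``:

        Cp(t') = Ab * (t'/tp) * exp(1 - t'/tp)
                 + dose * (a1*exp(-m1*t') + a2*exp(-m2*t')) * (1 - exp(-t'/tau))

    with t' in minutes measured from bolus arrival. The washout amplitudes
    and rates follow the classic bi-exponential plasma-clearance model for
    gadolinium chelates; the added bolus term gives a realistic first-pass
    peak of roughly 3 mM at a standard single dose.
    """

    bolus_arrival_s: float = 40.0
    bolus_amplitude: float = 2.5  # mM
    bolus_tp_min: float = 0.25  # gamma-variate time-to-peak, minutes
    a1: float = 3.99  # kg/L
    a2: float = 4.78  # kg/L
    m1: float = 0.144  # 1/min
    m2: float = 0.0111  # 1/min
    rise_tau_min: float = 0.1
    dose: float = 0.1  # mmol/kg


def population_aif(times_s: np.ndarray, params: AIFParams | None = None) -> AIF:
    """Deterministic population plasma input function on ``times_s``."""
    params = params or AIFParams()
    times_s = np.asarray(times_s, dtype=float)
    t_min = (times_s - params.bolus_arrival_s) / 60.0
    cp = np.zeros_like(t_min)
    post = t_min > 0
    tp = t_min[post]
    bolus = params.bolus_amplitude * (tp / params.bolus_tp_min) * np.exp(
        1.0 - tp / params.bolus_tp_min
    )
    washout = (
        params.dose
        * (params.a1 * np.exp(-params.m1 * tp) + params.a2 * np.exp(-params.m2 * tp))
        * (1.0 - np.exp(-tp / params.rise_tau_min))
    )
    cp[post] = bolus + washout
    return AIF(times_s, cp)


# ---------------------------------------------------------------------------
# extended Tofts model
# ---------------------------------------------------------------------------

def tofts_forward(
    ktrans: float, ve: float, vp: float, aif: AIF
) -> np.ndarray:
    """Tissue concentration predicted by the extended Tofts model.

    Ktrans in 1/min; Ve, Vp as fractions; the convolution integral is
    evaluated by trapezoidal quadrature on the AIF's own time grid.
    """
    if ktrans < 0:
        raise ValueError("ktrans must be non-negative")
    if ktrans > 0 and not 0.0 < ve <= 1.0:
        raise ValueError("ve must lie in (0, 1] when ktrans > 0")
    if not 0.0 <= vp <= 1.0:
        raise ValueError("vp must lie in [0, 1]")
    t_min = aif.times / 60.0
    cp = aif.cp
    if ktrans == 0.0:
        return vp * cp
    kep = ktrans / ve
    # The convolution solves dCe/dt = Ktrans*Cp - kep*Ce, or in integral
    # form Ce(t) = Ktrans*int_0^t Cp - kep*int_0^t Ce. Applying trapezoidal
    # quadrature to both integrals on the frame grid gives the recursion
    # below (the Crank-Nicolson step), which is exactly the discretization
    # the linear-least-squares fit inverts.
    ce = np.zeros_like(cp)
    dt = np.diff(t_min)
    for i in range(1, cp.size):
        h = 0.5 * dt[i - 1]
        ce[i] = (
            ce[i - 1] + h * (ktrans * (cp[i - 1] + cp[i]) - kep * ce[i - 1])
        ) / (1.0 + h * kep)
    return vp * cp + ce


@dataclass
class ToftsResults:
    """Estimates from an extended Tofts fit.

    All arrays have the model's voxel shape. ``flags`` is True where the
    raw estimate violated a physiological bound and was clipped (or where
    the fit was degenerate); such voxels remain usable for ROI statistics
    but should be interpreted with care.
    """

    ktrans: np.ndarray  # 1/min
    ve: np.ndarray
    vp: np.ndarray
    kep: np.ndarray  # 1/min
    rss: np.ndarray
    flags: np.ndarray
    method: str
    model: "ExtendedToftsModel"

    @property
    def n_flagged(self) -> int:
        return int(np.count_nonzero(self.flags))

    def summary(self) -> str:
        k = np.atleast_1d(self.ktrans)
        good = np.isfinite(k)
        lines = [
            "Extended Tofts fit results",
            "==========================",
            f"method:          {self.method}",
            f"voxels:          {k.size}",
            f"flagged/clipped: {self.n_flagged}",
        ]
        if good.any():
            lines += [
                f"Ktrans mean:     {np.nanmean(k):.4f} 1/min",
                f"Ktrans sd:       {np.nanstd(k, ddof=1) if good.sum() > 1 else 0.0:.4f} 1/min",
                f"Ve mean:         {np.nanmean(self.ve):.4f}",
                f"Vp mean:         {np.nanmean(self.vp):.4f}",
                f"RSS total:       {np.nansum(self.rss):.4g}",
            ]
        return "\n".join(lines)


class ExtendedToftsModel:
    """Extended Tofts model for one or many tissue concentration curves.

    Parameters
    ----------
    ct : ndarray
        Tissue concentration, shape (..., n_times) or (n_times,).
    aif : AIF
        Plasma input on the same time grid (resampling is never implicit).
    baseline_correct : bool
        If True (default), subtract each curve's pre-bolus mean (frames
        before the AIF's first nonzero sample, at least one frame) before
        fitting; this removes static offsets left by baseline R1 errors.
    """

    def __init__(self, ct: np.ndarray, aif: AIF, baseline_correct: bool = True):
        ct = np.asarray(ct, dtype=float)
        if ct.shape[-1] != aif.times.size:
            raise ValueError("ct and aif must share the time grid")
        if ct.shape[-1] < 4:
            raise ValueError("need at least 4 frames to fit the model")
        if not np.any(aif.cp > 0):
            raise ValueError("degenerate all-zero AIF")
        self.aif = aif
        self.baseline_correct = baseline_correct
        self._scalar_input = ct.ndim == 1
        self.ct = np.atleast_2d(ct) if self._scalar_input else ct
        if baseline_correct:
            nz = np.flatnonzero(aif.cp > 0)
            n_pre = max(int(nz[0]), 1) if nz.size else 1
            self._n_pre = n_pre
        else:
            self._n_pre = 0

    # -- internals --------------------------------------------------------

    def _prepared(self):
        flat = self.ct.reshape(-1, self.ct.shape[-1]).copy()
        if self._n_pre:
            base = np.nanmean(flat[:, : self._n_pre], axis=1, keepdims=True)
            base = np.where(np.isfinite(base), base, 0.0)
            flat = flat - base
        return flat

    def fit(self, method: str = "linear", init: tuple | None = None) -> ToftsResults:
        """Fit per voxel and return a :class:`ToftsResults`.

        ``method='linear'`` solves the closed-form linear reformulation
        (fast, the default); ``method='nls'`` runs bounded nonlinear least
        squares initialized at ``init`` or at the linear estimate.
        Estimates violating the bounds Ktrans >= 0, 0 < Ve <= 1,
        0 <= Vp <= 1 are clipped and flagged.
        """
        if method == "linear":
            out = self._fit_linear()
        elif method == "nls":
            out = self._fit_nls(init)
        else:
            raise ValueError(f"unknown method {method!r}")
        ktrans, ve, vp, kep, rss, flags = out
        spatial = () if self._scalar_input else self.ct.shape[:-1]
        if self._scalar_input:
            reshape = lambda a: a[0]
        else:
            reshape = lambda a: a.reshape(spatial)
        return ToftsResults(
            ktrans=reshape(ktrans),
            ve=reshape(ve),
            vp=reshape(vp),
            kep=reshape(kep),
            rss=reshape(rss),
            flags=reshape(flags),
            method=method,
            model=self,
        )

    def _design(self):
        t_min = self.aif.times / 60.0
        cp = self.aif.cp
        int_cp = cumulative_trapezoid(cp, t_min, initial=0.0)
        return t_min, cp, int_cp

    def _fit_linear(self):
        t_min, cp, int_cp = self._design()
        flat = self._prepared()
        n_vox, n_t = flat.shape
        ktrans = np.full(n_vox, np.nan)
        ve = np.full(n_vox, np.nan)
        vp = np.full(n_vox, np.nan)
        kep = np.full(n_vox, np.nan)
        rss = np.full(n_vox, np.nan)
        flags = np.zeros(n_vox, dtype=bool)
        for i in range(n_vox):
            ct = flat[i]
            good = np.isfinite(ct)
            if good.sum() < 4:
                flags[i] = True
                continue
            int_ct = cumulative_trapezoid(
                np.where(good, ct, 0.0), t_min, initial=0.0
            )
            X = np.column_stack((int_cp[good], -int_ct[good], cp[good]))
            y = ct[good]
            vp0, rss0 = _vp_only_fit(cp[good], y)
            beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
            if rank < 3:
                # singular design (e.g. zero or pure-plasma curve): fall
                # back to the identifiable vp-only model
                ktrans[i] = ve[i] = kep[i] = 0.0
                vp[i] = vp0
                rss[i] = rss0
                flags[i] = True
                continue
            b1, b2, b3 = beta
            pred = b1 * int_cp[good] - b2 * int_ct[good] + b3 * cp[good]
            rss_full = float(np.sum((y - pred) ** 2))
            if rss0 <= rss_full + 1e-12 * max(float(np.sum(y**2)), 1e-30):
                # the exchange terms add nothing beyond numerical noise:
                # keep the parsimonious no-exchange model (Ktrans pinned 0)
                ktrans[i] = ve[i] = kep[i] = 0.0
                vp[i] = vp0
                rss[i] = rss0
                continue
            k, v_e, v_p, k_ep, flag = _params_from_beta(b1, b2, b3)
            ktrans[i], ve[i], vp[i], kep[i] = k, v_e, v_p, k_ep
            flags[i] = flag
            rss[i] = rss_full
        return ktrans, ve, vp, kep, rss, flags

    def _fit_nls(self, init):
        t_min, cp, int_cp = self._design()
        flat = self._prepared()
        lin = self._fit_linear()
        n_vox = flat.shape[0]
        ktrans = lin[0].copy()
        ve = lin[1].copy()
        vp = lin[2].copy()
        kep = lin[3].copy()
        rss = lin[4].copy()
        flags = np.zeros(n_vox, dtype=bool)
        times_s = self.aif.times
        for i in range(n_vox):
            ct = flat[i]
            good = np.isfinite(ct)
            if good.sum() < 4:
                flags[i] = True
                continue
            if init is not None:
                x0 = np.asarray(init, dtype=float)
            else:
                x0 = np.array([ktrans[i], ve[i], vp[i]])
                if not np.all(np.isfinite(x0)):
                    x0 = np.array([0.05, 0.2, 0.02])
            lo = np.array([0.0, 1e-6, 0.0])
            hi = np.array([KTRANS_MAX, 1.0, 1.0])
            x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)

            def resid(p, y=np.where(good, ct, 0.0), g=good):
                pred = tofts_forward(p[0], p[1], p[2], self.aif)
                return (pred - y)[g]

            sol = least_squares(
                resid, x0=x0, bounds=(lo, hi), method="trf",
                ftol=1e-12, xtol=1e-12, gtol=1e-12,
            )
            if not sol.success:
                flags[i] = True  # keep linear estimate
                continue
            y = ct[good]
            vp0, rss0 = _vp_only_fit(cp[good], y)
            rss_nls = float(np.sum(sol.fun**2))
            if rss0 <= rss_nls + 1e-12 * max(float(np.sum(y**2)), 1e-30):
                # no resolvable exchange: pin Ktrans at the lower bound
                ktrans[i] = ve[i] = kep[i] = 0.0
                vp[i] = vp0
                rss[i] = rss0
                continue
            k, v_e, v_p = sol.x
            ktrans[i], ve[i], vp[i] = k, v_e, v_p
            kep[i] = k / v_e if v_e > 0 else 0.0
            rss[i] = rss_nls
            flags[i] = flags[i] or lin[5][i]
        return ktrans, ve, vp, kep, rss, flags


def _vp_only_fit(cp: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares Vp for the no-exchange model Ct = Vp*Cp (Vp clipped
    to [0, 1]) and its residual sum of squares."""
    denom = float(np.sum(cp**2))
    vp0 = float(np.clip(np.sum(cp * y) / denom, 0.0, 1.0)) if denom > 0 else 0.0
    return vp0, float(np.sum((y - vp0 * cp) ** 2))


def _params_from_beta(b1: float, b2: float, b3: float):
    """Map the linear-reformulation coefficients to (Ktrans, Ve, Vp, kep).

    b2 = kep, b3 = Vp, b1 = Ktrans + kep*Vp. Ktrans is formed from the raw
    coefficients first (b1 - b2*b3 stays an unbiased combination even when
    noise pushes individual coefficients slightly out of bounds); only
    afterwards are estimates clipped to the physiological box and flagged.
    """
    flag = False
    ktrans = b1 - b2 * b3
    kep = b2
    vp = b3
    if vp < 0.0:
        vp, flag = 0.0, True
    elif vp > 1.0:
        vp, flag = 1.0, True
    if kep < 0.0:
        kep, flag = 0.0, True
    if ktrans < 0.0:
        ktrans, flag = 0.0, True
    if kep > 0.0:
        ve = ktrans / kep
        if ve > 1.0:
            ve, flag = 1.0, True
            kep = ktrans / ve if ve > 0 else 0.0
    else:
        ve = 0.0
        flag = True if ktrans > 0 else flag
    return ktrans, ve, vp, kep, flag


def fit_extended_tofts_linear(ct: np.ndarray, aif: AIF, **kwargs) -> ToftsResults:
    """Functional wrapper for the closed-form linear fit."""
    return ExtendedToftsModel(ct, aif, **kwargs).fit(method="linear")


def fit_extended_tofts_nls(
    ct: np.ndarray, aif: AIF, init: tuple | None = None, **kwargs
) -> ToftsResults:
    """Functional wrapper for the bounded nonlinear cross-check fit."""
    return ExtendedToftsModel(ct, aif, **kwargs).fit(method="nls", init=init)


# ---------------------------------------------------------------------------
# ROI statistics
# ---------------------------------------------------------------------------

@dataclass
class ROIStats:
    """Ktrans summary for a lesion ROI and its contralateral mirror ROI."""

    lesion_mean: float
    lesion_sd: float
    lesion_n: int
    mirror_mean: float
    mirror_sd: float
    mirror_n: int

    @property
    def difference(self) -> float:
        """Lesion minus mirror mean (the within-patient contrast)."""
        return self.lesion_mean - self.mirror_mean


def roi_ktrans_stats(
    param_map: np.ndarray,
    roi_mask: np.ndarray,
    mirror_mask: np.ndarray,
) -> ROIStats:
    """Mean/SD/count of a parameter map over a lesion ROI and its mirror.

    ROIs are expected to have the same voxel count (matched-size ROIs);
    unequal counts raise a warning, not an error. NaN voxels (rejected
    fits) are excluded.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    mirror_mask = np.asarray(mirror_mask, dtype=bool)
    if not roi_mask.any() or not mirror_mask.any():
        raise ValueError("ROI masks must be non-empty")
    if roi_mask.sum() != mirror_mask.sum():
        warnings.warn(
            f"ROI sizes differ: lesion {int(roi_mask.sum())} vs "
            f"mirror {int(mirror_mask.sum())} voxels",
            stacklevel=2,
        )

    def _stats(mask):
        vals = np.asarray(param_map)[mask]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError("no usable voxels in ROI")
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        return float(vals.mean()), sd, int(vals.size)

    lm, ls, ln = _stats(roi_mask)
    mm, ms, mn = _stats(mirror_mask)
    return ROIStats(lm, ls, ln, mm, ms, mn)
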