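"""Acquisition and physiology constants for the DCE-MRI protocol.

The defaults describe a 3 T brain permeability protocol: a spoiled
gradient-echo (SPGR) dynamic series with a multi-flip-angle pre-contrast
T1-mapping block, a single-dose gadodiamide bolus, and the physiological
constants needed to convert relaxation-rate changes into plasma
concentration (longitudinal relaxivity, hematocrit).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ScanProtocol"]


@dataclass(frozen=True)
class ScanProtocol:
    """Scan timing, flip angles and contrast-agent physiology.

    Parameters
    ----------
    tr : float
        Repetition time in seconds.
    te : float
        Echo time in seconds (stored for provenance; the SPGR model used
        here neglects T2* decay at this short TE).
    flip_angles : tuple of float
        Flip angles (degrees) of the variable-flip-angle T1-mapping block.
    flip_angle_dynamic : float
        Flip angle (degrees) of the dynamic contrast-enhanced frames.
    n_dynamics : int
        Number of dynamic frames.
    dt : float
        Spacing between dynamic frames in seconds.
    n_baseline : int
        Number of pre-contrast dynamic frames; the bolus arrives at frame
        index ``n_baseline`` (0-based).
    relaxivity_r1 : float
        Longitudinal relaxivity of the contrast agent in 1/(s*mM).
    hematocrit : float
        Large-vessel hematocrit, used to scale blood to plasma
        concentration.
    dose : float
        Contrast dose in mmol/kg.
    """

    tr: float = 0.0032
    te: float = 0.0016
    flip_angles: tuple[float, ...] = (2.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0)
    flip_angle_dynamic: float = 15.0
    n_dynamics: int = 45
    dt: float = 8.0
    n_baseline: int = 5
    relaxivity_r1: float = 3.6
    hematocrit: float = 0.45
    dose: float = 0.1

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if len(self.flip_angles) < 1:
            raise ValueError("at least one flip angle required")
        for a in self.flip_angles + (self.flip_angle_dynamic,):
            if not 0.0 < a <= 90.0:
                raise ValueError(f"flip angle {a} outside (0, 90] degrees")
        if self.n_dynamics < 2:
            raise ValueError("n_dynamics must be at least 2")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 0 <= self.n_baseline < self.n_dynamics:
            raise ValueError("n_baseline must lie in [0, n_dynamics)")
        if not 0.0 <= self.hematocrit < 1.0:
            raise ValueError("hematocrit must lie in [0, 1)")
        if self.relaxivity_r1 <= 0:
            raise ValueError("relaxivity_r1 must be positive")

    @property
    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds, starting at zero."""
        return np.arange(self.n_dynamics, dtype=float) * self.dt

    @property
    def bolus_arrival(self) -> float:
        """Nominal bolus arrival time in seconds (first post-baseline frame)."""
        return self.n_baseline * self.dt

    def with_overrides(self, **kwargs) -> "ScanProtocol":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)
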