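"""Light in-memory containers for image series, concentration data and AIFs.

Arrays keep their spatial axes; the last axis is always the "series" axis
(flip angle for VFA data, time for dynamic data). Geometry is carried as a
NIfTI-style 4x4 affine (RAS); masks must share the spatial grid exactly —
no implicit resampling happens anywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .protocol import ScanProtocol

__all__ = ["VFASeries", "DynamicSeries", "ConcentrationSeries", "AIF"]


def _default_affine() -> np.ndarray:
    return np.eye(4)


@dataclass
class VFASeries:
    """Multi-flip-angle SPGR series: shape (..., n_flip_angles)."""

    signal: np.ndarray
    flip_angles: np.ndarray  # degrees
    tr: float  # seconds
    affine: np.ndarray = field(default_factory=_default_affine)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.flip_angles = np.asarray(self.flip_angles, dtype=float)
        if self.signal.shape[-1] != self.flip_angles.size:
            raise ValueError(
                f"last signal axis ({self.signal.shape[-1]}) must match the "
                f"number of flip angles ({self.flip_angles.size})"
            )
        if np.unique(self.flip_angles).size < 2:
            raise ValueError("need at least 2 distinct flip angles")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.signal.shape[:-1]


@dataclass
class DynamicSeries:
    """Dynamic contrast-enhanced series: shape (..., n_dynamics)."""

    signal: np.ndarray
    times: np.ndarray  # seconds from first frame
    protocol: ScanProtocol
    affine: np.ndarray = field(default_factory=_default_affine)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.signal.shape[-1] != self.times.size:
            raise ValueError("last signal axis must match the number of frames")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times.size != self.protocol.n_dynamics:
            raise ValueError(
                f"series length {self.times.size} does not match protocol "
                f"n_dynamics {self.protocol.n_dynamics}"
            )

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.signal.shape[:-1]


@dataclass
class ConcentrationSeries:
    """Tissue contrast concentration in mM: shape (..., n_dynamics).

    Voxels that could not be converted (rejected T1 fit, saturated signal)
    carry NaN.
    """

    conc: np.ndarray
    times: np.ndarray  # seconds
    affine: np.ndarray = field(default_factory=_default_affine)

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.conc.shape[-1] != self.times.size:
            raise ValueError("last conc axis must match the number of frames")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.conc.shape[:-1]


@dataclass
class AIF:
    """Plasma input function Cp(t) in mM on an explicit time grid (seconds)."""

    times: np.ndarray
    cp: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cp = np.asarray(self.cp, dtype=float)
        if self.times.shape != self.cp.shape:
            raise ValueError("times and cp must have the same shape")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.cp < -1e-12):
            raise ValueError("cp must be non-negative")
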