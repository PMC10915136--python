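"""Phase reconstruction for gradient light interference microscopy (GLIM).

A GLIM acquisition records four intensity frames at modulator phase shifts
of n*pi/2 (n = 0..3).  Each pixel follows

    I_n = A + B * cos(phi_g + n*pi/2)

where ``phi_g`` is the phase *gradient* along the shear axis of the
differential-interference-contrast optics.  The gradient is recovered with
the four-quadrant arctangent and converted to a phase image by spectral
(Hilbert-transform-style) integration along the shear axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np


class ShearAxis(str, Enum):
    """Shear direction of the DIC prism; axis along which the gradient acts."""

    X = "x"  # last array axis
    Y = "y"  # first array axis

    @property
    def array_axis(self) -> int:
        return -1 if self is ShearAxis.X else 0


@dataclass
class IntensityFrameSet:
    """Four co-registered intensity frames at phase shifts n*pi/2, n = 0..3."""

    frames: np.ndarray  # shape (4, H, W)
    shear_axis: ShearAxis = ShearAxis.X

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] != 4:
            raise ValueError(
                f"expected 4 stacked 2D frames, got shape {self.frames.shape}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("intensity frames must be finite")
        self.shear_axis = ShearAxis(self.shear_axis)


@dataclass
class PhaseVolume:
    """Calibrated optical-phase field (radians) with physical sampling metadata.

    Attributes
    ----------
    phi : ndarray
        Phase in radians, 2D (single section) or 3D ``(z, y, x)``.
    dx_um : float
        Lateral sampling in micrometres per pixel.
    dz_um : float
        Axial step in micrometres per section.
    wavelength_um : float
        Illumination wavelength λ in micrometres.
    gamma_um3_per_pg : float
        Refractive-index increment γ expressed in µm³/pg so that the
        dry-mass relation M = λ/(2πγ) ∫ φ d³r yields picograms.
    """

    phi: np.ndarray
    dx_um: float = 1.0 / 11.0
    dz_um: float = 1.0
    wavelength_um: float = 0.488
    gamma_um3_per_pg: float = 0.2

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=np.float32)
        for name in ("dx_um", "dz_um", "wavelength_um", "gamma_um3_per_pg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not np.all(np.isfinite(self.phi)):
            raise ValueError("phase field must be finite")

    @property
    def voxel_volume_um3(self) -> float:
        return self.dx_um * self.dx_um * self.dz_um


def synthesize_frames(
    gradient: np.ndarray,
    amplitude: float = 10.0,
    modulation: float = 3.0,
    shear_axis: ShearAxis = ShearAxis.X,
) -> IntensityFrameSet:
    """Forward model: build the 4-frame set produced by a gradient field.

    ``I_n = A + B cos(phi_g + n*pi/2)``.  Used for round-trip testing and to
    generate synthetic acquisitions.
    """
    g = np.asarray(gradient, dtype=float)
    frames = np.stack(
        [amplitude + modulation * np.cos(g + n * np.pi / 2.0) for n in range(4)]
    )
    return IntensityFrameSet(frames, shear_axis)


def reconstruct_gradient(
    frames: IntensityFrameSet, flip_sign: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Recover the phase-gradient image from four phase-shifted frames.

    Returns
    -------
    gradient : ndarray
        Pixelwise ``atan2(I3 - I1, I0 - I2)`` in (−π, π], radians.
    zero_modulation : ndarray of bool
        Pixels where all four frames coincide (no interferometric
        modulation); the gradient is defined as 0 there.
    """
    i0, i1, i2, i3 = frames.frames
    num = i3 - i1
    den = i0 - i2
    zero_mod = (num == 0) & (den == 0)
    gradient = np.arctan2(num, den)
    gradient[zero_mod] = 0.0
    if flip_sign:
        gradient = -gradient
    return gradient, zero_mod


def integrate_gradient(
    gradient: np.ndarray, shear_axis: ShearAxis = ShearAxis.X
) -> np.ndarray:
    """Integrate a phase-gradient image along the shear axis spectrally.

    The 1-D Fourier spectrum along the shear axis is divided by ``i 2π u``
    (inverse differentiation) with the DC term zeroed; the DC (per-line
    mean) of the gradient, which the spectral division cannot represent,
    is reintegrated separately as an explicit linear ramp.  Each line is
    recovered up to an additive constant; the output mean is set to 0.
    Periodic wrap-around at the line edges is the documented band-limited
    behaviour of the spectral part.
    """
    g = np.asarray(gradient, dtype=float)
    if not np.all(np.isfinite(g)):
        raise ValueError("gradient field must be finite")
    axis = ShearAxis(shear_axis).array_axis
    n = g.shape[axis]
    u = np.fft.fftfreq(n)  # cycles / pixel
    spec = np.fft.fft(g, axis=axis)
    denom = 2j * np.pi * u
    denom[0] = np.inf  # zero the DC term of the division
    shape = [1] * g.ndim
    shape[axis] = n
    spec = spec / denom.reshape(shape)
    phase = np.fft.ifft(spec, axis=axis).real
    ramp = np.arange(n, dtype=float) - (n - 1) / 2.0
    phase = phase + g.mean(axis=axis, keepdims=True) * ramp.reshape(shape)
    return phase - phase.mean()
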