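"""Inversion-recovery Look-Locker FLASH signal physics.

A slice-selective inversion pulse is followed by a continuous small-flip-angle
FLASH readout.  The continuous readout drives the longitudinal magnetization
toward a reduced steady state, so the observed recovery follows an *effective*
(shortened) relaxation time T1* rather than the true T1.  The pixel intensity
time course is the classic three-parameter model

    S(t) = A - B * exp(-t / T1*),

and the true relaxation time is recovered with the Look-Locker correction

    T1 = T1* * (B / A - 1).

All times are milliseconds, angles degrees.  Amplitudes are arbitrary units;
receive gain and sin(flip) factors are absorbed into the equilibrium
magnetization ``m0``, so only amplitude ratios matter for T1.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np

__all__ = [
    "AcquisitionProtocol",
    "LookLockerParams",
    "frame_footprint",
    "frame_times",
    "effective_t1star",
    "forward_signal",
    "looklocker_params_from_tissue",
    "correct_t1",
    "simulate_pixel_series",
]


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Fixed scan constants of the single-shot IR radial FLASH acquisition.

    Defaults reproduce the 3-T protocol: TR/TE = 4.0/2.2 ms, flip angle 6°,
    15 radial spokes merged per frame (60-ms temporal footprint), a 4-s
    readout (67 frames) and a 220-mm field of view at 1-mm in-plane
    resolution.  ``te_ms`` and ``slice_mm`` are carried as metadata only.
    """

    tr_ms: float = 4.0
    te_ms: float = 2.2
    flip_deg: float = 6.0
    spokes_per_frame: int = 15
    readout_ms: float = 4000.0
    inversion_efficiency: float = 1.0
    fov_mm: float = 220.0
    pixel_mm: float = 1.0
    slice_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.tr_ms <= 0:
            raise ValueError("tr_ms must be positive")
        if not (0 < self.flip_deg < 90):
            raise ValueError("flip_deg must lie in (0, 90)")
        if self.spokes_per_frame < 1:
            raise ValueError("spokes_per_frame must be >= 1")
        if not (0 < self.inversion_efficiency <= 1):
            raise ValueError("inversion_efficiency must lie in (0, 1]")
        if self.readout_ms <= self.tr_ms * self.spokes_per_frame:
            raise ValueError("readout_ms must exceed the frame footprint")
        m = self.fov_mm / self.pixel_mm
        if m <= 0 or abs(m - round(m)) > 1e-9:
            raise ValueError("fov_mm / pixel_mm must be a positive integer")

    @property
    def matrix_size(self) -> int:
        """In-plane matrix size (square), fov / pixel."""
        return int(round(self.fov_mm / self.pixel_mm))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AcquisitionProtocol":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class LookLockerParams:
    """Three-parameter pixel signal description S(t) = A - B exp(-t/T1*)."""

    a_amp: float
    b_amp: float
    t1_star_ms: float

    def __post_init__(self) -> None:
        if self.a_amp <= 0:
            raise ValueError("a_amp must be positive")
        if self.t1_star_ms <= 0:
            raise ValueError("t1_star_ms must be positive")


def frame_footprint(protocol: AcquisitionProtocol) -> float:
    """Temporal footprint of one reconstructed frame: spokes x TR, in ms."""
    return protocol.spokes_per_frame * protocol.tr_ms


def frame_times(protocol: AcquisitionProtocol) -> np.ndarray:
    """Mid-frame timestamps (ms after inversion) of the reconstructed series.

    Frame k spans [k, k+1) footprints; its timestamp is the window centre
    (k + 0.5) * footprint.  The number of frames is ceil(readout/footprint),
    67 for the default 4-s readout at a 60-ms footprint.
    """
    dt = frame_footprint(protocol)
    n = math.ceil(protocol.readout_ms / dt)
    return (np.arange(n) + 0.5) * dt


def effective_t1star(t1_ms: float, protocol: AcquisitionProtocol) -> float:
    """Apparent relaxation time under continuous small-flip FLASH readout.

    1/T1* = 1/T1 - ln(cos flip)/TR.  Strictly below T1 for any flip > 0.
    """
    t1 = np.asarray(t1_ms, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("t1_ms must be positive")
    rate = 1.0 / t1 - math.log(math.cos(math.radians(protocol.flip_deg))) / protocol.tr_ms
    out = 1.0 / rate
    return float(out) if np.isscalar(t1_ms) else out


def forward_signal(t_ms, params: LookLockerParams):
    """Signed pixel intensity A - B exp(-t/T1*) at time(s) ``t_ms``."""
    t = np.asarray(t_ms, dtype=float)
    s = params.a_amp - params.b_amp * np.exp(-t / params.t1_star_ms)
    return float(s) if np.isscalar(t_ms) else s


def looklocker_params_from_tissue(
    t1_ms: float, m0: float, protocol: AcquisitionProtocol
) -> LookLockerParams:
    """Map tissue (T1, M0) to the observable (A, B, T1*) triple.

    The steady-state plateau scales as A = M0 * T1*/T1; the recovery
    amplitude is B = A + eff * M0 where ``eff`` is the inversion efficiency.
    For eff = 1 this makes correct_t1 an exact inverse.
    """
    if m0 <= 0:
        raise ValueError("m0 must be positive")
    t1s = effective_t1star(t1_ms, protocol)
    a = m0 * t1s / t1_ms
    b = a + protocol.inversion_efficiency * m0
    return LookLockerParams(a_amp=a, b_amp=b, t1_star_ms=t1s)


def correct_t1(params: LookLockerParams) -> float:
    """Look-Locker correction T1 = T1* (B/A - 1).

    Raises for B <= A, which cannot arise from a physical inversion-recovery
    signal and signals a failed fit.
    """
    if params.b_amp <= params.a_amp:
        raise ValueError("non-physical fit: b_amp must exceed a_amp")
    return params.t1_star_ms * (params.b_amp / params.a_amp - 1.0)


def simulate_pixel_series(
    t1_ms: float,
    m0: float,
    protocol: AcquisitionProtocol,
    noise_sd: float = 0.0,
    magnitude_mode: bool = False,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Simulate one pixel's inversion-recovery frame series.

    Gaussian noise of standard deviation ``noise_sd`` is added to the signed
    signal.  In ``magnitude_mode`` the magnitude of the complex-Gaussian
    corrupted signal is returned instead (Rician noise law of magnitude MR
    images).  Reproducible for a fixed ``rng`` seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    params = looklocker_params_from_tissue(t1_ms, m0, protocol)
    clean = forward_signal(frame_times(protocol), params)
    if noise_sd == 0:
        return np.abs(clean) if magnitude_mode else clean
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if magnitude_mode:
        re = clean + gen.normal(0.0, noise_sd, clean.shape)
        im = gen.normal(0.0, noise_sd, clean.shape)
        return np.hypot(re, im)
    return clean + gen.normal(0.0, noise_sd, clean.shape)
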