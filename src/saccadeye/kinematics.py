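"""Photomechanical microsaccade kinematics.

Light changes make fly photoreceptors contract: a fast light-driven phase
displaces and narrows the receptive field (RF) along the cell's hardwired
movement axis, and a slower relaxation returns it in darkness.  This module
turns a light-intensity history into that time-varying RF state.

Model
-----
The contraction target follows Michaelis-Menten saturation of a first-order
low-pass-filtered copy of the intensity (time constant ``tau_drive_ms``),
gated by a fixed response latency.  The RF offset relaxes toward the target
with ``tau_fast_ms`` while the target exceeds it (fast phase) and decays
with ``tau_slow_ms`` otherwise (slower return), so a brief saturating flash
keeps contracting for tens of milliseconds after light-off and relaxes fully
within about a second.  An adaptation gain depletes under sustained drive
and recovers in dim light, scaling contraction amplitude.  RF narrowing is
proportional to the normalized offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KineticsParams",
    "SaccadeState",
    "KinematicsError",
    "saccade_amplitude",
    "rf_trajectory",
    "apply_saccade",
    "SaccadeIntegrator",
]


class KinematicsError(ValueError):
    """Raised for invalid kinematics inputs."""


@dataclass(frozen=True)
class KineticsParams:
    """Microsaccade kinetics parameters (times in ms, angles in deg).

    Defaults: onset latency below 10 ms, fast-phase contraction peaking
    40-50 ms after a brief flash, full relaxation well under a second, and
    a maximal RF displacement of 2 deg of visual angle at saturating
    intensity.  Intensities are normalized luminance in [0, 1] with
    half-saturation ``I50``.
    """

    latency_ms: float = 8.0
    tau_drive_ms: float = 35.0
    tau_fast_ms: float = 20.0
    tau_slow_ms: float = 300.0
    A_max_deg: float = 2.0
    I50: float = 0.1
    narrow_max: float = 0.2
    adapt_tau_ms: float = 500.0
    adapt_depletion_tau_ms: float = 300.0

    def validate(self) -> None:
        for name in ("latency_ms", "tau_drive_ms", "tau_fast_ms", "tau_slow_ms",
                     "adapt_tau_ms", "adapt_depletion_tau_ms"):
            if getattr(self, name) < 0 or (name != "latency_ms" and getattr(self, name) <= 0):
                raise KinematicsError(f"{name} must be positive")
        if self.tau_slow_ms <= self.tau_fast_ms:
            raise KinematicsError("tau_slow must exceed tau_fast")
        if not (0.0 <= self.narrow_max < 1.0):
            raise KinematicsError("narrow_max must lie in [0, 1)")
        if self.A_max_deg < 0 or self.I50 <= 0:
            raise KinematicsError("A_max must be >= 0 and I50 > 0")


@dataclass
class SaccadeState:
    """Microsaccade state trajectories for one or more units.

    ``offset_deg`` is the signed rhabdomere displacement along the saccade
    axis (0 in darkness, bounded by A_max); ``narrowing`` the fractional
    FWHM reduction; ``gain`` the adaptation gain in (0, 1].
    Arrays are (n_t,) for a single unit or (n_units, n_t).
    """

    time_ms: np.ndarray
    offset_deg: np.ndarray
    narrowing: np.ndarray
    gain: np.ndarray

    def at(self, t_ms: float) -> tuple[np.ndarray, np.ndarray]:
        """(offset, narrowing) at time ``t_ms`` (nearest sample)."""
        if not (self.time_ms[0] <= t_ms <= self.time_ms[-1]):
            raise KinematicsError("t outside the state's time range")
        i = int(np.argmin(np.abs(self.time_ms - t_ms)))
        return self.offset_deg[..., i], self.narrowing[..., i]

    def to_csv(self, path) -> None:
        """Export a single-unit trajectory as columnar CSV."""
        import pandas as pd

        if self.offset_deg.ndim != 1:
            raise KinematicsError("CSV export expects a single-unit state")
        pd.DataFrame({
            "t_ms": self.time_ms, "offset_deg": self.offset_deg,
            "narrowing": self.narrowing, "gain": self.gain,
        }).to_csv(path, index=False)


def saccade_amplitude(I, params: KineticsParams | None = None):
    """Steady-state contraction amplitude (deg) vs normalized intensity.

    Michaelis-Menten saturation A_max * I / (I + I50): half-maximal at
    I = I50, saturating toward A_max.
    """
    p = params or KineticsParams()
    I_arr = np.asarray(I, dtype=float)
    if np.any(I_arr < 0):
        raise KinematicsError("intensity must be non-negative")
    out = p.A_max_deg * I_arr / (I_arr + p.I50)
    return float(out) if np.isscalar(I) or out.ndim == 0 else out


class SaccadeIntegrator:
    """Forward-Euler integrator for ``n`` units sharing one parameter set.

    Used both by :func:`rf_trajectory` (single unit, full light history) and
    by the closed-loop scene renderer, which steps it one frame at a time.
    """

    def __init__(self, params: KineticsParams, n: int, dt_ms: float):
        params.validate()
        if dt_ms <= 0 or dt_ms > 1.0 + 1e-9:
            raise KinematicsError("sampling interval must be positive and <= 1 ms")
        self.p = params
        self.n = n
        self.dt = float(dt_ms)
        self.lat_steps = int(round(params.latency_ms / dt_ms))
        self._buffer = np.zeros((self.lat_steps + 1, n))
        self._head = 0
        self.drive = np.zeros(n)
        self.offset = np.zeros(n)
        self.gain = np.ones(n)

    @property
    def narrowing(self) -> np.ndarray:
        if self.p.A_max_deg == 0:
            return np.zeros(self.n)
        return self.p.narrow_max * self.offset / self.p.A_max_deg

    def step(self, intensity: np.ndarray) -> np.ndarray:
        """Advance one time step with the current per-unit light intensity."""
        p, dt = self.p, self.dt
        self._buffer[self._head] = intensity
        self._head = (self._head + 1) % self._buffer.shape[0]
        delayed = self._buffer[self._head]  # intensity latency steps ago

        self.drive += dt * (delayed - self.drive) / p.tau_drive_ms
        u = self.drive / (self.drive + p.I50)
        target = self.gain * p.A_max_deg * u
        rising = target > self.offset
        self.offset = np.where(
            rising,
            self.offset + dt * (target - self.offset) / p.tau_fast_ms,
            self.offset - dt * self.offset / p.tau_slow_ms,
        )
        self.gain += dt * ((1.0 - self.gain) / p.adapt_tau_ms
                           - self.gain * u / p.adapt_depletion_tau_ms)
        np.clip(self.gain, 1e-6, 1.0, out=self.gain)
        np.clip(self.offset, 0.0, p.A_max_deg, out=self.offset)
        return self.offset


def rf_trajectory(light: np.ndarray, params: KineticsParams | None = None,
                  dt_ms: float = 1.0, time_ms: np.ndarray | None = None) -> SaccadeState:
    """Integrate a light-intensity time series into a microsaccade state.

    ``light`` is a non-negative normalized intensity series sampled
    uniformly at ``dt_ms`` (<= 1 ms).  If ``time_ms`` is given it must be
    uniform and consistent with ``dt_ms``.
    """
    p = params or KineticsParams()
    light = np.asarray(light, dtype=float)
    if np.any(light < 0):
        raise KinematicsError("intensities must be non-negative")
    if time_ms is not None:
        steps = np.diff(time_ms)
        if steps.size and (np.ptp(steps) > 1e-9 or abs(steps[0] - dt_ms) > 1e-9):
            raise KinematicsError("non-uniform time base")
    integ = SaccadeIntegrator(p, 1, dt_ms)
    n_t = light.size
    offset = np.empty(n_t)
    narrowing = np.empty(n_t)
    gain = np.empty(n_t)
    for i in range(n_t):
        integ.step(light[i : i + 1])
        offset[i] = integ.offset[0]
        narrowing[i] = integ.narrowing[0]
        gain[i] = integ.gain[0]
    t = time_ms if time_ms is not None else np.arange(n_t) * dt_ms
    return SaccadeState(time_ms=np.asarray(t, dtype=float), offset_deg=offset,
                        narrowing=narrowing, gain=gain)


@dataclass(frozen=True)
class DisplacedRF:
    """A displaced/narrowed circular Gaussian RF profile in visual space."""

    center_az_deg: float
    center_el_deg: float
    fwhm_deg: float

    @property
    def sigma_deg(self) -> float:
        return self.fwhm_deg / 2.3548200450309493  # FWHM -> Gaussian sigma

    def sensitivity(self, az_deg, el_deg):
        """Unit-integral profile value at the given direction(s), per deg^2."""
        s = self.sigma_deg
        d2 = (np.asarray(az_deg) - self.center_az_deg) ** 2 + (
            np.asarray(el_deg) - self.center_el_deg
        ) ** 2
        return np.exp(-d2 / (2.0 * s * s)) / (2.0 * np.pi * s * s)


def apply_saccade(rf, state: SaccadeState, t_ms: float,
                  saccade_axis: tuple[float, float] = (1.0, 0.0)) -> DisplacedRF:
    """RF profile at time ``t_ms`` under the given microsaccade state.

    The rhabdomere moves +offset along ``saccade_axis``; the ommatidial lens
    inverts that motion, so the RF center in visual space shifts by -offset
    along the axis.  The FWHM shrinks by the narrowing fraction; the profile
    stays normalized to unit integral.  ``rf`` needs attributes
    ``center_az_deg``, ``center_el_deg`` and ``fwhm_deg`` (a
    :class:`DisplacedRF` works).
    """
    offset, narrowing = state.at(t_ms)
    off = float(np.asarray(offset).ravel()[0])
    nar = float(np.asarray(narrowing).ravel()[0])
    ax = np.asarray(saccade_axis, dtype=float)
    return DisplacedRF(
        center_az_deg=rf.center_az_deg - off * ax[0],
        center_el_deg=rf.center_el_deg - off * ax[1],
        fwhm_deg=rf.fwhm_deg * (1.0 - nar),
    )
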