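"""Depth from binocular time disparity.

A moving object crosses the corresponding left- and right-eye receptive
fields at slightly different times because the two eyes view it from
vantage points a baseline k apart: the inter-eye response lag Δt, together
with a velocity estimate ω from neighbor-correlation within one eye,
encodes the object depth z (static triangulation gives Δt = 2·atan(k/2z)/ω,
i.e. z = k / (2 tan(ω Δt / 2))).  With mirror-symmetric microsaccades the
measured Δt additionally reflects the light-driven receptive-field motion,
so the default decoder inverts a calibration table built by forward
simulation of the full dynamic model rather than the pure-geometry closed
form.

All disparities are signed with the convention: positive when the left-eye
response leads (rises earlier), the case for left-to-right object motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.signal import correlate, correlation_lags

from .geometry import EyePair, angular_distance_deg
from .kinematics import KineticsParams
from .phototransduction import (PhotoreceptorParams, VoltageResponse,
                                adaptive_response, bump_response)
from .stimuli import Dot, Scene, make_dot_pair, render_binocular

__all__ = [
    "DepthError",
    "UndefinedDisparityError",
    "VelocityUndefinedError",
    "DepthOutOfRangeError",
    "DepthEstimate",
    "DepthCalibration",
    "time_disparity",
    "velocity_estimate",
    "estimate_depth_closed_form",
    "estimate_depth",
    "build_calibration",
    "run_depth_trial",
    "depth_error_curve",
    "ablation_suite",
    "ablation_experiment",
    "frontal_cartridge_indices",
]


class DepthError(RuntimeError):
    pass


class UndefinedDisparityError(DepthError):
    """Raised when a response pair carries no usable disparity (flat input)."""


class VelocityUndefinedError(DepthError):
    """Raised when the neighbor lag is too small to normalize velocity."""


class DepthOutOfRangeError(DepthError):
    """Raised when a disparity cannot be mapped to a positive finite depth."""


@dataclass
class DepthEstimate:
    """One depth estimate with its intermediate quantities."""

    delta_t_ms: float
    omega_hat_dps: float
    z_hat_mm: float
    z_true_mm: float | None = None
    rel_error: float | None = None
    delta_t_neighbor_ms: float | None = None
    clamped: bool = False
    ok: bool = True
    failure: str | None = None
    seed: int | None = None


# ---------------------------------------------------------------------------
# Disparity and velocity measurement
# ---------------------------------------------------------------------------

def _series(v) -> np.ndarray:
    x = v.v if isinstance(v, VoltageResponse) else np.asarray(v, dtype=float)
    return np.asarray(x, dtype=float).ravel()


def time_disparity(left, right, dt_ms: float | None = None,
                   max_lag_ms: float = 250.0, start_ms: float = 0.0) -> float:
    """Signed inter-eye response lag (ms), positive when ``left`` leads.

    The lag maximizing the overlap-normalized (unbiased) cross-correlation
    of the mean-subtracted waveforms, refined to sub-sample precision by
    parabolic interpolation around the discrete peak.  ``start_ms`` crops
    an initial segment (e.g. a shared stimulus-onset transient) before
    correlating.
    """
    if dt_ms is None:
        if not isinstance(left, VoltageResponse):
            raise DepthError("dt_ms required for raw-array inputs")
        dt_ms = left.dt_ms
    i0 = int(start_ms / dt_ms)
    a = _series(left)[i0:]
    b = _series(right)[i0:]
    if a.size != b.size:
        raise DepthError("responses must share a common time base")
    # Channels carrying no stimulus-driven modulation (e.g. a dark eye whose
    # only activity is spontaneous dark bumps) have no usable disparity.
    if a.std() < 1e-3 or b.std() < 1e-3:
        raise UndefinedDisparityError("flat response: disparity undefined")
    # Correlate first differences: the (arbitrary) response baseline drops
    # out exactly, so the finite correlation window adds no triangular bias,
    # and the correlation peak sharpens onto the response transients.
    a = np.diff(a)
    b = np.diff(b)
    scale = np.sqrt(np.sum(a * a) * np.sum(b * b))
    if not np.isfinite(scale) or scale < 1e-12:
        raise UndefinedDisparityError("flat response: disparity undefined")
    c = correlate(b, a, mode="full") / scale
    lags = correlation_lags(b.size, a.size, mode="full")
    win = np.abs(lags) <= max_lag_ms / dt_ms
    c_w, lags_w = c[win], lags[win]
    i = int(np.argmax(c_w))
    lag = float(lags_w[i])
    if 0 < i < c_w.size - 1:
        denom = c_w[i - 1] - 2.0 * c_w[i] + c_w[i + 1]
        if abs(denom) > 1e-15:
            lag += 0.5 * (c_w[i - 1] - c_w[i + 1]) / denom
    return lag * dt_ms


def velocity_estimate(resp, resp_neighbor, delta_phi_deg: float,
                      dt_ms: float | None = None,
                      max_lag_ms: float = 400.0,
                      start_ms: float = 0.0) -> tuple[float, float]:
    """Angular-velocity estimate from along-motion neighbor correlation.

    Returns (omega_hat in deg/s, neighbor lag in ms): the stimulus needs
    ``|lag|`` > the sampling step to define a velocity.  ``delta_phi_deg``
    is signed along the motion axis (a neighbor the stimulus reaches first
    has negative separation and yields a negative lag).
    """
    if delta_phi_deg == 0:
        raise DepthError("neighbor separation must be non-zero")
    if dt_ms is None:
        dt_ms = resp.dt_ms
    try:
        lag_ms = time_disparity(resp, resp_neighbor, dt_ms, max_lag_ms, start_ms)
    except UndefinedDisparityError as exc:
        raise VelocityUndefinedError(str(exc)) from exc
    if abs(lag_ms) < 1.5 * dt_ms:
        raise VelocityUndefinedError("near-zero neighbor lag: velocity undefined")
    return 1000.0 * delta_phi_deg / lag_ms, lag_ms


# ---------------------------------------------------------------------------
# Depth decoding
# ---------------------------------------------------------------------------

def estimate_depth_closed_form(delta_t_ms: float, omega_hat_dps: float,
                               baseline_mm: float) -> float:
    """Static-triangulation depth: z = k / (2 tan(omega * delta_t / 2))."""
    x = np.deg2rad(omega_hat_dps) * delta_t_ms / 1000.0  # rad of angular disparity
    if x <= 0:
        raise DepthOutOfRangeError("non-positive disparity: depth out of range")
    return baseline_mm / (2.0 * np.tan(x / 2.0))


@dataclass
class DepthCalibration:
    """Monotone Δt·ω -> z lookup from forward simulation of the full model."""

    z_mm: np.ndarray
    delta_t_ms: np.ndarray
    omega_hat_dps: np.ndarray
    mode: str = "microsaccadic"
    _interp: PchipInterpolator | None = field(default=None, repr=False)

    @property
    def product(self) -> np.ndarray:
        """Calibration disparity products ω̂·Δt (deg·ms/1000 = mdeg·s... deg)."""
        return self.omega_hat_dps * self.delta_t_ms / 1000.0

    def __post_init__(self):
        p = self.product
        dz = np.diff(self.z_mm)
        dp = np.diff(p)
        if not (np.all(dz > 0) and (np.all(dp < 0) or np.all(dp > 0))):
            raise DepthError("calibration table is not monotone")
        order = np.argsort(p)
        self._interp = PchipInterpolator(p[order], np.log(self.z_mm[order]))

    @property
    def monotone_direction(self) -> str:
        """'decreasing' if Δt·ω shrinks with depth (closer = longer lag)."""
        return "decreasing" if self.product[0] > self.product[-1] else "increasing"

    def decode(self, delta_t_ms: float, omega_hat_dps: float) -> tuple[float, bool]:
        """(z_hat_mm, clamped): disparities beyond the table clamp to its ends."""
        p = omega_hat_dps * delta_t_ms / 1000.0
        lo, hi = self.product.min(), self.product.max()
        clamped = not (lo <= p <= hi)
        p = float(np.clip(p, lo, hi))
        return float(np.exp(self._interp(p))), clamped


def estimate_depth(delta_t_ms: float, omega_hat_dps: float, eye_pair: EyePair,
                   calibration: DepthCalibration | None = None) -> tuple[float, bool]:
    """Decode depth from (Δt, ω̂): calibrated lookup if given, else closed form."""
    if calibration is not None:
        return calibration.decode(delta_t_ms, omega_hat_dps)
    return estimate_depth_closed_form(delta_t_ms, omega_hat_dps, eye_pair.baseline_mm), False


# ---------------------------------------------------------------------------
# End-to-end trials
# ---------------------------------------------------------------------------

def frontal_cartridge_indices(eye_pair: EyePair) -> tuple[int, int]:
    """(frontal cartridge, its along-motion +azimuth neighbor) indices.

    By mirror construction the same index addresses the corresponding
    cartridge in both eyes.  The neighbor is the same-row lattice neighbor
    on the +azimuth side in head coordinates of the *left* eye (the next
    sampling station along left-to-right motion).
    """
    eye = eye_pair.left
    c = eye.nearest_ommatidium(0.0, 0.0)
    best, best_daz = None, 0.0
    for j in eye.neighbors[c]:
        daz = eye.az[j] - eye.az[c]
        if abs(eye.el[j] - eye.el[c]) < 0.5 * eye_pair.config.interommatidial_deg and daz > best_daz:
            best, best_daz = int(j), daz
    if best is None:
        raise DepthError("no along-motion neighbor found for the frontal cartridge")
    return int(c), best


def _equatorial_row(eye) -> np.ndarray:
    """Indices of the equatorial ommatidium row, sorted by head azimuth."""
    row = np.where(np.abs(eye.el) < 1e-6)[0]
    return row[np.argsort(eye.az[row])]


def _disparity_channels(eye_pair: EyePair, n_cartridges: int = 3
                        ) -> tuple[list, list, float]:
    """Binocular and along-motion channel member sets for depth trials.

    Each channel pools the shared-axis central photoreceptors (R7/R8) of
    ``n_cartridges`` consecutive equatorial cartridges.  The binocular
    channel is centered on azimuth 0 — an azimuth-symmetric member set, so
    the mirrored right-eye channel sees exactly the time-shifted copy of
    the left channel's waveform.  The velocity channel is the next disjoint
    cartridge block along the motion direction (left eye); the returned
    separation is the distance between channel centroids.
    """
    row_l = _equatorial_row(eye_pair.left)
    az_l = eye_pair.left.az[row_l]
    i0 = int(np.argmin(np.abs(az_l)))
    half = n_cartridges // 2
    a_idx = row_l[i0 - half: i0 - half + n_cartridges]
    # the preceding disjoint block: motion (left to right) arrives there first
    b_idx = row_l[i0 - half - n_cartridges: i0 - half]
    if a_idx.size < n_cartridges or b_idx.size < n_cartridges:
        raise DepthError("equatorial row too short for the requested channels")
    members_a = [(int(o), p) for o in a_idx for p in (6, 7)]
    members_b = [(int(o), p) for o in b_idx for p in (6, 7)]
    delta_phi = float(np.mean(eye_pair.left.az[b_idx]) - np.mean(eye_pair.left.az[a_idx]))
    return members_a, members_b, delta_phi


def _align_pool(v: np.ndarray, az_rel_deg: np.ndarray, omega_dps: float,
                dt_ms: float) -> np.ndarray:
    """Motion-compensated pooling of member responses.

    Each member's response is advanced by its azimuthal offset from the
    channel centroid divided by the estimated angular velocity (the time the
    moving stimulus needs to travel between them), so all members' transits
    superimpose coherently; the aligned responses are averaged.  Fractional
    shifts use linear interpolation with edge hold.
    """
    nt = v.shape[1]
    t = np.arange(nt, dtype=float)
    out = np.zeros(nt)
    for row, a in zip(v, az_rel_deg):
        adv = 1000.0 * a / omega_dps / dt_ms  # bins
        out += np.interp(t + adv, t, row)
    return out / v.shape[0]


def _trial_scene(z_mm: float, eye_pair: EyePair, speed_dps: float,
                 separation_deg: float, diameter_deg: float, dt_ms: float,
                 n_dots: int) -> Scene:
    half_disp = np.rad2deg(np.arctan(eye_pair.baseline_mm / (2.0 * z_mm)))
    # start far enough left that the velocity block's first receptive-field
    # contact falls after the onset settle window; cover the binocular block
    start = -(31.0 + half_disp)
    end = 13.0 + half_disp
    if n_dots >= 2:
        return make_dot_pair(separation_deg=separation_deg, speed_dps=speed_dps,
                             depth_mm=z_mm, diameter_deg=diameter_deg,
                             start_az_deg=start, end_az_deg=end, dt_ms=dt_ms)
    dot = Dot(az_deg=start, el_deg=0.0, diameter_deg=diameter_deg, luminance=0.0,
              depth_mm=z_mm, speed_dps=speed_dps)
    duration = 1000.0 * (end - start) / speed_dps if speed_dps > 0 else 400.0
    return Scene(objects=[dot], background=1.0, duration_ms=duration, dt_ms=dt_ms)


def run_depth_trial(eye_pair: EyePair, z_mm: float,
                    kinematics: KineticsParams | None = None,
                    photoreceptor: PhotoreceptorParams | None = None,
                    mode: str = "microsaccadic", stochastic: bool = True,
                    seed: int | None = None,
                    calibration: DepthCalibration | None = None,
                    speed_dps: float = 50.0, separation_deg: float = 3.5,
                    diameter_deg: float = 3.9, n_dots: int = 1,
                    dt_ms: float = 1.0,
                    phase_ms: float = 0.0, decode: bool = True) -> DepthEstimate:
    """One end-to-end depth-estimation trial.

    Renders the moving-dot scene for the frontal binocular cartridges (and
    the left eye's along-motion neighbor cartridge), converts the pooled
    cartridge light to photoreceptor responses (stochastic quantum-bump
    model or its deterministic mean-field surrogate), measures the
    inter-eye time disparity and the neighbor-correlation velocity, and
    decodes depth.  Failures (flat channels, undefined velocity) are
    reported in the returned estimate rather than raised.
    """
    kin = kinematics or KineticsParams()
    prp = photoreceptor or PhotoreceptorParams()
    members_a, members_b, delta_phi = _disparity_channels(eye_pair)
    omms = {("left", o) for o, _ in members_a + members_b}
    omms |= {("right", o) for o, _ in members_a}
    subset = sorted(omms)

    scene = _trial_scene(z_mm, eye_pair, speed_dps, separation_deg, diameter_deg,
                         dt_ms, n_dots)
    light = render_binocular(scene, eye_pair, kin, mode=mode, seed=seed,
                             subset=subset, phase_ms=phase_ms)
    rng = np.random.default_rng(seed)

    def transduce(rows):
        x = light.intensity[rows]
        if stochastic:
            return np.atleast_2d(bump_response(x, dt_ms, prp, rng).v)
        return np.atleast_2d(adaptive_response(x, dt_ms, prp).v)

    v_a_left = transduce(light.rows(members_a, "left"))
    v_a_right = transduce(light.rows(members_a, "right"))
    v_b_left = transduce(light.rows(members_b, "left"))
    az_a_left = np.array([eye_pair.left.az[o] for o, _ in members_a])
    az_a_right = np.array([eye_pair.right.az[o] for o, _ in members_a])
    az_b_left = np.array([eye_pair.left.az[o] for o, _ in members_b])

    # Crop the shared stimulus-onset transient before aligning: the
    # edge-held interpolation then only ever extends the flat plateau.
    settle_ms = 150.0
    i0 = int(settle_ms / dt_ms)
    v_a_left, v_a_right, v_b_left = (v[:, i0:] for v in
                                     (v_a_left, v_a_right, v_b_left))
    try:
        # pass 1: coarse velocity from the unaligned pooled channels
        omega_hat, lag_n = velocity_estimate(v_a_left.mean(axis=0),
                                             v_b_left.mean(axis=0), delta_phi,
                                             dt_ms)
        # pass 2: motion-compensated member alignment, then refined velocity
        for _ in range(2):
            p_a = _align_pool(v_a_left, az_a_left - az_a_left.mean(), omega_hat, dt_ms)
            p_b = _align_pool(v_b_left, az_b_left - az_b_left.mean(), omega_hat, dt_ms)
            omega_hat, lag_n = velocity_estimate(p_a, p_b, delta_phi, dt_ms)
        p_a_left = _align_pool(v_a_left, az_a_left - az_a_left.mean(), omega_hat, dt_ms)
        p_a_right = _align_pool(v_a_right, az_a_right - az_a_right.mean(),
                                omega_hat, dt_ms)
        delta_t = time_disparity(p_a_left, p_a_right, dt_ms)
        if decode:
            z_hat, clamped = estimate_depth(delta_t, omega_hat, eye_pair, calibration)
        else:
            z_hat, clamped = float("nan"), False
    except DepthError as exc:
        return DepthEstimate(delta_t_ms=np.nan, omega_hat_dps=np.nan,
                             z_hat_mm=np.nan, z_true_mm=z_mm, rel_error=np.nan,
                             ok=False, failure=type(exc).__name__, seed=seed)
    return DepthEstimate(
        delta_t_ms=delta_t, omega_hat_dps=omega_hat, z_hat_mm=z_hat,
        z_true_mm=z_mm,
        rel_error=abs(z_hat - z_mm) / z_mm if decode else float("nan"),
        delta_t_neighbor_ms=lag_n, clamped=clamped, seed=seed,
    )


def build_calibration(eye_pair: EyePair,
                      kinematics: KineticsParams | None = None,
                      photoreceptor: PhotoreceptorParams | None = None,
                      z_grid_mm: Sequence[float] | None = None,
                      mode: str = "microsaccadic", **trial_kw) -> DepthCalibration:
    """Forward-simulate the noise-free model to build the Δt·ω -> z table."""
    if z_grid_mm is None:
        z_grid_mm = np.geomspace(2.0, 450.0, 15)
    z_grid_mm = np.asarray(sorted(z_grid_mm), dtype=float)
    dts, omegas = [], []
    for z in z_grid_mm:
        est = run_depth_trial(eye_pair, float(z), kinematics, photoreceptor,
                              mode=mode, stochastic=False, calibration=None,
                              decode=False, **trial_kw)
        if not est.ok:
            raise DepthError(f"calibration failed at z={z} mm: {est.failure}")
        dts.append(est.delta_t_ms)
        omegas.append(est.omega_hat_dps)
    return DepthCalibration(z_mm=z_grid_mm, delta_t_ms=np.array(dts),
                            omega_hat_dps=np.array(omegas), mode=mode)


def depth_error_curve(eye_pair: EyePair, z_list_mm: Sequence[float],
                      n_trials: int, seed: int,
                      kinematics: KineticsParams | None = None,
                      photoreceptor: PhotoreceptorParams | None = None,
                      calibration: DepthCalibration | None = None,
                      mode: str = "microsaccadic",
                      **trial_kw) -> tuple[pd.DataFrame, dict]:
    """Monte-Carlo relative depth error vs object distance.

    Runs ``n_trials`` seeded stochastic end-to-end trials per depth and
    aggregates |z_hat - z| / z; per-trial estimation failures are excluded
    from the mean and reported as a failure rate.
    """
    if n_trials < 2:
        raise DepthError("n_trials must be >= 2")
    if calibration is None:
        calibration = build_calibration(eye_pair, kinematics, photoreceptor,
                                        mode="microsaccadic", **trial_kw)
    ss = np.random.SeedSequence(seed)
    rows = []
    for z in z_list_mm:
        if z <= 0:
            raise DepthError("depths must be positive")
        for trial, child in enumerate(ss.spawn(n_trials)):
            trial_seed = int(child.generate_state(1)[0] % (2 ** 31))
            est = run_depth_trial(eye_pair, float(z), kinematics, photoreceptor,
                                  mode=mode, stochastic=True, seed=trial_seed,
                                  calibration=calibration, **trial_kw)
            rows.append({
                "z_true_mm": z, "z_hat_mm": est.z_hat_mm,
                "delta_t_ms": est.delta_t_ms, "omega_dps": est.omega_hat_dps,
                "rel_error": est.rel_error, "trial": trial, "seed": trial_seed,
                "ok": est.ok, "failure": est.failure,
            })
    df = pd.DataFrame(rows)
    summary = {}
    for z in z_list_mm:
        sub = df[df.z_true_mm == z]
        ok = sub[sub.ok]
        summary[float(z)] = {
            "mean_rel_error": float(ok.rel_error.mean()) if len(ok) else float("nan"),
            "sd_rel_error": float(ok.rel_error.std()) if len(ok) > 1 else float("nan"),
            "failure_rate": float(1.0 - len(ok) / len(sub)),
            "n": int(len(sub)),
        }
    return df, summary


def ablation_suite(eye_pair: EyePair, modes: Sequence[str], z_mm: float = 25.0,
                   n_trials: int = 100, seed: int = 0, phase_ms: float = 20.0,
                   kinematics: KineticsParams | None = None,
                   photoreceptor: PhotoreceptorParams | None = None,
                   calibration: DepthCalibration | None = None,
                   **trial_kw) -> dict:
    """Sampling-mode ablations vs one shared mirror-symmetric control.

    The binocular microsaccadic control is simulated once per trial seed
    and every ablated mode reruns the identical trial (same seed, same
    scene), so all comparisons are paired.
    """
    for mode in modes:
        if mode not in ("monocular", "asynchronous", "asymmetric"):
            raise DepthError(f"unknown ablation mode {mode!r}")
    if calibration is None:
        calibration = build_calibration(eye_pair, kinematics, photoreceptor,
                                        mode="microsaccadic", **trial_kw)
    ss = np.random.SeedSequence(seed)
    seeds = [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n_trials)]

    def series(mode):
        errs, failures = [], 0
        for trial_seed in seeds:
            est = run_depth_trial(eye_pair, z_mm, kinematics, photoreceptor,
                                  mode=mode, stochastic=True, seed=trial_seed,
                                  calibration=calibration, phase_ms=phase_ms,
                                  **trial_kw)
            if est.ok:
                errs.append(est.rel_error)
            else:
                failures += 1
        return errs, failures

    ctrl_err, ctrl_fail = series("microsaccadic")
    out = {
        "z_mm": z_mm,
        "n_trials": n_trials,
        "control_mean_rel_error": float(np.mean(ctrl_err)) if ctrl_err else float("nan"),
        "control_failure_rate": ctrl_fail / n_trials,
        "modes": {},
    }
    for mode in modes:
        errs, failures = series(mode)
        out["modes"][mode] = {
            "ablated_mean_rel_error": float(np.mean(errs)) if errs else float("nan"),
            "ablated_failure_rate": failures / n_trials,
            "phase_ms": phase_ms if mode == "asynchronous" else None,
        }
    return out


def ablation_experiment(eye_pair: EyePair, mode: str, z_mm: float = 25.0,
                        n_trials: int = 100, seed: int = 0,
                        phase_ms: float = 20.0,
                        kinematics: KineticsParams | None = None,
                        photoreceptor: PhotoreceptorParams | None = None,
                        calibration: DepthCalibration | None = None,
                        **trial_kw) -> dict:
    """One sampling-mode ablation vs the mirror-symmetric binocular control.

    ``mode``: 'monocular' (one eye's channels zeroed), 'asynchronous' (one
    eye's kinematic state delayed by ``phase_ms``), or 'asymmetric' (one
    eye's receptive fields frozen).  See :func:`ablation_suite`.
    """
    suite = ablation_suite(eye_pair, [mode], z_mm=z_mm, n_trials=n_trials,
                           seed=seed, phase_ms=phase_ms, kinematics=kinematics,
                           photoreceptor=photoreceptor, calibration=calibration,
                           **trial_kw)
    return {
        "mode": mode,
        "z_mm": z_mm,
        "n_trials": n_trials,
        "control_mean_rel_error": suite["control_mean_rel_error"],
        **suite["modes"][mode],
    }
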