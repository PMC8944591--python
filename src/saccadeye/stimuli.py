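"""Synthetic scenes and binocular rendering.

Scenes are parametric 3D stimuli (moving dots, square-wave gratings, pins on
dots) on a uniform background.  ``render_binocular`` turns a scene into
per-photoreceptor light time series, viewing it in perspective from each
eye's vantage point (inter-eye baseline), with the photomechanical
microsaccade loop optionally closed: rendered light drives each
ommatidium's contraction state, the contraction displaces and narrows its
receptive fields, and the moved RFs change the light on the next frame.

Receptive fields are circular Gaussians (sigma = FWHM / 2.3548).  Dots are
integrated exactly over the Gaussian profile (offset disc-Gaussian mass via
the noncentral chi-square CDF); gratings are integrated analytically per
Fourier harmonic.  Gratings use an even (cosine) square-wave convention —
a white stripe is centered on the phase origin — which keeps mirrored
scenes bit-identical under azimuth sign flip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import ncx2

from .geometry import EyePair, Eye
from .kinematics import KineticsParams, SaccadeIntegrator, SaccadeState

__all__ = [
    "Dot",
    "Grating",
    "Pin",
    "Scene",
    "LightInput",
    "SceneError",
    "make_dot_pair",
    "make_hidden_dot_scene",
    "scene_from_dict",
    "load_scene",
    "render_binocular",
    "rasterize",
    "mirror_scene",
    "frontal_subset",
]

_FWHM_TO_SIGMA = 1.0 / 2.3548200450309493


class SceneError(ValueError):
    """Raised for invalid scene descriptions or render modes."""


# ---------------------------------------------------------------------------
# Scene objects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Dot:
    """A circular dot; angular diameter as seen from the head center.

    ``depth_mm=None`` places the dot at optical infinity (both eyes see the
    same direction); otherwise the dot sits ``depth_mm`` from the head
    origin and moves on that sphere at ``speed_dps`` in azimuth, so each eye
    sees it with its own perspective parallax.
    """

    az_deg: float
    el_deg: float = 0.0
    diameter_deg: float = 1.7
    luminance: float = 0.0
    depth_mm: float | None = None
    speed_dps: float = 0.0

    def azimuth_at(self, t_ms: float | np.ndarray):
        return self.az_deg + self.speed_dps * (np.asarray(t_ms) / 1000.0)


@dataclass(frozen=True)
class Pin:
    """A thin pin protruding axially (toward the viewer) from a base dot."""

    base: Dot
    length_mm: float = 4.0
    diameter_deg: float = 1.0
    n_segments: int = 5

    def segments(self) -> list[Dot]:
        if self.base.depth_mm is None:
            raise SceneError("a pin needs a base dot with finite depth")
        depths = np.linspace(self.base.depth_mm, self.base.depth_mm - self.length_mm,
                             self.n_segments)
        return [
            Dot(az_deg=self.base.az_deg, el_deg=self.base.el_deg,
                diameter_deg=self.diameter_deg, luminance=self.base.luminance,
                depth_mm=float(d), speed_dps=self.base.speed_dps)
            for d in depths
        ]


@dataclass(frozen=True)
class Grating:
    """Full-field vertical square-wave grating (black/white stripes).

    ``wavelength_deg`` is the spatial period (two stripe widths).  The
    pattern is sign(cos(2 pi (az - phase)/lambda)): a ``high`` stripe is
    centered at ``phase_deg``.  ``drift_dps`` moves the pattern in azimuth
    (a panoramic grating drifting at the yaw rate).
    """

    wavelength_deg: float
    high: float = 1.0
    low: float = 0.0
    phase_deg: float = 0.0
    drift_dps: float = 0.0
    n_harmonics: int = 13

    @property
    def contrast(self) -> float:
        tot = self.high + self.low
        return (self.high - self.low) / tot if tot > 0 else 0.0

    def phase_at(self, t_ms: float):
        return self.phase_deg + self.drift_dps * (t_ms / 1000.0)


@dataclass
class Scene:
    """A synthetic 3D stimulus with a time base.

    Before ``onset_ms`` every photoreceptor sees ``pre_onset_luminance``
    (default: the background), which lets experiments present a stimulus
    appearing out of darkness.
    """

    objects: list = field(default_factory=list)
    background: float = 1.0
    duration_ms: float = 500.0
    dt_ms: float = 1.0
    onset_ms: float = 0.0
    pre_onset_luminance: float | None = None

    def validate(self) -> None:
        if self.dt_ms <= 0 or self.dt_ms > 1.0 + 1e-9:
            raise SceneError("dt must be positive and <= 1 ms")
        if not (0.0 <= self.background <= 1.0):
            raise SceneError("background luminance must lie in [0, 1]")
        for obj in self.objects:
            for lum in _object_luminances(obj):
                if not (0.0 <= lum <= 1.0):
                    raise SceneError("object luminances must lie in [0, 1]")

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(0.0, self.duration_ms, self.dt_ms)


def _object_luminances(obj):
    if isinstance(obj, Dot):
        return [obj.luminance]
    if isinstance(obj, Pin):
        return [obj.base.luminance]
    if isinstance(obj, Grating):
        return [obj.high, obj.low]
    raise SceneError(f"unknown scene object {type(obj).__name__}")


def mirror_scene(scene: Scene) -> Scene:
    """The scene under azimuth sign flip (x -> -x)."""
    mirrored = []
    for obj in scene.objects:
        if isinstance(obj, Dot):
            mirrored.append(
                Dot(az_deg=-obj.az_deg, el_deg=obj.el_deg,
                    diameter_deg=obj.diameter_deg, luminance=obj.luminance,
                    depth_mm=obj.depth_mm, speed_dps=-obj.speed_dps))
        elif isinstance(obj, Pin):
            mirrored.append(
                Pin(base=mirror_scene(Scene(objects=[obj.base])).objects[0],
                    length_mm=obj.length_mm, diameter_deg=obj.diameter_deg,
                    n_segments=obj.n_segments))
        elif isinstance(obj, Grating):
            mirrored.append(
                Grating(wavelength_deg=obj.wavelength_deg, high=obj.high,
                        low=obj.low, phase_deg=-obj.phase_deg,
                        drift_dps=-obj.drift_dps, n_harmonics=obj.n_harmonics))
        else:
            raise SceneError(f"unknown scene object {type(obj).__name__}")
    return Scene(objects=mirrored, background=scene.background,
                 duration_ms=scene.duration_ms, dt_ms=scene.dt_ms,
                 onset_ms=scene.onset_ms,
                 pre_onset_luminance=scene.pre_onset_luminance)


# ---------------------------------------------------------------------------
# Scene factories
# ---------------------------------------------------------------------------

def make_dot_pair(separation_deg: float = 3.5, speed_dps: float = 50.0,
                  depth_mm: float = 25.0, diameter_deg: float = 1.7,
                  el_deg: float = 0.0, background: float = 1.0,
                  luminance: float = 0.0, start_az_deg: float = -12.0,
                  end_az_deg: float = 12.0, dt_ms: float = 1.0) -> Scene:
    """Two dark dots crossing the frontal field left to right.

    The leading dot starts at ``start_az_deg`` with the second one trailing
    ``separation_deg`` behind; both translate at ``speed_dps`` on the
    ``depth_mm`` sphere.  Duration is sized so the trailing dot clears
    ``end_az_deg`` (static if speed is zero).
    """
    if separation_deg <= 0 or depth_mm <= 0 or speed_dps < 0:
        raise SceneError("separation and depth must be positive, speed non-negative")
    dots = [
        Dot(az_deg=start_az_deg, el_deg=el_deg, diameter_deg=diameter_deg,
            luminance=luminance, depth_mm=depth_mm, speed_dps=speed_dps),
        Dot(az_deg=start_az_deg - separation_deg, el_deg=el_deg,
            diameter_deg=diameter_deg, luminance=luminance, depth_mm=depth_mm,
            speed_dps=speed_dps),
    ]
    if speed_dps > 0:
        duration = 1000.0 * (end_az_deg - start_az_deg + separation_deg) / speed_dps
    else:
        duration = 300.0
    return Scene(objects=dots, background=background, duration_ms=duration, dt_ms=dt_ms)


def make_hidden_dot_scene(dot_deg: float = 0.98, stripe_deg: float = 1.2,
                          dot_position_deg: float = 0.0,
                          el_deg: float = 0.0) -> tuple[Scene, Scene]:
    """A black dot hidden among black/white stripes, plus the dotless control.

    Stripes are ``stripe_deg`` wide (period 2*stripe_deg) at full contrast;
    the dot is placed centered on a white stripe.  ``dot_position_deg`` is
    snapped to the nearest white-stripe center so left/middle/right
    placements stay representable.
    """
    if dot_deg <= 0 or stripe_deg <= 0:
        raise SceneError("dot and stripe sizes must be positive")
    wavelength = 2.0 * stripe_deg
    snapped = wavelength * round(dot_position_deg / wavelength)
    grating = Grating(wavelength_deg=wavelength, high=1.0, low=0.0, phase_deg=0.0)
    dot = Dot(az_deg=snapped, el_deg=el_deg, diameter_deg=dot_deg, luminance=0.0,
              depth_mm=None)
    scene = Scene(objects=[grating, dot], background=1.0)
    control = Scene(objects=[grating], background=1.0)
    return scene, control


def scene_from_dict(data: dict) -> Scene:
    """Build a Scene from a plain mapping (YAML/JSON scene description)."""
    kinds = {"dot": Dot, "grating": Grating}
    objects = []
    for item in data.get("objects", []):
        item = dict(item)
        kind = item.pop("type", None)
        if kind == "pin":
            base = item.pop("base", None)
            if not isinstance(base, dict):
                raise SceneError("pin object needs a 'base' dot mapping")
            objects.append(Pin(base=Dot(**base), **item))
        elif kind in kinds:
            objects.append(kinds[kind](**item))
        else:
            raise SceneError(f"unknown scene object type {kind!r}")
    scene = Scene(objects=objects,
                  **{k: v for k, v in data.items() if k != "objects"})
    scene.validate()
    return scene


def load_scene(path) -> Scene:
    """Load a Scene from a YAML or JSON description file."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise SceneError(f"scene file {path} must contain a mapping")
    return scene_from_dict(data)


# ---------------------------------------------------------------------------
# Rasterization (for receptive-field convolution analyses)
# ---------------------------------------------------------------------------

def rasterize(scene: Scene, az_grid: np.ndarray, el_grid: np.ndarray,
              t_ms: float = 0.0) -> np.ndarray:
    """Angular luminance image of a scene, shape (n_el, n_az).

    Dots are drawn at their head-centric angular position regardless of
    depth (the raster is a single angular map); gratings cover the field.
    """
    AZ, EL = np.meshgrid(np.asarray(az_grid, float), np.asarray(el_grid, float))
    img = np.full(AZ.shape, scene.background, dtype=float)
    for obj in scene.objects:
        if isinstance(obj, Grating):
            arg = 2.0 * np.pi * (AZ - obj.phase_at(t_ms)) / obj.wavelength_deg
            img = np.where(np.cos(arg) >= 0.0, obj.high, obj.low)
    for obj in scene.objects:
        if isinstance(obj, Pin):
            obj = obj.base
        if isinstance(obj, Dot):
            d2 = (AZ - obj.azimuth_at(t_ms)) ** 2 + (EL - obj.el_deg) ** 2
            img = np.where(d2 <= (obj.diameter_deg / 2.0) ** 2, obj.luminance, img)
    return img


# ---------------------------------------------------------------------------
# Light input container
# ---------------------------------------------------------------------------

@dataclass
class LightInput:
    """Per-photoreceptor light time series with provenance.

    ``intensity`` rows are normalized luminance (or photon counts divided by
    the expected count when Poisson sampling is enabled) for the
    photoreceptor identified by (eye[i], omm[i], pr[i]).
    """

    time_ms: np.ndarray
    intensity: np.ndarray  # (n_pr, n_t)
    eye: np.ndarray  # (n_pr,) "left"/"right"
    omm: np.ndarray  # (n_pr,) ommatidium index within its eye
    pr: np.ndarray  # (n_pr,) photoreceptor index 0..7 (R1..R6, R7, R8)
    dt_ms: float
    seed: int | None = None
    states: dict | None = None  # side -> {"omm": ids, "state": SaccadeState}
    meta: dict = field(default_factory=dict)

    def row(self, side: str, omm: int, pr: int) -> int:
        hit = np.where((self.eye == side) & (self.omm == omm) & (self.pr == pr))[0]
        if hit.size == 0:
            raise KeyError(f"photoreceptor ({side}, {omm}, {pr}) not rendered")
        return int(hit[0])

    def rows(self, members: Sequence[tuple[int, int]], side: str) -> np.ndarray:
        return np.array([self.row(side, o, p) for o, p in members], dtype=int)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("time_ms", data=self.time_ms)
            f.create_dataset("intensity", data=self.intensity)
            f.create_dataset("eye", data=np.char.encode(self.eye.astype(str)))
            f.create_dataset("omm", data=self.omm)
            f.create_dataset("pr", data=self.pr)
            f.attrs["dt_ms"] = self.dt_ms
            f.attrs["seed"] = -1 if self.seed is None else int(self.seed)
            for k, v in self.meta.items():
                if isinstance(v, (int, float, str)):
                    f.attrs[k] = v

    @classmethod
    def from_hdf5(cls, path) -> "LightInput":
        import h5py

        with h5py.File(path, "r") as f:
            seed = int(f.attrs["seed"])
            return cls(
                time_ms=f["time_ms"][:],
                intensity=f["intensity"][:],
                eye=np.char.decode(f["eye"][:]).astype(str),
                omm=f["omm"][:],
                pr=f["pr"][:],
                dt_ms=float(f.attrs["dt_ms"]),
                seed=None if seed < 0 else seed,
                meta={k: f.attrs[k] for k in f.attrs if k not in ("dt_ms", "seed")},
            )


def frontal_subset(eye_pair: EyePair, az_extent_deg: float = 15.0,
                   el_extent_deg: float = 10.0) -> list[tuple[str, int]]:
    """(side, ommatidium) selectors for the frontal binocular patch."""
    out = []
    for eye in (eye_pair.left, eye_pair.right):
        sel = (np.abs(eye.az) <= az_extent_deg) & (np.abs(eye.el) <= el_extent_deg)
        out.extend((eye.side, int(i)) for i in np.where(sel)[0])
    return out


# ---------------------------------------------------------------------------
# Binocular rendering
# ---------------------------------------------------------------------------

_MODES = ("static", "microsaccadic", "asynchronous", "monocular", "asymmetric")


def _dot_view(dot: Dot, t_ms: float, eye_pos: np.ndarray):
    """(azimuth, elevation, angular radius) of a dot from one eye, degrees."""
    az = dot.azimuth_at(t_ms)
    if dot.depth_mm is None:
        return az, dot.el_deg, dot.diameter_deg / 2.0
    az_r = np.deg2rad(az)
    el_r = np.deg2rad(dot.el_deg)
    p = dot.depth_mm * np.array(
        [np.cos(el_r) * np.sin(az_r), np.cos(el_r) * np.cos(az_r), np.sin(el_r)]
    )
    rel = p - eye_pos
    dist = np.sqrt(rel @ rel)
    paz = np.rad2deg(np.arctan2(rel[0], rel[1]))
    pel = np.rad2deg(np.arcsin(rel[2] / dist))
    radius_mm = dot.depth_mm * np.tan(np.deg2rad(dot.diameter_deg / 2.0))
    rho = np.rad2deg(np.arctan(radius_mm / dist))
    return paz, pel, rho


def _disc_mass(d_deg: np.ndarray, rho_deg: float, sigma_deg: np.ndarray) -> np.ndarray:
    """Mass of a unit-integral Gaussian RF inside an offset disc.

    Exact for the planar (small-angle) Gaussian: the noncentral chi-square
    CDF with 2 degrees of freedom.
    """
    out = np.zeros_like(d_deg, dtype=float)
    near = d_deg < rho_deg + 6.0 * sigma_deg
    if np.any(near):
        s = sigma_deg[near] if np.ndim(sigma_deg) else sigma_deg
        out[near] = ncx2.cdf((rho_deg / s) ** 2, 2, (d_deg[near] / s) ** 2)
    return out


def _grating_intensity(g: Grating, t_ms: float, az_c: np.ndarray,
                       sigma: np.ndarray) -> np.ndarray:
    """Gaussian-RF-filtered luminance of the square-wave grating."""
    lam = g.wavelength_deg
    mean = 0.5 * (g.high + g.low)
    amp = 0.5 * (g.high - g.low)
    out = np.full(az_c.shape, mean, dtype=float)
    x = az_c - g.phase_at(t_ms)
    for k in range((g.n_harmonics + 1) // 2):
        n = 2 * k + 1
        att = np.exp(-2.0 * np.pi ** 2 * n ** 2 * sigma ** 2 / lam ** 2)
        if np.all(att < 1e-30):
            break
        coeff = amp * (4.0 / np.pi) * ((-1.0) ** k) / n
        out += coeff * att * np.cos(2.0 * np.pi * n * x / lam)
    return out


def render_binocular(scene: Scene, eye_pair: EyePair,
                     kinematics: KineticsParams | None = None,
                     mode: str = "static", seed: int | None = None,
                     subset: Sequence[tuple[str, int]] | None = None,
                     phase_ms: float = 0.0, monocular_side: str = "right",
                     asymmetric_static_side: str = "left",
                     delayed_side: str = "right",
                     photon_rate_per_ms: float | None = None) -> LightInput:
    """Render a scene into per-photoreceptor binocular light series.

    Modes: ``static`` (RFs immobile), ``microsaccadic`` (closed-loop
    light-driven RF motion), ``asynchronous`` (one eye's kinematic state
    applied delayed by ``phase_ms``), ``asymmetric`` (one eye's RFs frozen),
    ``monocular`` (only ``monocular_side`` carries light; the other eye's
    channels are zeroed).  ``subset`` restricts rendering to the listed
    (side, ommatidium) units; default is the whole sampling matrix.

    If ``photon_rate_per_ms`` is set, intensities are replaced by Poisson
    photon counts (normalized by the expected count) drawn with ``seed``.
    """
    scene.validate()
    if mode not in _MODES:
        raise SceneError(f"unknown render mode {mode!r}")
    if mode == "monocular" and monocular_side not in ("left", "right"):
        raise SceneError("monocular mode requires monocular_side 'left' or 'right'")
    kin = kinematics or KineticsParams()
    dt = scene.dt_ms
    time_ms = scene.time_ms
    n_t = time_ms.size

    if subset is None:
        subset = [("left", i) for i in range(eye_pair.left.n_ommatidia)] + [
            ("right", i) for i in range(eye_pair.right.n_ommatidia)
        ]

    # Flatten scene objects (pins become their segment dots)
    dots: list[Dot] = []
    gratings: list[Grating] = []
    for obj in scene.objects:
        if isinstance(obj, Dot):
            dots.append(obj)
        elif isinstance(obj, Pin):
            dots.extend(obj.segments())
        elif isinstance(obj, Grating):
            gratings.append(obj)

    sides_out, omm_out, pr_out, intens_out = [], [], [], []
    states: dict = {}
    pre = scene.background if scene.pre_onset_luminance is None else scene.pre_onset_luminance
    phase_steps = int(round(phase_ms / dt))

    for eye in (eye_pair.left, eye_pair.right):
        omm_ids = np.array(sorted(o for s, o in subset if s == eye.side), dtype=int)
        if omm_ids.size == 0:
            continue
        n_o = omm_ids.size
        base_az = (eye.az[omm_ids, None] + eye.pr_offsets[omm_ids, :, 0]).ravel()
        base_el = (eye.el[omm_ids, None] + eye.pr_offsets[omm_ids, :, 1]).ravel()
        sigma0 = (eye.pr_fwhm[omm_ids] * _FWHM_TO_SIGMA).ravel()
        axis = eye.saccade_axis[omm_ids]  # (n_o, 2) rhabdomere axis
        pr_to_omm = np.repeat(np.arange(n_o), 8)

        moving = mode in ("microsaccadic", "asynchronous", "monocular") or (
            mode == "asymmetric" and eye.side != asymmetric_static_side
        )
        integ = SaccadeIntegrator(kin, n_o, dt) if moving else None
        off_hist = np.zeros((n_t, n_o))
        nar_hist = np.zeros((n_t, n_o))
        intensity = np.empty((n_o * 8, n_t))

        off_now = np.zeros(n_o)
        for i, t in enumerate(time_ms):
            if moving:
                if mode == "asynchronous" and eye.side == delayed_side:
                    j = i - 1 - phase_steps
                    off_eff = off_hist[j] if j >= 0 else np.zeros(n_o)
                else:
                    off_eff = off_now
            else:
                off_eff = np.zeros(n_o)
            nar_eff = kin.narrow_max * off_eff / kin.A_max_deg if kin.A_max_deg else 0.0

            if t < scene.onset_ms:
                frame = np.full(n_o * 8, pre)
            else:
                # lens inversion: RF moves opposite to the rhabdomere
                caz = base_az - (off_eff * axis[:, 0])[pr_to_omm]
                cel = base_el - (off_eff * axis[:, 1])[pr_to_omm]
                sig = sigma0 * (1.0 - nar_eff)[pr_to_omm] if np.ndim(nar_eff) else sigma0
                if gratings:
                    frame = np.zeros(n_o * 8)
                    for g in gratings:
                        frame += _grating_intensity(g, t - scene.onset_ms, caz, sig)
                else:
                    frame = np.full(n_o * 8, scene.background)
                for dot in dots:
                    paz, pel, rho = _dot_view(dot, t - scene.onset_ms, eye.position_mm)
                    d = np.sqrt((caz - paz) ** 2 + (cel - pel) ** 2)
                    f = _disc_mass(d, rho, sig)
                    frame += f * (dot.luminance - scene.background)
                np.clip(frame, 0.0, None, out=frame)
            intensity[:, i] = frame

            if moving:
                omm_light = frame.reshape(n_o, 8).mean(axis=1)
                off_now = integ.step(omm_light).copy()
            off_hist[i] = off_eff
            nar_hist[i] = nar_eff if np.ndim(nar_eff) else 0.0

        states[eye.side] = {
            "omm": omm_ids,
            "state": SaccadeState(time_ms=time_ms.copy(), offset_deg=off_hist.T,
                                  narrowing=nar_hist.T,
                                  gain=(integ.gain[:, None] * np.ones(n_t)) if integ
                                  else np.ones((n_o, n_t))),
        }
        sides_out.append(np.repeat(eye.side, n_o * 8))
        omm_out.append(np.repeat(omm_ids, 8))
        pr_out.append(np.tile(np.arange(8), n_o))
        intens_out.append(intensity)

    eye_arr = np.concatenate(sides_out)
    intensity = np.concatenate(intens_out, axis=0)
    if mode == "monocular":
        intensity[eye_arr != monocular_side] = 0.0
    if photon_rate_per_ms is not None:
        rng = np.random.default_rng(seed)
        expected = np.maximum(intensity * photon_rate_per_ms * dt, 0.0)
        intensity = rng.poisson(expected) / (photon_rate_per_ms * dt)

    return LightInput(
        time_ms=time_ms, intensity=intensity, eye=eye_arr,
        omm=np.concatenate(omm_out), pr=np.concatenate(pr_out), dt_ms=dt,
        seed=seed, states=states,
        meta={"mode": mode, "background": scene.background},
    )
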