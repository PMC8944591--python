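"""Mirror-symmetric binocular compound-eye geometry.

Builds the left/right ommatidial sampling lattices of a fly-like compound
eye, the per-photoreceptor (R1-R8) receptive-field layout with neural
superposition pooling, projections of receptive fields onto virtual planes,
self-motion optic-flow fields on the viewing sphere, and microsaccade
direction maps with their angular-error comparison.

Coordinate conventions
----------------------
Head-centric spherical coordinates, degrees everywhere: azimuth positive to
the animal's right, elevation positive dorsal.  Cartesian frame: x to the
right, y forward, z dorsal.  The two eyes sit at (+/- baseline/2, 0, 0) mm.
Tangent-plane vectors are expressed in the local (azimuth, elevation) basis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "GeometryConfig",
    "OmmatidiumSpec",
    "Eye",
    "EyePair",
    "VectorFieldMap",
    "RFProjection",
    "GeometryError",
    "build_eye_pair",
    "binocular_pairs",
    "coverage_count",
    "rf_tiling",
    "optic_flow_field",
    "microsaccade_direction_map",
    "flow_match_error",
    "sph_to_unit",
    "unit_to_sph",
    "angular_distance_deg",
]


class GeometryError(ValueError):
    """Raised for invalid geometry configurations or queries."""


# ---------------------------------------------------------------------------
# Spherical helpers
# ---------------------------------------------------------------------------

def sph_to_unit(az_deg, el_deg):
    """Unit vector(s) for azimuth/elevation in degrees.

    x right, y forward, z dorsal; (0, 0) maps to +y.
    """
    az = np.deg2rad(np.asarray(az_deg, dtype=float))
    el = np.deg2rad(np.asarray(el_deg, dtype=float))
    return np.stack(
        [np.cos(el) * np.sin(az), np.cos(el) * np.cos(az), np.sin(el)], axis=-1
    )


def unit_to_sph(u):
    """Inverse of :func:`sph_to_unit`; returns (az_deg, el_deg)."""
    u = np.asarray(u, dtype=float)
    az = np.rad2deg(np.arctan2(u[..., 0], u[..., 1]))
    el = np.rad2deg(np.arcsin(np.clip(u[..., 2] / np.linalg.norm(u, axis=-1), -1, 1)))
    return az, el


def angular_distance_deg(az1, el1, az2, el2):
    """Great-circle separation (deg) between two directions."""
    u = sph_to_unit(az1, el1)
    v = sph_to_unit(az2, el2)
    dot = np.clip(np.sum(u * v, axis=-1), -1.0, 1.0)
    return np.rad2deg(np.arccos(dot))


def tangent_basis(az_deg, el_deg):
    """Local (e_az, e_el) orthonormal tangent basis at each direction."""
    az = np.deg2rad(np.asarray(az_deg, dtype=float))
    el = np.deg2rad(np.asarray(el_deg, dtype=float))
    e_az = np.stack([np.cos(az), -np.sin(az), np.zeros_like(az)], axis=-1)
    e_el = np.stack(
        [-np.sin(az) * np.sin(el), -np.cos(az) * np.sin(el), np.cos(el)], axis=-1
    )
    return e_az, e_el


# ---------------------------------------------------------------------------
# Configuration and domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeometryConfig:
    """Parameters of the binocular sampling matrix.

    The default field extents are sized so that one eye carries roughly 880
    ommatidia at the 4.5-deg interommatidial angle, the classic per-eye
    "pixel" count for Drosophila.  ``row_aspect`` is the vertical row spacing
    of the hexagonal lattice in units of the interommatidial angle; 0.95
    keeps every lattice-neighbor separation within 10% of the configured
    interommatidial angle on the sphere.
    """

    interommatidial_deg: float = 4.5
    rf_fwhm_deg: float = 5.4
    subrf_radius_deg: float = 1.5
    baseline_mm: float = 0.4
    field_az_deg: tuple[float, float] = (-13.5, 133.0)  # right eye; left mirrored
    field_el_deg: tuple[float, float] = (-87.7, 87.7)
    binocular_az_deg: float = 23.5
    row_aspect: float = 0.95

    def validate(self) -> None:
        if self.interommatidial_deg <= 0:
            raise GeometryError("interommatidial angle must be positive")
        if self.baseline_mm <= 0:
            raise GeometryError("inter-eye baseline must be positive")
        if self.field_az_deg[1] <= self.field_az_deg[0]:
            raise GeometryError("empty azimuth field extent")
        if self.field_el_deg[1] <= self.field_el_deg[0]:
            raise GeometryError("empty elevation field extent")
        if self.rf_fwhm_deg <= 0:
            raise GeometryError("receptive-field FWHM must be positive")
        if self.binocular_az_deg < 0:
            raise GeometryError("binocular overlap must be non-negative")


@dataclass(frozen=True)
class OmmatidiumSpec:
    """One lens unit: axis, its R1-R8 sub-receptive fields, lattice links."""

    id: int
    eye: str  # "left" | "right"
    axis: tuple[float, float]  # (azimuth, elevation) deg
    neighbors: tuple[int, ...]
    photoreceptor_offsets: np.ndarray  # (8, 2) deg, relative to the axis
    photoreceptor_fwhm: np.ndarray  # (8,) deg
    saccade_axis: tuple[float, float]  # rhabdomere fast-phase axis, tangent plane


@dataclass
class Eye:
    """One eye's lattice in struct-of-arrays form."""

    side: str
    az: np.ndarray  # (n,) ommatidial axis azimuths, deg
    el: np.ndarray  # (n,)
    neighbors: list[np.ndarray]
    pr_offsets: np.ndarray  # (n, 8, 2) deg
    pr_fwhm: np.ndarray  # (n, 8) deg
    saccade_axis: np.ndarray  # (n, 2) rhabdomere fast-phase axis (unit, az/el)
    position_mm: np.ndarray  # (3,)
    cartridges: list[list[tuple[int, int]]] = field(default_factory=list)

    @property
    def n_ommatidia(self) -> int:
        return self.az.size

    def pr_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Absolute (az, el) of every photoreceptor RF center, shape (n, 8)."""
        return (
            self.az[:, None] + self.pr_offsets[..., 0],
            self.el[:, None] + self.pr_offsets[..., 1],
        )

    def ommatidium(self, i: int) -> OmmatidiumSpec:
        return OmmatidiumSpec(
            id=int(i),
            eye=self.side,
            axis=(float(self.az[i]), float(self.el[i])),
            neighbors=tuple(int(j) for j in self.neighbors[i]),
            photoreceptor_offsets=self.pr_offsets[i].copy(),
            photoreceptor_fwhm=self.pr_fwhm[i].copy(),
            saccade_axis=(float(self.saccade_axis[i, 0]), float(self.saccade_axis[i, 1])),
        )

    def nearest_ommatidium(self, az_deg: float, el_deg: float) -> int:
        d = angular_distance_deg(self.az, self.el, az_deg, el_deg)
        return int(np.argmin(d))


@dataclass
class EyePair:
    """Mirror-symmetric pair of eyes plus binocular bookkeeping."""

    left: Eye
    right: Eye
    baseline_mm: float
    binocular_region: tuple[tuple[float, float], tuple[float, float]]  # (az, el) extents
    config: GeometryConfig

    def eye(self, side: str) -> Eye:
        if side == "left":
            return self.left
        if side == "right":
            return self.right
        raise GeometryError(f"unknown eye side {side!r}")


@dataclass
class VectorFieldMap:
    """Tangential unit vectors on an azimuth/elevation direction set."""

    az: np.ndarray  # (n,) deg
    el: np.ndarray  # (n,) deg
    vectors: np.ndarray  # (n, 2) tangent-plane (az, el) components, unit where magnitude>0
    magnitude: np.ndarray | None = None  # optional scalar per point
    eye: np.ndarray | None = None  # optional per-point eye label

    def mirrored(self) -> "VectorFieldMap":
        """The map under azimuth sign flip (left/right exchange)."""
        vec = self.vectors.copy()
        vec[:, 0] = -vec[:, 0]
        eye = None
        if self.eye is not None:
            swap = {"left": "right", "right": "left"}
            eye = np.array([swap.get(e, e) for e in self.eye])
        mag = None if self.magnitude is None else self.magnitude.copy()
        return VectorFieldMap(az=-self.az.copy(), el=self.el.copy(), vectors=vec,
                              magnitude=mag, eye=eye)


@dataclass
class RFProjection:
    """Receptive fields projected onto a virtual frontal plane."""

    depth_mm: float
    centers_mm: np.ndarray  # (n, 2) in-plane (x, z) coordinates
    radii_mm: np.ndarray  # (n,) half-width footprint radii
    eye: np.ndarray  # (n,) side labels


# ---------------------------------------------------------------------------
# Lattice construction
# ---------------------------------------------------------------------------

def _hex_lattice(cfg: GeometryConfig) -> tuple[np.ndarray, np.ndarray]:
    """Right-eye hexagonal-row lattice on the sphere.

    Rows of constant elevation spaced row_aspect * delta_phi, azimuth step
    delta_phi / cos(el) so the great-circle spacing within each row equals
    the interommatidial angle; alternate rows are offset half a step.
    """
    dphi = cfg.interommatidial_deg
    h = cfg.row_aspect * dphi
    el_lo, el_hi = cfg.field_el_deg
    az_lo, az_hi = cfg.field_az_deg
    n_up = int(np.floor(el_hi / h))
    n_dn = int(np.floor(-el_lo / h))
    az_all, el_all = [], []
    for j in range(-n_dn, n_up + 1):
        el = j * h
        step = dphi / max(np.cos(np.deg2rad(el)), 1e-9)
        offset = 0.5 * step if (j % 2) else 0.0
        az = np.arange(az_lo + offset, az_hi + 1e-9, step)
        if az.size == 0:
            continue
        az_all.append(az)
        el_all.append(np.full(az.size, el))
    if not az_all:
        raise GeometryError("field extent too small to place any ommatidium")
    return np.concatenate(az_all), np.concatenate(el_all)


def _find_neighbors(az: np.ndarray, el: np.ndarray, dphi: float) -> list[np.ndarray]:
    """Symmetric lattice-neighbor lists by great-circle distance threshold."""
    pts = sph_to_unit(az, el)
    chord = 2.0 * np.sin(np.deg2rad(1.1 * dphi) / 2.0)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=chord, output_type="ndarray")
    nbrs: list[list[int]] = [[] for _ in range(az.size)]
    for i, j in pairs:
        nbrs[i].append(int(j))
        nbrs[j].append(int(i))
    return [np.array(sorted(n), dtype=int) for n in nbrs]


def _subrf_offsets(cfg: GeometryConfig, el: np.ndarray, side: str) -> np.ndarray:
    """Per-ommatidium R1-R8 angular offsets, shape (n, 8, 2).

    R1-R6 sit on a regular hexagon of the configured radius; R7 and R8 share
    the central optical axis.  Ventral ommatidia mirror the offsets about
    the eye equator; the left eye mirrors azimuths (built via the caller).
    """
    n = el.size
    ang = np.deg2rad(np.arange(6) * 60.0 + 30.0)  # R1..R6 around the hexagon
    hexagon = cfg.subrf_radius_deg * np.stack([np.cos(ang), np.sin(ang)], axis=-1)
    off = np.zeros((n, 8, 2))
    off[:, :6, :] = hexagon[None, :, :]
    ventral = el < 0
    off[ventral, :, 1] *= -1.0  # equatorial mirror symmetry
    if side == "left":
        off[:, :, 0] *= -1.0
    return off


def _forward_flow_tangent(az: np.ndarray, el: np.ndarray) -> np.ndarray:
    """Unit tangent (az, el components) of forward-translation optic flow.

    Near the flow focus (frontal pole) the direction is ill-defined; fall
    back to the horizontal away-from-midline direction, matching the lateral
    recoil axis of frontal photoreceptors.
    """
    r = sph_to_unit(az, el)
    t = np.array([0.0, 1.0, 0.0])
    v = (r @ t)[:, None] * r - t[None, :]
    e_az, e_el = tangent_basis(az, el)
    comp = np.stack([np.sum(v * e_az, axis=-1), np.sum(v * e_el, axis=-1)], axis=-1)
    mag = np.linalg.norm(comp, axis=-1)
    out = np.zeros_like(comp)
    ok = mag > 1e-12
    out[ok] = comp[ok] / mag[ok, None]
    fallback = np.where(az[~ok] >= 0, 1.0, -1.0)
    out[~ok, 0] = np.where(az[~ok] == 0.0, 1.0, fallback)
    return out


def _build_cartridges(eye: Eye) -> list[list[tuple[int, int]]]:
    """Neural-superposition pooling map, one lamina cartridge per ommatidium.

    Cartridge c receives the resident R7/R8 (indices 6, 7) plus, from each
    lattice neighbor, the single R1-R6 photoreceptor whose RF center lies
    closest to c's axis — seven ommatidia pooled per cartridge away from the
    lattice edge.
    """
    paz, pel = eye.pr_centers()
    cartridges: list[list[tuple[int, int]]] = []
    for c in range(eye.n_ommatidia):
        members: list[tuple[int, int]] = [(c, 6), (c, 7)]
        for j in eye.neighbors[c]:
            d = angular_distance_deg(paz[j, :6], pel[j, :6], eye.az[c], eye.el[c])
            members.append((int(j), int(np.argmin(d))))
        cartridges.append(members)
    return cartridges


def build_eye_pair(config: GeometryConfig | None = None) -> EyePair:
    """Construct the mirror-symmetric binocular sampling matrix.

    The right eye is laid out on a hexagonal-row lattice over the configured
    field; the left eye is its exact mirror image (azimuth sign flip, mirrored
    sub-RF offsets and saccade axes).  The per-ommatidium ``saccade_axis`` is
    the rhabdomere fast-phase direction: opposite to the local
    forward-translation optic-flow direction, because the ommatidial lens
    inverts rhabdomere motion into RF motion and the RF fast phase follows
    the flow.
    """
    cfg = config or GeometryConfig()
    cfg.validate()

    az_r, el_r = _hex_lattice(cfg)
    nbrs_r = _find_neighbors(az_r, el_r, cfg.interommatidial_deg)
    n = az_r.size
    fwhm = np.full((n, 8), cfg.rf_fwhm_deg)

    # RF fast phase follows forward flow; the rhabdomere axis is its inverse.
    rf_fast_r = _forward_flow_tangent(az_r, el_r)
    sacc_r = -rf_fast_r
    right = Eye(
        side="right", az=az_r, el=el_r, neighbors=nbrs_r,
        pr_offsets=_subrf_offsets(cfg, el_r, "right"), pr_fwhm=fwhm.copy(),
        saccade_axis=sacc_r, position_mm=np.array([cfg.baseline_mm / 2.0, 0.0, 0.0]),
    )
    sacc_l = sacc_r.copy()
    sacc_l[:, 0] *= -1.0
    left = Eye(
        side="left", az=-az_r.copy(), el=el_r.copy(),
        neighbors=[nb.copy() for nb in nbrs_r],
        pr_offsets=_subrf_offsets(cfg, el_r, "left"), pr_fwhm=fwhm.copy(),
        saccade_axis=sacc_l, position_mm=np.array([-cfg.baseline_mm / 2.0, 0.0, 0.0]),
    )
    right.cartridges = _build_cartridges(right)
    left.cartridges = _build_cartridges(left)

    half_bin = cfg.binocular_az_deg / 2.0
    binocular = ((-half_bin, half_bin), (cfg.field_el_deg[0], cfg.field_el_deg[1]))
    return EyePair(left=left, right=right, baseline_mm=cfg.baseline_mm,
                   binocular_region=binocular, config=cfg)


# ---------------------------------------------------------------------------
# Binocular queries
# ---------------------------------------------------------------------------

def binocular_pairs(eye_pair: EyePair) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """Corresponding (left, right) photoreceptor pairs in the binocular field.

    Each left photoreceptor whose RF center falls inside the binocular region
    is matched to the right-eye photoreceptor with the nearest RF center
    (ties: smaller |elevation|, then smaller ommatidium id); pairs whose RFs
    do not overlap (center separation >= sum of half-widths) are dropped.
    Entries are ((left_omm, left_pr), (right_omm, right_pr)).
    """
    (az_lo, az_hi), (el_lo, el_hi) = eye_pair.binocular_region
    if az_hi <= az_lo:
        return []
    laz, lel = eye_pair.left.pr_centers()
    raz, rel = eye_pair.right.pr_centers()
    lsel = (laz >= az_lo) & (laz <= az_hi) & (lel >= el_lo) & (lel <= el_hi)
    rsel = (raz >= az_lo) & (raz <= az_hi) & (rel >= el_lo) & (rel <= el_hi)
    l_idx = np.argwhere(lsel)
    r_idx = np.argwhere(rsel)
    if l_idx.size == 0 or r_idx.size == 0:
        return []
    r_pts = sph_to_unit(raz[rsel], rel[rsel])
    # Deterministic tie-breaking: order right candidates by (|el|, omm id)
    order = np.lexsort((r_idx[:, 0], np.abs(rel[rsel])))
    tree = cKDTree(r_pts[order])
    l_pts = sph_to_unit(laz[lsel], lel[lsel])
    _, nearest = tree.query(l_pts)
    pairs = []
    for k, (lo, lp) in enumerate(l_idx):
        ro, rp = r_idx[order[nearest[k]]]
        sep = angular_distance_deg(laz[lo, lp], lel[lo, lp], raz[ro, rp], rel[ro, rp])
        halfsum = (eye_pair.left.pr_fwhm[lo, lp] + eye_pair.right.pr_fwhm[ro, rp]) / 2.0
        if sep < halfsum:
            pairs.append(((int(lo), int(lp)), (int(ro), int(rp))))
    return pairs


def coverage_count(eye_pair: EyePair, direction: tuple[float, float],
                   depth_mm: float) -> int:
    """Number of photoreceptors (both eyes) whose RF contains a point.

    The point sits at ``depth_mm`` along ``direction`` (head-centric az, el)
    from the head origin; each eye views it from its own vantage.  A
    photoreceptor counts once if the point's direction lies within its RF
    half-width (FWHM/2) of the RF center.
    """
    az, el = direction
    point = sph_to_unit(az, el) * float(depth_mm)
    total = 0
    for eye in (eye_pair.left, eye_pair.right):
        rel_vec = point - eye.position_mm
        paz, pel = unit_to_sph(rel_vec / np.linalg.norm(rel_vec))
        caz, cel = eye.pr_centers()
        d = angular_distance_deg(caz.ravel(), cel.ravel(), paz, pel)
        total += int(np.sum(d < eye.pr_fwhm.ravel() / 2.0))
    return total


def rf_tiling(eye_pair: EyePair, depth_mm: float,
              subset: Sequence[tuple[str, int]] | None = None) -> RFProjection:
    """Project every RF's half-width footprint onto a frontal plane.

    The plane is y = depth_mm; footprints are circles whose radius is the
    half-width cone radius at the RF center's range, so footprint diameter
    grows linearly with depth for a fixed angular half-width.
    """
    if depth_mm <= 0:
        raise GeometryError("depth must be positive")
    centers, radii, sides = [], [], []
    for eye in (eye_pair.left, eye_pair.right):
        caz, cel = eye.pr_centers()
        mask = np.ones_like(caz, dtype=bool)
        if subset is not None:
            mask[:] = False
            for side, omm in subset:
                if side == eye.side:
                    mask[omm, :] = True
        u = sph_to_unit(caz[mask], cel[mask])
        fy = u[:, 1]
        ok = fy > 1e-6  # forward-looking only
        u, fy = u[ok], fy[ok]
        trange = (depth_mm - eye.position_mm[1]) / fy
        pts = eye.position_mm[None, :] + trange[:, None] * u
        rho = np.deg2rad(eye.pr_fwhm[mask][ok] / 2.0)
        centers.append(pts[:, [0, 2]])
        radii.append(trange * np.tan(rho))
        sides.append(np.full(ok.sum(), eye.side))
    return RFProjection(
        depth_mm=float(depth_mm),
        centers_mm=np.concatenate(centers, axis=0),
        radii_mm=np.concatenate(radii, axis=0),
        eye=np.concatenate(sides),
    )


def tiling_gap_fraction(projection: RFProjection,
                        window_mm: tuple[float, float, float, float],
                        n_grid: int = 120) -> float:
    """Fraction of a rectangular plane window not covered by any footprint."""
    x0, x1, z0, z1 = window_mm
    gx = np.linspace(x0, x1, n_grid)
    gz = np.linspace(z0, z1, n_grid)
    X, Z = np.meshgrid(gx, gz)
    pts = np.stack([X.ravel(), Z.ravel()], axis=-1)
    c = projection.centers_mm
    r = projection.radii_mm
    near = ((c[:, 0] > x0 - r) & (c[:, 0] < x1 + r)
            & (c[:, 1] > z0 - r) & (c[:, 1] < z1 + r))
    if not near.any():
        return 1.0
    c, r = c[near], r[near]
    covered = np.zeros(pts.shape[0], dtype=bool)
    block = max(1, int(2e6 // c.shape[0]))
    for s in range(0, pts.shape[0], block):
        d = np.linalg.norm(pts[s:s + block, None, :] - c[None, :, :], axis=-1)
        covered[s:s + block] = np.any(d <= r[None, :], axis=1)
    return float(1.0 - covered.mean())


# ---------------------------------------------------------------------------
# Optic flow and direction maps
# ---------------------------------------------------------------------------

def optic_flow_field(translation: Sequence[float], rotation: Sequence[float],
                     az_deg: np.ndarray, el_deg: np.ndarray) -> VectorFieldMap:
    """Self-motion optic-flow field on the viewing sphere.

    The translational component at viewing direction r is the tangential
    projection of -t (magnitude proportional to sin of the angle between r
    and t); the rotational component is omega x r; the two add.  A zero
    motion vectorpair yields a zero field (flagged by zero magnitudes).
    """
    az = np.asarray(az_deg, dtype=float).ravel()
    el = np.asarray(el_deg, dtype=float).ravel()
    if az.size == 0:
        raise GeometryError("empty grid")
    t = np.asarray(translation, dtype=float)
    w = np.asarray(rotation, dtype=float)
    r = sph_to_unit(az, el)
    v = (r @ t)[:, None] * r - t[None, :] + np.cross(np.broadcast_to(w, r.shape), r)
    e_az, e_el = tangent_basis(az, el)
    comp = np.stack([np.sum(v * e_az, axis=-1), np.sum(v * e_el, axis=-1)], axis=-1)
    mag = np.linalg.norm(comp, axis=-1)
    unit = np.zeros_like(comp)
    ok = mag > 1e-12
    unit[ok] = comp[ok] / mag[ok, None]
    return VectorFieldMap(az=az, el=el, vectors=unit, magnitude=mag)


def microsaccade_direction_map(eye_pair: EyePair, source: str | "os.PathLike" = "model-default",
                               phase: str = "fast") -> VectorFieldMap:
    """RF microsaccade direction map across both eyes.

    ``model-default`` derives fast-phase RF directions from the stored
    rhabdomere saccade axes (lens inversion applied); the slower return phase
    is the opposite direction.  A CSV file source must carry columns
    azimuth_deg, elevation_deg, vx, vy, eye; non-unit vectors are normalized
    on load.
    """
    if phase not in ("fast", "slow"):
        raise GeometryError("phase must be 'fast' or 'slow'")
    sign = 1.0 if phase == "fast" else -1.0
    if source == "model-default":
        az = np.concatenate([eye_pair.left.az, eye_pair.right.az])
        el = np.concatenate([eye_pair.left.el, eye_pair.right.el])
        vec = np.concatenate(
            [-eye_pair.left.saccade_axis, -eye_pair.right.saccade_axis], axis=0
        ) * sign
        eye = np.concatenate([
            np.full(eye_pair.left.n_ommatidia, "left"),
            np.full(eye_pair.right.n_ommatidia, "right"),
        ])
        return VectorFieldMap(az=az, el=el, vectors=vec,
                              magnitude=np.ones(az.size), eye=eye)
    return load_vector_map(source, phase_sign=sign)


def load_vector_map(path, phase_sign: float = 1.0) -> VectorFieldMap:
    """Load a direction map from CSV (azimuth_deg, elevation_deg, vx, vy, eye)."""
    import logging

    import pandas as pd

    log = logging.getLogger(__name__)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - passthrough context
        raise GeometryError(f"cannot parse vector map file {path}: {exc}") from exc
    required = ["azimuth_deg", "elevation_deg", "vx", "vy"]
    for col in required:
        if col not in df.columns:
            raise GeometryError(f"vector map file {path} is missing column {col!r}")
    vec = df[["vx", "vy"]].to_numpy(dtype=float)
    bad = ~np.isfinite(vec).all(axis=1)
    if bad.any():
        row = int(np.argwhere(bad)[0, 0])
        raise GeometryError(f"vector map file {path}: non-finite vector at row {row}")
    norms = np.linalg.norm(vec, axis=1)
    zero = norms < 1e-12
    if zero.any():
        row = int(np.argwhere(zero)[0, 0])
        raise GeometryError(f"vector map file {path}: zero-length vector at row {row}")
    if np.any(np.abs(norms - 1.0) > 1e-9):
        log.info("normalizing %d non-unit vectors on load", int(np.sum(np.abs(norms - 1) > 1e-9)))
    vec = vec / norms[:, None]
    eye = df["eye"].to_numpy() if "eye" in df.columns else None
    return VectorFieldMap(
        az=df["azimuth_deg"].to_numpy(dtype=float),
        el=df["elevation_deg"].to_numpy(dtype=float),
        vectors=vec * phase_sign,
        magnitude=np.ones(len(df)),
        eye=eye,
    )


def flow_match_error(map_a: VectorFieldMap, map_b: VectorFieldMap) -> dict:
    """Angular error (deg per point) between two tangential vector maps.

    Both maps must be sampled on identical grids.  Errors lie in [0, 180]
    degrees; the summary reports median and mean.
    """
    if map_a.az.shape != map_b.az.shape or not (
        np.allclose(map_a.az, map_b.az) and np.allclose(map_a.el, map_b.el)
    ):
        raise GeometryError("vector maps are on different grids")
    a, b = map_a.vectors, map_b.vectors
    dot = np.sum(a * b, axis=-1)
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    err = np.rad2deg(np.abs(np.arctan2(cross, dot)))
    return {
        "error_deg": err,
        "az": map_a.az,
        "el": map_a.el,
        "median_deg": float(np.median(err)),
        "mean_deg": float(np.mean(err)),
    }
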