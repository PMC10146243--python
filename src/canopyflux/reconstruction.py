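"""3D canopy mock-up reconstruction from shoot skeletons.

Each digitized shoot is dressed with leaves according to the allometric
relationships: shoot length gives total shoot leaf area and leaf count,
leaves are evenly spaced along the shoot at the mean internode length,
each leaf is a planar hexagon calibrated so its polygon area equals the
allometric leaf area, successive leaf azimuths advance by 144 deg (2/5
phyllotaxy), and leaf elevation and rolling angles are drawn from
field-measured histograms per shoot type.

Coordinate convention: z up, azimuth clockwise from North (+y), elevation
from horizontal.  Lengths of skeletons in m; leaf dimensions in cm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from canopyflux.allometry import AllometricModel, predict_shoot
from canopyflux.shoots import ShootRecord, classify_shoot_length

PHYLLOTAXY_DEG = 144.0  # 2/5 phyllotaxy
AREA_TOLERANCE = 0.005  # hexagon calibration: polygon area within 0.5%


# ---------------------------------------------------------------------------
# leaf angles
# ---------------------------------------------------------------------------

def _rotate_about(v, axis, angle_rad):
    """Rodrigues rotation of v about unit axis."""
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    return (v * c + np.cross(axis, v) * s
            + axis * np.dot(axis, v) * (1.0 - c))


def midrib_vector(azimuth_deg: float, elevation_deg: float) -> np.ndarray:
    az, el = math.radians(azimuth_deg), math.radians(elevation_deg)
    return np.array([math.cos(el) * math.sin(az),
                     math.cos(el) * math.cos(az),
                     math.sin(el)])


def lamina_axes(azimuth_deg: float, elevation_deg: float,
                rolling_deg: float):
    """Orthonormal (midrib, width, normal) axes of a leaf lamina."""
    m = midrib_vector(azimuth_deg, elevation_deg)
    az, el = math.radians(azimuth_deg), math.radians(elevation_deg)
    n0 = np.array([-math.sin(el) * math.sin(az),
                   -math.sin(el) * math.cos(az),
                   math.cos(el)])
    w0 = np.cross(n0, m)
    roll = math.radians(rolling_deg)
    w = _rotate_about(w0, m, roll)
    n = _rotate_about(n0, m, roll)
    return m, w, n


def lamina_normal(azimuth_deg, elevation_deg, rolling_deg) -> np.ndarray:
    return lamina_axes(azimuth_deg, elevation_deg, rolling_deg)[2]


@dataclass
class AngleDistribution:
    """Leaf Euler-angle statistics per shoot type.

    ``elevation`` / ``rolling`` map shoot type to (bin_edges, masses)
    histograms (deg); masses sum to 1.  ``phyllotaxy_deg`` is the constant
    azimuth advance between successive leaves and
    ``petiole_shoot_angle_deg`` the angle between petiole and shoot axis.
    Default bin width for building histograms is 10 deg.
    """

    elevation: dict
    rolling: dict
    phyllotaxy_deg: float = PHYLLOTAXY_DEG
    petiole_shoot_angle_deg: float = 45.0
    _normals_cache: np.ndarray = field(default=None, repr=False,
                                       compare=False)

    def __post_init__(self):
        for hists in (self.elevation, self.rolling):
            for key, (edges, masses) in hists.items():
                masses = np.asarray(masses, float)
                if not np.isclose(masses.sum(), 1.0):
                    raise ValueError(
                        f"histogram masses for {key!r} must sum to 1")

    @classmethod
    def from_samples(cls, elevation_samples: dict, rolling_samples: dict,
                     bin_width: float = 10.0, **kwargs):
        def hist(samples):
            samples = np.asarray(samples, float)
            lo = np.floor(samples.min() / bin_width) * bin_width
            hi = np.ceil(samples.max() / bin_width) * bin_width
            hi = max(hi, lo + bin_width)
            edges = np.arange(lo, hi + bin_width / 2, bin_width)
            masses, _ = np.histogram(samples, bins=edges)
            return edges, masses / masses.sum()

        return cls(elevation={k: hist(v) for k, v in elevation_samples.items()},
                   rolling={k: hist(v) for k, v in rolling_samples.items()},
                   **kwargs)

    @classmethod
    def planophile(cls, shoot_types=("long", "short")):
        """Mostly horizontal laminae — a reasonable apple-leaf default."""
        edges = np.array([-30.0, -20, -10, 0, 10, 20, 30])
        masses = np.array([0.05, 0.15, 0.30, 0.30, 0.15, 0.05])
        roll_edges = np.array([-40.0, -20, 0, 20, 40])
        roll_masses = np.array([0.2, 0.3, 0.3, 0.2])
        return cls(elevation={t: (edges, masses) for t in shoot_types},
                   rolling={t: (roll_edges, roll_masses)
                            for t in shoot_types})

    def _hist_for(self, hists: dict, shoot_type: str):
        if shoot_type in hists:
            return hists[shoot_type]
        # bourse shoots fall back to the long/short class of their length
        for key in ("short", "long"):
            if key in hists:
                return hists[key]
        return next(iter(hists.values()))

    def sample_elevation(self, shoot_type: str, rng) -> float:
        return self._sample(self._hist_for(self.elevation, shoot_type), rng)

    def sample_rolling(self, shoot_type: str, rng) -> float:
        return self._sample(self._hist_for(self.rolling, shoot_type), rng)

    @staticmethod
    def _sample(hist, rng) -> float:
        edges, masses = hist
        edges = np.asarray(edges, float)
        i = rng.choice(len(masses), p=np.asarray(masses, float))
        return float(rng.uniform(edges[i], edges[i + 1]))

    def support(self, which: str, shoot_type: str):
        hists = self.elevation if which == "elevation" else self.rolling
        edges, _ = self._hist_for(hists, shoot_type)
        return float(edges[0]), float(edges[-1])

    def leaf_normals(self, n: int = 2000, seed: int = 0) -> np.ndarray:
        """Sample of unit lamina normals for G-function evaluation."""
        if self._normals_cache is not None:
            return self._normals_cache
        rng = np.random.default_rng(seed)
        types = list(self.elevation)
        out = np.empty((n, 3))
        for i in range(n):
            t = types[i % len(types)]
            az = rng.uniform(0.0, 360.0)
            el = self.sample_elevation(t, rng)
            rl = self.sample_rolling(t, rng)
            out[i] = lamina_normal(az, el, rl)
        self._normals_cache = out
        return out


# ---------------------------------------------------------------------------
# hexagonal leaf mock-up
# ---------------------------------------------------------------------------

@dataclass
class HexagonTemplate:
    """Planar hexagon in the lamina frame (cm): midrib along +x."""

    vertices_2d: np.ndarray  # (6, 2)
    LL: float
    LW: float
    PL: float
    area: float  # cm^2

    def polygon_area(self) -> float:
        v = self.vertices_2d
        x, y = v[:, 0], v[:, 1]
        return float(0.5 * abs(np.dot(x, np.roll(y, -1))
                               - np.dot(y, np.roll(x, -1))))


def build_hexagon(LL: float, model: AllometricModel) -> HexagonTemplate:
    """Hexagonal leaf outline calibrated to the allometric leaf area.

    Length along the midrib is LL, maximum width is LW(LL), and the two
    shoulder vertices are placed so the polygon area equals a_LA*LL^2.
    When LW alone cannot reach the target area the half-width is adjusted
    instead, keeping the area identity exact.
    """
    if LL <= 0:
        raise ValueError("leaf length must be positive")
    LW = model.a_LW * LL + model.b_LW
    if LW <= 0:
        raise ValueError(
            f"allometric leaf width non-positive ({LW:.3g} cm) at LL={LL}")
    PL = max(model.a_PL * LL + model.b_PL, 0.0)
    target = model.a_LA * LL**2
    # hexagon (0,0),(x1,-h),(x2,-h),(LL,0),(x2,h),(x1,h):
    # area = h * (LL + d), d = x2 - x1
    d = 2.0 * target / LW - LL
    d = min(max(d, 0.0), 0.98 * LL)
    h = target / (LL + d)
    x1 = 0.5 * (LL - d)
    x2 = 0.5 * (LL + d)
    verts = np.array([[0.0, 0.0], [x1, -h], [x2, -h],
                      [LL, 0.0], [x2, h], [x1, h]])
    return HexagonTemplate(vertices_2d=verts, LL=LL, LW=2.0 * h, PL=PL,
                           area=target)


# ---------------------------------------------------------------------------
# scene
# ---------------------------------------------------------------------------

@dataclass
class LeafMockup:
    vertices: np.ndarray  # (6, 3) m, planar
    area: float           # cm^2
    azimuth: float        # deg, midrib
    elevation: float      # deg
    rolling: float        # deg
    petiole_length: float  # cm
    attachment: np.ndarray  # (3,) m, insertion on the shoot
    shoot_id: int
    node_rank: int

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.node_rank < 1:
            raise ValueError("node_rank must be >= 1")

    def normal(self) -> np.ndarray:
        return lamina_normal(self.azimuth, self.elevation, self.rolling)

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def planarity_residual(self) -> float:
        v = self.vertices - self.vertices.mean(axis=0)
        return float(abs(v @ self.normal()).max())


@dataclass
class CanopyScene:
    leaves: list
    tree_spacing: tuple = (2.0, 3.5)  # row x inter-row, m

    def total_leaf_area_cm2(self) -> float:
        return float(sum(l.area for l in self.leaves))

    def bounding_box(self):
        if not self.leaves:
            raise ValueError("empty scene has no bounding box")
        allv = np.vstack([l.vertices for l in self.leaves])
        return allv.min(axis=0), allv.max(axis=0)

    def leaf_normals(self) -> np.ndarray:
        return np.array([l.normal() for l in self.leaves])

    def to_csv(self, path) -> None:
        rows = []
        for l in self.leaves:
            row = {"shoot_id": l.shoot_id, "node_rank": l.node_rank,
                   "area_cm2": l.area, "azimuth": l.azimuth,
                   "elevation": l.elevation, "rolling": l.rolling,
                   "petiole_cm": l.petiole_length}
            for i, v in enumerate(l.vertices):
                row[f"vx{i}"], row[f"vy{i}"], row[f"vz{i}"] = v
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)

    def to_obj(self, path) -> None:
        """Triangulated hexagons as a Wavefront OBJ."""
        with open(path, "w") as fh:
            offset = 1
            for l in self.leaves:
                for v in l.vertices:
                    fh.write(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
                for k in range(1, 5):
                    fh.write(f"f {offset} {offset + k} {offset + k + 1}\n")
                offset += 6


def layout_shoot(shoot: ShootRecord, model: AllometricModel,
                 angles: AngleDistribution, rng,
                 first_azimuth: float = None) -> list:
    """Place the shoot's leaves along its axis.

    Leaf count and total area come from the shoot-length allometry;
    insertion points segment the shoot evenly at the mean internode
    length; azimuths advance by the phyllotactic angle; elevation and
    rolling are drawn per shoot type.  Petiole, midrib and shoot axis
    share the vertical plane through the leaf azimuth.
    """
    SL = shoot.length_cm
    sla, sln, mean_la, internode = predict_shoot(model, SL)
    LL = math.sqrt(mean_la / model.a_LA) if mean_la > 0 else 1e-3
    hexa = build_hexagon(max(LL, 1e-3), model)
    if first_azimuth is None:
        first_azimuth = float(rng.uniform(0.0, 360.0))

    type_key = shoot.type if shoot.type in angles.elevation \
        else classify_shoot_length(SL)
    axis = shoot.axis
    psi = math.radians(angles.petiole_shoot_angle_deg)
    leaves = []
    for i in range(1, sln + 1):
        frac = i / sln
        insertion = shoot.proximal + frac * (shoot.distal - shoot.proximal)
        az = (first_azimuth + (i - 1) * angles.phyllotaxy_deg) % 360.0
        el = angles.sample_elevation(type_key, rng)
        rl = angles.sample_rolling(type_key, rng)
        # petiole in the plane of the shoot axis and the azimuth direction
        q = midrib_vector(az, 0.0)
        e2 = q - np.dot(q, axis) * axis
        nrm = np.linalg.norm(e2)
        e2 = e2 / nrm if nrm > 1e-9 else np.array([0.0, 0.0, 1.0])
        petiole_dir = math.cos(psi) * axis + math.sin(psi) * e2
        origin = insertion + petiole_dir * (hexa.PL / 100.0)
        m, w, _ = lamina_axes(az, el, rl)
        verts = (origin[None, :]
                 + hexa.vertices_2d[:, 0:1] / 100.0 * m[None, :]
                 + hexa.vertices_2d[:, 1:2] / 100.0 * w[None, :])
        leaves.append(LeafMockup(
            vertices=verts, area=hexa.polygon_area(), azimuth=az,
            elevation=el, rolling=rl, petiole_length=hexa.PL,
            attachment=insertion, shoot_id=shoot.shoot_id, node_rank=i))
    return leaves


def assemble_canopy(shoots, model: AllometricModel,
                    angles: AngleDistribution, seed: int = 0,
                    tree_spacing=(2.0, 3.5)) -> CanopyScene:
    """Reconstruct a whole-scene leaf mock-up from a shoot skeleton."""
    shoots = list(shoots)
    if not shoots:
        raise ValueError("need at least one shoot")
    rng = np.random.default_rng(seed)
    leaves = []
    for shoot in shoots:
        leaves.extend(layout_shoot(shoot, model, angles, rng))
    return CanopyScene(leaves=leaves, tree_spacing=tuple(tree_spacing))


def compute_lai(scene: CanopyScene) -> float:
    """Leaf area index: total leaf area over tree ground spacing."""
    row, inter = scene.tree_spacing
    if row <= 0 or inter <= 0:
        raise ValueError("tree spacing must be positive")
    return scene.total_leaf_area_cm2() * 1e-4 / (row * inter)
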