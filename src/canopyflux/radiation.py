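"""Voxel turbid-medium radiation transfer.

The canopy is discretized into axis-aligned voxels carrying leaf area
density (LAD, m^2 m^-3).  Radiation from any sky direction attenuates along
rays through the grid following Beer–Lambert, with extinction G*LAD where G
is the mean projection coefficient of leaf area toward the beam.  Diffuse
sky light is integrated over a 46-sector discretization; the direct beam
follows the solar position.  Scattering is neglected for PPFD by default
(leaf absorptance applied to intercepted flux), which keeps energy
conservation exact: intercepted + transmitted = incident for every
direction and time step.

Coordinate convention: z up, x East, y North; azimuth in degrees clockwise
from North; elevation in degrees above the horizon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: extraterrestrial PPFD normal to the beam (umol m-2 s-1); 1367 W m-2
#: solar constant x 0.45 PAR fraction x 4.57 umol J-1
PPFD_EXTRA = 2810.0
PAR_J_PER_UMOL = 1.0 / 4.57  # energy content of PAR quanta
SIGMA_SB = 5.670374419e-8
DEFAULT_ABSORPTANCE_PAR = 0.85
DEFAULT_LATITUDE = 34.5
DEFAULT_VOXEL_EDGE = 0.3


# ---------------------------------------------------------------------------
# solar geometry
# ---------------------------------------------------------------------------

def solar_declination(doy: int) -> float:
    """Solar declination (deg), Spencer Fourier-series form."""
    g = 2.0 * math.pi * (doy - 1) / 365.0
    dec = (0.006918 - 0.399912 * math.cos(g) + 0.070257 * math.sin(g)
           - 0.006758 * math.cos(2 * g) + 0.000907 * math.sin(2 * g)
           - 0.002697 * math.cos(3 * g) + 0.00148 * math.sin(3 * g))
    return math.degrees(dec)


def solar_position(latitude: float, longitude: float, doy: int,
                   solar_hour: float):
    """Sun elevation and azimuth (deg) at true solar time ``solar_hour``.

    Longitude is accepted for interface symmetry but true solar time
    already absorbs it.  Azimuth is clockwise from North.
    """
    if not 1 <= doy <= 366:
        raise ValueError("DOY must be in [1, 366]")
    dec = math.radians(solar_declination(doy))
    lat = math.radians(latitude)
    hour_angle = math.radians(15.0 * (solar_hour - 12.0))
    sin_el = (math.sin(lat) * math.sin(dec)
              + math.cos(lat) * math.cos(dec) * math.cos(hour_angle))
    elevation = math.degrees(math.asin(max(-1.0, min(1.0, sin_el))))
    cos_el = math.cos(math.radians(elevation))
    if abs(cos_el) < 1e-12:
        azimuth = 180.0
    else:
        sin_az = -math.cos(dec) * math.sin(hour_angle) / cos_el
        cos_az = ((math.sin(dec) - math.sin(lat) * sin_el)
                  / (math.cos(lat) * cos_el))
        azimuth = math.degrees(math.atan2(sin_az, cos_az)) % 360.0
    return elevation, azimuth


def extraterrestrial_ppfd_horizontal(solar_elevation: float,
                                     doy: int) -> float:
    """Extraterrestrial PPFD on a horizontal plane (umol m-2 s-1)."""
    if solar_elevation <= 0:
        return 0.0
    e0 = 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)
    return PPFD_EXTRA * e0 * math.sin(math.radians(solar_elevation))


def split_diffuse_direct(ppfd_total: float, solar_elevation: float,
                         doy: int):
    """Partition total PPFD into (direct, diffuse) on a horizontal plane.

    Uses the hourly clearness-index piecewise model: overcast skies
    (kt <= 0.22) are fully diffuse, and the diffuse fraction declines
    monotonically with kt down to a clear-sky floor that depends on solar
    elevation.  The two components always sum to the input exactly.
    """
    if ppfd_total < 0:
        raise ValueError("ppfd_total must be non-negative")
    if ppfd_total == 0.0:
        return 0.0, 0.0
    if solar_elevation <= 0:
        return 0.0, float(ppfd_total)
    i0h = extraterrestrial_ppfd_horizontal(solar_elevation, doy)
    kt = min(ppfd_total / i0h, 1.0) if i0h > 0 else 0.0
    sin_b = math.sin(math.radians(solar_elevation))
    R = 0.847 - 1.61 * sin_b + 1.04 * sin_b**2
    K = (1.47 - R) / 1.66
    if kt <= 0.22:
        fd = 1.0
    elif kt <= 0.35:
        fd = 1.0 - 6.4 * (kt - 0.22) ** 2
    elif kt <= K:
        fd = 1.47 - 1.66 * kt
    else:
        fd = R
    fd = min(max(fd, 0.0), 1.0)
    diffuse = fd * ppfd_total
    return float(ppfd_total - diffuse), float(diffuse)


def estimate_longwave_and_nir(air_temp: float, rh: float, ppfd_total: float,
                              ppfd_direct: float, solar_elevation: float,
                              doy: int):
    """Atmospheric longwave and NIR components (W m-2).

    Longwave uses the Brutsaert clear-sky emissivity
    eps = 1.24 (e_a/T)^(1/7) (e_a in hPa, T in K) increased toward 1 with
    cloudiness inferred from the diffuse fraction.  NIR is taken as equal
    in energy to PAR (about half of global shortwave each) and split
    direct/diffuse in the same ratio as PPFD.

    Returns (longwave, nir_direct, nir_diffuse).
    """
    if not 0.0 <= rh <= 100.0:
        raise ValueError("RH must be within [0, 100]")
    Tk = air_temp + 273.15
    es_kpa = 0.6108 * math.exp(17.27 * air_temp / (air_temp + 237.3))
    ea_hpa = es_kpa * rh / 100.0 * 10.0
    eps_clear = min(1.24 * (ea_hpa / Tk) ** (1.0 / 7.0), 1.0)
    if ppfd_total > 0 and solar_elevation > 0:
        _, diffuse = split_diffuse_direct(ppfd_total, solar_elevation, doy)
        cloud = min(max((diffuse / ppfd_total - 0.15) / 0.85, 0.0), 1.0)
    else:
        cloud = 0.5  # night: cloudiness unobservable from PPFD
    eps = eps_clear + (1.0 - eps_clear) * cloud
    longwave = eps * SIGMA_SB * Tk**4

    par_w = ppfd_total * PAR_J_PER_UMOL
    nir_total = par_w  # NIR ~ PAR in energy for global shortwave
    direct_frac = ppfd_direct / ppfd_total if ppfd_total > 0 else 0.0
    return float(longwave), float(nir_total * direct_frac), \
        float(nir_total * (1.0 - direct_frac))


# ---------------------------------------------------------------------------
# sky discretization
# ---------------------------------------------------------------------------

@dataclass
class SkyModel:
    """46-sector diffuse sky ("turtle"-style ring discretization).

    Directions are (elevation, azimuth) sector centers; weights are the
    uniform-overcast (isotropic radiance) fractions of horizontal diffuse
    irradiance contributed by each sector, summing to 1.
    """

    directions: np.ndarray  # (46, 2) elevation, azimuth in deg
    weights: np.ndarray     # (46,)
    latitude: float = DEFAULT_LATITUDE
    longitude: float = 0.0

    @classmethod
    def turtle46(cls, latitude: float = DEFAULT_LATITUDE,
                 longitude: float = 0.0) -> "SkyModel":
        ring_bounds = [0.0, 18.0, 36.0, 54.0, 72.0, 90.0]
        ring_counts = [12, 12, 10, 8, 4]
        dirs, wts = [], []
        for i, n in enumerate(ring_counts):
            lo, hi = ring_bounds[i], ring_bounds[i + 1]
            center = 0.5 * (lo + hi)
            # isotropic radiance: horizontal-flux share of the band is
            # sin^2(hi) - sin^2(lo)
            band_w = (math.sin(math.radians(hi)) ** 2
                      - math.sin(math.radians(lo)) ** 2)
            offset = 180.0 / n if i % 2 else 0.0
            for k in range(n):
                dirs.append((center, (offset + 360.0 * k / n) % 360.0))
                wts.append(band_w / n)
        w = np.array(wts)
        return cls(directions=np.array(dirs), weights=w / w.sum(),
                   latitude=latitude, longitude=longitude)

    def __post_init__(self):
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("sky weights must sum to 1")
        if np.any(self.directions[:, 0] <= 0):
            raise ValueError("all sky elevations must be above the horizon")

    def sun(self, doy: int, solar_hour: float):
        return solar_position(self.latitude, self.longitude, doy, solar_hour)


# ---------------------------------------------------------------------------
# voxel grid
# ---------------------------------------------------------------------------

@dataclass
class VoxelGrid:
    """Leaf area density on a regular axis-aligned grid.

    ``lad`` has shape (nx, ny, nz) in m^2 m^-3; ``normals`` is a sample of
    unit lamina normals used to evaluate the G-function for the whole
    stand (leaf-angle statistics are assumed homogeneous across voxels).
    """

    origin: np.ndarray           # (3,) m
    edge: np.ndarray             # (3,) m
    lad: np.ndarray              # (nx, ny, nz)
    normals: np.ndarray = None   # (K, 3) unit vectors

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.edge = np.asarray(self.edge, dtype=float)
        self.lad = np.asarray(self.lad, dtype=float)
        if np.any(self.lad < 0):
            raise ValueError("LAD must be non-negative")
        if self.normals is None:
            self.normals = np.array([[0.0, 0.0, 1.0]])

    def leaf_normals(self) -> np.ndarray:
        return self.normals

    @property
    def dims(self):
        return self.lad.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.edge))

    @property
    def total_leaf_area(self) -> float:
        return float(self.lad.sum() * self.voxel_volume)

    @property
    def leaf_area(self) -> np.ndarray:
        return self.lad * self.voxel_volume

    @property
    def upper_corner(self) -> np.ndarray:
        return self.origin + self.edge * np.array(self.dims)


def voxelize(scene, edge: float = DEFAULT_VOXEL_EDGE,
             method: str = "centroid") -> VoxelGrid:
    """Discretize a canopy scene into a leaf-area-density grid.

    ``method='centroid'`` assigns each leaf's whole area to the voxel
    containing its centroid; ``method='split'`` subdivides each hexagon
    into small triangles and assigns their areas separately, approximating
    area-weighted clipping.  Total leaf area is conserved exactly in both.
    """
    if edge <= 0:
        raise ValueError("voxel edge must be positive")
    if not scene.leaves:
        raise ValueError("cannot voxelize an empty scene")
    lo, hi = scene.bounding_box()
    span = hi - lo
    if np.any(span <= 0):
        span = np.maximum(span, 1e-6)
    dims = np.maximum(np.ceil(span / edge).astype(int), 1)
    lad = np.zeros(tuple(dims))
    edge3 = np.array([edge, edge, edge])

    def deposit(point, area_m2):
        idx = np.floor((point - lo) / edge3).astype(int)
        idx = np.clip(idx, 0, dims - 1)
        lad[tuple(idx)] += area_m2

    for leaf in scene.leaves:
        area_m2 = leaf.area * 1e-4
        verts = np.asarray(leaf.vertices)
        if method == "centroid":
            deposit(verts.mean(axis=0), area_m2)
        elif method == "split":
            centroid = verts.mean(axis=0)
            tri_areas = []
            tri_centers = []
            nv = len(verts)
            for i in range(nv):
                a, b = verts[i], verts[(i + 1) % nv]
                t_area = 0.5 * np.linalg.norm(np.cross(b - a, centroid - a))
                tri_areas.append(t_area)
                tri_centers.append((a + b + centroid) / 3.0)
            tri_areas = np.array(tri_areas)
            scale = area_m2 / tri_areas.sum() if tri_areas.sum() > 0 else 0.0
            for t_area, c in zip(tri_areas, tri_centers):
                deposit(c, t_area * scale)
        else:
            raise ValueError(f"unknown voxelization method {method!r}")

    lad /= edge**3
    normals = scene.leaf_normals()
    return VoxelGrid(origin=lo, edge=edge3, lad=lad, normals=normals)


# ---------------------------------------------------------------------------
# G-function
# ---------------------------------------------------------------------------

def direction_vector(elevation: float, azimuth: float) -> np.ndarray:
    """Unit vector pointing *toward* the sky direction."""
    el, az = math.radians(elevation), math.radians(azimuth)
    return np.array([math.cos(el) * math.sin(az),
                     math.cos(el) * math.cos(az),
                     math.sin(el)])


def g_function(angles, direction) -> float:
    """Mean projection coefficient G of unit leaf area toward a direction.

    ``angles`` is either an (K, 3) array of unit lamina normals or an
    object exposing ``leaf_normals()`` returning one (an
    ``AngleDistribution`` or ``VoxelGrid``).  ``direction`` is
    (elevation, azimuth) in degrees.  G = E[|n . s|] over the leaf-normal
    distribution, in [0, 1].
    """
    elevation, azimuth = direction
    if elevation <= 0:
        raise ValueError("direction must be above the horizon")
    if hasattr(angles, "leaf_normals"):
        normals = angles.leaf_normals()
    else:
        normals = np.asarray(angles, dtype=float)
    s = direction_vector(elevation, azimuth)
    return float(np.mean(np.abs(normals @ s)))


# ---------------------------------------------------------------------------
# beam traversal
# ---------------------------------------------------------------------------

@dataclass
class BeamResult:
    """Interception of a single beam direction by the grid."""

    intercepted: np.ndarray     # per-voxel intercepted flux (input units x m^2)
    sunlit_fraction: np.ndarray  # per-voxel fraction of leaf area lit
    incident: float             # total flux entering the domain
    transmitted: float          # total flux leaving the domain
    g_value: float

    @property
    def absorbed_per_leaf_area(self):
        return None  # filled by compute_irradiance with absorptance


def _ray_origins(grid: VoxelGrid, d: np.ndarray, spacing: float):
    """Deterministic ray origins on the plane z = z_top covering every
    entry point whose ray can reach the grid."""
    lo = grid.origin
    hi = grid.upper_corner
    H = hi[2] - lo[2]
    t_full = H / (-d[2])
    dx, dy = d[0] * t_full, d[1] * t_full
    x0 = lo[0] + min(-dx, 0.0)
    x1 = hi[0] + max(-dx, 0.0)
    y0 = lo[1] + min(-dy, 0.0)
    y1 = hi[1] + max(-dy, 0.0)
    nx = max(int(math.ceil((x1 - x0) / spacing)), 1)
    ny = max(int(math.ceil((y1 - y0) / spacing)), 1)
    xs = x0 + (np.arange(nx) + 0.5) * (x1 - x0) / nx
    ys = y0 + (np.arange(ny) + 0.5) * (y1 - y0) / ny
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    origins = np.column_stack([X.ravel(), Y.ravel(),
                               np.full(X.size, hi[2])])
    area = (x1 - x0) * (y1 - y0) / (nx * ny)
    return origins, area


def _traverse(grid: VoxelGrid, origin: np.ndarray, d: np.ndarray):
    """Amanatides–Woo voxel traversal; yields (ix, iy, iz, path_length)."""
    lo = grid.origin
    hi = grid.upper_corner
    dims = grid.dims
    # clip ray to the AABB
    t0, t1 = 0.0, np.inf
    for k in range(3):
        if abs(d[k]) < 1e-15:
            if origin[k] < lo[k] or origin[k] > hi[k]:
                return
        else:
            ta = (lo[k] - origin[k]) / d[k]
            tb = (hi[k] - origin[k]) / d[k]
            if ta > tb:
                ta, tb = tb, ta
            t0, t1 = max(t0, ta), min(t1, tb)
    if t0 >= t1:
        return
    eps = 1e-12 * max(1.0, float(np.max(hi - lo)))
    p = origin + (t0 + eps) * d
    idx = np.floor((p - lo) / grid.edge).astype(int)
    idx = np.clip(idx, 0, np.array(dims) - 1)
    step = np.sign(d).astype(int)
    t_max = np.empty(3)
    t_delta = np.empty(3)
    for k in range(3):
        if step[k] != 0:
            next_bound = lo[k] + (idx[k] + (step[k] > 0)) * grid.edge[k]
            t_max[k] = (next_bound - origin[k]) / d[k]
            t_delta[k] = grid.edge[k] / abs(d[k])
        else:
            t_max[k] = np.inf
            t_delta[k] = np.inf
    t = t0
    while t < t1 - 1e-12:
        k = int(np.argmin(t_max))
        t_next = min(t_max[k], t1)
        seg = t_next - t
        if seg > 0:
            yield int(idx[0]), int(idx[1]), int(idx[2]), float(seg)
        t = t_next
        idx[k] += step[k]
        if idx[k] < 0 or idx[k] >= dims[k]:
            return
        t_max[k] += t_delta[k]


def beam_interception(grid: VoxelGrid, direction, incident_flux: float,
                      ray_spacing: float = None, g_value: float = None,
                      origins_area=None) -> BeamResult:
    """Beer–Lambert interception of a beam through the voxel grid.

    ``direction`` is (elevation, azimuth) of the source; ``incident_flux``
    is the flux density on a horizontal plane (e.g. umol m-2 s-1).  Energy
    is conserved exactly: sum(intercepted) + transmitted = incident.
    """
    elevation, azimuth = direction
    if elevation <= 0:
        raise ValueError("beam must come from above the horizon")
    if incident_flux < 0:
        raise ValueError("incident flux must be non-negative")
    if g_value is None:
        g_value = g_function(grid, direction)
    d = -direction_vector(elevation, azimuth)  # propagation, dz < 0

    if origins_area is not None:
        origins, area = origins_area
    else:
        if ray_spacing is None:
            ray_spacing = float(min(grid.edge)) / 2.0
        origins, area = _ray_origins(grid, d, ray_spacing)

    dims = grid.dims
    intercepted = np.zeros(dims)
    lit_w = np.zeros(dims)
    lit_wt = np.zeros(dims)
    incident_total = 0.0
    transmitted_total = 0.0
    k_lad = g_value * grid.lad
    for o in origins:
        flux = incident_flux * area
        incident_total += flux
        trans = 1.0
        for ix, iy, iz, seg in _traverse(grid, o, d):
            tau = k_lad[ix, iy, iz] * seg
            if tau > 0:
                t_seg = math.exp(-tau)
                intercepted[ix, iy, iz] += flux * trans * (1.0 - t_seg)
                # potential interception if this voxel saw the unshaded beam
                lit_w[ix, iy, iz] += flux * trans * (1.0 - t_seg)
                lit_wt[ix, iy, iz] += flux * (1.0 - t_seg)
                trans *= t_seg
        transmitted_total += flux * trans
    with np.errstate(invalid="ignore", divide="ignore"):
        sunlit = np.where(lit_wt > 0, lit_w / lit_wt, 0.0)
    return BeamResult(intercepted=intercepted, sunlit_fraction=sunlit,
                      incident=float(incident_total),
                      transmitted=float(transmitted_total),
                      g_value=float(g_value))


# ---------------------------------------------------------------------------
# irradiance field
# ---------------------------------------------------------------------------

@dataclass
class IrradianceField:
    """Absorbed PPFD per unit leaf area, per voxel, for one time step."""

    absorbed_direct: np.ndarray   # umol m-2 leaf s-1
    absorbed_diffuse: np.ndarray
    sunlit_fraction: np.ndarray
    incident_direct: float        # umol m-2 ground s-1
    incident_diffuse: float
    nir_direct: float = 0.0
    nir_diffuse: float = 0.0
    longwave: float = 0.0


class RadiationModel:
    """Caches direction-independent quantities for repeated time steps.

    The normalized per-voxel diffuse interception pattern depends only on
    grid geometry and the sky discretization, so it is computed once; each
    time step then scales it by that step's incident diffuse PPFD.
    """

    def __init__(self, grid: VoxelGrid, sky: SkyModel,
                 absorptance_par: float = DEFAULT_ABSORPTANCE_PAR,
                 ray_spacing: float = None):
        self.grid = grid
        self.sky = sky
        self.absorptance = absorptance_par
        self.ray_spacing = ray_spacing or float(min(grid.edge)) / 2.0
        leaf_area = grid.leaf_area
        self._leaf_area = np.where(leaf_area > 0, leaf_area, np.nan)
        # normalized diffuse: interception per voxel for unit horizontal
        # diffuse flux
        acc = np.zeros(grid.dims)
        for (el, az), w in zip(sky.directions, sky.weights):
            res = beam_interception(grid, (el, az), 1.0,
                                    ray_spacing=self.ray_spacing)
            acc += w * res.intercepted
        self._diffuse_unit = acc

    def compute(self, weather_record) -> IrradianceField:
        """Irradiance field for one weather record.

        The record is a mapping with keys ``ppfd``, ``tair``, ``rh``,
        ``wind``, ``doy``, ``hour`` (true solar time, h).
        """
        ppfd = float(weather_record["ppfd"])
        doy = int(weather_record["doy"])
        hour = float(weather_record["hour"])
        elev, az = self.sky.sun(doy, hour)
        direct, diffuse = split_diffuse_direct(ppfd, elev, doy)
        longwave, nir_dir, nir_dif = estimate_longwave_and_nir(
            float(weather_record["tair"]), float(weather_record["rh"]),
            ppfd, direct, elev, doy)

        dims = self.grid.dims
        abs_dir = np.zeros(dims)
        sunlit = np.zeros(dims)
        if direct > 0 and elev > 0:
            res = beam_interception(self.grid, (elev, az), direct,
                                    ray_spacing=self.ray_spacing)
            abs_dir = (res.intercepted / self._leaf_area
                       * self.absorptance)
            abs_dir = np.nan_to_num(abs_dir)
            sunlit = res.sunlit_fraction
        abs_dif = (self._diffuse_unit * diffuse / self._leaf_area
                   * self.absorptance)
        abs_dif = np.nan_to_num(abs_dif)
        return IrradianceField(
            absorbed_direct=abs_dir, absorbed_diffuse=abs_dif,
            sunlit_fraction=sunlit, incident_direct=direct,
            incident_diffuse=diffuse, nir_direct=nir_dir,
            nir_diffuse=nir_dif, longwave=longwave)


def compute_irradiance(grid: VoxelGrid, sky: SkyModel, weather_record,
                       absorptance_par: float = DEFAULT_ABSORPTANCE_PAR
                       ) -> IrradianceField:
    """One-shot irradiance computation (see ``RadiationModel`` for the
    cached variant used inside time loops)."""
    return RadiationModel(grid, sky, absorptance_par).compute(weather_record)
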