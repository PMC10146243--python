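"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here — shoot skeletons,
allometry samples, weather series, A-Ci curves and stomatal response
curves — from a ``TruthConfig`` holding the true parameter values, so
every fitting and upscaling stage can be validated by parameter recovery
without any field data.

One global integer seed fans out into independent per-operation
substreams; a fixed seed gives byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from canopyflux.allometry import AllometricModel
from canopyflux.leaf import (FarquharParams, JarvisParams, farquhar_net_a,
                             GSW_GSC_RATIO)
from canopyflux.radiation import solar_position
from canopyflux.shoots import ShootRecord, classify_shoot_length

ACI_CA_PROTOCOL = (400, 300, 200, 100, 50, 400, 600, 800,
                   1000, 1200, 1500, 1800)  # umol mol-1, measurement order
GS_HOLDING = {"PPFD": 1500.0, "T": 30.0, "VPD": 1.2}
GS_RANGES = {"PPFD": (0.0, 1500.0), "T": (20.0, 35.0), "VPD": (1.0, 3.5)}

_STREAMS = {"shoots": 1, "weather": 2, "aci": 3, "gsresp": 4,
            "allometry": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(
        [int(seed), _STREAMS[stream]]))


def default_allometry() -> AllometricModel:
    """Plausible apple-shoot allometry used as ground truth.

    A 30 cm extension shoot carries ~16 leaves and ~5 dm^2 of leaf area
    (mean single-leaf area ~30 cm^2, leaf length ~7 cm), typical of
    spindle-trained orchard trees.
    """
    return AllometricModel(a_SLA=16.0, b_SLA=10.0, a_SLN=0.45, b_SLN=2.0,
                           a_LA=0.62, a_LW=0.55, b_LW=0.5,
                           a_PL=0.25, b_PL=0.8)


@dataclass
class TruthConfig:
    """Ground-truth parameters driving all generators."""

    allometry_truth: AllometricModel = field(default_factory=default_allometry)
    farquhar_truth: FarquharParams = field(
        default_factory=lambda: FarquharParams(60.0, 120.0, 1.5))
    jarvis_truth: JarvisParams = field(
        default_factory=lambda: JarvisParams(
            g_smax=0.4, K_ppfd=150.0, T_opt=27.0, T_breadth=12.0,
            vpd0=1.6, vpd_slope=0.35))
    na_gradient_truth: tuple = (0.025, 1.2)  # N_a = slope*PPFD_d + intercept
    noise_sd: dict = field(default_factory=lambda: {
        "aci": 0.5, "gs": 0.05, "allometry_area": 0.5, "shoot": 0.0})
    seed: int = 0

    def __post_init__(self):
        if not 0.8 <= self.jarvis_truth.vpd0 <= 3.0:
            raise ValueError("VPD breakpoint must lie within [0.8, 3.0] kPa")
        if self.na_gradient_truth[0] <= 0:
            raise ValueError("N_a gradient slope must be positive")

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(json.dumps(d, indent=2, default=float))


@dataclass
class WeatherSeries:
    """Half-hourly weather table.

    Columns: timestamp (ISO-8601), doy, hour (true solar time, h), ppfd
    (umol m-2 s-1), tair (degC), rh (%), wind (m s-1), plus the per-day
    target class used for generation checks.
    """

    data: pd.DataFrame
    latitude: float

    def __post_init__(self):
        df = self.data
        if (df["ppfd"] < 0).any():
            raise ValueError("ppfd must be non-negative")
        if ((df["rh"] < 0) | (df["rh"] > 100)).any():
            raise ValueError("rh must be within [0, 100]")
        steps = pd.to_datetime(df["timestamp"]).diff().dropna()
        if not (steps == pd.Timedelta(minutes=30)).all():
            raise ValueError("timestamps must be uniform 30-min steps")

    def days(self):
        for doy, day in self.data.groupby("doy", sort=True):
            yield int(doy), day.reset_index(drop=True)

    def ppfd_daily(self) -> pd.Series:
        """Daily cumulated PPFD (mol m-2 d-1)."""
        return self.data.groupby("doy")["ppfd"].sum() * 1800.0 * 1e-6

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# shoot skeletons
# ---------------------------------------------------------------------------

#: shoot length ranges (cm) by type; long/short straddle the 5 cm threshold
_LENGTH_RANGES = {"long": (6.0, 45.0), "short": (1.5, 5.0),
                  "bourse": (1.0, 4.0), "bourse_shoot": (3.0, 15.0)}

#: default per-tree shoot census of a fruiting spindle-trained apple tree
DEFAULT_SHOOT_COUNTS = {"long": 140, "short": 260, "bourse_shoot": 60}


def gen_shoot_skeleton(tree_params: dict, seed: int = 0):
    """Random shoot skeleton inside an ellipsoidal crown.

    ``tree_params``: ``crown_radius`` (m, horizontal semi-axis),
    ``crown_height`` (m, vertical semi-axis), ``crown_base`` (m, height of
    crown center), and ``counts`` mapping shoot type to number of shoots.
    Shoot axes are biased downward (100-120 deg from vertical), mimicking
    spindle training with scaffold branches tied below horizontal.
    """
    r = float(tree_params.get("crown_radius", 0.8))
    hz = float(tree_params.get("crown_height", 1.2))
    base = float(tree_params.get("crown_base", 1.5))
    counts = tree_params.get("counts", DEFAULT_SHOOT_COUNTS)
    if r <= 0 or hz <= 0:
        raise ValueError("crown dimensions must be positive")
    rng = _rng(seed, "shoots")
    shoots = []
    sid = 0
    for stype, n in counts.items():
        if n < 0:
            raise ValueError("shoot counts must be non-negative")
        lo, hi = _LENGTH_RANGES.get(stype, (1.0, 10.0))
        for _ in range(int(n)):
            # uniform point in the unit ball, scaled to the crown ellipsoid
            while True:
                p = rng.uniform(-1.0, 1.0, size=3)
                if np.dot(p, p) <= 1.0:
                    break
            prox = np.array([p[0] * r, p[1] * r, base + p[2] * hz])
            theta = np.radians(rng.uniform(100.0, 120.0))  # from vertical
            phi = rng.uniform(0.0, 2.0 * np.pi)
            direction = np.array([np.sin(theta) * np.cos(phi),
                                  np.sin(theta) * np.sin(phi),
                                  np.cos(theta)])
            length_m = rng.uniform(lo, hi) / 100.0
            shoots.append(ShootRecord(
                shoot_id=sid, type=stype, proximal=prox,
                distal=prox + direction * length_m))
            sid += 1
    return shoots


# ---------------------------------------------------------------------------
# weather
# ---------------------------------------------------------------------------

#: generated daily-light targets (mol m-2 d-1) per class; sunny safely
#: above the 45 threshold, cloudy safely below 15
_PPFD_D_TARGETS = {"sunny": (48.0, 56.0), "cloudy": (6.0, 12.0),
                   "intermediate": (22.0, 38.0)}


def gen_weather(n_days: int, day_mix=(1.0, 0.0, 0.0),
                latitude: float = 34.5, seed: int = 0,
                start_doy: int = 190, year: int = 2013) -> WeatherSeries:
    """Half-hourly weather with a chosen sunny/cloudy/intermediate mix.

    ``day_mix`` gives (sunny, cloudy, intermediate) day fractions.  The
    diurnal PPFD shape is the sine of solar elevation scaled so each day
    integrates exactly to its class's target daily light; cloudy days add
    multiplicative variability before rescaling.  PPFD is zero whenever
    the sun is below the horizon.
    """
    if n_days <= 0:
        raise ValueError("n_days must be positive")
    mix = np.asarray(day_mix, dtype=float)
    if not np.isclose(mix.sum(), 1.0):
        raise ValueError("day_mix fractions must sum to 1")
    rng = _rng(seed, "weather")

    # integer day counts by largest remainder, then shuffle
    raw = mix * n_days
    counts = np.floor(raw).astype(int)
    for _ in range(n_days - counts.sum()):
        counts[int(np.argmax(raw - counts))] += 1
    classes = (["sunny"] * counts[0] + ["cloudy"] * counts[1]
               + ["intermediate"] * counts[2])
    classes = [classes[i] for i in rng.permutation(n_days)]

    hours = (np.arange(48) + 0.5) * 0.5  # step centers
    rows = []
    t0 = pd.Timestamp(year=year, month=1, day=1)
    for di, cls in enumerate(classes):
        doy = start_doy + di
        elev = np.array([solar_position(latitude, 0.0, doy, h)[0]
                         for h in hours])
        shape = np.clip(np.sin(np.radians(np.maximum(elev, 0.0))), 0.0, None)
        shape[elev <= 0] = 0.0
        if cls == "cloudy":
            shape = shape * (0.5 + 0.5 * rng.random(48))
        target = rng.uniform(*_PPFD_D_TARGETS[cls])
        integral = shape.sum() * 1800.0 * 1e-6
        ppfd = shape * (target / integral) if integral > 0 else shape
        tmax = {"sunny": 30.0, "intermediate": 26.0, "cloudy": 23.0}[cls]
        tair = tmax - 6.0 + 6.0 * np.sin(np.pi * (hours - 8.0) / 12.0)
        rh = np.clip(85.0 - 1.2 * (tair - tair.min()) * 5.0, 35.0, 95.0)
        wind = np.clip(1.5 + 0.5 * rng.standard_normal(48), 0.1, None)
        day0 = t0 + pd.Timedelta(days=doy - 1)
        for k in range(48):
            rows.append({
                "timestamp": (day0 + pd.Timedelta(minutes=30 * k)
                              ).isoformat(),
                "doy": doy, "hour": hours[k], "ppfd": ppfd[k],
                "tair": tair[k], "rh": rh[k], "wind": wind[k],
                "target_class": cls})
    return WeatherSeries(data=pd.DataFrame(rows), latitude=latitude)


# ---------------------------------------------------------------------------
# gas-exchange datasets
# ---------------------------------------------------------------------------

def gen_aci_dataset(truth: TruthConfig, ca_sequence=ACI_CA_PROTOCOL,
                    n_leaves: int = 1, T_leaf: float = 30.0,
                    gs_chamber: float = 0.3) -> pd.DataFrame:
    """A-Ci observation table from the Farquhar forward model plus noise.

    For each chamber CO2 step, C_i follows from the diffusion identity at
    the (fixed) chamber stomatal conductance; the recorded A is the
    forward-model value at that C_i plus Gaussian noise of sd
    ``truth.noise_sd['aci']``.  Columns: leaf, ca, ci, a_obs, t_leaf.
    """
    ca_sequence = list(ca_sequence)
    if not ca_sequence:
        raise ValueError("ca_sequence must be non-empty")
    if any(ca <= 0 for ca in ca_sequence):
        raise ValueError("chamber CO2 must be positive")
    from scipy.optimize import brentq
    rng = _rng(truth.seed, "aci")
    sd = float(truth.noise_sd.get("aci", 0.0))
    fp = truth.farquhar_truth
    g_c = gs_chamber / GSW_GSC_RATIO
    rows = []
    for leaf in range(n_leaves):
        for ca in ca_sequence:
            def resid(ci):
                return farquhar_net_a(ci, 1500.0, T_leaf, fp) \
                    - g_c * (ca - ci)
            ci = brentq(resid, 1e-3, ca + 1000.0, xtol=1e-6)
            a_true = farquhar_net_a(ci, 1500.0, T_leaf, fp)
            a_obs = a_true + (rng.normal(0.0, sd) if sd > 0 else 0.0)
            rows.append({"leaf": leaf, "ca": float(ca), "ci": float(ci),
                         "a_obs": float(a_obs), "t_leaf": T_leaf})
    return pd.DataFrame(rows)


def gen_gs_response(truth: TruthConfig, factor: str,
                    grid=None) -> pd.DataFrame:
    """Relative stomatal conductance response curve for one factor.

    Only ``factor`` (one of PPFD/T/VPD) varies over ``grid``; the other
    drivers stay at the measurement holding values (PPFD 1500, T 30 degC,
    VPD 1.2 kPa).  Values are the Jarvis response plus Gaussian noise of
    sd ``truth.noise_sd['gs']``, clipped at zero.
    Columns: factor, value, gs_rel.
    """
    if factor not in GS_RANGES:
        raise ValueError(f"unknown factor {factor!r}; expected PPFD/T/VPD")
    if grid is None:
        lo, hi = GS_RANGES[factor]
        grid = np.linspace(lo if factor != "VPD" else 1.0, hi, 16)
    grid = np.asarray(grid, dtype=float)
    lo, hi = GS_RANGES[factor]
    if grid.min() < lo - 1e-9 or grid.max() > hi + 1e-9:
        import warnings
        warnings.warn(f"{factor} grid extends outside the measured "
                      f"range {GS_RANGES[factor]}")
    rng = _rng(truth.seed, "gsresp")
    sd = float(truth.noise_sd.get("gs", 0.0))
    jp = truth.jarvis_truth
    # with the other drivers clamped at the holding values their constant
    # factors divide out of the normalized g_s/g_smax curve, so the
    # observation is the varied factor's own response
    response = {"PPFD": jp.f_ppfd, "T": jp.f_t, "VPD": jp.f_vpd}[factor]
    rows = []
    for v in grid:
        obs = float(response(float(v))) \
            + (rng.normal(0.0, sd) if sd > 0 else 0.0)
        rows.append({"factor": factor, "value": float(v),
                     "gs_rel": max(obs, 0.0)})
    return pd.DataFrame(rows)


def gen_allometry_samples(truth: TruthConfig, n_shoots: int = 100,
                          seed: int = None) -> pd.DataFrame:
    """Per-shoot allometry observations (SL, SLA, SLN, LL, LA, LW, PL)."""
    rng = _rng(truth.seed if seed is None else seed, "allometry")
    m = truth.allometry_truth
    sd = float(truth.noise_sd.get("allometry_area", 0.0))
    SL = rng.uniform(2.0, 30.0, size=n_shoots)
    SLA = m.a_SLA * SL + m.b_SLA + rng.normal(0.0, sd, n_shoots)
    SLN = m.a_SLN * SL + m.b_SLN + rng.normal(0.0, sd * 0.2, n_shoots)
    LL = rng.uniform(3.0, 12.0, size=n_shoots)
    LA = m.a_LA * LL**2 + rng.normal(0.0, sd, n_shoots)
    LW = m.a_LW * LL + m.b_LW + rng.normal(0.0, sd * 0.1, n_shoots)
    PL = m.a_PL * LL + m.b_PL + rng.normal(0.0, sd * 0.1, n_shoots)
    return pd.DataFrame({"SL": SL, "SLA": SLA, "SLN": SLN, "LL": LL,
                         "LA": np.maximum(LA, 0.05), "LW": LW, "PL": PL})


def gen_na_gradient(truth: TruthConfig, ppfd_d_values,
                    noise_sd: float = 0.0, seed: int = None) -> pd.DataFrame:
    """Leaf N_a samples along a daily-light gradient."""
    rng = _rng(truth.seed if seed is None else seed, "allometry")
    ppfd_d = np.asarray(ppfd_d_values, dtype=float)
    s, b = truth.na_gradient_truth
    na = s * ppfd_d + b + rng.normal(0.0, noise_sd, ppfd_d.size)
    return pd.DataFrame({"ppfd_d": ppfd_d, "na": na})
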