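"""Canopy-scale time-loop engine.

Per 30-min step: radiation transfer gives each voxel its absorbed direct
and diffuse PPFD and sunlit leaf-area fraction; each voxel's leaf
parameters follow its daily-light position in the canopy nitrogen
gradient; sunlit and shaded leaf classes are coupled separately and
leaf-area-weighted into instantaneous canopy rates A_h (umol m-2 s-1) and
E_h (mmol m-2 s-1).  Days integrate to A_c (mmol m-2 d-1), E_c
(mol m-2 d-1) and WUE_c = A_c/E_c, and are classified sunny (> 45 mol
m-2 d-1 daily light), cloudy (< 15) or intermediate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from canopyflux.leaf import (LeafFunctionSet, couple_leaf,
                             scale_params_from_light, saturation_vp)
from canopyflux.radiation import (DEFAULT_VOXEL_EDGE, RadiationModel,
                                  SkyModel, VoxelGrid, voxelize,
                                  extraterrestrial_ppfd_horizontal)

SECONDS_PER_STEP = 1800.0
STEPS_PER_DAY = 48
SUNNY_THRESHOLD = 45.0   # mol m-2 d-1
CLOUDY_THRESHOLD = 15.0
CLEAR_SKY_TRANSMISSION = 0.75


def classify_day(ppfd_d: float) -> str:
    """Sunny / cloudy / intermediate classification of a day's light."""
    if ppfd_d < 0:
        raise ValueError("PPFD_d must be non-negative")
    if ppfd_d > SUNNY_THRESHOLD:
        return "sunny"
    if ppfd_d < CLOUDY_THRESHOLD:
        return "cloudy"
    return "intermediate"


def integrate_day(A_h, E_h):
    """Daily integrals A_c (mmol m-2 d-1) and E_c (mol m-2 d-1).

    Each half-hour value contributes rate x 1800 s x 10^-3; WUE_c is the
    ratio, NaN-flagged when no water was transpired.
    """
    A_h = np.asarray(A_h, dtype=float)
    E_h = np.asarray(E_h, dtype=float)
    if A_h.size != STEPS_PER_DAY or E_h.size != STEPS_PER_DAY:
        raise ValueError(f"need exactly {STEPS_PER_DAY} half-hour steps")
    A_c = float(A_h.sum() * SECONDS_PER_STEP * 1e-3)
    E_c = float(E_h.sum() * SECONDS_PER_STEP * 1e-3)
    WUE_c = A_c / E_c if E_c > 0 else float("nan")
    return A_c, E_c, WUE_c


@dataclass
class SimulationResult:
    steps: pd.DataFrame  # doy, hour, A_h, E_h
    days: pd.DataFrame   # doy, A_c, E_c, WUE_c, PPFD_d, day_class


class CanopySimulator:
    """Static-canopy simulator bound to one scene and one function set.

    The scene is voxelized once; the diffuse interception pattern and the
    per-voxel reference daily light (a clear-sky day at the start of the
    simulation window, used for the nitrogen gradient) are precomputed.
    """

    def __init__(self, scene=None, funcs: LeafFunctionSet = None,
                 grid: VoxelGrid = None, sky: SkyModel = None,
                 voxel_edge: float = DEFAULT_VOXEL_EDGE,
                 absorptance: float = 0.85,
                 reference_doy: int = 190):
        if grid is None:
            grid = voxelize(scene, edge=voxel_edge)
        self.grid = grid
        self.funcs = funcs
        self.sky = sky or SkyModel.turtle46()
        self.radiation = RadiationModel(grid, self.sky,
                                        absorptance_par=absorptance)
        self._occupied = np.argwhere(grid.leaf_area > 1e-12)
        self._leaf_area = grid.leaf_area
        self.voxel_ppfd_d = self._reference_ppfd_d(reference_doy)
        self._voxel_params = {}
        for idx in map(tuple, self._occupied):
            na, fp, gsmax = scale_params_from_light(
                float(self.voxel_ppfd_d[idx]), funcs)
            self._voxel_params[idx] = (na, fp, gsmax)

    def _reference_ppfd_d(self, doy: int) -> np.ndarray:
        """Per-voxel daily absorbed light on a clear-sky reference day
        (mol m-2 leaf d-1), held static over the season."""
        acc = np.zeros(self.grid.dims)
        hours = (np.arange(STEPS_PER_DAY) + 0.5) * 0.5
        for h in hours:
            elev, _ = self.sky.sun(doy, h)
            if elev <= 0:
                continue
            i0h = extraterrestrial_ppfd_horizontal(elev, doy)
            ppfd = CLEAR_SKY_TRANSMISSION * i0h
            rec = {"ppfd": ppfd, "tair": 25.0, "rh": 50.0, "wind": 1.5,
                   "doy": doy, "hour": h}
            irr = self.radiation.compute(rec)
            acc += ((irr.absorbed_direct + irr.absorbed_diffuse)
                    * SECONDS_PER_STEP * 1e-6)
        return acc

    def simulate_step(self, record):
        """Canopy A_h, E_h for one weather record.

        Sunlit leaves receive the voxel's direct beam concentrated on the
        sunlit fraction plus diffuse; shaded leaves receive diffuse only.
        Returns (A_h, E_h, states) with rates per unit leaf area.
        """
        irr = self.radiation.compute(record)
        tair = float(record["tair"])
        rh = float(record["rh"])
        wind = float(record["wind"])
        vpd_air = max(saturation_vp(tair) * (1.0 - rh / 100.0), 0.0)

        total_area = 0.0
        A_sum = 0.0
        E_sum = 0.0
        states = []
        for idx in map(tuple, self._occupied):
            area = float(self._leaf_area[idx])
            na, fp, gsmax = self._voxel_params[idx]
            abs_dif = float(irr.absorbed_diffuse[idx])
            abs_dir = float(irr.absorbed_direct[idx])
            f_sun = float(irr.sunlit_fraction[idx]) if abs_dir > 0 else 0.0
            classes = []
            if f_sun > 1e-9:
                classes.append((f_sun, abs_dir / f_sun + abs_dif))
                if f_sun < 1.0 - 1e-9:
                    classes.append((1.0 - f_sun, abs_dif))
            else:
                classes.append((1.0, abs_dif))
            for frac, ppfd_abs in classes:
                try:
                    st = couple_leaf(ppfd_abs, tair, vpd_air,
                                     self.funcs, N_a=na, wind=wind, rh=rh)
                except RuntimeError as err:
                    raise RuntimeError(f"voxel {idx}: {err}") from err
                w = area * frac
                A_sum += w * st.A_l
                E_sum += w * st.E_l
                states.append((idx, frac, st))
            total_area += area
        if total_area <= 0:
            raise ValueError("grid holds no leaf area")
        return A_sum / total_area, E_sum / total_area, states

    def run(self, weather) -> SimulationResult:
        """Simulate a weather series day by day (48 steps each)."""
        step_rows = []
        day_rows = []
        for doy, day in weather.days():
            if len(day) != STEPS_PER_DAY:
                raise ValueError(
                    f"day {doy}: expected {STEPS_PER_DAY} half-hour steps, "
                    f"got {len(day)} (missing steps in weather series)")
            A_series = np.empty(STEPS_PER_DAY)
            E_series = np.empty(STEPS_PER_DAY)
            for k, rec in enumerate(day.to_dict("records")):
                A_h, E_h, _ = self.simulate_step(rec)
                A_series[k] = A_h
                E_series[k] = E_h
                step_rows.append({"doy": doy, "hour": rec["hour"],
                                  "A_h": A_h, "E_h": E_h})
            ppfd_d = float(day["ppfd"].sum() * SECONDS_PER_STEP * 1e-6)
            A_c, E_c, WUE_c = integrate_day(A_series, E_series)
            day_rows.append({"doy": doy, "A_c": A_c, "E_c": E_c,
                             "WUE_c": WUE_c, "PPFD_d": ppfd_d,
                             "day_class": classify_day(ppfd_d)})
        return SimulationResult(steps=pd.DataFrame(step_rows),
                                days=pd.DataFrame(day_rows))


def run_season(scene, funcs: LeafFunctionSet, weather,
               voxel_edge: float = DEFAULT_VOXEL_EDGE,
               sky: SkyModel = None, absorptance: float = 0.85,
               from_doy: int = None, to_doy: int = None) -> SimulationResult:
    """Voxelize a scene once and simulate a weather series.

    ``from_doy``/``to_doy`` restrict the simulated window; the weather
    series must cover it without gaps.
    """
    data = weather.data
    if from_doy is not None or to_doy is not None:
        lo = from_doy if from_doy is not None else int(data["doy"].min())
        hi = to_doy if to_doy is not None else int(data["doy"].max())
        missing = sorted(set(range(lo, hi + 1)) - set(data["doy"].unique()))
        if missing:
            raise ValueError(f"weather series missing DOY(s): {missing}")
        data = data[(data["doy"] >= lo) & (data["doy"] <= hi)]
        weather = type(weather)(data=data.reset_index(drop=True),
                                latitude=weather.latitude)
    sky = sky or SkyModel.turtle46(latitude=weather.latitude)
    sim = CanopySimulator(scene=scene, funcs=funcs, sky=sky,
                          voxel_edge=voxel_edge, absorptance=absorptance,
                          reference_doy=int(data["doy"].min()))
    return sim.run(weather)
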