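"""Inverse procedures for leaf gas-exchange parameterization.

Farquhar parameters from A-Ci curves (multistart nonlinear least
squares), Jarvis response shapes including the two-segment VPD breakpoint
(profile search over candidate breakpoints), the maximum stomatal
conductance by the optimal-window percentile rule, and the five
nitrogen-scaling lines that map each curve fit onto the canopy light
gradient.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize_scalar, curve_fit

from canopyflux.allometry import fit_line
from canopyflux.leaf import FarquharParams, JarvisParams, farquhar_net_a


@dataclass
class FitResult:
    estimates: dict
    se: dict = field(default_factory=dict)
    rss: float = float("nan")
    converged: bool = True
    n_obs: int = 0

    def __post_init__(self):
        if self.converged:
            for k, v in self.se.items():
                if not np.isfinite(v):
                    raise ValueError(f"converged fit has non-finite SE {k}")
        if self.n_obs and self.n_obs < len(self.estimates):
            raise ValueError("fewer observations than parameters")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"estimates": self.estimates, "se": self.se, "rss": self.rss,
             "converged": self.converged, "n_obs": self.n_obs}, indent=2))


# ---------------------------------------------------------------------------
# A-Ci
# ---------------------------------------------------------------------------

_ACI_STARTS = [(30.0, 60.0), (60.0, 120.0), (100.0, 180.0),
               (150.0, 250.0), (45.0, 140.0)]


def fit_aci(obs: pd.DataFrame, T_leaf: float = None,
            R_d25_fixed: float = None, constants: dict = None,
            n_starts: int = 5) -> FitResult:
    """Farquhar parameters from an A-Ci response curve.

    ``obs`` needs columns ``ci`` and ``a_obs`` (and ``t_leaf`` unless
    ``T_leaf`` is given).  Estimates are expressed at 25 degC directly:
    the forward model applies the same temperature-response constant set
    used for generation, so no separate back-transformation step is
    required.  R_d25 is co-estimated unless a pre-dawn measured value is
    supplied via ``R_d25_fixed``.  Multistart (>= 5 starts) with best-RSS
    selection guards against the Rubisco/RuBP limitation-regime exchange
    ambiguity.
    """
    ci = np.asarray(obs["ci"], dtype=float)
    a = np.asarray(obs["a_obs"], dtype=float)
    if T_leaf is None:
        T_leaf = float(obs["t_leaf"].iloc[0])
    if np.unique(np.round(ci, 6)).size < 6:
        raise ValueError("need >= 6 distinct C_i values")
    co_rd = R_d25_fixed is None
    kw = {"constants": constants} if constants else {}

    def model(theta):
        vc, jm = theta[0], theta[1]
        rd = theta[2] if co_rd else R_d25_fixed
        p = FarquharParams(vc, jm, rd, **kw)
        return farquhar_net_a(ci, 1500.0, T_leaf, p)

    def resid(theta):
        return model(theta) - a

    best = None
    for k in range(max(n_starts, 5)):
        vc0, jm0 = _ACI_STARTS[k % len(_ACI_STARTS)]
        x0 = [vc0, jm0] + ([1.5] if co_rd else [])
        lb = [1.0, 1.0] + ([0.01] if co_rd else [])
        ub = [500.0, 800.0] + ([20.0] if co_rd else [])
        try:
            sol = least_squares(resid, x0, bounds=(lb, ub), xtol=1e-12,
                                ftol=1e-12)
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        raise RuntimeError("A-Ci fit failed to converge from any start")
    rss, sol = best

    names = ["V_cmax25", "J_max25"] + (["R_d25"] if co_rd else [])
    n, p = ci.size, len(names)
    dof = max(n - p, 1)
    J = sol.jac
    try:
        cov = np.linalg.inv(J.T @ J) * rss / dof
        se = {nm: float(np.sqrt(max(cov[i, i], 0.0)))
              for i, nm in enumerate(names)}
    except np.linalg.LinAlgError:
        se = {nm: float("inf") for nm in names}
    estimates = {nm: float(v) for nm, v in zip(names, sol.x)}
    if not co_rd:
        estimates["R_d25"] = float(R_d25_fixed)

    # limitation-regime identifiability warning
    p_hat = FarquharParams(estimates["V_cmax25"], estimates["J_max25"],
                           estimates["R_d25"], **kw)
    k25 = p_hat.at_temperature(T_leaf)
    from canopyflux.leaf import electron_transport, O2_MMOL
    Jv = electron_transport(1500.0, k25["Jmax"])
    Km = k25["Kc"] * (1.0 + O2_MMOL / k25["Ko"])
    wc = k25["Vcmax"] * (ci - k25["gamma_star"]) / (ci + Km)
    wj = Jv * (ci - k25["gamma_star"]) / (4 * ci + 8 * k25["gamma_star"])
    if np.all(wc < wj) or np.all(wj < wc):
        import warnings
        warnings.warn("A-Ci curve lies entirely in one limitation regime; "
                      "V_cmax or J_max may be unidentifiable")
    return FitResult(estimates=estimates, se=se, rss=rss,
                     converged=True, n_obs=int(n))


# ---------------------------------------------------------------------------
# VPD breakpoint
# ---------------------------------------------------------------------------

def _vpd_profile_rss(vpd, y, v0):
    """RSS of the plateau/decline model at breakpoint v0, with the
    decline slope solved in closed form (continuity at v0 enforced)."""
    above = vpd > v0
    rss_plateau = float(np.sum((y[~above] - 1.0) ** 2))
    if not np.any(above):
        return rss_plateau, 0.0
    dx = vpd[above] - v0
    dy = 1.0 - y[above]
    s = max(float(np.sum(dx * dy) / np.sum(dx * dx)), 0.0)
    rss = rss_plateau + float(np.sum((dy - s * dx) ** 2))
    return rss, s


def fit_vpd_threshold(obs: pd.DataFrame) -> FitResult:
    """Breakpoint VPD0 and decline slope of the g_s/g_smax VPD response.

    Two-segment model: flat at 1 up to VPD0, then linear decline, joined
    continuously.  The breakpoint is profiled over a dense candidate grid
    and then refined by bounded 1-D minimization of the profile RSS.
    """
    vpd = np.asarray(obs["value"], dtype=float)
    y = np.asarray(obs["gs_rel"], dtype=float)
    lo, hi = float(vpd.min()), float(vpd.max())
    candidates = np.unique(np.concatenate(
        [vpd, np.linspace(lo, hi, 201)]))
    candidates = candidates[(candidates > lo) & (candidates < hi)]
    if candidates.size == 0:
        raise ValueError("breakpoint unidentifiable: "
                         "no interior candidate VPD values")
    rss_grid = np.array([_vpd_profile_rss(vpd, y, v)[0]
                         for v in candidates])
    v_best = candidates[int(np.argmin(rss_grid))]
    # refine within the neighboring candidate interval
    i = int(np.argmin(rss_grid))
    lo_r = candidates[max(i - 1, 0)]
    hi_r = candidates[min(i + 1, candidates.size - 1)]
    if hi_r > lo_r:
        ref = minimize_scalar(lambda v: _vpd_profile_rss(vpd, y, v)[0],
                              bounds=(lo_r, hi_r), method="bounded",
                              options={"xatol": 1e-6})
        if ref.fun <= rss_grid[i] + 1e-12:
            v_best = float(ref.x)
    rss, slope = _vpd_profile_rss(vpd, y, v_best)
    plateau_n = int((vpd <= v_best).sum())
    decline_n = int((vpd > v_best).sum())
    if slope <= 1e-12 or plateau_n < 2 or decline_n < 2:
        raise ValueError("breakpoint unidentifiable: all observations "
                         "effectively on one segment")
    n = vpd.size
    sd = np.sqrt(rss / max(n - 2, 1))
    return FitResult(estimates={"vpd0": float(v_best),
                                "slope": float(slope)},
                     se={"vpd0": float(sd), "slope": float(sd)},
                     rss=float(rss), converged=True, n_obs=int(n))


# ---------------------------------------------------------------------------
# PPFD / temperature responses
# ---------------------------------------------------------------------------

def fit_response(obs: pd.DataFrame, factor: str,
                 ppfd_ref: float = 1500.0) -> FitResult:
    """Shape parameters of the PPFD or temperature Jarvis response."""
    x = np.asarray(obs["value"], dtype=float)
    y = np.asarray(obs["gs_rel"], dtype=float)
    if x.size < 5:
        raise ValueError("need >= 5 points")
    if factor == "PPFD":
        def f(x, K):
            norm = ppfd_ref / (ppfd_ref + K)
            return np.clip((x / (x + K)) / norm, 0.0, 1.0)

        popt, pcov = curve_fit(f, x, y, p0=[150.0],
                               bounds=(1e-3, 5000.0), maxfev=10000)
        est = {"K_ppfd": float(popt[0])}
        se = {"K_ppfd": float(np.sqrt(pcov[0, 0]))}
    elif factor == "T":
        def f(x, T_opt, breadth):
            return np.clip(1.0 - ((x - T_opt) / breadth) ** 2, 0.0, 1.0)

        popt, pcov = curve_fit(f, x, y, p0=[27.0, 10.0],
                               bounds=([10.0, 1.0], [45.0, 50.0]),
                               maxfev=10000)
        est = {"T_opt": float(popt[0]), "T_breadth": float(popt[1])}
        se = {k: float(np.sqrt(pcov[i, i])) for i, k in enumerate(est)}
    else:
        raise ValueError(f"unknown factor {factor!r}; expected PPFD or T")
    yhat = f(x, *popt)
    rss = float(np.sum((y - yhat) ** 2))
    se = {k: (v if np.isfinite(v) else 0.0) for k, v in se.items()}
    return FitResult(estimates=est, se=se, rss=rss, converged=True,
                     n_obs=int(x.size))


# ---------------------------------------------------------------------------
# g_smax percentile rule
# ---------------------------------------------------------------------------

GSMAX_WINDOWS = {"ppfd": (800.0, 1500.0), "t": (20.0, 30.0),
                 "vpd": (1.4, 2.0)}
GSMAX_CA = 380.0


def estimate_gsmax(obs: pd.DataFrame, rule: str = "mean_above_p90") -> float:
    """g_smax from observations inside the optimal-condition windows.

    Rows must carry ``gs`` plus ``ppfd``, ``t``, ``vpd`` (and optionally
    ``ca``, required to equal 380 umol mol-1).  ``rule='mean_above_p90'``
    (default) averages values strictly above the 90th percentile of the
    filtered set; ``rule='p90'`` returns the percentile itself.
    """
    mask = pd.Series(True, index=obs.index)
    fails = {}
    for col, (lo, hi) in GSMAX_WINDOWS.items():
        ok = (obs[col] >= lo) & (obs[col] <= hi)
        fails[col] = int((~ok).sum())
        mask &= ok
    if "ca" in obs.columns:
        ok = np.isclose(obs["ca"], GSMAX_CA, atol=5.0)
        fails["ca"] = int((~ok).sum())
        mask &= ok
    gs = np.asarray(obs.loc[mask, "gs"], dtype=float)
    if gs.size == 0:
        worst = max(fails, key=fails.get)
        raise ValueError("no observation satisfies the optimal-condition "
                         f"windows (most-violated condition: {worst}, "
                         f"{fails[worst]} rows outside)")
    p90 = float(np.percentile(gs, 90.0))
    if rule == "p90":
        return p90
    if rule != "mean_above_p90":
        raise ValueError(f"unknown gsmax rule {rule!r}")
    above = gs[gs > p90]
    return float(above.mean()) if above.size else float(gs.max())


# ---------------------------------------------------------------------------
# nitrogen-scaling lines
# ---------------------------------------------------------------------------

def fit_scaling_lines(samples: pd.DataFrame) -> dict:
    """Five OLS lines tying leaf function to the canopy light gradient.

    ``samples`` columns: ``ppfd_d``, ``na``, ``vcmax25``, ``jmax25``,
    ``rd25``, ``gsmax`` (one row per sampled leaf).  Returns a dict of
    relation name -> (slope, intercept, r2); N_a is regressed on PPFD_d
    and all physiological parameters on N_a.
    """
    if len(samples) < 3:
        raise ValueError("need >= 3 leaves spanning a light gradient")
    out = {"na_vs_ppfdd": fit_line(samples["ppfd_d"], samples["na"])}
    for name, col in [("vcmax_vs_na", "vcmax25"), ("jmax_vs_na", "jmax25"),
                      ("rd_vs_na", "rd25"), ("gsmax_vs_na", "gsmax")]:
        out[name] = fit_line(samples["na"], samples[col])
    return out


def build_function_set(treatment: str, lines: dict,
                       jarvis: JarvisParams):
    """Assemble a LeafFunctionSet from fitted scaling lines."""
    from canopyflux.leaf import LeafFunctionSet
    return LeafFunctionSet(
        treatment=treatment,
        na_vs_ppfdd=tuple(lines["na_vs_ppfdd"][:2]),
        vcmax_vs_na=tuple(lines["vcmax_vs_na"][:2]),
        jmax_vs_na=tuple(lines["jmax_vs_na"][:2]),
        rd_vs_na=tuple(lines["rd_vs_na"][:2]),
        gsmax_vs_na=tuple(lines["gsmax_vs_na"][:2]),
        jarvis=jarvis)
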