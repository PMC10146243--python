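"""Leaf-scale forward models.

Farquhar–von Caemmerer–Berry photosynthesis, Jarvis multiplicative stomatal
conductance, their coupling through intercellular CO2 (C_i), transpiration,
an optional leaf energy balance, and the nitrogen-gradient scaling that
parameterizes each canopy position from the daily light it receives.

Conventions
-----------
* Rates in umol m^-2 s^-1 (A, V_cmax, J_max, R_d), conductances in
  mol m^-2 s^-1 (water-vapour basis for g_s), CO2 in umol mol^-1,
  VPD in kPa, temperatures in degC.
* Temperature responses follow a single named constant set
  (``BERNACCHI_2001`` by default), swappable per ``FarquharParams``.
* g_s is independent of A (Jarvis formulation, not Ball–Berry): the
  coupling only closes the CO2 diffusion identity
  A(C_i) = (g_s/1.6) * (C_a - C_i).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

R_GAS = 8.314  # J mol-1 K-1
T_REF = 298.15  # K (25 degC)
O2_MMOL = 210.0  # mmol mol-1, chloroplastic O2
P_ATM = 101.325  # kPa
SIGMA_SB = 5.670374419e-8  # W m-2 K-4
CP_AIR_MOLAR = 29.2  # J mol-1 K-1
LAMBDA_MOLAR = 44000.0  # J mol-1, latent heat of vaporization
GSW_GSC_RATIO = 1.6  # diffusivity ratio H2O/CO2

#: Bernacchi et al. (2001)-style kinetic constants at 25 degC with
#: Arrhenius activation energies (J mol-1).  Kc, gamma_star in umol mol-1;
#: Ko in mmol mol-1.
BERNACCHI_2001 = {
    "Kc25": 404.9, "Ea_Kc": 79430.0,
    "Ko25": 278.4, "Ea_Ko": 36380.0,
    "gamma_star25": 42.75, "Ea_gamma": 37830.0,
    "Ea_Vcmax": 65330.0,
    "Ea_Jmax": 43540.0,
    "Ea_Rd": 46390.0,
    "theta_J": 0.9,       # curvature of the light response of J
    "alpha_J": 0.3,       # effective quantum yield of electron transport
}


def _arrhenius(k25: float, Ea: float, T_leaf_c) -> float:
    Tk = np.asarray(T_leaf_c) + 273.15
    return k25 * np.exp(Ea * (Tk - T_REF) / (R_GAS * T_REF * Tk))


@dataclass
class FarquharParams:
    """Biochemical photosynthesis parameters at 25 degC."""

    V_cmax25: float
    J_max25: float
    R_d25: float
    constants: dict = field(default_factory=lambda: dict(BERNACCHI_2001))

    def __post_init__(self):
        for name in ("V_cmax25", "J_max25", "R_d25"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def at_temperature(self, T_leaf_c: float) -> dict:
        """All temperature-adjusted kinetic quantities at T_leaf."""
        c = self.constants
        return {
            "Vcmax": _arrhenius(self.V_cmax25, c["Ea_Vcmax"], T_leaf_c),
            "Jmax": _arrhenius(self.J_max25, c["Ea_Jmax"], T_leaf_c),
            "Rd": _arrhenius(self.R_d25, c["Ea_Rd"], T_leaf_c),
            "Kc": _arrhenius(c["Kc25"], c["Ea_Kc"], T_leaf_c),
            "Ko": _arrhenius(c["Ko25"], c["Ea_Ko"], T_leaf_c),
            "gamma_star": _arrhenius(c["gamma_star25"], c["Ea_gamma"], T_leaf_c),
        }


def electron_transport(PPFD_abs, Jmax, theta=0.9, alpha=0.3):
    """Non-rectangular hyperbola light response of electron transport J."""
    PPFD_abs = np.asarray(PPFD_abs, dtype=float)
    b = alpha * PPFD_abs + Jmax
    disc = b**2 - 4.0 * theta * alpha * PPFD_abs * Jmax
    return (b - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * theta)


def farquhar_net_a(C_i, PPFD_abs, T_leaf, p: FarquharParams):
    """Net assimilation A_l = min(Wc, Wj) - Rd at intercellular CO2 C_i.

    Wc is the Rubisco-limited and Wj the RuBP-regeneration-limited
    carboxylation rate; both share the photorespiration term through the
    CO2 compensation point gamma*.
    """
    C_i = np.asarray(C_i, dtype=float)
    if np.any(C_i <= 0):
        raise ValueError("C_i must be positive")
    k = p.at_temperature(T_leaf)
    c = p.constants
    J = electron_transport(PPFD_abs, k["Jmax"], c["theta_J"], c["alpha_J"])
    Km = k["Kc"] * (1.0 + O2_MMOL / k["Ko"])
    Wc = k["Vcmax"] * (C_i - k["gamma_star"]) / (C_i + Km)
    Wj = J * (C_i - k["gamma_star"]) / (4.0 * C_i + 8.0 * k["gamma_star"])
    A = np.minimum(Wc, Wj) - k["Rd"]
    return A if A.ndim else float(A)


@dataclass
class JarvisParams:
    """Multiplicative stomatal response shapes.

    f_PPFD: saturating hyperbola with half-saturation ``K_ppfd``
    (umol m^-2 s^-1), normalized to 1 at ``ppfd_ref``.
    f_T: symmetric optimum curve 1 - ((T - T_opt)/breadth)^2, floored at 0.
    f_VPD: plateau at 1 up to threshold ``vpd0`` (kPa), then linear decline
    with slope ``vpd_slope`` (kPa^-1), floored at 0.
    """

    g_smax: float
    K_ppfd: float = 150.0
    ppfd_ref: float = 1500.0
    T_opt: float = 27.0
    T_breadth: float = 12.0
    vpd0: float = 1.5
    vpd_slope: float = 0.35

    def __post_init__(self):
        if self.g_smax <= 0:
            raise ValueError("g_smax must be positive")
        if self.vpd0 <= 0:
            raise ValueError("VPD threshold must be positive")

    def f_ppfd(self, PPFD):
        PPFD = np.asarray(PPFD, dtype=float)
        norm = self.ppfd_ref / (self.ppfd_ref + self.K_ppfd)
        f = (PPFD / (PPFD + self.K_ppfd)) / norm
        return np.clip(f, 0.0, 1.0)

    def f_t(self, T_leaf):
        T_leaf = np.asarray(T_leaf, dtype=float)
        f = 1.0 - ((T_leaf - self.T_opt) / self.T_breadth) ** 2
        return np.clip(f, 0.0, 1.0)

    def f_vpd(self, VPD):
        VPD = np.asarray(VPD, dtype=float)
        f = np.where(VPD <= self.vpd0, 1.0,
                     1.0 - self.vpd_slope * (VPD - self.vpd0))
        return np.clip(f, 0.0, 1.0)


def jarvis_gs(PPFD, T_leaf, VPD_surf, g_smax, shapes: JarvisParams):
    """Stomatal conductance g_s = g_smax * f_PPFD * f_T * f_VPD."""
    sh = replace(shapes, g_smax=g_smax)
    f = sh.f_ppfd(PPFD) * sh.f_t(T_leaf) * sh.f_vpd(VPD_surf)
    out = g_smax * f
    return float(out) if np.ndim(out) == 0 else out


@dataclass
class LeafFunctionSet:
    """Per-treatment leaf-function parameterization.

    Linear maps N_a = f(PPFD_d) and V_cmax25/J_max25/R_d25/g_smax = f(N_a),
    plus the Jarvis response shapes.  N_a in g m^-2, PPFD_d in
    mol m^-2 d^-1.  R_d here is a positive respiration magnitude; its
    slope against N_a is negative (shaded, low-N leaves respire relatively
    more per unit nitrogen in this canopy).
    """

    treatment: str
    na_vs_ppfdd: tuple  # (slope, intercept)
    vcmax_vs_na: tuple
    jmax_vs_na: tuple
    rd_vs_na: tuple
    gsmax_vs_na: tuple
    jarvis: JarvisParams
    constants: dict = field(default_factory=lambda: dict(BERNACCHI_2001))

    def __post_init__(self):
        if self.na_vs_ppfdd[0] <= 0:
            raise ValueError("N_a must increase with daily light (slope > 0)")

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "LeafFunctionSet":
        d = json.loads(Path(path).read_text())
        d["jarvis"] = JarvisParams(**d["jarvis"])
        for k in ("na_vs_ppfdd", "vcmax_vs_na", "jmax_vs_na", "rd_vs_na",
                  "gsmax_vs_na"):
            d[k] = tuple(d[k])
        return cls(**d)


_PARAM_FLOOR = 1e-3


def scale_params_from_light(PPFD_d: float, funcs: LeafFunctionSet):
    """Leaf parameters at a canopy position receiving PPFD_d daily light.

    Returns (N_a, FarquharParams, g_smax).  All outputs are clamped to a
    small positive floor so deeply shaded voxels stay physically valid.
    """
    if PPFD_d < 0:
        raise ValueError("PPFD_d must be non-negative")

    def lin(coefs, x):
        return coefs[0] * x + coefs[1]

    na = max(lin(funcs.na_vs_ppfdd, PPFD_d), _PARAM_FLOOR)
    vcmax = max(lin(funcs.vcmax_vs_na, na), _PARAM_FLOOR)
    jmax = max(lin(funcs.jmax_vs_na, na), _PARAM_FLOOR)
    rd = max(lin(funcs.rd_vs_na, na), _PARAM_FLOOR)
    gsmax = max(lin(funcs.gsmax_vs_na, na), _PARAM_FLOOR)
    fp = FarquharParams(vcmax, jmax, rd, constants=dict(funcs.constants))
    return na, fp, gsmax


@dataclass
class LeafState:
    """Coupled leaf gas-exchange state at one time step."""

    PPFD_abs: float
    T_leaf: float
    VPD_surf: float
    g_s: float
    C_i: float
    A_l: float
    E_l: float  # mmol m-2 s-1

    @property
    def WUE_l(self) -> float:
        """Instantaneous water-use efficiency A_l/E_l (umol mmol^-1)."""
        if self.E_l <= 0:
            return float("nan")
        return self.A_l / self.E_l


def saturation_vp(T_c):
    """Saturation vapour pressure (kPa), Tetens formula."""
    T_c = np.asarray(T_c, dtype=float)
    out = 0.6108 * np.exp(17.27 * T_c / (T_c + 237.3))
    return float(out) if np.ndim(out) == 0 else out


def boundary_layer_conductance(wind: float, leaf_dim: float = 0.08) -> float:
    """Leaf boundary-layer conductance to water vapour (mol m-2 s-1).

    Forced-convection flat-plate form g_b = 0.147 * sqrt(u/d); a floor of
    0.25 mol m-2 s-1 stands in for free convection in still air.
    """
    if wind < 0:
        raise ValueError("wind must be non-negative")
    return max(0.147 * np.sqrt(max(wind, 1e-6) / leaf_dim), 0.25)


def leaf_energy_balance(absorbed_rad: float, T_air: float, wind: float,
                        g_s: float, rh: float = 50.0,
                        leaf_dim: float = 0.08, max_iter: int = 50):
    """Solve the leaf energy budget for T_leaf.

    absorbed_rad is the total absorbed short- plus longwave load
    (W m-2, per unit leaf area).  The budget balances thermal emission,
    sensible heat through the boundary layer (both faces) and latent heat
    through stomata in series with the boundary layer.  Returns
    (T_leaf, residual W m-2).
    """
    g_bw = boundary_layer_conductance(wind, leaf_dim)
    g_bh = 0.924 * g_bw  # heat vs vapour diffusivity
    e_air = saturation_vp(T_air) * rh / 100.0

    def residual(T_leaf):
        emitted = 0.97 * SIGMA_SB * (T_leaf + 273.15) ** 4
        H = 2.0 * g_bh * CP_AIR_MOLAR * (T_leaf - T_air)
        g_tot = 1.0 / (1.0 / max(g_s, 1e-9) + 1.0 / g_bw)
        E = g_tot * max(saturation_vp(T_leaf) - e_air, 0.0) / P_ATM
        LE = LAMBDA_MOLAR * E
        return absorbed_rad - emitted - H - LE

    lo, hi = T_air - 10.0, T_air + 15.0
    flo, fhi = residual(lo), residual(hi)
    if flo * fhi > 0:
        # outside the sanity band; return the nearer bound with diagnostic
        raise RuntimeError(
            f"energy balance not bracketed in [{lo}, {hi}] degC "
            f"(residuals {flo:.1f}, {fhi:.1f} W m-2)")
    T_leaf = brentq(residual, lo, hi, xtol=1e-6, maxiter=max_iter * 2)
    return float(T_leaf), float(residual(T_leaf))


def couple_leaf(PPFD_abs: float, T_air: float, VPD_air: float,
                funcs: LeafFunctionSet, N_a: float = None,
                PPFD_d: float = None, C_a: float = 380.0,
                energy_balance: bool = False, wind: float = 1.5,
                rh: float = None, absorbed_rad: float = None,
                ci_tol: float = 1e-4) -> LeafState:
    """Coupled Farquhar/Jarvis solution at one leaf position.

    Parameters come either from an explicit N_a or from the position's
    daily light via ``scale_params_from_light``.  g_s is computed first
    (Jarvis is independent of A); C_i then solves the diffusion identity
    A(C_i) = (g_s/1.6)(C_a - C_i) by bracketed root finding.  In darkness
    respiration can push C_i above C_a, so the bracket extends beyond C_a.

    With ``energy_balance=True`` the leaf temperature solves the energy
    budget (requires ``absorbed_rad`` in W m-2 and ``rh`` in %), and the
    surface VPD is evaluated at T_leaf; otherwise T_leaf = T_air and
    VPD_surf = VPD_air.
    """
    if PPFD_d is not None:
        N_a, fp, g_smax = scale_params_from_light(PPFD_d, funcs)
    elif N_a is not None:
        _, fp, g_smax = _params_from_na(N_a, funcs)
    else:
        raise ValueError("provide N_a or PPFD_d")

    if energy_balance:
        if absorbed_rad is None:
            # shortwave load approximated from absorbed PPFD (~0.219 J/umol
            # PAR) plus an equal NIR share
            absorbed_rad = PPFD_abs * 0.219 * 2.0
        rh_eff = rh if rh is not None else 50.0
        T_leaf, _ = leaf_energy_balance(absorbed_rad, T_air, wind,
                                        funcs.jarvis.g_smax, rh=rh_eff)
        e_air = saturation_vp(T_air) - VPD_air
        VPD_surf = max(saturation_vp(T_leaf) - e_air, 0.0)
    else:
        T_leaf = T_air
        VPD_surf = VPD_air

    g_s = jarvis_gs(PPFD_abs, T_leaf, VPD_surf, g_smax, funcs.jarvis)
    g_c = g_s / GSW_GSC_RATIO

    lo, hi = 1e-3, C_a + 1000.0
    if g_c < 1e-7:
        # stomata effectively closed: no CO2 or water exchange with the
        # air; C_i settles where net assimilation vanishes (light) or at
        # the dark-respiration limit
        def gross(C_i):
            return farquhar_net_a(C_i, PPFD_abs, T_leaf, fp)

        if gross(lo) * gross(hi) < 0:
            C_i = brentq(gross, lo, hi, xtol=ci_tol)
        else:
            C_i = C_a
        return LeafState(PPFD_abs=float(PPFD_abs), T_leaf=float(T_leaf),
                         VPD_surf=float(VPD_surf), g_s=float(g_s),
                         C_i=float(C_i),
                         A_l=float(gross(C_i)) if C_i == C_a else 0.0,
                         E_l=0.0)

    def residual(C_i):
        return farquhar_net_a(C_i, PPFD_abs, T_leaf, fp) - g_c * (C_a - C_i)

    # nearly-closed stomata in darkness push C_i far above C_a before the
    # respiratory efflux balances diffusion; widen the bracket accordingly
    hi = C_a + max(1000.0, 20.0 / g_c)
    flo, fhi = residual(lo), residual(hi)
    if flo * fhi > 0:
        raise RuntimeError(
            "no C_i root: "
            f"state PPFD={PPFD_abs}, T={T_leaf}, VPD={VPD_surf}, gs={g_s}, "
            f"residuals ({flo:.3g}, {fhi:.3g})")
    C_i = brentq(residual, lo, hi, xtol=ci_tol)
    A_l = farquhar_net_a(C_i, PPFD_abs, T_leaf, fp)
    E_l = g_s * VPD_surf / P_ATM * 1000.0  # mmol m-2 s-1
    return LeafState(PPFD_abs=float(PPFD_abs), T_leaf=float(T_leaf),
                     VPD_surf=float(VPD_surf), g_s=float(g_s),
                     C_i=float(C_i), A_l=float(A_l), E_l=float(E_l))


def _params_from_na(N_a: float, funcs: LeafFunctionSet):
    def lin(coefs, x):
        return coefs[0] * x + coefs[1]

    vcmax = max(lin(funcs.vcmax_vs_na, N_a), _PARAM_FLOOR)
    jmax = max(lin(funcs.jmax_vs_na, N_a), _PARAM_FLOOR)
    rd = max(lin(funcs.rd_vs_na, N_a), _PARAM_FLOOR)
    gsmax = max(lin(funcs.gsmax_vs_na, N_a), _PARAM_FLOOR)
    fp = FarquharParams(vcmax, jmax, rd, constants=dict(funcs.constants))
    return N_a, fp, gsmax
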