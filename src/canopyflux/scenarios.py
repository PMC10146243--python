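"""Scenario switching design and statistics.

The switching design crosses leaf *distribution* (the 3D canopy of one
treatment) with leaf *function* (another treatment's physiological
parameter set).  S0 pairs each treatment with its own functions
(reference); S1 swaps functions between cultivars at fixed interstock;
S2 swaps functions between interstocks at fixed cultivar.  Contrasting
scenario outputs partitions the canopy-flux differences into
architecture and physiology contributions.

Also provides the variance partition (sequential two-way ANOVA with
interaction, percent of total sum of squares) and the RMSE/RRMSE model
validation metrics with their accuracy classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from canopyflux.simulate import run_season

#: the four cultivar x interstock treatments, in table order
DEFAULT_TREATMENTS = ("VD Fuji", "VD Gala", "VV Fuji", "VV Gala")

RRMSE_CLASSES = ((10.0, "excellent"), (20.0, "good"),
                 (30.0, "fair"), (float("inf"), "poor"))


@dataclass(frozen=True)
class ScenarioSpec:
    scenario_id: str       # S0a ... S2l
    distribution_source: str
    function_source: str


def _parse(treatment: str):
    inter, cultivar = treatment.split()
    return inter, cultivar


def build_scenarios(treatments=DEFAULT_TREATMENTS):
    """The 12-row switching design (S0 a-d, S1 e-h, S2 i-l).

    S0: identity pairs.  S1: functions swapped between cultivars with the
    same interstock.  S2: functions swapped between interstocks for the
    same cultivar.
    """
    treatments = list(treatments)
    if len(treatments) != 4:
        raise ValueError("need exactly the 4 cultivar x interstock "
                         "treatments")
    inters = sorted({_parse(t)[0] for t in treatments})
    cultivars = sorted({_parse(t)[1] for t in treatments})
    if len(inters) != 2 or len(cultivars) != 2:
        raise ValueError("treatments must cross 2 interstocks x 2 cultivars")

    def swap_cultivar(t):
        i, c = _parse(t)
        other = cultivars[1 - cultivars.index(c)]
        return f"{i} {other}"

    def swap_interstock(t):
        i, c = _parse(t)
        other = inters[1 - inters.index(i)]
        return f"{other} {c}"

    letters = iter("abcdefghijkl")
    specs = []
    for t in treatments:
        specs.append(ScenarioSpec(f"S0{next(letters)}", t, t))
    for t in treatments:
        specs.append(ScenarioSpec(f"S1{next(letters)}", t, swap_cultivar(t)))
    for t in treatments:
        specs.append(ScenarioSpec(f"S2{next(letters)}", t,
                                  swap_interstock(t)))
    return specs


def run_scenarios(specs, scenes: dict, funcs: dict, weather,
                  **season_kwargs) -> pd.DataFrame:
    """Simulate every scenario; returns one row per day per scenario.

    ``scenes`` and ``funcs`` map treatment label to CanopyScene /
    LeafFunctionSet.  Each scenario uses the distribution source's scene
    with the function source's parameter set.
    """
    frames = []
    for spec in specs:
        if spec.distribution_source not in scenes:
            raise KeyError(f"no scene for {spec.distribution_source!r}")
        if spec.function_source not in funcs:
            raise KeyError(f"no function set for {spec.function_source!r}")
        result = run_season(scenes[spec.distribution_source],
                            funcs[spec.function_source], weather,
                            **season_kwargs)
        df = result.days.copy()
        df.insert(0, "scenario_id", spec.scenario_id)
        df.insert(1, "leafdis", spec.distribution_source)
        df.insert(2, "leaffun", spec.function_source)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def percent_contrast(x: float, ref: float) -> float:
    """Percent difference of x relative to a reference, 100*(x-ref)/ref."""
    if ref == 0:
        raise ValueError("reference mean must be non-zero")
    return 100.0 * (x - ref) / ref


@dataclass
class VariancePartition:
    """Percent of total SS per factor with F-test p-values."""

    percent: dict   # factor (and 'residual') -> % of total SS
    p_values: dict

    def __post_init__(self):
        total = sum(self.percent.values())
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"percentages must sum to 100, got {total}")
        if any(v < 0 for v in self.percent.values()):
            raise ValueError("percentages must be non-negative")


def variance_partition(results: pd.DataFrame, response: str,
                       factors=("cultivar", "interstock")
                       ) -> VariancePartition:
    """Two-way sequential (type I) ANOVA variance decomposition.

    Each factor and the interaction get SS_factor/SS_total*100.  The
    design must be complete (no empty cells); balanced designs make the
    sequential decomposition order-invariant.
    """
    fa, fb = factors
    for f in factors:
        if results[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels")
    cells = results.groupby([fa, fb], observed=True).size()
    if len(cells) < results[fa].nunique() * results[fb].nunique():
        raise ValueError("empty cells: balanced design required")
    model = smf.ols(f"{response} ~ C({fa}) * C({fb})", data=results).fit()
    table = sm.stats.anova_lm(model, typ=1)
    ss_total = float(table["sum_sq"].sum())
    key_map = {f"C({fa})": fa, f"C({fb})": fb,
               f"C({fa}):C({fb})": f"{fa}:{fb}", "Residual": "residual"}
    percent = {}
    p_values = {}
    for row_name, row in table.iterrows():
        name = key_map.get(row_name, row_name)
        percent[name] = float(row["sum_sq"]) / ss_total * 100.0
        if name != "residual" and np.isfinite(row["PR(>F)"]):
            p_values[name] = float(row["PR(>F)"])
    return VariancePartition(percent=percent, p_values=p_values)


def rmse_rrmse(observed, simulated):
    """RMSE, RRMSE (% of observed mean), and the accuracy class.

    RMSE = sqrt(mean((O - S)^2)); RRMSE = RMSE / mean(O) * 100, with the
    class bins excellent (< 10%), good (< 20%), fair (< 30%), poor.
    """
    observed = np.asarray(observed, dtype=float)
    simulated = np.asarray(simulated, dtype=float)
    if observed.size != simulated.size or observed.size == 0:
        raise ValueError("need equal-length non-empty vectors")
    rmse = float(np.sqrt(np.mean((observed - simulated) ** 2)))
    mean_obs = float(observed.mean())
    if mean_obs == 0:
        raise ValueError("RRMSE undefined: observed mean is zero")
    rrmse = rmse / mean_obs * 100.0
    for bound, label in RRMSE_CLASSES:
        if rrmse < bound:
            return rmse, rrmse, label
    return rmse, rrmse, "poor"


def pairwise_welch(results: pd.DataFrame, response: str,
                   group: str) -> pd.DataFrame:
    """Pairwise Welch t-tests between group levels (simple post-hoc)."""
    from scipy.stats import ttest_ind
    levels = sorted(results[group].unique())
    rows = []
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            xa = results.loc[results[group] == a, response]
            xb = results.loc[results[group] == b, response]
            t, p = ttest_ind(xa, xb, equal_var=False)
            rows.append({"a": a, "b": b, "t": float(t), "p": float(p)})
    return pd.DataFrame(rows)
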