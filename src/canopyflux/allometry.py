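"""Shoot and leaf allometry.

Five linear-family relationships link shoot length (SL, cm) to shoot leaf
area (SLA, cm^2) and shoot leaf number (SLN), and leaf length (LL, cm) to
leaf area (LA, cm^2, via LA = a*LL^2), leaf width (LW, cm) and petiole
length (PL, cm).  These are the backbone of canopy reconstruction: given a
digitized shoot skeleton, they predict how many leaves a shoot bears, how
large each is, and how they are shaped.

Group comparisons (dwarf vs vigorous interstock, cultivar contrasts) use
ANCOVA-style nested F-tests: slope homogeneity first, then intercept
equality under a common slope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf


@dataclass
class AllometricModel:
    """Coefficients of the five allometric relationships.

    Units: a_SLA (cm^2 per cm), b_SLA (cm^2); a_SLN (leaves per cm),
    b_SLN (leaves); a_LA (dimensionless, LA = a_LA * LL^2); a_LW
    (dimensionless), b_LW (cm); a_PL (dimensionless), b_PL (cm).
    """

    a_SLA: float
    b_SLA: float
    a_SLN: float
    b_SLN: float
    a_LA: float
    a_LW: float
    b_LW: float
    a_PL: float
    b_PL: float
    r2: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.a_LA > 0:
            raise ValueError(f"a_LA must be positive, got {self.a_LA}")
        for name, val in asdict(self).items():
            if name == "r2":
                continue
            if not np.isfinite(val):
                raise ValueError(f"coefficient {name} is not finite")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AllometricModel":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class LineComparison:
    """ANCOVA-style comparison of straight lines across groups."""

    slope_p: float
    intercept_p: float
    slopes: dict
    intercepts: dict


def fit_line(x, y):
    """Ordinary least squares fit y = slope*x + intercept.

    Returns (slope, intercept, r2).  Requires >= 3 points and non-constant x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: x is constant")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    intercept, slope = res.params
    return float(slope), float(intercept), float(res.rsquared)


def fit_power_la(LL, LA) -> float:
    """Least-squares a in LA = a * LL^2 (no intercept).

    Closed form: a = sum(LA * LL^2) / sum(LL^4).
    """
    LL = np.asarray(LL, dtype=float)
    LA = np.asarray(LA, dtype=float)
    if np.any(LL <= 0) or np.any(LA <= 0):
        raise ValueError("leaf lengths and areas must be positive")
    ll2 = LL**2
    return float(np.sum(LA * ll2) / np.sum(ll2**2))


def compare_lines(groups: dict) -> LineComparison:
    """Test slope and intercept equality of per-group regressions.

    ``groups`` maps label -> (x, y).  The slope test is the F-test on the
    group x covariate interaction; the intercept test is the F-test on the
    group main effect in the common-slope (parallel-lines) model, the usual
    ANCOVA testing order.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    frames = []
    slopes, intercepts = {}, {}
    for label, (x, y) in groups.items():
        s, b, _ = fit_line(x, y)
        slopes[label] = s
        intercepts[label] = b
        frames.append(pd.DataFrame({"x": np.asarray(x, float),
                                    "y": np.asarray(y, float),
                                    "g": str(label)}))
    data = pd.concat(frames, ignore_index=True)

    full = smf.ols("y ~ x * C(g)", data=data).fit()
    parallel = smf.ols("y ~ x + C(g)", data=data).fit()
    common = smf.ols("y ~ x", data=data).fit()

    slope_test = full.compare_f_test(parallel)
    intercept_test = parallel.compare_f_test(common)
    return LineComparison(
        slope_p=float(slope_test[1]),
        intercept_p=float(intercept_test[1]),
        slopes=slopes,
        intercepts=intercepts,
    )


def predict_shoot(model: AllometricModel, SL: float):
    """Per-shoot predictions used by reconstruction.

    Returns (SLA cm^2, SLN count, mean leaf area cm^2, internode length cm).
    SLN is rounded to the nearest integer with a floor of one leaf; a
    negative raw SLA is clamped to zero.
    """
    if SL <= 0:
        raise ValueError("shoot length must be positive")
    sla = model.a_SLA * SL + model.b_SLA
    sla = max(sla, 0.0)
    sln_raw = model.a_SLN * SL + model.b_SLN
    sln = max(1, int(round(sln_raw)))
    mean_la = sla / sln
    internode = SL / sln
    return sla, sln, mean_la, internode
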