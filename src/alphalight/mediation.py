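"""Sobel mediation: does right-hemisphere pre-target alpha carry the
effect of light intensity on left-hemifield response times?

Mediation needs a binary treatment, so only the low and high light
conditions enter. Three multilevel fits give the paths: mediator on
treatment (a), outcome on treatment (total effect c), and outcome on
treatment plus mediator (b and the direct effect c'). The indirect
effect is a*b with first-order Sobel standard error
sqrt(b^2 SE_a^2 + a^2 SE_b^2). When the direct effect c' and the
indirect effect carry opposite signs the mediation is classified
'inconsistent' - the pattern where brighter light raises alpha yet
still speeds responses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import ModelSpec, fit_mixed


@dataclass(frozen=True)
class MediationResult:
    path_a: float
    se_a: float
    path_b: float
    se_b: float
    path_c: float
    se_c: float
    path_c_prime: float
    se_c_prime: float
    indirect: float
    sobel_se: float
    sobel_z: float
    sobel_p: float
    consistency: str
    mediator_scale: float
    n_obs: int

    def to_dict(self) -> dict:
        return {k: (v if isinstance(v, (str, int)) else float(v))
                for k, v in self.__dict__.items()}

    def summary(self) -> str:
        lines = [
            "mediation: treatment -> mediator -> outcome",
            f"  a  (treatment->mediator) = {self.path_a:.3f} "
            f"(SE {self.se_a:.3f})",
            f"  b  (mediator->outcome|t) = {self.path_b:.3f} "
            f"(SE {self.se_b:.3f})",
            f"  c  (total effect)        = {self.path_c:.3f} "
            f"(SE {self.se_c:.3f})",
            f"  c' (direct effect)       = {self.path_c_prime:.3f} "
            f"(SE {self.se_c_prime:.3f})",
            f"  indirect = a*b = {self.indirect:.3f}, "
            f"Sobel z = {self.sobel_z:.2f}, p = {self.sobel_p:.3f}",
            f"  classification: {self.consistency} mediation",
        ]
        return "\n".join(lines)


def sobel_from_summary(indirect_estimate: float, indirect_se: float
                       ) -> tuple[float, float]:
    """Sobel z and two-sided normal p from an indirect effect and SE."""
    if indirect_se <= 0:
        raise ValueError("indirect SE must be positive")
    z = indirect_estimate / indirect_se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def classify_consistency(path_c_prime: float, indirect: float) -> str:
    """'inconsistent' iff direct and indirect effects have opposite signs
    (both nonzero), else 'consistent'."""
    if path_c_prime * indirect < 0:
        return "inconsistent"
    return "consistent"


def mediation_sobel(data: pd.DataFrame,
                    treatment_col: str = "light_condition",
                    treatment_levels: tuple[str, str] = ("low", "high"),
                    mediator_col: str = "log_alpha_right",
                    outcome_col: str = "rt_ms",
                    groups: str = "participant_id",
                    random_slope_mediator: bool = True,
                    second_order_se: bool = False,
                    standardise_mediator: bool = True) -> MediationResult:
    """Multilevel Sobel mediation on trial-level data.

    ``data`` should already be restricted to the trials of interest
    (left-hemifield targets under the two treatment conditions); any
    other treatment levels present raise an error. The mediator is
    standardised before fitting (z and p are invariant to this scaling;
    the scale used is reported for back-transformation).
    """
    levels = set(data[treatment_col].unique())
    if levels != set(treatment_levels):
        raise ValueError(f"treatment must be binary {treatment_levels}, "
                         f"found levels {sorted(levels)}")
    df = data.copy()
    df["treatment"] = (df[treatment_col] == treatment_levels[1]).astype(
        float)
    med = pd.to_numeric(df[mediator_col]).to_numpy(float)
    scale = float(np.std(med))
    if scale == 0:
        raise ValueError("mediator is constant; mediation undefined")
    if standardise_mediator:
        df["mediator"] = (med - med.mean()) / scale
    else:
        df["mediator"] = med
        scale = 1.0

    fit_a = fit_mixed(ModelSpec(outcome="mediator",
                                fixed=("treatment",), groups=groups),
                      df)
    fit_c = fit_mixed(ModelSpec(outcome=outcome_col,
                                fixed=("treatment",), groups=groups),
                      df)
    re_b = ("1", "mediator") if random_slope_mediator else ("1",)
    fit_b = fit_mixed(ModelSpec(outcome=outcome_col,
                                fixed=("treatment", "mediator"),
                                groups=groups, re_terms=re_b),
                      df)

    a, se_a = fit_a.params["treatment"], fit_a.bse["treatment"]
    c, se_c = fit_c.params["treatment"], fit_c.bse["treatment"]
    b, se_b = fit_b.params["mediator"], fit_b.bse["mediator"]
    cp, se_cp = fit_b.params["treatment"], fit_b.bse["treatment"]

    indirect = a * b
    var = b * b * se_a * se_a + a * a * se_b * se_b
    if second_order_se:
        var += se_a * se_a * se_b * se_b
    sobel_se = math.sqrt(var)
    z, p = sobel_from_summary(indirect, sobel_se)
    return MediationResult(
        path_a=float(a), se_a=float(se_a), path_b=float(b),
        se_b=float(se_b), path_c=float(c), se_c=float(se_c),
        path_c_prime=float(cp), se_c_prime=float(se_cp),
        indirect=float(indirect), sobel_se=float(sobel_se),
        sobel_z=float(z), sobel_p=float(p),
        consistency=classify_consistency(float(cp), float(indirect)),
        mediator_scale=scale, n_obs=len(df))
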