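"""Variance decomposition of screen parameters by multi-level modelling.

Each parameter is modelled with random intercepts for batch, plate (nested
in batch through globally unique plate ids), a per-plate edge offset shared
by border wells, DIV, and shRNA treatment, on top of residual well noise.
The quantity of interest is the fraction of total variance attributable to
each component, as plotted in screen QC reports.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

COMPONENTS = ("batch", "plate", "edge", "div", "shrna", "residual")


@dataclass(frozen=True)
class VarianceDecomposition:
    parameter: str
    fractions: dict[str, float]   # component -> share of total variance
    variances: dict[str, float]   # component -> raw variance estimate
    n_obs: int
    converged: bool

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"variance fractions sum to {total}, not 1")


class VarianceModelError(RuntimeError):
    pass


_VC_FORMULAS = {
    "batch": "0 + C(batch)",
    "plate": "0 + C(plate)",
    "edge": "0 + C(plate):edge_flag",
    "div": "0 + C(div)",
    "shrna": "0 + C(shrna_level)",
}


def decompose_variance(
    table: pd.DataFrame,
    parameter: str,
    reml: bool = True,
    div_random: bool = True,
) -> VarianceDecomposition:
    """REML variance-component fractions for one (log-scale) parameter.

    ``div_random`` keeps DIV as a random intercept (the default, so its
    share appears in the fraction vector); set False to absorb DIV into
    the fixed mean structure instead.

    Factors with fewer than 2 observed levels are reported as 0 with a
    warning. A constant response raises (zero total variance).
    """
    df = table.dropna(subset=[parameter]).copy()
    if df.empty:
        raise VarianceModelError("no non-missing observations")
    y = df[parameter].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise VarianceModelError("response is constant; zero total variance")

    df["edge_flag"] = df["is_edge"].astype(float)
    df["shrna_level"] = df["shrna_id"].replace("", "none")

    vc = {}
    dropped: list[str] = []
    level_counts = {
        "batch": df["batch"].nunique(),
        "plate": df["plate"].nunique(),
        "edge": df.loc[df["edge_flag"] > 0, "plate"].nunique(),
        "div": df["div"].nunique(),
        "shrna": df["shrna_level"].nunique(),
    }
    for comp, formula in _VC_FORMULAS.items():
        if comp == "div" and not div_random:
            continue
        if level_counts[comp] < 2:
            dropped.append(comp)
            logger.warning("factor %s has < 2 levels; component set to 0", comp)
            continue
        vc[comp] = formula

    fixed = "y ~ 1" if div_random else "y ~ C(div)"
    df = df.assign(y=y, _one=1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM.from_formula(
            fixed, groups="_one", vc_formula=vc, data=df
        )
        try:
            # l-bfgs is fast but can stall at poor local optima of the
            # profiled REML surface; polish with derivative-free Powell and
            # keep whichever solution has the better restricted likelihood
            result = model.fit(reml=reml, method="lbfgs", maxiter=200)
            polished = model.fit(
                reml=reml, method="powell", maxiter=500,
                start_params=result.params_object,
            )
            if polished.llf > result.llf:
                result = polished
        except Exception as exc:  # pragma: no cover - estimator failure
            raise VarianceModelError(f"mixed model failed: {exc}") from exc

    variances = {comp: 0.0 for comp in COMPONENTS}
    names = list(model.exog_vc.names)
    for name, v in zip(names, np.asarray(result.vcomp, dtype=float)):
        variances[name] = max(float(v), 0.0)
    variances["residual"] = max(float(result.scale), 0.0)
    if not div_random:
        variances["div"] = 0.0

    total = sum(variances.values())
    if total <= 0:
        raise VarianceModelError("estimated total variance is zero")
    fractions = {comp: variances[comp] / total for comp in COMPONENTS}
    # renormalize exactly to 1 after truncation
    s = sum(fractions.values())
    fractions = {k: v / s for k, v in fractions.items()}
    return VarianceDecomposition(
        parameter=parameter,
        fractions=fractions,
        variances=variances,
        n_obs=len(df),
        converged=bool(getattr(result, "converged", True)),
    )


def decompose_all(
    table: pd.DataFrame, parameters: list[str], **kwargs
) -> pd.DataFrame:
    """Variance fractions for several parameters as a tidy table."""
    rows = []
    for param in parameters:
        dec = decompose_variance(table, param, **kwargs)
        for comp in COMPONENTS:
            rows.append({
                "parameter": param,
                "component": comp,
                "fraction": dec.fractions[comp],
                "variance": dec.variances[comp],
                "n_obs": dec.n_obs,
            })
    return pd.DataFrame(rows)
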