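"""Plate QC, per-plate normalization against scrambled controls, parameter
correlations, and the qPCR 2^-ddCp utility.

Normalization expresses every well as log2(value / per-plate scrambled
median), so each plate's scrambled wells are centred at zero and
multiplicative plate effects cancel.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .params import PARAMETERS, TREATMENT_SCRAMBLED

logger = logging.getLogger(__name__)


class NormalizationError(ValueError):
    """Raised when a plate cannot be normalized (e.g. no scrambled wells)."""


def parameter_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in PARAMETERS if c in table.columns]


def detect_outlier_plates(
    table: pd.DataFrame,
    low_count_quantile: float = 0.1,
    excess_fraction: float = 0.5,
    count_parameter: str = "nuclei_count",
) -> set[str]:
    """Flag plates with a disproportionate share of low-cell-count wells.

    A well is "low count" if its total cell count falls below the global
    ``low_count_quantile`` of all wells; a plate is flagged when more than
    ``excess_fraction`` of its wells are low count.
    """
    if table.empty:
        raise ValueError("empty well table")
    if table["plate"].nunique() < 2:
        raise ValueError("outlier-plate detection needs >= 2 plates")
    counts = table[count_parameter]
    cutoff = counts.quantile(low_count_quantile)
    low = counts < cutoff
    frac = low.groupby(table["plate"]).mean()
    return set(frac.index[frac > excess_fraction])


def normalize_log2(table: pd.DataFrame) -> pd.DataFrame:
    """Normalize every parameter per plate against the scrambled median and
    log2-transform.

    Raw values <= 0 become missing (NaN) rather than -inf; the rows are
    kept so downstream statistics can use pairwise-complete data.
    """
    params = parameter_columns(table)
    if not params:
        raise ValueError("no parameter columns to normalize")
    scrambled = table["treatment_class"] == TREATMENT_SCRAMBLED
    plates_without = set(table["plate"].unique()) - set(
        table.loc[scrambled, "plate"].unique()
    )
    if plates_without:
        raise NormalizationError(
            f"plates lack scrambled control wells: {sorted(plates_without)}"
        )

    out = table.copy()
    values = out[params].where(out[params] > 0)
    n_dropped = int(values.isna().sum().sum() - out[params].isna().sum().sum())
    if n_dropped:
        logger.warning(
            "%d non-positive raw values set to missing before log2", n_dropped
        )
    medians = (
        values[scrambled].groupby(table.loc[scrambled, "plate"]).median()
    )
    if medians.isna().any().any() or (medians <= 0).any().any():
        bad = medians.index[(medians.isna() | (medians <= 0)).any(axis=1)]
        raise NormalizationError(
            f"scrambled medians undefined or non-positive on plates: {list(bad)}"
        )
    ref = medians.reindex(table["plate"]).to_numpy()
    out[params] = np.log2(values.to_numpy() / ref)
    return out


def scrambled_sd(
    table: pd.DataFrame, by_div: bool = True, ddof: int = 1
) -> pd.DataFrame:
    """Standard deviation of normalized scrambled wells per parameter
    (per DIV when ``by_div``); the reference scale for the no-effect gate."""
    params = parameter_columns(table)
    scr = table[table["treatment_class"] == TREATMENT_SCRAMBLED]
    if scr.empty:
        raise ValueError("no scrambled wells in table")
    if by_div:
        return scr.groupby("div")[params].std(ddof=ddof)
    return scr[params].std(ddof=ddof).to_frame().T


def parameter_correlations(table: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank correlation between parameters over all wells,
    pairwise-complete; constant parameters yield missing correlations."""
    params = parameter_columns(table)
    data = table[params]
    if len(data.dropna(how="all")) < 3:
        raise ValueError("need >= 3 rows for parameter correlations")
    corr = pd.DataFrame(np.nan, index=params, columns=params, dtype=float)
    for i, a in enumerate(params):
        corr.loc[a, a] = 1.0 if data[a].nunique(dropna=True) > 1 else np.nan
        for b in params[i + 1:]:
            pair = data[[a, b]].dropna()
            if len(pair) < 3 or pair[a].nunique() < 2 or pair[b].nunique() < 2:
                continue
            rho = stats.spearmanr(pair[a], pair[b]).statistic
            corr.loc[a, b] = corr.loc[b, a] = rho
    return corr


def ddct_fold_change(
    cp: pd.DataFrame,
    target_col: str = "target_cp",
    reference_cols: tuple[str, ...] = ("actb_cp", "hprt_cp"),
    group_col: str = "group",
    control_label: str = "control",
) -> tuple[float, pd.Series]:
    """Relative expression by the 2^-ddCp method.

    dCp = target Cp - mean(reference Cps) per sample; ddCp is the mean dCp
    of knockdown samples minus the mean dCp of controls. Returns the
    group-level fold change 2^-ddCp and per-knockdown-sample fold changes
    relative to the control mean.
    """
    refs = [c for c in reference_cols if c in cp.columns]
    if not refs:
        raise ValueError("no reference gene Cp columns present")
    if cp[refs + [target_col]].isna().any().any():
        raise ValueError("missing Cp values")
    is_control = cp[group_col] == control_label
    if is_control.sum() < 1 or (~is_control).sum() < 1:
        raise ValueError("need >= 1 control and >= 1 knockdown sample")
    dcp = cp[target_col] - cp[refs].mean(axis=1)
    ddcp = dcp[~is_control].mean() - dcp[is_control].mean()
    per_sample = np.exp2(-(dcp[~is_control] - dcp[is_control].mean()))
    per_sample.index = cp.loc[~is_control].get(
        "sample", cp.loc[~is_control].index
    )
    return float(np.exp2(-ddcp)), per_sample
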