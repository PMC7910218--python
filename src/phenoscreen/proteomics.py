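"""Post-processing of label-free (DIA) protein quantification tables.

The filter chain runs in a fixed order: q-value thresholding (cutoff = mean
of per-sample median q-values) -> detection filtering (a protein may fail
detection in at most one replicate within its best group, and must be seen
in at least one sample of some other group) -> outlier-replicate removal
(groups whose replicate median-q CV exceeds 0.12 lose replicates whose
median q is > 10x the median of the others) -> contaminant removal
(immunoglobulins, keratins, trypsin) -> per-shRNA differential statistics
(Welch t-test on log2 intensities vs the scrambled group) -> the
cross-shRNA concordance filter that defines a gene's regulated proteins:
significant in at least one shRNA, and the same fold-change sign in every
shRNA in which the protein is quantified.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_CONTAMINANT_PATTERNS = ("immunoglobulin", "keratin", "trypsin")


class ProteomicsError(ValueError):
    pass


def q_threshold(metadata: pd.DataFrame) -> float:
    """Arithmetic mean of per-sample median q-values (the detection cutoff)."""
    if metadata.empty:
        raise ProteomicsError("empty sample metadata")
    if metadata["median_q"].isna().any():
        raise ProteomicsError("missing median q for some samples")
    return float(metadata["median_q"].mean())


def apply_q_threshold(
    quant: pd.DataFrame, q_values: pd.DataFrame, cutoff: float
) -> pd.DataFrame:
    """Set identifications with q above the cutoff to undetected (NaN)."""
    out = quant.copy()
    samples = [c for c in quant.columns if c != "description"]
    mask = q_values.reindex(quant.index)[samples].to_numpy() > cutoff
    vals = out[samples].to_numpy(dtype=float)
    vals[mask] = np.nan
    out[samples] = vals
    return out


def detection_filter(
    quant: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Keep proteins detected in >= (r - 1) replicates of at least one group
    and in >= 1 sample of at least one *other* group.

    The within-group rule tolerates a single failed replicate; the
    between-group rule requires the protein not to be private to a single
    group (this is the reading adopted for the ambiguous original phrasing;
    see the methods note).
    """
    samples_by_group = metadata.groupby("group")["sample"].apply(list)
    for group, samples in samples_by_group.items():
        if len(samples) < 2:
            raise ProteomicsError(f"group {group} has < 2 replicates")
    detected = quant[metadata["sample"]].notna()
    keep = []
    for group, samples in samples_by_group.items():
        r = len(samples)
        within = detected[samples].sum(axis=1) >= r - 1
        others = [
            s for g, ss in samples_by_group.items() if g != group for s in ss
        ]
        between = detected[others].sum(axis=1) >= 1
        keep.append(within & between)
    retained = np.logical_or.reduce(keep)
    return quant.loc[retained]


def remove_outlier_replicates(
    metadata: pd.DataFrame,
    cv_threshold: float = 0.12,
    deviation_factor: float = 10.0,
) -> tuple[pd.DataFrame, list[str]]:
    """Drop replicates with wildly deviating median q-values.

    Within each group whose replicate median-q coefficient of variation
    exceeds ``cv_threshold``, replicates whose median q is more than
    ``deviation_factor`` times the median of the remaining replicates'
    median q are removed. Raises if removal would leave < 2 replicates.

    Returns (filtered metadata, removed sample names).
    """
    removed: list[str] = []
    keep_rows = []
    for group, grp in metadata.groupby("group"):
        q = grp["median_q"].to_numpy(dtype=float)
        if len(q) >= 3 and q.mean() > 0:
            cv = q.std(ddof=1) / q.mean()
            if cv > cv_threshold:
                flags = []
                for i in range(len(q)):
                    others = np.delete(q, i)
                    flags.append(q[i] > deviation_factor * np.median(others))
                flags = np.asarray(flags)
                if flags.any():
                    if (~flags).sum() < 2:
                        raise ProteomicsError(
                            f"outlier removal would leave group {group} "
                            "with < 2 replicates"
                        )
                    removed += list(grp.loc[flags, "sample"])
                    grp = grp.loc[~flags]
        keep_rows.append(grp)
    if removed:
        logger.warning("removed outlier replicates: %s", removed)
    return pd.concat(keep_rows, ignore_index=True), removed


def remove_contaminants(
    quant: pd.DataFrame,
    patterns: tuple[str, ...] = DEFAULT_CONTAMINANT_PATTERNS,
) -> pd.DataFrame:
    """Drop proteins whose id or description matches a contaminant pattern
    (case-insensitive substring/regex)."""
    if not patterns:
        return quant
    regex = re.compile("|".join(patterns), re.IGNORECASE)
    desc = quant.get("description", pd.Series("", index=quant.index))
    hits = [
        bool(regex.search(str(pid)) or regex.search(str(d)))
        for pid, d in zip(quant.index, desc)
    ]
    return quant.loc[~np.asarray(hits)]


@dataclass(frozen=True)
class DifferentialResult:
    """Per-protein fold change and significance for one shRNA group."""

    shrna: str
    table: pd.DataFrame  # index protein, columns log2_fc, p_value, n_kd, n_ctrl


def shrna_differential(
    quant: pd.DataFrame,
    metadata: pd.DataFrame,
    shrna: str,
    scrambled_group: str = "scrambled",
    variance_floor: float = 1e-12,
) -> DifferentialResult:
    """Welch t-test on log2 intensities of one shRNA group vs scrambled.

    Proteins with fewer than 2 quantified replicates on either side are
    flagged not-testable (missing values in the output). A variance floor
    stabilises degenerate zero-variance comparisons.
    """
    kd_samples = metadata.loc[metadata["group"] == shrna, "sample"].tolist()
    ctrl_samples = metadata.loc[
        metadata["group"] == scrambled_group, "sample"
    ].tolist()
    if len(kd_samples) < 2 or len(ctrl_samples) < 2:
        raise ProteomicsError(
            f"need >= 2 replicates per side for {shrna} vs {scrambled_group}"
        )
    kd = np.log2(quant[kd_samples].to_numpy(dtype=float))
    ctrl = np.log2(quant[ctrl_samples].to_numpy(dtype=float))

    n_kd = np.sum(~np.isnan(kd), axis=1)
    n_ctrl = np.sum(~np.isnan(ctrl), axis=1)
    testable = (n_kd >= 2) & (n_ctrl >= 2)

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        m1 = np.nanmean(kd, axis=1)
        m2 = np.nanmean(ctrl, axis=1)
        v1 = np.maximum(np.nanvar(kd, axis=1, ddof=1), variance_floor)
        v2 = np.maximum(np.nanvar(ctrl, axis=1, ddof=1), variance_floor)
        se2 = v1 / n_kd + v2 / n_ctrl
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / (
            (v1 / n_kd) ** 2 / (n_kd - 1) + (v2 / n_ctrl) ** 2 / (n_ctrl - 1)
        )
        p = 2.0 * stats.t.sf(np.abs(t), df)
    log2_fc = m1 - m2
    p = np.where(np.abs(log2_fc) < 1e-15, 1.0, p)  # identical means
    out = pd.DataFrame({
        "log2_fc": np.where(testable, log2_fc, np.nan),
        "p_value": np.where(testable, p, np.nan),
        "n_kd": n_kd,
        "n_ctrl": n_ctrl,
    }, index=quant.index)
    return DifferentialResult(shrna=shrna, table=out)


def concordance_filter(
    differentials: list[DifferentialResult],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Regulated proteins of a gene from its per-shRNA differentials.

    A protein qualifies iff (i) p < alpha in at least one shRNA and
    (ii) its log2 fold change has the same (non-zero) sign in every shRNA
    in which it was testable. Proteins testable in fewer than two shRNAs
    are excluded.

    Returns a table indexed by protein with per-shRNA fold changes, the
    mean fold change, and which shRNAs were significant.
    """
    if len(differentials) < 2:
        raise ProteomicsError("concordance needs >= 2 shRNA differentials")
    fc = pd.DataFrame({d.shrna: d.table["log2_fc"] for d in differentials})
    pv = pd.DataFrame({d.shrna: d.table["p_value"] for d in differentials})

    n_testable = fc.notna().sum(axis=1)
    any_sig = ((pv < alpha) & fc.notna()).any(axis=1)
    signs = np.sign(fc)
    nonzero = (signs != 0) | fc.isna()
    concordant = (
        nonzero.all(axis=1)
        & ((signs.where(fc.notna()).nunique(axis=1, dropna=True)) == 1)
    )
    regulated = (n_testable >= 2) & any_sig & concordant

    out = fc.loc[regulated].copy()
    out.columns = [f"log2_fc_{c}" for c in out.columns]
    out["mean_log2_fc"] = fc.loc[regulated].mean(axis=1)
    out["significant_shrnas"] = [
        ",".join(pv.columns[(pv.loc[pid] < alpha) & fc.loc[pid].notna()])
        for pid in out.index
    ]
    return out


def set_overlaps(regulated: dict[str, set[str]]) -> pd.DataFrame:
    """Pairwise and full intersection sizes among per-gene regulated sets."""
    if len(regulated) < 2:
        raise ProteomicsError("need >= 2 regulated sets")
    rows = []
    names = sorted(regulated)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            rows.append({
                "sets": f"{a}&{b}",
                "size": len(regulated[a] & regulated[b]),
            })
    common = set.intersection(*(regulated[n] for n in names))
    rows.append({"sets": "&".join(names), "size": len(common)})
    return pd.DataFrame(rows)


@dataclass
class FilterReport:
    """Bookkeeping for one gene's full filter chain."""

    gene: str
    q_cutoff: float
    n_input: int
    n_after_detection: int
    n_after_contaminants: int
    removed_replicates: list[str] = field(default_factory=list)
    regulated: pd.DataFrame | None = None


def run_filter_chain(
    quant: pd.DataFrame,
    metadata: pd.DataFrame,
    q_values: pd.DataFrame,
    gene: str,
    shrnas: list[str],
    scrambled_group: str = "scrambled",
    alpha: float = 0.05,
    cv_threshold: float = 0.12,
    deviation_factor: float = 10.0,
    contaminant_patterns: tuple[str, ...] = DEFAULT_CONTAMINANT_PATTERNS,
) -> FilterReport:
    """The full pipelined filter order for one knockdown experiment."""
    cutoff = q_threshold(metadata)
    thresholded = apply_q_threshold(quant, q_values, cutoff)
    meta, removed = remove_outlier_replicates(
        metadata, cv_threshold, deviation_factor
    )
    thresholded = thresholded[
        ["description"] + meta["sample"].tolist()
        if "description" in thresholded.columns
        else meta["sample"].tolist()
    ]
    detected = detection_filter(thresholded, meta)
    clean = remove_contaminants(detected, contaminant_patterns)
    diffs = [
        shrna_differential(clean, meta, s, scrambled_group) for s in shrnas
    ]
    regulated = concordance_filter(diffs, alpha=alpha)
    return FilterReport(
        gene=gene,
        q_cutoff=cutoff,
        n_input=len(quant),
        n_after_detection=len(detected),
        n_after_contaminants=len(clean),
        removed_replicates=removed,
        regulated=regulated,
    )
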