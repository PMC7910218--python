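"""Gene-level significance testing with a within-plate permutation null.

Per DIV and parameter, the wells of all shRNAs targeting a gene are pooled
and compared with scrambled-control wells by a two-sided Mann-Whitney U
test. The null distribution is built by randomly relabelling wells within
each plate (one relabelling per permutation, shared by all genes and
parameters of that DIV, which preserves the correlation between tests).
Each observed p-value is converted to an empirical p-value against its own
null, and to a family-wise-corrected p-value by the single-step min-P rule:
the observed p is compared with the permutation distribution of the minimum
p across all gene tests.

Empirical p-values use the add-one formula (#{null <= observed} + 1)/(B + 1)
and therefore never reach 0; the single-step min-P corrected p dominates the
per-test empirical p by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .params import TREATMENT_EXPERIMENTAL, TREATMENT_SCRAMBLED
from .qc import parameter_columns

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PermutationConfig:
    """Settings for the permutation screen."""

    n_permutations: int = 10_000
    seed: int = 0
    alternative: str = "two-sided"
    parameters: tuple[str, ...] | None = None   # default: all present
    divs: tuple[int, ...] | None = None         # default: all present
    #: "stratum": min-P family = all genes within one parameter x DIV;
    #: "global": one family across every gene x parameter x DIV test.
    minp_scope: str = "stratum"
    #: "pool-wells" (default) pools every well of every shRNA of a gene;
    #: "per-shrna-mean" tests the 4-5 per-shRNA mean effects instead.
    aggregate: str = "pool-wells"

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.alternative != "two-sided":
            raise ValueError("only the two-sided alternative is supported")
        if self.minp_scope not in ("stratum", "global"):
            raise ValueError("minp_scope must be 'stratum' or 'global'")
        if self.aggregate not in ("pool-wells", "per-shrna-mean"):
            raise ValueError("unknown aggregate mode")


def mannwhitney_p(experimental, control) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact enumeration when the combined sample size is <= 12 and there are
    no ties; the normal approximation with midranks and tie correction
    otherwise. Completely tied data give p = 1.
    """
    x = np.asarray(experimental, dtype=float)
    y = np.asarray(control, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    combined = np.concatenate([x, y])
    if np.ptp(combined) == 0:
        return 1.0
    has_ties = len(np.unique(combined)) < combined.size
    if combined.size <= 12 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def permute_within_plates(
    table: pd.DataFrame,
    seed: int | np.random.Generator,
    label_columns: tuple[str, ...] = ("shrna_id", "gene", "treatment_class"),
) -> pd.DataFrame:
    """Randomly reassign treatment labels among the wells of each plate.

    Label tuples travel together, so per-plate label counts are conserved
    and parameter values are untouched.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    bad = table.groupby("plate").size()
    if (bad < 2).any():
        raise ValueError("every plate needs >= 2 wells to permute")
    out = table.copy()
    cols = [c for c in label_columns if c in table.columns]
    labels = out[cols].to_numpy()
    for _, idx in out.groupby("plate").indices.items():
        perm = rng.permutation(len(idx))
        labels[idx] = labels[idx][perm]
    out[cols] = labels
    return out


def empirical_p(observed_p: float, null_ps) -> float:
    """(#{null <= observed} + 1) / (B + 1); never returns 0."""
    nulls = np.asarray(null_ps, dtype=float)
    if nulls.size == 0:
        raise ValueError("null distribution is empty")
    return float((np.sum(nulls <= observed_p) + 1) / (nulls.size + 1))


def minp_correction(
    observed_ps: dict[str, float], null_ps: pd.DataFrame
) -> dict[str, float]:
    """Single-step min-P family-wise correction.

    ``null_ps`` holds one row per gene and one column per permutation.
    For each permutation the minimum p across genes is taken; a gene's
    corrected p is the add-one tail probability of that minimum falling at
    or below its observed p.
    """
    missing = set(observed_ps) - set(null_ps.index)
    if missing:
        raise ValueError(f"null matrix lacks genes: {sorted(missing)}")
    if null_ps.isna().any().any():
        raise ValueError("null p matrix must be complete")
    minima = null_ps.to_numpy().min(axis=0)
    b = minima.size
    return {
        gene: float((np.sum(minima <= p) + 1) / (b + 1))
        for gene, p in observed_ps.items()
    }


# ---------------------------------------------------------------------------
# Vectorized screen engine
# ---------------------------------------------------------------------------

def _within_plate_label_matrix(
    plates: np.ndarray, base_labels: np.ndarray, n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_wells, n_perm + 1) label matrix; column 0 is the observed labelling,
    the rest are independent within-plate shuffles."""
    n = len(base_labels)
    out = np.empty((n, n_perm + 1), dtype=np.int16)
    out[:, 0] = base_labels
    for plate in np.unique(plates):
        idx = np.flatnonzero(plates == plate)
        keys = rng.random((len(idx), n_perm))
        order = np.argsort(keys, axis=0, kind="stable")
        out[idx, 1:] = base_labels[idx][order]
    return out


def _renormalized_values(
    values: np.ndarray,
    labels: np.ndarray,
    plates: np.ndarray,
    tiebreak: np.ndarray,
) -> np.ndarray:
    """Per-column plate renormalization against the column's scrambled wells.

    The per-plate scrambled median is part of the analysis pipeline, so it
    must be recomputed under every permuted labelling: the observed
    labelling (whose scrambled wells are anchored at median 0 by the
    original normalization) is otherwise not exchangeable with permuted
    labellings and the permutation null is miscalibrated. A fixed per-well
    tie-break perturbation, orders of magnitude below the data scale,
    resolves the exact-zero ties the median subtraction creates.
    """
    out = np.repeat(values[:, None], labels.shape[1], axis=1)
    scram = labels == -1
    for plate in np.unique(plates):
        idx = np.flatnonzero(plates == plate)
        sub = np.where(scram[idx], values[idx, None], np.nan)
        med = np.nanmedian(sub, axis=0)
        out[idx] -= med
    return out + tiebreak[:, None]


def _mwu_p_matrix(
    values: np.ndarray, labels: np.ndarray, n_genes: int,
    plates: np.ndarray, tiebreak: np.ndarray,
) -> np.ndarray:
    """Normal-approximation two-sided MWU p for every gene x permutation.

    Each gene group is compared with the scrambled group (label -1) after
    per-column plate renormalization; scrambled-below-pair counts are
    accumulated in per-column sorted order. Continuity-corrected, matching
    the asymptotic two-sided test on tie-free data.
    """
    zb = _renormalized_values(values, labels, plates, tiebreak)
    order = np.argsort(zb, axis=0, kind="stable")
    ls = np.take_along_axis(labels, order, axis=0)
    scram = ls == -1
    n2 = int(scram[:, 0].sum())
    below = np.cumsum(scram, axis=0) - scram
    lm = np.where(ls >= 0, ls, n_genes).astype(np.int64)
    ncol = labels.shape[1]
    cols = np.broadcast_to(np.arange(ncol, dtype=np.int64), ls.shape)
    flat = lm * ncol + cols
    u1 = np.bincount(
        flat.ravel(), weights=below.ravel(),
        minlength=(n_genes + 1) * ncol,
    ).reshape(n_genes + 1, ncol)[:n_genes]
    n1 = np.bincount(
        np.where(labels[:, 0] >= 0, labels[:, 0], n_genes),
        minlength=n_genes + 1,
    )[:n_genes].astype(float)

    with np.errstate(divide="ignore", invalid="ignore"):
        mu = n1[:, None] * n2 / 2.0
        sigma = np.sqrt(n1[:, None] * n2 * (n1[:, None] + n2 + 1) / 12.0)
        z = (np.abs(u1 - mu) - 0.5) / sigma
        p = np.minimum(2.0 * stats.norm.sf(z), 1.0)
    p[n1 == 0, :] = np.nan
    if n2 == 0:
        p[:] = np.nan
    return p


def run_gene_screen(
    table: pd.DataFrame, config: PermutationConfig = PermutationConfig()
) -> pd.DataFrame:
    """Run the full permutation screen on a normalized well table.

    Returns one row per gene x parameter x DIV with the observed MWU p,
    the empirical permutation p, and the min-P family-wise corrected p.
    Genes without wells at a DIV are reported with missing p-values.
    """
    params = list(config.parameters or parameter_columns(table))
    divs = list(config.divs or sorted(table["div"].unique()))
    genes = sorted(
        g for g in table.loc[
            table["treatment_class"] == TREATMENT_EXPERIMENTAL, "gene"
        ].unique() if g
    )
    if not genes:
        return pd.DataFrame(
            columns=["gene", "parameter", "div", "p_obs", "p_emp", "p_fwer",
                     "n_exp", "n_ctrl"]
        )
    if not (table["treatment_class"] == TREATMENT_SCRAMBLED).any():
        raise ValueError("table has no scrambled control wells")

    rng = np.random.default_rng(config.seed)
    b = config.n_permutations
    gene_index = {g: i for i, g in enumerate(genes)}
    records: list[dict] = []
    global_null: list[np.ndarray] = []
    global_obs: list[tuple[int, str, int, float]] = []

    for div in divs:
        mask = (table["div"] == div) & table["treatment_class"].isin(
            (TREATMENT_SCRAMBLED, TREATMENT_EXPERIMENTAL)
        )
        sub = table.loc[mask]
        if config.aggregate == "per-shrna-mean":
            pmat_by_param = _per_shrna_mean_pmat(sub, genes, params, b, rng)
        else:
            pmat_by_param = _pool_wells_pmat(sub, genes, gene_index, params, b, rng)

        for param, (pmat, n1, n2) in pmat_by_param.items():
            obs = pmat[:, 0]
            nulls = pmat[:, 1:]
            valid = ~np.isnan(obs)
            emp = np.full(len(genes), np.nan)
            emp[valid] = (
                np.sum(nulls[valid] <= obs[valid, None], axis=1) + 1
            ) / (b + 1)
            if config.minp_scope == "stratum":
                if valid.any():
                    minima = np.nanmin(nulls[valid], axis=0)
                    fwer = np.full(len(genes), np.nan)
                    fwer[valid] = (
                        np.sum(minima[None, :] <= obs[valid, None], axis=1) + 1
                    ) / (b + 1)
                else:
                    fwer = np.full(len(genes), np.nan)
                for gi, gene in enumerate(genes):
                    records.append({
                        "gene": gene, "parameter": param, "div": div,
                        "p_obs": obs[gi], "p_emp": emp[gi], "p_fwer": fwer[gi],
                        "n_exp": int(n1[gi]), "n_ctrl": int(n2),
                    })
            else:
                global_null.append(nulls)
                for gi, gene in enumerate(genes):
                    records.append({
                        "gene": gene, "parameter": param, "div": div,
                        "p_obs": obs[gi], "p_emp": emp[gi], "p_fwer": np.nan,
                        "n_exp": int(n1[gi]), "n_ctrl": int(n2),
                    })

    result = pd.DataFrame(records)
    if config.minp_scope == "global" and global_null:
        stacked = np.vstack(global_null)
        minima = np.nanmin(stacked, axis=0)
        obs = result["p_obs"].to_numpy()
        fwer = np.full(len(obs), np.nan)
        ok = ~np.isnan(obs)
        fwer[ok] = (np.sum(minima[None, :] <= obs[ok, None], axis=1) + 1) / (b + 1)
        result["p_fwer"] = fwer
    return result


def _pool_wells_pmat(sub, genes, gene_index, params, b, rng):
    """p matrices for the default pooled-well test, one shared label shuffle
    per permutation across all parameters of the stratum."""
    use = sub.dropna(subset=params)
    if len(use) < len(sub):
        logger.warning(
            "dropping %d wells with missing parameter values", len(sub) - len(use)
        )
    labels = np.array([
        gene_index.get(g, -1) if c == TREATMENT_EXPERIMENTAL else -1
        for g, c in zip(use["gene"], use["treatment_class"])
    ], dtype=np.int16)
    is_scrambled = (use["treatment_class"] == TREATMENT_SCRAMBLED).to_numpy()
    base = labels.copy()
    base[is_scrambled] = -1
    # experimental wells of unlisted genes would collide with scrambled; keep
    # only listed genes and scrambled wells in the permutation pool
    keep = is_scrambled | np.array([
        c == TREATMENT_EXPERIMENTAL and g in gene_index
        for g, c in zip(use["gene"], use["treatment_class"])
    ])
    use = use.loc[keep]
    base = base[keep.to_numpy() if hasattr(keep, "to_numpy") else keep]

    plates = use["plate"].to_numpy()
    lmat = _within_plate_label_matrix(plates, base, b, rng)
    # fixed per-well tie-break, far below the log2 data scale
    tiebreak = rng.uniform(-1e-9, 1e-9, len(use))
    n2 = int(np.sum(base == -1))
    n1 = np.bincount(
        np.where(base >= 0, base, len(genes)), minlength=len(genes) + 1
    )[:len(genes)]
    out = {}
    for param in params:
        v = use[param].to_numpy(dtype=float)
        pmat = _mwu_p_matrix(v, lmat, len(genes), plates, tiebreak)
        out[param] = (pmat, n1, n2)
    return out


def renormalize_to_scrambled(table: pd.DataFrame, params: list[str]) -> pd.DataFrame:
    """Re-centre every plate so its scrambled-labelled wells have median 0.

    Applied after a label permutation so permuted data pass through the
    same normalization step as the observed data.
    """
    out = table.copy()
    scr = out[out["treatment_class"] == TREATMENT_SCRAMBLED]
    med = scr.groupby("plate")[params].median().reindex(out["plate"])
    out[params] = out[params].to_numpy() - med.to_numpy()
    return out


def _per_shrna_mean_pmat(sub, genes, params, b, rng):
    """Alternative aggregation: each gene is represented by its per-shRNA
    mean effects. Generic (slower) permutation loop."""
    out = {}
    perms = [sub] + [
        renormalize_to_scrambled(permute_within_plates(sub, rng), params)
        for _ in range(b)
    ]
    for param in params:
        pmat = np.full((len(genes), b + 1), np.nan)
        n1 = np.zeros(len(genes))
        n2 = 0
        for col, tab in enumerate(perms):
            scr = tab.loc[
                tab["treatment_class"] == TREATMENT_SCRAMBLED, param
            ].dropna()
            if col == 0:
                n2 = len(scr)
            exp = tab[tab["treatment_class"] == TREATMENT_EXPERIMENTAL]
            means = exp.groupby(["gene", "shrna_id"])[param].mean()
            for gi, gene in enumerate(genes):
                if gene not in means.index.get_level_values(0):
                    continue
                vals = means.xs(gene, level=0).dropna()
                if col == 0:
                    n1[gi] = len(vals)
                if len(vals) and len(scr):
                    pmat[gi, col] = mannwhitney_p(vals, scr)
        out[param] = (pmat, n1, n2)
    return out
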