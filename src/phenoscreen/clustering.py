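"""Phenotypic clustering of per-shRNA effect profiles.

shRNAs whose effects never exceed twice the scrambled-control SD (all four
representative parameters, all time points) form the no-effect cluster "0".
The remainder are clustered by average-linkage hierarchical clustering on
1 - Pearson correlation between profiles, the tree is cut at k clusters
(labelled I..V by descending severity), and genes with at least three
shRNAs sharing a non-zero cluster are selected as showing a consistent
phenotype. Co-clustering beyond chance is tested by permutation (default)
or by a chi-square goodness-of-fit on the selected-gene count.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .params import REPRESENTATIVE_PARAMETERS, TREATMENT_EXPERIMENTAL
from .qc import scrambled_sd

logger = logging.getLogger(__name__)

ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X")


@dataclass(frozen=True)
class ProfileSet:
    """Per-shRNA effect vectors plus the DIV handling they were built with."""

    profiles: pd.DataFrame          # index shrna_id, feature columns
    genes: pd.Series                # shrna_id -> gene
    div_mode: str                   # "averaged" | "concatenated"
    per_div: pd.DataFrame           # always param x DIV resolved (for gating)


def build_profiles(
    table: pd.DataFrame,
    div_mode: str = "averaged",
    parameters: tuple[str, ...] = REPRESENTATIVE_PARAMETERS,
) -> ProfileSet:
    """Mean normalized effect per shRNA over the representative parameters.

    ``averaged`` (default) averages across time points giving one feature
    per parameter; ``concatenated`` keeps parameters x DIVs as separate
    features. The per-(parameter, DIV) means are always retained for the
    no-effect gate.
    """
    if div_mode not in ("averaged", "concatenated"):
        raise ValueError("div_mode must be 'averaged' or 'concatenated'")
    exp = table[
        (table["treatment_class"] == TREATMENT_EXPERIMENTAL)
        & (table["shrna_id"] != "")
    ]
    if exp.empty:
        raise ValueError("no experimental wells to profile")
    per_div = exp.groupby(["shrna_id", "div"])[list(parameters)].mean()
    per_div = per_div.unstack("div")  # columns (param, div)
    per_div.columns = [f"{p}@DIV{d}" for p, d in per_div.columns]

    incomplete = per_div.index[per_div.isna().any(axis=1)]
    if len(incomplete):
        logger.warning(
            "excluding %d shRNAs with missing parameter/DIV coverage",
            len(incomplete),
        )
        per_div = per_div.drop(index=incomplete)

    if div_mode == "averaged":
        means = exp.groupby("shrna_id")[list(parameters)].mean()
        profiles = means.loc[per_div.index]
    else:
        profiles = per_div.copy()
    profiles = profiles.sort_index()
    per_div = per_div.sort_index()
    genes = (
        exp.drop_duplicates("shrna_id").set_index("shrna_id")["gene"]
        .loc[profiles.index]
    )
    return ProfileSet(profiles, genes, div_mode, per_div)


def gate_no_effect(
    profile_set: ProfileSet,
    scrambled_sds: pd.DataFrame,
    sd_multiple: float = 2.0,
    parameters: tuple[str, ...] = REPRESENTATIVE_PARAMETERS,
) -> tuple[list[str], list[str]]:
    """Split shRNAs into (gated no-effect "cluster 0", retained).

    An shRNA is gated iff |effect| <= sd_multiple * scrambled SD for every
    representative parameter at every time point. ``scrambled_sds`` is the
    DIV x parameter table from :func:`phenoscreen.qc.scrambled_sd`.
    """
    per_div = profile_set.per_div
    gated, retained = [], []
    thresholds: dict[str, float] = {}
    for col in per_div.columns:
        param, div_tag = col.split("@DIV")
        div = type(scrambled_sds.index[0])(div_tag)
        if div not in scrambled_sds.index or param not in scrambled_sds.columns:
            raise ValueError(f"missing scrambled SD for {param} at DIV {div_tag}")
        sd = scrambled_sds.loc[div, param]
        if pd.isna(sd):
            raise ValueError(f"scrambled SD undefined for {param} at DIV {div_tag}")
        thresholds[col] = sd_multiple * sd
    for shrna, row in per_div.iterrows():
        if all(abs(row[c]) <= thresholds[c] for c in per_div.columns):
            gated.append(shrna)
        else:
            retained.append(shrna)
    return gated, retained


def _severity(profile: np.ndarray) -> float:
    """Mean signed effect; more negative = more severe phenotype."""
    return float(np.mean(profile))


def cluster_shrnas(
    profile_set: ProfileSet,
    retained: list[str],
    k: int = 5,
    linkage_method: str = "average",
) -> pd.DataFrame:
    """Cut an average-linkage tree on 1 - Pearson correlation into k
    clusters, labelled I..k by descending cluster-mean severity.

    Constant (zero-variance) profiles have no defined correlation; they are
    assigned afterwards to the Euclidean-nearest cluster centroid, with a
    warning.
    """
    if k > len(retained):
        raise ValueError(f"k={k} exceeds {len(retained)} retained shRNAs")
    profiles = profile_set.profiles.loc[sorted(retained)]
    x = profiles.to_numpy(dtype=float)
    variable = x.std(axis=1) > 0
    if not variable.any():
        raise ValueError("all retained profiles are constant")
    if (~variable).any():
        logger.warning(
            "%d constant profiles assigned by Euclidean fallback",
            int((~variable).sum()),
        )
    xv = x[variable]
    corr = np.corrcoef(xv)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    z = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
    raw_labels = hierarchy.fcluster(z, t=k, criterion="maxclust")

    labels = np.zeros(len(x), dtype=int)
    labels[variable] = raw_labels
    if (~variable).any():
        centroids = {
            c: xv[raw_labels == c].mean(axis=0) for c in np.unique(raw_labels)
        }
        for i in np.flatnonzero(~variable):
            dists = {c: np.linalg.norm(x[i] - m) for c, m in centroids.items()}
            labels[i] = min(dists, key=dists.get)

    severity = {
        c: _severity(x[labels == c].mean(axis=0))
        for c in np.unique(labels)
    }
    order = sorted(severity, key=lambda c: severity[c])  # most negative first
    roman = {c: ROMAN[i] for i, c in enumerate(order)}
    return pd.DataFrame({
        "shrna_id": profiles.index,
        "gene": profile_set.genes.loc[profiles.index].to_numpy(),
        "cluster": [roman[c] for c in labels],
    })


def assignments_with_gated(
    clustered: pd.DataFrame, gated: list[str], genes: pd.Series
) -> pd.DataFrame:
    """Full assignment table: clustered shRNAs plus cluster-0 rows."""
    zero = pd.DataFrame({
        "shrna_id": gated,
        "gene": genes.loc[gated].to_numpy(),
        "cluster": "0",
    })
    return (
        pd.concat([clustered, zero], ignore_index=True)
        .sort_values("shrna_id")
        .reset_index(drop=True)
    )


def select_genes(
    assignments: pd.DataFrame, min_coclustered: int = 3
) -> dict[str, str]:
    """Genes with >= min_coclustered shRNAs sharing one non-zero cluster;
    returns gene -> consensus cluster label."""
    selected: dict[str, str] = {}
    for gene, grp in assignments.groupby("gene"):
        counts = grp.loc[grp["cluster"] != "0", "cluster"].value_counts()
        if len(counts) and counts.iloc[0] >= min_coclustered:
            selected[gene] = counts.index[0]
    return selected


def _prob_gene_selected(
    n_shrnas: int, probs: np.ndarray, min_coclustered: int
) -> float:
    """P(>= min_coclustered of n multinomial draws share one non-zero
    cluster), by exact enumeration over label assignments."""
    n_classes = len(probs)
    total = 0.0
    for combo in itertools.product(range(n_classes), repeat=n_shrnas):
        counts = np.bincount(combo, minlength=n_classes)
        # class 0 is the gated cluster; co-clustering requires a non-zero one
        if counts[1:].max(initial=0) >= min_coclustered:
            total += float(np.prod(probs[list(combo)]))
    return total


def coclustering_test(
    assignments: pd.DataFrame,
    method: str = "permutation",
    min_coclustered: int = 3,
    n_permutations: int = 2000,
    seed: int = 0,
) -> tuple[float, int]:
    """Significance of shRNAs of the same gene landing in the same cluster.

    Observed statistic: number of selected genes. ``permutation`` shuffles
    the shRNA -> cluster assignment (preserving cluster sizes and each
    gene's shRNA count) and reports the add-one upper-tail p. ``chi2``
    compares the observed selected-gene count with its expectation under
    independent multinomial assignment with probabilities proportional to
    cluster sizes (1-df goodness of fit on selected vs not-selected).

    Returns (p_value, observed_selected_count).
    """
    labels = assignments["cluster"].to_numpy()
    observed = len(select_genes(assignments, min_coclustered))
    populated = pd.unique(labels[labels != "0"])
    if len(populated) < 2 and observed == 0:
        return 1.0, observed

    if method == "permutation":
        rng = np.random.default_rng(seed)
        count = 0
        shuffled = assignments.copy()
        for _ in range(n_permutations):
            shuffled["cluster"] = rng.permutation(labels)
            if len(select_genes(shuffled, min_coclustered)) >= observed:
                count += 1
        return float((count + 1) / (n_permutations + 1)), observed

    if method == "chi2":
        classes = ["0"] + sorted(c for c in pd.unique(labels) if c != "0")
        sizes = np.array([(labels == c).sum() for c in classes], dtype=float)
        probs = sizes / sizes.sum()
        expected = 0.0
        n_genes = 0
        for _, grp in assignments.groupby("gene"):
            expected += _prob_gene_selected(len(grp), probs, min_coclustered)
            n_genes += 1
        if expected <= 0 or expected >= n_genes:
            return 1.0, observed
        chi2 = (
            (observed - expected) ** 2 / expected
            + ((n_genes - observed) - (n_genes - expected)) ** 2
            / (n_genes - expected)
        )
        return float(stats.chi2.sf(chi2, df=1)), observed

    raise ValueError("method must be 'permutation' or 'chi2'")
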