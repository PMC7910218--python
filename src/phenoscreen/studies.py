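"""Calibration and recovery studies over the synthetic generators.

These are the package's headline validation experiments: each function
runs a seeded simulation study end-to-end through the pipeline modules and
returns summary numbers. They back both the acceptance checks in the test
suite and ``scripts/acceptance.py``.

Problem sizes are chosen so each study finishes in minutes on one CPU:
the family-wise error calibration uses single-replicate screens (the
permutation test operates per DIV stratum, so calibration does not depend
on the replicate count), and variance recovery uses a many-level layout
because a variance component estimated from L levels carries relative
sampling error of about sqrt(2/L) — recovery is therefore assessed on the
across-seed mean.
"""

from __future__ import annotations

import collections

import numpy as np
import pandas as pd
from scipy import stats

from . import clustering, enrichment, genetests, proteomics, qc, synthetic, variance
from .params import REPRESENTATIVE_PARAMETERS


def _subseeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


# ---------------------------------------------------------------------------
# Proteomics worked example
# ---------------------------------------------------------------------------

def proteomics_worked_example(seed: int = 0) -> dict:
    """Run the full filter chain on the noise-free knockdown stand-ins.

    The generators plant regulated sets of 94 (Tcf4), 61 (Tbr1) and
    67 (Top3b) proteins with one protein shared by all three experiments;
    the returned counts are whatever the filter chain recovers.
    """
    configs = synthetic.make_worked_example_configs(seed=seed)
    regulated: dict[str, set[str]] = {}
    for gene, cfg in configs.items():
        tables = synthetic.generate_proteomics(cfg)
        report = proteomics.run_filter_chain(
            tables.quant, tables.metadata, tables.q_values,
            gene, list(cfg.genes[gene]),
        )
        regulated[gene] = set(report.regulated.index)
    overlaps = proteomics.set_overlaps(regulated)
    triple = int(
        overlaps.loc[overlaps["sets"].str.count("&") == 2, "size"].iloc[0]
    )
    return {
        "counts": {g: len(r) for g, r in regulated.items()},
        "triple_intersection": triple,
        "pairwise": {
            row["sets"]: int(row["size"])
            for _, row in overlaps.iterrows() if row["sets"].count("&") == 1
        },
    }


# ---------------------------------------------------------------------------
# FWER calibration
# ---------------------------------------------------------------------------

def fwer_calibration(
    n_screens: int = 200,
    n_permutations: int = 500,
    seed: int = 0,
) -> dict:
    """Fraction of genes flagged on fully null screens.

    Each screen carries the full 41-gene layout with no planted effects;
    a gene counts as a false positive when its min-P corrected p falls
    below 0.05 in any parameter x DIV stratum. Returns the mean fraction
    and the binomial Monte Carlo error of that mean.
    """
    fractions = []
    for s in _subseeds(seed, n_screens):
        cfg = synthetic.null_screen_config(
            seed=s, design=synthetic.ScreenDesign(n_replicates=1)
        )
        table = synthetic.generate_screen(cfg)
        normalized = qc.normalize_log2(table)
        res = genetests.run_gene_screen(
            normalized,
            genetests.PermutationConfig(
                n_permutations=n_permutations, seed=s
            ),
        )
        d = res.dropna()
        fractions.append(
            d.loc[d["p_fwer"] < 0.05, "gene"].nunique() / d["gene"].nunique()
        )
    fractions = np.asarray(fractions)
    return {
        "mean_fraction": float(fractions.mean()),
        "mc_error": float(fractions.std(ddof=1) / np.sqrt(len(fractions))),
        "n_screens": n_screens,
    }


# ---------------------------------------------------------------------------
# Variance recovery
# ---------------------------------------------------------------------------

PLANTED_VARIANCES = {
    "batch": 4.0, "plate": 1.0, "edge": 1.0, "div": 1.0, "shrna": 1.0,
    "residual": 2.0,
}


def variance_recovery(n_seeds: int = 20, seed: int = 0) -> dict:
    """Recover planted variance fractions (4,1,1,1,1; residual 2).

    Uses a 12-batch x 8-time-point layout (~3100 wells) so every factor has
    enough levels for the across-seed mean to be informative; returns the
    worst relative error of the mean fraction over components.
    """
    design = synthetic.ScreenDesign(
        genes=tuple(f"G{i:02d}" for i in range(5)),
        n_replicates=12,
        divs=tuple(range(1, 9)),
    )
    sds = dict(
        sd_batch=2.0, sd_plate=1.0, sd_edge=1.0, sd_div=1.0, sd_shrna=1.0,
        sd_residual=float(np.sqrt(2)),
    )
    rows = []
    for s in _subseeds(seed, n_seeds):
        cfg = synthetic.SimulationConfig(
            design=design, div_trend=False, gene_archetypes={},
            dud_fraction=0.0, seed=s, **sds,
        )
        table = synthetic.generate_screen(cfg)
        table["dendrite_length_per_neuron"] = np.log2(
            table["dendrite_length_per_neuron"]
        )
        dec = variance.decompose_variance(table, "dendrite_length_per_neuron")
        rows.append([dec.fractions[c] for c in variance.COMPONENTS])
    mean = np.asarray(rows).mean(axis=0)
    total = sum(PLANTED_VARIANCES.values())
    target = np.array(
        [PLANTED_VARIANCES[c] / total for c in variance.COMPONENTS]
    )
    rel = np.abs(mean - target) / target
    return {
        "mean_fractions": dict(zip(variance.COMPONENTS, mean.tolist())),
        "planted_fractions": dict(zip(variance.COMPONENTS, target.tolist())),
        "max_relative_error": float(rel.max()),
        "n_wells": len(table),
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# Clustering recovery
# ---------------------------------------------------------------------------

def clustering_recovery(n_seeds: int = 20, seed: int = 0, k: int = 5) -> dict:
    """Fraction of planted multi-shRNA effect genes recovered with the
    correct consensus cluster, at shRNA efficacy >= 0.8 and no duds.

    Correctness is judged through the majority mapping from found clusters
    to planted archetypes over the selected genes.
    """
    recovered = total = 0
    for s in _subseeds(seed, n_seeds):
        cfg = synthetic.SimulationConfig(
            seed=s, efficacy_range=(0.8, 1.0), dud_fraction=0.0
        )
        table = synthetic.generate_screen(cfg)
        normalized = qc.normalize_log2(table)
        profiles = clustering.build_profiles(normalized, "averaged")
        sds = qc.scrambled_sd(normalized)[list(REPRESENTATIVE_PARAMETERS)]
        gated, retained = clustering.gate_no_effect(profiles, sds)
        clustered = clustering.cluster_shrnas(profiles, retained, k=k)
        assignments = clustering.assignments_with_gated(
            clustered, gated, profiles.genes
        )
        selected = clustering.select_genes(assignments)
        planted = {
            g: a for g, a in synthetic.planted_effect_genes(cfg).items()
            if g != cfg.design.positive_control_label
        }
        votes: dict[str, collections.Counter] = collections.defaultdict(
            collections.Counter
        )
        for g, c in selected.items():
            if g in planted:
                votes[c][planted[g]] += 1
        mapping = {c: cnt.most_common(1)[0][0] for c, cnt in votes.items()}
        recovered += sum(
            1 for g, a in planted.items()
            if g in selected and mapping.get(selected[g]) == a
        )
        total += len(planted)
    return {"recovery": recovered / total, "n_planted": total,
            "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# Concordance filter study
# ---------------------------------------------------------------------------

def _concordance_sim_config(seed, planted, n_proteins, n_shrnas, noise_sd):
    effects = {
        f"REG_{i:03d}": (1.0 if i % 2 else -1.0) for i in range(planted)
    }
    return synthetic.SyntheticProteomicsConfig(
        n_proteins=n_proteins,
        genes={"G": [f"G_sh{i + 1}" for i in range(n_shrnas)]},
        planted_regulated={"G": effects} if planted else {},
        noise_sd=noise_sd,
        contaminant_fraction=0.0,
        q_tail_fraction=0.0,
        effect_jitter=(1.0, 1.0),
        seed=seed,
    )


def concordance_study(
    n_sims: int = 500,
    n_proteins: int = 40,
    n_shrnas: int = 4,
    noise_sd: float = 0.1,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Recovery of planted concordant proteins and the null false-positive
    rate of the concordance filter, plus an independent Monte Carlo oracle
    for the null rate.

    The oracle simulates the identical probability model directly (normal
    log2 noise, a scrambled group shared by all shRNA contrasts, Welch
    t-tests via scipy) without touching the pipeline code path.
    """
    sub = _subseeds(seed, 2 * n_sims + 1)
    planted_found = planted_total = 0
    fp = fp_total = 0
    for i in range(n_sims):
        cfg = _concordance_sim_config(sub[i], 10, n_proteins, n_shrnas, noise_sd)
        tables = synthetic.generate_proteomics(cfg)
        diffs = [
            proteomics.shrna_differential(
                tables.quant.drop(columns="description"), tables.metadata, sh
            )
            for sh in cfg.genes["G"]
        ]
        reg = set(proteomics.concordance_filter(diffs, alpha=alpha).index)
        truth = set(cfg.planted_regulated["G"])
        planted_found += len(reg & truth)
        planted_total += len(truth)
        fp += len(reg - truth)
        fp_total += n_proteins - len(truth)

        null_cfg = _concordance_sim_config(
            sub[n_sims + i], 0, n_proteins, n_shrnas, noise_sd
        )
        null_tables = synthetic.generate_proteomics(null_cfg)
        null_diffs = [
            proteomics.shrna_differential(
                null_tables.quant.drop(columns="description"),
                null_tables.metadata, sh,
            )
            for sh in null_cfg.genes["G"]
        ]
        fp += len(proteomics.concordance_filter(null_diffs, alpha=alpha).index)
        fp_total += n_proteins

    oracle = _concordance_null_oracle(
        n_draws=20_000, n_shrnas=n_shrnas, alpha=alpha, seed=sub[-1]
    )
    return {
        "recovery": planted_found / planted_total,
        "fp_rate": fp / fp_total,
        "fp_oracle": oracle,
        "n_sims": n_sims,
    }


def _concordance_null_oracle(n_draws, n_shrnas, alpha, seed, n_rep=3):
    """P(null protein passes the concordance rule), by direct simulation
    with scipy's Welch t-test (independent of the pipeline code path)."""
    rng = np.random.default_rng(seed)
    ctrl = rng.normal(size=(n_draws, 1, n_rep))
    kds = rng.normal(size=(n_draws, n_shrnas, n_rep))
    p = stats.ttest_ind(kds, ctrl, axis=-1, equal_var=False).pvalue
    fcs = kds.mean(axis=-1) - ctrl.mean(axis=-1)
    signs = np.sign(fcs)
    concordant = (signs == signs[:, :1]).all(axis=1) & (signs[:, 0] != 0)
    any_sig = (p < alpha).any(axis=1)
    hits = int((concordant & any_sig).sum())
    return {"rate": hits / n_draws, "n_draws": n_draws}


# ---------------------------------------------------------------------------
# Enrichment oracles
# ---------------------------------------------------------------------------

def ppi_null_uniformity(
    n_queries: int = 200,
    n_nodes: int = 250,
    density: float = 0.2,
    query_size: int = 30,
    n_null: int = 400,
    seed: int = 0,
) -> dict:
    """KS uniformity of interaction-enrichment p-values on random queries.

    The edge-count statistic is integer-valued and the add-one rule counts
    ties as extreme, so the permutation p is super-uniform by half the tie
    mass; the defaults use a query/graph large enough that tie mass is
    small and a KS check against the uniform is meaningful.
    """
    net, _ = synthetic.generate_network_and_annotations(
        n_nodes, density, [], seed=seed
    )
    g = enrichment.load_network(net, min_score=0.0)
    nodes = sorted(g.nodes)
    rng = np.random.default_rng(seed)
    ps = [
        enrichment.ppi_enrichment(
            g, set(rng.choice(nodes, size=query_size, replace=False)),
            n_null=n_null, seed=int(rng.integers(1 << 30)),
        ).p_value
        for _ in range(n_queries)
    ]
    return {
        "ks_p": float(stats.kstest(ps, "uniform").pvalue),
        "mean_p": float(np.mean(ps)),
    }


def ppi_planted_clique(
    module_size: int = 8,
    n_nodes: int = 300,
    density: float = 0.01,
    n_null: int = 1000,
    seed: int = 0,
) -> dict:
    """Interaction enrichment p of a planted clique on a sparse background."""
    module = [f"M{i}" for i in range(module_size)]
    net, _ = synthetic.generate_network_and_annotations(
        n_nodes, density, module, seed=seed
    )
    g = enrichment.load_network(net, min_score=0.0)
    res = enrichment.ppi_enrichment(g, set(module), n_null=n_null, seed=seed)
    return {"p_value": res.p_value, "floor": 1.0 / (n_null + 1),
            "observed_edges": res.observed}
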