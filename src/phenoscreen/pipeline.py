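"""End-to-end orchestration of the screen analysis workflow.

One config drives: normalization -> parameter correlations -> variance
decomposition -> gene-level permutation tests -> phenotype clustering and
gene selection -> (optionally) proteomics filtering -> (optionally) local
PPI/GO enrichment. Every stage writes a TSV under the output directory, a
manifest records seeds and thresholds, and a markdown summary collects the
headline numbers. The seed propagates to every stochastic stage, so a
rerun with the same config reproduces every output byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import clustering, enrichment, genetests, io, proteomics, qc, variance
from .params import REPRESENTATIVE_PARAMETERS

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    well_table: str
    output_dir: str
    seed: int = 0
    # QC / normalization
    low_count_quantile: float = 0.1
    excess_fraction: float = 0.5
    # permutation testing
    n_permutations: int = 10_000
    minp_scope: str = "stratum"
    aggregate: str = "pool-wells"
    # clustering
    k: int = 5
    min_coclustered: int = 3
    div_mode: str = "averaged"
    sd_multiple: float = 2.0
    # proteomics (optional): gene -> {quant, metadata, q_values, shrnas}
    proteomics_inputs: dict = field(default_factory=dict)
    alpha: float = 0.05
    cv_threshold: float = 0.12
    # enrichment (optional)
    network: str | None = None
    annotations: str | None = None
    min_score: float = 0.7
    max_first_shell: int = 10
    n_null: int = 2000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; returns the manifest dictionary."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": [],
        "thresholds": {
            "low_count_quantile": config.low_count_quantile,
            "excess_fraction": config.excess_fraction,
            "n_permutations": config.n_permutations,
            "k": config.k,
            "min_coclustered": config.min_coclustered,
            "sd_multiple": config.sd_multiple,
            "alpha": config.alpha,
            "cv_threshold": config.cv_threshold,
            "min_score": config.min_score,
            "max_first_shell": config.max_first_shell,
        },
    }
    summary: list[str] = ["# Screen analysis summary", ""]

    def stage(name):
        manifest["stages"].append({"name": name, "seed": config.seed})

    try:
        table = io.read_well_table(config.well_table)
        flagged = qc.detect_outlier_plates(
            table, config.low_count_quantile, config.excess_fraction
        )
        if flagged:
            table = table[~table["plate"].isin(flagged)]
        normalized = qc.normalize_log2(table)
        io.write_well_table(normalized, out / "normalized.tsv")
        stage("normalize")
        summary += [
            f"- wells analysed: {len(normalized)}; outlier plates removed: "
            f"{sorted(flagged) if flagged else 'none'}",
        ]
    except Exception as exc:
        raise PipelineStageError("normalize", exc) from exc

    try:
        corr = qc.parameter_correlations(normalized)
        io.write_tsv(corr, out / "parameter_correlations.tsv", index=True)
        stage("correlations")
    except Exception as exc:
        raise PipelineStageError("correlations", exc) from exc

    try:
        decomp = variance.decompose_all(
            normalized, qc.parameter_columns(normalized)
        )
        io.write_tsv(decomp, out / "variance_components.tsv")
        stage("variance")
    except Exception as exc:
        raise PipelineStageError("variance", exc) from exc

    try:
        perm_cfg = genetests.PermutationConfig(
            n_permutations=config.n_permutations,
            seed=config.seed,
            minp_scope=config.minp_scope,
            aggregate=config.aggregate,
        )
        gene_results = genetests.run_gene_screen(normalized, perm_cfg)
        io.write_tsv(gene_results, out / "gene_tests.tsv")
        stage("gene_tests")
        n_hits = int(
            (gene_results["p_fwer"] < 0.05).groupby(
                gene_results["gene"]
            ).any().sum()
        )
        summary.append(
            f"- genes with min-P corrected p < 0.05 in any stratum: {n_hits}"
        )
    except Exception as exc:
        raise PipelineStageError("gene_tests", exc) from exc

    try:
        profiles = clustering.build_profiles(normalized, config.div_mode)
        sds = qc.scrambled_sd(normalized)
        gated, retained = clustering.gate_no_effect(
            profiles, sds[list(REPRESENTATIVE_PARAMETERS)],
            sd_multiple=config.sd_multiple,
        )
        clustered = clustering.cluster_shrnas(profiles, retained, k=config.k)
        assignments = clustering.assignments_with_gated(
            clustered, gated, profiles.genes
        )
        io.write_tsv(
            profiles.profiles.reset_index(), out / "phenotype_profiles.tsv"
        )
        io.write_tsv(assignments, out / "cluster_assignments.tsv")
        selected = clustering.select_genes(assignments, config.min_coclustered)
        io.write_tsv(
            pd.DataFrame(
                sorted(selected.items()), columns=["gene", "consensus_cluster"]
            ),
            out / "selected_genes.tsv",
        )
        p_cocluster, observed = clustering.coclustering_test(
            assignments, min_coclustered=config.min_coclustered,
            seed=config.seed,
        )
        stage("clustering")
        summary += [
            f"- shRNAs gated to the no-effect cluster: {len(gated)} of "
            f"{len(gated) + len(retained)}",
            f"- genes with >= {config.min_coclustered} co-clustered shRNAs: "
            f"{len(selected)} (permutation p = {p_cocluster:.4g})",
        ]
    except Exception as exc:
        raise PipelineStageError("clustering", exc) from exc

    regulated_sets: dict[str, set[str]] = {}
    if config.proteomics_inputs:
        try:
            for gene, paths in config.proteomics_inputs.items():
                quant, meta = io.read_protein_quant(
                    paths["quant"], paths["metadata"]
                )
                qvals = pd.read_csv(paths["q_values"], sep="\t", index_col=0)
                report = proteomics.run_filter_chain(
                    quant, meta, qvals, gene, paths["shrnas"],
                    alpha=config.alpha, cv_threshold=config.cv_threshold,
                )
                io.write_tsv(
                    report.regulated.reset_index(),
                    out / f"regulated_{gene}.tsv",
                )
                regulated_sets[gene] = set(report.regulated.index)
                summary.append(
                    f"- {gene}: {len(report.regulated)} regulated proteins "
                    f"(q cutoff {report.q_cutoff:.2g})"
                )
            if len(regulated_sets) >= 2:
                overlaps = proteomics.set_overlaps(regulated_sets)
                io.write_tsv(overlaps, out / "regulated_overlaps.tsv")
            stage("proteomics")
        except Exception as exc:
            raise PipelineStageError("proteomics", exc) from exc

    if config.network and regulated_sets:
        try:
            net = enrichment.load_network(
                io.read_network(config.network), config.min_score
            )
            rows = []
            for gene, reg in regulated_sets.items():
                mapped = reg & set(net.nodes)
                if len(mapped) < 2:
                    continue
                expanded, added = enrichment.add_first_shell(
                    net, mapped, config.max_first_shell
                )
                res = enrichment.ppi_enrichment(
                    net, expanded, n_null=config.n_null, seed=config.seed
                )
                rows.append({
                    "set": gene, "observed_edges": res.observed,
                    "expected_edges": res.expected, "p_value": res.p_value,
                    "added_first_shell": ",".join(added),
                })
            if rows:
                io.write_tsv(pd.DataFrame(rows), out / "ppi_enrichment.tsv")
            if config.annotations:
                gmt = io.read_gmt(config.annotations)
                background = set(net.nodes) | set().union(*gmt.values())
                combined = set().union(*regulated_sets.values()) & background
                if combined:
                    go = enrichment.go_enrichment(gmt, combined, background)
                    io.write_tsv(go, out / "go_enrichment.tsv")
            stage("enrichment")
        except Exception as exc:
            raise PipelineStageError("enrichment", exc) from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out / "summary.md").write_text("\n".join(summary) + "\n")
    return manifest
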