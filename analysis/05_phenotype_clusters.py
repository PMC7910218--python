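#!/usr/bin/env python
"""Phenotypic clustering of shRNA effect profiles and gene selection.

Gates shRNAs whose effects never exceed twice the scrambled SD on the
four representative parameters at any time point (no-effect cluster 0),
clusters the rest by average-linkage on 1 - Pearson correlation (k=5),
selects genes with >= 3 shRNAs sharing a cluster, and tests whether that
co-clustering exceeds chance. Writes cluster_assignments.tsv and
selected_genes.tsv under results/screen/.
"""

import argparse
from pathlib import Path

import pandas as pd

from phenoscreen import clustering, io, qc
from phenoscreen.params import REPRESENTATIVE_PARAMETERS


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--in-dir", type=Path, default=Path("results/screen"))
    parser.add_argument("--k", type=int, default=5)
    parser.add_argument("--min-coclustered", type=int, default=3)
    parser.add_argument("--div-mode", default="averaged",
                        choices=["averaged", "concatenated"])
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    table = io.read_well_table(args.in_dir / "normalized.tsv")
    profiles = clustering.build_profiles(table, args.div_mode)
    sds = qc.scrambled_sd(table)[list(REPRESENTATIVE_PARAMETERS)]
    gated, retained = clustering.gate_no_effect(profiles, sds)
    clustered = clustering.cluster_shrnas(profiles, retained, k=args.k)
    assignments = clustering.assignments_with_gated(
        clustered, gated, profiles.genes
    )
    io.write_tsv(assignments, args.in_dir / "cluster_assignments.tsv")

    selected = clustering.select_genes(assignments, args.min_coclustered)
    io.write_tsv(
        pd.DataFrame(sorted(selected.items()),
                     columns=["gene", "consensus_cluster"]),
        args.in_dir / "selected_genes.tsv",
    )
    p_perm, observed = clustering.coclustering_test(
        assignments, min_coclustered=args.min_coclustered, seed=args.seed
    )
    p_chi2, _ = clustering.coclustering_test(
        assignments, method="chi2", min_coclustered=args.min_coclustered
    )

    sizes = assignments["cluster"].value_counts().sort_index()
    print("cluster sizes:", sizes.to_dict())
    print(f"genes with >= {args.min_coclustered} co-clustered shRNAs: "
          f"{observed}")
    print(f"co-clustering significance: permutation p = {p_perm:.2g}, "
          f"chi-square p = {p_chi2:.2g}")
    for gene, label in sorted(selected.items()):
        print(f"  {gene}: cluster {label}")


if __name__ == "__main__":
    main()
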