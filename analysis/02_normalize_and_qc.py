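#!/usr/bin/env python
"""Plate QC and normalization of the simulated screen.

Flags outlier plates with excess low-cell-count wells, normalizes every
parameter per plate against the scrambled-control median (log2), and
reports the Spearman correlation structure of the 10 parameters — the
nuclear/dendritic/synaptic blocks, with staining intensities running
opposite to puncta densities. Writes results/screen/normalized.tsv and
parameter_correlations.tsv.
"""

import argparse
from pathlib import Path

from phenoscreen import io, qc


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--in-dir", type=Path, default=Path("results/screen"))
    args = parser.parse_args()

    table = io.read_well_table(args.in_dir / "wells.tsv")
    flagged = qc.detect_outlier_plates(table)
    if flagged:
        print(f"removed outlier plates: {sorted(flagged)}")
        table = table[~table["plate"].isin(flagged)]
    normalized = qc.normalize_log2(table)
    io.write_well_table(normalized, args.in_dir / "normalized.tsv")

    corr = qc.parameter_correlations(normalized)
    io.write_tsv(corr, args.in_dir / "parameter_correlations.tsv", index=True)
    pre = corr.loc["presynaptic_intensity", "presynaptic_puncta_density"]
    post = corr.loc["postsynaptic_intensity", "postsynaptic_puncta_density"]
    print(f"normalized {len(normalized)} wells")
    print("synaptic intensity vs density correlations: "
          f"presynaptic {pre:+.2f}, postsynaptic {post:+.2f} "
          "(intensities fall as puncta densities rise)")


if __name__ == "__main__":
    main()
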