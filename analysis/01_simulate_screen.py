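#!/usr/bin/env python
"""Generate the synthetic high-content screen analysed by the later steps.

Simulates 41 candidate-gene knockdowns (4-5 shRNAs each, 3 culture
replicates, fixation at DIV 7/14/21) on 96-well plates using only the
inner 60 wells, with scrambled/positive/untreated control wells per plate,
batch/plate/edge/DIV variance components and planted phenotype archetypes.
Writes the well-level table to results/screen/wells.tsv.
"""

import argparse
from pathlib import Path

from phenoscreen import io, synthetic


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out-dir", type=Path, default=Path("results/screen"))
    args = parser.parse_args()

    cfg = synthetic.SimulationConfig(seed=args.seed)
    table = synthetic.generate_screen(cfg)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    io.write_well_table(table, args.out_dir / "wells.tsv")

    planted = synthetic.planted_effect_genes(cfg)
    print(f"simulated {len(table)} wells on {table['plate'].nunique()} plates")
    print(f"planted effect genes ({len(planted)}): "
          + ", ".join(f"{g}({a})" for g, a in sorted(planted.items())))


if __name__ == "__main__":
    main()
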