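#!/usr/bin/env python
"""Generate the synthetic paired-omics study.

Emulates the structure of the follicle-cell experiment: LP control, WT-AKT1
and five activating-variant lines; label-free proteome (3-4 replicates),
phosphopeptides and bulk transcriptome (3 replicates); planted DEPs, DEGs
(with ~20% proteome-transcriptome concordance), differentially
phosphorylated peptides whose parent proteins do not change, gain- and
loss-of-function gene subsets, two TF-target modules and one PPI hub.

Writes the dataset plus its ground-truth ledger under results/synthetic_data/.
"""

import argparse
import sys
from pathlib import Path

from phosphodiff import simulate as sim

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "synthetic_data")
    args = ap.parse_args()

    cfg = sim.SimulationConfig(seed=args.seed)
    bundle = sim.simulate(cfg)
    sim.write_dataset(bundle, args.out, overwrite=True)

    t = bundle.truth
    print(f"dataset written to {args.out}")
    print(f"  proteins {cfg.n_proteins} ({len(t.dep_directions)} planted DEPs), "
          f"transcripts {cfg.n_transcripts} ({len(t.deg_directions)} planted DEGs)")
    print(f"  phosphopeptides {cfg.n_phosphopeptides} "
          f"({len(t.dphospho_ids)} planted differentially phosphorylated)")
    print(f"  GoF genes {len(t.gof_gene_ids)}, LoF genes {len(t.lof_gene_ids)}, "
          f"TFs {cfg.n_tfs} in 2 modules, PPI hub {t.hub_id}")


if __name__ == "__main__":
    sys.exit(main())
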