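#!/usr/bin/env python
"""Differential proteins and genes.

Runs the stand-in differential test for the pooled all-mutants-vs-WT
contrast (proteome and transcriptome), the WT-vs-LP and LP-vs-WT contrasts,
and each mutant against WT; applies the adjusted-p < 0.05 and |log2FC| >=
0.585 (fold change 1.5) filters; and intersects the per-mutant DEG sets.

Writes one contrast table per comparison plus filter reports under results/.
"""

import argparse
import json
import sys
from pathlib import Path

from phosphodiff import diffexpr, io as pio, simulate as sim
from phosphodiff.model import Thresholds

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "synthetic_data")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    b = sim.read_dataset(args.data)
    th = Thresholds()
    mutants = [c for c in b.design_rna.conditions if c not in ("LP", "WT")]

    def run(table, design, test, ref, name):
        res = diffexpr.standin_test(
            table, design, diffexpr.contrast_samples(design, test, ref), th)
        pio.write_contrast(res, args.out / f"{name}.tsv")
        return res, diffexpr.apply_thresholds(res, th)

    _, dep_rep = run(b.proteins, b.design_protein, mutants, "WT", "protein_allmut_vs_wt")
    _, dep_lp = run(b.proteins, b.design_protein, "WT", "LP", "protein_wt_vs_lp")
    _, deg_rep = run(b.transcripts, b.design_rna, mutants, "WT", "rna_allmut_vs_wt")
    run(b.transcripts, b.design_rna, "LP", "WT", "rna_lp_vs_wt")

    per_mut = {}
    for m in mutants:
        _, rep = run(b.transcripts, b.design_rna, m, "WT", f"rna_{m}_vs_wt")
        per_mut[m] = set(rep.passing)
    common, overlap = diffexpr.intersect_degs(per_mut)
    overlap.to_csv(args.out / "deg_overlap_matrix.tsv", sep="\t")
    (args.out / "common_degs.txt").write_text("\n".join(sorted(common)) + "\n")

    report = {"dep_allmut_vs_wt": dep_rep.to_dict(),
              "dep_wt_vs_lp": dep_lp.to_dict(),
              "deg_allmut_vs_wt": deg_rep.to_dict(),
              "deg_per_mutant": {m: len(s) for m, s in per_mut.items()},
              "n_common_degs": len(common)}
    (args.out / "de_report.json").write_text(json.dumps(report, indent=1))

    truth_dep = set(b.truth.dep_directions)
    truth_deg = set(b.truth.deg_directions)
    print(f"allmut vs WT: {dep_rep.n_significant} significant proteins, "
          f"{dep_rep.n_pass_fc} pass the fold-change filter "
          f"({dep_rep.n_up} up / {dep_rep.n_down} down); "
          f"planted-DEP recovery "
          f"{len(set(dep_rep.passing) & truth_dep) / len(truth_dep):.2f}")
    print(f"allmut vs WT: {deg_rep.n_pass_fc} DEGs "
          f"({deg_rep.n_up} up / {deg_rep.n_down} down); "
          f"planted-DEG recovery "
          f"{len(set(deg_rep.passing) & truth_deg) / len(truth_deg):.2f}")
    print(f"{len(common)} DEGs common to all {len(per_mut)} mutant contrasts")


if __name__ == "__main__":
    sys.exit(main())
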