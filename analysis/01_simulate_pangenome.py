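"""Simulate the study's pan-genome inputs: a PAV truth matrix for 109
accessions (1000 genes split 719/61/208/12 across core/softcore/shell/cloud)
and the matching bimodal coverage-breadth table (present genes ~0.95 breadth,
absent ~0.05).  Writes the PAV matrix, coverage table and truth labels that
the later steps consume."""

import argparse
import json
from pathlib import Path

from panpav import io, simdata


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/sim"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = simdata.SimPavConfig(seed=args.seed)
    pav, truth = simdata.sim_pav(cfg)
    cov = simdata.sim_coverage(pav, 0.95, 0.05, seed=args.seed)

    io.write_pav_tsv(pav, args.out / "pav_truth.tsv")
    io.write_coverage_tsv(cov, args.out / "coverage.tsv")
    (args.out / "truth.json").write_text(
        json.dumps({"gene_class": truth.gene_class, "gene_freq": truth.gene_freq})
    )
    print(f"simulated {pav.shape[0]} genes x {pav.shape[1]} samples (seed {args.seed})")
    print(f"wrote pav_truth.tsv, coverage.tsv, truth.json under {args.out}")


if __name__ == "__main__":
    main()
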