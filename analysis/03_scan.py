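#!/usr/bin/env python
"""QTL scans of the fitted parameters.

Marker regression of the fitted k_o and S_0 vectors across all 192 markers
— single scan plus additive and interactive covariate scans on the focal
(chromosome II) marker — with 1000-permutation genome-wide thresholds and
Bayes credible intervals for significant chromosomes. This is the
parameter-resolved mapping step: a locus acting on oocyte production shows
up in the k_o scan, a sperm-count locus in the S_0 scan.
"""

import argparse
from pathlib import Path

import pandas as pd

from spermlimit.cli import _cmd_scan
from spermlimit.config import RunConfig
from spermlimit import io as slio
from spermlimit.qtl import ScanResult, bayes_credible_interval


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/run"))
    args = ap.parse_args()

    cfg = RunConfig(seed=args.seed, out_dir=str(args.out))
    run = Path(cfg.out_dir)
    _cmd_scan(cfg, run)

    for name in ("k_o", "s_0"):
        frame = pd.read_csv(run / f"scan_{name}.csv")
        thr = slio.read_json(run / f"thresholds_{name}.json")
        scan = ScanResult(frame=frame, n=0, primary_column="lod_single")
        print(f"{name} scan:")
        for col, rec in thr.items():
            sig = frame[frame[col] >= rec["threshold"]]
            chroms = sorted(set(sig["chrom"]))
            print(f"  {col}: threshold {rec['threshold']:.2f} "
                  f"({rec['n_perm']} perms), significant chromosomes {chroms}")
            for c in chroms:
                lo, hi = bayes_credible_interval(scan, c, column=col)
                print(f"    {c}: 95% Bayes interval [{lo:g}, {hi:g}] cM")


if __name__ == "__main__":
    main()
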