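#!/usr/bin/env python
"""Full-scale CCS benchmark driver (run on locally downloaded structures).

This reproduces the large-scale accuracy/convergence benchmarks on real data,
which require inputs that must be fetched separately (they are not bundled):

* an *experimental* benchmark: a directory of protonated PDB structures plus a
  CSV table ``pdb_id,ccs_exp,gas`` of measured ion-mobility CCS values — the
  driver predicts each structure's CCS and reports the mean absolute percent
  error and R² against experiment;
* a *convergence* benchmark: the same directory, where the driver reports the
  mean over structures of the run-to-run CCS standard deviation at chosen
  rotation counts.

Example:

    python scripts/fullscale_benchmark.py accuracy \
        --pdb-dir downloads/experimental --ccs-table ccs_values.csv \
        --rotations 300 --seed 1 --out accuracy.csv

    python scripts/fullscale_benchmark.py convergence \
        --pdb-dir downloads/evaluation_set --rotations 100 300 \
        --reps 100 --seed 1 --out convergence.csv

Note: predicted CCS values track the hydrogens present in the input files;
structures must be pre-protonated for accuracy comparable to measured values.
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from parcs import compute_ccs, convergence_profile, read_pdb
from parcs.core import subseeds


def run_accuracy(pdb_dir: Path, ccs_table: Path, rotations: int, seed: int,
                 out: Path) -> pd.DataFrame:
    table = pd.read_csv(ccs_table)
    required = {"pdb_id", "ccs_exp"}
    if not required <= set(table.columns):
        raise SystemExit(f"{ccs_table}: need columns {sorted(required)}")
    if "gas" not in table.columns:
        table["gas"] = "nitrogen"
    seeds = subseeds(seed, len(table))
    rows = []
    for (_, rec), s in zip(table.iterrows(), seeds):
        path = pdb_dir / f"{rec.pdb_id}.pdb"
        model = read_pdb(path)
        pred = compute_ccs(model, gas=rec.gas, rotations=rotations, seed=s).ccs
        rows.append({"pdb_id": rec.pdb_id, "gas": rec.gas,
                     "ccs_exp": rec.ccs_exp, "ccs_pred": pred,
                     "pct_error": 100.0 * abs(pred - rec.ccs_exp) / rec.ccs_exp})
    df = pd.DataFrame(rows)
    r2 = np.corrcoef(df.ccs_exp, df.ccs_pred)[0, 1] ** 2 if len(df) > 1 else np.nan
    df.to_csv(out, index=False)
    print(f"n={len(df)} mean_pct_error={df.pct_error.mean():.2f} R2={r2:.4f}")
    return df


def run_convergence(pdb_dir: Path, rotations: list[int], reps: int, seed: int,
                    out: Path) -> pd.DataFrame:
    paths = sorted(pdb_dir.glob("*.pdb"))
    if not paths:
        raise SystemExit(f"no PDB files in {pdb_dir}")
    seeds = subseeds(seed, len(paths))
    frames = []
    for path, s in zip(paths, seeds):
        model = read_pdb(path)
        prof = convergence_profile(model, rotation_counts=rotations,
                                   reps=reps, seed=s)
        prof.insert(0, "pdb_id", path.stem)
        frames.append(prof)
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(out, index=False)
    for count, grp in df.groupby("rotations"):
        print(f"rotations={count} mean_std={grp.std_ccs.mean():.2f} A^2")
    return df


def build_parser() -> argparse.ArgumentParser:
    parser = argparse.ArgumentParser(description=__doc__.splitlines()[0])
    sub = parser.add_subparsers(dest="command", required=True)
    a = sub.add_parser("accuracy", help="predicted vs measured CCS")
    a.add_argument("--pdb-dir", type=Path, required=True)
    a.add_argument("--ccs-table", type=Path, required=True)
    a.add_argument("--rotations", type=int, default=300)
    a.add_argument("--seed", type=int, default=1)
    a.add_argument("--out", type=Path, default=Path("accuracy.csv"))
    c = sub.add_parser("convergence", help="run-to-run spread vs rotation count")
    c.add_argument("--pdb-dir", type=Path, required=True)
    c.add_argument("--rotations", type=int, nargs="+", default=[100, 300])
    c.add_argument("--reps", type=int, default=100)
    c.add_argument("--seed", type=int, default=1)
    c.add_argument("--out", type=Path, default=Path("convergence.csv"))
    return parser


def main(argv=None) -> int:
    args = build_parser().parse_args(argv)
    if args.command == "accuracy":
        run_accuracy(args.pdb_dir, args.ccs_table, args.rotations, args.seed,
                     args.out)
    else:
        run_convergence(args.pdb_dir, args.rotations, args.reps, args.seed,
                        args.out)
    return 0


if __name__ == "__main__":
    sys.exit(main())
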