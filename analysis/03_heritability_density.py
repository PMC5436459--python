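"""REML heritability of both growth traits from the full marker panel, and
the heritability-vs-marker-density curve.

The study's protocol draws 50 random subsets per density; pass --reps 50 to
reproduce it exactly (a few minutes); the default 10 keeps this driver quick.
"""

import argparse
from pathlib import Path

import pandas as pd

import shrimpgs as sg
from shrimpgs import genio

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--out", type=Path, default=Path("results"))
parser.add_argument("--reps", type=int, default=10)
parser.add_argument("--seed", type=int, default=1)
args = parser.parse_args()

genotypes = genio.read_dosage_tsv(args.data / "genotypes_qc.tsv")
phenotypes = genio.read_phenotypes(args.data / "phenotypes.tsv")
grm = sg.grm_vanraden(genotypes)

densities = [d for d in (50, 100, 200, 400, 800, 1600, 3200, 6400, 12800, 20000)
             if d <= genotypes.n_markers]
rows = []
for trait in ("body_weight", "body_length"):
    vc = sg.reml_h2(grm, phenotypes, trait)
    print(f"{trait}: full-marker h2 = {vc.h2:.3f} "
          f"(V_A = {vc.V_A:.3f}, V_E = {vc.V_E:.3f})")
    curve = sg.h2_density_curve(
        genotypes, phenotypes, trait, densities=densities,
        n_reps=args.reps, seed=args.seed,
    )
    rows.append(curve.rows.assign(trait=trait))
    summary = curve.summary()
    print(summary.to_string(index=False))

out = genio.ensure_dir(args.out)
pd.concat(rows, ignore_index=True).to_csv(
    out / "h2_density.tsv", sep="\t", index=False
)
print(f"written to {out / 'h2_density.tsv'}")
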