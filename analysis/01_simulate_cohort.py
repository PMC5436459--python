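"""Simulate the study cohort: 200 shrimp from 13 full-sib families.

Generates founder lines, gene-drops 13 families, samples 200 individuals,
simulates body weight / body length at the study's heritabilities and
phenotype scale, injects ~3% missing genotype calls, and writes the raw
dataset under results/data/.
"""

import argparse
from pathlib import Path

import numpy as np

import shrimpgs as sg
from shrimpgs import genio

parser = argparse.ArgumentParser()
parser.add_argument("--n-markers", type=int, default=24_000,
                    help="pre-QC marker count (QC trims this to ~23k)")
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/data"))
args = parser.parse_args()

genotypes, phenotypes, families = sg.simulate_dataset(
    n_markers=args.n_markers, missing_rate_spec=0.03, seed=args.seed
)
out = genio.ensure_dir(args.out)
genio.write_dosage_tsv(genotypes, out / "genotypes_raw.tsv")
genio.write_phenotypes(phenotypes, out / "phenotypes.tsv")
genio.write_families(families, out / "families.tsv")

t = phenotypes.table
print(f"cohort: {genotypes.n_individuals} individuals x {genotypes.n_markers} markers")
print(f"families: {families.n_families}, lines: {families.table['line_index'].nunique()}")
print(f"body weight  (g): mean {t.body_weight.mean():.2f}, SD {t.body_weight.std():.2f}")
print(f"body length (mm): mean {t.body_length.mean():.2f}, SD {t.body_length.std():.2f}")
print(f"missing call rate: {np.isnan(genotypes.dosages).mean():.3f}")
print(f"written to {out}")
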