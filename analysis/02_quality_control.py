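"""SNP quality control: drop markers with >5% missing calls or MAF < 0.05,
then mean-impute the remaining missing genotypes."""

import argparse
from pathlib import Path

from shrimpgs import genio, qc

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
args = parser.parse_args()

genotypes = genio.read_dosage_tsv(args.data / "genotypes_raw.tsv")
filtered, report = qc.qc_filter(genotypes, max_missing=0.05, min_maf=0.05)
imputed = qc.impute_missing(filtered, method="mean_dosage")

genio.write_dosage_tsv(filtered, args.data / "genotypes_filtered.tsv")
genio.write_dosage_tsv(imputed, args.data / "genotypes_qc.tsv")
report.per_marker.to_csv(args.data / "qc_report.tsv", sep="\t", index=False)

print(f"markers in: {report.n_markers_in}")
print(f"removed by missing rate > 5%: {report.n_removed_missing}")
print(f"removed by MAF < 0.05:        {report.n_removed_maf}")
print(f"markers out: {report.n_markers_out}")
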