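"""Population stratification: IBS kinship, classical MDS on 1 - IBS, and
k-means subpopulations at the silhouette-chosen k."""

import argparse
from pathlib import Path

import pandas as pd

import shrimpgs as sg
from shrimpgs import genio

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--out", type=Path, default=Path("results"))
parser.add_argument("--seed", type=int, default=1)
args = parser.parse_args()

# IBS uses the filtered (pre-imputation, integral) calls
genotypes = genio.read_dosage_tsv(args.data / "genotypes_filtered.tsv")
ibs = sg.ibs_matrix(genotypes)
coords = sg.classical_mds(ibs, n_dims=3)
k, diagnostics = sg.choose_k(coords, seed=args.seed)
assignment = sg.kmeans_clusters(coords, k, seed=args.seed)

out = genio.ensure_dir(args.out)
genio.write_matrix_tsv(ibs.individual_ids, ibs.values, out / "ibs.tsv")
pd.DataFrame(
    {"individual_id": coords.individual_ids,
     "dim1": coords.coordinates[:, 0],
     "dim2": coords.coordinates[:, 1],
     "dim3": coords.coordinates[:, 2]}
).to_csv(out / "mds_coordinates.tsv", sep="\t", index=False)
pd.DataFrame(
    {"individual_id": assignment.individual_ids,
     "subpopulation": assignment.labels}
).to_csv(out / "subpopulations.tsv", sep="\t", index=False)
diagnostics.to_csv(out / "choose_k.tsv", sep="\t", index=False)

sizes = sorted(assignment.cluster_sizes.values(), reverse=True)
print(f"silhouette-chosen k = {k}")
print(f"subpopulation sizes (largest first): {sizes}")
print(f"subpopulations larger than 30 (DIST-eligible): {sum(s > 30 for s in sizes)}")
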