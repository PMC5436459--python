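"""Marker quality control and imputation.

Markers are filtered on per-marker missing rate (> 5% removed) and minor
allele frequency (< 0.05 removed), both computed in a single pass over the
input matrix; individuals are never removed. Remaining missing calls are
filled by mean-dosage or within-family-mean imputation, which may leave
fractional dosages in [0, 2].
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import FamilyStructure, GenotypeMatrix, QCReport


def allele_frequencies(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker alternate-allele frequency, MAF and missing rate.

    The alternate-allele frequency is the dosage sum over twice the number of
    non-missing calls; markers with no calls at all get ``nan`` frequencies
    (flagged, not fatal).
    """
    d = genotypes.dosages
    n = d.shape[0]
    called = (~np.isnan(d)).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(d, axis=0) / (2.0 * called)
    p = np.where(called == 0, np.nan, p)
    maf = np.minimum(p, 1.0 - p)
    return pd.DataFrame(
        {
            "marker_id": genotypes.marker_ids,
            "alt_freq": p,
            "maf": maf,
            "missing_rate": 1.0 - called / n,
        }
    )


def qc_filter(
    genotypes: GenotypeMatrix,
    max_missing: float = 0.05,
    min_maf: float = 0.05,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove markers with missing rate > ``max_missing`` or MAF < ``min_maf``.

    Both removal conditions are strict, so a marker at exactly 5% missingness
    and MAF exactly 0.05 is kept. Both statistics come from the same input
    pass (not sequentially recomputed). A marker failing both filters is
    counted once, under the missing-rate filter.
    """
    for name, t in (("max_missing", max_missing), ("min_maf", min_maf)):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {t}")
    freqs = allele_frequencies(genotypes)
    # strict inequalities with a float-rounding guard so exact-boundary
    # markers (e.g. 10/200 missing) are kept
    eps = 1e-12
    fail_missing = freqs["missing_rate"].to_numpy() > max_missing + eps
    maf = freqs["maf"].to_numpy()
    fail_maf = np.isnan(maf) | (maf < min_maf - eps)
    keep = ~(fail_missing | fail_maf)
    report = QCReport(
        n_markers_in=genotypes.n_markers,
        n_removed_missing=int(fail_missing.sum()),
        n_removed_maf=int((fail_maf & ~fail_missing).sum()),
        n_markers_out=int(keep.sum()),
        per_marker=freqs.assign(kept=keep),
    )
    return genotypes.subset_markers(np.flatnonzero(keep)), report


def impute_missing(
    genotypes: GenotypeMatrix,
    method: str = "mean_dosage",
    families: FamilyStructure | None = None,
) -> GenotypeMatrix:
    """Fill missing calls; observed calls are never altered.

    ``mean_dosage`` uses the marker's mean over called individuals.
    ``family_mean`` uses the within-full-sib-family marker mean when at least
    two family members are called, falling back to the global marker mean.
    """
    d = genotypes.dosages.copy()
    missing = np.isnan(d)
    if not missing.any():
        return genotypes
    col_called = (~missing).sum(axis=0)
    if (col_called == 0).any():
        bad = [genotypes.marker_ids[j] for j in np.flatnonzero(col_called == 0)[:5]]
        raise ValueError(f"markers with no calls must be filtered first: {bad}")
    col_mean = np.nanmean(d, axis=0)

    if method == "mean_dosage":
        d[missing] = np.broadcast_to(col_mean, d.shape)[missing]
    elif method == "family_mean":
        if families is None:
            raise ValueError("family_mean imputation needs a FamilyStructure")
        fam_of = families.family_of()
        fam = np.array([fam_of[i] for i in genotypes.individual_ids])
        for f in np.unique(fam):
            rows = fam == f
            block = d[rows, :]
            blk_missing = np.isnan(block)
            n_called = (~blk_missing).sum(axis=0)
            with np.errstate(invalid="ignore"):
                fam_mean = np.nanmean(block, axis=0)
            fill = np.where(n_called >= 2, fam_mean, col_mean)
            block[blk_missing] = np.broadcast_to(fill, block.shape)[blk_missing]
            d[rows, :] = block
    else:
        raise ValueError(f"unknown imputation method {method!r}")

    out = GenotypeMatrix(
        individual_ids=genotypes.individual_ids,
        marker_ids=genotypes.marker_ids,
        dosages=d,
        chrom=genotypes.chrom,
        pos=genotypes.pos,
        ref=genotypes.ref,
        alt=genotypes.alt,
    )
    return out
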