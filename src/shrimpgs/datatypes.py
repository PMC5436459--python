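"""Core in-memory containers shared across the package.

Genotypes are additive dosages: the count of the alternate (B) allele, so
0/1/2 encode AA/AB/BB. Missing calls are ``numpy.nan`` — never 0 — and after
imputation entries may be fractional in [0, 2].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class GenotypeMatrix:
    """Individuals x markers dosage matrix.

    Parameters
    ----------
    individual_ids : sequence of str
        Unique sample identifiers (rows).
    marker_ids : sequence of str
        Unique marker identifiers (columns).
    dosages : ndarray of shape (n_individuals, n_markers), float
        Alternate-allele dosages in {0, 1, 2} (or fractional in [0, 2] after
        imputation); ``nan`` marks a missing call.
    chrom, pos : optional per-marker chromosome name and 1-based position.
    ref, alt : optional per-marker allele labels.
    """

    individual_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.individual_ids = list(self.individual_ids)
        self.marker_ids = list(self.marker_ids)
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if len(self.individual_ids) != n:
            raise ValueError(
                f"{len(self.individual_ids)} individual ids for {n} dosage rows"
            )
        if len(self.marker_ids) != m:
            raise ValueError(f"{len(self.marker_ids)} marker ids for {m} dosage columns")
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual ids")
        if len(set(self.marker_ids)) != m:
            raise ValueError("duplicate marker ids")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and (vals.min() < 0 or vals.max() > 2):
            raise ValueError("dosages must lie in [0, 2] or be nan")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def is_complete(self) -> bool:
        return not np.isnan(self.dosages).any()

    def require_complete(self, what: str = "operation") -> None:
        if not self.is_complete():
            raise ValueError(f"{what} requires a complete genotype matrix (impute first)")

    def subset_markers(self, index: Sequence[int]) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        return replace(
            self,
            marker_ids=[self.marker_ids[i] for i in index],
            dosages=self.dosages[:, index],
            chrom=None if self.chrom is None else np.asarray(self.chrom)[index],
            pos=None if self.pos is None else np.asarray(self.pos)[index],
            ref=None if self.ref is None else np.asarray(self.ref)[index],
            alt=None if self.alt is None else np.asarray(self.alt)[index],
        )

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.individual_ids)}
        try:
            rows = [lookup[s] for s in ids]
        except KeyError as exc:
            raise KeyError(f"unknown individual id {exc.args[0]!r}") from None
        return replace(
            self,
            individual_ids=list(ids),
            dosages=self.dosages[rows, :],
        )


@dataclass
class PhenotypeTable:
    """Per-individual growth-trait records.

    ``body_weight`` is in grams, ``body_length`` in millimetres. The optional
    ``true_*`` columns carry the simulated genetic values (testing only; absent
    for real data).
    """

    table: pd.DataFrame

    TRAITS = ("body_weight", "body_length")

    def __post_init__(self) -> None:
        if "individual_id" not in self.table.columns:
            raise ValueError("phenotype table needs an individual_id column")
        if self.table["individual_id"].duplicated().any():
            raise ValueError("duplicate individual ids in phenotype table")
        for trait in self.TRAITS:
            if trait in self.table.columns:
                v = self.table[trait].dropna()
                if (v <= 0).any():
                    raise ValueError(f"{trait} values must be strictly positive")
        self.table = self.table.reset_index(drop=True)

    @property
    def individual_ids(self) -> list[str]:
        return self.table["individual_id"].astype(str).tolist()

    def trait_vector(self, trait: str, ids: Sequence[str] | None = None) -> np.ndarray:
        """Trait values aligned to ``ids`` (default: table order)."""
        if trait not in self.table.columns:
            raise KeyError(f"trait {trait!r} not in phenotype table")
        s = self.table.set_index("individual_id")[trait]
        if ids is not None:
            s = s.reindex(list(ids))
            if s.isna().any():
                missing = s.index[s.isna()].tolist()[:5]
                raise KeyError(f"no phenotype for individuals {missing}")
        return s.to_numpy(dtype=float)


@dataclass
class FamilyStructure:
    """Pedigree of a single full-sib cohort: each individual has exactly one
    sire and one dam; full sibs share both."""

    table: pd.DataFrame  # columns: individual_id, sire_id, dam_id, family_index

    def __post_init__(self) -> None:
        required = {"individual_id", "sire_id", "dam_id", "family_index"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"family table missing columns {sorted(missing)}")
        if self.table["individual_id"].duplicated().any():
            raise ValueError("duplicate individual ids in family table")
        self.table = self.table.reset_index(drop=True)

    @property
    def individual_ids(self) -> list[str]:
        return self.table["individual_id"].astype(str).tolist()

    @property
    def n_families(self) -> int:
        return int(self.table["family_index"].nunique())

    def family_of(self) -> dict[str, int]:
        return dict(
            zip(self.table["individual_id"].astype(str), self.table["family_index"])
        )


@dataclass
class QCReport:
    """Bookkeeping for one marker-QC pass (individuals are never removed)."""

    n_markers_in: int
    n_removed_missing: int
    n_removed_maf: int
    n_markers_out: int
    per_marker: pd.DataFrame = field(repr=False)  # marker_id, missing_rate, maf, kept

    def __post_init__(self) -> None:
        removed = self.n_markers_in - self.n_markers_out
        # markers failing both filters are attributed to the missing-rate filter
        if self.n_removed_missing + self.n_removed_maf != removed:
            raise ValueError("QC report counts are inconsistent")
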