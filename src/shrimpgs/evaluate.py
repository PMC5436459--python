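"""Prediction-accuracy statistic and the cross-validation protocols.

Accuracy is the Pearson correlation between out-of-sample GEBVs and observed
phenotypes, divided by the square root of the full-marker heritability of
the trait. Three protocols probe it: plain five-fold CV, five-fold CV on
random marker-density subsets, and the DIST/RAND designs where the
validation set is either a genetically distant subpopulation or a
stratified random sample across all subpopulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, PhenotypeTable
from .predict import McmcConfig, fit_model, predict_gebv
from .structure import SubpopulationAssignment


@dataclass
class CvDesign:
    """One train/validation split; training and validation are disjoint."""

    name: str
    training_ids: list[str]
    validation_ids: list[str]

    def __post_init__(self) -> None:
        if set(self.training_ids) & set(self.validation_ids):
            raise ValueError(f"design {self.name}: training and validation overlap")


def accuracy(gebv: np.ndarray, phenotypes: np.ndarray, h2_full: float) -> float:
    """cor(GEBV, y) / sqrt(h2_full); the sign is preserved (may be negative)."""
    gebv = np.asarray(gebv, dtype=float)
    y = np.asarray(phenotypes, dtype=float)
    if gebv.size != y.size or gebv.size < 3:
        raise ValueError("need at least 3 aligned (GEBV, phenotype) pairs")
    if not 0.0 < h2_full <= 1.0:
        raise ValueError("h2_full must be in (0, 1]")
    if np.std(gebv) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in GEBV or phenotypes")
    return float(np.corrcoef(gebv, y)[0, 1] / np.sqrt(h2_full))


def make_folds(ids: list[str], n_folds: int, rng: np.random.Generator) -> list[list[str]]:
    """Random partition into folds with sizes differing by at most one."""
    perm = rng.permutation(len(ids))
    return [[ids[i] for i in chunk] for chunk in np.array_split(perm, n_folds)]


def five_fold_cv(
    genotypes: GenotypeMatrix,
    phenotypes,
    model: str,
    h2_full: float,
    trait: str | None = None,
    seed: int | np.random.SeedSequence = 0,
    mcmc: McmcConfig | None = None,
    variance_ratio: float | None = None,
) -> tuple[pd.DataFrame, float]:
    """Pooled out-of-fold accuracy over a random five-fold partition.

    Each individual is validated exactly once, so each has exactly one
    out-of-fold GEBV; the accuracy is one correlation over the pooled GEBVs.
    Returns the per-individual GEBV table (with fold index) and the accuracy.
    """
    if genotypes.n_individuals < 10:
        raise ValueError("need at least 10 individuals for five-fold CV")
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    rng = np.random.default_rng(ss)
    if isinstance(phenotypes, PhenotypeTable):
        y_all = phenotypes.trait_vector(trait, ids=genotypes.individual_ids)
    else:
        y_all = np.asarray(phenotypes, dtype=float)
    ids = list(genotypes.individual_ids)
    y_of = dict(zip(ids, y_all))
    folds = make_folds(ids, 5, rng)
    records = []
    for f, fold in enumerate(folds, start=1):
        train_ids = [i for i in ids if i not in set(fold)]
        try:
            effects = fit_model(
                model,
                genotypes.subset_individuals(train_ids),
                np.array([y_of[i] for i in train_ids]),
                config=mcmc,
                variance_ratio=variance_ratio,
            )
            pred = predict_gebv(effects, genotypes.subset_individuals(fold))
        except Exception as exc:
            raise RuntimeError(f"model {model} failed in fold {f}: {exc}") from exc
        for i, v in zip(fold, pred.gebv):
            records.append({"individual_id": i, "fold": f, "gebv": v})
    table = pd.DataFrame(records)
    aligned = table.set_index("individual_id").loc[ids]
    acc = accuracy(aligned["gebv"].to_numpy(), y_all, h2_full)
    return table, acc


def density_cv(
    genotypes: GenotypeMatrix,
    phenotypes,
    models: list[str],
    densities: list[int],
    h2_full: float,
    trait: str | None = None,
    n_reps: int = 50,
    seed: int | np.random.SeedSequence = 0,
    mcmc: McmcConfig | None = None,
    include_full_reference: bool = True,
) -> pd.DataFrame:
    """Five-fold CV accuracy across random marker-density subsets.

    For each density, ``n_reps`` uniform marker subsets are drawn; the same
    subset (and CV partition) is shared across models within a replicate so
    model comparisons are paired. The full marker set is run once as the
    reference when ``include_full_reference`` is set.
    """
    m = genotypes.n_markers
    if densities and max(densities) > m:
        raise ValueError(f"density {max(densities)} exceeds marker count {m}")
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    work = [(d, rep) for d in densities for rep in range(1, n_reps + 1)]
    if include_full_reference:
        work.append((m, 0))  # replicate 0 marks the full-set reference
    streams = ss.spawn(len(work))
    rows = []
    for (density, rep), stream in zip(work, streams):
        sub_ss, cv_ss = stream.spawn(2)
        rng = np.random.default_rng(sub_ss)
        if density == m:
            subset = np.arange(m)
        else:
            subset = np.sort(rng.choice(m, size=density, replace=False))
        sub_geno = genotypes.subset_markers(subset)
        for model in models:
            _, acc = five_fold_cv(
                sub_geno, phenotypes, model, h2_full,
                trait=trait, seed=cv_ss, mcmc=mcmc,
            )
            rows.append(
                {"model": model, "density": density, "replicate": rep, "accuracy": acc}
            )
    return pd.DataFrame(rows)


def dist_rand_designs(
    assignment: SubpopulationAssignment,
    min_validation_size: int = 30,
    train_fraction: float = 0.8,
    n_rand: int = 3,
    seed: int | np.random.SeedSequence = 0,
) -> list[CvDesign]:
    """Build the relatedness designs from a subpopulation assignment.

    DIST designs: one per subpopulation with more than ``min_validation_size``
    members — that subpopulation validates, all others train. RAND designs:
    ``n_rand`` stratified splits taking ``train_fraction`` of every
    subpopulation for training and the rest for validation.
    """
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    rng = np.random.default_rng(ss)
    designs: list[CvDesign] = []
    sizes = assignment.cluster_sizes
    big = [lab for lab in sorted(sizes) if sizes[lab] > min_validation_size]
    if not big:
        import warnings

        warnings.warn("no subpopulation exceeds min_validation_size; DIST list empty")
    all_ids = list(assignment.individual_ids)
    for i, lab in enumerate(big, start=1):
        val = assignment.members(lab)
        train = [x for x in all_ids if x not in set(val)]
        designs.append(CvDesign(name=f"DIST{i}", training_ids=train, validation_ids=val))
    for r in range(1, n_rand + 1):
        train: list[str] = []
        val: list[str] = []
        for lab in sorted(sizes):
            members = assignment.members(lab)
            n_train = int(len(members) * train_fraction)
            picked = rng.choice(len(members), size=n_train, replace=False)
            picked_set = set(int(p) for p in picked)
            for j, x in enumerate(members):
                (train if j in picked_set else val).append(x)
        designs.append(CvDesign(name=f"RAND{r}", training_ids=train, validation_ids=val))
    return designs


def run_designs(
    genotypes: GenotypeMatrix,
    phenotypes,
    models: list[str],
    designs: list[CvDesign],
    h2_full: float,
    trait: str | None = None,
    mcmc: McmcConfig | None = None,
) -> pd.DataFrame:
    """Train each model on each design's training set; validate on its
    validation set, using the full supplied marker set."""
    if isinstance(phenotypes, PhenotypeTable):
        y_of = dict(
            zip(
                genotypes.individual_ids,
                phenotypes.trait_vector(trait, ids=genotypes.individual_ids),
            )
        )
    else:
        y_of = dict(zip(genotypes.individual_ids, np.asarray(phenotypes, dtype=float)))
    rows = []
    for design in designs:
        y_val = np.array([y_of[i] for i in design.validation_ids])
        if np.std(y_val) == 0:
            raise ValueError(
                f"design {design.name}: validation set has zero phenotype variance"
            )
        y_train = np.array([y_of[i] for i in design.training_ids])
        train_geno = genotypes.subset_individuals(design.training_ids)
        val_geno = genotypes.subset_individuals(design.validation_ids)
        for model in models:
            effects = fit_model(model, train_geno, y_train, config=mcmc)
            pred = predict_gebv(effects, val_geno)
            rows.append(
                {
                    "design": design.name,
                    "group": design.name.rstrip("0123456789"),
                    "model": model,
                    "n_train": len(design.training_ids),
                    "n_validation": len(design.validation_ids),
                    "accuracy": accuracy(pred.gebv, y_val, h2_full),
                }
            )
    return pd.DataFrame(rows)
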