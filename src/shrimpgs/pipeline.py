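"""End-to-end reproducible pipeline: simulate -> QC -> kinship -> h2 ->
structure -> cross-validation designs -> result tables.

One master seed deterministically derives every stage seed, so rerunning
with the same config reproduces every output file bit for bit (MCMC chains
included). Each run directory carries a manifest with the config hash, the
stage seeds and the SHA-256 of every file written.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genio, qc
from .evaluate import density_cv, dist_rand_designs, run_designs
from .kinship import grm_vanraden, ibs_matrix
from .predict import MODEL_NAMES, McmcConfig
from .simulate import simulate_dataset
from .structure import choose_k, classical_mds, kmeans_clusters
from .varcomp import h2_density_curve, reml_h2

TRAITS = ("body_weight", "body_length")


@dataclass
class PipelineConfig:
    """All generator, QC, model and design parameters plus the master seed."""

    seed: int = 0
    # generator
    n_families: int = 13
    offspring_per_family: int = 50
    n_sampled: int = 200
    n_markers: int = 23_049
    ld_decay: float = 0.05
    maf_low: float = 0.05
    maf_high: float = 0.5
    missing_rate: float = 0.03
    n_qtl: int | None = None  # None: default 500-QTL architectures
    # QC
    max_missing: float = 0.05
    min_maf: float = 0.05
    impute_method: str = "mean_dosage"
    # heritability / CV
    densities: list[int] = field(
        default_factory=lambda: [50, 100, 200, 400, 800, 1600, 3200, 6400, 12800, 20000]
    )
    h2_reps: int = 50
    cv_reps: int = 50
    models: list[str] = field(default_factory=lambda: ["rrblup", "bayesa", "bl"])
    mcmc_iters: int = 40_000
    mcmc_burn_in: int = 10_000
    # structure / designs
    k: int | str = "auto"
    min_validation_size: int = 30
    train_fraction: float = 0.8
    n_rand: int = 3

    def __post_init__(self) -> None:
        for model in self.models:
            if model not in MODEL_NAMES:
                raise ValueError(f"unknown model {model!r}; expected {MODEL_NAMES}")
        if self.mcmc_burn_in >= self.mcmc_iters:
            raise ValueError("mcmc_burn_in must be smaller than mcmc_iters")
        if self.k != "auto" and (not isinstance(self.k, int) or self.k < 2):
            raise ValueError("k must be 'auto' or an integer >= 2")

    @classmethod
    def fast(cls, seed: int = 0) -> "PipelineConfig":
        """Desk-scale profile: 2,000 markers, short chains, few replicates."""
        return cls(
            seed=seed,
            n_markers=2_000,
            densities=[50, 200, 800],
            h2_reps=5,
            cv_reps=3,
            mcmc_iters=4_000,
            mcmc_burn_in=1_000,
        )

    @classmethod
    def full_scale(cls, seed: int = 0) -> "PipelineConfig":
        """Full-scale profile mirroring the study conditions."""
        return cls(seed=seed)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Execute all stages in order and return the run directory.

    Any stage failure halts with the stage name; files written by earlier
    stages are left in place.
    """
    out = genio.ensure_dir(outdir)
    config.to_yaml(out / "config.yaml")
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = dict(
        zip(("simulate", "h2", "structure", "cv", "designs"), ss.spawn(5))
    )
    manifest: dict = {
        "config_hash": config.digest(),
        "stage_seeds": {
            name: int(seq.generate_state(1)[0]) for name, seq in stage_seeds.items()
        },
        "stages": {},
        "files": {},
    }
    log_lines: list[str] = []
    mcmc = McmcConfig(n_iter=config.mcmc_iters, burn_in=config.mcmc_burn_in)

    def log(stage: str, msg: str) -> None:
        log_lines.append(f"[{stage}] {msg}")

    def record(stage: str, t0: float, **summary) -> None:
        manifest["stages"][stage] = {
            "wall_seconds": round(time.perf_counter() - t0, 3),
            **summary,
        }

    stage = "simulate"
    try:
        t0 = time.perf_counter()
        genotypes, phenotypes, families = simulate_dataset(
            n_families=config.n_families,
            offspring_per_family=config.offspring_per_family,
            n_sampled=config.n_sampled,
            n_markers=config.n_markers,
            maf_spec=(config.maf_low, config.maf_high),
            ld_decay=config.ld_decay,
            n_qtl=config.n_qtl,
            missing_rate_spec=config.missing_rate or None,
            seed=stage_seeds["simulate"],
        )
        genio.write_dosage_tsv(genotypes, out / "genotypes_raw.tsv")
        genio.write_phenotypes(phenotypes, out / "phenotypes.tsv")
        genio.write_families(families, out / "families.tsv")
        record(stage, t0, n_individuals=genotypes.n_individuals,
               n_markers=genotypes.n_markers)
        log(stage, f"{genotypes.n_individuals} individuals x {genotypes.n_markers} markers")

        stage = "qc"
        t0 = time.perf_counter()
        filtered, report = qc.qc_filter(
            genotypes, max_missing=config.max_missing, min_maf=config.min_maf
        )
        imputed = qc.impute_missing(filtered, method=config.impute_method,
                                    families=families)
        report.per_marker.to_csv(out / "qc_report.tsv", sep="\t", index=False)
        genio.write_dosage_tsv(imputed, out / "genotypes_qc.tsv")
        record(stage, t0, n_markers_in=report.n_markers_in,
               n_markers_out=report.n_markers_out)
        log(stage, f"kept {report.n_markers_out}/{report.n_markers_in} markers")

        stage = "kinship"
        t0 = time.perf_counter()
        grm = grm_vanraden(imputed)
        ibs = ibs_matrix(filtered)
        genio.write_matrix_tsv(grm.individual_ids, grm.values, out / "grm.tsv")
        genio.write_matrix_tsv(ibs.individual_ids, ibs.values, out / "ibs.tsv")
        record(stage, t0, mean_diag=float(np.diag(grm.values).mean()))

        stage = "h2"
        t0 = time.perf_counter()
        h2_full = {}
        for trait in TRAITS:
            vc = reml_h2(grm, phenotypes, trait)
            h2_full[trait] = vc.h2
        densities = [d for d in config.densities if d <= imputed.n_markers]
        curves = []
        for i, trait in enumerate(TRAITS):
            curve = h2_density_curve(
                imputed, phenotypes, trait,
                densities=densities, n_reps=config.h2_reps,
                seed=stage_seeds["h2"].spawn(2)[i],
            )
            curves.append(curve.rows.assign(trait=trait))
        h2_rows = pd.concat(curves, ignore_index=True)
        h2_rows.to_csv(out / "h2_density.tsv", sep="\t", index=False)
        record(stage, t0, **{f"h2_{t}": round(v, 4) for t, v in h2_full.items()})
        log(stage, f"full-marker h2: {h2_full}")

        stage = "structure"
        t0 = time.perf_counter()
        coords = classical_mds(ibs, n_dims=3)
        if config.k == "auto":
            k, diag = choose_k(coords, seed=int(stage_seeds["structure"].generate_state(1)[0] % 2**31))
            diag.to_csv(out / "choose_k.tsv", sep="\t", index=False)
        else:
            k = int(config.k)
        assignment = kmeans_clusters(
            coords, k, seed=int(stage_seeds["structure"].generate_state(1)[0] % 2**31)
        )
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
        record(stage, t0, k=k, sizes=assignment.cluster_sizes)
        log(stage, f"k = {k}, sizes {assignment.cluster_sizes}")

        stage = "cv"
        t0 = time.perf_counter()
        if mcmc.n_iter < 40_000 and any(m != "rrblup" for m in config.models):
            log(stage, f"NOTE: MCMC reduced to {mcmc.n_iter}/{mcmc.burn_in} "
                       "iterations (fast profile) — full protocol is 40000/10000")
        cv_tables = []
        for i, trait in enumerate(TRAITS):
            table = density_cv(
                imputed, phenotypes, config.models, densities,
                h2_full[trait], trait=trait, n_reps=config.cv_reps,
                seed=stage_seeds["cv"].spawn(2)[i], mcmc=mcmc,
            )
            cv_tables.append(table.assign(trait=trait))
        cv_rows = pd.concat(cv_tables, ignore_index=True)
        cv_rows.to_csv(out / "accuracy_density.tsv", sep="\t", index=False)
        record(stage, t0, n_rows=len(cv_rows))

        stage = "designs"
        t0 = time.perf_counter()
        designs = dist_rand_designs(
            assignment,
            min_validation_size=config.min_validation_size,
            train_fraction=config.train_fraction,
            n_rand=config.n_rand,
            seed=stage_seeds["designs"],
        )
        design_tables = []
        for trait in TRAITS:
            tbl = run_designs(
                imputed, phenotypes, config.models, designs,
                h2_full[trait], trait=trait, mcmc=mcmc,
            )
            design_tables.append(tbl.assign(trait=trait))
        design_rows = pd.concat(design_tables, ignore_index=True)
        design_rows.to_csv(out / "accuracy_designs.tsv", sep="\t", index=False)
        record(stage, t0, n_designs=len(designs))
    except Exception as exc:
        (out / "log.txt").write_text("\n".join(log_lines) + "\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for path in sorted(out.glob("*.tsv")) + [out / "config.yaml"]:
        manifest["files"][path.name] = _sha256(path)
    manifest["master_seed"] = config.seed
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out / "log.txt").write_text("\n".join(log_lines) + "\n")
    return out
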