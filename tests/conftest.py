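"""Shared fixtures: small synthetic cohorts generated once per session."""

import numpy as np
import pytest

import shrimpgs as sg


@pytest.fixture(scope="session")
def cohort():
    """Complete 200-individual cohort at a small marker panel."""
    genotypes, phenotypes, families = sg.simulate_dataset(n_markers=800, seed=11)
    return genotypes, phenotypes, families


@pytest.fixture(scope="session")
def cohort_missing():
    """Cohort with injected missing calls, for QC tests."""
    genotypes, phenotypes, families = sg.simulate_dataset(
        n_markers=800, missing_rate_spec=0.03, seed=12
    )
    return genotypes, phenotypes, families


@pytest.fixture(scope="session")
def unstructured_founder_genotypes():
    """A panel of mutually unrelated outbred individuals (no LD, one line)."""
    founders = sg.simulate_founders(
        n_sires=30, n_dams=30, n_markers=10_000, ld_decay=0.0, seed=21
    )
    return founders.to_genotypes()


def toy_genotypes(dosages, ids=None, marker_ids=None):
    d = np.asarray(dosages, dtype=float)
    return sg.GenotypeMatrix(
        individual_ids=ids or [f"i{k}" for k in range(d.shape[0])],
        marker_ids=marker_ids or [f"m{k}" for k in range(d.shape[1])],
        dosages=d,
    )
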