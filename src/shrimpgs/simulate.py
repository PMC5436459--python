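"""Synthetic multi-family shrimp population generator.

Emulates the statistical structure of a single cultured cohort: unrelated
founder parents with tunable allele frequencies and background linkage
disequilibrium, 13 full-sib families produced by paired matings, Mendelian
gene-drop with Poisson crossovers on a Morgan-scaled genetic map, and
additive polygenic growth traits (body weight in g, body length in mm)
calibrated to a target narrow-sense heritability and phenotype scale.

Founder haplotypes follow a first-order Markov process along each chromosome:
adjacent markers share a latent uniform with probability exp(-d / ld_decay)
for inter-marker distance d (Morgans), so haplotype correlation decays with
genetic distance and ld_decay = 0 gives linkage equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import FamilyStructure, GenotypeMatrix, PhenotypeTable

# Shrimp-like karyotype: 44 chromosomes of 1 Morgan each.
DEFAULT_N_CHROMOSOMES = 44
DEFAULT_CHROM_LENGTH = 1.0


@dataclass
class GeneticMap:
    """Marker positions in Morgans on named chromosomes."""

    chromosomes: list[tuple[str, float]]  # (name, length in Morgans)
    marker_chrom: np.ndarray  # per-marker chromosome index
    marker_pos: np.ndarray  # per-marker genetic position (Morgans)

    def __post_init__(self) -> None:
        self.marker_chrom = np.asarray(self.marker_chrom, dtype=int)
        self.marker_pos = np.asarray(self.marker_pos, dtype=float)
        if self.marker_chrom.shape != self.marker_pos.shape:
            raise ValueError("marker_chrom and marker_pos must align")
        if (self.marker_pos < 0).any():
            raise ValueError("negative marker positions")
        lengths = np.array([L for _, L in self.chromosomes])
        if (self.marker_pos > lengths[self.marker_chrom]).any():
            raise ValueError("marker position beyond chromosome length")
        for c in range(len(self.chromosomes)):
            pos = self.marker_pos[self.marker_chrom == c]
            if pos.size and (np.diff(pos) < 0).any():
                raise ValueError(f"markers unsorted on chromosome {c}")

    @property
    def n_markers(self) -> int:
        return self.marker_pos.size

    def chromosome_blocks(self):
        """Yield (marker index array, positions, length) per chromosome."""
        for c, (_, length) in enumerate(self.chromosomes):
            idx = np.flatnonzero(self.marker_chrom == c)
            yield idx, self.marker_pos[idx], length

    @classmethod
    def uniform(
        cls,
        n_markers: int,
        n_chromosomes: int = DEFAULT_N_CHROMOSOMES,
        chrom_length: float = DEFAULT_CHROM_LENGTH,
    ) -> "GeneticMap":
        """Markers spread evenly over equal-length chromosomes."""
        if n_markers < 1:
            raise ValueError("need at least one marker")
        chrom = np.arange(n_markers) % n_chromosomes
        order = np.argsort(chrom, kind="stable")
        chrom = chrom[order]
        pos = np.empty(n_markers)
        for c in range(n_chromosomes):
            k = int((chrom == c).sum())
            # evenly spaced, avoiding both chromosome ends
            pos[chrom == c] = (np.arange(k) + 0.5) / k * chrom_length
        return cls(
            chromosomes=[(f"chr{c + 1}", chrom_length) for c in range(n_chromosomes)],
            marker_chrom=chrom,
            marker_pos=pos,
        )


@dataclass
class HaplotypeSet:
    """Phased haplotypes: individual i owns rows 2i and 2i+1."""

    individual_ids: list[str]
    haplotypes: np.ndarray  # (2n, m) 0/1
    gmap: GeneticMap

    def __post_init__(self) -> None:
        if self.haplotypes.shape[0] != 2 * len(self.individual_ids):
            raise ValueError("expected two haplotype rows per individual")

    def haplotype_pair(self, individual_id: str) -> tuple[np.ndarray, np.ndarray]:
        try:
            i = self.individual_ids.index(individual_id)
        except ValueError:
            raise KeyError(f"unknown parent id {individual_id!r}") from None
        return self.haplotypes[2 * i], self.haplotypes[2 * i + 1]

    def to_genotypes(self) -> GenotypeMatrix:
        n = len(self.individual_ids)
        dosages = self.haplotypes[0::2].astype(float) + self.haplotypes[1::2]
        return GenotypeMatrix(
            individual_ids=self.individual_ids,
            marker_ids=[f"M{j + 1:06d}" for j in range(dosages.shape[1])],
            dosages=dosages,
            chrom=np.array(
                [self.gmap.chromosomes[c][0] for c in self.gmap.marker_chrom]
            ),
            pos=np.round(self.gmap.marker_pos * 1_000_000).astype(int) + 1,
        )


@dataclass
class TraitArchitecture:
    """Additive polygenic architecture for one trait.

    Effects are in trait units per copy of the alternate allele; the
    environmental variance is set from the realized genetic variance so that
    V_A / (V_A + V_E) equals ``target_h2``, and the output is affinely mapped
    to the target mean/SD scale.
    """

    trait: str
    n_qtl: int
    target_h2: float
    target_mean: float
    target_sd: float
    qtl_marker_indices: np.ndarray | None = None
    qtl_effects: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_h2 <= 1.0:
            raise ValueError("target_h2 must be in [0, 1]")
        if self.target_sd <= 0:
            raise ValueError("target_sd must be positive")
        if self.n_qtl < 1:
            raise ValueError("need at least one QTL")


# Defaults calibrated to the study population's phenotype scale and
# full-marker heritability estimates.
def default_weight_architecture() -> TraitArchitecture:
    return TraitArchitecture(
        trait="body_weight", n_qtl=500, target_h2=0.321, target_mean=5.56, target_sd=2.16
    )


def default_length_architecture() -> TraitArchitecture:
    return TraitArchitecture(
        trait="body_length", n_qtl=500, target_h2=0.452, target_mean=76.99, target_sd=9.95
    )


def _draw_maf(maf_spec, rng: np.random.Generator, m: int) -> np.ndarray:
    """Resolve a MAF spec (scalar, (low, high) uniform range, or callable)."""
    if callable(maf_spec):
        p = np.asarray(maf_spec(rng, m), dtype=float)
    elif np.isscalar(maf_spec):
        p = np.full(m, float(maf_spec))
    else:
        low, high = maf_spec
        p = rng.uniform(low, high, m)
    if (p <= 0).any() or (p > 0.5).any():
        raise ValueError("minor allele frequencies must lie in (0, 0.5]")
    return p


def simulate_founders(
    n_sires: int,
    n_dams: int,
    n_markers: int,
    gmap: GeneticMap | None = None,
    maf_spec=(0.05, 0.5),
    ld_decay: float = 0.05,
    line_of_founder: np.ndarray | None = None,
    fst: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
) -> HaplotypeSet:
    """Draw phased founder haplotypes marker-by-marker along each chromosome.

    ``ld_decay`` is the correlation length in Morgans: adjacent markers at
    distance d share their latent draw with probability exp(-d / ld_decay),
    so 0 means no LD and larger values mean longer-range LD.

    Founders may be partitioned into divergent commercial lines:
    ``line_of_founder`` assigns a line index to each founder (sires first,
    then dams) and ``fst`` sets the Balding-Nichols divergence of line
    allele frequencies around the base frequencies drawn from ``maf_spec``.
    With one line (or fst = 0) founders are an unstructured panel.
    """
    if n_markers < 1:
        raise ValueError("need at least one marker")
    if gmap is None:
        gmap = GeneticMap.uniform(n_markers)
    if gmap.n_markers != n_markers:
        raise ValueError("map does not cover the requested markers")
    if not 0.0 <= fst < 1.0:
        raise ValueError("fst must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    p_base = _draw_maf(maf_spec, rng, n_markers)
    n_founders = n_sires + n_dams
    if line_of_founder is None:
        line_of_founder = np.zeros(n_founders, dtype=int)
    line_of_founder = np.asarray(line_of_founder, dtype=int)
    if line_of_founder.size != n_founders:
        raise ValueError("line_of_founder must cover every founder")
    lines = np.unique(line_of_founder)
    line_freqs = {}
    for line in lines:
        if fst > 0 and lines.size > 1:
            a = p_base * (1.0 - fst) / fst
            b = (1.0 - p_base) * (1.0 - fst) / fst
            line_freqs[line] = np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4)
        else:
            line_freqs[line] = p_base
    haps = np.empty((2 * n_founders, n_markers), dtype=np.uint8)
    hap_line = np.repeat(line_of_founder, 2)
    for idx, pos, _ in gmap.chromosome_blocks():
        k = idx.size
        if k == 0:
            continue
        d = np.diff(pos)
        if ld_decay > 0:
            r = np.exp(-d / ld_decay)
        else:
            r = (d == 0).astype(float)
        for line in lines:
            rows = np.flatnonzero(hap_line == line)
            u = rng.random((rows.size, k))
            for j in range(1, k):
                keep = rng.random(rows.size) < r[j - 1]
                u[:, j] = np.where(keep, u[:, j - 1], u[:, j])
            haps[np.ix_(rows, idx)] = (u < line_freqs[line][idx]).astype(np.uint8)
    ids = [f"S{i + 1:02d}" for i in range(n_sires)] + [
        f"D{i + 1:02d}" for i in range(n_dams)
    ]
    return HaplotypeSet(individual_ids=ids, haplotypes=haps, gmap=gmap)


def _gamete(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    gmap: GeneticMap,
    rng: np.random.Generator,
) -> np.ndarray:
    """One meiotic product: Poisson-count crossovers at the Morgan scale."""
    out = np.empty(gmap.n_markers, dtype=np.uint8)
    for idx, pos, length in gmap.chromosome_blocks():
        if idx.size == 0:
            continue
        start = rng.integers(2)
        n_xo = rng.poisson(length)
        if n_xo == 0:
            out[idx] = hap_a[idx] if start == 0 else hap_b[idx]
        else:
            xo = np.sort(rng.uniform(0.0, length, n_xo))
            parity = (np.searchsorted(xo, pos, side="right") + start) % 2
            out[idx] = np.where(parity == 0, hap_a[idx], hap_b[idx])
    return out


def make_families(
    founders: HaplotypeSet,
    matings: list[tuple[str, str]],
    offspring_per_family: int = 50,
    n_sampled: int | None = 200,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[GenotypeMatrix, FamilyStructure]:
    """Gene-drop full-sib families and sample a cohort.

    Each mating produces ``offspring_per_family`` full sibs; ``n_sampled``
    individuals (default 200) are then drawn uniformly without replacement
    across the whole roster, mirroring random collection at harvest. Offspring
    dosage at every marker is one gamete from each parent.
    """
    if offspring_per_family < 1:
        raise ValueError("offspring_per_family must be >= 1")
    gmap = founders.gmap
    rng = np.random.default_rng(seed)
    roster = [
        (f"F{f + 1:02d}_{k + 1:03d}", sire, dam, f + 1)
        for f, (sire, dam) in enumerate(matings)
        for k in range(offspring_per_family)
    ]
    # validate parents up front so errors precede any sampling
    parent_haps = {}
    for _, sire, dam, _ in roster:
        for pid in (sire, dam):
            if pid not in parent_haps:
                parent_haps[pid] = founders.haplotype_pair(pid)
    total = len(roster)
    if n_sampled is None:
        n_sampled = total
    if n_sampled > total:
        raise ValueError(f"cannot sample {n_sampled} from {total} offspring")
    chosen = np.sort(rng.choice(total, size=n_sampled, replace=False))
    dosages = np.empty((n_sampled, gmap.n_markers), dtype=float)
    rows = []
    for i, k in enumerate(chosen):
        oid, sire, dam, fam = roster[k]
        sa, sb = parent_haps[sire]
        da, db = parent_haps[dam]
        dosages[i] = _gamete(sa, sb, gmap, rng).astype(float) + _gamete(
            da, db, gmap, rng
        )
        rows.append((oid, sire, dam, fam))
    families = FamilyStructure(
        pd.DataFrame(rows, columns=["individual_id", "sire_id", "dam_id", "family_index"])
    )
    genotypes = GenotypeMatrix(
        individual_ids=[r[0] for r in rows],
        marker_ids=[f"M{j + 1:06d}" for j in range(gmap.n_markers)],
        dosages=dosages,
        chrom=np.array([gmap.chromosomes[c][0] for c in gmap.marker_chrom]),
        pos=np.round(gmap.marker_pos * 1_000_000).astype(int) + 1,
    )
    return genotypes, families


def paired_matings(founders: HaplotypeSet, n_families: int = 13) -> list[tuple[str, str]]:
    """Pair sire i with dam i (13 dams x 13 sires, one family each)."""
    sires = [i for i in founders.individual_ids if i.startswith("S")]
    dams = [i for i in founders.individual_ids if i.startswith("D")]
    if len(sires) < n_families or len(dams) < n_families:
        raise ValueError("not enough founders for the requested families")
    return list(zip(sires[:n_families], dams[:n_families]))


def draw_architecture(
    arch: TraitArchitecture,
    n_markers: int,
    rng: np.random.Generator,
    qtl_indices: np.ndarray | None = None,
    effects: np.ndarray | None = None,
) -> TraitArchitecture:
    """Fill in QTL positions/effects (Gaussian small effects) if unset."""
    if arch.n_qtl > n_markers:
        raise ValueError("more QTL than markers")
    if qtl_indices is None:
        qtl_indices = rng.choice(n_markers, size=arch.n_qtl, replace=False)
    if effects is None:
        effects = rng.standard_normal(arch.n_qtl)
    return TraitArchitecture(
        trait=arch.trait,
        n_qtl=arch.n_qtl,
        target_h2=arch.target_h2,
        target_mean=arch.target_mean,
        target_sd=arch.target_sd,
        qtl_marker_indices=np.asarray(qtl_indices, dtype=int),
        qtl_effects=np.asarray(effects, dtype=float),
    )


def simulate_traits(
    genotypes: GenotypeMatrix,
    arch: TraitArchitecture,
    seed: int | np.random.SeedSequence = 0,
) -> PhenotypeTable:
    """Simulate one additive trait on a complete genotype matrix.

    The genetic value is u_i = sum_q effect_q * dosage_iq. ``target_h2`` is
    the animal-model heritability V_A / (V_A + V_E) with V_A on the scale of
    the VanRaden relationship matrix of the cohort's markers: the additive
    variance is taken as V_A = var(u) (n-1) / tr(G), so that a G-based REML
    fit recovers the target in expectation even when population structure
    pushes the mean diagonal of G away from 1. The phenotype is affinely
    mapped so its expected mean/SD match the architecture's targets, and
    floored at 1% of the target mean to keep measurements physically
    positive (vanishingly rare at the default configurations). The returned
    table carries the observed phenotype and, for testing, the true genetic
    value on the output scale.
    """
    genotypes.require_complete("trait simulation")
    rng = np.random.default_rng(seed)
    if arch.qtl_marker_indices is None or arch.qtl_effects is None:
        arch = draw_architecture(arch, genotypes.n_markers, rng)
    X = genotypes.dosages
    u = X[:, arch.qtl_marker_indices] @ arch.qtl_effects
    n = u.size
    var_u = float(np.var(u, ddof=1))
    h2 = arch.target_h2
    if h2 == 1.0:
        if var_u == 0:
            raise ValueError("target_h2 = 1 requires non-zero genetic variance")
        a = arch.target_sd / np.sqrt(var_u)
        y = arch.target_mean + a * (u - u.mean())
        g = y.copy()
    elif h2 == 0.0:
        y = arch.target_mean + arch.target_sd * rng.standard_normal(n)
        g = np.zeros(n)
    else:
        if var_u == 0:
            raise ValueError("no genetic variance among QTL genotypes")
        # tr(G)/(n-1) converts the realized sample variance of u to the
        # G-scale additive variance (G has zero row sums, so this is exact
        # in expectation for u drawn with covariance proportional to G)
        p = X.mean(axis=0) / 2.0
        denom = 2.0 * np.sum(p * (1.0 - p))
        g_diag_sum = np.sum((X - 2.0 * p) ** 2) / denom
        V_A = var_u * (n - 1) / g_diag_sum
        V_E = V_A * (1.0 - h2) / h2
        e = rng.normal(0.0, np.sqrt(V_E), n)
        a = arch.target_sd / np.sqrt(var_u + V_E)
        y = arch.target_mean + a * ((u - u.mean()) + e)
        g = arch.target_mean + a * (u - u.mean())
    y = np.maximum(y, 0.01 * arch.target_mean)
    return PhenotypeTable(
        pd.DataFrame(
            {
                "individual_id": genotypes.individual_ids,
                arch.trait: y,
                f"true_{arch.trait}": g,
            }
        )
    )


def simulate_two_traits(
    genotypes: GenotypeMatrix,
    weight_arch: TraitArchitecture | None = None,
    length_arch: TraitArchitecture | None = None,
    shared_qtl_fraction: float = 0.7,
    seed: int | np.random.SeedSequence = 0,
) -> PhenotypeTable:
    """Body weight and body length with genetic overlap.

    A ``shared_qtl_fraction`` of the QTL (with identical standardized
    effects) is common to both traits, inducing a positive genetic
    correlation of roughly that magnitude.
    """
    weight_arch = weight_arch or default_weight_architecture()
    length_arch = length_arch or default_length_architecture()
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    s_arch, s_w, s_l = ss.spawn(3)
    rng = np.random.default_rng(s_arch)
    n_shared = int(round(shared_qtl_fraction * min(weight_arch.n_qtl, length_arch.n_qtl)))
    m = genotypes.n_markers
    n_union = weight_arch.n_qtl + length_arch.n_qtl - n_shared
    if n_union > m:
        raise ValueError("not enough markers for the requested QTL sets")
    union = rng.choice(m, size=n_union, replace=False)
    shared = union[:n_shared]
    own_w = union[n_shared : weight_arch.n_qtl]
    own_l = union[weight_arch.n_qtl :]
    eff_shared = rng.standard_normal(n_shared)
    arch_w = draw_architecture(
        weight_arch,
        m,
        rng,
        qtl_indices=np.concatenate([shared, own_w]),
        effects=np.concatenate([eff_shared, rng.standard_normal(own_w.size)]),
    )
    arch_l = draw_architecture(
        length_arch,
        m,
        rng,
        qtl_indices=np.concatenate([shared, own_l]),
        effects=np.concatenate([eff_shared, rng.standard_normal(own_l.size)]),
    )
    t_w = simulate_traits(genotypes, arch_w, s_w).table
    t_l = simulate_traits(genotypes, arch_l, s_l).table
    return PhenotypeTable(t_w.merge(t_l, on="individual_id"))


def inject_missingness(
    genotypes: GenotypeMatrix,
    per_marker_rate_spec=0.03,
    seed: int | np.random.SeedSequence = 0,
) -> GenotypeMatrix:
    """Set entries to missing independently at each marker's drawn rate."""
    rng = np.random.default_rng(seed)
    m = genotypes.n_markers
    if callable(per_marker_rate_spec):
        rates = np.asarray(per_marker_rate_spec(rng, m), dtype=float)
    elif np.isscalar(per_marker_rate_spec):
        rates = np.full(m, float(per_marker_rate_spec))
    else:
        low, high = per_marker_rate_spec
        rates = rng.uniform(low, high, m)
    if (rates < 0).any() or (rates > 1).any():
        raise ValueError("missingness rates must lie in [0, 1]")
    d = genotypes.dosages.copy()
    mask = rng.random(d.shape) < rates[None, :]
    d[mask] = np.nan
    return GenotypeMatrix(
        individual_ids=genotypes.individual_ids,
        marker_ids=genotypes.marker_ids,
        dosages=d,
        chrom=genotypes.chrom,
        pos=genotypes.pos,
        ref=genotypes.ref,
        alt=genotypes.alt,
    )


def default_line_of_family(n_families: int, n_lines: int) -> np.ndarray:
    """Assign families to commercial lines with uneven sizes.

    For the default 13 families over 7 lines this gives line sizes
    (3, 3, 2, 2, 1, 1, 1), echoing a cohort whose subpopulations range from
    large multi-family groups down to single families.
    """
    if n_lines > n_families:
        raise ValueError("more lines than families")
    base = n_families // n_lines
    extra = n_families % n_lines
    sizes = [base + (1 if i < extra else 0) for i in range(n_lines)]
    return np.repeat(np.arange(n_lines), sizes)


def simulate_dataset(
    n_families: int = 13,
    offspring_per_family: int = 50,
    n_sampled: int = 200,
    n_markers: int = 23_049,
    maf_spec=(0.05, 0.5),
    ld_decay: float = 0.05,
    n_lines: int = 7,
    fst: float = 0.1,
    weight_arch: TraitArchitecture | None = None,
    length_arch: TraitArchitecture | None = None,
    shared_qtl_fraction: float = 0.7,
    n_qtl: int | None = None,
    missing_rate_spec=None,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[GenotypeMatrix, PhenotypeTable, FamilyStructure]:
    """One full synthetic cohort at the study's default conditions.

    ``n_qtl`` overrides the per-trait QTL count of the default
    architectures (useful for small marker panels).

    Families are nested within ``n_lines`` divergent commercial lines
    (Balding-Nichols ``fst``); the returned family table carries the line
    index of each individual. Returns complete genotypes unless
    ``missing_rate_spec`` is given, in which case missing calls are injected
    for the QC stage to handle.
    """
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    s_found, s_fam, s_trait, s_miss = ss.spawn(4)
    line_of_family = default_line_of_family(n_families, n_lines)
    founders = simulate_founders(
        n_sires=n_families,
        n_dams=n_families,
        n_markers=n_markers,
        maf_spec=maf_spec,
        ld_decay=ld_decay,
        line_of_founder=np.concatenate([line_of_family, line_of_family]),
        fst=fst,
        seed=s_found,
    )
    genotypes, families = make_families(
        founders,
        paired_matings(founders, n_families),
        offspring_per_family=offspring_per_family,
        n_sampled=n_sampled,
        seed=s_fam,
    )
    families.table["line_index"] = [
        int(line_of_family[f - 1]) for f in families.table["family_index"]
    ]
    if n_qtl is not None:
        import dataclasses

        weight_arch = dataclasses.replace(
            weight_arch or default_weight_architecture(), n_qtl=n_qtl
        )
        length_arch = dataclasses.replace(
            length_arch or default_length_architecture(), n_qtl=n_qtl
        )
    phenotypes = simulate_two_traits(
        genotypes,
        weight_arch=weight_arch,
        length_arch=length_arch,
        shared_qtl_fraction=shared_qtl_fraction,
        seed=s_trait,
    )
    if missing_rate_spec is not None:
        genotypes = inject_missingness(genotypes, missing_rate_spec, seed=s_miss)
    return genotypes, phenotypes, families
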