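"""Forward-in-time breeding-program simulator.

Simulates the study populations end to end: a historical random-mating
population with a bottleneck (building baseline LD by drift and recurrent
mutation), pure breeds founded from it at different sizes, generations of
phenotypic and then EBV-based (pedigree BLUP) truncation selection with
sheep-like litter structure, composite breeds formed by admixture, an
additive trait controlled by multi-allelic QTLs plus a polygenic term, and
a bi-allelic SNP panel with configurable missingness and genotyping error.

Meiosis uses Poisson recombination under the Haldane map function (no
interference), implemented as independent Bernoulli exchanges on
inter-locus intervals, which is exactly equivalent.  All randomness flows
through a single ``numpy.random.Generator`` per operation, so a fixed seed
reproduces populations bit for bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import splu

from . import pedigree as pedmod

__all__ = [
    "GenomeConfig",
    "GenomeMap",
    "TraitConfig",
    "TraitArchitecture",
    "Population",
    "GenotypeMatrix",
    "MatingConfig",
    "HistPhase",
    "SimulationError",
    "sample_genome_and_architecture",
    "simulate_historical",
    "found_breed",
    "run_recent_selection",
    "make_composite",
    "assign_phenotypes",
    "apply_genotyping",
    "sample_medium_panel",
    "qc_variants",
    "reduced_preset",
    "full_preset",
    "simulate_breed",
    "simulate_population",
]

MALE, FEMALE = 1, 2


class SimulationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# configuration and domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeConfig:
    """Marker/QTL layout of the simulated genome.

    ``chromosomes`` is a list of (name, length_cM); 1 cM corresponds to
    ``1/cM_per_Mb`` Mb, and physical bp positions are derived from genetic
    positions by that ratio.
    """

    chromosomes: tuple[tuple[str, float], ...]
    n_markers_hd: int
    n_markers_medium: int
    n_qtl: int
    cM_per_Mb: float = 1.0
    marker_mutation_rate: float = 1e-4
    qtl_mutation_rate: float = 1e-4
    qtl_allele_range: tuple[int, int] = (2, 6)

    def __post_init__(self):
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")
        if self.n_markers_medium > self.n_markers_hd:
            raise ValueError("medium panel cannot exceed the HD panel")
        if not (2 <= self.qtl_allele_range[0] <= self.qtl_allele_range[1]):
            raise ValueError("QTL allele counts must be >= 2 and ordered")


@dataclass
class GenomeMap:
    """Realized loci: sorted positions per chromosome, markers and QTLs."""

    chrom: np.ndarray          # chromosome index per locus
    pos_cm: np.ndarray         # genetic position (cM) within chromosome
    is_qtl: np.ndarray         # bool per locus
    qtl_n_alleles: np.ndarray  # per QTL locus (order of QTLs in map order)
    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[float, ...]
    cM_per_Mb: float = 1.0

    @property
    def n_loci(self) -> int:
        return len(self.chrom)

    @property
    def marker_idx(self) -> np.ndarray:
        return np.flatnonzero(~self.is_qtl)

    @property
    def qtl_idx(self) -> np.ndarray:
        return np.flatnonzero(self.is_qtl)

    @property
    def pos_bp(self) -> np.ndarray:
        """1-based bp positions derived from the cM positions."""
        return np.maximum(1, np.round(self.pos_cm / self.cM_per_Mb * 1e6)).astype(
            np.int64
        )

    def rec_fractions(self) -> np.ndarray:
        """Recombination fraction between adjacent loci (0.5 across chromosomes).

        Haldane: r = (1 - exp(-2d)) / 2 with d in Morgans.
        """
        d = np.diff(self.pos_cm) / 100.0
        r = 0.5 * (1.0 - np.exp(-2.0 * d))
        r[np.diff(self.chrom) != 0] = 0.5
        return r

    def distance_morgans(self, i: int, j: int) -> float:
        if self.chrom[i] != self.chrom[j]:
            raise ValueError("loci on different chromosomes have no map distance")
        return abs(self.pos_cm[i] - self.pos_cm[j]) / 100.0


@dataclass(frozen=True)
class TraitConfig:
    h2: float
    qtl_h2: float
    var_pheno: float = 100.0
    mean: float = 0.0
    gamma_shape: float = 0.4


@dataclass
class TraitArchitecture:
    """Additive trait: gamma-distributed multi-allelic QTL effects + polygene.

    ``qtl_effects[k, a]`` is the additive value of allele ``a`` at the k-th
    QTL (map order); unused allele slots are zero.  Effects are rescaled once
    against a base population so the realized QTL variance equals
    ``qtl_h2 * var_pheno``, and the polygenic variance takes the remainder
    ``(h2 - qtl_h2) * var_pheno``.
    """

    h2: float
    qtl_h2: float
    var_pheno: float
    qtl_effects: np.ndarray
    mean: float = 0.0
    base_allele_freq: float = 0.5
    gamma_shape: float = 0.4
    scaled: bool = False

    def __post_init__(self):
        if not (0.0 <= self.qtl_h2 <= self.h2 <= 1.0):
            raise ValueError("need 0 <= qtl_h2 <= h2 <= 1")

    @property
    def var_polygenic(self) -> float:
        return (self.h2 - self.qtl_h2) * self.var_pheno

    @property
    def var_residual(self) -> float:
        return (1.0 - self.h2) * self.var_pheno

    @property
    def var_genetic(self) -> float:
        return self.h2 * self.var_pheno


@dataclass
class Population:
    """A pedigreed population with phased haplotypes and trait values.

    ``pedigree`` columns: id, sire, dam (0 = unknown), sex (1=M, 2=F),
    generation, breed, phase.  Row order is parents-first; ``haplotypes``
    rows align with pedigree rows: shape (n, 2, n_loci), uint8 allele codes.
    """

    pedigree: pd.DataFrame
    haplotypes: np.ndarray
    genome: GenomeMap
    trait: TraitArchitecture | None = None
    tbv: np.ndarray = field(default_factory=lambda: np.empty(0))
    polygenic_bv: np.ndarray = field(default_factory=lambda: np.empty(0))
    phenotype: np.ndarray = field(default_factory=lambda: np.empty(0))
    F: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n(self) -> int:
        return len(self.pedigree)

    def rows_of_generation(self, generations, phase: str | None = None) -> np.ndarray:
        gen = self.pedigree["generation"].to_numpy()
        mask = np.isin(gen, np.atleast_1d(generations))
        if phase is not None:
            mask &= (self.pedigree["phase"] == phase).to_numpy()
        return np.flatnonzero(mask)

    def allele_freq(self, loci: np.ndarray | None = None, rows=None) -> np.ndarray:
        """Frequency of allele 1 at marker loci (bi-allelic)."""
        H = self.haplotypes
        if rows is not None:
            H = H[rows]
        if loci is None:
            loci = self.genome.marker_idx
        return H[:, :, loci].mean(axis=(0, 1))

    def copy(self) -> "Population":
        return Population(
            pedigree=self.pedigree.copy(),
            haplotypes=self.haplotypes.copy(),
            genome=self.genome,
            trait=self.trait,
            tbv=self.tbv.copy(),
            polygenic_bv=self.polygenic_bv.copy(),
            phenotype=self.phenotype.copy(),
            F=self.F.copy(),
        )


@dataclass
class GenotypeMatrix:
    """Observed dosage matrix: individuals x loci, codes {0,1,2,-1=missing}."""

    dosages: np.ndarray
    loci: np.ndarray           # indices into the genome map
    animal_rows: np.ndarray    # rows into the source Population
    animal_ids: np.ndarray
    panel_tag: str = "hd"

    @property
    def allele_freqs(self) -> np.ndarray:
        d = np.ma.masked_equal(self.dosages, -1)
        return np.asarray(d.mean(axis=0) / 2.0)

    @property
    def missing_fraction(self) -> float:
        return float(np.mean(self.dosages == -1))


@dataclass(frozen=True)
class MatingConfig:
    """Mating and replacement design of the recent (selected) populations."""

    dams_per_sire: int = 25
    repl_male: float = 0.40
    repl_female: float = 0.20
    litter_odds: tuple[float, float, float] = (0.30, 0.50, 0.20)
    female_growth: float = 0.0
    n_dams: int | None = None       # initial dam count cap (None = all females)
    min_census: int | None = None   # per-generation assertion, scaled with preset


@dataclass(frozen=True)
class HistPhase:
    n_gens: int
    size_start: int
    size_end: int
    male_frac: float = 0.5


# ---------------------------------------------------------------------------
# genome and architecture sampling
# ---------------------------------------------------------------------------


def sample_genome_and_architecture(
    cfg: GenomeConfig, trait_cfg: TraitConfig, seed: int
) -> tuple[GenomeMap, TraitArchitecture]:
    """Place markers and QTLs uniformly (disjoint positions) and draw effects.

    QTL allele counts are uniform on ``qtl_allele_range``; per-allele
    additive values are gamma(shape)-distributed magnitudes with random
    signs.  Effects are unscaled here; they are calibrated against the last
    historical generation by :func:`simulate_historical`.
    """
    rng = np.random.default_rng(seed)
    total_cm = sum(length for _, length in cfg.chromosomes)
    n_total = cfg.n_markers_hd + cfg.n_qtl
    bp_per_cm = 1e6 / cfg.cM_per_Mb
    if n_total > int(total_cm * bp_per_cm):
        raise ValueError("more loci requested than distinguishable bp positions")

    # allocate loci to chromosomes proportionally to length
    lengths = np.array([length for _, length in cfg.chromosomes])
    chrom_arr, pos_arr, qtl_arr = [], [], []
    n_marker_per = _proportional_counts(cfg.n_markers_hd, lengths, rng)
    n_qtl_per = _proportional_counts(cfg.n_qtl, lengths, rng)
    for c, length in enumerate(lengths):
        n_c = n_marker_per[c] + n_qtl_per[c]
        n_bp = int(length * bp_per_cm)
        bp = rng.choice(n_bp, size=n_c, replace=False) + 1
        bp.sort()
        is_qtl = np.zeros(n_c, dtype=bool)
        is_qtl[rng.choice(n_c, size=n_qtl_per[c], replace=False)] = True
        chrom_arr.append(np.full(n_c, c))
        pos_arr.append(bp / bp_per_cm)
        qtl_arr.append(is_qtl)

    gmap = GenomeMap(
        chrom=np.concatenate(chrom_arr),
        pos_cm=np.concatenate(pos_arr),
        is_qtl=np.concatenate(qtl_arr),
        qtl_n_alleles=rng.integers(
            cfg.qtl_allele_range[0], cfg.qtl_allele_range[1] + 1, size=cfg.n_qtl
        ),
        chrom_names=tuple(name for name, _ in cfg.chromosomes),
        chrom_lengths=tuple(float(x) for x in lengths),
        cM_per_Mb=cfg.cM_per_Mb,
    )

    max_alleles = int(gmap.qtl_n_alleles.max()) if cfg.n_qtl else 0
    effects = np.zeros((cfg.n_qtl, max_alleles))
    for k, n_all in enumerate(gmap.qtl_n_alleles):
        mag = rng.gamma(shape=trait_cfg.gamma_shape, scale=1.0, size=n_all)
        sign = rng.choice([-1.0, 1.0], size=n_all)
        effects[k, :n_all] = mag * sign

    arch = TraitArchitecture(
        h2=trait_cfg.h2,
        qtl_h2=trait_cfg.qtl_h2,
        var_pheno=trait_cfg.var_pheno,
        qtl_effects=effects,
        mean=trait_cfg.mean,
    )
    return gmap, arch


def _proportional_counts(total: int, lengths: np.ndarray, rng) -> np.ndarray:
    raw = lengths / lengths.sum() * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    if short > 0:
        extra = rng.choice(len(lengths), size=short, replace=False)
        counts[extra] += 1
    return counts


def qtl_values(haplotypes: np.ndarray, gmap: GenomeMap, arch: TraitArchitecture) -> np.ndarray:
    """Sum of QTL allele effects over both haplotypes, per individual."""
    q = gmap.qtl_idx
    if len(q) == 0:
        return np.zeros(haplotypes.shape[0])
    k = np.arange(len(q))
    a0 = arch.qtl_effects[k, haplotypes[:, 0, q]]
    a1 = arch.qtl_effects[k, haplotypes[:, 1, q]]
    return a0.sum(axis=1) + a1.sum(axis=1)


def scale_architecture(
    arch: TraitArchitecture, haplotypes: np.ndarray, gmap: GenomeMap
) -> TraitArchitecture:
    """Rescale QTL effects so realized QTL variance = qtl_h2 * var_pheno."""
    v = qtl_values(haplotypes, gmap, arch)
    var = float(np.var(v))
    if var <= 0:
        raise SimulationError("no QTL variance in the base population")
    factor = np.sqrt(arch.qtl_h2 * arch.var_pheno / var)
    out = dataclasses.replace(arch, qtl_effects=arch.qtl_effects * factor, scaled=True)
    return out


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------


def _gametes(
    H: np.ndarray,
    parent_rows: np.ndarray,
    rec: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete per entry of ``parent_rows`` (vectorized meioses)."""
    n = len(parent_rows)
    L = H.shape[2]
    u = rng.random((n, L), dtype=np.float32)
    switch = np.empty((n, L), dtype=np.int8)
    switch[:, 0] = u[:, 0] < 0.5
    switch[:, 1:] = u[:, 1:] < rec
    strand = np.cumsum(switch, axis=1, dtype=np.int32) & 1
    return H[parent_rows[:, None], strand, np.arange(L)[None, :]]


def _mutate(
    gam: np.ndarray, gmap: GenomeMap, cfg: GenomeConfig, rng: np.random.Generator
) -> None:
    """Recurrent mutation in place: allele flip (markers), re-draw (QTLs)."""
    if cfg.marker_mutation_rate > 0:
        m = gmap.marker_idx
        hits = rng.random(size=(gam.shape[0], len(m)), dtype=np.float32) < cfg.marker_mutation_rate
        r, c = np.nonzero(hits)
        gam[r, m[c]] = 1 - gam[r, m[c]]
    if cfg.qtl_mutation_rate > 0 and len(gmap.qtl_idx):
        q = gmap.qtl_idx
        hits = rng.random(size=(gam.shape[0], len(q)), dtype=np.float32) < cfg.qtl_mutation_rate
        r, c = np.nonzero(hits)
        if len(r):
            k = gmap.qtl_n_alleles[c]
            gam[r, q[c]] = (rng.random(len(r)) * k).astype(np.uint8)


# ---------------------------------------------------------------------------
# historical population
# ---------------------------------------------------------------------------


def simulate_historical(
    cfg: GenomeConfig,
    gmap: GenomeMap,
    schedule: list[HistPhase],
    seed: int,
    arch: TraitArchitecture | None = None,
    init_freq: float = 0.5,
) -> Population:
    """Random-union-of-gametes historical phases with drift and mutation.

    Returns only the final generation (as breed-founder stock, generation 0,
    unknown parents).  If ``arch`` is given it is scaled against this
    generation and attached to the returned population.
    """
    rng = np.random.default_rng(seed)
    L = gmap.n_loci
    rec = gmap.rec_fractions()

    size0 = schedule[0].size_start
    H = np.empty((size0, 2, L), dtype=np.uint8)
    m = gmap.marker_idx
    H[:, :, m] = (rng.random((size0, 2, len(m))) < init_freq).astype(np.uint8)
    q = gmap.qtl_idx
    if len(q):
        k = gmap.qtl_n_alleles[None, None, :]
        H[:, :, q] = (rng.random((size0, 2, len(q))) * k).astype(np.uint8)
    sex = _balanced_sexes(size0, schedule[0].male_frac, rng)

    for phase in schedule:
        sizes = np.linspace(phase.size_start, phase.size_end, phase.n_gens + 1)[1:]
        for census in np.round(sizes).astype(int):
            if census <= 0:
                raise SimulationError("historical census reached zero (extinction)")
            males = np.flatnonzero(sex == MALE)
            females = np.flatnonzero(sex == FEMALE)
            if len(males) == 0 or len(females) == 0:
                raise SimulationError("one sex went extinct in the historical phase")
            sires = rng.choice(males, size=census)
            dams = rng.choice(females, size=census)
            pat = _gametes(H, sires, rec, rng)
            mat = _gametes(H, dams, rec, rng)
            _mutate(pat, gmap, cfg, rng)
            _mutate(mat, gmap, cfg, rng)
            H = np.stack([pat, mat], axis=1)
            sex = _balanced_sexes(census, phase.male_frac, rng)

    n = H.shape[0]
    ped = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "sire": 0,
            "dam": 0,
            "sex": sex,
            "generation": 0,
            "breed": "historical",
            "phase": "founder",
        }
    )
    pop = Population(
        pedigree=ped,
        haplotypes=H,
        genome=gmap,
        tbv=np.full(n, np.nan),
        polygenic_bv=np.full(n, np.nan),
        phenotype=np.full(n, np.nan),
        F=np.zeros(n),
    )
    if arch is not None:
        pop.trait = scale_architecture(arch, H, gmap)
    return pop


def _balanced_sexes(n: int, male_frac: float, rng) -> np.ndarray:
    n_m = max(1, int(round(n * male_frac)))
    sex = np.full(n, FEMALE, dtype=np.int8)
    sex[rng.choice(n, size=min(n_m, n - 1), replace=False)] = MALE
    return sex


def hd_panel(pop: Population, maf_min: float = 0.05) -> np.ndarray:
    """HD panel = marker loci segregating with MAF >= maf_min in ``pop``."""
    m = pop.genome.marker_idx
    p = pop.allele_freq(m)
    maf = np.minimum(p, 1 - p)
    return m[maf >= maf_min]


def sample_medium_panel(
    gmap: GenomeMap, hd_loci: np.ndarray, n_medium: int, seed: int
) -> np.ndarray:
    """Medium panel: random subset of the HD panel within each chromosome."""
    rng = np.random.default_rng(seed)
    counts = _proportional_counts(
        min(n_medium, len(hd_loci)),
        np.array([np.sum(gmap.chrom[hd_loci] == c) for c in range(len(gmap.chrom_names))], dtype=float) + 1e-9,
        rng,
    )
    chosen = []
    for c in range(len(gmap.chrom_names)):
        on_c = hd_loci[gmap.chrom[hd_loci] == c]
        take = min(counts[c], len(on_c))
        if take > 0:
            chosen.append(rng.choice(on_c, size=take, replace=False))
    out = np.sort(np.concatenate(chosen)) if chosen else np.empty(0, dtype=int)
    return out


# ---------------------------------------------------------------------------
# breed founding, trait values, phenotypes
# ---------------------------------------------------------------------------


def found_breed(
    hist: Population, n_founders: int, seed: int, breed: str = "breed"
) -> Population:
    """Random sample (without replacement) of the historical stock."""
    if n_founders > hist.n:
        raise ValueError("n_founders exceeds the historical census")
    rng = np.random.default_rng(seed)
    rows = np.sort(rng.choice(hist.n, size=n_founders, replace=False))
    ped = pd.DataFrame(
        {
            "id": np.arange(1, n_founders + 1),
            "sire": 0,
            "dam": 0,
            "sex": hist.pedigree["sex"].to_numpy()[rows],
            "generation": 0,
            "breed": breed,
            "phase": "founder",
        }
    )
    return Population(
        pedigree=ped,
        haplotypes=hist.haplotypes[rows].copy(),
        genome=hist.genome,
        trait=hist.trait,
        tbv=np.full(n_founders, np.nan),
        polygenic_bv=np.full(n_founders, np.nan),
        phenotype=np.full(n_founders, np.nan),
        F=np.zeros(n_founders),
    )


def assign_phenotypes(
    pop: Population, trait: TraitArchitecture | None = None, seed: int = 0
) -> Population:
    """Draw founder polygenic values and phenotypes (in place).

    Founders (unknown parents) get polygenic ~ N(0, var_polygenic); all
    animals get phenotype = mean + tbv + N(0, (1-h2) var_pheno).
    """
    trait = trait if trait is not None else pop.trait
    if trait is None or not trait.scaled:
        raise ValueError("a scaled TraitArchitecture is required")
    pop.trait = trait
    rng = np.random.default_rng(seed)
    n = pop.n
    missing = np.isnan(pop.polygenic_bv)
    pop.polygenic_bv[missing] = rng.normal(
        0.0, np.sqrt(trait.var_polygenic), size=missing.sum()
    )
    pop.tbv = qtl_values(pop.haplotypes, pop.genome, trait) + pop.polygenic_bv
    sd_e = np.sqrt(trait.var_residual)
    pop.phenotype = trait.mean + pop.tbv + rng.normal(0.0, sd_e, size=n)
    return pop


# ---------------------------------------------------------------------------
# recent populations under selection
# ---------------------------------------------------------------------------


def run_recent_selection(
    pop: Population,
    n_gens: int,
    mode: str,
    direction: str = "up",
    mating_cfg: MatingConfig = MatingConfig(),
    seed: int = 0,
    phase_label: str | None = None,
) -> Population:
    """Overlapping-generation truncation selection with litter structure.

    mode: 'phenotypic' (rank on own phenotype), 'ebv' (rank on pedigree-BLUP
    EBV solved on all records to date, true variance ratios), or 'random'.
    Breeding females ("dams") are replaced at ``repl_female`` per generation
    (plus exponential growth at ``female_growth``); males at ``repl_male``;
    one sire serves ``dams_per_sire`` dams; litter sizes 1/2/3 with the
    configured odds.  Selection ties are broken by a seeded shuffle.
    """
    if mode not in ("phenotypic", "ebv", "random"):
        raise ValueError(f"unknown selection mode: {mode}")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    trait = pop.trait
    if trait is None or not trait.scaled:
        raise ValueError("population needs a scaled trait before selection")
    if np.isnan(pop.phenotype).all():
        raise ValueError("population has no phenotypes; call assign_phenotypes first")
    phase_label = phase_label or {"phenotypic": "pheno_sel", "ebv": "ebv_sel", "random": "random"}[mode]

    rng = np.random.default_rng(seed)
    rec = pop.genome.rec_fractions()
    gmap, cfg_odds = pop.genome, np.asarray(mating_cfg.litter_odds, dtype=float)
    cfg_odds = cfg_odds / cfg_odds.sum()

    # growing state arrays (lists of per-generation blocks)
    ped0 = pop.pedigree
    ids = [ped0["id"].to_numpy().copy()]
    sires_col = [ped0["sire"].to_numpy().copy()]
    dams_col = [ped0["dam"].to_numpy().copy()]
    sex_col = [ped0["sex"].to_numpy().copy()]
    gen_col = [ped0["generation"].to_numpy().copy()]
    phase_col = [ped0["phase"].to_numpy().copy()]
    hap_blocks = [pop.haplotypes]
    tbv = [pop.tbv.copy()]
    pgv = [pop.polygenic_bv.copy()]
    phe = [pop.phenotype.copy()]
    Fs = [pop.F.copy()]
    breed = ped0["breed"].iloc[-1]
    next_id = int(ped0["id"].max()) + 1
    gen0 = int(ped0["generation"].max())
    n_total = pop.n

    # breeding stock: in 'random' mode generations are discrete and every
    # male is a potential sire of any litter; under selection the stock is
    # a sire battery plus dam herd with partial replacement.
    random_mating = mode == "random"
    last_gen_rows = np.flatnonzero(gen_col[0] == gen0)
    sex_last = sex_col[0][last_gen_rows]
    females = last_gen_rows[sex_last == FEMALE]
    males = last_gen_rows[sex_last == MALE]
    if len(females) == 0 or len(males) == 0:
        raise SimulationError("founder stock lacks one sex")
    init_crit = _criterion(pop, mode, direction, rng)
    n_dams = mating_cfg.n_dams or len(females)
    cur_dams = _top_rows(females, init_crit, n_dams)
    if random_mating:
        cur_sires = males
    else:
        n_sires = max(1, int(np.ceil(len(cur_dams) / mating_cfg.dams_per_sire)))
        cur_sires = _top_rows(males, init_crit, n_sires)

    active = np.concatenate([cur_sires, cur_dams])
    ids_all = np.concatenate(ids)
    A_act = _relationship_block(
        np.concatenate(sires_col), np.concatenate(dams_col), ids_all, active, Fs[0]
    )
    act_index = {int(r): i for i, r in enumerate(active)}

    H_all = pop.haplotypes
    var_mend_base = trait.var_polygenic
    sd_e = np.sqrt(trait.var_residual)

    for g in range(1, n_gens + 1):
        # matings: one random sire per dam, litter size 1/2/3
        dam_rows = np.asarray(cur_dams)
        sire_of_dam = rng.choice(cur_sires, size=len(dam_rows))
        litter = rng.choice([1, 2, 3], size=len(dam_rows), p=cfg_odds)
        off_sire = np.repeat(sire_of_dam, litter)
        off_dam = np.repeat(dam_rows, litter)
        n_off = len(off_sire)
        if n_off == 0:
            raise SimulationError("no offspring produced")

        pat = _gametes(H_all, off_sire, rec, rng)
        mat = _gametes(H_all, off_dam, rec, rng)
        H_off = np.stack([pat, mat], axis=1)

        # trait values: polygene = parent average + Mendelian deviation
        F_all = np.concatenate(Fs)
        pg_all = np.concatenate(pgv)
        f_par = 0.5 * (F_all[off_sire] + F_all[off_dam])
        mend_sd = np.sqrt(np.maximum(0.5 * var_mend_base * (1.0 - f_par), 0.0))
        pg_off = 0.5 * (pg_all[off_sire] + pg_all[off_dam]) + rng.normal(0, 1, n_off) * mend_sd
        tbv_off = qtl_values(H_off, gmap, trait) + pg_off
        phe_off = trait.mean + tbv_off + rng.normal(0.0, sd_e, size=n_off)
        sex_off = _balanced_sexes(n_off, 0.5, rng)

        # exact offspring inbreeding from the active relationship block
        si = np.array([act_index[int(r)] for r in off_sire])
        di = np.array([act_index[int(r)] for r in off_dam])
        F_off = 0.5 * A_act[si, di]

        ids.append(np.arange(next_id, next_id + n_off))
        sires_col.append(ids_all[off_sire])
        dams_col.append(ids_all[off_dam])
        sex_col.append(sex_off)
        gen_col.append(np.full(n_off, gen0 + g))
        phase_col.append(np.array([phase_label] * n_off, dtype=object))
        hap_blocks.append(H_off)
        H_all = np.concatenate([H_all, H_off], axis=0)
        tbv.append(tbv_off)
        pgv.append(pg_off)
        phe.append(phe_off)
        Fs.append(F_off)
        off_rows = np.arange(n_total, n_total + n_off)
        n_total += n_off
        next_id += n_off
        ids_all = np.concatenate(ids)

        if mating_cfg.min_census is not None and n_off < mating_cfg.min_census:
            raise SimulationError(
                f"generation {gen0 + g} census {n_off} below the configured floor"
            )

        crit = _selection_criterion(
            mode, direction, rng,
            ids=ids, sires=sires_col, dams=dams_col, gens=gen_col,
            phe=phe, Fs=Fs, trait=trait,
        )

        cand_f = off_rows[sex_off == FEMALE]
        cand_m = off_rows[sex_off == MALE]
        if random_mating:
            n_dams_target = min(
                len(cand_f), mating_cfg.n_dams or len(cand_f)
            )
            new_dams = cand_f[:n_dams_target]
            new_sires = cand_m
        else:
            n_dams_target = len(cur_dams)
            if mating_cfg.female_growth > 0:
                n_dams_target = int(round(n_dams_target * (1.0 + mating_cfg.female_growth)))
            keep_d = int(round(len(cur_dams) * (1.0 - mating_cfg.repl_female)))
            new_dams = _top_rows(cur_dams, crit, keep_d)
            need_f = min(n_dams_target - len(new_dams), len(cand_f))
            new_dams = np.concatenate([new_dams, _top_rows(cand_f, crit, need_f)])
            n_sires_target = max(1, int(np.ceil(len(new_dams) / mating_cfg.dams_per_sire)))
            keep_m = int(round(min(len(cur_sires), n_sires_target) * (1.0 - mating_cfg.repl_male)))
            new_sires = _top_rows(cur_sires, crit, keep_m)
            need_m = min(n_sires_target - len(new_sires), len(cand_m))
            new_sires = np.concatenate([new_sires, _top_rows(cand_m, crit, need_m)])
        if len(new_sires) == 0 or len(new_dams) == 0:
            raise SimulationError("mating configuration selected no breeders")

        new_active = np.concatenate([new_sires, new_dams])
        A_act, act_index = _extend_relationship_block(
            A_act, act_index, active, off_rows, off_sire, off_dam, F_off,
            keep=new_active,
        )
        active = new_active
        cur_sires, cur_dams = new_sires, new_dams

    out = Population(
        pedigree=pd.DataFrame(
            {
                "id": np.concatenate(ids),
                "sire": np.concatenate(sires_col),
                "dam": np.concatenate(dams_col),
                "sex": np.concatenate(sex_col),
                "generation": np.concatenate(gen_col),
                "breed": breed,
                "phase": np.concatenate([np.asarray(p, dtype=object) for p in phase_col]),
            }
        ),
        haplotypes=np.concatenate(hap_blocks, axis=0),
        genome=gmap,
        trait=trait,
        tbv=np.concatenate(tbv),
        polygenic_bv=np.concatenate(pgv),
        phenotype=np.concatenate(phe),
        F=np.concatenate(Fs),
    )
    return out


def _criterion(pop: Population, mode: str, direction: str, rng) -> np.ndarray:
    if mode == "random":
        score = rng.random(pop.n)
    else:
        score = pop.phenotype.copy()
    return _directed(score, direction, rng)


def _directed(score: np.ndarray, direction: str, rng) -> np.ndarray:
    s = score if direction == "up" else -score
    s = np.where(np.isnan(s), -np.inf, s)  # unscored animals rank last
    return s + rng.random(len(s)) * 1e-9   # seeded random tie-break


def _top_rows(rows: np.ndarray, crit: np.ndarray, k: int) -> np.ndarray:
    rows = np.asarray(rows)
    if k <= 0 or len(rows) == 0:
        return rows[:0]
    k = min(k, len(rows))
    order = np.argsort(-crit[rows], kind="stable")
    return rows[order[:k]]


def _selection_criterion(mode, direction, rng, *, ids, sires, dams, gens, phe, Fs, trait):
    n = sum(len(x) for x in ids)
    if mode == "random":
        return _directed(rng.random(n), "up", rng)
    if mode == "phenotypic":
        return _directed(np.concatenate(phe), direction, rng)
    # pedigree BLUP on all records to date with true variance components
    ids_all = np.concatenate(ids)
    ped = pd.DataFrame(
        {"id": ids_all, "sire": np.concatenate(sires), "dam": np.concatenate(dams)}
    )
    _, s_idx, d_idx = pedmod.ped_arrays(ped)
    Ai = pedmod.a_inverse_sparse(s_idx, d_idx, np.concatenate(Fs))
    y = np.concatenate(phe)
    gen = np.concatenate(gens)
    lam = trait.var_residual / trait.var_genetic
    ebv = _pedigree_blup(y, gen, Ai, lam)
    return _directed(ebv, direction, rng)


def _pedigree_blup(y: np.ndarray, gen_class: np.ndarray, A_inv, lam: float) -> np.ndarray:
    """Animal-model BLUP with generation fixed effect, sparse direct solve."""
    n = len(y)
    obs = ~np.isnan(y)
    levels, lev_idx = np.unique(gen_class[obs], return_inverse=True)
    p = len(levels)
    rows = np.flatnonzero(obs)
    X = sparse.csr_matrix(
        (np.ones(obs.sum()), (np.arange(obs.sum()), lev_idx)), shape=(obs.sum(), p)
    )
    Z = sparse.csr_matrix(
        (np.ones(obs.sum()), (np.arange(obs.sum()), rows)), shape=(obs.sum(), n)
    )
    yv = y[obs]
    C = sparse.bmat(
        [
            [X.T @ X, X.T @ Z],
            [Z.T @ X, Z.T @ Z + lam * A_inv],
        ],
        format="csc",
    )
    rhs = np.concatenate([X.T @ yv, Z.T @ yv])
    sol = splu(C).solve(rhs)
    return sol[p:]


def _relationship_block(sire_all, dam_all, ids_all, rows, F_all) -> np.ndarray:
    """Relationship matrix among ``rows`` via a renumbered sub-pedigree."""
    ped = pd.DataFrame({"id": ids_all, "sire": sire_all, "dam": dam_all})
    _, s_idx, d_idx = pedmod.ped_arrays(ped)
    return pedmod.a_submatrix(s_idx, d_idx, np.asarray(rows), F=F_all)


def _extend_relationship_block(A_act, act_index, active, off_rows, off_sire, off_dam, F_off, keep):
    """Grow the active-cohort A block by the new offspring, then subset."""
    n_old, n_off = len(active), len(off_rows)
    si = np.array([act_index[int(r)] for r in off_sire])
    di = np.array([act_index[int(r)] for r in off_dam])
    A_new = np.empty((n_old + n_off, n_old + n_off))
    A_new[:n_old, :n_old] = A_act
    cross = 0.5 * (A_act[si, :] + A_act[di, :])          # offspring x old
    A_new[n_old:, :n_old] = cross
    A_new[:n_old, n_old:] = cross.T
    # offspring x offspring: a(x,y) = 0.5*(a(x,s_y)+a(x,d_y))
    oo = 0.5 * (cross[:, si] + cross[:, di])
    oo = 0.5 * (oo + oo.T)
    A_new[n_old:, n_old:] = oo
    diag = 1.0 + F_off
    A_new[n_old + np.arange(n_off), n_old + np.arange(n_off)] = diag

    all_rows = np.concatenate([active, off_rows])
    pos = {int(r): i for i, r in enumerate(all_rows)}
    sel = np.array([pos[int(r)] for r in keep])
    A_keep = A_new[np.ix_(sel, sel)]
    new_index = {int(r): i for i, r in enumerate(keep)}
    return A_keep, new_index


# ---------------------------------------------------------------------------
# composites
# ---------------------------------------------------------------------------


def make_composite(
    pops: list[Population],
    proportions: list[float],
    n_random_gens: int,
    seed: int,
    n_founders: int | None = None,
    breed: str = "composite",
    mating_cfg: MatingConfig | None = None,
) -> Population:
    """Admix pure breeds at fixed proportions, then random-mate within.

    Founders are drawn from the last generation of each parent population;
    the pedigree keeps the founder's breed of origin in ``origin_breed``.
    """
    props = np.asarray(proportions, dtype=float)
    if abs(props.sum() - 1.0) > 1e-8:
        raise ValueError("proportions must sum to 1")
    genomes = {id(p.genome) for p in pops}
    if len(genomes) > 1:
        raise ValueError("parent populations must share a genome map")
    rng = np.random.default_rng(seed)
    if n_founders is None:
        n_founders = min(p.rows_of_generation(p.pedigree["generation"].max()).size for p in pops)
    counts = np.floor(props * n_founders).astype(int)
    counts[np.argmax(props)] += n_founders - counts.sum()

    hap, sex, origin, pg, tb = [], [], [], [], []
    for pop_i, k in zip(pops, counts):
        last = pop_i.rows_of_generation(pop_i.pedigree["generation"].max())
        rows = rng.choice(last, size=k, replace=False)
        hap.append(pop_i.haplotypes[rows])
        sex.append(pop_i.pedigree["sex"].to_numpy()[rows])
        origin.append(np.array([pop_i.pedigree["breed"].iloc[-1]] * k, dtype=object))
        pg.append(pop_i.polygenic_bv[rows])
        tb.append(pop_i.tbv[rows])

    n = int(counts.sum())
    ped = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "sire": 0,
            "dam": 0,
            "sex": np.concatenate(sex),
            "generation": 0,
            "breed": breed,
            "phase": "founder",
            "origin_breed": np.concatenate(origin),
        }
    )
    comp = Population(
        pedigree=ped,
        haplotypes=np.concatenate(hap, axis=0),
        genome=pops[0].genome,
        trait=pops[0].trait,
        tbv=np.concatenate(tb),
        polygenic_bv=np.concatenate(pg),
        phenotype=np.full(n, np.nan),
        F=np.zeros(n),
    )
    trait = comp.trait
    rng2 = np.random.default_rng(rng.integers(2**31))
    comp.phenotype = trait.mean + comp.tbv + rng2.normal(0, np.sqrt(trait.var_residual), n)
    if n_random_gens > 0:
        comp = run_recent_selection(
            comp,
            n_random_gens,
            mode="random",
            mating_cfg=mating_cfg or MatingConfig(),
            seed=int(rng.integers(2**31)),
            phase_label="random",
        )
    return comp


# ---------------------------------------------------------------------------
# genotyping and QC
# ---------------------------------------------------------------------------


def apply_genotyping(
    pop: Population,
    panel_loci: np.ndarray,
    rows: np.ndarray | None = None,
    missing_rate: float = 0.05,
    error_rate: float = 0.01,
    seed: int = 0,
) -> GenotypeMatrix:
    """Observed dosages on a panel: missing calls and genotyping errors.

    Each call is set missing with prob ``missing_rate``; each surviving call
    is replaced by a random *different* valid dosage with prob ``error_rate``.
    """
    rng = np.random.default_rng(seed)
    if rows is None:
        rows = np.arange(pop.n)
    H = pop.haplotypes[rows][:, :, panel_loci]
    D = (H[:, 0, :] + H[:, 1, :]).astype(np.int8)
    shape = D.shape
    if error_rate > 0:
        err = rng.random(shape, dtype=np.float32) < error_rate
        r, c = np.nonzero(err)
        if len(r):
            shift = rng.integers(1, 3, size=len(r))  # +1 or +2 mod 3 => different
            D[r, c] = ((D[r, c] + shift) % 3).astype(np.int8)
    if missing_rate > 0:
        miss = rng.random(shape, dtype=np.float32) < missing_rate
        D[miss] = -1
    return GenotypeMatrix(
        dosages=D,
        loci=np.asarray(panel_loci),
        animal_rows=np.asarray(rows),
        animal_ids=pop.pedigree["id"].to_numpy()[rows],
        panel_tag="panel",
    )


def qc_variants(
    geno: GenotypeMatrix, maf_min: float = 0.01, het_dev_max: float = 0.15
) -> tuple[GenotypeMatrix, dict]:
    """Keep loci with MAF >= maf_min and |obs het - 2p(1-p)| < het_dev_max.

    Returns the filtered matrix and a per-rule report; an empty result is
    allowed but flagged in the report.
    """
    D = np.ma.masked_equal(geno.dosages, -1)
    p = np.asarray(D.mean(axis=0)) / 2.0
    maf = np.minimum(p, 1.0 - p)
    het_obs = np.asarray((D == 1).sum(axis=0) / D.count(axis=0))
    het_exp = 2.0 * p * (1.0 - p)
    fail_maf = maf < maf_min
    fail_het = np.abs(het_obs - het_exp) >= het_dev_max
    keep = ~(fail_maf | fail_het)
    report = {
        "n_input": int(len(p)),
        "n_removed_maf": int(fail_maf.sum()),
        "n_removed_het_dev": int((fail_het & ~fail_maf).sum()),
        "n_kept": int(keep.sum()),
        "empty": bool(keep.sum() == 0),
    }
    out = GenotypeMatrix(
        dosages=geno.dosages[:, keep],
        loci=geno.loci[keep],
        animal_rows=geno.animal_rows,
        animal_ids=geno.animal_ids,
        panel_tag=geno.panel_tag,
    )
    return out, report


def impute_mean(dosages: np.ndarray) -> np.ndarray:
    """Replace missing dosages (-1) by twice the observed allele frequency."""
    D = dosages.astype(float)
    D[D < 0] = np.nan
    p = np.nanmean(D, axis=0) / 2.0
    idx = np.where(np.isnan(D))
    D[idx] = 2.0 * p[idx[1]]
    return D


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


def reduced_preset() -> dict:
    """Desk-scale defaults: same structure as the full study, smaller counts.

    4 chromosomes x 75 cM, 3,000 HD / 1,000 medium markers, 150 QTLs;
    historical 500 -> bottleneck 300 -> recovery 400; breed analogs sized so
    that a full replicate (simulation + predictions) runs on a laptop.  The
    genome is shorter than the full karyotype but keeps the study's marker
    regime: both panels dense enough to saturate short-range LD (the medium
    panel carries ~3 SNPs/cM; the full-scale design has ~18/cM).
    """
    genome = GenomeConfig(
        chromosomes=tuple((f"chr{i+1}", 75.0) for i in range(4)),
        n_markers_hd=3000,
        n_markers_medium=1000,
        n_qtl=150,
    )
    schedule = [HistPhase(80, 500, 500), HistPhase(15, 500, 300), HistPhase(10, 300, 400)]
    # 1 sire per 5 dams: with ~130 breeding dams this gives ~26 sires and a
    # variance effective size 4*Nm*Nf/(Nm+Nf) of ~90-120, matching the Ne
    # targets of the study design (the full-scale 1/25 ratio at ~4,000 dams
    # gives the same Ne range and ships in the full-scale preset).
    mating = dict(
        dams_per_sire=5, repl_male=0.40, repl_female=0.20, litter_odds=(0.3, 0.5, 0.2)
    )
    breeds = {
        # founders, phenotypic gens, growth, EBV dams, direction
        "Breed_A": dict(n_founders=140, pheno_gens=10, growth=0.10, n_dams_ebv=130, direction="up"),
        "Breed_B": dict(n_founders=140, pheno_gens=10, growth=0.10, n_dams_ebv=130, direction="down"),
        "Breed_C": dict(n_founders=250, pheno_gens=1, growth=0.15, n_dams_ebv=175, direction="up"),
        "Breed_D": dict(n_founders=350, pheno_gens=1, growth=0.15, n_dams_ebv=175, direction="up"),
        "Breed_E": dict(n_founders=350, pheno_gens=1, growth=0.15, n_dams_ebv=175, direction="down"),
    }
    composites = {
        "Comp_2": dict(parents=("Breed_D", "Breed_E"), proportions=(0.625, 0.375),
                       n_random_gens=5, n_founders=350, n_dams_ebv=130, direction="down", dams_per_sire=1),
        "Comp_3": dict(parents=("Breed_A", "Breed_B", "Breed_C"), proportions=(0.375, 0.375, 0.25),
                       n_random_gens=5, n_founders=350, n_dams_ebv=130, direction="up", dams_per_sire=1),
    }
    traits = {
        "MH2": TraitConfig(h2=0.30, qtl_h2=0.15, var_pheno=100.0),
        "LH2": TraitConfig(h2=0.10, qtl_h2=0.01, var_pheno=100.0),
    }
    split = dict(n_pheno_train=1600, n_geno_train=500, n_validation=300)
    return dict(
        name="reduced", genome=genome, schedule=schedule, mating=mating,
        breeds=breeds, composites=composites, traits=traits, split=split,
        ebv_gens=10,
    )


def full_preset() -> dict:
    """Full-scale study conditions (cluster scale; not run by the test suite).

    26 autosomes totalling 2,656 cM, 576,595 HD / 46,827 medium SNPs, 3,057
    QTLs; historical 80,000 -> 50,000 (generation 1,000) -> 60,000
    (generation 1,500); founder sizes 2,480 / 12,480 / 41,600; 1/25 mating
    ratio; per-generation floors 7,000 (pure) and 18,000 (composite).
    """
    # 26 autosome lengths between 43 and 301 cM summing to 2,656 (sheep-like
    # decreasing profile; per-chromosome values approximate the OAR_v4 karyotype)
    lengths = np.array([
        301, 263, 248, 132, 116, 129, 109, 98, 97, 94,
        67, 85, 89, 70, 88, 77, 76, 71, 65, 55,
        54, 53, 67, 45, 48, 43,
    ], dtype=float)
    lengths *= 2656.0 / lengths.sum()
    genome = GenomeConfig(
        chromosomes=tuple((f"chr{i+1}", float(l)) for i, l in enumerate(lengths)),
        n_markers_hd=576_595,
        n_markers_medium=46_827,
        n_qtl=3_057,
    )
    schedule = [
        HistPhase(1000, 80_000, 50_000),
        HistPhase(500, 50_000, 60_000, male_frac=1 / 3),
    ]
    mating = dict(dams_per_sire=25, repl_male=0.40, repl_female=0.20,
                  litter_odds=(0.3, 0.5, 0.2))
    breeds = {
        "Breed_A": dict(n_founders=2480, pheno_gens=10, growth=0.10, n_dams_ebv=4000, direction="up", min_census=7000),
        "Breed_B": dict(n_founders=2480, pheno_gens=10, growth=0.10, n_dams_ebv=4000, direction="down", min_census=7000),
        "Breed_C": dict(n_founders=12_480, pheno_gens=1, growth=0.15, n_dams_ebv=4000, direction="up", min_census=7000),
        "Breed_D": dict(n_founders=41_600, pheno_gens=1, growth=0.15, n_dams_ebv=4000, direction="up", min_census=7000),
        "Breed_E": dict(n_founders=41_600, pheno_gens=1, growth=0.15, n_dams_ebv=4000, direction="down", min_census=7000),
    }
    composites = {
        "Comp_2": dict(parents=("Breed_D", "Breed_E"), proportions=(0.625, 0.375),
                       n_random_gens=5, n_founders=20_000, n_dams_ebv=10_000, direction="down", min_census=18_000),
        "Comp_3": dict(parents=("Breed_A", "Breed_B", "Breed_C"), proportions=(0.375, 0.375, 0.25),
                       n_random_gens=5, n_founders=20_000, n_dams_ebv=10_000, direction="up", min_census=18_000),
    }
    traits = {
        "MH2": TraitConfig(h2=0.30, qtl_h2=0.15, var_pheno=100.0),
        "LH2": TraitConfig(h2=0.10, qtl_h2=0.01, var_pheno=100.0),
    }
    split = dict(n_pheno_train=60_000, n_geno_train=8_000, n_validation=2_000)
    return dict(
        name="full", genome=genome, schedule=schedule, mating=mating,
        breeds=breeds, composites=composites, traits=traits, split=split,
        ebv_gens=10,
    )


def simulate_population(preset: dict, name: str, trait_key: str, seed: int) -> Population:
    """Driver for any study population: pure breed or composite.

    Composites simulate their parent breeds through the phenotypic phase,
    admix them, random-mate, then run EBV selection; one seed controls the
    whole chain.
    """
    if name in preset["breeds"]:
        return simulate_breed(preset, name, trait_key, seed)
    if name not in preset["composites"]:
        raise KeyError(f"unknown population: {name}")
    cs = preset["composites"][name]
    root = np.random.SeedSequence(seed)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in root.spawn(8)]
    gmap, arch = sample_genome_and_architecture(
        preset["genome"], preset["traits"][trait_key], seeds[0]
    )
    hist = simulate_historical(preset["genome"], gmap, preset["schedule"], seeds[1], arch=arch)
    parents = []
    for i, b in enumerate(cs["parents"]):
        spec = preset["breeds"][b]
        pop = found_breed(hist, spec["n_founders"], seeds[2] + i, breed=b)
        assign_phenotypes(pop, seed=seeds[3] + i)
        mc = MatingConfig(female_growth=spec["growth"], **preset["mating"])
        if spec["pheno_gens"] > 0:
            pop = run_recent_selection(
                pop, spec["pheno_gens"], "phenotypic", spec["direction"],
                mc, seed=seeds[4] + i,
            )
        parents.append(pop)
    comp = make_composite(
        parents, list(cs["proportions"]), cs["n_random_gens"],
        seed=seeds[5], n_founders=cs["n_founders"], breed=name,
    )
    mcfg = dict(preset["mating"])
    mcfg["dams_per_sire"] = cs.get("dams_per_sire", mcfg["dams_per_sire"])
    mc_ebv = MatingConfig(
        n_dams=cs["n_dams_ebv"], min_census=cs.get("min_census"), **mcfg
    )
    return run_recent_selection(
        comp, preset["ebv_gens"], "ebv", cs["direction"], mc_ebv, seed=seeds[6]
    )


def simulate_breed(
    preset: dict, breed: str, trait_key: str, seed: int
) -> Population:
    """Convenience driver: historical -> founders -> selection for one breed."""
    ss = np.random.SeedSequence(seed)
    s_map, s_hist, s_found, s_ph, s_pheno, s_ebv = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(6)
    )
    gmap, arch = sample_genome_and_architecture(
        preset["genome"], preset["traits"][trait_key], s_map
    )
    hist = simulate_historical(preset["genome"], gmap, preset["schedule"], s_hist, arch=arch)
    spec = preset["breeds"][breed]
    pop = found_breed(hist, spec["n_founders"], s_found, breed=breed)
    assign_phenotypes(pop, seed=s_ph)
    mc = MatingConfig(female_growth=spec["growth"], **preset["mating"])
    if spec["pheno_gens"] > 0:
        pop = run_recent_selection(
            pop, spec["pheno_gens"], mode="phenotypic",
            direction=spec["direction"], mating_cfg=mc, seed=s_pheno,
        )
    mc_ebv = MatingConfig(
        n_dams=spec["n_dams_ebv"], min_census=spec.get("min_census"),
        **preset["mating"],
    )
    pop = run_recent_selection(
        pop, preset["ebv_gens"], mode="ebv",
        direction=spec["direction"], mating_cfg=mc_ebv, seed=s_ebv,
    )
    return pop
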