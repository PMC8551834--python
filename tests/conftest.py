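"""Shared fixtures: tiny genomes, toy pedigrees, and one small simulated
population reused across module tests.  Everything is generated
programmatically with fixed seeds."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from hapstep import simpop as sp

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def tiny_genome_config(n_chrom=2, length=60.0, n_markers=300, n_qtl=30):
    return sp.GenomeConfig(
        chromosomes=tuple((f"c{i+1}", length) for i in range(n_chrom)),
        n_markers_hd=n_markers,
        n_markers_medium=min(n_markers, 120),
        n_qtl=n_qtl,
    )


@pytest.fixture(scope="session")
def tiny_map_and_arch():
    cfg = tiny_genome_config()
    gmap, arch = sp.sample_genome_and_architecture(
        cfg, sp.TraitConfig(h2=0.30, qtl_h2=0.15), seed=11
    )
    return cfg, gmap, arch


@pytest.fixture(scope="session")
def small_pop():
    """A small breed with phenotypic + EBV selection phases (seeded)."""
    cfg = tiny_genome_config()
    gmap, arch = sp.sample_genome_and_architecture(
        cfg, sp.TraitConfig(h2=0.30, qtl_h2=0.15), seed=21
    )
    hist = sp.simulate_historical(
        cfg, gmap, [sp.HistPhase(25, 150, 150), sp.HistPhase(5, 150, 120)],
        seed=22, arch=arch,
    )
    pop = sp.found_breed(hist, 80, seed=23, breed="toy")
    sp.assign_phenotypes(pop, seed=24)
    mc = sp.MatingConfig(dams_per_sire=4, female_growth=0.10)
    pop = sp.run_recent_selection(pop, 2, "phenotypic", "up", mc, seed=25)
    mc2 = sp.MatingConfig(dams_per_sire=4, n_dams=45)
    pop = sp.run_recent_selection(pop, 5, "ebv", "up", mc2, seed=26)
    return pop


def wf_population(n=40, n_loci=60, n_gens=20, seed=0, length_cm=50.0,
                  n_chrom=1, mutation=0.0):
    """Neutral constant-size Wright-Fisher population (markers only)."""
    cfg = sp.GenomeConfig(
        chromosomes=tuple((f"c{i+1}", length_cm) for i in range(n_chrom)),
        n_markers_hd=n_loci,
        n_markers_medium=min(10, n_loci),
        n_qtl=0,
        marker_mutation_rate=mutation,
        qtl_mutation_rate=0.0,
    )
    gmap, _ = sp.sample_genome_and_architecture(
        cfg, sp.TraitConfig(h2=0.3, qtl_h2=0.0), seed=seed
    )
    pop = sp.simulate_historical(
        cfg, gmap, [sp.HistPhase(n_gens, n, n)], seed=seed + 1
    )
    return pop


def toy_pedigree_frame(records):
    """records: list of (id, sire, dam) tuples."""
    df = pd.DataFrame(records, columns=["id", "sire", "dam"])
    return df


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
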