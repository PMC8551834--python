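"""Linkage disequilibrium and effective population size estimators.

Characterizes simulated (or user-supplied) populations: pairwise r²
between loci, the Sved expectation E(r²) = 1/(4·Ne·c + 2), its inversion
Ne_LD = (1/(4c))·(1/r̄² − 2) with horizon t = 1/(2c) generations ago, and
the inbreeding-rate estimator Ne_Inb = 1/(2ΔF) with
ΔF = (F_n − F_{n−1})/(1 − F_{n−1}).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import pedigree as pedmod
from .simpop import GenotypeMatrix, Population

__all__ = [
    "LDEstimate",
    "NeEstimate",
    "pairwise_r2",
    "expected_r2",
    "ne_from_ld",
    "generations_from_distance",
    "pedigree_inbreeding",
    "ne_from_inbreeding",
    "mean_r2_at_distance",
    "ne_ld_from_population",
]


@dataclass(frozen=True)
class LDEstimate:
    locus_a: int
    locus_b: int
    c: float      # genetic distance, Morgans
    r2: float


@dataclass(frozen=True)
class NeEstimate:
    method: str               # 'LD' | 'inbreeding'
    value: float
    t_generations_ago: float
    inputs: dict


def _haplotype_r2(ha: np.ndarray, hb: np.ndarray) -> float:
    """r² from phased gamete allele indicators at two bi-allelic loci."""
    pa, pb = ha.mean(), hb.mean()
    denom = pa * (1 - pa) * pb * (1 - pb)
    if denom <= 0:
        return np.nan
    d = (ha * hb).mean() - pa * pb
    return float(d * d / denom)


def pairwise_r2(
    data: Population | GenotypeMatrix | np.ndarray,
    pairs: list[tuple[int, int]],
    maf_min: float = 0.05,
    loci: np.ndarray | None = None,
) -> pd.DataFrame:
    """r² for the requested locus pairs.

    ``data`` may be a Population (phased haplotypes; r² from gamete
    frequencies), a raw haplotype array of shape (n, 2, L), or a
    GenotypeMatrix (unphased; squared dosage correlation).  ``pairs``
    holds column indices into the locus dimension (``loci`` can remap
    them to genome-map indices for distance bookkeeping).  Pairs with a
    monomorphic or MAF-filtered locus are skipped and reported with
    r2 = NaN.
    """
    phased = None
    gmap = None
    if isinstance(data, Population):
        phased = data.haplotypes
        gmap = data.genome
    elif isinstance(data, np.ndarray):
        phased = data
    if phased is not None:
        n, two, L = phased.shape
        G = phased.reshape(n * 2, L).astype(float)  # gametes x loci
    else:
        G = None
        D = data.dosages.astype(float)
        D[D < 0] = np.nan

    recs = []
    for a, b in pairs:
        if G is not None:
            ha, hb = G[:, a], G[:, b]
            pa, pb = ha.mean(), hb.mean()
            if min(pa, 1 - pa) < maf_min or min(pb, 1 - pb) < maf_min:
                r2 = np.nan
            else:
                r2 = _haplotype_r2(ha, hb)
        else:
            da, db = D[:, a], D[:, b]
            ok = ~np.isnan(da) & ~np.isnan(db)
            pa, pb = da[ok].mean() / 2, db[ok].mean() / 2
            if min(pa, 1 - pa) < maf_min or min(pb, 1 - pb) < maf_min:
                r2 = np.nan
            else:
                with np.errstate(invalid="ignore"):
                    r = np.corrcoef(da[ok], db[ok])[0, 1]
                r2 = float(r * r)
        la = loci[a] if loci is not None else a
        lb = loci[b] if loci is not None else b
        c = gmap.distance_morgans(la, lb) if gmap is not None else np.nan
        recs.append((la, lb, c, r2))
    return pd.DataFrame(recs, columns=["locus_a", "locus_b", "c", "r2"])


def expected_r2(ne: float, c: float) -> float:
    """Sved's drift expectation E(r²) = 1 / (4·Ne·c + 2)."""
    if ne <= 0:
        raise ValueError("Ne must be positive")
    if c < 0:
        raise ValueError("genetic distance must be non-negative")
    return 1.0 / (4.0 * ne * c + 2.0)


def ne_from_ld(mean_r2: float, c: float) -> NeEstimate:
    """Invert Sved's formula: Ne = (1/(4c)) (1/r̄² − 2), horizon t = 1/(2c)."""
    if not (0.0 < mean_r2 <= 1.0):
        raise ValueError("mean r2 must be in (0, 1]")
    if c <= 0:
        raise ValueError("genetic distance must be positive")
    value = (1.0 / (4.0 * c)) * (1.0 / mean_r2 - 2.0)
    if value <= 0:
        raise ValueError(
            f"mean r2 = {mean_r2:.4f} >= 0.5 implies a non-positive Ne; "
            "the LD estimator is undefined here"
        )
    return NeEstimate(
        method="LD",
        value=value,
        t_generations_ago=generations_from_distance(c),
        inputs={"mean_r2": mean_r2, "c": c},
    )


def generations_from_distance(c: float) -> float:
    """Horizon of an LD-based Ne estimate: t = 1/(2c) generations ago."""
    if c <= 0:
        raise ValueError("genetic distance must be positive")
    return 1.0 / (2.0 * c)


def pedigree_inbreeding(pedigree: pd.DataFrame) -> pd.Series:
    """Inbreeding coefficient per animal (Meuwissen–Luo / tabular)."""
    ids, sire, dam = pedmod.ped_arrays(pedigree)
    F = pedmod.inbreeding(sire, dam)
    return pd.Series(F, index=ids, name="F")


def ne_from_inbreeding(f_by_generation: np.ndarray | list[float]) -> NeEstimate:
    """Ne from the realized inbreeding rate of the last two generations."""
    f = np.asarray(f_by_generation, dtype=float)
    if len(f) < 2:
        raise ValueError("need mean inbreeding for at least two generations")
    f_prev, f_last = f[-2], f[-1]
    delta = (f_last - f_prev) / (1.0 - f_prev)
    if delta <= 0:
        raise ValueError(
            f"ΔF = {delta:.4g} <= 0: diversity did not decrease, Ne undefined"
        )
    return NeEstimate(
        method="inbreeding",
        value=1.0 / (2.0 * delta),
        t_generations_ago=1.0,
        inputs={"F_n": f_last, "F_n_1": f_prev, "delta_F": delta},
    )


def mean_r2_at_distance(
    pop: Population,
    loci: np.ndarray,
    rows: np.ndarray | None = None,
    target_c: float = 0.1,
    window_frac: float = 0.05,
    maf_min: float = 0.05,
    max_pairs: int = 2000,
    per_chromosome: bool = False,
    seed: int = 0,
) -> float | dict[int, float]:
    """Mean r² over marker pairs ~``target_c`` Morgans apart.

    Pairs are drawn within chromosomes with distance in
    ``target_c * (1 ± window_frac)``; loci below the MAF filter are
    excluded.  ``per_chromosome=True`` returns per-chromosome means.
    """
    rng = np.random.default_rng(seed)
    H = pop.haplotypes if rows is None else pop.haplotypes[rows]
    gmap = pop.genome
    loci = np.asarray(loci)
    p = H[:, :, loci].mean(axis=(0, 1))
    ok = np.minimum(p, 1 - p) >= maf_min
    loci = loci[ok]

    lo, hi = target_c * (1 - window_frac), target_c * (1 + window_frac)
    by_chrom: dict[int, list[float]] = {}
    all_pairs: list[tuple[int, int, int]] = []
    for cidx in range(len(gmap.chrom_names)):
        on_c = loci[gmap.chrom[loci] == cidx]
        pos = gmap.pos_cm[on_c] / 100.0
        if len(on_c) < 2:
            continue
        # for each left locus, right partners inside the distance window
        j_lo = np.searchsorted(pos, pos + lo, side="left")
        j_hi = np.searchsorted(pos, pos + hi, side="right")
        for i in range(len(on_c)):
            for j in range(j_lo[i], j_hi[i]):
                all_pairs.append((cidx, on_c[i], on_c[j]))
    if not all_pairs:
        raise ValueError("no locus pairs in the requested distance window")
    if len(all_pairs) > max_pairs:
        sel = rng.choice(len(all_pairs), size=max_pairs, replace=False)
        all_pairs = [all_pairs[k] for k in sel]

    n, _, L = H.shape
    G = H.reshape(n * 2, L).astype(np.float32)
    for cidx, a, b in all_pairs:
        r2 = _haplotype_r2(G[:, a], G[:, b])
        if np.isfinite(r2):
            by_chrom.setdefault(cidx, []).append(r2)
    if per_chromosome:
        return {c: float(np.mean(v)) for c, v in by_chrom.items()}
    vals = [v for lst in by_chrom.values() for v in lst]
    return float(np.mean(vals))


def ne_ld_from_population(
    pop: Population,
    loci: np.ndarray,
    rows: np.ndarray | None = None,
    target_c: float = 0.1,
    **kwargs,
) -> NeEstimate:
    """Convenience wrapper: mean r² at ``target_c`` then Sved inversion."""
    r2bar = mean_r2_at_distance(pop, loci, rows=rows, target_c=target_c, **kwargs)
    return ne_from_ld(r2bar, target_c)
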