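"""LD-threshold haplotype blocks and pseudo-SNP encoding.

A haploblock is a run of >= 2 consecutive SNPs in strong mutual LD.
Blocks are found per chromosome from pairwise r² within a sliding window:
every interval [i..j] (up to ``window_snps`` long) in which each member
SNP is linked (r² >= threshold) to at least one other member and the mean
pairwise r² clears the same threshold is a candidate; a non-overlapping
subset maximizing the number of SNPs covered is then selected by
weighted-interval-scheduling dynamic programming.  This is a documented
approximation to clique-based LD blocking (same inputs, same output
contract: non-overlapping multi-SNP blocks); the stage is pluggable.

Each block's distinct haplotype alleles are re-coded as bi-allelic
"pseudo-SNPs": an individual's dosage at a pseudo-SNP is the number of
copies (0/1/2) of that haplotype allele it carries.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Haploblock",
    "PseudoSNPMatrix",
    "build_ld_blocks",
    "encode_pseudo_snps",
    "qc_pseudo_snps",
    "block_summary",
    "independent_snps",
]


@dataclass
class Haploblock:
    chromosome: int
    member_cols: np.ndarray            # column indices into the panel
    r2_threshold: float
    member_loci: np.ndarray | None = None   # genome-map locus ids
    alleles: list[str] = field(default_factory=list)

    @property
    def n_snps(self) -> int:
        return len(self.member_cols)


@dataclass
class PseudoSNPMatrix:
    """Pseudo-SNP dosages: individuals x pseudo-loci in {0,1,2}.

    Rows with imputed (missing-phase) contributions may be fractional and
    are listed in ``imputed_rows``.  Per individual and block, dosages over
    that block's pseudo-loci sum to 2.
    """

    dosages: np.ndarray
    origin_block: np.ndarray          # block index per pseudo-locus
    allele_label: list[str]
    imputed_rows: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def n_pseudo(self) -> int:
        return self.dosages.shape[1]

    @property
    def allele_freqs(self) -> np.ndarray:
        return self.dosages.mean(axis=0) / 2.0


def _gamete_matrix(phased: np.ndarray) -> np.ndarray:
    if phased.ndim != 3 or phased.shape[1] != 2:
        raise ValueError("phased input of shape (n, 2, loci) required; "
                         "unphased genotypes are rejected")
    n, _, L = phased.shape
    return phased.reshape(n * 2, L)


def _r2_matrix(G: np.ndarray) -> np.ndarray:
    """Pairwise r² between columns of a gamete matrix (monomorphic -> 0)."""
    X = G.astype(np.float64)
    X -= X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = np.inf
    X /= sd
    R = (X.T @ X) / X.shape[0]
    R2 = R * R
    np.fill_diagonal(R2, 0.0)
    return R2


def build_ld_blocks(
    phased: np.ndarray,
    r2_threshold: float,
    window_snps: int = 100,
    chrom: np.ndarray | None = None,
    loci: np.ndarray | None = None,
) -> list[Haploblock]:
    """Find non-overlapping multi-SNP LD blocks at the given r² threshold.

    ``phased``: (n, 2, m) allele array over the panel columns;
    ``chrom``: chromosome index per column (one chromosome assumed if None);
    ``loci``: optional genome-map ids per column, stored on the blocks.
    Ties in the interval selection are broken toward earlier start, then
    longer interval, so results are deterministic.
    """
    if not (0.0 < r2_threshold < 1.0):
        raise ValueError("r2_threshold must be in (0, 1)")
    G = _gamete_matrix(phased)
    m = G.shape[1]
    if chrom is None:
        chrom = np.zeros(m, dtype=int)
    blocks: list[Haploblock] = []
    for c in np.unique(chrom):
        cols = np.flatnonzero(chrom == c)
        if len(cols) < 2:
            continue
        R2 = _r2_matrix(G[:, cols])
        cands = _candidate_intervals(R2, r2_threshold, window_snps)
        chosen = _select_intervals(cands, len(cols))
        for s, e in chosen:
            mc = cols[s : e + 1]
            blocks.append(
                Haploblock(
                    chromosome=int(c),
                    member_cols=mc,
                    r2_threshold=r2_threshold,
                    member_loci=None if loci is None else np.asarray(loci)[mc],
                )
            )
    return blocks


def _candidate_intervals(
    R2: np.ndarray, thr: float, window: int
) -> list[tuple[int, int]]:
    """All intervals (>=2 SNPs, <=window) meeting both linkage conditions."""
    m = R2.shape[0]
    out = []
    for i in range(m - 1):
        hi = min(m, i + window)
        mx = np.zeros(hi - i)      # per-member max r² within the interval
        s = 0.0                    # sum of pairwise r²
        for j in range(i + 1, hi):
            col = R2[i:j, j]
            s += col.sum()
            k = j - i
            np.maximum(mx[:k], col, out=mx[:k])
            mx[k] = col.max()
            npairs = k * (k + 1) // 2
            if mx[: k + 1].min() >= thr and s / npairs >= thr:
                out.append((i, j))
    return out


def _select_intervals(
    cands: list[tuple[int, int]], m: int
) -> list[tuple[int, int]]:
    """Max-SNP-coverage non-overlapping subset (weighted interval DP)."""
    if not cands:
        return []
    by_end: dict[int, list[tuple[int, int]]] = {}
    for s, e in cands:
        by_end.setdefault(e, []).append((s, e))
    best = np.zeros(m + 1)
    pick: list[tuple[int, int] | None] = [None] * (m + 1)
    for j in range(1, m + 1):
        best[j] = best[j - 1]
        pick[j] = None
        for s, e in sorted(by_end.get(j - 1, []), key=lambda se: (se[0], -(se[1] - se[0]))):
            w = (e - s + 1) + best[s]
            if w > best[j]:
                best[j] = w
                pick[j] = (s, e)
    chosen = []
    j = m
    while j > 0:
        if pick[j] is None:
            j -= 1
        else:
            s, e = pick[j]
            chosen.append((s, e))
            j = s
    return sorted(chosen)


MISSING = 255  # allele code marking missing phase in a uint8 array


def encode_pseudo_snps(
    phased: np.ndarray, blocks: list[Haploblock]
) -> PseudoSNPMatrix:
    """One pseudo-locus per distinct haplotype allele per block.

    Alleles are enumerated among the provided (genotyped) individuals only.
    Gametes with missing phase inside a block contribute the block's allele
    frequencies instead of a hard count (mean imputation, flagged).
    """
    n = phased.shape[0]
    dose_cols: list[np.ndarray] = []
    origin: list[int] = []
    labels: list[str] = []
    imputed: set[int] = set()
    for b_idx, blk in enumerate(blocks):
        Gb = phased[:, :, blk.member_cols].reshape(n * 2, blk.n_snps)
        miss = (Gb == MISSING).any(axis=1)
        complete = Gb[~miss]
        if complete.shape[0] == 0:
            raise ValueError(f"block {b_idx}: no complete haplotypes to enumerate")
        alleles, inv = np.unique(complete, axis=0, return_inverse=True)
        k = alleles.shape[0]
        counts = np.zeros((n, k))
        gam_ind = np.repeat(np.arange(n), 2)[~miss]
        np.add.at(counts, (gam_ind, inv), 1.0)
        if miss.any():
            freq = np.bincount(inv, minlength=k) / len(inv)
            miss_per_ind = np.bincount(np.repeat(np.arange(n), 2)[miss], minlength=n)
            counts += miss_per_ind[:, None] * freq[None, :]
            imputed.update(np.flatnonzero(miss_per_ind).tolist())
        blk.alleles = ["".join(map(str, row)) for row in alleles]
        dose_cols.append(counts)
        origin.extend([b_idx] * k)
        labels.extend(blk.alleles)
    if not dose_cols:
        return PseudoSNPMatrix(
            dosages=np.zeros((n, 0)), origin_block=np.empty(0, dtype=int),
            allele_label=[],
        )
    return PseudoSNPMatrix(
        dosages=np.concatenate(dose_cols, axis=1),
        origin_block=np.asarray(origin),
        allele_label=labels,
        imputed_rows=np.asarray(sorted(imputed), dtype=int),
    )


def qc_pseudo_snps(
    ps: PseudoSNPMatrix, maf_min: float = 0.01, het_dev_max: float = 0.15
) -> tuple[PseudoSNPMatrix, dict]:
    """Same QC rules as for individual SNPs, per pseudo-locus.

    Each pseudo-locus is treated as bi-allelic (this haplotype allele vs
    all others) for the MAF and heterozygote-excess checks.
    """
    D = ps.dosages
    p = D.mean(axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    het_obs = (D == 1).mean(axis=0)
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
    out = PseudoSNPMatrix(
        dosages=D[:, keep],
        origin_block=ps.origin_block[keep],
        allele_label=[l for l, k in zip(ps.allele_label, keep) if k],
        imputed_rows=ps.imputed_rows,
    )
    return out, report


def independent_snps(n_panel: int, blocks: list[Haploblock]) -> np.ndarray:
    """Panel columns not captured by any block."""
    mask = np.ones(n_panel, dtype=bool)
    for blk in blocks:
        mask[blk.member_cols] = False
    return np.flatnonzero(mask)


def block_summary(
    blocks: list[Haploblock],
    ps_before_qc: PseudoSNPMatrix,
    ps_after_qc: PseudoSNPMatrix,
    n_snps_after_qc: int,
    elapsed_s: float | None = None,
) -> dict:
    """Per-scenario block statistics.

    ``n_snps_after_qc`` is the SNP-QC'd panel size; non-blocked SNPs plus
    QC'd pseudo-SNPs is the marker count entering combined predictions.
    """
    n_blocked = int(sum(b.n_snps for b in blocks))
    return {
        "n_blocks": len(blocks),
        "n_blocked_snps": n_blocked,
        "n_pseudo": int(ps_before_qc.n_pseudo),
        "n_pseudo_after_qc": int(ps_after_qc.n_pseudo),
        "n_nonblocked_plus_pseudo_after_qc": int(
            n_snps_after_qc - n_blocked + ps_after_qc.n_pseudo
        ),
        "elapsed_s": elapsed_s,
    }


def build_and_encode(
    phased: np.ndarray,
    r2_threshold: float,
    window_snps: int = 100,
    chrom: np.ndarray | None = None,
    loci: np.ndarray | None = None,
    maf_min: float = 0.01,
    het_dev_max: float = 0.15,
):
    """Blocking -> encoding -> pseudo-SNP QC, with wall time, in one call."""
    t0 = time.perf_counter()
    blocks = build_ld_blocks(phased, r2_threshold, window_snps, chrom, loci)
    ps = encode_pseudo_snps(phased, blocks)
    ps_qc, report = qc_pseudo_snps(ps, maf_min, het_dev_max)
    elapsed = time.perf_counter() - t0
    return blocks, ps, ps_qc, report, elapsed
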