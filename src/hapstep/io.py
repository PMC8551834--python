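"""Readers and writers for the pipeline's on-disk formats.

Simulated populations are exported as phased VCF 4.2 (GT like "0|1"),
pedigree CSV (id,sire,dam,sex,generation,breed; 0 = unknown parent) and
phenotype TSV (id,generation,phenotype,tbv).  User data enters the
pipeline the same way: a phased VCF (read with cyvcf2 when available),
a pedigree CSV and a phenotype TSV.  Every output directory carries a
manifest recording the seeds and configuration hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simpop import GenomeMap, Population

__all__ = [
    "write_phased_vcf",
    "read_phased_vcf",
    "write_pedigree_csv",
    "read_pedigree_csv",
    "write_phenotypes_tsv",
    "read_phenotypes_tsv",
    "write_blocks_tsv",
    "write_pseudo_dosages_tsv",
    "export_population",
    "write_manifest",
]


def write_phased_vcf(
    path, pop: Population, loci: np.ndarray | None = None,
    rows: np.ndarray | None = None,
) -> None:
    """Phased marker genotypes as VCF 4.2 (alleles A/B, GT pipe-separated)."""
    gmap = pop.genome
    loci = gmap.marker_idx if loci is None else np.asarray(loci)
    rows = np.arange(pop.n) if rows is None else np.asarray(rows)
    ids = pop.pedigree["id"].to_numpy()[rows]
    H = pop.haplotypes[rows][:, :, loci]
    pos_bp = gmap.pos_bp[loci]
    chrom = gmap.chrom[loci]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hapstep\n")
        for c, name in enumerate(gmap.chrom_names):
            length = int(gmap.chrom_lengths[c] / gmap.cM_per_Mb * 1e6)
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(f"ind{i}" for i in ids)
            + "\n"
        )
        for k in range(len(loci)):
            gts = "\t".join(
                f"{H[a, 0, k]}|{H[a, 1, k]}" for a in range(len(rows))
            )
            fh.write(
                f"{gmap.chrom_names[chrom[k]]}\t{pos_bp[k]}\tsnp{loci[k]}\t"
                f"A\tB\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_phased_vcf(path) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """Read a phased VCF into (haplotypes (n,2,m), variant table, sample names).

    Uses cyvcf2 when installed, falling back to a minimal text parser for
    plain uncompressed VCFs.
    """
    try:
        from cyvcf2 import VCF
    except ImportError:
        return _read_phased_vcf_text(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    h0, h1, rows = [], [], []
    for var in vcf:
        gts = np.array(var.genotypes)  # (n, 3): a0, a1, phased flag
        if not np.all(gts[:, 2]):
            raise ValueError(f"unphased genotype at {var.CHROM}:{var.POS}")
        h0.append(gts[:, 0])
        h1.append(gts[:, 1])
        rows.append((var.CHROM, var.POS, var.ID))
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "id"])
    H = np.stack(
        [np.array(h0, dtype=np.uint8).T, np.array(h1, dtype=np.uint8).T], axis=1
    )
    return H, variants, samples


def _read_phased_vcf_text(path):
    samples, h0, h1, rows = [], [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            parts = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = parts[9:]
                continue
            rows.append((parts[0], int(parts[1]), parts[2]))
            a0, a1 = [], []
            for g in parts[9:]:
                gt = g.split(":")[0]
                if "|" not in gt:
                    raise ValueError(f"unphased genotype at {parts[0]}:{parts[1]}")
                x, y = gt.split("|")
                a0.append(int(x))
                a1.append(int(y))
            h0.append(a0)
            h1.append(a1)
    H = np.stack(
        [np.array(h0, dtype=np.uint8).T, np.array(h1, dtype=np.uint8).T], axis=1
    )
    return H, pd.DataFrame(rows, columns=["chrom", "pos", "id"]), samples


def write_pedigree_csv(path, pop: Population) -> None:
    cols = ["id", "sire", "dam", "sex", "generation", "breed"]
    pop.pedigree[cols].to_csv(path, index=False)


def read_pedigree_csv(path) -> pd.DataFrame:
    ped = pd.read_csv(path)
    required = {"id", "sire", "dam"}
    if not required.issubset(ped.columns):
        raise ValueError(f"pedigree CSV needs columns {sorted(required)}")
    return ped


def write_phenotypes_tsv(path, pop: Population) -> None:
    pd.DataFrame(
        {
            "id": pop.pedigree["id"],
            "generation": pop.pedigree["generation"],
            "phenotype": pop.phenotype,
            "tbv": pop.tbv,
        }
    ).to_csv(path, sep="\t", index=False)


def read_phenotypes_tsv(path) -> pd.DataFrame:
    phe = pd.read_csv(path, sep="\t")
    if "id" not in phe.columns or "phenotype" not in phe.columns:
        raise ValueError("phenotype TSV needs at least 'id' and 'phenotype'")
    return phe


def write_blocks_tsv(path, blocks, gmap: GenomeMap | None = None) -> None:
    """BED-like block table: chrom, start_bp, end_bp, n_snps, n_alleles, thr."""
    rows = []
    for b in blocks:
        if gmap is not None and b.member_loci is not None:
            start = int(gmap.pos_bp[b.member_loci[0]])
            end = int(gmap.pos_bp[b.member_loci[-1]])
            name = gmap.chrom_names[b.chromosome]
        else:
            start, end = int(b.member_cols[0]), int(b.member_cols[-1])
            name = str(b.chromosome)
        rows.append((name, start, end, b.n_snps, len(b.alleles), b.r2_threshold))
    pd.DataFrame(
        rows,
        columns=["chrom", "start_bp", "end_bp", "n_snps", "n_alleles", "r2_threshold"],
    ).to_csv(path, sep="\t", index=False)


def write_pseudo_dosages_tsv(path, ps, ids: np.ndarray) -> None:
    """Pseudo-SNP dosage matrix with synthetic ids PS_<block>_<k>."""
    names = []
    counter: dict[int, int] = {}
    for blk in ps.origin_block:
        k = counter.get(blk, 0)
        counter[blk] = k + 1
        names.append(f"PS_{blk}_{k}")
    df = pd.DataFrame(ps.dosages, columns=names)
    df.insert(0, "id", ids)
    df.to_csv(path, sep="\t", index=False)


def export_population(outdir, pop: Population, loci=None) -> dict:
    """VCF + pedigree CSV + phenotype TSV under ``outdir``; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "pedigree": outdir / "pedigree.csv",
        "phenotypes": outdir / "phenotypes.tsv",
    }
    write_phased_vcf(paths["vcf"], pop, loci=loci)
    write_pedigree_csv(paths["pedigree"], pop)
    write_phenotypes_tsv(paths["phenotypes"], pop)
    return {k: str(v) for k, v in paths.items()}


def write_manifest(outdir, seed: int, config) -> str:
    """Record the seed and a hash of the configuration next to the outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        config = dataclasses.asdict(config)
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "seed": seed,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "config": config,
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return str(path)
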