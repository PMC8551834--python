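"""Training/validation design, the scenario grid, and accuracy/bias metrics.

The evaluation design mirrors a population-specific genetic evaluation:
phenotypes from the first eight generations of the EBV-selection phase
train the model (a subset of generations four to seven also contributes
genotypes), generation eight is a genotype gap, and GEBVs are validated
against true breeding values in genotyped but unphenotyped animals from
generations nine and ten.

Eleven marker configurations are evaluated per population and
heritability: HD-panel SNPs, medium-panel SNPs, independent SNPs plus
pseudo-SNPs from LD blocks (thresholds 0.1/0.3/0.6) in one G, pseudo-SNPs
alone, and independent plus pseudo-SNPs in two uncorrelated genetic
components.  Accuracy is the Pearson correlation r(GEBV, TBV) in the
validation set; dispersion bias is b1 - 1 from TBV = b0 + b1 * GEBV.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import haploblocks as hb
from . import pedigree as pedmod
from . import simpop as sp
from . import ssgblup as ss

__all__ = [
    "SplitSpec",
    "Split",
    "ScenarioDescriptor",
    "PredictionResult",
    "PipelineConfig",
    "SCENARIO_IDS",
    "split_training_validation",
    "scenario_grid",
    "accuracy",
    "bias",
    "prepare_replicate",
    "run_scenario",
    "summarize_replicates",
    "paired_comparison",
    "pedigree_reml_heritability",
]

SCENARIO_IDS = (
    "SNP_HD", "SNP_MD",
    "IPS_LD01", "IPS_LD03", "IPS_LD06",
    "PS_LD01", "PS_LD03", "PS_LD06",
    "IPS_2H_LD01", "IPS_2H_LD03", "IPS_2H_LD06",
)

_THRESHOLDS = {"LD01": 0.1, "LD03": 0.3, "LD06": 0.6}


@dataclass(frozen=True)
class SplitSpec:
    """Counts and generation windows of the training/validation design.

    Generations are relative to the EBV-selection phase (1..10); the gap
    generation contributes phenotypes but no genotypes.
    """

    n_pheno_train: int
    n_geno_train: int
    n_validation: int
    train_pheno_generations: tuple[int, ...] = tuple(range(1, 9))
    geno_train_generations: tuple[int, ...] = tuple(range(4, 8))
    validation_generations: tuple[int, ...] = (9, 10)
    gap_generation: int = 8
    seed: int = 0


@dataclass
class Split:
    pheno_train_rows: np.ndarray    # rows into the population
    geno_train_rows: np.ndarray
    validation_rows: np.ndarray
    relative_generation: np.ndarray  # per population row; 0 outside EBV phase


@dataclass(frozen=True)
class ScenarioDescriptor:
    scenario_id: str
    population: str
    heritability_level: str
    variant: str          # snp_single_G | snp_plus_pseudo_single_G | pseudo_only | two_G
    panel: str            # hd | medium
    r2_threshold: float | None


@dataclass
class PredictionResult:
    scenario_id: str
    population: str
    heritability_level: str
    replicate: int
    status: str                      # ok | failed_convergence | skipped_poor_G
    accuracy: float = np.nan
    bias: float = np.nan
    sigma_g: tuple = ()
    sigma_e: float = np.nan
    n_markers: int = 0
    detail: str = ""


@dataclass(frozen=True)
class PipelineConfig:
    alpha: float = 0.95
    beta: float = 0.05
    tau: float = 1.0
    omega: float = 1.0
    maf_min: float = 0.01
    het_dev_max: float = 0.15
    missing_rate: float = 0.05
    error_rate: float = 0.01
    window_snps: int = 100
    compat_threshold: float = 0.30
    reml_max_rounds: int = 25
    reml_tol: float = 1e-6
    pcg_tol: float = 1e-12
    pcg_maxiter: int = 5000


# ---------------------------------------------------------------------------
# split and grid
# ---------------------------------------------------------------------------


def ebv_phase_generations(pop: sp.Population, n_ebv_gens: int | None = None) -> np.ndarray:
    """Relative generation (1..n) within the EBV phase; 0 elsewhere.

    By default every EBV-selection generation counts; ``n_ebv_gens`` keeps
    only the last n.
    """
    gen = pop.pedigree["generation"].to_numpy()
    phase = pop.pedigree["phase"].to_numpy()
    ebv_gens = np.unique(gen[phase == "ebv_sel"])
    rel = np.zeros(pop.n, dtype=int)
    if len(ebv_gens) == 0:
        raise ValueError("population has no EBV-selection phase")
    n_keep = len(ebv_gens) if n_ebv_gens is None else n_ebv_gens
    start = ebv_gens.max() - n_keep + 1
    in_phase = (gen >= start) & (phase == "ebv_sel")
    rel[in_phase] = gen[in_phase] - start + 1
    return rel


def split_training_validation(pop: sp.Population, spec: SplitSpec) -> Split:
    """Seeded random sampling of the training and validation cohorts.

    Validation animals are genotyped but their phenotypes are masked for
    every downstream analysis; training genotypes come from the configured
    generation window, never from the gap generation.
    """
    rng = np.random.default_rng(spec.seed)
    rel = ebv_phase_generations(pop)

    def _sample(gens, k, exclude=None):
        cand = np.flatnonzero(np.isin(rel, gens))
        if exclude is not None:
            cand = np.setdiff1d(cand, exclude, assume_unique=False)
        if k > len(cand):
            raise ValueError(
                f"requested {k} animals but only {len(cand)} available in "
                f"generations {gens}"
            )
        return np.sort(rng.choice(cand, size=k, replace=False))

    pheno = _sample(spec.train_pheno_generations, spec.n_pheno_train)
    geno = _sample(spec.geno_train_generations, spec.n_geno_train)
    valid = _sample(spec.validation_generations, spec.n_validation)
    if np.intersect1d(valid, pheno).size or np.intersect1d(valid, geno).size:
        raise AssertionError("validation overlaps training")
    return Split(
        pheno_train_rows=pheno, geno_train_rows=geno, validation_rows=valid,
        relative_generation=rel,
    )


def scenario_grid(
    populations: list[str],
    h2_levels: list[str],
    scenario_ids: tuple[str, ...] = SCENARIO_IDS,
) -> list[ScenarioDescriptor]:
    """Cross product of marker configurations, heritabilities, populations."""
    out = []
    for pop_name in populations:
        for h2 in h2_levels:
            for sid in scenario_ids:
                out.append(_descriptor(sid, pop_name, h2))
    return out


def _descriptor(sid: str, population: str, h2: str) -> ScenarioDescriptor:
    if sid == "SNP_HD":
        variant, panel, thr = "snp_single_G", "hd", None
    elif sid == "SNP_MD":
        variant, panel, thr = "snp_single_G", "medium", None
    else:
        kind, ld = sid.rsplit("_LD", 1)
        thr = _THRESHOLDS["LD" + ld]
        panel = "medium"
        variant = {
            "IPS": "snp_plus_pseudo_single_G",
            "PS": "pseudo_only",
            "IPS_2H": "two_G",
        }[kind]
    return ScenarioDescriptor(
        scenario_id=sid, population=population, heritability_level=h2,
        variant=variant, panel=panel, r2_threshold=thr,
    )


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def accuracy(gebv: np.ndarray, tbv: np.ndarray) -> float:
    """Pearson correlation of GEBV with TBV in the validation set."""
    gebv, tbv = np.asarray(gebv, float), np.asarray(tbv, float)
    if len(gebv) < 3:
        raise ValueError("need at least 3 validation animals")
    if np.std(gebv) == 0 or np.std(tbv) == 0:
        raise ValueError("zero variance: accuracy undefined")
    return float(np.corrcoef(gebv, tbv)[0, 1])


def bias(gebv: np.ndarray, tbv: np.ndarray) -> float:
    """Dispersion bias: OLS slope of TBV on GEBV, minus one.

    Negative values indicate over-dispersed (inflated) GEBVs.
    """
    gebv, tbv = np.asarray(gebv, float), np.asarray(tbv, float)
    if len(gebv) < 3:
        raise ValueError("need at least 3 validation animals")
    g = gebv - gebv.mean()
    ss_g = float(g @ g)
    if ss_g == 0:
        raise ValueError("zero GEBV variance: bias undefined")
    b1 = float(g @ (tbv - tbv.mean())) / ss_g
    return b1 - 1.0


def pedigree_reml_heritability(pop: sp.Population, start=(30.0, 70.0),
                               tol: float = 1e-8):
    """Realized heritability: pedigree REML on the EBV-phase phenotypes.

    Phenotypes come from the EBV-selection generations (the recent
    population); the relationship matrix uses the breed's whole pedigree
    back to its founders, so the base population is the unselected founder
    cohort and selection in between is accounted for.  ``start`` only sets
    the REML starting values.
    """
    rel = ebv_phase_generations(pop)
    obs = np.flatnonzero(rel > 0)
    _, s_idx, d_idx = pedmod.ped_arrays(pop.pedigree[["id", "sire", "dam"]])
    F = pop.F if len(pop.F) == pop.n else pedmod.inbreeding(s_idx, d_idx)
    a_inv = pedmod.a_inverse_sparse(s_idx, d_idx, F)
    X, _ = ss.fixed_effects_design(rel[obs])
    return ss.estimate_varcomps(
        pop.phenotype[obs], X, obs, [a_inv], pop.n,
        start=(np.array([start[0]]), start[1]), tol=tol,
    )


# ---------------------------------------------------------------------------
# replicate preparation (everything shared across scenarios)
# ---------------------------------------------------------------------------


@dataclass
class ReplicateData:
    """Per-replicate products shared by all scenarios of one population."""

    pop: sp.Population
    split: Split
    config: PipelineConfig
    replicate: int
    # evaluation pedigree (EBV phase only), parents outside set as unknown
    eval_rows: np.ndarray
    A_inv: "object"
    F_eval: np.ndarray
    geno_eval_pos: np.ndarray        # genotyped positions within eval ordering
    A22: np.ndarray
    A22_inv: np.ndarray
    # genotype products
    hd_geno: sp.GenotypeMatrix       # after QC
    med_cols: np.ndarray             # columns of hd_geno forming the medium panel
    phased_med: np.ndarray           # true-phase haplotypes, genotyped set x medium loci
    med_chrom: np.ndarray
    y_train: np.ndarray
    train_records: np.ndarray        # positions within eval ordering
    gen_class: np.ndarray
    valid_pos: np.ndarray            # validation positions within eval ordering
    tbv_valid: np.ndarray
    block_cache: dict = field(default_factory=dict)
    block_stats: list = field(default_factory=list)
    start_values: tuple | None = None  # (sigma_g, sigma_e) warm start


def prepare_replicate(
    pop: sp.Population,
    split_spec: SplitSpec,
    seed: int,
    config: PipelineConfig = PipelineConfig(),
    replicate: int = 0,
    n_medium: int | None = None,
) -> ReplicateData:
    """Build the shared per-replicate products.

    Genotyping noise is applied once on the HD panel; the medium panel is
    a within-chromosome random subset of it.  Blocking uses the true
    phase of the genotyped animals (training + validation jointly).
    """
    ss_seq = np.random.SeedSequence(seed)
    s_split, s_panel, s_geno, s_med = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss_seq.spawn(4)
    )
    split = split_training_validation(
        pop, dataclasses.replace(split_spec, seed=s_split)
    )
    geno_rows = np.concatenate([split.geno_train_rows, split.validation_rows])

    # evaluation pedigree: the EBV phase (relative generations 1..10)
    rel = split.relative_generation
    eval_rows = np.flatnonzero(rel > 0)
    ped = pop.pedigree.iloc[eval_rows]
    in_set = set(ped["id"].to_numpy().tolist())
    sub = pd.DataFrame(
        {
            "id": ped["id"].to_numpy(),
            "sire": ped["sire"].where(ped["sire"].isin(in_set), 0).to_numpy(),
            "dam": ped["dam"].where(ped["dam"].isin(in_set), 0).to_numpy(),
        }
    )
    _, s_idx, d_idx = pedmod.ped_arrays(sub)
    F_eval = pedmod.inbreeding(s_idx, d_idx)
    A_inv = pedmod.a_inverse_sparse(s_idx, d_idx, F_eval)

    pos_of_row = {r: i for i, r in enumerate(eval_rows)}
    geno_eval_pos = np.array([pos_of_row[r] for r in geno_rows])
    A22 = pedmod.a_submatrix(s_idx, d_idx, geno_eval_pos, F=F_eval)
    A22_inv = np.linalg.inv(A22)

    # genotypes: HD observation -> QC; medium = subset of QC'd HD columns
    hd_loci = sp.hd_panel(pop)
    hd_raw = sp.apply_genotyping(
        pop, hd_loci, rows=geno_rows,
        missing_rate=config.missing_rate, error_rate=config.error_rate,
        seed=s_geno,
    )
    hd_qc, _ = sp.qc_variants(hd_raw, config.maf_min, config.het_dev_max)
    n_med = n_medium if n_medium is not None else len(hd_loci) // 3
    med_loci = sp.sample_medium_panel(pop.genome, hd_qc.loci, n_med, s_med)
    med_cols = np.searchsorted(hd_qc.loci, med_loci)

    phased_med = pop.haplotypes[np.ix_(geno_rows, [0, 1], med_loci)]
    med_chrom = pop.genome.chrom[med_loci]

    y_all = pop.phenotype
    train_records = np.array([pos_of_row[r] for r in split.pheno_train_rows])
    valid_pos = np.array([pos_of_row[r] for r in split.validation_rows])

    # pedigree-only REML supplies warm-start variance components for every
    # scenario of this replicate (they differ little across marker sets)
    y_train = y_all[split.pheno_train_rows]
    gen_class = rel[split.pheno_train_rows]
    X0, _ = ss.fixed_effects_design(gen_class)
    vc0 = ss.estimate_varcomps(
        y_train, X0, train_records, [A_inv], len(eval_rows),
        max_rounds=config.reml_max_rounds, tol=1e-4,
    )
    start = (float(vc0.sigma_g[0]), float(vc0.sigma_e)) if vc0.converged else None
    return ReplicateData(
        pop=pop, split=split, config=config, replicate=replicate,
        eval_rows=eval_rows, A_inv=A_inv, F_eval=F_eval,
        geno_eval_pos=geno_eval_pos, A22=A22, A22_inv=A22_inv,
        hd_geno=hd_qc, med_cols=med_cols,
        phased_med=phased_med, med_chrom=med_chrom,
        y_train=y_train,
        train_records=train_records,
        gen_class=gen_class,
        valid_pos=valid_pos,
        tbv_valid=pop.tbv[split.validation_rows],
        start_values=start,
    )


def _blocks_for(data: ReplicateData, thr: float):
    """Blocking+encoding per threshold, cached across model variants."""
    if thr not in data.block_cache:
        cfg = data.config
        blocks, ps, ps_qc, report, elapsed = hb.build_and_encode(
            data.phased_med, thr, cfg.window_snps, chrom=data.med_chrom,
            maf_min=cfg.maf_min, het_dev_max=cfg.het_dev_max,
        )
        summary = hb.block_summary(
            blocks, ps, ps_qc, n_snps_after_qc=len(data.med_cols),
            elapsed_s=elapsed,
        )
        summary["r2_threshold"] = thr
        data.block_stats.append(summary)
        indep = hb.independent_snps(len(data.med_cols), blocks)
        data.block_cache[thr] = (blocks, ps_qc, indep)
    return data.block_cache[thr]


# ---------------------------------------------------------------------------
# scenario execution
# ---------------------------------------------------------------------------


def run_scenario(
    desc: ScenarioDescriptor, data: ReplicateData
) -> PredictionResult:
    """QC -> (blocking/encoding) -> matrices -> REML -> MME -> metrics.

    Upstream failures map to an explicit status, never to silence: poor
    pedigree-genomic compatibility or an empty marker set skips the
    scenario; REML non-convergence flags it.
    """
    cfg = data.config
    res = PredictionResult(
        scenario_id=desc.scenario_id, population=desc.population,
        heritability_level=desc.heritability_level, replicate=data.replicate,
        status="ok",
    )

    # marker sets for this variant
    med_dosages = data.hd_geno.dosages[:, data.med_cols]
    sets: list[np.ndarray] = []
    if desc.variant == "snp_single_G":
        sets = [data.hd_geno.dosages if desc.panel == "hd" else med_dosages]
    else:
        blocks, ps_qc, indep = _blocks_for(data, desc.r2_threshold)
        if ps_qc.n_pseudo == 0:
            res.status = "skipped_poor_G"
            res.detail = "no pseudo-SNPs at this LD threshold"
            return res
        if desc.variant == "pseudo_only":
            sets = [ps_qc.dosages]
        elif desc.variant == "snp_plus_pseudo_single_G":
            sets = [np.hstack([med_dosages[:, indep], ps_qc.dosages])]
        elif desc.variant == "two_G":
            if len(indep) == 0:
                res.status = "skipped_poor_G"
                res.detail = "no independent SNPs left for the two-matrix model"
                return res
            sets = [med_dosages[:, indep], ps_qc.dosages]
    res.n_markers = int(sum(s.shape[1] for s in sets))

    # one H-inverse per genetic component
    k_invs = []
    for dos in sets:
        try:
            design = ss.build_marker_design(dos)
            G = ss.tune_g(ss.g_matrix(design), data.A22)
            Gb, Gb_inv = ss.blend_and_invert(G, data.A22, cfg.alpha, cfg.beta)
        except (ValueError, np.linalg.LinAlgError) as exc:
            res.status = "skipped_poor_G"
            res.detail = str(exc)
            return res
        compat = ss.compatibility_stats(Gb, data.A22, cfg.compat_threshold)
        if compat["poor_genomic_info"]:
            res.status = "skipped_poor_G"
            res.detail = (
                f"off-diagonal corr(G_b, A22) = {compat['corr_offdiag']:.3f} "
                f"< {cfg.compat_threshold}"
            )
            return res
        k_invs.append(
            ss.h_inverse(
                data.A_inv, data.A22_inv, Gb_inv, data.geno_eval_pos,
                cfg.tau, cfg.omega,
            )
        )

    # variance components then solutions
    n_eval = data.A_inv.shape[0]
    X, _ = ss.fixed_effects_design(data.gen_class)
    start = None
    if data.start_values is not None:
        sg0, se0 = data.start_values
        start = (np.full(len(k_invs), sg0 / len(k_invs)), se0)
    vc = ss.estimate_varcomps(
        data.y_train, X, data.train_records, k_invs, n_eval,
        start=start, max_rounds=cfg.reml_max_rounds, tol=cfg.reml_tol,
    )
    res.sigma_g = tuple(float(x) for x in vc.sigma_g)
    res.sigma_e = float(vc.sigma_e)
    if not vc.converged or vc.at_boundary:
        res.status = "failed_convergence"
        res.detail = (
            "variance estimate at boundary" if vc.at_boundary
            else f"REML stopped after {vc.n_rounds} rounds"
        )
        return res

    sol = ss.solve_mme(
        data.y_train, X, data.train_records, k_invs,
        vc.sigma_g, vc.sigma_e, n_eval,
        tol=cfg.pcg_tol, maxiter=cfg.pcg_maxiter,
    )
    if not sol.converged:
        res.status = "failed_convergence"
        res.detail = f"PCG residual {sol.final_residual_norm:.2e}"
        return res
    gebv_valid = sol.gebv[data.valid_pos]
    try:
        res.accuracy = accuracy(gebv_valid, data.tbv_valid)
        res.bias = bias(gebv_valid, data.tbv_valid)
    except ValueError as exc:
        res.status = "failed_convergence"
        res.detail = str(exc)
    return res


# ---------------------------------------------------------------------------
# replicate-level reporting
# ---------------------------------------------------------------------------


def results_frame(results: list[PredictionResult]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in results])


def summarize_replicates(results: list[PredictionResult] | pd.DataFrame) -> pd.DataFrame:
    """Mean and SE of accuracy/bias per scenario; failures counted apart."""
    df = results if isinstance(results, pd.DataFrame) else results_frame(results)
    ok = df[df["status"] == "ok"]
    rows = []
    for key, grp in df.groupby(["population", "heritability_level", "scenario_id"]):
        g_ok = ok[
            (ok["population"] == key[0])
            & (ok["heritability_level"] == key[1])
            & (ok["scenario_id"] == key[2])
        ]
        n = len(g_ok)
        rec = {
            "population": key[0], "heritability_level": key[1],
            "scenario_id": key[2], "n_ok": n,
            "n_failed": int((grp["status"] != "ok").sum()),
        }
        for metric in ("accuracy", "bias"):
            vals = g_ok[metric].to_numpy()
            rec[f"{metric}_mean"] = float(np.mean(vals)) if n else np.nan
            rec[f"{metric}_se"] = (
                float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else np.nan
            )
        rows.append(rec)
    return pd.DataFrame(rows)


def paired_comparison(
    results: list[PredictionResult] | pd.DataFrame,
    scenario_a: str,
    scenario_b: str,
    metric: str = "accuracy",
) -> dict:
    """Paired t-test across replicates (convenience only; the full
    covariance-structure model comparison is out of scope)."""
    df = results if isinstance(results, pd.DataFrame) else results_frame(results)
    a = df[(df["scenario_id"] == scenario_a) & (df["status"] == "ok")]
    b = df[(df["scenario_id"] == scenario_b) & (df["status"] == "ok")]
    merged = a.merge(b, on=["population", "heritability_level", "replicate"], suffixes=("_a", "_b"))
    if len(merged) < 2:
        return {"n": len(merged), "t": np.nan, "p": np.nan}
    t, p = stats.ttest_rel(merged[f"{metric}_a"], merged[f"{metric}_b"])
    return {"n": len(merged), "t": float(t), "p": float(p),
            "mean_diff": float((merged[f"{metric}_a"] - merged[f"{metric}_b"]).mean())}
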