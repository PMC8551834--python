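"""Single-step GBLUP: relationship matrices, MME solving, AI-REML.

The single-step evaluation replaces the pedigree relationship matrix A of
the animal model y = Xb + Zu + e, u ~ N(0, H sigma_g^2), with a hybrid H
combining pedigree and genomic information.  Its inverse is sparse apart
from a dense block over the genotyped animals:

    H^-1 = A^-1 + [0 0; 0  tau*(alpha G + beta A22)^-1 - omega*A22^-1]

G is VanRaden's method-1 matrix, G = M M' / (2 sum p_i (1 - p_i)) with M
the 2p-centered dosage matrix.  The two-matrix variant fits two
uncorrelated genetic components (independent SNPs; pseudo-SNPs), each
with its own H, and the overall GEBV is u1 + u2.

Mixed-model equations are solved by Jacobi-preconditioned conjugate
gradients; variance components by average-information REML with an EM
fallback whenever an AI update leaves the parameter space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import sparse

from . import pedigree as pedmod

__all__ = [
    "MarkerDesign",
    "SolveReport",
    "VarCompResult",
    "a_matrix",
    "a_inverse",
    "a22_matrix",
    "build_marker_design",
    "g_matrix",
    "tune_g",
    "blend_and_invert",
    "h_inverse",
    "compatibility_stats",
    "make_incidence",
    "solve_mme",
    "estimate_varcomps",
]


# ---------------------------------------------------------------------------
# pedigree-side matrices
# ---------------------------------------------------------------------------


def a_matrix(pedigree: pd.DataFrame, subset_ids=None) -> np.ndarray:
    """Dense numerator relationship matrix (tabular method).

    With ``subset_ids`` the block for those animals is extracted by
    Colleau's indirect method, never forming the full matrix.
    """
    ids, sire, dam = pedmod.ped_arrays(pedigree)
    if subset_ids is None:
        return pedmod.a_tabular(sire, dam)
    rows = _rows_for(ids, subset_ids)
    return pedmod.a_submatrix(sire, dam, rows)


def a_inverse(pedigree: pd.DataFrame, F: np.ndarray | None = None) -> sparse.csr_matrix:
    """Sparse A-inverse by Henderson's rules with inbreeding."""
    _, sire, dam = pedmod.ped_arrays(pedigree)
    return pedmod.a_inverse_sparse(sire, dam, F=F)


def a22_matrix(pedigree: pd.DataFrame, genotyped_ids, F: np.ndarray | None = None) -> np.ndarray:
    """Dense pedigree relationship block among the genotyped animals."""
    ids, sire, dam = pedmod.ped_arrays(pedigree)
    rows = _rows_for(ids, genotyped_ids)
    return pedmod.a_submatrix(sire, dam, rows, F=F)


def _rows_for(ids: np.ndarray, wanted) -> np.ndarray:
    pos = pd.Series(np.arange(len(ids)), index=ids)
    rows = pos.reindex(np.asarray(wanted))
    if rows.isna().any():
        missing = np.asarray(wanted)[rows.isna().to_numpy()]
        raise KeyError(f"ids not in pedigree: {missing[:5]}...")
    return rows.to_numpy().astype(int)


# ---------------------------------------------------------------------------
# genomic matrices
# ---------------------------------------------------------------------------


@dataclass
class MarkerDesign:
    """Centered dosage matrix and its VanRaden scale."""

    M: np.ndarray       # individuals x markers, centered by 2p
    p: np.ndarray       # allele frequencies used for centering
    scale: float        # 2 sum p_i (1 - p_i)


def build_marker_design(
    dosages: np.ndarray, p: np.ndarray | None = None
) -> MarkerDesign:
    """Mean-impute missing dosages (to 2p) and center by 2p.

    Frequencies default to the current genotyped set (the blending
    software's default behavior).
    """
    D = np.asarray(dosages, dtype=float)
    D = D.copy()
    D[D < 0] = np.nan
    if p is None:
        with np.errstate(invalid="ignore"):
            p = np.nanmean(D, axis=0) / 2.0
    idx = np.where(np.isnan(D))
    D[idx] = 2.0 * p[idx[1]]
    scale = float(2.0 * np.sum(p * (1.0 - p)))
    if scale <= 0:
        raise ValueError("all markers monomorphic: VanRaden scale is zero")
    return MarkerDesign(M=D - 2.0 * p, p=p, scale=scale)


def g_matrix(design: MarkerDesign) -> np.ndarray:
    """VanRaden method-1 genomic relationship matrix G = MM'/(2 sum p q)."""
    return (design.M @ design.M.T) / design.scale


def tune_g(G_raw: np.ndarray, A22: np.ndarray) -> np.ndarray:
    """Rescale G so its mean diagonal and off-diagonal match A22.

    Solves a + b*mean(off(G)) = mean(off(A22)) and a + b*mean(diag(G)) =
    mean(diag(A22)) and returns a + b*G.  This is the standard
    compatibility adjustment that puts the genomic matrix on the pedigree
    base before blending; without it, allele frequencies estimated from a
    selected, genotyped subset shift G's base and the single-step
    likelihood degenerates (genetic variance driven to the boundary).
    """
    iu = np.triu_indices_from(G_raw, k=1)
    dg, da = float(np.diag(G_raw).mean()), float(np.diag(A22).mean())
    og, oa = float(G_raw[iu].mean()), float(A22[iu].mean())
    if abs(dg - og) < 1e-12:
        raise ValueError("degenerate G: diagonal equals off-diagonal mean")
    b = (da - oa) / (dg - og)
    a = oa - b * og
    return a + b * G_raw


def blend_and_invert(
    G_raw: np.ndarray,
    A22: np.ndarray,
    alpha: float = 0.95,
    beta: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """G_b = alpha G + beta A22, with its dense inverse (PD enforced)."""
    if abs(alpha + beta - 1.0) > 1e-9:
        raise ValueError("alpha + beta must equal 1")
    Gb = alpha * G_raw + beta * A22
    try:
        cf = sla.cho_factor(Gb, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        w = sla.eigvalsh(Gb, subset_by_index=[0, 0], check_finite=False)
        raise np.linalg.LinAlgError(
            f"blended G not positive definite (min eigenvalue {w[0]:.3e})"
        )
    Gb_inv = sla.cho_solve(cf, np.eye(Gb.shape[0]), check_finite=False)
    return Gb, Gb_inv


def h_inverse(
    A_inv: sparse.spmatrix,
    A22_inv: np.ndarray,
    Gb_inv: np.ndarray,
    geno_rows: np.ndarray,
    tau: float = 1.0,
    omega: float = 1.0,
) -> sparse.csr_matrix:
    """H-inverse: A-inverse plus the genotyped-block augmentation.

    ``geno_rows`` give the positions of the genotyped animals within the
    pedigree ordering of ``A_inv``.
    """
    q = A_inv.shape[0]
    geno_rows = np.asarray(geno_rows)
    block = tau * Gb_inv - omega * A22_inv
    r = np.repeat(geno_rows, len(geno_rows))
    c = np.tile(geno_rows, len(geno_rows))
    aug = sparse.coo_matrix((block.ravel(), (r, c)), shape=(q, q))
    return (A_inv.tocsr() + aug.tocsr()).tocsr()


def compatibility_stats(G_b: np.ndarray, A22: np.ndarray, flag_threshold: float = 0.30) -> dict:
    """Element-wise agreement between the genomic and pedigree blocks.

    A low off-diagonal correlation signals genomic information too poor to
    anchor to the pedigree (such scenarios are skipped downstream).
    """
    iu = np.triu_indices_from(G_b, k=1)
    dg, da = np.diag(G_b), np.diag(A22)
    og, oa = G_b[iu], A22[iu]

    def _corr(x, y):
        if np.std(x) == 0 or np.std(y) == 0:
            return np.nan
        return float(np.corrcoef(x, y)[0, 1])

    off = _corr(og, oa)
    return {
        "corr_diag": _corr(dg, da),
        "corr_offdiag": off,
        "corr_all": _corr(
            np.concatenate([dg, og]), np.concatenate([da, oa])
        ),
        "g_diag_mean": float(dg.mean()),
        "g_diag_min": float(dg.min()),
        "g_diag_max": float(dg.max()),
        "poor_genomic_info": bool(not np.isfinite(off) or off < flag_threshold),
        "flag_threshold": flag_threshold,
    }


# ---------------------------------------------------------------------------
# mixed-model equations
# ---------------------------------------------------------------------------


@dataclass
class SolveReport:
    b: np.ndarray
    u: list[np.ndarray]
    gebv: np.ndarray
    iterations: int
    converged: bool
    final_residual_norm: float


@dataclass
class VarCompResult:
    sigma_g: np.ndarray       # one entry per genetic component
    sigma_e: float
    converged: bool
    n_rounds: int
    at_boundary: bool
    ai_degenerate: bool = False
    history: list[np.ndarray] = field(default_factory=list)

    @property
    def h2(self) -> float:
        tot = float(self.sigma_g.sum() + self.sigma_e)
        return float(self.sigma_g.sum() / tot)


def make_incidence(levels: np.ndarray, n_cols: int | None = None) -> sparse.csr_matrix:
    """0/1 incidence matrix mapping records to effect levels."""
    n = len(levels)
    n_cols = n_cols if n_cols is not None else int(levels.max()) + 1
    return sparse.csr_matrix(
        (np.ones(n), (np.arange(n), levels)), shape=(n, n_cols)
    )


def fixed_effects_design(gen_class: np.ndarray) -> tuple[sparse.csr_matrix, np.ndarray]:
    """Generation-class design, first class absorbed into the intercept."""
    levels, idx = np.unique(gen_class, return_inverse=True)
    n = len(gen_class)
    cols = [np.ones((n, 1))]
    for k in range(1, len(levels)):
        cols.append((idx == k).astype(float)[:, None])
    X = sparse.csr_matrix(np.hstack(cols))
    return X, levels


def _assemble_mme(y, X, Z, k_inv_list, sigma_g, sigma_e, dense=False):
    """Variance-scaled Henderson system: C s = rhs (C^-1 = solution covariance)."""
    X = sparse.csr_matrix(X)
    blocks_w = [X] + [Z] * len(k_inv_list)
    W = sparse.hstack(blocks_w).tocsr()
    C = (W.T @ W) / sigma_e
    offset = X.shape[1]
    q = Z.shape[1]
    K_big = sparse.block_diag(
        [sparse.csr_matrix((offset, offset))]
        + [Ki / sg for Ki, sg in zip(k_inv_list, sigma_g)]
    )
    C = (C + K_big).tocsr()
    rhs = (W.T @ y) / sigma_e
    if dense:
        return np.asarray(C.todense()), np.asarray(rhs).ravel(), W, offset, q
    return C, np.asarray(rhs).ravel(), W, offset, q


def pcg(C, rhs, tol=1e-12, maxiter=5000, x0=None):
    """Jacobi-preconditioned conjugate gradients; relative-residual stop."""
    diag = np.asarray(C.diagonal()) if sparse.issparse(C) else np.diag(C).copy()
    diag[diag == 0] = 1.0
    x = np.zeros_like(rhs) if x0 is None else x0.copy()
    r = rhs - C @ x
    z = r / diag
    p = z.copy()
    rz = r @ z
    nrm = np.linalg.norm(rhs)
    it = 0
    for it in range(1, maxiter + 1):
        Cp = C @ p
        alpha = rz / (p @ Cp)
        x += alpha * p
        r -= alpha * Cp
        res = np.linalg.norm(r) / nrm
        if res <= tol:
            return x, it, True, res
        z = r / diag
        rz_new = r @ z
        p = z + (rz_new / rz) * p
        rz = rz_new
    return x, it, False, float(np.linalg.norm(r) / nrm)


def solve_mme(
    y: np.ndarray,
    X,
    record_animal: np.ndarray,
    k_inv_list: list,
    sigma_g: np.ndarray | list[float],
    sigma_e: float,
    n_animals: int,
    tol: float = 1e-12,
    maxiter: int = 5000,
) -> SolveReport:
    """Solve Henderson's MME by PCG; GEBV = sum of genetic components.

    Animals without records (e.g. validation) receive GEBVs through the
    relationship structure of the K-inverses.
    """
    Z = make_incidence(record_animal, n_animals)
    C, rhs, W, p, q = _assemble_mme(y, X, Z, k_inv_list, np.atleast_1d(sigma_g), sigma_e)
    sol, it, conv, res = pcg(C, rhs, tol=tol, maxiter=maxiter)
    b = sol[:p]
    u = [sol[p + i * q : p + (i + 1) * q] for i in range(len(k_inv_list))]
    return SolveReport(
        b=b, u=u, gebv=np.sum(u, axis=0), iterations=it, converged=conv,
        final_residual_norm=res,
    )


# ---------------------------------------------------------------------------
# AI-REML
# ---------------------------------------------------------------------------


def _dense_inverse_from_cholesky(C: np.ndarray) -> np.ndarray:
    # dpotrf + dpotri: inverse from the Cholesky factor at n^3/3 each,
    # ~3x cheaper than triangular solves against the identity
    cf, info = sla.lapack.dpotrf(C, lower=1, overwrite_a=False)
    if info != 0:
        raise np.linalg.LinAlgError(f"coefficient matrix not PD (dpotrf info={info})")
    inv, info = sla.lapack.dpotri(cf, lower=1)
    if info != 0:
        raise np.linalg.LinAlgError(f"dpotri failed (info={info})")
    inv = np.tril(inv) + np.tril(inv, -1).T
    return inv


def _sparse_trace_product(K: sparse.spmatrix, B: np.ndarray) -> float:
    """tr(K @ B) for sparse K (symmetric use-case), dense B."""
    Kc = K.tocoo()
    return float(np.sum(Kc.data * B[Kc.row, Kc.col]))


def estimate_varcomps(
    y: np.ndarray,
    X,
    record_animal: np.ndarray,
    k_inv_list: list,
    n_animals: int,
    start: tuple | None = None,
    method: str = "ai_reml",
    max_rounds: int = 50,
    tol: float = 1e-8,
) -> VarCompResult:
    """AI-REML with EM fallback for one or two genetic components.

    Starting values split the phenotypic variance evenly unless given.
    Convergence: maximum relative parameter change < ``tol``.  Estimates
    hitting the lower boundary are floored (1e-6 of var(y)) and flagged;
    non-convergence is reported, never raised.
    """
    if method != "ai_reml":
        raise ValueError("only AI-REML is implemented")
    y = np.asarray(y, dtype=float)
    n = len(y)
    ncomp = len(k_inv_list)
    Z = make_incidence(record_animal, n_animals)
    X = sparse.csr_matrix(X)
    p = X.shape[1]
    vy = float(np.var(y))
    floor = 1e-6 * vy
    if start is None:
        sg = np.full(ncomp, 0.5 * vy / ncomp)
        se = 0.5 * vy
    else:
        sg = np.array(start[0], dtype=float, ndmin=1).copy()
        se = float(start[1])

    q = n_animals
    history = [np.append(sg, se)]
    converged = False
    at_boundary = False
    ai_degenerate = False
    Wx = X.toarray()
    rounds = 0
    for rounds in range(1, max_rounds + 1):
        C, rhs, W, _, _ = _assemble_mme(y, X, Z, k_inv_list, sg, se, dense=True)
        Cinv = _dense_inverse_from_cholesky(C)
        sol = Cinv @ rhs
        b = sol[:p]
        u = [sol[p + i * q : p + (i + 1) * q] for i in range(ncomp)]
        e_hat = y - Wx @ b - sum(np.asarray(Z @ ui).ravel() for ui in u)
        Py = e_hat / se

        # traces via the u-blocks of C^-1
        trPVdot = np.empty(ncomp)
        for i in range(ncomp):
            Cuu = Cinv[p + i * q : p + (i + 1) * q, p + i * q : p + (i + 1) * q]
            tKC = _sparse_trace_product(k_inv_list[i], Cuu)
            trPVdot[i] = (q - tKC / sg[i]) / sg[i]
        trP = (n - p - np.sum(sg * trPVdot)) / se

        # gradients of the restricted log-likelihood
        grad = np.empty(ncomp + 1)
        uKu = np.empty(ncomp)
        for i in range(ncomp):
            uKu[i] = float(u[i] @ (k_inv_list[i] @ u[i]))
            grad[i] = -0.5 * (trPVdot[i] - uKu[i] / sg[i] ** 2)
        grad[ncomp] = -0.5 * (trP - float(e_hat @ e_hat) / se**2)

        # average-information matrix from working vectors f_k = Vdot_k P y
        fs = [np.asarray(Z @ (u[i] / sg[i])).ravel() for i in range(ncomp)] + [Py]
        Pf = []
        for f in fs:
            wf = np.asarray(W.T @ f).ravel()
            Pf.append((f - np.asarray(W @ (Cinv @ wf)).ravel() / se) / se)
        AI = 0.5 * np.array([[fi @ Pfj for Pfj in Pf] for fi in fs])

        theta = np.append(sg, se)
        theta_new = None
        try:
            if np.linalg.cond(AI) > 1e10:
                ai_degenerate = True
                raise np.linalg.LinAlgError("average-information matrix singular")
            step = np.linalg.solve(AI, grad)
            # damped Newton: halve an overshooting step before giving up on it
            for damp in (1.0, 0.5, 0.25, 0.1, 0.05):
                cand = theta + damp * step
                if np.all(cand > 0) and np.all(np.isfinite(cand)):
                    theta_new = cand
                    break
        except np.linalg.LinAlgError:
            pass

        if theta_new is None:
            # EM fallback keeps the update inside the parameter space
            theta_new = np.empty_like(theta)
            for i in range(ncomp):
                Cuu = Cinv[p + i * q : p + (i + 1) * q, p + i * q : p + (i + 1) * q]
                tKC = _sparse_trace_product(k_inv_list[i], Cuu)
                theta_new[i] = (uKu[i] + tKC) / q
            theta_new[ncomp] = float(y @ e_hat) / (n - p)

        if np.any(theta_new < floor):
            at_boundary = True
            theta_new = np.maximum(theta_new, floor)

        rel = np.max(np.abs(theta_new - theta) / np.maximum(np.abs(theta), floor))
        sg, se = theta_new[:ncomp], float(theta_new[ncomp])
        history.append(theta_new.copy())
        if rel < tol:
            converged = True
            break

    return VarCompResult(
        sigma_g=np.asarray(sg), sigma_e=se, converged=converged,
        n_rounds=rounds, at_boundary=at_boundary,
        ai_degenerate=ai_degenerate, history=history,
    )
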