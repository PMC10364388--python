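"""REML variance-component estimation for the direct / social models.

The reference algorithm is EM-REML on Henderson's mixed-model
equations: each round solves the MME at the current components, takes
trace terms from the coefficient-matrix inverse, and updates

    sigma2_u  <- (u'K⁻¹u + tr(K⁻¹ C^uu)) / q          (each random effect)
    G_2x2     <- (S + Tr) / m                          (direct-social pair)
    sigma2_e  <- (y'y - sol' T'y) / (n - p)

EM is monotone in the restricted likelihood but crawls along the flat
ridges this model class produces (the direct variance trades off
against the direct-social covariance), so an average-information (AI)
accelerator is provided: damped Newton steps on an unconstrained
parameterisation (log variances, atanh correlation), accepted only
when they do not lose restricted likelihood, with the EM update as the
fallback.  AI and EM share every per-round quantity and have the same
fixed points (the REML score is zero at either).

The restricted log-likelihood uses the mixed-model identity

    -2 logL = (n-p) log 2*pi + log|R| + log|G| + log|C| + y'Py,

with all log-determinants taken from the same sparse structures and
the dense Cholesky factor of C.  Trace terms come from the inverse
Cholesky factor: only the diagonal of C⁻¹ and its entries on the
sparsity pattern of the relationship inverse are ever formed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.linalg as sla
from scipy.linalg.lapack import dtrtri

from .components import CLASSICAL, SOCIAL, VarianceComponents
from .mme import Design, ModelSpec, MMEError, build_design
from .pedigree import Pedigree, mendelian_variances


class REMLError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# log-determinants of relationship structures


def pedigree_logdet(ped: Pedigree) -> float:
    """``log|A|`` from the Mendelian-sampling variances."""
    return float(np.log(mendelian_variances(ped)).sum())


def h_logdet(ped: Pedigree, G_blend: np.ndarray, A22: np.ndarray) -> float:
    """``log|H| = log|A| + log|G_blend| - log|A22|``."""
    s1, ld1 = np.linalg.slogdet(G_blend)
    s2, ld2 = np.linalg.slogdet(A22)
    if s1 <= 0 or s2 <= 0:
        raise REMLError("G_blend and A22 must be positive definite")
    return pedigree_logdet(ped) + ld1 - ld2


def _rel_logdet_fallback(relinv: sp.spmatrix) -> float:
    n = relinv.shape[0]
    if n > 4000:
        raise REMLError(
            "pass rel_logdet explicitly for large relationship matrices "
            "(pedigree_logdet / h_logdet)")
    sign, ld = np.linalg.slogdet(relinv.toarray())
    if sign <= 0:
        raise REMLError("relationship inverse is not positive definite")
    return -ld


# ---------------------------------------------------------------------------
# per-round evaluation


class _Workspace:
    """Cached cross-products and index structures for one design.

    Keeps the dense ``T'T``, the COO pattern of the relationship
    inverse, and flat insertion indices so that reassembling the MME
    coefficient matrix at new components costs one large array write
    instead of sparse arithmetic.
    """

    def __init__(self, design: Design, relinv: sp.spmatrix):
        self.design = design
        TtT, Tty, yty = design.cross_products()
        self.TtT = TtT
        self.TtT_dense = TtT.toarray()
        self.Tty = Tty
        self.yty = yty
        self.K = relinv.tocoo()
        self.Kcsr = relinv.tocsr()
        self.slices = design.slices()
        self.n_eq = design.n_equations
        gen_slices = [self.slices[t.name] for t in design.genetic]
        self.gen_starts = [s.start for s in gen_slices]
        self.iid_slices = [self.slices[t.name] for t in design.iid]
        self.C_buf = np.empty((self.n_eq, self.n_eq))
        diag = np.arange(self.n_eq)
        self.diag_idx = diag

    def assemble(self, vc: VarianceComponents) -> np.ndarray:
        """Fill the reusable buffer with the MME coefficient matrix."""
        C = self.C_buf
        np.divide(self.TtT_dense, vc.sigma2_e, out=C)
        g2 = vc.genetic_matrix()
        try:
            ginv = np.linalg.inv(g2)
        except np.linalg.LinAlgError as err:
            raise REMLError(f"singular genetic matrix: {err}") from err
        K = self.K
        for x, sx in enumerate(self.gen_starts):
            for y, sy in enumerate(self.gen_starts):
                C[K.row + sx, K.col + sy] += ginv[x, y] * K.data
        for sl, s2 in zip(self.iid_slices,
                          (vc.sigma2_gr, vc.sigma2_cl, vc.sigma2_cg)):
            if s2 <= 0:
                raise REMLError("iid variances must be strictly positive")
            idx = self.diag_idx[sl]
            C[idx, idx] += 1.0 / s2
        return C


@dataclass
class _RoundState:
    """Everything one MME factorisation yields at a parameter point."""

    vc: VarianceComponents
    sol: np.ndarray
    chol: np.ndarray
    minus2logl: float
    ypy: float
    S: np.ndarray            # genetic cross products u_x' K⁻¹ u_y
    Tr: np.ndarray           # genetic traces tr(K⁻¹ C^xy)
    iid_ssq: np.ndarray
    iid_tr: np.ndarray
    e_ssq: float
    slices: dict


def _logdet_g(ws: _Workspace, vc: VarianceComponents, rel_logdet: float) -> float:
    g2 = vc.genetic_matrix()
    sign, ld_g2 = np.linalg.slogdet(g2)
    if sign <= 0:
        raise REMLError("genetic covariance matrix is not positive definite")
    out = ws.design.n_genetic_levels * ld_g2 + g2.shape[0] * rel_logdet
    for term, s2 in zip(ws.design.iid,
                        (vc.sigma2_gr, vc.sigma2_cl, vc.sigma2_cg)):
        out += term.n_levels * math.log(s2)
    return out


def _factor_and_solve(ws: _Workspace, vc: VarianceComponents):
    C = ws.assemble(vc)
    try:
        c, _ = sla.cho_factor(C, lower=True, overwrite_a=True,
                              check_finite=False)
    except np.linalg.LinAlgError as err:
        raise REMLError(f"MME not positive definite at {vc}: {err}") from err
    sol = sla.cho_solve((c, True), ws.Tty / vc.sigma2_e, check_finite=False)
    return c, sol


def _m2ll_from(ws: _Workspace, vc: VarianceComponents, c: np.ndarray,
               sol: np.ndarray, rel_logdet: float) -> tuple[float, float]:
    n, p = ws.design.n_records, ws.design.p
    se = vc.sigma2_e
    ypy = (ws.yty - sol @ ws.Tty) / se
    logdet_c = 2.0 * float(np.log(np.diag(c)).sum())
    m2ll = ((n - p) * math.log(2 * math.pi) + n * math.log(se)
            + _logdet_g(ws, vc, rel_logdet) + logdet_c + ypy)
    return m2ll, ypy


def _evaluate_round(
    ws: _Workspace, vc: VarianceComponents, rel_logdet: float,
    need_traces: bool = True, prefactored=None,
) -> _RoundState:
    if prefactored is None:
        c, sol = _factor_and_solve(ws, vc)
        m2ll, ypy = _m2ll_from(ws, vc, c, sol, rel_logdet)
    else:
        c, sol, m2ll, ypy = prefactored
    slices = ws.slices
    k = 2 if vc.is_social else 1
    u_gen = [sol[slices[t.name]] for t in ws.design.genetic]
    S = np.empty((k, k))
    for x in range(k):
        for y in range(x, k):
            S[x, y] = S[y, x] = float(u_gen[x] @ (ws.Kcsr @ u_gen[y]))
    Tr = np.zeros((k, k))
    iid_tr = np.zeros(len(ws.design.iid))
    if need_traces:
        # rows of inv(L).T give C^-1 blocks as Gram products:
        # C^-1[a, b] = B_a @ B_b' with B_a = inv(L).T[a, :]
        linv, info = dtrtri(c, lower=1)
        if info != 0:
            raise REMLError(f"dtrtri failed (info={info})")
        # dtrtri leaves the unreferenced triangle untouched; drop it
        linv_t = np.triu(linv.T)
        del linv
        B = [linv_t[slices[t.name], :] for t in ws.design.genetic]
        for x in range(k):
            KBx = ws.Kcsr @ B[x]
            for y in range(x, k):
                Tr[x, y] = Tr[y, x] = float(np.sum(KBx * B[y]))
        for j, sl in enumerate(ws.iid_slices):
            iid_tr[j] = float(np.sum(linv_t[sl, :] ** 2))
    iid_ssq = np.array([
        float(sol[sl] @ sol[sl]) for sl in ws.iid_slices])
    e_ssq = ws.yty - 2.0 * (sol @ ws.Tty) + float(sol @ (ws.TtT @ sol))
    return _RoundState(vc=vc, sol=sol, chol=c, minus2logl=m2ll, ypy=ypy,
                       S=S, Tr=Tr, iid_ssq=iid_ssq, iid_tr=iid_tr,
                       e_ssq=e_ssq, slices=slices)


# ---------------------------------------------------------------------------
# updates


def _em_update(state: _RoundState, ws: _Workspace) -> VarianceComponents:
    vc = state.vc
    design = ws.design
    m = design.n_genetic_levels
    n, p = design.n_records, design.p
    g_new = (state.S + state.Tr) / m
    if vc.is_social:
        w, v = np.linalg.eigh(g_new)
        floor = 1e-12 * max(np.trace(g_new), 1e-300)
        if w.min() < floor:
            warnings.warn("EM genetic update left the PD cone; bending",
                          stacklevel=3)
            g_new = (v * np.maximum(w, floor)) @ v.T
    q = np.array([t.n_levels for t in design.iid], dtype=float)
    iid_new = (state.iid_ssq + state.iid_tr) / q
    se_new = (ws.yty - state.sol @ ws.Tty) / (n - p)
    if vc.is_social:
        theta = [g_new[0, 0], g_new[0, 1], g_new[1, 1], *iid_new, se_new]
    else:
        theta = [g_new[0, 0], *iid_new, se_new]
    return VarianceComponents.from_vector(theta, vc.model)


def _score_and_ai(
    state: _RoundState, ws: _Workspace,
) -> tuple[np.ndarray, np.ndarray]:
    """REML score vector and average-information matrix.

    Parameter order: genetic block (sigma2_ud[, sigma_uds, sigma2_us]),
    pen, litter, cg, residual.
    """
    vc = state.vc
    design = ws.design
    n, p = design.n_records, design.p
    m = design.n_genetic_levels
    se = vc.sigma2_e
    g2 = vc.genetic_matrix()
    k = g2.shape[0]
    ginv = np.linalg.inv(g2)
    if k == 2:
        bases = [np.array([[1.0, 0.0], [0.0, 0.0]]),
                 np.array([[0.0, 1.0], [1.0, 0.0]]),
                 np.array([[0.0, 0.0], [0.0, 1.0]])]
    else:
        bases = [np.array([[1.0]])]

    score = []
    for E in bases:
        mid = ginv @ E @ ginv
        data_term = float(np.sum(mid * state.S))
        tr_term = float(np.sum(mid * (m * g2 - state.Tr)))
        score.append(0.5 * (data_term - tr_term))
    iid_s2 = np.array([vc.sigma2_gr, vc.sigma2_cl, vc.sigma2_cg])
    q = np.array([t.n_levels for t in design.iid], dtype=float)
    for j in range(len(design.iid)):
        s2 = iid_s2[j]
        score.append(0.5 * (state.iid_ssq[j] / s2**2
                            - (q[j] / s2 - state.iid_tr[j] / s2**2)))
    tr_p = (n - p - (k * m - float(np.sum(ginv * state.Tr)))
            - float(np.sum(q - state.iid_tr / iid_s2))) / se
    score.append(0.5 * (state.e_ssq / se**2 - tr_p))
    score = np.array(score)

    # working vectors f_theta = dV/dtheta @ P y
    T = design.t_matrix()
    e_hat = design.y - T @ state.sol
    u_gen = [state.sol[state.slices[t.name]] for t in design.genetic]
    fs = []
    for E in bases:
        B = E @ ginv
        rows = [sum(B[x, y] * u_gen[y] for y in range(k)) for x in range(k)]
        f = np.zeros(design.n_records)
        for term, v in zip(design.genetic, rows):
            f += term.Z @ v
        fs.append(f)
    for j, term in enumerate(design.iid):
        fs.append(term.Z @ state.sol[state.slices[term.name]] / iid_s2[j])
    fs.append(e_hat / se)
    F = np.column_stack(fs)

    rhs = (T.T @ F) / se
    solF = sla.cho_solve((state.chol, True), rhs, check_finite=False)
    PF = (F - T @ solF) / se
    AI = 0.5 * (F.T @ PF)
    return score, 0.5 * (AI + AI.T)


# ---------------------------------------------------------------------------
# unconstrained parameterisation for AI steps


def _to_unconstrained(theta: np.ndarray, model: str) -> np.ndarray:
    """Log variances; atanh of the direct-social correlation."""
    with np.errstate(divide="ignore"):  # a zero covariance is re-mapped below
        phi = np.log(np.abs(theta))
    if model == SOCIAL:
        r = theta[1] / math.sqrt(theta[0] * theta[2])
        phi[1] = np.arctanh(np.clip(r, -1 + 1e-10, 1 - 1e-10))
    return phi


def _from_unconstrained(phi: np.ndarray, model: str) -> np.ndarray:
    theta = np.exp(phi)
    if model == SOCIAL:
        theta[1] = np.tanh(phi[1]) * math.sqrt(theta[0] * theta[2])
    return theta


def _jacobian(theta: np.ndarray, model: str) -> np.ndarray:
    """J[i, j] = d theta_i / d phi_j at theta."""
    J = np.diag(theta.copy())
    if model == SOCIAL:
        sd = math.sqrt(theta[0] * theta[2])
        r = theta[1] / sd
        J[1, 0] = 0.5 * theta[1]
        J[1, 1] = (1.0 - r**2) * sd
        J[1, 2] = 0.5 * theta[1]
    return J


def _admissible(theta: np.ndarray, model: str, scale: float) -> bool:
    floor = 1e-10 * scale
    if model == SOCIAL:
        ud, uds, us = theta[0], theta[1], theta[2]
        rest = theta[3:]
        if min(ud, us) < floor or ud * us - uds**2 < floor**2:
            return False
    else:
        rest = theta[1:]
        if theta[0] < floor:
            return False
    return bool(np.all(rest > floor))


def _ai_step(
    theta: np.ndarray, score: np.ndarray, AI: np.ndarray, model: str,
    max_log_step: float = 1.5,
) -> np.ndarray | None:
    """Damped AI-Newton step on the unconstrained parameterisation.

    Variances move on the log scale and the direct-social correlation
    through atanh, so no step can leave the parameter space or cross
    the PD-cone boundary that traps constrained updates.  A
    Levenberg-Marquardt ladder handles the near-singular AI matrices
    of this model class; steps are clipped per element so that one
    coordinate running to a boundary cannot freeze the others.
    Returns the new theta or None (caller falls back to EM).
    """
    J = _jacobian(theta, model)
    g = J.T @ score
    H = J.T @ AI @ J
    diag = np.clip(np.diag(H), 1e-12, None)
    phi = _to_unconstrained(theta, model)
    for lam in (0.0, 1e-6, 1e-4, 1e-2, 1.0, 1e2):
        try:
            step = np.linalg.solve(H + lam * np.diag(diag), g)
        except np.linalg.LinAlgError:
            continue
        if not np.all(np.isfinite(step)):
            continue
        step = np.clip(step, -max_log_step, max_log_step)
        cand = _from_unconstrained(phi + step, model)
        if np.all(np.isfinite(cand)):
            return cand
    return None


# ---------------------------------------------------------------------------
# driver


@dataclass
class REMLOptions:
    tol: float = 1e-9
    maxiter: int = 500
    accelerate: str = "ai"   # "ai" or "none" (pure EM)
    n_em_warmup: int = 2
    aitken: bool = True      # periodic extrapolation along slow valleys
    verbose: bool = False


def _default_start(design: Design, spec: ModelSpec) -> VarianceComponents:
    """Equal split of the phenotypic variance; the social variance is
    scaled so its phenotypic contribution (N-1)*sigma2_us matches the
    other components' share; the covariance starts at zero."""
    vy = float(np.var(design.y, ddof=1))
    n_var = 6 if spec.is_social else 5
    share = vy / n_var
    if spec.is_social:
        nbar = float(np.asarray(
            design.genetic[1].Z.sum(axis=1)).mean()) + 1.0
        return VarianceComponents(share, share / max(nbar - 1.0, 1.0), 0.0,
                                  share, share, share, share, model=SOCIAL)
    return VarianceComponents(share, None, None, share, share, share, share,
                              model=CLASSICAL)


def em_reml(
    data: pd.DataFrame,
    spec: ModelSpec,
    relinv: sp.spmatrix,
    ped: Pedigree,
    init: VarianceComponents | None = None,
    tol: float = 1e-9,
    maxiter: int = 500,
    rel_logdet: float | None = None,
    options: REMLOptions | None = None,
) -> VarianceComponents:
    """Estimate variance components by (AI-accelerated) EM-REML.

    Convergence uses the squared-change criterion
    ``sum((theta_new - theta)**2) / sum(theta_new**2) < tol``.  AI
    steps that lose restricted likelihood are reverted in favour of
    the EM update, keeping the whole trajectory monotone.  On
    non-convergence the last iterate is returned with a warning and
    flagged in ``meta``.
    """
    opts = options or REMLOptions(tol=tol, maxiter=maxiter)
    design = build_design(data, spec, ped)
    if rel_logdet is None:
        rel_logdet = _rel_logdet_fallback(relinv)
    ws = _Workspace(design, relinv)
    vc = init if init is not None else _default_start(design, spec)
    scale = float(np.var(design.y, ddof=1))
    path: list[float] = []
    converged = False
    cc = math.inf
    it = 0
    state = _evaluate_round(ws, vc, rel_logdet)
    phi_hist: list[np.ndarray] = [_to_unconstrained(vc.as_vector(), vc.model)]
    for it in range(1, opts.maxiter + 1):
        path.append(state.minus2logl)
        theta_old = state.vc.as_vector()
        em_vc = _em_update(state, ws)
        new_vc, used, pre = em_vc, "em", None
        crawling = (opts.aitken
                    and len(path) >= 3
                    and path[-3] - path[-1] < 0.5
                    and it % 4 == 0
                    and opts.accelerate == "ai")
        if crawling and len(phi_hist) >= 3:
            # geometric extrapolation along the slow valley direction;
            # the stride-2 difference cancels the AI/EM zigzag
            phi_now = phi_hist[-1]
            direction = phi_now - phi_hist[-3]
            for gamma in (32.0, 8.0):
                cand = _from_unconstrained(phi_now + gamma * direction,
                                           vc.model)
                if not (np.all(np.isfinite(cand))
                        and _admissible(cand, vc.model, scale)):
                    continue
                trial_vc = VarianceComponents.from_vector(cand, vc.model)
                try:
                    c_t, sol_t = _factor_and_solve(ws, trial_vc)
                    m2_t, ypy_t = _m2ll_from(ws, trial_vc, c_t, sol_t,
                                             rel_logdet)
                except (REMLError, np.linalg.LinAlgError):
                    continue
                if m2_t < state.minus2logl - 0.5 * (path[-3] - path[-1]):
                    new_vc, used = trial_vc, "aitken"
                    pre = (c_t, sol_t, m2_t, ypy_t)
                    break
        # during a likelihood crawl the AI quadratic model is unreliable
        # (steps shrink to nothing); save its guard factorisation and
        # let EM plus the periodic extrapolation carry the iteration
        deep_crawl = len(path) >= 3 and path[-3] - path[-1] < 0.05
        if (opts.accelerate == "ai" and it > opts.n_em_warmup
                and used == "em" and not deep_crawl):
            score, AI = _score_and_ai(state, ws)
            cand = _ai_step(theta_old, score, AI, vc.model)
            if cand is not None:
                # guard: accept the longest (possibly shrunk) AI step
                # that does not lose restricted likelihood
                for shrink in (1.0, 0.5, 0.25, 0.1, 0.05, 0.02):
                    trial = theta_old + shrink * (cand - theta_old)
                    if not _admissible(trial, vc.model, scale):
                        continue
                    trial_vc = VarianceComponents.from_vector(trial, vc.model)
                    try:
                        c_t, sol_t = _factor_and_solve(ws, trial_vc)
                        m2_t, ypy_t = _m2ll_from(ws, trial_vc, c_t, sol_t,
                                                 rel_logdet)
                    except (REMLError, np.linalg.LinAlgError):
                        continue
                    if m2_t <= state.minus2logl + 1e-7:
                        new_vc, used = trial_vc, "ai"
                        pre = (c_t, sol_t, m2_t, ypy_t)
                        break
        new_state = _evaluate_round(ws, new_vc, rel_logdet, prefactored=pre)
        theta_new = new_vc.as_vector()
        phi_hist.append(_to_unconstrained(theta_new, vc.model))
        del phi_hist[:-3]
        cc = float(np.sum((theta_new - theta_old) ** 2) / np.sum(theta_new**2))
        if opts.verbose:
            print(f"iter {it:3d} [{used}] -2logL={new_state.minus2logl:.6f} "
                  f"cc={cc:.3e}")
        vc, state = new_vc, new_state
        if cc < opts.tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"REML did not converge in {opts.maxiter} iterations "
            f"(last squared change {cc:.2e})", stacklevel=2)
    path.append(state.minus2logl)
    m2ll = state.minus2logl
    vc.meta.update({
        "iterations": it,
        "converged": converged,
        "final_change": cc,
        "minus2logl": m2ll,
        "aic": aic(m2ll, vc.n_params),
        "minus2logl_path": path,
        "algorithm": "em" if opts.accelerate == "none" else "em+ai",
    })
    return vc


def restricted_loglik(
    varcomp: VarianceComponents,
    data: pd.DataFrame,
    spec: ModelSpec,
    relinv: sp.spmatrix,
    ped: Pedigree,
    rel_logdet: float | None = None,
) -> float:
    """``-2 logL`` of the restricted likelihood at the given components."""
    design = build_design(data, spec, ped)
    if rel_logdet is None:
        rel_logdet = _rel_logdet_fallback(relinv)
    ws = _Workspace(design, relinv)
    c, sol = _factor_and_solve(ws, varcomp)
    m2ll, _ = _m2ll_from(ws, varcomp, c, sol, rel_logdet)
    return m2ll


def aic(minus2logl: float, n_params: int) -> float:
    """Akaike information criterion over the (co)variance parameters.

    Fixed effects are profiled out by REML, so ``n_params`` counts only
    the estimated (co)variance parameters: 5 for the classical model
    and 7 for the social model.
    """
    if n_params < 1:
        raise ValueError("n_params must be positive")
    return minus2logl + 2.0 * n_params
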