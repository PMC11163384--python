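"""Restricted maximum likelihood for single-trait and bivariate multi-kernel
linear mixed models.

The model treats the same trait measured in two populations as two correlated
traits.  Stacking the records of both populations, the phenotypic covariance
is

    V = sum_k (M_k  "spread over"  G_k) + R,

where ``G_k`` is the k-th genomic relationship kernel, ``M_k`` its 2×2 genetic
(co)variance matrix (a scalar for single-trait models) and ``R`` a diagonal
residual with one variance per trait.  Because each individual carries a
record for exactly one trait (the populations are disjoint), V is an n×n
matrix with entries ``V[i, j] = sum_k M_k[t_i, t_j] G_k[i, j] + delta_ij
sigma2_e[t_i]`` — no explicit Kronecker product is ever formed.

Estimation is average-information (AI) REML.  The optimizer works in
unconstrained coordinates — log variances and a Fisher-z transform of each
kernel correlation — so positive-semidefiniteness holds by construction;
the score and AI matrix are formed on the natural scale and pulled back
through the Jacobian.  Newton steps are damped during a short warm-up and
step-halved whenever the restricted log-likelihood would decrease, giving a
monotone iteration.  Correlations are bounded at ±0.999 and variances at
1e-8 × the phenotypic variance.  The restricted log-likelihood includes its
full constant, ``-(n - p)/2 log 2π``, so values are comparable across
implementations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .data_io import DesignSpec, GenotypeMatrix, PhenotypeTable
from .grm import GRM

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "DerivedParams",
    "make_model_spec",
    "reml_loglik",
    "fit_reml",
    "derive_params",
    "lrt_zero_covariance",
]

LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class ModelSpec:
    """A fully assembled mixed model: kernels, records and fixed design.

    ``record_indiv[r]`` indexes the individual of record r inside every
    kernel; ``record_trait[r]`` is its trait (= population) index.  All
    kernels must cover the same individual set, which may be a superset of
    the phenotyped individuals (candidates contribute genotypes only).
    """

    kernels: list[GRM]
    y: np.ndarray
    record_indiv: np.ndarray
    record_trait: np.ndarray
    n_traits: int
    X: np.ndarray
    kernel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, float)
        self.record_indiv = np.asarray(self.record_indiv, int)
        self.record_trait = np.asarray(self.record_trait, int)
        n = len(self.y)
        if not (len(self.record_indiv) == len(self.record_trait) == n == self.X.shape[0]):
            raise ValueError("record arrays and design must have equal length")
        if self.n_traits not in (1, 2):
            raise ValueError("only 1 or 2 traits supported")
        if self.record_trait.max(initial=0) >= self.n_traits:
            raise ValueError("record trait index out of range")
        if not self.kernels:
            raise ValueError("at least one kernel required")
        n_ind = self.kernels[0].n
        for g in self.kernels:
            if g.n != n_ind:
                raise ValueError("kernels cover different individual sets")
        if self.record_indiv.max(initial=0) >= n_ind:
            raise ValueError("record refers to individual outside the kernels")
        if not self.kernel_labels:
            self.kernel_labels = [g.snp_set for g in self.kernels]
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("fixed-effect design is rank deficient on the records")

    @property
    def n_records(self) -> int:
        return len(self.y)

    @property
    def n_kernels(self) -> int:
        return len(self.kernels)

    def kernel_submatrices(self) -> list[np.ndarray]:
        """Each kernel restricted to the record individuals (cached)."""
        if not hasattr(self, "_Gs"):
            ix = np.ix_(self.record_indiv, self.record_indiv)
            self._Gs = [g.values[ix] for g in self.kernels]
        return self._Gs


@dataclass
class VarianceComponents:
    """Fitted (co)variance components of a multi-kernel model.

    ``M`` has shape (K, n_traits, n_traits); ``resid`` one residual variance
    per trait.  ``ai_inverse`` is the inverse average-information matrix over
    the free parameters (parameter order: per kernel var1[, cov, var2], then
    residuals), used for delta-method standard errors.
    """

    M: np.ndarray
    resid: np.ndarray
    loglik: float = np.nan
    converged: bool = False
    n_iter: int = 0
    kernel_labels: list[str] = field(default_factory=list)
    ai_inverse: np.ndarray | None = None
    free_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.M = np.atleast_3d(np.asarray(self.M, float))
        self.resid = np.atleast_1d(np.asarray(self.resid, float))
        for k in range(self.M.shape[0]):
            Mk = self.M[k]
            if not np.allclose(Mk, Mk.T):
                raise ValueError("kernel covariance matrices must be symmetric")
            if np.any(np.diag(Mk) < 0):
                raise ValueError("negative genetic variance")
        if np.any(self.resid <= 0):
            raise ValueError("residual variances must be positive")

    @property
    def n_kernels(self) -> int:
        return self.M.shape[0]

    @property
    def n_traits(self) -> int:
        return self.M.shape[1]


@dataclass
class DerivedParams:
    """Heritabilities (over the kernel sum) and per-kernel genetic correlations."""

    h2: np.ndarray                 # per trait
    h2_se: np.ndarray
    r_g: np.ndarray                # per kernel; NaN where undefined
    r_g_se: np.ndarray
    kernel_labels: list[str] = field(default_factory=list)


def make_model_spec(
    kernels: list[GRM] | GRM,
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    trait: str | None = None,
    train_ids=None,
    n_traits: int | None = None,
    pooled: bool = False,
    design: DesignSpec | None = None,
) -> ModelSpec:
    """Assemble a :class:`ModelSpec` from package containers.

    Records are the phenotyped individuals among ``train_ids`` (default: all
    with a non-missing response).  With ``pooled=True`` the two populations
    are treated as one trait with a common genetic variance (the combined
    single-trait model); otherwise population p contributes records on trait
    p.  ``n_traits=1`` with a single population gives within-population
    single-trait GBLUP.
    """
    if isinstance(kernels, GRM):
        kernels = [kernels]
    ids = np.asarray(train_ids) if train_ids is not None \
        else genotypes.individual_ids
    y = phenotypes.values_for(ids, trait)
    keep = ~np.isnan(y)
    if not keep.any():
        raise ValueError("no phenotyped training individuals")
    ids, y = ids[keep], y[keep]
    # records index into the kernel's individual set (which may be a
    # population-restricted subset of the genotype panel)
    kernel_ids = list(kernels[0].individual_ids)
    lookup = {iid: i for i, iid in enumerate(kernel_ids)}
    try:
        indiv = np.array([lookup[i] for i in ids], dtype=int)
    except KeyError as exc:
        raise ValueError(f"training individual {exc.args[0]!r} missing from "
                         "the kernels") from exc
    pop_idx = genotypes.population_index[genotypes.indices_of(ids)]
    if pooled:
        if not phenotypes.commensurable:
            raise ValueError(
                "responses are flagged non-commensurable across populations; "
                "the pooled single-trait model is not applicable")
        record_trait = np.zeros(len(y), int)
        nt = 1
        # per-population intercepts by default even in the pooled model
        X = np.zeros((len(y), len(np.unique(pop_idx))))
        for c, p in enumerate(np.unique(pop_idx)):
            X[pop_idx == p, c] = 1.0
    else:
        nt = n_traits if n_traits is not None else len(np.unique(pop_idx))
        if nt == 2 and len(np.unique(pop_idx)) < 2:
            raise ValueError("bivariate model needs records from both populations")
        record_trait = pop_idx if nt == 2 else np.zeros(len(y), int)
        X = (design or DesignSpec()).build(record_trait, nt)
    return ModelSpec(kernels=kernels, y=y, record_indiv=indiv,
                     record_trait=record_trait, n_traits=nt, X=X)


# ---------------------------------------------------------------------------
# Parameter vector layout
# ---------------------------------------------------------------------------

def _pack(vc: VarianceComponents) -> np.ndarray:
    parts = []
    for k in range(vc.n_kernels):
        if vc.n_traits == 1:
            parts.append([vc.M[k, 0, 0]])
        else:
            parts.append([vc.M[k, 0, 0], vc.M[k, 0, 1], vc.M[k, 1, 1]])
    parts.append(vc.resid)
    return np.concatenate(parts)


def _unpack(theta: np.ndarray, K: int, n_traits: int) -> tuple[np.ndarray, np.ndarray]:
    per = 1 if n_traits == 1 else 3
    M = np.empty((K, n_traits, n_traits))
    for k in range(K):
        chunk = theta[k * per:(k + 1) * per]
        if n_traits == 1:
            M[k, 0, 0] = chunk[0]
        else:
            M[k] = [[chunk[0], chunk[1]], [chunk[1], chunk[2]]]
    resid = theta[K * per:]
    return M, resid


_ZMAX = 3.8002  # atanh(0.999): kernel correlations live in [-0.999, 0.999]


def _theta_to_phi(theta: np.ndarray, K: int, n_traits: int) -> np.ndarray:
    """Natural scale -> unconstrained scale (log variances, Fisher-z corr)."""
    per = 1 if n_traits == 1 else 3
    phi = theta.copy()
    for k in range(K):
        off = k * per
        if n_traits == 2:
            v1, c, v2 = theta[off:off + 3]
            r = np.clip(c / np.sqrt(max(v1, 1e-300) * max(v2, 1e-300)),
                        -0.999, 0.999)
            phi[off] = np.log(max(v1, 1e-300))
            phi[off + 1] = np.arctanh(r)
            phi[off + 2] = np.log(max(v2, 1e-300))
        else:
            phi[off] = np.log(max(theta[off], 1e-300))
    phi[K * per:] = np.log(np.maximum(theta[K * per:], 1e-300))
    return phi


def _phi_to_theta(phi: np.ndarray, K: int, n_traits: int) -> np.ndarray:
    per = 1 if n_traits == 1 else 3
    theta = phi.copy()
    for k in range(K):
        off = k * per
        if n_traits == 2:
            v1 = np.exp(phi[off])
            v2 = np.exp(phi[off + 2])
            theta[off] = v1
            theta[off + 1] = np.tanh(phi[off + 1]) * np.sqrt(v1 * v2)
            theta[off + 2] = v2
        else:
            theta[off] = np.exp(phi[off])
    theta[K * per:] = np.exp(phi[K * per:])
    return theta


def _jacobian(phi: np.ndarray, K: int, n_traits: int) -> np.ndarray:
    """dθ/dφ, used to pull the natural-scale score and AI matrix back to the
    unconstrained coordinates."""
    per = 1 if n_traits == 1 else 3
    n = phi.size
    J = np.zeros((n, n))
    for k in range(K):
        off = k * per
        if n_traits == 2:
            v1 = np.exp(phi[off])
            v2 = np.exp(phi[off + 2])
            tz = np.tanh(phi[off + 1])
            s = np.sqrt(v1 * v2)
            J[off, off] = v1
            J[off + 1, off] = 0.5 * tz * s
            J[off + 1, off + 1] = (1.0 - tz**2) * s
            J[off + 1, off + 2] = 0.5 * tz * s
            J[off + 2, off + 2] = v2
        else:
            J[off, off] = np.exp(phi[off])
    for t in range(n_traits):
        i = K * per + t
        J[i, i] = np.exp(phi[i])
    return J


def _clip_phi(phi: np.ndarray, K: int, n_traits: int,
              log_floor: np.ndarray, log_cap: np.ndarray) -> np.ndarray:
    """Keep log-variances in a wide finite range and |z| ≤ atanh(0.999)."""
    phi = phi.copy()
    per = 1 if n_traits == 1 else 3
    for k in range(K):
        off = k * per
        phi[off] = np.clip(phi[off], log_floor[0], log_cap[0])
        if n_traits == 2:
            phi[off + 1] = np.clip(phi[off + 1], -_ZMAX, _ZMAX)
            phi[off + 2] = np.clip(phi[off + 2], log_floor[-1], log_cap[-1])
    for t in range(n_traits):
        i = K * per + t
        phi[i] = np.clip(phi[i], log_floor[t], log_cap[t])
    return phi


def _derivative_structures(spec: ModelSpec):
    """Per-parameter dV/dθ as (kernel_submatrix, trait mask) pairs.

    Returns a list of callables-free descriptors: each entry is the dense
    derivative matrix itself.  Memory is K·n² doubles extra, acceptable at
    desk scale and much faster than recomputation.
    """
    t = spec.record_trait
    Gs = spec.kernel_submatrices()
    derivs = []
    for Gsub in Gs:
        if spec.n_traits == 1:
            derivs.append(Gsub)
        else:
            m0 = (t == 0).astype(float)
            m1 = (t == 1).astype(float)
            derivs.append(Gsub * np.outer(m0, m0))
            derivs.append(Gsub * (np.outer(m0, m1) + np.outer(m1, m0)))
            derivs.append(Gsub * np.outer(m1, m1))
    for a in range(spec.n_traits):
        derivs.append(np.diag((t == a).astype(float)))
    return derivs


def _build_V(spec: ModelSpec, M: np.ndarray, resid: np.ndarray) -> np.ndarray:
    t = spec.record_trait
    V = np.zeros((spec.n_records, spec.n_records))
    for k, Gsub in enumerate(spec.kernel_submatrices()):
        V += M[k][t[:, None], t[None, :]] * Gsub
    V[np.diag_indices_from(V)] += resid[t]
    return V


def _loglik_chol(spec: ModelSpec, M, resid):
    """(loglik, cho_factor, Vinv_y-free intermediates) or (-inf, None, ...)."""
    V = _build_V(spec, M, resid)
    n, p = spec.n_records, spec.X.shape[1]
    try:
        c, low = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return -np.inf, None, None, None
    logdetV = 2.0 * np.sum(np.log(np.diag(c)))
    ViX = linalg.cho_solve((c, low), spec.X, check_finite=False)
    Viy = linalg.cho_solve((c, low), spec.y, check_finite=False)
    XtViX = spec.X.T @ ViX
    try:
        cx = linalg.cho_factor(XtViX, check_finite=False)
    except linalg.LinAlgError:
        return -np.inf, None, None, None
    logdetX = 2.0 * np.sum(np.log(np.diag(cx[0])))
    beta = linalg.cho_solve(cx, spec.X.T @ Viy, check_finite=False)
    Py = Viy - ViX @ beta
    yPy = float(spec.y @ Py)
    ll = -0.5 * (logdetV + logdetX + yPy + (n - p) * LOG2PI)
    return ll, (c, low), (ViX, cx), Py


def reml_loglik(spec: ModelSpec, vc: VarianceComponents) -> float:
    """Restricted log-likelihood at the given components.

    ``-1/2 [log|V| + log|X'V⁻¹X| + y'Py + (n-p) log 2π]`` with
    ``P = V⁻¹ - V⁻¹X(X'V⁻¹X)⁻¹X'V⁻¹``.  Raises on an indefinite V or design.
    """
    ll, chol, _, _ = _loglik_chol(spec, vc.M, vc.resid)
    if chol is None:
        raise linalg.LinAlgError("covariance matrix V or X'V⁻¹X not positive definite")
    return ll


def _default_init(spec: ModelSpec) -> np.ndarray:
    """Phenotypic variance split 50/50 genetic/residual, genetic part split
    equally across kernels, covariances 0."""
    K, nt = spec.n_kernels, spec.n_traits
    var_t = np.array([
        np.var(spec.y[spec.record_trait == a]) if (spec.record_trait == a).any()
        else 1.0
        for a in range(nt)
    ])
    var_t = np.where(var_t > 0, var_t, 1.0)
    M = np.zeros((K, nt, nt))
    for k in range(K):
        for a in range(nt):
            M[k, a, a] = 0.5 * var_t[a] / K
    return _pack(VarianceComponents(M=M, resid=0.5 * var_t))


def fit_reml(
    spec: ModelSpec,
    init: VarianceComponents | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
    warmup: int = 3,
    fix_cov_zero: tuple[int, ...] = (),
) -> VarianceComponents:
    """Average-information REML with damped warm-up and step-halving.

    Optimization runs in unconstrained coordinates — log variances and a
    Fisher-z transform of each kernel correlation — so the PSD constraints
    (variances > 0, |correlation| ≤ 0.999) hold by construction and boundary
    solutions are approached smoothly instead of being clamped mid-step.
    The natural-scale score and average-information matrix are pulled back
    through the Jacobian of the transform.

    The first ``warmup`` Newton steps are Levenberg-damped (the AI matrix is
    regularised toward its diagonal) to survive poor starting values; later
    steps are undamped.  Any step that would decrease the restricted
    log-likelihood is halved (and re-damped) until it does not; accepted
    steps therefore never decrease the log-likelihood.  Convergence requires
    a log-likelihood increase below ``tol`` together with a small parameter
    change, or a vanishing gradient.

    ``fix_cov_zero`` lists kernel indices whose between-population covariance
    is constrained to zero (used by the covariance likelihood-ratio test and
    by decoupled multi-trait fits).
    """
    K, nt = spec.n_kernels, spec.n_traits
    per = 1 if nt == 1 else 3
    if spec.n_records <= spec.X.shape[1]:
        raise ValueError("more fixed effects than records")
    var_t = np.array([
        np.var(spec.y[spec.record_trait == a]) if (spec.record_trait == a).any()
        else 1.0 for a in range(nt)])
    var_t = np.where(var_t > 0, var_t, 1.0)
    log_floor = np.log(1e-8 * var_t)
    log_cap = np.log(1e4 * var_t)

    theta = _pack(init) if init is not None else _default_init(spec)
    free = np.ones(theta.size, bool)
    for k in fix_cov_zero:
        if nt == 1:
            raise ValueError("cannot fix a covariance in a single-trait model")
        theta[k * per + 1] = 0.0
        free[k * per + 1] = False
    phi = _clip_phi(_theta_to_phi(theta, K, nt), K, nt, log_floor, log_cap)
    for k in fix_cov_zero:
        phi[k * per + 1] = 0.0
    theta = _phi_to_theta(phi, K, nt)

    derivs = _derivative_structures(spec)
    M, resid = _unpack(theta, K, nt)
    ll, chol, aux, Py = _loglik_chol(spec, M, resid)
    if chol is None:
        raise linalg.LinAlgError("initial covariance matrix not positive definite")

    converged = False
    n_iter = 0
    small_gain = 0
    AIf_theta = None
    for it in range(max_iter):
        n_iter = it + 1
        # P explicitly: V⁻¹ - V⁻¹X (X'V⁻¹X)⁻¹ X'V⁻¹
        Vinv = linalg.cho_solve(chol, np.eye(spec.n_records), check_finite=False)
        ViX, cx = aux
        P = Vinv - ViX @ linalg.cho_solve(cx, ViX.T, check_finite=False)
        P = (P + P.T) / 2.0

        q = np.column_stack([D @ Py for D in derivs])         # V_i P y
        grad = np.array([
            -0.5 * (np.sum(P * D) - Py @ qi) for D, qi in zip(derivs, q.T)
        ])
        AI = 0.5 * (q.T @ P @ q)
        AI = (AI + AI.T) / 2.0
        AIf_theta = AI[np.ix_(free, free)]

        J = _jacobian(phi, K, nt)
        grad_phi = (J.T @ grad)[free]
        AI_phi = (J.T @ AI @ J)[np.ix_(free, free)]
        scale = np.maximum(np.abs(np.diag(AI_phi)), 1e-10)
        lam = 0.1 if it < warmup else 0.0

        if np.max(np.abs(grad_phi)) < 1e-10:  # stationary point
            converged = True
            break

        accepted = False
        for _attempt in range(4):
            try:
                delta = np.linalg.solve(AI_phi + lam * np.diag(scale), grad_phi)
            except np.linalg.LinAlgError:
                delta = np.linalg.lstsq(AI_phi + lam * np.diag(scale),
                                        grad_phi, rcond=None)[0]
            step = 1.0
            for _half in range(20):
                cand = phi.copy()
                cand[free] += step * delta
                cand = _clip_phi(cand, K, nt, log_floor, log_cap)
                for k in fix_cov_zero:
                    cand[k * per + 1] = 0.0
                theta_c = _phi_to_theta(cand, K, nt)
                Mc, rc = _unpack(theta_c, K, nt)
                llc, cholc, auxc, Pyc = _loglik_chol(spec, Mc, rc)
                if llc > -np.inf and llc >= ll - 1e-12:
                    accepted = True
                    break
                step /= 2.0
            if accepted:
                break
            lam = max(lam, 1e-3) * 10.0  # re-damp and retry
        if not accepted:
            converged = True  # no admissible uphill move: treat as stationary
            break

        param_change = np.max(np.abs(cand - phi))
        improvement = llc - ll
        phi, ll, chol, aux, Py = cand, llc, cholc, auxc, Pyc
        theta = _phi_to_theta(phi, K, nt)
        M, resid = _unpack(theta, K, nt)
        if improvement < tol and param_change < 1e-6:
            converged = True
            break
        if improvement < tol:
            small_gain += 1
            if small_gain >= 2:  # likelihood flat: numerically converged
                converged = True
                break
        else:
            small_gain = 0

    try:
        ai_free_inv = np.linalg.inv(AIf_theta)
    except (np.linalg.LinAlgError, TypeError):
        ai_free_inv = None
    if not converged:
        warnings.warn(f"REML did not converge in {n_iter} iterations "
                      f"(loglik {ll:.6f})")
    return VarianceComponents(
        M=M, resid=resid, loglik=ll, converged=converged, n_iter=n_iter,
        kernel_labels=list(spec.kernel_labels), ai_inverse=ai_free_inv,
        free_mask=free)


def derive_params(vc: VarianceComponents) -> DerivedParams:
    """Heritabilities and per-kernel genetic correlations with delta-method SEs.

    ``h²_p = Σ_k σ²_{ap,k} / (Σ_k σ²_{ap,k} + σ²_{ep})`` and
    ``r_{g,k} = σ_{a12,k} / sqrt(σ²_{a1,k} σ²_{a2,k})``.  Kernels with (near)
    zero genetic variance in either population get ``r_g = NaN``.  Standard
    errors come from the inverse AI matrix when available.
    """
    K, nt = vc.n_kernels, vc.n_traits
    per = 1 if nt == 1 else 3
    h2 = np.empty(nt)
    for a in range(nt):
        ga = vc.M[:, a, a].sum()
        h2[a] = ga / (ga + vc.resid[a])
    r_g = np.full(K, np.nan)
    if nt == 2:
        for k in range(K):
            v1, v2 = vc.M[k, 0, 0], vc.M[k, 1, 1]
            if v1 > 1e-12 and v2 > 1e-12:
                r_g[k] = np.clip(vc.M[k, 0, 1] / np.sqrt(v1 * v2), -1.0, 1.0)

    h2_se = np.full(nt, np.nan)
    r_g_se = np.full(K, np.nan)
    if vc.ai_inverse is not None and vc.free_mask is not None:
        n_par = vc.free_mask.size
        cov = np.zeros((n_par, n_par))
        ixf = np.flatnonzero(vc.free_mask)
        cov[np.ix_(ixf, ixf)] = vc.ai_inverse
        for a in range(nt):
            grad = np.zeros(n_par)
            ga = vc.M[:, a, a].sum()
            tot = ga + vc.resid[a]
            for k in range(K):
                grad[k * per + (0 if (nt == 1 or a == 0) else 2)] = \
                    vc.resid[a] / tot**2
            grad[K * per + a] = -ga / tot**2
            h2_se[a] = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
        if nt == 2:
            for k in range(K):
                v1, c12, v2 = vc.M[k, 0, 0], vc.M[k, 0, 1], vc.M[k, 1, 1]
                if not (v1 > 1e-12 and v2 > 1e-12):
                    continue
                s = np.sqrt(v1 * v2)
                grad = np.zeros(n_par)
                grad[k * per + 0] = -0.5 * c12 / (s * v1)
                grad[k * per + 1] = 1.0 / s
                grad[k * per + 2] = -0.5 * c12 / (s * v2)
                r_g_se[k] = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    return DerivedParams(h2=h2, h2_se=h2_se, r_g=r_g, r_g_se=r_g_se,
                         kernel_labels=list(vc.kernel_labels))


def lrt_zero_covariance(
    spec: ModelSpec,
    kernel_index: int = 0,
    full: VarianceComponents | None = None,
    **fit_kwargs,
) -> tuple[float, float]:
    """Likelihood-ratio test of σ_a12 = 0 for one kernel.

    Fits the model with and without the between-population covariance of
    ``kernel_index`` and returns ``(statistic, p)`` with the statistic
    clamped at zero and p from a 1-df chi-square.  A pre-fitted unconstrained
    model may be passed to avoid refitting.
    """
    if spec.n_traits != 2:
        raise ValueError("covariance test requires the bivariate model")
    if full is None:
        full = fit_reml(spec, **fit_kwargs)
    null = fit_reml(spec, fix_cov_zero=(kernel_index,), **fit_kwargs)
    if null.loglik > full.loglik + 1e-6:
        raise RuntimeError(
            "constrained fit exceeds unconstrained log-likelihood: optimizer failure")
    stat = max(0.0, 2.0 * (full.loglik - null.loglik))
    p = float(stats.chi2.sf(stat, df=1))
    return stat, p


def fit_report(vc: VarianceComponents) -> "pd.DataFrame":
    """Tidy per-kernel fit report (TSV-ready)."""
    import pandas as pd

    dp = derive_params(vc)
    rows = []
    for k in range(vc.n_kernels):
        row = {"kernel": vc.kernel_labels[k] if vc.kernel_labels else str(k),
               "var_a1": vc.M[k, 0, 0]}
        if vc.n_traits == 2:
            row["cov_a12"] = vc.M[k, 0, 1]
            row["var_a2"] = vc.M[k, 1, 1]
            row["r_g"] = dp.r_g[k]
            row["r_g_se"] = dp.r_g_se[k]
        rows.append(row)
    df = pd.DataFrame(rows)
    df["loglik"] = vc.loglik
    df["converged"] = vc.converged
    return df
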