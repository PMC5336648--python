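"""Two-cycle AECM estimation for the OSGaBi family.

The alternating expectation-conditional maximization (AECM) algorithm uses
a different complete-data specification in each cycle:

* cycle 1 treats (x_i, z_i) as complete data, computes responsibilities
  zhat and updates the mixing proportions pi_g and means mu_g;
* cycle 2 treats (x_i, z_i, U_i) as complete data, recomputes zhat under
  the fresh (pi, mu), forms the conditional factor moments and updates the
  noise variances Psi_g (the loadings Lambda are supplied and never
  re-estimated).

All Gaussian densities are evaluated with the Woodbury identity

    (Psi + Lambda Lambda')^{-1}
        = Psi^{-1} - Psi^{-1} Lambda M^{-1} Lambda' Psi^{-1},
    M = I_q + Lambda' Psi^{-1} Lambda,

and the matching determinant identity |Psi + Lambda Lambda'| = |Psi| |M|,
so only diagonal and q x q systems are ever solved.  Convergence is judged
by Aitken acceleration of the log-likelihood sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp

from .core import (
    PSI_FLOOR,
    ExpressionMatrix,
    FitResult,
    LoadingsSpec,
    ModelParams,
    contract_psi,
    expand_psi,
    lambda_shared,
    psi_isotropic,
    psi_shared,
    validate_loadings,
    validate_model_name,
)

logger = logging.getLogger("osgabi")

#: Aitken stopping tolerance on the asymptotic log-likelihood gain.
DEFAULT_EPSILON = 0.1
DEFAULT_MAX_ITER = 1000
DEFAULT_N_STARTS = 20


class DegenerateComponentError(RuntimeError):
    """A component's effective size n_g dropped below the usable floor."""


# ---------------------------------------------------------------------------
# low-rank-plus-diagonal linear algebra
# ---------------------------------------------------------------------------

def woodbury_inverse(lam: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Inverse of (Lambda Lambda' + Psi) with Psi = diag(psi) via Woodbury.

    Only the q x q core M = I_q + Lambda' Psi^{-1} Lambda is factorized;
    no dense p x p system is solved.
    """
    lam = np.asarray(lam, dtype=float)
    psi = np.asarray(psi, dtype=float)
    psi_inv = 1.0 / psi
    lp = lam * psi_inv[:, None]                      # Psi^{-1} Lambda
    m = np.eye(lam.shape[1]) + lam.T @ lp
    core = cho_solve(cho_factor(m), lp.T)            # M^{-1} Lambda' Psi^{-1}
    return np.diag(psi_inv) - lp @ core


def logdet_identity(lam: np.ndarray, psi: np.ndarray) -> float:
    """log |Lambda Lambda' + Psi| through the q x q determinant lemma."""
    lam = np.asarray(lam, dtype=float)
    psi = np.asarray(psi, dtype=float)
    m = np.eye(lam.shape[1]) + (lam.T / psi) @ lam
    sign, logdet_m = np.linalg.slogdet(m)
    if sign <= 0:  # impossible for psi > 0; guards numerical breakdown
        raise FloatingPointError("Woodbury core matrix not positive definite")
    return float(np.sum(np.log(psi)) + logdet_m)


def _component_suffstats(lam: np.ndarray, psi: np.ndarray):
    """Cholesky of the Woodbury core plus the pieces reused per component."""
    psi_inv = 1.0 / psi
    lp = lam * psi_inv[:, None]
    m = np.eye(lam.shape[1]) + lam.T @ lp
    chol = cho_factor(m)
    logdet = float(np.sum(np.log(psi)) + 2.0 * np.sum(np.log(np.diag(chol[0]))))
    return psi_inv, lp, chol, logdet


def _component_logpdf(x: np.ndarray, mu: np.ndarray, lam: np.ndarray,
                      psi: np.ndarray) -> np.ndarray:
    """N(mu, Lambda Lambda' + diag(psi)) log-density of every row of x."""
    psi_inv, lp, chol, logdet = _component_suffstats(lam, psi)
    diff = x - mu
    a = diff @ lp                                    # n x q
    quad = (diff * diff) @ psi_inv - np.sum(a * cho_solve(chol, a.T).T, axis=1)
    p = x.shape[1]
    return -0.5 * (p * np.log(2.0 * np.pi) + logdet + quad)


def beta_matrix(lam: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Regression of factors on data: beta = Lambda' (Lambda Lambda' + Psi)^{-1}.

    Computed as M^{-1} Lambda' Psi^{-1} (a q x q solve), which equals the
    dense form by the Woodbury identity.
    """
    psi_inv, lp, chol, _ = _component_suffstats(lam, psi)
    return cho_solve(chol, lp.T)


# ---------------------------------------------------------------------------
# E-steps
# ---------------------------------------------------------------------------

def _log_density_matrix(x: np.ndarray, params: ModelParams) -> np.ndarray:
    psi_gp = params.psi_matrix()
    out = np.empty((x.shape[0], params.G))
    for g in range(params.G):
        out[:, g] = _component_logpdf(
            x, params.mu[g], params.loadings.matrix_for(g), psi_gp[g]
        )
    return out


def e_step_responsibilities(x: ExpressionMatrix | np.ndarray,
                            params: ModelParams) -> np.ndarray:
    """Posterior component probabilities zhat_ig, stabilized in log space.

    zhat_ig = pi_g phi(x_i | mu_g, Sigma_g) / sum_h pi_h phi(x_i | ...);
    rows sum to 1 exactly (log-sum-exp, never NaN on underflow).
    """
    xv = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, float)
    logp = _log_density_matrix(xv, params) + np.log(params.pi)
    return np.exp(logp - logsumexp(logp, axis=1, keepdims=True))


def observed_loglik(x: ExpressionMatrix | np.ndarray,
                    params: ModelParams) -> float:
    """Observed-data log-likelihood sum_i log sum_g pi_g phi(x_i|mu_g,Sigma_g)."""
    xv = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, float)
    logp = _log_density_matrix(xv, params) + np.log(params.pi)
    return float(np.sum(logsumexp(logp, axis=1)))


# ---------------------------------------------------------------------------
# CM-steps
# ---------------------------------------------------------------------------

def cm_step_pi_mu(x: ExpressionMatrix | np.ndarray, zhat: np.ndarray,
                  n_g_floor: float | None = None):
    """Cycle-1 maximizers: pi_g = n_g / n, mu_g = weighted mean.

    Raises :class:`DegenerateComponentError` if any effective component
    size n_g falls below ``n_g_floor``.
    """
    xv = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, float)
    n_g = zhat.sum(axis=0)
    if n_g_floor is not None and np.any(n_g < n_g_floor):
        raise DegenerateComponentError(
            f"component size {n_g.min():.3g} below floor {n_g_floor}"
        )
    pi = n_g / xv.shape[0]
    mu = (zhat.T @ xv) / n_g[:, None]
    return pi, mu


@dataclass
class FactorMoments:
    """Conditional moments of the latent factors, per component.

    beta[g] (q x p) maps centred data to E[U_ig | x_i]; S[g] is the
    responsibility-weighted scatter; Theta[g] = I_q - beta_g Lambda_g +
    beta_g S_g beta_g' aggregates E[U U'] over the component.
    """

    beta: list[np.ndarray]
    S: list[np.ndarray]
    Theta: list[np.ndarray]
    n_g: np.ndarray


def factor_moments(x: ExpressionMatrix | np.ndarray, params: ModelParams,
                   zhat: np.ndarray) -> FactorMoments:
    """Cycle-2 expected factor statistics under the current parameters."""
    xv = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, float)
    psi_gp = params.psi_matrix()
    n_g = zhat.sum(axis=0)
    beta, S, Theta = [], [], []
    q = params.q
    for g in range(params.G):
        lam = params.loadings.matrix_for(g)
        b = beta_matrix(lam, psi_gp[g])
        diff = xv - params.mu[g]
        s = (diff * zhat[:, g, None]).T @ diff / n_g[g]
        th = np.eye(q) - b @ lam + b @ s @ b.T
        beta.append(b)
        S.append(s)
        Theta.append(th)
    return FactorMoments(beta=beta, S=S, Theta=Theta, n_g=n_g)


def cm_step_psi(params: ModelParams, moments: FactorMoments) -> np.ndarray:
    """Cycle-2 maximizer of Q2 for the model's Psi constraint pattern.

    The per-component diagonal residual is

        d_g = diag{ S_g - 2 Lambda_g beta_g S_g + Lambda_g Theta_g Lambda_g' },

    and the eight family members reduce to four aggregation patterns of
    d_g: keep (?UU), trace/p (?UC), n_g-weighted average over g (?CU), and
    both (?CC).  Every variance is floored at ``PSI_FLOOR``.

    Returns psi in the model's natural (contracted) shape.
    """
    G, p = params.G, params.p
    d = np.empty((G, p))
    for g in range(G):
        lam = params.loadings.matrix_for(g)
        b, s, th = moments.beta[g], moments.S[g], moments.Theta[g]
        d[g] = np.diag(s - 2.0 * (lam @ b @ s) + lam @ th @ lam.T)
    if psi_shared(params.model):
        w = moments.n_g / moments.n_g.sum()
        d = np.repeat((w @ d)[None, :], G, axis=0)
    if psi_isotropic(params.model):
        d = np.repeat(d.mean(axis=1, keepdims=True), p, axis=1)
    if np.any(d <= 0):
        logger.warning(
            "non-positive noise variance before flooring (model %s); "
            "floor %.1e applied", params.model, PSI_FLOOR,
        )
    return contract_psi(np.maximum(d, PSI_FLOOR), params.model)


# ---------------------------------------------------------------------------
# convergence
# ---------------------------------------------------------------------------

@dataclass
class AitkenState:
    """The last three log-likelihood values l^(t-1), l^(t), l^(t+1)."""

    l_prev: float
    l_curr: float
    l_next: float

    @property
    def a(self) -> float:
        return (self.l_next - self.l_curr) / (self.l_curr - self.l_prev)

    @property
    def l_inf(self) -> float:
        return self.l_curr + (self.l_next - self.l_curr) / (1.0 - self.a)


def aitken_converged(state: AitkenState, epsilon: float = DEFAULT_EPSILON) -> bool:
    """Stop when the Aitken-extrapolated asymptote is within epsilon.

    Computes a^(t) = (l^(t+1)-l^(t)) / (l^(t)-l^(t-1)) and the asymptotic
    estimate l_inf^(t+1) = l^(t) + (l^(t+1)-l^(t)) / (1-a^(t)); declares
    convergence iff 0 <= l_inf^(t+1) - l^(t) < epsilon (the difference must
    be positive).  A flat sequence converges; a^(t) >= 1 or a vanishing
    denominator means "not yet".
    """
    denom = state.l_curr - state.l_prev
    num = state.l_next - state.l_curr
    if abs(denom) < 1e-12:
        return abs(num) < 1e-12  # flat sequence has reached its asymptote
    a = num / denom
    if a >= 1.0 - 1e-12:
        return False
    gain = num / (1.0 - a)
    return 0.0 <= gain < epsilon


# ---------------------------------------------------------------------------
# single fit and grid
# ---------------------------------------------------------------------------

def _initial_params(xv: np.ndarray, model: str, G: int, spec: LoadingsSpec,
                    rng: np.random.Generator, max_redraws: int = 5) -> ModelParams:
    """Random hard-partition start: uniform multinomial labels -> (pi, mu);
    Psi from the pooled per-variable sample variances."""
    n, p = xv.shape
    q = spec.q
    for _ in range(max_redraws + 1):
        labels = rng.integers(0, G, size=n)
        counts = np.bincount(labels, minlength=G)
        if np.all(counts >= q + 1):
            break
    else:
        raise DegenerateComponentError(
            f"could not draw a start with all components of size >= {q + 1}"
        )
    z = np.zeros((n, G))
    z[np.arange(n), labels] = 1.0
    pi, mu = cm_step_pi_mu(xv, z)
    pooled = np.maximum(xv.var(axis=0), PSI_FLOOR)
    psi_gp = np.repeat(pooled[None, :], G, axis=0)
    if psi_isotropic(model):
        psi_gp = np.full((G, p), pooled.mean())
    return ModelParams(
        model=model, G=G, pi=pi, mu=mu, loadings=spec,
        psi=contract_psi(psi_gp, model),
    )


def _aecm_run(xv: np.ndarray, params: ModelParams, epsilon: float,
              max_iter: int, n_g_floor: float):
    """One AECM run from given starting parameters.

    Returns (params, zhat, trace, n_iter, converged)."""
    trace: list[float] = []
    converged = False
    zhat = None
    for it in range(max_iter):
        # cycle 1: memberships complete-data; update pi, mu
        zhat = e_step_responsibilities(xv, params)
        pi, mu = cm_step_pi_mu(xv, zhat, n_g_floor=n_g_floor)
        params = ModelParams(
            model=params.model, G=params.G, pi=pi, mu=mu,
            loadings=params.loadings, psi=params.psi,
        )
        # cycle 2: memberships + factors; update Psi
        zhat = e_step_responsibilities(xv, params)
        moments = factor_moments(xv, params, zhat)
        psi = cm_step_psi(params, moments)
        params = ModelParams(
            model=params.model, G=params.G, pi=params.pi, mu=params.mu,
            loadings=params.loadings, psi=psi,
        )
        trace.append(observed_loglik(xv, params))
        if len(trace) == 2 and abs(trace[1] - trace[0]) < epsilon:
            converged = True
        elif len(trace) >= 3:
            state = AitkenState(trace[-3], trace[-2], trace[-1])
            converged = aitken_converged(state, epsilon)
        if converged:
            break
    zhat = e_step_responsibilities(xv, params)
    return params, zhat, np.asarray(trace), len(trace), converged


def fit_single(
    x: ExpressionMatrix | np.ndarray,
    model: str,
    G: int,
    spec: LoadingsSpec,
    n_starts: int = DEFAULT_N_STARTS,
    seed: int | np.random.SeedSequence = 0,
    max_iter: int = DEFAULT_MAX_ITER,
    epsilon: float = DEFAULT_EPSILON,
) -> FitResult:
    """Fit one (model, G) cell from ``n_starts`` random initializations.

    Each start draws an independent hard random partition, runs AECM to the
    Aitken criterion, and the best converged log-likelihood wins.  All
    randomness derives deterministically from ``seed`` (one substream per
    start).  Starts whose components degenerate (n_g < q + 1) are marked
    failed and skipped; if every start fails the result carries
    ``failed=True`` rather than raising.
    """
    validate_model_name(model)
    xv = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, float)
    spec = validate_loadings(spec, xv.shape[1], G, model)
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    n_g_floor = spec.q + 1
    best: FitResult | None = None
    n_failed = 0
    for child in ss.spawn(n_starts):
        rng = np.random.Generator(np.random.PCG64(child))
        try:
            params0 = _initial_params(xv, model, G, spec, rng)
            params, zhat, trace, n_iter, converged = _aecm_run(
                xv, params0, epsilon, max_iter, n_g_floor
            )
        except (DegenerateComponentError, FloatingPointError) as exc:
            logger.debug("start failed for %s G=%d: %s", model, G, exc)
            n_failed += 1
            continue
        cand = FitResult(
            params=params, zhat=zhat, loglik_trace=trace,
            n_iter=n_iter, converged=converged,
        )
        if best is None:
            best = cand
        elif (cand.converged, cand.loglik) > (best.converged, best.loglik):
            best = cand
    if best is None:
        return FitResult(
            params=None, zhat=None, loglik_trace=np.array([]), n_iter=0,
            converged=False, failed=True,
            failure_reason=f"all {n_starts} starts degenerate",
        )
    return best


def fit_grid(
    x: ExpressionMatrix | np.ndarray,
    models: list[str] | tuple[str, ...],
    G_range: list[int] | range,
    spec: LoadingsSpec,
    n_starts: int = DEFAULT_N_STARTS,
    seed: int | np.random.SeedSequence = 0,
    max_iter: int = DEFAULT_MAX_ITER,
    epsilon: float = DEFAULT_EPSILON,
    criterion: str = "bic",
):
    """Fit every (model, G) cell and select a winner by information criterion.

    For per-component-Lambda models (U??) the supplied number of loadings
    matrices pins G, so ``G_range`` is ignored for those models.  Returns
    ``(table, best_model, best_G)`` where ``table`` is a
    :class:`~osgabi.selection.CriterionTable`.
    """
    from .selection import CriterionTable, score_fit  # cycle-free at runtime

    models = list(models)
    G_list = list(G_range)
    if not models or not G_list:
        raise ValueError("empty model/G grid")
    for m in models:
        validate_model_name(m)
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    xv = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, float)
    cells = []
    for m in models:
        cells.extend(
            [(m, len(spec.matrices))] if not lambda_shared(m)
            else [(m, G) for G in G_list]
        )
    table = CriterionTable()
    for (m, G), child in zip(cells, ss.spawn(len(cells))):
        fit = fit_single(
            xv, m, G, spec, n_starts=n_starts, seed=child,
            max_iter=max_iter, epsilon=epsilon,
        )
        if not fit.failed:
            score_fit(fit, xv.shape[0], xv.shape[1])
        table.add(m, G, fit)
        logger.info(
            "fitted %s G=%d: loglik=%.2f converged=%s", m, G,
            fit.loglik, fit.converged,
        )
    best_model, best_G = table.select_best(criterion)
    return table, best_model, best_G
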