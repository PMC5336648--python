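"""Domain types for the OSGaBi model family.

OSGaBi ("one-way supervised Gaussian biclustering") is a family of eight
parsimonious Gaussian mixture models for biclustering a numeric
observations x variables matrix (genes x samples).  Each mixture component
is a factor-analysis model

    X_i = mu_g + Lambda_g U_ig + eps_ig,     U_ig ~ N(0, I_q),
    eps_ig ~ N(0, Psi_g),

where the p x q loadings matrix Lambda_g is *binary row-stochastic*: each
variable (column of the data) belongs to exactly one of q variable
clusters.  That makes the component covariance

    Sigma_g = Lambda_g Lambda_g' + Psi_g

block diagonal: variables in different variable clusters are uncorrelated.
The variable clustering is supplied by the user and held fixed (the
"one-way supervision"); only the observation clustering is estimated.

The family arises from three binary constraints, encoded as a three-letter
model name over {C, U} (C = constrained, U = unconstrained):

    letter 1: Lambda_g = Lambda  (shared loadings across components)
    letter 2: Psi_g    = Psi     (shared noise across components)
    letter 3: Psi_g    = psi_g I (isotropic noise)

giving the eight models CCC, CCU, CUC, CUU, UCC, UCU, UUC, UUU with
1, p, G, Gp, 1, p, G and Gp covariance parameters respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

MODEL_NAMES: tuple[str, ...] = (
    "CCC", "CCU", "CUC", "CUU", "UCC", "UCU", "UUC", "UUU",
)

#: Positivity floor applied to every noise variance during estimation.
PSI_FLOOR = 1e-6


class InvalidSpecError(ValueError):
    """A loadings specification violates the binary row-stochastic contract."""


class ModelSpecMismatchError(ValueError):
    """Loadings-matrix count is inconsistent with the model's Lambda constraint."""


def validate_model_name(code: str) -> str:
    if code not in MODEL_NAMES:
        raise ValueError(
            f"unknown model name {code!r}; expected one of {MODEL_NAMES}"
        )
    return code


def lambda_shared(code: str) -> bool:
    """True if the model constrains Lambda_g = Lambda across components."""
    return validate_model_name(code)[0] == "C"


def psi_shared(code: str) -> bool:
    """True if the model constrains Psi_g = Psi across components."""
    return validate_model_name(code)[1] == "C"


def psi_isotropic(code: str) -> bool:
    """True if the model constrains Psi_g = psi_g I (a single variance)."""
    return validate_model_name(code)[2] == "C"


def cov_param_count(code: str, G: int, p: int) -> int:
    """Number of free covariance parameters for one family member.

    Lambda is supplied, never estimated, so it contributes nothing; the
    count is driven entirely by the two Psi constraints:
    shared+isotropic -> 1, shared+diagonal -> p, per-component isotropic
    -> G, per-component diagonal -> G*p.
    """
    validate_model_name(code)
    per_group = 1 if psi_isotropic(code) else p
    groups = 1 if psi_shared(code) else G
    return groups * per_group


@dataclass
class ExpressionMatrix:
    """An n x p numeric matrix; rows are observations to be clustered.

    Orientation is fixed: rows are the observations (genes), columns the
    variables (samples) whose cluster labels are supplied via a
    :class:`LoadingsSpec`.  Transposition is the caller's job.
    """

    values: np.ndarray
    row_ids: Sequence[str] | None = None
    col_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression matrix must be two-dimensional")
        n, p = self.values.shape
        if n < 2 or p < 2:
            raise ValueError(f"need n >= 2 and p >= 2, got {n} x {p}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains missing/non-finite values")
        if self.row_ids is None:
            self.row_ids = [f"obs{i + 1}" for i in range(n)]
        if self.col_ids is None:
            self.col_ids = [f"var{j + 1}" for j in range(p)]
        if len(self.row_ids) != n or len(self.col_ids) != p:
            raise ValueError("id lengths do not match matrix shape")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass
class LoadingsSpec:
    """Binary row-stochastic p x q loadings, shared or per-component.

    ``matrices`` holds one p x q matrix when Lambda is shared across
    components and G matrices (one per component) otherwise.  Each row has
    exactly one 1 — every variable belongs to exactly one variable
    cluster — so (Lambda Lambda')_{jk} is 1 iff variables j and k share a
    cluster, which is what induces the block-diagonal covariance.
    """

    matrices: list[np.ndarray]

    def __post_init__(self) -> None:
        if not self.matrices:
            raise InvalidSpecError("loadings spec needs at least one matrix")
        mats = []
        shape = None
        for m in self.matrices:
            m = np.asarray(m, dtype=float)
            if m.ndim != 2:
                raise InvalidSpecError("each loadings matrix must be p x q")
            if shape is None:
                shape = m.shape
            elif m.shape != shape:
                raise InvalidSpecError("loadings matrices differ in shape")
            if not np.isin(m, (0.0, 1.0)).all():
                raise InvalidSpecError("loadings entries must be 0 or 1")
            if not np.array_equal(m.sum(axis=1), np.ones(m.shape[0])):
                raise InvalidSpecError(
                    "each variable must belong to exactly one variable cluster "
                    "(rows must sum to 1)"
                )
            if (m.sum(axis=0) == 0).any():
                raise InvalidSpecError("empty variable cluster in loadings spec")
            mats.append(m)
        p, q = shape
        if not q < p:
            raise InvalidSpecError(f"need q < p, got q={q}, p={p}")
        self.matrices = mats

    @property
    def p(self) -> int:
        return self.matrices[0].shape[0]

    @property
    def q(self) -> int:
        """Number of variable clusters, inferred from the column count."""
        return self.matrices[0].shape[1]

    @property
    def shared(self) -> bool:
        return len(self.matrices) == 1

    def matrix_for(self, g: int) -> np.ndarray:
        """Loadings of component ``g`` (0-based); the single matrix if shared."""
        return self.matrices[0] if self.shared else self.matrices[g]

    def var_labels(self) -> np.ndarray:
        """0-based variable-cluster labels, from the first component's matrix.

        When per-component matrices differ the first component's labelling
        is the reporting convention.
        """
        return np.argmax(self.matrices[0], axis=1)


def validate_loadings(
    spec: LoadingsSpec, p: int, G: int, model: str
) -> LoadingsSpec:
    """Check a loadings spec against the data shape and the model's constraint.

    Shared-Lambda models (C??) require exactly one matrix; per-component
    models (U??) require exactly G.  Returns the spec unchanged on success.
    """
    validate_model_name(model)
    if spec.p != p:
        raise InvalidSpecError(
            f"loadings have {spec.p} rows but the data has p={p} variables"
        )
    expected = 1 if lambda_shared(model) else G
    if len(spec.matrices) != expected:
        raise ModelSpecMismatchError(
            f"model {model} requires {expected} loadings matrix(es), "
            f"got {len(spec.matrices)}"
        )
    return spec


@dataclass
class ModelParams:
    """Parameters of one fitted (or generating) OSGaBi family member.

    ``psi`` is stored in the model's natural shape: a scalar for ?CC, a
    p-vector for ?CU, a G-vector for ?UC and a G x p matrix for ?UU.
    """

    model: str
    G: int
    pi: np.ndarray
    mu: np.ndarray
    loadings: LoadingsSpec
    psi: np.ndarray

    def __post_init__(self) -> None:
        validate_model_name(self.model)
        self.pi = np.asarray(self.pi, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        if self.pi.shape != (self.G,):
            raise ValueError("pi must be a G-vector")
        if np.any(self.pi <= 0) or np.any(self.pi > 1) or not np.isclose(
            self.pi.sum(), 1.0
        ):
            raise ValueError("mixing proportions must lie in (0,1] and sum to 1")
        if self.mu.shape != (self.G, self.loadings.p):
            raise ValueError("mu must be G x p")
        validate_loadings(self.loadings, self.loadings.p, self.G, self.model)
        if np.any(self.psi_matrix() <= 0):
            raise ValueError("all noise variances must be strictly positive")

    @property
    def p(self) -> int:
        return self.loadings.p

    @property
    def q(self) -> int:
        return self.loadings.q

    def psi_matrix(self) -> np.ndarray:
        """Noise variances expanded to a dense G x p array."""
        return expand_psi(self.psi, self.model, self.G, self.p)

    def psi_diag(self, g: int) -> np.ndarray:
        """The p-vector of noise variances of component ``g`` (0-based)."""
        return self.psi_matrix()[g]


def expand_psi(psi: np.ndarray, model: str, G: int, p: int) -> np.ndarray:
    """Expand a constrained psi representation to a dense G x p array."""
    psi = np.asarray(psi, dtype=float)
    iso, shared = psi_isotropic(model), psi_shared(model)
    if iso and shared:
        if psi.shape not in ((), (1,)):
            raise ValueError(f"model {model} expects a scalar psi")
        return np.full((G, p), float(psi))
    if iso:
        if psi.shape != (G,):
            raise ValueError(f"model {model} expects a G-vector psi")
        return np.repeat(psi[:, None], p, axis=1)
    if shared:
        if psi.shape != (p,):
            raise ValueError(f"model {model} expects a p-vector psi")
        return np.repeat(psi[None, :], G, axis=0)
    if psi.shape != (G, p):
        raise ValueError(f"model {model} expects a G x p psi")
    return psi


def contract_psi(psi_gp: np.ndarray, model: str) -> np.ndarray:
    """Collapse a dense G x p psi to the model's natural shape."""
    iso, shared = psi_isotropic(model), psi_shared(model)
    if iso and shared:
        return np.asarray(psi_gp[0, 0])
    if iso:
        return psi_gp[:, 0].copy()
    if shared:
        return psi_gp[0].copy()
    return psi_gp.copy()


def covariance_from_params(params: ModelParams, g: int) -> np.ndarray:
    """Dense component covariance Sigma_g = Lambda_g Lambda_g' + Psi_g.

    Off-block entries (variables in different variable clusters) are
    exactly zero off the diagonal.
    """
    lam = params.loadings.matrix_for(g)
    return lam @ lam.T + np.diag(params.psi_diag(g))


@dataclass
class FitResult:
    """Outcome of one AECM fit: parameters, responsibilities, diagnostics."""

    params: ModelParams | None
    zhat: np.ndarray | None
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool
    failed: bool = False
    failure_reason: str | None = None
    bic: float = float("nan")
    icl: float = float("nan")
    aic: float = float("nan")

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1]) if len(self.loglik_trace) else float("nan")


@dataclass
class BiclusterAssignment:
    """The G x q bicluster grid implied by a fit and its loadings spec.

    ``obs_labels`` are 0-based MAP component labels; ``var_labels`` are the
    0-based variable-cluster labels carried by the supplied loadings.  The
    row/column orders sort observations by component and variables by
    cluster (stable), exposing contiguous blocks in the reordered matrix.
    """

    obs_labels: np.ndarray
    var_labels: np.ndarray
    G: int
    q: int
    row_order: np.ndarray = field(default=None)  # type: ignore[assignment]
    col_order: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.row_order is None:
            self.row_order = np.argsort(self.obs_labels, kind="stable")
        if self.col_order is None:
            self.col_order = np.argsort(self.var_labels, kind="stable")

    @property
    def grid(self) -> np.ndarray:
        """G x q matrix of bicluster sizes (observations x variables)."""
        obs_counts = np.bincount(self.obs_labels, minlength=self.G)
        var_counts = np.bincount(self.var_labels, minlength=self.q)
        return np.outer(obs_counts, var_counts)
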