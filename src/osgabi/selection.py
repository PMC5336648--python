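"""Information criteria and winner selection over a fitted model grid.

All criteria use the *maximization* convention: BIC = 2l - m log n,
AIC = 2l - 2m, ICL = BIC + 2 sum_i sum_g MAP(zhat_ig) log zhat_ig, so the
largest value wins.  This matches the model-based-clustering literature;
the sign flip relative to the "minimize" convention is a classic source of
bugs, hence stated prominently here.

The free-parameter count excludes the loadings Lambda entirely: the
variable clustering is supervised input, not an estimated quantity, so
only the mixing proportions, the means and the constrained noise
variances are counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import FitResult, cov_param_count, validate_model_name

CRITERIA = ("bic", "icl", "aic")


class SelectionError(RuntimeError):
    """No converged fit is available to select from."""


def count_free_params(model: str, G: int, p: int) -> int:
    """(G-1) mixing + G*p means + constrained covariance parameters."""
    validate_model_name(model)
    return (G - 1) + G * p + cov_param_count(model, G, p)


def bic(loglik: float, n_params: int, n: int) -> float:
    return 2.0 * loglik - n_params * np.log(n)


def aic(loglik: float, n_params: int) -> float:
    return 2.0 * loglik - 2.0 * n_params


def icl(loglik: float, n_params: int, n: int, zhat: np.ndarray) -> float:
    """BIC penalized by the MAP-indicator classification entropy.

    Adds 2 * sum_i log zhat_{i, MAP(i)} (each term <= 0), so ICL <= BIC,
    with equality exactly when zhat is hard (one-hot).
    """
    map_idx = np.argmax(zhat, axis=1)
    map_probs = zhat[np.arange(zhat.shape[0]), map_idx]
    ent = 2.0 * np.sum(np.log(np.maximum(map_probs, 1e-300)))
    return bic(loglik, n_params, n) + ent


def score_fit(fit: FitResult, n: int, p: int) -> FitResult:
    """Attach bic/icl/aic to a successful FitResult in place."""
    m = count_free_params(fit.params.model, fit.params.G, p)
    fit.bic = bic(fit.loglik, m, n)
    fit.aic = aic(fit.loglik, m)
    fit.icl = icl(fit.loglik, m, n, fit.zhat)
    return fit


@dataclass
class CriterionTable:
    """One row per fitted (model, G) cell, criteria attached."""

    rows: list[dict] = field(default_factory=list)
    fits: dict = field(default_factory=dict)

    def add(self, model: str, G: int, fit: FitResult) -> None:
        p = fit.params.p if fit.params is not None else None
        self.rows.append({
            "model": model,
            "G": G,
            "loglik": fit.loglik,
            "n_params": (count_free_params(model, G, p)
                         if p is not None else np.nan),
            "bic": fit.bic,
            "icl": fit.icl,
            "aic": fit.aic,
            "converged": bool(fit.converged and not fit.failed),
        })
        self.fits[(model, G)] = fit

    def select_best(self, criterion: str = "bic") -> tuple[str, int]:
        """Argmax of the criterion over converged rows.

        Ties break toward smaller G, then fewer free parameters; row order
        never matters.
        """
        if criterion not in CRITERIA:
            raise ValueError(f"criterion must be one of {CRITERIA}")
        candidates = [r for r in self.rows if r["converged"]]
        if not candidates:
            raise SelectionError("no converged fits to select from")
        best = max(
            candidates,
            key=lambda r: (r[criterion], -r["G"], -r["n_params"]),
        )
        return best["model"], best["G"]

    def best_fit(self, criterion: str = "bic") -> FitResult:
        return self.fits[self.select_best(criterion)]

    def to_frame(self) -> pd.DataFrame:
        cols = ["model", "G", "loglik", "n_params", "bic", "icl", "aic",
                "converged"]
        return pd.DataFrame(self.rows, columns=cols)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
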