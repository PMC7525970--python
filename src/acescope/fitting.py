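"""Maximum-likelihood logistic regression with per-observation quantities.

The fitter is a Newton/IRLS scheme that retains everything the Vuong
two-step comparison needs downstream: per-observation log-likelihood
contributions, per-observation score (gradient) contributions, and the
observed-information Hessian at the optimum. Separation is a hard error:
every downstream comparison quantity requires finite per-observation
log-likelihoods, so a silently exploding fit would poison the whole
selection workflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import norm, rankdata

from .predictors import DesignMatrix, PredictorSpec

GRADIENT_TOL = 1e-8
MAX_ITER = 100
SEPARATION_BETA = 15.0
SEPARATION_SE = 10.0


class FitError(RuntimeError):
    """Logistic MLE unavailable (non-convergence or degenerate data)."""


class SeparationError(FitError):
    """Complete or quasi-complete separation detected."""


@dataclass
class ModelFit:
    """A fitted logistic model plus the per-observation machinery.

    ``hessian`` is the Hessian of the total log-likelihood at the
    optimum (negative definite); ``score_i`` holds the n x k matrix of
    per-observation gradient contributions (y_i - p_i) x_i.
    """

    design: DesignMatrix
    beta: np.ndarray
    se: np.ndarray
    loglik_total: float
    loglik_i: np.ndarray
    score_i: np.ndarray
    hessian: np.ndarray
    fitted: np.ndarray
    converged: bool
    n_iter: int

    @property
    def spec(self) -> PredictorSpec | str:
        return self.design.spec

    @property
    def columns(self) -> list[str]:
        return self.design.columns

    @property
    def n(self) -> int:
        return self.design.n

    @property
    def k(self) -> int:
        return self.design.k

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik_total + 2.0 * self.k

    def wald_p(self) -> np.ndarray:
        """Two-sided Wald p-values per coefficient."""
        z = self.beta / self.se
        return 2.0 * norm.sf(np.abs(z))

    def coef_table(self) -> "pd.DataFrame":
        """Coefficient summary with OR = exp(beta) and 95% Wald CI."""
        import pandas as pd

        lo = self.beta - 1.96 * self.se
        hi = self.beta + 1.96 * self.se
        return pd.DataFrame(
            {
                "coef": self.beta,
                "se": self.se,
                "or": np.exp(self.beta),
                "or_low": np.exp(lo),
                "or_high": np.exp(hi),
                "p": self.wald_p(),
            },
            index=self.columns,
        )

    def label(self) -> str:
        if isinstance(self.spec, PredictorSpec):
            return f"{self.spec.family}: {self.spec.label()}"
        return str(self.spec)


def _loglik_parts(X: np.ndarray, y: np.ndarray, beta: np.ndarray):
    eta = X @ beta
    # log p_i = y*eta - log(1 + e^eta), stable at both tails
    ll_i = y * eta - np.logaddexp(0.0, eta)
    p = expit(eta)
    return ll_i, p


def fit_logistic(
    design: DesignMatrix,
    tol: float = GRADIENT_TOL,
    max_iter: int = MAX_ITER,
) -> ModelFit:
    """Fit by Newton iteration with step halving.

    Converges when the sup-norm of the score vector falls below ``tol``.
    Raises :class:`SeparationError` when the MLE does not exist (constant
    outcome, perfectly predictive column) and :class:`FitError` on
    non-convergence — never returns a silently bad fit.
    """
    X, y = design.X, design.y
    n, k = X.shape
    if y.min() == y.max():
        raise SeparationError("outcome is constant; logistic MLE is undefined")

    beta = np.zeros(k)
    ll_i, p = _loglik_parts(X, y, beta)
    ll = float(ll_i.sum())
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        grad = X.T @ (y - p)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        w = p * (1.0 - p)
        info = X.T @ (X * w[:, None])  # observed information
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise FitError("singular information matrix during Newton iteration") from exc
        # halve the step until the log-likelihood does not decrease
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_i_new, p_new = _loglik_parts(X, y, cand)
            ll_new = float(ll_i_new.sum())
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            raise FitError("step halving failed to improve the log-likelihood")
        beta, ll_i, p, ll = cand, ll_i_new, p_new, ll_new
    else:
        raise FitError(f"no convergence in {max_iter} Newton iterations")

    w = p * (1.0 - p)
    info = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise FitError("singular observed information at the optimum") from exc
    se = np.sqrt(np.diag(cov))
    big = np.abs(beta) > SEPARATION_BETA
    if np.any(big & (se > SEPARATION_SE)):
        bad = [design.columns[i] for i in np.where(big & (se > SEPARATION_SE))[0]]
        raise SeparationError(
            f"separation suspected: exploding coefficient(s) with huge SE in {bad}"
        )
    return ModelFit(
        design=design,
        beta=beta,
        se=se,
        loglik_total=ll,
        loglik_i=ll_i,
        score_i=(y - p)[:, None] * X,
        hessian=-info,
        fitted=p,
        converged=converged,
        n_iter=it,
    )


# ---------------------------------------------------------------------------
# fit metrics
# ---------------------------------------------------------------------------

@dataclass
class FitMetrics:
    aic: float
    r2_nagelkerke: float
    c_stat: float
    r2_cox_snell: float
    vif_range: tuple[float, float] | None = None


def c_statistic(predictions: np.ndarray, y: np.ndarray) -> float:
    """Concordance: P(score of a random case > score of a random non-case),
    ties counted 1/2, computed via the Mann-Whitney rank identity."""
    y = np.asarray(y, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("c-statistic needs at least one case and one non-case")
    ranks = rankdata(predictions)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def compute_metrics(fit: ModelFit, null_fit: ModelFit) -> FitMetrics:
    """AIC, Cox-Snell / Nagelkerke pseudo-R² and the c-statistic.

    ``null_fit`` must be the intercept-only model on the same rows.
    """
    if null_fit.n != fit.n or not np.array_equal(null_fit.design.y, fit.design.y):
        raise ValueError("fit and null_fit are not on the same rows/outcome")
    n = fit.n
    ll1, ll0 = fit.loglik_total, null_fit.loglik_total
    cox_snell = 1.0 - np.exp(2.0 * (ll0 - ll1) / n)
    denom = 1.0 - np.exp(2.0 * ll0 / n)
    nagelkerke = cox_snell / denom if denom > 0 else 0.0
    return FitMetrics(
        aic=fit.aic,
        r2_nagelkerke=float(nagelkerke),
        c_stat=c_statistic(fit.fitted, fit.design.y),
        r2_cox_snell=float(cox_snell),
    )


# ---------------------------------------------------------------------------
# variance inflation factors
# ---------------------------------------------------------------------------

def vif(
    design: DesignMatrix,
    columns: list[str] | None = None,
    weights: np.ndarray | None = None,
) -> dict[str, float]:
    """VIF_j = 1/(1-R²_j) for each requested column regressed (by least
    squares) on every other design column.

    Defaults to the ACE predictor columns on the unweighted design;
    ``weights`` switches to information-weighted least squares. Perfectly
    collinear columns are reported as ``inf``.
    """
    if columns is None:
        columns = design.ace_columns
    X = design.X
    if weights is not None:
        X = X * np.sqrt(np.asarray(weights, dtype=float))[:, None]
    out: dict[str, float] = {}
    for name in columns:
        j = design.columns.index(name)
        target = X[:, j]
        others = np.delete(X, j, axis=1)
        coef, _, _, _ = np.linalg.lstsq(others, target, rcond=None)
        resid = target - others @ coef
        tss = float(((target - target.mean()) ** 2).sum())
        if tss <= 0:
            out[name] = float("inf")
            continue
        r2 = 1.0 - float((resid**2).sum()) / tss
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out
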