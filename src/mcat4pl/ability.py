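"""MAP ability estimation with a multivariate-normal prior.

The trait estimate is the posterior mode of likelihood x MVN prior.  The
per-dimension standard error of measurement (SEM) is the square root of the
diagonal of the inverse curvature (observed information + prior precision)
at the mode, and converts to a model-based reliability via
``Rel = 1 - SEM^2`` — the standard identity on a latent scale with unit
prior variance.  T-scores are the linear rescaling ``T = 50 + 10*theta``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .item_model import ItemBank


class EstimationError(RuntimeError):
    """MAP optimizer failed to converge."""


@dataclass(frozen=True)
class AbilityEstimate:
    """MAP trait vector with per-dimension uncertainty.

    ``sem`` are posterior standard deviations (Laplace approximation);
    ``reliability = 1 - sem**2`` elementwise; ``t_scores = 50 + 10*theta``.
    """

    theta: np.ndarray
    sem: np.ndarray

    @property
    def reliability(self) -> np.ndarray:
        return 1.0 - self.sem**2

    @property
    def t_scores(self) -> np.ndarray:
        return t_score(self.theta)

    def to_dict(self, labels: list[str] | None = None) -> dict:
        labels = labels or [f"dim{k}" for k in range(self.theta.size)]
        return {
            "theta": dict(zip(labels, map(float, self.theta))),
            "sem": dict(zip(labels, map(float, self.sem))),
            "reliability": dict(zip(labels, map(float, self.reliability))),
            "t_scores": dict(zip(labels, map(float, self.t_scores))),
        }


def sem_from_reliability(rel: float) -> float:
    """SEM = sqrt(1 - Rel); e.g. Rel=0.80 -> 0.447, Rel=0.90 -> 0.316."""
    if not 0.0 <= rel < 1.0:
        raise ValueError(f"reliability must be in [0, 1), got {rel}")
    return float(np.sqrt(1.0 - rel))


def reliability_from_sem(sem: float) -> float:
    """Rel = 1 - SEM^2 (inverse of :func:`sem_from_reliability`)."""
    if sem < 0:
        raise ValueError(f"sem must be nonnegative, got {sem}")
    return float(1.0 - sem**2)


def t_score(theta: np.ndarray | float) -> np.ndarray | float:
    """Linear T-metric: 50 + 10*theta (population mean 50, SD 10)."""
    return 50.0 + 10.0 * np.asarray(theta, dtype=float)


def _neg_log_posterior_parts(
    arrays,
    responses: np.ndarray,
    theta: np.ndarray,
    prior_mean: np.ndarray,
    prior_precision: np.ndarray,
):
    """Value, gradient, Hessian of -log posterior (analytic, vectorized).

    ``arrays`` = (A, d, chi, gamma): loadings matrix (k x D) plus the
    per-item intercept/asymptote vectors of the administered items.
    """
    dev = theta - prior_mean
    val = 0.5 * float(dev @ prior_precision @ dev)
    grad = prior_precision @ dev
    hess = prior_precision.copy()
    A, d, chi, gamma = arrays
    if A.shape[0]:
        y = responses
        z = A @ theta + d
        pstar = expit(z)
        p = np.clip(chi + (gamma - chi) * pstar, 1e-12, 1.0 - 1e-12)
        dp = (gamma - chi) * pstar * (1.0 - pstar)
        d2p = dp * (1.0 - 2.0 * pstar)
        val -= float(np.sum(y * np.log(p) + (1 - y) * np.log(1.0 - p)))
        # w1 = d loglik / dz; w2 = d2 loglik / dz2 (per item)
        w1 = np.where(y == 1, dp / p, -dp / (1.0 - p))
        w2 = np.where(
            y == 1,
            d2p / p - (dp / p) ** 2,
            -d2p / (1.0 - p) - (dp / (1.0 - p)) ** 2,
        )
        grad -= A.T @ w1
        hess -= A.T @ (w2[:, None] * A)
    return val, grad, hess


def map_estimate(
    bank: ItemBank,
    administered: list[str],
    responses: list[int],
    prior_mean: np.ndarray | None = None,
    prior_covariance: np.ndarray | None = None,
    use_expected_information: bool = False,
    x0: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> AbilityEstimate:
    """Maximum A Posteriori trait estimate with per-dimension SEM.

    Quasi-Newton (L-BFGS-B) minimization of the negative log posterior with
    analytic gradient — robust to the locally non-concave 4PL likelihood.
    SEM defaults to observed information (negative Hessian) + prior
    precision at the mode; set ``use_expected_information=True`` for the
    expected-information (Fisher) variant.  ``x0`` warm-starts the search
    (adaptive sessions pass the previous estimate).
    """
    if len(administered) != len(responses):
        raise ValueError("administered and responses must have equal length")
    D = bank.n_dimensions
    if prior_mean is None:
        prior_mean = np.zeros(D)
    prior_mean = np.asarray(prior_mean, dtype=float).ravel()
    if prior_covariance is None:
        prior_covariance = bank.trait_covariance
    prior_covariance = np.asarray(prior_covariance, dtype=float)
    prior_precision = np.linalg.inv(prior_covariance)
    items = [bank[iid] for iid in administered]
    resp = np.asarray(responses, dtype=int)
    if resp.size and not np.isin(resp, (0, 1)).all():
        raise ValueError("responses must be 0/1")
    if items:
        arrays = (
            np.vstack([it.loadings for it in items]),
            np.array([it.intercept for it in items]),
            np.array([it.lower_asymptote for it in items]),
            np.array([it.upper_asymptote for it in items]),
        )
    else:
        arrays = (np.empty((0, D)), np.empty(0), np.empty(0), np.empty(0))

    def objective(theta):
        val, grad, _ = _neg_log_posterior_parts(
            arrays, resp, theta, prior_mean, prior_precision
        )
        return val, grad

    start = prior_mean.copy() if x0 is None else np.asarray(x0, dtype=float).copy()
    res = minimize(
        objective,
        start,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": 1e-8, "ftol": tol},
    )
    theta = res.x
    _, grad, hess = _neg_log_posterior_parts(
        arrays, resp, theta, prior_mean, prior_precision
    )
    gnorm = float(np.linalg.norm(grad))
    if gnorm > 1e-4:
        # polish with a few damped Newton steps from the L-BFGS point
        for _ in range(50):
            try:
                step = np.linalg.solve(
                    hess + 1e-8 * np.eye(D), grad
                )
            except np.linalg.LinAlgError:
                step = grad
            theta = theta - np.clip(step, -1.0, 1.0)
            _, grad, hess = _neg_log_posterior_parts(
                arrays, resp, theta, prior_mean, prior_precision
            )
            gnorm = float(np.linalg.norm(grad))
            if gnorm < 1e-6:
                break
        if gnorm > 1e-3:
            raise EstimationError(
                f"MAP did not converge; gradient norm {gnorm:.3g}"
            )

    if use_expected_information or np.linalg.eigvalsh(hess).min() <= 0:
        # expected (Fisher) information; also the fallback when the observed
        # curvature is indefinite at the mode (possible under the 4PL)
        from .item_model import test_information

        curvature = test_information(bank, administered, theta, prior_precision)
    else:
        curvature = hess  # observed information + prior precision
    cov = np.linalg.inv(curvature)
    sem = np.sqrt(np.clip(np.diag(cov), 1e-12, None))
    return AbilityEstimate(theta=theta, sem=sem)
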