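"""Confirmatory MIRT calibration by marginal maximum likelihood.

Items are calibrated with an EM algorithm: the E-step integrates the
latent traits over a fixed quadrature (tensor Gauss-Hermite for up to
three dimensions, seeded quasi-Monte-Carlo beyond that), and the M-step
refits each item's free parameters against the expected response counts.
Three nested families are supported: M2PL (asymptotes fixed at 0/1),
M3PL (free guessing floor), M4PL (free floor and ceiling).  Asymptotes are
estimated on the logit scale with weakly informative quadratic penalties,
which stabilizes the notoriously ill-conditioned 3/4PL asymptotes at
modest sample sizes.

Goodness of fit uses the limited-information M2 statistic on first- and
second-order margins, with RMSEA (plus 90% CI), SRMSR on product-moment
residual correlations, and TLI/CFI against an independence null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from .item_model import ItemBank, ItemParameters

FAMILIES = ("M2PL", "M3PL", "M4PL")

# asymptote logit-scale penalty centers: chi ~ 0.047, gamma ~ 0.953
_CHI_CENTER = -3.0
_GAMMA_CENTER = 3.0
_LOGIT_BOUND = 6.0


class CalibrationError(RuntimeError):
    """All starts failed to converge, or the design is degenerate."""


@dataclass(frozen=True)
class ModelSpec:
    """Confirmatory model structure.

    ``loading_pattern`` is the J x D binary matrix of permitted loadings
    (primary dimension plus optional bifactor nuisance columns).  The free
    parameter count is pattern-driven: #nonzero loadings + J intercepts
    + family-dependent asymptotes + #free trait correlations.
    """

    model_family: str
    loading_pattern: np.ndarray
    n_dimensions: int
    correlated_traits: bool = False
    n_free_correlations: int | None = None

    def __post_init__(self) -> None:
        if self.model_family not in FAMILIES:
            raise ValueError(f"model_family must be one of {FAMILIES}")
        pat = np.asarray(self.loading_pattern, dtype=bool)
        object.__setattr__(self, "loading_pattern", pat)
        if pat.ndim != 2 or pat.shape[1] != self.n_dimensions:
            raise ValueError("loading_pattern must be J x n_dimensions")
        if not pat.any(axis=1).all():
            raise ValueError("every item needs at least one permitted loading")

    @property
    def n_items(self) -> int:
        return int(self.loading_pattern.shape[0])


def count_parameters(spec: ModelSpec, n_items: int | None = None) -> int:
    """Exact free-parameter count for a confirmatory model.

    M3PL adds one lower asymptote per item over M2PL; M4PL adds one upper
    asymptote per item over M3PL.
    """
    J = spec.n_items
    if n_items is not None and n_items != J:
        raise ValueError(
            f"n_items={n_items} inconsistent with loading pattern ({J} rows)"
        )
    count = int(spec.loading_pattern.sum()) + J
    if spec.model_family in ("M3PL", "M4PL"):
        count += J
    if spec.model_family == "M4PL":
        count += J
    if spec.correlated_traits:
        ncorr = spec.n_free_correlations
        if ncorr is None:
            ncorr = spec.n_dimensions * (spec.n_dimensions - 1) // 2
        count += ncorr
    return count


def m2_degrees_of_freedom(n_items: int, n_parameters: int) -> int:
    """df of the M2 statistic: J + J(J-1)/2 - q (first/second-order margins)."""
    J = n_items
    df = J + J * (J - 1) // 2 - n_parameters
    if df <= 0:
        raise ValueError(
            f"M2 undefined: {J} items give {J + J*(J-1)//2} margins "
            f"but the model has {n_parameters} parameters"
        )
    return df


# ---------------------------------------------------------------------------
# quadrature


def _gh_quadrature(D: int, n_points: int, cov: np.ndarray):
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_points)
    weights = weights / weights.sum()
    grids = np.meshgrid(*([nodes] * D), indexing="ij")
    theta = np.column_stack([g.ravel() for g in grids])
    wgrids = np.meshgrid(*([weights] * D), indexing="ij")
    w = np.ones(theta.shape[0])
    for g in wgrids:
        w *= g.ravel()
    L = np.linalg.cholesky(cov)
    return theta @ L.T, w


def _qmc_quadrature(D: int, n_points: int, cov: np.ndarray, seed: int):
    eng = stats.qmc.MultivariateNormalQMC(
        mean=np.zeros(D), cov=cov, seed=seed
    )
    theta = eng.random(n_points)
    w = np.full(n_points, 1.0 / n_points)
    return theta, w


def build_quadrature(
    D: int, cov: np.ndarray, n_points: int | None = None, seed: int = 0
):
    """Prior quadrature: tensor Gauss-Hermite for D<=3, seeded QMC above."""
    if D <= 3:
        per_dim = n_points or (21 if D == 1 else (15 if D == 2 else 9))
        return _gh_quadrature(D, per_dim, cov)
    return _qmc_quadrature(D, n_points or 2048, cov, seed)


# ---------------------------------------------------------------------------
# EM fitting


def _item_objective(x, theta_free, r, n, family, penalty):
    """Penalized expected complete-data negative loglik for one item."""
    k = theta_free.shape[1]
    a = x[:k]
    d = x[k]
    z = theta_free @ a + d
    pstar = expit(z)
    chi, gamma = 0.0, 1.0
    pos = k + 1
    pen = 0.0
    grad_pen = np.zeros_like(x)
    if family in ("M3PL", "M4PL"):
        c = x[pos]
        chi = expit(c)
        pen += 0.5 * penalty * (c - _CHI_CENTER) ** 2
        grad_pen[pos] = penalty * (c - _CHI_CENTER)
        pos += 1
    if family == "M4PL":
        g = x[pos]
        gamma = expit(g)
        pen += 0.5 * penalty * (g - _GAMMA_CENTER) ** 2
        grad_pen[pos] = penalty * (g - _GAMMA_CENTER)
    p = np.clip(chi + (gamma - chi) * pstar, 1e-10, 1 - 1e-10)
    val = -(r @ np.log(p) + (n - r) @ np.log(1.0 - p)) + pen

    w = r / p - (n - r) / (1.0 - p)  # d loglik / dP
    dp_dz = (gamma - chi) * pstar * (1.0 - pstar)
    grad = np.empty_like(x)
    grad[:k] = -(w * dp_dz) @ theta_free
    grad[k] = -np.sum(w * dp_dz)
    pos = k + 1
    if family in ("M3PL", "M4PL"):
        dchi = chi * (1.0 - chi)
        grad[pos] = -np.sum(w * (1.0 - pstar)) * dchi
        pos += 1
    if family == "M4PL":
        dgam = gamma * (1.0 - gamma)
        grad[pos] = -np.sum(w * pstar) * dgam
    return val, grad + grad_pen


def _response_matrix(responses) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if isinstance(responses, pd.DataFrame):
        item_ids = [str(c) for c in responses.columns]
        Y = responses.to_numpy(dtype=float)
    else:
        Y = np.asarray(responses, dtype=float)
        item_ids = [f"item{j + 1:03d}" for j in range(Y.shape[1])]
    mask = np.isfinite(Y)
    vals = Y[mask]
    if vals.size and not np.isin(vals, (0.0, 1.0)).all():
        raise ValueError("responses must be 0/1/missing")
    Y0 = np.where(mask, Y, 0.0)
    return Y0, mask.astype(float), item_ids


def screen_items(responses, min_responses: int = 10) -> list[str]:
    """Item ids with zero observed variance or too few responses.

    Such items carry no information about their parameters and are flagged
    for removal before calibration.
    """
    Y0, M, item_ids = _response_matrix(responses)
    n_obs = M.sum(axis=0)
    n_correct = Y0.sum(axis=0)
    bad = (n_obs < min_responses) | (n_correct == 0) | (n_correct == n_obs)
    return [iid for iid, b in zip(item_ids, bad) if b]


@dataclass
class CalibrationResult:
    bank: ItemBank
    loglik: float
    per_start_logliks: list[float]
    removed_items: list[str]
    spec: ModelSpec
    n_respondents: int
    converged: bool = True
    quadrature: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False
    )


def _marginal_loglik(P, Y0, M, w):
    logP = np.log(np.clip(P, 1e-300, None))
    log1mP = np.log(np.clip(1.0 - P, 1e-300, None))
    ll_iq = Y0 @ logP.T + (M - Y0) @ log1mP.T  # N x Q
    ll_iq += np.log(w)[None, :]
    m = ll_iq.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(ll_iq - m).sum(axis=1))
    f = np.exp(ll_iq - lse[:, None])
    return float(lse.sum()), f


def _probabilities(theta, A, d, chi, gamma):
    pstar = expit(theta @ A.T + d[None, :])
    return chi[None, :] + (gamma - chi)[None, :] * pstar


def fit_mirt(
    responses,
    spec: ModelSpec,
    n_starts: int = 1,
    seed: int = 0,
    trait_covariance: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-5,
    asymptote_penalty: float = 1.0,
    quadrature_points: int | None = None,
    min_responses: int = 10,
    item_meta: pd.DataFrame | None = None,
) -> CalibrationResult:
    """Calibrate an item bank by EM marginal maximum likelihood.

    The best of ``n_starts`` random starts (by marginal log-likelihood) is
    returned; the run is deterministic given ``seed``.  The trait
    covariance is held fixed at ``trait_covariance`` (identity by default)
    — the confirmatory correlation structure is an input here, not
    estimated.  Zero-variance items must be removed first (see
    :func:`screen_items`); their presence raises ``CalibrationError``.
    """
    Y0, M, item_ids = _response_matrix(responses)
    N, J = Y0.shape
    if J != spec.n_items:
        raise ValueError(
            f"responses have {J} items but loading_pattern has {spec.n_items} rows"
        )
    flagged = screen_items(responses, min_responses=min_responses)
    if flagged:
        raise CalibrationError(
            f"items with zero observed variance or <{min_responses} responses "
            f"must be removed before fitting: {flagged}"
        )
    D = spec.n_dimensions
    cov = np.eye(D) if trait_covariance is None else np.asarray(trait_covariance)
    theta_q, w_q = build_quadrature(D, cov, quadrature_points, seed=seed)
    pat = spec.loading_pattern
    family = spec.model_family
    n_extra = {"M2PL": 0, "M3PL": 1, "M4PL": 2}[family]

    rng = np.random.default_rng(seed)
    p_obs = np.clip(Y0.sum(axis=0) / np.maximum(M.sum(axis=0), 1.0), 0.05, 0.95)

    best = None
    per_start_logliks: list[float] = []
    diagnostics: list[str] = []
    for start in range(n_starts):
        A = pat * (1.0 + 0.5 * rng.standard_normal((J, D)) * (start > 0))
        A = np.abs(A) * pat
        dvec = logit(p_obs) + 0.25 * rng.standard_normal(J) * (start > 0)
        chi = np.full(J, expit(_CHI_CENTER) if n_extra >= 1 else 0.0)
        gamma = np.full(J, 1.0 - expit(-_GAMMA_CENTER) if n_extra == 2 else 1.0)
        if family == "M2PL":
            chi = np.zeros(J)
            gamma = np.ones(J)

        prev_ll = -np.inf
        converged = False
        for _ in range(max_iter):
            P = _probabilities(theta_q, A, dvec, chi, gamma)
            ll, f = _marginal_loglik(P, Y0, M, w_q)
            # expected counts per item and node
            r = f.T @ Y0  # Q x J
            n = f.T @ M
            for j in range(J):
                free = np.flatnonzero(pat[j])
                parts = [A[j, free], [dvec[j]]]
                if n_extra >= 1:
                    parts.append([logit(np.clip(chi[j], 1e-4, 1 - 1e-4))])
                if n_extra == 2:
                    parts.append([logit(np.clip(gamma[j], 1e-4, 1 - 1e-4))])
                x0 = np.concatenate(parts)
                k = free.size
                bounds = [(-8.0, 8.0)] * k + [(-8.0, 8.0)]
                bounds += [(-_LOGIT_BOUND, _LOGIT_BOUND)] * n_extra
                res = optimize.minimize(
                    _item_objective,
                    x0,
                    args=(theta_q[:, free], r[:, j], n[:, j], family,
                          asymptote_penalty),
                    jac=True,
                    method="L-BFGS-B",
                    bounds=bounds,
                    options={"maxiter": 50},
                )
                x = res.x
                A[j, free] = x[:k]
                dvec[j] = x[k]
                if n_extra >= 1:
                    chi[j] = expit(x[k + 1])
                if n_extra == 2:
                    gamma[j] = expit(x[k + 2])
            if abs(ll - prev_ll) < tol * max(1.0, abs(ll)) * 1e-2 or (
                abs(ll - prev_ll) < tol
            ):
                converged = True
                prev_ll = ll
                break
            prev_ll = ll
        P = _probabilities(theta_q, A, dvec, chi, gamma)
        ll, _ = _marginal_loglik(P, Y0, M, w_q)
        per_start_logliks.append(ll)
        if not converged:
            diagnostics.append(f"start {start}: no convergence (loglik {ll:.3f})")
        if best is None or ll > best[0]:
            best = (ll, A.copy(), dvec.copy(), chi.copy(), gamma.copy(), converged)

    if best is None or not any(np.isfinite(per_start_logliks)):
        raise CalibrationError(
            "all starts failed; diagnostics: " + "; ".join(diagnostics)
        )
    if not best[5] and all(
        "no convergence" in msg for msg in diagnostics
    ) and len(diagnostics) == n_starts:
        warnings.warn(
            "EM hit max_iter in every start; best loglik kept: "
            + "; ".join(diagnostics),
            RuntimeWarning,
        )

    ll, A, dvec, chi, gamma, converged = best
    items = []
    for j, iid in enumerate(item_ids):
        primary = int(np.flatnonzero(pat[j])[0])
        scale = ""
        if item_meta is not None and iid in set(item_meta.get("item_id", [])):
            row = item_meta.set_index("item_id").loc[iid]
            primary = int(row.get("primary_dimension", primary))
            scale = str(row.get("scale_label", ""))
        items.append(
            ItemParameters(
                item_id=iid,
                loadings=A[j] * pat[j],
                intercept=float(dvec[j]),
                lower_asymptote=float(chi[j]),
                upper_asymptote=float(gamma[j]),
                primary_dimension=primary,
                scale_label=scale,
            )
        )
    bank = ItemBank(
        items=items, n_dimensions=D, trait_covariance=cov, starting_items={}
    )
    return CalibrationResult(
        bank=bank,
        loglik=ll,
        per_start_logliks=per_start_logliks,
        removed_items=[],
        spec=spec,
        n_respondents=N,
        converged=converged,
        quadrature=(theta_q, w_q),
    )


# ---------------------------------------------------------------------------
# limited-information fit


@dataclass(frozen=True)
class FitIndices:
    m2: float
    df: int
    p: float
    rmsea: float
    rmsea_ci: tuple[float, float]
    srmsr: float
    tli: float
    cfi: float
    loglik: float

    def as_row(self) -> dict:
        return {
            "M2": self.m2,
            "df": self.df,
            "p": self.p,
            "RMSEA": self.rmsea,
            "RMSEA_5": self.rmsea_ci[0],
            "RMSEA_95": self.rmsea_ci[1],
            "SRMSR": self.srmsr,
            "TLI": self.tli,
            "CFI": self.cfi,
            "loglik": self.loglik,
        }


def _margin_sets(J: int) -> list[tuple[int, ...]]:
    sets: list[tuple[int, ...]] = [(j,) for j in range(J)]
    sets += [(j, k) for j in range(J) for k in range(j + 1, J)]
    return sets


def _model_margins(P: np.ndarray, w: np.ndarray) -> np.ndarray:
    """First- and second-order model-implied margins from node probabilities."""
    pi1 = w @ P
    pi2 = (P * w[:, None]).T @ P
    J = P.shape[1]
    iu = np.triu_indices(J, k=1)
    return np.concatenate([pi1, pi2[iu]])


def _sample_margins(Y: np.ndarray) -> np.ndarray:
    p1 = Y.mean(axis=0)
    p2 = (Y.T @ Y) / Y.shape[0]
    iu = np.triu_indices(Y.shape[1], k=1)
    return np.concatenate([p1, p2[iu]])


def _xi_matrix(P: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Asymptotic covariance of the sample margins under the model.

    Entry (a, b) is pi_{a∪b} - pi_a pi_b, where pi over an item set is the
    joint probability that all items in the set are answered correctly
    (union sets have at most four items).
    """
    J = P.shape[1]
    sets = _margin_sets(J)
    prods = {}
    for s in sets:
        col = P[:, s[0]].copy()
        for j in s[1:]:
            col = col * P[:, j]
        prods[s] = col
    pi = np.array([w @ prods[s] for s in sets])
    S = len(sets)
    xi = np.empty((S, S))
    wcol = w
    for a in range(S):
        pa = prods[sets[a]]
        set_a = set(sets[a])
        for b in range(a, S):
            extra = [j for j in sets[b] if j not in set_a]
            col = pa
            for j in extra:
                col = col * P[:, j]
            val = wcol @ col - pi[a] * pi[b]
            xi[a, b] = val
            xi[b, a] = val
    return xi


def _margins_at(params, shapes, theta_q, w_q, pat, family):
    A, dvec, chi, gamma = _params_from_vector(params, shapes, pat, family)
    P = _probabilities(theta_q, A, dvec, chi, gamma)
    return _model_margins(P, w_q)


def _params_to_vector(bank: ItemBank, pat, family):
    A = bank.loading_matrix()
    parts = [A[pat]]
    parts.append(bank.intercepts())
    if family in ("M3PL", "M4PL"):
        parts.append(logit(np.clip(bank.lower_asymptotes(), 1e-6, 1 - 1e-6)))
    if family == "M4PL":
        parts.append(logit(np.clip(bank.upper_asymptotes(), 1e-6, 1 - 1e-6)))
    shapes = pat.shape
    return np.concatenate(parts), shapes


def _params_from_vector(vec, shapes, pat, family):
    J, D = shapes
    nload = int(pat.sum())
    A = np.zeros((J, D))
    A[pat] = vec[:nload]
    pos = nload
    dvec = vec[pos : pos + J]
    pos += J
    chi = np.zeros(J)
    gamma = np.ones(J)
    if family in ("M3PL", "M4PL"):
        chi = expit(vec[pos : pos + J])
        pos += J
    if family == "M4PL":
        gamma = expit(vec[pos : pos + J])
    return A, dvec, chi, gamma


def _rmsea_ci(m2: float, df: int, N: int, level: float = 0.90):
    """Noncentrality-based RMSEA confidence interval."""

    def bound(prob):
        if stats.ncx2.cdf(m2, df, 0.0) < prob:
            return 0.0
        hi = max(m2 * 2, df * 2, 10.0)
        while stats.ncx2.cdf(m2, df, hi) > prob and hi < 1e8:
            hi *= 2
        lam = optimize.brentq(
            lambda nc: stats.ncx2.cdf(m2, df, nc) - prob, 0.0, hi
        )
        return np.sqrt(max(lam, 0.0) / (df * N))

    alpha = (1.0 - level) / 2.0
    return bound(1.0 - alpha), bound(alpha)


def fit_indices(
    result: CalibrationResult,
    responses,
    n_parameters: int | None = None,
) -> FitIndices:
    """M2, RMSEA (+90% CI), SRMSR, TLI, CFI for a calibrated model.

    Requires complete responses (the limited-information margins assume a
    common sample).  ``n_parameters`` defaults to the pattern-driven count
    of the fitted spec.
    """
    Y0, M, item_ids = _response_matrix(responses)
    if not np.all(M == 1.0):
        raise ValueError("fit indices require complete responses (no missing)")
    Y = Y0
    N, J = Y.shape
    q = n_parameters if n_parameters is not None else count_parameters(result.spec)
    df = m2_degrees_of_freedom(J, q)

    theta_q, w_q = result.quadrature
    bank = result.bank
    pat = result.spec.loading_pattern
    family = result.spec.model_family
    vec, shapes = _params_to_vector(bank, pat, family)

    P = _probabilities(
        theta_q,
        bank.loading_matrix(),
        bank.intercepts(),
        bank.lower_asymptotes(),
        bank.upper_asymptotes(),
    )
    pi = _model_margins(P, w_q)
    p = _sample_margins(Y)
    xi = _xi_matrix(P, w_q)

    # numerical Jacobian of the margins in the free parameters
    h = 1e-5
    S = pi.size
    delta = np.empty((S, vec.size))
    for t in range(vec.size):
        vp = vec.copy()
        vp[t] += h
        vm = vec.copy()
        vm[t] -= h
        delta[:, t] = (
            _margins_at(vp, shapes, theta_q, w_q, pat, family)
            - _margins_at(vm, shapes, theta_q, w_q, pat, family)
        ) / (2 * h)

    xi_j = xi + 1e-10 * np.eye(S)
    xi_inv = np.linalg.inv(xi_j)
    mid = delta.T @ xi_inv @ delta
    C2 = xi_inv - xi_inv @ delta @ np.linalg.solve(mid, delta.T @ xi_inv)
    resid = p - pi
    m2 = float(N * resid @ C2 @ resid)
    m2 = max(m2, 0.0)
    pval = float(stats.chi2.sf(m2, df))
    rmsea = float(np.sqrt(max((m2 - df) / (df * N), 0.0)))
    ci = _rmsea_ci(m2, df, N)

    # SRMSR on product-moment correlations
    iu = np.triu_indices(J, k=1)
    pi1 = pi[:J]
    pi2 = np.zeros((J, J))
    pi2[iu] = pi[J:]
    sd_model = np.sqrt(np.clip(pi1 * (1 - pi1), 1e-12, None))
    rho_model = (pi2[iu] - pi1[iu[0]] * pi1[iu[1]]) / (
        sd_model[iu[0]] * sd_model[iu[1]]
    )
    with np.errstate(invalid="ignore"):
        robs = np.corrcoef(Y, rowvar=False)[iu]
    srmsr = float(np.sqrt(np.nanmean((robs - rho_model) ** 2)))

    # independence null on the same margins
    m2_null, df_null = _null_m2(Y, theta_q, w_q)
    num = max(m2 - df, 0.0)
    den = max(m2_null - df_null, num, 1e-12)
    cfi = float(1.0 - num / den)
    denom_tli = m2_null / df_null - 1.0
    tli = float((m2_null / df_null - m2 / df) / denom_tli) if denom_tli > 0 else 1.0

    return FitIndices(
        m2=m2,
        df=df,
        p=pval,
        rmsea=rmsea,
        rmsea_ci=ci,
        srmsr=srmsr,
        tli=tli,
        cfi=cfi,
        loglik=result.loglik,
    )


def _null_m2(Y: np.ndarray, theta_q, w_q):
    """M2 of the independence model with free item margins."""
    N, J = Y.shape
    p1 = np.clip(Y.mean(axis=0), 1e-6, 1 - 1e-6)
    P = np.tile(p1, (theta_q.shape[0], 1))
    pi = _model_margins(P, w_q)
    p = _sample_margins(Y)
    xi = _xi_matrix(P, w_q)
    S = pi.size
    # analytic Jacobian: d pi1_j / d p1_j = 1; d pi2_jk / d p1_j = p1_k
    delta = np.zeros((S, J))
    delta[:J, :] = np.eye(J)
    iu = np.triu_indices(J, k=1)
    for row, (j, k) in enumerate(zip(*iu), start=J):
        delta[row, j] = p1[k]
        delta[row, k] = p1[j]
    xi_inv = np.linalg.inv(xi + 1e-10 * np.eye(S))
    mid = delta.T @ xi_inv @ delta
    C2 = xi_inv - xi_inv @ delta @ np.linalg.solve(mid, delta.T @ xi_inv)
    resid = p - pi
    m2 = max(float(N * resid @ C2 @ resid), 0.0)
    return m2, m2_degrees_of_freedom(J, J)


def compare_models(
    fits: list[tuple[ModelSpec, FitIndices]],
    criterion: str = "SRMSR",
    ascending: bool = True,
) -> pd.DataFrame:
    """Model-comparison table sorted by the configured criterion.

    Default ranks by SRMSR ascending (smaller residual first); ties keep
    input order.
    """
    if not fits:
        raise ValueError("no fits to compare")
    rows = []
    for spec, fi in fits:
        row = {"model": spec.model_family, "n_parameters": count_parameters(spec)}
        row.update(fi.as_row())
        rows.append(row)
    table = pd.DataFrame(rows)
    if criterion not in table.columns:
        raise ValueError(f"unknown criterion {criterion!r}")
    return table.sort_values(
        criterion, ascending=ascending, kind="stable"
    ).reset_index(drop=True)
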