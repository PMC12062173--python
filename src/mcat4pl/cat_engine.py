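"""Adaptive-session engine: starting items, information-based item
selection, and the staged SEM stopping rule.

A session administers one item at a time.  After each response the MAP
trait estimate and its per-dimension SEMs are recomputed, and the stop
rule is checked:

* stage 1 (items 1-49): stop when every reported dimension has
  SEM < 0.3873 (reliability 0.85);
* stage 2 (item 50 onward): threshold relaxes to SEM < 0.4472
  (reliability 0.80);
* from item 60 a stability criterion also applies: the sum over reported
  dimensions of the squared SEM range over the last 10 items must fall
  below 0.0005 (i.e. the SEMs have stopped moving by ~0.01 per dimension);
* exhausting the bank always stops the session.

Next-item selection maximizes an optimal-design criterion of
``M = prior precision + acquired information + candidate information``
evaluated at the current MAP: D (determinant), T (trace), A (negative
trace of the inverse), E (smallest eigenvalue), or W (weighted quadratic
form).  The *P variants (TP/AP/WP/EP/DP) average the same criterion over a
fixed sigma-point grid on the current trait posterior, which makes the
choice robust to estimation error early in the session.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .ability import AbilityEstimate, map_estimate
from .item_model import ItemBank

SELECTION_RULES = ("D", "T", "A", "W", "E", "DP", "TP", "AP", "WP", "EP")

#: Full-precision staged thresholds: sqrt(1-0.85) and sqrt(1-0.80).
STAGE1_SEM = 0.387298334620742
STAGE2_SEM = 0.447213595499958


class SessionError(RuntimeError):
    """Invalid session operation (duplicate item, administering after stop...)."""


@dataclass(frozen=True)
class StopRuleConfig:
    """Staged stopping rule.

    ``stage1_threshold`` applies through item ``stage2_start - 1``;
    ``stage2_threshold`` from item ``stage2_start``; from ``stability_start``
    the SEM-range stability criterion is also checked over the trailing
    ``stability_window`` items.
    """

    stage1_threshold: float = STAGE1_SEM
    stage2_threshold: float = STAGE2_SEM
    stage2_start: int = 50
    stability_start: int = 60
    stability_window: int = 10
    stability_threshold: float = 0.0005
    reported_dimensions: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.stage1_threshold >= self.stage2_threshold:
            raise ValueError("stage1_threshold must be < stage2_threshold")
        if self.stability_window < 2:
            raise ValueError("stability_window must be >= 2")


def single_threshold_stop(threshold: float) -> StopRuleConfig:
    """Pure one-stage rule: stop only when every reported dimension's SEM
    falls below ``threshold`` (the simulation studies compare these)."""
    return StopRuleConfig(
        stage1_threshold=threshold,
        stage2_threshold=threshold * (1.0 + 1e-12),
        stage2_start=2**31,
        stability_start=2**31,
    )


def reported_dims(bank: ItemBank, config: StopRuleConfig) -> np.ndarray:
    """Indices of the dimensions the stop rule watches.

    Defaults to every dimension whose label does not mark it as a nuisance
    (bifactor) dimension.
    """
    if config.reported_dimensions is not None:
        return np.asarray(config.reported_dimensions, dtype=int)
    keep = [
        k
        for k, lab in enumerate(bank.dimension_labels)
        if not lab.lower().startswith("nuisance")
    ]
    return np.asarray(keep, dtype=int)


def _age_bucket(age_group: str | int | float) -> str:
    """Normalize an age ('4;6', 5, '7;2', '6') to a bucket '4'/'5'/'6'."""
    if isinstance(age_group, str) and ";" in age_group:
        years = int(age_group.split(";")[0])
    else:
        try:
            years = int(float(age_group))
        except (TypeError, ValueError):
            raise SessionError(f"unparseable age group {age_group!r}") from None
    if years <= 4:
        return "4"
    if years == 5:
        return "5"
    return "6"


def select_starting_item(bank: ItemBank, age_group: str | int) -> str:
    """Designated first item for an age group (<=4, 5, >=6 buckets)."""
    bucket = _age_bucket(age_group)
    if bucket not in bank.starting_items:
        raise SessionError(
            f"bank defines no starting item for age group {bucket!r} "
            f"(available: {sorted(bank.starting_items)})"
        )
    return bank.starting_items[bucket]


@dataclass
class CatSession:
    """One examinee's adaptive session over an item bank."""

    bank: ItemBank
    age_group: str = "5"
    stop_config: StopRuleConfig = field(default_factory=StopRuleConfig)
    prior_mean: np.ndarray | None = None
    administered: list[str] = field(default_factory=list)
    responses: list[int] = field(default_factory=list)
    estimate_history: list[AbilityEstimate] = field(default_factory=list)
    stopped: bool = False
    stop_reason: str | None = None

    def __post_init__(self) -> None:
        if self.prior_mean is None:
            self.prior_mean = np.zeros(self.bank.n_dimensions)
        self.prior_mean = np.asarray(self.prior_mean, dtype=float)
        self._prior_precision = np.linalg.inv(self.bank.trait_covariance)

    @property
    def current_estimate(self) -> AbilityEstimate:
        if self.estimate_history:
            return self.estimate_history[-1]
        sem = np.sqrt(np.diag(self.bank.trait_covariance))
        return AbilityEstimate(theta=self.prior_mean.copy(), sem=sem)

    @property
    def remaining(self) -> list[str]:
        done = set(self.administered)
        return [iid for iid in self.bank.item_ids if iid not in done]


def _information_scalars(
    A: np.ndarray, d: np.ndarray, chi: np.ndarray, gamma: np.ndarray,
    theta: np.ndarray,
) -> np.ndarray:
    """Vectorized 4PL information scalar c_j (info matrix = c_j a_j a_j^T)."""
    z = A @ theta + d
    pstar = expit(z)
    p = chi + (gamma - chi) * pstar
    dp = (gamma - chi) * pstar * (1.0 - pstar)
    denom = p * (1.0 - p)
    out = np.zeros_like(z)
    ok = denom > 1e-300
    out[ok] = dp[ok] ** 2 / denom[ok]
    return out


def _sigma_points(theta: np.ndarray, cov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Equal-weight 2D+1 sigma-point grid on the trait posterior."""
    D = theta.size
    L = np.linalg.cholesky(cov)
    pts = [theta]
    for k in range(D):
        pts.append(theta + L[:, k])
        pts.append(theta - L[:, k])
    pts = np.array(pts)
    w = np.full(len(pts), 1.0 / len(pts))
    return pts, w


def _criterion_values(
    rule: str,
    base: np.ndarray,
    A: np.ndarray,
    c: np.ndarray,
    weight_vector: np.ndarray | None,
) -> np.ndarray:
    """Criterion value per candidate for M = base + c_j a_j a_j^T.

    Rank-1 update identities keep this O(candidates * D^2) for D/T/A/W;
    the E rule needs an eigendecomposition per candidate.
    """
    n = A.shape[0]
    if rule == "T":
        return np.trace(base) + c * np.einsum("jd,jd->j", A, A)
    if rule == "D":
        Binv = np.linalg.inv(base)
        sign, logdet = np.linalg.slogdet(base)
        quad = np.einsum("jd,de,je->j", A, Binv, A)
        return logdet + np.log1p(c * quad)  # monotone in det
    if rule == "A":
        Binv = np.linalg.inv(base)
        Binv2 = Binv @ Binv
        quad1 = np.einsum("jd,de,je->j", A, Binv, A)
        quad2 = np.einsum("jd,de,je->j", A, Binv2, A)
        return -(np.trace(Binv) - c * quad2 / (1.0 + c * quad1))
    if rule == "W":
        w = weight_vector
        return w @ base @ w + c * (A @ w) ** 2
    if rule == "E":
        vals = np.empty(n)
        for j in range(n):
            M = base + c[j] * np.outer(A[j], A[j])
            vals[j] = np.linalg.eigvalsh(M)[0]
        return vals
    raise ValueError(f"unknown selection rule {rule!r}")


def next_item(
    session: CatSession,
    rule: str = "AP",
    weight_vector: np.ndarray | None = None,
) -> str:
    """Choose the unadministered item maximizing the selection criterion.

    Deterministic: ties break toward the lowest bank index.
    """
    rule = rule.upper()
    if rule not in SELECTION_RULES:
        raise ValueError(f"unknown selection rule {rule!r}; use one of {SELECTION_RULES}")
    candidates = session.remaining
    if not candidates:
        raise SessionError("no unadministered items remain")
    bank = session.bank
    D = bank.n_dimensions
    est = session.current_estimate
    theta_hat = est.theta

    if weight_vector is None:
        rep = reported_dims(bank, session.stop_config)
        weight_vector = np.zeros(D)
        weight_vector[rep] = 1.0 / len(rep)
    else:
        weight_vector = np.asarray(weight_vector, dtype=float)

    cand_items = [bank[iid] for iid in candidates]
    A = np.vstack([it.loadings for it in cand_items])
    d = np.array([it.intercept for it in cand_items])
    chi = np.array([it.lower_asymptote for it in cand_items])
    gamma = np.array([it.upper_asymptote for it in cand_items])

    posterior = rule.endswith("P")
    base_rule = rule[:-1] if posterior else rule

    adm_items = [bank[iid] for iid in session.administered]
    if adm_items:
        A_adm = np.vstack([it.loadings for it in adm_items])
        d_adm = np.array([it.intercept for it in adm_items])
        chi_adm = np.array([it.lower_asymptote for it in adm_items])
        gam_adm = np.array([it.upper_asymptote for it in adm_items])

    def acquired(theta: np.ndarray) -> np.ndarray:
        if not adm_items:
            return session._prior_precision.copy()
        c_adm = _information_scalars(A_adm, d_adm, chi_adm, gam_adm, theta)
        return session._prior_precision + A_adm.T @ (c_adm[:, None] * A_adm)

    if not posterior:
        base = acquired(theta_hat)
        c = _information_scalars(A, d, chi, gamma, theta_hat)
        values = _criterion_values(base_rule, base, A, c, weight_vector)
    else:
        base0 = acquired(theta_hat)
        post_cov = np.linalg.inv(base0)
        pts, w = _sigma_points(theta_hat, post_cov)
        values = np.zeros(len(candidates))
        for theta_g, w_g in zip(pts, w):
            base_g = acquired(theta_g)
            c_g = _information_scalars(A, d, chi, gamma, theta_g)
            values += w_g * _criterion_values(
                base_rule, base_g, A, c_g, weight_vector
            )
    best = int(np.argmax(values))  # argmax takes the first maximum: lowest index
    return candidates[best]


def should_stop(
    session: CatSession, config: StopRuleConfig | None = None
) -> tuple[bool, str | None]:
    """Evaluate the staged stop rule on the current session state."""
    config = config or session.stop_config
    n = len(session.administered)
    if n == 0:
        return False, None
    rep = reported_dims(session.bank, config)
    sem = session.current_estimate.sem[rep]
    if n < config.stage2_start:
        if np.all(sem < config.stage1_threshold):
            return True, "stage1_sem"
    else:
        if np.all(sem < config.stage2_threshold):
            return True, "stage2_sem"
    if n >= config.stability_start:
        window = session.estimate_history[-config.stability_window:]
        sems = np.vstack([e.sem[rep] for e in window])
        ranges = sems.max(axis=0) - sems.min(axis=0)
        if float(np.sum(ranges**2)) < config.stability_threshold:
            return True, "stability"
    if not session.remaining:
        return True, "bank_exhausted"
    return False, None


def administer(session: CatSession, item_id: str, response: int) -> CatSession:
    """Record a response, refresh the MAP estimate, and re-check the stop rule."""
    if session.stopped:
        raise SessionError("session already stopped")
    if item_id in session.administered:
        raise SessionError(f"item {item_id!r} already administered")
    if response not in (0, 1):
        raise SessionError(f"response must be 0 or 1, got {response!r}")
    session.bank[item_id]  # raises BankError on unknown id
    session.administered.append(item_id)
    session.responses.append(int(response))
    est = map_estimate(
        session.bank,
        session.administered,
        session.responses,
        prior_mean=session.prior_mean,
        prior_covariance=session.bank.trait_covariance,
        x0=session.estimate_history[-1].theta if session.estimate_history else None,
    )
    session.estimate_history.append(est)
    stop, reason = should_stop(session)
    if stop:
        session.stopped = True
        session.stop_reason = reason
    return session


def run_session(
    session: CatSession,
    respond,
    rule: str = "AP",
    max_items: int | None = None,
) -> CatSession:
    """Drive a session to termination.

    ``respond(item_id) -> 0/1`` supplies answers (a scripted respondent in
    simulations).  The first item is the age-group starting item when the
    bank designates one, otherwise rule-selected.
    """
    limit = max_items if max_items is not None else len(session.bank)
    while not session.stopped and len(session.administered) < limit:
        if not session.administered and session.bank.starting_items:
            iid = select_starting_item(session.bank, session.age_group)
        else:
            iid = next_item(session, rule)
        administer(session, iid, respond(iid))
    if not session.stopped:
        session.stopped = True
        session.stop_reason = (
            "bank_exhausted" if not session.remaining else "max_items"
        )
    return session
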