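"""Monte-Carlo evaluation of the adaptive test.

Simulees are drawn from the trait prior, full response vectors are
generated from the 4PL model at each simulee's true traits, and adaptive
sessions are replayed against those vectors.  Summaries report the item
counts needed to reach the stop rule and the model-based reliabilities at
termination, in the statistic set used to compare selection rules and to
tune the staged stopping strategy.  An OLS helper quantifies how much each
candidate starting item reduces the summed squared SEM per age group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .ability import AbilityEstimate
from .cat_engine import CatSession, StopRuleConfig, reported_dims, run_session
from .item_model import ItemBank, prob_correct

ITEM_COUNT_PERCENTILES = (75, 80, 85, 90, 95)
RELIABILITY_PERCENTILES = (5, 25, 50, 75, 95)


def generate_simulees(
    n: int,
    prior_mean: np.ndarray,
    prior_covariance: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """n draws from the multivariate-normal trait prior (seeded)."""
    rng = np.random.default_rng(seed)
    mean = np.asarray(prior_mean, dtype=float)
    cov = np.asarray(prior_covariance, dtype=float)
    if n == 0:
        return np.empty((0, mean.size))
    return rng.multivariate_normal(mean, cov, size=n, method="cholesky")


def simulate_responses(
    bank: ItemBank, theta_true: np.ndarray, seed: int = 0
) -> np.ndarray:
    """Bernoulli response vector over the whole bank at fixed true traits."""
    rng = np.random.default_rng(seed)
    probs = np.array([prob_correct(it, theta_true) for it in bank.items])
    return (rng.random(probs.size) < probs).astype(int)


def nearest_rank_percentile(values: np.ndarray, q: float) -> float:
    """Nearest-rank percentile: the ceil(q/100 * n)-th order statistic."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        return float("nan")
    k = max(int(np.ceil(q / 100.0 * v.size)), 1)
    return float(v[k - 1])


@dataclass
class SimulationSummary:
    """Aggregate results of one Monte-Carlo CAT run."""

    item_counts: np.ndarray
    reliabilities: pd.DataFrame  # simulee x reported dimension, at termination
    stop_reasons: list[str]
    sum_squared_sem: np.ndarray  # per simulee, over reported dimensions
    bank_size: int
    sessions: list[CatSession] = field(default_factory=list, repr=False)

    def item_count_stats(self) -> pd.Series:
        n = self.item_counts
        stats = {
            "M": float(np.mean(n)),
            "SD": float(np.std(n, ddof=1)) if n.size > 1 else 0.0,
            "Min": float(np.min(n)),
            "Median": nearest_rank_percentile(n, 50),
        }
        for q in ITEM_COUNT_PERCENTILES:
            stats[f"{q}. Per."] = nearest_rank_percentile(n, q)
        stats["Max"] = float(np.max(n))
        stats["Full bank"] = float(np.mean(n == self.bank_size))
        return pd.Series(stats)

    def reliability_stats(self) -> pd.DataFrame:
        rows = {}
        rel = self.reliabilities
        rows["Mean"] = rel.mean()
        rows["SD"] = rel.std(ddof=1)
        rows["Min"] = rel.min()
        for q in RELIABILITY_PERCENTILES:
            rows[f"{q}. Per."] = rel.apply(
                lambda col: nearest_rank_percentile(col.to_numpy(), q)
            )
        rows["Max"] = rel.max()
        return pd.DataFrame(rows).T

    def summary_table(self) -> pd.DataFrame:
        """Single tidy table: item-count block + per-dimension reliability."""
        counts = self.item_count_stats().rename("Items")
        rel = self.reliability_stats()
        return pd.concat([counts.to_frame(), rel], axis=1)


def run_cat_simulation(
    bank: ItemBank,
    simulees: np.ndarray,
    rule: str = "AP",
    stop_config: StopRuleConfig | None = None,
    seed: int = 0,
    age_groups: list[str] | None = None,
    keep_sessions: bool = False,
) -> SimulationSummary:
    """Replay one adaptive session per simulee; deterministic given seed.

    Each simulee's full response vector is pre-drawn from an independent
    child stream of ``seed``, so results do not depend on administration
    order and identical inputs give byte-identical summaries.
    """
    stop_config = stop_config or StopRuleConfig()
    simulees = np.atleast_2d(np.asarray(simulees, dtype=float))
    n = simulees.shape[0]
    if age_groups is None:
        buckets = sorted(bank.starting_items) or ["5"]
        age_groups = [buckets[i % len(buckets)] for i in range(n)]
    child_seeds = np.random.SeedSequence(seed).generate_state(max(n, 1)) % (2**31)

    rep = reported_dims(bank, stop_config)
    labels = [bank.dimension_labels[k] for k in rep]
    counts = np.empty(n, dtype=int)
    rels = np.empty((n, rep.size))
    ssq = np.empty(n)
    reasons: list[str] = []
    sessions: list[CatSession] = []
    for i in range(n):
        responses = simulate_responses(bank, simulees[i], seed=int(child_seeds[i]))
        index = {iid: k for k, iid in enumerate(bank.item_ids)}
        session = CatSession(
            bank=bank, age_group=age_groups[i], stop_config=stop_config
        )
        run_session(session, lambda iid: int(responses[index[iid]]), rule=rule)
        counts[i] = len(session.administered)
        final: AbilityEstimate = session.estimate_history[-1]
        rels[i] = final.reliability[rep]
        ssq[i] = float(np.sum(final.sem[rep] ** 2))
        reasons.append(session.stop_reason or "")
        if keep_sessions:
            sessions.append(session)
    return SimulationSummary(
        item_counts=counts,
        reliabilities=pd.DataFrame(rels, columns=labels),
        stop_reasons=reasons,
        sum_squared_sem=ssq,
        bank_size=len(bank),
        sessions=sessions,
    )


def starting_item_regression(
    results: pd.DataFrame,
    reference_levels: dict[str, str],
    outcome: str = "sum_squared_sem",
    stop_rule_reference: str | None = None,
) -> pd.DataFrame:
    """OLS of the summed squared SEM on starting item and stop rule.

    ``results`` needs columns ``age_group``, ``start_item``, ``stop_rule``
    and the outcome.  Starting items are dummy-coded within age group
    against ``reference_levels[age_group]``; the stop rule enters as one
    indicator (reference = ``stop_rule_reference``, default the first level
    in sorted order, conventionally the stricter rule).  Returns a
    coefficient table (b, SE, t, p, standardized beta) with, per age group,
    the most beneficial (most negative) starting item first.

    Raises ``ValueError`` on a collinear design.
    """
    required = {"age_group", "start_item", "stop_rule", outcome}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"results table missing columns: {sorted(missing)}")
    y = results[outcome].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("outcome contains non-finite values")

    cols: dict[str, np.ndarray] = {}
    rule_levels = sorted(results["stop_rule"].unique())
    ref_rule = stop_rule_reference if stop_rule_reference is not None else rule_levels[0]
    for lev in rule_levels:
        if lev != ref_rule:
            cols[str(lev)] = (results["stop_rule"] == lev).to_numpy(float)
    group_of: dict[str, str] = {}
    for grp in sorted(results["age_group"].unique()):
        ref = reference_levels.get(str(grp))
        if ref is None:
            raise ValueError(f"no reference starting item for age group {grp!r}")
        mask = results["age_group"] == grp
        for item in sorted(results.loc[mask, "start_item"].unique()):
            if item == ref:
                continue
            cols[str(item)] = ((results["start_item"] == item) & mask).to_numpy(float)
            group_of[str(item)] = str(grp)
    X = pd.DataFrame(cols, index=results.index)
    X = sm.add_constant(X, prepend=True)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("collinear design: redundant starting-item/stop-rule levels")
    fit = sm.OLS(y, X).fit()

    sd_y = np.std(y, ddof=1)
    rows = []
    for name in X.columns:
        b = fit.params[name]
        beta = (
            b * np.std(X[name].to_numpy(), ddof=1) / sd_y if name != "const" else np.nan
        )
        rows.append(
            {
                "age_group": group_of.get(name, ""),
                "term": "(Intercept)" if name == "const" else name,
                "b": b,
                "SE": fit.bse[name],
                "t": fit.tvalues[name],
                "p": fit.pvalues[name],
                "beta": beta,
            }
        )
    table = pd.DataFrame(rows)
    head = table[table["term"].isin(["(Intercept)"] + [str(r) for r in rule_levels])]
    items = table.drop(head.index).sort_values(
        ["age_group", "b"], kind="stable"
    )
    return pd.concat([head, items], ignore_index=True)
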