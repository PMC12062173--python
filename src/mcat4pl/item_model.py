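"""Core multidimensional 4PL item response model.

The four-parameter logistic (4PL) model gives the probability of a correct
response to item *j* for a child with latent trait vector ``theta``::

    P_j(theta) = chi_j + (gamma_j - chi_j) * sigmoid(a_j . theta + d_j)

where ``a_j`` is the vector of discrimination slopes over the D latent
dimensions, ``d_j`` the intercept (easiness), ``chi_j`` the lower asymptote
(guessing floor) and ``gamma_j`` the upper asymptote (disengagement /
slipping ceiling).  With ``chi=0, gamma=1`` the model reduces to the
multidimensional 2PL.

Reckase's multidimensional summaries are derived views of the
slope-intercept parameterization: MDISC = ||a|| and MDIFF = -d / ||a||.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit


class BankError(ValueError):
    """Invalid item-bank structure or lookup."""


@dataclass(frozen=True)
class ItemParameters:
    """Parameters of one dichotomous 4PL item.

    Attributes
    ----------
    item_id : str
        Unique identifier within a bank.
    loadings : np.ndarray
        Length-D slope vector ``a``; under a confirmatory structure only the
        primary dimension (plus an optional nuisance dimension) is nonzero.
    intercept : float
        Easiness intercept ``d`` in the slope-intercept metric.
    lower_asymptote : float
        Guessing floor ``chi`` in [0, 1).
    upper_asymptote : float
        Slipping ceiling ``gamma`` in (0, 1].
    primary_dimension : int
        Index of the content dimension the item measures.
    scale_label : str
        Human-readable scale name (one of the six early-literacy scales, or
        a nuisance-dimension label).
    """

    item_id: str
    loadings: np.ndarray
    intercept: float
    lower_asymptote: float = 0.0
    upper_asymptote: float = 1.0
    primary_dimension: int = 0
    scale_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "loadings", np.asarray(self.loadings, dtype=float).ravel()
        )
        if not 0.0 <= self.lower_asymptote < self.upper_asymptote <= 1.0:
            raise BankError(
                f"item {self.item_id!r}: asymptotes must satisfy "
                f"0 <= chi < gamma <= 1, got chi={self.lower_asymptote}, "
                f"gamma={self.upper_asymptote}"
            )
        if not (0 <= self.primary_dimension < self.loadings.size):
            raise BankError(
                f"item {self.item_id!r}: primary_dimension "
                f"{self.primary_dimension} out of range for "
                f"{self.loadings.size} loadings"
            )

    @property
    def n_dimensions(self) -> int:
        return int(self.loadings.size)


@dataclass
class ItemBank:
    """Ordered collection of items sharing a D-dimensional latent space.

    ``trait_covariance`` is the prior covariance (usually a correlation
    matrix) of the latent traits; nuisance bifactor dimensions are
    conventionally uncorrelated with the content dimensions.
    ``starting_items`` maps an age-group label ("4", "5", "6") to the
    item_id administered first in an adaptive session.
    """

    items: list[ItemParameters]
    n_dimensions: int
    dimension_labels: list[str] = field(default_factory=list)
    trait_covariance: np.ndarray | None = None
    starting_items: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise BankError(f"duplicate item_ids in bank: {dupes}")
        for it in self.items:
            if it.n_dimensions != self.n_dimensions:
                raise BankError(
                    f"item {it.item_id!r} has {it.n_dimensions} loadings; "
                    f"bank dimension is {self.n_dimensions}"
                )
        if not self.dimension_labels:
            self.dimension_labels = [f"dim{k}" for k in range(self.n_dimensions)]
        if len(self.dimension_labels) != self.n_dimensions:
            raise BankError("dimension_labels length must equal n_dimensions")
        if self.trait_covariance is None:
            self.trait_covariance = np.eye(self.n_dimensions)
        self.trait_covariance = np.asarray(self.trait_covariance, dtype=float)
        cov = self.trait_covariance
        if cov.shape != (self.n_dimensions, self.n_dimensions):
            raise BankError("trait_covariance shape mismatch")
        if not np.allclose(cov, cov.T):
            raise BankError("trait_covariance must be symmetric")
        if np.linalg.eigvalsh(cov).min() <= 0:
            raise BankError("trait_covariance must be positive-definite")
        for grp, iid in self.starting_items.items():
            if iid not in self._index():
                raise BankError(
                    f"starting item {iid!r} for age group {grp!r} not in bank"
                )

    def _index(self) -> dict[str, int]:
        return {it.item_id: k for k, it in enumerate(self.items)}

    def __len__(self) -> int:
        return len(self.items)

    def __getitem__(self, item_id: str) -> ItemParameters:
        try:
            return self.items[self._index()[item_id]]
        except KeyError:
            raise BankError(f"unknown item_id {item_id!r}") from None

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def loading_matrix(self) -> np.ndarray:
        """J x D matrix of slopes (row order = bank order)."""
        return np.vstack([it.loadings for it in self.items])

    def intercepts(self) -> np.ndarray:
        return np.array([it.intercept for it in self.items])

    def lower_asymptotes(self) -> np.ndarray:
        return np.array([it.lower_asymptote for it in self.items])

    def upper_asymptotes(self) -> np.ndarray:
        return np.array([it.upper_asymptote for it in self.items])


def _check_theta(item: ItemParameters, theta: np.ndarray) -> np.ndarray:
    theta = np.asarray(theta, dtype=float).ravel()
    if theta.size != item.loadings.size:
        raise BankError(
            f"theta has {theta.size} dimensions, item {item.item_id!r} "
            f"expects {item.loadings.size}"
        )
    if not np.all(np.isfinite(theta)):
        raise BankError("theta must be finite")
    return theta


def prob_correct(item: ItemParameters, theta: np.ndarray) -> float:
    """4PL probability of a correct response.

    Strictly inside (chi, gamma); equals (chi+gamma)/2 where a.theta+d = 0.
    """
    theta = _check_theta(item, theta)
    z = float(item.loadings @ theta + item.intercept)
    chi, gamma = item.lower_asymptote, item.upper_asymptote
    return chi + (gamma - chi) * float(expit(z))


def item_information(item: ItemParameters, theta: np.ndarray) -> np.ndarray:
    """Fisher information matrix of one 4PL item at ``theta``.

    Rank-1: ``[(gamma-chi) p*(1-p*)]^2 / [P(1-P)] * a a^T`` with ``p*`` the
    inner logistic and ``P`` the 4PL probability.  Returns the zero matrix
    when P degenerates to 0 or 1 (information vanishes at the asymptotes).
    """
    theta = _check_theta(item, theta)
    a = item.loadings
    z = float(a @ theta + item.intercept)
    pstar = float(expit(z))
    chi, gamma = item.lower_asymptote, item.upper_asymptote
    p = chi + (gamma - chi) * pstar
    if p <= 0.0 or p >= 1.0:
        return np.zeros((a.size, a.size))
    dp = (gamma - chi) * pstar * (1.0 - pstar)
    scale = dp * dp / (p * (1.0 - p))
    return scale * np.outer(a, a)


def information_scalar(item: ItemParameters, theta: np.ndarray) -> float:
    """Scalar factor c such that the information matrix is c * a a^T."""
    theta = _check_theta(item, theta)
    z = float(item.loadings @ theta + item.intercept)
    pstar = float(expit(z))
    chi, gamma = item.lower_asymptote, item.upper_asymptote
    p = chi + (gamma - chi) * pstar
    if p <= 0.0 or p >= 1.0:
        return 0.0
    dp = (gamma - chi) * pstar * (1.0 - pstar)
    return dp * dp / (p * (1.0 - p))


def test_information(
    bank: ItemBank,
    administered: set[str] | list[str],
    theta: np.ndarray,
    prior_precision: np.ndarray | None = None,
) -> np.ndarray:
    """Accumulated information: prior precision + sum over administered items."""
    theta = np.asarray(theta, dtype=float).ravel()
    if prior_precision is None:
        prior_precision = np.zeros((bank.n_dimensions, bank.n_dimensions))
    total = np.array(prior_precision, dtype=float)
    for iid in set(administered):
        total += item_information(bank[iid], theta)
    return total


def mdisc(item: ItemParameters) -> float:
    """Reckase multidimensional discrimination: Euclidean norm of the slopes."""
    return float(np.linalg.norm(item.loadings))


def mdiff(item: ItemParameters, flip_sign: bool = False) -> float:
    """Reckase multidimensional difficulty ``-d / ||a||``.

    ``flip_sign=True`` applies the display convention in which difficulty
    increases left-to-right on a plot (multiplies by -1).
    """
    m = mdisc(item)
    if m == 0.0:
        raise BankError(
            f"item {item.item_id!r}: MDIFF undefined for zero discrimination"
        )
    val = -item.intercept / m
    return -val if flip_sign else val
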