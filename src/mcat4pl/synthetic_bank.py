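"""Synthetic item banks with the geometry of a calibrated early-literacy pool.

No real item parameters or child responses are available, so every numeric
study in this package runs on generated banks that reproduce the published
geometry of the calibrated pool: 177 items over six correlated content
scales, multidimensional difficulty (MDIFF) spread across -2..+2, mostly
high multidimensional discrimination (MDISC > 1.5) with a minority in
0.5-1.5, guessing floors up to 0.3, slipping ceilings down to 0.85, and an
optional bifactor block whose items also load on orthogonal nuisance
dimensions (numerical / iconic writing awareness).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .item_model import ItemBank, ItemParameters

SCALE_NAMES = (
    "concepts_of_print",
    "print_awareness",
    "word_awareness",
    "phonological_awareness",
    "alphabet_knowledge",
    "early_reading",
)

#: Per-scale item counts echoing the published scale sizes, summing to 177.
DEFAULT_SCALE_SIZES = (38, 19, 12, 29, 45, 34)

NUISANCE_NAMES = ("nuisance_numerical", "nuisance_iconic")


@dataclass(frozen=True)
class BankSpec:
    """Recipe for a synthetic bank.

    MDIFF is uniform on ``difficulty_range``; MDISC is lognormal
    (``log_mdisc_mean``, ``log_mdisc_sd``) truncated to ``mdisc_range`` so
    that most items discriminate strongly (the exact published shapes are
    unknown; only the verbal geometry is).  ``bifactor_scale`` names the
    scale whose items carry secondary loadings on the nuisance dimensions.
    """

    scale_sizes: tuple[int, ...] = DEFAULT_SCALE_SIZES
    difficulty_range: tuple[float, float] = (-2.0, 2.0)
    log_mdisc_mean: float = 1.1
    log_mdisc_sd: float = 0.6
    mdisc_range: tuple[float, float] = (0.5, 16.0)
    lower_asymptote_range: tuple[float, float] = (0.0, 0.3)
    upper_asymptote_range: tuple[float, float] = (0.85, 1.0)
    trait_correlation: float = 0.5
    n_nuisance: int = 2
    bifactor_scale: int = 0
    bifactor_angle_range: tuple[float, float] = (0.15, 0.35)  # radians
    # "excellent" subset: extremely discriminating items near average
    # ability, spread over the scales — the published pool reports ~15
    # such items and its shortest tests are impossible without them
    n_excellent: int = 15
    excellent_mdisc_range: tuple[float, float] = (15.0, 20.0)
    excellent_mdiff_range: tuple[float, float] = (-1.0, 1.0)

    def __post_init__(self) -> None:
        if len(self.scale_sizes) != len(SCALE_NAMES):
            raise ValueError(f"scale_sizes must have {len(SCALE_NAMES)} entries")
        if any(n <= 0 for n in self.scale_sizes):
            raise ValueError("every scale needs at least one item")
        if not -1.0 / (len(SCALE_NAMES) - 1) < self.trait_correlation < 1.0:
            raise ValueError("trait_correlation outside the positive-definite range")
        if self.n_nuisance not in (0, 1, 2):
            raise ValueError("n_nuisance must be 0, 1 or 2")

    @property
    def n_items(self) -> int:
        return int(sum(self.scale_sizes))

    @property
    def n_dimensions(self) -> int:
        return len(self.scale_sizes) + self.n_nuisance


def _trait_covariance(spec: BankSpec) -> np.ndarray:
    D = spec.n_dimensions
    S = len(spec.scale_sizes)
    cov = np.eye(D)
    cov[:S, :S] = spec.trait_correlation
    np.fill_diagonal(cov, 1.0)
    return cov


def _truncated_lognormal(
    rng: np.random.Generator, n: int, mu: float, sigma: float,
    lo: float, hi: float,
) -> np.ndarray:
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(mu, sigma, size=2 * (n - filled))
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(draw.size, n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def generate_bank(spec: BankSpec | None = None, seed: int = 0) -> ItemBank:
    """Draw a bank matching ``spec``; deterministic given ``seed``.

    Three easy, well-discriminating starting items are designated, one per
    age bucket, graded in difficulty (youngest gets the easiest).
    """
    spec = spec or BankSpec()
    rng = np.random.default_rng(seed)
    D = spec.n_dimensions
    S = len(spec.scale_sizes)

    items: list[ItemParameters] = []
    j = 0
    for s, (name, n_s) in enumerate(zip(SCALE_NAMES, spec.scale_sizes)):
        # stratified difficulty: jittered grid guarantees full-range coverage
        lo, hi = spec.difficulty_range
        grid = np.linspace(lo, hi, n_s)
        jitter = (hi - lo) / max(n_s - 1, 1) * 0.4
        mdiffs = np.clip(grid + rng.uniform(-jitter, jitter, n_s), lo, hi)
        mdiscs = _truncated_lognormal(
            rng, n_s, spec.log_mdisc_mean, spec.log_mdisc_sd, *spec.mdisc_range
        )
        n_exc = spec.n_excellent // S + (1 if s < spec.n_excellent % S else 0)
        if n_exc > 0:
            exc = np.argsort(np.abs(mdiffs))[:n_exc]
            mdiffs[exc] = rng.uniform(*spec.excellent_mdiff_range, n_exc)
            mdiscs[exc] = rng.uniform(*spec.excellent_mdisc_range, n_exc)
        chis = rng.uniform(*spec.lower_asymptote_range, n_s)
        gammas = rng.uniform(*spec.upper_asymptote_range, n_s)
        bifactor = spec.n_nuisance > 0 and s == spec.bifactor_scale
        for i in range(n_s):
            loadings = np.zeros(D)
            if bifactor:
                # split the MDISC norm between content and nuisance loading
                phi = rng.uniform(*spec.bifactor_angle_range)
                nuis = S + (i % spec.n_nuisance)
                loadings[s] = mdiscs[i] * np.cos(phi)
                loadings[nuis] = mdiscs[i] * np.sin(phi)
            else:
                loadings[s] = mdiscs[i]
            j += 1
            items.append(
                ItemParameters(
                    item_id=f"{name[:2].upper()}{s + 1}_{i + 1:03d}",
                    loadings=loadings,
                    intercept=-mdiffs[i] * mdiscs[i],
                    lower_asymptote=float(chis[i]),
                    upper_asymptote=float(gammas[i]),
                    primary_dimension=s,
                    scale_label=name,
                )
            )

    labels = list(SCALE_NAMES) + list(NUISANCE_NAMES[: spec.n_nuisance])
    bank = ItemBank(
        items=items,
        n_dimensions=D,
        dimension_labels=labels,
        trait_covariance=_trait_covariance(spec),
        starting_items={},
    )
    bank.starting_items = _pick_starting_items(bank)
    return bank


def _pick_starting_items(bank: ItemBank) -> dict[str, str]:
    """One easy, discriminating starter per age bucket (graded difficulty)."""
    from .item_model import mdiff, mdisc

    targets = {"4": -1.5, "5": -1.0, "6": -0.5}
    chosen: dict[str, str] = {}
    used: set[str] = set()
    for grp, target in targets.items():
        best, best_score = None, np.inf
        for it in bank.items:
            if it.item_id in used or mdisc(it) < 1.5:
                continue
            score = abs(mdiff(it) - target)
            if score < best_score:
                best, best_score = it.item_id, score
        if best is None:  # sparse custom banks: fall back to any unused item
            best = next(i for i in bank.item_ids if i not in used)
        chosen[grp] = best
        used.add(best)
    return chosen


def bank_digest(bank: ItemBank, thetas: np.ndarray | None = None) -> str:
    """Stable content hash of a bank (and optional simulee matrix)."""
    h = hashlib.sha256()
    for it in bank.items:
        h.update(it.item_id.encode())
        h.update(np.round(it.loadings, 10).tobytes())
        h.update(
            np.round(
                [it.intercept, it.lower_asymptote, it.upper_asymptote], 10
            ).tobytes()
        )
    h.update(np.round(bank.trait_covariance, 10).tobytes())
    h.update(repr(sorted(bank.starting_items.items())).encode())
    if thetas is not None:
        h.update(np.round(np.asarray(thetas, dtype=float), 10).tobytes())
    return h.hexdigest()


def make_reference_fixture(
    seed: int = 1, n_simulees: int = 200
) -> tuple[ItemBank, np.ndarray, str]:
    """Canonical test fixture: default bank + simulee traits + digest.

    The bank uses ``seed``; the simulee population (drawn from the bank's
    trait prior) uses ``seed + 1``.
    """
    from .simulation import generate_simulees

    bank = generate_bank(BankSpec(), seed=seed)
    thetas = generate_simulees(
        n_simulees,
        prior_mean=np.zeros(bank.n_dimensions),
        prior_covariance=bank.trait_covariance,
        seed=seed + 1,
    )
    return bank, thetas, bank_digest(bank, thetas)
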