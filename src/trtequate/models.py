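"""Item response functions for the four model families.

Two dichotomous models — the two-parameter logistic model (2PLM) and its
testlet extension (2PTM) — and two polytomous models — the graded response
model (GRM) and the graded response testlet model (GRTM).  The testlet
variants add a person-by-testlet random effect ``gamma`` inside the logit
with the same slope as the latent trait:

    2PLM:  P(y=1) = logistic(a * (theta - b))
    2PTM:  P(y=1) = logistic(a * (theta - b - gamma))
    GRM :  P*(x)  = logistic(a * (theta - b_x)),   x = 1..K-1
    GRTM:  P*(x)  = logistic(a * (theta - b_x - gamma))

where ``gamma ~ N(0, sigma2)`` per testlet and setting every gamma to zero
collapses each testlet model onto its classical counterpart.  Probabilities
are returned un-clamped; clamping to [1e-12, 1 - 1e-12] happens only inside
log-likelihoods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

#: Sentinel code for a structurally missing response (item not administered).
MISSING: int = -1

#: Families with a testlet random effect.
TESTLET_FAMILIES = frozenset({"2PTM", "GRTM"})
ALL_FAMILIES = frozenset({"2PLM", "2PTM", "GRM", "GRTM"})

_LOG_CLAMP = 1e-12


@dataclass(frozen=True)
class DichotomousItemParams:
    """True or estimated parameters of one dichotomous item."""

    item_id: str
    a: float
    b: float
    testlet_id: str | None = None

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"item {self.item_id}: discrimination must be > 0, got {self.a}")
        if not np.isfinite(self.b):
            raise ValueError(f"item {self.item_id}: difficulty must be finite")

    @property
    def n_categories(self) -> int:
        return 2


@dataclass(frozen=True)
class PolytomousItemParams:
    """Parameters of one graded (ordered polytomous) item.

    ``boundaries`` holds the K-1 ordered category boundaries b_1 < ... < b_{K-1}
    for an item scored 0..K-1.
    """

    item_id: str
    a: float
    boundaries: tuple[float, ...]
    testlet_id: str | None = None

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"item {self.item_id}: discrimination must be > 0, got {self.a}")
        bs = np.asarray(self.boundaries, dtype=float)
        if bs.size < 1:
            raise ValueError(f"item {self.item_id}: need at least one boundary (K >= 2)")
        if not np.all(np.isfinite(bs)):
            raise ValueError(f"item {self.item_id}: boundaries must be finite")
        if not np.all(np.diff(bs) > 0):
            raise ValueError(f"item {self.item_id}: boundaries must be strictly increasing, got {self.boundaries}")
        object.__setattr__(self, "boundaries", tuple(float(x) for x in bs))

    @property
    def n_categories(self) -> int:
        return len(self.boundaries) + 1


ItemParams = DichotomousItemParams | PolytomousItemParams


@dataclass(frozen=True)
class PersonState:
    """One examinee's latent state: trait level and per-testlet random effects."""

    theta: float
    gamma: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class TestletSpec:
    """A testlet: its member items and the variance of its random effect."""

    testlet_id: str
    item_ids: tuple[str, ...]
    sigma2: float

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValueError(f"testlet {self.testlet_id}: sigma2 must be >= 0")
        if len(self.item_ids) == 0:
            raise ValueError(f"testlet {self.testlet_id}: empty item list")
        object.__setattr__(self, "item_ids", tuple(self.item_ids))


def _effective_trait(item: ItemParams, person: PersonState, use_testlet: bool) -> float:
    """theta minus the testlet effect, if one applies."""
    if use_testlet and item.testlet_id is not None:
        if item.testlet_id not in person.gamma:
            raise KeyError(
                f"person has no random effect for testlet {item.testlet_id!r} "
                f"required by item {item.item_id!r}"
            )
        return person.theta - person.gamma[item.testlet_id]
    return person.theta


def prob_dichotomous(
    item: DichotomousItemParams, person: PersonState, use_testlet: bool = False
) -> float:
    """P(correct) under the 2PLM, or the 2PTM when ``use_testlet`` is set."""
    t = _effective_trait(item, person, use_testlet)
    return float(expit(item.a * (t - item.b)))


def grm_boundary_probs(
    item: PolytomousItemParams, person: PersonState, use_testlet: bool = False
) -> np.ndarray:
    """Cumulative probabilities P*_0..P*_K of responding in category x or higher.

    P*_0 = 1 and P*_K = 0 by convention; the sequence is non-increasing.
    """
    t = _effective_trait(item, person, use_testlet)
    bs = np.asarray(item.boundaries)
    inner = expit(item.a * (t - bs))
    return np.concatenate(([1.0], inner, [0.0]))


def grm_category_probs(
    item: PolytomousItemParams, person: PersonState, use_testlet: bool = False
) -> np.ndarray:
    """Probability of each response category 0..K-1 (adjacent boundary differences)."""
    star = grm_boundary_probs(item, person, use_testlet)
    return star[:-1] - star[1:]


def category_probs(item: ItemParams, person: PersonState, use_testlet: bool = False) -> np.ndarray:
    """Category probabilities for either item type, length ``item.n_categories``."""
    if isinstance(item, DichotomousItemParams):
        p = prob_dichotomous(item, person, use_testlet)
        return np.array([1.0 - p, p])
    return grm_category_probs(item, person, use_testlet)


def response_loglik(
    responses: Sequence[int],
    items: Sequence[ItemParams],
    person: PersonState,
    model: str,
) -> float:
    """Log-likelihood of a response vector for one person.

    Missing responses (code ``MISSING``) contribute zero.  ``model`` selects
    whether the testlet effect enters (2PTM/GRTM) or not (2PLM/GRM).
    """
    if model not in ALL_FAMILIES:
        raise ValueError(f"unknown model family {model!r}")
    use_testlet = model in TESTLET_FAMILIES
    if len(responses) != len(items):
        raise ValueError("responses and items must align")
    total = 0.0
    for y, item in zip(responses, items):
        y = int(y)
        if y == MISSING:
            continue
        if not 0 <= y < item.n_categories:
            raise ValueError(
                f"response {y} out of range 0..{item.n_categories - 1} for item {item.item_id!r}"
            )
        p = category_probs(item, person, use_testlet)[y]
        total += float(np.log(np.clip(p, _LOG_CLAMP, None)))
    return total


# ---------------------------------------------------------------------------
# Array kernels shared by the data generator and the calibration engine.
# ---------------------------------------------------------------------------

def dich_prob_array(a: float, b: float, trait: np.ndarray) -> np.ndarray:
    """Vectorised 2PL response probability over an array of effective traits."""
    return expit(a * (np.asarray(trait, dtype=float) - b))


def grm_cumulative_array(a: float, boundaries: np.ndarray, trait: np.ndarray) -> np.ndarray:
    """Vectorised GRM interior cumulative probabilities, shape (K-1,) + trait.shape."""
    trait = np.asarray(trait, dtype=float)
    bs = np.asarray(boundaries, dtype=float).reshape((-1,) + (1,) * trait.ndim)
    return expit(a * (trait[None, ...] - bs))


def grm_category_array(a: float, boundaries: np.ndarray, trait: np.ndarray) -> np.ndarray:
    """Vectorised GRM category probabilities, shape (K,) + trait.shape."""
    star = grm_cumulative_array(a, boundaries, trait)
    trait = np.asarray(trait, dtype=float)
    ones = np.ones((1,) + trait.shape)
    zeros = np.zeros((1,) + trait.shape)
    full = np.concatenate([ones, star, zeros], axis=0)
    return full[:-1] - full[1:]
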