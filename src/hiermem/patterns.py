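"""Hierarchically correlated binary pattern sets.

A memory task consists of ``K * M`` input/target associations organised in
``K`` categories of ``M`` members.  For each category a "typical" input and a
typical target pattern are drawn uniformly from {-1, +1}^N; every member is a
noisy copy of its typical pattern in which each element is sign-flipped
independently with probability ``p_flip``.  Two members of the same category
therefore have expected correlation ``C = (1 - 2 p_flip)^2``, while any pair
of patterns from different categories -- and every input/target pair -- is
uncorrelated in expectation.  The correlation is enforced only in ensemble
expectation, never per realisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PatternSpec",
    "PatternSet",
    "CorrelationSummary",
    "expected_correlation",
    "generate_pattern_set",
    "empirical_correlations",
]


def expected_correlation(p_flip: float) -> float:
    """Expected within-category correlation ``C = (1 - 2 p_flip)^2``.

    Parameters
    ----------
    p_flip : float
        Per-element sign-flip probability in [0, 0.5].

    Returns
    -------
    float
        Expected correlation between two members of the same category.
    """
    if not 0.0 <= p_flip <= 0.5:
        raise ValueError(f"p_flip must lie in [0, 0.5], got {p_flip}")
    return (1.0 - 2.0 * p_flip) ** 2


@dataclass(frozen=True)
class PatternSpec:
    """Parameters of a hierarchical pattern ensemble.

    Attributes
    ----------
    n : int
        Pattern length = network size N.
    k : int
        Number of categories.
    m : int
        Associations per category.
    p_flip : float
        Per-element flip probability in [0, 0.5]; the within-category
        correlation is ``(1 - 2 p_flip)^2`` in expectation.
    seed : int
        RNG seed; a spec is a complete recipe for one PatternSet.
    """

    n: int = 100
    k: int = 6
    m: int = 6
    p_flip: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1 or self.k < 1 or self.m < 1:
            raise ValueError("n, k and m must all be >= 1")
        if not 0.0 <= self.p_flip <= 0.5:
            raise ValueError(f"p_flip must lie in [0, 0.5], got {self.p_flip}")

    @property
    def n_assoc(self) -> int:
        """Total number of associations K*M."""
        return self.k * self.m


@dataclass
class PatternSet:
    """Inputs eta, targets xi and their category structure.

    ``inputs`` and ``targets`` are (K*M, N) arrays with entries in {-1, +1};
    association ``mu`` belongs to category ``mu // M``.
    """

    inputs: np.ndarray
    targets: np.ndarray
    typical_inputs: np.ndarray
    typical_targets: np.ndarray
    spec: PatternSpec

    def __post_init__(self) -> None:
        for name in ("inputs", "targets"):
            arr = getattr(self, name)
            if arr.shape != (self.spec.n_assoc, self.spec.n):
                raise ValueError(f"{name} must have shape (K*M, N)")
            if not np.isin(arr, (-1, 1)).all():
                raise ValueError(f"{name} entries must be exactly +/-1")

    @property
    def n_assoc(self) -> int:
        return self.spec.n_assoc

    def category_of(self, mu: int | np.ndarray) -> int | np.ndarray:
        """Category index a = floor(mu / M) of association mu."""
        return np.asarray(mu) // self.spec.m if np.ndim(mu) else int(mu) // self.spec.m

    @property
    def categories(self) -> np.ndarray:
        """Category label of every association, shape (K*M,)."""
        return np.arange(self.n_assoc) // self.spec.m


def _flip(members: np.ndarray, p_flip: float, rng: np.random.Generator) -> np.ndarray:
    signs = np.where(rng.random(members.shape) < p_flip, -1, 1)
    return (members * signs).astype(np.int8)


def generate_pattern_set(spec: PatternSpec) -> PatternSet:
    """Draw a PatternSet from its spec (deterministic given the seed).

    Draw order is fixed for reproducibility of saved sets: typical inputs,
    typical targets, then member flips for inputs, then for targets.  Input
    and target members are flipped independently, so an input is uncorrelated
    with its own target in expectation.
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.k, spec.n)
    typical_inputs = (rng.integers(0, 2, size=shape) * 2 - 1).astype(np.int8)
    typical_targets = (rng.integers(0, 2, size=shape) * 2 - 1).astype(np.int8)
    base_in = np.repeat(typical_inputs, spec.m, axis=0)
    base_tg = np.repeat(typical_targets, spec.m, axis=0)
    inputs = _flip(base_in, spec.p_flip, rng)
    targets = _flip(base_tg, spec.p_flip, rng)
    return PatternSet(inputs, targets, typical_inputs, typical_targets, spec)


@dataclass
class CorrelationSummary:
    """Mean pairwise correlations of one PatternSet.

    All quantities are sample means of ``sum_i a_i b_i / N`` over the stated
    pair class; for +/-1 patterns this equals the cosine similarity.
    """

    mean_within_input: float
    mean_within_target: float
    mean_cross: float
    mean_input_target: float
    expected_c: float


def _pair_means(g: np.ndarray, cats: np.ndarray) -> tuple[float, float]:
    """(within-category, cross-category) means of the off-diagonal of g."""
    same = cats[:, None] == cats[None, :]
    off = ~np.eye(len(cats), dtype=bool)
    return float(g[same & off].mean()), float(g[~same].mean())


def empirical_correlations(ps: PatternSet) -> CorrelationSummary:
    """Measure all pair-class mean correlations of a PatternSet."""
    n = ps.spec.n
    cats = ps.categories
    fi = ps.inputs.astype(np.float64)
    ft = ps.targets.astype(np.float64)
    within_in, cross_in = _pair_means(fi @ fi.T / n, cats)
    within_tg, cross_tg = _pair_means(ft @ ft.T / n, cats)
    return CorrelationSummary(
        mean_within_input=within_in,
        mean_within_target=within_tg,
        mean_cross=0.5 * (cross_in + cross_tg),
        mean_input_target=float((fi @ ft.T / n).mean()),
        expected_c=expected_correlation(ps.spec.p_flip),
    )
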