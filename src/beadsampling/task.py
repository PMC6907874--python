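"""Task structure, ideal-observer calculations, and behavioral optimality measures.

The task: on each trial the observer may sequentially draw up to 20 beads
(with replacement) from a hidden jar whose dominant-color proportion is
``q`` (0.6 or 0.8), paying ``unit_cost`` points per bead (0, 0.1, or 0.4),
then judges the jar's identity for a 10-point reward.  An ideal observer
judges by majority color (coin flip on ties), so the expected probability
of a correct judgment after ``n`` beads is a binomial tail sum, and the
expected gain is ``(10 - n*c) * p(n | q)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import binom

MAX_SAMPLES = 20
REWARD_POINTS = 10.0

COST_LEVELS = (0.0, 0.1, 0.4)
EVIDENCE_LEVELS = (0.6, 0.8)


@dataclass(frozen=True)
class Condition:
    """One of the six cost-by-evidence cells of the task.

    Parameters
    ----------
    unit_cost : float
        Points deducted per bead drawn (0, 0.1 or 0.4 in the task).
    q : float
        Proportion of the dominant bead color in the hidden jar,
        strictly between 0.5 and 1 (0.6 or 0.8 in the task).
    """

    unit_cost: float
    q: float

    def __post_init__(self) -> None:
        if self.unit_cost < 0:
            raise ValueError(f"unit_cost must be >= 0, got {self.unit_cost}")
        if not 0.5 < self.q < 1.0:
            raise ValueError(f"q must lie in (0.5, 1), got {self.q}")

    @property
    def cost_level_index(self) -> int:
        """Index of unit_cost within the canonical (0, 0.1, 0.4) ordering."""
        for i, c in enumerate(COST_LEVELS):
            if np.isclose(self.unit_cost, c):
                return i
        raise ValueError(f"unit_cost {self.unit_cost} is not a task cost level")

    @property
    def evidence_level_index(self) -> int:
        for i, q in enumerate(EVIDENCE_LEVELS):
            if np.isclose(self.q, q):
                return i
        raise ValueError(f"q {self.q} is not a task evidence level")


def all_conditions() -> list[Condition]:
    """The six canonical cost-by-evidence conditions, cost-major order."""
    return [Condition(c, q) for c in COST_LEVELS for q in EVIDENCE_LEVELS]


@dataclass
class TrialRecord:
    """A single trial: condition, bead sequence, choices and decision times.

    ``beads`` holds the drawn bead colors ("P"/"B"); its length is the
    sample size ``n_s``.  ``choice_dts`` holds one decision time (seconds)
    per *continue* choice, so ``len(choice_dts) == n_s``.  The stop key
    press time (``stop_dt``) is recorded but never modeled.  ``prev_correct``
    and ``prev_n`` carry the previous trial's outcome into the evidence
    decision variables (0.5 / 0 on the first trial of a session).
    """

    participant_id: str
    trial_index: int
    block_index: int
    condition: Condition
    hidden_jar: str  # "dominant-pink" | "dominant-blue"
    jar_side: str  # "left" | "right"
    beads: Sequence[str] = field(default_factory=list)
    choice_dts: Sequence[float] = field(default_factory=list)
    stop_dt: float | None = None
    judgment: str = ""
    correct: bool = False
    prev_correct: float = 0.5
    prev_n: int = 0

    def __post_init__(self) -> None:
        n_s = len(self.beads)
        if not 0 <= n_s <= MAX_SAMPLES:
            raise ValueError(f"sample size {n_s} outside [0, {MAX_SAMPLES}]")
        if len(self.choice_dts) != n_s:
            raise ValueError(
                f"choice_dts length {len(self.choice_dts)} != sample size {n_s}"
            )
        if any(dt <= 0 for dt in self.choice_dts):
            raise ValueError("decision times must be strictly positive")
        bad = set(self.beads) - {"P", "B"}
        if bad:
            raise ValueError(f"bead colors must be 'P' or 'B', got {bad}")

    @property
    def n_samples(self) -> int:
        return len(self.beads)


@dataclass
class OptimalityProfile:
    """Gain curve and optimum for one condition, over n = 0..20."""

    condition: Condition
    p_correct: np.ndarray
    expected_gain: np.ndarray
    n_opt: int
    max_gain: float


def expected_correct_prob(n: int, q: float) -> float:
    """Probability an ideal observer judges correctly after ``n`` beads.

    Majority rule with ties decided by a fair coin:

    * odd n  : P(dominant-color count > n/2)
    * even n : P(count > n/2) + P(count == n/2)/2
    * n == 0 : 1/2
    """
    if n < 0 or n > MAX_SAMPLES:
        raise ValueError(f"n must lie in [0, {MAX_SAMPLES}], got {n}")
    if not 0.5 < q < 1.0:
        raise ValueError(f"q must lie in (0.5, 1), got {q}")
    if n == 0:
        return 0.5
    if n % 2 == 1:
        # smallest winning count is (n+1)/2
        return float(binom.sf((n - 1) // 2, n, q))
    half = n // 2
    tie = float(binom.pmf(half, n, q))
    return float(binom.sf(half, n, q)) + 0.5 * tie


def expected_gain(
    n: int, condition: Condition, reward: float = REWARD_POINTS
) -> float:
    """Expected points: ``(reward - n * c) * p(n | q)``."""
    return (reward - n * condition.unit_cost) * expected_correct_prob(
        n, condition.q
    )


def optimal_policy(
    condition: Condition, reward: float = REWARD_POINTS
) -> OptimalityProfile:
    """Gain curve over n = 0..20 and its argmax (ties -> largest n).

    An even sample adds nothing over the preceding odd one (the extra tie
    mass is split by the coin flip), so at zero cost the curve is flat on
    (19, 20); the largest maximizer is reported, matching the
    sample-as-much-as-possible reading of the zero-cost optimum.
    """
    ns = np.arange(MAX_SAMPLES + 1)
    p = np.array([expected_correct_prob(int(n), condition.q) for n in ns])
    gain = (reward - ns * condition.unit_cost) * p
    n_opt = int(np.max(np.where(gain >= gain.max() - 1e-9)[0]))
    return OptimalityProfile(
        condition=condition,
        p_correct=p,
        expected_gain=gain,
        n_opt=n_opt,
        max_gain=float(gain[n_opt]),
    )


def efficiency(trials: Sequence[TrialRecord]) -> float:
    """Mean expected gain of the observed sample sizes over the best gain.

    All trials must share one condition; the result lies in (0, 1] and
    equals 1 exactly when every trial hits a maximizer of the gain curve.
    """
    if len(trials) == 0:
        raise ValueError("efficiency requires at least one trial")
    cond = trials[0].condition
    if any(t.condition != cond for t in trials):
        raise ValueError("all trials must share one condition")
    profile = optimal_policy(cond)
    gains = profile.expected_gain[[t.n_samples for t in trials]]
    return float(np.mean(gains) / profile.max_gain)


def sampling_bias_and_variability(
    trials: Sequence[TrialRecord],
) -> tuple[float, float]:
    """(mean n_s - n_opt, sample SD of n_s) within one condition."""
    if len(trials) < 2:
        raise ValueError("sampling variability requires at least 2 trials")
    cond = trials[0].condition
    if any(t.condition != cond for t in trials):
        raise ValueError("all trials must share one condition")
    ns = np.array([t.n_samples for t in trials], dtype=float)
    n_opt = optimal_policy(cond).n_opt
    return float(ns.mean() - n_opt), float(ns.std(ddof=1))


def flag_noncompliant(sample_counts: Sequence[float]) -> np.ndarray:
    """Boxplot-rule outlier flags for per-participant mean sample counts.

    Values below Q1 - 1.5*IQR or above Q3 + 1.5*IQR are flagged as likely
    noncompliant observations.  Quartiles use linear-interpolation
    (type-7) quantiles.
    """
    x = np.asarray(sample_counts, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 values for boxplot fences")
    q1, q3 = np.quantile(x, [0.25, 0.75])
    iqr = q3 - q1
    return (x < q1 - 1.5 * iqr) | (x > q3 + 1.5 * iqr)
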