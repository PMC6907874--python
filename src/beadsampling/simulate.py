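"""Synthetic task schedules and generative agent populations.

The schedule reproduces the study design: 3 cost blocks (0, 0.1, 0.4
points per bead, order given by a 1..6 permutation id) x 96 trials, the two
evidence levels (q = 0.6, 0.8) randomly mixed within block, 48 trials per
cost-by-evidence cell, the pink-dominant jar preselected on exactly half of
the trials in each cell, and left/right jar positions counterbalanced.

Agents generate choices from the two-stage stop-probability models and DTs
from the coupled lognormal model.  Strategic diversity is implemented as
per-trial mixing: each trial runs the agent's cost-first process with
probability ``pi_costfirst`` and the mirrored evidence-first process
otherwise.  In a population, AQ scores are drawn from the study's normal
distribution and linked to ``pi_costfirst`` through a logistic function of
standardized AQ, so higher-AQ agents tend to consider cost first on nearly
every trial while lower-AQ agents mix the two orders.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np

from . import dtime
from .choice import ChoiceModelSpec, get_model
from .dtime import DTParams
from .task import MAX_SAMPLES, Condition, TrialRecord

AQ_MEAN = 69.97
AQ_SD = 10.48
AQ_RANGE = (0, 150)

N_TRIALS = 288
N_PER_BLOCK = 96
N_PER_CELL = 48

COST_FIRST_MODEL = "Cost->C-cond,continue,Evidence"
EVIDENCE_FIRST_MODEL = "Evidence->C-cond,continue,Cost"

# Generative defaults.  Cost-stage weights are (zero, low, high intercepts,
# j, total cost); evidence-stage weights are (intercept, unit log evidence,
# |CI|, total log evidence, prev correctness, prev n).  Chosen so that mean
# sample sizes fall in plausible per-condition ranges (undersampling at
# zero/low cost, small samples at high cost) and the two DT components are
# well separated; see docs/methods.md.
DEFAULT_COST_STAGE_WEIGHTS = np.array([-7.5, -4.0, -2.0, 0.32, 1.2])
DEFAULT_EVIDENCE_STAGE2_WEIGHTS = np.array([-6.0, 0.8, 1.2, 0.6, 0.2, 0.01])
DEFAULT_EVIDENCE_STAGE1_WEIGHTS = np.array([-4.5, 0.7, 1.0, 0.5, 0.1, 0.005])
DEFAULT_COST_STAGE2_WEIGHTS = np.array([-5.0, -2.6, -1.1, 0.30, 1.0])
DEFAULT_P_SEC = np.array([0.15, 0.45, 0.65])  # zero-, low-, high-cost
DEFAULT_ALPHA = 0.95
DEFAULT_DT_STAGE1 = (0.20, -1.60, 0.50, 0.35)
DEFAULT_DT_STAGE2 = (0.40, 0.30, 0.30, 0.40)


@dataclass
class ScheduledTrial:
    block_index: int
    condition: Condition
    hidden_jar: str  # "dominant-pink" | "dominant-blue"
    jar_side: str  # side of the pink-dominant jar: "left" | "right"


@dataclass
class Schedule:
    permutation_id: int
    trials: list[ScheduledTrial]

    def __len__(self) -> int:
        return len(self.trials)


def make_schedule(
    permutation_id: int, rng: np.random.Generator | int | None = None
) -> Schedule:
    """One 288-trial session schedule with the given cost-block order."""
    orders = list(permutations((0.0, 0.1, 0.4)))
    if not 1 <= permutation_id <= 6:
        raise ValueError("permutation_id must lie in 1..6")
    rng = np.random.default_rng(rng)
    block_costs = orders[permutation_id - 1]
    trials: list[ScheduledTrial] = []
    for b, cost in enumerate(block_costs):
        block: list[ScheduledTrial] = []
        for q in (0.6, 0.8):
            cond = Condition(cost, q)
            # 48 per cell: jar (pink/blue dominant) x side fully crossed
            for jar in ("dominant-pink", "dominant-blue"):
                for side in ("left", "right"):
                    block += [
                        ScheduledTrial(b, cond, jar, side)
                        for _ in range(N_PER_CELL // 4)
                    ]
        order = rng.permutation(len(block))
        trials += [block[i] for i in order]
    return Schedule(permutation_id, trials)


@dataclass
class AgentProfile:
    """Generative agent: AQ, strategy mixing, and both process models.

    ``pi_costfirst`` is the probability a given trial is run by the
    cost-first two-stage process rather than the mirrored evidence-first
    one.  Both processes share the second-thought probabilities (per cost
    condition), the evidence decay rate, and the DT parameters.
    """

    agent_id: str
    aq: int
    pi_costfirst: float
    cost_stage_weights: np.ndarray = field(
        default_factory=lambda: DEFAULT_COST_STAGE_WEIGHTS.copy()
    )
    evidence_stage2_weights: np.ndarray = field(
        default_factory=lambda: DEFAULT_EVIDENCE_STAGE2_WEIGHTS.copy()
    )
    evidence_stage1_weights: np.ndarray = field(
        default_factory=lambda: DEFAULT_EVIDENCE_STAGE1_WEIGHTS.copy()
    )
    cost_stage2_weights: np.ndarray = field(
        default_factory=lambda: DEFAULT_COST_STAGE2_WEIGHTS.copy()
    )
    p_sec: np.ndarray = field(default_factory=lambda: DEFAULT_P_SEC.copy())
    alpha: float = DEFAULT_ALPHA
    dt_params: DTParams = field(
        default_factory=lambda: DTParams(DEFAULT_DT_STAGE1, DEFAULT_DT_STAGE2)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi_costfirst <= 1.0:
            raise ValueError("pi_costfirst must lie in [0, 1]")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if np.any((self.p_sec < 0) | (self.p_sec > 1)):
            raise ValueError("p_sec values must lie in [0, 1]")

    def choice_theta(self, process: str) -> np.ndarray:
        """Flat parameter vector of the given process's registry model."""
        if process == "cost_first":
            return np.concatenate(
                [
                    self.cost_stage_weights,
                    self.evidence_stage2_weights,
                    self.p_sec,
                    [self.alpha],
                ]
            )
        if process == "evidence_first":
            return np.concatenate(
                [
                    self.evidence_stage1_weights,
                    self.cost_stage2_weights,
                    self.p_sec,
                    [self.alpha],
                ]
            )
        raise ValueError(f"unknown process {process!r}")

    def spec(self, process: str) -> ChoiceModelSpec:
        return get_model(
            COST_FIRST_MODEL if process == "cost_first" else EVIDENCE_FIRST_MODEL
        )


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _stage_probs_scalar(
    j: int,
    absci: float,
    cond: Condition,
    w_cost: np.ndarray,
    w_evid: np.ndarray,
    prev_correct: float,
    prev_n: int,
    cost_first: bool,
) -> tuple[float, float]:
    """(p1, p2) at one state; the evidence stage carries the prev-trial DVs."""
    lvl = cond.cost_level_index
    llr = math.log(cond.q / (1.0 - cond.q))
    x_cost = w_cost[lvl] + w_cost[3] * j + w_cost[4] * j * cond.unit_cost
    x_evid = (
        w_evid[0]
        + w_evid[1] * llr
        + w_evid[2] * absci
        + w_evid[3] * llr * absci
        + w_evid[4] * prev_correct
        + w_evid[5] * prev_n
    )
    if cost_first:
        return _logistic(x_cost), _logistic(x_evid)
    return _logistic(x_evid), _logistic(x_cost)


def simulate_agent(
    profile: AgentProfile,
    schedule: Schedule,
    rng: np.random.Generator | int | None = None,
    paths_out: list[str] | None = None,
) -> list[TrialRecord]:
    """Simulate one agent through a schedule.

    Each trial runs the cost-first process with probability
    ``pi_costfirst``.  Beads are Bernoulli draws from the hidden jar; at
    each state with fewer than 20 beads the stop/continue choice is drawn
    from the process's two-stage stop probability, and each continue choice
    gets a DT from the finalization path's lognormal.  The judgment follows
    the majority color (ties split by a fair coin).
    """
    rng = np.random.default_rng(rng if rng is not None else profile.seed)
    trials: list[TrialRecord] = []
    prev_correct, prev_n = 0.5, 0
    dtp = profile.dt_params
    for t_idx, st in enumerate(schedule.trials):
        cond = st.condition
        q = cond.q
        p_pink = q if st.hidden_jar == "dominant-pink" else 1.0 - q
        cost_first = rng.random() < profile.pi_costfirst
        if cost_first:
            w_cost = profile.cost_stage_weights
            w_evid = profile.evidence_stage2_weights
        else:
            w_cost = profile.cost_stage2_weights
            w_evid = profile.evidence_stage1_weights
        p_sec = float(profile.p_sec[cond.cost_level_index])

        beads: list[str] = []
        dts: list[float] = []
        ci = 0.0
        j = 0
        while j < MAX_SAMPLES:
            p1, p2 = _stage_probs_scalar(
                j, abs(ci), cond, w_cost, w_evid, prev_correct, prev_n,
                cost_first,
            )
            # forward two-stage draw (continue-triggered)
            if rng.random() < p1:
                break  # first-stage stop is final
            if rng.random() < p_sec:  # second thought
                if rng.random() < p2:
                    break  # re-decided to stop
                path = "stage2"
            else:
                path = "stage1"
            y_loc, sigma = _path_loc(dtp, p1, p2, path)
            if paths_out is not None:
                paths_out.append(path)
            dts.append(float(np.exp(y_loc + sigma * rng.standard_normal())))
            bead = "P" if rng.random() < p_pink else "B"
            beads.append(bead)
            ci = profile.alpha * ci + (1.0 if bead == "P" else -1.0)
            j += 1

        n_pink = beads.count("P")
        n_blue = len(beads) - n_pink
        if n_pink > n_blue:
            judged = "dominant-pink"
        elif n_blue > n_pink:
            judged = "dominant-blue"
        else:
            judged = "dominant-pink" if rng.random() < 0.5 else "dominant-blue"
        correct = judged == st.hidden_jar
        pink_side = st.jar_side
        judgment = (
            pink_side
            if judged == "dominant-pink"
            else ("right" if pink_side == "left" else "left")
        )
        trials.append(
            TrialRecord(
                participant_id=profile.agent_id,
                trial_index=t_idx + 1,
                block_index=st.block_index,
                condition=cond,
                hidden_jar=st.hidden_jar,
                jar_side=st.jar_side,
                beads=beads,
                choice_dts=dts,
                stop_dt=None,
                judgment=judgment,
                correct=correct,
                prev_correct=prev_correct,
                prev_n=prev_n,
            )
        )
        prev_correct = 1.0 if correct else 0.0
        prev_n = len(beads)
    return trials


def simulate_from_model(
    spec: ChoiceModelSpec,
    choice_theta: np.ndarray,
    dt_params: DTParams,
    schedule: Schedule,
    rng: np.random.Generator | int | None = None,
    participant_id: str = "sim",
    paths_out: list[str] | None = None,
) -> list[TrialRecord]:
    """Simulate a session from any registry model (generic, slower path).

    Choices follow the model's exact stage structure (one-stage,
    continue-triggered, or stop-triggered two-stage); continue-choice DTs
    are drawn from the finalization path's lognormal.  The empirical stop
    frequency at a state therefore matches the model's closed-form stop
    probability.
    """
    from .choice import ChoiceState, stop_probability

    rng = np.random.default_rng(rng)
    params = spec.unpack(np.asarray(choice_theta, dtype=float))
    trials: list[TrialRecord] = []
    prev_correct, prev_n = 0.5, 0
    for t_idx, st in enumerate(schedule.trials):
        cond = st.condition
        p_pink = cond.q if st.hidden_jar == "dominant-pink" else 1.0 - cond.q
        beads: list[str] = []
        dts: list[float] = []
        ci = 0.0
        j = 0
        while j < MAX_SAMPLES:
            state = ChoiceState(j, cond, ci, prev_correct, prev_n)
            _, p1, p2, psec = stop_probability(spec, params, state)
            path = None
            if spec.family == "one_stage":
                if rng.random() < p1:
                    break
                path = "stage1"
            elif spec.trigger == "continue":
                if rng.random() < p1:
                    break
                if rng.random() < psec:
                    if rng.random() < p2:
                        break
                    path = "stage2"
                else:
                    path = "stage1"
            else:  # stop-triggered
                if rng.random() < p1:
                    if rng.random() >= psec:
                        break  # stop is final
                    if rng.random() < p2:
                        break  # re-decided, still stop
                    path = "stage2"  # overturned into continue
                else:
                    path = "stage1"
            y1, ystop1, y2 = dtime.expected_stage_dts(
                np.array([p1]),
                None if p2 is None else np.array([p2]),
                dt_params,
                spec.trigger,
            )
            if path == "stage1":
                loc, sigma = math.log(y1[0]), dt_params.stage1[3]
            else:
                loc, sigma = math.log(y2[0]), dt_params.stage2[3]
            if paths_out is not None:
                paths_out.append(path)
            dts.append(float(np.exp(loc + sigma * rng.standard_normal())))
            bead = "P" if rng.random() < p_pink else "B"
            beads.append(bead)
            ci = params.alpha * ci + (1.0 if bead == "P" else -1.0)
            j += 1
        n_pink = beads.count("P")
        n_blue = len(beads) - n_pink
        if n_pink != n_blue:
            judged = "dominant-pink" if n_pink > n_blue else "dominant-blue"
        else:
            judged = "dominant-pink" if rng.random() < 0.5 else "dominant-blue"
        correct = judged == st.hidden_jar
        judgment = (
            st.jar_side
            if judged == "dominant-pink"
            else ("right" if st.jar_side == "left" else "left")
        )
        trials.append(
            TrialRecord(
                participant_id=participant_id,
                trial_index=t_idx + 1,
                block_index=st.block_index,
                condition=cond,
                hidden_jar=st.hidden_jar,
                jar_side=st.jar_side,
                beads=beads,
                choice_dts=dts,
                judgment=judgment,
                correct=correct,
                prev_correct=prev_correct,
                prev_n=prev_n,
            )
        )
        prev_correct = 1.0 if correct else 0.0
        prev_n = len(beads)
    return trials


def _path_loc(dtp: DTParams, p1: float, p2: float, path: str):
    b0, b1, b2, s1 = dtp.stage1
    y1 = math.exp(b0 + b1 * (1.0 - p1) + b2 * p1 * (1.0 - p1))
    if path == "stage1":
        return math.log(y1), s1
    c0, c1, c2, s2 = dtp.stage2
    y2 = y1 + math.exp(c0 + c1 * (1.0 - p2) + c2 * p2 * (1.0 - p2))
    return math.log(y2), s2


def _jitter_profile(
    base: AgentProfile, rng: np.random.Generator, kappa_psec: float = 8.0
) -> dict:
    """Across-agent parameter variation around the generative defaults."""

    def beta_around(mu: float, kappa: float) -> float:
        mu = min(max(mu, 0.02), 0.98)
        return float(rng.beta(mu * kappa, (1.0 - mu) * kappa))

    p_sec = np.array([beta_around(m, kappa_psec) for m in DEFAULT_P_SEC])
    alpha = beta_around(DEFAULT_ALPHA, 60.0)
    jw = lambda w, s: w + rng.normal(0.0, s, w.size)  # noqa: E731
    d1 = np.array(DEFAULT_DT_STAGE1) + rng.normal(0.0, [0.05, 0.15, 0.1, 0.0], 4)
    d2 = np.array(DEFAULT_DT_STAGE2) + rng.normal(0.0, [0.05, 0.15, 0.1, 0.0], 4)
    d1[0] = max(d1[0], 0.02)
    d2[0] = max(d2[0], 0.02)
    d1[3] = float(np.clip(DEFAULT_DT_STAGE1[3] * np.exp(rng.normal(0, 0.2)), 0.1, 1.0))
    d2[3] = float(np.clip(DEFAULT_DT_STAGE2[3] * np.exp(rng.normal(0, 0.2)), 0.1, 1.0))
    return dict(
        cost_stage_weights=jw(DEFAULT_COST_STAGE_WEIGHTS, 0.3),
        evidence_stage2_weights=jw(DEFAULT_EVIDENCE_STAGE2_WEIGHTS, 0.15),
        evidence_stage1_weights=jw(DEFAULT_EVIDENCE_STAGE1_WEIGHTS, 0.15),
        cost_stage2_weights=jw(DEFAULT_COST_STAGE2_WEIGHTS, 0.3),
        p_sec=p_sec,
        alpha=alpha,
        dt_params=DTParams(tuple(d1), tuple(d2)),
    )


def simulate_population(
    n_agents: int = 104,
    aq_mean: float = AQ_MEAN,
    aq_sd: float = AQ_SD,
    strategy_link: tuple[float, float] = (1.0, 1.2),
    rng: np.random.Generator | int | None = None,
    vary_params: bool = True,
    psec_kappa: float = 8.0,
) -> tuple[dict[str, list[TrialRecord]], list[AgentProfile]]:
    """Simulate a population of agents with AQ-linked strategy mixing.

    AQ is drawn from Normal(aq_mean, aq_sd), rounded and clipped to the
    questionnaire range; ``pi_costfirst = logistic(a + b * zAQ)`` with
    ``(a, b) = strategy_link``, so b > 0 makes higher-AQ agents more
    cost-first.  Returns (datasets keyed by agent id, ground-truth
    profiles).
    """
    if n_agents < 2:
        raise ValueError("need at least 2 agents")
    rng = np.random.default_rng(rng)
    a, b = strategy_link
    datasets: dict[str, list[TrialRecord]] = {}
    profiles: list[AgentProfile] = []
    for i in range(n_agents):
        aq = int(np.clip(round(rng.normal(aq_mean, aq_sd)), *AQ_RANGE))
        z = (aq - aq_mean) / aq_sd
        pi = _logistic(a + b * z)
        extra = (
            _jitter_profile(AgentProfile("tmp", aq, pi), rng, psec_kappa)
            if vary_params
            else {}
        )
        profile = AgentProfile(
            agent_id=f"S{i + 1:03d}",
            aq=aq,
            pi_costfirst=pi,
            seed=int(rng.integers(2**31 - 1)),
            **extra,
        )
        schedule = make_schedule(
            permutation_id=int(rng.integers(1, 7)), rng=rng
        )
        datasets[profile.agent_id] = simulate_agent(profile, schedule, rng)
        profiles.append(profile)
    return datasets, profiles
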