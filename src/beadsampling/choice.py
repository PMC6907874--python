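"""One- and two-stage logistic models of sequential sampling choices.

Every choice of whether to draw another bead is a Bernoulli variable whose
stop probability is a logistic function of cost- and/or evidence-related
decision variables (DVs).  One-stage models use a single logistic stage;
two-stage models allow a probabilistic "second thought": conditional on the
first-stage decision (continue- or stop-triggered), a second stage driven by
the complementary DV set may re-decide, with second-thought probability
``p_sec`` set by the cost condition, the evidence condition, or a flexible
function of the first-stage stop probability.  The full registry holds
4 one-stage + 2 (order) x 2 (trigger) x 3 (rule) = 12 two-stage models.

Decision variables
------------------
cost set (5 weights, no global intercept):
    indicator(zero cost), indicator(low cost), indicator(high cost),
    beads drawn so far ``j``, total cost ``j * c``.
evidence set (6 weights when it is a stage of its own):
    intercept, unit log evidence ``ln(q/(1-q))``, |decayed cumulative
    information|, their product (total log evidence), previous-trial
    correctness (0/1, 0.5 on trial 1), previous-trial sample count.
When both sets share one stage (combined one-stage models) the evidence
intercept is dropped (the cost-level indicators span it): 10 weights.

Cumulative information (CI) is the signed pink-minus-blue count, updated
after each bead as ``alpha * CI +/- 1`` with decay rate ``alpha`` in [0, 1];
models "without decay" fix ``alpha = 1``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit, logit as sp_logit

from .task import MAX_SAMPLES, Condition, TrialRecord

logger = logging.getLogger(__name__)

PROB_FLOOR = 1e-12  # clamp for degenerate likelihood terms
WEIGHT_BOUND = 50.0  # implementation clipping bound for "unbounded" weights

N_COST_WEIGHTS = 5
N_EVIDENCE_WEIGHTS = 6  # with stage intercept
N_COMBINED_WEIGHTS = 10  # cost set + evidence set without its intercept

ONE_STAGE = "one_stage"
TWO_STAGE = "two_stage"


@dataclass(frozen=True)
class ChoiceModelSpec:
    """Identity of one model in the 16-model space.

    ``stage1_dvs``/``stage2_dvs`` name the DV set of each stage
    ("cost", "evidence", or "cost+evidence" for combined one-stage
    models; ``stage2_dvs`` is None for one-stage models).  ``trigger``
    states which first-stage decision can recruit the second stage and
    ``rule`` what sets the second-thought probability.
    """

    name: str
    family: str
    stage1_dvs: str
    stage2_dvs: str | None = None
    trigger: str | None = None  # "continue" | "stop"
    rule: str | None = None  # "cost_cond" | "evidence_cond" | "flexible"
    decay: bool = False

    def __post_init__(self) -> None:
        if self.family not in (ONE_STAGE, TWO_STAGE):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == TWO_STAGE:
            if {self.stage1_dvs, self.stage2_dvs} != {"cost", "evidence"}:
                raise ValueError(
                    "two-stage models use cost DVs in exactly one stage "
                    "and evidence DVs in the other"
                )
            if self.trigger not in ("continue", "stop"):
                raise ValueError("two-stage models need a trigger")
            if self.rule not in ("cost_cond", "evidence_cond", "flexible"):
                raise ValueError("two-stage models need a second-thought rule")
        else:
            if self.stage2_dvs or self.trigger or self.rule:
                raise ValueError("one-stage specs carry no stage-2 fields")

    # ---- parameter vector layout -------------------------------------
    @property
    def n_stage1_weights(self) -> int:
        return _n_weights(self.stage1_dvs)

    @property
    def n_stage2_weights(self) -> int:
        return 0 if self.stage2_dvs is None else _n_weights(self.stage2_dvs)

    @property
    def n_rule_params(self) -> int:
        return {"cost_cond": 3, "evidence_cond": 2, "flexible": 2, None: 0}[
            self.rule
        ]

    @property
    def n_params(self) -> int:
        return (
            self.n_stage1_weights
            + self.n_stage2_weights
            + self.n_rule_params
            + (1 if self.decay else 0)
        )

    def param_names(self) -> list[str]:
        names = [f"s1_{d}" for d in _dv_names(self.stage1_dvs)]
        if self.stage2_dvs:
            names += [f"s2_{d}" for d in _dv_names(self.stage2_dvs)]
        if self.rule == "cost_cond":
            names += ["psec_zero", "psec_low", "psec_high"]
        elif self.rule == "evidence_cond":
            names += ["psec_lowev", "psec_highev"]
        elif self.rule == "flexible":
            names += ["gamma", "phi"]
        if self.decay:
            names += ["alpha"]
        return names

    def bounds(self) -> list[tuple[float, float]]:
        b = [(-WEIGHT_BOUND, WEIGHT_BOUND)] * (
            self.n_stage1_weights + self.n_stage2_weights
        )
        if self.rule in ("cost_cond", "evidence_cond"):
            b += [(0.0, 1.0)] * self.n_rule_params
        elif self.rule == "flexible":
            b += [(-WEIGHT_BOUND, WEIGHT_BOUND)] * 2
        if self.decay:
            b += [(0.0, 1.0)]
        return b

    def default_init(self) -> np.ndarray:
        x = np.zeros(self.n_params)
        k = self.n_stage1_weights + self.n_stage2_weights
        if self.rule in ("cost_cond", "evidence_cond"):
            x[k : k + self.n_rule_params] = 0.5
        elif self.rule == "flexible":
            x[k] = 1.0  # gamma
            x[k + 1] = 0.0  # phi
        if self.decay:
            x[-1] = 0.9
        return x

    def unpack(self, theta: np.ndarray) -> "ChoiceParams":
        theta = np.asarray(theta, dtype=float)
        if theta.size != self.n_params:
            raise ValueError(
                f"{self.name}: expected {self.n_params} parameters, "
                f"got {theta.size}"
            )
        k1 = self.n_stage1_weights
        k2 = self.n_stage2_weights
        kr = self.n_rule_params
        return ChoiceParams(
            stage1_weights=theta[:k1].copy(),
            stage2_weights=theta[k1 : k1 + k2].copy() if k2 else None,
            second_thought=(
                theta[k1 + k2 : k1 + k2 + kr].copy() if kr else None
            ),
            alpha=float(theta[-1]) if self.decay else 1.0,
        )

    def pack(self, params: "ChoiceParams") -> np.ndarray:
        parts = [np.asarray(params.stage1_weights, dtype=float)]
        if self.stage2_dvs:
            parts.append(np.asarray(params.stage2_weights, dtype=float))
        if self.rule:
            parts.append(np.asarray(params.second_thought, dtype=float))
        if self.decay:
            parts.append(np.array([params.alpha]))
        theta = np.concatenate(parts)
        if theta.size != self.n_params:
            raise ValueError("parameter fields do not match spec layout")
        return theta


@dataclass
class ChoiceParams:
    """Fitted or generative parameters of one choice model."""

    stage1_weights: np.ndarray
    stage2_weights: np.ndarray | None = None
    second_thought: np.ndarray | None = None  # rule params
    alpha: float = 1.0


@dataclass
class ChoiceState:
    """The information available at one stop/continue choice."""

    j: int
    condition: Condition
    ci_decayed: float = 0.0
    prev_correct: float = 0.5
    prev_n: int = 0


def _n_weights(dv_set: str) -> int:
    return {
        "cost": N_COST_WEIGHTS,
        "evidence": N_EVIDENCE_WEIGHTS,
        "cost+evidence": N_COMBINED_WEIGHTS,
    }[dv_set]


def _dv_names(dv_set: str) -> list[str]:
    cost = ["zero", "low", "high", "j", "totcost"]
    evid = ["intercept", "llr", "absci", "totllr", "prevcorr", "prevn"]
    if dv_set == "cost":
        return cost
    if dv_set == "evidence":
        return evid
    return cost + evid[1:]


# ---------------------------------------------------------------------------
# scalar state-level kernels (reference implementation; fitting uses the
# vectorized path below)
# ---------------------------------------------------------------------------


def update_decayed_ci(ci: float, bead: str, alpha: float) -> float:
    """One CI update: ``alpha * ci + 1`` after pink, ``- 1`` after blue."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    if bead == "P":
        return alpha * ci + 1.0
    if bead == "B":
        return alpha * ci - 1.0
    raise ValueError(f"bead must be 'P' or 'B', got {bead!r}")


def decayed_ci_sequence(beads: Sequence[str], alpha: float) -> np.ndarray:
    """CI before each choice j = 0..len(beads) (CI at j=0 is 0)."""
    ci = np.empty(len(beads) + 1)
    ci[0] = 0.0
    for j, bead in enumerate(beads):
        ci[j + 1] = update_decayed_ci(ci[j], bead, alpha)
    return ci


def state_dvs(state: ChoiceState, dv_set: str) -> np.ndarray:
    """Decision-variable vector for one state and DV set."""
    cond = state.condition
    lvl = cond.cost_level_index
    cost = np.array(
        [
            1.0 if lvl == 0 else 0.0,
            1.0 if lvl == 1 else 0.0,
            1.0 if lvl == 2 else 0.0,
            float(state.j),
            float(state.j) * cond.unit_cost,
        ]
    )
    llr = math.log(cond.q / (1.0 - cond.q))
    absci = abs(state.ci_decayed)
    evid = np.array(
        [1.0, llr, absci, llr * absci, state.prev_correct, float(state.prev_n)]
    )
    if dv_set == "cost":
        return cost
    if dv_set == "evidence":
        return evid
    if dv_set == "cost+evidence":
        return np.concatenate([cost, evid[1:]])
    raise ValueError(f"unknown dv_set {dv_set!r}")


def stage_logit(state: ChoiceState, weights: np.ndarray, dv_set: str) -> float:
    """Linear predictor ``X = sum_k beta_k DV_k`` for one stage."""
    dvs = state_dvs(state, dv_set)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != dvs.shape:
        raise ValueError(
            f"weights arity {weights.shape} does not match "
            f"{dv_set} DVs {dvs.shape}"
        )
    return float(weights @ dvs)


def flexible_psec(p_stage1: float, gamma: float, phi: float) -> float:
    """Second-thought probability from logit(psec) = gamma*logit(p1) + phi."""
    l1 = sp_logit(np.clip(p_stage1, PROB_FLOOR, 1 - PROB_FLOOR))
    return float(expit(gamma * l1 + phi))


def combine_stages(
    p1: float, p2: float, p_sec: float, trigger: str
) -> float:
    """Overall stop probability of a two-stage model.

    continue-triggered: ``p1 + (1 - p1) * p_sec * p2``
    stop-triggered:     ``p1 * (1 - p_sec) + p1 * p_sec * p2``
    """
    if trigger == "continue":
        return p1 + (1.0 - p1) * p_sec * p2
    if trigger == "stop":
        return p1 * (1.0 - p_sec) + p1 * p_sec * p2
    raise ValueError(f"unknown trigger {trigger!r}")


def stop_probability(
    spec: ChoiceModelSpec, params: ChoiceParams, state: ChoiceState
) -> tuple[float, float, float | None, float | None]:
    """(p_stop, p_stage1, p_stage2 or None, p_sec or None) at one state."""
    p1 = float(expit(stage_logit(state, params.stage1_weights, spec.stage1_dvs)))
    if spec.family == ONE_STAGE:
        return p1, p1, None, None
    p2 = float(expit(stage_logit(state, params.stage2_weights, spec.stage2_dvs)))
    p_sec = _psec_scalar(spec, params, state, p1)
    return combine_stages(p1, p2, p_sec, spec.trigger), p1, p2, p_sec


def _psec_scalar(
    spec: ChoiceModelSpec,
    params: ChoiceParams,
    state: ChoiceState,
    p1: float,
) -> float:
    st = params.second_thought
    if spec.rule == "cost_cond":
        return float(st[state.condition.cost_level_index])
    if spec.rule == "evidence_cond":
        return float(st[state.condition.evidence_level_index])
    return flexible_psec(p1, float(st[0]), float(st[1]))


# ---------------------------------------------------------------------------
# vectorized per-participant machinery
# ---------------------------------------------------------------------------


@dataclass
class ChoiceData:
    """Flattened choice observations for one participant.

    One row per modeled stop/continue decision: every j = 0..n_s-1 is a
    continue choice, and j = n_s is a stop choice unless the trial hit the
    20-bead cap (the forced stop at j = 20 is not a choice and is excluded).
    """

    trial_row: np.ndarray  # index into trial-level arrays
    j: np.ndarray
    stop: np.ndarray  # observed choice: 1 stop, 0 continue
    cost_idx: np.ndarray  # 0 | 1 | 2
    evid_idx: np.ndarray  # 0 (q=0.6) | 1 (q=0.8)
    unit_cost: np.ndarray
    llr: np.ndarray
    prev_correct: np.ndarray
    prev_n: np.ndarray
    dt: np.ndarray  # seconds for continue choices, nan otherwise
    signs: np.ndarray  # (n_trials, 20) +1 pink / -1 blue, 0 padding
    n_trials: int

    @property
    def n_choices(self) -> int:
        return self.j.size

    def ci_at_choices(self, alpha: float) -> np.ndarray:
        """|alpha|-decayed CI before each choice, via the 20-step recursion."""
        ci = np.zeros((self.n_trials, MAX_SAMPLES + 1))
        for jj in range(1, MAX_SAMPLES + 1):
            ci[:, jj] = alpha * ci[:, jj - 1] + self.signs[:, jj - 1]
        return ci[self.trial_row, self.j]


def build_choice_data(trials: Sequence[TrialRecord]) -> ChoiceData:
    rows, js, stops, dts = [], [], [], []
    cost_idx, evid_idx, ucost, llrs, pcs, pns = [], [], [], [], [], []
    signs = np.zeros((len(trials), MAX_SAMPLES))
    for r, t in enumerate(trials):
        n_s = t.n_samples
        bead_signs = [1.0 if b == "P" else -1.0 for b in t.beads]
        signs[r, :n_s] = bead_signs
        llr = math.log(t.condition.q / (1.0 - t.condition.q))
        n_choices = n_s if n_s == MAX_SAMPLES else n_s + 1
        for j in range(n_choices):
            rows.append(r)
            js.append(j)
            stops.append(0.0 if j < n_s else 1.0)
            dts.append(t.choice_dts[j] if j < n_s else np.nan)
            cost_idx.append(t.condition.cost_level_index)
            evid_idx.append(t.condition.evidence_level_index)
            ucost.append(t.condition.unit_cost)
            llrs.append(llr)
            pcs.append(t.prev_correct)
            pns.append(float(t.prev_n))
    return ChoiceData(
        trial_row=np.array(rows, dtype=np.intp),
        j=np.array(js, dtype=np.intp),
        stop=np.array(stops),
        cost_idx=np.array(cost_idx, dtype=np.intp),
        evid_idx=np.array(evid_idx, dtype=np.intp),
        unit_cost=np.array(ucost),
        llr=np.array(llrs),
        prev_correct=np.array(pcs),
        prev_n=np.array(pns),
        dt=np.array(dts),
        signs=signs,
        n_trials=len(trials),
    )


def _stage_design(data: ChoiceData, dv_set: str, absci: np.ndarray) -> np.ndarray:
    jf = data.j.astype(float)
    cost = np.column_stack(
        [
            (data.cost_idx == 0).astype(float),
            (data.cost_idx == 1).astype(float),
            (data.cost_idx == 2).astype(float),
            jf,
            jf * data.unit_cost,
        ]
    )
    evid = np.column_stack(
        [
            np.ones(data.n_choices),
            data.llr,
            absci,
            data.llr * absci,
            data.prev_correct,
            data.prev_n,
        ]
    )
    if dv_set == "cost":
        return cost
    if dv_set == "evidence":
        return evid
    return np.column_stack([cost, evid[:, 1:]])


def stage_probabilities(
    spec: ChoiceModelSpec, theta: np.ndarray, data: ChoiceData
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None, np.ndarray | None]:
    """Per-observation (p_stop, p1, p2, psec) for a flat parameter vector."""
    params = spec.unpack(theta)
    absci = np.abs(data.ci_at_choices(params.alpha))
    x1 = _stage_design(data, spec.stage1_dvs, absci) @ params.stage1_weights
    p1 = expit(x1)
    if spec.family == ONE_STAGE:
        return p1, p1, None, None
    x2 = _stage_design(data, spec.stage2_dvs, absci) @ params.stage2_weights
    p2 = expit(x2)
    st = params.second_thought
    if spec.rule == "cost_cond":
        psec = st[data.cost_idx]
    elif spec.rule == "evidence_cond":
        psec = st[data.evid_idx]
    else:
        l1 = np.clip(x1, -WEIGHT_BOUND, WEIGHT_BOUND)
        psec = expit(st[0] * l1 + st[1])
    if spec.trigger == "continue":
        p_stop = p1 + (1.0 - p1) * psec * p2
    else:
        p_stop = p1 * (1.0 - psec) + p1 * psec * p2
    return p_stop, p1, p2, psec


def choice_loglik_data(
    spec: ChoiceModelSpec, theta: np.ndarray, data: ChoiceData
) -> float:
    """Bernoulli log likelihood of all modeled choices (fast path)."""
    p_stop, _, _, _ = stage_probabilities(spec, theta, data)
    p = np.clip(p_stop, PROB_FLOOR, 1.0 - PROB_FLOOR)
    return float(
        np.sum(data.stop * np.log(p) + (1.0 - data.stop) * np.log1p(-p))
    )


def choice_loglik(
    spec: ChoiceModelSpec,
    params: ChoiceParams | np.ndarray,
    trials: Sequence[TrialRecord],
) -> tuple[float, dict[str, np.ndarray]]:
    """Choice log likelihood plus per-choice stage quantities.

    Returns the summed log likelihood and a cache with per-observation
    arrays (``p_stop``, ``p_stage1``, ``p_stage2``, ``p_sec``, ``stop``,
    ``dt``, ``is_continue``) needed by the decision-time model.
    Probabilities that conflict with an observed choice are clamped at
    1e-12 and logged.
    """
    data = build_choice_data(trials)
    theta = params if isinstance(params, np.ndarray) else spec.pack(params)
    p_stop, p1, p2, psec = stage_probabilities(spec, theta, data)
    p = np.clip(p_stop, PROB_FLOOR, 1.0 - PROB_FLOOR)
    n_clamped = int(np.sum((p_stop <= PROB_FLOOR) & (data.stop == 1))) + int(
        np.sum((p_stop >= 1 - PROB_FLOOR) & (data.stop == 0))
    )
    if n_clamped:
        logger.warning(
            "%s: %d choice probabilities clamped at floor %.0e",
            spec.name,
            n_clamped,
            PROB_FLOOR,
        )
    ll = float(
        np.sum(data.stop * np.log(p) + (1.0 - data.stop) * np.log1p(-p))
    )
    cache = {
        "p_stop": p_stop,
        "p_stage1": p1,
        "p_stage2": p2,
        "p_sec": psec,
        "stop": data.stop,
        "dt": data.dt,
        "is_continue": data.stop == 0,
    }
    return ll, cache


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

BEST_MODEL_NAME = "Cost->C-cond,continue,Evidence"

_RULE_LABEL = {"cost_cond": "C-cond", "evidence_cond": "E-cond", "flexible": "flex"}


def enumerate_registry() -> list[ChoiceModelSpec]:
    """The full 16-model space: 4 one-stage + 2x2x3 two-stage models."""
    specs = [
        ChoiceModelSpec("Cost only", ONE_STAGE, "cost"),
        ChoiceModelSpec("Evidence only w/o decay", ONE_STAGE, "evidence"),
        ChoiceModelSpec(
            "Cost + Evidence w/o decay", ONE_STAGE, "cost+evidence"
        ),
        ChoiceModelSpec(
            "Cost + Evidence", ONE_STAGE, "cost+evidence", decay=True
        ),
    ]
    for order in ("cost_first", "evidence_first"):
        s1, s2 = (
            ("cost", "evidence") if order == "cost_first" else ("evidence", "cost")
        )
        first, second = (
            ("Cost", "Evidence") if order == "cost_first" else ("Evidence", "Cost")
        )
        for rule in ("cost_cond", "evidence_cond", "flexible"):
            for trigger in ("continue", "stop"):
                name = f"{first}->{_RULE_LABEL[rule]},{trigger},{second}"
                specs.append(
                    ChoiceModelSpec(
                        name, TWO_STAGE, s1, s2, trigger, rule, decay=True
                    )
                )
    return specs


def get_model(name: str) -> ChoiceModelSpec:
    for spec in enumerate_registry():
        if spec.name == name:
            return spec
    raise KeyError(f"no model named {name!r} in the registry")


def registry_manifest() -> list[dict]:
    """Machine-readable description of every model (for CLI/docs)."""
    out = []
    for spec in enumerate_registry():
        out.append(
            {
                "name": spec.name,
                "family": spec.family,
                "stage1_dvs": spec.stage1_dvs,
                "stage2_dvs": spec.stage2_dvs,
                "trigger": spec.trigger,
                "second_thought_rule": spec.rule,
                "decay": spec.decay,
                "n_params": spec.n_params,
                "param_names": spec.param_names(),
                "bounds": spec.bounds(),
            }
        )
    return out
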