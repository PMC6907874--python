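"""Lognormal decision-time (DT) model coupled to the choice models.

Only DTs of *continue* choices are modeled (stopping uses a different key).
The expected DT of a first-stage decision is an exponential-linear function
of the stage's stop probability:

    Y_cont1 = exp(b0 + b1 * (1 - p1) + b2 * p1 * (1 - p1))
    Y_stop1 = exp(b0 + b1 * p1       + b2 * p1 * (1 - p1))

The quadratic term carries choice difficulty; swapping ``p1`` for
``1 - p1`` lets correct/continue decisions be faster or slower than stop
decisions.  A decision finalized in the second stage adds a second-stage
term on top of the first-stage time:

    Y_cont2 = Y_first + exp(b0' + b1' * (1 - p2) + b2' * p2 * (1 - p2))

where ``Y_first`` is ``Y_cont1`` for continue-triggered models (the second
stage follows a first-stage continue) and ``Y_stop1`` for stop-triggered
models.  Observed DTs are lognormal around the path's expected DT, so a
two-stage model predicts a two-component lognormal mixture whose weights
are the stage posteriors given a continue choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass
class DTParams:
    """DT parameters: one (b0, b1, b2, sigma) tuple per stage.

    ``b0`` and ``sigma`` are positive (the exponential link keeps expected
    DTs positive); ``stage2`` is None for one-stage models.
    """

    stage1: tuple[float, float, float, float]
    stage2: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        for st in (self.stage1, self.stage2):
            if st is None:
                continue
            b0, _, _, sigma = st
            if b0 <= 0:
                raise ValueError(f"b0 must be positive, got {b0}")
            if sigma <= 0:
                raise ValueError(f"sigma must be positive, got {sigma}")

    def as_vector(self) -> np.ndarray:
        v = list(self.stage1)
        if self.stage2 is not None:
            v += list(self.stage2)
        return np.array(v)

    @classmethod
    def from_vector(cls, v: np.ndarray, two_stage: bool) -> "DTParams":
        v = np.asarray(v, dtype=float)
        if two_stage:
            if v.size != 8:
                raise ValueError("two-stage DT model has 8 parameters")
            return cls(tuple(v[:4]), tuple(v[4:]))
        if v.size != 4:
            raise ValueError("one-stage DT model has 4 parameters")
        return cls(tuple(v))


def expected_stage_dts(
    p_stage1: np.ndarray,
    p_stage2: np.ndarray | None,
    params: DTParams,
    trigger: str | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """(Y_cont1, Y_stop1, Y_cont2 or None) for per-observation stage probs."""
    p1 = np.asarray(p_stage1, dtype=float)
    b0, b1, b2, _ = params.stage1
    quad = p1 * (1.0 - p1)
    y_cont1 = np.exp(b0 + b1 * (1.0 - p1) + b2 * quad)
    y_stop1 = np.exp(b0 + b1 * p1 + b2 * quad)
    if params.stage2 is None:
        return y_cont1, y_stop1, None
    if trigger not in ("continue", "stop"):
        raise ValueError(f"two-stage DT model needs a trigger, got {trigger!r}")
    p2 = np.asarray(p_stage2, dtype=float)
    c0, c1, c2, _ = params.stage2
    stage2_time = np.exp(c0 + c1 * (1.0 - p2) + c2 * p2 * (1.0 - p2))
    y_first = y_cont1 if trigger == "continue" else y_stop1
    return y_cont1, y_stop1, y_first + stage2_time


def stage_posteriors(
    p_stage1: np.ndarray,
    p_stage2: np.ndarray,
    p_sec: np.ndarray,
    trigger: str,
) -> tuple[np.ndarray, np.ndarray]:
    """P(finalized at stage 1 | continue), P(stage 2 | continue).

    continue-triggered: P(S1|cont) = (1-psec) / ((1-psec) + psec*(1-p2))
    stop-triggered:     P(S1|cont) = (1-p1) / ((1-p1) + p1*psec*(1-p2))
    The pair always sums to 1.
    """
    p1 = np.asarray(p_stage1, dtype=float)
    p2 = np.asarray(p_stage2, dtype=float)
    ps = np.asarray(p_sec, dtype=float)
    if trigger == "continue":
        num = 1.0 - ps
        den = num + ps * (1.0 - p2)
    elif trigger == "stop":
        num = 1.0 - p1
        den = num + p1 * ps * (1.0 - p2)
    else:
        raise ValueError(f"unknown trigger {trigger!r}")
    den = np.asarray(den, dtype=float)
    if np.any(den <= 0):
        raise ValueError(
            "continue choice impossible under these stage probabilities"
        )
    w1 = num / den
    return w1, 1.0 - w1


def _lognorm_logpdf(dt: np.ndarray, log_y: np.ndarray, sigma: float) -> np.ndarray:
    z = (np.log(dt) - log_y) / sigma
    return -np.log(dt) - math.log(sigma) - _LOG_SQRT_2PI - 0.5 * z * z


def dt_loglik(
    dt: np.ndarray,
    params: DTParams,
    p_stage1: np.ndarray,
    p_stage2: np.ndarray | None = None,
    p_sec: np.ndarray | None = None,
    trigger: str | None = None,
    total: bool = True,
) -> float | np.ndarray:
    """Log likelihood of continue-choice DTs.

    One-stage models: lognormal density with location ``ln Y_cont1``.
    Two-stage models: two-component lognormal mixture with the stage
    posteriors given a continue choice as weights.
    """
    dt = np.asarray(dt, dtype=float)
    if np.any(dt <= 0):
        raise ValueError("decision times must be strictly positive")
    y_cont1, _, y_cont2 = expected_stage_dts(p_stage1, p_stage2, params, trigger)
    sigma1 = params.stage1[3]
    ll1 = _lognorm_logpdf(dt, np.log(y_cont1), sigma1)
    if params.stage2 is None:
        out = ll1
    else:
        sigma2 = params.stage2[3]
        w1, w2 = stage_posteriors(p_stage1, p_stage2, p_sec, trigger)
        ll2 = _lognorm_logpdf(dt, np.log(y_cont2), sigma2)
        # log of w1*exp(ll1) + w2*exp(ll2); log(0) = -inf is fine here
        # because the weights sum to 1, so at most one term vanishes
        with np.errstate(divide="ignore"):
            lw1 = np.log(np.clip(w1, 0.0, 1.0))
            lw2 = np.log(np.clip(w2, 0.0, 1.0))
        out = np.logaddexp(lw1 + ll1, lw2 + ll2)
    return float(np.sum(out)) if total else out


def joint_loglik(choice_ll: float, dt_ll: float) -> float:
    """Joint choice+DT log likelihood: the sum of the two parts.

    The joint density of a continue choice and its DT factorizes into the
    Bernoulli choice term and the conditional DT mixture, so the joint log
    likelihood is exactly the sum of the separately computed parts.
    """
    return choice_ll + dt_ll


def simulate_dt(
    path: str,
    params: DTParams,
    p_stage1: float,
    p_stage2: float | None,
    trigger: str | None,
    rng: np.random.Generator,
) -> float:
    """Draw one continue-choice DT for a finalization path.

    ``path`` is "stage1" (decision finalized in the first stage) or
    "stage2" (re-decided in the second stage).
    """
    y_cont1, _, y_cont2 = expected_stage_dts(
        np.array([p_stage1]),
        None if p_stage2 is None else np.array([p_stage2]),
        params,
        trigger,
    )
    if path == "stage1":
        loc, sigma = math.log(y_cont1[0]), params.stage1[3]
    elif path == "stage2":
        if y_cont2 is None:
            raise ValueError("stage2 path needs two-stage DT parameters")
        loc, sigma = math.log(y_cont2[0]), params.stage2[3]
    else:
        raise ValueError(f"unknown path {path!r}")
    return float(np.exp(loc + sigma * rng.standard_normal()))
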