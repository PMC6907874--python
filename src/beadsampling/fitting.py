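"""Two-step maximum-likelihood fitting, per participant and model.

Step 1 fits the choice model to the stop/continue sequence; step 2 fits the
DT parameters to the continue-choice decision times with the choice-derived
stage probabilities (including the second-thought probability) frozen — DTs
never adjust choice parameters.  Optimization is bounded L-BFGS-B from a
deterministic default start plus seeded random restarts; the restart seed is
derived from (seed, participant, model name) so refits are reproducible and
independent of execution order.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from . import dtime
from .choice import (
    ChoiceData,
    WEIGHT_BOUND,
    ChoiceModelSpec,
    ONE_STAGE,
    build_choice_data,
    enumerate_registry,
    stage_probabilities,
)
from .dtime import DTParams
from .task import MAX_SAMPLES, TrialRecord

logger = logging.getLogger(__name__)

PROB_FLOOR = 1e-12


@dataclass
class FitConfig:
    """Optimizer settings shared by the choice and DT steps."""

    n_restarts: int = 10
    maxiter: int = 400
    tol: float = 1e-6
    seed: int = 0
    # distinct choice optima whose log likelihood lies within tie_tol of the
    # best restart are near-ties on the nearly flat choice surface; the
    # joint (choice+DT) likelihood selects among them, which resolves the
    # second-thought-probability ridge without letting DTs move any choice
    # parameter away from a choice optimum.  0 disables tie-breaking.
    tie_tol: float = 10.0
    max_tie_candidates: int = 4


@dataclass
class FitResult:
    """Everything fitted for one participant x model."""

    participant_id: str
    spec: ChoiceModelSpec
    choice_theta: np.ndarray
    dt_theta: np.ndarray
    choice_loglik: float
    dt_loglik: float
    k_choice: int
    k_dt: int
    n_dt: int
    converged: bool
    n_restarts_used: int
    seed: int
    flags: list[str] = field(default_factory=list)

    @property
    def joint_loglik(self) -> float:
        return dtime.joint_loglik(self.choice_loglik, self.dt_loglik)

    @property
    def k_total(self) -> int:
        return self.k_choice + self.k_dt

    @property
    def choice_params(self):
        return self.spec.unpack(self.choice_theta)

    @property
    def dt_params(self) -> DTParams:
        return DTParams.from_vector(
            self.dt_theta, two_stage=self.spec.family != ONE_STAGE
        )


def derive_seed(seed: int, participant_id: str, model_name: str) -> int:
    """Deterministic sub-seed below 2**31 from (seed, participant, model)."""
    key = f"{seed}|{participant_id}|{model_name}".encode()
    return zlib.crc32(key) & 0x7FFFFFFF


class _ChoiceWorkspace:
    """Cached design matrices so the likelihood is cheap to re-evaluate.

    The cost-DV design is fully static.  The evidence predictor splits into
    a static part and an |CI|-proportional part, so only the decayed-CI
    vector (a 20-step recursion over trials) depends on alpha; the alpha=1
    CI is cached for the no-decay models.
    """

    def __init__(self, data: ChoiceData):
        self.data = data
        jf = data.j.astype(float)
        n = data.n_choices
        self.x_cost = np.column_stack(
            [
                (data.cost_idx == 0).astype(float),
                (data.cost_idx == 1).astype(float),
                (data.cost_idx == 2).astype(float),
                jf,
                jf * data.unit_cost,
            ]
        )
        self.llr = data.llr
        # evidence design with |CI| columns (2, 3) refreshed per alpha
        self._x_evid = np.column_stack(
            [
                np.ones(n),
                data.llr,
                np.zeros(n),
                np.zeros(n),
                data.prev_correct,
                data.prev_n,
            ]
        )
        self._x_comb = np.column_stack([self.x_cost, self._x_evid[:, 1:]])
        self._ci_alpha: float | None = None
        self._absci: np.ndarray | None = None
        self._dabsci: np.ndarray | None = None
        self._slow_weights: dict[str, np.ndarray] | None = None

    def _ci_and_grad(self, alpha: float) -> tuple[np.ndarray, np.ndarray]:
        """(|CI|, d|CI|/dalpha) at every choice for the given decay rate."""
        data = self.data
        ci = np.zeros((data.n_trials, MAX_SAMPLES + 1))
        dci = np.zeros_like(ci)
        for jj in range(1, MAX_SAMPLES + 1):
            dci[:, jj] = ci[:, jj - 1] + alpha * dci[:, jj - 1]
            ci[:, jj] = alpha * ci[:, jj - 1] + data.signs[:, jj - 1]
        ci_obs = ci[data.trial_row, data.j]
        dci_obs = dci[data.trial_row, data.j]
        return np.abs(ci_obs), np.sign(ci_obs) * dci_obs

    def refresh(self, alpha: float) -> None:
        if self._ci_alpha != alpha:
            self._absci, self._dabsci = self._ci_and_grad(alpha)
            self._ci_alpha = alpha
            self._x_evid[:, 2] = self._absci
            self._x_evid[:, 3] = self.llr * self._absci
            self._x_comb[:, 6] = self._absci
            self._x_comb[:, 7] = self.llr * self._absci

    def design(self, dv_set: str) -> np.ndarray:
        """Design matrix for the current alpha (call refresh first)."""
        if dv_set == "cost":
            return self.x_cost
        if dv_set == "evidence":
            return self._x_evid
        return self._x_comb

    def dx_dalpha(self, dv_set: str, w: np.ndarray) -> np.ndarray:
        """d(linear predictor)/dalpha through the decayed-CI columns."""
        if dv_set == "cost":
            return np.zeros(self.data.n_choices)
        if dv_set == "evidence":
            coef = w[2] + w[3] * self.llr
        else:
            coef = w[6] + w[7] * self.llr
        return coef * self._dabsci

    def stage_x(self, dv_set: str, w: np.ndarray, alpha: float) -> np.ndarray:
        self.refresh(alpha)
        return self.design(dv_set) @ w

    def slow_weight_by_condition(self) -> dict[str, np.ndarray] | None:
        """Share of slow (second-stage-like) DTs per cost/evidence level.

        A two-component Gaussian mixture on the continue-choice log DTs
        assigns each DT a slow-component responsibility; averaging these
        within condition moment-matches the second-thought probability and
        serves purely as an optimizer start.
        """
        if self._slow_weights is not None:
            return self._slow_weights
        cont = self.data.stop == 0
        dts = self.data.dt[cont]
        if dts.size < 20:
            return None
        from sklearn.mixture import GaussianMixture

        X = np.log(dts).reshape(-1, 1)
        gm = GaussianMixture(n_components=2, random_state=0, n_init=1).fit(X)
        slow = int(np.argmax(gm.means_.ravel()))
        resp = gm.predict_proba(X)[:, slow]
        out = {}
        for key, idx in (
            ("cost", self.data.cost_idx[cont]),
            ("evidence", self.data.evid_idx[cont]),
        ):
            n_lvl = 3 if key == "cost" else 2
            w = np.full(n_lvl, float(resp.mean()))
            for lvl in range(n_lvl):
                sel = idx == lvl
                if sel.sum() >= 10:
                    w[lvl] = float(resp[sel].mean())
            out[key] = np.clip(w, 0.02, 0.98)
        self._slow_weights = out
        return out


def _neg_loglik_and_grad(
    theta: np.ndarray, spec: ChoiceModelSpec, ws: _ChoiceWorkspace
) -> tuple[float, np.ndarray]:
    """Negative choice log likelihood and its analytic gradient."""
    params = spec.unpack(theta)
    data = ws.data
    y = data.stop
    alpha = params.alpha
    ws.refresh(alpha)
    x1_design = ws.design(spec.stage1_dvs)
    x1 = x1_design @ params.stage1_weights
    p1 = expit(x1)
    dp1 = p1 * (1.0 - p1)

    k1 = spec.n_stage1_weights
    grad = np.zeros(spec.n_params)

    if spec.family == ONE_STAGE:
        p_stop = p1
        dp_dx1 = dp1
        dp_dx2 = None
        x2_design = None
        dp_ds = None
        s = None
    else:
        x2_design = ws.design(spec.stage2_dvs)
        x2 = x2_design @ params.stage2_weights
        p2 = expit(x2)
        dp2 = p2 * (1.0 - p2)
        st = params.second_thought
        if spec.rule == "cost_cond":
            s = st[data.cost_idx]
            ds_dx1 = 0.0
        elif spec.rule == "evidence_cond":
            s = st[data.evid_idx]
            ds_dx1 = 0.0
        else:
            s = expit(st[0] * x1 + st[1])
            ds_dx1 = st[0] * s * (1.0 - s)
        if spec.trigger == "continue":
            p_stop = p1 + (1.0 - p1) * s * p2
            dp_dx1 = dp1 * (1.0 - s * p2)
            dp_ds = (1.0 - p1) * p2
            dp_dx2 = (1.0 - p1) * s * dp2
        else:
            p_stop = p1 * (1.0 - s * (1.0 - p2))
            dp_dx1 = dp1 * (1.0 - s * (1.0 - p2))
            dp_ds = -p1 * (1.0 - p2)
            dp_dx2 = p1 * s * dp2
        if spec.rule == "flexible":
            dp_dx1 = dp_dx1 + dp_ds * ds_dx1

    p = np.clip(p_stop, PROB_FLOOR, 1.0 - PROB_FLOOR)
    nll = -float(np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))
    g = y / p - (1.0 - y) / (1.0 - p)  # dll/dp at the clipped probability

    grad[:k1] = -(x1_design.T @ (g * dp_dx1))
    dalpha = 0.0
    if spec.decay:
        dalpha += float(
            np.sum(g * dp_dx1 * ws.dx_dalpha(spec.stage1_dvs, params.stage1_weights))
        )
    if spec.family != ONE_STAGE:
        k2 = spec.n_stage2_weights
        grad[k1 : k1 + k2] = -(x2_design.T @ (g * dp_dx2))
        kr = k1 + k2
        if spec.rule == "cost_cond":
            for lvl in range(3):
                sel = data.cost_idx == lvl
                grad[kr + lvl] = -float(np.sum((g * dp_ds)[sel]))
        elif spec.rule == "evidence_cond":
            for lvl in range(2):
                sel = data.evid_idx == lvl
                grad[kr + lvl] = -float(np.sum((g * dp_ds)[sel]))
        else:
            ds = s * (1.0 - s)
            grad[kr] = -float(np.sum(g * dp_ds * ds * x1))
            grad[kr + 1] = -float(np.sum(g * dp_ds * ds))
        if spec.decay:
            dalpha += float(
                np.sum(
                    g
                    * dp_dx2
                    * ws.dx_dalpha(spec.stage2_dvs, params.stage2_weights)
                )
            )
    if spec.decay:
        grad[-1] = -dalpha
    return nll, grad


def _neg_choice_loglik(
    theta: np.ndarray, spec: ChoiceModelSpec, ws: _ChoiceWorkspace
) -> float:
    return _neg_loglik_and_grad(theta, spec, ws)[0]


def _random_start(
    spec: ChoiceModelSpec,
    rng: np.random.Generator,
    prefits: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """A random start, anchored near the one-stage prefits when available.

    Pure stage-wise prefits overestimate each stage's own hazard (each
    absorbs the other stage's stopping), so anchored starts scale the
    prefit weights down by a random factor before perturbing them.
    """
    x = spec.default_init()
    k1 = spec.n_stage1_weights
    k2 = spec.n_stage2_weights
    if prefits and spec.family != ONE_STAGE and rng.random() < 0.7:
        w1 = prefits[spec.stage1_dvs]
        w2 = prefits[spec.stage2_dvs]
        x[:k1] = w1 * rng.uniform(0.4, 1.0) + rng.normal(
            0.0, 0.2 * np.abs(w1) + 0.1
        )
        x[k1 : k1 + k2] = w2 * rng.uniform(0.4, 1.2) + rng.normal(
            0.0, 0.2 * np.abs(w2) + 0.1
        )
    else:
        x[: k1 + k2] = rng.normal(0.0, 1.0, k1 + k2)
    k = k1 + k2
    if spec.rule in ("cost_cond", "evidence_cond"):
        x[k : k + spec.n_rule_params] = rng.uniform(0.05, 0.95, spec.n_rule_params)
    elif spec.rule == "flexible":
        x[k] = rng.normal(1.0, 0.5)
        x[k + 1] = rng.normal(0.0, 1.0)
    if spec.decay:
        x[-1] = rng.uniform(0.6, 1.0)
    return x


def _structured_starts(
    spec: ChoiceModelSpec, ws: _ChoiceWorkspace, config: "FitConfig"
) -> list[np.ndarray]:
    """Informed starts for two-stage models, plus the one-stage prefits.

    The first stage dominates the stopping hazard, so its weights are
    pre-fit with a stage-1-only logistic (the nested restriction with
    p_sec = 0); the second-thought probability is then started on a coarse
    grid, which guards against the local optima that arise because a
    strong first stage can partly absorb second-stage stopping.
    """
    if spec.family == ONE_STAGE:
        return [], None, None
    from .choice import ChoiceModelSpec as _Spec

    prefits = {}
    alpha_pre = 0.95
    for dv_set in ("cost", "evidence"):
        sub = _Spec(
            f"_pre_{dv_set}",
            ONE_STAGE,
            dv_set,
            decay=dv_set == "evidence" and spec.decay,
        )
        res = minimize(
            _neg_loglik_and_grad,
            sub.default_init(),
            args=(sub, ws),
            jac=True,
            method="L-BFGS-B",
            bounds=sub.bounds(),
            options={"maxiter": config.maxiter, "ftol": config.tol},
        )
        if sub.decay:
            alpha_pre = float(res.x[-1])
            prefits[dv_set] = res.x[:-1]
        else:
            prefits[dv_set] = res.x
    w1 = prefits[spec.stage1_dvs]

    def make_start(psec_vals):
        x = spec.default_init()
        x[: spec.n_stage1_weights] = w1
        k = spec.n_stage1_weights + spec.n_stage2_weights
        if spec.rule in ("cost_cond", "evidence_cond"):
            x[k : k + spec.n_rule_params] = psec_vals
        elif spec.rule == "flexible":
            mean_p = float(np.clip(np.mean(psec_vals), 0.02, 0.98))
            x[k], x[k + 1] = 1.0, math.log(mean_p / (1.0 - mean_p))
        if spec.decay:
            x[-1] = alpha_pre
        return x

    starts = [make_start(p0) for p0 in (0.2, 0.5, 0.8)]
    slow = ws.slow_weight_by_condition()
    if slow is not None:
        key = "cost" if spec.rule != "evidence_cond" else "evidence"
        starts.append(make_start(slow[key]))
    # nested floor: with p_sec = 0 the model IS its first stage, so the
    # stage-1 prefit bounds the attainable likelihood from below; keeping
    # it as an explicit candidate guarantees a two-stage fit can never end
    # up worse than its own first-stage restriction
    floor = make_start(0.0)
    if spec.rule == "flexible":
        k = spec.n_stage1_weights + spec.n_stage2_weights
        floor[k], floor[k + 1] = 0.0, -WEIGHT_BOUND
    starts.append(floor)
    return starts, prefits, floor


def fit_choice(
    spec: ChoiceModelSpec,
    trials: Sequence[TrialRecord] | ChoiceData,
    config: FitConfig | None = None,
    participant_id: str = "",
) -> tuple[np.ndarray, float, dict]:
    """MLE of the choice parameters; returns (theta, loglik, diagnostics)."""
    config = config or FitConfig()
    data = trials if isinstance(trials, ChoiceData) else build_choice_data(trials)
    if data.n_choices == 0:
        raise ValueError("no modeled choices to fit")
    ws = _ChoiceWorkspace(data)
    bounds = spec.bounds()
    rng = np.random.default_rng(
        derive_seed(config.seed, participant_id, spec.name)
    )
    structured, prefits, floor = _structured_starts(spec, ws, config)
    starts = [spec.default_init()] + structured
    n_random = max(config.n_restarts - len(starts), 0)
    starts += [_random_start(spec, rng, prefits) for _ in range(n_random)]
    solutions = []
    failures = []
    for x0 in starts:
        try:
            res = minimize(
                _neg_loglik_and_grad,
                x0,
                args=(spec, ws),
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": config.maxiter, "ftol": config.tol},
            )
        except Exception as exc:  # pragma: no cover - optimizer edge cases
            failures.append(str(exc))
            continue
        solutions.append(res)
    if not solutions:
        raise RuntimeError(
            f"all {len(starts)} restarts failed for {spec.name}: {failures}"
        )
    if floor is not None:
        from types import SimpleNamespace

        f_floor, _ = _neg_loglik_and_grad(floor, spec, ws)
        solutions.append(
            SimpleNamespace(fun=f_floor, x=floor, success=True)
        )
    solutions.sort(key=lambda r: r.fun)
    best = solutions[0]
    at_bound = any(
        np.isclose(v, lo) or np.isclose(v, hi)
        for v, (lo, hi) in zip(best.x, bounds)
    )
    # distinct near-optimal solutions (for joint tie-breaking downstream)
    candidates = []
    seen = set()
    for res in solutions:
        if res.fun > best.fun + config.tie_tol:
            break
        key = tuple(np.round(res.x, 2))
        if key in seen:
            continue
        seen.add(key)
        candidates.append((np.asarray(res.x), -float(res.fun)))
        if len(candidates) >= config.max_tie_candidates:
            break
    diag = {
        "converged": bool(best.success),
        "n_restarts_used": len(starts),
        "at_bound": at_bound,
        "n_failures": len(failures),
        "candidates": candidates,
    }
    return np.asarray(best.x), -float(best.fun), diag


_DT_B0_BOUNDS = (1e-6, 10.0)
_DT_B_BOUNDS = (-50.0, 50.0)
_DT_SIGMA_BOUNDS = (1e-3, 10.0)


def _neg_dt_loglik(
    theta: np.ndarray,
    two_stage: bool,
    dt: np.ndarray,
    p1: np.ndarray,
    p2: np.ndarray | None,
    psec: np.ndarray | None,
    trigger: str | None,
) -> float:
    params = DTParams.from_vector(theta, two_stage=two_stage)
    return -dtime.dt_loglik(dt, params, p1, p2, psec, trigger)


def fit_dt(
    spec: ChoiceModelSpec,
    choice_theta: np.ndarray,
    data: ChoiceData,
    config: FitConfig | None = None,
    dt_mask: np.ndarray | None = None,
    participant_id: str = "",
) -> tuple[np.ndarray, float, int, dict]:
    """MLE of DT parameters with choice-derived stage quantities frozen.

    ``dt_mask`` (aligned with the continue-choice observations, in data
    order) marks DTs retained after outlier exclusion; by default all
    continue DTs are modeled.  Returns (theta, loglik, n_dt, diagnostics).
    """
    config = config or FitConfig()
    _, p1, p2, psec = stage_probabilities(spec, choice_theta, data)
    cont = data.stop == 0
    dt = data.dt[cont]
    p1 = p1[cont]
    p2 = p2[cont] if p2 is not None else None
    psec = psec[cont] if psec is not None else None
    if dt_mask is not None:
        dt_mask = np.asarray(dt_mask, dtype=bool)
        if dt_mask.size != dt.size:
            raise ValueError(
                f"dt_mask length {dt_mask.size} != continue-DT count {dt.size}"
            )
        dt = dt[dt_mask]
        p1 = p1[dt_mask]
        p2 = p2[dt_mask] if p2 is not None else None
        psec = psec[dt_mask] if psec is not None else None
    if dt.size == 0:
        raise ValueError("no modeled DTs to fit")
    two_stage = spec.family != ONE_STAGE

    flags = []
    if two_stage and psec is not None and np.all(psec < 1e-6):
        flags.append("stage2_unidentifiable")

    logdt = np.log(dt)
    m, s = float(np.mean(logdt)), float(np.std(logdt))
    b0_init = max(m, 0.1)
    base = [b0_init, m - b0_init, 0.0, max(s, 0.1)]
    x0 = np.array(base * 2 if two_stage else base)
    extra_starts = []
    if two_stage and dt.size >= 30:
        # moment-match the two lognormal components to a 2-component GMM of
        # the log DTs: the slow component's extra time is the difference of
        # the component medians
        from sklearn.mixture import GaussianMixture

        gm = GaussianMixture(n_components=2, random_state=0, n_init=1).fit(
            logdt.reshape(-1, 1)
        )
        order = np.argsort(gm.means_.ravel())
        m1, m2 = gm.means_.ravel()[order]
        s1, s2 = np.sqrt(gm.covariances_.ravel()[order])
        gap = max(math.exp(m2) - math.exp(m1), 0.05)
        extra_starts.append(
            np.array(
                [0.1, m1 - 0.1, 0.0, max(s1, 0.05),
                 max(math.log(gap), 1e-3) if math.log(gap) > 0 else 0.1,
                 min(math.log(gap) - 0.1, 0.0), 0.0, max(s2, 0.05)]
            )
        )
    lo_hi = [_DT_B0_BOUNDS, _DT_B_BOUNDS, _DT_B_BOUNDS, _DT_SIGMA_BOUNDS]
    bounds = lo_hi * 2 if two_stage else lo_hi
    rng = np.random.default_rng(
        derive_seed(config.seed, participant_id, spec.name + "|dt")
    )
    # the DT surface is much better behaved than the choice surface, so a
    # data-informed start plus a couple of perturbations suffices
    n_dt_restarts = min(3, max(config.n_restarts, 1))
    starts = [x0] + extra_starts
    for _ in range(n_dt_restarts - 1):
        pert = x0 + rng.normal(0.0, 0.5, x0.size)
        starts.append(
            np.clip(pert, [b[0] for b in bounds], [b[1] for b in bounds])
        )
    best = None
    for start in starts:
        try:
            res = minimize(
                _neg_dt_loglik,
                start,
                args=(two_stage, dt, p1, p2, psec, spec.trigger),
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": config.maxiter, "ftol": config.tol},
            )
        except Exception:  # pragma: no cover
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(f"all DT restarts failed for {spec.name}")
    diag = {
        "converged": bool(best.success),
        "n_restarts_used": len(starts),
        "flags": flags,
    }
    return np.asarray(best.x), -float(best.fun), int(dt.size), diag


def fit_model(
    spec: ChoiceModelSpec,
    trials: Sequence[TrialRecord] | ChoiceData,
    config: FitConfig | None = None,
    dt_mask: np.ndarray | None = None,
    participant_id: str = "",
) -> FitResult:
    """Two-step fit of one model to one participant's data."""
    config = config or FitConfig()
    data = trials if isinstance(trials, ChoiceData) else build_choice_data(trials)
    theta_c, ll_c, diag_c = fit_choice(spec, data, config, participant_id)
    candidates = diag_c.get("candidates") or [(theta_c, ll_c)]
    best = None
    for cand_theta, cand_ll in candidates:
        cand_dt = fit_dt(spec, cand_theta, data, config, dt_mask, participant_id)
        joint = cand_ll + cand_dt[1]
        if best is None or joint > best[0]:
            best = (joint, cand_theta, cand_ll, cand_dt)
    _, theta_c, ll_c, (theta_d, ll_d, n_dt, diag_d) = best
    return FitResult(
        participant_id=participant_id,
        spec=spec,
        choice_theta=theta_c,
        dt_theta=theta_d,
        choice_loglik=ll_c,
        dt_loglik=ll_d,
        k_choice=spec.n_params,
        k_dt=theta_d.size,
        n_dt=n_dt,
        converged=diag_c["converged"] and diag_d["converged"],
        n_restarts_used=diag_c["n_restarts_used"],
        seed=config.seed,
        flags=list(diag_d["flags"]) + (["at_bound"] if diag_c["at_bound"] else []),
    )


def fit_participant(
    trials: Sequence[TrialRecord],
    registry: Sequence[ChoiceModelSpec] | None = None,
    config: FitConfig | None = None,
    dt_mask: np.ndarray | None = None,
    participant_id: str = "",
) -> list[FitResult]:
    """Fit every registry model to one participant; failures are recorded."""
    registry = registry if registry is not None else enumerate_registry()
    data = build_choice_data(trials)
    results = []
    for spec in registry:
        try:
            results.append(
                fit_model(spec, data, config, dt_mask, participant_id)
            )
        except Exception as exc:
            logger.error(
                "fit failed for participant %s model %s: %s",
                participant_id,
                spec.name,
                exc,
            )
    return results


def fit_all(
    participants: Mapping[str, Sequence[TrialRecord]],
    registry: Sequence[ChoiceModelSpec] | None = None,
    config: FitConfig | None = None,
    dt_masks: Mapping[str, np.ndarray] | None = None,
    n_jobs: int = 1,
) -> list[FitResult]:
    """Fit the registry to every participant.

    Results are keyed by (participant, model) and do not depend on
    execution order; ``n_jobs > 1`` parallelizes over participants.
    """
    registry = registry if registry is not None else enumerate_registry()
    items = sorted(participants.items())
    masks = dt_masks or {}

    def one(pid, trials):
        return fit_participant(
            trials, registry, config, masks.get(pid), participant_id=pid
        )

    if n_jobs != 1:
        from joblib import Parallel, delayed

        chunks = Parallel(n_jobs=n_jobs)(
            delayed(one)(pid, trials) for pid, trials in items
        )
    else:
        chunks = [one(pid, trials) for pid, trials in items]
    return [r for chunk in chunks for r in chunk]


def results_table(results: Sequence[FitResult]):
    """FitResults as a tidy DataFrame, one row per participant x model."""
    import pandas as pd

    rows = []
    for r in results:
        row = {
            "participant": r.participant_id,
            "model": r.spec.name,
            "choice_loglik": r.choice_loglik,
            "dt_loglik": r.dt_loglik,
            "joint_loglik": r.joint_loglik,
            "k_choice": r.k_choice,
            "k_dt": r.k_dt,
            "n_dt": r.n_dt,
            "converged": r.converged,
            "seed": r.seed,
            "flags": ";".join(r.flags),
        }
        for name, val in zip(r.spec.param_names(), r.choice_theta):
            row[f"choice.{name}"] = val
        dt_names = ["b0_1", "b1_1", "b2_1", "sigma_1"]
        if r.k_dt == 8:
            dt_names += ["b0_2", "b1_2", "b2_2", "sigma_2"]
        for name, val in zip(dt_names, r.dt_theta):
            row[f"dt.{name}"] = val
        rows.append(row)
    return pd.DataFrame(rows)
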