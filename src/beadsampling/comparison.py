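"""Model comparison: information criteria, fixed-effects summaries,
random-effects group Bayesian model selection, and strategy indices.

AICc uses the number of modeled DTs as the sample size.  Group-level BMS
treats models as random effects across participants: a variational
Dirichlet posterior over model frequencies is iterated to convergence, the
exceedance probability (EP) of each model is estimated by Dirichlet Monte
Carlo, and the protected exceedance probability (pEP) discounts the EP by
the Bayesian omnibus risk (BOR) that all models are equally frequent:
``pEP = EP * (1 - BOR) + BOR / K``.  Per-participant log model evidence is
approximated as ``-AICc / 2``.

The cost-evidence strategy index summarizes where a participant sits on the
cost-first vs. evidence-first dimension of the two-stage model space: mean
AICc of the 6 cost-first models minus mean AICc of the 6 evidence-first
models, so negative values indicate a cost-first preference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import digamma, gammaln, logsumexp

from .fitting import FitResult


def information_criteria(
    loglik: float, k: int, n: int
) -> tuple[float, float, float]:
    """(AIC, AICc, BIC) for a fitted model.

    AICc adds the small-sample correction ``2k(k+1)/(n-k-1)`` and requires
    ``n > k + 1``.
    """
    if k < 0 or n <= 0:
        raise ValueError("need k >= 0 and n > 0")
    aic = 2.0 * k - 2.0 * loglik
    if n <= k + 1:
        raise ValueError(
            f"AICc undefined for n={n} <= k+1={k + 1} (too few observations)"
        )
    aicc = aic + 2.0 * k * (k + 1.0) / (n - k - 1.0)
    bic = k * math.log(n) - 2.0 * loglik
    return aic, aicc, bic


@dataclass
class EvidenceTable:
    """Participants x models information criteria and log evidence."""

    participants: list[str]
    models: list[str]
    aicc: np.ndarray  # (n_participants, n_models)
    bic: np.ndarray

    @property
    def delta_aicc(self) -> np.ndarray:
        """AICc relative to each participant's best (lowest-AICc) model."""
        return self.aicc - self.aicc.min(axis=1, keepdims=True)

    @property
    def delta_bic(self) -> np.ndarray:
        return self.bic - self.bic.min(axis=1, keepdims=True)

    @property
    def log_evidence(self) -> np.ndarray:
        """Approximate log model evidence, -AICc/2."""
        return -0.5 * self.aicc

    def summed_delta_aicc(self) -> np.ndarray:
        return self.delta_aicc.sum(axis=0)

    def best_counts(self) -> np.ndarray:
        """How many participants each model fits best (by AICc)."""
        best = np.argmin(self.aicc, axis=1)
        return np.bincount(best, minlength=len(self.models))


def build_evidence_table(results: Sequence[FitResult]) -> EvidenceTable:
    """Assemble the participants x models AICc/BIC matrix from fits."""
    participants = sorted({r.participant_id for r in results})
    models = []
    for r in results:
        if r.spec.name not in models:
            models.append(r.spec.name)
    aicc = np.full((len(participants), len(models)), np.nan)
    bic = np.full_like(aicc, np.nan)
    p_idx = {p: i for i, p in enumerate(participants)}
    m_idx = {m: i for i, m in enumerate(models)}
    for r in results:
        _, a, b = information_criteria(r.joint_loglik, r.k_total, r.n_dt)
        aicc[p_idx[r.participant_id], m_idx[r.spec.name]] = a
        bic[p_idx[r.participant_id], m_idx[r.spec.name]] = b
    if np.isnan(aicc).any():
        raise ValueError("missing participant x model fits in evidence table")
    return EvidenceTable(participants, models, aicc, bic)


@dataclass
class BMSResult:
    """Random-effects group BMS output."""

    dirichlet_alpha: np.ndarray
    model_frequencies: np.ndarray  # expected frequency, sums to 1
    exceedance: np.ndarray  # sums to 1
    protected_exceedance: np.ndarray  # sums to 1
    bor: float  # P(frequencies are uniform | data)


def _vb_dirichlet(
    lme: np.ndarray, alpha0: float, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray]:
    n, k = lme.shape
    alpha = np.full(k, alpha0)
    for _ in range(max_iter):
        log_u = lme + (digamma(alpha) - digamma(alpha.sum()))
        log_u -= logsumexp(log_u, axis=1, keepdims=True)
        u = np.exp(log_u)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    return alpha, u


def _free_energy(
    lme: np.ndarray, alpha: np.ndarray, u: np.ndarray, alpha0: float
) -> float:
    """Variational free energy (ELBO) of the random-effects model."""
    k = alpha.size
    e_log_r = digamma(alpha) - digamma(alpha.sum())
    f = float(np.sum(u * lme))
    f += float(np.sum(u * e_log_r))
    with np.errstate(divide="ignore", invalid="ignore"):
        ulogu = np.where(u > 0, u * np.log(u), 0.0)
    f -= float(np.sum(ulogu))
    # KL(q(r) || prior) with symmetric Dirichlet(alpha0) prior
    f += float(
        gammaln(k * alpha0)
        - k * gammaln(alpha0)
        + np.sum((alpha0 - 1.0) * e_log_r)
    )
    f -= float(
        gammaln(alpha.sum())
        - np.sum(gammaln(alpha))
        + np.sum((alpha - 1.0) * e_log_r)
    )
    return f


def group_bms(
    evidence: EvidenceTable | np.ndarray,
    rng: np.random.Generator | int | None = None,
    n_samples: int = 1_000_000,
    alpha0: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> BMSResult:
    """Random-effects Bayesian model selection over the group.

    ``evidence`` is an EvidenceTable (log evidence = -AICc/2) or a raw
    (participants x models) log-evidence matrix.  Exceedance probabilities
    are estimated by Monte Carlo over the Dirichlet posterior; the BOR
    compares the free energy of the random-effects model against the null
    of uniform frequencies.
    """
    lme = (
        evidence.log_evidence
        if isinstance(evidence, EvidenceTable)
        else np.asarray(evidence, dtype=float)
    )
    if lme.ndim != 2 or lme.shape[0] < 2 or lme.shape[1] < 2:
        raise ValueError("need at least 2 participants and 2 models")
    if not np.all(np.isfinite(lme)):
        raise ValueError("log evidences must be finite")
    rng = np.random.default_rng(rng)
    n, k = lme.shape
    # center rows for numerical comfort; BMS is invariant to row constants
    lme = lme - lme.max(axis=1, keepdims=True)

    alpha, u = _vb_dirichlet(lme, alpha0, tol, max_iter)
    freq = alpha / alpha.sum()

    draws = rng.dirichlet(alpha, size=n_samples)
    winners = np.argmax(draws, axis=1)
    ep = np.bincount(winners, minlength=k) / n_samples

    f1 = _free_energy(lme, alpha, u, alpha0)
    f0 = float(np.sum(logsumexp(lme, axis=1) - math.log(k)))
    bor = float(1.0 / (1.0 + math.exp(min(max(f1 - f0, -700.0), 700.0))))
    pep = ep * (1.0 - bor) + bor / k
    return BMSResult(
        dirichlet_alpha=alpha,
        model_frequencies=freq,
        exceedance=ep,
        protected_exceedance=pep,
        bor=bor,
    )


# ---------------------------------------------------------------------------
# strategy indices over the two-stage model space
# ---------------------------------------------------------------------------

_DIMENSIONS = {
    "order": ("Cost->", "Evidence->"),
    "trigger": (",continue,", ",stop,"),
    "rule": ("C-cond", "E-cond"),  # flexible models belong to neither family
}


def _family_mean_aicc(
    aicc_by_model: Mapping[str, float], marker: str
) -> float:
    vals = [
        a
        for name, a in aicc_by_model.items()
        if marker in name and "->" in name
    ]
    if not vals:
        raise ValueError(f"no two-stage fits matching {marker!r}")
    return float(np.mean(vals))


def strategy_index(
    results: Sequence[FitResult], dimension: str = "order"
) -> float:
    """Mean-AICc family difference for one participant.

    ``dimension="order"`` (the cost-evidence strategy index) contrasts the
    6 cost-first against the 6 evidence-first two-stage models; negative
    values indicate a cost-first preference.  "trigger" and "rule" expose
    the analogous contrasts on the other two model dimensions.
    """
    if dimension not in _DIMENSIONS:
        raise ValueError(f"unknown dimension {dimension!r}")
    two_stage = [r for r in results if r.spec.family == "two_stage"]
    if dimension == "order" and len(two_stage) != 12:
        raise ValueError(
            f"strategy index needs all 12 two-stage fits, got {len(two_stage)}"
        )
    aicc = {}
    for r in two_stage:
        _, a, _ = information_criteria(r.joint_loglik, r.k_total, r.n_dt)
        aicc[r.spec.name] = a
    m_a, m_b = _DIMENSIONS[dimension]
    return _family_mean_aicc(aicc, m_a) - _family_mean_aicc(aicc, m_b)


def strategy_indices(
    results: Sequence[FitResult], dimension: str = "order"
) -> dict[str, float]:
    """Per-participant strategy indices from a pooled list of fits."""
    by_pid: dict[str, list[FitResult]] = {}
    for r in results:
        by_pid.setdefault(r.participant_id, []).append(r)
    return {
        pid: strategy_index(fits, dimension)
        for pid, fits in sorted(by_pid.items())
    }
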