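"""Descriptive and inferential statistics for sampling behavior and DTs.

Covers the DT preprocessing chain (log-transform, pooled boxplot-rule
outlier exclusion), the log-DT Gaussian-mixture and dip-based bimodality
analyses, Spearman correlations with Benjamini-Hochberg FDR, and the
cluster-based permutation test on running correlation curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps
from sklearn.mixture import GaussianMixture

from .dip import dip_pvalue

__all__ = [
    "DTPool",
    "preprocess_dts",
    "MixtureFit",
    "fit_logdt_mixture",
    "dip_test",
    "spearman_fdr",
    "CorrelationCurve",
    "cluster_permutation_curve",
]


@dataclass
class DTPool:
    """Log-transformed continue DTs with an outlier inclusion mask.

    Fences are the boxplot rule on the pooled log DTs: points outside
    [Q1 - 1.5*IQR, Q3 + 1.5*IQR] are excluded.  The raw data are kept
    untouched; ``mask`` marks retained points.
    """

    log_dts: np.ndarray
    mask: np.ndarray
    fences: tuple[float, float]
    participant: np.ndarray | None = None
    condition: np.ndarray | None = None

    @property
    def included(self) -> np.ndarray:
        return self.log_dts[self.mask]

    @property
    def n_excluded(self) -> int:
        return int((~self.mask).sum())


def _boxplot_mask(x: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    q1, q3 = np.quantile(x, [0.25, 0.75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return (x >= lo) & (x <= hi), (float(lo), float(hi))


def preprocess_dts(
    dts: Sequence[float],
    participant: Sequence | None = None,
    condition: Sequence | None = None,
    per_participant: bool = False,
) -> DTPool:
    """Log-transform continue DTs and apply boxplot-rule outlier exclusion.

    By default fences are computed on the pooled (all-participant) log-DT
    distribution; ``per_participant=True`` computes fences within each
    participant instead.
    """
    dts = np.asarray(dts, dtype=float)
    if dts.size == 0:
        raise ValueError("no decision times to preprocess")
    if np.any(dts <= 0):
        raise ValueError("decision times must be strictly positive")
    log_dts = np.log(dts)
    pid = None if participant is None else np.asarray(participant)
    cond = None if condition is None else np.asarray(condition)
    if per_participant:
        if pid is None:
            raise ValueError("per_participant exclusion needs participant labels")
        mask = np.zeros(log_dts.size, dtype=bool)
        for p in np.unique(pid):
            sel = pid == p
            m, _ = _boxplot_mask(log_dts[sel])
            mask[sel] = m
        fences = (float("nan"), float("nan"))
    else:
        mask, fences = _boxplot_mask(log_dts)
    return DTPool(log_dts, mask, fences, pid, cond)


@dataclass
class MixtureFit:
    """Gaussian-mixture fit of the log-DT distribution."""

    weights: np.ndarray  # ordered by component mean
    means: np.ndarray
    sds: np.ndarray
    bic_1: float
    bic_2: float

    @property
    def prefers_two_components(self) -> bool:
        return self.bic_2 < self.bic_1


def fit_logdt_mixture(
    pool: DTPool | np.ndarray,
    n_components: int = 2,
    rng: int | np.random.Generator | None = None,
    n_init: int = 3,
) -> MixtureFit:
    """EM fit of a Gaussian mixture to included log DTs.

    Components are reported in ascending order of mean; the one-component
    BIC is reported alongside for a bimodality comparison.
    """
    x = pool.included if isinstance(pool, DTPool) else np.asarray(pool, float)
    if x.size < 10:
        raise ValueError("mixture fit needs at least 10 points")
    seed = (
        rng
        if isinstance(rng, (int, type(None)))
        else int(rng.integers(2**31 - 1))
    )
    X = x.reshape(-1, 1)
    gm = GaussianMixture(
        n_components=n_components,
        n_init=n_init,
        random_state=seed,
        reg_covar=1e-6,
    ).fit(X)
    gm1 = GaussianMixture(n_components=1, random_state=seed).fit(X)
    order = np.argsort(gm.means_.ravel())
    return MixtureFit(
        weights=gm.weights_[order],
        means=gm.means_.ravel()[order],
        sds=np.sqrt(gm.covariances_.ravel()[order]),
        bic_1=float(gm1.bic(X)),
        bic_2=float(gm.bic(X)),
    )


def dip_test(
    pool: DTPool | np.ndarray,
    n_boot: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Hartigan's dip statistic with a bootstrap p under the uniform null."""
    x = pool.included if isinstance(pool, DTPool) else np.asarray(pool, float)
    return dip_pvalue(x, n_boot=n_boot, rng=rng)


def spearman_fdr(
    pairs: Sequence[tuple[Sequence[float], Sequence[float]]],
    alpha: float = 0.05,
) -> list[tuple[float, float, float]]:
    """Spearman rho for each (x, y) pair with BH-FDR adjusted p values.

    Returns [(rho, p_raw, p_fdr), ...]; the comparison family is the list
    itself.  Constant inputs make rho undefined and raise.
    """
    rhos, ps = [], []
    for k, (x, y) in enumerate(pairs):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        if x.size != y.size or x.size < 3:
            raise ValueError(f"pair {k}: need equal-length vectors of size >= 3")
        if np.all(x == x[0]) or np.all(y == y[0]):
            raise ValueError(f"pair {k}: constant vector, rho undefined")
        r = sps.spearmanr(x, y)
        rhos.append(float(r.statistic))
        ps.append(float(r.pvalue))
    p_fdr = sps.false_discovery_control(ps, method="bh")
    return [(r, p, float(pf)) for r, p, pf in zip(rhos, ps, p_fdr)]


# ---------------------------------------------------------------------------
# cluster-based permutation test on running correlation curves
# ---------------------------------------------------------------------------


@dataclass
class Cluster:
    start: int  # inclusion count at which the cluster starts
    end: int  # inclusive
    sign: int
    size: float  # |sum of Fisher z| over the cluster
    p_value: float = field(default=np.nan)


@dataclass
class CorrelationCurve:
    """Running Spearman correlation over ascending-index inclusion."""

    ks: np.ndarray  # inclusion counts
    rho: np.ndarray
    significant: np.ndarray
    clusters: list[Cluster]
    reference: str
    rho_overall: float
    n_perm: int


def _running_spearman(x_sorted: np.ndarray, y_cols: np.ndarray, ks: np.ndarray):
    """Spearman rho between x_sorted[:k] and each column's first k values.

    ``y_cols`` is (n, n_curves); returns (len(ks), n_curves).
    """
    out = np.empty((ks.size, y_cols.shape[1]))
    for i, k in enumerate(ks):
        rx = sps.rankdata(x_sorted[:k])
        ry = sps.rankdata(y_cols[:k], axis=0)
        rx = rx - rx.mean()
        ry = ry - ry.mean(axis=0)
        denom = np.sqrt((rx**2).sum() * (ry**2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            out[i] = (rx @ ry) / denom
    return out


def _pointwise_t_sig(rho: np.ndarray, ks: np.ndarray, alpha: float):
    df = np.asarray(ks - 2, dtype=float)
    if rho.ndim == 2:
        df = df[:, None]
    rho_c = np.clip(rho, -0.999999, 0.999999)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = rho_c * np.sqrt(df / (1.0 - rho_c**2))
    p = 2.0 * sps.t.sf(np.abs(tstat), df)
    return p < alpha


def _find_clusters(
    rho: np.ndarray, sig: np.ndarray, ks: np.ndarray, ref: float = 0.0
) -> list[Cluster]:
    clusters: list[Cluster] = []
    z = np.arctanh(np.clip(rho, -0.999999, 0.999999)) - (
        np.arctanh(ref) if ref else 0.0
    )
    signs = np.sign(z)
    i = 0
    n = rho.size
    while i < n:
        if sig[i] and signs[i] != 0:
            j = i
            while j + 1 < n and sig[j + 1] and signs[j + 1] == signs[i]:
                j += 1
            clusters.append(
                Cluster(
                    start=int(ks[i]),
                    end=int(ks[j]),
                    sign=int(signs[i]),
                    size=float(abs(z[i : j + 1].sum())),
                )
            )
            i = j + 1
        else:
            i += 1
    return clusters


def _max_cluster_sizes(
    rho_cols: np.ndarray, sig_cols: np.ndarray, ks: np.ndarray, ref: float = 0.0
) -> np.ndarray:
    """Maximum cluster size of each column's curve (0 if no cluster)."""
    out = np.zeros(rho_cols.shape[1])
    for c in range(rho_cols.shape[1]):
        cl = _find_clusters(rho_cols[:, c], sig_cols[:, c], ks, ref)
        if cl:
            out[c] = max(cc.size for cc in cl)
    return out


def cluster_permutation_curve(
    index: Sequence[float],
    aq: Sequence[float],
    n_perm: int = 10_000,
    rng: np.random.Generator | int | None = None,
    reference: str = "zero",
    min_include: int = 10,
    alpha: float = 0.05,
) -> CorrelationCurve:
    """Cluster-based permutation test on a running correlation curve.

    Participants are ranked ascending by ``index``; the Spearman
    correlation between index and ``aq`` is computed over the first k
    participants for k = min_include..n.  Points significant at the
    uncorrected ``alpha`` (t test against zero, or Monte-Carlo bands
    against the overall correlation under inclusion-order shuffling for
    ``reference="overall"``) are grouped into contiguous same-signed
    clusters sized by the absolute summed Fisher z.  Cluster p values come
    from the permutation distribution of the maximum cluster size
    (shuffling the index-AQ pairing for ``reference="zero"``, the
    inclusion order for ``reference="overall"``).
    """
    if n_perm < 100:
        raise ValueError("n_perm < 100 gives an unstable permutation null")
    index = np.asarray(index, dtype=float)
    aq = np.asarray(aq, dtype=float)
    if index.size != aq.size or index.size < max(min_include, 10):
        raise ValueError("need >= 10 participants with matching vectors")
    rng = np.random.default_rng(rng)
    n = index.size
    order = np.argsort(index, kind="stable")
    x = index[order]
    y = aq[order]
    ks = np.arange(min_include, n + 1)

    rho_overall = float(sps.spearmanr(index, aq).statistic)
    rho_obs = _running_spearman(x, y[:, None], ks)[:, 0]

    if reference == "zero":
        sig_obs = _pointwise_t_sig(rho_obs[:, None], ks, alpha)[:, 0]
        clusters = _find_clusters(rho_obs, sig_obs, ks, ref=0.0)
        if clusters:
            # null: re-pair index and AQ, re-rank, recompute the curve
            perm_y = np.empty((n, n_perm))
            for b in range(n_perm):
                perm_index = rng.permutation(index)
                perm_order = np.argsort(perm_index, kind="stable")
                perm_y[:, b] = aq[perm_order]
                # x values are the same sorted index values by construction
            rho_null = _running_spearman(x, perm_y, ks)
            sig_null = _pointwise_t_sig(rho_null, ks, alpha)
            null_max = _max_cluster_sizes(rho_null, sig_null, ks, ref=0.0)
            for cl in clusters:
                cl.p_value = float(
                    (1.0 + np.sum(null_max >= cl.size)) / (n_perm + 1.0)
                )
    elif reference == "overall":
        # Monte-Carlo pointwise bands from inclusion-order shuffling
        rho_null = np.empty((ks.size, n_perm))
        for b in range(n_perm):
            p = rng.permutation(n)
            rho_null[:, b] = _running_spearman(x[p], y[p][:, None], ks)[:, 0]
        lo = np.quantile(rho_null, alpha / 2.0, axis=1)
        hi = np.quantile(rho_null, 1.0 - alpha / 2.0, axis=1)
        sig_obs = (rho_obs < lo) | (rho_obs > hi)
        clusters = _find_clusters(rho_obs, sig_obs, ks, ref=rho_overall)
        if clusters:
            sig_null = (rho_null < lo[:, None]) | (rho_null > hi[:, None])
            null_max = _max_cluster_sizes(rho_null, sig_null, ks, ref=rho_overall)
            for cl in clusters:
                cl.p_value = float(
                    (1.0 + np.sum(null_max >= cl.size)) / (n_perm + 1.0)
                )
    else:
        raise ValueError(f"unknown reference {reference!r}")

    return CorrelationCurve(
        ks=ks,
        rho=rho_obs,
        significant=sig_obs,
        clusters=clusters,
        reference=reference,
        rho_overall=rho_overall,
        n_perm=n_perm,
    )
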