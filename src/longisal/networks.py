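"""Genotype- and period-specific conditional-dependence networks for
zero-inflated compositional data.

The estimator is a compact re-implementation of the SPRING idea:

1. modified CLR (``mclr``): CLR of the nonzero relative abundances, shifted
   positive, exact zeros preserved;
2. semiparametric latent correlation: Kendall's tau-a between observed
   vectors mapped to the latent Pearson correlation of a truncated Gaussian
   copula via the bridge function (closed-form arcsine when neither margin
   has zeros, numerically inverted 4-D normal-CDF bridge otherwise);
3. sparse conditional-dependence graph by nodewise L1 neighborhood
   selection on the (PSD-projected) latent correlation matrix, OR-rule;
4. StARS subsampling to pick the regularization: the least regularization
   whose monotonized edge-selection instability stays below beta.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

DEFAULT_PERIODS = ((0, 4), (8, 12), (16, 22))


# ---------------------------------------------------------------------------
# modified CLR
# ---------------------------------------------------------------------------


def mclr_transform(counts_row, eps: float = 1.0) -> np.ndarray:
    """Modified CLR: log nonzero relative abundances centered by their mean,
    shifted so the smallest transformed nonzero value equals ``eps`` > 0;
    zeros stay exactly zero."""
    row = np.asarray(counts_row, dtype=float)
    total = row.sum()
    if total <= 0:
        raise ValueError("all-zero row has no mclr transform")
    out = np.zeros_like(row)
    nz = row > 0
    logs = np.log(row[nz] / total)
    vals = logs - logs.mean()
    out[nz] = vals - vals.min() + eps
    return out


def mclr_matrix(counts: np.ndarray, eps: float = 1.0) -> np.ndarray:
    return np.vstack([mclr_transform(r, eps) for r in np.asarray(counts, dtype=float)])


# ---------------------------------------------------------------------------
# Kendall tau-a and the truncated-copula bridge
# ---------------------------------------------------------------------------


def kendall_tau_a(x, y) -> float:
    """Kendall's tau-a (ties count in the denominator n(n-1)/2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need n >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: Kendall tau undefined")
    n0 = n * (n - 1) / 2.0

    def tie_term(v):
        _, counts = np.unique(v, return_counts=True)
        return float((counts * (counts - 1) / 2.0).sum())

    t1, t2 = tie_term(x), tie_term(y)
    tau_b = stats.kendalltau(x, y).statistic
    c_minus_d = tau_b * np.sqrt((n0 - t1) * (n0 - t2))
    return float(c_minus_d / n0)


def _phi2(h, k, rho: float):
    """Vectorized standard bivariate normal CDF P(X<=h, Y<=k) via Owen's T."""
    from scipy.special import owens_t

    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    r = float(np.clip(rho, -0.99999, 0.99999))
    # avoid the h=0 / k=0 singularities of the Owen's-T decomposition
    hs = np.where(h == 0.0, 1e-12, h)
    ks = np.where(k == 0.0, 1e-12, k)
    denom = np.sqrt(1.0 - r * r)
    ah = (ks / hs - r) / denom
    ak = (hs / ks - r) / denom
    beta = np.where(hs * ks < 0, 0.5, 0.0)
    out = (
        0.5 * (stats.norm.cdf(hs) + stats.norm.cdf(ks))
        - owens_t(hs, ah)
        - owens_t(ks, ak)
        - beta
    )
    return np.clip(out, 0.0, 1.0)


_GL_NODES = 32


@lru_cache(maxsize=1)
def _gl_rule(n: int = _GL_NODES):
    x, w = np.polynomial.legendre.leggauss(n)
    return (x + 1.0) / 2.0, w / 2.0  # on (0, 1)


# Acklam's rational approximation to the standard normal quantile
# (|relative error| < 1.15e-9); vectorized, much faster than norm.ppf on
# the large inner quadrature grids.
_ACK_A = (-3.969683028665376e01, 2.209460984245205e02, -2.759285104469687e02,
          1.383577518672690e02, -3.066479806614716e01, 2.506628277459239e00)
_ACK_B = (-5.447609879822406e01, 1.615858368580409e02, -1.556989798598866e02,
          6.680131188771972e01, -1.328068155288572e01)
_ACK_C = (-7.784894002430293e-03, -3.223964580411365e-01, -2.400758277161838e00,
          -2.549732539343734e00, 4.374664141464968e00, 2.938163982698783e00)
_ACK_D = (7.784695709041462e-03, 3.224671290700398e-01, 2.445134137142996e00,
          3.754408661907416e00)


def _fast_norm_ppf(p):
    p = np.clip(np.asarray(p, dtype=float), 1e-300, 1.0 - 1e-16)
    out = np.empty_like(p)
    plow, phigh = 0.02425, 1.0 - 0.02425
    a, b, c, d = _ACK_A, _ACK_B, _ACK_C, _ACK_D

    lo = p < plow
    hi = p > phigh
    mid = ~(lo | hi)
    if mid.any():
        q = p[mid] - 0.5
        r = q * q
        num = ((((a[0] * r + a[1]) * r + a[2]) * r + a[3]) * r + a[4]) * r + a[5]
        den = (((((b[0] * r + b[1]) * r + b[2]) * r + b[3]) * r + b[4]) * r) + 1.0
        out[mid] = num * q / den
    if lo.any():
        q = np.sqrt(-2.0 * np.log(p[lo]))
        num = ((((c[0] * q + c[1]) * q + c[2]) * q + c[3]) * q + c[4]) * q + c[5]
        den = ((((d[0] * q + d[1]) * q + d[2]) * q + d[3]) * q) + 1.0
        out[lo] = num / den
    if hi.any():
        q = np.sqrt(-2.0 * np.log(1.0 - p[hi]))
        num = ((((c[0] * q + c[1]) * q + c[2]) * q + c[3]) * q + c[4]) * q + c[5]
        den = ((((d[0] * q + d[1]) * q + d[2]) * q + d[3]) * q) + 1.0
        out[hi] = -num / den
    return out


def _bridge_tt_mvncdf(rho: float, delta1: float, delta2: float) -> float:
    """Reference forward bridge through the 4-D normal CDF (slow; used as an
    independent cross-check of the quadrature implementation)."""
    r = float(np.clip(rho, -0.9999, 0.9999))
    d1, d2 = float(delta1), float(delta2)
    s = 1.0 / np.sqrt(2.0)
    upper = np.array([-d1, -d2, 0.0, 0.0])
    sig_a = np.array(
        [
            [1.0, 0.0, s, -r * s],
            [0.0, 1.0, -r * s, s],
            [s, -r * s, 1.0, -r],
            [-r * s, s, -r, 1.0],
        ]
    )
    sig_b = np.array(
        [
            [1.0, r, s, r * s],
            [r, 1.0, r * s, s],
            [s, r * s, 1.0, r],
            [r * s, s, r, 1.0],
        ]
    )

    def phi4(corr):
        mvn = stats.multivariate_normal(
            mean=np.zeros(4), cov=corr, allow_singular=True, seed=12345
        )
        return float(mvn.cdf(upper))

    return -2.0 * phi4(sig_a) + 2.0 * phi4(sig_b)


def bridge_tt(rho: float, delta1: float, delta2: float) -> float:
    """Forward bridge: Kendall tau-a of a truncated/truncated Gaussian-copula
    pair with latent correlation ``rho`` and truncation levels delta_j
    (= Phi^{-1} of the zero proportions).

    Derivation: with iid latent pairs (Z1, Z2), (Z1', Z2') ~ N2(rho) and
    x = 1(Z1 > d1) f(Z1) etc., {x > x'} = {Z1 > d1, Z1' < Z1}, so

        tau = 2 E[1(Z1>d1) (1(Z2>d2) Phi2(Z1, Z2) - Phi(Z1)
                            + Phi2(Z1, max(d2, Z2)))],

    evaluated by tensor Gauss-Legendre quadrature after probability-integral
    substitutions (the z2 <= d2 branch integrates in closed form).
    """
    r = float(np.clip(rho, -0.9999, 0.9999))
    d1, d2 = float(delta1), float(delta2)
    u, w = _gl_rule()
    s = np.sqrt(1.0 - r * r)

    p1 = stats.norm.cdf(d1)
    # z1 ~ N(0,1) truncated to (d1, inf)
    z1 = stats.norm.ppf(p1 + (1.0 - p1) * u)
    w1 = (1.0 - p1) * w

    w0 = (d2 - r * z1) / s  # threshold of the conditional z2 | z1
    phi_w0 = stats.norm.cdf(w0)
    phi_z1 = stats.norm.cdf(z1)

    # branch z2 <= d2: closed form in the conditional variable
    A = phi_w0 * (_phi2(z1, np.full_like(z1, d2), r) - phi_z1)

    # branch z2 > d2: 2 Phi2(z1, z2) - Phi(z1), z2 = r z1 + s wq
    pw0 = phi_w0
    wq = stats.norm.ppf(pw0[:, None] + (1.0 - pw0)[:, None] * u[None, :])
    z2 = r * z1[:, None] + s * wq
    inner = 2.0 * _phi2(np.broadcast_to(z1[:, None], z2.shape), z2, r) - phi_z1[:, None]
    B = ((1.0 - pw0)[:, None] * inner * w[None, :]).sum(axis=1)

    return float(2.0 * np.dot(w1, A + B))


def bridge_continuous(rho: float) -> float:
    return 2.0 / np.pi * np.arcsin(np.clip(rho, -1.0, 1.0))


def bridge_inverse(
    tau: float, delta1: float, delta2: float, tol: float = 1e-6
) -> float:
    """Invert the TT bridge numerically (brentq); clamps beyond the
    attainable tau range."""
    lo, hi = -0.999, 0.999
    f_lo = bridge_tt(lo, delta1, delta2) - tau
    f_hi = bridge_tt(hi, delta1, delta2) - tau
    if f_lo >= 0:
        return lo
    if f_hi <= 0:
        return hi
    return float(
        optimize.brentq(
            lambda r: bridge_tt(r, delta1, delta2) - tau, lo, hi, xtol=tol
        )
    )


def _bridge_tt_batch(r: np.ndarray, d1: np.ndarray, d2: np.ndarray) -> np.ndarray:
    """Vectorized forward TT bridge over aligned 1-D arrays."""
    from scipy.special import ndtr

    r = np.clip(np.asarray(r, dtype=float), -0.9999, 0.9999)
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    u, w = _gl_rule()
    s = np.sqrt(1.0 - r * r)

    p1 = ndtr(d1)
    z1 = _fast_norm_ppf(p1[:, None] + (1.0 - p1)[:, None] * u[None, :])  # (m, n)
    w1 = (1.0 - p1)[:, None] * w[None, :]

    w0 = (d2[:, None] - r[:, None] * z1) / s[:, None]
    pw0 = ndtr(w0)
    phi_z1 = ndtr(z1)

    A = pw0 * (_phi2_batch(z1, np.broadcast_to(d2[:, None], z1.shape), r[:, None]) - phi_z1)

    wq = _fast_norm_ppf(pw0[:, :, None] + (1.0 - pw0)[:, :, None] * u[None, None, :])
    z2 = r[:, None, None] * z1[:, :, None] + s[:, None, None] * wq
    inner = (
        2.0 * _phi2_batch(np.broadcast_to(z1[:, :, None], z2.shape), z2, r[:, None, None])
        - phi_z1[:, :, None]
    )
    B = ((1.0 - pw0)[:, :, None] * inner * w[None, None, :]).sum(axis=2)
    return 2.0 * (w1 * (A + B)).sum(axis=1)


def _phi2_batch(h, k, rho):
    """Owen's-T bivariate normal CDF, broadcasting over rho as well."""
    from scipy.special import ndtr, owens_t

    r = np.clip(rho, -0.99999, 0.99999)
    hs = np.where(h == 0.0, 1e-12, h)
    ks = np.where(k == 0.0, 1e-12, k)
    denom = np.sqrt(1.0 - r * r)
    ah = (ks / hs - r) / denom
    ak = (hs / ks - r) / denom
    beta = np.where(hs * ks < 0, 0.5, 0.0)
    out = (
        0.5 * (ndtr(hs) + ndtr(ks))
        - owens_t(hs, ah)
        - owens_t(ks, ak)
        - beta
    )
    return np.clip(out, 0.0, 1.0)


def _invert_tt_batch(tau, d1, d2, n_iter: int = 20) -> np.ndarray:
    """Vectorized bisection of the TT bridge for aligned 1-D arrays."""
    tau = np.asarray(tau, dtype=float)
    lo = np.full_like(tau, -0.999)
    hi = np.full_like(tau, 0.999)
    f_lo = _bridge_tt_batch(lo, d1, d2) - tau
    f_hi = _bridge_tt_batch(hi, d1, d2) - tau
    out = np.empty_like(tau)
    clamp_lo = f_lo >= 0
    clamp_hi = f_hi <= 0
    active = ~(clamp_lo | clamp_hi)
    out[clamp_lo] = -0.999
    out[clamp_hi] = 0.999
    if active.any():
        a = lo[active]
        b = hi[active]
        ta = tau[active]
        da1 = np.asarray(d1, dtype=float)[active]
        da2 = np.asarray(d2, dtype=float)[active]
        for _ in range(n_iter):
            mid = (a + b) / 2.0
            fm = _bridge_tt_batch(mid, da1, da2) - ta
            neg = fm < 0
            a = np.where(neg, mid, a)
            b = np.where(neg, b, mid)
        out[active] = (a + b) / 2.0
    return out


_ZERO_FLOOR = 1e-3


def latent_correlation(x, y, min_nonzero: int = 5) -> float:
    """Latent Pearson correlation of a zero-inflated pair.

    No zeros in either vector: tau = (2/pi) arcsin(rho) inverted in closed
    form.  Otherwise the truncated/truncated bridge is inverted; a margin
    without zeros is handled by flooring its zero proportion at 1e-3 (a
    documented approximation to the mixed truncated/continuous case).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.count_nonzero(x) < min_nonzero or np.count_nonzero(y) < min_nonzero:
        raise ValueError(f"each vector needs >= {min_nonzero} nonzero entries")
    tau = kendall_tau_a(x, y)
    p1 = float(np.mean(x == 0))
    p2 = float(np.mean(y == 0))
    if p1 == 0.0 and p2 == 0.0:
        rho = np.sin(np.pi * tau / 2.0)
    else:
        d1 = stats.norm.ppf(max(p1, _ZERO_FLOOR))
        d2 = stats.norm.ppf(max(p2, _ZERO_FLOOR))
        rho = bridge_inverse(tau, d1, d2)
    return float(np.clip(rho, -0.999, 0.999))


def latent_correlation_matrix(data: np.ndarray, min_nonzero: int = 5) -> np.ndarray:
    """Pairwise latent correlations of the columns, PSD-projected,
    unit diagonal.  Pairs with zero-inflation are inverted in one batched
    bisection pass for speed."""
    X = np.asarray(data, dtype=float)
    n, p = X.shape
    if (np.count_nonzero(X, axis=0) < min_nonzero).any():
        raise ValueError(f"every column needs >= {min_nonzero} nonzero entries")
    pz = (X == 0).mean(axis=0)
    delta = stats.norm.ppf(np.maximum(pz, _ZERO_FLOOR))
    R = np.eye(p)
    taus = {}
    batch_idx, batch_tau, batch_d1, batch_d2 = [], [], [], []
    for i in range(p):
        for j in range(i + 1, p):
            tau = kendall_tau_a(X[:, i], X[:, j])
            if pz[i] == 0.0 and pz[j] == 0.0:
                R[i, j] = R[j, i] = np.clip(np.sin(np.pi * tau / 2.0), -0.999, 0.999)
            else:
                batch_idx.append((i, j))
                batch_tau.append(tau)
                batch_d1.append(delta[i])
                batch_d2.append(delta[j])
    if batch_idx:
        rho = _invert_tt_batch(
            np.asarray(batch_tau), np.asarray(batch_d1), np.asarray(batch_d2)
        )
        for (i, j), r in zip(batch_idx, rho):
            R[i, j] = R[j, i] = float(np.clip(r, -0.999, 0.999))
    return psd_project(R)


def psd_project(R: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    evals, evecs = np.linalg.eigh((R + R.T) / 2.0)
    if evals.min() >= floor:
        return R
    evals = np.clip(evals, floor, None)
    R2 = (evecs * evals[None, :]) @ evecs.T
    d = np.sqrt(np.diag(R2))
    R2 = R2 / np.outer(d, d)
    np.fill_diagonal(R2, 1.0)
    return R2


# ---------------------------------------------------------------------------
# nodewise neighborhood selection on a correlation matrix
# ---------------------------------------------------------------------------


def _nodewise_lasso(R: np.ndarray, lam: float, theta0=None, max_sweep=200, tol=1e-6):
    """All p nodewise L1 regressions at once, coordinate descent on the
    correlation matrix.  Column j of the returned Theta holds node j's
    neighborhood coefficients (diagonal forced to zero)."""
    p = R.shape[0]
    theta = np.zeros((p, p)) if theta0 is None else theta0.copy()
    np.fill_diagonal(theta, 0.0)
    for _ in range(max_sweep):
        delta = 0.0
        for k in range(p):
            # coordinate k of every column's problem, updated jointly
            g = R[k] @ theta  # (p,)
            z = theta[k] + R[k] - g
            new = np.sign(z) * np.maximum(np.abs(z) - lam, 0.0)
            new[k] = 0.0
            delta = max(delta, np.abs(new - theta[k]).max())
            theta[k] = new
        if delta < tol:
            break
    return theta


def graph_path(latent_corr: np.ndarray, lambda_seq) -> list[np.ndarray]:
    """Signed adjacency matrices (OR-rule) along a decreasing lambda
    sequence: 0 = no edge, +/-1 = edge with the sign of the symmetrized
    neighborhood-regression coefficient."""
    R = np.asarray(latent_corr, dtype=float)
    evals = np.linalg.eigvalsh((R + R.T) / 2.0)
    if evals.min() < -1e-8:
        raise ValueError("correlation matrix must be PSD (project first)")
    lams = list(lambda_seq)
    if any(b > a for a, b in zip(lams, lams[1:])) and lams != sorted(lams, reverse=True):
        raise ValueError("lambda_seq must be decreasing")
    out = []
    theta = None
    for lam in lams:
        theta = _nodewise_lasso(R, lam, theta0=theta)
        sym = theta + theta.T
        adj = ((theta != 0) | (theta.T != 0)).astype(int)
        np.fill_diagonal(adj, 0)
        signed = adj * np.sign(np.where(sym == 0, 1.0, sym))
        out.append(signed.astype(int))
    return out


# ---------------------------------------------------------------------------
# StARS selection
# ---------------------------------------------------------------------------


@dataclass
class NetworkEstimate:
    """A selected conditional-dependence network for one (genotype, period)."""

    nodes: list
    edges: list  # (node_a, node_b, sign)
    genotype: str | None
    period: str | None
    lambda_selected: float
    instability_path: np.ndarray
    lambda_seq: np.ndarray
    adjacency: np.ndarray | None = None

    @property
    def edge_set(self) -> set:
        return {frozenset((a, b)) for a, b, _ in self.edges}


def default_lambda_seq(n_lambda: int = 25, lam_max: float = 1.0, lam_min_ratio=0.05):
    return np.geomspace(lam_max, lam_max * lam_min_ratio, n_lambda)


def stars_select(
    data: np.ndarray,
    lambda_seq=None,
    n_subsamples: int = 20,
    subsample_size: int | None = None,
    beta_threshold: float = 0.05,
    seed: int = 0,
    nodes: list | None = None,
    min_nonzero: int = 5,
) -> NetworkEstimate:
    """Stability-based regularization selection (StARS) for the
    neighborhood-selection graph on zero-inflated data columns.

    Instability at each lambda is the mean over node pairs of
    2 p(1-p), p the edge-selection frequency across subsamples (drawn
    without replacement, size ``min(floor(10 sqrt(n)), n-1)`` by default).
    The selected lambda is the least regularization whose monotonized
    instability stays <= beta; if none qualifies the densest lambda is
    returned with a warning.
    """
    X = np.asarray(data, dtype=float)
    n, p = X.shape
    if n_subsamples < 10:
        raise ValueError("n_subsamples must be >= 10")
    if subsample_size is None:
        subsample_size = min(int(np.floor(10 * np.sqrt(n))), n - 1)
    lams = (
        np.sort(np.asarray(lambda_seq, dtype=float))[::-1]
        if lambda_seq is not None
        else default_lambda_seq()
    )
    rng = np.random.default_rng(seed)
    nl = len(lams)
    sel_count = np.zeros((nl, p, p))
    for _ in range(n_subsamples):
        idx = rng.choice(n, size=subsample_size, replace=False)
        R = latent_correlation_matrix(X[idx], min_nonzero=min_nonzero)
        for li, signed in enumerate(graph_path(R, lams)):
            sel_count[li] += signed != 0

    phat = sel_count / n_subsamples
    iu = np.triu_indices(p, 1)
    instability = np.array([(2 * phat[li] * (1 - phat[li]))[iu].mean() for li in range(nl)])
    mono = np.maximum.accumulate(instability)  # lams decreasing -> density rises
    ok = np.nonzero(mono <= beta_threshold)[0]
    if len(ok):
        sel = int(ok[-1])  # least regularization still stable
    else:
        warnings.warn("all instabilities above beta; densest lambda returned")
        sel = nl - 1

    R_full = latent_correlation_matrix(X, min_nonzero=min_nonzero)
    signed = graph_path(R_full, lams[: sel + 1])[-1]
    names = nodes if nodes is not None else list(range(p))
    edges = [
        (names[i], names[j], int(signed[i, j]))
        for i, j in zip(*np.nonzero(np.triu(signed != 0, 1)))
    ]
    return NetworkEstimate(
        nodes=list(names),
        edges=edges,
        genotype=None,
        period=None,
        lambda_selected=float(lams[sel]),
        instability_path=instability,
        lambda_seq=lams,
        adjacency=signed,
    )


# ---------------------------------------------------------------------------
# period/genotype networks and comparison
# ---------------------------------------------------------------------------


def build_period_networks(
    table,
    rank: str,
    genotype: str,
    prevalence_min: float = 0.10,
    periods=DEFAULT_PERIODS,
    lambda_seq=None,
    n_subsamples: int = 20,
    beta_threshold: float = 0.05,
    seed: int = 0,
    min_samples: int = 10,
) -> list[NetworkEstimate]:
    """Aggregate to ``rank``, pool samples per period for one genotype,
    10%-prevalence filter within the pool, then StARS-selected networks."""
    from .prep import aggregate_taxonomy

    if rank not in ("family", "genus"):
        raise ValueError("rank must be 'family' or 'genus'")
    agg = aggregate_taxonomy(table, rank)
    meta = agg.sample_meta
    sub_ids = meta.index[meta["genotype"] == genotype]
    if len(sub_ids) == 0:
        warnings.warn(f"no samples for genotype {genotype}")
        return []
    results = []
    for pi, period in enumerate(periods):
        label = f"{period[0]}-{period[-1]}"
        ids = sub_ids[meta.loc[sub_ids, "week"].isin(period)]
        if len(ids) < min_samples:
            warnings.warn(f"period {label}: only {len(ids)} samples; skipped")
            continue
        counts = agg.counts.loc[ids]
        prev = (counts > 0).mean(axis=0)
        taxa = list(prev.index[prev >= prevalence_min])
        counts = counts[taxa]
        nonzero_rows = counts.sum(axis=1) > 0
        mclr = mclr_matrix(counts.loc[nonzero_rows].to_numpy())
        est = stars_select(
            mclr,
            lambda_seq=lambda_seq,
            n_subsamples=n_subsamples,
            beta_threshold=beta_threshold,
            seed=seed + pi,
            nodes=taxa,
            min_nonzero=min(5, max(2, len(ids) // 4)),
        )
        est.genotype = genotype
        est.period = label
        results.append(est)
    return results


@dataclass
class DifferentialNetworkReport:
    """Edge presence across (genotype x period) cells and its partition into
    core / genotype-stable / period-specific classes."""

    presence: pd.DataFrame  # edges x cells booleans
    classes: dict = field(default_factory=dict)

    def class_counts(self) -> dict:
        return {k: len(v) for k, v in self.classes.items()}


def compare_networks(networks: dict) -> DifferentialNetworkReport:
    """Classify edges across all (genotype, period) networks.

    ``networks`` maps (genotype, period) -> NetworkEstimate.  Core = present
    in every cell; genotype-stable = present in all periods of exactly one
    genotype; everything else period-specific.
    """
    if len(networks) < 2:
        raise ValueError("need >= 2 networks to compare")
    cells = sorted(networks.keys())
    genotypes = sorted({g for g, _ in cells})
    periods_by_geno = {g: sorted(p for gg, p in cells if gg == g) for g in genotypes}
    all_edges = sorted(
        {e for est in networks.values() for e in est.edge_set},
        key=lambda e: tuple(sorted(e)),
    )
    presence = pd.DataFrame(
        False,
        index=[" -- ".join(sorted(e)) for e in all_edges],
        columns=[f"{g}|{p}" for g, p in cells],
    )
    for (g, p), est in networks.items():
        col = f"{g}|{p}"
        es = est.edge_set
        for e, name in zip(all_edges, presence.index):
            if e in es:
                presence.loc[name, col] = True

    classes = {"core": [], "genotype-stable": [], "period-specific": []}
    for e, name in zip(all_edges, presence.index):
        row = presence.loc[name]
        if row.all():
            classes["core"].append(name)
            continue
        stable_in = [
            g
            for g in genotypes
            if periods_by_geno[g]
            and all(row[f"{g}|{p}"] for p in periods_by_geno[g])
        ]
        if len(stable_in) == 1:
            classes["genotype-stable"].append(name)
        else:
            classes["period-specific"].append(name)
    return DifferentialNetworkReport(presence=presence, classes=classes)
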