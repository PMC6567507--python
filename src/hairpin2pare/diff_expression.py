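"""Normalization, dispersion estimation, NB-GLM likelihood-ratio tests,
FDR control and clustering/MDS summaries for the 2 x 3 heat-stress design.

This is a from-first-principles count-GLM stack in the edgeR tradition:
trimmed-mean-of-M-values (TMM) normalization, a common negative-binomial
dispersion maximizing the Cox-Reid adjusted profile likelihood on a log
grid, tagwise dispersions shrunk toward the common value by weighted
likelihood, and per-tag likelihood-ratio tests between cell-mean models.
It is deliberately simpler than edgeR's empirical-Bayes machinery; its
contract is calibration (uniform null p-values, controlled FDR) and
parameter recovery rather than bit-compatibility.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .io_core import SampleSheet

_LN2 = np.log(2.0)
_MIN_BETA = -30.0


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def tmm_norm_factors(
    counts, trim_m: float = 0.3, trim_a: float = 0.05, ref_column: int | None = None
) -> np.ndarray:
    """Trimmed mean of M-values composition factors, rescaled to geometric
    mean 1. The reference library is the one whose upper-quartile CPM is
    closest to the mean upper quartile. Genes zero in either library are
    excluded; the M distribution is trimmed 30% each tail and A 5% each
    tail; the factor is 2^(precision-weighted mean M) with delta-method
    weights."""
    y = np.asarray(counts, dtype=float)
    if y.ndim != 2 or y.shape[1] < 2:
        raise ValueError("need a genes x libraries matrix with >= 2 libraries")
    N = y.sum(axis=0)
    if np.any(N <= 0):
        raise ValueError("library with zero total count")
    if ref_column is None:
        uq = np.array([np.percentile(y[:, j][y[:, j] > 0], 75) / N[j] for j in range(y.shape[1])])
        ref_column = int(np.argmin(np.abs(uq - uq.mean())))
    r = y[:, ref_column]
    Nr = N[ref_column]
    factors = np.ones(y.shape[1])
    for j in range(y.shape[1]):
        if j == ref_column:
            continue
        x = y[:, j]
        keep = (x > 0) & (r > 0)
        if keep.sum() == 0:
            continue
        xk, rk = x[keep], r[keep]
        M = np.log2((xk / N[j]) / (rk / Nr))
        A = 0.5 * np.log2((xk / N[j]) * (rk / Nr))
        v = (N[j] - xk) / (N[j] * xk) + (Nr - rk) / (Nr * rk)
        n = len(M)
        loM, hiM = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
        loA, hiA = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
        rM = pd.Series(M).rank().to_numpy()
        rA = pd.Series(A).rank().to_numpy()
        sel = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
        if sel.sum() == 0 or not np.isfinite(M[sel]).any():
            continue
        w = 1.0 / v[sel]
        factors[j] = 2.0 ** (np.sum(w * M[sel]) / np.sum(w))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


# ---------------------------------------------------------------------------
# NB GLM machinery (one-way cell-means layouts, vectorized across genes)
# ---------------------------------------------------------------------------

def _groups_from_sheet(sheet: SampleSheet, columns) -> list[np.ndarray]:
    col_pos = {c: i for i, c in enumerate(columns)}
    return [
        np.array([col_pos[l] for l in libs], dtype=int)
        for _, libs in sorted(sheet.cells().items())
    ]


def _fit_cells(y, offsets, groups, phi):
    """Fisher-scoring fit of per-cell means with log link and offsets.

    y: (G, n); phi: scalar or (G,). Returns (mu, beta per cell, ll, logdet
    of the expected information, converged flags)."""
    G, n = y.shape
    phi = np.broadcast_to(np.asarray(phi, dtype=float).reshape(-1, 1), (G, 1))
    mu = np.zeros_like(y, dtype=float)
    betas = np.full((G, len(groups)), _MIN_BETA)
    logdet = np.zeros(G)
    converged = np.ones(G, dtype=bool)
    for c, idx in enumerate(groups):
        yc = y[:, idx]
        s = np.exp(offsets[idx])
        tot = yc.sum(axis=1)
        beta = np.where(tot > 0, np.log(np.maximum(tot, 0.5) / s.sum()), _MIN_BETA)
        active = tot > 0
        for _ in range(60):
            m = np.exp(beta[:, None] + offsets[idx][None, :])
            score = ((yc - m) / (1.0 + phi * m)).sum(axis=1)
            info = (m / (1.0 + phi * m)).sum(axis=1)
            step = np.where(active, score / np.maximum(info, 1e-12), 0.0)
            step = np.clip(step, -5.0, 5.0)
            beta = beta + step
            if np.max(np.abs(step)) < 1e-10:
                break
        else:
            converged &= np.abs(step) < 1e-6
        betas[:, c] = beta
        m = np.exp(beta[:, None] + offsets[idx][None, :])
        mu[:, idx] = m
        info = (m / (1.0 + phi * m)).sum(axis=1)
        logdet += np.log(np.maximum(info, 1e-300))
    return mu, betas, _nb_loglik(y, mu, phi), logdet, converged


def _nb_loglik(y, mu, phi):
    """Row sums of the NB log-likelihood (Poisson limit for tiny phi)."""
    mu = np.maximum(mu, 1e-12)
    phi = np.broadcast_to(np.asarray(phi, dtype=float).reshape(-1, 1), y.shape[:1] + (1,))
    out = np.empty(y.shape[0])
    tiny = phi[:, 0] < 1e-8
    if np.any(~tiny):
        r = 1.0 / phi[~tiny]
        yy, mm = y[~tiny], mu[~tiny]
        out[~tiny] = (
            gammaln(yy + r) - gammaln(r) - gammaln(yy + 1)
            + yy * np.log(mm / (mm + r)) + r * np.log(r / (r + mm))
        ).sum(axis=1)
    if np.any(tiny):
        yy, mm = y[tiny], mu[tiny]
        out[tiny] = (yy * np.log(mm) - mm - gammaln(yy + 1)).sum(axis=1)
    return out


DISPERSION_GRID = np.logspace(-4, 1, 30)


def estimate_dispersion(
    counts,
    sheet: SampleSheet,
    norm_factors: np.ndarray | None = None,
    prior_df: float = 10.0,
    grid: np.ndarray = DISPERSION_GRID,
) -> tuple[float, np.ndarray]:
    """Common and tagwise NB dispersions (variance = mu + phi*mu^2).

    The common phi maximizes the summed Cox-Reid adjusted profile likelihood
    over a log grid; tagwise phi_g maximize APL_g + w * mean-APL with weight
    w = prior_df / residual df, shrinking single-tag estimates toward the
    common value."""
    df = pd.DataFrame(counts)
    y = df.to_numpy(dtype=float)
    groups = _groups_from_sheet(sheet, df.columns)
    if y.shape[1] != sum(len(g) for g in groups):
        raise ValueError("count columns do not match the sample sheet")
    resid_df = y.shape[1] - len(groups)
    if resid_df <= 0:
        raise ValueError("no replication anywhere: dispersion unidentifiable")
    N = y.sum(axis=0)
    if norm_factors is None:
        norm_factors = np.ones(y.shape[1])
    offsets = np.log(N * norm_factors)
    express = y.sum(axis=1) > 0
    ye = y[express]
    apl = np.empty((ye.shape[0], len(grid)))
    for k, phi in enumerate(grid):
        _, _, ll, logdet, _ = _fit_cells(ye, offsets, groups, phi)
        apl[:, k] = ll - 0.5 * logdet
    common = float(grid[int(np.argmax(apl.sum(axis=0)))])
    w = prior_df / resid_df
    score = apl + w * apl.mean(axis=0)[None, :]
    tag_e = grid[np.argmax(score, axis=1)]
    tagwise = np.full(y.shape[0], common)
    tagwise[express] = tag_e
    return common, tagwise


# contrasts mirroring the study design: heat vs control at each timepoint,
# plus early-vs-late within each treatment
def default_contrasts(timepoints=(0, 1, 4)) -> dict[str, tuple[tuple, tuple]]:
    out = {}
    for tp in timepoints:
        out[f"heat_vs_control_{tp}DAT"] = (("heat", tp), ("control", tp))
    first, last = timepoints[0], timepoints[-1]
    out[f"heat_{first}_vs_{last}DAT"] = (("heat", first), ("heat", last))
    out[f"control_{first}_vs_{last}DAT"] = (("control", first), ("control", last))
    return out


def glm_lrt(
    counts,
    sheet: SampleSheet,
    contrast: tuple[tuple, tuple],
    norm_factors: np.ndarray | None = None,
    dispersion=0.1,
    contrast_name: str = "",
) -> pd.DataFrame:
    """Likelihood-ratio test of equal means between two design cells under
    the full cell-means NB model (offset = log effective library size).
    Returns per-tag log2FC (cellA - cellB), LR statistic, p-value."""
    df = pd.DataFrame(counts)
    y = df.to_numpy(dtype=float)
    cells = sorted(sheet.cells().items())
    cell_keys = [k for k, _ in cells]
    groups = _groups_from_sheet(sheet, df.columns)
    ca, cb = contrast
    ia, ib = cell_keys.index(ca), cell_keys.index(cb)
    N = y.sum(axis=0)
    if norm_factors is None:
        norm_factors = np.ones(y.shape[1])
    offsets = np.log(N * norm_factors)

    _, betas, ll_full, _, conv_f = _fit_cells(y, offsets, groups, dispersion)
    red_groups = [g for i, g in enumerate(groups) if i not in (ia, ib)]
    red_groups.append(np.concatenate([groups[ia], groups[ib]]))
    _, _, ll_red, _, conv_r = _fit_cells(y, offsets, red_groups, dispersion)

    lr = np.maximum(2.0 * (ll_full - ll_red), 0.0)
    p = chi2.sf(lr, df=1)
    lfc = (betas[:, ia] - betas[:, ib]) / _LN2
    allzero = y.sum(axis=1) == 0
    bothzero = y[:, np.concatenate([groups[ia], groups[ib]])].sum(axis=1) == 0
    p[allzero | bothzero] = 1.0
    lr[allzero | bothzero] = 0.0
    lfc[allzero | bothzero] = 0.0
    bad = ~(conv_f & conv_r)
    p[bad] = np.nan
    out = pd.DataFrame(
        {
            "mirna": df.index,
            "contrast": contrast_name or f"{ca[0]}_{ca[1]}-vs-{cb[0]}_{cb[1]}",
            "log2FC": lfc,
            "lr_stat": lr,
            "p_value": p,
        }
    )
    out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    return out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up; NaNs propagate and are excluded from m."""
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qq = np.empty(m)
    qq[order] = np.minimum(ranked, 1.0)
    q[ok] = qq
    return q


def run_de(
    counts, sheet: SampleSheet, fdr: float = 0.05, prior_df: float = 10.0
) -> dict[str, pd.DataFrame]:
    """Full DE stage: TMM factors, dispersions, every default contrast."""
    df = pd.DataFrame(counts)
    nf = tmm_norm_factors(df)
    common, tagwise = estimate_dispersion(df, sheet, nf, prior_df=prior_df)
    timepoints = tuple(sorted({l.timepoint_days for l in sheet}))
    out = {}
    for name, contrast in default_contrasts(timepoints).items():
        res = glm_lrt(df, sheet, contrast, nf, tagwise, contrast_name=name)
        res["significant"] = res["fdr"] < fdr
        out[name] = res
    return out


# ---------------------------------------------------------------------------
# Clustering and MDS
# ---------------------------------------------------------------------------

def log_rpm(counts) -> pd.DataFrame:
    """log2(RPM + 1) matrix used for heat maps, clustering and MDS."""
    df = pd.DataFrame(counts, dtype=float)
    return np.log2(df * 1e6 / df.sum(axis=0) + 1.0)


def chebyshev_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return np.max(np.abs(X[:, None, :] - X[None, :, :]), axis=2)


def hcluster(X, labels=None) -> list[tuple[int, int, float, int]]:
    """Agglomerative complete-linkage clustering under the Chebyshev
    (maximum coordinate difference) distance.

    Returns scipy-style merges (id_a, id_b, height, size) with new clusters
    numbered n, n+1, ...; ties break on the lexicographically smallest pair
    of cluster ids, making the tree deterministic."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    D = {(i, j): float(np.max(np.abs(X[i] - X[j]))) for i in range(n) for j in range(i + 1, n)}
    active = list(range(n))
    sizes = {i: 1 for i in range(n)}
    merges = []
    next_id = n
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                key = (D[(i, j)], i, j)
                if best is None or key < best:
                    best = key
        d, i, j = best
        merges.append((i, j, d, sizes[i] + sizes[j]))
        for k in active:
            if k in (i, j):
                continue
            a, b = sorted((i, k))
            c, e = sorted((j, k))
            D[(k, next_id)] = max(D[(a, b)], D[(c, e)])
        active = [k for k in active if k not in (i, j)] + [next_id]
        sizes[next_id] = sizes[i] + sizes[j]
        next_id += 1
    return merges


def cophenetic_matrix(merges, n) -> np.ndarray:
    """Pairwise merge heights implied by a dendrogram (for comparisons)."""
    members = {i: [i] for i in range(n)}
    C = np.zeros((n, n))
    nid = n
    for i, j, h, _ in merges:
        for a in members[i]:
            for b in members[j]:
                C[a, b] = C[b, a] = h
        members[nid] = members[i] + members[j]
        nid += 1
    return C


def mds_embed(X) -> np.ndarray:
    """Classical (Torgerson) MDS to 2-D from Euclidean row distances:
    double-centered squared distances, top-2 eigenvectors scaled by root
    eigenvalues. Axis signs are fixed deterministically."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need >= 3 items for MDS")
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ sq @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if vals[1] <= 1e-10:
        warnings.warn("configuration has rank < 2; second MDS axis set to zero")
    coords = np.zeros((n, 2))
    for k in range(2):
        if vals[k] > 1e-10:
            v = vecs[:, k] * np.sqrt(vals[k])
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            coords[:, k] = v
    return coords
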