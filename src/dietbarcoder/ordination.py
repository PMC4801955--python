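"""Diet comparison: OTU filtering, transformation, (detrended)
correspondence analysis, per-OTU group tests.

The ordination is correspondence analysis computed by reciprocal averaging
(power iteration on the weighted double-averaging operator).  For DCA,
axes 2..n are detrended against every previous axis by Hill's method:
each previous axis is divided into equal-width segments and the running
axis's weighted segment means are removed, breaking the arch artefact of
plain CA.  Nonlinear rescaling is off by default; a simplified rescaling
(axis standardised to weighted unit variance of site scores) is available
for users who want scores in roughly standard-deviation units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assign import OtuTable

__all__ = [
    "OrdinationResult",
    "CANotConvergedError",
    "filter_for_ordination",
    "transform_sqrt",
    "ca",
    "dca",
    "per_otu_group_test",
]


class CANotConvergedError(RuntimeError):
    """Raised when reciprocal averaging fails to converge ("ca-not-converged")."""


@dataclass
class OrdinationResult:
    site_scores: pd.DataFrame  # samples x axes
    species_scores: pd.DataFrame  # otus x axes
    eigenvalues: np.ndarray
    method: str  # "CA" | "DCA"


def filter_for_ordination(table: OtuTable, min_frac: float = 0.005) -> OtuTable:
    """Keep OTUs exceeding ``min_frac`` relative abundance in >= 1 sample.

    The inequality is strict: an OTU at exactly the threshold is dropped.
    """
    rel = table.relative_abundance()
    keep = (rel > min_frac).any(axis=0)
    return table.copy(
        counts=table.counts[:, keep],
        otus=[o for o, k in zip(table.otus, keep) if k],
    )


def transform_sqrt(table: OtuTable) -> pd.DataFrame:
    """Element-wise square root of relative abundances."""
    return pd.DataFrame(
        np.sqrt(table.relative_abundance()), index=table.samples, columns=table.otus
    )


def _detrend_by_segments(x, prev_axis, weights, n_segments):
    """Remove weighted segment means of x along equal-width segments of a
    previous axis (Hill's detrending)."""
    lo, hi = prev_axis.min(), prev_axis.max()
    if hi - lo <= 0:
        return x - np.sum(weights * x) / weights.sum()
    edges = np.linspace(lo, hi, n_segments + 1)
    seg = np.clip(np.searchsorted(edges, prev_axis, side="right") - 1, 0, n_segments - 1)
    out = x.copy()
    for s in np.unique(seg):
        mask = seg == s
        w = weights[mask]
        out[mask] = x[mask] - np.sum(w * x[mask]) / w.sum()
    return out


def _reciprocal_averaging(
    Y, n_axes, detrend, n_segments, tol, max_iter
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    Y = np.asarray(Y, dtype=float)
    total = Y.sum()
    P = Y / total
    r = P.sum(axis=1)  # site (row) weights
    c = P.sum(axis=0)  # species (column) weights
    n_sites = Y.shape[0]
    site_axes, spp_axes, eigvals = [], [], []
    for axis_idx in range(n_axes):
        x = np.arange(n_sites, dtype=float)  # column-index ramp init
        x = x - np.sum(r * x)
        norm = np.sqrt(np.sum(r * x * x))
        if norm == 0:
            raise CANotConvergedError("ca-not-converged: degenerate init")
        x /= norm
        lam = 0.0
        for iteration in range(max_iter):
            u = (P.T @ x) / c
            x_new = (P @ u) / r
            if detrend and axis_idx > 0:
                for prev in site_axes:
                    x_new = _detrend_by_segments(x_new, prev, r, n_segments)
            else:
                for prev in site_axes:
                    x_new = x_new - np.sum(r * x_new * prev) * prev
            x_new = x_new - np.sum(r * x_new)
            lam = np.sqrt(np.sum(r * x_new * x_new))
            if lam == 0:
                break
            x_new /= lam
            if np.max(np.abs(x_new - x)) < tol:
                x = x_new
                break
            x = x_new
        else:
            raise CANotConvergedError(
                "ca-not-converged: axis %d after %d iterations" % (axis_idx + 1, max_iter)
            )
        u = (P.T @ x) / c
        site_axes.append(x)
        spp_axes.append(u)
        eigvals.append(lam)
    return np.array(site_axes).T, np.array(spp_axes).T, np.array(eigvals)


def ca(
    matrix,
    n_axes: int = 4,
    samples=None,
    otus=None,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> OrdinationResult:
    """Plain correspondence analysis by reciprocal averaging."""
    return _ordinate(matrix, n_axes, False, 26, False, samples, otus, tol, max_iter, "CA")


def dca(
    matrix,
    n_axes: int = 4,
    n_segments: int = 26,
    rescale: bool = False,
    samples=None,
    otus=None,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> OrdinationResult:
    """Detrended correspondence analysis (detrending by segments)."""
    return _ordinate(
        matrix, n_axes, True, n_segments, rescale, samples, otus, tol, max_iter, "DCA"
    )


def _ordinate(
    matrix, n_axes, detrend, n_segments, rescale, samples, otus, tol, max_iter, method
) -> OrdinationResult:
    if isinstance(matrix, pd.DataFrame):
        samples = list(matrix.index) if samples is None else list(samples)
        otus = list(matrix.columns) if otus is None else list(otus)
        Y = matrix.to_numpy(dtype=float)
    else:
        Y = np.asarray(matrix, dtype=float)
        samples = samples or ["S%d" % i for i in range(Y.shape[0])]
        otus = otus or ["O%d" % j for j in range(Y.shape[1])]
    if (Y < 0).any():
        raise ValueError("matrix must be non-negative")
    if (Y.sum(axis=1) == 0).any() or (Y.sum(axis=0) == 0).any():
        raise ValueError("all-zero rows/columns must be filtered out first")
    n_axes = min(n_axes, Y.shape[0] - 1, Y.shape[1] - 1)
    sites, spp, eigvals = _reciprocal_averaging(
        Y, n_axes, detrend, n_segments, tol, max_iter
    )
    # orientation: first sample non-negative on every axis
    for k in range(sites.shape[1]):
        if sites[0, k] < 0:
            sites[:, k] *= -1
            spp[:, k] *= -1
    if rescale:
        r = Y.sum(axis=1) / Y.sum()
        for k in range(sites.shape[1]):
            sd = np.sqrt(np.sum(r * sites[:, k] ** 2))
            if sd > 0:
                sites[:, k] /= sd
                spp[:, k] /= sd
    cols = ["axis%d" % (k + 1) for k in range(sites.shape[1])]
    return OrdinationResult(
        site_scores=pd.DataFrame(sites, index=samples, columns=cols),
        species_scores=pd.DataFrame(spp, index=otus, columns=cols),
        eigenvalues=eigvals,
        method=method,
    )


def per_otu_group_test(
    table: OtuTable, group_labels: dict[str, str], alpha: float = 0.05,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per OTU between exactly two sample groups.

    Exact null distribution when both groups have <= 8 samples, normal
    approximation with tie correction otherwise.  No multiplicity
    correction by default; ``bh_correction`` applies Benjamini-Hochberg.
    Returns per-OTU (U, p, significant) with a k-of-m summary in attrs.
    """
    groups = sorted(set(group_labels.values()))
    if len(groups) != 2:
        raise ValueError("use-kruskal-wallis: need exactly 2 groups")
    members = {g: [s for s in table.samples if group_labels.get(s) == g] for g in groups}
    if any(len(m) < 3 for m in members.values()):
        raise ValueError("each group needs >= 3 samples")
    rel = pd.DataFrame(
        table.relative_abundance(), index=table.samples, columns=table.otus
    )
    exact = all(len(m) <= 8 for m in members.values())
    rows = []
    for otu in table.otus:
        x = rel.loc[members[groups[0]], otu].to_numpy()
        y = rel.loc[members[groups[1]], otu].to_numpy()
        if np.ptp(np.concatenate([x, y])) == 0:
            u = len(x) * len(y) / 2.0
            p = 1.0
        else:
            method = "exact" if exact and not _has_ties(x, y) else "asymptotic"
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
            u, p = float(res.statistic), float(res.pvalue)
        rows.append((otu, u, p))
    df = pd.DataFrame(rows, columns=["otu", "U", "p"])
    if bh_correction:
        order = np.argsort(df["p"].to_numpy())
        m = len(df)
        adj = np.empty(m)
        running = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            running = min(running, df["p"].iloc[i] * m / (rank_idx + 1))
            adj[i] = running
        df["p_adjusted"] = adj
        df["significant"] = df["p_adjusted"] < alpha
    else:
        df["significant"] = df["p"] < alpha
    df.attrs["n_significant"] = int(df["significant"].sum())
    df.attrs["n_otus"] = len(df)
    return df


def _has_ties(x, y) -> bool:
    pooled = np.concatenate([x, y])
    return len(np.unique(pooled)) < len(pooled)
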