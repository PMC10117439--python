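"""Connectivity-matrix construction and proportional binarisation.

Three weighted, fully connected, symmetric connectivity constructions per
subject:

* **GMM** (gray matter matrix): morphological similarity between two
  ROIs' gray-matter voxel-value distributions, exp(-symmetric KL
  divergence) of their kernel density estimates; entries in (0, 1].
* **FBM** (functional brain matrix): absolute Pearson correlation of the
  ROI mean time series; entries in [0, 1].
* **GMM-FBM**: the two matrices min-max normalised separately over their
  off-diagonal entries, then summed; entries in [0, 2].

Binary graphs retain exactly the top fraction ``p`` of the N(N-1)/2
undirected edge weights ("proportional quantification"); the Erdos-Renyi
connectedness heuristic 2 ln N / N gives the sparsity floor below which
the graph risks disconnecting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

from .cohort import SubjectRaw

__all__ = [
    "ConnectivityMatrix",
    "roi_value_density",
    "sym_kl",
    "gmm_matrix",
    "fbm_matrix",
    "minmax_offdiag",
    "gmm_fbm_matrix",
    "proportional_binarize",
    "min_sparsity",
]

DENSITY_GRID_POINTS = 128
DENSITY_FLOOR = 1e-12
GRID_PAD_BANDWIDTHS = 3.0


@dataclass
class ConnectivityMatrix:
    """An N x N symmetric connectivity matrix with provenance tags."""

    values: np.ndarray
    kind: str  # GMM | FBM | GMM-FBM
    form: str = "weighted"  # weighted | binary
    sparsity: float | None = None
    subject_id: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("connectivity matrix must have zero diagonal")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _silverman_bandwidth(values: np.ndarray) -> float:
    # scipy's "silverman" factor for d=1: (3n/4)^(-1/5), scaled by data SD
    n = len(values)
    return float(np.std(values, ddof=1) * (3.0 * n / 4.0) ** (-0.2))


def roi_value_density(
    values: np.ndarray, grid: np.ndarray, widen_constant: bool = False
) -> np.ndarray:
    """Discrete probability vector: Gaussian KDE evaluated on ``grid``.

    Silverman-bandwidth kernel density estimate, floored at a tiny positive
    value and renormalised to sum to one, so downstream KL divergences see
    strictly positive aligned supports.
    """
    values = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values for a density estimate")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    if np.std(values) == 0:
        if not widen_constant:
            raise ValueError(
                "zero-variance values: no bandwidth (set widen_constant=True)"
            )
        values = values + np.linspace(-1e-6, 1e-6, values.size)
    kde = gaussian_kde(values, bw_method="silverman")
    dens = kde(grid)
    dens = np.maximum(dens, DENSITY_FLOOR)
    return dens / dens.sum()


def sym_kl(p: np.ndarray, q: np.ndarray) -> float:
    """Symmetrised Kullback-Leibler divergence KL(p||q) + KL(q||p)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must have the same length")
    if np.any(p <= 0) or np.any(q <= 0):
        raise ValueError("distributions must be strictly positive")
    if not (np.isclose(p.sum(), 1.0) and np.isclose(q.sum(), 1.0)):
        raise ValueError("distributions must sum to 1")
    ratio = np.log(p / q)
    return float(np.sum(p * ratio) - np.sum(q * ratio))


def _pair_grid(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    pad = GRID_PAD_BANDWIDTHS * max(_silverman_bandwidth(x), _silverman_bandwidth(y))
    lo = min(x.min(), y.min()) - pad
    hi = max(x.max(), y.max()) + pad
    return np.linspace(lo, hi, DENSITY_GRID_POINTS)


def _kde_on_grids(
    data: np.ndarray, bandwidths: np.ndarray, grids: np.ndarray
) -> np.ndarray:
    """Gaussian KDE of ``data[r]`` (bandwidth ``bandwidths[r]``) on ``grids[r]``.

    data: (R, V); grids: (R, G).  Returns (R, G) probability vectors
    (floored and renormalised), vectorised over rows.
    """
    diff = grids[:, None, :] - data[:, :, None]  # (R, V, G)
    h = bandwidths[:, None, None]
    dens = np.exp(-0.5 * (diff / h) ** 2).sum(axis=1)
    dens = np.maximum(dens, DENSITY_FLOOR)  # kernel prefactor cancels on renorm
    return dens / dens.sum(axis=1, keepdims=True)


def gmm_matrix(
    subject: SubjectRaw, grid: np.ndarray | None = None, chunk: int = 512
) -> ConnectivityMatrix:
    """Gray matter matrix: entry (i, j) = exp(-sym_kl(d_i, d_j)).

    Densities for a pair are evaluated on a shared grid spanning the
    pooled range of the two ROIs' gray-matter values (padded by 3
    bandwidths), unless an explicit common ``grid`` is supplied.  The
    pairwise construction is vectorised in chunks; it agrees with the
    explicit :func:`roi_value_density` / :func:`sym_kl` composition.
    """
    gm = subject.gm_values
    n = gm.shape[0]
    out = np.zeros((n, n))
    if grid is not None:
        try:
            dens = np.stack([roi_value_density(gm[r], grid) for r in range(n)])
        except ValueError as err:
            raise ValueError(f"density failure: {err}") from err
        logd = np.log(dens)
        for i in range(n):
            kl = np.sum((dens[i] - dens) * (logd[i] - logd), axis=1)
            out[i] = np.exp(-kl)
        np.fill_diagonal(out, 0.0)
    else:
        sds = np.std(gm, axis=1, ddof=1)
        bad = np.flatnonzero(sds == 0)
        if bad.size:
            raise ValueError(f"zero-variance gray-matter values in ROI(s) {bad.tolist()}")
        bw = sds * (3.0 * gm.shape[1] / 4.0) ** (-0.2)
        lo_r, hi_r = gm.min(axis=1), gm.max(axis=1)
        iu, ju = np.triu_indices(n, k=1)
        for start in range(0, iu.size, chunk):
            i = iu[start : start + chunk]
            j = ju[start : start + chunk]
            pad = GRID_PAD_BANDWIDTHS * np.maximum(bw[i], bw[j])
            lo = np.minimum(lo_r[i], lo_r[j]) - pad
            hi = np.maximum(hi_r[i], hi_r[j]) + pad
            step = (hi - lo) / (DENSITY_GRID_POINTS - 1)
            grids = lo[:, None] + step[:, None] * np.arange(DENSITY_GRID_POINTS)
            di = _kde_on_grids(gm[i], bw[i], grids)
            dj = _kde_on_grids(gm[j], bw[j], grids)
            kl = np.sum((di - dj) * (np.log(di) - np.log(dj)), axis=1)
            out[i, j] = out[j, i] = np.exp(-kl)
    return ConnectivityMatrix(out, kind="GMM", subject_id=subject.subject_id)


def fbm_matrix(subject: SubjectRaw) -> ConnectivityMatrix:
    """Functional brain matrix: |Pearson r| between ROI mean time series."""
    mean_ts = subject.timeseries.mean(axis=1)  # (n_rois, timepoints)
    sds = mean_ts.std(axis=1)
    bad = np.flatnonzero(sds == 0)
    if bad.size:
        raise ValueError(f"constant mean time series in ROI(s) {bad.tolist()}")
    corr = np.corrcoef(mean_ts)
    out = np.abs(corr)
    np.fill_diagonal(out, 0.0)
    out = np.clip((out + out.T) / 2.0, 0.0, 1.0)  # enforce exact symmetry
    return ConnectivityMatrix(out, kind="FBM", subject_id=subject.subject_id)


def minmax_offdiag(matrix: np.ndarray) -> np.ndarray:
    """Rescale off-diagonal entries to [0, 1] by the min-max map.

    Computed over the strictly-upper-triangle entries and mirrored; the
    (zero) diagonal is untouched.  Affine-invariant: a*M + b maps to the
    same output as M.
    """
    m = np.asarray(getattr(matrix, "values", matrix), dtype=float)
    n = m.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = m[iu]
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        raise ValueError("constant off-diagonal entries: min-max map undefined")
    out = np.zeros_like(m)
    scaled = (vals - lo) / (hi - lo)
    out[iu] = scaled
    out = out + out.T
    return out


def gmm_fbm_matrix(
    gmm: ConnectivityMatrix, fbm: ConnectivityMatrix
) -> ConnectivityMatrix:
    """Structural-functional matrix: separately min-max-normalised GMM and
    FBM, summed elementwise; entries lie in [0, 2]."""
    if gmm.n != fbm.n:
        raise ValueError("GMM and FBM dimensions differ")
    combined = minmax_offdiag(gmm.values) + minmax_offdiag(fbm.values)
    return ConnectivityMatrix(combined, kind="GMM-FBM", subject_id=gmm.subject_id)


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def proportional_binarize(
    matrix: ConnectivityMatrix | np.ndarray, proportion: float
) -> ConnectivityMatrix:
    """Retain exactly the top ``proportion`` of undirected edge weights as 1.

    k = round(p * E) edges (E = N(N-1)/2) chosen by descending weight;
    ties at the cut are broken by keeping the lexicographically smallest
    (i, j) pairs, so the retained count is exact regardless of ties.
    A warning (not an error) is raised below the 2 ln N / N floor.
    """
    values = np.asarray(getattr(matrix, "values", matrix), dtype=float)
    kind = getattr(matrix, "kind", "GMM")
    subject_id = getattr(matrix, "subject_id", None)
    n = values.shape[0]
    if not (0.0 < proportion < 1.0):
        raise ValueError(f"proportion must lie in (0, 1), got {proportion}")
    e = n * (n - 1) // 2
    k = _round_half_away(proportion * e)
    if k < 1:
        raise ValueError(f"proportion {proportion} retains no edges (E = {e})")
    floor = min_sparsity(n)
    if proportion < floor:
        warnings.warn(
            f"proportion {proportion:.4f} below the 2lnN/N connectivity floor "
            f"{floor:.4f} for N = {n}; the binary graph may disconnect",
            stacklevel=2,
        )
    iu, ju = np.triu_indices(n, k=1)
    w = values[iu, ju]
    order = np.lexsort((ju, iu, -w))  # descending weight, then (i, j) ascending
    keep = order[:k]
    out = np.zeros((n, n))
    out[iu[keep], ju[keep]] = 1.0
    out = out + out.T
    return ConnectivityMatrix(
        out, kind=kind, form="binary", sparsity=proportion, subject_id=subject_id
    )


def min_sparsity(n_rois: int) -> float:
    """Erdos-Renyi connectedness floor 2 ln N / N on the edge fraction."""
    if n_rois < 2:
        raise ValueError("need at least 2 nodes")
    return float(2.0 * np.log(n_rois) / n_rois)
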