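"""Per-ROI node features: GMV, WMV, ALFF, ReHo and degree centrality.

Six features per region:

* **GMV / WMV** — mean voxel gray-/white-matter value of the ROI.
* **ALFF** — amplitude of low-frequency fluctuation: the mean square-root
  power of a voxel's (linearly detrended) time series over 0.01-0.08 Hz,
  divided by the subject's all-voxel mean ALFF, then averaged per ROI.
* **ReHo** — regional homogeneity: Kendall's coefficient of concordance
  W between a voxel's series and its 26-connected within-block
  neighbours, normalised by the subject global mean, averaged per ROI.
* **sDC / fDC** — structural/functional degree centrality: the row sum
  of the weighted (pre-binarisation) connectivity matrix.
"""

from __future__ import annotations

import itertools
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy.stats import rankdata

from .cohort import AtlasPhantom, SubjectRaw

__all__ = [
    "roi_mean_volume",
    "voxel_alff",
    "roi_alff",
    "kendall_w",
    "roi_reho",
    "degree_centrality",
    "assemble_node_features",
    "SMRI_COLUMNS",
    "FMRI_COLUMNS",
    "ALL_COLUMNS",
]

DEFAULT_BAND = (0.01, 0.08)

SMRI_COLUMNS = ("GMV", "WMV", "sDC")
FMRI_COLUMNS = ("ReHo", "ALFF", "fDC")
ALL_COLUMNS = SMRI_COLUMNS + FMRI_COLUMNS


def roi_mean_volume(subject: SubjectRaw, tissue: str) -> np.ndarray:
    """Mean voxel tissue value per ROI; ``tissue`` is ``"gm"`` or ``"wm"``."""
    if tissue == "gm":
        values = subject.gm_values
    elif tissue == "wm":
        values = subject.wm_values
    else:
        raise ValueError(f"tissue must be 'gm' or 'wm', got {tissue!r}")
    if values.shape[1] == 0:
        raise ValueError("empty ROI: no voxels")
    return values.mean(axis=1)


def _band_bins(n: int, tr: float, band: tuple[float, float]) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, d=tr)
    low, high = band
    mask = (freqs >= low) & (freqs <= high) & (freqs > 0.0)
    if not mask.any():
        need = int(np.ceil(1.0 / (high * tr)))
        raise ValueError(
            f"band {band} Hz empty at length {n}, TR {tr}s; "
            f"need at least {need} timepoints"
        )
    return mask


def voxel_alff(
    series: np.ndarray, tr: float, band: tuple[float, float] = DEFAULT_BAND
) -> float | np.ndarray:
    """Mean square-root one-sided power over the closed band [low, high] Hz.

    Accepts one series (1D) or a stack (..., timepoints).  The series is
    linearly detrended first; the DC bin is always excluded.  Power is the
    periodogram ``|X_k|^2 / n`` of the real FFT.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[-1]
    if n < 32:
        raise ValueError(f"series length must be >= 32, got {n}")
    if tr <= 0:
        raise ValueError("tr must be positive")
    if band[1] >= 0.5 / tr:
        raise ValueError(f"band upper {band[1]} Hz >= Nyquist {0.5 / tr} Hz")
    mask = _band_bins(n, tr, band)
    detrended = sp_signal.detrend(series, axis=-1, type="linear")
    spectrum = np.fft.rfft(detrended, axis=-1)
    power = np.abs(spectrum) ** 2 / n
    out = np.sqrt(power[..., mask]).mean(axis=-1)
    return float(out) if out.ndim == 0 else out


def roi_alff(
    subject: SubjectRaw, tr: float, band: tuple[float, float] = DEFAULT_BAND
) -> np.ndarray:
    """Globally-normalised voxel ALFF averaged within each ROI.

    Voxel ALFF is divided by the mean over every voxel of every ROI of the
    subject (so the normalised values average to exactly 1), then averaged
    per ROI.
    """
    vox = voxel_alff(subject.timeseries, tr, band)  # (n_rois, voxels)
    gmean = vox.mean()
    if gmean <= 0:
        raise ValueError("degenerate subject: global mean ALFF is zero")
    return (vox / gmean).mean(axis=1)


def kendall_w(series_set: np.ndarray, constant: str = "error") -> float:
    """Kendall's coefficient of concordance over K series of length n.

    Ranks are computed independently within each series (average ranks on
    ties); with R_t the rank sum at time t over the K series,
    W = 12 * sum_t (R_t - mean R)^2 / (K^2 (n^3 - n)).

    ``constant``: what to do when some series is constant (its ranks are
    undefined) — ``"error"`` raises, ``"zero"`` returns 0.0.
    """
    arr = np.asarray(series_set, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need K >= 2 series of length n >= 2")
    k, n = arr.shape
    if np.any(arr.max(axis=1) == arr.min(axis=1)):
        if constant == "zero":
            return 0.0
        raise ValueError("constant series: ranks undefined (set constant='zero')")
    ranks = np.apply_along_axis(rankdata, 1, arr)
    r_t = ranks.sum(axis=0)
    s = np.sum((r_t - r_t.mean()) ** 2)
    return float(12.0 * s / (k**2 * (n**3 - n)))


def _block_neighbors(atlas: AtlasPhantom) -> list[np.ndarray]:
    """For each voxel of the block, the flat indices of itself + 26-neighbours."""
    shape = atlas.block_shape
    coords = list(itertools.product(*(range(d) for d in shape)))
    flat = {c: i for i, c in enumerate(coords)}
    groups = []
    for c in coords:
        members = [flat[c]]
        for off in atlas.neighbor_offsets:
            nb = (c[0] + off[0], c[1] + off[1], c[2] + off[2])
            if nb in flat:
                members.append(flat[nb])
        groups.append(np.array(sorted(members)))
    return groups


def roi_reho(
    subject: SubjectRaw, atlas: AtlasPhantom, constant: str = "error"
) -> np.ndarray:
    """Globally-normalised voxel ReHo averaged within each ROI.

    Each voxel's ReHo is Kendall's W over the voxel and its within-block
    26-connected neighbours (neighbourhoods truncate at block boundaries;
    no cross-ROI neighbours exist in the phantom).
    """
    groups = _block_neighbors(atlas)
    n_rois = subject.n_rois
    n_vox = subject.timeseries.shape[1]
    if len(groups) != n_vox:
        raise ValueError("atlas block does not match subject voxel count")
    w = np.empty((n_rois, n_vox))
    for r in range(n_rois):
        block = subject.timeseries[r]
        # rank once per voxel series, reuse across overlapping neighbourhoods
        if np.any(block.max(axis=1) == block.min(axis=1)):
            for v, members in enumerate(groups):
                try:
                    w[r, v] = kendall_w(block[members], constant=constant)
                except ValueError as err:
                    raise ValueError(f"ROI {r}, voxel {v}: {err}") from err
            continue
        ranks = np.apply_along_axis(rankdata, 1, block)
        n = block.shape[1]
        for v, members in enumerate(groups):
            k = len(members)
            r_t = ranks[members].sum(axis=0)
            s = np.sum((r_t - r_t.mean()) ** 2)
            w[r, v] = 12.0 * s / (k**2 * (n**3 - n))
    gmean = w.mean()
    if gmean <= 0:
        raise ValueError("degenerate subject: global mean ReHo is zero")
    return (w / gmean).mean(axis=1)


def degree_centrality(matrix) -> np.ndarray:
    """Weighted degree: the sum of a node's connectivity to all other nodes.

    Applied to the weighted gray-matter-similarity matrix this is sDC, to
    the weighted functional-correlation matrix fDC.  The input must be the
    full weighted matrix (symmetric, zero diagonal), not a binarised one.
    """
    values = getattr(matrix, "values", matrix)
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(values, values.T):
        raise ValueError("matrix must be symmetric")
    off = values - np.diag(np.diag(values))
    return off.sum(axis=1)


def assemble_node_features(
    subject: SubjectRaw,
    gmm,
    fbm,
    selection: str,
    tr: float = 2.0,
    band: tuple[float, float] = DEFAULT_BAND,
    atlas: AtlasPhantom | None = None,
    constant: str = "error",
) -> pd.DataFrame:
    """Node-feature table for one subject, restricted to a modality selection.

    ``selection``: ``"sMRI"`` -> (GMV, WMV, sDC); ``"fMRI"`` -> (ReHo, ALFF,
    fDC); ``"sMRI+fMRI"`` -> all six, in that order.  ``gmm``/``fbm`` are the
    weighted connectivity matrices used for the degree-centrality columns.
    """
    if selection not in ("sMRI", "fMRI", "sMRI+fMRI"):
        raise ValueError(f"unknown selection {selection!r}")
    cols: dict[str, np.ndarray] = {}
    if selection in ("sMRI", "sMRI+fMRI"):
        cols["GMV"] = roi_mean_volume(subject, "gm")
        cols["WMV"] = roi_mean_volume(subject, "wm")
        cols["sDC"] = degree_centrality(gmm)
    if selection in ("fMRI", "sMRI+fMRI"):
        if atlas is None:
            raise ValueError("atlas required for ReHo neighbourhoods")
        cols["ReHo"] = roi_reho(subject, atlas, constant=constant)
        cols["ALFF"] = roi_alff(subject, tr, band)
        cols["fDC"] = degree_centrality(fbm)
    order = [c for c in ALL_COLUMNS if c in cols]
    df = pd.DataFrame(cols, columns=order)
    df.index.name = "roi_index"
    df.attrs["subject_id"] = subject.subject_id
    df.attrs["selection"] = selection
    df.attrs["provenance"] = {"tr": tr, "band": band}
    return df
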