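"""Seeded synthetic multimodal phantom cohorts.

Real schizophrenia MRI cohorts are not publicly shareable, so every
downstream stage (node features, connectivity matrices, graph
classification, saliency) is exercised on phantom subjects generated
here.  A phantom subject carries, per region of interest (ROI), a small
lattice block of voxel gray-/white-matter values and voxel time series.

The generative model plants two kinds of group differences:

* a mean gray-matter-volume decrement (``gmv_shift``, in units of the
  ROI's voxel SD) in a configurable set of affected ROIs of patients;
* a reduction of the functional community loading (``coupling_drop``)
  of affected ROIs in patients, emulating dysconnectivity.

Everything is a pure function of the atlas, the config and the seed.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "AtlasPhantom",
    "CohortConfig",
    "SubjectRaw",
    "make_atlas_phantom",
    "simulate_subject",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
]

GROUP_CONTROL = "control"
GROUP_PATIENT = "patient"

#: moving-average window (timepoints) applied to the white-noise community
#: signal; at TR = 2 s this band-limits power into the 0.01-0.08 Hz range
#: so that ALFF is a meaningful feature of the phantom.
_SMOOTH_WINDOW = 5

#: hyperpriors for the per-ROI gray/white-matter baselines, drawn once per
#: cohort and shared by both groups so KL similarity has stable structure.
_MU_LOW, _MU_HIGH = 0.4, 0.8
_BASELINE_SD = 0.1


@dataclass(frozen=True)
class AtlasPhantom:
    """A phantom parcellation: ``n_rois`` ROIs, each a voxel lattice block.

    Stands in for an anatomical atlas (e.g. 90- or 246-region
    parcellations); the phantom has no global geometry, only a per-ROI
    block whose 26-connectivity drives the ReHo neighbourhood.
    """

    n_rois: int
    roi_names: tuple[str, ...]
    block_shape: tuple[int, int, int]
    neighbor_offsets: tuple[tuple[int, int, int], ...]

    @property
    def voxels_per_roi(self) -> int:
        return int(np.prod(self.block_shape))


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generative parameters.

    Group sizes default to the 205-control / 140-patient composition of
    the motivating clinical cohort; effect sizes default to zero (a null
    cohort) and must be set explicitly to plant a signal.
    """

    n_control: int = 205
    n_patient: int = 140
    seed: int = 0
    n_timepoints: int = 200
    tr_seconds: float = 2.0
    n_communities: int = 5
    affected_rois: tuple[int, ...] = ()
    gmv_shift: float = 0.0
    coupling_drop: float = 0.0
    voxel_noise_sd: float = 0.5
    temporal_noise_sd: float = 0.5

    def validate(self, n_rois: int | None = None) -> None:
        if self.n_control <= 0 or self.n_patient <= 0:
            raise ValueError("group sizes must be positive")
        if self.n_timepoints <= 0 or self.n_communities <= 0:
            raise ValueError("n_timepoints and n_communities must be positive")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not (0.0 <= self.coupling_drop <= 1.0):
            raise ValueError("coupling_drop must lie in [0, 1]")
        if self.voxel_noise_sd <= 0 or self.temporal_noise_sd <= 0:
            raise ValueError("noise scales must be positive")
        if n_rois is not None:
            bad = [r for r in self.affected_rois if not (0 <= r < n_rois)]
            if bad:
                raise ValueError(f"affected_rois out of range for n_rois={n_rois}: {bad}")


@dataclass
class SubjectRaw:
    """Raw per-subject multimodal data: the sole input to feature/edge code.

    ``gm_values``/``wm_values`` are (n_rois, voxels) arrays of voxel tissue
    values; ``timeseries`` is (n_rois, voxels, timepoints).
    """

    subject_id: str
    group: str
    gm_values: np.ndarray
    wm_values: np.ndarray
    timeseries: np.ndarray

    def __post_init__(self) -> None:
        if self.group not in (GROUP_CONTROL, GROUP_PATIENT):
            raise ValueError(f"unknown group {self.group!r}")
        if self.gm_values.shape[1] < 2:
            raise ValueError("every ROI needs at least 2 voxels")
        for arr in (self.gm_values, self.wm_values, self.timeseries):
            if not np.all(np.isfinite(arr)):
                raise ValueError("subject arrays must be finite")

    @property
    def n_rois(self) -> int:
        return self.gm_values.shape[0]

    @property
    def label(self) -> int:
        return 1 if self.group == GROUP_PATIENT else 0


def make_atlas_phantom(
    n_rois: int, block_shape: tuple[int, int, int] = (3, 3, 3)
) -> AtlasPhantom:
    """Construct a phantom atlas of ``n_rois`` identical lattice blocks.

    ``n_rois`` must be at least 10; below that, three rounds of graph
    pooling degenerate to near-empty graphs.
    """
    if n_rois < 10:
        raise ValueError(f"n_rois must be >= 10, got {n_rois}")
    if len(block_shape) != 3 or any(d < 2 for d in block_shape):
        raise ValueError("block_shape must be 3 dimensions, each >= 2")
    width = max(3, len(str(n_rois)))
    names = tuple(f"ROI_{i + 1:0{width}d}" for i in range(n_rois))
    offsets = tuple(
        off
        for off in itertools.product((-1, 0, 1), repeat=3)
        if off != (0, 0, 0)
    )
    return AtlasPhantom(
        n_rois=n_rois,
        roi_names=names,
        block_shape=tuple(block_shape),
        neighbor_offsets=offsets,
    )


def _cohort_baselines(
    atlas: AtlasPhantom, config: CohortConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Per-ROI (mu_r, sigma_r) tissue baselines, shared by both groups.

    Drawn from fixed hyperpriors with a stream derived from the cohort
    seed, so every subject of the cohort sees identical baselines.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xBA5E]))
    mu = rng.uniform(_MU_LOW, _MU_HIGH, size=atlas.n_rois)
    sigma = np.full(atlas.n_rois, _BASELINE_SD)
    return mu, sigma


def _smoothed_unit_signal(rng: np.random.Generator, n: int) -> np.ndarray:
    """Moving-average-smoothed white noise, restandardised to unit SD."""
    raw = rng.standard_normal(n + _SMOOTH_WINDOW - 1)
    kernel = np.full(_SMOOTH_WINDOW, 1.0 / _SMOOTH_WINDOW)
    sig = np.convolve(raw, kernel, mode="valid")
    sig = sig - sig.mean()
    sd = sig.std()
    if sd == 0:  # pragma: no cover - probability zero
        raise RuntimeError("degenerate community signal")
    return sig / sd


def community_of(roi: int | np.ndarray, n_communities: int) -> int | np.ndarray:
    """Round-robin community assignment: ROI i belongs to community i mod C."""
    return roi % n_communities


def simulate_subject(
    atlas: AtlasPhantom,
    group: str,
    config: CohortConfig,
    stream: np.random.Generator,
    subject_id: str = "subject",
) -> SubjectRaw:
    """Draw one phantom subject from the generative model.

    Functional side: each community c has a latent smoothed-Gaussian
    signal s_c(t); ROI r's mean series is lambda_r * s_{c(r)}(t) + eps_r(t)
    with loading lambda_r = 1, reduced to 1 - coupling_drop for affected
    ROIs of patients; voxel series add independent voxel noise.
    Structural side: voxel gray-matter values are Normal(mu_r - delta_r,
    sigma_r) with delta_r = gmv_shift * sigma_r for affected ROIs of
    patients; white matter is analogous with no shift.
    """
    config.validate(atlas.n_rois)
    if group not in (GROUP_CONTROL, GROUP_PATIENT):
        raise ValueError(f"unknown group {group!r}")
    n, v, t = atlas.n_rois, atlas.voxels_per_roi, config.n_timepoints
    mu, sigma = _cohort_baselines(atlas, config)

    affected = np.zeros(n, dtype=bool)
    if config.affected_rois:
        affected[list(config.affected_rois)] = True
    is_patient = group == GROUP_PATIENT

    delta = np.where(is_patient & affected, config.gmv_shift * sigma, 0.0)
    gm = stream.normal(mu - delta, sigma, size=(v, n)).T
    wm = stream.normal(mu, sigma, size=(v, n)).T

    signals = np.stack(
        [_smoothed_unit_signal(stream, t) for _ in range(config.n_communities)]
    )
    lam = np.ones(n)
    if is_patient:
        lam = np.where(affected, 1.0 - config.coupling_drop, 1.0)
    comm = community_of(np.arange(n), config.n_communities)
    roi_series = lam[:, None] * signals[comm] + stream.normal(
        0.0, config.temporal_noise_sd, size=(n, t)
    )
    ts = roi_series[:, None, :] + stream.normal(
        0.0, config.voxel_noise_sd, size=(n, v, t)
    )
    return SubjectRaw(
        subject_id=subject_id, group=group, gm_values=gm, wm_values=wm, timeseries=ts
    )


def _subject_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([master_seed, 1 + index])


def simulate_cohort(
    atlas: AtlasPhantom, config: CohortConfig
) -> tuple[list[SubjectRaw], dict]:
    """Generate the full two-group cohort plus a reproducibility manifest.

    Controls come first (``sub-C###``), patients second (``sub-P###``);
    per-subject seed streams are derived deterministically from the master
    seed so any subject can be regenerated in isolation.
    """
    config.validate(atlas.n_rois)
    subjects: list[SubjectRaw] = []
    entries = []
    groups = [GROUP_CONTROL] * config.n_control + [GROUP_PATIENT] * config.n_patient
    n_c = 0
    n_p = 0
    for i, group in enumerate(groups):
        if group == GROUP_CONTROL:
            n_c += 1
            sid = f"sub-C{n_c:03d}"
        else:
            n_p += 1
            sid = f"sub-P{n_p:03d}"
        ss = _subject_seed(config.seed, i)
        subj = simulate_subject(
            atlas, group, config, np.random.default_rng(ss), subject_id=sid
        )
        subjects.append(subj)
        entries.append(
            {"subject_id": sid, "group": group, "label": subj.label,
             "seed_words": [config.seed, 1 + i]}
        )
    manifest = {
        "config": asdict(config),
        "n_rois": atlas.n_rois,
        "block_shape": list(atlas.block_shape),
        "baseline_hyperpriors": {
            "note": "invented per-ROI baselines: mu ~ Uniform(0.4, 0.8), sigma = 0.1, "
                    "drawn once per cohort; not derived from any empirical cohort",
            "mu_range": [_MU_LOW, _MU_HIGH],
            "sigma": _BASELINE_SD,
        },
        "subjects": entries,
    }
    return subjects, manifest


# --------------------------------------------------------------------------
# plain-text serialisation (one directory per subject)

def write_cohort(
    subjects: list[SubjectRaw], manifest: dict, out_dir: str | Path
) -> Path:
    """Write `gm.tsv`, `wm.tsv`, `ts_ROI_<k>.tsv` per subject + manifest.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for subj in subjects:
        d = out / subj.subject_id
        d.mkdir(exist_ok=True)
        np.savetxt(d / "gm.tsv", subj.gm_values, delimiter="\t")
        np.savetxt(d / "wm.tsv", subj.wm_values, delimiter="\t")
        for k in range(subj.n_rois):
            np.savetxt(d / f"ts_ROI_{k:04d}.tsv", subj.timeseries[k], delimiter="\t")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def read_cohort(in_dir: str | Path) -> tuple[list[SubjectRaw], dict]:
    """Inverse of :func:`write_cohort`."""
    root = Path(in_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    subjects = []
    for entry in manifest["subjects"]:
        d = root / entry["subject_id"]
        gm = np.loadtxt(d / "gm.tsv", delimiter="\t")
        wm = np.loadtxt(d / "wm.tsv", delimiter="\t")
        ts = np.stack(
            [np.loadtxt(d / f"ts_ROI_{k:04d}.tsv", delimiter="\t")
             for k in range(gm.shape[0])]
        )
        subjects.append(
            SubjectRaw(entry["subject_id"], entry["group"], gm, wm, ts)
        )
    return subjects, manifest
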