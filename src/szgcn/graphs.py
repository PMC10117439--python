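"""Assembly of brain-graph datasets: the 9-per-atlas graph-type grid.

Each subject becomes one :class:`BrainGraphSample` per
:class:`GraphTypeSpec` — a binary adjacency (proportionally thresholded
connectivity) paired with a node-feature matrix (3 structural, 3
functional, or all 6 columns).  Node features are z-scored with
statistics fitted on the training subjects only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import AtlasPhantom, SubjectRaw
from .connectome import (
    ConnectivityMatrix,
    fbm_matrix,
    gmm_fbm_matrix,
    gmm_matrix,
    min_sparsity,
    proportional_binarize,
)
from .features import ALL_COLUMNS, assemble_node_features

__all__ = [
    "EDGE_KINDS",
    "NODE_KINDS",
    "GraphTypeSpec",
    "BrainGraphSample",
    "enumerate_graph_types",
    "build_graph",
    "build_dataset",
    "FeatureScaler",
    "zscore_features",
]

EDGE_KINDS = ("GMM", "FBM", "GMM-FBM")
NODE_KINDS = ("sMRI", "fMRI", "sMRI+fMRI")


def _default_sparsity(atlas_n: int) -> float:
    if atlas_n == 90:
        return 0.10
    if atlas_n == 246:
        return 0.05
    return min_sparsity(atlas_n)


@dataclass(frozen=True)
class GraphTypeSpec:
    """One cell of the graph-type grid: atlas x edge kind x node kind."""

    atlas_n: int
    edge_kind: str
    node_kind: str
    sparsity: float | None = None

    def __post_init__(self) -> None:
        if self.edge_kind not in EDGE_KINDS:
            raise ValueError(f"edge_kind must be one of {EDGE_KINDS}")
        if self.node_kind not in NODE_KINDS:
            raise ValueError(f"node_kind must be one of {NODE_KINDS}")
        if self.sparsity is None:
            object.__setattr__(self, "sparsity", _default_sparsity(self.atlas_n))
        if not (0.0 < self.sparsity < 1.0):
            raise ValueError("sparsity must lie in (0, 1)")

    @property
    def n_node_features(self) -> int:
        return 6 if self.node_kind == "sMRI+fMRI" else 3

    @property
    def name(self) -> str:
        return f"N{self.atlas_n}:{self.edge_kind}&{self.node_kind}@{self.sparsity:g}"


@dataclass
class BrainGraphSample:
    """One subject's graph: binary adjacency + node features + class label."""

    adjacency: np.ndarray
    features: np.ndarray
    label: int
    subject_id: str
    spec: GraphTypeSpec

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        f = np.asarray(self.features, dtype=float)
        if a.shape[0] != a.shape[1] or a.shape[0] != f.shape[0]:
            raise ValueError("adjacency/features shape mismatch")
        if not np.allclose(np.diag(a), 0.0):
            raise ValueError("adjacency must have zero diagonal")
        if f.shape[1] != self.spec.n_node_features:
            raise ValueError(
                f"expected {self.spec.n_node_features} feature columns, got {f.shape[1]}"
            )
        if not np.all(np.isfinite(f)):
            raise ValueError("node features must be finite")
        self.adjacency = a
        self.features = f

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


def enumerate_graph_types(
    atlas_ns: list[int], sparsities: dict[int, float] | None = None
) -> list[GraphTypeSpec]:
    """All edge x node combinations per atlas, edge-kind major.

    Order per atlas: GMM&sMRI, GMM&fMRI, GMM&sMRI+fMRI, FBM&sMRI, ...,
    GMM-FBM&sMRI+fMRI (9 per atlas).
    """
    if not atlas_ns:
        raise ValueError("atlas list must be non-empty")
    sparsities = sparsities or {}
    return [
        GraphTypeSpec(n, edge, node, sparsities.get(n))
        for n in atlas_ns
        for edge in EDGE_KINDS
        for node in NODE_KINDS
    ]


def subject_matrices(
    subject: SubjectRaw, caches: dict | None = None
) -> dict[str, ConnectivityMatrix]:
    """Weighted GMM/FBM/GMM-FBM for one subject, memoised in ``caches``."""
    caches = caches if caches is not None else {}
    key = subject.subject_id
    if key not in caches:
        gmm = gmm_matrix(subject)
        fbm = fbm_matrix(subject)
        caches[key] = {
            "GMM": gmm,
            "FBM": fbm,
            "GMM-FBM": gmm_fbm_matrix(gmm, fbm),
        }
    return caches[key]


def build_graph(
    subject: SubjectRaw,
    spec: GraphTypeSpec,
    atlas: AtlasPhantom,
    caches: dict | None = None,
    tr: float = 2.0,
    constant: str = "error",
) -> BrainGraphSample:
    """One brain graph: thresholded edge matrix + selected node features.

    Degree-centrality columns are computed from the weighted matrices;
    binarisation applies only to the adjacency.
    """
    if subject.n_rois != spec.atlas_n:
        raise ValueError(
            f"{spec.name}: subject has {subject.n_rois} ROIs, spec wants {spec.atlas_n}"
        )
    mats = subject_matrices(subject, caches)
    binary = proportional_binarize(mats[spec.edge_kind], spec.sparsity)
    feats = assemble_node_features(
        subject,
        mats["GMM"],
        mats["FBM"],
        spec.node_kind,
        tr=tr,
        atlas=atlas,
        constant=constant,
    )
    return BrainGraphSample(
        adjacency=binary.values,
        features=feats.to_numpy(),
        label=subject.label,
        subject_id=subject.subject_id,
        spec=spec,
    )


def build_dataset(
    subjects: list[SubjectRaw],
    spec: GraphTypeSpec,
    atlas: AtlasPhantom,
    caches: dict | None = None,
    tr: float = 2.0,
    constant: str = "error",
) -> list[BrainGraphSample]:
    """Build one graph per subject for a single spec (shared matrix cache)."""
    caches = caches if caches is not None else {}
    return [
        build_graph(s, spec, atlas, caches=caches, tr=tr, constant=constant)
        for s in subjects
    ]


class FeatureScaler:
    """Per-column z-scoring fitted on training subjects only.

    One mean/SD per feature column, pooled across all nodes of all
    training subjects (not per ROI), preserving between-ROI contrasts.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.sd_: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.mean_ is not None

    def fit(self, samples: list[BrainGraphSample]) -> "FeatureScaler":
        if self.fitted:
            raise RuntimeError("scaler already fitted")
        if not samples:
            raise ValueError("training set is empty")
        stacked = np.concatenate([s.features for s in samples], axis=0)
        mean = stacked.mean(axis=0)
        sd = stacked.std(axis=0)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            cols = [ALL_COLUMNS[c] if len(mean) == 6 else str(c) for c in zero]
            raise ValueError(f"zero-variance feature column(s): {cols}")
        self.mean_, self.sd_ = mean, sd
        return self

    def transform(self, sample: BrainGraphSample) -> BrainGraphSample:
        if not self.fitted:
            raise RuntimeError("scaler not fitted")
        z = (sample.features - self.mean_) / self.sd_
        return BrainGraphSample(
            adjacency=sample.adjacency,
            features=z,
            label=sample.label,
            subject_id=sample.subject_id,
            spec=sample.spec,
        )


def zscore_features(
    dataset: list[BrainGraphSample], train_ids: set[str] | list[str]
) -> tuple[list[BrainGraphSample], FeatureScaler]:
    """Standardise every sample with statistics fitted on ``train_ids`` only."""
    train_ids = set(train_ids)
    train = [s for s in dataset if s.subject_id in train_ids]
    scaler = FeatureScaler().fit(train)
    return [scaler.transform(s) for s in dataset], scaler
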