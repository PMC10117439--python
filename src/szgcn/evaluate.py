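"""Repeated random-split evaluation, the sparsity sweep and cohort statistics.

The evaluation protocol mirrors the study design: the cohort is split
into training and testing portions at a 300:45 proportion (scaled to the
cohort size), the split is repeated with fresh randomisation, and six
metrics are averaged — accuracy, AUC, sensitivity, specificity, F1 and
precision, with the patient group as the positive class.

Also provides the two demographic-table statistics: Welch's
unequal-variance t from summary triples and the Yates
continuity-corrected chi-square of a 2x2 count table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .gcn import ModelConfig, TrainConfig, TrainedModel, predict_proba, train
from .graphs import BrainGraphSample, GraphTypeSpec, build_dataset, zscore_features

__all__ = [
    "SplitPlan",
    "MetricsReport",
    "confusion_metrics",
    "auc_rank",
    "make_split_plans",
    "repeated_split_eval",
    "sparsity_sweep",
    "welch_t",
    "chi2_yates",
    "TRAIN_PROPORTION",
]

#: training fraction of the repeated random splits (300 of 345 subjects).
TRAIN_PROPORTION = 300.0 / 345.0

METRIC_NAMES = ("accuracy", "auc", "sensitivity", "specificity", "f1", "precision")


@dataclass(frozen=True)
class SplitPlan:
    """One train/test partition of the cohort."""

    repeat_index: int
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")


@dataclass
class MetricsReport:
    """Per-repeat and mean metrics for one graph type."""

    spec_name: str
    per_repeat: pd.DataFrame
    confusions: list[dict]
    config: dict = field(default_factory=dict)

    @property
    def means(self) -> pd.Series:
        return self.per_repeat[list(METRIC_NAMES)].mean()

    def summary(self) -> str:
        lines = [f"Repeated-split evaluation: {self.spec_name}",
                 f"repeats: {len(self.per_repeat)}"]
        for name in METRIC_NAMES:
            vals = self.per_repeat[name]
            lines.append(f"  {name:<12s} {vals.mean():6.3f} +/- {vals.std(ddof=1):5.3f}")
        return "\n".join(lines)


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, precision and F1 from counts.

    The patient class is positive.  Ratios with zero denominators are
    reported as NaN (missing), never coerced to 0.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("counts must be non-negative")
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("empty confusion table")

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    sens = ratio(tp, tp + fn)
    prec = ratio(tp, tp + fp)
    if math.isnan(sens) or math.isnan(prec) or (prec + sens) == 0:
        f1 = float("nan")
    else:
        f1 = 2.0 * prec * sens / (prec + sens)
    return {
        "accuracy": (tp + tn) / total,
        "sensitivity": sens,
        "specificity": ratio(tn, tn + fp),
        "precision": prec,
        "f1": f1,
    }


def auc_rank(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve by the Mann-Whitney rank formulation.

    Equals the probability that a random positive outscores a random
    negative, ties counting one half.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for AUC")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def make_split_plans(
    subject_ids: list[str],
    labels: np.ndarray,
    n_repeats: int,
    master_seed: int,
    train_proportion: float = TRAIN_PROPORTION,
) -> list[SplitPlan]:
    """Stratified repeated random splits at the given train proportion.

    The test portion receives ``round(n_c * (1 - proportion))`` subjects
    per class (at least one); splits are disjoint and exhaustive.  Each
    repeat draws from a seed derived from ``master_seed``.
    """
    labels = np.asarray(labels)
    ids = np.asarray(subject_ids)
    plans = []
    for rep in range(n_repeats):
        seed_words = [master_seed, 0x5B11, rep]
        rng = np.random.default_rng(np.random.SeedSequence(seed_words))
        train_idx, test_idx = [], []
        for cls in np.unique(labels):
            members = np.flatnonzero(labels == cls)
            members = members[rng.permutation(members.size)]
            n_test = int(round((1.0 - train_proportion) * members.size))
            n_test = min(max(n_test, 1), members.size - 1)
            test_idx.extend(members[:n_test])
            train_idx.extend(members[n_test:])
        plans.append(
            SplitPlan(
                repeat_index=rep,
                train_ids=tuple(ids[sorted(train_idx)]),
                test_ids=tuple(ids[sorted(test_idx)]),
                seed=rep,
            )
        )
    return plans


def evaluate_split(
    dataset: list[BrainGraphSample],
    plan: SplitPlan,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    zscore: bool = True,
) -> tuple[dict[str, float], dict, TrainedModel]:
    """Train on one split and score the held-out subjects."""
    if zscore:
        scaled, _ = zscore_features(dataset, plan.train_ids)
    else:
        scaled = dataset
    model = train(scaled, plan.train_ids, model_cfg, train_cfg)
    by_id = {s.subject_id: s for s in scaled}
    test = [by_id[i] for i in plan.test_ids]
    y_true = np.array([s.label for s in test])
    proba = predict_proba(model, test)[:, 1]
    y_pred = (proba >= 0.5).astype(int)
    tp = int(((y_pred == 1) & (y_true == 1)).sum())
    fp = int(((y_pred == 1) & (y_true == 0)).sum())
    tn = int(((y_pred == 0) & (y_true == 0)).sum())
    fn = int(((y_pred == 0) & (y_true == 1)).sum())
    metrics = confusion_metrics(tp, fp, tn, fn)
    metrics["auc"] = auc_rank(y_true, proba)
    confusion = {"tp": tp, "fp": fp, "tn": tn, "fn": fn}
    return metrics, confusion, model


def repeated_split_eval(
    dataset: list[BrainGraphSample],
    n_repeats: int = 10,
    model_cfg: ModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
    master_seed: int = 0,
    zscore: bool = True,
    train_proportion: float = TRAIN_PROPORTION,
) -> MetricsReport:
    """Average the six metrics over stratified repeated random splits.

    Per repeat: split, fit the feature scaler on the training portion
    only, train, and score the test portion.  Every seed derives from
    ``master_seed`` and is recorded in the report.
    """
    model_cfg = model_cfg or ModelConfig()
    train_cfg = train_cfg or TrainConfig()
    ids = [s.subject_id for s in dataset]
    labels = np.array([s.label for s in dataset])
    plans = make_split_plans(ids, labels, n_repeats, master_seed, train_proportion)
    rows, confusions = [], []
    for plan in plans:
        rep_cfg = TrainConfig(
            **{**_cfg_dict(train_cfg),
               "seed": int(np.random.SeedSequence(
                   [master_seed, 0x7E57, plan.repeat_index]).generate_state(1)[0] % (2**31))}
        )
        metrics, confusion, _ = evaluate_split(dataset, plan, model_cfg, rep_cfg, zscore)
        rows.append({"repeat": plan.repeat_index, **metrics})
        confusions.append(confusion)
    per_repeat = pd.DataFrame(rows)
    spec = dataset[0].spec
    return MetricsReport(
        spec_name=spec.name,
        per_repeat=per_repeat,
        confusions=confusions,
        config={
            "n_repeats": n_repeats,
            "master_seed": master_seed,
            "zscore": zscore,
            "train_proportion": train_proportion,
            "model_cfg": vars(model_cfg) if hasattr(model_cfg, "__dict__") else str(model_cfg),
        },
    )


def _cfg_dict(cfg) -> dict:
    from dataclasses import asdict

    return asdict(cfg)


DEFAULT_SPARSITY_GRID = tuple(round(0.05 * i, 2) for i in range(1, 11))


def sparsity_sweep(
    subjects,
    spec: GraphTypeSpec,
    atlas,
    sparsities: tuple[float, ...] = DEFAULT_SPARSITY_GRID,
    n_repeats: int = 10,
    model_cfg: ModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
    master_seed: int = 0,
    caches: dict | None = None,
) -> pd.DataFrame:
    """Re-threshold the graphs at each sparsity and re-run the evaluation.

    The default grid is 5% to 50% in 5% steps.  Weighted matrices are
    computed once and cached; only the binarisation changes per point.
    """
    from dataclasses import replace

    caches = caches if caches is not None else {}
    rows = []
    for sp in sparsities:
        sp_spec = replace(spec, sparsity=sp)
        dataset = build_dataset(subjects, sp_spec, atlas, caches=caches)
        report = repeated_split_eval(
            dataset, n_repeats, model_cfg, train_cfg, master_seed
        )
        rows.append({"sparsity": sp, **report.means.to_dict()})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# demographic-table statistics

def welch_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> float:
    """Welch's unequal-variance t statistic from two summary triples."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    return float((mean1 - mean2) / math.sqrt(sd1**2 / n1 + sd2**2 / n2))


def chi2_yates(a: int, b: int, c: int, d: int) -> float:
    """Continuity-corrected Pearson chi-square of the 2x2 table [[a,b],[c,d]].

    Yates correction: sum of (|O - E| - 0.5)^2 / E over the four cells,
    with the correction floored at zero when |O - E| < 0.5.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    total = table.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero margin in 2x2 table")
    expected = np.outer(row, col) / total
    adj = np.maximum(np.abs(table - expected) - 0.5, 0.0)
    return float((adj**2 / expected).sum())
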