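"""Node saliency from the last pooling layer's selections.

For every training subject, a forward pass records which 20 regions have
the highest pooling scores among the survivors of the third pooling
layer.  A region's frequency is the number of training subjects for
which it is among those 20; its significance score is frequency divided
by the total number of selections (20 x n_train), so scores sum to one
and are bounded by 1/20.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gcn import TrainedModel, forward_trace
from .graphs import BrainGraphSample

__all__ = ["SELECTION_SIZE", "saliency_scores", "top_k_table"]

SELECTION_SIZE = 20


def saliency_scores(
    model: TrainedModel,
    train_graphs: list[BrainGraphSample],
    roi_names: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Selection-frequency saliency table over the training subjects.

    One deterministic forward pass per subject with the final weights
    (no dropout, batch-norm in inference mode).  Ties in the pooling
    score are broken by ascending node index.  Returns a table with
    columns (roi_index, roi_name, frequency, score, rank) sorted by
    score descending, ties by ascending roi_index.
    """
    if not train_graphs:
        raise ValueError("no training graphs supplied")
    n_nodes = train_graphs[0].n_nodes
    last = model.model_cfg.survivor_counts(n_nodes)[-1]
    if last < SELECTION_SIZE:
        raise ValueError(
            f"last pooling layer retains {last} < {SELECTION_SIZE} nodes; "
            f"increase pool_ratio (currently {model.model_cfg.pool_ratio})"
        )
    freq = np.zeros(n_nodes, dtype=int)
    for sample in train_graphs:
        _, selections = forward_trace(model, sample)
        final = selections[-1]
        scores = final["scores"]
        indices = final["indices"]
        order = np.lexsort((indices, -scores))[:SELECTION_SIZE]
        freq[indices[order]] += 1
    denom = SELECTION_SIZE * len(train_graphs)
    if roi_names is None:
        width = max(3, len(str(n_nodes)))
        roi_names = tuple(f"ROI_{i + 1:0{width}d}" for i in range(n_nodes))
    table = pd.DataFrame(
        {
            "roi_index": np.arange(n_nodes),
            "roi_name": list(roi_names),
            "frequency": freq,
            "score": freq / denom,
        }
    )
    table = table.sort_values(
        ["score", "roi_index"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, n_nodes + 1)
    table.attrs["n_train"] = len(train_graphs)
    table.attrs["denominator"] = denom
    return table


def top_k_table(table: pd.DataFrame, k: int) -> pd.DataFrame:
    """First ``k`` rows of the saliency table (ties already index-broken)."""
    if k > len(table):
        raise ValueError(f"k = {k} exceeds table length {len(table)}")
    return table.iloc[:k].reset_index(drop=True)
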