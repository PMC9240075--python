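"""Benchmarking of reconstructions against simulated ground truth.

Reconstruction quality is measured with the adjusted Rand index (ARI)
between the true IS-to-clone partition and the reconstructed clustering,
restricted to the IS that survived filtering; per-clone precision/recall
mirror the in vitro validation, and the sweep harness maps ARI over grids
of simulator parameters with median/quartile summaries.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .cluster import KRange, select_best_clustering
from .io_model import ClusteringResult
from .similarity import FilterSpec, filter_is, similarity_matrix
from .simulate import ISMap, SimulationConfig, simulate

__all__ = [
    "adjusted_rand_index",
    "precision_recall",
    "CloneScore",
    "sweep",
    "summarize_sweep",
]


def adjusted_rand_index(truth: Mapping[str, object] | Sequence,
                        pred: Mapping[str, object] | Sequence) -> float:
    """Chance-corrected agreement of two partitions of the same items.

    Accepts either two equal-length label sequences or two mappings
    item -> label over the same item set; 1 means identical partitions up
    to relabeling, 0 is the chance level.
    """
    if isinstance(truth, Mapping) != isinstance(pred, Mapping):
        raise ValueError("truth and pred must both be mappings or both sequences")
    if isinstance(truth, Mapping):
        if set(truth) != set(pred):
            raise ValueError("truth and pred cover different items")
        items = sorted(truth)
        a = [truth[i] for i in items]
        b = [pred[i] for i in items]
    else:
        if len(truth) != len(pred):
            raise ValueError("label sequences differ in length")
        a, b = list(truth), list(pred)
    a = pd.factorize(np.asarray(a, dtype=object))[0]
    b = pd.factorize(np.asarray(b, dtype=object))[0]
    return float(adjusted_rand_score(a, b))


@dataclass(frozen=True)
class CloneScore:
    """Precision/recall of one true clone against its best-matching cluster."""

    clone_id: str
    matched_cluster: int
    precision: float
    recall: float
    n_is_observed: int


def precision_recall(truth: ISMap | Mapping[str, str],
                     pred: ClusteringResult) -> list[CloneScore]:
    """Match every true clone to the predicted cluster sharing most of its IS.

    TP = overlap with the matched cluster, FP = rest of that cluster,
    FN = the clone's observed IS outside it.  Ties between clusters go to
    the larger cluster, then to the smaller label.  Clones with no observed
    IS are excluded.
    """
    clone_of = truth.clone_of if isinstance(truth, ISMap) else dict(truth)
    covered = set(pred.is_ids)
    extra = covered - set(clone_of)
    if extra:
        raise ValueError(f"prediction contains IS missing from truth: {sorted(extra)[:3]}")
    label_of = dict(zip(pred.is_ids, pred.labels))
    cluster_size = {l: len(pred.members(l)) for l in range(1, pred.k + 1)}
    scores = []
    for cid in sorted(set(clone_of.values())):
        observed = [i for i, c in clone_of.items() if c == cid and i in covered]
        if not observed:
            continue  # clone has no observed IS: excluded with note
        overlap: dict[int, int] = {}
        for i in observed:
            overlap[label_of[i]] = overlap.get(label_of[i], 0) + 1
        best = min(
            overlap,
            key=lambda l: (-overlap[l], -cluster_size[l], l),
        )
        tp = overlap[best]
        fp = cluster_size[best] - tp
        fn = len(observed) - tp
        scores.append(
            CloneScore(
                clone_id=cid,
                matched_cluster=best,
                precision=tp / (tp + fp),
                recall=tp / (tp + fn),
                n_is_observed=len(observed),
            )
        )
    return scores


# ---------------------------------------------------------------------------
# Parameter-sweep harness
# ---------------------------------------------------------------------------

def _replicate_seed(base_seed: int, grid_index: int, rep: int) -> int:
    """Deterministic per-replicate seed below 2**31."""
    ss = np.random.SeedSequence(entropy=base_seed,
                                spawn_key=(grid_index, rep))
    return int(ss.generate_state(1)[0] % (2**31))


def run_reconstruction(config: SimulationConfig,
                       filter_spec: FilterSpec | None = None,
                       k_range: KRange | None = None) -> dict:
    """One simulate -> filter -> similarity -> cluster -> ARI run."""
    result = simulate(config)
    kept, _ = filter_is(result.observed, filter_spec or FilterSpec())
    s = similarity_matrix(kept)
    clustering = select_best_clustering(s, k_range)
    true_labels = result.is_map.labels_for(kept.is_ids)
    ari = adjusted_rand_index(true_labels, list(clustering.labels))
    return {
        "ari": ari,
        "n_clones_true": len(set(true_labels)),
        "n_clones_reconstructed": clustering.k,
        "n_is_filtered": len(kept.is_ids),
        "silhouette": clustering.silhouette,
    }


def sweep(base_config: SimulationConfig,
          vary: Mapping[str, Sequence],
          replicates: int = 20,
          filter_spec: FilterSpec | None = None,
          k_range: KRange | None = None) -> pd.DataFrame:
    """Run the full pipeline over a parameter grid with seeded replicates.

    ``vary`` maps SimulationConfig field names to value lists; the grid is
    their Cartesian product.  Replicate seeds derive deterministically from
    the base config's seed, the grid index and the replicate number.  A
    failed replicate is recorded with ARI = NaN and the error message.
    """
    if not vary:
        raise ValueError("vary must name at least one parameter")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    names = list(vary)
    grid = list(itertools.product(*(vary[n] for n in names)))
    records = []
    for gi, point in enumerate(grid):
        overrides = dict(zip(names, point))
        for rep in range(replicates):
            seed = _replicate_seed(base_config.seed, gi, rep)
            config = replace(base_config, seed=seed, **overrides)
            rec = {**overrides, "replicate": rep, "seed": seed}
            try:
                rec.update(run_reconstruction(config, filter_spec, k_range))
                rec["error"] = ""
            except Exception as exc:  # noqa: BLE001 - recorded, not raised
                rec.update(
                    ari=np.nan, n_clones_true=np.nan,
                    n_clones_reconstructed=np.nan, n_is_filtered=np.nan,
                    silhouette=np.nan, error=str(exc),
                )
            records.append(rec)
    return pd.DataFrame.from_records(records)


def summarize_sweep(results: pd.DataFrame,
                    by: Sequence[str]) -> pd.DataFrame:
    """Median and quartiles of ARI per grid point (as the figures report)."""
    def q1(x):
        return x.quantile(0.25)

    def q3(x):
        return x.quantile(0.75)

    grouped = results.groupby(list(by))["ari"]
    out = grouped.agg(median="median", q1=q1, q3=q3, n="count")
    return out.reset_index()
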