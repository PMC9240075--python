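"""Clone-level abundance reconstruction and weak-assignment flagging.

Every IS of a clone independently estimates the clone's relative size, so a
clone's abundance is the arithmetic mean of its member IS abundances.  IS
that did not pass the filter are pooled into a "background" row whose mass
is divided by the mean number of IS per reconstructed clone — without this
correction each of the many minor IS would be counted as a full clone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import KRange, pam, select_best_clustering
from .io_model import (
    AbundanceMatrix,
    ClonalAbundanceMatrix,
    ClusteringResult,
    SimilarityMatrix,
)
from .similarity import FilterSpec, filter_is, similarity_matrix

__all__ = [
    "clonal_abundance",
    "flag_weak_assignments",
    "PipelineResult",
    "reconstruct_pipeline",
]

BACKGROUND_ID = "background"


def clonal_abundance(a_kept: AbundanceMatrix, a_dropped: AbundanceMatrix,
                     c: ClusteringResult,
                     mean_is_per_clone: float | None = None
                     ) -> ClonalAbundanceMatrix:
    """Average member-IS abundances per cluster and correct the background.

    ``mean_is_per_clone`` overrides the in-sample mean cluster size (e.g.
    with a vector copy number measured experimentally).
    """
    if sorted(c.is_ids) != sorted(a_kept.is_ids):
        raise ValueError("clustering must cover exactly the kept IS")
    kept = a_kept.abundance
    rows = {}
    for label in range(1, c.k + 1):
        members = c.members(label)
        if not members:
            raise ValueError(f"cluster {label} is empty")
        rows[f"clone{label}"] = kept.loc[members].mean(axis=0)
    m_bar = (float(mean_is_per_clone) if mean_is_per_clone is not None
             else len(c.is_ids) / c.k)
    if m_bar <= 0:
        raise ValueError("mean IS per clone must be positive")
    if len(a_dropped.is_ids):
        rows[BACKGROUND_ID] = a_dropped.abundance.sum(axis=0) / m_bar
    else:
        rows[BACKGROUND_ID] = pd.Series(0.0, index=kept.columns)
    df = pd.DataFrame(rows).T
    totals = df.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ValueError(f"no clonal mass in column {bad!r}")
    return ClonalAbundanceMatrix(df / totals, a_kept.samples)


def flag_weak_assignments(s: SimilarityMatrix, c: ClusteringResult,
                          gap: float = 0.3) -> list[str]:
    """Flag cluster members separated from the rest by a similarity gap.

    For every cluster with >= 3 members, each member's mean similarity to
    the other members is computed; if the largest consecutive gap in the
    sorted values exceeds ``gap``, the members below the gap are flagged.
    This surfaces the typical misassignment of single-IS clones that were
    absorbed into another clone's cluster.  Flagged IS are reported for
    inspection, never reassigned automatically.
    """
    if s.is_ids != c.is_ids:
        raise ValueError("similarity matrix and clustering have different IS ids")
    vals = s.values_df
    flagged: list[str] = []
    for label in range(1, c.k + 1):
        members = c.members(label)
        if len(members) < 3:
            continue
        mean_sim = {
            m: float(vals.loc[m, [o for o in members if o != m]].mean())
            for m in members
        }
        ordered = sorted(members, key=lambda m: (mean_sim[m], m))
        sims = np.array([mean_sim[m] for m in ordered])
        gaps = np.diff(sims)
        if len(gaps) == 0:
            continue
        i_star = int(np.argmax(gaps))
        if gaps[i_star] > gap:
            flagged.extend(ordered[: i_star + 1])
    return sorted(flagged)


@dataclass
class PipelineResult:
    """Everything one reconstruction run produced."""

    kept: AbundanceMatrix
    dropped: AbundanceMatrix
    similarity: SimilarityMatrix
    clustering: ClusteringResult
    clones: ClonalAbundanceMatrix
    flags: list[str]


def reconstruct_pipeline(a: AbundanceMatrix,
                         filter_spec: FilterSpec | None = None,
                         k_range: KRange | None = None,
                         k: int | None = None,
                         mean_is_per_clone: float | None = None,
                         flag_gap: float = 0.3) -> PipelineResult:
    """Filter -> similarity -> cluster -> clonal abundances, in one call.

    ``k`` forces a fixed number of clusters; otherwise the silhouette
    optimum over ``k_range`` is used.
    """
    kept, dropped = filter_is(a, filter_spec or FilterSpec())
    s = similarity_matrix(kept)
    if k is not None:
        clustering = pam(s, k)
    else:
        clustering = select_best_clustering(s, k_range)
    clones = clonal_abundance(kept, dropped, clustering, mean_is_per_clone)
    flags = flag_weak_assignments(s, clustering, flag_gap)
    return PipelineResult(kept, dropped, s, clustering, clones, flags)
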