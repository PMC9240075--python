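"""Filtering of IS abundance series and pairwise R-squared similarity.

Two IS of the same clone are carried by the same cells, so their relative
abundances stay proportional across measurements; the squared Pearson
correlation (the R-squared of a simple linear regression with intercept)
of two IS series is therefore close to 1 for clone-mates and lower for IS
of different clones.  Filtering restricts the analysis to the abundant IS
where this signal is quantifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_model import AbundanceMatrix, SimilarityMatrix

__all__ = ["FilterSpec", "filter_is", "pairwise_r2", "similarity_matrix"]

_MODES = ("top_n_final", "threshold_any", "threshold_final")


@dataclass
class FilterSpec:
    """Which IS enter the similarity analysis.

    top_n_final    — the ``n`` largest IS at the final measurement(s)
    threshold_any  — IS above ``threshold`` in at least one measurement
    threshold_final— IS above ``threshold`` in at least one final measurement

    ``final_samples`` defaults to the last column of the table, matching the
    "final time point" convention.
    """

    mode: str = "top_n_final"
    n: int = 50
    threshold: float = 0.01
    final_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.n < 1:
            raise ValueError("n must be positive")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")


def _final_columns(a: AbundanceMatrix, spec: FilterSpec) -> list[str]:
    if spec.final_samples:
        missing = [s for s in spec.final_samples if s not in a.sample_ids]
        if missing:
            raise ValueError(f"unknown final sample(s): {missing}")
        return list(spec.final_samples)
    return [a.sample_ids[-1]]


def filter_is(a: AbundanceMatrix, spec: FilterSpec
              ) -> tuple[AbundanceMatrix, AbundanceMatrix]:
    """Split ``a`` into (kept, dropped) rows without renormalizing either."""
    df = a.abundance
    if spec.mode == "top_n_final":
        finals = _final_columns(a, spec)
        score = df[finals].max(axis=1)
        if spec.n >= len(df):
            kept_ids = list(df.index)
        else:
            # rank by final abundance, ties broken by lexicographic IS id
            order = sorted(df.index, key=lambda i: (-score.loc[i], str(i)))
            kept_ids = sorted(order[: spec.n], key=list(df.index).index)
    elif spec.mode == "threshold_any":
        kept_ids = list(df.index[(df > spec.threshold).any(axis=1)])
    else:  # threshold_final
        finals = _final_columns(a, spec)
        kept_ids = list(df.index[(df[finals] > spec.threshold).any(axis=1)])
    if not kept_ids:
        raise ValueError(
            "no IS passed the filter; lower the threshold or check the input"
        )
    dropped_ids = [i for i in df.index if i not in set(kept_ids)]
    return a.subset(kept_ids), a.subset(dropped_ids)


def pairwise_r2(x, y) -> float:
    """R-squared of a linear regression (with intercept) of y on x.

    Equals the squared Pearson correlation, hence symmetric in (x, y).
    A zero-variance vector carries no co-fluctuation evidence and returns 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 measurements for a regression")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("NaN in input vector")
    xd = x - x.mean()
    yd = y - y.mean()
    sxx = float(xd @ xd)
    syy = float(yd @ yd)
    if sxx == 0.0 or syy == 0.0:
        return 0.0
    r = float(xd @ yd) / np.sqrt(sxx * syy)
    return min(r * r, 1.0)


def similarity_matrix(a: AbundanceMatrix) -> SimilarityMatrix:
    """All-pairs R-squared of the rows of ``a`` as the matrix S."""
    vals = a.values
    n, m = vals.shape
    if n < 2:
        raise ValueError("need at least 2 IS")
    if m < 3:
        raise ValueError("need at least 3 measurements")
    if np.isnan(vals).any():
        raise ValueError("NaN in abundance matrix")
    sd = vals.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(vals)
    s = np.square(np.nan_to_num(corr, nan=0.0))
    s[sd == 0.0, :] = 0.0  # zero-variance convention
    s[:, sd == 0.0] = 0.0
    np.fill_diagonal(s, 1.0)
    s = np.clip((s + s.T) / 2.0, 0.0, 1.0)
    df = pd.DataFrame(s, index=a.is_ids, columns=a.is_ids)
    return SimilarityMatrix(df)
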