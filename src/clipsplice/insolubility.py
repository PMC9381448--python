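"""Proteomic insolubility enrichment screen with a shuffled-label null.

Label-free quantification (LFQ) intensities of the detergent-insoluble
fraction are compared between a target group (ALS) and controls.  For
each protein:

* fold change = mean(LFQ + 1)_target / mean(LFQ + 1)_control -- the +1
  pseudocount handles proteins undetected (intensity 0) in one group;
* significance = two-sided Welch's t test on log2(LFQ + 1).

A protein is a hit when P < p_max and fold change >= fc_min (defaults
0.05 and 1.5).  The specificity control re-runs the identical screen on
every mixed relabeling that puts half of each group on either side
(3 ALS + 3 Ctrl vs the remaining 3 + 3 for a 6v6 design) and reports how
the true-label hit count compares with that null distribution.
"""

from __future__ import annotations

import itertools
import operator
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from scipy import stats as sps

__all__ = ["LFQMatrix", "InsolubilityHit", "ShuffleNull", "insolubility_screen", "shuffle_null"]


@dataclass(frozen=True)
class LFQMatrix:
    """Protein x sample intensity matrix with a two-group sample labeling."""

    intensities: pd.DataFrame  # rows: proteins, columns: samples
    groups: pd.Series  # sample -> group label
    target: str
    control: str

    def __post_init__(self) -> None:
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("negative LFQ intensities")
        missing = [s for s in self.intensities.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without group labels: {missing}")
        for g in (self.target, self.control):
            if (self.groups == g).sum() < 2:
                raise ValueError(f"group {g!r} needs >= 2 samples")

    def samples_of(self, group: str) -> list[str]:
        return [s for s in self.intensities.columns if self.groups[s] == group]


@dataclass(frozen=True)
class InsolubilityHit:
    protein: str
    fold_change: float
    p_welch: float
    is_hit: bool


@dataclass(frozen=True)
class ShuffleNull:
    hit_counts: tuple[int, ...]
    mean_null: float
    observed: int
    fold_observed_over_null: float


def _screen_arrays(
    target_vals: np.ndarray, control_vals: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-protein fold changes and Welch P on log2(x+1).

    Proteins with zero variance in both groups after the transform are
    degenerate and get P = 1.
    """
    fc = (target_vals + 1).mean(axis=1) / (control_vals + 1).mean(axis=1)
    lt = np.log2(target_vals + 1)
    lc = np.log2(control_vals + 1)
    degenerate = (np.ptp(lt, axis=1) == 0) & (np.ptp(lc, axis=1) == 0)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        _, pvals = sps.ttest_ind(lt, lc, axis=1, equal_var=False)
    pvals = np.asarray(pvals, dtype=float)
    pvals[degenerate | ~np.isfinite(pvals)] = 1.0
    return fc, pvals


def insolubility_screen(
    matrix: LFQMatrix,
    fc_min: float = 1.5,
    p_max: float = 0.05,
    fc_comparator: Callable[[float, float], bool] = operator.ge,
) -> list[InsolubilityHit]:
    """Per-protein fold change + Welch P; hits flagged at the default cutoffs.

    The fold-change comparator is inclusive (>= 1.5) by default and
    exposed for the strict variant.  Proteins with zero variance in both
    groups after the log transform get P = 1.
    """
    t_cols = matrix.samples_of(matrix.target)
    c_cols = matrix.samples_of(matrix.control)
    tv = matrix.intensities[t_cols].to_numpy(dtype=float)
    cv = matrix.intensities[c_cols].to_numpy(dtype=float)
    fc, pvals = _screen_arrays(tv, cv)
    return [
        InsolubilityHit(
            protein=str(prot),
            fold_change=float(f),
            p_welch=float(p),
            is_hit=bool(p < p_max and fc_comparator(f, fc_min)),
        )
        for prot, f, p in zip(matrix.intensities.index, fc, pvals)
    ]


def hits_frame(hits: Sequence[InsolubilityHit]) -> pd.DataFrame:
    """Volcano-ready table: log2 fold change and -log10 P per protein."""
    df = pd.DataFrame([h.__dict__ for h in hits]).set_index("protein")
    df["log2_fc"] = np.log2(df["fold_change"])
    df["neg_log10_p"] = -np.log10(df["p_welch"].clip(lower=1e-300))
    return df


def shuffle_null(
    matrix: LFQMatrix,
    fc_min: float = 1.5,
    p_max: float = 0.05,
    fc_comparator: Callable[[float, float], bool] = operator.ge,
) -> ShuffleNull:
    """Exhaustive mixed-split label shuffle null for the screen.

    Every split takes half of the target samples plus half of the control
    samples as the pseudo-target group and compares it with the remaining
    half of each group, re-running the identical screen.  Any relabeling
    identical to the true labels (or their swap) is excluded; for a 6v6
    design this enumerates all C(6,3)^2 = 400 mixed splits, none of which
    is label-faithful.
    """
    t_cols = matrix.samples_of(matrix.target)
    c_cols = matrix.samples_of(matrix.control)
    if len(t_cols) % 2 or len(c_cols) % 2:
        raise ValueError("shuffle null needs evenly splittable group sizes")
    half_t, half_c = len(t_cols) // 2, len(c_cols) // 2
    X = matrix.intensities.to_numpy(dtype=float)
    col_index = {s: i for i, s in enumerate(matrix.intensities.columns)}
    t_idx = [col_index[s] for s in t_cols]
    c_idx = [col_index[s] for s in c_cols]
    true_set = frozenset(t_idx)

    observed_hits = sum(h.is_hit for h in insolubility_screen(matrix, fc_min, p_max, fc_comparator))

    counts = []
    for sub_t in itertools.combinations(t_idx, half_t):
        rest_t = [i for i in t_idx if i not in sub_t]
        for sub_c in itertools.combinations(c_idx, half_c):
            rest_c = [i for i in c_idx if i not in sub_c]
            pseudo_target = list(sub_t) + list(sub_c)
            pseudo_control = rest_t + rest_c
            if frozenset(pseudo_target) == true_set or frozenset(pseudo_control) == true_set:
                continue  # label-faithful relabeling
            fc, pvals = _screen_arrays(X[:, pseudo_target], X[:, pseudo_control])
            n_hits = int(
                np.sum((pvals < p_max) & np.array([fc_comparator(f, fc_min) for f in fc]))
            )
            counts.append(n_hits)
    mean_null = float(np.mean(counts))
    ratio = float("inf") if mean_null == 0 else observed_hits / mean_null
    return ShuffleNull(tuple(counts), mean_null, observed_hits, ratio)
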