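"""Multi-dataset dPSI matrix assembly, k-means clustering, and GOF/LOF calls.

Events significant in at least one anchor dataset (e.g. the ALS patient
comparisons) form the rows; columns are dPSI values per dataset, with 0
imputed where an event did not pass coverage in a dataset (an imputation
mask is kept so summaries can exclude imputed cells).  Clusters of events
are then characterized by per-dataset median dPSI and classified against
the perturbation datasets: a loss-of-function (LOF) signature moves the
disease datasets the same way as the knockout and opposite to the
overexpression; gain-of-function (GOF) is the mirror image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .as_events import ASEvent
from .clip_peaks import Peak
from .splice_enrichment import EnrichmentResult, region_enrichment, REGION_LABELS

__all__ = [
    "ClusterConfig",
    "DpsiMatrix",
    "assemble_matrix",
    "run_kmeans",
    "cluster_medians",
    "classify_signature",
    "cluster_positional_enrichment",
]


@dataclass(frozen=True)
class ClusterConfig:
    k: int = 8
    n_init: int = 10
    max_iter: int = 300
    seed: int = 42
    init: str = "random"


@dataclass
class DpsiMatrix:
    """dPSI values (rows: event keys, columns: datasets) plus imputation mask."""

    values: pd.DataFrame
    observed: pd.DataFrame  # boolean, False where 0 was imputed
    events: dict[str, ASEvent] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.observed.index) or not self.values.columns.equals(
            self.observed.columns
        ):
            raise ValueError("values and observed mask must align")


def assemble_matrix(
    datasets: Mapping[str, Mapping[str, ASEvent]],
    anchors: Sequence[str],
    fdr_max: float = 0.05,
    min_abs_dpsi: float = 0.1,
) -> DpsiMatrix:
    """Build the event x dataset dPSI matrix.

    ``datasets`` maps dataset name -> {event_key: coverage-passed event}.
    Rows are the union of events significant in >= 1 anchor dataset;
    entries where the event is absent from a dataset are imputed 0 with
    the mask bit cleared.
    """
    if not anchors:
        raise ValueError("at least one anchor dataset required")
    for a in anchors:
        if a not in datasets:
            raise KeyError(f"anchor {a!r} not among datasets")
    row_keys: list[str] = []
    seen = set()
    for a in anchors:
        indexed = datasets[a]
        for key, ev in indexed.items():
            if ev.fdr < fdr_max and abs(ev.inc_level_difference) > min_abs_dpsi and key not in seen:
                seen.add(key)
                row_keys.append(key)
    if not row_keys:
        raise ValueError("no significant events in any anchor dataset")
    cols = list(datasets)
    values = np.zeros((len(row_keys), len(cols)))
    observed = np.zeros_like(values, dtype=bool)
    events: dict[str, ASEvent] = {}
    for j, name in enumerate(cols):
        table = datasets[name]
        for i, key in enumerate(row_keys):
            ev = table.get(key)
            if ev is not None:
                values[i, j] = ev.inc_level_difference
                observed[i, j] = True
                events.setdefault(key, ev)
    idx = pd.Index(row_keys, name="event_key")
    return DpsiMatrix(
        pd.DataFrame(values, index=idx, columns=cols),
        pd.DataFrame(observed, index=idx, columns=cols),
        events,
    )


def run_kmeans(matrix: DpsiMatrix, cfg: ClusterConfig = ClusterConfig()):
    """K-means on the imputed dPSI matrix; deterministic for a fixed seed.

    Returns (labels: pd.Series indexed like the matrix, model: fitted KMeans).
    """
    X = matrix.values.to_numpy()
    if cfg.k > X.shape[0]:
        raise ValueError(f"k={cfg.k} exceeds number of rows {X.shape[0]}")
    km = KMeans(
        n_clusters=cfg.k,
        init=cfg.init,
        n_init=cfg.n_init,
        max_iter=cfg.max_iter,
        random_state=cfg.seed,
    )
    labels = km.fit_predict(X)
    return pd.Series(labels, index=matrix.values.index, name="cluster"), km


def cluster_medians(matrix: DpsiMatrix, labels: pd.Series) -> pd.DataFrame:
    """Per-cluster, per-dataset median dPSI.

    Medians use only observed (non-imputed) entries when >= 50% of a
    cluster's entries in that dataset are observed; otherwise the median
    is over all entries and the cell is flagged in the companion
    ``imputed_median`` attribute (stored in ``DataFrame.attrs``).
    """
    vals = matrix.values
    obs = matrix.observed
    out = {}
    flagged = {}
    for cid, idx in labels.groupby(labels).groups.items():
        sub_v = vals.loc[idx]
        sub_o = obs.loc[idx]
        med = {}
        flag = {}
        for col in vals.columns:
            col_obs = sub_o[col]
            if col_obs.mean() >= 0.5:
                med[col] = float(sub_v.loc[col_obs, col].median())
                flag[col] = False
            else:
                med[col] = float(sub_v[col].median())
                flag[col] = True
        out[cid] = med
        flagged[cid] = flag
    medians = pd.DataFrame(out).T.sort_index()
    medians.index.name = "cluster"
    medians.attrs["imputed_median"] = pd.DataFrame(flagged).T.sort_index()
    return medians


def classify_signature(
    medians: Mapping[str, float],
    als_cols: Sequence[str],
    oe_col: str,
    ko_col: str,
    min_magnitude: float = 0.025,
) -> str:
    """Label one cluster's median pattern as LOF / GOF / dataset_specific / no_change / mixed.

    LOF: disease datasets agree in sign with the knockout and oppose the
    overexpression (all at |median| >= min_magnitude).  GOF mirrors this.
    dataset_specific: disease medians disagree in sign but at least one is
    material. no_change: everything below magnitude.  mixed: the rest.
    """
    for col in list(als_cols) + [oe_col, ko_col]:
        if col not in medians:
            raise KeyError(f"missing median for column {col!r}")
    als = np.array([medians[c] for c in als_cols], dtype=float)
    oe = float(medians[oe_col])
    ko = float(medians[ko_col])
    if np.all(np.abs(als) < min_magnitude) and abs(oe) < min_magnitude and abs(ko) < min_magnitude:
        return "no_change"
    als_signs = np.sign(als)
    als_agree = np.all(als_signs == als_signs[0]) and np.all(np.abs(als) >= min_magnitude)
    if als_agree:
        s = als_signs[0]
        if abs(ko) >= min_magnitude and abs(oe) >= min_magnitude:
            if np.sign(ko) == s and np.sign(oe) == -s:
                return "LOF"
            if np.sign(oe) == s and np.sign(ko) == -s:
                return "GOF"
        return "mixed"
    if not np.all(als_signs == als_signs[0]) and np.any(np.abs(als) >= min_magnitude):
        return "dataset_specific"
    return "mixed"


def cluster_positional_enrichment(
    matrix: DpsiMatrix,
    labels: pd.Series,
    peaks: Sequence[Peak],
    background_events: Sequence[ASEvent],
    regions: Sequence[str] = REGION_LABELS[:5],
) -> pd.DataFrame:
    """Hypergeometric peak enrichment per cluster per sub-region.

    Background = all coverage-passed events of the anchor datasets.
    Empty clusters yield flagged rows with NaN P.
    """
    rows = []
    for cid in sorted(labels.unique()):
        keys = labels.index[labels == cid]
        cluster_events = [matrix.events[k] for k in keys if k in matrix.events]
        for region in regions:
            if not cluster_events:
                rows.append(
                    {"cluster": cid, "region": region, "p_hypergeom": float("nan"), "flag": "empty"}
                )
                continue
            res = region_enrichment(
                cluster_events, list(background_events), peaks, region, direction="all"
            )
            rows.append(
                {
                    "cluster": cid,
                    "region": region,
                    "n_selected": res.n_selected,
                    "k_selected": res.k_selected,
                    "k_background": res.k_background,
                    "fold_enrichment": res.fold_enrichment,
                    "p_hypergeom": res.p_hypergeom,
                    "flag": "",
                }
            )
    return pd.DataFrame(rows)
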