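"""Microarray co-expression selection pipeline.

Implements the comparative transcriptome workflow used to nominate
transcription-factor regulators of starch biosynthesis:

1. three-step normalization (floor to 5, per-chip scaling to the 50th
   percentile, per-feature scaling to the median across the dataset);
2. volcano-plot differential selection per experiment (fold change >= 2
   and a Welch t-test on log2 ratios, Benjamini-Hochberg FDR correction
   applied only for experiments with >= 4 replicates);
3. intersection of the per-experiment feature sets (Venn regions);
4. K-means clustering of the intersected features under Pearson
   correlation distance (k = 5 by default), realised as Euclidean K-means
   on row-standardized profiles;
5. selection of the clusters carrying marker genes, functional
   composition summaries, and ranking of transcription-factor candidates
   by correlation with the marker mean profile.

Expression matrices are pandas DataFrames with feature ids as the index
and sample ids as columns; the design table maps each sample to an
(experiment, condition, replicate).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExperimentDesign",
    "NormalizedMatrix",
    "ClusterResult",
    "normalize",
    "select_differential",
    "bh_adjust",
    "intersect_feature_sets",
    "cluster_kmeans_pearson",
    "select_clusters",
    "summarize_function",
    "extract_tf_candidates",
]

DEFAULT_FLOOR = 5.0
DEFAULT_CHIP_PERCENTILE = 50.0
DEFAULT_FC_CUTOFF = 2.0
DEFAULT_ALPHA = 0.05
BH_MIN_REPLICATES = 4  # correction applied only for >= 4 biological replicates


@dataclass
class ExperimentDesign:
    """Sample annotation: one row per sample with experiment/condition/replicate.

    ``table`` columns: sample, experiment, condition, replicate. Every
    experiment must carry at least two replicates per condition.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample", "experiment", "condition", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        if self.table["sample"].duplicated().any():
            raise ValueError("each sample must map to exactly one experiment/condition")
        reps = self.table.groupby(["experiment", "condition"])["sample"].count()
        if (reps < 2).any():
            bad = reps[reps < 2].index.tolist()
            raise ValueError(f"conditions with < 2 replicates: {bad}")

    def experiments(self) -> list[str]:
        return list(dict.fromkeys(self.table["experiment"]))

    def conditions(self, experiment: str) -> list[str]:
        sub = self.table[self.table["experiment"] == experiment]
        if sub.empty:
            raise KeyError(f"unknown experiment {experiment!r}")
        return list(dict.fromkeys(sub["condition"]))

    def samples(self, experiment: str, condition: str | None = None) -> list[str]:
        sub = self.table[self.table["experiment"] == experiment]
        if condition is not None:
            sub = sub[sub["condition"] == condition]
        return list(sub["sample"])

    def replicate_count(self, experiment: str) -> int:
        """Replicates per condition for an experiment (minimum over conditions)."""
        sub = self.table[self.table["experiment"] == experiment]
        if sub.empty:
            raise KeyError(f"unknown experiment {experiment!r}")
        return int(sub.groupby("condition")["sample"].count().min())


@dataclass
class NormalizedMatrix:
    """Normalized ratios plus the provenance of the three normalization steps."""

    values: pd.DataFrame
    provenance: dict = field(default_factory=dict)


def normalize(
    raw: pd.DataFrame,
    floor: float = DEFAULT_FLOOR,
    chip_percentile: float = DEFAULT_CHIP_PERCENTILE,
) -> NormalizedMatrix:
    """Three-step normalization of a raw intensity matrix.

    (1) intensities below ``floor`` are set to ``floor``; (2) each chip
    (sample column) is divided by its post-floor ``chip_percentile``-th
    percentile; (3) each feature row is divided by its median across all
    samples of the dataset. The per-feature median of the output is 1.
    """
    if raw.empty:
        raise ValueError("raw matrix is empty")
    if floor <= 0:
        raise ValueError("floor must be > 0")
    if (raw.values < 0).any():
        raise ValueError("raw intensities must be >= 0")
    floored = raw.clip(lower=floor)
    chip_scale = floored.quantile(chip_percentile / 100.0, axis=0)
    if (chip_scale <= 0).any():
        bad = list(chip_scale.index[chip_scale <= 0])
        raise ValueError(f"chips with non-positive percentile: {bad}")
    per_chip = floored / chip_scale
    feature_median = per_chip.median(axis=1)
    values = per_chip.div(feature_median, axis=0)
    return NormalizedMatrix(
        values=values,
        provenance={
            "floor": floor,
            "chip_percentile": chip_percentile,
            "chip_scale": chip_scale.to_dict(),
            "feature_centering": "median",
            "dataset_samples": list(raw.columns),
        },
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _extreme_pair(norm: pd.DataFrame, design: ExperimentDesign, experiment: str) -> tuple[str, str]:
    """Convenience contrast: conditions with maximal and minimal overall mean."""
    means = {
        c: float(norm[design.samples(experiment, c)].values.mean())
        for c in design.conditions(experiment)
    }
    hi = max(means, key=means.get)  # type: ignore[arg-type]
    lo = min(means, key=means.get)  # type: ignore[arg-type]
    if hi == lo:
        raise ValueError("cannot pick an extreme pair: all condition means equal")
    return hi, lo


def select_differential(
    norm: NormalizedMatrix,
    design: ExperimentDesign,
    experiment: str,
    pair: tuple[str, str] | None = None,
    fc_cutoff: float = DEFAULT_FC_CUTOFF,
    alpha: float = DEFAULT_ALPHA,
    bh_min_replicates: int = BH_MIN_REPLICATES,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Volcano-plot differential selection between two conditions.

    Per feature: ``fold_change = max(mean_A/mean_B, mean_B/mean_A)`` of
    normalized values (orientation-free, always >= 1) and a two-sided
    t-test on log2 values (pooled-variance Student t by default, the
    convention of array-era volcano filters and the only usable choice at
    two replicates, where Welch's Satterthwaite df collapses toward 1;
    pass ``equal_var=False`` for Welch). Benjamini-Hochberg correction is
    applied iff the experiment carries at least ``bh_min_replicates``
    replicates per condition; otherwise the raw p-value gates selection.
    A feature passes when fold_change >= fc_cutoff and the (adjusted)
    p <= alpha.

    If ``pair`` is None the extreme pair (max-mean vs min-mean condition)
    is contrasted; the chosen pair is recorded in the result attributes.
    """
    values = norm.values
    conditions = design.conditions(experiment)
    if pair is None:
        pair = _extreme_pair(values, design, experiment)
    cond_a, cond_b = pair
    for c in (cond_a, cond_b):
        if c not in conditions:
            raise ValueError(f"condition {c!r} not in experiment {experiment!r}")
    samples_a = design.samples(experiment, cond_a)
    samples_b = design.samples(experiment, cond_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("both conditions need >= 2 replicates")

    a = values[samples_a].to_numpy(dtype=float)
    b = values[samples_b].to_numpy(dtype=float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    if np.any(mean_a <= 0) or np.any(mean_b <= 0):
        raise ValueError("non-positive condition means; normalized values must be > 0")
    fold = np.maximum(mean_a / mean_b, mean_b / mean_a)

    t_res = stats.ttest_ind(np.log2(a), np.log2(b), axis=1, equal_var=equal_var)
    p = np.asarray(t_res.pvalue, dtype=float)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance-in-both features are null

    use_bh = design.replicate_count(experiment) >= bh_min_replicates
    adj = bh_adjust(p) if use_bh else np.full_like(p, np.nan)
    gate = adj if use_bh else p
    passes = (fold >= fc_cutoff) & (gate <= alpha)

    result = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fold_change": fold,
            "p_value": p,
            "adjusted_p": adj,
            "passes": passes,
        },
        index=values.index,
    )
    result.attrs.update(
        experiment=experiment, pair=(cond_a, cond_b), fc_cutoff=fc_cutoff,
        alpha=alpha, bh_applied=use_bh,
    )
    return result


def intersect_feature_sets(
    sets: Mapping[str, Iterable] | Sequence[Iterable],
) -> tuple[set, dict[tuple[str, ...], int]]:
    """Intersection of feature sets plus all Venn region cardinalities.

    Returns ``(common, regions)`` where ``regions`` maps each non-empty
    membership combination (tuple of set names the region belongs to,
    exclusively) to its cardinality. Region counts sum to |union|.
    """
    if isinstance(sets, Mapping):
        named = {str(k): set(v) for k, v in sets.items()}
    else:
        named = {f"set{i+1}": set(v) for i, v in enumerate(sets)}
    if len(named) < 2:
        raise ValueError("need >= 2 feature sets")
    names = list(named)
    common = set.intersection(*named.values())
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for inside in itertools.combinations(names, r):
            outside = [n for n in names if n not in inside]
            region = set.intersection(*(named[n] for n in inside))
            for n in outside:
                region -= named[n]
            regions[inside] = len(region)
    return common, regions


@dataclass
class ClusterResult:
    """K-cluster partition of z-scored expression profiles.

    ``assignment`` maps feature id -> cluster id (0..k-1); ``centroids``
    are the standardized cluster mean profiles; ``inertia`` is the summed
    squared Euclidean distance on the standardized rows.
    """

    k: int
    assignment: pd.Series
    centroids: pd.DataFrame
    inertia: float

    def members(self, cluster: int) -> list:
        return list(self.assignment.index[self.assignment == cluster])


def _zscore_rows(profiles: pd.DataFrame) -> pd.DataFrame:
    mu = profiles.mean(axis=1)
    sd = profiles.std(axis=1, ddof=0)
    zero = sd[sd == 0]
    if not zero.empty:
        raise ValueError(f"zero-variance profile(s): {list(zero.index[:5])}")
    return profiles.sub(mu, axis=0).div(sd, axis=0)


def cluster_kmeans_pearson(
    profiles: pd.DataFrame,
    k: int = 5,
    n_init: int = 25,
    seed: int = 0,
) -> ClusterResult:
    """K-means under Pearson correlation distance.

    Each feature row is z-scored across samples, after which squared
    Euclidean distance is a monotone transform of 1 - r (for z-scored
    rows, ||x - y||^2 = 2 n (1 - r)); Euclidean K-means on the
    standardized rows therefore clusters by profile shape, invariant to
    positive affine transforms of each row. Best of ``n_init`` seeded
    random restarts by inertia; deterministic given ``seed``.
    """
    if len(profiles) < k:
        raise ValueError(f"need >= k={k} features, got {len(profiles)}")
    z = _zscore_rows(profiles)
    km = KMeans(n_clusters=k, init="random", n_init=n_init, random_state=seed)
    labels = km.fit_predict(z.to_numpy(dtype=float))
    return ClusterResult(
        k=k,
        assignment=pd.Series(labels, index=profiles.index, name="cluster"),
        centroids=pd.DataFrame(km.cluster_centers_, columns=profiles.columns),
        inertia=float(km.inertia_),
    )


def select_clusters(
    clusters: ClusterResult,
    markers: Iterable,
    min_fraction: float = 0.0,
) -> list[int]:
    """Clusters containing marker features, ranked by marker count.

    A cluster is selected when it holds more than ``min_fraction`` of the
    markers present in the clustering (default: any marker at all).
    Returns an empty list when no marker was clustered.
    """
    markers = set(markers)
    if not markers:
        raise ValueError("markers must be non-empty")
    present = markers & set(clusters.assignment.index)
    if not present:
        return []
    counts = clusters.assignment.loc[sorted(present, key=str)].value_counts()
    threshold = min_fraction * len(present)
    ranked = [int(c) for c, n in counts.items() if n > threshold or (threshold == 0 and n > 0)]
    return ranked


def summarize_function(features: Iterable, annotation: pd.Series) -> pd.DataFrame:
    """Functional composition of a feature set: category -> (count, percent).

    ``annotation`` maps feature -> category; features absent from the
    annotation count as "unknown". Percentages are over the feature set
    and sum to 100 up to rounding.
    """
    features = list(features)
    if not features:
        raise ValueError("empty feature set")
    cats = [annotation.get(f, "unknown") for f in features]
    counts = pd.Series(cats).value_counts()
    out = pd.DataFrame({"count": counts})
    out["percent"] = 100.0 * out["count"] / len(features)
    out.index.name = "category"
    return out.sort_values("count", ascending=False)


def extract_tf_candidates(
    features: Iterable,
    profiles: pd.DataFrame,
    annotation: pd.Series,
    markers: Iterable,
) -> list:
    """Transcription-factor candidates ranked by correlation with markers.

    From ``features`` (typically the union of marker-bearing clusters),
    keeps those annotated "transcription factor" and orders them by the
    Pearson correlation of their profile with the mean profile of the
    ``markers`` present in ``profiles``, descending. May be empty.
    """
    features = [f for f in features if annotation.get(f, "unknown") == "transcription factor"]
    if not features:
        return []
    marker_rows = [m for m in markers if m in profiles.index]
    if not marker_rows:
        return list(features)
    ref = profiles.loc[marker_rows].mean(axis=0).to_numpy(dtype=float)
    scores = {}
    for f in features:
        prof = profiles.loc[f].to_numpy(dtype=float)
        if np.ptp(prof) == 0 or np.ptp(ref) == 0:
            scores[f] = -np.inf
        else:
            scores[f] = float(np.corrcoef(prof, ref)[0, 1])
    return sorted(features, key=lambda f: (-scores[f], str(f)))
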