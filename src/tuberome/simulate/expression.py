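"""Planted-cluster expression matrices with known differential features.

Emulates the three microarray designs of the original study: a diurnal
leaf time course (2 biological replicates), tuber-induction stages
(stolon vs swollen stolon, 2 replicates) and growing vs non-growing
tubers (4 replicates). Members of a planted co-expression cluster follow
a per-condition profile template scaled by a log2 effect size, with
multiplicative log-normal noise; non-members are flat. A chosen fraction
of each cluster is annotated "transcription factor" so candidate
extraction can be scored against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tuberome.expression import ExperimentDesign

__all__ = [
    "Experiment",
    "PlantedCluster",
    "ExpressionSimSpec",
    "ExpressionTruth",
    "generate_expression",
    "default_study_spec",
]

_OTHER_CATEGORIES = ("metabolism", "storage protein", "transport", "signalling")


@dataclass(frozen=True)
class Experiment:
    """One hybridization experiment: ordered conditions and replicates each."""

    experiment_id: str
    conditions: tuple[str, ...]
    replicates: int

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("replicates_per_condition must be >= 2")
        if len(self.conditions) < 2:
            raise ValueError("an experiment needs >= 2 conditions")


@dataclass(frozen=True)
class PlantedCluster:
    """A co-expressed feature group with a per-condition log2 template.

    ``template`` maps experiment id -> (one value per condition); the
    expected log2 expression of a member in a condition is
    ``log2_effect * template value``, so a 0/1 template with effect 2
    plants 4-fold changes. ``tf_fraction`` of members are annotated
    "transcription factor".
    """

    name: str
    template: dict[str, tuple[float, ...]]
    n_members: int
    log2_effect: float = 2.0
    tf_fraction: float = 0.06

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        if not (0.0 <= self.tf_fraction <= 1.0):
            raise ValueError("tf_fraction must be in [0, 1]")


@dataclass(frozen=True)
class ExpressionSimSpec:
    n_features: int = 1000
    experiments: tuple[Experiment, ...] = ()
    clusters: tuple[PlantedCluster, ...] = ()
    noise_sd: float = 0.25  # log2 scale
    baseline_intensity: float = 1000.0
    feature_scale_sd: float = 1.0  # per-feature log2 abundance spread
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_intensity <= 0:
            raise ValueError("baseline_intensity must be > 0")
        if self.noise_sd < 0 or self.feature_scale_sd < 0:
            raise ValueError("noise sds must be >= 0")
        if sum(c.n_members for c in self.clusters) > self.n_features:
            raise ValueError("planted members exceed n_features")
        for c in self.clusters:
            for e in self.experiments:
                tpl = c.template.get(e.experiment_id)
                if tpl is None or len(tpl) != len(e.conditions):
                    raise ValueError(
                        f"cluster {c.name!r}: template must cover every condition "
                        f"of experiment {e.experiment_id!r}"
                    )


@dataclass
class ExpressionTruth:
    """Planted structure: cluster labels, TF members, expected log2 levels."""

    cluster_labels: pd.Series  # feature -> cluster name ("" = unplanted)
    tf_features: set
    # experiment -> features x conditions expected log2 offsets
    expected_log2: dict[str, pd.DataFrame] = field(repr=False)

    def true_de(
        self,
        experiment: str,
        pair: tuple[str, str] | None = None,
        fc_cutoff: float = 2.0,
    ) -> set:
        """Features whose expected fold change reaches ``fc_cutoff``.

        With ``pair`` the fold is between the two named conditions (what a
        volcano contrast of that pair should find); without it the max-min
        fold over all conditions of the experiment.
        """
        exp = self.expected_log2[experiment]
        if pair is None:
            diff = exp.max(axis=1) - exp.min(axis=1)
        else:
            diff = (exp[pair[0]] - exp[pair[1]]).abs()
        return set(diff.index[diff >= np.log2(fc_cutoff)])


def _feature_ids(n: int) -> list[str]:
    return [f"feat{i:05d}" for i in range(n)]


def generate_expression(
    spec: ExpressionSimSpec,
) -> tuple[dict[str, pd.DataFrame], ExperimentDesign, pd.Series, ExpressionTruth]:
    """Simulate raw intensity matrices for every experiment.

    Returns ``(matrices, design, annotation, truth)``: one raw matrix per
    experiment (features x samples), the combined design table, a
    feature -> category annotation, and the planted ground truth.

    Intensity model: baseline * 2**(feature offset) * 2**(effect *
    template) * 2**N(0, noise_sd). The per-feature abundance offset is
    shared across experiments (as for one physical probe) and removed by
    per-feature median normalization downstream.
    """
    features = _feature_ids(spec.n_features)
    ss = np.random.SeedSequence(spec.seed)
    rng_assign, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))

    cluster_of = pd.Series("", index=features, dtype=object)
    pos = 0
    for c in spec.clusters:
        for f in features[pos : pos + c.n_members]:
            cluster_of[f] = c.name
        pos += c.n_members

    # functional annotation: tf_fraction of each cluster, rest rotating categories
    annotation = pd.Series("unknown", index=features, dtype=object)
    tf_features: set = set()
    for c in spec.clusters:
        members = list(cluster_of.index[cluster_of == c.name])
        n_tf = int(round(c.tf_fraction * len(members)))
        chosen = list(rng_assign.choice(members, size=n_tf, replace=False)) if n_tf else []
        tf_features.update(chosen)
        for f in chosen:
            annotation[f] = "transcription factor"
        rest = [f for f in members if f not in tf_features]
        for j, f in enumerate(rest):
            annotation[f] = _OTHER_CATEGORIES[j % len(_OTHER_CATEGORIES)]

    feature_offset = rng_noise.normal(0.0, spec.feature_scale_sd, size=spec.n_features)

    # expected log2 level per feature per (experiment, condition)
    matrices: dict[str, pd.DataFrame] = {}
    design_rows = []
    expected_log2: dict[str, pd.DataFrame] = {}
    templates = {c.name: c for c in spec.clusters}
    for exp in spec.experiments:
        expected = np.zeros((spec.n_features, len(exp.conditions)))
        for i, f in enumerate(features):
            cname = cluster_of[f]
            if cname:
                c = templates[cname]
                expected[i] = c.log2_effect * np.asarray(c.template[exp.experiment_id])
        expected_log2[exp.experiment_id] = pd.DataFrame(
            expected, index=features, columns=list(exp.conditions)
        )
        cols = []
        data = []
        for ci, cond in enumerate(exp.conditions):
            for rep in range(1, exp.replicates + 1):
                sample = f"{exp.experiment_id}_{cond}_r{rep}"
                cols.append(sample)
                design_rows.append(
                    {
                        "sample": sample,
                        "experiment": exp.experiment_id,
                        "condition": cond,
                        "replicate": rep,
                    }
                )
                noise = rng_noise.normal(0.0, spec.noise_sd, size=spec.n_features)
                log2_level = feature_offset + expected[:, ci] + noise
                data.append(spec.baseline_intensity * np.exp2(log2_level))
        matrices[exp.experiment_id] = pd.DataFrame(
            np.column_stack(data), index=features, columns=cols
        )
    design = ExperimentDesign(pd.DataFrame(design_rows))
    truth = ExpressionTruth(
        cluster_labels=cluster_of, tf_features=tf_features, expected_log2=expected_log2
    )
    return matrices, design, annotation, truth


def default_study_spec(
    n_features: int = 1000,
    log2_effect: float = 2.0,
    noise_sd: float = 0.25,
    tf_fraction: float = 0.06,
    members_per_cluster: int = 50,
    seed: int = 0,
) -> ExpressionSimSpec:
    """Three-experiment design mirroring the original study layout.

    Experiments: diurnal leaf time course (4 timepoints, 2 replicates),
    tuber induction (stolon vs swollen stolon, 2 replicates), tuber
    growth (growing vs non-growing, 4 replicates). Five planted clusters
    (A-E) are differentially expressed in every experiment — they model
    the five K-means clusters the intersected feature set splits into, of
    which three (B, C, D) carry the starch-biosynthesis-like pattern and
    host the co-regulated transcription factors. Two further small groups
    respond in a single experiment only (leaf- and growth-specific) and
    must fall out of the all-experiment Venn intersection.
    """
    experiments = (
        Experiment("leaf_diurnal", ("t0", "t6", "t12", "t18"), 2),
        Experiment("induction", ("stolon", "swollen_stolon"), 2),
        Experiment("growth", ("growing", "non_growing"), 4),
    )
    # full-strength effect at the canonical contrast pairs (t0 vs t12,
    # stolon vs swollen stolon, growing vs non-growing) for B/C/D
    up = {
        "leaf_diurnal": (0.0, 0.6, 1.0, 0.4),
        "induction": (0.0, 1.0),
        "growth": (1.0, 0.0),
    }
    down = {
        "leaf_diurnal": (1.0, 0.4, 0.0, 0.6),
        "induction": (1.0, 0.0),
        "growth": (0.0, 1.0),
    }
    phase = {
        "leaf_diurnal": (1.0, 0.6, 0.0, 0.2),
        "induction": (0.0, 1.0),
        "growth": (1.0, 0.0),
    }
    early = {
        "leaf_diurnal": (0.0, 1.0, 1.0, 0.0),
        "induction": (1.0, 0.0),
        "growth": (0.0, 1.0),
    }
    late = {
        "leaf_diurnal": (1.0, 0.0, 0.0, 1.0),
        "induction": (0.0, 1.0),
        "growth": (0.0, 1.0),
    }
    leaf_only = {
        "leaf_diurnal": (0.0, 0.0, 1.0, 1.0),
        "induction": (0.0, 0.0),
        "growth": (0.0, 0.0),
    }
    growth_only = {
        "leaf_diurnal": (0.0, 0.0, 0.0, 0.0),
        "induction": (0.0, 0.0),
        "growth": (1.0, 0.0),
    }
    m = members_per_cluster
    clusters = (
        PlantedCluster("A_early", early, m, log2_effect, tf_fraction),
        PlantedCluster("B_starch_up", up, m, log2_effect, tf_fraction),
        PlantedCluster("C_starch_phase", phase, m, log2_effect, tf_fraction),
        PlantedCluster("D_starch_down", down, m, log2_effect, tf_fraction),
        PlantedCluster("E_late", late, m, log2_effect, tf_fraction),
        PlantedCluster("F_leaf_specific", leaf_only, m // 2, log2_effect, tf_fraction),
        PlantedCluster("G_growth_specific", growth_only, m // 2, log2_effect, tf_fraction),
    )
    return ExpressionSimSpec(
        n_features=n_features,
        experiments=experiments,
        clusters=clusters,
        noise_sd=noise_sd,
        seed=seed,
    )


#: canonical contrast pair per experiment of :func:`default_study_spec`
DEFAULT_CONTRASTS: dict[str, tuple[str, str]] = {
    "leaf_diurnal": ("t0", "t12"),
    "induction": ("stolon", "swollen_stolon"),
    "growth": ("growing", "non_growing"),
}
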