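"""Held-out evaluation of discovered behavior features.

The segment pool is split 80/20 (seeded, stratified by phase by default
so the binomial null keeps p0 = 0.5 in both sets).  Features, PCA,
rescaling and the FuzzyART model are fitted on the training set only;
test segments are pushed through the frozen states and assigned to the
trained categories, giving per-phase occurrence counts for every
cluster — in particular for the ES-specific clusters identified on the
training set.  Cluster-level kinematic profiles from the training and
test sets are compared by average-linkage hierarchical clustering on
z-scored parameters, and any two segment groups can be contrasted
parameter-by-parameter with a two-tailed t-test (Welch by default).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import ttest_ind

from .assoc import AssociationResult, binomial_association, run_cell, screen_significant
from .core import PHASE_ES, PHASE_QT
from .features import (PROFILE_FIELDS, BehaviorProfile, FeaturePipeline,
                       Segment, kinematic_profile)
from .fuzzyart import FuzzyART

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    seed: int = 0
    stratify_by: str = "phase"      # "none" or "phase"

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.stratify_by not in ("none", "phase"):
            raise ValueError("stratify_by must be 'none' or 'phase'")


def split_segments(segments: list[Segment], spec: SplitSpec
                   ) -> tuple[list[Segment], list[Segment]]:
    """Seeded uniform split into disjoint, exhaustive train/test sets.

    With phase stratification each phase is split separately, so both
    phases appear in both sets in (near-)original proportion.  Segment
    order within each returned set is the original (chronological) one.
    """
    rng = np.random.default_rng(spec.seed)
    idx = np.arange(len(segments))
    if spec.stratify_by == "phase":
        groups = [idx[[s.phase == ph for s in segments]]
                  for ph in (PHASE_QT, PHASE_ES)]
        groups = [g for g in groups if len(g)]
    else:
        groups = [idx]
    train_idx: list[int] = []
    for g in groups:
        perm = rng.permutation(g)
        n_train = int(round(spec.train_fraction * len(g)))
        train_idx.extend(perm[:n_train].tolist())
    train_set = set(train_idx)
    train = [segments[i] for i in idx if i in train_set]
    test = [segments[i] for i in idx if i not in train_set]
    return train, test


def evaluate_transfer(model: FuzzyART, train_results: list[AssociationResult],
                      test_segments: list[Segment],
                      pipeline: FeaturePipeline,
                      mode: str = "nearest") -> pd.DataFrame:
    """Assign held-out segments with the frozen model; count per phase.

    Refuses a feature pipeline whose fitted row count differs from the
    model's training size (leakage guard).  Returns one row per trained
    cluster: test-set ES/QT counts plus the training-set direction flag.
    """
    if pipeline.n_fit_rows != len(model.assignments_):
        raise ValueError(
            "feature pipeline was not fitted on the model's training set "
            f"({pipeline.n_fit_rows} rows vs {len(model.assignments_)})")
    directions = {r.cluster: r.direction for r in train_results}
    rows = []
    if test_segments:
        X = pipeline.transform(test_segments)
        labels, _ = model.predict(X, mode=mode)
        phases = np.array([s.phase for s in test_segments], dtype=object)
    else:
        logger.info("empty test set; transfer table is empty")
        labels = np.empty(0, dtype=int)
        phases = np.empty(0, dtype=object)
    for cluster in range(model.n_categories):
        members = labels == cluster
        rows.append({
            "cluster": cluster,
            "count_es_test": int((phases[members] == PHASE_ES).sum()),
            "count_qt_test": int((phases[members] == PHASE_QT).sum()),
            "train_direction": directions.get(cluster, "none"),
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ClusterProfile:
    cluster: int
    source: str                    # "train" or "test"
    mean_profile: BehaviorProfile
    count: int


def cluster_profiles(segments: list[Segment], assignments: np.ndarray,
                     source: str, top_threshold: float) -> list[ClusterProfile]:
    """Mean kinematic profile per cluster over its member segments."""
    assignments = np.asarray(assignments)
    profiles = []
    for cluster in sorted(set(int(c) for c in assignments if c >= 0)):
        members = [s for s, c in zip(segments, assignments) if c == cluster]
        arr = np.array([kinematic_profile(s, top_threshold).as_array()
                        for s in members])
        profiles.append(ClusterProfile(
            cluster=cluster, source=source,
            mean_profile=BehaviorProfile(*arr.mean(axis=0)),
            count=len(members)))
    return profiles


def hierarchy(profiles: list[ClusterProfile]
              ) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """Average-linkage hierarchy over z-scored cluster profiles.

    Profiles are ordered lexicographically by (source, cluster id) before
    linkage so the leaf order is deterministic; parameters are z-scored
    across all profiles pooled because their units are incommensurate.
    Returns the SciPy linkage table and the leaf order as
    (source, cluster) pairs.  A single profile yields an empty linkage.
    """
    if not profiles:
        raise ValueError("no profiles to cluster")
    profiles = sorted(profiles, key=lambda p: (p.source, p.cluster))
    keys = [(p.source, p.cluster) for p in profiles]
    if len(profiles) == 1:
        return np.empty((0, 4)), keys
    M = np.array([p.mean_profile.as_array() for p in profiles])
    sd = M.std(axis=0, ddof=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    Z = linkage((M - M.mean(axis=0)) / sd, method="average",
                metric="euclidean")
    order = leaves_list(Z)
    return Z, [keys[i] for i in order]


def compare_cluster_params(segments_a: list[Segment],
                           segments_b: list[Segment],
                           top_threshold: float,
                           equal_var: bool = False) -> pd.DataFrame:
    """Per-parameter two-tailed t-test between two segment groups.

    Welch's t by default (``equal_var=False``); set ``equal_var=True``
    for the pooled-variance Student variant.  Output drives the
    bar-with-error comparison of an ES-specific vs a QT-specific
    cluster: mean, SEM, t and p per kinematic parameter.
    """
    if len(segments_a) < 2 or len(segments_b) < 2:
        raise ValueError("both groups need at least 2 segments")
    A = np.array([kinematic_profile(s, top_threshold).as_array()
                  for s in segments_a])
    B = np.array([kinematic_profile(s, top_threshold).as_array()
                  for s in segments_b])
    rows = []
    for j, name in enumerate(PROFILE_FIELDS):
        t, p = ttest_ind(A[:, j], B[:, j], equal_var=equal_var)
        rows.append({
            "parameter": name,
            "mean_a": A[:, j].mean(),
            "sem_a": A[:, j].std(ddof=1) / np.sqrt(len(A)),
            "mean_b": B[:, j].mean(),
            "sem_b": B[:, j].std(ddof=1) / np.sqrt(len(B)),
            "t": float(t), "p": float(p)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# end-to-end orchestration


@dataclass
class ExperimentResult:
    """Everything the end-to-end run produces, ready for export."""

    model: FuzzyART
    pipeline: FeaturePipeline
    train_segments: list[Segment]
    test_segments: list[Segment]
    train_results: list[AssociationResult]
    es_specific: list[AssociationResult]
    qt_specific: list[AssociationResult]
    transfer: pd.DataFrame
    linkage: np.ndarray
    leaf_order: list[tuple[str, int]]
    timings: dict[str, float] = field(default_factory=dict)

    def summary(self) -> dict:
        es_rows = self.transfer[self.transfer["train_direction"] == "ES"]
        return {
            "n_train_segments": len(self.train_segments),
            "n_test_segments": len(self.test_segments),
            "n_clusters": self.model.n_categories,
            "n_es_specific": len(self.es_specific),
            "n_qt_specific": len(self.qt_specific),
            "es_specific_clusters": [
                {"cluster": r.cluster, "n": r.n, "k_es": r.k_es,
                 "p_value": r.p_value, "neg_log10_p": r.neg_log10_p}
                for r in self.es_specific],
            "test_counts_es_specific": es_rows[
                ["cluster", "count_es_test", "count_qt_test"]
            ].to_dict(orient="records"),
            "leaf_order": [list(k) for k in self.leaf_order],
        }


def run_experiment(trajs, seg_len_s: float = 5.0, cum_var: float = 0.72,
                   rho: float = 0.73, p0: float = 0.5,
                   split: SplitSpec | None = None, alpha: float = 0.05,
                   top_threshold: float | None = None) -> ExperimentResult:
    """Train/test the full discovery pipeline on labelled 3D trajectories.

    Segments all trajectories, splits 80/20, fits features + FuzzyART on
    the training set, screens clusters with the exact binomial test, and
    evaluates the identified features on the held-out set.
    """
    from .features import segment_trajectory

    split = split or SplitSpec()
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    segments: list[Segment] = []
    for fish, traj in enumerate(trajs):
        segments.extend(segment_trajectory(traj, seg_len_s, fish_id=fish))
    timings["segment"] = time.perf_counter() - t0

    train, test = split_segments(segments, split)
    phases = np.array([s.phase for s in train], dtype=object)

    t0 = time.perf_counter()
    model, pipeline, results = run_cell(train, phases, cum_var, rho, p0=p0)
    timings["fit"] = time.perf_counter() - t0
    es, qt = screen_significant(results, alpha=alpha)

    t0 = time.perf_counter()
    transfer = evaluate_transfer(model, results, test, pipeline)
    timings["transfer"] = time.perf_counter() - t0

    if top_threshold is None:
        top_threshold = trajs[0].tank[2] / 2.0
    test_X = pipeline.transform(test) if test else np.empty((0, model.d_))
    test_labels = model.predict(test_X)[0] if len(test_X) else np.empty(0, int)
    profs = (cluster_profiles(train, model.assignments_, "train", top_threshold)
             + cluster_profiles(test, test_labels, "test", top_threshold))
    Z, leaf_order = hierarchy(profs)

    for stage, dt in timings.items():
        logger.info("stage %-8s %.2f s", stage, dt)
    return ExperimentResult(model=model, pipeline=pipeline,
                            train_segments=train, test_segments=test,
                            train_results=results, es_specific=es,
                            qt_specific=qt, transfer=transfer, linkage=Z,
                            leaf_order=leaf_order, timings=timings)
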