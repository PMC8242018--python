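"""Cluster-treatment association screening and the parameter grid search.

Each discovered cluster is tested for enrichment in electric-stimulus
(ES) segments with an exact two-tailed binomial test: under the null,
membership is phase-blind, so the ES count k among the cluster's n
members is Binomial(n, p0), with p0 the ES fraction of the schedule
(0.5 for the balanced 30 s / 30 s protocol).  The two-tailed p-value is
the minimum-likelihood construction — the total probability of all
outcomes no more likely than the observed one — which at p0 = 0.5
reduces to the familiar doubling rule capped at 1.

The grid search reruns the whole segmentation -> PCA -> rescale ->
FuzzyART -> binomial chain over segment length x cumulative-variance x
vigilance and records, per cell, the strongest cluster-treatment
association (max -log10 p), producing the tidy table behind the
parameter-selection heatmap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

from .core import PHASE_ES, PHASE_QT, Trajectory3D
from .features import FeaturePipeline, segment_trajectory
from .fuzzyart import UNCOMMITTED, FuzzyART, FuzzyARTParams

logger = logging.getLogger(__name__)

LOW_POWER_N = 5
GRID_COLUMNS = ["seg_len_s", "cum_var", "rho", "n_clusters",
                "best_neg_log10_p", "best_cluster", "best_neg_log10_p_all"]


@dataclass(frozen=True)
class AssociationResult:
    """Exact binomial association of one cluster with the ES phase."""

    cluster: int
    n: int
    k_es: int
    p0: float
    p_value: float
    neg_log10_p: float
    direction: str             # "ES", "QT" or "none"
    low_power: bool


def binomial_association(assignments: np.ndarray, phase_labels: np.ndarray,
                         p0: float = 0.5, alpha: float = 0.05
                         ) -> list[AssociationResult]:
    """Exact two-tailed binomial test of every cluster's ES composition.

    ``direction`` is ES when the cluster is significantly ES-enriched at
    ``alpha`` (k/n > p0), QT when ES-depleted, else "none".  Rows
    assigned to the uncommitted sentinel are skipped with a log entry.
    """
    assignments = np.asarray(assignments)
    phase_labels = np.asarray(phase_labels, dtype=object)
    if len(assignments) != len(phase_labels):
        raise ValueError("assignments and phase labels differ in length")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    bad = set(np.unique(phase_labels)) - {PHASE_ES, PHASE_QT}
    if bad:
        raise ValueError(f"unknown phase labels {sorted(map(str, bad))}")

    n_sentinel = int((assignments == UNCOMMITTED).sum())
    if n_sentinel:
        logger.info("skipping %d unassigned segments", n_sentinel)

    results = []
    for cluster in np.unique(assignments):
        if cluster == UNCOMMITTED:
            continue
        members = assignments == cluster
        n = int(members.sum())
        k_es = int((phase_labels[members] == PHASE_ES).sum())
        p = binomtest(k_es, n, p0, alternative="two-sided").pvalue
        p = min(float(p), 1.0)
        frac = k_es / n
        if p < alpha and frac > p0:
            direction = "ES"
        elif p < alpha and frac < p0:
            direction = "QT"
        else:
            direction = "none"
        results.append(AssociationResult(
            cluster=int(cluster), n=n, k_es=k_es, p0=p0, p_value=p,
            neg_log10_p=float(-np.log10(p)), direction=direction,
            low_power=n < LOW_POWER_N))
    return results


def association_table(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"cluster": r.cluster, "n": r.n, "k_es": r.k_es, "p0": r.p0,
          "p_value": r.p_value, "neg_log10_p": r.neg_log10_p,
          "direction": r.direction, "low_power": r.low_power}
         for r in results])


def screen_significant(results: list[AssociationResult], alpha: float = 0.05,
                       correction: str = "none"
                       ) -> tuple[list[AssociationResult], list[AssociationResult]]:
    """Partition significant clusters into ES-specific and QT-specific.

    ``correction="none"`` thresholds raw p-values at ``alpha`` (the
    dashed-line convention); ``"BH"`` applies Benjamini-Hochberg over
    all tested clusters first.
    """
    if not results:
        raise ValueError("no association results to screen")
    if correction not in ("none", "BH"):
        raise ValueError("correction must be 'none' or 'BH'")
    pvals = np.array([r.p_value for r in results])
    if correction == "BH":
        significant = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
    else:
        significant = pvals < alpha
    es, qt = [], []
    for r, sig in zip(results, significant):
        if not sig:
            continue
        if r.k_es / r.n > r.p0:
            es.append(r)
        elif r.k_es / r.n < r.p0:
            qt.append(r)
    return es, qt


def run_cell(segments: list, seg_phases: np.ndarray, cum_var: float,
             rho: float, p0: float = 0.5,
             base_params: FuzzyARTParams | None = None,
             n_resample: int | None = None
             ) -> tuple[FuzzyART, FeaturePipeline, list[AssociationResult]]:
    """One grid cell: features -> FuzzyART -> association, on given segments."""
    kw = {} if n_resample is None else {"n_resample": n_resample}
    X01, pipeline = FeaturePipeline.fit(segments, target_cum_var=cum_var, **kw)
    assert ((X01 >= 0) & (X01 <= 1)).all(), "clustering inputs must be in [0,1]"
    bp = base_params or FuzzyARTParams()
    params = FuzzyARTParams(rho=rho, alpha=bp.alpha, beta=bp.beta,
                            max_epochs=bp.max_epochs)
    model = FuzzyART(params).fit(X01)
    results = binomial_association(model.assignments_, seg_phases, p0=p0)
    return model, pipeline, results


def _best(results: list[AssociationResult], es_only: bool
          ) -> tuple[float, int]:
    pool = [r for r in results if (not es_only) or
            (r.k_es / r.n > r.p0)]
    if not pool:
        return 0.0, -1
    top = max(pool, key=lambda r: (r.neg_log10_p, -r.cluster))
    return top.neg_log10_p, top.cluster


def grid_search(trajs: list[Trajectory3D],
                seg_lens_s: list[float] | None = None,
                var_grid: list[float] | None = None,
                rho_grid: list[float] | None = None,
                p0: float = 0.5,
                base_params: FuzzyARTParams | None = None) -> pd.DataFrame:
    """Exhaustive screen over segment length x cum. variance x vigilance.

    Per cell, the pipeline runs end to end on all trajectories pooled and
    the cell records the number of clusters and the strongest
    ES-leaning association (``best_neg_log10_p``; the max over all
    clusters regardless of direction is kept in
    ``best_neg_log10_p_all``).  Cells whose segmentation is empty are
    recorded with zero clusters.  The run is fully deterministic.
    """
    seg_lens_s = list(seg_lens_s) if seg_lens_s is not None \
        else [float(s) for s in range(1, 11)]
    var_grid = list(var_grid) if var_grid is not None \
        else [0.5, 0.6, 0.72, 0.8, 0.9]
    rho_grid = list(rho_grid) if rho_grid is not None \
        else [0.5, 0.6, 0.73, 0.8, 0.9]
    if not (seg_lens_s and var_grid and rho_grid):
        raise ValueError("all grids must be non-empty")

    rows = []
    for seg_len in seg_lens_s:
        try:
            segments = []
            for fish, traj in enumerate(trajs):
                segments.extend(segment_trajectory(traj, seg_len, fish_id=fish))
        except ValueError:
            segments = []
        if not segments:
            logger.info("segment length %.3g s yields no segments", seg_len)
            for cum_var in var_grid:
                for rho in rho_grid:
                    rows.append((seg_len, cum_var, rho, 0, 0.0, -1, 0.0))
            continue
        phases = np.array([s.phase for s in segments], dtype=object)
        for cum_var in var_grid:
            for rho in rho_grid:
                model, _, results = run_cell(segments, phases, cum_var, rho,
                                             p0=p0, base_params=base_params)
                best_es, best_cluster = _best(results, es_only=True)
                best_all, _ = _best(results, es_only=False)
                rows.append((seg_len, cum_var, rho, model.n_categories,
                             best_es, best_cluster, best_all))
    return pd.DataFrame(rows, columns=GRID_COLUMNS)


def select_condition(cells: pd.DataFrame, seg_len_s: float = 5.0) -> pd.Series:
    """Best cell at a fixed segment length.

    Maximizes ``best_neg_log10_p``; ties resolve to the smallest rho,
    then the smallest cumulative-variance target.
    """
    at = cells[cells["seg_len_s"] == seg_len_s]
    if at.empty:
        raise ValueError(f"no grid cells at seg_len_s={seg_len_s}")
    at = at.sort_values(["best_neg_log10_p", "rho", "cum_var"],
                        ascending=[False, True, True], kind="stable")
    return at.iloc[0]


def plot_grid_heatmap(cells: pd.DataFrame, path: str, seg_len_s: float | None = None):
    """Basic heatmap of best -log10(p) over (rho, cum_var) for one segment length."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if seg_len_s is None:
        seg_len_s = float(cells["seg_len_s"].iloc[0])
    at = cells[cells["seg_len_s"] == seg_len_s]
    pivot = at.pivot(index="rho", columns="cum_var", values="best_neg_log10_p")
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(pivot.to_numpy(), origin="lower", aspect="auto",
                   cmap="viridis")
    ax.set_xticks(range(len(pivot.columns)), [f"{v:g}" for v in pivot.columns])
    ax.set_yticks(range(len(pivot.index)), [f"{v:g}" for v in pivot.index])
    ax.set_xlabel("cumulative variance target")
    ax.set_ylabel("vigilance rho")
    ax.set_title(f"best -log10(p), {seg_len_s:g} s segments")
    fig.colorbar(im, ax=ax, label="-log10(p)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
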