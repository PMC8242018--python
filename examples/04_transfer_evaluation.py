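"""Evaluate discovered behavior features on held-out data.

Segments are split 80/20 (stratified by phase); features, PCA,
rescaling and the FuzzyART model are fitted on the training set only,
and the frozen model assigns the held-out segments.  ES-specific
clusters found in training should collect mostly ES segments in the
test set; the traditional kinematic parameters of the strongest ES- and
QT-specific clusters are compared with Welch's t-test.
"""

from zebra3d import (SimConfig, SplitSpec, StimulusSchedule,
                     compare_cluster_params, run_experiment,
                     simulate_trajectory)

cfg = SimConfig(n_fish=10, schedule=StimulusSchedule.alternating(30, 30, 10),
                seed=42)
trajs = [simulate_trajectory(cfg, f) for f in range(cfg.n_fish)]
res = run_experiment(trajs, seg_len_s=5.0, cum_var=0.72, rho=0.73,
                     split=SplitSpec(seed=42))

print(f"train {len(res.train_segments)} / test {len(res.test_segments)} "
      f"segments, {res.model.n_categories} clusters")
print(f"ES-specific on training: {[r.cluster for r in res.es_specific]}")
print(res.transfer[res.transfer['train_direction'] != 'none']
      .to_string(index=False))

if res.es_specific and res.qt_specific:
    best_es = max(res.es_specific, key=lambda r: r.neg_log10_p).cluster
    best_qt = max(res.qt_specific, key=lambda r: r.neg_log10_p).cluster
    a = [s for s, c in zip(res.train_segments, res.model.assignments_)
         if c == best_es]
    b = [s for s, c in zip(res.train_segments, res.model.assignments_)
         if c == best_qt]
    table = compare_cluster_params(a, b, top_threshold=10.0)
    print(f"\ncluster {best_es} (ES) vs cluster {best_qt} (QT), "
          f"Welch two-tailed t per kinematic parameter:")
    print(table.round(3).to_string(index=False))
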