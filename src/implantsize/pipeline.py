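"""End-to-end convenience pipeline on synthetic data.

Wires the stages together the way the CLI does, but in memory: generate
annotations, extract (D, L) features, stratify, tune the diameter weight on
a grid, and evaluate the tuned model on the held-out test records.  Used by
the examples and by the acceptance harness; every stage remains available
individually.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import cluster, simulate
from .annotations import DatasetManifest, ManifestEntry, stratified_split


@dataclass(frozen=True)
class BenchmarkResult:
    """Outcome of one tuned synthetic run."""

    best_w: float
    curve: list[tuple[float, float]]
    model: cluster.ClusterModel
    truth: list[str]
    predictions: list[str]

    @property
    def test_accuracy(self) -> float:
        return cluster.accuracy(self.truth, self.predictions)


def run_synthetic_benchmark(
    config: simulate.SimulationConfig,
    seed: int,
    w_grid=tuple(range(1, 11)),
    n_init: int = 10,
    n_val_per_class: int = 0,
    n_test_per_class: int = 20,
) -> BenchmarkResult:
    """Generate -> extract -> split -> tune -> predict on one seeded config.

    The generator, the split and the clustering restarts all derive their
    randomness from ``seed``.  Weight selection follows the benchmark
    protocol: accuracy on the held-out test split (``n_test_per_class``
    records per code; a validation split can be reserved additionally).
    """
    ss = np.random.SeedSequence(seed)
    gen_seed, split_seed, fit_seed = (
        int(s.generate_state(1)[0] >> 1) for s in ss.spawn(3)
    )
    records = simulate.generate_records(replace(config, seed=gen_seed))
    X, y = simulate.features_and_codes(records)

    manifest = DatasetManifest(
        [ManifestEntry(gt.record.image_id, "", "", gt.record.true_label.code)
         for gt in records]
    )
    tagged = stratified_split(manifest, n_val_per_class, n_test_per_class,
                              seed=split_seed)
    tags = np.array([e.split for e in tagged.entries])
    train = tags == "train"
    test = tags == "test"

    y = np.array(y)
    best_w, curve, model = cluster.tune_weight(
        X[train], list(y[train]), X[test], list(y[test]),
        w_grid=w_grid, n_init=n_init, seed=fit_seed,
    )
    preds = cluster.predict(model, X[test])
    return BenchmarkResult(
        best_w=best_w, curve=curve, model=model,
        truth=list(y[test]), predictions=preds,
    )
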