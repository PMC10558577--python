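"""Published benchmark one-vs-rest counts for implant-size classifiers.

A clinical benchmark evaluated two nine-class implant-size classifiers — a
fine-tuned convolutional network and the weighted k-means pipeline this
package implements — on the same test set of 180 periapical radiographs
(20 per size code) and reported per-code one-vs-rest TP/TN/FP/FN counts.
Those counts are inputs here: feeding them through
:func:`implantsize.evaluation.metrics_from_counts` reproduces the reported
metric table (3-decimal display) and its DeLong confidence intervals, which
is how the evaluation arithmetic is validated end to end.
"""

from __future__ import annotations

from .evaluation import BinaryCounts

#: Final deep-learning model, one-vs-rest counts per size code (test n=180).
DEEP_LEARNING_COUNTS: dict[str, BinaryCounts] = {
    "3308": BinaryCounts(tp=20, tn=160, fp=0, fn=0),
    "3310": BinaryCounts(tp=19, tn=160, fp=0, fn=1),
    "3312": BinaryCounts(tp=20, tn=160, fp=0, fn=0),
    "4108": BinaryCounts(tp=20, tn=159, fp=1, fn=0),
    "4110": BinaryCounts(tp=20, tn=160, fp=0, fn=0),
    "4112": BinaryCounts(tp=20, tn=159, fp=1, fn=0),
    "4808": BinaryCounts(tp=19, tn=160, fp=0, fn=1),
    "4810": BinaryCounts(tp=20, tn=160, fp=0, fn=0),
    "4812": BinaryCounts(tp=20, tn=160, fp=0, fn=0),
}

#: Final clustering model (weight w=2), one-vs-rest counts per size code.
CLUSTERING_COUNTS: dict[str, BinaryCounts] = {
    "3308": BinaryCounts(tp=19, tn=160, fp=0, fn=1),
    "3310": BinaryCounts(tp=18, tn=159, fp=1, fn=2),
    "3312": BinaryCounts(tp=20, tn=158, fp=2, fn=0),
    "4108": BinaryCounts(tp=20, tn=160, fp=0, fn=0),
    "4110": BinaryCounts(tp=20, tn=158, fp=2, fn=0),
    "4112": BinaryCounts(tp=18, tn=160, fp=0, fn=2),
    "4808": BinaryCounts(tp=20, tn=160, fp=0, fn=0),
    "4810": BinaryCounts(tp=20, tn=160, fp=0, fn=0),
    "4812": BinaryCounts(tp=20, tn=160, fp=0, fn=0),
}

#: Published display table for both models: per code,
#: (ACC, SE, SP, F1, PPV, NPV, AUC, CI_low, CI_high) at 3-decimal display.
PUBLISHED_METRICS: dict[str, dict[str, tuple[float, ...]]] = {
    "deep_learning": {
        "3308": (1.000, 1.000, 1.000, 1.000, 1.000, 1.000, 1.000, 1.000, 1.000),
        "3310": (0.994, 0.950, 1.000, 0.974, 1.000, 0.994, 0.975, 0.926, 1.000),
        "3312": (1.000, 1.000, 1.000, 1.000, 1.000, 1.000, 1.000, 1.000, 1.000),
        "4108": (0.994, 1.000, 0.994, 0.976, 0.952, 1.000, 0.997, 0.991, 1.000),
        "4110": (1.000, 1.000, 1.000, 1.000, 1.000, 1.000, 1.000, 1.000, 1.000),
        "4112": (0.994, 1.000, 0.994, 0.976, 0.952, 1.000, 0.997, 0.991, 1.000),
        "4808": (0.994, 0.950, 1.000, 0.974, 1.000, 0.994, 0.975, 0.926, 1.000),
        "4810": (1.000, 1.000, 1.000, 1.000, 1.000, 1.000, 1.000, 1.000, 1.000),
        "4812": (1.000, 1.000, 1.000, 1.000, 1.000, 1.000, 1.000, 1.000, 1.000),
    },
    "clustering": {
        "3308": (0.994, 0.950, 1.000, 0.974, 1.000, 0.994, 0.975, 0.926, 1.000),
        "3310": (0.983, 0.900, 0.994, 0.923, 0.947, 0.988, 0.947, 0.879, 1.000),
        "3312": (0.989, 1.000, 0.988, 0.952, 0.909, 1.000, 0.994, 0.985, 1.000),
        "4108": (1.000, 1.000, 1.000, 1.000, 1.000, 1.000, 1.000, 1.000, 1.000),
        "4110": (0.989, 1.000, 0.988, 0.952, 0.909, 1.000, 0.994, 0.985, 1.000),
        "4112": (0.989, 0.900, 1.000, 0.947, 1.000, 0.988, 0.950, 0.883, 1.000),
        "4808": (1.000, 1.000, 1.000, 1.000, 1.000, 1.000, 1.000, 1.000, 1.000),
        "4810": (1.000, 1.000, 1.000, 1.000, 1.000, 1.000, 1.000, 1.000, 1.000),
        "4812": (1.000, 1.000, 1.000, 1.000, 1.000, 1.000, 1.000, 1.000, 1.000),
    },
}

#: Reported total misclassification counts on the shared 180-image test set.
PUBLISHED_TOTAL_ERRORS = {"deep_learning": 2, "clustering": 5}
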