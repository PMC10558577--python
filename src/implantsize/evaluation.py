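"""One-vs-rest performance evaluation of hard nine-class size predictions.

Each of the nine size codes is scored one-vs-rest: the 9x9 confusion
matrix collapses to per-code TP/TN/FP/FN, from which accuracy, sensitivity
(recall), specificity, F1, PPV (precision) and NPV follow.  For a
hard-label classifier the ROC consists of a single operating point, so the
AUC collapses to balanced accuracy, (sensitivity + specificity)/2; its 95%
confidence interval is computed nonparametrically by the DeLong method,
treating the binarised prediction as a two-valued score and using
placement values with sample variances.  A Pearson chi-square test on the
per-code correct/incorrect 2x2 table compares two models' predictions on
the same evaluation set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CardinalityError
from .labels import CODES


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Round with ties away from zero (display convention for metric tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def confusion_matrix(
    truth: Sequence[str], pred: Sequence[str], codes: Sequence[str] = CODES
) -> np.ndarray:
    """9x9 count grid, rows = true code, columns = predicted code.

    Label order is fixed ascending; unknown codes are rejected.
    """
    truth, pred = list(truth), list(pred)
    if len(truth) != len(pred):
        raise CardinalityError(
            f"truth ({len(truth)}) and pred ({len(pred)}) differ in length"
        )
    index = {c: i for i, c in enumerate(codes)}
    cm = np.zeros((len(codes), len(codes)), dtype=np.int64)
    for t, p in zip(truth, pred):
        if t not in index or p not in index:
            raise ValueError(f"unknown size code in pair ({t!r}, {p!r})")
        cm[index[t], index[p]] += 1
    return cm


@dataclass(frozen=True)
class BinaryCounts:
    """One-vs-rest confusion counts for a single size code."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def binarize(cm: np.ndarray, code: str, codes: Sequence[str] = CODES) -> BinaryCounts:
    """Collapse the multiclass matrix to one-vs-rest counts for ``code``."""
    i = list(codes).index(code)
    tp = int(cm[i, i])
    fn = int(cm[i, :].sum() - tp)
    fp = int(cm[:, i].sum() - tp)
    tn = int(cm.sum() - tp - fn - fp)
    return BinaryCounts(tp=tp, tn=tn, fp=fp, fn=fn)


@dataclass(frozen=True)
class MetricsRow:
    """The seven derived performance values for one code, with CI on AUC."""

    code: str
    counts: BinaryCounts
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    ppv: float
    npv: float
    auc: float
    ci_low: float | None = None
    ci_high: float | None = None


def _ratio(num: float, den: float) -> float:
    # zero-denominator convention: metric defined as 0
    return num / den if den > 0 else 0.0


def compute_metrics(counts: BinaryCounts, code: str = "") -> MetricsRow:
    """Accuracy, SE, SP, F1, PPV, NPV and single-point AUC from counts.

    AUC for a hard classifier is (SE + SP)/2 (balanced accuracy).  Any
    metric whose denominator is zero is reported as 0.
    """
    if counts.total == 0:
        raise ValueError("empty counts")
    se = _ratio(counts.tp, counts.tp + counts.fn)
    sp = _ratio(counts.tn, counts.tn + counts.fp)
    ppv = _ratio(counts.tp, counts.tp + counts.fp)
    npv = _ratio(counts.tn, counts.tn + counts.fn)
    f1 = _ratio(2 * se * ppv, se + ppv)
    acc = (counts.tp + counts.tn) / counts.total
    return MetricsRow(
        code=code,
        counts=counts,
        accuracy=acc,
        sensitivity=se,
        specificity=sp,
        f1=f1,
        ppv=ppv,
        npv=npv,
        auc=0.5 * (se + sp),
    )


def auc_ci_delong(counts: BinaryCounts, z: float = 1.96) -> tuple[float, float]:
    """DeLong 95% CI for the single-operating-point AUC, clipped to [0, 1].

    The hard prediction is treated as a two-valued score (1 = predicted
    positive).  Placement values — for each positive, the fraction of
    negatives scored strictly lower plus half the ties, and symmetrically
    for negatives — have means equal to the AUC; the AUC variance is
    var(positive placements)/n_pos + var(negative placements)/n_neg with
    sample (n-1) variances.  The variance is exactly 0 iff the classifier
    is perfect for this code.
    """
    if counts.n_pos == 0 or counts.n_neg == 0:
        raise ValueError("DeLong CI needs at least one positive and one negative")
    pos = np.concatenate([np.ones(counts.tp), np.zeros(counts.fn)])
    neg = np.concatenate([np.ones(counts.fp), np.zeros(counts.tn)])
    v10 = np.array(
        [(np.sum(neg < s) + 0.5 * np.sum(neg == s)) / counts.n_neg for s in pos]
    )
    v01 = np.array(
        [(np.sum(pos > s) + 0.5 * np.sum(pos == s)) / counts.n_pos for s in neg]
    )
    auc = float(v10.mean())
    var = 0.0
    if counts.n_pos > 1:
        var += float(np.var(v10, ddof=1)) / counts.n_pos
    if counts.n_neg > 1:
        var += float(np.var(v01, ddof=1)) / counts.n_neg
    half = z * math.sqrt(var)
    return (max(0.0, auc - half), min(1.0, auc + half))


def total_errors(truth: Sequence[str], pred: Sequence[str]) -> int:
    """Number of misclassified items (total minus confusion-matrix trace)."""
    truth, pred = list(truth), list(pred)
    if len(truth) != len(pred):
        raise CardinalityError("truth and pred differ in length")
    return sum(t != p for t, p in zip(truth, pred))


def compare_before_after(
    truth: Sequence[str],
    pred_before: Sequence[str],
    pred_after: Sequence[str],
    code: str,
) -> tuple[float, float]:
    """Pearson chi-square comparing two models' one-vs-rest correctness.

    For the given code, each prediction is "correct" when it agrees with
    the truth about membership in that code (one-vs-rest).  The 2x2 table
    model (before/after) x correctness is tested with Pearson chi-square
    without continuity correction.  Degenerate tables (a zero margin, e.g.
    both models perfect) yield (0.0, 1.0) with a warning.
    """
    from scipy.stats import chi2_contingency

    truth = list(truth)
    if len(pred_before) != len(truth) or len(pred_after) != len(truth):
        raise CardinalityError("prediction sequences must match truth length")

    def correct(pred: Sequence[str]) -> int:
        return sum((p == code) == (t == code) for t, p in zip(truth, pred))

    n = len(truth)
    cb, ca = correct(pred_before), correct(pred_after)
    table = np.array([[cb, n - cb], [ca, n - ca]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn(
            f"code {code}: degenerate 2x2 table {table.tolist()}; "
            "chi-square undefined, reporting (0, 1)",
            stacklevel=2,
        )
        return 0.0, 1.0
    stat, p, _, _ = chi2_contingency(table, correction=False)
    return float(stat), float(p)


def metrics_from_counts(
    counts_by_code: Mapping[str, BinaryCounts], z: float = 1.96
) -> list[MetricsRow]:
    """Full metric rows (with DeLong CI) from per-code one-vs-rest counts."""
    rows = []
    for code in sorted(counts_by_code):
        row = compute_metrics(counts_by_code[code], code=code)
        try:
            lo, hi = auc_ci_delong(counts_by_code[code], z=z)
        except ValueError:
            # single-class set for this code: CI undefined
            lo = hi = None
        rows.append(MetricsRow(**{**row.__dict__, "ci_low": lo, "ci_high": hi}))
    return rows


def metrics_table(
    truth: Sequence[str], pred: Sequence[str], codes: Sequence[str] = CODES
) -> list[MetricsRow]:
    """One metric row per code (ascending order), from raw label sequences."""
    cm = confusion_matrix(truth, pred, codes=codes)
    return metrics_from_counts({c: binarize(cm, c, codes) for c in codes})


def render_metrics(rows: Sequence[MetricsRow]) -> pd.DataFrame:
    """Display table: counts plus metrics rounded half-up to 3 decimals."""
    out = []
    for r in rows:
        out.append(
            {
                "label": r.code,
                "TP": r.counts.tp,
                "TN": r.counts.tn,
                "FP": r.counts.fp,
                "FN": r.counts.fn,
                "ACC": round_half_up(r.accuracy),
                "SE": round_half_up(r.sensitivity),
                "SP": round_half_up(r.specificity),
                "F1": round_half_up(r.f1),
                "PPV": round_half_up(r.ppv),
                "NPV": round_half_up(r.npv),
                "AUC": round_half_up(r.auc),
                "CI_low": round_half_up(r.ci_low) if r.ci_low is not None else None,
                "CI_high": round_half_up(r.ci_high) if r.ci_high is not None else None,
            }
        )
    return pd.DataFrame(out)


def scatter_export(
    features,
    cluster_assignments: Sequence[int],
    centroids_feature_plane: np.ndarray,
    out_csv=None,
    out_png=None,
    true_codes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Feature-plane scatter: D on x, L on y, colour per cluster, centroids marked.

    Writes the underlying table (and optionally a figure) and returns the
    table.  Centroids must already be in the raw (D, L) plane.
    """
    features = np.asarray(features, dtype=float)
    if len(features) != len(cluster_assignments):
        raise CardinalityError("features and assignments differ in length")
    df = pd.DataFrame(
        {
            "D_mm": features[:, 0],
            "L_mm": features[:, 1],
            "cluster": np.asarray(cluster_assignments, dtype=int),
        }
    )
    if true_codes is not None:
        df["true_code"] = list(true_codes)
    if out_csv is not None:
        Path(out_csv).parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_csv, index=False)
    if out_png is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        centroids = np.asarray(centroids_feature_plane, dtype=float)
        k = len(centroids)
        fig, ax = plt.subplots(figsize=(6, 6))
        cmap = matplotlib.colormaps["tab10"]
        for c in range(k):
            mask = df["cluster"].to_numpy() == c
            ax.scatter(
                df.loc[mask, "D_mm"],
                df.loc[mask, "L_mm"],
                s=12,
                color=cmap(c % 10),
                label=f"cluster {c}",
            )
        ax.scatter(
            centroids[:, 0], centroids[:, 1],
            s=140, marker="o", facecolor="gold", edgecolor="black", zorder=5,
            label="centroids",
        )
        # pad axes around data and centroid extremes
        allx = np.concatenate([features[:, 0], centroids[:, 0]])
        ally = np.concatenate([features[:, 1], centroids[:, 1]])
        padx = 0.05 * max(float(np.ptp(allx)), 1e-6)
        pady = 0.05 * max(float(np.ptp(ally)), 1e-6)
        ax.set_xlim(allx.min() - padx, allx.max() + padx)
        ax.set_ylim(ally.min() - pady, ally.max() + pady)
        ax.set_xlabel("radiographic diameter D (mm)")
        ax.set_ylabel("radiographic length L (mm)")
        ax.legend(fontsize=7, ncol=2)
        fig.tight_layout()
        Path(out_png).parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(out_png, dpi=120)
        plt.close(fig)
    return df
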