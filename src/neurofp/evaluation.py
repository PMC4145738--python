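"""Clustering evaluation: weighted F-score, accuracy with Wald CIs,
Bland-Altman interrater agreement, and reproduction of the packaged
19-subject reference table.

The F-score weights, per reference class, the best-matching cluster's
harmonic mean of precision (|P_j ∩ C_i| / |C_i|) and recall
(|P_j ∩ C_i| / |P_j|) by the class's share of subjects:

    F = sum_j (|P_j| / n) * max_i 2 P R / (P + R)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .clustering import align_labels
from .errors import ValidationError
from .io import TABLE1_METHOD_COLUMNS, load_table1_fixture

__all__ = [
    "clustering_f_score",
    "accuracy",
    "round_half_up",
    "wald_ci",
    "AgreementStats",
    "bland_altman",
    "reproduce_table1",
]


def clustering_f_score(reference_labels, cluster_labels) -> float:
    """Class-size-weighted best-match F between a reference partition and
    a clustering.  1.0 iff the two partitions coincide up to relabeling.
    Invariant to cluster relabeling and ordering; pairs with empty
    intersection contribute 0 to the per-class max."""
    ref = np.asarray(reference_labels)
    lab = np.asarray(cluster_labels)
    if ref.shape != lab.shape or ref.ndim != 1:
        raise ValidationError("reference and cluster labels must be equal-length 1D")
    n = ref.size
    total = 0.0
    for j in np.unique(ref):
        pj = ref == j
        best = 0.0
        for i in np.unique(lab):
            ci = lab == i
            inter = int((pj & ci).sum())
            if inter == 0:
                continue
            precision = inter / int(ci.sum())
            recall = inter / int(pj.sum())
            best = max(best, 2 * precision * recall / (precision + recall))
        total += (int(pj.sum()) / n) * best
    return total


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero-free: .5 goes up."""
    return int(math.floor(x + 0.5))


def accuracy(reference_labels, labels, align: bool = False) -> tuple[float, int]:
    """Direct per-subject agreement.  Returns (fraction, integer percent,
    half-up).  With ``align`` on, cluster labels are first mapped
    one-to-one onto the reference by optimal assignment — use this for
    de-novo clusterings whose labels are arbitrary."""
    ref = np.asarray(reference_labels)
    lab = np.asarray(labels)
    if ref.shape != lab.shape:
        raise ValidationError("label vectors of unequal length")
    if align:
        lab = align_labels(lab, ref)
    frac = float((ref == lab).mean())
    return frac, round_half_up(100.0 * frac)


def wald_ci(successes: int, n: int, confidence: float = 0.95) -> tuple[int, int]:
    """Wald normal-approximation binomial CI in integer percent, clipped
    to [0, 100] and rounded half-up."""
    if n <= 0:
        raise ValidationError("n must be positive")
    if not 0 <= successes <= n:
        raise ValidationError("successes must be in [0, n]")
    p = successes / n
    z = sstats.norm.ppf(0.5 + confidence / 2.0)
    half = z * math.sqrt(p * (1.0 - p) / n)
    lo = min(max(100.0 * (p - half), 0.0), 100.0)
    hi = min(max(100.0 * (p + half), 0.0), 100.0)
    return round_half_up(lo), round_half_up(hi)


@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman bias and limits of agreement plus Pearson r."""

    bias: float
    loa_low: float
    loa_high: float
    pearson_r: float | None


def bland_altman(values_a, values_b) -> AgreementStats:
    """Paired-agreement statistics with differences d = a - b: bias is
    mean(d), limits are bias ± 1.96 * sample SD(d) (n-1 denominator).
    Pearson r of (a, b) is None when either side has zero variance."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValidationError("need equal-length paired samples with n >= 2")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    r: float | None
    if a.std() == 0 or b.std() == 0:
        r = None
    else:
        r = float(np.corrcoef(a, b)[0, 1])
    return AgreementStats(bias, bias - 1.96 * sd, bias + 1.96 * sd, r)


def reproduce_table1(fixture: pd.DataFrame | None = None) -> pd.DataFrame:
    """F-score (2 decimals) and direct accuracy (integer percent, no
    alignment — the table's labels are already matched to the reference)
    for each of the six method x metric columns of the packaged table."""
    df = fixture if fixture is not None else load_table1_fixture()
    ref = df["clinical"].to_numpy(int)
    rows = []
    for col in TABLE1_METHOD_COLUMNS:
        lab = df[col].to_numpy(int)
        f = clustering_f_score(ref, lab)
        frac, pct = accuracy(ref, lab, align=False)
        matches = int(round(frac * len(ref)))
        ci = wald_ci(matches, len(ref))
        rows.append({
            "column": col,
            "f_score": round(f, 2),
            "accuracy_percent": pct,
            "matches": matches,
            "n": len(ref),
            "ci_low": ci[0],
            "ci_high": ci[1],
        })
    return pd.DataFrame(rows).set_index("column")
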