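"""Binary diagnostic evaluation: Se/Sp/Ac and the balanced-accuracy grades.

Marker tables are tidy pandas DataFrames with columns
``sample``, ``group``, ``marker``, ``value``; group labels are ``control``
and ``experimental``.  The classifier is a leave-one-out midpoint-threshold
rule (the simplest defensible estimator at n = 12-15 per group); sensitivity,
specificity and accuracy follow ``Se = 100·A/N``, ``Sp = 100·B/H``,
``Ac = 100·(A+B)/(N+H)``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "DiagnosticReport",
    "summarize_markers",
    "threshold_classify",
    "operating_characteristics",
    "grade_accuracy",
    "CONTROL",
    "EXPERIMENTAL",
]

CONTROL = "control"
EXPERIMENTAL = "experimental"

_TABLE_COLUMNS = ("sample", "group", "marker", "value")


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"marker table missing columns {sorted(missing)}")
    if table.duplicated(subset=["sample", "marker"]).any():
        raise ValueError("duplicated (sample, marker) pairs")
    return table


@dataclass(frozen=True)
class DiagnosticReport:
    """Operating characteristics of one marker's binary classification."""

    marker: str
    a: int  # true positives
    b: int  # true negatives
    n: int  # experimental group size
    h: int  # control group size
    se: float  # percent
    sp: float
    ac: float
    grade: str
    balanced: bool

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("se", "sp", "ac"):
            d[k] = round(d[k], 1)  # paper-style 1-decimal reporting
        return d


def summarize_markers(table: pd.DataFrame) -> pd.DataFrame:
    """Per-(group, marker) mean and standard error of the mean."""
    table = _validate_table(table)
    sizes = table.groupby(["group", "marker"])["value"].size()
    if (sizes < 2).any():
        raise ValueError("each (group, marker) cell needs >= 2 samples")
    out = (
        table.groupby(["group", "marker"])["value"]
        .agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)))
        .reset_index()
    )
    return out


def operating_characteristics(a: int, b: int, n: int, h: int):
    """``(Se, Sp, Ac)`` percentages from counts.

    ``a``/``b`` are correct positives/negatives, ``n``/``h`` the experimental
    and control group sizes.
    """
    for name, v in (("a", a), ("b", b), ("n", n), ("h", h)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer")
    a, b, n, h = int(a), int(b), int(n), int(h)
    if n < 1 or h < 1 or a > n or b > h:
        raise ValueError("need 0 <= a <= n, 0 <= b <= h, n,h >= 1")
    se = 100.0 * a / n
    sp = 100.0 * b / h
    ac = 100.0 * (a + b) / (n + h)
    return se, sp, ac


def grade_accuracy(ac: float) -> str:
    """Balanced-accuracy grade label.

    Bands (half-open closure of the printed thresholds, graded on the
    unrounded value): <=80 Unsatisfactory, (80, 85] Satisfactory,
    (85, 90] Good, (90, 95] Very good, (95, 100] Excellent.
    """
    if not (0 <= ac <= 100):
        raise ValueError("accuracy must be within [0, 100]")
    if ac <= 80:
        return "Unsatisfactory"
    if ac <= 85:
        return "Satisfactory"
    if ac <= 90:
        return "Good"
    if ac <= 95:
        return "Very good"
    return "Excellent"


def threshold_classify(table: pd.DataFrame, marker: str) -> DiagnosticReport:
    """Leave-one-out midpoint-threshold classification of one marker.

    For each held-out sample the threshold is the midpoint of the two
    training-group means; the sample joins the side of the nearer group mean.
    Ties (value exactly at the threshold, or equal training means) go to the
    control group.  The ``balanced`` flag uses the conventional equal-group
    condition N = H (the printed condition "(A+B) = (N+H)" literally denotes
    perfect classification and is not used).
    """
    table = _validate_table(table)
    sub = table[table["marker"] == marker]
    groups = set(sub["group"])
    if groups != {CONTROL, EXPERIMENTAL}:
        raise ValueError(
            f"marker {marker!r} needs both groups {{{CONTROL!r}, {EXPERIMENTAL!r}}}, got {sorted(groups)}"
        )
    all_samples = set(table["sample"])
    if set(sub["sample"]) != all_samples:
        raise ValueError(f"marker {marker!r} missing for some samples")
    exp = sub[sub["group"] == EXPERIMENTAL]
    ctl = sub[sub["group"] == CONTROL]
    n, h = len(exp), len(ctl)
    if n < 2 or h < 2:
        raise ValueError("both groups need >= 2 samples")
    a = b = 0
    for _, row in sub.iterrows():
        if row["group"] == EXPERIMENTAL:
            tr_exp = exp[exp["sample"] != row["sample"]]["value"].to_numpy()
            tr_ctl = ctl["value"].to_numpy()
        else:
            tr_exp = exp["value"].to_numpy()
            tr_ctl = ctl[ctl["sample"] != row["sample"]]["value"].to_numpy()
        mu_e, mu_c = tr_exp.mean(), tr_ctl.mean()
        thr = 0.5 * (mu_e + mu_c)
        v = row["value"]
        if mu_e == mu_c or v == thr:
            predicted = CONTROL  # conservative tie rule
        elif mu_e > mu_c:
            predicted = EXPERIMENTAL if v > thr else CONTROL
        else:
            predicted = EXPERIMENTAL if v < thr else CONTROL
        if predicted == row["group"]:
            if row["group"] == EXPERIMENTAL:
                a += 1
            else:
                b += 1
    se, sp, ac = operating_characteristics(a, b, n, h)
    return DiagnosticReport(
        marker=marker,
        a=a,
        b=b,
        n=n,
        h=h,
        se=se,
        sp=sp,
        ac=ac,
        grade=grade_accuracy(ac),
        balanced=(n == h),
    )
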