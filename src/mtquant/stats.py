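"""Group summaries and significance annotation.

Conventions shared by every stage: error bars are the standard error of the
mean; pairs of conditions are compared with the unequal-variance (Welch)
t-test; p-values are star-coded with inclusive thresholds
(* p≤0.05, ** p≤0.01, *** p≤0.001, **** p≤0.0001).  No multiple-testing
correction is applied (pairwise tests are reported as-is; noted in output
metadata).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = ["GroupStats", "Comparison", "welch_t", "star_code", "group_stats", "sem"]


def sem(values) -> float:
    """Standard error of the mean (sample SD / √n)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return float("nan")
    return float(v.std(ddof=1) / np.sqrt(v.size))


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test, two-sided.

    Returns (t, dof, p) with Welch–Satterthwaite degrees of freedom.
    Degenerate contract: when both samples have zero variance, t=0 and p=1
    if the means are equal, else t=±inf and p=0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        dof = float(a.size + b.size - 2)
        if a.mean() == b.mean():
            return 0.0, dof, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), dof, 0.0
    res = sps.ttest_ind(a, b, equal_var=False)
    se2 = va / a.size + vb / b.size
    dof = se2**2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    return float(res.statistic), float(dof), float(res.pvalue)


def star_code(p: float) -> str:
    """Star-code a p-value with inclusive boundaries.

    "ns" if p>0.05; "*" if 0.01<p≤0.05; "**" if 0.001<p≤0.01;
    "***" if 0.0001<p≤0.001; "****" if p≤0.0001.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p > 0.05:
        return "ns"
    if p > 0.01:
        return "*"
    if p > 0.001:
        return "**"
    if p > 0.0001:
        return "***"
    return "****"


@dataclass(frozen=True)
class Comparison:
    group_a: str
    group_b: str
    t: float
    dof: float
    p: float
    stars: str


@dataclass
class GroupStats:
    """Per-group n/mean/SEM and all pairwise Welch comparisons."""

    groups: dict[str, dict] = field(default_factory=dict)  # name -> {n, mean, sem}
    comparisons: list[Comparison] = field(default_factory=list)
    note: str = "pairwise Welch t-tests, no multiple-testing correction"

    def to_dict(self) -> dict:
        return {
            "groups": self.groups,
            "comparisons": [vars(c) for c in self.comparisons],
            "note": self.note,
        }


def group_stats(groups: dict[str, list[float]]) -> GroupStats:
    """Summarize named groups and run all pairwise Welch t-tests.

    Groups with fewer than 2 values cannot be tested and are excluded with a
    warning.
    """
    usable: dict[str, np.ndarray] = {}
    for name, values in groups.items():
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            warnings.warn(f"group {name!r} has n={v.size} < 2; excluded")
            continue
        usable[name] = v
    if len(usable) < 2:
        raise ValueError("need at least 2 groups with n >= 2")
    out = GroupStats()
    for name, v in usable.items():
        out.groups[name] = {"n": int(v.size), "mean": float(v.mean()), "sem": sem(v)}
    names = list(usable)
    for i, na in enumerate(names):
        for nb in names[i + 1 :]:
            t, dof, p = welch_t(usable[na], usable[nb])
            out.comparisons.append(
                Comparison(group_a=na, group_b=nb, t=t, dof=dof, p=p, stars=star_code(p))
            )
    return out
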