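"""Intra-cluster dispersion statistics and between-group comparison.

Dispersion is quantified per sequence as the Euclidean distance from its
embedding (in PCA space) to its assigned cluster centroid. Groups are
compared with Levene's test for equality of variances on those distances:
with Z_ij = |Y_ij − center(Y_i)| the statistic is

    W = (N − g)/(g − 1) · Σ_i n_i (Z̄_i − Z̄)² / Σ_i Σ_j (Z_ij − Z̄_i)²

referred to the upper tail of F(g−1, N−g). The classical test centers at
the group mean; centering at the median gives the Brown–Forsythe variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .cluster import ClusteringResult


class DegenerateInputError(ValueError):
    """Levene denominator is zero while group spreads differ."""


def centroid_distances(points: np.ndarray, result: ClusteringResult) -> np.ndarray:
    """Euclidean distance of every point to its assigned centroid.

    The squared distances sum to the clustering inertia by definition.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(result.labels)
    if len(points) != len(labels):
        raise ValueError("points and labels lengths differ")
    if labels.min() < 0 or labels.max() >= len(result.centroids):
        raise ValueError("label out of centroid range")
    return np.linalg.norm(points - result.centroids[labels], axis=1)


@dataclass
class LeveneResult:
    statistic: float            # W
    df: tuple[int, int]         # (g − 1, N − g)
    pvalue: float
    centering: str              # "mean" (classical) or "median" (Brown–Forsythe)


def levene_test(groups: list[np.ndarray], center: str = "mean") -> LeveneResult:
    """Levene's test for equality of variances across two or more groups.

    Each group needs at least two values. If every group's absolute
    deviations are internally constant the statistic is degenerate: when
    the group-level deviations are also all equal, dispersion is exactly
    equal and the test returns W=0, p=1; otherwise the input is rejected
    as degenerate (the F reference distribution does not apply).
    """
    if center not in ("mean", "median"):
        raise ValueError(f"unknown centering {center!r}")
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    g = len(groups)
    if g < 2:
        raise ValueError("need at least 2 groups")
    if any(len(y) < 2 for y in groups):
        raise ValueError("every group needs at least 2 values")
    loc = np.mean if center == "mean" else np.median
    Z = [np.abs(y - loc(y)) for y in groups]
    n = np.array([len(z) for z in Z])
    N = int(n.sum())
    zbar_i = np.array([z.mean() for z in Z])
    zbar = float(np.concatenate(Z).mean())
    numer = float((n * (zbar_i - zbar) ** 2).sum())
    denom = float(sum(((z - zb) ** 2).sum() for z, zb in zip(Z, zbar_i)))
    df = (g - 1, N - g)
    if denom == 0.0:
        if numer == 0.0:
            return LeveneResult(0.0, df, 1.0, center)
        raise DegenerateInputError(
            "zero within-group variability of absolute deviations")
    W = (N - g) / (g - 1) * numer / denom
    p = float(f_dist.sf(W, *df))
    return LeveneResult(float(W), df, p, center)


@dataclass
class PairwiseLevene:
    group_a: str
    group_b: str
    statistic: float
    pvalue: float               # raw
    pvalue_adjusted: float      # Bonferroni over the requested pairs
    df: tuple[int, int]


@dataclass
class GroupDispersionReport:
    """Per-group dispersion summaries plus pairwise Levene comparisons."""

    table: pd.DataFrame         # index: group; columns: n, mean_distance, var_distance
    pairwise: list[PairwiseLevene] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "groups": {str(g): {"n": int(r["n"]),
                                "mean_distance": float(r["mean_distance"]),
                                "var_distance": float(r["var_distance"])}
                       for g, r in self.table.iterrows()},
            "pairwise": [{"group_a": p.group_a, "group_b": p.group_b,
                          "W": p.statistic, "p_raw": p.pvalue,
                          "p_bonferroni": p.pvalue_adjusted,
                          "df": list(p.df)} for p in self.pairwise],
            "warnings": list(self.warnings),
        }


def group_dispersion_report(distances: np.ndarray, group_labels,
                            pairs: list[tuple[str, str]] | None = None,
                            center: str = "mean") -> GroupDispersionReport:
    """Summarize dispersion by group and test all (or requested) pairs.

    Groups with fewer than 2 members are excluded with a warning; a
    single usable group yields summaries only. Raw p-values are reported
    alongside Bonferroni-adjusted ones (adjusted over the number of pairs
    actually tested).
    """
    distances = np.asarray(distances, dtype=float)
    group_labels = np.asarray(group_labels)
    if len(distances) != len(group_labels):
        raise ValueError("distances and group labels lengths differ")
    notes: list[str] = []
    by_group: dict[str, np.ndarray] = {}
    for gname in pd.unique(group_labels):
        vals = distances[group_labels == gname]
        if len(vals) < 2:
            msg = f"group {gname!r} has fewer than 2 members; excluded from tests"
            warnings.warn(msg)
            notes.append(msg)
            continue
        by_group[str(gname)] = vals
    table = pd.DataFrame(
        {"n": {g: len(v) for g, v in by_group.items()},
         "mean_distance": {g: float(v.mean()) for g, v in by_group.items()},
         "var_distance": {g: float(v.var(ddof=1)) for g, v in by_group.items()}})
    if len(by_group) < 2:
        msg = "fewer than 2 usable groups; no pairwise tests run"
        warnings.warn(msg)
        notes.append(msg)
        return GroupDispersionReport(table=table, warnings=notes)
    if pairs is None:
        pairs = list(combinations(by_group, 2))
    m = len(pairs)
    results = []
    for a, b in pairs:
        if a not in by_group or b not in by_group:
            notes.append(f"pair ({a}, {b}) skipped: group unusable")
            continue
        res = levene_test([by_group[a], by_group[b]], center=center)
        results.append(PairwiseLevene(
            group_a=a, group_b=b, statistic=res.statistic,
            pvalue=res.pvalue, pvalue_adjusted=min(1.0, res.pvalue * m),
            df=res.df))
    return GroupDispersionReport(table=table, pairwise=results, warnings=notes)
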