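"""Subnetwork analysis: regional connectivity strength and wiring cost.

Networks are thresholded (q < 0.05 and |r| >= 0.3 by default), surviving
edges are partitioned into PFC-intra, M1_S1-intra and PFC-M1_S1 inter
subnetworks, and per-subject mean correlation (signed) and node degree
(surviving-edge count) feed normality-gated group comparisons: Shapiro-Wilk
on each group decides between the two-sample t-test (mean, SD reported) and
the Wilcoxon rank-sum test (median, IQR reported).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import ConnectivityNetwork
from .probe import M1S1, PFC

SUBNETWORKS = (PFC, M1S1, f"{PFC}-{M1S1}")
INTER = SUBNETWORKS[2]


@dataclass(frozen=True)
class SubnetworkSummary:
    """Per-subject regional summary of one thresholded network."""

    subject: str
    group: str
    week: int
    stimulus: str
    subnetwork: str
    mean_correlation: float  # signed; NaN when no edge survives
    degree: int              # surviving-edge count


@dataclass(frozen=True)
class GroupComparison:
    """Active-vs-sham comparison of one subnetwork metric."""

    subnetwork: str
    metric: str
    active_location: float
    active_spread: float
    sham_location: float
    sham_spread: float
    test_used: str            # "t" | "wilcoxon"
    p_value: float
    ties_flagged: bool = False


def threshold_network(net: ConnectivityNetwork, q_max: float = 0.05,
                      r_min: float = 0.3) -> list[tuple[int, int, float]]:
    """Edges surviving the dual gate q < q_max and |r| >= r_min.

    The |.| keeps anticorrelated (negative) links; the sign of r is
    preserved on the surviving edges.
    """
    edges = []
    for i, j, r, q in net.edges():
        if q < q_max and abs(r) >= r_min:
            edges.append((i, j, float(r)))
    return edges


def subnetwork_metrics(edges: list[tuple[int, int, float]], regions,
                       provenance: dict | None = None) -> list[SubnetworkSummary]:
    """Partition surviving edges into the three subnetworks and summarize.

    ``regions`` maps channel index -> region label (sequence). An empty
    partition reports degree 0 and NaN mean correlation.
    """
    regions = list(regions)
    buckets: dict[str, list[float]] = {s: [] for s in SUBNETWORKS}
    for i, j, r in edges:
        ri, rj = regions[i], regions[j]
        key = ri if ri == rj else INTER
        buckets[key].append(r)
    prov = provenance or {}
    out = []
    for sub in SUBNETWORKS:
        vals = buckets[sub]
        out.append(SubnetworkSummary(
            subject=prov.get("subject", ""), group=prov.get("group", ""),
            week=prov.get("week", -1), stimulus=prov.get("stimulus", ""),
            subnetwork=sub,
            mean_correlation=float(np.mean(vals)) if vals else math.nan,
            degree=len(vals)))
    return out


def summarize_network(net: ConnectivityNetwork, regions, q_max: float = 0.05,
                      r_min: float = 0.3) -> list[SubnetworkSummary]:
    """Threshold one network and compute its three subnetwork summaries."""
    edges = threshold_network(net, q_max=q_max, r_min=r_min)
    return subnetwork_metrics(edges, regions, provenance=net.provenance)


def compare_groups(active: np.ndarray, sham: np.ndarray, subnetwork: str = "",
                   metric: str = "", alpha: float = 0.05) -> GroupComparison:
    """Normality-gated two-group comparison.

    Shapiro-Wilk at ``alpha`` on each group; when both pass, a two-sample
    t-test with mean (SD) reporting, otherwise a Wilcoxon rank-sum
    (Mann-Whitney, tie-corrected) with median (IQR) reporting. Two-sided.
    """
    a = np.asarray(active, float)
    s = np.asarray(sham, float)
    a, s = a[np.isfinite(a)], s[np.isfinite(s)]
    if a.size < 3 or s.size < 3:
        raise ValueError("at least 3 subjects per group required")

    ties_flagged = False

    def _normal(x: np.ndarray) -> bool:
        if np.ptp(x) == 0:
            return False  # degenerate all-tied sample
        return stats.shapiro(x).pvalue >= alpha

    if _normal(a) and _normal(s):
        test_used = "t"
        if np.ptp(np.concatenate([a, s])) == 0:
            p = 1.0
        else:
            p = float(stats.ttest_ind(a, s).pvalue)
        loc_a, loc_s = a.mean(), s.mean()
        spr_a, spr_s = a.std(ddof=1), s.std(ddof=1)
    else:
        test_used = "wilcoxon"
        if np.ptp(np.concatenate([a, s])) == 0:
            p, ties_flagged = 1.0, True
        else:
            ties_flagged = len(np.unique(np.concatenate([a, s]))) < a.size + s.size
            p = float(stats.mannwhitneyu(a, s, alternative="two-sided").pvalue)
        loc_a, loc_s = np.median(a), np.median(s)
        spr_a = np.subtract(*np.percentile(a, [75, 25]))
        spr_s = np.subtract(*np.percentile(s, [75, 25]))
    return GroupComparison(subnetwork=subnetwork, metric=metric,
                           active_location=float(loc_a), active_spread=float(spr_a),
                           sham_location=float(loc_s), sham_spread=float(spr_s),
                           test_used=test_used, p_value=p,
                           ties_flagged=ties_flagged)


def weekly_report(summaries: list[SubnetworkSummary],
                  alpha: float = 0.05,
                  bh_correct: bool = False) -> pd.DataFrame:
    """Group comparisons per (week, subnetwork, metric): the study-table shape.

    One row per cell with per-group location (spread), the test used, and the
    two-sided p-value; significance marked at p < alpha. ``bh_correct``
    additionally adjusts p across the whole comparison family (off by
    default: the comparisons are reported per cell, uncorrected).
    Missing cells are flagged.
    """
    df = pd.DataFrame([vars(s) for s in summaries])
    if df.empty:
        raise ValueError("no summaries supplied")
    rows = []
    for (stim, week, sub) in sorted(
            df[["stimulus", "week", "subnetwork"]].drop_duplicates()
            .itertuples(index=False), key=lambda t: (t[0], t[1], t[2])):
        cell = df[(df.stimulus == stim) & (df.week == week) & (df.subnetwork == sub)]
        for metric, col in (("correlation", "mean_correlation"), ("degree", "degree")):
            a = cell.loc[cell.group == "active", col].to_numpy(float)
            s = cell.loc[cell.group == "sham", col].to_numpy(float)
            base = {"stimulus": stim, "week": week, "subnetwork": sub,
                    "metric": metric}
            if a[np.isfinite(a)].size < 3 or s[np.isfinite(s)].size < 3:
                rows.append({**base, "missing": True, "p_value": np.nan})
                continue
            cmp = compare_groups(a, s, subnetwork=sub, metric=metric, alpha=alpha)
            rows.append({**base, "missing": False,
                         "active_location": cmp.active_location,
                         "active_spread": cmp.active_spread,
                         "sham_location": cmp.sham_location,
                         "sham_spread": cmp.sham_spread,
                         "test_used": cmp.test_used,
                         "p_value": cmp.p_value})
    out = pd.DataFrame(rows)
    if bh_correct:
        from statsmodels.stats.multitest import multipletests
        mask = out["p_value"].notna()
        if mask.any():
            _, q, _, _ = multipletests(out.loc[mask, "p_value"], method="fdr_bh")
            out.loc[mask, "q_value"] = q
    out["significant"] = out["p_value"] < alpha
    return out
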