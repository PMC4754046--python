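"""Group-wise comparisons of structural features between variant classes.

Reproduces the boxplot-style analysis: for a feature such as axial (Z)
position, burial, conservation or an external pathogenicity score, compare
the residue groups {diagnostic, tetrad, hotspot, population, all-residues}
pairwise with a two-sided Mann-Whitney U test (rank-based, so the arbitrary
Z origin is immaterial).  Welch's t is available for sensitivity analysis.
No multiple-testing correction is applied by default (raw P-values are
reported); Holm adjustment is optional.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "compare_groups",
    "run_group_suite",
    "five_number_summary",
    "holm_adjust",
    "GROUP_ORDER",
]

GROUP_ORDER = ("diagnostic", "tetrad", "hotspot", "population", "all_residues")

EXACT_LIMIT = 2000  # n_a * n_b at or below which the exact null is enumerated


def five_number_summary(values) -> tuple[float, float, float, float, float]:
    v = np.asarray(values, float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return float(v.min()), float(q1), float(med), float(q3), float(v.max())


@dataclass(frozen=True)
class GroupComparison:
    feature: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic: float            # Mann-Whitney U (of group_a) or Welch t
    p_value: float              # two-sided
    direction: int              # sign of median(a) - median(b)
    method: str
    summary_a: tuple[float, float, float, float, float]
    summary_b: tuple[float, float, float, float, float]
    members_a: tuple[int, ...] = ()
    members_b: tuple[int, ...] = ()

    def __post_init__(self):
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")


def compare_groups(values_a, values_b, method: str = "mann_whitney",
                   feature: str = "", group_a: str = "a", group_b: str = "b",
                   members_a=(), members_b=()) -> GroupComparison:
    """Two-sided two-sample test between feature value lists.

    Mann-Whitney: the exact null distribution is enumerated when
    ``n_a * n_b <= 2000`` and the pooled sample has no ties; otherwise the
    normal approximation with tie and continuity corrections is used.
    """
    a = np.asarray(list(values_a), float)
    b = np.asarray(list(values_b), float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("feature values must not contain NaN")

    if method == "mann_whitney":
        pooled = np.concatenate([a, b])
        no_ties = len(np.unique(pooled)) == len(pooled)
        if len(a) * len(b) <= EXACT_LIMIT and no_ties:
            used = "mann_whitney_exact"
            res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        else:
            used = "mann_whitney_normal"
            res = sps.mannwhitneyu(a, b, alternative="two-sided",
                                   method="asymptotic", use_continuity=True)
        stat, p = float(res.statistic), float(res.pvalue)
    elif method == "welch_t":
        used = "welch_t"
        res = sps.ttest_ind(a, b, equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")

    p = min(max(p, np.nextafter(0, 1)), 1.0)
    direction = int(np.sign(np.median(a) - np.median(b)))
    return GroupComparison(
        feature=feature, group_a=group_a, group_b=group_b,
        n_a=len(a), n_b=len(b), statistic=stat, p_value=p,
        direction=direction, method=used,
        summary_a=five_number_summary(a), summary_b=five_number_summary(b),
        members_a=tuple(members_a), members_b=tuple(members_b),
    )


def holm_adjust(pvalues: list[float]) -> list[float]:
    """Holm step-down adjusted p-values (optional; off by default upstream)."""
    m = len(pvalues)
    order = np.argsort(pvalues)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvalues[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


def build_groups(annotated, motif=None, tetrads=None,
                 hotspot_residues: set[int] | None = None,
                 all_residue_numbers: list[int] | None = None,
                 unique_residues: bool = True) -> dict[str, list[int]]:
    """Member residue lists of the five standard comparison groups.

    ``diagnostic`` / ``population`` from the annotated variants (deduplicated
    to unique residues by default, matching the "six amino acids vs 29 amino
    acids" comparison); ``tetrad`` = all member residues of all tetrad
    records; ``hotspot`` from the supplied list; ``all_residues`` = every
    domain residue.  A residue may belong to several groups.
    """
    groups: dict[str, list[int]] = {}
    for cat in ("diagnostic", "population"):
        nums = [a.variant.residue_number for a in annotated
                if a.variant.source_category == cat]
        if unique_residues:
            nums = sorted(set(nums))
        groups[cat] = nums
    tet = set()
    for t in (tetrads or []):
        tet |= {v for v in t.members.values() if v is not None}
    groups["tetrad"] = sorted(tet)
    groups["hotspot"] = sorted(hotspot_residues) if hotspot_residues else []
    groups["all_residues"] = sorted(all_residue_numbers or [])
    return groups


def run_group_suite(annotated, feature_values: dict[str, dict[int, float]],
                    motif=None, tetrads=None,
                    hotspot_residues: set[int] | None = None,
                    all_residue_numbers: list[int] | None = None,
                    method: str = "mann_whitney",
                    unique_residues: bool = True,
                    holm: bool = False) -> list[GroupComparison]:
    """All pairwise group comparisons for each feature.

    *feature_values* maps feature name -> {residue number -> value}.  A
    comparison is skipped with a warning when a whole group lacks the feature.
    """
    groups = build_groups(annotated, motif=motif, tetrads=tetrads,
                          hotspot_residues=hotspot_residues,
                          all_residue_numbers=all_residue_numbers,
                          unique_residues=unique_residues)
    results: list[GroupComparison] = []
    for feature, per_res in feature_values.items():
        feats: dict[str, tuple[list[int], list[float]]] = {}
        for name, members in groups.items():
            kept = [(n, per_res[n]) for n in members if n in per_res]
            feats[name] = ([n for n, _ in kept], [v for _, v in kept])
        names = [g for g in GROUP_ORDER if groups.get(g)]
        for i, ga in enumerate(names):
            for gb in names[i + 1:]:
                ma, va = feats[ga]
                mb, vb = feats[gb]
                if not va or not vb:
                    warnings.warn(f"{feature}: group {ga if not va else gb} "
                                  f"has no values; comparison skipped")
                    continue
                results.append(compare_groups(
                    va, vb, method=method, feature=feature,
                    group_a=ga, group_b=gb, members_a=ma, members_b=mb))
    if holm:
        adj = holm_adjust([r.p_value for r in results])
        results = [GroupComparison(**{**r.__dict__, "p_value": max(p, r.p_value)})
                   for r, p in zip(results, adj)]
    return results


def comparisons_to_records(results: list[GroupComparison]) -> list[dict]:
    """JSON/TSV-friendly dicts (full provenance: sizes and member lists)."""
    out = []
    for r in results:
        out.append({
            "feature": r.feature, "group_a": r.group_a, "group_b": r.group_b,
            "n_a": r.n_a, "n_b": r.n_b, "statistic": r.statistic,
            "p_value": r.p_value, "direction": r.direction, "method": r.method,
            "summary_a": list(r.summary_a), "summary_b": list(r.summary_b),
            "members_a": list(r.members_a), "members_b": list(r.members_b),
        })
    return out
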