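"""Influential-metabolite selection and the Venn partition with direction arrows.

A metabolite is influential when its PLS-DA VIP is >= 1 and the joint p of
the two-factor univariate model is < 0.05 (both thresholds configurable).
Selected metabolites are then partitioned by which of the three model terms
(capacity, age, interaction) are individually significant, and each
qualifying term contributes a direction arrow from the sign of its
regression coefficient under the documented dummy coding: "up" means higher
in HCR (capacity), higher in old (age), extra old-HCR effect positive
(interaction).  A selected metabolite with no individually significant term
falls into a separate "joint_only" bucket.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

TERMS = ("capacity", "age", "interaction")
REGIONS = (
    "capacity_only",
    "age_only",
    "interaction_only",
    "capacity_age",
    "capacity_interaction",
    "age_interaction",
    "all_three",
    "joint_only",
)

_REGION_BY_TERMS = {
    ("capacity",): "capacity_only",
    ("age",): "age_only",
    ("interaction",): "interaction_only",
    ("capacity", "age"): "capacity_age",
    ("capacity", "interaction"): "capacity_interaction",
    ("age", "interaction"): "age_interaction",
    ("capacity", "age", "interaction"): "all_three",
    (): "joint_only",
}


@dataclass
class SelectionRule:
    """Thresholds combining multivariate and univariate evidence."""

    vip_threshold: float = 1.0
    p_threshold: float = 0.05
    fdr_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.vip_threshold <= 0:
            raise ValueError("vip_threshold must be positive")
        for name in ("p_threshold", "fdr_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")


def select_influential(vip: pd.Series, joint_p: pd.Series,
                       rule: SelectionRule | None = None) -> list:
    """Metabolites with VIP >= threshold AND joint p < threshold (sorted)."""
    rule = rule or SelectionRule()
    if set(vip.index) != set(joint_p.index):
        raise ValueError("VIP and joint-p tables cover different metabolites")
    joint_p = joint_p.reindex(vip.index)
    keep = (vip >= rule.vip_threshold) & (joint_p < rule.p_threshold)
    return sorted(vip.index[keep.fillna(False)])


@dataclass
class VennPartition:
    """Region assignment and per-term direction arrows for selected metabolites."""

    table: pd.DataFrame  # columns: metabolite, region, arrows, terms
    p_threshold: float = 0.05

    def region_counts(self) -> pd.DataFrame:
        counts = {r: 0 for r in REGIONS}
        for r in self.table["region"]:
            counts[r] += 1
        return pd.DataFrame({"region": list(counts), "count": list(counts.values())})

    def members(self, region: str) -> list:
        return sorted(self.table.loc[self.table["region"] == region, "metabolite"])


def partition_venn(selected, per_term_p: pd.DataFrame,
                   coefficients: pd.DataFrame, p_threshold: float = 0.05
                   ) -> VennPartition:
    """Assign each selected metabolite to its Venn region with arrows.

    ``per_term_p`` and ``coefficients`` are indexed by metabolite with columns
    capacity, age, interaction (p-values resp. regression coefficients).
    Arrows are ordered capacity, age, interaction — one per qualifying term.
    """
    selected = sorted(selected)
    missing = [m for m in selected if m not in per_term_p.index]
    if missing:
        raise ValueError(f"selected metabolites missing from tables: {missing}")
    rows = []
    for met in selected:
        sig = tuple(t for t in TERMS if per_term_p.loc[met, t] < p_threshold)
        arrows = ";".join(
            ("up" if coefficients.loc[met, t] > 0 else "down") for t in sig
        )
        rows.append(
            {
                "metabolite": met,
                "region": _REGION_BY_TERMS[sig],
                "terms": ";".join(sig),
                "arrows": arrows,
            }
        )
    table = pd.DataFrame(rows, columns=["metabolite", "region", "terms", "arrows"])
    return VennPartition(table, p_threshold=p_threshold)


def summarize_report(partition: VennPartition, tissue: str = ""
                     ) -> tuple[pd.DataFrame, pd.DataFrame, str]:
    """Machine-readable membership and counts tables plus a text rendering."""
    membership = partition.table.copy()
    membership.insert(0, "tissue", tissue)
    counts = partition.region_counts()
    counts.insert(0, "tissue", tissue)
    lines = [f"Venn partition — {tissue or 'unlabelled tissue'}",
             f"selected metabolites: {len(membership)}"]
    for region in REGIONS:
        members = partition.members(region)
        if not members:
            continue
        lines.append(f"  {region} ({len(members)}):")
        for met in members:
            row = membership.loc[membership["metabolite"] == met].iloc[0]
            arrow_txt = f" [{row['arrows']}]" if row["arrows"] else ""
            lines.append(f"    {met}{arrow_txt}")
    return membership, counts, "\n".join(lines) + "\n"
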