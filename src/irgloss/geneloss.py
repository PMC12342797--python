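"""Outgroup-referenced gene-loss accounting over syntenic orthogroups.

Each (crop, wild relative, outgroup) triplicate contributes a pan-gene
presence/absence matrix in which the outgroup gene anchors every
orthogroup.  A crop loss event is an orthogroup with the outgroup and the
wild relative present but the crop absent; symmetrically for wild losses.
Orthogroups without an outgroup reference gene are excluded entirely.
Loss proportions are reported separately for IRG orthogroups (those whose
outgroup reference gene classifies as an immune receptor) and genome-wide
(all outgroup-referenced orthogroups, IRGs included).

Two contrasts mirror the downstream questions: a paired test of IRG loss
against each crop's own genome-wide loss, and a Welch two-sample test of
crop IRG loss against wild IRG loss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .repertoire import one_sample_t, shapiro_wilk, wilcoxon_signed_rank

__all__ = [
    "PanGeneMatrix",
    "LossSummary",
    "ContrastResult",
    "score_losses",
    "loss_proportions",
    "contrast_irg_vs_genomewide",
    "contrast_crop_vs_wild",
    "welch_t_from_summary",
]

_REQUIRED_COLS = ("orthogroup_id", "crop", "wild", "outgroup", "outgroup_gene_id", "is_irg")


@dataclass
class PanGeneMatrix:
    """Presence/absence of genes per species over one triplicate.

    ``table`` columns: ``orthogroup_id`` (unique), boolean ``crop``,
    ``wild``, ``outgroup`` presence flags (presence = at least one gene of
    that species in the orthogroup; copy number is ignored), an
    ``outgroup_gene_id`` (empty/NA when the orthogroup has no outgroup
    reference gene) and a boolean ``is_irg`` flag carried by the outgroup
    reference gene's classification.
    """

    triplicate_id: str
    crop_species: str
    wild_species: str
    outgroup_species: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED_COLS if c not in self.table.columns]
        if missing:
            raise ValueError(f"pan-gene table missing columns: {missing}")
        if self.table["orthogroup_id"].duplicated().any():
            dup = self.table.loc[self.table["orthogroup_id"].duplicated(), "orthogroup_id"]
            raise ValueError(f"duplicate orthogroup ids: {list(dup.head())}")
        t = self.table
        has_ref = t["outgroup_gene_id"].notna() & (t["outgroup_gene_id"].astype(str) != "")
        if (t["is_irg"].astype(bool) & ~has_ref).any():
            raise ValueError("is_irg set on orthogroups lacking an outgroup reference gene")

    @property
    def referenced(self) -> pd.DataFrame:
        """Rows carrying an outgroup reference gene (the analysis universe)."""
        t = self.table
        mask = t["outgroup_gene_id"].notna() & (t["outgroup_gene_id"].astype(str) != "")
        return t.loc[mask]


@dataclass
class LossSummary:
    """Per-species loss proportions for one triplicate member."""

    species_id: str
    role: str  # "crop" | "wild"
    irg_loss_pct: float
    gw_loss_pct: float
    n_irg_reference: int
    n_gw_reference: int
    n_irg_lost: int
    n_gw_lost: int

    def __post_init__(self) -> None:
        if not (0 <= self.irg_loss_pct <= 100 and 0 <= self.gw_loss_pct <= 100):
            raise ValueError("loss percentages must lie in [0, 100]")


@dataclass
class ContrastResult:
    mean_diff: float
    statistic: float
    df: float
    p_value: float
    test_used: str


def score_losses(m: PanGeneMatrix) -> pd.DataFrame:
    """Flag loss events per outgroup-referenced orthogroup.

    A crop loss requires outgroup AND wild presence with crop absence; a
    wild loss requires outgroup AND crop presence with wild absence.  The
    two events are mutually exclusive per orthogroup.  Orthogroups with
    no outgroup reference gene are excluded from the returned frame.
    """
    t = m.referenced
    crop = t["crop"].astype(bool).to_numpy()
    wild = t["wild"].astype(bool).to_numpy()
    out = t["outgroup"].astype(bool).to_numpy()
    events = pd.DataFrame(
        {
            "orthogroup_id": t["orthogroup_id"].to_numpy(),
            "is_irg": t["is_irg"].astype(bool).to_numpy(),
            "crop_loss": out & wild & ~crop,
            "wild_loss": out & crop & ~wild,
        }
    )
    return events


def loss_proportions(events: pd.DataFrame, m: PanGeneMatrix) -> tuple[LossSummary, LossSummary]:
    """Loss percentages for the crop and the wild relative of a triplicate.

    Denominators are counts of outgroup-referenced orthogroups: the IRG
    subset for ``irg_loss_pct`` and all of them for ``gw_loss_pct`` (IRG
    orthogroups are part of the genome-wide universe).
    """
    n_gw = len(events)
    n_irg = int(events["is_irg"].sum())
    if n_gw == 0:
        raise ValueError("no outgroup-referenced orthogroups: denominators are zero")
    if n_irg == 0:
        raise ValueError("no IRG reference orthogroups: IRG denominator is zero")

    out = []
    for role, species, col in (
        ("crop", m.crop_species, "crop_loss"),
        ("wild", m.wild_species, "wild_loss"),
    ):
        lost_gw = int(events[col].sum())
        lost_irg = int((events[col] & events["is_irg"]).sum())
        out.append(
            LossSummary(
                species_id=species,
                role=role,
                irg_loss_pct=100.0 * lost_irg / n_irg,
                gw_loss_pct=100.0 * lost_gw / n_gw,
                n_irg_reference=n_irg,
                n_gw_reference=n_gw,
                n_irg_lost=lost_irg,
                n_gw_lost=lost_gw,
            )
        )
    return out[0], out[1]


def contrast_irg_vs_genomewide(
    summaries: list[LossSummary], shapiro_threshold: float = 0.05
) -> ContrastResult:
    """Paired contrast of IRG loss against genome-wide loss within species.

    Works on the per-species differences ``irg_loss_pct − gw_loss_pct``; a
    Shapiro–Wilk gate on those differences dispatches to the paired t-test
    (one-sample t on the differences) or, when normality is rejected, to
    the Wilcoxon signed-rank test.
    """
    if len(summaries) < 2:
        raise ValueError("paired contrast requires at least 2 species")
    diffs = np.array([s.irg_loss_pct - s.gw_loss_pct for s in summaries], dtype=float)
    mean_diff = float(diffs.mean())
    if np.ptp(diffs) == 0:
        # constant differences: if all zero, nothing to test
        if diffs[0] == 0:
            return ContrastResult(0.0, 0.0, float(len(diffs) - 1), 1.0, "degenerate")
        w = wilcoxon_signed_rank(diffs)
        return ContrastResult(mean_diff, w.statistic, float("nan"), w.p_value, "wilcoxon_signed_rank")
    sp = shapiro_wilk(diffs)
    if sp > shapiro_threshold:
        t, df, p = one_sample_t(diffs)
        return ContrastResult(mean_diff, t, float(df), p, "paired_t")
    w = wilcoxon_signed_rank(diffs)
    return ContrastResult(mean_diff, w.statistic, float("nan"), w.p_value, "wilcoxon_signed_rank")


def welch_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float, float, float]:
    """Welch two-sample t-test from group summaries.

    Returns ``(mean_diff, t, df, p)`` with the Welch–Satterthwaite
    degrees of freedom and a two-sided p-value.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("Welch test requires n >= 2 per group")
    v1 = sd1**2 / n1
    v2 = sd2**2 / n2
    if v1 + v2 == 0:
        raise ValueError("Welch test undefined: zero variance in both groups")
    mean_diff = mean1 - mean2
    se = math.sqrt(v1 + v2)
    t = mean_diff / se
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(mean_diff), float(t), float(df), float(p)


def contrast_crop_vs_wild(
    crop_summaries: list[LossSummary], wild_summaries: list[LossSummary]
) -> ContrastResult:
    """Welch two-sample contrast of crop vs wild IRG loss percentages."""
    if len(crop_summaries) < 2 or len(wild_summaries) < 2:
        raise ValueError("two-sample contrast requires n >= 2 per group")
    a = np.array([s.irg_loss_pct for s in crop_summaries], dtype=float)
    b = np.array([s.irg_loss_pct for s in wild_summaries], dtype=float)
    mean_diff, t, df, p = welch_t_from_summary(
        a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
    )
    return ContrastResult(mean_diff, t, df, p, "welch_t")
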