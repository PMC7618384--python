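"""Ligand-receptor matching and communication scoring between stromal senders
and sensory-neuron receivers.

Sender populations (Pdgfrb+ fibroblasts or mural cells) contribute ligands
selected from a differential-expression table; a curated ligand -> receptor
database (multi-subunit aware: a receptor complex needs *all* its chains)
is joined against the receptor expression of a receiver population (e.g.
neurofilament-positive neurons, nociceptors, C-LTMRs). Matched pairs are
scored as scaled ligand expression x min-over-subunits scaled receptor
expression and summed per interaction family (ECM, cytokine, growth factor,
adhesion, chemokine, other); higher family scores mean more matching pairs
expressed on both sides. Enabled-interaction counts before vs after injury
are compared with a two-sided Fisher exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FAMILIES",
    "LRPair",
    "ReceiverProfile",
    "MatchedPair",
    "CommunicationScore",
    "InteractionComparison",
    "validate_de_table",
    "select_regulated_genes",
    "validate_lr_database",
    "match_ligand_receptor",
    "minmax_scale_panel",
    "communication_scores",
    "compare_interaction_counts",
    "fold_change_from_log2",
    "volcano_regulated",
]

FAMILIES = ("ECM", "cytokine", "growth factor", "adhesion", "chemokine", "other")

DE_COLUMNS = ("gene", "log2fc", "padj", "mean_a", "mean_b")


def validate_de_table(de: pd.DataFrame) -> pd.DataFrame:
    """Check a differential-expression table (as consumed, not recomputed)."""
    missing = [c for c in DE_COLUMNS if c not in de.columns]
    if missing:
        raise ValueError(f"DE table lacks columns {missing}")
    if de["gene"].duplicated().any():
        dupes = de.loc[de["gene"].duplicated(), "gene"].tolist()
        raise ValueError(f"duplicate gene symbols in DE table: {dupes}")
    if len(de) and not de["padj"].between(0.0, 1.0).all():
        raise ValueError("padj values must lie in [0, 1]")
    return de


def select_regulated_genes(
    de: pd.DataFrame, alpha: float = 0.05, direction: str = "both"
) -> set[str]:
    """Genes with adjusted p < alpha whose fold-change sign matches ``direction``."""
    validate_de_table(de)
    if direction not in ("up", "down", "both"):
        raise ValueError(f"unknown direction {direction!r}")
    if de.empty:
        return set()
    sig = de["padj"] < alpha
    if direction == "up":
        sig &= de["log2fc"] > 0
    elif direction == "down":
        sig &= de["log2fc"] < 0
    return set(de.loc[sig, "gene"])


def fold_change_from_log2(log2fc: float) -> float:
    """Linear fold change at a log2 fold-change value (log2FC of 3 = eightfold)."""
    return float(2.0 ** log2fc)


def volcano_regulated(
    de: pd.DataFrame, log2fc_cutoff: float = 3.0, alpha: float = 0.05
) -> pd.DataFrame:
    """Rows significant at ``alpha`` and beyond the volcano |log2FC| cutoff."""
    validate_de_table(de)
    keep = (de["padj"] < alpha) & (de["log2fc"].abs() > log2fc_cutoff)
    return de.loc[keep].copy()


# ---------------------------------------------------------------------------
# ligand-receptor database and matching


@dataclass(frozen=True)
class LRPair:
    ligand: str
    receptors: tuple[str, ...]  # every subunit is required
    family: str = "other"
    source: str = ""

    def __post_init__(self) -> None:
        if not self.receptors:
            raise ValueError(f"pair for ligand {self.ligand!r} lists no receptor subunits")
        if self.family not in FAMILIES:
            raise ValueError(f"unknown interaction family {self.family!r}")


def validate_lr_database(db: Sequence[LRPair]) -> tuple[LRPair, ...]:
    seen = set()
    for p in db:
        key = (p.ligand, tuple(sorted(p.receptors)))
        if key in seen:
            raise ValueError(f"duplicate ligand/receptor-set row: {key}")
        seen.add(key)
    return tuple(db)


@dataclass(frozen=True)
class ReceiverProfile:
    """A receiver population (sensory-neuron subtype) and its expression vector."""

    label: str
    expression: Mapping[str, float]

    def __post_init__(self) -> None:
        bad = {g: v for g, v in self.expression.items() if v < 0}
        if bad:
            raise ValueError(f"negative expression in receiver {self.label!r}: {bad}")

    def get(self, gene: str, default: float = 0.0) -> float:
        return float(self.expression.get(gene, default))


@dataclass(frozen=True)
class MatchedPair:
    ligand: str
    receptors: tuple[str, ...]
    family: str


def match_ligand_receptor(
    ligands: set[str],
    db: Sequence[LRPair],
    receiver: ReceiverProfile,
    expr_threshold: float = 0.0,
) -> list[MatchedPair]:
    """Pairs whose ligand is in ``ligands`` and whose every receptor subunit is
    expressed strictly above ``expr_threshold`` in the receiver."""
    if expr_threshold < 0:
        raise ValueError("expr_threshold must be non-negative")
    validate_lr_database(db)
    out = []
    for pair in db:
        if pair.ligand not in ligands:
            continue
        if all(receiver.get(r) > expr_threshold for r in pair.receptors):
            out.append(
                MatchedPair(ligand=pair.ligand, receptors=pair.receptors, family=pair.family)
            )
    return out


# ---------------------------------------------------------------------------
# communication scores


def minmax_scale_panel(panel: pd.DataFrame, top: float = 10.0) -> pd.DataFrame:
    """Rescale each gene (row) to [0, top] across the population panel (columns).

    Constant rows map to 0; the scaling is invariant to multiplying all
    expression values by a positive constant.
    """
    lo = panel.min(axis=1)
    hi = panel.max(axis=1)
    span = (hi - lo).replace(0.0, np.nan)
    scaled = panel.sub(lo, axis=0).div(span, axis=0).mul(top).fillna(0.0)
    return scaled


@dataclass(frozen=True)
class CommunicationScore:
    sender: str
    receiver: str
    family: str
    score: float
    contributions: tuple[tuple[MatchedPair, float], ...] = ()


def communication_scores(
    sender_expr: Mapping[str, float],
    receiver: ReceiverProfile,
    pairs: Sequence[MatchedPair],
    scaling: str = "minmax_0_10",
    panel: pd.DataFrame | None = None,
    sender_label: str = "sender",
) -> list[CommunicationScore]:
    """Aggregate per-pair contributions into per-family communication scores.

    Contribution = scaled sender ligand expression x min over receptor
    subunits of scaled receiver expression; the family score is the sum over
    its matched pairs. With ``scaling='minmax_0_10'`` every gene is first
    rescaled to [0, 10] across ``panel`` (defaults to the two populations at
    hand); ``'none'`` scores raw expression.
    """
    if scaling not in ("minmax_0_10", "none"):
        raise ValueError(f"unknown scaling {scaling!r}")

    for pair in pairs:
        for gene in (pair.ligand, *pair.receptors):
            if gene not in sender_expr and gene not in receiver.expression:
                raise ValueError(
                    f"matched pair references gene {gene!r} absent from both "
                    "expression tables"
                )

    if scaling == "minmax_0_10":
        if panel is None:
            genes = sorted(set(sender_expr) | set(receiver.expression))
            panel = pd.DataFrame(
                {
                    sender_label: [float(sender_expr.get(g, 0.0)) for g in genes],
                    receiver.label: [receiver.get(g) for g in genes],
                },
                index=genes,
            )
        scaled = minmax_scale_panel(panel)

        def s_expr(g: str) -> float:
            return float(scaled.at[g, sender_label]) if g in scaled.index else 0.0

        def r_expr(g: str) -> float:
            return float(scaled.at[g, receiver.label]) if g in scaled.index else 0.0

    else:

        def s_expr(g: str) -> float:
            return float(sender_expr.get(g, 0.0))

        def r_expr(g: str) -> float:
            return receiver.get(g)

    by_family: dict[str, list[tuple[MatchedPair, float]]] = {f: [] for f in FAMILIES}
    for pair in pairs:
        contrib = s_expr(pair.ligand) * min(r_expr(r) for r in pair.receptors)
        by_family[pair.family].append((pair, contrib))

    return [
        CommunicationScore(
            sender=sender_label,
            receiver=receiver.label,
            family=fam,
            score=float(sum(c for _, c in contribs)),
            contributions=tuple(contribs),
        )
        for fam, contribs in by_family.items()
    ]


# ---------------------------------------------------------------------------
# interaction-count comparison


@dataclass(frozen=True)
class InteractionComparison:
    p_value: float
    odds_ratio: float
    direction: str  # "post > pre" | "pre > post" | "equal"
    table: tuple[tuple[int, int], tuple[int, int]]


def compare_interaction_counts(
    pre_count: int, post_count: int, universe_size: int
) -> InteractionComparison:
    """Two-sided Fisher exact test on enabled vs not-enabled interactions,
    before vs after injury, out of a shared universe of candidate pairs."""
    for name, c in (("pre_count", pre_count), ("post_count", post_count)):
        if not 0 <= c <= universe_size:
            raise ValueError(f"{name}={c} outside [0, universe_size={universe_size}]")
    table = (
        (post_count, universe_size - post_count),
        (pre_count, universe_size - pre_count),
    )
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    if post_count > pre_count:
        direction = "post > pre"
    elif pre_count > post_count:
        direction = "pre > post"
    else:
        direction = "equal"
    return InteractionComparison(
        p_value=float(p), odds_ratio=float(odds), direction=direction, table=table
    )
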