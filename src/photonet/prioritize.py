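"""Integrate network, VIS flags, specificity and assay summaries into a
ranked list of candidate photosensitizer clusters.

An extract is *active* when its relative singlet-oxygen yield reaches the
activity floor (default 5%, below which formation is negligible) on any
light source, or any irradiated EC50 falls in the high / very-high band.
A cluster's priority is the number of its nodes that are simultaneously
VIS-positive and specific (majority share above the chosen level) to an
active extract — a direct codification of the visual highlighting rule
(node colored by specificity to an active extract, node size by VIS flag).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .exceptions import ValidationError
from .types import MolecularNetwork, SpecificityRecord, VisFlag

logger = logging.getLogger(__name__)

__all__ = [
    "DMA_ACTIVITY_FLOOR",
    "ExtractActivity",
    "ClusterScore",
    "flag_active_extracts",
    "score_clusters",
    "select_candidate_features",
]

#: Relative singlet-oxygen yield (%) below which formation is negligible.
DMA_ACTIVITY_FLOOR = 5.0

_ACTIVE_BANDS = {"high", "very high"}


@dataclass
class ExtractActivity:
    """Photoactivity verdict for one extract."""

    extract_id: str
    dma_yields: dict[str, float] = field(default_factory=dict)  # light → %
    cytotox_classes: dict[str, str] = field(default_factory=dict)  # cell line → band
    active: bool = False


@dataclass
class ClusterScore:
    """Priority score of one network cluster."""

    cluster_id: int
    n_nodes: int
    n_vis_positive: int
    n_active_specific: int
    priority: int
    rank: int | None = None  # None for unranked (priority 0)

    def __post_init__(self) -> None:
        if self.n_vis_positive > self.n_nodes:
            raise ValidationError("more VIS-positive nodes than nodes")


def flag_active_extracts(
    assay_summaries: dict[str, dict],
    extracts: list[str] | None = None,
    dma_floor: float = DMA_ACTIVITY_FLOOR,
) -> list[ExtractActivity]:
    """Classify extracts as photoactive or not.

    ``assay_summaries`` maps extract id → ``{"dma_yields": {light: percent},
    "cytotox_classes": {cell line: band}}`` where the bands refer to
    irradiated EC50s.  Active iff any DMA yield ≥ ``dma_floor`` (boundary
    inclusive) or any irradiated band is high / very high.  Extracts without
    a summary are inactive (warned).
    """
    ids = extracts if extracts is not None else sorted(assay_summaries)
    out: list[ExtractActivity] = []
    for ext in ids:
        summary = assay_summaries.get(ext)
        if summary is None:
            logger.warning("extract %s has no assay summary; marked inactive", ext)
            out.append(ExtractActivity(extract_id=ext))
            continue
        yields = dict(summary.get("dma_yields", {}))
        classes = dict(summary.get("cytotox_classes", {}))
        active = any(y >= dma_floor for y in yields.values()) or any(
            band in _ACTIVE_BANDS for band in classes.values()
        )
        out.append(
            ExtractActivity(
                extract_id=ext,
                dma_yields=yields,
                cytotox_classes=classes,
                active=active,
            )
        )
    return out


def _candidate_ids(
    vis_flags: dict[str, VisFlag],
    specificity: list[SpecificityRecord],
    active_extracts: set[str],
    level: float,
) -> dict[str, list[str]]:
    """Feature ids with flag 1 ∧ max_share > level ∧ max_extract active, by extract."""
    out: dict[str, list[str]] = {e: [] for e in sorted(active_extracts)}
    for rec in specificity:
        if rec.degenerate or rec.max_share <= level:
            continue
        if rec.max_extract not in active_extracts:
            continue
        flag = vis_flags.get(rec.feature_id)
        if flag is None or flag.flag != 1:
            continue
        out[rec.max_extract].append(rec.feature_id)
    for ids in out.values():
        ids.sort()
    return out


def select_candidate_features(
    vis_flags: dict[str, VisFlag],
    specificity: list[SpecificityRecord],
    activity: list[ExtractActivity],
    level: float = 0.99,
) -> dict[str, list[str]]:
    """Potentially photoactive features, grouped by the extract they are
    specific to.

    A candidate is VIS-positive, has majority share strictly above ``level``,
    and that majority extract is active.  Lowering the level can only grow
    the lists.
    """
    if not (0.0 < level < 1.0):
        raise ValidationError(f"specificity level must lie in (0, 1), got {level}")
    active = {a.extract_id for a in activity if a.active}
    return _candidate_ids(vis_flags, specificity, active, level)


def score_clusters(
    network: MolecularNetwork,
    vis_flags: dict[str, VisFlag],
    specificity: list[SpecificityRecord],
    activity: list[ExtractActivity],
    level: float = 0.99,
) -> list[ClusterScore]:
    """Rank network clusters as candidate photosensitizer compound families.

    Priority = number of cluster nodes that are both VIS-positive and
    specific (majority share > ``level``) to an active extract.  Ranking is
    by priority descending, ties by VIS-positive count then cluster id;
    priority-0 clusters are returned unranked.  Raises if the specificity
    records mention extracts absent from the activity table.
    """
    known = {a.extract_id for a in activity}
    for rec in specificity:
        unknown = set(rec.shares) - known
        if unknown:
            raise ValidationError(
                f"specificity references unknown extracts {sorted(unknown)}"
            )
    active = {a.extract_id for a in activity if a.active}
    candidates = _candidate_ids(vis_flags, specificity, active, level)
    candidate_set = {fid for ids in candidates.values() for fid in ids}

    scores: list[ClusterScore] = []
    for cid, members in network.cluster_members().items():
        n_vis = sum(
            1
            for m in members
            if (f := vis_flags.get(m)) is not None and f.flag == 1
        )
        n_active_specific = sum(1 for m in members if m in candidate_set)
        scores.append(
            ClusterScore(
                cluster_id=cid,
                n_nodes=len(members),
                n_vis_positive=n_vis,
                n_active_specific=n_active_specific,
                priority=n_active_specific,
            )
        )
    scores.sort(key=lambda s: (-s.priority, -s.n_vis_positive, s.cluster_id))
    rank = 1
    for s in scores:
        if s.priority > 0:
            s.rank = rank
            rank += 1
    return scores
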