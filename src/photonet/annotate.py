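"""Simplified dereplication: spectral-library matching, taxonomically
informed re-ranking, and marker-compound propagation through network
clusters.

Library matching reuses the networking modified cosine, so analogs whose
precursor differs by a derivatization mass shift (methylation, oxidation,
glycosylation, chlorination, ...) still match through shifted fragment
pairs.  Marker compounds — authentic standards spiked into the network —
yield identification level 1; all other spectral matches are level 2.
Candidates sharing the sample's taxonomy get an additive score boost per
matching rank, a deliberately simple stand-in for published taxonomically
informed annotation weighting.
"""
from __future__ import annotations

import logging

from .exceptions import ParameterError
from .networking import DEFAULT_FRAG_TOL, modified_cosine
from .types import AnnotationHit, FragmentSpectrum, LibraryEntry, MolecularNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_RANK_WEIGHTS",
    "library_match",
    "taxonomic_rerank",
    "propagate_markers",
]

#: Additive score boost per matching taxonomy rank (most- to least-specific).
DEFAULT_RANK_WEIGHTS = {"species": 0.20, "genus": 0.10, "family": 0.05}


def library_match(
    spectrum: FragmentSpectrum,
    library: list[LibraryEntry],
    frag_tol: float = DEFAULT_FRAG_TOL,
    min_score: float = 0.7,
    min_matched: int = 4,
    precursor_tol: float | None = None,
) -> list[AnnotationHit]:
    """Match one query spectrum against a spectral library.

    Entries scoring ``≥ min_score`` with ``≥ min_matched`` matched peaks are
    kept, ranked by score descending.  A marker entry whose precursor lies
    within ``precursor_tol`` (default: ``frag_tol``) of the query's is a
    level-1 hit; everything else is level 2.
    """
    if not library:
        logger.warning("empty spectral library: no annotation hits")
        return []
    if precursor_tol is None:
        precursor_tol = frag_tol
    hits: list[AnnotationHit] = []
    for entry in library:
        score, n_matched = modified_cosine(spectrum, entry.spectrum, frag_tol)
        if score < min_score or n_matched < min_matched:
            continue
        is_marker = (
            entry.marker
            and abs(spectrum.precursor_mz - entry.spectrum.precursor_mz) <= precursor_tol
        )
        hits.append(
            AnnotationHit(
                feature_id=spectrum.feature_id,
                name=entry.name,
                base_score=score,
                identification_level=1 if is_marker else 2,
                n_matched=n_matched,
                taxonomy=entry.taxonomy,
            )
        )
    hits.sort(key=lambda h: (-h.base_score, h.name))
    return hits


def taxonomic_rerank(
    hits: list[AnnotationHit],
    sample_taxonomy: tuple[str, ...],
    weights: dict[str, float] | None = None,
) -> list[AnnotationHit]:
    """Boost candidates sharing the sample's taxonomy and re-sort.

    ``sample_taxonomy`` is ordered (family, genus, species); each matching
    rank adds the configured weight to the hit's ``tax_boost``.  The re-sort
    by final score is stable, so equal final scores keep their prior order;
    the multiset of hits is preserved (pure permutation plus boost).
    """
    if weights is None:
        weights = DEFAULT_RANK_WEIGHTS
    if any(w < 0 for w in weights.values()):
        raise ParameterError("taxonomy rank weights must be non-negative")
    rank_names = ("family", "genus", "species")
    sample = dict(zip(rank_names, sample_taxonomy))
    boosted: list[AnnotationHit] = []
    for h in hits:
        candidate = dict(zip(rank_names, h.taxonomy))
        boost = sum(
            weights.get(rank, 0.0)
            for rank in rank_names
            if rank in sample and candidate.get(rank) == sample[rank]
        )
        boosted.append(
            AnnotationHit(
                feature_id=h.feature_id,
                name=h.name,
                base_score=h.base_score,
                tax_boost=boost,
                identification_level=h.identification_level,
                n_matched=h.n_matched,
                taxonomy=h.taxonomy,
            )
        )
    boosted.sort(key=lambda h: -h.final_score)  # stable: ties keep input order
    return boosted


def propagate_markers(
    network: MolecularNetwork, hits: dict[str, list[AnnotationHit]]
) -> dict[str, list[str]]:
    """Spread marker identities through their network clusters.

    Every node in a cluster containing at least one level-1 marker hit is
    tagged with the marker name(s); scores are untouched.  Returns the
    mapping node → sorted marker names and also writes it into the network's
    node attributes as ``marker_family``.
    """
    cluster_markers: dict[int, set[str]] = {}
    for fid, feature_hits in hits.items():
        if fid not in network.components:
            continue
        for h in feature_hits:
            if h.identification_level == 1:
                cluster_markers.setdefault(network.components[fid], set()).add(h.name)
    tags: dict[str, list[str]] = {}
    for node, cid in network.components.items():
        if cid in cluster_markers:
            names = sorted(cluster_markers[cid])
            tags[node] = names
            network.node_attrs[node]["marker_family"] = ";".join(names)
    return tags
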