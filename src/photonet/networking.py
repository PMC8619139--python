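"""Feature-based molecular networking.

Implements the modified-cosine spectral similarity — cosine similarity in
which fragment peaks may match either directly or offset by the precursor
mass difference — and GNPS-style network construction with score threshold,
mutual top-k edge pruning, and maximum-component-size splitting.

The peak assignment underlying the score is the exact maximum-weight
one-to-one matching over the candidate pairs (solved as a rectangular
assignment problem), so the reported score is the true optimum rather than a
greedy approximation; the two coincide whenever no fragment participates in
both a direct and a shifted candidate.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment

from .exceptions import ParameterError, ValidationError
from .types import FragmentSpectrum, MolecularNetwork, ScoredEdge, as_spectrum_index

logger = logging.getLogger(__name__)

__all__ = [
    "CandidatePair",
    "match_peaks",
    "modified_cosine",
    "build_network",
    "DEFAULT_FRAG_TOL",
    "DEFAULT_SCORE_THRESHOLD",
    "DEFAULT_MIN_MATCHED",
    "DEFAULT_TOP_K",
    "DEFAULT_MAX_COMPONENT_SIZE",
]

# GNPS-convention defaults; the original job's parameters are not published,
# so these remain overridable everywhere they are used.
DEFAULT_FRAG_TOL = 0.02  # Th
DEFAULT_SCORE_THRESHOLD = 0.7
DEFAULT_MIN_MATCHED = 6
DEFAULT_TOP_K = 10
DEFAULT_MAX_COMPONENT_SIZE = 100


@dataclass(frozen=True)
class CandidatePair:
    """A candidate fragment-peak match between two spectra.

    ``weight`` is the product of the square-root-scaled intensities;
    ``shifted`` records whether the match used the precursor mass offset.
    """

    index_a: int
    index_b: int
    weight: float
    shifted: bool


def match_peaks(
    a: FragmentSpectrum,
    b: FragmentSpectrum,
    frag_tol: float = DEFAULT_FRAG_TOL,
) -> list[CandidatePair]:
    """Enumerate candidate matched peak pairs between two spectra.

    A pair (i, j) is a candidate if ``|mz_a[i] − mz_b[j]| ≤ frag_tol``
    (direct) or ``|mz_a[i] − (mz_b[j] − Δ)| ≤ frag_tol`` with
    Δ = precursor_b − precursor_a (shifted).  A peak may appear in several
    candidates; when a pair qualifies both directly and shifted (Δ ≈ 0) it is
    reported once, as direct.
    """
    if frag_tol <= 0:
        raise ParameterError(f"fragment tolerance must be positive, got {frag_tol}")
    delta = b.precursor_mz - a.precursor_mz
    pairs: list[CandidatePair] = []
    sqrt_ia = np.sqrt(a.intensities)
    sqrt_ib = np.sqrt(b.intensities)
    for i in range(a.n_peaks):
        for j in range(b.n_peaks):
            direct = abs(a.mz[i] - b.mz[j]) <= frag_tol
            shifted = abs(a.mz[i] - (b.mz[j] - delta)) <= frag_tol
            if direct or shifted:
                pairs.append(
                    CandidatePair(
                        index_a=i,
                        index_b=j,
                        weight=float(sqrt_ia[i] * sqrt_ib[j]),
                        shifted=not direct,
                    )
                )
    return pairs


def _assign(pairs: list[CandidatePair]) -> list[CandidatePair]:
    """Maximum-weight one-to-one assignment over candidate pairs.

    Solved exactly with the rectangular linear-sum-assignment algorithm on a
    dense weight matrix where non-candidate cells carry weight 0; cells chosen
    at weight 0 that are not candidates are discarded afterwards.  Candidate
    pairs of weight 0 (zero-intensity peaks) still count as matches.
    """
    if not pairs:
        return []
    rows = sorted({p.index_a for p in pairs})
    cols = sorted({p.index_b for p in pairs})
    ri = {r: k for k, r in enumerate(rows)}
    ci = {c: k for k, c in enumerate(cols)}
    weight = np.zeros((len(rows), len(cols)))
    best: dict[tuple[int, int], CandidatePair] = {}
    for p in pairs:
        key = (ri[p.index_a], ci[p.index_b])
        if key not in best or p.weight > best[key].weight:
            best[key] = p
        weight[key] = max(weight[key], p.weight)
    # small epsilon bonus keeps zero-weight candidate cells preferable to
    # non-candidate cells without affecting the optimum among real weights
    eps = 1e-12
    cost = -weight
    for key in best:
        cost[key] -= eps
    row_ind, col_ind = linear_sum_assignment(cost)
    chosen = []
    for r, c in zip(row_ind, col_ind):
        if (r, c) in best:
            chosen.append(best[(r, c)])
    return chosen


def modified_cosine(
    a: FragmentSpectrum,
    b: FragmentSpectrum,
    frag_tol: float = DEFAULT_FRAG_TOL,
) -> tuple[float, int]:
    """Modified-cosine similarity between two MS² spectra.

    Returns ``(score, n_matched)`` where the score is the optimal one-to-one
    assignment weight over the candidate pairs of :func:`match_peaks`,
    normalized by the product of the Euclidean norms of the square-root-scaled
    intensity vectors.  Symmetric under argument swap; two empty spectra give
    (0.0, 0).
    """
    pairs = match_peaks(a, b, frag_tol)
    if not pairs:
        return 0.0, 0
    chosen = _assign(pairs)
    total = sum(p.weight for p in chosen)
    norm_a = float(np.sqrt(a.intensities.sum()))
    norm_b = float(np.sqrt(b.intensities.sum()))
    if norm_a == 0.0 or norm_b == 0.0:
        return 0.0, len(chosen)
    score = total / (norm_a * norm_b)
    return min(float(score), 1.0), len(chosen)


def _mutual_top_k(edges: list[ScoredEdge], top_k: int) -> list[ScoredEdge]:
    """Keep an edge only if both endpoints rank it within their top_k."""
    incident: dict[str, list[ScoredEdge]] = {}
    for e in edges:
        incident.setdefault(e.feature_a, []).append(e)
        incident.setdefault(e.feature_b, []).append(e)
    ranks: dict[tuple[str, str], int] = {}
    for node, node_edges in incident.items():
        node_edges.sort(key=lambda e: (-e.score, e.feature_a, e.feature_b))
        for rank, e in enumerate(node_edges):
            ranks[(node, _edge_key(e))] = rank
    kept = []
    for e in edges:
        key = _edge_key(e)
        if ranks[(e.feature_a, key)] < top_k and ranks[(e.feature_b, key)] < top_k:
            kept.append(e)
    return kept


def _edge_key(e: ScoredEdge) -> str:
    return f"{min(e.feature_a, e.feature_b)}\x00{max(e.feature_a, e.feature_b)}"


def _split_components(
    g: nx.Graph, max_component_size: int
) -> None:
    """Remove lowest-scoring edges until no component exceeds the size cap.

    Ties are broken by lexicographic endpoint ids; components are recomputed
    after each removal.
    """
    while True:
        oversized = [
            c for c in nx.connected_components(g) if len(c) > max_component_size
        ]
        if not oversized:
            return
        comp = oversized[0]
        worst = min(
            (e for e in g.subgraph(comp).edges(data=True)),
            key=lambda e: (e[2]["score"], min(e[0], e[1]), max(e[0], e[1])),
        )
        g.remove_edge(worst[0], worst[1])


def build_network(
    spectra: list[FragmentSpectrum],
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    min_matched: int = DEFAULT_MIN_MATCHED,
    top_k: int = DEFAULT_TOP_K,
    max_component_size: int = DEFAULT_MAX_COMPONENT_SIZE,
    frag_tol: float = DEFAULT_FRAG_TOL,
) -> MolecularNetwork:
    """Construct a feature-based molecular network.

    Steps: (1) score all pairs with :func:`modified_cosine` and keep edges
    with ``score ≥ score_threshold`` and ``n_matched ≥ min_matched``;
    (2) mutual top-k pruning — an edge survives only if it is among the
    ``top_k`` highest-scoring edges of both endpoints; (3) any connected
    component larger than ``max_component_size`` sheds its lowest-scoring
    edge, repeatedly; (4) connected components are labelled and edge-less
    nodes become singletons.
    """
    index = as_spectrum_index(spectra)  # raises on duplicate ids
    ids = list(index)
    edges: list[ScoredEdge] = []
    for id_a, id_b in itertools.combinations(ids, 2):
        a, b = index[id_a], index[id_b]
        score, n_matched = modified_cosine(a, b, frag_tol)
        if score >= score_threshold and n_matched >= min_matched:
            edges.append(
                ScoredEdge(
                    feature_a=id_a,
                    feature_b=id_b,
                    score=score,
                    n_matched=n_matched,
                    delta_mz=b.precursor_mz - a.precursor_mz,
                )
            )
    edges = _mutual_top_k(edges, top_k)

    g = nx.Graph()
    g.add_nodes_from(ids)
    for e in edges:
        g.add_edge(e.feature_a, e.feature_b, score=e.score)
    _split_components(g, max_component_size)
    surviving = {frozenset((a, b)) for a, b in g.edges}
    edges = [e for e in edges if frozenset((e.feature_a, e.feature_b)) in surviving]

    components: dict[str, int] = {}
    # deterministic cluster ids: order components by their smallest member
    comps = sorted(nx.connected_components(g), key=lambda c: min(c))
    for cid, comp in enumerate(comps):
        for node in comp:
            components[node] = cid
    singletons = {n for n in ids if g.degree[n] == 0}
    node_attrs = {
        fid: {
            "mz": float(index[fid].precursor_mz),
            "rt": float(index[fid].rt),
        }
        for fid in ids
    }
    logger.info(
        "network: %d nodes, %d edges, %d clusters, %d singletons",
        len(ids),
        len(edges),
        len(comps) - len(singletons),
        len(singletons),
    )
    return MolecularNetwork(
        node_attrs=node_attrs,
        edges=edges,
        components=components,
        singletons=singletons,
    )
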