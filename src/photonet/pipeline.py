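"""End-to-end orchestration: read inputs, network, overlay flags and
specificity, summarize assays, annotate, and rank candidate clusters.

``run(config)`` executes the stages in order and writes the exported
artifacts (GraphML, node-attribute TSV, ranked-cluster TSV, candidate TSV,
summary JSON).  The run summary records counts per stage and a hash of the
configuration, so reruns with identical inputs are verifiably identical
(timestamps are deliberately absent).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__, annotate, bioassay, msio, networking, photoflags, prioritize
from .exceptions import PhotonetError
from .photoflags import SPECIFICITY_LEVELS, VisConfig
from .types import DMAKinetics, MolecularNetwork

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunSummary", "run"]


@dataclass
class PipelineConfig:
    """Paths and parameters of one pipeline run.

    The input layout matches what the synthetic generator emits; any bundle
    following the same file conventions works.
    """

    input_dir: str
    output_dir: str
    # networking.*
    frag_tol: float = networking.DEFAULT_FRAG_TOL
    score_threshold: float = networking.DEFAULT_SCORE_THRESHOLD
    min_matched: int = networking.DEFAULT_MIN_MATCHED
    top_k: int = networking.DEFAULT_TOP_K
    max_component_size: int = networking.DEFAULT_MAX_COMPONENT_SIZE
    # vis.*
    vis_wavelength_nm: float = 468.0
    vis_rt_window_min: float = 0.1
    vis_snr_threshold: float = 3.0
    # specificity / prioritization
    specificity_level: float = 0.99
    dma_floor: float = prioritize.DMA_ACTIVITY_FLOOR
    c_max: float = bioassay.C_MAX
    # annotation
    library_min_score: float = 0.7
    library_min_matched: int = 4
    rank_weights: dict[str, float] = field(
        default_factory=lambda: dict(annotate.DEFAULT_RANK_WEIGHTS)
    )
    sample_taxonomy: tuple[str, ...] = ("Cortinariaceae", "Cortinarius")
    seed: int = 0

    def config_hash(self) -> str:
        """Hash of the analysis parameters (I/O paths excluded, so reruns of
        the same analysis into different directories hash identically)."""
        payload = dataclasses.asdict(self)
        payload.pop("input_dir")
        payload.pop("output_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RunSummary:
    counts: dict
    ranked_clusters: list[dict]
    candidates: dict[str, list[str]]
    assay: dict
    config_hash: str
    version: str

    def to_json(self) -> dict:
        return dataclasses.asdict(self)


def _vis_config(cfg: PipelineConfig) -> VisConfig:
    return VisConfig(
        wavelength_nm=cfg.vis_wavelength_nm,
        rt_window_min=cfg.vis_rt_window_min,
        snr_threshold=cfg.vis_snr_threshold,
    )


def _summarize_assays(
    wells: list[DMAKinetics], doses, cfg: PipelineConfig
) -> tuple[dict, dict]:
    """Per-extract assay summary: DMA yields, EC50 fits, S.I., activity bands."""
    from .synthetic_data import POSITIVE_CONTROLS  # control-well naming convention

    by_key: dict[tuple[str, str, str], list[DMAKinetics]] = {}
    for w in wells:
        by_key.setdefault((w.extract_id, w.light, w.condition), []).append(w)

    extract_ids = sorted(
        {w.extract_id for w in wells} - set(POSITIVE_CONTROLS.values())
    )
    summaries: dict[str, dict] = {}
    for ext in extract_ids:
        yields: dict[str, float] = {}
        for light, control_id in POSITIVE_CONTROLS.items():
            samples = by_key.get((ext, light, "DMA"))
            controls = by_key.get((control_id, light, "DMA"))
            if not samples or not controls:
                continue
            blanks = by_key.get((ext, light, "blank"))
            result = bioassay.dma_relative_yield(
                samples, controls, blanks[0] if blanks else None
            )
            yields[light] = result.percent
        summaries[ext] = {"dma_yields": yields, "cytotox_classes": {}, "ec50": {}, "si": {}}

    for dr in doses:
        if dr.extract_id not in summaries:
            continue
        fits, mean_ec50, se = bioassay.fit_hill_by_replicate(dr, cfg.c_max)
        pooled = bioassay.fit_hill(dr, cfg.c_max)
        summaries[dr.extract_id]["ec50"][f"{dr.cell_line}|{dr.light}"] = {
            "ec50": pooled.ec50,
            "censored": pooled.censored,
            "ci95": list(pooled.ci95),
            "replicate_mean": mean_ec50,
            "replicate_se": se,
        }
    for ext, s in summaries.items():
        for key, rec in s["ec50"].items():
            line, light = key.split("|")
            if light == "dark":
                continue
            band = bioassay.classify_photocytotoxicity(rec["ec50"])
            prev = s["cytotox_classes"].get(line)
            order = {"no/low": 0, "high": 1, "very high": 2}
            if prev is None or order[band] > order[prev]:
                s["cytotox_classes"][line] = band
            dark = s["ec50"].get(f"{line}|dark")
            if dark is not None:
                from .types import EC50Result

                dark_res = EC50Result(
                    ec50=dark["ec50"],
                    ci95=tuple(dark["ci95"]),
                    hill_slope=1.0,
                    censored=dark["censored"],
                    c_max=cfg.c_max,
                )
                irr_res = EC50Result(
                    ec50=rec["ec50"],
                    ci95=tuple(rec["ci95"]),
                    hill_slope=1.0,
                    censored=rec["censored"],
                    c_max=cfg.c_max,
                )
                si = bioassay.selectivity_index(dark_res, irr_res)
                s["si"][key] = {
                    "value": round(si.value, 1),
                    "lower_bound": si.lower_bound,
                }
    return summaries, {
        ext: {
            "dma_yields": s["dma_yields"],
            "cytotox_classes": s["cytotox_classes"],
        }
        for ext, s in summaries.items()
    }


def run(config: PipelineConfig) -> RunSummary:
    """Execute the full analysis and write all artifacts.

    Raises a located :class:`PhotonetError` naming the failing stage; partial
    outputs are removed on failure.
    """
    in_dir = Path(config.input_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    try:
        stage = "msio"
        spectra = msio.read_mgf(in_dir / "spectra.mgf")
        table = msio.read_feature_table(in_dir / "feature_table.csv")
        traces = {}
        for path in sorted(in_dir.glob("dad_*.csv")):
            trace = msio.read_dad_trace(path)
            traces[trace.extract_id] = trace
        wells = msio.read_dma_kinetics(in_dir / "dma_kinetics.csv")
        doses = msio.read_dose_response(in_dir / "dose_response.csv")
        library = []
        if (in_dir / "library.mgf").exists():
            library = msio.read_library(in_dir / "library.mgf", in_dir / "library_meta.csv")

        stage = "networking"
        known = set(table.feature_ids)
        networked = [s for s in spectra if s.feature_id in known]
        dropped = len(spectra) - len(networked)
        if dropped:
            logger.warning("%d spectra have no feature-table row; excluded", dropped)
        network = networking.build_network(
            networked,
            score_threshold=config.score_threshold,
            min_matched=config.min_matched,
            top_k=config.top_k,
            max_component_size=config.max_component_size,
            frag_tol=config.frag_tol,
        )

        stage = "photoflags"
        specificity = photoflags.feature_specificity(table)
        vis_flags = photoflags.assign_vis_flags(
            table, traces, _vis_config(config), spectra=networked
        )
        spec_by_id = {r.feature_id: r for r in specificity}
        for node in network.node_attrs:
            rec = spec_by_id[node]
            flag = vis_flags.get(node)
            network.node_attrs[node]["vis_signal"] = int(flag.flag) if flag else 0
            network.node_attrs[node]["max_share"] = rec.max_share
            network.node_attrs[node]["max_extract"] = rec.max_extract or ""
            for ext, share in rec.shares.items():
                network.node_attrs[node][f"share_{ext}"] = share

        stage = "bioassay"
        assay_full, assay_brief = _summarize_assays(wells, doses, config)

        stage = "annotate"
        hits: dict[str, list] = {}
        if library:
            for s in networked:
                feature_hits = annotate.library_match(
                    s,
                    library,
                    frag_tol=config.frag_tol,
                    min_score=config.library_min_score,
                    min_matched=config.library_min_matched,
                )
                feature_hits = annotate.taxonomic_rerank(
                    feature_hits, config.sample_taxonomy, config.rank_weights
                )
                if feature_hits:
                    hits[s.feature_id] = feature_hits
                    best = feature_hits[0]
                    network.node_attrs[s.feature_id]["annotation"] = best.name
                    network.node_attrs[s.feature_id]["annotation_level"] = (
                        best.identification_level
                    )
            annotate.propagate_markers(network, hits)

        stage = "prioritize"
        activity = prioritize.flag_active_extracts(
            assay_brief, extracts=table.extracts, dma_floor=config.dma_floor
        )
        cluster_scores = prioritize.score_clusters(
            network, vis_flags, specificity, activity, config.specificity_level
        )
        candidates = prioritize.select_candidate_features(
            vis_flags, specificity, activity, config.specificity_level
        )

        stage = "export"
        graphml = out_dir / "network.graphml"
        msio.write_graphml(network, graphml)
        written.append(graphml)
        node_tsv = out_dir / "node_attributes.tsv"
        msio.write_node_attributes(network, node_tsv)
        written.append(node_tsv)
        cluster_tsv = out_dir / "clusters.tsv"
        with cluster_tsv.open("w") as fh:
            fh.write("rank\tcluster_id\tn_nodes\tn_vis_positive\tn_active_specific\tpriority\n")
            for s in cluster_scores:
                fh.write(
                    f"{s.rank if s.rank is not None else ''}\t{s.cluster_id}\t"
                    f"{s.n_nodes}\t{s.n_vis_positive}\t{s.n_active_specific}\t{s.priority}\n"
                )
        written.append(cluster_tsv)
        cand_tsv = out_dir / "candidates.tsv"
        with cand_tsv.open("w") as fh:
            fh.write("extract_id\tfeature_id\n")
            for ext in sorted(candidates):
                for fid in candidates[ext]:
                    fh.write(f"{ext}\t{fid}\n")
        written.append(cand_tsv)

        specific_counts = {
            name: photoflags.count_specific_features(specificity, level)
            for name, level in SPECIFICITY_LEVELS.items()
        }
        specific_vis_counts = photoflags.count_specific_features(
            specificity, config.specificity_level, restrict_to_vis=vis_flags
        )
        summary = RunSummary(
            counts={
                "spectra_read": len(spectra),
                "spectra_networked": len(networked),
                "nodes": network.n_nodes,
                "edges": network.n_edges,
                "clusters": network.n_components,
                "singletons": len(network.singletons),
                "vis_positive": sum(1 for f in vis_flags.values() if f.flag == 1),
                "specific": specific_counts,
                "specific_vis": specific_vis_counts,
                "candidates_per_extract": {e: len(v) for e, v in candidates.items()},
                "annotated": len(hits),
            },
            ranked_clusters=[dataclasses.asdict(s) for s in cluster_scores],
            candidates=candidates,
            assay=assay_full,
            config_hash=config.config_hash(),
            version=__version__,
        )
        summary_json = out_dir / "summary.json"
        summary_json.write_text(json.dumps(summary.to_json(), indent=1, sort_keys=True))
        written.append(summary_json)
        return summary
    except Exception as err:
        for path in written:
            path.unlink(missing_ok=True)
        if isinstance(err, PhotonetError):
            raise type(err)(f"stage {stage!r}: {err}") from err
        raise PhotonetError(f"stage {stage!r} failed: {err}") from err
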