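"""Prioritization overlays: feature specificity and the VIS-Signal flag.

Specificity of a feature is the LC peak area in one extract divided by the
summed areas over all extracts; the conventional reporting levels are
>60% (major occurrence), >95% (virtual specificity) and >99% (complete
specificity), all with strict inequality.

The VIS-Signal is a binary flag marking features with detectable absorbance
in the visible range (default 468 nm) at their retention time — by the first
law of photochemistry a necessary condition for photosensitization.  The
evidence is a baseline-subtracted DAD peak height expressed as a
signal-to-noise ratio against a robust (MAD-based) local noise estimate; the
best SNR across extracts decides the flag.  Low-abundance chromophores fall
below the SNR threshold and correctly receive flag 0.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError
from .types import DADTrace, FeatureTable, FragmentSpectrum, SpecificityRecord, VisFlag

logger = logging.getLogger(__name__)

__all__ = [
    "VisConfig",
    "feature_specificity",
    "count_specific_features",
    "extract_vis_signal",
    "assign_vis_flags",
    "SPECIFICITY_LEVELS",
]

#: Conventional specificity reporting levels (strict lower bounds).
SPECIFICITY_LEVELS = {"major": 0.60, "virtual": 0.95, "complete": 0.99}


@dataclass(frozen=True)
class VisConfig:
    """VIS-Signal detection parameters.

    wavelength_nm: DAD wavelength the traces must be recorded at.
    rt_window_min: half-width of the peak search window around the feature RT.
    snr_threshold: minimum SNR for a positive flag (3 = conventional
        detection limit).
    baseline_factor: the local baseline/noise region spans
        ± baseline_factor × rt_window_min around the feature RT, excluding the
        peak window itself.
    """

    wavelength_nm: float = 468.0
    rt_window_min: float = 0.1
    snr_threshold: float = 3.0
    baseline_factor: float = 5.0


def feature_specificity(table: FeatureTable) -> list[SpecificityRecord]:
    """Per-feature extract shares: area in extract / total area over extracts.

    Features with zero total area are returned as degenerate with all shares
    zero and no majority extract.
    """
    records: list[SpecificityRecord] = []
    totals = table.areas.sum(axis=1)
    for i, fid in enumerate(table.feature_ids):
        if totals[i] <= 0:
            records.append(
                SpecificityRecord(
                    feature_id=fid,
                    shares={e: 0.0 for e in table.extracts},
                    max_share=0.0,
                    max_extract=None,
                    degenerate=True,
                )
            )
            continue
        shares = table.areas[i] / totals[i]
        j = int(np.argmax(shares))
        records.append(
            SpecificityRecord(
                feature_id=fid,
                shares={e: float(s) for e, s in zip(table.extracts, shares)},
                max_share=float(shares[j]),
                max_extract=table.extracts[j],
            )
        )
    return records


def count_specific_features(
    records: list[SpecificityRecord],
    level: float,
    restrict_to_vis: dict[str, VisFlag] | None = None,
) -> dict[str, int]:
    """Count features whose majority share strictly exceeds ``level``.

    Counts are attributed to the majority extract.  With ``restrict_to_vis``
    given, only VIS-positive features are counted.  Degenerate (all-zero)
    features never count.
    """
    if not (0.0 < level < 1.0):
        raise ParameterError(f"specificity level must lie in (0, 1), got {level}")
    counts: dict[str, int] = {}
    for r in records:
        for e in r.shares:
            counts.setdefault(e, 0)
    for r in records:
        if r.degenerate or r.max_share <= level:
            continue
        if restrict_to_vis is not None:
            flag = restrict_to_vis.get(r.feature_id)
            if flag is None or flag.flag != 1:
                continue
        counts[r.max_extract] += 1
    return counts


def _window_snr(
    trace: DADTrace, rt: float, cfg: VisConfig
) -> tuple[float, float]:
    """(height, snr) of the trace around ``rt``; (0, 0) on an empty window."""
    lo, hi = rt - cfg.rt_window_min, rt + cfg.rt_window_min
    in_window = (trace.rt >= lo) & (trace.rt <= hi)
    if not np.any(in_window):
        return 0.0, 0.0
    span = cfg.baseline_factor * cfg.rt_window_min
    in_region = (trace.rt >= rt - span) & (trace.rt <= rt + span)
    baseline_mask = in_region & ~in_window
    if not np.any(baseline_mask):
        baseline_mask = ~in_window & (trace.rt >= trace.rt[0])  # whole trace fallback
    baseline_vals = trace.absorbance[baseline_mask]
    if baseline_vals.size == 0:
        return 0.0, 0.0
    baseline = float(np.median(baseline_vals))
    noise = 1.4826 * float(np.median(np.abs(baseline_vals - baseline)))
    height = float(trace.absorbance[in_window].max() - baseline)
    if height <= 0:
        return max(height, 0.0), 0.0
    if noise == 0.0:
        return height, float("inf")
    return height, height / noise


def extract_vis_signal(
    feature_id: str,
    rt: float,
    traces: dict[str, DADTrace],
    config: VisConfig = VisConfig(),
) -> VisFlag:
    """VIS-Signal evidence for one feature across all extract DAD traces.

    Peak height is measured within ± ``rt_window_min`` of the feature RT after
    subtracting the local baseline (median of the surrounding
    ± ``baseline_factor × rt_window_min`` region excluding the window); noise
    is the scaled median absolute deviation of the same baseline region.  The
    flag is 1 iff the best SNR across extracts reaches ``snr_threshold``.
    """
    best_snr, best_extract = 0.0, None
    for extract_id in sorted(traces):
        trace = traces[extract_id]
        if trace.wavelength != config.wavelength_nm:
            logger.warning(
                "trace %s at %g nm skipped (configured wavelength %g nm)",
                extract_id,
                trace.wavelength,
                config.wavelength_nm,
            )
            continue
        _, snr = _window_snr(trace, rt, config)
        if snr > best_snr:
            best_snr, best_extract = snr, extract_id
    flag = 1 if best_snr >= config.snr_threshold else 0
    return VisFlag(
        feature_id=feature_id,
        flag=flag,
        snr=best_snr if np.isfinite(best_snr) else float("inf"),
        source_extract=best_extract if flag else None,
    )


def assign_vis_flags(
    table: FeatureTable,
    traces: dict[str, DADTrace],
    config: VisConfig = VisConfig(),
    spectra: list[FragmentSpectrum] | None = None,
) -> dict[str, VisFlag]:
    """Apply :func:`extract_vis_signal` to every feature of the table.

    Deterministic; extracts without a trace are simply absent from the
    evidence (warned once).  If ``spectra`` are given, features are restricted
    to those with an MS² spectrum.
    """
    missing = set(table.extracts) - set(traces)
    if missing:
        logger.warning("no DAD trace for extracts %s; skipped", sorted(missing))
    keep = None
    if spectra is not None:
        keep = {s.feature_id for s in spectra}
    flags: dict[str, VisFlag] = {}
    for fid, rt in zip(table.feature_ids, table.rt):
        if keep is not None and fid not in keep:
            continue
        flags[fid] = extract_vis_signal(fid, float(rt), traces, config)
    return flags
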