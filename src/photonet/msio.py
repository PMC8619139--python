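"""Readers and writers for all external formats.

Formats handled: MGF fragment spectra (via pyteomics), MZmine-style aligned
feature quantification CSV, per-extract DAD trace CSV, DMA-kinetics CSV,
dose-response CSV, GraphML + Cytoscape-importable node-attribute TSV, and the
spectral library (MGF + sidecar CSV).

All numeric columns use "." as decimal separator; retention times are minutes
and m/z are Thomson throughout.  Readers are strict: a malformed record raises
a located :class:`~photonet.exceptions.FormatError` or
:class:`~photonet.exceptions.ValidationError` rather than being dropped.
"""
from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .exceptions import FormatError, ValidationError
from .types import (
    DADTrace,
    DMAKinetics,
    DoseResponse,
    FeatureTable,
    FragmentSpectrum,
    LibraryEntry,
    MolecularNetwork,
    ScoredEdge,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_mgf",
    "write_mgf",
    "read_feature_table",
    "write_feature_table",
    "read_dad_trace",
    "write_dad_trace",
    "read_dma_kinetics",
    "write_dma_kinetics",
    "read_dose_response",
    "write_dose_response",
    "read_library",
    "write_library",
    "write_graphml",
    "read_graphml",
    "write_node_attributes",
]


# ---------------------------------------------------------------------------
# MGF
# ---------------------------------------------------------------------------

def read_mgf(path: str | Path) -> list[FragmentSpectrum]:
    """Read an MGF file into a list of :class:`FragmentSpectrum`.

    Feature identity is taken from ``FEATURE_ID`` if present, else ``SCANS``,
    else ``TITLE``.  Retention time is read from ``RTINSECONDS`` (converted to
    minutes).  Blocks without fragment peaks are retained as empty-peak
    spectra; a block missing ``PEPMASS`` raises a :class:`FormatError` naming
    the block index.
    """
    path = Path(path)
    spectra: list[FragmentSpectrum] = []
    with _mgf.MGF(str(path), convert_arrays=1, read_charges=True) as reader:
        for i, entry in enumerate(reader):
            params = entry["params"]
            pepmass = params.get("pepmass")
            if pepmass is None or pepmass[0] is None:
                raise FormatError(f"{path.name}: block {i} has no PEPMASS")
            fid = params.get("feature_id") or params.get("scans") or params.get("title")
            if fid is None:
                raise FormatError(
                    f"{path.name}: block {i} has no FEATURE_ID/SCANS/TITLE"
                )
            charge = -1
            if params.get("charge"):
                charge = int(params["charge"][0])
            rt = float(params.get("rtinseconds", 0.0)) / 60.0
            mz = np.asarray(entry["m/z array"], dtype=float)
            inten = np.asarray(entry["intensity array"], dtype=float)
            order = np.argsort(mz, kind="stable")
            spectra.append(
                FragmentSpectrum(
                    feature_id=str(fid),
                    precursor_mz=float(pepmass[0]),
                    rt=rt,
                    mz=mz[order],
                    intensities=inten[order],
                    charge=charge,
                )
            )
    return spectra


def write_mgf(spectra: Iterable[FragmentSpectrum], path: str | Path) -> None:
    """Write spectra as MGF with FEATURE_ID/SCANS/RTINSECONDS headers."""
    path = Path(path)
    with path.open("w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"FEATURE_ID={s.feature_id}\n")
            fh.write(f"SCANS={s.feature_id}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            sign = "-" if s.charge < 0 else "+"
            fh.write(f"CHARGE={abs(s.charge)}{sign}\n")
            fh.write(f"RTINSECONDS={s.rt * 60.0:.4f}\n")
            for mz, inten in zip(s.mz, s.intensities):
                fh.write(f"{mz:.6f} {inten:.6f}\n")
            fh.write("END IONS\n\n")


# ---------------------------------------------------------------------------
# Feature quantification table
# ---------------------------------------------------------------------------

def read_feature_table(path: str | Path) -> FeatureTable:
    """Read an aligned feature table CSV: columns ``id, mz, rt, <extract>...``.

    Blank area cells are read as 0.0.  Duplicate ids and negative areas raise
    :class:`ValidationError`.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"id": str})
    required = {"id", "mz", "rt"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path.name}: feature table must have columns id, mz, rt; "
            f"found {list(df.columns)}"
        )
    extracts = [c for c in df.columns if c not in required]
    if not extracts:
        raise FormatError(f"{path.name}: no extract area columns")
    areas = df[extracts].fillna(0.0).to_numpy(dtype=float)
    return FeatureTable(
        feature_ids=df["id"].tolist(),
        mz=df["mz"].to_numpy(dtype=float),
        rt=df["rt"].to_numpy(dtype=float),
        extracts=extracts,
        areas=areas,
    )


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    df = pd.DataFrame(
        {"id": table.feature_ids, "mz": table.mz, "rt": table.rt}
    )
    for j, e in enumerate(table.extracts):
        df[e] = table.areas[:, j]
    df.to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# DAD traces
# ---------------------------------------------------------------------------

def read_dad_trace(path: str | Path) -> DADTrace:
    """Read a DAD trace CSV.

    The first two lines are comment headers carrying the extract id and
    wavelength::

        # extract_id=<id>
        # wavelength_nm=<nm>
        rt,absorbance
        ...
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
    if "extract_id" not in meta or "wavelength_nm" not in meta:
        raise FormatError(
            f"{path.name}: missing '# extract_id=' / '# wavelength_nm=' header"
        )
    df = pd.read_csv(path, comment="#")
    if not {"rt", "absorbance"}.issubset(df.columns):
        raise FormatError(f"{path.name}: DAD trace needs rt,absorbance columns")
    return DADTrace(
        extract_id=meta["extract_id"],
        wavelength=float(meta["wavelength_nm"]),
        rt=df["rt"].to_numpy(dtype=float),
        absorbance=df["absorbance"].to_numpy(dtype=float),
    )


def write_dad_trace(trace: DADTrace, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# extract_id={trace.extract_id}\n")
        fh.write(f"# wavelength_nm={trace.wavelength:g}\n")
        fh.write("rt,absorbance\n")
        for rt, ab in zip(trace.rt, trace.absorbance):
            fh.write(f"{rt:.6f},{ab:.6f}\n")


# ---------------------------------------------------------------------------
# Assay tables
# ---------------------------------------------------------------------------

_DMA_COLS = ["extract_id", "light", "condition", "replicate", "time_min", "a377"]


def read_dma_kinetics(path: str | Path) -> list[DMAKinetics]:
    """Read DMA-assay kinetics CSV (one row per well × timepoint).

    Columns: ``extract_id, light, condition, replicate, time_min, a377``.
    Rows are grouped into one :class:`DMAKinetics` per
    (extract, light, condition, replicate) well.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"extract_id": str, "replicate": str})
    missing = set(_DMA_COLS) - set(df.columns)
    if missing:
        raise FormatError(f"{path.name}: missing columns {sorted(missing)}")
    out: list[DMAKinetics] = []
    for (ext, light, cond, rep), grp in df.groupby(
        ["extract_id", "light", "condition", "replicate"], sort=True
    ):
        grp = grp.sort_values("time_min")
        out.append(
            DMAKinetics(
                extract_id=ext,
                light=light,
                condition=cond,
                times=grp["time_min"].to_numpy(dtype=float),
                a377=grp["a377"].to_numpy(dtype=float),
                replicate=rep,
            )
        )
    return out


def write_dma_kinetics(wells: Iterable[DMAKinetics], path: str | Path) -> None:
    rows = []
    for w in wells:
        for t, a in zip(w.times, w.a377):
            rows.append((w.extract_id, w.light, w.condition, w.replicate, t, a))
    pd.DataFrame(rows, columns=_DMA_COLS).to_csv(path, index=False, float_format="%.6f")


_DR_COLS = ["cell_line", "extract_id", "light", "replicate", "concentration_ug_ml", "viability_pct"]


def read_dose_response(path: str | Path) -> list[DoseResponse]:
    """Read viability dose-response CSV, grouped per (cell line, extract, light)."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"extract_id": str, "replicate": str})
    missing = set(_DR_COLS) - set(df.columns)
    if missing:
        raise FormatError(f"{path.name}: missing columns {sorted(missing)}")
    out: list[DoseResponse] = []
    for (line, ext, light), grp in df.groupby(["cell_line", "extract_id", "light"], sort=True):
        grp = grp.sort_values(["replicate", "concentration_ug_ml"])
        out.append(
            DoseResponse(
                cell_line=line,
                extract_id=ext,
                light=light,
                concentrations=grp["concentration_ug_ml"].to_numpy(dtype=float),
                viability=grp["viability_pct"].to_numpy(dtype=float),
                replicates=grp["replicate"].tolist(),
            )
        )
    return out


def write_dose_response(tables: Iterable[DoseResponse], path: str | Path) -> None:
    rows = []
    for t in tables:
        reps = t.replicates or ["r1"] * t.concentrations.size
        for rep, c, v in zip(reps, t.concentrations, t.viability):
            rows.append((t.cell_line, t.extract_id, t.light, rep, c, v))
    pd.DataFrame(rows, columns=_DR_COLS).to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# Spectral library (MGF + sidecar metadata CSV)
# ---------------------------------------------------------------------------

def read_library(mgf_path: str | Path, meta_path: str | Path) -> list[LibraryEntry]:
    """Read a spectral library: MGF plus sidecar CSV.

    Sidecar columns: ``feature_id, name, adduct, family, genus, species,
    marker`` (marker as 0/1).  Empty taxonomy cells are allowed.
    """
    spectra = {s.feature_id: s for s in read_mgf(mgf_path)}
    df = pd.read_csv(meta_path, dtype={"feature_id": str})
    entries: list[LibraryEntry] = []
    for _, row in df.iterrows():
        fid = str(row["feature_id"])
        if fid not in spectra:
            raise FormatError(f"library metadata row {fid!r} has no MGF spectrum")
        taxonomy = tuple(
            str(row[r]) for r in ("family", "genus", "species")
            if r in df.columns and pd.notna(row[r]) and str(row[r])
        )
        entries.append(
            LibraryEntry(
                name=str(row["name"]),
                spectrum=spectra[fid],
                adduct=str(row.get("adduct", "[M-H]-")),
                taxonomy=taxonomy,
                marker=bool(int(row.get("marker", 0))),
            )
        )
    return entries


def write_library(entries: Sequence[LibraryEntry], mgf_path: str | Path, meta_path: str | Path) -> None:
    write_mgf([e.spectrum for e in entries], mgf_path)
    rows = []
    for e in entries:
        tax = list(e.taxonomy) + [""] * (3 - len(e.taxonomy))
        rows.append(
            (e.spectrum.feature_id, e.name, e.adduct, tax[0], tax[1], tax[2], int(e.marker))
        )
    pd.DataFrame(
        rows, columns=["feature_id", "name", "adduct", "family", "genus", "species", "marker"]
    ).to_csv(meta_path, index=False)


# ---------------------------------------------------------------------------
# GraphML / node-attribute export (Cytoscape-compatible)
# ---------------------------------------------------------------------------

def _to_nx(network: MolecularNetwork) -> nx.Graph:
    g = nx.Graph()
    for node, attrs in network.node_attrs.items():
        clean = {k: v for k, v in attrs.items() if v is not None}
        clean["cluster_id"] = int(network.components[node])
        clean["singleton"] = int(node in network.singletons)
        g.add_node(node, **clean)
    for e in network.edges:
        g.add_edge(
            e.feature_a,
            e.feature_b,
            score=float(e.score),
            n_matched=int(e.n_matched),
            delta_mz=float(e.delta_mz),
        )
    return g


def write_graphml(network: MolecularNetwork, path: str | Path) -> None:
    """Export the network as GraphML loadable by Cytoscape.

    Node attributes carried: everything in ``node_attrs`` plus ``cluster_id``
    and ``singleton``; edge attributes: ``score``, ``n_matched``, ``delta_mz``.
    """
    nx.write_graphml(_to_nx(network), str(path))


def read_graphml(path: str | Path) -> MolecularNetwork:
    """Re-import a GraphML export (round-trip of :func:`write_graphml`)."""
    g = nx.read_graphml(str(path))
    node_attrs: dict[str, dict] = {}
    components: dict[str, int] = {}
    singletons: set[str] = set()
    for node, attrs in g.nodes(data=True):
        attrs = dict(attrs)
        components[node] = int(attrs.pop("cluster_id"))
        if int(attrs.pop("singleton", 0)):
            singletons.add(node)
        node_attrs[node] = attrs
    edges = [
        ScoredEdge(
            feature_a=a,
            feature_b=b,
            score=float(d["score"]),
            n_matched=int(d["n_matched"]),
            delta_mz=float(d["delta_mz"]),
        )
        for a, b, d in g.edges(data=True)
    ]
    return MolecularNetwork(
        node_attrs=node_attrs, edges=edges, components=components, singletons=singletons
    )


def write_node_attributes(network: MolecularNetwork, path: str | Path) -> None:
    """Write the node-attribute table as TSV for Cytoscape "Import Table"."""
    keys: list[str] = []
    for attrs in network.node_attrs.values():
        for k in attrs:
            if k not in keys:
                keys.append(k)
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["feature_id", "cluster_id", "singleton", *keys])
        for node in sorted(network.node_attrs):
            attrs = network.node_attrs[node]
            writer.writerow(
                [
                    node,
                    network.components[node],
                    int(node in network.singletons),
                    *[attrs.get(k, "") for k in keys],
                ]
            )
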