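"""Domain containers shared across the pipeline.

Conventions (fixed, not configurable): retention times in minutes, m/z in
Thomson, absorbances in mAU, concentrations in µg/mL.  MS acquisition is
negative ionization mode, hence the default charge of −1.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "FragmentSpectrum",
    "FeatureTable",
    "DADTrace",
    "ScoredEdge",
    "MolecularNetwork",
    "VisFlag",
    "SpecificityRecord",
    "DMAKinetics",
    "ReferencePhotosensitizer",
    "DoseResponse",
    "EC50Result",
    "SelectivityIndex",
    "LibraryEntry",
    "AnnotationHit",
]


@dataclass
class FragmentSpectrum:
    """One MS² scan tied to an aligned LC-MS feature.

    Parameters
    ----------
    feature_id
        Identifier linking the scan to a row of the feature table
        (MZmine FBMN convention: SCANS equals the quant-table row id).
    precursor_mz
        Precursor m/z in Thomson, > 0.
    rt
        Retention time in minutes, ≥ 0.
    mz, intensities
        Fragment peak arrays; m/z strictly increasing, intensities ≥ 0.
    charge
        Signed charge state; −1 by default (negative ionization mode).
    """

    feature_id: str
    precursor_mz: float
    rt: float
    mz: np.ndarray
    intensities: np.ndarray
    charge: int = -1

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.precursor_mz <= 0:
            raise ValidationError(
                f"spectrum {self.feature_id!r}: precursor m/z must be > 0, "
                f"got {self.precursor_mz}"
            )
        if self.rt < 0:
            raise ValidationError(f"spectrum {self.feature_id!r}: negative retention time")
        if self.mz.shape != self.intensities.shape or self.mz.ndim != 1:
            raise ValidationError(
                f"spectrum {self.feature_id!r}: mz and intensity arrays must be "
                "1-D and of equal length"
            )
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ValidationError(
                f"spectrum {self.feature_id!r}: peak m/z must be strictly increasing"
            )
        if np.any(self.intensities < 0):
            raise ValidationError(f"spectrum {self.feature_id!r}: negative intensity")

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensities.tolist()))


@dataclass
class FeatureTable:
    """Aligned features × extracts LC peak-area matrix."""

    feature_ids: list[str]
    mz: np.ndarray
    rt: np.ndarray
    extracts: list[str]
    areas: np.ndarray  # shape (n_features, n_extracts)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.rt = np.asarray(self.rt, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        n = len(self.feature_ids)
        if len(set(self.feature_ids)) != n:
            raise ValidationError("duplicate feature ids in feature table")
        if len(set(self.extracts)) != len(self.extracts):
            raise ValidationError("duplicate extract ids in feature table")
        if self.areas.shape != (n, len(self.extracts)):
            raise ValidationError(
                f"area matrix shape {self.areas.shape} does not match "
                f"{n} features × {len(self.extracts)} extracts"
            )
        if np.any(self.areas < 0):
            raise ValidationError("negative LC peak area")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def row(self, feature_id: str) -> np.ndarray:
        return self.areas[self.feature_ids.index(feature_id)]


@dataclass
class DADTrace:
    """Diode-array detector chromatogram of one extract at one wavelength."""

    extract_id: str
    wavelength: float  # nm
    rt: np.ndarray  # minutes, strictly increasing
    absorbance: np.ndarray  # mAU

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.rt.size < 2:
            raise ValidationError(
                f"DAD trace {self.extract_id!r}: needs at least 2 points"
            )
        if np.any(np.diff(self.rt) <= 0):
            raise ValidationError(
                f"DAD trace {self.extract_id!r}: retention times must be strictly increasing"
            )
        if self.rt.shape != self.absorbance.shape:
            raise ValidationError(
                f"DAD trace {self.extract_id!r}: rt/absorbance length mismatch"
            )


@dataclass(frozen=True)
class ScoredEdge:
    """A modified-cosine edge between two features."""

    feature_a: str
    feature_b: str
    score: float
    n_matched: int
    delta_mz: float  # precursor_b − precursor_a, Thomson

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0 + 1e-12):
            raise ValidationError(f"edge score {self.score} outside [0, 1]")
        if self.n_matched < 0:
            raise ValidationError("negative matched-peak count")
        if self.feature_a == self.feature_b:
            raise ValidationError(f"self edge on {self.feature_a!r}")


@dataclass
class MolecularNetwork:
    """Feature-based molecular network: nodes, scored edges, cluster labels.

    ``components`` maps every node to a cluster id; singletons (nodes with no
    surviving edge) each occupy their own cluster and are listed in
    ``singletons``.
    """

    node_attrs: dict[str, dict]
    edges: list[ScoredEdge]
    components: dict[str, int]
    singletons: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        nodes = set(self.node_attrs)
        for e in self.edges:
            if e.feature_a not in nodes or e.feature_b not in nodes:
                raise ValidationError(
                    f"edge {e.feature_a!r}–{e.feature_b!r} references unknown node"
                )
        if set(self.components) != nodes:
            raise ValidationError("component labels do not partition the node set")

    @property
    def n_nodes(self) -> int:
        return len(self.node_attrs)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_components(self) -> int:
        """Number of multi-node clusters (singletons not counted)."""
        multi = {c for node, c in self.components.items() if node not in self.singletons}
        return len(multi)

    def cluster_members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, cid in self.components.items():
            out.setdefault(cid, []).append(node)
        for members in out.values():
            members.sort()
        return out


@dataclass(frozen=True)
class VisFlag:
    """Binary light-absorption call for one feature (VIS-Signal)."""

    feature_id: str
    flag: int  # 0 or 1
    snr: float
    source_extract: str | None = None

    def __post_init__(self) -> None:
        if self.flag not in (0, 1):
            raise ValidationError("VIS flag must be 0 or 1")
        if self.snr < 0:
            raise ValidationError("negative SNR")


@dataclass
class SpecificityRecord:
    """Per-extract share of a feature's total LC peak area."""

    feature_id: str
    shares: dict[str, float]
    max_share: float
    max_extract: str | None
    degenerate: bool = False  # all-zero total area

    def __post_init__(self) -> None:
        if not self.degenerate:
            total = sum(self.shares.values())
            if abs(total - 1.0) > 1e-6:
                raise ValidationError(
                    f"feature {self.feature_id!r}: shares sum to {total}, expected 1"
                )


@dataclass
class DMAKinetics:
    """A377 absorbance time series for one well of the DMA photobleaching assay."""

    extract_id: str
    light: str  # "blue" | "green"
    condition: str  # "blank" | "DMA" | "AA" | "DMA+AA"
    times: np.ndarray  # cumulative irradiation minutes, starting at 0
    a377: np.ndarray
    replicate: str = "r1"

    VALID_CONDITIONS = ("blank", "DMA", "AA", "DMA+AA")

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.a377 = np.asarray(self.a377, dtype=float)
        if self.condition not in self.VALID_CONDITIONS:
            raise ValidationError(f"unknown DMA condition {self.condition!r}")
        if self.times.size < 2:
            raise ValidationError("DMA kinetics needs at least 2 timepoints")
        if self.times[0] != 0 or np.any(np.diff(self.times) < 0):
            raise ValidationError("DMA timepoints must start at 0 and be non-decreasing")
        if self.times.shape != self.a377.shape:
            raise ValidationError("time/absorbance length mismatch")


@dataclass(frozen=True)
class ReferencePhotosensitizer:
    """A positive-control photosensitizer with its singlet-oxygen quantum yield."""

    name: str
    lambda_max: float  # nm
    phi_delta: float  # quantum yield
    solvent: str = "EtOH"

    def __post_init__(self) -> None:
        if not (0.0 <= self.phi_delta <= 1.0):
            raise ValidationError("quantum yield must lie in [0, 1]")


#: The two reference photosensitizers used as positive controls.
ROSE_BENGAL = ReferencePhotosensitizer("rose bengal", 555.0, 0.86, "EtOH")
BERBERINE = ReferencePhotosensitizer("berberine", 420.0, 0.04, "EtOH")


@dataclass
class DoseResponse:
    """Viability (% of control) versus concentration for one extract × cell line × light."""

    cell_line: str
    extract_id: str
    light: str  # "dark" | "blue" | "green"
    concentrations: np.ndarray  # µg/mL, > 0
    viability: np.ndarray  # % of untreated control
    replicates: list[str] | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if np.any(self.concentrations <= 0):
            raise ValidationError("concentrations must be positive")
        if self.concentrations.shape != self.viability.shape:
            raise ValidationError("concentration/viability length mismatch")
        if self.replicates is not None and len(self.replicates) != self.concentrations.size:
            raise ValidationError("replicate labels length mismatch")

    @property
    def n_distinct_doses(self) -> int:
        return int(np.unique(self.concentrations).size)


@dataclass
class EC50Result:
    """Hill-fit EC50 with 95% CI; censored when the curve never reaches 50% viability."""

    ec50: float  # µg/mL
    ci95: tuple[float, float]
    hill_slope: float
    censored: bool
    c_max: float
    top: float = float("nan")
    bottom: float = float("nan")

    def __post_init__(self) -> None:
        if self.censored:
            if self.ec50 != self.c_max:
                raise ValidationError("censored EC50 must equal c_max")
        else:
            lo, hi = self.ci95
            if not (lo <= self.ec50 <= hi):
                raise ValidationError("CI does not bracket the EC50")


@dataclass(frozen=True)
class SelectivityIndex:
    """Dark EC50 divided by irradiated EC50; ≫ 1 means light-dependent toxicity."""

    value: float
    lower_bound: bool  # dark EC50 censored → report as "≥"

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValidationError("selectivity index must be positive")

    def __str__(self) -> str:  # presentation rounds to one decimal
        prefix = "≥" if self.lower_bound else ""
        return f"{prefix}{self.value:.1f}"


@dataclass
class LibraryEntry:
    """Spectral-library record with taxonomy for taxonomically informed re-ranking."""

    name: str
    spectrum: FragmentSpectrum
    adduct: str = "[M-H]-"
    taxonomy: tuple[str, ...] = ()  # ordered, e.g. (family, genus, species)
    marker: bool = False


@dataclass
class AnnotationHit:
    """One candidate annotation for a feature.

    ``identification_level`` follows the four-level metabolomics reporting
    convention: 1 = marker compound confirmed against an authentic standard,
    2 = putative spectral-match annotation, 3 = compound class only,
    4 = unknown.
    """

    feature_id: str
    name: str
    base_score: float
    tax_boost: float = 0.0
    identification_level: int = 2
    n_matched: int = 0
    taxonomy: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.identification_level not in (1, 2, 3, 4):
            raise ValidationError("identification level must be 1–4")
        if self.tax_boost < 0:
            raise ValidationError("negative taxonomy boost")

    @property
    def final_score(self) -> float:
        return self.base_score + self.tax_boost


def as_spectrum_index(spectra: Iterable[FragmentSpectrum]) -> dict[str, FragmentSpectrum]:
    """Index spectra by feature id, enforcing uniqueness."""
    out: dict[str, FragmentSpectrum] = {}
    for s in spectra:
        if s.feature_id in out:
            raise ValidationError(f"duplicate feature id {s.feature_id!r}")
        out[s.feature_id] = s
    return out
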