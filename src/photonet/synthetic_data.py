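"""Ground-truth-labelled synthetic input bundles.

The generator emulates the statistical structure the analysis assumes, so
every pipeline stage can be tested end to end without the original raw data:

* compound families sharing a fragment scaffold, with analogs shifted by
  common derivatization mass deltas (methylation +14.0157, oxidation
  +15.9949, glycosylation +162.0528, H→Cl +33.9610) — within-family modified
  cosine is high by construction, between-family similarity negligible
  (scaffold m/z drawn independently per family);
* species-specific abundance patterns, including the planted plan of
  completely (>99%) specific chromophore features in the two active
  extracts (defaults 9 and 52, mirroring the study system);
* chromophore-bearing features producing DAD peaks at their retention time
  in their majority extract, with amplitude well above baseline noise;
* first-order DMA photobleaching kinetics scaled to planted relative
  singlet-oxygen yields, plus positive-control and blank wells;
* Hill-shaped viability dose-response with light-dependent EC50 shifts and
  censored-by-design dark conditions.

Chromatographic layout: chromophore features sit on a 0.6-min retention-time
grid and all other features at grid midpoints.  This keeps each pigment's
DAD peak clear of every other feature's detection window — the generator
emulates a run in which the pigments are chromatographically resolved, which
real dense extracts do not guarantee (see the methods note).  The DAD
baseline is slow drift (lamp / refractive-index wander) over a tiny fast
noise floor, the regime in which a MAD-based local noise estimate is
conservative.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import msio
from .bioassay import DOSE_LADDER, hill_curve
from .exceptions import ParameterError, ValidationError
from .types import (
    DADTrace,
    DMAKinetics,
    DoseResponse,
    FeatureTable,
    FragmentSpectrum,
    LibraryEntry,
)

logger = logging.getLogger(__name__)

__all__ = ["GeneratorConfig", "GroundTruth", "generate_spectra",
           "generate_quant_and_dad", "generate_assays", "generate_library",
           "generate_bundle"]

#: Derivatization precursor shifts (Th): none, methylation, oxidation,
#: di-methylation, H→Cl exchange, glycosylation.
MASS_SHIFTS = (0.0, 14.0157, 15.9949, 28.0314, 33.9610, 162.0528)

EXTRACTS = (
    "rubrophyllus",
    "xanthophyllus",
    "callisteus",
    "venetus",
    "traganus",
    "trivialis",
)

POSITIVE_CONTROLS = {"blue": "berberine", "green": "rose bengal"}

#: Planted relative singlet-oxygen yields (%), per extract and light.
TRUE_DMA_YIELDS = {
    "blue": {
        "rubrophyllus": 123.2,
        "xanthophyllus": 183.5,
        "callisteus": 2.0,
        "venetus": 1.5,
        "traganus": 2.5,
        "trivialis": 1.0,
    },
    "green": {
        "rubrophyllus": 11.3,
        "xanthophyllus": 10.0,
        "callisteus": 1.0,
        "venetus": 0.5,
        "traganus": 1.5,
        "trivialis": 0.5,
    },
}

#: Planted true EC50s (µg/mL) per extract → cell line → light.  Dark values
#: above the 37.5 µg/mL top dose are censored by design.
TRUE_EC50 = {
    "xanthophyllus": {
        "A549": {"dark": 75.0, "blue": 3.7, "green": 1.6},
        "AGS": {"dark": 75.0, "blue": 4.6, "green": 0.8},
        "T24": {"dark": 75.0, "blue": 1.5, "green": 1.2},
        "NIH3T3": {"dark": 75.0, "green": 2.1},
    },
    "rubrophyllus": {
        "A549": {"dark": 28.9, "blue": 11.1, "green": 30.0},
        "AGS": {"dark": 29.3, "blue": 10.1, "green": 30.0},
        "T24": {"dark": 22.6, "blue": 6.1, "green": 25.0},
        "NIH3T3": {"dark": 40.0, "green": 20.0},
    },
    "callisteus": {"A549": {"dark": 40.0, "blue": 40.0}},
    "venetus": {"A549": {"dark": 45.0, "blue": 45.0}},
    "traganus": {"A549": {"dark": 35.0, "blue": 35.0}},
    "trivialis": {"A549": {"dark": 48.0, "blue": 48.0}},
}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic study.

    The defaults ARE the study conditions every ground-truth test assumes;
    they are not tuned per run.
    """

    seed: int
    extracts: tuple[str, ...] = EXTRACTS
    active_extracts: tuple[str, ...] = ("rubrophyllus", "xanthophyllus")
    #: >99%-specific chromophore features per active extract.
    specific_feature_plan: dict[str, int] = field(
        default_factory=lambda: {"rubrophyllus": 9, "xanthophyllus": 52}
    )
    #: >99%-specific non-chromophore features in inactive extracts.
    inactive_specific_plan: dict[str, int] = field(
        default_factory=lambda: {"callisteus": 4, "traganus": 4}
    )
    n_families: int = 10
    family_size_min: int = 4
    family_size_max: int = 6
    n_background: int = 24  # non-specific, non-chromophore standalone features
    scaffold_peaks_min: int = 8
    scaffold_peaks_max: int = 15
    # noise levels
    area_dirichlet_conc: float = 60.0  # concentration around target shares
    dad_baseline_sd: float = 0.2  # mAU
    dad_amp_min: float = 15.0  # chromophore amplitude, × baseline sd
    dad_amp_max: float = 40.0
    viability_sd: float = 5.0  # % viability noise
    a377_sd: float = 0.0005  # absorbance noise (plate-reader OD repeatability)
    dma_control_rate: float = 0.006  # positive-control bleaching rate, 1/min
    dma_protection: float = 0.3  # planted ascorbate quench fraction
    hill_slope: float = 1.2
    dose_ladder: tuple[float, ...] = DOSE_LADDER
    n_dr_replicates: int = 3
    n_dma_replicates: int = 2
    dad_wavelength: float = 468.0
    rt_step: float = 0.02  # DAD sampling interval, minutes
    lc_peak_sd: float = 0.05  # chromatographic peak sd, minutes
    true_dma_yields: dict = field(default_factory=lambda: json.loads(json.dumps(TRUE_DMA_YIELDS)))
    true_ec50: dict = field(default_factory=lambda: json.loads(json.dumps(TRUE_EC50)))

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ParameterError("generator seed is mandatory")
        if self.n_families < 2:
            raise ParameterError("need at least the two active-extract families")
        for ext in list(self.specific_feature_plan) + list(self.inactive_specific_plan):
            if ext not in self.extracts:
                raise ParameterError(f"plan references unknown extract {ext!r}")


@dataclass
class GroundTruth:
    """Planted truth for every emitted feature and assay."""

    family_of: dict[str, str]  # feature → family label ("famNN" or "single")
    chromophore: dict[str, bool]
    designed_extract: dict[str, str | None]  # planned majority extract (specific only)
    active_extracts: list[str]
    true_dma_yields: dict
    true_ec50: dict
    dma_protection: float

    def to_json(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class _FeaturePlan:
    feature_id: str
    family: str
    chromophore: bool
    specific_to: str | None  # extract id, share forced > 0.99
    shift: float  # precursor shift from the family base


def _plan_features(config: GeneratorConfig, rng: np.random.Generator) -> list[_FeaturePlan]:
    """Lay out the feature roster: families, specific singles, background."""
    plans: list[_FeaturePlan] = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return str(counter)

    sizes = rng.integers(
        config.family_size_min, config.family_size_max + 1, size=config.n_families
    )
    # families 0 and 1 are the photoactive pigment families, completely
    # specific to the first two active extracts respectively
    remaining_plan = dict(config.specific_feature_plan)
    family_home: list[str | None] = [None] * config.n_families
    actives = list(config.active_extracts)
    for fam_idx in range(min(len(actives), 2)):
        ext = actives[1 - fam_idx] if len(actives) > 1 else actives[0]
        # family 0 → second active extract (the large plan), family 1 → first
        family_home[fam_idx] = ext
        sizes[fam_idx] = min(int(sizes[fam_idx]), remaining_plan.get(ext, 0)) or 1

    for fam_idx in range(config.n_families):
        home = family_home[fam_idx]
        for member in range(int(sizes[fam_idx])):
            shift = MASS_SHIFTS[member % len(MASS_SHIFTS)]
            specific_to = None
            chromo = False
            if home is not None and remaining_plan.get(home, 0) > 0:
                specific_to = home
                chromo = True
                remaining_plan[home] -= 1
            plans.append(
                _FeaturePlan(
                    feature_id=new_id(),
                    family=f"fam{fam_idx:02d}",
                    chromophore=chromo,
                    specific_to=specific_to,
                    shift=shift,
                )
            )
    # standalone specific chromophores to complete the plan
    for ext in sorted(remaining_plan):
        for _ in range(remaining_plan[ext]):
            plans.append(
                _FeaturePlan(
                    feature_id=new_id(),
                    family="single",
                    chromophore=True,
                    specific_to=ext,
                    shift=0.0,
                )
            )
    # specific (non-chromophore) features of inactive extracts
    for ext in sorted(config.inactive_specific_plan):
        for _ in range(config.inactive_specific_plan[ext]):
            plans.append(
                _FeaturePlan(
                    feature_id=new_id(),
                    family="single",
                    chromophore=False,
                    specific_to=ext,
                    shift=0.0,
                )
            )
    # unspecific background
    for _ in range(config.n_background):
        plans.append(
            _FeaturePlan(
                feature_id=new_id(),
                family="single",
                chromophore=False,
                specific_to=None,
                shift=0.0,
            )
        )
    return plans


def _scaffold(rng: np.random.Generator, n_peaks: int) -> tuple[np.ndarray, np.ndarray]:
    """Random fragment scaffold: m/z with ≥ 1 Th mutual spacing, log-normal intensities."""
    while True:
        mz = np.sort(rng.uniform(80.0, 800.0, size=n_peaks))
        if np.all(np.diff(mz) >= 1.0):
            break
    intensities = rng.lognormal(mean=0.0, sigma=1.0, size=n_peaks)
    intensities = 100.0 * intensities / intensities.max()
    return mz, intensities


def generate_spectra(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[list[FragmentSpectrum], list[_FeaturePlan]]:
    """Generate MS² spectra for the planned feature roster.

    Family members share a scaffold; a fixed subset of the scaffold (the
    "mobile" substructure) shifts with each member's precursor delta, so any
    two members match on every fragment (directly or shifted) and their
    modified cosine stays high.  Standalone features draw independent
    scaffolds.  Deterministic per seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    plans = _plan_features(config, rng)
    max_members = max(
        (sum(1 for p in plans if p.family == fam) for fam in {p.family for p in plans if p.family != "single"}),
        default=1,
    )
    if config.n_families * max_members > 600:
        raise ParameterError("family plan exceeds available m/z space")

    spectra: list[FragmentSpectrum] = []
    scaffolds: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, float]] = {}
    for plan in plans:
        if plan.family != "single" and plan.family in scaffolds:
            mz, inten, mobile, base_prec = scaffolds[plan.family]
        else:
            n_peaks = int(rng.integers(config.scaffold_peaks_min, config.scaffold_peaks_max + 1))
            mz, inten = _scaffold(rng, n_peaks)
            n_mobile = max(1, n_peaks // 3)
            mobile = np.zeros(n_peaks, dtype=bool)
            mobile[rng.choice(n_peaks, size=n_mobile, replace=False)] = True
            base_prec = float(mz.max() + rng.uniform(60.0, 180.0))
            if plan.family != "single":
                scaffolds[plan.family] = (mz, inten, mobile, base_prec)
        member_mz = mz + mobile * plan.shift
        order = np.argsort(member_mz)
        member_inten = inten * rng.lognormal(0.0, 0.10, size=mz.size)
        spectra.append(
            FragmentSpectrum(
                feature_id=plan.feature_id,
                precursor_mz=base_prec + plan.shift,
                rt=0.0,  # assigned with the quant table
                mz=member_mz[order],
                intensities=member_inten[order],
            )
        )
    return spectra, plans


def _baseline_wander(rng: np.random.Generator, grid: np.ndarray, sd: float) -> np.ndarray:
    """DAD baseline: slow wander plus a small fast detector-noise component.

    Real diode-array baselines are dominated by low-frequency drift (lamp and
    refractive-index wander) with only a tiny fast noise floor; the wander is
    modelled as three sinusoids with periods of a few minutes and random
    phases, scaled to marginal sd ``sd``, the fast component as white noise
    at sd/100.
    """
    periods = rng.uniform([4.0, 2.0, 1.2], [8.0, 4.0, 2.0])
    phases = rng.uniform(0.0, 2.0 * math.pi, size=3)
    rel_amp = np.array([1.0, 0.6, 0.35])
    drift = np.zeros_like(grid)
    for T, phi, a in zip(periods, phases, rel_amp):
        drift += a * np.sin(2.0 * math.pi * grid / T + phi)
    drift *= sd / math.sqrt(float(np.sum((rel_amp**2) / 2.0)))
    return drift + rng.normal(0.0, sd / 100.0, size=grid.size)


def generate_quant_and_dad(
    config: GeneratorConfig,
    spectra: list[FragmentSpectrum],
    plans: list[_FeaturePlan],
    rng: np.random.Generator,
) -> tuple[FeatureTable, dict[str, DADTrace]]:
    """Peak-area matrix honoring the specificity plan, plus DAD traces.

    Retention times: chromophores occupy a 0.5-min grid (their DAD peaks stay
    clear of each other's baseline regions), all other features the grid
    midpoints.  Planned-specific features get their majority share drawn in
    (0.992, 0.998); everything else draws Dirichlet shares capped below 0.99.
    Chromophores add a Gaussian DAD peak (sd ``lc_peak_sd`` minutes) at
    their RT in their majority extract.
    """
    n = len(plans)
    chromo_idx = [i for i, p in enumerate(plans) if p.chromophore]
    other_idx = [i for i, p in enumerate(plans) if not p.chromophore]
    pitch = 0.6
    rt = np.zeros(n)
    chromo_slots = rng.permutation(len(chromo_idx))
    for k, i in enumerate(chromo_idx):
        rt[i] = 1.0 + pitch * chromo_slots[k] + rng.uniform(-0.01, 0.01)
    other_slots = rng.permutation(max(len(other_idx), len(chromo_idx)))[: len(other_idx)]
    for k, i in enumerate(other_idx):
        rt[i] = 1.0 + pitch * other_slots[k] + pitch / 2 + rng.uniform(-0.01, 0.01)
    run_end = float(rt.max() + 1.5)

    extracts = list(config.extracts)
    areas = np.zeros((n, len(extracts)))
    for i, plan in enumerate(plans):
        total = rng.lognormal(math.log(1e6), 0.8)
        if plan.specific_to is not None:
            u = rng.uniform(0.992, 0.998)
            rest = rng.dirichlet(np.ones(len(extracts) - 1))
            shares = np.empty(len(extracts))
            j = extracts.index(plan.specific_to)
            shares[j] = u
            shares[[k for k in range(len(extracts)) if k != j]] = (1 - u) * rest
        else:
            target = rng.dirichlet(np.ones(len(extracts)))
            while True:
                shares = rng.dirichlet(config.area_dirichlet_conc * target + 0.5)
                if shares.max() <= 0.99:
                    break
        areas[i] = total * shares

    table = FeatureTable(
        feature_ids=[p.feature_id for p in plans],
        mz=np.array([s.precursor_mz for s in spectra]),
        rt=rt,
        extracts=extracts,
        areas=areas,
    )
    for s, r in zip(spectra, rt):
        s.rt = float(r)

    grid = np.arange(0.0, run_end + config.rt_step, config.rt_step)
    traces: dict[str, DADTrace] = {}
    signal = {e: np.zeros_like(grid) for e in extracts}
    for i, plan in enumerate(plans):
        if not plan.chromophore:
            continue
        home = plan.specific_to or extracts[int(np.argmax(areas[i]))]
        amp = config.dad_baseline_sd * rng.uniform(
            config.dad_amp_min, config.dad_amp_max
        )
        signal[home] += amp * np.exp(
            -0.5 * ((grid - rt[i]) / config.lc_peak_sd) ** 2
        )
    for e in extracts:
        baseline = 1.0 + _baseline_wander(rng, grid, config.dad_baseline_sd)
        traces[e] = DADTrace(
            extract_id=e,
            wavelength=config.dad_wavelength,
            rt=grid.copy(),
            absorbance=baseline + signal[e],
        )
    return table, traces


def generate_assays(
    config: GeneratorConfig, rng: np.random.Generator
) -> tuple[list[DMAKinetics], list[DoseResponse]]:
    """DMA kinetics and viability dose-response tables from the planted truth.

    A377 in DMA wells decays exponentially at a rate proportional to the
    planted relative yield (control rate × yield / 100); blank wells drift
    negligibly; ascorbate co-incubation wells decay at the quenched rate.
    Viabilities follow the Hill model at the planted EC50s with Gaussian
    noise.
    """
    wells: list[DMAKinetics] = []
    cycle = {"blue": 5.0, "green": 4.6}
    for light in ("blue", "green"):
        times = np.array([0.0, 1.0, 2.0, 3.0, 4.0]) * cycle[light]
        k_ctrl = config.dma_control_rate
        subjects = list(config.extracts) + [POSITIVE_CONTROLS[light]]
        for subject in subjects:
            if subject in POSITIVE_CONTROLS.values():
                yield_pct = 100.0
            else:
                yield_pct = config.true_dma_yields[light][subject]
            k = k_ctrl * yield_pct / 100.0
            for rep in range(config.n_dma_replicates):
                rid = f"r{rep + 1}"
                noise = lambda: rng.normal(0.0, config.a377_sd, size=times.size)  # noqa: E731
                a0 = 1.0 + rng.normal(0.0, 0.01)
                wells.append(
                    DMAKinetics(subject, light, "DMA", times,
                                a0 * np.exp(-k * times) + noise(), rid)
                )
                wells.append(
                    DMAKinetics(subject, light, "blank", times,
                                0.05 - 1e-5 * times + noise(), rid)
                )
                wells.append(
                    DMAKinetics(subject, light, "AA", times,
                                0.30 + noise(), rid)
                )
                k_aa = k * (1.0 - (config.dma_protection if yield_pct >= 5.0 else 0.0))
                wells.append(
                    DMAKinetics(subject, light, "DMA+AA", times,
                                a0 * np.exp(-k_aa * times) + noise(), rid)
                )

    doses: list[DoseResponse] = []
    ladder = np.array(config.dose_ladder, dtype=float)
    for ext in sorted(config.true_ec50):
        for line in sorted(config.true_ec50[ext]):
            for light in sorted(config.true_ec50[ext][line]):
                ec50 = float(config.true_ec50[ext][line][light])
                conc, via, reps = [], [], []
                for rep in range(config.n_dr_replicates):
                    v = hill_curve(ladder, 100.0, 0.0, ec50, config.hill_slope)
                    v = v + rng.normal(0.0, config.viability_sd, size=ladder.size)
                    conc.extend(ladder.tolist())
                    via.extend(v.tolist())
                    reps.extend([f"r{rep + 1}"] * ladder.size)
                doses.append(
                    DoseResponse(
                        cell_line=line,
                        extract_id=ext,
                        light=light,
                        concentrations=np.array(conc),
                        viability=np.array(via),
                        replicates=reps,
                    )
                )
    return wells, doses


MARKER_NAMES = ("dermolutein", "dermorubin", "5-chlorodermorubin", "7,7'-biphyscion")


def generate_library(
    config: GeneratorConfig,
    spectra: list[FragmentSpectrum],
    plans: list[_FeaturePlan],
    rng: np.random.Generator,
) -> list[LibraryEntry]:
    """Small in-house library: marker standards drawn from the pigment families.

    Markers are slightly intensity-jittered copies of members of the two
    photoactive families (the authentic-standard scenario); two non-marker
    entries from another family round out the library.
    """
    by_family: dict[str, list[int]] = {}
    for i, p in enumerate(plans):
        by_family.setdefault(p.family, []).append(i)
    entries: list[LibraryEntry] = []
    pigment_members = by_family.get("fam00", [])[:2] + by_family.get("fam01", [])[:2]
    for name, idx in zip(MARKER_NAMES, pigment_members):
        src = spectra[idx]
        entries.append(
            LibraryEntry(
                name=name,
                spectrum=FragmentSpectrum(
                    feature_id=f"lib_{name}",
                    precursor_mz=src.precursor_mz,
                    rt=src.rt,
                    mz=src.mz.copy(),
                    intensities=src.intensities * rng.lognormal(0.0, 0.05, src.n_peaks),
                ),
                taxonomy=("Cortinariaceae", "Cortinarius", "uliginosus-like"),
                marker=True,
            )
        )
    for k, idx in enumerate(by_family.get("fam02", [])[:2]):
        src = spectra[idx]
        entries.append(
            LibraryEntry(
                name=f"reference-compound-{k + 1}",
                spectrum=FragmentSpectrum(
                    feature_id=f"lib_ref{k + 1}",
                    precursor_mz=src.precursor_mz,
                    rt=src.rt,
                    mz=src.mz.copy(),
                    intensities=src.intensities * rng.lognormal(0.0, 0.05, src.n_peaks),
                ),
                taxonomy=("Cortinariaceae", "Cortinarius", "other"),
                marker=False,
            )
        )
    return entries


def generate_bundle(
    config: GeneratorConfig, out_dir: str | Path, force: bool = False
) -> GroundTruth:
    """Write a complete input bundle plus ground truth and manifest.

    Deterministic per (seed, config): identical calls yield byte-identical
    files.  Refuses to write into a non-empty directory unless ``force``.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise ValidationError(f"output directory {out} is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    spectra, plans = generate_spectra(config, rng)
    table, traces = generate_quant_and_dad(config, spectra, plans, rng)
    wells, doses = generate_assays(config, rng)
    library = generate_library(config, spectra, plans, rng)

    msio.write_mgf(spectra, out / "spectra.mgf")
    msio.write_feature_table(table, out / "feature_table.csv")
    for ext, trace in traces.items():
        msio.write_dad_trace(trace, out / f"dad_{ext}.csv")
    msio.write_dma_kinetics(wells, out / "dma_kinetics.csv")
    msio.write_dose_response(doses, out / "dose_response.csv")
    msio.write_library(library, out / "library.mgf", out / "library_meta.csv")

    truth = GroundTruth(
        family_of={p.feature_id: p.family for p in plans},
        chromophore={p.feature_id: p.chromophore for p in plans},
        designed_extract={p.feature_id: p.specific_to for p in plans},
        active_extracts=sorted(config.active_extracts),
        true_dma_yields=config.true_dma_yields,
        true_ec50=config.true_ec50,
        dma_protection=config.dma_protection,
    )
    (out / "ground_truth.json").write_text(
        json.dumps(truth.to_json(), indent=1, sort_keys=True)
    )

    files = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "seed": config.seed,
        "n_features": len(plans),
        "files": files,
        "checksums": {
            name: hashlib.sha256((out / name).read_bytes()).hexdigest()
            for name in files
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("bundle written to %s (%d features)", out, len(plans))
    return truth
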