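"""Synthetic PTR-TOF-MS experiments with known ground truth.

This module emulates the full study design: a compound library anchored on
the signals reported for *Phaeodactylum tricornutum* (BTEX, C11H16,
methanol, acetaldehyde, acetone, DMS, acetonitrile plus randomized extras),
liquid-phase concentration trajectories for an axenic culture and five
diatom-bacteria cocultures (n = 6 replicate flasks, exponential and
stationary phases), the dynamic-stripping + soft-ionization forward model
producing raw spectra (Gaussian peaks with isotopologue satellites,
reference ions, mass-axis drift, background contaminant peaks, additive
noise), flow-cytometry/SEM cell counts, and 14C GCP observations.

The forward gas-phase map inverts exactly the quantification chain
(:func:`phycovoc.quantify.molar_to_ppbv`, :func:`ppbv_to_ncps`), so the
processing pipeline recovers the planted liquid concentrations on
noise-free data — the closure property the recovery tests rely on.

Default magnitudes follow the reported culture measurements: a total
exponential-phase VOC pool of ~18.5 nM at 2.18e5 diatom cells/ml with
hydrocarbons ~60% of it, stationary per-cell production at ~10% of
exponential, and lognormal replicate noise (CV 20%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import formula_mass, parse_formula, protonated_mass
from .gcp import DPM_PER_UCI, GcpSample
from .quantify import (
    CultureSample,
    KineticsParams,
    StrippingParams,
    isotopologue_fractions,
    molar_to_ppbv,
    per_cell_normalize,
    ppbv_to_ncps,
)
from .signal_table import mz_label
from .spectral import RawSpectrumSeries

__all__ = [
    "CompoundSpec",
    "InstrumentParams",
    "ExperimentDesign",
    "SyntheticTruth",
    "ANCHOR_COMPOUNDS",
    "make_compound_library",
    "simulate_liquid_concentrations",
    "simulate_blank_concentrations",
    "render_spectrum_series",
    "simulate_cell_counts",
    "simulate_gcp_dataset",
]

MZ_MIN_DEFAULT, MZ_MAX_DEFAULT = 30.0, 240.0


@dataclass
class CompoundSpec:
    """A volatile compound the simulated diatom produces."""

    label: str
    formula: dict[str, int] | None
    neutral_mass: float
    production_exp: float  # fmol per diatom cell, exponential phase
    production_stat: float  # fmol per diatom cell, stationary phase
    depletion_factor: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.neutral_mass <= 0:
            raise ValueError("neutral_mass must be > 0")
        if self.formula is not None:
            if abs(formula_mass(self.formula) - self.neutral_mass) > 0.001:
                raise ValueError(
                    f"{self.label}: neutral_mass {self.neutral_mass} inconsistent "
                    f"with formula (monoisotopic {formula_mass(self.formula):.4f})"
                )
        pm = protonated_mass(self.neutral_mass)
        if not (MZ_MIN_DEFAULT <= pm <= MZ_MAX_DEFAULT):
            raise ValueError(
                f"{self.label}: protonated mass {pm:.3f} outside the "
                f"[{MZ_MIN_DEFAULT}, {MZ_MAX_DEFAULT}] acquisition range"
            )
        for name, f in self.depletion_factor.items():
            if not 0 <= f <= 1:
                raise ValueError(f"{self.label}: depletion factor for {name} not in [0,1]")

    @property
    def mz(self) -> float:
        return protonated_mass(self.neutral_mass)

    @property
    def signal_label(self) -> str:
        return mz_label(self.mz)


@dataclass(frozen=True)
class InstrumentParams:
    """PTR-TOF acquisition parameters of the simulated instrument."""

    mz_min: float = MZ_MIN_DEFAULT
    mz_max: float = MZ_MAX_DEFAULT
    cycle_s: float = 5.0
    peak_sigma: float = 0.02  # Da; mass-resolution width
    noise_sd: float = 0.0  # counts per axis point per cycle
    mass_drift: tuple[float, float] = (1.0, 0.0)  # observed = scale*true + offset
    reference_ions: tuple[float, ...] = (29.998, 203.943, 330.848)
    reference_counts: float = 5e4  # counts per cycle per reference ion
    h3o_counts: float = 1e7  # primary-ion counts per cycle
    en_ratio: float = 126.0  # Td
    axis_step: float = 0.005  # Da
    background_peaks: dict = field(
        default_factory=lambda: {37.03: 2e3, 55.04: 1e3}  # water clusters, counts/cycle
    )
    kinetics: KineticsParams = field(default_factory=KineticsParams)

    def __post_init__(self):
        if self.mz_min >= self.mz_max:
            raise ValueError("mz_min must be < mz_max")
        if self.peak_sigma <= 0:
            raise ValueError("peak_sigma must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


#: Coculture treatment names (bacteria grown with the diatom).
COCULTURES = ("Marinobacter", "Roseibium", "Yoonia", "Rhodophyticola", "Stappia")
AXENIC = "Axenic"


def _default_densities() -> dict[str, float]:
    return {"exponential": 2.18e5, "stationary": 1.0e6}


def _default_free_bacteria() -> dict[str, float]:
    return {name: 1.0e6 for name in COCULTURES}


def _default_attached() -> dict[str, float]:
    # VOC specialists attach (flat / polar orientation); generalists do not
    return {
        "Marinobacter": 5.0,
        "Roseibium": 3.0,
        "Yoonia": 1.0,
        "Rhodophyticola": 0.0,
        "Stappia": 0.0,
    }


@dataclass
class ExperimentDesign:
    """Treatments, replication, phases, densities and instrument settings."""

    treatments: tuple[str, ...] = (AXENIC,) + COCULTURES
    n_replicates: int = 6
    phases: tuple[str, ...] = ("exponential", "stationary")
    diatom_density: dict[str, float] = field(default_factory=_default_densities)
    free_bacteria_density: dict[str, float] = field(default_factory=_default_free_bacteria)
    attached_per_diatom: dict[str, float] = field(default_factory=_default_attached)
    instrument: InstrumentParams = field(default_factory=InstrumentParams)
    stripping: StrippingParams = field(default_factory=StrippingParams)
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 2:
            raise ValueError("need n_replicates >= 2")
        for d in (self.diatom_density, self.free_bacteria_density):
            if any(v < 0 for v in d.values()):
                raise ValueError("densities must be >= 0")

    @property
    def cocultures(self) -> tuple[str, ...]:
        return tuple(t for t in self.treatments if t != AXENIC)

    def sample_id(self, treatment: str, phase: str, replicate: int) -> str:
        return f"{treatment}-{phase}-r{replicate}"


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated experiment, for recovery tests."""

    true_liquid_conc: pd.DataFrame  # nM, expected (noise-free), signal x (treatment, phase)
    true_produced_set: dict[str, set[str]]  # phase -> signal labels
    true_depleted_set: dict[tuple[str, str], set[str]]  # (coculture, phase) -> labels
    true_percell_depletion: pd.DataFrame  # fmol per bacterial cell, signal x (coculture, phase)


# ---------------------------------------------------------------------------
# compound library
# ---------------------------------------------------------------------------

# (name, formula, exponential production in fmol/cell). The per-cell scale is
# anchored so that the exponential-phase total pool is ~18.5 nM at
# 2.18e5 cells/ml; see the methods note on the per-cell unit convention.
ANCHOR_COMPOUNDS: tuple[tuple[str, str, float], ...] = (
    ("C11H16", "C11H16", 0.0325),
    ("benzene", "C6H6", 0.0050),
    ("toluene", "C7H8", 0.0040),
    ("ethylbenzene/xylene", "C8H10", 0.0034),
    ("methanol", "CH4O", 0.0050),
    ("acetaldehyde", "C2H4O", 0.0040),
    ("acetone", "C3H6O", 0.0012),
    ("DMS", "C2H6S", 0.0008),
    ("acetonitrile", "C2H3N", 0.0008),
)
_ANCHOR_HYDROCARBONS = 4  # C11H16 + BTEX

#: Signals reported as never depleted in any coculture.
NEVER_DEPLETED = ("methanol", "acetone")

# Per-coculture depletion regimes: fraction of eligible produced signals
# depleted, and typical fractional consumption for hydrocarbons vs others.
_DEPLETION_REGIMES = {
    "Marinobacter": dict(frac=0.82, hc=0.70, other=0.50),
    "Stappia": dict(frac=0.70, hc=0.65, other=0.45),
    "Rhodophyticola": dict(frac=0.60, hc=0.45, other=0.35),
    "Roseibium": dict(frac=0.45, hc=0.65, other=0.40),
    # Yoonia depletes only acetaldehyde in exponential phase
}

_TOTAL_EXP = 0.0849  # fmol/cell, exponential total pool
_TOTAL_HC_EXP = 0.0524  # hydrocarbon share of it
STATIONARY_SCALING = 0.1  # stationary per-cell production relative to exponential


def _is_hydrocarbon(formula: dict[str, int] | None) -> bool:
    return formula is not None and set(k for k, v in formula.items() if v) <= {"C", "H"}


def _candidate_formulas(hydrocarbon: bool) -> list[dict[str, int]]:
    """All plausible CxHy(+heteroatom) formulas in the acquisition range."""
    out = []
    for nC in range(2, 17):
        for nH in range(max(2, nC - 6), 2 * nC + 3):
            base = {"C": nC, "H": nH}
            if hydrocarbon:
                out.append(base)
            else:
                for het in ({"O": 1}, {"O": 2}, {"N": 1}, {"S": 1}):
                    out.append({**base, **het})
    return out


def _mass_ok(
    mz: float,
    taken: list[float],
    min_sep: float = 0.08,  # ~4 sigma at the default 0.02-Da peak width
    reference_ions: tuple[float, ...] = (29.998, 203.943, 330.848),
) -> bool:
    """Keep peaks (and their M+1/M+2 satellites) resolvable from each other,
    clear of the half-unit bin boundaries, and out of the +/- 0.25 Da
    search windows of the calibration reference ions (a brighter analyte
    inside a reference window would hijack the mass calibration)."""
    frac = mz % 0.5
    if abs(frac - 0.25) < 0.07:  # within ~3.5 sigma of a bin boundary
        return False
    for off in (0.0, 1.003, 2.004):
        for ref in reference_ions:
            if abs((mz + off) - ref) < 0.27:
                return False
        for t in taken:
            for toff in (0.0, 1.003, 2.004):
                if abs((mz + off) - (t + toff)) < min_sep:
                    return False
    return True


def make_compound_library(
    n_compounds: int = 72,
    n_hydrocarbons: int = 40,
    seed: int = 0,
    unidentified_fraction: float = 0.15,
) -> list[CompoundSpec]:
    """Compound library: fixed anchors plus randomized extras.

    ``n_hydrocarbons`` counts hydrocarbons including the four anchor
    hydrocarbons (C11H16 and BTEX); ~``unidentified_fraction`` of the
    library carries no formula. Identical seeds give identical libraries.
    """
    n_anchors = len(ANCHOR_COMPOUNDS)
    if n_compounds < n_anchors:
        raise ValueError(
            f"n_compounds={n_compounds} is below the {n_anchors} fixed anchor compounds"
        )
    if not _ANCHOR_HYDROCARBONS <= n_hydrocarbons <= n_compounds:
        raise ValueError(
            f"n_hydrocarbons must lie in [{_ANCHOR_HYDROCARBONS}, n_compounds]"
        )
    rng = np.random.default_rng(seed)
    specs: list[CompoundSpec] = []
    taken: list[float] = []
    for name, formula_s, prod in ANCHOR_COMPOUNDS:
        f = parse_formula(formula_s)
        m = formula_mass(f)
        specs.append(CompoundSpec(name, f, m, prod, prod * STATIONARY_SCALING))
        taken.append(protonated_mass(m))

    n_random = n_compounds - n_anchors
    n_random_hc = n_hydrocarbons - _ANCHOR_HYDROCARBONS
    n_unid = min(int(round(unidentified_fraction * n_compounds)), n_random - n_random_hc)
    n_other = n_random - n_random_hc - n_unid

    kinds = ["hc"] * n_random_hc + ["other"] * n_other + ["unid"] * n_unid
    pools = {
        "hc": _candidate_formulas(hydrocarbon=True),
        "other": _candidate_formulas(hydrocarbon=False),
    }
    new: list[tuple[str, dict | None, float]] = []
    for i, kind in enumerate(kinds):
        if kind == "unid":
            placed = False
            for _ in range(10_000):
                mass = float(rng.uniform(35.0, 200.0))
                mz = protonated_mass(mass)
                if _mass_ok(mz, taken):
                    taken.append(mz)
                    new.append((f"cmpd_{i:02d}", None, mass))
                    placed = True
                    break
            if not placed:  # pragma: no cover - continuous masses, unreachable
                raise RuntimeError("could not place an unidentified compound mass")
        else:
            feasible = [
                f for f in pools[kind]
                if MZ_MIN_DEFAULT + 1 <= protonated_mass(formula_mass(f)) <= MZ_MAX_DEFAULT - 3
                and _mass_ok(protonated_mass(formula_mass(f)), taken)
            ]
            if not feasible:
                raise RuntimeError(
                    f"compound mass space exhausted for kind {kind!r}; "
                    f"reduce n_compounds or n_hydrocarbons"
                )
            f = feasible[int(rng.integers(len(feasible)))]
            taken.append(protonated_mass(formula_mass(f)))
            new.append((f"cmpd_{i:02d}", f, formula_mass(f)))

    # distribute the remaining production budget with lognormal weights
    anchor_hc = sum(p for _, fs, p in ANCHOR_COMPOUNDS if _is_hydrocarbon(parse_formula(fs)))
    anchor_other = sum(p for _, fs, p in ANCHOR_COMPOUNDS) - anchor_hc
    budget_hc = max(_TOTAL_HC_EXP - anchor_hc, 0.0)
    budget_other = max((_TOTAL_EXP - _TOTAL_HC_EXP) - anchor_other, 0.0)
    hc_idx = [i for i, (nm, f, m) in enumerate(new) if _is_hydrocarbon(f)]
    other_idx = [i for i in range(len(new)) if i not in hc_idx]
    prods = np.zeros(len(new))
    for idx, budget in ((hc_idx, budget_hc), (other_idx, budget_other)):
        if idx:
            w = rng.lognormal(0.0, 0.8, size=len(idx))
            prods[idx] = budget * w / w.sum()
    for (name, f, mass), prod in zip(new, prods):
        specs.append(
            CompoundSpec(name, f, mass, float(prod), float(prod) * STATIONARY_SCALING)
        )

    _assign_depletion(specs, rng)
    return specs


def _assign_depletion(specs: list[CompoundSpec], rng: np.random.Generator) -> None:
    """Plant per-coculture depletion factors into the library, in place."""
    protected = set(NEVER_DEPLETED)
    eligible = [s for s in specs if s.label not in protected]
    # hold out ~13/72 of signals from depletion in any coculture
    n_hold = max(1, int(round(len(specs) * 13 / 72)) - len(protected))
    held = rng.choice(len(eligible), size=min(n_hold, len(eligible)), replace=False)
    held_labels = {eligible[i].label for i in held} | protected
    held_labels.discard("acetaldehyde")  # depleted in every coculture
    for name, regime in _DEPLETION_REGIMES.items():
        pool = [s for s in specs if s.label not in held_labels]
        n_dep = int(round(regime["frac"] * len(pool)))
        chosen = rng.choice(len(pool), size=n_dep, replace=False)
        chosen_specs = {pool[i].label for i in chosen}
        for s in specs:
            if s.label in chosen_specs or s.label == "acetaldehyde":
                base = regime["hc"] if _is_hydrocarbon(s.formula) else regime["other"]
                s.depletion_factor[name] = float(
                    np.clip(base + rng.normal(0, 0.05), 0.05, 0.95)
                )
    # Yoonia: acetaldehyde only; strong enough to survive FDR correction
    # as the lone depleted signal in its contrast
    for s in specs:
        if s.label == "acetaldehyde":
            s.depletion_factor["Yoonia"] = 0.7


# ---------------------------------------------------------------------------
# liquid concentrations
# ---------------------------------------------------------------------------

def _conc_nM(production_fmol: float, density_cells_per_ml: float) -> float:
    """Liquid concentration from a per-cell pool:
    nM = fmol/cell * 1e-15 mol/fmol * cells/ml * 1e3 ml/l * 1e9 nM/M."""
    return production_fmol * density_cells_per_ml * 1e-3


def simulate_liquid_concentrations(
    library: list[CompoundSpec],
    design: ExperimentDesign,
    cv: float = 0.2,
    seed: int | None = None,
) -> tuple[SyntheticTruth, pd.DataFrame]:
    """Per-sample liquid concentrations (nM) plus the ground truth.

    Axenic expected concentration = per-cell production x diatom density
    (phase-specific); coculture = axenic x (1 - depletion factor). Replicate
    noise is lognormal with the given CV, mean-preserving. Identical seeds
    give identical tables.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    labels = [s.signal_label for s in library]
    sigma = float(np.sqrt(np.log(1 + cv**2)))

    cols: dict[str, np.ndarray] = {}
    expected_cols = {}
    produced: dict[str, set[str]] = {}
    depleted: dict[tuple[str, str], set[str]] = {}
    percell_dep = {}

    for phase in design.phases:
        density = design.diatom_density[phase]
        base = np.array(
            [
                _conc_nM(
                    s.production_exp if phase == "exponential" else s.production_stat,
                    density,
                )
                for s in library
            ]
        )
        produced[phase] = {l for l, b in zip(labels, base) if b > 0}
        for treatment in design.treatments:
            if treatment == AXENIC:
                expect = base
            else:
                factors = np.array(
                    [1.0 - s.depletion_factor.get(treatment, 0.0) for s in library]
                )
                expect = base * factors
                dep_labels = {
                    s.signal_label
                    for s in library
                    if s.depletion_factor.get(treatment, 0.0) > 0
                    and s.signal_label in produced[phase]
                }
                depleted[(treatment, phase)] = dep_labels
                eff_density = design.free_bacteria_density.get(
                    treatment, 0.0
                ) + design.attached_per_diatom.get(treatment, 0.0) * density
                if eff_density > 0:
                    percell_dep[(treatment, phase)] = per_cell_normalize(
                        (base - expect) * 1e-9, eff_density
                    )
            expected_cols[(treatment, phase)] = expect
            for rep in range(1, design.n_replicates + 1):
                noise = np.exp(rng.normal(0.0, sigma, size=len(library)) - sigma**2 / 2)
                cols[design.sample_id(treatment, phase, rep)] = expect * noise

    conc = pd.DataFrame(cols, index=pd.Index(labels, name="signal"))
    truth = SyntheticTruth(
        true_liquid_conc=pd.DataFrame(expected_cols, index=conc.index),
        true_produced_set=produced,
        true_depleted_set=depleted,
        true_percell_depletion=pd.DataFrame(
            percell_dep, index=conc.index
        ),
    )
    return truth, conc


def simulate_blank_concentrations(
    library: list[CompoundSpec],
    n_replicates: int = 6,
    seed: int = 0,
) -> pd.DataFrame:
    """Media-blank (ASW) concentrations: zero for every library signal."""
    labels = [s.signal_label for s in library]
    cols = {f"Blank-r{r}": np.zeros(len(labels)) for r in range(1, n_replicates + 1)}
    return pd.DataFrame(cols, index=pd.Index(labels, name="signal"))


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def _add_gaussian(
    intensity: np.ndarray,
    axis: np.ndarray,
    center: float,
    sigma: float,
    counts_per_cycle: float,
    dx: float,
) -> None:
    """Add a Gaussian peak (integrated counts per cycle) to every cycle."""
    lo = np.searchsorted(axis, center - 6 * sigma)
    hi = np.searchsorted(axis, center + 6 * sigma)
    if hi <= lo:
        return
    x = axis[lo:hi]
    dens = np.exp(-0.5 * ((x - center) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
    intensity[:, lo:hi] += counts_per_cycle * dens * dx


def render_spectrum_series(
    liquid_conc_sample,
    library: list[CompoundSpec],
    instrument: InstrumentParams = InstrumentParams(),
    stripping: StrippingParams = StrippingParams(),
    seed: int = 0,
    duration_s: float = 300.0,
) -> RawSpectrumSeries:
    """Render one sample's raw spectrum series from liquid concentrations.

    ``liquid_conc_sample`` maps signal labels to nM (a dict or pandas
    Series); zero/missing entries contribute nothing, so an all-zero map
    yields a blank (ASW) series with only reference ions, background peaks,
    H3O+ and noise. The gas-phase forward map inverts the quantification
    chain exactly; drift distorts the m/z axis affinely.
    """
    conc = dict(liquid_conc_sample)
    rng = np.random.default_rng(seed)
    dx = instrument.axis_step
    axis = np.arange(instrument.mz_min - 0.75, instrument.mz_max + 0.25 + dx / 2, dx)
    cycles = np.arange(0.0, duration_s, instrument.cycle_s)
    intensity = np.zeros((cycles.size, axis.size))
    scale, offset = instrument.mass_drift

    def drifted(m: float) -> float:
        return scale * m + offset

    # reference ions and background contaminant peaks
    for m in instrument.reference_ions:
        pos = drifted(m)
        if axis[0] <= pos <= axis[-1]:
            _add_gaussian(intensity, axis, pos, instrument.peak_sigma,
                          instrument.reference_counts, dx)
    for m, counts in instrument.background_peaks.items():
        pos = drifted(m)
        if axis[0] <= pos <= axis[-1]:
            _add_gaussian(intensity, axis, pos, instrument.peak_sigma, counts, dx)

    # analyte peaks with isotopologue satellites
    for spec in library:
        c_nM = float(conc.get(spec.signal_label, 0.0))
        if c_nM <= 0:
            continue
        mz = spec.mz
        if not (instrument.mz_min <= mz <= instrument.mz_max):
            warnings.warn(
                f"{spec.label}: m/z {mz:.3f} outside acquisition range, omitted"
            )
            continue
        ppbv = molar_to_ppbv(c_nM * 1e-9, stripping)
        total_counts = (
            ppbv_to_ncps(ppbv, instrument.kinetics)
            / instrument.kinetics.ncps_scale
            * instrument.h3o_counts
        )
        f_m1, f_m2 = isotopologue_fractions(spec.formula)
        parent_counts = total_counts / (1.0 + f_m1 + f_m2)
        for moff, frac in ((0.0, 1.0), (1.003, f_m1), (2.004, f_m2)):
            if frac <= 0:
                continue
            pos = drifted(mz + moff)
            if axis[0] <= pos <= axis[-1]:
                _add_gaussian(intensity, axis, pos, instrument.peak_sigma,
                              parent_counts * frac, dx)

    if instrument.noise_sd > 0:
        intensity += rng.normal(0.0, instrument.noise_sd, size=intensity.shape)
        np.clip(intensity, 0.0, None, out=intensity)

    meta = {
        "mz_min": instrument.mz_min,
        "mz_max": instrument.mz_max,
        "cycle_s": instrument.cycle_s,
        "peak_sigma": instrument.peak_sigma,
        "reference_ions": tuple(instrument.reference_ions),
        "h3o_counts": np.full(cycles.size, instrument.h3o_counts),
        "en_ratio": instrument.en_ratio,
    }
    return RawSpectrumSeries(axis, cycles, intensity, meta)


# ---------------------------------------------------------------------------
# cell counts and GCP
# ---------------------------------------------------------------------------

def simulate_cell_counts(
    design: ExperimentDesign,
    seed: int | None = None,
    n_diatoms_imaged: int = 50,
) -> list[CultureSample]:
    """Flow-cytometry densities and SEM attached-cell counts per sample.

    Diatom and free-living bacterial densities get Poisson-like relative
    noise; the attached-per-diatom estimate is the mean of per-diatom
    Poisson counts over ``n_diatoms_imaged`` imaged diatom cells.
    """
    rng = np.random.default_rng(design.seed + 1 if seed is None else seed)
    out: list[CultureSample] = []
    for phase in design.phases:
        for treatment in design.treatments:
            for rep in range(1, design.n_replicates + 1):
                d_mean = design.diatom_density[phase]
                diatom = d_mean * np.exp(rng.normal(0, 0.05) - 0.05**2 / 2)
                free_mean = design.free_bacteria_density.get(treatment, 0.0)
                free = (
                    free_mean * np.exp(rng.normal(0, 0.1) - 0.1**2 / 2)
                    if free_mean > 0
                    else 0.0
                )
                att_mean = design.attached_per_diatom.get(treatment, 0.0)
                attached = (
                    float(rng.poisson(att_mean, size=n_diatoms_imaged).mean())
                    if att_mean > 0
                    else 0.0
                )
                out.append(
                    CultureSample(
                        sample_id=design.sample_id(treatment, phase, rep),
                        treatment=treatment,
                        phase=phase,
                        replicate=rep,
                        diatom_density=float(diatom),
                        free_bacteria_density=float(free),
                        attached_per_diatom=attached,
                    )
                )
    return out


def simulate_gcp_dataset(
    design: ExperimentDesign,
    stimulation_map: dict[str, float],
    seed: int | None = None,
    base_gcp: float = 0.4,  # nmol C cell^-1 h^-1, axenic
    cv: float = 0.1,
    day: int = 4,
    dic: float = 2e-3,  # mol C / l
    spike_uci: float = 2.0,
    dpm_dark: float = 200.0,
    incubation: float = 1.0 / 3.0,  # h
    volume: float = 0.01,  # l
) -> list[GcpSample]:
    """14C light/dark bottle observations with planted GCP stimulation.

    The expected GCP of each treatment is axenic GCP x (1 + stimulation/100)
    with mean-preserving lognormal replicate noise; light DPM values are
    back-computed from the target rates so that :func:`phycovoc.gcp.compute_gcp`
    recovers them. Treatments absent from ``stimulation_map`` get 0%.
    """
    for t, pct in stimulation_map.items():
        if pct < -100:
            raise ValueError(f"stimulation for {t} below -100%")
    rng = np.random.default_rng(design.seed + 2 if seed is None else seed)
    dpm_total = spike_uci * DPM_PER_UCI
    density = design.diatom_density["exponential"]
    sigma = float(np.sqrt(np.log(1 + cv**2)))
    samples: list[GcpSample] = []
    treatments = list(design.treatments) + [
        t for t in stimulation_map if t not in design.treatments
    ]
    for treatment in treatments:
        stim = stimulation_map.get(treatment, 0.0)
        target = base_gcp * (1 + stim / 100.0)
        for rep in range(1, design.n_replicates + 1):
            rate = target * np.exp(rng.normal(0, sigma) - sigma**2 / 2)
            n_cells = density * volume * 1e3
            fixed_mol = rate * 1e-9 * incubation * n_cells
            net_dpm = fixed_mol * dpm_total / (dic * volume)
            samples.append(
                GcpSample(
                    sample_id=f"{treatment}-gcp-d{day}-r{rep}",
                    treatment=treatment,
                    day=day,
                    dpm_light=float(dpm_dark + net_dpm),
                    dpm_dark=float(dpm_dark),
                    dpm_total_added=dpm_total,
                    dic=dic,
                    incubation=incubation,
                    volume=volume,
                    diatom_density=density,
                )
            )
    return samples
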