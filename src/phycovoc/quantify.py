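"""Signal quantification: ncps -> ppbv -> liquid molarity -> per-cell pools.

Chain of conversions for dynamically stripped culture samples measured by
PTR-TOF-MS:

1. ``compute_ppbv`` — normalized counts to a headspace mixing ratio via the
   simple-reaction-kinetics approach (no calibration standards; the method
   carries a stated ~30% accuracy when the reduced field E/N exceeds 100 Td).
2. ``attribute_isotope_peaks`` — fold natural-abundance M+1/M+2 isotopologue
   satellites back into their parent signal.
3. ``ppbv_to_molar`` — blank-corrected mixing ratio to the molar
   concentration originally dissolved in the stripped liquid,

       C_t = (C_c - C_b) * Q * p * t / (V * R * T)

   with C_c, C_b as mole fractions, Q the bubbling rate (l/h), p the
   pressure (atm), t the collected-data duration (h), V the liquid volume
   (l), R the gas constant (l atm / K / mol) and T the temperature (K).
4. ``per_cell_normalize`` — molarity to a per-cell pool (fmol per cell).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem import M1_OFFSET, M2_OFFSET
from .signal_table import SignalTable, label_mz

__all__ = [
    "KineticsParams",
    "StrippingParams",
    "IsotopeTable",
    "CultureSample",
    "compute_ppbv",
    "ppbv_to_ncps",
    "isotopologue_fractions",
    "attribute_isotope_peaks",
    "ppbv_to_molar",
    "molar_to_ppbv",
    "effective_bacterial_density",
    "per_cell_normalize",
]


@dataclass(frozen=True)
class KineticsParams:
    """Constants of the simple-reaction-kinetics mixing-ratio estimate.

    rate_constant : proton-transfer rate coefficient, cm^3 s^-1
    reaction_time : ion residence time in the drift tube, s
    air_density   : number density of the drift-tube gas, cm^-3
    en_ratio      : reduced electric field, Td; > 100 Td flags the method
                    as valid at its stated ~30% accuracy
    ncps_scale    : counts per this many primary ions equal 1 ncps unit
    """

    rate_constant: float = 2e-9
    reaction_time: float = 1e-4
    air_density: float = 2.46e19
    en_ratio: float = 126.0
    ncps_scale: float = 1e6

    def __post_init__(self):
        for name in ("rate_constant", "reaction_time", "air_density", "ncps_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"KineticsParams.{name} must be positive")

    @property
    def kinetics_valid(self) -> bool:
        return self.en_ratio > 100.0


@dataclass(frozen=True)
class StrippingParams:
    """Constants of the stripping-chamber molarity conversion.

    Q (l/h) bubbling rate, p (atm), t (h) duration of the analyzed data
    window, V (l) liquid volume, R (l atm K^-1 mol^-1), T (K).
    """

    Q: float = 0.3
    p: float = 1.0
    t: float = 0.075  # 4.5 min
    V: float = 0.1
    R: float = 0.0821
    T: float = 292.15

    def __post_init__(self):
        for name in ("Q", "p", "t", "V", "R", "T"):
            if getattr(self, name) <= 0:
                raise ValueError(f"StrippingParams.{name} must be strictly positive")

    @property
    def liquid_per_gas_factor(self) -> float:
        """Molarity produced in V by a unit mole-fraction stream: Q p t/(V R T)."""
        return self.Q * self.p * self.t / (self.V * self.R * self.T)


@dataclass(frozen=True)
class IsotopeTable:
    """Natural abundances of the heavy isotopes considered (fractions)."""

    a13C: float = 0.0107
    a15N: float = 0.00364
    a18O: float = 0.00205
    a34S: float = 0.0425

    def __post_init__(self):
        for name in ("a13C", "a15N", "a18O", "a34S"):
            v = getattr(self, name)
            if not 0 < v <= 0.05:
                raise ValueError(f"IsotopeTable.{name}={v} outside (0, 0.05]")


@dataclass
class CultureSample:
    """Per-sample culture metadata used for per-cell normalization."""

    sample_id: str
    treatment: str
    phase: str
    replicate: int
    diatom_density: float  # cells / ml
    free_bacteria_density: float = 0.0  # cells / ml
    attached_per_diatom: float = 0.0  # mean bacteria attached per diatom

    def __post_init__(self):
        if self.diatom_density < 0 or self.free_bacteria_density < 0:
            raise ValueError("cell densities must be >= 0")


# ---------------------------------------------------------------------------
# mixing ratios
# ---------------------------------------------------------------------------

def compute_ppbv(ncps, kinetics: KineticsParams = KineticsParams()):
    """Mixing ratio (ppbv) from an H3O+-normalized signal.

    ``ncps`` is the analyte signal per ``ncps_scale`` primary ions. The
    analyte number density is (analyte/primary ratio)/(k * t); dividing by
    the drift-tube gas density gives the mole fraction, scaled to ppbv.
    """
    ncps = np.asarray(ncps, dtype=float)
    if np.any(ncps < 0):
        raise ValueError("ncps values must be >= 0")
    ratio = ncps / kinetics.ncps_scale
    mole_fraction = ratio / (
        kinetics.rate_constant * kinetics.reaction_time * kinetics.air_density
    )
    out = mole_fraction * 1e9
    return float(out) if out.ndim == 0 else out


def ppbv_to_ncps(ppbv, kinetics: KineticsParams = KineticsParams()):
    """Inverse of :func:`compute_ppbv` (forward model of the simulator)."""
    ppbv = np.asarray(ppbv, dtype=float)
    ratio = (
        ppbv
        * 1e-9
        * kinetics.rate_constant
        * kinetics.reaction_time
        * kinetics.air_density
    )
    out = ratio * kinetics.ncps_scale
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# isotopologues
# ---------------------------------------------------------------------------

def isotopologue_fractions(
    formula: dict[str, int] | None, isotopes: IsotopeTable = IsotopeTable()
) -> tuple[float, float]:
    """First-order M+1 and M+2 satellite fractions of the parent signal.

    f_M1 = nC*a13C + nN*a15N, f_M2 = nO*a18O + nS*a34S — the linear term of
    the natural-abundance expansion over the isotope set considered
    (2H, 17O, 33S and multiple substitutions are ignored).
    """
    if formula is None:
        return 0.0, 0.0
    if any(n < 0 for n in formula.values()):
        raise ValueError("element counts must be nonnegative")
    f_m1 = formula.get("C", 0) * isotopes.a13C + formula.get("N", 0) * isotopes.a15N
    f_m2 = formula.get("O", 0) * isotopes.a18O + formula.get("S", 0) * isotopes.a34S
    return f_m1, f_m2


def attribute_isotope_peaks(
    table: SignalTable,
    records,
    min_parent_ppbv: float = 0.05,
    expectation_window: tuple[float, float] = (0.5, 2.0),
    mz_tol: float = 0.01,
    isotopes: IsotopeTable = IsotopeTable(),
) -> tuple[SignalTable, pd.DataFrame]:
    """Fold M+1/M+2 isotopologue satellites into their parent rows.

    ``records`` is an iterable with ``signal_label`` and ``formula``
    attributes (see :class:`phycovoc.differential.CompoundRecord`). For each
    parent present in ``table`` with a formula and mean value >=
    ``min_parent_ppbv``, candidate satellite rows at parent m/z + 1.003 /
    + 2.004 (within ``mz_tol``) are attributed when their mean value lies
    within ``expectation_window`` times the natural-abundance expectation.
    Attributed satellites are added to the parent (column-wise) and removed;
    a satellite matching two parents goes to the parent whose expectation is
    closer. Total table mass is conserved. Returns the new table and an
    attribution log.
    """
    if table.level != "ppbv":
        raise ValueError("isotope attribution operates on a ppbv-level table")
    data = table.data.copy()
    mzs = {lbl: label_mz(lbl) for lbl in data.index}
    means = data.mean(axis=1)

    # candidate (satellite, parent, expectation) triplets
    candidates: dict[str, list[tuple[str, float, str]]] = {}
    for rec in records:
        parent = rec.signal_label
        if parent not in data.index or rec.formula is None:
            continue
        if means[parent] < min_parent_ppbv:
            continue
        f_m1, f_m2 = isotopologue_fractions(rec.formula, isotopes)
        for offset, frac, kind in ((M1_OFFSET, f_m1, "M+1"), (M2_OFFSET, f_m2, "M+2")):
            if frac <= 0:
                continue
            target = mzs[parent] + offset
            for lbl, mz in mzs.items():
                if lbl == parent or abs(mz - target) > mz_tol:
                    continue
                expected = means[parent] * frac
                lo, hi = expectation_window
                if expected > 0 and lo * expected <= means[lbl] <= hi * expected:
                    candidates.setdefault(lbl, []).append((parent, expected, kind))

    log_rows = []
    for sat, options in candidates.items():
        # closest expectation wins when a satellite matches several parents
        parent, expected, kind = min(options, key=lambda o: abs(means[sat] - o[1]))
        data.loc[parent] = data.loc[parent] + data.loc[sat]
        data = data.drop(index=sat)
        log_rows.append(
            {
                "satellite": sat,
                "parent": parent,
                "kind": kind,
                "observed_mean_ppbv": means[sat],
                "expected_mean_ppbv": expected,
                "n_candidate_parents": len(options),
            }
        )
    log = pd.DataFrame(
        log_rows,
        columns=[
            "satellite",
            "parent",
            "kind",
            "observed_mean_ppbv",
            "expected_mean_ppbv",
            "n_candidate_parents",
        ],
    )
    return table.with_rows(data), log


# ---------------------------------------------------------------------------
# liquid molarity and per-cell pools
# ---------------------------------------------------------------------------

def ppbv_to_molar(
    ppbv_sample, ppbv_blank, params: StrippingParams = StrippingParams()
):
    """Liquid molar concentration from blank-corrected headspace ppbv.

    Negative blank-corrected mixing ratios are floored at zero (a separate
    boolean array of flags is returned alongside the concentrations).
    """
    sample = np.asarray(ppbv_sample, dtype=float)
    blank = np.asarray(ppbv_blank, dtype=float)
    net = sample - blank
    flagged = net < 0
    net = np.where(flagged, 0.0, net)
    molar = net * 1e-9 * params.liquid_per_gas_factor
    if molar.ndim == 0:
        return float(molar), bool(flagged)
    return molar, flagged


def molar_to_ppbv(molar, params: StrippingParams = StrippingParams()):
    """Headspace mixing ratio (ppbv, net of blank) that a stripped liquid
    concentration corresponds to — the inverse of :func:`ppbv_to_molar`,
    used as the simulator's forward map."""
    molar = np.asarray(molar, dtype=float)
    out = molar / params.liquid_per_gas_factor * 1e9
    return float(out) if out.ndim == 0 else out


def effective_bacterial_density(sample: CultureSample) -> float:
    """Free-living plus attached bacterial density (cells/ml).

    Attached cells are counted via the mean attached-per-diatom estimate
    times the diatom density.
    """
    if sample.diatom_density < 0 or sample.free_bacteria_density < 0:
        raise ValueError("densities must be >= 0")
    return sample.free_bacteria_density + sample.attached_per_diatom * sample.diatom_density


def per_cell_normalize(conc_molar, density_cells_per_ml):
    """Per-cell pool (fmol/cell) from molarity and a cell density.

    fmol cell^-1 = (mol l^-1 * 1e15 fmol/mol) / (cells ml^-1 * 1e3 ml/l).
    """
    density = np.asarray(density_cells_per_ml, dtype=float)
    if np.any(density <= 0):
        raise ValueError("cell density must be > 0 for per-cell normalization")
    conc = np.asarray(conc_molar, dtype=float)
    out = conc * 1e15 / (density * 1e3)
    return float(out) if out.ndim == 0 else out
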