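"""Raw PTR-TOF spectra -> calibrated, binned, peak-fitted signal tables.

The processing chain mirrors standard PTR-TOF practice: affine mass
calibration against reference ions present in every spectrum, restriction
to the analyzed time window, unit-mass binning (0.5-Da bins bounded at
x-0.25 / x+0.75... i.e. half-open [x-0.25, x+0.25) intervals around each
half-integer), Gaussian decomposition of each bin into one or more peaks,
normalization of integrated areas to the H3O+ primary-ion signal, and
removal of known contaminants / water clusters / fragments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .signal_table import SignalTable, mz_label, label_mz

__all__ = [
    "RawSpectrumSeries",
    "MassCalibration",
    "PeakBin",
    "PeakFit",
    "CalibrationError",
    "calibrate_mass_axis",
    "time_window",
    "bin_axis",
    "estimate_noise_sd",
    "decompose_bin",
    "decompose_series",
    "normalize_to_primary_ion",
    "apply_exclusion_list",
    "assemble_signal_table",
]


class CalibrationError(RuntimeError):
    pass


@dataclass
class RawSpectrumSeries:
    """Time series of spectra: strictly increasing m/z axis, cycle
    timestamps (s), an intensity matrix (cycle x axis point, counts) and
    metadata including the per-cycle H3O+ primary-ion counts."""

    axis: np.ndarray
    cycles: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.axis = np.asarray(self.axis, dtype=float)
        self.cycles = np.asarray(self.cycles, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.axis) <= 0):
            raise ValueError("m/z axis must be strictly increasing")
        if self.intensity.shape != (self.cycles.size, self.axis.size):
            raise ValueError("intensity must be cycles x axis points")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")

    @property
    def summed(self) -> np.ndarray:
        """Cycle-summed spectrum."""
        return self.intensity.sum(axis=0)

    @property
    def h3o_counts(self) -> np.ndarray:
        """Per-cycle primary-ion counts from metadata."""
        h3o = np.asarray(self.meta["h3o_counts"], dtype=float)
        if h3o.ndim == 0:
            h3o = np.full(self.cycles.size, float(h3o))
        return h3o


@dataclass
class MassCalibration:
    reference_masses: list
    fit: tuple  # (scale, offset) of the applied correction: m' = scale*m + offset
    residuals: list  # corrected reference positions minus true masses (Da)
    tolerance: float = 0.005

    @property
    def accepted(self) -> bool:
        return all(abs(r) <= self.tolerance for r in self.residuals)


@dataclass
class PeakBin:
    label: float  # nominal m/z (half-integer grid)
    lo: float  # inclusive
    hi: float  # exclusive
    index: slice  # axis slice covered by the bin


@dataclass
class PeakFit:
    center: float
    sigma: float
    area: float  # integrated counts over the fitted window
    bin_label: float
    flagged: bool = False

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.area < 0:
            raise ValueError("area must be >= 0")


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def _refine_center(axis: np.ndarray, y: np.ndarray, i: int) -> float:
    """Sub-pixel peak center by quadratic interpolation of log-intensity
    (exact for a Gaussian sampled on a uniform grid)."""
    if i <= 0 or i >= y.size - 1:
        return float(axis[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    if min(y0, y1, y2) <= 0:
        denom = y0 - 2 * y1 + y2
        if denom == 0:
            return float(axis[i])
        delta = 0.5 * (y0 - y2) / denom
    else:
        l0, l1, l2 = math.log(y0), math.log(y1), math.log(y2)
        denom = l0 - 2 * l1 + l2
        if denom == 0:
            return float(axis[i])
        delta = 0.5 * (l0 - l2) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    step = axis[min(i + 1, axis.size - 1)] - axis[i] if delta >= 0 else axis[i] - axis[i - 1]
    return float(axis[i] + delta * step)


def locate_peak(series: RawSpectrumSeries, mz: float, half_width: float = 0.25):
    """Observed center of the local maximum within +/- half_width of mz, or
    None if no point in the window rises above the local background."""
    axis, y = series.axis, series.summed
    sel = (axis >= mz - half_width) & (axis < mz + half_width)
    if not sel.any():
        return None
    idx = np.flatnonzero(sel)
    j = idx[np.argmax(y[idx])]
    background = np.median(y[idx])
    if y[j] <= background or y[j] <= 0:
        return None
    return _refine_center(axis, y, j)


def calibrate_mass_axis(
    series: RawSpectrumSeries,
    reference_masses,
    tolerance: float = 0.005,
    half_width: float = 0.25,
) -> tuple[RawSpectrumSeries, MassCalibration]:
    """Affine mass calibration against reference ions.

    Each reference is located as the local maximum within ``half_width`` of
    its nominal position; an affine map observed -> true minimizing squared
    residuals is fitted and applied to the axis. References outside the axis
    range are skipped; at least two must be found.
    """
    in_range = [m for m in reference_masses if series.axis[0] <= m <= series.axis[-1]]
    observed, used = [], []
    missing = []
    for m in in_range:
        pos = locate_peak(series, m, half_width)
        if pos is None:
            missing.append(m)
        else:
            observed.append(pos)
            used.append(m)
    if len(used) < 2:
        raise CalibrationError(
            f"need >= 2 detectable reference peaks, found {len(used)}; "
            f"missing references: {missing or in_range}"
        )
    obs = np.asarray(observed)
    true = np.asarray(used)
    A = np.vstack([obs, np.ones_like(obs)]).T
    (scale, offset), *_ = np.linalg.lstsq(A, true, rcond=None)
    corrected_axis = scale * series.axis + offset
    residuals = (scale * obs + offset - true).tolist()
    cal = MassCalibration(list(used), (float(scale), float(offset)), residuals, tolerance)
    out = RawSpectrumSeries(corrected_axis, series.cycles, series.intensity, dict(series.meta))
    return out, cal


# ---------------------------------------------------------------------------
# windowing and binning
# ---------------------------------------------------------------------------

def time_window(
    series: RawSpectrumSeries, t_start: float = 30.0, t_end: float = 300.0
) -> RawSpectrumSeries:
    """Restrict to cycles with timestamp in [t_start, t_end)."""
    if t_start >= t_end:
        raise ValueError("t_start must be < t_end")
    keep = (series.cycles >= t_start) & (series.cycles < t_end)
    if not keep.any():
        raise ValueError(
            f"time window [{t_start}, {t_end}) contains no acquisition cycles"
        )
    meta = dict(series.meta)
    if "h3o_counts" in meta and np.ndim(meta["h3o_counts"]) == 1:
        meta["h3o_counts"] = np.asarray(meta["h3o_counts"])[keep]
    return RawSpectrumSeries(series.axis, series.cycles[keep], series.intensity[keep], meta)


def bin_axis(series: RawSpectrumSeries, mz_min: float | None = None, mz_max: float | None = None):
    """Half-unit-mass bins: half-open intervals [x-0.25, x+0.25) for x on the
    0.5-Da grid covering the acquisition range. Bins partition
    [mz_min-0.25, mz_max+0.25) with no gaps or overlap."""
    if mz_min is None:
        mz_min = float(series.meta.get("mz_min", math.ceil(series.axis[0] * 2) / 2))
    if mz_max is None:
        mz_max = float(series.meta.get("mz_max", math.floor(series.axis[-1] * 2) / 2))
    centers = np.arange(mz_min, mz_max + 0.25, 0.5)
    bins = []
    axis = series.axis
    for c in centers:
        lo, hi = c - 0.25, c + 0.25
        i0 = int(np.searchsorted(axis, lo, side="left"))
        i1 = int(np.searchsorted(axis, hi, side="left"))
        bins.append(PeakBin(float(c), lo, hi, slice(i0, i1)))
    return bins


def assign_bin(mz: float, mz_min: float = 30.0) -> float:
    """Nominal bin label for an m/z value under the half-open convention."""
    return float(np.floor((mz - (mz_min - 0.25)) / 0.5) * 0.5 + mz_min)


# ---------------------------------------------------------------------------
# peak decomposition
# ---------------------------------------------------------------------------

def estimate_noise_sd(y: np.ndarray) -> tuple[float, float]:
    """Robust (baseline, noise SD) of a spectrum: the median and 1.4826 x
    median absolute deviation (peaks occupy a tiny fraction of axis
    points, so both are dominated by the baseline)."""
    y = np.asarray(y, dtype=float)
    med = float(np.median(y))
    mad = float(np.median(np.abs(y - med)))
    return med, 1.4826 * mad


def _gauss_sum(x, *params):
    y = np.zeros_like(x)
    for k in range(0, len(params), 3):
        amp, c, s = params[k : k + 3]
        y = y + amp * np.exp(-0.5 * ((x - c) / s) ** 2)
    return y


def _gauss_jac(x, *params):
    cols = []
    for k in range(0, len(params), 3):
        amp, c, s = params[k : k + 3]
        z = (x - c) / s
        g = np.exp(-0.5 * z**2)
        cols.extend([g, amp * g * z / s, amp * g * z**2 / s])
    return np.stack(cols, axis=1)


def decompose_bin(
    axis_seg: np.ndarray,
    y_seg: np.ndarray,
    bin_label: float,
    noise_sd: float,
    min_snr: float = 3.0,
    max_components: int = 3,
    improvement: float = 0.05,
    sigma_guess: float = 0.02,
):
    """Fit 1..k Gaussians to a bin's cycle-summed intensities.

    Components are added while the residual sum of squares drops by more
    than ``improvement`` relatively (k capped at ``max_components``). Peaks
    are only sought when the bin maximum clears ``min_snr`` times the noise
    SD; extra components are only attempted when either multiple local
    maxima clear the threshold or the single-component residual stays well
    above the noise floor (an unexplained shoulder). Areas are analytic
    Gaussian integrals (amp * sigma * sqrt(2 pi)) divided by the axis step,
    i.e. total counts. Non-convergent fits fall back to a flagged
    single-Gaussian moment estimate.
    """
    axis_seg = np.asarray(axis_seg, dtype=float)
    y_raw = np.asarray(y_seg, dtype=float)
    if axis_seg.size < 5:
        return []
    threshold = min_snr * noise_sd
    if y_raw.max() <= threshold or y_raw.max() <= 0:
        return []
    dx = float(np.median(np.diff(axis_seg)))

    # candidate maxima: prominent local peaks above threshold, > 2 sigma apart
    from scipy.signal import find_peaks

    peak_idx, _ = find_peaks(
        y_raw,
        height=threshold,
        prominence=threshold,
        distance=max(1, int(2 * sigma_guess / dx)),
    )
    maxima = sorted(peak_idx.tolist(), key=lambda i: -y_raw[i])
    if not maxima:
        maxima = [int(np.argmax(y_raw))]
    n_max = len(maxima)
    maxima_x = [float(axis_seg[i]) for i in maxima]
    maxima_y = [float(y_raw[i]) for i in maxima]

    if n_max == 1:
        # single-peak bin: restrict the fit to a window around the maximum
        half = max(5 * sigma_guess, 0.05)
        i0 = int(np.searchsorted(axis_seg, axis_seg[maxima[0]] - half))
        i1 = int(np.searchsorted(axis_seg, axis_seg[maxima[0]] + half))
        axis_seg, y_raw = axis_seg[i0:i1], y_raw[i0:i1]
        if axis_seg.size < 5:
            return []

    # local, normalized coordinates keep the least-squares problem
    # well-conditioned (amplitudes O(1), centers O(0.1))
    y_scale = float(y_raw.max())
    y_seg = y_raw / y_scale
    x_seg = axis_seg - bin_label
    lo, hi = float(x_seg[0]), float(x_seg[-1])
    threshold_n = threshold / y_scale

    def moment_fallback():
        w = np.clip(y_raw, 0, None)
        tot = w.sum()
        c = float((axis_seg * w).sum() / tot)
        var = float(((axis_seg - c) ** 2 * w).sum() / tot)
        s = max(math.sqrt(max(var, 1e-12)), dx / 2)
        return [PeakFit(c, s, float(tot), bin_label, flagged=True)]

    def initial_guess(k):
        # seed components at the k most prominent detected maxima; when the
        # model asks for more components than maxima (shoulder search),
        # offset extra seeds beside the strongest peak
        seeds = [(x - bin_label, h / y_scale) for x, h in zip(maxima_x[:k], maxima_y[:k])]
        j = 0
        while len(seeds) < k:
            side = 1 if j % 2 == 0 else -1
            seeds.append(
                (
                    float(np.clip(seeds[0][0] + side * (j // 2 + 1) * 2 * sigma_guess, lo, hi)),
                    0.3 * seeds[0][1],
                )
            )
            j += 1
        p0 = []
        for c, h in sorted(seeds):
            p0 += [max(h, threshold_n), c, sigma_guess]
        return p0

    best = None
    best_rss = float((y_seg**2).sum())
    total_ss = best_rss
    noise_floor = y_seg.size * (max(noise_sd, 0.0) / y_scale) ** 2
    for k in range(1, max_components + 1):
        if best is not None and k > n_max and best_rss <= 10.0 * noise_floor:
            break  # one component per maximum suffices; no shoulder left
        p0 = initial_guess(k)
        lower = [0.0, lo, dx / 4] * k
        upper = [np.inf, hi, 0.25] * k
        # weak bins near the detection limit get a short iteration budget;
        # they carry little signal and their fits otherwise wander
        maxfev = 600 if y_scale > 10 * threshold else 80
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    _gauss_sum, x_seg, y_seg, p0=p0, jac=_gauss_jac,
                    bounds=(lower, upper), maxfev=maxfev,
                    ftol=1e-8, xtol=1e-8, gtol=1e-8,
                )
            rss = float(((y_seg - _gauss_sum(x_seg, *popt)) ** 2).sum())
        except (RuntimeError, ValueError):
            if k == 1:
                return moment_fallback()
            break
        if best is None or rss < best_rss * (1 - improvement):
            best, best_rss = popt, rss
        else:
            break
        # residuals at the noise floor (or a negligible fraction of the
        # signal): more components cannot help
        if best_rss <= 2.0 * noise_floor or best_rss <= 1e-6 * total_ss:
            break
    if best is None:
        return moment_fallback()
    fits = []
    for j in range(0, len(best), 3):
        amp, c, s = best[j : j + 3]
        if amp < threshold_n:  # component below detection: drop
            continue
        area = amp * y_scale * s * math.sqrt(2 * math.pi) / dx
        fits.append(PeakFit(float(c) + bin_label, float(s), float(area), bin_label))
    fits.sort(key=lambda f: f.center)
    return fits


def decompose_series(
    series: RawSpectrumSeries,
    min_snr: float = 3.0,
    max_components: int = 3,
    sigma_guess: float | None = None,
):
    """Bin the cycle-summed spectrum and decompose every bin.

    The spectrum-wide baseline (median) is subtracted before fitting so the
    detection threshold works on net signal."""
    baseline, noise = estimate_noise_sd(series.summed)
    y = np.clip(series.summed - baseline, 0.0, None)
    if noise <= 0:
        noise = max(y.max() * 1e-9, 1e-12)
    if sigma_guess is None:
        sigma_guess = float(series.meta.get("peak_sigma", 0.02))
    fits: list[PeakFit] = []
    for b in bin_axis(series):
        seg = series.axis[b.index]
        if seg.size == 0:
            continue
        fits.extend(
            decompose_bin(
                seg, y[b.index], b.label, noise,
                min_snr=min_snr, max_components=max_components,
                sigma_guess=sigma_guess,
            )
        )
    return fits


# ---------------------------------------------------------------------------
# normalization and table assembly
# ---------------------------------------------------------------------------

def normalize_to_primary_ion(area, h3o_area, scale: float = 1e6):
    """Signal per ``scale`` primary ions (default: per-million, ncps units)."""
    h3o = np.asarray(h3o_area, dtype=float)
    if np.any(h3o <= 0):
        raise ValueError("H3O+ area must be > 0")
    out = np.asarray(area, dtype=float) / h3o * scale
    return float(out) if out.ndim == 0 else out


def process_series(
    series: RawSpectrumSeries,
    reference_masses=None,
    t_start: float = 30.0,
    t_end: float = 300.0,
    min_snr: float = 3.0,
) -> list[tuple[float, float]]:
    """Calibrate, window and decompose one series.

    Returns (center, ncps) pairs: each fitted peak's integrated area
    normalized to the summed primary-ion counts over the same window.
    """
    if reference_masses is None:
        reference_masses = series.meta.get(
            "reference_ions", (29.998, 203.943, 330.848)
        )
    calibrated, _ = calibrate_mass_axis(series, reference_masses)
    windowed = time_window(calibrated, t_start, t_end)
    fits = decompose_series(windowed, min_snr=min_snr)
    h3o_total = float(windowed.h3o_counts.sum())
    return [(f.center, normalize_to_primary_ion(f.area, h3o_total)) for f in fits]


def assemble_signal_table(
    peaks_per_sample: dict[str, list[tuple[float, float]]],
    match_tol: float = 0.01,
    min_samples: int = 2,
) -> SignalTable:
    """Merge per-sample (center, ncps) peak lists into an ncps SignalTable.

    Peak centers from all samples are pooled and clustered by sorting and
    splitting at gaps > 2*match_tol; each cluster becomes a signal row
    labeled by its median center at the 2-decimal convention. Absent peaks
    are zeros. Clusters supported by fewer than ``min_samples`` distinct
    samples are dropped (a prevalence filter against one-off noise peaks).
    """
    all_centers = sorted(
        c for peaks in peaks_per_sample.values() for c, _ in peaks
    )
    if not all_centers:
        empty = pd.DataFrame(
            index=pd.Index([], name="signal"),
            columns=list(peaks_per_sample),
            dtype=float,
        )
        return SignalTable(empty, "ncps")
    clusters: list[list[float]] = [[all_centers[0]]]
    for c in all_centers[1:]:
        if c - clusters[-1][-1] > 2 * match_tol:
            clusters.append([c])
        else:
            clusters[-1].append(c)
    centers = [float(np.median(cl)) for cl in clusters]
    bounds = [(cl[0] - match_tol, cl[-1] + match_tol) for cl in clusters]
    labels = [mz_label(c) for c in centers]
    data = pd.DataFrame(
        0.0, index=pd.Index(labels, name="signal"), columns=list(peaks_per_sample)
    )
    support: dict[str, set[str]] = {lbl: set() for lbl in labels}
    for sample, peaks in peaks_per_sample.items():
        for c, v in peaks:
            for lbl, (lo, hi) in zip(labels, bounds):
                if lo <= c <= hi:
                    data.loc[lbl, sample] += v
                    support[lbl].add(sample)
                    break
    keep = [lbl for lbl in labels if len(support[lbl]) >= min_samples]
    return SignalTable(data.loc[keep], "ncps")


def apply_exclusion_list(
    table: SignalTable,
    exclusions,
    fragment_map: dict | None = None,
    reassign_fragments: bool = False,
    match_tol: float = 0.25,
) -> tuple[SignalTable, list[str]]:
    """Drop known contaminants / water clusters / fragments from the table.

    ``exclusions`` are m/z values; a row is removed when its label is within
    ``match_tol`` of one. ``fragment_map`` maps fragment m/z to parent m/z;
    fragment rows are dropped, optionally adding their values to the parent
    first. Returns the filtered table and a removal log.
    """
    if table.level not in ("counts", "ncps"):
        raise ValueError("exclusion filtering operates on counts/ncps tables")
    data = table.data.copy()
    removed: list[str] = []

    def find_row(mz):
        hits = [lbl for lbl in data.index if abs(label_mz(lbl) - mz) <= match_tol]
        return hits

    for mz in exclusions:
        for lbl in find_row(mz):
            data = data.drop(index=lbl)
            removed.append(f"excluded {lbl} (matched {mz})")
    for frag_mz, parent_mz in (fragment_map or {}).items():
        frag_rows = find_row(frag_mz)
        parent_rows = find_row(parent_mz)
        for lbl in frag_rows:
            if reassign_fragments and parent_rows:
                data.loc[parent_rows[0]] += data.loc[lbl]
                removed.append(f"fragment {lbl} reassigned to {parent_rows[0]}")
            elif not parent_rows:
                warnings.warn(
                    f"fragment {lbl}: parent {parent_mz} absent, dropping"
                )
                removed.append(f"fragment {lbl} dropped (parent {parent_mz} absent)")
            else:
                removed.append(f"fragment {lbl} dropped")
            data = data.drop(index=lbl)
    return table.with_rows(data), removed
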