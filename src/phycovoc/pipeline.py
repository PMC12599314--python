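"""End-to-end orchestration: simulate -> process -> quantify -> diffs -> gcp.

A single YAML-able config dict drives every stage; a global seed is
expanded into per-stage substreams so stages are individually
reproducible. The run report collects stage counts, contrast results,
class totals, GCP stimulation and (for synthetic runs) recovery against
the planted ground truth, plus a config hash for idempotence checks.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .differential import (
    CompoundRecord,
    aggregate_by_class,
    call_depletion,
    call_production,
    permanova,
)
from .gcp import compute_gcp, stimulation
from .io import config_hash
from .quantify import (
    KineticsParams,
    StrippingParams,
    attribute_isotope_peaks,
    compute_ppbv,
)
from .signal_table import SignalTable, label_mz, subset_columns
from .spectral import apply_exclusion_list, assemble_signal_table, process_series
from .synthetic import (
    AXENIC,
    ExperimentDesign,
    InstrumentParams,
    make_compound_library,
    render_spectrum_series,
    simulate_cell_counts,
    simulate_gcp_dataset,
    simulate_liquid_concentrations,
)

__all__ = ["default_config", "validate_config", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def default_config() -> dict:
    """The bundled default synthetic experiment configuration."""
    return {
        "seed": 0,
        "library": {"n_compounds": 72, "n_hydrocarbons": 40},
        "design": {
            "n_replicates": 6,
            "phases": ["exponential", "stationary"],
        },
        "noise": {"concentration_cv": 0.2},
        "instrument": {
            "noise_sd": 1.0,
            "mass_drift": [1.0002, 0.01],
            "axis_step": 0.005,
        },
        "processing": {
            "t_start": 30.0,
            "t_end": 300.0,
            "min_snr": 3.0,
            "exclusions": [37.0, 55.0],
            "min_feature_samples": 3,
        },
        "quantify": {"min_parent_ppbv": 0.05},
        "stripping": {"Q": 0.3, "p": 1.0, "t": 0.075, "V": 0.1, "R": 0.0821, "T": 292.15},
        "stats": {"alpha": 0.05, "q_max": 0.1, "permutations": 999},
        "gcp": {
            "stimulation": {
                "Trap": 24.9,
                "Marinobacter": 29.3,
                "Stappia": 25.0,
                "Rhodophyticola": 20.1,
                "Roseibium": 5.0,
                "Yoonia": 2.0,
            },
            "base_gcp": 0.4,
            "cv": 0.1,
        },
    }


def validate_config(config: dict) -> list[str]:
    """Range checks; all violations reported at once (empty list = valid)."""
    findings: list[str] = []
    stats = config.get("stats", {})
    for key in ("alpha", "q_max"):
        v = stats.get(key, 0.05 if key == "alpha" else 0.1)
        if not 0 < v < 1:
            findings.append(f"stats.{key}={v} outside (0, 1)")
    strip = config.get("stripping", {})
    for key in ("Q", "p", "t", "V", "R", "T"):
        v = strip.get(key, getattr(StrippingParams(), key))
        if v <= 0:
            findings.append(f"stripping.{key}={v} must be strictly positive")
    lib = config.get("library", {})
    if lib.get("n_compounds", 72) < 9:
        findings.append("library.n_compounds below the 9 fixed anchor compounds")
    design = config.get("design", {})
    if design.get("n_replicates", 6) < 2:
        findings.append("design.n_replicates must be >= 2")
    proc = config.get("processing", {})
    if proc.get("t_start", 30.0) >= proc.get("t_end", 300.0):
        findings.append("processing.t_start must be < processing.t_end")
    if "spectra_path" in config and not Path(config["spectra_path"]).exists():
        findings.append(f"spectra_path {config['spectra_path']} does not exist")
    return findings


def _stage_seeds(seed: int) -> dict[str, int]:
    names = ("library", "concentrations", "cells", "spectra", "gcp", "permanova")
    state = np.random.SeedSequence(seed).generate_state(len(names))
    return {n: int(s % (2**31)) for n, s in zip(names, state)}


def _build_design(config: dict, seed: int) -> ExperimentDesign:
    inst_cfg = dict(config.get("instrument", {}))
    if "mass_drift" in inst_cfg:
        inst_cfg["mass_drift"] = tuple(inst_cfg["mass_drift"])
    kin = KineticsParams(**config.get("kinetics", {}))
    instrument = InstrumentParams(kinetics=kin, **inst_cfg)
    stripping = StrippingParams(**config.get("stripping", {}))
    design_cfg = dict(config.get("design", {}))
    if "phases" in design_cfg:
        design_cfg["phases"] = tuple(design_cfg["phases"])
    if "treatments" in design_cfg:
        design_cfg["treatments"] = tuple(design_cfg["treatments"])
    return ExperimentDesign(
        instrument=instrument, stripping=stripping, seed=seed, **design_cfg
    )


def match_library_rows(table: SignalTable, library, tol: float = 0.012):
    """CompoundRecords whose signal labels are the observed table rows.

    Each library compound is matched to the nearest table row within
    ``tol`` Da of its protonated mass; unmatched compounds are skipped.
    """
    row_mz = {lbl: label_mz(lbl) for lbl in table.signals}
    records, mapping = [], {}
    for spec in library:
        best = None
        for lbl, mz in row_mz.items():
            d = abs(mz - spec.mz)
            if d <= tol and (best is None or d < abs(row_mz[best] - spec.mz)):
                best = lbl
        if best is not None:
            records.append(CompoundRecord(signal_label=best, formula=spec.formula))
            mapping[spec.signal_label] = best
    return records, mapping


def run_pipeline(config: dict | None = None, outdir=None) -> dict:
    """Execute the full synthetic pipeline; returns the run report dict.

    When ``outdir`` is given, intermediate tables (CSV) and the report
    (JSON) are written there. The report hash is a pure function of the
    config and the seeds, so identical configs reproduce identical reports.
    """
    cfg = default_config()
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key] = {**cfg[key], **val}
        else:
            cfg[key] = val
    findings = validate_config(cfg)
    if findings:
        raise PipelineError("validate", "; ".join(findings))

    seeds = _stage_seeds(cfg["seed"])
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    # ---- simulate ------------------------------------------------------
    try:
        library = make_compound_library(seed=seeds["library"], **cfg["library"])
        design = _build_design(cfg, seed=cfg["seed"])
        truth, conc = simulate_liquid_concentrations(
            library, design, cv=cfg["noise"]["concentration_cv"],
            seed=seeds["concentrations"],
        )
        cells = simulate_cell_counts(design, seed=seeds["cells"])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("simulate", str(exc)) from exc

    # ---- process (per phase, all samples + blanks) ---------------------
    proc_cfg = cfg["processing"]
    spectra_rng = np.random.SeedSequence(seeds["spectra"])
    tables_nM: dict[str, SignalTable] = {}
    blank_cols: dict[str, list[str]] = {}
    records_by_phase: dict[str, list[CompoundRecord]] = {}
    n_signals_raw: dict[str, int] = {}
    try:
        for phase in design.phases:
            peaks: dict[str, list] = {}
            sample_ids = [
                design.sample_id(t, phase, r)
                for t in design.treatments
                for r in range(1, design.n_replicates + 1)
            ]
            blanks = [f"Blank-{phase}-r{r}" for r in range(1, design.n_replicates + 1)]
            child_seeds = spectra_rng.spawn(len(sample_ids) + len(blanks))
            for sid, child in zip(sample_ids + blanks, child_seeds):
                conc_map = (
                    conc[sid] if sid in conc.columns
                    else {lbl: 0.0 for lbl in conc.index}
                )
                series = render_spectrum_series(
                    conc_map, library, design.instrument, design.stripping,
                    seed=int(child.generate_state(1)[0] % (2**31)),
                )
                peaks[sid] = process_series(
                    series,
                    t_start=proc_cfg["t_start"],
                    t_end=proc_cfg["t_end"],
                    min_snr=proc_cfg["min_snr"],
                )
            table = assemble_signal_table(
                peaks, min_samples=proc_cfg.get("min_feature_samples", 2)
            )
            n_signals_raw[phase] = len(table.signals)
            table, _ = apply_exclusion_list(table, proc_cfg["exclusions"])

            # ---- quantify ------------------------------------------------
            kin = design.instrument.kinetics
            ppbv = table.promote(
                pd.DataFrame(
                    compute_ppbv(table.data.values, kin),
                    index=table.data.index, columns=table.data.columns,
                ),
                "ppbv",
            )
            records, _ = match_library_rows(ppbv, library)
            records_by_phase[phase] = records
            ppbv, _ = attribute_isotope_peaks(
                ppbv, records, min_parent_ppbv=cfg["quantify"]["min_parent_ppbv"]
            )
            factor = design.stripping.liquid_per_gas_factor
            nM = ppbv.promote(ppbv.data * factor, "nM")
            tables_nM[phase] = nM
            blank_cols[phase] = blanks
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("process", str(exc)) from exc

    # ---- differential ---------------------------------------------------
    stats_cfg = cfg["stats"]
    report_diffs: dict = {}
    class_totals: dict = {}
    recovery: dict = {}
    try:
        cell_df = pd.DataFrame([vars(c) for c in cells])
        for phase in design.phases:
            nM = tables_nM[phase]
            blanks = blank_cols[phase]
            axenic_cols = [
                design.sample_id(AXENIC, phase, r)
                for r in range(1, design.n_replicates + 1)
            ]
            prod = call_production(
                subset_columns(nM, axenic_cols),
                subset_columns(nM, blanks),
                alpha=stats_cfg["alpha"],
                q_max=stats_cfg["q_max"],
            )
            produced = prod.index[prod["produced"]].tolist()
            report_diffs[phase] = {"n_signals_produced": len(produced)}

            # class totals of per-cell production (axenic, blank-corrected)
            records = records_by_phase[phase]
            known = {r.signal_label: r for r in records}
            density = design.diatom_density[phase]
            percell = {
                lbl: float(
                    (prod.loc[lbl, "mean_culture"] - prod.loc[lbl, "mean_blank"])
                    * 1e-9 * 1e15 / (density * 1e3)
                )
                for lbl in produced
            }
            classed = {l: v for l, v in percell.items() if l in known}
            for lbl in set(percell) - set(classed):
                known[lbl] = CompoundRecord(signal_label=lbl, formula=None)
                classed[lbl] = percell[lbl]
            agg = aggregate_by_class(classed, known.values())
            class_totals[phase] = {
                k: {"total_fmol_per_cell": float(agg.loc[k, "total"]),
                    "fraction": float(agg.loc[k, "fraction"])}
                for k in agg.index
            }

            # depletion per coculture, restricted to the produced set
            dep_counts = {}
            dep_profiles = {}
            called_sets: dict[str, set] = {}
            produced_nM = nM.with_rows(nM.data.loc[produced])
            for coc in design.cocultures:
                coc_cols = [
                    design.sample_id(coc, phase, r)
                    for r in range(1, design.n_replicates + 1)
                ]
                mask = (cell_df["treatment"] == coc) & (cell_df["phase"] == phase)
                eff = (
                    cell_df.loc[mask, "free_bacteria_density"]
                    + cell_df.loc[mask, "attached_per_diatom"]
                    * cell_df.loc[mask, "diatom_density"]
                ).mean()
                results = call_depletion(
                    subset_columns(produced_nM, axenic_cols),
                    subset_columns(produced_nM, coc_cols),
                    bacteria_density=float(eff),
                    alpha=stats_cfg["alpha"],
                    q_max=stats_cfg["q_max"],
                )
                sig = [r for r in results if r.significant]
                called_sets[coc] = {r.signal_label for r in sig}
                dep_counts[coc] = {
                    "n_signals_depleted": len(sig),
                    "total_percell_depletion_fmol": float(
                        sum(r.percell_depletion for r in sig)
                    ),
                }
                # per-sample cell-normalized depletion profile (fmol per
                # bacterial cell) for the multivariate contrast
                ax_mean = subset_columns(produced_nM, axenic_cols).data.mean(axis=1)
                dep_profiles[coc] = (
                    (ax_mean.values[:, None]
                     - subset_columns(produced_nM, coc_cols).data.values)
                    * 1e-9 * 1e15 / (float(eff) * 1e3)
                )
            report_diffs[phase]["depletion"] = dep_counts

            # PERMANOVA across coculture depletion profiles
            if len(design.cocultures) >= 2:
                mat = np.vstack(
                    [dep_profiles[c].T for c in design.cocultures]
                )
                groups = np.concatenate(
                    [[c] * design.n_replicates for c in design.cocultures]
                )
                pres = permanova(
                    mat, groups, n_permutations=stats_cfg["permutations"],
                    seed=seeds["permanova"],
                )
                report_diffs[phase]["permanova"] = {
                    "pseudo_F": pres.statistic, "p": pres.p,
                    "n_permutations": pres.n_permutations,
                }

            # recovery against planted truth
            _, mapping = match_library_rows(nM, library)
            true_prod = {
                mapping[l] for l in truth.true_produced_set[phase] if l in mapping
            }
            tp = len(set(produced) & true_prod)
            recovery.setdefault(phase, {})["production"] = {
                "n_true": len(true_prod),
                "recall": tp / len(true_prod) if true_prod else 1.0,
                "false_discovery_rate": (
                    (len(produced) - tp) / len(produced) if produced else 0.0
                ),
            }
            dep_rec = {}
            for coc in design.cocultures:
                true_dep = {
                    mapping[l]
                    for l in truth.true_depleted_set.get((coc, phase), set())
                    if l in mapping
                }
                called = called_sets[coc]
                tp_d = len(called & true_dep)
                dep_rec[coc] = {
                    "n_true": len(true_dep),
                    "sensitivity": tp_d / len(true_dep) if true_dep else 1.0,
                    "false_discovery_rate": (
                        (len(called) - tp_d) / len(called) if called else 0.0
                    ),
                }
            recovery[phase]["depletion"] = dep_rec
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("diffs", str(exc)) from exc

    # ---- GCP -------------------------------------------------------------
    try:
        gcp_cfg = cfg["gcp"]
        gcp_samples = simulate_gcp_dataset(
            design, gcp_cfg["stimulation"], seed=seeds["gcp"],
            base_gcp=gcp_cfg["base_gcp"], cv=gcp_cfg["cv"],
        )
        rates = pd.DataFrame(
            {
                "treatment": [s.treatment for s in gcp_samples],
                "rate": [compute_gcp(s) for s in gcp_samples],
            }
        )
        control = rates.loc[rates["treatment"] == AXENIC, "rate"].values
        gcp_report = {}
        for treatment in rates["treatment"].unique():
            if treatment == AXENIC:
                continue
            tr = rates.loc[rates["treatment"] == treatment, "rate"].values
            pct, p = stimulation(tr, control)
            gcp_report[treatment] = {"stimulation_pct": pct, "p": p}
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("gcp", str(exc)) from exc

    report = {
        "version": __version__,
        "seed": cfg["seed"],
        "n_compounds": len(library),
        "n_signals_raw": n_signals_raw,
        "contrasts": report_diffs,
        "class_totals": class_totals,
        "gcp": gcp_report,
        "recovery": recovery,
        "config_hash": config_hash(cfg),
    }
    report["report_hash"] = config_hash(report)

    if outdir is not None:
        for phase, table in tables_nM.items():
            table.to_csv(outdir / f"signals_nM_{phase}.csv")
        conc.to_csv(outdir / "true_concentrations_nM.csv")
        pd.DataFrame([vars(c) for c in cells]).to_csv(
            outdir / "cell_counts.csv", index=False
        )
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
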