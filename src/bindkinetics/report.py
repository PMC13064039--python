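"""Full-study orchestration: run every analysis over a directory of inputs
and emit one structured report.

The YAML config lists inputs per analysis block; blocks that are absent are
skipped with a warning, and a block whose inputs cannot be read records a
per-block failure without aborting the run. Numeric values are serialized at
full precision with display-rounded companions for the human-readable
tables. The report is deterministic for identical inputs apart from its
timestamp field.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import warnings
from typing import Any

import yaml

from . import __version__
from .binding import BindingFit, fit_double_log, interpret_stoichiometry
from .competition import ConditionFit, assign_site, metal_modulation
from .core_spectra import AnalysisError, correct_series, read_spectra_csv, read_titration_csv
from .modality import (
    SynchronousSeries,
    amide_band_shift,
    corroborate_mechanism,
    synchronous_shift,
    uv_titration_features,
)
from .quenching import classify_mechanism, fit_stern_volmer
from .thermo import thermo_pipeline

__all__ = ["run_report", "render_summary"]

SCHEMA_VERSION = "1"


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _disp(x: float, sig: int = 3) -> str:
    return f"{x:.{sig}g}"


def _load_series(path, correct: bool = True):
    series = read_titration_csv(path)
    if correct and all(p.has_absorbances for p in series.points):
        series = correct_series(series)
    return series


def _quench_block(cfg: dict, hashes: dict) -> dict:
    tau0 = float(cfg.get("tau0", 1e-8))
    kq_limit = float(cfg.get("kq_limit", 2e10))
    fits = []
    for path in cfg["series"]:
        hashes[str(path)] = _sha256(path)
        fits.append(fit_stern_volmer(_load_series(path, cfg.get("correct_ife", True)), tau0=tau0))
    call = classify_mechanism(fits, kq_limit=kq_limit)
    return {
        "fits": [
            {
                "temperature_K": f.temperature,
                "ksv": f.ksv,
                "kq": f.kq,
                "r_squared": f.r_squared,
                "slope_se": f.slope_se,
                "display": {"ksv": _disp(f.ksv), "kq": _disp(f.kq), "r_squared": f"{f.r_squared:.4f}"},
            }
            for f in sorted(fits, key=lambda f: f.temperature)
        ],
        "mechanism": dataclasses.asdict(call),
    }


def _binding_fits(paths, hashes: dict, correct: bool = True) -> list[BindingFit]:
    fits = []
    for path in paths:
        hashes[str(path)] = _sha256(path)
        fits.append(fit_double_log(_load_series(path, correct)))
    return sorted(fits, key=lambda f: f.temperature)


def _binding_block(fits: list[BindingFit]) -> dict:
    rows = []
    for f in fits:
        stoich = interpret_stoichiometry(f)
        rows.append(
            {
                "temperature_K": f.temperature,
                "log_kb": f.log_kb,
                "kb": f.kb,
                "n_sites": f.n_sites,
                "r_squared": f.r_squared,
                "slope_se": f.slope_se,
                "excluded_points": [list(e) for e in f.excluded_points],
                "stoichiometry": stoich.ratio,
                "affinity": stoich.affinity,
                "display": {
                    "log_kb": f"{f.log_kb:.2f}",
                    "kb": _disp(f.kb),
                    "n": f"{f.n_sites:.2f}",
                    "r_squared": f"{f.r_squared:.4f}",
                },
            }
        )
    return {"fits": rows}


def _thermo_block(fits: list[BindingFit], cfg: Any) -> dict:
    h_tol = 4.0
    if isinstance(cfg, dict):
        h_tol = float(cfg.get("h_tol", 4.0))
    res = thermo_pipeline(fits, h_tol=h_tol)
    return {
        "delta_h_kJ_mol": res.delta_h,
        "delta_s_kJ_mol_K": res.delta_s,
        "delta_g_kJ_mol_by_T": {str(t): g for t, g in res.delta_g_by_T.items()},
        "r_squared": res.r_squared,
        "force_class": res.force_class,
        "endothermic": res.endothermic,
        "spontaneous_at_K": list(res.spontaneous_at),
        "two_point": res.two_point,
        "display": {
            "delta_h": f"{res.delta_h:.3f}",
            "delta_s": f"{res.delta_s:.3f}",
            "delta_g": {str(t): f"{g:.3f}" for t, g in res.delta_g_by_T.items()},
        },
    }


def _modality_block(cfg: dict, hashes: dict, mechanism_call) -> dict:
    out: dict[str, Any] = {}

    def _sync(key, delta_lambda):
        if key not in cfg:
            return None
        hashes[str(cfg[key])] = _sha256(cfg[key])
        spectra = read_spectra_csv(cfg[key])
        concs = [s.meta if isinstance(s.meta, float) else float(i) for i, s in enumerate(spectra)]
        series = SynchronousSeries(delta_lambda=delta_lambda, spectra=spectra, quencher_concs=concs)
        rep = synchronous_shift(series)
        return {
            "residue": rep.residue,
            "shift": rep.shift,
            "direction": rep.direction,
            "interpretation": rep.interpretation,
        }

    if (s60 := _sync("sync60", 60.0)) is not None:
        out["synchronous_60"] = s60
    if (s15 := _sync("sync15", 15.0)) is not None:
        out["synchronous_15"] = s15

    if "ftir_free" in cfg and "ftir_complex" in cfg:
        hashes[str(cfg["ftir_free"])] = _sha256(cfg["ftir_free"])
        hashes[str(cfg["ftir_complex"])] = _sha256(cfg["ftir_complex"])
        free = read_spectra_csv(cfg["ftir_free"])[0]
        complexed = read_spectra_csv(cfg["ftir_complex"])[0]
        out["ftir"] = [
            {
                "band": r.residue,
                "shift": r.shift,
                "direction": r.direction,
                "interpretation": r.interpretation,
            }
            for r in amide_band_shift(free, complexed)
        ]

    if "uv" in cfg:
        hashes[str(cfg["uv"])] = _sha256(cfg["uv"])
        spectra = read_spectra_csv(cfg["uv"])
        protein_conc = float(cfg.get("protein_conc_uM", 2.0)) * 1e-6
        feats = uv_titration_features(spectra, protein_conc, float(cfg.get("path_cm", 1.0)))
        out["uv"] = {
            "position_trend_220": feats.position_trend_220.direction,
            "shift_220_nm": feats.position_trend_220.shift,
            "intensity_change_220": feats.intensity_change_220,
            "epsilon_279_M_cm": feats.epsilon_279,
            "spectra_changed": feats.spectra_changed,
        }
        if mechanism_call is not None:
            out["uv"]["mechanism_corroboration"] = corroborate_mechanism(feats, mechanism_call)
    return out


def _condition_fits(cfg: dict, hashes: dict, role_key: str) -> list[ConditionFit]:
    fits = [
        ConditionFit(
            condition="blank",
            site_role="blank",
            fit=fit_double_log(_load_series(cfg["blank"])),
        )
    ]
    hashes[str(cfg["blank"])] = _sha256(cfg["blank"])
    for entry in cfg[role_key]:
        hashes[str(entry["path"])] = _sha256(entry["path"])
        fits.append(
            ConditionFit(
                condition=entry["name"],
                site_role=entry.get("role", "metal"),
                fit=fit_double_log(_load_series(entry["path"])),
            )
        )
    return fits


def run_report(config_path) -> dict:
    """Run every configured analysis block and assemble the study report."""
    with open(config_path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not cfg:
        raise AnalysisError("empty config")

    hashes: dict[str, str] = {}
    report: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "provenance": {
            "software": f"bindkinetics {__version__}",
            "config": cfg,
            "input_sha256": hashes,
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        },
        "warnings": [],
        "failures": {},
    }

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        mechanism_call = None
        if "quenching" in cfg:
            try:
                block = _quench_block(cfg["quenching"], hashes)
                report["quenching"] = block
                from .quenching import MechanismCall

                mechanism_call = MechanismCall(**block["mechanism"])
            except Exception as exc:  # per-block failure, run continues
                report["failures"]["quenching"] = str(exc)
        else:
            report["warnings"].append("quenching block absent; skipped")

        binding_fits: list[BindingFit] = []
        if "binding" in cfg:
            try:
                binding_fits = _binding_fits(
                    cfg["binding"]["series"], hashes, cfg["binding"].get("correct_ife", True)
                )
                report["binding"] = _binding_block(binding_fits)
            except Exception as exc:
                report["failures"]["binding"] = str(exc)
        else:
            report["warnings"].append("binding block absent; skipped")

        if cfg.get("thermo"):
            try:
                if len(binding_fits) < 2:
                    raise AnalysisError(">= 2 temperatures required")
                report["thermo"] = _thermo_block(binding_fits, cfg.get("thermo"))
            except Exception as exc:
                report["failures"]["thermo"] = str(exc)

        if "modality" in cfg:
            try:
                report["modality"] = _modality_block(cfg["modality"], hashes, mechanism_call)
            except Exception as exc:
                report["failures"]["modality"] = str(exc)

        if "sites" in cfg:
            try:
                fits = _condition_fits(cfg["sites"], hashes, "probes")
                call = assign_site(fits, threshold=float(cfg["sites"].get("threshold", 0.2)))
                report["sites"] = {
                    "assigned_site": call.assigned_site,
                    "delta_log_kb": call.delta_log_kb_by_condition,
                    "threshold": call.threshold,
                }
            except Exception as exc:
                report["failures"]["sites"] = str(exc)

        if "metals" in cfg:
            try:
                fits = _condition_fits(cfg["metals"], hashes, "metals")
                rep = metal_modulation(fits, threshold=float(cfg["metals"].get("threshold", 0.15)))
                report["metals"] = {
                    "blank_log_kb": rep.blank_log_kb,
                    "threshold": rep.threshold,
                    "effects": [dataclasses.asdict(e) for e in rep.effects],
                }
            except Exception as exc:
                report["failures"]["metals"] = str(exc)

        report["warnings"].extend(str(w.message) for w in caught)

    return report


def render_summary(report: dict) -> str:
    """Assemble the human-readable conclusion sentences from the report."""
    lines = ["# Binding study summary", ""]
    if "quenching" in report:
        mech = report["quenching"]["mechanism"]
        lines.append(
            f"- Quenching mechanism: **{mech['mechanism']}** "
            f"(K_SV trend {mech['ksv_trend']}; K_q above diffusion limit: "
            f"{mech['kq_exceeds_limit']})."
        )
        for f in report["quenching"]["fits"]:
            d = f["display"]
            lines.append(
                f"  - T = {f['temperature_K']:g} K: K_SV = {d['ksv']} L/mol, "
                f"K_q = {d['kq']} L/mol/s, R² = {d['r_squared']}"
            )
    if "binding" in report:
        for f in report["binding"]["fits"]:
            d = f["display"]
            lines.append(
                f"- Binding at {f['temperature_K']:g} K: log K_b = {d['log_kb']}, "
                f"n = {d['n']} → stoichiometry {f['stoichiometry']}, "
                f"{f['affinity']} affinity."
            )
    if "thermo" in report:
        t = report["thermo"]
        d = t["display"]
        spont = ", ".join(f"{v:g} K" for v in t["spontaneous_at_K"])
        lines.append(
            f"- Thermodynamics: ΔH = {d['delta_h']} kJ/mol, ΔS = {d['delta_s']} "
            f"kJ/mol/K → dominant force **{t['force_class']}**; "
            f"{'endothermic' if t['endothermic'] else 'exothermic'}; "
            f"spontaneous (ΔG < 0) at {spont or 'no studied temperature'}."
        )
    if "modality" in report:
        m = report["modality"]
        for key in ("synchronous_60", "synchronous_15"):
            if key in m:
                lines.append(f"- Synchronous Δλ={key.split('_')[1]}: {m[key]['interpretation']}.")
        if "ftir" in m:
            for band in m["ftir"]:
                lines.append(
                    f"- FTIR {band['band']}: shift {band['shift']:+.1f} cm⁻¹ "
                    f"({band['interpretation']})."
                )
        if "uv" in m:
            uv = m["uv"]
            lines.append(
                f"- UV-vis: 220 nm band {uv['position_trend_220']} shift, "
                f"ε(279 nm) = {uv['epsilon_279_M_cm']:.3g} M⁻¹cm⁻¹"
                + (
                    f"; {uv['mechanism_corroboration']} with the quenching mechanism."
                    if "mechanism_corroboration" in uv
                    else "."
                )
            )
    if "sites" in report:
        lines.append(f"- Site-marker competition assigns binding to **{report['sites']['assigned_site']}**.")
    if "metals" in report:
        for e in report["metals"]["effects"]:
            lines.append(
                f"- Metal {e['condition']}: K_b ratio {e['ratio']:.3g} → {e['label']}."
            )
    if report.get("failures"):
        lines.append("")
        lines.append("Failures: " + "; ".join(f"{k}: {v}" for k, v in report["failures"].items()))
    return "\n".join(lines) + "\n"


def write_report(report: dict, out_path, summary_path=None) -> None:
    with open(out_path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=False)
        fh.write("\n")
    if summary_path is not None:
        with open(summary_path, "w", encoding="utf-8") as fh:
            fh.write(render_summary(report))
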