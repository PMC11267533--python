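"""Residue-level structure mapping and the end-to-end pipeline driver.

``map_to_structure`` tabulates per-residue CSPs with their annotation
categories and top-shifter flags, and can paint CSPs onto a PDB file by
rewriting only the temperature-factor column of ATOM records
(B = CSP x 1000, capped at 999.99; unmapped residues set to 0) — the
output differs from the input in columns 61-66 only.

``run_pipeline`` orchestrates the screening workflow from a config
mapping (or YAML file): simulate / screen / deconvolute / titrate modes,
each writing CSV/JSON reports plus a run log (config hash, seed,
version, per-stage counts) to an output directory.  Identical config and
seed reproduce identical result files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__ as _version
from .binding import (
    DEFAULT_KD_CUTOFF,
    DEFAULT_LOCALITY_FRACTION,
    DEFAULT_R2_CUTOFF,
    FragmentClass,
    classify_fragment,
    fit_global,
)
from .csp import ALPHA_N, CSPProfile, compute_csp, select_top_shifters, TopShifterSet
from .peaklists import (
    InterfaceAnnotation,
    build_titration_series,
    read_annotation,
    read_peaklist,
)
from .screening import (
    DEFAULT_CSP_THRESHOLD,
    DEFAULT_MIN_COUNT,
    Priority,
    call_hit_deconvolution,
    count_above_threshold,
    summarize_screen,
    triage_mixture,
)
from .synthetic import SimulationConfig, simulate_screen

__all__ = ["ResidueMapRecord", "map_to_structure", "annotate_pdb", "run_pipeline"]

logger = logging.getLogger(__name__)

_BFACTOR_CAP = 999.99
_DEFAULT_ADVANCE_TIERS = ("high", "medium")


@dataclass(frozen=True)
class ResidueMapRecord:
    residue: int
    csp: float  # ppm
    category: str
    shifter_flag: bool


def map_to_structure(
    profile: CSPProfile,
    shifters: TopShifterSet,
    annotation: InterfaceAnnotation,
    structure: str | Path | None = None,
    out_structure: str | Path | None = None,
    numbering_offset: int = 0,
) -> pd.DataFrame:
    """Tabulate per-residue CSPs with categories and top-shifter flags.

    If a PDB path is supplied, a copy annotated in the B-factor column is
    written to ``out_structure`` (default: alongside with ``_csp`` suffix).
    ``numbering_offset`` is added to profile residue numbers to match the
    PDB numbering.
    """
    if not profile.values:
        raise ValueError("empty CSP profile")
    records = [
        ResidueMapRecord(
            residue=res,
            csp=profile.values[res],
            category=annotation.category(res),
            shifter_flag=res in shifters.residues,
        )
        for res in sorted(profile.values)
    ]
    table = pd.DataFrame([r.__dict__ for r in records]).set_index("residue")
    if structure is not None:
        if out_structure is None:
            structure = Path(structure)
            out_structure = structure.with_name(structure.stem + "_csp" + structure.suffix)
        annotate_pdb(profile, structure, out_structure, numbering_offset=numbering_offset)
    return table


def annotate_pdb(
    profile: CSPProfile,
    pdb_in: str | Path,
    pdb_out: str | Path,
    numbering_offset: int = 0,
) -> Path:
    """Rewrite ATOM temperature factors as CSP x 1000 (fixed-width, cols 61-66).

    Residues without a CSP get 0.00; profile residues never found in the
    PDB are reported with a warning, not an error.
    """
    csp_by_pdb_res = {res + numbering_offset: v for res, v in profile.values.items()}
    seen: set[int] = set()
    out_lines = []
    for line in Path(pdb_in).read_text().splitlines(keepends=True):
        if line.startswith(("ATOM  ", "HETATM")) and len(line) >= 66:
            try:
                resseq = int(line[22:26])
            except ValueError:
                out_lines.append(line)
                continue
            seen.add(resseq)
            b = min(csp_by_pdb_res.get(resseq, 0.0) * 1000.0, _BFACTOR_CAP)
            line = line[:60] + f"{b:6.2f}" + line[66:]
        out_lines.append(line)
    unmatched = sorted(set(csp_by_pdb_res) - seen)
    if unmatched:
        logger.warning(
            "%d profile residues not found in %s: %s", len(unmatched), pdb_in, unmatched
        )
    Path(pdb_out).write_text("".join(out_lines))
    return Path(pdb_out)


# ---------------------------------------------------------------------------
# pipeline driver


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config) -> dict:
    """Run one pipeline mode from a config mapping or YAML file path.

    ``config['mode']`` selects the stage set: ``simulate`` (synthetic
    end-to-end screen), ``screen`` (triage measured mixture spectra),
    ``deconvolute`` (single-fragment hit calls), or ``titrate`` (CSP +
    global Kd fit for one fragment).  Returns the summary dict written to
    ``<outdir>/summary.json``.
    """
    cfg = _load_config(config)
    mode = cfg.get("mode")
    if mode not in ("simulate", "screen", "deconvolute", "titrate"):
        raise ValueError(
            f"config must set mode to one of simulate/screen/deconvolute/titrate, got {mode!r}"
        )
    outdir = Path(cfg.get("outdir", "cspscreen_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    summary = {"mode": mode}
    stage_counts: dict[str, int] = {}
    if mode == "simulate":
        summary.update(_run_simulate(cfg, outdir, stage_counts))
    elif mode == "screen":
        summary.update(_run_screen(cfg, outdir, stage_counts))
    elif mode == "deconvolute":
        summary.update(_run_deconvolute(cfg, outdir, stage_counts))
    else:
        summary.update(_run_titrate(cfg, outdir, stage_counts))
    run_log = {
        "config_hash": _config_hash(cfg),
        "seed": cfg.get("seed"),
        "version": _version,
        "stage_counts": stage_counts,
    }
    _write_json(summary, outdir / "summary.json")
    _write_json(run_log, outdir / "run_log.json")
    return summary


def _common(cfg):
    return {
        "alpha": float(cfg.get("alpha", ALPHA_N)),
        "csp_threshold": float(cfg.get("csp_threshold", DEFAULT_CSP_THRESHOLD)),
        "min_count": int(cfg.get("min_count", DEFAULT_MIN_COUNT)),
        "k_sigma": float(cfg.get("k_sigma", 1.0)),
        "r2_cutoff": float(cfg.get("r2_cutoff", DEFAULT_R2_CUTOFF)),
        "kd_cutoff": float(cfg.get("kd_cutoff", DEFAULT_KD_CUTOFF)),
        "locality_fraction": float(cfg.get("locality_fraction", DEFAULT_LOCALITY_FRACTION)),
        "advance_tiers": tuple(cfg.get("advance_tiers", _DEFAULT_ADVANCE_TIERS)),
    }


def _run_simulate(cfg: dict, outdir: Path, counts: dict) -> dict:
    """Synthetic screen end-to-end: simulate -> triage -> deconvolute -> titrate."""
    opts = _common(cfg)
    sim_cfg = dict(cfg.get("simulate", {}))
    library_size = int(sim_cfg.pop("library_size", 200))
    n_binders = int(sim_cfg.pop("n_binders", 3))
    mixture_size = int(sim_cfg.pop("mixture_size", 10))
    base = SimulationConfig(seed=int(cfg.get("seed", 0)), **_sim_kwargs(sim_cfg))
    sim = simulate_screen(library_size, n_binders, mixture_size, base)
    counts["fragments_simulated"] = library_size
    counts["mixtures"] = len(sim.mixtures)

    # triage
    mixture_rows = []
    for mix in sim.mixtures:
        mix.priority = triage_mixture(mix.profile, sim.annotation, opts["csp_threshold"])
        interest = sim.annotation.membrane_interface | sim.annotation.observable_functional
        mixture_rows.append(
            {
                "mixture_id": mix.mixture_id,
                "fragment_ids": ";".join(mix.fragment_ids),
                "priority": mix.priority.value,
                "n_above_threshold": count_above_threshold(
                    mix.profile, interest, opts["csp_threshold"]
                ),
            }
        )
    pd.DataFrame(mixture_rows).to_csv(outdir / "mixtures.csv", index=False)
    advanced = [
        m for m in sim.mixtures if m.priority.value in opts["advance_tiers"]
    ]
    counts["mixtures_flagged"] = sum(1 for m in sim.mixtures if m.priority != Priority.NONE)
    counts["mixtures_advanced"] = len(advanced)

    # deconvolution: retest every member of an advanced mixture singly
    deconv_rows, deconvoluted = [], []
    for mix in advanced:
        for fid in mix.fragment_ids:
            profile = sim.deconvolution_profile(fid)
            is_hit = call_hit_deconvolution(
                profile, sim.annotation, opts["min_count"], opts["csp_threshold"]
            )
            deconv_rows.append(
                {
                    "mixture_id": mix.mixture_id,
                    "fragment_id": fid,
                    "n_above_threshold": count_above_threshold(
                        profile, sim.annotation.observable_functional, opts["csp_threshold"]
                    ),
                    "hit": is_hit,
                }
            )
            if is_hit:
                deconvoluted.append(fid)
    pd.DataFrame(deconv_rows).to_csv(outdir / "deconvolution.csv", index=False)
    counts["fragments_deconvoluted"] = len(deconv_rows)
    counts["deconvolution_hits"] = len(deconvoluted)

    # titration of every deconvolution hit
    fit_rows, validated = [], []
    for fid in deconvoluted:
        series = sim.titration_for(fid)
        top = max(series.points, key=lambda p: p.ligand_conc)
        profile = compute_csp(series.reference, top, alpha=opts["alpha"])
        shifters = select_top_shifters(profile, k_sigma=opts["k_sigma"])
        result = fit_global(
            series, set(shifters.residues), r2_cutoff=opts["r2_cutoff"], alpha=opts["alpha"]
        )
        klass = classify_fragment(
            result,
            profile,
            sim.annotation,
            kd_cutoff=opts["kd_cutoff"],
            locality_fraction=opts["locality_fraction"],
            k_sigma=opts["k_sigma"],
        )
        if klass is FragmentClass.HIT:
            validated.append(fid)
        fit_rows.append(
            {
                "fragment_id": fid,
                "kd_uM": result.kd,
                "kd_stderr_uM": result.kd_stderr,
                "n_residues_used": len(result.residues_used),
                "classification": klass.value,
            }
        )
    pd.DataFrame(
        fit_rows,
        columns=["fragment_id", "kd_uM", "kd_stderr_uM", "n_residues_used", "classification"],
    ).to_csv(outdir / "fits.csv", index=False)
    counts["validated_hits"] = len(validated)

    # truth table for comparison against the planted ground truth
    pd.DataFrame(
        [
            {
                "fragment_id": t.fragment_id,
                "scenario": t.scenario,
                "true_kd_uM": t.true_kd,
                "responsive_residues": ";".join(map(str, sorted(t.responsive_residues))),
            }
            for t in sim.truth.values()
        ]
    ).to_csv(outdir / "truth.csv", index=False)

    screen_summary = summarize_screen(
        library_size,
        sim.mixtures,
        deconvoluted=deconvoluted,
        validated_hits=validated,
    )
    return {
        "library_size": library_size,
        "n_mixtures": screen_summary.n_mixtures,
        "n_flagged": screen_summary.n_flagged,
        "n_deconvoluted": screen_summary.n_deconvoluted,
        "n_validated_hits": screen_summary.n_validated_hits,
        "hit_rate_percent": screen_summary.hit_rate_percent,
        "validated_hits": sorted(validated),
        "kd_uM": {row["fragment_id"]: row["kd_uM"] for row in fit_rows},
        "planted_binders": sorted(sim.planted_binders),
    }


_SIM_KEYS = (
    "n_residues",
    "protein_conc",
    "true_kd",
    "dmax_range",
    "noise_h",
    "noise_n",
    "ligand_concs",
    "scenario",
    "alpha",
)


def _sim_kwargs(sim_cfg: dict) -> dict:
    out = {}
    for key in _SIM_KEYS:
        if key in sim_cfg:
            val = sim_cfg[key]
            if key in ("dmax_range", "ligand_concs"):
                val = tuple(val)
            out[key] = val
    if "responsive_residues" in sim_cfg:
        out["responsive_residues"] = set(sim_cfg["responsive_residues"])
    if "functional_residues" in sim_cfg:
        out["functional_residues"] = set(sim_cfg["functional_residues"])
    return out


def _read_listed_peaklist(entry: dict, protein_conc: float, alpha: float):
    return read_peaklist(
        entry["path"],
        condition_label=entry.get("label", ""),
        ligand_conc=float(entry.get("ligand_conc", 0.0)),
        protein_conc=protein_conc,
        environment=entry.get("environment", "mmRM"),
    )


def _run_screen(cfg: dict, outdir: Path, counts: dict) -> dict:
    """Triage measured mixture spectra against a shared reference."""
    opts = _common(cfg)
    sc = cfg["screen"]
    annotation = read_annotation(sc["annotation"])
    protein_conc = float(sc.get("protein_conc", 100.0))
    shared_reference = read_peaklist(sc["reference"], protein_conc=protein_conc)
    rows = []
    for entry in sc["mixtures"]:
        reference = (
            read_peaklist(entry["reference"], protein_conc=protein_conc)
            if "reference" in entry
            else shared_reference
        )
        observed = _read_listed_peaklist(entry, protein_conc, opts["alpha"])
        profile = compute_csp(reference, observed, alpha=opts["alpha"])
        priority = triage_mixture(profile, annotation, opts["csp_threshold"])
        interest = annotation.membrane_interface | annotation.observable_functional
        rows.append(
            {
                "mixture_id": entry["mixture_id"],
                "priority": priority.value,
                "n_above_threshold": count_above_threshold(
                    profile, interest, opts["csp_threshold"]
                ),
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "mixtures.csv", index=False)
    counts["mixtures"] = len(rows)
    counts["mixtures_flagged"] = int((table["priority"] != "none").sum())
    return {
        "n_mixtures": len(rows),
        "n_flagged": counts["mixtures_flagged"],
        "priorities": {r["mixture_id"]: r["priority"] for r in rows},
    }


def _run_deconvolute(cfg: dict, outdir: Path, counts: dict) -> dict:
    """Single-fragment hit calls from measured spectra."""
    opts = _common(cfg)
    dc = cfg["deconvolute"]
    annotation = read_annotation(dc["annotation"])
    protein_conc = float(dc.get("protein_conc", 100.0))
    shared_reference = read_peaklist(dc["reference"], protein_conc=protein_conc)
    rows = []
    for entry in dc["fragments"]:
        reference = (
            read_peaklist(entry["reference"], protein_conc=protein_conc)
            if "reference" in entry
            else shared_reference
        )
        observed = _read_listed_peaklist(entry, protein_conc, opts["alpha"])
        profile = compute_csp(reference, observed, alpha=opts["alpha"])
        rows.append(
            {
                "fragment_id": entry["fragment_id"],
                "n_above_threshold": count_above_threshold(
                    profile, annotation.observable_functional, opts["csp_threshold"]
                ),
                "hit": call_hit_deconvolution(
                    profile, annotation, opts["min_count"], opts["csp_threshold"]
                ),
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "deconvolution.csv", index=False)
    counts["fragments_deconvoluted"] = len(rows)
    counts["deconvolution_hits"] = int(table["hit"].sum())
    return {
        "n_fragments": len(rows),
        "hits": sorted(r["fragment_id"] for r in rows if r["hit"]),
    }


def _run_titrate(cfg: dict, outdir: Path, counts: dict) -> dict:
    """CSP profile, top shifters, global Kd fit and class for one fragment."""
    opts = _common(cfg)
    tc = cfg["titrate"]
    annotation = read_annotation(tc["annotation"])
    protein_conc = float(tc.get("protein_conc", 100.0))
    lists = [_read_listed_peaklist(e, protein_conc, opts["alpha"]) for e in tc["peaklists"]]
    series = build_titration_series(lists, tc.get("fragment_id", "fragment"))
    top_point = max(series.points, key=lambda p: p.ligand_conc)
    profile = compute_csp(series.reference, top_point, alpha=opts["alpha"])
    profile.to_csv(outdir / "csp_profile.csv")
    shifters = select_top_shifters(profile, k_sigma=opts["k_sigma"])
    result = fit_global(
        series, set(shifters.residues), r2_cutoff=opts["r2_cutoff"], alpha=opts["alpha"]
    )
    klass = classify_fragment(
        result,
        profile,
        annotation,
        kd_cutoff=opts["kd_cutoff"],
        locality_fraction=opts["locality_fraction"],
        k_sigma=opts["k_sigma"],
    )
    pd.DataFrame(
        [
            {
                "fragment_id": series.fragment_id,
                "kd_uM": result.kd,
                "kd_stderr_uM": result.kd_stderr,
                "n_residues_used": len(result.residues_used),
                "classification": klass.value,
            }
        ]
    ).to_csv(outdir / "fits.csv", index=False)
    counts["titration_points"] = len(series.points)
    counts["top_shifters"] = len(shifters.residues)
    counts["residues_used"] = len(result.residues_used)
    if tc.get("structure"):
        map_to_structure(
            profile,
            shifters,
            annotation,
            structure=tc["structure"],
            out_structure=outdir / "structure_csp.pdb",
            numbering_offset=int(tc.get("numbering_offset", 0)),
        ).to_csv(outdir / "residue_map.csv")
    return {
        "fragment_id": series.fragment_id,
        "kd_uM": result.kd,
        "kd_stderr_uM": result.kd_stderr,
        "top_shifters": sorted(shifters.residues),
        "residues_used": sorted(result.residues_used),
        "residues_rejected": {str(k): v for k, v in result.residues_rejected.items()},
        "classification": klass.value,
    }
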