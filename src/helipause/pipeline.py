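"""End-to-end pipeline with provenance and stage caching.

A run configuration (dict, usually loaded from YAML) drives
synth -> simulate -> stepfind -> analyze.  Every stage writes its outputs
under the run directory together with a manifest recording the
configuration hash and seed; a stage whose manifest hash already matches is
skipped on re-run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import io as hio
from .substrates import make_hairpin, make_mismatch_variant
from .simulator import (
    MeasurementConfig,
    SimulationConfig,
    calibrate_prefactor,
    generate_trace_set,
)
from .thermo import IonicConditions, compute_bp_energies, stability_profile, fit_gaussian_peaks
from . import stepfind
from . import pause_analysis as pa

log = logging.getLogger("helipause")

__all__ = ["run_pipeline", "config_hash", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "substrate": {"length": 174, "background_gc": 0.35},
    "conditions": {"na_mM": 50.0, "mg_mM": 5.0, "temperature_C": 25.0},
    "simulate": {"model": "delayed", "n": 5, "target_mean_rate": 46.0, "n_traces": 20},
    "measure": {"noise_sigma_nm": 14.0, "sampling_hz": 200.0, "force_pN": 8.0},
    "stepfind": {"algo": "ttest", "noisy": True},
    "analyze": {"pause_threshold_s": 0.14},
}


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _stage_cached(outdir: Path, stage: str, h: str) -> bool:
    mf = outdir / f"{stage}.manifest.json"
    if mf.exists():
        return json.loads(mf.read_text()).get("hash") == h
    return False


def _write_manifest(outdir: Path, stage: str, h: str, extra: dict | None = None) -> None:
    (outdir / f"{stage}.manifest.json").write_text(
        json.dumps({"stage": stage, "hash": h, **(extra or {})}, indent=1)
    )


def run_pipeline(config: dict, outdir) -> dict:
    """Execute the configured pipeline; returns a result-bundle dict.

    Stage failures raise with a stage-tagged message.  Re-running with an
    identical configuration reuses cached stage outputs.
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = config_hash(cfg)
    seed = int(cfg["seed"])
    results: dict = {"config_hash": h, "seed": seed}

    try:  # ---- synth
        fasta = outdir / "substrates.fasta"
        if not (_stage_cached(outdir, "synth", h) and fasta.exists()):
            sub_cfg = cfg["substrate"]
            sub = make_hairpin(
                length=int(sub_cfg.get("length", 174)),
                background_gc=float(sub_cfg.get("background_gc", 0.35)),
                seed=seed,
            )
            if sub_cfg.get("mismatches"):
                sub = make_mismatch_variant(sub, list(sub_cfg["mismatches"]))
            hio.write_fasta([sub], fasta)
            _write_manifest(outdir, "synth", h)
            log.info("synth: wrote %s", fasta)
        else:
            log.info("synth: cached")
        substrate = hio.read_fasta(fasta)[0]
        results["substrate"] = substrate
    except Exception as err:
        raise RuntimeError(f"[synth] {err}") from err

    try:  # ---- simulate
        conditions = IonicConditions(**cfg["conditions"])
        sim = SimulationConfig(
            model=cfg["simulate"].get("model", "delayed"),
            n=int(cfg["simulate"].get("n", 5)),
            target_mean_rate=float(cfg["simulate"].get("target_mean_rate", 46.0)),
        )
        meas = MeasurementConfig(**cfg["measure"])
        n_traces = int(cfg["simulate"].get("n_traces", 20))
        trace_dir = outdir / "traces"
        if not (_stage_cached(outdir, "simulate", h) and trace_dir.exists()):
            trace_dir.mkdir(exist_ok=True)
            profile = compute_bp_energies(substrate, conditions)
            sim = calibrate_prefactor(substrate, sim, profile)
            traces = generate_trace_set(substrate, sim, meas, n_traces, seed=seed)
            for i, tr in enumerate(traces):
                hio.write_trace(tr, trace_dir / f"trace_{i:03d}.tsv")
            _write_manifest(outdir, "simulate", h, {"n_traces": n_traces})
            log.info("simulate: %d traces", n_traces)
        else:
            traces = [
                hio.read_trace(p, substrate)
                for p in sorted(trace_dir.glob("trace_*.tsv"))
            ]
            log.info("simulate: cached (%d traces)", len(traces))
        results["traces"] = traces
    except Exception as err:
        raise RuntimeError(f"[simulate] {err}") from err

    try:  # ---- stepfind
        algo = cfg["stepfind"].get("algo", "ttest")
        noisy = bool(cfg["stepfind"].get("noisy", True)) and meas.noise_sigma_nm > 0
        fits = []
        for tid, tr in enumerate(results["traces"]):
            if algo == "ttest":
                kw = stepfind.NOISY_TTEST_PARAMS if noisy else {}
                f = stepfind.tstep_find(tr, trace_id=tid, **kw)
            else:
                kw = stepfind.NOISY_KM_PARAMS if noisy else {}
                f = stepfind.km_step_find(tr, trace_id=tid, **kw)
            fits.append(stepfind.to_bp(f, meas))
        results["stepfits"] = fits
        _write_manifest(outdir, "stepfind", h, {"algo": algo})
    except Exception as err:
        raise RuntimeError(f"[stepfind] {err}") from err

    try:  # ---- analyze
        thresh = float(cfg["analyze"].get("pause_threshold_s", 0.14))
        dwell = stepfind.dwell_histogram(
            [tr.trajectory for tr in results["traces"] if tr.trajectory is not None]
            or results["stepfits"]
        )
        profile = compute_bp_energies(substrate, conditions)
        stab = stability_profile(profile)
        energy_peaks = fit_gaussian_peaks(stab.positions, stab.values)
        dwell_peaks = fit_gaussian_peaks(
            dwell.bin_centers[1:-1], dwell.dwell_s[1:-1]
        )
        results["dwell_histogram"] = dwell
        results["energy_peaks"] = energy_peaks
        results["dwell_peaks"] = dwell_peaks
        try:
            results["regression"] = pa.pause_energy_regression(dwell_peaks, energy_peaks)
        except ValueError as err:
            log.warning("analyze: regression skipped (%s)", err)
        pauses = [
            stepfind.extract_pauses(f, min_duration_s=thresh) for f in results["stepfits"]
        ]
        results["pauses"] = pauses
        _write_manifest(outdir, "analyze", h)
    except Exception as err:
        raise RuntimeError(f"[analyze] {err}") from err

    (outdir / "run.manifest.json").write_text(
        json.dumps(
            {
                "hash": h, "seed": seed,
                "stages": ["synth", "simulate", "stepfind", "analyze"],
            },
            indent=1,
        )
    )
    return results
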