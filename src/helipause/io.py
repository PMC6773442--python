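"""File formats: FASTA substrates, TSV traces with JSON sidecars, configs.

Sequences travel as standard FASTA (one record per substrate) with
key=value annotations in the description line (``type=hairpin``,
``mm=90,104,124`` for displaced-strand mismatch positions, ``arm=21`` for
forks).  Traces travel as two-column TSV (``time_s``, ``extension_nm``)
with an optional JSON sidecar carrying the measurement configuration and
the ground-truth step ledger, so a loaded trace can serve as a test oracle.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .substrates import HairpinSubstrate, ForkSubstrate
from .simulator import (
    MeasuredTrace,
    MeasurementConfig,
    SimulationConfig,
    Trajectory,
)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_trace",
    "write_trace",
    "read_profile",
    "write_profile",
    "load_run_config",
    "dump_run_config",
]


def _annots(description: str) -> dict[str, str]:
    out = {}
    for tok in description.split()[1:]:
        if "=" in tok:
            k, v = tok.split("=", 1)
            out[k] = v
    return out


def write_fasta(substrates, path) -> None:
    """Write substrates as FASTA with annotation tokens in the description."""
    records = []
    for s in substrates:
        if isinstance(s, HairpinSubstrate):
            desc = f"type=hairpin loop={s.loop_length}"
            if s.mismatch_positions:
                desc += " mm=" + ",".join(str(p) for p in s.mismatch_positions)
            records.append(SeqRecord(Seq(s.stem_sequence), id=s.name, description=desc))
        elif isinstance(s, ForkSubstrate):
            desc = f"type=fork arm={s.arm_length}"
            records.append(SeqRecord(Seq(s.duplex_sequence), id=s.name, description=desc))
        else:
            raise TypeError(f"cannot serialize {type(s).__name__}")
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> list[HairpinSubstrate | ForkSubstrate]:
    """Read substrates back; sequences are upper-cased, annotations parsed."""
    out = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"record {rec.id!r} (#{i + 1}) in {path} has an empty sequence")
        ann = _annots(rec.description)
        kind = ann.get("type", "fork" if len(seq) == 33 else "hairpin")
        try:
            if kind == "fork":
                out.append(
                    ForkSubstrate(
                        name=rec.id, duplex_sequence=seq,
                        arm_length=int(ann.get("arm", 21)),
                    )
                )
            else:
                mm = tuple(
                    int(p) for p in ann.get("mm", "").split(",") if p
                )
                out.append(
                    HairpinSubstrate(
                        name=rec.id, stem_sequence=seq, mismatch_positions=mm,
                        loop_length=int(ann.get("loop", 4)),
                    )
                )
        except ValueError as err:
            raise ValueError(f"record {rec.id!r} (#{i + 1}) in {path}: {err}") from err
    return out


def write_trace(trace: MeasuredTrace, path, sidecar: bool = True) -> None:
    """TSV with header plus a JSON sidecar (<path>.json) holding the
    measurement config and, when available, the ground-truth ledger."""
    path = Path(path)
    pd.DataFrame(
        {"time_s": trace.time_s, "extension_nm": trace.extension_nm}
    ).to_csv(path, sep="\t", index=False)
    if not sidecar:
        return
    meta: dict = {"meas_config": asdict(trace.meas_config)}
    traj = trace.trajectory
    if traj is not None:
        meta["ground_truth"] = {
            "substrate": traj.substrate.name,
            "event_times": traj.event_times.tolist(),
            "event_positions": traj.event_positions.tolist(),
            "step_start": traj.step_start.tolist(),
            "pause_s": traj.pause_s.tolist(),
            "trans_s": traj.trans_s.tolist(),
            "bp_covered": traj.bp_covered.tolist(),
        }
        if traj.config is not None:
            meta["sim_config"] = asdict(traj.config)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_trace(path, substrate=None) -> MeasuredTrace:
    """Load a TSV trace; the sidecar restores config and ground truth when
    present, otherwise the trace loads with default provenance.

    Rejects non-monotonic time columns.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    t = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: time column is not strictly increasing")
    meas = None
    traj = None
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if "meas_config" in meta:
            meas = MeasurementConfig(**meta["meas_config"])
        gt = meta.get("ground_truth")
        if gt is not None and substrate is not None:
            cfg = SimulationConfig(**meta["sim_config"]) if "sim_config" in meta else None
            traj = Trajectory(
                substrate=substrate,
                event_times=np.array(gt["event_times"]),
                event_positions=np.array(gt["event_positions"]),
                step_start=np.array(gt["step_start"]),
                pause_s=np.array(gt["pause_s"]),
                trans_s=np.array(gt["trans_s"]),
                bp_covered=np.array(gt["bp_covered"]),
                config=cfg,
            )
    if meas is None:
        dt = float(np.median(np.diff(t)))
        meas = MeasurementConfig(sampling_hz=round(1.0 / dt, 6))
    return MeasuredTrace(
        time_s=t, extension_nm=df["extension_nm"].to_numpy(dtype=float),
        meas_config=meas, trajectory=traj,
    )


def write_profile(profile, path) -> None:
    """Per-bp energy profile as TSV (position_bp, g1bp_kbt) with a JSON
    sidecar recording the ionic conditions and substrate name."""
    path = Path(path)
    pd.DataFrame(
        {"position_bp": np.arange(1, len(profile.g1bp) + 1), "g1bp_kbt": profile.g1bp}
    ).to_csv(path, sep="\t", index=False)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(
            {
                "substrate": profile.substrate.name,
                "conditions": asdict(profile.conditions),
                "parameter_set": "unified nearest-neighbor, monovalent salt entropy correction",
            },
            indent=1,
        )
    )


def read_profile(path, substrate):
    """Load a profile written by :func:`write_profile`."""
    from .thermo import DuplexEnergyProfile, IonicConditions

    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return DuplexEnergyProfile(
        substrate=substrate,
        g1bp=df["g1bp_kbt"].to_numpy(),
        conditions=IonicConditions(**meta["conditions"]),
    )


def load_run_config(path) -> dict:
    """YAML/JSON run configuration; round-trips losslessly through
    :func:`dump_run_config`."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".json",):
        return json.loads(text)
    return yaml.safe_load(text)


def dump_run_config(config: dict, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(config, indent=1, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(config, sort_keys=True))
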