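"""File formats and run configuration.

User-facing files use flexion-positive degrees and extension-positive
N m.  Trial CSV: columns ``time_s, angle_deg, moment_Nm``.  EMG CSV:
``time_s`` plus one column per channel named ``<muscle>_<side>``, with a
JSON sidecar holding the sampling rate and channel map.  Plant/muscle
parameters and results are JSON; run configuration is YAML.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .emg import EmgRecording
from .hill import MuscleParams
from .identify import CalibrationResult
from .plant import IapParams, IsokineticProtocol, PlantGeometry, TrunkPlant
from .synergy import SynergySet
from .trace import MomentTrace

__all__ = [
    "read_trial_csv",
    "write_trial_csv",
    "read_emg_csv",
    "write_emg_csv",
    "load_plant_json",
    "save_plant_json",
    "save_results_json",
    "save_synergy_json",
    "RunConfig",
    "load_run_config",
]

TRIAL_COLUMNS = ["time_s", "angle_deg", "moment_Nm"]


def read_trial_csv(path: str | Path, kind: str = "measured") -> MomentTrace:
    df = pd.read_csv(path)
    for col in TRIAL_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        # +2: header line plus 1-based indexing of the offending data row
        raise ValueError(f"{path}: non-monotone time at line {bad[0] + 2}")
    return MomentTrace(t, df["angle_deg"].to_numpy(float), df["moment_Nm"].to_numpy(float), kind=kind)


def write_trial_csv(path: str | Path, trace: MomentTrace) -> None:
    pd.DataFrame(
        {"time_s": trace.time, "angle_deg": trace.angle_deg, "moment_Nm": trace.moment}
    ).to_csv(path, index=False, float_format="%.9g")


def read_emg_csv(path: str | Path, sidecar: str | Path | None = None) -> EmgRecording:
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".json")
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing required column 'time_s'")
    channels = [c for c in df.columns if c != "time_s"]
    meta = json.loads(Path(sidecar).read_text())
    fs = float(meta["fs"])
    channel_map = {i: ch for i, ch in enumerate(channels)}
    return EmgRecording(df[channels].to_numpy(float).T, fs, channel_map)


def write_emg_csv(path: str | Path, rec: EmgRecording) -> None:
    path = Path(path)
    t = np.arange(rec.samples.shape[1]) / rec.fs
    cols = {"time_s": t}
    for i, lab in enumerate(rec.labels):
        cols[lab] = rec.samples[i]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6g")
    path.with_suffix(".json").write_text(
        json.dumps({"fs": rec.fs, "channel_map": rec.labels}, indent=1)
    )


def _muscle_to_json(m: MuscleParams, arm: float, mt_ref: float) -> dict:
    return {
        "name": m.name, "group": m.group, "f0_N": m.f0, "l0_m": m.l0,
        "v0_mps": m.v0, "alpha_rad": m.alpha, "tendon_slack_m": m.tendon_slack,
        "eps0": m.eps0, "pcsa_cm2": m.pcsa,
        "moment_arm_m": arm, "mt_length_ref_m": mt_ref,
    }


def save_plant_json(path: str | Path, plant: TrunkPlant) -> None:
    g = plant.geometry
    data = {
        "geometry": {
            "trunk_mass_kg": g.trunk_mass, "com_distance_m": g.com_distance,
            "trunk_inertia_kgm2": g.trunk_inertia,
            "ivd_stiffness_Nm_rad": g.ivd_stiffness, "ivd_damping_Nms_rad": g.ivd_damping,
            "coupling_stiffness_Nm_rad": g.coupling_stiffness,
            "coupling_damping_Nms_rad": g.coupling_damping,
        },
        "iap": dataclasses.asdict(plant.iap),
        "muscles": [
            _muscle_to_json(m, g.moment_arm[m.name], g.mt_length_ref[m.name])
            for m in plant.muscles
        ],
    }
    Path(path).write_text(json.dumps(data, indent=1))


def load_plant_json(path: str | Path) -> TrunkPlant:
    data = json.loads(Path(path).read_text())
    gj = data["geometry"]
    muscles = []
    arms, refs = {}, {}
    for mj in data["muscles"]:
        muscles.append(
            MuscleParams(
                name=mj["name"], group=mj["group"], f0=mj["f0_N"], l0=mj["l0_m"],
                v0=mj["v0_mps"], alpha=mj.get("alpha_rad", 0.0),
                tendon_slack=mj.get("tendon_slack_m", 0.0),
                eps0=mj.get("eps0", 0.04), pcsa=mj.get("pcsa_cm2", 10.0),
            )
        )
        arms[mj["name"]] = mj["moment_arm_m"]
        refs[mj["name"]] = mj["mt_length_ref_m"]
    geom = PlantGeometry(
        trunk_mass=gj["trunk_mass_kg"], com_distance=gj["com_distance_m"],
        trunk_inertia=gj["trunk_inertia_kgm2"],
        moment_arm=arms, mt_length_ref=refs,
        ivd_stiffness=gj["ivd_stiffness_Nm_rad"], ivd_damping=gj["ivd_damping_Nms_rad"],
        coupling_stiffness=gj["coupling_stiffness_Nm_rad"],
        coupling_damping=gj["coupling_damping_Nms_rad"],
    )
    iap = IapParams(**data["iap"]) if "iap" in data else IapParams()
    return TrunkPlant(geom, muscles, iap=iap)


def save_results_json(path: str | Path, result: CalibrationResult) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(result), indent=1))


def save_synergy_json(path: str | Path, syn: SynergySet, coupling=None) -> None:
    data = {
        "S": syn.S,
        "vaf_by_order": syn.vaf_by_order,
        "residual_norm": syn.residual_norm,
        "W": {lab: list(map(float, row)) for lab, row in zip(syn.labels, syn.W)}
        if syn.labels
        else syn.W.tolist(),
        "H_peak_per_synergy": syn.H.max(axis=1).tolist(),
    }
    if coupling is not None:
        data["coupling"] = dataclasses.asdict(coupling)
    Path(path).write_text(json.dumps(data, indent=1))


@dataclass
class RunConfig:
    """Identification run configuration (YAML file, CLI flags override)."""

    trial_csv: str | None = None
    emg_csv: str | None = None
    plant_json: str | None = None
    with_synergy: bool = False
    with_iap: bool = False
    delta: float = 0.2
    max_iters: int = 10
    seed: int = 0
    out_dir: str = "results"
    protocol: dict = field(default_factory=dict)

    def validate(self) -> None:
        for attr in ("trial_csv", "emg_csv", "plant_json"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p} does not exist")
        if not isinstance(self.with_synergy, bool) or not isinstance(self.with_iap, bool):
            raise TypeError("with_synergy and with_iap must be booleans")
        if not 0.0 < self.delta < 1.0:
            raise ValueError("delta must lie in (0, 1)")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")


def load_run_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown run-config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg
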