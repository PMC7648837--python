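"""Run configuration: one flat key/value text file for every tunable.

Format: ``key = value`` lines, ``#`` comments. The master seed determines
each stage's seed through a documented derivation (CRC-32 of the stage name
added to the master seed, modulo 2**32).
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Union

from .data_model import ValidationError

PathLike = Union[str, Path]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: (master + crc32(stage)) % 2**32."""
    return (int(master_seed) + zlib.crc32(stage.encode())) % (2**32)


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with the documented defaults."""

    # paths / stage toggles
    input_session: str = ""
    out_dir: str = "run"
    simulate: bool = True
    clean: bool = True
    cluster_spikes: bool = False  # SPC is expensive; pooled stats don't need it
    master_seed: int = 0
    log_level: str = "INFO"

    # simulate
    sim_duration_s: float = 30.0
    sim_fs: float = 24000.0
    sim_target_trajectory: str = "central"
    sim_target_depth_mm: int = -1
    sim_offtarget_gain: float = 0.6
    sim_stn_beta_scale: float = 1.0
    sim_beta_offpeak_factor: float = 0.45
    sim_artifact_rate_per_30s: float = 0.0

    # clean
    clean_epoch_len_s: float = 0.5
    clean_vc_threshold: float = 1.8
    clean_bridge_ms: float = 2.0
    clean_n_anchors: int = 5

    # sort
    sort_k_thresh: float = 4.0
    sort_lockout_ms: float = 1.5
    sort_n_select: int = 10
    spc_K: int = 11
    spc_n_iter: int = 500
    spc_temp_start: float = 0.01
    spc_temp_stop: float = 0.251
    spc_temp_step: float = 0.01
    spc_min_cluster_size: int = 20

    # features
    feat_R_ms: float = 5.0
    feat_epoch_len_s: float = 0.5
    feat_welch_window_s: float = 1.0

    @classmethod
    def from_file(cls, path: PathLike) -> "RunConfig":
        values = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValidationError(f"{path}:{lineno}: expected 'key = value'")
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in fields:
                raise ValidationError(f"{path}:{lineno}: unknown key {key!r}")
            ftype = fields[key].type
            if ftype in ("bool", bool):
                values[key] = raw.lower() in ("1", "true", "yes", "on")
            elif ftype in ("int", int):
                values[key] = int(raw)
            elif ftype in ("float", float):
                values[key] = float(raw)
            else:
                values[key] = raw
        return cls(**values)

    def to_file(self, path: PathLike) -> None:
        lines = [
            f"{f.name} = {getattr(self, f.name)}" for f in dataclasses.fields(self)
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return f"{zlib.crc32(payload.encode()):08x}"

    def seed_for(self, stage: str) -> int:
        return stage_seed(self.master_seed, stage)
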