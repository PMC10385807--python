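"""Study configuration and file round-tripping.

Files store field data in tesla; logs and tables display femtotesla.
Recordings are written as ``.npy`` arrays next to a JSON sidecar carrying
the sampling rate, units and channel labels (plus optional ground-truth
arrays); small recordings can also be exported as delimited text.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Tuple

import numpy as np
import yaml

from .exceptions import InvalidConfigError
from .simulate import (
    DipoleSource,
    EXTERNAL_MOMENT,
    EXTERNAL_SHELL,
    INTERNAL_MOMENT,
    INTERNAL_SHELL,
    Recording,
    SHELL_CENTRE,
)

__all__ = [
    "StudyConfig",
    "load_config",
    "save_config",
    "write_recording",
    "read_recording",
    "write_recording_csv",
    "write_dipoles",
    "read_dipoles",
]


@dataclass
class StudyConfig:
    """Parameters of the simulation study.

    Defaults are the reference study conditions: a 64-sensor (192-channel)
    helmet, 100 runs of 5 internal + 5 external dipoles, 1 s at 1200 Hz
    with 30 fT sensor noise, truncation grid L_in = 7..11 x L_out = 3..5,
    and 20 solver iterations.
    """

    l_in_range: Tuple[int, ...] = tuple(range(7, 12))
    l_out_range: Tuple[int, ...] = tuple(range(3, 6))
    n_runs: int = 100
    n_iterations: int = 20
    n_sensors: int = 64
    n_internal: int = 5
    n_external: int = 5
    internal_shell: Tuple[float, float] = INTERNAL_SHELL
    external_shell: Tuple[float, float] = EXTERNAL_SHELL
    shell_centre: Tuple[float, float, float] = tuple(float(v) for v in SHELL_CENTRE)
    internal_moment: float = INTERNAL_MOMENT
    external_moment: float = EXTERNAL_MOMENT
    duration: float = 1.0
    fs: float = 1200.0
    noise_sd: float = 30e-15
    seed: int = 0
    helmet_seed: int = 0
    output_dir: str = "study_output"

    def validate(self) -> None:
        """Check every field against the module preconditions it feeds."""
        checks = [
            (all(l >= 1 for l in (*self.l_in_range, *self.l_out_range)), "truncation degrees must be >= 1"),
            (len(self.l_in_range) > 0 and len(self.l_out_range) > 0, "empty truncation grid"),
            (self.n_runs >= 1, "n_runs must be >= 1"),
            (self.n_iterations >= 1, "n_iterations must be >= 1"),
            (self.n_sensors >= 4, "n_sensors must be >= 4"),
            (self.n_internal >= 0 and self.n_external >= 0, "dipole counts must be >= 0"),
            (self.n_internal + self.n_external <= 100, "at most 100 distinct drive frequencies exist"),
            (0 <= self.internal_shell[0] < self.internal_shell[1], "bad internal shell radii"),
            (0 <= self.external_shell[0] < self.external_shell[1], "bad external shell radii"),
            (self.duration > 0 and self.fs > 0, "duration and fs must be positive"),
            (self.noise_sd >= 0, "noise_sd must be >= 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise InvalidConfigError(msg)

    def to_dict(self) -> dict:
        def plain(v):
            if isinstance(v, tuple):
                return [plain(x) for x in v]
            if isinstance(v, np.floating):
                return float(v)
            if isinstance(v, np.integer):
                return int(v)
            return v

        return {k: plain(v) for k, v in dataclasses.asdict(self).items()}

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(d)
        for f in dataclasses.fields(cls):
            if f.name in kwargs and isinstance(getattr(cls(), f.name), tuple):
                kwargs[f.name] = tuple(kwargs[f.name])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


def load_config(path) -> StudyConfig:
    """Read a YAML or JSON study configuration; fields validate on load."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return StudyConfig.from_dict(data or {})


def save_config(config: StudyConfig, path) -> None:
    path = Path(path)
    d = config.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=1) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def write_recording(rec: Recording, stem) -> None:
    """Write ``<stem>.npy`` (+ ground-truth arrays if present) and the
    ``<stem>.json`` sidecar."""
    stem = Path(stem)
    np.save(stem.with_suffix(".npy"), rec.data)
    sidecar = {
        "fs": rec.fs,
        "units": "T",
        "labels": list(rec.labels),
        "ground_truth": rec.ground_truth_in is not None,
    }
    if rec.ground_truth_in is not None:
        np.save(stem.parent / (stem.name + "_in.npy"), rec.ground_truth_in)
        np.save(stem.parent / (stem.name + "_out.npy"), rec.ground_truth_out)
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1) + "\n")


def read_recording(stem) -> Recording:
    stem = Path(stem)
    sidecar = json.loads(stem.with_suffix(".json").read_text())
    data = np.load(stem.with_suffix(".npy"))
    gt_in = gt_out = None
    if sidecar.get("ground_truth"):
        gt_in = np.load(stem.parent / (stem.name + "_in.npy"))
        gt_out = np.load(stem.parent / (stem.name + "_out.npy"))
    return Recording(
        data=data,
        fs=float(sidecar["fs"]),
        ground_truth_in=gt_in,
        ground_truth_out=gt_out,
        labels=list(sidecar.get("labels", [])),
    )


def write_recording_csv(rec: Recording, path) -> None:
    """Delimited-text export (channels as rows) for small recordings."""
    np.savetxt(path, rec.data, delimiter=",")


def write_dipoles(dipoles: List[DipoleSource], path) -> None:
    payload = [
        {
            "position": d.position.tolist(),
            "moment": d.moment.tolist(),
            "frequency": d.frequency,
            "kind": d.kind,
        }
        for d in dipoles
    ]
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_dipoles(path) -> List[DipoleSource]:
    payload = json.loads(Path(path).read_text())
    return [
        DipoleSource(
            position=np.asarray(d["position"]),
            moment=np.asarray(d["moment"]),
            frequency=int(d["frequency"]),
            kind=d["kind"],
        )
        for d in payload
    ]
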