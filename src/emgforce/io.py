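"""Readers/writers and run configuration.

Native interchange format for a recording is a pair of CSV matrices plus a
JSON sidecar, all human-inspectable and diff-able::

    <stem>_emg.csv    channels x time matrix, one channel per row
    <stem>_force.csv  one force value per line
    <stem>.json       fs, grid layout, gesture, subject, group, mode, meta

Sample sets are stored as NPZ archives with arrays ``windows`` (n, L),
``targets`` (n,), ``subjects``, ``gestures``, ``repetitions``.  Model
checkpoints are NPZ weight archives with a JSON config sidecar.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from .errors import FormatError, ValidationError
from .model import EstimatorConfig, ForceEstimator, build_estimator
from .preprocess import PreprocessConfig, SampleSet, ScreeningCriteria
from .sim import ForceTrace, GridLayout, Recording


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------

def write_recording(rec: Recording, path: str | Path) -> dict[str, Path]:
    """Write a recording as CSV matrices plus a JSON metadata sidecar.

    ``path`` is the file stem; returns the mapping of written files.
    """
    stem = Path(path)
    stem.parent.mkdir(parents=True, exist_ok=True)
    emg_path = stem.with_name(stem.name + "_emg.csv")
    force_path = stem.with_name(stem.name + "_force.csv")
    meta_path = stem.with_name(stem.name + ".json")
    np.savetxt(emg_path, rec.semg, delimiter=",", fmt="%.9g")
    np.savetxt(force_path, rec.force.values, delimiter=",", fmt="%.9g")
    meta = {
        "fs": rec.fs,
        "grid": {"n_grids": rec.grid.n_grids, "rows": rec.grid.rows,
                 "cols": rec.grid.cols, "gap": rec.grid.gap},
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "gesture": rec.gesture,
        "subject_id": rec.subject_id,
        "repetition": rec.repetition,
        "group": rec.group,
        "force_mode": rec.force.mode,
        "force_params": rec.force.params,
        "units": {"semg": "mV (arbitrary)", "force": "fraction of MVC"},
        "meta": _jsonable(rec.meta),
    }
    meta_path.write_text(json.dumps(meta, indent=1))
    return {"emg": emg_path, "force": force_path, "meta": meta_path}


def read_recording(path: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording`.

    The sEMG channel order is the grid's row-major order (grid piece, then
    row, then column) as documented in the sidecar.
    """
    stem = Path(path)
    meta_path = stem.with_name(stem.name + ".json")
    if not meta_path.exists():
        raise FormatError(f"missing sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    emg_path = stem.with_name(stem.name + "_emg.csv")
    force_path = stem.with_name(stem.name + "_force.csv")
    if not emg_path.exists():
        raise FormatError(f"missing sEMG matrix {emg_path}")
    if not force_path.exists():
        raise FormatError(f"missing force channel {force_path}")
    semg = np.atleast_2d(np.loadtxt(emg_path, delimiter=","))
    if semg.shape[0] != meta["n_channels"]:
        raise FormatError(
            f"{emg_path}: {semg.shape[0]} rows but sidecar declares "
            f"{meta['n_channels']} channels")
    force_values = np.atleast_1d(np.loadtxt(force_path, delimiter=","))
    grid = GridLayout(**meta["grid"])
    force = ForceTrace(force_values, meta["fs"], meta.get("force_mode", "constant"),
                       meta.get("force_params", {}))
    return Recording(
        semg, force, meta["fs"], grid, meta.get("gesture", "G1"),
        meta.get("subject_id", "S1"), meta.get("repetition", 0),
        meta.get("group", "HC"), meta.get("meta", {}),
    )


def write_cohort(recordings: list[Recording], out_dir: str | Path) -> Path:
    """Write a cohort plus a manifest JSON listing every recording."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in recordings:
        stem = f"{rec.subject_id}_{rec.gesture}_r{rec.repetition}"
        files = write_recording(rec, out_dir / stem)
        entries.append({
            "stem": stem,
            "subject_id": rec.subject_id,
            "group": rec.group,
            "gesture": rec.gesture,
            "repetition": rec.repetition,
            "fs": rec.fs,
            "checksums": {k: _sha256(p) for k, p in files.items()},
        })
    manifest = {"root": str(out_dir), "recordings": entries}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out_dir / "manifest.json"


def read_cohort(manifest_path: str | Path) -> list[Recording]:
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    root = manifest_path.parent
    seen = set()
    out = []
    for entry in manifest["recordings"]:
        key = (entry["subject_id"], entry["gesture"], entry["repetition"])
        if key in seen:
            raise FormatError(f"duplicate (subject, gesture, repetition) {key}")
        seen.add(key)
        out.append(read_recording(root / entry["stem"]))
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


# ---------------------------------------------------------------------------
# sample sets
# ---------------------------------------------------------------------------

def save_samples(samples: SampleSet, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, windows=samples.windows, targets=samples.targets,
             subjects=samples.subjects, gestures=samples.gestures,
             repetitions=samples.repetitions)
    return path


def load_samples(path: str | Path) -> SampleSet:
    with np.load(path, allow_pickle=False) as z:
        return SampleSet(z["windows"], z["targets"], z["subjects"].astype("<U32"),
                         z["gestures"].astype("<U32"), z["repetitions"])


# ---------------------------------------------------------------------------
# model checkpoints
# ---------------------------------------------------------------------------

def save_estimator(est: ForceEstimator, path: str | Path) -> Path:
    """NPZ weights + JSON config sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **est.net.get_weights())
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "config": dataclasses.asdict(est.config),
        "is_trained": est.is_trained,
        "history": est.history,
        "frozen_depth": est.net.frozen_depth,
    }, indent=1))
    return path


def load_estimator(path: str | Path) -> ForceEstimator:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg = EstimatorConfig(**{**sidecar["config"],
                             "layer_units": tuple(sidecar["config"]["layer_units"])})
    est = build_estimator(cfg, seed=0)
    with np.load(path) as z:
        est.net.set_weights({k: z[k] for k in z.files})
    est.is_trained = sidecar["is_trained"]
    est.history = sidecar["history"]
    est.net.frozen_depth = sidecar.get("frozen_depth", 0)
    return est


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_KNOWN_SECTIONS = ("sim", "preprocess", "estimator", "transfer", "seed")


@dataclasses.dataclass
class RunConfig:
    """All tunables of the pipeline, serializable to/from YAML.

    Unknown keys are rejected so a typo cannot silently fall back to a
    default.  Every stage derives its own seed deterministically from the
    single top-level ``seed``.
    """

    seed: int = 0
    sim: dict = dataclasses.field(default_factory=dict)
    preprocess: dict = dataclasses.field(default_factory=dict)
    estimator: dict = dataclasses.field(default_factory=dict)
    transfer: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        self.preprocess_config()   # validate eagerly
        self.estimator_config()

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - set(_KNOWN_SECTIONS)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict()))
        return path

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the top-level seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "little") % (2 ** 31)

    def preprocess_config(self) -> PreprocessConfig:
        d = dict(self.preprocess)
        screening = d.pop("screening", None)
        known = {f.name for f in dataclasses.fields(PreprocessConfig)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown preprocess keys: {sorted(unknown)}")
        cfg = PreprocessConfig(**d)
        if screening:
            cfg.screening = ScreeningCriteria(**screening)
        if cfg.window <= 0 or cfg.step <= 0:
            raise ValidationError("window and step must be positive")
        return cfg

    def estimator_config(self) -> EstimatorConfig:
        d = dict(self.estimator)
        known = {f.name for f in dataclasses.fields(EstimatorConfig)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown estimator keys: {sorted(unknown)}")
        if "layer_units" in d:
            d["layer_units"] = tuple(d["layer_units"])
        return EstimatorConfig(**d)
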