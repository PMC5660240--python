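"""Readers, writers, manifests and configuration.

NIfTI for volumes (via nibabel), tab-separated tables for motion / events /
gaze / manifests, ``.npz`` containers with JSON sidecars for pair-correlation
tensors, and JSON reproducibility records for every pipeline stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .inference import StatMap
from .isc import CONDITIONS, BoldRun, PairCorrelationTensor, PairSet

__version__ = "0.1.0"

MANIFEST_REQUIRED = ("subject_id", "session_index", "condition", "perspective",
                     "bold_path", "motion_path")
MANIFEST_OPTIONAL = ("gaze_path", "physio_path", "rating_path")


@dataclass
class ManifestRow:
    subject_id: int
    session_index: int
    condition: str
    perspective: str
    bold_path: Path
    motion_path: Path
    gaze_path: Path | None = None
    physio_path: Path | None = None
    rating_path: Path | None = None


@dataclass
class RunManifest:
    rows: list[ManifestRow]
    root: Path

    def __len__(self) -> int:
        return len(self.rows)

    def select(self, condition: str | None = None) -> list[ManifestRow]:
        return [r for r in self.rows
                if condition is None or r.condition == condition]


def load_manifest(path: str | Path, check_files: bool = True) -> RunManifest:
    """Load and validate a tab-separated run manifest.

    Rejects duplicate (subject, condition, session) rows, unknown condition
    labels, and (by default) rows whose referenced files do not exist; error
    messages name the offending row.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    missing_cols = [c for c in MANIFEST_REQUIRED if c not in table.columns]
    if missing_cols:
        raise ValueError(f"manifest is missing columns {missing_cols}")
    root = path.parent
    rows: list[ManifestRow] = []
    seen: set[tuple[int, str, int]] = set()
    for idx, rec in table.iterrows():
        cond = str(rec["condition"])
        if cond not in CONDITIONS:
            raise ValueError(f"manifest row {idx}: unknown condition {cond!r}")
        key = (int(rec["subject_id"]), cond, int(rec["session_index"]))
        if key in seen:
            raise ValueError(f"manifest row {idx}: duplicate run {key}")
        seen.add(key)
        paths = {}
        for col in ("bold_path", "motion_path", *MANIFEST_OPTIONAL):
            if col in table.columns and isinstance(rec.get(col), str) and rec[col]:
                p = root / rec[col]
                if check_files and not p.exists():
                    raise ValueError(f"manifest row {idx}: missing file {p}")
                paths[col] = p
        rows.append(ManifestRow(
            subject_id=int(rec["subject_id"]),
            session_index=int(rec["session_index"]), condition=cond,
            perspective=str(rec["perspective"]),
            bold_path=paths["bold_path"], motion_path=paths["motion_path"],
            gaze_path=paths.get("gaze_path"),
            physio_path=paths.get("physio_path"),
            rating_path=paths.get("rating_path")))
    return RunManifest(rows=rows, root=root)


def write_bold_run(run: BoldRun, bold_path: str | Path,
                   mask_path: str | Path | None = None) -> None:
    """Write a run as 4-D NIfTI (and optionally its 3-D mask)."""
    vol = np.zeros(run.mask.shape + (run.n_trs,), dtype=np.float32)
    vol[run.mask] = run.data
    nib.save(nib.Nifti1Image(vol, run.affine), str(bold_path))
    if mask_path is not None:
        nib.save(nib.Nifti1Image(run.mask.astype(np.uint8), run.affine),
                 str(mask_path))


def read_bold_run(bold_path: str | Path, mask_path: str | Path,
                  subject_id: int, condition: str, session_index: int,
                  tr_seconds: float = 2.0, perspective: str = "none") -> BoldRun:
    img = nib.load(str(bold_path))
    mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    data = np.asarray(img.dataobj, dtype=float)[mask]
    return BoldRun(subject_id=subject_id, condition=condition,
                   session_index=session_index, data=data, mask=mask,
                   tr_seconds=tr_seconds, perspective=perspective,
                   affine=np.asarray(img.affine))


def write_table(array: np.ndarray, path: str | Path,
                columns: list[str]) -> None:
    pd.DataFrame(np.asarray(array), columns=columns).to_csv(
        path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_statmap(statmap: StatMap, out_prefix: str | Path,
                  mask: np.ndarray | None = None,
                  affine: np.ndarray | None = None) -> dict[str, Path]:
    """Write t/p/mask NIfTI volumes plus a JSON parameter sidecar.

    ``mask`` unflattens per-voxel vectors when the StatMap was computed on
    mask-flattened data; with no mask the StatMap's own grid shape is used.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4) if affine is None else affine

    def unflatten(values: np.ndarray, fill: float) -> np.ndarray:
        if mask is not None:
            vol = np.full(mask.shape, fill, dtype=float)
            vol[mask] = values
            return vol
        if statmap.grid_shape is not None:
            return np.asarray(values, dtype=float).reshape(statmap.grid_shape)
        raise ValueError("no mask or grid shape available to unflatten")

    paths = {}
    for name, values, fill in (("t", statmap.stat, 0.0),
                               ("p", statmap.p, 1.0),
                               ("mask", statmap.mask.astype(float), 0.0)):
        p = out_prefix.parent / f"{out_prefix.name}_{name}.nii"
        nib.save(nib.Nifti1Image(unflatten(values, fill).astype(np.float32),
                                 affine), str(p))
        paths[name] = p
    sidecar = out_prefix.parent / f"{out_prefix.name}.json"
    meta = {"q": statmap.q, "p_cutoff": statmap.p_cutoff,
            "stat_threshold": statmap.stat_threshold, "tail": statmap.tail,
            "n_permutations": statmap.n_permutations, "seed": statmap.seed,
            "software_version": __version__}
    sidecar.write_text(json.dumps(_jsonable(meta), indent=2))
    paths["sidecar"] = sidecar
    return paths


def save_tensor(tensor: PairCorrelationTensor, path: str | Path) -> None:
    """Tensor as .npz with a JSON metadata sidecar (pair list, condition)."""
    path = Path(path)
    np.savez_compressed(path, z=tensor.z)
    meta = {"condition": tensor.pairs.condition,
            "n_subjects": tensor.pairs.n_subjects,
            "sessions_per_condition": tensor.pairs.sessions_per_condition,
            "pairs": tensor.pairs.pairs, "analysis_id": tensor.analysis_id}
    path.with_suffix(".json").write_text(json.dumps(_jsonable(meta)))


def load_tensor(path: str | Path) -> PairCorrelationTensor:
    path = Path(path)
    z = np.load(path.with_suffix(".npz") if path.suffix != ".npz" else path)["z"]
    meta = json.loads(path.with_suffix(".json").read_text())
    pairs = PairSet(
        pairs=[((p[0][0], p[0][1]), (p[1][0], p[1][1])) for p in meta["pairs"]],
        condition=meta["condition"], n_subjects=meta["n_subjects"],
        sessions_per_condition=meta["sessions_per_condition"])
    return PairCorrelationTensor(z=z, pairs=pairs,
                                 analysis_id=meta.get("analysis_id", ""))


@dataclass
class PipelineConfig:
    """Stage parameters with the study defaults."""

    q: float = 0.05
    n_permutations_contrast: int = 5000
    n_permutations_glm: int = 5000
    n_permutations_eyeisc: int = 100000
    n_permutations_behavior: int = 5000
    cluster_min_extent: int = 64
    cluster_connectivity: int = 6
    tfce_extent_exponent: float = 0.5
    tfce_height_exponent: float = 2.0
    tfce_connectivity: int = 26
    highpass_isc_hz: float = 0.01
    highpass_glm_s: float = 128.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.q < 1:
            raise ValueError("q must be in (0, 1)")
        positive = (self.n_permutations_contrast, self.n_permutations_glm,
                    self.n_permutations_eyeisc, self.n_permutations_behavior,
                    self.cluster_min_extent, self.highpass_glm_s)
        if any(v <= 0 for v in positive):
            raise ValueError("all thresholds and permutation counts must be > 0")


def load_config(path: str | Path | None, **overrides) -> PipelineConfig:
    """YAML config file, flag overrides on top; unknown keys are an error."""
    values: dict = {}
    if path is not None:
        values.update(yaml.safe_load(Path(path).read_text()) or {})
    values.update({k: v for k, v in overrides.items() if v is not None})
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}")
    cfg = PipelineConfig(**values)
    cfg.validate()
    return cfg


def write_repro_record(out_dir: str | Path, stage: str,
                       config: PipelineConfig, **extra) -> Path:
    """Config hash + seeds + version: enough to regenerate outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = asdict(config)
    digest = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]
    record = {"stage": stage, "config": cfg, "config_sha256": digest,
              "software_version": __version__, **_jsonable(extra)}
    path = out_dir / f"{stage}_record.json"
    path.write_text(json.dumps(record, indent=2))
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, float) and (obj != obj):  # NaN -> null
        return None
    return obj
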