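"""Domain types, file I/O and run configuration.

Volumes travel as NIfTI-1, ROI time-series and manifests as CSV, and run
configurations as YAML. Readers validate aggressively and raise typed
errors so pipeline failures point at the offending input.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LoadError", "FormatError", "ValidationError", "ConfigError", "FeatureError",
    "VolumeImage", "AtlasSpec", "BrainGraph", "SubjectRecord", "RunConfig",
    "read_volume", "read_timeseries", "load_manifest", "write_manifest",
    "make_atlas_spec", "load_atlas_csv", "write_atlas_csv",
    "get_logger", "log_stage",
]


class LoadError(RuntimeError):
    """A volume or table could not be loaded."""


class FormatError(RuntimeError):
    """A table was readable but its shape/dialect is wrong."""


class ValidationError(RuntimeError):
    """Record-level constraint violation (labels, ids, ages ...)."""


class ConfigError(RuntimeError):
    """Invalid run configuration."""


class FeatureError(RuntimeError):
    """Feature computation hit a degenerate input."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass
class VolumeImage:
    """Dense 3D scalar grid with voxel spacing in millimetres."""

    data: np.ndarray          # D x H x W
    spacing: tuple[float, float, float]
    subject_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValidationError(f"volume must be 3D with all dims >= 1, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("volume contains non-finite voxels")


@dataclass
class AtlasSpec:
    """A brain parcellation: ordered ROI labels plus bilateral homolog pairing.

    ``region_labels`` excludes the appended average-signal node; when
    ``has_average_node`` is set the constructed graph gains one extra node
    carrying the whole-brain mean time series.
    """

    name: str
    region_labels: list[str]
    homolog_pairs: list[tuple[int, int]]
    has_average_node: bool = True

    def __post_init__(self):
        n = len(self.region_labels)
        seen: set[int] = set()
        for left, right in self.homolog_pairs:
            for idx in (left, right):
                if not (0 <= idx < n):
                    raise ValidationError(f"atlas {self.name}: homolog index {idx} out of range")
                if idx in seen:
                    raise ValidationError(f"atlas {self.name}: region {idx} appears in two homolog pairs")
                seen.add(idx)

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    @property
    def n_nodes(self) -> int:
        return self.n_regions + int(self.has_average_node)


def make_atlas_spec(name: str, n_pairs: int, n_unpaired: int = 0,
                    has_average_node: bool = True) -> AtlasSpec:
    """Build a symmetric atlas with `n_pairs` left/right homolog pairs.

    Region order is [L1..Ln, R1..Rn, extra...]; pair i links L_i to R_i.
    """
    labels = ([f"{name}_L{i + 1}" for i in range(n_pairs)]
              + [f"{name}_R{i + 1}" for i in range(n_pairs)]
              + [f"{name}_X{i + 1}" for i in range(n_unpaired)])
    pairs = [(i, n_pairs + i) for i in range(n_pairs)]
    return AtlasSpec(name=name, region_labels=labels, homolog_pairs=pairs,
                     has_average_node=has_average_node)


@dataclass
class BrainGraph:
    """Per-subject, per-atlas graph: node features + binary adjacency."""

    X: np.ndarray             # M_nodes x d_feat
    A: np.ndarray             # M x M symmetric {0,1}, zero diagonal
    atlas: AtlasSpec
    subject_id: str = ""

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        self.A = np.asarray(self.A, dtype=np.float64)
        m = self.A.shape[0]
        if self.A.shape != (m, m):
            raise ValidationError("adjacency must be square")
        if self.X.shape[0] != m:
            raise ValidationError("node feature rows must match adjacency order")
        if not np.array_equal(self.A, self.A.T):
            raise ValidationError("adjacency must be symmetric")
        if np.any(np.diag(self.A) != 0):
            raise ValidationError("adjacency diagonal must be zero")

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]


@dataclass
class SubjectRecord:
    subject_id: str
    label: int                   # 0 = control, 1 = case
    site: str
    sex: str
    age: float
    iq: float
    smri_path: str | None = None
    fmri_path: str | None = None
    timeseries_paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValidationError(f"subject {self.subject_id}: label must be 0/1, got {self.label}")
        if not self.age > 0:
            raise ValidationError(f"subject {self.subject_id}: age must be positive")


@dataclass
class RunConfig:
    """All tunables of the pipeline, YAML round-trippable."""

    # volume feature extractor
    acfe_channels: tuple[int, ...] = (8, 16, 32)
    acfe_kernel: int = 3
    reduction_ratio: int = 8
    spatial_kernel: int = 7
    pooled_grid: int = 4
    embed_dim: int = 64
    share_acfe_weights: bool = False
    fmri_collapse: str = "mean"           # or "std"
    # brain-graph branch
    knn_k: int = 10
    espm_hidden: int = 32
    # fusion
    fusion_dim: int = 64
    scalar_gate: bool = False
    # population graph
    similarity_threshold: float = 0.5     # th in the binarization rule
    popgraph_mode: str = "both"           # both | features | phenotypes
    gat_hidden: int = 64
    gat_heads: int = 4
    gat_out_dim: int = 16
    leaky_slope: float = 0.2
    dropout: float = 0.5
    prune_percent: float = 70.0           # p, % of directed edges kept by DAGP
    # optimisation
    weight_decay: float = 5e-4            # lambda of the L2 penalty
    lr: float = 1e-3
    batch_size: int = 32
    epochs: int = 200
    patience: int = 20
    min_epochs: int = 60          # burn-in before early stopping may trigger
    folds: int = 10
    mc_passes: int = 20
    seed: int = 0
    # ablation toggles
    use_channel_attn: bool = True
    use_spatial_attn: bool = True
    use_residual: bool = True
    use_acfe: bool = True
    use_espm: bool = True
    use_marl: bool = True
    use_papg: bool = True

    def __post_init__(self):
        if not (0 < self.prune_percent <= 100):
            raise ConfigError("prune_percent must lie in (0, 100]")
        if not (0 <= self.similarity_threshold < 1):
            raise ConfigError("similarity_threshold must lie in [0, 1)")
        if self.weight_decay < 0:
            raise ConfigError("weight_decay must be >= 0")
        if self.folds < 2:
            raise ConfigError("folds must be >= 2")
        for c in self.acfe_channels:
            if c % self.reduction_ratio != 0:
                raise ConfigError(
                    f"reduction_ratio {self.reduction_ratio} must divide channel count {c}")
        if self.fmri_collapse not in ("mean", "std"):
            raise ConfigError("fmri_collapse must be 'mean' or 'std'")
        if self.popgraph_mode not in ("both", "features", "phenotypes"):
            raise ConfigError("popgraph_mode must be both/features/phenotypes")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["acfe_channels"] = list(self.acfe_channels)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "acfe_channels" in d:
            d["acfe_channels"] = tuple(d["acfe_channels"])
        return cls(**d)

    def hash(self) -> str:
        d = asdict(self)
        d["acfe_channels"] = list(self.acfe_channels)
        return hashlib.sha256(yaml.safe_dump(d, sort_keys=True).encode()).hexdigest()[:12]


# --------------------------------------------------------------------------
# Readers / writers
# --------------------------------------------------------------------------

def read_volume(path: str | Path, subject_id: str = "",
                collapse: str = "mean") -> VolumeImage:
    """Load a NIfTI volume; 4D series are collapsed over time.

    Collapse is the voxelwise temporal mean by default ("std" gives the
    temporal standard deviation instead, exposing fluctuation amplitude).
    """
    path = Path(path)
    if not path.exists():
        raise LoadError(f"volume not found: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise LoadError(f"cannot parse NIfTI {path}: {exc}") from exc
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4:
        data = data.std(axis=3) if collapse == "std" else data.mean(axis=3)
    elif data.ndim != 3:
        raise LoadError(f"{path}: expected 3D or 4D image, got {data.ndim}D")
    if not np.all(np.isfinite(data)):
        raise LoadError(f"{path}: non-finite voxels after loading")
    zooms = img.header.get_zooms()[:3]
    return VolumeImage(data=data, spacing=tuple(float(z) for z in zooms),
                       subject_id=subject_id)


def read_timeseries(path: str | Path, atlas: AtlasSpec) -> np.ndarray:
    """Read an ROI x time CSV, auto-detecting a transposed layout.

    Returns an (n_regions, T) array ordered like ``atlas.region_labels``.
    Square tables are taken as already row-per-ROI.
    """
    path = Path(path)
    if not path.exists():
        raise LoadError(f"time-series table not found: {path}")
    arr = np.loadtxt(path, delimiter=",", ndmin=2)
    m = atlas.n_regions
    if arr.shape[0] == m:
        ts = arr
    elif arr.shape[1] == m:
        ts = arr.T
    else:
        raise FormatError(
            f"{path}: shape {arr.shape} matches neither {m} rows nor {m} columns "
            f"for atlas {atlas.name}")
    if ts.shape[1] < 2:
        raise FormatError(f"{path}: need at least 2 time points, got {ts.shape[1]}")
    return ts.astype(np.float64)


_MANIFEST_COLUMNS = ["subject_id", "label", "site", "sex", "age", "iq"]


def load_manifest(path: str | Path) -> list[SubjectRecord]:
    """Read a subject manifest CSV (header required, UTF-8)."""
    df = pd.read_csv(path, dtype={"subject_id": str, "site": str, "sex": str})
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"manifest missing required columns: {missing}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValidationError(f"duplicate subject ids in manifest: {dupes}")
    ts_cols = [c for c in df.columns if c.startswith("ts_")]
    records = []
    for _, row in df.iterrows():
        records.append(SubjectRecord(
            subject_id=row["subject_id"],
            label=int(row["label"]),
            site=row["site"], sex=row["sex"],
            age=float(row["age"]), iq=float(row["iq"]),
            smri_path=row.get("smri_path"),
            fmri_path=row.get("fmri_path"),
            timeseries_paths={c[3:]: row[c] for c in ts_cols},
        ))
    return records


def write_manifest(records: Sequence[SubjectRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id, "label": r.label, "site": r.site,
               "sex": r.sex, "age": r.age, "iq": r.iq}
        if r.smri_path is not None:
            row["smri_path"] = r.smri_path
        if r.fmri_path is not None:
            row["fmri_path"] = r.fmri_path
        for atlas, p in r.timeseries_paths.items():
            row[f"ts_{atlas}"] = p
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_atlas_csv(path: str | Path, name: str | None = None,
                   has_average_node: bool = True) -> AtlasSpec:
    """Read an atlas table (columns: label, hemisphere, homolog).

    ``homolog`` holds the label of the contralateral region, empty for
    unpaired regions; row order fixes the region order.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str).fillna("")
    for col in ("label", "hemisphere", "homolog"):
        if col not in df.columns:
            raise FormatError(f"atlas table {path} missing column '{col}'")
    labels = df["label"].tolist()
    index = {lab: i for i, lab in enumerate(labels)}
    if len(index) != len(labels):
        raise ValidationError(f"atlas table {path} has duplicate labels")
    pairs = []
    for i, row in df.iterrows():
        mate = row["homolog"]
        if not mate:
            continue
        if mate not in index:
            raise ValidationError(f"atlas table {path}: homolog '{mate}' unknown")
        j = index[mate]
        if i < j:
            pairs.append((i, j))
    return AtlasSpec(name=name or path.stem, region_labels=labels,
                     homolog_pairs=pairs, has_average_node=has_average_node)


def write_atlas_csv(atlas: AtlasSpec, path: str | Path) -> None:
    mate: dict[int, str] = {}
    for left, right in atlas.homolog_pairs:
        mate[left] = atlas.region_labels[right]
        mate[right] = atlas.region_labels[left]
    rows = [{"label": lab,
             "hemisphere": ("L" if i in dict(atlas.homolog_pairs) else
                            "R" if i in {r for _, r in atlas.homolog_pairs} else ""),
             "homolog": mate.get(i, "")}
            for i, lab in enumerate(atlas.region_labels)]
    pd.DataFrame(rows).to_csv(path, index=False)


# --------------------------------------------------------------------------
# Logging
# --------------------------------------------------------------------------

def get_logger(name: str = "neurofuse") -> logging.Logger:
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter(
            "%(asctime)s %(name)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


class log_stage:
    """Context manager logging one structured line per pipeline stage."""

    def __init__(self, stage: str, seed: int | None = None,
                 config_hash: str | None = None, logger: logging.Logger | None = None):
        self.stage = stage
        self.seed = seed
        self.config_hash = config_hash
        self.logger = logger or get_logger()

    def __enter__(self):
        self._t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self._t0
        status = "failed" if exc_type else "ok"
        self.logger.info(
            "stage=%s status=%s seed=%s config=%s elapsed=%.3fs",
            self.stage, status, self.seed, self.config_hash, dt)
        return False
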