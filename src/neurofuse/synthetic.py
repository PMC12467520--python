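"""Synthetic two-class neuroimaging cohorts with known planted structure.

The generator emulates the statistical structure the model assumes,
without any download:

* volumes — unit-variance Gaussian background plus a spherical blob at a
  fixed anatomical-proxy location whose intensity is ``blob_contrast``
  for class 1 and absent for class 0 (structural); functional volumes
  add independent frame noise around a class-dependent pattern so the
  temporal collapse recovers it;
* ROI time series — a latent-factor model with two functional modules;
  the cross-module loading rises by ``delta_r`` for class 1, and each
  bilateral homolog pair shares an extra factor so left/right regions
  correlate above chance;
* phenotypes — sites (optionally class-correlated), sex, age and IQ.

All randomness flows through one explicitly threaded seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

import yaml

from .core_io import (AtlasSpec, LoadError, SubjectRecord, ValidationError,
                      VolumeImage, load_manifest, make_atlas_spec,
                      read_timeseries, read_volume, write_manifest)

__all__ = ["CohortSpec", "Cohort", "gen_volume", "gen_functional_volume",
           "gen_timeseries", "gen_cohort", "write_cohort", "load_cohort"]


@dataclass
class CohortSpec:
    """Study-condition knobs of a synthetic cohort."""

    n_subjects: int = 200
    n_cases: int | None = None        # default: balanced
    volume_shape: tuple[int, int, int] = (16, 16, 16)
    blob_contrast: float = 5.0        # class effect in units of noise SD
    blob_radius: int = 3
    atlas_names: tuple[str, ...] = ("ho", "ez")
    pairs_per_atlas: int = 20         # regions per hemisphere per atlas
    rho: float = 0.2                  # cross-module loading, class 0
    delta_r: float = 0.4              # class-1 increment to the loading
    bilateral_loading: float = 0.6
    noise_sd: float = 1.0
    n_timepoints: int = 60            # ROI series length
    n_frames: int = 6                 # functional volume frames
    n_sites: int = 3
    site_class_corr: float = 0.0      # 0 = sites independent of class
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValidationError("need at least 2 subjects")
        if self.blob_contrast < 0 or self.delta_r < 0:
            raise ValidationError("contrasts must be >= 0")
        if self.n_timepoints < 10:
            raise ValidationError("need at least 10 time points")
        if 2 * self.blob_radius + 1 > min(self.volume_shape):
            raise ValidationError("blob does not fit inside the volume")

    @property
    def cases(self) -> int:
        return self.n_cases if self.n_cases is not None else self.n_subjects // 2

    def atlases(self) -> list[AtlasSpec]:
        return [make_atlas_spec(name, self.pairs_per_atlas)
                for name in self.atlas_names]


def _blob_mask(shape: tuple[int, int, int], radius: int,
               center: tuple[int, int, int]) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return dist2 <= radius ** 2


def _blob_center(shape: tuple[int, int, int], functional: bool
                 ) -> tuple[int, int, int]:
    # structural blob sits forward of centre, functional behind it
    off = -shape[0] // 4 if functional else shape[0] // 4
    return (shape[0] // 2 + off // 2, shape[1] // 2, shape[2] // 2)


def gen_volume(label: int, spec: CohortSpec, rng: np.random.Generator,
               subject_id: str = "") -> VolumeImage:
    """Structural volume: N(0, noise_sd) background + class-1 blob."""
    data = rng.normal(0.0, spec.noise_sd, spec.volume_shape)
    if label == 1 and spec.blob_contrast > 0:
        mask = _blob_mask(spec.volume_shape, spec.blob_radius,
                          _blob_center(spec.volume_shape, functional=False))
        data[mask] += spec.blob_contrast
    return VolumeImage(data=data, spacing=spec.spacing, subject_id=subject_id)


def gen_functional_volume(label: int, spec: CohortSpec,
                          rng: np.random.Generator) -> np.ndarray:
    """4D functional series: class-dependent pattern + per-frame noise."""
    pattern = np.zeros(spec.volume_shape)
    if label == 1 and spec.blob_contrast > 0:
        mask = _blob_mask(spec.volume_shape, spec.blob_radius,
                          _blob_center(spec.volume_shape, functional=True))
        pattern[mask] = spec.blob_contrast
    frames = pattern[..., None] + rng.normal(
        0.0, spec.noise_sd, spec.volume_shape + (spec.n_frames,))
    return frames


def gen_timeseries(label: int, atlas: AtlasSpec, spec: CohortSpec,
                   rng: np.random.Generator) -> np.ndarray:
    """Latent-factor ROI series with class-dependent cross-module coupling.

    Pairs are split into two modules (a pair's left and right regions
    share a module). Region i in module m follows
    ``z_m + rho_c * z_other + b * u_pair(i) + noise`` with
    ``rho_c = rho + delta_r * label``.
    """
    n_pairs = len(atlas.homolog_pairs)
    t = spec.n_timepoints
    rho_c = spec.rho + spec.delta_r * label
    z = rng.normal(0.0, 1.0, (2, t))                     # module factors
    u = rng.normal(0.0, 1.0, (n_pairs, t))               # bilateral factors
    noise = rng.normal(0.0, spec.noise_sd, (atlas.n_regions, t))
    ts = np.empty((atlas.n_regions, t))
    module_of_pair = (np.arange(n_pairs) < n_pairs // 2).astype(int)
    for p, (left, right) in enumerate(atlas.homolog_pairs):
        m = module_of_pair[p]
        base = z[m] + rho_c * z[1 - m] + spec.bilateral_loading * u[p]
        ts[left] = base + noise[left]
        ts[right] = base + noise[right]
    return ts


@dataclass
class Cohort:
    """In-memory synthetic cohort in the exact layout the pipeline consumes."""

    spec: CohortSpec
    records: list[SubjectRecord]
    smri: np.ndarray                     # n x D x H x W
    fmri: np.ndarray                     # n x D x H x W x frames
    timeseries: dict[str, np.ndarray]    # atlas -> n x regions x T
    atlases: list[AtlasSpec] = field(default_factory=list)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records])


def gen_cohort(spec: CohortSpec) -> Cohort:
    """Generate a full cohort deterministically from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    labels = np.zeros(n, dtype=int)
    labels[:spec.cases] = 1
    rng.shuffle(labels)
    sites = [f"site{chr(ord('A') + i)}" for i in range(spec.n_sites)]
    atlases = spec.atlases()

    records: list[SubjectRecord] = []
    smri = np.empty((n,) + spec.volume_shape)
    fmri = np.empty((n,) + spec.volume_shape + (spec.n_frames,))
    ts = {a.name: np.empty((n, a.n_regions, spec.n_timepoints)) for a in atlases}
    for i in range(n):
        label = int(labels[i])
        # class-correlated site assignment: with probability site_class_corr
        # the subject goes to a class-preferred site, else uniform
        if spec.n_sites > 1 and rng.random() < spec.site_class_corr:
            site = sites[label % spec.n_sites]
        else:
            site = sites[rng.integers(spec.n_sites)]
        sid = f"sub-{i:04d}"
        records.append(SubjectRecord(
            subject_id=sid, label=label, site=site,
            sex="M" if rng.random() < 0.5 else "F",
            age=float(np.round(rng.uniform(7, 40), 1)),
            iq=float(np.round(rng.normal(105, 15), 1))))
        smri[i] = gen_volume(label, spec, rng, subject_id=sid).data
        fmri[i] = gen_functional_volume(label, spec, rng)
        for atlas in atlases:
            ts[atlas.name][i] = gen_timeseries(label, atlas, spec, rng)
    return Cohort(spec=spec, records=records, smri=smri, fmri=fmri,
                  timeseries=ts, atlases=atlases)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Materialise a cohort on disk (NIfTI volumes, CSV tables, manifest)."""
    out = Path(out_dir)
    (out / "volumes").mkdir(parents=True, exist_ok=True)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(cohort.spec.spacing) + [1.0])
    for i, rec in enumerate(cohort.records):
        sid = rec.subject_id
        smri_path = out / "volumes" / f"{sid}_smri.nii"
        fmri_path = out / "volumes" / f"{sid}_fmri.nii"
        nib.save(nib.Nifti1Image(cohort.smri[i].astype(np.float32), affine),
                 str(smri_path))
        nib.save(nib.Nifti1Image(cohort.fmri[i].astype(np.float32), affine),
                 str(fmri_path))
        rec.smri_path = str(smri_path)
        rec.fmri_path = str(fmri_path)
        for atlas in cohort.atlases:
            ts_path = out / "timeseries" / f"{sid}_{atlas.name}.csv"
            np.savetxt(ts_path, cohort.timeseries[atlas.name][i],
                       delimiter=",", fmt="%.6f")
            rec.timeseries_paths[atlas.name] = str(ts_path)
    manifest = out / "manifest.csv"
    write_manifest(cohort.records, manifest)
    spec_dict = {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in vars(cohort.spec).items()}
    (out / "cohort.yaml").write_text(yaml.safe_dump(spec_dict, sort_keys=True))
    return manifest


def load_cohort(manifest_path: str | Path) -> Cohort:
    """Reload a materialised cohort (manifest + sidecar spec) from disk."""
    manifest_path = Path(manifest_path)
    spec_file = manifest_path.parent / "cohort.yaml"
    if not spec_file.exists():
        raise LoadError(f"cohort spec sidecar not found: {spec_file}")
    raw = yaml.safe_load(spec_file.read_text())
    for key in ("volume_shape", "atlas_names", "spacing"):
        raw[key] = tuple(raw[key])
    spec = CohortSpec(**raw)
    records = load_manifest(manifest_path)
    atlases = spec.atlases()
    n = len(records)
    smri = np.empty((n,) + spec.volume_shape)
    fmri = np.empty((n,) + spec.volume_shape + (spec.n_frames,))
    ts = {a.name: np.empty((n, a.n_regions, spec.n_timepoints)) for a in atlases}
    for i, rec in enumerate(records):
        smri[i] = read_volume(rec.smri_path, subject_id=rec.subject_id).data
        fdata = np.asarray(nib.load(rec.fmri_path).dataobj, dtype=np.float64)
        if fdata.ndim != 4:
            raise LoadError(f"{rec.fmri_path}: expected a 4D functional volume")
        fmri[i] = fdata
        for atlas in atlases:
            ts[atlas.name][i] = read_timeseries(rec.timeseries_paths[atlas.name],
                                                atlas)
    return Cohort(spec=spec, records=records, smri=smri, fmri=fmri,
                  timeseries=ts, atlases=atlases)
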