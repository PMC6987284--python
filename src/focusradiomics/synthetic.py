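"""Synthetic dynamic contrast-enhanced (DCE) breast-MRI cohorts.

Real enhancing foci are tiny (< 5 mm) dots of contrast uptake whose
time-intensity curves carry the diagnostic signal: benign foci tend to
enhance slowly and persistently, malignant ones show a fast wash-in
followed by wash-out.  This module builds volumetric phantoms with exactly
that structure — an ellipsoidal lesion with a known kinetic curve and
spatial texture inside a smooth parenchyma-like background — so that every
downstream stage (registration, feature extraction, selection,
classification, reporting) can be exercised with known ground truth.

The kinetic model is a three-parameter closed form

    e(t) = A · (1 − exp(−k_in · t)) · exp(−k_out · t)

with amplitude ``A`` (relative to baseline), wash-in rate ``k_in`` and
wash-out rate ``k_out`` (``k_out = 0`` gives a persistent, monotonically
rising curve).  Lesion voxels follow ``baseline · (1 + e(t))`` modulated by
a zero-mean spatial texture field, so the noiseless masked mean reproduces
the curve exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .affine import Affine2D, resample_slice

BENIGN = "benign"
MALIGNANT = "malignant"

#: acquisition time grid in minutes (one unenhanced + four enhanced, 60 s apart)
TIME_POINTS = (0.0, 1.0, 2.0, 3.0, 4.0)


@dataclass(frozen=True)
class KineticParams:
    """Parameters of the lesion enhancement curve.

    baseline_intensity : arbitrary signal units, > 0
    wash_in_amplitude  : peak-scale enhancement as a fraction of baseline, >= 0
    wash_in_rate       : 1/min, >= 0
    wash_out_rate      : 1/min, >= 0 (0 for persistent curves)
    time_points        : minutes, strictly increasing, first = 0
    """

    baseline_intensity: float
    wash_in_amplitude: float
    wash_in_rate: float
    wash_out_rate: float = 0.0
    time_points: tuple = TIME_POINTS

    def __post_init__(self) -> None:
        if self.baseline_intensity <= 0:
            raise ValueError("baseline_intensity must be > 0")
        if self.wash_in_amplitude < 0:
            raise ValueError("wash_in_amplitude must be >= 0")
        if self.wash_in_rate < 0 or self.wash_out_rate < 0:
            raise ValueError("rates must be >= 0")
        t = np.asarray(self.time_points, dtype=float)
        if t.size != 5 or t[0] != 0.0 or np.any(np.diff(t) <= 0):
            raise ValueError("time_points must be length 5, start at 0, "
                             "strictly increasing")
        object.__setattr__(self, "time_points", tuple(float(x) for x in t))


def kinetic_curve(p: KineticParams) -> np.ndarray:
    """Relative enhancement e(t) at the five acquisition times (e(0) = 0)."""
    t = np.asarray(p.time_points, dtype=float)
    return (p.wash_in_amplitude
            * (1.0 - np.exp(-p.wash_in_rate * t))
            * np.exp(-p.wash_out_rate * t))


#: default class kinetics: slow persistent enhancement for benign foci,
#: fast wash-in + wash-out for malignant ones.
DEFAULT_KINETICS = {
    BENIGN: KineticParams(baseline_intensity=100.0, wash_in_amplitude=0.8,
                          wash_in_rate=0.7, wash_out_rate=0.0),
    MALIGNANT: KineticParams(baseline_intensity=100.0, wash_in_amplitude=1.2,
                             wash_in_rate=3.0, wash_out_rate=0.4),
}


def _per_class(value, name: str) -> dict:
    if isinstance(value, dict):
        out = {BENIGN: float(value[BENIGN]) if not isinstance(value[BENIGN], tuple)
               else value[BENIGN],
               MALIGNANT: value[MALIGNANT]}
        return {k: v for k, v in out.items()}
    return {BENIGN: value, MALIGNANT: value}


@dataclass
class CohortConfig:
    """Study-condition knobs for a synthetic cohort.

    Defaults emulate the acquisition geometry the pipeline is meant for:
    1 mm slices, 1x1 mm in-plane, a 60 s dynamic grid, and sub-5-mm foci.
    """

    n_benign: int = 20
    n_malignant: int = 20
    volume_shape: tuple = (24, 32, 32)            # voxels, (z, y, x)
    voxel_spacing: tuple = (1.0, 1.0, 1.0)        # mm, (z, y, x)
    #: per-class (min, max) lesion diameter in mm; foci are < 5 mm
    lesion_diameter_range: dict = field(
        default_factory=lambda: {BENIGN: (3.5, 5.0), MALIGNANT: (3.5, 5.0)})
    noise_sigma: float = 2.0                       # signal units, per volume
    #: per-class texture scale: SD of the multiplicative lesion texture field
    texture_heterogeneity: dict = field(
        default_factory=lambda: {BENIGN: 0.05, MALIGNANT: 0.15})
    motion_amplitude: float = 0.0                  # pixels; 0 disables motion
    seed: int = 0
    kinetics: dict = field(default_factory=lambda: dict(DEFAULT_KINETICS))
    kinetic_jitter: float = 0.1        # relative per-case parameter jitter
    background_mean: float = 60.0      # parenchyma signal level
    background_texture: float = 8.0    # SD of smoothed background field
    background_smoothness: float = 3.0  # Gaussian sigma, voxels

    def __post_init__(self) -> None:
        if self.n_benign < 1 or self.n_malignant < 1:
            raise ValueError("both classes must be present (n >= 1 each)")
        if self.n_benign + self.n_malignant < 2:
            raise ValueError("need at least 2 cases")
        if len(self.volume_shape) != 3 or min(self.volume_shape) < 4:
            raise ValueError("volume_shape must be 3D and at least 4 voxels "
                             "per axis")
        if self.noise_sigma < 0 or self.motion_amplitude < 0:
            raise ValueError("noise_sigma and motion_amplitude must be >= 0")
        self.lesion_diameter_range = _per_class(self.lesion_diameter_range,
                                                "lesion_diameter_range")
        self.texture_heterogeneity = _per_class(self.texture_heterogeneity,
                                                "texture_heterogeneity")
        for cls, rng_ in self.lesion_diameter_range.items():
            lo, hi = rng_
            if not (0 < lo <= hi):
                raise ValueError("lesion diameters must be positive, lo <= hi")
        for cls, h in self.texture_heterogeneity.items():
            if h < 0:
                raise ValueError("texture_heterogeneity must be >= 0")


@dataclass
class DynamicSeries:
    """Five spatially aligned 3D volumes: T0 unenhanced + T1-T4 enhanced."""

    data: np.ndarray          # (5, nz, ny, nx), float
    spacing: tuple            # mm, (z, y, x)
    times: tuple = TIME_POINTS  # minutes

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[0] != 5:
            raise ValueError("series must hold exactly 5 volumes")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.times = tuple(float(t) for t in self.times)

    @property
    def shape(self) -> tuple:
        return self.data.shape[1:]


@dataclass
class LesionMask:
    """One binary lesion mask per series, aligned to it."""

    data: np.ndarray          # (nz, ny, nx), bool
    spacing: tuple

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.spacing = tuple(float(s) for s in self.spacing)


@dataclass
class SyntheticCase:
    series: DynamicSeries
    mask: LesionMask
    label: str
    truth: dict
    case_id: str = "case"


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random 3D rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _jitter(rng: np.random.Generator, value: float, rel: float) -> float:
    return value * (1.0 + rel * rng.uniform(-1.0, 1.0))


def generate_case(class_label: str, cfg: CohortConfig,
                  rng: np.random.Generator,
                  case_id: str = "case") -> SyntheticCase:
    """Build one synthetic DCE case of the given class.

    The lesion is a randomly oriented ellipsoid with per-axis diameters drawn
    from the class range; lesion voxels follow the class kinetic curve times
    a zero-mean spatial texture modulation; independent Gaussian noise is
    added per volume.  All ground truth is stored in ``truth``.
    """
    if class_label not in (BENIGN, MALIGNANT):
        raise ValueError(f"unknown class label {class_label!r}")
    shape = tuple(cfg.volume_shape)
    spacing = np.asarray(cfg.voxel_spacing, dtype=float)
    size_mm = (np.asarray(shape) - 1) * spacing

    base = cfg.kinetics[class_label]
    kin = KineticParams(
        baseline_intensity=_jitter(rng, base.baseline_intensity, cfg.kinetic_jitter),
        wash_in_amplitude=_jitter(rng, base.wash_in_amplitude, cfg.kinetic_jitter),
        wash_in_rate=_jitter(rng, base.wash_in_rate, cfg.kinetic_jitter),
        wash_out_rate=_jitter(rng, base.wash_out_rate, cfg.kinetic_jitter),
        time_points=base.time_points,
    )

    lo, hi = cfg.lesion_diameter_range[class_label]
    semi = rng.uniform(lo, hi, size=3) / 2.0          # per-axis semi-axes, mm
    rot = _random_rotation(rng)
    r_max = float(semi.max())
    lo_c = r_max + spacing
    hi_c = size_mm - r_max - spacing
    if np.any(hi_c < lo_c):
        raise ValueError("lesion does not fit inside the volume")
    center = rng.uniform(lo_c, hi_c)

    zz, yy, xx = np.meshgrid(*(np.arange(n) * s for n, s in zip(shape, spacing)),
                             indexing="ij")
    rel = np.stack([zz - center[0], yy - center[1], xx - center[2]], axis=-1)
    u = rel @ rot                                     # into lesion frame
    mask = (u ** 2 / semi ** 2).sum(axis=-1) <= 1.0
    if not mask.any():
        raise ValueError("lesion does not fit inside the volume")

    bg_field = ndimage.gaussian_filter(rng.normal(size=shape),
                                       cfg.background_smoothness)
    bg_sd = bg_field.std()
    if bg_sd > 0:
        bg_field = bg_field / bg_sd     # unit SD so background_texture is in
    background = cfg.background_mean + cfg.background_texture * bg_field

    tex = ndimage.gaussian_filter(rng.normal(size=shape), 1.0)
    tex_m = tex[mask]
    tex = tex - tex_m.mean()                # exactly zero-mean inside mask
    sd = tex_m.std()
    if sd > 0:
        tex = tex / sd
    h = cfg.texture_heterogeneity[class_label]

    curve = kinetic_curve(kin)
    data = np.empty((5,) + shape, dtype=float)
    for ti in range(5):
        vol = background.copy()
        vol[mask] = kin.baseline_intensity * (1.0 + curve[ti]) * (1.0 + h * tex[mask])
        if cfg.noise_sigma > 0:
            vol = vol + rng.normal(0.0, cfg.noise_sigma, size=shape)
        data[ti] = vol

    series = DynamicSeries(data, tuple(spacing), base.time_points)
    n_slices = shape[0]
    truth = {
        "kinetics": kin,
        "enhancement_curve": curve.tolist(),
        "semi_axes_mm": semi.tolist(),
        "rotation": rot.tolist(),
        "center_mm": center.tolist(),
        "motion": [[Affine2D.identity() for _ in range(n_slices)]
                   for _ in range(4)],
    }
    case = SyntheticCase(series, LesionMask(mask, tuple(spacing)),
                         class_label, truth, case_id)
    if cfg.motion_amplitude > 0:
        case = inject_motion(case, cfg.motion_amplitude, rng)
    return case


def inject_motion(case: SyntheticCase, amplitude: float,
                  rng: np.random.Generator) -> SyntheticCase:
    """Resample each slice of T1-T4 under a random small 2D affine.

    Translation components are uniform in [-amplitude, amplitude] pixels;
    rotation (up to 2 degrees) and shear (up to 0.02) are added whenever
    amplitude > 0.  T0 is untouched.  The true pull-back transforms are
    recorded in ``truth['motion'][t-1][z]`` for recovery experiments.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if amplitude == 0:
        return case
    data = case.series.data.copy()
    n_slices = data.shape[1]
    c = (np.asarray(data.shape[2:], dtype=float) - 1.0) / 2.0
    motion = []
    for ti in range(1, 5):
        per_slice = []
        for z in range(n_slices):
            t = rng.uniform(-amplitude, amplitude, size=2)
            angle = np.deg2rad(rng.uniform(-2.0, 2.0))
            shear = rng.uniform(-0.02, 0.02)
            rotm = np.array([[np.cos(angle), -np.sin(angle)],
                             [np.sin(angle), np.cos(angle)]])
            m = rotm @ np.array([[1.0, shear], [0.0, 1.0]])
            trans = c - m @ c + t       # rotate/shear about the slice centre
            aff = Affine2D(m, trans)
            data[ti, z] = resample_slice(data[ti, z], aff)
            per_slice.append(aff)
        motion.append(per_slice)
    truth = dict(case.truth)
    truth["motion"] = motion
    series = DynamicSeries(data, case.series.spacing, case.series.times)
    return SyntheticCase(series, case.mask, case.label, truth, case.case_id)


def apply_slice_transforms(series: DynamicSeries,
                           transforms: list) -> DynamicSeries:
    """Resample every slice of T1-T4 under the given per-slice transforms
    (``transforms[t-1][z]``); used e.g. to undo recorded motion with the
    inverse transforms."""
    data = series.data.copy()
    for ti in range(1, 5):
        for z in range(data.shape[1]):
            data[ti, z] = resample_slice(data[ti, z], transforms[ti - 1][z])
    return DynamicSeries(data, series.spacing, series.times)


def generate_cohort(cfg: CohortConfig) -> list:
    """Generate the full cohort; per-case RNG streams are spawned from
    ``cfg.seed`` so cohorts are reproducible and order-independent."""
    labels = [BENIGN] * cfg.n_benign + [MALIGNANT] * cfg.n_malignant
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(len(labels))
    return [generate_case(lab, cfg, np.random.default_rng(ch),
                          case_id=f"case{idx:03d}")
            for idx, (lab, ch) in enumerate(zip(labels, children))]


# ---------------------------------------------------------------------------
# NIfTI + JSON persistence
# ---------------------------------------------------------------------------

def _nifti_affine(spacing: tuple) -> np.ndarray:
    # arrays are (z, y, x); NIfTI wants (x, y, z)
    sz, sy, sx = spacing
    return np.diag([sx, sy, sz, 1.0])


def save_case(case: SyntheticCase, out_dir) -> Path:
    """Write t0.nii.gz … t4.nii.gz, mask.nii.gz and a JSON sidecar."""
    out = Path(out_dir) / case.case_id
    out.mkdir(parents=True, exist_ok=True)
    aff = _nifti_affine(case.series.spacing)
    for ti in range(5):
        img = nib.Nifti1Image(
            np.ascontiguousarray(case.series.data[ti].T.astype(np.float32)), aff)
        nib.save(img, out / f"t{ti}.nii.gz")
    mimg = nib.Nifti1Image(
        np.ascontiguousarray(case.mask.data.T.astype(np.uint8)), aff)
    nib.save(mimg, out / "mask.nii.gz")
    truth = case.truth
    sidecar = {
        "case_id": case.case_id,
        "label": case.label,
        "spacing_zyx_mm": list(case.series.spacing),
        "times_min": list(case.series.times),
        "kinetics": dataclasses.asdict(truth["kinetics"]),
        "enhancement_curve": truth.get("enhancement_curve"),
        "semi_axes_mm": truth.get("semi_axes_mm"),
        "rotation": truth.get("rotation"),
        "center_mm": truth.get("center_mm"),
        "motion": [[a.to_dict() for a in per_t] for per_t in truth["motion"]],
    }
    (out / "case.json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return out


def load_case(case_dir) -> SyntheticCase:
    """Load a case previously written by :func:`save_case`."""
    d = Path(case_dir)
    meta = json.loads((d / "case.json").read_text())
    vols = []
    for ti in range(5):
        img = nib.load(d / f"t{ti}.nii.gz")
        vols.append(np.asarray(img.dataobj, dtype=float).T)
    mask = np.asarray(nib.load(d / "mask.nii.gz").dataobj).T.astype(bool)
    spacing = tuple(meta["spacing_zyx_mm"])
    kin = meta["kinetics"]
    kin["time_points"] = tuple(kin["time_points"])
    truth = {
        "kinetics": KineticParams(**kin),
        "enhancement_curve": meta.get("enhancement_curve"),
        "semi_axes_mm": meta.get("semi_axes_mm"),
        "rotation": meta.get("rotation"),
        "center_mm": meta.get("center_mm"),
        "motion": [[Affine2D.from_dict(a) for a in per_t]
                   for per_t in meta["motion"]],
    }
    series = DynamicSeries(np.stack(vols), spacing, tuple(meta["times_min"]))
    return SyntheticCase(series, LesionMask(mask, spacing), meta["label"],
                         truth, meta["case_id"])


def save_cohort(cases: list, out_dir) -> list:
    return [save_case(c, out_dir) for c in cases]


def load_cohort(in_dir) -> list:
    root = Path(in_dir)
    dirs = sorted(p for p in root.iterdir() if (p / "case.json").exists())
    return [load_case(p) for p in dirs]


# ---------------------------------------------------------------------------
# Tabular generator for selection experiments
# ---------------------------------------------------------------------------

def planted_feature_table(n_per_class: int = 30, n_informative: int = 3,
                          n_noise: int = 50, effect_size: float = 2.0,
                          seed: int = 0):
    """Feature table with a known informative subset.

    Informative features are unit-variance Gaussians whose class means differ
    by ``effect_size`` standard deviations; noise features are pure N(0, 1).
    Returns a DataFrame shaped like the radiomic feature table (features +
    'label' column), with informative columns named ``info_00`` … and noise
    columns ``noise_00`` ….
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    y = np.array([0] * n_per_class + [1] * n_per_class)
    info = rng.normal(size=(n, n_informative)) + effect_size * y[:, None]
    noise = rng.normal(size=(n, n_noise))
    cols = {f"info_{i:02d}": info[:, i] for i in range(n_informative)}
    cols.update({f"noise_{i:02d}": noise[:, i] for i in range(n_noise)})
    df = pd.DataFrame(cols, index=[f"case{i:03d}" for i in range(n)])
    df["label"] = np.where(y == 1, MALIGNANT, BENIGN)
    return df
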