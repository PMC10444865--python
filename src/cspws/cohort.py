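"""Synthetic labeled cohorts of patients, cells and packing-scaling D images.

Generates the statistical structure the downstream analysis assumes, so
every stage is testable without clinical data:

* a hierarchical patient model — per-patient mean nuclear D with a
  case-control shift, a weak negative age trend, and between-patient /
  between-cell dispersion, all truncated to the physical range [5/3, 3];
* demographics (age, pack-years, gender, race) drawn per group;
* per-cell D images: an elliptical nucleus on a fixed canvas carrying
  correlated Gaussian texture plus sub-pixel packing-domain events whose
  rate increases with D (higher packing scaling means more, denser packing
  domains per unit area, i.e. greater sub-nuclear heterogeneity);
* optionally, full interference spectral cubes through the forward optical
  model for small end-to-end runs.

Because every nucleus image is min-max normalized before feature
extraction, the absolute D level of a cell is not visible to the classifier;
the packing-domain event rate is the generator's physically motivated carrier
of group signal through that normalization.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from . import dmap
from .dmap import D_LOWER, D_UPPER, AcfModel, DImage
from .instrument import (
    GridSpec,
    InstrumentConfig,
    default_cell_grid,
    save_float_image,
    save_spectral_cube,
)

__all__ = [
    "CohortSpec",
    "PatientRecord",
    "CohortManifest",
    "sample_patient",
    "sample_domain_radii",
    "render_d_image",
    "render_patient_cells",
    "generate_manifest",
    "generate_cohort",
    "generate_spectral_cohort",
    "save_mask_png",
    "load_mask_png",
]


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of a synthetic cohort.

    Demographic defaults follow the Site-1 cohort table (control age
    59 +- 11, case 67 +- 12; pack-years 35 +- 26 vs 37 +- 30; 49 % / 56 %
    female; 80 % Caucasian in both groups).  The case age distribution is
    deliberately offset so age-confounding analyses are meaningful.  D is
    dimensionless; ages in years; lengths in nm.
    """

    n_case: int = 42
    n_control: int = 40
    cells_per_patient: int = 30
    baseline_d: float = 2.0
    effect_delta_d: float = 0.2
    between_patient_sd: float = 0.12
    between_cell_sd: float = 0.08
    age_slope_per_year: float = -0.006
    age_mean_control: float = 59.0
    age_sd_control: float = 11.0
    age_mean_case: float = 67.0
    age_sd_case: float = 12.0
    pct_female_control: float = 0.49
    pct_female_case: float = 0.56
    pct_caucasian_control: float = 0.80
    pct_caucasian_case: float = 0.80
    packyear_mean_control: float = 35.0
    packyear_sd_control: float = 26.0
    packyear_mean_case: float = 37.0
    packyear_sd_case: float = 30.0
    image_width: int = 960
    image_height: int = 720
    pixel_nm: float = 250.0
    nucleus_radius_px_mean: float = 22.0
    nucleus_radius_px_sd: float = 2.5
    nucleus_min_axis_ratio: float = 0.7
    texture_correlation_nm: float = 750.0
    texture_sd: float = 0.06
    domain_radius_mean_nm: float = 80.0
    domain_radius_sd_nm: float = 20.0
    domain_rate_per_px: float = 1.0
    domain_amp_d: float = 0.08
    site: str = "site1"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_case, self.n_control, self.cells_per_patient) <= 0:
            raise ValueError("patient and cell counts must be positive")
        if not (D_LOWER <= self.baseline_d <= D_UPPER):
            raise ValueError("baseline_d outside [5/3, 3]")
        for name in ("between_patient_sd", "between_cell_sd", "texture_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.image_width < 64 or self.image_height < 64:
            raise ValueError("canvas too small for a nucleus")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PatientRecord:
    patient_id: str
    site: str
    group: str  # "case" | "control"
    true_mean_d: float
    age: float
    pack_years: float
    gender: str  # "F" | "M"
    race: str  # "caucasian" | "other"
    cell_seed: int
    image_paths: list = field(default_factory=list)
    mask_paths: list = field(default_factory=list)


@dataclass
class CohortManifest:
    patients: list
    spec: CohortSpec
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            if p.image_paths:
                for j, (ip, mp) in enumerate(zip(p.image_paths, p.mask_paths)):
                    rows.append(
                        dict(
                            patient_id=p.patient_id, site=p.site, group=p.group,
                            age=p.age, pack_years=p.pack_years, gender=p.gender,
                            race=p.race, cell_id=f"{p.patient_id}_c{j:03d}",
                            image_path=str(ip), mask_path=str(mp),
                        )
                    )
            else:
                rows.append(
                    dict(
                        patient_id=p.patient_id, site=p.site, group=p.group,
                        age=p.age, pack_years=p.pack_years, gender=p.gender,
                        race=p.race, cell_id="", image_path="", mask_path="",
                    )
                )
        return pd.DataFrame(rows)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float) -> float:
    """Truncated-normal draw (not clip-after-the-fact), degenerate sd allowed."""
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def sample_patient(spec: CohortSpec, group: str, rng: np.random.Generator,
                   index: int = 0) -> PatientRecord:
    """Draw one patient: demographics and the true mean nuclear D.

    true_mean_d = baseline + effect (cases) + age_slope * (age - control mean
    age) + N(0, between_patient_sd^2), truncated to [5/3, 3].
    """
    if group not in ("case", "control"):
        raise ValueError(f"unknown group {group!r}")
    case = group == "case"
    age = _truncnorm(
        rng,
        spec.age_mean_case if case else spec.age_mean_control,
        spec.age_sd_case if case else spec.age_sd_control,
        18.0, 100.0,
    )
    pack_years = _truncnorm(
        rng,
        spec.packyear_mean_case if case else spec.packyear_mean_control,
        spec.packyear_sd_case if case else spec.packyear_sd_control,
        0.0, np.inf,
    )
    gender = "F" if rng.random() < (
        spec.pct_female_case if case else spec.pct_female_control) else "M"
    race = "caucasian" if rng.random() < (
        spec.pct_caucasian_case if case else spec.pct_caucasian_control) else "other"
    center = (
        spec.baseline_d
        + (spec.effect_delta_d if case else 0.0)
        + spec.age_slope_per_year * (age - spec.age_mean_control)
    )
    true_mean_d = _truncnorm(rng, center, spec.between_patient_sd, D_LOWER, D_UPPER)
    return PatientRecord(
        patient_id=f"{'C' if case else 'N'}{index:04d}",
        site=spec.site,
        group=group,
        true_mean_d=true_mean_d,
        age=age,
        pack_years=pack_years,
        gender=gender,
        race=race,
        cell_seed=int(rng.integers(0, 2**31 - 1)),
    )


def sample_domain_radii(spec: CohortSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Packing-domain radii (nm): lognormal with the configured mean and SD."""
    m, s = spec.domain_radius_mean_nm, spec.domain_radius_sd_nm
    sigma2 = np.log1p((s / m) ** 2)
    mu = np.log(m) - 0.5 * sigma2
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)


_D_MID = 2.25  # family midpoint at which the domain parameters equal the spec values


def _domain_rate(spec: CohortSpec, cell_mean_d: float) -> float:
    """Per-pixel packing-domain event rate, increasing linearly with D."""
    return spec.domain_rate_per_px * (cell_mean_d - D_LOWER) / (_D_MID - D_LOWER)


def _domain_amp(spec: CohortSpec, cell_mean_d: float) -> float:
    """Per-event D kick, increasing linearly with D.

    Higher packing scaling means a steeper radial density profile within a
    domain — denser cores — so both the number of domain events per pixel
    and their individual contrast grow with D.
    """
    return spec.domain_amp_d * (cell_mean_d - D_LOWER) / (_D_MID - D_LOWER)


def render_d_image(cell_mean_d: float, spec: CohortSpec,
                   rng: np.random.Generator) -> tuple[DImage, np.ndarray]:
    """Render one nucleus: elliptical mask + textured D values on the canvas.

    In-mask D = cell_mean_d + correlated Gaussian texture + centred compound-
    Poisson packing-domain field (sub-pixel domains modulate local amplitude
    rather than appear as resolved blobs), truncated to [5/3, 3]; background
    is NaN.  The domain event rate grows with D, so higher-D nuclei carry a
    more positively skewed, heavier texture.
    """
    if not (D_LOWER <= cell_mean_d <= D_UPPER):
        raise ValueError("cell_mean_d outside [5/3, 3]")
    h, w = spec.image_height, spec.image_width
    # nucleus geometry; kept away from the canvas border
    a = max(_truncnorm(rng, spec.nucleus_radius_px_mean, spec.nucleus_radius_px_sd,
                       6.0, min(h, w) / 3.0), 6.0)
    b = a * rng.uniform(spec.nucleus_min_axis_ratio, 1.0)
    theta = rng.uniform(0.0, np.pi)
    margin = int(np.ceil(a)) + 3
    cy = rng.uniform(margin, h - margin)
    cx = rng.uniform(margin, w - margin)

    yy, xx = np.mgrid[0:h, 0:w]
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0

    d = np.full((h, w), np.nan, dtype=np.float32)
    ys, xs = np.nonzero(mask)
    y0, y1, x0, x1 = ys.min(), ys.max() + 1, xs.min(), xs.max() + 1
    bh, bw = y1 - y0, x1 - x0
    sub = mask[y0:y1, x0:x1]

    # correlated Gaussian texture, unit variance then scaled
    tex = np.zeros((bh, bw), dtype=np.float64)
    if spec.texture_sd > 0:
        corr_px = spec.texture_correlation_nm / spec.pixel_nm
        white = rng.standard_normal((bh, bw))
        tex = ndimage.gaussian_filter(white, corr_px, mode="reflect")
        tex /= np.sqrt(max(tex.var(), 1e-30))
        tex *= spec.texture_sd

    # sub-pixel packing-domain events: centred compound Poisson
    dom = np.zeros((bh, bw), dtype=np.float64)
    if spec.domain_amp_d > 0 and spec.domain_rate_per_px > 0:
        lam = _domain_rate(spec, cell_mean_d)
        amp = _domain_amp(spec, cell_mean_d)
        counts = rng.poisson(lam, size=(bh, bw))
        total = int(counts.sum())
        if total:
            radii = sample_domain_radii(spec, total, rng)
            # event weight scales with domain volume, normalized to unit mean
            m, s = spec.domain_radius_mean_nm, spec.domain_radius_sd_nm
            sigma2 = np.log1p((s / m) ** 2)
            mean_r3 = np.exp(3 * (np.log(m) - 0.5 * sigma2) + 4.5 * sigma2)
            kicks = amp * (radii**3 / mean_r3)
            flat = np.repeat(np.arange(bh * bw), counts.ravel())
            dom = np.bincount(flat, weights=kicks, minlength=bh * bw).reshape(bh, bw)
        dom -= lam * amp  # centre so the in-mask mean is unbiased

    vals = np.clip(cell_mean_d + tex + dom, D_LOWER, D_UPPER)
    block = d[y0:y1, x0:x1]
    block[sub] = vals[sub].astype(np.float32)
    d[y0:y1, x0:x1] = block
    clamped = float(
        np.mean((vals[sub] <= D_LOWER) | (vals[sub] >= D_UPPER))
    )
    return DImage(d=d, mask=mask, clamped_fraction=clamped), mask


def render_patient_cells(record: PatientRecord, spec: CohortSpec):
    """Yield (cell_index, DImage, mask) for one patient, deterministically.

    Per-cell mean D is a truncated-normal draw around the patient's true
    mean with ``between_cell_sd`` dispersion.
    """
    rng = np.random.default_rng(record.cell_seed)
    for j in range(spec.cells_per_patient):
        cell_d = _truncnorm(rng, record.true_mean_d, spec.between_cell_sd,
                            D_LOWER, D_UPPER)
        dimg, mask = render_d_image(cell_d, spec, rng)
        yield j, dimg, mask


def generate_manifest(spec: CohortSpec) -> CohortManifest:
    """Patient-level cohort (no images): fully seeded, ids unique."""
    rng = np.random.default_rng(spec.seed)
    patients = [
        sample_patient(spec, "control", rng, index=i) for i in range(spec.n_control)
    ] + [
        sample_patient(spec, "case", rng, index=i) for i in range(spec.n_case)
    ]
    return CohortManifest(patients=patients, spec=spec, seed=spec.seed)


def save_mask_png(path, mask: np.ndarray) -> None:
    """8-bit PNG, 255 = nucleus."""
    from PIL import Image

    Image.fromarray((np.asarray(mask, bool) * 255).astype(np.uint8)).save(Path(path))


def load_mask_png(path) -> np.ndarray:
    from PIL import Image

    return np.asarray(Image.open(Path(path))) >= 128


def generate_cohort(spec: CohortSpec, out_dir) -> CohortManifest:
    """Write the full image cohort to disk and return its manifest.

    Layout: <out>/images/<patient>_c###.tif (float32 D image + JSON sidecar),
    <out>/masks/<patient>_c###.png, <out>/manifest.csv, <out>/cohort_spec.json.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    manifest = generate_manifest(spec)
    for rec in manifest.patients:
        for j, dimg, mask in render_patient_cells(rec, spec):
            stem = f"{rec.patient_id}_c{j:03d}"
            ipath = out / "images" / f"{stem}.tif"
            mpath = out / "masks" / f"{stem}.png"
            save_float_image(
                ipath, dimg.d,
                metadata={
                    "patient_id": rec.patient_id,
                    "cell_id": stem,
                    "clamped_fraction": dimg.clamped_fraction,
                    "kind": "d_image",
                },
            )
            save_mask_png(mpath, mask)
            # manifest paths are relative to the cohort directory (portable,
            # and identical runs in different directories stay bit-identical)
            rec.image_paths.append(str(ipath.relative_to(out)))
            rec.mask_paths.append(str(mpath.relative_to(out)))
    manifest.to_frame().to_csv(out / "manifest.csv", index=False)
    (out / "cohort_spec.json").write_text(
        json.dumps(spec.to_dict(), sort_keys=True, indent=1)
    )
    return manifest


def generate_spectral_cohort(
    spec: CohortSpec,
    instrument: InstrumentConfig,
    out_dir,
    acf_template: AcfModel | None = None,
    grid: GridSpec | None = None,
) -> CohortManifest:
    """End-to-end mode: per cell, a chromatin realization at the cell's D
    drives the interference simulator; cubes + sidecars are written to disk.

    Expensive (a full 3-D field per cell) — intended for small counts.
    """
    from .instrument import (
        density_to_ri,
        sample_chromatin_density,
        simulate_interference_cube,
    )

    out = Path(out_dir)
    (out / "cubes").mkdir(parents=True, exist_ok=True)
    template = acf_template if acf_template is not None else AcfModel(d_b=2.0)
    grid = grid if grid is not None else default_cell_grid()
    manifest = generate_manifest(spec)
    for rec in manifest.patients:
        rng = np.random.default_rng(rec.cell_seed)
        for j in range(spec.cells_per_patient):
            cell_d = _truncnorm(rng, rec.true_mean_d, spec.between_cell_sd,
                                D_LOWER, D_UPPER)
            model = dmap.domain_pinned_model(template, cell_d)
            seed = int(rng.integers(0, 2**31 - 1))
            realization = sample_chromatin_density(model, grid, seed)
            ri = density_to_ri(realization, instrument)
            cube = simulate_interference_cube(ri, grid, instrument)
            stem = f"{rec.patient_id}_c{j:03d}"
            cpath = out / "cubes" / f"{stem}.tif"
            save_spectral_cube(
                cpath, cube,
                metadata={
                    "patient_id": rec.patient_id,
                    "cell_id": stem,
                    "true_cell_d": cell_d,
                    "seed": seed,
                    "grid": grid.to_dict(),
                    "instrument": instrument.to_dict(),
                    "kind": "raw_interference_cube",
                },
            )
            rec.image_paths.append(str(cpath.relative_to(out)))
            rec.mask_paths.append("")
    manifest.to_frame().to_csv(out / "manifest.csv", index=False)
    (out / "cohort_spec.json").write_text(
        json.dumps(spec.to_dict(), sort_keys=True, indent=1)
    )
    return manifest
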