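"""Forward optical model for chromatin-sensitive partial wave spectroscopy (csPWS).

Simulates 3-D chromatin mass-density fields with a prescribed autocorrelation
function, converts density to refractive index (RI) via the Gladstone-Dale
relation n(r) = n_media + alpha * rho(r), and renders reference-normalized
interference spectral cubes from which the per-pixel spectral standard
deviation (Sigma) is computed.

The interference model is a 1-D first-Born axial backscatter sum per
transverse pixel: the measured reflectance at wavenumber k is
|r_ref + s(k)|^2 where r_ref is the Fresnel reflection coefficient of the
cell-glass interface and

    s(k) = i * k_m * sum_z  dn_blur(z) * exp(2 i k_m z) * w(z) * dz

with k_m the wavenumber in the intracellular medium, dn_blur the RI
fluctuation field blurred transversely by a Gaussian of FWHM equal to the
transverse coherence length, and w(z) a Gaussian depth-of-field window.
A homogeneous cell therefore yields a wavelength-flat spectrum and Sigma = 0.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "FWHM_TO_SIGMA",
    "DEFAULT_MEAN_CROWDING",
    "InstrumentConfig",
    "GridSpec",
    "ChromatinRealization",
    "SpectralCube",
    "SigmaImage",
    "make_default_instrument",
    "default_cell_grid",
    "sample_chromatin_density",
    "density_to_ri",
    "simulate_interference_cube",
    "make_reference_cube",
    "reference_normalize",
    "compute_sigma_image",
    "interior_mask",
    "save_spectral_cube",
    "load_spectral_cube",
    "save_float_image",
    "load_float_image",
]

#: Conversion between a Gaussian full width at half maximum and its sigma.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Default mean macromolecular crowding of chromatin (g/mL).  Only RI
#: *fluctuations* contribute to Sigma in this model; the mean sets the
#: Fresnel coefficient of the cell-glass interface.
DEFAULT_MEAN_CROWDING = 0.2


@dataclass(frozen=True)
class InstrumentConfig:
    """Illumination/collection geometry and spectral sampling of the instrument.

    Lengths are in nanometers.  ``ri_increment_alpha`` is the specific
    refraction increment (mL/g) relating macromolecular density to RI;
    ``n_media`` is the RI of the liquid cover (95% ethanol) and ``n_glass``
    that of the slide.
    """

    na_illumination: float = 0.6
    na_collection: float = 0.8
    wavelength_min_nm: float = 450.0
    wavelength_max_nm: float = 700.0
    wavelength_step_nm: float = 3.0
    n_media: float = 1.364
    n_glass: float = 1.517
    ri_increment_alpha: float = 0.18
    transverse_coherence_nm: float = 458.0
    depth_of_field_nm: float = 2874.0

    def __post_init__(self) -> None:
        if not (0.0 < self.na_illumination <= self.na_collection < self.n_media):
            raise ValueError(
                "require 0 < na_illumination <= na_collection < n_media, got "
                f"{self.na_illumination}, {self.na_collection}, {self.n_media}"
            )
        if not self.wavelength_min_nm < self.wavelength_max_nm:
            raise ValueError("wavelength_min_nm must be < wavelength_max_nm")
        for name in (
            "wavelength_min_nm",
            "wavelength_max_nm",
            "wavelength_step_nm",
            "transverse_coherence_nm",
            "depth_of_field_nm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def wavelengths_nm(self) -> np.ndarray:
        """Acquisition wavelength grid (ascending, inclusive of the minimum)."""
        return np.arange(
            self.wavelength_min_nm,
            self.wavelength_max_nm + 0.5 * self.wavelength_step_nm,
            self.wavelength_step_nm,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def make_default_instrument() -> InstrumentConfig:
    """Instrument with the published csPWS acquisition parameters."""
    return InstrumentConfig()


def default_cell_grid() -> "GridSpec":
    """Synthesis grid for single-cell forward simulations.

    11 nm voxels resolve the 23 nm fractal-regime lower bound; the axial
    extent (4.9 um) covers the depth-of-field window out to +-2 sigma and
    the transverse extent (2.1 um) is large enough that the reciprocal
    lattice resolves the transverse coherence cutoff, which controls the
    accuracy of the simulated Sigma (verified by convergence tests).
    """
    return GridSpec(nx=192, ny=192, nz=448, voxel_nm=11.0)


@dataclass(frozen=True)
class GridSpec:
    """Voxel grid for chromatin realizations. Arrays are indexed (y, x, z)."""

    nx: int
    ny: int
    nz: int
    voxel_nm: float

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) <= 0 or self.voxel_nm <= 0:
            raise ValueError("grid dimensions and voxel size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.ny, self.nx, self.nz)

    def extent_nm(self) -> tuple[float, float, float]:
        return (self.ny * self.voxel_nm, self.nx * self.voxel_nm, self.nz * self.voxel_nm)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ChromatinRealization:
    """A sampled chromatin density field rho(r) in g/mL (mean + fluctuation)."""

    density: np.ndarray  # (ny, nx, nz), float32
    grid: GridSpec
    true_acf: "object"  # AcfModel; typed loosely to avoid a circular import
    seed: int
    mean_crowding_g_ml: float = DEFAULT_MEAN_CROWDING


@dataclass
class SpectralCube:
    """Reflectance-normalized intensity indexed (y, x, wavelength)."""

    values: np.ndarray
    wavelengths_nm: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (y, x, wavelength)")
        if self.values.shape[2] != self.wavelengths_nm.size:
            raise ValueError("wavelength axis mismatch")
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")


@dataclass
class SigmaImage:
    """Per-pixel spectral standard deviation with its nucleus mask."""

    sigma: np.ndarray
    mask: np.ndarray


def sample_chromatin_density(
    model,
    grid: GridSpec,
    seed: int,
    mean_crowding_g_ml: float = DEFAULT_MEAN_CROWDING,
) -> ChromatinRealization:
    """Sample a Gaussian random field whose ACF is the model's B(r).

    Uses periodic spectral synthesis: the model's realizable radial spectral
    density P+(q) (see ``dmap.radial_power_spectrum``) is sampled on the
    grid's reciprocal lattice and filters white Gaussian noise.  The DC mode
    is zeroed so the fluctuation is exactly zero-mean.  The returned density
    is mean crowding plus the fluctuation; callers analysing the field
    should discard the outer 10% of each axis to suppress periodic
    wrap-around.
    """
    extent = min(grid.extent_nm())
    if extent < model.r_max_nm:
        raise ValueError(
            f"grid extent {extent:.0f} nm is smaller than the fractal-regime "
            f"upper bound {model.r_max_nm:.0f} nm"
        )
    if grid.voxel_nm > model.r_min_nm / 2.0:
        raise ValueError(
            f"voxel ({grid.voxel_nm} nm) must be <= half the fractal-regime "
            f"lower bound ({model.r_min_nm} nm)"
        )
    rng = np.random.default_rng(seed)
    if model.amplitude == 0.0:
        fluct = np.zeros(grid.shape, dtype=np.float32)
    else:
        from .dmap import radial_power_spectrum  # avoids a cycle at import time

        # |q| on the reciprocal lattice of the periodic grid
        freqs = [
            2.0 * np.pi * np.fft.fftfreq(n, d=grid.voxel_nm) for n in grid.shape
        ]
        fy, fx, fz = freqs
        q2 = (
            fy[:, None, None] ** 2
            + fx[None, :, None] ** 2
            + fz[None, None, :] ** 2
        )
        qmag = np.sqrt(q2, out=q2)
        q_tab = np.linspace(0.0, float(qmag.max()) * 1.0001, 4096)
        p_tab = radial_power_spectrum(model, q_tab)
        spec = np.interp(qmag, q_tab, p_tab) / grid.voxel_nm**3
        spec.flat[0] = 0.0  # zero-mean fluctuation
        white = rng.standard_normal(grid.shape)
        f = np.fft.fftn(white)
        f *= np.sqrt(spec)
        fluct = np.fft.ifftn(f).real.astype(np.float32)
    density = fluct + np.float32(mean_crowding_g_ml)
    return ChromatinRealization(
        density=density,
        grid=grid,
        true_acf=model,
        seed=seed,
        mean_crowding_g_ml=mean_crowding_g_ml,
    )


def density_to_ri(realization: ChromatinRealization, instrument: InstrumentConfig) -> np.ndarray:
    """Gladstone-Dale relation: n(r) = n_media + alpha * rho(r), elementwise."""
    return instrument.n_media + instrument.ri_increment_alpha * np.asarray(
        realization.density, dtype=np.float64
    )


def _transverse_blur(field: np.ndarray, sigma_px: float) -> np.ndarray:
    """Gaussian blur in the two transverse axes via FFT (periodic boundaries)."""
    if sigma_px <= 0:
        return field
    ny, nx, _ = field.shape
    fy = np.fft.fftfreq(ny)[:, None] * 2.0 * np.pi
    fx = np.fft.fftfreq(nx)[None, :] * 2.0 * np.pi
    transfer = np.exp(-0.5 * sigma_px**2 * (fy**2 + fx**2))
    out = np.fft.ifft2(
        np.fft.fft2(field, axes=(0, 1)) * transfer[:, :, None], axes=(0, 1)
    ).real
    return out


def simulate_interference_cube(
    ri_field: np.ndarray,
    grid: GridSpec,
    instrument: InstrumentConfig,
) -> SpectralCube:
    """Render the raw interference spectral cube for an RI field.

    Per transverse pixel, reflectance(lambda) = |r_ref + s(k)|^2 with r_ref
    the Fresnel glass/cell coefficient at the mean cell RI and s(k) the
    first-Born axial backscatter sum of the transversely blurred RI
    fluctuations, windowed by a Gaussian depth of field centred mid-cell.
    """
    ri = np.asarray(ri_field, dtype=np.float64)
    if not np.all(np.isfinite(ri)):
        raise ValueError("RI field must be finite")
    if ri.shape != grid.shape:
        raise ValueError(f"RI field shape {ri.shape} != grid shape {grid.shape}")
    n0 = float(ri.mean())
    dn = ri - n0
    sigma_t_px = instrument.transverse_coherence_nm * FWHM_TO_SIGMA / grid.voxel_nm
    dn = _transverse_blur(dn, sigma_t_px)

    dz = grid.voxel_nm
    z = (np.arange(grid.nz) + 0.5) * dz
    zc = 0.5 * grid.nz * dz
    sigma_a = instrument.depth_of_field_nm * FWHM_TO_SIGMA
    w = np.exp(-0.5 * ((z - zc) / sigma_a) ** 2)

    lam = instrument.wavelengths_nm
    k = 2.0 * np.pi * n0 / lam  # wavenumber in the intracellular medium
    # s(k) = i k sum_z dn(z) exp(2ikz) w(z) dz, split into real/imag GEMMs
    phase = 2.0 * k[None, :] * z[:, None]
    wre = (-k[None, :] * np.sin(phase) * w[:, None] * dz).astype(np.float32)
    wim = (k[None, :] * np.cos(phase) * w[:, None] * dz).astype(np.float32)
    flat = dn.reshape(-1, grid.nz).astype(np.float32)
    s_re = flat @ wre
    s_im = flat @ wim

    r_ref = (instrument.n_glass - n0) / (instrument.n_glass + n0)
    intensity = (r_ref + s_re) ** 2 + s_im**2
    values = intensity.reshape(grid.ny, grid.nx, lam.size)
    return SpectralCube(values=values, wavelengths_nm=lam)


def make_reference_cube(
    instrument: InstrumentConfig, shape_yx: tuple[int, int]
) -> SpectralCube:
    """Reference wave from a blank glass/cover-media region (wavelength-flat)."""
    r_blank = (instrument.n_glass - instrument.n_media) / (
        instrument.n_glass + instrument.n_media
    )
    lam = instrument.wavelengths_nm
    values = np.full(shape_yx + (lam.size,), r_blank**2, dtype=np.float64)
    return SpectralCube(values=values, wavelengths_nm=lam)


def reference_normalize(raw: SpectralCube, reference: SpectralCube) -> SpectralCube:
    """Elementwise ratio of the raw cube to the blank-region reference cube."""
    if raw.wavelengths_nm.shape != reference.wavelengths_nm.shape or not np.allclose(
        raw.wavelengths_nm, reference.wavelengths_nm
    ):
        raise ValueError("wavelength grids do not match")
    if np.any(reference.values <= 0):
        raise ValueError("reference cube must be strictly positive")
    return SpectralCube(
        values=raw.values / reference.values, wavelengths_nm=raw.wavelengths_nm.copy()
    )


def compute_sigma_image(cube: SpectralCube, mask: np.ndarray) -> SigmaImage:
    """Sample standard deviation (n-1 denominator) over wavelength per pixel.

    Pixels outside the nucleus mask are NaN.
    """
    mask = np.asarray(mask, dtype=bool)
    if cube.values.shape[2] < 3:
        raise ValueError("need at least 3 wavelengths to estimate Sigma")
    if mask.shape != cube.values.shape[:2]:
        raise ValueError("mask does not match the cube's spatial dimensions")
    sigma = np.std(cube.values, axis=2, ddof=1)
    sigma = np.where(mask, sigma, np.nan)
    return SigmaImage(sigma=sigma, mask=mask)


def interior_mask(shape_yx: tuple[int, int], fraction: float = 0.1) -> np.ndarray:
    """Boolean mask excluding the outer ``fraction`` of each transverse axis.

    Used to discard periodic-synthesis wrap-around before analysis.
    """
    ny, nx = shape_yx
    my = int(round(ny * fraction))
    mx = int(round(nx * fraction))
    mask = np.zeros((ny, nx), dtype=bool)
    mask[my : ny - my, mx : nx - mx] = True
    return mask


# ---------------------------------------------------------------------------
# Disk formats: float32 TIFF + JSON sidecar


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_spectral_cube(path, cube: SpectralCube, metadata: dict | None = None) -> None:
    """Multi-page float32 TIFF (page per wavelength) plus a JSON sidecar."""
    path = Path(path)
    pages = np.moveaxis(cube.values.astype(np.float32), 2, 0)
    tifffile.imwrite(path, pages)
    sidecar = {"wavelengths_nm": cube.wavelengths_nm.tolist()}
    if metadata:
        sidecar.update(metadata)
    _sidecar_path(path).write_text(json.dumps(sidecar, sort_keys=True, indent=1))


def load_spectral_cube(path) -> tuple[SpectralCube, dict]:
    path = Path(path)
    pages = tifffile.imread(path)
    sidecar = json.loads(_sidecar_path(path).read_text())
    cube = SpectralCube(
        values=np.moveaxis(pages, 0, 2),
        wavelengths_nm=np.asarray(sidecar["wavelengths_nm"]),
    )
    return cube, sidecar


def save_float_image(path, image: np.ndarray, metadata: dict | None = None) -> None:
    """Single-page float32 TIFF with an optional JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
    if metadata is not None:
        _sidecar_path(path).write_text(json.dumps(metadata, sort_keys=True, indent=1))


def load_float_image(path) -> np.ndarray:
    return tifffile.imread(Path(path))
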