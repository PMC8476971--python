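"""Synthetic thorax phantoms with analytic ground truth.

A phantom volume is a stack of axial slices holding a body-density thorax
ellipse (+40 HU) in air (-1024 HU), containing two lung ellipses whose
semi-axes taper toward apex and base.  Lung voxels carry HU values from an
aeration profile:

* ``normal`` — homogeneous, well-aerated lung (default -800 HU);
* ``ards_gradient`` — a linear ventral-to-dorsal density ramp (default
  -950 to +50 HU) crossing all four aeration compartments, emulating the
  gravitational density distribution of ARDS; optionally with a dorsal
  pleural-effusion-like crescent of +10 HU outside the lungs.

Ground truth (mask, gas volume, tissue mass, compartment masses) is
computed from the noiseless integer-HU field by exact integer accumulation
before optional Gaussian HU noise is added, so every downstream module can
be tested against closed-form totals.

Paired "pressure level" phantoms share identical total tissue mass but
different gas content: at the higher pressure a chosen mass fraction of the
non-aerated tissue regains aeration, and the displaced tissue mass is moved
— with exact integer bookkeeping — into a newly aerated expansion shell of
lung voxels, mimicking lung expansion under pressure.  The recruited mass
fraction is recorded in the truth object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .dicom_io import CTSlice, CTVolume, ROIContour, write_dicom_series, write_mask_pngs, write_roi
from .ctqa import AerationClass

log = logging.getLogger(__name__)

HU_AIR = -1024
HU_BODY = 40
COHORTS = ("normal", "ARDS", "COVID-19")


@dataclass
class PhantomSpec:
    """Geometry, aeration and noise parameters of one synthetic subject."""

    grid_px: int = 64
    n_slices: int = 10
    pixel_spacing_mm: tuple[float, float] = (4.0, 4.0)
    slice_thickness_mm: float = 5.0
    # fractions of grid size; rows run ventral (0) -> dorsal (grid_px - 1)
    thorax_semiaxes_frac: tuple[float, float] = (0.38, 0.46)  # (row, col)
    lung_semiaxes_frac: tuple[float, float] = (0.24, 0.15)
    lung_center_row_frac: float = 0.52
    lung_center_offset_frac: float = 0.22  # lateral lung-center offset
    lung_taper_floor: float = 0.35  # apex/base semi-axis scale
    aeration_profile: str = "normal"  # or "ards_gradient"
    hu_normal_lung: int = -800
    hu_ventral: int = -950
    hu_dorsal: int = 50
    effusion: bool = False
    effusion_hu: int = 10
    effusion_frac: float = 0.25  # dorsal fraction of the thorax depth
    noise_sd_hu: float = 10.0
    seed: int = 0
    gas_scale: float = 1.0  # pressure surrogate; scales the gas fraction

    def validate(self) -> None:
        if self.aeration_profile not in ("normal", "ards_gradient"):
            raise ValueError(f"unknown aeration profile {self.aeration_profile!r}")
        if not (0 < self.gas_scale <= 1):
            raise ValueError("gas_scale must be in (0, 1]")
        if self.grid_px < 16 or self.n_slices < 1:
            raise ValueError("grid too small")


@dataclass
class PhantomTruth:
    """Analytic ground truth for one phantom (from the noiseless HU field)."""

    mask: np.ndarray  # (n_slices, H, W) uint8
    voxel_volume_ml: float
    gas_volume_ml: float
    tissue_mass_g: float
    lung_volume_ml: float
    compartment_masses_g: dict[str, float]
    compartment_counts: dict[str, int]
    lung_ellipses: list[list[tuple[tuple[float, float], tuple[float, float]]]]
    recruited_fraction: float | None = None


def _ellipse(h: int, w: int, center: tuple[float, float], semi: tuple[float, float]) -> np.ndarray:
    rr, cc = np.mgrid[0:h, 0:w]
    return ((rr - center[0]) / semi[0]) ** 2 + ((cc - center[1]) / semi[1]) ** 2 <= 1.0


def _taper(spec: PhantomSpec, k: int) -> float:
    if spec.n_slices == 1:
        return 1.0
    zeta = (k + 0.5) / spec.n_slices
    return spec.lung_taper_floor + (1 - spec.lung_taper_floor) * float(
        np.sqrt(max(0.0, 1.0 - (2 * zeta - 1) ** 2))
    )


def _truth_from_field(hu: np.ndarray, mask: np.ndarray, v_voxel: float,
                      ellipses, recruited: float | None = None) -> PhantomTruth:
    """Exact totals via integer accumulation (HU must be integer-valued)."""
    m_units = hu[mask.astype(bool)].astype(np.int64) + 1000  # density in milli-g/ml
    gas_units = np.where(m_units <= 1000, 1000 - m_units, 0)
    comp_mass: dict[str, float] = {}
    comp_count: dict[str, int] = {}
    hu_int = m_units - 1000
    for cls in AerationClass:
        lo, hi = cls.hu_range
        sel = (hu_int >= lo) & (hu_int <= hi)
        comp_count[cls.name] = int(sel.sum())
        comp_mass[cls.name] = int(m_units[sel].sum()) * v_voxel / 1000.0
    return PhantomTruth(
        mask=mask.astype(np.uint8),
        voxel_volume_ml=v_voxel,
        gas_volume_ml=int(gas_units.sum()) * v_voxel / 1000.0,
        tissue_mass_g=int(m_units.sum()) * v_voxel / 1000.0,
        lung_volume_ml=int(m_units.size) * v_voxel,
        compartment_masses_g=comp_mass,
        compartment_counts=comp_count,
        lung_ellipses=ellipses,
        recruited_fraction=recruited,
    )


def _build_field(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray, list]:
    """Noiseless integer HU field, lung mask, thorax mask, ellipse bookkeeping."""
    spec.validate()
    n = spec.grid_px
    hu = np.full((spec.n_slices, n, n), HU_AIR, dtype=np.int64)
    mask = np.zeros_like(hu, dtype=np.uint8)
    thorax = np.zeros_like(mask)
    center = (n / 2.0, n / 2.0)
    th_semi = (spec.thorax_semiaxes_frac[0] * n, spec.thorax_semiaxes_frac[1] * n)
    lung_row = spec.lung_center_row_frac * n
    ellipses = []
    for k in range(spec.n_slices):
        tx = _ellipse(n, n, center, th_semi)
        thorax[k] = tx
        hu[k][tx] = HU_BODY
        s = _taper(spec, k)
        semi = (spec.lung_semiaxes_frac[0] * n * s, spec.lung_semiaxes_frac[1] * n * s)
        slice_ellipses = []
        lung = np.zeros((n, n), dtype=bool)
        for side in (-1, +1):
            c = (lung_row, n / 2.0 + side * spec.lung_center_offset_frac * n)
            e = _ellipse(n, n, c, semi)
            lung |= e
            slice_ellipses.append((c, semi))
        if (lung & ~tx).any():
            raise ValueError("infeasible geometry: lung ellipse extends outside the thorax")
        # aeration profile inside the lungs
        if spec.aeration_profile == "normal":
            lung_hu = np.full(int(lung.sum()), spec.hu_normal_lung, dtype=np.float64)
        else:
            rr = np.nonzero(lung)[0].astype(np.float64)
            r0, r1 = rr.min(), rr.max()
            frac = (rr - r0) / max(r1 - r0, 1.0)
            lung_hu = spec.hu_ventral + frac * (spec.hu_dorsal - spec.hu_ventral)
        neg = lung_hu < 0
        lung_hu[neg] = spec.gas_scale * lung_hu[neg]
        hu[k][lung] = np.clip(np.rint(lung_hu).astype(np.int64), -1000, 100)
        mask[k][lung] = 1
        if spec.effusion and spec.aeration_profile == "ards_gradient":
            r_thresh = center[0] + th_semi[0] * (1.0 - 2.0 * spec.effusion_frac)
            rr_all = np.arange(n)[:, None]
            crescent = tx & ~lung & (rr_all >= r_thresh)
            hu[k][crescent] = spec.effusion_hu
        ellipses.append(slice_ellipses)
    return hu, mask, thorax, ellipses


def _to_volume(hu: np.ndarray, spec: PhantomSpec) -> CTVolume:
    slices = []
    for k in range(hu.shape[0]):
        slices.append(
            CTSlice(
                raw_pixels=(hu[k] + 1024).astype(np.int32),
                rescale_slope=1.0,
                rescale_intercept=-1024.0,
                pixel_spacing_mm=spec.pixel_spacing_mm,
                slice_thickness_mm=spec.slice_thickness_mm,
                z_position_mm=float((hu.shape[0] - 1 - k) * spec.slice_thickness_mm),
                patient_position="HFS",
            )
        )
    return CTVolume(slices=slices)


def _add_noise(hu: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.noise_sd_hu <= 0:
        return hu
    noisy = hu + rng.normal(0.0, spec.noise_sd_hu, size=hu.shape)
    return np.clip(np.rint(noisy), -1024, 100).astype(np.int64)


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, PhantomTruth]:
    """Generate one phantom volume plus its analytic truth (deterministic per seed)."""
    hu, mask, _, ellipses = _build_field(spec)
    v_voxel = spec.pixel_spacing_mm[0] * spec.pixel_spacing_mm[1] * spec.slice_thickness_mm / 1000.0
    truth = _truth_from_field(hu, mask, v_voxel, ellipses)
    rng = np.random.default_rng(spec.seed)
    noisy = _add_noise(hu, spec, rng)
    return _to_volume(noisy, spec), truth


def paired_pressure_phantoms(
    spec: PhantomSpec, gas_scales: tuple[float, float]
) -> tuple[tuple[CTVolume, PhantomTruth], tuple[CTVolume, PhantomTruth]]:
    """Two phantoms of one subject at a low and a high airway pressure.

    The low-pressure member is the spec built with ``gas_scale = low``.  At
    the high pressure, a target mass fraction ``1 - low/high`` of the
    non-aerated tissue is recruited: those voxels become normally aerated
    (-700 HU) and the tissue mass they lose is redistributed, in exact
    integer units, into an aerated expansion shell grown around the lungs.
    Total tissue mass is therefore exactly conserved while gas content
    rises.  The achieved recruited-mass fraction (exact, voxel-granular) is
    recorded in both truth objects.
    """
    low, high = gas_scales
    if not (0 < low <= high <= 1):
        raise ValueError("need 0 < low <= high <= 1")
    spec_low = replace(spec, gas_scale=low)
    hu_low, mask, thorax, ellipses = _build_field(spec_low)
    v_voxel = (
        spec.pixel_spacing_mm[0] * spec.pixel_spacing_mm[1] * spec.slice_thickness_mm / 1000.0
    )
    truth_low = _truth_from_field(hu_low, mask, v_voxel, ellipses)
    f_target = 1.0 - low / high

    lungmask = mask.astype(bool)
    na = lungmask & (hu_low >= -100)  # non-aerated lung voxels
    m_na = (hu_low[na] + 1000).sum()
    if f_target <= 0 or m_na == 0:
        truth_low.recruited_fraction = 0.0
        rng = np.random.default_rng(spec.seed)
        vol_low = _to_volume(_add_noise(hu_low, spec_low, rng), spec_low)
        rng2 = np.random.default_rng(spec.seed + 1)
        vol_high = _to_volume(_add_noise(hu_low.copy(), spec_low, rng2), spec_low)
        import copy

        truth_high = copy.deepcopy(truth_low)
        return (vol_low, truth_low), (vol_high, truth_high)

    # recruit ventral-most non-aerated voxels until >= target mass fraction
    kk, rr, cc = np.nonzero(na)
    order = np.lexsort((cc, kk, rr))  # ventral rows first
    m_vox = hu_low[kk[order], rr[order], cc[order]] + 1000
    csum = np.cumsum(m_vox)
    n_rec = int(np.searchsorted(csum, f_target * m_na) + 1)
    n_rec = min(n_rec, len(m_vox))
    rec = (kk[order[:n_rec]], rr[order[:n_rec]], cc[order[:n_rec]])
    hu_recruited = -700  # normally aerated after recruitment
    removed = int((hu_low[rec] + 1000).sum() - n_rec * (hu_recruited + 1000))
    achieved = float((hu_low[rec] + 1000).sum()) / float(m_na)

    # expansion shell: grow the lungs inside the thorax until the shell can
    # absorb the removed mass at aerated densities (< 900 milli-g/ml)
    hu_high = hu_low.copy()
    hu_high[rec] = hu_recruited
    grown = lungmask.copy()
    shell = np.zeros_like(lungmask)
    for _ in range(8):
        nxt = np.zeros_like(grown)
        for k in range(grown.shape[0]):
            nxt[k] = ndimage.binary_dilation(grown[k]) & thorax[k].astype(bool)
        shell = nxt & ~lungmask
        grown = nxt
        if shell.sum() * 899 >= removed:
            break
    n_shell = int(shell.sum())
    if n_shell * 899 < removed:
        raise ValueError("infeasible geometry: expansion shell cannot absorb recruited mass")
    base, remn = divmod(removed, n_shell)
    units = np.full(n_shell, base, dtype=np.int64)
    units[:remn] += 1
    hu_high[shell] = units - 1000
    mask_high = (lungmask | shell).astype(np.uint8)
    truth_high = _truth_from_field(hu_high, mask_high, v_voxel, ellipses)
    truth_low.recruited_fraction = achieved
    truth_high.recruited_fraction = achieved

    rng = np.random.default_rng(spec.seed)
    vol_low = _to_volume(_add_noise(hu_low, spec_low, rng), spec_low)
    rng2 = np.random.default_rng(spec.seed + 1)
    vol_high = _to_volume(_add_noise(hu_high, spec, rng2), spec)
    return (vol_low, truth_low), (vol_high, truth_high)


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------


def default_cohort_mix(n_subjects: int) -> dict[str, int]:
    """Cohort proportions roughly matching a mixed clinical corpus
    (normal : ARDS : COVID-19 = 15 : 100 : 20)."""
    weights = np.array([15.0, 100.0, 20.0])
    counts = np.floor(weights / weights.sum() * n_subjects).astype(int)
    counts[counts == 0] = 1
    while counts.sum() > n_subjects:
        counts[int(np.argmax(counts))] -= 1
    counts[1] += n_subjects - counts.sum()  # remainder to the ARDS cohort
    return dict(zip(COHORTS, (int(c) for c in counts)))


def random_spec(cohort: str, rng: np.random.Generator, grid_px: int = 64,
                n_slices: int = 10, noise_sd_hu: float = 10.0) -> PhantomSpec:
    """A randomized subject spec for a cohort."""
    if cohort not in COHORTS:
        raise ValueError(f"unknown cohort {cohort!r}; expected one of {COHORTS}")
    jitter = lambda lo, hi: float(rng.uniform(lo, hi))
    common = dict(
        grid_px=grid_px,
        n_slices=n_slices,
        thorax_semiaxes_frac=(jitter(0.34, 0.40), jitter(0.42, 0.47)),
        lung_semiaxes_frac=(jitter(0.20, 0.26), jitter(0.12, 0.16)),
        lung_center_row_frac=jitter(0.50, 0.55),
        lung_center_offset_frac=jitter(0.20, 0.24),
        lung_taper_floor=jitter(0.30, 0.45),
        noise_sd_hu=noise_sd_hu,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    if cohort == "normal":
        return PhantomSpec(aeration_profile="normal",
                           hu_normal_lung=int(rng.integers(-850, -750)), **common)
    if cohort == "ARDS":
        return PhantomSpec(
            aeration_profile="ards_gradient",
            hu_ventral=int(rng.integers(-960, -900)),
            hu_dorsal=int(rng.integers(20, 60)),
            effusion=bool(rng.random() < 0.5),
            **common,
        )
    return PhantomSpec(  # COVID-19: ground-glass-like, milder dorsal densities
        aeration_profile="ards_gradient",
        hu_ventral=int(rng.integers(-920, -860)),
        hu_dorsal=int(rng.integers(-350, -150)),
        effusion=bool(rng.random() < 0.2),
        **common,
    )


def generate_dataset(
    n_subjects: int,
    out_dir,
    cohort_mix: dict[str, int] | None = None,
    seed: int = 0,
    grid_px: int = 64,
    n_slices: int = 10,
    noise_sd_hu: float = 10.0,
    roi_format: str = "png",
) -> Path:
    """Write a phantom corpus to disk in the formats the pipeline consumes.

    Per subject: a DICOM series directory and a ground-truth ROI (per-slice
    PNG masks by default, or a polygon-JSON contour).  Returns the path of
    the manifest CSV (columns patient_id, image_path, roi_path, cohort).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if roi_format not in ("png", "json"):
        raise ValueError("roi_format must be 'png' or 'json'")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mix = cohort_mix or default_cohort_mix(n_subjects)
    unknown = set(mix) - set(COHORTS)
    if unknown:
        raise ValueError(f"unknown cohorts in mix: {sorted(unknown)}")
    if sum(mix.values()) != n_subjects:
        raise ValueError("cohort mix does not sum to n_subjects")
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for cohort in COHORTS:
        for _ in range(mix.get(cohort, 0)):
            pid = f"P{i:03d}"
            spec = random_spec(cohort, rng, grid_px=grid_px, n_slices=n_slices,
                               noise_sd_hu=noise_sd_hu)
            volume, truth = generate_phantom(spec)
            img_dir = out_dir / pid / "dicom"
            write_dicom_series(volume, img_dir)
            if roi_format == "png":
                roi_path = out_dir / pid / "roi"
                write_mask_pngs(truth.mask, roi_path)
            else:
                roi_path = out_dir / pid / "roi.json"
                write_roi(_mask_to_contour(truth.mask), roi_path)
            rows.append(
                {
                    "patient_id": pid,
                    "image_path": str(img_dir.relative_to(out_dir)),
                    "roi_path": str(roi_path.relative_to(out_dir)),
                    "cohort": cohort,
                }
            )
            i += 1
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def _mask_to_contour(mask: np.ndarray) -> ROIContour:
    """Approximate polygon contours of a binary mask stack (marching squares)."""
    from skimage import measure

    slices: dict[int, list[np.ndarray]] = {}
    for k in range(mask.shape[0]):
        polys = []
        for contour in measure.find_contours(mask[k].astype(float), 0.5):
            if len(contour) >= 3:
                polys.append(contour[:, ::-1].copy())  # (row, col) -> (x, y)
        if polys:
            slices[k] = polys
    return ROIContour(slices=slices)
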