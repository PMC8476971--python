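"""Quantitative CT analysis (CT-qa) of the lung.

Inside a lung mask, every voxel is decomposed into gas and tissue from its
Hounsfield number: a voxel at -1000 HU is pure gas, a voxel at 0 HU is pure
tissue (water density), and intermediate values mix linearly,

    gas fraction      = -HU / 1000          (HU <= 0)
    tissue density    = (HU + 1000) / 1000  [g/ml]

so per voxel ``V_gas = -HU/1000 * V_voxel`` and
``tissue mass = (HU+1000)/1000 * V_voxel``.  Voxels are additionally
classified into the four standard aeration compartments:

    non-aerated        +100 ... -100 HU
    poorly aerated     -101 ... -500 HU
    normally aerated   -501 ... -900 HU
    hyper-inflated     -901 ... -1000 HU

Recruitability between two airway pressures is the fraction of non-aerated
tissue at the low pressure that regains aeration at the high pressure.

HU values are clamped to [-1000, +100] before any of the above, so that
values below -1000 count as pure gas and gas volume is never negative.
Classification uses integer HU (round half away from zero), because the
compartment bounds are closed integer ranges.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

HU_GAS = -1000.0
HU_TISSUE_MAX = 100.0


class AerationClass(enum.Enum):
    """The four aeration compartments with their closed integer HU ranges."""

    non_aerated = (-100, 100)
    poorly_aerated = (-500, -101)
    normally_aerated = (-900, -501)
    hyper_inflated = (-1000, -901)

    @property
    def hu_range(self) -> tuple[int, int]:
        return self.value


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (np.round rounds half to even)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def clamp_hu_for_qa(hu: np.ndarray) -> np.ndarray:
    """Clamp HU to the quantitative range [-1000, +100]."""
    return np.clip(np.asarray(hu, dtype=np.float64), HU_GAS, HU_TISSUE_MAX)


def voxel_volume_ml(pixel_spacing_mm: tuple[float, float], slice_thickness_mm: float) -> float:
    """Voxel volume in ml from in-plane spacing and slice thickness (mm)."""
    sr, sc = pixel_spacing_mm
    if sr <= 0 or sc <= 0 or slice_thickness_mm <= 0:
        raise ValueError("pixel spacing and slice thickness must be positive")
    return float(sr) * float(sc) * float(slice_thickness_mm) / 1000.0


def voxel_gas_volume(hu, v_voxel: float):
    """Gas volume (ml) of voxels at the given (clamped) HU."""
    hu = clamp_hu_for_qa(hu)
    return np.where(hu <= 0, -hu / 1000.0 * v_voxel, 0.0)


def voxel_density(hu):
    """Lung density (g/ml): (HU + 1000)/1000 after clamping."""
    return (clamp_hu_for_qa(hu) + 1000.0) / 1000.0


def voxel_tissue_mass(hu, v_voxel: float):
    """Tissue mass (g) of voxels at the given (clamped) HU."""
    return voxel_density(hu) * v_voxel


def classify_aeration(hu_int) -> np.ndarray:
    """Map integer HU in [-1000, +100] to AerationClass (vectorized).

    Returns an object array of AerationClass for array input, or a single
    AerationClass for scalar input.
    """
    arr = np.asarray(hu_int)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr).astype(np.int64)
    if arr.size and (arr.min() < -1000 or arr.max() > 100):
        raise ValueError("integer HU outside [-1000, +100]; clamp and round first")
    out = np.empty(arr.shape, dtype=object)
    for cls in AerationClass:
        lo, hi = cls.hu_range
        out[(arr >= lo) & (arr <= hi)] = cls
    return out.item() if scalar else out


@dataclass
class CompartmentStats:
    voxel_count: int = 0
    volume_ml: float = 0.0
    gas_volume_ml: float = 0.0
    tissue_mass_g: float = 0.0


@dataclass
class QuantitativeReport:
    """Per-compartment and total gas/tissue quantities for one masked lung."""

    voxel_volume_ml: float
    mask_voxel_count: int
    compartments: dict[str, CompartmentStats]
    total_volume_ml: float = 0.0
    total_gas_volume_ml: float = 0.0
    total_tissue_mass_g: float = 0.0

    @property
    def lung_weight_g(self) -> float:
        """Total tissue mass; the 'lung weight' used in consistency audits."""
        return self.total_tissue_mass_g

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_row(self) -> dict:
        row = {
            "voxel_volume_ml": self.voxel_volume_ml,
            "mask_voxel_count": self.mask_voxel_count,
            "total_volume_ml": self.total_volume_ml,
            "total_gas_volume_ml": self.total_gas_volume_ml,
            "total_tissue_mass_g": self.total_tissue_mass_g,
        }
        for name, c in self.compartments.items():
            row.update(
                {
                    f"{name}_voxels": c.voxel_count,
                    f"{name}_volume_ml": c.volume_ml,
                    f"{name}_gas_ml": c.gas_volume_ml,
                    f"{name}_mass_g": c.tissue_mass_g,
                }
            )
        return row


def analyze(hu_volume: np.ndarray, mask: np.ndarray, voxel_vol_ml: float) -> QuantitativeReport:
    """Run CT-qa over every masked voxel of an HU volume.

    Parameters
    ----------
    hu_volume : array
        HU values, any shape.
    mask : array
        Binary mask of the same shape (1 = lung).
    voxel_vol_ml : float
        Physical voxel volume in ml.

    Operates on the original HU values (not on the 8-bit preprocessed image,
    whose quantization would bias the gas/tissue decomposition).
    """
    hu_volume = np.asarray(hu_volume)
    mask = np.asarray(mask).astype(bool)
    if hu_volume.shape != mask.shape:
        raise ValueError(f"shape mismatch: volume {hu_volume.shape} vs mask {mask.shape}")
    hu = clamp_hu_for_qa(hu_volume[mask])
    if hu.size == 0:
        warnings.warn("empty lung mask: quantitative report is all zeros", stacklevel=2)
    gas = np.where(hu <= 0, -hu / 1000.0 * voxel_vol_ml, 0.0)
    mass = (hu + 1000.0) / 1000.0 * voxel_vol_ml
    hu_int = _round_half_away(hu).astype(np.int64)

    comps: dict[str, CompartmentStats] = {}
    for cls in AerationClass:
        lo, hi = cls.hu_range
        sel = (hu_int >= lo) & (hu_int <= hi)
        comps[cls.name] = CompartmentStats(
            voxel_count=int(sel.sum()),
            volume_ml=float(sel.sum()) * voxel_vol_ml,
            gas_volume_ml=float(gas[sel].sum()),
            tissue_mass_g=float(mass[sel].sum()),
        )
    return QuantitativeReport(
        voxel_volume_ml=voxel_vol_ml,
        mask_voxel_count=int(hu.size),
        compartments=comps,
        total_volume_ml=float(hu.size) * voxel_vol_ml,
        total_gas_volume_ml=float(gas.sum()),
        total_tissue_mass_g=float(mass.sum()),
    )


@dataclass
class RecruitabilityResult:
    """Recruited-tissue fractions between a low and a high airway pressure."""

    recruitability_nonaerated: float | None
    recruitability_wellaerated: float | None
    pressure_low: str = "5 cmH2O"
    pressure_high: str = "45 cmH2O"
    undefined_reason: str | None = None
    wellaerated_denominator: str = "total_tissue_mass_at_low_pressure"


def recruitability(
    report_low: QuantitativeReport,
    report_high: QuantitativeReport,
    pressure_low: str = "5 cmH2O",
    pressure_high: str = "45 cmH2O",
) -> RecruitabilityResult:
    """Recruitability between two pressure levels.

    Non-aerated form: (m_na_low - m_na_high) / m_na_low, the fraction of
    gasless tissue that regains inflation at the higher pressure.
    Well-aerated form: (m_well_high - m_well_low) / total tissue mass at the
    low pressure ("well aerated" = normally aerated compartment).  The
    denominator of the well-aerated form is a package choice, recorded in
    the result metadata.
    """
    na_low = report_low.compartments["non_aerated"].tissue_mass_g
    na_high = report_high.compartments["non_aerated"].tissue_mass_g
    well_low = report_low.compartments["normally_aerated"].tissue_mass_g
    well_high = report_high.compartments["normally_aerated"].tissue_mass_g
    total_low = report_low.total_tissue_mass_g

    if na_low <= 0:
        return RecruitabilityResult(
            None,
            (well_high - well_low) / total_low if total_low > 0 else None,
            pressure_low,
            pressure_high,
            undefined_reason="non-aerated tissue mass at low pressure is zero",
        )
    rec_na = (na_low - na_high) / na_low
    rec_well = (well_high - well_low) / total_low if total_low > 0 else None
    return RecruitabilityResult(rec_na, rec_well, pressure_low, pressure_high)


def weight_consistency(
    reports: Sequence[tuple[str, QuantitativeReport]] | Mapping[str, QuantitativeReport],
) -> pd.DataFrame:
    """Pairwise lung-weight differences across pressure levels for one subject.

    The lung weight (total tissue mass) should not change with airway
    pressure; a nonzero difference quantifies segmentation inaccuracy.
    Returns one row per ordered pair (low label first).
    """
    if isinstance(reports, Mapping):
        items = list(reports.items())
    else:
        items = list(reports)
    if len(items) < 2:
        raise ValueError("need at least two pressure-labeled reports")
    rows = []
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            (la, ra), (lb, rb) = items[i], items[j]
            rows.append(
                {
                    "pressure_a": la,
                    "pressure_b": lb,
                    "weight_a_g": ra.lung_weight_g,
                    "weight_b_g": rb.lung_weight_g,
                    "difference_g": ra.lung_weight_g - rb.lung_weight_g,
                }
            )
    return pd.DataFrame(rows)


def weight_consistency_summary(per_subject: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Mean/SD/min/max of pairwise weight differences across subjects."""
    all_rows = pd.concat(per_subject, ignore_index=True)
    g = all_rows.groupby(["pressure_a", "pressure_b"])["difference_g"]
    return g.agg(mean="mean", sd="std", min="min", max="max").reset_index()


def reports_to_csv(rows: Sequence[tuple[str, str, QuantitativeReport]], path) -> None:
    """Write (subject, pressure, report) rows as a flat CSV."""
    records = []
    for subject, pressure, rep in rows:
        rec = {"subject": subject, "pressure": pressure}
        rec.update(rep.to_row())
        records.append(rec)
    pd.DataFrame(records).to_csv(path, index=False)
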