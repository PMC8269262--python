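"""Absolute quantification of identified compounds.

A response factor (RF, peak area per unit concentration in water) turns an
area into a concentration once two corrections are applied: the volume
ratio between the reconstituted extract and the water sampled, and the
matrix effect RF_ratio (RF in a marine-particulate matrix over RF in
water):

    Concentration = (Area / RF) × (Vol_reconst / Vol_filtered) × (1 / RF_ratio)

Compounds whose authentic standard was only run in a later batch are
calibrated through a structurally matched standard present in every batch:
RF_relative = RF_analyte / RF_matched, and the analyte's RF in an earlier
batch is RF_relative × that batch's matched-standard RF.

Concentrations convert to carbon/nitrogen equivalents through the
compound's element counts, to fractions of the bulk particulate carbon
pool, and — for cultures — to intracellular concentrations via the total
biovolume harvested (1 µm³ = 1e-15 L).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .feature_tables import CompoundInfo, ValidationError

__all__ = ["QuantContext", "ConcentrationResult", "compute_rf",
           "compute_rf_ratio", "compute_rf_relative", "estimate_rf",
           "concentration_in_sample", "element_equivalents",
           "fraction_of_bulk", "intracellular_concentration",
           "quantify_table"]

#: liters per cubic micrometer
L_PER_UM3 = 1e-15

#: default reconstitution volume: 400 µL, in liters
DEFAULT_VOL_RECONST_L = 400e-6


@dataclass(frozen=True)
class QuantContext:
    """Everything needed to turn one peak area into a concentration.

    ``rf`` is in area per concentration unit (conventionally area·µM⁻¹, in
    water); ``rf_ratio`` is dimensionless (RF in matrix / RF in water);
    volumes are liters.  ``vol_filtered_L`` is the water volume filtered
    (environmental) or the total biovolume expressed in liters (cultures).
    ``dilution_factor`` multiplies the result when the extract was diluted
    before injection (e.g. 3.0 for 1 part sample + 2 parts water).
    """

    rf: float
    vol_filtered_L: float
    rf_ratio: float = 1.0
    vol_reconst_L: float = DEFAULT_VOL_RECONST_L
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("rf", "vol_filtered_L", "rf_ratio", "vol_reconst_L",
                     "dilution_factor"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValidationError(f"QuantContext.{name} must be finite and > 0, got {v}")


@dataclass
class ConcentrationResult:
    """A quantified compound in one sample."""

    compound: str
    sample: str
    concentration: float              # in the RF's concentration unit
    nM_carbon: float
    nM_nitrogen: float
    provenance: str = "direct_rf"     # or "rf_relative"
    unreliable: bool = False          # e.g. DMSP in methanol extractions


def compute_rf(standard_areas, standard_concentrations) -> float:
    """Response factor: mean area/concentration over standard injections.

    Standards are typically injected before and after each batch; the
    batch RF is the mean of the per-injection ratios.
    """
    areas = np.asarray(standard_areas, dtype=float)
    concs = np.asarray(standard_concentrations, dtype=float)
    if areas.shape != concs.shape or areas.size == 0:
        raise ValidationError(
            f"areas and concentrations must be same-length non-empty lists, "
            f"got {areas.shape} vs {concs.shape}")
    if (concs <= 0).any():
        raise ValidationError("standard concentrations must be > 0")
    if (areas <= 0).any():
        raise ValidationError("standard areas must be > 0")
    return float(np.mean(areas / concs))


def compute_rf_ratio(rf_matrix: float, rf_water: float) -> float:
    """Matrix effect: RF in a representative matrix over RF in water."""
    if rf_matrix <= 0 or rf_water <= 0:
        raise ValidationError(
            f"RFs must be > 0, got matrix={rf_matrix}, water={rf_water}")
    return rf_matrix / rf_water


def compute_rf_relative(rf_analyte: float, rf_matched: float) -> float:
    """Relative response factor versus a structurally matched standard."""
    if rf_analyte <= 0 or rf_matched <= 0:
        raise ValidationError(
            f"RFs must be > 0, got analyte={rf_analyte}, matched={rf_matched}")
    return rf_analyte / rf_matched


def estimate_rf(rf_relative: float, rf_matched_in_batch: float) -> float:
    """Transfer a calibration to an earlier batch through the matched
    standard: estimated RF = RF_relative × that batch's matched RF."""
    if rf_relative <= 0 or rf_matched_in_batch <= 0:
        raise ValidationError("rf_relative and matched RF must be > 0")
    return rf_relative * rf_matched_in_batch


def concentration_in_sample(area: float, ctx: QuantContext) -> float:
    """Apply the concentration equation to one area.

    The result is in the RF's concentration unit (µM when RF is
    area·µM⁻¹), scaled by the reconstitution/filtration volume ratio.
    """
    if area < 0 or not math.isfinite(area):
        raise ValidationError(f"area must be finite and >= 0, got {area}")
    return ((area / ctx.rf)
            * (ctx.vol_reconst_L / ctx.vol_filtered_L)
            * (1.0 / ctx.rf_ratio)
            * ctx.dilution_factor)


def element_equivalents(conc: float, compound: CompoundInfo) -> tuple[float, float]:
    """Carbon and nitrogen equivalents of a molar concentration.

    Returns ``(conc × n_C, conc × n_N)`` in the same unit as ``conc``.
    """
    if compound.n_C == 0 and compound.n_N == 0 and compound.n_S == 0:
        raise ValidationError(
            f"{compound.name}: element counts unknown; parse the formula first")
    return conc * compound.n_C, conc * compound.n_N


def fraction_of_bulk(total_metabolite_c: float, bulk_pc: float) -> float:
    """Quantified-metabolite carbon as a fraction of bulk particulate carbon."""
    if bulk_pc <= 0:
        raise ValidationError(f"bulk PC must be > 0, got {bulk_pc}")
    if total_metabolite_c < 0:
        raise ValidationError("metabolite carbon must be >= 0")
    return total_metabolite_c / bulk_pc


def intracellular_concentration(moles_on_filter: float,
                                total_biovolume_um3: float) -> float:
    """Intracellular concentration in mM from moles and total biovolume.

    concentration = moles / (biovolume × 1e-15 L·µm⁻³), reported in mM.
    """
    if total_biovolume_um3 <= 0:
        raise ValidationError(
            f"biovolume must be > 0, got {total_biovolume_um3}")
    if moles_on_filter <= 0:
        raise ValidationError(f"moles must be > 0, got {moles_on_filter}")
    molar = moles_on_filter / (total_biovolume_um3 * L_PER_UM3)
    return molar * 1e3


#: compounds quantified but flagged unreliable under methanol extraction
UNRELIABLE_COMPOUNDS = ("DMSP",)


def quantify_table(areas: pd.DataFrame,
                   compounds: list[CompoundInfo],
                   contexts: dict[str, QuantContext],
                   rf_by_compound: pd.Series | None = None,
                   provenance: dict[str, str] | None = None,
                   ) -> pd.DataFrame:
    """Quantify a compounds × samples area table.

    ``contexts`` maps sample id → :class:`QuantContext`; ``rf_by_compound``
    optionally overrides each context's RF per compound (e.g. RF_relative-
    derived estimates), with ``provenance`` recording how each compound's
    RF was obtained.  Returns a long-form table (compound, sample,
    concentration, nM_carbon, nM_nitrogen, provenance, unreliable); missing
    areas yield no row.
    """
    by_name = {c.name: c for c in compounds}
    unknown = set(areas.index) - set(by_name)
    if unknown:
        raise ValidationError(f"no CompoundInfo for: {sorted(unknown)}")
    rows = []
    for name in areas.index:
        comp = by_name[name]
        for sid in areas.columns:
            area = areas.loc[name, sid]
            if pd.isna(area):
                continue
            ctx = contexts[sid]
            if rf_by_compound is not None and name in rf_by_compound.index:
                ctx = QuantContext(rf=float(rf_by_compound[name]),
                                   vol_filtered_L=ctx.vol_filtered_L,
                                   rf_ratio=ctx.rf_ratio,
                                   vol_reconst_L=ctx.vol_reconst_L,
                                   dilution_factor=ctx.dilution_factor)
            conc = concentration_in_sample(float(area), ctx)
            c_eq, n_eq = element_equivalents(conc, comp)
            rows.append({
                "compound": name, "sample": sid, "concentration": conc,
                "nM_carbon": c_eq * 1e3, "nM_nitrogen": n_eq * 1e3,
                "provenance": (provenance or {}).get(name, "direct_rf"),
                "unreliable": name in UNRELIABLE_COMPOUNDS,
            })
    return pd.DataFrame(rows, columns=["compound", "sample", "concentration",
                                       "nM_carbon", "nM_nitrogen",
                                       "provenance", "unreliable"])
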