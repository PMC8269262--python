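"""Synthetic community-metabolome datasets with full ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, so that every stage can be exercised and scored without any real
LC-MS data:

* a **signature matrix**: a "core metabolome" block produced by every
  species, taxon-group-specific blocks, and a "rare" block never observed
  in culture (default geometry: 313 features across 21 species in 5
  taxonomic groups);
* **culture tables**: replicate harvests per species, peak area =
  signature × biovolume × multiplicative log-normal noise;
* **environmental tables**: samples along a latitude or depth axis whose
  true composition is a biomass-scaled mixture of the group signatures,
  with plantable monotone / peaked / flat gradient shapes;
* **instrument artifacts**: per-injection multiplicative drift shared with
  spiked internal standards, pooled QC injections, matrix blanks carrying a
  fraction of the dissolved pool, and contaminant-only features;
* **satellite features**: isotopologue / adduct / doubly charged companions
  at exact mass offsets with optional ppm and retention-time jitter;
* **planted concentrations** for quantification round trips.

Everything is deterministic given a seed, and every planted structure is
recorded in a :class:`SyntheticTruth` so downstream recovery can be scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dereplication import ADDUCT_OFFSETS, ISOTOPE_OFFSETS, PROTON_MASS
from .feature_tables import (MassFeature, PeakTable, SampleRecord,
                             ValidationError, make_feature_id)

__all__ = [
    "SignatureMatrix", "CommunityDesign", "SyntheticTruth",
    "GRADIENT_SHAPES", "generate_signatures", "make_gradient_design",
    "simulate_culture_table", "simulate_environment_table",
    "add_instrument_artifacts", "add_adducts_isotopes",
    "plant_concentration_areas", "mode_recovery_dataset",
    "satellite_benchmark",
]


@dataclass
class SignatureMatrix:
    """True mean abundances per (species, feature) with block labels.

    ``abundances`` is species × features (arbitrary units per µm³ of
    biovolume); ``blocks`` labels each feature ``core``, ``group:<g>`` or
    ``rare``; ``species_groups`` maps species → taxon-group index; ``base``
    keeps the per-feature base abundance (used as the environmental source
    strength of rare features, which have all-zero culture signatures).
    """

    abundances: pd.DataFrame
    blocks: pd.Series
    species_groups: pd.Series
    base: pd.Series

    def __post_init__(self) -> None:
        if (self.abundances.to_numpy() < 0).any():
            raise ValidationError("signature abundances must be non-negative")
        for fid, block in self.blocks.items():
            col = self.abundances[fid]
            if block == "core" and (col <= 0).any():
                raise ValidationError(f"core feature {fid} missing from some species")
            if block.startswith("group:"):
                g = int(block.split(":")[1])
                outside = col[self.species_groups != g]
                if (outside > 0).any():
                    raise ValidationError(f"{fid} leaks outside group {g}")

    @property
    def feature_ids(self) -> pd.Index:
        return self.abundances.columns

    def group_means(self) -> pd.DataFrame:
        """Mean signature per taxon group (groups × features)."""
        return self.abundances.groupby(self.species_groups).mean()


@dataclass
class CommunityDesign:
    """Ordered environmental stations and their taxon mixing weights.

    ``weights`` is stations × groups (non-negative, need not sum to 1); an
    optional ``rare`` column drives the environmental abundance of the
    rare block.  ``axis`` must be strictly monotone (latitude or depth).
    """

    axis: np.ndarray
    weights: pd.DataFrame
    biomass: np.ndarray
    axis_name: str = "latitude"

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.biomass = np.asarray(self.biomass, dtype=float)
        d = np.diff(self.axis)
        if not ((d > 0).all() or (d < 0).all()):
            raise ValidationError("design axis must be strictly monotone")
        w = self.weights.to_numpy()
        if not np.isfinite(w).all() or (w < 0).any():
            raise ValidationError("mixing weights must be finite and >= 0")
        if len(self.axis) != len(self.weights) or len(self.axis) != len(self.biomass):
            raise ValidationError("axis, weights and biomass lengths differ")

    @property
    def n_stations(self) -> int:
        return len(self.axis)


@dataclass
class SyntheticTruth:
    """Everything planted: the oracle for downstream recovery."""

    signatures: SignatureMatrix | None = None
    design: CommunityDesign | None = None
    mode_labels: pd.Series | None = None          # feature -> true mode
    drift: pd.Series | None = None                # sample -> f_s
    satellites: pd.DataFrame | None = None        # satellite_id, parent_id, kind
    concentrations: pd.DataFrame | None = None    # compound x sample, µM
    internal_standard_ids: list[str] = field(default_factory=list)
    contaminant_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# signatures
# ---------------------------------------------------------------------------

def _draw_feature_ids(rng: np.random.Generator, n: int,
                      taken: set[str] | None = None,
                      mz_range=(80.0, 800.0),
                      rt_range_sec=(120.0, 1140.0)) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Random unique feature coordinates (rejection-sampled on ID collision)."""
    taken = set(taken or ())
    ids: list[str] = []
    mzs = np.empty(n)
    rts = np.empty(n)
    i = 0
    while i < n:
        mz = rng.uniform(*mz_range)
        rt = rng.uniform(*rt_range_sec)
        fid = make_feature_id(mz, rt / 60.0)
        if fid in taken:
            continue
        taken.add(fid)
        ids.append(fid)
        mzs[i], rts[i] = mz, rt
        i += 1
    return ids, mzs, rts


def _as_counts(value, n_groups: int, name: str) -> list[int]:
    if np.isscalar(value):
        return [int(value)] * n_groups
    value = list(value)
    if len(value) != n_groups:
        raise ValidationError(f"{name} must have one entry per group")
    return [int(v) for v in value]


def generate_signatures(n_groups: int = 5,
                        species_per_group=(5, 4, 4, 4, 4),
                        n_core: int = 52,
                        n_specific_per_group=(25, 25, 25, 24, 24),
                        n_rare: int = 138,
                        seed: int = 0,
                        base_median: float = 1e3,
                        base_sigma: float = 1.0,
                        species_sigma: float = 0.3) -> SignatureMatrix:
    """Draw a block-structured species × features signature matrix.

    Defaults mirror the study geometry: 313 features (52 core + 123
    taxon-specific + 138 rare) over 21 species in 5 groups.  Within-block
    abundances are log-normal around a per-feature base level (median ~1e3 units per µm³ of
    biovolume, so per-biovolume abundances stay well above 1 and the
    culture log10 scale is positive); rare
    features keep a base level but are absent from every culture.
    """
    if n_groups < 1:
        raise ValidationError("need at least one taxon group")
    counts = _as_counts(species_per_group, n_groups, "species_per_group")
    if min(counts) < 1:
        raise ValidationError("every group needs at least one species")
    spec_counts = _as_counts(n_specific_per_group, n_groups, "n_specific_per_group")
    if n_core < 0 or n_rare < 0 or min(spec_counts) < 0:
        raise ValidationError("feature counts must be >= 0")

    rng = np.random.default_rng(seed)
    species = []
    groups = []
    for g, c in enumerate(counts):
        for i in range(c):
            species.append(f"sp_g{g}_{i}")
            groups.append(g)
    species_groups = pd.Series(groups, index=pd.Index(species, name="species"))

    blocks_list = (["core"] * n_core
                   + [f"group:{g}" for g, c in enumerate(spec_counts) for _ in range(c)]
                   + ["rare"] * n_rare)
    n_features = len(blocks_list)
    ids, mzs, rts = _draw_feature_ids(rng, n_features)
    blocks = pd.Series(blocks_list, index=pd.Index(ids, name="feature_id"))
    base = pd.Series(rng.lognormal(math.log(base_median), base_sigma, n_features),
                     index=blocks.index)

    abund = np.zeros((len(species), n_features))
    group_arr = species_groups.to_numpy()
    for j, fid in enumerate(ids):
        block = blocks_list[j]
        if block == "core":
            active = np.ones(len(species), dtype=bool)
        elif block.startswith("group:"):
            active = group_arr == int(block.split(":")[1])
        else:                                  # rare: never observed in culture
            active = np.zeros(len(species), dtype=bool)
        abund[active, j] = base.iloc[j] * rng.lognormal(0.0, species_sigma,
                                                        active.sum())
    abundances = pd.DataFrame(abund, index=species_groups.index, columns=blocks.index)
    sig = SignatureMatrix(abundances, blocks, species_groups, base)
    sig._coords = pd.DataFrame({"mz": mzs, "rt_sec": rts}, index=blocks.index)
    return sig


# ---------------------------------------------------------------------------
# community designs
# ---------------------------------------------------------------------------

def _band(center: float, width: float = 0.12):
    return lambda x: np.exp(-((x - center) / width) ** 2)


#: named gradient shapes on a normalized axis x in [0, 1]
GRADIENT_SHAPES = {
    "increasing": lambda x: 0.15 + 0.85 * x,
    "decreasing": lambda x: 1.00 - 0.85 * x,
    "peak_south": _band(0.30),
    "peak_north": _band(0.70),
    "flat": lambda x: np.full_like(x, 0.55),
    "deep": lambda x: 0.10 + 0.90 * x ** 2,
    # five latitude bands, mutually near-equidistant community types
    "band_1": _band(0.10),
    "band_2": _band(0.30),
    "band_3": _band(0.50),
    "band_4": _band(0.70),
    "band_5": _band(0.90),
}


def make_gradient_design(axis, shapes, biomass_slope: float = 0.5,
                         rare_shape: str | None = None,
                         axis_name: str = "latitude") -> CommunityDesign:
    """Build a community design from named gradient shapes.

    ``shapes`` is one shape name per taxon group (see
    :data:`GRADIENT_SHAPES`).  Total biomass rises linearly along the axis
    with slope ``biomass_slope``.  ``rare_shape`` adds a ``rare`` source
    column for the never-cultured block.
    """
    axis = np.asarray(axis, dtype=float)
    span = float(np.ptp(axis))
    x = (axis - axis.min()) / span if span else np.zeros_like(axis)
    cols = {}
    for g, name in enumerate(shapes):
        if name not in GRADIENT_SHAPES:
            raise ValidationError(f"unknown gradient shape {name!r}")
        cols[g] = GRADIENT_SHAPES[name](x)
    if rare_shape is not None:
        cols["rare"] = GRADIENT_SHAPES[rare_shape](x)
    weights = pd.DataFrame(cols, index=pd.RangeIndex(len(axis), name="station"))
    biomass = 1.0 + biomass_slope * x
    return CommunityDesign(axis, weights, biomass, axis_name)


# ---------------------------------------------------------------------------
# culture and environmental tables
# ---------------------------------------------------------------------------

def _feature_records(sig: SignatureMatrix, column="HILIC", polarity="pos",
                     rng: np.random.Generator | None = None) -> list[MassFeature]:
    coords = getattr(sig, "_coords", None)
    if coords is None:
        ids, mzs, rts = _draw_feature_ids(rng or np.random.default_rng(0),
                                          len(sig.feature_ids))
        coords = pd.DataFrame({"mz": mzs, "rt_sec": rts}, index=sig.feature_ids)
    return [MassFeature(fid, coords.loc[fid, "mz"], coords.loc[fid, "rt_sec"],
                        column, polarity) for fid in sig.feature_ids]


def _true_mode(block: str) -> str:
    if block.startswith("group:"):
        return "g" + block.split(":")[1]
    return block


def simulate_culture_table(sig: SignatureMatrix,
                           n_reps: int = 3,
                           noise_sigma: float = 0.2,
                           biovolume_um3: float = 1e9,
                           biovolume_sigma: float = 0.2,
                           dataset_id: str = "culture",
                           seed: int = 0) -> tuple[PeakTable, SyntheticTruth]:
    """Replicate harvests of every species under exponential growth.

    area = signature × biovolume × lognormal(0, noise_sigma); the realized
    biovolume of each replicate is recorded in its :class:`SampleRecord`.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    if noise_sigma < 0:
        raise ValidationError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    features = _feature_records(sig, rng=rng)
    samples, columns = [], []
    for species in sig.abundances.index:
        for r in range(n_reps):
            biovol = biovolume_um3 * rng.lognormal(0.0, biovolume_sigma)
            sid = f"{dataset_id}_{species}_r{r + 1}"
            samples.append(SampleRecord(
                sample_id=sid, dataset_id=dataset_id, role="sample",
                replicate_group=species, biovolume_um3=biovol, organism=species))
            col = sig.abundances.loc[species].to_numpy() * biovol
            noise = rng.lognormal(0.0, noise_sigma, col.size) if noise_sigma else 1.0
            columns.append(col * noise)
    areas = np.column_stack(columns)
    table = PeakTable.from_records(features, samples, areas,
                                   meta={"dataset_id": dataset_id,
                                         "units": "area"})
    truth = SyntheticTruth(signatures=sig,
                           mode_labels=sig.blocks.map(_true_mode))
    return table, truth


def simulate_environment_table(sig: SignatureMatrix,
                               design: CommunityDesign,
                               n_reps: int = 1,
                               noise_sigma: float = 0.1,
                               vol_filtered_L: float = 10.0,
                               dataset_id: str = "env",
                               seed: int = 0) -> tuple[PeakTable, SyntheticTruth]:
    """Environmental samples as gradient-weighted mixtures of signatures.

    True abundance of feature j at station s is
    ``biomass_s × Σ_g w_{s,g} × mean signature of j in group g``
    (plus ``biomass_s × w_{s,rare} × base_j`` for the rare block when the
    design carries a rare source).  Areas scale with volume filtered and
    multiplicative log-normal noise.
    """
    if noise_sigma < 0:
        raise ValidationError("noise_sigma must be >= 0")
    group_cols = [c for c in design.weights.columns if c != "rare"]
    means = sig.group_means()                      # groups x features
    missing = set(group_cols) - set(means.index)
    if missing:
        raise ValidationError(f"design references unknown groups {sorted(missing)}")
    w = design.weights[group_cols].to_numpy()      # stations x groups
    m = means.loc[group_cols].to_numpy()           # groups x features
    true_abund = design.biomass[:, None] * (w @ m)  # stations x features
    if "rare" in design.weights.columns:
        rare_mask = (sig.blocks == "rare").to_numpy()
        rare_src = (design.biomass * design.weights["rare"].to_numpy())[:, None]
        true_abund[:, rare_mask] += rare_src * sig.base.to_numpy()[rare_mask]

    rng = np.random.default_rng(seed)
    features = _feature_records(sig, rng=rng)
    samples, columns = [], []
    pos_kw = "latitude" if design.axis_name == "latitude" else "depth_m"
    for s in range(design.n_stations):
        for r in range(n_reps):
            sid = f"{dataset_id}_st{s:02d}_r{r + 1}"
            samples.append(SampleRecord(
                sample_id=sid, dataset_id=dataset_id, role="sample",
                replicate_group=f"st{s:02d}", vol_filtered_L=vol_filtered_L,
                **{pos_kw: float(design.axis[s])}))
            col = true_abund[s] * vol_filtered_L
            noise = rng.lognormal(0.0, noise_sigma, col.size) if noise_sigma else 1.0
            columns.append(col * noise)
    areas = np.column_stack(columns)
    table = PeakTable.from_records(features, samples, areas,
                                   meta={"dataset_id": dataset_id,
                                         "units": "area"})
    truth = SyntheticTruth(signatures=sig, design=design,
                           mode_labels=sig.blocks.map(_true_mode))
    return table, truth


# ---------------------------------------------------------------------------
# instrument artifacts
# ---------------------------------------------------------------------------

def add_instrument_artifacts(table: PeakTable,
                             drift_sigma: float = 0.3,
                             internal_standards=("d3-glycine-betaine", "13C-homarine"),
                             seed: int = 0,
                             n_pooled: int = 3,
                             n_blanks: int = 2,
                             blank_fraction: float = 0.1,
                             n_contaminants: int = 0,
                             contaminant_area: float = 1e6,
                             is_base_area: float = 5e6,
                             is_tracks_drift: bool = True,
                             truth: SyntheticTruth | None = None,
                             ) -> tuple[PeakTable, SyntheticTruth]:
    """Plant the obscuring variation that B-MIS normalization must remove.

    Appends pooled QC injections (mean of the sample columns, pre-drift),
    matrix blanks (``blank_fraction`` of the per-feature median sample
    area), optional contaminant-only features (a constant level in every
    column, so only the blank comparison can catch them), and internal-
    standard rows.  Every column c is then multiplied by a drift factor
    f_c ~ lognormal(0, drift_sigma); internal standards share f_c exactly
    when ``is_tracks_drift`` (the B-MIS best case) and carry independent
    variation of the same magnitude otherwise (the no-matching-IS case).
    """
    if drift_sigma < 0:
        raise ValidationError("drift_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    truth = truth or SyntheticTruth()
    sample_ids = table.sample_ids("sample")
    areas = table.areas.copy()
    features = table.features.copy()
    samples = table.samples.copy()
    dataset_id = table.meta.get("dataset_id", "")
    column = features["column"].iloc[0] if len(features) else "HILIC"
    polarity = features["polarity"].iloc[0] if len(features) else "pos"

    # contaminant-only features: constant everywhere, incl. the blanks
    contaminant_ids = []
    if n_contaminants:
        taken = set(features.index)
        cids, mzs, rts = _draw_feature_ids(rng, n_contaminants, taken)
        crows = pd.DataFrame({"mz": mzs, "rt_sec": rts, "column": column,
                              "polarity": polarity}, index=pd.Index(cids, name="feature_id"))
        features = pd.concat([features, crows])
        areas = pd.concat([areas, pd.DataFrame(
            contaminant_area, index=crows.index, columns=areas.columns)])
        contaminant_ids = cids

    # pooled QC columns: mean of the sample columns before drift
    pooled_pre = areas[sample_ids].mean(axis=1)
    pooled_ids = [f"{dataset_id}_pooled_{i + 1}".lstrip("_") for i in range(n_pooled)]
    for pid in pooled_ids:
        areas[pid] = pooled_pre

    # matrix blanks: residual dissolved pool at blank_fraction of the median
    blank_pre = areas[sample_ids].median(axis=1).fillna(0.0) * blank_fraction
    if contaminant_ids:
        blank_pre.loc[contaminant_ids] = contaminant_area
    blank_ids = [f"{dataset_id}_blank_{i + 1}".lstrip("_") for i in range(n_blanks)]
    for bid in blank_ids:
        areas[bid] = blank_pre

    new_meta = pd.DataFrame(
        [_meta_row(dataset_id, "pooled")] * n_pooled
        + [_meta_row(dataset_id, "blank")] * n_blanks,
        index=pd.Index(pooled_ids + blank_ids, name="sample_id"),
        columns=samples.columns)
    if len(new_meta):
        samples = pd.concat([samples, new_meta.astype(samples.dtypes.to_dict(),
                                                      errors="ignore")])

    # internal-standard rows (constant base level before drift)
    is_ids = []
    taken = set(features.index)
    for name in internal_standards:
        fid = f"IS_{name}"
        if fid in taken:
            raise ValidationError(f"duplicate internal standard {name}")
        mz = float(rng.uniform(100.0, 400.0))
        rt = float(rng.uniform(120.0, 1140.0))
        features.loc[fid] = {"mz": mz, "rt_sec": rt, "column": column,
                             "polarity": polarity}
        areas.loc[fid] = is_base_area
        is_ids.append(fid)

    # per-injection multiplicative drift
    drift = pd.Series(rng.lognormal(0.0, drift_sigma, areas.shape[1])
                      if drift_sigma else np.ones(areas.shape[1]),
                      index=areas.columns, name="drift")
    areas = areas.mul(drift, axis=1)
    if not is_tracks_drift and is_ids:
        # IS variability of the same magnitude but uncorrelated with drift
        indep = rng.lognormal(0.0, drift_sigma, (len(is_ids), areas.shape[1]))
        areas.loc[is_ids] = is_base_area * indep

    out = PeakTable(features, samples, areas, dict(table.meta))
    out.meta["internal_standards"] = list(is_ids)
    truth.drift = drift
    truth.internal_standard_ids = list(is_ids)
    truth.contaminant_ids = list(contaminant_ids)
    return out, truth


def _meta_row(dataset_id: str, role: str) -> dict:
    return {"dataset_id": dataset_id, "role": role, "replicate_group": None,
            "vol_filtered_L": None, "biovolume_um3": None, "latitude": None,
            "depth_m": None, "organism": None}


# ---------------------------------------------------------------------------
# satellite features
# ---------------------------------------------------------------------------

_SATELLITE_RULES = {
    "pos": {**ISOTOPE_OFFSETS, **ADDUCT_OFFSETS["pos"], "2+": None},
    "neg": {**ISOTOPE_OFFSETS, **ADDUCT_OFFSETS["neg"]},
}


def _satellite_mz(parent_mz: float, kind: str) -> float:
    if kind == "2+":
        return (parent_mz + PROTON_MASS) / 2.0
    for pol_rules in (_SATELLITE_RULES["pos"], _SATELLITE_RULES["neg"]):
        if kind in pol_rules and pol_rules[kind] is not None:
            return parent_mz + pol_rules[kind]
    raise ValidationError(f"unknown satellite kind {kind!r}")


def add_adducts_isotopes(table: PeakTable,
                         rate_per_kind: dict[str, float] | float = 0.1,
                         area_fraction: float = 0.2,
                         ppm_jitter: float = 0.0,
                         rt_jitter_sec: float = 0.0,
                         seed: int = 0,
                         exclude: tuple[str, ...] = (),
                         truth: SyntheticTruth | None = None,
                         ) -> tuple[PeakTable, SyntheticTruth]:
    """Append satellite features at the exact isotope/adduct/charge offsets.

    ``rate_per_kind`` is the per-parent planting probability, either one
    rate for every polarity-compatible kind or a kind → rate mapping
    (requesting a kind the table's polarity cannot produce is an error).
    Satellite areas are ``area_fraction`` of the parent's; m/z gets uniform
    jitter within ±``ppm_jitter`` and retention time within
    ±``rt_jitter_sec``.
    """
    polarity = table.features["polarity"].iloc[0]
    valid = _SATELLITE_RULES[polarity]
    if isinstance(rate_per_kind, dict):
        bad = set(rate_per_kind) - set(valid)
        if bad:
            raise ValidationError(
                f"satellite kind(s) {sorted(bad)} invalid for {polarity} mode")
        rates = dict(rate_per_kind)
    else:
        rates = {k: float(rate_per_kind) for k in valid}
    for k, r in rates.items():
        if not 0.0 <= r <= 1.0:
            raise ValidationError(f"rate for {k} must be in [0, 1], got {r}")

    rng = np.random.default_rng(seed)
    truth = truth or SyntheticTruth()
    features = table.features.copy()
    areas = table.areas.copy()
    taken = set(features.index)
    records = []
    new_rows, new_areas = [], []
    parent_ids = [f for f in table.features.index if f not in set(exclude)]
    for fid in parent_ids:
        prow = table.features.loc[fid]
        for kind in sorted(rates):
            if rng.random() >= rates[kind]:
                continue
            mz = _satellite_mz(float(prow["mz"]), kind)
            if ppm_jitter:
                mz *= 1.0 + rng.uniform(-ppm_jitter, ppm_jitter) * 1e-6
            rt = float(prow["rt_sec"])
            if rt_jitter_sec:
                rt = max(0.0, rt + rng.uniform(-rt_jitter_sec, rt_jitter_sec))
            sid = make_feature_id(mz, rt / 60.0)
            if sid in taken:        # coordinate collision: skip this satellite
                continue
            taken.add(sid)
            new_rows.append(pd.Series({"mz": mz, "rt_sec": rt,
                                       "column": prow["column"],
                                       "polarity": prow["polarity"]}, name=sid))
            new_areas.append(table.areas.loc[fid] * area_fraction)
            records.append({"satellite_id": sid, "parent_id": fid, "kind": kind})
    if new_rows:
        features = pd.concat([features, pd.DataFrame(new_rows)])
        adds = pd.DataFrame(new_areas)
        adds.index = [r.name for r in new_rows]
        areas = pd.concat([areas, adds])
    out = PeakTable(features, table.samples.copy(), areas, dict(table.meta))
    truth.satellites = pd.DataFrame(records,
                                    columns=["satellite_id", "parent_id", "kind"])
    return out, truth


# ---------------------------------------------------------------------------
# planted concentrations
# ---------------------------------------------------------------------------

def plant_concentration_areas(concentrations: pd.DataFrame,
                              rf: pd.Series,
                              rf_ratio: float,
                              vol_filtered_L: pd.Series,
                              vol_reconst_L: float = 400e-6) -> pd.DataFrame:
    """Forward model for the quantification round trip (noiseless).

    ``concentrations`` is compounds × samples in the RF concentration unit;
    ``rf`` is area per unit concentration per compound.  The generated area
    is ``conc × RF × RF_ratio × Vol_filtered / Vol_reconst`` — exactly what
    the concentration equation inverts.
    """
    conc = concentrations.to_numpy(dtype=float)
    area = (conc * rf.to_numpy()[:, None] * rf_ratio
            * vol_filtered_L.to_numpy()[None, :] / vol_reconst_L)
    return pd.DataFrame(area, index=concentrations.index,
                        columns=concentrations.columns)


# ---------------------------------------------------------------------------
# ready-made study-scale benchmarks
# ---------------------------------------------------------------------------

def mode_recovery_dataset(seed: int = 0,
                          n_features: int = 313,
                          n_samples: int = 36,
                          noise_sigma: float = 0.1,
                          ) -> tuple[PeakTable, SyntheticTruth]:
    """A transect-scale table with five planted gradient modes.

    313 features split evenly across 5 taxon groups whose mixing weights
    peak in five distinct latitude bands over 36 stations — five community
    types that are mutually well separated in pattern space, the geometry
    the transect mode discovery is expected to resolve.  (Mixtures of
    monotone and peaked shapes form super-clusters that dominate any
    occupancy-based choice of k; banded communities do not.)
    """
    per = n_features // 5
    counts = [per] * 5
    for i in range(n_features - 5 * per):
        counts[i] += 1
    sig = generate_signatures(n_groups=5, species_per_group=2, n_core=0,
                              n_specific_per_group=counts, n_rare=0, seed=seed)
    design = make_gradient_design(
        axis=np.linspace(23.5, 41.5, n_samples),
        shapes=("band_1", "band_2", "band_3", "band_4", "band_5"))
    return simulate_environment_table(sig, design, n_reps=1,
                                      noise_sigma=noise_sigma,
                                      dataset_id="transect", seed=seed + 1)


def satellite_benchmark(seed: int = 0,
                        polarity: str = "pos",
                        n_parents: int = 30,
                        ppm_jitter: float = 0.0,
                        rt_jitter_sec: float = 0.5,
                        rate: float = 0.5,
                        ) -> tuple[PeakTable, SyntheticTruth]:
    """Planted-satellite fixture with parents in separated elution slots.

    Parents elute 20 s apart (beyond any co-elution window), so the only
    co-eluting features are a parent and its own satellites; every
    polarity-compatible satellite kind is planted at probability ``rate``.
    """
    rng = np.random.default_rng(seed)
    features, samples = [], []
    for i in range(n_parents):
        mz = float(rng.uniform(120.0, 700.0))
        rt = 120.0 + 20.0 * i
        features.append(MassFeature.from_coordinates(mz, rt, "HILIC", polarity))
    for j in range(3):
        samples.append(SampleRecord(sample_id=f"bench_s{j + 1}",
                                    dataset_id="bench", role="sample",
                                    vol_filtered_L=10.0))
    areas = rng.lognormal(math.log(1e6), 0.3, (n_parents, len(samples)))
    table = PeakTable.from_records(features, samples, areas,
                                   meta={"dataset_id": "bench"})
    return add_adducts_isotopes(table, rate_per_kind=rate, area_fraction=0.2,
                                ppm_jitter=ppm_jitter,
                                rt_jitter_sec=rt_jitter_sec, seed=seed + 1)
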