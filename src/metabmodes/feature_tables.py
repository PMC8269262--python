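"""Domain types and tabular I/O for untargeted LC-MS feature tables.

The currency of the whole pipeline is the :class:`PeakTable`: a features ×
samples matrix of integrated peak areas together with per-feature chemistry
(m/z, retention time, chromatography column, ionization polarity) and
per-sample metadata (role, replicate group, volume filtered or biovolume,
position).  Mass features follow the ``I<mz>R<rt-minutes>`` naming
convention used in polar-metabolomics work, e.g. ``I121.0684R10.7`` for an
ion at m/z 121.0684 eluting at 10.7 min.

Retention time is stored internally in **seconds** (co-elution windows are
specified in seconds) while feature IDs render minutes.  A missing area is
*not detected* and is distinct from a measured zero; missing values survive
read/write round trips as empty cells.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _pyteomics_mass

__all__ = [
    "COLUMNS",
    "POLARITIES",
    "ROLES",
    "ValidationError",
    "FeatureIdError",
    "MassFeature",
    "SampleRecord",
    "CompoundInfo",
    "PeakTable",
    "make_feature_id",
    "parse_feature_id",
    "read_peak_table",
    "write_peak_table",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_compound_library",
    "write_compound_library",
]

COLUMNS = ("HILIC", "RP")
POLARITIES = ("pos", "neg")
ROLES = ("sample", "pooled", "blank", "medium_blank")

#: roles whose columns count as blanks for the blank filter
BLANK_ROLES = ("blank", "medium_blank")

_FEATURE_ID_RE = re.compile(r"^I(?P<mz>\d+\.\d{4})R(?P<rt>\d+\.\d)$")


class ValidationError(ValueError):
    """A table or record violates a structural invariant."""


class FeatureIdError(ValueError):
    """A feature-ID string does not follow the I<mz>R<rt> convention."""


def make_feature_id(mz: float, rt_min: float) -> str:
    """Render the canonical feature ID for an ion.

    ``mz`` is printed to 4 decimal places and ``rt_min`` (retention time in
    minutes) to 1, both with round-half-even, e.g.
    ``make_feature_id(121.0684, 10.7) == "I121.0684R10.7"``.
    """
    if not (math.isfinite(mz) and math.isfinite(rt_min)):
        raise ValueError(f"non-finite feature coordinates: mz={mz}, rt_min={rt_min}")
    if mz <= 0:
        raise ValueError(f"m/z must be positive, got {mz}")
    if rt_min < 0:
        raise ValueError(f"retention time must be non-negative, got {rt_min}")
    return f"I{mz:.4f}R{rt_min:.1f}"


def parse_feature_id(feature_id: str) -> tuple[float, float]:
    """Invert :func:`make_feature_id`; returns ``(mz, rt_min)``.

    Raises :class:`FeatureIdError` naming the offending token when the
    string does not match ``I<mz>R<rt>``.
    """
    m = _FEATURE_ID_RE.match(feature_id)
    if m is None:
        raise FeatureIdError(
            f"feature id {feature_id!r} does not match the I<mz>R<rt> pattern "
            "(expected e.g. 'I121.0684R10.7')"
        )
    return float(m.group("mz")), float(m.group("rt"))


@dataclass(frozen=True)
class MassFeature:
    """A chromatographic peak defined by m/z and retention time."""

    feature_id: str
    mz: float
    rt_sec: float
    column: str = "HILIC"
    polarity: str = "pos"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mz) and self.mz > 0):
            raise ValidationError(f"{self.feature_id}: m/z must be finite and > 0, got {self.mz}")
        if not (math.isfinite(self.rt_sec) and self.rt_sec >= 0):
            raise ValidationError(f"{self.feature_id}: rt_sec must be >= 0, got {self.rt_sec}")
        if self.column not in COLUMNS:
            raise ValidationError(f"{self.feature_id}: unknown column {self.column!r}")
        if self.polarity not in POLARITIES:
            raise ValidationError(f"{self.feature_id}: unknown polarity {self.polarity!r}")

    @property
    def rt_min(self) -> float:
        return self.rt_sec / 60.0

    @classmethod
    def from_coordinates(cls, mz: float, rt_sec: float, column: str = "HILIC",
                         polarity: str = "pos") -> "MassFeature":
        """Build a feature whose ID is derived from its own coordinates."""
        return cls(make_feature_id(mz, rt_sec / 60.0), mz, rt_sec, column, polarity)


@dataclass(frozen=True)
class SampleRecord:
    """Metadata for one analyzed sample (one column of the peak table)."""

    sample_id: str
    dataset_id: str = ""
    role: str = "sample"
    replicate_group: str | None = None
    vol_filtered_L: float | None = None
    biovolume_um3: float | None = None
    latitude: float | None = None
    depth_m: float | None = None
    organism: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"{self.sample_id}: unknown role {self.role!r}")
        if self.vol_filtered_L is not None and self.biovolume_um3 is not None:
            raise ValidationError(
                f"{self.sample_id}: vol_filtered_L and biovolume_um3 are mutually "
                "exclusive (environmental vs culture sample)"
            )
        for name in ("vol_filtered_L", "biovolume_um3"):
            v = getattr(self, name)
            if v is not None and not (math.isfinite(v) and v > 0):
                raise ValidationError(f"{self.sample_id}: {name} must be > 0, got {v}")

    @property
    def normalizer_volume(self) -> float | None:
        """Volume filtered (L) or biovolume (µm³), whichever is present."""
        return self.vol_filtered_L if self.vol_filtered_L is not None else self.biovolume_um3


_FORMULA_RE = re.compile(r"^([A-Z][a-z]?\d*)+$")


@dataclass
class CompoundInfo:
    """An identified compound with its empirical formula and element counts."""

    name: str
    formula: str
    n_C: int = 0
    n_N: int = 0
    n_S: int = 0
    monoisotopic_mass: float = 0.0
    matched_feature_id: str | None = None

    def __post_init__(self) -> None:
        if min(self.n_C, self.n_N, self.n_S) < 0:
            raise ValidationError(f"{self.name}: element counts must be >= 0")

    @classmethod
    def from_formula(cls, name: str, formula: str,
                     matched_feature_id: str | None = None) -> "CompoundInfo":
        """Parse element counts and monoisotopic mass from a formula string."""
        if not _FORMULA_RE.match(formula):
            raise ValidationError(f"{name}: cannot parse formula {formula!r}")
        comp = _pyteomics_mass.Composition(formula=formula)
        return cls(
            name=name,
            formula=formula,
            n_C=comp.get("C", 0),
            n_N=comp.get("N", 0),
            n_S=comp.get("S", 0),
            monoisotopic_mass=_pyteomics_mass.calculate_mass(composition=comp),
            matched_feature_id=matched_feature_id,
        )


@dataclass
class PeakTable:
    """Features × samples matrix of peak areas with aligned metadata.

    Attributes
    ----------
    features : pandas.DataFrame
        Indexed by ``feature_id`` with columns ``mz``, ``rt_sec``,
        ``column``, ``polarity``.
    samples : pandas.DataFrame
        Indexed by ``sample_id`` with columns ``dataset_id``, ``role``,
        ``replicate_group``, ``vol_filtered_L``, ``biovolume_um3``,
        ``latitude``, ``depth_m``, ``organism``.
    areas : pandas.DataFrame
        Peak areas (arbitrary instrument units); NaN means not detected.
    meta : dict
        Free-form provenance (units, normalization applied, ...).
    """

    features: pd.DataFrame
    samples: pd.DataFrame
    areas: pd.DataFrame
    meta: dict = field(default_factory=dict)

    FEATURE_COLS = ("mz", "rt_sec", "column", "polarity")
    SAMPLE_COLS = ("dataset_id", "role", "replicate_group", "vol_filtered_L",
                   "biovolume_um3", "latitude", "depth_m", "organism")

    def __post_init__(self) -> None:
        self.features.index.name = "feature_id"
        self.areas.index.name = "feature_id"
        self.samples.index.name = "sample_id"
        self.areas.columns.name = "sample_id"
        self.validate()

    # -- construction ----------------------------------------------------
    @classmethod
    def from_records(cls, features: Sequence[MassFeature],
                     samples: Sequence[SampleRecord],
                     areas: np.ndarray | pd.DataFrame,
                     meta: dict | None = None) -> "PeakTable":
        fdf = pd.DataFrame(
            {c: [getattr(f, c) for f in features] for c in cls.FEATURE_COLS},
            index=pd.Index([f.feature_id for f in features], name="feature_id"),
        )
        sdf = pd.DataFrame(
            {c: [getattr(s, c) for s in samples] for c in cls.SAMPLE_COLS},
            index=pd.Index([s.sample_id for s in samples], name="sample_id"),
        )
        adf = pd.DataFrame(np.asarray(areas, dtype=float),
                           index=fdf.index.copy(), columns=sdf.index.copy())
        return cls(fdf, sdf, adf, meta or {})

    def validate(self) -> None:
        if self.features.index.has_duplicates:
            dups = self.features.index[self.features.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups}")
        if self.samples.index.has_duplicates:
            dups = self.samples.index[self.samples.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if not self.areas.index.equals(self.features.index):
            raise ValidationError("area matrix rows do not match feature list")
        if not self.areas.columns.equals(self.samples.index):
            raise ValidationError("area matrix columns do not match sample list")
        neg = self.areas.lt(0)
        if neg.any().any():
            offenders = self.areas.index[neg.any(axis=1)].tolist()
            raise ValidationError(f"negative areas for features: {offenders}")
        bad_roles = set(self.samples["role"]) - set(ROLES)
        if bad_roles:
            raise ValidationError(f"unknown sample roles: {sorted(bad_roles)}")

    # -- convenience -----------------------------------------------------
    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_ids(self, role: str | Iterable[str] = "sample") -> list[str]:
        roles = (role,) if isinstance(role, str) else tuple(role)
        return self.samples.index[self.samples["role"].isin(roles)].tolist()

    def blank_ids(self) -> list[str]:
        return self.sample_ids(BLANK_ROLES)

    def copy(self) -> "PeakTable":
        return PeakTable(self.features.copy(), self.samples.copy(),
                         self.areas.copy(), dict(self.meta))

    def with_areas(self, areas: pd.DataFrame, **meta_updates) -> "PeakTable":
        new = PeakTable(self.features.copy(), self.samples.copy(), areas,
                        dict(self.meta))
        new.meta.update(meta_updates)
        return new

    def subset_features(self, feature_ids: Sequence[str]) -> "PeakTable":
        idx = pd.Index(feature_ids)
        missing = idx.difference(self.features.index)
        if len(missing):
            raise ValidationError(f"unknown feature ids: {missing.tolist()}")
        return PeakTable(self.features.loc[idx], self.samples.copy(),
                         self.areas.loc[idx], dict(self.meta))

    def drop_features(self, feature_ids: Sequence[str]) -> "PeakTable":
        keep = self.features.index.difference(pd.Index(feature_ids), sort=False)
        return self.subset_features(keep.tolist())

    def feature_records(self) -> list[MassFeature]:
        return [MassFeature(fid, row.mz, row.rt_sec, row.column, row.polarity)
                for fid, row in self.features.iterrows()]

    def sample_records(self) -> list[SampleRecord]:
        out = []
        for sid, row in self.samples.iterrows():
            kw = {c: (None if pd.isna(row[c]) else row[c]) for c in self.SAMPLE_COLS}
            out.append(SampleRecord(sample_id=sid, **kw))
        return out


# ---------------------------------------------------------------------------
# I/O — comma-separated UTF-8 text with a header row; delimiter configurable.
# ---------------------------------------------------------------------------

def read_peak_table(areas_path: str | Path,
                    samples_path: str | Path | None = None,
                    features_path: str | Path | None = None,
                    delimiter: str = ",",
                    column: str = "HILIC",
                    polarity: str = "pos") -> PeakTable:
    """Read a peak table from text files.

    ``areas_path`` holds the matrix: first column ``feature_id``, one column
    per sample; empty cells are missing (not zero).  If ``features_path`` is
    omitted, m/z and retention time are parsed from the feature IDs
    themselves (IDs that do not follow the convention get NaN coordinates).
    If ``samples_path`` is omitted, every column is taken as ``role=sample``.
    """
    areas = pd.read_csv(areas_path, sep=delimiter, index_col=0)
    areas.index = areas.index.astype(str)
    areas.index.name = "feature_id"
    if areas.index.has_duplicates:
        dups = areas.index[areas.index.duplicated()].unique().tolist()
        raise ValidationError(f"{areas_path}: duplicate feature ids {dups}")
    non_numeric = areas.apply(lambda c: ~c.map(_is_number_or_na)).any(axis=None)
    if non_numeric:
        raise ValidationError(f"{areas_path}: non-numeric area entries")
    areas = areas.astype(float)

    if features_path is not None:
        fdf = pd.read_csv(features_path, sep=delimiter, index_col="feature_id")
        fdf.index = fdf.index.astype(str)
        missing = areas.index.difference(fdf.index)
        if len(missing):
            raise ValidationError(f"features file lacks entries for {missing.tolist()}")
        fdf = fdf.loc[areas.index, list(PeakTable.FEATURE_COLS)]
    else:
        coords = []
        for fid in areas.index:
            try:
                mz, rt_min = parse_feature_id(fid)
                coords.append((mz, rt_min * 60.0))
            except FeatureIdError:
                coords.append((np.nan, np.nan))
        fdf = pd.DataFrame(coords, index=areas.index, columns=["mz", "rt_sec"])
        fdf["column"] = column
        fdf["polarity"] = polarity

    if samples_path is not None:
        records = read_sample_metadata(samples_path, delimiter=delimiter)
        sdf = _samples_to_frame(records)
        missing = areas.columns.difference(sdf.index)
        if len(missing):
            raise ValidationError(f"sample metadata lacks entries for {missing.tolist()}")
        sdf = sdf.loc[areas.columns]
        sdf.index.name = "sample_id"
    else:
        sdf = _samples_to_frame(
            [SampleRecord(sample_id=str(s)) for s in areas.columns])
    areas.columns = sdf.index
    return PeakTable(fdf, sdf, areas)


def _is_number_or_na(x) -> bool:
    if pd.isna(x):
        return True
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


def _samples_to_frame(records: Sequence[SampleRecord]) -> pd.DataFrame:
    sdf = pd.DataFrame(
        {c: [getattr(s, c) for s in records] for c in PeakTable.SAMPLE_COLS},
        index=pd.Index([s.sample_id for s in records], name="sample_id"),
    )
    if sdf.index.has_duplicates:
        dups = sdf.index[sdf.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids: {dups}")
    return sdf


def write_peak_table(table: PeakTable,
                     areas_path: str | Path,
                     samples_path: str | Path | None = None,
                     features_path: str | Path | None = None,
                     delimiter: str = ",") -> None:
    """Write a :class:`PeakTable` to text; missing areas become empty cells."""
    table.areas.to_csv(areas_path, sep=delimiter)
    if features_path is not None:
        table.features.to_csv(features_path, sep=delimiter)
    if samples_path is not None:
        table.samples.to_csv(samples_path, sep=delimiter)


def read_sample_metadata(path: str | Path, delimiter: str = ",") -> list[SampleRecord]:
    """Read sample metadata; every row is validated as a :class:`SampleRecord`."""
    df = pd.read_csv(path, sep=delimiter, dtype={"sample_id": str})
    if "sample_id" not in df.columns or "role" not in df.columns:
        raise ValidationError(f"{path}: sample metadata needs sample_id and role columns")
    records = []
    for _, row in df.iterrows():
        kw = {}
        for col in PeakTable.SAMPLE_COLS:
            if col in df.columns and not pd.isna(row[col]):
                kw[col] = row[col]
        records.append(SampleRecord(sample_id=str(row["sample_id"]), **kw))
    if len({r.sample_id for r in records}) != len(records):
        raise ValidationError(f"{path}: duplicate sample ids")
    return records


def write_sample_metadata(records: Sequence[SampleRecord], path: str | Path,
                          delimiter: str = ",") -> None:
    _samples_to_frame(records).to_csv(path, sep=delimiter)


def read_compound_library(path: str | Path, delimiter: str = ",") -> list[CompoundInfo]:
    """Read a compound library (name, formula[, matched_feature_id])."""
    df = pd.read_csv(path, sep=delimiter)
    if "name" not in df.columns or "formula" not in df.columns:
        raise ValidationError(f"{path}: compound library needs name and formula columns")
    out = []
    for _, row in df.iterrows():
        matched = row.get("matched_feature_id")
        out.append(CompoundInfo.from_formula(
            str(row["name"]), str(row["formula"]),
            None if pd.isna(matched) else str(matched)))
    return out


def write_compound_library(compounds: Sequence[CompoundInfo], path: str | Path,
                           delimiter: str = ",") -> None:
    pd.DataFrame([{
        "name": c.name, "formula": c.formula, "n_C": c.n_C, "n_N": c.n_N,
        "n_S": c.n_S, "monoisotopic_mass": c.monoisotopic_mass,
        "matched_feature_id": c.matched_feature_id,
    } for c in compounds]).to_csv(path, sep=delimiter, index=False)
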