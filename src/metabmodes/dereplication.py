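"""Dereplication of isotopologue, adduct, and doubly charged satellites.

One analyte can yield several mass features: natural-abundance heavy-isotope
peaks (13C, 15N, 34S), alternative cation/anion adducts (Na+, NH4+, K+ in
positive mode; Cl- in negative mode), and doubly charged ions.  Leaving
them in a feature table gives the analyte extra statistical weight, so
satellites are flagged against their parent and removed before multivariate
analysis.

A candidate pair is flagged when the m/z offset matches one of the known
mass differences within a ppm tolerance, the two features co-elute within
the column's retention-time window (3 s reversed-phase, 6 s HILIC, as an
absolute |ΔRT| bound), and the satellite's mean area is below the parent's.
The offset table is data, not code (:data:`ISOTOPE_OFFSETS`,
:data:`ADDUCT_OFFSETS`).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .feature_tables import PeakTable, ValidationError

__all__ = [
    "PROTON_MASS", "ISOTOPE_OFFSETS", "ADDUCT_OFFSETS", "RT_WINDOW_SEC",
    "SatelliteAnnotation", "find_isotopologues", "find_adducts",
    "find_multiply_charged", "annotate_satellites", "dereplicate_table",
]

#: mass of a proton (Da); [M+H]+ = M + PROTON_MASS
PROTON_MASS = 1.007276

#: heavy-isotope mass offsets relative to the monoisotopic feature (Da)
ISOTOPE_OFFSETS = {
    "13C": 1.003355,
    "15N": 0.997035,
    "34S": 1.995796,
}

#: adduct offsets relative to the (de)protonated feature (Da), by polarity
ADDUCT_OFFSETS = {
    "pos": {"Na": 21.981944, "NH4": 17.026549, "K": 37.955882},
    "neg": {"Cl": 35.976678},
}

#: default co-elution window per chromatography column (seconds, |ΔRT| bound)
RT_WINDOW_SEC = {"RP": 3.0, "HILIC": 6.0}

SATELLITE_KINDS = ("13C", "15N", "34S", "Na", "NH4", "K", "Cl", "2+")


@dataclass(frozen=True)
class SatelliteAnnotation:
    """A flagged (satellite, parent) relationship."""

    satellite_id: str
    parent_id: str
    kind: str
    mass_error_ppm: float = 0.0
    rt_gap_sec: float = 0.0


def _single_column_polarity(table: PeakTable) -> tuple[str, str]:
    cols = table.features["column"].unique()
    pols = table.features["polarity"].unique()
    if len(cols) > 1 or len(pols) > 1:
        raise ValidationError(
            f"dereplication search needs a single column/polarity, got "
            f"columns={sorted(cols)}, polarities={sorted(pols)}")
    return cols[0], pols[0]


def _mean_areas(table: PeakTable) -> pd.Series:
    sample_ids = table.sample_ids("sample") or table.areas.columns.tolist()
    return table.areas[sample_ids].mean(axis=1).fillna(0.0)


def _match_offsets(table: PeakTable, offsets: dict[str, float],
                   window_sec: float | None, ppm_tol: float,
                   require_smaller_area: bool = True) -> list[SatelliteAnnotation]:
    """Core pair search: satellite at parent m/z + offset, co-eluting.

    When several parents explain one (satellite, kind) pair, the parent with
    the larger mean area wins (satellite intensity scales with its parent).
    """
    column, _ = _single_column_polarity(table)
    if window_sec is None:
        window_sec = RT_WINDOW_SEC[column]
    mz = table.features["mz"].to_numpy()
    rt = table.features["rt_sec"].to_numpy()
    ids = table.features.index.to_numpy()
    mean_area = _mean_areas(table).to_numpy()

    best: dict[tuple[str, str], SatelliteAnnotation] = {}
    best_parent_area: dict[tuple[str, str], float] = {}
    for kind, offset in offsets.items():
        for i in range(len(ids)):          # i = parent
            expected = mz[i] + offset
            tol_da = ppm_tol * 1e-6 * expected
            cand = np.nonzero(
                (np.abs(mz - expected) <= tol_da)
                & (np.abs(rt - rt[i]) <= window_sec))[0]
            for j in cand:
                if j == i:
                    continue
                if require_smaller_area and not (mean_area[j] < mean_area[i]):
                    continue
                key = (ids[j], kind)
                if key in best and best_parent_area[key] >= mean_area[i]:
                    continue
                best[key] = SatelliteAnnotation(
                    satellite_id=ids[j], parent_id=ids[i], kind=kind,
                    mass_error_ppm=float((mz[j] - expected) / expected * 1e6),
                    rt_gap_sec=float(rt[j] - rt[i]))
                best_parent_area[key] = mean_area[i]
    return sorted(best.values(), key=lambda a: (a.satellite_id, a.kind))


def find_isotopologues(table: PeakTable, window_sec: float | None = None,
                       ppm_tol: float = 5.0,
                       require_smaller_area: bool = True) -> list[SatelliteAnnotation]:
    """Flag 13C, 15N, and 34S isotopologues of other features."""
    return _match_offsets(table, ISOTOPE_OFFSETS, window_sec, ppm_tol,
                          require_smaller_area)


def find_adducts(table: PeakTable, window_sec: float | None = None,
                 ppm_tol: float = 5.0,
                 kinds: tuple[str, ...] | None = None) -> list[SatelliteAnnotation]:
    """Flag Na/NH4/K (positive mode) or Cl (negative mode) adducts.

    ``kinds`` restricts the search; requesting an adduct incompatible with
    the table's polarity is an error.
    """
    _, polarity = _single_column_polarity(table)
    offsets = ADDUCT_OFFSETS[polarity]
    if kinds is not None:
        bad = set(kinds) - set(offsets)
        if bad:
            raise ValidationError(
                f"adduct kind(s) {sorted(bad)} not valid in {polarity} mode "
                f"(valid: {sorted(offsets)})")
        offsets = {k: offsets[k] for k in kinds}
    return _match_offsets(table, offsets, window_sec, ppm_tol)


def find_multiply_charged(table: PeakTable, window_sec: float | None = None,
                          ppm_tol: float = 5.0) -> list[SatelliteAnnotation]:
    """Flag doubly charged ions of features whose M+H ion is present.

    A singly charged feature at m (taken as [M+H]+) has its 2+ companion at
    (m + 1.007276) / 2.
    """
    column, polarity = _single_column_polarity(table)
    if polarity != "pos":
        raise ValidationError("doubly-charged search is defined for positive mode")
    if window_sec is None:
        window_sec = RT_WINDOW_SEC[column]
    mz = table.features["mz"].to_numpy()
    rt = table.features["rt_sec"].to_numpy()
    ids = table.features.index.to_numpy()
    mean_area = _mean_areas(table).to_numpy()

    best: dict[str, SatelliteAnnotation] = {}
    best_area: dict[str, float] = {}
    for i in range(len(ids)):              # i = singly charged parent
        expected = (mz[i] + PROTON_MASS) / 2.0
        tol_da = ppm_tol * 1e-6 * expected
        cand = np.nonzero((np.abs(mz - expected) <= tol_da)
                          & (np.abs(rt - rt[i]) <= window_sec))[0]
        for j in cand:
            if j == i or not (mean_area[j] < mean_area[i]):
                continue
            if ids[j] in best and best_area[ids[j]] >= mean_area[i]:
                continue
            best[ids[j]] = SatelliteAnnotation(
                satellite_id=ids[j], parent_id=ids[i], kind="2+",
                mass_error_ppm=float((mz[j] - expected) / expected * 1e6),
                rt_gap_sec=float(rt[j] - rt[i]))
            best_area[ids[j]] = mean_area[i]
    return sorted(best.values(), key=lambda a: a.satellite_id)


def annotate_satellites(table: PeakTable, window_sec: float | None = None,
                        ppm_tol: float = 5.0) -> list[SatelliteAnnotation]:
    """Run all three searches, splitting the table by (column, polarity)."""
    annotations: list[SatelliteAnnotation] = []
    for (_, pol), fids in table.features.groupby(["column", "polarity"]).groups.items():
        sub = table.subset_features(list(fids))
        annotations += find_isotopologues(sub, window_sec, ppm_tol)
        annotations += find_adducts(sub, window_sec, ppm_tol)
        if pol == "pos":
            annotations += find_multiply_charged(sub, window_sec, ppm_tol)
    return sorted(annotations, key=lambda a: (a.satellite_id, a.kind))


def dereplicate_table(table: PeakTable,
                      annotations: list[SatelliteAnnotation],
                      ) -> tuple[PeakTable, pd.DataFrame]:
    """Remove flagged satellites; parents stay.

    Chains resolve transitively to the ultimate parent (A←B and B←C drop
    both B and C, keep A); a feature is removed only in its satellite role.
    A cycle in the satellite→parent graph is an error reporting the cycle.

    Returns the filtered table and a removal list (satellite_id, parent_id,
    ultimate_parent_id, kind).
    """
    unknown = {a.satellite_id for a in annotations} | {a.parent_id for a in annotations}
    unknown -= set(table.features.index)
    if unknown:
        raise ValidationError(f"annotations reference unknown features: {sorted(unknown)}")

    g = nx.DiGraph()
    for a in annotations:
        g.add_edge(a.satellite_id, a.parent_id, kind=a.kind)
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        raise ValidationError(f"satellite/parent annotation cycle: {cycle}")

    def ultimate(fid: str) -> str:
        while g.out_degree(fid) > 0:
            # deterministic walk: follow the lexicographically first parent
            fid = min(g.successors(fid))
        return fid

    removed = sorted({a.satellite_id for a in annotations})
    rows = [{"satellite_id": a.satellite_id, "parent_id": a.parent_id,
             "ultimate_parent_id": ultimate(a.parent_id), "kind": a.kind,
             "mass_error_ppm": a.mass_error_ppm, "rt_gap_sec": a.rt_gap_sec}
            for a in annotations]
    removal = pd.DataFrame(rows, columns=["satellite_id", "parent_id",
                                          "ultimate_parent_id", "kind",
                                          "mass_error_ppm", "rt_gap_sec"])
    return table.drop_features(removed), removal
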