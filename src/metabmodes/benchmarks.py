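"""Self-validation experiments: recover planted structure from synthetic data.

Each function runs one end-to-end recovery experiment at a fixed problem
size and returns the measured quantities (agreement with an exact oracle,
error rates, recovered-structure scores).  They are used both by the test
suite and by the reproduction script; everything is deterministic given
the seed.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import hypergeom
from sklearn.metrics import adjusted_rand_score

from . import synthetic_data as sd
from .dereplication import annotate_satellites
from .enrichment_network import permutation_enrichment
from .normalization import bmis_normalize
from .pattern_analysis import (CLARA, KMedoids, ModePartition, anosim,
                               select_k_silhouette)
from .qc_filters import _row_cv, apply_qc

__all__ = [
    "enrichment_toy", "null_type_one_error", "pam_optimality",
    "mode_recovery", "dereplication_recovery", "bmis_recovery",
    "quantification_roundtrip", "qc_recovery", "anosim_checks",
    "metacluster_toy",
]


def _partition(dataset_id: str, labels: dict[str, str]) -> ModePartition:
    s = pd.Series(labels)
    return ModePartition(dataset_id=dataset_id, labels=s, medoids={},
                         k=int(s.nunique()))


def enrichment_toy(n_perm: int = 10_000, seed: int = 0) -> dict:
    """Two size-10 modes sharing 8 of 20 features: the Monte Carlo p-value
    against the exact hypergeometric tail P(X >= 8), X ~ HG(20, 10, 10)."""
    ids = [f"f{i}" for i in range(20)]
    pa = _partition("a", {f: ("A" if i < 10 else "B")
                          for i, f in enumerate(ids)})
    pb = _partition("b", {f: ("X" if (i < 8 or 10 <= i < 12) else "Y")
                          for i, f in enumerate(ids)})
    res = permutation_enrichment(pa, pb, n_perm=n_perm, seed=seed)
    exact = float(hypergeom.sf(7, 20, 10, 10))
    p = float(res.p_values.loc["A", "X"])
    return {"p_perm": p, "p_exact": exact, "abs_diff": abs(p - exact),
            "mc_se": float(np.sqrt(exact * (1 - exact) / n_perm)),
            "n_perm": n_perm}


#: mode-size profiles mirroring the published partitions at 300 features:
#: culture-like = one shared mode (~17%), five taxon modes, a rare mode and
#: a large never-observed tail; transect-like = 40/19/4x7.5/8 percent modes
_NULL_SIZES_A = (50, 29, 26, 24, 20, 19, 57, 75)      # culture-like, 300
_NULL_SIZES_B = (120, 57, 24, 23, 23, 23, 30)         # transect-like, 300


def null_type_one_error(n_reps: int = 200, n_perm: int = 1000,
                        alpha: float = 0.05, seed: int = 0) -> dict:
    """Fraction of mode pairs called enriched between independent random
    partitions of 300 features; should sit near alpha."""
    rng = np.random.default_rng(seed)
    ids = [f"f{i}" for i in range(sum(_NULL_SIZES_A))]
    base_a = np.repeat([f"m{i}" for i in range(len(_NULL_SIZES_A))],
                       _NULL_SIZES_A)
    base_b = np.repeat([f"n{i}" for i in range(len(_NULL_SIZES_B))],
                       _NULL_SIZES_B)
    hits = total = 0
    for _ in range(n_reps):
        pa = _partition("a", dict(zip(ids, rng.permutation(base_a))))
        pb = _partition("b", dict(zip(ids, rng.permutation(base_b))))
        res = permutation_enrichment(pa, pb, n_perm=n_perm,
                                     seed=int(rng.integers(2 ** 31)))
        hits += int((res.p_values.to_numpy() < alpha).sum())
        total += res.p_values.size
    return {"fraction_significant": hits / total, "n_pairs": total,
            "alpha": alpha}


def pam_optimality(n_instances: int = 25, n_points: int = 8, k: int = 2,
                   seed: int = 0) -> dict:
    """PAM objective vs the exhaustive minimum over all medoid subsets."""
    rng = np.random.default_rng(seed)
    matches = 0
    for _ in range(n_instances):
        X = rng.uniform(0.0, 1.0, (n_points, 2))
        D = squareform(pdist(X))
        est = KMedoids(n_clusters=k, metric="precomputed").fit(D)
        brute = min(D[:, list(c)].min(axis=1).sum()
                    for c in itertools.combinations(range(n_points), k))
        matches += int(np.isclose(est.inertia_, brute))
    return {"fraction_optimal": matches / n_instances,
            "n_instances": n_instances}


def mode_recovery(seed: int = 0, n_seeds_auto_k: int = 20,
                  noise_sigma: float = 0.1) -> dict:
    """Recover five planted gradient modes (313 features × 36 samples).

    Scores CLARA at the true k by adjusted Rand index against the planted
    labels, and the silhouette rule's hit rate for k=5 over fresh seeds.
    """
    from .normalization import standardize_to_total
    table, truth = sd.mode_recovery_dataset(seed=seed,
                                            noise_sigma=noise_sigma)
    std = standardize_to_total(table)
    est = CLARA(n_clusters=5, random_state=seed).fit(std.to_numpy())
    ari = adjusted_rand_score(truth.mode_labels.loc[std.index], est.labels_)

    hits = 0
    for s in range(n_seeds_auto_k):
        t, _ = sd.mode_recovery_dataset(seed=seed + 1 + s,
                                        noise_sigma=noise_sigma)
        vals = standardize_to_total(t)
        k, _ = select_k_silhouette(vals.to_numpy(), k_min=2, k_max=8,
                                   seed=seed + 1 + s)
        hits += int(k == 5)
    return {"ari_true_k": float(ari), "auto_k_hit_rate": hits / n_seeds_auto_k,
            "n_features": len(std), "n_seeds": n_seeds_auto_k}


def _satellite_scores(seed: int, ppm_jitter: float, ppm_tol: float) -> tuple:
    tp = n_found = n_planted = 0
    for polarity in ("pos", "neg"):
        table, truth = sd.satellite_benchmark(seed=seed, polarity=polarity,
                                              ppm_jitter=ppm_jitter)
        found = {(a.satellite_id, a.parent_id, a.kind)
                 for a in annotate_satellites(table, ppm_tol=ppm_tol)}
        planted = set(map(tuple, truth.satellites[
            ["satellite_id", "parent_id", "kind"]].itertuples(index=False)))
        tp += len(found & planted)
        n_found += len(found)
        n_planted += len(planted)
    return tp, n_found, n_planted


def dereplication_recovery(seed: int = 0) -> dict:
    """Precision/recall of satellite flagging against planted truth."""
    tp, n_found, n_planted = _satellite_scores(seed, ppm_jitter=0.0,
                                               ppm_tol=5.0)
    out = {"precision_noiseless": tp / n_found if n_found else 1.0,
           "recall_noiseless": tp / n_planted if n_planted else 1.0,
           "n_planted": n_planted}
    tp, n_found, n_planted = _satellite_scores(seed + 1, ppm_jitter=2.0,
                                               ppm_tol=5.0)
    out["recall_2ppm_jitter"] = tp / n_planted if n_planted else 1.0
    return out


def _bmis_table(seed: int, is_tracks_drift: bool):
    sig = sd.generate_signatures(seed=seed)
    design = sd.make_gradient_design(
        np.linspace(23.5, 41.5, 12),
        shapes=("band_1", "band_2", "band_3", "band_4", "band_5"),
        rare_shape="deep")
    table, truth = sd.simulate_environment_table(sig, design, n_reps=2,
                                                 noise_sigma=0.02,
                                                 seed=seed + 1)
    return sd.add_instrument_artifacts(table, drift_sigma=0.3, seed=seed + 2,
                                       is_tracks_drift=is_tracks_drift,
                                       truth=truth)


def bmis_recovery(seed: int = 0) -> dict:
    """B-MIS with drift shared by an internal standard (and the negative
    control where no standard tracks the drift)."""
    table, truth = _bmis_table(seed, is_tracks_drift=True)
    out, _ = bmis_normalize(table)
    true_ids = truth.mode_labels.index
    post_cv = _row_cv(out.areas.loc[true_ids, table.sample_ids("pooled")])
    frac_clean = float((post_cv <= 0.05).mean())

    table2, truth2 = _bmis_table(seed + 10, is_tracks_drift=False)
    _, res = bmis_normalize(table2)
    frac_baseline = float(
        (res.chosen.loc[truth2.mode_labels.index] == "none").mean())
    return {"fraction_pooled_cv_le_0p05": frac_clean,
            "fraction_baseline_retained_no_is": frac_baseline,
            "n_features": len(true_ids)}


def quantification_roundtrip(seed: int = 0) -> dict:
    """Plant concentrations, generate noiseless areas, invert, compare."""
    from .quantification import (QuantContext, compute_rf_relative,
                                 concentration_in_sample, estimate_rf)
    rng = np.random.default_rng(seed)
    compounds = [f"cmp{i}" for i in range(20)]
    samples = [f"s{j}" for j in range(10)]
    conc = pd.DataFrame(rng.lognormal(-2.0, 1.0, (20, 10)), index=compounds,
                        columns=samples)
    rf = pd.Series(rng.lognormal(11.0, 0.5, 20), index=compounds)
    vols = pd.Series(rng.uniform(4.0, 15.0, 10), index=samples)
    rf_ratio = 0.8
    areas = sd.plant_concentration_areas(conc, rf, rf_ratio, vols)
    errs = []
    for c in compounds:
        for s in samples:
            ctx = QuantContext(rf=float(rf[c]), vol_filtered_L=float(vols[s]),
                               rf_ratio=rf_ratio)
            got = concentration_in_sample(float(areas.loc[c, s]), ctx)
            errs.append(abs(got - conc.loc[c, s]) / conc.loc[c, s])
    rf_a, rf_b = float(rng.lognormal(11, 0.5)), float(rng.lognormal(11, 0.5))
    rfrel_err = abs(estimate_rf(compute_rf_relative(rf_a, rf_b), rf_b) - rf_a)
    return {"max_rel_error": float(max(errs)),
            "rf_relative_roundtrip_error": rfrel_err,
            "n_values": len(errs)}


def qc_recovery(seed: int = 0, n_contaminants: int = 10) -> dict:
    """Noiseless table: contaminants must fall to the blank filter, true
    features must all survive."""
    sig = sd.generate_signatures(seed=seed)
    design = sd.make_gradient_design(
        np.linspace(23.5, 41.5, 12),
        shapes=("band_1", "band_2", "band_3", "band_4", "band_5"),
        rare_shape="deep")
    table, truth = sd.simulate_environment_table(sig, design, n_reps=2,
                                                 noise_sigma=0.0,
                                                 seed=seed + 1)
    table, truth = sd.add_instrument_artifacts(
        table, drift_sigma=0.0, seed=seed + 2,
        n_contaminants=n_contaminants, truth=truth)
    filtered, report = apply_qc(table)
    removed_by_blank = float(
        report.flags.loc[truth.contaminant_ids, "blank_fail"].mean())
    surviving_contaminants = len(
        set(truth.contaminant_ids) & set(filtered.features.index))
    true_ids = truth.mode_labels.index
    false_removed = float(report.flags.loc[true_ids].any(axis=1).mean())
    return {"contaminant_blank_removal": removed_by_blank,
            "contaminants_surviving": surviving_contaminants,
            "true_feature_false_removal": false_removed,
            "n_true_features": len(true_ids)}


def anosim_checks(seed: int = 0, n_perm: int = 20_000) -> dict:
    """R = 1 on separated groups; permutation p vs exact enumeration for
    n = 4 (2+2) and n = 6 (3+3)."""
    rng = np.random.default_rng(seed)

    pts = np.vstack([rng.normal(0, 0.3, (3, 2)),
                     rng.normal(10, 0.3, (3, 2))])
    D = squareform(pdist(pts))
    labels = np.array(["a"] * 3 + ["b"] * 3)
    r_sep = anosim(D, labels, n_perm=999, seed=seed).r

    diffs = {}
    for sizes in ((2, 2), (3, 3)):
        n = sum(sizes)
        pts = np.vstack([rng.normal(0, 1.5, (sizes[0], 2)),
                         rng.normal(3, 1.5, (sizes[1], 2))])
        D = squareform(pdist(pts))
        labels = np.array(["a"] * sizes[0] + ["b"] * sizes[1])
        exact = anosim(D, labels, method="exact")
        perm = anosim(D, labels, n_perm=n_perm, seed=seed + n)
        diffs[f"p_abs_diff_n{n}"] = abs(perm.p_value - exact.p_value)
        diffs[f"p_exact_n{n}"] = exact.p_value
    return {"r_separated": float(r_sep), **diffs, "n_perm": n_perm}


def metacluster_toy() -> dict:
    """The hand-built rooted network: three membership decisions.

    Root culture mode C-a is linked to environmental modes T-a, Z-a, G-a.
    A compound in {C-a, T-a, Z-a} is a member; one in {C-a, T-a} only is
    not (one environmental mode); one in {T-a, Z-a, G-a} but not C-a is
    not (outside the root mode).
    """
    import networkx as nx
    from .enrichment_network import assign_metaclusters

    ids = [f"x{i}" for i in range(12)]
    culture = _partition("C", {"c_in2": "a", "c_in1": "a", "c_out": "b",
                               **{f: "b" for f in ids}})
    t_part = _partition("T", {"c_in2": "a", "c_in1": "a", "c_out": "a",
                              **{f: "b" for f in ids}})
    z_part = _partition("Z", {"c_in2": "a", "c_in1": "b", "c_out": "a",
                              **{f: "b" for f in ids}})
    g_part = _partition("G", {"c_in2": "b", "c_in1": "b", "c_out": "a",
                              **{f: "b" for f in ids}})
    g = nx.Graph()
    for node in [("C", "a"), ("T", "a"), ("Z", "a"), ("G", "a")]:
        g.add_node(node)
    g.add_edge(("C", "a"), ("T", "a"))
    g.add_edge(("C", "a"), ("Z", "a"))
    g.add_edge(("C", "a"), ("G", "a"))
    mcs, _ = assign_metaclusters(g, [culture, t_part, z_part, g_part], "C")
    members = set(mcs[0].compounds) if mcs else set()
    correct = (("c_in2" in members)        # root + 2 env modes -> member
               + ("c_in1" not in members)  # only 1 env mode -> out
               + ("c_out" not in members)  # not in root mode -> out
               )
    return {"correct_decisions": correct, "n_decisions": 3}
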