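"""Generator invariants: block structure, determinism, conservation,
drift algebra, satellite offsets."""

import numpy as np
import pandas as pd
import pytest

from metabmodes.feature_tables import ValidationError
from metabmodes import synthetic_data as sd


class TestSignatures:
    def test_single_group_core_features_everywhere(self):
        sig = sd.generate_signatures(n_groups=1, species_per_group=2, n_core=3,
                                     n_specific_per_group=0, n_rare=0, seed=0)
        assert sig.abundances.shape == (2, 3)
        assert (sig.abundances.to_numpy() > 0).all()

    def test_default_geometry_matches_study_scale(self):
        sig = sd.generate_signatures(seed=0)
        assert sig.abundances.shape == (21, 313)
        counts = sig.blocks.value_counts()
        assert counts["core"] == 52
        assert counts["rare"] == 138
        assert sum(counts[f"group:{g}"] for g in range(5)) == 123

    def test_block_exclusivity(self):
        sig = sd.generate_signatures(n_groups=3, species_per_group=2, n_core=2,
                                     n_specific_per_group=4, n_rare=5, seed=1)
        for fid, block in sig.blocks.items():
            col = sig.abundances[fid]
            if block.startswith("group:"):
                g = int(block.split(":")[1])
                assert (col[sig.species_groups == g] > 0).all()
                assert (col[sig.species_groups != g] == 0).all()
            elif block == "rare":
                assert (col == 0).all()

    def test_deterministic(self):
        a = sd.generate_signatures(seed=42)
        b = sd.generate_signatures(seed=42)
        pd.testing.assert_frame_equal(a.abundances, b.abundances)

    def test_zero_species_rejected(self):
        with pytest.raises(ValidationError):
            sd.generate_signatures(n_groups=1, species_per_group=0)


@pytest.fixture
def small_sig():
    return sd.generate_signatures(n_groups=2, species_per_group=2, n_core=4,
                                  n_specific_per_group=3, n_rare=2, seed=5)


class TestCultureTable:
    def test_noiseless_areas_are_signature_times_biovolume(self, small_sig):
        t, _ = sd.simulate_culture_table(small_sig, n_reps=2, noise_sigma=0.0,
                                         seed=0)
        for sid, row in t.samples.iterrows():
            expected = (small_sig.abundances.loc[row["organism"]]
                        * row["biovolume_um3"])
            np.testing.assert_allclose(t.areas[sid], expected)

    def test_group_specific_zero_outside_group(self, small_sig):
        t, truth = sd.simulate_culture_table(small_sig, seed=1)
        fid = small_sig.blocks.index[small_sig.blocks == "group:0"][0]
        outside = t.samples.index[t.samples["organism"].map(
            small_sig.species_groups) != 0]
        assert (t.areas.loc[fid, outside] == 0).all()

    def test_replicate_structure(self, small_sig):
        t, _ = sd.simulate_culture_table(small_sig, n_reps=3, seed=2)
        groups = t.samples.groupby("replicate_group").size()
        assert (groups == 3).all()
        assert len(groups) == 4

    def test_negative_sigma_rejected(self, small_sig):
        with pytest.raises(ValidationError):
            sd.simulate_culture_table(small_sig, noise_sigma=-0.1)


class TestEnvironmentTable:
    def test_single_group_monotone_with_weights(self):
        sig = sd.generate_signatures(n_groups=1, species_per_group=3, n_core=5,
                                     n_specific_per_group=0, n_rare=0, seed=3)
        design = sd.CommunityDesign(
            axis=np.arange(6, dtype=float),
            weights=pd.DataFrame({0: np.linspace(0.1, 1.0, 6)}),
            biomass=np.ones(6))
        t, _ = sd.simulate_environment_table(sig, design, noise_sigma=0.0,
                                             seed=0)
        diffs = np.diff(t.areas.to_numpy(), axis=1)
        assert (diffs > 0).all()

    def test_peaked_weights_peak_group_features(self, small_sig):
        w = np.zeros((5, 2))
        w[:, 0] = [0.1, 0.5, 2.0, 0.5, 0.1]          # group 0 peaks at station 2
        w[:, 1] = 1.0
        design = sd.CommunityDesign(axis=np.arange(5, dtype=float),
                                    weights=pd.DataFrame(w),
                                    biomass=np.ones(5))
        t, _ = sd.simulate_environment_table(small_sig, design,
                                             noise_sigma=0.0, seed=0)
        fid = small_sig.blocks.index[small_sig.blocks == "group:0"][0]
        assert t.areas.loc[fid].to_numpy().argmax() == 2

    def test_zero_biomass_zero_abundance(self, small_sig):
        design = sd.CommunityDesign(axis=np.arange(3, dtype=float),
                                    weights=pd.DataFrame(np.ones((3, 2))),
                                    biomass=np.array([1.0, 0.0, 1.0]))
        t, _ = sd.simulate_environment_table(small_sig, design,
                                             noise_sigma=0.0, seed=0)
        assert (t.areas.iloc[:, 1] == 0).all()

    def test_rare_source_populates_rare_block(self, small_sig):
        design = sd.make_gradient_design(np.arange(6, dtype=float),
                                         shapes=("increasing", "decreasing"),
                                         rare_shape="deep")
        t, truth = sd.simulate_environment_table(small_sig, design,
                                                 noise_sigma=0.0, seed=0)
        rare = truth.mode_labels.index[truth.mode_labels == "rare"]
        assert (t.areas.loc[rare].to_numpy() > 0).all()

    def test_dimension_mismatch_rejected(self, small_sig):
        design = sd.CommunityDesign(axis=np.arange(4, dtype=float),
                                    weights=pd.DataFrame(np.ones((4, 3))),
                                    biomass=np.ones(4))
        with pytest.raises(ValidationError, match="unknown groups"):
            sd.simulate_environment_table(small_sig, design)

    def test_non_monotone_axis_rejected(self):
        with pytest.raises(ValidationError, match="monotone"):
            sd.CommunityDesign(axis=np.array([0.0, 2.0, 1.0]),
                               weights=pd.DataFrame(np.ones((3, 1))),
                               biomass=np.ones(3))


def env_table(noise=0.1, seed=0):
    sig = sd.generate_signatures(n_groups=2, species_per_group=2, n_core=10,
                                 n_specific_per_group=4, n_rare=0, seed=seed)
    design = sd.make_gradient_design(np.arange(8, dtype=float),
                                     shapes=("increasing", "decreasing"))
    return sd.simulate_environment_table(sig, design, n_reps=2,
                                         noise_sigma=noise, seed=seed + 1)


class TestInstrumentArtifacts:
    def test_zero_drift_leaves_areas_unchanged(self):
        t, truth = env_table(noise=0.0)
        out, truth = sd.add_instrument_artifacts(t, drift_sigma=0.0, seed=2,
                                                 truth=truth)
        orig = t.features.index
        pd.testing.assert_frame_equal(
            out.areas.loc[orig, t.samples.index], t.areas)
        assert (truth.drift == 1.0).all()

    def test_pooled_is_mean_of_samples_before_drift(self):
        t, truth = env_table(noise=0.1)
        out, truth = sd.add_instrument_artifacts(t, drift_sigma=0.4, seed=3,
                                                 truth=truth)
        pooled = out.sample_ids("pooled")
        sample_ids = out.sample_ids("sample")
        undrifted = out.areas.div(truth.drift, axis=1)
        expected = undrifted.loc[t.features.index, sample_ids].mean(axis=1)
        for pid in pooled:
            np.testing.assert_allclose(
                undrifted.loc[t.features.index, pid], expected)

    def test_is_rows_carry_drift_exactly(self):
        t, truth = env_table()
        out, truth = sd.add_instrument_artifacts(t, drift_sigma=0.3, seed=4,
                                                 truth=truth)
        for is_id in truth.internal_standard_ids:
            ratio = out.areas.loc[is_id] / out.areas.loc[is_id].mean()
            np.testing.assert_allclose(ratio,
                                       truth.drift / truth.drift.mean())

    def test_deterministic(self):
        t, _ = env_table()
        a, _ = sd.add_instrument_artifacts(t, drift_sigma=0.3, seed=9)
        b, _ = sd.add_instrument_artifacts(t, drift_sigma=0.3, seed=9)
        pd.testing.assert_frame_equal(a.areas, b.areas)


class TestSatellites:
    def test_13c_exact_offset(self):
        t, truth = env_table(noise=0.0)
        out, truth = sd.add_adducts_isotopes(t, rate_per_kind={"13C": 1.0},
                                             ppm_jitter=0.0, rt_jitter_sec=0.0,
                                             seed=0, truth=truth)
        sats = truth.satellites
        assert len(sats) > 0
        for _, row in sats.iterrows():
            parent_mz = out.features.loc[row["parent_id"], "mz"]
            sat_mz = out.features.loc[row["satellite_id"], "mz"]
            assert sat_mz == pytest.approx(parent_mz + 1.003355, abs=1e-9)

    def test_doubly_charged_arithmetic(self):
        t, _ = env_table(noise=0.0)
        fid = t.features.index[0]
        t.features.loc[fid, "mz"] = 301.1500
        out, truth = sd.add_adducts_isotopes(t, rate_per_kind={"2+": 1.0},
                                             seed=0)
        sat = truth.satellites.set_index("parent_id").loc[fid, "satellite_id"]
        assert out.features.loc[sat, "mz"] == pytest.approx(151.078638, abs=1e-6)

    def test_rate_zero_no_satellites(self):
        t, _ = env_table()
        out, truth = sd.add_adducts_isotopes(t, rate_per_kind=0.0, seed=0)
        assert truth.satellites.empty
        assert out.n_features == t.n_features

    def test_polarity_incompatible_kind_rejected(self):
        t, _ = env_table()
        with pytest.raises(ValidationError, match="Cl"):
            sd.add_adducts_isotopes(t, rate_per_kind={"Cl": 0.5}, seed=0)

    def test_satellite_area_fraction(self):
        t, _ = env_table(noise=0.0)
        out, truth = sd.add_adducts_isotopes(t, rate_per_kind={"Na": 1.0},
                                             area_fraction=0.2, seed=0)
        row = truth.satellites.iloc[0]
        np.testing.assert_allclose(out.areas.loc[row["satellite_id"]],
                                   0.2 * out.areas.loc[row["parent_id"]])
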