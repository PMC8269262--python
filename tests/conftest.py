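import numpy as np
import pytest

from metabmodes.feature_tables import MassFeature, PeakTable, SampleRecord


def make_table(areas, roles=None, replicate_groups=None, column="HILIC",
               polarity="pos", mz0=100.0, rt0=300.0, vol=10.0):
    """Small hand-built PeakTable: features f0..fn, samples s0..sm."""
    areas = np.asarray(areas, dtype=float)
    n_feat, n_samp = areas.shape
    features = [MassFeature(f"f{i}", mz0 + 10.0 * i, rt0 + 30.0 * i,
                            column, polarity) for i in range(n_feat)]
    roles = roles or ["sample"] * n_samp
    samples = []
    for j in range(n_samp):
        rg = replicate_groups[j] if replicate_groups else None
        kw = {"vol_filtered_L": vol} if roles[j] == "sample" else {}
        samples.append(SampleRecord(sample_id=f"s{j}", dataset_id="toy",
                                    role=roles[j], replicate_group=rg, **kw))
    return PeakTable.from_records(features, samples, areas)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
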