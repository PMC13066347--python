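import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from csense import metabolome_prep as mp
from csense import synthetic_data as sd
from csense.errors import (
    InvalidParameterError,
    InvariantError,
    MissingQcError,
)


def tiny_table(intensities: dict, orders=None, qc_cols=(), batches=None):
    """intensities: column -> list of feature values."""
    df = pd.DataFrame(intensities, index=[f"f{i}" for i in
                                          range(len(next(iter(intensities.values()))))])
    cols = list(df.columns)
    inj = pd.DataFrame({
        "sample_id": cols,
        "order": orders if orders is not None else list(range(len(cols))),
        "batch": batches if batches is not None else ["B0"] * len(cols),
        "is_qc": [c in qc_cols for c in cols],
    }, index=pd.Index(cols, name="injection_id"))
    return mp.FeatureTable(intensities=df, injections=inj)


class TestFeatureTable:
    def test_duplicate_order_within_batch_rejected(self):
        with pytest.raises(InvariantError, match="order"):
            tiny_table({"a": [1.0], "b": [2.0]}, orders=[0, 0])

    def test_io_round_trip(self, tmp_path, lcms_seed3):
        _, table = lcms_seed3
        mp.write_feature_table(table, tmp_path / "f.tsv", tmp_path / "i.tsv")
        again = mp.read_feature_table(tmp_path / "f.tsv", tmp_path / "i.tsv")
        pd.testing.assert_frame_equal(
            again.intensities, table.intensities, rtol=1e-12, check_names=False)
        assert list(again.qc_columns) == list(table.qc_columns)


class TestPqn:
    def test_proportional_sample(self):
        # QC reference (2,4,6); a sample at exactly 2x the reference gets
        # coefficient 2 and comes back equal to the reference
        table = tiny_table({"q1": [2, 4, 6], "q2": [2, 4, 6], "s": [4, 8, 12]},
                           qc_cols=("q1", "q2"))
        normalized, coeffs = mp.pqn_normalize(table)
        assert coeffs["s"] == pytest.approx(2.0)
        np.testing.assert_allclose(normalized.intensities["s"], [2, 4, 6])

    def test_identity_when_all_equal_reference(self):
        table = tiny_table({"q1": [2, 4, 6], "s1": [2, 4, 6], "s2": [2, 4, 6]},
                           qc_cols=("q1",))
        normalized, coeffs = mp.pqn_normalize(table)
        assert (coeffs == 1.0).all()
        pd.testing.assert_frame_equal(normalized.intensities, table.intensities,
                                      check_dtype=False)

    def test_three_feature_hand_calculation(self):
        # reference (2,4,6), sample (4,8,18): quotients (2,2,3), median 2,
        # normalized sample (2,4,9)
        table = tiny_table({"q1": [2, 4, 6], "s": [4, 8, 18]}, qc_cols=("q1",))
        normalized, coeffs = mp.pqn_normalize(table)
        assert coeffs["s"] == pytest.approx(2.0)
        np.testing.assert_allclose(normalized.intensities["s"], [2, 4, 9])

    def test_no_qc_raises(self):
        table = tiny_table({"s": [1, 2, 3]})
        with pytest.raises(MissingQcError):
            mp.pqn_normalize(table)

    def test_recovers_planted_dilution(self, lcms_seed3):
        scenario, table = lcms_seed3
        _, coeffs = mp.pqn_normalize(table)
        r = pearsonr(coeffs[scenario.dilution.index], scenario.dilution).statistic
        assert r >= 0.95

    def test_idempotent_on_clean_qcs(self):
        # exact idempotence requires self-consistent QCs (no measurement
        # noise); with noisy QCs the reference shifts on re-application
        scenario, table = sd.make_lcms_scenario(
            40, 10, 5, noise_cv=0.0, rng_seed=6, drift_slope=0.0)
        once, _ = mp.pqn_normalize(table)
        twice, coeffs2 = mp.pqn_normalize(once)
        assert np.abs(coeffs2 - 1.0).max() <= 1e-9
        pd.testing.assert_frame_equal(twice.intensities, once.intensities, rtol=1e-9)

    def test_approximately_idempotent_with_noise(self, lcms_seed3):
        _, table = lcms_seed3
        once, _ = mp.pqn_normalize(table)
        _, coeffs2 = mp.pqn_normalize(once)
        assert np.abs(coeffs2 - 1.0).max() <= 0.05


class TestQcRlsc:
    def test_flat_drift_identity(self):
        scenario, table = sd.make_lcms_scenario(
            20, 8, 4, noise_cv=0.0, rng_seed=5, drift_slope=0.0)
        corrected = mp.qc_rlsc(table)
        pd.testing.assert_frame_equal(corrected.intensities, table.intensities,
                                      rtol=1e-9)

    def test_linear_drift_reduces_qc_cv(self):
        _, table = sd.make_lcms_scenario(50, 12, 6, noise_cv=0.05, rng_seed=3,
                                         drift_slope=0.02)
        corrected = mp.qc_rlsc(table, span=0.75)
        qc = table.qc_columns
        pre = table.intensities[qc].std(axis=1, ddof=1) / table.intensities[qc].mean(axis=1)
        post = (corrected.intensities[qc].std(axis=1, ddof=1)
                / corrected.intensities[qc].mean(axis=1))
        assert (post < pre).mean() >= 0.95

    def test_batch_split_of_identical_data(self):
        # one batch of 6 injections (3 QCs), vs the same data duplicated
        # into a second batch: per-batch independence means each copy is
        # corrected exactly like the single-batch original
        rng = np.random.default_rng(12)
        block = rng.uniform(10, 20, size=(5, 6))
        one = tiny_table({f"c{i}": list(block[:, i]) for i in range(6)},
                         qc_cols=("c0", "c2", "c4"))
        two = tiny_table(
            {f"c{i}": list(block[:, i % 6]) for i in range(12)},
            qc_cols=("c0", "c2", "c4", "c6", "c8", "c10"),
            batches=["B0"] * 6 + ["B1"] * 6,
            orders=[0, 1, 2, 3, 4, 5, 0, 1, 2, 3, 4, 5])
        out_one = mp.qc_rlsc(one)
        out_two = mp.qc_rlsc(two)
        for i in range(6):
            np.testing.assert_allclose(out_two.intensities[f"c{i}"],
                                       out_one.intensities[f"c{i}"], rtol=1e-12)
            np.testing.assert_allclose(out_two.intensities[f"c{i + 6}"],
                                       out_one.intensities[f"c{i}"], rtol=1e-12)

    def test_span_validation(self, lcms_seed3):
        _, table = lcms_seed3
        with pytest.raises(InvalidParameterError):
            mp.qc_rlsc(table, span=1.5)

    def test_too_few_qcs_per_batch(self):
        table = tiny_table({"q1": [1.0], "q2": [1.0], "s": [1.0]},
                           qc_cols=("q1", "q2"))
        with pytest.raises(MissingQcError):
            mp.qc_rlsc(table)


class TestCvFilter:
    def test_zero_cv_kept(self):
        table = tiny_table({"q1": [10.0], "q2": [10.0], "q3": [10.0]},
                           qc_cols=("q1", "q2", "q3"))
        kept, removed = mp.cv_filter(table, 30.0)
        assert len(kept.intensities) == 1
        assert removed.empty

    def test_hand_computed_cv_removed(self):
        # QC values (1,2,3): mean 2, sd 1 -> CV 50% > 30% -> removed
        table = tiny_table({"q1": [1.0, 10.0], "q2": [2.0, 10.0], "q3": [3.0, 10.0]},
                           qc_cols=("q1", "q2", "q3"))
        kept, removed = mp.cv_filter(table, 30.0)
        assert list(removed["feature_id"]) == ["f0"]
        assert removed["cv_percent"].iloc[0] == pytest.approx(50.0)
        assert list(kept.intensities.index) == ["f1"]

    def test_monotone_in_cutoff(self, lcms_seed3):
        _, table = lcms_seed3
        kept30, _ = mp.cv_filter(table, 30.0)
        kept100, _ = mp.cv_filter(table, 100.0)
        assert set(kept30.intensities.index) <= set(kept100.intensities.index)

    def test_nonpositive_mean_removed_with_reason(self):
        table = tiny_table({"q1": [0.0, 5.0], "q2": [0.0, 5.0], "q3": [0.0, 5.0]},
                           qc_cols=("q1", "q2", "q3"))
        _, removed = mp.cv_filter(table, 30.0)
        assert removed["reason"].tolist() == ["nonpositive-mean"]


class TestPipelineOrder:
    def test_provenance_records_order(self, lcms_seed3):
        _, table = lcms_seed3
        out, removed, coeffs = mp.preprocess(table)
        assert out.provenance[0] == "pqn"
        assert out.provenance[1] == "qc_rlsc"
        assert out.provenance[2].startswith("cv_filter")
        assert coeffs is not None

    def test_skip_stages(self, lcms_seed3):
        _, table = lcms_seed3
        out, removed, coeffs = mp.preprocess(table, skip=("pqn", "cv"))
        assert out.provenance == ["qc_rlsc"]
        assert coeffs is None
        assert removed.empty
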