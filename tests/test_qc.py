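"""Normalization arithmetic, sample QC thresholds, replicate-outlier rule."""

import numpy as np
import pandas as pd
import pytest

import hepapod as hp
from hepapod.qc import QC_THRESHOLDS
from hepapod.synth import CountMatrix


def make_cm(counts, attenuation=None, meta_extra=None):
    probes = [f"P{i}" for i in range(counts.shape[0])]
    samples = [f"S{i}" for i in range(counts.shape[1])]
    counts = pd.DataFrame(counts, index=probes, columns=samples)
    att = pd.Series(
        attenuation if attenuation is not None else 1.0, index=counts.index
    )
    meta = pd.DataFrame(
        {
            "substance": "X",
            "concentration": list(range(counts.shape[1])),
            "replicate": 1,
            "run": "R1",
            "total_reads": 1_000_000,
            "total_alignment_rate": 0.9,
            "unique_alignment_rate": 0.8,
            "aligned_reads": 1_000_000,
            "pct_probes_expressed": 0.9,
        },
        index=counts.columns,
    )
    if meta_extra:
        for col, vals in meta_extra.items():
            meta[col] = vals
    return CountMatrix(counts=counts, attenuation=att, sample_meta=meta)


class TestNormalize:
    def test_rpm_log2_arithmetic(self):
        # a probe carrying 1000 of 1e6 reads -> RPM 1000 -> log2(1001)
        counts = np.zeros((2, 1), dtype=int)
        counts[0, 0] = 1000
        counts[1, 0] = 999_000
        expr = hp.normalize(make_cm(counts))
        assert expr.values.iloc[0, 0] == pytest.approx(np.log2(1001), rel=1e-12)

    def test_zero_count_floor(self):
        counts = np.array([[0, 0], [10, 20]])
        expr = hp.normalize(make_cm(counts))
        assert (expr.values.iloc[0] == 0).all()

    def test_attenuation_equivalence(self):
        """Attenuated raw 100 at factor 10 normalizes like unattenuated 1000."""
        raw_att = make_cm(np.array([[100], [5000]]), attenuation=[10.0, 1.0])
        raw_unatt = make_cm(np.array([[1000], [5000]]))
        a = hp.normalize(raw_att).values.iloc[0, 0]
        b = hp.normalize(raw_unatt).values.iloc[0, 0]
        assert a == pytest.approx(b, rel=1e-12)

    def test_scale_equivariance(self):
        """Multiplying one sample's counts by a constant changes nothing."""
        rng = np.random.default_rng(0)
        base = rng.integers(1, 500, size=(30, 3))
        scaled = base.copy()
        scaled[:, 1] *= 7
        a = hp.normalize(make_cm(base)).values
        b = hp.normalize(make_cm(scaled)).values
        pd.testing.assert_frame_equal(a, b)

    def test_zero_total_sample_named(self):
        counts = np.array([[0, 5], [0, 5]])
        with pytest.raises(ValueError, match="S0"):
            hp.normalize(make_cm(counts))


class TestQcFilter:
    def test_boundary_strict_below(self):
        cm = make_cm(
            np.full((3, 2), 100),
            meta_extra={"total_reads": [299_999, 300_000]},
        )
        filtered, report = hp.qc_filter(cm)
        assert list(filtered.counts.columns) == ["S1"]
        assert not report.table.loc["S0", "pass_total_reads"]
        assert report.table.loc["S1", "overall_pass"]

    def test_three_planted_failures(self):
        cm = make_cm(
            np.full((3, 6), 100),
            meta_extra={
                "total_alignment_rate": [0.9, 0.39, 0.9, 0.9, 0.9, 0.9],
                "unique_alignment_rate": [0.8, 0.8, 0.29, 0.8, 0.8, 0.8],
                "pct_probes_expressed": [0.9, 0.9, 0.9, 0.49, 0.9, 0.9],
            },
        )
        filtered, report = hp.qc_filter(cm)
        assert filtered.counts.shape[1] == 3
        assert sorted(report.removed_samples) == ["S1", "S2", "S3"]

    def test_idempotent(self):
        cm = make_cm(
            np.full((3, 4), 100),
            meta_extra={"total_reads": [100, 1e6, 1e6, 1e6]},
        )
        once, _ = hp.qc_filter(cm)
        twice, _ = hp.qc_filter(once)
        assert once.counts.equals(twice.counts)

    def test_missing_metadata_listed(self):
        cm = make_cm(np.full((2, 2), 100))
        cm.sample_meta = cm.sample_meta.drop(columns=["unique_alignment_rate"])
        with pytest.raises(ValueError, match="unique_alignment_rate"):
            hp.qc_filter(cm)

    def test_verdict_fail_iff_any_criterion_fails(self):
        cm = make_cm(
            np.full((3, 3), 100),
            meta_extra={"total_reads": [1e6, 200, 1e6],
                        "pct_probes_expressed": [0.9, 0.9, 0.2]},
        )
        _, report = hp.qc_filter(cm)
        expected = ~report.table.filter(like="pass_").drop(
            columns="overall_pass", errors="ignore"
        ).eq(False).any(axis=1)
        assert (report.table["overall_pass"] == expected).all()


def _replicate_expr(n_probes=200, discordant=False, seed=0):
    rng = np.random.default_rng(seed)
    signal = rng.normal(5, 2, n_probes)
    cols = {}
    for i in range(4):
        if discordant and i == 3:
            cols[f"W{i}"] = np.clip(rng.normal(5, 2, n_probes), 0, None)
        else:
            cols[f"W{i}"] = np.clip(signal + rng.normal(0, 0.2, n_probes), 0, None)
    values = pd.DataFrame(cols, index=[f"P{i}" for i in range(n_probes)])
    meta = pd.DataFrame(
        {"substance": "X", "concentration": 1.0, "replicate": range(4), "run": "R1"},
        index=values.columns,
    )
    return hp.ExprMatrix(values=values, sample_meta=meta)


class TestReplicateOutliers:
    def test_identical_replicates_kept(self):
        values = pd.DataFrame(
            np.tile(np.linspace(1, 5, 50)[:, None], (1, 4)),
            index=[f"P{i}" for i in range(50)],
            columns=[f"W{i}" for i in range(4)],
        )
        meta = pd.DataFrame(
            {"substance": "X", "concentration": 1.0, "replicate": range(4),
             "run": "R1"},
            index=values.columns,
        )
        expr = hp.ExprMatrix(values=values, sample_meta=meta)
        out, report = hp.drop_outlier_replicates(expr)
        assert out.values.shape[1] == 4
        assert report.dropped_replicates.empty

    def test_discordant_replicate_removed_with_margin(self):
        expr = _replicate_expr(discordant=True, seed=1)
        out, report = hp.drop_outlier_replicates(expr)
        assert list(report.dropped_replicates["sample_id"]) == ["W3"]
        assert abs(report.dropped_replicates["margin"].iloc[0]) > 0.05
        assert out.values.shape[1] == 3

    def test_group_of_two_untouched(self, caplog):
        expr = _replicate_expr(seed=2)
        expr = hp.ExprMatrix(
            values=expr.values.iloc[:, :2], sample_meta=expr.sample_meta.iloc[:2]
        )
        with caplog.at_level("WARNING"):
            out, report = hp.drop_outlier_replicates(expr)
        assert out.values.shape[1] == 2
        assert "skipped" in caplog.text

    def test_at_most_one_removal_per_group(self):
        expr = _replicate_expr(discordant=True, seed=3)
        _, report = hp.drop_outlier_replicates(expr)
        assert len(report.dropped_replicates) <= 1
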