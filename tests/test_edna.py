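"""eDNA read-count filtering, scaling, pooling and frequency estimation."""

import numpy as np
import pandas as pd
import pytest

from ednamix.edna import (
    ThresholdScheme,
    edna_allele_freqs,
    edna_pipeline,
    freqs_to_dict,
    low_freq_filter,
    min_read_filter,
    pool_replicates,
    scale_to_100,
    threshold_filter,
    to_mixture_profile,
    variable_threshold,
)


def counts(rows):
    return pd.DataFrame(rows, columns=["sample", "locus", "allele", "reads"])


def scaled(rows):
    return pd.DataFrame(rows, columns=["sample", "locus", "allele", "scaled_reads"])


class TestPerSampleFilters:
    def test_min_read_filter_boundary_is_inclusive(self):
        table = counts(
            [("s1", "L1", "a", 9), ("s1", "L1", "b", 10), ("s2", "L1", "a", 500)]
        )
        out = min_read_filter(table)
        assert list(zip(out["sample"], out["allele"])) == [("s1", "b"), ("s2", "a")]

    def test_min_read_filter_empty_table(self):
        assert min_read_filter(counts([])).empty

    @pytest.mark.parametrize(
        "reads, expected",
        [
            ({"a": 900, "b": 100}, {"a": 90.0, "b": 10.0}),
            ({"a": 37}, {"a": 100.0}),
            ({"a": 1, "b": 2}, {"a": 100 / 3, "b": 200 / 3}),
        ],
    )
    def test_scale_to_100(self, reads, expected):
        table = counts([("s1", "L1", a, r) for a, r in reads.items()])
        out = scale_to_100(table)
        got = dict(zip(out["allele"], out["scaled_reads"]))
        assert got == pytest.approx(expected)
        assert sum(got.values()) == pytest.approx(100.0, abs=1e-9)

    def test_scale_preserves_proportions_exactly(self):
        rng = np.random.default_rng(0)
        reads = rng.integers(1, 10_000, size=12)
        table = counts([("s", "L", f"a{i}", int(r)) for i, r in enumerate(reads)])
        out = scale_to_100(table)
        np.testing.assert_allclose(
            out["scaled_reads"] / 100.0, reads / reads.sum(), rtol=1e-12
        )

    def test_low_freq_filter_boundary(self):
        table = scaled(
            [("s", "L1", "a", 99.2), ("s", "L1", "b", 0.8),
             ("s", "L2", "a", 99.0), ("s", "L2", "b", 1.0)]
        )
        out = low_freq_filter(table)
        assert set(zip(out["locus"], out["allele"])) == {
            ("L1", "a"), ("L2", "a"), ("L2", "b")
        }
        # surviving counts are not renormalised
        assert out.loc[out["locus"] == "L1", "scaled_reads"].item() == 99.2


class TestPoolingAndFrequencies:
    def test_pool_sums_and_unions(self):
        table = scaled(
            [("m1_w1", "L1", "a", 90.0), ("m1_w1", "L1", "b", 10.0),
             ("m1_w2", "L1", "a", 80.0), ("m1_w2", "L1", "b", 20.0),
             ("m1_w1", "L2", "c", 100.0)]  # L2 missing from replicate 2
        )
        out = pool_replicates(table, {"m1_w1": "m1", "m1_w2": "m1"})
        got = {(r.locus, r.allele): r.scaled_reads for r in out.itertuples()}
        assert got == {("L1", "a"): 170.0, ("L1", "b"): 30.0, ("L2", "c"): 100.0}

    def test_single_replicate_is_identity(self):
        table = scaled([("w", "L1", "a", 60.0), ("w", "L1", "b", 40.0)])
        out = pool_replicates(table, {"w": "unit"})
        assert sorted(out["scaled_reads"]) == [40.0, 60.0]

    def test_edna_allele_freqs(self):
        pooled = scaled([("m", "L1", "a", 170.0), ("m", "L1", "b", 30.0),
                         ("m", "L2", "c", 55.5)])
        freqs = freqs_to_dict(edna_allele_freqs(pooled))
        assert freqs["L1"] == pytest.approx({"a": 0.85, "b": 0.15})
        assert freqs["L2"] == {"c": 1.0}

    def test_freqs_sum_to_one_per_locus(self):
        rng = np.random.default_rng(1)
        rows = [
            ("m", f"L{l}", f"a{i}", float(rng.uniform(0.1, 100)))
            for l in range(5) for i in range(rng.integers(1, 9))
        ]
        out = edna_allele_freqs(scaled(rows))
        sums = out.groupby("locus")["freq"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)


class TestThresholds:
    SCHEME = ThresholdScheme("variable", r_min=2, r_max=21)

    @pytest.mark.parametrize(
        "richness, expected",
        [(2, 0.1), (21, 0.001), (1, 0.1), (40, 0.001)],
    )
    def test_variable_threshold_endpoints_and_clamping(self, richness, expected):
        assert variable_threshold(richness, self.SCHEME) == pytest.approx(
            expected, rel=1e-9
        )

    def test_variable_threshold_midpoint_is_middle_cutoff(self):
        # log-linear interpolation forces the midpoint onto the middle of the
        # three fixed cutoffs
        scheme = ThresholdScheme("variable", r_min=2, r_max=20)
        assert variable_threshold(11, scheme) == pytest.approx(0.01, rel=1e-9)

    def test_fixed_threshold_filter(self):
        pooled = scaled([("m", "L1", "a", 95.0), ("m", "L1", "b", 5.0)])
        out = threshold_filter(pooled, ThresholdScheme("fixed", t=0.1))
        assert list(out["allele"]) == ["a"]
        out2 = threshold_filter(pooled, ThresholdScheme("fixed", t=0.001))
        assert len(out2) == 2

    def test_two_allele_locus_behaves_as_strictest_variable(self):
        pooled = scaled([("m", "L1", "a", 92.0), ("m", "L1", "b", 8.0)])
        out = threshold_filter(pooled, self.SCHEME, richness={"L1": 2})
        fixed = threshold_filter(pooled, ThresholdScheme("fixed", t=0.1))
        assert list(out["allele"]) == list(fixed["allele"]) == ["a"]

    def test_surviving_sets_nest_with_threshold(self):
        rng = np.random.default_rng(2)
        pooled = scaled(
            [("m", "L1", f"a{i}", float(rng.uniform(0.01, 50))) for i in range(15)]
        )
        sets = {
            t: set(threshold_filter(pooled, ThresholdScheme("fixed", t=t))["allele"])
            for t in (0.1, 0.01, 0.001)
        }
        assert sets[0.1] <= sets[0.01] <= sets[0.001]


class TestMixtureProfileConstruction:
    def test_unknown_alleles_dropped(self):
        filtered = scaled([("m", "L1", "a", 50.0), ("m", "L1", "b", 50.0)])
        prof, dropped = to_mixture_profile(filtered, {"L1": {"a": 1.0}})
        assert prof.loci == {"L1": frozenset({"a"})}
        assert dropped == 1

    def test_pop_superset_is_identity(self):
        filtered = scaled([("m", "L1", "a", 50.0), ("m", "L1", "b", 50.0)])
        prof, dropped = to_mixture_profile(
            filtered, {"L1": {"a": 0.4, "b": 0.4, "c": 0.2}}
        )
        assert prof.loci["L1"] == frozenset({"a", "b"}) and dropped == 0

    def test_fully_dropped_locus_absent(self):
        filtered = scaled([("m", "L1", "x", 100.0), ("m", "L2", "a", 100.0)])
        prof, dropped = to_mixture_profile(filtered, {"L2": {"a": 1.0}})
        assert "L1" not in prof.loci and dropped == 1


def test_pipeline_runs_in_fixed_order():
    """Raw counts -> per-sample filters -> pooling; 10-read and 1% rules apply
    per sample before replicates are combined."""
    table = counts(
        [("w1", "L1", "a", 980), ("w1", "L1", "b", 20), ("w1", "L1", "c", 5),
         ("w2", "L1", "a", 580), ("w2", "L1", "b", 12), ("w2", "L1", "d", 408)]
    )
    pooled = edna_pipeline(table, {"w1": "m", "w2": "m"})
    got = dict(zip(pooled["allele"], pooled["scaled_reads"]))
    # c fails the 10-read rule; every surviving allele is >=1% in its sample
    assert set(got) == {"a", "b", "d"}
    assert got["a"] == pytest.approx(98.0 + 58.0)
    assert got["d"] == pytest.approx(40.8)
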