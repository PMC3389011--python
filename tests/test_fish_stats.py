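"""Unit and property tests for FISH pairing scoring and spatial statistics."""

import math
import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from homopair import fish_stats as fs


def _nucleus(nid, spots_xyz, probe="P", radius=5.0, replicate=0):
    spots = [fs.Spot(nid, probe, *xyz) for xyz in spots_xyz]
    return fs.NucleusRecord(nid, (0.0, 0.0, 0.0), radius, spots, replicate)


def _pair_nucleus(nid, distance, **kw):
    return _nucleus(nid, [(0, 0, 0), (distance, 0, 0)], **kw)


class TestScorePairing:
    def test_hand_enumerated_toy_table(self):
        # 8 two-spot nuclei at known distances + one 3-spot + one 1-spot;
        # strict inequality at 0.5 um leaves exactly 3 paired of 10 scored
        distances = [0.1, 0.3, 0.49, 0.5, 0.51, 0.6, 1.0, 2.0]
        nuclei = [_pair_nucleus(f"n{i}", d) for i, d in enumerate(distances)]
        nuclei.append(_nucleus("n8", [(0, 0, 0), (0.1, 0, 0), (3, 3, 3)]))
        nuclei.append(_nucleus("n9", [(1, 1, 1)]))
        result = fs.score_pairing(nuclei, "P")
        assert result.n_scored == 10
        assert result.n_paired == 3
        assert result.frequency == pytest.approx(30.0)

    def test_coincident_spots_paired(self):
        result = fs.score_pairing([_pair_nucleus("n", 0.0)], "P")
        assert result.n_paired == 1

    def test_three_spots_never_paired(self):
        nuc = _nucleus("n", [(0, 0, 0), (0.1, 0, 0), (0.2, 0, 0)])
        result = fs.score_pairing([nuc], "P")
        assert result.n_scored == 1 and result.n_paired == 0

    def test_unknown_probe_raises(self):
        with pytest.raises(KeyError):
            fs.score_pairing([_pair_nucleus("n", 0.1)], "missing")

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            fs.score_pairing([], "P")

    def test_replicate_aggregation(self):
        nuclei = [
            _pair_nucleus("a", 0.1, replicate=0),
            _pair_nucleus("b", 1.0, replicate=0),
            _pair_nucleus("c", 0.2, replicate=1),
        ]
        result = fs.score_pairing(nuclei, "P")
        assert result.per_replicate == [(2, 1), (1, 1)]
        assert result.frequency == pytest.approx(100.0 * 2 / 3)

    @given(st.lists(st.floats(0.0, 2.0), min_size=1, max_size=30))
    def test_threshold_monotonicity(self, distances):
        nuclei = [_pair_nucleus(f"n{i}", d) for i, d in enumerate(distances)]
        paired = [
            fs.score_pairing(nuclei, "P", tau=tau).n_paired
            for tau in (0.1, 0.3, 0.5, 0.8, 1.5)
        ]
        assert paired == sorted(paired)


class TestDistances:
    def test_radial_at_centroid_and_surface(self):
        nuc = _nucleus("n", [])
        assert fs.radial_distance(fs.Spot("n", "P", 0, 0, 0), nuc) == 0.0
        assert fs.radial_distance(fs.Spot("n", "P", 5, 0, 0), nuc) == 1.0

    def test_radial_beyond_radius_not_clipped(self):
        nuc = _nucleus("n", [])
        assert fs.radial_distance(fs.Spot("n", "P", 5.5, 0, 0), nuc) == pytest.approx(1.1)

    def test_interallelic_345_triangle(self):
        nuc = _nucleus("n", [])
        a = fs.Spot("n", "P", 0, 0, 0)
        b = fs.Spot("n", "P", 3, 4, 0)
        assert fs.interallelic_distance(a, b, nuc) == pytest.approx(1.0)

    def test_interallelic_antipodal_is_two(self):
        nuc = _nucleus("n", [])
        a = fs.Spot("n", "P", -5, 0, 0)
        b = fs.Spot("n", "P", 5, 0, 0)
        assert fs.interallelic_distance(a, b, nuc) == pytest.approx(2.0)


class TestHistogram:
    def test_empty_input(self):
        counts, overflow = fs.distance_histogram([])
        assert counts.tolist() == [0, 0, 0, 0] and overflow == 0

    def test_default_binning_matches_oracle(self, rng):
        values = rng.uniform(0, 3, 600)
        counts, overflow = fs.distance_histogram(values)
        # brute-force oracle over the stated bin edges
        edges = [(c - 0.35, c + 0.35) for c in (0.0, 0.7, 1.4, 2.1)]
        oracle = [sum(lo <= v < hi for v in values) for lo, hi in edges]
        assert counts.tolist() == oracle
        assert counts.sum() + overflow == 600

    @given(st.lists(st.floats(0, 5), max_size=200))
    def test_conservation(self, values):
        counts, overflow = fs.distance_histogram(values)
        assert counts.sum() + overflow == len(values)


def _tukey_oracle(values):
    """Independent enumeration-based Tukey box statistics."""
    vals = sorted(values)
    n = len(vals)
    med = statistics.median(vals)
    half = vals[: (n + 1) // 2]
    upper = vals[n - (n + 1) // 2 :]
    lh, uh = statistics.median(half), statistics.median(upper)
    iqr = uh - lh
    inside = [v for v in vals if lh - 1.5 * iqr <= v <= uh + 1.5 * iqr]
    outliers = [v for v in vals if v < lh - 1.5 * iqr or v > uh + 1.5 * iqr]
    return med, lh, uh, min(inside), max(inside), outliers


class TestTukey:
    def test_one_to_nine(self):
        box = fs.tukey_box_stats(range(1, 10))
        assert (box.median, box.lower_hinge, box.upper_hinge) == (5, 3, 7)
        assert (box.whisker_low, box.whisker_high) == (1, 9)
        assert box.outliers == ()

    def test_constant_list(self):
        box = fs.tukey_box_stats([2.0] * 7)
        assert box.median == box.lower_hinge == box.upper_hinge == 2.0
        assert box.whisker_low == box.whisker_high == 2.0
        assert box.outliers == ()

    def test_extreme_point_flagged(self):
        box = fs.tukey_box_stats(list(range(1, 10)) + [100])
        assert 100 in box.outliers
        assert box.whisker_high < 100

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            fs.tukey_box_stats([])

    def test_against_oracle_random_lists(self, rng):
        for _ in range(200):
            vals = rng.normal(size=rng.integers(1, 25)).round(3).tolist()
            box = fs.tukey_box_stats(vals)
            med, lh, uh, wl, wh, out = _tukey_oracle(vals)
            assert (box.median, box.lower_hinge, box.upper_hinge) == (med, lh, uh)
            assert (box.whisker_low, box.whisker_high) == (wl, wh)
            assert sorted(box.outliers) == sorted(out)


class TestClassifyFrequency:
    @pytest.mark.parametrize(
        "freq,expected",
        [
            (4.0, "high"),
            (3.6, "high"),
            (3.5, "medium"),
            (3.0, "medium"),
            (2.5, "medium"),
            (2.0, "low"),
            (0.0, "low"),
            (100.0, "high"),
        ],
    )
    def test_boundaries(self, freq, expected):
        assert fs.classify_frequency(freq) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            fs.classify_frequency(-1.0)

    @given(st.floats(0, 100))
    def test_total_function_with_two_breakpoints(self, freq):
        category = fs.classify_frequency(freq)
        if freq > 3.5:
            assert category == "high"
        elif freq < 2.5:
            assert category == "low"
        else:
            assert category == "medium"


class TestGroupComparison:
    def test_identical_constant_groups(self):
        out = fs.group_comparison([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]])
        assert out["t"] == 0.0 and out["p"] == 1.0

    def test_pooled_t_matches_textbook_formula(self):
        a, b = [1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0]
        out = fs.group_comparison([a, b])
        # textbook pooled-variance t computed from first principles
        na, nb = len(a), len(b)
        va = sum((x - sum(a) / na) ** 2 for x in a) / (na - 1)
        vb = sum((x - sum(b) / nb) ** 2 for x in b) / (nb - 1)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        t_hand = (sum(a) / na - sum(b) / nb) / math.sqrt(sp2 * (1 / na + 1 / nb))
        assert out["t"] == pytest.approx(t_hand)

    def test_bonferroni_adjustment(self, rng):
        groups = [rng.normal(loc, 1, 20).tolist() for loc in (0, 0.5, 1.0)]
        out = fs.group_comparison(groups)
        assert out["method"] == "anova_bonferroni"
        assert len(out["pairwise"]) == 3
        for pair in out["pairwise"]:
            assert pair["p_adj"] == pytest.approx(min(1.0, pair["p_raw"] * 3))

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            fs.group_comparison([[1.0], [2.0, 3.0]])


class TestProbeCovariates:
    def test_no_gene_overlap(self):
        density, count = fs.probe_covariates((0, 1000), [], [])
        assert density == 0.0 and count == 0

    def test_probe_within_gene(self):
        density, _ = fs.probe_covariates((100, 200), [(0, 1000)], [])
        assert density == 1.0

    def test_hand_union_and_count(self):
        # overlapping genes [100,300) and [250,350) union to 250 bp in probe
        probe = (0, 1000)
        genes = [(100, 300), (250, 350)]
        reads = [5, 150, 320, 900, 999, 1000, 1500]  # 5 inside [0,1000)
        density, count = fs.probe_covariates(probe, genes, reads)
        assert density == pytest.approx(0.25)
        assert count == 5

    def test_malformed_interval(self):
        with pytest.raises(ValueError):
            fs.probe_covariates((0, 100), [(50, 50)], [])


class TestPearson:
    def test_identity_r_one(self):
        r, _ = fs.pearson_correlation([1, 2, 3, 4], [1, 2, 3, 4])
        assert r == pytest.approx(1.0)

    def test_constant_errors(self):
        with pytest.raises(ValueError, match="variance"):
            fs.pearson_correlation([1, 2, 3], [5, 5, 5])

    def test_five_point_toy_matches_formula(self):
        x = [1.0, 2.0, 4.0, 5.0, 8.0]
        y = [2.0, 3.0, 3.0, 6.0, 9.0]
        r, _ = fs.pearson_correlation(x, y)
        mx, my = sum(x) / 5, sum(y) / 5
        num = sum((a - mx) * (b - my) for a, b in zip(x, y))
        den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
        assert r == pytest.approx(num / den)


def test_nuclei_from_tables_roundtrip():
    nuc_df = pd.DataFrame(
        {
            "nucleus_id": ["a", "b"],
            "cx": [0.0, 10.0],
            "cy": [0.0, 10.0],
            "cz": [0.0, 10.0],
            "radius_um": [5.0, 4.0],
            "replicate": [0, 1],
        }
    )
    spot_df = pd.DataFrame(
        {
            "nucleus_id": ["a", "a", "b"],
            "probe_id": ["P", "P", "P"],
            "x_um": [0.0, 0.2, 10.0],
            "y_um": [0.0, 0.0, 10.0],
            "z_um": [0.0, 0.0, 10.0],
        }
    )
    nuclei = fs.nuclei_from_tables(nuc_df, spot_df)
    assert [n.nucleus_id for n in nuclei] == ["a", "b"]
    assert len(nuclei[0].spots) == 2 and nuclei[1].replicate == 1
    with pytest.raises(ValueError, match="missing columns"):
        fs.nuclei_from_tables(nuc_df.drop(columns="radius_um"), spot_df)
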