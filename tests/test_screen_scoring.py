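"""Absence filter, normalization, ratios, fold-changes, classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from repliid.screen_scoring import (
    HIT_CLASSES,
    ScreenConfig,
    classify_mutants,
    classify_table,
    filter_absent,
    ip_over_input,
    log2_fold_change,
    median_normalize,
    merge_replicates,
    replicate_correlation,
    replicate_ratios,
    score_screen,
)
from tests.conftest import make_counts


class TestFilterAbsent:
    def test_strictly_below_cutoff_excluded(self):
        # 2.5e-5 of 1e6 reads = 25 reads: 24 is out, 25 stays in
        counts = {"b24": 24, "b25": 25, "rest": 1_000_000 - 49}
        sc = make_counts(counts)
        assert sc.total_reads == 1_000_000
        retained = filter_absent(sc, ScreenConfig())
        assert retained == {"b25", "rest"}

    def test_zero_counts_dropped_sole_survivor_kept(self):
        sc = make_counts({"a": 0, "b": 0, "c": 100})
        assert filter_absent(sc, ScreenConfig()) == {"c"}

    def test_empty_sample_is_hard_error(self):
        with pytest.raises(ValueError, match="empty input"):
            filter_absent(make_counts({"a": 0}), ScreenConfig())

    def test_filter_applies_to_input_only(self):
        with pytest.raises(ValueError, match="input"):
            filter_absent(make_counts({"a": 5}, role="IP"), ScreenConfig())


class TestMedianNormalize:
    def test_odd_sized_example(self):
        scores = median_normalize({"a": 10, "b": 20, "c": 30}, ["a", "b", "c"])
        assert scores.to_dict() == {"a": 0.5, "b": 1.0, "c": 1.5}

    def test_even_sized_midpoint_median(self):
        scores = median_normalize({"a": 4, "b": 8}, ["a", "b"])
        assert scores["a"] == pytest.approx(4 / 6)
        assert scores["b"] == pytest.approx(8 / 6)

    def test_scale_invariance(self):
        counts = {"a": 3, "b": 11, "c": 7, "d": 2}
        base = median_normalize(counts, counts)
        scaled = median_normalize({k: 7 * v for k, v in counts.items()}, counts)
        pd.testing.assert_series_equal(base, scaled)

    def test_median_of_scores_is_one(self, rng):
        counts = {f"b{i}": int(x) for i, x in enumerate(rng.integers(1, 500, size=101))}
        scores = median_normalize(counts, counts)
        assert float(scores.median()) == pytest.approx(1.0)

    def test_zero_median_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            median_normalize({"a": 0, "b": 0, "c": 1}, ["a", "b", "c"])

    def test_excluded_barcodes_absent_from_output(self):
        scores = median_normalize({"a": 10, "b": 20, "c": 30}, ["a", "b"])
        assert set(scores.index) == {"a", "b"}


class TestIpOverInput:
    def test_simple_ratio(self):
        r = ip_over_input(pd.Series({"a": 2.0}), pd.Series({"a": 1.0}))
        assert r["a"] == 2.0

    def test_identical_scores_give_unit_ratios(self):
        s = pd.Series({"a": 0.5, "b": 1.0, "c": 2.0})
        assert (ip_over_input(s, s) == 1.0).all()

    def test_zero_ip_gives_zero_ratio(self):
        r = ip_over_input(pd.Series({"a": 0.0, "b": 2.0}), pd.Series({"a": 1.0, "b": 1.0}))
        assert r["a"] == 0.0

    def test_zero_input_asserts(self):
        with pytest.raises(AssertionError):
            ip_over_input(pd.Series({"a": 1.0}), pd.Series({"a": 0.0}))


class TestMergeReplicates:
    CFG = ScreenConfig()

    @staticmethod
    def tables(r1_40, r2_40, r1_80=None, r2_80=None):
        return {
            (40, 1): pd.Series(r1_40),
            (40, 2): pd.Series(r2_40),
            (80, 1): pd.Series(r1_80 if r1_80 is not None else r1_40),
            (80, 2): pd.Series(r2_80 if r2_80 is not None else r2_40),
        }

    def test_arithmetic_mean_of_ratios(self):
        merged = merge_replicates(self.tables({"g": 0.5}, {"g": 0.7}), self.CFG)
        assert merged.loc["g", 40] == pytest.approx(0.6)

    def test_intersection_drops_partially_retained(self):
        merged = merge_replicates(
            self.tables({"g": 1.0, "h": 2.0}, {"g": 1.0}), self.CFG
        )
        assert list(merged.index) == ["g"]

    def test_single_shared_gene_survives(self):
        merged = merge_replicates(
            self.tables({"g": 1.0, "x": 2.0}, {"g": 1.0, "y": 2.0}), self.CFG
        )
        assert len(merged) == 1

    def test_no_overlap_is_hard_error(self):
        with pytest.raises(ValueError, match="overlap"):
            merge_replicates(self.tables({"x": 1.0}, {"y": 1.0}), self.CFG)

    def test_requires_two_replicates(self):
        with pytest.raises(ValueError, match="replicates"):
            merge_replicates({(40, 1): pd.Series({"g": 1.0}), (80, 1): pd.Series({"g": 1.0})}, self.CFG)

    def test_mean_of_logs_option_is_geometric_mean(self):
        cfg = ScreenConfig(replicate_combine="mean_of_logs")
        merged = merge_replicates(self.tables({"g": 2.0}, {"g": 8.0}), cfg)
        assert merged.loc["g", 40] == pytest.approx(4.0)


class TestLog2FoldChange:
    def test_ratio_at_baseline_gives_zero(self):
        ratios = pd.DataFrame({40: [1.0, 2.0], 80: [1.0, 2.0]}, index=["wt", "g"])
        fc, baselines, _ = log2_fold_change(ratios, {"wt"}, "wildtype_median")
        assert baselines == {40: 1.0, 80: 1.0}
        assert fc.loc["wt", 40] == 0.0
        assert fc.loc["g", 40] == 1.0

    def test_half_baseline_is_minus_one(self):
        ratios = pd.DataFrame({40: [2.0, 1.0]}, index=["wt", "g"])
        fc, _, _ = log2_fold_change(ratios, {"wt"}, "wildtype_median")
        assert fc.loc["g", 40] == -1.0

    def test_zero_ratio_floored_to_smallest_positive(self):
        # five-gene toy table, recomputed by hand:
        # ratios (0, 0.5, 1, 2, 4); baseline over all = median = 1;
        # eps = 0.5, so the zero gene gets log2(0.5/1) = -1
        ratios = pd.DataFrame({40: [0.0, 0.5, 1.0, 2.0, 4.0]}, index=list("abcde"))
        fc, baselines, floored = log2_fold_change(ratios, (), "all_median")
        assert baselines[40] == 1.0
        assert fc[40].tolist() == [-1.0, -1.0, 0.0, 1.0, 2.0]
        assert floored[40].tolist() == [True, False, False, False, False]

    def test_none_policy_uses_unit_baseline(self):
        ratios = pd.DataFrame({40: [0.25]}, index=["g"])
        fc, _, _ = log2_fold_change(ratios, (), "none")
        assert fc.loc["g", 40] == -2.0

    def test_missing_wildtypes_is_hard_error(self):
        ratios = pd.DataFrame({40: [1.0]}, index=["g"])
        with pytest.raises(ValueError, match="wild-type"):
            log2_fold_change(ratios, set(), "wildtype_median")

    def test_wildtype_median_log2fc_is_centered(self, rng):
        wt = [f"w{i}" for i in range(11)]
        vals = rng.lognormal(0.3, 0.8, size=11)
        ratios = pd.DataFrame({40: vals, 80: vals[::-1]}, index=wt)
        fc, _, _ = log2_fold_change(ratios, set(wt), "wildtype_median")
        assert float(fc[40].median()) == pytest.approx(0.0, abs=1e-12)
        assert float(fc[80].median()) == pytest.approx(0.0, abs=1e-12)


class TestClassify:
    @pytest.mark.parametrize(
        "fc40,fc80,expected",
        [
            (-1.5, -1.4, "down_both"),
            (1.5, 1.4, "up_both"),
            (-1.25, -1.30, "down_80_only"),  # boundary: -1.25 is not < -1.25
            (-1.30, -1.25, "down_40_only"),
            (-1.30, 0.0, "down_40_only"),
            (0.0, -1.30, "down_80_only"),
            (0.0, 0.0, "other"),
            (1.5, -1.5, "other"),  # mixed directions fall through
            (-1.5, 1.5, "down_40_only"),
            (1.26, 1.25, "other"),
        ],
    )
    def test_rule_table(self, fc40, fc80, expected):
        assert classify_mutants(fc40, fc80) == expected

    def test_classes_partition_the_plane(self, rng):
        # exactly one class per point, "other" included
        pts = rng.uniform(-3, 3, size=(500, 2))
        for f40, f80 in pts:
            cls = classify_mutants(f40, f80)
            assert cls in HIT_CLASSES
            matches = [
                f40 < -1.25 and f80 < -1.25,
                f40 > 1.25 and f80 > 1.25,
                f40 < -1.25 and f80 >= -1.25,
                abs(f40) <= 1.25 and f80 < -1.25,
            ]
            assert sum(matches) <= 1
            if cls == "other":
                assert not any(matches)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_mutants(float("nan"), 0.0)

    def test_vectorized_agrees_with_scalar(self, rng):
        fc = pd.DataFrame(rng.uniform(-2, 2, size=(50, 2)), columns=[40, 80])
        vec = classify_table(fc)
        for i in fc.index:
            assert vec[i] == classify_mutants(fc.loc[i, 40], fc.loc[i, 80])


class TestReplicateCorrelation:
    def test_identical_replicates(self):
        r = pd.Series({"a": 0.5, "b": 1.0, "c": 2.0, "d": 4.0})
        assert replicate_correlation(r, r) == pytest.approx(1.0)

    def test_log_inverse_replicates(self):
        r = pd.Series({"a": 0.5, "b": 1.0, "c": 2.0, "d": 4.0})
        assert replicate_correlation(r, 1 / r) == pytest.approx(-1.0)

    def test_matches_definitional_pearson(self):
        # five-point toy vectors; expected value computed from the
        # definitional formula on the log2 ratios
        x = pd.Series([1.0, 2.0, 4.0, 8.0, 3.0], index=list("abcde"))
        y = pd.Series([2.0, 2.0, 8.0, 4.0, 6.0], index=list("abcde"))
        lx, ly = np.log2(x.to_numpy()), np.log2(y.to_numpy())
        expected = float(
            ((lx - lx.mean()) * (ly - ly.mean())).sum()
            / np.sqrt(((lx - lx.mean()) ** 2).sum() * ((ly - ly.mean()) ** 2).sum())
        )
        assert replicate_correlation(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_is_na(self):
        x = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        y = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        assert np.isnan(replicate_correlation(x, y))

    def test_needs_three_shared_genes(self):
        x = pd.Series([1.0, 2.0], index=list("ab"))
        with pytest.raises(ValueError, match="3 shared"):
            replicate_correlation(x, x)

    def test_spearman_option(self):
        x = pd.Series([1.0, 2.0, 4.0, 9.0], index=list("abcd"))
        y = pd.Series([2.0, 3.0, 5.0, 90.0], index=list("abcd"))
        assert replicate_correlation(x, y, "spearman_raw") == pytest.approx(1.0)


# --- end-to-end scoring invariants ----------------------------------------

def _toy_samples(tiny_map, ip_counts_by_rep=None):
    """Two replicates x two timepoints over the three-barcode map."""
    base_input = {bc: 100 for bc in tiny_map.barcodes}
    samples = []
    for rep in (1, 2):
        for t in (40, 80):
            ip = dict(base_input)
            if ip_counts_by_rep:
                ip.update(ip_counts_by_rep.get((t, rep), {}))
            samples.append(make_counts(ip, role="IP", timepoint=t, replicate=rep))
            samples.append(make_counts(dict(base_input), role="input", timepoint=t, replicate=rep))
    return samples


def test_score_screen_null_gives_zero_fold_changes(tiny_map):
    res = score_screen(_toy_samples(tiny_map), tiny_map)
    assert res.info["n_scored"] == 2  # wild type never emitted as a gene
    assert (res.scores["log2fc_t40"] == 0).all()
    assert (res.scores["hit_class"] == "other").all()


def test_score_screen_sample_scale_invariance(tiny_map):
    bcs = tiny_map.barcodes
    varied = {(40, 1): {bcs[0]: 400, bcs[1]: 50}, (80, 2): {bcs[0]: 20}}
    res1 = score_screen(_toy_samples(tiny_map, varied), tiny_map)
    # scale one sample's counts by 13: nothing downstream may change
    samples = _toy_samples(tiny_map, varied)
    target = samples[0]
    scaled = make_counts(
        {k: 13 * v for k, v in target.counts.items()},
        role=target.sample.role,
        timepoint=target.sample.timepoint,
        replicate=target.sample.replicate,
    )
    res2 = score_screen([scaled] + samples[1:], tiny_map)
    pd.testing.assert_frame_equal(res1.scores, res2.scores)


def test_score_screen_monotone_in_ip_count(tiny_map):
    bcs = tiny_map.barcodes
    fcs = []
    for ip0 in (40, 100, 250, 600):
        res = score_screen(_toy_samples(tiny_map, {(40, 1): {bcs[0]: ip0}}), tiny_map)
        fcs.append(res.scores.loc["GENE1", "log2fc_t40"])
    assert all(a <= b for a, b in zip(fcs, fcs[1:]))


def test_replicate_ratios_chain(tiny_map):
    # hand-checked chain on one replicate: input {100,200,400}, IP {400,200,100}
    bcs = tiny_map.barcodes
    ip = make_counts(dict(zip(bcs, [400, 200, 100])), role="IP")
    inp = make_counts(dict(zip(bcs, [100, 200, 400])), role="input")
    ratios, retained = replicate_ratios(ip, inp, ScreenConfig())
    assert retained == set(bcs)
    # medians are both 200 -> scores IP (2,1,.5), input (.5,1,2)
    assert ratios[bcs[0]] == pytest.approx(4.0)
    assert ratios[bcs[1]] == pytest.approx(1.0)
    assert ratios[bcs[2]] == pytest.approx(0.25)


@settings(max_examples=25, deadline=None, derandomize=True, database=None)
@given(scale=st.floats(min_value=0.25, max_value=64), tau=st.floats(min_value=0.3, max_value=3))
def test_classification_threshold_symmetry(scale, tau):
    """A gene exactly mirrored around the baseline flips down_both<->up_both."""
    fc = abs(np.log2(scale))
    down = classify_mutants(-fc, -fc, tau)
    up = classify_mutants(fc, fc, tau)
    if fc > tau:
        assert (up, down) == ("up_both", "down_both")
    else:
        assert up == down == "other"
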