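import numpy as np
import pandas as pd
import pytest
from scipy import stats

from faire_memory.differential import (
    DECREASED_PATTERNS,
    INCREASED_PATTERNS,
    assign_meta_groups,
    calibrate_fpr,
    call_change,
    classify_sets,
    flag_rottlerin_sensitive,
    subdivide_by_st_rs,
    wilcoxon_rank_sum,
)
from conftest import make_counts


def calls_from_directions(directions, name="x"):
    return pd.DataFrame(
        {"direction": directions, "test": name, "ref": "NS"},
        index=pd.Index([f"r{i}" for i in range(len(directions))], name="region_id"),
    )


class TestCallChange:
    @pytest.mark.parametrize(
        "test,ref,expected",
        [
            (180, 100, "up"),        # fold 1.8 >= 1.75, max 180 >= 30
            (170, 100, "unchanged"), # fold 1.70 < 1.75
            (25, 10, "unchanged"),   # fold 2.5 but max 25 < 30
            (100, 180, "down"),
        ],
    )
    def test_cutoff_rules(self, test, ref, expected):
        counts = make_counts({"ST_DMSO": [float(test)], "NS_DMSO": [float(ref)]})
        calls = call_change(counts, "ST_DMSO", "NS_DMSO")
        assert calls["direction"].iloc[0] == expected

    def test_swap_symmetry(self, rng):
        """Swapping test and reference maps up<->down and fold -> 1/fold."""
        counts = make_counts(
            {
                "ST_DMSO": rng.integers(0, 400, 100).astype(float),
                "NS_DMSO": rng.integers(0, 400, 100).astype(float),
            }
        )
        fwd = call_change(counts, "ST_DMSO", "NS_DMSO")
        rev = call_change(counts, "NS_DMSO", "ST_DMSO")
        assert np.allclose(fwd["fold_change"] * rev["fold_change"], 1.0)
        swap = {"up": "down", "down": "up", "unchanged": "unchanged"}
        assert (fwd["direction"].map(swap) == rev["direction"]).all()

    def test_monotone_in_fc_cutoff(self, small_dataset):
        counts = small_dataset.counts
        n_called = [
            (call_change(counts, "ST_DMSO", "NS_DMSO", fc)["direction"] != "unchanged").sum()
            for fc in (1.5, 1.75, 2.0, 3.0)
        ]
        assert n_called == sorted(n_called, reverse=True)

    def test_bad_cutoff_raises(self, small_dataset):
        with pytest.raises(ValueError):
            call_change(small_dataset.counts, "ST_DMSO", "NS_DMSO", fc_cutoff=0.9)


class TestClassifySets:
    @pytest.mark.parametrize(
        "triple,expected",
        [
            (("up", "unchanged", "unchanged"), "a"),
            (("up", "unchanged", "up"), "b"),
            (("unchanged", "unchanged", "up"), "c"),
            (("up", "up", "unchanged"), "d"),
            (("up", "up", "up"), "e"),
            (("unchanged", "up", "up"), "f"),
            (("unchanged", "up", "unchanged"), "g"),
            (("down", "unchanged", "unchanged"), "h"),
            (("down", "unchanged", "down"), "i"),
            (("unchanged", "unchanged", "down"), "j"),
            (("down", "down", "unchanged"), "k"),
            (("down", "down", "down"), "l"),
            (("unchanged", "down", "down"), "m"),
            (("unchanged", "down", "unchanged"), "n"),
            (("unchanged", "unchanged", "unchanged"), "unchanged"),
        ],
    )
    def test_pure_patterns(self, triple, expected):
        st, sw, rs = ([d] for d in triple)
        out = classify_sets(
            calls_from_directions(st), calls_from_directions(sw), calls_from_directions(rs)
        )
        assert out["set_label"].iloc[0] == expected
        assert not out["ambiguous"].iloc[0]

    def test_mixed_directions_flagged_ambiguous(self):
        out = classify_sets(
            calls_from_directions(["up"]),
            calls_from_directions(["down"]),
            calls_from_directions(["down"]),
        )
        assert out["ambiguous"].iloc[0]
        # majority direction (2 down) wins -> pattern (0,1,1) of downs -> m
        assert out["set_label"].iloc[0] == "m"

    def test_partition_on_random_triples(self, rng):
        """Every region gets exactly one label; a-g need an up call, h-n a
        down call."""
        n = 2000
        dirs = rng.choice(["up", "down", "unchanged"], size=(n, 3))
        out = classify_sets(
            calls_from_directions(dirs[:, 0]),
            calls_from_directions(dirs[:, 1]),
            calls_from_directions(dirs[:, 2]),
        )
        assert out["set_label"].notna().all()
        has_up = (dirs == "up").any(axis=1)
        has_down = (dirs == "down").any(axis=1)
        inc = out["set_label"].isin(list(INCREASED_PATTERNS.values())).to_numpy()
        dec = out["set_label"].isin(list(DECREASED_PATTERNS.values())).to_numpy()
        assert (~inc | has_up).all()
        assert (~dec | has_down).all()
        assert ((inc | dec) == (has_up | has_down)).all()

    def test_mismatched_regions_raise(self):
        with pytest.raises(ValueError):
            classify_sets(
                calls_from_directions(["up", "up"]),
                calls_from_directions(["up"]),
                calls_from_directions(["up"]),
            )


class TestSubdivideAndMetaGroups:
    def make_assignment(self, label, st, rs):
        counts = make_counts({"ST_DMSO": [float(st)], "RS_DMSO": [float(rs)],
                              "NS_DMSO": [100.0]})
        assign = pd.DataFrame({"set_label": [label], "ambiguous": [False]},
                              index=pd.Index(["r0"], name="region_id"))
        return subdivide_by_st_rs(assign, counts)

    @pytest.mark.parametrize(
        "label,st,rs,expected",
        [
            ("b", 200, 400, "b2"),  # RS/ST = 2.0 >= 1.75
            ("e", 400, 200, "e1"),  # ST/RS = 2.0
            ("b", 200, 250, "b0"),  # neither ratio >= 1.75
            ("a", 200, 400, "a"),   # non-subdivided labels pass through
            ("l", 400, 200, "l1"),
        ],
    )
    def test_ratio_rule(self, label, st, rs, expected):
        out = self.make_assignment(label, st, rs)
        assert out["set_label"].iloc[0] == expected

    @pytest.mark.parametrize(
        "label,expected",
        [
            ("a", "primary_enriched"), ("b1", "primary_enriched"), ("e1", "primary_enriched"),
            ("b2", "secondary_enriched"), ("c", "secondary_enriched"), ("e2", "secondary_enriched"),
            ("f", "sw_enriched"), ("g", "sw_enriched"),
            ("b0", "other_increased"), ("d", "other_increased"),
            ("l2", "decreased"), ("h", "decreased"),
            ("unchanged", "unchanged"),
        ],
    )
    def test_meta_groups(self, label, expected):
        assign = pd.DataFrame({"set_label": [label]},
                              index=pd.Index(["r0"], name="region_id"))
        assert assign_meta_groups(assign)["meta_group"].iloc[0] == expected

    def test_unknown_label_raises(self):
        assign = pd.DataFrame({"set_label": ["zz"]}, index=["r0"])
        with pytest.raises(ValueError):
            assign_meta_groups(assign)


class TestCalibrateFpr:
    def test_zero_null_calls(self):
        null = calls_from_directions(["unchanged"] * 5)
        real = {"ST": calls_from_directions(["up"] * 3 + ["unchanged"] * 2)}
        fpr = calibrate_fpr(null, real)
        assert fpr.expected_fp == 0
        assert fpr.rate_range == (0.0, 0.0)

    def test_rate_arithmetic(self):
        null = calls_from_directions(["up"] * 10 + ["unchanged"] * 90)
        real = {
            "ST": calls_from_directions(["up"] * 100),
            "RS": calls_from_directions(["up"] * 50),
        }
        fpr = calibrate_fpr(null, real)
        assert fpr.expected_fp == 10
        assert fpr.fp_rate_per_comparison["ST"] == pytest.approx(0.10)
        assert fpr.fp_rate_per_comparison["RS"] == pytest.approx(0.20)
        assert fpr.rate_range == (pytest.approx(0.10), pytest.approx(0.20))

    def test_zero_call_comparison_flagged_nan(self):
        null = calls_from_directions(["up"])
        fpr = calibrate_fpr(null, {"ST": calls_from_directions(["unchanged"])})
        assert np.isnan(fpr.fp_rate_per_comparison["ST"])


class TestRottlerinSensitivity:
    def test_attenuation_ratio_rule(self):
        counts = make_counts(
            {"RS_DMSO": [350.0, 350.0], "RS_ROTT": [150.0, 300.0], "NS_DMSO": [100.0, 100.0]}
        )
        assign = pd.DataFrame(
            {"set_label": ["c", "c"]}, index=pd.Index(["r0", "r1"], name="region_id")
        )
        calls = {"RS": calls_from_directions(["up", "up"])[:2].set_index(assign.index)}
        out = flag_rottlerin_sensitive(assign, counts, calls)
        assert out["rott_sensitive_RS"].tolist() == [True, False]

    def test_planted_sensitivity_recovered(self, small_dataset):
        """Regions generated with full rottlerin attenuation of an RS
        increase should be flagged sensitive."""
        ds = small_dataset
        from faire_memory.differential import call_change
        from faire_memory.region_core import ma_normalize

        norm = ma_normalize(ds.counts, "NS_DMSO")
        calls = {
            st: call_change(norm, f"{st}_DMSO", "NS_DMSO") for st in ("ST", "SW", "RS")
        }
        assign = pd.DataFrame({"set_label": ds.truth["set_label"]}, index=ds.truth.index)
        out = flag_rottlerin_sensitive(assign, norm, calls)
        truth = ds.truth
        rs_up_sensitive = truth.index[
            truth["set_label"].isin(["b", "c", "e", "f"]) & truth["rott_sensitive"]
        ]
        called_up = calls["RS"].loc[rs_up_sensitive, "direction"] == "up"
        flagged = out.loc[rs_up_sensitive, "rott_sensitive_RS"]
        recovery = (flagged & called_up).sum() / max(called_up.sum(), 1)
        assert recovery >= 0.9


class TestWilcoxon:
    def test_identical_subsets_p_one(self):
        assert wilcoxon_rank_sum([1.0, 2, 3, 4], [1.0, 2, 3, 4]) == pytest.approx(1.0, abs=0.05)

    def test_complete_separation_small_p(self, rng):
        a = rng.normal(0, 1, 50)
        assert wilcoxon_rank_sum(a, a + 10) < 0.001

    def test_matches_exact_enumeration(self, rng):
        """Continuity-corrected normal approximation tracks the exact
        rank-sum distribution at n=8 vs 8."""
        a = rng.normal(0, 1, 8)
        b = rng.normal(0.5, 1, 8)
        approx = wilcoxon_rank_sum(a, b)
        exact = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        assert approx == pytest.approx(exact, abs=0.02)

    def test_tiny_subset_raises(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([1.0], [2.0, 3.0])
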