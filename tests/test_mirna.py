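import numpy as np
import pandas as pd
import pytest

from convergeomics.mirna import (
    NormalizedTable,
    ProbeCountTable,
    differential_mirna,
    mirna_feature_set,
    mirna_state_concordance,
    normalize_counts,
    presence_filter,
    read_probe_counts,
)
from convergeomics.pipeline import ConvergeParams, run_mirna_layer
from convergeomics.simulate import SimConfig, simulate_mirna


def table_from(counts: dict[str, list[int]], classes: dict[str, str],
               conditions: dict[str, str]) -> ProbeCountTable:
    lanes = list(conditions)
    return ProbeCountTable(
        counts=pd.DataFrame(counts, index=lanes).T.astype(int),
        probe_class=pd.Series(classes),
        conditions=pd.Series(conditions),
    )


@pytest.fixture
def two_lane_table():
    return table_from(
        counts={
            "POS_1": [100, 400],
            "POS_2": [100, 400],
            "mir_a": [50, 200],
            "mir_b": [10, 40],
            "NEG_1": [0, 0],
        },
        classes={
            "POS_1": "positive",
            "POS_2": "positive",
            "mir_a": "endogenous",
            "mir_b": "endogenous",
            "NEG_1": "negative",
        },
        conditions={"L1": "kd", "L2": "kd"},
    )


class TestNormalization:
    def test_positive_factors_from_spikein_ratio(self, two_lane_table):
        norm = normalize_counts(two_lane_table)
        # grand geomean of (100, 400) is 200 -> factors 2 and 0.5
        assert norm.factors.loc["L1", "positive_factor"] == pytest.approx(2.0)
        assert norm.factors.loc["L2", "positive_factor"] == pytest.approx(0.5)

    def test_exact_lane_scale_invariance(self, two_lane_table):
        # L2 is exactly 4x L1: normalized endogenous values coincide
        norm = normalize_counts(two_lane_table)
        a = norm.values.loc[["mir_a", "mir_b"], "L1"]
        b = norm.values.loc[["mir_a", "mir_b"], "L2"]
        assert np.allclose(a, b, rtol=1e-12)

    def test_identical_lanes_give_unit_factors(self):
        t = table_from(
            counts={"POS_1": [100, 100], "mir_a": [50, 50], "NEG_1": [2, 2]},
            classes={"POS_1": "positive", "mir_a": "endogenous", "NEG_1": "negative"},
            conditions={"L1": "kd", "L2": "kd"},
        )
        norm = normalize_counts(t)
        assert np.allclose(norm.factors["positive_factor"], 1.0)
        assert np.allclose(norm.factors["content_factor"], 1.0)

    def test_all_zero_positives_rejected(self):
        t = table_from(
            counts={"POS_1": [0, 100], "mir_a": [5, 5], "NEG_1": [0, 0]},
            classes={"POS_1": "positive", "mir_a": "endogenous", "NEG_1": "negative"},
            conditions={"L1": "kd", "L2": "kd"},
        )
        with pytest.raises(ValueError, match="L1"):
            normalize_counts(t)

    def test_background_threshold_mean_plus_two_sd(self):
        t = table_from(
            counts={
                "POS_1": [100, 100],
                "mir_a": [50, 50],
                "NEG_1": [2, 2],
                "NEG_2": [6, 6],
            },
            classes={
                "POS_1": "positive",
                "mir_a": "endogenous",
                "NEG_1": "negative",
                "NEG_2": "negative",
            },
            conditions={"L1": "kd", "L2": "kd"},
        )
        norm = normalize_counts(t)
        # factors are 1, negatives (2, 6): mean 4, sd (ddof=1) = 2*sqrt(2)
        expected = 4 + 2 * 2 * np.sqrt(2)
        assert norm.factors.loc["L1", "background_threshold"] == pytest.approx(expected)


class TestPresenceFilter:
    def make_norm(self, detected: dict[str, list[bool]], lanes: list[str]):
        """Build a NormalizedTable where detection is value 10 vs 0, thr 5."""
        values = pd.DataFrame(
            {p: [10.0 if d else 0.0 for d in flags] for p, flags in detected.items()},
            index=lanes,
        ).T
        return NormalizedTable(
            values=values,
            probe_class=pd.Series({p: "endogenous" for p in detected}),
            conditions=pd.Series({l: "x" for l in lanes}),
            factors=pd.DataFrame(
                {"positive_factor": 1.0, "content_factor": 1.0,
                 "background_threshold": 5.0},
                index=lanes,
            ),
        )

    def test_or_rule(self):
        lanes = [f"c{i}" for i in range(7)] + [f"k{i}" for i in range(4)]
        norm = self.make_norm(
            {
                "everywhere": [True] * 11,
                "six_controls": [True] * 6 + [False] * 5,
                "five_and_two": [True] * 5 + [False, False] + [True, True, False, False],
                "three_kd": [False] * 7 + [True, True, True, False],
            },
            lanes,
        )
        kept = presence_filter(norm, lanes[:7], lanes[7:], min_a=6, min_b=3)
        assert kept == {"everywhere", "six_controls", "three_kd"}

    def test_detection_is_strict_inequality(self):
        lanes = ["a1", "a2", "b1", "b2"]
        norm = self.make_norm({"at_thr": [True] * 4}, lanes)
        norm.values.loc["at_thr"] = 5.0  # exactly the threshold
        assert presence_filter(norm, lanes[:2], lanes[2:], 1, 1) == set()

    def test_monotone_in_minimums(self):
        lanes = [f"c{i}" for i in range(5)] + [f"k{i}" for i in range(4)]
        rng = np.random.default_rng(0)
        detected = {f"p{i}": list(rng.random(9) < 0.6) for i in range(30)}
        norm = self.make_norm(detected, lanes)
        prev = None
        for min_a in range(1, 6):
            kept = presence_filter(norm, lanes[:5], lanes[5:], min_a, 4)
            if prev is not None:
                assert kept <= prev
            prev = kept

    def test_minimums_beyond_group_size_raise(self):
        lanes = ["a1", "a2", "b1", "b2"]
        norm = self.make_norm({"p": [True] * 4}, lanes)
        with pytest.raises(ValueError):
            presence_filter(norm, lanes[:2], lanes[2:], 3, 1)


class TestDifferentialMirna:
    def test_identical_groups_yield_no_nominal(self):
        rng = np.random.default_rng(1)
        base = rng.integers(20, 500, size=10)
        counts = {f"mir{i}": [int(base[i])] * 8 for i in range(10)}
        counts["POS_1"] = [100] * 8
        counts["NEG_1"] = [1] * 8
        classes = {f"mir{i}": "endogenous" for i in range(10)}
        classes.update({"POS_1": "positive", "NEG_1": "negative"})
        lanes = {f"a{i}": "kd" for i in range(4)}
        lanes.update({f"b{i}": "nt_prolif" for i in range(4)})
        t = table_from(counts, classes, lanes)
        de = differential_mirna(normalize_counts(t), ("kd", "nt_prolif"))
        assert not de["nominal"].any()

    def test_recovers_planted_probes(self):
        # 2-fold planted effects on well-expressed probes (counting noise
        # dominates near the background and caps power for rare probes)
        cfg = SimConfig(
            seed=31, n_mirna=200, frac_de=0.15, effect_log2fc=1.0,
            mirna_base_log2_mean=8.0, mirna_base_log2_sd=1.0,
        )
        table, truth = simulate_mirna(cfg)
        norm = normalize_counts(table)
        de = differential_mirna(norm, ("kd", "nt_prolif"))
        nominal = set(de.index[de["nominal"]])
        planted = truth.de_kd.ids
        assert len(nominal & planted) / len(planted) >= 0.8

    def test_all_unit_p_gives_unit_q(self):
        # identical constant groups: p=1 everywhere, so q=1 everywhere
        counts = {f"mir{i}": [30] * 4 for i in range(5)}
        counts["POS_1"] = [100] * 4
        counts["NEG_1"] = [0] * 4
        classes = {f"mir{i}": "endogenous" for i in range(5)}
        classes.update({"POS_1": "positive", "NEG_1": "negative"})
        lanes = {"a1": "kd", "a2": "kd", "b1": "nt_prolif", "b2": "nt_prolif"}
        de = differential_mirna(
            normalize_counts(table_from(counts, classes, lanes)), ("kd", "nt_prolif")
        )
        assert (de["q"] == 1.0).all()


class TestStateConcordance:
    def make_norm_values(self, values: pd.DataFrame, conditions: pd.Series):
        return NormalizedTable(
            values=values,
            probe_class=pd.Series({p: "endogenous" for p in values.index}),
            conditions=conditions,
            factors=pd.DataFrame(
                {"positive_factor": 1.0, "content_factor": 1.0,
                 "background_threshold": 0.0},
                index=values.columns,
            ),
        )

    def _state_table(self, fc_map: dict[str, float]):
        """State table whose (nt_diff - nt_prolif) log2fc equals fc_map."""
        lanes = ["d1", "d2", "p1", "p2"]
        conditions = pd.Series(
            {"d1": "nt_diff", "d2": "nt_diff", "p1": "nt_prolif", "p2": "nt_prolif"}
        )
        rows = {}
        for probe, fc in fc_map.items():
            base = 63.0  # log2(63+1) = 6
            shifted = 2 ** (6 + fc) - 1
            rows[probe] = [shifted, shifted, base, base]
        values = pd.DataFrame(rows, index=lanes).T
        return self.make_norm_values(values, conditions)

    def test_equal_fold_changes_give_r_one(self):
        from convergeomics.core_stats import DirectionalFeatureSet, FeatureRecord

        kd = DirectionalFeatureSet(
            {
                "m1": FeatureRecord(1, 1.0),
                "m2": FeatureRecord(-1, -2.0),
                "m3": FeatureRecord(1, 0.5),
                "m4": FeatureRecord(1, 2.5),
            }
        )
        state = self._state_table({"m1": 1.0, "m2": -2.0, "m3": 0.5, "m4": 2.5})
        res = mirna_state_concordance(kd, state, ("nt_diff", "nt_prolif"))
        assert res.pearson_r == pytest.approx(1.0, abs=1e-9)
        assert res.frac_directionally_identical == 1.0

    def test_negated_fold_changes_give_r_minus_one(self):
        from convergeomics.core_stats import DirectionalFeatureSet, FeatureRecord

        kd = DirectionalFeatureSet(
            {
                "m1": FeatureRecord(1, 1.0),
                "m2": FeatureRecord(-1, -2.0),
                "m3": FeatureRecord(1, 0.5),
            }
        )
        state = self._state_table({"m1": -1.0, "m2": 2.0, "m3": -0.5})
        res = mirna_state_concordance(kd, state, ("nt_diff", "nt_prolif"))
        assert res.pearson_r == pytest.approx(-1.0, abs=1e-9)
        assert res.frac_directionally_identical == 0.0

    def test_too_few_shared_flagged(self):
        from convergeomics.core_stats import DirectionalFeatureSet, FeatureRecord

        kd = DirectionalFeatureSet({"m1": FeatureRecord(1, 1.0)})
        state = self._state_table({"m1": 1.0})
        res = mirna_state_concordance(kd, state, ("nt_diff", "nt_prolif"))
        assert res.pearson_r is None

    def test_shared_signal_produces_positive_r(self):
        wins = 0
        for seed in range(10):
            cfg = SimConfig(seed=seed + 40, n_mirna=200, frac_de=0.15,
                            rho_shared=1.0, effect_log2fc=2.0)
            table, _ = simulate_mirna(cfg)
            rep = run_mirna_layer(table, ConvergeParams())
            if rep.concordance.pearson_r is not None and rep.concordance.pearson_r > 0.5:
                wins += 1
        assert wins >= 9


class TestIO:
    def test_read_toy_fixture(self, toy_mirna_paths):
        counts_path, samples_path = toy_mirna_paths
        t = read_probe_counts(counts_path, samples_path)
        assert len(t.probes_of_class("endogenous")) == 6
        assert t.lanes_for("nt_prolif") == [f"ctrl{i}" for i in range(1, 8)]

    def test_missing_class_column_raises(self, tmp_path):
        bad = tmp_path / "counts.csv"
        bad.write_text("probe_id,L1\nm1,5\n")
        sheet = tmp_path / "samples.csv"
        sheet.write_text("sample,condition\nL1,kd\n")
        with pytest.raises(ValueError, match="class"):
            read_probe_counts(bad, sheet)
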