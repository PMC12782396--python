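"""Emotion identification points: stability rule, frequency tables, summaries."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vocalgate.core import GateSpec
from vocalgate.eip import (
    cumulative_percent,
    eip_summary,
    eip_table,
    gate_frequency_table,
    identify_point,
    records_frame,
    round_half_up,
)
from vocalgate.simulate import default_config, simulate_dataset

from conftest import GATES, make_dataset

LABELS = ("anger", "happiness", "fear", "sadness", "neutral")


def seq(responses):
    return list(zip(GATES, responses))


class TestIdentifyPoint:
    def test_correct_at_all_gates_gives_earliest(self):
        rec = identify_point(seq(["anger"] * 5), "anger", 1448.0)
        assert rec.status == "identified"
        assert rec.identification_gate == "G200"
        assert rec.eip_ms == 200.0

    def test_single_deviation_resets_stability(self):
        rec = identify_point(
            seq(["anger", "anger", "fear", "anger", "anger"]), "anger", 1448.0
        )
        assert rec.identification_gate == "G600"
        assert rec.eip_ms == 600.0

    def test_never_target_at_full_is_error(self):
        rec = identify_point(seq(["anger"] * 4 + ["fear"]), "anger", 1448.0)
        assert rec.status == "error"
        assert rec.eip_ms is None

    def test_full_gate_maps_to_actual_duration(self):
        rec = identify_point(
            seq(["fear", "fear", "fear", "fear", "anger"]), "anger", 2000.0
        )
        assert rec.identification_gate == "GFULL"
        assert rec.eip_ms == 2000.0

    def test_neutral_breaks_stability_like_wrong_emotion(self):
        via_neutral = identify_point(
            seq(["anger", "neutral", "anger", "anger", "anger"]), "anger", 1448.0
        )
        via_wrong = identify_point(
            seq(["anger", "fear", "anger", "anger", "anger"]), "anger", 1448.0
        )
        assert via_neutral.eip_ms == via_wrong.eip_ms == 500.0

    def test_missing_gate_is_incomplete(self):
        rec = identify_point(seq(["anger", None, "anger", "anger", "anger"]), "anger", 1448.0)
        assert rec.status == "incomplete"
        short = identify_point(list(zip(GATES[:4], ["anger"] * 4)), "anger", 1448.0)
        assert short.status == "incomplete"

    def test_unordered_or_duplicate_gates_rejected(self):
        with pytest.raises(ValueError):
            identify_point(list(zip(["G400", "G200"], ["anger", "anger"])), "anger", 1000.0)
        with pytest.raises(ValueError):
            identify_point(list(zip(["G200", "G200"], ["anger", "anger"])), "anger", 1000.0)

    @settings(max_examples=300, derandomize=True)
    @given(
        st.lists(st.sampled_from(LABELS), min_size=5, max_size=5),
        st.integers(min_value=0, max_value=4),
    )
    def test_monotone_refinement(self, responses, flip):
        """Correcting any single wrong response never delays the EIP."""
        target = "anger"
        base = identify_point(seq(responses), target, 1448.0)
        improved_responses = list(responses)
        improved_responses[flip] = target
        improved = identify_point(seq(improved_responses), target, 1448.0)
        base_ms = base.eip_ms if base.status == "identified" else float("inf")
        imp_ms = improved.eip_ms if improved.status == "identified" else float("inf")
        assert imp_ms <= base_ms


class TestEipTable:
    def _two_pair_dataset(self):
        items = {
            "a1": ("vocalization", "none", "anger", 1448.0),
            "h1": ("vocalization", "none", "happiness_pleasure", 2000.0),
        }
        rows = []
        for g, r in zip(GATES, ["anger", "anger", "anger", "anger", "anger"]):
            rows.append(("p1", "chinese", "a1", g, r))
        for g, r in zip(GATES, ["neutral", "neutral", "neutral", "neutral", "happiness"]):
            rows.append(("p1", "chinese", "h1", g, r))
        return make_dataset(rows, items)

    def test_vectorized_table_matches_scalar_rule(self):
        """Dual route: the wide-array scan equals identify_point per pair."""
        cfg = default_config(seed=9)
        small = cfg.__class__(
            groups=(("chinese", 2), ("arab", 2)),
            conditions=cfg.conditions[:4],
            seed=9,
        )
        ds = simulate_dataset(small)
        recs = {(r.participant_id, r.item_id): r for r in eip_table(ds)}
        df = ds.to_frame()
        from vocalgate.core import target_response

        for (pid, item), sub in df.groupby(["participant", "item"]):
            sub = sub.sort_values("gate", key=lambda s: s.map(ds.gate_spec.order_key))
            expected = identify_point(
                list(zip(sub["gate"], sub["response"])),
                target_response(sub["emotion"].iloc[0]),
                float(sub["full_duration_ms"].iloc[0]),
                ds.gate_spec,
            )
            got = recs[(pid, item)]
            assert got.status == expected.status
            assert got.eip_ms == expected.eip_ms

    def test_happiness_pleasure_target_is_happiness(self):
        ds = self._two_pair_dataset()
        recs = {r.item_id: r for r in eip_table(ds)}
        assert recs["h1"].status == "identified"
        assert recs["h1"].identification_gate == "GFULL"
        assert recs["h1"].eip_ms == 2000.0

    def test_empty_dataset_empty_list(self):
        assert eip_table(make_dataset([])) == []

    def test_category_filter(self):
        ds = self._two_pair_dataset()
        recs = eip_table(ds, include_categories=("anger",))
        assert [r.emotion for r in recs] == ["anger"]

    def test_partition_of_outcomes(self):
        cfg = default_config(seed=4)
        ds = simulate_dataset(cfg)
        rf = records_frame(eip_table(ds))
        n_pairs = ds.to_frame().groupby(["participant", "item"]).ngroups
        assert rf["status"].isin(["identified", "error", "incomplete"]).all()
        assert len(rf) == n_pairs


class TestRounding:
    @pytest.mark.parametrize(
        "x,expected", [(0.5, 1), (1.5, 2), (2.4, 2), (19.6, 20), (7.5, 8), (60.4, 60)]
    )
    def test_round_half_up(self, x, expected):
        assert round_half_up(x) == expected

    def test_cumulative_percent_known_row(self):
        assert cumulative_percent([151, 15, 7, 9, 19], 250) == [60, 66, 69, 73, 80]


class TestGateFrequencyTable:
    def _records_dataset(self, pattern_by_item):
        items = {}
        rows = []
        for item_id, responses in pattern_by_item.items():
            items[item_id] = ("vocalization", "none", "anger", 1000.0)
            for g, r in zip(GATES, responses):
                rows.append(("p1", "chinese", item_id, g, r))
        return make_dataset(rows, items)

    def test_single_identified_at_g200(self):
        ds = self._records_dataset({"a1": ["anger"] * 5})
        table = gate_frequency_table(eip_table(ds))
        row = table.iloc[0]
        assert [row[f"cum_pct_{g}"] for g in GATES] == [100] * 5
        assert row["n_errors"] == 0

    def test_counts_cumulative_and_errors(self):
        patterns = {
            "a1": ["anger"] * 5,  # identified at G200
            "a2": ["fear", "anger", "anger", "anger", "anger"],  # G400
            "a3": ["fear"] * 4 + ["anger"],  # GFULL
            "a4": ["anger"] * 4 + ["fear"],  # error
        }
        table = gate_frequency_table(eip_table(self._records_dataset(patterns)))
        row = table.iloc[0]
        assert [row[f"n_{g}"] for g in GATES] == [1, 1, 0, 0, 1]
        assert [row[f"cum_pct_{g}"] for g in GATES] == [25, 50, 50, 50, 75]
        assert row["n_errors"] == 1 and row["error_pct"] == 25
        # identified latencies: 200, 400, 1000
        assert row["eip_mean_ms"] == pytest.approx(np.mean([200, 400, 1000]))
        assert row["eip_sd_ms"] == pytest.approx(np.std([200, 400, 1000], ddof=1))

    def test_cumulative_non_decreasing_and_closure_on_simulated_data(self):
        ds = simulate_dataset(default_config(seed=2))
        table = gate_frequency_table(eip_table(ds))
        for _, row in table.iterrows():
            cums = [row[f"cum_pct_{g}"] for g in GATES]
            assert cums == sorted(cums)
            assert abs(cums[-1] + row["error_pct"] - 100) <= 1  # rounding slack
            counts = sum(row[f"n_{g}"] for g in GATES)
            assert counts + row["n_errors"] == row["n_total"]


class TestEipSummary:
    def _records(self, latencies, emotion="anger"):
        items = {}
        rows = []
        for k, ms in enumerate(latencies):
            item_id = f"i{k}"
            items[item_id] = ("vocalization", "none", emotion, 1000.0)
            target = "happiness" if emotion.startswith("happiness") else emotion
            responses = [
                target if GateSpec().gate_duration(g, 1000.0) >= ms else "neutral"
                for g in GATES
            ]
            for g, r in zip(GATES, responses):
                rows.append(("p1", "chinese", item_id, g, r))
        return eip_table(make_dataset(rows, items))

    def test_degenerate_all_at_200(self):
        out = eip_summary(self._records([200, 200, 200]))
        assert out["eip_mean_ms"].iloc[0] == 200.0
        assert out["eip_sd_ms"].iloc[0] == 0.0

    def test_pair_mean_and_sample_sd(self):
        out = eip_summary(self._records([200, 600]))
        assert out["eip_mean_ms"].iloc[0] == 400.0
        assert out["eip_sd_ms"].iloc[0] == pytest.approx(np.std([200, 600], ddof=1))

    def test_twenty_record_fixture_matches_arithmetic_oracle(self):
        rng = np.random.default_rng(8)
        lats = [float(rng.choice([200, 400, 500, 600, 1000])) for _ in range(20)]
        out = eip_summary(self._records(lats))
        assert out["eip_mean_ms"].iloc[0] == pytest.approx(np.mean(lats))
        assert out["eip_sd_ms"].iloc[0] == pytest.approx(np.std(lats, ddof=1))

    def test_happiness_pleasure_excluded_by_default(self):
        recs = self._records([200, 400], emotion="happiness_pleasure")
        assert eip_summary(recs).empty
        kept = eip_summary(recs, exclude_categories=())
        assert len(kept) == 1 and kept["n_identified"].iloc[0] == 2
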