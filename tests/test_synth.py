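import numpy as np
import pandas as pd
import pytest

from epimem import io, simple, synth
from epimem.types import DegenerateDataError, GenerativeParams, SchemaError, SimulationConfig, expit


class TestEncodingSchedule:
    @pytest.mark.parametrize(
        "protocol,lo_min,hi_min",
        [("SL", 14.2, 15.2), ("VR", 42.3, 42.7), ("RW", 3 * 1440.0, 17 * 1440.0)],
    )
    def test_span_within_protocol_envelope(self, protocol, lo_min, hi_min):
        cfg = SimulationConfig(protocol=protocol, seed=3, n_participants=8)
        _, sessions = synth.generate_encoding_schedule(cfg)
        span_min = sessions["encoding_span"] / 60.0
        assert (span_min >= lo_min).all() and (span_min <= hi_min).all()

    def test_same_seed_identical_schedules(self):
        cfg = SimulationConfig(protocol="SL", seed=9, n_participants=3)
        s1, r1 = synth.generate_encoding_schedule(cfg)
        s2, r2 = synth.generate_encoding_schedule(cfg)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(r1, r2)

    def test_times_strictly_increasing_and_unique_ids(self, sl_data):
        for _, ev in sl_data["encoding"].groupby("participant_id"):
            obj = ev[ev["has_object"]].sort_values("encode_time")
            assert (np.diff(obj["encode_time"].to_numpy(float)) > 0).all()
            assert ev["event_id"].is_unique

    def test_too_few_objects_rejected(self):
        with pytest.raises(SchemaError):
            SimulationConfig(protocol="SL", n_objects=1)


class TestSourceGeneration:
    def test_marginal_recognition_rate_calibrated(self):
        cfg = SimulationConfig(protocol="SL", seed=21, n_participants=20)
        data = synth.simulate_protocol(cfg)
        old = data["source"][data["source"]["is_old"].astype(bool)]
        rate = old["object_response"].isin(["Rem", "Fam"]).mean()
        p = cfg.p_recognize_old
        n = len(old)
        assert abs(rate - p) < 4 * np.sqrt(p * (1 - p) / n)

    def test_null_effects_give_logistic_gamma0_rem_rate(self):
        params = GenerativeParams(gamma_place=0.0, gamma_time=0.0, sigma_u=0.0, gamma0=-0.5)
        cfg = SimulationConfig(protocol="SL", seed=22, n_participants=20, params=params)
        data = synth.simulate_protocol(cfg)
        old = data["source"][data["source"]["is_old"].astype(bool)]
        rec = old[old["object_response"].isin(["Rem", "Fam"])]
        p_rem = (rec["object_response"] == "Rem").mean()
        expect = expit(-0.5)
        assert abs(p_rem - expect) < 4 * np.sqrt(expect * (1 - expect) / len(rec))

    def test_flat_accuracy_link_equalizes_confidence_cells(self):
        params = GenerativeParams(a1=0.0, a0=0.0)
        cfg = SimulationConfig(protocol="SL", seed=23, n_participants=20, params=params)
        data = synth.simulate_protocol(cfg)
        src = data["source"]
        rec = src[src["object_response"].isin(["Rem", "Fam"]) & src["is_old"].astype(bool)]
        for conf in ("high", "low"):
            acc = rec.loc[rec["place_conf"] == conf, "place_correct"].astype(bool).mean()
            assert abs(acc - 0.5) < 0.05

    def test_truth_table_contains_latents(self, sl_data):
        truth = sl_data["truth_source"]
        assert set(truth["kind"]) >= {"subject_intercept", "s_place", "s_time"}

    def test_output_passes_schema_validation(self, sl_data):
        io.validate_source(sl_data["source"])  # raises on violation


class TestOrderGeneration:
    def test_flat_rt_slope_decorrelates_ts_and_rt(self):
        params = GenerativeParams(rt_slope_obj=0.0, rt_slope_loc=0.0)
        cfg = SimulationConfig(protocol="SL", seed=31, n_participants=20, params=params)
        data = synth.simulate_protocol(cfg)
        r = np.corrcoef(data["order"]["ts"], data["order"]["rt"])[0, 1]
        assert abs(r) < 0.05

    def test_matched_pairs_share_encoding_distance(self, sl_data):
        """ev_TOloc probes the same event pairs as TOobj, so the multiset of
        encoding distances is identical within participant."""
        order = sl_data["order"]
        for _, sub in order.groupby("participant_id"):
            d_obj = np.sort(
                (sub.loc[sub["condition"] == "TOobj", "encode_b"] - sub.loc[sub["condition"] == "TOobj", "encode_a"]).to_numpy(float)
            )
            d_ev = np.sort(
                (sub.loc[sub["condition"] == "ev_TOloc", "encode_b"] - sub.loc[sub["condition"] == "ev_TOloc", "encode_a"]).to_numpy(float)
            )
            np.testing.assert_allclose(d_obj, d_ev, rtol=0)

    def test_matched_pairs_equal_ts_at_equal_retrieval_time(self, sl_data):
        """With retrieval timestamps equalized, matched object/place pairs
        have identical temporal similarity."""
        order = sl_data["order"]
        sub = order[order["participant_id"] == order["participant_id"].iloc[0]].copy()
        sub = sub[sub["condition"].isin(["TOobj", "ev_TOloc"])]
        sub["retrieval_time"] = sub["retrieval_time"].max()
        scored, _ = simple.score_order_trials(sub, scope="per_participant_per_block")
        key = ["encode_a", "encode_b"]
        merged = scored[scored["condition"] == "TOobj"].merge(
            scored[scored["condition"] == "ev_TOloc"], on=key, suffixes=("_obj", "_ev")
        )
        assert len(merged) > 0
        np.testing.assert_allclose(merged["ts_obj"], merged["ts_ev"], rtol=1e-12)

    def test_retrieval_timestamps_advance_through_session(self, sl_data):
        for _, sub in sl_data["order"].groupby("participant_id"):
            rt_times = sub["retrieval_time"].to_numpy(float)
            assert (np.diff(rt_times) > 0).all()

    def test_too_few_place_events_rejected(self):
        cfg = SimulationConfig(protocol="SL", seed=1, n_participants=2, n_place_only=1)
        rng = np.random.default_rng(0)
        schedule, sessions = synth.generate_encoding_schedule(cfg, rng)
        with pytest.raises(DegenerateDataError, match="noe_TOloc"):
            synth.generate_order_trials(schedule, cfg.params, sessions, cfg, rng)


class TestDeterminism:
    def test_identical_config_byte_identical_tables(self, tmp_path):
        cfg = SimulationConfig(protocol="RW", seed=77, n_participants=3)
        paths = []
        for run in ("a", "b"):
            data = synth.simulate_protocol(cfg)
            p = io.write_trials(data["order"], tmp_path / f"{run}.csv", "order", meta={"seed": 77})
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_different_protocols_use_independent_streams(self):
        study = synth.simulate_study(seed=4, overrides={"n_participants": 2})
        vr = study["VR"]["order"]["rt"].to_numpy()
        sl = study["SL"]["order"]["rt"].to_numpy()
        assert not np.allclose(vr[: len(sl)], sl[: len(vr)])
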