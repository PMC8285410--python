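import numpy as np
import pandas as pd
import pytest

from epimem import order, simple, synth
from epimem.types import GenerativeParams, SimulationConfig


@pytest.fixture(scope="module")
def order_study():
    """Three protocols, 8 participants each, default generative slopes."""
    return synth.simulate_study(seed=17, overrides={"n_participants": 8})


class TestSlopes:
    def test_incorrect_trials_do_not_enter_slopes(self, sl_data):
        trials = sl_data["order"]
        slopes = order.compute_slopes(trials)
        tampered = trials.copy()
        wrong = ~tampered["correct"].astype(bool)
        tampered.loc[wrong, "rt"] = 1e6  # absurd RTs on incorrect trials only
        slopes_t = order.compute_slopes(tampered)
        pd.testing.assert_frame_equal(slopes, slopes_t)

    def test_slope_recovery_toward_generative_value(self, order_study):
        slopes = pd.concat(
            [order.compute_slopes(order_study[p]["order"]) for p in order_study],
            ignore_index=True,
        )
        obj = slopes.loc[slopes["condition"] == "TOobj", "beta"]
        assert obj.mean() == pytest.approx(900.0, rel=0.15)
        loc = slopes.loc[slopes["condition"] != "TOobj", "beta"]
        assert loc.mean() == pytest.approx(450.0, abs=150.0)

    def test_constant_ts_cell_absent(self):
        trials = pd.DataFrame(
            {
                "participant_id": ["P0"] * 8,
                "condition": ["TOobj"] * 8,
                "ts": [0.5] * 8,
                "rt": np.linspace(2000, 2500, 8),
                "correct": [True] * 8,
            }
        )
        slopes = order.compute_slopes(trials)
        assert slopes.empty

    def test_unscored_trials_rejected(self, sl_data):
        df = sl_data["order"].copy()
        df.loc[df.index[0], "ts"] = np.nan
        with pytest.raises(ValueError, match="scored"):
            order.compute_slopes(df)


class TestAccuracyAnovas:
    def test_all_correct_subject_scores_one(self, rng):
        def proto_trials(prefix, flip):
            conds = ["TOobj", "ev_TOloc", "noe_TOloc"]
            frames = []
            for cond in conds:
                frames.append(
                    pd.DataFrame(
                        {
                            "participant_id": [f"{prefix}0"] * 6 + [f"{prefix}1"] * 6,
                            "condition": cond,
                            "ts": np.tile(np.linspace(0.4, 0.9, 6), 2),
                            "rt": 2000.0,
                            "correct": ([True] * 6 + [False] * 6)
                            if not flip
                            else list(rng.random(12) < 0.5),
                        }
                    )
                )
            return pd.concat(frames, ignore_index=True)

        res = order.order_accuracy_anovas({"VR": proto_trials("P", False), "RW": proto_trials("Q", True)})
        acc = res["accuracy"].groupby("participant_id")["correct"].mean()
        assert acc["P0"] == 1.0 and acc["P1"] == 0.0

    def test_anova_structure(self, order_study):
        res = order.order_accuracy_anovas({p: order_study[p]["order"] for p in order_study})
        assert res["anova_toobj"].table.df_num[0] == 2
        assert res["anova_toobj"].table.df_den[0] == 21  # 3 x 8 subjects
        effects = set(res["anova_toloc"].table["effect"])
        assert {"experiment", "condition", "condition*experiment"} <= effects
        assert len(res["tukey_toloc_experiment"]) == 3


class TestSlopeInference:
    def test_df_structure_with_full_sample(self):
        study = synth.simulate_study(seed=29)
        slopes = {p: order.compute_slopes(study[p]["order"]) for p in study}
        res = order.slope_inference(slopes)
        assert res["pooled_t"].df == 59  # 3 x 20 subjects
        cond = res["anova_slopes"].effect("condition")
        assert (cond["df_num"], cond["df_den"]) == (2, 114)

    def test_condition_effect_with_equal_experiment_slopes(self, order_study):
        slopes = {p: order.compute_slopes(order_study[p]["order"]) for p in order_study}
        res = order.slope_inference(slopes)
        # TOobj generated at 900, TOloc at 450 -> condition effect present
        assert res["anova_slopes"].p("condition") < 0.05
        means = res["condition_means"].groupby("condition")["beta"].mean()
        assert means["TOobj"] > means["ev_TOloc"]
        assert means["TOobj"] > means["noe_TOloc"]
        # positive similarity->RT coupling overall
        assert res["pooled_t"].t > 2.0

    def test_pure_noise_slopes_behave_null(self, rng):
        slopes = {
            proto: pd.DataFrame(
                {
                    "participant_id": [f"{proto}{i}" for i in range(10) for _ in range(3)],
                    "condition": ["TOobj", "ev_TOloc", "noe_TOloc"] * 10,
                    "beta": rng.normal(0, 100, 30),
                    "n_trials_used": 30,
                }
            )
            for proto in ("VR", "RW", "SL")
        }
        res = order.slope_inference(slopes)
        assert abs(res["pooled_t"].t) < 2.5
        assert res["bf_experiment"].bf10 < 1.0

    def test_incomplete_subjects_excluded(self, order_study):
        slopes = {p: order.compute_slopes(order_study[p]["order"]) for p in order_study}
        # remove one condition for one subject
        vr = slopes["VR"]
        drop_pid = vr["participant_id"].iloc[0]
        slopes["VR"] = vr[~((vr["participant_id"] == drop_pid) & (vr["condition"] == "TOobj"))]
        res = order.slope_inference(slopes)
        # the incomplete subject must be absent from the pooled t-test
        assert res["pooled_t"].n == 23


class TestPipelineScaleInvariance:
    def test_rescaled_timestamps_leave_inference_bit_identical(self, order_study):
        """Multiplying every timestamp by 2^k reproduces TS, slopes, F, t and
        BF exactly — the computational form of temporal scale invariance."""
        k = 2.0**7
        orig = {}
        scaled = {}
        for proto in order_study:
            trials = order_study[proto]["order"]
            re_scored, _ = simple.score_order_trials(trials)
            orig[proto] = re_scored
            resc = trials.copy()
            for col in ("encode_a", "encode_b", "retrieval_time"):
                resc[col] = resc[col].astype(float) * k
            re_scored_k, _ = simple.score_order_trials(resc)
            scaled[proto] = re_scored_k
            assert (re_scored_k["ts"].to_numpy() == re_scored["ts"].to_numpy()).all()

        s1 = {p: order.compute_slopes(orig[p]) for p in orig}
        s2 = {p: order.compute_slopes(scaled[p]) for p in scaled}
        for p in s1:
            assert (s1[p]["beta"].to_numpy() == s2[p]["beta"].to_numpy()).all()
        r1, r2 = order.slope_inference(s1), order.slope_inference(s2)
        assert r1.keys() == r2.keys()
        assert (
            r1["anova_slopes"].table["F"].to_numpy() == r2["anova_slopes"].table["F"].to_numpy()
        ).all()
        assert r1["pooled_t"].t == r2["pooled_t"].t
        assert r1["bf_experiment"].bf10 == r2["bf_experiment"].bf10
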