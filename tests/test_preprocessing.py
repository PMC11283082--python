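"""Circular error arithmetic, sinusoid bias removal and the cleaning cascade."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import serialdep as sd


def wrap_oracle(r, t):
    """Brute force: the unique representative of r - t (mod 180) in [-90, 90)."""
    cands = [r - t - 180.0 * k for k in range(-2, 3)]
    hits = [c for c in cands if -90.0 <= c < 90.0]
    assert len(hits) == 1
    return hits[0]


class TestCircularArithmetic:
    @pytest.mark.parametrize(
        "reported,theta,expected",
        [(10, 10, 0.0), (170, 10, -20.0), (100, 10, -90.0)],
    )
    def test_error_examples(self, reported, theta, expected):
        assert sd.compute_error(reported, theta) == expected

    @pytest.mark.parametrize(
        "prev,curr,expected", [(30, 10, 20.0), (10, 30, -20.0), (77, 77, 0.0)]
    )
    def test_delta_examples(self, prev, curr, expected):
        assert sd.compute_delta(prev, curr) == expected

    @given(
        r=st.floats(0, 360, allow_nan=False),
        t=st.floats(0, 180, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_error_matches_wrap_oracle(self, r, t):
        assert sd.compute_error(r, t) == pytest.approx(wrap_oracle(r, t), abs=1e-9)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            sd.compute_error(np.nan, 10.0)
        with pytest.raises(ValueError):
            sd.compute_delta(10.0, np.inf)


class TestBiasModel:
    def test_zero_signal_gives_zero_model(self, rng):
        thetas = rng.uniform(1, 180, 300)
        model, resid = sd.fit_bias_model(np.zeros(300), thetas)
        assert np.allclose(resid, 0.0, atol=1e-9)
        assert np.allclose(model(thetas), 0.0, atol=1e-9)

    def test_injected_sinusoid_removed(self, rng):
        thetas = rng.uniform(1, 180, 400)
        signal = 2.0 * np.sin(4 * np.pi * thetas / 180.0)
        errors = signal + rng.normal(0, 0.2, 400)
        model, resid = sd.fit_bias_model(errors, thetas)
        assert float(resid @ resid) < 0.10 * float(errors @ errors)

    def test_residuals_orthogonal_to_fit_noiseless(self, rng):
        thetas = rng.uniform(1, 180, 500)
        errors = 1.5 * np.sin(4 * np.pi * thetas / 180.0 + 0.3)
        model, resid = sd.fit_bias_model(errors, thetas)
        fitted = model(thetas)
        cos_sim = abs(float(resid @ fitted)) / (
            np.linalg.norm(errors) * np.linalg.norm(fitted) + 1e-30
        )
        assert cos_sim < 1e-6

    def test_too_few_trials_pass_through(self):
        errors = np.array([1.0, -2.0, 0.5] * 10)
        model, resid = sd.fit_bias_model(errors, np.linspace(1, 180, 30))
        assert not model.fitted
        assert np.array_equal(resid, errors)

    def test_residual_ss_never_exceeds_input_ss(self, rng):
        thetas = rng.uniform(1, 180, 200)
        errors = rng.normal(0, 5, 200)
        model, resid = sd.fit_bias_model(errors, thetas)
        assert model.sse <= model.total_ss + 1e-9


def _degenerate_config(**kw):
    base = dict(
        n_participants=3,
        n_trials=60,
        alpha_by_condition={"no_load": 0.0, "low": 0.0, "high": 0.0},
        noise_sd=0.0,
        lapse_rate=0.0,
        bias_terms=[],
        seed=5,
    )
    base.update(kw)
    return sd.SimConfig(**base)


class TestPreprocessCascade:
    def test_degenerate_dataset_keeps_everything(self):
        cleaned = sd.preprocess(sd.generate_dataset(_degenerate_config()))
        reasons = cleaned.data["exclusion_reason"]
        assert (reasons == "no_previous").sum() == 3  # one per participant
        assert set(reasons.unique()) == {"none", "no_previous"}
        assert cleaned.exclusion_fraction == 0.0

    def test_forced_lapses_flagged_exactly(self):
        df = sd.generate_dataset(_degenerate_config(n_participants=2, n_trials=200))
        forced = df.sample(frac=0.05, random_state=1).index
        df.loc[forced, "reported"] = np.mod(df.loc[forced, "theta"] + 90.0, 180.0)
        cleaned = sd.preprocess(df)
        flagged = set(cleaned.data.index[cleaned.data["exclusion_reason"] == "lapse"])
        # indices survive the per-participant sort because the table is ordered
        assert flagged == set(forced)
        assert len(flagged) / len(df) == 0.05

    def test_iqr_hand_computed_quartile_example(self):
        # errors {0, -1, -10, 1, 10}: q1=-1, q3=1 (linear interpolation),
        # fences at -/+4 -> -10 and 10 flagged
        errors = [0.0, -1.0, -10.0, 1.0, 10.0]
        df = pd.DataFrame(
            {
                "participant": 1,
                "trial_index": np.arange(1, 6),
                "has_load": False,
                "load_level": "none",
                "theta": 90.0,
                "reported": [90.0 + e for e in errors],
                "rt": 1.0,
            }
        )
        cleaned = sd.preprocess(df)
        reasons = cleaned.data["exclusion_reason"].tolist()
        assert reasons == ["no_previous", "none", "iqr_outlier", "none", "iqr_outlier"]

    def test_stage_order_lapse_beats_later_flags(self):
        # a lapse with a 20 s RT is reported as a lapse, not slow_rt; an IQR
        # outlier with slow RT keeps the earlier iqr_outlier reason
        errors = [0.0, 1.0, -1.0, 0.5, -0.5, 60.0, 25.0, 0.0]
        rts = [1, 1, 1, 1, 1, 20.0, 20.0, 20.0]
        df = pd.DataFrame(
            {
                "participant": 1,
                "trial_index": np.arange(1, 9),
                "has_load": False,
                "load_level": "none",
                "theta": 90.0,
                "reported": np.mod(90.0 + np.array(errors), 180.0),
                "rt": rts,
            }
        )
        cleaned = sd.preprocess(df)
        reasons = cleaned.data["exclusion_reason"].tolist()
        assert reasons[5] == "lapse"
        assert reasons[6] == "iqr_outlier"
        assert reasons[7] == "slow_rt"

    def test_demeaning_ignores_lapse_trials(self):
        # one huge lapse must not shift the mean of the kept errors
        errors = np.array([60.0] + [1.0, -1.0] * 30)
        df = pd.DataFrame(
            {
                "participant": 1,
                "trial_index": np.arange(1, errors.size + 1),
                "has_load": False,
                "load_level": "none",
                "theta": 90.0,
                "reported": np.mod(90.0 + errors, 180.0),
                "rt": 1.0,
            }
        )
        cleaned = sd.preprocess(df)
        kept = cleaned.data[cleaned.data["exclusion_reason"] != "lapse"]
        assert abs(kept["error_clean"].mean()) < 1e-9

    def test_clean_error_mean_invariant(self, cleaned):
        for _, grp in cleaned.data.groupby("participant"):
            non_lapse = grp[grp["exclusion_reason"] != "lapse"]
            assert abs(non_lapse["error_clean"].mean()) < 1e-9

    def test_delta_survives_excluded_previous_trial(self):
        df = sd.generate_dataset(_degenerate_config(n_participants=1, n_trials=60))
        df.loc[4, "reported"] = np.mod(df.loc[4, "theta"] + 80.0, 180.0)  # lapse
        cleaned = sd.preprocess(df)
        row = cleaned.data.iloc[5]
        assert cleaned.data.iloc[4]["exclusion_reason"] == "lapse"
        assert np.isfinite(row["delta"])
        assert row["included"]

    def test_exclusion_fraction_on_paper_like_data(self, cleaned):
        assert cleaned.exclusion_fraction < 0.15
        first = cleaned.data[cleaned.data["trial_index"] == 1]
        assert not first["included"].any()  # first trials never enter delta fits
        # no_previous only ever labels first trials (earlier reasons take precedence)
        tagged = cleaned.data[cleaned.data["exclusion_reason"] == "no_previous"]
        assert (tagged["trial_index"] == 1).all()

    def test_missing_columns_raise(self):
        with pytest.raises(ValueError, match="missing required columns"):
            sd.preprocess(pd.DataFrame({"participant": [1], "theta": [10.0]}))

    def test_bias_scope_validated(self, paper_like_dataset):
        with pytest.raises(ValueError, match="bias_scope"):
            sd.preprocess(paper_like_dataset, bias_scope="global")
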