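"""End-to-end trial simulation: populations, titration, sampling, censoring."""

import dataclasses

import numpy as np
import pytest

from pedpk import cli_io
from pedpk.covariate_model import OmegaSpec, SigmaSpec, ped_dose, typical_params
from pedpk.structural_pk import DoseRegimen, ValidationError, conc_regimen
from pedpk.trial_sim import (
    PKDataset,
    SimulationModel,
    TitrationRules,
    draw_sampling_times,
    sample_population,
    simulate_titration,
    simulate_trial,
)



def noise_free_model(mc: cli_io.ModelConfig) -> SimulationModel:
    return SimulationModel(
        coeffs=mc.coeffs,
        omega=OmegaSpec({"cl_f": 0.0, "v2_f": 0.0, "ka": 0.0}),
        sigma=SigmaSpec(),
    )


class TestSamplePopulation:
    def test_children_weight_mean(self, lion_cfg):
        big = dataclasses.replace(
            lion_cfg,
            strata=(dataclasses.replace(lion_cfg.strata[0], n=1000),),
        )
        subjects = sample_population(big, np.random.default_rng(11))
        weights = np.array([s.weight for s in subjects])
        assert abs(weights.mean() - 29.32) / 29.32 < 0.03
        ages = np.array([s.age for s in subjects])
        assert ages.min() >= 5.0 and ages.max() < 12.0

    def test_empty_stratum(self, lion_cfg):
        empty = dataclasses.replace(
            lion_cfg, strata=(dataclasses.replace(lion_cfg.strata[0], n=0),)
        )
        assert sample_population(empty, np.random.default_rng(0)) == []

    def test_deterministic(self, lion_cfg):
        a = sample_population(lion_cfg, np.random.default_rng(5))
        b = sample_population(lion_cfg, np.random.default_rng(5))
        assert a == b

    def test_ffm_and_agp_plausible(self, lion_cfg):
        subjects = sample_population(lion_cfg, np.random.default_rng(2))
        for s in subjects:
            assert 0 < s.ffm <= s.weight
            assert s.agp > 0


class TestTitration:
    def test_forced_up_titration_hits_ceiling(self, lion_cfg):
        rules = TitrationRules(p_up=1.0, p_down=0.0)
        s = sample_population(lion_cfg, np.random.default_rng(1))[0]
        sched = simulate_titration(s, rules, lion_cfg, np.random.default_rng(0))
        assert sched == {0: 5.0, 3: 7.5, 6: 10.0, 9: 10.0}

    def test_no_titration_stays_at_start(self, lion_cfg):
        rules = TitrationRules(p_up=0.0, p_down=0.0)
        s = sample_population(lion_cfg, np.random.default_rng(1))[0]
        sched = simulate_titration(s, rules, lion_cfg, np.random.default_rng(0))
        assert set(sched.values()) == {5.0}

    def test_infant_starts_low(self):
        cfg = cli_io.load_trial_config("marmoset")
        rng = np.random.default_rng(3)
        subjects = sample_population(cfg, rng)
        infants = [s for s in subjects if s.age < 2]
        assert infants, "design includes infants"
        sched = simulate_titration(
            infants[0], TitrationRules(p_up=0.0, p_down=0.0), cfg, rng
        )
        assert sched[0] == 2.5

    def test_default_policy_calibration(self, lion_cfg):
        # week-12 share on the top dose observed in the 12-week OAB trial
        rng = np.random.default_rng(12)
        subjects = sample_population(
            dataclasses.replace(
                lion_cfg,
                strata=(dataclasses.replace(lion_cfg.strata[0], n=1000),),
            ),
            rng,
        )
        final = [
            simulate_titration(s, lion_cfg.titration, lion_cfg, rng)[9]
            for s in subjects
        ]
        frac10 = np.mean([lv == 10.0 for lv in final])
        assert abs(frac10 - 0.69) < 0.10

    def test_moves_at_most_one_level(self, lion_cfg):
        rng = np.random.default_rng(8)
        s = sample_population(lion_cfg, rng)[0]
        for seed in range(30):
            sched = simulate_titration(
                s, TitrationRules(p_up=0.5, p_down=0.3), lion_cfg,
                np.random.default_rng(seed),
            )
            levels = [sched[w] for w in sorted(sched)]
            ladder = [2.5, 5.0, 7.5, 10.0]
            for a, b in zip(levels, levels[1:]):
                assert abs(ladder.index(a) - ladder.index(b)) <= 1


class TestSamplingTimes:
    def test_lion_week12_windows(self, lion_cfg):
        rng = np.random.default_rng(0)
        times = draw_sampling_times(lion_cfg, 12, rng)
        assert len(times) == 5
        pre, w1, w2, w3, washout = times
        assert -3 <= pre < 0
        assert 1 <= w1 <= 3
        assert 4 <= w2 <= 5
        assert 7 <= w3 <= 10
        assert 48 <= washout <= 72

    def test_monkey_windows(self):
        cfg = cli_io.load_trial_config("monkey")
        rng = np.random.default_rng(0)
        times = draw_sampling_times(cfg, 24, rng)
        assert len(times) == 4
        assert 4 <= times[2] <= 6

    def test_draws_always_inside_windows(self, lion_cfg):
        rng = np.random.default_rng(99)
        for _ in range(2000):
            for (_, lo, hi), t in zip(
                lion_cfg.sampling_windows, draw_sampling_times(lion_cfg, 12, rng)
            ):
                assert lo <= t <= hi
                if hi <= 0:
                    assert t < 0


class TestSimulateTrial:
    def test_noise_free_observations_match_regimen(self, lion_cfg, lion_final):
        ds = simulate_trial(
            lion_cfg, noise_free_model(lion_final), 5, noise=False, censor=False
        )
        sid = ds.df["ID"].iloc[0]
        g = ds.df[ds.df["ID"] == sid]
        doses = g[g["EVID"] == 1]
        obs = g[g["EVID"] == 0]
        cov = g.iloc[0]
        from pedpk.covariate_model import Subject

        subj = Subject(id=sid, age=cov["AGE"], weight=cov["WT"], ffm=cov["FFM"],
                       agp=cov["AGP"], formulation=cov["FORM"])
        p = typical_params(subj, lion_final.coeffs)
        expected = conc_regimen(
            obs["TIME"].to_numpy(),
            DoseRegimen(list(zip(doses["TIME"], doses["AMT"]))),
            p,
        )
        np.testing.assert_allclose(obs["DV"].to_numpy(), expected, rtol=1e-12)

    def test_dataset_invariants_hold(self, lion_cfg, lion_final):
        ds = simulate_trial(lion_cfg, lion_final.simulation_model("LION"), 3)
        ds.validate()  # raises on violation
        assert ds.n_subjects == 95

    def test_deterministic_under_seed(self, giraffe_cfg, lion_final):
        model = lion_final.simulation_model("GIRAFFE")
        a = simulate_trial(giraffe_cfg, model, 17)
        b = simulate_trial(giraffe_cfg, model, 17)
        assert a.df.equals(b.df)

    def test_most_observations_within_assay_range(self, lion_cfg, lion_final):
        cfg = dataclasses.replace(
            lion_cfg,
            strata=tuple(
                dataclasses.replace(s, n=n)
                for s, n in zip(lion_cfg.strata, (38, 12))
            ),
        )
        ds = simulate_trial(cfg, lion_final.simulation_model("LION"), 23)
        obs = ds.df[(ds.df["EVID"] == 0) & (ds.df["TAD"] <= 24)]
        dv = obs["DV"]
        in_range = ((dv >= 0.2) & (dv <= 200)) | (obs["BLQ"] == 1).to_numpy() * False
        frac = in_range.fillna(False).mean()
        assert frac > 0.90

    def test_censoring_monotone_in_lloq(self, lion_cfg, lion_final):
        model = lion_final.simulation_model("LION")
        fracs = []
        for lloq in (0.2, 2.0, 10.0):
            cfg = dataclasses.replace(lion_cfg, lloq=lloq)
            ds = simulate_trial(cfg, model, 31)
            obs = ds.df[ds.df["EVID"] == 0]
            fracs.append((obs["BLQ"] == 1).mean())
        assert fracs[0] <= fracs[1] <= fracs[2]
        assert fracs[2] > fracs[0]  # sensitivity check actually bites

    def test_censored_rows_withhold_value(self, lion_cfg, lion_final):
        cfg = dataclasses.replace(lion_cfg, lloq=5.0)
        ds = simulate_trial(cfg, lion_final.simulation_model("LION"), 31)
        blq = ds.df[ds.df["BLQ"] == 1]
        assert len(blq) > 0
        assert blq["DV"].isna().all()
        assert (blq["MDV"] == 1).all()

    def test_giraffe_single_dose_rich_grid(self, giraffe_cfg, lion_final):
        ds = simulate_trial(
            giraffe_cfg, lion_final.simulation_model("GIRAFFE"), 2,
            noise=False, censor=False,
        )
        for _, g in ds.df.groupby("ID"):
            assert (g["EVID"] == 1).sum() == 1
            assert (g["EVID"] == 0).sum() == len(giraffe_cfg.rich_grid)
            # dose is 3x the weight-adjusted PED of the assigned level
            amt = g[g["EVID"] == 1]["AMT"].iloc[0]
            assert amt % 0.5 == 0 or amt > 0

    def test_invalid_visit_after_end_rejected(self, lion_cfg):
        with pytest.raises(ValidationError):
            dataclasses.replace(lion_cfg, pk_visit_weeks=(99,))


class TestDoseNormalizedExposure:
    def test_typical_auc_size_independent(self, lion_final):
        """Weight-based PED dosing targets size-independent steady-state AUC:
        dose scales with ffm^0.652, exactly the clearance exponent."""
        from pedpk.covariate_model import Subject

        aucs = []
        for ffm, wt in ((15, 19), (24, 29), (35, 44), (45, 57)):
            s = Subject(id=f"F{ffm}", age=10.0, weight=wt, ffm=ffm, agp=67.0)
            dose = ped_dose(10.0, s)
            p = typical_params(s, lion_final.coeffs)
            aucs.append(dose / p.cl_f * 1000.0)
        aucs = np.array(aucs)
        assert aucs.std() / aucs.mean() < 0.06  # only rounding jitter remains
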