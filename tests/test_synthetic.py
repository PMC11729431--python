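import numpy as np
import pytest

from erfesim.engine import predict
from erfesim.synthetic import (
    DESIGNS,
    get_design,
    make_cohort,
    make_dataset,
    make_hyporesponder_cohort,
)


class TestMakeCohort:
    def test_zero_cv_reproduces_table_values(self, table2):
        cohort = make_cohort("cia", 5, cv={"ec50": 0.0}, seed=0)
        assert all(s.params.values == table2.values for s in cohort)

    def test_seed_reproducibility(self):
        a = make_cohort("ckd", 6, cv={"ec50": 0.3, "rbc0": 0.05}, seed=123)
        b = make_cohort("ckd", 6, cv={"ec50": 0.3, "rbc0": 0.05}, seed=123)
        assert [s.params.values for s in a] == [s.params.values for s in b]
        c = make_cohort("ckd", 6, cv={"ec50": 0.3, "rbc0": 0.05}, seed=124)
        assert [s.params.values for s in c] != [s.params.values for s in a]

    def test_lognormal_spread_matches_nominal_cv(self, table1):
        """Law of large numbers: empirical log-SD of EC50 within 5% of
        sqrt(ln(1+CV^2)) at n=1000."""
        cv = 0.3
        cohort = make_cohort("ckd", 1000, cv={"ec50": cv}, seed=99)
        log_ec50 = np.log([s.params.ec50 for s in cohort])
        nominal = np.sqrt(np.log1p(cv**2))
        assert np.std(log_ec50) == pytest.approx(nominal, rel=0.05)
        assert np.mean(log_ec50) == pytest.approx(np.log(table1.ec50), abs=0.05)

    def test_negative_cv_rejected(self):
        with pytest.raises(ValueError):
            make_cohort("cia", 2, cv={"ec50": -0.1})


class TestMakeDataset:
    def test_cia_design_layout(self, pk_config):
        cohort = make_cohort("cia", 27, seed=1)
        table = make_dataset(cohort, "cia_study", seed=1, pk_config=pk_config)
        assert len(table.subjects) == 27
        arms = table.df.groupby("arm")["subject"].nunique()
        assert dict(arms) == {"saline": 9, "epo450": 9, "epo1350": 9}
        one = table.subjects[-1]  # an epo1350 subject
        erfe = table.observations(one, "ERFE")
        assert list(erfe["time_h"] - 192.0) == [0, 1, 2, 4, 6, 8, 10, 12, 24]
        assert len(table.observations(one, "RBC")) == 17
        epo, carb = table.dose_schedule(one)
        assert epo == ((192.0, 1350.0),) and carb == ((24.0, 60.0),)
        # saline arm: carboplatin only
        epo0, carb0 = table.dose_schedule(table.subjects[0])
        assert epo0 == () and carb0 == ((24.0, 60.0),)

    def test_observations_center_on_noiseless_predictions(self, pk_config, table2):
        """Proportional-error draws: (dv/yhat - 1)/sigma is standard normal;
        empirical CV of replicated observations matches sigma."""
        cohort = make_cohort("cia", 100, seed=2)
        design = {
            "model": "cia",
            "arms": (("hi", 1350.0, None),),
            "epo_dose_times": (192.0,),
            "carb_dose": (24.0, 60.0),
            "first_epo_time": 192.0,
            "erfe_times": (196.0,),
            "hema_times": (336.0,),
        }
        table = make_dataset(cohort, design, seed=2, pk_config=pk_config)
        preds = predict(table, table2, "cia", pk_config=pk_config)
        obs = table.observations(analyte="ERFE")
        z = (obs["dv"].to_numpy() / preds.loc[obs.index].to_numpy() - 1.0)
        assert np.std(z) == pytest.approx(table2.sigma_frac("ERFE"), rel=0.2)
        assert np.mean(z) == pytest.approx(0.0, abs=3 * table2.sigma_frac("ERFE") / 10)

    def test_seeded_reproducibility_and_trunc_flag(self, pk_config):
        cohort = make_cohort("cia", 3, seed=3)
        design = dict(get_design("hyporesponder_study"))
        a = make_dataset(cohort, design, seed=3, pk_config=pk_config)
        b = make_dataset(cohort, design, seed=3, pk_config=pk_config)
        assert a == b
        assert "trunc" in a.df.columns
        assert (a.df.loc[a.df["evid"] == 0, "dv"] >= 0).all()

    def test_cohort_size_must_match_design(self, pk_config):
        cohort = make_cohort("cia", 5, seed=4)
        with pytest.raises(ValueError, match="cohort size"):
            make_dataset(cohort, "cia_study", seed=4, pk_config=pk_config)


class TestHyporesponderCohort:
    def test_benign_cohort_has_no_hyporesponders(self, pk_config):
        """All-benign severities: every subject gains >= 1 g/dL HGB within
        a week of rHuEPO (EPO-responsive, mild myelosuppression)."""
        from erfesim.biomarkers import biomarker_table

        cohort = make_hyporesponder_cohort(3, seed=6, severities=[0.0, 0.05, 0.1])
        dataset = make_dataset(cohort, "hyporesponder_study", seed=6, pk_config=pk_config)
        table = biomarker_table(dataset, dose_time=192.0, hgb_window_h=144.0)
        assert not table["hyporesponder"].any()

    def test_severe_cohort_all_hyporesponders(self, pk_config):
        from erfesim.biomarkers import biomarker_table

        cohort = make_hyporesponder_cohort(3, seed=7, severities=[0.9, 0.95, 1.0])
        dataset = make_dataset(cohort, "hyporesponder_study", seed=7, pk_config=pk_config)
        table = biomarker_table(dataset, dose_time=192.0, hgb_window_h=144.0)
        assert table["hyporesponder"].all()

    def test_ground_truth_labels_recorded(self):
        cohort = make_hyporesponder_cohort(4, seed=8, severities=[0.1, 0.4, 0.6, 0.9])
        assert [s.true_hyporesponder for s in cohort] == [False, False, True, True]
        # severity scales the kill effect and potency monotonically
        assert cohort[0].params.k_carb < cohort[3].params.k_carb
        assert cohort[0].params.ec50 < cohort[3].params.ec50
        assert cohort[0].p3_scale > cohort[3].p3_scale

    def test_invalid_severities_rejected(self):
        with pytest.raises(ValueError):
            make_hyporesponder_cohort(2, severities=[0.5, 1.5])


def test_full_pipeline_smoke(pk_config, table1):
    """Dataset generation -> objective evaluation -> pcVPC runs end to end."""
    from erfesim.estimation import objective, pc_vpc

    cohort = make_cohort("ckd", 17, seed=9)
    dataset = make_dataset(cohort, "ckd_study", seed=9, pk_config=pk_config)
    ofv = objective(table1, dataset, "ckd", pk_config=pk_config, rtol=1e-6, atol=1e-8)
    assert np.isfinite(ofv)
    vpc = pc_vpc(dataset, table1, "ckd", n_sim=100, seed=1, pk_config=pk_config)
    assert not vpc.empty


def test_designs_registry():
    assert set(DESIGNS) == {"ckd_study", "cia_study", "hyporesponder_study"}
    with pytest.raises(ValueError):
        get_design("nope")
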