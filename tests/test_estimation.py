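import numpy as np
import pytest
from scipy import stats

from erfesim.engine import predict
from erfesim.estimation import fit, objective, ofv_from_residuals, pc_vpc
from erfesim.events import EventTable
from erfesim.synthetic import make_cohort, make_dataset

LOG_2PI = np.log(2.0 * np.pi)


class TestObjectiveClosedForms:
    def test_zero_residuals(self):
        yhat = np.array([2.0, 5.0, 9.0])
        sigma = np.full(3, 0.2)
        expected = np.sum(np.log(sigma**2 * yhat**2)) + 3 * LOG_2PI
        assert ofv_from_residuals(yhat, yhat, sigma) == pytest.approx(expected, rel=1e-12)

    def test_single_observation_hand_value(self):
        # y=11, yhat=10, sigma=0.1 -> 1 + ln(1) + ln(2*pi)
        ofv = ofv_from_residuals(np.array([11.0]), np.array([10.0]), np.array([0.1]))
        assert ofv == pytest.approx(1.0 + 0.0 + 1.8378770664093453, abs=1e-10)

    def test_doubling_sigma_with_zero_residuals(self):
        yhat = np.array([3.0, 4.0, 5.0, 6.0])
        a = ofv_from_residuals(yhat, yhat, np.full(4, 0.1))
        b = ofv_from_residuals(yhat, yhat, np.full(4, 0.2))
        assert b - a == pytest.approx(2 * 4 * np.log(2.0), rel=1e-12)

    def test_matches_gaussian_logpdf_oracle(self, rng):
        """OFV == -2 * sum log N(y; yhat, sigma*yhat) on random data."""
        for _ in range(5):
            n = rng.integers(3, 30)
            yhat = rng.uniform(0.5, 20.0, n)
            sigma = rng.uniform(0.01, 0.5, n)
            y = yhat * (1 + sigma * rng.standard_normal(n))
            oracle = -2.0 * np.sum(stats.norm.logpdf(y, loc=yhat, scale=sigma * yhat))
            assert ofv_from_residuals(y, yhat, sigma) == pytest.approx(oracle, abs=1e-8)

    def test_nonpositive_prediction_penalized_with_warning(self):
        with pytest.warns(RuntimeWarning, match="non-positive"):
            ofv = ofv_from_residuals(
                np.array([1.0, 2.0]), np.array([1.0, 0.0]), np.array([0.1, 0.1])
            )
        assert ofv > 1e5


def _noiseless_cia_dataset(params, pk_config, n_subjects=1):
    """Single-arm CIA dataset whose dv equal the model predictions exactly."""
    records = []
    for i in range(n_subjects):
        sid = f"s{i}"
        records.append(dict(subject=sid, arm="hi", time_h=24.0, evid=1,
                            drug="carboplatin", amt=60.0))
        records.append(dict(subject=sid, arm="hi", time_h=192.0, evid=1,
                            drug="rHuEPO", amt=1350.0))
        for off in (0, 1, 2, 4, 6, 8, 10, 12, 24):
            records.append(dict(subject=sid, arm="hi", time_h=192.0 + off, evid=0,
                                analyte="ERFE", dv=1.0, mdv=0))
        for day in (0, 3, 6):
            records.append(dict(subject=sid, arm="hi", time_h=192.0 + 24.0 * day,
                                evid=0, analyte="HGB", dv=1.0, mdv=0))
    table = EventTable.from_records(records)
    preds = predict(table, params, "cia", pk_config=pk_config)
    df = table.df
    obs = df["evid"] == 0
    df.loc[obs, "dv"] = preds[obs]
    return EventTable(df)


def test_objective_consistent_with_predict_path(table2, pk_config):
    events = _noiseless_cia_dataset(table2, pk_config)
    obs = events.observations()
    preds = predict(events, table2, "cia", pk_config=pk_config)
    yhat = preds.loc[obs.index].to_numpy(float)
    sigma = np.array([table2.sigma_frac(a) for a in obs["analyte"]])
    manual = ofv_from_residuals(obs["dv"].to_numpy(float), yhat, sigma)
    assert objective(table2, events, "cia", pk_config=pk_config) == pytest.approx(
        manual, rel=1e-10
    )


def test_fit_noise_free_self_consistency(table2, pk_config):
    """Starting at the generating truth on noise-free data, the optimizer
    stays in the truth's immediate neighborhood. (The exact proportional-
    error ML optimum sits a fraction of a percent off the generating value
    at finite n because the ln(sigma^2*yhat^2) normalization term carries
    its own parameter gradient.)"""
    events = _noiseless_cia_dataset(table2, pk_config)
    result = fit(events, table2, ["ec50"], "cia", pk_config=pk_config, maxiter=60)
    assert result.estimates["ec50"] == pytest.approx(table2.ec50, rel=0.02)
    assert result.ofv <= result.ofv_initial + 1e-9


def test_adding_a_parameter_never_worsens_ofv(table2, pk_config):
    events = _noiseless_cia_dataset(table2, pk_config)
    start = table2.replace(ec50=200.0)
    one = fit(events, start, ["ec50"], "cia", pk_config=pk_config, maxiter=60)
    two = fit(events, start, ["ec50", "emax"], "cia", pk_config=pk_config, maxiter=120)
    assert two.ofv <= one.ofv + 1e-6


def test_dropping_erfe_transits_degrades_fit_significantly(table2, pk_config):
    """Refitting with the transit compartments removed raises the OFV by far
    more than the 3.84 single-parameter significance drop."""
    cohort = make_cohort("cia", 3, seed=11)
    dataset = make_dataset(cohort, {
        "model": "cia",
        "arms": (("hi", 1350.0, None),),
        "epo_dose_times": (192.0,),
        "carb_dose": (24.0, 60.0),
        "first_epo_time": 192.0,
        "erfe_times": tuple(192.0 + o for o in (0, 1, 2, 4, 6, 8, 10, 12, 24)),
        "hema_times": (),
    }, seed=11, pk_config=pk_config)
    full = fit(dataset, table2, ["ec50"], "cia", pk_config=pk_config, maxiter=60)
    reduced = fit(dataset, table2, ["ec50"], "cia", pk_config=pk_config,
                  maxiter=60, erfe_stages=2)
    assert reduced.ofv - full.ofv > 3.84


def test_fit_reports_rse_and_residuals(table2, pk_config):
    cohort = make_cohort("cia", 2, seed=3)
    dataset = make_dataset(cohort, {
        "model": "cia",
        "arms": (("hi", 1350.0, None),),
        "epo_dose_times": (192.0,),
        "carb_dose": (24.0, 60.0),
        "first_epo_time": 192.0,
        "erfe_times": tuple(192.0 + o for o in (0, 2, 4, 8, 12, 24)),
        "hema_times": (),
    }, seed=3, pk_config=pk_config)
    res = fit(dataset, table2, ["ec50"], "cia", pk_config=pk_config, maxiter=60)
    assert np.isfinite(res.ofv)
    assert res.rse_percent["ec50"] > 0
    assert len(res.residuals) == res.n_obs == 12
    # with IIV=0 the CWRES analogue is (y-yhat)/(sigma*yhat)
    r = res.residuals
    assert r["wres"].to_numpy() == pytest.approx(
        (r["dv"] - r["pred"]) / (table2.sigma_frac("ERFE") * r["pred"]), rel=1e-12
    )


def test_estimator_calibration_median_bias(table2, pk_config):
    """Across >= 20 seeded replicates of a scaled-down CIA recovery
    experiment (carboplatin arm only, k_carb and MTT free), the median
    relative bias of each recovered parameter stays below 10%."""
    design = {
        "model": "cia",
        "arms": (("carb", 0.0, None),),
        "epo_dose_times": (),
        "carb_dose": (24.0, 60.0),
        "first_epo_time": 192.0,
        "erfe_times": (),
        "hema_times": tuple(192.0 + 24.0 * d for d in (-8, -4, 0, 3, 6, 9, 12, 14, 17)),
    }
    estimates = {"k_carb": [], "mtt": []}
    for seed in range(20):
        rng = np.random.default_rng(1000 + seed)
        cohort = make_cohort("cia", 4, seed=seed)
        dataset = make_dataset(cohort, design, seed=seed, pk_config=pk_config)
        start = table2.replace(
            k_carb=table2.k_carb * rng.uniform(0.7, 1.3),
            mtt=table2.mtt * rng.uniform(0.7, 1.3),
        )
        res = fit(dataset, start, ["k_carb", "mtt"], "cia", pk_config=pk_config,
                  rtol=1e-6, maxiter=250)
        for name in estimates:
            estimates[name].append(res.estimates[name])
    for name, truth in (("k_carb", table2.k_carb), ("mtt", table2.mtt)):
        bias = np.median(np.abs(np.array(estimates[name]) / truth - 1.0))
        assert bias < 0.10, f"{name} median |bias| {bias:.3f}"


class TestPcVpc:
    def test_self_calibration_coverage(self, table1, pk_config):
        """Data generated from the model itself: observed bin medians fall
        inside the simulated 95% CI in >= 90% of bins."""
        cohort = make_cohort("ckd", 17, seed=7)
        dataset = make_dataset(cohort, "ckd_study", seed=7, pk_config=pk_config)
        table = pc_vpc(dataset, table1, "ckd", n_sim=200, seed=42, pk_config=pk_config)
        assert len(table) > 20
        assert table["covered"].mean() >= 0.90

    def test_correction_is_identity_for_constant_pred(self, table2, pk_config):
        """All subjects share one schedule -> PRED constant within each bin
        -> pcY = Y, so the observed median is the plain median."""
        cohort = make_cohort("cia", 4, seed=5)
        design = {
            "model": "cia",
            "arms": (("hi", 1350.0, None),),
            "epo_dose_times": (192.0,),
            "carb_dose": (24.0, 60.0),
            "first_epo_time": 192.0,
            "erfe_times": (192.0, 196.0),
            "hema_times": (),
        }
        dataset = make_dataset(cohort, design, seed=5, pk_config=pk_config)
        table = pc_vpc(dataset, table2, "cia", n_sim=100, seed=1, pk_config=pk_config)
        obs = dataset.observations(analyte="ERFE")
        for _, row in table.iterrows():
            plain = obs[np.isclose(obs["time_h"], row["time_h"])]["dv"].median()
            assert row["obs_median_pc"] == pytest.approx(plain, rel=1e-12)

    def test_interval_collapses_with_tiny_sigma(self, table2, pk_config):
        tiny = table2.replace(sigma_erfe=1e-4, sigma_rbc=1e-4, sigma_hgb=1e-4)
        cohort = [s for s in make_cohort("cia", 4, seed=5, base=tiny)]
        design = {
            "model": "cia",
            "arms": (("hi", 1350.0, None),),
            "epo_dose_times": (192.0,),
            "carb_dose": (24.0, 60.0),
            "first_epo_time": 192.0,
            "erfe_times": (196.0,),
            "hema_times": (),
        }
        dataset = make_dataset(cohort, design, seed=5, pk_config=pk_config)
        table = pc_vpc(dataset, tiny, "cia", n_sim=100, seed=1, pk_config=pk_config)
        width = table["sim_median_hi"] - table["sim_median_lo"]
        assert (width / table["obs_median_pc"] < 1e-4).all()

    def test_requires_minimum_simulations(self, table2, pk_config):
        with pytest.raises(ValueError, match="n_sim"):
            pc_vpc(EventTable.from_records(
                [dict(subject="1", time_h=0.0, evid=0, analyte="ERFE", dv=9.0, mdv=0)]
            ), table2, "cia", n_sim=10)
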