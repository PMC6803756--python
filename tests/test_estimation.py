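"""Maximum-likelihood and hierarchical-Bayesian PVL estimation."""

import numpy as np
import pytest

from igt_pvl import PVLParameters, compare_rules, fit_hba, fit_mle, simulate_agent
from igt_pvl.estimation import fits_table, simulate_hba_cohort_params
from igt_pvl.pvl_model import MLE_BOUNDS

from conftest import make_session


def _inside_box(params):
    return (
        MLE_BOUNDS["alpha"][0] < params.alpha < MLE_BOUNDS["alpha"][1]
        and MLE_BOUNDS["lam"][0] < params.lam < MLE_BOUNDS["lam"][1]
        and MLE_BOUNDS["A"][0] < params.recency_A < MLE_BOUNDS["A"][1]
        and MLE_BOUNDS["c"][0] < params.consistency_c < MLE_BOUNDS["c"][1]
    )


class TestFitMLE:
    def test_random_agent_degenerate_case(self):
        """Data from a c~0 agent: loglik ~ n log(1/4), fitted c near zero."""
        p = PVLParameters(alpha=0.5, lam=2.0, recency_A=0.5, consistency_c=1e-300)
        sess = simulate_agent(p, seed=0)
        fit = fit_mle(sess, rule="decay", n_starts=10, seed=1)
        assert fit.loglik == pytest.approx(100 * np.log(0.25), abs=1.5)
        assert fit.params.consistency_c < 0.5
        assert _inside_box(fit.params)

    def test_determinism_and_bounds(self, sample_session):
        a = fit_mle(sample_session, n_starts=8, seed=3)
        b = fit_mle(sample_session, n_starts=8, seed=3)
        assert a.params == b.params and a.loglik == b.loglik
        assert _inside_box(a.params)

    def test_loglik_is_max_over_starts(self, sample_session):
        few = fit_mle(sample_session, n_starts=2, seed=0)
        many = fit_mle(sample_session, n_starts=20, seed=0)
        assert many.loglik >= few.loglik - 1e-6

    def test_recovery_midrange_truth(self, midrange_params):
        """Fits on sessions from a known agent cluster near the truth."""
        fits = [
            fit_mle(simulate_agent(midrange_params, seed=s), n_starts=10, seed=s)
            for s in range(25)
        ]
        med_A = np.median([f.params.recency_A for f in fits])
        med_c = np.median([f.params.consistency_c for f in fits])
        assert abs(med_A - 0.5) < 0.15
        assert abs(med_c - 1.0) < 0.3

    def test_empty_session_rejected(self):
        with pytest.raises(ValueError):
            fit_mle(make_session([]))


class TestCompareRules:
    def test_one_trial_no_learning_signal(self):
        s = make_session(["C"], nets=[50])
        out = compare_rules(s, n_starts=3, seed=0)
        for rule in ("decay", "delta"):
            assert out[rule].loglik == pytest.approx(np.log(0.25))

    def test_decay_wins_on_decay_data(self, midrange_params):
        wins = 0
        n = 12
        for s in range(n):
            sess = simulate_agent(midrange_params, seed=100 + s)
            out = compare_rules(sess, n_starts=10, seed=s)
            wins += out["decay"].loglik >= out["delta"].loglik
        assert wins > n / 2

    def test_determinism(self, sample_session):
        a = compare_rules(sample_session, n_starts=5, seed=7)
        b = compare_rules(sample_session, n_starts=5, seed=7)
        assert a["decay"].loglik == b["decay"].loglik
        assert a["delta"].params == b["delta"].params

    def test_fits_table_layout(self, sample_session):
        out = compare_rules(sample_session, n_starts=3, seed=0)
        df = fits_table(list(out.values()), subject_ids=["s1", "s1"])
        assert set(df.columns) >= {"subject_id", "alpha", "lam", "A", "c", "rule", "loglik"}


@pytest.fixture(scope="module")
def small_hba_cohort():
    mu = [-0.3, -0.6, 0.0, -0.8]
    sigma = [0.3, 0.3, 0.3, 0.3]
    theta = simulate_hba_cohort_params(mu, sigma, 8, seed=12)
    sessions = []
    for i, (a, l, A, c) in enumerate(theta):
        p = PVLParameters(alpha=a, lam=l, recency_A=min(A, 0.999), consistency_c=c)
        sessions.append(simulate_agent(p, seed=500 + i))
    return sessions


class TestFitHBA:
    def test_summary_contract_and_shrinkage(self, small_hba_cohort):
        summ = fit_hba(
            small_hba_cohort, rule="decay", chains=4, iterations=150, warmup=500, seed=2
        )
        assert set(summ.subject_means.columns) == {"alpha", "lam", "A", "c"}
        assert len(summ.subject_means) == len(small_hba_cohort)
        # posterior means respect the hierarchical bounds
        assert (summ.subject_means["alpha"] < 2).all()
        assert (summ.subject_means["lam"] < 10).all()
        assert ((summ.subject_means > 0).all()).all()
        # partial pooling: posterior means vary less than per-subject MLEs
        mles = [fit_mle(s, n_starts=10, seed=0).params for s in small_hba_cohort]
        mle_c = np.array([p.consistency_c for p in mles])
        assert summ.subject_means["c"].var() <= mle_c.var() + 1e-9
        # diagnostics present and finite
        assert set(summ.rhat) == {
            f"{k}_{p}" for k in ("mu", "sigma") for p in ("alpha", "lam", "A", "c")
        }
        assert all(np.isfinite(v) for v in summ.rhat.values())
        # JSON export round-trips
        import json

        blob = json.loads(summ.to_json())
        assert blob["rule"] == "decay" and len(blob["subject_ids"]) == 8

    def test_too_few_subjects(self, sample_session):
        with pytest.raises(ValueError):
            fit_hba([sample_session], iterations=10, warmup=10)

    def test_determinism(self, small_hba_cohort):
        kw = dict(rule="decay", chains=2, iterations=40, warmup=80, seed=5)
        a = fit_hba(small_hba_cohort[:4], **kw)
        b = fit_hba(small_hba_cohort[:4], **kw)
        assert np.allclose(a.subject_means.values, b.subject_means.values)
        assert a.group_location_mean == b.group_location_mean
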