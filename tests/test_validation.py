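"""Follow-up assembly, Kaplan-Meier, Cox fitting and concordance."""

import numpy as np
import pandas as pd
import pytest

from funsi.validation import (
    assemble_followup,
    c_index,
    fit_cox,
    km_cumulative_incidence,
)


def person_frame(**cols) -> pd.DataFrame:
    """Persons table with latent times defaulting to 'never'."""
    n = len(next(iter(cols.values())))
    base = {
        "person_id": np.arange(n),
        "t_event": np.full(n, np.inf),
        "t_competing": np.full(n, np.inf),
        "t_death_loss": np.full(n, np.inf),
        "t_cataract": np.full(n, np.inf),
    }
    base.update(cols)
    return pd.DataFrame(base)


class TestAssembleFollowup:
    def test_event_before_admin_end(self):
        df = person_frame(t_event=[5.0])
        fu = assemble_followup(df, "rd", admin_horizon=13.0)
        assert fu.loc[0, "time"] == 5.0 and fu.loc[0, "status"] == 1

    def test_competing_event_censors(self):
        df = person_frame(t_event=[5.0], t_competing=[3.0])
        fu = assemble_followup(df, "rd")
        assert fu.loc[0, "time"] == 3.0 and fu.loc[0, "status"] == 0

    def test_cataract_censors_rd_but_not_poag(self):
        df = person_frame(t_event=[5.0], t_cataract=[2.0])
        rd = assemble_followup(df, "rd")
        poag = assemble_followup(df, "poag")
        assert rd.loc[0, "time"] == 2.0 and rd.loc[0, "status"] == 0
        assert poag.loc[0, "time"] == 5.0 and poag.loc[0, "status"] == 1

    def test_unknown_analysis(self):
        with pytest.raises(ValueError):
            assemble_followup(person_frame(t_event=[1.0]), "amd")

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError, match="onpositive"):
            assemble_followup(person_frame(t_event=[0.0]))


def brute_force_km(times, events, at):
    """Product-limit estimator by direct evaluation of the formula."""
    surv = 1.0
    for t in sorted(set(times[events == 1])):
        if t > at:
            break
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        surv *= 1 - d / at_risk
    return surv


class TestKaplanMeier:
    def test_hand_worked_four_person_example(self):
        df = pd.DataFrame(
            {"time": [1.0, 2.0, 3.0, 4.0], "status": [1, 1, 0, 0]}
        )
        km = km_cumulative_incidence(df, np.ones(4, dtype=int))
        # survival 0.75 after year 1, 0.50 after year 2
        as_dict = dict(zip(km["time"], km["cum_incidence_pct"]))
        assert as_dict[1.0] == pytest.approx(25.0)
        assert as_dict[2.0] == pytest.approx(50.0)
        assert np.all(np.diff(km["cum_incidence_pct"]) >= 0)

    def test_no_events_gives_flat_zero(self):
        df = pd.DataFrame({"time": [1.0, 2.0, 3.0], "status": [0, 0, 0]})
        km = km_cumulative_incidence(df, np.ones(3, dtype=int))
        assert (km["cum_incidence_pct"] == 0).all()

    def test_all_events_reduce_to_ecdf(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(5, 40)
        df = pd.DataFrame({"time": t, "status": 1})
        km = km_cumulative_incidence(df, np.ones(40, dtype=int))
        for time, ci in zip(km["time"], km["cum_incidence_pct"]):
            if time > 0:
                assert ci == pytest.approx(np.mean(t <= time) * 100, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_product_limit_on_random_toys(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 11)
        times = rng.integers(1, 6, n).astype(float)
        events = rng.integers(0, 2, n)
        df = pd.DataFrame({"time": times, "status": events})
        km = km_cumulative_incidence(df, np.ones(n, dtype=int))
        for t_q in np.unique(times):
            row = km[km["time"] == t_q]
            if row.empty:
                continue
            expected = (1 - brute_force_km(times, events, t_q)) * 100
            assert row["cum_incidence_pct"].iloc[0] == pytest.approx(expected)

def simulate_two_group_exponential(n, hr, seed, horizon=10.0):
    """Exponential PH data: binary covariate with true hazard ratio."""
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, n)
    rate = 0.05 * hr**x
    t = rng.exponential(1 / rate)
    time = np.minimum(t, horizon)
    status = (t <= horizon).astype(int)
    return pd.DataFrame({"time": time, "status": status, "x": x})


class TestCox:
    def test_recovers_true_hazard_ratio(self):
        df = simulate_two_group_exponential(2000, hr=2.0, seed=1)
        fit = fit_cox(df, ("x",), funsi_col=None)
        hr = fit.hazard_ratios["x"]
        assert fit.ci95.loc["x", "lower"] <= 2.0 <= fit.ci95.loc["x", "upper"]
        assert 1.8 <= hr <= 2.2

    def test_null_covariate_near_unity(self):
        df = simulate_two_group_exponential(5000, hr=1.0, seed=2)
        fit = fit_cox(df, ("x",), funsi_col=None)
        assert 0.9 <= fit.hazard_ratios["x"] <= 1.1

    def test_spurious_quadratic_not_significant(self):
        """On data with a purely linear log-hazard in z, the added
        quadratic term should be rejected at alpha=0.05 in >= 90% of
        replicates (type-I error control)."""
        hits = 0
        reps = 60
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            n = 800
            z = rng.normal(size=n)
            t = rng.exponential(1 / (0.05 * np.exp(0.4 * z)))
            df = pd.DataFrame(
                {
                    "time": np.minimum(t, 15.0),
                    "status": (t <= 15.0).astype(int),
                    "funsi_z": z,
                }
            )
            fit = fit_cox(df, (), funsi_col="funsi_z", funsi_poly_degree=2)
            if fit.p_values["funsi_z_sq"] >= 0.05:
                hits += 1
        assert hits >= 0.9 * reps

    def test_zero_events_is_fit_error(self):
        df = pd.DataFrame(
            {"time": [1.0, 2.0], "status": [0, 0], "x": [0.0, 1.0]}
        )
        with pytest.raises(ValueError):
            fit_cox(df, ("x",), funsi_col=None)

    def test_constant_covariate_named(self):
        df = simulate_two_group_exponential(200, hr=1.0, seed=3)
        df["flat"] = 1.0
        with pytest.raises(ValueError, match="flat"):
            fit_cox(df, ("x", "flat"), funsi_col=None)


class TestConcordance:
    def test_perfect_ranking_gives_one(self):
        times = np.array([5.0, 3.0, 8.0, 1.0])
        risk = -times  # shorter survival = higher risk
        assert c_index(times, risk, np.ones(4)) == 1.0

    def test_random_score_near_half(self):
        rng = np.random.default_rng(4)
        times = rng.exponential(5, 4000)
        risk = rng.normal(size=4000)
        assert 0.48 <= c_index(times, risk, np.ones(4000)) <= 0.52

    def test_matches_brute_force_pair_enumeration(self):
        rng = np.random.default_rng(5)
        times = rng.exponential(5, 30)
        events = rng.integers(0, 2, 30)
        risk = rng.normal(size=30)
        conc = ties = usable = 0
        for i in range(30):
            for j in range(30):
                if times[i] < times[j] and events[i] == 1:
                    usable += 1
                    if risk[i] > risk[j]:
                        conc += 1
                    elif risk[i] == risk[j]:
                        ties += 1
        expected = (conc + 0.5 * ties) / usable
        assert c_index(times, risk, events) == pytest.approx(expected)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            c_index(np.array([]), np.array([]), np.array([]))
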