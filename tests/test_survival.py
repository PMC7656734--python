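"""Cox fitting, prognostic index, concordance, Kaplan-Meier, log-rank and the
minimum-P cutoff scan, each checked against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import mireqtl as m
from mireqtl.survival import (
    CoxModel,
    concordance_index,
    cox_fit,
    km_curve,
    logrank_test,
    optimal_cutoff,
    prognostic_index,
)


def cohort_frame(time, event, **features):
    n = len(time)
    frame = pd.DataFrame({"time": time, "event": event},
                         index=[f"S{i:03d}" for i in range(n)])
    for k, v in features.items():
        frame[k] = v
    return frame


# ---------------------------------------------------------------------------
# brute-force oracles


def c_index_oracle(scores, time, event):
    num = den = 0.0
    n = len(scores)
    for i in range(n):
        for j in range(n):
            if i == j or event[i] != 1:
                continue
            if time[i] < time[j] or (time[i] == time[j] and event[j] == 0):
                den += 1
                if scores[i] > scores[j]:
                    num += 1
                elif scores[i] == scores[j]:
                    num += 0.5
    return num / den if den else None


def km_oracle(time, event):
    times = sorted({t for t, e in zip(time, event) if e == 1})
    surv, s = [], 1.0
    for t in times:
        at_risk = sum(ti >= t for ti in time)
        d = sum(ti == t and ei == 1 for ti, ei in zip(time, event))
        s *= 1 - d / at_risk
        surv.append(s)
    return np.array(times), np.array(surv)


def logrank_oracle(time, event, groups):
    levels = sorted(set(groups))
    o = e = v = 0.0
    for t in sorted({ti for ti, ei in zip(time, event) if ei == 1}):
        n_t = sum(ti >= t for ti in time)
        d_t = sum(ti == t and ei == 1 for ti, ei in zip(time, event))
        n1 = sum(ti >= t and g == levels[1] for ti, g in zip(time, groups))
        d1 = sum(ti == t and ei == 1 and g == levels[1]
                 for ti, ei, g in zip(time, event, groups))
        o += d1
        e += d_t * n1 / n_t
        if n_t > 1:
            v += d_t * (n1 / n_t) * (1 - n1 / n_t) * (n_t - d_t) / (n_t - 1)
    from scipy import stats

    chi2 = (o - e) ** 2 / v if v > 0 else 0.0
    return chi2, stats.chi2.sf(chi2, 1) if v > 0 else 1.0


def cutoff_oracle(scores, time, event, frac=0.1):
    distinct = np.unique(scores)
    best = None
    n = len(scores)
    for c in (distinct[:-1] + distinct[1:]) / 2:
        high = scores > c
        if high.sum() < frac * n or (n - high.sum()) < frac * n:
            continue
        _, p = logrank_oracle(time, event, np.where(high, "hi", "lo"))
        if best is None or p < best[1]:
            best = (c, p)
    return best


def random_instance(rng, n=8):
    time = rng.integers(1, 12, n).astype(float)
    event = rng.integers(0, 2, n)
    if event.sum() == 0:
        event[rng.integers(n)] = 1
    scores = np.round(rng.normal(size=n), 1)
    return scores, time, event


# ---------------------------------------------------------------------------
# Cox model


def test_cox_recovers_binary_hazard_ratio():
    rng = np.random.default_rng(0)
    n = 1000
    x = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(1.0 / (0.01 * np.exp(np.log(2.0) * x)))
    cohort = cohort_frame(t, np.ones(n, dtype=int))
    model = cox_fit(pd.DataFrame({"x": x}, index=cohort.index), cohort)
    assert model.converged
    assert abs(model.params["x"] - np.log(2.0)) < 3 * model.standard_errors["x"]


def test_cox_null_covariate_near_zero():
    rng = np.random.default_rng(1)
    n = 1000
    x = rng.normal(size=n)
    t = rng.exponential(100.0, n)
    cohort = cohort_frame(t, np.ones(n, dtype=int))
    model = cox_fit(pd.DataFrame({"x": x}, index=cohort.index), cohort)
    assert abs(model.params["x"]) < 3 * model.standard_errors["x"]


def test_cox_toy_matches_partial_likelihood_maximum():
    # tie-free 8-sample toy: the fit equals an independent numeric
    # maximization of the literal partial likelihood
    time = np.array([3.0, 5.0, 7.0, 2.0, 11.0, 13.0, 4.0, 9.0])
    event = np.array([1, 1, 0, 1, 1, 0, 1, 1])
    x = np.array([0.5, -1.0, 0.3, 2.0, -0.7, 1.1, 0.0, -1.5])

    def neg_pl(beta):
        ll = 0.0
        for i in range(8):
            if event[i]:
                risk = time >= time[i]
                ll += x[i] * beta - np.log(np.sum(np.exp(x[risk] * beta)))
        return -ll

    opt = optimize.minimize_scalar(neg_pl, bounds=(-5, 5), method="bounded",
                                   options={"xatol": 1e-10})
    cohort = cohort_frame(time, event)
    model = cox_fit(pd.DataFrame({"x": x}, index=cohort.index), cohort)
    assert model.params["x"] == pytest.approx(opt.x, abs=1e-6)
    assert model.log_likelihood == pytest.approx(-neg_pl(model.params["x"]), abs=1e-8)


def test_cox_error_contracts():
    time = np.arange(1.0, 9.0)
    cohort = cohort_frame(time, np.r_[1, np.zeros(7, dtype=int)])
    X = pd.DataFrame({"x": np.arange(8.0)}, index=cohort.index)
    with pytest.raises(m.DegenerateModelError):  # a single event
        cox_fit(X, cohort)
    cohort2 = cohort_frame(time, np.ones(8, dtype=int))
    with pytest.raises(m.InputError, match="constant"):
        cox_fit(X.assign(c=1.0), cohort2)
    with pytest.raises(m.InputError, match="collinear"):
        cox_fit(X.assign(x2=2 * X["x"]), cohort2)


def test_cox_score_test_equals_logrank_for_binary_covariate():
    # classic identity: the Cox score statistic at beta = 0 for a binary
    # covariate equals the log-rank chi-square (tie-free data)
    rng = np.random.default_rng(2)
    time = rng.permutation(np.arange(1.0, 13.0))
    event = np.ones(12, dtype=int)
    x = rng.integers(0, 2, 12).astype(float)

    u = info = 0.0
    for i in range(12):
        if event[i]:
            risk = time >= time[i]
            xr = x[risk]
            u += x[i] - xr.mean()
            info += xr.var()
    score_stat = u**2 / info
    lr = logrank_test(time, event, np.where(x == 1, "a", "b"))
    assert score_stat == pytest.approx(lr.statistic, abs=1e-8)


def test_prognostic_index_is_exact_linear_combination():
    model = CoxModel(
        params=pd.Series({"age": 0.077, "sex": 0.530, "apoe4": 0.602}),
        standard_errors=pd.Series({"age": 0.1, "sex": 0.1, "apoe4": 0.1}),
        log_likelihood=0.0,
        converged=True,
    )
    feats = pd.DataFrame({"age": [1.0, 0.0], "sex": [1.0, 0.0],
                          "apoe4": [1.0, 0.0]}, index=["a", "b"])
    pi = prognostic_index(model, feats)
    assert pi["a"] == pytest.approx(1.209)
    assert pi["b"] == 0.0

    rng = np.random.default_rng(3)
    feats_r = pd.DataFrame(rng.normal(size=(20, 3)),
                           columns=["age", "sex", "apoe4"])
    pi_r = prognostic_index(model, feats_r)
    oracle = feats_r.to_numpy() @ model.params.to_numpy()
    assert np.allclose(pi_r.to_numpy(), oracle, atol=1e-12)

    with pytest.raises(m.InputError):
        prognostic_index(model, feats_r.drop(columns="sex"))


# ---------------------------------------------------------------------------
# concordance


def test_concordance_examples():
    assert concordance_index([3, 2, 1], [10, 20, 30], [1, 1, 1]) == 1.0
    assert concordance_index([1, 1, 1], [10, 20, 30], [1, 1, 1]) == 0.5
    with pytest.raises(m.InputError):
        concordance_index([1, 2], [5, 5], [0, 0])


def test_concordance_matches_bruteforce_and_sksurv():
    from sksurv.metrics import concordance_index_censored

    rng = np.random.default_rng(4)
    for _ in range(40):
        scores, time, event = random_instance(rng)
        expected = c_index_oracle(scores, time, event)
        if expected is None:
            continue
        assert concordance_index(scores, time, event) == pytest.approx(expected)
    # tie-free cross-check against an established implementation
    scores = rng.normal(size=30)
    time = rng.permutation(np.arange(1.0, 31.0))
    event = rng.integers(0, 2, 30).astype(bool)
    event[:2] = True
    ours = concordance_index(scores, time, event.astype(int))
    theirs = concordance_index_censored(event, time, scores)[0]
    assert ours == pytest.approx(theirs)


def test_concordance_complement_symmetry():
    rng = np.random.default_rng(5)
    scores = rng.normal(size=25)  # tie-free
    time = rng.permutation(np.arange(1.0, 26.0))
    event = rng.integers(0, 2, 25)
    event[0] = 1
    c1 = concordance_index(scores, time, event)
    c2 = concordance_index(-scores, time, event)
    assert c1 + c2 == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Kaplan-Meier


def test_km_examples_and_oracle():
    curve = km_curve([1, 2, 3, 4], [1, 1, 1, 1])
    assert np.allclose(curve.survival, [0.75, 0.5, 0.25, 0.0])

    all_censored = km_curve([1, 2, 3], [0, 0, 0])
    assert all_censored.times.size == 0  # S identically 1

    mixed = km_curve([2, 3, 4, 5], [1, 0, 1, 0])
    assert np.allclose(mixed.survival, [0.75, 0.375])

    rng = np.random.default_rng(6)
    for _ in range(30):
        _, time, event = random_instance(rng)
        curve = km_curve(time, event)
        o_times, o_surv = km_oracle(time, event)
        assert np.allclose(curve.times, o_times)
        assert np.allclose(curve.survival, o_surv)


def test_km_censored_at_event_time_counts_at_risk():
    curve = km_curve([5, 5, 10], [1, 0, 1])
    assert curve.at_risk[0] == 3


# ---------------------------------------------------------------------------
# log-rank


def test_logrank_identical_groups_and_symmetry():
    time = [1, 2, 3, 4, 1, 2, 3, 4]
    event = [1, 0, 1, 1, 1, 0, 1, 1]
    groups = ["a"] * 4 + ["b"] * 4
    res = logrank_test(time, event, groups)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)

    rng = np.random.default_rng(7)
    _, t, e = random_instance(rng, n=10)
    g = np.array(["a"] * 5 + ["b"] * 5)
    r1 = logrank_test(t, e, g)
    r2 = logrank_test(t, e, np.where(g == "a", "b", "a"))
    assert r1.statistic == pytest.approx(r2.statistic)


def test_logrank_matches_oracle_and_lifelines():
    from lifelines.statistics import logrank_test as ll_logrank

    rng = np.random.default_rng(8)
    for _ in range(40):
        _, time, event = random_instance(rng, n=10)
        groups = rng.permutation(["a"] * 5 + ["b"] * 5)
        ours = logrank_test(time, event, groups)
        chi2, p = logrank_oracle(list(time), list(event), list(groups))
        assert ours.statistic == pytest.approx(chi2, abs=1e-10)
        assert ours.p == pytest.approx(p, abs=1e-10)
    # cross-check one instance against lifelines
    time = np.array([3, 5, 7, 2, 11, 13, 4, 9, 6, 8], dtype=float)
    event = np.array([1, 1, 0, 1, 1, 0, 1, 1, 1, 0])
    groups = np.array(["a"] * 5 + ["b"] * 5)
    ours = logrank_test(time, event, groups)
    ref = ll_logrank(time[groups == "a"], time[groups == "b"],
                     event[groups == "a"], event[groups == "b"])
    assert ours.statistic == pytest.approx(ref.test_statistic, abs=1e-8)
    assert ours.p == pytest.approx(ref.p_value, abs=1e-8)


def test_logrank_requires_two_groups():
    with pytest.raises(m.InputError):
        logrank_test([1, 2, 3], [1, 1, 0], ["a", "a", "a"])


# ---------------------------------------------------------------------------
# optimal cutoff


def test_cutoff_falls_in_gap_between_risk_modes():
    rng = np.random.default_rng(9)
    n = 60
    scores = np.r_[rng.normal(0, 0.3, 30), rng.normal(5, 0.3, 30)]
    time = np.r_[rng.uniform(500, 1000, 30), rng.uniform(10, 100, 30)]
    event = np.r_[np.zeros(30, dtype=int), np.ones(30, dtype=int)]
    cutoff, min_p = optimal_cutoff(scores, time, event)
    assert 1.5 < cutoff < 3.5
    # self-consistency: the returned P equals the test at the returned cutoff
    groups = np.where(scores > cutoff, "hi", "lo")
    assert min_p == pytest.approx(logrank_test(time, event, groups).p)


def test_cutoff_matches_exhaustive_oracle():
    rng = np.random.default_rng(10)
    for _ in range(25):
        scores, time, event = random_instance(rng, n=10)
        if np.unique(scores).size < 2:
            continue
        cutoff, min_p = optimal_cutoff(scores, time, event, min_group_frac=0.1)
        o_cut, o_p = cutoff_oracle(scores, time, event, 0.1)
        # distinct cutoffs can achieve the same minimum to float precision;
        # the achieved minimum P must agree
        assert min_p == pytest.approx(o_p, abs=1e-9)
        if abs(min_p - o_p) > 1e-14:
            assert cutoff == pytest.approx(o_cut)


def test_cutoff_degenerate_inputs_rejected():
    with pytest.raises(m.InputError):
        optimal_cutoff([1.0] * 5, [1, 2, 3, 4, 5], [1, 1, 1, 0, 0])
    with pytest.raises(m.InputError):  # no admissible candidate at frac 0.5
        optimal_cutoff([1, 2, 2, 2, 2, 2, 2, 2], np.arange(1, 9),
                       np.ones(8, dtype=int), min_group_frac=0.5)
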