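"""Deviation statistics, acceptability flags and DP4 ranking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from shiftsieve import (
    CandidateSet,
    DP4Params,
    acceptability_flags,
    build_report,
    deviations,
    dp4,
    dp4_log_likelihood,
)
from shiftsieve.discrimination import round_half_up

from conftest import make_table


class TestDeviations:
    def test_anhydride_c11_outlier(self, cereoanhydride):
        exp, cands = cereoanhydride
        st_ = deviations(cands["anhydride"], exp, "C")
        assert st_.per_nucleus["C11"] == pytest.approx(9.6)
        assert st_.max_label == "C11"
        assert st_.max == pytest.approx(9.6)

    def test_acid_alpha_proton_outlier(self, cereoanhydride):
        exp, cands = cereoanhydride
        st_ = deviations(cands["acid"], exp, "H")
        assert st_.per_nucleus["H23"] == pytest.approx(0.54)
        assert st_.max_label == "H23"

    def test_identical_tables_give_zero(self):
        t = make_table(["C1", "C2"], exp=[100.0, 50.0], calc=[100.0, 50.0])
        st_ = deviations(t, t, "C")
        assert st_.mad == 0.0 and st_.max == 0.0

    def test_label_mismatch_lists_orphans(self):
        calc = make_table(["C1", "C2"], calc=[1.0, 2.0])
        exp = make_table(["C1", "C3"], exp=[1.0, 2.0])
        with pytest.raises(ValueError, match="C2.*C3|C3.*C2"):
            deviations(calc, exp, "C")

    @settings(deadline=None, max_examples=50)
    @given(
        seed=st.integers(0, 2**16),
        n=st.integers(2, 12),
        c=st.floats(-50, 50),
    )
    def test_mad_translation_invariant_and_worst_removal_identity(self, seed, n, c):
        r = np.random.default_rng(seed)
        e = r.uniform(0, 200, n)
        k = e + r.standard_normal(n)
        labels = [f"C{i + 1}" for i in range(n)]
        st0 = deviations(make_table(labels, calc=list(k)),
                         make_table(labels, exp=list(e)), "C")
        # adding c to both columns leaves every deviation unchanged
        st1 = deviations(make_table(labels, calc=list(k + c)),
                         make_table(labels, exp=list(e + c)), "C")
        assert st1.mad == pytest.approx(st0.mad, abs=1e-9)
        assert st0.mad <= st0.max + 1e-15
        if n > 1:
            # dropping the worst nucleus: MAD' = (mad*n - max)/(n-1), MAX' <= MAX
            keep = [l for l in labels if l != st0.max_label]
            st2 = deviations(
                make_table(keep, calc=[k[labels.index(l)] for l in keep]),
                make_table(keep, exp=[e[labels.index(l)] for l in keep]),
                "C",
            )
            assert st2.mad == pytest.approx(
                (st0.mad * n - st0.max) / (n - 1), abs=1e-9
            )
            assert st2.max <= st0.max + 1e-15


class TestFlags:
    def test_large_carbon_deviation_unacceptable(self, cereoanhydride):
        exp, cands = cereoanhydride
        st_ = deviations(cands["anhydride"], exp, "C")
        flags = acceptability_flags(st_)
        assert flags["C11"] == "unacceptable"
        assert {l for l, f in flags.items() if f == "unacceptable"} == {
            "C11", "C10", "C2", "C13"
        }

    def test_just_under_threshold_is_borderline_acceptable(self, cereoanhydride):
        exp, cands = cereoanhydride
        flags = acceptability_flags(deviations(cands["acid"], exp, "H"))
        assert flags["H27"] == "borderline"  # 0.29 ppm vs the 0.3 ppm rule
        assert flags["H23"] == "unacceptable"  # 0.54 ppm

    def test_threshold_is_strict_less_than(self):
        t_calc = make_table(["C1", "C2", "C3"], calc=[105.0, 104.0, 100.0])
        t_exp = make_table(["C1", "C2", "C3"], exp=[100.0, 100.0, 100.0])
        flags = acceptability_flags(deviations(t_calc, t_exp, "C"))
        assert flags["C1"] == "unacceptable"  # exactly 5.0 is not acceptable
        assert flags["C2"] != "unacceptable"
        assert flags["C3"] == "acceptable"

    def test_rounding_is_half_up(self):
        assert round_half_up(1.35, 1) == 1.4
        assert round_half_up(0.125, 2) == 0.13


def two_candidate_single_nucleus(err_a, err_b, sigma=2.306):
    exp = make_table(["C1"], exp=[100.0])
    cands = CandidateSet(
        {
            "A": make_table(["C1"], calc=[100.0 + err_a], name="A"),
            "B": make_table(["C1"], calc=[100.0 + err_b], name="B"),
        }
    )
    return cands, exp


class TestDP4:
    def test_identical_candidates_split_evenly(self):
        exp = make_table(["C1", "C2", "C3"], exp=[10.0, 50.0, 120.0])
        tab = make_table(["C1", "C2", "C3"], calc=[11.0, 49.0, 122.0])
        cands = CandidateSet({"A": tab, "B": tab})
        res = dp4(cands, exp, mode="C")
        assert res.p_carbon["A"] == pytest.approx(0.5, abs=1e-12)

    def test_single_nucleus_matches_direct_t_formula(self):
        # hand oracle: term = 1 - T_nu(|e|/sigma); A at 0, B at 3 sigma
        sigma, nu = 2.306, 11.38
        cands, exp = two_candidate_single_nucleus(0.0, 3 * sigma)
        res = dp4(cands, exp, DP4Params(), mode="C")
        term_a = 1 - sps.t.cdf(0.0, nu)
        term_b = 1 - sps.t.cdf(3.0, nu)
        expect_a = term_a / (term_a + term_b)
        assert res.p_carbon["A"] == pytest.approx(expect_a, abs=1e-12)
        assert res.p_carbon["A"] > res.p_carbon["B"]

    def test_probabilities_normalize_and_combined_factorizes(self, rng):
        labels_c = [f"C{i + 1}" for i in range(6)]
        labels_h = [f"H{i + 1}" for i in range(4)]
        e_c, e_h = rng.uniform(10, 180, 6), rng.uniform(0.5, 9, 4)
        exp = make_table(labels_c + labels_h, exp=list(e_c) + list(e_h))
        cands = {}
        for name in "ABC":
            c = list(e_c + rng.standard_normal(6)) + list(e_h + 0.2 * rng.standard_normal(4))
            cands[name] = make_table(labels_c + labels_h, calc=c, name=name)
        cs = CandidateSet(cands)
        params = DP4Params()
        res = dp4(cs, exp, params, mode="both")
        for p in (res.p_carbon, res.p_proton, res.p_combined):
            assert sum(p.values()) == pytest.approx(1.0, abs=1e-9)
            assert all(0 <= v <= 1 for v in p.values())
        # combined unnormalized score = product of C and H scores
        for name, tab in cs.items():
            ll_c = dp4_log_likelihood(tab, exp, params, "C")
            ll_h = dp4_log_likelihood(tab, exp, params, "H")
            ratio = np.log(res.p_combined[name]) - np.log(res.p_combined["A"])
            direct = (ll_c + ll_h) - (
                dp4_log_likelihood(cs["A"], exp, params, "C")
                + dp4_log_likelihood(cs["A"], exp, params, "H")
            )
            assert ratio == pytest.approx(direct, abs=1e-9)

    def test_nonuniform_prior_shifts_probabilities(self):
        exp = make_table(["C1", "C2", "C3"], exp=[10.0, 50.0, 120.0])
        tab = make_table(["C1", "C2", "C3"], calc=[11.0, 49.0, 122.0])
        cands = CandidateSet({"A": tab, "B": tab})
        res = dp4(cands, exp, DP4Params(prior={"A": 0.9, "B": 0.1}), mode="C")
        assert res.p_carbon["A"] == pytest.approx(0.9, abs=1e-12)

    def test_missing_nucleus_is_error(self):
        exp = make_table(["C1", "C2"], exp=[10.0, 50.0])
        cands = CandidateSet({"A": make_table(["C1"], calc=[11.0])})
        with pytest.raises(ValueError, match="unmatched"):
            dp4(cands, exp, mode="C")


class TestOnBundledData:
    def test_mad_orderings_match_the_structural_narrative(self, cereoanhydride):
        # carbon MADs favour the acid; proton MADs favour anhydride/carboxylate
        exp, cands = cereoanhydride
        mad_c = {n: deviations(t, exp, "C").mad for n, t in cands.items()}
        mad_h = {n: deviations(t, exp, "H").mad for n, t in cands.items()}
        assert mad_c["acid"] < mad_c["carboxylate"] < mad_c["anhydride"]
        assert mad_h["anhydride"] < mad_h["acid"]
        assert mad_h["carboxylate"] < mad_h["acid"]
        assert mad_h["anhydride"] == pytest.approx(mad_h["carboxylate"], abs=0.02)

    def test_report_verdict_is_carboxylate(self, cereoanhydride):
        exp, cands = cereoanhydride
        rep = build_report(cands, exp)
        assert rep.verdict == "carboxylate"
        assert rep.dp4_result.top("C") == "acid"
        assert len(rep.candidate_names) == 3

    def test_single_candidate_report(self, cereoanhydride):
        exp, cands = cereoanhydride
        solo = CandidateSet({"acid": cands["acid"]})
        rep = build_report(solo, exp)
        assert rep.dp4_result.p_combined["acid"] == pytest.approx(1.0)
        assert rep.verdict == "acid"

    def test_four_candidate_synthetic_report_rowcount(self, rng):
        labels = [f"C{i + 1}" for i in range(5)] + ["H1", "H2", "H3"]
        e = list(rng.uniform(10, 180, 5)) + list(rng.uniform(1, 9, 3))
        exp = make_table(labels, exp=e)
        cands = CandidateSet(
            {
                f"cand{k}": make_table(
                    labels,
                    calc=[v + float(rng.standard_normal() * (2.3 if l[0] == "C" else 0.18))
                          for l, v in zip(labels, e)],
                    name=f"cand{k}",
                )
                for k in range(4)
            }
        )
        rep = build_report(cands, exp)
        assert len(rep.candidate_names) == 4
        assert set(rep.stats) == set(rep.candidate_names)
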