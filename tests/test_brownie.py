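"""Cell probabilities, multinomial log-likelihood, and the candidate set."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from driftfate import (
    EncounterRecord,
    ModelSpec,
    ParameterStructure,
    ParameterVector,
    StudyDesign,
    build_candidate_set,
    build_marray,
    cell_probability,
    log_likelihood,
    never_recovered_probability,
    saturated_minus2logl,
)
from driftfate.brownie import get_cell_model

CONST = ModelSpec(
    "S(.) f(.)", ParameterStructure.constant(), ParameterStructure.constant()
)
REF = ParameterVector.constant(0.829, 0.0242)
D35 = StudyDesign(n_occasions=35)


class TestCellProbability:
    def test_release_day_beaching_is_f(self):
        # a carcass can beach on its very first day afloat: b_1 = f
        assert cell_probability(CONST, REF, D35, 3, 3) == pytest.approx(0.0242)

    def test_age_three_product(self):
        expected = 0.0242 * 0.829**2  # float two days then beach: f * S * S
        assert cell_probability(CONST, REF, D35, 1, 3) == pytest.approx(
            expected, rel=1e-12
        )
        assert expected == pytest.approx(0.016631, abs=5e-7)

    def test_zero_f_gives_zero_everywhere(self):
        p = ParameterVector.constant(0.9, 0.0)
        assert all(
            cell_probability(CONST, p, D35, 1, j) == 0.0 for j in range(1, 36)
        )

    @pytest.mark.parametrize("i,j", [(5, 4), (1, 36), (0, 3)])
    def test_inadmissible_cells_error(self, i, j):
        with pytest.raises(ValueError):
            cell_probability(CONST, REF, D35, i, j)

    def test_age_structure_indexes_by_age_time_by_day(self):
        age2 = ModelSpec(
            "S(.) f(age-2)",
            ParameterStructure.constant(),
            ParameterStructure.age((1, 2)),
        )
        p = ParameterVector((0.8,), (0.1, 0.02))
        # released day 5, beached day 5 -> age 1 -> first f class
        assert cell_probability(age2, p, D35, 5, 5) == pytest.approx(0.1)
        # beached day 6 -> age 2 -> second class, one survival factor
        assert cell_probability(age2, p, D35, 5, 6) == pytest.approx(0.8 * 0.02)
        timed = ModelSpec(
            "S(.) f(t)", ParameterStructure.constant(), ParameterStructure.time()
        )
        f_t = tuple(0.01 * k for k in range(1, 36))
        pt = ParameterVector((0.8,), f_t)
        # beaching day 6 uses day-6 f regardless of release day
        assert cell_probability(timed, pt, D35, 5, 6) == pytest.approx(0.8 * 0.06)
        assert cell_probability(timed, pt, D35, 6, 6) == pytest.approx(0.06)

    def test_constant_cells_decrease_with_age(self):
        probs = [cell_probability(CONST, REF, D35, 1, j) for j in range(1, 36)]
        assert all(a > b for a, b in zip(probs, probs[1:]))


class TestNeverRecovered:
    def test_zero_f_means_never_recovered(self):
        p = ParameterVector.constant(0.9, 0.0)
        assert never_recovered_probability(CONST, p, D35, 1) == pytest.approx(1.0)

    def test_geometric_closed_form_full_window(self):
        S, f = 0.829, 0.0242
        expected = 1 - f * (1 - S**35) / (1 - S)
        got = never_recovered_probability(CONST, REF, D35, 1)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.8587, abs=5e-4)

    def test_single_day_window(self):
        assert never_recovered_probability(CONST, REF, D35, 35) == pytest.approx(
            1 - 0.0242
        )

    @pytest.mark.parametrize("spec_idx", range(14))
    def test_cells_plus_never_sum_to_one_every_cohort(self, spec_idx):
        spec = build_candidate_set(D35)[spec_idx]
        rng = np.random.default_rng(spec_idx)
        nS = spec.S_structure.n_classes(D35)
        nf = spec.f_structure.n_classes(D35)
        params = ParameterVector(
            tuple(rng.uniform(0.3, 0.9, nS)), tuple(rng.uniform(0.0, 0.1, nf))
        )
        cm = get_cell_model(spec, D35)
        totals = cm.cell_probs_matrix(params).sum(axis=1) + cm.never_probs(params)
        assert np.allclose(totals, 1.0, atol=1e-12)


class TestLogLikelihood:
    def test_single_recovery_on_release_day_is_log_f(self):
        recs = [EncounterRecord("a", 1, 1)]
        ma = build_marray(recs, D35)
        assert log_likelihood(ma, CONST, REF) == pytest.approx(np.log(0.0242))

    def test_matches_individual_record_product(self):
        rng = np.random.default_rng(3)
        design = StudyDesign(n_occasions=8)
        recs = []
        for k in range(10):
            rel = int(rng.integers(1, 4))
            rec = int(rng.integers(rel, 9))
            recs.append(EncounterRecord(f"r{k}", rel, rec if rec <= 8 else None))
        ma = build_marray(recs, design)
        p = ParameterVector.constant(0.7, 0.1)
        brute = 0.0
        for r in recs:
            if r.recovery_day is None:
                brute += np.log(
                    never_recovered_probability(CONST, p, design, r.release_day)
                )
            else:
                brute += np.log(
                    cell_probability(CONST, p, design, r.release_day, r.recovery_day)
                )
        assert log_likelihood(ma, CONST, p) == pytest.approx(brute, abs=1e-10)

    def test_linear_in_counts(self, ref_marray):
        ll = log_likelihood(ref_marray, CONST, REF)
        doubled = build_marray([], ref_marray.design)
        doubled = type(ref_marray)(
            design=ref_marray.design,
            R=2 * ref_marray.R,
            m=2 * ref_marray.m,
            never=2 * ref_marray.never,
        )
        assert log_likelihood(doubled, CONST, REF) == pytest.approx(2 * ll, rel=1e-12)

    def test_zero_probability_cell_warns_minus_inf(self):
        recs = [EncounterRecord("a", 1, 2)]
        ma = build_marray(recs, D35)
        p = ParameterVector.constant(0.0, 0.5)  # cannot survive to day 2
        with pytest.warns(UserWarning, match="zero-probability"):
            assert log_likelihood(ma, CONST, p) == -np.inf

    def test_analytic_gradient_matches_finite_differences(self, ref_marray):
        spec = build_candidate_set(D35)[3]  # S(.) f(age-3)
        cm = get_cell_model(spec, D35)
        rng = np.random.default_rng(0)
        # stay where S + f < 1 (outside, the clipped penalty is non-smooth)
        eta = np.concatenate([
            rng.normal(1.0, 0.8, cm.n_S), rng.normal(-3.0, 0.8, cm.n_f)
        ])
        _, grad = cm.negloglik_and_grad(eta, ref_marray)
        num = np.empty_like(eta)
        for k in range(eta.size):
            e = np.zeros_like(eta)
            e[k] = 1e-6
            fp = cm.negloglik_and_grad(eta + e, ref_marray)[0]
            fm = cm.negloglik_and_grad(eta - e, ref_marray)[0]
            num[k] = (fp - fm) / 2e-6
        assert np.allclose(grad, num, rtol=1e-5, atol=1e-7)


class TestSaturated:
    def test_all_never_recovered_contributes_zero(self):
        recs = [EncounterRecord(f"r{k}", 1, None) for k in range(5)]
        assert saturated_minus2logl(build_marray(recs, D35)) == 0.0

    def test_toy_hand_computation(self):
        # R=4: one recovered day 1, one day 2, two never
        recs = [
            EncounterRecord("a", 1, 1),
            EncounterRecord("b", 1, 2),
            EncounterRecord("c", 1, None),
            EncounterRecord("d", 1, None),
        ]
        val = saturated_minus2logl(build_marray(recs, D35))
        assert val == pytest.approx(8.3178, abs=5e-5)

    def test_saturated_deviance_of_itself_is_zero(self, ref_marray):
        # the empirical proportions maximize the multinomial likelihood,
        # so -2logL at them equals the saturated value by construction
        assert saturated_minus2logl(ref_marray) >= 0.0


class TestCandidateSet:
    def test_fourteen_unique_names(self):
        specs = build_candidate_set(D35)
        names = [m.name for m in specs]
        assert len(specs) == 14 and len(set(names)) == 14

    @pytest.mark.parametrize(
        "name, nominal",
        [
            ("S(.) f(.)", 2),
            ('S(.) f(age-4 w/1st "age" = 2 days)', 5),
            ("S(.) f(age-2)", 3),
            ("S(.) f(age-5)", 6),
            ("S(age-3) f(.)", 4),
            ("S(age) f(age)", 70),
            ("S(t) f(t)", 70),
            ("S(.) f(t)", 36),
        ],
    )
    def test_nominal_parameter_counts(self, name, nominal):
        spec = {m.name: m for m in build_candidate_set(D35)}[name]
        assert spec.n_nominal(D35) == nominal

    def test_json_roundtrip(self):
        for spec in build_candidate_set(D35):
            assert ModelSpec.from_json(spec.to_json()) == spec


@given(st.integers(1, 35), st.integers(0, 34))
@settings(max_examples=60, derandomize=True, deadline=None)
def test_cell_probability_matches_vectorized_model(i, extra):
    """The scalar per-cell product equals the precomputed vectorized cells."""
    j = min(i + extra, 35)
    spec = build_candidate_set(D35)[5]
    p = ParameterVector((0.8,), (0.05, 0.03, 0.02, 0.01))
    cm = get_cell_model(spec, D35)
    assert cm.cell_probs_matrix(p)[i - 1, j - 1] == pytest.approx(
        cell_probability(spec, p, D35, i, j), rel=1e-12
    )
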