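import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hpoxbs.conversion import EmissionParameters, IDEAL_BS, IDEAL_OXBS
from hpoxbs.model import (
    CountData,
    DivisionSchedule,
    EnzymeEfficiencies,
    READ_CLASSES,
    STATES,
    STATE_PAIRS,
    division_step,
    emission_matrix,
    fit,
    hydroxylation_summary,
    log_likelihood,
    naive_5hmc,
    observed_counts_from_patterns,
    strand_levels,
    transition_matrix,
)
from hpoxbs.simulate import SimulationConfig, simulate_counts
from hpoxbs import presets

# ---------------------------------------------------------------------------
# Independent oracles: exhaustive enumeration of every per-strand event
# outcome within one division, and path enumeration for multi-step chains.
# ---------------------------------------------------------------------------


def oracle_transition(mu, delta, eta):
    """One-division transition matrix by brute-force event enumeration."""
    T = np.zeros((9, 9))
    for i, (top, bottom) in enumerate(STATE_PAIRS):
        for retained, p_r in (("top", 0.5), ("bottom", 0.5)):
            template = top if retained == "top" else bottom
            # enumerate: maintenance on new strand; de novo on each u strand;
            # hydroxylation on each m strand -- all Bernoulli, in that order
            for maint, dn_new, dn_old, hx_new, hx_old in itertools.product(
                (0, 1), repeat=5
            ):
                p = p_r
                new = "u"
                old = template
                # maintenance only against an m template
                if template == "m":
                    p *= mu if maint else 1 - mu
                    if maint:
                        new = "m"
                elif maint:
                    continue  # impossible event
                # de novo acts on strands still u
                if new == "u":
                    p *= delta if dn_new else 1 - delta
                    if dn_new:
                        new = "m"
                elif dn_new:
                    continue
                if old == "u":
                    p *= delta if dn_old else 1 - delta
                    if dn_old:
                        old = "m"
                elif dn_old:
                    continue
                # hydroxylation acts on strands that are m after methylation
                if new == "m":
                    p *= eta if hx_new else 1 - eta
                    if hx_new:
                        new = "h"
                elif hx_new:
                    continue
                if old == "m":
                    p *= eta if hx_old else 1 - eta
                    if hx_old:
                        old = "h"
                elif hx_old:
                    continue
                final = (old, new) if retained == "top" else (new, old)
                T[i, STATE_PAIRS.index(final)] += p
    return T


def oracle_emission(params):
    """9x4 emission matrix by enumerating the four read outcomes."""
    E = np.zeros((9, 4))
    for i, pair in enumerate(STATE_PAIRS):
        for j, cls in enumerate(READ_CLASSES):
            p = 1.0
            for strand_base, read_base in zip(pair, cls):
                p_t = params.p_t(strand_base)
                p *= p_t if read_base == "T" else 1 - p_t
            E[i, j] = p
    return E


def oracle_distribution_by_paths(init, T, k):
    """Distribution after k divisions by explicit path enumeration."""
    out = np.zeros(9)
    for path in itertools.product(range(9), repeat=k + 1):
        p = init[path[0]]
        for a, b in zip(path, path[1:]):
            p *= T[a, b]
        out[path[-1]] += p
    return out


def _delta_dist(state):
    d = np.zeros(9)
    d[STATES.index(state)] = 1.0
    return d


class TestTransition:
    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
    @settings(deadline=None, max_examples=60)
    def test_rows_stochastic(self, mu, delta, eta):
        T = transition_matrix(EnzymeEfficiencies(mu, delta, eta))
        assert np.all(T >= -1e-12)
        np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-9)

    @pytest.mark.parametrize(
        "mu,delta,eta",
        [
            (0.8, 0.1, 0.05),
            (0.0, 0.0, 0.0),
            (1.0, 0.0, 0.0),
            (0.5, 0.5, 0.5),
            (1.0, 1.0, 1.0),
            (0.3, 0.0, 0.9),
        ],
    )
    def test_matches_bruteforce_enumeration(self, mu, delta, eta):
        T = transition_matrix(EnzymeEfficiencies(mu, delta, eta))
        np.testing.assert_allclose(T, oracle_transition(mu, delta, eta), atol=1e-12)

    def test_perfect_maintenance_fixes_mm(self):
        out = division_step(_delta_dist("mm"), EnzymeEfficiencies(1, 0, 0))
        np.testing.assert_allclose(out, _delta_dist("mm"), atol=1e-12)

    def test_passive_dilution_one_step(self):
        out = division_step(_delta_dist("mm"), EnzymeEfficiencies(0, 0, 0))
        expected = 0.5 * _delta_dist("um") + 0.5 * _delta_dist("mu")
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_passive_dilution_halves_methylated_strands(self):
        """Without maintenance the methylated-strand fraction is 2^-k."""
        eff = EnzymeEfficiencies(0, 0, 0)
        d = _delta_dist("mm")
        for k in range(1, 6):
            d = division_step(d, eff)
            assert strand_levels(d)["5mC"] == pytest.approx(2.0 ** -k, abs=1e-12)

    def test_multi_division_matches_path_enumeration(self):
        eff = EnzymeEfficiencies(0.7, 0.15, 0.1)
        T = oracle_transition(*eff.as_array())
        init = np.full(9, 1 / 9)
        d = init.copy()
        for k in (1, 2, 3):
            d = division_step(d, eff)
            np.testing.assert_allclose(
                d, oracle_distribution_by_paths(init, T, k), atol=1e-12
            )

    def test_maintenance_only_preserves_m_content(self, rng):
        eff = EnzymeEfficiencies(1, 0, 0)
        for _ in range(5):
            d = rng.dirichlet(np.ones(9))
            before = strand_levels(d)["5mC"]
            after = strand_levels(division_step(d, eff))["5mC"]
            assert after == pytest.approx(before, abs=1e-12)

    def test_full_de_novo_then_hydroxylation_saturates(self):
        # full de novo drives any h-free population to mm in one division
        # (h is terminal, so h-containing states can never return to m)
        d = np.zeros(9)
        d[[0, 1, 2, 3]] = 0.25  # uniform over uu, um, mu, mm
        d = division_step(d, EnzymeEfficiencies(0, 1, 0))
        np.testing.assert_allclose(d, _delta_dist("mm"), atol=1e-12)
        d2 = division_step(division_step(np.full(9, 1 / 9), EnzymeEfficiencies(0, 1, 1)),
                           EnzymeEfficiencies(0, 1, 1))
        np.testing.assert_allclose(d2, _delta_dist("hh"), atol=1e-12)


class TestEmission:
    def test_hemimethylated_ideal_bs_reads_ct(self):
        E = emission_matrix(IDEAL_BS)
        row = E[STATES.index("mu")]
        np.testing.assert_allclose(row, [0, 1, 0, 0], atol=1e-12)  # top C, bottom T

    def test_hydroxylated_ideal_oxbs_reads_tt(self):
        E = emission_matrix(IDEAL_OXBS)
        row = E[STATES.index("hu")]
        np.testing.assert_allclose(row, [0, 0, 0, 1], atol=1e-12)

    def test_bs_sees_h_as_modified(self):
        E = emission_matrix(IDEAL_BS)
        row = E[STATES.index("hh")]
        np.testing.assert_allclose(row, [1, 0, 0, 0], atol=1e-12)

    def test_measured_parameters_match_enumeration(self, afp_emissions):
        for params in afp_emissions.values():
            np.testing.assert_allclose(
                emission_matrix(params), oracle_emission(params), atol=1e-12
            )

    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
    @settings(deadline=None, max_examples=40)
    def test_rows_stochastic(self, a, b, c):
        E = emission_matrix(EmissionParameters(a, b, c))
        np.testing.assert_allclose(E.sum(axis=1), 1.0, atol=1e-9)

    def test_treatments_agree_on_h_free_states(self, afp_emissions):
        """With equal C/5mC parameters the channels differ only where h sits."""
        bs = EmissionParameters(0.99, 0.07, 0.08)
        ox = EmissionParameters(0.99, 0.07, 0.92)
        Eb, Eo = emission_matrix(bs), emission_matrix(ox)
        for i, (a, b) in enumerate(STATE_PAIRS):
            if "h" not in (a, b):
                np.testing.assert_allclose(Eb[i], Eo[i], atol=1e-12)
            else:
                assert not np.allclose(Eb[i], Eo[i])


class TestLikelihood:
    def _schedule(self):
        return DivisionSchedule(days=(0, 1), divisions=(0, 2))

    def test_certain_observation_gives_zero(self):
        counts = CountData(counts={"BS": np.array([[50, 0, 0, 0]])})
        sched = DivisionSchedule(days=(0,), divisions=(0,))
        ll = log_likelihood(
            np.empty((0, 3)), _delta_dist("mm"), sched, {"BS": IDEAL_BS}, counts
        )
        assert ll == 0.0

    def test_treatment_additivity(self, afp_emissions, rng):
        sched = self._schedule()
        eff = np.array([[0.8, 0.1, 0.05]])
        init = rng.dirichlet(np.ones(9))
        cb = rng.integers(0, 50, size=(2, 4))
        co = rng.integers(0, 50, size=(2, 4))
        joint = log_likelihood(
            eff, init, sched, afp_emissions, CountData(counts={"BS": cb, "oxBS": co})
        )
        sep = log_likelihood(
            eff, init, sched, afp_emissions, CountData(counts={"BS": cb})
        ) + log_likelihood(
            eff, init, sched, afp_emissions, CountData(counts={"oxBS": co})
        )
        assert joint == pytest.approx(sep, rel=1e-12)

    def test_matches_path_enumeration_oracle(self, afp_emissions):
        """Small instance: likelihood from explicit hidden-path enumeration."""
        sched = self._schedule()
        eff = EnzymeEfficiencies(0.6, 0.2, 0.1)
        init = np.array([0.1, 0.05, 0.05, 0.5, 0.05, 0.05, 0.05, 0.05, 0.1])
        counts = CountData(
            counts={"BS": np.array([[5, 3, 2, 10], [2, 2, 2, 14]]),
                    "oxBS": np.array([[4, 2, 3, 11], [1, 1, 1, 17]])}
        )
        T = oracle_transition(*eff.as_array())
        dists = [init, oracle_distribution_by_paths(init, T, 2)]
        expected = 0.0
        for tr, arr in counts.counts.items():
            E = oracle_emission(afp_emissions[tr])
            for t in range(2):
                probs = dists[t] @ E
                expected += float(np.sum(arr[t] * np.log(probs)))
        got = log_likelihood(eff, init, sched, afp_emissions, counts)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_impossible_observation_gives_minus_inf(self):
        counts = CountData(counts={"BS": np.array([[0, 0, 0, 5]])})
        sched = DivisionSchedule(days=(0,), divisions=(0,))
        ll = log_likelihood(
            np.empty((0, 3)), _delta_dist("mm"), sched, {"BS": IDEAL_BS}, counts
        )
        assert ll == float("-inf")

    def test_distributions_stay_on_simplex(self, rng):
        eff = EnzymeEfficiencies(0.9, 0.2, 0.3)
        d = rng.dirichlet(np.ones(9))
        for _ in range(20):
            d = division_step(d, eff)
            assert np.all(d >= -1e-12)
            assert d.sum() == pytest.approx(1.0, abs=1e-9)


class TestFit:
    def test_recovers_simulated_efficiencies(self, afp_emissions, esc_schedule):
        truth = EnzymeEfficiencies(0.8, 0.1, 0.05)
        cfg = SimulationConfig(
            reference=presets.demo_reference(),
            efficiencies=truth,
            initial_distribution=presets.DEFAULT_INIT_DISTRIBUTION,
            schedule=esc_schedule,
            emissions=afp_emissions,
            n_molecules=5000,
            seed=42,
        )
        counts = simulate_counts(cfg)
        res = fit(counts, esc_schedule, afp_emissions, mode="constant", n_starts=6, seed=1)
        np.testing.assert_allclose(res.efficiencies[0], truth.as_array(), atol=0.05)
        assert res.converged
        np.testing.assert_allclose(res.fitted_distributions.sum(axis=1), 1.0, atol=1e-8)

    def test_single_time_point_fits_init_only(self, afp_emissions):
        sched = DivisionSchedule(days=(0,), divisions=(0,))
        counts = CountData(counts={"BS": np.array([[700, 100, 100, 100]]),
                                   "oxBS": np.array([[600, 120, 120, 160]])})
        res = fit(counts, sched, afp_emissions, n_starts=4, seed=0)
        assert res.mode == "init_only"
        assert res.efficiencies.shape == (0, 3)
        assert res.initial_distribution.sum() == pytest.approx(1.0, abs=1e-8)

    def test_per_interval_mode_shape(self, afp_emissions):
        sched = DivisionSchedule(days=(0, 1, 3), divisions=(0, 2, 6))
        cfg = SimulationConfig(
            reference=presets.demo_reference(),
            efficiencies=EnzymeEfficiencies(0.9, 0.05, 0.02),
            initial_distribution=presets.DEFAULT_INIT_DISTRIBUTION,
            schedule=sched,
            emissions=afp_emissions,
            n_molecules=1500,
            seed=3,
        )
        res = fit(simulate_counts(cfg), sched, afp_emissions, mode="per_interval",
                  n_starts=4, seed=2)
        assert res.efficiencies.shape == (2, 3)

    def test_boundary_fit_is_representable_and_flagged(self, esc_schedule, afp_emissions):
        """Zero de novo / hydroxylation truth must be expressible (estimates
        pinned at the box boundary are flagged, not rejected)."""
        truth = EnzymeEfficiencies(0.95, 0.0, 0.0)
        cfg = SimulationConfig(
            reference=presets.demo_reference(),
            efficiencies=truth,
            initial_distribution=presets.DEFAULT_INIT_DISTRIBUTION,
            schedule=esc_schedule,
            emissions=afp_emissions,
            n_molecules=4000,
            seed=11,
        )
        res = fit(simulate_counts(cfg), esc_schedule, afp_emissions, mode="constant",
                  n_starts=6, seed=5)
        assert res.efficiencies[0, 1] < 0.02  # delta
        assert res.efficiencies[0, 2] < 0.02  # eta
        assert any("delta" in f or "eta" in f for f in res.boundary_flags)

    def test_zero_eta_truth_bootstrap_interval_covers_zero(self, esc_schedule, afp_emissions):
        """When the simulated hydroxylation efficiency is zero, the fitted
        eta must not be significantly positive: its bootstrap interval
        reaches the zero boundary."""
        truth = EnzymeEfficiencies(0.85, 0.08, 0.0)
        cfg = SimulationConfig(
            reference=presets.demo_reference(),
            efficiencies=truth,
            initial_distribution=np.array([0.2, 0.04, 0.04, 0.7, 0, 0, 0, 0, 0.02]),
            schedule=esc_schedule,
            emissions=afp_emissions,
            n_molecules=4000,
            seed=21,
        )
        res = fit(simulate_counts(cfg), esc_schedule, afp_emissions, mode="constant",
                  n_starts=4, seed=6, n_bootstrap=15)
        lo, _ = res.bootstrap_intervals["eta"]
        assert lo <= 0.01

    def test_bootstrap_coverage_of_true_efficiencies(self, esc_schedule, afp_emissions):
        """90% bootstrap intervals cover the simulated truth in at least 80%
        of checks (12 seeded replicates x 3 efficiencies, 4000 molecules per
        time point, 30 bootstrap draws)."""
        truth = EnzymeEfficiencies(0.8, 0.1, 0.05)
        hits = total = 0
        for rep in range(12):
            cfg = SimulationConfig(
                reference=presets.demo_reference(),
                efficiencies=truth,
                initial_distribution=presets.DEFAULT_INIT_DISTRIBUTION,
                schedule=esc_schedule,
                emissions=afp_emissions,
                n_molecules=4000,
                seed=500 + rep,
            )
            res = fit(simulate_counts(cfg), esc_schedule, afp_emissions,
                      mode="constant", n_starts=4, seed=rep, n_bootstrap=30)
            for name, value in zip(("mu", "delta", "eta"), truth.as_array()):
                lo, hi = res.bootstrap_intervals[name]
                hits += lo - 1e-9 <= value <= hi + 1e-9
                total += 1
        assert hits / total >= 0.8, (hits, total)

    def test_json_roundtrip(self, afp_emissions, tmp_path):
        sched = DivisionSchedule(days=(0,), divisions=(0,))
        counts = CountData(counts={"BS": np.array([[700, 100, 100, 100]]),
                                   "oxBS": np.array([[600, 120, 120, 160]])})
        res = fit(counts, sched, afp_emissions, n_starts=2, seed=0)
        import json

        payload = json.loads(res.to_json(tmp_path / "fit.json"))
        assert payload["states"] == list(STATES)
        assert (tmp_path / "fit.json").exists()


class TestSummaries:
    def test_symmetric_h_concentration(self):
        s = hydroxylation_summary(_delta_dist("hh"))
        assert s["h_symmetric"] == 1.0
        assert s["total_5hmc_per_strand"] == 1.0

    def test_uniform_distribution_counting(self):
        s = hydroxylation_summary(np.full(9, 1 / 9))
        assert s["h_with_u"] == pytest.approx(2 / 9)
        assert s["h_with_m"] == pytest.approx(2 / 9)
        assert s["h_symmetric"] == pytest.approx(1 / 9)

    def test_class_sums_conserve_any_h_probability(self, rng):
        d = rng.dirichlet(np.ones(9))
        s = hydroxylation_summary(d)
        any_h = sum(d[i] for i, st_ in enumerate(STATES) if "h" in st_)
        assert s["h_with_u"] + s["h_with_m"] + s["h_symmetric"] == pytest.approx(any_h)

    def test_pattern_counts_mapping(self):
        from hpoxbs.refold import DyadPattern

        p = DyadPattern("m", "BS", ("both", "hemi_top", "hemi_bottom", "unmod", "unknown"))
        np.testing.assert_array_equal(observed_counts_from_patterns([p]), [1, 1, 1, 1])


class TestNaive:
    def _summary(self, both, hemi_top, hemi_bottom, unmod):
        import pandas as pd
        from hpoxbs.refold import PatternSummary

        freq = pd.DataFrame(
            [[both, hemi_top, hemi_bottom, unmod]],
            columns=["both", "hemi_top", "hemi_bottom", "unmod"],
        )
        return PatternSummary(
            n_molecules=100,
            coverage=np.array([100]),
            class_freq=freq,
            mean_class_freq={"both": both, "hemi_top": hemi_top,
                             "hemi_bottom": hemi_bottom, "unmod": unmod},
        )

    def test_subtraction(self):
        bs = self._summary(0.5, 0.1, 0.1, 0.3)  # mean level 0.60
        ox = self._summary(0.4, 0.05, 0.05, 0.5)  # mean level 0.45
        out = naive_5hmc(bs, ox)
        assert out["total_5hmc"] == pytest.approx(0.15)
        assert out["both"] == pytest.approx(0.1)

    def test_identical_summaries_give_zero(self):
        s = self._summary(0.5, 0.1, 0.1, 0.3)
        out = naive_5hmc(s, s)
        assert all(v == pytest.approx(0.0) for v in out.values())

    def test_negative_estimates_warn_not_clip(self):
        bs = self._summary(0.4, 0.1, 0.1, 0.4)
        ox = self._summary(0.5, 0.1, 0.1, 0.3)
        with pytest.warns(UserWarning, match="negative"):
            out = naive_5hmc(bs, ox)
        assert out["total_5hmc"] == pytest.approx(-0.1)
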