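"""Structure enumeration, candidate designs, Conformity Rate and the
pattern-detection experiment against a brute-force oracle."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

import predseek as ps
from predseek.structures import equation_factors


class TestEnumeration:
    def test_full_count_is_728_per_equation(self):
        # sum over subset sizes k of C(6,k) * 2^k = 3^6 - 1
        for eq in ("search", "consult"):
            specs = ps.enumerate_structures(eq)
            assert len(specs) == 728
            assert len({s.id for s in specs}) == 728

    def test_six_factor_subsets_contribute_64(self):
        specs = [s for s in ps.enumerate_structures("search") if len(s.factors) == 6]
        assert len(specs) == 64

    def test_contains_the_predation_search_structure(self):
        ids = {s.id for s in ps.enumerate_structures("search")}
        assert "+x2^2-x1^2*x2" in ids

    def test_enumeration_order_is_deterministic(self):
        a = [s.id for s in ps.enumerate_structures("consult")]
        b = [s.id for s in ps.enumerate_structures("consult")]
        assert a == b
        sizes = [len(s.factors) for s in ps.enumerate_structures("consult")]
        assert sizes == sorted(sizes)


class TestCandidateDesign:
    def test_zero_factor_structure_reduces_to_baseline(self, noiseless_ensemble):
        pair = noiseless_ensemble[0]
        empty = ps.StructureSpec(equation="search")
        X, y = ps.build_candidate_design(pair, empty, 20)
        Xb, yb = ps.build_logistic_design(pair.x1[:20])
        np.testing.assert_array_equal(X, Xb)
        np.testing.assert_array_equal(y, yb)

    def test_hand_built_design_on_five_day_toy(self):
        pair = ps.CumulativePair("toy", np.arange(1, 6), [1, 2, 4, 7, 11], [1, 3, 6, 10, 15])
        spec = ps.StructureSpec("search", ("x2^2", "x1^2*x2"), (1, -1))
        X, y = ps.build_candidate_design(pair, spec, 5)
        lag1 = np.array([1.0, 2.0, 4.0, 7.0])
        lag2 = np.array([1.0, 3.0, 6.0, 10.0])
        np.testing.assert_array_equal(y, [1, 2, 3, 4])
        np.testing.assert_array_equal(X[:, 0], lag1)
        np.testing.assert_array_equal(X[:, 1], lag1**2)
        np.testing.assert_array_equal(X[:, 2], lag2**2)
        np.testing.assert_array_equal(X[:, 3], lag1**2 * lag2)

    def test_full_structure_shape(self, noiseless_ensemble):
        pair = noiseless_ensemble[0]
        spec = ps.StructureSpec("consult", equation_factors("consult"), (1,) * 6)
        X, y = ps.build_candidate_design(pair, spec, 61)
        assert X.shape == (60, 8)
        assert y.shape == (60,)

    def test_too_short_window_signals_insufficient_data(self, noiseless_ensemble):
        # an 8-regressor candidate on a 9-day window has zero residual dof:
        # the design builds, but the fit refuses it (pattern detection skips it)
        spec = ps.StructureSpec("search", equation_factors("search"), (1,) * 6)
        X, y = ps.build_candidate_design(noiseless_ensemble[0], spec, 9)
        assert X.shape == (8, 8)
        with pytest.raises(ps.InsufficientDataError):
            ps.ols_no_intercept(X, y)
        with pytest.raises(ps.InsufficientDataError):
            ps.build_candidate_design(noiseless_ensemble[0], spec, 1)


class TestWindows:
    def test_sixty_one_days_gives_31_windows(self):
        w = ps.dynamic_windows(61)
        assert w == list(range(31, 62))
        assert len(w) == 31

    def test_four_days(self):
        assert ps.dynamic_windows(4) == [2, 3, 4]

    def test_stride_thinning(self):
        assert ps.dynamic_windows(61, stride=3) == list(range(31, 62, 3))


class TestConformityRate:
    @pytest.mark.parametrize(
        "n_pass, n_total, expected", [(0, 992, 0.0), (992, 992, 1.0), (3, 4, 0.75)]
    )
    def test_exact_ratio(self, n_pass, n_total, expected):
        assert ps.conformity_rate(n_pass, n_total) == expected

    def test_never_attempted_is_undefined(self):
        assert np.isnan(ps.conformity_rate(0, 0))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ps.conformity_rate(5, 4)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(n_pass=st.integers(0, 100), n_extra=st.integers(0, 100))
    def test_monotonicity_under_appended_outcomes(self, n_pass, n_extra):
        n_total = n_pass + n_extra
        if n_total == 0:
            return
        cr = ps.conformity_rate(n_pass, n_total)
        assert 0.0 <= cr <= 1.0
        # appending a failed regression never increases CR
        assert ps.conformity_rate(n_pass, n_total + 1) <= cr
        # appending a pass never decreases it
        assert ps.conformity_rate(n_pass + 1, n_total + 1) >= cr


def brute_force_pattern(pairs, equation, cfg, cond_max=1e10):
    """Naive per-window recomputation with textbook normal equations.

    Also reports each structure's worst window condition number: for
    near-singular windows the binary pass/fail decision is not a
    well-defined quantity (it depends on solver rounding), so the
    equivalence check is restricted to well-posed candidates.
    """
    out = {}
    for spec in ps.enumerate_structures(equation):
        if len(spec.factors) > 3:
            continue
        n_pass = n_total = 0
        worst_cond = 0.0
        signs = np.array([1.0, -1.0] + [float(s) for s in spec.signs])
        for pair in pairs:
            for w in ps.dynamic_windows(len(pair), cfg.start_fraction, cfg.stride):
                k = 2 + len(spec.factors)
                if (w - 1) - k < 1:
                    continue
                X, y = ps.build_candidate_design(pair, spec, w)
                n_total += 1
                # unit-norm columns: a positive rescaling that leaves the
                # decisions invariant but keeps the toy problems solvable
                norms = np.linalg.norm(X, axis=0)
                norms[norms == 0] = 1.0
                Xs = X / norms
                gram = Xs.T @ Xs
                worst_cond = max(worst_cond, np.linalg.cond(gram))
                try:
                    xtx_inv = np.linalg.inv(gram)
                except np.linalg.LinAlgError:
                    worst_cond = np.inf
                    continue  # collinear window: attempted and failed
                beta = xtx_inv @ (Xs.T @ y)
                resid = y - Xs @ beta
                rss = float(resid @ resid)
                dof = X.shape[0] - k
                with np.errstate(divide="ignore", invalid="ignore"):
                    se = np.sqrt(rss / dof * np.diag(xtx_inv))
                    p = 2 * scipy.stats.t.sf(np.abs(beta / se), dof)
                r2 = 1.0 - rss / float(y @ y)
                ok = (
                    np.all(signs * beta > 0)
                    and r2 > cfg.r2_min
                    and np.all(np.isfinite(p))
                    and np.all(p < cfg.alpha)
                )
                n_pass += int(ok)
        if worst_cond < cond_max:
            out[spec.id] = (n_pass, n_total)
    return out


class TestPatternDetect:
    def test_matches_brute_force_oracle_on_small_fixture(self):
        """Pass/fail decisions and CRs agree with an independent naive
        recomputation on a 2-region, 10-day noisy toy (<= 3-factor specs)."""
        # fast-growth, small-capacity wave so 10 days cover the full cycle
        toy = ps.ModelParams(r1=0.9, r2=0.9, K1=1000.0, K2=600.0, x1_0=30.0, x2_0=20.0)
        series = ps.generate_ensemble(
            toy, n_regions=2, n_days=10, heterogeneity=0.1, noise=ps.NoiseSpec(0.005, seed=9)
        )
        pairs = [ps.cumulate(s) for s in series]
        cfg = ps.PatternConfig()
        expected = brute_force_pattern(pairs, "search", cfg)
        ranked = ps.pattern_detect(pairs, "search", cfg)
        checked = 0
        for res in ranked:
            if res.structure.id not in expected:
                continue
            n_pass, n_total = expected[res.structure.id]
            assert (res.n_pass, res.n_total) == (n_pass, n_total), res.structure.id
            if n_total:
                assert res.cr == pytest.approx(n_pass / n_total, abs=1e-12)
            checked += 1
        # well-posed candidates dominate the 12 + 60 + 160 small structures
        assert checked >= 150

    def test_generating_structure_wins_noiseless(self, noiseless_ensemble, predation_params):
        ranked = ps.pattern_detect(noiseless_ensemble, "search", ps.PatternConfig(stride=3))
        true_id = ps.structure_from_coefficients("search", predation_params.a).id
        assert ranked[0].structure.id == true_id
        assert ranked[0].cr == 1.0
        assert ranked[0].mean_r2 == pytest.approx(1.0, abs=1e-8)

    def test_ranking_independent_of_region_order(self, noiseless_ensemble):
        cfg = ps.PatternConfig(stride=5)
        a = ps.pattern_detect(noiseless_ensemble, "consult", cfg)
        b = ps.pattern_detect(list(reversed(noiseless_ensemble)), "consult", cfg)
        assert [r.structure.id for r in a] == [r.structure.id for r in b]
        np.testing.assert_allclose([r.cr for r in a], [r.cr for r in b], atol=1e-14)

    def test_structure_recovery_across_seeded_ensembles(self, predation_params):
        """The generating structure tops the ranking in every noiseless
        jittered ensemble (20 seeds, reduced scale)."""
        true_id = ps.structure_from_coefficients("search", predation_params.a).id
        cfg = ps.PatternConfig(stride=3)
        wins = 0
        for seed in range(20):
            series = ps.generate_ensemble(
                predation_params, n_regions=4, n_days=61, noise=ps.NoiseSpec(0.0, seed=seed)
            )
            pairs = [ps.cumulate(s) for s in series]
            ranked = ps.pattern_detect(pairs, "search", cfg)
            wins += ranked[0].structure.id == true_id
        assert wins == 20

    def test_per_region_pooling_option(self, noiseless_ensemble):
        cfg = ps.PatternConfig(stride=5, cr_pooling="per-region")
        ranked = ps.pattern_detect(noiseless_ensemble, "search", cfg)
        assert ranked[0].cr == 1.0

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            ps.pattern_detect([], "search")


class TestSelect:
    def _res(self, spec_id_factors, cr, mean_r2):
        factors, signs = spec_id_factors
        spec = ps.StructureSpec("search", factors, signs)
        n_total = 100
        return ps.ConformityResult(spec, int(cr * n_total), n_total, cr, mean_r2)

    def test_single_result_above_gate(self):
        res = self._res((("x2",), (1,)), 0.8, 0.95)
        assert ps.select_structure([res], min_cr=0.5) == res.structure

    def test_below_gate_returns_none(self):
        res = self._res((("x2",), (1,)), 0.3, 0.95)
        assert ps.select_structure([res], min_cr=0.5) is None

    def test_mean_r2_tie_break(self):
        a = self._res((("x2",), (1,)), 1.0, 1.0)
        b = self._res((("x2^2",), (1,)), 1.0, 0.97)
        ranked = sorted([b, a], key=lambda r: r.rank_key)
        assert ranked[0].structure.id == "+x2"
        assert ps.select_structure(ranked, 0.5) == a.structure

    def test_parsimony_tie_break(self):
        small = self._res((("x2",), (1,)), 1.0, 1.0)
        big = self._res((("x2", "x2^2"), (1, 1)), 1.0, 1.0)
        ranked = sorted([big, small], key=lambda r: r.rank_key)
        assert ranked[0].structure.id == "+x2"
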