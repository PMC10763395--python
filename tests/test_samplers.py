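"""Chord geometry, shrinkage, chain initialization, and the three samplers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import looplessflux as lf
from looplessflux.errors import StateCorruptionError
from looplessflux.samplers import _chain_counts, adsb_step, initialize_chains


def mc_se(x):
    """Naive Monte Carlo standard error of the mean (iid approximation)."""
    return x.std(ddof=1) / np.sqrt(len(x))


def ess_se(archive):
    """Autocorrelation-aware MC standard errors: sd / sqrt(ESS) per flux."""
    n_eff, _ = lf.effective_sample_size(archive.chains_array)
    return archive.samples.std(axis=0, ddof=1) / np.sqrt(n_eff)


class TestChordLimits:
    def test_centered_unit_box(self):
        lam = lf.chord_limits(np.zeros(3), np.eye(3)[0], -np.ones(3), np.ones(3))
        assert lam == (-1.0, 1.0)

    def test_point_on_face_one_sided(self):
        lb, ub = np.zeros(2), np.ones(2)
        lam = lf.chord_limits(np.array([0.0, 0.5]), np.array([1.0, 0.0]), lb, ub)
        assert lam[0] == 0.0 and lam[1] == 1.0

    def test_hand_computed_ratios(self):
        """u=(1,2) from (1,1) in [0,10]^2: lambda in (-0.5, 4.5)."""
        lam = lf.chord_limits(
            np.array([1.0, 1.0]), np.array([1.0, 2.0]), np.zeros(2), np.full(2, 10.0)
        )
        assert lam == (-0.5, 4.5)

    def test_tiny_components_impose_no_constraint(self):
        lam = lf.chord_limits(
            np.array([0.5, 0.5]), np.array([1.0, 1e-13]), np.zeros(2), np.ones(2)
        )
        assert lam == (-0.5, 0.5)

    def test_out_of_box_point_is_state_corruption(self):
        with pytest.raises(StateCorruptionError):
            lf.chord_limits(np.array([2.0]), np.array([1.0]), np.zeros(1), np.ones(1))

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        data=st.data(),
        n=st.integers(min_value=1, max_value=6),
    )
    def test_chord_contains_current_point_and_stays_in_box(self, data, n):
        """For any interior point and direction: lambda_min <= 0 <= lambda_max
        and both chord endpoints lie inside the box (up to round-off)."""
        lb = np.array(data.draw(st.lists(
            st.floats(-50, 0, allow_nan=False), min_size=n, max_size=n)))
        width = np.array(data.draw(st.lists(
            st.floats(0.1, 100, allow_nan=False), min_size=n, max_size=n)))
        ub = lb + width
        frac = np.array(data.draw(st.lists(
            st.floats(0.0, 1.0, allow_nan=False), min_size=n, max_size=n)))
        v = lb + frac * width
        u = np.array(data.draw(st.lists(
            st.floats(-1, 1, allow_nan=False), min_size=n, max_size=n)))
        lam_min, lam_max = lf.chord_limits(v, u, lb, ub)
        assert lam_min <= 0.0 <= lam_max
        for lam in (lam_min, lam_max):
            end = v + lam * np.where(np.abs(u) > 1e-12, u, 0.0)
            assert np.all(end >= lb - 1e-7) and np.all(end <= ub + 1e-7)


class TestShrinkSample:
    def test_no_loops_first_draw_accepted(self):
        rng = np.random.default_rng(0)
        v, n_shrinks = lf.shrink_sample(
            np.zeros(2), np.array([1.0, 0.0]), (-1.0, 1.0),
            lambda v: False, rng, 1e-8,
        )
        assert n_shrinks == 0 and -1 <= v[0] <= 1

    def test_rejections_shrink_toward_current_point(self):
        """Loop region at x > 0.5: every accepted point lies in the loopless
        segment and every rejected draw was loop-active."""
        rejected = []

        def loop_test(v):
            bad = v[0] > 0.5
            if bad:
                rejected.append(v[0])
            return bad

        rng = np.random.default_rng(1)
        for _ in range(50):
            v, _ = lf.shrink_sample(
                np.zeros(1), np.ones(1), (-1.0, 1.0), loop_test, rng, 1e-10
            )
            assert v[0] <= 0.5
        assert all(x > 0.5 for x in rejected)

    def test_everything_rejected_returns_none(self):
        rng = np.random.default_rng(2)
        v, n_shrinks = lf.shrink_sample(
            np.zeros(1), np.ones(1), (-1.0, 1.0), lambda v: True, rng, 1e-3
        )
        assert v is None and n_shrinks > 0

    def test_eps_wider_than_interval_fails_immediately(self):
        rng = np.random.default_rng(3)
        v, n_shrinks = lf.shrink_sample(
            np.zeros(1), np.ones(1), (-0.1, 0.1), lambda v: False, rng, 1.0
        )
        assert v is None and n_shrinks == 0


class TestInitializeChains:
    def test_chain_fixture_spans_the_line(self, chain_space):
        opts = lf.SamplerOptions(n_samples=10, K=2, k=3, burn_in=0, thinning=1, seed=0)
        state = initialize_chains(chain_space, opts)
        assert state.V.shape == (2, 3, chain_space.model.n_reactions)
        for chain in state.V:
            diffs = chain[1:] - chain[0]
            assert np.linalg.matrix_rank(diffs, tol=1e-8) == 1  # = d

    def test_small_k_records_conditional_spanning_warning(self, box_space):
        opts = lf.SamplerOptions(n_samples=10, K=1, k=3, burn_in=0, seed=0)
        state = initialize_chains(box_space, opts)  # d=5 > k-1
        assert any("conditionally" in w for w in state.warnings)

    def test_points_are_loopless_and_feasible(self, cycle3_space):
        opts = lf.SamplerOptions(n_samples=10, K=2, burn_in=0, seed=4)
        state = initialize_chains(cycle3_space, opts)
        checker = cycle3_space.make_checker()
        for chain in state.V:
            for v in chain:
                assert not checker(v)
                assert np.max(np.abs(cycle3_space.model.S @ v)) < 1e-9


class TestAdsbStep:
    def test_on_chain_fixture_stays_on_flux_line(self, chain_space):
        opts = lf.SamplerOptions(n_samples=10, K=1, k=3, burn_in=0, seed=1)
        state = initialize_chains(chain_space, opts)
        pts = state.V[0].copy()
        rng = state.rng_streams[0]
        checker = chain_space.make_checker()
        for _ in range(100):
            adsb_step(pts, chain_space, checker, opts, rng)
        # every point still of the form (c, c, c)
        np.testing.assert_allclose(pts, pts[:, [0]] * np.ones(3), atol=1e-8)

    def test_duplicate_direction_points_skip(self, chain_space):
        from looplessflux.samplers import _Counters

        opts = lf.SamplerOptions(n_samples=10, K=1, k=3, burn_in=0, seed=2)
        pts = np.tile(chain_space.v0, (3, 1))
        cnt = _Counters()
        adsb_step(pts, chain_space, chain_space.make_checker(), opts,
                  np.random.default_rng(0), cnt)
        assert cnt.skipped_degenerate == 1
        np.testing.assert_array_equal(pts, np.tile(chain_space.v0, (3, 1)))


class TestRunAdsb:
    def test_bookkeeping_and_chain_balance(self, cycle3_space):
        opts = lf.SamplerOptions(n_samples=1000, K=4, thinning=2, burn_in=10, seed=0)
        arc = lf.run_adsb(cycle3_space, opts)
        assert arc.samples.shape == (1000, cycle3_space.model.n_reactions)
        counts = np.bincount(arc.chain_index)
        np.testing.assert_array_equal(counts, [250, 250, 250, 250])

    def test_chain_fixture_mean_matches_uniform_midpoint(self, chain_space):
        """The 1-D flux line is [0, cap]; uniform sampling puts the mean at
        cap/2 within Monte Carlo error."""
        opts = lf.SamplerOptions(n_samples=4000, K=2, thinning=5, burn_in=100, seed=1)
        arc = lf.run_adsb(chain_space, opts)
        cap = chain_space.model.ub.min()
        x = arc.samples[:, 0]
        assert abs(x.mean() - cap / 2) < 3 * mc_se(x) + 0.02 * cap

    def test_seed_reproducibility_bitwise(self, cycle3_space):
        opts = lf.SamplerOptions(n_samples=300, K=2, thinning=2, burn_in=5, seed=7)
        a = lf.run_adsb(cycle3_space, opts)
        b = lf.run_adsb(cycle3_space, opts)
        assert np.array_equal(a.samples, b.samples)
        assert np.array_equal(a.chain_index, b.chain_index)

    def test_all_samples_loopless_by_construction(self, cycle3_space):
        opts = lf.SamplerOptions(n_samples=500, K=2, thinning=2, burn_in=10, seed=3)
        arc = lf.run_adsb(cycle3_space, opts)
        assert arc.meta["audit"]["loop_active_rows"] == 0

    def test_direction_null_space_closure(self, cycle3_space):
        """Proposal directions are differences of mass-balanced points; after
        projection they satisfy ||S u|| <= 1e-8 exactly as sampled."""
        opts = lf.SamplerOptions(n_samples=10, K=1, burn_in=0, seed=5)
        state = initialize_chains(cycle3_space, opts)
        pts = state.V[0]
        S = cycle3_space.model.S
        for i in range(1, len(pts)):
            u = pts[i] - pts[0]
            u = cycle3_space.N_perp @ (cycle3_space.N_perp.T @ u)
            if np.linalg.norm(u) > 1e-12:
                assert np.max(np.abs(S @ (u / np.linalg.norm(u)))) <= 1e-8

    def test_archive_save_load_round_trip(self, cycle3_space, tmp_path):
        opts = lf.SamplerOptions(n_samples=100, K=2, thinning=1, burn_in=2, seed=9)
        arc = lf.run_adsb(cycle3_space, opts)
        arc.save(tmp_path / "run")
        back = lf.load_archive(tmp_path / "run")
        np.testing.assert_allclose(back.samples, arc.samples)
        assert back.rxn_ids == arc.rxn_ids
        assert back.options == arc.options


class TestRunHr:
    def test_box_moments_match_closed_form(self, box_space):
        opts = lf.SamplerOptions(n_samples=8000, K=2, thinning=3, burn_in=100, seed=2)
        arc = lf.run_hr(box_space, opts)
        for j in range(5):
            x = arc.samples[:, j]
            assert abs(x.mean() - 0.5) < 3 * mc_se(x) + 0.01
            assert abs(x.var() - 1 / 12) < 0.01

    def test_cycle3_marks_loopy_fraction_strictly_inside_01(self, cycle3_space):
        """Both the loopless and the loop-active region of the relaxation
        have positive volume, so HR must visit both."""
        opts = lf.SamplerOptions(
            n_samples=1000, K=2, thinning=2, burn_in=20, seed=3, loopless_filter=True
        )
        arc = lf.run_hr(cycle3_space, opts)
        assert 0.0 < arc.meta["loop_active_fraction"] < 1.0

    def test_reproducible(self, box_space):
        opts = lf.SamplerOptions(n_samples=200, K=2, thinning=1, burn_in=5, seed=4)
        assert np.array_equal(
            lf.run_hr(box_space, opts).samples, lf.run_hr(box_space, opts).samples
        )


class TestRunLlAchrb:
    def test_box_moments_agree_with_hr(self, box_space):
        opts = lf.SamplerOptions(n_samples=6000, K=2, thinning=3, burn_in=100, seed=5)
        ll = lf.run_ll_achrb(box_space, opts)
        hr = lf.run_hr(box_space, opts)
        se = np.sqrt(ess_se(ll) ** 2 + ess_se(hr) ** 2)
        diff = np.abs(ll.samples.mean(axis=0) - hr.samples.mean(axis=0))
        assert np.all(diff < 3 * se + 0.01)

    def test_flagged_non_markovian(self, cycle3_space):
        opts = lf.SamplerOptions(n_samples=100, K=2, thinning=1, burn_in=2, seed=6)
        arc = lf.run_ll_achrb(cycle3_space, opts)
        assert arc.meta["non_markovian"] is True
        assert arc.meta["audit"]["loop_active_rows"] == 0


class TestOptionsAndHelpers:
    def test_chain_counts_distribute_remainder(self):
        assert _chain_counts(10, 4) == [3, 3, 2, 2]
        assert _chain_counts(8, 4) == [2, 2, 2, 2]

    def test_invalid_options_rejected(self):
        with pytest.raises(ValueError):
            lf.SamplerOptions(k=2)
        with pytest.raises(ValueError):
            lf.SamplerOptions(K=0)
        with pytest.raises(ValueError):
            lf.SamplerOptions(target="gaussian")

    def test_default_k_tracks_dimension(self):
        opts = lf.SamplerOptions()
        assert opts.resolved_k(2) == 5
        assert opts.resolved_k(100) == 50

    def test_permuting_reactions_permutes_statistics(self):
        """Column statistics follow the reaction ordering of the model (the
        sampler has no hidden dependence on column position)."""
        lb = np.array([0.0, -1.0, 2.0])
        ub = np.array([1.0, 1.0, 5.0])
        perm = [2, 0, 1]
        opts = lf.SamplerOptions(n_samples=4000, K=2, thinning=2, burn_in=50, seed=8)
        fs_a = lf.build_flux_space(lf.make_box_model(lb, ub), seed=0)
        fs_b = lf.build_flux_space(lf.make_box_model(lb[perm], ub[perm]), seed=0)
        a = lf.run_adsb(fs_a, opts)
        b = lf.run_adsb(fs_b, opts)
        se = np.sqrt(ess_se(a)[perm] ** 2 + ess_se(b) ** 2)
        diff = np.abs(a.samples[:, perm].mean(axis=0) - b.samples.mean(axis=0))
        assert np.all(diff < 3 * se + 0.01 * (ub[perm] - lb[perm]))
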