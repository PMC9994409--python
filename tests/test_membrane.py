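"""Geometry, torus metric, step proposal and packing tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from raftsim.membrane import (
    Agent,
    BoxSpec,
    Circle,
    DomainSet,
    MotionParams,
    NeighborGrid,
    PackingError,
    Species,
    local_diffusivity,
    make_domains,
    minimal_image,
    overlaps,
    place_uniform,
    propose_step,
    wrap,
)

BOX = BoxSpec(30.0)


class TestWrap:
    @pytest.mark.parametrize(
        "point, expected",
        [((31.5, -0.5), (1.5, 29.5)), ((15, 15), (15, 15)),
         ((60.0, 90.0), (0.0, 0.0))],
    )
    def test_examples(self, point, expected):
        assert wrap(np.array(point), BOX) == pytest.approx(expected)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            wrap(np.array([np.nan, 0.0]), BOX)

    @given(st.floats(-1e6, 1e6), st.floats(-1e6, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_always_in_box(self, x, y):
        out = wrap(np.array([x, y]), BOX)
        assert np.all(out >= 0) and np.all(out < BOX.length)


class TestMinimalImage:
    def test_zero_for_identical(self):
        p = np.array([3.0, 4.0])
        assert minimal_image(p, p, BOX) == pytest.approx((0.0, 0.0))

    def test_wraparound_distance(self):
        d = minimal_image(np.array([0.1, 0.0]), np.array([29.9, 0.0]), BOX)
        assert d == pytest.approx((-0.2, 0.0))

    def test_matches_brute_force_over_images(self, rng):
        """Oracle: the minimal-image distance equals the minimum over all
        nine periodic image shifts."""
        shifts = np.array([(i, j) for i in (-1, 0, 1) for j in (-1, 0, 1)])
        for _ in range(1000):
            p, q = rng.uniform(0, BOX.length, (2, 2))
            d = minimal_image(p, q, BOX)
            brute = min(
                np.hypot(*(q + BOX.length * s - p)) for s in shifts
            )
            assert np.hypot(*d) == pytest.approx(brute, abs=1e-9)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_torus_metric(self, seed):
        """Symmetry, identity and triangle inequality on sampled triples."""
        r = np.random.default_rng(seed)
        a, b, c = r.uniform(0, BOX.length, (3, 2))
        dab = np.hypot(*minimal_image(a, b, BOX))
        dba = np.hypot(*minimal_image(b, a, BOX))
        dac = np.hypot(*minimal_image(a, c, BOX))
        dcb = np.hypot(*minimal_image(c, b, BOX))
        assert dab == pytest.approx(dba)
        assert np.hypot(*minimal_image(a, a, BOX)) == 0.0
        assert dab <= dac + dcb + 1e-9


class TestLocalDiffusivity:
    motion = MotionParams(d_out=1.0, d_in=0.1)

    def test_membership_conventions(self):
        domains = DomainSet([Circle((15.0, 15.0), 5.0)], BOX)
        assert local_diffusivity((15, 15), domains, self.motion) == 0.1
        assert local_diffusivity((1, 1), domains, self.motion) == 1.0
        # point exactly on the boundary: closed-disc convention
        assert local_diffusivity((20.0, 15.0), domains, self.motion) == 0.1

    def test_wrap_aware_membership(self):
        domains = DomainSet([Circle((0.5, 0.5), 2.0)], BOX)
        assert local_diffusivity((29.5, 29.5), domains, self.motion) == 0.1


class TestProposeStep:
    def test_frozen_agent(self, rng):
        agent = Agent(0, Species.MONOMER, 0.57, np.array([5.0, 5.0]))
        cand = propose_step(agent, 0.0, rng, BOX)
        assert cand == pytest.approx((5.0, 5.0))

    def test_half_normal_moments(self, rng):
        """At D=1 the half-normal law has mean step sqrt(2/pi) and mean
        squared step 1 (these moments drive the MSD calibration)."""
        agent = Agent(0, Species.MONOMER, 0.57, np.array([15.0, 15.0]))
        motion = MotionParams(step_length_law="half_normal")
        lengths = []
        for _ in range(100_000):
            cand = propose_step(agent, 1.0, rng, BOX, motion)
            lengths.append(np.hypot(*minimal_image(agent.position, cand, BOX)))
        lengths = np.array(lengths)
        assert lengths.mean() == pytest.approx(math.sqrt(2 / math.pi),
                                               rel=0.01)
        assert (lengths**2).mean() == pytest.approx(1.0, rel=0.02)

    def test_rayleigh_mean(self, rng):
        agent = Agent(0, Species.MONOMER, 0.57, np.array([15.0, 15.0]))
        motion = MotionParams(step_length_law="rayleigh")
        lengths = [
            np.hypot(*minimal_image(agent.position,
                                    propose_step(agent, 1.0, rng, BOX, motion),
                                    BOX))
            for _ in range(50_000)
        ]
        assert np.mean(lengths) == pytest.approx(math.sqrt(math.pi / 2),
                                                 rel=0.02)

    def test_dimer_step_ratio(self, rng):
        """Stokes-Einstein: monomer steps 2^(1/4) times further than a
        dimer at equal D."""
        mono = Agent(0, Species.MONOMER, 0.57, np.array([15.0, 15.0]))
        dim = Agent(1, Species.DIMER, 0.81, np.array([15.0, 15.0]))
        m = np.mean([
            np.hypot(*minimal_image(mono.position,
                                    propose_step(mono, 1.0, rng, BOX), BOX))
            for _ in range(30_000)
        ])
        d = np.mean([
            np.hypot(*minimal_image(dim.position,
                                    propose_step(dim, 1.0, rng, BOX), BOX))
            for _ in range(30_000)
        ])
        assert m / d == pytest.approx(2**0.25, rel=0.03)


class TestOverlaps:
    def test_tangency_is_not_overlap(self):
        pos = np.array([[5.0, 5.0]])
        radii = np.array([1.0])
        assert not overlaps((7.0, 5.0), 1.0, pos, radii, BOX)
        assert overlaps((6.9, 5.0), 1.0, pos, radii, BOX)

    def test_wraparound_overlap(self):
        pos = np.array([[29.8, 15.0]])
        radii = np.array([1.0])
        assert overlaps((0.5, 15.0), 1.0, pos, radii, BOX)

    def test_grid_matches_all_pairs_oracle(self, rng):
        """The cell-list result agrees with the brute-force all-pairs
        check on random configurations."""
        for _ in range(500):
            n = rng.integers(2, 40)
            pos = rng.uniform(0, BOX.length, (n, 2))
            radii = rng.uniform(0.2, 1.2, n)
            grid = NeighborGrid.build(pos, radii, BOX)
            cand = rng.uniform(0, BOX.length, 2)
            r = rng.uniform(0.2, 1.2)
            assert overlaps(cand, r, pos, radii, BOX, grid=grid) == overlaps(
                cand, r, pos, radii, BOX)


class TestPlaceUniform:
    def test_zero_discs(self, rng):
        assert place_uniform(0, 0.5, BOX, rng).shape == (0, 2)

    def test_default_monomer_packing(self, rng):
        """47 receptor-sized discs (about 5% packing) place cleanly with
        all pairwise distances at least one diameter."""
        pos = place_uniform(47, 0.57, BOX, rng)
        assert pos.shape == (47, 2)
        for i in range(47):
            for j in range(i + 1, 47):
                d = np.hypot(*minimal_image(pos[i], pos[j], BOX))
                assert d >= 2 * 0.57 * (1 - 1e-12)

    def test_infeasible_packing_reports_achieved(self, rng):
        with pytest.raises(PackingError) as exc:
            place_uniform(40, 4.0, BOX, rng, max_attempts_per_disc=2000)
        assert exc.value.achieved < 40


class TestMakeDomains:
    def test_single_central_circle(self):
        ds = make_domains(0.35, 1, BOX)
        assert len(ds.circles) == 1
        assert ds.circles[0].center == (15.0, 15.0)
        assert ds.occupied_fraction == pytest.approx(0.35, rel=1e-9)

    def test_area_conserved_across_splits(self, rng):
        for n in (2, 4, 9, 16):
            ds = make_domains(0.35, n, BOX, rng)
            assert ds.occupied_fraction == pytest.approx(0.35, rel=1e-6)
            assert len(ds.circles) == n

    def test_four_way_split_radius(self, rng):
        """Closed form: r = L sqrt(f / (n pi)); for n=4, f=0.35, L=30
        each circle has radius 5.007 and the four areas total 0.35 L^2."""
        ds = make_domains(0.35, 4, BOX, rng)
        expected = 30.0 * math.sqrt(0.35 / (4 * math.pi))
        assert ds.circles[0].radius == pytest.approx(expected)
        assert expected == pytest.approx(5.0067, abs=1e-3)
        assert 4 * math.pi * expected**2 == pytest.approx(0.35 * 30.0**2)

    def test_domains_do_not_overlap(self, rng):
        ds = make_domains(0.30, 8, BOX, rng)
        for i in range(8):
            for j in range(i + 1, 8):
                d = np.hypot(*minimal_image(
                    np.array(ds.circles[i].center),
                    np.array(ds.circles[j].center), BOX))
                assert d >= 2 * ds.circles[i].radius - 1e-9
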