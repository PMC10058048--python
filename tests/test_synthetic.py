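"""Synthetic quadratic response surfaces and their exact argmax."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import chamopt as c
from chamopt.synthetic import SurfaceSpec, full_factorial

UNIT_BOX = ((-5.0, 5.0), (-5.0, 5.0), (-5.0, 5.0))


def make_spec(intercept=0.0, linear=(0, 0, 0), quadratic=(0, 0, 0),
              interactions=(0, 0, 0), noise_sd=0.0, bounds=UNIT_BOX):
    return SurfaceSpec(intercept, tuple(linear), tuple(quadratic),
                       tuple(interactions), noise_sd, bounds)


def poly_oracle(spec, x):
    """Independent term-by-term evaluation of the quadratic."""
    x1, x2, x3 = x
    terms = [spec.intercept]
    terms += [b * v for b, v in zip(spec.linear, (x1, x2, x3))]
    terms += [a * v**2 for a, v in zip(spec.quadratic, (x1, x2, x3))]
    terms += [q * u * v for q, (u, v) in
              zip(spec.interactions, ((x1, x2), (x1, x3), (x2, x3)))]
    return sum(terms)


class TestEvaluate:
    def test_constant_surface(self):
        spec = make_spec(intercept=7.5)
        assert c.evaluate_surface(spec, np.array([1.0, -2.0, 3.0])) == 7.5

    def test_vertex(self):
        # y = -(x1 - 1)^2 = -x1^2 + 2 x1 - 1
        spec = make_spec(intercept=-1.0, linear=(2, 0, 0), quadratic=(-1, 0, 0))
        assert c.evaluate_surface(spec, np.array([1.0, 0.0, 0.0])) == pytest.approx(0.0)

    @given(
        coefs=st.lists(st.floats(-3, 3), min_size=10, max_size=10),
        x=st.lists(st.floats(-5, 5), min_size=3, max_size=3),
    )
    def test_matches_term_by_term_oracle(self, coefs, x):
        spec = make_spec(coefs[0], coefs[1:4], coefs[4:7], coefs[7:10])
        got = c.evaluate_surface(spec, np.array(x))
        assert got == pytest.approx(poly_oracle(spec, x), rel=1e-12, abs=1e-12)

    def test_out_of_bounds_rejected(self):
        spec = make_spec()
        with pytest.raises(ValueError, match="bounds"):
            c.evaluate_surface(spec, np.array([6.0, 0.0, 0.0]))


class TestGenerate:
    DESIGN = full_factorial([(41, 50, 79), (1, 2, 3), (1, 2, 4)])
    BOUNDS = ((40.0, 80.0), (1.0, 3.0), (1.0, 4.0))

    def test_noiseless_limit_exact(self):
        spec = make_spec(intercept=2.0, linear=(0.1, 1.0, -1.0), bounds=self.BOUNDS)
        data = c.generate(spec, self.DESIGN, seed=0)
        expected = [c.evaluate_surface(spec, p) for p in self.DESIGN]
        assert np.array_equal(data.y, expected)

    def test_seed_determinism(self):
        spec = make_spec(intercept=50.0, noise_sd=2.0, bounds=self.BOUNDS)
        a = c.generate(spec, self.DESIGN, seed=42)
        b = c.generate(spec, self.DESIGN, seed=42)
        assert np.array_equal(a.y, b.y)
        assert not np.array_equal(a.y, c.generate(spec, self.DESIGN, seed=43).y)

    def test_noise_mean_clt_bound(self):
        """10,000 replicate draws at one point: sample mean within 4 SE."""
        spec = make_spec(intercept=50.0, noise_sd=2.0, bounds=self.BOUNDS)
        point = self.DESIGN[0]
        n = 10_000
        draws = np.array(
            [c.generate(spec, [point], seed=s).y[0] for s in range(n)]
        )
        se = spec.noise_sd / np.sqrt(n)
        assert abs(draws.mean() - c.evaluate_surface(spec, point)) < 4 * se


class TestArgmax:
    def test_separable_concave(self):
        # y = -(x1-2)^2 - (x2+1)^2 - x3^2
        spec = make_spec(
            intercept=-5.0, linear=(4, -2, 0), quadratic=(-1, -1, -1)
        )
        x, val = c.analytic_argmax(spec)
        assert np.allclose(x, [2, -1, 0], atol=1e-9)
        assert val == pytest.approx(0.0, abs=1e-9)

    def test_interaction_matches_grid_oracle(self):
        spec = make_spec(
            intercept=1.0, linear=(1.0, -0.5, 0.3),
            quadratic=(-0.5, -0.8, -0.4), interactions=(0.3, -0.2, 0.1),
        )
        x, val = c.analytic_argmax(spec)
        axes = [np.linspace(lo, hi, 201) for lo, hi in spec.bounds]
        G = np.meshgrid(*axes, indexing="ij")
        X = np.column_stack([g.ravel() for g in G])
        grid_best = c.evaluate_surface(spec, X).max()
        # within grid resolution: the grid can only undershoot the true max
        assert val >= grid_best - 1e-9
        assert val - grid_best < 1e-2

    def test_monotone_linear_hits_boundary(self):
        spec = make_spec(linear=(1.0, 0.0, 0.0))
        x, val = c.analytic_argmax(spec)
        assert x[0] == pytest.approx(5.0)
        assert val == pytest.approx(5.0)

    def test_maximality_on_random_sample(self, rng):
        spec = c.chamomile_like_surface(noise_sd=0.0)
        x, val = c.analytic_argmax(spec)
        lo = np.array([b[0] for b in spec.bounds])
        hi = np.array([b[1] for b in spec.bounds])
        X = lo + rng.uniform(size=(1000, 3)) * (hi - lo)
        assert val >= c.evaluate_surface(spec, X).max() - 1e-9


class TestSerialization:
    def test_dict_round_trip(self):
        spec = c.chamomile_like_surface()
        assert SurfaceSpec.from_dict(spec.to_dict()) == spec
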