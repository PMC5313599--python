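import numpy as np
import pytest

import localroi as lr


class DenseOperator:
    """Stand-in forward model wrapping an explicit matrix (for CG tests)."""

    def __init__(self, A):
        self.A = A
        self.n_coeffs = A.shape[1]

    def forward(self, c):
        return self.A @ c

    def adjoint(self, y):
        return self.A.T @ y


class TestConjugateGradient:
    def test_matches_direct_normal_equations_solve(self, rng):
        A = rng.normal(size=(30, 9))
        f = rng.normal(size=30)
        prob = lr.CorrectionProblem(
            operator=DenseOperator(A), residual_sino=f, beta=0.0, max_iters=9
        )
        res = lr.solve_correction(prob)
        direct = np.linalg.solve(A.T @ A, A.T @ f)
        assert np.linalg.norm(res.coefficients - direct) <= 1e-5 * np.linalg.norm(direct)

    def test_with_zone_term_matches_direct(self, rng):
        import scipy.sparse

        A = rng.normal(size=(25, 7))
        M = scipy.sparse.csr_matrix(rng.normal(size=(4, 7)))
        f = rng.normal(size=25)
        r = rng.normal(size=4)
        beta = 3.0
        prob = lr.CorrectionProblem(
            operator=DenseOperator(A),
            residual_sino=f,
            zone_matrix=M,
            zone_residual=r,
            beta=beta,
            max_iters=7,
        )
        res = lr.solve_correction(prob)
        Md = M.toarray()
        direct = np.linalg.solve(
            A.T @ A + beta * Md.T @ Md, A.T @ f + beta * Md.T @ r
        )
        assert np.linalg.norm(res.coefficients - direct) <= 1e-5 * np.linalg.norm(direct)

    def test_objective_trace_nonincreasing(self, rng):
        A = rng.normal(size=(40, 12))
        prob = lr.CorrectionProblem(
            operator=DenseOperator(A), residual_sino=rng.normal(size=40),
            beta=0.0, max_iters=12,
        )
        res = lr.solve_correction(prob)
        tr = res.objective_trace
        assert np.all(np.diff(tr) <= 1e-6 * abs(tr[0]))

    def test_objective_equals_true_objective(self, rng):
        # the cheap trace formula must agree with the explicitly evaluated
        # objective ||Ac - f||^2
        A = rng.normal(size=(20, 6))
        f = rng.normal(size=20)
        prob = lr.CorrectionProblem(
            operator=DenseOperator(A), residual_sino=f, beta=0.0, max_iters=6
        )
        res = lr.solve_correction(prob)
        explicit = np.linalg.norm(A @ res.coefficients - f) ** 2
        assert np.isclose(res.objective_trace[-1], explicit, rtol=1e-8)

    def test_tolerance_stops_early(self, rng):
        A = rng.normal(size=(20, 5))
        prob = lr.CorrectionProblem(
            operator=DenseOperator(A), residual_sino=rng.normal(size=20),
            beta=0.0, max_iters=50, tolerance=1e-12,
        )
        res = lr.solve_correction(prob)
        assert res.iterations_run <= 10

    def test_deterministic(self, rng):
        A = rng.normal(size=(30, 9))
        f = rng.normal(size=30)
        kw = dict(operator=DenseOperator(A), residual_sino=f, beta=0.0, max_iters=9)
        r1 = lr.solve_correction(lr.CorrectionProblem(**kw))
        r2 = lr.solve_correction(lr.CorrectionProblem(**kw))
        assert np.array_equal(r1.coefficients, r2.coefficients)

    def test_invalid_problem(self):
        with pytest.raises(ValueError):
            lr.CorrectionProblem(operator=None, residual_sino=np.zeros(3), beta=-1.0)
        with pytest.raises(ValueError):
            lr.CorrectionProblem(operator=None, residual_sino=np.zeros(3), max_iters=0)


class TestResidualSinogram:
    def test_zero_x0_gives_data(self, toy128):
        setup = toy128["setup"]
        f = lr.residual_sinogram(
            setup.sinogram, np.zeros((68, 68)), setup.geom
        )
        assert np.allclose(f, setup.sinogram)

    def test_dual_route_equality(self, toy128):
        # C P-tilde x0-ext == P x0: the zero-extension adds no projection mass
        setup, x0 = toy128["setup"], toy128["x0"]
        geom = setup.geom
        route1 = lr.crop_sinogram(
            lr.project(lr.embed_image(x0, geom.n_ext), geom.angles), geom.n_roi
        )
        route2 = lr.crop_sinogram(lr.project(x0, geom.angles), geom.n_roi)
        assert np.linalg.norm(route1 - route2) <= 1e-6 * np.linalg.norm(route2)

    def test_full_data_residual_is_small(self):
        # self-calibration: FBP of complete data reprojects close to the data
        ph = lr.make_shepp_logan(128, supersample=4)
        geom = lr.LocalGeometry(n_roi=128, n_ext=128, n_angles=200)
        d = lr.project(ph, geom.angles)
        x0, _ = lr.padded_fbp(d, geom)
        f = lr.residual_sinogram(d, x0, geom)
        assert np.linalg.norm(f) <= 0.08 * np.linalg.norm(d)

    def test_shape_checks(self, toy128):
        setup = toy128["setup"]
        with pytest.raises(ValueError):
            lr.residual_sinogram(setup.sinogram, np.zeros((67, 67)), setup.geom)


class TestCompose:
    def test_zero_coeffs_returns_x0(self, toy256):
        result = toy256["result"]
        basis = result.basis
        x0_ext = lr.embed_image(result.x0, basis.n_ext)
        x = lr.compose_result(x0_ext, basis, np.zeros(basis.n_coeffs), result.x0.shape[0])
        assert np.allclose(x, result.x0)

    def test_additivity(self, toy256, rng):
        result = toy256["result"]
        basis = result.basis
        n = result.x0.shape[0]
        x0_ext = lr.embed_image(result.x0, basis.n_ext)
        c1 = rng.normal(size=basis.n_coeffs)
        c2 = rng.normal(size=basis.n_coeffs)
        lhs = lr.compose_result(x0_ext, basis, c1 + c2, n)
        rhs = lr.compose_result(x0_ext, basis, c1, n) + lr.crop_image(
            lr.synthesize(basis, c2), n
        )
        assert np.allclose(lhs, rhs)


class TestEndToEndCorrection:
    def test_correction_reduces_roi_error(self, toy256):
        setup, result = toy256["setup"], toy256["result"]
        mae_fbp = np.abs(result.x0 - setup.truth_roi).mean()
        mae_corr = np.abs(result.corrected_roi - setup.truth_roi).mean()
        assert mae_corr < mae_fbp

    def test_known_zone_bias_nearly_removed(self, toy256):
        setup, result = toy256["setup"], toy256["result"]
        z = setup.zone
        bias_fbp = (result.x0 - setup.truth_roi)[z.rows, z.cols].mean()
        bias_corr = (result.corrected_roi - setup.truth_roi)[z.rows, z.cols].mean()
        assert abs(bias_corr) <= 0.1 * abs(bias_fbp)

    def test_pipeline_is_deterministic(self, toy256):
        setup, result = toy256["setup"], toy256["result"]
        again = lr.correct_reconstruction(setup, sigma0=9.4, max_iters=100)
        assert np.array_equal(again.coefficients, result.coefficients)


class TestPixelExactBaseline:
    def test_least_squares_with_zone_improves_on_fbp(self, toy128):
        setup, x0 = toy128["setup"], toy128["x0"]
        x = lr.baseline_pixel_exact(
            setup.sinogram, setup.geom, setup.zone, lam=10.0, tv_weight=0.0, iters=300
        )
        assert np.abs(x - setup.truth_roi).mean() < np.abs(x0 - setup.truth_roi).mean()

    def test_tv_regularized_near_exact_recovery(self, toy128, tv_baseline128):
        # piecewise-constant phantom: TV + known zone removes both the
        # low-frequency bias and the least-squares noise
        setup, x0 = toy128["setup"], toy128["x0"]
        x = tv_baseline128
        assert np.abs(x - setup.truth_roi).mean() <= 0.25 * np.abs(x0 - setup.truth_roi).mean()

    def test_least_squares_trades_bias_for_noise(self, toy128, ls_baseline128):
        # a long unregularized run shrinks the smooth cupping bias of the
        # padded FBP but leaves high-frequency noise in the profiles
        setup, x0 = toy128["setup"], toy128["x0"]

        def hf(x):
            p = lr.line_profile(x - setup.truth_roi)
            return np.abs(np.diff(p)).mean()

        def bias(x):
            return abs((x - setup.truth_roi).mean())

        assert bias(ls_baseline128) < 0.5 * bias(x0)
        assert hf(ls_baseline128) > hf(x0)

    def test_invalid_iters(self, toy128):
        setup = toy128["setup"]
        with pytest.raises(ValueError):
            lr.baseline_pixel_exact(setup.sinogram, setup.geom, None, iters=0)
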