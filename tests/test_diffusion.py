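"""Forward noising, reverse reconstruction, structural distance, filtering."""

import numpy as np
import pytest

from cropclr.autodiff import Tensor, no_grad
from cropclr.diffusion import (DiffusionConfig, DiffusionSchedule,
                               FilterConfig, ReconstructionNet,
                               diffusion_loss, feature_covariance,
                               filter_batch, filter_pair, forward_diffuse,
                               forward_trajectory, joint_pretrain_loss,
                               pair_structural_distance, reconstruct,
                               reverse_step, structural_distance)
from cropclr.nn import Adam


def tiny_diff_config(**kw):
    base = dict(T=4, dim=8, grid_size=4, n_layers=1, n_heads=2, ffn_hidden=16)
    base.update(kw)
    return DiffusionConfig(**base)


class TestSchedule:
    def test_bounds_and_monotonicity_enforced(self):
        with pytest.raises(ValueError):
            DiffusionSchedule(np.array([0.5, 0.9]))     # increasing
        with pytest.raises(ValueError):
            DiffusionSchedule(np.array([1.2, 0.5]))     # above 1
        s = DiffusionSchedule.linear(10, 0.95, 0.5)
        assert s.T == 10 and s.alphas[0] == 0.95 and s.alphas[-1] == 0.5


class TestForwardDiffuse:
    def test_alpha_one_is_identity(self, rng):
        sched = DiffusionSchedule(np.array([1.0]))
        e0 = rng.normal(size=(3, 4, 4))
        assert np.array_equal(forward_diffuse(e0, sched, 1, rng), e0)

    def test_shape_preserved(self, rng):
        sched = DiffusionSchedule.linear(5)
        e0 = rng.normal(size=(2, 8, 4, 4))
        assert forward_diffuse(e0, sched, 3, rng).shape == e0.shape

    def test_moments_match_monte_carlo(self):
        """At α_t = 0.75 with e₀ ≡ 2: mean → 1.5, variance → 0.25, each
        within 3 standard errors over 10⁴ scalar draws."""
        sched = DiffusionSchedule(np.array([0.75]))
        rng = np.random.default_rng(7)
        n = 10_000
        draws = np.array([forward_diffuse(np.array([2.0]), sched, 1, rng)[0]
                          for _ in range(n)])
        se_mean = np.sqrt(0.25 / n)
        se_var = 0.25 * np.sqrt(2.0 / (n - 1))
        assert abs(draws.mean() - 1.5) < 3 * se_mean
        assert abs(draws.var(ddof=1) - 0.25) < 3 * se_var

    def test_out_of_range_timestep_rejected(self, rng):
        sched = DiffusionSchedule.linear(5)
        with pytest.raises(ValueError):
            forward_diffuse(np.zeros((2, 2, 2)), sched, 6, rng)

    def test_sqrt_cumulative_convention_differs(self, rng):
        sched = DiffusionSchedule.linear(3, 0.9, 0.7)
        e0 = np.full((1, 2, 2), 4.0)
        r1 = forward_diffuse(e0, sched, 3, np.random.default_rng(0))
        r2 = forward_diffuse(e0, sched, 3, np.random.default_rng(0),
                             convention="sqrt_cumulative")
        assert not np.allclose(r1, r2)


class TestReverseStep:
    def test_shapes_finite_and_eta_positive(self, rng):
        cfg = tiny_diff_config()
        net = ReconstructionNet(cfg, rng)
        e = rng.normal(size=(cfg.dim, cfg.grid_size, cfg.grid_size))
        mu, eta = reverse_step(e, 2, net)
        assert mu.shape == e.shape and eta.shape == e.shape
        assert np.isfinite(mu.numpy()).all()
        assert (eta.numpy() > 0).all()

    def test_deterministic_in_inference(self, rng):
        cfg = tiny_diff_config()
        net = ReconstructionNet(cfg, rng)
        e = rng.normal(size=(cfg.dim, cfg.grid_size, cfg.grid_size))
        with no_grad():
            a = reverse_step(e, 1, net)[0].numpy()
            b = reverse_step(e, 1, net)[0].numpy()
        assert np.array_equal(a, b)


class TestReconstruct:
    def test_single_step_equals_reverse_step(self, rng):
        cfg = tiny_diff_config(T=1)
        net = ReconstructionNet(cfg, rng)
        sched = DiffusionSchedule(np.array([0.8]))
        e1 = rng.normal(size=(cfg.dim, cfg.grid_size, cfg.grid_size))
        with no_grad():
            full = reconstruct(e1, sched, net).numpy()
            single = reverse_step(e1, 1, net)[0].numpy()
        assert np.array_equal(full, single)

    def test_shape_preserved(self, rng):
        cfg = tiny_diff_config()
        net = ReconstructionNet(cfg, rng)
        sched = cfg.schedule()
        e = rng.normal(size=(2, cfg.dim, cfg.grid_size, cfg.grid_size))
        with no_grad():
            assert reconstruct(e, sched, net).shape == e.shape

    def test_training_reduces_reconstruction_error(self, rng):
        """Short training-run oracle: after fitting the net on trajectories
        of one fixed feature map, reconstruction error to it drops."""
        cfg = tiny_diff_config()
        sched = cfg.schedule()
        net = ReconstructionNet(cfg, rng)
        target = rng.normal(size=(1, cfg.dim, cfg.grid_size, cfg.grid_size))

        def recon_err(n):
            with no_grad():
                eT = forward_diffuse(target, sched, cfg.T,
                                     np.random.default_rng(0))
                rec = reconstruct(eT, sched, n).numpy()
            return float(((rec - target) ** 2).sum())

        before = recon_err(net)
        opt = Adam(net.parameters(), lr=1e-3)
        for i in range(200):
            traj = forward_trajectory(target, sched,
                                      np.random.default_rng(i))
            loss = diffusion_loss(traj, net)
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert recon_err(net) < before


class TestDiffusionLoss:
    def test_perfect_predictor_gives_zero(self, rng):
        """Oracle net that looks up e_{t−1} exactly → loss 0."""
        cfg = tiny_diff_config()
        sched = cfg.schedule()
        e0 = rng.normal(size=(cfg.dim, cfg.grid_size, cfg.grid_size))
        traj = forward_trajectory(e0, sched, rng)

        class LookupNet:
            config = cfg

            def forward(self, e_t, t):
                return Tensor(traj[t - 1]), Tensor(np.ones_like(traj[t - 1]))

            __call__ = forward

        assert diffusion_loss(traj, LookupNet()).item() == pytest.approx(0.0)

    def test_matches_term_by_term_summation(self, rng):
        cfg = tiny_diff_config()
        sched = cfg.schedule()
        net = ReconstructionNet(cfg, rng)
        e0 = rng.normal(size=(cfg.dim, cfg.grid_size, cfg.grid_size))
        traj = forward_trajectory(e0, sched, rng)
        loss = diffusion_loss(traj, net).item()
        brute = 0.0
        for t in range(1, len(traj)):
            with no_grad():
                mu, _ = reverse_step(traj[t], t, net)
            brute += float(((traj[t - 1] - mu.numpy()) ** 2).sum())
        assert loss == pytest.approx(brute, rel=1e-6)
        assert loss >= 0

    def test_length_mismatch_rejected(self, rng):
        cfg = tiny_diff_config()
        net = ReconstructionNet(cfg, rng)
        with pytest.raises(ValueError):
            diffusion_loss([np.zeros((cfg.dim, 4, 4))] * (cfg.T), net)


class TestFeatureCovariance:
    def test_constant_map_gives_zero_matrix(self):
        e = np.full((3, 4, 4), 2.5)
        assert feature_covariance(e) == pytest.approx(np.zeros((3, 3)))

    def test_two_position_hand_case(self):
        """Positions (1,0) and (−1,0) in C=2 → Σ = diag(1, 0)."""
        e = np.zeros((2, 1, 2))
        e[0, 0, 0], e[0, 0, 1] = 1.0, -1.0
        assert feature_covariance(e) == pytest.approx(np.diag([1.0, 0.0]))

    def test_symmetric_psd_eigen_oracle(self, rng):
        for _ in range(20):
            e = rng.normal(size=(6, 5, 5))
            cov = feature_covariance(e)
            assert cov == pytest.approx(cov.T)
            assert np.linalg.eigvalsh(cov).min() >= -1e-8

    def test_single_position_rejected(self):
        with pytest.raises(ValueError):
            feature_covariance(np.ones((3, 1, 1)))


def random_psd(rng, c=5):
    a = rng.normal(size=(c, c))
    return a @ a.T / c


class TestStructuralDistance:
    def test_identical_symmetric_gives_zero(self, rng):
        s = random_psd(rng)
        assert structural_distance(s, s) == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_diagonal_supports_give_one(self):
        assert structural_distance(np.diag([1.0, 0.0]), np.diag([0.0, 1.0])) \
            == pytest.approx(1.0)

    def test_symmetric_bounded_brute_force(self, rng):
        """1000 random PSD pairs: D ∈ [0,1], D(a,b)=D(b,a), and equals the
        brute-force trace/Frobenius computation."""
        for _ in range(1000):
            a, b = random_psd(rng), random_psd(rng)
            d = structural_distance(a, b)
            brute = 1.0 - np.sum(a * b.T) / (
                np.sqrt((a * a).sum()) * np.sqrt((b * b).sum()))
            assert d == pytest.approx(brute, abs=1e-12)
            assert -1e-12 <= d <= 1.0 + 1e-12
            assert d == pytest.approx(structural_distance(b, a), abs=1e-12)

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            structural_distance(np.zeros((3, 3)), np.eye(3))


class TestFiltering:
    def test_identical_maps_kept(self, rng):
        e = rng.normal(size=(4, 4, 4))
        keep, d = filter_pair(e, e, FilterConfig(delta=0.1, delta_mode="fixed"))
        assert keep and d == pytest.approx(0.0, abs=1e-12)

    def test_zero_delta_rejects_positive_distance(self, rng):
        e1 = rng.normal(size=(4, 4, 4))
        e2 = rng.normal(size=(4, 4, 4))
        keep, d = filter_pair(e1, e2, FilterConfig(delta=0.0,
                                                   delta_mode="fixed"))
        assert d > 0 and not keep

    def test_threshold_scan_oracle(self):
        """Distances {0.1, 0.3, 0.9} at fixed δ=0.5 → first two retained."""
        mask = filter_batch(np.array([0.1, 0.3, 0.9]),
                            FilterConfig(delta=0.5, delta_mode="fixed"))
        assert mask.tolist() == [1.0, 1.0, 0.0]
        # independent scan
        assert [d < 0.5 for d in (0.1, 0.3, 0.9)] == [bool(m) for m in mask]

    def test_retention_monotone_in_delta(self, rng):
        dists = rng.uniform(0, 1, size=50)
        kept_sets = []
        for delta in (0.2, 0.5, 0.8):
            mask = filter_batch(dists, FilterConfig(delta=delta,
                                                    delta_mode="fixed"))
            kept_sets.append({i for i, m in enumerate(mask) if m})
        assert kept_sets[0] <= kept_sets[1] <= kept_sets[2]

    def test_batch_quantile_retains_expected_fraction(self, rng):
        dists = rng.uniform(0, 1, size=100)
        mask = filter_batch(dists, FilterConfig(delta_mode="batch-quantile",
                                                delta_quantile=0.8))
        assert mask.sum() == pytest.approx(80, abs=1)


class TestSemanticSensitivity:
    def test_extreme_cutout_raises_structural_distance(self):
        """Over 100 synthetic pairs through an untrained-but-fixed encoder,
        pairs where one view lost ~60% of its content to occlusion must have
        stochastically larger D_struct than mildly augmented pairs."""
        from cropclr.contrastive import ContrastiveConfig, Encoder, \
            images_to_tensor
        from cropclr.synthetic import SyntheticDatasetSpec, \
            generate_synthetic_image
        from cropclr.synthetic import ImageSample
        from scipy import ndimage

        cfg = ContrastiveConfig(backbone_profile="tiny", tiny_width=8,
                                input_size=32, proj_in=32, proj_hidden=32,
                                embed_dim=16, grid_channels=16, grid_size=4,
                                queue_capacity=8)
        enc = Encoder(cfg, np.random.default_rng(0))
        spec = SyntheticDatasetSpec(n_classes=2, per_class_count=50,
                                    image_size=32, seed=9)
        rng = np.random.default_rng(1)

        def grid_of(samples):
            with no_grad():
                _, g = enc(images_to_tensor(samples))
            return g.numpy()

        mild_d, harsh_d = [], []
        for i in range(100):
            img = generate_synthetic_image(i % 2, spec, seed=i)
            px = img.pixels.astype(float)
            rot = ndimage.rotate(px, rng.uniform(-10, 10), axes=(0, 1),
                                 reshape=False, mode="reflect", order=1)
            mild = ImageSample(np.clip(rot, 0, 255).astype(np.uint8),
                               img.label, img.source_id)
            occ = img.pixels.copy()
            side = int(0.78 * 32)
            occ[:side, :side] = 128
            harsh = ImageSample(occ, img.label, img.source_id)
            g = grid_of([img, mild, harsh])
            mild_d.append(pair_structural_distance(g[0], g[1]))
            harsh_d.append(pair_structural_distance(g[0], g[2]))
        assert np.mean(harsh_d) > np.mean(mild_d)
        assert np.median(harsh_d) > np.median(mild_d)


class TestJointLoss:
    def test_lambda_zero_is_contrastive_only(self):
        assert joint_pretrain_loss(2.5, 99.0, 0.0) == 2.5

    def test_default_lambda_is_half(self):
        assert FilterConfig().lam == 0.5

    def test_arithmetic(self):
        assert joint_pretrain_loss(2.0, 3.0, 0.5) == pytest.approx(3.5)
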