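import numpy as np
import pytest
from scipy.constants import epsilon_0

from ferropyro import domains, fields, fixtures, landau, materials, tdgl


class TestInitializeField:
    def test_zero_amplitude_random_is_zero(self, small_grid):
        f = tdgl.initialize_field(small_grid, mode="random", amplitude=0.0, seed=3)
        assert np.all(f.vectors == 0.0)

    def test_same_seed_bit_identical(self, small_grid):
        a = tdgl.initialize_field(small_grid, mode="random", seed=9)
        b = tdgl.initialize_field(small_grid, mode="random", seed=9)
        assert np.array_equal(a.vectors, b.vectors)

    def test_uniform_mode(self, small_grid):
        f = tdgl.initialize_field(small_grid, mode="uniform", uniform_value=(0.0, 0.0, 0.2))
        assert np.all(f.vectors == np.array([0.0, 0.0, 0.2]))

    def test_variant_mix_directions_are_canonical(self, small_grid):
        f = tdgl.initialize_field(small_grid, mode="seeded-variant-mix", amplitude=0.2, seed=4)
        norms = f.magnitudes()
        assert np.allclose(norms, 0.2)


class TestGridValidation:
    @pytest.mark.parametrize("shape", [(7, 8), (8, 9), (4, 4), (8,)])
    def test_bad_shapes_rejected(self, shape):
        with pytest.raises(ValueError):
            fields.SimulationGrid(shape)

    def test_3d_grid_accepted(self):
        grid = fields.SimulationGrid((8, 8, 8), spacing=1e-9)
        assert grid.dimensions == 3


class TestEnergies:
    def test_zero_field_zero_total(self, small_grid):
        config = tdgl.TdglConfig(material="btz")
        f = tdgl.initialize_field(small_grid, mode="uniform", uniform_value=(0, 0, 0), temperature=273.0)
        breakdown = tdgl.total_free_energy(f, config)
        assert breakdown.total == 0.0

    def test_uniform_field_has_no_gradient_or_elastic_energy(self, small_grid):
        """A uniform state is stress-free under zero mean stress, so only
        the bulk term survives with electrostatics off."""
        config = tdgl.TdglConfig(material="btz", electrostatic_mode="off")
        f = tdgl.initialize_field(
            small_grid, mode="uniform", uniform_value=(0.1, 0.05, 0.02), temperature=273.0
        )
        breakdown = tdgl.total_free_energy(f, config)
        coeffs = materials.coefficients_at("btz", 273.0)
        assert breakdown.gradient == pytest.approx(0.0, abs=1e-6)
        assert breakdown.elastic == pytest.approx(0.0, abs=1e-6)
        assert breakdown.total == pytest.approx(
            float(landau.bulk_energy(np.array([0.1, 0.05, 0.02]), coeffs)), rel=1e-12
        )

    @pytest.mark.parametrize("component,expected_g", [(0, "g11"), (1, "2*g44")])
    def test_single_mode_gradient_energy_closed_form(self, small_grid, component, expected_g):
        """A single Fourier mode has gradient energy (1/2) G_eff k^2 <P^2>:
        G11 for the longitudinal component, 2*G44 for a transverse one."""
        config = tdgl.TdglConfig(material="btz", electrostatic_mode="off")
        config.elastic = tdgl.ElasticSet(enabled=False)
        n = small_grid.shape[0]
        x = np.arange(n)
        amplitude, mode = 0.07, 3
        k = 2 * np.pi * mode / (n * small_grid.spacing)
        vectors = np.zeros((*small_grid.shape, 3))
        vectors[..., component] = (amplitude * np.cos(2 * np.pi * mode * x / n))[:, None]
        f = fields.PolarizationField(grid=small_grid, vectors=vectors, temperature=273.0)
        g = config.gradient
        g_eff = g.g11 if expected_g == "g11" else 2 * g.g44
        expected = 0.5 * g_eff * k**2 * amplitude**2 / 2
        assert tdgl.total_free_energy(f, config).gradient == pytest.approx(expected, rel=1e-10)


class TestDepolarizationField:
    def test_uniform_field_zero_under_short_circuit(self, small_grid):
        f = tdgl.initialize_field(small_grid, mode="uniform", uniform_value=(0.1, 0.0, 0.0))
        assert np.max(np.abs(tdgl.depolarization_field(f))) == 0.0

    def test_transverse_mode_no_depolarization(self, small_grid):
        n = small_grid.shape[0]
        x = np.arange(n)
        vectors = np.zeros((*small_grid.shape, 3))
        vectors[..., 1] = (0.1 * np.cos(2 * np.pi * 3 * x / n))[:, None]  # div-free
        f = fields.PolarizationField(grid=small_grid, vectors=vectors)
        assert np.max(np.abs(tdgl.depolarization_field(f))) == pytest.approx(0.0, abs=1e-18)

    def test_head_to_head_wall_matches_1d_closed_form(self, small_grid):
        """In 1-D the bound-charge solution is E = -(P - <P>)/(eps0 epsb)."""
        n = small_grid.shape[0]
        x = np.arange(n)
        vectors = np.zeros((*small_grid.shape, 3))
        vectors[..., 0] = np.where(x < n // 2, 0.2, -0.2)[:, None]
        f = fields.PolarizationField(grid=small_grid, vectors=vectors)
        eps_b = 50.0
        E = tdgl.depolarization_field(f, background_permittivity=eps_b)
        expected = -(vectors[..., 0] - vectors[..., 0].mean()) / (epsilon_0 * eps_b)
        assert np.max(np.abs(E[..., 0] - expected)) <= 1e-6 * np.max(np.abs(expected))
        assert np.max(np.abs(E[..., 1:])) <= 1e-12

    def test_open_circuit_recovers_mean_depolarization(self, small_grid):
        f = tdgl.initialize_field(small_grid, mode="uniform", uniform_value=(0.1, 0.0, 0.0))
        E = tdgl.depolarization_field(f, background_permittivity=50.0, open_circuit=True)
        assert E[..., 0] == pytest.approx(-0.1 / (epsilon_0 * 50.0))


class TestEvolve:
    def test_zero_field_is_fixed_point(self, small_grid):
        config = tdgl.TdglConfig(material="btz")
        f = tdgl.initialize_field(small_grid, mode="uniform", uniform_value=(0, 0, 0), temperature=273.0)
        out = tdgl.evolve(f, config, 50)
        assert np.all(out.vectors == 0.0)
        assert out.step_count == 50

    @pytest.mark.parametrize("material", ["btz", "bto"])
    @pytest.mark.parametrize("temperature", [273.0, 288.0, 298.0])
    def test_uniform_trajectory_matches_0d_euler_oracle(self, small_grid, material, temperature):
        """With a spatially uniform state the spectral update must reduce
        exactly to 0-D relaxation of the bulk force; the oracle is an
        independent scalar integration with the same first-order step."""
        config = tdgl.TdglConfig(material=material)
        start = np.array([0.05, 0.02, 0.08])
        f = tdgl.initialize_field(small_grid, mode="uniform", uniform_value=start, temperature=temperature)
        steps = 300
        out = tdgl.evolve(f, config, steps)
        coeffs = materials.coefficients_at(material, temperature)
        kappa = landau.bulk_curvature_scale(coeffs)
        P = start.copy()
        for _ in range(steps):
            P = P - config.dt / kappa * landau.bulk_energy_derivative(P, coeffs)
        assert np.max(np.abs(out.vectors - P)) <= 1e-6 * max(np.max(np.abs(P)), 1e-3)

    def test_determinism(self, small_grid):
        defect = fixtures.make_defect_field(small_grid.shape, seed=5)
        config = tdgl.TdglConfig(material="btz", defect_field=defect)
        f = fixtures.make_random_field(small_grid.shape, seed=5, temperature=273.0)
        a = tdgl.evolve(f, config, 100)
        b = tdgl.evolve(f, config, 100)
        assert np.array_equal(a.vectors, b.vectors)

    def test_lyapunov_energy_decrease(self, small_grid):
        """Domain-averaged free energy is non-increasing under static
        applied and defect fields, at dt half the documented bound."""
        for seed in range(10):
            defect = fixtures.make_defect_field(small_grid.shape, seed=seed)
            config = tdgl.TdglConfig(
                material="btz", dt=tdgl.DT_STABILITY_BOUND / 2, defect_field=defect,
                applied_field=np.array([1e5, 0.0, 0.0]),
            )
            f = fixtures.make_random_field(small_grid.shape, amplitude=0.1, seed=seed, temperature=273.0)
            previous = tdgl.total_free_energy(f, config).total
            for _ in range(8):
                f = tdgl.evolve(f, config, 25)
                current = tdgl.total_free_energy(f, config).total
                assert current <= previous + 1e-8 * abs(previous)
                previous = current

    def test_divergence_raises_helpful_error(self, small_grid):
        config = tdgl.TdglConfig(material="btz", dt=500.0)  # far above the bound
        f = fixtures.make_random_field(small_grid.shape, amplitude=0.1, seed=1, temperature=273.0)
        with pytest.raises(tdgl.DivergenceError, match="dt"):
            tdgl.evolve(f, config, 200)

    def test_converged_random_start_is_multivariant(self, relaxed_btz_273):
        """A defect-seeded quench at 273 K develops coexisting nanoscale
        variants rather than a single domain."""
        field, _ = relaxed_btz_273
        vmap = domains.classify_field(field, threshold=domains.default_threshold("btz", 273.0))
        report = domains.phase_fractions(vmap)
        assert report.n_variant_classes >= 2
        assert report.fractions["para"] < 0.5

    def test_mesh_refinement_energy_stable(self):
        """Halving dx on a relaxed 1-D transverse wall changes the
        domain-averaged energy by < 2%."""
        energies = []
        for n, spacing in ((64, 1e-9), (128, 0.5e-9)):
            grid = fields.SimulationGrid((n, 8), spacing=spacing)
            x = np.arange(n)
            vectors = np.zeros((n, 8, 3))
            coeffs = materials.coefficients_at("btz", 273.0)
            p0 = landau.minimize_phase("T", coeffs).component_magnitude
            vectors[..., 2] = np.where((x > n // 4) & (x <= 3 * n // 4), p0, -p0)[:, None]
            f = fields.PolarizationField(grid=grid, vectors=vectors, temperature=273.0)
            config = tdgl.TdglConfig(material="btz", electrostatic_mode="off")
            config.elastic = tdgl.ElasticSet(enabled=False)
            f = tdgl.evolve(f, config, 1500)
            energies.append(tdgl.total_free_energy(f, config).total)
        ref = abs(energies[0])
        assert abs(energies[1] - energies[0]) < 0.02 * ref


class TestElasticSet:
    def test_stiffness_is_compliance_inverse(self):
        elastic = tdgl.ElasticSet()
        c11, c12, c44 = elastic.stiffness()
        S = elastic.compliance_matrix()
        C = np.diag([c11] * 3 + [c44] * 3)
        C[:3, :3] += c12 * (1 - np.eye(3))
        assert np.allclose(C @ S, np.eye(6), atol=1e-9)

    def test_singular_compliance_rejected(self):
        bad = tdgl.ElasticSet(s11=1e-12, s12=-0.5e-12, s44=1e-12)  # s11 + 2 s12 = 0
        with pytest.raises(np.linalg.LinAlgError):
            bad.stiffness()


class TestHysteresis:
    def test_sweep_is_triangular_and_closed(self):
        sweep = tdgl.triangular_sweep(1.0, 10)
        assert sweep[0] == 0.0
        assert sweep.max() == 1.0 and sweep.min() == -1.0
        assert sweep[-1] == 1.0
        assert np.allclose(np.abs(np.diff(sweep)), 0.1)

    def test_subcoercive_sweep_is_quasi_reversible(self, small_grid):
        """Far below coercivity a single-domain loop encloses ~no area."""
        coeffs = materials.coefficients_at("btz", 273.0)
        p0 = landau.minimize_phase("T", coeffs, allow_metastable=True).component_magnitude
        f = tdgl.initialize_field(
            small_grid, mode="uniform", uniform_value=(p0, 0.0, 0.0), temperature=273.0
        )
        config = tdgl.TdglConfig(material="btz")
        loop = tdgl.run_hysteresis(f, config, component=0, max_field=2e5, n_steps=8, equilibration_steps=300)
        E, P = loop.loop()
        box = np.ptp(E) * np.ptp(P)
        assert abs(np.trapezoid(P, E)) < 0.05 * box

    def test_full_loop_antisymmetric_and_closed(self):
        """A fully poled defect-free sweep is antisymmetric under
        (E, P) -> (-E, -P) within 2% of saturation, and closes."""
        grid = fields.SimulationGrid((24, 24), spacing=1e-9)
        config = tdgl.TdglConfig(material="btz")
        f = fixtures.make_random_field(grid.shape, amplitude=0.1, seed=1, temperature=273.0)
        f = tdgl.evolve(f, config, 600)
        loop = tdgl.run_hysteresis(f, config, component=0, max_field=3e7, n_steps=8, equilibration_steps=500)
        (Ed, Pd), (Ea, Pa) = loop.branches()
        sat = loop.saturation_polarization()
        assert np.allclose(Ed, -Ea)  # branch fields are exact negatives
        assert np.max(np.abs(Pd + Pa)) <= 0.02 * sat
        E, P = loop.loop()
        assert loop.is_closed
        assert abs(P[0] - P[-1]) <= 0.02 * sat

    def test_saturation_matches_single_domain_landau_state(self):
        """At max field the loop saturation approaches the single-domain
        value from relaxing a uniform state in the same field."""
        grid = fields.SimulationGrid((24, 24), spacing=1e-9)
        config = tdgl.TdglConfig(material="btz")
        f = fixtures.make_random_field(grid.shape, amplitude=0.1, seed=2, temperature=273.0)
        f = tdgl.evolve(f, config, 600)
        loop = tdgl.run_hysteresis(f, config, component=0, max_field=3e7, n_steps=8, equilibration_steps=400)
        uniform = tdgl.initialize_field(grid, mode="uniform", uniform_value=(0.05, 0.04, 0.03), temperature=273.0)
        poled = tdgl.evolve(
            uniform,
            tdgl.TdglConfig(material="btz", applied_field=np.array([3e7, 0.0, 0.0])),
            3000,
        )
        single = poled.mean_polarization()[0]
        assert loop.saturation_polarization() == pytest.approx(single, rel=0.05)


class TestFieldIO:
    def test_hdf5_roundtrip(self, tmp_path, small_grid):
        f = fixtures.make_random_field(small_grid.shape, seed=8, temperature=285.0)
        f = f.with_vectors(f.vectors, extra_steps=42)
        path = tmp_path / "state.h5"
        fields.save_field(path, f)
        loaded = fields.load_field(path)
        assert np.array_equal(loaded.vectors, f.vectors)
        assert loaded.temperature == f.temperature
        assert loaded.seed == f.seed
        assert loaded.step_count == 42
        assert loaded.grid == f.grid
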