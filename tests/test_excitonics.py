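"""Point-dipole couplings, Frenkel Hamiltonians and exciton states."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exciton2des.excitonics import (
    DIPOLE_COUPLING_CONSTANT,
    Chromophore,
    StructureError,
    all_couplings,
    build_hamiltonian,
    diagonalize,
    exciton_gap,
    parse_structure,
    point_dipole_coupling,
    stick_absorption,
)
from conftest import write_synthetic_chl_pdb


def chrom(label, center, qy, mu=4.58, e=15000.0):
    qy = np.asarray(qy, dtype=float)
    return Chromophore(label, center, qy / np.linalg.norm(qy), mu, e)


class TestPointDipoleCoupling:
    def test_parallel_side_by_side(self):
        # both dipoles perpendicular to R: kappa = +1
        a = chrom("a", [0, 0, 0], [0, 0, 1])
        b = chrom("b", [10, 0, 0], [0, 0, 1])
        t = point_dipole_coupling(a, b)
        assert t.kappa == pytest.approx(1.0, abs=1e-12)
        assert t.distance_R == pytest.approx(10.0)
        assert t.V == pytest.approx(DIPOLE_COUPLING_CONSTANT * 4.58**2 / 1000.0)
        assert t.V == pytest.approx(105.6, abs=0.1)

    def test_collinear_head_to_tail(self):
        a = chrom("a", [0, 0, 0], [1, 0, 0])
        b = chrom("b", [10, 0, 0], [1, 0, 0])
        assert point_dipole_coupling(a, b).kappa == pytest.approx(-2.0, abs=1e-12)

    def test_orthogonal_null(self):
        a = chrom("a", [0, 0, 0], [0, 0, 1])
        b = chrom("b", [10, 0, 0], [0, 1, 0])
        t = point_dipole_coupling(a, b)
        assert t.kappa == pytest.approx(0.0, abs=1e-12)
        assert t.V == pytest.approx(0.0, abs=1e-12)

    def test_scaling_laws(self):
        a = chrom("a", [0, 0, 0], [0, 1, 1], mu=3.0)
        b = chrom("b", [8, 1, 2], [1, 0, 1], mu=2.0)
        v0 = point_dipole_coupling(a, b).V
        a2 = chrom("a", a.center, a.qy_unit, mu=6.0)
        b2 = chrom("b", b.center, b.qy_unit, mu=4.0)
        assert point_dipole_coupling(a2, b2).V == pytest.approx(4 * v0, rel=1e-9)
        b3 = chrom("b", a.center + 2 * (b.center - a.center), b.qy_unit, mu=2.0)
        assert point_dipole_coupling(a, b3).V == pytest.approx(v0 / 8, rel=1e-9)

    def test_screening_multiplier(self):
        a = chrom("a", [0, 0, 0], [0, 0, 1])
        b = chrom("b", [10, 0, 0], [0, 0, 1])
        assert point_dipole_coupling(a, b, screening=0.5).V == pytest.approx(
            0.5 * point_dipole_coupling(a, b).V
        )

    def test_coincident_centers_error(self):
        a = chrom("a", [1, 2, 3], [0, 0, 1])
        b = chrom("b", [1, 2, 3], [0, 1, 0])
        with pytest.raises(ValueError, match="coincident"):
            point_dipole_coupling(a, b)

    def test_close_contact_flagged(self):
        a = chrom("a", [0, 0, 0], [0, 0, 1])
        b = chrom("b", [1.5, 0, 0], [0, 0, 1])
        with pytest.warns(UserWarning, match="point-dipole"):
            t = point_dipole_coupling(a, b)
        assert not t.point_dipole_valid

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_kappa_bounds_and_swap_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = chrom("a", rng.normal(size=3), rng.normal(size=3), mu=rng.uniform(1, 8))
        b = chrom(
            "b", rng.normal(size=3) + [12, 0, 0], rng.normal(size=3), mu=rng.uniform(1, 8)
        )
        t_ab = point_dipole_coupling(a, b)
        t_ba = point_dipole_coupling(b, a)
        assert -2.0 - 1e-12 <= t_ab.kappa <= 2.0 + 1e-12
        assert t_ab.V == pytest.approx(t_ba.V, rel=1e-12)
        assert t_ab.distance_R == pytest.approx(t_ba.distance_R, rel=1e-12)


class TestChromophoreValidation:
    def test_non_unit_direction_rejected(self):
        with pytest.raises(ValueError, match="not normalized"):
            Chromophore("a", [0, 0, 0], [0, 0, 2.0], 4.58, 15000.0)

    @pytest.mark.parametrize("mu,e", [(-1.0, 15000.0), (4.58, 0.0)])
    def test_positive_parameters_required(self, mu, e):
        with pytest.raises(ValueError):
            Chromophore("a", [0, 0, 0], [0, 0, 1.0], mu, e)


class TestHamiltonian:
    def test_two_site_matrix(self):
        a = chrom("a", [0, 0, 0], [0, 0, 1], e=15000.0)
        b = chrom("b", [10, 0, 0], [0, 0, 1], e=15000.0)
        model = build_hamiltonian([a, b])
        v = point_dipole_coupling(a, b).V
        assert np.allclose(model.hamiltonian, [[15000.0, v], [v, 15000.0]])

    def test_duplicate_labels_rejected(self):
        a = chrom("x", [0, 0, 0], [0, 0, 1])
        b = chrom("x", [10, 0, 0], [0, 0, 1])
        with pytest.raises(ValueError, match="duplicate"):
            build_hamiltonian([a, b])

    def test_missing_pair_defaults_to_zero_with_notice(self, caplog):
        sites = [
            chrom("a", [0, 0, 0], [0, 0, 1]),
            chrom("b", [10, 0, 0], [0, 0, 1]),
            chrom("c", [0, 10, 0], [0, 0, 1]),
        ]
        terms = [point_dipole_coupling(sites[0], sites[1])]
        with caplog.at_level(logging.INFO, logger="exciton2des.excitonics"):
            model = build_hamiltonian(sites, terms)
        assert model.hamiltonian[0, 2] == 0.0
        assert model.hamiltonian[1, 2] == 0.0
        assert any("defaulting to 0" in r.message for r in caplog.records)

    def test_trace_equals_site_energy_sum(self):
        sites = [
            chrom(f"s{i}", np.array([12.0 * i, 0, 0]), [0, 0, 1], e=14800.0 + 50 * i)
            for i in range(4)
        ]
        model = build_hamiltonian(sites)
        assert np.trace(model.hamiltonian) == pytest.approx(
            sum(c.site_energy for c in sites), abs=1e-6
        )


class TestDiagonalization:
    def test_degenerate_dimer_closed_form(self):
        a = chrom("a", [0, 0, 0], [0, 0, 1], e=15000.0)
        b = chrom("b", [10, 0, 0], [0, 0, 1], e=15000.0)
        model = diagonalize(build_hamiltonian([a, b]))
        v = abs(model.hamiltonian[0, 1])
        assert model.exciton_energies == pytest.approx([15000.0 - v, 15000.0 + v])
        assert exciton_gap(model, 0, 1) == pytest.approx(2 * v)
        assert exciton_gap(model, 1, 0) == pytest.approx(-2 * v)

    def test_dark_state_of_parallel_homodimer(self):
        a = chrom("a", [0, 0, 0], [0, 0, 1], e=15000.0)
        b = chrom("b", [10, 0, 0], [0, 0, 1], e=15000.0)
        model = diagonalize(build_hamiltonian([a, b]))
        strengths = np.sort(model.dipole_strengths)
        assert strengths[0] == pytest.approx(0.0, abs=1e-6)
        assert strengths[1] == pytest.approx(2 * 4.58**2, abs=1e-6)

    def test_eigen_reconstruction(self):
        rng = np.random.default_rng(5)
        sites = [
            chrom(f"s{i}", rng.normal(size=3) * 10 + [40 * i, 0, 0], rng.normal(size=3))
            for i in range(5)
        ]
        model = diagonalize(build_hamiltonian(sites))
        H = model.hamiltonian
        recon = model.exciton_vectors @ np.diag(model.exciton_energies) @ model.exciton_vectors.T
        assert np.linalg.norm(H - recon) < 1e-8 * np.linalg.norm(H)

    def test_dipole_strength_sum_rule_random_models(self):
        # sum_k |d_k|^2 == sum_i mu_i^2 for random Hamiltonians of size 2-8
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(2, 9))
            mus = rng.uniform(1.0, 8.0, size=n)
            sites = [
                chrom(f"s{i}", rng.normal(size=3) * 20 + [50 * i, 0, 0],
                      rng.normal(size=3), mu=mus[i], e=rng.uniform(14000, 16000))
                for i in range(n)
            ]
            model = diagonalize(build_hamiltonian(sites))
            assert model.dipole_strengths.sum() == pytest.approx(
                np.sum(mus**2), abs=1e-6
            )

    def test_uncoupled_dimers_spectrum_is_union(self):
        # zeroing inter-dimer couplings makes the 4x4 spectrum the union of
        # the two 2x2 spectra exactly
        sites = [
            chrom("a1", [0, 0, 0], [0, 0, 1], e=15000.0),
            chrom("a2", [9, 0, 0], [0, 1, 1], e=15020.0),
            chrom("b1", [0, 30, 0], [1, 0, 1], e=14950.0),
            chrom("b2", [9, 30, 0], [0, 0, 1], e=14980.0),
        ]
        terms = [
            t
            for t in all_couplings(sites)
            if {t.pair[0][0], t.pair[1][0]} in ({"a"}, {"b"})
        ]
        model4 = diagonalize(build_hamiltonian(sites, terms))
        e_union = []
        for pair in (sites[:2], sites[2:]):
            sub = diagonalize(build_hamiltonian(pair, all_couplings(pair)))
            e_union.extend(sub.exciton_energies)
        assert np.allclose(np.sort(e_union), model4.exciton_energies, atol=1e-10)

    def test_weakly_coupled_dimers_split_in_pairs(self):
        # strong intradimer V, weak interdimer terms: two nearly degenerate
        # pairs separated by ~2V, matching the exact 4x4 eigenvalues
        e0, v, w = 15000.0, 100.0, 5.0
        H = np.array(
            [
                [e0, v, w, w],
                [v, e0, w, w],
                [w, w, e0, v],
                [w, w, v, e0],
            ]
        )
        sites = [chrom(f"s{i}", [12.0 * i, 0, 0], [0, 0, 1]) for i in range(4)]
        model = diagonalize(build_hamiltonian(sites, []))
        model.hamiltonian[:] = H
        model = diagonalize(model)
        exact = np.linalg.eigvalsh(H)
        assert np.allclose(model.exciton_energies, exact)
        e = model.exciton_energies
        assert abs(e[1] - e[0]) < 0.5 * v
        assert abs(e[3] - e[2]) < 0.5 * v
        assert e[2] - e[1] == pytest.approx(2 * v, rel=0.15)

    def test_gap_index_errors(self):
        a = chrom("a", [0, 0, 0], [0, 0, 1])
        b = chrom("b", [10, 0, 0], [0, 0, 1])
        model = diagonalize(build_hamiltonian([a, b]))
        with pytest.raises(IndexError):
            exciton_gap(model, 0, 2)
        with pytest.raises(ValueError):
            exciton_gap(model, 1, 1)

    def test_nonsymmetric_hamiltonian_rejected(self):
        a = chrom("a", [0, 0, 0], [0, 0, 1])
        b = chrom("b", [10, 0, 0], [0, 0, 1])
        model = build_hamiltonian([a, b])
        model.hamiltonian[0, 1] += 1.0
        with pytest.raises(ValueError, match="symmetric"):
            diagonalize(model)


class TestStickAbsorption:
    def test_single_site_band_at_site_energy(self):
        model = diagonalize(build_hamiltonian([chrom("a", [0, 0, 0], [0, 0, 1], e=15000.0)], []))
        axis, intensity = stick_absorption(model, broadening_fwhm=100.0)
        assert axis[np.argmax(intensity)] == pytest.approx(15000.0, abs=1.0)

    def test_area_conserved_across_broadening(self):
        a = chrom("a", [0, 0, 0], [0, 0, 1], e=15000.0)
        b = chrom("b", [10, 0, 0], [0, 1, 0], e=15100.0)
        model = diagonalize(build_hamiltonian([a, b]))
        axis = np.linspace(13000, 17000, 8000)
        areas = [
            np.trapezoid(stick_absorption(model, fwhm, axis=axis)[1], axis)
            for fwhm in (50.0, 200.0)
        ]
        assert areas[0] == pytest.approx(areas[1], rel=1e-6)

    def test_dark_state_gives_single_band(self):
        a = chrom("a", [0, 0, 0], [0, 0, 1], e=15000.0)
        b = chrom("b", [10, 0, 0], [0, 0, 1], e=15000.0)
        model = diagonalize(build_hamiltonian([a, b]))
        axis = np.linspace(14000, 16000, 4000)
        _, intensity = stick_absorption(model, 60.0, axis=axis)
        bright = model.exciton_energies[np.argmax(model.dipole_strengths)]
        dark = model.exciton_energies[np.argmin(model.dipole_strengths)]
        i_bright = intensity[np.argmin(np.abs(axis - bright))]
        i_dark = intensity[np.argmin(np.abs(axis - dark))]
        assert i_dark < 1e-3 * i_bright

    def test_nonpositive_broadening_rejected(self):
        model = diagonalize(build_hamiltonian([chrom("a", [0, 0, 0], [0, 0, 1])], []))
        with pytest.raises(ValueError):
            stick_absorption(model, 0.0)


class TestParseStructure:
    def test_four_pigments_with_unit_directions(self, two_dimer_pdb):
        chroms = parse_structure(two_dimer_pdb)
        assert len(chroms) == 4
        for c in chroms:
            assert np.linalg.norm(c.qy_unit) == pytest.approx(1.0, abs=1e-9)
            assert c.dipole_magnitude == pytest.approx(4.58)

    def test_two_close_pairs_geometry(self, two_dimer_pdb):
        chroms = parse_structure(two_dimer_pdb)
        centers = np.array([c.center for c in chroms])
        d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
        intra = [d[0, 1], d[2, 3]]
        inter = [d[0, 2], d[0, 3], d[1, 2], d[1, 3]]
        assert max(intra) < min(inter)

    def test_missing_atom_names_residue(self, tmp_path):
        path = tmp_path / "broken.pdb"
        write_synthetic_chl_pdb(
            path, mg_positions=[[0, 0, 0], [9, 0, 0]], drop_atom=(1, "ND")
        )
        with pytest.raises(StructureError, match=r"CLA 101.*ND"):
            parse_structure(path)

    def test_no_pigments_found(self, two_dimer_pdb):
        with pytest.raises(StructureError, match="no pigments found"):
            parse_structure(two_dimer_pdb, pigment_selector={"BCL"})
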