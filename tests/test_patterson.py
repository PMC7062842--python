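"""Diffuse Patterson construction, model route and comparisons."""

import dataclasses

import numpy as np
import pytest

from diffusekit.crystal import UnitCell
from diffusekit.dynamics import assemble_hessian, compute_covariances
from diffusekit.internal import assign_couplings, build_projected_hessian
from diffusekit.maps import MASK_MISSING, MASK_OK, ReciprocalMap
from diffusekit.network import build_internal_network
from diffusekit.patterson import (
    _pad_and_fft,
    experimental_patterson,
    fill_missing_voxels,
    model_patterson,
    patterson_reciprocal_cc,
    patterson_shell_stats,
)
from diffusekit.scattering import ScatteringAtoms, one_phonon_map

ALL_SHIFTS = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]


def _small_map(value=0.0, subdivisions=(2, 2, 2), hkl_max=(1, 1, 1)):
    cell = UnitCell(20.0, 22.0, 24.0, 90, 90, 90)
    rmap = ReciprocalMap.empty(cell, subdivisions, hkl_max)
    rmap.intensity[:] = value
    rmap.mask[:] = MASK_OK
    return rmap


class TestExperimentalPatterson:
    def test_fft_matches_direct_double_sum(self):
        """Tiny 5^3 map: the FFT route equals the direct Fourier sum."""
        rmap = _small_map()
        rng = np.random.default_rng(0)
        rmap.intensity = rng.uniform(0, 1, rmap.shape)
        # symmetrize (Friedel) so the Patterson is real
        rmap.intensity = 0.5 * (rmap.intensity + rmap.intensity[::-1, ::-1, ::-1])
        divisions = (4, 4, 4)
        p = _pad_and_fft(rmap, rmap.intensity, divisions)
        sub = rmap.subdivisions
        vrecip = 1.0 / (rmap.cell.volume * np.prod(sub))
        hkl = rmap.frac_grid().reshape(-1, 3)
        inten = rmap.intensity.ravel()
        npad = [d * s for d, s in zip(divisions, sub)]
        for idx in [(0, 0, 0), (1, 2, 3), (4, 4, 4), (2, 0, 5)]:
            rfrac = np.array([(i - n // 2) / d for i, n, d in
                              zip(idx, p.shape, divisions)])
            direct = vrecip * np.sum(inten * np.cos(2 * np.pi * (hkl @ rfrac)))
            assert np.isclose(p.values[idx], direct, rtol=1e-9, atol=1e-12)

    def test_reciprocal_deltas_give_real_lattice(self):
        """Equal spikes on the reciprocal-lattice nodes transform to peaks on
        the real-space lattice nodes."""
        rmap = _small_map(subdivisions=(4, 4, 4))
        bv = rmap.bragg_voxels()
        inten = np.zeros(rmap.shape)
        inten[bv] = 1.0
        divisions = (8, 8, 8)
        p = _pad_and_fft(rmap, inten, divisions)
        vals = p.values
        ctr = np.array(vals.shape) // 2
        origin = vals[tuple(ctr)]
        lattice_peak = vals[tuple(ctr + np.array(divisions))]  # r = one cell
        off = vals[tuple(ctr + np.array(divisions) // 2)]      # half cell
        assert origin > 0
        assert np.isclose(lattice_peak, origin, rtol=1e-6)
        assert abs(off) < 0.2 * origin

    def test_constant_map_vanishes_off_origin(self):
        rmap = _small_map(value=5.0, subdivisions=(4, 4, 4))
        rmap.smin, rmap.smax = 0.0, 1.0
        p = experimental_patterson(rmap, divisions=(6, 6, 6), ds=0.02)
        vals = np.abs(p.values)
        assert vals.max() < 1e-10 or vals.max() < 1e-6 * 5.0

    def test_centrosymmetric(self):
        rmap = _small_map(subdivisions=(4, 4, 4))
        rng = np.random.default_rng(1)
        rmap.intensity = rng.uniform(0, 1, rmap.shape)
        rmap.intensity = 0.5 * (rmap.intensity + rmap.intensity[::-1, ::-1, ::-1])
        rmap.smax = 1.0
        p = experimental_patterson(rmap, divisions=(6, 6, 6))
        v = p.values
        flip = v[::-1, ::-1, ::-1]
        # centro-symmetry up to the one-voxel offset of the even-sized grid
        core = v[1:, 1:, 1:]
        flipc = np.flip(core)
        assert np.allclose(core, flipc, atol=1e-10 * max(abs(v).max(), 1))

    def test_missing_fill_uses_neighbor_means(self):
        rmap = _small_map(value=2.0, subdivisions=(4, 4, 4))
        rmap.smax = 1.0
        rmap.mask[4, 4, 4] = MASK_MISSING
        rmap.intensity[4, 4, 4] = 0.0
        filled = fill_missing_voxels(rmap)
        assert np.isclose(filled[4, 4, 4], 2.0)

    def test_too_many_missing_errors(self):
        rmap = _small_map(value=1.0, subdivisions=(4, 4, 4))
        rmap.smax = 1.0
        rmap.mask[:] = MASK_MISSING
        with pytest.raises(ValueError):
            fill_missing_voxels(rmap)


@pytest.fixture
def lattice_cov(mini_lattice):
    crystal, network = mini_lattice
    for e in network.edges:
        e.gamma_gauss, e.gamma_dir = 1.0, 0.0
    model = assemble_hessian(network)
    cov = compute_covariances(model, (5, 5, 5), translations=ALL_SHIFTS)
    return crystal, network, model, cov


@pytest.fixture
def internal_cov(mini_lattice):
    crystal, _ = mini_lattice
    net = build_internal_network(crystal, cutoff=30.0)
    assign_couplings(net, {int(r): 0.5 for r in crystal.residues})
    model = build_projected_hessian(net, suppress="molecule")
    cov = compute_covariances(model, (1, 1, 1))
    return net, model, cov


class TestModelPatterson:
    def test_zero_covariance_zero_map(self, mini_lattice):
        crystal, network = mini_lattice
        for e in network.edges:
            e.gamma_gauss = 1e8  # frozen crystal: covariances ~ 0
        model = assemble_hessian(network)
        cov = compute_covariances(model, (3, 3, 3), translations=ALL_SHIFTS)
        atoms = ScatteringAtoms.from_crystal(crystal, adps=cov.adps)
        p = model_patterson(atoms, cov, None, subdivisions=(3, 3, 3),
                            hkl_max=(1, 1, 1), divisions=(8, 8, 8),
                            component="lattice", smax=1.0)
        for e in network.edges:
            e.gamma_gauss = 1.0
        assert np.abs(p.values).max() < 1e-6

    def test_route_equivalence_with_one_phonon_fft(self, lattice_cov):
        """The exact pair-sum Patterson of a lattice model agrees with the
        FFT of its one-phonon map within 5% (shell stddev, 2-10 A)."""
        crystal, network, model, cov = lattice_cov
        atoms = ScatteringAtoms.from_crystal(crystal, adps=cov.adps)
        sub, hmax, divisions = (5, 5, 5), (3, 3, 3), (24, 24, 24)
        p_model = model_patterson(atoms, cov, None, subdivisions=sub,
                                  hkl_max=hmax, divisions=divisions,
                                  component="lattice", smax=1.0, cutoff=29.0)
        rmap = one_phonon_map(model, atoms, sub, hmax)
        rmap.smax = 1.0
        p_fft = experimental_patterson(rmap, divisions=divisions, ds=0.02)
        r, sd_model = patterson_shell_stats(p_model, dr=1.0, rmax=12.0)
        _, sd_fft = patterson_shell_stats(p_fft, dr=1.0, rmax=12.0)
        sel = (r >= 2.0) & (r <= 10.0) & np.isfinite(sd_model) & np.isfinite(sd_fft)
        assert sel.sum() >= 5
        rel = np.abs(sd_model[sel] / sd_fft[sel] - 1.0)
        assert np.max(rel) < 0.05

    def test_additivity_exact(self, lattice_cov, internal_cov):
        """Patterson(lattice) + Patterson(internal) == Patterson(combined)."""
        crystal, network, model, cov = lattice_cov
        _, _, cov_int = internal_cov
        atoms = ScatteringAtoms.from_crystal(
            crystal, adps=cov.adps + cov_int.adps
        )
        kw = dict(subdivisions=(3, 3, 3), hkl_max=(2, 2, 2),
                  divisions=(12, 12, 12), smax=1.0)
        p_l = model_patterson(atoms, cov, cov_int, component="lattice", **kw)
        p_i = model_patterson(atoms, cov, cov_int, component="internal", **kw)
        p_c = model_patterson(atoms, cov, cov_int, component="combined", **kw)
        assert np.allclose(p_l.values + p_i.values, p_c.values,
                           atol=1e-10 * max(np.abs(p_c.values).max(), 1))

    def test_internal_support_bound(self, toy):
        """Internal-only Patterson fluctuations die off beyond the largest
        intramolecular pair distance (plus transform smearing)."""
        crystal, lattice, internal = toy
        for e in lattice.edges:
            e.gamma_gauss = 1e8  # frozen lattice: only internal motion left
        cov_frozen = compute_covariances(
            assemble_hessian(lattice), (3, 3, 3), translations=ALL_SHIFTS
        )
        for e in lattice.edges:
            e.gamma_gauss = 1.0
        assign_couplings(internal, {int(r): 4.0 for r in crystal.residues})
        mint = build_projected_hessian(internal, suppress="molecule")
        cov_int = compute_covariances(mint, (1, 1, 1))
        atoms = ScatteringAtoms.from_crystal(crystal, adps=cov_int.adps)
        p = model_patterson(atoms, cov_frozen, cov_int, component="internal",
                            subdivisions=(3, 3, 3), hkl_max=(4, 4, 4),
                            divisions=(16, 16, 16), smax=1.0)
        rmag = p.r_magnitude()
        pairs = crystal.positions[None] - crystal.positions[:, None]
        rmax_intra = np.linalg.norm(pairs, axis=-1).max()
        inner = (rmag > 1.0) & (rmag < rmax_intra)
        outer = rmag > rmax_intra + 8.0
        assert outer.any()
        assert p.values[outer].std() < 0.1 * p.values[inner].std()


class TestPattersonStatistics:
    def test_zero_map_zero_profile(self):
        rmap = _small_map(subdivisions=(4, 4, 4))
        rmap.smax = 1.0
        p = experimental_patterson(rmap, divisions=(6, 6, 6))
        r, sd = patterson_shell_stats(p, dr=2.0)
        assert np.nanmax(sd) < 1e-12

    def test_combined_exceeds_lattice_at_short_range(self, toy):
        """With internal motion comparable to lattice motion, the combined
        Patterson fluctuations exceed the lattice-only ones at short
        pair distances (the two-scale structure of the signal)."""
        crystal, lattice, internal = toy
        cov = compute_covariances(assemble_hessian(lattice), (3, 3, 3),
                                  translations=ALL_SHIFTS)
        assign_couplings(internal, {int(r): 1.0 for r in crystal.residues})
        mint = build_projected_hessian(internal, suppress="molecule")
        cov_int = compute_covariances(mint, (1, 1, 1))
        atoms = ScatteringAtoms.from_crystal(crystal,
                                             adps=cov.adps + cov_int.adps)
        kw = dict(subdivisions=(3, 3, 3), hkl_max=(3, 3, 3),
                  divisions=(12, 12, 12), smax=1.0)
        p_l = model_patterson(atoms, cov, cov_int, component="lattice", **kw)
        p_c = model_patterson(atoms, cov, cov_int, component="combined", **kw)
        r, sd_l = patterson_shell_stats(p_l, dr=2.0, rmax=10.0)
        _, sd_c = patterson_shell_stats(p_c, dr=2.0, rmax=10.0)
        sel = np.isfinite(sd_l) & np.isfinite(sd_c) & (r > 2.0) & (r < 8.0)
        assert sel.sum() >= 3
        assert np.all(sd_c[sel] > sd_l[sel] * 1.05)

    def test_reciprocal_cc_self_is_one(self, lattice_cov):
        crystal, network, model, cov = lattice_cov
        atoms = ScatteringAtoms.from_crystal(crystal, adps=cov.adps)
        p = model_patterson(atoms, cov, None, subdivisions=(3, 3, 3),
                            hkl_max=(2, 2, 2), divisions=(12, 12, 12),
                            component="lattice", smax=1.0)
        centers, cc = patterson_reciprocal_cc(p, p, r_window=(2.0, 25.0),
                                              ds=0.04, smin=0.02, smax=0.3)
        got = cc[np.isfinite(cc)]
        assert len(got) and np.allclose(got, 1.0, atol=1e-9)

    def test_reciprocal_cc_against_noise_small(self, lattice_cov):
        crystal, network, model, cov = lattice_cov
        atoms = ScatteringAtoms.from_crystal(crystal, adps=cov.adps)
        p = model_patterson(atoms, cov, None, subdivisions=(3, 3, 3),
                            hkl_max=(2, 2, 2), divisions=(12, 12, 12),
                            component="lattice", smax=1.0)
        rng = np.random.default_rng(3)
        noise = dataclasses.replace(
            p, values=rng.standard_normal(p.values.shape) * p.values.std()
        )
        centers, cc = patterson_reciprocal_cc(p, noise, r_window=(2.0, 25.0),
                                              ds=0.04, smin=0.02, smax=0.3)
        got = cc[np.isfinite(cc)]
        assert len(got)
        assert np.mean(np.abs(got)) < 0.3

    def test_grid_mismatch_errors(self, lattice_cov):
        crystal, network, model, cov = lattice_cov
        atoms = ScatteringAtoms.from_crystal(crystal, adps=cov.adps)
        p1 = model_patterson(atoms, cov, None, subdivisions=(3, 3, 3),
                             hkl_max=(1, 1, 1), divisions=(8, 8, 8),
                             component="lattice", smax=1.0)
        p2 = model_patterson(atoms, cov, None, subdivisions=(3, 3, 3),
                             hkl_max=(1, 1, 1), divisions=(10, 10, 10),
                             component="lattice", smax=1.0)
        with pytest.raises(ValueError):
            patterson_reciprocal_cc(p1, p2)
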