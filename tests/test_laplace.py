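"""Radial coordinate: harmonic potential, arc lengths, layers.

Oracles: on a slab between parallel planes the potential is linear and
streamlines are straight (u mid-plane = 0.5, L0 + L1 = thickness); on a
spherical shell (r0, r1) the harmonic potential is
(1/r0 - 1/r)/(1/r0 - 1/r1) while the relative distance is the *linear*
(r - r0)/(r1 - r0) — the two differ, which is exactly why the arc-length
construction matters.
"""

import numpy as np
import pytest

from bullseye_wmh import (LabeledVolume, PhantomSpec, discretize_layers,
                          generate_phantom, relative_distance, solve_laplace,
                          streamline_lengths)
from bullseye_wmh.laplace import radial_frame
from bullseye_wmh.volume import ScalarField

from conftest import make_slab


def radius_grid(shape):
    centre = (np.array(shape) - 1) / 2.0
    gx, gy, gz = np.indices(shape)
    return np.sqrt((gx - centre[0]) ** 2 + (gy - centre[1]) ** 2
                   + (gz - centre[2]) ** 2)


@pytest.fixture(scope="module")
def slab_fields():
    wm, inn, out = make_slab(thickness=10)
    u = solve_laplace(wm, inn, out)
    L0, L1 = streamline_lengths(u)
    d = relative_distance(L0, L1)
    return wm, u, L0, L1, d


@pytest.fixture(scope="module")
def shell_fields(spherical_phantom):
    ph = spherical_phantom
    outer = LabeledVolume((ph.cortex_lobes.grid > 0).astype(np.int16))
    u = solve_laplace(ph.wm, ph.ventricles, outer)
    L0, L1 = streamline_lengths(u)
    d = relative_distance(L0, L1)
    return ph, u, L0, L1, d


class TestPotential:
    def test_slab_potential_linear(self, slab_fields):
        wm, u, *_ = slab_fields
        dom = wm.mask()
        # mid-plane voxels sit at x = 8, 9 -> u = 0.409, 0.5 on an
        # 11-interval ladder; average over both is 0.5 by symmetry
        xs = np.nonzero(dom.any(axis=(1, 2)))[0]
        mid = u.values[xs[4]:xs[5] + 1][:, dom[xs[4]]].mean()
        assert mid == pytest.approx(0.5, abs=1e-3)
        # linearity: u depends only on x, equally spaced
        prof = [u.values[x][dom[x]].mean() for x in xs]
        assert np.allclose(np.diff(prof), np.diff(prof)[0], atol=1e-3)

    def test_shell_potential_matches_harmonic_form(self, shell_fields):
        ph, u, *_ = shell_fields
        r = radius_grid(ph.wm.shape)
        mid = ph.wm.mask() & (np.abs(r - 12) < 0.3)
        # analytic u(12) = (1/8 - 1/12)/(1/8 - 1/16) = 2/3
        assert u.values[mid].mean() == pytest.approx(2 / 3, abs=0.02)

    def test_maximum_principle(self, shell_fields):
        ph, u, *_ = shell_fields
        interior = ph.wm.mask()
        vals = u.values[interior]
        assert vals.min() > 0.0
        assert vals.max() < 1.0

    def test_unreachable_voxels_excluded(self):
        wm, inn, out = make_slab(thickness=6)
        grid = wm.grid.copy()
        grid[0, 0, 0] = 1  # isolated island, no path to either boundary
        u = solve_laplace(LabeledVolume(grid), inn, out)
        assert not u.domain_mask[0, 0, 0]


class TestStreamlines:
    def test_slab_arc_lengths_sum_to_thickness(self, slab_fields):
        wm, _, L0, L1, _ = slab_fields
        total = (L0.values + L1.values)[wm.mask()]
        assert np.all(np.abs(total - 10.0) < 0.5)

    def test_shell_L0_is_distance_from_inner_surface(self, shell_fields):
        ph, _, L0, _, _ = shell_fields
        r = radius_grid(ph.wm.shape)
        mid = ph.wm.mask() & (np.abs(r - 12) < 0.3)
        assert L0.values[mid].mean() == pytest.approx(4.0, abs=0.5)

    def test_lengths_non_negative(self, shell_fields):
        _, _, L0, L1, _ = shell_fields
        assert np.nanmin(L0.values) >= 0
        assert np.nanmin(L1.values) >= 0


class TestRelativeDistance:
    def test_shell_midpoint_is_half(self, shell_fields):
        ph, _, _, _, d = shell_fields
        r = radius_grid(ph.wm.shape)
        mid = ph.wm.mask() & (np.abs(r - 12) < 0.3)
        # d is linear in r (0.5 at r=12) even though u(12) = 2/3
        assert d.values[mid].mean() == pytest.approx(0.5, abs=0.03)

    def test_matches_analytic_oracle(self, shell_fields):
        ph, _, _, _, d = shell_fields
        dom = ph.wm.mask()
        err = np.abs(d.values[dom] - ph.analytic_d.values[dom])
        assert err.mean() < 0.03

    def test_scale_invariance(self):
        """Doubling the geometry leaves d unchanged at matched radii."""
        spec = PhantomSpec(shape=(80, 80, 80), ventricle_radii=(16.,) * 3,
                           wm_outer_radii=(32.,) * 3, include_bgit=False)
        ph = generate_phantom(spec)
        outer = LabeledVolume((ph.cortex_lobes.grid > 0).astype(np.int16))
        u = solve_laplace(ph.wm, ph.ventricles, outer)
        d = relative_distance(*streamline_lengths(u))
        r = radius_grid(spec.shape)
        mid = ph.wm.mask() & (np.abs(r - 24) < 0.3)  # r=24 <-> r=12 at half size
        assert d.values[mid].mean() == pytest.approx(0.5, abs=0.03)

    def test_monotone_in_radius(self, shell_fields):
        ph, _, _, _, d = shell_fields
        r = radius_grid(ph.wm.shape)
        dom = ph.wm.mask()
        means = [d.values[dom & (np.abs(r - rr) < 0.4)].mean()
                 for rr in (9, 11, 13, 15)]
        assert np.all(np.diff(means) > 0)


class TestLayers:
    @pytest.mark.parametrize("dval,layer", [
        (0.1, 1), (0.25, 2), (0.49, 2), (0.5, 3), (0.99, 4), (1.0, 4)])
    def test_binning_convention(self, dval, layer):
        vals = np.full((1, 1, 1), dval)
        fld = ScalarField(vals, np.ones((1, 1, 1), bool))
        assert discretize_layers(fld, 4).labels[0, 0, 0] == layer

    def test_single_layer(self):
        vals = np.random.default_rng(0).uniform(0, 1, (3, 3, 3))
        fld = ScalarField(vals, np.ones((3, 3, 3), bool))
        assert np.all(discretize_layers(fld, 1).labels == 1)

    def test_slab_equipartition(self, slab_fields):
        wm, _, _, _, d = slab_fields
        layers = discretize_layers(d, 4)
        counts = np.bincount(layers.labels[wm.mask()], minlength=5)[1:]
        plane = wm.mask()[wm.mask().any(axis=(1, 2))][0].sum()  # 1 voxel plane
        assert np.all(np.abs(counts - counts.mean()) <= plane)

    def test_potential_method_differs_from_arc_length_on_shell(
            self, spherical_phantom):
        """The raw potential is a biased radial coordinate on curved walls."""
        ph = spherical_phantom
        outer = LabeledVolume((ph.cortex_lobes.grid > 0).astype(np.int16))
        *_, d_pot, _ = radial_frame(ph.wm, ph.ventricles, outer,
                                    method="potential")
        r = radius_grid(ph.wm.shape)
        mid = ph.wm.mask() & (np.abs(r - 12) < 0.3)
        assert d_pot.values[mid].mean() == pytest.approx(2 / 3, abs=0.02)
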