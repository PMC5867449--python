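"""Subject-level pipeline: volumes in, 36-region map and loads out.

The parcellation domain is the union of the white matter and the BGIT
structures (basal ganglia, thalami, infratentorial). The inner boundary
is the full ventricular system; the outer boundary is the domain's outer
surface (the WM/cortical-GM interface where cortex abuts, and each BGIT
structure's own outer boundary elsewhere). Connected components without
any ventricular boundary — typically infratentorial white matter — fall
back to a normalized Euclidean depth coordinate (deepest voxel = 0,
surface = 1), logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .laplace import LayerField, discretize_layers, radial_frame
from .loads import RegionalLoadTable, compute_regional_loads
from .volume import LabeledVolume, ScalarField, check_same_grid
from .zones import RegionMap, ZoneField, assign_lobes, build_region_map, merge_bgit

__all__ = ["ParcellationResult", "parcellate", "subject_loads"]

log = logging.getLogger(__name__)


@dataclass
class ParcellationResult:
    regions: RegionMap
    zones: ZoneField
    layers: LayerField
    u: ScalarField | None
    d: ScalarField
    L0: ScalarField | None = None
    L1: ScalarField | None = None


def _outer_surface(domain: np.ndarray, inner: np.ndarray) -> np.ndarray:
    """Voxels just outside the domain that are not ventricle."""
    struct = ndimage.generate_binary_structure(3, 1)
    return ndimage.binary_dilation(domain, structure=struct) & ~domain & ~inner


def _euclidean_depth(component: np.ndarray, voxel_size) -> np.ndarray:
    """Normalized depth: 1 at the component surface, 0 at its deepest point."""
    dist = ndimage.distance_transform_edt(component, sampling=voxel_size)
    dmax = dist[component].max()
    dmin = dist[component].min()
    if dmax <= dmin:
        return np.where(component, 0.5, np.nan)
    return np.where(component,
                    np.clip((dmax - dist) / (dmax - dmin), 0.0, 1.0), np.nan)


def _radial_for_subdomain(domain: np.ndarray, inner: np.ndarray,
                          forbidden_outer: np.ndarray, vs, affine,
                          method: str, tolerance: float, max_iterations: int,
                          n_layers: int, what: str):
    """Relative-distance field for one subdomain.

    ``forbidden_outer`` marks voxels that may never act as the u = 1
    surface (e.g. BGIT structures when solving the WM frame). Connected
    components without a ventricular boundary fall back to the
    normalized Euclidean depth coordinate.
    """
    # crop to the domain bounding box (+2) — the solvers scale with grid size
    full_shape = domain.shape
    obj = ndimage.find_objects(domain.astype(np.int8), max_label=1)[0]
    box = tuple(slice(max(s.start - 2, 0), min(s.stop + 2, n))
                for s, n in zip(obj, full_shape))
    domain = domain[box]
    inner = inner[box]
    forbidden_outer = forbidden_outer[box]

    struct = ndimage.generate_binary_structure(3, 1)
    lab, n_comp = ndimage.label(domain, structure=struct)
    inner_dil = ndimage.binary_dilation(inner, structure=struct)
    touch_inner = np.bincount(lab[inner_dil & domain].ravel(),
                              minlength=n_comp + 1).astype(bool)
    touch_inner[0] = False
    laplace_dom = touch_inner[lab] & domain

    d_vals = np.full(domain.shape, np.nan)
    d_dom = np.zeros(domain.shape, dtype=bool)
    u = None
    if laplace_dom.any():
        outer = (_outer_surface(laplace_dom, inner) & ~forbidden_outer)
        dvol = LabeledVolume(grid=laplace_dom.astype(np.int16), voxel_size=vs,
                             affine=affine)
        ivol = LabeledVolume(grid=inner.astype(np.int16), voxel_size=vs,
                             affine=affine)
        ovol = LabeledVolume(grid=outer.astype(np.int16), voxel_size=vs,
                             affine=affine)
        u, _, _, d, _ = radial_frame(dvol, ivol, ovol, n_layers=n_layers,
                                     method=method, tolerance=tolerance,
                                     max_iterations=max_iterations)
        keep = d.domain_mask & laplace_dom
        d_vals[keep] = d.values[keep]
        d_dom |= keep

    fallback = domain & ~laplace_dom
    if fallback.any():
        log.info("parcellate: %d %s voxel(s) in component(s) without a "
                 "ventricular boundary use the Euclidean depth fallback",
                 int(fallback.sum()), what)
        for comp in range(1, n_comp + 1):
            if touch_inner[comp]:
                continue
            cmask = lab == comp
            depth = _euclidean_depth(cmask, vs)
            d_vals[cmask] = depth[cmask]
            d_dom |= cmask

    full_d = np.full(full_shape, np.nan)
    full_dom = np.zeros(full_shape, dtype=bool)
    full_d[box] = d_vals
    full_dom[box] = d_dom
    if u is not None:
        uu = np.full(full_shape, np.nan)
        um = np.zeros(full_shape, dtype=bool)
        uu[box] = u.values
        um[box] = u.domain_mask
        u = ScalarField(values=uu, domain_mask=um, voxel_size=vs)
    return full_d, full_dom, u


def parcellate(wm: LabeledVolume, ventricles: LabeledVolume,
               cortex_lobes: LabeledVolume,
               basal_ganglia: LabeledVolume | None = None,
               thalami: LabeledVolume | None = None,
               infratentorial: LabeledVolume | None = None,
               lobe_map: dict[int, int] | None = None,
               n_layers: int = 4, method: str = "arc_length",
               tolerance: float = 1e-5, max_iterations: int = 5000,
               ) -> ParcellationResult:
    """Build the 36-region map for one subject.

    All volumes must be co-registered (same grid and voxel size; hard
    error otherwise). ``method`` selects the radial coordinate
    ("arc_length" default, or "potential").
    """
    vols = [wm, ventricles, cortex_lobes]
    bgit = [m for m in (basal_ganglia, thalami, infratentorial) if m is not None]
    check_same_grid(*(vols + bgit))
    vs = wm.voxel_size
    inner = ventricles.mask()

    bgit_mask = np.zeros(wm.shape, dtype=bool)
    for m in bgit:
        bgit_mask |= m.mask()
    bgit_mask &= ~inner
    wm_dom = wm.mask() & ~inner & ~bgit_mask
    domain = wm_dom | bgit_mask

    # the WM frame runs ventricles -> WM/cortical interface; each BGIT
    # structure gets its own frame, ventricles -> structure outer surface,
    # so the bullseye's 4 rings exist inside BGIT as well
    d_vals, d_dom, u = _radial_for_subdomain(
        wm_dom, inner, forbidden_outer=bgit_mask, vs=vs, affine=wm.affine,
        method=method, tolerance=tolerance, max_iterations=max_iterations,
        n_layers=n_layers, what="WM")
    if bgit_mask.any():
        db, domb, _ = _radial_for_subdomain(
            bgit_mask, inner, forbidden_outer=np.zeros_like(bgit_mask),
            vs=vs, affine=wm.affine, method=method, tolerance=tolerance,
            max_iterations=max_iterations, n_layers=n_layers, what="BGIT")
        d_vals = np.where(domb, db, d_vals)
        d_dom |= domb
    d_full = ScalarField(values=d_vals, domain_mask=d_dom, voxel_size=vs)
    # restrict layers to the anatomical domain (drop boundary-only voxels)
    layers_all = discretize_layers(d_full, n_layers=n_layers)
    lay_labels = np.where(domain, layers_all.labels, 0)
    layers = LayerField(labels=lay_labels, n_layers=n_layers)

    zones = assign_lobes(
        LabeledVolume(grid=domain.astype(np.int16), voxel_size=vs,
                      affine=wm.affine),
        cortex_lobes, lobe_map=lobe_map)
    zones = merge_bgit(zones, *bgit)
    # zones may extend beyond the domain via merge; clip to domain
    zones = ZoneField(labels=np.where(domain, zones.labels, 0))

    regions = build_region_map(layers, zones, voxel_size=vs)
    return ParcellationResult(regions=regions, zones=zones, layers=layers,
                              u=u, d=d_full)


def subject_loads(lesion: LabeledVolume, parc: ParcellationResult,
                  ) -> RegionalLoadTable:
    """Regional loads of one subject's lesion mask under its parcellation."""
    return compute_regional_loads(lesion, parc.regions)
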