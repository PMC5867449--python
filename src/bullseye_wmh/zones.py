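"""Angular parcellation: 9 zones and the 36-region map.

Every white-matter voxel is assigned to one of 8 lobar zones (frontal,
parietal, occipital, temporal x left/right) by nearest cortical lobe
under Euclidean distance in world (mm) coordinates; voxels of the basal
ganglia, thalami or infratentorial structures are then overwritten with
the combined BGIT zone (zone 9). Crossing zones with the radial layers
yields the 36-region map: region id = (zone - 1) * 4 + layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .laplace import LayerField
from .volume import GridMismatchError, LabeledVolume

__all__ = [
    "ZONE_NAMES",
    "N_ZONES",
    "BGIT_ZONE",
    "ZoneField",
    "RegionMap",
    "region_id",
    "region_zone_layer",
    "region_name",
    "assign_lobes",
    "merge_bgit",
    "build_region_map",
]

log = logging.getLogger(__name__)

ZONE_NAMES: dict[int, str] = {
    1: "Front-L", 2: "Front-R",
    3: "Par-L", 4: "Par-R",
    5: "Occ-L", 6: "Occ-R",
    7: "Temp-L", 8: "Temp-R",
    9: "BGIT",
}
N_ZONES = 9
BGIT_ZONE = 9


@dataclass
class ZoneField:
    """Zone labels 1..9 on the WM domain, 0 elsewhere."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        on = self.labels[self.labels > 0]
        if on.size and (on.min() < 1 or on.max() > N_ZONES):
            raise ValueError("zone labels outside 1..9")

    @property
    def domain_mask(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class RegionMap:
    """Region ids 1..36 on the WM domain, 0 elsewhere.

    region id r encodes (zone, layer) as r = (zone - 1) * n_layers + layer.
    """

    labels: np.ndarray
    n_layers: int = 4
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        on = self.labels[self.labels > 0]
        if on.size and (on.min() < 1 or on.max() > self.n_regions):
            raise ValueError(f"region ids outside 1..{self.n_regions}")

    @property
    def n_regions(self) -> int:
        return N_ZONES * self.n_layers

    @property
    def domain_mask(self) -> np.ndarray:
        return self.labels > 0

    def region_voxel_counts(self) -> np.ndarray:
        """Voxel count per region id (length n_regions, index r-1)."""
        return np.bincount(self.labels[self.labels > 0].ravel(),
                           minlength=self.n_regions + 1)[1:]


def region_id(zone: int, layer: int, n_layers: int = 4) -> int:
    if not 1 <= zone <= N_ZONES or not 1 <= layer <= n_layers:
        raise ValueError(f"invalid (zone, layer) = ({zone}, {layer})")
    return (zone - 1) * n_layers + layer


def region_zone_layer(rid: int, n_layers: int = 4) -> tuple[int, int]:
    if not 1 <= rid <= N_ZONES * n_layers:
        raise ValueError(f"invalid region id {rid}")
    return (rid - 1) // n_layers + 1, (rid - 1) % n_layers + 1


def region_name(rid: int, n_layers: int = 4) -> str:
    zone, layer = region_zone_layer(rid, n_layers)
    return f"{ZONE_NAMES[zone]}-L{layer}"


def assign_lobes(wm_domain: LabeledVolume, cortex: LabeledVolume,
                 lobe_map: dict[int, int] | None = None) -> ZoneField:
    """Assign each WM voxel to the nearest cortical lobe (zones 1..8).

    ``cortex`` is an integer parcellation; ``lobe_map`` maps its labels
    to zone indices 1..8 (identity for labels already coded 1..8).
    Distances are Euclidean in mm (per-label distance transforms,
    arg-min across labels). Exact ties go to the lower zone index.
    """
    if not wm_domain.same_grid_as(cortex):
        raise GridMismatchError("WM domain and cortical parcellation grids differ")
    if lobe_map is None:
        present = [int(v) for v in cortex.labels() if v != 0]
        bad = [v for v in present if not 1 <= v <= 8]
        if bad:
            raise ValueError(
                f"cortical labels {bad} are not zone indices 1..8; "
                "provide a lobe_map"
            )
        lobe_map = {v: v for v in present}

    dom = wm_domain.mask()
    sampling = wm_domain.voxel_size
    best_dist = np.full(dom.shape, np.inf)
    zone = np.zeros(dom.shape, dtype=np.int16)
    # iterate in ascending zone order so strict '<' keeps the lower zone on ties
    for z in range(1, 9):
        labels = [lab for lab, zz in lobe_map.items() if zz == z]
        if not labels:
            raise ValueError(f"no cortical label maps to zone {z} ({ZONE_NAMES[z]})")
        m = np.isin(cortex.grid, labels)
        if not m.any():
            raise ValueError(
                f"cortical lobe {ZONE_NAMES[z]} (labels {labels}) is empty")
        dist = ndimage.distance_transform_edt(~m, sampling=sampling)
        closer = dom & (dist < best_dist)
        best_dist[closer] = dist[closer]
        zone[closer] = z
    return ZoneField(labels=zone)


def merge_bgit(zones: ZoneField, *bgit_masks: LabeledVolume) -> ZoneField:
    """Overwrite zone labels with the combined BGIT zone (9).

    Voxels belonging to any of the given masks (basal ganglia, thalami,
    infratentorial structures, both sides) take zone 9, with precedence
    over any lobar assignment; they are added to the domain if absent.
    """
    labels = zones.labels.copy()
    for vol in bgit_masks:
        m = vol.mask()
        if m.shape != labels.shape:
            raise GridMismatchError("BGIT mask grid differs from zone field")
        labels[m] = BGIT_ZONE
    return ZoneField(labels=labels)


def build_region_map(layers: LayerField, zones: ZoneField,
                     voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
                     ) -> RegionMap:
    """Cross layers and zones into region ids 1..36.

    Both fields must cover the same domain; voxels present in only one of
    the two are attached to the nearest jointly-defined voxel's missing
    label (counted and logged), so the region map partitions the union
    domain.
    """
    if layers.labels.shape != zones.labels.shape:
        raise GridMismatchError("layer and zone field shapes differ")
    lay = layers.labels.astype(np.int32).copy()
    zon = zones.labels.astype(np.int32).copy()
    union = (lay > 0) | (zon > 0)
    for arr, name in ((lay, "layer"), (zon, "zone")):
        hole = union & (arr == 0)
        if hole.any():
            n = int(hole.sum())
            log.info("build_region_map: %d voxel(s) missing a %s label, "
                     "filled from nearest labelled voxel", n, name)
            idx = ndimage.distance_transform_edt(
                arr == 0, sampling=voxel_size,
                return_distances=False, return_indices=True)
            arr[hole] = arr[tuple(i[hole] for i in idx)]
    region = np.zeros(lay.shape, dtype=np.int16)
    region[union] = (zon[union] - 1) * layers.n_layers + lay[union]
    return RegionMap(labels=region, n_layers=layers.n_layers,
                     voxel_size=voxel_size)
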