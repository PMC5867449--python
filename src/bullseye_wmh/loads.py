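"""Per-region WMH load features.

The regional WMH load of region r is the fraction of r's voxels covered
by lesion. Loads are exact voxel-count ratios, so the conservation
identity sum_r load_r * volume_r = lesion volume inside the domain holds
exactly. Aggregate features per visual-scale subscale are
region-volume-weighted means of the loads over a configurable
subscale -> region mapping.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scales import ScaleSpec
from .volume import GridMismatchError, LabeledVolume
from .zones import BGIT_ZONE, RegionMap, region_id, region_name, region_zone_layer

__all__ = [
    "RegionalLoadTable",
    "FeatureSet",
    "compute_regional_loads",
    "total_burden",
    "aggregate_scale_features",
    "default_subscale_regions",
    "loads_to_frame",
    "cohort_to_frame",
]

log = logging.getLogger(__name__)


@dataclass
class RegionalLoadTable:
    """One subject's regional lesion-load profile.

    Attributes
    ----------
    load
        36-vector of lesion fractions in [0, 1] (index r-1).
    region_volume_mm3
        36-vector of region volumes in mm^3.
    total_lesion_volume_ml
        Total lesion volume within the domain, in mL.
    global_relative_burden
        Total lesion volume / WM-domain volume (the frame the loads
        live in).
    unassigned_lesion_voxels
        Lesion voxels outside the region map (excluded from loads).
    """

    load: np.ndarray
    region_volume_mm3: np.ndarray
    total_lesion_volume_ml: float
    global_relative_burden: float
    unassigned_lesion_voxels: int = 0
    empty_regions: tuple[int, ...] = field(default_factory=tuple)
    n_layers: int = 4

    def __post_init__(self) -> None:
        self.load = np.asarray(self.load, dtype=float)
        self.region_volume_mm3 = np.asarray(self.region_volume_mm3, dtype=float)
        if self.load.shape != self.region_volume_mm3.shape:
            raise ValueError("load and region_volume shapes differ")
        if np.any((self.load < 0) | (self.load > 1)):
            raise ValueError("loads must lie in [0, 1]")

    @property
    def n_regions(self) -> int:
        return self.load.size


def compute_regional_loads(lesion: LabeledVolume, regions: RegionMap,
                           ) -> RegionalLoadTable:
    """Fraction of each region occupied by lesion.

    Lesion voxels outside the region map are counted separately and
    excluded from the loads. Empty regions get load 0 and are flagged.
    """
    if lesion.shape != regions.labels.shape:
        raise GridMismatchError("lesion and region map grids differ")
    les = lesion.mask()
    n = regions.n_regions
    region_counts = regions.region_voxel_counts().astype(np.int64)
    lesion_counts = np.bincount(
        regions.labels[les & regions.domain_mask].ravel(), minlength=n + 1
    )[1:].astype(np.int64)
    unassigned = int((les & ~regions.domain_mask).sum())
    if unassigned:
        log.info("compute_regional_loads: %d lesion voxel(s) outside the "
                 "region map excluded from loads", unassigned)
    with np.errstate(invalid="ignore", divide="ignore"):
        load = np.where(region_counts > 0,
                        lesion_counts / np.maximum(region_counts, 1), 0.0)
    empty = tuple(int(r + 1) for r in np.nonzero(region_counts == 0)[0])
    if empty:
        log.info("compute_regional_loads: empty region(s) %s given load 0", empty)
    vv = float(np.prod(regions.voxel_size))
    domain_voxels = int(region_counts.sum())
    in_domain_lesion = int(lesion_counts.sum())
    return RegionalLoadTable(
        load=load,
        region_volume_mm3=region_counts * vv,
        total_lesion_volume_ml=in_domain_lesion * vv / 1000.0,
        global_relative_burden=(in_domain_lesion / domain_voxels
                                if domain_voxels else 0.0),
        unassigned_lesion_voxels=unassigned,
        empty_regions=empty,
        n_layers=regions.n_layers,
    )


def total_burden(lesion: LabeledVolume) -> float:
    """Total lesion volume in mL: voxel count x voxel volume / 1000."""
    return float(lesion.mask().sum()) * lesion.voxel_volume_mm3 / 1000.0


@dataclass
class FeatureSet:
    """Named aggregate load features with their region provenance."""

    features: dict[str, float]
    provenance: dict[str, tuple[int, ...]]

    def __post_init__(self) -> None:
        for name, rids in self.provenance.items():
            if not all(1 <= r <= 36 for r in rids):
                raise ValueError(f"feature {name!r} references invalid regions")

    def vector(self, names: list[str] | None = None) -> np.ndarray:
        names = names or list(self.features)
        return np.array([self.features[n] for n in names], dtype=float)


def default_subscale_regions(scale: ScaleSpec, n_layers: int = 4,
                             ) -> dict[str, tuple[int, ...]]:
    """Default anatomical mapping of subscales to region ids.

    Follows each subscale's anatomy: periventricular items map to
    layer-1 regions of the relevant lobes, lobar deep-WM items to that
    lobe's layers 2..n, basal-ganglia and infratentorial items to the
    BGIT zone, and global scores to every region. Fully overridable via
    configuration (see :func:`load_region_mapping`).
    """
    def rids(zones, layers):
        return tuple(sorted(region_id(z, l, n_layers) for z in zones for l in layers))

    lobar_zones = {"F": (1, 2), "P": (3, 4), "O": (5, 6), "T": (7, 8)}
    all_lobar = (1, 2, 3, 4, 5, 6, 7, 8)
    deep = tuple(range(2, n_layers + 1))
    all_layers = tuple(range(1, n_layers + 1))
    name = scale.name.lower()
    if name == "manolio":
        return {"Manolio": rids(all_lobar + (BGIT_ZONE,), all_layers)}
    if name == "fazekas":
        return {
            "PV": rids(all_lobar + (BGIT_ZONE,), (1,)),
            "DWM": rids(all_lobar + (BGIT_ZONE,), deep),
        }
    if name == "scheltens":
        bgit = rids((BGIT_ZONE,), all_layers)
        mapping = {
            "FC": rids(lobar_zones["F"], (1,)),
            "LB": rids(all_lobar, (1,)),
            "PC": rids(lobar_zones["P"] + lobar_zones["O"], (1,)),
        }
        for lob, zs in lobar_zones.items():
            mapping[f"DWM{lob}"] = rids(zs, deep)
        for sid in ("BGCN", "BGPU", "BGGP", "BGTH", "BGIC",
                    "ITCE", "ITME", "ITPO", "ITMO"):
            mapping[sid] = bgit
        return mapping
    raise KeyError(f"no default region mapping for scale {scale.name!r}")


def load_region_mapping(path) -> dict[str, tuple[int, ...]]:
    """Read a subscale -> region-id mapping from JSON or YAML."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) if str(path).endswith((".yml", ".yaml")) \
            else json.load(fh)
    return {k: tuple(int(r) for r in v) for k, v in raw.items()}


def aggregate_scale_features(loads: RegionalLoadTable, scale: ScaleSpec,
                             mapping: dict[str, tuple[int, ...]] | None = None,
                             ) -> FeatureSet:
    """Region-volume-weighted mean load per subscale.

    ``mapping`` must cover every subscale of the scale; defaults to
    :func:`default_subscale_regions`.
    """
    if mapping is None:
        mapping = default_subscale_regions(scale, loads.n_layers)
    missing = [s for s in scale.subscale_ids if s not in mapping]
    if missing:
        raise KeyError(f"subscales without region mapping: {missing}")
    feats = {}
    for sid in scale.subscale_ids:
        rids = np.asarray(mapping[sid], dtype=int) - 1
        w = loads.region_volume_mm3[rids]
        if w.sum() > 0:
            feats[sid] = float(np.average(loads.load[rids], weights=w))
        else:
            feats[sid] = 0.0
    return FeatureSet(features=feats,
                      provenance={s: tuple(mapping[s]) for s in scale.subscale_ids})


def loads_to_frame(loads: RegionalLoadTable, subject="subject-0") -> pd.DataFrame:
    """Long-format frame: one row per region, plus identifying columns."""
    n = loads.n_regions
    rows = []
    for r in range(1, n + 1):
        zone, layer = region_zone_layer(r, loads.n_layers)
        rows.append({
            "subject": subject, "region_id": r,
            "region": region_name(r, loads.n_layers),
            "zone": zone, "layer": layer,
            "load": loads.load[r - 1],
            "region_volume_mm3": loads.region_volume_mm3[r - 1],
            "total_volume_ml": loads.total_lesion_volume_ml,
            "global_relative_burden": loads.global_relative_burden,
        })
    return pd.DataFrame(rows)


def cohort_to_frame(cohort: dict[str, RegionalLoadTable]) -> pd.DataFrame:
    return pd.concat(
        [loads_to_frame(t, subject=s) for s, t in cohort.items()],
        ignore_index=True,
    )


def frame_to_cohort(frame: pd.DataFrame) -> dict[str, RegionalLoadTable]:
    """Inverse of :func:`cohort_to_frame`."""
    cohort = {}
    for subject, g in frame.groupby("subject", sort=True):
        g = g.sort_values("region_id")
        n_layers = int(g["layer"].max())
        cohort[subject] = RegionalLoadTable(
            load=g["load"].to_numpy(),
            region_volume_mm3=g["region_volume_mm3"].to_numpy(),
            total_lesion_volume_ml=float(g["total_volume_ml"].iloc[0]),
            global_relative_burden=float(g["global_relative_burden"].iloc[0]),
            n_layers=n_layers,
        )
    return cohort
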