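"""Segmentation evaluation: DICE across structural hierarchies, Hausdorff
distances between voxelized surfaces and label volumes, and two-stage
summary statistics.

Conventions: the DICE of two empty masks is 1.0 (agreement on absence) and
of an empty against a non-empty mask 0.0.  Hausdorff is the classic max of
the two directed maximum nearest-neighbor distances (not a percentile
variant).  Percentile summaries use the median-unbiased quantile definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import GridError, UndefinedDistanceError
from .types import LabeledSurface, LabelVolume

__all__ = [
    "Hierarchy",
    "dice",
    "dice_hierarchy",
    "hausdorff_distance_mm",
    "hausdorff_surface_volume",
    "summarize_scores",
    "band_hierarchies",
]

_QUANTILE_METHOD = "median_unbiased"


@dataclass
class Hierarchy:
    """A named grouping of fine label ids into evaluation groups.

    Typical hierarchies for cerebellar evaluation are ``coarse`` (whole
    cerebellum / white matter / whole vermis), ``lobe`` (anterior, superior
    posterior, inferior posterior and flocculonodular groups per hemisphere)
    and ``lobule`` (every division excluding the corpus medullare).  Groups
    within one hierarchy must be disjoint.
    """

    name: str
    groups: Dict[str, Set[int]]

    def __post_init__(self):
        seen: Set[int] = set()
        for g, ids in self.groups.items():
            ids = set(int(i) for i in ids)
            if seen & ids:
                raise ValueError(
                    f"hierarchy {self.name!r}: group {g!r} overlaps another")
            seen |= ids
            self.groups[g] = ids


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != mask_b.shape:
        raise GridError(f"mask shapes differ: {mask_a.shape} vs {mask_b.shape}")
    na, nb = int(mask_a.sum()), int(mask_b.sum())
    if na + nb == 0:
        return 1.0
    inter = int(np.count_nonzero(mask_a & mask_b))
    return 2.0 * inter / (na + nb)


def dice_hierarchy(seg_a: LabelVolume, seg_b: LabelVolume,
                   hierarchy: Hierarchy) -> Dict[str, Optional[float]]:
    """Per-group Dice between two segmentations on the same grid.

    Group masks are unions of the member fine labels.  A group with no
    member label present in either volume is reported as ``None`` (missing),
    not as 0.
    """
    if seg_a.shape != seg_b.shape:
        raise GridError("segmentations must share a grid")
    out: Dict[str, Optional[float]] = {}
    for g, ids in hierarchy.groups.items():
        ids_arr = np.asarray(sorted(ids))
        ma = np.isin(seg_a.array, ids_arr)
        mb = np.isin(seg_b.array, ids_arr)
        if not ma.any() and not mb.any():
            out[g] = None
        else:
            out[g] = dice(ma, mb)
    return out


def hausdorff_distance_mm(points_a: np.ndarray, points_b: np.ndarray) -> float:
    """Classic symmetric Hausdorff distance between two point sets (mm)."""
    if len(points_a) == 0 or len(points_b) == 0:
        raise UndefinedDistanceError("empty point set")
    ta, tb = cKDTree(points_a), cKDTree(points_b)
    d_ab = tb.query(points_a)[0].max()
    d_ba = ta.query(points_b)[0].max()
    return float(max(d_ab, d_ba))


def hausdorff_surface_volume(surface: LabeledSurface,
                             label_volume: LabelVolume,
                             group_labels: Iterable[int]) -> float:
    """Hausdorff distance (mm) between a voxelized surface group and the
    corresponding volume group.

    Set A are the centers of voxels (on the volume's grid) that contain a
    group-labeled surface vertex; set B are the centers of voxels carrying a
    group label in ``label_volume``.
    """
    ids = np.asarray(sorted(set(int(i) for i in group_labels)))
    if surface.labels is None:
        raise UndefinedDistanceError("surface has no labels")
    sel = np.isin(surface.labels, ids)
    vox = np.floor(label_volume.world_to_voxel(surface.vertices[sel]) + 0.5)
    vox = np.unique(vox.astype(np.int64), axis=0) if len(vox) else vox
    mask_b = np.isin(label_volume.array, ids)
    idx_b = np.argwhere(mask_b)
    if len(vox) == 0 or len(idx_b) == 0:
        raise UndefinedDistanceError(
            f"group {ids.tolist()} empty on the "
            f"{'surface' if len(vox) == 0 else 'volume'} side")
    pa = label_volume.voxel_to_world(vox)
    pb = label_volume.voxel_to_world(idx_b)
    return hausdorff_distance_mm(pa, pb)


def summarize_scores(scores: pd.DataFrame) -> dict:
    """Two-stage summaries of per-subject per-group scores.

    ``scores`` must have columns ``subject``, ``group``, ``value`` (missing
    groups omitted or NaN).  Per group the median across subjects is taken;
    the unweighted median and mean over groups of those medians follow, with
    the extreme groups identified, plus pooled dispersion summaries (SD, IQR
    and range, median-unbiased quantiles).
    """
    df = scores.dropna(subset=["value"])
    if df.empty:
        raise ValueError("no scores to summarize")
    med = df.groupby("group")["value"].median()
    values = df["value"].to_numpy()
    q25, q75 = np.quantile(values, [0.25, 0.75], method=_QUANTILE_METHOD)
    return {
        "group_medians": med.to_dict(),
        "median_of_medians": float(med.median()),
        "mean_of_medians": float(med.mean()),
        "min_group": (str(med.idxmin()), float(med.min())),
        "max_group": (str(med.idxmax()), float(med.max())),
        "pooled_mean": float(values.mean()),
        "pooled_sd": float(values.std(ddof=1)) if len(values) > 1 else 0.0,
        "pooled_iqr": (float(q25), float(q75)),
        "pooled_range": (float(values.min()), float(values.max())),
    }


def band_hierarchies(n_regions: int,
                     white_matter_id: int,
                     vermis_id: Optional[int] = None) -> Dict[str, Hierarchy]:
    """Coarse / lobe / lobule hierarchies for latitude-band phantoms.

    ``coarse`` holds the whole cortex, the white matter and (if present) the
    midline strip standing in for the vermis; ``lobe`` groups adjacent bands
    in pairs; ``lobule`` is one group per band.
    """
    bands = list(range(1, n_regions + 1))
    coarse = {"whole_cortex": set(bands) | ({vermis_id} if vermis_id else set()),
              "white_matter": {white_matter_id}}
    if vermis_id:
        coarse = {"whole_cortex": set(bands),
                  "white_matter": {white_matter_id},
                  "vermis": {vermis_id}}
    lobe = {}
    for i in range(0, n_regions, 2):
        members = set(bands[i:i + 2])
        lobe[f"lobe_{i // 2 + 1}"] = members
    lobule = {f"band_{b}": {b} for b in bands}
    if vermis_id:
        lobule[f"vermis"] = {vermis_id}
    return {
        "coarse": Hierarchy("coarse", coarse),
        "lobe": Hierarchy("lobe", lobe),
        "lobule": Hierarchy("lobule", lobule),
    }
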