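"""Stochastic equal-area subdivision of anatomical regions into patches.

Each anatomical region is split into a number of patches proportional to its
share of the cortical surface area.  Random per-region seed vertices are
spread apart by iteratively moving each pointer to the same-region neighbor
vertex that maximizes its minimum distance to the region's other pointers
(distance measured as Euclidean chord length in the aligned spherical
representation, a monotone proxy for geodesic distance).  Patches then grow
by multi-source breadth-first expansion confined to their region, the patch
map is smoothed with the modal surface filter, fragments are repaired, and
patch areas are balanced by split/merge passes: patches above twice the mean
area are split at their spherical farthest vertex pair, patches below half
the mean are merged into the same-region neighbor sharing the longest
border.  Each patch undergoes at most ``max_ops`` such operations before a
final forced pass splits all remaining oversize and merges all remaining
undersize patches.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ApportionmentError, FoliakitError, FragmentationWarning, SeedingError
from .mesh_core import (AdjacencyGraph, build_adjacency, mode_filter_surface,
                        region_area_fractions, vertex_areas)
from .types import LabeledSurface

__all__ = [
    "Parcellation",
    "patches_per_region",
    "spread_seeds",
    "grow_patches",
    "balance_patches",
    "parcellate",
]


@dataclass
class Parcellation:
    """Per-vertex patch ids (contiguous from 1) nested inside regions."""

    patch_ids: np.ndarray
    patch_to_region: Dict[int, int]
    areas_mm2: Dict[int, float] = field(default_factory=dict)
    rng_seed: Optional[int] = None

    @property
    def n_patches(self) -> int:
        return len(self.patch_to_region)

    def area_array(self) -> np.ndarray:
        return np.array([self.areas_mm2[p] for p in sorted(self.areas_mm2)])

    @property
    def area_cv(self) -> float:
        """Coefficient of variation of patch areas (population SD / mean)."""
        a = self.area_array()
        return float(a.std() / a.mean())

    @property
    def range_ratio(self) -> float:
        a = self.area_array()
        return float(a.max() / a.min())

    def stats_frame(self) -> pd.DataFrame:
        rows = [(p, self.patch_to_region[p], self.areas_mm2[p])
                for p in sorted(self.patch_to_region)]
        return pd.DataFrame(rows, columns=["patch_id", "region", "area_mm2"])

    def summary(self) -> dict:
        return {"n_patches": self.n_patches,
                "cv": self.area_cv,
                "range_ratio": self.range_ratio,
                "rng_seed": self.rng_seed}


def patches_per_region(area_fractions: Dict[int, float],
                       total_patches: int) -> Dict[int, int]:
    """Largest-remainder apportionment of patches to regions.

    ``count_r`` is ``total_patches * fraction_r`` rounded by the
    largest-remainder rule; every region receives at least one patch and the
    counts sum exactly to ``total_patches``.
    """
    regions = sorted(area_fractions)
    if total_patches < len(regions):
        raise ApportionmentError("fewer patches than regions")
    fr = np.array([area_fractions[r] for r in regions], dtype=float)
    if np.any(fr <= 0):
        bad = [r for r, f in zip(regions, fr) if f <= 0]
        raise ApportionmentError(f"region(s) with zero area: {bad}")
    if abs(fr.sum() - 1.0) > 1e-6:
        raise ApportionmentError("area fractions must sum to 1")
    quota = total_patches * fr
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    # distribute leftovers by largest remainder, ties to the smaller region id
    for i in sorted(range(len(regions)),
                    key=lambda i: (-remainder[i], regions[i]))[: total_patches - counts.sum()]:
        counts[i] += 1
    # guarantee >= 1 by stealing from the largest count
    while np.any(counts == 0):
        counts[int(np.argmax(counts))] -= 1
        counts[int(np.argmin(counts))] += 1
    return {r: int(c) for r, c in zip(regions, counts)}


def _chord(a: np.ndarray, b: np.ndarray) -> float:
    d = a - b
    return float(np.sqrt(d @ d))


def spread_seeds(surface: LabeledSurface,
                 region_labels: np.ndarray,
                 counts: Dict[int, int],
                 iterations: int = 100,
                 rng_seed: int = 0,
                 adjacency: Optional[AdjacencyGraph] = None,
                 return_history: bool = False):
    """Draw and spread per-region seed pointers over the surface.

    Initial seeds are drawn uniformly without replacement within each region.
    Then, for ``iterations`` sweeps, each pointer (visited sequentially in
    ascending patch-id order) moves to the same-region neighbor vertex that
    maximizes its minimum spherical chord distance to the region's other
    pointers, staying put when no neighbor strictly improves it.  Within a
    region the minimum pairwise pointer distance is therefore non-decreasing
    across sweeps.

    Returns the seed vertex ids (ordered by patch id); with
    ``return_history`` also a per-sweep list of ``{region: min pairwise
    distance}`` dicts (regions with a single pointer are omitted).
    """
    if surface.spherical is None:
        raise FoliakitError("spherical coordinates are required")
    sph = surface.spherical
    adjacency = adjacency or build_adjacency(surface)
    rng = np.random.default_rng(rng_seed)

    seeds: List[int] = []
    seed_region: List[int] = []
    for region in sorted(counts):
        verts = np.flatnonzero(region_labels == region)
        if counts[region] > len(verts):
            raise SeedingError(
                f"region {region}: {counts[region]} seeds requested but only "
                f"{len(verts)} vertices")
        chosen = rng.choice(verts, size=counts[region], replace=False)
        seeds.extend(int(v) for v in np.sort(chosen))
        seed_region.extend([region] * counts[region])

    by_region: Dict[int, List[int]] = {}
    for i, r in enumerate(seed_region):
        by_region.setdefault(r, []).append(i)

    def min_dist(i: int, pos_i: int) -> float:
        others = [seeds[j] for j in by_region[seed_region[i]] if j != i]
        if not others:
            return np.inf
        return min(_chord(sph[pos_i], sph[o]) for o in others)

    history = []
    for _ in range(iterations):
        for i in range(len(seeds)):
            cur = seeds[i]
            best_v, best_d = cur, min_dist(i, cur)
            region = seed_region[i]
            for nb in adjacency.neighbors(cur):
                nb = int(nb)
                if region_labels[nb] != region:
                    continue
                d = min_dist(i, nb)
                if d > best_d:
                    best_v, best_d = nb, d
            seeds[i] = best_v
        if return_history:
            snap = {}
            for r, idxs in by_region.items():
                if len(idxs) < 2:
                    continue
                pos = sph[[seeds[j] for j in idxs]]
                dmat = np.linalg.norm(pos[:, None] - pos[None], axis=-1)
                np.fill_diagonal(dmat, np.inf)
                snap[r] = float(dmat.min())
            history.append(snap)
    seeds_arr = np.asarray(seeds, dtype=np.int64)
    return (seeds_arr, history) if return_history else seeds_arr


def grow_patches(surface: LabeledSurface,
                 region_labels: np.ndarray,
                 seeds: np.ndarray,
                 adjacency: Optional[AdjacencyGraph] = None) -> np.ndarray:
    """Multi-source FIFO breadth-first growth confined to regions.

    Seeds are enqueued in ascending patch id (patch ids are 1-based positions
    in ``seeds``); every vertex ends up assigned.  A disconnected region
    component that contains no seed is assigned to the nearest same-region
    patch by spherical chord distance, with a warning.
    """
    adjacency = adjacency or build_adjacency(surface)
    n = surface.n_vertices
    patch = np.zeros(n, dtype=np.int64)
    q = deque()
    for pid, s in enumerate(seeds, start=1):
        s = int(s)
        if patch[s]:
            raise FoliakitError(f"duplicate seed vertex {s}")
        patch[s] = pid
        q.append(s)
    while q:
        u = q.popleft()
        pu, ru = patch[u], region_labels[u]
        for w in adjacency.neighbors(u):
            w = int(w)
            if patch[w] == 0 and region_labels[w] == ru:
                patch[w] = pu
                q.append(w)
    unreached = np.flatnonzero(patch == 0)
    if len(unreached):
        warnings.warn(f"{len(unreached)} vertices in seedless components; "
                      "assigned to nearest same-region patch",
                      FragmentationWarning, stacklevel=2)
        if surface.spherical is None:
            raise FoliakitError("spherical coordinates required to repair "
                                "seedless components")
        sph = surface.spherical
        for v in unreached:
            same = np.flatnonzero((region_labels == region_labels[v]) & (patch > 0))
            if len(same) == 0:
                raise FoliakitError(
                    f"region {region_labels[v]} has no seeded vertices")
            d = np.linalg.norm(sph[same] - sph[v], axis=1)
            patch[v] = patch[same[np.argmin(d)]]
    return patch


def _patch_areas(patch: np.ndarray, varea: np.ndarray) -> Dict[int, float]:
    out: Dict[int, float] = {}
    for pid in np.unique(patch):
        if pid > 0:
            out[int(pid)] = float(varea[patch == pid].sum())
    return out


def _border_counts(patch: np.ndarray, adjacency: AdjacencyGraph,
                   members: np.ndarray) -> Dict[int, int]:
    """Number of boundary edges between ``members`` and each adjacent patch."""
    counts: Dict[int, int] = {}
    member_set = set(int(v) for v in members)
    pid = patch[members[0]]
    for v in member_set:
        for w in adjacency.neighbors(v):
            w = int(w)
            if patch[w] != pid:
                counts[int(patch[w])] = counts.get(int(patch[w]), 0) + 1
    return counts


def _split_patch(patch: np.ndarray, pid: int, sph: np.ndarray,
                 adjacency: AdjacencyGraph, next_id: int) -> bool:
    """Split patch ``pid`` in two by 2-source BFS from its spherical
    farthest vertex pair.  Returns False (skipped) for patches < 2 vertices."""
    members = np.flatnonzero(patch == pid)
    if len(members) < 2:
        warnings.warn(f"patch {pid} too small to split", FragmentationWarning,
                      stacklevel=3)
        return False
    P = sph[members]
    d2 = np.sum((P[:, None] - P[None]) ** 2, axis=-1)
    a, b = np.unravel_index(np.argmax(d2), d2.shape)
    sa, sb = int(members[a]), int(members[b])
    member_mask = np.zeros(len(patch), dtype=bool)
    member_mask[members] = True
    side = np.zeros(len(patch), dtype=np.int8)
    side[sa], side[sb] = 1, 2
    q = deque([sa, sb])
    while q:
        u = q.popleft()
        for w in adjacency.neighbors(u):
            w = int(w)
            if member_mask[w] and side[w] == 0:
                side[w] = side[u]
                q.append(w)
    # patch connectivity guarantees both halves reach everything
    leftovers = members[side[members] == 0]
    for v in leftovers:  # safety: attach any unreachable member to side 1
        side[v] = 1
    patch[(side == 2)] = next_id
    return True


def _merge_patch(patch: np.ndarray, pid: int, adjacency: AdjacencyGraph,
                 patch_to_region: Dict[int, int]) -> Optional[int]:
    """Merge ``pid`` into the same-region neighbor sharing the most boundary
    edges; returns the absorbing patch id, or None if the patch has no
    same-region neighbor."""
    members = np.flatnonzero(patch == pid)
    counts = _border_counts(patch, adjacency, members)
    region = patch_to_region[pid]
    cands = {q: c for q, c in counts.items()
             if q > 0 and patch_to_region.get(q) == region}
    if not cands:
        return None
    # most shared edges; ties to the smaller patch id
    target = min(cands, key=lambda q: (-cands[q], q))
    patch[members] = target
    return target


def balance_patches(surface: LabeledSurface,
                    patch: np.ndarray,
                    patch_to_region: Dict[int, int],
                    max_ops: int = 5,
                    forced_final_pass: bool = True,
                    adjacency: Optional[AdjacencyGraph] = None,
                    max_rounds: int = 25):
    """Split/merge balancing of patch areas.

    Iteratively splits patches above twice the current mean area and merges
    patches below half the mean into their longest-border same-region
    neighbor, with the mean recomputed after each batch of operations and at
    most ``max_ops`` operations per patch (children inherit their parent's
    operation count).  A final forced pass then splits every remaining
    oversize patch once and merges every remaining undersize patch.  Patch
    ids are relabeled to contiguous 1..K on return.

    Returns ``(patch_ids, patch_to_region)``.
    """
    if surface.spherical is None:
        raise FoliakitError("spherical coordinates are required")
    adjacency = adjacency or build_adjacency(surface)
    sph = surface.spherical
    varea = vertex_areas(surface)
    patch = patch.astype(np.int64).copy()
    patch_to_region = dict(patch_to_region)
    ops = {pid: 0 for pid in patch_to_region}
    next_id = max(patch_to_region) + 1

    def batch(forced: bool) -> int:
        nonlocal next_id
        n_ops = 0
        areas = _patch_areas(patch, varea)
        mean = np.mean(list(areas.values()))
        for pid in sorted(areas):
            if areas[pid] > 2 * mean and (forced or ops[pid] < max_ops):
                if _split_patch(patch, pid, sph, adjacency, next_id):
                    patch_to_region[next_id] = patch_to_region[pid]
                    ops[next_id] = ops[pid] = ops[pid] + 1
                    next_id += 1
                    n_ops += 1
        areas = _patch_areas(patch, varea)
        mean = np.mean(list(areas.values()))
        for pid in sorted(areas):
            if pid not in patch_to_region or not np.any(patch == pid):
                continue
            area = float(varea[patch == pid].sum())
            if area < 0.5 * mean and (forced or ops[pid] < max_ops):
                target = _merge_patch(patch, pid, adjacency, patch_to_region)
                if target is not None:
                    ops[target] = ops.get(target, 0) + 1
                    del patch_to_region[pid]
                    ops.pop(pid, None)
                    n_ops += 1
                    areas = _patch_areas(patch, varea)
                    mean = np.mean(list(areas.values()))
        return n_ops

    for _ in range(max_rounds):
        if batch(forced=False) == 0:
            break
    if forced_final_pass:
        batch(forced=True)
    return _relabel(patch, patch_to_region)


def _relabel(patch: np.ndarray, patch_to_region: Dict[int, int]):
    """Relabel patch ids to contiguous 1..K (ascending original id)."""
    old = sorted(int(p) for p in np.unique(patch) if p > 0)
    mapping = {o: i + 1 for i, o in enumerate(old)}
    new = np.zeros_like(patch)
    for o, nw in mapping.items():
        new[patch == o] = nw
    p2r = {mapping[o]: patch_to_region[o] for o in old}
    return new, p2r


def _reconnect_fragments(patch: np.ndarray, region_labels: np.ndarray,
                         adjacency: AdjacencyGraph,
                         patch_to_region: Dict[int, int]) -> np.ndarray:
    """Repair patches fragmented by smoothing: the largest connected
    component keeps the id, fragments join the adjacent same-region patch
    with the longest shared border (falling back to any adjacent patch of
    the region)."""
    patch = patch.copy()
    changed = True
    guard = 0
    while changed and guard < 20:
        changed = False
        guard += 1
        for pid in sorted(patch_to_region):
            members = np.flatnonzero(patch == pid)
            if len(members) == 0:
                continue
            comps = _components(members, adjacency)
            if len(comps) == 1:
                continue
            comps.sort(key=len, reverse=True)
            for frag in comps[1:]:
                frag = np.asarray(frag)
                counts = _border_counts(patch, adjacency, frag)
                region = patch_to_region[pid]
                cands = {q: c for q, c in counts.items()
                         if q > 0 and q != pid and patch_to_region.get(q) == region}
                if cands:
                    target = min(cands, key=lambda q: (-cands[q], q))
                    patch[frag] = target
                    changed = True
    return patch


def _components(members: np.ndarray, adjacency: AdjacencyGraph) -> List[List[int]]:
    member_set = set(int(v) for v in members)
    seen = set()
    comps = []
    for v in members:
        v = int(v)
        if v in seen:
            continue
        comp = [v]
        seen.add(v)
        q = deque([v])
        while q:
            u = q.popleft()
            for w in adjacency.neighbors(u):
                w = int(w)
                if w in member_set and w not in seen:
                    seen.add(w)
                    comp.append(w)
                    q.append(w)
        comps.append(comp)
    return comps


def parcellate(surface: LabeledSurface,
               region_labels: Optional[np.ndarray] = None,
               total_patches: int = 800,
               rng_seed: int = 0,
               spread_iterations: int = 100,
               smooth_radius: int = 3,
               smooth_iterations: int = 3,
               max_ops: int = 5,
               exclude: Sequence[int] = ()) -> Parcellation:
    """End-to-end equal-area parcellation of a labeled surface.

    Runs apportionment, seed spreading, region-confined growth, modal
    smoothing of the patch map (confined to regions), fragment repair and
    split/merge balancing.  ``exclude`` removes labels (e.g. a
    white-matter-tract patch) from the apportionment denominator; excluded
    regions still receive their apportioned share of no patches and keep
    patch id 0.
    """
    region_labels = surface.labels if region_labels is None else region_labels
    if region_labels is None:
        raise FoliakitError("region labels are required")
    adjacency = build_adjacency(surface)

    frame = region_area_fractions(surface.with_labels(region_labels),
                                  exclude=exclude)
    fractions = {int(r.label_id): float(r.fraction)
                 for r in frame.itertuples() if np.isfinite(r.fraction)}
    counts = patches_per_region(fractions, total_patches)

    seeds = spread_seeds(surface, region_labels, counts,
                         iterations=spread_iterations, rng_seed=rng_seed,
                         adjacency=adjacency)
    patch = grow_patches(surface, region_labels, seeds, adjacency=adjacency)

    patch_to_region = {}
    pid = 0
    for region in sorted(counts):
        for _ in range(counts[region]):
            pid += 1
            patch_to_region[pid] = region

    smoothed = mode_filter_surface(patch, adjacency, smooth_radius,
                                   smooth_iterations,
                                   region_mask=region_labels)
    # smoothing may annihilate or fragment patches; drop empty ids, repair
    patch_to_region = {p: r for p, r in patch_to_region.items()
                       if np.any(smoothed == p)}
    smoothed = _reconnect_fragments(smoothed, region_labels, adjacency,
                                    patch_to_region)
    patch, patch_to_region = balance_patches(
        surface, smoothed, patch_to_region, max_ops=max_ops,
        adjacency=adjacency)

    varea = vertex_areas(surface)
    areas = _patch_areas(patch, varea)
    return Parcellation(patch, patch_to_region, areas, rng_seed=rng_seed)
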