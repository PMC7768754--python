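"""Image-to-network pipeline for confocal stacks of stained bone porosity.

Stages: fixed-threshold binarization → segmentation of the pore space
into canaliculi, lacunae and vascular channels → 3D skeletonization of
the canalicular phase → conversion into an :class:`LCNNetwork`.

Conventions
-----------
Image arrays are indexed ``[z, y, x]`` (TIFF page order).  Voxel
``(iz, iy, ix)`` has its centre at ``((ix+0.5)·s, (iy+0.5)·s,
(iz+0.5)·s)`` µm with ``s`` the isotropic voxel size.  Segmentation of
"bulky" bodies uses morphological opening with a spherical element;
each lacunar body then absorbs the pore voxels within one opening
radius ("expanding the lacunae into the canaliculi").  Canalicular
diameters are below the optical resolution, so edges never carry an
image-derived cross-section: a constant annulus area is imposed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from skimage.measure import label as cc_label
from skimage.morphology import ball, opening, skeletonize
from skimage.segmentation import expand_labels

from .errors import ValidationError
from .network import (
    DEFAULT_CROSS_SECTION_AREA,
    Canaliculus,
    LCNNetwork,
    Node,
    NodeKind,
)

logger = logging.getLogger(__name__)

BACKGROUND, CANALICULUS, LACUNA, VASCULAR = 0, 1, 2, 3


@dataclass
class ImageStack:
    """3D greyscale (or binary) stack, indexed [z, y, x], isotropic voxels."""

    voxels: np.ndarray
    voxel_size: float  # µm

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValidationError("image stack must be a non-empty 3D array")
        if self.voxel_size <= 0:
            raise ValidationError("voxel_size must be > 0")

    def write_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(str(path), self.voxels)

    @classmethod
    def read_tiff(cls, path, voxel_size: float) -> "ImageStack":
        import tifffile

        return cls(np.asarray(tifffile.imread(str(path))), voxel_size)


@dataclass
class PoreLabels:
    """Semantic classes plus instance labels of the segmented pore space.

    ``class_volume`` holds {0: background, 1: canaliculus, 2: lacuna,
    3: vascular}; ``body_labels`` holds a positive instance id on the
    voxels of each lacunar/vascular body including the absorbed collar
    (0 elsewhere); ``core_labels`` holds the same instance ids on the
    pre-expansion body voxels only (the actual body surface).
    """

    class_volume: np.ndarray
    body_labels: np.ndarray
    voxel_size: float
    core_labels: np.ndarray | None = None

    def __post_init__(self):
        if self.class_volume.shape != self.body_labels.shape:
            raise ValidationError("class and body label volumes differ in shape")
        if self.core_labels is None:
            self.core_labels = self.body_labels

    def write_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(str(path), self.class_volume.astype(np.uint8))


def threshold_stack(image: ImageStack, threshold: float) -> ImageStack:
    """Fixed global threshold: voxel ≥ threshold becomes pore."""
    lo, hi = image.voxels.min(), image.voxels.max()
    if threshold < lo or threshold > hi:
        warnings.warn(
            f"threshold {threshold} outside image value range [{lo}, {hi}]; "
            "mask will be empty or full",
            stacklevel=2,
        )
    return ImageStack((image.voxels >= threshold).astype(np.uint8), image.voxel_size)


def segment_pores(
    binary: ImageStack,
    lacuna_min_volume: float = 50.0,
    vascular_min_volume: float = 1000.0,
    lacuna_opening_radius: float = 1.0,
) -> PoreLabels:
    """Separate the pore mask into canaliculi, lacunae and vascular channels.

    Opening with a spherical element of ``lacuna_opening_radius`` (µm)
    removes the thin canaliculi and leaves the bulky bodies, which are
    classified by volume (µm³): ≥ ``vascular_min_volume`` together with
    a slab-spanning/thick-tube check → vascular; within
    [``lacuna_min_volume``, ``vascular_min_volume``) → lacuna.  Each
    body then absorbs pore voxels within one opening radius.
    """
    mask = binary.voxels > 0
    s = binary.voxel_size
    r_vox = max(1, int(round(lacuna_opening_radius / s)))
    opened = opening(mask, ball(r_vox))
    bodies = cc_label(opened, connectivity=3)
    nz = mask.shape[0]
    vox_vol = s**3

    keep = np.zeros(bodies.max() + 1, dtype=np.uint8)  # 0 drop, else class
    for lab in range(1, bodies.max() + 1):
        where = bodies == lab
        vol = where.sum() * vox_vol
        zs = np.any(where, axis=(1, 2))
        spans_slab = bool(zs[0] and zs[nz - 1])
        extents = [np.ptp(idx) + 1 for idx in np.nonzero(where)]
        thick = min(extents) * s > 10.0
        if vol >= vascular_min_volume and (spans_slab or thick):
            keep[lab] = VASCULAR
        elif vol >= lacuna_min_volume:
            keep[lab] = LACUNA
        else:
            logger.info(
                "body %d (%.1f µm³) below lacuna_min_volume kept as canaliculus",
                lab,
                vol,
            )
    bodies = np.where(keep[bodies] > 0, bodies, 0)

    # "expanding the lacunae into the canaliculi": absorb a one-radius collar
    expanded = expand_labels(bodies, distance=r_vox)
    body_labels = np.where(mask, expanded, 0)
    classes = np.where(mask, CANALICULUS, BACKGROUND).astype(np.uint8)
    on_body = body_labels > 0
    classes[on_body] = keep[body_labels[on_body]]
    return PoreLabels(
        classes,
        body_labels.astype(np.int32),
        s,
        core_labels=np.where(mask, bodies, 0).astype(np.int32),
    )


_OFFSETS = np.array(
    [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ],
    dtype=np.int64,
)


def _voxel_position(coord, s):
    z, y, x = coord
    return np.array([(x + 0.5) * s, (y + 0.5) * s, (z + 0.5) * s])


def _path_length(path_coords: np.ndarray, s: float, stride: int = 5) -> float:
    """Centerline length from voxel path: summed chords over ``stride`` steps.

    Chord summing suppresses the systematic overestimate of summing
    single 26-connectivity steps along oblique digital lines while
    following genuine curvature of the canaliculus.
    """
    n = len(path_coords)
    if n < 2:
        return 0.0
    idx = list(range(0, n - 1, stride)) + [n - 1]
    pts = path_coords[idx].astype(float) * s
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def skeletonize_to_network(
    labels: PoreLabels,
    voxel_size: float | None = None,
    cross_section_area: float = DEFAULT_CROSS_SECTION_AREA,
    attach_distance: float = 4.0,
    prune_spurs: float = 0.75,
    junction_merge: float = 1.5,
) -> LCNNetwork:
    """Thin the canalicular phase and convert the skeleton into a network.

    Skeleton voxels with ≥3 neighbours (26-connectivity) become junction
    nodes (adjacent junction voxels merged, and junction pairs closer
    than ``junction_merge`` µm fused — thinning can split one anatomical
    intersection into nearby branch voxels); each lacunar/vascular body
    becomes a single node at its centroid carrying the body volume.
    Skeleton endpoints within ``attach_distance`` (µm) of a body connect
    to that body's node, with the gap to the pre-expansion body surface
    added to the edge length; other endpoints become boundary nodes
    (canaliculi leaving the imaged volume).  Free-ending spur edges
    shorter than ``prune_spurs`` (µm) are removed.  Deterministic:
    voxels are processed in lexicographic order.
    """
    s = voxel_size if voxel_size is not None else labels.voxel_size
    canal = labels.class_volume == CANALICULUS
    body_lab = labels.body_labels
    core_lab = labels.core_labels
    shape = canal.shape

    skel = skeletonize(canal) if canal.any() else np.zeros(shape, dtype=bool)
    coords = np.argwhere(skel)  # lexicographic (z, y, x)
    n_vox = len(coords)

    # ---- body nodes --------------------------------------------------
    nodes: list[Node] = []
    body_node: dict[int, int] = {}
    for lab in sorted(np.unique(body_lab[body_lab > 0]).tolist()):
        where = body_lab == lab
        cls = int(labels.class_volume[where].max())
        centroid_vox = np.argwhere(where).mean(axis=0)
        pos = np.array(
            [
                (centroid_vox[2] + 0.5) * s,
                (centroid_vox[1] + 0.5) * s,
                (centroid_vox[0] + 0.5) * s,
            ]
        )
        nid = len(nodes)
        kind = NodeKind.VASCULAR if cls == VASCULAR else NodeKind.LACUNA
        nodes.append(Node(nid, pos, kind, pore_volume=float(where.sum()) * s**3))
        body_node[lab] = nid

    if n_vox == 0:
        return LCNNetwork.from_components(nodes, [], voxel_size=s)

    # ---- skeleton adjacency -----------------------------------------
    flat = np.ravel_multi_index(coords.T, shape)
    order = np.argsort(flat)
    flat_sorted = flat[order]
    idx_of = {int(f): int(i) for i, f in enumerate(flat)}
    neighbors: list[list[int]] = [[] for _ in range(n_vox)]
    for off in _OFFSETS:
        shifted = coords + off
        valid = np.all((shifted >= 0) & (shifted < np.array(shape)), axis=1)
        if not valid.any():
            continue
        nb_flat = np.ravel_multi_index(shifted[valid].T, shape)
        pos_in = np.searchsorted(flat_sorted, nb_flat)
        pos_in = np.clip(pos_in, 0, n_vox - 1)
        hits = flat_sorted[pos_in] == nb_flat
        src = np.flatnonzero(valid)[hits]
        dst = order[pos_in[hits]]
        for a, b in zip(src, dst):
            neighbors[a].append(int(b))
    for lst in neighbors:
        lst.sort()
    degree = np.array([len(lst) for lst in neighbors])

    # ---- junction clusters ------------------------------------------
    is_junction = degree >= 3
    cluster = np.full(n_vox, -1, dtype=np.int64)
    clusters: list[list[int]] = []
    for i in range(n_vox):
        if is_junction[i] and cluster[i] < 0:
            cid = len(clusters)
            stack, members = [i], []
            cluster[i] = cid
            while stack:
                u = stack.pop()
                members.append(u)
                for w in neighbors[u]:
                    if is_junction[w] and cluster[w] < 0:
                        cluster[w] = cid
                        stack.append(w)
            clusters.append(sorted(members))

    junction_node: dict[int, int] = {}
    for cid, members in enumerate(clusters):
        pos = np.mean([_voxel_position(coords[i], s) for i in members], axis=0)
        nid = len(nodes)
        nodes.append(Node(nid, pos, NodeKind.JUNCTION, 0.0))
        junction_node[cid] = nid

    # ---- nearest-body attachment for endpoints -----------------------
    # search against the pre-expansion body surface so that the absorbed
    # collar is counted back into the canalicular length
    collar = max(attach_distance, 2.0 * s)
    attach_vox = max(1, int(np.ceil(collar / s)) + 2)

    def nearest_body(i):
        z, y, x = coords[i]
        zlo, zhi = max(z - attach_vox, 0), min(z + attach_vox + 1, shape[0])
        ylo, yhi = max(y - attach_vox, 0), min(y + attach_vox + 1, shape[1])
        xlo, xhi = max(x - attach_vox, 0), min(x + attach_vox + 1, shape[2])
        sub = core_lab[zlo:zhi, ylo:yhi, xlo:xhi]
        hit = np.argwhere(sub > 0)
        if len(hit) == 0:
            return None, 0.0
        abs_hit = hit + [zlo, ylo, xlo]
        d = np.linalg.norm((abs_hit - coords[i]) * s, axis=1)
        k = int(np.argmin(d))
        lab = int(core_lab[tuple(abs_hit[k])])
        if body_node.get(lab) is None or d[k] > collar + 2 * s:
            return None, 0.0
        return body_node.get(lab), float(d[k])

    # ---- trace chains ------------------------------------------------
    visited_chain = np.zeros(n_vox, dtype=bool)
    seen_direct: set[frozenset] = set()
    raw_edges = []  # (end_a_voxel, end_b_voxel, centerline_length, path)

    def is_terminal(i):
        return is_junction[i] or degree[i] == 1

    for start in range(n_vox):
        if not is_terminal(start):
            continue
        for nb in neighbors[start]:
            if is_terminal(nb):
                if (
                    is_junction[start]
                    and is_junction[nb]
                    and cluster[start] == cluster[nb]
                ):
                    continue
                key = frozenset((int(start), int(nb)))
                if key in seen_direct:
                    continue
                seen_direct.add(key)
                length = _path_length(coords[[start, nb]], s)
                raw_edges.append((start, nb, length, [start, nb]))
                continue
            if visited_chain[nb]:
                continue
            # walk the degree-2 chain until the next terminal voxel
            path = [start, nb]
            prev, cur = start, nb
            while not is_terminal(cur):
                visited_chain[cur] = True
                nxt = [w for w in neighbors[cur] if w != prev]
                if not nxt:
                    break
                prev, cur = cur, nxt[0]
                path.append(cur)
            raw_edges.append((start, cur, _path_length(coords[path], s), path))

    n_isolated = int((degree == 0).sum())
    if n_isolated:
        logger.info("dropped %d isolated skeleton voxels", n_isolated)

    # ---- map terminals to nodes, build edges -------------------------
    endpoint_node: dict[int, int] = {}
    edges: list[Canaliculus] = []

    def terminal_node(i):
        """(node id, extra length) for a terminal skeleton voxel."""
        if is_junction[i]:
            return junction_node[cluster[i]], 0.0
        if i in endpoint_node:
            return endpoint_node[i], 0.0
        nid, gap = nearest_body(i)
        if nid is not None:
            return nid, gap
        new_id = len(nodes)
        nodes.append(Node(new_id, _voxel_position(coords[i], s), NodeKind.JUNCTION))
        endpoint_node[i] = new_id
        return new_id, 0.0

    pruned = 0
    for a, b, length, path in raw_edges:
        na, extra_a = terminal_node(a)
        nb_, extra_b = terminal_node(b)
        total = length + extra_a + extra_b
        free_end = (degree[a] == 1 and extra_a == 0.0 and not is_junction[a]) or (
            degree[b] == 1 and extra_b == 0.0 and not is_junction[b]
        )
        if free_end and total < prune_spurs:
            pruned += 1
            continue
        if na == nb_:
            if total < 3 * s:
                logger.info("collapsed a short skeleton cycle")
                continue
            # longer cycle back to the same node: split with a midpoint node
            mid_vox = path[len(path) // 2]
            mid_id = len(nodes)
            nodes.append(
                Node(mid_id, _voxel_position(coords[mid_vox], s), NodeKind.JUNCTION)
            )
            edges.append(Canaliculus(len(edges), na, mid_id, max(total / 2, s / 2),
                                     cross_section_area))
            edges.append(Canaliculus(len(edges), mid_id, nb_, max(total / 2, s / 2),
                                     cross_section_area))
            continue
        edges.append(Canaliculus(len(edges), na, nb_, max(total, s / 2),
                                 cross_section_area))
    if pruned:
        logger.info("pruned %d spur edges", pruned)

    # fuse junction nodes joined by very short edges: thinning can split
    # one anatomical intersection into nearby branch voxels
    body_ids = set(body_node.values())
    parent = list(range(len(nodes)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for e in edges:
        if (
            e.length < junction_merge
            and e.node_a not in body_ids
            and e.node_b not in body_ids
        ):
            ra, rb = find(e.node_a), find(e.node_b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    groups: dict[int, list[int]] = {}
    for n in nodes:
        groups.setdefault(find(n.id), []).append(n.id)
    for root, members in groups.items():
        if len(members) > 1:
            nodes[root].position = np.mean(
                [np.asarray(nodes[i].position) for i in members], axis=0
            )
    merged_edges = []
    for e in edges:
        a, b = find(e.node_a), find(e.node_b)
        if a == b:
            continue
        merged_edges.append(
            Canaliculus(len(merged_edges), a, b, e.length, e.cross_section_area)
        )
    edges = merged_edges

    # drop nodes that ended up unused (pruned spurs, fused junctions)
    used = {e.node_a for e in edges} | {e.node_b for e in edges} | body_ids
    kept_nodes = [n for n in nodes if n.id in used]
    return LCNNetwork.from_components(kept_nodes, edges, voxel_size=s)
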