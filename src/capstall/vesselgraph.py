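"""Capillary centerline extraction.

The extraction chain mirrors the standard semi-automated workflow: a
Hessian-eigenvalue (Frangi) tubularity filter boosts thin vessels, a global
threshold segments vessel from background, morphological thinning produces a
one-pixel skeleton, the skeleton is converted to a graph of junction/endpoint
nodes and traced edges, and each user click selects the nearest edge as that
capillary's centerline.  Centerlines of 5 pixels or less are excluded from
analysis — too short for a meaningful length-time image.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import frangi, threshold_otsu
from skimage.morphology import skeletonize

from .errors import ConfigurationError, NoVesselNearClickError, ValidationError
from .types import Centerline, GraphEdge, GraphNode, VesselGraph

__all__ = [
    "enhance_vessels",
    "segment",
    "skeletonize_mask",
    "skeleton_to_graph",
    "select_centerline",
    "filter_short_centerlines",
    "extract_centerlines",
]

MIN_CENTERLINE_PX = 6  # paths of 5 px or less are excluded


def enhance_vessels(image, scales_px, polarity="bright"):
    """Frangi vesselness of a 2D image, normalized to [0, 1].

    ``scales_px`` are the Gaussian scales (pixels) of the Hessian; choose them
    to span the expected vessel radii.  ``polarity`` selects bright tubes on a
    dark background (angiograms) or the reverse.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValidationError("enhance_vessels expects a 2D image")
    if not np.all(np.isfinite(image)):
        raise ValidationError("image must be finite")
    scales = list(scales_px)
    if len(scales) == 0:
        raise ConfigurationError("at least one vesselness scale is required")
    if any(s <= 0 for s in scales):
        raise ConfigurationError("vesselness scales must be positive")
    if polarity not in ("bright", "dark"):
        raise ConfigurationError("polarity must be 'bright' or 'dark'")
    v = frangi(image, sigmas=scales, black_ridges=(polarity == "dark"))
    vmax = v.max()
    if vmax > 0:
        v = v / vmax
    return np.clip(v, 0.0, 1.0)


def segment(vesselness, threshold=None):
    """Binary vessel mask: ``vesselness >= threshold``.

    With ``threshold=None`` Otsu's method picks the threshold from the
    vesselness histogram.
    """
    vesselness = np.asarray(vesselness, dtype=float)
    if threshold is None:
        threshold = float(threshold_otsu(vesselness))
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError("segmentation threshold must lie in [0, 1]")
    return vesselness >= threshold


def skeletonize_mask(mask):
    """One-pixel-wide centerline skeleton of a binary mask (thinning)."""
    mask = np.asarray(mask).astype(bool)
    return skeletonize(mask)


_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _has_2x2_block(skel):
    return bool(np.any(skel[:-1, :-1] & skel[:-1, 1:] & skel[1:, :-1] & skel[1:, 1:]))


def skeleton_to_graph(skeleton) -> VesselGraph:
    """Convert a thin skeleton to a graph of nodes and traced edge paths.

    Nodes are skeleton pixels with a number of 8-neighbors other than two
    (endpoints have one, branchpoints three or more); edges are the maximal
    paths of degree-two pixels between nodes.  An isolated closed loop has no
    such pixel, so its lexicographically smallest pixel is promoted to an
    anchor node carrying a closed self-edge.
    """
    skel = np.asarray(skeleton).astype(bool)
    if skel.ndim != 2:
        raise ValidationError("skeleton must be 2D")
    if _has_2x2_block(skel):
        raise ValidationError("skeleton is not one pixel wide (contains a 2x2 block)")

    ys, xs = np.nonzero(skel)
    pixels = set(zip(xs.tolist(), ys.tolist()))  # (x, y)
    if not pixels:
        return VesselGraph()

    def neighbors(p):
        x, y = p
        return [(x + dx, y + dy) for dy, dx in _NEIGHBORS if (x + dx, y + dy) in pixels]

    degree = {p: len(neighbors(p)) for p in pixels}
    node_pixels = sorted(p for p, d in degree.items() if d != 2)
    node_id = {p: i for i, p in enumerate(node_pixels)}
    nodes = [GraphNode(i, p[0], p[1]) for i, p in enumerate(node_pixels)]

    edges = []
    used_steps = set()  # directed (from, to) steps already traced

    def trace(start, first):
        """Follow degree-2 pixels from node pixel ``start`` via ``first``."""
        path = [start, first]
        used_steps.add((start, first))
        prev, cur = start, first
        while cur not in node_id:
            nxt = [q for q in neighbors(cur) if q != prev]
            if len(nxt) != 1:  # pragma: no cover - guarded by degree census
                raise ValidationError("skeleton tracing failed; is the skeleton thin?")
            prev, cur = cur, nxt[0]
            path.append(cur)
        used_steps.add((path[-2], path[-1]))
        return path

    for p in node_pixels:
        for q in sorted(neighbors(p)):
            if (p, q) in used_steps:
                continue
            if q in node_id:
                # two adjacent node pixels form a two-pixel edge
                used_steps.add((p, q))
                used_steps.add((q, p))
                path = [p, q]
            else:
                path = trace(p, q)
                used_steps.add((path[-1], path[-2]))
            edges.append((p, path[-1], path))

    # isolated cycles: every remaining untraced pixel has degree 2
    traced = {p for _, _, path in edges for p in path}
    remaining = sorted(pixels - traced - set(node_pixels))
    visited = set()
    for p in remaining:
        if p in visited:
            continue
        anchor = p
        node_id[anchor] = len(nodes)
        nodes.append(GraphNode(node_id[anchor], anchor[0], anchor[1]))
        nbrs = sorted(neighbors(anchor))
        path = trace(anchor, nbrs[0])
        visited.update(path)
        edges.append((anchor, anchor, path))

    graph_edges = []
    for i, (a, b, path) in enumerate(edges):
        graph_edges.append(
            GraphEdge(i, node_id[a], node_id[b], np.array(path, dtype=int))
        )
    return VesselGraph(nodes, graph_edges)


def select_centerline(graph: VesselGraph, click, capillary_id=None, max_click_distance=20.0):
    """Return the graph edge nearest a click as a :class:`Centerline`.

    The selected edge is the one whose path contains the pixel with minimum
    Euclidean distance to the click; exact ties go to the lowest edge id.  A
    nearest distance beyond ``max_click_distance`` raises
    :class:`NoVesselNearClickError`.
    """
    if graph.n_edges == 0:
        raise ValidationError("graph has no edges")
    click = np.asarray(click, dtype=float)
    best_id, best_d = None, np.inf
    for edge in sorted(graph.edges, key=lambda e: e.id):
        d = np.sqrt(((edge.path - click[None, :]) ** 2).sum(axis=1)).min()
        if d < best_d - 1e-12:
            best_id, best_d = edge.id, d
    if best_d > max_click_distance:
        raise NoVesselNearClickError(tuple(click), best_d, max_click_distance)
    edge = graph.edges[best_id]
    return Centerline(capillary_id if capillary_id is not None else edge.id, edge.path.astype(float))


def filter_short_centerlines(centerlines):
    """Drop centerlines of 5 pixels or less (length >= 6 retained)."""
    return [c for c in centerlines if c.length_px >= MIN_CENTERLINE_PX]


def extract_centerlines(
    image,
    clicks,
    scales_px=(1.0, 2.0, 3.0, 4.0),
    segmentation_threshold=None,
    max_click_distance=20.0,
    polarity="bright",
):
    """Full extraction chain from a single 2D image and a list of clicks.

    ``clicks`` is a sequence of ``(label, x, y)``; the returned list holds one
    :class:`Centerline` per click that found a vessel, already filtered for
    the minimum length.  Clicks that miss (``NoVesselNearClickError``) are
    skipped and reported in the second return value.
    """
    v = enhance_vessels(image, scales_px, polarity)
    mask = segment(v, segmentation_threshold)
    skel = skeletonize_mask(mask)
    graph = skeleton_to_graph(skel)
    centerlines, missed = [], []
    for label, x, y in clicks:
        try:
            centerlines.append(
                select_centerline(graph, (x, y), capillary_id=label, max_click_distance=max_click_distance)
            )
        except NoVesselNearClickError:
            missed.append(label)
    return filter_short_centerlines(centerlines), missed
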