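"""Synthetic fundus images, vascular trees, DLA clusters and fractal phantoms.

Every generator here is a pure function of its spec (seed included), so
downstream stages — segmentation, skeleton/graph extraction, network features,
fractal analysis — can be validated against exact ground truth without any
external image database.

The vascular tree generator emulates the gross geometry of a fundus
photograph: a bright optic disc from which dark vessels radiate, branching
dichotomously with tapering width.  A "disease" cohort is emulated either by
globally wider vessels (an intraocular-pressure surrogate) or by extra short
thin side branches (a neovascularization surrogate).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "TreeSpec",
    "GroundTruthTree",
    "GtNode",
    "GtSegment",
    "SyntheticImage",
    "DlaSpec",
    "generate_vessel_tree",
    "generate_cohort",
    "generate_dla",
    "make_phantom",
    "disease_variant",
    "clean_tree_spec",
    "connected",
]


# ---------------------------------------------------------------------------
# specs and ground-truth containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TreeSpec:
    """Parameters of a synthetic dichotomous vascular tree.

    Attributes
    ----------
    image_size : int
        Side of the square raster in pixels (>= 256).
    root_position : (float, float) or None
        (row, col) of the optic-disc center; defaults to mid-height,
        15% of the width from the left edge.
    root_width : float
        Stroke width of the primary trunks, pixels.
    n_trunks : int
        Number of primary vessels leaving the disc.
    branch_probability : float or sequence of float
        Probability that a segment bifurcates at its distal end; a sequence
        gives one probability per generation (last value reused beyond).
    max_depth : int
        Maximum number of segment generations (trunk = generation 1).
    trunk_length : float or None
        Length of a generation-1 segment in pixels; defaults to 22% of
        ``image_size``.
    length_decay, width_decay : float
        Multiplicative decay of child length / width per bifurcation
        (Murray-like tapering); widths floored at 1 px.
    branch_angle_spread : float
        Half-opening angle (radians) between the two children of a
        bifurcation, jittered per branch.
    thin_branch_rate : float
        Expected number of extra short, thin side branches spawned along each
        segment (Poisson), a neovascularization surrogate.
    seed : int
        Seed for all randomness in the generator.
    """

    image_size: int = 512
    root_position: tuple[float, float] | None = None
    root_width: float = 5.0
    n_trunks: int = 4
    branch_probability: float | tuple[float, ...] = 0.9
    max_depth: int = 5
    trunk_length: float | None = None
    length_decay: float = 0.72
    width_decay: float = 0.80
    branch_angle_spread: float = 0.55
    thin_branch_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 256:
            raise ValueError("image_size must be >= 256")
        if self.root_width < 1:
            raise ValueError("root_width must be >= 1")
        if self.thin_branch_rate < 0 or self.n_trunks < 1:
            raise ValueError("rates and counts must be non-negative")

    def branch_prob(self, generation: int) -> float:
        p = self.branch_probability
        if isinstance(p, Sequence):
            return float(p[min(generation - 1, len(p) - 1)])
        return float(p)

    @property
    def root(self) -> tuple[float, float]:
        if self.root_position is not None:
            return self.root_position
        return (self.image_size / 2.0, 0.15 * self.image_size)

    @property
    def trunk_len(self) -> float:
        return self.trunk_length if self.trunk_length is not None else 0.22 * self.image_size

    @property
    def disc_radius(self) -> float:
        return max(8.0, 2.5 * self.root_width + 4.0)


@dataclass
class GtNode:
    id: int
    position: tuple[float, float]  # (row, col)
    kind: Literal["root", "bifurcation", "endpoint"]


@dataclass
class GtSegment:
    node_a: int
    node_b: int
    length: float  # centerline length, px
    width: float  # stroke width, px
    clipped: bool = False


@dataclass
class GroundTruthTree:
    """Connected acyclic centerline tree with per-segment length and width."""

    nodes: list[GtNode]
    segments: list[GtSegment]

    def counts(self) -> dict[str, int]:
        deg: dict[int, int] = {n.id: 0 for n in self.nodes}
        for s in self.segments:
            deg[s.node_a] += 1
            deg[s.node_b] += 1
        return {
            "nodes": len(self.nodes),
            "links": len(self.segments),
            "endpoints": sum(1 for n in self.nodes if deg[n.id] == 1),
            "bifurcations": sum(1 for n in self.nodes if deg[n.id] >= 3),
        }

    def to_json(self) -> str:
        return json.dumps(
            {
                "nodes": [
                    {"id": n.id, "row": n.position[0], "col": n.position[1], "kind": n.kind}
                    for n in self.nodes
                ],
                "segments": [
                    {
                        "a": s.node_a,
                        "b": s.node_b,
                        "length": s.length,
                        "width": s.width,
                        "clipped": s.clipped,
                    }
                    for s in self.segments
                ],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthTree":
        d = json.loads(text)
        nodes = [GtNode(n["id"], (n["row"], n["col"]), n["kind"]) for n in d["nodes"]]
        segs = [
            GtSegment(s["a"], s["b"], s["length"], s["width"], s.get("clipped", False))
            for s in d["segments"]
        ]
        return cls(nodes, segs)


@dataclass
class SyntheticImage:
    """Pseudo-fundus raster with its exact vessel mask and centerline tree."""

    raster: np.ndarray  # (H, W, 3) uint8, vessels darker than background
    mask: np.ndarray  # (H, W) bool, exactly the rasterized segments
    tree: GroundTruthTree
    group_label: str = ""
    spec: TreeSpec | None = None
    clipped: bool = False

    @property
    def disc_center(self) -> tuple[float, float]:
        assert self.spec is not None
        return self.spec.root

    @property
    def disc_radius(self) -> float:
        assert self.spec is not None
        return self.spec.disc_radius


@dataclass(frozen=True)
class DlaSpec:
    """Diffusion-limited aggregation run: sticky random walkers on a lattice."""

    particle_count: int = 20_000
    lattice_size: int = 1024
    seed: int = 0

    def __post_init__(self) -> None:
        if self.particle_count < 1:
            raise ValueError("particle_count must be >= 1")
        if self.particle_count > (self.lattice_size // 2) ** 2:
            raise ValueError("lattice too small for the requested particle count")


# ---------------------------------------------------------------------------
# vascular tree generation
# ---------------------------------------------------------------------------


def _grow_tree(spec: TreeSpec, rng: np.random.Generator) -> tuple[GroundTruthTree, bool]:
    """Grow the centerline tree; returns (tree, any_segment_clipped)."""
    size = spec.image_size
    root_pos = spec.root
    nodes: list[GtNode] = [GtNode(0, root_pos, "root")]
    segments: list[GtSegment] = []
    clipped_any = False

    def add_node(pos: tuple[float, float], kind: str) -> int:
        nid = len(nodes)
        nodes.append(GtNode(nid, pos, kind))  # type: ignore[arg-type]
        return nid

    def clip_point(p0: np.ndarray, p1: np.ndarray) -> tuple[np.ndarray, bool]:
        """Clip p1 so the segment p0->p1 stays 2 px inside the raster."""
        lo, hi = 2.0, size - 3.0
        d = p1 - p0
        t = 1.0
        for k in range(2):
            if d[k] > 0 and p1[k] > hi:
                t = min(t, (hi - p0[k]) / d[k])
            elif d[k] < 0 and p1[k] < lo:
                t = min(t, (lo - p0[k]) / d[k])
        if t < 1.0:
            return p0 + max(t, 0.0) * d, True
        return p1, False

    # stack of (parent_node_id, origin, angle, length, width, generation)
    trunk_angles = _trunk_angles(spec, rng)
    stack = [
        (0, np.asarray(root_pos, float), ang, spec.trunk_len, float(spec.root_width), 1)
        for ang in trunk_angles
    ]
    while stack:
        parent_id, origin, angle, length, width, gen = stack.pop()
        direction = np.array([np.sin(angle), np.cos(angle)])  # row, col
        end = origin + length * direction
        end, was_clipped = clip_point(origin, end)
        clipped_any |= was_clipped
        seg_len = float(np.hypot(*(end - origin)))
        if seg_len < 2.0:
            # too short to raster meaningfully; drop the branch
            continue

        will_branch = (
            not was_clipped
            and gen < spec.max_depth
            and rng.random() < spec.branch_prob(gen)
        )

        # optional thin side branches, splitting this segment where they attach
        n_side = rng.poisson(spec.thin_branch_rate) if spec.thin_branch_rate > 0 else 0
        attach_ts = np.sort(rng.uniform(0.25, 0.75, size=n_side)) if n_side else []
        prev_id, prev_pos, prev_t = parent_id, origin, 0.0
        for t in attach_ts:
            jpos = origin + t * (end - origin)
            jid = add_node(tuple(jpos), "bifurcation")
            segments.append(
                GtSegment(prev_id, jid, seg_len * (t - prev_t), width, was_clipped)
            )
            side_angle = angle + rng.choice([-1.0, 1.0]) * rng.uniform(0.8, 1.3)
            side_len = max(6.0, 0.3 * length)
            side_w = max(1.0, min(1.5, 0.35 * width))
            s_end = jpos + side_len * np.array([np.sin(side_angle), np.cos(side_angle)])
            s_end, s_clip = clip_point(jpos, s_end)
            if float(np.hypot(*(s_end - jpos))) >= 2.0:
                eid = add_node(tuple(s_end), "endpoint")
                segments.append(
                    GtSegment(jid, eid, float(np.hypot(*(s_end - jpos))), side_w, s_clip)
                )
                clipped_any |= s_clip
            prev_id, prev_pos, prev_t = jid, jpos, t

        end_kind = "bifurcation" if will_branch else "endpoint"
        end_id = add_node(tuple(end), end_kind)
        segments.append(
            GtSegment(prev_id, end_id, seg_len * (1.0 - prev_t), width, was_clipped)
        )

        if will_branch:
            half = spec.branch_angle_spread
            jitter = rng.uniform(0.7, 1.3, size=2)
            child_len = length * spec.length_decay * rng.uniform(0.85, 1.15)
            child_w = max(1.0, width * spec.width_decay)
            for sign, j in zip((-1.0, 1.0), jitter):
                stack.append(
                    (end_id, end, angle + sign * half * j, child_len, child_w, gen + 1)
                )

    return GroundTruthTree(nodes, segments), clipped_any


def _trunk_angles(spec: TreeSpec, rng: np.random.Generator) -> np.ndarray:
    """Primary vessels fan out from the disc toward the image interior."""
    if spec.n_trunks == 1:
        return np.array([rng.uniform(-0.25, 0.25)])
    fan = np.linspace(-1.05, 1.05, spec.n_trunks)
    return fan + rng.uniform(-0.08, 0.08, size=spec.n_trunks)


def _rasterize_tree(tree: GroundTruthTree, size: int) -> tuple[np.ndarray, np.ndarray]:
    """Anti-aliased capsule strokes; mask = soft intensity thresholded at 0.5.

    Returns (soft, mask) where soft in [0,1] is the anti-aliased vessel map.
    """
    soft = np.zeros((size, size), dtype=np.float64)
    pos = {n.id: np.asarray(n.position, float) for n in tree.nodes}
    for s in tree.segments:
        p0, p1 = pos[s.node_a], pos[s.node_b]
        r = s.width / 2.0
        lo = np.maximum(np.floor(np.minimum(p0, p1) - r - 1).astype(int), 0)
        hi = np.minimum(np.ceil(np.maximum(p0, p1) + r + 2).astype(int), size)
        if np.any(hi <= lo):
            continue
        rows = np.arange(lo[0], hi[0])
        cols = np.arange(lo[1], hi[1])
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        d = p1 - p0
        L2 = float(d @ d)
        vr = rr - p0[0]
        vc = cc - p0[1]
        if L2 > 0:
            t = np.clip((vr * d[0] + vc * d[1]) / L2, 0.0, 1.0)
        else:
            t = 0.0
        dr = vr - t * d[0]
        dc = vc - t * d[1]
        dist = np.sqrt(dr * dr + dc * dc)
        # 1 inside the capsule, linear anti-aliased ramp over one pixel
        patch = np.clip(r + 0.5 - dist, 0.0, 1.0)
        np.maximum(soft[lo[0] : hi[0], lo[1] : hi[1]], patch, out=soft[lo[0] : hi[0], lo[1] : hi[1]])
    return soft, soft > 0.5


def _render_fundus(
    spec: TreeSpec, soft: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Pseudo-fundus RGB: warm vignetted background, bright disc, dark vessels."""
    size = spec.image_size
    rr, cc = np.mgrid[0:size, 0:size]
    center = size / 2.0
    radial = np.sqrt((rr - center) ** 2 + (cc - center) ** 2) / (center * np.sqrt(2))
    bg = 0.82 - 0.25 * radial**2
    bg = bg + 0.015 * rng.standard_normal((size, size))

    r0, c0 = spec.root
    disc_d = np.sqrt((rr - r0) ** 2 + (cc - c0) ** 2)
    disc = np.clip(spec.disc_radius + 0.5 - disc_d, 0.0, 1.0)

    green = bg * (1.0 - 0.55 * soft) + 0.18 * disc
    red = (bg * 0.9 + 0.25) * (1.0 - 0.35 * soft) + 0.15 * disc
    blue = bg * 0.35 * (1.0 - 0.3 * soft) + 0.10 * disc
    img = np.stack([red, green, blue], axis=-1)
    return (np.clip(img, 0.0, 1.0) * 255).round().astype(np.uint8)


def generate_vessel_tree(spec: TreeSpec) -> SyntheticImage:
    """Generate one synthetic fundus image with exact ground truth.

    Deterministic given ``spec`` (including ``spec.seed``).  Segments that
    would leave the raster are clipped at the border and flagged; a spec with
    ``max_depth=0`` degenerates to a single trunk segment.
    """
    rng = np.random.default_rng(spec.seed)
    eff_spec = spec
    if spec.max_depth < 1:
        eff_spec = replace(spec, max_depth=1, branch_probability=0.0)
    tree, clipped = _grow_tree(eff_spec, rng)
    soft, mask = _rasterize_tree(tree, spec.image_size)
    raster = _render_fundus(spec, soft, rng)
    return SyntheticImage(
        raster=raster, mask=mask, tree=tree, spec=spec, clipped=clipped
    )


def disease_variant(
    healthy: TreeSpec,
    *,
    width_scale: float = 1.0,
    thin_branch_rate: float | None = None,
) -> TreeSpec:
    """Derive a diseased-cohort spec from a healthy one.

    ``width_scale > 1`` emulates globally swollen vessels (pressure surrogate,
    glaucoma-like); ``thin_branch_rate > 0`` emulates neovascular sprouting of
    short thin vessels (diabetic-retinopathy-like).
    """
    kwargs: dict = {"root_width": healthy.root_width * width_scale}
    if thin_branch_rate is not None:
        kwargs["thin_branch_rate"] = thin_branch_rate
    return replace(healthy, **kwargs)


def clean_tree_spec(seed: int = 0, image_size: int = 512) -> TreeSpec:
    """Spec for a validation tree whose branches never cross or leave the frame.

    Used to compare extracted-graph node/segment counts against the
    generator's bookkeeping: three trunks (so the root itself is a
    bifurcation), always-branching recursion of depth 4, and a narrow branch
    fan with fast length decay so sibling subtrees stay disjoint.
    """
    return TreeSpec(
        image_size=image_size,
        n_trunks=3,
        branch_probability=1.0,
        max_depth=4,
        trunk_length=95.0 * image_size / 512.0,
        length_decay=0.62,
        width_decay=0.8,
        branch_angle_spread=0.4,
        root_width=4.0,
        thin_branch_rate=0.0,
        seed=seed,
    )


def generate_cohort(
    healthy: TreeSpec,
    disease: TreeSpec,
    n_per_group: int,
    seed: int,
    labels: tuple[str, str] = ("healthy", "disease"),
) -> list[SyntheticImage]:
    """Two labelled groups of synthetic images with per-image derived seeds."""
    if n_per_group < 0:
        raise ValueError("n_per_group must be >= 0")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(2 * n_per_group) % (2**31 - 1)
    out: list[SyntheticImage] = []
    for i in range(n_per_group):
        for j, (spec, label) in enumerate(zip((healthy, disease), labels)):
            img = generate_vessel_tree(replace(spec, seed=int(child_seeds[2 * i + j])))
            img.group_label = label
            out.append(img)
    return out


# ---------------------------------------------------------------------------
# diffusion-limited aggregation
# ---------------------------------------------------------------------------


def generate_dla(spec: DlaSpec) -> np.ndarray:
    """Grow an on-lattice DLA aggregate; returns a boolean mask.

    Walkers are born on a circle just outside the cluster, take 4-neighbour
    steps, stick on 4-neighbour contact, and are respawned when they wander
    past a kill radius of 3x the current cluster radius.  Deterministic given
    ``spec.seed``.
    """
    from ._dla import grow_dla  # deferred: numba compilation on first use

    grid = grow_dla(spec.lattice_size, spec.particle_count, spec.seed)
    return grid.astype(bool)


# ---------------------------------------------------------------------------
# analytic phantoms for the box-counting suite
# ---------------------------------------------------------------------------


def make_phantom(
    kind: Literal["filled_square", "line", "sierpinski_carpet"], size: int
) -> np.ndarray:
    """Deterministic binary phantoms with known box-counting dimension."""
    if kind == "filled_square":
        return np.ones((size, size), dtype=bool)
    if kind == "line":
        m = np.zeros((size, size), dtype=bool)
        m[size // 2, :] = True
        return m
    if kind == "sierpinski_carpet":
        depth = round(np.log(size) / np.log(3))
        if 3**depth != size:
            raise ValueError("sierpinski_carpet size must be a power of 3")
        idx = np.arange(size)
        digits = np.stack([(idx // 3**k) % 3 for k in range(depth)])  # (depth, size)
        mid = digits == 1
        # a pixel is removed iff some base-3 digit position has 1 in both axes
        hole = np.zeros((size, size), dtype=bool)
        for k in range(depth):
            hole |= mid[k][:, None] & mid[k][None, :]
        return ~hole
    raise ValueError(f"unknown phantom kind: {kind!r}")


def connected(mask: np.ndarray) -> bool:
    """Flood-fill check that all set pixels form one 8-connected component."""
    from scipy import ndimage

    if not mask.any():
        return True
    _, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    return n == 1
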