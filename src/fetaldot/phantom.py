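"""Synthetic maternal-fetal tetrahedral phantoms and optode layouts.

The phantom is a layered abdominal slab (fat, abdominal muscle/uterus,
amniotic fluid) with an embedded spherical fetal head built from concentric
shells (scalp muscle, skull, CSF, brain).  The slab can optionally be bent
into a cylindrical abdomen surface.  Meshes are structured (each hex cell is
split into six tetrahedra along a consistent diagonal), which keeps the
generator deterministic and the element quality uniform.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree


class TissueLabel(enum.IntEnum):
    """Tissue classes carried per element.

    Maternal muscle and uterus share optical properties and are merged into
    one label; likewise fetal skull and spinal cord.
    """

    MATERNAL_FAT = 0
    MATERNAL_MUSCLE_UTERUS = 1
    AMNIOTIC_FLUID = 2
    FETAL_MUSCLE = 3
    FETAL_SKULL_SPINAL = 4
    FETAL_CSF = 5
    FETAL_BRAIN = 6


MATERNAL_LABELS = frozenset(
    {TissueLabel.MATERNAL_FAT, TissueLabel.MATERNAL_MUSCLE_UTERUS}
)
FLUID_LABELS = frozenset({TissueLabel.AMNIOTIC_FLUID, TissueLabel.FETAL_CSF})
PULSATILE_LABELS = frozenset({TissueLabel.FETAL_BRAIN, TissueLabel.FETAL_MUSCLE})


class GeometryError(ValueError):
    """Raised when a phantom specification is geometrically impossible."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric description of a layered maternal-fetal phantom.

    All lengths in mm.  Depth is measured from the abdominal surface into
    the body.  ``brain_depth`` is derived (surface -> brain boundary) and,
    if supplied, must be consistent with the layer stack.
    """

    fat_thickness: float = 10.0
    muscle_thickness: float = 10.0
    fluid_gap: float = 4.0
    fetal_head_radius: float = 45.0
    scalp_thickness: float = 2.0
    skull_thickness: float = 2.0
    csf_thickness: float = 2.0
    brain_depth: float | None = None
    abdomen_curvature_radius: float | None = None
    target_edge_length: float = 5.0
    lateral_extent: tuple[float, float] = (170.0, 140.0)
    depth_extent: float | None = None

    @property
    def shell_sum(self) -> float:
        return self.scalp_thickness + self.skull_thickness + self.csf_thickness

    @property
    def head_top_depth(self) -> float:
        """Depth of the fetal scalp surface below the abdominal surface."""
        return self.fat_thickness + self.muscle_thickness + self.fluid_gap

    @property
    def derived_brain_depth(self) -> float:
        return self.head_top_depth + self.shell_sum

    @property
    def brain_radius(self) -> float:
        return self.fetal_head_radius - self.shell_sum

    def validate(self) -> None:
        for name in ("fat_thickness", "muscle_thickness", "fluid_gap",
                     "fetal_head_radius", "scalp_thickness",
                     "skull_thickness", "csf_thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.target_edge_length <= 0:
            raise ValueError("target_edge_length must be > 0")
        if self.brain_radius <= 0:
            raise GeometryError(
                "shell thicknesses exceed fetal head radius "
                f"({self.shell_sum} >= {self.fetal_head_radius})"
            )
        if self.brain_depth is not None:
            if abs(self.brain_depth - self.derived_brain_depth) > 1e-9:
                raise ValueError(
                    "brain_depth inconsistent with layer stack: "
                    f"{self.brain_depth} != {self.derived_brain_depth}"
                )
        if self.abdomen_curvature_radius is not None:
            if self.abdomen_curvature_radius <= self.domain_depth:
                raise GeometryError(
                    "abdomen curvature radius must exceed domain depth"
                )

    @property
    def domain_depth(self) -> float:
        if self.depth_extent is not None:
            return self.depth_extent
        # deep enough to contain most of the head plus a fluid margin
        return self.head_top_depth + 2.0 * self.fetal_head_radius * 0.8


@dataclass
class TetMesh:
    """Labeled tetrahedral mesh.

    ``nodes`` are (n, 3) coordinates in mm; ``elements`` are (m, 4) node
    indices with positive orientation; one :class:`TissueLabel` per element.
    """

    nodes: np.ndarray
    elements: np.ndarray
    element_labels: np.ndarray
    surface_faces: np.ndarray = field(default=None)  # type: ignore[assignment]
    _volumes: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        self.element_labels = np.asarray(self.element_labels, dtype=np.int64)
        if self.elements.max(initial=-1) >= len(self.nodes):
            raise ValueError("element refers to a node index out of range")
        if self.surface_faces is None:
            self.surface_faces = boundary_faces(self.elements)

    @property
    def num_nodes(self) -> int:
        return len(self.nodes)

    @property
    def num_elements(self) -> int:
        return len(self.elements)

    @property
    def element_volumes(self) -> np.ndarray:
        if self._volumes is None:
            self._volumes = tet_volumes(self.nodes, self.elements)
        return self._volumes

    @property
    def node_volumes(self) -> np.ndarray:
        """Lumped nodal volumes (mm^3): each tet contributes V/4 per vertex."""
        nv = np.zeros(self.num_nodes)
        np.add.at(nv, self.elements.ravel(),
                  np.repeat(self.element_volumes / 4.0, 4))
        return nv

    def nodes_with_label(self, label: TissueLabel) -> np.ndarray:
        """Sorted unique indices of nodes touching any element of ``label``."""
        mask = self.element_labels == int(label)
        return np.unique(self.elements[mask].ravel())

    def surface_node_ids(self) -> np.ndarray:
        return np.unique(self.surface_faces.ravel())


def tet_volumes(nodes: np.ndarray, elements: np.ndarray) -> np.ndarray:
    a, b, c, d = (nodes[elements[:, i]] for i in range(4))
    return np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a) / 6.0


def boundary_faces(elements: np.ndarray) -> np.ndarray:
    """Faces that belong to exactly one tetrahedron."""
    faces = elements[:, [[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]]]
    faces = faces.reshape(-1, 3)
    key = np.sort(faces, axis=1)
    _, idx, counts = np.unique(key, axis=0, return_index=True,
                               return_counts=True)
    return faces[idx[counts == 1]]


# Alternating five-tet subdivision of a hex cell (four right-corner tets
# plus one central regular tet).  The two mirrored variants are applied in a
# checkerboard over cells so face diagonals match and the mesh carries the
# lattice mirror symmetries (keeps the numerical anisotropy non-chiral).
# Corner index = dx*4 + dy*2 + dz.
_FIVE_TETS_EVEN = (
    (0, 6, 5, 3),  # central
    (4, 0, 6, 5),
    (2, 0, 6, 3),
    (1, 0, 5, 3),
    (7, 6, 5, 3),
)
_FIVE_TETS_ODD = (
    (4, 2, 1, 7),  # central
    (0, 4, 2, 1),
    (6, 4, 2, 7),
    (5, 4, 1, 7),
    (3, 2, 1, 7),
)


def structured_box_mesh(
    size: Sequence[float],
    edge_length: float,
    origin: Sequence[float] = (0.0, 0.0, 0.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Structured tet mesh of an axis-aligned box; returns (nodes, elements)."""
    size = np.asarray(size, dtype=float)
    if edge_length <= 0:
        raise ValueError("edge_length must be > 0")
    counts = np.maximum(np.round(size / edge_length).astype(int), 1)
    axes = [np.linspace(0.0, size[i], counts[i] + 1) + origin[i]
            for i in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    nodes = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    nx, ny, nz = counts
    # node linear index helper on the (nx+1, ny+1, nz+1) lattice
    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    ii, jj, kk = ii.ravel(), jj.ravel(), kk.ravel()
    corner = np.empty((len(ii), 8), dtype=np.int64)
    for bit in range(8):
        dx, dy, dz = (bit >> 2) & 1, (bit >> 1) & 1, bit & 1
        corner[:, bit] = nid(ii + dx, jj + dy, kk + dz)
    parity = (ii + jj + kk) % 2 == 0
    parts = []
    for mask, tets in ((parity, _FIVE_TETS_EVEN),
                       (~parity, _FIVE_TETS_ODD)):
        for tet in tets:
            parts.append(corner[mask][:, list(tet)])
    elements = np.concatenate(parts, axis=0)
    vol = tet_volumes(nodes, elements)
    flip = vol < 0
    elements[flip] = elements[flip][:, [0, 1, 3, 2]]
    return nodes, elements


def _bend_cylindrical(nodes: np.ndarray, radius: float) -> np.ndarray:
    """Bend a flat slab (z = depth) onto a cylinder of the given radius.

    The surface z=0 maps onto the cylinder arc; layer depth is preserved
    radially.  Bending is about an axis parallel to x.
    """
    out = nodes.copy()
    theta = nodes[:, 1] / radius
    r = radius - nodes[:, 2]
    out[:, 1] = r * np.sin(theta)
    out[:, 2] = radius - r * np.cos(theta)
    return out


def build_phantom(spec: PhantomSpec, seed: int = 0) -> TetMesh:
    """Build a labeled maternal-fetal phantom mesh.

    Layers are stacked in depth (z >= 0, surface at z = 0): maternal fat,
    maternal muscle/uterus, then amniotic fluid containing the fetal-head
    sphere (scalp muscle / skull / CSF / brain, centred under the origin).
    Deterministic for a fixed (spec, seed).
    """
    spec.validate()
    lx, ly = spec.lateral_extent
    lz = spec.domain_depth
    nodes, elements = structured_box_mesh(
        (lx, ly, lz), spec.target_edge_length, origin=(-lx / 2, -ly / 2, 0.0)
    )

    # seed reserved for optional interior jitter; kept at zero amplitude so
    # fixture meshes stay structured, but the RNG draw keeps the contract
    # "identical spec+seed -> identical mesh" explicit.
    np.random.default_rng(seed)

    centroids = nodes[elements].mean(axis=1)
    labels = np.empty(len(elements), dtype=np.int64)
    z = centroids[:, 2]
    labels[:] = TissueLabel.AMNIOTIC_FLUID
    labels[z < spec.fat_thickness + spec.muscle_thickness] = (
        TissueLabel.MATERNAL_MUSCLE_UTERUS
    )
    labels[z < spec.fat_thickness] = TissueLabel.MATERNAL_FAT

    centre = np.array([0.0, 0.0, spec.head_top_depth + spec.fetal_head_radius])
    dist = np.linalg.norm(centroids - centre, axis=1)
    in_head = dist <= spec.fetal_head_radius
    # only below the maternal wall can the head exist (guards thin specs)
    in_head &= z >= spec.fat_thickness + spec.muscle_thickness
    r = spec.fetal_head_radius
    labels[in_head & (dist > r - spec.scalp_thickness)] = TissueLabel.FETAL_MUSCLE
    sel = in_head & (dist <= r - spec.scalp_thickness)
    labels[sel & (dist > r - spec.scalp_thickness - spec.skull_thickness)] = (
        TissueLabel.FETAL_SKULL_SPINAL
    )
    sel &= dist <= r - spec.scalp_thickness - spec.skull_thickness
    labels[sel & (dist > spec.brain_radius)] = TissueLabel.FETAL_CSF
    labels[sel & (dist <= spec.brain_radius)] = TissueLabel.FETAL_BRAIN

    if spec.abdomen_curvature_radius is not None:
        nodes = _bend_cylindrical(nodes, spec.abdomen_curvature_radius)

    return TetMesh(nodes=nodes, elements=elements, element_labels=labels)


@dataclass
class ProbeLayout:
    """Optode positions on the phantom surface."""

    source_positions: np.ndarray
    detector_positions: np.ndarray
    grid_shape: tuple[int, int]
    grid_extent: tuple[float, float]

    @property
    def num_sources(self) -> int:
        return len(self.source_positions)

    @property
    def num_detectors(self) -> int:
        return len(self.detector_positions)


@dataclass(frozen=True)
class Channel:
    """One source-detector pair."""

    source_id: int
    detector_id: int
    distance: float
    group_id: int = -1


@dataclass
class ChannelGroup:
    """Channels binned by source-detector distance."""

    label: str
    lower: float
    upper: float
    channels: list[Channel]

    @property
    def nm(self) -> int:
        """Number of member channels."""
        return len(self.channels)


class ProjectionError(ValueError):
    """Raised when grid points cannot be projected onto the mesh surface."""


def _top_surface_faces(mesh: TetMesh) -> np.ndarray:
    """Boundary faces whose outward normal points toward -z (the probe side)."""
    faces = mesh.surface_faces
    tri = mesh.nodes[faces]
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norm = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = normals / np.where(norm == 0, 1.0, norm)
    # orient outward: compare with direction away from the mesh centroid
    centroid = mesh.nodes.mean(axis=0)
    outward = tri.mean(axis=1) - centroid
    sign = np.sign(np.einsum("ij,ij->i", normals, outward))
    normals *= sign[:, None]
    return faces[normals[:, 2] < -0.5]


def project_to_surface(mesh: TetMesh, xy: np.ndarray) -> np.ndarray:
    """Project (x, y) points vertically onto the top surface of the mesh."""
    faces = _top_surface_faces(mesh)
    if len(faces) == 0:
        raise ProjectionError("mesh has no upward-facing surface")
    tri = mesh.nodes[faces]
    out = np.empty((len(xy), 3))
    t2d = tri[:, :, :2]
    v0 = t2d[:, 1] - t2d[:, 0]
    v1 = t2d[:, 2] - t2d[:, 0]
    den = v0[:, 0] * v1[:, 1] - v0[:, 1] * v1[:, 0]
    ok = np.abs(den) > 1e-12
    for i, p in enumerate(np.asarray(xy, dtype=float)):
        w = p[None, :] - t2d[:, 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            l1 = (w[:, 0] * v1[:, 1] - w[:, 1] * v1[:, 0]) / den
            l2 = (v0[:, 0] * w[:, 1] - v0[:, 1] * w[:, 0]) / den
        inside = ok & (l1 >= -1e-9) & (l2 >= -1e-9) & (l1 + l2 <= 1 + 1e-9)
        if not inside.any():
            raise ProjectionError(f"grid point {p} falls outside the surface")
        cand = np.flatnonzero(inside)
        zs = (tri[cand, 0, 2] * (1 - l1[cand] - l2[cand])
              + tri[cand, 1, 2] * l1[cand] + tri[cand, 2, 2] * l2[cand])
        j = cand[np.argmin(zs)]
        out[i] = (p[0], p[1],
                  tri[j, 0, 2] * (1 - l1[j] - l2[j])
                  + tri[j, 1, 2] * l1[j] + tri[j, 2, 2] * l2[j])
    return out


def build_probe_layout(
    mesh: TetMesh,
    grid_shape: tuple[int, int] = (6, 6),
    extent: tuple[float, float] = (100.0, 70.0),
    pattern: str = "alternating",
) -> ProbeLayout:
    """Place a rows x cols optode grid on the top surface.

    ``extent`` is (x span, y span) in mm, centred over the origin.  The
    ``alternating`` pattern assigns sources and detectors in a checkerboard,
    which for a 6 x 6 grid yields 18 sources and 18 detectors.
    """
    if pattern != "alternating":
        raise ValueError(f"unknown optode pattern: {pattern!r}")
    rows, cols = grid_shape
    if rows < 1 or cols < 1:
        raise ValueError("grid_shape entries must be >= 1")
    xs = np.linspace(-extent[0] / 2, extent[0] / 2, cols)
    ys = np.linspace(-extent[1] / 2, extent[1] / 2, rows)
    pts, is_source = [], []
    for j, y in enumerate(ys):
        for i, x in enumerate(xs):
            pts.append((x, y))
            is_source.append((i + j) % 2 == 0)
    positions = project_to_surface(mesh, np.asarray(pts))
    is_source = np.asarray(is_source)
    return ProbeLayout(
        source_positions=positions[is_source],
        detector_positions=positions[~is_source],
        grid_shape=(rows, cols),
        grid_extent=tuple(extent),
    )


def select_channels(
    layout: ProbeLayout, dmin: float = 20.0, dmax: float = 120.0
) -> list[Channel]:
    """All source-detector pairs whose chord distance lies in [dmin, dmax]."""
    if dmin >= dmax:
        raise ValueError(f"dmin must be < dmax ({dmin} >= {dmax})")
    if layout.num_sources == 0 or layout.num_detectors == 0:
        raise ValueError("layout has no optodes")
    diff = layout.source_positions[:, None, :] - layout.detector_positions[None]
    dist = np.linalg.norm(diff, axis=2)
    channels = []
    for s in range(layout.num_sources):
        for d in range(layout.num_detectors):
            if dmin <= dist[s, d] <= dmax:
                channels.append(Channel(s, d, float(dist[s, d])))
    return channels


def group_channels(
    channels: Sequence[Channel],
    edges: Sequence[float] = (20.0, 40.0, 60.0, 80.0, 100.0, 120.0),
) -> list[ChannelGroup]:
    """Bin channels into distance groups: [lo, hi) except the last, closed.

    Returns one :class:`ChannelGroup` per interval (possibly empty), and the
    channels are re-tagged with their ``group_id``.
    """
    edges = np.asarray(edges, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing, length >= 2")
    groups = [
        ChannelGroup(label=f"{edges[i]:g}-{edges[i + 1]:g}",
                     lower=float(edges[i]), upper=float(edges[i + 1]),
                     channels=[])
        for i in range(len(edges) - 1)
    ]
    for ch in channels:
        if ch.distance < edges[0] or ch.distance > edges[-1]:
            raise ValueError(
                f"channel distance {ch.distance} outside bins "
                f"[{edges[0]}, {edges[-1]}]"
            )
        gid = int(np.searchsorted(edges, ch.distance, side="right")) - 1
        gid = min(gid, len(groups) - 1)  # close the last bin at the top edge
        groups[gid].channels.append(
            Channel(ch.source_id, ch.detector_id, ch.distance, gid)
        )
    return groups


def find_element(mesh: TetMesh, point: np.ndarray,
                 tree: cKDTree | None = None) -> tuple[int, np.ndarray]:
    """Element containing ``point`` and its barycentric coordinates."""
    point = np.asarray(point, dtype=float)
    if tree is None:
        tree = cKDTree(mesh.nodes[mesh.elements].mean(axis=1))
    k = min(64, mesh.num_elements)
    _, cand = tree.query(point, k=k)
    cand = np.atleast_1d(cand)
    best, best_bary, best_viol = -1, None, np.inf
    for e in cand:
        verts = mesh.nodes[mesh.elements[e]]
        T = (verts[1:] - verts[0]).T
        try:
            lam = np.linalg.solve(T, point - verts[0])
        except np.linalg.LinAlgError:
            continue
        bary = np.concatenate([[1.0 - lam.sum()], lam])
        viol = -min(bary.min(), 0.0)
        if viol < best_viol:
            best, best_bary, best_viol = int(e), bary, viol
        if viol <= 1e-9:
            return int(e), bary
    if best >= 0 and best_viol < 1e-6:
        return best, np.clip(best_bary, 0.0, None)
    raise ValueError(f"point {point} not inside any mesh element")


def min_surface_to_label_distance(mesh: TetMesh, label: TissueLabel) -> float:
    """Shortest distance from the probe-side surface to any node of ``label``.

    Measured from the upward-facing (abdominal) surface only; the box sides
    and bottom truncate the phantom and carry no physical meaning.
    """
    surf = mesh.nodes[np.unique(_top_surface_faces(mesh).ravel())]
    target = mesh.nodes[mesh.nodes_with_label(label)]
    if len(target) == 0:
        raise ValueError(f"mesh has no elements labeled {label!r}")
    tree = cKDTree(target)
    d, _ = tree.query(surf)
    return float(d.min())
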