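"""Continuous-wave diffusion finite-element forward solver.

Solves -div(kappa grad phi) + mua phi = q with the Robin boundary condition
phi + 2 A kappa dphi/dn = 0 on P1 tetrahedra.  Optical properties are given
per element in cm^-1 (kappa in cm) and converted to the mesh's mm units at
assembly.  Sources are isotropic points placed one transport mean free path
beneath their surface anchor; large detectors integrate the surface fluence
rate over a 10 x 10 mm patch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from .optics import PropertyField
from .phantom import TetMesh, _top_surface_faces, find_element

CM_PER_MM = 0.1


class AssemblyError(ValueError):
    pass


class SolverError(RuntimeError):
    pass


def internal_reflection_parameter(n: float) -> float:
    """Robin coefficient A from the refractive-index mismatch.

    Groenhuis/Keijzer polynomial fit for the effective internal reflection
    coefficient at a tissue-air interface.
    """
    r_d = -1.4399 / n**2 + 0.7099 / n + 0.6681 + 0.0636 * n
    return (1.0 + r_d) / (1.0 - r_d)


def element_to_nodal(mesh: TetMesh, values: np.ndarray) -> np.ndarray:
    """Volume-weighted average of an element field onto the nodes."""
    num = np.zeros(mesh.num_nodes)
    den = np.zeros(mesh.num_nodes)
    w = np.repeat(mesh.element_volumes / 4.0, 4)
    np.add.at(num, mesh.elements.ravel(), w * np.repeat(values, 4))
    np.add.at(den, mesh.elements.ravel(), w)
    return num / den


def _basis_gradients(mesh: TetMesh) -> np.ndarray:
    """(ne, 4, 3) gradients of the P1 basis functions, units 1/mm."""
    verts = mesh.nodes[mesh.elements]
    T = np.stack([verts[:, i] - verts[:, 0] for i in range(1, 4)], axis=2)
    g123 = np.linalg.inv(T)  # row k = grad lambda_{k+1}
    g0 = -g123.sum(axis=1, keepdims=True)
    return np.concatenate([g0, g123], axis=1)


@dataclass
class FemSystem:
    """Assembled sparse SPD system with cached factorization."""

    matrix: sp.csc_matrix
    mesh: TetMesh
    props: PropertyField
    mua_nodal: np.ndarray  # cm^-1
    kappa_nodal: np.ndarray  # cm
    direct_limit: int = 4_000
    _factor: object = field(default=None, repr=False)
    _precond: object = field(default=None, repr=False)

    @property
    def num_nodes(self) -> int:
        return self.matrix.shape[0]

    def solve_rhs(self, rhs: np.ndarray, rtol: float = 1e-12) -> np.ndarray:
        # sparse direct for small systems; Jacobi-preconditioned CG (the
        # matrix is SPD) is far cheaper than SuperLU fill on 3D meshes
        if self.num_nodes <= self.direct_limit:
            if self._factor is None:
                self._factor = spla.factorized(self.matrix)
            x = self._factor(rhs)
        else:
            if self._precond is None:
                self._precond = sp.diags(1.0 / self.matrix.diagonal())
            x, info = spla.cg(self.matrix, rhs, rtol=rtol, maxiter=50_000,
                              M=self._precond)
            if info != 0:
                raise SolverError(f"CG failed to converge (info={info})")
        res = np.linalg.norm(self.matrix @ x - rhs) / np.linalg.norm(rhs)
        if res > 1e-8:
            raise SolverError(f"solver residual too large: {res:.3e}")
        return x


def assemble(
    mesh: TetMesh,
    props: PropertyField,
    boundary_a: float | None = None,
) -> FemSystem:
    """Galerkin P1 assembly of the CW diffusion operator.

    ``boundary_a`` overrides the index-mismatch Robin coefficient (A = 1
    reproduces a matched boundary, handy for analytic checks).
    """
    if len(props.mua) != mesh.num_elements:
        raise AssemblyError("property field does not match mesh element count")
    mua_n = element_to_nodal(mesh, props.mua)  # cm^-1
    kappa_n = element_to_nodal(mesh, props.kappa)  # cm
    n_nodal = element_to_nodal(mesh, props.n)
    if (props.musp < 1.0).any():
        warnings.warn(
            "property field contains low-scattering regions (musp < 1 cm^-1); "
            "the diffusion approximation is of limited validity there",
            stacklevel=2,
        )
    return assemble_nodal(mesh, mua_n, kappa_n, props,
                          n_nodal=n_nodal, boundary_a=boundary_a)


def assemble_nodal(
    mesh: TetMesh,
    mua_nodal: np.ndarray,
    kappa_nodal: np.ndarray,
    props: PropertyField,
    n_nodal: np.ndarray | None = None,
    boundary_a: float | None = None,
) -> FemSystem:
    """Assemble directly from nodal mua (cm^-1) and kappa (cm) fields.

    The absorption field is P1-interpolated inside each element, which makes
    the system an exact linear function of the nodal mua values — the
    parameterization the absorption Jacobian differentiates.
    """
    vol = mesh.element_volumes
    bad = np.flatnonzero(vol <= 1e-12)
    if len(bad):
        raise AssemblyError(
            f"degenerate element(s) with near-zero volume: {bad[:5].tolist()}"
        )
    mua_n = np.asarray(mua_nodal, dtype=float)
    kappa_n = np.asarray(kappa_nodal, dtype=float)
    if n_nodal is None and boundary_a is None:
        raise AssemblyError("need either n_nodal or boundary_a")

    elems = mesh.elements
    ne = mesh.num_elements

    # stiffness: kappa (mm) * V * G G^T with element-mean nodal kappa
    grads = _basis_gradients(mesh)
    kappa_e = kappa_n[elems].mean(axis=1) / CM_PER_MM  # cm -> mm
    ke = np.einsum("e,eai,ebi->eab", kappa_e * vol, grads, grads)

    # lumped absorption mass with P1-interpolated nodal mua (mm^-1):
    # M_aa = int mua(x) lambda_a dV = V/20 * (sum(mu) + mu_a).  Lumping keeps
    # the system an M-matrix on the non-obtuse structured tets, so solutions
    # stay strictly positive and absorption Jacobian entries non-positive.
    mu_e = mua_n[elems] * CM_PER_MM  # cm^-1 -> mm^-1
    mu_sum = mu_e.sum(axis=1)
    me = np.zeros((ne, 4, 4))
    for a in range(4):
        me[:, a, a] = vol / 20.0 * (mu_sum + mu_e[:, a])

    rows = np.repeat(elems, 4, axis=1).reshape(ne, 4, 4)
    cols = np.tile(elems, (1, 4)).reshape(ne, 4, 4)
    data = (ke + me).ravel()
    A = sp.coo_matrix(
        (data, (rows.ravel(), cols.ravel())),
        shape=(mesh.num_nodes, mesh.num_nodes),
    )

    # Robin boundary: (1/(2A)) * int phi_a phi_b dS over every boundary face
    faces = mesh.surface_faces
    tri = mesh.nodes[faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    if boundary_a is not None:
        a_face = np.full(len(faces), float(boundary_a))
    else:
        n_face = n_nodal[faces].mean(axis=1)
        a_face = np.array([internal_reflection_parameter(nv) for nv in n_face])
    coeff = areas / (2.0 * a_face)
    face_mass = np.eye(3) / 3.0  # lumped boundary mass
    bdata = coeff[:, None, None] * face_mass[None]
    brows = np.repeat(faces, 3, axis=1).reshape(-1, 3, 3)
    bcols = np.tile(faces, (1, 3)).reshape(-1, 3, 3)
    B = sp.coo_matrix(
        (bdata.ravel(), (brows.ravel(), bcols.ravel())),
        shape=(mesh.num_nodes, mesh.num_nodes),
    )

    return FemSystem(
        matrix=(A + B).tocsc(),
        mesh=mesh,
        props=props,
        mua_nodal=mua_n,
        kappa_nodal=kappa_n,
    )


@dataclass
class SourceSpec:
    """Isotropic point source one transport mean free path below its anchor."""

    anchor: np.ndarray
    position: np.ndarray
    element: int
    barycentric: np.ndarray
    power: float = 1.0

    def rhs(self, num_nodes: int, mesh: TetMesh) -> np.ndarray:
        if self.power <= 0:
            raise ValueError("source power must be > 0")
        b = np.zeros(num_nodes)
        b[mesh.elements[self.element]] = self.power * self.barycentric
        return b


def _inward_normal(mesh: TetMesh, anchor: np.ndarray) -> np.ndarray:
    faces = _top_surface_faces(mesh)
    tri = mesh.nodes[faces]
    centroids = tri.mean(axis=1)
    i = int(np.argmin(np.linalg.norm(centroids - anchor, axis=1)))
    nrm = np.cross(tri[i, 1] - tri[i, 0], tri[i, 2] - tri[i, 0])
    nrm /= np.linalg.norm(nrm)
    if nrm[2] < 0:  # outward points to -z on the probe side; flip inward
        nrm = -nrm
    return nrm


def make_source(
    mesh: TetMesh,
    props: PropertyField,
    anchor: np.ndarray,
    tree: cKDTree | None = None,
) -> SourceSpec:
    """Place a unit-power point source 1/musp' beneath the surface anchor."""
    anchor = np.asarray(anchor, dtype=float)
    inward = _inward_normal(mesh, anchor)
    probe = anchor + 0.5 * inward
    elem, _ = find_element(mesh, probe, tree)
    depth_mm = 10.0 / props.musp[elem]  # 1/musp, cm -> mm
    pos = anchor + depth_mm * inward
    elem, bary = find_element(mesh, pos, tree)
    return SourceSpec(anchor=anchor, position=pos, element=elem,
                      barycentric=bary)


@dataclass
class FluenceSolution:
    """Nodal fluence rate (s^-1 mm^-2, unit source power)."""

    phi: np.ndarray
    wavelength: float
    phase: str
    source_id: int = -1

    def __post_init__(self):
        if not np.all(np.isfinite(self.phi)):
            raise SolverError("non-finite fluence values")


def solve(system: FemSystem, source: SourceSpec,
          source_id: int = -1) -> FluenceSolution:
    rhs = source.rhs(system.num_nodes, system.mesh)
    phi = system.solve_rhs(rhs)
    return FluenceSolution(
        phi=phi,
        wavelength=system.props.wavelength,
        phase=str(getattr(system.props.phase, "value", system.props.phase)),
        source_id=source_id,
    )


class SurfaceSampler:
    """Linear interpolation of probe-side surface nodal values onto points.

    Interpolates on the mesh's own upward-facing boundary triangles (their
    (x, y) projection forms the surface chart), so sampling inherits the
    mesh's symmetries exactly.  ``weight_matrix`` returns sparse barycentric
    weights mapping full nodal vectors to sample points.
    """

    def __init__(self, mesh: TetMesh):
        self.mesh = mesh
        self.faces = _top_surface_faces(mesh)
        if len(self.faces) == 0:
            raise ValueError("mesh has no upward-facing surface")
        tri_xy = mesh.nodes[self.faces][:, :, :2]
        self._origin = tri_xy[:, 0]
        edges = np.stack(
            [tri_xy[:, 1] - tri_xy[:, 0], tri_xy[:, 2] - tri_xy[:, 0]],
            axis=2,
        )
        self._inv = np.linalg.inv(edges)
        self._tree = cKDTree(tri_xy.mean(axis=1))

    def weight_matrix(self, points: np.ndarray,
                      strict: bool = True) -> sp.csr_matrix:
        points = np.asarray(points, dtype=float)[:, :2]
        k = min(24, len(self.faces))
        _, cand = self._tree.query(points, k=k)
        cand = np.atleast_2d(cand)
        # barycentric coords of each point in each candidate face
        d = points[:, None, :] - self._origin[cand]
        bc2 = np.einsum("pkij,pkj->pki", self._inv[cand], d)
        lam = np.concatenate([1.0 - bc2.sum(axis=2, keepdims=True), bc2],
                             axis=2)
        ok = (lam >= -1e-9).all(axis=2)
        found = ok.any(axis=1)
        if not found.all():
            n_out = int((~found).sum())
            if strict:
                raise ValueError(
                    f"{n_out} sample point(s) fall outside the surface"
                )
            warnings.warn(
                f"clipping {n_out} sample point(s) outside the surface",
                stacklevel=2,
            )
        rows_idx = np.flatnonzero(found)
        first = ok[rows_idx].argmax(axis=1)
        faces = self.faces[cand[rows_idx, first]]
        bary = np.clip(lam[rows_idx, first], 0.0, None)
        rows = np.repeat(rows_idx, 3)
        return sp.csr_matrix(
            (bary.ravel(), (rows, faces.ravel())),
            shape=(len(points), self.mesh.num_nodes),
        )


@dataclass
class DetectorPatch:
    """Square large-detector patch integrating the surface fluence rate."""

    anchor: np.ndarray
    side: float
    dx: float
    dy: float
    weights: sp.csr_matrix  # (1, num_nodes): Phi = weights @ phi
    num_grid_points: int

    @property
    def area(self) -> float:
        return self.side * self.side


def build_patch(
    sampler: SurfaceSampler,
    anchor: np.ndarray,
    side: float = 10.0,
    dx: float = 0.4,
    dy: float = 0.4,
    strict: bool = True,
) -> DetectorPatch:
    """Build the quadrature functional Phi = dx*dy*sum(phi_i) over the patch.

    Grid points are cell centres, so for a uniform field the integral equals
    field value x side^2 exactly when side/dx is an integer.
    """
    if not (0 < dx < 0.5 and 0 < dy < 0.5):
        raise ValueError("patch grid spacings must be in (0, 0.5) mm")
    anchor = np.asarray(anchor, dtype=float)
    nx = int(round(side / dx))
    ny = int(round(side / dy))
    gx = anchor[0] - side / 2 + (np.arange(nx) + 0.5) * dx
    gy = anchor[1] - side / 2 + (np.arange(ny) + 0.5) * dy
    pts = np.column_stack([np.repeat(gx, ny), np.tile(gy, nx)])
    W = sampler.weight_matrix(pts, strict=strict)
    d = sp.csr_matrix(W.sum(axis=0)) * (dx * dy)
    return DetectorPatch(anchor=anchor, side=side, dx=dx, dy=dy,
                         weights=d, num_grid_points=len(pts))


def detector_fluence(sol: FluenceSolution, patch: DetectorPatch) -> float:
    """Large-detector fluence Phi (s^-1)."""
    val = float((patch.weights @ sol.phi)[0])
    if val <= 0:
        raise SolverError(f"non-positive detector fluence: {val}")
    return val
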