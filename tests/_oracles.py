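"""Independent oracles shared by unit and acceptance tests.

Everything here deliberately avoids the code paths it is used to check:
closed forms, dense linear algebra, finite differences, brute-force loops.
"""

import numpy as np

from fetaldot.forward import assemble, assemble_nodal, element_to_nodal


def infinite_medium_green(r_mm, mua_cm, musp_cm):
    """CW diffusion Green's function exp(-mueff r)/(4 pi kappa r), mm units."""
    kappa_mm = 10.0 / (3.0 * (mua_cm + musp_cm))
    mueff_mm = np.sqrt(3.0 * mua_cm * (mua_cm + musp_cm)) / 10.0
    return np.exp(-mueff_mm * r_mm) / (4.0 * np.pi * kappa_mm * r_mm)


def finite_difference_jacobian_entry(mesh, props, source, patch, node,
                                     delta=1e-4, boundary_a=None):
    """Central finite difference dPhi/dmua at one node (mua in cm^-1).

    Perturbs the nodal absorption field directly (kappa held at baseline),
    re-solving the forward problem twice.
    """
    mua_n = element_to_nodal(mesh, props.mua)
    kappa_n = element_to_nodal(mesh, props.kappa)
    n_n = element_to_nodal(mesh, props.n)
    phis = []
    for sign in (+1.0, -1.0):
        mua_pert = mua_n.copy()
        mua_pert[node] += sign * delta
        system = assemble_nodal(mesh, mua_pert, kappa_n, props,
                                n_nodal=n_n, boundary_a=boundary_a)
        phi = system.solve_rhs(source.rhs(system.num_nodes, mesh))
        phis.append(float((patch.weights @ phi)[0]))
    return (phis[0] - phis[1]) / (2.0 * delta)


def dense_flatfield_reconstruction(J, dphi):
    """Dense closed-form evaluation of the regularized Moore-Penrose steps.

    Uses explicit diagonal matrices and np.linalg.inv throughout; checks the
    sparse/solver-based implementation against the printed equations.
    """
    J = np.atleast_2d(np.asarray(J, dtype=float))
    dphi = np.atleast_1d(np.asarray(dphi, dtype=float))
    JtJ_diag = np.diag(J.T @ J)
    alpha = 1e-2 * JtJ_diag.max()
    L = np.diag((JtJ_diag + alpha) ** -0.5)
    Linv = np.linalg.inv(L)
    Jhat = J @ Linv
    JJt_diag = np.diag(Jhat @ Jhat.T)
    beta = 1e-2 * JJt_diag.max()
    M = np.diag((JJt_diag + beta) ** -0.5)
    Jtilde = M @ Jhat
    dphi_tilde = M @ dphi
    inner = np.linalg.inv(Jtilde @ Jtilde.T + np.eye(len(dphi)))
    return Linv @ Jtilde.T @ inner @ dphi_tilde


def point_triangle_distance(p, tri):
    """Exact distance from a 3D point to a triangle (brute-force oracle)."""
    a, b, c = (np.asarray(v, dtype=float) for v in tri)
    p = np.asarray(p, dtype=float)
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return np.linalg.norm(ap)
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return np.linalg.norm(bp)
    vc = d1 * d4 - d3 * d2
    if vc <= 0 <= d1 and d3 <= 0:
        t = d1 / (d1 - d3)
        return np.linalg.norm(ap - t * ab)
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return np.linalg.norm(cp)
    vb = d5 * d2 - d1 * d6
    if vb <= 0 <= d2 and d6 <= 0:
        t = d2 / (d2 - d6)
        return np.linalg.norm(ap - t * ac)
    va = d3 * d6 - d5 * d4
    if va <= 0 and d4 - d3 >= 0 and d5 - d6 >= 0:
        t = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return np.linalg.norm(bp - t * (c - b))
    den = va + vb + vc
    v, w = vb / den, vc / den
    return np.linalg.norm(p - (a + ab * v + ac * w))
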