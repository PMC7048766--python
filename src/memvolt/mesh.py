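"""Axisymmetric triangular mesh for the cell-in-field problem.

The 3D problem is rotationally symmetric, so it is solved on the (r, z)
half-plane: a rectangle [0, W] × [−H, H] containing a half-disk of radius R
(the cell) centered at the origin.  The mesher is a structured polar ladder:

* rays at uniform polar angles θ ∈ [0, π] measured from the +z axis,
* geometrically graded rings inward from the membrane circle to a central
  fan, and outward from the circle to the rectangular truncation boundary
  (each ray's outermost node lies exactly on the rectangle),
* the membrane itself is *not* meshed as a thin shell — the circle carries
  double nodes (an intracellular and an extracellular copy per ray) so the
  solver can impose a potential jump across it.

Grading concentrates resolution at the membrane, where the solution bends;
the interior potential is nearly linear, so the coarse central fan costs no
accuracy.  All triangles are oriented counter-clockwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AxisymMesh", "build_axisym_mesh"]

_GROWTH = 1.2  # geometric ring-spacing growth factor
_MAX_STEP_FACTOR = 10.0  # ring spacing cap, in units of the target edge length


@dataclass(frozen=True)
class AxisymMesh:
    """Triangulated (r, z) half-plane with a double-noded cell interface."""

    nodes: np.ndarray  # (N, 2) float, columns r, z
    triangles: np.ndarray  # (M, 3) int, CCW
    tri_domain: np.ndarray  # (M,) int: 0 intracellular, 1 extracellular
    interface_pairs: np.ndarray  # (m, 2) int: inner node id, outer node id
    interface_theta: np.ndarray  # (m,) rad, ascending from the +z pole
    top_nodes: np.ndarray  # ids on z = +H
    bottom_nodes: np.ndarray  # ids on z = -H
    cell_radius: float
    half_height: float
    domain_radius: float

    def __post_init__(self) -> None:
        if np.any(self.nodes[:, 0] < -1e-15):
            raise ValueError("mesh nodes must have r >= 0")
        a = _signed_areas(self.nodes, self.triangles)
        if np.any(a <= 0):
            raise ValueError("mesh contains degenerate or misoriented triangles")

    @property
    def n_interface(self) -> int:
        return len(self.interface_pairs)

    def interface_radial_error(self) -> float:
        """Max relative deviation of interface nodes from the circle R."""
        ids = self.interface_pairs.ravel()
        rho = np.hypot(self.nodes[ids, 0], self.nodes[ids, 1])
        return float(np.max(np.abs(rho - self.cell_radius)) / self.cell_radius)

    def interface_lumped_weights(self) -> np.ndarray:
        """Axisymmetric surface weight per interface sample (m²).

        Lumped P1 boundary mass of the revolved interface polyline,
        ∫ 2πr φ_k dΓ; sums to the sphere area 4πR² up to the polyline
        chord error.
        """
        th = self.interface_theta
        R = self.cell_radius
        pts = np.column_stack([R * np.sin(th), R * np.cos(th)])
        w = np.zeros(len(th))
        for k in range(len(th) - 1):
            L = float(np.hypot(*(pts[k + 1] - pts[k])))
            r0, r1 = pts[k, 0], pts[k + 1, 0]
            w[k] += 2 * np.pi * L * (2 * r0 + r1) / 6.0
            w[k + 1] += 2 * np.pi * L * (r0 + 2 * r1) / 6.0
        return w


def _signed_areas(nodes: np.ndarray, tris: np.ndarray) -> np.ndarray:
    p = nodes[tris]
    return 0.5 * (
        (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
        - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
    )


def _graded_ladder(h0: float, total: float, max_step: float) -> np.ndarray:
    """Cumulative distances 0 < c_1 < … < c_K = total, starting near h0."""
    steps = []
    c = 0.0
    s = h0
    while c + s < total:
        steps.append(s)
        c += s
        s = min(s * _GROWTH, max_step)
    steps.append(total - c)
    # merge an undersized final step into its neighbour
    if len(steps) > 1 and steps[-1] < 0.4 * steps[-2]:
        steps[-2] += steps.pop()
    return np.cumsum(steps)


def build_axisym_mesh(cell, config) -> AxisymMesh:
    """Build the graded polar-ladder mesh for a cell and solver config.

    ``cell`` provides the radius R; ``config`` (see
    :class:`memvolt.fem.SolverConfig`) sets the domain extent in multiples
    of R, the target edge length at the interface and the angular sample
    count.
    """
    R = cell.radius
    H = config.domain_half_height_factor * R
    W = config.domain_radius_factor * R
    n_theta = config.n_theta_intervals(R)
    h = config.interface_edge_length(R)
    if n_theta < 8:
        raise ValueError(f"too few angular intervals ({n_theta}); refine the mesh")

    thetas = np.linspace(0.0, np.pi, n_theta + 1)
    # insert (or snap to) the rays through the two box corners so the outer
    # node ladder follows the rectangle exactly instead of cutting corners
    corner = float(np.arctan2(W, H))
    for tc in (corner, np.pi - corner):
        j = int(np.argmin(np.abs(thetas - tc)))
        if abs(thetas[j] - tc) < 0.3 * np.pi / n_theta and 0 < j < len(thetas) - 1:
            thetas[j] = tc
        elif abs(thetas[j] - tc) > 1e-15:
            thetas = np.sort(np.append(thetas, tc))
    n_theta = len(thetas) - 1
    sin_t = np.sin(thetas)
    cos_t = np.cos(thetas)
    sin_t[0] = sin_t[-1] = 0.0  # exactly on the symmetry axis
    cos_t[-1] = -1.0

    # interior rings: R down to a central fan
    max_step = _MAX_STEP_FACTOR * h  # scales with refinement so the far
    # field converges along with the interface region
    c_int = _graded_ladder(h, 0.75 * R, min(max_step, 0.2 * R))
    int_radii = np.concatenate([[R], R - c_int])  # last entry = 0.25 R

    # exterior rings: distance ladder normalized per ray so the outermost
    # node lands exactly on the rectangle boundary
    t_side = np.full(n_theta + 1, np.inf)
    t_cap = np.full(n_theta + 1, np.inf)
    np.divide(W, sin_t, out=t_side, where=sin_t > 1e-12)
    np.divide(H, np.abs(cos_t), out=t_cap, where=np.abs(cos_t) > 1e-12)
    t_max = np.minimum(t_side, t_cap)
    L_min = float(np.min(t_max)) - R
    c_ext = _graded_ladder(h, L_min, max_step)
    u_ext = c_ext / c_ext[-1]  # (K_e,) in (0, 1]

    nodes: list[np.ndarray] = []

    def add_ring(t_per_ray: np.ndarray) -> np.ndarray:
        start = sum(len(b) for b in nodes)
        ring = np.column_stack([t_per_ray * sin_t, t_per_ray * cos_t])
        ring[0, 0] = 0.0
        ring[-1, 0] = 0.0
        nodes.append(ring)
        return np.arange(start, start + n_theta + 1)

    # --- intracellular side ---
    int_ring_ids = [add_ring(np.full(n_theta + 1, rho)) for rho in int_radii]
    center_id = sum(len(b) for b in nodes)
    nodes.append(np.array([[0.0, 0.0]]))

    # --- extracellular side (fresh copies on the circle: double nodes) ---
    ext_ring_ids = [add_ring(np.full(n_theta + 1, R))]
    for u in u_ext:
        ext_ring_ids.append(add_ring(R + u * (t_max - R)))

    node_arr = np.concatenate(nodes, axis=0)

    tris: list[tuple[int, int, int]] = []
    domain: list[int] = []

    def add_band(ids_a: np.ndarray, ids_b: np.ndarray, dom: int) -> None:
        for j in range(n_theta):
            a, b = ids_a[j], ids_a[j + 1]
            c, d = ids_b[j], ids_b[j + 1]
            tris.append((a, b, c))
            domain.append(dom)
            tris.append((b, d, c))
            domain.append(dom)

    for k in range(len(int_ring_ids) - 1):
        add_band(int_ring_ids[k], int_ring_ids[k + 1], 0)
    inner_most = int_ring_ids[-1]
    for j in range(n_theta):
        tris.append((inner_most[j], inner_most[j + 1], center_id))
        domain.append(0)
    for k in range(len(ext_ring_ids) - 1):
        add_band(ext_ring_ids[k], ext_ring_ids[k + 1], 1)

    tri_arr = np.asarray(tris, dtype=np.int64)
    dom_arr = np.asarray(domain, dtype=np.int64)

    # orient CCW
    areas = _signed_areas(node_arr, tri_arr)
    flip = areas < 0
    tri_arr[flip] = tri_arr[flip][:, [0, 2, 1]]
    if np.any(np.abs(_signed_areas(node_arr, tri_arr)) < 1e-30):
        raise ValueError("mesh generation produced a degenerate triangle")

    outer = ext_ring_ids[-1]
    z_out = node_arr[outer, 1]
    tol = 1e-9 * H
    top = outer[np.abs(z_out - H) < tol]
    bottom = outer[np.abs(z_out + H) < tol]
    if len(top) == 0 or len(bottom) == 0:
        raise ValueError("mesh truncation boundary has no Dirichlet nodes")

    pairs = np.column_stack([int_ring_ids[0], ext_ring_ids[0]])
    return AxisymMesh(
        nodes=node_arr,
        triangles=tri_arr,
        tri_domain=dom_arr,
        interface_pairs=pairs,
        interface_theta=thetas,
        top_nodes=top,
        bottom_nodes=bottom,
        cell_radius=R,
        half_height=H,
        domain_radius=W,
    )
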