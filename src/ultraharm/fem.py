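"""P1 finite-element operators on triangles, source loads and field export.

Assembles the real sparse matrices entering the sesquilinear form of every
per-harmonic Helmholtz solve: the stiffness matrix K (∫ ∇φ_i·∇φ_j), the
consistent mass matrix M (∫ φ_i φ_j) and the boundary mass matrix M_bnd
(∫_∂Ω φ_i φ_j along the boundary polygon).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .mesh import Mesh

__all__ = ["FemOperators", "SourceSpec", "assemble_operators", "assemble_load", "export_field"]

# Degree-4 symmetric 6-point quadrature rule on the reference triangle
# (Dunavant); barycentric points and weights summing to 1.
_QUAD_BARY = np.array(
    [
        [0.108103018168070, 0.445948490915965, 0.445948490915965],
        [0.445948490915965, 0.108103018168070, 0.445948490915965],
        [0.445948490915965, 0.445948490915965, 0.108103018168070],
        [0.816847572980459, 0.091576213509771, 0.091576213509771],
        [0.091576213509771, 0.816847572980459, 0.091576213509771],
        [0.091576213509771, 0.091576213509771, 0.816847572980459],
    ]
)
_QUAD_W = np.array(
    [
        0.223381589678011,
        0.223381589678011,
        0.223381589678011,
        0.109951743655322,
        0.109951743655322,
        0.109951743655322,
    ]
)


@dataclass(frozen=True)
class FemOperators:
    """Sparse CSR operators of a P1 discretization (all real symmetric)."""

    K: sp.csr_matrix
    M: sp.csr_matrix
    M_bnd: sp.csr_matrix

    @property
    def n(self) -> int:
        return self.K.shape[0]

    def l2_norm(self, u: np.ndarray) -> float:
        """Discrete L²(Ω) norm, ‖u‖ = sqrt(uᴴ M u)."""
        return float(np.sqrt(np.real(np.vdot(u, self.M @ u))))


@dataclass(frozen=True)
class SourceSpec:
    """Monopole source specification.

    The spatial profile is the cosine bump

        h(x) = a / (4 r_delta) * (1 + cos(pi ‖x - x0‖ / (2 r_delta)))

    supported on ‖x - x0‖ <= 2 r_delta, with exact total integral
    ∫ h dx = a r_delta (π − 4/π).  By default only the fundamental harmonic
    (m = 1) carries the profile.
    """

    a: float
    r_delta: float
    x0: tuple[float, float] = (0.0, 0.0)
    excited_harmonics: tuple[int, ...] = (1,)

    def profile(self, points: np.ndarray) -> np.ndarray:
        """Evaluate h at an (n, 2) array of points."""
        r = np.hypot(points[..., 0] - self.x0[0], points[..., 1] - self.x0[1])
        vals = self.a / (4.0 * self.r_delta) * (1.0 + np.cos(np.pi * r / (2.0 * self.r_delta)))
        return np.where(r <= 2.0 * self.r_delta, vals, 0.0)

    def total_integral(self) -> float:
        return self.a * self.r_delta * (np.pi - 4.0 / np.pi)


def assemble_operators(mesh: Mesh) -> FemOperators:
    """Assemble K, M and M_bnd by the exact formulas for linear elements."""
    p = mesh.nodes
    t = mesh.triangles
    x = p[t, 0]  # (T, 3)
    y = p[t, 1]
    # b_i, c_i: gradient components of the barycentric basis, times 2A
    b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    area2 = x[:, 0] * b[:, 0] + x[:, 1] * b[:, 1] + x[:, 2] * b[:, 2]
    if np.any(area2 <= 0):
        bad = int(np.flatnonzero(area2 <= 0)[0])
        raise ValueError(f"degenerate triangle {bad} (area {area2[bad] / 2:g})")
    area = 0.5 * area2

    ke = (b[:, :, None] * b[:, None, :] + c[:, :, None] * c[:, None, :]) / (2.0 * area2)[
        :, None, None
    ]
    me = (area[:, None, None] / 12.0) * (np.ones((3, 3)) + np.eye(3))[None, :, :]

    rows = np.repeat(t, 3, axis=1).ravel()
    cols = np.tile(t, (1, 3)).ravel()
    n = mesh.n_nodes
    K = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    M = sp.coo_matrix((me.ravel(), (rows, cols)), shape=(n, n)).tocsr()

    be = mesh.boundary_edges
    lengths = np.hypot(
        p[be[:, 1], 0] - p[be[:, 0], 0], p[be[:, 1], 1] - p[be[:, 0], 1]
    )
    mb = (lengths[:, None, None] / 6.0) * np.array([[2.0, 1.0], [1.0, 2.0]])[None, :, :]
    rows_b = np.repeat(be, 2, axis=1).ravel()
    cols_b = np.tile(be, (1, 2)).ravel()
    M_bnd = sp.coo_matrix((mb.ravel(), (rows_b, cols_b)), shape=(n, n)).tocsr()
    return FemOperators(K=K, M=M, M_bnd=M_bnd)


def assemble_load(mesh: Mesh, ops: FemOperators, src: SourceSpec, m: int) -> np.ndarray:
    """Discrete load vector of the harmonic source profile, (b)_i = ∫ h_m φ_i dx.

    Uses a fixed degree-4 (6-point) quadrature per triangle, sufficient to
    resolve the cosine bump on meshes with h ≲ r_delta.  Harmonics not listed
    in ``excited_harmonics`` get the zero vector.
    """
    b = np.zeros(mesh.n_nodes, dtype=complex)
    if m not in src.excited_harmonics:
        return b
    sup = 2.0 * src.r_delta
    center_dist = np.hypot(mesh.nodes[:, 0] - src.x0[0], mesh.nodes[:, 1] - src.x0[1])
    if mesh.radius is not None and np.hypot(*src.x0) + sup > mesh.radius + 1e-12:
        warnings.warn(
            "source support intersects the boundary; absorbing-boundary "
            "assumption degraded",
            stacklevel=2,
        )
    # restrict to triangles that can intersect the support
    t = mesh.triangles
    near = np.any(center_dist[t] < sup + mesh.max_edge_length(), axis=1)
    t_near = t[near]
    if t_near.size == 0:
        return b
    p = mesh.nodes
    verts = p[t_near]  # (T, 3, 2)
    d1 = verts[:, 1] - verts[:, 0]
    d2 = verts[:, 2] - verts[:, 0]
    areas = 0.5 * np.abs(d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])
    # quadrature points: (T, Q, 2)
    qp = np.einsum("qi,tid->tqd", _QUAD_BARY, verts)
    hvals = src.profile(qp)  # (T, Q)
    # (T, 3) local loads: area * sum_q w_q h(x_q) bary_iq
    local = areas[:, None] * np.einsum("tq,q,qi->ti", hvals, _QUAD_W, _QUAD_BARY)
    np.add.at(b, t_near.ravel(), local.ravel().astype(complex))
    return b


def export_field(
    mesh: Mesh,
    values: dict[str, np.ndarray],
    path: str | Path,
) -> Path:
    """Write nodal fields to VTU (``.vtu``) or columnar CSV (``.csv``).

    ``values`` maps field names to complex (or real) nodal vectors.  The VTU
    file stores real part, imaginary part and magnitude per field; the CSV file
    stores columns x, y then Re/Im per field, in full double precision.
    """
    path = Path(path)
    for name, vec in values.items():
        if vec.shape[0] != mesh.n_nodes:
            raise ValueError(
                f"field {name!r} has length {vec.shape[0]}, expected {mesh.n_nodes}"
            )
    if path.suffix == ".vtu":
        _write_vtu(mesh, values, path)
    elif path.suffix == ".csv":
        _write_csv(mesh, values, path)
    else:
        raise ValueError(f"unsupported export format {path.suffix!r} (use .vtu or .csv)")
    return path


def _fmt(arr: np.ndarray) -> str:
    return " ".join(repr(float(v)) for v in np.asarray(arr, dtype=float).ravel())


def _write_vtu(mesh: Mesh, values: dict[str, np.ndarray], path: Path) -> None:
    n, t = mesh.n_nodes, mesh.n_triangles
    pts3 = np.column_stack([mesh.nodes, np.zeros(n)])
    parts = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{n}" NumberOfCells="{t}">',
        "<Points>",
        f'<DataArray type="Float64" NumberOfComponents="3" format="ascii">{_fmt(pts3)}</DataArray>',
        "</Points>",
        "<Cells>",
        f'<DataArray type="Int64" Name="connectivity" format="ascii">'
        f'{" ".join(map(str, mesh.triangles.ravel()))}</DataArray>',
        f'<DataArray type="Int64" Name="offsets" format="ascii">'
        f'{" ".join(str(3 * (i + 1)) for i in range(t))}</DataArray>',
        f'<DataArray type="UInt8" Name="types" format="ascii">{" ".join(["5"] * t)}</DataArray>',
        "</Cells>",
        "<PointData>",
    ]
    for name, vec in values.items():
        vec = np.asarray(vec)
        parts.append(
            f'<DataArray type="Float64" Name="{name}_re" format="ascii">'
            f"{_fmt(vec.real)}</DataArray>"
        )
        parts.append(
            f'<DataArray type="Float64" Name="{name}_im" format="ascii">'
            f"{_fmt(vec.imag)}</DataArray>"
        )
        parts.append(
            f'<DataArray type="Float64" Name="{name}_abs" format="ascii">'
            f"{_fmt(np.abs(vec))}</DataArray>"
        )
    parts += ["</PointData>", "</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    path.write_text("\n".join(parts))


def _write_csv(mesh: Mesh, values: dict[str, np.ndarray], path: Path) -> None:
    cols = ["x", "y"]
    data = [mesh.nodes[:, 0], mesh.nodes[:, 1]]
    for name, vec in values.items():
        vec = np.asarray(vec)
        cols += [f"{name}_re", f"{name}_im"]
        data += [vec.real, vec.imag]
    with open(path, "w") as fh:
        fh.write(",".join(cols) + "\n")
        for row in zip(*data):
            fh.write(",".join(repr(float(v)) for v in row) + "\n")
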