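"""Two-layer bulge geometry: reference/current triangulations of the media
and adventitia, boundary bookkeeping, mesh motion, and diameter measurement.

The 2D section is bounded by three cosine profiles (inner to outer)::

    Gamma_B : x = 0.5 cos(pi y)/2           (lumen / media)
    Gamma_M : x = 0.55 cos(pi y)/2 + 0.2    (media / adventitia)
    Gamma_A : x = 0.7 cos(pi y)/2 + 0.3     (adventitia / outside)

on y in [y1, y2] = [-1, 1], with the bulge apex at y = 0 and the straight
vessel at the horizontal cuts Gamma_0 (y = y1, y2).  The section is scaled
uniformly so the measured initial lumen diameter equals R0, and shifted so
the vessel centerline sits at x = 0.

The two layers are triangulated as structured strips with node-for-node
matching along Gamma_M.  Species fields are one-sided (interface nodes
duplicated between the media and adventitia meshes); displacement and the
continuous ECM field live on a merged mesh where the interface nodes are
identified.  Boundary ids in mesh output: 1 = Gamma_B, 2 = Gamma_M,
3 = Gamma_A, 4 = Gamma_0.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import _fem

__all__ = [
    "WallGeometry",
    "GeometryError",
    "cosine_profiles",
    "build_initial_geometry",
    "move_mesh",
    "measure_diameter",
    "discrete_mean_curvature",
    "surface_to_volume_ratios",
    "write_vtk",
]

DEFAULT_PROFILES = {
    "a_B": 0.5, "b_B": 0.0,
    "a_M": 0.55, "b_M": 0.2,
    "a_A": 0.7, "b_A": 0.3,
}


class GeometryError(ValueError):
    """Invalid geometry: crossing profiles, inverted elements, bad motion."""


def cosine_profiles(y, profile_params=None):
    """Evaluate the three boundary curves x_B(y), x_M(y), x_A(y)."""
    p = {**DEFAULT_PROFILES, **(profile_params or {})}
    y = np.asarray(y, dtype=float)
    c = np.cos(np.pi * y) / 2.0
    return p["a_B"] * c + p["b_B"], p["a_M"] * c + p["b_M"], p["a_A"] * c + p["b_A"]


@dataclass
class _Layer:
    """One structured strip: (ny+1) x (nx+1) node grid, inner->outer in x."""

    ny: int
    nx: int
    coords: np.ndarray        # reference coords, ((ny+1)*(nx+1), 2)
    tris: np.ndarray

    def node(self, iy, ix):
        return iy * (self.nx + 1) + ix

    @property
    def nnodes(self):
        return (self.ny + 1) * (self.nx + 1)

    def column(self, ix):
        return np.arange(self.ny + 1) * (self.nx + 1) + ix

    def row(self, iy):
        return iy * (self.nx + 1) + np.arange(self.nx + 1)

    def column_edges(self, ix):
        col = self.column(ix)
        return np.stack([col[:-1], col[1:]], axis=1)


def _structured_layer(ny, nx, y_grid, x_inner, x_outer):
    xi = np.linspace(0.0, 1.0, nx + 1)
    X = (1 - xi)[None, :] * x_inner[:, None] + xi[None, :] * x_outer[:, None]
    Y = np.broadcast_to(y_grid[:, None], X.shape)
    coords = np.stack([X.ravel(), Y.ravel()], axis=1)
    tris = []
    for iy in range(ny):
        for ix in range(nx):
            a = iy * (nx + 1) + ix
            b = a + 1
            c = b + (nx + 1)
            d = a + (nx + 1)
            tris.append((a, b, c))    # CCW: x to the right, y up
            tris.append((a, c, d))
    return _Layer(ny, nx, coords, np.asarray(tris, dtype=np.int64))


@dataclass
class WallGeometry:
    """Reference and current two-subdomain triangulations with labels.

    Node numbering: media nodes first on the merged mesh; adventitia
    interface nodes are identified with their media partners.  ``disp``
    holds the total Lagrangian displacement on merged nodes; current
    coordinates are reference + displacement.
    """

    media: _Layer
    adventitia: _Layer
    scale: float
    R0: float
    x_axis: float = 0.0       # centerline after shifting (always 0 here)
    y_bounds: tuple = (-1.0, 1.0)
    profile_params: dict = field(default_factory=dict)

    # merged-mesh bookkeeping (filled by build)
    media_to_merged: np.ndarray = None
    adv_to_merged: np.ndarray = None
    merged_coords: np.ndarray = None
    merged_tris: np.ndarray = None
    merged_subdomain: np.ndarray = None   # per merged element: 0 media, 1 adv
    disp: np.ndarray = None

    # boundary edges in submesh-local numbering (ordered along y)
    edges_B: np.ndarray = None            # media mesh
    edges_M_media: np.ndarray = None
    edges_M_adv: np.ndarray = None
    edges_A: np.ndarray = None            # adventitia mesh

    def __post_init__(self):
        if self.disp is None:
            self.disp = np.zeros_like(self.merged_coords)

    # --- node sets -----------------------------------------------------
    @property
    def n_merged(self):
        return self.merged_coords.shape[0]

    def clamp_nodes(self):
        """Merged node ids on Gamma_0 (the cuts y = y1, y2)."""
        m, a = self.media, self.adventitia
        ids = np.concatenate([
            self.media_to_merged[m.row(0)], self.media_to_merged[m.row(m.ny)],
            self.adv_to_merged[a.row(0)], self.adv_to_merged[a.row(a.ny)],
        ])
        return np.unique(ids)

    def periodic_reduction(self, which: str):
        """(n_reduced, prolongation CSR) identifying y=y2 nodes with y=y1.

        ``which`` is "media", "adventitia" or "merged".  Species transport
        is periodic in y; displacement is clamped instead.
        """
        if which == "media":
            n = self.media.nnodes
            slaves = self.media.row(self.media.ny)
            masters = self.media.row(0)
        elif which == "adventitia":
            n = self.adventitia.nnodes
            slaves = self.adventitia.row(self.adventitia.ny)
            masters = self.adventitia.row(0)
        elif which == "merged":
            n = self.n_merged
            slaves = np.concatenate([
                self.media_to_merged[self.media.row(self.media.ny)],
                self.adv_to_merged[self.adventitia.row(self.adventitia.ny)],
            ])
            masters = np.concatenate([
                self.media_to_merged[self.media.row(0)],
                self.adv_to_merged[self.adventitia.row(0)],
            ])
        else:
            raise ValueError(which)
        target = np.arange(n)
        target[slaves] = masters
        keep = np.setdiff1d(np.arange(n), slaves)
        red = -np.ones(n, dtype=np.int64)
        red[keep] = np.arange(keep.size)
        red[slaves] = red[masters]
        P = sp.coo_matrix(
            (np.ones(n), (np.arange(n), red)), shape=(n, keep.size)
        ).tocsr()
        return keep.size, P

    # --- current configuration -----------------------------------------
    def current_merged(self):
        return self.merged_coords + self.disp

    def current_media(self):
        return self.current_merged()[self.media_to_merged]

    def current_adventitia(self):
        return self.current_merged()[self.adv_to_merged]

    def check_valid(self, current=True):
        coords = self.current_merged() if current else self.merged_coords
        areas = _fem.element_areas(coords, self.merged_tris)
        bad = np.nonzero(areas <= 0)[0]
        if bad.size:
            raise GeometryError(f"inverted element(s): {bad[:5].tolist()}")

    def boundary_polyline(self, name: str, current=True):
        """Ordered node coordinates along a labeled boundary curve."""
        if name == "Gamma_B":
            ids = self.media_to_merged[self.media.column(0)]
        elif name == "Gamma_M":
            ids = self.media_to_merged[self.media.column(self.media.nx)]
        elif name == "Gamma_A":
            ids = self.adv_to_merged[self.adventitia.column(self.adventitia.nx)]
        else:
            raise ValueError(name)
        coords = self.current_merged() if current else self.merged_coords
        return coords[ids], ids


def build_initial_geometry(R0: float, mesh_size: float = 0.05,
                           profile_params: dict | None = None,
                           y_bounds: tuple = (-1.0, 1.0),
                           x_axis_unscaled: float = -0.75,
                           n_y: int | None = None,
                           nx_media: int | None = None,
                           nx_adv: int | None = None) -> WallGeometry:
    """Construct the scaled two-layer reference mesh.

    The unit-profile section is scaled uniformly so that the measured
    initial lumen diameter (twice the maximal horizontal distance from the
    centerline to Gamma_B) equals ``R0``, and translated so the centerline
    is x = 0.  ``mesh_size`` sets the target element size (cm); explicit
    ``n_y``/``nx_media``/``nx_adv`` override it.
    """
    if R0 <= 0:
        raise GeometryError("R0 must be positive")
    y1, y2 = y_bounds
    if not y1 < y2:
        raise GeometryError("need y1 < y2")

    # layer ordering on a fine grid (pre- and post-scaling equivalent)
    yy = np.linspace(y1, y2, 801)
    xB, xM, xA = cosine_profiles(yy, profile_params)
    if not (np.all(xB < xM) and np.all(xM < xA)):
        raise GeometryError("boundary profiles must satisfy x_B < x_M < x_A")
    if np.min(xB) <= x_axis_unscaled:
        raise GeometryError("centerline must lie inside the lumen")

    half_width = np.max(xB) - x_axis_unscaled
    scale = R0 / (2.0 * half_width)

    if n_y is None:
        n_y = max(16, int(round((y2 - y1) * scale / mesh_size)))
    if nx_media is None:
        nx_media = max(3, int(round(float(np.mean(xM - xB)) * scale / mesh_size)))
    if nx_adv is None:
        nx_adv = max(2, int(round(float(np.mean(xA - xM)) * scale / mesh_size)))

    y_grid = np.linspace(y1, y2, n_y + 1)
    xB, xM, xA = cosine_profiles(y_grid, profile_params)
    media = _structured_layer(n_y, nx_media, y_grid, xB, xM)
    adv = _structured_layer(n_y, nx_adv, y_grid, xM, xA)
    for layer in (media, adv):
        layer.coords[:, 0] = scale * (layer.coords[:, 0] - x_axis_unscaled)
        layer.coords[:, 1] = scale * layer.coords[:, 1]

    # merge interface nodes: media column nx <-> adventitia column 0
    media_to_merged = np.arange(media.nnodes)
    adv_to_merged = -np.ones(adv.nnodes, dtype=np.int64)
    adv_to_merged[adv.column(0)] = media_to_merged[media.column(nx_media)]
    others = np.nonzero(adv_to_merged < 0)[0]
    adv_to_merged[others] = media.nnodes + np.arange(others.size)
    n_merged = media.nnodes + others.size

    merged_coords = np.empty((n_merged, 2))
    merged_coords[media_to_merged] = media.coords
    merged_coords[adv_to_merged] = adv.coords
    merged_tris = np.concatenate([
        media_to_merged[media.tris], adv_to_merged[adv.tris]
    ])
    merged_sub = np.concatenate([
        np.zeros(len(media.tris), dtype=np.int64),
        np.ones(len(adv.tris), dtype=np.int64),
    ])

    geom = WallGeometry(
        media=media, adventitia=adv, scale=scale, R0=R0,
        y_bounds=(y1, y2), profile_params=dict(profile_params or {}),
        media_to_merged=media_to_merged, adv_to_merged=adv_to_merged,
        merged_coords=merged_coords, merged_tris=merged_tris,
        merged_subdomain=merged_sub,
        edges_B=media.column_edges(0),
        edges_M_media=media.column_edges(nx_media),
        edges_M_adv=adv.column_edges(0),
        edges_A=adv.column_edges(nx_adv),
    )
    geom.check_valid(current=False)
    return geom


def move_mesh(geom: WallGeometry, u_merged: np.ndarray) -> WallGeometry:
    """Return the geometry displaced by the flow map x = x_ref + u.

    ``u_merged`` must vanish on Gamma_0 (the displacement clamp); element
    validity is re-checked and an inverted element raises
    :class:`GeometryError` (callers use this to trigger step halving).
    """
    u_merged = np.asarray(u_merged, dtype=float)
    if u_merged.shape != geom.merged_coords.shape:
        raise GeometryError("displacement shape does not match merged nodes")
    clamp = geom.clamp_nodes()
    if np.max(np.abs(u_merged[clamp])) > 1e-12 * max(1.0, geom.R0):
        raise GeometryError("displacement must vanish on Gamma_0")
    new = dataclasses.replace(geom, disp=u_merged.copy())
    new.check_valid(current=True)
    return new


def measure_diameter(geom: WallGeometry, current=True) -> float:
    """Lumen diameter: twice the maximal horizontal distance from the
    centerline (x = x_axis) to the current Gamma_B curve."""
    pts, _ = geom.boundary_polyline("Gamma_B", current=current)
    return 2.0 * float(np.max(pts[:, 0] - geom.x_axis))


def discrete_mean_curvature(polyline: np.ndarray) -> np.ndarray:
    """Signed curvature (1/cm) at each node of an open polyline.

    Interior nodes use the circumscribed-circle formula through the node
    and its two neighbours (exact for points on a circle); endpoints copy
    their neighbour's one-sided value.  Sign follows the orientation of
    the polyline (positive when turning left).
    """
    pts = np.asarray(polyline, dtype=float)
    if pts.shape[0] < 3:
        raise GeometryError("polyline needs at least 3 nodes")
    e = np.diff(pts, axis=0)
    L = np.hypot(e[:, 0], e[:, 1])
    if np.any(L == 0):
        raise GeometryError("duplicate consecutive nodes")
    a = pts[:-2] - pts[1:-1]
    b = pts[2:] - pts[1:-1]
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    chord = pts[2:] - pts[:-2]
    denom = L[:-1] * L[1:] * np.hypot(chord[:, 0], chord[:, 1])
    kappa = np.empty(pts.shape[0])
    kappa[1:-1] = -2.0 * cross / denom
    kappa[0] = kappa[1]
    kappa[-1] = kappa[-2]
    return kappa


def surface_to_volume_ratios(geom: WallGeometry) -> dict[str, float]:
    """Reference boundary-length / subdomain-area ratios (cm^-1) used by
    the well-mixed two-compartment reduction."""
    area_m = float(np.sum(_fem.element_areas(geom.media.coords, geom.media.tris)))
    area_a = float(np.sum(_fem.element_areas(geom.adventitia.coords, geom.adventitia.tris)))
    LB = float(np.sum(_fem.edge_lengths(geom.media.coords, geom.edges_B)))
    LM = float(np.sum(_fem.edge_lengths(geom.media.coords, geom.edges_M_media)))
    LA = float(np.sum(_fem.edge_lengths(geom.adventitia.coords, geom.edges_A)))
    return {
        "B_media": LB / area_m,
        "M_media": LM / area_m,
        "M_adv": LM / area_a,
        "A_adv": LA / area_a,
        "area_media": area_m,
        "area_adv": area_a,
    }


def write_vtk(path, geom: WallGeometry, point_data=None, cell_data=None,
              current=True):
    """Write the merged mesh as legacy ASCII VTK with subdomain cell data.

    ``point_data``/``cell_data`` map names to arrays (scalars per merged
    node / per merged element).
    """
    coords = geom.current_merged() if current else geom.merged_coords
    tris = geom.merged_tris
    cell_data = {"subdomain": geom.merged_subdomain, **(cell_data or {})}
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\naawall snapshot\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(coords)} double\n")
        for x, y in coords:
            fh.write(f"{x:.10g} {y:.10g} 0\n")
        fh.write(f"CELLS {len(tris)} {4 * len(tris)}\n")
        for t in tris:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        fh.write(f"CELL_TYPES {len(tris)}\n")
        fh.write("5\n" * len(tris))
        if point_data:
            fh.write(f"POINT_DATA {len(coords)}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 1:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    fh.write("\n".join(f"{v:.10g}" for v in arr) + "\n")
                else:
                    fh.write(f"VECTORS {name} double\n")
                    for row in arr:
                        fh.write(f"{row[0]:.10g} {row[1]:.10g} 0\n")
        fh.write(f"CELL_DATA {len(tris)}\n")
        for name, arr in cell_data.items():
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            fh.write("\n".join(f"{float(v):.10g}" for v in np.asarray(arr)) + "\n")
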