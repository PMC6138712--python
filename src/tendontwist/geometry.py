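"""Tendon geometry: lofted elliptical hexahedral meshes, compartment and
sub-tendon labelling, and free-form mid-section CSA morphing.

The free Achilles tendon is represented as a solid lofted through elliptical
cross-sections measured at a few axial stations (emulating transverse
ultrasound planes). The cross-section is meshed with a butterfly O-grid — a
square core surrounded by ``n_radial`` circumferential layers — extruded
axially, which keeps all hexahedra well-shaped with no degenerate center.

Coordinate convention (documented in every output file):
x = medial(+)/lateral(-), y = anterior(+)/posterior(-),
z = distal(0) -> proximal(+). Units mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import PchipInterpolator

from .element import gauss_points, jacobians

__all__ = [
    "CrossSectionProfile",
    "TendonMesh",
    "MeshQualityError",
    "build_mesh",
    "label_compartments",
    "label_subtendons",
    "ffd_scale_csa",
    "section_area",
    "mesh_volume",
]

# sub-tendon label codes
SOL, MG, LG = 0, 1, 2
GAS = 1  # two-way scheme reuses code 1 for the merged gastrocnemius
MEDIAL, LATERAL = 1, -1

SUBTENDON_NAMES_3 = {SOL: "SOL", MG: "MG", LG: "LG"}
SUBTENDON_NAMES_2 = {SOL: "SOL", GAS: "GAS"}

_CORE_HALF_WIDTH = 0.45  # O-grid square core half-width in unit-disc coords


class MeshQualityError(RuntimeError):
    """Raised when an operation would produce inverted or degenerate elements."""


@dataclass(frozen=True)
class CrossSectionProfile:
    """Elliptical cross-section stations along the free tendon.

    ``stations`` rows are (z mm, semi-axis a mm, semi-axis b mm,
    centroid offset x mm, centroid offset y mm); a is the medial-lateral
    semi-axis, b the anterior-posterior one.
    """

    stations: np.ndarray

    def __post_init__(self):
        st = np.atleast_2d(np.asarray(self.stations, dtype=float))
        if st.shape[0] < 2 or st.shape[1] != 5:
            raise ValueError("profile needs >= 2 stations of (z, a, b, ox, oy)")
        if np.any(np.diff(st[:, 0]) <= 0):
            raise ValueError("station axial positions must be strictly increasing")
        if np.any(st[:, 1:3] <= 0):
            raise ValueError("ellipse semi-axes must be positive")
        object.__setattr__(self, "stations", st)

    @property
    def z_min(self) -> float:
        return float(self.stations[0, 0])

    @property
    def z_max(self) -> float:
        return float(self.stations[-1, 0])

    @property
    def length(self) -> float:
        return self.z_max - self.z_min

    def interpolators(self):
        """Monotone (PCHIP) interpolants of (a, b, ox, oy) versus z."""
        z = self.stations[:, 0]
        return [PchipInterpolator(z, self.stations[:, k]) for k in range(1, 5)]

    def area(self, z) -> np.ndarray:
        """Analytic cross-sectional area pi*a*b at axial position(s) z."""
        fa, fb, _, _ = self.interpolators()
        return np.pi * fa(z) * fb(z)

    @classmethod
    def circular(cls, radius: float, length: float, n_stations: int = 3):
        z = np.linspace(0.0, length, n_stations)
        st = np.column_stack([z, np.full_like(z, radius), np.full_like(z, radius),
                              np.zeros_like(z), np.zeros_like(z)])
        return cls(st)


def _unit_disc_grid(n_circ: int, n_radial: int):
    """Butterfly O-grid of the unit disc.

    Returns node xy (Nn, 2), quad connectivity (Nq, 4) counter-clockwise,
    the outer-boundary node indices in angular order, and per-quad metadata
    (is_ring flag, ring column index or -1, ring layer or -1).
    """
    if n_circ < 4 or n_circ % 4:
        raise ValueError("n_circ must be a positive multiple of 4")
    if n_radial < 1:
        raise ValueError("n_radial must be >= 1")
    m = n_circ // 4
    c0 = _CORE_HALF_WIDTH

    # core grid
    u = np.linspace(-c0, c0, m + 1)
    core_xy = np.array([(x, y) for y in u for x in u])  # row-major, y slow
    core_id = lambda i, j: j * (m + 1) + i  # noqa: E731

    # core perimeter anticlockwise from corner (c0, -c0)
    perim = []
    perim += [core_id(m, j) for j in range(m)]          # right side, going up
    perim += [core_id(m - i, m) for i in range(m)]      # top, right->left
    perim += [core_id(0, m - j) for j in range(m)]      # left, top->bottom
    perim += [core_id(i, 0) for i in range(m)]          # bottom, left->right
    perim = np.array(perim)

    theta = -np.pi / 4.0 + 2.0 * np.pi * np.arange(n_circ) / n_circ
    outer = np.column_stack([np.cos(theta), np.sin(theta)])

    nodes = [core_xy]
    n_core = core_xy.shape[0]
    ring_ids = np.empty((n_radial + 1, n_circ), dtype=int)
    ring_ids[0] = perim
    nid = n_core
    for layer in range(1, n_radial + 1):
        t = layer / n_radial
        pts = (1.0 - t) * core_xy[perim] + t * outer
        nodes.append(pts)
        ring_ids[layer] = np.arange(nid, nid + n_circ)
        nid += n_circ
    xy = np.vstack(nodes)
    # area-preserving sizing: scale so the boundary polygon area is exactly
    # pi, making every discrete section area match pi*a*b of the profile
    poly = 0.5 * n_circ * np.sin(2.0 * np.pi / n_circ)
    xy *= np.sqrt(np.pi / poly)

    quads, meta = [], []
    for j in range(m):
        for i in range(m):
            quads.append([core_id(i, j), core_id(i + 1, j),
                          core_id(i + 1, j + 1), core_id(i, j + 1)])
            meta.append((False, -1, -1))
    for layer in range(n_radial):
        for k in range(n_circ):
            k1 = (k + 1) % n_circ
            quads.append([ring_ids[layer, k], ring_ids[layer + 1, k],
                          ring_ids[layer + 1, k1], ring_ids[layer, k1]])
            meta.append((True, k, layer))
    return xy, np.array(quads), ring_ids[n_radial], meta


@dataclass
class TendonMesh:
    """Structured hexahedral tendon mesh with compartment/sub-tendon labels.

    Elements are grouped per axial slab; ``elem_inplane`` and ``elem_axial``
    give each element's in-plane quad index and axial slab index, which the
    rupture analysis uses to stack axial Gauss-point columns.
    """

    node_coords: np.ndarray
    hexes: np.ndarray
    long_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    gauss_order: int = 2
    compartment_label: np.ndarray | None = None  # +1 medial / -1 lateral
    subtendon_label: np.ndarray | None = None
    subtendon_scheme: str | None = None  # "three_way" | "two_way"
    profile: CrossSectionProfile | None = None
    # structured-grid metadata
    n_axial: int = 0
    nodes_per_section: int = 0
    elems_per_section: int = 0
    elem_inplane: np.ndarray | None = None
    elem_axial: np.ndarray | None = None
    boundary_ring: np.ndarray | None = None  # outer node ids of section 0
    inplane_area: np.ndarray | None = None   # reference area of each in-plane quad
    ring_meta: list | None = None            # per in-plane quad (is_ring, col, layer)

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_elems(self) -> int:
        return self.hexes.shape[0]

    @property
    def n_sections(self) -> int:
        return self.n_axial + 1

    def section_nodes(self, s: int) -> np.ndarray:
        return np.arange(s * self.nodes_per_section, (s + 1) * self.nodes_per_section)

    def section_boundary(self, s: int) -> np.ndarray:
        """Outer-boundary node ids of section s, in angular order."""
        return self.boundary_ring + s * self.nodes_per_section

    @property
    def distal_node_set(self) -> np.ndarray:
        return self.section_nodes(0)

    @property
    def proximal_node_set(self) -> np.ndarray:
        return self.section_nodes(self.n_axial)

    def section_z(self) -> np.ndarray:
        ids = [s * self.nodes_per_section for s in range(self.n_sections)]
        return self.node_coords[ids, 2]

    def section_centroid(self, s: int) -> np.ndarray:
        return self.node_coords[self.section_nodes(s)].mean(axis=0)

    def check_jacobians(self) -> float:
        """Minimum Gauss-point Jacobian determinant; raises if non-positive."""
        xi, _ = gauss_points(self.gauss_order)
        detJ, _ = jacobians(self.node_coords, self.hexes, xi)
        mn = float(detJ.min())
        if mn <= 0:
            raise MeshQualityError(f"inverted element: min detJ = {mn:g}")
        return mn

    def copy(self, **kw) -> "TendonMesh":
        out = replace(self)
        out.node_coords = self.node_coords.copy()
        for k, v in kw.items():
            setattr(out, k, v)
        return out

    def subtendon_names(self) -> dict:
        return SUBTENDON_NAMES_2 if self.subtendon_scheme == "two_way" else SUBTENDON_NAMES_3

    def subtendon_nodes(self, code: int, section: int | None = None) -> np.ndarray:
        """Nodes used by elements of a sub-tendon (optionally one section)."""
        if self.subtendon_label is None:
            raise ValueError("mesh has no sub-tendon labels")
        nodes = np.unique(self.hexes[self.subtendon_label == code])
        if section is not None:
            sec = self.section_nodes(section)
            nodes = nodes[np.isin(nodes, sec)]
        return nodes


def build_mesh(profile: CrossSectionProfile, n_axial: int = 6,
               n_circ: int = 16, n_radial: int = 2) -> TendonMesh:
    """Hexahedral mesh of the lofted elliptical solid.

    The unit-disc O-grid section is scaled per axial level by the
    interpolated ellipse semi-axes and shifted by the centroid offsets.
    """
    if n_axial < 1:
        raise ValueError("n_axial must be >= 1")
    xy, quads, outer_ring, meta = _unit_disc_grid(n_circ, n_radial)
    fa, fb, fox, foy = profile.interpolators()
    zs = np.linspace(profile.z_min, profile.z_max, n_axial + 1)

    npersec = xy.shape[0]
    coords = np.empty((npersec * (n_axial + 1), 3))
    for s, z in enumerate(zs):
        a, b, ox, oy = fa(z), fb(z), fox(z), foy(z)
        if a <= 0 or b <= 0:
            raise ValueError("degenerate profile: non-positive semi-axis")
        sl = slice(s * npersec, (s + 1) * npersec)
        coords[sl, 0] = ox + a * xy[:, 0]
        coords[sl, 1] = oy + b * xy[:, 1]
        coords[sl, 2] = z

    nq = quads.shape[0]
    hexes = np.empty((n_axial * nq, 8), dtype=int)
    elem_inplane = np.empty(n_axial * nq, dtype=int)
    elem_axial = np.empty(n_axial * nq, dtype=int)
    for s in range(n_axial):
        lo, hi = s * npersec, (s + 1) * npersec
        blk = slice(s * nq, (s + 1) * nq)
        hexes[blk, :4] = quads + lo
        hexes[blk, 4:] = quads + hi
        elem_inplane[blk] = np.arange(nq)
        elem_axial[blk] = s

    # reference in-plane quad areas (unit disc coords; used for area fractions)
    q = xy[quads]
    area = 0.5 * np.abs(
        np.sum(q[:, :, 0] * np.roll(q[:, :, 1], -1, axis=1)
               - np.roll(q[:, :, 0], -1, axis=1) * q[:, :, 1], axis=1)
    )

    mesh = TendonMesh(
        node_coords=coords, hexes=hexes, profile=profile,
        n_axial=n_axial, nodes_per_section=npersec, elems_per_section=nq,
        elem_inplane=elem_inplane, elem_axial=elem_axial,
        boundary_ring=outer_ring, inplane_area=area, ring_meta=meta,
    )
    mesh.check_jacobians()
    return mesh


def section_area(mesh: TendonMesh, s: int) -> float:
    """Shoelace area of section ``s``'s outer boundary polygon (mm^2)."""
    ring = mesh.node_coords[mesh.section_boundary(s)]
    x, y = ring[:, 0], ring[:, 1]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def mesh_volume(mesh: TendonMesh) -> float:
    """Total mesh volume from Gauss-point Jacobians (mm^3)."""
    xi, w = gauss_points(mesh.gauss_order)
    detJ, _ = jacobians(mesh.node_coords, mesh.hexes, xi)
    return float((detJ * w).sum())


def label_compartments(mesh: TendonMesh, medial_dir: np.ndarray | None = None) -> TendonMesh:
    """Split elements into medial/lateral halves about the section centroid.

    An element is medial when its centroid lies on the +medial side of the
    anterior-posterior plane through its axial slab's section centroid.
    """
    if mesh.nodes_per_section == 0:
        raise ValueError("mesh lacks section structure")
    d = np.array([1.0, 0.0, 0.0]) if medial_dir is None else np.asarray(medial_dir, float)
    d = d / np.linalg.norm(d)
    cent = mesh.node_coords[mesh.hexes].mean(axis=1)
    sec_c = np.array([mesh.section_centroid(s) for s in range(mesh.n_sections)])
    slab_c = 0.5 * (sec_c[:-1] + sec_c[1:])[mesh.elem_axial]
    side = (cent - slab_c) @ d
    if np.allclose(side, 0.0):
        raise MeshQualityError("zero-width mesh: cannot split medial/lateral")
    out = mesh.copy()
    out.compartment_label = np.where(side >= 0, MEDIAL, LATERAL)
    return out


def _inplane_angles(mesh: TendonMesh):
    """Normalized elliptical angle of each in-plane quad centroid in [0, 2pi).

    Uses the distal section's geometry; the partition is axially constant.
    Angles are measured anticlockwise from the medial (+x) axis with
    coordinates normalized by the local semi-axes, so equal angle spans
    correspond to equal area fractions of the ellipse.
    """
    nq = mesh.elems_per_section
    first = np.arange(nq)  # elements of slab 0 are in in-plane order
    cent = mesh.node_coords[mesh.hexes[first], :2].mean(axis=1)
    c = mesh.section_centroid(0)[:2] * 0.5 + mesh.section_centroid(1)[:2] * 0.5
    fa, fb, _, _ = mesh.profile.interpolators()
    zmid = 0.5 * (mesh.node_coords[mesh.section_nodes(0), 2].mean()
                  + mesh.node_coords[mesh.section_nodes(1), 2].mean())
    rel = cent - c
    ang = np.arctan2(rel[:, 1] / fb(zmid), rel[:, 0] / fa(zmid))
    return np.mod(ang, 2.0 * np.pi)


def label_subtendons(mesh: TendonMesh, scheme: str = "three_way",
                     fractions: tuple | None = None) -> TendonMesh:
    """Partition the cross-section into sub-tendon regions.

    three_way: angular sectors with area fractions 6:2:1 by default
    (soleus : medial gastrocnemius : lateral gastrocnemius), walked
    anticlockwise from the medial axis so the soleus sector is centred
    medially. ``fractions`` overrides the sector areas (anatomical
    sub-tendon areas differ from the 6:2:1 muscle PCSA ratio that sets the
    load split; the mismatch is what differential loading concentrates).

    two_way: a gastrocnemius sleeve — the outer-ring arc centred posteriorly
    holding ~1/3 of the section area — against the soleus remainder (6:3
    split). The sleeve's interface follows mesh surfaces exactly, which is
    what permits conforming node-to-node sliding constraints.
    """
    if mesh.inplane_area is None:
        raise ValueError("mesh lacks in-plane structure")
    nq = mesh.elems_per_section
    area = mesh.inplane_area
    total = area.sum()
    max_frac = area.max() / total
    inplane_label = np.empty(nq, dtype=int)

    n_circ_mesh = max(m[1] for m in mesh.ring_meta) + 1
    if scheme == "three_way":
        wanted = list(fractions) if fractions is not None \
            else [2.0 / 3.0, 2.0 / 9.0, 1.0 / 9.0]
        if len(wanted) != 3 or abs(sum(wanted) - 1.0) > 1e-9:
            raise ValueError("three_way fractions must be 3 values summing to 1")
        # the smallest sector must span at least one ring column
        if n_circ_mesh * min(wanted) < 1.0:
            raise MeshQualityError(
                f"n_circ={n_circ_mesh} too coarse for "
                f"{np.round(wanted, 3)} sectors"
            )
        ang = _inplane_angles(mesh)
        # start the walk at the medial axis shifted back by half the SOL span
        start = -0.5 * wanted[0] * 2.0 * np.pi
        order = np.lexsort((np.arange(nq), np.mod(ang - start, 2.0 * np.pi)))
        cum = np.cumsum(area[order]) / total
        targets = np.array([wanted[0], wanted[0] + wanted[1]])
        codes_sorted = np.where(cum <= targets[0] + 1e-12, SOL,
                                np.where(cum <= targets[1] + 1e-12, MG, LG))
        inplane_label[order] = codes_sorted
        fracs = [area[inplane_label == c].sum() / total for c in (SOL, MG, LG)]
        if any(f == 0.0 for f in fracs) or any(
            abs(f - t) > max_frac for f, t in zip(fracs, wanted)
        ):
            raise MeshQualityError(
                f"circumferential resolution too coarse for the requested sectors "
                f"(achieved fractions {np.round(fracs, 3)})"
            )
        names = "three_way"
    elif scheme == "two_way":
        is_ring = np.array([m[0] for m in mesh.ring_meta])
        col = np.array([m[1] for m in mesh.ring_meta])
        if not is_ring.any():
            raise MeshQualityError("mesh has no ring layer for a two-way split")
        ang = _inplane_angles(mesh)
        n_circ = col.max() + 1
        # mean angle of each ring column; grow the GAS arc nearest-first
        # around the posterior (-y) direction
        col_ang = np.array([
            np.arctan2(np.sin(ang[is_ring & (col == k)]).mean(),
                       np.cos(ang[is_ring & (col == k)]).mean())
            for k in range(n_circ)
        ])
        dist = np.abs(np.mod(col_ang - (-np.pi / 2.0) + np.pi, 2 * np.pi) - np.pi)
        col_area = np.array([area[is_ring & (col == k)].sum() for k in range(n_circ)])
        order = np.lexsort((np.arange(n_circ), dist))
        chosen, acc = [], 0.0
        for k in order:
            if acc >= total / 3.0:
                break
            chosen.append(k)
            acc += col_area[k]
        inplane_label[:] = SOL
        inplane_label[is_ring & np.isin(col, chosen)] = GAS
        gas_frac = acc / total
        if abs(gas_frac - 1.0 / 3.0) > max(col_area.max() / total, max_frac):
            raise MeshQualityError(
                f"cannot realize 6:3 split on this mesh (GAS fraction {gas_frac:.3f})"
            )
        names = "two_way"
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    out = mesh.copy()
    out.subtendon_label = inplane_label[mesh.elem_inplane]
    out.subtendon_scheme = names
    return out


def ffd_scale_csa(mesh: TendonMesh, scale: float) -> TendonMesh:
    """Free-form morph scaling the mid-section CSA by ``scale``.

    In-plane coordinates are scaled about the interpolated section centroid
    by ``1 + (sqrt(scale)-1) sin^2(pi t)`` with t the axial fraction, which
    leaves the end sections untouched and multiplies mid-section area by
    ``scale``. Raises on element inversion or severe quality loss.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if scale == 1.0:
        return mesh.copy()
    out = mesh.copy()
    z = mesh.node_coords[:, 2]
    z0, z1 = z.min(), z.max()
    t = (z - z0) / (z1 - z0)
    f = 1.0 + (np.sqrt(scale) - 1.0) * np.sin(np.pi * t) ** 2
    _, _, fox, foy = mesh.profile.interpolators()
    cx, cy = fox(z), foy(z)
    out.node_coords[:, 0] = cx + f * (mesh.node_coords[:, 0] - cx)
    out.node_coords[:, 1] = cy + f * (mesh.node_coords[:, 1] - cy)

    xi, _ = gauss_points(mesh.gauss_order)
    det_new, _ = jacobians(out.node_coords, out.hexes, xi)
    det_old, _ = jacobians(mesh.node_coords, mesh.hexes, xi)
    ratio = det_new / det_old
    if det_new.min() <= 0 or ratio.min() < 0.25:
        raise MeshQualityError(
            f"CSA scale {scale} degenerates elements "
            f"(min detJ ratio {ratio.min():.3f})"
        )
    return out
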