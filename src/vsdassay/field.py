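"""Finite-element model of extracellular stimulation on a coverslip.

The extracellular potential phi between a pair of bipolar electrodes in a
purely resistive bath obeys the Laplace equation div(sigma grad phi) = 0.
The coverslip is meshed with a Delaunay triangulation refined by a size
field (fine near the small electrode discs, coarse far away), the equation is
solved with linear (P1) finite elements under Dirichlet data +A/2 / -A/2 on
the electrode nodes and a zero-flux condition on the insulating outer
boundary, and the resulting field is coupled one-way to passive cells: the
cell does not perturb the field, and each boundary segment of the cell
charges toward its local extracellular drive with the membrane time constant
tau = R_in * C_m.

Two drive references are supported:

``perimeter``
    The transmembrane drive at a segment is -(phi_e - mean over the cell
    perimeter): the compact closed cell, which feels only the *variation* of
    the potential across its own outline.  A spatially uniform potential
    produces no drive.
``bath``
    The drive is -(phi_e - 0): the cell interior is pinned to the bath
    reference, the limit of a cell whose processes extend far outside the
    stimulated region (the long-fiber limit of the cable description of
    extracellular stimulation).  A cell parked near one pole of a widely
    spaced electrode pair then receives a large, spatially uniform
    polarization — the regime exploited experimentally by moving the counter
    electrode away from the field of view.

Units: coordinates in mm, potentials in volts, conductivity in S/m, membrane
quantities in the package's patch-clamp units (mV, ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from shapely.geometry import Point, Polygon
from shapely.validation import explain_validity

from .errors import (
    ConfigurationError,
    GeometryError,
    LocationError,
    ProtocolError,
    ThresholdUnreachableError,
)
from .membrane import PassiveMembrane

__all__ = [
    "Electrode",
    "CultureGeometry",
    "TriMesh",
    "FieldSolution",
    "StimulusPulse",
    "PolarizationResult",
    "triangulate",
    "solve_laplace",
    "potential_at",
    "membrane_polarization",
    "min_suprathreshold_voltage",
]


@dataclass
class Electrode:
    """A stimulation pole regularized as a disc (center mm, radius mm, polarity +-1)."""

    center: tuple[float, float]
    radius: float = 0.025
    polarity: int = 1

    def __post_init__(self):
        if self.radius <= 0:
            raise GeometryError("electrode radius must be positive")
        if self.polarity not in (+1, -1):
            raise GeometryError("electrode polarity must be +1 or -1")


@dataclass
class CultureGeometry:
    """Coverslip outline, electrode poles and cell outlines, all in mm."""

    domain: np.ndarray                      # (N, 2) closed polygon (last vertex omitted)
    electrodes: list[Electrode] = dc_field(default_factory=list)
    cells: list[np.ndarray] = dc_field(default_factory=list)
    cell_membranes: list[PassiveMembrane] | None = None

    def __post_init__(self):
        self.domain = np.asarray(self.domain, dtype=float)
        self.cells = [np.asarray(c, dtype=float) for c in self.cells]
        poly = Polygon(self.domain)
        if not poly.is_valid:
            idx = self._offending_vertex(poly)
            raise GeometryError(
                f"domain polygon is invalid ({explain_validity(poly)})", vertex_index=idx
            )
        for j, e in enumerate(self.electrodes):
            if not poly.contains(Point(*e.center).buffer(e.radius)):
                raise GeometryError(f"electrode {j} not strictly inside domain")
        discs = [Point(*e.center).buffer(e.radius) for e in self.electrodes]
        for j in range(len(discs)):
            for l in range(j + 1, len(discs)):
                if discs[j].intersects(discs[l]):
                    raise GeometryError(f"electrodes {j} and {l} overlap")
        for j, c in enumerate(self.cells):
            cp = Polygon(c)
            if not cp.is_valid:
                idx = self._offending_vertex(cp)
                raise GeometryError(f"cell {j} polygon is invalid", vertex_index=idx)
            if not poly.contains(cp):
                raise GeometryError(f"cell {j} not strictly inside domain")
            for l, d in enumerate(discs):
                if cp.intersects(d):
                    raise GeometryError(f"cell {j} overlaps electrode {l}")
        if self.electrodes:
            pols = {e.polarity for e in self.electrodes}
            if pols != {+1, -1}:
                raise GeometryError("need at least one positive and one negative electrode")
        if self.cell_membranes is not None and len(self.cell_membranes) != len(self.cells):
            raise GeometryError("cell_membranes must match cells in length")

    def _offending_vertex(self, poly) -> int | None:
        # shapely reports a location like "Self-intersection[x y]"; map to nearest vertex
        msg = explain_validity(poly)
        if "[" in msg:
            try:
                loc = msg[msg.index("[") + 1 : msg.index("]")].split()
                p = np.array([float(loc[0]), float(loc[1])])
                verts = np.asarray(poly.exterior.coords)[:-1]
                return int(np.argmin(np.linalg.norm(verts - p, axis=1)))
            except (ValueError, IndexError):
                return None
        return None

    @property
    def domain_polygon(self) -> Polygon:
        return Polygon(self.domain)


@dataclass
class TriMesh:
    """Conforming triangular mesh: nodes (mm), positively oriented triangles,
    and a per-node boundary tag ('outer', 'electrode_<k>' or 'interior')."""

    nodes: np.ndarray
    triangles: np.ndarray
    boundary_tags: list[str]
    electrode_polarity: dict[str, int] = dc_field(default_factory=dict)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)
        if len(self.boundary_tags) != len(self.nodes):
            raise GeometryError("boundary_tags must have one entry per node")
        areas = self.areas()
        if np.any(areas <= 0):
            bad = int(np.argmin(areas))
            raise GeometryError(f"triangle {bad} is degenerate or negatively oriented")

    def areas(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        return 0.5 * ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                      - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))

    def save_txt(self, path) -> None:
        """Plain-text export: node block (x y tag) then element block (i j k)."""
        with open(path, "w") as fh:
            fh.write(f"# vsdassay trimesh: {len(self.nodes)} nodes, "
                     f"{len(self.triangles)} triangles\n")
            fh.write("# nodes: x_mm y_mm tag\n")
            for (x, y), tag in zip(self.nodes, self.boundary_tags):
                fh.write(f"{x:.9g} {y:.9g} {tag}\n")
            fh.write("# triangles: i j k\n")
            for i, j, k in self.triangles:
                fh.write(f"{i} {j} {k}\n")


@dataclass
class FieldSolution:
    """Nodal potentials (volts) of a Laplace solve on a TriMesh."""

    mesh: TriMesh
    phi: np.ndarray
    conductivity: float
    amplitude: float

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        self._interp = None

    def save_csv(self, path) -> None:
        arr = np.column_stack([self.mesh.nodes, self.phi])
        np.savetxt(path, arr, delimiter=",", header="x_mm,y_mm,phi_V", comments="", fmt="%.9g")


@dataclass
class StimulusPulse:
    """Rectangular extracellular pulse: amplitude in volts, duration in ms."""

    amplitude: float = 1.0
    duration: float = 5.0

    def __post_init__(self):
        if not 0.0 < self.amplitude <= 10.0:
            raise ProtocolError(f"amplitude {self.amplitude} V outside (0, 10] V")
        if self.duration <= 0:
            raise ProtocolError("pulse duration must be positive")


# ---------------------------------------------------------------------------
# meshing
# ---------------------------------------------------------------------------

def _polygon_boundary_points(poly: np.ndarray, h: float) -> np.ndarray:
    """Sample a closed polygon's edges at spacing <= h, keeping the vertices."""
    pts = []
    n = len(poly)
    for i in range(n):
        a, b = poly[i], poly[(i + 1) % n]
        seg = np.linalg.norm(b - a)
        k = max(1, int(np.ceil(seg / h)))
        for j in range(k):
            pts.append(a + (b - a) * (j / k))
    return np.asarray(pts)


def _circle_points(center, radius, h) -> np.ndarray:
    n = max(12, int(np.ceil(2 * np.pi * radius / h)))
    th = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + radius * np.cos(th),
                            center[1] + radius * np.sin(th)])


def triangulate(geom: CultureGeometry, max_area: float, grading: float = 0.35,
                max_rounds: int = 40) -> TriMesh:
    """Mesh the culture geometry with a graded Delaunay triangulation.

    Every interior triangle satisfies area <= max_area; near electrode and
    cell boundaries the target area shrinks with distance (slope ``grading``)
    down to the scale of the local feature, regularizing the near-singular
    log potential around the small electrode discs.
    """
    from scipy.spatial import Delaunay

    if max_area <= 0:
        raise GeometryError("max_area must be positive")
    poly = geom.domain_polygon
    h_glob = np.sqrt(max_area * 4.0 / np.sqrt(3.0))

    feature_pts = []   # (x, y, local_h) anchors of the size field
    pts = [_polygon_boundary_points(geom.domain, h_glob)]
    for e in geom.electrodes:
        h_e = min(h_glob, 2 * np.pi * e.radius / 16)
        ring = _circle_points(e.center, e.radius, h_e)
        pts.append(ring)
        pts.append(np.asarray([e.center]))
        feature_pts.append((e.center[0], e.center[1], h_e, e.radius))
        # a couple of graded rings ease the transition away from the disc
        r = 2.0 * e.radius
        while r < 16 * e.radius and r < 0.5 * np.sqrt(poly.area):
            ring = _circle_points(e.center, r, max(h_e, grading * (r - e.radius)))
            pts.append(ring[[poly.contains(Point(*q)) for q in ring]])
            r *= 2.0
    for c in geom.cells:
        per = Polygon(c).length
        h_c = min(h_glob, per / 64)
        pts.append(_polygon_boundary_points(c, h_c))

    # interior seeds from a deterministic low-discrepancy sequence whose length
    # scales with domain_area / max_area, so refining the request always adds
    # points (the sequence prefix only ever grows)
    from scipy.stats import qmc

    minx, miny, maxx, maxy = poly.bounds
    n_seed = max(4, int(np.ceil(poly.area / (1.5 * max_area))))
    unit = qmc.Halton(d=2, scramble=False).random(n_seed)
    seeds = unit * [maxx - minx, maxy - miny] + [minx, miny]
    boundary_clear = poly.exterior.distance
    keep = [q for q in seeds
            if poly.contains(Point(*q)) and boundary_clear(Point(*q)) > 0.25 * h_glob]
    if keep:
        pts.append(np.asarray(keep))

    points = np.vstack([p for p in pts if len(p)])
    points = np.unique(np.round(points, 9), axis=0)

    def size_at(xy: np.ndarray) -> np.ndarray:
        """Target triangle area at positions xy (n, 2)."""
        h = np.full(len(xy), h_glob)
        for (cx, cy, h_e, rad) in feature_pts:
            d = np.hypot(xy[:, 0] - cx, xy[:, 1] - cy) - rad
            h = np.minimum(h, np.maximum(h_e, grading * np.maximum(d, 0.0) + h_e))
        return np.minimum(max_area, 0.5 * h * h)

    prepared = poly.buffer(1e-9)
    for _ in range(max_rounds):
        tri = Delaunay(points)
        simp = tri.simplices
        p = points[simp]
        areas = 0.5 * np.abs((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                             - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))
        cent = p.mean(axis=1)
        interior = np.array([prepared.contains(Point(*q)) for q in cent])
        too_big = interior & (areas > size_at(cent) + 1e-15)
        if not np.any(too_big):
            break
        new_pts = cent[too_big]
        points = np.unique(np.round(np.vstack([points, new_pts]), 9), axis=0)

    tri = Delaunay(points)
    simp = tri.simplices
    p = points[simp]
    cross = ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
             - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))
    cent = p.mean(axis=1)
    interior = np.array([prepared.contains(Point(*q)) for q in cent])
    keep = interior & (np.abs(cross) > 1e-14)
    simp = simp[keep]
    # orient CCW
    flip = cross[keep] < 0
    simp[flip] = simp[flip][:, [0, 2, 1]]

    # drop unused nodes
    used = np.unique(simp)
    remap = -np.ones(len(points), dtype=int)
    remap[used] = np.arange(len(used))
    nodes = points[used]
    triangles = remap[simp]

    tol = 1e-9
    tags = []
    ext = poly.exterior
    for q in nodes:
        tag = "interior"
        for k, e in enumerate(geom.electrodes):
            if np.hypot(q[0] - e.center[0], q[1] - e.center[1]) <= e.radius + 1e-7:
                tag = f"electrode_{k}"
                break
        if tag == "interior" and ext.distance(Point(*q)) < tol:
            tag = "outer"
        tags.append(tag)

    polarity = {f"electrode_{k}": e.polarity for k, e in enumerate(geom.electrodes)}
    return TriMesh(nodes=nodes, triangles=triangles, boundary_tags=tags,
                   electrode_polarity=polarity)


# ---------------------------------------------------------------------------
# FEM solve
# ---------------------------------------------------------------------------

def _stiffness(mesh: TriMesh, sigma: float) -> sp.csr_matrix:
    """P1 stiffness matrix for -div(sigma grad phi)."""
    tri = mesh.triangles
    p = mesh.nodes[tri]
    x, y = p[..., 0], p[..., 1]
    b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    area = 0.5 * (b[:, 0] * c[:, 1] - b[:, 1] * c[:, 0])
    coef = sigma / (4.0 * area)
    ke = coef[:, None, None] * (b[:, :, None] * b[:, None, :] + c[:, :, None] * c[:, None, :])
    rows = np.repeat(tri, 3, axis=1).ravel()
    cols = np.tile(tri, (1, 3)).ravel()
    return sp.coo_matrix((ke.ravel(), (rows, cols)),
                         shape=(len(mesh.nodes),) * 2).tocsr()


def solve_laplace(mesh: TriMesh, sigma: float = 1.5, amplitude: float = 1.0) -> FieldSolution:
    """Solve div(sigma grad phi) = 0 with phi = +-amplitude/2 on the electrode
    nodes and natural (zero-flux) conditions on the remaining boundary.

    Under pure Dirichlet data the solution is independent of sigma; the
    conductivity is retained for future current-source boundary conditions.
    """
    tags = np.asarray(mesh.boundary_tags)
    dirichlet = np.zeros(len(mesh.nodes), dtype=bool)
    values = np.zeros(len(mesh.nodes))
    seen_pol = set()
    for tag, pol in mesh.electrode_polarity.items():
        sel = tags == tag
        if np.any(sel):
            dirichlet |= sel
            values[sel] = pol * amplitude / 2.0
            seen_pol.add(pol)
    if seen_pol != {+1, -1}:
        raise ConfigurationError(
            "mesh must carry at least one node for each electrode polarity"
        )

    k_mat = _stiffness(mesh, sigma)
    free = ~dirichlet
    rhs = -k_mat[:, dirichlet] @ values[dirichlet]
    phi = values.copy()
    a_ff = k_mat[free][:, free].tocsc()
    phi[free] = spla.spsolve(a_ff, rhs[free])

    resid = np.linalg.norm(a_ff @ phi[free] - rhs[free])
    scale = max(np.linalg.norm(rhs[free]), np.linalg.norm(phi[free]), 1e-30)
    if resid / scale > 1e-10:
        raise ConfigurationError(f"linear system residual too large: {resid / scale:.2e}")
    return FieldSolution(mesh=mesh, phi=phi, conductivity=sigma, amplitude=amplitude)


def _interpolator(sol: FieldSolution):
    if sol._interp is None:
        import matplotlib.tri as mtri

        t = mtri.Triangulation(sol.mesh.nodes[:, 0], sol.mesh.nodes[:, 1],
                               sol.mesh.triangles)
        sol._interp = mtri.LinearTriInterpolator(t, sol.phi)
    return sol._interp


def potential_at(sol: FieldSolution, p) -> float | np.ndarray:
    """Barycentric (P1) interpolation of phi at point(s) p, exact at nodes."""
    q = np.atleast_2d(np.asarray(p, dtype=float))
    out = _interpolator(sol)(q[:, 0], q[:, 1])
    if np.ma.is_masked(out) and np.any(np.ma.getmaskarray(out)):
        bad = q[np.ma.getmaskarray(out)][0]
        raise LocationError(f"point ({bad[0]:.4g}, {bad[1]:.4g}) is outside the meshed domain")
    out = np.ma.getdata(out)
    return float(out[0]) if np.asarray(p).ndim == 1 else out


# ---------------------------------------------------------------------------
# membrane coupling
# ---------------------------------------------------------------------------

@dataclass
class PolarizationResult:
    """Per-segment transmembrane deviation of one cell during/after a pulse."""

    times: np.ndarray            # ms
    dvm: np.ndarray              # (n_segments, n_times) in mV
    segments: np.ndarray         # (n_segments, 2) midpoint coordinates, mm
    steady_drive: np.ndarray     # (n_segments,) steady-state drive, mV
    reference: str

    @property
    def peak_depolarization(self) -> float:
        return float(self.dvm.max())

    @property
    def peak_hyperpolarization(self) -> float:
        return float(self.dvm.min())

    @property
    def peak_polarization(self) -> float:
        """Largest |dVm| over segments and time, mV."""
        return float(np.abs(self.dvm).max())


def membrane_polarization(
    sol: FieldSolution,
    cell: np.ndarray,
    mem: PassiveMembrane,
    pulse: StimulusPulse,
    n_segments: int = 64,
    reference: str = "perimeter",
    dt: float = 0.1,
    t_total: float | None = None,
) -> PolarizationResult:
    """First-order response of a passive cell outline to the extracellular field.

    Each of >= 64 equal-arc-length boundary segments obeys

        tau * d(dVm)/dt + dVm = drive(s)      during the pulse,
        tau * d(dVm)/dt + dVm = 0             afterwards,

    with tau = R_in * C_m and drive(s) = -(phi_e(s) - ref) * 1000 mV where
    ``ref`` is the perimeter mean of phi_e ('perimeter') or the bath zero
    ('bath').  The solution is written in closed form, so dt only sets the
    reporting grid.
    """
    if pulse.duration <= 0:
        raise ProtocolError("pulse duration must be positive")
    if reference not in ("perimeter", "bath"):
        raise ConfigurationError(f"unknown reference '{reference}'")
    boundary = Polygon(np.asarray(cell, dtype=float)).exterior
    n_seg = max(64, int(n_segments))
    s = (np.arange(n_seg) + 0.5) / n_seg * boundary.length
    mids = np.asarray([boundary.interpolate(si).coords[0] for si in s])
    phi_e = np.asarray([potential_at(sol, q) for q in mids])

    ref_val = phi_e.mean() if reference == "perimeter" else 0.0
    drive = -(phi_e - ref_val) * 1000.0     # volts -> mV

    tau = mem.tau_ms
    if t_total is None:
        t_total = pulse.duration + 5.0 * tau
    times = np.arange(0.0, t_total + dt / 2, dt)
    on = times <= pulse.duration
    rise = 1.0 - np.exp(-times[on] / tau)
    end_level = 1.0 - np.exp(-pulse.duration / tau)
    decay = end_level * np.exp(-(times[~on] - pulse.duration) / tau)
    shape = np.concatenate([rise, decay])
    dvm = drive[:, None] * shape[None, :]
    return PolarizationResult(times=times, dvm=dvm, segments=mids,
                              steady_drive=drive, reference=reference)


def min_suprathreshold_voltage(
    geom: CultureGeometry,
    threshold: float,
    pulse_duration: float = 5.0,
    max_area: float | None = None,
    reference: str = "perimeter",
    sigma: float = 1.5,
    resolution: float = 0.01,
) -> tuple[float, np.ndarray]:
    """Smallest amplitude in (0, 10] V whose pulse depolarizes every cell past
    ``threshold`` mV; returns (amplitude, per-cell peak depolarization at it).

    The field and the membrane response are both linear in the applied
    amplitude, so a single unit-amplitude solve suffices; the bisection to
    ``resolution`` V mirrors the amplitude search an experimenter would run.
    """
    if not geom.cells:
        raise ConfigurationError("geometry contains no cells")
    if max_area is None:
        max_area = geom.domain_polygon.area / 400.0
    mesh = triangulate(geom, max_area)
    sol = solve_laplace(mesh, sigma=sigma, amplitude=1.0)
    membranes = geom.cell_membranes or [PassiveMembrane() for _ in geom.cells]
    pulse = StimulusPulse(amplitude=1.0, duration=pulse_duration)
    unit_peaks = np.asarray([
        membrane_polarization(sol, c, m, pulse, reference=reference).peak_depolarization
        for c, m in zip(geom.cells, membranes)
    ])

    def ok(amplitude: float) -> bool:
        return bool(np.all(unit_peaks * amplitude >= threshold))

    lo, hi = resolution, 10.0
    if ok(lo):
        return lo, unit_peaks * lo
    if not ok(hi):
        limiting = int(np.argmin(unit_peaks))
        raise ThresholdUnreachableError(
            f"cell {limiting} stays below {threshold} mV even at 10 V", limiting_cell=limiting
        )
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if ok(mid):
            hi = mid
        else:
            lo = mid
    return hi, unit_peaks * hi
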