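"""Tissue geometries for the shoot apical meristem (SAM) model.

The meristem is abstracted as a graph of cells.  The standard template is a
half disk drawn on a square lattice: a quarter circle centred on the
bottom-left grid corner, mirrored through its left edge.  A lattice cell
belongs to the tissue when its centre ``(i, j)`` satisfies ``i**2 + j**2 <
radius**2``; with ``radius=30`` this yields the canonical 732-cell template.
The curved boundary is the epidermis (L1, the source of the positional
morphogens), the bottom row is a sink abstracting flux into the stem, and
the left column is the symmetry axis: each axis cell carries a phantom
neighbour, the reflection of its inward neighbour, standing in for the
removed half of the meristem.

A 1D chain (sink at one end, epidermis at the other) and a synthetic 3D
dome (cell volumes and pairwise contact surfaces, emulating a segmented
meristem) are also provided, along with the binary target expression domains
used by the parameter optimisation.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp


class TemplateError(ValueError):
    """Invalid tissue geometry or template file."""


@dataclass
class TissueTemplate:
    """Cell graph of a meristem representation.

    Attributes
    ----------
    n_cells:
        Number of cells.
    coords:
        ``(n_cells, 2)`` integer lattice coordinates for 1D/2D templates or
        ``(n_cells, 3)`` real positions for 3D templates.
    neighbor_weights:
        Symmetric sparse matrix of coupling weights; 1 for adjacent lattice
        cells (1D/2D), contact surface area ``C_ij`` in 3D.
    degree:
        Effective neighbour count per cell, including the +1 bonus recorded
        for cells on the mirror boundary.
    volumes:
        Cell volumes; all 1 for 1D/2D templates.
    L:
        Epidermis (L1) indicator vector in {0, 1}.
    S:
        Sink indicator vector in {0, 1}.
    mirror:
        Indicator of cells sitting on the mirror (symmetry) boundary.
    kind:
        "1d", "2d" or "3d"; selects the transport discretisation.
    """

    n_cells: int
    coords: np.ndarray
    neighbor_weights: sp.csr_matrix
    degree: np.ndarray
    volumes: np.ndarray
    L: np.ndarray
    S: np.ndarray
    mirror: np.ndarray
    kind: str = "2d"

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise TemplateError("template must contain at least one cell")
        W = self.neighbor_weights
        if W.shape != (self.n_cells, self.n_cells):
            raise TemplateError("neighbor_weights shape mismatch")
        if np.any(W.diagonal() != 0):
            raise TemplateError("neighbor_weights must have a zero diagonal")
        if (abs(W - W.T)).max() > 1e-9 * max(1.0, abs(W).max()):
            raise TemplateError("neighbor_weights must be symmetric")
        if W.nnz and W.data.min() < 0:
            raise TemplateError("neighbor_weights must be non-negative")
        if np.any((self.L == 1) & (self.S == 1)):
            raise TemplateError("epidermis and sink masks overlap")
        if np.any(self.volumes <= 0):
            raise TemplateError("cell volumes must be positive")

    @property
    def central_axis(self) -> np.ndarray:
        """Indices of the cells on the central (mirror) axis, stem to apex.

        For 2D templates these are the ``x == 0`` cells ordered by height
        ``y``; for a 1D chain the whole chain; for 3D, the cells closest to
        the vertical axis in each height band.
        """
        if self.kind == "1d":
            return np.arange(self.n_cells)
        if self.kind == "2d":
            on_axis = np.flatnonzero(self.coords[:, 0] == 0)
            return on_axis[np.argsort(self.coords[on_axis, 1])]
        # 3D: nearest-to-axis cell per unit height slab
        r = np.hypot(self.coords[:, 0], self.coords[:, 1])
        z = self.coords[:, 2]
        order = []
        for lo in np.arange(np.floor(z.min()), np.ceil(z.max()) + 1):
            band = np.flatnonzero((z >= lo) & (z < lo + 1))
            if band.size:
                order.append(band[np.argmin(r[band])])
        return np.asarray(order, dtype=int)

    def axis_cell(self, y: int) -> int:
        """Index of the axis cell at height ``y`` (2D templates)."""
        hits = np.flatnonzero((self.coords[:, 0] == 0) & (self.coords[:, 1] == y))
        if hits.size != 1:
            raise TemplateError(f"no unique axis cell at y={y}")
        return int(hits[0])

    def is_connected(self) -> bool:
        n, _ = sp.csgraph.connected_components(self.neighbor_weights, directed=False)
        return n == 1

    @property
    def mirror_partner(self) -> np.ndarray:
        """For each mirror-boundary cell, the index of the tissue cell its
        phantom neighbour reflects (the cell one column inward, same row);
        -1 where there is no such cell or the cell is not on the boundary.

        The symmetry axis runs through the x = 0 cell column, so the phantom
        neighbour of an axis cell is the mirror image of its (1, y)
        neighbour and, on a left-right-symmetric field, carries that
        neighbour's value.
        """
        if getattr(self, "_mirror_partner", None) is None:
            partner = np.full(self.n_cells, -1, dtype=int)
            if self.kind == "2d" and self.mirror.any():
                index = {tuple(c): k for k, c in enumerate(self.coords)}
                for k in np.flatnonzero(self.mirror == 1):
                    x, y = self.coords[k]
                    partner[k] = index.get((x + 1, y), -1)
            object.__setattr__(self, "_mirror_partner", partner)
        return self._mirror_partner


@dataclass
class TargetDomains:
    """Binary target expression domains used by the optimisation.

    ``W_t``, ``C_t``, ``H_t`` are {0,1} cell vectors for the WUS, CLV3 and
    HAM targets.  ``c_t`` (the CLV3-peptide gradient produced by ``C_t``) is
    computed during optimisation stage 2 and cached here afterwards.
    """

    W_t: np.ndarray
    C_t: np.ndarray
    H_t: np.ndarray
    c_t: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("W_t", "C_t", "H_t"):
            v = getattr(self, name)
            if not np.isin(v, (0, 1)).all():
                raise TemplateError(f"{name} must be binary")
            if v.sum() == 0:
                raise TemplateError(f"target domain {name} is empty")


def _grid_template(cells: list[tuple[int, int]], inside) -> TissueTemplate:
    """Assemble a 2D template from lattice cells and an inside-predicate."""
    index = {c: k for k, c in enumerate(cells)}
    n = len(cells)
    coords = np.array(cells, dtype=int)
    rows, cols = [], []
    L = np.zeros(n, dtype=int)
    S = np.zeros(n, dtype=int)
    mirror = np.zeros(n, dtype=int)
    for (i, j), k in index.items():
        epidermal = False
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            p = (i + di, j + dj)
            if p in index:
                rows.append(k)
                cols.append(index[p])
            elif p[0] >= 0 and p[1] >= 0 and not inside(*p):
                # neighbour lattice point outside the circle (not below the
                # bottom row, not across the mirror axis): epidermis
                epidermal = True
        if j == 0:
            S[k] = 1
        elif epidermal:
            L[k] = 1  # sink wins at the arc/bottom corner
        if i == 0:
            mirror[k] = 1
    W = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n), dtype=float
    )
    degree = np.asarray(W.sum(axis=1)).ravel() + mirror  # mirror bonus
    return TissueTemplate(
        n_cells=n,
        coords=coords,
        neighbor_weights=W,
        degree=degree,
        volumes=np.ones(n),
        L=L,
        S=S,
        mirror=mirror,
        kind="2d",
    )


def build_2d_template(
    radius: int, shape: str = "dome", width: int | None = None
) -> TissueTemplate:
    """Build the half-disk SAM template.

    ``shape="dome"`` draws a quarter circle centred on the bottom-left grid
    corner; a cell belongs to the tissue when its centre lies strictly within
    the circle.  ``shape="fasciated"`` builds a half stadium: a flat cap of
    ``width`` columns inserted between the mirror axis and a quarter circle
    of the given radius, mimicking the laterally expanded *clavata* meristem.
    The mirror boundary stays on the left edge in both cases.
    """
    if radius < 1:
        raise TemplateError("radius must be >= 1")
    if shape == "dome":
        def inside(i: int, j: int) -> bool:
            return i >= 0 and j >= 0 and i * i + j * j < radius * radius
    elif shape == "fasciated":
        if width is None:
            raise TemplateError("fasciated template requires a cap width")
        if width < 0:
            raise TemplateError("cap width must be >= 0")
        def inside(i: int, j: int) -> bool:
            if i < 0 or j < 0:
                return False
            if i <= width:
                return j < radius
            di = i - width
            return di * di + j * j < radius * radius
    else:
        raise TemplateError(f"unknown template shape {shape!r}")

    imax = radius + (width or 0) + 1
    cells = [
        (i, j)
        for i in range(imax)
        for j in range(radius + 1)
        if inside(i, j)
    ]
    return _grid_template(cells, inside)


def build_1d_template(length: int) -> TissueTemplate:
    """Chain of cells: cell 0 is the sink, the last cell the epidermis."""
    if length < 2:
        raise TemplateError("1D template needs at least 2 cells")
    n = length
    coords = np.stack([np.zeros(n, dtype=int), np.arange(n)], axis=1)
    rows = np.concatenate([np.arange(n - 1), np.arange(1, n)])
    cols = np.concatenate([np.arange(1, n), np.arange(n - 1)])
    W = sp.csr_matrix((np.ones(2 * (n - 1)), (rows, cols)), shape=(n, n))
    L = np.zeros(n, dtype=int)
    S = np.zeros(n, dtype=int)
    S[0] = 1
    L[-1] = 1
    return TissueTemplate(
        n_cells=n,
        coords=coords,
        neighbor_weights=W,
        degree=np.asarray(W.sum(axis=1)).ravel(),
        volumes=np.ones(n),
        L=L,
        S=S,
        mirror=np.zeros(n, dtype=int),
        kind="1d",
    )


def generate_synthetic_3d_template(
    n_cells: int,
    seed: int,
    radius: float = 30.0,
    contact_mu: float = 2.0,
    contact_sigma: float = 0.5,
    volume_mu: float = 0.0,
    volume_sigma: float = 0.3,
) -> TissueTemplate:
    """Synthetic 3D dome template with cell volumes and contact surfaces.

    A stand-in for a confocal-segmented meristem: cell centres are sampled
    inside a half ball of the given radius, adjacency comes from spatial
    proximity (Delaunay edges trimmed to a distance cutoff), and volumes and
    contact areas are drawn from log-normal distributions.  The outermost
    shell is marked L1 and the basal cells the sink.  Deterministic given
    ``seed``; synthetic by construction, it mimics only the graph statistics
    of a real segmentation, not its anatomy.
    """
    if n_cells < 20:
        raise TemplateError("3D template needs at least 20 cells")
    rng = np.random.default_rng(seed)
    # rejection-sample a half ball, slight upward bias for a dome
    pts = []
    while len(pts) < n_cells:
        cand = rng.uniform(-1, 1, size=(4 * n_cells, 3))
        cand[:, 2] = np.abs(cand[:, 2])
        keep = (cand**2).sum(axis=1) < 1.0
        pts.extend(cand[keep].tolist())
    coords = np.array(pts[:n_cells]) * radius

    from scipy.spatial import Delaunay

    tri = Delaunay(coords)
    edges = set()
    for simplex in tri.simplices:
        for a in range(4):
            for b in range(a + 1, 4):
                i, j = sorted((simplex[a], simplex[b]))
                edges.add((i, j))
    # typical cell diameter ~ (total volume / n)^(1/3); drop long Delaunay edges
    cutoff = 2.5 * radius / n_cells ** (1 / 3)
    edges = [
        (i, j)
        for i, j in edges
        if np.linalg.norm(coords[i] - coords[j]) < cutoff
    ]
    if not edges:
        raise TemplateError("3D template generation produced no contacts")
    areas = rng.lognormal(contact_mu, contact_sigma, size=len(edges))
    rows = [e[0] for e in edges] + [e[1] for e in edges]
    cols = [e[1] for e in edges] + [e[0] for e in edges]
    W = sp.csr_matrix(
        (np.concatenate([areas, areas]), (rows, cols)),
        shape=(n_cells, n_cells),
    )
    volumes = rng.lognormal(volume_mu, volume_sigma, size=n_cells)
    r = np.linalg.norm(coords, axis=1)
    L = (r > np.quantile(r, 0.8)).astype(int)
    S = (coords[:, 2] < np.quantile(coords[:, 2], 0.12)).astype(int)
    L[S == 1] = 0
    # make sure the graph is connected: bridge stray components to the core
    ncomp, labels = sp.csgraph.connected_components(W, directed=False)
    if ncomp > 1:
        main = np.argmax(np.bincount(labels))
        W = W.tolil()
        for comp in range(ncomp):
            if comp == main:
                continue
            members = np.flatnonzero(labels == comp)
            core = np.flatnonzero(labels == main)
            d = ((coords[members][:, None, :] - coords[core][None, :, :]) ** 2).sum(-1)
            a, b = np.unravel_index(np.argmin(d), d.shape)
            i, j = members[a], core[b]
            area = float(np.exp(contact_mu))
            W[i, j] = W[j, i] = area
        W = W.tocsr()
    return TissueTemplate(
        n_cells=n_cells,
        coords=coords,
        neighbor_weights=W,
        degree=np.asarray((W > 0).sum(axis=1)).ravel().astype(float),
        volumes=volumes,
        L=L,
        S=S,
        mirror=np.zeros(n_cells, dtype=int),
        kind="3d",
    )


# ---------------------------------------------------------------------------
# target expression domains


@dataclass
class TargetSpec:
    """Geometry of the default binary target domains on a dome template.

    Frozen default approximating the qualitative wild-type layout: a central
    WUS domain at mid depth, surmounted by an apical CLV3 cap, inside a broad
    HAM domain that excludes the outermost cell layers.  Distances are in
    cell units on the radius-30 dome and scale with the template radius.

    The WUS domain is drawn the way the epidermis-driven regulation shapes
    it -- the intersection of "deeper than ``wus_depth`` below the arc" (the
    short-range repressor boundary) and "above height ``wus_min_y``" (the
    sink-depleted long-range activator boundary), L1 excluded.  The CLV3 cap
    is the apical part of the outer shell: cells within ``clv3_depth`` of the
    arc and above height ``clv3_min_y``.  ``ham_margin``: HAM covers cells at
    Euclidean distance below ``R - ham_margin`` from the origin.
    """

    wus_depth: float = 9.0
    wus_min_y: float = 12.0
    clv3_depth: float = 5.0
    clv3_min_y: float = 16.0
    ham_margin: float = 2.0


def make_target_domains(
    template: TissueTemplate, spec: TargetSpec | None = None
) -> TargetDomains:
    """Binary W_t/C_t/H_t domains on a 2D dome (or 3D) template."""
    spec = spec or TargetSpec()
    coords = template.coords.astype(float)
    if template.kind == "3d":
        # axial coordinates: height z and distance from the vertical axis
        x = np.hypot(coords[:, 0], coords[:, 1])
        y = coords[:, 2]
    else:
        x, y = coords[:, 0], coords[:, 1]
    r_out = float(np.hypot(x, y).max())
    scale = r_out / 30.0
    W_t = (
        (np.hypot(x, y) <= r_out - spec.wus_depth * scale)
        & (y >= spec.wus_min_y * scale)
        & (template.L == 0)
    ).astype(int)
    C_t = (
        (np.hypot(x, y) > r_out - spec.clv3_depth * scale)
        & (y >= spec.clv3_min_y * scale)
    ).astype(int)
    H_t = (np.hypot(x, y) < r_out - spec.ham_margin).astype(int)
    for name, v in (("W_t", W_t), ("C_t", C_t), ("H_t", H_t)):
        if v.sum() == 0:
            raise TemplateError(f"degenerate target: {name} is empty")
    return TargetDomains(W_t=W_t, C_t=C_t, H_t=H_t)


# ---------------------------------------------------------------------------
# serialisation: plain TSV with CELLS and EDGES blocks, 0-based indices


def save_template(template: TissueTemplate, path) -> None:
    """Write a template as TSV with CELLS and EDGES header blocks."""
    buf = _io.StringIO()
    dim3 = template.kind == "3d"
    buf.write(f"#KIND\t{template.kind}\n")
    cols = "id\tx\ty" + ("\tz" if dim3 else "") + "\tvolume\tL\tS\tmirror\n"
    buf.write("#CELLS\t" + cols)
    for k in range(template.n_cells):
        xyz = "\t".join(repr(float(v)) for v in template.coords[k])
        buf.write(
            f"{k}\t{xyz}\t{float(template.volumes[k])!r}\t{template.L[k]}"
            f"\t{template.S[k]}\t{template.mirror[k]}\n"
        )
    buf.write("#EDGES\tid_a\tid_b\tweight\n")
    coo = sp.triu(template.neighbor_weights).tocoo()
    for i, j, w in zip(coo.row, coo.col, coo.data):
        buf.write(f"{i}\t{j}\t{float(w)!r}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def load_template(path) -> TissueTemplate:
    """Read a template written by :func:`save_template` (or by hand)."""
    kind = "2d"
    cells: list[list[float]] = []
    vols, Ls, Ss, mirrors = [], [], [], []
    edges: list[tuple[int, int, float]] = []
    section = None
    ncols = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if parts[0] == "#KIND":
                kind = parts[1].strip()
                continue
            if parts[0] == "#CELLS":
                section = "cells"
                ncols = len(parts) - 1
                continue
            if parts[0] == "#EDGES":
                section = "edges"
                continue
            try:
                if section == "cells":
                    if len(parts) != ncols:
                        raise ValueError(
                            f"expected {ncols} columns, got {len(parts)}"
                        )
                    vals = [float(v) for v in parts]
                    coord = vals[1:-4]
                    if kind == "3d" and len(coord) != 3:
                        raise ValueError("3D template cell rows need x, y, z, volume")
                    cells.append(coord)
                    vols.append(vals[-4])
                    Ls.append(int(vals[-3]))
                    Ss.append(int(vals[-2]))
                    mirrors.append(int(vals[-1]))
                elif section == "edges":
                    edges.append((int(parts[0]), int(parts[1]), float(parts[2])))
                else:
                    raise ValueError("data before a #CELLS/#EDGES header")
            except ValueError as exc:
                raise TemplateError(f"{path}: line {lineno}: {exc}") from None
    n = len(cells)
    if n == 0:
        raise TemplateError(f"{path}: no cells found")
    rows = [e[0] for e in edges] + [e[1] for e in edges]
    cols_ = [e[1] for e in edges] + [e[0] for e in edges]
    data = [e[2] for e in edges] * 2
    W = sp.csr_matrix((data, (rows, cols_)), shape=(n, n))
    mirror = np.array(mirrors)
    if kind == "3d":
        degree = np.asarray((W > 0).sum(axis=1)).ravel().astype(float)
    else:
        degree = np.asarray(W.sum(axis=1)).ravel() + mirror
    coords = np.array(cells)
    if kind != "3d":
        coords = coords.astype(int)
    return TissueTemplate(
        n_cells=n,
        coords=coords,
        neighbor_weights=W,
        degree=degree,
        volumes=np.array(vols),
        L=np.array(Ls),
        S=np.array(Ss),
        mirror=mirror,
        kind=kind,
    )


def mirrored_full_template(template: TissueTemplate) -> tuple[TissueTemplate, np.ndarray]:
    """Explicitly mirrored full-disk version of a 2D half template.

    Returns the full template and, for each half-template cell, its index in
    the full template.  Used to validate the zero-flux mirror boundary:
    equilibria of left-right symmetric systems on the full template must
    restrict to the half-template solution.
    """
    if template.kind != "2d":
        raise TemplateError("mirroring is defined for 2D templates")
    cells = [tuple(c) for c in template.coords]
    cellset = set(cells)
    full = sorted(cellset | {(-i, j) for i, j in cells})
    index = {c: k for k, c in enumerate(full)}
    n = len(full)
    rows, cols = [], []
    for (i, j), k in index.items():
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            p = (i + di, j + dj)
            if p in index:
                rows.append(k)
                cols.append(index[p])
    W = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    L = np.zeros(n, dtype=int)
    S = np.zeros(n, dtype=int)
    for (i, j), k in index.items():
        half_idx = cells.index((abs(i), j))
        L[k] = template.L[half_idx]
        S[k] = template.S[half_idx]
    fullt = TissueTemplate(
        n_cells=n,
        coords=np.array(full, dtype=int),
        neighbor_weights=W,
        degree=np.asarray(W.sum(axis=1)).ravel(),
        volumes=np.ones(n),
        L=L,
        S=S,
        mirror=np.zeros(n, dtype=int),
        kind="2d",
    )
    half_to_full = np.array([index[c] for c in cells])
    return fullt, half_to_full
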