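"""Force-based cell removal from the tissue surface.

Surface cells (the highest cell centre in each lateral grid square) feel a
constant vertical removal force; once a cell - or a connected clump of
cells - loses contact with the main tissue body it is culled and logged as
a removal event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .mechanics import CellPopulation, Domain, NeighborList, build_neighbor_lists

try:  # optional fast path for the per-step connectivity check
    from numba import njit as _njit

    @_njit(cache=True)
    def _uf_labels(n, ei, ej):  # pragma: no cover - exercised via main_body_labels
        parent = np.arange(n, dtype=np.int64)
        for k in range(ei.shape[0]):
            a = ei[k]
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            b = ej[k]
            while parent[b] != b:
                parent[b] = parent[parent[b]]
                b = parent[b]
            if a != b:
                if a < b:
                    parent[b] = a
                else:
                    parent[a] = b
        for i in range(n):
            r = i
            while parent[r] != r:
                r = parent[r]
            j = i
            while parent[j] != r:
                nxt = parent[j]
                parent[j] = r
                j = nxt
        return parent

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "DesquamationParams",
    "RemovalEvent",
    "identify_surface_cells",
    "removal_forces",
    "main_body_labels",
    "cull_detached",
]


@dataclass(frozen=True)
class DesquamationParams:
    """Surface grid, removal force and connectivity threshold."""

    dx: float = 1.0           # surface grid size (CD)
    F_D: float = 5.0          # vertical removal force (uN)
    contact_gap: float = 0.7  # boundary gap below which cells are connected (CD)

    def __post_init__(self):
        if self.dx <= 0:
            raise ValueError("dx must be positive")
        if self.F_D < 0:
            raise ValueError("F_D must be non-negative")
        if self.contact_gap <= 0:
            raise ValueError("contact_gap must be positive")

    def validate_domain(self, domain: Domain) -> None:
        for L in (domain.Lx, domain.Ly):
            if abs(round(L / self.dx) - L / self.dx) > 1e-9:
                raise ValueError("dx must divide the domain extents")


@dataclass(frozen=True)
class RemovalEvent:
    """One desquamated cell: identity, timing, location and state at removal."""

    cell_id: int
    time: float
    age: float
    z: float
    s: float
    clump_id: int

    def __post_init__(self):
        if self.age <= 0:
            raise ValueError("age at removal must be positive")


def identify_surface_cells(cells: CellPopulation, domain: Domain, dx: float = 1.0) -> np.ndarray:
    """Indices of the highest cell (by centre) in each occupied grid square."""
    n = cells.n
    if n == 0:
        return np.empty(0, dtype=int)
    pos = domain.wrap(cells.positions[:n])
    nx = max(int(round(domain.Lx / dx)), 1)
    ny = max(int(round(domain.Ly / dx)), 1)
    ix = np.minimum((pos[:, 0] / dx).astype(int), nx - 1)
    iy = np.minimum((pos[:, 1] / dx).astype(int), ny - 1)
    square = ix * ny + iy
    order = np.lexsort((pos[:, 2], square))  # within square, ascending z
    sq_sorted = square[order]
    last = np.nonzero(np.append(sq_sorted[1:] != sq_sorted[:-1], True))[0]
    return np.sort(order[last])


def removal_forces(n_cells: int, surface_ids: np.ndarray, F_D: float) -> np.ndarray:
    """(n, 3) external force array: +z force F_D on each surface cell."""
    out = np.zeros((n_cells, 3))
    if F_D > 0 and len(surface_ids) > 0:
        out[np.asarray(surface_ids, dtype=int), 2] = F_D
    return out


def main_body_labels(
    cells: CellPopulation,
    domain: Domain,
    contact_gap: float = 0.7,
    nlist: NeighborList | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Partition cells into the main tissue body and detached components.

    Two cells are "in contact" when their boundary gap is below
    ``contact_gap`` (periodic minimum image). The main body is the closure
    of the basal seed set: all cells within ``contact_gap`` of the basal
    membrane (z <= radius + contact_gap).

    Returns ``(main_mask, component_labels)``. Raises if no cell touches
    the basal membrane (simulation integrity failure).
    """
    n = cells.n
    if n == 0:
        raise RuntimeError("empty cell population")
    seed = cells.positions[:n, 2] <= cells.radii[:n] + contact_gap
    if not np.any(seed):
        raise RuntimeError("no basal seed cells: tissue detached from the membrane")
    if nlist is None:
        nlist = build_neighbor_lists(cells, domain, cutoff=2.0)
    touching = nlist.gaps < contact_gap
    i = nlist.pairs[touching, 0]
    j = nlist.pairs[touching, 1]
    if _HAVE_NUMBA:
        labels = _uf_labels(n, np.ascontiguousarray(i, dtype=np.int64),
                            np.ascontiguousarray(j, dtype=np.int64))
    else:
        adj = coo_matrix((np.ones(len(i)), (i, j)), shape=(n, n))
        _, labels = connected_components(adj, directed=False)
    main_components = np.unique(labels[seed])
    main_mask = np.isin(labels, main_components)
    return main_mask, labels


def cull_detached(
    cells: CellPopulation,
    main_mask: np.ndarray,
    labels: np.ndarray,
    t: float,
    clump_counter: int = 0,
) -> tuple[list[RemovalEvent], int]:
    """Delete detached cells, returning their removal events.

    Cells removed in the same step that are mutually connected share a
    clump id. Returns ``(events, next_clump_counter)``.
    """
    n = cells.n
    detached = np.nonzero(~main_mask[:n])[0]
    if detached.size == 0:
        return [], clump_counter
    comp_to_clump: dict[int, int] = {}
    events: list[RemovalEvent] = []
    for k in detached:
        comp = int(labels[k])
        if comp not in comp_to_clump:
            comp_to_clump[comp] = clump_counter
            clump_counter += 1
        events.append(RemovalEvent(
            cell_id=int(cells.ids[k]),
            time=t,
            age=float(t - cells.birth_times[k]),
            z=float(cells.positions[k, 2]),
            s=float(cells.chem[k, 1]),
            clump_id=comp_to_clump[comp],
        ))
    cells.remove(detached)
    return events, clump_counter
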