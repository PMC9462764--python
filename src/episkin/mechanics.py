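"""3D overlapping-spheres cell-centre mechanics.

Cells are spheres on a laterally periodic box with a rigid basal plane at
z = 0. Pairwise forces combine a short-range exponential adhesion law and a
logarithmic overlap repulsion; dividing daughter pairs feel a torsional
force that rotates their axis to vertical; positions follow overdamped
forward-Euler dynamics.

Unit system: lengths in cell diameters (CD), forces in uN, times in hours;
the drag coefficient eta is 0.1 uN.hr/CD so the force balance closes
without a CD-to-um conversion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.spatial import cKDTree

from .kinetics import ChemParams, RateConstants, initial_chem_state

__all__ = [
    "MechanicsParams",
    "Domain",
    "Cell",
    "CellPopulation",
    "ProliferationParams",
    "NeighborList",
    "DivisionEvent",
    "build_neighbor_lists",
    "adhesion_shape",
    "adhesion_peak",
    "pair_interaction_force",
    "calibrate_alpha0",
    "adhesion_coefficient",
    "division_rotation_force",
    "attempt_divisions",
    "advance_positions",
    "basal_membrane_forces",
    "dual_cycle_times",
]

STEM = 0
DIFFERENTIATED = 1

# KD-tree boxsize trick: x/y are periodic with the domain, z is padded with a
# huge period so it is effectively non-periodic.
_Z_PERIOD = 1e6


@dataclass(frozen=True)
class MechanicsParams:
    """Force-law and integration parameters (Table-style defaults)."""

    k_rep: float = 150.0          # repulsive spring constant (uN)
    gamma: float = 7.0            # adhesion shape parameter
    alpha_0: float = 374.7        # reference adhesion coefficient (uN)
    F_max: float = 10.0           # target peak pair adhesion force (uN)
    k_phi: float = 100.0          # torsional spring constant (uN)
    eta: float = 0.1              # drag coefficient (uN.hr/CD)
    dt: float = 1.0 / 120.0       # time step (hr; 30 s)
    R_0: float = 0.5              # normal cell radius (CD)
    neighbour_cutoff: float = 2.0  # centre-distance cutoff (CD)

    @property
    def c_shape(self) -> float:
        return 1.0 / (2.0 * self.gamma)

    def __post_init__(self):
        for name in ("k_rep", "gamma", "alpha_0", "F_max", "k_phi", "eta", "dt",
                     "R_0", "neighbour_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class Domain:
    """Laterally periodic box of extent Lx x Ly (CD), basal plane at z = 0."""

    Lx: float = 10.0
    Ly: float = 10.0

    def validate(self, cutoff: float) -> None:
        if min(self.Lx, self.Ly) < 2.0 * cutoff:
            raise ValueError("domain must span at least twice the neighbour cutoff")

    def wrap(self, positions: np.ndarray) -> np.ndarray:
        out = positions.copy()
        out[..., 0] %= self.Lx
        out[..., 1] %= self.Ly
        return out

    def min_image(self, disp: np.ndarray) -> np.ndarray:
        out = disp.copy()
        out[..., 0] -= self.Lx * np.round(out[..., 0] / self.Lx)
        out[..., 1] -= self.Ly * np.round(out[..., 1] / self.Ly)
        return out


@dataclass
class Cell:
    """Record view of one cell (convenience type for tests and snapshots)."""

    id: int
    position: np.ndarray
    radius: float
    type: int
    birth_time: float
    T_C: float
    i_T_level: float
    chem: np.ndarray
    is_surface: bool = False
    partner: int | None = None


class CellPopulation:
    """Structure-of-arrays container for the cell population.

    Arrays are kept contiguous over live cells; removals compact the
    arrays. ``ids`` are unique and never reused within a simulation.
    """

    def __init__(self, capacity: int = 256):
        self._n = 0
        self._next_id = 0
        self.version = 0  # bumped on every add/remove (invalidates pair caches)
        cap = max(capacity, 16)
        self.ids = np.zeros(cap, dtype=np.int64)
        self.positions = np.zeros((cap, 3))
        self.radii = np.zeros(cap)
        self.types = np.zeros(cap, dtype=np.int8)
        self.birth_times = np.zeros(cap)
        self.cycle_times = np.zeros(cap)
        self.i_T_levels = np.zeros(cap)
        self.chem = np.zeros((cap, 6))
        self.is_surface = np.zeros(cap, dtype=bool)
        self.partners = np.full(cap, -1, dtype=np.int64)  # division twin id
        self.division_end = np.zeros(cap)  # time at which post-division growth ends
        self.corneum_entry = np.full(cap, np.nan)  # first time z crossed the corneum base

    def __len__(self) -> int:
        return self._n

    @property
    def n(self) -> int:
        return self._n

    def _grow(self, need: int) -> None:
        cap = len(self.ids)
        if self._n + need <= cap:
            return
        new_cap = max(2 * cap, self._n + need)
        for name in ("ids", "positions", "radii", "types", "birth_times",
                     "cycle_times", "i_T_levels", "chem", "is_surface",
                     "partners", "division_end", "corneum_entry"):
            arr = getattr(self, name)
            shape = (new_cap,) + arr.shape[1:]
            new = np.zeros(shape, dtype=arr.dtype)
            if name == "partners":
                new[:] = -1
            if name == "corneum_entry":
                new[:] = np.nan
            new[: self._n] = arr[: self._n]
            setattr(self, name, new)

    def add(self, position, radius, cell_type, birth_time, T_C, i_T_level,
            chem, partner: int = -1, division_end: float = 0.0) -> int:
        self._grow(1)
        k = self._n
        cid = self._next_id
        self._next_id += 1
        self.ids[k] = cid
        self.positions[k] = position
        self.radii[k] = radius
        self.types[k] = cell_type
        self.birth_times[k] = birth_time
        self.cycle_times[k] = T_C
        self.i_T_levels[k] = i_T_level
        self.chem[k] = chem
        self.is_surface[k] = False
        self.partners[k] = partner
        self.division_end[k] = division_end
        self.corneum_entry[k] = np.nan
        self._n += 1
        self.version += 1
        return cid

    def remove(self, indices) -> None:
        """Remove cells by array index (not id)."""
        if len(indices) == 0:
            return
        keep = np.ones(self._n, dtype=bool)
        keep[np.asarray(indices, dtype=int)] = False
        m = int(keep.sum())
        for name in ("ids", "positions", "radii", "types", "birth_times",
                     "cycle_times", "i_T_levels", "chem", "is_surface",
                     "partners", "division_end", "corneum_entry"):
            arr = getattr(self, name)
            arr[:m] = arr[: self._n][keep]
        self._n = m
        self.version += 1

    def index_of(self, cid: int) -> int:
        idx = np.nonzero(self.ids[: self._n] == cid)[0]
        if idx.size == 0:
            raise KeyError(f"no live cell with id {cid}")
        return int(idx[0])

    def view(self, k: int) -> Cell:
        partner = int(self.partners[k])
        return Cell(
            id=int(self.ids[k]),
            position=self.positions[k].copy(),
            radius=float(self.radii[k]),
            type=int(self.types[k]),
            birth_time=float(self.birth_times[k]),
            T_C=float(self.cycle_times[k]),
            i_T_level=float(self.i_T_levels[k]),
            chem=self.chem[k].copy(),
            is_surface=bool(self.is_surface[k]),
            partner=None if partner < 0 else partner,
        )

    def cells(self) -> list[Cell]:
        return [self.view(k) for k in range(self._n)]

    @property
    def stem_mask(self) -> np.ndarray:
        return self.types[: self._n] == STEM

    @property
    def s_levels(self) -> np.ndarray:
        return self.chem[: self._n, 1]


@dataclass(frozen=True)
class ProliferationParams:
    """Stem-cell cycle-time distribution.

    ``single`` mode draws T_C ~ U(cycle_low, cycle_high); ``dual`` mode
    assigns a fraction of stems the fast cycle T_1 and the rest the slow
    cycle T_1 + dT_C (fixed values, matched to a target harmonic mean).
    """

    cycle_low: float = 13.0
    cycle_high: float = 17.0
    population_mode: str = "single"
    T_1: float | None = None
    dT_C: float | None = None
    fraction_fast: float = 0.5

    def __post_init__(self):
        if self.population_mode not in ("single", "dual"):
            raise ValueError("population_mode must be 'single' or 'dual'")
        if self.population_mode == "single":
            if not 0 < self.cycle_low <= self.cycle_high:
                raise ValueError("require 0 < cycle_low <= cycle_high")
        else:
            if self.T_1 is None or self.dT_C is None:
                raise ValueError("dual mode requires T_1 and dT_C")
            if self.T_1 <= 0 or self.dT_C < 0:
                raise ValueError("require T_1 > 0 and dT_C >= 0")
        if not 0.0 <= self.fraction_fast <= 1.0:
            raise ValueError("fraction_fast must be in [0, 1]")

    def draw_cycle(self, rng: np.random.Generator, fast: bool | None = None) -> float:
        if self.population_mode == "single":
            return float(rng.uniform(self.cycle_low, self.cycle_high))
        if fast is None:
            fast = bool(rng.random() < self.fraction_fast)
        return float(self.T_1 if fast else self.T_1 + self.dT_C)


def dual_cycle_times(harmonic_mean: float, dT_C: float) -> tuple[float, float]:
    """Fast/slow cycle pair (T_1, T_1 + dT_C) with the requested harmonic mean
    for a 50:50 split."""
    if harmonic_mean <= 0 or dT_C < 0:
        raise ValueError("harmonic_mean must be positive and dT_C non-negative")
    # 2 / (1/T1 + 1/(T1+dT)) = H  ->  (2/H) T1^2 + (2 dT/H - 2) T1 - dT = 0
    a = 2.0 / harmonic_mean
    b = 2.0 * dT_C / harmonic_mean - 2.0
    c = -dT_C
    t1 = (-b + np.sqrt(b * b - 4 * a * c)) / (2 * a)
    return float(t1), float(t1 + dT_C)


# ---------------------------------------------------------------------------
# Neighbour search and pair forces
# ---------------------------------------------------------------------------

@dataclass
class NeighborList:
    """Symmetric pair list with minimum-image geometry.

    ``pairs[k] = (i, j)`` are array indices with i < j; ``gaps[k]`` is the
    boundary gap ||c_j - c_i|| - (R_i + R_j); ``units[k]`` the unit vector
    from i to j.
    """

    pairs: np.ndarray
    gaps: np.ndarray
    units: np.ndarray

    def __len__(self) -> int:
        return len(self.pairs)


def build_neighbor_lists(
    cells: CellPopulation,
    domain: Domain,
    cutoff: float = 2.0,
    rng: np.random.Generator | None = None,
) -> NeighborList:
    """All pairs within ``cutoff`` centre distance under lateral periodicity.

    Coincident centres get a unit vector drawn from ``rng`` (seeded random
    direction) so the repulsion still separates them.
    """
    domain.validate(cutoff)
    n = cells.n
    if n < 2:
        return NeighborList(np.empty((0, 2), dtype=int), np.empty(0), np.empty((0, 3)))
    pos = domain.wrap(cells.positions[:n])
    boxed = pos.copy()
    tree = cKDTree(boxed, boxsize=[domain.Lx, domain.Ly, _Z_PERIOD])
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    if pairs.size == 0:
        return NeighborList(np.empty((0, 2), dtype=int), np.empty(0), np.empty((0, 3)))
    disp = domain.min_image(pos[pairs[:, 1]] - pos[pairs[:, 0]])
    dist = np.linalg.norm(disp, axis=1)
    units = np.zeros_like(disp)
    ok = dist > 1e-12
    units[ok] = disp[ok] / dist[ok, None]
    if not np.all(ok):
        if rng is None:
            rng = np.random.default_rng(0)
        n_bad = int((~ok).sum())
        v = rng.normal(size=(n_bad, 3))
        units[~ok] = v / np.linalg.norm(v, axis=1, keepdims=True)
    gaps = dist - (cells.radii[pairs[:, 0]] + cells.radii[pairs[:, 1]])
    return NeighborList(pairs=pairs, gaps=gaps, units=units)


def adhesion_shape(r_star, gamma: float = 7.0):
    """Dimensionless adhesion profile g(r*) for boundary gap r* = r/R_0 > 0.

    g(r*) = (r* + c) exp(-gamma (r* + c)^2) - c exp(-gamma (r*^2 + c^2)),
    with c = 1/(2 gamma): zero at contact, a single positive peak at finite
    separation, decaying to zero at large gaps.
    """
    c = 1.0 / (2.0 * gamma)
    r = np.asarray(r_star, dtype=float)
    return (r + c) * np.exp(-gamma * (r + c) ** 2) - c * np.exp(-gamma * (r * r + c * c))


def adhesion_peak(gamma: float = 7.0) -> tuple[float, float]:
    """(g_max, r*_max): peak value and location of the adhesion profile."""
    res = minimize_scalar(lambda r: -adhesion_shape(r, gamma), bounds=(1e-6, 2.0),
                          method="bounded", options={"xatol": 1e-10})
    return float(-res.fun), float(res.x)


def pair_interaction_force(r_ij, alpha_ij, params: MechanicsParams):
    """Signed pair-force magnitude along the axis from i to j.

    Positive values attract (adhesion branch, boundary gap r_ij > 0);
    negative values repel (logarithmic branch, r_ij < 0); the force is
    continuous (zero) at contact. Total overlap (r_ij <= -1 CD) is a hard
    error. Vectorised over ``r_ij`` and ``alpha_ij``.
    """
    r = np.asarray(r_ij, dtype=float)
    if np.any(r <= -2.0 * params.R_0):
        raise ValueError("total overlap: boundary gap <= -1 CD")
    alpha = np.asarray(alpha_ij, dtype=float)
    out = np.where(
        r > 0,
        alpha * adhesion_shape(np.maximum(r, 0.0) / params.R_0, params.gamma),
        params.k_rep * np.log1p(np.minimum(r, 0.0)),
    )
    if np.isscalar(r_ij):
        return float(out)
    return out


def calibrate_alpha0(F_max: float, gamma: float = 7.0) -> float:
    """Adhesion coefficient alpha_0 giving peak pair force exactly F_max."""
    if F_max <= 0:
        raise ValueError("F_max must be positive")
    g_max, _ = adhesion_peak(gamma)
    return F_max / g_max


def adhesion_coefficient(s_i, s_j, alpha_0: float):
    """Pair adhesion coefficient alpha_ij = (s_i + s_j)/2 * alpha_0."""
    return 0.5 * (np.asarray(s_i) + np.asarray(s_j)) * alpha_0


def division_rotation_force(pos_i, pos_j, k_phi: float) -> np.ndarray:
    """Torsional force on daughter ``i`` of a dividing pair.

    The force has magnitude k_phi * phi (phi: angle between the vertical and
    the inter-daughter axis) directed along -n_hat, where n_hat is the
    component of the vertical unit vector perpendicular to the axis. The
    partner receives the opposite force, so the pair rotates to vertical with
    ``j`` uppermost. Returns zero when the axis is already vertical.
    """
    r = np.asarray(pos_j, dtype=float) - np.asarray(pos_i, dtype=float)
    norm = np.linalg.norm(r)
    if norm < 1e-12:
        return np.zeros(3)
    rhat = r / norm
    k = np.array([0.0, 0.0, 1.0])
    perp = k - rhat * rhat[2]  # k - (k.rhat) rhat
    pnorm = np.linalg.norm(perp)
    if pnorm < 1e-10:
        return np.zeros(3)
    n_hat = perp / pnorm
    phi = float(np.arccos(np.clip(rhat[2], -1.0, 1.0)))
    return -k_phi * phi * n_hat


@dataclass(frozen=True)
class DivisionEvent:
    parent_id: int
    daughter_id: int
    time: float
    position: np.ndarray


# Post-division growth: daughters start at half size and grow linearly back
# to R_0 over this many hours.
GROWTH_DURATION = 1.0
DAUGHTER_OFFSET = 0.3


def attempt_divisions(
    cells: CellPopulation,
    t: float,
    rng: np.random.Generator,
    prolif: ProliferationParams,
    chem_params: ChemParams | None = None,
    rates: RateConstants | None = None,
    R_0: float = 0.5,
) -> list[DivisionEvent]:
    """Divide every stem cell whose age has reached its cycle time.

    Each division is asymmetric: the stem stays in place (clock reset, new
    cycle drawn) and one differentiated daughter is placed DAUGHTER_OFFSET CD
    away along a random upward-hemisphere direction. The daughter inherits
    the stem's i_T level; its chemistry is set to the quasi-equilibrium
    initial state for that inhibitor level. Both members of the pair restart
    at half radius and grow back over GROWTH_DURATION; the rotational force
    stays active while they remain marked as partners.
    """
    n = cells.n
    ages = t - cells.birth_times[:n]
    ready = np.nonzero((cells.types[:n] == STEM) & (ages >= cells.cycle_times[:n]))[0]
    events: list[DivisionEvent] = []
    for k in ready:
        direction = rng.normal(size=3)
        direction[2] = abs(direction[2])
        nrm = np.linalg.norm(direction)
        if nrm < 1e-12:
            direction = np.array([0.0, 0.0, 1.0])
            nrm = 1.0
        direction /= nrm
        pos_d = cells.positions[k] + DAUGHTER_OFFSET * direction
        i_T = float(cells.i_T_levels[k])
        if chem_params is not None and rates is not None:
            p = ChemParams(s_0=chem_params.s_0, e_T=chem_params.e_T, i_T=i_T)
            chem0 = initial_chem_state(p, rates).as_array()
        else:
            chem0 = np.array([0.0, 1.0, 0.0, 0.0, 0.0, 0.0])
        stem_id = int(cells.ids[k])
        # dual mode: daughters are not proliferative, only stems carry cycles;
        # the stem keeps its fast/slow class by redrawing from its own value.
        if prolif.population_mode == "dual":
            fast = bool(abs(cells.cycle_times[k] - prolif.T_1) < 1e-9)
            new_tc = prolif.draw_cycle(rng, fast=fast)
        else:
            new_tc = prolif.draw_cycle(rng)
        d_id = cells.add(
            position=pos_d,
            radius=0.5 * R_0,
            cell_type=DIFFERENTIATED,
            birth_time=t,
            T_C=np.inf,
            i_T_level=i_T,
            chem=chem0,
            partner=stem_id,
            division_end=t + GROWTH_DURATION,
        )
        # reset the stem
        cells.birth_times[k] = t
        cells.cycle_times[k] = new_tc
        cells.radii[k] = 0.5 * R_0
        cells.partners[k] = d_id
        cells.division_end[k] = t + GROWTH_DURATION
        events.append(DivisionEvent(parent_id=stem_id, daughter_id=d_id, time=t,
                                    position=pos_d.copy()))
    return events


def update_division_state(cells: CellPopulation, t: float, R_0: float = 0.5,
                          pair_release_distance: float = 1.0,
                          domain: Domain | None = None) -> None:
    """Grow post-division radii and release partner pairs.

    Radii grow linearly from R_0/2 back to R_0 over GROWTH_DURATION. A pair
    is released (rotational force switched off) once the centre distance
    reaches ``pair_release_distance`` and growth has completed.
    """
    n = cells.n
    growing = cells.division_end[:n] > t
    frac = np.clip(1.0 - (cells.division_end[:n] - t) / GROWTH_DURATION, 0.0, 1.0)
    cells.radii[:n] = np.where(growing, 0.5 * R_0 * (1.0 + frac), R_0)
    lower, upper = _partner_indices(cells)
    if lower.size == 0:
        return
    d = cells.positions[upper] - cells.positions[lower]
    if domain is not None:
        d = domain.min_image(d)
    release = (np.linalg.norm(d, axis=1) >= pair_release_distance) \
        & ~growing[lower] & ~growing[upper]
    cells.partners[lower[release]] = -1
    cells.partners[upper[release]] = -1


def basal_membrane_forces(cells: CellPopulation, params: MechanicsParams,
                          alpha_plane: float | None = None) -> np.ndarray:
    """Vertical forces from the rigid basal plane at z = 0.

    Every cell overlapping the plane (z < radius) is repelled by the same
    logarithmic law used between cells. Stem cells additionally adhere to
    the plane through the pair adhesion profile, which keeps the
    proliferative population basal.
    """
    n = cells.n
    gap = cells.positions[:n, 2] - cells.radii[:n]
    fz = np.zeros(n)
    below = gap < 0
    if np.any(below):
        fz[below] = -params.k_rep * np.log1p(np.maximum(gap[below], -0.99))
    if alpha_plane is None:
        alpha_plane = calibrate_alpha0(params.F_max, params.gamma)
    stems = (cells.types[:n] == STEM) & (gap > 0)
    if np.any(stems):
        g = adhesion_shape(gap[stems] / params.R_0, params.gamma)
        fz[stems] = -alpha_plane * g  # pulls stems back towards the plane
    out = np.zeros((n, 3))
    out[:, 2] = fz
    return out


def advance_positions(
    cells: CellPopulation,
    net_forces: np.ndarray,
    eta: float,
    dt: float,
    domain: Domain,
    max_step: float = 1.0,
) -> None:
    """Overdamped forward-Euler position update, in place.

    Displacements are F dt / eta; lateral coordinates wrap, z is floored at
    zero (the basal plane is rigid). A displacement above ``max_step`` CD in
    one step aborts with the offending cell named.
    """
    n = cells.n
    if net_forces.shape != (n, 3):
        raise ValueError("net_forces must be (n, 3)")
    disp = net_forces * (dt / eta)
    mags = np.linalg.norm(disp, axis=1)
    worst = int(np.argmax(mags)) if n else 0
    if n and mags[worst] > max_step:
        raise RuntimeError(
            f"mechanics instability: cell id {int(cells.ids[worst])} moved "
            f"{mags[worst]:.3f} CD in one step (force {net_forces[worst]})"
        )
    cells.positions[:n] += disp
    cells.positions[:n] = domain.wrap(cells.positions[:n])
    np.maximum(cells.positions[:n, 2], 0.0, out=cells.positions[:n, 2])


def assemble_pair_forces(
    cells: CellPopulation,
    nlist: NeighborList,
    params: MechanicsParams,
    alpha_0: float,
) -> np.ndarray:
    """Net force on every cell from the pair interaction law.

    Adhesion coefficients are scaled by the mean remaining substrate of the
    pair. Newton's third law holds by construction.
    """
    n = cells.n
    forces = np.zeros((n, 3))
    if len(nlist) == 0:
        return forces
    i, j = nlist.pairs[:, 0], nlist.pairs[:, 1]
    s = cells.s_levels
    alpha = adhesion_coefficient(s[i], s[j], alpha_0)
    mag = pair_interaction_force(nlist.gaps, alpha, params)
    fvec = mag[:, None] * nlist.units
    for c in range(3):
        forces[:, c] = np.bincount(i, weights=fvec[:, c], minlength=n)
        forces[:, c] -= np.bincount(j, weights=fvec[:, c], minlength=n)
    return forces


def _partner_indices(cells: CellPopulation) -> tuple[np.ndarray, np.ndarray]:
    """(lower, upper) index arrays of the live division pairs, one entry per
    pair, with the stem (or the first-listed cell) as 'lower'. Relies on cell
    ids being strictly increasing in array order."""
    n = cells.n
    paired = np.nonzero(cells.partners[:n] >= 0)[0]
    if paired.size == 0:
        return paired, paired
    ids = cells.ids[:n]
    pidx = np.searchsorted(ids, cells.partners[paired])
    valid = (pidx < n)
    valid[valid] &= ids[pidx[valid]] == cells.partners[paired[valid]]
    # drop dangling partners (twin already removed)
    dangling = paired[~valid]
    if dangling.size:
        cells.partners[dangling] = -1
    paired, pidx = paired[valid], pidx[valid]
    first = paired < pidx  # each pair appears twice; keep one orientation
    k, j = paired[first], pidx[first]
    # orient stems (or the elder cell) as 'lower'
    swap = (cells.types[j] == STEM) & (cells.types[k] != STEM)
    lower = np.where(swap, j, k)
    upper = np.where(swap, k, j)
    return lower, upper


def assemble_rotation_forces(cells: CellPopulation, params: MechanicsParams,
                             domain: Domain | None = None) -> np.ndarray:
    """Torsional forces for currently paired daughter cells (vectorised)."""
    n = cells.n
    forces = np.zeros((n, 3))
    lower, upper = _partner_indices(cells)
    if lower.size == 0:
        return forces
    r = cells.positions[upper] - cells.positions[lower]
    if domain is not None:
        r = domain.min_image(r)
    norm = np.linalg.norm(r, axis=1)
    ok = norm > 1e-12
    rhat = np.zeros_like(r)
    rhat[ok] = r[ok] / norm[ok, None]
    perp = -rhat * rhat[:, 2:3]
    perp[:, 2] += 1.0  # k - (k.rhat) rhat
    pnorm = np.linalg.norm(perp, axis=1)
    ok &= pnorm > 1e-10
    phi = np.arccos(np.clip(rhat[:, 2], -1.0, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(ok[:, None], -params.k_phi * phi[:, None] * perp / pnorm[:, None], 0.0)
    for c in range(3):
        forces[:, c] += np.bincount(lower, weights=f[:, c], minlength=n)
        forces[:, c] -= np.bincount(upper, weights=f[:, c], minlength=n)
    return forces
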