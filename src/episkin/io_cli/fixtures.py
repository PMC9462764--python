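"""Deterministic toy states for tests and examples."""

from __future__ import annotations

import zlib

import numpy as np

from ..coupling import CouplingConfig, ModelParams, SimulationState, initialize_tissue
from ..kinetics import initial_chem_state
from ..mechanics import DIFFERENTIATED, STEM, CellPopulation, Domain

__all__ = ["FIXTURE_NAMES", "make_fixture"]

FIXTURE_NAMES = ("single-cell", "chain-gap", "column-block", "mini-tissue")


def _fresh_chem(mp: ModelParams, i_T: float) -> np.ndarray:
    from ..kinetics import ChemParams

    if mp.chem.e_T == 0:
        return np.array([0.0, 1.0, 0.0, 0.0, 0.0, 0.0])
    p = ChemParams(s_0=mp.chem.s_0, e_T=mp.chem.e_T, i_T=i_T)
    return initial_chem_state(p, mp.rates).as_array()


def make_fixture(name: str, seed: int = 0, mp: ModelParams | None = None) -> SimulationState:
    """Build a named deterministic toy state.

    * ``single-cell``: one stem at the domain centre.
    * ``chain-gap``: a 5-cell vertical chain with one 0.9-CD boundary gap.
    * ``column-block``: a 2x2 block of 6-cell columns.
    * ``mini-tissue``: a 5x5 domain pre-filled to 8 CD.
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    if mp is None:
        mp = ModelParams(domain=Domain(5.0, 5.0),
                         coupling=CouplingConfig(seed=seed, fill_ceiling=8.0))
    rng = np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))

    if name == "mini-tissue":
        return initialize_tissue(mp, np.random.SeedSequence([seed, 0]))

    cells = CellPopulation()
    R0 = mp.mechanics.R_0
    i_T = mp.inhibitor_fraction * mp.chem.e_T
    chem = _fresh_chem(mp, i_T)

    def add(pos, ctype):
        cells.add(position=np.asarray(pos, dtype=float), radius=R0, cell_type=ctype,
                  birth_time=0.0, T_C=np.inf if ctype == DIFFERENTIATED else 15.0,
                  i_T_level=i_T, chem=chem.copy())

    cx, cy = mp.domain.Lx / 2, mp.domain.Ly / 2
    if name == "single-cell":
        add([cx, cy, R0], STEM)
    elif name == "chain-gap":
        # boundary gaps: 0.5, 0.5, 0.9, 0.5 (centre spacings gap + 1)
        z = R0
        add([cx, cy, z], STEM)
        for gap in (0.5, 0.5, 0.9, 0.5):
            z += gap + 2 * R0
            add([cx, cy, z], DIFFERENTIATED)
    elif name == "column-block":
        for ix in range(2):
            for iy in range(2):
                x, y = ix + 0.5, iy + 0.5
                add([x, y, R0], STEM)
                for k in range(1, 6):
                    add([x, y, R0 + 0.95 * k], DIFFERENTIATED)

    state = SimulationState(cells=cells, rng=rng)
    state.refresh_thickness(mp)
    state.refresh_surface(mp)
    return state
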