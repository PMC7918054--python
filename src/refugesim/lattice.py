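"""The cellular automaton: lattice state, neighbourhood census, update rules.

The lattice is toroidal (periodic boundaries); each cell is one cotton plant
and holds at most one larval cohort of either species.  One time step is one
insect generation, updated synchronously from the previous generation's state.

Update rules
------------
An *occupied* cell empties through three sequential hazards: natural
mortality / dispersal (``NM``); insecticide mortality (``IM``) for
susceptible occupants during a spray; and competition mortality
``theta = 1 - s``, where the stage survival ``s`` is read from the
high- or low-density payoff matrix (high iff the occupied fraction of the
8 Moore neighbours reaches the threshold ``T``), in the intraspecific column
or — with probability equal to the competitor's neighbourhood share — the
interspecific column.

An *empty* cell is colonised by oviposition from the neighbouring cohorts.
Each species' odds are its share of the neighbourhood's expected adult
reproductive output (cohorts x reproductive capacity x expected stage
survival), scaled by adult emergence ``AE``; species 1 (S. frugiperda) is
tested first.  During a spray generation only the expected insecticide
survivors contribute offspring, which is what makes a spray suppress the
susceptible species' recruitment and lets a resistant species take over.

Randomness contract
-------------------
Every generation consumes one uniform(0,1) draw table of shape
``(rows, cols, 4)``.  A cell uses its four slots positionally:

* occupied cell: (0) natural mortality / dispersal, (1) insecticide,
  (2) competitor encounter, (3) competition survival;
* empty cell: (0) species-1 oviposition, (1) species-2 oviposition,
  (2) resistance inheritance; slot 3 is unused.

The vectorised :func:`step_from_draws` and the naive per-cell
:func:`reference_step_from_draws` consume the same table identically, so they
produce bit-identical next lattices — the per-cell path is the testing oracle
for the array path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParams, ParameterError, PayoffMatrices, Scenario, Species

__all__ = [
    "CellState",
    "NeighborCensus",
    "Lattice",
    "init_lattice",
    "census_neighborhood",
    "select_density_matrix",
    "encounter_probability",
    "competition_survival",
    "expected_stage_survival",
    "contributing_cohorts",
    "colonization_probabilities",
    "occupied_update",
    "colonization_update",
    "occupied_fate_from_draws",
    "colonize_from_draws",
    "neighbor_count_arrays",
    "step",
    "step_from_draws",
    "reference_step_from_draws",
]

EMPTY = Species.EMPTY
SF = Species.SF
HA = Species.HA

_MOORE_OFFSETS = [
    (dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)
]


@dataclass(frozen=True)
class CellState:
    """One plant: its occupant (if any) and the occupant's resistance phenotype."""

    occupant: Species = Species.EMPTY
    resistant: bool = False

    def __post_init__(self) -> None:
        if self.occupant == Species.EMPTY and self.resistant:
            raise ParameterError("an empty cell cannot carry a resistance flag")


@dataclass(frozen=True)
class NeighborCensus:
    """Occupancy counts over the 8-cell Moore neighbourhood of a focal cell."""

    n_sf: int = 0
    n_ha: int = 0
    r_sf: int = 0
    r_ha: int = 0

    def __post_init__(self) -> None:
        ok = (
            0 <= self.r_sf <= self.n_sf
            and 0 <= self.r_ha <= self.n_ha
            and self.n_sf + self.n_ha <= 8
        )
        if not ok:
            raise ParameterError(f"inconsistent neighbourhood census: {self}")

    @property
    def n_occupied(self) -> int:
        return self.n_sf + self.n_ha


class Lattice:
    """Toroidal grid of cell states.

    Internally two arrays: ``occ`` (int8 occupancy codes, see
    :class:`~refugesim.params.Species`) and ``res`` (bool resistance flags,
    False wherever empty).
    """

    def __init__(self, occ: np.ndarray, res: np.ndarray | None = None):
        occ = np.asarray(occ, dtype=np.int8)
        if occ.ndim != 2 or occ.shape[0] < 3 or occ.shape[1] < 3:
            raise ParameterError(f"lattice must be 2-D and at least 3x3, got {occ.shape}")
        if not np.isin(occ, (0, 1, 2)).all():
            raise ParameterError("occupancy codes must be 0 (empty), 1 (SF) or 2 (HA)")
        if res is None:
            res = np.zeros(occ.shape, dtype=bool)
        res = np.asarray(res, dtype=bool)
        if res.shape != occ.shape:
            raise ParameterError("resistance array shape must match occupancy array")
        if (res & (occ == 0)).any():
            raise ParameterError("empty cells cannot carry resistance flags")
        self.occ = occ
        self.res = res

    @property
    def rows(self) -> int:
        return self.occ.shape[0]

    @property
    def cols(self) -> int:
        return self.occ.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.occ.shape

    @classmethod
    def empty(cls, rows: int, cols: int) -> "Lattice":
        return cls(np.zeros((rows, cols), dtype=np.int8))

    def counts(self) -> tuple[int, int]:
        """(N_sf, N_ha) occupancy counts over the whole lattice."""
        return int((self.occ == SF).sum()), int((self.occ == HA).sum())

    def resistant_counts(self) -> tuple[int, int]:
        return (
            int(((self.occ == SF) & self.res).sum()),
            int(((self.occ == HA) & self.res).sum()),
        )

    def cell(self, r: int, c: int) -> CellState:
        return CellState(Species(int(self.occ[r, c])), bool(self.res[r, c]))

    def copy(self) -> "Lattice":
        return Lattice(self.occ.copy(), self.res.copy())

    def equals(self, other: "Lattice") -> bool:
        return np.array_equal(self.occ, other.occ) and np.array_equal(
            self.res, other.res
        )

    def __repr__(self) -> str:
        n_sf, n_ha = self.counts()
        return f"<Lattice {self.rows}x{self.cols}: {n_sf} SF, {n_ha} HA>"


# ---------------------------------------------------------------------------
# initialisation
# ---------------------------------------------------------------------------

def init_lattice(
    rows: int,
    cols: int,
    params: ModelParams,
    scenario: Scenario = Scenario.NO_SPRAY,
    rng: np.random.Generator | int | None = None,
) -> Lattice:
    """Place ``params.IF`` individuals of each species uniformly at random.

    Cells are drawn without replacement; the first ``IF`` positions receive
    S. frugiperda, the next ``IF`` H. armigera.  For each species flagged
    resistant in ``scenario`` (SF drawn first), every individual is
    independently resistant with probability ``params.RF``.
    """
    rng = np.random.default_rng(rng)
    n = rows * cols
    if 2 * params.IF > n:
        raise ParameterError(
            f"cannot place 2*{params.IF} individuals on {rows}x{cols} cells"
        )
    occ = np.zeros(n, dtype=np.int8)
    if params.IF > 0:
        pos = rng.choice(n, size=2 * params.IF, replace=False)
        occ[pos[: params.IF]] = SF
        occ[pos[params.IF:]] = HA
    occ = occ.reshape(rows, cols)
    res = np.zeros((rows, cols), dtype=bool)
    if params.resistance_model == "tracked" and params.IF > 0:
        for sp in (SF, HA):
            if sp in scenario.resistant_species:
                mask = occ == sp
                res[mask] = rng.random(params.IF) < params.RF
    return Lattice(occ, res)


# ---------------------------------------------------------------------------
# per-cell (scalar) operations — the reference semantics
# ---------------------------------------------------------------------------

def census_neighborhood(lat: Lattice, r: int, c: int) -> NeighborCensus:
    """Count the 8 toroidal Moore neighbours of cell (r, c); focal excluded."""
    if not (0 <= r < lat.rows and 0 <= c < lat.cols):
        raise IndexError(f"cell ({r}, {c}) outside {lat.rows}x{lat.cols} lattice")
    n_sf = n_ha = r_sf = r_ha = 0
    for dr, dc in _MOORE_OFFSETS:
        rr = (r + dr) % lat.rows
        cc = (c + dc) % lat.cols
        o = lat.occ[rr, cc]
        if o == SF:
            n_sf += 1
            r_sf += int(lat.res[rr, cc])
        elif o == HA:
            n_ha += 1
            r_ha += int(lat.res[rr, cc])
    return NeighborCensus(n_sf, n_ha, r_sf, r_ha)


def select_density_matrix(census: NeighborCensus, T: float) -> str:
    """``"H"`` when the occupied-neighbour fraction reaches the threshold T."""
    return "H" if census.n_occupied / 8.0 >= T else "L"


def encounter_probability(census: NeighborCensus, focal: Species) -> float:
    """Probability of meeting the competitor: its Moore-neighbourhood share."""
    n_other = census.n_ha if focal == SF else census.n_sf
    return n_other / 8.0


def competition_survival(
    focal: Species,
    matrix_id: str,
    encountered: bool,
    matrices: PayoffMatrices,
) -> float:
    """Stage survival from the selected payoff matrix; theta = 1 - survival."""
    return matrices.survival(focal, encountered, high_density=(matrix_id == "H"))


def expected_stage_survival(
    census: NeighborCensus, params: ModelParams
) -> tuple[float, float]:
    """Expected stage survival (s_sf, s_ha) of the neighbouring cohorts.

    Averages each species' intra- and interspecific survival at the focal
    cell's density state, weighting the interspecific entry by the joint
    local presence of both species ((n_sf/8) * (n_ha/8)) — interspecific
    encounters are rare unless both competitors are locally dense.
    """
    high = census.n_occupied / 8.0 >= params.T
    m = params.matrices.H if high else params.matrices.L
    e = (census.n_sf / 8.0) * (census.n_ha / 8.0)
    s_sf = (1.0 - e) * m[0, 0] + e * m[0, 1]
    s_ha = (1.0 - e) * m[1, 1] + e * m[1, 0]
    return float(s_sf), float(s_ha)


def contributing_cohorts(
    census: NeighborCensus,
    params: ModelParams,
    spray_active: bool,
    scenario: Scenario = Scenario.NO_SPRAY,
) -> tuple[float, float]:
    """Expected numbers of neighbouring cohorts that parent the next generation.

    Without a spray every occupied neighbour contributes.  During a spray a
    killed cohort leaves no offspring, so contributions shrink to the expected
    insecticide survivors: resistant cohorts plus a fraction ``1 - IM`` of the
    susceptible ones.
    """
    if not spray_active:
        return float(census.n_sf), float(census.n_ha)
    if params.resistance_model == "immune":
        m_sf = census.n_sf * (1.0 if SF in scenario.resistant_species else 1.0 - params.IM)
        m_ha = census.n_ha * (1.0 if HA in scenario.resistant_species else 1.0 - params.IM)
        return m_sf, m_ha
    m_sf = census.r_sf + (census.n_sf - census.r_sf) * (1.0 - params.IM)
    m_ha = census.r_ha + (census.n_ha - census.r_ha) * (1.0 - params.IM)
    return m_sf, m_ha


def colonization_probabilities(
    census: NeighborCensus,
    params: ModelParams,
    spray_active: bool = False,
    scenario: Scenario = Scenario.NO_SPRAY,
) -> tuple[float, float, float]:
    """Oviposition probabilities (f1, f2) and overall colonisation w.

    Each species' odds are its share of the neighbourhood's expected adult
    reproductive output — contributing cohorts x reproductive capacity x
    expected stage survival — scaled by adult emergence.  Species 1 is tested
    first, so w = f1 + (1 - f1) * f2.
    """
    m_sf, m_ha = contributing_cohorts(census, params, spray_active, scenario)
    s_sf, s_ha = expected_stage_survival(census, params)
    w1 = m_sf * params.Ro_Sf * s_sf
    w2 = m_ha * params.Ro_Ha * s_ha
    tot = w1 + w2
    if tot <= 0:
        return 0.0, 0.0, 0.0
    f1 = params.AE * w1 / tot
    f2 = params.AE * w2 / tot
    return f1, f2, f1 + (1.0 - f1) * f2


def _susceptible(state: CellState, params: ModelParams, scenario: Scenario) -> bool:
    if params.resistance_model == "immune":
        return state.occupant not in scenario.resistant_species
    return not state.resistant


def occupied_update(
    state: CellState,
    census: NeighborCensus,
    params: ModelParams,
    spray_active: bool,
    draws,
    scenario: Scenario = Scenario.NO_SPRAY,
) -> CellState:
    """Fate of an occupied cell given four ordered uniform draws.

    Draw order: natural mortality, insecticide, encounter, competition.  The
    cell empties if natural mortality strikes; otherwise, during a spray, a
    susceptible occupant dies with probability IM; otherwise competition
    mortality theta = 1 - s applies, with s read from the density-selected
    payoff matrix in the (randomly realised) encounter context.
    """
    if state.occupant == EMPTY:
        raise ParameterError("occupied_update called on an empty cell")
    d_nm, d_im, d_enc, d_comp = draws[0], draws[1], draws[2], draws[3]
    if d_nm < params.NM:
        return CellState()
    if spray_active and _susceptible(state, params, scenario) and d_im < params.IM:
        return CellState()
    encountered = d_enc < encounter_probability(census, state.occupant)
    matrix_id = select_density_matrix(census, params.T)
    s = competition_survival(state.occupant, matrix_id, encountered, params.matrices)
    if d_comp < 1.0 - s:
        return CellState()
    return state


def colonization_update(
    census: NeighborCensus,
    params: ModelParams,
    draws,
    spray_active: bool = False,
    scenario: Scenario = Scenario.NO_SPRAY,
) -> CellState:
    """Fate of an empty cell: oviposition by species 1, else species 2.

    Draw order: species-1 oviposition, species-2 oviposition, resistance
    inheritance.  A colonist of species i is resistant with probability equal
    to the resistant fraction among the contributing species-i cohorts.
    """
    f1, f2, _ = colonization_probabilities(census, params, spray_active, scenario)
    m_sf, m_ha = contributing_cohorts(census, params, spray_active, scenario)
    if draws[0] < f1:
        p_res = census.r_sf / m_sf if m_sf > 0 else 0.0
        return CellState(SF, bool(draws[2] < p_res))
    if draws[1] < f2:
        p_res = census.r_ha / m_ha if m_ha > 0 else 0.0
        return CellState(HA, bool(draws[2] < p_res))
    return CellState()


# ---------------------------------------------------------------------------
# vectorised kernels
# ---------------------------------------------------------------------------

def neighbor_count_arrays(lat: Lattice) -> tuple[np.ndarray, ...]:
    """(n_sf, n_ha, r_sf, r_ha) Moore-neighbour counts for every cell at once."""
    layers = (
        (lat.occ == SF).astype(np.int16),
        (lat.occ == HA).astype(np.int16),
        ((lat.occ == SF) & lat.res).astype(np.int16),
        ((lat.occ == HA) & lat.res).astype(np.int16),
    )
    out = []
    for a in layers:
        s = np.zeros_like(a)
        for dr, dc in _MOORE_OFFSETS:
            s += np.roll(np.roll(a, dr, axis=0), dc, axis=1)
        out.append(s)
    return tuple(out)


def occupied_fate_from_draws(
    occ: np.ndarray,
    res: np.ndarray,
    n_sf: np.ndarray,
    n_ha: np.ndarray,
    params: ModelParams,
    scenario: Scenario,
    spray_active: bool,
    draws: np.ndarray,
) -> np.ndarray:
    """Boolean array: True where an occupied cell empties this generation.

    Vector counterpart of :func:`occupied_update`; entries where ``occ`` is
    empty are meaningless and must be masked by the caller.  Because the three
    lethal events use independent positional draws, the sequential else-if
    structure reduces to a logical OR of the raw conditions.
    """
    nm_die = draws[..., 0] < params.NM
    if spray_active:
        if params.resistance_model == "immune":
            susceptible = np.ones(occ.shape, dtype=bool)
            for sp in scenario.resistant_species:
                susceptible &= occ != sp
        else:
            susceptible = ~res
        spray_die = susceptible & (draws[..., 1] < params.IM)
    else:
        spray_die = np.zeros(occ.shape, dtype=bool)
    n_other = np.where(occ == SF, n_ha, n_sf)
    encountered = draws[..., 2] < n_other / 8.0
    i = np.clip(occ.astype(np.intp) - 1, 0, 1)
    j = np.where(encountered, 1 - i, i)
    s = np.where(
        (n_sf + n_ha) / 8.0 >= params.T,
        params.matrices.H[i, j],
        params.matrices.L[i, j],
    )
    comp_die = draws[..., 3] < 1.0 - s
    return nm_die | spray_die | comp_die


def colonize_from_draws(
    n_sf: np.ndarray,
    n_ha: np.ndarray,
    r_sf: np.ndarray,
    r_ha: np.ndarray,
    params: ModelParams,
    scenario: Scenario,
    spray_active: bool,
    draws: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """(new_occ, new_res) for empty cells; vector form of colonization_update."""
    if spray_active:
        if params.resistance_model == "immune":
            k_sf = 1.0 if SF in scenario.resistant_species else 1.0 - params.IM
            k_ha = 1.0 if HA in scenario.resistant_species else 1.0 - params.IM
            m_sf = n_sf * k_sf
            m_ha = n_ha * k_ha
        else:
            m_sf = r_sf + (n_sf - r_sf) * (1.0 - params.IM)
            m_ha = r_ha + (n_ha - r_ha) * (1.0 - params.IM)
    else:
        m_sf = n_sf.astype(float)
        m_ha = n_ha.astype(float)
    high = (n_sf + n_ha) / 8.0 >= params.T
    e = (n_sf / 8.0) * (n_ha / 8.0)
    M = params.matrices
    s_sf = np.where(high, (1 - e) * M.H[0, 0] + e * M.H[0, 1],
                    (1 - e) * M.L[0, 0] + e * M.L[0, 1])
    s_ha = np.where(high, (1 - e) * M.H[1, 1] + e * M.H[1, 0],
                    (1 - e) * M.L[1, 1] + e * M.L[1, 0])
    w1 = m_sf * params.Ro_Sf * s_sf
    w2 = m_ha * params.Ro_Ha * s_ha
    tot = w1 + w2
    safe = np.where(tot > 0, tot, 1.0)
    f1 = np.where(tot > 0, params.AE * w1 / safe, 0.0)
    f2 = np.where(tot > 0, params.AE * w2 / safe, 0.0)
    sf_new = draws[..., 0] < f1
    ha_new = ~sf_new & (draws[..., 1] < f2)
    p_res = np.zeros(n_sf.shape, dtype=float)
    np.divide(r_sf, m_sf, out=p_res, where=(m_sf > 0) & sf_new)
    np.divide(r_ha, m_ha, out=p_res, where=(m_ha > 0) & ha_new)
    new_occ = np.where(sf_new, np.int8(SF), np.where(ha_new, np.int8(HA), np.int8(0)))
    new_res = (sf_new | ha_new) & (draws[..., 2] < p_res)
    return new_occ, new_res


# ---------------------------------------------------------------------------
# synchronous generation step
# ---------------------------------------------------------------------------

def step_from_draws(
    lat: Lattice,
    params: ModelParams,
    scenario: Scenario,
    spray_active: bool,
    draws: np.ndarray,
) -> Lattice:
    """Synchronous update of every cell from a shared draw table."""
    if draws.shape != lat.shape + (4,):
        raise ParameterError(
            f"draw table must have shape {lat.shape + (4,)}, got {draws.shape}"
        )
    n_sf, n_ha, r_sf, r_ha = neighbor_count_arrays(lat)
    occupied = lat.occ != EMPTY

    die = occupied_fate_from_draws(
        lat.occ, lat.res, n_sf, n_ha, params, scenario, spray_active, draws
    )
    col_occ, col_res = colonize_from_draws(
        n_sf, n_ha, r_sf, r_ha, params, scenario, spray_active, draws
    )

    new_occ = np.where(occupied, np.where(die, np.int8(0), lat.occ), col_occ)
    new_res = np.where(occupied, np.where(die, False, lat.res), col_res)
    return Lattice(new_occ, new_res)


def step(
    lat: Lattice,
    params: ModelParams,
    scenario: Scenario = Scenario.NO_SPRAY,
    spray_active: bool = False,
    rng: np.random.Generator | int | None = None,
) -> Lattice:
    """One generation: draw the table from ``rng`` and update synchronously."""
    rng = np.random.default_rng(rng)
    draws = rng.random(lat.shape + (4,))
    return step_from_draws(lat, params, scenario, spray_active, draws)


def reference_step_from_draws(
    lat: Lattice,
    params: ModelParams,
    scenario: Scenario,
    spray_active: bool,
    draws: np.ndarray,
) -> Lattice:
    """Naive double-loop update used as the brute-force oracle for step()."""
    new_occ = np.zeros(lat.shape, dtype=np.int8)
    new_res = np.zeros(lat.shape, dtype=bool)
    for r in range(lat.rows):
        for c in range(lat.cols):
            census = census_neighborhood(lat, r, c)
            state = lat.cell(r, c)
            if state.occupant == EMPTY:
                nxt = colonization_update(
                    census, params, draws[r, c], spray_active, scenario
                )
            else:
                nxt = occupied_update(
                    state, census, params, spray_active, draws[r, c], scenario
                )
            new_occ[r, c] = nxt.occupant
            new_res[r, c] = nxt.resistant
    return Lattice(new_occ, new_res)
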