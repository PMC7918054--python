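"""Core parameter types for the refuge-competition cellular automaton.

The simulator models two lepidopteran pests competing for cotton plants in a
non-Bt refuge: *Spodoptera frugiperda* (species 1, ``SF``) and *Helicoverpa
armigera* (species 2, ``HA``).  Each lattice cell is one plant holding at most
one surviving larval cohort.  Stage survival under competition is encoded in
two 2x2 payoff matrices (one per neighbourhood-density state); all remaining
demographic rates live on :class:`ModelParams`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum, IntEnum

import numpy as np

__all__ = [
    "Species",
    "Scenario",
    "PayoffMatrices",
    "ModelParams",
    "ParameterError",
    "MATRIX_H_ALTERNATE",
]


class ParameterError(ValueError):
    """Raised when a parameter set violates its domain constraints."""


class Species(IntEnum):
    """Cell occupancy codes: empty plant, S. frugiperda, H. armigera."""

    EMPTY = 0
    SF = 1
    HA = 2


class Scenario(str, Enum):
    """The five insecticide / resistance management scenarios.

    ``NO_SPRAY``        no insecticide use in the refuge;
    ``SPRAY_NO_RES``    insecticide triggered at the control level, no
                        resistant individuals in either species;
    ``SPRAY_SF_RES``    insecticide use with S. frugiperda carrying resistant
                        individuals at the initial resistant frequency;
    ``SPRAY_HA_RES``    as above for H. armigera;
    ``SPRAY_BOTH_RES``  both species carry resistant individuals.
    """

    NO_SPRAY = "no_spray"
    SPRAY_NO_RES = "spray_no_res"
    SPRAY_SF_RES = "spray_sf_res"
    SPRAY_HA_RES = "spray_ha_res"
    SPRAY_BOTH_RES = "spray_both_res"

    @property
    def insecticide_enabled(self) -> bool:
        return self is not Scenario.NO_SPRAY

    @property
    def resistant_species(self) -> frozenset[Species]:
        return _RESISTANT[self]


_RESISTANT = {
    Scenario.NO_SPRAY: frozenset(),
    Scenario.SPRAY_NO_RES: frozenset(),
    Scenario.SPRAY_SF_RES: frozenset({Species.SF}),
    Scenario.SPRAY_HA_RES: frozenset({Species.HA}),
    Scenario.SPRAY_BOTH_RES: frozenset({Species.SF, Species.HA}),
}

# Default stage-survival payoff matrices, row 0 = SF, row 1 = HA; column j is
# the interaction context (j == row: intraspecific only; j != row: encounter
# with the competitor).  L applies below the density threshold T, H at or
# above it.
_DEFAULT_L = ((0.63, 0.58), (0.46, 0.90))
_DEFAULT_H = ((0.31, 0.11), (0.38, 0.16))

# Alternate high-density matrix quoted in the worked rule example (same index
# convention): SF intra 0.48 / inter 0.18, HA intra 0.22 / inter 0.47.
MATRIX_H_ALTERNATE = ((0.48, 0.18), (0.47, 0.22))


@dataclass(frozen=True)
class PayoffMatrices:
    """Stage-survival probabilities conditioned on density state and encounter.

    ``s[i][j]`` is the probability that a larval cohort of focal species ``i``
    (0 = SF, 1 = HA) survives the larval stage in interaction context ``j``:
    the diagonal is intraspecific competition only, the off-diagonal an
    interspecific encounter.  ``H`` applies in the high-density neighbourhood
    state, ``L`` in the low-density state.  Competition mortality is
    ``theta = 1 - s``.
    """

    H: np.ndarray = field(default_factory=lambda: np.array(_DEFAULT_H))
    L: np.ndarray = field(default_factory=lambda: np.array(_DEFAULT_L))

    def __post_init__(self) -> None:
        for name in ("H", "L"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != (2, 2):
                raise ParameterError(f"{name} must be a 2x2 matrix, got {m.shape}")
            if np.any(m < 0) or np.any(m > 1):
                raise ParameterError(f"{name} entries must lie in [0, 1]: {m}")
            object.__setattr__(self, name, m)

    def survival(self, focal: Species, encountered: bool, high_density: bool) -> float:
        """Stage-survival probability for ``focal`` in the given context."""
        i = int(focal) - 1
        j = 1 - i if encountered else i
        m = self.H if high_density else self.L
        return float(m[i, j])

    def swap_species(self) -> "PayoffMatrices":
        """Matrices with the two species' roles exchanged (for symmetry tests)."""
        flip = lambda m: m[::-1, ::-1]
        return PayoffMatrices(H=flip(self.H), L=flip(self.L))

    # Flat alpha/beta naming used by config files: alpha = low density,
    # beta = high density; first index focal species, second context.
    def to_flat(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for prefix, m in (("alpha", self.L), ("beta", self.H)):
            for i in range(2):
                for j in range(2):
                    out[f"{prefix}{i + 1}{j + 1}"] = float(m[i, j])
        return out

    @classmethod
    def from_flat(cls, flat: dict[str, float]) -> "PayoffMatrices":
        L = np.array(_DEFAULT_L)
        H = np.array(_DEFAULT_H)
        for prefix, m in (("alpha", L), ("beta", H)):
            for i in range(2):
                for j in range(2):
                    key = f"{prefix}{i + 1}{j + 1}"
                    if key in flat:
                        m[i, j] = float(flat[key])
        return cls(H=H, L=L)


@dataclass
class ModelParams:
    """Full parameter set of the automaton.

    Parameters
    ----------
    AE : float
        Adult emergence probability; scales both species' oviposition odds.
    T : float
        Density-state threshold, as a fraction of the 8 Moore neighbours that
        must be occupied for the high-density payoff matrix to apply.
    CL : float
        Control level: fraction of *all* lattice cells that one species must
        occupy to trigger an insecticide application.
    Ro_Sf, Ro_Ha : float
        Reproductive capacity (viable neonates per female) of each species.
    NM : float
        Per-generation probability of natural mortality or dispersal out of
        the refuge (mu).
    IM : float
        Insecticide-induced mortality of susceptible larvae per application.
    RF : float
        Initial frequency of insecticide-resistant individuals in a resistant
        species (Hardy-Weinberg derived).
    IF : int
        Initial number of individuals of each species.
    matrices : PayoffMatrices
        Stage-survival payoff matrices.
    rows, cols : int
        Lattice dimensions (toroidal).
    steps : int
        Number of generations to simulate.
    resistance_model : str
        ``"tracked"`` (default): a per-individual resistance phenotype is
        drawn at initialisation with probability ``RF`` and inherited by
        colonists with probability equal to the resistant fraction among
        same-species neighbours.  ``"immune"``: every individual of a
        resistant species ignores the insecticide.
    """

    AE: float = 0.86
    T: float = 0.50
    CL: float = 0.20
    Ro_Sf: float = 400.00
    Ro_Ha: float = 725.06
    NM: float = 0.25
    IM: float = 0.99
    RF: float = 0.0625
    IF: int = 500
    matrices: PayoffMatrices = field(default_factory=PayoffMatrices)
    rows: int = 1000
    cols: int = 1000
    steps: int = 80
    resistance_model: str = "tracked"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("AE", "T", "CL", "NM", "IM", "RF"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        if self.Ro_Sf <= 0 or self.Ro_Ha <= 0:
            raise ParameterError("reproductive capacities Ro_Sf, Ro_Ha must be > 0")
        if self.rows < 3 or self.cols < 3:
            raise ParameterError(
                "lattice must be at least 3x3 for a radius-1 Moore neighbourhood"
            )
        if self.IF < 0 or 2 * self.IF > self.rows * self.cols:
            raise ParameterError(
                f"need 2*IF <= rows*cols cells, got IF={self.IF} on "
                f"{self.rows}x{self.cols}"
            )
        if self.steps < 0:
            raise ParameterError("steps must be >= 0")
        if self.resistance_model not in ("tracked", "immune"):
            raise ParameterError(
                f"resistance_model must be 'tracked' or 'immune', "
                f"got {self.resistance_model!r}"
            )

    def replace(self, **changes) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    # -- flat (config-file) representation -------------------------------
    def to_flat(self) -> dict:
        out = {
            "AE": self.AE,
            "T": self.T,
            "CL": self.CL,
            "Ro_Sf": self.Ro_Sf,
            "Ro_Ha": self.Ro_Ha,
            "NM": self.NM,
            "IM": self.IM,
            "RF": self.RF,
            "IF": self.IF,
            "rows": self.rows,
            "cols": self.cols,
            "steps": self.steps,
            "resistance_model": self.resistance_model,
        }
        out.update(self.matrices.to_flat())
        return out

    @classmethod
    def from_flat(cls, flat: dict) -> "ModelParams":
        matrices = PayoffMatrices.from_flat(flat)
        kwargs = {
            k: v
            for k, v in flat.items()
            if k in _SCALAR_KEYS
        }
        unknown = set(flat) - _SCALAR_KEYS - set(matrices.to_flat())
        if unknown:
            raise ParameterError(f"unknown parameter key(s): {sorted(unknown)}")
        return cls(matrices=matrices, **kwargs)


_SCALAR_KEYS = {
    "AE", "T", "CL", "Ro_Sf", "Ro_Ha", "NM", "IM", "RF", "IF",
    "rows", "cols", "steps", "resistance_model",
}
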