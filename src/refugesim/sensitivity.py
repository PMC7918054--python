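"""PCA-based global sensitivity analysis of the simulator.

Factors are perturbed over uniform ranges (by default the published +/-25%
bands), the simulator is run over a two-level factorial — or an orthogonal
Hadamard fraction of it — with replicate seeds, and the multivariate output
(both species' dominance trajectories) is reduced by a single PCA.  Each
factor's main-effect ANOVA share of every retained component score, weighted
by the component's inertia, yields the generalized sensitivity index (GSI).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import hadamard
from sklearn.decomposition import PCA

from .params import ModelParams, ParameterError, PayoffMatrices, Scenario
from .scenarios import run_scenario

__all__ = [
    "ParameterRanges",
    "GsiResult",
    "sample_design",
    "apply_factors",
    "run_ensemble",
    "compute_gsi",
    "plot_gsi",
]

# Probability-type factors whose perturbed ranges are clipped to [0, 1].
_PROB_FACTORS = frozenset(
    {"AE", "CL", "NM"}
    | {f"{p}{i}{j}" for p in ("alpha", "beta") for i in (1, 2) for j in (1, 2)}
)

# Published uniform perturbation bands (+/-25% of the default value, with
# probabilities capped at 1).  The density threshold T is deliberately absent.
_DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "AE": (0.65, 1.00),
    "CL": (0.15, 0.25),
    "Ro_Ha": (543.80, 965.33),
    "Ro_Sf": (300.00, 500.00),
    "NM": (0.19, 0.31),
    "IF": (375, 625),
    "alpha11": (0.47, 0.79),
    "alpha12": (0.44, 0.73),
    "alpha21": (0.35, 0.58),
    "alpha22": (0.68, 1.00),
    "beta11": (0.23, 0.39),
    "beta12": (0.08, 0.14),
    "beta21": (0.29, 0.48),
    "beta22": (0.12, 0.18),
}

_META_COLS = ("replicate", "run_seed")


@dataclass(frozen=True)
class ParameterRanges:
    """Lower/upper perturbation bounds per factor."""

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_BOUNDS)
    )

    def __post_init__(self) -> None:
        if not self.bounds:
            raise ParameterError("ParameterRanges needs at least one factor")
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ParameterError(f"factor {name}: need lower < upper, got ({lo}, {hi})")
            if name in _PROB_FACTORS and (lo < 0 or hi > 1):
                raise ParameterError(f"factor {name}: probability bounds must lie in [0, 1]")

    @property
    def factors(self) -> list[str]:
        return list(self.bounds)

    @classmethod
    def from_rate(cls, params: ModelParams, rate: float = 0.25) -> "ParameterRanges":
        """Bands of +/-``rate`` around the given parameter values, clipped."""
        flat = params.to_flat()
        bounds = {}
        for name in _DEFAULT_BOUNDS:
            v = float(flat[name])
            lo, hi = v * (1 - rate), v * (1 + rate)
            if name in _PROB_FACTORS:
                lo, hi = max(lo, 0.0), min(hi, 1.0)
            bounds[name] = (lo, hi)
        return cls(bounds)


def sample_design(
    ranges: ParameterRanges,
    levels: int = 2,
    replicates: int = 1,
    seed: int | None = None,
    design: str = "full",
) -> pd.DataFrame:
    """Design table: one simulator parameterisation + run seed per row.

    ``design="full"`` crosses ``levels`` equally spaced values per factor;
    ``design="hadamard"`` takes an orthogonal two-level fraction (resolution
    III: main effects mutually orthogonal) whose run count is the smallest
    power of two exceeding the factor count.  Each design point is replicated
    ``replicates`` times with distinct seeds spawned from ``seed``.
    """
    factors = ranges.factors
    if design == "full":
        if levels < 1:
            raise ParameterError("levels must be >= 1")
        grids = [np.linspace(lo, hi, levels) if levels > 1 else [lo]
                 for lo, hi in (ranges.bounds[f] for f in factors)]
        points = np.array(list(itertools.product(*grids)))
    elif design == "hadamard":
        if levels != 2:
            raise ParameterError("the Hadamard fraction is a two-level design")
        n = 1
        while n < len(factors) + 1:
            n *= 2
        Hmat = hadamard(n)[:, 1 : len(factors) + 1]  # drop the all-ones column
        lows = np.array([ranges.bounds[f][0] for f in factors])
        highs = np.array([ranges.bounds[f][1] for f in factors])
        points = np.where(Hmat > 0, highs, lows)
    else:
        raise ParameterError(f"unknown design {design!r}; use 'full' or 'hadamard'")

    ss = np.random.SeedSequence(seed)
    run_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                 ss.spawn(len(points) * replicates)]
    rows = []
    k = 0
    for point in points:
        for rep in range(replicates):
            row = dict(zip(factors, point))
            row["replicate"] = rep
            row["run_seed"] = run_seeds[k]
            k += 1
            rows.append(row)
    return pd.DataFrame(rows)


def apply_factors(base: ModelParams, row: pd.Series | dict) -> ModelParams:
    """A parameter set with the design row's factor values substituted in."""
    flat = base.to_flat()
    for name, value in dict(row).items():
        if name in _META_COLS:
            continue
        if name not in flat:
            raise ParameterError(f"unknown factor {name!r}")
        flat[name] = int(round(value)) if name in ("IF", "rows", "cols", "steps") else float(value)
    return ModelParams.from_flat(flat)


def run_ensemble(
    design: pd.DataFrame,
    base: ModelParams,
    scenario: Scenario = Scenario.NO_SPRAY,
    output_spec: str = "dominance",
    progress: bool = False,
) -> np.ndarray:
    """Run the simulator once per design row.

    Returns a (runs x outputs) matrix; row r concatenates the two species'
    trajectories at generations 1..steps of design row r, in design order.
    ``output_spec`` selects the series: relative ``"dominance"`` (default),
    ``"abundance"`` counts, or ``"both"`` concatenated.  Failed runs abort
    with the offending row attached rather than being dropped.
    """
    if design.empty:
        raise ParameterError("design table is empty")
    if output_spec not in ("dominance", "abundance", "both"):
        raise ParameterError(f"unknown output_spec {output_spec!r}")
    outputs = []
    iterator = design.iterrows()
    if progress:
        from tqdm import tqdm  # type: ignore

        iterator = tqdm(iterator, total=len(design))
    for idx, row in iterator:
        try:
            params = apply_factors(base, row)
            res = run_scenario(params, scenario, seed=int(row["run_seed"]))
        except Exception as exc:
            raise RuntimeError(f"simulation failed for design row {idx}: "
                               f"{dict(row)}") from exc
        dom = np.concatenate([res.dominance[1:, 0], res.dominance[1:, 1]])
        ab = np.concatenate([res.abundance[1:, 0], res.abundance[1:, 1]]).astype(float)
        if output_spec == "dominance":
            outputs.append(dom)
        elif output_spec == "abundance":
            outputs.append(ab)
        else:
            outputs.append(np.concatenate([ab, dom]))
    return np.vstack(outputs)


@dataclass
class GsiResult:
    """Generalized sensitivity indices and their per-component decomposition."""

    gsi: pd.Series                      # factor -> GSI in [0, 1]
    component_indices: pd.DataFrame     # factors x retained components
    inertia: np.ndarray                 # inertia share of each retained component
    n_runs: int
    n_components: int
    meta: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        """Factors in decreasing GSI order with the per-component indices."""
        out = self.component_indices.copy()
        out.insert(0, "GSI", self.gsi)
        return out.sort_values("GSI", ascending=False)

    def ranking(self) -> list[str]:
        return list(self.gsi.sort_values(ascending=False).index)


def compute_gsi(
    outputs: np.ndarray,
    design: pd.DataFrame,
    n_components: float | int = 0.95,
    scale: bool = False,
) -> GsiResult:
    """Inertia-weighted main-effect sensitivity indices from one PCA.

    The output matrix is centred (and optionally scaled to unit column
    variance), decomposed by PCA, and components are retained up to the given
    cumulative-inertia fraction (or an explicit count).  On each component's
    scores a one-way main-effect ANOVA per factor gives the component index
    SS_factor / SS_total; the GSI is the inertia-weighted mean of those
    indices over the retained components.
    """
    outputs = np.asarray(outputs, dtype=float)
    factors = [c for c in design.columns if c not in _META_COLS]
    if outputs.shape[0] != len(design):
        raise ParameterError("outputs rows must align with design rows")
    if outputs.shape[0] <= len(factors):
        raise ParameterError(
            f"need more runs ({outputs.shape[0]}) than factors ({len(factors)})"
        )
    col_var = outputs.var(axis=0)
    if np.all(col_var == 0):
        raise ParameterError(
            f"all output columns are constant (columns {list(range(outputs.shape[1]))})"
        )
    X = outputs - outputs.mean(axis=0)
    if scale:
        sd = np.sqrt(col_var)
        X = X / np.where(sd > 0, sd, 1.0)

    pca = PCA()
    scores = pca.fit_transform(X)
    ratios = pca.explained_variance_ratio_
    if isinstance(n_components, int) and n_components >= 1:
        k = min(n_components, scores.shape[1])
    else:
        k = int(np.searchsorted(np.cumsum(ratios), float(n_components)) + 1)
        k = min(k, scores.shape[1])
    inertia = ratios[:k]

    comp_idx = np.zeros((len(factors), k))
    for ci in range(k):
        y = scores[:, ci]
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot == 0:
            continue
        for fi, f in enumerate(factors):
            comp_idx[fi, ci] = _main_effect_share(design[f].to_numpy(), y, ss_tot)

    weights = inertia / inertia.sum()
    gsi = comp_idx @ weights
    cols = [f"PC{i + 1}" for i in range(k)]
    return GsiResult(
        gsi=pd.Series(gsi, index=factors, name="GSI"),
        component_indices=pd.DataFrame(comp_idx, index=factors, columns=cols),
        inertia=inertia,
        n_runs=outputs.shape[0],
        n_components=k,
        meta={"scale": scale},
    )


def _main_effect_share(levels: np.ndarray, y: np.ndarray, ss_tot: float) -> float:
    """Between-level sum of squares of y over its total sum of squares."""
    gm = y.mean()
    ss = 0.0
    for v in np.unique(levels):
        sel = y[levels == v]
        ss += sel.size * (sel.mean() - gm) ** 2
    return ss / ss_tot


def plot_gsi(result: GsiResult, ax=None):
    """Bar chart of the generalized sensitivity indices, largest first."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ordered = result.gsi.sort_values(ascending=False)
    ax.bar(ordered.index, ordered.to_numpy())
    ax.set_ylabel("generalized sensitivity index")
    ax.tick_params(axis="x", rotation=60)
    return ax
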