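"""Binomial survival GLMs from competition trials, and payoff-matrix assembly.

The field design emulated here is a randomized block design: each species is
reared on caged non-Bt cotton plants either in isolation (intraspecific
competition only) or combined with the competitor, at per-species densities of
5, 10, 15 and 20 larvae per plant, across four blocks.  Stage survival is
modelled as binomial with a logit-linear density effect, fitted per
(species, setting) stratum by maximum likelihood.  Predictions at the low- and
high-density reference points (5 and 20 larvae per plant) populate the
automaton's payoff matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit

from .params import ParameterError, PayoffMatrices, Species

__all__ = [
    "Setting",
    "CompetitionTrial",
    "GlmFit",
    "FittingError",
    "fit_survival_model",
    "fit_all_strata",
    "predict_survival",
    "build_payoff_matrices",
    "generate_field_data",
    "bootstrap_block_uncertainty",
    "matrix_truth_coefficients",
    "read_trials",
    "write_trials",
    "trials_to_dataframe",
    "trials_from_dataframe",
]

DENSITY_LOW = 5
DENSITY_HIGH = 20
DEFAULT_DENSITIES = (5, 10, 15, 20)
DEFAULT_BLOCKS = 4


class FittingError(RuntimeError):
    """Raised when a survival GLM cannot be estimated from the data."""


class Setting(str, Enum):
    ISOLATED = "isolated"   # intraspecific competition only
    COMBINED = "combined"   # intra- + interspecific competition


@dataclass(frozen=True)
class CompetitionTrial:
    """One plant-level record of a competition trial.

    ``density`` is the per-species infestation (larvae per plant);
    ``n_initial`` larvae were placed, ``n_surviving`` were alive at the
    evaluation.
    """

    species: Species
    setting: Setting
    density: int
    block: int
    n_initial: int
    n_surviving: int

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ParameterError("density must be a positive integer")
        if not (0 <= self.n_surviving <= self.n_initial):
            raise ParameterError(
                f"need 0 <= n_surviving <= n_initial, got "
                f"{self.n_surviving}/{self.n_initial}"
            )


@dataclass(frozen=True)
class GlmFit:
    """A fitted logit-linear survival curve for one (species, setting) stratum."""

    species: Species
    setting: Setting
    intercept: float
    slope: float
    cov: np.ndarray  # 2x2 covariance of (intercept, slope)
    n_obs: int

    def predict(self, density) -> np.ndarray | float:
        """Survival probability at the given density (inverse-logit)."""
        return expit(self.intercept + self.slope * np.asarray(density, dtype=float))

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm

        se = float(np.sqrt(self.cov[1, 1]))
        z = norm.ppf(0.5 + level / 2.0)
        return self.slope - z * se, self.slope + z * se

    @classmethod
    def from_coefficients(
        cls, species: Species, setting: Setting, intercept: float, slope: float
    ) -> "GlmFit":
        """A fit object from known coefficients (no data, zero covariance)."""
        return cls(species, setting, intercept, slope, np.zeros((2, 2)), 0)

    @classmethod
    def from_survival_pair(
        cls,
        species: Species,
        setting: Setting,
        s_low: float,
        s_high: float,
        low_density: float = DENSITY_LOW,
        high_density: float = DENSITY_HIGH,
    ) -> "GlmFit":
        """The unique logit-linear curve through two (density, survival) points."""
        lo, hi = logit(s_low), logit(s_high)
        slope = (hi - lo) / (high_density - low_density)
        return cls.from_coefficients(
            species, setting, lo - slope * low_density, slope
        )


def fit_survival_model(
    trials: list[CompetitionTrial],
    species: Species,
    setting: Setting,
) -> GlmFit:
    """Maximum-likelihood binomial GLM of survival on density (logit link).

    Raises :class:`FittingError` when the stratum has fewer than two distinct
    densities with larvae, or when the responses are completely separated
    (e.g. every larva survived), leaving the MLE undefined.
    """
    rows = [
        t for t in trials
        if t.species == species and t.setting == setting and t.n_initial > 0
    ]
    densities = sorted({t.density for t in rows})
    if len(densities) < 2:
        raise FittingError(
            f"stratum ({species.name}, {setting.value}) needs >= 2 distinct "
            f"densities with larvae, found {densities}"
        )
    surv = np.array([t.n_surviving for t in rows], dtype=float)
    init = np.array([t.n_initial for t in rows], dtype=float)
    if surv.sum() == 0 or surv.sum() == init.sum():
        raise FittingError(
            f"stratum ({species.name}, {setting.value}) is completely separated "
            "(all larvae died or all survived); the binomial MLE does not exist"
        )
    x = np.array([t.density for t in rows], dtype=float)
    X = sm.add_constant(x)
    endog = np.column_stack([surv, init - surv])
    try:
        res = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
    except Exception as exc:  # pragma: no cover - statsmodels-internal failures
        raise FittingError(
            f"binomial GLM failed for ({species.name}, {setting.value}): {exc}"
        ) from exc
    params = np.asarray(res.params, dtype=float)
    return GlmFit(
        species=species,
        setting=setting,
        intercept=float(params[0]),
        slope=float(params[1]),
        cov=np.asarray(res.cov_params(), dtype=float),
        n_obs=len(rows),
    )


def fit_all_strata(
    trials: list[CompetitionTrial],
) -> dict[tuple[Species, Setting], GlmFit]:
    """Fit every (species, setting) stratum present in the data."""
    strata = sorted(
        {(t.species, t.setting) for t in trials},
        key=lambda k: (int(k[0]), k[1].value),
    )
    return {key: fit_survival_model(trials, *key) for key in strata}


def predict_survival(fit: GlmFit, density) -> np.ndarray | float:
    return fit.predict(density)


def build_payoff_matrices(
    fits: dict[tuple[Species, Setting], GlmFit],
    low_density: float = DENSITY_LOW,
    high_density: float = DENSITY_HIGH,
) -> PayoffMatrices:
    """Assemble payoff matrices from the four stratum fits.

    Diagonal entries come from the ISOLATED fits, off-diagonals from the
    COMBINED fits, evaluated at the low/high reference densities and clipped
    to [0, 1].
    """
    if low_density >= high_density:
        raise ParameterError("low_density must be below high_density")
    missing = [
        (sp.name, st.value)
        for sp in (Species.SF, Species.HA)
        for st in Setting
        if (sp, st) not in fits
    ]
    if missing:
        raise ParameterError(f"missing stratum fit(s): {missing}")

    def entry(sp: Species, st: Setting, density: float) -> float:
        return float(np.clip(fits[(sp, st)].predict(density), 0.0, 1.0))

    def matrix(density: float) -> np.ndarray:
        m = np.empty((2, 2))
        for i, sp in enumerate((Species.SF, Species.HA)):
            m[i, i] = entry(sp, Setting.ISOLATED, density)
            m[i, 1 - i] = entry(sp, Setting.COMBINED, density)
        return m

    return PayoffMatrices(H=matrix(high_density), L=matrix(low_density))


def matrix_truth_coefficients(
    matrices: PayoffMatrices | None = None,
) -> dict[tuple[Species, Setting], tuple[float, float]]:
    """Logit-linear coefficients implied by a payoff-matrix pair.

    For each stratum, the unique (intercept, slope) whose survival curve
    passes through the matrix entries at the low/high reference densities.
    Used as the default ground truth of the synthetic field-data generator.
    """
    matrices = matrices or PayoffMatrices()
    out: dict[tuple[Species, Setting], tuple[float, float]] = {}
    for i, sp in enumerate((Species.SF, Species.HA)):
        for st in Setting:
            j = i if st is Setting.ISOLATED else 1 - i
            fit = GlmFit.from_survival_pair(
                sp, st, matrices.L[i, j], matrices.H[i, j]
            )
            out[(sp, st)] = (fit.intercept, fit.slope)
    return out


def generate_field_data(
    truth: dict[tuple[Species, Setting], tuple[float, float]] | None = None,
    densities: tuple[int, ...] = DEFAULT_DENSITIES,
    blocks: int = DEFAULT_BLOCKS,
    block_sd: float = 0.25,
    rng: np.random.Generator | int | None = None,
) -> list[CompetitionTrial]:
    """Synthetic randomized-block competition experiment.

    One plant per stratum x density x block, infested with ``density`` larvae.
    Blocks share a normal(0, block_sd) effect on the logit scale; survivors
    are binomial with probability inverse-logit(intercept + slope * density +
    block effect).  ``truth`` maps each (species, setting) stratum to
    (intercept, slope); defaults to the curves implied by the default payoff
    matrices.
    """
    if not densities:
        raise ParameterError("need at least one density")
    if blocks < 1:
        raise ParameterError("need at least one block")
    rng = np.random.default_rng(rng)
    truth = truth if truth is not None else matrix_truth_coefficients()
    block_eff = rng.normal(0.0, block_sd, size=blocks) if block_sd > 0 else np.zeros(blocks)
    trials: list[CompetitionTrial] = []
    for (sp, st), (b0, b1) in truth.items():
        for density in densities:
            for block in range(blocks):
                p = float(expit(b0 + b1 * density + block_eff[block]))
                surv = int(rng.binomial(density, p))
                trials.append(
                    CompetitionTrial(sp, st, int(density), block + 1, int(density), surv)
                )
    return trials


def bootstrap_block_uncertainty(
    trials: list[CompetitionTrial],
    species: Species,
    setting: Setting,
    n_boot: int = 200,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Design-based uncertainty: resample blocks with replacement and refit.

    Returns one row per successful bootstrap fit with columns ``intercept``
    and ``slope``; degenerate resamples (separation) are skipped.
    """
    rng = np.random.default_rng(rng)
    blocks = sorted({t.block for t in trials})
    by_block = {b: [t for t in trials if t.block == b] for b in blocks}
    rows = []
    for _ in range(n_boot):
        chosen = rng.choice(blocks, size=len(blocks), replace=True)
        sample = [t for b in chosen for t in by_block[b]]
        try:
            fit = fit_survival_model(sample, species, setting)
        except FittingError:
            continue
        rows.append({"intercept": fit.intercept, "slope": fit.slope})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trial-table I/O (delimited text, header: species,setting,density,block,...)
# ---------------------------------------------------------------------------

def trials_to_dataframe(trials: list[CompetitionTrial]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "species": [t.species.name for t in trials],
            "setting": [t.setting.value for t in trials],
            "density": [t.density for t in trials],
            "block": [t.block for t in trials],
            "n_initial": [t.n_initial for t in trials],
            "n_surviving": [t.n_surviving for t in trials],
        }
    )


def trials_from_dataframe(df: pd.DataFrame) -> list[CompetitionTrial]:
    required = {"species", "setting", "density", "block", "n_initial", "n_surviving"}
    missing = required - set(df.columns)
    if missing:
        raise ParameterError(f"trial table missing column(s): {sorted(missing)}")
    return [
        CompetitionTrial(
            species=Species[str(row.species).upper()],
            setting=Setting(str(row.setting).lower()),
            density=int(row.density),
            block=int(row.block),
            n_initial=int(row.n_initial),
            n_surviving=int(row.n_surviving),
        )
        for row in df.itertuples()
    ]


def write_trials(trials: list[CompetitionTrial], path: str | Path) -> None:
    trials_to_dataframe(trials).to_csv(path, index=False)


def read_trials(path: str | Path) -> list[CompetitionTrial]:
    return trials_from_dataframe(pd.read_csv(path))
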