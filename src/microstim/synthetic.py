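"""Synthetic macrophage cultures and their stimulus responses.

Cultured RAW 264.7 macrophages grow in clumps rather than an even lawn, so
cell positions are drawn from a Thomas cluster process: Poisson-distributed
parent cluster centres, each with a Poisson number of offspring cells
scattered with Gaussian dispersion around the parent.  Each resting cell
carries a nuclear/cytoplasmic NF-kB reporter ratio drawn log-normally below
one; activation moves the ratio to a log-normal centred above one
(translocation into the nucleus).

The response model is a logistic dose curve in log concentration whose
midpoint shifts with culture density: crowded cultures need a higher agonist
concentration for the same 5-minute stimulus, and the shift decays linearly
in stimulation time so that by 15 minutes the dense-culture threshold has
relaxed back to the sparse one.  The functional form is

    p(C) = b + (1 - b) * logistic(k * (log10 C - log10 EC50_eff))
    EC50_eff = EC50 * (1 + beta * max(0, rho/rho_ref - 1) * h(t))
    h(t) = max(0, (t_restore - t) / (t_restore - t_min))

with background rate ``b``, Hill-type slope ``k``, culture density ``rho``,
and no response at all for stimulation shorter than ``t_min``.  This is a
deliberately phenomenological ground truth for exercising the analysis
stages; it encodes the observed density and time dependence, not a
mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
import pandas as pd
from scipy.special import expit

from .diffusion import ConcentrationField

__all__ = [
    "CultureConfig",
    "ResponseModelParams",
    "generate_culture",
    "activation_probability",
    "simulate_response",
    "draw_resting_ratios",
    "CELL_COLUMNS",
]

#: bit-exact column order of the per-cell table used throughout the package.
CELL_COLUMNS = [
    "cell_id",
    "x_um",
    "y_um",
    "nuc_intensity",
    "cyt_intensity",
    "nuc_cyt_ratio",
    "conc_nM",
    "ground_truth",
    "called",
    "n_neighbors",
    "experiment_id",
]

_MAX_CELLS = 1_000_000


@dataclass(frozen=True)
class CultureConfig:
    """Thomas-process culture layout.

    density is in cells/mm^2; field dimensions in um.  cluster_rate (parent
    clusters per mm^2) defaults to density/8, i.e. a mean of 8 cells per
    clump; cluster_spread is the Gaussian offspring dispersion (um).
    """

    density: float
    field_width_um: float = 1000.0
    field_height_um: float = 1000.0
    cluster_rate: float | None = None
    cluster_spread_um: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError("density must be non-negative")
        if self.field_width_um <= 0 or self.field_height_um <= 0:
            raise ValueError("field dimensions must be positive")
        if self.cluster_spread_um <= 0:
            raise ValueError("cluster_spread_um must be positive")
        if self.cluster_rate is None:
            object.__setattr__(self, "cluster_rate", self.density / 8.0)

    @property
    def area_mm2(self) -> float:
        return self.field_width_um * self.field_height_um / 1e6


# presets matching the plating densities used for sparse vs dense comparisons
SPARSE_DENSITY = 400.0
DENSE_DENSITY = 3750.0


def sparse_preset(seed: int = 0, **kwargs) -> CultureConfig:
    return CultureConfig(density=SPARSE_DENSITY, seed=seed, **kwargs)


def dense_preset(seed: int = 0, **kwargs) -> CultureConfig:
    return CultureConfig(density=DENSE_DENSITY, seed=seed, **kwargs)


@dataclass(frozen=True)
class ResponseModelParams:
    """Dose-time-density activation model and reporter-ratio distributions.

    beta defaults to 36/11 so that at 3750 cells/mm^2 and a 5-minute
    stimulus the effective threshold is exactly tenfold the sparse-culture
    EC50.  Ratio distributions are log-normal: resting median 0.75,
    activated median 1.5, both with log-sd 0.2 (activated ratios sit above
    1, resting below, with modest overlap).
    """

    ec50_base_nM: float = 100.0
    hill_slope: float = 4.0
    background_rate: float = 0.05
    density_coef: float = 36.0 / 11.0
    density_ref: float = 1000.0
    t_min_stim_min: float = 5.0
    t_restore_min: float = 15.0
    resting_ratio_log_mean: float = math.log(0.75)
    resting_ratio_log_sd: float = 0.2
    activated_ratio_log_mean: float = math.log(1.5)
    activated_ratio_log_sd: float = 0.2

    def __post_init__(self) -> None:
        if not (0 <= self.background_rate < 1):
            raise ValueError("background_rate must be in [0, 1)")
        if self.ec50_base_nM <= 0 or self.hill_slope <= 0:
            raise ValueError("ec50_base_nM and hill_slope must be positive")
        if self.t_min_stim_min >= self.t_restore_min:
            raise ValueError("t_min_stim_min must be below t_restore_min")

    def ec50_effective(self, density: float, t_stim_min: float) -> float:
        """Density- and time-shifted activation threshold (nM)."""
        span = self.t_restore_min - self.t_min_stim_min
        h = max(0.0, (self.t_restore_min - t_stim_min) / span)
        crowding = max(0.0, density / self.density_ref - 1.0)
        return self.ec50_base_nM * (1.0 + self.density_coef * crowding * h)


def draw_resting_ratios(n: int, params: ResponseModelParams, rng: np.random.Generator):
    return rng.lognormal(params.resting_ratio_log_mean, params.resting_ratio_log_sd, size=n)


def _empty_cells() -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "cell_id": pd.Series([], dtype=int),
            "x_um": pd.Series([], dtype=float),
            "y_um": pd.Series([], dtype=float),
            "nuc_intensity": pd.Series([], dtype=float),
            "cyt_intensity": pd.Series([], dtype=float),
            "nuc_cyt_ratio": pd.Series([], dtype=float),
            "conc_nM": pd.Series([], dtype=float),
            "ground_truth": pd.Series([], dtype=object),
            "called": pd.Series([], dtype=object),
            "n_neighbors": pd.Series([], dtype=object),
            "experiment_id": pd.Series([], dtype=object),
        }
    )
    return df[CELL_COLUMNS]


def generate_culture(
    config: CultureConfig,
    params: ResponseModelParams | None = None,
    experiment_id: str = "",
) -> pd.DataFrame:
    """Draw a resting culture from the Thomas cluster process.

    Parents are a homogeneous Poisson process at ``cluster_rate`` per mm^2,
    offspring counts are Poisson with mean density/cluster_rate, and
    offspring positions Gaussian around the parent (clipped to the field).
    Resting reporter ratios are attached to every cell.  Deterministic
    given ``config.seed``.
    """
    params = params or ResponseModelParams()
    if config.density * config.area_mm2 > _MAX_CELLS:
        raise ValueError(
            f"refusing to generate more than {_MAX_CELLS} expected cells "
            f"(density {config.density}/mm^2 over {config.area_mm2:.1f} mm^2)"
        )
    rng = np.random.default_rng(config.seed)
    if config.density == 0:
        return _empty_cells()

    n_parents = rng.poisson(config.cluster_rate * config.area_mm2)
    if n_parents == 0:
        return _empty_cells()
    parents_x = rng.uniform(0, config.field_width_um, size=n_parents)
    parents_y = rng.uniform(0, config.field_height_um, size=n_parents)
    mean_offspring = config.density / config.cluster_rate
    counts = rng.poisson(mean_offspring, size=n_parents)
    n = int(counts.sum())
    if n == 0:
        return _empty_cells()
    cx = np.repeat(parents_x, counts)
    cy = np.repeat(parents_y, counts)
    x = np.clip(rng.normal(cx, config.cluster_spread_um), 0, config.field_width_um)
    y = np.clip(rng.normal(cy, config.cluster_spread_um), 0, config.field_height_um)

    ratio = draw_resting_ratios(n, params, rng)
    cyt = rng.lognormal(math.log(400.0), 0.15, size=n)
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "x_um": x,
            "y_um": y,
            "nuc_intensity": ratio * cyt,
            "cyt_intensity": cyt,
            "nuc_cyt_ratio": ratio,
            "conc_nM": np.nan,
            "ground_truth": pd.array([pd.NA] * n, dtype="boolean"),
            "called": pd.array([pd.NA] * n, dtype="boolean"),
            "n_neighbors": pd.array([pd.NA] * n, dtype="Int64"),
            "experiment_id": experiment_id,
        }
    )
    return cells[CELL_COLUMNS]


def activation_probability(
    conc_nM,
    t_stim_min: float,
    density: float,
    params: ResponseModelParams | None = None,
):
    """Probability that a cell activates under the given local conditions.

    Vectorized over ``conc_nM``.  Below the minimum stimulation time only
    the background rate remains; otherwise a logistic curve in log10
    concentration with the density/time-shifted EC50.
    """
    params = params or ResponseModelParams()
    conc = np.asarray(conc_nM, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentration must be non-negative")
    if t_stim_min < 0:
        raise ValueError("stimulation time must be non-negative")
    b = params.background_rate
    if t_stim_min < params.t_min_stim_min:
        p = np.full_like(conc, b)
        return p if p.ndim else float(p)
    ec50 = params.ec50_effective(density, t_stim_min)
    with np.errstate(divide="ignore"):
        logdose = np.log10(conc)  # conc == 0 -> -inf -> p = b
    p = b + (1.0 - b) * expit(params.hill_slope * (logdose - math.log10(ec50)))
    return p if p.ndim else float(p)


def simulate_response(
    cells: pd.DataFrame,
    stimulus: "ConcentrationField | float",
    t_stim_min: float,
    params: ResponseModelParams | None = None,
    seed: int = 0,
    density: float | None = None,
    field_area_mm2: float | None = None,
) -> pd.DataFrame:
    """Draw ground-truth activation and post-stimulation reporter ratios.

    ``stimulus`` is either a :class:`~microstim.diffusion.ConcentrationField`
    (cells get their local concentration at the end of dispensing) or a
    uniform bath concentration in nM.  ``density`` is the culture density
    used by the response model; if omitted it is estimated from the cell
    count and ``field_area_mm2``.  Activation is Bernoulli per cell; the
    ground-truth flag is stored separately from the downstream ``called``
    column.  Deterministic given ``seed``.
    """
    params = params or ResponseModelParams()
    cells = cells.copy()
    if isinstance(stimulus, ConcentrationField):
        if cells["x_um"].isna().any() or cells["y_um"].isna().any():
            raise ValueError("cells must carry positions to evaluate the field")
        t_end = stimulus.conditions.duration_s
        conc = stimulus.at_points(
            cells["x_um"].to_numpy(), cells["y_um"].to_numpy(), t_end
        )
    else:
        conc = np.full(len(cells), float(stimulus))
    cells["conc_nM"] = conc

    if density is None:
        if field_area_mm2 is None:
            raise ValueError("provide density or field_area_mm2")
        density = len(cells) / field_area_mm2

    rng = np.random.default_rng(seed)
    p = activation_probability(conc, t_stim_min, density, params)
    activated = rng.random(len(cells)) < p

    n = len(cells)
    ratios = np.empty(n)
    ratios[~activated] = rng.lognormal(
        params.resting_ratio_log_mean, params.resting_ratio_log_sd, size=int((~activated).sum())
    )
    ratios[activated] = rng.lognormal(
        params.activated_ratio_log_mean, params.activated_ratio_log_sd, size=int(activated.sum())
    )
    cells["nuc_cyt_ratio"] = ratios
    cells["nuc_intensity"] = ratios * cells["cyt_intensity"].to_numpy()
    cells["ground_truth"] = pd.array(activated, dtype="boolean")
    return cells
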