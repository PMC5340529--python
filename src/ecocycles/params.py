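"""Model parameters and population state for the seasonal eco-evolutionary IPM.

The model tracks a quantitative trait (female dry body weight, mg) through
alternating breeding and non-breeding seasons.  Fecundity increases with body
size while non-breeding survival decreases with body size, more steeply at
high density, so the two seasons impose opposing episodes of selection.
Abundances up to two generations back enter the vital rates (delayed density
dependence), which is what allows multigenerational cycles to emerge.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = ["ModelParams", "SuParams", "PopState", "load_params", "save_params"]


@dataclass(frozen=True)
class ModelParams:
    """All constants of the seasonal integral projection model.

    ``phi1..phi6`` parameterize per-capita fecundity, ``ups1..ups6``
    non-breeding survival.  ``lamX``/``lamY`` are the slopes of the mean
    environmental effect on body size per individual of density at the
    start of the breeding / non-breeding season.  ``VA`` and ``VE`` are the
    additive-genetic and environmental variances of body weight (mg^2);
    both are held constant across generations.  ``zmin``/``zmax`` bound the
    trait domain (mg) and ``n_grid`` sets the quadrature nodes per axis.
    """

    phi1: float = 1.5       # intrinsic fecundity of a vanishingly small fly
    phi2: float = 2.8       # rate of increase of fecundity with body size
    phi3: float = 0.00007   # baseline density-driven fecundity decline
    phi4: float = 0.04588   # size-amplified density-driven fecundity decline
    phi5: float = 1.0       # carry-over weight of last non-breeding density
    phi6: float = 0.001     # current x past density interaction (carry-over)
    ups1: float = 0.005     # survival decline per individual one generation back
    ups2: float = 0.0026    # survival decline per individual two generations back
    ups3: float = 0.7       # size x current-density interaction strength
    ups4: float = 0.7       # shape of the size x current-density interaction
    ups5: float = 6.0       # exponent of the current-density survival penalty
    ups6: float = 350.0     # density scale of the current-density penalty
    lamX: float = 0.00001   # env. body-size decline per breeding-season individual
    lamY: float = 0.00025   # env. body-size decline per non-breeding individual
    VA: float = 0.003       # additive genetic variance (mg^2)
    VE: float = 0.007       # environmental variance (mg^2)
    zmin: float = 0.0       # lower trait-domain bound (mg)
    zmax: float = 1.0       # upper trait-domain bound (mg)
    n_grid: int = 201       # quadrature nodes per axis

    def __post_init__(self) -> None:
        if self.VA < 0:
            raise ValueError(f"VA must be >= 0, got {self.VA}")
        if self.VE <= 0:
            raise ValueError(f"VE must be > 0, got {self.VE}")
        if not self.zmin < self.zmax:
            raise ValueError("zmin must be < zmax")
        if self.n_grid < 3:
            raise ValueError("n_grid must be >= 3")

    @property
    def h2(self) -> float:
        """Narrow-sense heritability VA / (VA + VE)."""
        return self.VA / (self.VA + self.VE)

    @property
    def VP(self) -> float:
        """Total phenotypic variance VA + VE (mg^2)."""
        return self.VA + self.VE

    def with_heritability(self, h2: float) -> "ModelParams":
        """Return a copy with VA/VE rescaled to heritability ``h2``.

        Total phenotypic variance VA + VE is preserved, so the width of the
        body-size distribution is unchanged; only the fraction of variance
        that is heritable moves.
        """
        if not 0.0 <= h2 < 1.0:
            raise ValueError("h2 must be in [0, 1)")
        vp = self.VP
        return replace(self, VA=h2 * vp, VE=(1.0 - h2) * vp)

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SuParams:
    """Parameters of the logistic non-breeding survival curve.

    ``Su(N) = 1 / (1 + (N / v) ** w)`` where ``N`` is abundance at the start
    of the non-breeding season.  ``v`` is the half-survival abundance and
    ``w`` the shape exponent.  Defaults are the long-term-control fit.
    """

    v: float = 375.22
    w: float = 1.83

    def __post_init__(self) -> None:
        if self.v <= 0 or self.w <= 0:
            raise ValueError("SuParams v and w must both be > 0")


@dataclass
class PopState:
    """Lagged abundances and trait means at one point in the seasonal cycle.

    ``X[i]`` / ``Y[i]`` are abundances at the start of the breeding /
    non-breeding season ``i`` generations ago (index 0 = current generation).
    ``b_mean_*`` are mean breeding values and ``p_mean_*`` mean phenotypes at
    the corresponding season starts (mg).
    """

    X: np.ndarray = field(default_factory=lambda: np.full(3, np.nan))
    Y: np.ndarray = field(default_factory=lambda: np.full(3, np.nan))
    b_mean_X: float = np.nan
    b_mean_Y: float = np.nan
    p_mean_X: float = np.nan
    p_mean_Y: float = np.nan

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.shape != (3,) or self.Y.shape != (3,):
            raise ValueError("X and Y must each hold lags 0..2")
        for arr in (self.X, self.Y):
            if np.any(arr[~np.isnan(arr)] < 0):
                raise ValueError("abundances must be >= 0")

    def copy(self) -> "PopState":
        return PopState(
            X=self.X.copy(), Y=self.Y.copy(),
            b_mean_X=self.b_mean_X, b_mean_Y=self.b_mean_Y,
            p_mean_X=self.p_mean_X, p_mean_Y=self.p_mean_Y,
        )


_PARAM_KEYS = (
    "phi1", "phi2", "phi3", "phi4", "phi5", "phi6",
    "ups1", "ups2", "ups3", "ups4", "ups5", "ups6",
    "lamX", "lamY", "VA", "VE", "zmin", "zmax", "n_grid",
)


def load_params(path: str | Path | None = None) -> ModelParams:
    """Load :class:`ModelParams` from a flat YAML mapping.

    With no argument, loads the packaged default parameter file.  Unknown
    keys raise so that typos in config files never pass silently.
    """
    if path is None:
        with resources.files("ecocycles.data").joinpath("default_params.yaml").open() as fh:
            raw = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("parameter file must be a flat key-value mapping")
    unknown = set(raw) - set(_PARAM_KEYS)
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    return ModelParams(**raw)


def save_params(params: ModelParams, path: str | Path) -> None:
    """Write :class:`ModelParams` to a flat YAML mapping."""
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(params), fh, sort_keys=False)
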