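"""Demographic building blocks of the dynamic energy budget integral
projection model (DEB-IPM).

The DEB-IPM projects the number distribution ``N(L, t)`` of female body
lengths one day forward through a kernel composed of four functions:

* ``S(L)``   — survival: constant background mortality ``exp(-mu)`` up to
  the starvation bound ``L_m * E(Y) / kappa``, zero above it;
* ``G(L', L)`` — growth: a Gaussian around the von Bertalanffy expectation,
  whose asymptote ``L_inf = L_m * E(Y)`` moves with the feeding level, so
  individuals shrink when food drops;
* ``R(L)``   — reproduction: ``E(Y) * R_m * L^2 / L_m^2`` for mature,
  non-starving females, zero otherwise;
* ``D(L', L)`` — parent-offspring association: where newborn lengths land
  (for the bulb mite parameterisation, a point mass at ``L_b``).

The environment enters through a single dimensionless feeding level
``E(Y)`` in (0, 1] (empty to full gut), which scales the growth asymptote,
the maturation threshold ``L_p = lp_coeff * L_inf`` and the reproduction
rate.  Discretising the length domain into equal-width bins (midpoint
rule) turns the kernel into a projection matrix ``A`` with
``A = D R + G S``.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass
from functools import cached_property
from typing import Union

import numpy as np
import yaml
from scipy import linalg, optimize

__all__ = [
    "DEBParams",
    "SizeGrid",
    "DiscretizedKernel",
    "default_grid",
    "ultimate_length",
    "maturation_length",
    "vb_growth_rate",
    "survival_prob",
    "growth_mean",
    "growth_sd",
    "growth_density",
    "fecundity",
    "offspring_column",
    "build_kernel",
    "dominant_eigenvalue",
    "equilibrium_feeding_level",
]

ArrayLike = Union[float, np.ndarray]


def _check_feeding_level(ey: float) -> float:
    ey = float(ey)
    if not 0.0 < ey <= 1.0:
        raise ValueError(f"feeding level E(Y) must lie in (0, 1], got {ey}")
    return ey


@dataclass(frozen=True)
class DEBParams:
    """Life-history parameter set of the female bulb mite DEB-IPM.

    Defaults are the published bulb mite (*Rhizoglyphus robini*) values.

    Parameters
    ----------
    L_b : float
        Body length at birth (mm).
    L_m : float
        Maximum length at feeding level ``E(Y) = 1`` (mm).
    kappa : float
        Fraction of assimilated energy allocated to somatic maintenance and
        growth, in (0, 1).  Sets the starvation bound ``L_m * E(Y) / kappa``.
    mu : float
        Background mortality rate (per day).
    R_m : float
        Maximum rate of producing female offspring at length ``L_m``
        (number per day).
    sigma_Y : float
        Standard deviation of the feeding level; drives growth stochasticity.
    lp_coeff : float
        Length at maturity as a fraction of ultimate length,
        ``L_p = lp_coeff * L_inf``.
    rb_c0, rb_c1 : float
        Coefficients of the feeding-level plasticity of the von Bertalanffy
        growth rate, ``r_B = 1 / (rb_c0 - rb_c1 * L_inf)`` (days, days/mm).
    rb_scale : float
        Multiplicative scale applied to the computed growth rate; 1 leaves
        the published relationship untouched (perturbation knob).
    sigma_Lb : float
        Standard deviation of offspring length (mm); 0 means all offspring
        are born at exactly ``L_b``.
    """

    L_b: float = 0.166
    L_m: float = 1.008
    kappa: float = 0.083
    mu: float = 0.03
    R_m: float = 16.0
    sigma_Y: float = 0.3
    lp_coeff: float = 0.539
    rb_c0: float = 151.0
    rb_c1: float = 137.8
    rb_scale: float = 1.0
    sigma_Lb: float = 0.0

    def __post_init__(self) -> None:
        if self.L_b <= 0 or self.L_m <= 0:
            raise ValueError("lengths L_b and L_m must be positive")
        if self.L_b >= self.L_m:
            raise ValueError("L_b must be smaller than L_m")
        if not 0.0 < self.kappa < 1.0:
            raise ValueError("kappa must lie in (0, 1)")
        if self.mu < 0:
            raise ValueError("mortality rate mu must be non-negative")
        if self.R_m < 0:
            raise ValueError("R_m must be non-negative")
        if self.sigma_Y < 0 or self.sigma_Lb < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0.0 < self.lp_coeff < 1.0:
            raise ValueError("lp_coeff must lie in (0, 1)")
        if self.rb_scale <= 0:
            raise ValueError("rb_scale must be positive")
        # growth-rate denominator must stay positive over the admissible
        # range of ultimate lengths L_inf in (0, L_m]
        if self.rb_c0 - self.rb_c1 * self.L_m <= 0:
            raise ValueError(
                "rb_c0 - rb_c1 * L_m must be positive for the growth rate "
                "to be defined at all feeding levels"
            )

    def replace(self, **changes) -> "DEBParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path=None) -> str:
        """Serialise as flat key-value YAML; write to *path* if given."""
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "DEBParams":
        """Read a parameter set from a YAML file path or string."""
        try:
            with open(source) as fh:
                data = yaml.safe_load(fh)
        except (OSError, TypeError):
            data = yaml.safe_load(source)
        if not isinstance(data, dict):
            raise ValueError("parameter file must be a flat key-value mapping")
        return cls(**data)


@dataclass(frozen=True)
class SizeGrid:
    """Uniform discretisation of the length domain into ``n_bins`` bins.

    Mesh points are the bin midpoints; the bin width is
    ``(upper - lower) / n_bins``.
    """

    lower: float
    upper: float
    n_bins: int = 200

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("grid requires lower < upper")
        if self.n_bins < 1:
            raise ValueError("n_bins must be at least 1")

    @property
    def bin_width(self) -> float:
        return (self.upper - self.lower) / self.n_bins

    @cached_property
    def edges(self) -> np.ndarray:
        return np.linspace(self.lower, self.upper, self.n_bins + 1)

    @cached_property
    def midpoints(self) -> np.ndarray:
        return self.edges[:-1] + 0.5 * self.bin_width

    def bin_index(self, length: float) -> int:
        """Index of the bin whose interval contains *length*."""
        if not self.lower <= length <= self.upper:
            raise ValueError(
                f"length {length} outside grid domain "
                f"[{self.lower}, {self.upper}]"
            )
        return min(int((length - self.lower) / self.bin_width), self.n_bins - 1)


def default_grid(params: DEBParams, n_bins: int = 200) -> SizeGrid:
    """Length domain ``[0.9 * L_b, L_m]``.

    The 10% margin below the birth length accommodates Gaussian growth mass
    that falls just below ``L_b``; offspring enter exactly at ``L_b``.
    """
    return SizeGrid(0.9 * params.L_b, params.L_m, n_bins)


# ---------------------------------------------------------------------------
# individual-level demographic functions


def ultimate_length(ey: float, params: DEBParams) -> float:
    """Asymptote of the von Bertalanffy curve, ``L_inf = L_m * E(Y)``."""
    return params.L_m * _check_feeding_level(ey)


def maturation_length(ey: float, params: DEBParams) -> float:
    """Length at maturity ``L_p``, a fixed fraction of the ultimate length."""
    return params.lp_coeff * ultimate_length(ey, params)


def vb_growth_rate(ey: float, params: DEBParams) -> float:
    """von Bertalanffy growth rate at feeding level *ey* (per day).

    Plasticity rule ``r_B = 1 / (rb_c0 - rb_c1 * L_inf)``: better-fed
    individuals approach their (larger) asymptote faster.
    """
    denom = params.rb_c0 - params.rb_c1 * ultimate_length(ey, params)
    if denom <= 0:
        raise ValueError("growth-rate denominator must be positive")
    return params.rb_scale / denom


def starvation_bound(ey: float, params: DEBParams) -> float:
    """Length above which maintenance exceeds assimilation: certain death."""
    return params.L_m * _check_feeding_level(ey) / params.kappa


def survival_prob(L: ArrayLike, ey: float, params: DEBParams) -> ArrayLike:
    """Daily survival probability ``S(L)``.

    ``exp(-mu)`` below the starvation bound ``L_m * E(Y) / kappa``, zero
    above it.
    """
    bound = starvation_bound(ey, params)
    L = np.asarray(L, dtype=float)
    if np.any(L <= 0):
        raise ValueError("length must be positive")
    out = np.where(L <= bound, np.exp(-params.mu), 0.0)
    return out if out.ndim else float(out)


def growth_mean(L: ArrayLike, ey: float, params: DEBParams) -> ArrayLike:
    """Expected next-day length ``E(L(t+1))`` under von Bertalanffy growth.

    Individuals above the asymptote ``L_m * E(Y)`` shrink toward it.
    """
    rb = vb_growth_rate(ey, params)
    linf = ultimate_length(ey, params)
    L = np.asarray(L, dtype=float)
    out = L * np.exp(-rb) + (1.0 - np.exp(-rb)) * linf
    return out if out.ndim else float(out)


def growth_sd(ey: float, params: DEBParams) -> float:
    """Standard deviation of next-day length (length independent)."""
    rb = vb_growth_rate(ey, params)
    return (1.0 - np.exp(-rb)) * params.L_m * params.sigma_Y


def growth_density(
    L_next: ArrayLike, L: float, ey: float, params: DEBParams
) -> ArrayLike:
    """Gaussian growth kernel ``G(L', L)`` evaluated at *L_next* (per mm)."""
    sd = growth_sd(ey, params)
    if sd <= 0:
        raise ValueError(
            "growth_density undefined for sigma_Y = 0; use the degenerate "
            "single-bin assignment instead"
        )
    mean = growth_mean(L, ey, params)
    L_next = np.asarray(L_next, dtype=float)
    z = (L_next - mean) / sd
    out = np.exp(-0.5 * z * z) / (np.sqrt(2.0 * np.pi) * sd)
    return out if out.ndim else float(out)


def fecundity(L: ArrayLike, ey: float, params: DEBParams) -> ArrayLike:
    """Daily female-offspring production ``R(L)``.

    Zero below the maturation length ``L_p`` and above the starvation bound
    (starving individuals are dead under ``S`` and must not reproduce);
    ``E(Y) * R_m * L^2 / L_m^2`` in between.
    """
    ey = _check_feeding_level(ey)
    lp = maturation_length(ey, params)
    bound = starvation_bound(ey, params)
    L = np.asarray(L, dtype=float)
    rate = ey * params.R_m * L**2 / params.L_m**2
    out = np.where((L >= lp) & (L <= bound), rate, 0.0)
    return out if out.ndim else float(out)


def offspring_column(
    L_parent: float, ey: float, grid: SizeGrid, params: DEBParams
) -> np.ndarray:
    """Offspring-length distribution ``D(L', L_parent)`` over grid bins.

    Immature parents get an all-zero column.  With ``sigma_Lb = 0`` the
    whole mass sits in the single bin containing ``L_b`` (exact assignment,
    not a numerical delta); otherwise a discretised Gaussian normalised to
    sum to one.
    """
    if not grid.lower <= params.L_b <= grid.upper:
        raise ValueError("grid does not contain the birth length L_b")
    col = np.zeros(grid.n_bins)
    if L_parent < maturation_length(ey, params):
        return col
    if params.sigma_Lb == 0.0:
        col[grid.bin_index(params.L_b)] = 1.0
    else:
        z = (grid.midpoints - params.L_b) / params.sigma_Lb
        w = np.exp(-0.5 * z * z)
        col = w / w.sum()
    return col


# ---------------------------------------------------------------------------
# kernel discretisation


@dataclass(frozen=True)
class DiscretizedKernel:
    """Daily projection matrix ``A`` at one feeding level.

    ``matrix = fecundity_part + survival_part`` where
    ``survival_part[i, j] = G(x_i, x_j) S(x_j) dx`` (midpoint rule) and
    ``fecundity_part[i, j] = D_column(x_j)[i] R(x_j)``, optionally weighted
    by the parent's survival.
    """

    matrix: np.ndarray
    fecundity_part: np.ndarray
    survival_part: np.ndarray
    ey: float
    grid: SizeGrid

    def save(self, path) -> None:
        """Write the matrix as delimited text with a metadata header."""
        header = (
            f"EY={self.ey} n_bins={self.grid.n_bins} "
            f"lower={self.grid.lower} upper={self.grid.upper}"
        )
        np.savetxt(path, self.matrix, header=header)

    @staticmethod
    def load(path) -> "DiscretizedKernel":
        with open(path) as fh:
            meta = dict(
                item.split("=") for item in fh.readline().lstrip("# ").split()
            )
        matrix = np.loadtxt(path)
        grid = SizeGrid(
            float(meta["lower"]), float(meta["upper"]), int(meta["n_bins"])
        )
        zeros = np.zeros_like(matrix)
        return DiscretizedKernel(matrix, zeros, zeros, float(meta["EY"]), grid)


def build_kernel(
    ey: float,
    grid: SizeGrid,
    params: DEBParams,
    fecundity_survival_weighted: bool = False,
) -> DiscretizedKernel:
    """Discretise the DEB-IPM kernel at feeding level *ey*.

    Midpoint rule over the bin midpoints.  Gaussian growth mass falling
    outside the domain is truncated, not renormalised: the loss is
    negligible for the bulb mite parameters and renormalising would
    silently inflate survival.

    When *fecundity_survival_weighted* is set, the fecundity term is
    additionally multiplied by the parent's survival probability (the
    "only surviving adults reproduce" reading of the model); the default
    is the literal kernel ``D R + G S``.
    """
    ey = _check_feeding_level(ey)
    x = grid.midpoints
    dx = grid.bin_width

    s = np.asarray(survival_prob(x, ey, params))
    sd = growth_sd(ey, params)
    means = np.asarray(growth_mean(x, ey, params))
    if sd > 0:
        z = (x[:, None] - means[None, :]) / sd
        G = np.exp(-0.5 * z * z) / (np.sqrt(2.0 * np.pi) * sd)
        survival_part = G * s[None, :] * dx
    else:
        # deterministic growth: all mass into the bin containing the mean
        survival_part = np.zeros((grid.n_bins, grid.n_bins))
        for j, m in enumerate(means):
            if s[j] > 0 and grid.lower <= m <= grid.upper:
                survival_part[grid.bin_index(m), j] = s[j]

    R = np.asarray(fecundity(x, ey, params))
    lp = maturation_length(ey, params)
    if params.sigma_Lb == 0.0:
        D = np.zeros((grid.n_bins, grid.n_bins))
        D[grid.bin_index(params.L_b), x >= lp] = 1.0
    else:
        zb = (x - params.L_b) / params.sigma_Lb
        col = np.exp(-0.5 * zb * zb)
        col /= col.sum()
        D = np.where(x[None, :] >= lp, col[:, None], 0.0)
    fecundity_part = D * R[None, :]
    if fecundity_survival_weighted:
        fecundity_part = fecundity_part * s[None, :]

    return DiscretizedKernel(
        matrix=fecundity_part + survival_part,
        fecundity_part=fecundity_part,
        survival_part=survival_part,
        ey=ey,
        grid=grid,
    )


def dominant_eigenvalue(kernel: DiscretizedKernel | np.ndarray) -> float:
    """Spectral radius of the projection matrix (asymptotic growth rate)."""
    matrix = kernel.matrix if isinstance(kernel, DiscretizedKernel) else kernel
    return float(np.max(np.abs(linalg.eigvals(matrix))))


def equilibrium_feeding_level(
    params: DEBParams,
    grid: SizeGrid,
    fecundity_survival_weighted: bool = False,
    bracket: tuple[float, float] = (0.15, 0.9),
    xtol: float = 1e-6,
) -> float:
    """Constant feeding level at which the population is stationary.

    Locates by bisection the ``E(Y)`` where the kernel's dominant
    eigenvalue equals one (``log lambda = 0``).
    """

    def log_growth(ey: float) -> float:
        k = build_kernel(ey, grid, params, fecundity_survival_weighted)
        return np.log(dominant_eigenvalue(k))

    lo, hi = bracket
    if log_growth(lo) >= 0 or log_growth(hi) <= 0:
        raise ValueError("bracket does not straddle the stationary point")
    return float(optimize.brentq(log_growth, lo, hi, xtol=xtol))
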