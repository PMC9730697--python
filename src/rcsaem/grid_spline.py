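"""Quadrature grid, B-spline basis, and Ramsay-curve densities.

The latent-trait density is modelled as a *Ramsay curve*: the normalized
exponential of a B-spline expansion evaluated on a fixed equidistant grid,

    g(x_q | eta) = exp(B*_q . eta) / C,    C = sum_q exp(B*_q . eta),

where ``B*`` is the Q x m matrix of B-spline basis functions evaluated at the
grid points.  The basis dimension is ``m = degree + knots - 1``, where
``knots`` counts evenly spaced breakpoints on [lo, hi] including both
endpoints.  Because the basis is a partition of unity, adding a constant to
``eta`` leaves the density unchanged; normalization is done in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.special import logsumexp

__all__ = [
    "Grid",
    "SplineSpec",
    "SplineBasis",
    "RamsayDensity",
    "MomentSummary",
    "build_grid",
    "build_basis",
    "ramsay_pdf",
    "density_moments",
    "discretized_normal",
    "standardize_mass",
    "export_density",
]

DEFAULT_LO = -6.0
DEFAULT_HI = 6.0
DEFAULT_STEP = 0.1


@dataclass(frozen=True)
class Grid:
    """Equidistant quadrature grid on [lo, hi] with inclusive endpoints."""

    points: np.ndarray
    lo: float
    hi: float
    step: float

    @property
    def Q(self) -> int:
        return self.points.size

    def __eq__(self, other) -> bool:  # grids compare by geometry
        if not isinstance(other, Grid):
            return NotImplemented
        return (
            self.lo == other.lo
            and self.hi == other.hi
            and self.step == other.step
        )

    __hash__ = None


@dataclass(frozen=True)
class SplineSpec:
    """B-spline configuration: breakpoint count and polynomial degree."""

    knots: int
    degree: int

    def __post_init__(self) -> None:
        if self.knots < 2:
            raise ValueError(f"knots must be >= 2, got {self.knots}")
        if self.degree < 1:
            raise ValueError(f"degree must be >= 1, got {self.degree}")

    @property
    def m(self) -> int:
        """Basis dimension: degree + knots - 1."""
        return self.degree + self.knots - 1


@dataclass(frozen=True)
class SplineBasis:
    """Q x m B-spline basis matrix evaluated on a grid (partition of unity)."""

    matrix: np.ndarray
    spec: SplineSpec
    grid: Grid

    @property
    def m(self) -> int:
        return self.spec.m


@dataclass(frozen=True)
class RamsayDensity:
    """Normalized exponential-spline density on a grid.

    ``g[q] = exp(B*_q . eta - logC)`` with ``logC`` the log normalizer.
    """

    eta: np.ndarray
    g: np.ndarray
    logC: float
    basis: SplineBasis = field(repr=False)

    @property
    def grid(self) -> Grid:
        return self.basis.grid

    @property
    def log_g(self) -> np.ndarray:
        """Exact log-masses B* eta - logC (safe where g underflows)."""
        return self.basis.matrix @ self.eta - self.logC


@dataclass(frozen=True)
class MomentSummary:
    """First four moments; kurtosis is the plain fourth standardized moment
    (normal = 3, not excess)."""

    mean: float
    sd: float
    skewness: float
    kurtosis: float


def build_grid(lo: float = DEFAULT_LO, hi: float = DEFAULT_HI,
               step: float = DEFAULT_STEP) -> Grid:
    """Build an equidistant grid; (hi - lo) must be an integer multiple of step.

    The default (-6, 6, 0.1) gives the conventional 121-point latent-trait
    grid used throughout Ramsay-curve IRT.
    """
    if not (lo < hi):
        raise ValueError(f"need lo < hi, got ({lo}, {hi})")
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    span = (hi - lo) / step
    n_intervals = round(span)
    if abs(span - n_intervals) > 1e-9:
        raise ValueError(
            f"(hi - lo)/step = {span} is not integral; "
            "grid endpoints would not be representable"
        )
    points = lo + step * np.arange(n_intervals + 1)
    points[-1] = hi
    points.setflags(write=False)
    return Grid(points=points, lo=float(lo), hi=float(hi), step=float(step))


def _knot_vector(spec: SplineSpec, lo: float, hi: float) -> np.ndarray:
    """Open (clamped) knot vector: `knots` evenly spaced breakpoints on
    [lo, hi], boundary knots repeated degree+1 times."""
    breakpoints = np.linspace(lo, hi, spec.knots)
    return np.concatenate([
        np.full(spec.degree, lo), breakpoints, np.full(spec.degree, hi),
    ])


def build_basis(grid: Grid, knots: int, degree: int) -> SplineBasis:
    """Evaluate the B-spline basis on the grid as a Q x m matrix.

    Rows sum to one (partition of unity on the clamped knot span).
    """
    spec = SplineSpec(knots=knots, degree=degree)
    if spec.m >= grid.Q:
        raise ValueError(
            f"basis dimension m={spec.m} must be < grid size Q={grid.Q}"
        )
    t = _knot_vector(spec, grid.lo, grid.hi)
    matrix = BSpline.design_matrix(grid.points, t, degree).toarray()
    matrix.setflags(write=False)
    return SplineBasis(matrix=matrix, spec=spec, grid=grid)


def ramsay_pdf(basis: SplineBasis, eta: np.ndarray) -> RamsayDensity:
    """Normalize exp(B* eta) over the grid (log-sum-exp stabilized)."""
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (basis.m,):
        raise ValueError(f"eta must have length m={basis.m}, got {eta.shape}")
    if not np.all(np.isfinite(eta)):
        raise ValueError("eta contains non-finite entries")
    log_unnorm = basis.matrix @ eta
    logC = float(logsumexp(log_unnorm))
    g = np.exp(log_unnorm - logC)
    g.setflags(write=False)
    return RamsayDensity(eta=eta.copy(), g=g, logC=logC, basis=basis)


def density_moments(density: RamsayDensity | np.ndarray,
                    grid: Grid | None = None) -> MomentSummary:
    """Moments of the discrete distribution with mass g_q at grid point x_q."""
    if isinstance(density, RamsayDensity):
        g = density.g
        x = density.grid.points
    else:
        if grid is None:
            raise ValueError("grid required when passing a raw mass vector")
        g = np.asarray(density, dtype=float)
        x = grid.points
    if np.any(g < -1e-12) or abs(g.sum() - 1.0) > 1e-8:
        raise ValueError("masses must be nonnegative and sum to 1")
    mean = float(g @ x)
    d = x - mean
    var = float(g @ d**2)
    if var <= 1e-12:
        raise ValueError("degenerate density: zero variance on the grid")
    sd = np.sqrt(var)
    skew = float(g @ d**3) / sd**3
    kurt = float(g @ d**4) / var**2
    return MomentSummary(mean=mean, sd=sd, skewness=skew, kurtosis=kurt)


def discretized_normal(grid: Grid, mean: float = 0.0, sd: float = 1.0) -> np.ndarray:
    """Standard-normal (by default) pdf evaluated on the grid, renormalized
    to a unit mass vector."""
    z = (grid.points - mean) / sd
    g = np.exp(-0.5 * z**2)
    return g / g.sum()


def standardize_mass(g: np.ndarray, grid: Grid) -> np.ndarray:
    """Affinely rescale a grid density to mean 0 / sd 1 and resample it on
    the same grid by linear interpolation of the density heights.

    If X has mass vector g, the returned vector approximates the law of
    (X - mean)/sd restricted to the grid (mass outside [lo, hi] is dropped
    by renormalization).
    """
    mom = density_moments(g, grid)
    x = grid.points
    h = np.interp(mom.mean + mom.sd * x, x, g / grid.step,
                  left=0.0, right=0.0) * mom.sd
    mass = h * grid.step
    total = mass.sum()
    if total <= 0:
        raise ValueError("standardization moved all mass off the grid")
    return mass / total


def export_density(density: RamsayDensity | np.ndarray, grid: Grid | None,
                   path) -> None:
    """Write a two-column TSV (theta, mass) for a grid density."""
    if isinstance(density, RamsayDensity):
        g, x = density.g, density.grid.points
    else:
        g, x = np.asarray(density, float), grid.points
    with open(path, "w") as fh:
        fh.write("theta\tmass\n")
        for xq, gq in zip(x, g):
            fh.write(f"{xq:.6g}\t{gq:.12g}\n")
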