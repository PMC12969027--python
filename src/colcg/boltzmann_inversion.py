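"""Gaussian fits to bonded-term distributions and harmonic inversion.

An equilibrium bonded degree of freedom q sampled from a canonical ensemble
with harmonic potential V(q) = k/2 (q - q0)^2 is Gaussian with mean q0 and
variance kB*T/k. Fitting a Gaussian to the observed density therefore yields
the harmonic equilibrium value (mu) and force constant (kB*T / sigma^2)
directly — the classic direct Boltzmann inversion.

Collagen backbone bond lengths are bimodal (proline-like first residues sit
on a shorter, stiffer bond), so a two-component Gaussian fit plus the density
crossing point between the two means is provided; the crossing is the
threshold of the sequence-specific bond-class rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize

from .constants import KB, DEFAULT_TEMPERATURE, BOND_CLASS_THRESHOLD


class DegenerateDistributionError(ValueError):
    """Samples have (numerically) zero spread; no Gaussian can be fitted."""


class InsufficientResolutionError(ValueError):
    """Histogram occupies too few bins to constrain a fit."""


class NoCrossingError(ValueError):
    """The two component densities do not cross between their means."""


@dataclass
class GaussianComponent:
    """One Gaussian density component C * exp(-(q-mu)^2 / (2 sigma^2))."""

    mu: float
    sigma: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")

    def density(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.amplitude * np.exp(-0.5 * ((x - self.mu) / self.sigma) ** 2)


@dataclass
class BimodalFit:
    lower: GaussianComponent
    upper: GaussianComponent
    intersection_x0: float | None
    fit_residual: float
    separable: bool = True

    def __post_init__(self) -> None:
        if self.lower.mu > self.upper.mu:
            self.lower, self.upper = self.upper, self.lower
        if self.separable and self.intersection_x0 is not None:
            if not (self.lower.mu < self.intersection_x0 < self.upper.mu):
                raise ValueError("intersection must lie between the two means")


@dataclass
class BondedParameter:
    """A harmonic bonded term ready for topology emission.

    eq_value in nm (bond) or degrees (angle/dihedral); force_constant in
    kJ mol^-1 nm^-2 (bond) or kJ mol^-1 rad^-2 (angle/dihedral).
    """

    kind: str
    beads: tuple
    eq_value: float
    force_constant: float
    funct: int = 1
    source: str = "manual"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.force_constant < 0:
            raise ValueError("force constant must be non-negative")


# ---------------------------------------------------------------------------
# Histogramming and fitting
# ---------------------------------------------------------------------------

_MIN_BINS = 50


def _density_histogram(samples: np.ndarray, min_bins: int = _MIN_BINS):
    """Freedman–Diaconis density histogram with a bin-count floor."""
    q25, q75 = np.percentile(samples, [25, 75])
    iqr = q75 - q25
    n = samples.size
    span = samples.max() - samples.min()
    if iqr > 0:
        width = 2 * iqr / n ** (1 / 3)
        bins = max(min_bins, int(np.ceil(span / width)))
    else:
        bins = min_bins
    hist, edges = np.histogram(samples, bins=bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return hist, centers


def fit_gaussian(samples: Sequence[float], unit: str = "nm") -> GaussianComponent:
    """Least-squares Gaussian fit to the density histogram of ``samples``.

    Requires at least 100 samples with nonzero spread. The free amplitude
    absorbs any normalization mismatch of the histogram.
    """
    x = np.asarray(samples, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size < 100:
        raise ValueError(f"need >= 100 samples, got {x.size}")
    sd = x.std()
    if sd <= 0 or x.max() == x.min():
        raise DegenerateDistributionError("samples have zero variance")

    hist, centers = _density_histogram(x)
    if np.count_nonzero(hist) < 5:
        raise InsufficientResolutionError(
            "fewer than 5 occupied histogram bins; distribution too narrow "
            "relative to its range"
        )

    def model(q, amp, mu, sigma):
        return amp * np.exp(-0.5 * ((q - mu) / sigma) ** 2)

    p0 = (hist.max(), float(x.mean()), float(sd))
    popt, _ = optimize.curve_fit(
        model, centers, hist, p0=p0,
        bounds=([0.0, x.min(), 1e-12], [np.inf, x.max(), np.inf]),
        maxfev=20000,
    )
    amp, mu, sigma = popt
    return GaussianComponent(mu=float(mu), sigma=float(abs(sigma)), amplitude=float(amp))


def _two_gaussians(q, a1, m1, s1, a2, m2, s2):
    return a1 * np.exp(-0.5 * ((q - m1) / s1) ** 2) + a2 * np.exp(
        -0.5 * ((q - m2) / s2) ** 2
    )


def fit_bimodal(
    samples: Sequence[float],
    init: tuple | None = None,
) -> BimodalFit:
    """Fit a two-component Gaussian mixture density by least squares.

    ``init`` may supply two ``GaussianComponent`` guesses; otherwise the
    25th/75th percentiles seed the two means. Components are returned
    ordered by mean. When the optimizer collapses onto coincident
    components (means closer than the sum of the sigmas), the fit is
    flagged non-separable and no intersection is reported.
    """
    x = np.asarray(samples, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size < 1000:
        raise ValueError(f"need >= 1000 samples, got {x.size}")
    if x.std() <= 0:
        raise DegenerateDistributionError("samples have zero variance")

    hist, centers = _density_histogram(x)

    if init is not None:
        c1, c2 = init
        p0 = [c1.amplitude, c1.mu, c1.sigma, c2.amplitude, c2.mu, c2.sigma]
        if p0[0] <= 0 or p0[3] <= 0:
            peak = hist.max()
            p0[0] = p0[3] = 0.5 * peak
    else:
        m1, m2 = np.percentile(x, [25, 75])
        s = max(x.std() / 2, 1e-6)
        peak = hist.max()
        p0 = [0.5 * peak, m1, s, 0.5 * peak, m2, s]

    lo = [0.0, x.min(), 1e-12, 0.0, x.min(), 1e-12]
    hi = [np.inf, x.max(), np.inf, np.inf, x.max(), np.inf]
    popt, _ = optimize.curve_fit(
        _two_gaussians, centers, hist, p0=p0, bounds=(lo, hi), maxfev=50000
    )
    a1, m1, s1, a2, m2, s2 = (float(v) for v in popt)
    c_lo = GaussianComponent(m1, abs(s1), a1)
    c_hi = GaussianComponent(m2, abs(s2), a2)
    if c_lo.mu > c_hi.mu:
        c_lo, c_hi = c_hi, c_lo
    resid = float(np.sum((_two_gaussians(centers, *popt) - hist) ** 2))

    separable = abs(c_hi.mu - c_lo.mu) >= (c_lo.sigma + c_hi.sigma)
    x0 = None
    if separable:
        try:
            x0 = gaussian_intersection(c_lo, c_hi)
        except NoCrossingError:
            separable = False
    return BimodalFit(c_lo, c_hi, x0, resid, separable=separable)


def gaussian_intersection(
    lower: GaussianComponent, upper: GaussianComponent
) -> float:
    """Density crossing point between the two component means.

    Solves the log-density equality analytically (a quadratic in x) and
    returns the root inside (lower.mu, upper.mu); falls back to a bracketed
    numeric solve for the equal-sigma (linear) case.
    """
    if lower.mu >= upper.mu:
        raise ValueError("components must be ordered by mean")
    a1, m1, s1 = lower.amplitude, lower.mu, lower.sigma
    a2, m2, s2 = upper.amplitude, upper.mu, upper.sigma
    if a1 <= 0 or a2 <= 0:
        raise ValueError("both amplitudes must be positive")

    # log a1 - (x-m1)^2/(2 s1^2) = log a2 - (x-m2)^2/(2 s2^2)
    A = 1.0 / (2 * s2**2) - 1.0 / (2 * s1**2)
    B = m1 / s1**2 - m2 / s2**2
    C = m2**2 / (2 * s2**2) - m1**2 / (2 * s1**2) + math.log(a1 / a2)
    if abs(A) < 1e-300:
        if abs(B) < 1e-300:
            raise ValueError("identical components have no unique crossing")
        roots = [-C / B]
    else:
        disc = B**2 - 4 * A * C
        if disc < 0:
            roots = []
        else:
            sq = math.sqrt(disc)
            roots = [(-B - sq) / (2 * A), (-B + sq) / (2 * A)]
    inside = [r for r in roots if m1 < r < m2]
    if inside:
        return float(inside[0] if len(inside) == 1 else min(inside, key=lambda r: abs(r - 0.5 * (m1 + m2))))

    # numeric fallback when the quadratic is ill-conditioned: the density
    # difference must change sign between the means for a crossing to exist
    f = lambda q: lower.density(q) - upper.density(q)
    if f(m1) * f(m2) > 0:
        raise NoCrossingError(
            "densities do not cross between the component means "
            "(amplitudes too unequal for a separating threshold)"
        )
    return float(optimize.brentq(f, m1, m2))


# ---------------------------------------------------------------------------
# Inversion
# ---------------------------------------------------------------------------


def invert_to_harmonic(
    component: GaussianComponent,
    temperature: float = DEFAULT_TEMPERATURE,
    kind: str = "bond",
    beads: tuple = (),
) -> BondedParameter:
    """Invert a fitted Gaussian to a harmonic bonded parameter.

    eq_value = mu; force constant = kB*T / sigma^2. For angles/dihedrals the
    sigma (degrees) is converted to radians so the constant comes out in
    kJ mol^-1 rad^-2, the GROMACS convention; eq_value stays in degrees.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if kind not in ("bond", "angle", "dihedral"):
        raise ValueError(f"unknown term kind {kind!r}")
    sigma = component.sigma
    if kind in ("angle", "dihedral"):
        sigma = math.radians(sigma)
    k = KB * temperature / sigma**2
    return BondedParameter(
        kind=kind,
        beads=tuple(beads),
        eq_value=component.mu,
        force_constant=k,
        funct=1,
        source="equilibrium_inversion",
        meta={"temperature": temperature, "sigma": component.sigma},
    )


def apply_fine_tuning(param: BondedParameter, override_k: float) -> BondedParameter:
    """Replace the force constant by a value fitted under load.

    Both the original and the override are retained in the metadata so the
    provenance of every emitted constant stays traceable.
    """
    if override_k <= 0:
        raise ValueError("override force constant must be positive")
    meta = dict(param.meta)
    meta["equilibrium_force_constant"] = param.force_constant
    meta["previous_source"] = param.source
    return replace(
        param, force_constant=float(override_k), source="force_fine_tuned", meta=meta
    )


def default_bond_threshold() -> float:
    """Documented default bond-class threshold (nm): the density crossing
    of the two backbone bond-length components."""
    return BOND_CLASS_THRESHOLD
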