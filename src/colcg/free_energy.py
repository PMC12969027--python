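"""Equilibrium free energies from nonequilibrium work distributions.

The Crooks fluctuation theorem relates forward and reverse work
distributions, P_F(W) / P_R(-W) = exp[(W - dG)/kB T]. Its maximum-likelihood
estimator (equivalent to the Bennett acceptance ratio) solves a
self-consistent Fermi-function balance for dG. Uncertainties come from
bootstrap resampling of both work sets.

Sign convention: ``forward_work`` is the work to couple the solute into the
solvent (vacuum -> solvated); ``backward_work`` is the work of the reverse
(decoupling) process as recorded, so Crooks-consistent reverse samples have
mean close to -dG (plus dissipation).

Transfer free energies between two solvents follow by subtraction
(ddG = dG_solvent2 - dG_solvent1), and the octanol/water partition
coefficient is logP = -ddG_{W->O} / (ln(10) R T), negative for hydrophilic
solutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .constants import KB, R_GAS, DEFAULT_TEMPERATURE


class NonOverlappingWorkError(RuntimeError):
    pass


@dataclass
class WorkSet:
    """Forward/backward nonequilibrium work samples (kJ/mol) at one T."""

    forward_work: np.ndarray
    backward_work: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        self.forward_work = np.asarray(self.forward_work, dtype=float).ravel()
        self.backward_work = np.asarray(self.backward_work, dtype=float).ravel()
        if self.forward_work.size == 0 or self.backward_work.size == 0:
            raise ValueError("both work arrays must be non-empty")
        if not (
            np.all(np.isfinite(self.forward_work))
            and np.all(np.isfinite(self.backward_work))
        ):
            raise ValueError("work values must be finite")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    def swapped(self) -> "WorkSet":
        """Exchange the roles of the two directions (negates dG)."""
        return WorkSet(self.backward_work, self.forward_work, self.temperature)


@dataclass
class FreeEnergyEstimate:
    dg: float  # kJ/mol
    se: float  # kJ/mol, bootstrap or propagated
    n_forward: int
    n_backward: int
    temperature: float = DEFAULT_TEMPERATURE
    overlap_warning: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("standard error must be non-negative")


def _bar_imbalance(dg: float, wf: np.ndarray, wr_fwd: np.ndarray, beta: float) -> float:
    """ML score whose root is dG.

    ``wr_fwd`` holds the reverse samples expressed in the forward frame,
    i.e. -backward_work. With M = ln(nF/nR) and the Fermi function
    f(x) = 1/(1+exp(x)):

        sum_F f(M + beta (W_i - dG)) - sum_R f(-M - beta (W_j - dG)) = 0
    """
    n_f, n_r = wf.size, wr_fwd.size
    m = math.log(n_f / n_r)
    xf = m + beta * (wf - dg)
    xr = -m - beta * (wr_fwd - dg)
    # numerically stable Fermi function
    return float(_fermi(xf).sum() - _fermi(xr).sum())


def _fermi(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = np.exp(-x[pos]) / (1.0 + np.exp(-x[pos]))
    out[~pos] = 1.0 / (1.0 + np.exp(x[~pos]))
    return out


def _overlap_measure(wf: np.ndarray, wr_fwd: np.ndarray) -> float:
    """Fraction of each distribution's span overlapping the other."""
    lo = max(wf.min(), wr_fwd.min())
    hi = min(wf.max(), wr_fwd.max())
    if hi < lo:
        return 0.0
    span = max(wf.max(), wr_fwd.max()) - min(wf.min(), wr_fwd.min())
    return float((hi - lo) / span) if span > 0 else 1.0


def _solve_bar(wf: np.ndarray, wr_fwd: np.ndarray, beta: float) -> float:
    lo = float(min(wf.min(), wr_fwd.min())) - 50.0
    hi = float(max(wf.max(), wr_fwd.max())) + 50.0
    f_lo = _bar_imbalance(lo, wf, wr_fwd, beta)
    f_hi = _bar_imbalance(hi, wf, wr_fwd, beta)
    # the score is monotonically increasing in dG; expand if needed
    tries = 0
    while f_lo * f_hi > 0 and tries < 10:
        lo -= 200.0
        hi += 200.0
        f_lo = _bar_imbalance(lo, wf, wr_fwd, beta)
        f_hi = _bar_imbalance(hi, wf, wr_fwd, beta)
        tries += 1
    if f_lo * f_hi > 0:
        raise RuntimeError("could not bracket the maximum-likelihood root")
    return float(optimize.brentq(
        lambda g: _bar_imbalance(g, wf, wr_fwd, beta), lo, hi, xtol=1e-8
    ))


def ml_estimate(
    work: WorkSet,
    n_bootstrap: int = 1000,
    seed: int = 0,
    overlap_tolerance: float = 1e-3,
) -> FreeEnergyEstimate:
    """Crooks maximum-likelihood (BAR) estimate of dG with bootstrap SE.

    Requires at least 10 samples per direction. When the forward and
    reversed-backward work distributions do not overlap the estimate is
    still returned but flagged, since the ML solution then rests on
    exponential extrapolation.
    """
    wf = work.forward_work
    wr = work.backward_work
    if wf.size < 10 or wr.size < 10:
        raise ValueError("need >= 10 work samples in each direction")
    beta = 1.0 / (KB * work.temperature)
    wr_fwd = -wr  # reverse samples expressed in the forward frame

    dg = _solve_bar(wf, wr_fwd, beta)
    warn = _overlap_measure(wf, wr_fwd) < overlap_tolerance

    rng = np.random.default_rng(seed)
    boots = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        bf = wf[rng.integers(0, wf.size, wf.size)]
        br = wr_fwd[rng.integers(0, wr.size, wr.size)]
        boots[b] = _solve_bar(bf, br, beta)
    se = float(boots.std(ddof=1)) if n_bootstrap > 1 else 0.0

    return FreeEnergyEstimate(
        dg=dg,
        se=se,
        n_forward=int(wf.size),
        n_backward=int(wr.size),
        temperature=work.temperature,
        overlap_warning=warn,
        meta={"n_bootstrap": n_bootstrap, "seed": seed},
    )


def ddg(dg_s2: FreeEnergyEstimate, dg_s1: FreeEnergyEstimate) -> FreeEnergyEstimate:
    """Transfer free energy S1 -> S2: dG_s2 - dG_s1 with quadrature SE."""
    if abs(dg_s2.temperature - dg_s1.temperature) > 1e-9:
        raise ValueError(
            f"temperature mismatch: {dg_s2.temperature} vs {dg_s1.temperature}"
        )
    return FreeEnergyEstimate(
        dg=dg_s2.dg - dg_s1.dg,
        se=math.hypot(dg_s2.se, dg_s1.se),
        n_forward=min(dg_s2.n_forward, dg_s1.n_forward),
        n_backward=min(dg_s2.n_backward, dg_s1.n_backward),
        temperature=dg_s1.temperature,
        overlap_warning=dg_s2.overlap_warning or dg_s1.overlap_warning,
        meta={"operation": "ddg"},
    )


def logp(
    ddg_w_to_o: float,
    temperature: float = DEFAULT_TEMPERATURE,
    hydrophilic_negative: bool = True,
) -> float:
    """Partition coefficient from a water->octanol transfer free energy.

    Default convention: logP = -ddG_{W->O} / (ln(10) R T), so a compound
    that prefers water (positive transfer free energy into octanol) gets a
    negative logP. Setting ``hydrophilic_negative=False`` flips the sign.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    value = -ddg_w_to_o / (math.log(10.0) * R_GAS * temperature)
    return value if hydrophilic_negative else -value


# ---------------------------------------------------------------------------
# Plain-text work file I/O
# ---------------------------------------------------------------------------


def read_work_file(path) -> np.ndarray:
    """Read work values (kJ/mol), one per line; '#' comments allowed."""
    vals = []
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#")[0].strip()
            if not line:
                continue
            vals.append(float(line.split()[-1]))
    if not vals:
        raise ValueError(f"{path}: no work values found")
    return np.asarray(vals, dtype=float)


def load_work_set(forward_path, backward_path, temperature=DEFAULT_TEMPERATURE) -> WorkSet:
    return WorkSet(
        forward_work=read_work_file(forward_path),
        backward_work=read_work_file(backward_path),
        temperature=temperature,
    )
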