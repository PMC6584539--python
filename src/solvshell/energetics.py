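"""Solute-solvent interaction energies and diffusion coefficients.

Nonbonded energies use the CHARMM functional forms: a 12-6
Lennard-Jones term with Lorentz-Berthelot combining (geometric-mean
well depth, arithmetic Rmin) and a real-space Coulomb term, both
multiplied by the CHARMM switching polynomial between r_on = 10 A and
r_off = 12 A and zero beyond the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Trajectory, minimum_image, solute_center_of_mass
from .errors import (
    AnalysisWindowError,
    InsufficientDataError,
    InvalidSwitchError,
    SingularPairError,
)
from .stats import block_standard_error

#: Coulomb constant in kcal A / (mol e^2), CHARMM convention
COULOMB_CONSTANT = 332.0636
R_ON_DEFAULT = 10.0
R_OFF_DEFAULT = 12.0


def switching_factor(r, r_on: float = R_ON_DEFAULT, r_off: float = R_OFF_DEFAULT):
    """CHARMM switching function: 1 below r_on, 0 beyond r_off.

    Between the two radii,
    S(r) = (r_off^2 - r^2)^2 (r_off^2 + 2 r^2 - 3 r_on^2) / (r_off^2 - r_on^2)^3,
    which is continuous and once differentiable at both boundaries.
    """
    if r_on >= r_off:
        raise InvalidSwitchError(f"r_on ({r_on}) must be < r_off ({r_off})")
    r = np.asarray(r, dtype=float)
    r2 = r * r
    ron2, roff2 = r_on * r_on, r_off * r_off
    s = (roff2 - r2) ** 2 * (roff2 + 2 * r2 - 3 * ron2) / (roff2 - ron2) ** 3
    out = np.where(r <= r_on, 1.0, np.where(r >= r_off, 0.0, s))
    return float(out) if out.ndim == 0 else out


def combine_lj(eps_i, eps_j, rmin_half_i, rmin_half_j):
    """Lorentz-Berthelot: geometric-mean epsilon, summed Rmin halves."""
    return np.sqrt(np.asarray(eps_i) * np.asarray(eps_j)), (
        np.asarray(rmin_half_i) + np.asarray(rmin_half_j)
    )


def pair_energy(atom_i, atom_j, r: float,
                r_on: float = R_ON_DEFAULT, r_off: float = R_OFF_DEFAULT):
    """Switched (electrostatic, Lennard-Jones) energy of one atom pair."""
    if r <= 0:
        raise SingularPairError(f"pair distance must be positive, got {r}")
    eps, rmin = combine_lj(atom_i.lj_epsilon, atom_j.lj_epsilon,
                           atom_i.lj_rmin_half, atom_j.lj_rmin_half)
    s = switching_factor(r, r_on, r_off)
    if r >= r_off:
        return 0.0, 0.0
    elec = COULOMB_CONSTANT * atom_i.charge * atom_j.charge / r * s
    x6 = (rmin / r) ** 6
    lj = eps * (x6 * x6 - 2.0 * x6) * s
    return float(elec), float(lj)


@dataclass
class EnergyBreakdown:
    """Per-frame solute-solvent energy components plus ensemble summary."""

    total: np.ndarray          # kcal/mol per frame
    electrostatic: np.ndarray
    lennard_jones: np.ndarray

    @property
    def mean_total(self) -> float:
        return float(self.total.mean())

    @property
    def mean_electrostatic(self) -> float:
        return float(self.electrostatic.mean())

    @property
    def mean_lennard_jones(self) -> float:
        return float(self.lennard_jones.mean())

    @property
    def stderr_total(self) -> float:
        return block_standard_error(self.total)

    @property
    def stderr_electrostatic(self) -> float:
        return block_standard_error(self.electrostatic)

    @property
    def stderr_lennard_jones(self) -> float:
        return block_standard_error(self.lennard_jones)


def solute_solvent_energy(
    trajectory: Trajectory,
    discard_fraction: float = 0.2,
    r_on: float = R_ON_DEFAULT,
    r_off: float = R_OFF_DEFAULT,
) -> EnergyBreakdown:
    """Sum switched pair energies over all solute-solvent atom pairs.

    The first ``discard_fraction`` of frames is treated as
    equilibration and dropped before averaging.
    """
    n = len(trajectory)
    start = int(np.floor(discard_fraction * n))
    if start >= n:
        raise AnalysisWindowError(
            f"discarding {start} of {n} frames leaves nothing to analyze"
        )
    top = trajectory.topology
    si = top.solute_indices
    vi = np.flatnonzero(top.molecule_ids != top.solute_molecule_id)
    qq = COULOMB_CONSTANT * np.outer(top.charges[si], top.charges[vi])
    eps, rmin = combine_lj(
        top.lj_epsilon[si][:, None], top.lj_epsilon[vi][None, :],
        top.lj_rmin_half[si][:, None], top.lj_rmin_half[vi][None, :],
    )
    elec_t, lj_t = [], []
    for frame in trajectory.frames[start:]:
        d = minimum_image(
            frame.positions[si][:, None, :] - frame.positions[vi][None, :, :],
            frame.box,
        )
        r = np.sqrt((d * d).sum(axis=-1))
        inside = r < r_off
        s = np.zeros_like(r)
        s[inside] = switching_factor(r[inside], r_on, r_off)
        with np.errstate(divide="ignore"):
            e = np.where(inside, qq / np.where(inside, r, 1.0) * s, 0.0)
        x6 = np.where(inside, (rmin / np.where(inside, r, 1.0)) ** 6, 0.0)
        lj = eps * (x6 * x6 - 2.0 * x6) * s
        elec_t.append(float(e.sum()))
        lj_t.append(float(lj.sum()))
    elec = np.array(elec_t)
    lj = np.array(lj_t)
    return EnergyBreakdown(total=elec + lj, electrostatic=elec, lennard_jones=lj)


def relative_energy(
    breakdowns: dict, reference
) -> dict:
    """Mean energies relative to a reference environment (e.g. 0 M).

    Returns per-key (d_total, d_elec, d_lj); the reference maps to
    (0, 0, 0) by construction.
    """
    ref = breakdowns[reference]
    out = {}
    for key, b in breakdowns.items():
        out[key] = (
            b.mean_total - ref.mean_total,
            b.mean_electrostatic - ref.mean_electrostatic,
            b.mean_lennard_jones - ref.mean_lennard_jones,
        )
    return out


# ---------------------------------------------------------------------------
# diffusion
# ---------------------------------------------------------------------------

@dataclass
class DiffusionResult:
    D: float                   # A^2/ps
    fit_window: tuple          # (t_min, t_max) ps
    msd: np.ndarray            # MSD(tau)
    lags: np.ndarray           # tau grid, ps
    linearity_residual: float  # rms fit residual / mean MSD in window


def _msd_fft(x: np.ndarray) -> np.ndarray:
    """Time-origin-averaged MSD via the FFT autocorrelation identity."""
    n = x.shape[0]
    nfft = 1 << (2 * n - 1).bit_length()
    sq = (x * x).sum(axis=1)
    # S2: autocorrelation of each coordinate, summed over dimensions
    f = np.fft.rfft(x, n=nfft, axis=0)
    s2 = np.fft.irfft((f * f.conj()).real + 0j, n=nfft, axis=0)[:n].sum(axis=1)
    # S1 recursion
    sumsq = 2.0 * sq.sum()
    s1 = np.empty(n)
    for m in range(n):
        s1[m] = sumsq
        sumsq -= sq[m] + sq[n - 1 - m]
    return s1 / (n - np.arange(n)) - 2.0 * s2 / (n - np.arange(n))


def com_positions(trajectory: Trajectory) -> np.ndarray:
    """Solute COM per frame, stacked (n_frames, 3)."""
    return np.array([solute_center_of_mass(f, trajectory.topology) for f in trajectory])


def diffusion_coefficient(
    com_trajectory,
    dt: float | None = None,
    fit_window_fraction: tuple = (0.1, 0.5),
) -> DiffusionResult:
    """Einstein-relation diffusion coefficient D = slope(MSD)/6.

    ``com_trajectory`` is either a Trajectory (solute COM is taken,
    coordinates assumed unwrapped) or an (n, 3) array with ``dt``
    given. The MSD is averaged over all time origins; lags are capped
    at 0.5% of the trajectory length (the estimator's variance grows
    like lag/n, so long lags are mostly noise) and a straight line is
    fitted over the middle window of that range.
    """
    if isinstance(com_trajectory, Trajectory):
        x = com_positions(com_trajectory)
        dt = com_trajectory.dt
    else:
        x = np.asarray(com_trajectory, dtype=float)
        if dt is None:
            raise ValueError("dt required when passing a coordinate array")
    n = x.shape[0]
    if n < 100:
        raise InsufficientDataError(f"need >= 100 frames for MSD, got {n}")
    msd = _msd_fft(x)
    lags = np.arange(n) * dt
    n_max = max(n // 200, 20)
    lo = max(1, int(fit_window_fraction[0] * n_max))
    hi = max(lo + 2, int(fit_window_fraction[1] * n_max))
    t_fit = lags[lo:hi]
    m_fit = msd[lo:hi]
    slope, intercept = np.polyfit(t_fit, m_fit, 1)
    resid = m_fit - (slope * t_fit + intercept)
    rel = float(np.sqrt((resid**2).mean()) / max(abs(m_fit).mean(), 1e-300))
    return DiffusionResult(
        D=float(max(slope / 6.0, 0.0)),
        fit_window=(float(t_fit[0]), float(t_fit[-1])),
        msd=msd,
        lags=lags,
        linearity_residual=rel,
    )
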