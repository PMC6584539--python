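"""Two-step thermodynamic integration with soft-core Lennard-Jones.

Solvation free energies are computed along the two-step coupling path
U(s=0, g=0) -> U(s=1, g=0) -> U(s=1, g=1): the Lennard-Jones cross
term is scaled up first (s-leg, with a Beutler soft core so the r -> 0
end point stays finite), then the electrostatic cross term (g-leg,
plain Coulomb, since the LJ core is already fully on). Each leg's
free-energy contribution is the lambda-integral of <dU/dlambda>,
estimated from Metropolis sampling of desk-scale toy systems with
analytically known answers; the forward/backward sum (hysteresis)
diagnoses convergence. Transfer free energies between two solvent
environments follow from the difference of two solvation runs
(closing a thermodynamic cycle whose gas legs cancel).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energetics import COULOMB_CONSTANT
from .errors import InvalidSoftCoreError, ScheduleError

HYSTERESIS_TOLERANCE = 0.5  # kcal/mol


# ---------------------------------------------------------------------------
# lambda schedule
# ---------------------------------------------------------------------------

@dataclass
class LambdaPoint:
    lam: float                 # progress variable within the leg, in (0, 1]
    s: float                   # LJ scaling
    g: float                   # electrostatic scaling
    leg: str                   # "lj" | "elec"
    mean_dudl: float = float("nan")
    stderr: float = float("nan")
    n_samples: int = 0


def lambda_schedule(n_per_leg: int = 100) -> list[LambdaPoint]:
    """Two-leg scaffold: s ramps 1/n..1 with g=0, then g ramps with s=1."""
    if n_per_leg < 1:
        raise ScheduleError("n_per_leg must be >= 1")
    lams = np.arange(1, n_per_leg + 1) / n_per_leg
    points = [LambdaPoint(lam=float(x), s=float(x), g=0.0, leg="lj") for x in lams]
    points += [LambdaPoint(lam=float(x), s=1.0, g=float(x), leg="elec") for x in lams]
    return points


# ---------------------------------------------------------------------------
# soft-core LJ
# ---------------------------------------------------------------------------

def _sigma6(r_min: float) -> float:
    return (r_min / 2.0 ** (1.0 / 6.0)) ** 6


def soft_core_lj(r, s: float, epsilon: float, r_min: float, alpha: float = 0.5):
    """Beutler soft-core LJ: finite at r=0 for s<1, s x standard LJ at s=1.

    With sigma^6 = (r_min / 2^(1/6))^6 and D = alpha (1-s) sigma^6 + r^6:
    U = 4 eps s (sigma^12 / D^2 - sigma^6 / D).
    """
    if alpha < 0:
        raise InvalidSoftCoreError(f"alpha must be >= 0, got {alpha}")
    r = np.asarray(r, dtype=float)
    s6 = _sigma6(r_min)
    d = alpha * (1.0 - s) * s6 + r**6
    u = 4.0 * epsilon * s * (s6**2 / d**2 - s6 / d)
    return float(u) if u.ndim == 0 else u


def soft_core_lj_dds(r, s: float, epsilon: float, r_min: float, alpha: float = 0.5):
    """Analytic d/ds of the soft-core LJ (prefactor and core both move)."""
    if alpha < 0:
        raise InvalidSoftCoreError(f"alpha must be >= 0, got {alpha}")
    r = np.asarray(r, dtype=float)
    s6 = _sigma6(r_min)
    d = alpha * (1.0 - s) * s6 + r**6
    base = 4.0 * epsilon * (s6**2 / d**2 - s6 / d)
    # dD/ds = -alpha sigma^6
    core = 4.0 * epsilon * s * alpha * s6 * (2.0 * s6**2 / d**3 - s6 / d**2)
    out = base + core
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# coupled cross energy
# ---------------------------------------------------------------------------

@dataclass
class PairTable:
    """Combined parameters of the solute-solvent cross pairs."""

    q_product: np.ndarray      # q_i q_j, e^2
    epsilon: np.ndarray        # combined well depth, kcal/mol
    r_min: np.ndarray          # combined Rmin, A
    alpha: float = 0.5

    def __post_init__(self):
        self.q_product = np.atleast_1d(np.asarray(self.q_product, dtype=float))
        self.epsilon = np.atleast_1d(np.asarray(self.epsilon, dtype=float))
        self.r_min = np.atleast_1d(np.asarray(self.r_min, dtype=float))


def coupling_energy(pairs: PairTable, r: np.ndarray, s: float, g: float) -> float:
    """Cross-term energy s U_LJ (soft core) + g U_elec at distances r.

    Self terms of either subsystem are lambda-independent and excluded
    by construction. The electrostatic term is plain Coulomb: the
    schedule only raises g once the LJ core is fully on.
    """
    r = np.atleast_1d(np.asarray(r, dtype=float))
    lj = sum(
        soft_core_lj(ri, s, eps, rm, pairs.alpha)
        for ri, eps, rm in zip(r, pairs.epsilon, pairs.r_min)
    )
    elec = g * float((COULOMB_CONSTANT * pairs.q_product / r).sum()) if g else 0.0
    return float(lj + elec)


def coupling_dudl(pairs: PairTable, r: np.ndarray, s: float, g: float, leg: str) -> float:
    """dU/dlambda of the cross term along the active leg."""
    r = np.atleast_1d(np.asarray(r, dtype=float))
    if leg == "lj":
        return float(
            sum(
                soft_core_lj_dds(ri, s, eps, rm, pairs.alpha)
                for ri, eps, rm in zip(r, pairs.epsilon, pairs.r_min)
            )
        )
    if leg == "elec":
        return float((COULOMB_CONSTANT * pairs.q_product / r).sum())
    raise ScheduleError(f"unknown leg {leg!r}")


# ---------------------------------------------------------------------------
# Metropolis toy sampler
# ---------------------------------------------------------------------------

@dataclass
class SampleResult:
    samples: np.ndarray        # (n_production, n_walkers, dim)
    acceptance_rate: float
    final: np.ndarray          # (n_walkers, dim) last configurations


def sample_toy_system(
    energy_fn,
    kT: float,
    n_steps: int,
    seed_or_rng,
    x0: np.ndarray,
    step_size: float = 0.5,
    burn_in: int = 100,
) -> SampleResult:
    """Metropolis random walk, vectorized over independent walkers.

    ``energy_fn`` maps (n_walkers, dim) -> (n_walkers,) energies in
    kcal/mol; ``n_steps`` counts production sweeps after ``burn_in``.
    Bit-reproducible for a fixed seed.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    x = np.array(x0, dtype=float, copy=True)
    if x.ndim == 1:
        x = x[None, :]
    e = np.asarray(energy_fn(x), dtype=float)
    n_walkers, dim = x.shape
    accepted = 0
    proposed = 0
    samples = np.empty((n_steps, n_walkers, dim))
    for step in range(burn_in + n_steps):
        trial = x + rng.uniform(-step_size, step_size, size=x.shape)
        e_trial = np.asarray(energy_fn(trial), dtype=float)
        if kT > 0:
            accept = rng.random(n_walkers) < np.exp(
                np.clip(-(e_trial - e) / kT, -700, 0)
            )
        else:
            accept = e_trial <= e  # zero-temperature limit: only downhill
        x[accept] = trial[accept]
        e[accept] = e_trial[accept]
        if step >= burn_in:
            accepted += int(accept.sum())
            proposed += n_walkers
            samples[step - burn_in] = x
    return SampleResult(
        samples=samples,
        acceptance_rate=accepted / max(proposed, 1),
        final=x.copy(),
    )


# ---------------------------------------------------------------------------
# TI quadrature
# ---------------------------------------------------------------------------

@dataclass
class TIResult:
    delta_g: float             # kcal/mol
    stderr: float
    direction: str             # forward | backward
    per_leg: dict = field(default_factory=dict)
    quadrature: str = "trapezoid"


def _integrate_leg(lams: np.ndarray, means: np.ndarray, errs: np.ndarray):
    """Trapezoid over [0, 1]; the integrand is linearly extrapolated to
    lambda=0 (and to 1) from the nearest two points when the grid does
    not reach the boundary, keeping the rule exact for linear data."""
    order = np.argsort(lams)
    lams, means, errs = lams[order], means[order], errs[order]
    if np.any(np.diff(lams) <= 0):
        raise ScheduleError("duplicate lambda values within a leg")
    errs = np.where(np.isfinite(errs), errs, 0.0)
    if lams[0] > 0.0:
        if lams.size >= 2:
            slope = (means[1] - means[0]) / (lams[1] - lams[0])
            m0 = means[0] - slope * lams[0]
        else:
            m0 = means[0]
        lams = np.r_[0.0, lams]
        means = np.r_[m0, means]
        errs = np.r_[errs[0], errs]
    if lams[-1] < 1.0:
        if lams.size >= 2:
            slope = (means[-1] - means[-2]) / (lams[-1] - lams[-2])
            m1 = means[-1] + slope * (1.0 - lams[-1])
        else:
            m1 = means[-1]
        lams = np.r_[lams, 1.0]
        means = np.r_[means, m1]
        errs = np.r_[errs, errs[-1]]
    dg = float(np.trapezoid(means, lams))
    w = np.zeros_like(lams)
    dl = np.diff(lams)
    w[:-1] += dl / 2
    w[1:] += dl / 2
    err = float(np.sqrt(((w * errs) ** 2).sum()))
    return dg, err


def ti_integrate(points: list[LambdaPoint], direction: str = "forward") -> TIResult:
    """Per-leg trapezoidal quadrature of <dU/dlambda>, legs summed."""
    if not points:
        raise ScheduleError("no lambda points")
    legs: dict[str, list[LambdaPoint]] = {}
    for p in points:
        legs.setdefault(p.leg, []).append(p)
    total = 0.0
    var = 0.0
    per_leg = {}
    for leg, pts in legs.items():
        lams = np.array([p.lam for p in pts])
        means = np.array([p.mean_dudl for p in pts])
        errs = np.array([p.stderr for p in pts])
        if np.any(~np.isfinite(means)):
            raise ScheduleError(f"leg {leg!r} has unsampled lambda points")
        dg, err = _integrate_leg(lams, means, errs)
        per_leg[leg] = (dg, err)
        total += dg
        var += err**2
    return TIResult(delta_g=total, stderr=float(np.sqrt(var)),
                    direction=direction, per_leg=per_leg)


def hysteresis(forward: TIResult, backward: TIResult,
               tolerance: float = HYSTERESIS_TOLERANCE):
    """|dG_fwd + dG_bwd| and a convergence flag (backward path reversed)."""
    h = abs(forward.delta_g + backward.delta_g)
    return h, h < tolerance


def transfer_free_energy(dg_solv_water: float, dg_solv_urea: float) -> float:
    """ddG(transfer) = dG_solv(urea env) - dG_solv(water env); negative
    means the cosolvent environment is favored."""
    return float(dg_solv_urea - dg_solv_water)


# ---------------------------------------------------------------------------
# built-in toy systems with analytic answers
# ---------------------------------------------------------------------------

@dataclass
class HarmonicLambdaSystem:
    """U(lambda, x) = 0.5 (k0 + lambda (k1 - k0)) x^2 in ``dim`` dimensions.

    Exact free-energy change per dimension: (kT/2) ln(k1/k0).
    """

    k0: float
    k1: float
    dim: int = 1

    def k(self, lam: float) -> float:
        return self.k0 + lam * (self.k1 - self.k0)

    def energy(self, lam: float):
        k = self.k(lam)

        def f(x):
            return 0.5 * k * (x * x).sum(axis=-1)

        return f

    def dudl(self, x: np.ndarray) -> np.ndarray:
        return 0.5 * (self.k1 - self.k0) * (x * x).sum(axis=-1)

    def analytic_delta_g(self, kT: float) -> float:
        return 0.5 * kT * self.dim * float(np.log(self.k1 / self.k0))


def _block_se(series: np.ndarray, n_blocks: int = 5) -> float:
    n = series.size
    if n < n_blocks * 2:
        return float(series.std(ddof=1) / np.sqrt(max(n, 2)))
    m = n // n_blocks
    b = series[: m * n_blocks].reshape(n_blocks, m).mean(axis=1)
    return float(b.std(ddof=1) / np.sqrt(n_blocks))


def ti_harmonic(
    system: HarmonicLambdaSystem,
    kT: float = 1.0,
    n_lambda: int = 100,
    n_production: int = 600,
    n_burn_in: int = 100,
    n_walkers: int = 8,
    seed: int = 0,
    direction: str = "forward",
) -> TIResult:
    """TI of the lambda-scaled harmonic well with the built-in sampler.

    The backward direction traverses lambda 1 -> 0 (its own progress
    variable runs k1 -> k0), so forward and backward free energies sum
    to zero for a converged run.
    """
    rng = np.random.default_rng(seed)
    lams = np.arange(1, n_lambda + 1) / n_lambda
    sys_eff = (
        system
        if direction == "forward"
        else HarmonicLambdaSystem(system.k1, system.k0, system.dim)
    )
    sigma0 = np.sqrt(kT / min(sys_eff.k0, sys_eff.k1))
    x = rng.normal(0.0, sigma0, size=(n_walkers, sys_eff.dim))
    points = []
    for lam in lams:
        step = 2.0 * np.sqrt(kT / sys_eff.k(lam))
        res = sample_toy_system(
            sys_eff.energy(lam), kT, n_production, rng, x,
            step_size=step, burn_in=n_burn_in,
        )
        x = res.final
        du = sys_eff.dudl(res.samples).mean(axis=1)  # per-step walker mean
        points.append(
            LambdaPoint(
                lam=float(lam), s=float(lam), g=0.0, leg="harmonic",
                mean_dudl=float(du.mean()), stderr=_block_se(du),
                n_samples=du.size * n_walkers,
            )
        )
    return ti_integrate(points, direction=direction)


@dataclass
class ToySolvationSystem:
    """One fixed solute particle plus a few mobile solvent particles.

    Periodic cubic box; solvent-solvent interactions (plain LJ +
    Coulomb) are always fully on and form the lambda-independent
    self-term; the solute-solvent cross term carries the (s, g)
    coupling with the soft-core LJ.
    """

    box: float = 12.0
    n_solvent: int = 2
    solute_epsilon: float = 0.2
    solute_rmin: float = 3.5
    solute_charge: float = 0.3
    solvent_epsilon: float = 0.15
    solvent_rmin: float = 3.2
    solvent_charge: float = -0.15
    alpha: float = 0.5

    def pair_table(self) -> PairTable:
        n = self.n_solvent
        return PairTable(
            q_product=np.full(n, self.solute_charge * self.solvent_charge),
            epsilon=np.full(n, np.sqrt(self.solute_epsilon * self.solvent_epsilon)),
            r_min=np.full(n, (self.solute_rmin + self.solvent_rmin) / 2.0),
            alpha=self.alpha,
        )

    def _min_image(self, d):
        return d - self.box * np.floor(d / self.box + 0.5)

    def cross_distances(self, x: np.ndarray) -> np.ndarray:
        """Solvent distances to the solute at the origin; x is
        (n_walkers, 3 * n_solvent)."""
        pos = x.reshape(x.shape[0], self.n_solvent, 3)
        d = self._min_image(pos)
        return np.sqrt((d * d).sum(axis=-1))

    def _solvent_self_energy(self, pos: np.ndarray) -> np.ndarray:
        n = self.n_solvent
        e = np.zeros(pos.shape[0])
        qq = COULOMB_CONSTANT * self.solvent_charge**2
        s6 = _sigma6(self.solvent_rmin)
        for i in range(n):
            for j in range(i + 1, n):
                d = self._min_image(pos[:, i] - pos[:, j])
                r = np.sqrt((d * d).sum(axis=-1))
                r = np.maximum(r, 0.5)
                r6 = r**6
                e += 4.0 * self.solvent_epsilon * (s6**2 / r6**2 - s6 / r6)
                e += qq / r
        return e

    def _cross_params(self):
        eps = np.sqrt(self.solute_epsilon * self.solvent_epsilon)
        rmin = (self.solute_rmin + self.solvent_rmin) / 2.0
        qq = self.solute_charge * self.solvent_charge
        return eps, rmin, qq

    def energy(self, s: float, g: float):
        eps, rmin, qq = self._cross_params()

        def f(x):
            pos = x.reshape(x.shape[0], self.n_solvent, 3)
            r = np.maximum(self.cross_distances(x), 1e-3)
            cross = soft_core_lj(r, s, eps, rmin, self.alpha).sum(axis=-1)
            if g:
                cross = cross + g * (COULOMB_CONSTANT * qq / r).sum(axis=-1)
            return cross + self._solvent_self_energy(pos)

        return f

    def dudl(self, x: np.ndarray, s: float, g: float, leg: str) -> np.ndarray:
        eps, rmin, qq = self._cross_params()
        r = np.maximum(self.cross_distances(x), 1e-3)
        if leg == "lj":
            return soft_core_lj_dds(r, s, eps, rmin, self.alpha).sum(axis=-1)
        if leg == "elec":
            return (COULOMB_CONSTANT * qq / r).sum(axis=-1)
        raise ScheduleError(f"unknown leg {leg!r}")


def ti_solvation(
    system: ToySolvationSystem,
    kT: float = 0.6,
    n_per_leg: int = 20,
    n_production: int = 600,
    n_burn_in: int = 100,
    n_walkers: int = 8,
    seed: int = 0,
    direction: str = "forward",
) -> TIResult:
    """Two-step solvation TI (LJ leg then electrostatic leg) on the toy
    system; backward runs the schedule in reverse from the coupled state."""
    rng = np.random.default_rng(seed)
    schedule = lambda_schedule(n_per_leg)
    if direction == "backward":
        schedule = list(reversed(schedule))
    dim = 3 * system.n_solvent
    x = rng.uniform(-system.box / 2, system.box / 2, size=(n_walkers, dim))
    points = []
    for p in schedule:
        res = sample_toy_system(
            system.energy(p.s, p.g), kT, n_production, rng, x,
            step_size=0.8, burn_in=n_burn_in,
        )
        x = res.final
        t_n, w_n, dim_n = res.samples.shape
        du = system.dudl(
            res.samples.reshape(t_n * w_n, dim_n), p.s, p.g, p.leg
        ).reshape(t_n, w_n).mean(axis=1)
        points.append(
            LambdaPoint(
                lam=p.lam, s=p.s, g=p.g, leg=p.leg,
                mean_dudl=float(du.mean()), stderr=_block_se(du),
                n_samples=du.size * n_walkers,
            )
        )
    if direction == "backward":
        # dG along the reversed path: the integrand sign flips and the
        # per-leg quadrature re-sorts the lambda grid itself
        for q in points:
            q.mean_dudl = -q.mean_dudl
    return ti_integrate(points, direction=direction)
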