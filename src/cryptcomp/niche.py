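"""Stochastic niche competition in a single crypt.

A crypt niche holds a fixed number ``N`` of stem cells.  Replacement events
occur at total rate ``N * lam`` (each stem cell is replaced at rate ``lam``
per year): a dividing cell is chosen uniformly, its daughter inherits the
parent's type unless it mutates (wild-type -> benign with probability ``u``,
benign -> malignant with probability ``v``), and the daughter replaces a
competitor — any of the other ``N - 1`` cells under all-to-all competition
(:attr:`Arrangement.WELL_MIXED`) or one of the two ring neighbours of the
parent (:attr:`Arrangement.LINEAR_RING`).

Two absorbing outcomes exist.  If benign cells take over the whole niche the
crypt has clonally converted and seeds an adenoma (ADENOMA).  If a malignant
daughter arises first, its strong proliferative advantage lets it take over
the niche essentially instantaneously, so the first malignant mutation
absorbs the crypt directly into CARCINOMA (stochastic tunneling).

The chain over the benign-cell count ``i = 0..N-1`` plus the two absorbing
states is small, so its master equation is solved exactly: by spectral
decomposition of the (symmetrizable) tridiagonal transient block when the
mutation probabilities permit, and by stepwise matrix exponentials of the
full generator otherwise.  An event-driven cell-level simulator — which does
not use the single-clone reduction employed by the ring-topology chain —
serves as an independent Monte-Carlo referee.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh_tridiagonal, expm

__all__ = [
    "Arrangement",
    "NicheParams",
    "NicheGenerator",
    "CryptAbsorptionCurves",
    "CryptKernel",
    "NicheSimulationSummary",
    "ParameterDomainError",
    "build_generator",
    "solve_absorption",
    "simulate_niche",
    "default_time_grid",
]


class ParameterDomainError(ValueError):
    """A model parameter lies outside its admissible domain."""


class Arrangement(enum.Enum):
    """Limiting spatial arrangements of the stem cells in the niche."""

    WELL_MIXED = "well_mixed"
    LINEAR_RING = "linear_ring"


@dataclass(frozen=True)
class NicheParams:
    """Parameters of the crypt-level competition process.

    Parameters
    ----------
    N : int
        Number of stem cells in the niche (>= 2).
    u : float
        Probability per division that a wild-type daughter is benign.
    v : float
        Probability per division that a benign daughter is malignant.
    lam : float
        Effective replacement rate, per stem cell per year (> 0).
    arrangement : Arrangement
        Competition topology; all-to-all or one-dimensional ring.
    """

    N: int
    u: float
    v: float
    lam: float
    arrangement: Arrangement = Arrangement.WELL_MIXED

    def __post_init__(self) -> None:
        if not (isinstance(self.N, (int, np.integer)) and self.N >= 2):
            raise ParameterDomainError(f"N must be an integer >= 2, got {self.N!r}")
        if not 0.0 <= self.u <= 1.0:
            raise ParameterDomainError(f"u must lie in [0, 1], got {self.u!r}")
        if not 0.0 <= self.v <= 1.0:
            raise ParameterDomainError(f"v must lie in [0, 1], got {self.v!r}")
        if not self.lam > 0.0:
            raise ParameterDomainError(f"lam must be > 0, got {self.lam!r}")
        if not isinstance(self.arrangement, Arrangement):
            raise ParameterDomainError(
                f"arrangement must be an Arrangement member, got {self.arrangement!r}"
            )

    def with_lam(self, lam: float) -> "NicheParams":
        """Copy of these parameters with a different replacement rate."""
        return NicheParams(self.N, self.u, self.v, lam, self.arrangement)


def _transition_rates(
    N: int, u: float, v: float, lam: float, arrangement: Arrangement
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (up, down, carc) rate vectors over transient states i = 0..N-1.

    ``up[i]`` is the rate i -> i+1 (the move from i = N-1 lands in ADENOMA),
    ``down[i]`` the rate i -> i-1 (zero at i = 0) and ``carc[i]`` the rate of
    direct absorption into CARCINOMA through a malignant daughter.
    """
    i = np.arange(N, dtype=float)
    carc = lam * i * v
    if arrangement is Arrangement.WELL_MIXED:
        up = lam * ((1.0 - v) * i * (N - i) + u * (N - i) * (N - i - 1)) / (N - 1)
        down = lam * (1.0 - u) * (N - i) * i / (N - 1)
    elif arrangement is Arrangement.LINEAR_RING:
        # Single contiguous-clone reduction: only the clone boundaries move.
        up = np.full(N, lam * (1.0 - v))
        up[0] = N * lam * u
        down = np.full(N, lam * (1.0 - u))
        down[0] = 0.0
    else:  # pragma: no cover - guarded by NicheParams validation
        raise ParameterDomainError(f"unknown arrangement {arrangement!r}")
    return up, down, carc


@dataclass(frozen=True)
class NicheGenerator:
    """Continuous-time Markov generator of the benign-count chain.

    States are ordered ``0..N-1`` (transient benign-cell counts), then
    ADENOMA (index ``N``) and CARCINOMA (index ``N + 1``), both absorbing.
    ``Q`` uses the row-from convention: ``Q[i, j]`` is the rate from state
    ``i`` to state ``j`` and rows sum to zero.
    """

    params: NicheParams
    Q: np.ndarray = field(repr=False)

    @property
    def n_states(self) -> int:
        return self.params.N + 2

    @property
    def adenoma_index(self) -> int:
        return self.params.N

    @property
    def carcinoma_index(self) -> int:
        return self.params.N + 1

    @property
    def adenoma_inflow(self) -> np.ndarray:
        """Rates from each transient state into ADENOMA."""
        return self.Q[: self.params.N, self.adenoma_index]

    @property
    def carcinoma_inflow(self) -> np.ndarray:
        """Rates from each transient state into CARCINOMA."""
        return self.Q[: self.params.N, self.carcinoma_index]


def build_generator(params: NicheParams) -> NicheGenerator:
    """Assemble the generator matrix of the niche-competition chain."""
    N = params.N
    up, down, carc = _transition_rates(
        N, params.u, params.v, params.lam, params.arrangement
    )
    Q = np.zeros((N + 2, N + 2))
    for i in range(N):
        Q[i, i + 1] = up[i]  # i = N-1 lands on the ADENOMA index
        if i > 0:
            Q[i, i - 1] = down[i]
        Q[i, N + 1] = carc[i]
        Q[i, i] = -(up[i] + (down[i] if i > 0 else 0.0) + carc[i])
    return NicheGenerator(params=params, Q=Q)


def default_time_grid(t_max: float = 90.0, dt: float = 0.25) -> np.ndarray:
    """Default solver grid: 0 to ``t_max`` years in steps of ``dt``."""
    n = int(round(t_max / dt))
    return np.linspace(0.0, n * dt, n + 1)


@dataclass
class CryptAbsorptionCurves:
    """Per-crypt absorption probabilities and fluxes on a time grid.

    ``Pa``/``Pc`` are the probabilities that the crypt has been absorbed
    into ADENOMA/CARCINOMA by age ``t``; ``dPa``/``dPc`` are the analytic
    instantaneous inflow rates (per year) into those states.
    """

    t: np.ndarray
    Pa: np.ndarray
    Pc: np.ndarray
    dPa: np.ndarray
    dPc: np.ndarray
    transient: np.ndarray | None = field(default=None, repr=False)

    def at(self, t: float | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Interpolate (Pa, Pc) at arbitrary ages inside the grid."""
        t = np.asarray(t, dtype=float)
        if np.any(t < self.t[0]) or np.any(t > self.t[-1]):
            raise ValueError("requested age outside the solved grid")
        return np.interp(t, self.t, self.Pa), np.interp(t, self.t, self.Pc)

    def to_tsv(self, path) -> None:
        """Write the curves as TSV (t_years, Pa, Pc, dPa_per_y, dPc_per_y)."""
        data = np.column_stack([self.t, self.Pa, self.Pc, self.dPa, self.dPc])
        np.savetxt(
            path,
            data,
            delimiter="\t",
            header="t_years\tPa\tPc\tdPa_per_y\tdPc_per_y",
            comments="",
        )


class CryptKernel:
    """Spectral solution of the niche chain, reusable across time scales.

    Because the generator is proportional to ``lam``, the chain solved at
    unit replacement rate on the dimensionless time ``tau = lam * t`` yields
    the solution for every ``lam`` at once.  The transient block is a
    tridiagonal matrix with positive off-diagonals whenever ``0 < u < 1``
    and ``v < 1``; a diagonal similarity turns it symmetric, so its exact
    eigendecomposition (all eigenvalues real and negative) gives machine
    precision absorption curves at arbitrary ages without time stepping.
    """

    def __init__(self, N: int, u: float, v: float, arrangement: Arrangement):
        params = NicheParams(N, u, v, 1.0, arrangement)
        if not self.is_spectral(params):
            raise ParameterDomainError(
                "spectral kernel requires 0 < u < 1 and v < 1 "
                "(degenerate chains are handled by the stepping solver)"
            )
        self.params = params
        up, down, carc = _transition_rates(N, u, v, 1.0, arrangement)
        diag = -(up + np.where(np.arange(N) > 0, down, 0.0) + carc)
        sup = up[:-1]  # i -> i+1 inside the transient block
        sub = down[1:]  # i+1 -> i
        # Diagonal similarity d with (d[i+1]/d[i])^2 = sub[i] / sup[i]
        log_d = np.concatenate([[0.0], np.cumsum(0.5 * (np.log(sub) - np.log(sup)))])
        d = np.exp(log_d)
        w, V = eigh_tridiagonal(diag, np.sqrt(sup * sub))
        # p(tau) = D^-1 V e^{w tau} V^T D e0  with D = diag(d)
        self._w = w
        self._b = V[0, :] * d[0]  # V^T D e0
        self._V_over_d = V / d[:, None]
        a_ad = np.zeros(N)
        a_ad[N - 1] = up[N - 1]
        self._c_ad = (a_ad @ self._V_over_d) * self._b
        self._c_ca = (carc @ self._V_over_d) * self._b
        self._d = d

    @staticmethod
    def is_spectral(params: NicheParams) -> bool:
        """Whether the transient block is symmetrizable for these parameters."""
        return 0.0 < params.u < 1.0 and params.v < 1.0

    def curves_at(
        self, lam: float, t: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Return (Pa, Pc, dPa, dPc) at ages ``t`` for replacement rate ``lam``.

        Fluxes are per year; probabilities are exact absorbing-state
        occupancies of the master equation started from the all-wild-type
        state.
        """
        tau = lam * np.atleast_1d(np.asarray(t, dtype=float))
        E = np.exp(np.outer(tau, self._w))
        # integral of e^{w s} ds from 0 to tau = expm1(w tau) / w; w < 0 strictly
        I = np.expm1(np.outer(tau, self._w)) / self._w
        Pa = I @ self._c_ad
        Pc = I @ self._c_ca
        dPa = lam * (E @ self._c_ad)
        dPc = lam * (E @ self._c_ca)
        return (
            np.clip(Pa, 0.0, 1.0),
            np.clip(Pc, 0.0, 1.0),
            np.maximum(dPa, 0.0),
            np.maximum(dPc, 0.0),
        )

    def transient_occupancy(self, lam: float, t: np.ndarray) -> np.ndarray:
        """Occupancy of the transient states, shape (len(t), N)."""
        tau = lam * np.atleast_1d(np.asarray(t, dtype=float))
        E = np.exp(np.outer(tau, self._w)) * self._b
        return E @ self._V_over_d.T

    def solve(self, lam: float, t_grid: np.ndarray) -> CryptAbsorptionCurves:
        """Package the spectral solution on a grid as absorption curves."""
        Pa, Pc, dPa, dPc = self.curves_at(lam, t_grid)
        return CryptAbsorptionCurves(
            t=np.asarray(t_grid, dtype=float),
            Pa=Pa,
            Pc=Pc,
            dPa=dPa,
            dPc=dPc,
            transient=self.transient_occupancy(lam, t_grid),
        )


def _check_grid(t_grid: np.ndarray) -> np.ndarray:
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 1:
        raise ValueError("t_grid must be a one-dimensional array")
    if t_grid[0] != 0.0:
        raise ValueError("t_grid must start at 0")
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    return t_grid


def _solve_by_stepping(gen: NicheGenerator, t_grid: np.ndarray) -> CryptAbsorptionCurves:
    """Propagate the master equation with per-interval matrix exponentials.

    Exact for a time-homogeneous chain (the step matrix is the transition
    kernel itself); used for degenerate parameters where the spectral path
    is unavailable (u = 0, u = 1 or v = 1).
    """
    N = gen.params.N
    n = t_grid.size
    p = np.zeros(gen.n_states)
    p[0] = 1.0
    occ = np.empty((n, gen.n_states))
    occ[0] = p
    step_cache: dict[float, np.ndarray] = {}
    for k in range(1, n):
        dt = t_grid[k] - t_grid[k - 1]
        key = round(dt, 15)
        if key not in step_cache:
            step_cache[key] = expm(gen.Q * dt)
        p = p @ step_cache[key]
        occ[k] = p
    trans = occ[:, :N]
    return CryptAbsorptionCurves(
        t=t_grid,
        Pa=occ[:, gen.adenoma_index],
        Pc=occ[:, gen.carcinoma_index],
        dPa=trans @ gen.adenoma_inflow,
        dPc=trans @ gen.carcinoma_inflow,
        transient=trans,
    )


def solve_absorption(gen: NicheGenerator, t_grid: np.ndarray) -> CryptAbsorptionCurves:
    """Solve the master equation from the all-wild-type state on ``t_grid``.

    Returns absorbing-state occupancies ``Pa``, ``Pc`` and the analytic
    inflow fluxes ``dPa``, ``dPc`` (occupancy of each transient state times
    its absorption rate, summed) — never finite differences.
    """
    t_grid = _check_grid(t_grid)
    p = gen.params
    if CryptKernel.is_spectral(p):
        return CryptKernel(p.N, p.u, p.v, p.arrangement).solve(p.lam, t_grid)
    return _solve_by_stepping(gen, t_grid)


@dataclass(frozen=True)
class NicheSimulationSummary:
    """Empirical absorption fractions from the cell-level simulator."""

    p_adenoma: float
    p_carcinoma: float
    se_adenoma: float
    se_carcinoma: float
    n_reps: int
    horizon: float


def simulate_niche(
    params: NicheParams, horizon: float, n_reps: int, seed: int
) -> NicheSimulationSummary:
    """Event-driven exact simulation of the full cell-level process.

    Unlike the ring-topology master equation, the simulator places no
    single-clone restriction: every cell carries its own type and multiple
    benign clones may coexist.  Because the total event rate ``N * lam`` is
    independent of the niche state, the number of replacement events within
    the horizon is Poisson(N * lam * horizon) per replicate and the embedded
    discrete chain can be advanced synchronously across replicates.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    N, u, v = params.N, params.u, params.v
    ring = params.arrangement is Arrangement.LINEAR_RING
    rng = np.random.default_rng(seed)
    n_events = rng.poisson(N * params.lam * horizon, size=n_reps)
    types = np.zeros((n_reps, N), dtype=np.int8)  # 0 wild-type, 1 benign
    status = np.zeros(n_reps, dtype=np.int8)  # 0 active, 1 adenoma, 2 carcinoma
    for step in range(int(n_events.max(initial=0))):
        active = np.nonzero((status == 0) & (n_events > step))[0]
        if active.size == 0:
            break
        m = active.size
        divider = rng.integers(0, N, size=m)
        parent_benign = types[active, divider] == 1
        r = rng.random(m)
        # Daughter type: at most one mutation per division.
        daughter = parent_benign | (~parent_benign & (r < u))
        malignant = parent_benign & (r < v)
        if ring:
            target = (divider + rng.choice([-1, 1], size=m)) % N
        else:
            target = (divider + rng.integers(1, N, size=m)) % N
        status[active[malignant]] = 2
        keep = np.nonzero(~malignant)[0]
        rows = active[keep]
        types[rows, target[keep]] = daughter[keep]
        fixed = rows[types[rows].sum(axis=1) == N]
        status[fixed] = 1
    pa = float(np.mean(status == 1))
    pc = float(np.mean(status == 2))
    return NicheSimulationSummary(
        p_adenoma=pa,
        p_carcinoma=pc,
        se_adenoma=float(np.sqrt(pa * (1.0 - pa) / n_reps)),
        se_carcinoma=float(np.sqrt(pc * (1.0 - pc) / n_reps)),
        n_reps=int(n_reps),
        horizon=float(horizon),
    )
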