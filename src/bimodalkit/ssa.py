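"""Exact stochastic simulation (direct-method SSA) of reaction systems.

Two surfaces are provided:

* :func:`simulate_ssa` — a single trajectory with every reaction event
  recorded (plain-Python loop; meant for small systems and tests).
* :func:`sample_snapshot` / :func:`evolve_ensemble` — ensemble simulation of
  many independent cells recording only the end state, with a numba-compiled
  inner loop.  Per-cell seeds are derived from one master seed through
  ``numpy.random.SeedSequence``, so ensembles are reproducible and
  order-independent.

Copy numbers in these models are small, so the exact direct method is used
throughout (no tau-leaping).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .rates import RateSet, effective_transcription_rate

__all__ = [
    "Trajectory",
    "SnapshotDistribution",
    "Moments",
    "simulate_ssa",
    "sample_snapshot",
    "sample_final_states",
    "evolve_ensemble",
    "stationary_promoter_inits",
    "default_snapshot_time",
    "stationary_moments_closed_form",
    "project_states",
]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------
@dataclass
class Trajectory:
    """Event-resolved sample path: times (min) and the state after each event."""

    times: np.ndarray          # (E,) strictly increasing, starts at 0
    states: np.ndarray         # (E, S) int64
    seed: int
    label: str = ""
    ended_early: bool = False  # all propensities hit zero before t_end

    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def species_path(self, system, name: str) -> np.ndarray:
        return self.states[:, system.species_index(name)]


@dataclass
class SnapshotDistribution:
    """Per-cell scalar expression values with replicate/condition labels."""

    values: np.ndarray
    replicate: np.ndarray
    condition: str = ""
    kind: str = "count"   # "count" (protein numbers) or "intensity" (a.u.)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.replicate = np.asarray(self.replicate)
        if self.values.size == 0:
            raise ValueError("SnapshotDistribution must be non-empty")
        if np.any(self.values < 0):
            raise ValueError("expression values must be >= 0")
        if self.kind not in ("count", "intensity"):
            raise ValueError(f"unknown value kind {self.kind!r}")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class Moments:
    """Mean and CV² (= variance/mean²) per species or for a scalar sample."""

    mean: dict = field(default_factory=dict)
    cv2: dict = field(default_factory=dict)

    @classmethod
    def from_values(cls, values: np.ndarray, name: str = "Protein") -> "Moments":
        values = np.asarray(values, dtype=float)
        m = float(values.mean())
        out = cls(mean={name: m})
        if m > 0:
            out.cv2[name] = float(values.var() / m**2)
        return out


# --------------------------------------------------------------------------
# kernels
# --------------------------------------------------------------------------
@njit(cache=True)
def _ensemble_final(rates, react_ptr, react_idx, stoich_ptr, stoich_idx,
                    stoich_val, inits, t_end, seeds):  # pragma: no cover - jitted
    n_cells, n_species = inits.shape
    n_react = rates.shape[0]
    out = np.empty((n_cells, n_species), dtype=np.int64)
    a = np.empty(n_react, dtype=np.float64)
    for c in range(n_cells):
        np.random.seed(seeds[c])
        x = inits[c].copy()
        t = 0.0
        while True:
            a0 = 0.0
            for r in range(n_react):
                p = rates[r]
                for j in range(react_ptr[r], react_ptr[r + 1]):
                    p *= x[react_idx[j]]
                a[r] = p
                a0 += p
            if a0 <= 0.0:
                break
            t += -np.log(np.random.random()) / a0
            if t > t_end:
                break
            u = np.random.random() * a0
            acc = 0.0
            rsel = n_react - 1
            for r in range(n_react):
                acc += a[r]
                if acc >= u:
                    rsel = r
                    break
            for j in range(stoich_ptr[rsel], stoich_ptr[rsel + 1]):
                x[stoich_idx[j]] += stoich_val[j]
        out[c] = x
    return out


def _cell_seeds(seed: int, n_cells: int, stream: int = 0) -> np.ndarray:
    """Counter-based per-cell seeds (order-independent, reproducible)."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(stream,))
    return ss.generate_state(n_cells, dtype=np.uint32).astype(np.int64)


# --------------------------------------------------------------------------
# public API
# --------------------------------------------------------------------------
def simulate_ssa(system, init, t_end: float, seed: int) -> Trajectory:
    """Statistically exact sample path of the system's Markov jump process.

    If every propensity vanishes before ``t_end`` the trajectory simply ends
    early with the final (absorbing) state recorded.
    """
    init = np.asarray(init, dtype=np.int64)
    if np.any(init < 0):
        raise ValueError("initial copy numbers must be non-negative")
    if not t_end > 0:
        raise ValueError("t_end must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    times = [0.0]
    states = [init.copy()]
    x = init.copy()
    t = 0.0
    ended_early = False
    while True:
        a = system.propensities(x)
        a0 = a.sum()
        if a0 <= 0:
            ended_early = True
            break
        t += rng.exponential(1.0 / a0)
        if t > t_end:
            break
        r = int(np.searchsorted(np.cumsum(a), rng.random() * a0))
        x = system.apply(x, r)
        times.append(t)
        states.append(x.copy())
    return Trajectory(
        times=np.array(times),
        states=np.array(states, dtype=np.int64),
        seed=int(seed),
        label=system.label,
        ended_early=ended_early,
    )


def default_snapshot_time(system, lifetimes: float = 20.0) -> float:
    """Default snapshot time: ``lifetimes`` protein lifetimes (20 by default)."""
    kd = system.metadata.get("kd_prot")
    if kd is None or kd <= 0:
        raise ValueError("system has no positive protein decay rate recorded")
    return lifetimes / kd


def stationary_promoter_inits(system, n_cells: int, seed: int) -> np.ndarray:
    """Per-cell initial states with the promoter drawn from its stationary law.

    For the reduced two-state model each cell starts in L_free or H_free with
    probabilities pi_L, pi_H = k_L/(k_H+k_L), k_H/(k_H+k_L) (RNA = Protein =
    0).  For single-state or feedback systems this is the default init for
    every cell.
    """
    inits = np.tile(system.default_init(), (n_cells, 1))
    k_H = system.metadata.get("k_H", 0.0)
    k_L = system.metadata.get("k_L", 0.0)
    if k_H + k_L > 0 and "Pr_H_free" in system.species:
        pi_H = k_H / (k_H + k_L)
        rng = np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(1,)))
        high = rng.random(n_cells) < pi_H
        iL = system.species_index("Pr_L_free")
        iH = system.species_index("Pr_H_free")
        inits[high, iL] = 0
        inits[high, iH] = 1
    return inits


def sample_final_states(system, inits: np.ndarray, t: float, seed: int,
                        stream: int = 0) -> np.ndarray:
    """Advance every row of ``inits`` independently for ``t`` minutes."""
    c = system.compiled
    inits = np.ascontiguousarray(np.asarray(inits, dtype=np.int64))
    seeds = _cell_seeds(seed, inits.shape[0], stream)
    return _ensemble_final(
        c.rates, c.react_ptr, c.react_idx, c.stoich_ptr, c.stoich_idx,
        c.stoich_val, inits, float(t), seeds,
    )


def evolve_ensemble(system, states: np.ndarray, dt: float, seed: int,
                    stream: int = 0) -> np.ndarray:
    """Continue an existing per-cell ensemble for ``dt`` more minutes."""
    return sample_final_states(system, states, dt, seed, stream)


def sample_snapshot(
    system,
    init=None,
    t_snap: float | None = None,
    n_cells: int = 5000,
    seed: int = 0,
    *,
    condition: str = "",
    value_species: str = "Protein",
    replicate: int = 0,
    return_states: bool = False,
):
    """Snapshot distribution of ``value_species`` over independent cells.

    ``init`` may be a single state vector (shared by all cells), an (n, S)
    matrix of per-cell states, or None, in which case the promoter is drawn
    from its stationary switching law and RNA = Protein = 0.  ``t_snap``
    defaults to 20 protein lifetimes.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if t_snap is None:
        t_snap = default_snapshot_time(system)
    if init is None:
        inits = stationary_promoter_inits(system, n_cells, seed)
    else:
        init = np.asarray(init, dtype=np.int64)
        inits = np.tile(init, (n_cells, 1)) if init.ndim == 1 else init
        if inits.shape[0] != n_cells:
            raise ValueError("per-cell init matrix must have n_cells rows")
    finals = sample_final_states(system, inits, t_snap, seed)
    snap = SnapshotDistribution(
        values=finals[:, system.species_index(value_species)].astype(float),
        replicate=np.full(n_cells, replicate),
        condition=condition or system.label,
        kind="count",
    )
    return (snap, finals) if return_states else snap


def project_states(src_system, states: np.ndarray, dst_system) -> np.ndarray:
    """Carry shared species (by name) into another system's state space.

    Promoter indicators of the destination are reset to its default init;
    used when handing a stationary ensemble of the two-state model to a
    single-state variant.
    """
    out = np.tile(dst_system.default_init(), (states.shape[0], 1))
    for j, name in enumerate(dst_system.species):
        if name in src_system.species and name not in dst_system.promoter_species:
            out[:, j] = states[:, src_system.species_index(name)]
    return out


def stationary_moments_closed_form(
    rates: RateSet, locked_state: str = "none", sigma_preference: str = "sigma70"
) -> Moments:
    """Closed-form stationary means for locked-state (or switching) models.

    With the promoter locked in state X the initiation cycle delivers RNA at
    the effective rate r_X = 1/(1/(k_bind_X·n_holo) + 1/k_esc_X), so
    mean RNA = r_X/kd_rna and mean Protein = r_X·k_tr/(kd_rna·kd_prot).
    With switching (``locked_state="none"``) only the state-weighted mean is
    returned (weights pi_H = k_H/(k_H+k_L)); CV² is omitted.
    """
    n = rates.holoenzymes(sigma_preference)
    r_L = effective_transcription_rate(rates.k_bind_L * n, rates.k_esc_L)
    r_H = effective_transcription_rate(rates.k_bind_H * n, rates.k_esc_H)
    if locked_state == "L":
        r = r_L
    elif locked_state == "H":
        r = r_H
    elif locked_state == "none":
        if rates.k_H + rates.k_L <= 0:
            raise ValueError("locked_state='none' needs k_H + k_L > 0")
        pi_H = rates.k_H / (rates.k_H + rates.k_L)
        r = pi_H * r_H + (1.0 - pi_H) * r_L
    else:
        raise ValueError(f"unknown locked_state {locked_state!r}")
    if rates.kd_rna <= 0 or rates.kd_prot <= 0:
        raise ValueError("decay rates must be > 0 for stationary moments")
    mean_rna = r / rates.kd_rna
    mean_prot = r * rates.k_tr / (rates.kd_rna * rates.kd_prot)
    return Moments(mean={"RNA": mean_rna, "Protein": mean_prot})
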