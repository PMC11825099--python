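"""In-silico perturbation experiments on the reduced two-state model.

Four experiment families:

* single-parameter multiplicative sweeps over a log-spaced 0.1x–10x grid
  (optionally a coupled pair such as k_L and k_H at fixed ratio);
* extended sweeps that raise the L-state initiation rates all the way to
  the H-state values (with the companion rate-limiting step matched), past
  the point where the two transcription states become indistinguishable;
* the gradual exponential→stationary growth-phase transition, interpolating
  between the two condition rate sets;
* bimodal→unimodal transient shifts: the two-state stationary ensemble is
  handed to a single-state variant and its relaxation is watched over time.

Each grid point records the rate set used, the snapshot distribution, the
modality verdict, shape parameters (where bimodal) and empirical moments.
Everything is deterministic under the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .modality import ModalityConfig, DEFAULT_CONFIG, classify_modality, shape_params
from .rates import RateSet, interpolate_condition
from .reactions import build_reduced_model, build_unimodal_variant
from .ssa import (
    Moments,
    SnapshotDistribution,
    default_snapshot_time,
    evolve_ensemble,
    project_states,
    sample_snapshot,
    stationary_promoter_inits,
    sample_final_states,
)

__all__ = [
    "LOG_GRID",
    "SweepSpec",
    "SweepPoint",
    "SweepResult",
    "run_sweep",
    "run_extended_L_sweep",
    "run_stationary_transition",
    "run_unimodal_shift",
    "run_ramp_cycle",
]

#: default multiplicative grid, symmetric in log space around the reference
LOG_GRID = (0.1, 0.215, 0.464, 1.0, 2.15, 4.64, 10.0)


@dataclass(frozen=True)
class SweepSpec:
    """One single-parameter (or coupled-pair) sweep."""

    base: RateSet
    field: str | tuple[str, ...]
    factors: tuple[float, ...] = LOG_GRID
    n_cells: int = 5000
    t_snap: float | None = None     # None: 20 protein lifetimes per point
    seed: int = 0
    sigma_preference: str = "sigma70"
    config: ModalityConfig = DEFAULT_CONFIG

    def __post_init__(self) -> None:
        fields = (self.field,) if isinstance(self.field, str) else tuple(self.field)
        for f in fields:
            if not hasattr(self.base, f):
                raise ValueError(f"unknown rate field {f!r}")
        if any(not f > 0 for f in self.factors):
            raise ValueError("grid factors must be > 0")

    @property
    def fields(self) -> tuple[str, ...]:
        return (self.field,) if isinstance(self.field, str) else tuple(self.field)


@dataclass
class SweepPoint:
    """Everything recorded at one grid point."""

    label: str
    factor: float
    rates: RateSet
    snapshot: SnapshotDistribution
    call: object
    shapes: object | None
    moments: Moments


@dataclass
class SweepResult:
    points: list
    spec: object = None

    def verdicts(self) -> list[str]:
        return [p.call.verdict for p in self.points]

    def mean_protein(self) -> np.ndarray:
        return np.array([p.moments.mean["Protein"] for p in self.points])


def _analyze_point(label, factor, rates, snapshot, config) -> SweepPoint:
    call = classify_modality(snapshot.values, kind=snapshot.kind, config=config)
    shapes = shape_params(call, snapshot.values, kind=snapshot.kind) if call.is_bimodal else None
    return SweepPoint(
        label=label, factor=factor, rates=rates, snapshot=snapshot,
        call=call, shapes=shapes,
        moments=Moments.from_values(snapshot.values),
    )


def _snapshot_for(rates, spec: SweepSpec, label: str, point_seed: int):
    system = build_reduced_model(rates, spec.sigma_preference)
    t = spec.t_snap if spec.t_snap is not None else default_snapshot_time(system)
    return sample_snapshot(
        system, t_snap=t, n_cells=spec.n_cells, seed=point_seed, condition=label
    )


def _point_seed(master: int, i: int) -> int:
    # derived deterministically, independent of evaluation order
    return int(np.random.SeedSequence(int(master), spawn_key=(100 + i,)).generate_state(1)[0] % (2**31))


def run_sweep(spec: SweepSpec) -> SweepResult:
    """Sweep one rate field (or coupled fields at fixed ratio) over the grid."""
    points = []
    for i, factor in enumerate(spec.factors):
        rates = spec.base.replace(
            **{f: getattr(spec.base, f) * factor for f in spec.fields}
        )
        label = "+".join(spec.fields) + f" x{factor:g}"
        snap = _snapshot_for(rates, spec, label, _point_seed(spec.seed, i))
        points.append(_analyze_point(label, factor, rates, snap, spec.config))
    return SweepResult(points=points, spec=spec)


def run_extended_L_sweep(
    base: RateSet,
    progress: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0),
    n_cells: int = 5000,
    seed: int = 0,
    sigma_preference: str = "sigma70",
    config: ModalityConfig = DEFAULT_CONFIG,
) -> SweepResult:
    """Raise the L-state initiation rates toward the H-state values.

    At progress p both k_bind_L and k_esc_L move geometrically toward
    k_bind_H and k_esc_H (the companion rate-limiting step is matched, not
    left behind); at p=1 the two transcription states are identical and the
    distribution collapses onto the original high state.
    """
    points = []
    for i, p in enumerate(progress):
        if not 0.0 <= p <= 1.0:
            raise ValueError("progress values must be in [0, 1]")
        rates = base.replace(
            k_bind_L=base.k_bind_L ** (1 - p) * base.k_bind_H**p,
            k_esc_L=base.k_esc_L ** (1 - p) * base.k_esc_H**p,
        )
        spec = SweepSpec(base=rates, field="k_tr", factors=(1.0,), n_cells=n_cells,
                         seed=seed, sigma_preference=sigma_preference, config=config)
        label = f"L→H progress {p:g}"
        snap = _snapshot_for(rates, spec, label, _point_seed(seed, i))
        points.append(_analyze_point(label, p, rates, snap, config))
    return SweepResult(points=points)


def run_stationary_transition(
    f_grid,
    rates_exp: RateSet,
    rates_stat: RateSet,
    n_cells: int = 5000,
    seed: int = 0,
    sigma_preference: str = "sigma70",
    config: ModalityConfig = DEFAULT_CONFIG,
) -> SweepResult:
    """Gradual exponential→stationary transition (f = growth-phase progress).

    Bimodality is expected to survive across the default grid, with both
    mode means decreasing in f; this is recorded per point, not enforced.
    """
    points = []
    for i, f in enumerate(f_grid):
        rates = interpolate_condition(rates_exp, rates_stat, float(f))
        spec = SweepSpec(base=rates, field="k_tr", factors=(1.0,), n_cells=n_cells,
                         seed=seed, sigma_preference=sigma_preference, config=config)
        label = f"stationary f={f:g}"
        snap = _snapshot_for(rates, spec, label, _point_seed(seed, i))
        points.append(_analyze_point(label, float(f), rates, snap, config))
    return SweepResult(points=points)


@dataclass
class ShiftResult:
    """Time-indexed record of a bimodal→unimodal transient."""

    points: list                  # SweepPoint per snapshot time (factor = time)
    relaxation_time: float | None  # first time the verdict turns (and stays) unimodal


def run_unimodal_shift(
    variant: str,
    parent: RateSet,
    times,
    n_cells: int = 5000,
    seed: int = 0,
    sigma_preference: str = "sigma70",
    config: ModalityConfig = DEFAULT_CONFIG,
) -> ShiftResult:
    """Watch the two-state stationary ensemble relax under a one-state variant.

    The ensemble starts from the parent two-state model's stationary
    snapshot (the reaction change happens at t=0), then evolves under the
    ``variant`` system; the distribution and its verdict are recorded at
    each requested time.
    """
    times = sorted(float(t) for t in times)
    if any(t < 0 for t in times):
        raise ValueError("snapshot times must be >= 0")
    parent_sys = build_reduced_model(parent, sigma_preference)
    inits = stationary_promoter_inits(parent_sys, n_cells, seed)
    parent_states = sample_final_states(
        parent_sys, inits, default_snapshot_time(parent_sys), seed
    )
    var_sys = build_unimodal_variant(parent, variant, sigma_preference)
    states = project_states(parent_sys, parent_states, var_sys)
    iP = var_sys.species_index("Protein")
    points = []
    t_prev = 0.0
    for i, t in enumerate(times):
        if t > t_prev:
            states = evolve_ensemble(var_sys, states, t - t_prev, seed, stream=200 + i)
            t_prev = t
        snap = SnapshotDistribution(
            values=states[:, iP].astype(float),
            replicate=np.zeros(n_cells, dtype=int),
            condition=f"{variant} t={t:g}",
            kind="count",
        )
        points.append(_analyze_point(f"t={t:g}", t, parent, snap, config))
    relax = None
    for j in range(len(points)):
        if all(p.call.verdict == "unimodal" for p in points[j:]):
            relax = points[j].factor
            break
    return ShiftResult(points=points, relaxation_time=relax)


def run_ramp_cycle(
    base: RateSet,
    field_name: str,
    factors_up: tuple[float, ...],
    n_cells: int = 6000,
    seed: int = 0,
    mode: str = "equilibrated",
    dt_lagged: float = 30.0,
    turnaround_hold: float = 8.0,
    sigma_preference: str = "sigma70",
    config: ModalityConfig = DEFAULT_CONFIG,
):
    """Forward/backward parameter ramp for hysteresis studies.

    ``factors_up`` is the forward condition sequence; the backward pass
    revisits the same conditions in reverse.  In ``equilibrated`` mode every
    condition gets a fresh stationary snapshot (snapshot time = 20 protein
    lifetimes), erasing history; in ``lagged`` mode one ensemble is carried
    through the whole cycle and only evolves ``dt_lagged`` minutes per
    condition — about half a protein lifetime, far less than the relaxation
    time — so the measured distribution lags the conditions and the two
    passes separate.  A ramp whose turnaround reaches the unimodal-collapse
    region (e.g. ``k_bind_H`` down to 0.1x) produces a strong lag, and the
    deepest condition is held for ``turnaround_hold`` dwell periods (a
    sustained stress episode), so the forward pass still resembles the
    starting distribution while the backward pass carries a clear memory of
    the collapse.

    Returns (forward, backward) condition/value sequences ready for
    :func:`bimodalkit.hysteresis.track_path`.
    """
    if mode not in ("equilibrated", "lagged"):
        raise ValueError("mode must be 'equilibrated' or 'lagged'")
    factors = list(factors_up) + list(reversed(factors_up))[1:]
    n_fwd = len(factors_up)
    conditions = [
        (f"{field_name} x{f:g}", base.replace(**{field_name: getattr(base, field_name) * f}))
        for f in factors
    ]
    sequences = []
    if mode == "equilibrated":
        for i, (label, rates) in enumerate(conditions):
            system = build_reduced_model(rates, sigma_preference)
            snap = sample_snapshot(
                system, n_cells=n_cells, seed=_point_seed(seed, i), condition=label
            )
            sequences.append((label, snap.values))
    else:
        system0 = build_reduced_model(conditions[0][1], sigma_preference)
        inits = stationary_promoter_inits(system0, n_cells, seed)
        states = sample_final_states(
            system0, inits, default_snapshot_time(system0), seed
        )
        iP = system0.species_index("Protein")
        sequences.append((conditions[0][0], states[:, iP].astype(float)))
        i_turn = len(factors_up) - 1
        for i, (label, rates) in enumerate(conditions[1:], start=1):
            system = build_reduced_model(rates, sigma_preference)
            dwell = dt_lagged * (turnaround_hold if i == i_turn else 1.0)
            states = evolve_ensemble(system, states, dwell, seed, stream=300 + i)
            sequences.append((label, states[:, iP].astype(float)))
    forward = sequences[:n_fwd]
    backward = sequences[n_fwd - 1:]
    return forward, backward
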