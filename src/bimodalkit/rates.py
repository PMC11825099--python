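"""Rate constants of the reduced two-state expression model and condition arithmetic.

The reduced model describes a bacterial gene whose promoter switches between a
low- (L) and a high-transcription (H) state.  Transcription initiation in each
state is a two rate-limiting-step process: RNAP-holoenzyme binding (second
order in the holoenzyme copy number, which is treated as a fixed parameter)
followed by promoter escape.  Translation and first-order RNA/protein decay
(degradation plus dilution) close the model.  All rates are per minute.

Stress conditions are expressed as multiplicative perturbations of a
:class:`RateSet` (antibiotics acting on escape, switching, or translation) or
as a geometric interpolation between an exponential-phase and a
stationary-phase rate set (growth-phase transition).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "RateSet",
    "PerturbationScenario",
    "REFERENCE_RATES",
    "reference_rates",
    "stationary_rates",
    "effective_transcription_rate",
    "apply_scenario",
    "interpolate_condition",
    "named_scenario",
    "rifampicin",
    "novobiocin",
    "streptomycin",
]

_RATE_FIELDS = (
    "k_H",
    "k_L",
    "k_bind_L",
    "k_bind_H",
    "k_esc_L",
    "k_esc_H",
    "k_tr",
    "kd_rna",
    "kd_prot",
)
_HOLO_FIELDS = ("n_rnap70", "n_rnap38")


@dataclass(frozen=True)
class RateSet:
    """All rate constants and holoenzyme copy numbers of the reduced model.

    Parameters
    ----------
    k_H, k_L
        Promoter-state switching rates (1/min); ``k_H`` drives L→H and
        ``k_L`` drives H→L (destination-state subscripts).
    k_bind_L, k_bind_H
        Second-order RNAP-holoenzyme binding rate constants per promoter
        state (1/(molecule·min)); the effective first-order binding rate is
        ``k_bind_X * n_holo``.
    k_esc_L, k_esc_H
        Promoter-escape rates per state (1/min).
    k_tr
        Translation rate per RNA (1/min).
    kd_rna, kd_prot
        RNA and protein decay rates, degradation plus dilution (1/min).
    n_rnap70, n_rnap38
        Available RNAP.σ70 and RNAP.σ38 holoenzyme copy numbers (molecules).
    """

    k_H: float
    k_L: float
    k_bind_L: float
    k_bind_H: float
    k_esc_L: float
    k_esc_H: float
    k_tr: float
    kd_rna: float
    kd_prot: float
    n_rnap70: int
    n_rnap38: int

    def __post_init__(self) -> None:
        for name in _RATE_FIELDS:
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise ValueError(f"{name} must be a finite number, got {v!r}")
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        for name in _HOLO_FIELDS:
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise ValueError(f"{name} must be an integer, got {v!r}")
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    # -- helpers -----------------------------------------------------------
    def holoenzymes(self, sigma_preference: str = "sigma70") -> int:
        """Holoenzyme copy number seen by a promoter with the given σ preference."""
        if sigma_preference == "sigma70":
            return self.n_rnap70
        if sigma_preference == "sigma38":
            return self.n_rnap38
        raise ValueError(f"unknown sigma_preference {sigma_preference!r}")

    def replace(self, **changes) -> "RateSet":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "RateSet":
        return cls(**{k: d[k] for k in _RATE_FIELDS + _HOLO_FIELDS})

    def is_reference_like(self, sigma_preference: str = "sigma70") -> bool:
        """Check the orderings expected of a reference parameterization.

        The L-state effective binding and escape rates are about an order of
        magnitude below the H-state ones, and the switching rates are smaller
        than every other (effective first-order) rate.
        """
        n = self.holoenzymes(sigma_preference)
        eff = {
            "bind_L": self.k_bind_L * n,
            "bind_H": self.k_bind_H * n,
            "esc_L": self.k_esc_L,
            "esc_H": self.k_esc_H,
            "k_tr": self.k_tr,
            "kd_rna": self.kd_rna,
            "kd_prot": self.kd_prot,
        }
        if not (eff["bind_L"] < eff["bind_H"] and eff["esc_L"] < eff["esc_H"]):
            return False
        slowest_other = min(eff.values())
        return max(self.k_H, self.k_L) < slowest_other


def effective_transcription_rate(k_bind_eff: float, k_esc: float) -> float:
    """Effective rate of the two-step initiation cycle, ``1/(1/k_bind_eff + 1/k_esc)``.

    ``k_bind_eff`` is the first-order binding rate (``k_bind * n_holo``).
    Zero if either step is blocked.
    """
    if k_bind_eff <= 0 or k_esc <= 0:
        return 0.0
    return 1.0 / (1.0 / k_bind_eff + 1.0 / k_esc)


def reference_rates() -> RateSet:
    """Documented default reference parameterization (exponential growth).

    Effective values: L-state two-step rates one order of magnitude below the
    H-state ones (0.05 and 0.1 vs 0.5 and 1.0 /min), translation 0.4/min,
    RNA lifetime 5 min, protein lifetime 50 min (decay dominated by
    dilution), and state switching slower than everything else (residence
    ~1000 min, so promoter-state memory outlives the protein lifetime by
    ~20x, which keeps the two expression modes resolved).  The resulting
    stationary protein means are ~3 (L state) and ~33 (H state) molecules:
    low enough that ten-fold reductions of H-state initiation, translation
    or decay-rate increases genuinely merge the two modes, while the
    low-noise stationary-growth condition keeps them resolved.
    """
    return RateSet(
        k_H=0.001,
        k_L=0.001,
        k_bind_L=1e-4,
        k_bind_H=1e-3,
        k_esc_L=0.1,
        k_esc_H=1.0,
        k_tr=0.4,
        kd_rna=0.2,
        kd_prot=0.02,
        n_rnap70=500,
        n_rnap38=50,
    )


REFERENCE_RATES = reference_rates()


def stationary_rates(
    reference: RateSet | None = None,
    *,
    rna_lifetime_min: float = 7.8,
    dilution_rate: float = 0.019,
    dilution_reduction: float = 0.915,
    degradation_increase: float = 0.08,
    translation_reduction: float = 40.0,
    sigma38_fraction: float = 0.3,
) -> RateSet:
    """Stationary-growth-phase rate set derived from known physiology.

    On entry into stationary phase the mean mRNA lifetime rises to ~7.8 min,
    dilution due to division drops by ~91.5% while protein degradation rises
    by ~8%/h, translation activity drops ~40-fold, and the holoenzyme pool
    shifts from RNAP.σ70 toward RNAP.σ38.  The reference protein decay rate
    is decomposed into ``dilution_rate`` plus degradation (the remainder);
    stable reporter fusions degrade slowly, so dilution dominates.
    """
    ref = REFERENCE_RATES if reference is None else reference
    degradation = max(ref.kd_prot - dilution_rate, 0.0)
    kd_prot = dilution_rate * (1.0 - dilution_reduction) + degradation * (
        1.0 + degradation_increase
    )
    pool = ref.n_rnap70 + ref.n_rnap38
    n38 = int(round(pool * sigma38_fraction))
    return ref.replace(
        kd_rna=1.0 / rna_lifetime_min,
        kd_prot=kd_prot,
        k_tr=ref.k_tr / translation_reduction,
        n_rnap70=pool - n38,
        n_rnap38=n38,
    )


@dataclass(frozen=True)
class PerturbationScenario:
    """Multiplicative perturbation of named rate constants.

    ``factors`` maps RateSet rate-field names to positive multipliers;
    ``holoenzymes`` optionally replaces the holoenzyme copy numbers outright.
    """

    name: str
    factors: Mapping[str, float] = field(default_factory=dict)
    holoenzymes: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.factors.items():
            if k not in _RATE_FIELDS:
                raise ValueError(f"unknown rate field {k!r} in scenario {self.name!r}")
            if not v > 0:
                raise ValueError(f"factor for {k} must be > 0, got {v}")
        for k, v in self.holoenzymes.items():
            if k not in _HOLO_FIELDS:
                raise ValueError(f"unknown holoenzyme field {k!r}")
            if int(v) != v or v < 0:
                raise ValueError(f"{k} replacement must be a non-negative integer")


def apply_scenario(rates: RateSet, scenario: PerturbationScenario) -> RateSet:
    """Return a new RateSet with the scenario's factors/replacements applied."""
    changes: dict = {
        k: getattr(rates, k) * f for k, f in scenario.factors.items()
    }
    changes.update({k: int(v) for k, v in scenario.holoenzymes.items()})
    return rates.replace(**changes)


def rifampicin(factor: float = 0.1) -> PerturbationScenario:
    """Rifampicin blocks promoter escape: both escape rates reduced."""
    return PerturbationScenario(
        "rifampicin", {"k_esc_L": factor, "k_esc_H": factor}
    )


def novobiocin(which: str = "k_L", factor: float = 10.0) -> PerturbationScenario:
    """Novobiocin (gyrase inhibition) retunes promoter-state residence times."""
    if which not in ("k_L", "k_H"):
        raise ValueError("novobiocin acts on k_L or k_H")
    return PerturbationScenario(f"novobiocin_{which[-1]}", {which: factor})


def streptomycin(factor: float = 0.1) -> PerturbationScenario:
    """Streptomycin corrupts translation: functional-protein rate reduced."""
    return PerturbationScenario("streptomycin", {"k_tr": factor})


def stationary_condition(f: float, reference: RateSet | None = None, **kwargs) -> RateSet:
    """Rate set at fraction ``f`` of the exponential→stationary transition.

    Shorthand for ``interpolate_condition(ref, stationary_rates(ref), f)``;
    keyword arguments are forwarded to :func:`stationary_rates`.
    """
    ref = REFERENCE_RATES if reference is None else reference
    return interpolate_condition(ref, stationary_rates(ref, **kwargs), f)


def named_scenario(name: str, **kwargs) -> PerturbationScenario:
    """Look up a built-in multiplicative scenario by name.

    Known names: ``rifampicin``, ``novobiocin_L``, ``novobiocin_H``,
    ``streptomycin``, ``identity``.  The growth-phase transition is not
    multiplicative; use :func:`stationary_condition` (or the ``stationary:f``
    spelling accepted by the CLI and pipeline).
    """
    if name == "rifampicin":
        return rifampicin(**kwargs)
    if name == "novobiocin_L":
        return novobiocin("k_L", **kwargs)
    if name == "novobiocin_H":
        return novobiocin("k_H", **kwargs)
    if name == "streptomycin":
        return streptomycin(**kwargs)
    if name == "identity":
        return PerturbationScenario("identity", {})
    raise KeyError(f"unknown scenario {name!r}")


def interpolate_condition(rates_exp: RateSet, rates_stat: RateSet, f: float) -> RateSet:
    """Interpolate between exponential- and stationary-phase rate sets.

    ``f`` is the progress fraction (0 = exponential, 1 = stationary).  Rates
    are interpolated geometrically (they span orders of magnitude and must
    stay positive); a rate that is zero at either endpoint falls back to
    linear interpolation.  Holoenzyme counts are interpolated linearly and
    rounded to the nearest integer.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"f must be in [0, 1], got {f}")
    changes: dict = {}
    for name in _RATE_FIELDS:
        a = getattr(rates_exp, name)
        b = getattr(rates_stat, name)
        if a > 0 and b > 0:
            changes[name] = a ** (1.0 - f) * b**f
        else:
            changes[name] = (1.0 - f) * a + f * b
    for name in _HOLO_FIELDS:
        a = getattr(rates_exp, name)
        b = getattr(rates_stat, name)
        changes[name] = int(round((1.0 - f) * a + f * b))
    if f == 0.0:
        return rates_exp
    if f == 1.0:
        return rates_stat
    return RateSet(**changes)
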