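"""Reaction networks: the reduced two-state model and its variants.

A :class:`ReactionSystem` is a list of species and mass-action reactions with
integer stoichiometries.  Propensities are ``rate * product of reactant copy
numbers``; holoenzyme pools are folded into the binding rate constants (they
are fixed parameters, not consumed species).  The promoter is represented by
indicator species (exactly one equals 1 in any reachable state), and while it
is occupied by an initiating RNAP it is unavailable both for new bindings and
(by default) for state switching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from .rates import RateSet, effective_transcription_rate

__all__ = [
    "Reaction",
    "ReactionSystem",
    "CompiledSystem",
    "FeedbackParams",
    "DEFAULT_FEEDBACK_PARAMS",
    "build_reduced_model",
    "build_unimodal_variant",
    "build_feedback_model",
    "REDUCED_SPECIES",
]

REDUCED_SPECIES = ("Pr_L_free", "Pr_L_occ", "Pr_H_free", "Pr_H_occ", "RNA", "Protein")
VARIANT_SPECIES = ("Pr_free", "Pr_occ", "RNA", "Protein")
FEEDBACK_SPECIES = ("Pr_off_free", "Pr_off_occ", "Pr_on_free", "Pr_on_occ", "RNA", "Protein")


@dataclass(frozen=True)
class Reaction:
    """One mass-action reaction.

    ``reactants`` are species indices (repeated for order > 1) whose copy
    numbers multiply the rate constant; ``changes`` is the sparse integer
    stoichiometry as (species index, delta) pairs.
    """

    name: str
    rate: float
    reactants: tuple[int, ...]
    changes: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError(f"reaction {self.name!r} has negative rate")


@dataclass(frozen=True)
class CompiledSystem:
    """Flat array form of a ReactionSystem for the simulation kernels."""

    rates: np.ndarray       # (R,) float64
    react_ptr: np.ndarray   # (R+1,) int64 into react_idx
    react_idx: np.ndarray   # species indices of reactants
    stoich_ptr: np.ndarray  # (R+1,) int64 into stoich_idx/val
    stoich_idx: np.ndarray
    stoich_val: np.ndarray


@dataclass(frozen=True)
class ReactionSystem:
    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    label: str = ""
    promoter_species: tuple[str, ...] = ()
    #: decay rate of the reporter protein, used for default snapshot times
    metadata: dict = field(default_factory=dict, compare=False)

    def species_index(self, name: str) -> int:
        return self.species.index(name)

    @cached_property
    def compiled(self) -> CompiledSystem:
        rates = np.array([r.rate for r in self.reactions], dtype=np.float64)
        react_ptr = [0]
        react_idx: list[int] = []
        stoich_ptr = [0]
        stoich_idx: list[int] = []
        stoich_val: list[int] = []
        for r in self.reactions:
            react_idx.extend(r.reactants)
            react_ptr.append(len(react_idx))
            for i, d in r.changes:
                stoich_idx.append(i)
                stoich_val.append(d)
            stoich_ptr.append(len(stoich_idx))
        return CompiledSystem(
            rates=rates,
            react_ptr=np.array(react_ptr, dtype=np.int64),
            react_idx=np.array(react_idx, dtype=np.int64),
            stoich_ptr=np.array(stoich_ptr, dtype=np.int64),
            stoich_idx=np.array(stoich_idx, dtype=np.int64),
            stoich_val=np.array(stoich_val, dtype=np.int64),
        )

    def default_init(self) -> np.ndarray:
        """All-zero state with the first promoter indicator set to 1."""
        x = np.zeros(len(self.species), dtype=np.int64)
        if self.promoter_species:
            x[self.species_index(self.promoter_species[0])] = 1
        return x

    def propensities(self, state: np.ndarray) -> np.ndarray:
        a = np.empty(len(self.reactions))
        for k, r in enumerate(self.reactions):
            p = r.rate
            for i in r.reactants:
                p *= state[i]
            a[k] = p
        return a

    def apply(self, state: np.ndarray, reaction_index: int) -> np.ndarray:
        out = state.copy()
        for i, d in self.reactions[reaction_index].changes:
            out[i] += d
        return out

    def promoter_count(self, state: np.ndarray) -> int:
        return int(sum(state[self.species_index(s)] for s in self.promoter_species))


def _two_step(
    name: str, i_free: int, i_occ: int, i_rna: int, k_bind_eff: float, k_esc: float
) -> list[Reaction]:
    return [
        Reaction(f"bind_{name}", k_bind_eff, (i_free,), ((i_free, -1), (i_occ, +1))),
        Reaction(f"esc_{name}", k_esc, (i_occ,), ((i_occ, -1), (i_free, +1), (i_rna, +1))),
    ]


def _expression(i_rna: int, i_prot: int, k_tr: float, kd_rna: float, kd_prot: float) -> list[Reaction]:
    return [
        Reaction("translate", k_tr, (i_rna,), ((i_prot, +1),)),
        Reaction("rna_decay", kd_rna, (i_rna,), ((i_rna, -1),)),
        Reaction("prot_decay", kd_prot, (i_prot,), ((i_prot, -1),)),
    ]


def build_reduced_model(
    rates: RateSet,
    sigma_preference: str = "sigma70",
    *,
    switch_when_occupied: bool = False,
) -> ReactionSystem:
    """Build the reduced two-state stochastic expression model.

    Species: ``Pr_L_free, Pr_L_occ, Pr_H_free, Pr_H_occ, RNA, Protein``.
    The promoter switches L_free→H_free at ``k_H`` and H_free→L_free at
    ``k_L``; in each state RNAP binding (effective rate ``k_bind_X * n_holo``)
    is followed by promoter escape releasing one RNA.  Translation and decays
    are promoter-state independent.  With ``switch_when_occupied`` the
    occupied promoter may also change state (off by default: an engaged RNAP
    plausibly blocks the change).
    """
    n_holo = rates.holoenzymes(sigma_preference)
    sp = REDUCED_SPECIES
    iLf, iLo, iHf, iHo, iR, iP = range(6)
    rx: list[Reaction] = [
        Reaction("switch_LH", rates.k_H, (iLf,), ((iLf, -1), (iHf, +1))),
        Reaction("switch_HL", rates.k_L, (iHf,), ((iHf, -1), (iLf, +1))),
    ]
    rx += _two_step("L", iLf, iLo, iR, rates.k_bind_L * n_holo, rates.k_esc_L)
    rx += _two_step("H", iHf, iHo, iR, rates.k_bind_H * n_holo, rates.k_esc_H)
    rx += _expression(iR, iP, rates.k_tr, rates.kd_rna, rates.kd_prot)
    if switch_when_occupied:
        rx.append(Reaction("switch_LH_occ", rates.k_H, (iLo,), ((iLo, -1), (iHo, +1))))
        rx.append(Reaction("switch_HL_occ", rates.k_L, (iHo,), ((iHo, -1), (iLo, +1))))
    return ReactionSystem(
        species=sp,
        reactions=tuple(rx),
        label=f"reduced[{sigma_preference}]",
        promoter_species=("Pr_L_free", "Pr_L_occ", "Pr_H_free", "Pr_H_occ"),
        metadata={
            "kind": "reduced",
            "rates": rates,
            "sigma_preference": sigma_preference,
            "kd_prot": rates.kd_prot,
            "k_H": rates.k_H,
            "k_L": rates.k_L,
        },
    )


def build_unimodal_variant(
    rates: RateSet, variant: str, sigma_preference: str = "sigma70"
) -> ReactionSystem:
    """Single-state reduction of the two-state model.

    The remaining transcription state's effective two-step rate equals, per
    ``variant``: ``"low"`` → r_L, ``"average"`` → (r_L + r_H)/2, ``"high"`` →
    r_H, where r_X = 1/(1/(k_bind_X·n_holo) + 1/k_esc_X).  The averaged
    variant keeps the two-step structure (and its occupancy noise) by scaling
    the H-state binding and escape rates by a common factor; scaling both
    steps by c scales the effective rate by c exactly.
    """
    n_holo = rates.holoenzymes(sigma_preference)
    if variant == "low":
        kb, ke = rates.k_bind_L * n_holo, rates.k_esc_L
    elif variant == "high":
        kb, ke = rates.k_bind_H * n_holo, rates.k_esc_H
    elif variant == "average":
        r_L = effective_transcription_rate(rates.k_bind_L * n_holo, rates.k_esc_L)
        r_H = effective_transcription_rate(rates.k_bind_H * n_holo, rates.k_esc_H)
        if r_H <= 0:
            raise ValueError("average variant needs a nonzero H-state rate")
        c = (r_L + r_H) / (2.0 * r_H)
        kb, ke = c * rates.k_bind_H * n_holo, c * rates.k_esc_H
    else:
        raise ValueError(f"unknown variant {variant!r} (expected low/average/high)")
    iF, iO, iR, iP = range(4)
    rx = _two_step("X", iF, iO, iR, kb, ke)
    rx += _expression(iR, iP, rates.k_tr, rates.kd_rna, rates.kd_prot)
    return ReactionSystem(
        species=VARIANT_SPECIES,
        reactions=tuple(rx),
        label=f"unimodal[{variant}]",
        promoter_species=("Pr_free", "Pr_occ"),
        metadata={"kind": "variant", "variant": variant, "rates": rates,
                  "kd_prot": rates.kd_prot},
    )


@dataclass(frozen=True)
class FeedbackParams:
    """Positive-feedback-loop model parameters.

    The expressed protein binds the promoter region and switches it to the
    high-transcription (on) configuration; unbinding restores the basal
    configuration.  Transcription in each configuration is the usual two-step
    scheme with first-order effective rates (holoenzymes folded in).
    """

    k_act: float = 6e-4       # activation, 1/(molecule·min), propensity ∝ Protein
    k_deact: float = 2e-3     # unbinding, 1/min
    k_bind_basal: float = 0.05
    k_esc_basal: float = 0.1
    k_bind_act: float = 0.5
    k_esc_act: float = 1.0
    k_tr: float = 0.4
    kd_rna: float = 0.2
    kd_prot: float = 0.02

    def __post_init__(self) -> None:
        import dataclasses

        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"feedback rate {f.name} must be >= 0")


DEFAULT_FEEDBACK_PARAMS = FeedbackParams()


def build_feedback_model(params: FeedbackParams) -> ReactionSystem:
    """Positive feedback loop: Protein activates its own promoter.

    Activation consumes one protein molecule (it is bound at the promoter)
    and deactivation releases it.  With the default parameters both the
    basal (off) and the self-sustained (on) configurations persist for many
    protein lifetimes, producing a bimodal single-cell protein distribution.
    """
    iOf, iOo, iNf, iNo, iR, iP = range(6)
    rx: list[Reaction] = [
        Reaction("activate", params.k_act, (iOf, iP), ((iOf, -1), (iNf, +1), (iP, -1))),
        Reaction("deactivate", params.k_deact, (iNf,), ((iNf, -1), (iOf, +1), (iP, +1))),
    ]
    rx += _two_step("off", iOf, iOo, iR, params.k_bind_basal, params.k_esc_basal)
    rx += _two_step("on", iNf, iNo, iR, params.k_bind_act, params.k_esc_act)
    rx += _expression(iR, iP, params.k_tr, params.kd_rna, params.kd_prot)
    return ReactionSystem(
        species=FEEDBACK_SPECIES,
        reactions=tuple(rx),
        label="feedback",
        promoter_species=("Pr_off_free", "Pr_off_occ", "Pr_on_free", "Pr_on_occ"),
        metadata={"kind": "feedback", "params": params, "kd_prot": params.kd_prot},
    )
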