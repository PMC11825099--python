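import numpy as np
import pytest

from bimodalkit.rates import effective_transcription_rate
from bimodalkit.reactions import (
    DEFAULT_FEEDBACK_PARAMS,
    FeedbackParams,
    Reaction,
    build_feedback_model,
    build_reduced_model,
    build_unimodal_variant,
)
from bimodalkit.ssa import simulate_ssa, stationary_moments_closed_form


def test_reduced_model_structure(ref_system):
    assert len(ref_system.promoter_species) == 4
    assert len(ref_system.reactions) == 9
    assert set(ref_system.species) == {
        "Pr_L_free", "Pr_L_occ", "Pr_H_free", "Pr_H_occ", "RNA", "Protein"
    }


def test_occupied_switching_flag_adds_reactions(ref_rates):
    sys_occ = build_reduced_model(ref_rates, switch_when_occupied=True)
    assert len(sys_occ.reactions) == 11


def test_zero_translation_never_produces_protein(ref_rates):
    system = build_reduced_model(ref_rates.replace(k_tr=0.0))
    traj = simulate_ssa(system, system.default_init(), t_end=200.0, seed=3)
    assert traj.species_path(system, "Protein").max() == 0


def test_silent_promoter_with_zero_holoenzymes_is_legal(ref_rates):
    system = build_reduced_model(ref_rates.replace(n_rnap70=0, n_rnap38=0))
    traj = simulate_ssa(system, system.default_init(), t_end=500.0, seed=4)
    assert traj.species_path(system, "RNA").max() == 0


def test_promoter_conservation_along_trajectories(ref_system):
    traj = simulate_ssa(ref_system, ref_system.default_init(), t_end=500.0, seed=5)
    idx = [ref_system.species_index(s) for s in ref_system.promoter_species]
    assert (traj.states[:, idx].sum(axis=1) == 1).all()
    assert (np.diff(traj.times) > 0).all()
    assert (traj.states >= 0).all()


def test_locked_reduced_model_equals_low_variant(ref_rates):
    """k_H=k_L=0 from the L state is the one-state low model: same L-cycle
    reactions and the same closed-form stationary mean."""
    locked = build_reduced_model(ref_rates.replace(k_H=0.0, k_L=0.0))
    low = build_unimodal_variant(ref_rates, "low")
    by_name = {r.name: r for r in locked.reactions}
    n = ref_rates.n_rnap70
    assert by_name["bind_L"].rate == pytest.approx(ref_rates.k_bind_L * n)
    low_rates = {r.name: r.rate for r in low.reactions}
    assert low_rates["bind_X"] == pytest.approx(by_name["bind_L"].rate)
    assert low_rates["esc_X"] == pytest.approx(by_name["esc_L"].rate)
    m_locked = stationary_moments_closed_form(ref_rates, "L")
    assert m_locked.mean["Protein"] == pytest.approx(
        ref_rates.k_tr * effective_transcription_rate(
            ref_rates.k_bind_L * n, ref_rates.k_esc_L
        ) / (ref_rates.kd_rna * ref_rates.kd_prot)
    )


@pytest.mark.parametrize("variant", ["low", "average", "high"])
def test_variant_effective_rates(ref_rates, variant):
    n = ref_rates.n_rnap70
    r_L = effective_transcription_rate(ref_rates.k_bind_L * n, ref_rates.k_esc_L)
    r_H = effective_transcription_rate(ref_rates.k_bind_H * n, ref_rates.k_esc_H)
    target = {"low": r_L, "average": (r_L + r_H) / 2, "high": r_H}[variant]
    system = build_unimodal_variant(ref_rates, variant)
    rates = {r.name: r.rate for r in system.reactions}
    got = effective_transcription_rate(rates["bind_X"], rates["esc_X"])
    assert got == pytest.approx(target, rel=1e-12)
    assert len(system.promoter_species) == 2  # two-step structure retained


def test_unknown_variant_rejected(ref_rates):
    with pytest.raises(ValueError):
        build_unimodal_variant(ref_rates, "medium")


def test_feedback_zero_activation_stays_basal():
    params = FeedbackParams(k_act=0.0)
    system = build_feedback_model(params)
    traj = simulate_ssa(system, system.default_init(), t_end=2000.0, seed=6)
    assert traj.species_path(system, "Pr_on_free").max() == 0
    # basal expression only: mean well below the active-state closed form
    prot = traj.species_path(system, "Protein")
    basal_mean = params.k_tr * effective_transcription_rate(
        params.k_bind_basal, params.k_esc_basal
    ) / (params.kd_rna * params.kd_prot)
    assert prot[len(prot) // 2:].mean() < 3 * basal_mean


def test_feedback_zero_unbinding_absorbs_in_high_state():
    params = FeedbackParams(k_deact=0.0)
    system = build_feedback_model(params)
    init = system.default_init()
    init[system.species_index("Protein")] = 20
    traj = simulate_ssa(system, init, t_end=3000.0, seed=7)
    on = traj.species_path(system, "Pr_on_free") + traj.species_path(system, "Pr_on_occ")
    assert on[-1] == 1  # activated and never released
    high_mean = params.k_tr * effective_transcription_rate(
        params.k_bind_act, params.k_esc_act
    ) / (params.kd_rna * params.kd_prot)
    assert traj.species_path(system, "Protein")[-1] > 0.3 * high_mean


def test_feedback_promoter_conservation():
    system = build_feedback_model(DEFAULT_FEEDBACK_PARAMS)
    init = system.default_init()
    init[system.species_index("Protein")] = 10
    traj = simulate_ssa(system, init, t_end=500.0, seed=8)
    idx = [system.species_index(s) for s in system.promoter_species]
    assert (traj.states[:, idx].sum(axis=1) == 1).all()


def test_feedback_fixture_is_bimodal():
    """The shipped positive-feedback parameter set shows two expression
    modes near the basal and active closed-form means."""
    from bimodalkit.modality import classify_modality
    from bimodalkit.ssa import sample_snapshot

    system = build_feedback_model(DEFAULT_FEEDBACK_PARAMS)
    snap = sample_snapshot(system, n_cells=4000, seed=21)
    call = classify_modality(snap.values)
    assert call.is_bimodal
    lo, hi = call.fit2.means
    basal = DEFAULT_FEEDBACK_PARAMS.k_tr * effective_transcription_rate(
        DEFAULT_FEEDBACK_PARAMS.k_bind_basal, DEFAULT_FEEDBACK_PARAMS.k_esc_basal
    ) / (DEFAULT_FEEDBACK_PARAMS.kd_rna * DEFAULT_FEEDBACK_PARAMS.kd_prot)
    active = DEFAULT_FEEDBACK_PARAMS.k_tr * effective_transcription_rate(
        DEFAULT_FEEDBACK_PARAMS.k_bind_act, DEFAULT_FEEDBACK_PARAMS.k_esc_act
    ) / (DEFAULT_FEEDBACK_PARAMS.kd_rna * DEFAULT_FEEDBACK_PARAMS.kd_prot)
    assert lo == pytest.approx(basal, rel=0.5)
    assert hi == pytest.approx(active, rel=0.3)


def test_reaction_rejects_negative_rate():
    with pytest.raises(ValueError):
        Reaction("bad", -1.0, (), ())
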