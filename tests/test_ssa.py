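import numpy as np
import pytest
from scipy import stats

from bimodalkit.reactions import Reaction, ReactionSystem, build_reduced_model, build_unimodal_variant
from bimodalkit.ssa import (
    Moments,
    sample_final_states,
    sample_snapshot,
    simulate_ssa,
    stationary_moments_closed_form,
    stationary_promoter_inits,
    project_states,
    default_snapshot_time,
)


def make_birth_system(lam: float) -> ReactionSystem:
    return ReactionSystem(
        species=("X",),
        reactions=(Reaction("birth", lam, (), ((0, +1),)),),
        label="pure-birth",
    )


def test_pure_birth_event_count_is_poisson():
    """Counting process of a rate-lambda birth reaction: mean ~ Poisson(lam*T)."""
    lam, T, n = 5.0, 10.0, 2000
    system = make_birth_system(lam)
    finals = sample_final_states(system, np.zeros((n, 1), dtype=np.int64), T, seed=9)
    counts = finals[:, 0]
    assert abs(counts.mean() - lam * T) < 3 * np.sqrt(lam * T / n)
    assert abs(counts.var() / counts.mean() - 1.0) < 0.15  # Fano factor ~ 1


def test_waiting_times_are_exponential():
    """KS test of inter-event times in a constant-propensity system."""
    system = make_birth_system(1.0)
    passed = 0
    for seed in range(10):
        traj = simulate_ssa(system, [0], t_end=2000.0, seed=seed)
        waits = np.diff(traj.times)
        p = stats.kstest(waits, "expon", args=(0, 1.0)).pvalue
        passed += p > 0.01
    assert passed >= 9


def test_same_seed_same_trajectory(ref_system):
    t1 = simulate_ssa(ref_system, ref_system.default_init(), 200.0, seed=11)
    t2 = simulate_ssa(ref_system, ref_system.default_init(), 200.0, seed=11)
    assert np.array_equal(t1.times, t2.times)
    assert np.array_equal(t1.states, t2.states)


def test_snapshot_reproducible_and_order_independent(ref_system):
    s1 = sample_snapshot(ref_system, n_cells=200, seed=12, t_snap=300.0)
    s2 = sample_snapshot(ref_system, n_cells=200, seed=12, t_snap=300.0)
    assert np.array_equal(s1.values, s2.values)
    # first 100 per-cell seeds coincide with the length-100 ensemble's
    s3 = sample_snapshot(ref_system, n_cells=100, seed=12, t_snap=300.0)
    assert np.array_equal(s1.values[:100], s3.values)


def test_protein_decay_only_path_reaches_zero(ref_rates):
    system = build_reduced_model(ref_rates.replace(k_tr=0.0))
    init = system.default_init()
    init[system.species_index("Protein")] = 5
    traj = simulate_ssa(system, init, t_end=2000.0, seed=13)
    prot = traj.species_path(system, "Protein")
    assert (np.diff(prot) <= 0).all()
    assert prot[-1] == 0


def test_absorbing_state_ends_trajectory_early():
    system = ReactionSystem(
        species=("X",), reactions=(Reaction("decay", 1.0, (0,), ((0, -1),)),),
    )
    traj = simulate_ssa(system, [3], t_end=1e9, seed=14)
    assert traj.ended_early
    assert traj.final_state()[0] == 0


def test_one_state_snapshot_matches_closed_form_mean(ref_rates):
    system = build_unimodal_variant(ref_rates, "high")
    m = stationary_moments_closed_form(ref_rates, "H").mean["Protein"]
    snap = sample_snapshot(system, n_cells=3000, seed=15)
    se = snap.values.std() / np.sqrt(len(snap))
    assert abs(snap.values.mean() - m) < 4 * se


def test_single_cell_snapshot(ref_system):
    snap = sample_snapshot(ref_system, n_cells=1, seed=16, t_snap=50.0)
    assert len(snap) == 1


def test_closed_form_arithmetic():
    from bimodalkit.rates import RateSet

    r = RateSet(k_H=0.5, k_L=0.5, k_bind_L=1.0, k_bind_H=1.0, k_esc_L=1.0,
                k_esc_H=1.0, k_tr=1.0, kd_rna=1.0, kd_prot=1.0,
                n_rnap70=1, n_rnap38=0)
    m = stationary_moments_closed_form(r, "H")
    assert m.mean["RNA"] == pytest.approx(0.5)       # harmonic mean of 1 and 1
    assert m.mean["Protein"] == pytest.approx(0.5)
    m_sw = stationary_moments_closed_form(r, "none")
    assert m_sw.mean["Protein"] == pytest.approx(0.5)  # pi_H = 0.5, r_L = r_H
    with pytest.raises(ValueError):
        stationary_moments_closed_form(r.replace(kd_rna=0.0), "H")


def test_stationary_promoter_inits_split(ref_rates):
    system = build_reduced_model(ref_rates.replace(k_H=0.003, k_L=0.001))
    inits = stationary_promoter_inits(system, 4000, seed=17)
    frac_H = inits[:, system.species_index("Pr_H_free")].mean()
    assert abs(frac_H - 0.75) < 0.03
    assert (inits.sum(axis=1) == 1).all()  # promoter only, RNA=Protein=0


def test_project_states_carries_shared_species(ref_rates, ref_system):
    variant = build_unimodal_variant(ref_rates, "low")
    states = np.zeros((3, len(ref_system.species)), dtype=np.int64)
    states[:, ref_system.species_index("Pr_H_free")] = 1
    states[:, ref_system.species_index("RNA")] = [1, 2, 3]
    states[:, ref_system.species_index("Protein")] = [10, 20, 30]
    out = project_states(ref_system, states, variant)
    assert list(out[:, variant.species_index("RNA")]) == [1, 2, 3]
    assert list(out[:, variant.species_index("Protein")]) == [10, 20, 30]
    assert (out[:, variant.species_index("Pr_free")] == 1).all()


def test_default_snapshot_time_is_twenty_lifetimes(ref_system, ref_rates):
    assert default_snapshot_time(ref_system) == pytest.approx(20 / ref_rates.kd_prot)


def test_moments_from_values():
    m = Moments.from_values(np.array([1.0, 2.0, 3.0]))
    assert m.mean["Protein"] == pytest.approx(2.0)
    assert m.cv2["Protein"] == pytest.approx(np.var([1, 2, 3]) / 4.0)
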