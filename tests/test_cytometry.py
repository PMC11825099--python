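import dataclasses

import numpy as np
import pytest

from bimodalkit.cytometry import (
    SYNTHETIC_FIXTURES,
    PopulationSpec,
    generate_population,
    generate_wt_background,
    merge_replicates,
    model_to_intensity,
)
from bimodalkit.modality import classify_modality


def small(spec: PopulationSpec, n=3000) -> PopulationSpec:
    return dataclasses.replace(spec, n_cells=n)


def test_generation_is_deterministic():
    spec = small(SYNTHETIC_FIXTURES["synthetic_distant_even"])
    a = generate_population(spec, seed=5)
    b = generate_population(spec, seed=5)
    assert a.frame.equals(b.frame)
    c = generate_population(spec, seed=6)
    assert not a.frame["FITC-H"].equals(c.frame["FITC-H"])


def test_spec_validation():
    with pytest.raises(ValueError):
        PopulationSpec(components=((0.5, 2.0, 0.1), (0.4, 3.0, 0.1)))  # weights != 1
    with pytest.raises(ValueError):
        PopulationSpec(components=((1.0, 2.0, -0.1),))
    with pytest.raises(ValueError):
        PopulationSpec(components=((1.0, 2.0, 0.1),), size_corr=1.0)


def test_single_component_population_is_unimodal():
    spec = PopulationSpec(components=((1.0, 3.0, 0.15),), n_cells=4000,
                          n_replicates=1, extrinsic_sd=0.0, replicate_shift_sd=0.0)
    table = generate_population(spec, seed=7)
    call = classify_modality(table.intensities().values, kind="intensity")
    assert call.verdict == "unimodal"


def test_two_component_recovery():
    spec = PopulationSpec(
        components=((0.4, 2.0, 0.12), (0.6, 3.5, 0.15)),
        n_cells=10000, autofluor_mean=1.0, autofluor_sd=0.05,
    )
    table = generate_population(spec, seed=8)
    call = classify_modality(table.intensities().values, kind="intensity")
    assert call.is_bimodal
    assert call.fit2.weights == pytest.approx([0.4, 0.6], abs=0.05)
    assert call.fit2.means == pytest.approx([2.0, 3.5], abs=0.1)


def test_size_channel_correlation():
    spec = PopulationSpec(
        components=((0.4, 2.0, 0.2), (0.6, 3.5, 0.2)),
        n_cells=10000, size_corr=0.5, autofluor_mean=1.0, autofluor_sd=0.05,
    )
    table = generate_population(spec, seed=9)
    r = np.corrcoef(
        np.log10(table.channel("FITC-H")), np.log10(table.channel("FSC-H"))
    )[0, 1]
    assert r == pytest.approx(0.5, abs=0.05)


def test_scatter_channels_unimodal_for_all_fixtures():
    """Size-proxy channels must never mirror the intensity bimodality."""
    for name, spec in SYNTHETIC_FIXTURES.items():
        table = generate_population(small(spec, 2000), seed=10)
        for ch in ("SSC-H", "FSC-H", "Width"):
            call = classify_modality(table.channel(ch), kind="intensity")
            assert call.verdict == "unimodal", (name, ch)


def test_wt_background_unimodal_and_below_expressing_modes():
    wt = generate_wt_background(3000, seed=11)
    call = classify_modality(wt.intensities().values, kind="intensity")
    assert call.verdict == "unimodal"
    wt_mean = np.log10(wt.intensities().values).mean()
    lowest_mode = min(
        c[1] for spec in SYNTHETIC_FIXTURES.values() for c in spec.components
    )
    assert wt_mean < lowest_mode
    assert wt.frame.equals(generate_wt_background(3000, seed=11).frame)


def test_merge_replicates():
    spec = small(SYNTHETIC_FIXTURES["synthetic_close_even"], 500)
    tables = [generate_population(dataclasses.replace(spec, n_replicates=1), seed=s)
              for s in (1, 2, 3)]
    merged = merge_replicates(tables)
    assert len(merged) == 1500
    assert merge_replicates([tables[0]]).frame.equals(tables[0].frame)
    other = generate_population(
        dataclasses.replace(spec, n_replicates=1, condition="other"), seed=4
    )
    with pytest.raises(ValueError):
        merge_replicates([tables[0], other])


def test_replicate_ids_preserved():
    table = generate_population(small(SYNTHETIC_FIXTURES["synthetic_distant_even"], 400), seed=12)
    assert sorted(table.frame["replicate"].unique()) == [0, 1, 2]


def test_model_to_intensity_noise_free_is_affine(ref_snapshot):
    table = model_to_intensity(
        ref_snapshot, gain=1.0, extrinsic_sd=0.0, autofluor=(1.7, 0.0), seed=13
    )
    np.testing.assert_allclose(
        table.channel("FITC-H") - 10**1.7, ref_snapshot.values, rtol=1e-12
    )
    with pytest.raises(ValueError):
        model_to_intensity(ref_snapshot, gain=0.0)


def test_model_snapshot_with_moderate_noise_stays_bimodal(ref_snapshot):
    table = model_to_intensity(ref_snapshot, gain=30.0, extrinsic_sd=0.15, seed=14)
    call = classify_modality(table.intensities().values, kind="intensity")
    assert call.is_bimodal


def test_extrinsic_noise_pulls_modes_together(ref_snapshot):
    """Convolving with multiplicative noise broadens the modes: the relative
    peak distance d shrinks monotonically.  (o need not grow: the peaks also
    converge, shrinking the between-peak window, and at these conditions the
    window effect wins, so o drifts down as the modes approach.)"""
    from bimodalkit.modality import shape_params

    ds, seps = [], []
    for sd in (0.02, 0.15, 0.30):
        table = model_to_intensity(ref_snapshot, gain=30.0, extrinsic_sd=sd, seed=15)
        vals = table.intensities().values
        call = classify_modality(vals, kind="intensity")
        assert call.is_bimodal
        sp = shape_params(call, vals, kind="intensity")
        ds.append(sp.d)
        seps.append(sp.pk2 - sp.pk1)
    assert ds[0] > ds[1] > ds[2]
    assert seps[0] >= seps[1] - 0.02 and seps[1] >= seps[2] - 0.02
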