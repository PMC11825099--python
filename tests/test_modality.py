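import numpy as np
import pytest

from bimodalkit.modality import (
    MixtureFit,
    ModalityCall,
    ModalityConfig,
    DensityCurve,
    classify_bic,
    classify_modality,
    detect_peaks,
    estimate_density,
    mixture_is_bimodal,
    shape_params,
)


def test_kde_mode_near_true_mean(rng):
    x = rng.normal(100, 10, 10000)
    dens = estimate_density(x)
    mode = dens.grid[np.argmax(dens.density)]
    assert abs(mode - 100) < 2
    assert dens.integral() == pytest.approx(1.0, abs=0.01)


def test_density_rejects_degenerate_input(rng):
    with pytest.raises(ValueError):
        estimate_density(np.full(200, 7.0))
    with pytest.raises(ValueError):
        estimate_density(rng.normal(0, 1, 30))
    with pytest.raises(ValueError):
        estimate_density(-np.abs(rng.normal(1, 0.1, 100)) , kind="intensity")


def test_peak_detection_on_mixtures(rng):
    x = np.concatenate([rng.normal(50, 5, 5000), rng.normal(200, 15, 5000)])
    peaks = detect_peaks(estimate_density(x))
    assert len(peaks) == 2
    (p1, _), (p2, _) = peaks
    assert abs(p1 - 50) < 5 and abs(p2 - 200) < 10

    single = detect_peaks(estimate_density(rng.normal(100, 10, 5000)))
    assert len(single) == 1

    coincident = np.concatenate([rng.normal(100, 5, 5000), rng.normal(100, 15, 5000)])
    assert len(detect_peaks(estimate_density(coincident))) == 1


def test_bic_criterion_on_known_mixtures(rng):
    # well-separated mixture on log scale: overwhelming evidence
    x = np.concatenate([rng.normal(2, 0.1, 5000), rng.normal(3, 0.1, 5000)])
    ok, _, _, b1, b2 = classify_bic(x)
    assert ok and b2 < b1 - 10
    # tiny minor weight: rejected by the weight floor
    y = np.concatenate([rng.normal(2, 0.1, 9920), rng.normal(3.5, 0.1, 80)])
    assert not classify_bic(y)[0]
    # single Gaussians: rarely called bimodal
    false_pos = sum(
        classify_bic(np.random.default_rng(1000 + i).normal(5, 1, 10000))[0]
        for i in range(10)
    )
    assert false_pos == 0


def test_mixture_mode_guard():
    two_moded = MixtureFit(
        weights=np.array([0.5, 0.5]), means=np.array([0.0, 6.0]),
        sds=np.array([1.0, 1.0]), bic=0.0,
    )
    one_moded = MixtureFit(
        weights=np.array([0.5, 0.5]), means=np.array([0.0, 1.0]),
        sds=np.array([1.0, 1.5]), bic=0.0,
    )
    assert mixture_is_bimodal(two_moded)
    assert not mixture_is_bimodal(one_moded)


def test_verdict_is_or_of_criteria(ref_snapshot, rng):
    for values, kind in [
        (ref_snapshot.values, "count"),
        (rng.normal(100, 10, 2000), "count"),
        (10 ** np.concatenate([rng.normal(2, 0.1, 2000), rng.normal(3, 0.1, 2000)]), "intensity"),
    ]:
        call = classify_modality(values, kind=kind)
        assert call.is_bimodal == (call.bic_criterion or call.peaks_criterion)
        if call.is_bimodal:
            assert call.pk1 < call.pk2


def test_reference_model_snapshot_is_bimodal(ref_call):
    assert ref_call.verdict == "bimodal"
    # weak asymmetry with the taller first mode
    assert ref_call.pdf1 > ref_call.pdf2


def _call_with_peaks(pk1, pk2, pdf1, pdf2, max_density):
    dens = DensityCurve(
        grid=np.linspace(0, 100, 11),
        density=np.full(11, max_density), bandwidth=1.0,
    )
    return ModalityCall(
        verdict="bimodal", bic_criterion=False, peaks_criterion=True,
        fit1=None, fit2=None, density=dens,
        pk1=pk1, pk2=pk2, pdf1=pdf1, pdf2=pdf2,
    )


def test_shape_parameter_micro_examples():
    values = np.concatenate([[0.0, 100.0], np.full(48, 5.0), np.full(50, 95.0)])
    call = _call_with_peaks(10.0, 90.0, 0.02, 0.02, 0.02)
    sp = shape_params(call, values)
    assert sp.d == pytest.approx(0.8)          # (90-10)/(100-0)
    assert sp.h == pytest.approx(0.0)          # equal peak heights
    assert sp.o == pytest.approx(0.0)          # nothing strictly between peaks
    # observations strictly between the peaks count toward o
    values2 = np.concatenate([values, np.full(25, 50.0)])
    sp2 = shape_params(call, values2)
    assert sp2.o == pytest.approx(25 / 125)


def test_shape_params_refuse_unimodal(rng):
    call = classify_modality(rng.normal(100, 10, 2000))
    assert not call.is_bimodal
    with pytest.raises(ValueError):
        shape_params(call, rng.normal(100, 10, 2000))


def test_shape_params_affine_invariant(ref_snapshot):
    base = shape_params(classify_modality(ref_snapshot.values), ref_snapshot.values)
    rng = np.random.default_rng(7)
    for _ in range(5):
        a = 10 ** rng.uniform(-2, 2)
        b = rng.uniform(0, 50)
        v = a * ref_snapshot.values + b
        sp = shape_params(classify_modality(v), v)
        assert sp.d == pytest.approx(base.d, rel=1e-6, abs=1e-9)
        assert sp.h == pytest.approx(base.h, rel=1e-6, abs=1e-9)
        assert sp.o == pytest.approx(base.o, abs=1e-12)


def test_estimated_distance_monotone_in_true_separation(rng):
    seps = [20, 35, 50, 65]
    ds = []
    for s in seps:
        x = np.concatenate([rng.normal(50, 5, 5000), rng.normal(50 + s, 5, 5000)])
        call = classify_modality(x)
        ds.append(shape_params(call, x).d)
    assert all(b >= a - 0.02 for a, b in zip(ds, ds[1:]))


def test_shape_bounds(ref_snapshot, ref_call):
    sp = shape_params(ref_call, ref_snapshot.values)
    assert 0 <= sp.d <= 1 and 0 <= sp.o <= 1 and -1 <= sp.h <= 1


def test_config_thresholds_are_respected(rng):
    x = np.concatenate([rng.normal(2, 0.1, 5000), rng.normal(3, 0.1, 5000)])
    strict = ModalityConfig(delta_bic=1e9)
    ok, *_ = classify_bic(x, config=strict)
    assert not ok
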