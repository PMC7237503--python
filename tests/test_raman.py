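"""Raman preprocessing, QC, normalisation, ratios and group comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ariomics.raman import (
    RamanMap,
    band_ratios,
    compare_groups,
    crop_and_mask,
    despike,
    normalize_spectra,
    preprocess,
    qc_filter,
    run_map_pipeline,
)
from ariomics.synthetic import gen_raman_map


def make_map(spectra, lo=2700.0, hi=3100.0, map_id="m"):
    spectra = np.atleast_2d(spectra)
    wn = np.linspace(lo, hi, spectra.shape[1])
    coords = pd.DataFrame(
        {"x": 100.0 * np.arange(spectra.shape[0]), "y": 0.0}
    )
    coords.index.name = "pixel"
    return RamanMap(wn, spectra, coords, map_id=map_id)


def gauss(wn, c, s=7.0):
    return np.exp(-0.5 * ((wn - c) / s) ** 2)


def test_despike_removes_planted_spikes_only():
    study = gen_raman_map(nx=5, ny=5, n_spikes=4, seed=2, n_maps_per_group=1)
    for map_id, rmap in study.maps.items():
        spikes = study.spikes.query("map_id == @map_id")
        clean = despike(rmap.spectra)
        for _, row in spikes.iterrows():
            px, ch = int(row.pixel), int(row.channel)
            # essentially the whole planted spike magnitude is removed ...
            assert rmap.spectra[px, ch] - clean[px, ch] > 0.9 * 8.0 * 2e4
            # ... leaving the channel within noise of its local median
            window = rmap.spectra[px, max(ch - 10, 0): ch + 10]
            local = np.delete(window, np.argmax(window))
            mad = np.median(np.abs(local - np.median(local)))
            assert abs(clean[px, ch] - np.median(local)) < 5 * mad


def test_despike_identity_on_spike_free_spectrum():
    wn = np.linspace(2700, 3100, 401)
    spec = 10 + gauss(wn, 2880) + 0.5 * gauss(wn, 2935)
    assert np.array_equal(despike(spec[None, :]), spec[None, :])


def test_baseline_removes_exact_polynomial():
    wn = np.linspace(2700, 3100, 401)
    x = (wn - wn.mean()) / 200.0
    poly = np.polynomial.polynomial.polyval(x, np.arange(12, dtype=float) - 6)
    out = preprocess(make_map(poly), baseline_order=11)
    assert np.max(np.abs(out.spectra)) <= 1e-8 * np.max(np.abs(poly))


def test_baseline_order_validation():
    with pytest.raises(ValueError, match="baseline order"):
        preprocess(make_map(np.ones(10)), baseline_order=10)


def test_crop_point_count_and_range_error():
    spec = np.ones((2, 401))
    rmap = make_map(spec)  # 1/cm steps from 2700 to 3100
    cropped, _ = crop_and_mask(rmap)
    assert cropped.wavenumbers.size == 221
    assert cropped.wavenumbers[0] == 2800.0 and cropped.wavenumbers[-1] == 3020.0
    with pytest.raises(ValueError, match="outside axis"):
        crop_and_mask(rmap, lo=2000.0, hi=3020.0)


def test_all_zero_map_has_empty_tissue_mask():
    rmap = make_map(np.zeros((4, 401)))
    _, mask = crop_and_mask(rmap)
    assert not mask.any()


def test_qc_floor_boundary():
    n = 221
    base = np.zeros((3, n))
    base[0, 0] = 59_999.0   # strictly below the floor: dropped
    base[1, 0] = 60_000.0   # exactly the floor: retained
    base[2, 0] = 70_000.0
    rmap = make_map(base, lo=2800, hi=3020)
    kept, report = qc_filter(rmap, sd_k=100.0)  # disable stage 2
    assert report["dropped_stage1"] == 1
    assert set(kept.coords.index) == {1, 2}


def test_qc_identical_spectra_keep_all():
    rmap = make_map(np.full((6, 221), 500.0), lo=2800, hi=3020)
    kept, report = qc_filter(rmap)
    assert report["dropped_stage2"] == 0 and report["retained"] == 6


def test_qc_counts_add_up_and_empty_map_error():
    study = gen_raman_map(nx=6, ny=6, seed=5, n_maps_per_group=1)
    rmap = study.maps["CTL1"]
    pre = preprocess(rmap)
    cropped, mask = crop_and_mask(pre, tissue_quantile=0.0)
    kept, report = qc_filter(cropped)
    assert report["retained"] + report["dropped_stage1"] + report["dropped_stage2"] == report["n_input"]
    with pytest.raises(ValueError, match="every pixel"):
        qc_filter(make_map(np.ones((2, 221)), lo=2800, hi=3020), intensity_floor=1e9)


def test_background_pixels_all_dropped_at_floor_stage():
    study = gen_raman_map(nx=8, ny=8, frac_background=0.3, seed=7, n_maps_per_group=1)
    truth = study.truth
    for map_id, rmap in study.maps.items():
        pre = preprocess(rmap)
        cropped, _ = crop_and_mask(pre, tissue_quantile=0.0)
        kept, report = qc_filter(cropped)
        bg = set(truth.query("map_id == @map_id and is_background").pixel)
        assert bg.isdisjoint(set(kept.coords.index))
        assert report["dropped_stage1"] >= len(bg)
        # exact planted count: 0.3 * 64 rounds to 19
        assert len(bg) == 19


def test_normalize_affine_invariance_and_anchor():
    wn = np.linspace(2800, 3020, 221)
    spec = gauss(wn, 2845) + 0.6 * gauss(wn, 2880) + gauss(wn, 2933)
    rmap = make_map(np.vstack([spec, 3.5 * spec + 12.0]), lo=2800, hi=3020)
    out, flags = normalize_spectra(rmap)
    assert flags.empty
    assert np.allclose(out.spectra[0], out.spectra[1], atol=1e-12)
    anchor_ch = out.channel_of(2933.0)
    assert np.allclose(out.spectra[:, anchor_ch], 1.0)


def test_normalize_flags_constant_spectrum():
    rmap = make_map(np.vstack([np.ones(221), np.linspace(0, 1, 221)]), lo=2800, hi=3020)
    out, flags = normalize_spectra(rmap)
    assert list(flags["reason"]) == ["constant spectrum"]
    assert out.n_pixels == 1


def test_band_ratio_symmetry_and_monotonicity():
    wn = np.linspace(2700, 3100, 401)
    # equal amplitudes in a symmetric two-band spectrum: ratio exactly 1
    sym = gauss(wn, 2845) + gauss(wn, 2935)
    assert band_ratios(make_map(sym)).per_pixel["r_lipid"].iloc[0] == pytest.approx(
        1.0, abs=1e-6)
    # doubling the lipid-band amplitude increases the ratio
    base = 0.6 * gauss(wn, 2880)
    r1 = band_ratios(make_map(1.0 * gauss(wn, 2845) + base + gauss(wn, 2935))).per_pixel["r_lipid"][0]
    r2 = band_ratios(make_map(2.0 * gauss(wn, 2845) + base + gauss(wn, 2935))).per_pixel["r_lipid"][0]
    assert r2 > r1


def test_mannwhitney_brute_force_oracle():
    """U equals the count of pairwise wins (+ half ties) on small inputs."""
    rng = np.random.default_rng(0)
    for trial in range(10):
        na, nb = rng.integers(3, 8), rng.integers(3, 8)
        xa = np.round(rng.normal(1.0, 0.2, na), 2)
        xb = np.round(rng.normal(1.1, 0.2, nb), 2)
        results, grouping = {}, {}
        for i, v in enumerate(xa):
            mid = f"a{i}"
            results[mid] = _const_result(mid, v)
            grouping[mid] = "CTL"
        for i, v in enumerate(xb):
            mid = f"b{i}"
            results[mid] = _const_result(mid, v)
            grouping[mid] = "KO"
        table = compare_groups(results, grouping).set_index("ratio")
        brute = sum(
            1.0 if a > b else (0.5 if a == b else 0.0)
            for a, b in itertools.product(xa, xb)
        )
        assert table.loc["r_lipid", "U"] == pytest.approx(brute)


def _const_result(map_id, value):
    from ariomics.raman import BandRatioResult

    per_pixel = pd.DataFrame({"r_lipid": [value], "r_chol": [value]})
    return BandRatioResult(per_pixel, map_id=map_id)


def test_compare_groups_identical_and_errors():
    results = {m: _const_result(m, 1.0) for m in ["a", "b", "c", "d"]}
    grouping = {"a": "CTL", "b": "CTL", "c": "KO", "d": "KO"}
    table = compare_groups(results, grouping)
    assert (table["p"] == 1.0).all()
    with pytest.raises(KeyError):
        compare_groups(results, {"a": "CTL"})
    with pytest.raises(ValueError, match="two conditions"):
        compare_groups(results, {m: "CTL" for m in results})


def test_end_to_end_affine_invariance():
    """Band ratios are unchanged under positive affine rescaling of raw spectra.

    The absolute intensity floor is rescaled along with the spectra (the
    documented exception: the floor lives in input units).
    """
    study = gen_raman_map(nx=6, ny=6, seed=3, n_maps_per_group=1)
    rmap = study.maps["KO1"]
    a, b = 2.7, 350.0
    scaled = rmap.replace(spectra=a * rmap.spectra + b)
    res1, _ = run_map_pipeline(rmap)
    res2, _ = run_map_pipeline(scaled, intensity_floor=a * 60_000.0)
    assert np.allclose(
        res1.per_pixel.sort_index(), res2.per_pixel.sort_index(), rtol=1e-6
    )


def test_group_delta_recovery_and_power_smoke():
    """Planted ratio difference of 0.3 recovered within 10% (3-seed smoke).

    The 20-seed recovery and 100-seed power checks live in the acceptance
    suite.
    """
    deltas = []
    for seed in range(3):
        study = gen_raman_map(nx=6, ny=6, group_delta=0.3, seed=seed, n_maps_per_group=3)
        means = {}
        for map_id, rmap in study.maps.items():
            res, _ = run_map_pipeline(rmap)
            means[map_id] = res.mean["r_lipid"]
        ctl = np.mean([v for k, v in means.items() if study.grouping[k] == "CTL"])
        ko = np.mean([v for k, v in means.items() if study.grouping[k] == "KO"])
        deltas.append(ko - ctl)
    assert np.mean(deltas) == pytest.approx(0.3, rel=0.10)
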