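"""Localization pipeline: detection accuracy, superposition, projections."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from palocal.localization import (LocalizationEvent, LocalizationEventSet,
                                  acquisition_speedup, depth_encode,
                                  events_from_csv, events_to_csv,
                                  localize_frame, localize_series, make_dense,
                                  make_sparse, map_project, rasterize)
from palocal.phantom import AbsorberEvent, ImagingConfig, render_frame


def _single_absorber_frame(pos_um, noise=0.0, seed=0):
    config = ImagingConfig((64, 64), (25.0, 25.0), (125.0, 125.0),
                           noise_std=noise)
    rng = np.random.default_rng(seed) if noise > 0 else None
    return render_frame([AbsorberEvent(pos_um, 1.0, 0)], config, rng)


def test_centroid_subpixel_accuracy_noise_free():
    errors = []
    for pos_px in [(20.3, 41.7), (33.0, 33.5), (10.25, 50.75), (44.9, 12.1)]:
        frame = _single_absorber_frame(tuple(p * 25.0 for p in pos_px))
        # window 11 covers +-2.4 sigma of the 125 um PSF (sigma = 2.12 px)
        events = localize_frame(frame, amplitude_threshold=0.3, dog_sigma=2.0,
                                window=11)
        assert len(events) == 1
        err = np.linalg.norm(np.subtract(events.events[0].position, pos_px))
        errors.append(err)
    assert max(errors) < 0.2  # sub-pixel: worst case under a fifth of a pixel


def test_localization_much_finer_than_psf():
    """The localization error is far below the PSF width (the whole point)."""
    frame = _single_absorber_frame((20.3 * 25.0, 41.7 * 25.0))
    events = localize_frame(frame, amplitude_threshold=0.3, dog_sigma=2.0,
                            window=11)
    err_um = 25.0 * np.linalg.norm(np.subtract(events.events[0].position,
                                               (20.3, 41.7)))
    assert err_um < 125.0 / 10  # better than a tenth of the PSF FWHM


def test_localize_empty_and_all_zero_frame():
    empty = localize_frame(np.zeros((16, 16)))
    assert len(empty) == 0
    assert empty.grid_shape == (16, 16)


def test_localize_frame_separates_two_absorbers():
    config = ImagingConfig((64, 64), (25.0, 25.0), (125.0, 125.0), noise_std=0.0)
    frame = render_frame([AbsorberEvent((400.0, 400.0), 1.0, 0),
                          AbsorberEvent((400.0, 1200.0), 0.8, 0)], config)
    events = localize_frame(frame, amplitude_threshold=0.3, dog_sigma=2.0)
    assert len(events) == 2
    ys = sorted(ev.position[1] for ev in events.events)
    assert ys[0] == pytest.approx(16.0, abs=0.2)
    assert ys[1] == pytest.approx(48.0, abs=0.2)


def test_localize_frame_validation():
    with pytest.raises(ValueError, match="amplitude_threshold"):
        localize_frame(np.ones((8, 8)), amplitude_threshold=1.5)
    with pytest.raises(ValueError, match="window"):
        localize_frame(np.ones((8, 8)), window=4)


def test_rasterize_sum_conserves_total_amplitude():
    events = LocalizationEventSet(
        [LocalizationEvent((3.2, 4.7), 0.5, 0),
         LocalizationEvent((3.2, 4.7), 0.25, 1),
         LocalizationEvent((10.0, 2.0), 1.0, 2)], (16, 16))
    img = rasterize(events, superres_factor=2, mode="sum", normalize=False)
    assert img.data.shape == (32, 32)
    assert img.data.sum() == pytest.approx(1.75, abs=1e-12)
    assert img.data[6, 9] == pytest.approx(0.75)  # co-located events add


def test_rasterize_max_keeps_peak_amplitude():
    events = LocalizationEventSet(
        [LocalizationEvent((3.2, 4.7), 0.5, 0),
         LocalizationEvent((3.2, 4.7), 0.25, 1)], (16, 16))
    img = rasterize(events, superres_factor=2, mode="max", normalize=False)
    assert img.data[6, 9] == pytest.approx(0.5)


def test_rasterize_normalizes_to_unit_peak():
    events = LocalizationEventSet([LocalizationEvent((1.0, 1.0), 0.3, 0)], (4, 4))
    img = rasterize(events, mode="sum", normalize=True)
    assert img.data.max() == pytest.approx(1.0)


@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_rasterize_permutation_invariant(seed):
    r = np.random.default_rng(seed)
    evs = [LocalizationEvent((float(r.uniform(0, 16)), float(r.uniform(0, 16))),
                             float(r.uniform(0.1, 1.0)), i) for i in range(10)]
    base = rasterize(LocalizationEventSet(evs, (16, 16)), 2, "sum", False)
    perm = [evs[i] for i in r.permutation(10)]
    shuffled = rasterize(LocalizationEventSet(perm, (16, 16)), 2, "sum", False)
    assert np.allclose(base.data, shuffled.data)


def _toy_event_sets(n_frames=6, per_frame=3, seed=0):
    r = np.random.default_rng(seed)
    sets = []
    for fi in range(n_frames):
        evs = [LocalizationEvent((float(r.uniform(0, 16)), float(r.uniform(0, 16))),
                                 float(r.uniform(0.1, 1.0)), fi)
               for _ in range(per_frame)]
        sets.append(LocalizationEventSet(evs, (16, 16)))
    return sets


def test_make_dense_uses_all_frames():
    sets = _toy_event_sets()
    dense = make_dense(sets, superres_factor=2, mode="sum", normalize=False)
    assert dense.k_used == dense.n_total == len(sets)
    total = sum(ev.amplitude for s in sets for ev in s.events)
    assert dense.data.sum() == pytest.approx(total)


def test_make_sparse_frames_subset_and_determinism():
    sets = _toy_event_sets()
    s1 = make_sparse(sets, k=2, seed=5, mode="sum", unit="frames", normalize=False)
    s2 = make_sparse(sets, k=2, seed=5, mode="sum", unit="frames", normalize=False)
    assert np.array_equal(s1.data, s2.data)
    assert s1.k_used == 2 and s1.n_total == len(sets)
    dense = make_dense(sets, mode="sum", normalize=False)
    assert s1.data.sum() < dense.data.sum()


def test_make_sparse_events_unit_counts_droplets():
    sets = _toy_event_sets()
    n_events = sum(len(s) for s in sets)
    sp = make_sparse(sets, k=4, seed=1, mode="sum", unit="events", normalize=False)
    assert sp.n_total == n_events and sp.k_used == 4
    with pytest.raises(ValueError, match="k must be in"):
        make_sparse(sets, k=n_events + 1, seed=1, unit="events")


def test_acquisition_speedup_values():
    assert acquisition_speedup(60, 5) == pytest.approx(12.0)
    assert acquisition_speedup(240_000, 20_000) == pytest.approx(12.0)
    with pytest.raises(ValueError):
        acquisition_speedup(10, 0)


def test_map_project_and_depth_encode_against_bruteforce(rng):
    vol = rng.random((6, 5, 7))
    mp = map_project(vol)
    depth, amp = depth_encode(vol)
    for i in range(6):
        for j in range(5):
            assert mp[i, j] == vol[i, j].max()
            assert depth[i, j] == int(np.argmax(vol[i, j]))
            assert amp[i, j] == vol[i, j, depth[i, j]]
    with pytest.raises(ValueError):
        map_project(vol[:, :, 0])


def test_depth_encode_tie_breaks_to_smallest_z():
    vol = np.zeros((1, 1, 4))
    vol[0, 0, [1, 3]] = 1.0
    depth, _ = depth_encode(vol)
    assert depth[0, 0] == 1


def test_events_csv_roundtrip(tmp_path):
    sets = _toy_event_sets(n_frames=4)
    path = tmp_path / "events.csv"
    events_to_csv(sets, path)
    back = events_from_csv(path, (16, 16))
    assert len(back) == 4
    for orig, rt in zip(sets, back):
        assert len(orig) == len(rt)
        for a, b in zip(orig.events, rt.events):
            assert np.allclose(a.position, b.position, atol=1e-6)
            assert a.frame_index == b.frame_index


def test_localize_series_preserves_frame_indices():
    config = ImagingConfig((32, 32), (25.0, 25.0), (125.0, 125.0), noise_std=0.0)
    frames = [render_frame([AbsorberEvent((400.0, 400.0), 1.0, i)], config)
              for i in range(3)]
    from palocal.phantom import FrameSeries

    series = FrameSeries(frames, config)
    sets = localize_series(series, amplitude_threshold=0.3, dog_sigma=2.0)
    assert [s.events[0].frame_index for s in sets] == [0, 1, 2]
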