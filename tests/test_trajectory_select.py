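import numpy as np
import pytest

from ncitraj.trajectory_select import (
    EmptyContactSetError,
    NativeContactSet,
    QSeries,
    TransitionSegment,
    build_native_contacts,
    detect_transitions,
    ensemble_frames,
    fraction_native_contacts,
    q_series,
    sample_transition_frames,
)


def brute_force_transitions(values, q_low=0.1, q_high=0.9):
    """Independent re-derivation: for every first-entry into a basin different
    from the previously visited one, the segment starts at the last frame in
    the departure basin."""
    out = []
    visited = None
    last_in_basin = None
    for t, v in enumerate(values):
        b = 1 if v >= q_high else (-1 if v <= q_low else None)
        if b is None:
            continue
        if visited is not None and b != visited:
            out.append((last_in_basin, t, "folding" if b == 1 else "unfolding"))
        visited, last_in_basin = b, t
    return out


def _contact():
    return NativeContactSet(
        atom_i=np.array([0]), atom_j=np.array([1]), r0=np.array([2.0]),
        heavy_cutoff=4.5, min_sep=3,
    )


def test_sigmoid_midpoint_is_exactly_half():
    c = _contact()
    frame = np.array([[0.0, 0.0, 0.0], [1.8 * 2.0, 0.0, 0.0]])  # d = lam * r0
    assert fraction_native_contacts(frame, c) == pytest.approx(0.5, abs=1e-15)


def test_q_limits():
    c = _contact()
    near = np.array([[0.0, 0.0, 0.0], [0.5, 0.0, 0.0]])
    far = np.array([[0.0, 0.0, 0.0], [30.0, 0.0, 0.0]])
    assert fraction_native_contacts(near, c) > 0.99
    assert fraction_native_contacts(far, c) < 1e-6


def test_q_series_matches_per_frame():
    c = _contact()
    frames = np.stack([
        np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]]) for d in (0.5, 2.0, 3.6, 10.0)
    ])
    q = q_series(frames, c)
    singles = [fraction_native_contacts(f, c) for f in frames]
    np.testing.assert_allclose(q.q, singles, rtol=1e-12)


def test_qseries_validates_range():
    with pytest.raises(ValueError):
        QSeries(q=np.array([0.5, 1.2]))


def test_build_native_contacts_requires_contacts():
    from ncitraj.fragments_io import Fragment

    frags = [
        Fragment(f"A:R{i}", "RES", "A", i, ["C"], np.array([[i * 50.0, 0, 0]]),
                 np.array([i - 1]))
        for i in (1, 6)
    ]
    with pytest.raises(EmptyContactSetError):
        build_native_contacts(frags)


def test_detect_transitions_recrossing_excluded():
    # leaves the unfolded basin, returns, then folds: one folding event
    q = [0.05, 0.5, 0.05, 0.95]
    segs = detect_transitions(q)
    assert len(segs) == 1
    assert segs[0].direction == "folding"
    assert (segs[0].start_frame, segs[0].end_frame) == (2, 3)


def test_detect_transitions_matches_brute_force():
    rng = np.random.default_rng(12)
    for _ in range(50):
        vals = rng.uniform(0, 1, size=rng.integers(5, 200))
        segs = detect_transitions(vals)
        ref = brute_force_transitions(vals)
        assert [(s.start_frame, s.end_frame, s.direction) for s in segs] == ref


def test_detect_transitions_mirror_symmetry():
    rng = np.random.default_rng(3)
    vals = rng.uniform(0, 1, 300)
    fwd = detect_transitions(vals)
    rev = detect_transitions(vals[::-1])
    n = len(vals)
    fwd_mapped = sorted((n - 1 - s.end_frame, n - 1 - s.start_frame) for s in fwd)
    rev_bounds = sorted((s.start_frame, s.end_frame) for s in rev)
    assert fwd_mapped == rev_bounds


def test_no_transition_without_both_basins():
    assert detect_transitions([0.5, 0.6, 0.4]) == []
    assert detect_transitions([0.05, 0.06, 0.02]) == []


def test_sample_transition_frames_density_and_flanks():
    seg = TransitionSegment(start_frame=1000, end_frame=1999, direction="folding")
    frames = sample_transition_frames(seg, n_frames_total=5000, n_target=100, flank=10)
    inside = frames[(frames >= 1000) & (frames <= 1999)]
    assert 95 <= len(inside) <= 115
    assert (frames < 1000).sum() == 10
    assert (frames > 1999).sum() == 10
    assert np.all(np.diff(frames) > 0)


def test_sample_transition_frames_clipped_at_bounds():
    seg = TransitionSegment(start_frame=2, end_frame=40, direction="folding")
    frames = sample_transition_frames(seg, n_frames_total=45, n_target=100, flank=10)
    assert frames.min() >= 0 and frames.max() <= 44


def test_ensemble_frames_deterministic_and_disjoint_basins():
    rng = np.random.default_rng(0)
    q = rng.uniform(0, 1, 3000)
    folded = ensemble_frames(q, "folded", n=50, seed=4)
    folded2 = ensemble_frames(q, "folded", n=50, seed=4)
    np.testing.assert_array_equal(folded, folded2)
    assert len(folded) == 50
    assert np.all(q[folded] >= 0.9)
    unfolded = ensemble_frames(q, "unfolded", n=50, seed=4)
    assert np.all(q[unfolded] <= 0.1)
    assert not set(folded) & set(unfolded)


def test_ensemble_frames_transition_band():
    q = np.concatenate([[0.05], np.linspace(0.05, 0.95, 41), [0.95]])
    frames = ensemble_frames(q, "transition", n=500, seed=0)
    assert len(frames) > 0
    assert np.all((q[frames] >= 0.4) & (q[frames] <= 0.6))


def test_ensemble_frames_empty_raises():
    with pytest.raises(ValueError):
        ensemble_frames(np.full(10, 0.5), "folded")
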