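import numpy as np
import pytest

from ncitraj.synthetic_fixtures import (
    MOTIF_A_PAIRS,
    MOTIF_B_PAIRS,
    make_apolar_dimer,
    make_hbond_dimer,
    make_toy_folding_trajectory,
)


def test_hbond_dimer_geometry():
    d = make_hbond_dimer(2.9)
    n = d.fragA.coords[0]
    h = d.fragA.coords[1]
    o = d.fragB.coords[0]
    assert np.linalg.norm(o - n) == pytest.approx(2.9)
    assert np.linalg.norm(o - h) == pytest.approx(2.9 - 1.01)
    # collinear donor-H-acceptor
    v1, v2 = n - h, o - h
    cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
    assert cosang == pytest.approx(-1.0)


def test_dimer_determinism():
    a = make_hbond_dimer(3.1)
    b = make_hbond_dimer(3.1)
    np.testing.assert_array_equal(a.fragA.coords, b.fragA.coords)
    np.testing.assert_array_equal(a.fragB.coords, b.fragB.coords)
    c = make_apolar_dimer(4.2)
    d = make_apolar_dimer(4.2)
    np.testing.assert_array_equal(c.fragB.coords, d.fragB.coords)


def test_dimer_separation_validation():
    with pytest.raises(ValueError):
        make_hbond_dimer(1.0)
    with pytest.raises(ValueError):
        make_apolar_dimer(2.0)


def test_apolar_dimer_geometry():
    d = make_apolar_dimer(4.0)
    assert d.fragA.elements == ["C", "H", "H", "H", "H"]
    cc = np.linalg.norm(d.fragB.coords[0] - d.fragA.coords[0])
    assert cc == pytest.approx(4.0)
    for frag in (d.fragA, d.fragB):
        for h in frag.coords[1:]:
            assert np.linalg.norm(h - frag.coords[0]) == pytest.approx(1.09, abs=1e-9)


def test_apolar_total_decays_with_separation(coarse_params):
    from ncitraj.grid_engine import pair_integrals

    near = make_apolar_dimer(4.0)
    far = make_apolar_dimer(8.0)
    t_near = pair_integrals(near.fragA, near.fragB, coarse_params).total
    t_far = pair_integrals(far.fragA, far.fragB, coarse_params).total
    assert t_near > 0
    assert t_far < 0.05 * t_near


def test_toy_trajectory_structure():
    toy = make_toy_folding_trajectory(n_events=4, seed=2)
    assert toy.xyz.shape[1] == 24
    assert len(toy.fragments) == 8
    assert len(toy.event_bounds) == 4
    assert toy.event_directions == ["folding", "unfolding", "folding", "unfolding"]
    assert MOTIF_A_PAIRS == ((1, 5), (2, 6))
    assert MOTIF_B_PAIRS == ((3, 7), (4, 8))


def test_toy_trajectory_determinism():
    a = make_toy_folding_trajectory(n_events=2, seed=9)
    b = make_toy_folding_trajectory(n_events=2, seed=9)
    np.testing.assert_array_equal(a.xyz, b.xyz)
    c = make_toy_folding_trajectory(n_events=2, seed=10)
    assert not np.array_equal(a.xyz, c.xyz)


def test_toy_single_event_detected():
    from ncitraj.trajectory_select import build_native_contacts, detect_transitions, q_series

    toy = make_toy_folding_trajectory(n_events=1, seed=0)
    contacts = build_native_contacts(toy.fragments)
    q = q_series(toy.xyz, contacts)
    segs = detect_transitions(q)
    assert len(segs) == 1
    assert segs[0].direction == "folding"


def test_toy_q_spans_basins():
    from ncitraj.trajectory_select import build_native_contacts, q_series

    toy = make_toy_folding_trajectory(n_events=2, seed=1)
    q = q_series(toy.xyz, build_native_contacts(toy.fragments))
    assert q.q[0] < 0.1
    mid_gap = (toy.event_bounds[0][1] + toy.event_bounds[1][0]) // 2
    assert q.q[mid_gap] > 0.9


def test_toy_noise_free_contact_distances_decrease_in_window():
    toy = make_toy_folding_trajectory(n_events=1, noise_sigma=0.0, seed=0)
    start, end = toy.event_bounds[0]
    # motif-A partners approach each other inside their formation window;
    # the linear approach path allows a sub-angstrom bounce near closest
    # approach, so monotonicity is asserted up to that geometric tolerance
    i, j = 0, 4  # residues 1 and 5 (0-based fragment indices)
    d = np.linalg.norm(
        toy.xyz[start : end + 1, 3 * i, :] - toy.xyz[start : end + 1, 3 * j, :], axis=1
    )
    window = slice(int(0.10 * len(d)), int(0.45 * len(d)))
    dw = d[window]
    assert dw[0] > 20.0 and dw[-1] < 5.5
    assert np.all(np.diff(dw) <= 0.2)
    # outside the window the pair does not move at all (noise-free)
    before = d[: window.start]
    assert np.allclose(before, before[0])


def test_toy_pathway_mix_counts():
    toy = make_toy_folding_trajectory(n_events=20, pathway1_fraction=0.6, seed=3)
    folding_paths = [
        p for p, d in zip(toy.event_pathways, toy.event_directions) if d == "folding"
    ]
    assert folding_paths.count(0) == 6
    assert folding_paths.count(1) == 4


def test_toy_validation():
    with pytest.raises(ValueError):
        make_toy_folding_trajectory(n_events=0)
    with pytest.raises(ValueError):
        make_toy_folding_trajectory(pathway1_fraction=1.5)
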