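import numpy as np
import pytest

from ncitraj.fragments_io import Fragment, enumerate_pairs
from ncitraj.interaction_analysis import (
    PairSeries,
    build_contact_maps,
    correlate_hbonds_attractive,
    delta_integrals,
    detect_hbonds,
    pair_integral_series,
    pair_min_heavy_distance,
    series_dataframe,
    smooth_series,
    total_channel_series,
)


def _frag(fid, seq, elements, coords, chain="A"):
    return Fragment(fid, "RES", chain, seq, elements, np.asarray(coords, float),
                    atom_indices=None)


def hbond_geometry(distance_ha, angle_deg):
    """Donor N-H (1.01 angstrom) plus acceptor O at the given H...O geometry."""
    theta = np.radians(180.0 - angle_deg)
    h = np.array([1.01, 0.0, 0.0])
    o = h + distance_ha * np.array([np.cos(theta), np.sin(theta), 0.0])
    donor = _frag("A:DON1", 1, ["N", "H"], [[0, 0, 0], h])
    acceptor = _frag("A:ACC5", 5, ["O"], [o])
    return [donor, acceptor]


def test_hbond_geometry_scan():
    counts = [len(detect_hbonds(hbond_geometry(d, 170.0))) for d in (1.8, 2.4, 2.6)]
    assert counts == [1, 1, 0]


def test_hbond_angle_cut():
    assert len(detect_hbonds(hbond_geometry(2.0, 110.0))) == 0
    assert len(detect_hbonds(hbond_geometry(2.0, 121.0))) == 1


def test_hbond_sequence_separation_excluded():
    frags = hbond_geometry(1.9, 175.0)
    close = [frags[0], _frag("A:ACC2", 2, ["O"], frags[1].coords)]
    assert len(detect_hbonds(close)) == 0  # |1-2| <= 3 on the same chain


def test_hbond_requires_hydrogens():
    a = _frag("A:R1", 1, ["N"], [[0, 0, 0]])
    b = _frag("A:R5", 5, ["O"], [[2.5, 0, 0]])
    with pytest.raises(ValueError):
        detect_hbonds([a, b])


def test_hbond_record_geometry_fields():
    rec = detect_hbonds(hbond_geometry(1.9, 170.0))[0]
    assert rec.distance_ha == pytest.approx(1.9, abs=1e-9)
    assert rec.angle_dha == pytest.approx(170.0, abs=1e-6)
    assert rec.distance_da < 1.01 + 1.9


def test_correlate_perfect_linear_series():
    x = np.array([0.0, 1, 2, 3, 4, 5])
    assert correlate_hbonds_attractive(x, 2.0 * x + 1.0) == pytest.approx(1.0)


def test_correlate_zero_variance_is_nan():
    with pytest.warns(UserWarning):
        out = correlate_hbonds_attractive(np.ones(5), np.arange(5.0))
    assert np.isnan(out)


def test_smooth_series_preserves_linear_ramp():
    # centred odd-window moving average leaves a linear ramp unchanged inside
    x = np.arange(30.0)
    sm = smooth_series(x, window=5)
    np.testing.assert_allclose(sm[2:-2], x[2:-2], rtol=1e-12)
    assert len(sm) == len(x)


def test_smooth_series_window_longer_than_series():
    x = np.array([1.0, 2.0, 3.0])
    with pytest.warns(UserWarning):
        sm = smooth_series(x, window=10)
    np.testing.assert_allclose(sm, 2.0)


def test_smooth_series_reduces_noise_variance():
    rng = np.random.default_rng(1)
    x = rng.normal(0, 1, 500)
    assert np.var(smooth_series(x, 10)) < 0.3 * np.var(x)


def test_pair_series_validation():
    with pytest.raises(ValueError):
        PairSeries(("a", "b"), np.arange(3), np.zeros(2), np.zeros(3), np.zeros(3))
    with pytest.raises(ValueError):
        PairSeries(("a", "b"), np.arange(2), np.array([-1.0, 0]), np.zeros(2), np.zeros(2))


def test_pair_integral_series_prefilter_and_channels(toy_small, coarse_params):
    toy = toy_small
    pairs = enumerate_pairs(toy.fragments)
    frames = [0, 40]  # unfolded and mid-folding
    series = pair_integral_series(toy.xyz, frames, toy.fragments, pairs, coarse_params)
    assert len(series) == len(pairs)
    by_pair = {s.pair: s for s in series}
    far = by_pair[("A:RES1", "A:RES8")]  # never in contact
    assert np.all(far.total == 0.0)
    df = series_dataframe(series)
    assert set(df.columns) >= {"frame", "resi", "resj", "attractive", "vdw", "repulsive"}
    agg = total_channel_series(series, "vdw")
    assert agg.shape == (2,)


def test_min_heavy_distance():
    a = _frag("a", 1, ["C", "H"], [[0, 0, 0], [0.5, 0, 0]])
    b = _frag("b", 5, ["C", "H"], [[3.0, 0, 0], [2.0, 0, 0]])
    assert pair_min_heavy_distance(a, b) == pytest.approx(3.0)  # H ignored


def test_contact_maps_symmetry(toy_small, coarse_params):
    toy = toy_small
    pairs = enumerate_pairs(toy.fragments)
    maps = build_contact_maps(toy.xyz, [60, 62], toy.fragments, pairs,
                              coarse_params, label="folded")
    for m in (maps.vdw, maps.att_minus_rep, maps.inv_dist6, maps.inv_hbond_dist):
        np.testing.assert_allclose(m, m.T)
        assert np.all(np.diag(m) == 0)
    # the planted contacts must dominate the inverse-distance map
    assert maps.inv_dist6[0, 4] > maps.inv_dist6[0, 7]


def test_delta_integrals_maps(toy_small, coarse_params):
    toy = toy_small
    pairs = enumerate_pairs(toy.fragments)
    folded = build_contact_maps(toy.xyz, [62], toy.fragments, pairs, coarse_params)
    unfolded = build_contact_maps(toy.xyz, [0], toy.fragments, pairs, coarse_params)
    delta = delta_integrals(folded, unfolded)
    assert delta["vdw"][0, 4] > 0  # contact formed on folding
    with pytest.raises(TypeError):
        delta_integrals(folded, 3)


def test_sasa_monotone_under_burial(toy_small):
    from ncitraj.fragments_io import fragments_to_mdtraj
    from ncitraj.interaction_analysis import sasa

    toy = toy_small
    traj = fragments_to_mdtraj(toy.fragments, xyz_frames=toy.xyz[[0, 62]])
    area = sasa(traj)
    assert area.shape == (2, 8)
    # folding buries surface of the docking partners
    assert area[1].sum() < area[0].sum()
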