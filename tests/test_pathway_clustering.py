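import numpy as np
import pytest

from ncitraj.interaction_analysis import PairSeries
from ncitraj.pathway_clustering import (
    NOISE_LABEL,
    PairFeatureMatrix,
    PathwayProfile,
    build_pair_features,
    cluster_pairs,
    cluster_transitions,
    first_crossing,
    motif_formation_order,
    motif_profiles,
    resample_profile,
    transition_features,
)


def _ramp(n, start, stop):
    t = np.linspace(0, 1, n)
    return np.clip((t - start) / max(stop - start, 1e-9), 0, 1)


def _series(pair, profile, frames=None):
    n = len(profile)
    frames = np.arange(n) if frames is None else frames
    return PairSeries(pair=pair, frames=frames, attractive=np.asarray(profile),
                      vdw=np.zeros(n), repulsive=np.zeros(n))


def planted_features(noise=0.0, seed=0, n=60):
    """Two motifs: early formers and late formers, plus one silent pair."""
    rng = np.random.default_rng(seed)
    series = []
    norms = {}
    for i in range(3):
        prof = _ramp(n, 0.1, 0.4) + noise * rng.normal(0, 1, n)
        pair = (f"A:R{i}", f"A:R{i + 10}")
        series.append(_series(pair, np.clip(prof, 0, None)))
        norms[pair] = 1.0
    for i in range(3, 6):
        prof = _ramp(n, 0.6, 0.9) + noise * rng.normal(0, 1, n)
        pair = (f"A:R{i}", f"A:R{i + 10}")
        series.append(_series(pair, np.clip(prof, 0, None)))
        norms[pair] = 1.0
    silent = ("A:R9", "A:R19")
    series.append(_series(silent, np.zeros(n)))
    norms[silent] = 0.0
    return series, norms


def test_resample_profile_endpoints():
    x = np.array([1.0, 2.0, 4.0])
    out = resample_profile(x, 5)
    assert out[0] == 1.0 and out[-1] == 4.0 and len(out) == 5


def test_first_crossing():
    p = np.array([0.0, 0.2, 0.6, 1.0])
    assert first_crossing(p, 0.5) == pytest.approx(1.75)
    assert first_crossing(p, 2.0) == np.inf
    assert first_crossing(p, 0.0) == 0.0


def test_build_pair_features_normalisation_and_reversal():
    series, norms = planted_features()
    fwd = build_pair_features(series, "folding", norms)
    rev = build_pair_features(series, "unfolding", norms)
    assert fwd.features.max() <= 1.5
    # unfolding features are the time-reversed folding features
    n = fwd.n_progress
    np.testing.assert_allclose(fwd.features[0][:n], rev.features[0][:n][::-1], atol=1e-9)
    assert not fwd.active[-1]  # silent pair
    with pytest.raises(ValueError):
        build_pair_features(series, "sideways", norms)


def test_cluster_pairs_recovers_planted_motifs():
    series, norms = planted_features(noise=0.02, seed=4)
    fm = build_pair_features(series, "folding", norms)
    out = cluster_pairs(fm)
    assert out.n_motifs == 2
    early = {s.pair for s in series[:3]}
    late = {s.pair for s in series[3:6]}
    # motif 0 forms first by construction of the labels
    assert set(out.members(0)) == early
    assert set(out.members(1)) == late
    assert out.labels[-1] == NOISE_LABEL  # silent pair


def test_cluster_pairs_all_inactive():
    fm = PairFeatureMatrix(pair_ids=(("a", "b"),), features=np.zeros((1, 300)),
                           active=np.zeros(1, dtype=bool))
    out = cluster_pairs(fm)
    assert out.n_motifs == 0
    assert out.labels[0] == NOISE_LABEL


def test_synchrony_merges_simultaneous_clusters():
    # two "groups" with identical timing but different amplitude jitter
    rng = np.random.default_rng(0)
    n = 60
    series, norms = [], {}
    for i in range(6):
        prof = (1.0 + 0.2 * rng.normal()) * _ramp(n, 0.3, 0.6) + 0.01 * rng.normal(0, 1, n)
        pair = (f"A:R{i}", f"A:R{i + 10}")
        series.append(_series(pair, np.clip(prof, 0, None)))
        norms[pair] = 1.0
    fm = build_pair_features(series, "folding", norms)
    out = cluster_pairs(fm)
    assert out.n_motifs == 1  # simultaneity must not be split into sequence


def test_motif_profiles_monotone_in_unit_interval():
    series, norms = planted_features(noise=0.02, seed=4)
    fm = build_pair_features(series, "folding", norms)
    out = cluster_pairs(fm)
    prof = motif_profiles(fm, out)
    assert prof.shape == (out.n_motifs, fm.n_progress)
    assert np.all(prof >= 0) and np.all(prof <= 1)
    assert np.all(np.diff(prof, axis=1) >= -1e-12)
    # motif 0 (early) reaches half formation before motif 1 (late)
    p = PathwayProfile(0, "folding", prof)
    assert motif_formation_order(p) == (0, 1)


def _profile(order, n=100, jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for rank in order:
        lo = 0.1 + 0.5 * rank + jitter * rng.normal()
        rows.append(_ramp(n, lo, lo + 0.3))
    return np.stack(rows)


def test_cluster_transitions_two_planted_pathways():
    profiles = []
    planted = [0, 1, 0, 0, 1, 0, 1, 0, 0, 1]
    for i, p in enumerate(planted):
        order = (0, 1) if p == 0 else (1, 0)
        mf = _profile([order.index(0), order.index(1)], jitter=0.01, seed=i)
        profiles.append(PathwayProfile(i, "folding", mf))
    labels, k = cluster_transitions(profiles)
    assert k == 2
    # permutation-invariant agreement
    planted = np.array(planted)
    agree = max(np.mean(labels == planted), np.mean(labels == 1 - planted))
    assert agree == 1.0


def test_cluster_transitions_single_pathway():
    profiles = [
        PathwayProfile(i, "folding", _profile([0, 1], jitter=0.005, seed=i))
        for i in range(8)
    ]
    labels, k = cluster_transitions(profiles)
    assert k == 1
    assert np.all(labels == 0)


def test_transition_features_shape_mismatch():
    p1 = PathwayProfile(0, "folding", _profile([0, 1]))
    p2 = PathwayProfile(1, "folding", _profile([0]))
    with pytest.raises(ValueError):
        transition_features([p1, p2])
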