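"""Clustering of interaction formation profiles and of folding transitions.

Two clustering problems are solved here:

1. **Pair motifs.** Within one transition, each residue pair contributes a
   3-channel NCI integral profile over the sampled frames.  Profiles are
   resampled onto a common progress axis (unfolding events time-reversed so
   that progress always runs unfolded -> folded), normalised by the
   folded-ensemble mean total of the same pair, and clustered with
   average-linkage agglomerative clustering under correlation distance.  The
   cluster count is chosen by silhouette score; pairs whose profile correlates
   weakly with their own cluster mean are relabelled noise, and clusters whose
   members form essentially simultaneously are merged into an "other" label.

2. **Pathways.** Each transition is summarised by the concatenated
   motif-fraction formation profiles (fraction of each motif's eventual signal
   formed as a function of progress).  Transitions are clustered the same way;
   the cluster count is chosen by consensus of silhouette, Calinski-Harabasz
   and Davies-Bouldin over k = 2..k_max, falling back to one cluster when no
   split is supported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .interaction_analysis import PairSeries

__all__ = [
    "PairFeatureMatrix",
    "MotifAssignment",
    "PathwayProfile",
    "NOISE_LABEL",
    "OTHER_LABEL",
    "resample_profile",
    "build_pair_features",
    "correlation_distance_matrix",
    "cluster_pairs",
    "motif_profiles",
    "first_crossing",
    "motif_formation_order",
    "transition_features",
    "cluster_transitions",
]

NOISE_LABEL = -1
OTHER_LABEL = -2

#: number of points on the common progress axis
N_PROGRESS = 100


@dataclass
class PairFeatureMatrix:
    """Resampled, normalised per-pair profiles for one transition.

    ``features`` is (n_pairs, 3 * n_progress): the attractive, vdW and
    repulsive profiles concatenated.  ``active`` flags pairs with nonzero
    signal; inactive pairs are excluded from clustering and labelled noise.
    """

    pair_ids: tuple[tuple[str, str], ...]
    features: np.ndarray
    active: np.ndarray
    n_progress: int = N_PROGRESS


@dataclass
class MotifAssignment:
    """Cluster labels per pair for one transition.

    Labels >= 0 are motifs; NOISE_LABEL marks weak/zero-signal pairs and
    OTHER_LABEL pairs from merged near-simultaneous clusters.
    """

    pair_ids: tuple[tuple[str, str], ...]
    labels: np.ndarray
    n_motifs: int
    silhouette: float

    def members(self, label: int) -> list[tuple[str, str]]:
        return [pid for pid, lab in zip(self.pair_ids, self.labels) if lab == label]


@dataclass
class PathwayProfile:
    """One transition summarised by its motif formation profiles."""

    transition_index: int
    direction: str
    motif_fraction: np.ndarray  # (n_motifs, n_progress), each in [0, 1]
    motif_half_points: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.motif_fraction = np.asarray(self.motif_fraction, dtype=float)
        self.motif_half_points = np.array(
            [first_crossing(row, 0.5) for row in self.motif_fraction], dtype=float
        )


def resample_profile(values: np.ndarray, n: int = N_PROGRESS) -> np.ndarray:
    """Linear resampling of a series onto n evenly spaced progress points."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        return np.full(n, x[0] if len(x) else 0.0)
    src = np.linspace(0.0, 1.0, len(x))
    dst = np.linspace(0.0, 1.0, n)
    return np.interp(dst, src, x)


def build_pair_features(
    series: Sequence[PairSeries],
    direction: str,
    folded_mean_total: dict[tuple[str, str], float],
    *,
    n_progress: int = N_PROGRESS,
    smooth_window: int = 10,
) -> PairFeatureMatrix:
    """Assemble the clustering feature matrix for one transition.

    ``folded_mean_total`` maps pair id -> mean total integral over the folded
    ensemble, the normalisation that puts pairs of different contact size on
    one scale.  Pairs with zero folded signal and zero transition signal are
    flagged inactive.  Unfolding transitions are time-reversed so the progress
    axis always runs unfolded -> folded.
    """
    from .interaction_analysis import smooth_series

    if direction not in ("folding", "unfolding"):
        raise ValueError(f"unknown direction {direction!r}")
    feats = np.zeros((len(series), 3 * n_progress))
    active = np.zeros(len(series), dtype=bool)
    ids = []
    for i, ps in enumerate(series):
        ids.append(ps.pair)
        norm = folded_mean_total.get(ps.pair, 0.0)
        raw = np.stack([ps.attractive, ps.vdw, ps.repulsive])
        if norm <= 0.0:
            if np.max(raw) <= 0.0:
                continue  # never interacts: stays inactive / noise
            norm = float(np.max(raw.sum(axis=0)))
        channels = []
        for ch in raw:
            sm = smooth_series(ch, min(smooth_window, len(ch)))
            if direction == "unfolding":
                sm = sm[::-1]
            channels.append(resample_profile(sm, n_progress) / norm)
        feats[i] = np.concatenate(channels)
        active[i] = np.ptp(feats[i]) > 0.0
    return PairFeatureMatrix(
        pair_ids=tuple(ids), features=feats, active=active, n_progress=n_progress
    )


def correlation_distance_matrix(features: np.ndarray) -> np.ndarray:
    """Pairwise correlation distance 1 - corr, with constant rows handled as
    maximally distant from everything non-identical."""
    x = np.asarray(features, dtype=float)
    const = np.ptp(x, axis=1) == 0.0
    if np.any(const):
        # jitter-free handling: constant rows get distance 1 to all others
        d = np.ones((len(x), len(x)))
        np.fill_diagonal(d, 0.0)
        ok = ~const
        if ok.sum() >= 2:
            sub = squareform(pdist(x[ok], metric="correlation"))
            idx = np.nonzero(ok)[0]
            d[np.ix_(idx, idx)] = sub
        return d
    return squareform(pdist(x, metric="correlation"))


def _agglomerate(dist: np.ndarray, k: int) -> np.ndarray:
    z = linkage(squareform(dist, checks=False), method="average")
    return fcluster(z, t=k, criterion="maxclust") - 1


def cluster_pairs(
    fm: PairFeatureMatrix,
    *,
    k_max: int = 6,
    noise_threshold: float = 0.4,
    synchrony_tolerance: float = 0.1,
) -> MotifAssignment:
    """Cluster active pair profiles into formation motifs.

    k is chosen by silhouette score (correlation distance) over k = 2..k_max.
    After clustering, a pair whose correlation with its own cluster mean is
    below ``noise_threshold`` is relabelled NOISE_LABEL.  If the half-formation
    points of two clusters differ by less than ``synchrony_tolerance`` of the
    progress axis, the later-listed cluster is merged into the earlier one;
    genuine simultaneity therefore produces fewer, larger motifs instead of
    artificial sequence.  Clusters reduced below two members become
    OTHER_LABEL.
    """
    labels = np.full(len(fm.pair_ids), NOISE_LABEL)
    idx = np.nonzero(fm.active)[0]
    if idx.size == 0:
        return MotifAssignment(fm.pair_ids, labels, 0, float("nan"))
    if idx.size == 1:
        labels[idx] = 0
        return MotifAssignment(fm.pair_ids, labels, 1, float("nan"))

    x = fm.features[idx]
    dist = correlation_distance_matrix(x)
    best_k, best_sil, best_lab = 1, -np.inf, np.zeros(idx.size, dtype=int)
    for k in range(2, min(k_max, idx.size - 1) + 1):
        lab = _agglomerate(dist, k)
        if len(np.unique(lab)) < 2:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sil = silhouette_score(dist, lab, metric="precomputed")
        if sil > best_sil:
            best_k, best_sil, best_lab = k, float(sil), lab

    sub = best_lab.copy()

    # noise relabelling: weak correlation with own cluster mean
    for lab in np.unique(sub):
        members = np.nonzero(sub == lab)[0]
        if members.size < 2:
            continue
        mean = x[members].mean(axis=0)
        if np.ptp(mean) == 0:
            continue
        for m in members:
            if np.ptp(x[m]) == 0:
                sub[m] = NOISE_LABEL
                continue
            corr = float(np.corrcoef(x[m], mean)[0, 1])
            if corr < noise_threshold:
                sub[m] = NOISE_LABEL

    # synchrony merge on half-formation points of cluster-mean total profiles;
    # features may hold several n_progress-length blocks (channels x events)
    n = fm.n_progress
    half: dict[int, float] = {}
    for lab in sorted(set(sub) - {NOISE_LABEL}):
        members = np.nonzero(sub == lab)[0]
        total = x[members].reshape(members.size, -1, n).sum(axis=1).mean(axis=0)
        hp = first_crossing(_formation_fraction(total), 0.5)
        half[lab] = hp / (n - 1) if np.isfinite(hp) else np.nan
    labs_sorted = sorted(half, key=lambda l: (np.isnan(half[l]), half[l]))
    merged: dict[int, int] = {}
    for a_i, a in enumerate(labs_sorted):
        if a in merged:
            continue
        for b in labs_sorted[a_i + 1 :]:
            if b in merged:
                continue
            if (
                np.isfinite(half[a])
                and np.isfinite(half[b])
                and abs(half[a] - half[b]) < synchrony_tolerance
            ):
                merged[b] = a
    for i, lab in enumerate(sub):
        if lab in merged:
            sub[i] = merged[lab]

    # drop singleton remnants into OTHER, renumber 0..n_motifs-1 by half point
    final = sub.copy()
    kept = []
    for lab in sorted(set(final) - {NOISE_LABEL}):
        members = np.nonzero(final == lab)[0]
        if members.size < 2:
            final[members] = OTHER_LABEL
        else:
            kept.append(lab)
    kept.sort(key=lambda l: (np.isnan(half.get(l, np.nan)), half.get(l, np.inf)))
    remap = {old: new for new, old in enumerate(kept)}
    for i, lab in enumerate(final):
        if lab in remap:
            final[i] = remap[lab]

    labels[idx] = final
    n_motifs = len(kept)
    if n_motifs >= 2 and np.sum(final >= 0) > n_motifs:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            keep = final >= 0
            sil_final = (
                float(silhouette_score(dist[np.ix_(keep, keep)], final[keep], metric="precomputed"))
                if np.unique(final[keep]).size >= 2
                else float("nan")
            )
    else:
        sil_final = float("nan")
    return MotifAssignment(fm.pair_ids, labels, n_motifs, sil_final)


def _formation_fraction(total_profile: np.ndarray) -> np.ndarray:
    """Monotone formation fraction in [0, 1] from a total-integral profile."""
    run = np.maximum.accumulate(np.asarray(total_profile, dtype=float))
    hi = run[-1]
    lo = run[0]
    if hi - lo <= 0:
        return np.zeros_like(run)
    return (run - lo) / (hi - lo)


def first_crossing(profile: np.ndarray, level: float) -> float:
    """Index (fractional) where a profile first reaches ``level``; inf if never."""
    p = np.asarray(profile, dtype=float)
    above = np.nonzero(p >= level)[0]
    if above.size == 0:
        return float("inf")
    k = int(above[0])
    if k == 0 or p[k] == p[k - 1]:
        return float(k)
    return float(k - 1 + (level - p[k - 1]) / (p[k] - p[k - 1]))


def motif_profiles(fm: PairFeatureMatrix, assignment: MotifAssignment) -> np.ndarray:
    """(n_motifs, n_progress) formation-fraction profiles of each motif:
    the monotone-normalised mean total integral of the motif's members."""
    n = fm.n_progress
    out = np.zeros((assignment.n_motifs, n))
    for lab in range(assignment.n_motifs):
        members = np.nonzero(assignment.labels == lab)[0]
        if members.size == 0:
            continue
        total = fm.features[members].reshape(members.size, -1, n).sum(axis=1).mean(axis=0)
        out[lab] = _formation_fraction(total)
    return out


def motif_formation_order(profile: PathwayProfile) -> tuple[int, ...]:
    """Motif indices sorted by half-formation point (earliest first)."""
    hp = profile.motif_half_points
    order = np.argsort(np.where(np.isfinite(hp), hp, np.inf), kind="stable")
    return tuple(int(i) for i in order)


def transition_features(profiles: Sequence[PathwayProfile]) -> np.ndarray:
    """Concatenated motif-fraction profiles, one row per transition.

    All transitions must describe the same motifs (same matrix shape).
    """
    shapes = {p.motif_fraction.shape for p in profiles}
    if len(shapes) != 1:
        raise ValueError("transitions carry differently shaped motif profiles")
    return np.stack([p.motif_fraction.ravel() for p in profiles])


def cluster_transitions(
    profiles: Sequence[PathwayProfile],
    *,
    k_max: int = 5,
) -> tuple[np.ndarray, int]:
    """Cluster transitions by their motif formation profiles.

    Returns (labels, k).  k is picked over 2..k_max by majority vote of
    silhouette (max), Calinski-Harabasz (max) and Davies-Bouldin (min) on the
    Euclidean feature matrix; if fewer than 4 transitions exist, or the best
    silhouette is non-positive, all transitions get one label.

    Correlation distance is scale-free, so amplitude jitter between otherwise
    identical profiles would otherwise look like structure; profiles whose
    pairwise correlation distances never exceed 0.05 are treated as a single
    degenerate pathway.
    """
    x = transition_features(profiles)
    n = len(profiles)
    if n < 4:
        return np.zeros(n, dtype=int), 1
    dist = correlation_distance_matrix(x)
    if dist.max() < 0.05:
        return np.zeros(n, dtype=int), 1
    candidates = list(range(2, min(k_max, n - 1) + 1))
    votes: dict[int, int] = {k: 0 for k in candidates}
    sils: dict[int, float] = {}
    labs: dict[int, np.ndarray] = {}
    ch: dict[int, float] = {}
    db: dict[int, float] = {}
    for k in candidates:
        lab = _agglomerate(dist, k)
        labs[k] = lab
        if len(np.unique(lab)) < 2:
            sils[k], ch[k], db[k] = -np.inf, -np.inf, np.inf
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sils[k] = float(silhouette_score(dist, lab, metric="precomputed"))
            ch[k] = float(calinski_harabasz_score(x, lab))
            db[k] = float(davies_bouldin_score(x, lab))
    if not candidates or max(sils.values()) <= 0:
        return np.zeros(n, dtype=int), 1
    votes[max(sils, key=sils.get)] += 1
    votes[max(ch, key=ch.get)] += 1
    votes[min(db, key=db.get)] += 1
    best_votes = max(votes.values())
    tied = [k for k, v in votes.items() if v == best_votes]
    k_best = max(tied, key=lambda k: sils[k]) if len(tied) > 1 else tied[0]
    lab = labs[k_best]
    # renumber by cluster size (largest first), ties by first appearance
    sizes = {l: int(np.sum(lab == l)) for l in np.unique(lab)}
    order = sorted(sizes, key=lambda l: (-sizes[l], int(np.nonzero(lab == l)[0][0])))
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[l] for l in lab], dtype=int), k_best
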