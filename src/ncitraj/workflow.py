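"""End-to-end analysis workflow: configuration, staged pipeline, provenance.

The pipeline runs, in order:

1. native-contact construction from the reference (folded) fragment geometry;
2. the Q(t) fraction-of-native-contacts series and transition detection;
3. per-transition frame sampling and per-pair 3-channel NCI integral series;
4. folded-ensemble normalisation constants (mean total integral per pair);
5. motif clustering of pair formation profiles (one global assignment over
   all transitions, so motif identities are comparable between events);
6. per-transition motif formation profiles and pathway clustering.

A :class:`RunConfig` collects every tunable parameter, serialises to YAML and
hashes canonically, so a result can always be traced to the exact
configuration that produced it.  All configuration is validated before any
computation starts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__ as _pkg_version
from .fragments_io import Fragment, PairList, enumerate_pairs
from .grid_engine import NCIParams
from .interaction_analysis import PairSeries, pair_integral_series
from .pathway_clustering import (
    MotifAssignment,
    PairFeatureMatrix,
    PathwayProfile,
    build_pair_features,
    cluster_pairs,
    cluster_transitions,
    motif_profiles,
)
from .trajectory_select import (
    QSeries,
    TransitionSegment,
    build_native_contacts,
    detect_transitions,
    ensemble_frames,
    q_series,
    sample_transition_frames,
)

__all__ = [
    "QParams",
    "SamplingParams",
    "ClusteringParams",
    "RunConfig",
    "WorkflowResult",
    "config_to_dict",
    "config_from_dict",
    "save_config",
    "load_config",
    "config_hash",
    "run_workflow",
    "pathway_fractions",
]


@dataclass(frozen=True)
class QParams:
    """Fraction-of-native-contacts and basin parameters."""

    beta: float = 5.0          # 1/angstrom, switch steepness
    lam: float = 1.8           # reference-distance scale
    heavy_cutoff: float = 4.5  # angstrom, native-contact definition
    min_sep: int = 3           # residues; contacts need separation > min_sep
    q_low: float = 0.1         # unfolded basin: q <= q_low
    q_high: float = 0.9        # folded basin: q >= q_high

    def __post_init__(self) -> None:
        if self.beta <= 0 or self.lam <= 0 or self.heavy_cutoff <= 0:
            raise ValueError("beta, lam and heavy_cutoff must be positive")
        if not 0.0 <= self.q_low < self.q_high <= 1.0:
            raise ValueError("require 0 <= q_low < q_high <= 1")
        if self.min_sep < 0:
            raise ValueError("min_sep must be >= 0")


@dataclass(frozen=True)
class SamplingParams:
    """Frame sampling for transitions and ensembles."""

    n_target: int = 100        # frames per transition
    flank: int = 10            # extra frames each side, at the same stride
    ensemble_n: int = 500      # frames per equilibrium ensemble
    band: tuple[float, float] = (0.4, 0.6)  # mid-transition q window

    def __post_init__(self) -> None:
        if self.n_target < 2 or self.flank < 0 or self.ensemble_n < 1:
            raise ValueError("invalid sampling sizes")
        if not 0.0 <= self.band[0] < self.band[1] <= 1.0:
            raise ValueError("band must be an increasing pair in [0, 1]")


@dataclass(frozen=True)
class ClusteringParams:
    """Motif and pathway clustering parameters."""

    k_max_pairs: int = 6
    noise_threshold: float = 0.4
    synchrony_tolerance: float = 0.1
    k_max_transitions: int = 5
    smooth_window: int = 10

    def __post_init__(self) -> None:
        if self.k_max_pairs < 2 or self.k_max_transitions < 2:
            raise ValueError("k_max values must be >= 2")
        if not 0.0 <= self.noise_threshold <= 1.0:
            raise ValueError("noise_threshold must lie in [0, 1]")
        if self.smooth_window < 1:
            raise ValueError("smooth_window must be >= 1")


@dataclass(frozen=True)
class RunConfig:
    """Complete, validated configuration of one workflow run."""

    nci: NCIParams = NCIParams()
    q: QParams = QParams()
    sampling: SamplingParams = SamplingParams()
    clustering: ClusteringParams = ClusteringParams()
    pair_min_separation: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pair_min_separation < 0:
            raise ValueError("pair_min_separation must be >= 0")
        if not 0 <= self.seed < 2**31:
            raise ValueError("seed must lie in [0, 2^31)")


@dataclass
class WorkflowResult:
    """Everything one workflow run computes, plus provenance."""

    config: RunConfig
    q: QSeries
    transitions: list[TransitionSegment]
    pairs: PairList
    folded_mean_total: dict[tuple[str, str], float]
    transition_series: list[list[PairSeries]]
    feature_matrices: list[PairFeatureMatrix]
    assignment: MotifAssignment | None
    profiles: list[PathwayProfile]
    pathway_labels: np.ndarray
    n_pathways: int
    provenance: dict


def config_to_dict(config: RunConfig) -> dict:
    d = asdict(config)
    # tuples -> lists for clean YAML
    d["nci"]["thresholds"] = list(d["nci"]["thresholds"])
    d["sampling"]["band"] = list(d["sampling"]["band"])
    return d


def config_from_dict(d: dict) -> RunConfig:
    d = dict(d)
    nci = dict(d.get("nci", {}))
    if "thresholds" in nci:
        nci["thresholds"] = tuple(nci["thresholds"])
    sampling = dict(d.get("sampling", {}))
    if "band" in sampling:
        sampling["band"] = tuple(sampling["band"])
    return RunConfig(
        nci=NCIParams(**nci),
        q=QParams(**d.get("q", {})),
        sampling=SamplingParams(**sampling),
        clustering=ClusteringParams(**d.get("clustering", {})),
        pair_min_separation=d.get("pair_min_separation", 3),
        seed=d.get("seed", 0),
    )


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def config_hash(config: RunConfig) -> str:
    """Short stable hash of the canonical JSON form of a configuration."""
    blob = json.dumps(config_to_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _global_motif_assignment(
    matrices: Sequence[PairFeatureMatrix],
    clustering: ClusteringParams,
) -> MotifAssignment | None:
    """One motif assignment from the concatenated per-transition features."""
    if not matrices:
        return None
    feats = np.hstack([m.features for m in matrices])
    active = np.logical_or.reduce([m.active for m in matrices])
    combined = PairFeatureMatrix(
        pair_ids=matrices[0].pair_ids,
        features=feats,
        active=active,
        n_progress=matrices[0].n_progress,
    )
    return cluster_pairs(
        combined,
        k_max=clustering.k_max_pairs,
        noise_threshold=clustering.noise_threshold,
        synchrony_tolerance=clustering.synchrony_tolerance,
    )


def run_workflow(
    fragments: Sequence[Fragment],
    frames_xyz: np.ndarray,
    config: RunConfig = RunConfig(),
    out_dir: str | Path | None = None,
) -> WorkflowResult:
    """Run the full analysis pipeline on a trajectory.

    ``fragments`` must carry the reference (native) geometry; ``frames_xyz``
    is (n_frames, n_atoms, 3) angstrom in the fragments' atom order.  If
    ``out_dir`` is given, the configuration, Q series, transition table and
    pathway summary are written there as YAML/CSV/JSON.
    """
    frames_xyz = np.asarray(frames_xyz, dtype=float)
    if frames_xyz.ndim != 3:
        raise ValueError("frames_xyz must be (n_frames, n_atoms, 3)")

    contacts = build_native_contacts(
        fragments, heavy_cutoff=config.q.heavy_cutoff, min_sep=config.q.min_sep
    )
    q = q_series(frames_xyz, contacts, beta=config.q.beta, lam=config.q.lam)
    transitions = detect_transitions(q, q_low=config.q.q_low, q_high=config.q.q_high)
    pairs = enumerate_pairs(fragments, min_separation=config.pair_min_separation)

    # folded-ensemble normalisation
    folded_mean_total: dict[tuple[str, str], float] = {pid: 0.0 for pid in pairs.ids}
    try:
        folded = ensemble_frames(
            q, "folded", n=config.sampling.ensemble_n, seed=config.seed,
            q_low=config.q.q_low, q_high=config.q.q_high,
        )
    except ValueError:
        folded = np.array([], dtype=int)
    if folded.size:
        # a modest subsample keeps the normalisation pass cheap
        norm_frames = folded[:: max(1, folded.size // 20)]
        for ps in pair_integral_series(frames_xyz, norm_frames, fragments, pairs, config.nci):
            folded_mean_total[ps.pair] = float(np.mean(ps.total))

    transition_series: list[list[PairSeries]] = []
    matrices: list[PairFeatureMatrix] = []
    for seg in transitions:
        frames = sample_transition_frames(
            seg, len(frames_xyz), n_target=config.sampling.n_target, flank=config.sampling.flank
        )
        seg.sampled_frames = frames
        series = pair_integral_series(frames_xyz, frames, fragments, pairs, config.nci)
        transition_series.append(series)
        matrices.append(
            build_pair_features(
                series, seg.direction, folded_mean_total,
                smooth_window=config.clustering.smooth_window,
            )
        )

    assignment = _global_motif_assignment(matrices, config.clustering)

    profiles: list[PathwayProfile] = []
    if assignment is not None and assignment.n_motifs > 0:
        for i, (seg, fm) in enumerate(zip(transitions, matrices)):
            per_event = MotifAssignment(
                pair_ids=fm.pair_ids, labels=assignment.labels,
                n_motifs=assignment.n_motifs, silhouette=assignment.silhouette,
            )
            profiles.append(
                PathwayProfile(
                    transition_index=i,
                    direction=seg.direction,
                    motif_fraction=motif_profiles(fm, per_event),
                )
            )
    if profiles:
        pathway_labels, n_pathways = cluster_transitions(
            profiles, k_max=config.clustering.k_max_transitions
        )
    else:
        pathway_labels, n_pathways = np.zeros(0, dtype=int), 0

    provenance = {
        "package": "ncitraj",
        "version": _pkg_version,
        "config_hash": config_hash(config),
        "seed": config.seed,
        "n_frames": int(frames_xyz.shape[0]),
        "n_fragments": len(fragments),
        "n_pairs": len(pairs),
        "n_transitions": len(transitions),
    }
    result = WorkflowResult(
        config=config,
        q=q,
        transitions=transitions,
        pairs=pairs,
        folded_mean_total=folded_mean_total,
        transition_series=transition_series,
        feature_matrices=matrices,
        assignment=assignment,
        profiles=profiles,
        pathway_labels=pathway_labels,
        n_pathways=n_pathways,
        provenance=provenance,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def pathway_fractions(result: WorkflowResult) -> dict[int, float]:
    """Fraction of transitions assigned to each pathway label."""
    labels = np.asarray(result.pathway_labels)
    if labels.size == 0:
        return {}
    return {int(l): float(np.mean(labels == l)) for l in np.unique(labels)}


def _write_outputs(result: WorkflowResult, out_dir: Path) -> None:
    import pandas as pd

    out_dir.mkdir(parents=True, exist_ok=True)
    save_config(result.config, out_dir / "config.yaml")
    pd.DataFrame({"frame": np.arange(len(result.q)), "q": result.q.q}).to_csv(
        out_dir / "q_series.csv", index=False
    )
    pd.DataFrame(
        [
            dict(index=i, start=seg.start_frame, end=seg.end_frame,
                 direction=seg.direction,
                 pathway=int(result.pathway_labels[i]) if i < len(result.pathway_labels) else -1)
            for i, seg in enumerate(result.transitions)
        ]
    ).to_csv(out_dir / "transitions.csv", index=False)
    summary = {
        "provenance": result.provenance,
        "n_pathways": int(result.n_pathways),
        "pathway_fractions": pathway_fractions(result),
        "n_motifs": int(result.assignment.n_motifs) if result.assignment else 0,
        "motif_members": (
            {str(m): [list(p) for p in result.assignment.members(m)]
             for m in range(result.assignment.n_motifs)}
            if result.assignment
            else {}
        ),
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
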