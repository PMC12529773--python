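"""Fraction of native contacts, transition detection and frame sampling.

The folding order parameter is the soft-switch fraction of native contacts

    Q(X) = (1/N) sum_{(i,j)} 1 / (1 + exp(beta * (r_ij(X) - lam * r0_ij)))

over all heavy-atom pairs (i, j) that are closer than a cutoff in the native
reference and belong to residues more than ``min_sep`` positions apart.
Defaults beta = 5 / angstrom, lam = 1.8, cutoff 4.5 angstrom, min_sep 3 are
the standard convention for this order parameter.

Folding and unfolding events are located by transition-based assignment
between the unfolded (Q <= 0.1) and folded (Q >= 0.9) basins: a transition
runs from the *last* frame in the departure basin to the *first* frame in the
arrival basin, so excursions that return to the departure basin (recrossings)
are never counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .fragments_io import Fragment

__all__ = [
    "NativeContactSet",
    "QSeries",
    "TransitionSegment",
    "EmptyContactSetError",
    "build_native_contacts",
    "fraction_native_contacts",
    "q_series",
    "detect_transitions",
    "sample_transition_frames",
    "ensemble_frames",
]


class EmptyContactSetError(ValueError):
    """The reference frame yields no native contacts; Q would be undefined."""


@dataclass(frozen=True)
class NativeContactSet:
    """Heavy-atom native contacts with their reference distances (angstrom)."""

    atom_i: np.ndarray          # global atom indices
    atom_j: np.ndarray
    r0: np.ndarray              # reference distances, angstrom
    heavy_cutoff: float
    min_sep: int

    def __len__(self) -> int:
        return len(self.r0)


@dataclass
class QSeries:
    """Per-frame fraction of native contacts, each value in [0, 1]."""

    q: np.ndarray
    frame_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if np.any((self.q < 0) | (self.q > 1)):
            raise ValueError("Q values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.q)


@dataclass
class TransitionSegment:
    """One folding or unfolding event on the Q series.

    ``start_frame`` is the last frame in the departure basin, ``end_frame``
    the first frame in the arrival basin.
    """

    start_frame: int
    end_frame: int
    direction: Literal["folding", "unfolding"]
    sampled_frames: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.start_frame < self.end_frame:
            raise ValueError("start_frame must precede end_frame")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


def build_native_contacts(
    fragments: Sequence[Fragment],
    heavy_cutoff: float = 4.5,
    min_sep: int = 3,
) -> NativeContactSet:
    """All heavy-atom pairs below ``heavy_cutoff`` in the reference frame,
    from residues with sequence separation > ``min_sep`` (or different chains).

    The fragments must carry their reference-frame coordinates and source
    atom indices.
    """
    atom_i: list[int] = []
    atom_j: list[int] = []
    r0: list[float] = []
    heavy = []
    for frag in fragments:
        if frag.is_water:
            continue
        hi = frag.heavy_indices
        heavy.append((frag, frag.coords[hi], frag.atom_indices[hi]))
    for a in range(len(heavy)):
        fa, ca, ia = heavy[a]
        for b in range(a + 1, len(heavy)):
            fb, cb, ib = heavy[b]
            if fa.chain_id == fb.chain_id and abs(fa.sequence_index - fb.sequence_index) <= min_sep:
                continue
            d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2)
            ii, jj = np.nonzero(d < heavy_cutoff)
            atom_i.extend(ia[ii])
            atom_j.extend(ib[jj])
            r0.extend(d[ii, jj])
    if not r0:
        raise EmptyContactSetError(
            f"no native contacts below {heavy_cutoff} angstrom at separation > {min_sep}"
        )
    return NativeContactSet(
        atom_i=np.asarray(atom_i, dtype=int),
        atom_j=np.asarray(atom_j, dtype=int),
        r0=np.asarray(r0, dtype=float),
        heavy_cutoff=heavy_cutoff,
        min_sep=min_sep,
    )


def fraction_native_contacts(
    frame_xyz: np.ndarray,
    contacts: NativeContactSet,
    beta: float = 5.0,
    lam: float = 1.8,
) -> float:
    """Soft-switch Q of one frame (coordinates (n_atoms, 3) in angstrom)."""
    if len(contacts) == 0:
        raise EmptyContactSetError("empty contact set")
    xyz = np.asarray(frame_xyz, dtype=float)
    d = np.linalg.norm(xyz[contacts.atom_i] - xyz[contacts.atom_j], axis=1)
    return float(np.mean(1.0 / (1.0 + np.exp(beta * (d - lam * contacts.r0)))))


def q_series(
    frames_xyz: np.ndarray,
    contacts: NativeContactSet,
    beta: float = 5.0,
    lam: float = 1.8,
) -> QSeries:
    """Q for every frame of a trajectory array (n_frames, n_atoms, 3) angstrom."""
    xyz = np.asarray(frames_xyz, dtype=float)
    diff = xyz[:, contacts.atom_i, :] - xyz[:, contacts.atom_j, :]
    d = np.sqrt(np.einsum("fij,fij->fi", diff, diff))
    q = np.mean(1.0 / (1.0 + np.exp(beta * (d - lam * contacts.r0[None, :]))), axis=1)
    return QSeries(q=q)


def detect_transitions(
    q: QSeries | np.ndarray,
    q_low: float = 0.1,
    q_high: float = 0.9,
) -> list[TransitionSegment]:
    """Transition-based assignment between the Q basins.

    A folding segment runs from the last frame with q <= q_low before the
    first subsequent frame with q >= q_high (and symmetrically for
    unfolding); excursions that return to the departure basin are
    recrossings, not transitions.  Segments are chronological and
    non-overlapping; a series that never visits both basins yields [].
    """
    if not q_low < q_high:
        raise ValueError("q_low must be < q_high")
    values = q.q if isinstance(q, QSeries) else np.asarray(q, dtype=float)
    segments: list[TransitionSegment] = []
    last_basin = 0
    last_idx = -1
    for t, v in enumerate(values):
        basin = 1 if v >= q_high else (-1 if v <= q_low else 0)
        if basin == 0:
            continue
        if last_basin != 0 and basin != last_basin:
            segments.append(
                TransitionSegment(
                    start_frame=last_idx,
                    end_frame=t,
                    direction="folding" if basin == 1 else "unfolding",
                )
            )
        last_basin, last_idx = basin, t
    return segments


def sample_transition_frames(
    segment: TransitionSegment,
    n_frames_total: int,
    n_target: int = 100,
    flank: int = 10,
) -> np.ndarray:
    """Approximately ``n_target`` evenly spaced frames inside the segment plus
    ``flank`` frames at the same stride on each side, clipped to the
    trajectory bounds.  Deterministic.
    """
    stride = max(1, segment.n_frames // n_target)
    inside = np.arange(segment.start_frame, segment.end_frame + 1, stride)
    before = segment.start_frame - stride * np.arange(flank, 0, -1)
    after = segment.end_frame + stride * np.arange(1, flank + 1)
    frames = np.concatenate([before, inside, after])
    frames = frames[(frames >= 0) & (frames < n_frames_total)]
    return np.unique(frames)


def ensemble_frames(
    q: QSeries | np.ndarray,
    ensemble: Literal["folded", "unfolded", "transition"],
    n: int = 500,
    seed: int = 0,
    *,
    q_low: float = 0.1,
    q_high: float = 0.9,
    transitions: Sequence[TransitionSegment] | None = None,
    band: tuple[float, float] = (0.4, 0.6),
) -> np.ndarray:
    """Draw up to ``n`` frames uniformly without replacement from an ensemble.

    folded: q >= q_high; unfolded: q <= q_low; transition: frames inside
    detected transitions with q in ``band`` (the mid-transition window).
    """
    values = q.q if isinstance(q, QSeries) else np.asarray(q, dtype=float)
    if ensemble == "folded":
        eligible = np.nonzero(values >= q_high)[0]
    elif ensemble == "unfolded":
        eligible = np.nonzero(values <= q_low)[0]
    elif ensemble == "transition":
        if transitions is None:
            transitions = detect_transitions(values, q_low=q_low, q_high=q_high)
        inside = np.zeros(len(values), dtype=bool)
        for seg in transitions:
            inside[seg.start_frame : seg.end_frame + 1] = True
        eligible = np.nonzero(inside & (values >= band[0]) & (values <= band[1]))[0]
    else:
        raise ValueError(f"unknown ensemble {ensemble!r}")
    if eligible.size == 0:
        raise ValueError(f"no frames eligible for the {ensemble} ensemble")
    if eligible.size <= n:
        return eligible
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(eligible, size=n, replace=False))
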