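"""Synthetic structures and trajectories with known ground truth.

Everything here is generated programmatically from documented geometry rules
and a seed, so fixtures are reproducible, tiny, and carry exact labels:

* :func:`make_hbond_dimer` — an N-H···O=C hydrogen-bonded dimer whose
  interaction critical point has clearly negative second Hessian eigenvalue
  (attractive signal).
* :func:`make_apolar_dimer` — two methane molecules in van der Waals contact;
  the intermolecular density trough is near-flat (|sign(lambda2) rho| small).
* :func:`make_toy_folding_trajectory` — a multi-event folding/unfolding
  trajectory of 8 rigid pseudo-residues with two planted contact motifs
  (A = pairs (1,5),(2,6); B = pairs (3,7),(4,8)), two pathways (A-then-B vs
  B-then-A) mixed in a chosen ratio, seeded coordinate jitter, and per-event
  ground-truth labels.

Distances are in angstrom.  Pseudo-residues are 3-atom N/C/O triangles:
real elements (so the density tables apply) on a deliberately artificial
scaffold; no claim of protein realism is made.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fragments_io import Fragment

__all__ = [
    "DimerFixture",
    "ToyTrajectory",
    "make_hbond_dimer",
    "make_apolar_dimer",
    "make_toy_folding_trajectory",
    "MOTIF_A_PAIRS",
    "MOTIF_B_PAIRS",
]

#: ground-truth motif memberships of the toy trajectory (1-based residue ids)
MOTIF_A_PAIRS = ((1, 5), (2, 6))
MOTIF_B_PAIRS = ((3, 7), (4, 8))


@dataclass
class DimerFixture:
    """Two fragments plus the geometric parameter that defines them."""

    fragA: Fragment
    fragB: Fragment
    separation: float
    kind: str


@dataclass
class ToyTrajectory:
    """A synthetic folding trajectory with exhaustive ground truth.

    ``xyz`` is (n_frames, n_atoms, 3) angstrom in the concatenated fragment
    atom order.  ``event_bounds`` are (start, end) frame indices of each
    planted event, ``event_directions`` its direction, ``event_pathways`` the
    planted pathway label (0: motif A forms first, 1: motif B first; for
    unfolding the labels follow the time-reversed formation order of the same
    pathway).
    """

    fragments: list[Fragment]
    xyz: np.ndarray
    event_bounds: list[tuple[int, int]]
    event_directions: list[str]
    event_pathways: list[int]
    seed: int
    noise_sigma: float
    motif_a: tuple[tuple[int, int], ...] = MOTIF_A_PAIRS
    motif_b: tuple[tuple[int, int], ...] = MOTIF_B_PAIRS

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]


def _fragment(fid: str, elements: list[str], coords, seq: int, chain: str = "A",
              name: str = "RES", offset: int = 0) -> Fragment:
    coords = np.asarray(coords, dtype=float)
    return Fragment(
        fragment_id=fid,
        residue_name=name,
        chain_id=chain,
        sequence_index=seq,
        elements=elements,
        coords=coords,
        atom_indices=np.arange(offset, offset + len(elements)),
    )


def make_hbond_dimer(separation: float = 2.9) -> DimerFixture:
    """N-H···O=C dimer with donor-acceptor (N···O) distance ``separation``.

    Donor fragment: amine-like N-H with a carbon anchor; acceptor fragment:
    carbonyl-like O=C.  The N-H bond points straight at the O, so the
    hydrogen bond is linear.  At the 2.9 angstrom default the promolecular
    interaction point is clearly attractive (sign(lambda2) rho < -0.02 a.u.).
    """
    if separation <= 1.2:
        raise ValueError("separation must exceed the N-H bond length")
    donor = _fragment(
        "A:DON1",
        ["N", "H", "C"],
        [[0.0, 0.0, 0.0], [1.01, 0.0, 0.0], [-0.70, 1.26, 0.0]],
        seq=1,
        offset=0,
    )
    acceptor = _fragment(
        "A:ACC5",
        ["O", "C", "H", "H"],
        [
            [separation, 0.0, 0.0],
            [separation + 1.10, 0.55, 0.0],
            [separation + 1.05, 1.63, 0.0],
            [separation + 2.13, 0.18, 0.0],
        ],
        seq=5,
        offset=3,
    )
    return DimerFixture(donor, acceptor, separation, "hbond")


def make_apolar_dimer(separation: float = 4.0) -> DimerFixture:
    """Two methane molecules, C···C distance ``separation``, three-H faces
    pointing at each other — a pure van der Waals contact."""
    if separation <= 2.2:
        raise ValueError("separation must exceed twice the C-H bond length")
    d = 1.09 / np.sqrt(3.0)  # C-H component along each axis for tetrahedral CH4

    def methane(center_x: float, flip: float):
        c = np.array([center_x, 0.0, 0.0])
        hs = np.array(
            [
                [flip * d, d, d],
                [flip * d, -d, -d],
                [flip * d, d, -d],
                [-flip * d, -d, d],
            ]
        )
        return ["C", "H", "H", "H", "H"], np.vstack([c, c + hs])

    elsA, xyzA = methane(0.0, +1.0)
    elsB, xyzB = methane(separation, -1.0)
    fragA = _fragment("A:MET1", elsA, xyzA, seq=1, offset=0)
    fragB = _fragment("A:MET5", elsB, xyzB, seq=5, offset=5)
    return DimerFixture(fragA, fragB, separation, "apolar")


# ---------------------------------------------------------------------------
# toy folding trajectory
# ---------------------------------------------------------------------------

#: rigid 3-atom pseudo-residue template (N, C, O triangle), angstrom
_RESIDUE_TEMPLATE = np.array(
    [[-0.62, -0.37, 0.0], [0.62, -0.37, 0.0], [0.0, 0.74, 0.0]]
)
_RESIDUE_ELEMENTS = ["N", "C", "O"]

#: base residues 1-4 sit on the x axis; partners 5-8 dock above them (folded)
#: or stretch far along x (unfolded)
_BASE_X = np.array([0.0, 6.0, 12.0, 18.0])
_FOLDED_Y = 4.2
_UNFOLDED_X = np.array([24.0, 30.0, 36.0, 42.0])


def _residue_centers(fold_a: float, fold_b: float) -> np.ndarray:
    """Centers of the 8 pseudo-residues given motif formation coordinates.

    ``fold_a``/``fold_b`` in [0, 1] interpolate the motif-A partners (5, 6)
    and motif-B partners (7, 8) between their unfolded and folded positions.
    """
    centers = np.zeros((8, 3))
    centers[:4, 0] = _BASE_X
    for partner, frac in [(4, fold_a), (5, fold_a), (6, fold_b), (7, fold_b)]:
        folded = np.array([_BASE_X[partner - 4], _FOLDED_Y, 0.0])
        unfolded = np.array([_UNFOLDED_X[partner - 4], 0.0, 0.0])
        centers[partner] = frac * folded + (1.0 - frac) * unfolded
    return centers


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _motif_schedule(n: int, first: str) -> tuple[np.ndarray, np.ndarray]:
    """Formation fractions of motifs A and B over an n-frame folding event.

    The first motif forms in the window [0.10, 0.45] of the event, the second
    in [0.55, 0.90]; both use smoothstep ramps.
    """
    t = np.linspace(0.0, 1.0, n)
    early = _smoothstep((t - 0.10) / 0.35)
    late = _smoothstep((t - 0.55) / 0.35)
    if first == "A":
        return early, late
    return late, early


def make_toy_folding_trajectory(
    n_events: int = 10,
    frames_per_event: int = 50,
    gap_frames: int = 25,
    lead_frames: int = 15,
    pathway1_fraction: float = 0.6,
    noise_sigma: float = 0.05,
    seed: int = 0,
) -> ToyTrajectory:
    """Build the 8-residue toy trajectory with planted motifs and pathways.

    Events alternate folding/unfolding (starting folded requires an even
    pathway bookkeeping, so the trajectory starts unfolded and the first event
    folds).  Pathway labels are assigned so that a fraction
    ``pathway1_fraction`` of folding events use pathway 0 (motif A first) and
    the rest pathway 1 (motif B first); each unfolding event is the time
    reversal of the preceding folding event's schedule, which keeps the
    trajectory continuous.  Gaussian jitter of ``noise_sigma`` angstrom is
    added to every coordinate (seeded).
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if not 0.0 <= pathway1_fraction <= 1.0:
        raise ValueError("pathway1_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    n_folding = (n_events + 1) // 2
    n_path0 = int(round(pathway1_fraction * n_folding))
    fold_paths = [0] * n_path0 + [1] * (n_folding - n_path0)
    rng.shuffle(fold_paths)

    # per-frame motif coordinates
    fa_parts: list[np.ndarray] = [np.zeros(lead_frames)]
    fb_parts: list[np.ndarray] = [np.zeros(lead_frames)]
    event_bounds: list[tuple[int, int]] = []
    event_directions: list[str] = []
    event_pathways: list[int] = []
    cursor = lead_frames
    fold_i = 0
    current_path = 0
    for e in range(n_events):
        direction = "folding" if e % 2 == 0 else "unfolding"
        if direction == "folding":
            current_path = fold_paths[fold_i]
            fold_i += 1
            fa, fb = _motif_schedule(frames_per_event, "A" if current_path == 0 else "B")
        else:
            fa, fb = _motif_schedule(frames_per_event, "A" if current_path == 0 else "B")
            fa, fb = fa[::-1], fb[::-1]
        fa_parts.append(fa)
        fb_parts.append(fb)
        event_bounds.append((cursor, cursor + frames_per_event - 1))
        event_directions.append(direction)
        event_pathways.append(current_path)
        cursor += frames_per_event
        hold = np.full(gap_frames, fa[-1])
        fa_parts.append(hold)
        fb_parts.append(np.full(gap_frames, fb[-1]))
        cursor += gap_frames
    # trailing lead
    fa_parts.append(np.full(lead_frames, fa_parts[-1][-1]))
    fb_parts.append(np.full(lead_frames, fb_parts[-1][-1]))

    fold_a = np.concatenate(fa_parts)
    fold_b = np.concatenate(fb_parts)
    n_frames = len(fold_a)

    fragments: list[Fragment] = []
    offset = 0
    for r in range(8):
        fragments.append(
            _fragment(
                f"A:RES{r + 1}",
                list(_RESIDUE_ELEMENTS),
                _RESIDUE_TEMPLATE,  # placeholder; per-frame below
                seq=r + 1,
                offset=offset,
            )
        )
        offset += 3

    xyz = np.zeros((n_frames, 24, 3))
    for f in range(n_frames):
        centers = _residue_centers(fold_a[f], fold_b[f])
        for r in range(8):
            flip = -1.0 if r >= 4 else 1.0  # partners point their O face down
            template = _RESIDUE_TEMPLATE * np.array([1.0, flip, 1.0])
            xyz[f, 3 * r : 3 * r + 3] = centers[r] + template
    xyz += rng.normal(0.0, noise_sigma, size=xyz.shape)

    # native (folded) coordinates define the fragments' reference geometry
    ref_centers = _residue_centers(1.0, 1.0)
    for r, frag in enumerate(fragments):
        flip = -1.0 if r >= 4 else 1.0
        frag.coords = ref_centers[r] + _RESIDUE_TEMPLATE * np.array([1.0, flip, 1.0])

    return ToyTrajectory(
        fragments=fragments,
        xyz=xyz,
        event_bounds=event_bounds,
        event_directions=event_directions,
        event_pathways=event_pathways,
        seed=seed,
        noise_sigma=noise_sigma,
    )
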