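"""Per-pair integral time series, smoothing, hydrogen bonds, contact maps, SASA.

This module turns the per-pair NCI machinery into trajectory-level analyses:

* 3-channel (attractive / vdW / repulsive) integral series for every residue
  pair over sampled frames, with a heavy-atom distance prefilter that skips
  grid evaluation for pairs too far apart to overlap;
* centred moving-average smoothing of sampled series;
* geometric hydrogen-bond detection (donor-H···acceptor angle > 120 degrees,
  H···acceptor distance <= 2.5 angstrom, evaluated per frame) and its
  correlation with the total attractive density;
* ensemble contact maps: mean vdW and attractive-minus-repulsive integrals
  next to the classical inverse-minimum-heavy-atom-distance^6 and inverse
  hydrogen-bond donor-acceptor distance maps;
* Shrake-Rupley solvent-accessible surface areas (via mdtraj);
* end-minus-start difference maps, including residue-water channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import mdtraj as md
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import linregress

from .fragments_io import Fragment, PairList, fragments_to_mdtraj, water_shell
from .grid_engine import NCIParams, PairIntegrals, pair_integrals

__all__ = [
    "PairSeries",
    "HBondRecord",
    "ContactMapEnsemble",
    "pair_min_heavy_distance",
    "pair_integral_series",
    "series_dataframe",
    "total_channel_series",
    "smooth_series",
    "detect_hbonds",
    "hbond_counts_series",
    "correlate_hbonds_attractive",
    "build_contact_maps",
    "sasa",
    "residue_water_integrals",
    "delta_integrals",
    "plot_contact_map",
]


@dataclass
class PairSeries:
    """3-channel NCI integral time series for one residue pair."""

    pair: tuple[str, str]
    frames: np.ndarray
    attractive: np.ndarray
    vdw: np.ndarray
    repulsive: np.ndarray

    def __post_init__(self) -> None:
        lengths = {len(self.frames), len(self.attractive), len(self.vdw), len(self.repulsive)}
        if len(lengths) != 1:
            raise ValueError("channel lengths differ")
        for ch in (self.attractive, self.vdw, self.repulsive):
            if np.any(np.asarray(ch) < 0):
                raise ValueError("integrals must be >= 0")

    @property
    def total(self) -> np.ndarray:
        return self.attractive + self.vdw + self.repulsive


@dataclass(frozen=True)
class HBondRecord:
    """One detected hydrogen bond in one frame."""

    frame: int
    donor_fragment: int      # index into the fragment list
    acceptor_fragment: int
    donor_atom: int          # atom index within the donor fragment
    hydrogen_atom: int
    acceptor_atom: int       # atom index within the acceptor fragment
    distance_ha: float       # H...acceptor, angstrom
    distance_da: float       # donor...acceptor, angstrom
    angle_dha: float         # degrees


@dataclass
class ContactMapEnsemble:
    """Ensemble-averaged residue-residue maps (symmetric, zero inside the
    excluded sequence-separation band)."""

    label: str
    n_frames: int
    vdw: np.ndarray
    att_minus_rep: np.ndarray
    inv_dist6: np.ndarray
    inv_hbond_dist: np.ndarray


def pair_min_heavy_distance(fragA: Fragment, fragB: Fragment) -> float:
    """Minimum heavy-atom distance between two fragments (angstrom)."""
    ca = fragA.coords[fragA.heavy_indices]
    cb = fragB.coords[fragB.heavy_indices]
    if ca.size == 0 or cb.size == 0:  # water H-only edge case
        ca, cb = fragA.coords, fragB.coords
    return float(np.min(np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2)))


def _integrals_for_pair(
    fragA: Fragment,
    fragB: Fragment,
    params: NCIParams,
    frame_index: int,
) -> PairIntegrals:
    pair_ids = (fragA.fragment_id, fragB.fragment_id)
    if pair_min_heavy_distance(fragA, fragB) > params.prefilter_distance:
        return PairIntegrals(frame_index, pair_ids, 0.0, 0.0, 0.0, 0.0)
    return pair_integrals(fragA, fragB, params, frame_index=frame_index, pair=pair_ids)


def pair_integral_series(
    frames_xyz: np.ndarray,
    frame_indices: Sequence[int],
    fragments: Sequence[Fragment],
    pairs: PairList,
    params: NCIParams = NCIParams(),
) -> list[PairSeries]:
    """One PairSeries per pair over the given frames.

    ``frames_xyz`` is the full trajectory array (n_frames, n_atoms, 3) in
    angstrom; ``frame_indices`` selects the frames to evaluate.  Pairs whose
    minimum heavy-atom distance exceeds the prefilter in a frame contribute
    exact zeros for that frame.
    """
    frame_indices = np.asarray(frame_indices, dtype=int)
    att = np.zeros((len(pairs), len(frame_indices)))
    vdw = np.zeros_like(att)
    rep = np.zeros_like(att)
    for fi, frame in enumerate(frame_indices):
        xyz = frames_xyz[frame]
        frags = [fragments[i].at_frame(xyz) for i in range(len(fragments))]
        for pi, (i, j) in enumerate(pairs):
            res = _integrals_for_pair(frags[i], frags[j], params, int(frame))
            att[pi, fi] = res.attractive
            vdw[pi, fi] = res.vdw
            rep[pi, fi] = res.repulsive
    return [
        PairSeries(pair=pairs.ids[pi], frames=frame_indices.copy(),
                   attractive=att[pi], vdw=vdw[pi], repulsive=rep[pi])
        for pi in range(len(pairs))
    ]


def series_dataframe(series: Iterable[PairSeries]) -> pd.DataFrame:
    """Long-format table: frame, resi, resj, attractive, vdw, repulsive, total."""
    rows = []
    for ps in series:
        for k, frame in enumerate(ps.frames):
            rows.append(
                dict(frame=int(frame), resi=ps.pair[0], resj=ps.pair[1],
                     attractive=ps.attractive[k], vdw=ps.vdw[k],
                     repulsive=ps.repulsive[k], total=ps.total[k])
            )
    return pd.DataFrame(rows)


def total_channel_series(series: Sequence[PairSeries], channel: str = "attractive") -> np.ndarray:
    """Sum of one channel over all pairs, per frame (the Fig-3-style aggregate)."""
    return np.sum([getattr(ps, channel) for ps in series], axis=0)


def smooth_series(values: np.ndarray, window: int = 10) -> np.ndarray:
    """Centred moving average with edge windows truncated to available frames.

    Output length equals input length.  A window longer than the series
    degrades to the global mean (with a warning).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(values, dtype=float)
    if window > len(x):
        warnings.warn("smoothing window exceeds series length; using the global mean")
        return np.full_like(x, x.mean())
    return (
        pd.Series(x).rolling(window=window, center=True, min_periods=1).mean().to_numpy()
    )


def detect_hbonds(
    fragments: Sequence[Fragment],
    frame: int = 0,
    *,
    max_ha: float = 2.5,
    min_angle: float = 120.0,
    min_sep: int = 3,
    covalent_dh: float = 1.25,
) -> list[HBondRecord]:
    """Geometric hydrogen-bond detection on one frame's fragments.

    A bond is counted when the H···acceptor distance is <= ``max_ha``
    angstrom and the donor-H···acceptor angle exceeds ``min_angle`` degrees.
    Donors are N/O atoms with a hydrogen within ``covalent_dh`` angstrom in
    the same fragment; acceptors are N/O atoms.  Only fragment pairs outside
    the sequence-separation band (or on different chains, or involving water)
    are compared.
    """
    donors: list[tuple[int, int, int, np.ndarray, np.ndarray]] = []
    acceptors: list[tuple[int, int, np.ndarray]] = []
    any_h = False
    for fidx, frag in enumerate(fragments):
        els = [el.capitalize() for el in frag.elements]
        h_idx = [i for i, el in enumerate(els) if el == "H"]
        heavy_no = [i for i, el in enumerate(els) if el in ("N", "O")]
        any_h = any_h or bool(h_idx)
        for a in heavy_no:
            acceptors.append((fidx, a, frag.coords[a]))
        for h in h_idx:
            if not heavy_no:
                continue
            d = np.linalg.norm(frag.coords[heavy_no] - frag.coords[h], axis=1)
            k = int(np.argmin(d))
            if d[k] <= covalent_dh:
                donors.append((fidx, heavy_no[k], h, frag.coords[heavy_no[k]], frag.coords[h]))
    if not any_h:
        raise ValueError("no hydrogens present; hydrogen-bond detection needs explicit-H input")

    records: list[HBondRecord] = []
    for dfrag, datom, hatom, dpos, hpos in donors:
        fd = fragments[dfrag]
        for afrag, aatom, apos in acceptors:
            if afrag == dfrag:
                continue
            fa = fragments[afrag]
            if (
                not fd.is_water
                and not fa.is_water
                and fd.chain_id == fa.chain_id
                and abs(fd.sequence_index - fa.sequence_index) <= min_sep
            ):
                continue
            dist_ha = float(np.linalg.norm(apos - hpos))
            if dist_ha > max_ha:
                continue
            v1 = dpos - hpos
            v2 = apos - hpos
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if angle <= min_angle:
                continue
            records.append(
                HBondRecord(
                    frame=frame,
                    donor_fragment=dfrag,
                    acceptor_fragment=afrag,
                    donor_atom=datom,
                    hydrogen_atom=hatom,
                    acceptor_atom=aatom,
                    distance_ha=dist_ha,
                    distance_da=float(np.linalg.norm(apos - dpos)),
                    angle_dha=angle,
                )
            )
    return records


def hbond_counts_series(
    frames_xyz: np.ndarray,
    frame_indices: Sequence[int],
    fragments: Sequence[Fragment],
    *,
    min_frequency: float = 0.0,
    **kwargs,
) -> tuple[np.ndarray, list[HBondRecord]]:
    """Per-frame hydrogen-bond counts over sampled frames.

    ``min_frequency`` > 0 keeps only donor/acceptor atom triplets detected in
    at least that fraction of the sampled frames (the frequency filter of the
    classical criterion); the default counts instantaneous per-frame bonds.
    """
    frame_indices = np.asarray(frame_indices, dtype=int)
    all_records: list[HBondRecord] = []
    for frame in frame_indices:
        frags = [f.at_frame(frames_xyz[frame]) for f in fragments]
        all_records.extend(detect_hbonds(frags, frame=int(frame), **kwargs))
    if min_frequency > 0.0:
        keys = {}
        for r in all_records:
            key = (r.donor_fragment, r.donor_atom, r.hydrogen_atom, r.acceptor_fragment, r.acceptor_atom)
            keys[key] = keys.get(key, 0) + 1
        min_count = min_frequency * len(frame_indices)
        all_records = [
            r for r in all_records
            if keys[(r.donor_fragment, r.donor_atom, r.hydrogen_atom, r.acceptor_fragment, r.acceptor_atom)]
            >= min_count
        ]
    counts = np.array([sum(r.frame == f for r in all_records) for f in frame_indices], dtype=float)
    return counts, all_records


def correlate_hbonds_attractive(hbond_counts: np.ndarray, attractive: np.ndarray) -> float:
    """Ordinary-least-squares coefficient of determination R^2 in [0, 1].

    Returns NaN (with a warning) for a zero-variance predictor.
    """
    x = np.asarray(hbond_counts, dtype=float)
    y = np.asarray(attractive, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("series must be aligned and of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero-variance series: R^2 undefined")
        return float("nan")
    res = linregress(x, y)
    return float(res.rvalue**2)


def _pair_hbond_atoms(records: Iterable[HBondRecord]) -> dict[tuple[int, int], set[tuple[int, int]]]:
    """Residue pair -> set of (donor_atom_global_slot, acceptor_atom_global_slot)."""
    out: dict[tuple[int, int], set[tuple[int, int]]] = {}
    for r in records:
        i, j = sorted((r.donor_fragment, r.acceptor_fragment))
        if (r.donor_fragment, r.acceptor_fragment) == (i, j):
            da = (r.donor_atom, r.acceptor_atom)
        else:
            da = (r.acceptor_atom, r.donor_atom)
        out.setdefault((i, j), set()).add(da)
    return out


def build_contact_maps(
    frames_xyz: np.ndarray,
    frame_indices: Sequence[int],
    fragments: Sequence[Fragment],
    pairs: PairList,
    params: NCIParams = NCIParams(),
    *,
    label: str = "ensemble",
    hbond_kwargs: dict | None = None,
) -> ContactMapEnsemble:
    """Ensemble-mean NCI and distance maps over the given frames.

    The hydrogen-bond distance map records, for every residue pair in which a
    bond was ever detected, the per-frame minimum donor-acceptor distance
    among that pair's recorded donor/acceptor atom pairs, inverted and
    averaged; pairs with no bond in any frame stay zero.
    """
    n = len(fragments)
    frame_indices = np.asarray(frame_indices, dtype=int)
    vdw = np.zeros((n, n))
    amr = np.zeros((n, n))
    inv6 = np.zeros((n, n))

    series = pair_integral_series(frames_xyz, frame_indices, fragments, pairs, params)
    for ps, (i, j) in zip(series, pairs):
        vdw[i, j] = vdw[j, i] = float(np.mean(ps.vdw))
        amr[i, j] = amr[j, i] = float(np.mean(ps.attractive - ps.repulsive))

    # hydrogen-free (coarse) models legitimately have no hydrogen bonds
    has_h = any(e.upper() == "H" for f in fragments for e in f.elements)
    if has_h:
        _, records = hbond_counts_series(frames_xyz, frame_indices, fragments,
                                         **(hbond_kwargs or {}))
    else:
        records = []
    hb_atoms = _pair_hbond_atoms(records)

    inv_hb = np.zeros((n, n))
    pair_set = set(pairs.pairs)
    for fi, frame in enumerate(frame_indices):
        frags = [f.at_frame(frames_xyz[frame]) for f in fragments]
        for i, j in pairs:
            d = pair_min_heavy_distance(frags[i], frags[j])
            inv6[i, j] += (1.0 / d) ** 6
        for (i, j), atom_pairs in hb_atoms.items():
            if (i, j) not in pair_set:
                continue
            dmin = min(
                float(np.linalg.norm(frags[i].coords[da] - frags[j].coords[aa]))
                for da, aa in atom_pairs
            )
            inv_hb[i, j] += 1.0 / dmin
    inv6 /= max(len(frame_indices), 1)
    inv_hb /= max(len(frame_indices), 1)
    inv6 = inv6 + inv6.T
    inv_hb = inv_hb + inv_hb.T

    return ContactMapEnsemble(
        label=label,
        n_frames=len(frame_indices),
        vdw=vdw,
        att_minus_rep=amr,
        inv_dist6=inv6,
        inv_hbond_dist=inv_hb,
    )


def sasa(
    traj: md.Trajectory,
    frame_indices: Sequence[int] | None = None,
    residue_indices: Sequence[int] | None = None,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> np.ndarray:
    """Shrake-Rupley SASA per residue, in angstrom^2 (frames x residues).

    ``probe_radius`` is in angstrom.  ``residue_indices`` selects columns.
    """
    sub = traj if frame_indices is None else traj[list(np.asarray(frame_indices, dtype=int))]
    area_nm2 = md.shrake_rupley(sub, probe_radius=probe_radius / 10.0,
                                n_sphere_points=n_sphere_points, mode="residue")
    area = area_nm2 * 100.0
    if residue_indices is not None:
        area = area[:, list(residue_indices)]
    return area


def residue_water_integrals(
    frames_xyz: np.ndarray,
    frame_indices: Sequence[int],
    fragments: Sequence[Fragment],
    params: NCIParams = NCIParams(),
    shell_cutoff: float = 4.0,
) -> pd.DataFrame:
    """Mean NCI integrals between each protein residue and its first water
    shell over the given frames (rows: residue, columns: channels)."""
    frame_indices = np.asarray(frame_indices, dtype=int)
    protein = [(i, f) for i, f in enumerate(fragments) if not f.is_water]
    acc = {i: np.zeros(3) for i, _ in protein}
    for frame in frame_indices:
        frags = [f.at_frame(frames_xyz[frame]) for f in fragments]
        for i, _ in protein:
            res = frags[i]
            shell = water_shell(frags, res, cutoff=shell_cutoff)
            if shell is None:
                continue
            out = pair_integrals(res, shell, params, frame_index=int(frame),
                                 pair=(res.fragment_id, shell.fragment_id))
            acc[i] += np.array([out.attractive, out.vdw, out.repulsive])
    rows = []
    for i, frag in protein:
        mean = acc[i] / max(len(frame_indices), 1)
        rows.append(dict(residue=frag.fragment_id, attractive=mean[0], vdw=mean[1],
                         repulsive=mean[2], total=float(mean.sum())))
    return pd.DataFrame(rows)


def delta_integrals(end, start):
    """Elementwise end - start for matched channel maps.

    Accepts two ContactMapEnsemble (returns a dict of difference matrices) or
    two aligned DataFrames from :func:`residue_water_integrals` (returns a
    DataFrame of differences).  Mismatched pair sets raise.
    """
    if isinstance(end, ContactMapEnsemble) and isinstance(start, ContactMapEnsemble):
        if end.vdw.shape != start.vdw.shape:
            raise ValueError("ensembles cover different residue sets")
        return {
            "vdw": end.vdw - start.vdw,
            "att_minus_rep": end.att_minus_rep - start.att_minus_rep,
        }
    if isinstance(end, pd.DataFrame) and isinstance(start, pd.DataFrame):
        if list(end["residue"]) != list(start["residue"]):
            raise ValueError("residue sets differ between the two ensembles")
        out = end.copy()
        for col in ("attractive", "vdw", "repulsive", "total"):
            out[col] = end[col].to_numpy() - start[col].to_numpy()
        return out
    raise TypeError("end and start must be of the same supported type")


def plot_contact_map(lower: np.ndarray, upper: np.ndarray, path, *,
                     labels: tuple[str, str] = ("lower", "upper"), title: str = "") -> None:
    """Render a two-triangle residue-residue map to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = lower.shape[0]
    combined = np.tril(lower, -1) + np.triu(upper, 1)
    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(combined, origin="lower", cmap="viridis")
    ax.set_xlabel(f"residue ({labels[1]} above diagonal)")
    ax.set_ylabel(f"residue ({labels[0]} below diagonal)")
    ax.set_title(title)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
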