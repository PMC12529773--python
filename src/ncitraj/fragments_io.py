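"""Structure and trajectory handling: residue fragments, pair lists, water shells.

A protein frame is split into per-residue fragments — the promolecular
density of a fragment needs only elements and positions, so residues cut at
peptide bonds are used exactly as annotated, with no caps added (the
predefined atomic densities are not altered by missing bonding partners).
Waters are grouped one fragment per molecule and can be merged into a
first-shell fragment around a residue.

Parsing is delegated to mdtraj; multi-model PDB files load as multi-frame
trajectories.  Coordinates are handled in angstrom throughout this package
(mdtraj stores nm internally).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import mdtraj as md
import numpy as np
from scipy.spatial import cKDTree

from .promolecular import UnsupportedElementError, default_density_table

__all__ = [
    "Fragment",
    "PairList",
    "WATER_RESIDUE_NAMES",
    "ELEMENT_NUMBERS",
    "load_structure",
    "split_into_residues",
    "enumerate_pairs",
    "water_shell",
    "fragments_to_mdtraj",
    "write_fragment_xyz",
]

WATER_RESIDUE_NAMES = {"HOH", "WAT", "TIP3", "TIP4", "SOL", "SPC", "H2O"}

ELEMENT_NUMBERS = {"H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16}
_NUMBER_ELEMENTS = {v: k for k, v in ELEMENT_NUMBERS.items()}


@dataclass
class Fragment:
    """One residue (or water molecule / water shell) as an element+coordinate set.

    ``sequence_index`` is the author-assigned residue sequence number (PDB
    resSeq), which survives file round trips; ``atom_indices`` point into
    the source topology so coordinates can be re-extracted per frame with
    :meth:`at_frame`.  Coordinates are in angstrom.
    """

    fragment_id: str
    residue_name: str
    chain_id: str
    sequence_index: int
    elements: list[str]
    coords: np.ndarray
    atom_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.elements) == 0:
            raise ValueError(f"fragment {self.fragment_id}: empty atom list")
        if len(self.elements) != len(self.coords):
            raise ValueError(f"fragment {self.fragment_id}: elements/coords length mismatch")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def is_water(self) -> bool:
        return self.residue_name == "WAT"

    @property
    def heavy_indices(self) -> np.ndarray:
        return np.array([i for i, el in enumerate(self.elements) if el.capitalize() != "H"], dtype=int)

    def at_frame(self, frame_xyz: np.ndarray) -> "Fragment":
        """Same fragment with coordinates taken from ``frame_xyz`` (n_atoms_total, 3) angstrom."""
        if self.atom_indices is None:
            raise ValueError("fragment carries no source atom indices")
        return replace(self, coords=np.asarray(frame_xyz, dtype=float)[self.atom_indices])

    def atoms(self) -> list[tuple[str, np.ndarray]]:
        return list(zip(self.elements, self.coords))


@dataclass(frozen=True)
class PairList:
    """Unordered residue pairs (i < j by list position) above a sequence separation."""

    pairs: tuple[tuple[int, int], ...]  # indices into the fragment list
    ids: tuple[tuple[str, str], ...]
    min_separation: int

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


def load_structure(path) -> md.Trajectory:
    """Load a structure or multi-model trajectory (PDB and friends) via mdtraj."""
    return md.load(str(path))


def _element_symbol(atom) -> str:
    if atom.element is not None and atom.element.symbol != "VS":
        return atom.element.symbol
    name = "".join(ch for ch in atom.name if ch.isalpha())
    return name[:1].capitalize()


def split_into_residues(
    traj: md.Trajectory,
    frame: int = 0,
    *,
    validate_elements: bool = True,
) -> list[Fragment]:
    """Split a frame into residue fragments (one per residue; waters one per molecule).

    Every atom is assigned to exactly one fragment; atom counts are conserved.
    Unknown elements raise if ``validate_elements`` (they could not be used in
    any density evaluation downstream).
    """
    table = default_density_table() if validate_elements else None
    xyz = np.asarray(traj.xyz[frame], dtype=float) * 10.0  # nm -> angstrom
    fragments: list[Fragment] = []
    for chain in traj.topology.chains:
        chain_id = chain.chain_id or str(chain.index)
        for residue in chain.residues:
            idx = np.array([a.index for a in residue.atoms], dtype=int)
            if idx.size == 0:
                raise ValueError(f"residue {residue} has no atoms")
            elements = [_element_symbol(a) for a in residue.atoms]
            if table is not None:
                for el in elements:
                    if el.capitalize() not in table:
                        raise UnsupportedElementError(
                            f"residue {residue}: element {el!r} not in the density table"
                        )
            name = residue.name.upper()
            if name in WATER_RESIDUE_NAMES:
                name = "WAT"
            fragments.append(
                Fragment(
                    fragment_id=f"{chain_id}:{name}{residue.resSeq}",
                    residue_name=name,
                    chain_id=chain_id,
                    sequence_index=int(residue.resSeq),
                    elements=elements,
                    coords=xyz[idx],
                    atom_indices=idx,
                )
            )
    total = sum(f.n_atoms for f in fragments)
    if total != traj.n_atoms:
        raise AssertionError(f"fragmentation lost atoms: {total} != {traj.n_atoms}")
    return fragments


def enumerate_pairs(fragments: Sequence[Fragment], min_separation: int = 3) -> PairList:
    """All unordered protein-residue pairs with sequence separation strictly
    greater than ``min_separation`` (pairs on different chains always qualify).

    Ordering is deterministic: (i, j) with i < j, lexicographic by position in
    the fragment list.
    """
    if min_separation < 0:
        raise ValueError("min_separation must be >= 0")
    pairs: list[tuple[int, int]] = []
    ids: list[tuple[str, str]] = []
    for i in range(len(fragments)):
        fi = fragments[i]
        if fi.is_water:
            continue
        for j in range(i + 1, len(fragments)):
            fj = fragments[j]
            if fj.is_water:
                continue
            if fi.chain_id == fj.chain_id and abs(fi.sequence_index - fj.sequence_index) <= min_separation:
                continue
            pairs.append((i, j))
            ids.append((fi.fragment_id, fj.fragment_id))
    return PairList(pairs=tuple(pairs), ids=tuple(ids), min_separation=min_separation)


def water_shell(fragments: Sequence[Fragment], residue: Fragment, cutoff: float = 4.0) -> Fragment:
    """Merge all water molecules with any atom within ``cutoff`` angstrom of
    ``residue`` into a single shell fragment (whole molecules only).

    Returns ``None`` when no water is in range; callers treat an empty shell
    as zero integrals.
    """
    waters = [f for f in fragments if f.is_water and f is not residue]
    if not waters:
        return None
    tree = cKDTree(residue.coords)
    keep: list[Fragment] = []
    for w in waters:
        d, _ = tree.query(w.coords, k=1)
        if np.any(d <= cutoff):
            keep.append(w)
    if not keep:
        return None
    return Fragment(
        fragment_id=f"WATSHELL:{residue.fragment_id}",
        residue_name="WAT",
        chain_id=residue.chain_id,
        sequence_index=residue.sequence_index,
        elements=[el for w in keep for el in w.elements],
        coords=np.vstack([w.coords for w in keep]),
        atom_indices=(
            np.concatenate([w.atom_indices for w in keep])
            if all(w.atom_indices is not None for w in keep)
            else None
        ),
    )


def fragments_to_mdtraj(
    fragments: Sequence[Fragment],
    xyz_frames: np.ndarray | None = None,
) -> md.Trajectory:
    """Build an mdtraj Trajectory from fragments (coordinates in angstrom).

    ``xyz_frames`` (n_frames, n_atoms, 3), if given, supplies multiple frames
    in the concatenated fragment atom order; otherwise the fragments' own
    coordinates form a single frame.
    """
    top = md.Topology()
    chains: dict[str, object] = {}
    for frag in fragments:
        ch = chains.get(frag.chain_id)
        if ch is None:
            ch = top.add_chain()
            chains[frag.chain_id] = ch
        res = top.add_residue(frag.residue_name, ch, resSeq=frag.sequence_index)
        counts: dict[str, int] = {}
        for el in frag.elements:
            counts[el] = counts.get(el, 0) + 1
            element = md.element.Element.getBySymbol(el.capitalize())
            top.add_atom(f"{el.upper()}{counts[el]}", element, res)
    if xyz_frames is None:
        xyz = np.vstack([f.coords for f in fragments])[None, :, :]
    else:
        xyz = np.asarray(xyz_frames, dtype=float)
        if xyz.ndim == 2:
            xyz = xyz[None, :, :]
    return md.Trajectory(xyz / 10.0, top)  # angstrom -> nm


def write_fragment_xyz(fragment: Fragment, path) -> None:
    """Write one fragment as a plain xyz file (angstrom), mirroring the
    per-residue coordinate files of the analysis workflow."""
    with open(path, "w") as fh:
        fh.write(f"{fragment.n_atoms}\n{fragment.fragment_id}\n")
        for el, (x, y, z) in fragment.atoms():
            fh.write(f"{el:<2s} {x:14.8f} {y:14.8f} {z:14.8f}\n")
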