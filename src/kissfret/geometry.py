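"""Idealized RNA geometry builders (synthetic structures).

Programmatically generated, reduced-atom A-form-like RNA models used as
reference structures for the coarse-grained topology builder and as steric
models for accessible-volume calculations.  These are synthetic idealized
constructs -- regular helical geometry with a reduced atom set (P, C4', C1',
O3' backbone plus three base atoms per residue) -- not experimental
coordinates.  Each builder returns the structure together with its
base-pairing list so native contacts can be defined unambiguously.

``synthetic_kissing_construct`` models the guanidine-II riboswitch FRET
construct in the kissing-loop conformation: the 9-bp P1 stem-loop and the
4-bp P2 stem-loop stacked coaxially with two inter-loop C.G kissing pairs,
dye attachment points at the C5 aminoallyl arm of U3 and at the 3' oxygen of
the final P2 residue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .avfret import Structure

__all__ = [
    "ideal_hairpin",
    "synthetic_kissing_construct",
    "PAIR_RISE",
    "PAIR_TWIST",
]

PAIR_RISE = 2.81  # Angstrom per base pair
PAIR_TWIST = np.deg2rad(32.7)

# reduced-atom template in the base-pair frame (Angstrom), strand +1;
# strand -1 atoms are the point reflection through the pair center
_TEMPLATE = {
    "P": (7.5, 4.5, 1.5),
    "C4'": (6.5, 2.4, 0.5),
    "C1'": (5.2, 0.0, 0.0),
    "O3'": (6.9, 3.6, 2.3),
    "N1": (3.2, 0.4, 0.0),
    "C5": (3.9, 1.5, 0.0),
    "C2": (2.35, -0.1, 0.0),
}

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _rot(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


_BASE_ATOMS = ("N1", "C5", "C2")


def _residue_atoms(pair_index: float, strand: int,
                   angle_offset: float = 0.0,
                   radial_scale: float = 1.0,
                   base_shift: float = 0.0) -> dict[str, np.ndarray]:
    """Atoms of one residue; ``base_shift`` pushes the base atoms radially
    outward (used for loop/bulge residues so their bases point away from the
    helix instead of clashing with the stack)."""
    rot = _rot(pair_index * PAIR_TWIST + angle_offset)
    out = {}
    for name, xyz in _TEMPLATE.items():
        p = np.array(xyz, dtype=float)
        if name in _BASE_ATOMS and base_shift:
            p[0] += base_shift
        p = p * (1.0 if strand > 0 else -1.0)
        p = p * np.array([radial_scale, radial_scale, 1.0])
        out[name] = rot @ p + np.array([0.0, 0.0, pair_index * PAIR_RISE])
    return out


@dataclass
class _Builder:
    names: list
    res_ids: list
    res_names: list
    chains: list
    coords: list

    def add_residue(self, chain: str, res_id: int, res_name: str,
                    atoms: dict[str, np.ndarray], skip: tuple[str, ...] = ()):
        for name, xyz in atoms.items():
            if name in skip:
                continue
            self.names.append(name)
            self.res_ids.append(res_id)
            self.res_names.append(res_name)
            self.chains.append(chain)
            self.coords.append(xyz)

    def build(self) -> Structure:
        elements = np.array([n[0] for n in self.names])
        return Structure(
            atom_name=np.array(self.names),
            res_id=np.array(self.res_ids),
            res_name=np.array(self.res_names),
            chain_id=np.array(self.chains),
            element=elements,
            coord=np.array(self.coords),
            hetero=np.zeros(len(self.names), dtype=bool),
        )


def ideal_hairpin(
    n_bp: int = 4,
    loop: str = "ACGA",
    stem_seq: str | None = None,
    chain: str = "A",
) -> tuple[Structure, list[tuple[int, int]]]:
    """Synthetic idealized stem-loop: ``n_bp`` helical pairs capped by a loop.

    Residues are numbered 5'->3': stem strand 1 (1..n), loop, stem strand 2
    descending.  Returns ``(structure, pairing)`` with pairing as residue-id
    tuples.  The 5'-terminal residue has no phosphate.
    """
    if stem_seq is None:
        stem_seq = ("GCGC" * n_bp)[:n_bp]
    b = _Builder([], [], [], [], [])
    n_loop = len(loop)
    pairing = []
    res = 0
    for i in range(n_bp):
        res += 1
        skip = ("P",) if res == 1 else ()
        b.add_residue(chain, res, stem_seq[i], _residue_atoms(i, +1), skip=skip)
    # loop residues arc over the top at backbone radius
    top = n_bp - 1
    for l in range(1, n_loop + 1):
        res += 1
        frac = l / (n_loop + 1)
        angle = np.deg2rad(-85.0 + 170.0 * frac)
        atoms = _residue_atoms(top + 0.5 + 0.8 * np.sin(np.pi * frac), +1,
                               angle_offset=angle, radial_scale=1.0,
                               base_shift=6.0)
        b.add_residue(chain, res, loop[l - 1], atoms)
    for i in range(n_bp - 1, -1, -1):
        res += 1
        b.add_residue(chain, res, _COMPLEMENT[stem_seq[i]],
                      _residue_atoms(i, -1))
        pairing.append((i + 1, res))
    return b.build(), sorted(pairing)


# --- the guanidine-II riboswitch FRET construct, kissing conformation -----

# chain A: P1 stem-loop (res 1-23); chain B: P2 stem-loop (res 36-47)
_P1_SEQ = "GUUUGCAGGACGACCUGCAAACG"  # res 1..23
_P2_SEQ = "GGGGACGGCCCC"             # res 36..47


def synthetic_kissing_construct() -> tuple[Structure, list[tuple[str, int, str, int]]]:
    """Synthetic idealized model of the FRET construct in the K-state.

    Coaxial stack: 9-bp P1 stem (pairs A1.A22 .. A9.A14), two kissing pairs
    between the ACGA/ACGG loops (A11.B42, A12.B41), then the 4-bp P2 stem
    (B39.B44 .. B36.B47).  Unpaired loop adenines and the dangling A23 sit
    off-helix.  Residue A3 carries an extra "C5A" aminoallyl attachment atom
    in the major groove (Cy3 site); the Cy5 site is the "O3'" of B47.

    Returns ``(structure, pairing)`` with pairing entries
    ``(chain_i, res_i, chain_j, res_j)``.
    """
    b = _Builder([], [], [], [], [])
    pairing: list[tuple[str, int, str, int]] = []

    # P1 stem, strand 1 (A1..A9) and strand 2 (A14..A22)
    for i in range(9):
        res = i + 1
        skip = ("P",) if res == 1 else ()
        atoms = _residue_atoms(i, +1)
        if res == 3:  # aminoallyl arm of U3, pointing into the major groove
            rot = _rot(i * PAIR_TWIST)
            atoms["C5A"] = rot @ np.array([5.8, 3.2, 0.3]) + np.array(
                [0.0, 0.0, i * PAIR_RISE])
        b.add_residue("A", res, _P1_SEQ[res - 1], atoms, skip=skip)
    for i in range(9):
        res = 22 - i
        b.add_residue("A", res, _P1_SEQ[res - 1], _residue_atoms(i, -1))
        pairing.append(("A", i + 1, "A", res))

    # P1 loop: C11/G12 form the kissing pairs (helical positions 9, 10);
    # A10 and A13 bulge outward
    b.add_residue("A", 11, "C", _residue_atoms(9, +1))
    b.add_residue("A", 12, "G", _residue_atoms(10, +1))
    b.add_residue("A", 10, "A", _residue_atoms(8.7, +1,
                                               angle_offset=np.deg2rad(55),
                                               radial_scale=1.15,
                                               base_shift=5.0))
    b.add_residue("A", 13, "A", _residue_atoms(10.3, +1,
                                               angle_offset=np.deg2rad(-55),
                                               radial_scale=1.15,
                                               base_shift=5.0))
    # dangling 3' G23 below the P1 stem
    b.add_residue("A", 23, "G", _residue_atoms(-1.0, -1,
                                               angle_offset=np.deg2rad(40),
                                               radial_scale=1.1,
                                               base_shift=5.0))

    # P2 loop partners of the kissing pairs
    b.add_residue("B", 42, "G", _residue_atoms(9, -1))
    b.add_residue("B", 41, "C", _residue_atoms(10, -1))
    pairing.append(("A", 11, "B", 42))
    pairing.append(("A", 12, "B", 41))
    b.add_residue("B", 40, "A", _residue_atoms(10.4, -1,
                                               angle_offset=np.deg2rad(55),
                                               radial_scale=1.15,
                                               base_shift=5.0))
    b.add_residue("B", 43, "G", _residue_atoms(8.6, -1,
                                               angle_offset=np.deg2rad(-55),
                                               radial_scale=1.15,
                                               base_shift=5.0))

    # P2 stem: pairs B39.B44 (position 11) .. B36.B47 (position 14)
    for p in range(11, 15):
        res1 = 50 - p        # 39, 38, 37, 36
        res2 = 33 + p        # 44, 45, 46, 47
        skip = ("P",) if res1 == 36 else ()
        b.add_residue("B", res1, _P2_SEQ[res1 - 36], _residue_atoms(p, +1),
                      skip=skip)
        b.add_residue("B", res2, _P2_SEQ[res2 - 36], _residue_atoms(p, -1))
        pairing.append(("B", res1, "B", res2))

    return b.build(), pairing
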