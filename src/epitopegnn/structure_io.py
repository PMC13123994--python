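"""Reading, representing and writing protein structures.

Structures come in as PDB or mmCIF (experimental or predicted); what the
rest of the pipeline needs is an ordered list of polymer residues per chain
with their heavy-atom coordinates, plus per-residue Cα geometry.  Scores can
be written back into the B-factor column for visualization.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "read_structure",
    "ca_coordinates",
    "heavy_atom_coords",
    "write_structure_pdb",
    "write_prediction_pdb",
]

_HYDROGEN = {"H", "D", "T"}


@dataclasses.dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray  # (3,) Å

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in _HYDROGEN

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not self.element:
            raise ValueError(f"atom {self.name} has empty element symbol")


@dataclasses.dataclass
class Residue:
    chain_id: str
    author_number: int
    insertion_code: str
    index: int  # 0-based position within the chain
    aa_type: str  # one-letter code, 'X' for nonstandard
    atoms: list

    @property
    def heavy_atoms(self) -> list:
        return [a for a in self.atoms if not a.is_hydrogen]

    def atom(self, name: str):
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self):
        return self.atom("CA")


@dataclasses.dataclass
class Structure:
    id: str
    chains: list  # list of (chain_id, list[Residue])

    def chain_ids(self) -> list:
        return [cid for cid, _ in self.chains]

    def chain(self, chain_id: str) -> list:
        for cid, residues in self.chains:
            if cid == chain_id:
                return residues
        raise KeyError(
            f"chain {chain_id!r} not found; available: {self.chain_ids()}"
        )

    def residue(self, chain_id: str, index: int) -> Residue:
        return self.chain(chain_id)[index]


def _one_letter(resname: str) -> str:
    info = gemmi.find_tabulated_residue(resname)
    if info is not None and info.is_amino_acid():
        code = info.one_letter_code.upper()
        if code.isalpha():
            return code
    return "X"


def _resolve_altlocs(res: gemmi.Residue) -> list:
    """Keep one location per atom name: highest occupancy, ties → altloc 'A'."""
    chosen: dict = {}
    for atom in res:
        alt = atom.altloc if atom.altloc != "\0" else ""
        key = atom.name
        prev = chosen.get(key)
        if prev is None:
            chosen[key] = (atom, alt)
            continue
        prev_atom, prev_alt = prev
        if atom.occ > prev_atom.occ or (
            atom.occ == prev_atom.occ and alt < prev_alt
        ):
            chosen[key] = (atom, alt)
    return [a for a, _ in chosen.values()]


def read_structure(path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Polymer residues with at least one heavy atom are retained in file
    order; waters and ligands are dropped; alternate locations resolve to
    the highest-occupancy conformer.  Only the first model of multi-model
    files is read.
    """
    path = Path(path)
    fmt = {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "auto": gemmi.CoorFormat.Detect,
    }[format]
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"could not parse {path}: {exc}") from exc
    st.setup_entities()

    chains = []
    model = st[0]
    for gchain in model:
        residues = []
        for gres in gchain:
            if gres.entity_type not in (
                gemmi.EntityType.Polymer,
                gemmi.EntityType.Unknown,
            ):
                continue
            if gres.is_water():
                continue
            atoms = []
            for gatom in _resolve_altlocs(gres):
                atoms.append(
                    Atom(
                        name=gatom.name,
                        element=gatom.element.name,
                        coords=np.array(
                            [gatom.pos.x, gatom.pos.y, gatom.pos.z]
                        ),
                    )
                )
            if not any(not a.is_hydrogen for a in atoms):
                continue
            residues.append(
                Residue(
                    chain_id=gchain.name,
                    author_number=gres.seqid.num,
                    insertion_code=(gres.seqid.icode or "").strip(),
                    index=len(residues),
                    aa_type=_one_letter(gres.name),
                    atoms=atoms,
                )
            )
        if residues:
            chains.append((gchain.name, residues))
    if not chains:
        raise ValueError(f"no polymer residues found in {path}")
    return Structure(id=path.stem, chains=chains)


def ca_coordinates(structure: Structure, chain_id: str):
    """Cα coordinate matrix for a chain.

    Returns ``(coords, kept_indices, dropped_indices)`` where ``coords`` is
    an (M, 3) array over residues that have a Cα, in chain order.
    """
    residues = structure.chain(chain_id)
    coords, kept, dropped = [], [], []
    for res in residues:
        ca = res.ca
        if ca is None:
            dropped.append(res.index)
        else:
            coords.append(ca.coords)
            kept.append(res.index)
    return np.array(coords).reshape(-1, 3), kept, dropped


def heavy_atom_coords(residues: Iterable[Residue]) -> np.ndarray:
    """All heavy-atom coordinates of an iterable of residues, stacked."""
    pts = [a.coords for r in residues for a in r.heavy_atoms]
    return np.array(pts).reshape(-1, 3)


_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "E": "GLU", "Q": "GLN", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}


def _to_gemmi(structure: Structure, bfactors=None) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model(1)
    flat_i = 0
    for cid, residues in structure.chains:
        chain = gemmi.Chain(cid)
        for res in residues:
            gres = gemmi.Residue()
            gres.name = _AA3.get(res.aa_type, "UNK")
            gres.seqid = gemmi.SeqId(res.author_number, res.insertion_code or " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.coords)
                ga.occ = 1.0
                ga.b_iso = 0.0 if bfactors is None else float(bfactors[flat_i])
                gres.add_atom(ga)
            chain.add_residue(gres)
            flat_i += 1
        model.add_chain(chain)
    st.add_model(model)
    return st


def write_structure_pdb(structure: Structure, path) -> None:
    _to_gemmi(structure).write_pdb(str(path))


def write_prediction_pdb(structure: Structure, scores: Sequence[float],
                         path) -> None:
    """Write the structure with per-residue scores ×100 in the B-factor column.

    Scores must be in [0, 1], one per residue over all chains in order;
    re-reading the file recovers each score to within 0.01 (the PDB
    B-factor field has two decimals).
    """
    n_res = sum(len(res) for _, res in structure.chains)
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (n_res,):
        raise ValueError(
            f"got {scores.size} scores for {n_res} residues"
        )
    _to_gemmi(structure, bfactors=100.0 * scores).write_pdb(str(path))


def read_prediction_scores(path) -> np.ndarray:
    """Recover per-residue scores written by :func:`write_prediction_pdb`."""
    st = read_structure(path, format="pdb")
    gst = gemmi.read_structure(str(path))
    scores = []
    for gchain in gst[0]:
        for gres in gchain:
            if gres.is_water():
                continue
            scores.append(gres[0].b_iso / 100.0)
    del st
    return np.array(scores)
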