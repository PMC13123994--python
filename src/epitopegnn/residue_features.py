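"""Per-residue featurization: DSSP-derived descriptors, surface mask, labels.

Each residue gets a 14-dimensional structural feature vector — a 9-state
secondary-structure one-hot (8 DSSP states plus "unknown"), relative solvent
accessibility in [0, 1], and sin/cos of the backbone torsions φ and ψ —
plus a surface flag (rASA ≥ 0.15) and a binary epitope label derived from
antigen–antibody heavy-atom contacts within 4 Å.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import Structure

__all__ = [
    "DSSP_STATES",
    "UNKNOWN",
    "MAX_ASA",
    "DsspRecord",
    "parse_dssp",
    "encode_ss",
    "compute_rasa",
    "dihedral",
    "backbone_torsions",
    "torsion_features",
    "label_epitopes",
    "surface_mask",
    "build_feature_table",
    "feature_table_to_tsv",
]

#: the eight DSSP secondary-structure states, in fixed one-hot order
DSSP_STATES = ("H", "B", "E", "G", "I", "T", "S", "-")
UNKNOWN = "UNKNOWN"

#: theoretical maximum accessible surface areas per residue type (Å²),
#: Tien et al. 2013
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}
_MEAN_MAX_ASA = sum(MAX_ASA.values()) / len(MAX_ASA)


@dataclasses.dataclass
class DsspRecord:
    ss_state: str  # one of DSSP_STATES or UNKNOWN
    asa: float  # Å², >= 0

    def __post_init__(self):
        if self.ss_state not in DSSP_STATES and self.ss_state != UNKNOWN:
            raise ValueError(f"bad secondary-structure state {self.ss_state!r}")
        if self.asa < 0:
            raise ValueError("ASA must be non-negative")


def _parse_dssp_classic(lines, chain_id):
    records = []
    in_body = False
    for line in lines:
        if not in_body:
            if line.lstrip().startswith("#  RESIDUE"):
                in_body = True
            continue
        if len(line) < 38:
            continue
        aa = line[13]
        if aa == "!":  # chain break
            continue
        chain = line[11]
        if chain_id is not None and chain.strip() != chain_id:
            continue
        ss = line[16]
        ss = ss if ss in DSSP_STATES else ("-" if ss == " " else UNKNOWN)
        # lowercase letters (disulfide-bonded cysteines) are not SS states
        try:
            asa = float(line[34:38])
        except ValueError:
            asa = 0.0
        records.append(DsspRecord(ss_state=ss, asa=max(asa, 0.0)))
    if not in_body:
        raise ValueError("malformed DSSP file: no '#  RESIDUE' header line")
    return records


def _parse_dssp_mmcif(path, chain_id):
    import gemmi.cif

    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()
    cat = block.find(
        "_dssp_struct_summary.",
        ["label_asym_id", "secondary_structure", "accessibility"],
    )
    if len(cat) == 0:
        raise ValueError("malformed DSSP mmCIF: no _dssp_struct_summary loop")
    records = []
    for row in cat:
        if chain_id is not None and row[0] != chain_id:
            continue
        ss = row[1].strip("'\"")
        ss = "-" if ss in (".", "?", "") else ss
        ss = ss if ss in DSSP_STATES else UNKNOWN
        try:
            asa = float(row[2])
        except ValueError:
            asa = 0.0
        records.append(DsspRecord(ss_state=ss, asa=max(asa, 0.0)))
    return records


def parse_dssp(path, chain_id=None, n_residues=None):
    """Parse DSSP output (classic text or mmCIF dialect) for one chain.

    Records are aligned positionally to the chain's residues; chain-break
    markers are skipped.  If the chain has more residues than the DSSP file
    provides, trailing residues get ``UNKNOWN`` state with zero ASA.
    """
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith("data_") or "_dssp_struct_summary" in text:
        records = _parse_dssp_mmcif(path, chain_id)
    else:
        records = _parse_dssp_classic(text.splitlines(), chain_id)
    if n_residues is not None:
        records = records[:n_residues]
        while len(records) < n_residues:
            records.append(DsspRecord(ss_state=UNKNOWN, asa=0.0))
    return records


def encode_ss(ss_state: str) -> np.ndarray:
    """9-dim one-hot; the ninth position encodes unknown/undefined."""
    vec = np.zeros(9)
    if ss_state in DSSP_STATES:
        vec[DSSP_STATES.index(ss_state)] = 1.0
    else:
        vec[8] = 1.0
    return vec


def compute_rasa(asa: float, aa_type: str) -> float:
    """Relative solvent accessibility: ASA / max-ASA of the residue type.

    Capped at 1.0; nonstandard residues ('X') use the table mean.
    """
    if asa < 0:
        raise ValueError("ASA must be non-negative")
    max_asa = MAX_ASA.get(aa_type, _MEAN_MAX_ASA)
    return min(asa / max_asa, 1.0)


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle (radians) defined by four points.

    Follows the standard convention (anti/trans = ±π): looking along
    p1→p2, positive angles are clockwise.
    """
    b0 = np.asarray(p0, dtype=float) - np.asarray(p1, dtype=float)
    b1 = np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float)
    b2 = np.asarray(p3, dtype=float) - np.asarray(p2, dtype=float)
    b1 /= np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    return math.atan2(np.dot(np.cross(b1, v), w), np.dot(v, w))


def backbone_torsions(residues):
    """Backbone (φ, ψ) per residue in radians; ``None`` where undefined.

    φ_i needs C(i−1), N(i), Cα(i), C(i); ψ_i needs N(i), Cα(i), C(i),
    N(i+1).  Chain termini and residues with missing backbone atoms get
    ``None`` for the affected angle.
    """
    def bb(res):
        return {name: res.atom(name) for name in ("N", "CA", "C")}

    atoms = [bb(r) for r in residues]
    n = len(residues)
    out = []
    for i in range(n):
        phi = psi = None
        a = atoms[i]
        if i > 0:
            prev_c = atoms[i - 1]["C"]
            if all(x is not None for x in (prev_c, a["N"], a["CA"], a["C"])):
                phi = dihedral(prev_c.coords, a["N"].coords,
                               a["CA"].coords, a["C"].coords)
        if i < n - 1:
            next_n = atoms[i + 1]["N"]
            if all(x is not None for x in (a["N"], a["CA"], a["C"], next_n)):
                psi = dihedral(a["N"].coords, a["CA"].coords,
                               a["C"].coords, next_n.coords)
        out.append((phi, psi))
    return out


def torsion_features(phi, psi) -> np.ndarray:
    """[sin φ, cos φ, sin ψ, cos ψ]; an undefined angle maps to (0, 0).

    The (0, 0) pair is off the unit circle, so "undefined" is
    distinguishable from every real angle.
    """
    def pair(angle):
        if angle is None:
            return (0.0, 0.0)
        return (math.sin(angle), math.cos(angle))

    return np.array([*pair(phi), *pair(psi)])


def label_epitopes(antigen: Structure, chain_id: str,
                   antibody_atoms: np.ndarray, cutoff: float = 4.0
                   ) -> np.ndarray:
    """Binary epitope labels: 1 iff any heavy atom of the residue lies
    within ``cutoff`` Å (inclusive) of any antibody atom."""
    residues = antigen.chain(chain_id)
    antibody_atoms = np.asarray(antibody_atoms, dtype=float).reshape(-1, 3)
    labels = np.zeros(len(residues), dtype=int)
    if antibody_atoms.shape[0] == 0:
        warnings.warn("empty antibody atom set: all labels are 0")
        return labels
    tree = cKDTree(antibody_atoms)
    for i, res in enumerate(residues):
        pts = np.array([a.coords for a in res.heavy_atoms])
        if pts.size and tree.query(pts)[0].min() <= cutoff:
            labels[i] = 1
    return labels


def surface_mask(rasa: np.ndarray, threshold: float = 0.15) -> np.ndarray:
    """Surface residues: rASA ≥ threshold (boundary inclusive)."""
    return np.asarray(rasa, dtype=float) >= threshold


def build_feature_table(residues, dssp_records, labels=None,
                        surface_threshold: float = 0.15) -> pd.DataFrame:
    """Assemble the per-residue feature table for one chain.

    Columns: chain, index, author_number, aa, ss one-hot (9), rasa,
    torsion features (4), surface, label.  The 14-dim structural vector is
    the concatenation [ss_onehot | rasa | torsions] in that order.
    """
    n = len(residues)
    if len(dssp_records) < n:
        dssp_records = list(dssp_records) + [
            DsspRecord(UNKNOWN, 0.0) for _ in range(n - len(dssp_records))
        ]
    torsions = backbone_torsions(residues)
    rows = []
    for i, res in enumerate(residues):
        rec = dssp_records[i]
        ss = encode_ss(rec.ss_state)
        rasa = compute_rasa(rec.asa, res.aa_type)
        tf = torsion_features(*torsions[i])
        row = {
            "chain": res.chain_id,
            "index": res.index,
            "author_number": res.author_number,
            "aa": res.aa_type,
        }
        for j in range(9):
            row[f"ss{j}"] = ss[j]
        row["rasa"] = rasa
        for name, val in zip(("sin_phi", "cos_phi", "sin_psi", "cos_psi"), tf):
            row[name] = val
        row["surface"] = bool(rasa >= surface_threshold)
        row["label"] = int(labels[i]) if labels is not None else 0
        rows.append(row)
    return pd.DataFrame(rows)


_FEATURE_COLS = [f"ss{j}" for j in range(9)] + [
    "rasa", "sin_phi", "cos_phi", "sin_psi", "cos_psi"]


def dssp_feature_matrix(table: pd.DataFrame) -> np.ndarray:
    """Extract the N×13 structural feature matrix from a feature table."""
    return table[_FEATURE_COLS].to_numpy(dtype=float)


def feature_table_to_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
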