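"""Synthetic inputs for exercising the full pipeline without downloads.

The generators emulate the shapes and statistics the pipeline consumes in
production: torsion-parameterized backbones (so torsion recovery is exact
by construction), toy antigen–antibody contact geometries for the 4 Å
labeling rule, class-conditional Gaussian embeddings with a plantable
signal of effect size δ, and spatially clustered epitope patches.
Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np

from .graph_builder import GraphParams, assemble_graph
from .model_core import ModalityBundle
from .residue_features import (
    DSSP_STATES,
    DsspRecord,
    build_feature_table,
    dssp_feature_matrix,
)
from .structure_io import Atom, Residue, Structure, ca_coordinates
from .training import ProteinSample

__all__ = [
    "FixtureSpec",
    "make_backbone",
    "make_toy_complex",
    "make_embeddings",
    "make_dataset",
    "write_fixture_dir",
    "BOND_GEOMETRY",
]

#: idealized backbone internal coordinates (lengths in Å, angles in degrees)
BOND_GEOMETRY = {
    "n_ca": 1.458,
    "ca_c": 1.525,
    "c_n": 1.329,
    "angle_n_ca_c": 111.2,
    "angle_ca_c_n": 116.2,
    "angle_c_n_ca": 121.7,
    "omega": 180.0,
}


@dataclasses.dataclass(frozen=True)
class FixtureSpec:
    n_proteins: int = 30
    min_residues: int = 40
    max_residues: int = 60
    seq_dim: int = 2560
    if_dim: int = 512
    delta: float = 2.0            # class-mean shift in pooled-SD units
    patch_radius: float = 10.0    # Å, epitope patch extent fallback
    positive_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.seq_dim < 1 or self.if_dim < 1:
            raise ValueError("embedding dims must be >= 1")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")


def _place_atom(a, b, c, bond: float, angle_deg: float,
                torsion_rad: float) -> np.ndarray:
    """Next atom from three predecessors by internal coordinates (NeRF)."""
    angle = math.radians(angle_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(torsion_rad),
        bond * math.sin(angle) * math.sin(torsion_rad),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def make_backbone(phi_psi, chain_id: str = "A",
                  structure_id: str = "synthetic",
                  geometry: dict = BOND_GEOMETRY) -> Structure:
    """Build an N/Cα/C backbone from a list of (φ, ψ) pairs in radians.

    Atoms are placed by sequential internal-coordinate chaining with ideal
    bond geometry and trans peptide bonds (ω = 180°), so recomputing the
    torsions from coordinates reproduces the inputs exactly.  φ of the
    first residue and ψ of the last are geometrically undefined and their
    entries ignored.
    """
    n = len(phi_psi)
    if n < 1:
        raise ValueError("need at least one residue")
    g = geometry
    coords = []  # flat list: N0, CA0, C0, N1, ...
    # seed the first residue in a canonical frame
    n0 = np.zeros(3)
    ca0 = np.array([g["n_ca"], 0.0, 0.0])
    ang = math.radians(g["angle_n_ca_c"])
    c0 = ca0 + g["ca_c"] * np.array([-math.cos(ang), math.sin(ang), 0.0])
    coords += [n0, ca0, c0]
    omega = math.radians(g["omega"])
    for i in range(1, n):
        prev_n, prev_ca, prev_c = coords[-3], coords[-2], coords[-1]
        psi_prev = phi_psi[i - 1][1]
        ni = _place_atom(prev_n, prev_ca, prev_c,
                         g["c_n"], g["angle_ca_c_n"], psi_prev)
        cai = _place_atom(prev_ca, prev_c, ni,
                          g["n_ca"], g["angle_c_n_ca"], omega)
        ci = _place_atom(prev_c, ni, cai,
                         g["ca_c"], g["angle_n_ca_c"], phi_psi[i][0])
        coords += [ni, cai, ci]

    residues = []
    for i in range(n):
        atoms = [
            Atom("N", "N", coords[3 * i]),
            Atom("CA", "C", coords[3 * i + 1]),
            Atom("C", "C", coords[3 * i + 2]),
        ]
        residues.append(
            Residue(chain_id=chain_id, author_number=i + 1,
                    insertion_code="", index=i, aa_type="A", atoms=atoms)
        )
    return Structure(id=structure_id, chains=[(chain_id, residues)])


def _random_torsions(n: int, rng: np.random.Generator):
    """Torsion draws biased toward the broad allowed region: a compact,
    non-self-intersecting coil."""
    phi = rng.uniform(math.radians(-150), math.radians(-60), size=n)
    psi = rng.uniform(math.radians(-60), math.radians(160), size=n)
    return list(zip(phi, psi))


def make_toy_complex(n_antigen: int, contact_indices, gap: float = 3.5,
                     seed: int = 0, far_min: float = 4.5):
    """An antigen chain plus antibody pseudo-atoms at controlled distances.

    Each listed antigen residue gets one antibody atom at exactly ``gap`` Å
    from its nearest heavy atom; every antibody atom is > ``far_min`` Å
    from all other antigen residues' atoms (directions are searched and
    verified by brute force).  The antigen is an extended strand: on a
    connected backbone adjacent residues sit ~3.8 Å apart, which caps the
    achievable clearance near 5 Å — ``far_min`` must stay below that and
    above the labeling cutoff it guards.
    """
    rng = np.random.default_rng(seed)
    strand = [(math.radians(-135), math.radians(135))] * n_antigen
    antigen = make_backbone(strand, structure_id="toy_antigen")
    residues = antigen.chain("A")
    all_atoms = np.array(
        [a.coords for r in residues for a in r.heavy_atoms]
    )
    owner = np.concatenate(
        [[r.index] * len(r.heavy_atoms) for r in residues]
    )
    antibody = []
    for ci in contact_indices:
        target = residues[ci].atom("CA").coords
        placed = False
        for _ in range(500):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            pos = target + gap * u
            d = np.linalg.norm(all_atoms - pos, axis=1)
            if abs(d[owner == ci].min() - gap) > 1e-9:
                continue  # another atom of the residue is closer
            if d[owner != ci].min() > max(far_min, gap):
                antibody.append(pos)
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place an antibody atom near residue {ci}"
            )
    return antigen, np.array(antibody).reshape(-1, 3)


def signal_directions(dims: dict, seed: int = 0) -> dict:
    """One fixed unit signal direction per modality, drawn from ``seed``."""
    rng = np.random.default_rng(seed)
    out = {}
    for name, d in dims.items():
        u = rng.normal(size=d)
        out[name] = u / np.linalg.norm(u)
    return out


def make_embeddings(labels, dims, delta: float, seed: int = 0,
                    directions: dict | None = None) -> dict:
    """Class-conditional Gaussian embeddings with a planted signal.

    Rows are unit-variance Gaussian; the positive-class mean is shifted by
    ``delta`` along a fixed random unit direction per modality, so δ = 0
    means no class signal.  ``dims`` maps modality name → dimension.
    Pass shared ``directions`` to plant the same signal across proteins
    (what a dataset needs for the signal to generalize).
    """
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    if directions is None:
        directions = signal_directions(dims, seed)
    out = {}
    for name, d in dims.items():
        X = rng.normal(size=(labels.size, d))
        X[labels == 1] += delta * directions[name]
        out[name] = X
    return out


def _patch_labels(ca: np.ndarray, target_fraction: float,
                  patch_radius: float, rng: np.random.Generator):
    """Spatially contiguous positives: residues nearest to a random center.

    The patch radius adapts to hit the target positive fraction; the
    ``patch_radius`` argument is used as-is when no target is given.
    """
    n = ca.shape[0]
    center = int(rng.integers(0, n))
    d = np.linalg.norm(ca - ca[center], axis=1)
    if target_fraction is None:
        radius = patch_radius
    else:
        n_pos = max(1, int(round(target_fraction * n)))
        radius = np.sort(d)[n_pos - 1]
    labels = (d <= radius).astype(int)
    return labels, center, float(radius)


def _synthetic_dssp(n: int, rng: np.random.Generator):
    states = [DSSP_STATES[i] for i in rng.integers(0, 8, size=n)]
    asa = rng.uniform(0.0, 250.0, size=n)
    return [DsspRecord(s, float(a)) for s, a in zip(states, asa)]


def make_dataset(spec: FixtureSpec,
                 graph_params: GraphParams = GraphParams()):
    """Generate a list of :class:`ProteinSample` plus per-protein metadata.

    Each protein is a random coil backbone; positives form one spatial
    patch; embeddings carry the planted class signal of effect size δ; the
    14-dim structural descriptor mixes synthetic DSSP records with true
    geometric torsions.
    """
    rng = np.random.default_rng(spec.seed)
    dims = {"seq": spec.seq_dim, "if": spec.if_dim}
    directions = signal_directions(dims, seed=spec.seed)
    samples, meta = [], []
    for p in range(spec.n_proteins):
        n = int(rng.integers(spec.min_residues, spec.max_residues + 1))
        structure = make_backbone(
            _random_torsions(n, rng), structure_id=f"synth{p:03d}"
        )
        ca, _, _ = ca_coordinates(structure, "A")
        labels, center, radius = _patch_labels(
            ca, spec.positive_fraction, spec.patch_radius, rng
        )
        emb = make_embeddings(
            labels, dims, spec.delta,
            seed=int(rng.integers(0, 2**31 - 1)), directions=directions,
        )
        table = build_feature_table(
            structure.chain("A"), _synthetic_dssp(n, rng), labels
        )
        bundle = ModalityBundle(
            seq_emb=emb["seq"], if_emb=emb["if"], dssp_feats=dssp_feature_matrix(table)
        )
        graph = assemble_graph(ca, graph_params)
        samples.append(
            ProteinSample(protein_id=structure.id, bundle=bundle,
                          graph=graph, labels=labels)
        )
        meta.append({
            "protein_id": structure.id,
            "n_residues": n,
            "patch_center": center,
            "patch_radius": radius,
            "n_positive": int(labels.sum()),
            "structure": structure,
        })
    return samples, meta


def write_fixture_dir(spec: FixtureSpec, out_dir,
                      graph_params: GraphParams = GraphParams()) -> Path:
    """Materialize a fixture bundle: PDB files, embedding TSVs, labels,
    and a manifest JSON.  Returns the directory path."""
    from .structure_io import write_structure_pdb

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples, meta = make_dataset(spec, graph_params)
    with open(out_dir / "labels.tsv", "w") as lab:
        lab.write("protein_id\tindex\tlabel\n")
        for s, m in zip(samples, meta):
            write_structure_pdb(m["structure"],
                                out_dir / f"{s.protein_id}.pdb")
            np.savetxt(out_dir / f"{s.protein_id}.seq.tsv",
                       s.bundle.seq_emb, delimiter="\t")
            np.savetxt(out_dir / f"{s.protein_id}.if.tsv",
                       s.bundle.if_emb, delimiter="\t")
            np.savetxt(out_dir / f"{s.protein_id}.dssp.tsv",
                       s.bundle.dssp_feats, delimiter="\t")
            for i, y in enumerate(s.labels):
                lab.write(f"{s.protein_id}\t{i}\t{int(y)}\n")
    manifest_meta = [{k: v for k, v in m.items() if k != "structure"}
                     for m in meta]
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump({"spec": dataclasses.asdict(spec),
                   "proteins": manifest_meta}, fh, indent=2)
        fh.write("\n")
    return out_dir
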