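"""Structure-side mapping: CA models, MSA-column -> residue correspondence,
residue neighbor networks per conformation, Kabsch superposition RMSD and
classical MDS conformer maps.

The transporter fold alternates between outward-open and inward-open
conformations; sites of interest (rate-shifted alignment columns) are mapped
onto CA coordinates of each conformation, joined into contact networks at a
CA-CA distance cutoff, and the rearrangement of those networks between
conformations is reported per site. Whole models are compared by minimal
RMSD after optimal rigid superposition, and an all-against-all RMSD matrix
is embedded in 2D by classical (Torgerson) multidimensional scaling with
each model labelled by its nearest reference conformer in the full distance
matrix (not the 2D projection).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence as TypingSequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform
from scipy.spatial.transform import Rotation

from Bio.PDB import PDBParser

try:  # one-letter lookup moved between Biopython versions
    from Bio.PDB.Polypeptide import protein_letters_3to1
except ImportError:  # pragma: no cover
    from Bio.Data.PDBData import protein_letters_3to1

from .constants import GAP

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}

DEFAULT_CONTACT_CUTOFF = 10.0  # Angstrom, CA-CA


@dataclass(frozen=True)
class StructureResidue:
    number: int
    aa: str
    xyz: tuple[float, float, float]
    icode: str = ""

    @property
    def label(self) -> str:
        return f"{self.number}{self.icode}"


@dataclass
class StructureModel:
    """Ordered CA trace of one conformation."""

    model_id: str
    residues: list[StructureResidue]

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"model {self.model_id!r} has no residues")
        keys = [(r.number, r.icode) for r in self.residues]
        if any(b <= a for a, b in zip(keys, keys[1:])):
            raise ValueError(f"model {self.model_id!r}: residue numbers not increasing")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"model {self.model_id!r}: non-finite coordinates")

    @property
    def coords(self) -> np.ndarray:
        return np.array([r.xyz for r in self.residues], dtype=float)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)


def read_pdb_ca(
    path: str | Path, model_id: str | None = None, chain: str | None = None
) -> StructureModel:
    """Read CA coordinates from a PDB file.

    Takes the first MODEL and, by default, its first chain; only ATOM records
    with atom name CA and altloc ' ' or 'A' are used. Insertion codes are
    kept alongside residue numbers. Raises ValueError when no CA atoms are
    found (e.g. a HETATM-only file).
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    models = list(structure)
    if not models:
        raise ValueError(f"{path}: no models in PDB file")
    first = models[0]
    chains = list(first)
    if chain is not None:
        chains = [c for c in chains if c.id == chain]
        if not chains:
            raise ValueError(f"{path}: chain {chain!r} not found")
    elif not chains:
        raise ValueError(f"{path}: no chains in first model")
    target = chains[0]
    residues: list[StructureResidue] = []
    for res in target:
        hetflag, resseq, icode = res.id
        if hetflag.strip():
            continue  # skip HETATM / waters
        if "CA" not in res:
            continue
        atom = res["CA"]
        if atom.is_disordered():
            try:
                atom = atom.disordered_get("A")
            except KeyError:
                continue
        aa = protein_letters_3to1.get(res.get_resname().upper(), "X")
        x, y, z = atom.get_coord()
        residues.append(
            StructureResidue(
                number=int(resseq),
                aa=aa,
                xyz=(float(x), float(y), float(z)),
                icode=icode.strip(),
            )
        )
    if not residues:
        raise ValueError(f"{path}: no CA atoms found")
    return StructureModel(model_id=model_id or path.stem, residues=residues)


def write_pdb_ca(model: StructureModel, path: str | Path, chain: str = "A") -> None:
    """Write a CA-only model as fixed-column PDB ATOM records."""
    with Path(path).open("w") as fh:
        for serial, res in enumerate(model.residues, start=1):
            x, y, z = res.xyz
            resname = ONE_TO_THREE.get(res.aa, "UNK")
            fh.write(
                f"ATOM  {serial:5d}  CA  {resname:>3s} {chain}"
                f"{res.number:4d}{res.icode or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {'C':>2s}\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Column <-> residue mapping


@dataclass
class ColumnResidueMap:
    """Partial, injective map from 1-based MSA columns to residue indices."""

    mapping: dict[int, int]
    mismatches: list[int] = field(default_factory=list)

    def residue_index(self, column: int) -> int | None:
        return self.mapping.get(column)


def map_columns(
    gapped_query: str, gapped_structure_seq: str, model: StructureModel
) -> ColumnResidueMap:
    """Derive the column->residue map from a gapped query/structure alignment.

    A column maps to a residue index where both rows are non-gap; columns
    where the two letters disagree are still mapped but reported in
    ``mismatches``.
    """
    if len(gapped_query) != len(gapped_structure_seq):
        raise ValueError("gapped rows must have equal length")
    n_struct = len(gapped_structure_seq.replace(GAP, ""))
    if n_struct != len(model):
        raise ValueError(
            f"structure row has {n_struct} residues but model has {len(model)}"
        )
    mapping: dict[int, int] = {}
    mismatches: list[int] = []
    res_idx = -1
    for col0, (q, t) in enumerate(zip(gapped_query, gapped_structure_seq)):
        if t != GAP:
            res_idx += 1
        if q == GAP or t == GAP:
            continue
        col = col0 + 1
        mapping[col] = res_idx
        if q != t:
            mismatches.append(col)
    return ColumnResidueMap(mapping=mapping, mismatches=mismatches)


# ---------------------------------------------------------------------------
# Neighbor networks


@dataclass
class ResidueNetwork:
    """Contact graph over MSA columns in one conformation."""

    graph: nx.Graph
    conformation: str
    cutoff: float
    unmapped: tuple[int, ...] = ()

    @property
    def nodes(self) -> list[int]:
        return sorted(self.graph.nodes)

    def neighbors(self, column: int) -> set[int]:
        return set(self.graph.neighbors(column))


def neighbor_network(
    model: StructureModel,
    colmap: ColumnResidueMap,
    sites: Iterable[int],
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    conformation: str = "",
) -> ResidueNetwork:
    """Build the CA-CA contact network over mapped sites.

    Edge iff the CA distance between two mapped sites is <= cutoff (no
    self-edges). Sites without a residue mapping are excluded and listed in
    ``unmapped``.
    """
    sites = sorted(set(sites))
    mapped = [c for c in sites if colmap.residue_index(c) is not None]
    unmapped = tuple(c for c in sites if colmap.residue_index(c) is None)
    graph = nx.Graph()
    graph.add_nodes_from(mapped)
    coords = model.coords
    pts = np.array([coords[colmap.mapping[c]] for c in mapped])
    if len(mapped) >= 2:
        dists = squareform(pdist(pts))
        for i in range(len(mapped)):
            for j in range(i + 1, len(mapped)):
                if dists[i, j] <= cutoff:
                    graph.add_edge(mapped[i], mapped[j], distance=float(dists[i, j]))
    return ResidueNetwork(
        graph=graph, conformation=conformation, cutoff=cutoff, unmapped=unmapped
    )


@dataclass(frozen=True)
class SiteRearrangement:
    column: int
    neighbors_a: frozenset[int]
    neighbors_b: frozenset[int]
    jaccard: float
    rearranged: bool


def compare_conformations(
    net_a: ResidueNetwork, net_b: ResidueNetwork
) -> list[SiteRearrangement]:
    """Per-site neighbor-set comparison between two conformations.

    For each site present in both networks, reports the neighbor sets in A
    and B and their Jaccard similarity (1.0 when both sets are empty); sites
    with Jaccard < 1 are flagged as rearranged. The report is symmetric in
    (A, B) up to swapping the neighbor-set fields.
    """
    common = sorted(set(net_a.graph.nodes) & set(net_b.graph.nodes))
    report: list[SiteRearrangement] = []
    for col in common:
        na = frozenset(net_a.neighbors(col))
        nb = frozenset(net_b.neighbors(col))
        union = na | nb
        jac = 1.0 if not union else len(na & nb) / len(union)
        report.append(
            SiteRearrangement(
                column=col,
                neighbors_a=na,
                neighbors_b=nb,
                jaccard=jac,
                rearranged=jac < 1.0,
            )
        )
    return report


# ---------------------------------------------------------------------------
# Kabsch RMSD and classical MDS


def kabsch_rmsd(x: np.ndarray, y: np.ndarray) -> float:
    """Minimal RMSD between matched point sets over rotations + translation.

    Proper rotations only (no reflection). Both inputs are (n, 3) with
    n >= 3 matched points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("inputs must be matched (n, 3) arrays")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 points")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    rot, _ = Rotation.align_vectors(xc, yc)
    # recompute the RMSD from residuals: align_vectors' reported rssd loses
    # ~sqrt(eps) precision to cancellation when the sets nearly coincide
    diff = xc - rot.apply(yc)
    return float(np.sqrt((diff**2).sum() / x.shape[0]))


def classical_mds(
    dist: np.ndarray, k: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Classical (Torgerson) MDS of a symmetric distance matrix.

    Double-centers the squared distances, eigendecomposes, and returns the
    embedding on the top-``k`` non-negative eigenvalues (axes with
    non-positive eigenvalues contribute zero coordinates) together with the
    full eigenvalue spectrum in descending order. Exact for matrices that
    are Euclidean of rank <= k.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dist**2) @ j
    eigvals, eigvecs = eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    coords = np.zeros((n, k))
    for axis in range(min(k, n)):
        lam = eigvals[axis]
        if lam > 0:
            coords[:, axis] = eigvecs[:, axis] * np.sqrt(lam)
    return coords, eigvals


@dataclass
class ConformerEmbedding:
    """2D conformer map with nearest-reference labels and MDS eigenvalues."""

    ids: list[str]
    coords: np.ndarray
    eigenvalues: np.ndarray
    nearest_reference: dict[str, tuple[str, float]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": self.ids,
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "nearest_ref": [self.nearest_reference[i][0] for i in self.ids],
                "ref_distance": [self.nearest_reference[i][1] for i in self.ids],
            }
        )


def mds_map(
    models: Mapping[str, StructureModel],
    references: TypingSequence[str],
) -> ConformerEmbedding:
    """All-against-all Kabsch RMSD matrix embedded by classical MDS.

    Every model is labelled by its nearest reference model in the *full*
    RMSD matrix, not the 2D projection, to avoid projection artifacts.
    Requires >= 3 models of equal residue count; references must be among
    the models.
    """
    ids = list(models)
    if len(ids) < 3:
        raise ValueError("mds_map needs at least 3 models")
    missing = [r for r in references if r not in models]
    if missing:
        raise ValueError(f"references not among models: {missing}")
    sizes = {len(models[i]) for i in ids}
    if len(sizes) != 1:
        raise ValueError(f"models have unequal residue counts: {sorted(sizes)}")
    n = len(ids)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = kabsch_rmsd(models[ids[i]].coords, models[ids[j]].coords)
            dist[i, j] = dist[j, i] = d
    coords, eigvals = classical_mds(dist, k=2)
    ref_idx = [ids.index(r) for r in references]
    nearest: dict[str, tuple[str, float]] = {}
    for i, mid in enumerate(ids):
        dists_to_refs = [(dist[i, j], ids[j]) for j in ref_idx]
        best_d, best_ref = min(dists_to_refs)
        nearest[mid] = (best_ref, float(best_d))
    return ConformerEmbedding(
        ids=ids, coords=coords, eigenvalues=eigvals, nearest_reference=nearest
    )
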