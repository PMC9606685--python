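"""Synthetic data generators with planted ground truth.

Every downstream stage is testable without downloads: grouped MSAs with
planted conserved / type I / type II columns, scannable databases embedding
group-specific segment motifs, hydrophobic 11- vs 12-TMS architectures, and
paired-conformation helical CA traces with planted spatial clusters. All
generators are pure functions of their spec + seed.

Background columns share one consensus residue across groups (no
between-group signal), so they are exact null columns for the permutation
test. Planted columns never receive gaps and plant their modal residue by
exact count (ceil(conservation * n) copies), so the advertised modal
frequencies hold by construction, not just in expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence as TypingSequence

import numpy as np
from scipy.optimize import brentq

from .constants import AMINO_ACIDS, GAP, grantham
from .profiler import PrositePattern, PositionSpec, ResidueClass, Wildcard
from .seqcore import GroupedAlignment, Sequence
from .structmap import ColumnResidueMap, StructureModel, StructureResidue

HYDROPHOBIC = "LIVFAM"
POLAR = "STNQDEKRGP"

SITE_KINDS = ("conserved_since_stage", "typeI", "typeII", "typeI_II")


# ---------------------------------------------------------------------------
# Specs and truth


@dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one planted alignment column.

    * ``typeII`` / ``typeI_II``: ``modal`` holds the modal residue of each
      contrasted group.
    * ``typeI``: ``modal`` holds the conserved group's residue and
      ``variable`` the residue set the other group varies over (>= 4
      residues, uniform).
    * ``conserved_since_stage``: ``residue`` is fixed from group ``stage``
      onward; earlier groups are uniform noise.
    """

    column: int
    kind: str
    modal: tuple[tuple[str, str], ...] = ()       # (group, residue) pairs
    variable: tuple[tuple[str, str], ...] = ()    # (group, residue-set) pairs
    stage: str | None = None
    residue: str | None = None
    conservation: float = 0.95

    def modal_of(self, group: str) -> str | None:
        return dict(self.modal).get(group)

    def variable_of(self, group: str) -> str | None:
        return dict(self.variable).get(group)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a planted grouped MSA."""

    group_order: tuple[str, ...]
    sizes: tuple[tuple[str, int], ...]
    length: int
    planted_sites: tuple[PlantedSite, ...] = ()
    background_identity: float = 0.35
    gap_rate: float = 0.02
    seed: int = 0

    def size_of(self, group: str) -> int:
        return dict(self.sizes)[group]

    def validate(self) -> None:
        if len(self.group_order) < 1:
            raise ValueError("need at least one group")
        sizes = dict(self.sizes)
        if set(sizes) != set(self.group_order):
            raise ValueError("sizes must cover exactly the groups in group_order")
        if any(n < 2 for n in sizes.values()):
            raise ValueError("each group needs >= 2 sequences")
        if not 0.0 <= self.gap_rate < 1.0:
            raise ValueError("gap_rate must be in [0, 1)")
        if not 0.05 <= self.background_identity <= 1.0:
            raise ValueError("background_identity must be in [0.05, 1]")
        cols = [s.column for s in self.planted_sites]
        if len(set(cols)) != len(cols):
            raise ValueError("planted columns must be distinct")
        if cols and (min(cols) < 1 or max(cols) > self.length):
            raise ValueError("planted columns must lie within 1..length")
        for site in self.planted_sites:
            self._validate_site(site)

    def _validate_site(self, site: PlantedSite) -> None:
        where = f"planted column {site.column}"
        if site.kind not in SITE_KINDS:
            raise ValueError(f"{where}: unknown kind {site.kind!r}")
        if not 0.0 < site.conservation <= 1.0:
            raise ValueError(f"{where}: conservation must be in (0, 1]")
        if site.kind == "conserved_since_stage":
            if site.stage not in self.group_order:
                raise ValueError(f"{where}: stage {site.stage!r} not in group_order")
            if site.residue not in AMINO_ACIDS:
                raise ValueError(f"{where}: invalid fixed residue {site.residue!r}")
        elif site.kind in ("typeII", "typeI_II"):
            modal = dict(site.modal)
            if len(modal) != 2:
                raise ValueError(f"{where}: {site.kind} needs modal residues for 2 groups")
            (g1, r1), (g2, r2) = site.modal
            if r1 == r2:
                raise ValueError(f"{where}: contrasted modal residues are identical")
            d = grantham(r1, r2)
            if site.kind == "typeII" and d < 60:
                raise ValueError(
                    f"{where}: typeII modal pair {r1}/{r2} has Grantham {d} < 60"
                )
            if site.kind == "typeI_II" and d >= 60:
                raise ValueError(
                    f"{where}: typeI_II modal pair {r1}/{r2} has Grantham {d} >= 60"
                )
        elif site.kind == "typeI":
            if len(site.modal) != 1 or len(site.variable) != 1:
                raise ValueError(
                    f"{where}: typeI needs one conserved and one variable group"
                )
            (_, varset), = site.variable
            if len(set(varset)) < 4:
                raise ValueError(f"{where}: typeI variable set needs >= 4 residues")


@dataclass
class PlantedTruth:
    """Ground truth emitted alongside synthetic data."""

    sites: dict[int, PlantedSite] = field(default_factory=dict)
    groups: dict[str, str] = field(default_factory=dict)        # seq id -> group
    structure_clusters: dict[int, int] = field(default_factory=dict)  # column -> cluster
    tms_counts: dict[str, int] = field(default_factory=dict)    # seq id -> TMS count
    scan_members: dict[str, str] = field(default_factory=dict)  # member id -> group


# ---------------------------------------------------------------------------
# Grouped MSA generator


def _consensus_weight(identity: float) -> float:
    """Probability of copying the column consensus so that the expected
    within-group pairwise identity matches ``identity``."""
    n_aa = len(AMINO_ACIDS)

    def f(rho: float) -> float:
        q = (1.0 - rho) / n_aa
        return (rho + q) ** 2 + (n_aa - 1) * q**2 - identity

    if identity >= 1.0:
        return 1.0
    return float(brentq(f, 0.0, 1.0))


def _plant_column(
    rng: np.random.Generator, n: int, residue: str, conservation: float
) -> np.ndarray:
    """Exact-count planting: ceil(conservation*n) modal copies, rest random others."""
    m = math.ceil(conservation * n)
    others = [a for a in AMINO_ACIDS if a != residue]
    col = np.array(
        [residue] * m + list(rng.choice(list(others), size=n - m)), dtype="<U1"
    )
    rng.shuffle(col)
    return col


def generate_msa(spec: SyntheticSpec) -> tuple[GroupedAlignment, PlantedTruth]:
    """Generate a grouped alignment with planted columns; deterministic in seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    aa = np.array(list(AMINO_ACIDS), dtype="<U1")
    rho = _consensus_weight(spec.background_identity)
    planted = {s.column: s for s in spec.planted_sites}

    matrices: dict[str, np.ndarray] = {
        g: np.empty((spec.size_of(g), spec.length), dtype="<U1")
        for g in spec.group_order
    }

    for col in range(1, spec.length + 1):
        site = planted.get(col)
        if site is None:
            consensus = rng.choice(aa)
            for g in spec.group_order:
                n = spec.size_of(g)
                copy = rng.random(n) < rho
                random_fill = rng.choice(aa, size=n)
                matrices[g][:, col - 1] = np.where(copy, consensus, random_fill)
            continue
        for g in spec.group_order:
            n = spec.size_of(g)
            if site.kind == "conserved_since_stage":
                stage_idx = spec.group_order.index(site.stage)  # type: ignore[arg-type]
                if spec.group_order.index(g) >= stage_idx:
                    column = _plant_column(rng, n, site.residue, site.conservation)  # type: ignore[arg-type]
                else:
                    column = rng.choice(aa, size=n)
            elif site.kind in ("typeII", "typeI_II"):
                r = site.modal_of(g)
                if r is not None:
                    column = _plant_column(rng, n, r, site.conservation)
                else:
                    column = rng.choice(aa, size=n)
            else:  # typeI
                r = site.modal_of(g)
                varset = site.variable_of(g)
                if r is not None:
                    column = _plant_column(rng, n, r, site.conservation)
                elif varset is not None:
                    column = rng.choice(np.array(list(varset), dtype="<U1"), size=n)
                else:
                    column = rng.choice(aa, size=n)
            matrices[g][:, col - 1] = column

    # gaps: i.i.d. per cell, never inside planted columns
    if spec.gap_rate > 0:
        planted_cols = np.array(sorted(planted), dtype=int) - 1
        for g in spec.group_order:
            mask = rng.random(matrices[g].shape) < spec.gap_rate
            if planted_cols.size:
                mask[:, planted_cols] = False
            matrices[g][mask] = GAP

    sequences: list[Sequence] = []
    labels: dict[str, str] = {}
    for g in spec.group_order:
        for i in range(spec.size_of(g)):
            sid = f"{g}_{i:03d}"
            sequences.append(Sequence(id=sid, residues="".join(matrices[g][i])))
            labels[sid] = g
    aln = GroupedAlignment(sequences, labels, list(spec.group_order))
    truth = PlantedTruth(sites=planted, groups=labels)
    return aln, truth


# ---------------------------------------------------------------------------
# Canonical study specs


def default_two_group_spec(
    seed: int,
    n_per_group: int = 20,
    n_type_ii: int = 10,
    n_type_i: int = 10,
    n_null: int = 80,
    gap_rate: float = 0.02,
) -> SyntheticSpec:
    """Two contrasted groups with planted type I and type II columns.

    These are the default recovery-study conditions: 2 groups x 20
    sequences, 10 type II columns (modal residues with Grantham >= 60,
    planted at modal frequency 0.95), 10 type I columns (one side conserved,
    the other uniform over 5 residues disjoint from the conserved one) and
    80 shared-consensus null columns.
    """
    rng = np.random.default_rng(seed)
    length = n_type_ii + n_type_i + n_null
    groups = ("g1", "g2")
    columns = rng.permutation(np.arange(1, length + 1))
    sites: list[PlantedSite] = []
    aa = list(AMINO_ACIDS)
    idx = 0
    for _ in range(n_type_ii):
        while True:
            r1, r2 = rng.choice(aa, size=2, replace=False)
            if grantham(str(r1), str(r2)) >= 60:
                break
        sites.append(
            PlantedSite(
                column=int(columns[idx]),
                kind="typeII",
                modal=(("g1", str(r1)), ("g2", str(r2))),
            )
        )
        idx += 1
    for _ in range(n_type_i):
        conserved_group = str(rng.choice(groups))
        other = "g2" if conserved_group == "g1" else "g1"
        r = str(rng.choice(aa))
        varset = "".join(
            sorted(rng.choice([a for a in aa if a != r], size=5, replace=False))
        )
        sites.append(
            PlantedSite(
                column=int(columns[idx]),
                kind="typeI",
                modal=((conserved_group, r),),
                variable=((other, varset),),
            )
        )
        idx += 1
    return SyntheticSpec(
        group_order=groups,
        sizes=tuple((g, n_per_group) for g in groups),
        length=length,
        planted_sites=tuple(sites),
        gap_rate=gap_rate,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def default_succession_spec(
    seed: int,
    n_groups: int = 5,
    n_per_group: int = 12,
    n_per_stage: int = 3,
    length: int = 60,
    gap_rate: float = 0.05,
) -> SyntheticSpec:
    """Ordered succession with columns fixed at each stage.

    Five ordered groups (outgroup first) and ``n_per_stage`` columns planted
    as conserved-from-stage-s-onward for every stage s, uniform noise before.
    """
    rng = np.random.default_rng(seed)
    groups = tuple(f"s{i}" for i in range(n_groups))
    n_planted = n_groups * n_per_stage
    if n_planted > length:
        raise ValueError("length too small for the planted sites")
    columns = rng.permutation(np.arange(1, length + 1))[:n_planted]
    sites: list[PlantedSite] = []
    aa = list(AMINO_ACIDS)
    idx = 0
    for stage in groups:
        for _ in range(n_per_stage):
            sites.append(
                PlantedSite(
                    column=int(columns[idx]),
                    kind="conserved_since_stage",
                    stage=stage,
                    residue=str(rng.choice(aa)),
                )
            )
            idx += 1
    return SyntheticSpec(
        group_order=groups,
        sizes=tuple((g, n_per_group) for g in groups),
        length=length,
        planted_sites=tuple(sites),
        gap_rate=gap_rate,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


# ---------------------------------------------------------------------------
# Scan database generator


@dataclass(frozen=True)
class GroupScanModel:
    """Per-group segment motifs: allowed residue sets per position, plus the
    (min, max) linker lengths between adjacent segments."""

    segments: tuple[tuple[frozenset[str], ...], ...]
    gap_ranges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("need at least one segment")
        if len(self.gap_ranges) != len(self.segments) - 1:
            raise ValueError("need one gap range per adjacent segment pair")
        for lo, hi in self.gap_ranges:
            if lo < 0 or hi < lo:
                raise ValueError(f"gap range ({lo},{hi}) has min > max")
        for seg in self.segments:
            for pos in seg:
                if not pos or not set(pos) <= set(AMINO_ACIDS):
                    raise ValueError("invalid residue set in segment model")

    def to_pattern(self) -> PrositePattern:
        specs: list[PositionSpec] = []
        for i, seg in enumerate(self.segments):
            if i > 0:
                lo, hi = self.gap_ranges[i - 1]
                specs.append(Wildcard(lo, hi))
            specs.extend(ResidueClass(pos) for pos in seg)
        return PrositePattern(tuple(specs))


def default_segment_models(
    groups: TypingSequence[str],
    seed: int,
    n_segments: int = 6,
    segment_length: int = 6,
    gap_range: tuple[int, int] = (3, 8),
) -> dict[str, GroupScanModel]:
    """Disjoint per-group segment models (groups draw from disjoint alphabets)."""
    if len(groups) > 4:
        raise ValueError("at most 4 disjoint group alphabets supported")
    rng = np.random.default_rng(seed)
    alphabet = list(AMINO_ACIDS)
    rng.shuffle(alphabet)
    slice_size = len(alphabet) // len(groups)
    models: dict[str, GroupScanModel] = {}
    for gi, g in enumerate(groups):
        letters = alphabet[gi * slice_size : (gi + 1) * slice_size]
        segments = []
        for _ in range(n_segments):
            seg = []
            for _ in range(segment_length):
                k = int(rng.integers(1, 3))  # class of 1 or 2 residues
                seg.append(frozenset(rng.choice(letters, size=k, replace=False)))
            segments.append(tuple(seg))
        models[g] = GroupScanModel(
            segments=tuple(segments),
            gap_ranges=tuple(gap_range for _ in range(n_segments - 1)),
        )
    return models


def generate_scan_db(
    n_per_group: Mapping[str, int] | int,
    segment_models: Mapping[str, GroupScanModel],
    decoy_count: int,
    seed: int,
) -> tuple[list[Sequence], PlantedTruth]:
    """Emit a labelled database of planted pattern members plus decoys.

    Each in-group sequence embeds its group's segment motifs separated by
    linkers with lengths drawn within the declared gap ranges; decoys are
    shuffled-composition copies of randomly chosen members (taxon "decoy").
    """
    rng = np.random.default_rng(seed)
    if isinstance(n_per_group, int):
        n_per_group = {g: n_per_group for g in segment_models}
    seqs: list[Sequence] = []
    truth = PlantedTruth()
    polar = list(POLAR)
    for g, model in segment_models.items():
        for i in range(n_per_group.get(g, 0)):
            parts: list[str] = [
                "".join(rng.choice(polar, size=int(rng.integers(5, 16))))
            ]
            for si, seg in enumerate(model.segments):
                if si > 0:
                    lo, hi = model.gap_ranges[si - 1]
                    linker_len = int(rng.integers(lo, hi + 1))
                    parts.append("".join(rng.choice(polar, size=linker_len)))
                parts.append(
                    "".join(str(rng.choice(sorted(pos))) for pos in seg)
                )
            parts.append("".join(rng.choice(polar, size=int(rng.integers(5, 16)))))
            sid = f"{g}_m{i:03d}"
            seqs.append(Sequence(id=sid, residues="".join(parts), taxon=g))
            truth.scan_members[sid] = g
    members = [s for s in seqs]
    for i in range(decoy_count):
        template = members[int(rng.integers(0, len(members)))]
        shuffled = np.array(list(template.residues), dtype="<U1")
        rng.shuffle(shuffled)
        seqs.append(
            Sequence(id=f"decoy_{i:03d}", residues="".join(shuffled), taxon="decoy")
        )
    return seqs, truth


# ---------------------------------------------------------------------------
# TMS architecture generator


def generate_tms_sequence(
    n_tms: int,
    seed: int,
    tms_len_range: tuple[int, int] = (19, 23),
    linker_len_range: tuple[int, int] = (10, 25),
    flank_len_range: tuple[int, int] = (10, 16),
    seq_id: str | None = None,
) -> Sequence:
    """A sequence with ``n_tms`` hydrophobic stretches separated by polar linkers.

    Stretches are 19-23 residues from {L,I,V,F,A,M}; linkers and flanks are
    >= 10 residues from the polar set. ``n_tms`` 0 yields an all-polar
    sequence.
    """
    if n_tms < 0:
        raise ValueError("n_tms must be >= 0")
    rng = np.random.default_rng(seed)
    hydro = list(HYDROPHOBIC)
    polar = list(POLAR)
    parts: list[str] = [
        "".join(rng.choice(polar, size=int(rng.integers(*_incl(flank_len_range)))))
    ]
    for k in range(n_tms):
        if k > 0:
            parts.append(
                "".join(rng.choice(polar, size=int(rng.integers(*_incl(linker_len_range)))))
            )
        parts.append(
            "".join(rng.choice(hydro, size=int(rng.integers(*_incl(tms_len_range)))))
        )
    parts.append(
        "".join(rng.choice(polar, size=int(rng.integers(*_incl(flank_len_range)))))
    )
    if n_tms == 0:
        parts = ["".join(rng.choice(polar, size=60))]
    return Sequence(
        id=seq_id or f"tms{n_tms}_seed{seed}", residues="".join(parts)
    )


def _incl(rng_pair: tuple[int, int]) -> tuple[int, int]:
    lo, hi = rng_pair
    if lo > hi:
        raise ValueError(f"range ({lo},{hi}) has min > max")
    return lo, hi + 1


# ---------------------------------------------------------------------------
# Paired-conformation structures


@dataclass(frozen=True)
class StructureSpec:
    """Layout of the paired-conformation helical CA traces.

    Helices are ideal alpha-helical traces (rise 1.5 A, 100 deg/residue,
    radius 2.3 A) along z, spaced along x. ``clusters`` are
    (helix, start_residue, size) runs of consecutive residues — consecutive
    runs of <= 7 residues sit within 10 A of each other by helix geometry.
    Conformation B applies a rigid rotation about the bundle center to the
    declared helix subset.
    """

    n_helices: int = 6
    helix_length: int = 30
    spacing: float = 24.0
    clusters: tuple[tuple[int, int, int], ...] = ((0, 5, 5), (2, 12, 5), (4, 20, 4))
    moved_helices: tuple[int, ...] = (4, 5)
    rotation_deg: float = 25.0
    jitter: float = 0.02

    def __post_init__(self) -> None:
        for h, start, size in self.clusters:
            if not 0 <= h < self.n_helices:
                raise ValueError(f"cluster helix {h} out of range")
            if size < 1 or size > 7:
                raise ValueError("cluster size must be 1..7 (10 A guarantee)")
            if start < 0 or start + size > self.helix_length:
                raise ValueError("cluster run outside helix")
        if any(not 0 <= h < self.n_helices for h in self.moved_helices):
            raise ValueError("moved helix index out of range")


def _helix_coords(
    spec: StructureSpec, rng: np.random.Generator
) -> np.ndarray:
    rise, turn, radius = 1.5, math.radians(100.0), 2.3
    coords = np.empty((spec.n_helices * spec.helix_length, 3))
    for h in range(spec.n_helices):
        x0 = h * spec.spacing
        for j in range(spec.helix_length):
            idx = h * spec.helix_length + j
            coords[idx] = (
                x0 + radius * math.cos(turn * j),
                radius * math.sin(turn * j),
                rise * j,
            )
    coords += rng.normal(scale=spec.jitter, size=coords.shape)
    return coords


def generate_structures(
    spec: StructureSpec, seed: int
) -> tuple[StructureModel, StructureModel, ColumnResidueMap, PlantedTruth]:
    """Two conformations of a helical bundle plus planted spatial clusters.

    Returns conformations A and B, a column->residue map for the planted
    sites (columns numbered 1..n_sites over the cluster runs, in order), and
    the truth assigning each column its cluster id. With an empty
    ``moved_helices`` (or zero rotation) the conformations are identical.
    """
    rng = np.random.default_rng(seed)
    coords_a = _helix_coords(spec, rng)

    coords_b = coords_a.copy()
    if spec.moved_helices and spec.rotation_deg != 0.0:
        theta = math.radians(spec.rotation_deg)
        rot = np.array(
            [
                [math.cos(theta), -math.sin(theta), 0.0],
                [math.sin(theta), math.cos(theta), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        center = coords_a.mean(axis=0)
        for h in spec.moved_helices:
            lo, hi = h * spec.helix_length, (h + 1) * spec.helix_length
            coords_b[lo:hi] = (coords_b[lo:hi] - center) @ rot.T + center

    def build(model_id: str, coords: np.ndarray) -> StructureModel:
        residues = [
            StructureResidue(number=i + 1, aa="A", xyz=tuple(coords[i]))
            for i in range(coords.shape[0])
        ]
        return StructureModel(model_id=model_id, residues=residues)

    model_a = build("confA", coords_a)
    model_b = build("confB", coords_b)

    mapping: dict[int, int] = {}
    truth = PlantedTruth()
    col = 1
    for cluster_id, (h, start, size) in enumerate(spec.clusters):
        for j in range(size):
            res_idx = h * spec.helix_length + start + j
            mapping[col] = res_idx
            truth.structure_clusters[col] = cluster_id
            col += 1
    colmap = ColumnResidueMap(mapping=mapping)
    return model_a, model_b, colmap, truth


def make_morphs(
    model_a: StructureModel, model_b: StructureModel, n: int
) -> dict[str, StructureModel]:
    """Linear coordinate interpolations between two conformations.

    Returns an ordered dict: the two endpoints (under their own ids) plus
    ``n`` intermediate models morph_01..morph_n.
    """
    if len(model_a) != len(model_b):
        raise ValueError("conformations must have equal residue counts")
    ca, cb = model_a.coords, model_b.coords
    out: dict[str, StructureModel] = {model_a.model_id: model_a}
    for i in range(1, n + 1):
        t = i / (n + 1)
        coords = (1 - t) * ca + t * cb
        residues = [
            StructureResidue(
                number=r.number, aa=r.aa, xyz=tuple(coords[j]), icode=r.icode
            )
            for j, r in enumerate(model_a.residues)
        ]
        out[f"morph_{i:02d}"] = StructureModel(
            model_id=f"morph_{i:02d}", residues=residues
        )
    out[model_b.model_id] = model_b
    return out
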