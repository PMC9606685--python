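"""Sequence and alignment primitives.

FASTA I/O with strict validation, grouped (phylogroup-labelled) alignments,
global pairwise identity, greedy identity-tier filtering (the 95% / 70% / 60%
curation tiers used to build non-redundant representative sets), and
parsimony-informative site counting.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence as TypingSequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .constants import AMINO_ACIDS, GAP, UNKNOWN

VALID_RESIDUES = frozenset(AMINO_ACIDS + UNKNOWN)
VALID_ALIGNED = frozenset(AMINO_ACIDS + UNKNOWN + GAP)


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; message names the offending line."""


@dataclass(frozen=True)
class Sequence:
    """A protein sequence.

    residues are uppercase one-letter codes over the 20 amino acids plus
    'X' (unknown); '-' (gap) is permitted only in aligned sequences.
    """

    id: str
    residues: str
    description: str = ""
    taxon: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: residues must be nonempty")
        bad = set(self.residues) - VALID_ALIGNED
        if bad:
            raise ValueError(
                f"sequence {self.id!r}: illegal residue characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def is_aligned(self) -> bool:
        return GAP in self.residues

    def ungapped(self) -> "Sequence":
        return replace(self, residues=self.residues.replace(GAP, ""))


@dataclass(frozen=True)
class IdentityResult:
    """A global pairwise alignment plus its fractional identity."""

    aligned_a: str
    aligned_b: str
    score: float
    identity: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must be in [0, 1]")


@dataclass
class GroupedAlignment:
    """A gapped protein MSA with per-sequence phylogroup labels.

    ``group_order`` lists groups in their evolutionary succession (outgroup
    first); alignment columns are 1-based, the family's canonical coordinate
    system.
    """

    sequences: list[Sequence]
    labels: dict[str, str]
    group_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("alignment must contain at least one sequence")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        ids = [s.id for s in self.sequences]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids in alignment")
        missing = [i for i in ids if i not in self.labels]
        if missing:
            raise ValueError(f"unlabelled sequences: {missing[:5]}")
        groups = {self.labels[i] for i in ids}
        if not self.group_order:
            self.group_order = sorted(groups)
        unknown = groups - set(self.group_order)
        if unknown:
            raise ValueError(f"labels not in group_order: {sorted(unknown)}")
        for g in self.group_order:
            if not any(self.labels[i] == g for i in ids):
                raise ValueError(f"group {g!r} has no sequences")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def n(self) -> int:
        return len(self.sequences)

    def group_members(self, group: str) -> list[Sequence]:
        if group not in self.group_order:
            raise KeyError(f"unknown group {group!r}")
        return [s for s in self.sequences if self.labels[s.id] == group]

    def column(self, col: int) -> str:
        """Residues at 1-based column ``col``, in sequence order."""
        if not 1 <= col <= self.length:
            raise IndexError(f"column {col} outside 1..{self.length}")
        return "".join(s.residues[col - 1] for s in self.sequences)

    def group_column(self, group: str, col: int) -> str:
        if not 1 <= col <= self.length:
            raise IndexError(f"column {col} outside 1..{self.length}")
        return "".join(s.residues[col - 1] for s in self.group_members(group))

    @classmethod
    def from_files(
        cls,
        msa_path: str | Path,
        labels_path: str | Path,
        group_order: Iterable[str] | None = None,
    ) -> "GroupedAlignment":
        seqs = read_fasta(msa_path, aligned=True)
        labels = read_labels(labels_path)
        return cls(seqs, labels, list(group_order) if group_order else [])


# ---------------------------------------------------------------------------
# FASTA / labels I/O


def read_fasta(path: str | Path, aligned: bool = False) -> list[Sequence]:
    """Read a FASTA file into validated :class:`Sequence` records.

    Order is preserved. Raises :class:`FastaParseError` naming the offending
    line for malformed records or illegal characters, and for duplicate ids.
    """
    path = Path(path)
    text = path.read_text()
    _validate_fasta_text(text, aligned=aligned, name=str(path))
    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    seqs: list[Sequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        seqs.append(Sequence(id=rec.id, residues=str(rec.seq).upper(), description=desc))
    return seqs


def _validate_fasta_text(text: str, aligned: bool, name: str) -> None:
    allowed = VALID_ALIGNED if aligned else VALID_RESIDUES
    in_record = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            if len(line) == 1:
                raise FastaParseError(f"{name}, line {lineno}: empty FASTA header")
            in_record = True
            continue
        if not in_record:
            raise FastaParseError(
                f"{name}, line {lineno}: sequence data before any '>' header"
            )
        bad = set(line.upper()) - allowed
        if bad:
            raise FastaParseError(
                f"{name}, line {lineno}: illegal character(s) {sorted(bad)}"
            )
    if not in_record:
        raise FastaParseError(f"{name}: no FASTA records found")


def write_fasta(seqs: Iterable[Sequence], path: str | Path, width: int = 60) -> None:
    """Write sequences as FASTA, wrapping residue lines at ``width``."""
    path = Path(path)
    with path.open("w") as fh:
        for s in seqs:
            header = s.id if not s.description else f"{s.id} {s.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV (id <TAB> group) into a dict."""
    labels: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}, line {lineno}: expected 'id<TAB>group'")
        sid, group = parts[0].strip(), parts[1].strip()
        if sid in labels:
            raise ValueError(f"{path}, line {lineno}: duplicate id {sid!r}")
        labels[sid] = group
    return labels


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for sid, group in labels.items():
            fh.write(f"{sid}\t{group}\n")


# ---------------------------------------------------------------------------
# Pairwise identity and greedy filtering


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: Sequence, b: Sequence) -> IdentityResult:
    """Globally align two unaligned sequences and report fractional identity.

    Scoring is BLOSUM62 with affine gaps (open 11, extend 1). Identity is the
    number of identical aligned residue pairs over the number of alignment
    columns; in a pairwise global alignment no column can carry a gap in both
    rows, so no column is excluded. Internal gap columns count as mismatches,
    and 'X' never matches anything (including another 'X').
    """
    for s in (a, b):
        if GAP in s.residues:
            raise ValueError(f"sequence {s.id!r} is aligned; pass ungapped sequences")
        if not s.residues:
            raise ValueError("empty sequence")
    alignment = _ALIGNER.align(a.residues, b.residues)[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    matches = sum(
        1
        for x, y in zip(row_a, row_b)
        if x == y and x != GAP and x != UNKNOWN
    )
    identity = matches / len(row_a)
    return IdentityResult(
        aligned_a=row_a, aligned_b=row_b, score=float(alignment.score), identity=identity
    )


def greedy_filter(
    seqs: TypingSequence[Sequence], threshold: float
) -> list[Sequence]:
    """Greedy representative selection at a pairwise-identity threshold.

    Sequences are visited longest-first (ties broken by id); a sequence is
    retained iff its identity to every already-retained representative is
    below ``threshold``. Returns representatives in retention order. This is
    the CD-HIT-style tiering used to build the <95%, <70% and <60% identity
    sets.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    ordered = sorted(seqs, key=lambda s: (-len(s), s.id))
    retained: list[Sequence] = []
    for cand in ordered:
        if all(
            pairwise_identity(cand, rep).identity < threshold for rep in retained
        ):
            retained.append(cand)
    return retained


# ---------------------------------------------------------------------------
# Parsimony-informative sites


def count_pi_sites(aln: GroupedAlignment | TypingSequence[Sequence]) -> int:
    """Count parsimony-informative columns of an alignment.

    A column is parsimony-informative when it shows at least two distinct
    non-gap residue states, each present in at least two sequences. 'X' is a
    non-gap character and counts as a state of its own here, per the literal
    counting rule.
    """
    seqs = aln.sequences if isinstance(aln, GroupedAlignment) else list(aln)
    if not seqs:
        raise ValueError("empty alignment")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("sequences have unequal lengths")
    count = 0
    for col in range(len(seqs[0])):
        tally: dict[str, int] = {}
        for s in seqs:
            r = s.residues[col]
            if r != GAP:
                tally[r] = tally.get(r, 0) + 1
        if sum(1 for v in tally.values() if v >= 2) >= 2:
            count += 1
    return count
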