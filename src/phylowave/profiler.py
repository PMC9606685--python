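"""Group-specific logos, PROSITE-verbose patterns, database scanning and
taxonomic profiling.

The profiling loop mirrors pattern-hit-initiated database surveying: build a
per-phylogroup logo over a handful of diagnostic segments of the family
alignment, collapse it into a single PROSITE-verbose pattern (residue classes
joined by bounded wildcards), scan an unaligned database, tally hits per
taxon, and iterate pattern refinement to a fixed point. Hit extension and
E-values are out of scope; the pattern match itself localizes the segments.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence as TypingSequence

from .constants import AMINO_ACIDS, GAP, UNKNOWN
from .seqcore import GroupedAlignment, Sequence

_AA_SET = frozenset(AMINO_ACIDS)


# ---------------------------------------------------------------------------
# Pattern model


@dataclass(frozen=True)
class ResidueClass:
    """One pattern position: the set of amino acids accepted there."""

    residues: frozenset[str]

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("empty residue class")
        bad = set(self.residues) - _AA_SET
        if bad:
            raise ValueError(f"residue class contains non-amino-acid letters {sorted(bad)}")

    def text(self) -> str:
        letters = "".join(sorted(self.residues))
        return letters if len(letters) == 1 else f"[{letters}]"

    def accepts(self, residue: str) -> bool:
        return residue in self.residues


@dataclass(frozen=True)
class Wildcard:
    """A bounded any-residue spacer ``x(min,max)``."""

    min: int
    max: int

    def __post_init__(self) -> None:
        if self.min < 0 or self.max < self.min:
            raise ValueError(f"invalid wildcard bounds ({self.min},{self.max})")

    def text(self) -> str:
        if self.min == self.max:
            return "x" if self.min == 1 else f"x({self.min})"
        return f"x({self.min},{self.max})"


PositionSpec = ResidueClass | Wildcard

_TOKEN_CLASS = re.compile(r"^\[([A-Z]+)\]$")
_TOKEN_X = re.compile(r"^x(?:\((\d+)(?:,(\d+))?\))?$")


@dataclass(frozen=True)
class PrositePattern:
    """An ordered list of position specs with PROSITE-verbose serialization."""

    specs: tuple[PositionSpec, ...]

    def __post_init__(self) -> None:
        if not self.specs:
            raise ValueError("pattern must have at least one position")

    @property
    def text(self) -> str:
        return "-".join(s.text() for s in self.specs)

    @classmethod
    def parse(cls, text: str) -> "PrositePattern":
        text = text.strip().rstrip(".")
        specs: list[PositionSpec] = []
        for token in text.split("-"):
            token = token.strip()
            m = _TOKEN_X.match(token)
            if m:
                lo = int(m.group(1)) if m.group(1) else 1
                hi = int(m.group(2)) if m.group(2) else lo
                specs.append(Wildcard(lo, hi))
                continue
            m = _TOKEN_CLASS.match(token)
            if m:
                specs.append(ResidueClass(frozenset(m.group(1))))
                continue
            if len(token) == 1 and token in _AA_SET:
                specs.append(ResidueClass(frozenset(token)))
                continue
            raise ValueError(f"unsupported pattern token {token!r}")
        return cls(tuple(specs))

    def segments(self) -> tuple[list[list[ResidueClass]], list[Wildcard]]:
        """Split into maximal runs of residue classes and the wildcards between.

        Requires the pattern to start and end with a residue class and to have
        exactly one wildcard between consecutive segments (the shape produced
        by :func:`assemble_pattern`).
        """
        segs: list[list[ResidueClass]] = []
        gaps: list[Wildcard] = []
        current: list[ResidueClass] = []
        prev_wild = True
        for spec in self.specs:
            if isinstance(spec, ResidueClass):
                current.append(spec)
                prev_wild = False
            else:
                if prev_wild or not current:
                    raise ValueError(
                        "pattern is not in segment form (leading/adjacent wildcards)"
                    )
                segs.append(current)
                gaps.append(spec)
                current = []
                prev_wild = True
        if prev_wild:
            raise ValueError("pattern is not in segment form (trailing wildcard)")
        segs.append(current)
        return segs, gaps


# ---------------------------------------------------------------------------
# Segment specification and logos


@dataclass(frozen=True)
class SegmentSpec:
    """Diagnostic alignment segments and the residue spacing between them.

    ``segments`` are 1-based inclusive column intervals of the family MSA,
    disjoint and ascending; ``gap_ranges`` gives the (min, max) number of
    residues separating each adjacent segment pair in unaligned sequences.
    """

    segments: tuple[tuple[int, int], ...]
    gap_ranges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("need at least one segment")
        prev_end = 0
        for lo, hi in self.segments:
            if lo > hi:
                raise ValueError(f"segment ({lo},{hi}) has lo > hi")
            if lo <= prev_end:
                raise ValueError("segments must be disjoint and ascending")
            prev_end = hi
        if len(self.gap_ranges) != len(self.segments) - 1:
            raise ValueError("need one gap range per adjacent segment pair")
        for lo, hi in self.gap_ranges:
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid gap range ({lo},{hi})")

    @property
    def columns(self) -> list[int]:
        cols: list[int] = []
        for lo, hi in self.segments:
            cols.extend(range(lo, hi + 1))
        return cols


@dataclass
class GroupLogo:
    """Per-column residue counts/frequencies and information content for one group.

    Gaps are excluded from frequencies but reported as a per-column gap
    fraction; 'X' (unknown) is likewise excluded from the 20-letter
    frequency vector. Information content is log2(20) minus the Shannon
    entropy of the column, in bits; columns with no usable residues are
    flagged and their IC reported as missing (None).
    """

    group: str
    columns: list[int]
    counts: dict[int, dict[str, int]]
    gap_fraction: dict[int, float]
    n_sequences: int

    def frequencies(self, col: int) -> dict[str, float]:
        c = self.counts[col]
        total = sum(c.values())
        if total == 0:
            return {}
        return {r: k / total for r, k in c.items()}

    def information_content(self, col: int) -> float | None:
        freqs = self.frequencies(col)
        if not freqs:
            return None
        entropy = -sum(f * math.log2(f) for f in freqs.values() if f > 0)
        return math.log2(20) - entropy

    def observed(self, col: int, min_freq: float = 0.0) -> set[str]:
        return {r for r, f in self.frequencies(col).items() if f > min_freq}

    @property
    def missing_columns(self) -> list[int]:
        return [c for c in self.columns if not self.counts[c]]


def build_group_logo(
    aln: GroupedAlignment, group: str, spec: SegmentSpec
) -> GroupLogo:
    """Tally the group's residues over the spec's columns into a logo."""
    members = aln.group_members(group)
    cols = spec.columns
    if cols and cols[-1] > aln.length:
        raise ValueError(
            f"segment column {cols[-1]} outside alignment length {aln.length}"
        )
    counts: dict[int, dict[str, int]] = {}
    gap_fraction: dict[int, float] = {}
    for col in cols:
        tally: dict[str, int] = {}
        gaps = 0
        for s in members:
            r = s.residues[col - 1]
            if r == GAP:
                gaps += 1
            elif r != UNKNOWN:
                tally[r] = tally.get(r, 0) + 1
        counts[col] = tally
        gap_fraction[col] = gaps / len(members)
    return GroupLogo(
        group=group,
        columns=cols,
        counts=counts,
        gap_fraction=gap_fraction,
        n_sequences=len(members),
    )


def assemble_pattern(
    logo: GroupLogo, spec: SegmentSpec, min_freq: float = 0.0
) -> PrositePattern:
    """Collapse a logo into a PROSITE-verbose pattern.

    Each selected column becomes the class of all residues observed there
    with frequency above ``min_freq`` (default 0: every observed residue);
    adjacent segments are joined by a bounded wildcard from the spec's gap
    ranges.
    """
    specs: list[PositionSpec] = []
    for i, (lo, hi) in enumerate(spec.segments):
        if i > 0:
            gmin, gmax = spec.gap_ranges[i - 1]
            specs.append(Wildcard(gmin, gmax))
        for col in range(lo, hi + 1):
            residues = logo.observed(col, min_freq)
            if not residues:
                raise ValueError(
                    f"column {col}: no residues above min_freq={min_freq} "
                    f"for group {logo.group!r}"
                )
            specs.append(ResidueClass(frozenset(residues)))
    return PrositePattern(tuple(specs))


# ---------------------------------------------------------------------------
# Scanning


@dataclass(frozen=True)
class ScanHit:
    """A pattern match: 1-based inclusive span plus per-segment sub-spans."""

    seq_id: str
    start: int
    end: int
    segment_spans: tuple[tuple[int, int], ...]


def _match_from(
    residues: str, pos: int, specs: tuple[PositionSpec, ...], k: int,
    consumed: list[int],
) -> bool:
    """Backtracking matcher; wildcards try shortest expansions first.

    Fills ``consumed`` with the residue count eaten by each spec, yielding
    the leftmost-then-shortest expansion for the given start position.
    """
    if k == len(specs):
        return True
    spec = specs[k]
    if isinstance(spec, ResidueClass):
        if pos < len(residues) and spec.accepts(residues[pos]):
            consumed[k] = 1
            return _match_from(residues, pos + 1, specs, k + 1, consumed)
        return False
    for width in range(spec.min, spec.max + 1):
        if pos + width > len(residues):
            break
        consumed[k] = width
        if _match_from(residues, pos + width, specs, k + 1, consumed):
            return True
    return False


def scan(
    pattern: PrositePattern, seqs: Iterable[Sequence]
) -> list[ScanHit]:
    """Report every match of ``pattern`` against unaligned sequences.

    Matches at distinct start positions are all reported (overlaps included);
    for variable-length wildcards the leftmost-then-shortest expansion is the
    one reported per start. Wildcards accept any residue including 'X';
    residue classes accept only their own letters.
    """
    hits: list[ScanHit] = []
    specs = pattern.specs
    min_width = sum(s.min if isinstance(s, Wildcard) else 1 for s in specs)
    for seq in seqs:
        if GAP in seq.residues:
            raise ValueError(f"sequence {seq.id!r} is aligned; scan unaligned sequences")
        residues = seq.residues
        for start in range(0, len(residues) - min_width + 1):
            consumed = [0] * len(specs)
            if _match_from(residues, start, specs, 0, consumed):
                end = start + sum(consumed)
                spans: list[tuple[int, int]] = []
                pos = start
                seg_start: int | None = None
                for spec, width in zip(specs, consumed):
                    if isinstance(spec, ResidueClass):
                        if seg_start is None:
                            seg_start = pos
                    else:
                        if seg_start is not None:
                            spans.append((seg_start + 1, pos))
                            seg_start = None
                    pos += width
                if seg_start is not None:
                    spans.append((seg_start + 1, pos))
                hits.append(
                    ScanHit(
                        seq_id=seq.id,
                        start=start + 1,
                        end=end,
                        segment_spans=tuple(spans),
                    )
                )
    return hits


# ---------------------------------------------------------------------------
# Taxonomic profiling


@dataclass
class TaxonomicProfile:
    """Hit counts per taxon plus per-group specificity."""

    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def specificity(self, group: str) -> float | None:
        """In-group hits over total hits; None when there are no hits."""
        if self.total == 0:
            return None
        return self.counts.get(group, 0) / self.total


def profile_hits(
    hits: Iterable[ScanHit], taxon_labels: Mapping[str, str]
) -> TaxonomicProfile:
    """Tally hits per taxon; hits on unlabelled sequences count as 'unknown'."""
    counts: dict[str, int] = {}
    for hit in hits:
        taxon = taxon_labels.get(hit.seq_id, "unknown")
        counts[taxon] = counts.get(taxon, 0) + 1
    return TaxonomicProfile(counts=counts)


# ---------------------------------------------------------------------------
# Iterative refinement


def _pattern_from_instances(
    instances: TypingSequence[tuple[str, ...]],
    wildcards: TypingSequence[Wildcard],
    min_freq: float = 0.0,
) -> PrositePattern:
    """Rebuild a segment-form pattern from matched segment instances."""
    n_segments = len(instances[0])
    specs: list[PositionSpec] = []
    for seg_idx in range(n_segments):
        if seg_idx > 0:
            specs.append(wildcards[seg_idx - 1])
        seg_len = len(instances[0][seg_idx])
        for pos in range(seg_len):
            tally: dict[str, int] = {}
            for inst in instances:
                r = inst[seg_idx][pos]
                if r in _AA_SET:
                    tally[r] = tally.get(r, 0) + 1
            total = sum(tally.values())
            residues = {
                r for r, k in tally.items() if total and k / total > min_freq
            }
            if not residues:
                raise ValueError(
                    f"segment {seg_idx + 1} position {pos + 1}: empty class"
                )
            specs.append(ResidueClass(frozenset(residues)))
    return PrositePattern(tuple(specs))


def refine(
    pattern: PrositePattern,
    db: TypingSequence[Sequence],
    rounds: int,
    min_freq: float = 0.0,
) -> tuple[PrositePattern, str]:
    """Iteratively re-derive a pattern from its own database matches.

    Each round scans the database, extracts the matched segment instances
    (the pattern match localizes the segments), removes exact duplicate
    segment tuples, rebuilds the logo and reassembles the pattern. Stops
    early once the pattern text no longer changes.

    Returns ``(pattern, status)`` with status ``"converged"``,
    ``"max_rounds"`` or ``"no_hits"`` (round with zero hits: the last
    pattern is returned unchanged with a warning status).
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    _, wildcards = pattern.segments()
    by_id = {s.id: s for s in db}
    current = pattern
    for _ in range(rounds):
        hits = scan(current, db)
        if not hits:
            return current, "no_hits"
        seen: dict[tuple[str, ...], None] = {}
        for hit in hits:
            seq = by_id[hit.seq_id]
            inst = tuple(
                seq.residues[lo - 1 : hi] for lo, hi in hit.segment_spans
            )
            seen.setdefault(inst, None)
        new = _pattern_from_instances(list(seen), wildcards, min_freq)
        if new.text == current.text:
            return current, "converged"
        current = new
    return current, "max_rounds"
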