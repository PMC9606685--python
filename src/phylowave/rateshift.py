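"""Evolutionary rate-shift typing, permutation significance, and fixation
stages across an ordered phylogroup succession.

Site typing follows the classical functional-divergence taxonomy:

* **type I** — a column conserved in one group but variable in the other
  (heterotachy: altered structural constraint on one side);
* **type II** — conserved in both groups but with radically different
  residues (operationalized as Grantham distance >= a threshold);
* **type I/II** — mixed properties: conserved on both sides with a
  non-radical difference, or conserved on one side with intermediate
  conservation of a different residue on the other.

Statistical support comes from a per-column permutation test of a
between-group divergence score with Benjamini-Hochberg FDR control; a site
is *called* only when the categorical type and the permutation test agree.
A column's fixation stage is the earliest group of an ordered succession
from which its residue state stays conserved onward; significant sites that
share a stage (and, when structures are available, a 3D neighborhood) form
coevolution collections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence as TypingSequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .constants import AA_INDEX, AMINO_ACIDS, GAP, UNKNOWN, grantham
from .seqcore import GroupedAlignment

N_AA = len(AMINO_ACIDS)

# Default thresholds; conventional values, all exposed in the public API.
C_HI = 0.9          # modal frequency for "conserved"
C_LO = 0.6          # modal frequency at or below which a column is "variable"
GRANTHAM_MIN = 60   # minimal Grantham distance for a "radical" difference
GAP_FRACTION_MAX = 0.5
DEFAULT_B = 999
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class GroupColumnStats:
    """Per-group conservation summary of one alignment column."""

    modal_residue: str | None
    modal_freq: float | None
    gap_fraction: float
    usable: int

    @property
    def callable(self) -> bool:
        return (
            self.usable >= 2
            and self.gap_fraction <= GAP_FRACTION_MAX
            and self.modal_residue is not None
        )


@dataclass
class ConservationProfile:
    """Modal residue/frequency per column per group (gaps and 'X' excluded)."""

    groups: list[str]
    length: int
    stats: dict[str, dict[int, GroupColumnStats]]

    def get(self, group: str, column: int) -> GroupColumnStats:
        return self.stats[group][column]


def _column_stats(residues: str) -> GroupColumnStats:
    usable = [r for r in residues if r != GAP and r != UNKNOWN]
    gap_fraction = residues.count(GAP) / len(residues)
    if not usable:
        return GroupColumnStats(None, None, gap_fraction, 0)
    tally: dict[str, int] = {}
    for r in usable:
        tally[r] = tally.get(r, 0) + 1
    # alphabetical tie-break
    modal = min(tally, key=lambda r: (-tally[r], r))
    return GroupColumnStats(
        modal_residue=modal,
        modal_freq=tally[modal] / len(usable),
        gap_fraction=gap_fraction,
        usable=len(usable),
    )


def conservation_profile(
    aln: GroupedAlignment, groups: Iterable[str] | None = None
) -> ConservationProfile:
    """Per-column per-group modal residues and frequencies.

    A column is callable for a group when it has >= 2 usable (non-gap,
    non-'X') residues and a gap fraction <= 0.5 there.
    """
    groups = list(groups) if groups is not None else list(aln.group_order)
    for g in groups:
        if g not in aln.group_order:
            raise KeyError(f"unknown group {g!r}")
    stats: dict[str, dict[int, GroupColumnStats]] = {}
    for g in groups:
        members = aln.group_members(g)
        per_col: dict[int, GroupColumnStats] = {}
        for col in range(1, aln.length + 1):
            per_col[col] = _column_stats(
                "".join(s.residues[col - 1] for s in members)
            )
        stats[g] = per_col
    return ConservationProfile(groups=groups, length=aln.length, stats=stats)


def classify_site(
    stats_a: GroupColumnStats,
    stats_b: GroupColumnStats,
    c_hi: float = C_HI,
    c_lo: float = C_LO,
    grantham_min: float = GRANTHAM_MIN,
) -> tuple[str, str | None]:
    """Type a column from its two per-group summaries.

    Returns ``(type, reason)`` with type in {"I", "II", "I_II", "none"};
    ``reason`` explains a "none" call on an uncallable column.
    """
    if not stats_a.callable or not stats_b.callable:
        return "none", "uncallable"
    fa, fb = stats_a.modal_freq, stats_b.modal_freq
    ra, rb = stats_a.modal_residue, stats_b.modal_residue
    assert fa is not None and fb is not None and ra is not None and rb is not None
    if fa >= c_hi and fb >= c_hi and ra != rb:
        if grantham(ra, rb) >= grantham_min:
            return "II", None
        return "I_II", None
    one_hi_other_lo = (fa >= c_hi and fb <= c_lo) or (fb >= c_hi and fa <= c_lo)
    if one_hi_other_lo:
        return "I", None
    one_hi_other_mid = (
        (fa >= c_hi and c_lo < fb < c_hi) or (fb >= c_hi and c_lo < fa < c_hi)
    )
    if one_hi_other_mid and ra != rb:
        return "I_II", None
    return "none", None


# ---------------------------------------------------------------------------
# Divergence score and permutation null


def _encode(residues: str) -> np.ndarray:
    return np.array(
        [AA_INDEX[r] for r in residues if r != GAP and r != UNKNOWN],
        dtype=np.int64,
    )


def divergence_score(codes_a: np.ndarray, codes_b: np.ndarray) -> float:
    """Between-group divergence D of one column.

    D = (1 - frequency of group B's modal residue within group A)
      + (1 - frequency of group A's modal residue within group B).

    D is 0 when both groups are fixed for the same residue and approaches 2
    when each group is fixed for a residue absent from the other. Modal
    residues are tie-broken alphabetically.
    """
    if codes_a.size == 0 or codes_b.size == 0:
        raise ValueError("divergence_score needs usable residues in both groups")
    ca = np.bincount(codes_a, minlength=N_AA)
    cb = np.bincount(codes_b, minlength=N_AA)
    ma = int(np.argmax(ca))  # argmax returns lowest index on ties = alphabetical
    mb = int(np.argmax(cb))
    return float((1.0 - ca[mb] / codes_a.size) + (1.0 - cb[ma] / codes_b.size))


def _permutation_pvalue(
    codes_a: np.ndarray, codes_b: np.ndarray, B: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Observed D and its permutation p-value (label shuffle within column)."""
    d_obs = divergence_score(codes_a, codes_b)
    pooled = np.concatenate([codes_a, codes_b])
    if np.unique(pooled).size <= 1:
        return d_obs, 1.0
    n_a = codes_a.size
    perms = rng.permuted(np.tile(pooled, (B, 1)), axis=1)
    ra, rb = perms[:, :n_a], perms[:, n_a:]
    offsets = N_AA * np.arange(B)[:, None]
    counts_a = np.bincount(
        (ra + offsets).ravel(), minlength=N_AA * B
    ).reshape(B, N_AA)
    counts_b = np.bincount(
        (rb + offsets).ravel(), minlength=N_AA * B
    ).reshape(B, N_AA)
    modal_a = counts_a.argmax(axis=1)
    modal_b = counts_b.argmax(axis=1)
    rows = np.arange(B)
    d_perm = (
        (1.0 - counts_a[rows, modal_b] / n_a)
        + (1.0 - counts_b[rows, modal_a] / rb.shape[1])
    )
    n_ge = int(np.sum(d_perm >= d_obs - 1e-12))
    return d_obs, (1 + n_ge) / (B + 1)


def permutation_test(
    aln: GroupedAlignment,
    column: int,
    group_a: str,
    group_b: str,
    B: int = DEFAULT_B,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Permutation p-value for between-group divergence at one column.

    The null is built by shuffling group labels among the column's usable
    residues; p = (1 + #{D_perm >= D_obs}) / (B + 1), so p >= 1/(B+1). A
    degenerate column (a single residue overall) returns p = 1.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    codes_a = _encode(aln.group_column(group_a, column))
    codes_b = _encode(aln.group_column(group_b, column))
    if codes_a.size == 0 or codes_b.size == 0:
        raise ValueError(f"column {column}: no usable residues in one group")
    return _permutation_pvalue(codes_a, codes_b, B, rng)


# ---------------------------------------------------------------------------
# Full scans


@dataclass(frozen=True)
class RateShiftCall:
    """Typed divergence call for one column between two groups."""

    column: int
    type: str                 # "I" | "II" | "I_II" | "none"
    D: float | None
    p: float | None
    q: float | None
    reason: str | None = None

    @property
    def significant(self) -> bool:
        return self.type != "none" and self.q is not None and self.q <= DEFAULT_ALPHA


def rate_shift_scan(
    aln: GroupedAlignment,
    group_a: str,
    group_b: str,
    c_hi: float = C_HI,
    c_lo: float = C_LO,
    grantham_min: float = GRANTHAM_MIN,
    B: int = DEFAULT_B,
    seed: int | None = None,
    columns: Iterable[int] | None = None,
) -> list[RateShiftCall]:
    """Type and test every (callable) column between two groups.

    Permutation p-values are BH-adjusted across the tested columns;
    uncallable columns get type "none" with no p/q.
    """
    profile = conservation_profile(aln, [group_a, group_b])
    rng = np.random.default_rng(seed)
    cols = list(columns) if columns is not None else list(range(1, aln.length + 1))
    calls: list[RateShiftCall] = []
    tested_idx: list[int] = []
    pvalues: list[float] = []
    for col in cols:
        sa, sb = profile.get(group_a, col), profile.get(group_b, col)
        site_type, reason = classify_site(sa, sb, c_hi, c_lo, grantham_min)
        if not sa.callable or not sb.callable:
            calls.append(RateShiftCall(col, "none", None, None, None, reason))
            continue
        codes_a = _encode(aln.group_column(group_a, col))
        codes_b = _encode(aln.group_column(group_b, col))
        d_obs, p = _permutation_pvalue(codes_a, codes_b, B, rng)
        tested_idx.append(len(calls))
        pvalues.append(p)
        calls.append(RateShiftCall(col, site_type, d_obs, p, None, reason))
    if pvalues:
        _, qvalues, _, _ = multipletests(pvalues, method="fdr_bh")
        qvalues = np.maximum(qvalues, np.asarray(pvalues))  # guard q >= p
        for idx, q in zip(tested_idx, qvalues):
            c = calls[idx]
            calls[idx] = RateShiftCall(c.column, c.type, c.D, c.p, float(q), c.reason)
    return calls


# ---------------------------------------------------------------------------
# Fixation stages


@dataclass(frozen=True)
class FixationStage:
    """Earliest group of the succession from which a column stays conserved."""

    column: int
    stage: str                # a group name or "unfixed"
    residue: str | None


def fixation_stage(
    aln: GroupedAlignment,
    column: int,
    c_hi: float = C_HI,
    profile: ConservationProfile | None = None,
) -> FixationStage:
    """Earliest group g such that g and every later group share one conserved
    modal residue (modal frequency >= c_hi).

    When that holds from the first group (the outgroup) on, the stage is the
    outgroup itself. A group that is uncallable at the column breaks every
    suffix containing it. If no suffix qualifies, the column is "unfixed".
    """
    if len(aln.group_order) < 2:
        raise ValueError("fixation_stage needs >= 2 groups in group_order")
    if profile is None:
        profile = conservation_profile(aln)
    order = aln.group_order
    stats = [profile.get(g, column) for g in order]
    best: FixationStage | None = None
    for i in range(len(order)):
        suffix = stats[i:]
        if any(
            not s.callable or s.modal_freq is None or s.modal_freq < c_hi
            for s in suffix
        ):
            continue
        residues = {s.modal_residue for s in suffix}
        if len(residues) == 1:
            best = FixationStage(column, order[i], suffix[0].modal_residue)
            break
    if best is None:
        return FixationStage(column, "unfixed", None)
    return best


# ---------------------------------------------------------------------------
# Coevolution collections


@dataclass(frozen=True)
class CoevolutionCollection:
    """Significant columns sharing a fixation stage (and a 3D neighborhood)."""

    collection_id: int
    stage: str
    columns: tuple[int, ...]


def collect_coevolved(
    calls: TypingSequence[RateShiftCall],
    stages: Mapping[int, FixationStage],
    network: "object | None" = None,
    alpha: float = DEFAULT_ALPHA,
    stage_order: TypingSequence[str] | None = None,
) -> list[CoevolutionCollection]:
    """Group significant sites into coevolution collections.

    Sites are partitioned by fixation stage; within a stage, if a residue
    network (see :mod:`phylowave.structmap`) is supplied, members are split
    into the network's connected components (spatial waves); columns absent
    from the network form singleton collections.
    """
    significant = [
        c.column
        for c in calls
        if c.type != "none" and c.q is not None and c.q <= alpha
    ]
    by_stage: dict[str, list[int]] = {}
    for col in significant:
        st = stages[col].stage if col in stages else "unfixed"
        by_stage.setdefault(st, []).append(col)

    if stage_order is not None:
        rank = {g: i for i, g in enumerate(stage_order)}
        stage_keys = sorted(by_stage, key=lambda s: (rank.get(s, len(rank)), s))
    else:
        stage_keys = sorted(by_stage)

    collections: list[CoevolutionCollection] = []
    next_id = 0
    for st in stage_keys:
        cols = sorted(by_stage[st])
        if network is None:
            collections.append(CoevolutionCollection(next_id, st, tuple(cols)))
            next_id += 1
            continue
        import networkx as nx

        graph = network.graph  # ResidueNetwork
        in_net = [c for c in cols if c in graph]
        out_net = [c for c in cols if c not in graph]
        sub = graph.subgraph(in_net)
        components = sorted(
            (sorted(comp) for comp in nx.connected_components(sub)),
            key=lambda comp: comp[0],
        )
        for comp in components:
            collections.append(CoevolutionCollection(next_id, st, tuple(comp)))
            next_id += 1
        for col in out_net:
            collections.append(CoevolutionCollection(next_id, st, (col,)))
            next_id += 1
    return collections
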