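"""Independent oracles used by the test suite.

These deliberately re-derive results through different routes than the
package (plain dynamic programming, regex translation, numerical
optimization) so agreement is evidence, not tautology.
"""

from __future__ import annotations

import math
import re

import numpy as np
from Bio.Align import substitution_matrices
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from phylowave.constants import AMINO_ACIDS
from phylowave.profiler import PrositePattern, ResidueClass, Wildcard
from phylowave.seqcore import Sequence

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

NEG_INF = float("-inf")


def gotoh_score(a: str, b: str, open_score: float = -11.0, extend: float = -1.0) -> float:
    """Optimal global affine-gap alignment score (Gotoh three-matrix DP).

    The first gap position scores ``open_score`` and each further position
    ``extend``; terminal gaps are penalized like internal ones.
    """
    n, m = len(a), len(b)
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Iy = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = open_score + (i - 1) * extend
    for j in range(1, m + 1):
        Iy[0][j] = open_score + (j - 1) * extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _BLOSUM62[a[i - 1], b[j - 1]]
            best_prev = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            M[i][j] = best_prev + s
            Ix[i][j] = max(
                M[i - 1][j] + open_score,
                Ix[i - 1][j] + extend,
                Iy[i - 1][j] + open_score,
            )
            Iy[i][j] = max(
                M[i][j - 1] + open_score,
                Iy[i][j - 1] + extend,
                Ix[i][j - 1] + open_score,
            )
    return max(M[n][m], Ix[n][m], Iy[n][m])


# ---------------------------------------------------------------------------
# Pattern-scan oracle: regex translation


def pattern_to_regex(pattern: PrositePattern) -> re.Pattern:
    parts: list[str] = []
    for spec in pattern.specs:
        if isinstance(spec, ResidueClass):
            parts.append("[" + "".join(sorted(spec.residues)) + "]")
        else:
            parts.append(f"[A-Z]{{{spec.min},{spec.max}}}?")  # lazy: shortest-first
    return re.compile("".join(parts))


def regex_hits(pattern: PrositePattern, seqs) -> set[tuple[str, int, int]]:
    """All (id, start, end) matches, one (shortest) per start position."""
    rx = pattern_to_regex(pattern)
    out: set[tuple[str, int, int]] = set()
    for seq in seqs:
        for start in range(len(seq.residues)):
            m = rx.match(seq.residues, start)
            if m:
                out.add((seq.id, start + 1, m.end()))
    return out


def random_pattern(rng: np.random.Generator) -> PrositePattern:
    """A random segment-form pattern (classes joined by bounded wildcards)."""
    aa = list(AMINO_ACIDS)
    specs = []
    n_segments = int(rng.integers(1, 4))
    for si in range(n_segments):
        if si > 0:
            lo = int(rng.integers(0, 3))
            hi = lo + int(rng.integers(0, 4))
            specs.append(Wildcard(lo, hi))
        for _ in range(int(rng.integers(1, 4))):
            k = int(rng.integers(1, 5))
            specs.append(
                ResidueClass(frozenset(rng.choice(aa, size=k, replace=False)))
            )
    return PrositePattern(tuple(specs))


def random_protein(rng: np.random.Generator, length: int, seq_id: str) -> Sequence:
    letters = rng.choice(list(AMINO_ACIDS + "X"), size=length,
                         p=[0.049] * 20 + [0.02])
    return Sequence(id=seq_id, residues="".join(letters))


# ---------------------------------------------------------------------------
# Kabsch oracle: direct numerical minimization over rotations


def rmsd_minimization_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Minimal RMSD via multi-start numerical optimization over Euler angles."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    n = x.shape[0]

    def cost(angles: np.ndarray) -> float:
        rot = Rotation.from_euler("xyz", angles).as_matrix()
        diff = xc - yc @ rot.T
        return math.sqrt(float((diff**2).sum()) / n)

    best = math.inf
    starts = [
        (0.0, 0.0, 0.0),
        (math.pi, 0.0, 0.0),
        (0.0, math.pi, 0.0),
        (0.0, 0.0, math.pi),
        (math.pi / 2, math.pi / 2, 0.0),
        (-math.pi / 2, 0.0, math.pi / 2),
        (math.pi / 3, -math.pi / 3, math.pi / 3),
        (-2.0, 1.0, 2.0),
    ]
    for s in starts:
        res = minimize(cost, s, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        best = min(best, float(res.fun))
    return best
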