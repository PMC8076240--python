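"""Pairwise miRNA similarity scores.

Two scores drive the cross-kingdom screen:

* the **global match-fraction score** ``S = matches / max(len_a, len_b)`` —
  the maximum number of identically aligned nucleotides over all gapped
  alignments (mismatches and gaps cost nothing), divided by the longer
  sequence's length. The match-maximization problem is exactly the longest
  common subsequence, solved here by the standard dynamic program.

* the **seed-specific local score** — an affine-gap Smith-Waterman score of
  the two seed windows (canonically nucleotides 2-8) with a +1 match
  reward, -0.5 mismatch penalty and -1 per gap position by default. The
  stringent penalties make the seed comparison reward near-perfect seed
  homology, which dominates miRNA target recognition.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .seqio import MiRNARecord

__all__ = [
    "AlignmentMode",
    "AlignmentParams",
    "AlignmentOutcome",
    "SeedRegion",
    "max_matches",
    "global_score",
    "extract_seed",
    "seed_local_score",
    "align_global",
    "align_seed",
]


class AlignmentMode(str, Enum):
    GLOBAL_MATCH_COUNT = "global_match_count"
    SEED_LOCAL = "seed_local"


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring parameters.

    In global_match_count mode only matches score (+1); mismatch and gap
    parameters are ignored. In seed_local mode the affine gap model charges
    ``gap_open_penalty`` for the first position of a gap run and
    ``gap_extend_penalty`` for each subsequent position, so a run of g >= 1
    gap positions costs ``gap_open + (g - 1) * gap_extend``. With the
    default open == extend == -1 this coincides with a linear -1/position
    model; the machinery stays configurable for unequal values.
    """

    match_reward: float = 1.0
    mismatch_penalty: float = -0.5
    gap_open_penalty: float = -1.0
    gap_extend_penalty: float = -1.0
    mode: AlignmentMode = AlignmentMode.SEED_LOCAL

    def __post_init__(self) -> None:
        if self.match_reward <= 0:
            raise ValueError("match_reward must be positive")


@dataclass(frozen=True)
class SeedRegion:
    """1-based inclusive window of the mature sequence scored as the seed.

    The default (2, 8) is the canonical metazoan seed: nucleotides 2-8 of
    the mature miRNA, 7 nt.
    """

    start: int = 2
    end: int = 8

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid seed region ({self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class AlignmentOutcome:
    """Result of one pairwise alignment."""

    matches: int
    raw_score: float
    len_a: int
    len_b: int
    mode: AlignmentMode
    normalized_score: float | None = None


def _check_nonempty(a: str, b: str) -> None:
    if not a or not b:
        raise ValueError("alignment requires two non-empty sequences")


def max_matches(a: str, b: str) -> int:
    """Maximum number of aligned identical positions over all gapped
    alignments with zero cost for mismatches and gaps.

    This is the longest-common-subsequence length, computed with the LCS
    recurrence; rows are vectorized with a running maximum, exploiting the
    monotonicity of LCS rows.
    """
    _check_nonempty(a, b)
    bv = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    prev = np.zeros(len(b) + 1, dtype=np.int64)
    for ch in a.encode("ascii"):
        cand = np.maximum(prev[1:], prev[:-1] + (bv == ch))
        prev[1:] = np.maximum.accumulate(cand)
    return int(prev[-1])


def global_score(a: str, b: str) -> float:
    """Global match-fraction score: matches / max(len_a, len_b), in [0, 1].

    Equals 1 iff the sequences are identical, and is symmetric.
    """
    return max_matches(a, b) / max(len(a), len(b))


def align_global(a: str, b: str) -> AlignmentOutcome:
    """Full global-mode outcome (match count plus normalized score)."""
    m = max_matches(a, b)
    return AlignmentOutcome(
        matches=m,
        raw_score=float(m),
        len_a=len(a),
        len_b=len(b),
        mode=AlignmentMode.GLOBAL_MATCH_COUNT,
        normalized_score=m / max(len(a), len(b)),
    )


def extract_seed(record: MiRNARecord | str, region: SeedRegion = SeedRegion()) -> str:
    """1-based inclusive substring of the mature sequence.

    Raises if the window extends past the sequence end, naming the record.
    """
    if isinstance(record, MiRNARecord):
        seq, name = record.sequence, record.id
    else:
        seq, name = record, "<sequence>"
    if region.end > len(seq):
        raise ValueError(
            f"seed region ({region.start}, {region.end}) extends past the end "
            f"of {name!r} (length {len(seq)})"
        )
    return seq[region.start - 1 : region.end]


def seed_local_score(
    a_seed: str, b_seed: str, params: AlignmentParams = AlignmentParams()
) -> float:
    """Optimal local alignment score of two seed windows under the affine
    gap model (Smith-Waterman / Gotoh), floored at 0.

    Three-state recurrence: H (last column aligns two residues), E (gap in
    the first sequence) and F (gap in the second). Opening a gap from H
    costs ``gap_open_penalty``; each further gap position costs
    ``gap_extend_penalty``.
    """
    _check_nonempty(a_seed, b_seed)
    match = params.match_reward
    mis = params.mismatch_penalty
    go = params.gap_open_penalty
    ge = params.gap_extend_penalty

    la, lb = len(a_seed), len(b_seed)
    neg = float("-inf")
    H = [[0.0] * (lb + 1) for _ in range(la + 1)]
    E = [[neg] * (lb + 1) for _ in range(la + 1)]
    F = [[neg] * (lb + 1) for _ in range(la + 1)]
    best = 0.0
    for i in range(1, la + 1):
        ai = a_seed[i - 1]
        for j in range(1, lb + 1):
            E[i][j] = max(H[i][j - 1] + go, E[i][j - 1] + ge)
            F[i][j] = max(H[i - 1][j] + go, F[i - 1][j] + ge)
            sub = match if ai == b_seed[j - 1] else mis
            h = max(H[i - 1][j - 1], E[i - 1][j - 1], F[i - 1][j - 1]) + sub
            H[i][j] = max(h, 0.0)
            if H[i][j] > best:
                best = H[i][j]
    return best


def align_seed(
    a: MiRNARecord | str,
    b: MiRNARecord | str,
    region: SeedRegion = SeedRegion(),
    params: AlignmentParams = AlignmentParams(),
) -> AlignmentOutcome:
    """Extract both seed windows and score them locally."""
    sa, sb = extract_seed(a, region), extract_seed(b, region)
    score = seed_local_score(sa, sb, params)
    return AlignmentOutcome(
        matches=max_matches(sa, sb),
        raw_score=score,
        len_a=len(sa),
        len_b=len(sb),
        mode=AlignmentMode.SEED_LOCAL,
    )
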