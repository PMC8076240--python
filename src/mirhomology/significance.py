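"""Scramble-null significance for one plant x animal comparison.

For a pair (A from plants, B from animals) the observed alignment score is
referred to an empirical null built from composition-matched scrambles of
B: each scramble B' is a uniform random permutation of B's nucleotides, so
it has exactly the same length and nucleotide percentages. Scoring A
against n scrambles (default 100) gives a null sample; a one-sample
Student-t tail probability then asks whether the real pair is more similar
than composition-matched chance. The procedure runs twice per pair — once
on the whole sequences with the global match-fraction score, once on the
seed windows with the penalized local score — yielding two p-values.

The t statistic treats the observed score as a single new draw from the
null population: t = (observed - mean) / (sd * sqrt(1 + 1/n)), referred to
Student's t with n - 1 degrees of freedom. The sqrt(1 + 1/n) predictive
scaling keeps the test approximately calibrated (about a 5% type-I rate at
alpha = 0.05 on unrelated random pairs); dividing by sd/sqrt(n) instead
would test the null *mean* and reject unrelated pairs at a ~40% rate.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
from scipy import stats

from . import alignment
from .seqio import MiRNARecord

__all__ = [
    "NullDistribution",
    "scramble",
    "null_distribution",
    "one_sample_t_pvalue",
    "compare_pair",
    "pair_rng",
]

ScrambleMode = Literal["permute", "iid"]
Tail = Literal["upper", "two_sided"]


@dataclass(frozen=True)
class NullDistribution:
    """The scramble-score sample for one pair and one score type."""

    scores: tuple[float, ...]
    mean: float
    sd: float

    @property
    def n(self) -> int:
        return len(self.scores)

    @classmethod
    def from_scores(cls, scores: Sequence[float]) -> "NullDistribution":
        arr = np.asarray(scores, dtype=float)
        if arr.size < 2:
            raise ValueError("a null distribution needs at least 2 scores")
        # a constant sample is exactly degenerate: its mean is the constant
        # and its sd is exactly 0 (np.mean/np.std round to ~1e-17 otherwise)
        if arr.max() == arr.min():
            mean, sd = float(arr[0]), 0.0
        else:
            mean, sd = float(arr.mean()), float(arr.std(ddof=1))
        return cls(scores=tuple(float(x) for x in arr), mean=mean, sd=sd)

    def t_statistic(self, observed: float) -> float:
        """Predictive one-sample t statistic for a single new observation."""
        if self.sd == 0.0:
            return float("inf") if observed > self.mean else float("-inf") \
                if observed < self.mean else 0.0
        return (observed - self.mean) / (self.sd * np.sqrt(1.0 + 1.0 / self.n))


def scramble(
    b: str,
    n: int,
    rng: np.random.Generator | int,
    mode: ScrambleMode = "permute",
) -> list[str]:
    """Generate n composition-matched scrambles of sequence b.

    ``permute`` (default) draws uniform random permutations of b's
    characters, conserving the nucleotide multiset exactly. ``iid`` draws
    each position independently from b's empirical nucleotide frequencies,
    conserving composition only in expectation.
    """
    if not b:
        raise ValueError("cannot scramble an empty sequence")
    if n < 1:
        raise ValueError(f"number of scrambles must be >= 1, got {n}")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    chars = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    out: list[str] = []
    if mode == "permute":
        for _ in range(n):
            out.append(gen.permutation(chars).tobytes().decode("ascii"))
    elif mode == "iid":
        alphabet, counts = np.unique(chars, return_counts=True)
        probs = counts / counts.sum()
        for _ in range(n):
            draw = gen.choice(alphabet, size=chars.size, p=probs)
            out.append(draw.astype(np.uint8).tobytes().decode("ascii"))
    else:
        raise ValueError(f"unknown scramble mode {mode!r}")
    return out


def null_distribution(
    a: str,
    b: str,
    scorer: Callable[[str, str], float],
    n: int,
    rng: np.random.Generator | int,
    mode: ScrambleMode = "permute",
) -> NullDistribution:
    """Score a against n scrambles of b and summarize the sample."""
    scrambles = scramble(b, n, rng, mode)
    return NullDistribution.from_scores([scorer(a, s) for s in scrambles])


def one_sample_t_pvalue(
    observed: float, null: NullDistribution, tail: Tail = "upper"
) -> float:
    """Student-t tail probability of the observed score under the null.

    Upper tail (default) answers the screening question "is the real pair
    more similar than composition-matched chance?"; ``two_sided`` doubles
    the smaller tail. A degenerate null (sd == 0, e.g. a homopolymer B) is
    handled as the limiting case: p = 0 when the observed score strictly
    exceeds the constant null, else p = 1.
    """
    df = null.n - 1
    if null.sd == 0.0:
        if tail == "upper":
            return 0.0 if observed > null.mean else 1.0
        return 0.0 if observed != null.mean else 1.0
    t = null.t_statistic(observed)
    if tail == "upper":
        return float(stats.t.sf(t, df))
    return float(2.0 * stats.t.sf(abs(t), df))


def pair_rng(master_seed: int, plant_id: str, animal_id: str) -> np.random.Generator:
    """Reproducible per-pair RNG stream keyed by the two ids.

    The stream depends on the ids through CRC-32 (stable across processes,
    unlike Python's salted hash), so re-sorting a library permutes output
    rows without changing any per-pair number.
    """
    key = (
        int(master_seed) & 0xFFFFFFFF,
        zlib.crc32(plant_id.encode("utf-8")),
        zlib.crc32(animal_id.encode("utf-8")),
    )
    return np.random.default_rng(np.random.SeedSequence(key))


def compare_pair(a: MiRNARecord, b: MiRNARecord, config) -> "ComparisonResult":
    """Score one plant x animal pair and attach both scramble-null p-values.

    The global and seed nulls use independent scramble draws from the
    pair's RNG stream. In seed mode the full-length B is scrambled and the
    seed window re-extracted from each scramble, preserving whole-sequence
    composition; scrambling the extracted seed alone is available via
    ``config.scramble_scope = "seed_only"``.
    """
    from .screen import ComparisonResult  # deferred: screen imports this module

    region = config.seed_region
    params = config.alignment_params
    s_global = alignment.global_score(a.sequence, b.sequence)
    a_seed = alignment.extract_seed(a, region)
    b_seed = alignment.extract_seed(b, region)
    s_seed = alignment.seed_local_score(a_seed, b_seed, params)

    rng = pair_rng(config.rng_seed, a.id, b.id)
    null_g = null_distribution(
        a.sequence,
        b.sequence,
        alignment.global_score,
        config.n_scrambles,
        rng,
        config.scramble_mode,
    )
    if config.scramble_scope == "full":
        scrambles = scramble(b.sequence, config.n_scrambles, rng, config.scramble_mode)
        seed_scores = [
            alignment.seed_local_score(
                a_seed, alignment.extract_seed(s, region), params
            )
            for s in scrambles
        ]
        null_s = NullDistribution.from_scores(seed_scores)
    elif config.scramble_scope == "seed_only":
        null_s = null_distribution(
            a_seed,
            b_seed,
            lambda x, y: alignment.seed_local_score(x, y, params),
            config.n_scrambles,
            rng,
            config.scramble_mode,
        )
    else:
        raise ValueError(f"unknown scramble scope {config.scramble_scope!r}")

    p_global = one_sample_t_pvalue(s_global, null_g, config.test_tail)
    p_seed = one_sample_t_pvalue(s_seed, null_s, config.test_tail)
    return ComparisonResult(
        plant_id=a.id,
        animal_id=b.id,
        s_global=s_global,
        s_seed=s_seed,
        null_global=null_g,
        null_seed=null_s,
        p_global=p_global,
        p_seed=p_seed,
        selected=False,
    )
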