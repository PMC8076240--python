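"""The all-pairs cross-kingdom screen.

Every plant miRNA is compared against every animal miRNA (Cartesian
product, plant-major order); each pair gets a global and a seed p-value
from the scramble-null t-test, and a pair is *selected* as a putative
functional homolog only when both p-values clear their thresholds
simultaneously. Selected plant miRNAs then inherit the experimentally
supported target genes of their animal homologs, on the premise that a
plant miRNA with significant whole-sequence and seed homology regulates
the same transcripts as its animal counterpart.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

from statsmodels.stats.multitest import multipletests

from .alignment import AlignmentParams, SeedRegion
from .seqio import MiRNALibrary
from .significance import NullDistribution, ScrambleMode, Tail, compare_pair

__all__ = ["ScreenConfig", "ComparisonResult", "run_screen", "filter_pairs", "join_targets"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenConfig:
    """Everything that parameterizes one screening run.

    Thresholds default to raw p < 0.05 on both tests; Benjamini-Hochberg
    adjustment of each p-value vector before thresholding is available via
    ``p_adjust = "BH"``.
    """

    alignment_params: AlignmentParams = AlignmentParams()
    seed_region: SeedRegion = SeedRegion()
    n_scrambles: int = 100
    rng_seed: int = 0
    alpha_global: float = 0.05
    alpha_seed: float = 0.05
    p_adjust: Literal["none", "BH"] = "none"
    scramble_mode: ScrambleMode = "permute"
    scramble_scope: Literal["full", "seed_only"] = "full"
    test_tail: Tail = "upper"

    def __post_init__(self) -> None:
        for name in ("alpha_global", "alpha_seed"):
            a = getattr(self, name)
            if not 0.0 < a <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {a}")
        if self.n_scrambles < 2:
            raise ValueError("n_scrambles must be >= 2 for a t-test")

    @classmethod
    def from_file(cls, path: str | Path) -> "ScreenConfig":
        """Load a config from a flat YAML (or TOML-style key: value) file.

        Recognized keys mirror the CLI options: seed_start, seed_end,
        seed_match, seed_mismatch, seed_gap_open, seed_gap_extend,
        n_scrambles, rng_seed, alpha_global, alpha_seed, p_adjust,
        scramble_mode, scramble_scope, test_tail.
        """
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, Mapping):
            raise ValueError(f"{path}: expected flat key: value pairs")
        params = AlignmentParams(
            match_reward=float(raw.get("seed_match", 1.0)),
            mismatch_penalty=float(raw.get("seed_mismatch", -0.5)),
            gap_open_penalty=float(raw.get("seed_gap_open", -1.0)),
            gap_extend_penalty=float(raw.get("seed_gap_extend", -1.0)),
        )
        region = SeedRegion(
            start=int(raw.get("seed_start", 2)), end=int(raw.get("seed_end", 8))
        )
        kwargs = {
            k: raw[k]
            for k in (
                "n_scrambles",
                "rng_seed",
                "alpha_global",
                "alpha_seed",
                "p_adjust",
                "scramble_mode",
                "scramble_scope",
                "test_tail",
            )
            if k in raw
        }
        return cls(alignment_params=params, seed_region=region, **kwargs)


@dataclass
class ComparisonResult:
    """One plant x animal pair: both scores, both nulls, both p-values."""

    plant_id: str
    animal_id: str
    s_global: float
    s_seed: float
    null_global: NullDistribution
    null_seed: NullDistribution
    p_global: float
    p_seed: float
    selected: bool = False


def run_screen(
    plant: MiRNALibrary, animal: MiRNALibrary, config: ScreenConfig = ScreenConfig()
) -> list[ComparisonResult]:
    """Compare every plant miRNA against every animal miRNA.

    Returns exactly ``len(plant) * len(animal)`` results in plant-major,
    animal-minor order, with selection flags already applied per
    ``config``. Per-pair RNG streams are keyed by the two ids and the
    master seed, so reordering either library permutes rows without
    changing any number.
    """
    if len(plant) == 0 or len(animal) == 0:
        raise ValueError("both libraries must be non-empty")
    results: list[ComparisonResult] = []
    for a in plant:
        for b in animal:
            results.append(compare_pair(a, b, config))
    selected = filter_pairs(results, config)
    logger.info(
        "screened %d x %d = %d pairs; %d selected (alpha_global=%g, alpha_seed=%g, adjust=%s)",
        len(plant),
        len(animal),
        len(results),
        len(selected),
        config.alpha_global,
        config.alpha_seed,
        config.p_adjust,
    )
    return results


def filter_pairs(
    results: Sequence[ComparisonResult], config: ScreenConfig = ScreenConfig()
) -> list[ComparisonResult]:
    """Flag and return the pairs significant on BOTH tests.

    Sets ``selected`` in place on every result: selected iff the
    (optionally BH-adjusted) global p < alpha_global AND the (optionally
    BH-adjusted) seed p < alpha_seed. With ``p_adjust = "BH"`` the
    Benjamini-Hochberg step-up runs separately on the global and seed
    p-value vectors across all screened pairs.
    """
    if not results:
        return []
    pg = [r.p_global for r in results]
    ps = [r.p_seed for r in results]
    if config.p_adjust == "BH":
        pg = list(multipletests(pg, method="fdr_bh")[1])
        ps = list(multipletests(ps, method="fdr_bh")[1])
    elif config.p_adjust != "none":
        raise ValueError(f"unknown p_adjust {config.p_adjust!r}")
    out: list[ComparisonResult] = []
    for r, qg, qs in zip(results, pg, ps):
        r.selected = qg < config.alpha_global and qs < config.alpha_seed
        if r.selected:
            out.append(r)
    return out


def join_targets(
    selected: Iterable[ComparisonResult],
    target_table: Mapping[str, Sequence[str]],
) -> list[tuple[str, str]]:
    """Transfer animal target genes to their selected plant homologs.

    For each selected pair the plant miRNA inherits every target gene of
    its animal homolog, preserving the table's within-miRNA gene order
    (pre-ranked tables stay ranked). Output is deduplicated per
    (plant_id, gene); selected pairs whose animal id is absent from the
    table are skipped with a warning.
    """
    import warnings

    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    missing: set[str] = set()
    for r in selected:
        genes = target_table.get(r.animal_id)
        if genes is None:
            if r.animal_id not in missing:
                warnings.warn(
                    f"animal miRNA {r.animal_id!r} not found in target table; skipping"
                )
                missing.add(r.animal_id)
            continue
        for g in genes:
            key = (r.plant_id, g)
            if key not in seen:
                seen.add(key)
                pairs.append(key)
    return pairs
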