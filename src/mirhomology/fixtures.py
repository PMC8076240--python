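"""Synthetic miRNA libraries with planted cross-kingdom homologs.

Everything downstream of FASTA input is testable without downloads: this
module draws an "animal" library of i.i.d. random sequences, plants
"plant" homologs of some of them (seed region untouched, a fixed number of
substitutions outside the seed), pads the plant library with fresh random
decoys, and returns the planted truth pairs. Because decoys come from the
same generator as the animal library, their selection rate estimates the
screen's realized false-positive rate; because homolog mutations avoid the
seed, seed-test power and global-test power can be probed independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment import SeedRegion
from .seqio import Kingdom, MiRNALibrary, MiRNARecord, write_fasta

__all__ = ["FixtureSpec", "random_library", "plant_homolog", "make_screen_fixture", "write_fixture"]

_NUCS = ("A", "C", "G", "U")

#: AU-poor preset; scramble nulls are composition-sensitive, so a skewed
#: composition exercises the composition-matching of the null.
GC_SKEW_COMPOSITION = (0.15, 0.35, 0.35, 0.15)


@dataclass(frozen=True)
class FixtureSpec:
    """Generator settings for one synthetic screen fixture.

    Defaults model a small but realistic screening problem: 22-nt mature
    sequences (the modal animal miRNA length), a 20-sequence animal
    library, 5 planted homologs carrying at most 2 substitutions outside
    the canonical 2-8 seed, and 15 unrelated decoys.
    """

    n_animal: int = 20
    n_plant_homologs: int = 5
    n_plant_decoys: int = 15
    seq_length: int = 22
    n_mutations_outside_seed: int = 2
    composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed_region: SeedRegion = SeedRegion()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_animal, self.n_plant_homologs, self.n_plant_decoys) < 0:
            raise ValueError("library counts must be >= 0")
        if self.n_plant_homologs > self.n_animal:
            raise ValueError(
                f"cannot plant {self.n_plant_homologs} homologs from "
                f"{self.n_animal} animal sequences"
            )
        if self.seq_length <= self.seed_region.end:
            raise ValueError("seq_length must exceed the seed region end")
        comp = np.asarray(self.composition, dtype=float)
        if comp.shape != (4,) or np.any(comp < 0) or abs(comp.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"composition must be 4 non-negative probabilities summing to 1, "
                f"got {self.composition}"
            )


def _random_sequence(length: int, composition, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_NUCS, size=length, p=list(composition)))


def random_library(
    n: int,
    spec: FixtureSpec,
    kingdom: Kingdom | str,
    rng: np.random.Generator | None = None,
    prefix: str | None = None,
) -> MiRNALibrary:
    """n i.i.d. random sequences drawn from spec.composition."""
    if n < 1:
        raise ValueError("a library needs at least one record")
    kingdom = Kingdom(kingdom)
    rng = rng if rng is not None else np.random.default_rng(spec.rng_seed)
    prefix = prefix or ("pla-miR" if kingdom is Kingdom.PLANT else "ani-miR")
    records = [
        MiRNARecord(
            id=f"{prefix}-{i + 1}",
            kingdom=kingdom,
            sequence=_random_sequence(spec.seq_length, spec.composition, rng),
        )
        for i in range(n)
    ]
    return MiRNALibrary(records=records, kingdom=kingdom, source_path="<synthetic>")


def plant_homolog(
    animal: MiRNARecord,
    spec: FixtureSpec,
    rng: np.random.Generator,
    new_id: str,
) -> MiRNARecord:
    """A plant copy of an animal miRNA, mutated only outside the seed.

    Exactly ``spec.n_mutations_outside_seed`` substitutions are placed at
    distinct non-seed positions, each to a different nucleotide, so the
    Hamming distance to the template is exactly that count and the seed
    window is untouched.
    """
    if len(animal.sequence) != spec.seq_length:
        raise ValueError(
            f"animal record {animal.id!r} has length {len(animal.sequence)}, "
            f"spec expects {spec.seq_length}"
        )
    region = spec.seed_region
    non_seed = [
        i for i in range(spec.seq_length) if not region.start - 1 <= i <= region.end - 1
    ]
    if spec.n_mutations_outside_seed > len(non_seed):
        raise ValueError(
            f"{spec.n_mutations_outside_seed} mutations requested but only "
            f"{len(non_seed)} non-seed positions exist"
        )
    seq = list(animal.sequence)
    sites = rng.choice(len(non_seed), size=spec.n_mutations_outside_seed, replace=False)
    for s in sites:
        pos = non_seed[int(s)]
        alternatives = [n for n in _NUCS if n != seq[pos]]
        seq[pos] = alternatives[int(rng.integers(len(alternatives)))]
    return MiRNARecord(
        id=new_id, kingdom=Kingdom.PLANT, sequence="".join(seq),
        description=f"homolog of {animal.id}",
    )


def make_screen_fixture(
    spec: FixtureSpec = FixtureSpec(),
) -> tuple[MiRNALibrary, MiRNALibrary, set[tuple[str, str]]]:
    """Build (plant, animal, truth) libraries for a planted-homolog screen.

    The animal library is random; the plant library holds homologs of the
    first ``n_plant_homologs`` animal records followed by fresh random
    decoys; truth lists the planted (plant_id, animal_id) pairs. Fully
    deterministic under ``spec.rng_seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence((int(spec.rng_seed) & 0x7FFFFFFF,)))
    animal = random_library(spec.n_animal, spec, Kingdom.ANIMAL, rng=rng)
    plant_records: list[MiRNARecord] = []
    truth: set[tuple[str, str]] = set()
    for i in range(spec.n_plant_homologs):
        template = animal[i]
        rec = plant_homolog(template, spec, rng, new_id=f"pla-miR-{i + 1}")
        plant_records.append(rec)
        truth.add((rec.id, template.id))
    for j in range(spec.n_plant_decoys):
        plant_records.append(
            MiRNARecord(
                id=f"pla-miR-{spec.n_plant_homologs + j + 1}",
                kingdom=Kingdom.PLANT,
                sequence=_random_sequence(spec.seq_length, spec.composition, rng),
                description="decoy",
            )
        )
    if not plant_records:
        raise ValueError("fixture needs at least one plant record")
    plant = MiRNALibrary(records=plant_records, kingdom=Kingdom.PLANT,
                         source_path="<synthetic>")
    return plant, animal, truth


def write_fixture(
    spec: FixtureSpec, outdir: str | Path
) -> tuple[Path, Path, Path]:
    """Write plant.fa, animal.fa and truth.tsv for a fixture spec."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    plant, animal, truth = make_screen_fixture(spec)
    plant_fa = outdir / "plant.fa"
    animal_fa = outdir / "animal.fa"
    truth_tsv = outdir / "truth.tsv"
    write_fasta(plant, plant_fa)
    write_fasta(animal, animal_fa)
    with open(truth_tsv, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("plant_id\tanimal_id\n")
        for plant_id, animal_id in sorted(truth):
            fh.write(f"{plant_id}\t{animal_id}\n")
    return plant_fa, animal_fa, truth_tsv
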