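"""Reading and writing miRNA libraries and result tables.

Mature-miRNA libraries arrive as FASTA (the de-facto miRBase distribution
format) in either the RNA or DNA alphabet; everything downstream of this
module sees a strictly normalized RNA alphabet {A, C, G, U}. Result tables
are plain TSV with UTF-8 encoding, LF line endings and '.' decimals, so
they diff cleanly and load into any spreadsheet or DataFrame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

__all__ = [
    "Kingdom",
    "MiRNARecord",
    "MiRNALibrary",
    "normalize_sequence",
    "read_fasta",
    "write_fasta",
    "write_results_tsv",
    "read_results_tsv",
    "read_target_table",
]

RNA_ALPHABET = frozenset("ACGU")

#: mature miRNAs are typically 16-30 nt; far outside that suggests the wrong
#: input (hairpins, fragments) but is not fatal to the arithmetic.
_LENGTH_SOFT_RANGE = (10, 50)


class Kingdom(str, Enum):
    """Which side of the cross-kingdom comparison a sequence belongs to."""

    PLANT = "plant"
    ANIMAL = "animal"


def normalize_sequence(raw: str, *, record_id: str = "<sequence>") -> str:
    """Uppercase, convert T to U, and enforce the {A,C,G,U} alphabet.

    Ambiguity codes (N, R, ...) are rejected: match/mismatch scoring is
    defined only over concrete nucleotides.
    """
    seq = raw.strip().upper().replace("T", "U")
    if not seq:
        raise ValueError(f"record {record_id!r}: empty sequence")
    for pos, ch in enumerate(seq, start=1):
        if ch not in RNA_ALPHABET:
            raise ValueError(
                f"record {record_id!r}: invalid character {ch!r} at position "
                f"{pos}; only A/C/G/U (or T, converted to U) are accepted"
            )
    return seq


@dataclass(frozen=True)
class MiRNARecord:
    """One mature miRNA: identifier, kingdom tag and normalized RNA sequence."""

    id: str
    kingdom: Kingdom
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(
                f"record id {self.id!r} is empty or contains whitespace "
                "(ids must be TSV-safe)"
            )
        seq = normalize_sequence(self.sequence, record_id=self.id)
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "kingdom", Kingdom(self.kingdom))
        lo, hi = _LENGTH_SOFT_RANGE
        if not lo <= len(seq) <= hi:
            warnings.warn(
                f"record {self.id!r} has length {len(seq)} nt, outside the "
                f"typical mature-miRNA range [{lo}, {hi}]",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class MiRNALibrary:
    """An ordered, id-unique collection of miRNAs from one kingdom."""

    records: list[MiRNARecord]
    kingdom: Kingdom
    source_path: str = ""

    def __post_init__(self) -> None:
        self.kingdom = Kingdom(self.kingdom)
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate miRNA id {rec.id!r} in library")
            seen.add(rec.id)
            if rec.kingdom != self.kingdom:
                raise ValueError(
                    f"record {rec.id!r} is tagged {rec.kingdom.value}, "
                    f"library is {self.kingdom.value}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MiRNARecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> MiRNARecord:
        return self.records[i]

    def ids(self) -> list[str]:
        return [r.id for r in self.records]


def read_fasta(path: str | Path, kingdom: Kingdom | str) -> MiRNALibrary:
    """Read a FASTA miRNA library, normalizing sequences to RNA uppercase.

    The id is the first whitespace-delimited header token; the remainder is
    kept as a free-text description. Duplicate ids, an empty file, and
    non-ACGTU characters are hard errors.
    """
    path = Path(path)
    kingdom = Kingdom(kingdom)
    records: list[MiRNARecord] = []
    for seq_rec in SeqIO.parse(str(path), "fasta"):
        desc = seq_rec.description
        if desc.startswith(seq_rec.id):
            desc = desc[len(seq_rec.id):].strip()
        records.append(
            MiRNARecord(
                id=seq_rec.id,
                kingdom=kingdom,
                sequence=str(seq_rec.seq),
                description=desc,
            )
        )
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return MiRNALibrary(records=records, kingdom=kingdom, source_path=str(path))


def write_fasta(library: MiRNALibrary, path: str | Path) -> None:
    """Write a library as unwrapped FASTA (one sequence per line)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in library:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n{rec.sequence}\n")


_RESULT_COLUMNS = (
    "plant_id",
    "animal_id",
    "S_global",
    "S_seed",
    "null_mean_global",
    "null_sd_global",
    "null_mean_seed",
    "null_sd_seed",
    "p_global",
    "p_seed",
    "selected",
)


def _fmt(x: float) -> str:
    return format(float(x), ".6g")


def write_results_tsv(results: Iterable, path: str | Path) -> None:
    """Write comparison results as TSV, one row per plant x animal pair.

    Floats are rendered with 6 significant digits; row order follows the
    input; an empty collection writes the header line only. The output is
    byte-identical for identical results, which makes whole-screen runs
    diffable.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_RESULT_COLUMNS) + "\n")
        for r in results:
            fh.write(
                "\t".join(
                    (
                        r.plant_id,
                        r.animal_id,
                        _fmt(r.s_global),
                        _fmt(r.s_seed),
                        _fmt(r.null_global.mean),
                        _fmt(r.null_global.sd),
                        _fmt(r.null_seed.mean),
                        _fmt(r.null_seed.sd),
                        _fmt(r.p_global),
                        _fmt(r.p_seed),
                        "true" if r.selected else "false",
                    )
                )
                + "\n"
            )


def read_results_tsv(path: str | Path):
    """Load a results TSV back into a pandas DataFrame (typed columns)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"plant_id": str, "animal_id": str})
    if list(df.columns) != list(_RESULT_COLUMNS):
        raise ValueError(f"{path}: unexpected result columns {list(df.columns)}")
    df["selected"] = df["selected"].map({"true": True, "false": False, True: True, False: False})
    return df


def read_target_table(path: str | Path) -> dict[str, list[str]]:
    """Parse a miRNA -> target-gene TSV into an ordered mapping.

    Each row is ``animal_miRNA_id<TAB>gene`` (one gene per row) or
    ``animal_miRNA_id<TAB>gene1,gene2,...``. Gene order within a miRNA is
    preserved so pre-ranked tables (e.g. ranked by experimental support)
    stay ranked. Malformed rows are skipped with a warning naming the line.
    """
    table: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                warnings.warn(f"{path}: skipping malformed row at line {lineno}")
                continue
            mirna = parts[0].strip()
            genes = [g.strip() for g in parts[1].split(",") if g.strip()]
            bucket = table.setdefault(mirna, [])
            for g in genes:
                if g not in bucket:
                    bucket.append(g)
    return table
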