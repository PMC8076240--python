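"""Overrepresentation analysis (ORA) of predicted target-gene lists.

Given the set of genes a screened plant miRNA is predicted to target, ORA
asks which annotated gene sets (pathways, ontology terms, signatures)
contain more of those genes than expected when drawing the same number of
genes at random from a background universe. The tail probability is the
hypergeometric P(X >= k) with population N (universe), K successes (term
genes in the universe) and n draws (query genes in the universe); raw
p-values are adjusted across all tested terms, Benjamini-Hochberg by
default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "EnrichmentRow",
    "read_gmt",
    "hypergeometric_test",
    "enrich",
    "write_enrichment_tsv",
]

AdjustMethod = Literal["BH", "bonferroni", "none"]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets: term_id -> (term_name, frozenset of gene symbols)."""

    sets: Mapping[str, tuple[str, frozenset[str]]]
    source_name: str = ""

    def __post_init__(self) -> None:
        for term_id, (_, genes) in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {term_id!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for _, genes in self.sets.values():
            out |= genes
        return frozenset(out)


@dataclass(frozen=True)
class EnrichmentRow:
    """One tested term: overlap counts, hypergeometric p, adjusted p."""

    term_id: str
    term_name: str
    k: int            # query genes in the term
    n_query: int      # query genes in the universe
    K: int            # term genes in the universe
    N: int            # universe size
    p: float
    p_adj: float
    overlap_genes: tuple[str, ...]

    @property
    def gene_ratio(self) -> float:
        return self.k / self.n_query


def read_gmt(path: str | Path, source_name: str | None = None) -> GeneSetCollection:
    """Parse a GMT file: term_id <TAB> description <TAB> gene1 <TAB> gene2 ...

    Genes are uppercased and deduplicated within a set. Lines with fewer
    than three fields are skipped with a warning; a duplicate term_id is a
    hard error.
    """
    path = Path(path)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                warnings.warn(f"{path}: line {lineno} has fewer than 3 fields; skipped")
                continue
            term_id, desc = parts[0], parts[1]
            if term_id in sets:
                raise ValueError(f"{path}: duplicate term id {term_id!r} at line {lineno}")
            genes = frozenset(g.strip().upper() for g in parts[2:] if g.strip())
            if genes:
                sets[term_id] = (desc, genes)
    return GeneSetCollection(sets=sets, source_name=source_name or path.name)


def hypergeometric_test(
    query: Iterable[str], term_set: Iterable[str], universe: Iterable[str]
) -> tuple[int, int, int, int, float]:
    """Upper-tail hypergeometric overlap test.

    Returns (k, K, n, N, p) with p = P(X >= k), X ~ Hypergeom(N, K, n).
    Query genes outside the universe are dropped with a warning; the term
    set is silently intersected with the universe.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("gene universe is empty")
    query = frozenset(query)
    outside = query - universe
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the universe dropped "
            f"(e.g. {sorted(outside)[:3]})"
        )
    query &= universe
    if not query:
        raise ValueError("query is empty after intersection with the universe")
    term = frozenset(term_set) & universe
    k = len(query & term)
    K, n, N = len(term), len(query), len(universe)
    # P(X >= k) == sf(k - 1); k = 0 gives p = 1 exactly
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return k, K, n, N, min(p, 1.0)


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str] | None = None,
    top: int = 50,
    method: AdjustMethod = "BH",
) -> list[EnrichmentRow]:
    """Test every term in the collection against the query gene list.

    The universe defaults to the union of all genes in the collection.
    Every term with at least one gene in the universe is tested and counts
    toward the multiple-testing burden m; terms with zero query overlap
    are then dropped from the output (but not from m — dropping them from
    m would inflate significance). Rows are sorted by (p_adj, p, term_id)
    ascending and truncated to ``top``.
    """
    universe_set = frozenset(universe) if universe is not None else collection.all_genes()
    query_set = frozenset(g.upper() for g in query)

    tested: list[tuple[str, str, int, int, int, int, float, tuple[str, ...]]] = []
    for term_id, (term_name, genes) in collection.sets.items():
        if not genes & universe_set:
            continue
        k, K, n, N, p = hypergeometric_test(query_set, genes, universe_set)
        overlap = tuple(sorted(query_set & genes & universe_set))
        tested.append((term_id, term_name, k, n, K, N, p, overlap))
    if not tested:
        return []

    raw_p = [t[6] for t in tested]
    if method == "BH":
        adj = multipletests(raw_p, method="fdr_bh")[1]
    elif method == "bonferroni":
        adj = np.minimum(np.asarray(raw_p) * len(raw_p), 1.0)
    elif method == "none":
        adj = np.asarray(raw_p)
    else:
        raise ValueError(f"unknown adjustment method {method!r}")

    rows = [
        EnrichmentRow(
            term_id=t[0],
            term_name=t[1],
            k=t[2],
            n_query=t[3],
            K=t[4],
            N=t[5],
            p=t[6],
            p_adj=float(q),
            overlap_genes=t[7],
        )
        for t, q in zip(tested, adj)
        if t[2] >= 1
    ]
    rows.sort(key=lambda r: (r.p_adj, r.p, r.term_id))
    return rows[:top]


def write_enrichment_tsv(rows: Iterable[EnrichmentRow], path: str | Path) -> None:
    """Tabular export mirroring the EnrichmentRow fields."""
    header = (
        "term_id\tterm_name\tk\tn_query\tK\tN\tgene_ratio\tp\tp_adj\toverlap_genes\n"
    )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(header)
        for r in rows:
            fh.write(
                f"{r.term_id}\t{r.term_name}\t{r.k}\t{r.n_query}\t{r.K}\t{r.N}\t"
                f"{format(r.gene_ratio, '.6g')}\t{format(r.p, '.6g')}\t"
                f"{format(r.p_adj, '.6g')}\t{','.join(r.overlap_genes)}\n"
            )
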