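"""Transfer target genes to selected plant miRNAs and test for
overrepresentation.

A selected plant miRNA inherits its animal homolog's experimentally
supported target genes; the pooled gene list is then tested against a
tiny gene-set collection with the hypergeometric upper tail and
Benjamini-Hochberg adjustment.
"""

from mirhomology import GeneSetCollection, enrich, join_targets
from mirhomology.screen import ComparisonResult
from mirhomology.significance import NullDistribution

# two selected pairs, as the screen would report them
null = NullDistribution.from_scores([0.3, 0.4, 0.5, 0.6])
selected = [
    ComparisonResult("pla-miR-1", "ani-miR-1", 0.91, 7.0, null, null,
                     1e-6, 1e-4, selected=True),
    ComparisonResult("pla-miR-2", "ani-miR-3", 0.86, 7.0, null, null,
                     1e-4, 1e-3, selected=True),
]
target_table = {
    "ani-miR-1": ["TP53", "CDKN1A", "BAX"],
    "ani-miR-3": ["BAX", "IL6", "TNF"],
}
pairs = join_targets(selected, target_table)
query = sorted({gene for _, gene in pairs})
print(f"{len(pairs)} (plant miRNA, gene) pairs -> query of {len(query)} genes: {query}")

collection = GeneSetCollection(sets={
    "APOPTOSIS": ("apoptosis signalling", frozenset({"TP53", "BAX", "CASP3", "BCL2"})),
    "INFLAMMATION": ("inflammatory response", frozenset({"IL6", "TNF", "NFKB1", "IL1B"})),
    "GLYCOLYSIS": ("glycolysis", frozenset({"HK1", "PFKM", "PKM", "ENO1"})),
})
# the universe is every gene that could have appeared in the target table:
# the collection's genes plus a background of other assayable genes
background = [f"BG{i}" for i in range(40)]
universe = sorted(collection.all_genes() | set(query) | set(background))

for row in enrich(query, collection, universe=universe):
    print(f"{row.term_id:<14} k={row.k}/{row.n_query} K={row.K} N={row.N} "
          f"p={row.p:.4f} p_adj={row.p_adj:.4f} overlap={','.join(row.overlap_genes)}")

print("\nk of n_query query genes fall in a K-gene set drawn from an N-gene")
print("universe; small p_adj marks gene sets overrepresented among the")
print("predicted targets of the selected plant miRNAs.")
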