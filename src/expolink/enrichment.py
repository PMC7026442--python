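"""Over-representation analysis of a query gene set against GMT libraries.

For each term the one-sided (greater) Fisher exact test is applied to the
2x2 table (overlap, query-only, term-only, neither) over a background
universe; p-values are BH-adjusted within one library.  This is the
statistical core behind pathway/ontology enrichment tables; library
snapshots (KEGG, GO, ...) are supplied by the user as GMT files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust


class GmtParseError(ValueError):
    """Malformed GMT gene-set library."""


@dataclass(frozen=True)
class GeneSetTerm:
    term: str
    term_id: str
    genes: frozenset


@dataclass(eq=False)
class GeneSetLibrary:
    """Named collection of gene-set terms with a background universe size."""

    name: str
    terms: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t in self.terms.values():
            if not t.genes:
                raise ValueError(f"library {self.name!r}: term {t.term!r} has no genes")

    @property
    def universe(self) -> frozenset:
        out: frozenset = frozenset()
        for t in self.terms.values():
            out = out | t.genes
        return out

    @property
    def background_size(self) -> int:
        return len(self.universe)


def load_gmt(path, name: str | None = None) -> GeneSetLibrary:
    """Parse a GMT file: term <tab> description <tab> gene1 <tab> gene2 ..."""
    terms: dict[str, GeneSetTerm] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(f"{path}: line {i}: expected >=3 fields, got {len(fields)}")
            term, term_id = fields[0], fields[1]
            if term in terms:
                raise GmtParseError(f"{path}: line {i}: duplicated term {term!r}")
            genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            if not genes:
                raise GmtParseError(f"{path}: line {i}: term {term!r} has no genes")
            terms[term] = GeneSetTerm(term, term_id, genes)
    return GeneSetLibrary(name or str(path), terms)


def write_gmt(library: GeneSetLibrary, path) -> None:
    with open(path, "w") as fh:
        for term in sorted(library.terms):
            t = library.terms[term]
            fh.write("\t".join([t.term, t.term_id, *sorted(t.genes)]) + "\n")


def fisher_enrichment(query, library: GeneSetLibrary,
                      background_n: int | None = None) -> pd.DataFrame:
    """Rank library terms by one-sided Fisher exact over-representation.

    Background defaults to the union of all genes in the library.  Rows are
    sorted by adjusted p, then raw p, then term name.
    """
    query = frozenset(str(g).upper() for g in query)
    if not query:
        raise ValueError("empty query gene set")
    universe = library.universe
    n_bg = background_n if background_n is not None else len(universe)
    rows = []
    for term in sorted(library.terms):
        t = library.terms[term]
        if len(query | t.genes) > n_bg:
            raise ValueError(
                f"background ({n_bg}) smaller than observed union for term {term!r}"
            )
        overlap = query & t.genes
        k, q, m = len(overlap), len(query), len(t.genes)
        # P(X >= k) for X ~ Hypergeom(n_bg, m, q)
        p = float(stats.hypergeom.sf(k - 1, n_bg, m, q))
        a, b, c, d = k, q - k, m - k, n_bg - q - m + k
        odds = (a * d) / (b * c) if b * c > 0 else float("inf")
        rows.append({
            "term": t.term, "term_id": t.term_id,
            "overlap_genes": ",".join(sorted(overlap)),
            "overlap": k, "term_size": m, "odds_ratio": odds, "p": p,
        })
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    table = table.sort_values(["p_adj", "p", "term"], kind="stable").reset_index(drop=True)
    return table


def write_enrichment(table: pd.DataFrame, path, top_k: int | None = None) -> None:
    """TSV mirroring the usual enrichment-table layout (term, genes, adjusted p)."""
    out = table if top_k is None else table.head(top_k)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
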