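"""Hypergeometric over-representation analysis of gene classes against
user-supplied gene-set collections (GMT format).

For a universe of ``N`` background genes, a set of ``K`` members and a query
of ``n`` genes with ``k`` overlapping, the enrichment p-value is the upper
hypergeometric tail ``P(X >= k)``.  Adjusted p-values are Benjamini-Hochberg
within each query (one gene class at a time).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .errors import ConfigurationError, FormatError


@dataclass
class GeneSet:
    name: str
    description: str
    genes: list[str]


@dataclass
class GeneSetCollection:
    sets: dict[str, GeneSet]
    universe: list[str]

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path, universe: Sequence[str] | None = None) -> GeneSetCollection:
    """Parse a GMT file: per line ``name<TAB>description<TAB>member...``.

    Duplicate members within a set are dropped; when a universe is supplied,
    members outside it are removed and sets left empty are discarded with a
    warning.  The default universe is the union of all members.
    """
    sets: dict[str, GeneSet] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and >= 1 member"
                )
            name, description, *members = fields
            members = list(dict.fromkeys(m for m in members if m))
            sets[name] = GeneSet(name=name, description=description, genes=members)

    if universe is None:
        uni = list(dict.fromkeys(g for s in sets.values() for g in s.genes))
    else:
        uni = list(dict.fromkeys(str(g) for g in universe))
        uniset = set(uni)
        kept: dict[str, GeneSet] = {}
        for name, s in sets.items():
            genes = [g for g in s.genes if g in uniset]
            if genes:
                kept[name] = GeneSet(name=name, description=s.description, genes=genes)
            else:
                warnings.warn(f"gene set {name!r} has no members in the universe; dropped")
        sets = kept
    return GeneSetCollection(sets=sets, universe=uni)


@dataclass
class EnrichmentResult:
    query_name: str
    table: pd.DataFrame  # one row per set, BH-adjusted within this query

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p_adj"] <= alpha]


def hypergeometric_ora(
    query: Iterable[str],
    collection: GeneSetCollection,
    query_name: str = "query",
) -> EnrichmentResult:
    """Upper-tail hypergeometric over-representation test of ``query``.

    Query genes outside the universe are dropped with a warning (matching the
    background-restriction convention of standard ORA tools).
    """
    if not collection.universe:
        raise ConfigurationError("empty universe")
    uni = set(collection.universe)
    query = list(dict.fromkeys(str(g) for g in query))
    inside = [g for g in query if g in uni]
    if len(inside) < len(query):
        warnings.warn(
            f"{len(query) - len(inside)} query gene(s) outside the universe were dropped"
        )
    N, n = len(uni), len(inside)
    qset = set(inside)
    rows = []
    for name, s in collection.sets.items():
        K = len(s.genes)
        overlap = sorted(qset & set(s.genes))
        k = len(overlap)
        # P(X >= k) for X ~ Hypergeom(N, K, n); sf(k-1) is the closed form
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append(
            {
                "set": name,
                "description": s.description,
                "set_size": K,
                "query_size": n,
                "universe_size": N,
                "overlap": k,
                "overlap_genes": ",".join(overlap),
                "p": min(p, 1.0),
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adj"] = bh_adjust(table["p"].to_numpy())
        table = table.sort_values(["p", "set"], kind="stable").reset_index(drop=True)
    else:
        table["p_adj"] = []
    return EnrichmentResult(query_name=query_name, table=table)


def enrich_clusters(
    cluster_members: Mapping[str, Sequence[str]],
    collection: GeneSetCollection,
) -> dict[str, EnrichmentResult]:
    """Run ORA for every gene class; BH correction is within each class."""
    return {
        label: hypergeometric_ora(genes, collection, query_name=label)
        for label, genes in cluster_members.items()
    }
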