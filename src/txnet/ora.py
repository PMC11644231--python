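"""Hypergeometric over-representation analysis (ORA) of gene lists.

Given a query gene list, a GMT collection of annotated gene sets and a
background universe of *N* genes, each term with *K* annotated genes is
tested for enrichment of the *n*-gene query via the upper-tail
hypergeometric probability P(X >= k), where *k* is the observed overlap.
Per-term results carry a Benjamini–Hochberg FDR across all tested terms
and the fold enrichment (k/n) / (K/N).  The ranked report filters at an
FDR cutoff and sorts by fold enrichment, the convention used to surface
the most specific terms first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom

from txnet.deg import bh_adjust

__all__ = ["GeneSet", "read_gmt", "write_gmt", "hypergeom_enrichment", "enrich_report"]


@dataclass(frozen=True)
class GeneSet:
    term: str
    description: str
    members: frozenset


def read_gmt(path) -> dict[str, GeneSet]:
    """Parse a GMT file into term -> GeneSet.

    Each line: ``term<TAB>description<TAB>member1<TAB>member2...``.
    Duplicate members are deduplicated; a line with fewer than 3 fields or
    no members raises a ValueError naming the line.
    """
    collection: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line {lineno}: fewer than 3 fields")
            term, description = fields[0], fields[1]
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise ValueError(f"malformed GMT line {lineno}: empty gene set {term!r}")
            collection[term] = GeneSet(term, description, members)
    return collection


def write_gmt(collection: Mapping[str, GeneSet], path) -> None:
    with open(path, "w") as fh:
        for term in collection:
            gs = collection[term]
            fh.write("\t".join([gs.term, gs.description, *sorted(gs.members)]) + "\n")


def hypergeom_enrichment(
    query: Iterable[str],
    collection: Mapping[str, GeneSet],
    background: Iterable[str],
) -> pd.DataFrame:
    """Per-term enrichment of ``query`` against ``collection``.

    Every set is intersected with the background before testing; the query
    is likewise restricted to the background.  Terms with no member in the
    background are skipped.

    Returns a DataFrame with columns ``term, description, K, n, k, N,
    pvalue, fdr, fold_enrichment`` in collection order.
    """
    bg = set(background)
    q = set(query)
    if not q:
        raise ValueError("empty query gene list")
    if not bg:
        raise ValueError("empty background universe")
    stray = q - bg
    if stray:
        q &= bg
        if not q:
            raise ValueError("query has no gene in the background universe")
    n, N = len(q), len(bg)

    rows = []
    for term, gs in collection.items():
        members = gs.members & bg
        K = len(members)
        if K == 0:
            continue
        k = len(members & q)
        p = float(hypergeom.sf(k - 1, N, K, n))
        fe = (k / n) / (K / N)
        rows.append((term, gs.description, K, n, k, N, min(p, 1.0), fe))
    if not rows:
        raise ValueError("no term overlaps the background universe")
    df = pd.DataFrame(
        rows, columns=["term", "description", "K", "n", "k", "N", "pvalue", "fold_enrichment"]
    )
    df["fdr"] = bh_adjust(df["pvalue"].to_numpy())
    return df[["term", "description", "K", "n", "k", "N", "pvalue", "fdr", "fold_enrichment"]]


def enrich_report(records: pd.DataFrame, fdr_max: float = 0.05) -> pd.DataFrame:
    """Significant terms sorted by fold enrichment after FDR.

    Filters at ``fdr <= fdr_max``; sorts by fold enrichment descending,
    ties broken by FDR ascending then term id.
    """
    out = records[records["fdr"] <= fdr_max].sort_values(
        ["fold_enrichment", "fdr", "term"], ascending=[False, True, True], kind="stable"
    )
    return out.reset_index(drop=True)
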