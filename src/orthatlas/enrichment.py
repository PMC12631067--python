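"""Hypergeometric over-representation analysis against GMT gene sets.

For a query gene list and a named collection of gene sets restricted to a
background universe, the enrichment p-value of a set is the upper tail of
the hypergeometric distribution — the probability of drawing at least the
observed overlap k when n query genes are sampled from a universe of N
genes containing K set members — BH-adjusted across the tested sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneSetCollection:
    sets: dict[str, frozenset[str]]
    universe: frozenset[str]

    def restrict(self, universe) -> "GeneSetCollection":
        """Intersect every set with a new universe."""
        uni = frozenset(universe)
        return GeneSetCollection(
            sets={name: s & uni for name, s in self.sets.items()}, universe=uni
        )


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (name, description, members...); members deduplicated."""
    sets: dict[str, frozenset[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line {lineno}: expected name, description, members")
        name = parts[0].strip()
        if not name:
            raise ValueError(f"GMT line {lineno}: empty set name")
        if name in sets:
            raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
        members = frozenset(g for g in parts[2:] if g)
        sets[name] = members
    universe = frozenset().union(*sets.values()) if sets else frozenset()
    return GeneSetCollection(sets=sets, universe=universe)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, "", *sorted(members)])
        for name, members in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def hypergeom_ora(query, sets: GeneSetCollection, universe=None) -> pd.DataFrame:
    """Upper-tail hypergeometric ORA of a query against each named set.

    ``universe`` defaults to the collection's own universe; the query and
    every set are restricted to it first.  Returns a DataFrame with columns
    term, k, K, n, N, p, q sorted by ascending q.
    """
    uni = frozenset(universe) if universe is not None else sets.universe
    if not uni:
        raise ValueError("empty universe")
    q = frozenset(query) & uni
    if not q:
        raise ValueError("query does not intersect the universe")
    coll = sets.restrict(uni)
    N, n = len(uni), len(q)
    rows = []
    for term, members in coll.sets.items():
        K = len(members)
        k = len(q & members)
        p = float(st.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, n, N, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.sort_values(["q", "p", "term"]).reset_index(drop=True)
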