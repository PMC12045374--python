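"""Hypergeometric over-representation analysis (ORA) of gene groups.

For a query gene list (e.g. the Group I paused genes) and a collection of
annotation gene sets, the upper-tail hypergeometric probability

    p = P[X >= k],  X ~ Hypergeom(N=universe, K=set size, n=query size)

asks how surprising the observed overlap ``k`` is if the query were drawn
uniformly from the universe. p-values are Benjamini-Hochberg adjusted
across all tested sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ParseError, ValidationError


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} is empty")


def read_gmt(path: str) -> list[GeneSet]:
    """Read gene sets from GMT (name, description, members...) lines."""
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    "GMT line needs name, description and >=1 member", path, lineno
                )
            name = fields[0]
            if name in seen:
                raise ValidationError(f"duplicate gene set name {name!r} in {path}")
            seen.add(name)
            members = frozenset(g for g in fields[2:] if g)
            if not members:
                raise ParseError(f"gene set {name!r} has no members", path, lineno)
            sets.append(GeneSet(name, members))
    return sets


def write_gmt(sets: list[GeneSet], path: str, description: str = "pausekit") -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, description, *sorted(s.members)]) + "\n")


def hypergeom_ora(
    query: set[str],
    sets: list[GeneSet],
    universe: set[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric test of each gene set against the query.

    Each set is intersected with the universe before testing; the query
    must be a subset of the universe. Returns one row per set with the raw
    p-value and the BH-adjusted value, sorted by adjusted then raw p-value
    (name-tie-broken, so output order is deterministic).
    """
    query = set(query)
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    if not query:
        raise ValidationError("empty query")
    if not query <= universe:
        extra = sorted(query - universe)[:5]
        raise ValidationError(
            f"query contains genes outside the universe (e.g. {extra})"
        )
    rows = []
    for s in sets:
        members = s.members & universe
        if not members:
            continue
        k = len(query & members)
        # P[X >= k] via the survival function at k-1
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(members), len(query)))
        rows.append((s.name, k, len(members), len(query), len(universe), min(p, 1.0)))
    if not rows:
        raise ValidationError("no gene set overlaps the universe")
    df = pd.DataFrame(
        rows,
        columns=["set_name", "overlap", "set_size", "query_size",
                 "universe_size", "p_value"],
    )
    df["adjusted_p"] = multipletests(df["p_value"], method="fdr_bh")[1]
    df = df.sort_values(
        ["adjusted_p", "p_value", "set_name"], kind="stable"
    ).reset_index(drop=True)
    return df
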