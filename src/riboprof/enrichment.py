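"""Gene-set over-representation and cross-list overlap.

Over-representation is a one-sided (upper-tail) hypergeometric test per
set with Benjamini-Hochberg correction across sets — an explicit,
reproducible replacement for web-tool GO analysis.  No EASE-style score
adjustment and no GO-DAG propagation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .difftrans import bh_fdr
from .errors import ConfigurationError


@dataclass
class GeneSetCollection:
    """Named gene sets over a universe; members outside the universe are
    dropped at harmonization time, duplicates removed (order preserved)."""

    sets: dict[str, list[str]]
    universe: list[str]

    def __post_init__(self):
        self.universe = list(dict.fromkeys(self.universe))
        uni = set(self.universe)
        self.sets = {name: [g for g in dict.fromkeys(members) if g in uni]
                     for name, members in self.sets.items()}


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    fold_enrichment: float
    p_value: float
    q_value: float


def read_gmt(path, universe: Sequence[str] | None = None) -> GeneSetCollection:
    """Parse a GMT file (name <tab> description <tab> members...).

    Malformed lines (fewer than 3 fields) are reported with their line
    numbers and skipped; an empty file is an error.  If no universe is
    given, the union of all set members is used.
    """
    sets: dict[str, list[str]] = {}
    bad: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                bad.append(lineno)
                continue
            name, _desc, *members = fields
            members = [m for m in members if m]
            deduped = list(dict.fromkeys(members))
            if len(deduped) < len(members):
                warnings.warn(f"GMT line {lineno} ({name}): duplicate members removed")
            sets[name] = deduped
    if bad:
        warnings.warn(f"GMT: skipped malformed lines {bad}")
    if not sets:
        raise ConfigurationError(f"no gene sets parsed from {path}")
    if universe is None:
        universe = [g for members in sets.values() for g in members]
    return GeneSetCollection(sets=sets, universe=list(universe))


def write_gmt(collection: GeneSetCollection, path,
              descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def hypergeometric_enrichment(query: Iterable[str],
                              collection: GeneSetCollection
                              ) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric p of >= observed overlap, per set.

    Query genes outside the universe are dropped with a warning; q-values
    are BH across the collection's sets.
    """
    uni = set(collection.universe)
    query = list(dict.fromkeys(query))
    outside = [g for g in query if g not in uni]
    if outside:
        warnings.warn(f"{len(outside)} query gene(s) outside the universe dropped")
    query_set = set(query) & uni
    if not query_set:
        raise ConfigurationError("query is empty after harmonization")

    M = len(collection.universe)
    N = len(query_set)
    rows = []
    for name, members in collection.sets.items():
        n = len(members)
        k = len(query_set & set(members))
        # P(X >= k) for X ~ Hypergeom(M, n, N)
        p = float(stats.hypergeom.sf(k - 1, M, n, N))
        p = min(max(p, 5e-324), 1.0)
        fold = (k / N) / (n / M) if n else float("nan")
        rows.append((name, k, n, fold, p))
    qs = bh_fdr([r[4] for r in rows])
    return [EnrichmentResult(set_name=name, overlap=k, set_size=n,
                             query_size=N, universe_size=M,
                             fold_enrichment=fold, p_value=p, q_value=float(q))
            for (name, k, n, fold, p), q in zip(rows, qs)]


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


@dataclass(frozen=True)
class OverlapResult:
    fraction_a_in_b: float
    jaccard: float
    n_common: int


def overlap_fraction(list_a: Iterable[str], list_b: Iterable[str]) -> OverlapResult:
    """|a intersect b| / |a| and the Jaccard index (duplicates ignored)."""
    a = set(list_a)
    b = set(list_b)
    if not a:
        raise ConfigurationError("list_a must be nonempty")
    common = a & b
    union = a | b
    return OverlapResult(fraction_a_in_b=len(common) / len(a),
                         jaccard=len(common) / len(union),
                         n_common=len(common))
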