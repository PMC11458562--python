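"""Local gene-set over-representation analysis.

Fisher's exact test (one-sided, over-representation) of a query gene list
against GMT-style gene sets, with Haldane-Anscombe-corrected odds ratios
and Benjamini-Hochberg q-values.  The background universe defaults to the
union of all genes appearing in the collection.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection", "EnrichmentRow",
    "read_gmt", "map_snps_to_genes", "fisher_enrichment", "bh_adjust",
]


@dataclass
class GeneSetCollection:
    """Named gene sets with ontology tags and a background universe."""

    sets: dict[str, frozenset[str]]
    ontology: dict[str, str] = field(default_factory=dict)
    universe: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        bad = {name for name, genes in self.sets.items() if not genes}
        if bad:
            raise ValueError(f"empty gene sets: {sorted(bad)}")
        if not self.universe:
            self.universe = frozenset().union(*self.sets.values()) if self.sets else frozenset()
        else:
            self.universe = frozenset(self.universe)
        # harmonize: clip every set to the universe
        self.sets = {name: frozenset(genes) & self.universe
                     for name, genes in self.sets.items()}


@dataclass
class EnrichmentRow:
    term: str
    ontology: str
    overlap: list[str]
    odds_ratio: float
    p_value: float
    q_value: float = float("nan")


def read_gmt(path: str | os.PathLike,
             universe: set[str] | None = None) -> GeneSetCollection:
    """Read a GMT file (name TAB description TAB gene...).

    The description field is used as the ontology tag when it looks like
    one (BP/MF/CC), otherwise stored verbatim.
    """
    sets: dict[str, frozenset[str]] = {}
    ontology: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            sets[name] = frozenset(genes)
            ontology[name] = desc
    return GeneSetCollection(sets=sets, ontology=ontology,
                             universe=frozenset(universe) if universe else frozenset())


def map_snps_to_genes(snp_ids: list[str], annotation: pd.DataFrame) -> list[str]:
    """Join SNP IDs to mapped/nearest gene symbols; dedup, keep first-seen order.

    SNPs absent from the annotation are skipped (logged via warning).
    """
    if annotation.empty or not {"snp", "gene"} <= set(annotation.columns):
        raise ValueError("annotation must be non-empty with columns snp, gene")
    lookup: dict[str, list[str]] = {}
    for row in annotation.itertuples():
        lookup.setdefault(str(row.snp), []).append(str(row.gene))
    genes: list[str] = []
    seen: set[str] = set()
    dropped = []
    for sid in snp_ids:
        if sid not in lookup:
            dropped.append(sid)
            continue
        for g in lookup[sid]:
            if g not in seen:
                seen.add(g)
                genes.append(g)
    if dropped:
        import warnings
        warnings.warn(f"SNPs without gene annotation (excluded): {dropped}")
    return genes


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_enrichment(query_genes: list[str],
                      collection: GeneSetCollection) -> list[EnrichmentRow]:
    """One-sided Fisher exact over-representation test per gene set.

    2x2 table per set: (query n set, query \\ set, set \\ query, remainder of
    the universe).  OR uses the Haldane-Anscombe 0.5 correction when any
    cell is zero.  Rows come back sorted by ascending p, with BH q-values.
    """
    universe = collection.universe
    query = set(query_genes) & universe
    if not query:
        raise ValueError("query genes are disjoint from the background universe")
    N = len(universe)
    rows: list[EnrichmentRow] = []
    for name in sorted(collection.sets):
        genes = collection.sets[name] & universe
        a = len(query & genes)
        b = len(query) - a
        c = len(genes) - a
        d = N - a - b - c
        _, p = sps.fisher_exact([[a, b], [c, d]], alternative="greater")
        if min(a, b, c, d) == 0:
            orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            orr = (a * d) / (b * c)
        rows.append(EnrichmentRow(term=name,
                                  ontology=collection.ontology.get(name, ""),
                                  overlap=sorted(query & genes),
                                  odds_ratio=float(orr), p_value=float(p)))
    rows.sort(key=lambda r: (r.p_value, r.term))
    qvals = bh_adjust([r.p_value for r in rows])
    for r, q in zip(rows, qvals):
        r.q_value = float(q)
    return rows


def enrichment_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame([{
        "term": r.term, "ontology": r.ontology,
        "overlap": ",".join(r.overlap), "odds_ratio": r.odds_ratio,
        "p": r.p_value, "q": r.q_value,
    } for r in rows])
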