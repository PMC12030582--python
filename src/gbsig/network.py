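"""Protein-interaction overlap, over-representation and tissue profiles.

Works on a STRING-style scored edge list (combined score 0-1000), GMT
pathway collections and a gene-by-tissue expression matrix.  The central
question: how strongly does a set of susceptibility genes touch a set of
drug-target genes, which genes carry that contact, and which pathways and
tissues are over-represented among them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError, UsageError
from .mr import fdr_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "OverlapResult",
    "load_network",
    "network_from_frame",
    "cross_set_interactions",
    "ora_enrichment",
    "tissue_profile",
    "read_gmt",
    "write_gmt",
]

DEFAULT_SCORE_THRESHOLD = 400  # STRING "medium confidence"


@dataclass
class Network:
    """Undirected scored graph without self-loops or duplicate edges."""

    edges: dict[frozenset, float] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for e in self.edges:
            out |= set(e)
        return out

    def __len__(self) -> int:
        return len(self.edges)

    def neighbors(self, gene: str) -> set[str]:
        out = set()
        for e in self.edges:
            if gene in e:
                out |= set(e) - {gene}
        return out


def network_from_frame(df: pd.DataFrame, score_threshold: float = DEFAULT_SCORE_THRESHOLD) -> Network:
    """Build a network from a (protein1, protein2, combined_score) frame.

    Keeps edges with score >= threshold, symmetrizes (an (a,b)/(b,a) pair is
    one edge, keeping the higher score), drops self-loops.
    """
    net = Network()
    for row in df.itertuples(index=False):
        a, b, score = str(row[0]), str(row[1]), float(row[2])
        if not (0 <= score <= 1000):
            raise FormatError(f"combined score {score} outside [0, 1000] for edge {a}-{b}")
        if a == b or score < score_threshold:
            continue
        key = frozenset((a, b))
        net.edges[key] = max(net.edges.get(key, 0.0), score)
    return net


def load_network(path, score_threshold: float = DEFAULT_SCORE_THRESHOLD) -> Network:
    """Read a three-column TSV edge list; malformed rows raise with the
    offending line number."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        header = fh.readline()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}")
            try:
                rows.append((parts[0], parts[1], float(parts[2])))
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric combined score {parts[2]!r}")
    return network_from_frame(pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"]),
                              score_threshold)


@dataclass
class OverlapResult:
    cross_edges: int
    a_touched: int
    b_touched: int
    degrees: dict[str, int]  # cross-set degree per set-A gene
    b_degrees: dict[str, int]
    drugs: set[str]
    ranked: pd.DataFrame  # set-A genes by cross-set degree desc


def cross_set_interactions(
    net: Network,
    set_a,
    set_b,
    target_to_drug: dict[str, list[str]] | None = None,
) -> OverlapResult:
    """Count interactions between a susceptibility set and a target set.

    Only A-B edges count; within-set edges are ignored.  Per-gene cross-set
    degrees are returned for both sides, with set A ranked by degree
    (descending, ties alphabetical).  When a target->drug map is supplied,
    the union of drugs over touched targets is reported.
    """
    set_a, set_b = set(set_a), set(set_b)
    if not set_a or not set_b:
        raise UsageError("both gene sets must be non-empty")
    deg_a = {g: 0 for g in set_a}
    deg_b = {g: 0 for g in set_b}
    cross = 0
    for edge in net.edges:
        pair = tuple(edge)
        if len(pair) != 2:
            continue
        x, y = pair
        if x in set_a and y in set_b:
            a_gene, b_gene = x, y
        elif y in set_a and x in set_b:
            a_gene, b_gene = y, x
        else:
            continue
        cross += 1
        deg_a[a_gene] += 1
        deg_b[b_gene] += 1
    touched_b = {g for g, d in deg_b.items() if d > 0}
    drugs: set[str] = set()
    if target_to_drug:
        for g in touched_b:
            drugs |= set(target_to_drug.get(g, []))
    ranked = pd.DataFrame(
        sorted(((g, d) for g, d in deg_a.items() if d > 0), key=lambda kv: (-kv[1], kv[0])),
        columns=["gene", "cross_degree"],
    )
    return OverlapResult(
        cross_edges=cross,
        a_touched=sum(1 for d in deg_a.values() if d > 0),
        b_touched=len(touched_b),
        degrees=deg_a,
        b_degrees=deg_b,
        drugs=drugs,
        ranked=ranked,
    )


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT rows need name, description, >=1 gene")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def ora_enrichment(
    query,
    gene_sets: dict[str, list[str]],
    universe=None,
    alpha: float = 0.05,
    keep_all: bool = False,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation with BH adjustment.

    For each pathway with K genes in the universe of size M, the p-value is
    the upper tail P(X >= k) of Hypergeometric(M, K, n) where n is the query
    size and k the overlap.  The universe defaults to the union of all
    pathway genes; query genes outside it are an input error.  Rows are BH
    adjusted across pathways, filtered to adjusted p < *alpha* (unless
    ``keep_all``) and sorted by p ascending.
    """
    query = set(query)
    if universe is None:
        universe = set()
        for genes in gene_sets.values():
            universe |= set(genes)
    else:
        universe = set(universe)
    offenders = sorted(query - universe)
    if offenders:
        raise UsageError(f"query gene(s) outside the universe: {offenders}")
    m = len(universe)
    n = len(query)
    rows = []
    for name, genes in gene_sets.items():
        members = set(genes) & universe
        k_size = len(members)
        overlap = len(members & query)
        p = float(stats.hypergeom.sf(overlap - 1, m, k_size, n)) if overlap else 1.0
        rows.append(
            {
                "pathway": name,
                "overlap": overlap,
                "pathway_size": k_size,
                "query_size": n,
                "universe_size": m,
                "p": min(p, 1.0),
                "genes": ";".join(sorted(members & query)),
            }
        )
    table = pd.DataFrame(rows)
    table["p_adjusted"] = fdr_adjust(table["p"].to_numpy())
    table.sort_values(["p", "pathway"], inplace=True)
    if not keep_all:
        table = table[table["p_adjusted"] < alpha]
    return table.reset_index(drop=True)


def tissue_profile(expression: pd.DataFrame, genes) -> pd.DataFrame:
    """Subset an expression matrix to *genes* and append a per-tissue mean row.

    Missing genes are logged; an entirely absent query is an error.  The
    result is heatmap-ready: one row per found gene plus a final ``MEAN``
    row with the arithmetic per-tissue mean.
    """
    genes = list(genes)
    present = [g for g in genes if g in expression.index]
    missing = sorted(set(genes) - set(present))
    if missing:
        logger.info("%d query gene(s) absent from the expression matrix: %s", len(missing), missing)
    if not present:
        raise UsageError("no query gene present in the expression matrix")
    sub = expression.loc[present].astype(float)
    mean_row = sub.mean(axis=0).to_frame().T
    mean_row.index = ["MEAN"]
    return pd.concat([sub, mean_row])
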