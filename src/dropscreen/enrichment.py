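"""Gene-set enrichment: hypergeometric over-representation and a
rank-based enrichment score with a gene-permutation null.

Over-representation uses the exact hypergeometric upper tail (equivalent to
a one-sided Fisher exact test) of the overlap between a query set and a
gene set within an explicit background universe. The rank-based statistic
is the classic weighted Kolmogorov–Smirnov running sum over a ranked gene
list: at each hit the sum rises by ``|score|**p`` (normalized over the
set's hits), at each miss it falls by ``1/(N - m)``; the enrichment score
is the signed extremum. Its significance comes from permuting which genes
belong to the set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import ParameterError, ValidationError
from .multitest import bh_adjust

P_ENRICH = 0.05  # enrichment calls use P <= 0.05, inclusive
GSEA_WEIGHT = 1.0


@dataclass
class GeneSetCollection:
    """Named gene sets, typically read from a GMT file."""

    sets: dict[str, set[str]]
    source: str = ""
    universe: set[str] | None = None

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (name, description, then one gene per column)."""
    sets: dict[str, set[str]] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(f"{path}:{line_no}: GMT line needs name, description, genes")
        name = parts[0]
        if name in sets:
            raise ValidationError(f"{path}:{line_no}: duplicate set name {name!r}")
        sets[name] = {g.strip().upper() for g in parts[2:] if g.strip()}
    return GeneSetCollection(sets=sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, collection.source or "na", *sorted(genes)])
        for name, genes in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def hypergeom_test(query: set[str], gene_set: set[str], universe: set[str]) -> float:
    """Exact upper-tail P[X >= k] of the query/set overlap in the universe."""
    bad = (set(query) - set(universe)) | (set(gene_set) - set(universe))
    if bad:
        raise ValidationError(f"genes outside the universe: {sorted(bad)[:10]}")
    N, m, n = len(universe), len(gene_set), len(query)
    k = len(set(query) & set(gene_set))
    # sf(k-1) is P[X >= k]
    return float(hypergeom.sf(k - 1, N, m, n))


def _es_from_hits(abs_scores_p: np.ndarray, hits: np.ndarray) -> tuple[float, np.ndarray]:
    m = int(hits.sum())
    n_total = hits.size
    norm = abs_scores_p[hits].sum()
    if norm > 0:
        inc = np.where(hits, abs_scores_p / norm, 0.0)
    else:  # all hit scores zero: fall back to unweighted steps
        inc = np.where(hits, 1.0 / m, 0.0)
    dec = np.where(hits, 0.0, 1.0 / (n_total - m))
    running = np.cumsum(inc - dec)
    es = running[np.argmax(np.abs(running))]
    return float(es), running


def gsea_es(
    ranked_genes: pd.Series,
    gene_set: set[str],
    weight: float = GSEA_WEIGHT,
) -> tuple[float, np.ndarray]:
    """Enrichment score of ``gene_set`` along a ranked, scored gene list.

    ``ranked_genes`` is a Series indexed by gene in ranking order (highest
    score first) with the ranking scores as values. Returns the signed
    extremum of the running sum and the full running profile.
    """
    genes = ranked_genes.index
    if genes.has_duplicates:
        raise ValidationError("ranked list contains duplicate genes")
    hits = np.asarray(genes.isin(gene_set))
    m = int(hits.sum())
    if m == 0:
        raise ValidationError("gene set is disjoint from the ranked list")
    if m == len(genes):
        raise ValidationError("gene set covers the entire ranked list")
    abs_p = np.abs(ranked_genes.to_numpy(dtype=float)) ** weight
    return _es_from_hits(abs_p, hits)


def gsea_perm_p(
    ranked_genes: pd.Series,
    gene_set: set[str],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = GSEA_WEIGHT,
) -> tuple[float, float]:
    """Gene-permutation p-value for the enrichment score.

    The null permutes set membership over the ranked list's positions; the
    two-sided p uses the plus-one estimator
    ``(1 + #{|es_perm| >= |es_obs|}) / (1 + n_perm)``.
    """
    if n_perm < 100:
        raise ParameterError("n_perm must be >= 100")
    es_obs, _ = gsea_es(ranked_genes, gene_set, weight)
    hits = np.asarray(ranked_genes.index.isin(gene_set))
    m = int(hits.sum())
    n_total = hits.size
    abs_p = np.abs(ranked_genes.to_numpy(dtype=float)) ** weight
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm_hits = np.zeros(n_total, dtype=bool)
        perm_hits[rng.choice(n_total, size=m, replace=False)] = True
        es_p, _ = _es_from_hits(abs_p, perm_hits)
        # tolerance guards ties against cumulative-sum rounding
        if abs(es_p) >= abs(es_obs) - 1e-12:
            exceed += 1
    return es_obs, (1 + exceed) / (1 + n_perm)


def ora_table(
    query: set[str],
    collection: GeneSetCollection,
    universe: set[str],
) -> pd.DataFrame:
    """Over-representation of the query against every set in the collection.

    Sets are clipped to the universe; empty clipped sets are skipped. The
    table carries overlap counts, the hypergeometric p, its BH adjustment,
    and the inclusive significance call at P <= 0.05.
    """
    query = set(query) & set(universe)
    rows = []
    for name, genes in collection.sets.items():
        clipped = set(genes) & set(universe)
        if not clipped:
            continue
        k = len(query & clipped)
        p = hypergeom_test(query, clipped, universe)
        rows.append(
            {
                "set_name": name,
                "overlap_k": k,
                "set_size_m": len(clipped),
                "query_size_n": len(query),
                "universe_N": len(universe),
                "p_hyper": p,
            }
        )
    table = pd.DataFrame(rows)
    if not table.empty:
        table["padj"] = bh_adjust(table["p_hyper"].to_numpy())
        table["significant"] = table["p_hyper"] <= P_ENRICH
        table = table.sort_values("p_hyper", kind="stable").reset_index(drop=True)
    return table
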