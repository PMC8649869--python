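"""Set-overlay candidate calling and Venn summaries.

The candidate logic of a dropout screen crossed with expression data is a
sequence of intersections: screen hits × genes differentially regulated
during resistance establishment; knockdown-downregulated × resistant-
upregulated (direct target candidates); and the genes co-downregulated by
two knockdowns. Gene symbols are upper-cased and whitespace-trimmed before
any set operation; every intersection records its parents.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ParameterError, ValidationError
from .screen import GeneDepletionSummary, genes_at_tier


def normalize_symbols(genes) -> set[str]:
    """Upper-case and strip gene symbols; drops empties."""
    return {g.strip().upper() for g in genes if g and g.strip()}


@dataclass(frozen=True)
class Intersection:
    """A named gene-set intersection with provenance."""

    name: str
    genes: frozenset[str]
    parents: tuple[str, ...]


def _intersect(name: str, named_sets: dict[str, set[str]]) -> Intersection:
    normalized = {k: normalize_symbols(v) for k, v in named_sets.items()}
    out = set.intersection(*normalized.values()) if normalized else set()
    return Intersection(name=name, genes=frozenset(out), parents=tuple(normalized))


def overlay_screen_de(
    screen: list[GeneDepletionSummary],
    de_changed: set[str],
    tier: str = "candidate",
) -> Intersection:
    """Screen hits (at the selected tier) ∩ differentially regulated genes."""
    screen_genes = genes_at_tier(screen, tier)
    return _intersect(
        f"screen_{tier}_x_de",
        {f"screen_{tier}": screen_genes, "de_changed": set(de_changed)},
    )


def target_candidates(down_on_knockdown: set[str], up_in_resistant: set[str]) -> Intersection:
    """Genes down on regulator knockdown and up in resistant cells."""
    return _intersect(
        "target_candidates",
        {"down_on_knockdown": set(down_on_knockdown), "up_in_resistant": set(up_in_resistant)},
    )


def coregulated(down_set_1: set[str], down_set_2: set[str], names: tuple[str, str] = ("down_1", "down_2")) -> Intersection:
    """Genes downregulated by both knockdowns (co-regulated targets)."""
    return _intersect("coregulated", {names[0]: set(down_set_1), names[1]: set(down_set_2)})


def venn_summary(named_sets: dict[str, set[str]]) -> dict[str, int]:
    """Region cardinalities of a 2- or 3-set Venn diagram.

    Region keys join the member set names with '&' (exclusive regions: a
    gene is counted in the single region matching exactly its memberships).
    Counts over all regions sum to the union's cardinality.
    """
    if len(named_sets) not in (2, 3):
        raise ParameterError("venn_summary supports exactly 2 or 3 sets")
    if len(set(named_sets)) != len(named_sets):
        raise ValidationError("set names must be unique")
    normalized = {k: normalize_symbols(v) for k, v in named_sets.items()}
    names = list(normalized)
    universe = set().union(*normalized.values())
    regions: dict[str, int] = {}
    n = len(names)
    for mask in range(1, 2 ** n):
        members = [names[i] for i in range(n) if mask >> i & 1]
        key = "&".join(members)
        regions[key] = 0
    for gene in universe:
        mask = sum(1 << i for i, name in enumerate(names) if gene in normalized[name])
        members = [names[i] for i in range(n) if mask >> i & 1]
        regions["&".join(members)] += 1
    return regions
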