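"""Dropout-screen scoring: per-shRNA depletion, acute-arm subtraction, and
gene-level candidate tiers.

The analysis follows the logic of a pooled synthetic-lethality screen: a
hairpin whose barcode abundance falls under long-term drug selection marks
its target gene as required for maintained resistance. Hairpins that also
drop out of drug-naive parental cells under acute treatment are subtracted,
so that only genes specific to the maintenance of resistance survive.
A gene is a *candidate* when at least ``min_candidate`` of its surviving
hairpins are depleted and *stringent* when more than three are
(``min_stringent`` = 4 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .matrix import CountMatrix

#: default call thresholds (CPM scale)
LFC_THRESHOLD = -1.0
ABUNDANCE_FLOOR = 5.0
PSEUDOCOUNT = 0.5
MIN_CANDIDATE = 2
MIN_STRINGENT = 4

TIERS = ("none", "candidate", "stringent")


@dataclass(frozen=True)
class ShRNADepletion:
    """Depletion call for one hairpin in one treated-vs-reference contrast."""

    shrna_id: str
    gene: str
    lfc: float
    ref_abundance: float
    depleted: bool


@dataclass(frozen=True)
class GeneDepletionSummary:
    """Per-gene aggregation of surviving depletion calls with its tier."""

    gene: str
    n_shrnas: int
    n_depleted: int
    median_lfc: float
    tier: str


def shrna_depletion(
    counts: CountMatrix,
    treated_samples: list[str],
    reference_samples: list[str],
    gene_map: dict[str, str],
    pseudocount: float = PSEUDOCOUNT,
    lfc_threshold: float = LFC_THRESHOLD,
    abundance_floor: float = ABUNDANCE_FLOOR,
) -> list[ShRNADepletion]:
    """Score each hairpin's log2 fold change of treated over reference.

    ``lfc_i = log2((mean treated + eps) / (mean reference + eps))`` on the
    normalized matrix; a hairpin is called depleted when its lfc is strictly
    below ``lfc_threshold`` and its mean reference abundance is at least
    ``abundance_floor`` (suppressing calls driven by low coverage).
    """
    if not counts.normalized:
        raise ValidationError("depletion scoring requires a normalized matrix")
    if not treated_samples or not reference_samples:
        raise ValidationError("both sample groups must be non-empty")
    counts.require_samples(list(treated_samples) + list(reference_samples))
    treated = counts.values[list(treated_samples)].mean(axis=1).to_numpy()
    reference = counts.values[list(reference_samples)].mean(axis=1).to_numpy()
    lfc = np.log2((treated + pseudocount) / (reference + pseudocount))
    calls = []
    for i, shrna in enumerate(counts.feature_ids):
        gene = gene_map.get(shrna)
        if gene is None:
            raise ValidationError(f"shRNA {shrna} has no gene mapping")
        depleted = bool(lfc[i] < lfc_threshold and reference[i] >= abundance_floor)
        calls.append(
            ShRNADepletion(
                shrna_id=shrna,
                gene=gene,
                lfc=float(lfc[i]),
                ref_abundance=float(reference[i]),
                depleted=depleted,
            )
        )
    return calls


def subtract_acute(
    resistant_calls: list[ShRNADepletion],
    acute_calls: list[ShRNADepletion],
    level: str = "shrna",
) -> list[ShRNADepletion]:
    """Clear the depleted flag of hairpins that also dropped out acutely.

    At ``level='shrna'`` (default) any hairpin depleted in the acute arm is
    removed from the depleted set; at ``level='gene'`` every hairpin of a
    gene with any acute-depleted hairpin is cleared. All other calls pass
    through unchanged.
    """
    if level not in ("shrna", "gene"):
        raise ParameterError("level must be 'shrna' or 'gene'")
    res_ids = {c.shrna_id for c in resistant_calls}
    acu_ids = {c.shrna_id for c in acute_calls}
    if res_ids != acu_ids:
        raise ValidationError(
            "resistant and acute calls cover different shRNA universes "
            f"(e.g. {sorted(res_ids ^ acu_ids)[:5]})"
        )
    acute_depleted = {c.shrna_id for c in acute_calls if c.depleted}
    if level == "gene":
        hit_genes = {c.gene for c in acute_calls if c.depleted}
        return [
            replace(c, depleted=False) if c.gene in hit_genes else c
            for c in resistant_calls
        ]
    return [
        replace(c, depleted=False) if c.shrna_id in acute_depleted else c
        for c in resistant_calls
    ]


def aggregate_genes(
    calls: list[ShRNADepletion],
    min_candidate: int = MIN_CANDIDATE,
    min_stringent: int = MIN_STRINGENT,
) -> list[GeneDepletionSummary]:
    """Aggregate hairpin calls per gene and assign candidate tiers.

    Tier is ``stringent`` when ``n_depleted >= min_stringent`` (default 4,
    i.e. depletion supported by more than three independent hairpins),
    ``candidate`` when ``>= min_candidate``, else ``none``. ``median_lfc``
    is taken over all the gene's hairpins, depleted or not.
    """
    if not (1 <= min_candidate <= min_stringent):
        raise ParameterError("need min_stringent >= min_candidate >= 1")
    by_gene: dict[str, list[ShRNADepletion]] = {}
    for c in calls:
        by_gene.setdefault(c.gene, []).append(c)
    out = []
    for gene, group in by_gene.items():
        n_dep = sum(c.depleted for c in group)
        if n_dep >= min_stringent:
            tier = "stringent"
        elif n_dep >= min_candidate:
            tier = "candidate"
        else:
            tier = "none"
        out.append(
            GeneDepletionSummary(
                gene=gene,
                n_shrnas=len(group),
                n_depleted=n_dep,
                median_lfc=float(np.median([c.lfc for c in group])),
                tier=tier,
            )
        )
    return out


def genes_at_tier(summaries: list[GeneDepletionSummary], tier: str = "candidate") -> set[str]:
    """Genes whose tier is at least ``tier`` ('candidate' includes stringent)."""
    if tier not in ("candidate", "stringent"):
        raise ParameterError("tier must be 'candidate' or 'stringent'")
    if tier == "stringent":
        return {s.gene for s in summaries if s.tier == "stringent"}
    return {s.gene for s in summaries if s.tier in ("candidate", "stringent")}


def calls_to_frame(calls: list[ShRNADepletion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "shrna_id": [c.shrna_id for c in calls],
            "gene": [c.gene for c in calls],
            "lfc": [c.lfc for c in calls],
            "ref_abundance": [c.ref_abundance for c in calls],
            "depleted": [c.depleted for c in calls],
        }
    )


def summaries_to_frame(summaries: list[GeneDepletionSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [s.gene for s in summaries],
            "n_shrnas": [s.n_shrnas for s in summaries],
            "n_depleted": [s.n_depleted for s in summaries],
            "median_lfc": [s.median_lfc for s in summaries],
            "tier": [s.tier for s in summaries],
        }
    )


def write_screen_tables(
    calls: list[ShRNADepletion],
    summaries: list[GeneDepletionSummary],
    shrna_path: str | Path,
    gene_path: str | Path,
) -> None:
    calls_to_frame(calls).to_csv(shrna_path, sep="\t", index=False)
    summaries_to_frame(summaries).to_csv(gene_path, sep="\t", index=False)
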