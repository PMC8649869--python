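"""Synthetic pooled-screen and RNA-seq data with planted ground truth.

This module generates every input the analysis stages consume — a barcoded
shRNA library, arm-structured screen count matrices, barcode FASTQ reads and
RNA-seq count matrices — from explicit truth tables, so that each downstream
stage can be tested against a known answer.

The screen generative model: each shRNA *i* targeting gene *g* starts at a
log-normal baseline abundance; after ``w`` weeks of selection in an arm where
the gene's per-week log2 fitness effect ``s_g`` applies, its expected
abundance is ``baseline_i * 2**(s_g * efficacy_i * w)``. Resistance-driver
genes feel ``s_g`` only in the resistant-selected arm, acute-essential genes
in both the resistant-selected and parental-acute arms, neutral genes
nowhere. Observed counts are negative-binomial around the multinomial
expectation at the configured sequencing depth, with variance ``mu + phi *
mu**2``.
"""

from __future__ import annotations

import gzip
import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .matrix import CountMatrix

NUCLEOTIDES = np.frombuffer(b"ACGT", dtype="S1")

GENE_ROLES = ("neutral", "resistance_driver", "acute_essential")
ARMS = ("reference", "resistant_selected", "parental_acute")


# ---------------------------------------------------------------------------
# library
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShRNARecord:
    """One hairpin: an opaque id, the gene symbol it targets, its barcode."""

    shrna_id: str
    gene: str
    barcode: str


@dataclass
class ShRNALibrary:
    """Ordered collection of shRNA records with uniform barcode length.

    Invariants: barcodes and shRNA ids are unique library-wide, all barcodes
    share ``barcode_length``, and every record names a gene.
    """

    records: list[ShRNARecord]
    barcode_length: int

    def __post_init__(self) -> None:
        barcodes = [r.barcode for r in self.records]
        ids = [r.shrna_id for r in self.records]
        if len(set(barcodes)) != len(barcodes):
            raise ValidationError("library barcodes are not unique")
        if len(set(ids)) != len(ids):
            raise ValidationError("library shRNA ids are not unique")
        for r in self.records:
            if not r.gene:
                raise ValidationError(f"shRNA {r.shrna_id} has an empty gene symbol")
            if len(r.barcode) != self.barcode_length:
                raise ValidationError(
                    f"barcode of {r.shrna_id} has length {len(r.barcode)}, "
                    f"expected {self.barcode_length}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def shrna_ids(self) -> list[str]:
        return [r.shrna_id for r in self.records]

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.gene, None)
        return list(seen)

    @property
    def barcode_to_id(self) -> dict[str, str]:
        return {r.barcode: r.shrna_id for r in self.records}

    @property
    def id_to_gene(self) -> dict[str, str]:
        return {r.shrna_id: r.gene for r in self.records}

    @property
    def id_to_barcode(self) -> dict[str, str]:
        return {r.shrna_id: r.barcode for r in self.records}

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "shrna_id": [r.shrna_id for r in self.records],
                "gene": [r.gene for r in self.records],
                "barcode": [r.barcode for r in self.records],
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ShRNALibrary":
        df = pd.read_csv(path, sep="\t", dtype=str)
        for col in ("shrna_id", "gene", "barcode"):
            if col not in df.columns:
                raise ValidationError(f"library table missing column {col!r}")
        records = [
            ShRNARecord(row.shrna_id, row.gene, row.barcode)
            for row in df.itertuples(index=False)
        ]
        if not records:
            raise ValidationError("library table is empty")
        return cls(records=records, barcode_length=len(records[0].barcode))


def generate_library(
    n_genes: int,
    shrnas_per_gene: int = 8,
    barcode_length: int = 18,
    seed: int = 0,
) -> ShRNALibrary:
    """Generate a library of ``n_genes * shrnas_per_gene`` distinct barcodes.

    Barcodes are drawn uniformly without replacement from the ``4**L``
    sequence space; the call is deterministic given ``seed``.
    """
    if n_genes < 1 or shrnas_per_gene < 1:
        raise ParameterError("n_genes and shrnas_per_gene must be >= 1")
    if barcode_length < 1:
        raise ParameterError("barcode_length must be >= 1")
    n_total = n_genes * shrnas_per_gene
    space = 4 ** barcode_length
    if space < n_total:
        raise ParameterError(
            f"barcode space 4^{barcode_length} = {space} cannot hold {n_total} "
            "distinct barcodes"
        )
    rng = np.random.default_rng(seed)
    if space <= max(4 * n_total, 2 ** 16):
        # small space: enumerate and sample without replacement
        all_codes = ["".join(p) for p in itertools.product("ACGT", repeat=barcode_length)]
        idx = rng.choice(space, size=n_total, replace=False)
        barcodes = [all_codes[i] for i in idx]
    else:
        chosen: dict[str, None] = {}
        while len(chosen) < n_total:
            batch = rng.integers(0, 4, size=(n_total - len(chosen) + 16, barcode_length))
            for row in NUCLEOTIDES[batch]:
                bc = row.tobytes().decode()
                if bc not in chosen:
                    chosen[bc] = None
                    if len(chosen) == n_total:
                        break
        barcodes = list(chosen)
    width = max(4, len(str(n_genes)))
    records = []
    k = 0
    for gi in range(n_genes):
        gene = f"GENE{gi + 1:0{width}d}"
        for si in range(shrnas_per_gene):
            records.append(ShRNARecord(f"{gene}_sh{si + 1}", gene, barcodes[k]))
            k += 1
    return ShRNALibrary(records=records, barcode_length=barcode_length)


# ---------------------------------------------------------------------------
# screen truth and design
# ---------------------------------------------------------------------------

@dataclass
class ScreenTruth:
    """Planted per-gene roles and per-shRNA knockdown efficacies.

    ``selection_coeff`` is the per-week log2 fitness effect of a full
    knockdown (<= 0 for non-neutral roles, exactly 0 for neutral genes);
    ``efficacy`` scales it per hairpin in [0, 1].
    """

    gene_role: dict[str, str]
    selection_coeff: dict[str, float]
    efficacy: dict[str, float]

    def __post_init__(self) -> None:
        for gene, role in self.gene_role.items():
            if role not in GENE_ROLES:
                raise ValidationError(f"unknown role {role!r} for gene {gene}")
            s = self.selection_coeff.get(gene)
            if s is None:
                raise ValidationError(f"gene {gene} missing selection coefficient")
            if role == "neutral" and s != 0:
                raise ValidationError(f"neutral gene {gene} has nonzero selection_coeff")
        for shrna, e in self.efficacy.items():
            if not (0.0 <= e <= 1.0):
                raise ValidationError(f"efficacy of {shrna} outside [0, 1]")

    def validate_against(self, library: ShRNALibrary) -> None:
        missing_genes = [g for g in library.genes if g not in self.gene_role]
        if missing_genes:
            raise ValidationError(f"truth missing genes: {missing_genes[:5]} ...")
        missing_sh = [s for s in library.shrna_ids if s not in self.efficacy]
        if missing_sh:
            raise ValidationError(f"truth missing shRNA efficacies: {missing_sh[:5]} ...")

    def genes_with_role(self, role: str) -> list[str]:
        return [g for g, r in self.gene_role.items() if r == role]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "gene_role": self.gene_role,
            "selection_coeff": self.selection_coeff,
            "efficacy": self.efficacy,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScreenTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            gene_role=payload["gene_role"],
            selection_coeff={k: float(v) for k, v in payload["selection_coeff"].items()},
            efficacy={k: float(v) for k, v in payload["efficacy"].items()},
        )


@dataclass
class ScreenDesign:
    """Arms, selection duration, sequencing depth and noise of one screen.

    Defaults mirror a four-week drug-selection screen read at two million
    reads per sample with mild overdispersion.
    """

    weeks: dict[str, float] = field(
        default_factory=lambda: {
            "reference": 0.0,
            "resistant_selected": 4.0,
            "parental_acute": 4.0,
        }
    )
    depth: float = 2e6
    dispersion: float = 0.05
    replicates: int = 3

    def __post_init__(self) -> None:
        if self.weeks.get("reference", 0.0) != 0.0:
            raise ValidationError("reference arm must have weeks = 0")
        unknown = set(self.weeks) - set(ARMS)
        if unknown:
            raise ValidationError(f"unknown arms: {sorted(unknown)}")
        if self.depth <= 0:
            raise ParameterError("depth must be > 0")
        if self.dispersion < 0:
            raise ParameterError("dispersion must be >= 0")
        if self.replicates < 1:
            raise ParameterError("replicates must be >= 1")

    @property
    def arms(self) -> list[str]:
        return [a for a in ARMS if a in self.weeks]


def plant_screen_truth(
    library: ShRNALibrary,
    n_drivers: int,
    n_acute: int,
    s_driver: float = -0.75,
    s_acute: float = -0.75,
    active_fraction: float = 0.8,
    efficacy_beta: tuple[float, float] = (5.0, 2.0),
    seed: int = 0,
) -> ScreenTruth:
    """Assign roles and hairpin efficacies for a simulated screen.

    ``n_drivers`` genes become resistance drivers and ``n_acute`` genes
    acute-essential, chosen at random; the rest are neutral. For each gene a
    fraction ``active_fraction`` of its hairpins is active with efficacy
    drawn Beta(5, 2); the rest are inert (efficacy 0), which is what makes a
    minimum-shRNA gene filter meaningful on real libraries.
    """
    if s_driver > 0 or s_acute > 0:
        raise ParameterError("selection coefficients must be <= 0 (dropout screen)")
    genes = library.genes
    if n_drivers + n_acute > len(genes):
        raise ParameterError("more planted genes requested than genes in library")
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(genes), size=n_drivers + n_acute, replace=False)
    drivers = {genes[i] for i in picked[:n_drivers]}
    acute = {genes[i] for i in picked[n_drivers:]}
    gene_role, selection = {}, {}
    for g in genes:
        if g in drivers:
            gene_role[g], selection[g] = "resistance_driver", float(s_driver)
        elif g in acute:
            gene_role[g], selection[g] = "acute_essential", float(s_acute)
        else:
            gene_role[g], selection[g] = "neutral", 0.0
    a, b = efficacy_beta
    efficacy: dict[str, float] = {}
    by_gene: dict[str, list[str]] = {}
    for r in library.records:
        by_gene.setdefault(r.gene, []).append(r.shrna_id)
    for g in genes:
        ids = by_gene[g]
        n_active = int(round(active_fraction * len(ids)))
        active_idx = set(rng.choice(len(ids), size=n_active, replace=False))
        for i, shrna in enumerate(ids):
            efficacy[shrna] = float(rng.beta(a, b)) if i in active_idx else 0.0
    return ScreenTruth(gene_role=gene_role, selection_coeff=selection, efficacy=efficacy)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """Negative-binomial draw with variance mu + phi*mu^2 (Poisson at phi=0)."""
    mean = np.asarray(mean, dtype=float)
    if phi == 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_screen(
    library: ShRNALibrary,
    truth: ScreenTruth,
    design: ScreenDesign,
    seed: int = 0,
) -> CountMatrix:
    """Simulate the shRNA × sample count matrix of an arm-structured screen.

    Deterministic given ``seed``. Columns are named ``{arm}_rep{r}`` and the
    sample sheet carries arm/replicate/group labels (group = arm).
    """
    truth.validate_against(library)
    rng = np.random.default_rng(seed)
    n = len(library)
    baseline = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    s = np.array([truth.selection_coeff[r.gene] for r in library.records])
    eff = np.array([truth.efficacy[r.shrna_id] for r in library.records])
    role = np.array([truth.gene_role[r.gene] for r in library.records])

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for arm in design.arms:
        w = design.weeks[arm]
        applies = np.zeros(n, dtype=bool)
        if arm == "resistant_selected":
            applies = (role == "resistance_driver") | (role == "acute_essential")
        elif arm == "parental_acute":
            applies = role == "acute_essential"
        expected = baseline * np.power(2.0, np.where(applies, s * eff * w, 0.0))
        p = expected / expected.sum()
        mu = design.depth * p
        for rep in range(1, design.replicates + 1):
            name = f"{arm}_rep{rep}"
            columns[name] = _nb_counts(rng, mu, design.dispersion)
            meta_rows.append({"sample": name, "arm": arm, "replicate": str(rep), "group": arm})
    values = pd.DataFrame(columns, index=pd.Index(library.shrna_ids, name="feature_id"))
    samples = pd.DataFrame(meta_rows).set_index("sample")
    return CountMatrix(values=values, samples=samples, normalized=False)


# ---------------------------------------------------------------------------
# barcode FASTQ emission
# ---------------------------------------------------------------------------

def write_barcode_fastq(
    counts: CountMatrix,
    library: ShRNALibrary,
    flank5: str = "ACCG",
    flank3: str = "GTTT",
    error_rate: float = 0.0,
    seed: int = 0,
    out_dir: str | Path = ".",
    compress: bool = False,
) -> dict[str, int]:
    """Emit one FASTQ per sample; each count cell becomes that many reads.

    Every read is ``flank5 + barcode + flank3`` with independent per-base
    substitution noise at ``error_rate``; qualities are constant Phred+33
    'I'. Returns the written read total per sample.
    """
    if not (0.0 <= error_rate < 0.25):
        raise ParameterError("error_rate must be in [0, 0.25)")
    id_to_barcode = library.id_to_barcode
    unknown = [f for f in counts.feature_ids if f not in id_to_barcode]
    if unknown:
        raise ValidationError(f"count rows not in library: {unknown[:5]}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    read_len = len(flank5) + library.barcode_length + len(flank3)
    templates = np.array(
        [
            np.frombuffer((flank5 + id_to_barcode[f] + flank3).encode(), dtype="S1")
            for f in counts.feature_ids
        ]
    )
    totals: dict[str, int] = {}
    for sample in counts.sample_ids:
        col = counts.values[sample].to_numpy()
        cell_counts = np.asarray(np.rint(col), dtype=np.int64)
        if (cell_counts < 0).any():
            raise ValidationError(f"negative counts in sample {sample}")
        n_reads = int(cell_counts.sum())
        reads = np.repeat(templates, cell_counts, axis=0)
        if error_rate > 0 and n_reads:
            mask = rng.random(reads.shape) < error_rate
            n_err = int(mask.sum())
            if n_err:
                base_idx = np.searchsorted(NUCLEOTIDES, reads[mask])
                shift = rng.integers(1, 4, size=n_err)
                reads[mask] = NUCLEOTIDES[(base_idx + shift) % 4]
        suffix = ".fastq.gz" if compress else ".fastq"
        path = out_dir / f"{sample}{suffix}"
        opener = gzip.open if compress else open
        qual = "I" * read_len
        with opener(path, "wt") as fh:
            for i in range(n_reads):
                fh.write(f"@{sample}:{i}\n{reads[i].tobytes().decode()}\n+\n{qual}\n")
        totals[sample] = n_reads
    return totals


# ---------------------------------------------------------------------------
# RNA-seq simulation
# ---------------------------------------------------------------------------

@dataclass
class ExpressionTruth:
    """Planted expression baselines and per-contrast log2 fold changes.

    ``contrasts`` maps a contrast name to its (reference group, alternative
    group) pair; ``de_effect[(gene, contrast)]`` is the log2 fold change of
    the alternative group over the reference for that gene (0 or absent for
    non-DE genes). Groups may be shared between contrasts, which is how
    effects shared between knockdown conditions are expressed.
    """

    baseline_mean: dict[str, float]
    contrasts: dict[str, tuple[str, str]]
    de_effect: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g, m in self.baseline_mean.items():
            if not (m > 0):
                raise ValidationError(f"baseline mean of {g} must be > 0")
        for (g, c) in self.de_effect:
            if c not in self.contrasts:
                raise ValidationError(f"effect refers to unknown contrast {c!r}")
            if g not in self.baseline_mean:
                raise ValidationError(f"effect refers to unknown gene {g!r}")

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for ref, alt in self.contrasts.values():
            seen.setdefault(ref, None)
            seen.setdefault(alt, None)
        return list(seen)

    def group_mean(self, gene: str, group: str) -> float:
        log2_shift = 0.0
        for name, (_ref, alt) in self.contrasts.items():
            if group == alt:
                log2_shift += self.de_effect.get((gene, name), 0.0)
        return self.baseline_mean[gene] * 2.0 ** log2_shift

    def genes_changed(self, contrast: str, direction: str = "both") -> set[str]:
        out = set()
        for (g, c), e in self.de_effect.items():
            if c != contrast or e == 0:
                continue
            if direction == "both" or (direction == "up" and e > 0) or (
                direction == "down" and e < 0
            ):
                out.add(g)
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "baseline_mean": self.baseline_mean,
            "contrasts": {k: list(v) for k, v in self.contrasts.items()},
            "de_effect": [[g, c, e] for (g, c), e in self.de_effect.items()],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ExpressionTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            baseline_mean={k: float(v) for k, v in payload["baseline_mean"].items()},
            contrasts={k: (v[0], v[1]) for k, v in payload["contrasts"].items()},
            de_effect={(g, c): float(e) for g, c, e in payload["de_effect"]},
        )


def plant_expression_truth(
    genes: list[str],
    contrasts: dict[str, tuple[str, str]],
    effects: dict[str, dict[str, float]] | None = None,
    mean_log2_baseline: float = 8.0,
    sigma_log2: float = 1.5,
    seed: int = 0,
) -> ExpressionTruth:
    """Draw log-normal baselines and attach planted per-contrast effects.

    ``effects`` maps contrast name -> {gene: log2 fold change}.
    """
    rng = np.random.default_rng(seed)
    baseline = {
        g: float(2.0 ** rng.normal(mean_log2_baseline, sigma_log2)) for g in genes
    }
    de: dict[tuple[str, str], float] = {}
    for contrast, table in (effects or {}).items():
        for g, e in table.items():
            de[(g, contrast)] = float(e)
    return ExpressionTruth(baseline_mean=baseline, contrasts=dict(contrasts), de_effect=de)


def simulate_rnaseq(
    truth: ExpressionTruth,
    n_replicates: int = 3,
    dispersion: float = 0.1,
    seed: int = 0,
) -> CountMatrix:
    """Simulate a gene × sample NB count matrix for every group in ``truth``.

    Group means are ``baseline * 2**effect``; deterministic given ``seed``.
    """
    if dispersion < 0:
        raise ParameterError("dispersion must be >= 0")
    if n_replicates < 2:
        raise ParameterError("need >= 2 replicates per group")
    rng = np.random.default_rng(seed)
    genes = list(truth.baseline_mean)
    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for group in truth.groups:
        mu = np.array([truth.group_mean(g, group) for g in genes])
        for rep in range(1, n_replicates + 1):
            name = f"{group}_rep{rep}"
            columns[name] = _nb_counts(rng, mu, dispersion)
            meta_rows.append(
                {"sample": name, "arm": "", "replicate": str(rep), "group": group}
            )
    values = pd.DataFrame(columns, index=pd.Index(genes, name="feature_id"))
    samples = pd.DataFrame(meta_rows).set_index("sample")
    return CountMatrix(values=values, samples=samples, normalized=False)
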