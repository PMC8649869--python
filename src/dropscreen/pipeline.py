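"""End-to-end pipeline: simulate → (count) → screen → DE → integrate → enrich.

A :class:`RunConfig` collects every stage's thresholds (defaults equal the
per-module defaults), all seeds, and the input/output paths; ``run_pipeline``
executes the configured stages, writes all artifacts under the output
directory, and returns a machine-readable report that is byte-identical
across reruns of the same config.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diffexpr import (
    MIN_ABS_LFC,
    P_MAX,
    estimate_dispersion,
    filter_de,
    nb_test,
    normalize_by_size_factors,
)
from .enrichment import (
    GeneSetCollection,
    gsea_es,
    gsea_perm_p,
    ora_table,
    read_gmt,
    write_gmt,
)
from .errors import ValidationError
from .integration import (
    coregulated,
    overlay_screen_de,
    target_candidates,
    venn_summary,
)
from .matrix import CountMatrix
from .quant import cpm_normalize
from .screen import (
    ABUNDANCE_FLOOR,
    LFC_THRESHOLD,
    MIN_CANDIDATE,
    MIN_STRINGENT,
    PSEUDOCOUNT,
    aggregate_genes,
    genes_at_tier,
    shrna_depletion,
    subtract_acute,
    write_screen_tables,
)
from .synthetic import (
    ScreenDesign,
    ShRNALibrary,
    generate_library,
    plant_expression_truth,
    plant_screen_truth,
    simulate_rnaseq,
    simulate_screen,
)

ALL_STAGES = ("simulate", "screen", "de", "integrate", "enrich")


@dataclass
class RunConfig:
    """Every knob of a pipeline run; defaults match the per-module defaults."""

    out_dir: str = "dropscreen_out"
    seed: int = 1
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))

    # simulate: screen
    n_genes: int = 100
    shrnas_per_gene: int = 8
    barcode_length: int = 18
    n_drivers: int = 10
    n_acute: int = 5
    s_driver: float = -0.75
    s_acute: float = -0.75
    active_fraction: float = 0.8
    weeks: dict = field(
        default_factory=lambda: {
            "reference": 0.0,
            "resistant_selected": 4.0,
            "parental_acute": 4.0,
        }
    )
    depth: float = 2e6
    screen_dispersion: float = 0.05
    replicates: int = 3

    # simulate: expression
    rnaseq_replicates: int = 3
    rnaseq_dispersion: float = 0.1
    driver_de_effect: float = 2.0
    n_target_genes: int = 15
    n_coregulated: int = 10
    n_extra_up: int = 15
    n_extra_down: int = 15
    extra_de_effect: float = 2.0
    mean_log2_baseline: float = 8.0
    sigma_log2: float = 1.5

    # screen thresholds
    lfc_threshold: float = LFC_THRESHOLD
    abundance_floor: float = ABUNDANCE_FLOOR
    pseudocount: float = PSEUDOCOUNT
    min_candidate: int = MIN_CANDIDATE
    min_stringent: int = MIN_STRINGENT

    # DE filter
    p_max: float = P_MAX
    min_abs_lfc: float = MIN_ABS_LFC
    use_fdr: bool = False

    # enrichment
    gsea_weight: float = 1.0
    n_perm: int = 200

    # external inputs (used when the simulate stage is disabled)
    library_tsv: str | None = None
    counts_tsv: str | None = None
    sample_sheet: str | None = None
    gmt: str | None = None

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValidationError(f"unknown stages: {sorted(unknown)}")
        if "simulate" not in self.stages:
            for attr in ("library_tsv", "counts_tsv", "sample_sheet"):
                path = getattr(self, attr)
                if path is None:
                    raise ValidationError(
                        f"config missing required path {attr!r} (simulate stage disabled)"
                    )
                if not Path(path).exists():
                    raise ValidationError(f"{attr} does not exist: {path}")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    @classmethod
    def demo(cls, out_dir: str = "demo_out") -> "RunConfig":
        """The bundled seeded demo: 100 genes x 8 shRNAs, 10 drivers."""
        return cls(out_dir=out_dir, seed=7)


def _write_gene_list(genes: set[str], path: Path) -> None:
    path.write_text("\n".join(sorted(genes)) + ("\n" if genes else ""))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the run report (also written
    to ``<out_dir>/report.json``)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "stages": {},
        "files": [],
    }

    def record(path: Path) -> Path:
        report["files"].append(str(path.relative_to(out)))
        return path

    library: ShRNALibrary | None = None
    screen_counts: CountMatrix | None = None
    screen_truth = None
    expr_truth = None
    rnaseq: CountMatrix | None = None

    # ---------------------------------------------------------------- simulate
    if "simulate" in config.stages:
        library = generate_library(
            config.n_genes, config.shrnas_per_gene, config.barcode_length, seed=config.seed
        )
        screen_truth = plant_screen_truth(
            library,
            n_drivers=config.n_drivers,
            n_acute=config.n_acute,
            s_driver=config.s_driver,
            s_acute=config.s_acute,
            active_fraction=config.active_fraction,
            seed=config.seed + 1,
        )
        design = ScreenDesign(
            weeks=dict(config.weeks),
            depth=config.depth,
            dispersion=config.screen_dispersion,
            replicates=config.replicates,
        )
        screen_counts = simulate_screen(library, screen_truth, design, seed=config.seed + 2)
        library.to_tsv(record(out / "library.tsv"))
        screen_truth.to_json(record(out / "screen_truth.json"))
        screen_counts.to_tsv(
            record(out / "screen_counts.tsv"), record(out / "screen_samples.tsv")
        )

        genes = library.genes
        drivers = sorted(screen_truth.genes_with_role("resistance_driver"))
        neutral = sorted(screen_truth.genes_with_role("neutral"))
        rng = np.random.default_rng(config.seed + 3)
        pool = list(neutral)
        rng.shuffle(pool)
        take = lambda n: [pool.pop() for _ in range(min(n, len(pool)))]
        targets = take(config.n_target_genes)
        coreg = take(config.n_coregulated)
        extra_up = take(config.n_extra_up)
        extra_down = take(config.n_extra_down)
        e = config.extra_de_effect
        effects = {
            "resistant_vs_parental": {
                **{g: config.driver_de_effect for g in drivers},
                **{g: e for g in targets},
                **{g: e for g in extra_up},
                **{g: -e for g in extra_down},
            },
            "kd1_vs_ctrl": {
                **{g: -e for g in targets},
                **{g: -e for g in coreg},
            },
            "kd2_vs_ctrl": {g: -e for g in coreg},
        }
        contrasts = {
            "resistant_vs_parental": ("parental", "resistant"),
            "kd1_vs_ctrl": ("ctrl", "kd1"),
            "kd2_vs_ctrl": ("ctrl", "kd2"),
        }
        expr_truth = plant_expression_truth(
            genes,
            contrasts,
            effects,
            mean_log2_baseline=config.mean_log2_baseline,
            sigma_log2=config.sigma_log2,
            seed=config.seed + 4,
        )
        rnaseq = simulate_rnaseq(
            expr_truth,
            n_replicates=config.rnaseq_replicates,
            dispersion=config.rnaseq_dispersion,
            seed=config.seed + 5,
        )
        expr_truth.to_json(record(out / "expression_truth.json"))
        rnaseq.to_tsv(record(out / "rnaseq_counts.tsv"), record(out / "rnaseq_samples.tsv"))
        report["stages"]["simulate"] = {
            "n_shrnas": len(library),
            "n_genes": len(genes),
            "screen_samples": screen_counts.sample_ids,
            "rnaseq_samples": rnaseq.sample_ids,
            "planted": {
                "drivers": drivers,
                "acute_essential": sorted(screen_truth.genes_with_role("acute_essential")),
                "targets": sorted(targets),
                "coregulated": sorted(coreg),
            },
        }
    else:
        library = ShRNALibrary.from_tsv(config.library_tsv)
        screen_counts = CountMatrix.from_tsv(config.counts_tsv, config.sample_sheet)

    # ------------------------------------------------------------------ screen
    summaries = []
    if "screen" in config.stages:
        cpm = cpm_normalize(screen_counts)
        gene_map = library.id_to_gene
        kwargs = dict(
            gene_map=gene_map,
            pseudocount=config.pseudocount,
            lfc_threshold=config.lfc_threshold,
            abundance_floor=config.abundance_floor,
        )
        ref = cpm.samples_in_arm("reference")
        resistant_calls = shrna_depletion(cpm, cpm.samples_in_arm("resistant_selected"), ref, **kwargs)
        acute_calls = shrna_depletion(cpm, cpm.samples_in_arm("parental_acute"), ref, **kwargs)
        surviving = subtract_acute(resistant_calls, acute_calls)
        summaries = aggregate_genes(surviving, config.min_candidate, config.min_stringent)
        write_screen_tables(
            surviving,
            summaries,
            record(out / "shrna_depletion.tsv"),
            record(out / "gene_tiers.tsv"),
        )
        candidate = genes_at_tier(summaries, "candidate")
        stringent = genes_at_tier(summaries, "stringent")
        _write_gene_list(candidate, record(out / "screen_candidates.txt"))
        report["stages"]["screen"] = {
            "n_resistant_depleted": sum(c.depleted for c in resistant_calls),
            "n_acute_depleted": sum(c.depleted for c in acute_calls),
            "n_surviving_depleted": sum(c.depleted for c in surviving),
            "n_candidate_genes": len(candidate),
            "n_stringent_genes": len(stringent),
            "stringent_genes": sorted(stringent),
        }

    # ---------------------------------------------------------------------- de
    de_sets: dict[str, dict[str, set[str]]] = {}
    de_tables: dict[str, pd.DataFrame] = {}
    if "de" in config.stages:
        if rnaseq is None:
            raise ValidationError("de stage requires the simulate stage (or rnaseq inputs)")
        norm = normalize_by_size_factors(rnaseq)
        contrasts = {
            "resistant_vs_parental": ("parental", "resistant"),
            "kd1_vs_ctrl": ("ctrl", "kd1"),
            "kd2_vs_ctrl": ("ctrl", "kd2"),
        }
        de_summary = {}
        for name, (ga, gb) in contrasts.items():
            sa, sb = norm.samples_in_group(ga), norm.samples_in_group(gb)
            phi = estimate_dispersion(norm, {ga: sa, gb: sb})
            table = nb_test(norm, sa, sb, phi)
            sets = filter_de(table, config.p_max, config.min_abs_lfc, config.use_fdr)
            de_tables[name] = table
            de_sets[name] = sets
            table.to_csv(record(out / f"de_{name}.tsv"), sep="\t")
            _write_gene_list(sets["up"], record(out / f"de_{name}_up.txt"))
            _write_gene_list(sets["down"], record(out / f"de_{name}_down.txt"))
            de_summary[name] = {"n_up": len(sets["up"]), "n_down": len(sets["down"])}
        report["stages"]["de"] = de_summary

    # ----------------------------------------------------------------- integrate
    overlay = None
    if "integrate" in config.stages:
        if not summaries or "resistant_vs_parental" not in de_sets:
            raise ValidationError("integrate stage requires screen and de stages")
        res_sets = de_sets["resistant_vs_parental"]
        de_changed = res_sets["up"] | res_sets["down"]
        overlay = overlay_screen_de(summaries, de_changed, tier="candidate")
        targets_ix = target_candidates(de_sets["kd1_vs_ctrl"]["down"], res_sets["up"])
        coreg_ix = coregulated(
            de_sets["kd1_vs_ctrl"]["down"], de_sets["kd2_vs_ctrl"]["down"]
        )
        _write_gene_list(set(overlay.genes), record(out / "candidates_screen_x_de.txt"))
        _write_gene_list(set(targets_ix.genes), record(out / "target_candidates.txt"))
        _write_gene_list(set(coreg_ix.genes), record(out / "coregulated.txt"))
        report["stages"]["integrate"] = {
            ix.name: {
                "parents": list(ix.parents),
                "n_genes": len(ix.genes),
                "genes": sorted(ix.genes),
            }
            for ix in (overlay, targets_ix, coreg_ix)
        }
        report["stages"]["integrate"]["venn"] = {
            "screen_x_de": venn_summary(
                {"screen": genes_at_tier(summaries, "candidate"), "de": de_changed}
            ),
            "kd1_x_kd2_down": venn_summary(
                {
                    "kd1_down": de_sets["kd1_vs_ctrl"]["down"],
                    "kd2_down": de_sets["kd2_vs_ctrl"]["down"],
                }
            ),
        }

    # -------------------------------------------------------------------- enrich
    if "enrich" in config.stages:
        if overlay is None or "resistant_vs_parental" not in de_tables:
            raise ValidationError("enrich stage requires the integrate stage")
        universe = {g.upper() for g in library.genes}
        if config.gmt:
            collection = read_gmt(config.gmt)
        else:
            # truth-derived collection: planted sets plus a seeded random set
            rng = np.random.default_rng(config.seed + 6)
            genes_sorted = sorted(universe)
            rand = set(
                rng.choice(genes_sorted, size=min(30, len(genes_sorted)), replace=False)
            )
            sets = {"RANDOM_30": rand}
            if screen_truth is not None:
                sets["PLANTED_DRIVERS"] = {
                    g.upper() for g in screen_truth.genes_with_role("resistance_driver")
                }
                sets["PLANTED_ACUTE"] = {
                    g.upper() for g in screen_truth.genes_with_role("acute_essential")
                }
            collection = GeneSetCollection(sets=sets, source="planted")
            write_gmt(collection, record(out / "genesets.gmt"))
        query = set(overlay.genes)
        ora = ora_table(query, collection, universe)
        ora.to_csv(record(out / "ora.tsv"), sep="\t", index=False)
        ranked = (
            de_tables["resistant_vs_parental"]["log2fc"]
            .sort_values(ascending=False, kind="stable")
        )
        ranked.index = ranked.index.str.upper()
        gsea_rows = {}
        for name, genes in collection.sets.items():
            hits = set(genes) & set(ranked.index)
            if not hits or len(hits) == len(ranked):
                continue
            es, p_perm = gsea_perm_p(
                ranked, genes, n_perm=config.n_perm, seed=config.seed + 7,
                weight=config.gsea_weight,
            )
            gsea_rows[name] = {"es": round(es, 10), "p_perm": p_perm}
        report["stages"]["enrich"] = {
            "ora": {
                row.set_name: {"k": int(row.overlap_k), "p_hyper": float(row.p_hyper)}
                for row in ora.itertuples()
            },
            "gsea": gsea_rows,
        }

    report_path = out / "report.json"
    report["files"].append("report.json")
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
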