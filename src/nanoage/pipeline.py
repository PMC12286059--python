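"""End-to-end runner: bedMethyl cohort -> age-CpG tables, panel, annotation,
enrichment and clock overlap, with a machine-readable run manifest.

Stage order follows the preprocessing contract: aggregate -> coverage filter
-> complete cases -> split by modification -> per-CpG regression -> filters /
slope ranking / direction summary -> elastic-net selection -> genomic
annotation + GO enrichment -> clock harmonization and overlap.  Every stage
writes its TSV next to the others in ``outdir`` and reports its row count in
``run_manifest.json``; counts are monotone non-increasing through the filter
stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from . import agestats, annotate, clocks, cohort, io, selection

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, thresholds and flags of one pipeline run.

    Threshold defaults are the framework's standard operating point: minimum
    depth 5, univariate significance R² >= 0.8 and p < 0.001, elastic-net
    post-hoc report p < 0.0005, alpha = 0.5, 1 bp clock-match tolerance.
    """

    sample_sheet: str
    outdir: str
    gene_model: str | None = None
    term_map: str | None = None
    clock_manifest: str | None = None
    chains: dict[str, str] = field(default_factory=dict)  # build -> chain file
    min_cov: int = 5
    min_r2: float = 0.8
    max_p: float = 0.001
    enet_max_p: float = 0.0005
    alpha: float = 0.5
    n_lambda: int = 100
    lambda_rule: str = "min"
    tolerance: int = 1
    flat_epsilon: float = 0.0
    collapse_strands: bool = False
    sort: str = "slope"
    top_k: int = 20
    seed: int = 17

    def __post_init__(self) -> None:
        if self.min_cov < 1:
            raise ValueError("min_cov must be >= 1")
        if not (0 <= self.min_r2 <= 1) or not (0 < self.max_p <= 1):
            raise ValueError("regression thresholds out of range")
        if not (0 <= self.alpha <= 1):
            raise ValueError("alpha must be in [0, 1]")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("outdir")  # where results land does not change what they are
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Execute every stage and return the run manifest (also written to
    ``outdir/run_manifest.json``)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    manifest: dict[str, Any] = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "counts": counts,
    }

    sheet = io.read_sample_sheet(cfg.sample_sheet)
    samples = [s for s, _ in sheet]
    per_sample: dict[str, list[io.MethylRecord]] = {}
    for info, path in sheet:
        records = io.read_bedmethyl(path)
        if cfg.collapse_strands:
            records = cohort.collapse_strands(records)
        per_sample[info.sample_id] = records
    counts["input_records"] = sum(len(r) for r in per_sample.values())

    results: dict[str, Any] = {"manifest": manifest}
    all_rows: list[agestats.AgeRegressionRow] = []
    analyzed_sites: list[io.CpGSite] = []
    for mod in ("m", "h"):
        stage = f"{mod}"
        mat = cohort.aggregate(per_sample, samples, mod)
        counts[f"{stage}_sites_aggregated"] = mat.n_sites
        mat = cohort.filter_coverage(mat, cfg.min_cov)
        mat = cohort.complete_cases(mat)
        counts[f"{stage}_sites_complete"] = mat.n_sites
        cohort.write_matrix(mat, outdir / f"matrix_{mod}.tsv")

        rows = agestats.fit_age_regression(mat, flat_epsilon=cfg.flat_epsilon)
        counts[f"{stage}_sites_regressed"] = len(rows)
        agestats.write_rows(rows, outdir / f"regression_{mod}.tsv", sort=cfg.sort)
        sig = agestats.filter_rows(rows, cfg.min_r2, cfg.max_p)
        counts[f"{stage}_sites_significant"] = len(sig)
        agestats.write_rows(sig, outdir / f"significant_{mod}.tsv", sort=cfg.sort)
        if sig:
            neg, pos, flat = agestats.direction_summary(sig)
            manifest[f"{mod}_direction"] = {
                "frac_negative": neg, "frac_positive": pos, "frac_flat": flat,
            }
            for direction in ("positive", "negative"):
                top = agestats.top_by_slope(sig, cfg.top_k, direction)
                agestats.write_rows(top, outdir / f"top_{direction}_{mod}.tsv")

        model = None
        if mat.n_sites:
            model = selection.elasticnet_fit(
                mat, alpha=cfg.alpha, n_lambda=cfg.n_lambda,
                lambda_rule=cfg.lambda_rule, seed=cfg.seed,
            )
            counts[f"{stage}_sites_enet_selected"] = len(model.selected)
            selection.write_model(
                model, outdir / f"enet_weights_{mod}.tsv", outdir / f"enet_path_{mod}.tsv"
            )
            picked = selection.selected_with_stats(model, rows, cfg.min_r2, cfg.enet_max_p)
            counts[f"{stage}_sites_enet_reported"] = len(picked)
            agestats.write_rows(picked, outdir / f"enet_selected_{mod}.tsv")
        results[f"rows_{mod}"] = rows
        results[f"significant_{mod}"] = sig
        results[f"model_{mod}"] = model
        all_rows.extend(sig)
        analyzed_sites.extend(r.site for r in rows)

    sig_sites = [r.site for r in all_rows]
    counts["sites_significant_all"] = len(sig_sites)

    if cfg.gene_model:
        genes = io.read_gene_model(cfg.gene_model)
        ann = annotate.classify_sites(sig_sites, genes)
        annotate.write_annotations(ann, outdir / "annotation.tsv")
        counts["sites_annotated"] = len(ann)
        if ann:
            intra, inter = annotate.category_fractions(ann)
            manifest["annotation"] = {
                "frac_intragenic": intra,
                "frac_intergenic": inter,
                "biotype_counts": annotate.biotype_counts(ann),
            }
        results["annotation"] = ann

        if cfg.term_map:
            term_map = io.read_term_map(cfg.term_map)
            # universe: genes overlapping any analyzed (pre-significance) site,
            # guarding against panel ascertainment bias
            universe_ann = annotate.classify_sites(
                sorted(set(analyzed_sites), key=lambda s: s.key()), genes
            )
            universe = {g for a in universe_ann for g in a.gene_ids}
            selected = {g for a in ann for g in a.gene_ids}
            if universe:
                enriched = annotate.ora(selected, universe, term_map)
                annotate.write_ora(enriched, outdir / "go_enrichment.tsv")
                counts["go_terms_tested"] = len(enriched)
                results["ora"] = enriched

    if cfg.clock_manifest:
        manifest_cpgs = io.read_clock_manifest(cfg.clock_manifest)
        chains_by_build = {
            build: clocks.read_chain(path) for build, path in cfg.chains.items()
        }
        lifted, unmapped = clocks.harmonize_clock(manifest_cpgs, chains_by_build)
        counts["clock_cpgs_total"] = len(manifest_cpgs)
        counts["clock_cpgs_lifted"] = len(lifted)
        clock_sizes: dict[str, int] = {}
        for cpg in manifest_cpgs:
            clock_sizes[cpg.clock_name] = clock_sizes.get(cpg.clock_name, 0) + 1
        reports = clocks.overlap(
            sorted(set(sig_sites), key=lambda s: s.key()), lifted,
            tolerance=cfg.tolerance, clock_sizes=clock_sizes,
        )
        clocks.write_overlaps(reports, outdir / "clock_overlap.tsv")
        counts["clock_cpgs_overlapping"] = sum(r.n_overlap for r in reports)
        manifest["clock_overlap"] = {
            r.clock_name: {"size": r.clock_size, "lifted": r.n_lifted, "overlap": r.n_overlap}
            for r in reports
        }
        results["clock_reports"] = reports

    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("pipeline complete: %s", json.dumps(counts))
    return results
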