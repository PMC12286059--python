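"""Seeded synthetic methylation cohorts with planted age trends.

The generator emulates the data shape of a small nanopore adaptive-sampling
ageing cohort: one bedMethyl file per donor carrying both 5mC (``m``) and
5hmC (``h``) records at every site, a sample sheet with chronological ages,
and a ground-truth manifest.  Per site i and donor j the true methylation is

    beta_ij = clip(a_i + b_i * age_j + eps_ij, 0, 1),   eps ~ N(0, sigma^2)

with b_i = 0 for null sites and |b_i| drawn from ``slope_range`` for planted
hypo-/hypermethylating sites; intercepts are placed so that the noiseless
trajectory stays inside the ``clip`` band at every age.  Read sampling is
binomial at 1 + Poisson(lambda - 1) coverage, so the emitted percent column
carries realistic counting noise.  Everything is deterministic given the
seed.

Defaults mirror a seven-donor blood cohort spanning ages 5-91, beta drift of
0.002-0.008 per year at the planted sites, residual scatter of 0.02 and mean
depth 30x.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    CpGSite,
    Interval,
    MethylRecord,
    SampleInfo,
    write_bed,
    write_bedmethyl,
)

DEFAULT_AGES = (5.0, 13.0, 24.0, 46.0, 60.0, 75.0, 91.0)


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort."""

    ages: Sequence[float] = DEFAULT_AGES
    n_null: int = 500          # per modification
    n_pos: int = 100
    n_neg: int = 100
    slope_range: tuple[float, float] = (0.002, 0.008)  # |beta|/year
    noise_sd: float = 0.02
    coverage_mean: float = 30.0
    coverage_model: str = "poisson_plus_one"  # or "exact"
    missing_rate: float = 0.0
    clip: tuple[float, float] = (0.02, 0.98)  # trajectory placement band
    chrom: str = "chr1"
    first_pos0: int = 100
    spacing: int = 10
    seed: int = 17

    def __post_init__(self) -> None:
        ages = [float(a) for a in self.ages]
        if any(a <= 0 for a in ages) or len(set(ages)) < 3:
            raise ValueError("need >= 3 distinct positive ages")
        self.ages = tuple(ages)
        span = max(ages) - min(ages)
        lo, hi = self.slope_range
        if not (0 < lo <= hi):
            raise ValueError("slope_range must be positive and ordered")
        band = self.clip[1] - self.clip[0]
        if hi * span >= band:
            raise ValueError(
                f"slope {hi} infeasible: drift over {span} years exceeds the "
                f"placement band {band}"
            )
        if self.coverage_model not in ("poisson_plus_one", "exact"):
            raise ValueError(f"unknown coverage model {self.coverage_model!r}")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")

    @property
    def n_sites(self) -> int:
        return self.n_null + self.n_pos + self.n_neg


@dataclass
class SimResult:
    """Paths and ground truth of one simulated cohort."""

    sample_sheet: Path
    bedmethyl: dict[str, Path]
    truth_path: Path
    truth: pd.DataFrame          # site, pos0, mod_code, intercept, slope, planted, direction
    samples: list[SampleInfo] = field(default_factory=list)


def _plant_slopes(cfg: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (intercept, slope) with feasible intercept placement."""
    ages = np.asarray(cfg.ages)
    lo_c, hi_c = cfg.clip
    slopes = np.zeros(cfg.n_sites)
    mag = rng.uniform(*cfg.slope_range, size=cfg.n_pos + cfg.n_neg)
    slopes[: cfg.n_pos] = mag[: cfg.n_pos]
    slopes[cfg.n_pos : cfg.n_pos + cfg.n_neg] = -mag[cfg.n_pos :]
    # trajectory a + b*age must stay in [lo_c, hi_c] at every sampled age
    a_lo = np.maximum(lo_c - slopes * ages.min(), lo_c - slopes * ages.max())
    a_hi = np.minimum(hi_c - slopes * ages.min(), hi_c - slopes * ages.max())
    bad = a_lo >= a_hi
    if bad.any():
        raise ValueError(f"infeasible intercept placement for slope {slopes[bad][0]:g}")
    intercepts = rng.uniform(a_lo, a_hi)
    return intercepts, slopes


def simulate_cohort(cfg: SimConfig, outdir: str | Path) -> SimResult:
    """Write a cohort of per-sample bedMethyl files plus sheet and truth.

    Site role assignment, trajectory parameters and read sampling are all
    drawn from one generator seeded with ``cfg.seed``; two runs with the same
    config produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    ages = np.asarray(cfg.ages)
    n_samples = len(ages)
    positions = cfg.first_pos0 + cfg.spacing * np.arange(cfg.n_sites)
    sites = [CpGSite(cfg.chrom, int(p), "+") for p in positions]

    truth_rows = []
    per_mod: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for mod in ("m", "h"):
        order = rng.permutation(cfg.n_sites)  # which sites carry planted trends
        intercepts_r, slopes_r = _plant_slopes(cfg, rng)
        intercepts = np.empty(cfg.n_sites)
        slopes = np.empty(cfg.n_sites)
        intercepts[order] = intercepts_r
        slopes[order] = slopes_r
        per_mod[mod] = (intercepts, slopes, order)
        for i, site in enumerate(sites):
            b = slopes[i]
            truth_rows.append(
                dict(
                    chrom=site.chrom,
                    pos0=site.pos0,
                    mod_code=mod,
                    intercept=intercepts[i],
                    slope=b,
                    planted=bool(b != 0.0),
                    direction="positive" if b > 0 else ("negative" if b < 0 else "flat"),
                )
            )
    truth = pd.DataFrame(truth_rows)

    samples = [SampleInfo(f"S{int(a):02d}" if float(a).is_integer() else f"S{a:g}", float(a))
               for a in ages]
    if len({s.sample_id for s in samples}) != len(samples):
        samples = [SampleInfo(f"S{j:02d}_{a:g}", float(a)) for j, a in enumerate(ages)]

    bed_paths: dict[str, Path] = {}
    for j, sample in enumerate(samples):
        records: list[MethylRecord] = []
        for mod in ("m", "h"):
            intercepts, slopes, _ = per_mod[mod]
            beta_true = np.clip(
                intercepts + slopes * ages[j] + rng.normal(0, cfg.noise_sd, cfg.n_sites),
                0.0,
                1.0,
            )
            if cfg.coverage_model == "exact":
                cov = np.full(cfg.n_sites, int(round(cfg.coverage_mean)))
                n_mod = np.round(cov * beta_true).astype(int)
            else:
                cov = 1 + rng.poisson(cfg.coverage_mean - 1.0, cfg.n_sites)
                n_mod = rng.binomial(cov, beta_true)
            keep = (
                rng.random(cfg.n_sites) >= cfg.missing_rate
                if cfg.missing_rate > 0
                else np.ones(cfg.n_sites, dtype=bool)
            )
            for i, site in enumerate(sites):
                if not keep[i]:
                    continue
                c, nm = int(cov[i]), int(n_mod[i])
                records.append(
                    MethylRecord(site, mod, c, nm, nm / c if c else float("nan"))
                )
        # stable bedMethyl order: position then mod code
        records.sort(key=lambda r: (r.site.chrom, r.site.pos0, r.mod_code))
        path = outdir / f"{sample.sample_id}.bedmethyl"
        write_bedmethyl(records, path)
        bed_paths[sample.sample_id] = path

    sheet_path = outdir / "samples.csv"
    with open(sheet_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "age_years", "path"])
        for s in samples:
            writer.writerow([s.sample_id, f"{s.age_years:g}", bed_paths[s.sample_id].name])

    truth_path = outdir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return SimResult(sheet_path, bed_paths, truth_path, truth, samples)


# ---------------------------------------------------------------------------
# Tiny deterministic fixtures for tests and the end-to-end smoke run
# ---------------------------------------------------------------------------


def make_fixtures(outdir: str | Path) -> dict[str, Path]:
    """Write the bundled fixture set: a 5-line bedMethyl, a 10-gene GFF3,
    toy chain files (identity / offset / minus-strand / gapped), a 4-clock
    manifest with the published clock sizes (353/71/102/391) at synthetic
    coordinates, a gene-to-GO map and a chrom.sizes table.

    All content is generated, deterministic and coordinate-compatible with
    :func:`simulate_cohort` defaults (sites on chr1 from pos0 100, step 10).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    # --- bedMethyl with one non-m/h row (6mA) that readers must skip
    bm = outdir / "tiny.bedmethyl"
    bm.write_text(
        "chr1\t9\t10\tm\t12\t+\t9\t10\t255,0,0\t12\t50.00\t6\t6\t0\t0\t0\t0\t0\n"
        "chr1\t19\t20\th\t8\t+\t19\t20\t255,0,0\t8\t25.00\t2\t6\t0\t0\t0\t0\t0\n"
        "chr1\t29\t30\ta\t5\t+\t29\t30\t255,0,0\t5\t20.00\t1\t4\t0\t0\t0\t0\t0\n"
        "chr2\t9\t10\tm\t20\t-\t9\t10\t255,0,0\t20\t10.00\t2\t18\t0\t0\t0\t0\t0\n"
        "chr2\t99\t100\tm\t0\t+\t99\t100\t255,0,0\t0\t0.00\t0\t0\t0\t0\t0\t0\t0\n"
    )
    paths["bedmethyl"] = bm

    # --- 10-gene GFF3 over the simulated site grid (chr1:100 + 10*i)
    biotypes = [
        "protein_coding", "protein_coding", "protein_coding", "protein_coding",
        "lncRNA", "lncRNA", "transcribed_unprocessed_pseudogene",
        "unprocessed_pseudogene", "protein_coding", "lncRNA",
    ]
    gff = outdir / "genes.gff3"
    lines = ["##gff-version 3"]
    for i, bt in enumerate(biotypes):
        start1 = 101 + 800 * i           # 1-based inclusive
        end1 = start1 + 599              # 600-bp gene bodies, 200-bp gaps
        lines.append(
            f"chr1\tsynthetic\tgene\t{start1}\t{end1}\t.\t{'+' if i % 2 == 0 else '-'}\t.\t"
            f"ID=G{i:02d};Name=GENE{i:02d};gene_biotype={bt}"
        )
    # one exon feature that read_gene_model must ignore
    lines.append("chr1\tsynthetic\texon\t101\t200\t.\t+\t.\tID=G00.e1;Parent=G00")
    gff.write_text("\n".join(lines) + "\n")
    paths["gff3"] = gff

    # --- gene -> GO term map
    go = outdir / "gene2go.tsv"
    go_lines = ["gene_id\tterm_id\tterm_name\tnamespace"]
    terms = [
        ("GO:0000001", "synthetic process one", "BP"),
        ("GO:0000002", "synthetic process two", "BP"),
        ("GO:0000003", "synthetic function", "MF"),
        ("GO:0000004", "synthetic component", "CC"),
    ]
    for i in range(10):
        go_lines.append(f"G{i:02d}\t{terms[i % 4][0]}\t{terms[i % 4][1]}\t{terms[i % 4][2]}")
        if i < 4:  # first genes carry a second, shared term
            go_lines.append(f"G{i:02d}\t{terms[0][0]}\t{terms[0][1]}\t{terms[0][2]}")
    go.write_text("\n".join(dict.fromkeys(go_lines)) + "\n")
    paths["gene2go"] = go

    # --- chrom sizes + interval panels
    sizes = outdir / "genome.sizes"
    sizes.write_text("chr1\t100000\nchr2\t50000\n")
    paths["genome_sizes"] = sizes
    panel_a = outdir / "panel_rrms.bed"
    write_bed([Interval("chr1", 0, 6000), Interval("chr2", 100, 2000)], panel_a)
    panel_b = outdir / "panel_cancer.bed"
    write_bed([Interval("chr1", 4000, 9000), Interval("chr2", 3000, 3500)], panel_b)
    paths["panel_a"], paths["panel_b"] = panel_a, panel_b

    # --- toy chains on a 100 kb chromosome
    def chain_file(name: str, text: str) -> Path:
        p = outdir / name
        p.write_text(text)
        return p

    paths["chain_identity"] = chain_file(
        "identity.chain",
        "chain 1000 chr1 100000 + 0 100000 chr1 100000 + 0 100000 1\n100000\n\n",
    )
    # hg19 -> hg38 surrogate: everything shifts +50
    paths["chain_offset"] = chain_file(
        "hg19_offset.chain",
        "chain 900 chr1 100000 + 0 99950 chr1 100000 + 50 100000 1\n99950\n\n",
    )
    # hg18 -> hg38 surrogate: minus-strand mapping of a 1 kb window,
    # plus a gapped chain with a 100 bp target deletion
    paths["chain_minus"] = chain_file(
        "hg18_minus.chain",
        "chain 800 chr1 100000 + 10000 11000 chr1 100000 - 89000 90000 1\n1000\n\n",
    )
    paths["chain_gapped"] = chain_file(
        "gapped.chain",
        "chain 700 chr2 50000 + 1000 2100 chr2 50000 + 5000 6000 1\n"
        "500\t100\t0\n500\n\n",
    )

    # --- clock manifests: published sizes, synthetic coordinates
    clock_sizes = {
        "Horvath353": (353, "hg19"),
        "Hannum71": (71, "hg19"),
        "Weidner102": (102, "hg18"),
        "HorvathSkinBlood391": (391, "hg19"),
    }
    manifest = outdir / "clock_manifest.tsv"
    rows = ["ilmn_id\tclock_name\tbuild\tchrom\tpos1"]
    probe = 0
    for clock, (size, build) in clock_sizes.items():
        for i in range(size):
            probe += 1
            if build == "hg19":
                # lifted position = pos1 - 1 + 50; aligned to the simulated
                # site grid (100 + 10*i) for every 8th probe
                if i % 8 == 0:
                    pos0_hg38 = 100 + 10 * (i // 8)
                    pos1 = pos0_hg38 - 50 + 1
                else:
                    pos1 = 20000 + 37 * probe
            else:
                # hg18 probes live in the minus-strand window
                pos1 = 10000 + (i % 1000) + 1
            rows.append(f"cg{probe:08d}\t{clock}\t{build}\tchr1\t{pos1}")
    manifest.write_text("\n".join(rows) + "\n")
    paths["clock_manifest"] = manifest
    return paths
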