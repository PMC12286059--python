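"""Readers and writers for the text formats the pipeline touches.

The central input is modkit-style bedMethyl: a BED9+ tab text with one row per
(CpG, strand, modification code) carrying valid coverage, the percent of
modified calls, and optionally the raw call counts.  Around it sit BED interval
panels (adaptive-sampling targets), GFF3 gene models, epigenetic-clock CpG
manifests, gene-to-GO-term maps, UCSC chrom.sizes tables and sample sheets.

Coordinates are 0-based half-open internally; report writers emit both ``pos0``
and ``pos1`` columns so downstream users never have to guess the basing.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

MOD_CODES = ("m", "h")
KNOWN_BUILDS = ("hg18", "hg19", "hg38")


class ParseError(ValueError):
    """A malformed line in an input file; message names file and line number."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class CpGSite:
    """A cytosine position: chromosome, 0-based start, strand (+/-/.)."""

    chrom: str
    pos0: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("CpGSite.chrom must be non-empty")
        if self.pos0 < 0:
            raise ValueError(f"CpGSite.pos0 must be >= 0, got {self.pos0}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def pos1(self) -> int:
        """1-based position of the same base."""
        return self.pos0 + 1

    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos0)


@dataclass(frozen=True)
class MethylRecord:
    """One bedMethyl row: site, modification code, coverage, modified count.

    ``beta`` is the fraction of modified calls.  When ``valid_coverage`` is 0
    the beta is undefined and flagged missing (``beta_missing``).
    """

    site: CpGSite
    mod_code: str
    valid_coverage: int
    n_mod: int
    beta: float

    def __post_init__(self) -> None:
        if self.mod_code not in MOD_CODES:
            raise ValueError(f"mod_code must be one of {MOD_CODES}, got {self.mod_code!r}")
        if self.valid_coverage < 0 or self.n_mod < 0:
            raise ValueError("counts must be non-negative")
        if self.n_mod > self.valid_coverage:
            raise ValueError(
                f"n_mod ({self.n_mod}) exceeds valid_coverage ({self.valid_coverage})"
            )
        if self.valid_coverage > 0:
            expect = self.n_mod / self.valid_coverage
            # tolerate the 2-decimal rounding of the percent column
            if abs(self.beta - expect) > 0.5 / self.valid_coverage + 1e-9:
                raise ValueError(
                    f"beta {self.beta} inconsistent with {self.n_mod}/{self.valid_coverage}"
                )

    @property
    def beta_missing(self) -> bool:
        return self.valid_coverage == 0


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"interval start must be < end: {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneFeature:
    interval: Interval
    gene_id: str
    gene_name: str
    biotype: str
    strand: str

    def __post_init__(self) -> None:
        if not self.biotype:
            raise ValueError("biotype must be non-empty")


@dataclass(frozen=True)
class ClockCpG:
    """One Illumina-array CpG from a published clock, with its genome build."""

    ilmn_id: str
    clock_name: str
    build: str
    chrom: str
    pos1: int

    def __post_init__(self) -> None:
        if self.build not in KNOWN_BUILDS:
            raise ValueError(f"unknown genome build {self.build!r}")
        if self.pos1 < 1:
            raise ValueError(f"pos1 must be >= 1, got {self.pos1}")


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    age_years: float

    def __post_init__(self) -> None:
        if not self.age_years > 0 or self.age_years != self.age_years:
            raise ValueError(f"age must be a finite positive number, got {self.age_years}")


# ---------------------------------------------------------------------------
# bedMethyl
# ---------------------------------------------------------------------------

# modkit BED9+ column order; columns 12+ are count columns and optional
_BEDMETHYL_MIN_COLS = 11


def read_bedmethyl(path: str | Path, dialect: str = "auto") -> list[MethylRecord]:
    """Parse a modkit bedMethyl file into :class:`MethylRecord` objects.

    Rows whose modification code is not ``m`` (5mC) or ``h`` (5hmC) — e.g.
    6mA's ``a`` — are skipped; the skipped count is logged.  ``dialect`` may be
    ``tab`` (split on tabs only) or ``auto``/``mixed`` (split on any whitespace
    run, covering modkit's historical tab+space output).

    Beta is taken from Nmod/Nvalid_cov when the count columns are present and
    from the rounded percent column otherwise.
    """
    path = Path(path)
    records: list[MethylRecord] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if dialect == "tab" else line.split()
            if len(fields) < _BEDMETHYL_MIN_COLS:
                raise ParseError(
                    f"{path}:{lineno}: expected >= {_BEDMETHYL_MIN_COLS} columns, "
                    f"got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start = int(fields[1])
                end = int(fields[2])
                code = fields[3]
                strand = fields[5]
                cov = int(fields[9])
                pct = float(fields[10])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start ({start}) >= end ({end})")
            if cov < 0:
                raise ParseError(f"{path}:{lineno}: negative coverage {cov}")
            if code not in MOD_CODES:
                skipped += 1
                continue
            if len(fields) >= 12:
                n_mod = int(fields[11])
                if n_mod < 0:
                    raise ParseError(f"{path}:{lineno}: negative Nmod {n_mod}")
            else:
                n_mod = round(cov * pct / 100.0)
            beta = (n_mod / cov) if cov > 0 else float("nan")
            try:
                records.append(
                    MethylRecord(
                        site=CpGSite(chrom, start, strand),
                        mod_code=code,
                        valid_coverage=cov,
                        n_mod=n_mod,
                        beta=beta,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    if skipped:
        log.info("read_bedmethyl(%s): skipped %d non-m/h rows", path, skipped)
    return records


def write_bedmethyl(records: Iterable[MethylRecord], path: str | Path) -> Path:
    """Write records as 18-column modkit bedMethyl; round-trips exactly."""
    path = Path(path)
    with open(path, "w") as fh:
        for r in records:
            cov, nm = r.valid_coverage, r.n_mod
            pct = 100.0 * nm / cov if cov > 0 else 0.0
            fh.write(
                "\t".join(
                    [
                        r.site.chrom,
                        str(r.site.pos0),
                        str(r.site.pos0 + 1),
                        r.mod_code,
                        str(cov),
                        r.site.strand,
                        str(r.site.pos0),
                        str(r.site.pos0 + 1),
                        "255,0,0",
                        str(cov),
                        f"{pct:.2f}",
                        str(nm),
                        str(cov - nm),
                        "0",
                        "0",
                        "0",
                        "0",
                        "0",
                    ]
                )
                + "\n"
            )
    return path


# ---------------------------------------------------------------------------
# BED panels
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[Interval]:
    """Read a BED3/BED4 interval panel."""
    path = Path(path)
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                iv = Interval(
                    fields[0],
                    int(fields[1]),
                    int(fields[2]),
                    fields[3] if len(fields) > 3 else None,
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            out.append(iv)
    return out


def write_bed(intervals: Iterable[Interval], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None:
                cols.append(iv.name)
            fh.write("\t".join(cols) + "\n")
    return path


def merge_panels(panels: Sequence[Sequence[Interval]]) -> list[Interval]:
    """Union of interval panels: sorted, non-overlapping, touching runs merged."""
    all_ivs = sorted(
        (iv for panel in panels for iv in panel), key=lambda iv: (iv.chrom, iv.start, iv.end)
    )
    merged: list[Interval] = []
    for iv in all_ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = Interval(last.chrom, last.start, iv.end)
        else:
            merged.append(Interval(iv.chrom, iv.start, iv.end))
    return merged


def panel_stats(
    panel: Sequence[Interval], genome_sizes: Mapping[str, int]
) -> tuple[int, float]:
    """Total bp covered by a merged panel and the genome fraction it targets."""
    missing = sorted({iv.chrom for iv in panel} - set(genome_sizes))
    if missing:
        raise ValueError(f"panel chromosomes absent from genome sizes: {', '.join(missing)}")
    total = sum(len(iv) for iv in panel)
    genome = sum(genome_sizes.values())
    return total, (total / genome if genome else 0.0)


def read_genome_sizes(path: str | Path) -> dict[str, int]:
    """Read a UCSC chrom.sizes two-column table."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
    return sizes


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

_BIOTYPE_KEYS = ("gene_biotype", "biotype", "gene_type")  # Ensembl, generic, GENCODE


def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in text.strip().rstrip(";").split(";"):
        if not item:
            continue
        if "=" in item:
            key, _, val = item.partition("=")
            attrs[key.strip()] = val.strip()
    return attrs


def read_gene_model(path: str | Path) -> list[GeneFeature]:
    """Extract ``gene`` features from a GFF3 file (1-based inclusive -> 0-based
    half-open). Non-gene features are ignored; a missing biotype attribute is
    kept as ``unknown`` with a warning."""
    path = Path(path)
    genes: list[GeneFeature] = []
    n_unknown = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated columns")
            if fields[2] != "gene":
                continue
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            attrs = _parse_gff_attributes(fields[8])
            gene_id = attrs.get("ID", attrs.get("gene_id", f"gene@{lineno}"))
            gene_name = attrs.get("Name", attrs.get("gene_name", gene_id))
            biotype = next((attrs[k] for k in _BIOTYPE_KEYS if k in attrs), None)
            if biotype is None:
                biotype = "unknown"
                n_unknown += 1
            genes.append(
                GeneFeature(
                    interval=Interval(fields[0], start1 - 1, end1, name=gene_id),
                    gene_id=gene_id,
                    gene_name=gene_name,
                    biotype=biotype,
                    strand=fields[6],
                )
            )
    if n_unknown:
        log.warning("read_gene_model(%s): %d genes lack a biotype attribute", path, n_unknown)
    return genes


# ---------------------------------------------------------------------------
# Clock manifests, term maps, sample sheets
# ---------------------------------------------------------------------------


def read_clock_manifest(path: str | Path) -> list[ClockCpG]:
    """Read a TSV/CSV clock manifest: ilmn_id, clock_name, build, chrom, pos1.

    Duplicate (ilmn_id, clock_name) rows are an error — each array probe
    appears at most once per clock.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    out: list[ClockCpG] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        reader = csv.DictReader(
            (l for l in fh if not l.startswith("#")), delimiter=sep
        )
        required = {"ilmn_id", "clock_name", "build", "chrom", "pos1"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ParseError(f"{path}: manifest must have columns {sorted(required)}")
        for i, row in enumerate(reader, start=2):
            try:
                cpg = ClockCpG(
                    ilmn_id=row["ilmn_id"],
                    clock_name=row["clock_name"],
                    build=row["build"],
                    chrom=row["chrom"],
                    pos1=int(row["pos1"]),
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{i}: {exc}") from None
            key = (cpg.ilmn_id, cpg.clock_name)
            if key in seen:
                raise ParseError(f"{path}:{i}: duplicate probe {key[0]} in clock {key[1]}")
            seen.add(key)
            out.append(cpg)
    return out


def read_term_map(path: str | Path) -> dict[str, list[tuple[str, str, str]]]:
    """Read a gene-to-GO map TSV (gene_id, term_id, term_name, namespace) into
    ``{gene_id: [(term_id, term_name, namespace), ...]}``."""
    mapping: dict[str, list[tuple[str, str, str]]] = {}
    with open(path) as fh:
        reader = csv.DictReader((l for l in fh if not l.startswith("#")), delimiter="\t")
        for row in reader:
            ns = row["namespace"]
            if ns not in ("BP", "MF", "CC"):
                raise ParseError(f"{path}: unknown GO namespace {ns!r}")
            mapping.setdefault(row["gene_id"], []).append(
                (row["term_id"], row["term_name"], ns)
            )
    return mapping


def read_sample_sheet(path: str | Path) -> list[tuple[SampleInfo, Path]]:
    """Read a cohort sample sheet CSV (sample_id, age_years, path)."""
    path = Path(path)
    out: list[tuple[SampleInfo, Path]] = []
    ids: set[str] = set()
    with open(path) as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            sid = row["sample_id"]
            if sid in ids:
                raise ParseError(f"{path}: duplicate sample_id {sid}")
            ids.add(sid)
            bm = Path(row["path"])
            if not bm.is_absolute():
                bm = path.parent / bm
            out.append((SampleInfo(sid, float(row["age_years"])), bm))
    return out
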