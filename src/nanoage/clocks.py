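"""Cross-build harmonization of published epigenetic-clock CpGs.

Published clocks (Horvath 353, Hannum 71, Weidner 102, Horvath Skin & Blood
391) are defined on Illumina array probes whose manifests carry hg18 or hg19
coordinates; nanopore CpG calls live on hg38.  This module implements point
liftover natively from the UCSC chain format — each chain is an ungapped-block
alignment between a target (source assembly, always + strand) and a query
(destination assembly, either strand) — and counts which lifted clock CpGs
coincide with the nanopore CpG set.

Chain semantics: a target position falling inside an aligned block maps to the
query at the same block offset; positions falling in a target gap (``dt``) are
deleted in the destination and unmapped.  For minus-strand chains the query
coordinates in the file run on the reverse strand and are flipped back with
``q_size - 1 - pos``.  When several chains cover a position the highest-scoring
one wins (the UCSC convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io import ClockCpG, CpGSite, ParseError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChainBlock:
    size: int  # aligned bases
    dt: int    # gap on the target after the block
    dq: int    # gap on the query after the block

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("block size must be > 0")
        if self.dt < 0 or self.dq < 0:
            raise ValueError("gaps must be >= 0")


@dataclass(frozen=True)
class Chain:
    score: float
    t_name: str
    t_size: int
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    chain_id: str
    blocks: tuple[ChainBlock, ...]

    def __post_init__(self) -> None:
        t_span = sum(b.size + b.dt for b in self.blocks)
        q_span = sum(b.size + b.dq for b in self.blocks)
        if t_span != self.t_end - self.t_start:
            raise ValueError(
                f"chain {self.chain_id}: blocks span {t_span} target bases, "
                f"header says {self.t_end - self.t_start}"
            )
        if q_span != self.q_end - self.q_start:
            raise ValueError(
                f"chain {self.chain_id}: blocks span {q_span} query bases, "
                f"header says {self.q_end - self.q_start}"
            )


@dataclass(frozen=True)
class LiftResult:
    mapped: bool
    chrom: str | None = None
    pos0: int | None = None
    same_strand: bool = True
    reason: str | None = None


@dataclass
class OverlapReport:
    clock_name: str
    clock_size: int
    n_lifted: int
    n_overlap: int
    pairs: list[tuple[ClockCpG, CpGSite]]

    def __post_init__(self) -> None:
        if not (self.n_overlap <= self.n_lifted <= self.clock_size):
            raise ValueError("expected n_overlap <= n_lifted <= clock_size")


def read_chain(path: str | Path) -> list[Chain]:
    """Parse a UCSC chain file, verifying block sums against header spans."""
    path = Path(path)
    chains: list[Chain] = []
    header: list[str] | None = None
    header_line = 0
    blocks: list[tuple[int, int, int]] = []

    def finish(lineno: int) -> None:
        nonlocal header, blocks
        if header is None:
            return
        if not blocks or blocks[-1][1] != 0 or blocks[-1][2] != 0:
            raise ParseError(
                f"{path}:{header_line}: chain has no terminating bare-size block"
            )
        (_, score, t_name, t_size, t_strand, t_start, t_end,
         q_name, q_size, q_strand, q_start, q_end, *rest) = header
        if t_strand != "+":
            raise ParseError(f"{path}:{header_line}: target strand must be '+'")
        if q_strand not in ("+", "-"):
            raise ParseError(f"{path}:{header_line}: bad query strand {q_strand!r}")
        cid = rest[0] if rest else str(len(chains) + 1)
        try:
            chain = Chain(
                score=float(score),
                t_name=t_name, t_size=int(t_size),
                t_start=int(t_start), t_end=int(t_end),
                q_name=q_name, q_size=int(q_size), q_strand=q_strand,
                q_start=int(q_start), q_end=int(q_end),
                chain_id=cid,
                blocks=tuple(ChainBlock(*b) for b in blocks),
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{header_line}: {exc}") from None
        chains.append(chain)
        header, blocks = None, []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("chain"):
                finish(lineno)
                header = line.split()
                if len(header) not in (12, 13):
                    raise ParseError(f"{path}:{lineno}: chain header needs 12-13 fields")
                header_line = lineno
                continue
            if header is None:
                raise ParseError(f"{path}:{lineno}: alignment line outside a chain")
            parts = line.split()
            try:
                if len(parts) == 3:
                    blocks.append((int(parts[0]), int(parts[1]), int(parts[2])))
                elif len(parts) == 1:
                    blocks.append((int(parts[0]), 0, 0))
                else:
                    raise ValueError("expected 1 or 3 integers")
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    finish(-1)
    return chains


def liftover_point(
    chains: Sequence[Chain], chrom: str, pos0: int
) -> LiftResult:
    """Map one 0-based target position to the query assembly.

    Walks the aligned blocks of the highest-scoring chain covering the
    position.  ``unmapped`` is a value (reason ``no_chain`` or ``deleted``),
    never an exception.  Chromosome names are compared after normalizing the
    ``chrN``/``N`` spelling.
    """
    covering = [
        c for c in chains
        if _norm_chrom(c.t_name) == _norm_chrom(chrom) and c.t_start <= pos0 < c.t_end
    ]
    if not covering:
        return LiftResult(False, reason="no_chain")
    chain = max(covering, key=lambda c: c.score)
    t_cursor = chain.t_start
    q_cursor = chain.q_start
    for block in chain.blocks:
        if pos0 < t_cursor + block.size:
            offset = pos0 - t_cursor
            q_pos = q_cursor + offset
            if chain.q_strand == "-":
                return LiftResult(
                    True, chain.q_name, chain.q_size - 1 - q_pos, same_strand=False
                )
            return LiftResult(True, chain.q_name, q_pos, same_strand=True)
        t_cursor += block.size + block.dt
        q_cursor += block.size + block.dq
        if pos0 < t_cursor:  # inside the dt gap: deleted in the query assembly
            return LiftResult(False, reason="deleted")
    return LiftResult(False, reason="deleted")  # unreachable for valid chains


def _norm_chrom(name: str) -> str:
    return name if name.startswith("chr") else f"chr{name}"


def harmonize_clock(
    clock: Sequence[ClockCpG],
    chains_by_build: Mapping[str, Sequence[Chain]],
) -> tuple[list[ClockCpG], list[tuple[ClockCpG, str]]]:
    """Lift a clock manifest to hg38.

    hg38 rows pass through unchanged; hg18/hg19 rows are lifted point-wise on
    pos1-1.  Chromosome names are normalized to the ``chrN`` convention on
    both sides.  Returns (lifted manifest, unmapped report with reasons).
    """
    lifted: list[ClockCpG] = []
    unmapped: list[tuple[ClockCpG, str]] = []
    chain_index: dict[str, dict[str, list[Chain]]] = {}
    for build, chains in chains_by_build.items():
        idx: dict[str, list[Chain]] = {}
        for c in chains:
            idx.setdefault(_norm_chrom(c.t_name), []).append(c)
        chain_index[build] = idx

    for cpg in clock:
        if cpg.build == "hg38":
            lifted.append(
                ClockCpG(cpg.ilmn_id, cpg.clock_name, "hg38", _norm_chrom(cpg.chrom), cpg.pos1)
            )
            continue
        if cpg.build not in chains_by_build:
            raise ValueError(f"no chain set supplied for build {cpg.build}")
        chains = chain_index[cpg.build].get(_norm_chrom(cpg.chrom), [])
        res = liftover_point(chains, cpg.chrom, cpg.pos1 - 1)
        if not res.mapped:
            unmapped.append((cpg, res.reason or "no_chain"))
            continue
        lifted.append(
            ClockCpG(cpg.ilmn_id, cpg.clock_name, "hg38", _norm_chrom(res.chrom), res.pos0 + 1)
        )
    if unmapped:
        log.info("harmonize_clock: %d CpGs failed liftover", len(unmapped))
    return lifted, unmapped


def overlap(
    ont_sites: Sequence[CpGSite],
    clock_hg38: Sequence[ClockCpG],
    tolerance: int = 1,
    clock_sizes: Mapping[str, int] | None = None,
) -> list[OverlapReport]:
    """Match lifted clock CpGs against the nanopore CpG set, per clock.

    A clock CpG matches an ONT site when the chromosomes agree and
    |(pos1-1) - pos0| <= tolerance (default 1 bp: the array annotation marks
    the C on one strand of the CpG dinucleotide, the nanopore record may sit
    on the other).  Each clock CpG takes its nearest site, ties to the lower
    position; a CpG shared by several clocks counts once in each.
    """
    by_chrom: dict[str, np.ndarray] = {}
    site_lookup: dict[str, list[CpGSite]] = {}
    for s in sorted(ont_sites, key=lambda s: (s.chrom, s.pos0)):
        site_lookup.setdefault(s.chrom, []).append(s)
    for chrom, slist in site_lookup.items():
        by_chrom[chrom] = np.array([s.pos0 for s in slist])

    clocks: dict[str, list[ClockCpG]] = {}
    for cpg in clock_hg38:
        clocks.setdefault(cpg.clock_name, []).append(cpg)

    reports: list[OverlapReport] = []
    for clock_name in sorted(clocks):
        members = clocks[clock_name]
        pairs: list[tuple[ClockCpG, CpGSite]] = []
        for cpg in members:
            positions = by_chrom.get(cpg.chrom)
            if positions is None or positions.size == 0:
                continue
            target = cpg.pos1 - 1
            j = int(np.searchsorted(positions, target))
            # nearest among the two flanking candidates; tie -> lower pos0
            best = None
            for cand in (j - 1, j):
                if 0 <= cand < positions.size:
                    d = abs(int(positions[cand]) - target)
                    if d <= tolerance and (best is None or d < best[0]):
                        best = (d, cand)
            if best is not None:
                pairs.append((cpg, site_lookup[cpg.chrom][best[1]]))
        size = len(members) if clock_sizes is None else clock_sizes[clock_name]
        reports.append(
            OverlapReport(
                clock_name=clock_name,
                clock_size=size,
                n_lifted=len(members),
                n_overlap=len(pairs),
                pairs=pairs,
            )
        )
    return reports


def write_overlaps(reports: Sequence[OverlapReport], path: str | Path) -> Path:
    """One row per matched (probe, ONT site) pair, plus per-clock totals in
    the header comments."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#ilmn_id\tclock_name\tont_chrom\tont_pos0\tont_pos1\tdistance\n")
        for rep in reports:
            fh.write(
                f"# clock {rep.clock_name}: size={rep.clock_size} "
                f"lifted={rep.n_lifted} overlap={rep.n_overlap}\n"
            )
            for cpg, site in rep.pairs:
                d = abs((cpg.pos1 - 1) - site.pos0)
                fh.write(
                    f"{cpg.ilmn_id}\t{rep.clock_name}\t{site.chrom}\t{site.pos0}\t"
                    f"{site.pos1}\t{d}\n"
                )
    return path
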