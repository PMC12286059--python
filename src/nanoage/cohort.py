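"""Per-sample bedMethyl records -> cohort beta-value matrices.

A :class:`BetaMatrix` holds one modification code (5mC ``m`` or 5hmC ``h``) as
a sites x samples matrix of beta values with an explicit missing mask (NaN)
and a parallel integer coverage matrix.  Aggregation is an outer join over
sites; the coverage filter and the complete-case filter below reproduce the
standard minimum-depth-5 / no-missing-value preprocessing for small cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import CpGSite, MethylRecord, SampleInfo

log = logging.getLogger(__name__)


@dataclass
class BetaMatrix:
    """Beta values of one modification across a cohort.

    ``beta`` is float with NaN marking missing entries (site absent in that
    sample, zero-coverage record, or masked by a filter); ``coverage`` is the
    read depth backing each entry (0 where the site was absent).
    """

    mod_code: str
    sites: list[CpGSite]
    samples: list[SampleInfo]
    beta: np.ndarray
    coverage: np.ndarray

    def __post_init__(self) -> None:
        n_sites, n_samples = len(self.sites), len(self.samples)
        if self.beta.shape != (n_sites, n_samples):
            raise ValueError(f"beta shape {self.beta.shape} != ({n_sites}, {n_samples})")
        if self.coverage.shape != (n_sites, n_samples):
            raise ValueError("coverage shape mismatch")
        obs = ~np.isnan(self.beta)
        vals = self.beta[obs]
        if vals.size and (vals.min() < 0 or vals.max() > 1):
            raise ValueError("beta values outside [0, 1]")

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.beta)

    @property
    def ages(self) -> np.ndarray:
        return np.array([s.age_years for s in self.samples], dtype=float)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def copy(self) -> "BetaMatrix":
        return replace(
            self,
            sites=list(self.sites),
            samples=list(self.samples),
            beta=self.beta.copy(),
            coverage=self.coverage.copy(),
        )


def collapse_strands(records: Iterable[MethylRecord]) -> list[MethylRecord]:
    """Collapse a CpG dinucleotide's two strands into one record.

    A minus-strand record at position p pairs with the plus-strand record at
    p-1 (the G's complementary C); counts are summed, beta recomputed, and the
    merged record is anchored on the forward-strand C with strand ".".
    Unpaired minus-strand records are re-anchored the same way.  Total n_mod
    and coverage are conserved.
    """
    merged: dict[tuple[str, str, int], list[int]] = {}
    order: list[tuple[str, str, int]] = []
    for r in records:
        anchor = r.site.pos0 - 1 if r.site.strand == "-" else r.site.pos0
        if anchor < 0:  # minus-strand record at position 0 cannot be re-anchored
            anchor = r.site.pos0
        key = (r.site.chrom, r.mod_code, anchor)
        if key not in merged:
            merged[key] = [0, 0]
            order.append(key)
        merged[key][0] += r.valid_coverage
        merged[key][1] += r.n_mod
    out: list[MethylRecord] = []
    for chrom, code, pos0 in order:
        cov, nm = merged[(chrom, code, pos0)]
        out.append(
            MethylRecord(
                site=CpGSite(chrom, pos0, "."),
                mod_code=code,
                valid_coverage=cov,
                n_mod=nm,
                beta=(nm / cov) if cov > 0 else float("nan"),
            )
        )
    return out


def aggregate(
    per_sample: Mapping[str, Sequence[MethylRecord]],
    sheet: Sequence[SampleInfo],
    mod_code: str,
) -> BetaMatrix:
    """Outer-join one modification's records across the cohort.

    Sites are the union over samples, sorted by (chrom, pos0); samples are
    ordered by ascending age.  Site-sample pairs with no record are missing.
    A site recorded twice within one sample is an error (upstream strand
    collapse or deduplication should have removed it).
    """
    missing_samples = [s.sample_id for s in sheet if s.sample_id not in per_sample]
    if missing_samples:
        raise ValueError(f"no records supplied for samples: {', '.join(missing_samples)}")
    samples = sorted(sheet, key=lambda s: (s.age_years, s.sample_id))

    site_keys: set[tuple[str, int]] = set()
    per_sample_maps: dict[str, dict[tuple[str, int], MethylRecord]] = {}
    for s in samples:
        smap: dict[tuple[str, int], MethylRecord] = {}
        for r in per_sample[s.sample_id]:
            if r.mod_code != mod_code:
                continue
            key = r.site.key()
            if key in smap:
                raise ValueError(
                    f"duplicate site {key[0]}:{key[1]} ({mod_code}) in sample {s.sample_id}"
                )
            smap[key] = r
        per_sample_maps[s.sample_id] = smap
        site_keys.update(smap)

    keys = sorted(site_keys)
    index = {k: i for i, k in enumerate(keys)}
    beta = np.full((len(keys), len(samples)), np.nan)
    coverage = np.zeros((len(keys), len(samples)), dtype=np.int64)
    sites: list[CpGSite | None] = [None] * len(keys)
    for j, s in enumerate(samples):
        for key, r in per_sample_maps[s.sample_id].items():
            i = index[key]
            if sites[i] is None:
                sites[i] = r.site
            coverage[i, j] = r.valid_coverage
            if not r.beta_missing:
                beta[i, j] = r.beta
    return BetaMatrix(mod_code, [s for s in sites if s is not None], samples, beta, coverage)


def filter_coverage(m: BetaMatrix, min_cov: int = 5) -> BetaMatrix:
    """Mask entries with read depth below ``min_cov`` (default 5). Idempotent;
    sites and samples are unchanged."""
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    out = m.copy()
    out.beta[out.coverage < min_cov] = np.nan
    return out


def complete_cases(m: BetaMatrix) -> BetaMatrix:
    """Keep only sites observed in every sample (no missing beta values)."""
    keep = ~np.isnan(m.beta).any(axis=1)
    return BetaMatrix(
        m.mod_code,
        [s for s, k in zip(m.sites, keep) if k],
        list(m.samples),
        m.beta[keep],
        m.coverage[keep],
    )


def combine_mods(m5mc: BetaMatrix, m5hmc: BetaMatrix) -> BetaMatrix:
    """Sum 5mC and 5hmC calls per site into a combined-modification matrix.

    Counts are added where both modifications were measured at a site; a site
    present for only one code keeps that code's counts.  This is the
    "both modifications" view of the cohort; all headline statistics use the
    per-code matrices instead.
    """
    if m5mc.samples != m5hmc.samples:
        raise ValueError("matrices must share the sample ordering")
    keys = sorted({s.key() for s in m5mc.sites} | {s.key() for s in m5hmc.sites})
    index = {k: i for i, k in enumerate(keys)}
    n = (len(keys), len(m5mc.samples))
    nmod = np.zeros(n)
    cov = np.zeros(n, dtype=np.int64)
    sites: list[CpGSite | None] = [None] * len(keys)
    for mat in (m5mc, m5hmc):
        rows = [index[s.key()] for s in mat.sites]
        obs = ~np.isnan(mat.beta)
        for r_local, r_global in enumerate(rows):
            if sites[r_global] is None:
                sites[r_global] = mat.sites[r_local]
            sel = obs[r_local]
            nmod[r_global, sel] += mat.beta[r_local, sel] * mat.coverage[r_local, sel]
            cov[r_global, sel] += mat.coverage[r_local, sel]
    beta = np.full(n, np.nan)
    nz = cov > 0
    beta[nz] = nmod[nz] / cov[nz]
    return BetaMatrix("m+h", [s for s in sites if s is not None], list(m5mc.samples), beta, cov)


def write_matrix(m: BetaMatrix, path: str | Path) -> Path:
    """Export a wide TSV: site, pos0, pos1, strand, then one beta column per
    sample named ``<sample_id>_<age>`` (the heatmap-style layout)."""
    path = Path(path)
    cols = [f"{s.sample_id}_{s.age_years:g}" for s in m.samples]
    with open(path, "w") as fh:
        fh.write("#site\tpos0\tpos1\tstrand\t" + "\t".join(cols) + "\n")
        for i, site in enumerate(m.sites):
            vals = [
                "NA" if np.isnan(v) else f"{v:.6g}" for v in m.beta[i]
            ]
            fh.write(
                f"{site.chrom}_{site.pos1}\t{site.pos0}\t{site.pos1}\t{site.strand}\t"
                + "\t".join(vals)
                + "\n"
            )
    return path
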