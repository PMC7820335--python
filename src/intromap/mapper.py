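"""Candidate-locus extraction, merging, fine-scale refinement and checks.

Windows passing both introgression tests (f_d and the introgression-topology
weight above their thresholds, default 0.75) are candidate windows; a
d_XY discordance flag records windows where recipient-vs-line divergence
rises toward the recipient-vs-donor baseline while line-vs-donor divergence
collapses. Candidates merge into regions, which are rescanned at fine
resolution and bounded by the outermost passing fine windows — an explicit,
reproducible stand-in for visual inspection of locus-scan tracks. A
homozygosity check then asks whether the introgressed group is both
near-monomorphic and fixed for donor-diagnostic alleles across the region,
as expected for a recessive phenotype driven to homozygosity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genotype import GenotypeMatrix, PopulationMap, Window, make_windows, window_site_index
from .popgen import WindowStats, pi as pi_stat, scan_genome
from .trees import scan_trees


class MappingError(ValueError):
    pass


class RefinementError(MappingError):
    """No fine window passed the candidate criteria; carries the fine scan."""

    def __init__(self, msg: str, fine_stats: list[WindowStats]):
        super().__init__(msg)
        self.fine_stats = fine_stats


@dataclass
class CandidateRegion:
    chrom: str
    start: int
    end: int
    supporting_windows: list[Window] = field(default_factory=list)
    evidence: dict = field(
        default_factory=lambda: {
            "fd_pass": False,
            "weighting_pass": False,
            "dxy_discordant": False,
            "homozygous": False,
        }
    )

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("region start must be < end")

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end

    def contains(self, chrom: str, pos0: int) -> bool:
        return self.chrom == chrom and self.start <= pos0 < self.end


@dataclass(frozen=True)
class HomozygosityResult:
    passed: bool
    pi_introgressed: float
    donor_fixed_fraction: float
    n_diagnostic_sites: int
    defined: bool = True


def candidate_windows(
    stats: Sequence[WindowStats],
    fd_min: float = 0.75,
    weight_min: float = 0.75,
) -> list[Window]:
    """Windows with f_d > fd_min and introgression-topology weight > weight_min.

    Undefined statistics never pass.
    """
    out = []
    for ws in stats:
        if ws.weights is None:
            continue
        fd_val = ws.fd
        w_intro = ws.weights.w_introgression
        if math.isnan(fd_val) or w_intro is None:
            continue
        if fd_val > fd_min and w_intro > weight_min:
            out.append(ws.window)
    return out


def dxy_discordance_flag(
    stats: Sequence[WindowStats],
    pair_recipient_line: tuple[str, str],
    pair_line_donor: tuple[str, str],
    pair_recipient_donor: tuple[str, str] | None = None,
    elevated_mult: float = 0.75,
    reduced_mult: float = 0.25,
) -> list[bool]:
    """Flag windows whose d_XY pattern indicates introgression.

    A window is flagged when d_XY(recipient, line) >= elevated_mult x the
    genome median of d_XY(recipient, donor) (i.e. the divergence between the
    recipient and the line approaches the interspecies baseline) AND
    d_XY(line, donor) <= reduced_mult x its own genome median.
    """
    if len(stats) < 10:
        raise MappingError("fewer than 10 windows: genome medians unreliable")
    if pair_recipient_donor is None:
        pair_recipient_donor = (pair_recipient_line[0], pair_line_donor[1])

    def values(pair):
        key = tuple(pair)
        vals = []
        for ws in stats:
            v = ws.dxy.get(key, ws.dxy.get((key[1], key[0]), float("nan")))
            vals.append(v)
        return np.asarray(vals)

    v_rl = values(pair_recipient_line)
    v_ld = values(pair_line_donor)
    v_rd = values(pair_recipient_donor)
    med_rd = float(np.nanmedian(v_rd))
    med_ld = float(np.nanmedian(v_ld))
    flags = []
    for a, b in zip(v_rl, v_ld):
        flags.append(
            bool(
                not math.isnan(a)
                and not math.isnan(b)
                and a >= elevated_mult * med_rd
                and b <= reduced_mult * med_ld
            )
        )
    return flags


def merge_windows(
    selected: Sequence[Window], max_gap: int
) -> list[CandidateRegion]:
    """Merge same-chrom windows whose gaps are <= max_gap bp into regions."""
    regions: list[CandidateRegion] = []
    by_chrom: dict[str, list[Window]] = {}
    for w in selected:
        by_chrom.setdefault(w.chrom, []).append(w)
    for chrom in by_chrom:
        wins = sorted(by_chrom[chrom], key=lambda w: (w.start, w.end))
        cur: CandidateRegion | None = None
        for w in wins:
            if cur is not None and w.start - cur.end <= max_gap:
                cur.end = max(cur.end, w.end)
                cur.supporting_windows.append(w)
            else:
                cur = CandidateRegion(chrom, w.start, w.end, supporting_windows=[w])
                regions.append(cur)
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def refine_locus(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    region: CandidateRegion,
    fine_size: int = 10_000,
    coarse_size: int = 100_000,
    fd_min: float = 0.75,
    weight_min: float = 0.75,
    contig_length: int | None = None,
    tree_method: str = "exact",
    tree_draws: int = 10_000,
    seed: int | None = None,
) -> CandidateRegion:
    """Rescan a region (padded by one coarse window) at fine resolution.

    The refined bounds are the span from the first to the last fine window
    that passes the candidate criteria (f_d and introgression weight above
    their thresholds). Raises :class:`RefinementError` with the fine-scan
    table attached when nothing passes.
    """
    if fine_size >= region.end - region.start:
        raise MappingError("fine_size must be smaller than the region")
    block = gm.chrom_block(region.chrom)
    if contig_length is None:
        contig_length = int(gm.pos[block].max()) if block.stop > block.start else region.end
    lo = max(0, region.start - coarse_size)
    hi = min(contig_length, region.end + coarse_size)
    # fine windows tiled from the padded start, truncated at the contig end
    fine: list[Window] = []
    start = lo
    while start < hi:
        fine.append(Window(region.chrom, start, min(start + fine_size, hi), "locus_10kb"))
        start += fine_size
    stats = scan_genome(gm, pm, fine)
    weighted = scan_trees(
        gm, pm, fine, method=tree_method, draws=tree_draws, seed=seed
    )
    for ws, (_, qw, _) in zip(stats, weighted):
        ws.weights = qw
    passing = candidate_windows(stats, fd_min=fd_min, weight_min=weight_min)
    if not passing:
        raise RefinementError("no fine window passes the candidate criteria", stats)
    new_start = min(w.start for w in passing)
    new_end = max(w.end for w in passing)
    refined = CandidateRegion(
        region.chrom,
        new_start,
        new_end,
        supporting_windows=list(passing),
        evidence=dict(region.evidence),
    )
    refined.evidence["fd_pass"] = True
    refined.evidence["weighting_pass"] = True
    return refined


def homozygosity_check(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    region: CandidateRegion,
    pi_max: float = 0.001,
    donor_fix_min: float = 0.95,
) -> HomozygosityResult:
    """Is the introgressed group homozygous-donor across the region?

    Passes when (a) pi of the introgressed group (P2) within the region is
    <= pi_max and (b) the fraction of donor-diagnostic sites (fixed-different
    between P1 and P3 among called haplotypes) at which every called P2
    haplotype carries the donor allele is >= donor_fix_min.
    """
    w = Window(region.chrom, region.start, region.end, "custom")
    sl = window_site_index(gm, w)
    sub = gm.take(np.arange(sl.start, sl.stop))
    if sub.n_sites == 0:
        return HomozygosityResult(False, float("nan"), float("nan"), 0, defined=False)
    pi_val = pi_stat(sub, pm, pm.role_group("P2"))

    c1 = sub.codes[:, sub.group_columns(pm, pm.role_group("P1"))]
    c3 = sub.codes[:, sub.group_columns(pm, pm.role_group("P3"))]
    c2 = sub.codes[:, sub.group_columns(pm, pm.role_group("P2"))]

    def fixed_allele(c):
        """Per site: the single allele carried by all called haplotypes, else -2."""
        called = c >= 0
        n = called.sum(axis=1)
        first = np.where(called.any(axis=1), c.max(axis=1), -2)
        mono = np.all((c == first[:, None]) | ~called, axis=1) & (n > 0)
        return np.where(mono, first, -2)

    a1 = fixed_allele(c1)
    a3 = fixed_allele(c3)
    diagnostic = (a1 >= 0) & (a3 >= 0) & (a1 != a3)
    n_diag = int(diagnostic.sum())
    if n_diag == 0:
        return HomozygosityResult(False, pi_val, float("nan"), 0, defined=False)
    a2 = fixed_allele(c2)
    donor_fixed = (a2 >= 0) & (a2 == a3) & diagnostic
    frac = float(donor_fixed.sum() / n_diag)
    passed = (not math.isnan(pi_val)) and pi_val <= pi_max and frac >= donor_fix_min
    return HomozygosityResult(passed, pi_val, frac, n_diag)


def narrow_by_homozygosity(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    region: CandidateRegion,
    fine_size: int = 10_000,
    pi_max: float = 0.001,
    donor_fix_min: float = 0.95,
    gap_windows: int = 1,
) -> CandidateRegion:
    """Reduce a refined region to its homozygous-introgression core.

    Fine windows across the region are tested individually with the
    homozygosity criteria (pi of the introgressed group and donor-diagnostic
    fixation); the narrowed bounds span the longest run of passing windows,
    tolerating interior gaps of up to *gap_windows* failing windows (a single
    borderline window should not split a fixed tract, mirroring the
    one-window merge gap of the coarse scan). This is the diversity-based
    reduction of a maximum introgressed range to the tract actually driven
    to homozygosity.
    """
    fine: list[Window] = []
    start = region.start
    while start < region.end:
        fine.append(
            Window(region.chrom, start, min(start + fine_size, region.end), "locus_10kb")
        )
        start += fine_size
    passing = []
    for w in fine:
        sub_region = CandidateRegion(w.chrom, w.start, w.end)
        hz = homozygosity_check(
            gm, pm, sub_region, pi_max=pi_max, donor_fix_min=donor_fix_min
        )
        passing.append(hz.defined and hz.passed)
    # longest run of passing windows, tolerating small interior gaps
    pass_idx = [i for i, p in enumerate(passing) if p]
    if not pass_idx:
        raise RefinementError("no fine window passes the homozygosity criteria", [])
    runs: list[list[int]] = [[pass_idx[0]]]
    for i in pass_idx[1:]:
        if i - runs[-1][-1] <= gap_windows + 1:
            runs[-1].append(i)
        else:
            runs.append([i])
    best_run = max(runs, key=lambda r: fine[r[-1]].end - fine[r[0]].start)
    best = (None, best_run[0], best_run[-1])
    narrowed = CandidateRegion(
        region.chrom,
        fine[best[1]].start,
        fine[best[2]].end,
        supporting_windows=[w for w, p in zip(fine, passing) if p],
        evidence=dict(region.evidence),
    )
    return narrowed


def regions_to_bed(
    regions: Sequence[CandidateRegion],
    path: str,
    mean_fd: dict | None = None,
) -> None:
    """BED6: name = evidence flags, score = mean f_d (scaled to 0-1000)."""
    with open(path, "w") as fh:
        for r in regions:
            flags = ",".join(k for k, v in r.evidence.items() if v) or "none"
            fd_val = (mean_fd or {}).get((r.chrom, r.start, r.end), float("nan"))
            score = 0 if math.isnan(fd_val) else int(round(1000 * min(1.0, fd_val)))
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{flags}\t{score}\t.\n")


@dataclass
class MappingReport:
    coarse_stats: list[WindowStats]
    candidate_wins: list[Window]
    regions: list[CandidateRegion]
    refined: list[CandidateRegion]  # maximum introgressed range per region
    narrowed: list[CandidateRegion | None]  # homozygous core, if any
    homozygosity: list[HomozygosityResult]

    @property
    def passing_regions(self) -> list[CandidateRegion]:
        return [
            r
            for r in self.narrowed
            if r is not None and r.evidence.get("homozygous")
        ]


def run_mapping(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    contig_lengths: dict[str, int],
    coarse_size: int = 100_000,
    fine_size: int = 10_000,
    fd_min: float = 0.75,
    weight_min: float = 0.75,
    pi_max: float = 0.001,
    donor_fix_min: float = 0.95,
    max_gap: int | None = None,
    seed: int | None = None,
) -> MappingReport:
    """Full coarse scan -> candidate extraction -> refinement -> checks."""
    coarse = make_windows(contig_lengths, coarse_size, "genome_100kb")
    stats = scan_genome(gm, pm, coarse)
    weighted = scan_trees(gm, pm, coarse, method="exact", seed=seed)
    for ws, (_, qw, _) in zip(stats, weighted):
        ws.weights = qw
    flags = dxy_discordance_flag(
        stats,
        pair_recipient_line=(pm.role_group("P1"), pm.role_group("P2")),
        pair_line_donor=(pm.role_group("P2"), pm.role_group("P3")),
        pair_recipient_donor=(pm.role_group("P1"), pm.role_group("P3")),
    )
    flagged = {
        (ws.window.chrom, ws.window.start, ws.window.end)
        for ws, f in zip(stats, flags)
        if f
    }
    cand = candidate_windows(stats, fd_min=fd_min, weight_min=weight_min)
    regions = merge_windows(cand, max_gap=coarse_size if max_gap is None else max_gap)
    for r in regions:
        r.evidence["fd_pass"] = True
        r.evidence["weighting_pass"] = True
        r.evidence["dxy_discordant"] = any(
            r.overlaps(c, s, e) for (c, s, e) in flagged
        )
    refined: list[CandidateRegion] = []
    narrowed: list[CandidateRegion | None] = []
    homo: list[HomozygosityResult] = []
    for r in regions:
        try:
            rr = refine_locus(
                gm,
                pm,
                r,
                fine_size=fine_size,
                coarse_size=coarse_size,
                fd_min=fd_min,
                weight_min=weight_min,
                contig_length=contig_lengths.get(r.chrom),
                seed=seed,
            )
        except RefinementError:
            continue
        refined.append(rr)
        try:
            nr = narrow_by_homozygosity(
                gm, pm, rr, fine_size=fine_size, pi_max=pi_max,
                donor_fix_min=donor_fix_min,
            )
        except RefinementError:
            narrowed.append(None)
            homo.append(
                HomozygosityResult(False, float("nan"), float("nan"), 0, defined=False)
            )
            rr.evidence["homozygous"] = False
            continue
        hz = homozygosity_check(
            gm, pm, nr, pi_max=pi_max, donor_fix_min=donor_fix_min
        )
        nr.evidence["homozygous"] = hz.passed
        rr.evidence["homozygous"] = hz.passed
        narrowed.append(nr)
        homo.append(hz)
    return MappingReport(stats, cand, regions, refined, narrowed, homo)
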