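"""Genotype data model: matrices of allele codes, population/role maps, windows.

Every downstream statistic operates on a :class:`GenotypeMatrix`, a dense
sites x haplotypes array of allele codes (``MISSING`` = -1) together with
per-sample read depth. Samples may have any ploidy: individuals are diploid,
pooled libraries are typically called at ploidy ``2 x pool size``, and each
sample owns a contiguous block of haplotype columns.

Coordinates follow the two conventions of the field: VCF positions are stored
1-based exactly as read, while all windowing is half-open 0-based (BED
convention), so tiling arithmetic is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

MISSING = -1

ROLES = ("P1", "P2", "P3", "O")


class ConfigurationError(ValueError):
    """A population map / role configuration does not match the data."""


class VcfParseError(ValueError):
    """A VCF record could not be interpreted."""


@dataclass(frozen=True)
class SiteRecord:
    """One variant site: alleles, per-haplotype codes and per-sample depth."""

    chrom: str
    pos: int  # 1-based, as in the source VCF
    ref_allele: str
    alt_alleles: tuple[str, ...]
    genotype_codes: np.ndarray  # (n_haplotypes,) int16, MISSING = -1
    depth: np.ndarray | None  # (n_samples,) int32, -1 = absent

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref_allele,) + self.alt_alleles

    @property
    def is_indel(self) -> bool:
        return any(len(a) != 1 for a in self.alleles)

    def validate(self) -> None:
        codes = self.genotype_codes
        called = codes[codes != MISSING]
        if called.size and (called.min() < 0 or called.max() >= len(self.alleles)):
            raise VcfParseError(
                f"{self.chrom}:{self.pos}: genotype code outside declared alleles"
            )


@dataclass(frozen=True)
class PopulationMap:
    """sample -> group assignment plus the four-taxon role configuration.

    Roles follow the ABBA-BABA convention: P1 = recipient, P2 = putatively
    introgressed line, P3 = donor, O = outgroup.
    """

    assignment: Mapping[str, str]
    roles: Mapping[str, str]

    def __post_init__(self) -> None:
        missing = [r for r in ROLES if r not in self.roles]
        if missing:
            raise ConfigurationError(f"roles not set: {missing}")
        groups = [self.roles[r] for r in ROLES]
        if len(set(groups)) != 4:
            raise ConfigurationError("the four roles must map to four distinct groups")
        assigned = set(self.assignment.values())
        empty = [g for g in groups if g not in assigned]
        if empty:
            raise ConfigurationError(f"role groups with no samples: {empty}")

    @property
    def groups(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for g in self.assignment.values():
            seen.setdefault(g)
        return tuple(seen)

    def samples_of(self, group: str) -> list[str]:
        return [s for s, g in self.assignment.items() if g == group]

    def role_group(self, role: str) -> str:
        return self.roles[role]

    @classmethod
    def from_tsv(cls, path: str, roles: Mapping[str, str]) -> "PopulationMap":
        assignment: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ConfigurationError(f"bad population-map line: {line!r}")
                assignment[parts[0]] = parts[1]
        return cls(assignment=assignment, roles=dict(roles))

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            for s, g in self.assignment.items():
                fh.write(f"{s}\t{g}\n")


@dataclass(frozen=True)
class Window:
    """Half-open 0-based interval on one sequence."""

    chrom: str
    start: int
    end: int
    scheme: str = "custom"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid window [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


class GenotypeMatrix:
    """Sites x haplotypes allele-code matrix with depth and missingness.

    Parameters
    ----------
    chrom, pos : per-site sequence id and 1-based position, sorted by
        (chrom block, pos) with strictly increasing positions per chrom.
    ref, alt : per-site reference allele and tuple of alternate alleles.
    codes : (n_sites, n_haplotypes) int16, ``MISSING`` (-1) for uncalled.
    depth : (n_sites, n_samples) int32 or None; -1 marks absent DP.
    samples : ordered sample ids.
    ploidy : haplotype count per sample, in sample order.
    """

    def __init__(
        self,
        chrom: Sequence[str],
        pos: Sequence[int],
        ref: Sequence[str],
        alt: Sequence[tuple[str, ...]],
        codes: np.ndarray,
        depth: np.ndarray | None,
        samples: Sequence[str],
        ploidy: Sequence[int],
    ):
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.ref = list(ref)
        self.alt = [tuple(a) for a in alt]
        self.codes = np.asarray(codes, dtype=np.int16)
        self.depth = None if depth is None else np.asarray(depth, dtype=np.int32)
        self.samples = list(samples)
        self.ploidy = list(int(p) for p in ploidy)
        if self.codes.shape != (len(self.pos), sum(self.ploidy)):
            raise ValueError(
                f"codes shape {self.codes.shape} != "
                f"({len(self.pos)}, {sum(self.ploidy)})"
            )
        if self.depth is not None and self.depth.shape != (
            len(self.pos),
            len(self.samples),
        ):
            raise ValueError("depth shape does not match (n_sites, n_samples)")
        self._check_sorted()

    # -- structure ---------------------------------------------------------

    def _check_sorted(self) -> None:
        if self.n_sites < 2:
            return
        same = self.chrom[1:] == self.chrom[:-1]
        if np.any(same & (np.diff(self.pos) <= 0)):
            raise ValueError("positions not strictly increasing within a chrom")
        starts = [self.chrom[0]] + list(self.chrom[1:][~same])
        if len(starts) != len(set(starts)):
            raise ValueError("a chrom appears in non-contiguous blocks")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_haplotypes(self) -> int:
        return self.codes.shape[1]

    def haplotype_columns(self, sample: str) -> range:
        i = self.samples.index(sample)
        start = sum(self.ploidy[:i])
        return range(start, start + self.ploidy[i])

    def group_columns(self, pm: PopulationMap, group: str) -> np.ndarray:
        cols: list[int] = []
        for s in pm.samples_of(group):
            if s not in self.samples:
                raise ConfigurationError(f"sample {s!r} not present in matrix")
            cols.extend(self.haplotype_columns(s))
        return np.asarray(cols, dtype=np.intp)

    def haplotype_labels(self) -> list[str]:
        labels = []
        for s, p in zip(self.samples, self.ploidy):
            labels.extend(f"{s}|{k}" for k in range(p))
        return labels

    def site(self, i: int) -> SiteRecord:
        return SiteRecord(
            chrom=self.chrom[i],
            pos=int(self.pos[i]),
            ref_allele=self.ref[i],
            alt_alleles=self.alt[i],
            genotype_codes=self.codes[i],
            depth=None if self.depth is None else self.depth[i],
        )

    @property
    def is_indel(self) -> np.ndarray:
        if getattr(self, "_is_indel", None) is None:
            self._is_indel = np.fromiter(
                (
                    len(r) != 1 or any(len(a) != 1 for a in al)
                    for r, al in zip(self.ref, self.alt)
                ),
                dtype=bool,
                count=self.n_sites,
            )
        return self._is_indel

    def take(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the given site indices (order preserved)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=[self.ref[i] for i in index],
            alt=[self.alt[i] for i in index],
            codes=self.codes[index],
            depth=None if self.depth is None else self.depth[index],
            samples=self.samples,
            ploidy=self.ploidy,
        )

    def _block_map(self) -> dict[str, slice]:
        blocks = getattr(self, "_blocks", None)
        if blocks is None:
            blocks = {}
            if self.n_sites:
                change = np.flatnonzero(self.chrom[1:] != self.chrom[:-1]) + 1
                bounds = [0, *change.tolist(), self.n_sites]
                for lo, hi in zip(bounds[:-1], bounds[1:]):
                    blocks[self.chrom[lo]] = slice(lo, hi)
            self._blocks = blocks
        return blocks

    def chrom_block(self, chrom: str) -> slice:
        """Site-index slice covering one chrom (empty slice if absent)."""
        return self._block_map().get(chrom, slice(0, 0))

    def contigs(self) -> list[str]:
        return list(self._block_map())


# -- IO ---------------------------------------------------------------------


def read_vcf(path: str, pop_map: PopulationMap | None = None) -> GenotypeMatrix:
    """Read GT (+ optional DP) from a VCF into a :class:`GenotypeMatrix`.

    Phased and unphased genotypes are accepted; per-sample ploidy is taken
    from the first record and must be constant. If *pop_map* is given, every
    mapped sample must be present in the VCF header.
    """
    vf = pysam.VariantFile(path)
    samples = list(vf.header.samples)
    if pop_map is not None:
        absent = [s for s in pop_map.assignment if s not in samples]
        if absent:
            raise ConfigurationError(f"samples in population map absent from VCF: {absent}")

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[tuple[str, ...]] = []
    code_rows: list[list[int]] = []
    depth_rows: list[list[int]] = []
    ploidy: list[int] | None = None
    any_depth = False

    for rec in vf:
        try:
            alleles = rec.alleles
            if alleles is None or len(alleles) < 1:
                raise ValueError("no alleles")
            row_codes: list[int] = []
            row_depth: list[int] = []
            rec_ploidy: list[int] = []
            for s in samples:
                sd = rec.samples[s]
                gt = sd.get("GT")
                if gt is None:
                    gt = (None,)
                rec_ploidy.append(len(gt))
                for a in gt:
                    row_codes.append(MISSING if a is None else int(a))
                dp = sd.get("DP")
                if dp is None:
                    row_depth.append(-1)
                else:
                    row_depth.append(int(dp))
                    any_depth = True
        except Exception as exc:  # pragma: no cover - defensive
            raise VcfParseError(f"malformed VCF record at {rec.chrom}:{rec.pos}: {exc}")
        if ploidy is None:
            ploidy = rec_ploidy
        elif rec_ploidy != ploidy:
            raise VcfParseError(
                f"inconsistent ploidy at {rec.chrom}:{rec.pos}: {rec_ploidy} != {ploidy}"
            )
        n_alleles = len(alleles)
        if any(c >= n_alleles for c in row_codes):
            raise VcfParseError(f"genotype allele index out of range at {rec.chrom}:{rec.pos}")
        chroms.append(rec.chrom)
        poss.append(rec.pos)
        refs.append(alleles[0])
        alts.append(tuple(alleles[1:]))
        code_rows.append(row_codes)
        depth_rows.append(row_depth)
    vf.close()

    if ploidy is None:
        raise VcfParseError(f"no records in {path}")
    codes = np.asarray(code_rows, dtype=np.int16)
    depth = np.asarray(depth_rows, dtype=np.int32) if any_depth else None
    return GenotypeMatrix(chroms, poss, refs, alts, codes, depth, samples, ploidy)


def write_vcf(
    gm: GenotypeMatrix,
    path: str,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write the matrix back out as an uncompressed VCF (GT + DP)."""
    header = pysam.VariantHeader()
    header.add_meta("source", "intromap")
    lengths: dict[str, int] = {}
    for c in gm.contigs():
        block = gm.chrom_block(c)
        maxpos = int(gm.pos[block].max()) if block.stop > block.start else 1
        lengths[c] = int(contig_lengths[c]) if contig_lengths else maxpos + 1
    for c, ln in lengths.items():
        header.contigs.add(c, length=ln)
    header.add_meta(
        "FORMAT",
        items=[("ID", "GT"), ("Number", 1), ("Type", "String"), ("Description", "Genotype")],
    )
    header.add_meta(
        "FORMAT",
        items=[("ID", "DP"), ("Number", 1), ("Type", "Integer"), ("Description", "Read depth")],
    )
    for s in gm.samples:
        header.add_sample(s)

    with pysam.VariantFile(path, "w", header=header) as out:
        col0 = np.cumsum([0] + gm.ploidy)
        for i in range(gm.n_sites):
            rec = out.new_record(
                contig=gm.chrom[i],
                start=int(gm.pos[i]) - 1,
                alleles=(gm.ref[i],) + tuple(gm.alt[i]) if gm.alt[i] else (gm.ref[i], "."),
            )
            for j, s in enumerate(gm.samples):
                block = gm.codes[i, col0[j] : col0[j + 1]]
                rec.samples[s]["GT"] = tuple(None if a == MISSING else int(a) for a in block)
                if gm.depth is not None and gm.depth[i, j] >= 0:
                    rec.samples[s]["DP"] = int(gm.depth[i, j])
            out.write(rec)


# -- filtering and windowing -------------------------------------------------


def apply_depth_mask(gm: GenotypeMatrix, min_depth: int) -> GenotypeMatrix:
    """Set genotypes with depth below *min_depth* to missing.

    The mask applies only where depth is known; calls without a DP value are
    retained unchanged.
    """
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    if gm.depth is None or min_depth == 0:
        return gm
    codes = gm.codes.copy()
    col0 = np.cumsum([0] + gm.ploidy)
    low = (gm.depth >= 0) & (gm.depth < min_depth)
    for j in range(len(gm.samples)):
        rows = low[:, j]
        if rows.any():
            codes[rows, col0[j] : col0[j + 1]] = MISSING
    return GenotypeMatrix(
        gm.chrom, gm.pos, gm.ref, gm.alt, codes, gm.depth, gm.samples, gm.ploidy
    )


def filter_sites(
    gm: GenotypeMatrix, max_missing_frac: float = 0.20, drop_indels: bool = True
) -> GenotypeMatrix:
    """Drop sites with too much missingness and (optionally) indel sites.

    A site is removed when missing haplotype codes / total haplotype columns
    strictly exceeds *max_missing_frac*. The missingness denominator is
    haplotype columns, so pooled high-ploidy samples weigh by their ploidy.
    """
    if not (0.0 <= max_missing_frac <= 1.0):
        raise ValueError("max_missing_frac must be in [0, 1]")
    missing_frac = (gm.codes == MISSING).sum(axis=1) / gm.n_haplotypes
    keep = missing_frac <= max_missing_frac
    if drop_indels:
        keep &= ~gm.is_indel
    return gm.take(keep)


def make_windows(
    contig_lengths: Mapping[str, int],
    size: int,
    scheme: str = "custom",
    step: int | None = None,
) -> list[Window]:
    """Tile each contig with adjacent half-open windows of *size* bp.

    The final window is truncated at the contig end. *step* defaults to
    *size* (non-overlapping tiling).
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    step = size if step is None else step
    if step < 1:
        raise ValueError("step must be >= 1")
    out: list[Window] = []
    for chrom, length in contig_lengths.items():
        if length < 1:
            raise ValueError(f"contig {chrom} has non-positive length")
        start = 0
        while start < length:
            out.append(Window(chrom, start, min(start + size, length), scheme))
            start += step
    return out


def window_slice(gm: GenotypeMatrix, w: Window) -> GenotypeMatrix:
    """Sites whose 0-based position lies in [w.start, w.end)."""
    idx = window_site_index(gm, w)
    return gm.take(np.arange(idx.start, idx.stop))


def window_site_index(gm: GenotypeMatrix, w: Window) -> slice:
    """Site-index slice of *gm* covered by window *w* (may be empty)."""
    block = gm.chrom_block(w.chrom)
    if block.stop == block.start:
        return slice(block.start, block.start)
    pos0 = gm.pos[block] - 1  # 0-based
    lo = int(np.searchsorted(pos0, w.start, side="left"))
    hi = int(np.searchsorted(pos0, w.end, side="left"))
    return slice(block.start + lo, block.start + hi)


def windows_to_bed(windows: Iterable[Window], path: str) -> None:
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.scheme}\n")
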