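"""Forward simulation of a backcross-introgression breeding design.

The generator emulates the data underlying an introgression-mapping study:
a recessive marker allele (here called ``wp``) is moved from a donor species
into a recipient species by an interspecific F1 cross, an F2 intercross with
phenotypic selection, repeated backcrosses of selected females to recipient
males, and a final intercross that fixes the donor tract to homozygosity.

Genomes are mosaics over a fixed founder-haplotype panel rather than
coalescent samples: every site carries an allele per founder haplotype, and
every simulated chromosome is a list of ancestry tracts pointing back into
that panel. Meiosis places Poisson-distributed crossovers uniformly per
chromosome (no interference). This gives exact, seeded control of the
divergence/diversity structure the downstream statistics consume, and exact
ground truth (ancestry tracts) against which locus recovery is scored.

Site classes:

* fixed differences between recipient and donor lineages (density per bp),
  the derived state assigned to either lineage with equal probability;
* additional outgroup-private fixed differences (multiplier x density);
* within-population polymorphism per lineage, with founder allele
  frequencies drawn from a truncated Beta(0.5, 0.5);
* the ``wp`` null allele itself, a 37 bp deletion carried by every donor
  founder haplotype.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genotype import GenotypeMatrix, PopulationMap, write_vcf


class SimulationError(RuntimeError):
    pass


def _default_chrom_lengths() -> dict[str, int]:
    return {f"chr{i}": 10_000_000 for i in range(1, 6)}


def _default_pool_specs() -> list[tuple[int, int]]:
    # the sequencing design this emulates: two pools of five line
    # individuals called at ploidy ten, alongside the diploid individuals
    return [(5, 10), (5, 10)]


@dataclass
class SimConfig:
    """Study-design parameters of the simulated introgression experiment."""

    seed: int
    chrom_lengths: dict[str, int] = field(default_factory=_default_chrom_lengths)
    wp_locus: tuple[str, int] = ("chr3", 5_000_000)  # (chrom, 1-based position)
    fixed_diff_density: float = 0.005  # recipient/donor fixed differences per bp
    outgroup_divergence_multiplier: float = 3.0
    polymorphism_density: float = 0.001  # within-lineage polymorphic sites per bp
    crossover_rate: float = 1.5  # Poisson mean crossovers per chromosome per meiosis
    n_backcross: int = 6
    reselect_homozygotes: bool = False  # intercross before every backcross round
    # optional generations of mass intercrossing after the marker is fixed
    # (the established line keeps segregating unlinked donor drag while the
    # selected tract stays homozygous); 0 samples the fixing intercross
    n_line_generations: int = 0
    brood_size: int = 50
    n_select: int = 10
    n_individuals_per_group: int = 2  # diploid sequenced individuals per group
    pool_specs: list[tuple[int, int]] = field(default_factory=_default_pool_specs)
    depth_mean: float = 30.0
    n_recipient_founders: int = 10  # founder haplotypes per lineage panel
    n_donor_founders: int = 10
    n_outgroup_founders: int = 10
    genotype_error_rate: float = 0.0
    retry_limit: int = 20
    wp_deletion_length: int = 37

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SimulationError("seed is mandatory")
        chrom, pos = self.wp_locus
        if chrom not in self.chrom_lengths:
            raise SimulationError(f"wp locus chrom {chrom!r} not in chrom_lengths")
        if not (1 <= pos <= self.chrom_lengths[chrom]):
            raise SimulationError("wp locus position outside its chromosome")
        for name in ("fixed_diff_density", "polymorphism_density", "genotype_error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SimulationError(f"{name} must be in [0, 1]")
        for n, p in self.pool_specs:
            if p != 2 * n:
                raise SimulationError("pool ploidy must equal 2 x pool size")
        if self.n_backcross < 1:
            raise SimulationError("n_backcross must be >= 1")

    # founder panel layout: [recipient | donor | outgroup]
    @property
    def recipient_founders(self) -> range:
        return range(0, self.n_recipient_founders)

    @property
    def donor_founders(self) -> range:
        a = self.n_recipient_founders
        return range(a, a + self.n_donor_founders)

    @property
    def outgroup_founders(self) -> range:
        a = self.n_recipient_founders + self.n_donor_founders
        return range(a, a + self.n_outgroup_founders)

    @property
    def n_founders(self) -> int:
        return self.n_recipient_founders + self.n_donor_founders + self.n_outgroup_founders


# -- founders ----------------------------------------------------------------


@dataclass
class ChromSites:
    pos: np.ndarray  # 1-based, strictly increasing
    ref: list[str]
    alt: list[str]
    founder_alleles: np.ndarray  # (n_sites, n_founders) int8


@dataclass
class Founders:
    cfg: SimConfig
    sites: dict[str, ChromSites]

    def wp_row(self) -> tuple[str, int]:
        chrom, pos = self.cfg.wp_locus
        row = int(np.searchsorted(self.sites[chrom].pos, pos))
        return chrom, row


_BASES = np.array(list("ACGT"))


def simulate_founders(cfg: SimConfig, rng: np.random.Generator | None = None) -> Founders:
    """Place sites and assign founder-panel alleles for every lineage."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    lineages = {
        "recipient": cfg.recipient_founders,
        "donor": cfg.donor_founders,
        "outgroup": cfg.outgroup_founders,
    }
    sites: dict[str, ChromSites] = {}
    for chrom, length in cfg.chrom_lengths.items():
        n_fixed = rng.poisson(cfg.fixed_diff_density * length)
        n_og = rng.poisson(
            cfg.outgroup_divergence_multiplier * cfg.fixed_diff_density * length
        )
        n_poly = {
            lin: rng.poisson(cfg.polymorphism_density * length) for lin in lineages
        }
        n_total = n_fixed + n_og + sum(n_poly.values())
        pos = rng.choice(length, size=min(n_total, length), replace=False) + 1
        # category blocks in a fixed order, then a joint position sort
        n_total = len(pos)
        counts = [n_fixed, n_og] + [n_poly[lin] for lin in lineages]
        while sum(counts) > n_total:  # only if n_total hit the contig size
            counts[int(np.argmax(counts))] -= 1

        F = np.zeros((n_total, cfg.n_founders), dtype=np.int8)
        o = 0
        # fixed recipient/donor differences; derived lineage by fair coin
        k = counts[0]
        donor_derived = rng.random(k) < 0.5
        rows = np.arange(o, o + k)
        F[np.ix_(rows[donor_derived], list(cfg.donor_founders))] = 1
        F[np.ix_(rows[~donor_derived], list(cfg.recipient_founders))] = 1
        o += k
        # outgroup-private fixed differences
        k = counts[1]
        F[np.ix_(np.arange(o, o + k), list(cfg.outgroup_founders))] = 1
        o += k
        # within-lineage polymorphism, founder alleles Bernoulli(freq)
        for lin, cnt in zip(lineages, counts[2:]):
            cols = list(lineages[lin])
            freq = np.clip(rng.beta(0.5, 0.5, size=cnt), 0.05, 0.95)
            F[o : o + cnt, cols] = (
                rng.random((cnt, len(cols))) < freq[:, None]
            ).astype(np.int8)
            o += cnt

        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        F = F[order]
        refs = _BASES[rng.integers(0, 4, size=n_total)]
        shift = rng.integers(1, 4, size=n_total)
        alts = _BASES[(np.searchsorted(_BASES, refs) + shift) % 4]

        ref_list = refs.tolist()
        alt_list = alts.tolist()

        # the wp null allele: a deletion carried by every donor founder
        wp_chrom, wp_pos = cfg.wp_locus
        if chrom == wp_chrom:
            hit = np.searchsorted(pos, wp_pos)
            if hit < len(pos) and pos[hit] == wp_pos:
                keep = np.ones(len(pos), dtype=bool)
                keep[hit] = False
                pos, F = pos[keep], F[keep]
                del ref_list[hit], alt_list[hit]
            ins = int(np.searchsorted(pos, wp_pos))
            pos = np.insert(pos, ins, wp_pos)
            row = np.zeros((1, cfg.n_founders), dtype=np.int8)
            row[0, list(cfg.donor_founders)] = 1
            F = np.vstack([F[:ins], row, F[ins:]])
            anchor = "A"
            ref_list.insert(ins, anchor + "T" * cfg.wp_deletion_length)
            alt_list.insert(ins, anchor)

        sites[chrom] = ChromSites(pos=pos, ref=ref_list, alt=alt_list, founder_alleles=F)
    return Founders(cfg=cfg, sites=sites)


# -- haplotypes, tracts, meiosis ---------------------------------------------

# a haplotype is {chrom: [(start, end, founder_index), ...]} with half-open
# 0-based tracts partitioning [0, length)

Haplotype = dict


@dataclass(frozen=True)
class AncestryTract:
    haplotype_id: str
    chrom: str
    start: int
    end: int
    ancestry: str  # "donor" | "recurrent" | "outgroup"


def founder_haplotype(cfg: SimConfig, founder: int) -> Haplotype:
    return {c: [(0, length, founder)] for c, length in cfg.chrom_lengths.items()}


def _slice_tracts(tracts: list, start: int, end: int) -> list:
    out = []
    for s, e, f in tracts:
        if e <= start or s >= end:
            continue
        out.append((max(s, start), min(e, end), f))
    return out


def _merge_tracts(tracts: list) -> list:
    out: list = []
    for t in tracts:
        if out and out[-1][2] == t[2] and out[-1][1] == t[0]:
            out[-1] = (out[-1][0], t[1], t[2])
        else:
            out.append(t)
    return out


def check_tracts(hap: Haplotype, chrom_lengths: Mapping[str, int]) -> None:
    """Tracts must exactly partition [0, length) on every chromosome."""
    for chrom, length in chrom_lengths.items():
        tracts = hap[chrom]
        cur = 0
        for s, e, _ in tracts:
            if s != cur or e <= s:
                raise SimulationError(f"tract bookkeeping broken on {chrom}")
            cur = e
        if cur != length:
            raise SimulationError(f"tracts do not cover {chrom}")


def meiosis(
    parent: tuple[Haplotype, Haplotype],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> Haplotype:
    """One recombinant gamete: Poisson crossovers, uniform breakpoints."""
    hapA, hapB = parent
    gamete: Haplotype = {}
    for chrom, length in cfg.chrom_lengths.items():
        k = int(rng.poisson(cfg.crossover_rate))
        if k:
            breaks = np.unique(rng.integers(1, length, size=k)).tolist()
        else:
            breaks = []
        cur = int(rng.integers(0, 2))
        pieces = []
        prev = 0
        for b in breaks + [length]:
            src = hapA if cur == 0 else hapB
            pieces.extend(_slice_tracts(src[chrom], prev, b))
            prev = b
            cur ^= 1
        gamete[chrom] = _merge_tracts(pieces)
    return gamete


def founder_at(hap: Haplotype, chrom: str, pos0: int) -> int:
    for s, e, f in hap[chrom]:
        if s <= pos0 < e:
            return f
    raise SimulationError(f"position {pos0} not covered on {chrom}")


def ancestry_of(cfg: SimConfig, founder: int) -> str:
    if founder in cfg.donor_founders:
        return "donor"
    if founder in cfg.recipient_founders:
        return "recurrent"
    return "outgroup"


def ancestry_tracts(cfg: SimConfig, hap: Haplotype, hap_id: str) -> list[AncestryTract]:
    out: list[AncestryTract] = []
    for chrom, tracts in hap.items():
        merged: list = []
        for s, e, f in tracts:
            a = ancestry_of(cfg, f)
            if merged and merged[-1][2] == a and merged[-1][1] == s:
                merged[-1] = (merged[-1][0], e, a)
            else:
                merged.append((s, e, a))
        out.extend(AncestryTract(hap_id, chrom, s, e, a) for s, e, a in merged)
    return out


def donor_fraction(
    cfg: SimConfig, hap: Haplotype, exclude_chrom: str | None = None
) -> float:
    """Donor-ancestry fraction of a haplotype, optionally excluding one chrom."""
    tot = 0
    donor = 0
    for chrom, tracts in hap.items():
        if chrom == exclude_chrom:
            continue
        for s, e, f in tracts:
            tot += e - s
            if ancestry_of(cfg, f) == "donor":
                donor += e - s
    return donor / tot if tot else 0.0


# -- the breeding scheme -----------------------------------------------------

Individual = tuple  # (maternal Haplotype, paternal Haplotype)


def _wp_donor_dose(cfg: SimConfig, ind: Individual) -> int:
    chrom, pos = cfg.wp_locus
    return sum(
        ancestry_of(cfg, founder_at(h, chrom, pos - 1)) == "donor" for h in ind
    )


@dataclass
class TruthSet:
    """Ground truth emitted with every simulated dataset."""

    individuals: dict  # sample/individual id -> list[AncestryTract] (both haps)
    hom_donor_tract: tuple[str, int, int]  # homozygous donor interval around wp
    wp_locus: tuple[str, int]
    bc_maternal_donor_fraction: float  # outside the selected chromosome


def _recipient_individual(cfg: SimConfig, rng: np.random.Generator) -> Individual:
    i, j = rng.choice(len(cfg.recipient_founders), size=2, replace=False)
    r = list(cfg.recipient_founders)
    return (founder_haplotype(cfg, r[i]), founder_haplotype(cfg, r[j]))


def _offspring(
    mother: Individual, father: Individual, cfg: SimConfig, rng: np.random.Generator
) -> Individual:
    return (meiosis(mother, cfg, rng), meiosis(father, cfg, rng))


def _select_offspring(
    mother: Individual,
    father: Individual,
    cfg: SimConfig,
    rng: np.random.Generator,
    wanted_dose: int,
    n_wanted: int = 1,
) -> list[Individual]:
    """Draw offspring until *n_wanted* carry the wanted wp donor dose."""
    hits: list[Individual] = []
    for _ in range(cfg.retry_limit):
        for _ in range(cfg.brood_size):
            child = _offspring(mother, father, cfg, rng)
            if _wp_donor_dose(cfg, child) == wanted_dose:
                hits.append(child)
                if len(hits) >= n_wanted:
                    return hits
    raise SimulationError(
        f"selection found {len(hits)}/{n_wanted} offspring with wp dose "
        f"{wanted_dose} within retry limit"
    )


def breed_introgression_line(
    cfg: SimConfig, rng: np.random.Generator | None = None, n_final: int | None = None
) -> tuple[list[Individual], TruthSet]:
    """Run F1 -> F2 selection -> backcrosses -> fixing intercross.

    Returns the final homozygous-introgression individuals and the truth set
    (ancestry tracts, realized homozygous donor tract, and the donor-genome
    fraction of the introgressed haplotype after the last backcross).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if n_final is None:
        n_final = cfg.n_individuals_per_group + sum(n for n, _ in cfg.pool_specs)

    d = list(cfg.donor_founders)
    donor_mother: Individual = (
        founder_haplotype(cfg, d[0]),
        founder_haplotype(cfg, d[1]),
    )
    # F1 hybrids (donor mother x recipient fathers); all wp heterozygous
    f1_a = _offspring(donor_mother, _recipient_individual(cfg, rng), cfg, rng)
    f1_b = _offspring(donor_mother, _recipient_individual(cfg, rng), cfg, rng)
    # F2 intercross; select a wp homozygote for the first backcross
    mother = _select_offspring(f1_a, f1_b, cfg, rng, wanted_dose=2)[0]

    for round_no in range(1, cfg.n_backcross + 1):
        if cfg.reselect_homozygotes and _wp_donor_dose(cfg, mother) < 2:
            sibs = _select_offspring(
                mother, _recipient_individual(cfg, rng), cfg, rng, wanted_dose=1, n_wanted=2
            )
            mother = _select_offspring(sibs[0], sibs[1], cfg, rng, wanted_dose=2)[0]
        father = _recipient_individual(cfg, rng)
        wanted = 1  # mother is either hom (dose 2 -> all carriers) or het
        n_wanted = 2 if round_no == cfg.n_backcross else 1
        selected = _select_offspring(mother, father, cfg, rng, wanted, n_wanted)
        mother = selected[0]

    sib_a, sib_b = selected
    bc_frac = donor_fraction(cfg, sib_a[0], exclude_chrom=cfg.wp_locus[0])

    # fixing intercross, then line establishment: homozygote x homozygote
    # crosses breed true for the marker, so propagation needs no selection
    pop_size = max(n_final, 8)
    generation = _select_offspring(
        sib_a, sib_b, cfg, rng, wanted_dose=2, n_wanted=pop_size
    )
    for _ in range(cfg.n_line_generations):
        nxt = []
        for _ in range(pop_size):
            i, j = rng.choice(len(generation), size=2, replace=False)
            nxt.append(_offspring(generation[i], generation[j], cfg, rng))
        generation = nxt
    final = generation[:n_final]

    individuals = {}
    for i, ind in enumerate(final):
        tracts = []
        for h, hap in enumerate(ind):
            tracts.extend(ancestry_tracts(cfg, hap, f"line_{i + 1}|{h}"))
        individuals[f"line_{i + 1}"] = tracts
    truth = TruthSet(
        individuals=individuals,
        hom_donor_tract=_hom_donor_tract(cfg, final),
        wp_locus=cfg.wp_locus,
        bc_maternal_donor_fraction=bc_frac,
    )
    return final, truth


def _hom_donor_tract(cfg: SimConfig, individuals: Sequence[Individual]) -> tuple[str, int, int]:
    """Largest interval around wp where every individual is donor on both haps."""
    chrom, pos = cfg.wp_locus
    pos0 = pos - 1
    lo, hi = 0, cfg.chrom_lengths[chrom]
    for ind in individuals:
        for hap in ind:
            # project to ancestry and merge before locating wp
            merged: list = []
            for s, e, f in hap[chrom]:
                a = ancestry_of(cfg, f)
                if merged and merged[-1][2] == a and merged[-1][1] == s:
                    merged[-1] = (merged[-1][0], e, a)
                else:
                    merged.append((s, e, a))
            for s, e, a in merged:
                if s <= pos0 < e:
                    if a != "donor":
                        raise SimulationError("wp locus not on a donor tract")
                    lo, hi = max(lo, s), min(hi, e)
                    break
    return (chrom, lo, hi)


# -- observation emission ----------------------------------------------------


@dataclass
class SimResult:
    gm: GenotypeMatrix
    pm: PopulationMap
    truth: TruthSet
    founders: Founders
    cfg: SimConfig


GROUPS = {"P1": "recipient", "P2": "line", "P3": "donor", "O": "outgroup"}


def _hap_codes(founders: Founders, hap: Haplotype) -> np.ndarray:
    """Allele codes of one haplotype, concatenated over chrom blocks."""
    parts = []
    for chrom, cs in founders.sites.items():
        col = np.empty(len(cs.pos), dtype=np.int16)
        for s, e, f in hap[chrom]:
            lo = np.searchsorted(cs.pos, s + 1)
            hi = np.searchsorted(cs.pos, e + 1)
            col[lo:hi] = cs.founder_alleles[lo:hi, f]
        parts.append(col)
    return np.concatenate(parts)


def emit_observations(
    final_individuals: Sequence[Individual],
    founders: Founders,
    cfg: SimConfig,
    rng: np.random.Generator,
    truth: TruthSet | None = None,
) -> SimResult:
    """Assemble the observed genotype matrix, population map and truth."""
    n_ind = cfg.n_individuals_per_group
    need = n_ind + sum(n for n, _ in cfg.pool_specs)
    if len(final_individuals) < need:
        raise SimulationError(f"need {need} final individuals, got {len(final_individuals)}")

    samples: list[str] = []
    ploidy: list[int] = []
    assignment: dict[str, str] = {}
    hap_sources: list = []  # per sample: list of haplotypes or founder columns

    def founder_pair(pool: range) -> list[int]:
        idx = rng.choice(len(pool), size=2, replace=False)
        base = list(pool)
        return [base[i] for i in idx]

    for i in range(n_ind):
        samples.append(f"rec_{i + 1}")
        ploidy.append(2)
        assignment[samples[-1]] = GROUPS["P1"]
        hap_sources.append([("founder", f) for f in founder_pair(cfg.recipient_founders)])
    for i in range(n_ind):
        samples.append(f"line_{i + 1}")
        ploidy.append(2)
        assignment[samples[-1]] = GROUPS["P2"]
        hap_sources.append([("hap", h) for h in final_individuals[i]])
    for i in range(n_ind):
        samples.append(f"don_{i + 1}")
        ploidy.append(2)
        assignment[samples[-1]] = GROUPS["P3"]
        hap_sources.append([("founder", f) for f in founder_pair(cfg.donor_founders)])
    for i in range(n_ind):
        samples.append(f"out_{i + 1}")
        ploidy.append(2)
        assignment[samples[-1]] = GROUPS["O"]
        hap_sources.append([("founder", f) for f in founder_pair(cfg.outgroup_founders)])
    used = n_ind
    for k, (n_pool, pl) in enumerate(cfg.pool_specs):
        samples.append(f"line_pool_{k + 1}")
        ploidy.append(pl)
        assignment[samples[-1]] = GROUPS["P2"]
        members = final_individuals[used : used + n_pool]
        used += n_pool
        src = []
        for ind in members:
            src.extend(("hap", h) for h in ind)
        hap_sources.append(src)

    chroms: list[str] = []
    pos_parts = []
    refs: list[str] = []
    alts: list[tuple[str, ...]] = []
    for chrom, cs in founders.sites.items():
        chroms.extend([chrom] * len(cs.pos))
        pos_parts.append(cs.pos)
        refs.extend(cs.ref)
        alts.extend((a,) for a in cs.alt)
    pos = np.concatenate(pos_parts) if pos_parts else np.array([], dtype=np.int64)

    cols: list[np.ndarray] = []
    founder_cols = np.concatenate(
        [cs.founder_alleles for cs in founders.sites.values()]
    )
    for src in hap_sources:
        for kind, obj in src:
            if kind == "founder":
                cols.append(founder_cols[:, obj].astype(np.int16))
            else:
                cols.append(_hap_codes(founders, obj))
    codes = np.column_stack(cols) if cols else np.zeros((0, 0), dtype=np.int16)

    if cfg.genotype_error_rate > 0:
        flip = rng.random(codes.shape) < cfg.genotype_error_rate
        codes = np.where(flip, 1 - codes, codes).astype(np.int16)

    depth = rng.poisson(cfg.depth_mean, size=(len(pos), len(samples))).astype(np.int32)

    gm = GenotypeMatrix(chroms, pos, refs, alts, codes, depth, samples, ploidy)
    pm = PopulationMap(assignment=assignment, roles=dict(GROUPS))
    if truth is None:
        truth = TruthSet(
            individuals={}, hom_donor_tract=("", 0, 0), wp_locus=cfg.wp_locus,
            bc_maternal_donor_fraction=float("nan"),
        )
    return SimResult(gm=gm, pm=pm, truth=truth, founders=founders, cfg=cfg)


def simulate_dataset(cfg: SimConfig) -> SimResult:
    """Founders -> breeding -> observations, all from one seeded generator."""
    rng = np.random.default_rng(cfg.seed)
    founders = simulate_founders(cfg, rng)
    final, truth = breed_introgression_line(cfg, rng)
    return emit_observations(final, founders, cfg, rng, truth)


# -- file outputs ------------------------------------------------------------


def truth_to_bed(truth: TruthSet, path: str) -> None:
    with open(path, "w") as fh:
        chrom, lo, hi = truth.hom_donor_tract
        fh.write(f"{chrom}\t{lo}\t{hi}\thom_donor_tract\n")
        for ind, tracts in truth.individuals.items():
            for t in tracts:
                fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.haplotype_id}:{t.ancestry}\n")


def write_outputs(result: SimResult, outdir: str | Path) -> dict[str, str]:
    """Write VCF, sample map, truth BED and a config echo; return a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": str(outdir / "simulated.vcf"),
        "sample_map": str(outdir / "sample_map.tsv"),
        "truth_bed": str(outdir / "truth_tracts.bed"),
        "config": str(outdir / "sim_config.json"),
    }
    write_vcf(result.gm, paths["vcf"], contig_lengths=result.cfg.chrom_lengths)
    result.pm.to_tsv(paths["sample_map"])
    truth_to_bed(result.truth, paths["truth_bed"])
    cfg_dict = asdict(result.cfg)
    with open(paths["config"], "w") as fh:
        json.dump(cfg_dict, fh, indent=2, default=str)
    manifest = dict(paths)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    manifest["manifest"] = str(outdir / "manifest.json")
    return manifest
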