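"""Forward simulation of a two-parent RIL cross and pooled bulk sequencing.

The simulator reproduces, stage by stage, the experiment a bulked-segregant
analysis (BSA) is run on:

1. an F1 heterozygote between two inbred strains (N2-like reference and
   CB4856-like wild isolate) is selfed for ``G`` generations to derive a
   panel of recombinant inbred lines (RILs), each a homozygous mosaic of
   the two parental genomes;
2. each line gets a quantitative phenotype (seam cell number, SCN) from a
   small set of additive QTLs plus per-animal noise, averaged over the
   animals scored per line;
3. the phenotypic extremes are pooled into a low bulk and a high bulk;
4. each bulk is "sequenced": at every strain-discriminating SNP the
   alternate-allele read count is binomial in the bulk's local ancestry
   frequency, at a Poisson depth.

Meiosis uses a no-interference crossover model: the per-chromosome
crossover count is Poisson with mean ``genetic_length/100`` and breakpoints
are uniform on the genetic map projected to physical coordinates (linear
projection, so uniform in bp).

Haplotypes are stored as change-point lists ``[(start, ancestry), ...]``
(1-based, first start = 1); a diploid genome is a pair of haplotype
mosaics keyed by chromosome.  Finished RILs collapse to closed segment
lists ``[(start, end, ancestry), ...]`` that partition each chromosome.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import CB4856, N2, ANCESTRIES, GenomeMap

# A haplotype for one chromosome: ancestry change points, first start == 1.
Haplotype = list[tuple[int, str]]
# A haplotype mosaic: one haplotype per chromosome.
HaplotypeMosaic = dict[str, Haplotype]
# A diploid individual: two haplotype mosaics.
Diplotype = tuple[HaplotypeMosaic, HaplotypeMosaic]


# ---------------------------------------------------------------------------
# configuration dataclasses
# ---------------------------------------------------------------------------

@dataclass
class QtlEffect:
    """Additive effect (in seam cells) of carrying the CB4856 allele at ``pos``."""

    chrom: str
    pos: int
    effect: float

    @property
    def sign(self) -> int:
        return 1 if self.effect > 0 else -1


def default_qtl_architecture() -> list[QtlEffect]:
    """Four-QTL architecture: II/III/X raise SCN on the CB4856 allele, the
    right arm of V lowers it.  The positive effects sum to +2.0 cells,
    matching the ~2-cell parental contrast."""
    return [
        QtlEffect("II", 7_500_000, +0.8),
        QtlEffect("III", 7_000_000, +0.8),
        QtlEffect("V", 18_000_000, -0.5),
        QtlEffect("X", 9_000_000, +0.4),
    ]


def default_forced_regions() -> list[tuple[str, int, int, str]]:
    """Tracts fixed for the reference parent in every line: the *peel-1/zeel-1*
    incompatibility region (left arm of I), the *egl-18(ga97)* introgression
    (left arm of IV) and the *scm::GFP* insertion region (centre of V)."""
    return [
        ("I", 1, 3_000_000, N2),
        ("IV", 1, 5_000_000, N2),
        ("V", 5_000_000, 15_000_000, N2),
    ]


@dataclass
class CrossConfig:
    n_rils: int = 116
    selfing_generations: int = 10
    forced_regions: list[tuple[str, int, int, str]] = field(
        default_factory=default_forced_regions
    )
    seed: int | None = None

    def validate(self, gmap: GenomeMap) -> None:
        if self.n_rils <= 0:
            raise ValueError("n_rils must be > 0")
        if self.selfing_generations < 1:
            raise ValueError("selfing_generations must be >= 1")
        for chrom, start, end, anc in self.forced_regions:
            plen = gmap.length_of(chrom)
            if not (1 <= start <= end <= plen):
                raise ValueError(
                    f"forced region {chrom}:{start}-{end} outside [1, {plen}]"
                )
            if anc not in ANCESTRIES:
                raise ValueError(f"unknown ancestry {anc!r} in forced region")


@dataclass
class PhenotypeModel:
    """Line phenotype: baseline + additive CB4856 QTL effects + animal noise.

    ``baseline`` is the mean SCN of an all-reference line; ``animal_sd`` the
    per-animal standard deviation; the line mean averages
    ``animals_per_line`` scored animals.
    """

    baseline: float = 12.0
    qtls: list[QtlEffect] = field(default_factory=default_qtl_architecture)
    animal_sd: float = 1.5
    animals_per_line: int = 80

    def validate(self, gmap: GenomeMap) -> None:
        if self.animal_sd < 0:
            raise ValueError("animal_sd must be >= 0")
        if self.animals_per_line < 1:
            raise ValueError("animals_per_line must be >= 1")
        for q in self.qtls:
            plen = gmap.length_of(q.chrom)
            if not (1 <= q.pos <= plen):
                raise ValueError(f"QTL position {q.chrom}:{q.pos} outside chromosome")


@dataclass
class BulkDesign:
    """Sizes of the phenotypic-extreme pools (number of RILs per bulk)."""

    n_low: int = 22
    n_high: int = 24

    def validate(self) -> None:
        if self.n_low <= 0 or self.n_high <= 0:
            raise ValueError("bulk sizes must be > 0")


@dataclass
class ReadSimConfig:
    """Pooled-sequencing model: Poisson depth, binomial allele sampling with
    symmetric base error, and a two-point genotype-quality distribution
    (``gq_value`` with an optional contaminating ``low_gq_fraction`` at
    ``low_gq_value``)."""

    mean_depth: float = 25.0
    base_error: float = 0.001
    gq_value: int = 60
    low_gq_fraction: float = 0.0
    low_gq_value: int = 20
    seed: int | None = None

    def validate(self) -> None:
        if not (0 <= self.base_error < 0.5):
            raise ValueError("base_error must be in [0, 0.5)")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if not (0 <= self.low_gq_fraction <= 1):
            raise ValueError("low_gq_fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# haplotype primitives
# ---------------------------------------------------------------------------

def _ancestry_in_hap(hap: Haplotype, pos: int) -> str:
    i = bisect_right([s for s, _ in hap], pos) - 1
    return hap[i][1]


def _slice_hap(hap: Haplotype, a: int, b: int) -> Haplotype:
    """Segments of ``hap`` covering the closed range [a, b]."""
    starts = [s for s, _ in hap]
    i = bisect_right(starts, a) - 1
    out: Haplotype = []
    while i < len(hap) and hap[i][0] <= b:
        out.append((max(hap[i][0], a), hap[i][1]))
        i += 1
    return out


def _merge_hap(hap: Haplotype) -> Haplotype:
    out: Haplotype = []
    for start, anc in hap:
        if out and out[-1][1] == anc:
            continue
        out.append((start, anc))
    return out


def _gamete_chromosome(
    h0: Haplotype, h1: Haplotype, plen: int, glen_cm: float, rng: np.random.Generator
) -> Haplotype:
    n_x = int(rng.poisson(glen_cm / 100.0)) if glen_cm > 0 else 0
    first = int(rng.integers(2))
    if n_x == 0:
        return list(h0 if first == 0 else h1)
    # a crossover at float b switches strands from floor(b)+1 onwards
    switches = sorted(int(math.floor(b)) + 1 for b in rng.uniform(1.0, plen, size=n_x))
    bounds = [1] + [s for s in switches if s <= plen] + [plen + 1]
    parents = (h0, h1)
    child: Haplotype = []
    for i in range(len(bounds) - 1):
        a, b = bounds[i], bounds[i + 1] - 1
        if a > b:
            continue
        child.extend(_slice_hap(parents[(first + i) % 2], a, b))
    return _merge_hap(child)


def simulate_gamete(
    diplotype: Diplotype, gmap: GenomeMap, rng: np.random.Generator
) -> HaplotypeMosaic:
    """One meiotic product of ``diplotype`` under the no-interference model.

    Per chromosome the crossover count is Poisson(genetic_length/100) and
    breakpoints fall uniformly in physical coordinates (linear genetic map).
    """
    h0, h1 = diplotype
    if set(h0) != set(gmap.names) or set(h1) != set(gmap.names):
        raise ValueError("diplotype chromosomes do not match the genome map")
    return {
        name: _gamete_chromosome(
            h0[name], h1[name], gmap.length_of(name), gmap.genetic_length_of(name), rng
        )
        for name in gmap.names
    }


def f1_diplotype(gmap: GenomeMap) -> Diplotype:
    """The cross founder: one all-reference and one all-CB4856 haplotype."""
    return (
        {name: [(1, N2)] for name in gmap.names},
        {name: [(1, CB4856)] for name in gmap.names},
    )


def simulate_selfed_diplotype(
    gmap: GenomeMap, generations: int, rng: np.random.Generator
) -> Diplotype:
    """Self an F1 heterozygote for ``generations`` meioses (F2 = generation 1).

    The expected heterozygous genome fraction after G generations is (1/2)^G.
    """
    dip = f1_diplotype(gmap)
    for _ in range(generations):
        dip = (simulate_gamete(dip, gmap, rng), simulate_gamete(dip, gmap, rng))
    return dip


def _overlay(h0: Haplotype, h1: Haplotype) -> list[tuple[int, str, str]]:
    """Common refinement of two haplotypes: (start, ancestry0, ancestry1)."""
    starts = sorted({s for s, _ in h0} | {s for s, _ in h1})
    return [(s, _ancestry_in_hap(h0, s), _ancestry_in_hap(h1, s)) for s in starts]


def heterozygous_fraction(diplotype: Diplotype, gmap: GenomeMap) -> float:
    """Genome fraction where the two haplotypes carry different ancestries."""
    het_bp = 0
    total_bp = 0
    h0, h1 = diplotype
    for name in gmap.names:
        plen = gmap.length_of(name)
        total_bp += plen
        cells = _overlay(h0[name], h1[name])
        for i, (start, a0, a1) in enumerate(cells):
            end = cells[i + 1][0] - 1 if i + 1 < len(cells) else plen
            if a0 != a1:
                het_bp += end - start + 1
    return het_bp / total_bp


def _resolve_to_segments(
    h0: Haplotype, h1: Haplotype, plen: int, rng: np.random.Generator
) -> list[tuple[int, int, str]]:
    """Collapse a diploid chromosome to homozygous segments; each maximal
    residual heterozygous interval is fixed to one ancestry by a fair coin."""
    cells = _overlay(h0, h1)
    segs: list[tuple[int, int, str]] = []
    i = 0
    while i < len(cells):
        start, a0, a1 = cells[i]
        if a0 == a1:
            end = cells[i + 1][0] - 1 if i + 1 < len(cells) else plen
            segs.append((start, end, a0))
            i += 1
        else:
            # extend over the whole heterozygous run, then flip one coin
            j = i
            while j < len(cells) and cells[j][1] != cells[j][2]:
                j += 1
            end = cells[j][0] - 1 if j < len(cells) else plen
            segs.append((start, end, CB4856 if rng.integers(2) else N2))
            i = j
    return _merge_segments(segs)


def _merge_segments(segs: list[tuple[int, int, str]]) -> list[tuple[int, int, str]]:
    out: list[tuple[int, int, str]] = []
    for start, end, anc in segs:
        if out and out[-1][2] == anc and out[-1][1] + 1 == start:
            out[-1] = (out[-1][0], end, anc)
        else:
            out.append((start, end, anc))
    return out


def _force_region(
    segs: list[tuple[int, int, str]], start: int, end: int, anc: str
) -> list[tuple[int, int, str]]:
    out: list[tuple[int, int, str]] = []
    for s, e, a in segs:
        if e < start or s > end:
            out.append((s, e, a))
            continue
        if s < start:
            out.append((s, start - 1, a))
        if e > end:
            out.append((end + 1, e, a))
    out.append((start, end, anc))
    out.sort()
    return _merge_segments(out)


# ---------------------------------------------------------------------------
# RIL genomes
# ---------------------------------------------------------------------------

@dataclass
class RilGenome:
    """A finished RIL: homozygous ancestry mosaic over all chromosomes.

    ``segments[chrom]`` is an ordered list of closed ``(start, end, ancestry)``
    intervals partitioning ``[1, physical_length]``, with adjacent segments of
    different ancestry.
    """

    line_id: str
    segments: dict[str, list[tuple[int, int, str]]]

    def chrom_length(self, chrom: str) -> int:
        return self.segments[chrom][-1][1]


def ancestry_at(line: RilGenome, chrom: str, pos: int) -> str:
    """Ancestry of the segment containing ``pos`` (1-based)."""
    segs = line.segments[chrom]
    if not (1 <= pos <= segs[-1][1]):
        raise ValueError(f"position {pos} outside {chrom} [1, {segs[-1][1]}]")
    i = bisect_right([s for s, _, _ in segs], pos) - 1
    return segs[i][2]


def make_rils(
    config: CrossConfig, gmap: GenomeMap, rng: np.random.Generator
) -> list[RilGenome]:
    """Derive the RIL panel: each line is an independent selfing lineage from
    the F1 heterozygote, fixed after the final generation and overwritten in
    the forced regions."""
    config.validate(gmap)
    rils: list[RilGenome] = []
    width = max(3, len(str(config.n_rils)))
    for k in range(config.n_rils):
        dip = simulate_selfed_diplotype(gmap, config.selfing_generations, rng)
        segments = {
            name: _resolve_to_segments(
                dip[0][name], dip[1][name], gmap.length_of(name), rng
            )
            for name in gmap.names
        }
        for chrom, start, end, anc in config.forced_regions:
            segments[chrom] = _force_region(segments[chrom], start, end, anc)
        rils.append(RilGenome(line_id=f"RIL{k + 1:0{width}d}", segments=segments))
    return rils


def phenotype(
    line: RilGenome, model: PhenotypeModel, rng: np.random.Generator
) -> float:
    """Line-mean SCN: genetic value plus the mean of per-animal noise draws."""
    value = model.baseline
    for q in model.qtls:
        if ancestry_at(line, q.chrom, q.pos) == CB4856:
            value += q.effect
    if model.animal_sd == 0:
        return value
    noise = rng.normal(0.0, model.animal_sd, size=model.animals_per_line)
    return value + float(noise.mean())


def select_bulks(
    phenotypes: dict[str, float], design: BulkDesign
) -> tuple[list[str], list[str]]:
    """Extreme-phenotype pools: the ``n_low`` smallest and ``n_high`` largest
    line means; ties broken by ascending line id."""
    design.validate()
    if len(phenotypes) < design.n_low + design.n_high:
        raise ValueError(
            f"need at least {design.n_low + design.n_high} lines, "
            f"got {len(phenotypes)}"
        )
    order = sorted(phenotypes, key=lambda lid: (phenotypes[lid], lid))
    return order[: design.n_low], order[-design.n_high:]


# ---------------------------------------------------------------------------
# pooled sequencing
# ---------------------------------------------------------------------------

def bulk_ancestry_frequency(
    bulk: list[RilGenome], gmap: GenomeMap, chrom: str
) -> np.ndarray:
    """Per-SNP fraction of bulk lines carrying CB4856 ancestry on ``chrom``."""
    pos = np.asarray(gmap.snp_positions.get(chrom, []), dtype=np.int64)
    counts = np.zeros(len(pos), dtype=np.int64)
    for line in bulk:
        segs = line.segments[chrom]
        starts = np.array([s for s, _, _ in segs], dtype=np.int64)
        is_cb = np.array([a == CB4856 for _, _, a in segs])
        counts += is_cb[np.searchsorted(starts, pos, side="right") - 1]
    return counts / len(bulk)


def simulate_bulk_reads(
    bulk: list[RilGenome],
    gmap: GenomeMap,
    cfg: ReadSimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Pooled sequencing of one bulk.

    At each SNP with bulk CB4856 ancestry frequency q, depth ~ Poisson(mean)
    and alt_count ~ Binomial(depth, q(1-e) + (1-q)e) with base-error e.
    Returns a frame with columns chrom, pos, ref_count, alt_count, depth, gq.
    """
    if not bulk:
        raise ValueError("bulk must be non-empty")
    cfg.validate()
    frames = []
    for chrom in gmap.names:
        pos = np.asarray(gmap.snp_positions.get(chrom, []), dtype=np.int64)
        if len(pos) == 0:
            continue
        q = bulk_ancestry_frequency(bulk, gmap, chrom)
        depth = rng.poisson(cfg.mean_depth, size=len(pos))
        p_alt = q * (1.0 - cfg.base_error) + (1.0 - q) * cfg.base_error
        alt = rng.binomial(depth, p_alt)
        gq = np.full(len(pos), cfg.gq_value, dtype=np.int64)
        if cfg.low_gq_fraction > 0:
            low = rng.random(len(pos)) < cfg.low_gq_fraction
            gq[low] = cfg.low_gq_value
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref_count": depth - alt,
                    "alt_count": alt,
                    "depth": depth,
                    "gq": gq,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# full experiment
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    rils: list[RilGenome]
    phenotypes: pd.DataFrame  # line_id, mean_scn, bulk in {low, high, none}
    low_ids: list[str]
    high_ids: list[str]
    reads_low: pd.DataFrame
    reads_high: pd.DataFrame
    truth: list[QtlEffect]


def simulate_experiment(
    gmap: GenomeMap | None = None,
    cross: CrossConfig | None = None,
    model: PhenotypeModel | None = None,
    design: BulkDesign | None = None,
    reads: ReadSimConfig | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SimulationResult:
    """Run the full generative pipeline: cross → phenotypes → bulks → reads."""
    gmap = gmap or _default_map()
    cross = cross or CrossConfig()
    model = model or PhenotypeModel()
    design = design or BulkDesign()
    reads = reads or ReadSimConfig()
    if rng is None:
        rng = np.random.default_rng(seed if seed is not None else cross.seed)
    model.validate(gmap)
    if design.n_low + design.n_high > cross.n_rils:
        raise ValueError("bulk sizes exceed the number of RILs")

    rils = make_rils(cross, gmap, rng)
    means = {line.line_id: phenotype(line, model, rng) for line in rils}
    low_ids, high_ids = select_bulks(means, design)
    by_id = {line.line_id: line for line in rils}
    reads_low = simulate_bulk_reads([by_id[i] for i in low_ids], gmap, reads, rng)
    reads_high = simulate_bulk_reads([by_id[i] for i in high_ids], gmap, reads, rng)

    bulk_of = {i: "low" for i in low_ids} | {i: "high" for i in high_ids}
    pheno = pd.DataFrame(
        {
            "line_id": list(means),
            "mean_scn": [means[i] for i in means],
            "bulk": [bulk_of.get(i, "none") for i in means],
        }
    ).sort_values("line_id", ignore_index=True)
    return SimulationResult(
        rils=rils,
        phenotypes=pheno,
        low_ids=low_ids,
        high_ids=high_ids,
        reads_low=reads_low,
        reads_high=reads_high,
        truth=list(model.qtls),
    )


def _default_map() -> GenomeMap:
    from .genome import default_genome_map

    return default_genome_map()
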