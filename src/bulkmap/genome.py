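"""Genome map: chromosome sizes, genetic lengths, and marker positions.

The map describes the two-parent cross coordinate system: each chromosome
has a physical length in bp, a genetic length in cM (used by the meiosis
simulator), and a sorted list of SNP positions that distinguish the two
parental strains.  Defaults approximate the six *C. elegans* chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field


#: The two parental ancestries of the cross.  ``ALT`` (CB4856-style wild
#: isolate) carries the alternate allele at every marker SNP; ``REF`` is the
#: reference (N2-style) background.
N2 = "N2"
CB4856 = "CB4856"
ANCESTRIES = (N2, CB4856)

# Approximate C. elegans chromosome sizes (Mb) and a uniform 50 cM map.
_DEFAULT_CHROMS = [
    ("I", 15_100_000, 50.0),
    ("II", 15_300_000, 50.0),
    ("III", 13_800_000, 50.0),
    ("IV", 17_500_000, 50.0),
    ("V", 20_900_000, 50.0),
    ("X", 17_700_000, 50.0),
]


@dataclass
class GenomeMap:
    """Ordered chromosomes with physical/genetic lengths and SNP positions.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, physical_length_bp, genetic_length_cM)`` triples.
    snp_positions
        Mapping chromosome name -> sorted list of 1-based bp positions of
        the parental-discriminating SNPs.  May be empty for chromosomes
        that carry no markers.
    """

    chromosomes: list[tuple[str, int, float]]
    snp_positions: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for name, plen, glen in self.chromosomes:
            if plen <= 0:
                raise ValueError(f"chromosome {name}: physical length must be > 0")
            if glen < 0:
                raise ValueError(f"chromosome {name}: genetic length must be >= 0")
            if name in seen:
                raise ValueError(f"duplicate chromosome {name}")
            seen.add(name)
        for name, positions in self.snp_positions.items():
            plen = self.length_of(name)
            prev = 0
            for p in positions:
                if not (1 <= p <= plen):
                    raise ValueError(f"SNP position {p} outside {name} [1, {plen}]")
                if p <= prev:
                    raise ValueError(f"SNP positions on {name} not strictly increasing")
                prev = p

    @property
    def names(self) -> list[str]:
        return [c[0] for c in self.chromosomes]

    def length_of(self, chrom: str) -> int:
        for name, plen, _ in self.chromosomes:
            if name == chrom:
                return plen
        raise KeyError(f"unknown chromosome {chrom!r}")

    def genetic_length_of(self, chrom: str) -> float:
        for name, _, glen in self.chromosomes:
            if name == chrom:
                return glen
        raise KeyError(f"unknown chromosome {chrom!r}")


def default_genome_map(snp_spacing: int = 10_000) -> GenomeMap:
    """Six-chromosome map with markers every ``snp_spacing`` bp.

    SNP positions start at ``snp_spacing`` on each chromosome, mimicking a
    dense genome-wide panel of strain-discriminating variants (~1 per 10 kb
    by default, ~10,000 SNPs genome-wide).
    """
    snps = {
        name: list(range(snp_spacing, plen + 1, snp_spacing))
        for name, plen, _ in _DEFAULT_CHROMS
    }
    return GenomeMap(chromosomes=list(_DEFAULT_CHROMS), snp_positions=snps)
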