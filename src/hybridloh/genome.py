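"""Hybrid diploid genome model and synthetic genome construction.

The model genome is a two-haplotype (``W`` x ``Y``) yeast-like diploid:
16 chromosomes totalling about 12 Mb, heterozygous SNP markers spaced
roughly 1 kb apart, an rDNA tandem array on chromosome XII with a
per-haplotype repeat count, and an optional annotation of repeated or
functional elements (Ty, delta, ARS, tRNA, tandem repeats, ...).

All coordinates are 1-based inclusive throughout the package; BED files
on disk use the conventional 0-based half-open system and are converted
at the I/O boundary (:mod:`hybridloh.io`).

The per-SNP state of the diploid is stored as integer copy counts of the
two parental alleles (``n_W``, ``n_Y``): a heterozygous disomic site is
``(1, 1)``, an LOH site retaining the Y allele is ``(0, 2)``, a site in a
heterozygous deletion of the W homolog is ``(0, 1)``, and so on.  Every
downstream simulator (read counts, microarray ratios) derives its
expectations from these counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._util import rng_from
from .errors import ConfigurationError

#: Approximate S. cerevisiae chromosome lengths and centromere midpoints
#: (bp); total ~12.07 Mb, smallest chromosome (chrI) ~230 kb.
DEFAULT_CHROMOSOMES = {
    "chrI": (230_218, 151_465),
    "chrII": (813_184, 238_207),
    "chrIII": (316_620, 114_385),
    "chrIV": (1_531_933, 449_711),
    "chrV": (576_874, 151_987),
    "chrVI": (270_161, 148_510),
    "chrVII": (1_090_940, 496_920),
    "chrVIII": (562_643, 105_586),
    "chrIX": (439_888, 355_629),
    "chrX": (745_751, 436_307),
    "chrXI": (666_816, 440_129),
    "chrXII": (1_078_177, 150_828),
    "chrXIII": (924_431, 268_031),
    "chrXIV": (784_333, 628_758),
    "chrXV": (1_091_291, 326_584),
    "chrXVI": (948_066, 555_957),
}

#: Eighteen element classes used for breakpoint-enrichment analysis.
ELEMENT_CLASSES = (
    "Ty",
    "delta",
    "sigma",
    "tau",
    "ARS",
    "tRNA",
    "snoRNA",
    "snRNA",
    "centromere",
    "telomere",
    "X_element",
    "Y_prime",
    "tandem_repeat",
    "rRNA",
    "LTR_remnant",
    "ncRNA",
    "G4_motif",
    "origin_flank",
)

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class RdnaLocus:
    """The rDNA tandem array: locus interval plus per-haplotype repeat counts."""

    chrom: str = "chrXII"
    start: int = 451_575
    end: int = 468_931
    repeats: dict = field(default_factory=lambda: {"W": 123, "Y": 72})


@dataclass(frozen=True)
class HybridGenomeConfig:
    """Configuration of the synthetic hybrid diploid.

    Parameters
    ----------
    chromosome_lengths, centromeres
        Mapping of chromosome name to length / centromere position (bp).
    snp_spacing
        Mean distance between heterozygous markers (bp).  The default of
        1000 bp gives ~12,000 markers on the 12 Mb genome (array-like
        density); ``sequencing`` mode uses ~218 bp for ~55,000 markers.
    haplotypes
        The two parental labels; by convention ``W`` carries the
        ribonucleotide-dense genome (the lesion-bearing parent).
    rdna
        rDNA array locus and per-haplotype repeat counts.
    gc_content
        Genomic G+C fraction used when synthesizing sequence (default 0.38).
    rnmp_density
        Ribonucleotides embedded per bp per strand; the ribodysgenic
        condition corresponds to ~1/500.
    """

    chromosome_lengths: dict = field(
        default_factory=lambda: {c: l for c, (l, _) in DEFAULT_CHROMOSOMES.items()}
    )
    centromeres: dict = field(
        default_factory=lambda: {c: cen for c, (_, cen) in DEFAULT_CHROMOSOMES.items()}
    )
    snp_spacing: int = 1000
    haplotypes: tuple = ("W", "Y")
    rdna: RdnaLocus = field(default_factory=RdnaLocus)
    gc_content: float = 0.38
    rnmp_density: float = 1.0 / 500.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.gc_content < 1.0):
            raise ConfigurationError(f"G+C content must lie in (0, 1), got {self.gc_content}")
        if self.snp_spacing <= 0:
            raise ConfigurationError("SNP spacing must be positive")
        if len(self.haplotypes) != 2 or self.haplotypes[0] == self.haplotypes[1]:
            raise ConfigurationError("exactly two distinct haplotype labels required")
        if self.rnmp_density < 0:
            raise ConfigurationError("rNMP density must be non-negative")
        if set(self.chromosome_lengths) != set(self.centromeres):
            raise ConfigurationError("chromosome_lengths and centromeres must name the same chromosomes")
        for chrom, length in self.chromosome_lengths.items():
            if length <= 0:
                raise ConfigurationError(f"{chrom}: non-positive length")
            cen = self.centromeres[chrom]
            if not (1 <= cen <= length):
                raise ConfigurationError(f"{chrom}: centromere {cen} outside 1..{length}")
        rd = self.rdna
        if rd is not None:
            if rd.chrom not in self.chromosome_lengths:
                raise ConfigurationError(f"rDNA chromosome {rd.chrom} not in genome")
            if not (1 <= rd.start <= rd.end <= self.chromosome_lengths[rd.chrom]):
                raise ConfigurationError("rDNA interval outside chromosome bounds")
            if any(v < 0 for v in rd.repeats.values()):
                raise ConfigurationError("rDNA repeat counts must be >= 0")

    @property
    def genome_length(self) -> int:
        return int(sum(self.chromosome_lengths.values()))

    @property
    def chromosomes(self) -> list:
        return list(self.chromosome_lengths)

    @classmethod
    def default(cls, mode: str = "array", seed: int = 0) -> "HybridGenomeConfig":
        """Full-size genome preset.

        ``mode='sequencing'`` targets ~55,000 markers (the density of a
        whole-genome sequencing comparison of two hybrid parents);
        ``mode='array'`` targets ~13,000 probes about 1 kb apart.
        """
        base = cls(seed=seed)
        if mode == "sequencing":
            return replace(base, snp_spacing=max(1, round(base.genome_length / 55_000)))
        if mode == "array":
            return replace(base, snp_spacing=max(1, round(base.genome_length / 13_000)))
        raise ConfigurationError(f"unknown mode {mode!r}")

    @classmethod
    def miniature(cls, n_chroms: int = 3, scale: float = 0.5, seed: int = 0,
                  snp_spacing: int = 1000) -> "HybridGenomeConfig":
        """Small genome for fast tests: first ``n_chroms`` chromosomes scaled."""
        names = list(DEFAULT_CHROMOSOMES)[:n_chroms]
        lengths = {c: int(DEFAULT_CHROMOSOMES[c][0] * scale) for c in names}
        cens = {c: max(1, int(DEFAULT_CHROMOSOMES[c][1] * scale)) for c in names}
        rdna = None
        return cls(chromosome_lengths=lengths, centromeres=cens, rdna=rdna,
                   snp_spacing=snp_spacing, seed=seed)


@dataclass
class DiploidGenome:
    """A realized diploid: config + SNP map with per-allele copy counts.

    ``snps`` columns: chrom, pos, allele_W, allele_Y, n_W, n_Y.
    """

    config: HybridGenomeConfig
    snps: pd.DataFrame
    rdna_repeats: dict = field(default_factory=dict)

    def copy(self) -> "DiploidGenome":
        return DiploidGenome(self.config, self.snps.copy(), dict(self.rdna_repeats))

    def chrom_snps(self, chrom: str) -> pd.DataFrame:
        return self.snps[self.snps["chrom"] == chrom]

    @property
    def n_snps(self) -> int:
        return len(self.snps)


def build_hybrid_genome(config: HybridGenomeConfig) -> DiploidGenome:
    """Construct the heterozygous diploid marker map.

    Markers are placed one per ``snp_spacing`` window with a deterministic
    seeded jitter, so the mean spacing equals the configured value while
    positions are strictly increasing within each chromosome.  Every
    marker starts heterozygous at copy one per haplotype.
    """
    rng = rng_from(config.seed)
    frames = []
    hapW, hapY = config.haplotypes
    for chrom, length in config.chromosome_lengths.items():
        n = max(1, length // config.snp_spacing)
        grid = (np.arange(n) + 0.5) * config.snp_spacing
        jitter = rng.integers(-config.snp_spacing // 4, config.snp_spacing // 4 + 1, size=n)
        pos = np.clip(np.round(grid).astype(np.int64) + jitter, 1, length)
        pos = np.unique(pos)
        idx = rng.integers(0, 4, size=len(pos))
        allele_w = BASES[idx]
        allele_y = BASES[(idx + rng.integers(1, 4, size=len(pos))) % 4]
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "pos": pos,
            f"allele_{hapW}": allele_w,
            f"allele_{hapY}": allele_y,
            f"n_{hapW}": np.ones(len(pos), dtype=np.int64),
            f"n_{hapY}": np.ones(len(pos), dtype=np.int64),
        }))
    snps = pd.concat(frames, ignore_index=True)
    snps["chrom"] = pd.Categorical(snps["chrom"], categories=config.chromosomes, ordered=True)
    rdna = dict(config.rdna.repeats) if config.rdna is not None else {}
    return DiploidGenome(config=config, snps=snps, rdna_repeats=rdna)


def chromosome_sequence(config: HybridGenomeConfig, chrom: str) -> str:
    """Deterministic random sequence for one chromosome at the configured G+C.

    Derived from the config seed and the chromosome index, so repeated
    calls (and both haplotypes, which share the backbone apart from the
    SNP alleles) agree.
    """
    if chrom not in config.chromosome_lengths:
        raise ConfigurationError(f"unknown chromosome {chrom!r}")
    idx = config.chromosomes.index(chrom)
    rng = np.random.default_rng([config.seed, idx])
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    draw = rng.choice(4, size=config.chromosome_lengths[chrom], p=probs)
    return "".join(BASES[draw])


def random_element_annotation(config: HybridGenomeConfig,
                              classes=ELEMENT_CLASSES,
                              per_class_per_mb: float = 3.0,
                              mean_length: int = 3000,
                              seed=None) -> pd.DataFrame:
    """Scatter element intervals over the genome (1-based inclusive).

    Returns a DataFrame with columns chrom, start, end, cls.  Interval
    lengths are exponential around ``mean_length``; counts per class are
    proportional to chromosome length.  Used to exercise the enrichment
    and translocation machinery when no real annotation is supplied.
    """
    rng = rng_from(config.seed if seed is None else seed)
    rows = []
    for cls in classes:
        for chrom, length in config.chromosome_lengths.items():
            n = rng.poisson(per_class_per_mb * length / 1e6)
            for _ in range(n):
                ln = max(50, int(rng.exponential(mean_length)))
                start = int(rng.integers(1, max(2, length - ln)))
                rows.append((chrom, start, min(start + ln - 1, length), cls))
    ann = pd.DataFrame(rows, columns=["chrom", "start", "end", "cls"])
    return ann.sort_values(["cls", "chrom", "start"], ignore_index=True)


def validate_annotation(ann: pd.DataFrame, config: HybridGenomeConfig) -> None:
    """Raise :class:`ConfigurationError` if any interval exceeds its chromosome."""
    for chrom, grp in ann.groupby("chrom", observed=True):
        if chrom not in config.chromosome_lengths:
            raise ConfigurationError(f"annotation references unknown chromosome {chrom!r}")
        length = config.chromosome_lengths[chrom]
        bad = grp[(grp["start"] < 1) | (grp["end"] > length) | (grp["start"] > grp["end"])]
        if len(bad):
            raise ConfigurationError(f"{len(bad)} annotation interval(s) out of bounds on {chrom}")
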