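"""Synthetic inputs with the statistical structure the pipeline assumes.

Generates a 10-chromosome maize-like genetic map, founder genomes
differing at InDel sites (with controllable length difference, flank GC,
tandem-repeat content and genotype quality), and backcross populations
descending from a donor x recurrent cross carrying a transgene locus on
chromosome 8 — so every other module is testable without downloads.

All randomness flows from one top-level seed through named child streams
(:class:`SimulationConfig.rng_for`), so module-level reproducibility
holds no matter the call order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from mabckit.breeding_sim import (
    DONOR,
    RECURRENT,
    DiploidIndividual,
    Haplotype,
    SchemeConfig,
    backcross,
    make_founder,
)
from mabckit.genmap import Chromosome, GeneticMap
from mabckit.marker_design import IndelSite, gc_content, has_repeat

__all__ = [
    "DEFAULT_CHROM_LENGTHS_CM",
    "FounderPair",
    "SiteSimConfig",
    "SimulationConfig",
    "make_maize_like_map",
    "simulate_candidate_sites",
    "make_founders",
    "make_f1",
    "simulate_backcross_population",
]

#: Default maize-like genetic lengths (cM), chr1..chr10, total 2100 cM.
#: Chosen so a 20 cM grid yields a panel in the ~105-marker regime.
DEFAULT_CHROM_LENGTHS_CM = (259, 239, 219, 219, 219, 199, 199, 189, 179, 179)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def make_maize_like_map(
    n_chrom: int = 10,
    lengths_cM: Sequence[float] | None = None,
    total_cM: float | None = None,
    bp_per_cM: float = 1000.0,
) -> GeneticMap:
    """A genetic map with maize-like geometry.

    With no arguments: 10 chromosomes, lengths
    :data:`DEFAULT_CHROM_LENGTHS_CM`, total 2100 cM. ``total_cM`` rescales
    the default profile; explicit ``lengths_cM`` wins. Each chromosome
    carries a physical length of ``bp_per_cM * length_cM`` for bp<->cM
    interpolation.
    """
    if n_chrom < 1:
        raise ValueError(f"n_chrom must be >= 1, got {n_chrom}")
    if lengths_cM is not None:
        lengths = [float(x) for x in lengths_cM]
        if len(lengths) != n_chrom:
            raise ValueError(
                f"{len(lengths)} lengths given for {n_chrom} chromosomes"
            )
    else:
        if n_chrom == 10:
            profile = list(DEFAULT_CHROM_LENGTHS_CM)
        else:
            # linearly decreasing profile, same flavour
            profile = [
                259.0 - (259.0 - 179.0) * i / max(n_chrom - 1, 1)
                for i in range(n_chrom)
            ]
        if total_cM is not None:
            scale = float(total_cM) / sum(profile)
            profile = [x * scale for x in profile]
        lengths = profile
    if any(x <= 0 for x in lengths):
        raise ValueError("chromosome lengths must be positive")
    return GeneticMap(
        [
            Chromosome(
                name=f"chr{i + 1}",
                length_cM=length,
                length_bp=int(round(length * bp_per_cM)),
            )
            for i, length in enumerate(lengths)
        ]
    )


@dataclass(frozen=True)
class SiteSimConfig:
    """Distributions for candidate-site simulation."""

    length_diff_range: tuple[int, int] = (1, 80)
    gc_target_range: tuple[float, float] = (0.40, 0.70)
    repeat_fraction: float = 0.2
    gq_range: tuple[int, int] = (10, 60)  # inclusive; straddles 30
    flank_len: int = 150
    #: probabilities of reference length-difference 0,1,2,3 bp
    ref_length_diff_probs: tuple[float, ...] = (0.45, 0.2, 0.15, 0.2)
    #: probabilities of reference mismatch count 0,1,2,3
    ref_mismatch_probs: tuple[float, ...] = (0.4, 0.25, 0.2, 0.15)

    def __post_init__(self) -> None:
        lo, hi = self.length_diff_range
        if not (0 <= lo <= hi):
            raise ValueError("bad length_diff_range")
        if not 0.0 <= self.repeat_fraction <= 1.0:
            raise ValueError("repeat_fraction must be in [0, 1]")


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p).tobytes().decode()


def _inject_tandem_repeat(
    seq: str, rng: np.random.Generator, max_motif: int = 6, span: int = 14
) -> str:
    k = int(rng.integers(1, max_motif + 1))
    copies = -(-span // k)  # ceil
    motif = _random_seq(rng, k)
    tract = motif * copies
    start = int(rng.integers(0, len(seq) - len(tract) + 1))
    return seq[:start] + tract + seq[start + len(tract):]


def simulate_candidate_sites(
    gmap: GeneticMap,
    n: int,
    rng: np.random.Generator | int,
    config: SiteSimConfig = SiteSimConfig(),
) -> list[IndelSite]:
    """Simulate ``n`` candidate InDel sites on a map.

    Sites get map positions (cM and, when the map carries physical
    lengths, interpolated bp), ref/alt alleles with the drawn length
    difference, a flank with controlled GC (tandem repeats injected in a
    configurable fraction, and guaranteed absent otherwise), GQ values
    straddling the quality threshold, and reference-divergence metadata.
    Deterministic for a given seed/generator state.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    lengths = np.array([c.length_cM for c in gmap.chromosomes])
    chrom_p = lengths / lengths.sum()
    names = gmap.names
    diff_lo, diff_hi = config.length_diff_range
    sites: list[IndelSite] = []
    for i in range(n):
        ci = int(rng.choice(len(names), p=chrom_p))
        chrom = names[ci]
        pos_cm = float(rng.uniform(0, lengths[ci]))
        pos_bp = (
            gmap.bp_from_cm(chrom, pos_cm)
            if gmap[chrom].length_bp is not None
            else i + 1
        )
        d = int(rng.integers(diff_lo, diff_hi + 1))
        anchor = _random_seq(rng, 1)
        inserted = _random_seq(rng, d)
        if rng.random() < 0.5:  # deletion in the alternate genome
            ref, alt = anchor + inserted, anchor
        else:
            ref, alt = anchor, anchor + inserted
        gc_target = float(rng.uniform(*config.gc_target_range))
        want_repeat = bool(rng.random() < config.repeat_fraction)
        for _ in range(40):
            flank = _random_seq(rng, config.flank_len, gc_target)
            if want_repeat:
                flank = _inject_tandem_repeat(flank, rng)
                break
            if not has_repeat(flank):
                break
        ref_diff = int(
            rng.choice(len(config.ref_length_diff_probs),
                       p=config.ref_length_diff_probs)
        )
        ref_mm = int(
            rng.choice(len(config.ref_mismatch_probs),
                       p=config.ref_mismatch_probs)
        )
        sites.append(
            IndelSite(
                chrom=chrom,
                pos_bp=pos_bp,
                ref_allele=ref,
                alt_allele=alt,
                gq=int(rng.integers(config.gq_range[0], config.gq_range[1] + 1)),
                pos_cM=pos_cm,
                name=f"site{i + 1}",
                flank_seq=flank,
                flank_gc=gc_content(flank),
                divergence_vs_reference=(ref_diff, ref_mm),
                has_repeat=want_repeat,
            )
        )
    return sites


@dataclass
class FounderPair:
    """Two founder genomes differing only at the variant sites, plus the
    donor-only transgene locus."""

    recurrent_genome: dict[str, str]
    donor_genome: dict[str, str]
    variant_sites: list[IndelSite]
    transgene_locus: tuple[str, float]
    #: B73-like reference the flanks diverge from (recurrent plus sparse
    #: substitutions' worth of distance)
    reference_genome: dict[str, str] | None = None


def make_founders(
    gmap: GeneticMap,
    n_sites: int,
    rng: np.random.Generator | int,
    transgene_chrom: str = "chr8",
    transgene_cM: float | None = None,
    substitution_rate: float = 2e-4,
    min_site_gap_bp: int = 400,
) -> FounderPair:
    """Build a reference genome, a recurrent parent (reference plus sparse
    substitutions) and a donor carrying insertions/deletions at simulated
    variant sites; record the sites as a VCF-ready table.

    The map must carry physical lengths. Variant positions are kept at
    least ``min_site_gap_bp`` apart so flank windows do not overlap.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if transgene_chrom not in gmap:
        raise KeyError(f"transgene chromosome {transgene_chrom!r} not on map")
    reference: dict[str, str] = {}
    recurrent: dict[str, str] = {}
    donor: dict[str, str] = {}
    sites: list[IndelSite] = []
    per_chrom = _apportion(gmap, n_sites)
    idx = 0
    for c in gmap.chromosomes:
        if c.length_bp is None:
            raise ValueError(f"chromosome {c.name} lacks a physical length")
        seq = _random_seq(rng, c.length_bp)
        reference[c.name] = seq
        # recurrent: sparse substitutions relative to the reference
        arr = np.frombuffer(seq.encode(), dtype="S1").copy()
        n_sub = rng.binomial(c.length_bp, substitution_rate)
        if n_sub:
            locs = rng.choice(c.length_bp, size=n_sub, replace=False)
            arr[locs] = rng.choice(_BASES, size=n_sub)
        rec_seq = arr.tobytes().decode()
        recurrent[c.name] = rec_seq
        # donor: indels at variant sites on this chromosome
        k = per_chrom[c.name]
        margin = 200
        lo, hi = margin, c.length_bp - margin
        if hi <= lo:
            raise ValueError(
                f"chromosome {c.name} too short ({c.length_bp} bp) for "
                "flank-safe variant placement; increase bp_per_cM"
            )
        # shrink the gap when the chromosome cannot host k sites at the
        # requested spacing
        gap = min(min_site_gap_bp, max((hi - lo) // max(2 * k, 1), 1))
        positions: list[int] = []
        attempts = 0
        while len(positions) < k:
            attempts += 1
            if attempts > 200 * max(k, 1):
                raise ValueError(
                    f"cannot place {k} variant sites on {c.name} "
                    f"({c.length_bp} bp) at >= {gap} bp spacing"
                )
            cand = int(rng.integers(lo, hi))
            if all(abs(cand - p) >= gap for p in positions):
                positions.append(cand)
        positions.sort()
        pieces: list[str] = []
        prev = 0
        for pos in positions:
            idx += 1
            d = int(rng.integers(1, 81))
            anchor = rec_seq[pos - 1]
            inserted = _random_seq(rng, d)
            if rng.random() < 0.5:
                # deletion in donor: recurrent carries the extra bases
                ref_allele = anchor + rec_seq[pos : pos + d]
                alt_allele = anchor
                pieces.append(rec_seq[prev : pos])
                prev = pos + d
            else:
                # insertion in donor
                ref_allele = anchor
                alt_allele = anchor + inserted
                pieces.append(rec_seq[prev : pos] + inserted)
                prev = pos
            sites.append(
                IndelSite(
                    chrom=c.name,
                    pos_bp=pos,
                    ref_allele=ref_allele,
                    alt_allele=alt_allele,
                    gq=int(rng.integers(10, 61)),
                    pos_cM=gmap.cm_from_bp(c.name, pos),
                    name=f"iv{idx}",
                )
            )
        pieces.append(rec_seq[prev:])
        donor[c.name] = "".join(pieces)
    locus_cm = (
        transgene_cM
        if transgene_cM is not None
        else gmap[transgene_chrom].length_cM / 2.0
    )
    return FounderPair(
        recurrent_genome=recurrent,
        donor_genome=donor,
        variant_sites=sites,
        transgene_locus=(transgene_chrom, locus_cm),
        reference_genome=reference,
    )


def _apportion(gmap: GeneticMap, n: int) -> dict[str, int]:
    total = gmap.total_length_cM
    out = {}
    assigned = 0
    for i, c in enumerate(gmap.chromosomes):
        if i == len(gmap.chromosomes) - 1:
            out[c.name] = n - assigned
        else:
            k = int(round(n * c.length_cM / total))
            out[c.name] = k
            assigned += k
    return out


def make_f1(gmap: GeneticMap, id: str = "F1") -> DiploidIndividual:
    """The donor x recurrent hybrid: one haplotype of each ancestry,
    hemizygous for the transgene."""
    return DiploidIndividual(
        hap1=Haplotype.uniform(gmap, RECURRENT),
        hap2=Haplotype.uniform(gmap, DONOR),
        id=id,
        generation="F1",
    )


def simulate_backcross_population(
    founders: FounderPair,
    gmap: GeneticMap,
    other_parent: DiploidIndividual,
    n_offspring: int,
    rng: np.random.Generator | int,
    require_carrier_parent: bool = True,
    generation: str = "BC",
) -> list[DiploidIndividual]:
    """Backcross ``other_parent`` to the recurrent parent.

    Each offspring combines a recombinant gamete from ``other_parent``
    with a pure recurrent gamete. With ``require_carrier_parent`` the
    parent must carry the transgene (so foreground carriers are possible
    in the offspring); a non-carrier parent is rejected.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if n_offspring < 1:
        raise ValueError("n_offspring must be >= 1")
    if require_carrier_parent and not other_parent.is_carrier(
        founders.transgene_locus
    ):
        raise ValueError(
            f"parent {other_parent.id!r} does not carry the transgene at "
            f"{founders.transgene_locus}; no foreground carriers possible"
        )
    recurrent = make_founder(gmap, RECURRENT, id="RP")
    return backcross(
        other_parent, recurrent, gmap, n_offspring, rng, generation
    )


@dataclass
class SimulationConfig:
    """Top-level configuration binding one seed to every stochastic stage."""

    seed: int = 0
    scheme: SchemeConfig = field(default_factory=SchemeConfig)
    sites: SiteSimConfig = field(default_factory=SiteSimConfig)
    n_candidate_sites: int = 2000
    panel_spacing_cM: float = 20.0

    def __post_init__(self) -> None:
        if self.n_candidate_sites < 0:
            raise ValueError("n_candidate_sites must be >= 0")
        if self.panel_spacing_cM <= 0:
            raise ValueError("panel_spacing_cM must be positive")

    def rng_for(self, label: str) -> np.random.Generator:
        """A named child stream: stable under the top-level seed and
        independent of the order streams are requested in."""
        key = zlib.crc32(label.encode())
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(key,))
        )
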