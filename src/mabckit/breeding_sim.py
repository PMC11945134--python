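"""Forward-in-time simulator of a marker-assisted backcross scheme.

Genomes are represented as ancestry-segment lists on a genetic map:
each haplotype tiles every chromosome's ``[0, length_cM]`` interval with
segments labelled recurrent (``"R"``) or donor (``"D"``). Meiosis draws
crossover counts Poisson with mean length/100 Morgans and uniform
crossover positions (Haldane model, no interference).

The transgene travels with donor ancestry at its map position: an
individual is a carrier on a haplotype iff that haplotype is
donor-derived at the locus.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from mabckit.genmap import GeneticMap
from mabckit.scoring import (
    DD,
    MISSING,
    RD,
    RR,
    HomozygosityVerdict,
    RecoveryReport,
    SegregationTest,
    chi_square_1to1,
    homozygosity_by_progeny,
    select_individuals,
)

logger = logging.getLogger(__name__)

RECURRENT = "R"
DONOR = "D"

#: (start_cM, end_cM, ancestry) — half-open [start, end)
Segment = tuple[float, float, str]


class Haplotype:
    """One gamete's ancestry mosaic: per chromosome, an ordered segment
    list tiling ``[0, length_cM]`` with no gaps or overlaps and adjacent
    segments of different ancestry."""

    __slots__ = ("segments",)

    def __init__(self, segments: dict[str, list[Segment]]) -> None:
        self.segments = segments

    @classmethod
    def uniform(cls, gmap: GeneticMap, ancestry: str) -> "Haplotype":
        if ancestry not in (RECURRENT, DONOR):
            raise ValueError(f"unknown ancestry {ancestry!r}")
        return cls(
            {c.name: [(0.0, c.length_cM, ancestry)] for c in gmap.chromosomes}
        )

    def validate(self, gmap: GeneticMap) -> None:
        """Raise if the tiling invariant is violated anywhere."""
        if set(self.segments) != set(gmap.names):
            raise ValueError("haplotype chromosomes do not match the map")
        for name, segs in self.segments.items():
            length = gmap[name].length_cM
            if not segs:
                raise ValueError(f"{name}: empty segment list")
            if segs[0][0] != 0.0 or abs(segs[-1][1] - length) > 1e-9:
                raise ValueError(f"{name}: segments do not span [0, {length}]")
            for (s0, e0, a0), (s1, e1, a1) in zip(segs, segs[1:]):
                if abs(e0 - s1) > 1e-9:
                    raise ValueError(f"{name}: gap/overlap at {e0} vs {s1}")
                if a0 == a1:
                    raise ValueError(f"{name}: unmerged adjacent segments")
            for s, e, a in segs:
                if e <= s:
                    raise ValueError(f"{name}: empty or inverted segment")
                if a not in (RECURRENT, DONOR):
                    raise ValueError(f"{name}: bad ancestry {a!r}")

    def ancestry_at(self, chrom: str, pos_cM: float) -> str:
        segs = self.segments[chrom]
        # rightmost segment whose start <= pos
        starts = [s for s, _, _ in segs]
        i = max(bisect_right(starts, pos_cM) - 1, 0)
        return segs[i][2]

    def donor_length_cM(self) -> float:
        return sum(
            e - s
            for segs in self.segments.values()
            for s, e, a in segs
            if a == DONOR
        )

    def total_length_cM(self) -> float:
        return sum(segs[-1][1] for segs in self.segments.values())


def _merge(segs: list[Segment]) -> list[Segment]:
    out: list[Segment] = []
    for seg in segs:
        if seg[1] - seg[0] <= 1e-12:
            continue
        if out and out[-1][2] == seg[2]:
            out[-1] = (out[-1][0], seg[1], seg[2])
        else:
            out.append(seg)
    return out


def _slice(segs: Sequence[Segment], start: float, end: float) -> list[Segment]:
    """Clip a segment list to [start, end)."""
    out = []
    for s, e, a in segs:
        if e <= start or s >= end:
            continue
        out.append((max(s, start), min(e, end), a))
    return out


@dataclass
class DiploidIndividual:
    """Two haplotypes per chromosome plus bookkeeping labels."""

    hap1: Haplotype
    hap2: Haplotype
    id: str = ""
    generation: str = ""

    def ancestries_at(self, chrom: str, pos_cM: float) -> tuple[str, str]:
        return (
            self.hap1.ancestry_at(chrom, pos_cM),
            self.hap2.ancestry_at(chrom, pos_cM),
        )

    def carrier_state(self, locus: tuple[str, float]) -> str:
        """``absent`` / ``hemizygous`` / ``homozygous`` from ancestry at
        the transgene locus."""
        chrom, pos = locus
        n = sum(a == DONOR for a in self.ancestries_at(chrom, pos))
        return ("absent", "hemizygous", "homozygous")[n]

    def is_carrier(self, locus: tuple[str, float]) -> bool:
        return self.carrier_state(locus) != "absent"

    def recurrent_fraction(self, gmap: GeneticMap) -> float:
        """True genome-wide recurrent-ancestry fraction (both haplotypes)."""
        total = 2.0 * gmap.total_length_cM
        donor = self.hap1.donor_length_cM() + self.hap2.donor_length_cM()
        return 1.0 - donor / total

    def validate(self, gmap: GeneticMap) -> None:
        self.hap1.validate(gmap)
        self.hap2.validate(gmap)


def make_founder(
    gmap: GeneticMap, ancestry: str, id: str = "", generation: str = "P"
) -> DiploidIndividual:
    """A fully homozygous founder of the given ancestry."""
    return DiploidIndividual(
        hap1=Haplotype.uniform(gmap, ancestry),
        hap2=Haplotype.uniform(gmap, ancestry),
        id=id,
        generation=generation,
    )


def cross(
    mother: DiploidIndividual,
    father: DiploidIndividual,
    gmap: GeneticMap,
    rng: np.random.Generator,
    id: str = "",
    generation: str = "",
) -> DiploidIndividual:
    return DiploidIndividual(
        hap1=meiosis(mother, gmap, rng),
        hap2=meiosis(father, gmap, rng),
        id=id,
        generation=generation,
    )


def meiosis(
    parent: DiploidIndividual, gmap: GeneticMap, rng: np.random.Generator
) -> Haplotype:
    """Draw one gamete from a parent.

    Per chromosome: crossover count ~ Poisson(length_cM / 100), crossover
    positions uniform on the chromosome, starting haplotype a fair coin;
    the gamete alternates between the two parental haplotypes at each
    crossover (no interference, no obligate chiasma).
    """
    gamete: dict[str, list[Segment]] = {}
    haps = (parent.hap1.segments, parent.hap2.segments)
    for c in gmap.chromosomes:
        length = c.length_cM
        n_xo = rng.poisson(length / 100.0)
        cuts = np.sort(rng.uniform(0.0, length, size=n_xo)) if n_xo else []
        current = int(rng.integers(2))
        segs: list[Segment] = []
        prev = 0.0
        for cut in [*cuts, length]:
            segs.extend(_slice(haps[current][c.name], prev, float(cut)))
            current ^= 1
            prev = float(cut)
        gamete[c.name] = _merge(segs)
        if not gamete[c.name]:  # zero-length chromosome cannot happen; guard
            gamete[c.name] = [(0.0, length, haps[current ^ 1][c.name][0][2])]
    return Haplotype(gamete)


def backcross(
    pop_parent: DiploidIndividual,
    recurrent: DiploidIndividual,
    gmap: GeneticMap,
    n: int,
    rng: np.random.Generator,
    generation: str = "BC",
    id_prefix: str | None = None,
) -> list[DiploidIndividual]:
    """Cross a (possibly heterozygous) parent to the recurrent parent.

    Each offspring combines a recombinant gamete from ``pop_parent`` with
    a gamete from the homozygous recurrent parent.
    """
    if n < 1:
        raise ValueError(f"population size must be >= 1, got {n}")
    prefix = id_prefix if id_prefix is not None else (pop_parent.id or generation)
    return [
        DiploidIndividual(
            hap1=meiosis(pop_parent, gmap, rng),
            hap2=meiosis(recurrent, gmap, rng),
            id=f"{prefix}-{i + 1}",
            generation=generation,
        )
        for i in range(n)
    ]


def self_cross(
    parent: DiploidIndividual,
    gmap: GeneticMap,
    n: int,
    rng: np.random.Generator,
    generation: str = "F2",
) -> list[DiploidIndividual]:
    """Self-pollinate: both gametes drawn from the same parent."""
    if n < 1:
        raise ValueError(f"population size must be >= 1, got {n}")
    return [
        DiploidIndividual(
            hap1=meiosis(parent, gmap, rng),
            hap2=meiosis(parent, gmap, rng),
            id=f"{parent.id}-{i + 1}",
            generation=generation,
        )
        for i in range(n)
    ]


def foreground_select(
    population: Sequence[DiploidIndividual],
    locus: tuple[str, float],
    rng: np.random.Generator | None = None,
    false_negative: float = 0.0,
    false_positive: float = 0.0,
) -> tuple[list[DiploidIndividual], SegregationTest]:
    """Split a population on transgene carrier state.

    Returns the retained (assay-positive) individuals and the 1:1
    segregation test on the positive:negative split. The carrier assay is
    error-free by default; optional false-negative/false-positive rates
    model assay noise.
    """
    if (false_negative or false_positive) and rng is None:
        raise ValueError("assay error rates need an rng")
    positives: list[DiploidIndividual] = []
    n_neg = 0
    for ind in population:
        carrier = ind.is_carrier(locus)
        if carrier and false_negative and rng.random() < false_negative:
            carrier = False
        elif not carrier and false_positive and rng.random() < false_positive:
            carrier = True
        if carrier:
            positives.append(ind)
        else:
            n_neg += 1
    return positives, chi_square_1to1(len(positives), n_neg)


def genotype_at_markers(
    individual: DiploidIndividual,
    positions: Sequence[tuple[str, float]],
    rng: np.random.Generator | None = None,
    missing_rate: float = 0.0,
) -> list[str]:
    """Genotype calls (RR/RD/DD) from ancestry at each marker position.

    ``positions`` is a list of ``(chromosome, cM)``; an optional
    missingness rate replaces calls by ``NA`` at random.
    """
    if missing_rate and rng is None:
        raise ValueError("missing_rate needs an rng")
    calls = []
    for chrom, pos in positions:
        if chrom not in individual.hap1.segments:
            raise KeyError(f"marker chromosome {chrom!r} not in genome")
        if missing_rate and rng.random() < missing_rate:
            calls.append(MISSING)
            continue
        a1, a2 = individual.ancestries_at(chrom, pos)
        n_donor = (a1 == DONOR) + (a2 == DONOR)
        calls.append((RR, RD, DD)[n_donor])
    return calls


def score_population(
    population: Sequence[DiploidIndividual],
    positions: Sequence[tuple[str, float]],
    rng: np.random.Generator | None = None,
    missing_rate: float = 0.0,
) -> list[RecoveryReport]:
    from mabckit.scoring import recovery_rate

    return [
        recovery_rate(
            genotype_at_markers(ind, positions, rng, missing_rate),
            individual=ind.id,
        )
        for ind in population
    ]


def marker_transmission_shortcut(
    parent_report: RecoveryReport,
    n_offspring: int,
    rng: np.random.Generator,
    id_prefix: str | None = None,
) -> list[RecoveryReport]:
    """Fast surrogate for one backcross: each heterozygous marker of the
    parent transmits the recurrent allele independently with probability
    1/2 (linkage ignored); RR markers stay RR.

    Only valid for parents without donor homozygotes (``dd = 0``).
    """
    if parent_report.dd > 0:
        raise ValueError(
            "marker_transmission_shortcut requires dd = 0 "
            f"(got dd={parent_report.dd} for {parent_report.individual})"
        )
    if n_offspring < 1:
        raise ValueError("n_offspring must be >= 1")
    prefix = id_prefix or parent_report.individual
    fixed = rng.binomial(parent_report.het, 0.5, size=n_offspring)
    return [
        RecoveryReport(
            individual=f"{prefix}-{i + 1}",
            I=parent_report.I,
            S=parent_report.S + int(k),
            het=parent_report.het - int(k),
            dd=0,
        )
        for i, k in enumerate(fixed)
    ]


# -- whole-scheme driver ----------------------------------------------------


@dataclass
class SchemeConfig:
    """Sizes, thresholds and panel geometry for the standard two-backcross
    scheme with two selfing generations."""

    n_bc1_seedlings: int = 224
    n_bc1_keep: int = 103
    bc1_min_rg: float = 80.0
    n_bc1_parents: int = 7
    bc2_family_sizes: tuple[int, ...] | None = (8, 12, 11, 9, 11, 8, 11)
    bc2_min_rg: float = 90.0
    n_bc2_picks: int = 2
    bc1_panel_size: int = 108
    bc2_panel_size: int = 87
    transgene_chrom: str = "chr8"
    transgene_cM: float | None = None  # None -> mid-chromosome
    missing_rate: float = 0.0
    n_self_progeny: int = 40
    n_progeny_test: int = 20
    assay_false_negative: float = 0.0
    assay_false_positive: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_bc1_seedlings", "n_bc1_keep", "n_bc1_parents",
                     "n_bc2_picks", "n_self_progeny", "n_progeny_test"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("bc1_min_rg", "bc2_min_rg"):
            v = getattr(self, name)
            if not 50.0 <= v <= 100.0:
                raise ValueError(f"{name} must be in [50, 100], got {v}")
        if self.bc2_family_sizes is not None and any(
            s < 1 for s in self.bc2_family_sizes
        ):
            raise ValueError("family sizes must be >= 1")


@dataclass
class GenerationSummary:
    label: str
    reports: list[RecoveryReport] = field(default_factory=list)
    selected: list[str] = field(default_factory=list)
    segregation: SegregationTest | None = None

    @property
    def mean_rg(self) -> float:
        return float(np.mean([r.rg for r in self.reports]))

    @property
    def sd_rg(self) -> float:
        return float(np.std([r.rg for r in self.reports], ddof=1))

    def summary_dict(self) -> dict:
        d: dict = {
            "label": self.label,
            "n_scored": len(self.reports),
            "selected": list(self.selected),
        }
        if self.reports:
            d["mean_rg"] = self.mean_rg
            if len(self.reports) > 1:
                d["sd_rg"] = self.sd_rg
        if self.segregation is not None:
            d["segregation"] = {
                "positive": self.segregation.n_positive,
                "negative": self.segregation.n_negative,
                "chi2": self.segregation.chi2,
                "passed_1to1": self.segregation.passed,
            }
        return d


@dataclass
class SchemeResult:
    generations: dict[str, GenerationSummary]
    homozygosity: dict[str, HomozygosityVerdict] = field(default_factory=dict)
    stopped_early: str | None = None

    def summary_dict(self) -> dict:
        return {
            "generations": {
                k: g.summary_dict() for k, g in self.generations.items()
            },
            "homozygosity": {
                k: {
                    "verdict": v.verdict,
                    "n_progeny": v.n_progeny,
                    "n_carriers": v.n_carriers,
                    "p_null": v.p_null,
                }
                for k, v in self.homozygosity.items()
            },
            "stopped_early": self.stopped_early,
        }


def collect_carriers(
    parent: DiploidIndividual,
    recurrent: DiploidIndividual,
    gmap: GeneticMap,
    locus: tuple[str, float],
    n_keep: int,
    rng: np.random.Generator,
    batch_size: int = 224,
    generation: str = "BC",
    false_negative: float = 0.0,
    false_positive: float = 0.0,
) -> tuple[list[DiploidIndividual], SegregationTest]:
    """Backcross, foreground-select, and keep ``n_keep`` carriers, sowing
    further batches if the first draw falls short (as a breeder would).

    The returned segregation test describes the first batch only."""
    pop = backcross(parent, recurrent, gmap, batch_size, rng, generation)
    carriers, seg = foreground_select(
        pop, locus, rng, false_negative, false_positive
    )
    while len(carriers) < n_keep:
        extra = backcross(
            parent, recurrent, gmap, batch_size, rng, generation,
            id_prefix=f"{parent.id or generation}x",
        )
        more, _ = foreground_select(
            extra, locus, rng, false_negative, false_positive
        )
        carriers.extend(more)
    return carriers[:n_keep], seg


def run_mabc_scheme(
    config: SchemeConfig,
    gmap: GeneticMap,
    rng: np.random.Generator,
    bc1_positions: Sequence[tuple[str, float]] | None = None,
    bc2_positions: Sequence[tuple[str, float]] | None = None,
    pick_policy: Callable[[list[RecoveryReport], int], list[str]] | None = None,
) -> SchemeResult:
    """Run the full scheme: F1 -> BC1 (foreground select, score, threshold,
    pick parents) -> BC2 (foreground select, score, threshold, pick) ->
    two selfing generations with progeny-based homozygosity testing.

    Marker panels default to evenly spaced positions of the configured
    sizes. ``pick_policy(reports, k)`` chooses among threshold survivors
    (default: top-k by Rg).
    """
    chrom = config.transgene_chrom
    if chrom not in gmap:
        raise KeyError(f"transgene chromosome {chrom!r} not on map")
    pos = (
        config.transgene_cM
        if config.transgene_cM is not None
        else gmap[chrom].length_cM / 2.0
    )
    locus = (chrom, pos)
    if bc1_positions is None:
        bc1_positions = gmap.evenly_spaced_positions(config.bc1_panel_size)
    if bc2_positions is None:
        bc2_positions = gmap.evenly_spaced_positions(config.bc2_panel_size)

    def pick(reports: list[RecoveryReport], k: int) -> list[str]:
        if pick_policy is not None:
            return pick_policy(reports, k)
        ranked = sorted(reports, key=lambda r: (-r.rg, r.individual))
        return [r.individual for r in ranked[:k]]

    recurrent = make_founder(gmap, RECURRENT, id="RP")
    donor = make_founder(gmap, DONOR, id="DP")
    f1 = cross(recurrent, donor, gmap, rng, id="F1", generation="F1")

    result = SchemeResult(generations={})

    # ---- BC1 ----
    bc1_carriers, seg1 = collect_carriers(
        f1, recurrent, gmap, locus, config.n_bc1_keep, rng,
        batch_size=config.n_bc1_seedlings, generation="BC1",
        false_negative=config.assay_false_negative,
        false_positive=config.assay_false_positive,
    )
    for i, ind in enumerate(bc1_carriers):
        ind.id = f"BC1-{i + 1}"
    bc1_reports = score_population(
        bc1_carriers, bc1_positions, rng, config.missing_rate
    )
    bc1_pass = select_individuals(bc1_reports, config.bc1_min_rg)
    gen1 = GenerationSummary("BC1", bc1_reports, segregation=seg1)
    result.generations["BC1"] = gen1
    if not bc1_pass:
        logger.warning("no BC1 individual exceeded Rg %.1f%%", config.bc1_min_rg)
        result.stopped_early = "BC1"
        return result
    parent_ids = pick(
        [r for r in bc1_reports if r.individual in set(bc1_pass)],
        config.n_bc1_parents,
    )
    gen1.selected = parent_ids
    by_id = {ind.id: ind for ind in bc1_carriers}
    bc1_parents = [by_id[i] for i in parent_ids]

    # ---- BC2 ----
    sizes = config.bc2_family_sizes
    if sizes is None or len(sizes) != len(bc1_parents):
        total = sum(sizes) if sizes else 70
        base, rem = divmod(total, len(bc1_parents))
        sizes = tuple(
            base + (1 if i < rem else 0) for i in range(len(bc1_parents))
        )
    bc2_carriers: list[DiploidIndividual] = []
    for parent, fam in zip(bc1_parents, sizes):
        fam_carriers, _ = collect_carriers(
            parent, recurrent, gmap, locus, fam, rng,
            batch_size=2 * fam + 8, generation="BC2",
            false_negative=config.assay_false_negative,
            false_positive=config.assay_false_positive,
        )
        for j, ind in enumerate(fam_carriers):
            ind.id = f"{parent.id}-{j + 1}"
        bc2_carriers.extend(fam_carriers)
    bc2_reports = score_population(
        bc2_carriers, bc2_positions, rng, config.missing_rate
    )
    bc2_pass = select_individuals(bc2_reports, config.bc2_min_rg)
    gen2 = GenerationSummary("BC2", bc2_reports)
    result.generations["BC2"] = gen2
    if not bc2_pass:
        logger.warning("no BC2 individual exceeded Rg %.1f%%", config.bc2_min_rg)
        result.stopped_early = "BC2"
        return result
    pick_ids = pick(
        [r for r in bc2_reports if r.individual in set(bc2_pass)],
        config.n_bc2_picks,
    )
    gen2.selected = pick_ids
    by_id = {ind.id: ind for ind in bc2_carriers}
    picks = [by_id[i] for i in pick_ids]

    # ---- selfing with homozygosity testing ----
    f2_reports: list[RecoveryReport] = []
    for parent in picks:
        f2 = self_cross(parent, gmap, config.n_self_progeny, rng, "BC2F2")
        survivors, _ = foreground_select(f2, locus, rng)
        f2_reports.extend(score_population(survivors, bc2_positions))
        for cand in survivors:
            f3 = self_cross(cand, gmap, config.n_progeny_test, rng, "BC2F3")
            verdict = homozygosity_by_progeny(
                [p.is_carrier(locus) for p in f3]
            )
            result.homozygosity[cand.id] = verdict
            if verdict.verdict == "homozygous":
                break  # one fixed line per pick is enough
    result.generations["BC2F2"] = GenerationSummary("BC2F2", f2_reports)
    return result
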