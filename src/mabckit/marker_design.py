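"""InDel candidate screening cascade and spaced marker-panel selection.

The cascade turns a table of two-parent length-variation sites into PCR-
ready markers by applying, in order: a genotype-quality filter, a length-
difference window, amplicon-scale flank extraction, tandem-repeat
exclusion, a flank G/C window, and a reference-divergence envelope.
Survivors are then thinned to an approximately evenly spaced panel on the
genetic map.

Every filter is a contraction (output is a subset of input, order
preserved) and the whole cascade is idempotent; each stage logs its
in/out counts so the audit trail of a real screening run is recoverable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from Bio import Align

from mabckit.genmap import GeneticMap

logger = logging.getLogger(__name__)

__all__ = [
    "IndelSite",
    "MarkerPanel",
    "ScreenConfig",
    "LowSpecificityError",
    "filter_gq",
    "filter_length_diff",
    "extract_flank",
    "gc_content",
    "filter_gc",
    "has_repeat",
    "divergence_class",
    "compute_divergence",
    "screen_candidates",
    "select_spaced_panel",
    "sites_from_variants",
]


@dataclass
class IndelSite:
    """One candidate length-variation site flowing through the cascade.

    ``pos_bp`` is 1-based (VCF convention); ``pos_cM`` is filled from the
    genetic map's bp->cM interpolation when available. Flank and
    divergence fields are populated by the cascade stages (or supplied
    up-front for pre-extracted tables).
    """

    chrom: str
    pos_bp: int
    ref_allele: str
    alt_allele: str
    gq: int | None = None
    pos_cM: float | None = None
    name: str = ""
    flank_seq: str | None = None
    flank_start_bp: int | None = None
    flank_end_bp: int | None = None
    flank_gc: float | None = None
    divergence_vs_reference: tuple[int, int] | None = None
    has_repeat: bool | None = None

    def __post_init__(self) -> None:
        if self.pos_bp < 1:
            raise ValueError(f"pos_bp must be >= 1, got {self.pos_bp}")

    @property
    def length_diff_bp(self) -> int:
        return abs(len(self.ref_allele) - len(self.alt_allele))


@dataclass
class MarkerPanel:
    markers: list[IndelSite]
    target_spacing_cM: float
    #: per-chromosome marker counts, in map order
    counts: dict[str, int] = field(default_factory=dict)
    #: (chrom, window-centre cM) positions where no candidate was found
    gaps: list[tuple[str, float]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.markers)

    def positions(self) -> list[tuple[str, float]]:
        return [(m.chrom, m.pos_cM) for m in self.markers]


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the screening cascade (all configurable; defaults
    follow the standard protocol)."""

    min_gq: int = 30
    length_diff_min: int = 30
    length_diff_max: int = 50
    flank_min_len: int = 120
    flank_max_len: int = 150
    gc_min: float = 0.55
    gc_max: float = 0.60
    repeat_max_motif: int = 6
    repeat_min_span: int = 12
    min_alignment_score_fraction: float = 0.5


class LowSpecificityError(ValueError):
    """No reference alignment reached the floor score."""


# -- individual filters -----------------------------------------------------


def filter_gq(
    sites: Sequence[IndelSite], min_gq: int = 30
) -> list[IndelSite]:
    """Keep sites with genotype quality strictly above ``min_gq``.

    Sites lacking a GQ value are dropped with a warning (conservative).
    """
    kept = []
    n_missing = 0
    for s in sites:
        if s.gq is None:
            n_missing += 1
            continue
        if s.gq > min_gq:
            kept.append(s)
    if n_missing:
        logger.warning("filter_gq: dropped %d sites with missing GQ", n_missing)
    logger.info("filter_gq: %d -> %d", len(sites), len(kept))
    return kept


def filter_length_diff(
    sites: Sequence[IndelSite], lo: int = 30, hi: int = 50
) -> list[IndelSite]:
    """Keep sites whose ref/alt length difference lies in the closed
    interval [lo, hi] bp."""
    kept = [s for s in sites if lo <= s.length_diff_bp <= hi]
    logger.info("filter_length_diff: %d -> %d", len(sites), len(kept))
    return kept


def extract_flank(
    site: IndelSite,
    genome: Mapping[str, str],
    min_len: int = 120,
    max_len: int = 150,
) -> IndelSite | None:
    """Extract an amplicon-scale window containing the site.

    The window is centred on the site and is ``max_len`` long when the
    chromosome permits, shrinking down to ``min_len`` near the ends; a
    site without ``min_len`` of centred sequence is rejected (returns
    None). The coordinates used are recorded on the returned copy
    (1-based, inclusive).
    """
    if site.chrom not in genome:
        logger.warning("extract_flank: %s not in genome", site.chrom)
        return None
    seq = genome[site.chrom]
    chrom_len = len(seq)
    for length in (max_len, min_len):
        half = length // 2
        start = site.pos_bp - half  # 1-based
        end = start + length - 1
        if start >= 1 and end <= chrom_len:
            return replace(
                site,
                flank_seq=seq[start - 1 : end].upper(),
                flank_start_bp=start,
                flank_end_bp=end,
                flank_gc=None,
            )
    logger.warning(
        "extract_flank: site %s:%d too close to chromosome end, dropped",
        site.chrom,
        site.pos_bp,
    )
    return None


def gc_content(seq: str) -> float:
    """Fraction of G/C bases; the sequence must be non-empty A/C/G/T."""
    if not seq:
        raise ValueError("cannot compute GC of an empty sequence")
    seq = seq.upper()
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT characters in sequence: {sorted(bad)}")
    return (seq.count("G") + seq.count("C")) / len(seq)


def filter_gc(
    sites: Sequence[IndelSite], lo: float = 0.55, hi: float = 0.60
) -> list[IndelSite]:
    """Keep sites whose flank GC lies in the closed interval [lo, hi].

    Flank GC is computed from ``flank_seq`` when not already set; sites
    whose flank contains ambiguous bases fail.
    """
    kept = []
    for s in sites:
        gc = s.flank_gc
        if gc is None:
            if s.flank_seq is None:
                logger.warning("filter_gc: site %s:%d has no flank, dropped",
                               s.chrom, s.pos_bp)
                continue
            try:
                gc = gc_content(s.flank_seq)
            except ValueError:
                logger.warning(
                    "filter_gc: ambiguous bases in flank of %s:%d, dropped",
                    s.chrom, s.pos_bp,
                )
                continue
            s.flank_gc = gc
        if lo <= gc <= hi:
            kept.append(s)
    logger.info("filter_gc: %d -> %d", len(sites), len(kept))
    return kept


def has_repeat(seq: str, max_motif: int = 6, min_span: int = 12) -> bool:
    """True when the sequence contains a tandem repeat: some motif of
    1..``max_motif`` bp repeated contiguously to span >= ``min_span`` bp.

    Detection uses the self-match run criterion: a maximal run of ``r``
    consecutive positions with ``seq[i] == seq[i+k]`` implies a region of
    period ``k`` spanning ``r + k`` bases.
    """
    n = len(seq)
    if not n:
        raise ValueError("empty sequence")
    seq = seq.upper()
    for k in range(1, max_motif + 1):
        run = 0
        for i in range(n - k):
            if seq[i] == seq[i + k]:
                run += 1
                if run + k >= min_span:
                    return True
            else:
                run = 0
    return False


def divergence_class(length_diff_vs_ref: int, mismatches_vs_ref: int) -> bool:
    """Reference-divergence envelope: pass iff (0 bp different, <=2
    mismatches) or (1 bp different, <=1 mismatch) or (2 bp different, 0
    mismatches)."""
    d, m = length_diff_vs_ref, mismatches_vs_ref
    if d < 0 or m < 0:
        raise ValueError("divergence counts must be non-negative")
    return (d == 0 and m <= 2) or (d == 1 and m <= 1) or (d == 2 and m == 0)


_aligner = Align.PairwiseAligner(
    mode="local",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-1,
    extend_gap_score=-1,
)

_MAX_COOPTIMAL = 32


def compute_divergence(
    flank: str,
    reference: str,
    min_score_fraction: float = 0.5,
) -> tuple[int, int]:
    """Best local alignment of a flank against a reference sequence,
    decomposed into (net length difference, mismatch count).

    Unit mismatch/indel costs; among co-optimal alignments the one with
    the fewest indel columns wins. Raises :class:`LowSpecificityError`
    when no alignment reaches ``min_score_fraction * len(flank)``.
    """
    if not flank:
        raise ValueError("empty flank")
    flank = flank.upper()
    reference = reference.upper()
    alignments = _aligner.align(reference, flank)
    if alignments.score < min_score_fraction * len(flank):
        raise LowSpecificityError(
            f"best alignment score {alignments.score:.0f} below floor "
            f"{min_score_fraction * len(flank):.0f}"
        )
    best: tuple[int, int, int] | None = None  # (indel_cols, length_diff, mm)
    for i, aln in enumerate(alignments):
        if i >= _MAX_COOPTIMAL:
            break
        t_blocks, q_blocks = aln.aligned
        mm = 0
        for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
            mm += sum(
                1
                for a, b in zip(reference[ts:te], flank[qs:qe])
                if a != b
            )
        ins = dels = 0
        for j in range(1, len(t_blocks)):
            dels += t_blocks[j][0] - t_blocks[j - 1][1]
            ins += q_blocks[j][0] - q_blocks[j - 1][1]
        cand = (ins + dels, abs(ins - dels), mm)
        if best is None or cand < best:
            best = cand
    assert best is not None
    return best[1], best[2]


# -- cascade and panel ------------------------------------------------------


def screen_candidates(
    sites: Sequence[IndelSite],
    genome: Mapping[str, str] | None = None,
    reference: Mapping[str, str] | None = None,
    config: ScreenConfig = ScreenConfig(),
) -> list[IndelSite]:
    """Apply the full screening cascade in order.

    ``genome`` (the amplified parent) supplies flank sequence; when None,
    sites must already carry ``flank_seq``. ``reference`` supplies the
    divergence comparison; when None, the stored
    ``divergence_vs_reference`` metadata is used (sites without it are
    dropped).
    """
    out = filter_gq(sites, config.min_gq)
    out = filter_length_diff(
        out, config.length_diff_min, config.length_diff_max
    )

    # flank extraction
    flanked: list[IndelSite] = []
    for s in out:
        if genome is not None and s.flank_seq is None:
            s2 = extract_flank(
                s, genome, config.flank_min_len, config.flank_max_len
            )
            if s2 is not None:
                flanked.append(s2)
        elif s.flank_seq is not None:
            flanked.append(s)
        else:
            logger.warning(
                "screen: site %s:%d has no flank and no genome given, dropped",
                s.chrom, s.pos_bp,
            )
    logger.info("extract_flank: %d -> %d", len(out), len(flanked))
    out = flanked

    # tandem-repeat exclusion
    kept = []
    for s in out:
        rep = has_repeat(
            s.flank_seq, config.repeat_max_motif, config.repeat_min_span
        )
        s.has_repeat = rep
        if not rep:
            kept.append(s)
    logger.info("repeat exclusion: %d -> %d", len(out), len(kept))
    out = kept

    out = filter_gc(out, config.gc_min, config.gc_max)

    # divergence envelope
    kept = []
    for s in out:
        div = s.divergence_vs_reference
        if reference is not None and s.chrom in reference:
            try:
                div = compute_divergence(
                    s.flank_seq,
                    _reference_window(s, reference),
                    config.min_alignment_score_fraction,
                )
            except LowSpecificityError:
                logger.warning(
                    "divergence: site %s:%d fails specificity floor, dropped",
                    s.chrom, s.pos_bp,
                )
                continue
            s.divergence_vs_reference = div
        if div is None:
            logger.warning(
                "divergence: site %s:%d has no reference metadata, dropped",
                s.chrom, s.pos_bp,
            )
            continue
        if divergence_class(*div):
            kept.append(s)
    logger.info("divergence envelope: %d -> %d", len(out), len(kept))
    return kept


def _reference_window(site: IndelSite, reference: Mapping[str, str]) -> str:
    """Reference slice around the site's flank window, padded so the best
    local alignment is not clipped by the window boundary."""
    seq = reference[site.chrom]
    pad = 50
    start = max((site.flank_start_bp or site.pos_bp) - 1 - pad, 0)
    end = min((site.flank_end_bp or site.pos_bp) + pad, len(seq))
    return seq[start:end]


def select_spaced_panel(
    sites: Sequence[IndelSite],
    gmap: GeneticMap,
    spacing_cM: float = 20.0,
    tolerance_cM: float | None = None,
) -> MarkerPanel:
    """Greedy left-to-right thinning to ~``spacing_cM`` intervals.

    Per chromosome: take the left-most candidate, then repeatedly the
    candidate nearest to (last selected + spacing) within +/- tolerance
    (default spacing/2). Windows with no candidate are recorded as gaps
    and skipped.
    """
    if tolerance_cM is None:
        tolerance_cM = spacing_cM / 2.0
    panel = MarkerPanel(markers=[], target_spacing_cM=spacing_cM)
    if not sites:
        logger.warning("select_spaced_panel: empty candidate set")
        return panel
    for s in sites:
        if s.pos_cM is None:
            raise ValueError(
                f"site {s.chrom}:{s.pos_bp} lacks pos_cM; interpolate first"
            )
        if s.chrom not in gmap:
            raise KeyError(f"site chromosome {s.chrom!r} not on map")
    by_chrom: dict[str, list[IndelSite]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom in gmap.names:
        cands = sorted(by_chrom.get(chrom, []), key=lambda s: s.pos_cM)
        if not cands:
            panel.gaps.append((chrom, gmap[chrom].length_cM / 2.0))
            logger.warning("panel: no candidates on %s", chrom)
            continue
        chosen = [cands[0]]
        target = cands[0].pos_cM + spacing_cM
        end = gmap[chrom].length_cM
        while target <= end + 1e-9:
            window = [
                c
                for c in cands
                if abs(c.pos_cM - target) <= tolerance_cM
                and c.pos_cM > chosen[-1].pos_cM
            ]
            if window:
                nxt = min(window, key=lambda c: abs(c.pos_cM - target))
                chosen.append(nxt)
                target = nxt.pos_cM + spacing_cM
            else:
                panel.gaps.append((chrom, target))
                target += spacing_cM
        panel.markers.extend(chosen)
        panel.counts[chrom] = len(chosen)
    order = {name: i for i, name in enumerate(gmap.names)}
    panel.markers.sort(key=lambda s: (order[s.chrom], s.pos_cM))
    logger.info(
        "panel: %d markers over %d chromosomes (%d gap windows)",
        len(panel.markers), len(panel.counts), len(panel.gaps),
    )
    return panel


def sites_from_variants(records, gmap: GeneticMap | None = None) -> list[IndelSite]:
    """Build candidate sites from parsed VCF records.

    The site GQ is the minimum across the (up to two) sample GQs; a
    record with any missing GQ yields ``gq=None``. cM positions are
    interpolated when a map with physical lengths is given.
    """
    sites = []
    for rec in records:
        gqs = [s.gq for s in rec.samples]
        gq = None if (not gqs or any(g is None for g in gqs)) else min(gqs)
        pos_cm = None
        if gmap is not None and rec.chrom in gmap:
            if gmap[rec.chrom].length_bp is not None:
                pos_cm = gmap.cm_from_bp(rec.chrom, rec.pos)
        sites.append(
            IndelSite(
                chrom=rec.chrom,
                pos_bp=rec.pos,
                ref_allele=rec.ref,
                alt_allele=rec.alt,
                gq=gq,
                pos_cM=pos_cm,
                name=rec.id if rec.id not in (None, ".") else "",
            )
        )
    return sites
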