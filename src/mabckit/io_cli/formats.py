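"""Minimal readers/writers for the formats the pipeline exchanges.

Only the VCF subset actually consumed is supported: CHROM/POS/ID/REF/ALT/
QUAL plus per-sample GT and GQ for up to two samples. Positions are
1-based in VCF/TSV and 0-based half-open in BED.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from mabckit.genmap import Chromosome, GeneticMap
from mabckit.marker_design import MarkerPanel
from mabckit.scoring import GenotypeMatrix, RecoveryReport

logger = logging.getLogger(__name__)

_VCF_HEADER = [
    "##fileformat=VCFv4.2",
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">',
]


@dataclass(frozen=True)
class SampleCall:
    gt: str | None = None
    gq: int | None = None


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    id: str
    ref: str
    alt: str
    qual: float | None
    samples: tuple[SampleCall, ...] = ()

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"VCF positions are 1-based, got {self.pos}")


class VcfParseError(ValueError):
    pass


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Parse a minimal VCF 4.x file.

    Records with symbolic or multi-allelic ALTs are skipped with a
    warning; malformed lines raise :class:`VcfParseError` with the line
    number.
    """
    path = Path(path)
    records: list[VariantRecord] = []
    saw_header = False
    n_samples = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                if lineno == 1 and not line.startswith("##fileformat=VCF"):
                    raise VcfParseError(
                        f"{path}:{lineno}: missing ##fileformat header"
                    )
                saw_header = True
                continue
            if line.startswith("#CHROM"):
                saw_header = True
                cols = line.split("\t")
                n_samples = max(len(cols) - 9, 0)
                continue
            if not saw_header:
                raise VcfParseError(f"{path}:{lineno}: no VCF header found")
            fields = line.split("\t")
            if len(fields) < 8:
                raise VcfParseError(
                    f"{path}:{lineno}: expected >= 8 columns, got {len(fields)}"
                )
            chrom, pos_s, rid, ref, alt, qual_s = fields[:6]
            if alt.startswith("<") or "," in alt or alt == "*":
                logger.warning(
                    "%s:%d: skipping symbolic/multi-allelic ALT %r",
                    path, lineno, alt,
                )
                continue
            try:
                pos = int(pos_s)
            except ValueError:
                raise VcfParseError(
                    f"{path}:{lineno}: bad POS {pos_s!r}"
                ) from None
            qual = None if qual_s in (".", "") else float(qual_s)
            samples: list[SampleCall] = []
            if len(fields) > 9:
                fmt = fields[8].split(":")
                gt_i = fmt.index("GT") if "GT" in fmt else None
                gq_i = fmt.index("GQ") if "GQ" in fmt else None
                for sample_field in fields[9:]:
                    parts = sample_field.split(":")
                    gt = (
                        parts[gt_i]
                        if gt_i is not None and gt_i < len(parts)
                        else None
                    )
                    gq: int | None = None
                    if gq_i is not None and gq_i < len(parts):
                        raw = parts[gq_i]
                        if raw not in (".", ""):
                            try:
                                gq = int(raw)
                            except ValueError:
                                raise VcfParseError(
                                    f"{path}:{lineno}: bad GQ {raw!r}"
                                ) from None
                    samples.append(SampleCall(gt=gt, gq=gq))
            records.append(
                VariantRecord(
                    chrom=chrom,
                    pos=pos,
                    id=rid,
                    ref=ref,
                    alt=alt,
                    qual=qual,
                    samples=tuple(samples),
                )
            )
    return records


def write_vcf(
    records: Iterable[VariantRecord],
    path: str | Path,
    sample_names: Sequence[str] = (),
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for line in _VCF_HEADER:
            fh.write(line + "\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if sample_names:
            cols += ["FORMAT", *sample_names]
        fh.write("\t".join(cols) + "\n")
        for rec in records:
            qual = "." if rec.qual is None else f"{rec.qual:g}"
            row = [
                rec.chrom, str(rec.pos), rec.id or ".", rec.ref, rec.alt,
                qual, ".", ".",
            ]
            if sample_names:
                row.append("GT:GQ")
                for s in rec.samples:
                    gt = s.gt if s.gt is not None else "./."
                    gq = "." if s.gq is None else str(s.gq)
                    row.append(f"{gt}:{gq}")
            fh.write("\t".join(row) + "\n")


# -- FASTA ------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA into an id -> sequence dict (uppercased; duplicate ids are an
    error)."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        s = str(rec.seq)
        if not s.isupper():
            logger.info("%s: normalising %r to upper case", path, rec.id)
            s = s.upper()
        seqs[rec.id] = s
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq.upper()), id=name, description="")
        for name, seq in seqs.items()
    ]
    with Path(path).open("w") as fh:
        SeqIO.write(records, fh, "fasta")
    del width  # SeqIO wraps at 60; parameter kept for API stability


# -- genetic map TSV --------------------------------------------------------


def read_map_tsv(path: str | Path) -> GeneticMap:
    """TSV with columns ``chrom``, ``length_cM`` and optionally
    ``length_bp`` and ``markers_cM`` (comma-separated positions)."""
    chroms = []
    with Path(path).open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            markers = ()
            if row.get("markers_cM"):
                markers = tuple(
                    float(x) for x in row["markers_cM"].split(",") if x
                )
            chroms.append(
                Chromosome(
                    name=row["chrom"],
                    length_cM=float(row["length_cM"]),
                    length_bp=(
                        int(row["length_bp"]) if row.get("length_bp") else None
                    ),
                    marker_positions_cM=markers,
                )
            )
    return GeneticMap(chroms)


def write_map_tsv(gmap: GeneticMap, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["chrom", "length_cM", "length_bp", "markers_cM"])
        for c in gmap.chromosomes:
            w.writerow(
                [
                    c.name,
                    f"{c.length_cM:g}",
                    "" if c.length_bp is None else c.length_bp,
                    ",".join(f"{x:g}" for x in c.marker_positions_cM),
                ]
            )


# -- genotype matrices ------------------------------------------------------


def read_genotype_csv(path: str | Path) -> GenotypeMatrix:
    """CSV with individuals as rows (first column = id) and markers as
    columns; cells RR/RD/DD/NA."""
    import pandas as pd

    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    return GenotypeMatrix.from_dataframe(df)


def write_genotype_csv(matrix: GenotypeMatrix, path: str | Path) -> None:
    matrix.to_dataframe().to_csv(path, index_label="individual")


# -- reports / panels -------------------------------------------------------


def write_reports_tsv(
    reports: Sequence[RecoveryReport], path: str | Path
) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["individual", "I", "S", "het", "dd", "Rg_pct"])
        for r in reports:
            w.writerow([r.individual, r.I, r.S, r.het, r.dd, f"{r.rg:.2f}"])


def write_panel_tsv(panel: MarkerPanel, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(
            ["marker", "chrom", "pos_bp", "pos_cM", "length_diff_bp",
             "flank_gc", "flank_seq"]
        )
        for i, m in enumerate(panel.markers, start=1):
            w.writerow(
                [
                    m.name or f"M{i:03d}",
                    m.chrom,
                    m.pos_bp,
                    "" if m.pos_cM is None else f"{m.pos_cM:.3f}",
                    m.length_diff_bp,
                    "" if m.flank_gc is None else f"{m.flank_gc:.4f}",
                    m.flank_seq or "",
                ]
            )


def write_panel_bed(panel: MarkerPanel, path: str | Path) -> None:
    """Flank windows as BED (0-based half-open)."""
    with Path(path).open("w", newline="") as fh:
        for i, m in enumerate(panel.markers, start=1):
            if m.flank_start_bp is None or m.flank_end_bp is None:
                continue
            fh.write(
                f"{m.chrom}\t{m.flank_start_bp - 1}\t{m.flank_end_bp}\t"
                f"{m.name or f'M{i:03d}'}\n"
            )
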