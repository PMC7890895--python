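"""Readers and writers for the tabular formats used across the pipeline.

Formats handled here:

* BED3+ — tab-separated, 0-based half-open; extra columns kept as strings.
* Repeat table — 7-column TSV with header
  ``#seq start end strand class subgroup pct_div`` (a simplified dialect of
  the RepeatMasker ``.out`` table).
* Alignment map — 8-column TSV of gapless pairwise blocks with header
  ``#species_a seq_a start_a end_a species_b seq_b start_b end_b``.
* Divergence table — 3-column TSV ``#species_a species_b divergence_mya``.

All writers emit LF line endings and no trailing whitespace. Inputs with
1-based inclusive coordinates can be declared via ``dialect="one-based"``
and are converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .intervals import GenomicInterval

__all__ = [
    "PeakCall",
    "RepeatElement",
    "AlignmentBlock",
    "BedRecord",
    "read_bed",
    "write_bed",
    "read_repeat_table",
    "write_repeat_table",
    "read_alignment_map",
    "write_alignment_map",
    "read_divergence_table",
    "write_divergence_table",
]

RECOGNIZED_MARKS = ("H3K4me3", "H3K27ac", "H3K4me1")
MOBILE_CLASSES = ("DNA", "LINE", "SINE", "LTR")


@dataclass(frozen=True)
class PeakCall:
    """A single replicate's histone-mark enrichment call."""

    interval: GenomicInterval
    mark: str
    species: str
    tissue: str
    replicate_id: str
    q_value: float = 0.0
    fold_change: float = 1.0

    def __post_init__(self) -> None:
        if self.mark not in RECOGNIZED_MARKS:
            raise ValueError(f"unrecognized histone mark {self.mark!r}")


@dataclass(frozen=True)
class RepeatElement:
    """One RepeatMasker-style repeat annotation."""

    interval: GenomicInterval
    repeat_class: str  # DNA / LINE / SINE / LTR / other
    subgroup: str  # e.g. L1, L2, Alu, CR1
    pct_divergence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_divergence <= 100.0:
            raise ValueError(f"pct_divergence {self.pct_divergence} outside [0, 100]")
        if self.repeat_class in MOBILE_CLASSES and not self.subgroup:
            raise ValueError(f"empty subgroup for class {self.repeat_class}")


@dataclass(frozen=True)
class AlignmentBlock:
    """A gapless collinear block pairing an interval in two genomes.

    Alignment gaps are represented as block boundaries, so the two sides
    always have equal length.
    """

    interval_a: GenomicInterval
    interval_b: GenomicInterval
    species_a: str
    species_b: str

    def __post_init__(self) -> None:
        if self.interval_a.length() != self.interval_b.length():
            raise ValueError(
                f"alignment block sides differ in length: "
                f"{self.interval_a} vs {self.interval_b}"
            )


@dataclass(frozen=True)
class BedRecord:
    interval: GenomicInterval
    name: str = "."
    score: str = "0"
    extra: tuple[str, ...] = ()


def _open_lines(path: str | Path) -> list[str]:
    return Path(path).read_text().splitlines()


def read_bed(path: str | Path, dialect: str = "zero-based") -> list[BedRecord]:
    """Parse a BED3+ file, preserving input order and extra columns.

    ``dialect="one-based"`` converts 1-based inclusive coordinates to the
    internal 0-based half-open convention.
    """
    if dialect not in ("zero-based", "one-based"):
        raise ValueError(f"unknown BED dialect {dialect!r}")
    records: list[BedRecord] = []
    for lineno, line in enumerate(_open_lines(path), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
        if dialect == "one-based":
            start -= 1
        if end <= start:
            raise ValueError(f"{path}:{lineno}: end must exceed start ({start} >= {end})")
        strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
        records.append(
            BedRecord(
                interval=GenomicInterval(fields[0], start, end, strand),
                name=fields[3] if len(fields) > 3 else ".",
                score=fields[4] if len(fields) > 4 else "0",
                extra=tuple(fields[6:]),
            )
        )
    return records


def write_bed(records: Iterable[BedRecord | GenomicInterval], path: str | Path) -> None:
    lines = []
    for rec in records:
        if isinstance(rec, GenomicInterval):
            rec = BedRecord(rec)
        iv = rec.interval
        fields = [iv.seq_id, str(iv.start), str(iv.end)]
        if rec.name != "." or rec.score != "0" or rec.extra or iv.strand != ".":
            fields += [rec.name, rec.score, iv.strand if iv.strand != "." else "."]
            fields += list(rec.extra)
        lines.append("\t".join(fields))
    Path(path).write_text("".join(line + "\n" for line in lines))


_REPEAT_HEADER = "#seq\tstart\tend\tstrand\tclass\tsubgroup\tpct_div"


def read_repeat_table(path: str | Path) -> list[RepeatElement]:
    """Parse the simplified repeat-annotation TSV.

    Classes outside {DNA, LINE, SINE, LTR} (e.g. ``Simple_repeat``) map to
    ``other`` so downstream grouping only sees the four mobile-element
    classes plus a catch-all.
    """
    out: list[RepeatElement] = []
    for lineno, line in enumerate(_open_lines(path), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 7:
            raise ValueError(f"{path}:{lineno}: expected 7 columns, got {len(fields)}")
        seq_id, start, end, strand, cls, subgroup, pct = fields
        pct_div = float(pct)
        if not 0.0 <= pct_div <= 100.0:
            raise ValueError(f"{path}:{lineno}: pct_div {pct_div} outside [0, 100]")
        if cls not in MOBILE_CLASSES:
            cls = "other"
        out.append(
            RepeatElement(
                interval=GenomicInterval(seq_id, int(start), int(end), strand),
                repeat_class=cls,
                subgroup=subgroup,
                pct_divergence=pct_div,
            )
        )
    return out


def write_repeat_table(elements: Iterable[RepeatElement], path: str | Path) -> None:
    lines = [_REPEAT_HEADER]
    for el in elements:
        iv = el.interval
        lines.append(
            "\t".join(
                [
                    iv.seq_id,
                    str(iv.start),
                    str(iv.end),
                    iv.strand if iv.strand != "." else "+",
                    el.repeat_class,
                    el.subgroup,
                    f"{el.pct_divergence:g}",
                ]
            )
        )
    Path(path).write_text("".join(line + "\n" for line in lines))


_MAP_HEADER = "#species_a\tseq_a\tstart_a\tend_a\tspecies_b\tseq_b\tstart_b\tend_b"


def read_alignment_map(path: str | Path) -> list[AlignmentBlock]:
    """Parse a pairwise alignment-map TSV of gapless blocks."""
    blocks: list[AlignmentBlock] = []
    for lineno, line in enumerate(_open_lines(path), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 8:
            raise ValueError(f"{path}:{lineno}: expected 8 columns, got {len(fields)}")
        sp_a, seq_a, sa, ea, sp_b, seq_b, sb, eb = fields
        iv_a = GenomicInterval(seq_a, int(sa), int(ea))
        iv_b = GenomicInterval(seq_b, int(sb), int(eb))
        if iv_a.length() != iv_b.length():
            raise ValueError(
                f"{path}:{lineno}: block sides differ in length "
                f"({iv_a.length()} vs {iv_b.length()})"
            )
        blocks.append(AlignmentBlock(iv_a, iv_b, sp_a, sp_b))
    return blocks


def write_alignment_map(blocks: Iterable[AlignmentBlock], path: str | Path) -> None:
    lines = [_MAP_HEADER]
    for b in blocks:
        lines.append(
            "\t".join(
                [
                    b.species_a,
                    b.interval_a.seq_id,
                    str(b.interval_a.start),
                    str(b.interval_a.end),
                    b.species_b,
                    b.interval_b.seq_id,
                    str(b.interval_b.start),
                    str(b.interval_b.end),
                ]
            )
        )
    Path(path).write_text("".join(line + "\n" for line in lines))


def read_divergence_table(path: str | Path) -> dict[frozenset[str], float]:
    """Read pairwise divergence times (million years) keyed by species pair."""
    out: dict[frozenset[str], float] = {}
    for lineno, line in enumerate(_open_lines(path), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 columns")
        out[frozenset((fields[0], fields[1]))] = float(fields[2])
    return out


def write_divergence_table(times: dict[frozenset[str], float], path: str | Path) -> None:
    lines = ["#species_a\tspecies_b\tdivergence_mya"]
    for pair, mya in sorted(times.items(), key=lambda kv: sorted(kv[0])):
        a, b = sorted(pair)
        lines.append(f"{a}\t{b}\t{mya:g}")
    Path(path).write_text("".join(line + "\n" for line in lines))
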