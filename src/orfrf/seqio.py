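"""Reading and writing the formats the tool touches: FASTA, GFF3, tabular CDS lists.

Conventions
-----------
* Coordinates are 1-based inclusive everywhere (the GFF3 convention).
* Sequences are uppercased on ingest and restricted to ``{A,C,G,T,N}``;
  IUPAC ambiguity codes other than N (R, Y, S, W, K, M, B, D, H, V) are
  mapped to N with a logged warning — metagenomic assemblies contain them,
  and the downstream feature code is strict about its 5-letter alphabet.
* A record's ``id`` is the first whitespace-delimited token of its header;
  everything after it is the ``description``.
"""

from __future__ import annotations

import logging
from bisect import insort
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .errors import AnnotationError, FastaFormatError

logger = logging.getLogger(__name__)

_CANONICAL = set("ACGTN")
_AMBIGUOUS = set("RYSWKMBDHV")
# str.translate table: lowercase -> uppercase, ambiguity codes -> N
_NORMALIZE = str.maketrans(
    "acgtnryswkmbdhvRYSWKMBDHV",
    "ACGTN" + "N" * 20,
)


@dataclass(frozen=True)
class SeqRecord:
    """One named DNA sequence (contig, read or genome)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaFormatError("record id must be non-empty")
        if not self.seq:
            raise FastaFormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - _CANONICAL
        if bad:
            raise FastaFormatError(
                f"record {self.id!r}: invalid symbols {sorted(bad)} "
                "(normalize with seqio.normalize_seq or read via read_fasta)"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class CdsInterval:
    """A CDS location: 1-based inclusive [start, end] on one strand."""

    seqid: str
    start: int
    end: int
    strand: Literal["+", "-"]

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise AnnotationError(
                f"invalid interval {self.seqid}:{self.start}-{self.end} "
                "(need 1 <= start <= end)"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"unknown strand symbol {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeAnnotation:
    """Per-seqid sorted lists of CDS intervals."""

    _by_seqid: dict[str, list[CdsInterval]] = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, intervals: Iterable[CdsInterval]) -> "GenomeAnnotation":
        ann = cls()
        for iv in intervals:
            ann.add(iv)
        return ann

    def add(self, interval: CdsInterval) -> None:
        insort(self._by_seqid.setdefault(interval.seqid, []), interval)

    def add_seqid(self, seqid: str) -> None:
        """Register a sequence that may carry zero CDS."""
        self._by_seqid.setdefault(seqid, [])

    def seqids(self) -> list[str]:
        return sorted(self._by_seqid)

    def intervals(self, seqid: str) -> list[CdsInterval]:
        try:
            return self._by_seqid[seqid]
        except KeyError:
            raise AnnotationError(f"unknown seqid {seqid!r} in annotation") from None

    def __contains__(self, seqid: str) -> bool:
        return seqid in self._by_seqid

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_seqid.values())

    def validate_against(self, records: Iterable[SeqRecord]) -> None:
        """Check every seqid resolves to a record and intervals fit inside it."""
        lengths = {r.id: len(r.seq) for r in records}
        for seqid, ivs in self._by_seqid.items():
            if seqid not in lengths:
                raise AnnotationError(f"annotation seqid {seqid!r} missing from FASTA")
            for iv in ivs:
                if iv.end > lengths[seqid]:
                    raise AnnotationError(
                        f"interval {seqid}:{iv.start}-{iv.end} exceeds sequence "
                        f"length {lengths[seqid]}"
                    )


def normalize_seq(raw: str, *, context: str = "") -> str:
    """Uppercase, map non-N ambiguity codes to N, reject anything else."""
    seq = raw.translate(_NORMALIZE)
    bad = set(seq) - _CANONICAL
    if bad:
        raise FastaFormatError(
            f"{context}invalid sequence characters: {sorted(bad)}"
        )
    n_mapped = sum(1 for ch in raw if ch.upper() in _AMBIGUOUS)
    if n_mapped:
        logger.warning(
            "%smapped %d IUPAC ambiguity bases to N", context, n_mapped
        )
    return seq


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file into validated :class:`SeqRecord` objects.

    Multi-line bodies are concatenated; lowercase is uppercased; ambiguity
    codes other than N become N (logged). Duplicate ids are an error.
    """
    path = Path(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        first = fh.read(1)
        if first == "":
            raise FastaFormatError(f"{path}: empty file")
        if first != ">":
            raise FastaFormatError(f"{path}: not FASTA (must begin with '>')")
        fh.seek(0)
        for header, body in SimpleFastaParser(fh):
            tokens = header.split(None, 1)
            if not tokens:
                raise FastaFormatError(f"{path}: empty header line")
            rid = tokens[0]
            desc = tokens[1] if len(tokens) > 1 else ""
            if rid in seen:
                raise FastaFormatError(f"{path}: duplicate record id {rid!r}")
            seen.add(rid)
            seq = normalize_seq(body.replace(" ", ""), context=f"{path}:{rid}: ")
            if not seq:
                raise FastaFormatError(f"{path}: record {rid!r} has no sequence")
            records.append(SeqRecord(id=rid, seq=seq, description=desc))
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, wrap: int = 60) -> None:
    """Write records so that ``read_fasta`` reproduces them exactly."""
    if wrap < 1:
        raise ValueError("wrap must be >= 1")
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), wrap):
                fh.write(rec.seq[i : i + wrap] + "\n")


def read_annotations(
    path: str | Path, format: Literal["gff3", "tsv"] = "gff3"
) -> GenomeAnnotation:
    """Read CDS intervals from GFF3 (CDS-type rows only) or a 4-column TSV.

    The TSV dialect is header-less: ``seqid<TAB>start<TAB>end<TAB>strand``.
    Coordinates stay 1-based inclusive. Malformed rows raise with their
    line number.
    """
    path = Path(path)
    if format not in ("gff3", "tsv"):
        raise ValueError(f"unknown annotation format {format!r}")
    ann = GenomeAnnotation()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if format == "gff3":
                    if len(fields) < 8:
                        raise AnnotationError("expected >= 8 tab-separated columns")
                    seqid, _source, ftype, start, end, _score, strand = fields[:7]
                    if ftype != "CDS":
                        continue
                else:
                    if len(fields) != 4:
                        raise AnnotationError("expected 4 tab-separated columns")
                    seqid, start, end, strand = fields
                ann.add(CdsInterval(seqid, int(start), int(end), strand))  # type: ignore[arg-type]
            except (AnnotationError, ValueError) as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from None
    return ann


def write_gff3(ann: GenomeAnnotation, path: str | Path, source: str = "orfrf") -> None:
    """Write the annotation as GFF3 CDS rows (sorted, 1-based inclusive)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seqid in ann.seqids():
            for i, iv in enumerate(ann.intervals(seqid), start=1):
                fh.write(
                    f"{seqid}\t{source}\tCDS\t{iv.start}\t{iv.end}\t.\t{iv.strand}\t0\t"
                    f"ID=cds-{seqid}-{i}\n"
                )
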