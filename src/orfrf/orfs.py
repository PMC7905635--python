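"""ORF enumeration: every start-codon-to-nearest-in-frame-stop on both strands.

An ORF here is a stretch that begins with a configured start codon
(ATG by default; GTG/TTG optionally) and ends at the *nearest* downstream
in-frame stop codon (always TAA/TAG/TGA). Every such start is emitted, so
internal ORFs nested inside a longer one and sharing its stop are all
reported — they belong to the positive class during ground-truth labeling.

Coordinates are 1-based inclusive on the forward strand regardless of the
ORF's own strand; the ORF ``seq`` is given on its coding strand and
includes the stop codon. ORF windows containing N are dropped (counted),
as is any start codon with no in-frame stop before the sequence end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal

import numpy as np

from .seqio import SeqRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# base encoding A=0 C=1 G=2 T=3 N=4; codon id = 16a + 4b + c, or 64 if any N
_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _BASE_CODE[ord(_b)] = _i

STOP_CODONS = ("TAA", "TAG", "TGA")
START_CODON_CHOICES = ("ATG", "GTG", "TTG")


def _codon_id(codon: str) -> int:
    a, b, c = (int(_BASE_CODE[ord(ch)]) for ch in codon)
    return 16 * a + 4 * b + c


_STOP_IDS = np.array(sorted(_codon_id(c) for c in STOP_CODONS))


def reverse_complement(seq: str) -> str:
    """Watson-Crick complement, reversed; N maps to N."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class OrfConfig:
    """ORF enumeration settings.

    start_codons : subset of {ATG, GTG, TTG}; stops are always TAA/TAG/TGA.
    min_len_nt   : minimum ORF length in nt, stop codon included; must be a
                   positive multiple of 3 and at least 6.
    both_strands : scan the reverse complement too (metagenomic contigs are
                   unoriented; disable for single-strand labeling studies).
    """

    start_codons: tuple[str, ...] = ("ATG",)
    min_len_nt: int = 60
    both_strands: bool = True

    def __post_init__(self) -> None:
        codons = tuple(sorted({c.upper() for c in self.start_codons}))
        if not codons:
            raise ValueError("start_codons must be non-empty")
        bad = set(codons) - set(START_CODON_CHOICES)
        if bad:
            raise ValueError(
                f"unsupported start codons {sorted(bad)}; "
                f"choose from {START_CODON_CHOICES}"
            )
        object.__setattr__(self, "start_codons", codons)
        if self.min_len_nt < 6 or self.min_len_nt % 3:
            raise ValueError("min_len_nt must be >= 6 and a multiple of 3")

    def to_dict(self) -> dict:
        return {
            "start_codons": list(self.start_codons),
            "min_len_nt": self.min_len_nt,
            "both_strands": self.both_strands,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OrfConfig":
        return cls(
            start_codons=tuple(d["start_codons"]),
            min_len_nt=int(d["min_len_nt"]),
            both_strands=bool(d["both_strands"]),
        )


@dataclass(frozen=True)
class Orf:
    """A candidate coding interval on a source sequence.

    start/end are 1-based inclusive forward-strand coordinates; frame is
    1..3 relative to the ORF's own strand; seq is the coding-strand
    sequence including the stop codon.
    """

    source_id: str
    start: int
    end: int
    strand: Literal["+", "-"]
    frame: int
    seq: str = field(repr=False)

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.seq):
            raise ValueError("coordinate span does not match sequence length")
        if len(self.seq) % 3:
            raise ValueError("ORF length must be a multiple of 3")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def ref(self) -> tuple[str, int, int, str]:
        """Hashable reference (source_id, start, end, strand)."""
        return (self.source_id, self.start, self.end, self.strand)


@dataclass
class OrfScanStats:
    """Per-record enumeration counters."""

    n_dropped: int = 0  # ORF windows containing N
    unterminated: int = 0  # start codons with no downstream in-frame stop


def _scan_strand(
    codes: np.ndarray, start_ids: np.ndarray, stats: OrfScanStats
) -> list[tuple[int, int]]:
    """Yield (nt_start0, nt_end0_exclusive) pairs on one strand's encoding."""
    spans: list[tuple[int, int]] = []
    L = codes.shape[0]
    for f in range(3):
        m = (L - f) // 3
        if m < 2:
            continue
        tri = codes[f : f + 3 * m].reshape(m, 3).astype(np.int32)
        codons = np.where(
            (tri >= 4).any(axis=1),
            64,
            16 * tri[:, 0] + 4 * tri[:, 1] + tri[:, 2],
        )
        stop_pos = np.flatnonzero(np.isin(codons, _STOP_IDS))
        start_pos = np.flatnonzero(np.isin(codons, start_ids))
        if start_pos.size == 0:
            continue
        j = np.searchsorted(stop_pos, start_pos)
        terminated = j < stop_pos.size
        stats.unterminated += int((~terminated).sum())
        s = start_pos[terminated]
        e = stop_pos[j[terminated]]
        # drop windows containing N (codon id 64 anywhere in [s, e])
        ncum = np.concatenate(([0], np.cumsum(codons == 64)))
        has_n = (ncum[e + 1] - ncum[s]) > 0
        stats.n_dropped += int(has_n.sum())
        for si, ei in zip(s[~has_n], e[~has_n]):
            spans.append((f + 3 * si, f + 3 * ei + 3))
    return spans


def extract_orfs(
    record: SeqRecord,
    cfg: OrfConfig = OrfConfig(),
    stats: OrfScanStats | None = None,
) -> list[Orf]:
    """Enumerate every ORF of ``record`` under ``cfg``.

    Output is sorted by (start, end, strand); minus-strand ORFs carry
    forward-strand coordinates. An empty list is a valid result.
    """
    if stats is None:
        stats = OrfScanStats()
    start_ids = np.array(sorted(_codon_id(c) for c in cfg.start_codons))
    seq = record.seq
    L = len(seq)
    fwd = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    orfs: list[Orf] = []

    for s0, e0 in _scan_strand(fwd, start_ids, stats):
        if e0 - s0 < cfg.min_len_nt:
            continue
        orfs.append(
            Orf(record.id, s0 + 1, e0, "+", s0 % 3 + 1, seq[s0:e0])
        )

    if cfg.both_strands:
        rc = reverse_complement(seq)
        rcv = _BASE_CODE[np.frombuffer(rc.encode(), dtype=np.uint8)]
        for s0, e0 in _scan_strand(rcv, start_ids, stats):
            if e0 - s0 < cfg.min_len_nt:
                continue
            # rc coordinates [s0, e0) map to forward [L-e0+1, L-s0] 1-based
            orfs.append(
                Orf(record.id, L - e0 + 1, L - s0, "-", s0 % 3 + 1, rc[s0:e0])
            )

    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    if stats.n_dropped or stats.unterminated:
        logger.info(
            "%s: dropped %d ORF windows containing N, %d unterminated starts",
            record.id,
            stats.n_dropped,
            stats.unterminated,
        )
    return orfs


def extract_all(
    records: Iterable[SeqRecord], cfg: OrfConfig = OrfConfig()
) -> Iterator[Orf]:
    """ORFs of many records, record order preserved."""
    for rec in records:
        yield from extract_orfs(rec, cfg)


def longest_per_stop(orfs: Iterable[Orf]) -> list[Orf]:
    """Reporting helper: keep only the longest ORF per (stop, strand).

    The stop anchor is ``end`` on '+' and ``start`` on '-'.
    """
    best: dict[tuple[str, str, int], Orf] = {}
    for o in orfs:
        anchor = o.end if o.strand == "+" else o.start
        key = (o.source_id, o.strand, anchor)
        if key not in best or len(o) > len(best[key]):
            best[key] = o
    return sorted(best.values(), key=lambda o: (o.source_id, o.start, o.end, o.strand))
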