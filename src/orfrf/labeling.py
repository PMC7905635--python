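"""Ground-truth labeling of extracted ORFs against CDS annotations.

Label rule
----------
* **coding** — the ORF is fully contained within an annotated CDS interval
  on the same strand *and in the same reading frame*. This captures
  annotated CDS and their internal ORFs: an in-frame ORF contained in a
  CDS necessarily shares its stop codon, which is what makes internal
  ORFs part of the positive class.
* **intergenic** — the ORF overlaps no CDS interval on either strand: it
  lies entirely between annotated genes.
* **discarded** — anything else: ORFs straddling a CDS boundary, lying
  antisense within a CDS, or contained same-strand but frame-shifted.
  These are neither internal ORFs nor "between genes"; they are ambiguous
  and excluded from training (counted).

Every input ORF falls in exactly one of the three bins.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import LabelingError
from .features import FEATURE_NAMES, GENETIC_CODE, FeatureVector, GeneticCode, featurize
from .orfs import Orf
from .seqio import GenomeAnnotation

logger = logging.getLogger(__name__)

Label = Literal["coding", "intergenic"]
LABELS: tuple[Label, ...] = ("coding", "intergenic")


@dataclass(frozen=True)
class LabeledInstance:
    """One training/test instance: features + class + ORF provenance."""

    features: FeatureVector
    label: Label
    orf_ref: tuple[str, int, int, str]

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise LabelingError(f"unknown label {self.label!r}")


@dataclass
class LabelCounts:
    coding: int = 0
    intergenic: int = 0
    discarded: int = 0


def classify_interval(
    seqid: str, start: int, end: int, strand: str, annotation: GenomeAnnotation
) -> Label | None:
    """Label one interval: 'coding', 'intergenic', or None (discard)."""
    intervals = annotation.intervals(seqid)  # raises on unknown seqid
    starts = [iv.start for iv in intervals]
    # candidates that could overlap [start, end] have iv.start <= end
    hi = bisect_right(starts, end)
    overlap = False
    for iv in intervals[:hi]:
        if iv.end < start:
            continue
        overlap = True
        if iv.strand == strand and iv.start <= start and end <= iv.end:
            in_frame = (
                (start - iv.start) % 3 == 0
                if strand == "+"
                else (iv.end - end) % 3 == 0
            )
            if in_frame:
                return "coding"
    return None if overlap else "intergenic"


def classify_orf(orf: Orf, annotation: GenomeAnnotation) -> Label | None:
    """Label one ORF against the CDS annotation of its source sequence."""
    return classify_interval(orf.source_id, orf.start, orf.end, orf.strand, annotation)


def assign_labels(
    orfs: Iterable[Orf],
    annotation: GenomeAnnotation,
    counts: LabelCounts | None = None,
) -> list[tuple[Orf, Label]]:
    """Label many ORFs; discarded ones are dropped (and counted)."""
    if counts is None:
        counts = LabelCounts()
    out: list[tuple[Orf, Label]] = []
    for orf in orfs:
        label = classify_orf(orf, annotation)
        if label is None:
            counts.discarded += 1
        else:
            setattr(counts, label, getattr(counts, label) + 1)
            out.append((orf, label))
    logger.info(
        "labeled ORFs: %d coding, %d intergenic, %d discarded",
        counts.coding,
        counts.intergenic,
        counts.discarded,
    )
    return out


def label_orfs(
    orfs: Iterable[Orf],
    annotation: GenomeAnnotation,
    code: GeneticCode = GENETIC_CODE,
) -> list[LabeledInstance]:
    """Featurized labeled instances for all non-discarded ORFs."""
    return [
        LabeledInstance(featurize(orf, code), label, orf.ref)
        for orf, label in assign_labels(orfs, annotation)
    ]


def balance(
    instances: Sequence[LabeledInstance], seed: int
) -> list[LabeledInstance]:
    """Randomly undersample the majority class to the minority count.

    Deterministic in ``seed``; the returned order is a seeded shuffle.
    """
    rng = np.random.default_rng(seed)
    by_label = {lab: [i for i in instances if i.label == lab] for lab in LABELS}
    if any(not v for v in by_label.values()):
        raise LabelingError(
            "balance requires both classes present; got "
            + ", ".join(f"{lab}={len(v)}" for lab, v in by_label.items())
        )
    n = min(len(v) for v in by_label.values())
    kept: list[LabeledInstance] = []
    for lab in LABELS:
        pool = by_label[lab]
        idx = rng.choice(len(pool), size=n, replace=False)
        kept.extend(pool[i] for i in sorted(idx))
    order = rng.permutation(len(kept))
    return [kept[i] for i in order]


def build_dataset(
    orfs: Iterable[Orf],
    annotation: GenomeAnnotation,
    seed: int,
    max_per_class: int | None = None,
    code: GeneticCode = GENETIC_CODE,
) -> list[LabeledInstance]:
    """Extract -> label -> (cap) -> balance -> featurize, in one call.

    ``max_per_class`` caps each class with a seeded subsample *before*
    feature computation, which keeps large synthetic communities cheap; the
    distribution of retained instances is unchanged.
    """
    rng = np.random.default_rng(seed)
    labeled = assign_labels(orfs, annotation)
    by_label: dict[str, list[Orf]] = {lab: [] for lab in LABELS}
    for orf, lab in labeled:
        by_label[lab].append(orf)
    if any(not v for v in by_label.values()):
        raise LabelingError(
            "dataset needs both classes; got "
            + ", ".join(f"{lab}={len(v)}" for lab, v in by_label.items())
        )
    n = min(len(v) for v in by_label.values())
    if max_per_class is not None:
        n = min(n, max_per_class)
    instances: list[LabeledInstance] = []
    for lab in LABELS:
        pool = by_label[lab]
        idx = rng.choice(len(pool), size=n, replace=False)
        for i in sorted(idx):
            orf = pool[i]
            instances.append(LabeledInstance(featurize(orf, code), lab, orf.ref))
    order = rng.permutation(len(instances))
    return [instances[i] for i in order]


def to_frame(instances: Sequence[LabeledInstance]) -> pd.DataFrame:
    """Feature table with orf reference columns and a label column."""
    rows = []
    for inst in instances:
        row = dict(zip(FEATURE_NAMES, inst.features.as_array()))
        sid, start, end, strand = inst.orf_ref
        row.update(
            source_id=sid, start=start, end=end, strand=strand, label=inst.label
        )
        rows.append(row)
    cols = list(FEATURE_NAMES) + ["source_id", "start", "end", "strand", "label"]
    return pd.DataFrame(rows, columns=cols)


def write_tsv(instances: Sequence[LabeledInstance], path: str | Path) -> None:
    to_frame(instances).to_csv(path, sep="\t", index=False)
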