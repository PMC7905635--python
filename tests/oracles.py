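"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately naive (string walks, dictionary counting,
quadratic scans) and shares no code with the package paths it checks.
"""

from __future__ import annotations

import itertools
from statistics import mean

import numpy as np

STOPS = {"TAA", "TAG", "TGA"}
COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# Standard/bacterial genetic code synonymous families, written out by hand.
STANDARD_FAMILIES: dict[str, tuple[str, ...]] = {
    "F": ("TTT", "TTC"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),
    "I": ("ATT", "ATC", "ATA"),
    "M": ("ATG",),
    "V": ("GTT", "GTC", "GTA", "GTG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "P": ("CCT", "CCC", "CCA", "CCG"),
    "T": ("ACT", "ACC", "ACA", "ACG"),
    "A": ("GCT", "GCC", "GCA", "GCG"),
    "Y": ("TAT", "TAC"),
    "H": ("CAT", "CAC"),
    "Q": ("CAA", "CAG"),
    "N": ("AAT", "AAC"),
    "K": ("AAA", "AAG"),
    "D": ("GAT", "GAC"),
    "E": ("GAA", "GAG"),
    "C": ("TGT", "TGC"),
    "W": ("TGG",),
    "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "G": ("GGT", "GGC", "GGA", "GGG"),
}


def rc_oracle(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


def orf_oracle(
    seq: str,
    start_codons=("ATG",),
    min_len_nt: int = 60,
    both_strands: bool = True,
):
    """All (start, end, strand, frame, orf_seq) tuples by a plain string walk."""
    found = []

    def scan(s: str, strand: str):
        L = len(s)
        for f in range(3):
            for i in range(f, L - 2, 3):
                if s[i : i + 3] in start_codons:
                    j = i
                    while j <= L - 3:
                        if s[j : j + 3] in STOPS:
                            sub = s[i : j + 3]
                            if len(sub) >= min_len_nt and "N" not in sub:
                                if strand == "+":
                                    found.append((i + 1, j + 3, "+", f + 1, sub))
                                else:
                                    found.append(
                                        (L - (j + 3) + 1, L - i, "-", f + 1, sub)
                                    )
                            break
                        j += 3

    scan(seq, "+")
    if both_strands:
        scan(rc_oracle(seq), "-")
    return sorted(found, key=lambda t: (t[0], t[1], t[2]))


def gc_oracle(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def gc_pos_oracle(seq: str) -> tuple[float, float, float]:
    out = []
    for pos in range(3):
        bases = seq[pos::3]
        out.append((bases.count("G") + bases.count("C")) / len(bases))
    return tuple(out)


def kmer_freq_oracle(seq: str, k: int) -> dict[str, float]:
    counts: dict[str, int] = {}
    n = len(seq) - k + 1
    for i in range(n):
        counts[seq[i : i + k]] = counts.get(seq[i : i + k], 0) + 1
    return {kmer: c / n for kmer, c in counts.items()}


def kmer_variance_oracle(seq: str, k: int) -> float:
    freqs = kmer_freq_oracle(seq, k)
    vals = [
        freqs.get("".join(p), 0.0)
        for p in itertools.product("ACGT", repeat=k)
    ]
    m = sum(vals) / len(vals)
    return sum((v - m) ** 2 for v in vals) / (len(vals) - 1)


def c_weight_oracle(seq: str) -> float:
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    counts: dict[str, int] = {}
    for c in codons:
        counts[c] = counts.get(c, 0) + 1
    weights = []
    for fam in STANDARD_FAMILIES.values():
        if len(fam) < 2:
            continue
        observed = [c for c in fam if counts.get(c, 0) > 0]
        if not observed:
            continue
        mx = max(counts[c] for c in observed)
        weights.extend(counts[c] / mx for c in observed)
    return mean(weights) if weights else 1.0


def label_oracle(orf, intervals) -> str | None:
    """Quadratic all-pairs containment/overlap scan, frame-aware."""
    overlap = False
    for iv in intervals:
        if iv.seqid != orf.source_id:
            continue
        if iv.end < orf.start or orf.end < iv.start:
            continue
        overlap = True
        contained = iv.start <= orf.start and orf.end <= iv.end
        if contained and iv.strand == orf.strand:
            if orf.strand == "+" and (orf.start - iv.start) % 3 == 0:
                return "coding"
            if orf.strand == "-" and (iv.end - orf.end) % 3 == 0:
                return "coding"
    return None if overlap else "intergenic"


def auc_trapezoid(scores, labels, positive="coding") -> float:
    """Area under the empirical ROC curve by the trapezoidal rule."""
    scores = np.asarray(scores, dtype=float)
    y = np.array([t == positive for t in labels])
    order = np.argsort(-scores, kind="mergesort")
    y = y[order]
    s = scores[order]
    P, N = y.sum(), (~y).sum()
    tpr = [0.0]
    fpr = [0.0]
    tp = fp = 0
    i = 0
    n = len(y)
    while i < n:
        j = i
        while j < n and s[j] == s[i]:  # process score ties as one block
            tp += y[j]
            fp += not y[j]
            j += 1
        tpr.append(tp / P)
        fpr.append(fp / N)
        i = j
    return float(np.trapezoid(tpr, fpr))
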