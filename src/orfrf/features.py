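"""The 11-feature composition signature of an ORF.

The classifier separates coding from intergenic ORFs using signals that
differ systematically between the two: coding DNA is 3-periodic (GC at the
three codon positions diverges, GC3 especially), its k-mer spectrum is
skewed by amino-acid and codon preferences, and it is long, while
intergenic ORFs are short and compositionally bland.

The canonical feature order is fixed (``FEATURE_NAMES``) and recorded in
every trained model:

====================  =========================================================
length_nt             ORF length in nucleotides, stop codon included
gc                    fraction of G+C over the whole sequence
gc1, gc2, gc3         fraction of G+C at codon positions 1, 2, 3
var2 .. var6          sample variance (ddof=1) of the 4^k-dimensional k-mer
                      frequency vector, k = 2..6, overlapping windows
c_weight              mean relative synonymous-codon preference: for each
                      distinct observed sense codon, its count divided by the
                      maximum count within its synonymous family, averaged;
                      stop codons and single-codon families (Met, Trp)
                      excluded
====================  =========================================================

k-mer *frequencies* (not counts) feed the variance so the feature is
comparable across lengths; length information is carried solely by
``length_nt``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .errors import FeatureDomainError
from .orfs import Orf

logger = logging.getLogger(__name__)

FEATURE_NAMES: tuple[str, ...] = (
    "length_nt",
    "gc",
    "gc1",
    "gc2",
    "gc3",
    "var2",
    "var3",
    "var4",
    "var5",
    "var6",
    "c_weight",
)

_BASE_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_INDEX[ord(_b)] = _i


def _encode(seq: str, *, op: str) -> np.ndarray:
    if not seq:
        raise FeatureDomainError(f"{op}: empty sequence")
    arr = _BASE_INDEX[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        raise FeatureDomainError(
            f"{op}: sequence contains symbols outside ACGT (N is not featurizable)"
        )
    return arr.astype(np.int64)


class GeneticCode:
    """Codon degeneracy structure of one translation table.

    Families partition the sense codons by encoded amino acid; the three
    stops (TAA/TAG/TGA in table 11) stand apart.
    """

    def __init__(self, table_id: int = 11):
        table = CodonTable.unambiguous_dna_by_id[table_id]
        self.table_id = table_id
        self.stop_codons: tuple[str, ...] = tuple(sorted(table.stop_codons))
        by_aa: dict[str, list[str]] = {}
        for codon, aa in table.forward_table.items():
            by_aa.setdefault(aa, []).append(codon)
        self.families: dict[str, tuple[str, ...]] = {
            aa: tuple(sorted(codons)) for aa, codons in sorted(by_aa.items())
        }
        self.sense_codons: tuple[str, ...] = tuple(
            sorted(c for codons in by_aa.values() for c in codons)
        )
        # codon id (base-4 over ACGT) -> family index; -1 for stops,
        # -2 for members of single-codon families
        self._family_of = np.full(64, -1, dtype=np.int64)
        self._family_list: list[np.ndarray] = []
        for aa, codons in self.families.items():
            ids = np.array([self._cid(c) for c in codons])
            if len(codons) == 1:
                self._family_of[ids] = -2
                continue
            self._family_of[ids] = len(self._family_list)
            self._family_list.append(ids)

    @staticmethod
    def _cid(codon: str) -> int:
        a, b, c = (int(_BASE_INDEX[ord(ch)]) for ch in codon)
        return 16 * a + 4 * b + c

    def family_of(self, codon: str) -> tuple[str, ...] | None:
        """Synonymous family of a sense codon; None for stops."""
        for codons in self.families.values():
            if codon in codons:
                return codons
        return None


#: default degeneracy: the bacterial/archaeal translation table (11)
GENETIC_CODE = GeneticCode(11)


def gc_content(seq: str) -> float:
    """(#G + #C) / length over the whole sequence."""
    arr = _encode(seq, op="gc_content")
    return float(((arr == 1) | (arr == 2)).mean())


def gc_by_position(seq: str) -> tuple[float, float, float]:
    """GC fraction at codon positions 1, 2, 3 (triplets read from base 1)."""
    arr = _encode(seq, op="gc_by_position")
    if arr.size % 3:
        raise FeatureDomainError("gc_by_position: length must be a multiple of 3")
    tri = arr.reshape(-1, 3)
    gc = (tri == 1) | (tri == 2)
    g1, g2, g3 = gc.mean(axis=0)
    return float(g1), float(g2), float(g3)


def kmer_frequency_vector(seq: str, k: int) -> np.ndarray:
    """Frequencies of all 4^k k-mers (lexicographic order, overlapping windows)."""
    if not 2 <= k <= 6:
        raise FeatureDomainError(f"k must be in 2..6, got {k}")
    arr = _encode(seq, op="kmer_frequency_vector")
    if arr.size < k:
        raise FeatureDomainError(f"sequence shorter than k={k}")
    ids = arr[: arr.size - k + 1].copy()
    for j in range(1, k):
        ids = ids * 4 + arr[j : arr.size - k + 1 + j]
    counts = np.bincount(ids, minlength=4**k)
    return counts / (arr.size - k + 1)


def kmer_variance(seq: str, k: int) -> float:
    """Sample variance (ddof=1, n=4^k) of the k-mer frequency vector."""
    return float(kmer_frequency_vector(seq, k).var(ddof=1))


def _codon_counts(seq: str, op: str) -> np.ndarray:
    arr = _encode(seq, op=op)
    if arr.size % 3:
        raise FeatureDomainError(f"{op}: length must be a multiple of 3")
    tri = arr.reshape(-1, 3)
    cids = 16 * tri[:, 0] + 4 * tri[:, 1] + tri[:, 2]
    return np.bincount(cids, minlength=64)


def c_weight(seq: str, code: GeneticCode = GENETIC_CODE) -> float:
    """Mean relative synonymous-codon preference of the observed codons.

    For each distinct observed sense codon c, w(c) = count(c) / max count
    within c's synonymous family; c_weight is the arithmetic mean of w over
    those codons. Stops and single-codon families carry no bias information
    and are excluded. Returns 1.0 when no eligible codon is observed.
    """
    counts = _codon_counts(seq, "c_weight")
    weights: list[float] = []
    for fam_ids in code._family_list:
        fam_counts = counts[fam_ids]
        observed = fam_counts > 0
        if observed.any():
            mx = fam_counts.max()
            weights.extend((fam_counts[observed] / mx).tolist())
    return float(np.mean(weights)) if weights else 1.0


@dataclass(frozen=True)
class FeatureVector:
    """The 11 named features of one ORF, in canonical order."""

    length_nt: int
    gc: float
    gc1: float
    gc2: float
    gc3: float
    var2: float
    var3: float
    var4: float
    var5: float
    var6: float
    c_weight: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)

    def __post_init__(self) -> None:
        if not np.isfinite(self.as_array()).all():
            raise FeatureDomainError("non-finite feature value")


def feature_vector(seq: str, code: GeneticCode = GENETIC_CODE) -> FeatureVector:
    """All 11 features of one ORF-shaped sequence (stop codon included)."""
    arr = _encode(seq, op="featurize")
    L = arr.size
    if L % 3:
        raise FeatureDomainError("featurize: length must be a multiple of 3")
    if L < 8:
        raise FeatureDomainError("featurize: need length >= 8 so var6 is defined")
    gcmask = (arr == 1) | (arr == 2)
    tri_gc = gcmask.reshape(-1, 3)
    g1, g2, g3 = tri_gc.mean(axis=0)
    variances = []
    for k in range(2, 7):
        ids = arr[: L - k + 1].copy()
        for j in range(1, k):
            ids = ids * 4 + arr[j : L - k + 1 + j]
        counts = np.bincount(ids, minlength=4**k)
        variances.append(float((counts / (L - k + 1)).var(ddof=1)))
    return FeatureVector(
        length_nt=L,
        gc=float(gcmask.mean()),
        gc1=float(g1),
        gc2=float(g2),
        gc3=float(g3),
        var2=variances[0],
        var3=variances[1],
        var4=variances[2],
        var5=variances[3],
        var6=variances[4],
        c_weight=c_weight(seq, code),
    )


def featurize(orf: Orf, code: GeneticCode = GENETIC_CODE) -> FeatureVector:
    """Feature vector of an extracted ORF (deterministic)."""
    return feature_vector(orf.seq, code)


def feature_frame(
    seqs: Iterable[str], code: GeneticCode = GENETIC_CODE
) -> pd.DataFrame:
    """Feature matrix (rows = sequences, columns = canonical names)."""
    rows = [feature_vector(s, code).as_array() for s in seqs]
    return pd.DataFrame(
        np.asarray(rows).reshape(-1, len(FEATURE_NAMES)), columns=list(FEATURE_NAMES)
    )


def feature_correlation(matrix: pd.DataFrame | Sequence[FeatureVector]) -> pd.DataFrame:
    """Pearson correlation of feature columns; symmetric with unit diagonal.

    Constant columns get zero off-diagonal correlations (with a warning)
    instead of NaN.
    """
    if not isinstance(matrix, pd.DataFrame):
        matrix = pd.DataFrame(
            [fv.as_array() for fv in matrix], columns=list(FEATURE_NAMES)
        )
    if len(matrix) < 3:
        raise FeatureDomainError("feature_correlation: need at least 3 rows")
    values = matrix.to_numpy(dtype=float)
    constant = values.std(axis=0) == 0
    if constant.any():
        warnings.warn(
            "constant feature columns in correlation: "
            + ", ".join(np.asarray(matrix.columns)[constant]),
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values, rowvar=False)
    corr[np.isnan(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=matrix.columns, columns=matrix.columns)
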