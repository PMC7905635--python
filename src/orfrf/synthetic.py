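"""Synthetic prokaryote-like genomes with known gene placement.

The generator emulates exactly the structure the classifier exploits:
coding sequences are 3-periodic (a GC3 target steers the wobble position)
and show tunable synonymous-codon bias, while intergenic spacers are
order-0 i.i.d. nucleotides with a flat GC. Coding and intergenic length
distributions are distinct (genes are long, spacers short). Everything —
layouts, sequences, strands — derives from a single spec seed through
NumPy's splittable SeedSequence, so artifacts are reproducible bit for bit.

``codon_bias_strength`` spans the difficulty axis: at 0 every synonymous
family is used uniformly (and with matched lengths/GC the classes are
indistinguishable); at 1 each family collapses onto one preferred codon.

What this does *not* model: promoters/terminators and other intergenic
structure, operons, sequencing error, incomplete edge ORFs. Passing tests
on these genomes therefore demonstrates that the pipeline recovers planted
periodicity/bias/length signal, not field performance on real assemblies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .features import GENETIC_CODE, GeneticCode
from .labeling import LabeledInstance, Label
from .features import feature_vector
from .orfs import STOP_CODONS
from .seqio import CdsInterval, GenomeAnnotation, SeqRecord

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class LengthDist:
    """Shifted gamma over integers: minimum + Gamma(shape, scale)."""

    mean: float
    minimum: int
    shape: float = 3.0

    def __post_init__(self) -> None:
        if self.mean <= self.minimum:
            raise ValueError("mean must exceed minimum")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        scale = (self.mean - self.minimum) / self.shape
        return self.minimum + np.floor(rng.gamma(self.shape, scale, size=n)).astype(int)


class CodonUsage:
    """Per-family synonymous codon probabilities plus the implied marginal.

    The marginal over sense codons weights each amino-acid family by its
    size, so at bias 0 sampling is uniform over the 61 sense codons.
    """

    def __init__(self, code: GeneticCode, conditional: dict[str, float]):
        self.code = code
        self.conditional = dict(conditional)  # codon -> P(codon | its family)
        n_sense = len(code.sense_codons)
        self.codons = np.array(code.sense_codons)
        marginal = np.empty(n_sense)
        fam_size = {
            c: len(fam) for fam in code.families.values() for c in fam
        }
        for i, c in enumerate(self.codons):
            marginal[i] = fam_size[c] / n_sense * self.conditional[c]
        self.marginal = marginal / marginal.sum()

    def family_probs(self, family: Sequence[str]) -> np.ndarray:
        return np.array([self.conditional[c] for c in family])

    def sample_codons(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self.codons[rng.choice(len(self.codons), size=n, p=self.marginal)]


def sample_codon_usage(
    code: GeneticCode,
    bias_strength: float,
    seed: int | np.random.Generator,
    gc3_preference: float | None = None,
) -> CodonUsage:
    """Draw one codon-usage table.

    Within each synonymous family the distribution interpolates between
    uniform (``bias_strength`` 0) and a point mass on one seeded preferred
    codon (``bias_strength`` 1). ``gc3_preference``, if given, is the
    probability the preferred codon is chosen among the family's G/C-ending
    codons, steering the GC3 of biased genes.
    """
    if not 0.0 <= bias_strength <= 1.0:
        raise ValueError("bias_strength must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    conditional: dict[str, float] = {}
    for family in code.families.values():
        k = len(family)
        if k == 1:
            conditional[family[0]] = 1.0
            continue
        gc_ending = [c for c in family if c[2] in "GC"]
        at_ending = [c for c in family if c[2] in "AT"]
        if gc3_preference is None or not gc_ending or not at_ending:
            preferred = family[rng.integers(k)]
        else:
            pool = gc_ending if rng.random() < gc3_preference else at_ending
            preferred = pool[rng.integers(len(pool))]
        for c in family:
            p = (1.0 - bias_strength) / k + (bias_strength if c == preferred else 0.0)
            conditional[c] = p
    return CodonUsage(code, conditional)


def generate_cds(
    n_codons: int, usage: CodonUsage, seed: int | np.random.Generator
) -> str:
    """ATG + (n_codons - 2) sense codons drawn i.i.d. from usage + one stop.

    Sense-only sampling guarantees no internal in-frame stop; total length
    is exactly 3 * n_codons.
    """
    if n_codons < 10:
        raise ValueError("n_codons must be >= 10")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    body = usage.sample_codons(rng, n_codons - 2)
    stop = STOP_CODONS[rng.integers(len(STOP_CODONS))]
    return "ATG" + "".join(body) + stop


def generate_intergenic(
    len_nt: int, gc: float, seed: int | np.random.Generator
) -> str:
    """i.i.d. bases with P(G)+P(C) = gc split evenly; no periodicity."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=len_nt, p=p)])


@dataclass(frozen=True)
class GenomeSpec:
    """Conditions for one synthetic genome.

    Defaults: ~300-codon genes (mean 900 nt), ~120-nt spacers, GC3 target
    0.65 in genes vs flat GC 0.45 between them, strong (0.8) codon bias.
    """

    n_genes: int = 50
    cds_len_codons: LengthDist = field(default_factory=lambda: LengthDist(300, 30))
    intergenic_len_nt: LengthDist = field(default_factory=lambda: LengthDist(120, 20))
    cds_gc3_target: float = 0.65
    intergenic_gc: float = 0.45
    codon_bias_strength: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for name in ("cds_gc3_target", "intergenic_gc", "codon_bias_strength"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def generate_genome(
    spec: GenomeSpec,
    name: str | None = None,
    code: GeneticCode = GENETIC_CODE,
) -> tuple[SeqRecord, GenomeAnnotation]:
    """One genome: alternating spacer/CDS layout with exact CDS coordinates.

    Each CDS sits on + or - with equal probability (reverse-complemented
    into the forward sequence when -). The annotation records every planted
    CDS; accidental ORFs arising inside spacers are intentionally *not*
    annotated — they are realistic negatives.
    """
    root = np.random.SeedSequence(spec.seed)
    usage_ss, layout_ss = root.spawn(2)
    usage = sample_codon_usage(
        code,
        spec.codon_bias_strength,
        np.random.default_rng(usage_ss),
        gc3_preference=spec.cds_gc3_target,
    )
    rng = np.random.default_rng(layout_ss)
    gene_lens = spec.cds_len_codons.sample(rng, spec.n_genes)
    spacer_lens = spec.intergenic_len_nt.sample(rng, spec.n_genes + 1)

    parts: list[str] = []
    intervals: list[CdsInterval] = []
    rid = name if name is not None else f"synth_{spec.seed}"
    pos = 0  # 0-based running length
    for i in range(spec.n_genes):
        spacer = generate_intergenic(int(spacer_lens[i]), spec.intergenic_gc, rng)
        parts.append(spacer)
        pos += len(spacer)
        cds = generate_cds(int(gene_lens[i]), usage, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            from .orfs import reverse_complement

            parts.append(reverse_complement(cds))
        else:
            parts.append(cds)
        intervals.append(CdsInterval(rid, pos + 1, pos + len(cds), strand))
        pos += len(cds)
    parts.append(generate_intergenic(int(spacer_lens[-1]), spec.intergenic_gc, rng))

    record = SeqRecord(id=rid, seq="".join(parts))
    ann = GenomeAnnotation.from_intervals(intervals)
    ann.add_seqid(rid)
    return record, ann


@dataclass(frozen=True)
class CommunitySpec:
    """A set of genomes with per-genome jitter on the spec means."""

    n_genomes: int = 5
    base: GenomeSpec = field(default_factory=GenomeSpec)
    jitter: float = 0.1  # relative jitter on mean lengths and GC targets
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        if not 0.0 <= self.jitter < 1.0:
            raise ValueError("jitter must be in [0, 1)")


#: preset community sizes, loosely mirroring low/medium/high metagenome
#: complexity tiers at desk scale
COMMUNITY_PRESETS: dict[str, int] = {"low": 5, "medium": 15, "high": 40}


def generate_community(
    cspec: CommunitySpec, code: GeneticCode = GENETIC_CODE
) -> list[tuple[SeqRecord, GenomeAnnotation]]:
    """Independent genomes with jittered specs, seeded from one root."""
    root = np.random.SeedSequence(cspec.seed)
    jitter_rng = np.random.default_rng(root.spawn(1)[0])
    genome_seeds = np.random.default_rng(root.spawn(1)[0]).integers(
        0, 2**31 - 1, size=cspec.n_genomes
    )
    out = []
    for g in range(cspec.n_genomes):
        j = cspec.jitter
        f = lambda: 1.0 + jitter_rng.uniform(-j, j)  # noqa: E731
        base = cspec.base
        spec = replace(
            base,
            cds_len_codons=replace(
                base.cds_len_codons, mean=base.cds_len_codons.mean * f()
            ),
            intergenic_len_nt=replace(
                base.intergenic_len_nt, mean=base.intergenic_len_nt.mean * f()
            ),
            cds_gc3_target=float(np.clip(base.cds_gc3_target * f(), 0, 1)),
            intergenic_gc=float(np.clip(base.intergenic_gc * f(), 0, 1)),
            seed=int(genome_seeds[g]),
        )
        out.append(generate_genome(spec, name=f"synth_{cspec.seed}_g{g:03d}", code=code))
    return out


def community_preset(
    preset: str, seed: int, base: GenomeSpec | None = None
) -> list[tuple[SeqRecord, GenomeAnnotation]]:
    """Convenience presets low/medium/high = 5/15/40 genomes."""
    try:
        n = COMMUNITY_PRESETS[preset]
    except KeyError:
        raise ValueError(
            f"unknown preset {preset!r}; choose from {sorted(COMMUNITY_PRESETS)}"
        ) from None
    spec = CommunitySpec(n_genomes=n, base=base or GenomeSpec(), seed=seed)
    return generate_community(spec)


def generate_null_dataset(
    n: int,
    seed: int,
    len_codons: LengthDist = LengthDist(300, 30),
    code: GeneticCode = GENETIC_CODE,
) -> list[LabeledInstance]:
    """A labeled dataset carrying *no* class signal (the exact null).

    Both classes are drawn from the same bias-0 ORF generator with the same
    length distribution, so labels are independent of features by
    construction. This is the matched-GC, matched-length null: an ORF
    extracted from i.i.d. equal-GC DNA, conditioned on its length, is
    distributionally a uniform-sense-codon sequence, which is exactly what
    bias 0 produces — without rejection-sampling long ORFs from spacers.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    usage = sample_codon_usage(code, 0.0, rng)
    lens = len_codons.sample(rng, n)
    instances: list[LabeledInstance] = []
    for i in range(n):
        label: Label = "coding" if i % 2 == 0 else "intergenic"
        seq = generate_cds(int(lens[i]), usage, rng)
        instances.append(
            LabeledInstance(
                feature_vector(seq, code), label, (f"null_{seed}_{i}", 1, len(seq), "+")
            )
        )
    return instances
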