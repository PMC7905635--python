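"""The 11-feature signature separates biased coding from random ORFs.

Generates one strongly codon-biased gene and one ORF-shaped sequence with
uniform synonymous usage, and prints both feature vectors side by side.
Expect the biased gene to show elevated GC3 and k-mer variances, and a
*depressed* c_weight: when one codon per family dominates, the rarely
used synonymous codons score near zero relative to it, pulling the mean
relative preference down. Uniform usage keeps all per-codon ratios close
to one another and the mean higher.
"""

import numpy as np

from orfrf import FEATURE_NAMES, synthetic
from orfrf.features import GENETIC_CODE, feature_vector

rng = np.random.default_rng(11)
biased = synthetic.sample_codon_usage(GENETIC_CODE, 0.9, rng, gc3_preference=0.8)
uniform = synthetic.sample_codon_usage(GENETIC_CODE, 0.0, rng)

gene = synthetic.generate_cds(300, biased, rng)
random_orf = synthetic.generate_cds(300, uniform, rng)

fv_gene = feature_vector(gene)
fv_rand = feature_vector(random_orf)
print(f"{'feature':>10} {'biased gene':>12} {'random ORF':>12}")
for name in FEATURE_NAMES:
    print(f"{name:>10} {getattr(fv_gene, name):>12.4g} {getattr(fv_rand, name):>12.4g}")
print(
    "\ngc3, c_weight and the k-mer variances carry the codon-bias signal\n"
    "(c_weight drops under strong bias). Length is identical here by design."
)
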