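from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def random_dna(rng: np.random.Generator, length: int, with_n: bool = False) -> str:
    alphabet = "ACGTN" if with_n else "ACGT"
    p = [0.23, 0.25, 0.25, 0.23, 0.04] if with_n else None
    return "".join(np.array(list(alphabet))[rng.choice(len(alphabet), length, p=p)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tiny_community():
    """Small high-bias community with merged annotation, shared across tests."""
    from orfrf.seqio import GenomeAnnotation
    from orfrf import synthetic

    cs = synthetic.CommunitySpec(
        n_genomes=3, base=synthetic.GenomeSpec(n_genes=60), seed=424242
    )
    genomes = synthetic.generate_community(cs)
    ann = GenomeAnnotation()
    records = []
    for rec, a in genomes:
        records.append(rec)
        ann.add_seqid(rec.id)
        for sid in a.seqids():
            for iv in a.intervals(sid):
                ann.add(iv)
    return records, ann


@pytest.fixture(scope="session")
def toy_length_model():
    """Forest trained on data separable on length_nt alone; noise elsewhere."""
    from orfrf import classifier
    from orfrf.features import FEATURE_NAMES, FeatureVector
    from orfrf.labeling import LabeledInstance

    rng = np.random.default_rng(7)
    instances = []
    for i in range(600):
        coding = i % 2 == 0
        length = int(rng.normal(900, 100)) if coding else int(rng.normal(90, 30))
        length = max(60, length - length % 3)
        noise = rng.uniform(0, 1, size=10)
        fv = FeatureVector(
            **{"length_nt": length, **dict(zip(FEATURE_NAMES[1:], noise))}
        )
        instances.append(
            LabeledInstance(
                fv, "coding" if coding else "intergenic", (f"toy{i}", 1, length, "+")
            )
        )
    config = classifier.TrainingConfig(mtry_grid=(2, 3), cv_repeats=2, seed=7)
    model, cv_results = classifier.train(instances, config)
    return model, cv_results, instances
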