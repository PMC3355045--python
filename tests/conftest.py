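import numpy as np
import pytest

from mslseq import features as feat
from mslseq.synth import SynthConfig, generate_dataset


def brute_force_counts(sequence: str, k: int) -> dict[str, int]:
    """Independent window-enumeration oracle for canonical word counting."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    counts: dict[str, int] = {}
    for i in range(len(sequence) - k + 1):
        w = sequence[i : i + k]
        if any(b not in comp for b in w):
            continue
        rc = "".join(comp[b] for b in reversed(w))
        counts[min(w, rc)] = counts.get(min(w, rc), 0) + 1
    return counts


@pytest.fixture(scope="session")
def small_dataset():
    """A small default-condition dataset shared across tests."""
    cfg = SynthConfig(n_genes_per_class=20, seed=11)
    return cfg, generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_features(small_dataset):
    _, ds = small_dataset
    genes = feat.parse_annotation(ds.gff3)
    lengths = {c: len(s) for c, s in ds.genome.items()}
    coords = feat.derive_features(genes, lengths)
    return genes, feat.extract_sequences(coords, ds.genome)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
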