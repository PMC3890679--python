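import numpy as np
import pytest

import barcodekit as bk


def matrix_from_pairs(labels, pairs):
    """Build a DistanceMatrix from {(a, b): d} with zero diagonal."""
    n = len(labels)
    vals = np.zeros((n, n))
    for (a, b), d in pairs.items():
        i, j = labels.index(a), labels.index(b)
        vals[i, j] = vals[j, i] = d
    return bk.DistanceMatrix(labels, vals)


def random_matrix(rng, n=20, n_species=5, tie_prob=0.5, missing_prob=0.0):
    """Random symmetric distance matrix with species labels; optional ties
    (coarse rounding) and MISSING entries."""
    vals = rng.random((n, n)) * 0.2
    vals = (vals + vals.T) / 2
    if rng.random() < tie_prob:
        vals = np.round(vals, 2)  # force ties
    np.fill_diagonal(vals, 0.0)
    if missing_prob:
        mask = rng.random((n, n)) < missing_prob
        mask = np.triu(mask, k=1)
        vals[mask] = np.nan
        vals[mask.T] = np.nan
    labels = [f"r{i:02d}" for i in range(n)]
    species = {lab: f"sp{rng.integers(0, n_species)}" for lab in labels}
    return bk.DistanceMatrix(labels, vals), species


@pytest.fixture
def four_record_lib():
    """2 species x 2 individuals, 120-bp alignment, conspecifics nearly
    identical and heterospecifics well separated."""
    rng = np.random.default_rng(7)
    base_a = "".join(rng.choice(list("ACGT"), 120))
    base_b = list(base_a)
    for i in range(0, 120, 10):  # 12 differences -> ~10% divergence
        base_b[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[base_b[i]]
    base_b = "".join(base_b)
    a2 = base_a[:-1] + ("A" if base_a[-1] != "A" else "C")
    b2 = base_b[:-1] + ("A" if base_b[-1] != "A" else "C")
    recs = [
        bk.SequenceRecord(id="A1", species="SpA", locus="rbcLa", sequence=base_a),
        bk.SequenceRecord(id="A2", species="SpA", locus="rbcLa", sequence=a2),
        bk.SequenceRecord(id="B1", species="SpB", locus="rbcLa", sequence=base_b),
        bk.SequenceRecord(id="B2", species="SpB", locus="rbcLa", sequence=b2),
    ]
    return bk.ReferenceLibrary(locus="rbcLa", records=tuple(recs))


@pytest.fixture(scope="session")
def panel20():
    """20 species x 3 individuals, 600 bp, intra 0.3% / inter 10%."""
    cfg = bk.SyntheticConfig(
        n_species=20,
        individuals_per_species=3,
        seq_length=600,
        inter_target=0.10,
        intra_target=0.003,
        seed=1,
    )
    lib, truth = bk.generate_library(cfg)
    m = bk.build_distance_matrix(lib)
    return cfg, lib, m
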