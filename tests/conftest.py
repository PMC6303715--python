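import numpy as np
import pytest

from snpharmony.panel import GenotypePanel, LocusDef, SampleUnit


def make_panel(
    dosages,
    allele_pairs=None,
    locations=None,
    dataset="DS0",
    locus_ids=None,
    id_prefix="ind",
):
    """Build a small panel from a dosage matrix.

    ``locations`` maps location_code -> row indices; default puts every
    individual in one location "LOC".
    """
    dosages = np.asarray(dosages, dtype=np.int8)
    n_ind, n_loci = dosages.shape
    if locus_ids is None:
        locus_ids = [f"L{j:03d}" for j in range(n_loci)]
    if allele_pairs is None:
        allele_pairs = [("A", "C")] * n_loci
    loci = [LocusDef(lid, pair) for lid, pair in zip(locus_ids, allele_pairs)]
    if locations is None:
        locations = {"LOC": list(range(n_ind))}
    row_loc = {}
    for loc, rows in locations.items():
        for r in rows:
            row_loc[r] = loc
    individuals = [(f"{dataset}_{id_prefix}{i}", row_loc[i]) for i in range(n_ind)]
    samples = [SampleUnit(loc, dataset, len(rows)) for loc, rows in locations.items()]
    return GenotypePanel(loci, samples, individuals, dosages)


def random_panel(rng, n_ind=8, n_loci=6, dataset="DS0", missing_rate=0.1):
    """Random valid panel, possibly with missing calls, for round-trip tests."""
    from snpharmony.panel import BASES, MISSING

    pairs = []
    for _ in range(n_loci):
        a, b = rng.choice(4, size=2, replace=False)
        pairs.append((BASES[a], BASES[b]))
    dosages = rng.integers(0, 3, size=(n_ind, n_loci)).astype(np.int8)
    if missing_rate:
        dosages[rng.random(dosages.shape) < missing_rate] = MISSING
    half = max(1, n_ind // 2)
    locations = {"AAA": list(range(half)), "BBB": list(range(half, n_ind))}
    locations = {k: v for k, v in locations.items() if v}
    return make_panel(dosages, pairs, locations, dataset=dataset)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
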