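import numpy as np
import pytest

from hscurves.data_io import SampleRecord, TraitRecord, validate_dataset


@pytest.fixture
def traits_small():
    return [
        TraitRecord("Caenis sp.", "Ephemeroptera", "Caenidae", {"GAT": 8, "GRA": 2}),
        TraitRecord("Chironomidae", "Diptera", "Chironomidae", {"GAT": 8, "PRE": 2}),
        TraitRecord("Simuliidae", "Diptera", "Simuliidae", {"FF": 10}),
        TraitRecord("Limnephilus sp.", "Trichoptera", "Limnephilidae",
                    {"SHR": 8, "GAT": 2}),
        TraitRecord("Ephemerella sp.", "Ephemeroptera", "Ephemerellidae",
                    {"GAT": 6, "GRA": 4}),
        TraitRecord("Erpobdella sp.", "Hirudinida", "Erpobdellidae", {"PRE": 10}),
    ]


@pytest.fixture
def samples_small():
    return [
        SampleRecord("s1", "2018", 0.22, 0.31, "e", 1.0,
                     {"Simuliidae": 14, "Caenis sp.": 4}),
        SampleRecord("s2", "2018", 0.05, 0.15, "a", 1.0,
                     {"Chironomidae": 50, "Caenis sp.": 2}),
        SampleRecord("s3", "2019", 0.10, 0.20, "f", 1.0,
                     {"Chironomidae": 10, "Limnephilus sp.": 2}),
        SampleRecord("s4", "2019", 0.35, 0.40, "ce", 1.0,
                     {"Simuliidae": 5, "Ephemerella sp.": 3,
                      "Erpobdella sp.": 1}),
    ]


@pytest.fixture
def dataset_small(samples_small, traits_small):
    return validate_dataset(samples_small, traits_small)


def random_dataset(rng: np.random.Generator, n_samples: int, taxa=None):
    """Small random dataset for oracle comparisons (test-side helper)."""
    taxa = taxa or ["A", "B", "C", "D"]
    orders = {"A": "Ephemeroptera", "B": "Diptera", "C": "Trichoptera",
              "D": "Coleoptera"}
    families = {"A": "FamA", "B": "FamB", "C": "FamC", "D": "FamD"}
    allocs = {"A": {"GAT": 10}, "B": {"GAT": 5, "SHR": 5}, "C": {"FF": 10},
              "D": {"GRA": 7, "PRE": 3}}
    subs = ["a", "c", "ae", "ce", "e", "f"]
    samples = []
    for i in range(n_samples):
        counts = {t: int(rng.poisson(3)) for t in taxa if rng.random() < 0.8}
        samples.append(
            SampleRecord(
                sample_id=f"r{i:02d}",
                campaign_id="c1" if i % 2 == 0 else "c2",
                velocity=float(rng.uniform(0, 0.6)),
                depth=float(rng.uniform(0.02, 0.6)),
                substrate=subs[int(rng.integers(len(subs)))],
                area=float(rng.uniform(0.5, 2.0)),
                counts=counts,
            )
        )
    traits = [TraitRecord(t, orders[t], families[t], allocs[t]) for t in taxa]
    return validate_dataset(samples, traits)
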