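"""Shared fixtures: toy pedigrees, random pedigree generator, cached dataset."""

import numpy as np
import pytest

from socped import (
    PedigreeRecord,
    TrueParameters,
    make_dataset,
    validate_pedigree,
)


def random_pedigree(rng, n=50, p_parent=0.7):
    """Random valid pedigree: each individual may draw parents among earlier
    individuals of the right sex."""
    records = []
    males, females = [], []
    for i in range(n):
        iid = f"R{i:03d}"
        sex = "F" if rng.random() < 0.5 else "M"
        dam = sire = None
        if females and rng.random() < p_parent:
            dam = females[rng.integers(len(females))]
        if males and rng.random() < p_parent:
            sire = males[rng.integers(len(males))]
        records.append(PedigreeRecord(iid, dam=dam, sire=sire, sex=sex))
        (females if sex == "F" else males).append(iid)
    return validate_pedigree(records)


def kinship_oracle(ped):
    """Recursive coefficient-of-kinship oracle: A = 2 f, f(i,i) =
    0.5 (1 + f(dam, sire)).  Independent of the tabular method."""
    order = {v: k for k, v in enumerate(ped.ids)}
    cache = {}

    def f(a, b):
        if a is None or b is None:
            return 0.0
        if order[a] < order[b]:
            a, b = b, a
        key = (a, b)
        if key in cache:
            return cache[key]
        dam, sire = ped.parents_of(a)
        if a == b:
            val = 0.5 * (1.0 + f(dam, sire))
        else:
            # a is not an ancestor of b since b precedes a in pedigree order
            val = 0.5 * (f(dam, b) + f(sire, b))
        cache[key] = val
        return val

    n = len(ped)
    ids = ped.ids
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1):
            A[i, j] = A[j, i] = 2.0 * f(ids[i], ids[j])
    return A


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic dataset at the default study-emulating scale."""
    return make_dataset(TrueParameters(), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
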