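"""Shared fixtures: the published 36-MLG reference panel and small helpers."""

from collections import Counter

import numpy as np
import pytest

from clonepart import clonal
from clonepart.genotype_io import load_table1_fixture, panel_from_records


@pytest.fixture(scope="session")
def table1_panel():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def table1_mlgs(table1_panel):
    return clonal.collapse_mlg(table1_panel)


@pytest.fixture(scope="session")
def table1_distances(table1_mlgs):
    return clonal.distance_matrix(table1_mlgs)


@pytest.fixture(scope="session")
def table1_printed_mll(table1_panel):
    """Published lineage label (A-E) per MLG name."""
    return dict(zip(table1_panel.meta["individual"], table1_panel.meta["mll"]))


def brute_force_allele_distance(g1, g2):
    """Independent shared-allele counter: per locus, 2 minus the multiset
    intersection computed with collections.Counter."""
    total = 0
    for (a1, a2), (b1, b2) in zip(g1, g2):
        shared = sum((Counter([a1, a2]) & Counter([b1, b2])).values())
        total += 2 - shared
    return total


@pytest.fixture(scope="session")
def toy_panel():
    """3 individuals, 2 loci, 2 samples; includes a missing pair."""
    return panel_from_records(
        ["LocA", "LocB"],
        [
            ("i1", "s1", "", "", [(189, 203), (100, 100)]),
            ("i2", "s1", "", "", [(189, 189), (100, 102)]),
            ("i3", "s2", "", "", [(0, 0), (100, 102)]),
        ],
    )


def random_panel(rng, n=50, loci=10, n_samples=5, missing_fraction=0.0):
    """Random valid panel for round-trip property tests."""
    sizes = np.arange(180, 241, 2)
    records = []
    for i in range(n):
        pairs = []
        for _ in range(loci):
            if missing_fraction and rng.random() < missing_fraction:
                pairs.append((0, 0))
            else:
                pairs.append(tuple(sorted(rng.choice(sizes, 2))))
        records.append(
            (
                f"ind{i:03d}",
                f"s{rng.integers(n_samples)}",
                f"loc{i % 3}",
                "sorghum" if i % 2 else "sugarcane",
                pairs,
            )
        )
    return panel_from_records([f"L{j:02d}" for j in range(loci)], records)
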