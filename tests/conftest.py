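"""Shared fixtures: small fixed trees and independent covariance oracles."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from lifecube import parse_newick, simulate_yule


@pytest.fixture
def cherry_plus_one():
    """((A:1,B:1):1,C:2); height 2, classic 3-tip example."""
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star5():
    return parse_newick("(A:1,B:1,C:1,D:1,E:1);")


@pytest.fixture
def yule():
    """Factory for seeded pure-birth trees."""

    def make(n, seed, rate=1.0):
        return simulate_yule(n, rate, seed)

    return make


def dense_vcv(tree):
    """Independent BM covariance via dendropy MRCA depths.

    C_ij = root-to-MRCA(i, j) distance, computed from the tree's Newick
    serialization with dendropy only — no lifecube covariance code.
    """
    dt = dendropy.Tree.get(data=tree.to_newick(), schema="newick",
                           preserve_underscores=True)
    dt.is_rooted = True  # keep the root bifurcation when encoding bipartitions
    taxa = {t.label: t for t in dt.taxon_namespace}
    depths = {lf.taxon.label: lf.distance_from_root()
              for lf in dt.leaf_node_iter()}
    names = tree.tip_names
    n = len(names)
    C = np.zeros((n, n))
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i == j:
                C[i, j] = depths[a]
            else:
                C[i, j] = dt.mrca(taxa=[taxa[a], taxa[b]]).distance_from_root()
    return C


@pytest.fixture
def dense_vcv_oracle():
    return dense_vcv


@pytest.fixture
def trait_table():
    """A small hand-built trait table with known metric values."""
    return pd.DataFrame(
        {
            "species": ["Rana una", "Lacerta dua", "Mus tria", "Avis quarta"],
            "clade": ["Amphibia", "Reptilia", "Mammalia", "Aves"],
            "adult_body_mass": [100.0, 50.0, 20.0, 30.0],
            "litter_size": [2.0, 4.0, 5.0, 3.0],
            "litters_per_year": [1.0, 2.0, 2.5, 1.0],
            "mass_at_independence": [10.0, 5.0, 4.0, 25.0],
            "max_longevity": [12.0, 10.0, 4.0, 20.0],
            "female_maturity_age": [2.0, 2.0, 0.5, 2.0],
            "svl_min": [40.0, np.nan, np.nan, np.nan],
            "svl_max": [60.0, np.nan, np.nan, np.nan],
        }
    )
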