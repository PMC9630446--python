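import numpy as np
import pandas as pd
import pytest

import vusannot as v


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic study (99 variants, 6-member family)."""
    return v.generate()


@pytest.fixture(scope="session")
def default_cmap(default_bundle):
    b = default_bundle
    return v.build_coordinate_map(b.alignment, "MLL1", b.offsets)


@pytest.fixture(scope="session")
def default_scores(default_bundle, default_cmap):
    return v.compute_cluster_scores(default_bundle.table, default_cmap)


@pytest.fixture()
def toy_table():
    df = pd.DataFrame({
        "protein_id": ["A", "A", "B"],
        "position": [100, 103, 500],
        "wt_aa": ["G", "K", "Y"],
        "mut_aa": ["A", "E", "C"],
    })
    return v.VariantTable(df)


@pytest.fixture()
def ungapped_pair_alignment():
    seqs = {"A": "ACDEFGHIKL", "B": "ACDEFGHIKL", "C": "ACDEFGHIKL"}
    return v.ParalogAlignment(seqs)


def brute_force_prox(events, w=7):
    """Independent O(n^2) pure-python oracle for the proximity statistics."""
    n = len(events)
    out = []
    for i in range(n):
        count = 0
        nearest = None
        for j in range(n):
            if j == i:
                continue
            d = abs(events[j] - events[i])
            if d <= w:
                count += 1
            nearest = d if nearest is None else min(nearest, d)
        if nearest is None:
            out.append((0, None, 0.0))
            continue
        nearest = max(1, nearest)
        ratio = count / nearest if count > 0 else 0.0
        out.append((count, nearest, ratio))
    return out
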