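import numpy as np
import pandas as pd
import pytest

from oosplit import HalfProteomeMatrix, TwinPairTable


def make_matrix(rows, axis="equatorial", hems=("A", "V")):
    """Build a HalfProteomeMatrix from {protein: [(h1, h2), ...]} per oocyte."""
    n_oo = len(next(iter(rows.values())))
    half_ids = [f"oo{o+1}_{h}" for o in range(n_oo) for h in hems]
    design = pd.DataFrame(
        {
            "oocyte": [f"oo{o+1}" for o in range(n_oo) for _ in hems],
            "hemisphere": [h for _ in range(n_oo) for h in hems],
        },
        index=pd.Index(half_ids, name="half_id"),
    )
    values = pd.DataFrame(
        {p: np.array(pairs, dtype=float).ravel() for p, pairs in rows.items()},
        index=design.index,
    ).T
    return HalfProteomeMatrix(values, design, axis)


def random_matrix(rng, n_proteins=8, n_oocytes=4, axis="equatorial"):
    rows = {
        f"P{i:03d}": [tuple(rng.normal(10, 3, 2)) for _ in range(n_oocytes)]
        for i in range(n_proteins)
    }
    return make_matrix(rows, axis=axis)


def make_pairs(records, tpm=None):
    """Build a TwinPairTable from (pair, group, total, epi, pe, te[, es]) rows."""
    rows = []
    for rec in records:
        pair, group, totals, epis, pes, tes = rec[:6]
        ess = rec[6] if len(rec) > 6 else (None, None)
        for m in range(2):
            rows.append(
                {
                    "pair_id": pair,
                    "sample_id": f"{pair}_{m+1}",
                    "group": group,
                    "total_cells": totals[m],
                    "epiblast": epis[m],
                    "primitive_endoderm": pes[m],
                    "trophectoderm": tes[m],
                    "es_colonies": ess[m],
                }
            )
    return TwinPairTable(pd.DataFrame(rows), tpm)


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


@pytest.fixture
def toy_matrix():
    # worked decomposition example: two proteins at the two extremes plus
    # the mixed case (1,3),(4,8)
    return make_matrix(
        {
            "between": [(5, 5), (9, 9)],
            "within": [(1, 3), (2, 2)],
            "mixed": [(1, 3), (4, 8)],
        }
    )


@pytest.fixture
def toy_pairs():
    return make_pairs(
        [
            ("p1", "equatorial", (48, 52), (4, 6), (8, 8), (30, 32)),
            ("p2", "equatorial", (50, 50), (5, 8), (7, 7), (30, 30)),
            ("p3", "equatorial", (45, 55), (5, 5), (9, 8), (28, 35)),
            ("p4", "equatorial", (52, 52), (3, 6), (8, 9), (33, 30)),
        ]
    )
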