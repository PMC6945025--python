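"""Shared fixtures: small hand-built genotype matrices and flag tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dsrscan.matrix import LOCUS_COLUMNS, GenotypeMatrix


def make_matrix(
    genotypes,
    breeds,
    chroms=None,
    positions=None,
    sample_ids=None,
):
    """Build a GenotypeMatrix from a samples x loci nested list.

    ``breeds`` is one breed label per sample; -1 encodes a missing call.
    """
    g = np.asarray(genotypes, dtype=np.int8)
    n_samples, n_loci = g.shape
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n_samples)]
    if chroms is None:
        chroms = ["chr1"] * n_loci
    if positions is None:
        pos_counter: dict[str, int] = {}
        positions = []
        for c in chroms:
            pos_counter[c] = pos_counter.get(c, 0) + 1
            positions.append(pos_counter[c] * 1000)
    loci = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "locus_id": [f"{c}:{p}" for c, p in zip(chroms, positions)],
            "ref": "A",
            "alt": "G",
        },
        columns=list(LOCUS_COLUMNS),
    )
    return GenotypeMatrix(
        sample_ids=list(sample_ids),
        breed_of=dict(zip(sample_ids, breeds)),
        loci=loci,
        genotypes=g,
    )


def flags_to_frame(flags: str, chrom: str = "chr1") -> pd.DataFrame:
    """Flag string over {N, S, C} -> a scan-ready table; theta values
    are placeholders consistent with the flag ordering."""
    code = {"N": ("NONE", 0.0), "S": ("SIG", 0.5), "C": ("CORE", 0.9)}
    rows = []
    for i, f in enumerate(flags):
        name, theta = code[f]
        rows.append((chrom, (i + 1) * 1000, f"{chrom}:{(i + 1) * 1000}", theta, name))
    return pd.DataFrame(rows, columns=["chrom", "pos", "locus_id", "theta", "flag"])


@pytest.fixture
def two_breed_matrix():
    """5 + 5 diploid samples over 4 loci with assorted genotypes."""
    genotypes = [
        [0, 0, 1, 2],
        [0, 1, 1, 2],
        [0, 0, 0, 2],
        [1, 0, 2, 2],
        [0, 0, 1, 2],
        [2, 2, 1, 0],
        [2, 1, 2, 0],
        [2, 2, 1, 0],
        [1, 2, 0, 0],
        [2, 2, 2, 0],
    ]
    return make_matrix(genotypes, ["A"] * 5 + ["B"] * 5)


@pytest.fixture
def rng():
    return np.random.default_rng(20191119)
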