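"""Breed-labelled diploid genotype matrix, the pipeline's central container.

Genotypes are coded as the number of alternate alleles carried by a diploid
individual: 0 (hom ref), 1 (het), 2 (hom alt), with :data:`MISSING` (= -1)
for a missing call.  Loci are biallelic SNPs kept in genomic order
(chromosomes in natural order, positions strictly increasing within each
chromosome, 1-based coordinates throughout).
"""

from __future__ import annotations

import dataclasses
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

#: genotype code for a missing diploid call
MISSING = -1

#: required columns of the locus table, in order
LOCUS_COLUMNS = ("chrom", "pos", "locus_id", "ref", "alt")


class LocusRecord(NamedTuple):
    """One biallelic SNP: chromosome, 1-based position, id and alleles."""

    chrom: str
    pos: int
    locus_id: str
    ref: str
    alt: str


def default_locus_id(chrom: str, pos: int) -> str:
    """Generated locus name in the conventional ``chrom:pos`` style."""
    return f"{chrom}:{pos}"


def chrom_sort_key(name: str) -> tuple[int, int, str]:
    """Natural chromosome ordering: numeric autosomes first (1 < 2 < 10),
    then non-numeric names (W, Z, MT, ...) lexicographically."""
    core = name[3:] if name.lower().startswith("chr") else name
    if core.isdigit():
        return (0, int(core), "")
    return (1, 0, core)


@dataclasses.dataclass
class GenotypeMatrix:
    """Samples x loci table of diploid genotype codes with breed labels.

    Parameters
    ----------
    sample_ids
        Ordered sample names; rows of ``genotypes``.
    breed_of
        Mapping of every sample id to its breed label.
    loci
        DataFrame with columns ``chrom, pos, locus_id, ref, alt``;
        columns of ``genotypes``, in genomic order.
    genotypes
        int8 array of shape ``(n_samples, n_loci)`` with values in
        ``{0, 1, 2, MISSING}``.
    """

    sample_ids: list[str]
    breed_of: dict[str, str]
    loci: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sample_ids), len(self.loci)):
            raise ValueError(
                f"genotype table shape {self.genotypes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.loci)} loci"
            )
        missing_labels = [s for s in self.sample_ids if s not in self.breed_of]
        if missing_labels:
            raise ValueError(f"samples without a breed label: {missing_labels}")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be in {0, 1, 2, MISSING}")
        if list(self.loci.columns[: len(LOCUS_COLUMNS)]) != list(LOCUS_COLUMNS):
            raise ValueError(f"locus table must have columns {LOCUS_COLUMNS}")

    # ------------------------------------------------------------------ views
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def breeds(self) -> list[str]:
        """Breed labels in order of first appearance among samples."""
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.breed_of[s], None)
        return list(seen)

    def sample_indices(self, breeds: Sequence[str] | set[str]) -> np.ndarray:
        """Row indices of all samples belonging to any of ``breeds``."""
        want = set(breeds)
        return np.array(
            [i for i, s in enumerate(self.sample_ids) if self.breed_of[s] in want],
            dtype=np.intp,
        )

    def locus_records(self) -> Iterator[LocusRecord]:
        for row in self.loci.itertuples(index=False):
            yield LocusRecord(row.chrom, int(row.pos), row.locus_id, row.ref, row.alt)

    # ------------------------------------------------------------- subsetting
    def take_loci(self, index: np.ndarray | Sequence[int]) -> "GenotypeMatrix":
        """New matrix restricted to the given locus positions (order kept)."""
        index = np.asarray(index, dtype=np.intp)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            breed_of=dict(self.breed_of),
            loci=self.loci.iloc[index].reset_index(drop=True),
            genotypes=self.genotypes[:, index],
        )

    def take_samples(self, index: np.ndarray | Sequence[int]) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=np.intp)
        ids = [self.sample_ids[i] for i in index]
        return GenotypeMatrix(
            sample_ids=ids,
            breed_of={s: self.breed_of[s] for s in ids},
            loci=self.loci.copy(),
            genotypes=self.genotypes[index, :],
        )

    # ---------------------------------------------------------------- probity
    def genomic_order(self) -> np.ndarray:
        """Stable argsort of loci by natural chromosome order then position."""
        keys = [chrom_sort_key(c) for c in self.loci["chrom"]]
        order = sorted(
            range(self.n_loci), key=lambda i: (keys[i], int(self.loci["pos"].iat[i]))
        )
        return np.asarray(order, dtype=np.intp)

    def sort_genomic(self) -> "GenotypeMatrix":
        return self.take_loci(self.genomic_order())

    def validate_order(self) -> None:
        """Raise unless positions are strictly increasing within chromosomes
        and chromosomes appear in contiguous natural-order blocks."""
        chroms = list(self.loci["chrom"])
        pos = self.loci["pos"].to_numpy()
        prev_key = None
        seen: set[str] = set()
        for i, c in enumerate(chroms):
            key = chrom_sort_key(c)
            if prev_key is None or key != prev_key:
                if c in seen:
                    raise ValueError(f"chromosome {c} appears in two blocks")
                if prev_key is not None and key < prev_key:
                    raise ValueError("chromosomes out of natural order")
                seen.add(c)
            else:
                if pos[i] <= pos[i - 1]:
                    raise ValueError(
                        f"positions not strictly increasing on {c} at {pos[i]}"
                    )
            prev_key = key
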