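"""SNP retention and subsampling rules.

The retention chain is: keep autosomal SNPs, then keep loci genotyped in
at least 70% of the samples of *every* breed.  A pooled minor-allele-
frequency filter (MAF >= 0.2) and random locus subsampling are applied
only when preparing the reduced panels used for population-structure
analyses.  All thresholds are boundary-inclusive.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np

from .matrix import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


def default_autosome_names(n: int = 33) -> set[str]:
    """Autosome name set accepted with and without a ``chr`` prefix."""
    names = set()
    for i in range(1, n + 1):
        names.add(str(i))
        names.add(f"chr{i}")
    return names


@dataclasses.dataclass
class FilterReport:
    """Locus bookkeeping along the retention chain (counts non-increasing)."""

    n_input_loci: int
    n_after_autosome: int | None = None
    n_after_callrate: int | None = None
    n_after_maf: int | None = None

    @property
    def n_removed_autosome(self) -> int | None:
        if self.n_after_autosome is None:
            return None
        return self.n_input_loci - self.n_after_autosome

    @property
    def n_removed_callrate(self) -> int | None:
        if self.n_after_callrate is None:
            return None
        before = (
            self.n_after_autosome
            if self.n_after_autosome is not None
            else self.n_input_loci
        )
        return before - self.n_after_callrate

    @property
    def n_removed_maf(self) -> int | None:
        if self.n_after_maf is None:
            return None
        for before in (self.n_after_callrate, self.n_after_autosome, self.n_input_loci):
            if before is not None:
                return before - self.n_after_maf
        return None  # pragma: no cover

    def to_tsv(self) -> str:
        lines = ["stage\tn_loci\tn_removed"]
        lines.append(f"input\t{self.n_input_loci}\t0")
        if self.n_after_autosome is not None:
            lines.append(f"autosome\t{self.n_after_autosome}\t{self.n_removed_autosome}")
        if self.n_after_callrate is not None:
            lines.append(f"call_rate\t{self.n_after_callrate}\t{self.n_removed_callrate}")
        if self.n_after_maf is not None:
            lines.append(f"maf\t{self.n_after_maf}\t{self.n_removed_maf}")
        return "\n".join(lines) + "\n"


def filter_autosomes(
    m: GenotypeMatrix, autosome_names: set[str] | None = None
) -> GenotypeMatrix:
    """Drop loci on chromosomes outside ``autosome_names`` (order kept)."""
    if autosome_names is None:
        autosome_names = default_autosome_names()
    if not autosome_names:
        raise ValueError("autosome_names must be non-empty")
    keep = np.array(
        [c in autosome_names for c in m.loci["chrom"]], dtype=bool
    )
    if not keep.any():
        raise ValueError("no autosomal loci retained")
    if keep.all():
        return m
    return m.take_loci(np.flatnonzero(keep))


def _per_breed_call_rate(m: GenotypeMatrix) -> tuple[list[str], np.ndarray]:
    """Call rate per (breed, locus): fraction of non-missing genotypes."""
    breeds = m.breeds
    rates = np.empty((len(breeds), m.n_loci), dtype=float)
    called = m.genotypes != MISSING
    for bi, breed in enumerate(breeds):
        idx = m.sample_indices([breed])
        rates[bi] = called[idx].mean(axis=0)
    return breeds, rates


def filter_call_rate(
    m: GenotypeMatrix, min_rate: float = 0.7
) -> tuple[GenotypeMatrix, FilterReport]:
    """Keep a locus iff every breed has call rate >= ``min_rate`` there.

    The denominator for each breed is the number of that breed's samples
    actually present in the matrix, and the boundary is inclusive: with
    10 samples, 7 genotyped passes (0.7 >= 0.7) and 6 fails.
    """
    if not (0 < min_rate <= 1):
        raise ValueError("min_rate must be in (0, 1]")
    _, rates = _per_breed_call_rate(m)
    keep = (rates >= min_rate).all(axis=0)
    report = FilterReport(n_input_loci=m.n_loci, n_after_callrate=int(keep.sum()))
    if not keep.any():
        raise ValueError("no loci pass the per-breed call-rate filter")
    out = m if keep.all() else m.take_loci(np.flatnonzero(keep))
    return out, report


def pooled_maf(m: GenotypeMatrix) -> np.ndarray:
    """Minor allele frequency per locus over all non-missing genotypes,
    pooled across samples; NaN where every genotype is missing."""
    g = m.genotypes
    called = g != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / (2.0 * n_called)
    p = np.where(n_called > 0, p, np.nan)
    return np.minimum(p, 1.0 - p)


def per_breed_maf(m: GenotypeMatrix) -> np.ndarray:
    """Per-breed MAF table, shape (n_breeds, n_loci); NaN where a breed
    has no calls at a locus."""
    out = np.empty((len(m.breeds), m.n_loci))
    for bi, breed in enumerate(m.breeds):
        out[bi] = pooled_maf(m.take_samples(m.sample_indices([breed])))
    return out


def filter_maf(
    m: GenotypeMatrix, min_maf: float = 0.2, per_breed: bool = False
) -> GenotypeMatrix:
    """Keep loci with MAF >= ``min_maf`` (inclusive).

    By default the frequency is pooled over all retained samples; with
    ``per_breed=True`` every breed must individually satisfy the bound.
    Loci with no non-missing genotypes are removed with a warning.
    """
    if not (0 <= min_maf <= 0.5):
        raise ValueError("min_maf must be in [0, 0.5]")
    if per_breed:
        maf = per_breed_maf(m)
        keep = np.nan_to_num(maf, nan=-1.0).min(axis=0) >= min_maf
        all_missing = np.isnan(maf).any(axis=0)
    else:
        maf = pooled_maf(m)
        all_missing = np.isnan(maf)
        keep = np.nan_to_num(maf, nan=-1.0) >= min_maf
    if all_missing.any():
        logger.warning(
            "%d locus/loci with no callable genotypes removed by the MAF filter",
            int(all_missing.sum()),
        )
    if not keep.any():
        raise ValueError("no loci pass the MAF filter")
    logger.info(
        "MAF filter (%s, >= %.3g): %d of %d loci kept",
        "per-breed" if per_breed else "pooled", min_maf, int(keep.sum()), m.n_loci,
    )
    return m if keep.all() else m.take_loci(np.flatnonzero(keep))


def sample_loci(m: GenotypeMatrix, n: int = 1000, seed: int = 0) -> GenotypeMatrix:
    """Uniform random locus subset without replacement, genomic order kept.

    Deterministic for a given ``seed``; asking for more loci than exist
    is an error rather than a silent truncation.
    """
    if n > m.n_loci:
        raise ValueError(f"requested {n} loci but only {m.n_loci} available")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(m.n_loci, size=n, replace=False)
    chosen.sort()
    return m.take_loci(chosen)


def filter_chain(
    m: GenotypeMatrix,
    autosome_names: set[str] | None = None,
    min_call_rate: float = 0.7,
    min_maf: float | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the retention chain in its fixed order:
    autosome -> per-breed call rate -> (optional) pooled MAF."""
    n_input = m.n_loci
    m = filter_autosomes(m, autosome_names)
    n_auto = m.n_loci
    m, _ = filter_call_rate(m, min_call_rate)
    report = FilterReport(
        n_input_loci=n_input, n_after_autosome=n_auto, n_after_callrate=m.n_loci
    )
    if min_maf is not None:
        m = filter_maf(m, min_maf)
        report.n_after_maf = m.n_loci
    return m, report
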