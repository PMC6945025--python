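"""Per-locus and multi-locus Weir & Cockerham (1984) F_ST for a
two-group contrast, plus the top-quantile outlier thresholds.

The estimator decomposes allelic variance at each biallelic SNP into
among-population (a), among-individual-within-population (b) and
within-individual (c) components, with

    theta = a / (a + b + c).

Inputs per subpopulation i are n_i (genotyped diploid individuals),
p_i (alternate-allele frequency) and h_i (observed heterozygote
proportion).  With r subpopulations:

    n_bar = sum n_i / r
    n_c   = (r n_bar - sum n_i^2 / (r n_bar)) / (r - 1)
    p_bar = sum n_i p_i / (r n_bar)
    s^2   = sum n_i (p_i - p_bar)^2 / ((r - 1) n_bar)
    h_bar = sum n_i h_i / (r n_bar)
    a = (n_bar/n_c) [ s^2 - (1/(n_bar-1)) ( p_bar(1-p_bar)
          - ((r-1)/r) s^2 - h_bar/4 ) ]
    b = (n_bar/(n_bar-1)) [ p_bar(1-p_bar) - ((r-1)/r) s^2
          - ((2 n_bar - 1)/(4 n_bar)) h_bar ]
    c = h_bar / 2

theta is undefined when a + b + c = 0 (a monomorphic locus with no
heterozygotes) or when either group has fewer than 2 genotyped
individuals; undefined loci are excluded from quantile computation but
kept in the plot-ready table.  Negative estimates are retained — they
can never enter the top quantiles.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

#: flag labels for the outlier tiers (CORE = top 1%, SIG = top 5%)
FLAG_NONE = "NONE"
FLAG_SIG = "SIG"
FLAG_CORE = "CORE"


@dataclasses.dataclass(frozen=True)
class Contrast:
    """A two-group breed contrast, e.g. pooled natives vs one control."""

    label: str
    group_a: frozenset[str]
    group_b: frozenset[str]

    def __init__(self, label: str, group_a: Iterable[str], group_b: Iterable[str]):
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "group_a", frozenset(group_a))
        object.__setattr__(self, "group_b", frozenset(group_b))
        if not self.group_a or not self.group_b:
            raise ValueError("both contrast groups must be non-empty")
        if self.group_a & self.group_b:
            raise ValueError(
                f"contrast groups overlap: {sorted(self.group_a & self.group_b)}"
            )

    def validate_against(self, m: GenotypeMatrix) -> None:
        known = set(m.breeds)
        unknown = (self.group_a | self.group_b) - known
        if unknown:
            raise ValueError(f"contrast {self.label}: unknown breeds {sorted(unknown)}")


@dataclasses.dataclass
class LocusCounts:
    """Per-subpopulation tallies feeding the estimator at one locus."""

    n: np.ndarray  # genotyped diploid individuals per subpopulation
    p: np.ndarray  # alt-allele frequency per subpopulation
    h: np.ndarray  # observed heterozygote proportion per subpopulation

    @property
    def r(self) -> int:
        return len(self.n)


@dataclasses.dataclass
class PerLocusFst:
    """WC84 components and theta for one locus (NaN theta = undefined)."""

    a: float
    b: float
    c: float
    theta: float
    n_bar: float
    n_c: float
    p_bar: float
    s2: float
    h_bar: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.theta)


@dataclasses.dataclass
class ThresholdSet:
    """Genome-wide outlier cutoffs: SIG = top 5%, CORE = top 1%."""

    q_sig: float
    q_core: float
    n_flagged_sig: int
    n_flagged_core: int


# ------------------------------------------------------------------- tallying
def group_counts(
    m: GenotypeMatrix, breeds: Iterable[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n, p, h) arrays over all loci for the pooled samples of ``breeds``."""
    idx = m.sample_indices(breeds)
    g = m.genotypes[idx]
    called = g != MISSING
    n = called.sum(axis=0).astype(float)
    alt = np.where(called, g, 0).sum(axis=0)
    het = (g == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
        h = np.where(n > 0, het / n, np.nan)
    return n, p, h


def locus_counts(m: GenotypeMatrix, contrast: Contrast, locus_index: int) -> LocusCounts:
    """Tallies for one locus under a two-group contrast."""
    contrast.validate_against(m)
    counts = []
    for group in (contrast.group_a, contrast.group_b):
        n, p, h = group_counts(m, group)
        counts.append((n[locus_index], p[locus_index], h[locus_index]))
    n, p, h = (np.array(x, dtype=float) for x in zip(*counts))
    return LocusCounts(n=n, p=p, h=h)


# ------------------------------------------------------------------ estimator
def wc84_components(lc: LocusCounts) -> PerLocusFst:
    """Evaluate the variance components and theta for one locus."""
    r = lc.r
    n = lc.n.astype(float)
    p = lc.p
    h = lc.h
    n_bar = n.sum() / r
    if n_bar <= 1 or (n < 2).any() or np.isnan(p).any():
        return PerLocusFst(
            a=math.nan, b=math.nan, c=math.nan, theta=math.nan,
            n_bar=n_bar, n_c=math.nan, p_bar=math.nan, s2=math.nan, h_bar=math.nan,
        )
    n_c = (r * n_bar - (n ** 2).sum() / (r * n_bar)) / (r - 1)
    p_bar = (n * p).sum() / (r * n_bar)
    s2 = (n * (p - p_bar) ** 2).sum() / ((r - 1) * n_bar)
    h_bar = (n * h).sum() / (r * n_bar)
    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2
    denom = a + b + c
    theta = a / denom if denom != 0 else math.nan
    return PerLocusFst(
        a=a, b=b, c=c, theta=theta,
        n_bar=n_bar, n_c=n_c, p_bar=p_bar, s2=s2, h_bar=h_bar,
    )


def fst_scan(m: GenotypeMatrix, contrast: Contrast) -> pd.DataFrame:
    """Vectorised per-locus WC84 scan over the whole matrix.

    Returns the per-locus table with columns chrom, pos, locus_id,
    n1, n2, p1, p2, h1, h2, a, b, c, theta (theta NaN where undefined).
    Agrees with :func:`wc84_components` locus by locus.
    """
    contrast.validate_against(m)
    n1, p1, h1 = group_counts(m, contrast.group_a)
    n2, p2, h2 = group_counts(m, contrast.group_b)
    r = 2.0
    n_bar = (n1 + n2) / r
    ok = (n1 >= 2) & (n2 >= 2) & (n_bar > 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (r * n_bar - (n1 ** 2 + n2 ** 2) / (r * n_bar)) / (r - 1)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar)
            - (r - 1) / r * s2
            - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2
        denom = a + b + c
        theta = np.where(denom != 0, a / denom, np.nan)
    for arr in (a, b, c, theta):
        arr[~ok] = np.nan
    out = m.loci[["chrom", "pos", "locus_id"]].copy()
    out["n1"], out["n2"] = n1, n2
    out["p1"], out["p2"] = p1, p2
    out["h1"], out["h2"] = h1, h2
    out["a"], out["b"], out["c"], out["theta"] = a, b, c, theta
    return out


def multilocus_theta(per_locus: pd.DataFrame | Sequence[PerLocusFst]) -> float:
    """Ratio-of-sums multi-locus estimate, sum(a) / sum(a+b+c), over
    loci with a defined theta."""
    if isinstance(per_locus, pd.DataFrame):
        a = per_locus["a"].to_numpy(dtype=float)
        b = per_locus["b"].to_numpy(dtype=float)
        c = per_locus["c"].to_numpy(dtype=float)
        theta = per_locus["theta"].to_numpy(dtype=float)
    else:
        a = np.array([x.a for x in per_locus], dtype=float)
        b = np.array([x.b for x in per_locus], dtype=float)
        c = np.array([x.c for x in per_locus], dtype=float)
        theta = np.array([x.theta for x in per_locus], dtype=float)
    ok = ~np.isnan(theta)
    if not ok.any():
        raise ValueError("no locus has a defined theta")
    return float(a[ok].sum() / (a[ok] + b[ok] + c[ok]).sum())


# ------------------------------------------------------------------ quantiles
def theta_quantile_thresholds(
    thetas: np.ndarray | Sequence[float], q_sig: float = 0.95, q_core: float = 0.99
) -> ThresholdSet:
    """Top-quantile cutoffs over the defined per-locus theta values.

    The cutoff at level q is the k-th largest value with
    k = ceil((1 - q) * L); a locus is flagged iff theta >= cutoff, so
    ties at the cutoff are all flagged (deterministic, order
    independent).  CORE-flagged loci are a subset of SIG-flagged ones.
    """
    if not (0 < q_sig < q_core < 1):
        raise ValueError("need 0 < q_sig < q_core < 1")
    thetas = np.asarray(thetas, dtype=float)
    thetas = thetas[~np.isnan(thetas)]
    L = len(thetas)
    if L == 0:
        raise ValueError("no defined theta values to threshold")
    if L < 100:
        logger.warning("only %d defined loci; top-quantile cutoffs are coarse", L)
    ordered = np.sort(thetas)[::-1]
    # tolerance guards against float artifacts like (1 - 0.99) * 100 > 1
    k_sig = max(1, math.ceil((1 - q_sig) * L - 1e-9))
    k_core = max(1, math.ceil((1 - q_core) * L - 1e-9))
    cut_sig = float(ordered[k_sig - 1])
    cut_core = float(ordered[k_core - 1])
    return ThresholdSet(
        q_sig=cut_sig,
        q_core=cut_core,
        n_flagged_sig=int((thetas >= cut_sig).sum()),
        n_flagged_core=int((thetas >= cut_core).sum()),
    )


def manhattan_table(per_locus: pd.DataFrame, thresholds: ThresholdSet) -> pd.DataFrame:
    """Plot-ready per-SNP table: chrom, pos, locus_id, theta, flag.

    Flag is CORE iff theta >= the top-1% cutoff, SIG iff >= the top-5%
    cutoff, else NONE; undefined-theta loci get NONE with theta left
    NaN (rendered empty in the TSV).  Rows keep genomic order.
    """
    theta = per_locus["theta"].to_numpy(dtype=float)
    flag = np.full(len(theta), FLAG_NONE, dtype=object)
    with np.errstate(invalid="ignore"):
        flag[theta >= thresholds.q_sig] = FLAG_SIG
        flag[theta >= thresholds.q_core] = FLAG_CORE
    out = per_locus[["chrom", "pos", "locus_id", "theta"]].copy()
    out["flag"] = flag
    return out
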