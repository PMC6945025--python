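"""Two-rule scan for differentially selected regions (DSRs) over the
genomically ordered sequence of per-SNP outlier flags.

Flags come from the genome-wide top-quantile thresholds: CORE = top 1%
of theta, SIG = top 5% (CORE implies SIG), NONE otherwise.  Per
chromosome the scanner forms maximal clusters of SIG SNPs in which
consecutive SIG SNPs are separated by at most ``gap_max`` NONE SNPs
(the gap is counted in SNPs, not base pairs):

* Rule 1 (CORE_SEEDED): a cluster containing at least one CORE SNP
  becomes a region bounded by its outermost SIG SNPs.  A lone CORE SNP
  with no SIG neighbours forms a single-SNP region.
* Rule 2 (SIG_RUN): a maximal zero-gap run of at least ``run_min`` SIG
  SNPs containing no CORE also becomes a region ("more than 5
  sequential" reads strictly, so the default run_min is 6).

Region boundaries are the positions of the outermost member SNPs, and
overlapping or SNP-adjacent regions are merged unconditionally (the
merge inherits CORE_SEEDED if any member had it).  Clusters never span
chromosomes.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .diffstat import FLAG_CORE, FLAG_NONE, FLAG_SIG, PerLocusFst, ThresholdSet
from .matrix import chrom_sort_key

_FLAGGED = (FLAG_SIG, FLAG_CORE)

RULE_CORE_SEEDED = "CORE_SEEDED"
RULE_SIG_RUN = "SIG_RUN"


@dataclasses.dataclass
class Region:
    """A detected DSR: a chromosome span over flagged SNPs.

    ``start_index``/``end_index`` are row indices into the flag table
    the scan ran on (inclusive); positions are 1-based inclusive.
    Boundary SNPs are always SIG (possibly CORE).
    """

    chrom: str
    start_pos: int
    end_pos: int
    start_index: int
    end_index: int
    n_snps: int
    n_sig: int
    n_core: int
    max_theta: float
    rule: str

    def __post_init__(self) -> None:
        if self.start_pos > self.end_pos:
            raise ValueError("region start_pos > end_pos")
        if self.rule not in (RULE_CORE_SEEDED, RULE_SIG_RUN):
            raise ValueError(f"unknown rule {self.rule}")


def flag_loci(
    per_locus: Sequence[PerLocusFst] | pd.DataFrame, thresholds: ThresholdSet
) -> list[str]:
    """Per-locus flags from theta and a threshold set (NaN -> NONE)."""
    if isinstance(per_locus, pd.DataFrame):
        thetas = per_locus["theta"].to_numpy(dtype=float)
    else:
        thetas = np.array([x.theta for x in per_locus], dtype=float)
    out = []
    for t in thetas:
        if math.isnan(t):
            out.append(FLAG_NONE)
        elif t >= thresholds.q_core:
            out.append(FLAG_CORE)
        elif t >= thresholds.q_sig:
            out.append(FLAG_SIG)
        else:
            out.append(FLAG_NONE)
    return out


def _clusters(flag_idx: np.ndarray, gap_max: int) -> list[np.ndarray]:
    """Split the sorted indices of flagged SNPs into maximal clusters in
    which consecutive flagged SNPs are <= gap_max unflagged SNPs apart."""
    if len(flag_idx) == 0:
        return []
    breaks = np.flatnonzero(np.diff(flag_idx) > gap_max + 1)
    return np.split(flag_idx, breaks + 1)


def _zero_gap_runs(cluster: np.ndarray) -> list[np.ndarray]:
    breaks = np.flatnonzero(np.diff(cluster) > 1)
    return np.split(cluster, breaks + 1)


def _make_region(
    flags: pd.DataFrame, lo: int, hi: int, rule: str, offset: int
) -> Region:
    """Build a Region over table rows [lo, hi] (chromosome-local)."""
    span = flags.iloc[lo : hi + 1]
    fl = span["flag"].to_numpy()
    theta = span["theta"].to_numpy(dtype=float)
    defined = theta[~np.isnan(theta)]
    return Region(
        chrom=str(span["chrom"].iat[0]),
        start_pos=int(span["pos"].iat[0]),
        end_pos=int(span["pos"].iat[-1]),
        start_index=offset + lo,
        end_index=offset + hi,
        n_snps=hi - lo + 1,
        n_sig=int(np.isin(fl, _FLAGGED).sum()),
        n_core=int((fl == FLAG_CORE).sum()),
        max_theta=float(defined.max()) if len(defined) else math.nan,
        rule=rule,
    )


def _merge(regions: list[Region], flags: pd.DataFrame, offset: int) -> list[Region]:
    """Merge overlapping or SNP-adjacent regions on one chromosome."""
    regions = sorted(regions, key=lambda r: r.start_index)
    out: list[Region] = []
    for r in regions:
        if out and r.start_index <= out[-1].end_index + 1:
            prev = out.pop()
            rule = (
                RULE_CORE_SEEDED
                if RULE_CORE_SEEDED in (prev.rule, r.rule)
                else RULE_SIG_RUN
            )
            out.append(
                _make_region(
                    flags,
                    prev.start_index - offset,
                    max(prev.end_index, r.end_index) - offset,
                    rule,
                    offset,
                )
            )
        else:
            out.append(r)
    return out


def scan_dsrs(
    flags: pd.DataFrame, gap_max: int = 2, run_min: int = 6
) -> list[Region]:
    """Run the two-rule DSR scan over a flag table.

    Parameters
    ----------
    flags
        Per-SNP table with columns chrom, pos, theta, flag in genomic
        order (the output of :func:`dsrscan.diffstat.manhattan_table`).
    gap_max
        Maximum number of consecutive NONE SNPs bridged inside a Rule-1
        cluster; a gap of gap_max + 1 or more terminates it.
    run_min
        Minimum length of a zero-gap, CORE-free SIG run for Rule 2.

    Returns
    -------
    list of Region in genomic order (possibly empty).
    """
    if gap_max < 0 or run_min < 1:
        raise ValueError("need gap_max >= 0 and run_min >= 1")
    regions: list[Region] = []
    offset = 0
    fl_all = flags["flag"].to_numpy()
    chrom_all = flags["chrom"].to_numpy()
    # contiguous per-chromosome blocks, preserving table order
    block_starts = [0] + [
        i for i in range(1, len(flags)) if chrom_all[i] != chrom_all[i - 1]
    ]
    block_bounds = list(zip(block_starts, block_starts[1:] + [len(flags)]))
    for lo, hi in block_bounds:
        sub = flags.iloc[lo:hi]
        fl = fl_all[lo:hi]
        sig_idx = np.flatnonzero(np.isin(fl, _FLAGGED))
        chrom_regions: list[Region] = []
        for cluster in _clusters(sig_idx, gap_max):
            has_core = (fl[cluster] == FLAG_CORE).any()
            if has_core:
                chrom_regions.append(
                    _make_region(sub, int(cluster[0]), int(cluster[-1]),
                                 RULE_CORE_SEEDED, lo)
                )
            else:
                for run in _zero_gap_runs(cluster):
                    if len(run) >= run_min:
                        chrom_regions.append(
                            _make_region(sub, int(run[0]), int(run[-1]),
                                         RULE_SIG_RUN, lo)
                        )
        regions.extend(_merge(chrom_regions, sub, lo))
        offset = hi
    regions.sort(key=lambda r: (chrom_sort_key(r.chrom), r.start_index))
    return regions


def summarize_dsrs(regions: Sequence[Region], label: str | None = None) -> pd.DataFrame:
    """Tabulate regions: chrom, start, end, n_snps, n_sig, n_core,
    max_theta, rule.  The row count is the per-contrast DSR total."""
    rows = [
        {
            "chrom": r.chrom,
            "start": r.start_pos,
            "end": r.end_pos,
            "n_snps": r.n_snps,
            "n_sig": r.n_sig,
            "n_core": r.n_core,
            "max_theta": r.max_theta,
            "rule": r.rule,
        }
        for r in regions
    ]
    df = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "n_snps", "n_sig", "n_core",
                 "max_theta", "rule"],
    )
    if label is not None:
        df.insert(0, "contrast", label)
    return df
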