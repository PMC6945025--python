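"""Balding-Nichols synthetic genotype data with implanted
divergent-selection windows and the ground truth needed for recovery
tests.

Background loci follow the classical Balding-Nichols model: each locus
has an ancestral allele frequency p_anc drawn uniformly from
``anc_freq_range``, and every breed independently draws its own
frequency from Beta(p_anc (1-F)/F, (1-p_anc)(1-F)/F) with
F = ``background_F``, whose variance around p_anc is F p_anc (1-p_anc)
— i.e. F *is* the expected locus-wise F_ST.

Window loci emulate regions *differentially selected* between two
breed groups (``divergent_groups``, e.g. the native pool vs the
control).  Independent high-F draws for the two groups would fix the
same allele in both about half the time, leaving no between-group
signal at half the window SNPs; a differentially selected region
instead diverges the groups in opposite directions.  Window loci
therefore implant the divergence by construction: the two groups'
base frequencies are set to pbar +/- sqrt(F pbar (1-pbar)) — which
makes the parametric between-group F_ST of the bases exactly the
window F — with a random sign per locus deciding which group carries
the high allele, and with pbar equal to p_anc shrunk into the
feasible band [F/(1+F), 1/(1+F)] (a sweep shifts the mean frequency;
outside that band no frequency pair attains the requested F_ST).
Each breed then drifts around its group's base frequency at
``background_F`` (breeds in neither group drift around p_anc as
usual), so realised per-SNP estimates scatter around a value slightly
above the implanted F.

Diploid genotypes are Binomial(2, p_breed) per individual, and calls
are knocked out independently at ``missing_rate``.  Loci are
independent: no linkage disequilibrium is simulated, because every
downstream statistic here is single-SNP.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from typing import Sequence

import numpy as np
import pandas as pd

from .dsr_scan import Region
from .matrix import LOCUS_COLUMNS, MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

#: breed labels used by the canonical desk-scale scenario: seven native
#: breeds pooled as one group plus one commercial control
STANDARD_NATIVE_BREEDS = ("SH", "NDY", "LSX", "XY", "LSF", "LYW", "DLW")
STANDARD_CONTROL_BREED = "Cobb"


@dataclasses.dataclass(frozen=True)
class SimWindow:
    """An implanted elevated-differentiation window: a 0-based inclusive
    SNP-index range on one chromosome with its own F."""

    chrom: str
    start_snp: int
    end_snp: int
    F: float

    def __post_init__(self) -> None:
        if self.start_snp > self.end_snp or self.start_snp < 0:
            raise ValueError("bad window SNP-index range")
        if not (0 < self.F < 1):
            raise ValueError("window F must be in (0, 1)")

    @property
    def n_snps(self) -> int:
        return self.end_snp - self.start_snp + 1


@dataclasses.dataclass
class SimConfig:
    """Simulator parameters (the study conditions, not tuning knobs)."""

    breeds: list[tuple[str, int]]
    n_chrom: int = 5
    snps_per_chrom: int = 4000
    bp_spacing: int = 1000
    anc_freq_range: tuple[float, float] = (0.05, 0.95)
    background_F: float = 0.05
    windows: list[SimWindow] = dataclasses.field(default_factory=list)
    divergent_groups: tuple[tuple[str, ...], tuple[str, ...]] | None = None
    missing_rate: float = 0.05
    missing_rate_by_breed: dict[str, float] = dataclasses.field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.background_F < 1):
            raise ValueError("background_F must be in (0, 1)")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        lo, hi = self.anc_freq_range
        if not (0 < lo < hi < 1):
            raise ValueError("anc_freq_range must satisfy 0 < lo < hi < 1")
        by_chrom: dict[str, list[SimWindow]] = {}
        for w in self.windows:
            if w.end_snp >= self.snps_per_chrom:
                raise ValueError(f"window {w} exceeds chromosome bounds")
            by_chrom.setdefault(w.chrom, []).append(w)
        for chrom, ws in by_chrom.items():
            ws = sorted(ws, key=lambda w: w.start_snp)
            for a, b in zip(ws, ws[1:]):
                if b.start_snp <= a.end_snp:
                    raise ValueError(f"overlapping windows on {chrom}")
        if self.windows:
            if self.divergent_groups is None:
                raise ValueError("windows require divergent_groups")
            ga, gb = (set(g) for g in self.divergent_groups)
            known = {b for b, _ in self.breeds}
            if not ga or not gb or ga & gb or (ga | gb) - known:
                raise ValueError(
                    "divergent_groups must be disjoint non-empty subsets of breeds"
                )

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i}" for i in range(1, self.n_chrom + 1)]

    @property
    def n_loci(self) -> int:
        return self.n_chrom * self.snps_per_chrom


@dataclasses.dataclass
class SimTruth:
    """Ground truth emitted next to the genotypes."""

    loci: pd.DataFrame          # chrom, pos, locus_id, ref, alt, orig_index
    p_anc: np.ndarray           # ancestral frequency per locus
    breed_freqs: pd.DataFrame   # breeds x loci drawn frequencies
    locus_F: np.ndarray         # F used at each locus
    windows: list[SimWindow]

    def window_bounds(self, cfg: SimConfig) -> list[tuple[str, int, int]]:
        """Truth windows as (chrom, start_pos, end_pos) in base pairs."""
        out = []
        for w in self.windows:
            start = (w.start_snp + 1) * cfg.bp_spacing
            end = (w.end_snp + 1) * cfg.bp_spacing
            out.append((w.chrom, start, end))
        return out


_NUC = np.array(list("ACGT"))


def simulate(cfg: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Draw a genotype matrix plus its ground truth from the model."""
    rng = np.random.default_rng(cfg.seed)
    L = cfg.n_loci
    chroms = np.repeat(cfg.chrom_names, cfg.snps_per_chrom)
    snp_in_chrom = np.tile(np.arange(cfg.snps_per_chrom), cfg.n_chrom)
    pos = (snp_in_chrom + 1) * cfg.bp_spacing

    locus_F = np.full(L, cfg.background_F)
    chrom_offset = {c: i * cfg.snps_per_chrom for i, c in enumerate(cfg.chrom_names)}
    for w in cfg.windows:
        lo = chrom_offset[w.chrom] + w.start_snp
        hi = chrom_offset[w.chrom] + w.end_snp
        locus_F[lo : hi + 1] = w.F

    lo, hi = cfg.anc_freq_range
    p_anc = rng.uniform(lo, hi, size=L)

    ref_idx = rng.integers(0, 4, size=L)
    alt_shift = rng.integers(1, 4, size=L)
    ref = _NUC[ref_idx]
    alt = _NUC[(ref_idx + alt_shift) % 4]

    # group-level base frequencies: p_anc outside windows; inside them,
    # a frequency pair pbar +/- sqrt(F pbar qbar) whose parametric
    # between-group F_ST is exactly the window F, sign random per locus
    base_a = p_anc.copy()
    base_b = p_anc.copy()
    win_mask = np.zeros(L, dtype=bool)
    for w in cfg.windows:
        lo_i = chrom_offset[w.chrom] + w.start_snp
        hi_i = chrom_offset[w.chrom] + w.end_snp
        win_mask[lo_i : hi_i + 1] = True
    if win_mask.any():
        f_w = locus_F[win_mask]
        p_bar = np.clip(p_anc[win_mask], f_w / (1 + f_w), 1 / (1 + f_w))
        half_gap = np.sqrt(f_w * p_bar * (1 - p_bar))
        sign = rng.choice([-1.0, 1.0], size=int(win_mask.sum()))
        eps = 1e-9
        base_a[win_mask] = np.clip(p_bar + sign * half_gap, eps, 1 - eps)
        base_b[win_mask] = np.clip(p_bar - sign * half_gap, eps, 1 - eps)
    group_a = set(cfg.divergent_groups[0]) if cfg.divergent_groups else set()
    group_b = set(cfg.divergent_groups[1]) if cfg.divergent_groups else set()

    shape_bg = (1.0 - cfg.background_F) / cfg.background_F
    breed_rows = []
    geno_blocks = []
    sample_ids: list[str] = []
    breed_of: dict[str, str] = {}
    for breed, n_samples in cfg.breeds:
        base = base_a if breed in group_a else base_b if breed in group_b else p_anc
        p_b = rng.beta(base * shape_bg, (1.0 - base) * shape_bg)
        breed_rows.append(p_b)
        g = rng.binomial(2, p_b[None, :], size=(n_samples, L)).astype(np.int8)
        rate = cfg.missing_rate_by_breed.get(breed, cfg.missing_rate)
        if rate > 0:
            g[rng.random((n_samples, L)) < rate] = MISSING
        geno_blocks.append(g)
        for k in range(1, n_samples + 1):
            sid = f"{breed}_{k:02d}"
            sample_ids.append(sid)
            breed_of[sid] = breed

    loci = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "locus_id": [f"{c}:{p}" for c, p in zip(chroms, pos)],
            "ref": ref,
            "alt": alt,
        },
        columns=list(LOCUS_COLUMNS),
    )
    m = GenotypeMatrix(
        sample_ids=sample_ids,
        breed_of=breed_of,
        loci=loci,
        genotypes=np.concatenate(geno_blocks, axis=0),
    )
    truth_loci = loci.copy()
    truth_loci["orig_index"] = np.arange(L)
    truth = SimTruth(
        loci=truth_loci,
        p_anc=p_anc,
        breed_freqs=pd.DataFrame(
            np.stack(breed_rows), index=[b for b, _ in cfg.breeds]
        ),
        locus_F=locus_F,
        windows=list(cfg.windows),
    )
    return m, truth


def standard_scenario() -> SimConfig:
    """The canonical desk-scale scenario used across the test suite:
    8 breeds x 10 samples (seven native + one control), 5 chromosomes x
    4,000 SNPs at 1 kb spacing, background F = 0.05, ten 25-SNP windows
    at F = 0.7 (two per chromosome), 5% missing calls, fixed seed."""
    breeds = [(b, 10) for b in STANDARD_NATIVE_BREEDS]
    breeds.append((STANDARD_CONTROL_BREED, 10))
    windows = []
    for i in range(1, 6):
        windows.append(SimWindow(f"chr{i}", 800, 824, 0.7))
        windows.append(SimWindow(f"chr{i}", 2800, 2824, 0.7))
    return SimConfig(
        breeds=breeds,
        windows=windows,
        divergent_groups=(STANDARD_NATIVE_BREEDS, (STANDARD_CONTROL_BREED,)),
        seed=20191119,
    )


def standard_contrast():
    """The native-pool vs control contrast of the standard scenario."""
    from .diffstat import Contrast

    return Contrast(
        "GX_vs_Cobb", set(STANDARD_NATIVE_BREEDS), {STANDARD_CONTROL_BREED}
    )


# ------------------------------------------------------------------- recovery
def evaluate_recovery(
    regions: Sequence[Region],
    truth: SimTruth,
    cfg: SimConfig,
    min_reciprocal: float = 0.5,
) -> dict:
    """Score detected regions against the truth windows.

    Overlap is measured in original SNP indices (region positions are
    mapped back through the fixed bp spacing).  A (region, window) pair
    matches when the overlap covers at least ``min_reciprocal`` of each
    of the two index spans.  Sensitivity is the fraction of truth
    windows matched by some region; FDR is the fraction of regions
    matching no truth window.
    """
    def snp_span(chrom: str, start_pos: int, end_pos: int) -> tuple[int, int]:
        return (start_pos // cfg.bp_spacing - 1, end_pos // cfg.bp_spacing - 1)

    window_spans = [(w.chrom, w.start_snp, w.end_snp) for w in truth.windows]
    region_spans = [
        (r.chrom, *snp_span(r.chrom, r.start_pos, r.end_pos)) for r in regions
    ]
    matched_windows = set()
    matched_regions = set()
    for wi, (wc, wlo, whi) in enumerate(window_spans):
        for ri, (rc, rlo, rhi) in enumerate(region_spans):
            if rc != wc:
                continue
            inter = min(whi, rhi) - max(wlo, rlo) + 1
            if inter <= 0:
                continue
            if (
                inter >= min_reciprocal * (whi - wlo + 1)
                and inter >= min_reciprocal * (rhi - rlo + 1)
            ):
                matched_windows.add(wi)
                matched_regions.add(ri)
    n_regions = len(regions)
    n_windows = len(window_spans)
    sensitivity = len(matched_windows) / n_windows if n_windows else float("nan")
    fdr = (
        (n_regions - len(matched_regions)) / n_regions if n_regions else float("nan")
    )
    return {
        "n_truth_windows": n_windows,
        "n_regions": n_regions,
        "n_matched_windows": len(matched_windows),
        "n_false_regions": n_regions - len(matched_regions),
        "sensitivity": sensitivity,
        "fdr": fdr,
    }


# -------------------------------------------------------------------- emitter
def write_scenario(
    cfg: SimConfig, out_dir: str | os.PathLike, prefix: str = "sim"
) -> dict[str, str]:
    """Simulate and emit VCF + breed map + truth BED/TSV files."""
    from .variant_io import write_breed_map, write_vcf

    os.makedirs(out_dir, exist_ok=True)
    m, truth = simulate(cfg)
    paths = {
        "vcf": os.path.join(out_dir, f"{prefix}.vcf"),
        "breeds": os.path.join(out_dir, f"{prefix}.breeds.tsv"),
        "truth_bed": os.path.join(out_dir, f"{prefix}.truth.bed"),
        "truth_tsv": os.path.join(out_dir, f"{prefix}.truth.tsv"),
    }
    write_vcf(m, paths["vcf"])
    write_breed_map(m.breed_of, paths["breeds"])
    with open(paths["truth_bed"], "w") as fh:
        for i, (chrom, start, end) in enumerate(truth.window_bounds(cfg), 1):
            fh.write(f"{chrom}\t{start - 1}\t{end}\twindow{i}\t{0}\t.\n")
    cols = truth.loci.copy()
    cols["p_anc"] = truth.p_anc
    cols["locus_F"] = truth.locus_F
    cols.to_csv(paths["truth_tsv"], sep="\t", index=False)
    return paths
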