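"""Region-to-gene annotation, Venn partition of gene sets across
contrasts, and Fisher/Bonferroni term enrichment.

A gene maps to a region iff its span intersects the region span
extended by a configurable flank (default 0 bp) on the same
chromosome.  Enrichment is the one-sided (over-representation)
Fisher's exact test, i.e. the hypergeometric tail P(X >= k), with a
Bonferroni-corrected p reported alongside; the conventional retention
rule keeps terms with fold enrichment > 1 and p < 0.05 (raw p by
default, switchable to the Bonferroni-corrected p).
"""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom

from .dsr_scan import Region
from .variant_io import GeneInterval

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RegionGeneMap:
    """Per-region gene sets for one contrast plus their union."""

    contrast: str
    region_genes: dict[tuple[str, int, int], set[str]]
    genes: set[str]


@dataclasses.dataclass
class VennCounts:
    """The 7 exclusive cells of a three-set Venn partition."""

    labels: tuple[str, str, str]
    a_only: int
    b_only: int
    c_only: int
    ab: int
    ac: int
    bc: int
    abc: int

    @property
    def cells(self) -> dict[str, int]:
        a, b, c = self.labels
        return {
            a: self.a_only,
            b: self.b_only,
            c: self.c_only,
            f"{a}&{b}": self.ab,
            f"{a}&{c}": self.ac,
            f"{b}&{c}": self.bc,
            f"{a}&{b}&{c}": self.abc,
        }

    @property
    def total(self) -> int:
        return sum(
            (self.a_only, self.b_only, self.c_only, self.ab, self.ac, self.bc,
             self.abc)
        )


def annotate_regions(
    regions: Sequence[Region],
    genes: Sequence[GeneInterval],
    flank_bp: int = 0,
    contrast: str = "",
) -> RegionGeneMap:
    """Map each region to the genes it overlaps (flank-extended).

    Gene g maps to region r iff [g.start, g.end] intersects
    [r.start - flank_bp, r.end + flank_bp] on the same chromosome.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        # IntervalTree is half-open; +1 makes the inclusive end queryable
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g.gene_id)
    region_chroms = {r.chrom for r in regions}
    unmatched = region_chroms - set(trees)
    if regions and genes and unmatched:
        tally = Counter(r.chrom for r in regions if r.chrom in unmatched)
        logger.warning(
            "no gene annotations on chromosome(s) %s",
            ", ".join(f"{c} ({n} region(s))" for c, n in sorted(tally.items())),
        )
    region_genes: dict[tuple[str, int, int], set[str]] = {}
    union: set[str] = set()
    for r in regions:
        lo = max(1, r.start_pos - flank_bp)
        hi = r.end_pos + flank_bp
        tree = trees.get(r.chrom)
        hits = {iv.data for iv in tree.overlap(lo, hi + 1)} if tree else set()
        region_genes[(r.chrom, r.start_pos, r.end_pos)] = hits
        union |= hits
    return RegionGeneMap(contrast=contrast, region_genes=region_genes, genes=union)


def venn_counts(
    set_a: set, set_b: set, set_c: set,
    labels: tuple[str, str, str] = ("A", "B", "C"),
) -> VennCounts:
    """Disjoint three-way Venn cells of the given sets."""
    return VennCounts(
        labels=labels,
        a_only=len(set_a - set_b - set_c),
        b_only=len(set_b - set_a - set_c),
        c_only=len(set_c - set_a - set_b),
        ab=len((set_a & set_b) - set_c),
        ac=len((set_a & set_c) - set_b),
        bc=len((set_b & set_c) - set_a),
        abc=len(set_a & set_b & set_c),
    )


def fisher_enrichment(
    study: set[str],
    background: set[str],
    term_map: Mapping[str, Iterable[str]] | pd.DataFrame,
    significant_only: bool = False,
    alpha: float = 0.05,
    min_fold: float = 1.0,
    use_bonferroni: bool = False,
) -> pd.DataFrame:
    """One-sided Fisher (hypergeometric-tail) term over-representation.

    Parameters
    ----------
    study, background
        Gene-id sets with study a subset of background.
    term_map
        gene -> iterable of term ids, or a 2-column DataFrame/TSV table
        (gene_id, term_id) with one row per association.  Genes without
        terms are allowed.
    significant_only
        Keep only rows with fold > ``min_fold`` and p < ``alpha``
        (raw p by default; the Bonferroni-corrected p when
        ``use_bonferroni``).  The Bonferroni column is always reported.

    Returns
    -------
    DataFrame with columns term, k, n, K, N, fold, p, p_bonf, one row
    per term with at least one study hit, sorted by p.
    """
    if not study <= background:
        raise ValueError(
            f"study genes outside the background: {sorted(study - background)[:5]} ..."
        )
    gene_terms = _as_gene_terms(term_map)
    n = len(study)
    N = len(background)
    study_hits: Counter[str] = Counter()
    bg_hits: Counter[str] = Counter()
    for gene in background:
        for term in set(gene_terms.get(gene, ())):
            bg_hits[term] += 1
            if gene in study:
                study_hits[term] += 1
    n_tested = len(study_hits)
    rows = []
    for term, k in study_hits.items():
        K = bg_hits[term]
        fold = (k / n) / (K / N)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, n, K, N, fold, p, min(1.0, p * n_tested)))
    df = pd.DataFrame(
        rows, columns=["term", "k", "n", "K", "N", "fold", "p", "p_bonf"]
    ).sort_values(["p", "term"], kind="stable").reset_index(drop=True)
    if significant_only:
        p_col = "p_bonf" if use_bonferroni else "p"
        df = df[(df["fold"] > min_fold) & (df[p_col] < alpha)].reset_index(drop=True)
    return df


def _as_gene_terms(
    term_map: Mapping[str, Iterable[str]] | pd.DataFrame,
) -> dict[str, list[str]]:
    if isinstance(term_map, pd.DataFrame):
        gene_col, term_col = term_map.columns[:2]
        out: dict[str, list[str]] = {}
        for gene, term in zip(term_map[gene_col], term_map[term_col]):
            out.setdefault(str(gene), []).append(str(term))
        return out
    return {g: list(t) for g, t in term_map.items()}


def read_term_map(path) -> pd.DataFrame:
    """Read a 2-column TSV (gene_id, term_id), one association per row."""
    return pd.read_csv(
        path, sep="\t", header=None, names=["gene_id", "term_id"], dtype=str,
        comment="#",
    )
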