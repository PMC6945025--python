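"""End-to-end orchestration: run one contrast, or all contrasts plus
the cross-contrast Venn partition, writing every stage's outputs under
a contrast-named prefix with a reproducibility manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from typing import Sequence

import pandas as pd

from . import __version__
from .annotation_enrichment import (
    RegionGeneMap,
    VennCounts,
    annotate_regions,
    fisher_enrichment,
    venn_counts,
)
from .diffstat import (
    Contrast,
    ThresholdSet,
    fst_scan,
    manhattan_table,
    theta_quantile_thresholds,
)
from .dsr_scan import Region, scan_dsrs, summarize_dsrs
from .matrix import GenotypeMatrix
from .variant_io import GeneInterval, write_regions_bed

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class ScanSettings:
    """Knobs consumed by the scan stages, with the defaults used
    throughout: genome-wide top 5%/1% flags, gaps of at most 2 NONE
    SNPs bridged, Rule-2 runs of at least 6 SIG SNPs."""

    q_sig: float = 0.95
    q_core: float = 0.99
    gap_max: int = 2
    run_min: int = 6
    flank_bp: int = 0
    enrich_alpha: float = 0.05
    enrich_min_fold: float = 1.0
    enrich_use_bonferroni: bool = False


@dataclasses.dataclass
class ContrastBundle:
    """Everything one contrast produces."""

    contrast: Contrast
    fst: pd.DataFrame
    thresholds: ThresholdSet
    manhattan: pd.DataFrame
    regions: list[Region]
    region_genes: RegionGeneMap | None
    enrichment: pd.DataFrame | None


def run_contrast(
    m: GenotypeMatrix,
    contrast: Contrast,
    settings: ScanSettings | None = None,
    genes: Sequence[GeneInterval] | None = None,
    term_map: pd.DataFrame | None = None,
    background: set[str] | None = None,
) -> ContrastBundle:
    """Per-SNP F_ST -> thresholds -> flags -> DSR scan -> genes -> terms.

    Deterministic for fixed inputs.  Annotation runs only when gene
    intervals are supplied, enrichment only when a term map is too
    (with the background defaulting to all supplied genes).
    """
    settings = settings or ScanSettings()
    logger.info(
        "contrast %s: WC84 theta, top flags at q_sig=%.2f q_core=%.2f, "
        "scanner gap_max=%d run_min=%d (gaps counted in SNPs; ties at the "
        "cutoff all flagged)",
        contrast.label, settings.q_sig, settings.q_core,
        settings.gap_max, settings.run_min,
    )
    per_locus = fst_scan(m, contrast)
    thresholds = theta_quantile_thresholds(
        per_locus["theta"].to_numpy(), q_sig=settings.q_sig, q_core=settings.q_core
    )
    manhattan = manhattan_table(per_locus, thresholds)
    regions = scan_dsrs(
        manhattan, gap_max=settings.gap_max, run_min=settings.run_min
    )
    region_genes = None
    enrichment = None
    if genes is not None:
        region_genes = annotate_regions(
            regions, genes, flank_bp=settings.flank_bp, contrast=contrast.label
        )
        if term_map is not None:
            bg = background if background is not None else {g.gene_id for g in genes}
            enrichment = fisher_enrichment(
                region_genes.genes & bg,
                bg,
                term_map,
                significant_only=False,
                alpha=settings.enrich_alpha,
                min_fold=settings.enrich_min_fold,
                use_bonferroni=settings.enrich_use_bonferroni,
            )
    return ContrastBundle(
        contrast=contrast,
        fst=per_locus,
        thresholds=thresholds,
        manhattan=manhattan,
        regions=regions,
        region_genes=region_genes,
        enrichment=enrichment,
    )


def run_all(
    m: GenotypeMatrix,
    contrasts: Sequence[Contrast],
    settings: ScanSettings | None = None,
    genes: Sequence[GeneInterval] | None = None,
    term_map: pd.DataFrame | None = None,
) -> tuple[dict[str, ContrastBundle], VennCounts | None]:
    """All contrasts plus the Venn partition of their union gene sets
    (three-way when exactly three contrasts are configured)."""
    if len(contrasts) < 1:
        raise ValueError("need at least one contrast")
    bundles = {
        c.label: run_contrast(m, c, settings=settings, genes=genes, term_map=term_map)
        for c in contrasts
    }
    venn = None
    if genes is not None and len(contrasts) == 3:
        labels = tuple(c.label for c in contrasts)
        sets = [bundles[lab].region_genes.genes for lab in labels]
        venn = venn_counts(*sets, labels=labels)
    elif genes is not None and len(contrasts) != 3:
        logger.warning(
            "Venn partition needs exactly 3 contrasts; got %d — skipped",
            len(contrasts),
        )
    return bundles, venn


# ------------------------------------------------------------------- emitting
def write_bundle(bundle: ContrastBundle, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write a contrast's outputs under ``<out_dir>/<label>.*``."""
    os.makedirs(out_dir, exist_ok=True)
    prefix = os.path.join(str(out_dir), bundle.contrast.label)
    paths: dict[str, str] = {}

    paths["fst"] = f"{prefix}.fst.tsv"
    bundle.fst.to_csv(paths["fst"], sep="\t", index=False, float_format="%.10g")

    paths["thresholds"] = f"{prefix}.thresholds.json"
    with open(paths["thresholds"], "w") as fh:
        json.dump(dataclasses.asdict(bundle.thresholds), fh, indent=2)
        fh.write("\n")

    paths["manhattan"] = f"{prefix}.manhattan.tsv"
    bundle.manhattan.to_csv(
        paths["manhattan"], sep="\t", index=False, float_format="%.10g"
    )

    paths["dsr"] = f"{prefix}.dsr.tsv"
    summarize_dsrs(bundle.regions, label=bundle.contrast.label).to_csv(
        paths["dsr"], sep="\t", index=False, float_format="%.10g"
    )
    paths["dsr_bed"] = f"{prefix}.dsr.bed"
    write_regions_bed(bundle.regions, paths["dsr_bed"])

    if bundle.region_genes is not None:
        paths["genes"] = f"{prefix}.genes.tsv"
        with open(paths["genes"], "w") as fh:
            fh.write("chrom\tstart\tend\tgenes\n")
            for (chrom, start, end), gs in bundle.region_genes.region_genes.items():
                fh.write(f"{chrom}\t{start}\t{end}\t{','.join(sorted(gs))}\n")
    if bundle.enrichment is not None:
        paths["enrichment"] = f"{prefix}.enrichment.tsv"
        bundle.enrichment.to_csv(
            paths["enrichment"], sep="\t", index=False, float_format="%.10g"
        )
    return paths


def _sha256(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | os.PathLike,
    config: dict,
    input_paths: dict[str, str],
    seed: int | None = None,
) -> str:
    """Echo the run configuration, package version, seed and input
    checksums so a run is self-describing and auditable."""
    manifest = {
        "dsrscan_version": __version__,
        "seed": seed,
        "config": config,
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in input_paths.items()
            if p and os.path.exists(p)
        },
    }
    path = os.path.join(str(out_dir), "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
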