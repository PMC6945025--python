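"""Read/write the standard formats the pipeline touches.

Reads multi-sample VCF into a :class:`~dsrscan.matrix.GenotypeMatrix`
(biallelic SNPs only), gene intervals from BED or GFF3, and writes the
plumbing formats the pipeline emits (VCF, BED of detected regions).

Coordinate conventions: everything in memory is 1-based inclusive; the
0-based half-open convention is used only at the BED boundary.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .matrix import (
    LOCUS_COLUMNS,
    MISSING,
    GenotypeMatrix,
    default_locus_id,
)

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .dsr_scan import Region

logger = logging.getLogger(__name__)

_NUCLEOTIDES = frozenset("ACGT")


@dataclasses.dataclass(frozen=True)
class GeneInterval:
    """A gene span: 1-based inclusive coordinates, strand in {+, -, .}."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )


# --------------------------------------------------------------------- breeds
def read_breed_map(path: str | os.PathLike) -> dict[str, str]:
    """Read a 2-column TSV (sample_id, breed) into a mapping."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["sample_id", "breed"], dtype=str,
        comment="#",
    )
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in breed map: {dup}")
    return dict(zip(df["sample_id"], df["breed"]))


def write_breed_map(breed_of: dict[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for sample, breed in breed_of.items():
            fh.write(f"{sample}\t{breed}\n")


# ------------------------------------------------------------------------ VCF
def _is_biallelic_snp(ref: str, alts: Sequence[str]) -> bool:
    return (
        len(alts) == 1
        and len(ref) == 1
        and len(alts[0]) == 1
        and ref.upper() in _NUCLEOTIDES
        and alts[0].upper() in _NUCLEOTIDES
        and ref.upper() != alts[0].upper()
    )


def read_vcf(
    path: str | os.PathLike, breed_map: dict[str, str] | str | os.PathLike
) -> GenotypeMatrix:
    """Build a genotype matrix from a VCF 4.x file.

    Only biallelic SNP records are retained; multiallelic records and
    indels are dropped at read time so all downstream allele-frequency
    math stays biallelic.  GT codes map 0/0 -> 0, 0/1 or 1/0 -> 1,
    1/1 -> 2, ./. -> MISSING; phase separators are ignored and half
    calls (e.g. ``0/.``) are treated as MISSING with a logged note.
    Samples absent from ``breed_map`` are dropped with a warning.

    Parameters
    ----------
    path
        VCF file with GT fields.
    breed_map
        Mapping sample_id -> breed, or path to a 2-column TSV of it.

    Returns
    -------
    GenotypeMatrix
        Loci sorted genomically, breed labels attached.
    """
    if not isinstance(breed_map, dict):
        breed_map = read_breed_map(breed_map)

    vcf = VCF(str(path), gts012=False)
    vcf_samples = list(vcf.samples)
    keep = [i for i, s in enumerate(vcf_samples) if s in breed_map]
    dropped = [s for s in vcf_samples if s not in breed_map]
    if dropped:
        logger.warning(
            "dropping %d sample(s) absent from the breed map: %s",
            len(dropped), ", ".join(dropped),
        )
    if not keep:
        raise ValueError("no VCF samples are present in the breed map")
    sample_ids = [vcf_samples[i] for i in keep]

    rows: list[tuple] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    n_half = 0
    for variant in vcf:
        if not _is_biallelic_snp(variant.REF, variant.ALT):
            n_skipped += 1
            continue
        gts = variant.genotypes  # [[allele1, allele2, phased], ...]
        col = np.empty(len(keep), dtype=np.int8)
        for out_i, vcf_i in enumerate(keep):
            a, b = gts[vcf_i][0], gts[vcf_i][1]
            if a < 0 or b < 0:
                if (a < 0) != (b < 0):
                    n_half += 1
                col[out_i] = MISSING
            else:
                col[out_i] = a + b
        locus_id = variant.ID or default_locus_id(variant.CHROM, variant.POS)
        rows.append(
            (variant.CHROM, int(variant.POS), locus_id, variant.REF, variant.ALT[0])
        )
        columns.append(col)
    if n_skipped:
        logger.info("skipped %d non-biallelic-SNP record(s)", n_skipped)
    if n_half:
        logger.warning("treated %d half-call genotype(s) as MISSING", n_half)
    if not rows:
        raise ValueError(f"no biallelic SNP records retained from {path}")

    loci = pd.DataFrame(rows, columns=list(LOCUS_COLUMNS))
    genotypes = np.stack(columns, axis=1)

    dup = loci.duplicated(subset=["chrom", "pos"])
    if dup.any():
        logger.warning(
            "dropping %d record(s) duplicated at the same chrom/pos (keeping first)",
            int(dup.sum()),
        )
        keep_idx = np.flatnonzero(~dup.to_numpy())
        loci = loci.iloc[keep_idx].reset_index(drop=True)
        genotypes = genotypes[:, keep_idx]

    m = GenotypeMatrix(
        sample_ids=sample_ids,
        breed_of={s: breed_map[s] for s in sample_ids},
        loci=loci,
        genotypes=genotypes,
    ).sort_genomic()
    m.validate_order()
    return m


def write_vcf(m: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a genotype matrix as a minimal VCF 4.2 file (GT only)."""
    code_to_gt = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=dsrscan\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        seen: dict[str, None] = {}
        for c in m.loci["chrom"]:
            seen.setdefault(c, None)
        for c in seen:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(m.sample_ids)
            + "\n"
        )
        for j, rec in enumerate(m.locus_records()):
            gts = "\t".join(code_to_gt[int(g)] for g in m.genotypes[:, j])
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.locus_id}\t{rec.ref}\t{rec.alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ------------------------------------------------------------------------ BED
def write_regions_bed(regions: Iterable["Region"], path: str | os.PathLike) -> None:
    """Write detected regions as BED (0-based half-open), sorted, with the
    region's max theta as the score column."""
    from .matrix import chrom_sort_key  # local import to avoid cycle noise

    regions = sorted(regions, key=lambda r: (chrom_sort_key(r.chrom), r.start_pos))
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tmax_theta\trule\n")
        for i, r in enumerate(regions, start=1):
            name = f"DSR{i:04d}"
            theta = "" if r.max_theta is None or np.isnan(r.max_theta) else f"{r.max_theta:.6g}"
            fh.write(
                f"{r.chrom}\t{r.start_pos - 1}\t{r.end_pos}\t{name}\t{theta}\t{r.rule}\n"
            )


def read_gene_intervals(
    path: str | os.PathLike, format_hint: str | None = None
) -> list[GeneInterval]:
    """Read gene intervals from BED (4+ columns) or GFF3.

    BED starts are shifted +1 to the internal 1-based inclusive
    convention.  For GFF3, only rows whose feature type is ``gene`` are
    kept and the id is taken from the ``ID`` or ``gene_id`` attribute
    (an optional ``gene:`` prefix is stripped); genes without an id are
    skipped with a warning.
    """
    fmt = format_hint
    if fmt is None:
        name = str(path).lower()
        if name.endswith((".bed",)):
            fmt = "bed"
        elif name.endswith((".gff", ".gff3")):
            fmt = "gff3"
        else:
            raise ValueError(f"cannot infer format of {path}; pass format_hint")
    fmt = fmt.lower()
    if fmt == "bed":
        return _read_bed_genes(path)
    if fmt in ("gff", "gff3"):
        return _read_gff3_genes(path)
    raise ValueError(f"unknown gene-interval format: {format_hint}")


def _read_bed_genes(path: str | os.PathLike) -> list[GeneInterval]:
    out: list[GeneInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: BED gene line needs >= 4 columns")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
            out.append(GeneInterval(name, chrom, start + 1, end, strand))
    return out


def _gff3_attr(attrs: str, keys: tuple[str, ...]) -> str | None:
    fields = dict(
        kv.split("=", 1) for kv in attrs.strip().split(";") if "=" in kv
    )
    for k in keys:
        if k in fields:
            val = fields[k]
            return val[5:] if val.startswith("gene:") else val
    return None


def _read_gff3_genes(path: str | os.PathLike) -> list[GeneInterval]:
    out: list[GeneInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}:{ln}: GFF3 line needs 9 columns")
            if parts[2] != "gene":
                continue
            gene_id = _gff3_attr(parts[8], ("ID", "gene_id"))
            if gene_id is None:
                logger.warning("%s:%d: gene row without ID/gene_id, skipped", path, ln)
                continue
            strand = parts[6] if parts[6] in "+-" else "."
            out.append(
                GeneInterval(gene_id, parts[0], int(parts[3]), int(parts[4]), strand)
            )
    return out


def write_gene_intervals_bed(
    genes: Iterable[GeneInterval], path: str | os.PathLike
) -> None:
    """Inverse of the BED reader (1-based inclusive -> 0-based half-open)."""
    with open(path, "w") as fh:
        for g in genes:
            strand = g.strand if g.strand in "+-" else "."
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{strand}\n")
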