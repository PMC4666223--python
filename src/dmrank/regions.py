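"""Generation of testing regions: genome tilings and GTF-derived windows.

Tilings partition each chromosome into fixed-width half-open windows
(the final partial window is kept).  Promoter regions are fixed-width
windows anchored at each gene's transcription start site, strand-aware;
both the downstream and the upstream side of the TSS are supported
because annotation conventions differ.  Exon regions come from the same
GTF reader with deduplication of identical intervals across transcripts.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

from .io import Region, RegionSet, read_chrom_sizes

__all__ = ["make_tiles", "promoters_from_gtf", "exons_from_gtf"]

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def make_tiles(chrom_sizes: dict[str, int], window_bp: int) -> RegionSet:
    """Non-overlapping fixed-width windows covering each chromosome.

    Windows are [0, w), [w, 2w), ... per chromosome; a final partial
    window keeps coverage exact, so the tiled bases always sum to the
    genome length.  Window sizes outside the usual 50 bp – 100 kb range
    only warn.
    """
    if window_bp <= 0:
        raise ValueError(f"window_bp must be positive, got {window_bp}")
    if not 50 <= window_bp <= 100_000:
        warnings.warn(
            f"window size {window_bp} bp outside the usual 50 bp - 100 kb range",
            stacklevel=2,
        )
    regions = []
    for chrom in chrom_sizes:
        length = chrom_sizes[chrom]
        for start in range(0, length, window_bp):
            end = min(start + window_bp, length)
            regions.append(Region(chrom, start, end, f"{chrom}:{start}-{end}"))
    return RegionSet(regions)


def _parse_gtf_features(gtf_path: str | Path, feature_type: str):
    """Yield (chrom, start0, end, strand, gene_name) for GTF features.

    GTF is 1-based closed; coordinates are converted to 0-based
    half-open.  ``gene_name`` falls back to ``gene_id`` when absent.
    """
    with open(gtf_path) as fh:
        for line_no, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{gtf_path}:{line_no}: fewer than 9 GTF columns")
            if fields[2] != feature_type:
                continue
            chrom, start, end, strand = fields[0], int(fields[3]) - 1, int(fields[4]), fields[6]
            attrs = dict(_ATTR_RE.findall(fields[8]))
            gene = attrs.get("gene_name") or attrs.get("gene_id")
            if gene is None:
                raise ValueError(
                    f"{gtf_path}:{line_no}: feature without gene_name/gene_id"
                )
            if strand not in ("+", "-"):
                raise ValueError(f"{gtf_path}:{line_no}: gene {gene} without strand")
            yield chrom, start, end, strand, gene


def promoters_from_gtf(
    gtf_path: str | Path,
    span_bp: int = 2000,
    orientation: str = "downstream",
    chrom_sizes: dict[str, int] | str | Path | None = None,
) -> RegionSet:
    """Fixed-width TSS-anchored windows for every gene in a GTF.

    The TSS is the gene start on the plus strand and (end - 1) on the
    minus strand.  ``orientation`` selects which side of the TSS the
    window covers, in the direction of transcription: ``downstream``
    covers [TSS, TSS + span) on plus-strand genes, ``upstream`` covers
    [TSS - span, TSS).  Windows are clamped to [0, chrom length] when
    sizes are given.
    """
    if orientation not in ("downstream", "upstream"):
        raise ValueError(f"orientation must be downstream/upstream, got {orientation!r}")
    if span_bp <= 0:
        raise ValueError("span_bp must be positive")
    if isinstance(chrom_sizes, (str, Path)):
        chrom_sizes = read_chrom_sizes(chrom_sizes)
    regions = []
    seen: set[str] = set()
    for chrom, start, end, strand, gene in _parse_gtf_features(gtf_path, "gene"):
        tss = start if strand == "+" else end - 1
        # downstream includes the TSS base and runs with transcription;
        # upstream excludes it and runs against transcription
        if strand == "+":
            lo, hi = (tss, tss + span_bp) if orientation == "downstream" else (tss - span_bp, tss)
        else:
            lo, hi = (tss - span_bp + 1, tss + 1) if orientation == "downstream" else (tss + 1, tss + span_bp + 1)
        lo = max(0, lo)
        if chrom_sizes is not None and chrom in chrom_sizes:
            hi = min(hi, chrom_sizes[chrom])
        if hi <= lo:
            continue  # window entirely off-chromosome
        name = gene if gene not in seen else f"{gene}@{chrom}:{lo}-{hi}"
        seen.add(gene)
        regions.append(Region(chrom, lo, hi, name, gene_name=gene))
    return RegionSet(regions)


def exons_from_gtf(gtf_path: str | Path) -> RegionSet:
    """All distinct exon intervals, deduplicated across transcripts."""
    seen: dict[tuple[str, int, int], str] = {}
    for chrom, start, end, _strand, gene in _parse_gtf_features(gtf_path, "exon"):
        seen.setdefault((chrom, start, end), gene)
    regions = [
        Region(chrom, start, end, f"{gene}:{chrom}:{start}-{end}", gene_name=gene)
        for (chrom, start, end), gene in sorted(seen.items())
    ]
    return RegionSet(regions)
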