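"""Readers and writers for every on-disk format the pipeline touches.

Formats: BED3/BED4 (tab-separated, 0-based half-open), ``chrom.sizes``
(name<TAB>length), whitespace-delimited HapMap-style genetic maps, VCF 4.x
(via cyvcf2), and the TSV results table with ``NA`` for undefined values.
Every reader rejects malformed input with a line-numbered message; there is
no silent coercion.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

from .intervals import (GenomeAssembly, GenomicInterval, IntervalError,
                        IntervalTrack, merge_intervals)
from .maps import GeneticMap, GeneticMapMarker, MapError
from .records import BWindow, GeneModel, OutgroupStatus, RegionRecord, VariantSite

__all__ = [
    "read_chrom_sizes",
    "read_bed",
    "write_bed",
    "read_genes",
    "read_genetic_map",
    "read_variant_sites",
    "read_b_track",
    "read_outgroup",
    "write_region_table",
    "read_region_table",
    "X_MAP_SCALE",
]

log = logging.getLogger(__name__)

#: Sex-averaging correction for an X-chromosome map estimated without male
#: recombination: X spends 2/3 of its time in females, where all of its
#: recombination happens.
X_MAP_SCALE = 2.0 / 3.0

_SKIP_PREFIXES = ("#", "track", "browser")


def _data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            yield lineno, line


def read_chrom_sizes(path) -> GenomeAssembly:
    sizes: dict[str, int] = {}
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) < 2:
            raise IntervalError(f"{path}:{lineno}: expected 'name<TAB>length', got {line!r}")
        try:
            sizes[fields[0]] = int(fields[1])
        except ValueError:
            raise IntervalError(f"{path}:{lineno}: non-integer length {fields[1]!r}") from None
    return GenomeAssembly(sizes)


def _parse_bed_line(path, lineno: str | int, line: str, min_cols: int = 3) -> list[str]:
    fields = line.split("\t")
    if len(fields) < min_cols:
        raise IntervalError(f"{path}:{lineno}: expected >= {min_cols} tab-separated columns")
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError:
        raise IntervalError(f"{path}:{lineno}: non-integer coordinates {fields[1]!r}/{fields[2]!r}") from None
    if start >= end or start < 0:
        raise IntervalError(f"{path}:{lineno}: invalid interval {fields[0]}:{start}-{end}")
    return fields


def read_bed(path, name: Optional[str] = None, role: str = "user") -> IntervalTrack:
    """Parse a BED3+ file into a normalized track (extra columns ignored)."""
    intervals: list[GenomicInterval] = []
    for lineno, line in _data_lines(path):
        fields = _parse_bed_line(path, lineno, line)
        intervals.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
    return merge_intervals(intervals, name=name or Path(path).stem, role=role)


def write_bed(track: IntervalTrack, path) -> None:
    """Write a normalized track as BED3; coordinates emitted verbatim, so
    ``read_bed(write_bed(t)) == t``."""
    with open(path, "w") as fh:
        for iv in track.intervals():
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_genes(path) -> list[GeneModel]:
    """Gene/transcript spans from BED3+; column 4 (if present) is the name.
    Models are kept unmerged — nearest-edge distances need individual spans."""
    genes: list[GeneModel] = []
    for lineno, line in _data_lines(path):
        fields = _parse_bed_line(path, lineno, line)
        name = fields[3] if len(fields) > 3 else ""
        genes.append(GeneModel(GenomicInterval(fields[0], int(fields[1]), int(fields[2])), name))
    return genes


def _looks_numeric(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_genetic_map(path, x_scale: bool = False, x_chrom: str = "chrX",
                     chrom: Optional[str] = None) -> GeneticMap:
    """Read a whitespace-delimited HapMap-style genetic map.

    Columns: chromosome, position (bp), rate (cM/Mb), cumulative map (cM);
    a 3-column file omits the chromosome, which must then be supplied via
    ``chrom`` (column 1 wins when both are present).  A single header line
    is tolerated.  With ``x_scale``, every rate and cumulative value on
    ``x_chrom`` is multiplied by 2/3; other chromosomes are untouched.
    """
    markers: list[GeneticMapMarker] = []
    last_pos: dict[str, int] = {}
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) < 3:
            raise MapError(f"{path}:{lineno}: expected >= 3 whitespace-delimited columns")
        if len(fields) >= 4 and not _looks_numeric(fields[0]):
            c, rest = fields[0], fields[1:4]
        elif len(fields) == 3:
            if chrom is None:
                raise MapError(f"{path}:{lineno}: 3-column map requires an explicit chromosome")
            c, rest = chrom, fields[:3]
        else:
            c, rest = fields[0], fields[1:4]
        if not all(_looks_numeric(t) for t in rest):
            if lineno == 1 or not markers:
                continue  # header line
            raise MapError(f"{path}:{lineno}: non-numeric map fields {rest!r}")
        pos, rate, cum = int(float(rest[0])), float(rest[1]), float(rest[2])
        if rate < 0:
            raise MapError(f"{path}:{lineno}: negative recombination rate {rate}")
        if c in last_pos and pos <= last_pos[c]:
            raise MapError(f"{path}:{lineno}: non-increasing position {pos} on {c}")
        last_pos[c] = pos
        if x_scale and c == x_chrom:
            rate *= X_MAP_SCALE
            cum *= X_MAP_SCALE
        markers.append(GeneticMapMarker(c, pos, rate, cum))
    return GeneticMap(markers)


def read_variant_sites(path) -> list[VariantSite]:
    """Biallelic SNP sites with allele counts from a VCF.

    When genotypes are present, ``ac``/``an`` are derived from them with
    missing calls excluded from ``an``; otherwise INFO AC/AN is used.
    Monomorphic records and sites with ``an < 2`` are dropped (the latter
    with a warning).  Positions are converted to 0-based.
    """
    from cyvcf2 import VCF

    sites: list[VariantSite] = []
    vcf = VCF(str(path))
    has_samples = len(vcf.samples) > 0
    for variant in vcf:
        if not variant.is_snp or len(variant.ALT) != 1:
            continue
        if has_samples:
            ac = an = 0
            for gt in variant.genotypes:
                for allele in gt[:-1]:  # last element is the phasing flag
                    if allele < 0:
                        continue
                    an += 1
                    if allele == 1:
                        ac += 1
        else:
            ac_info = variant.INFO.get("AC")
            an_info = variant.INFO.get("AN")
            if ac_info is None or an_info is None:
                raise IntervalError(
                    f"{path}: site {variant.CHROM}:{variant.POS} has neither genotypes nor INFO AC/AN")
            ac = int(ac_info[0] if isinstance(ac_info, (tuple, list)) else ac_info)
            an = int(an_info)
        if an < 2:
            log.warning("skipping %s:%d: only %d called chromosomes", variant.CHROM, variant.POS, an)
            continue
        if ac == 0 or ac == an:
            continue  # monomorphic in this sample
        sites.append(VariantSite(variant.CHROM, variant.POS - 1, ac, an))
    return sites


def read_b_track(path, scale_1000: bool = False) -> list[BWindow]:
    """Background-selection B windows from BED4 (value in column 4).

    ``scale_1000`` divides by 1000 for legacy integer-scaled tracks; values
    outside [0, 1] after scaling are rejected.
    """
    windows: list[BWindow] = []
    for lineno, line in _data_lines(path):
        fields = _parse_bed_line(path, lineno, line, min_cols=4)
        try:
            value = float(fields[3])
        except ValueError:
            raise IntervalError(f"{path}:{lineno}: non-numeric B value {fields[3]!r}") from None
        if scale_1000:
            value /= 1000.0
        if not (0.0 <= value <= 1.0):
            raise IntervalError(f"{path}:{lineno}: B value {value} outside [0, 1]")
        windows.append(BWindow(GenomicInterval(fields[0], int(fields[1]), int(fields[2])), value))
    return windows


def read_outgroup(aligned_path, mismatch_path) -> OutgroupStatus:
    """Outgroup alignment status from an 'aligned' BED plus a 'mismatch' BED
    (mismatch must be a subset of aligned)."""
    aligned = read_bed(aligned_path, name="outgroup_aligned")
    mismatch = read_bed(mismatch_path, name="outgroup_mismatch")
    return OutgroupStatus(aligned, mismatch)


# -- results table ------------------------------------------------------

_FIXED_COLS = ["chrom", "start", "end", "length_bp", "dist_gene_bp",
               "dist_gene_cM", "rec_cM_per_Mb", "pi", "b_mean"]
_TAIL_COLS = ["div_raw", "div_jc"]
_NA = "NA"


def _fmt(value, fmt: str = "{:.6g}") -> str:
    if value is None:
        return _NA
    if isinstance(value, int):
        return str(value)
    return fmt.format(value)


def write_region_table(records: Sequence[RegionRecord], path,
                       soft_names: Optional[Sequence[str]] = None) -> None:
    """Write the annotated results TSV; undefined values appear as ``NA``.

    One ``pct_<name>`` column per soft track; ``soft_names`` fixes the
    column set/order, defaulting to the union over records.
    """
    if soft_names is None:
        seen: dict[str, None] = {}
        for rec in records:
            for k in rec.soft_pct:
                seen.setdefault(k)
        soft_names = list(seen)
    cols = _FIXED_COLS + [f"pct_{n}" for n in soft_names] + _TAIL_COLS
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for rec in records:
            row = [rec.chrom, str(rec.interval.start), str(rec.interval.end),
                   str(rec.length), _fmt(rec.dist_gene_bp),
                   _fmt(rec.dist_gene_cM, "{:.8g}"), _fmt(rec.rec_rate),
                   _fmt(rec.pi, "{:.8g}"), _fmt(rec.b_mean)]
            row += [_fmt(rec.soft_pct.get(n), "{:.4f}") for n in soft_names]
            row += [_fmt(rec.div_raw, "{:.8g}"), _fmt(rec.div_jc, "{:.8g}")]
            fh.write("\t".join(row) + "\n")


def _opt_float(token: str) -> Optional[float]:
    return None if token == _NA else float(token)


def read_region_table(path) -> list[RegionRecord]:
    """Read back a TSV written by :func:`write_region_table`."""
    records: list[RegionRecord] = []
    header: Optional[list[str]] = None
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if header is None:
            header = fields
            if header[:3] != ["chrom", "start", "end"]:
                raise IntervalError(f"{path}:{lineno}: unrecognized region-table header")
            continue
        if len(fields) != len(header):
            raise IntervalError(f"{path}:{lineno}: expected {len(header)} columns, got {len(fields)}")
        row = dict(zip(header, fields))
        rec = RegionRecord(
            GenomicInterval(row["chrom"], int(row["start"]), int(row["end"])),
            dist_gene_bp=None if row["dist_gene_bp"] == _NA else int(float(row["dist_gene_bp"])),
            dist_gene_cM=_opt_float(row["dist_gene_cM"]),
            rec_rate=_opt_float(row["rec_cM_per_Mb"]),
            pi=_opt_float(row["pi"]),
            b_mean=_opt_float(row["b_mean"]),
            soft_pct={k[4:]: float(v) for k, v in row.items()
                      if k.startswith("pct_") and v != _NA},
            div_raw=_opt_float(row["div_raw"]),
            div_jc=_opt_float(row["div_jc"]),
        )
        records.append(rec)
    if header is None:
        raise IntervalError(f"{path}: empty region table (missing header)")
    return records
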