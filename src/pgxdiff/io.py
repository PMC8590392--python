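"""Readers and writers for the formats the pipeline touches.

VCF parsing is delegated to :mod:`cyvcf2`; only biallelic-SNP decomposition
and dosage extraction are done here.  Tabular inputs (panel, reference
frequencies, annotations) are plain tab-separated files read with pandas.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .types import (
    MISSING,
    Annotation,
    AnnotationTable,
    ReferenceFrequencySet,
    SamplePanel,
    VariantRecord,
    is_autosome,
)

logger = logging.getLogger(__name__)

_SNP_BASES = frozenset("ACGT")


class VcfFormatError(ValueError):
    """Raised when a VCF cannot be parsed."""


class PanelError(ValueError):
    """Raised for panel problems (duplicates, missing samples)."""


@dataclass
class VcfScan:
    """Result of scanning a VCF: decomposed SNP records plus accounting."""

    records: list[VariantRecord] = field(default_factory=list)
    n_non_snp_skipped: int = 0
    n_multiallelic_decomposed: int = 0
    n_non_autosomal: int = 0

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def read_vcf(path: str | os.PathLike, panel: SamplePanel) -> VcfScan:
    """Read biallelic SNP records from a VCF, decomposing multi-allelic sites.

    Every VCF sample column must appear in *panel*.  Multi-allelic sites are
    split into one record per alternate allele; at a decomposed record, a
    sample carrying a different alternate allele is treated as missing.
    Non-SNP alternate alleles (indels, symbolic alleles) are skipped and
    counted.  Records are returned sorted by (chrom, pos).
    """
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise VcfFormatError(f"cannot open VCF {path}: {exc}") from exc

    vcf_samples = list(vcf.samples)
    missing = [s for s in vcf_samples if s not in panel]
    if missing:
        raise PanelError(
            f"VCF samples absent from panel: {', '.join(missing[:5])}"
            + (" ..." if len(missing) > 5 else "")
        )
    # map VCF column order -> panel order
    order = np.asarray([vcf_samples.index(s) for s in panel.samples if s in vcf_samples])
    if len(order) != len(panel.samples):
        absent = [s for s in panel.samples if s not in vcf_samples]
        raise PanelError(f"panel samples absent from VCF: {', '.join(absent[:5])}")

    scan = VcfScan()
    try:
        for v in vcf:
            alts = v.ALT or []
            ref = v.REF
            ref_is_base = len(ref) == 1 and ref in _SNP_BASES
            # allele index (per GT) for each sample pair
            gts = np.asarray(v.genotype.array())  # shape (n, ploidy+1); last col = phased flag
            a1 = gts[:, 0]
            a2 = gts[:, 1]
            snp_alts = [
                (i + 1, alt)
                for i, alt in enumerate(alts)
                if len(alt) == 1 and alt in _SNP_BASES and ref_is_base and alt != ref
            ]
            scan.n_non_snp_skipped += len(alts) - len(snp_alts)
            if not snp_alts:
                continue
            if len(alts) > 1:
                scan.n_multiallelic_decomposed += 1
            if not is_autosome(v.CHROM):
                scan.n_non_autosomal += 1
                logger.warning("non-autosomal record at %s:%d", v.CHROM, v.POS)
            for alt_index, alt in snp_alts:
                dosage = np.full(len(vcf_samples), MISSING, dtype=np.int8)
                called = (a1 >= 0) & (a2 >= 0)
                # alleles other than REF and this ALT make the call missing here
                foreign = called & (
                    ((a1 != 0) & (a1 != alt_index)) | ((a2 != 0) & (a2 != alt_index))
                )
                ok = called & ~foreign
                dosage[ok] = (a1[ok] == alt_index).astype(np.int8) + (
                    a2[ok] == alt_index
                ).astype(np.int8)
                rsid = v.ID if v.ID not in (None, ".", "") else None
                scan.records.append(
                    VariantRecord(
                        chrom=v.CHROM,
                        pos=v.POS,
                        rsid=rsid,
                        ref=ref,
                        alt=alt,
                        genotypes=dosage[order],
                    )
                )
    except VcfFormatError:
        raise
    except Exception as exc:
        raise VcfFormatError(f"malformed VCF {path}: {exc}") from exc

    scan.records.sort(key=VariantRecord.sort_key)
    logger.info(
        "read %d SNP records from %s (%d non-SNP alleles skipped, %d multi-allelic sites decomposed)",
        len(scan.records),
        path,
        scan.n_non_snp_skipped,
        scan.n_multiallelic_decomposed,
    )
    return scan


def write_vcf(records: list[VariantRecord], panel: SamplePanel, path: str | os.PathLike) -> None:
    """Write biallelic SNP records as an uncompressed VCF v4.2 file.

    Dosages are rendered as unphased genotypes (0/0, 0/1, 1/1, ./.); phasing
    is not represented because no downstream stage consumes it.
    """
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = []
        for rec in records:
            if rec.chrom not in chroms:
                chroms.append(rec.chrom)
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples)
            + "\n"
        )
        for rec in sorted(records, key=VariantRecord.sort_key):
            gts = "\t".join(gt_map[int(g)] for g in rec.genotypes)
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.rsid or '.'}\t{rec.ref}\t{rec.alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_panel(path: str | os.PathLike) -> SamplePanel:
    """Read a tab-separated sample panel (sample, population[, super_population])."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise PanelError(f"panel file {path} is empty") from exc
    if df.shape[1] < 2:
        raise PanelError(f"panel file {path} needs >= 2 tab-separated columns")
    entries = []
    for row in df.itertuples(index=False):
        sample, pop = row[0], row[1]
        super_pop = row[2] if df.shape[1] > 2 and pd.notna(row[2]) else None
        if pd.isna(sample) or pd.isna(pop) or not str(pop):
            raise PanelError(f"incomplete panel row: {tuple(row)}")
        entries.append((str(sample), str(pop), super_pop))
    try:
        return SamplePanel(entries)
    except ValueError as exc:
        raise PanelError(str(exc)) from exc


def write_panel(panel: SamplePanel, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for sample, (pop, super_pop) in panel.items():
            fh.write(f"{sample}\t{pop}" + (f"\t{super_pop}" if super_pop else "") + "\n")


def read_reference_frequencies(path: str | os.PathLike) -> ReferenceFrequencySet:
    """Read a reference-frequency table: variant key, population, alt freq, allele number."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={0: str, 1: str},
        names=["variant", "population", "frequency", "allele_number"],
        header=0,
        comment="#",
    )
    refs = ReferenceFrequencySet()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        freq = float(row.frequency)
        if not 0.0 <= freq <= 1.0:
            raise ValueError(
                f"{path} line {i}: frequency {freq} for {row.variant}/{row.population} "
                "outside [0, 1]"
            )
        refs.add(str(row.variant), str(row.population), freq, int(row.allele_number))
    return refs


def write_reference_frequencies(refs: ReferenceFrequencySet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("variant\tpopulation\tfrequency\tallele_number\n")
        for key in refs._data:
            for pop, entry in refs._data[key].items():
                fh.write(f"{key}\t{pop}\t{entry.frequency:.10g}\t{entry.allele_number}\n")


def read_annotations(path: str | os.PathLike) -> AnnotationTable:
    """Read an annotation table: rsid, gene, consequence, cadd, pharmgkb flag."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    required = {"rsid", "gene", "consequence", "cadd", "pharmgkb"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation table {path} must have columns {sorted(required)}")
    table = AnnotationTable()
    for row in df.itertuples(index=False):
        cadd = None if pd.isna(row.cadd) or row.cadd == "" else float(row.cadd)
        pharmgkb = str(row.pharmgkb).strip().lower() in ("1", "true", "yes")
        table.add(str(row.rsid), Annotation(str(row.gene), str(row.consequence), cadd, pharmgkb))
    return table


def write_annotations(table: AnnotationTable, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("rsid\tgene\tconsequence\tcadd\tpharmgkb\n")
        for rsid, ann in table.items():
            cadd = "" if ann.cadd is None else f"{ann.cadd:.10g}"
            fh.write(f"{rsid}\t{ann.gene}\t{ann.consequence}\t{cadd}\t{int(ann.pharmgkb)}\n")


#: fixed rendering widths for report columns (Fst tables show 2 d.p.)
_FLOAT_FORMATS = {
    "chi2_forward": "{:.4f}",
    "chi2_reverse": "{:.4f}",
    "chi2_total": "{:.4f}",
    "p_value": "{:.3e}",
    "theta": "{:.2f}",
    "a": "{:.6g}",
    "b": "{:.6g}",
    "c": "{:.6g}",
    "frequency": "{:.6g}",
    "maf": "{:.6g}",
}


def write_report_table(
    rows: pd.DataFrame,
    path: str | os.PathLike,
    float_formats: dict[str, str] | None = None,
) -> None:
    """Write a deterministic TSV report.

    Columns keep the frame's order; rows are sorted by (chrom, pos) when those
    columns exist, else by all columns.  Statistic columns get fixed decimal
    rendering (chi-square 4 d.p., p-values scientific 3 s.f., theta 2 d.p.)
    so repeated writes are byte-identical.
    """
    df = rows.copy()
    if {"chrom", "pos"}.issubset(df.columns):
        from .types import chromosome_sort_key

        df["_ck"] = df["chrom"].map(lambda c: chromosome_sort_key(str(c)))
        df = df.sort_values(["_ck", "pos"], kind="mergesort").drop(columns="_ck")
    else:
        df = df.sort_values(list(df.columns), kind="mergesort")
    formats = dict(_FLOAT_FORMATS)
    formats.update(float_formats or {})
    out = df.copy()
    for col, fmt in formats.items():
        if col in out.columns:
            out[col] = out[col].map(
                lambda x, fmt=fmt: "" if pd.isna(x) else fmt.format(float(x))
            )
    out.to_csv(path, sep="\t", index=False)
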