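"""Reading and writing the standard formats the pipeline touches.

VCF I/O goes through :mod:`pysam`; everything else (FAM pedigrees, GMT gene
sets, gene lists, association tables) is plain delimited text.  Functional
annotations travel as INFO keys whose names are configurable — the defaults
are ``GENE``, ``IMPACT``, ``CADD``, ``AF_GNOMAD`` and ``AF_1KG``.  Absent
annotations stay absent (``None``) at this layer; the classifier decides
their semantics.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Optional

import pysam

from .model import (
    AssociationRow,
    ChCall,
    Genotype,
    HaCall,
    PathwayCollection,
    Pedigree,
    SiteKey,
    Trio,
    VariantCohort,
    VariantRecord,
    normalize_chrom,
)


class VcfParseError(ValueError):
    """A malformed VCF header or data line."""


class MultiallelicSiteError(VcfParseError):
    """A data line with more than one ALT allele, in strict biallelic mode."""


class FamValidationError(ValueError):
    """A pedigree row that violates FAM semantics."""


@dataclass(frozen=True)
class AnnotationKeys:
    """INFO key names carrying the functional annotations."""

    gene: str = "GENE"
    impact: str = "IMPACT"
    cadd: str = "CADD"
    maf_gnomad: str = "AF_GNOMAD"
    maf_1kg: str = "AF_1KG"


DEFAULT_KEYS = AnnotationKeys()


def _info_scalar(info, key: str):
    if key not in info:
        return None
    value = info[key]
    if isinstance(value, tuple):
        value = value[0] if value else None
    return value


def read_vcf(
    path: str | os.PathLike,
    annotation_keys: AnnotationKeys = DEFAULT_KEYS,
    multiallelic: str = "error",
) -> VariantCohort:
    """Read a VCF 4.x file into a :class:`VariantCohort`.

    Parameters
    ----------
    multiallelic:
        ``"error"`` raises :class:`MultiallelicSiteError` on the first line
        with more than one ALT allele; ``"mark"`` skips such lines but
        records their positions in ``cohort.multiallelic_positions`` so the
        preprocessing step can purge every record at those positions.

    ``|``-separated genotypes are parsed as phased, ``/`` as unphased, and
    ``.`` alleles as missing.  Sample order is preserved.
    """
    if multiallelic not in ("error", "mark"):
        raise ValueError("multiallelic must be 'error' or 'mark'")
    try:
        vcf = pysam.VariantFile(os.fspath(path))
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"cannot parse VCF header of {path}: {exc}") from exc
    samples = list(vcf.header.samples)
    sites: list[tuple[VariantRecord, dict[str, Optional[Genotype]]]] = []
    multiallelic_positions: set[tuple[str, int]] = set()
    # data lines start right after the header
    lineno = str(vcf.header).count("\n")
    with vcf:
        while True:
            lineno += 1
            try:
                rec = next(vcf, None)
            except (ValueError, OSError) as exc:
                raise VcfParseError(f"malformed VCF data line {lineno} in {path}: {exc}") from exc
            if rec is None:
                break
            alts = rec.alts or ()
            chrom = normalize_chrom(rec.chrom)
            if len(alts) != 1:
                if multiallelic == "error":
                    raise MultiallelicSiteError(
                        f"line {lineno} at {rec.chrom}:{rec.pos} has {len(alts)} ALT alleles; "
                        "expected a normalized biallelic record"
                    )
                multiallelic_positions.add((chrom, rec.pos))
                continue
            info = rec.info
            try:
                record = VariantRecord(
                    chrom=chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alts[0],
                    gene=_info_scalar(info, annotation_keys.gene),
                    impact=_info_scalar(info, annotation_keys.impact),
                    cadd=_maybe_float(_info_scalar(info, annotation_keys.cadd)),
                    maf_gnomad=_maybe_float(_info_scalar(info, annotation_keys.maf_gnomad)),
                    maf_1kg=_maybe_float(_info_scalar(info, annotation_keys.maf_1kg)),
                )
            except ValueError as exc:
                raise VcfParseError(f"invalid record on line {lineno} of {path}: {exc}") from exc
            genotypes: dict[str, Optional[Genotype]] = {}
            for sample in samples:
                fmt = rec.samples[sample]
                gt = fmt.get("GT", (None, None))
                if gt is None or len(gt) == 0:
                    gt = (None, None)
                if len(gt) == 1:  # haploid call: treat second allele as missing
                    gt = (gt[0], None)
                phased = bool(fmt.phased) and None not in gt
                genotypes[sample] = Genotype(gt[0], gt[1], phased=phased)
            sites.append((record, genotypes))
    return VariantCohort(samples=samples, sites=sites, multiallelic_positions=multiallelic_positions)


def _maybe_float(value) -> Optional[float]:
    return None if value is None else float(value)


def _build_header(
    samples: Iterable[str], contigs: Iterable[str], annotation_keys: AnnotationKeys
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for contig in contigs:
        header.contigs.add(contig)
    header.info.add(annotation_keys.gene, 1, "String", "Gene symbol(s), comma separated")
    header.info.add(annotation_keys.impact, 1, "String", "Predicted impact severity class")
    header.info.add(annotation_keys.cadd, 1, "Float", "Scaled CADD deleteriousness score")
    header.info.add(annotation_keys.maf_gnomad, 1, "Float", "gnomAD minor allele frequency")
    header.info.add(annotation_keys.maf_1kg, 1, "Float", "1000 Genomes minor allele frequency")
    header.formats.add("GT", 1, "String", "Genotype")
    for sample in samples:
        header.add_sample(sample)
    return header


def write_vcf(
    path: str | os.PathLike,
    cohort: VariantCohort,
    annotation_keys: AnnotationKeys = DEFAULT_KEYS,
) -> None:
    """Write a cohort as an uncompressed VCF, preserving phase separators."""
    contigs = sorted(
        {record.chrom for record, _ in cohort.sites},
        key=lambda c: (0, int(c)) if c.isdigit() else (1, c),
    )
    if not contigs:
        contigs = [str(c) for c in range(1, 23)]
    header = _build_header(cohort.samples, contigs, annotation_keys)
    with pysam.VariantFile(os.fspath(path), "w", header=header) as out:
        for record, genotypes in cohort.sites:
            rec = out.new_record(
                contig=record.chrom,
                start=record.pos - 1,
                alleles=(record.ref, record.alt),
            )
            rec.id = None
            if record.gene is not None:
                rec.info[annotation_keys.gene] = record.gene
            if record.impact is not None:
                rec.info[annotation_keys.impact] = record.impact
            if record.cadd is not None:
                rec.info[annotation_keys.cadd] = record.cadd
            if record.maf_gnomad is not None:
                rec.info[annotation_keys.maf_gnomad] = record.maf_gnomad
            if record.maf_1kg is not None:
                rec.info[annotation_keys.maf_1kg] = record.maf_1kg
            for sample in cohort.samples:
                gt = genotypes.get(sample)
                if gt is None:
                    gt = Genotype(None, None)
                rec.samples[sample]["GT"] = (gt.a, gt.b)
                rec.samples[sample].phased = gt.phased
            out.write(rec)


def read_fam(path: str | os.PathLike) -> Pedigree:
    """Parse a 6-column PLINK FAM file into a :class:`Pedigree`.

    Columns: family id, sample id, father id, mother id, sex, phenotype
    (2 = affected).  A parent id of ``0`` marks an unknown parent; samples
    with any unknown parent are listed as non-trio.
    """
    pedigree = Pedigree()
    seen: set[str] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 6:
                raise FamValidationError(
                    f"line {lineno} of {path}: expected 6 whitespace-delimited columns, "
                    f"got {len(fields)}"
                )
            family_id, sample_id, father_id, mother_id, _sex, phenotype = fields
            if sample_id in seen:
                raise FamValidationError(
                    f"line {lineno} of {path}: duplicated sample id {sample_id!r}"
                )
            seen.add(sample_id)
            if sample_id in (father_id, mother_id):
                raise FamValidationError(
                    f"line {lineno} of {path}: sample {sample_id!r} listed as its own parent"
                )
            if father_id == "0" or mother_id == "0":
                pedigree.non_trio_samples.append(sample_id)
                continue
            if father_id == mother_id:
                raise FamValidationError(
                    f"line {lineno} of {path}: mother and father of {sample_id!r} are identical"
                )
            pedigree.trios.append(
                Trio(
                    family_id=family_id,
                    child=sample_id,
                    mother=mother_id,
                    father=father_id,
                    affected=phenotype == "2",
                )
            )
    return pedigree


def write_fam(path: str | os.PathLike, pedigree: Pedigree) -> None:
    with open(path, "w") as handle:
        for trio in pedigree.trios:
            phenotype = "2" if trio.affected else "1"
            handle.write(
                f"{trio.family_id}\t{trio.child}\t{trio.father}\t{trio.mother}\t0\t{phenotype}\n"
            )
        for sample in pedigree.non_trio_samples:
            handle.write(f"{sample}\t{sample}\t0\t0\t0\t1\n")


def read_gene_sets(path: str | os.PathLike) -> PathwayCollection:
    """Read GMT-format pathway gene sets (name, description, genes...)."""
    pathways: dict[str, frozenset[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"line {lineno} of {path}: GMT lines need name, description and "
                    f">= 1 gene, got {len(fields)} fields"
                )
            name = fields[0]
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise ValueError(f"line {lineno} of {path}: pathway {name!r} has no genes")
            pathways[name] = genes
    return PathwayCollection(pathways=pathways)


def read_gene_list(path: str | os.PathLike) -> frozenset[str]:
    """Read a plain gene-list file (first whitespace-delimited column)."""
    genes: set[str] = set()
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            genes.add(line.split()[0])
    return frozenset(genes)


def read_association_table(path: str | os.PathLike) -> list[AssociationRow]:
    """Read a tab-separated association-score table.

    Header columns: entity, disease, score, kind (GDA or VDA).
    """
    rows: list[AssociationRow] = []
    with open(path) as handle:
        header = handle.readline()
        if not header:
            return rows
        columns = [c.strip().lower() for c in header.rstrip("\n").split("\t")]
        expected = ["entity", "disease", "score", "kind"]
        if columns[:4] != expected:
            raise ValueError(f"{path}: expected header columns {expected}, got {columns}")
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"line {lineno} of {path}: expected 4 columns")
            try:
                rows.append(
                    AssociationRow(
                        entity=fields[0],
                        disease=fields[1],
                        score=float(fields[2]),
                        kind=fields[3].strip().upper(),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"line {lineno} of {path}: {exc}") from exc
    return rows


def _format_site(site: SiteKey) -> str:
    return "{}:{}:{}:{}".format(*site)


def _parse_site(text: str) -> SiteKey:
    chrom, pos, ref, alt = text.split(":")
    return (chrom, int(pos), ref, alt)


def write_calls(path: str | os.PathLike, calls: Iterable) -> None:
    """Write CH/HA calls as a TSV (sample, gene, kind, site_a, site_b)."""
    with open(path, "w") as handle:
        handle.write("sample\tgene\tkind\tsite_a\tsite_b\n")
        for call in calls:
            if isinstance(call, ChCall):
                handle.write(
                    f"{call.sample}\t{call.gene}\tCH\t"
                    f"{_format_site(call.site_maternal)}\t{_format_site(call.site_paternal)}\n"
                )
            elif isinstance(call, HaCall):
                handle.write(f"{call.sample}\t{call.gene}\tHA\t{_format_site(call.site)}\t\n")
            else:
                raise TypeError(f"cannot serialise call of type {type(call).__name__}")


def read_calls(path: str | os.PathLike) -> list:
    """Read a call TSV written by :func:`write_calls`."""
    calls: list = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header[:3] != ["sample", "gene", "kind"]:
            raise ValueError(f"{path}: unrecognised call-table header {header}")
        for line in handle:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4 or not fields[0]:
                continue
            sample, gene, kind = fields[0], fields[1], fields[2]
            if kind == "CH":
                calls.append(
                    ChCall(
                        sample=sample,
                        gene=gene,
                        site_maternal=_parse_site(fields[3]),
                        site_paternal=_parse_site(fields[4]),
                    )
                )
            elif kind == "HA":
                calls.append(HaCall(sample=sample, gene=gene, site=_parse_site(fields[3])))
            else:
                raise ValueError(f"{path}: unknown call kind {kind!r}")
    return calls
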