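"""Reading and writing the pipeline's on-disk formats.

A cohort is persisted as three files sharing a prefix: a minimal VCF v4.2
(GT-only genotypes), a phenotype TSV (sample_id, label, age, pack_years) and a
site-annotation TSV (gene, functional class, site QC metrics). Gene-set
collections are read from GMT. All formats are plain text.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .errors import InputError
from .simulate import NOCALL, Cohort

ANNOTATION_COLUMNS = [
    "variant_id", "chrom", "pos", "ref", "alt", "gene",
    "func_class", "var_type", "DP", "FS", "SOR",
]

_GT_BY_CODE = {NOCALL: (None, None), 0: (0, 0), 1: (0, 1), 2: (1, 1)}


def _split_variant_id(variant_id: str) -> tuple[str, int, str, str]:
    try:
        chrom, pos, ref, alt = variant_id.split(":")
        return chrom, int(pos), ref, alt
    except ValueError:
        raise InputError(
            f"variant_id {variant_id!r} is not chrom:pos:ref:alt"
        ) from None


def write_cohort(cohort: Cohort, annotations: pd.DataFrame, prefix: str | Path):
    """Write ``<prefix>.vcf``, ``<prefix>.pheno.tsv`` and ``<prefix>.anno.tsv``.

    The VCF carries GT only; no-calls serialise as ``./.``. The annotation
    table must cover exactly the cohort's variant panel.

    Returns the three paths written.
    """
    prefix = str(prefix)
    anno_ids = list(annotations["variant_id"])
    if anno_ids != list(cohort.variant_ids):
        if set(anno_ids) == set(cohort.variant_ids):
            annotations = (
                annotations.set_index("variant_id")
                .loc[cohort.variant_ids]
                .reset_index()
            )
        else:
            raise InputError(
                "annotation table and cohort cover different variant panels"
            )

    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    contigs = list(dict.fromkeys(_split_variant_id(v)[0] for v in cohort.variant_ids))
    for contig in contigs:
        header.contigs.add(contig)
    for s in cohort.sample_ids:
        header.add_sample(s)

    vcf_path = prefix + ".vcf"
    with pysam.VariantFile(vcf_path, "w", header=header) as vcf:
        for j, vid in enumerate(cohort.variant_ids):
            chrom, pos, ref, alt = _split_variant_id(vid)
            rec = vcf.new_record(
                contig=chrom, start=pos - 1, stop=pos - 1 + len(ref),
                alleles=(ref, alt), id=vid,
            )
            col = cohort.genotypes[:, j]
            for i, s in enumerate(cohort.sample_ids):
                rec.samples[s]["GT"] = _GT_BY_CODE[int(col[i])]
                rec.samples[s].phased = False
            vcf.write(rec)

    pheno = pd.DataFrame(
        {
            "sample_id": cohort.sample_ids,
            "label": cohort.labels,
            "age": cohort.age,
            "pack_years": cohort.pack_years,
        }
    )
    pheno_path = prefix + ".pheno.tsv"
    pheno.to_csv(pheno_path, sep="\t", index=False)

    anno_path = prefix + ".anno.tsv"
    annotations.to_csv(anno_path, sep="\t", index=False)
    return vcf_path, pheno_path, anno_path


def _code_from_gt(gt) -> int:
    if gt is None or any(a is None for a in gt):
        return NOCALL
    alt_count = sum(1 for a in gt if a == 1)
    return alt_count


def read_cohort(prefix: str | Path) -> tuple[Cohort, pd.DataFrame]:
    """Read a cohort written by :func:`write_cohort`; inverse round-trip.

    Returns ``(cohort, annotations)``. Multi-allelic records are rejected:
    sites must be pre-split into biallelic records.
    """
    prefix = str(prefix)
    pheno = pd.read_csv(prefix + ".pheno.tsv", sep="\t")
    annotations = pd.read_csv(prefix + ".anno.tsv", sep="\t")

    variant_ids: list[str] = []
    columns: list[np.ndarray] = []
    with pysam.VariantFile(prefix + ".vcf") as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if len(rec.alts or ()) != 1:
                raise InputError(
                    f"record {rec.chrom}:{rec.pos} is not biallelic; "
                    "split multi-allelic sites before ingestion"
                )
            vid = rec.id or f"{rec.chrom}:{rec.pos}:{rec.ref}:{rec.alts[0]}"
            variant_ids.append(vid)
            columns.append(
                np.array(
                    [_code_from_gt(rec.samples[s].get("GT")) for s in samples],
                    dtype=np.int8,
                )
            )
    geno = np.column_stack(columns) if columns else np.zeros((len(samples), 0), np.int8)

    pheno = pheno.set_index("sample_id").loc[samples].reset_index()
    cohort = Cohort(
        sample_ids=samples,
        labels=pheno["label"].to_numpy(dtype=object),
        genotypes=geno,
        variant_ids=variant_ids,
        age=pheno["age"].to_numpy(dtype=float),
        pack_years=pheno["pack_years"].to_numpy(dtype=float),
    )
    return cohort, annotations


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    # keep_default_na: the status value "null" is data, not a missing cell
    return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read gene-set collections from GMT (name, description, genes...)."""
    collections: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            collections[fields[0]] = {g for g in fields[2:] if g}
    if not collections:
        raise InputError(f"no gene sets found in {os.fspath(path)}")
    return collections


def write_gmt(collections: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collections.items():
            fh.write("\t".join([name, name] + sorted(genes)) + "\n")
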