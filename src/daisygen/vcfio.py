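"""VCF reading and writing (VCFv4.2, GT + AD + DP).

The writer emits plain-text VCF; the reader is a thin wrapper around
cyvcf2 that keeps only biallelic SNPs and converts GT to 0/1/2 dosages.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
from cyvcf2 import VCF

from .datatypes import MISSING, AlleleDepthTable, GenotypeDataset

log = logging.getLogger(__name__)

_HEADER = """\
##fileformat=VCFv4.2
##source=daisygen
##contig=<ID=1>
##INFO=<ID=NS,Number=1,Type=Integer,Description="Number of samples with data">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""

_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(ds: GenotypeDataset, depths: AlleleDepthTable | None, path: str | Path) -> None:
    """Write calls (and read depths, if given) as an uncompressed VCFv4.2 file.

    Sites are placed on a single synthetic contig at 1-based consecutive
    positions; REF/ALT are fixed to A/T (the analyses depend only on
    allele identity, not sequence context).
    """
    if depths is not None and depths.ref_reads.shape != ds.calls.shape:
        raise ValueError("depth table shape does not match calls")
    path = Path(path)
    n, m = ds.calls.shape
    with open(path, "w") as fh:
        fh.write(_HEADER)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, ds.sample_ids))
            + "\n"
        )
        fmt = "GT:AD:DP" if depths is not None else "GT"
        for j in range(m):
            fields = []
            for i in range(n):
                gt = _GT[int(ds.calls[i, j])]
                if depths is None:
                    fields.append(gt)
                else:
                    r = int(depths.ref_reads[i, j])
                    a = int(depths.alt_reads[i, j])
                    fields.append(f"{gt}:{r},{a}:{r + a}")
            ns = int((ds.calls[:, j] != MISSING).sum())
            fh.write(
                f"1\t{j + 1}\t{ds.site_ids[j]}\tA\tT\t.\tPASS\tNS={ns}\t{fmt}\t"
                + "\t".join(fields)
                + "\n"
            )


def read_vcf(path: str | Path) -> tuple[GenotypeDataset, AlleleDepthTable | None]:
    """Read a VCF into a GenotypeDataset (biallelic SNPs only).

    Multiallelic or non-SNP records are skipped (count logged).  Missing
    genotypes ("./.") become -1.  Returns an AlleleDepthTable when the
    file carries AD, otherwise None.  Locality/group labels are left
    empty; they come from the sample metadata table, not the VCF.
    """
    vcf = VCF(str(path))
    samples = np.array(vcf.samples)
    calls_cols: list[np.ndarray] = []
    ref_cols: list[np.ndarray] = []
    alt_cols: list[np.ndarray] = []
    site_ids: list[str] = []
    n_skipped = 0
    has_ad = True
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        gt = np.asarray(rec.gt_types)
        # cyvcf2 codes: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
        col = np.where(gt == 0, 0, np.where(gt == 1, 1, np.where(gt == 3, 2, MISSING)))
        calls_cols.append(col.astype(np.int8))
        site_ids.append(rec.ID if rec.ID else f"{rec.CHROM}:{rec.POS}")
        if has_ad:
            try:
                ad = rec.format("AD")
            except KeyError:
                ad = None
            if ad is None:
                has_ad = False
            else:
                ad = np.asarray(ad)
                ref_cols.append(np.maximum(ad[:, 0], 0).astype(np.int32))
                alt_cols.append(np.maximum(ad[:, 1], 0).astype(np.int32))
    if n_skipped:
        log.info("skipped %d non-biallelic/non-SNP records", n_skipped)
    if not calls_cols:
        raise ValueError(f"no biallelic SNP records in {path}")
    calls = np.column_stack(calls_cols)
    n = calls.shape[0]
    ds = GenotypeDataset(
        calls=calls,
        sample_ids=samples,
        locality_labels=np.array([""] * n),
        group_labels=np.array([], dtype=str),
        coordinates=np.zeros((n, 2)),
        site_ids=np.array(site_ids),
    )
    depths = None
    if has_ad and ref_cols:
        depths = AlleleDepthTable(np.column_stack(ref_cols), np.column_stack(alt_cols))
    return ds, depths
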