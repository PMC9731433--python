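"""Readers and writers for the pipeline's file formats.

All genomic files follow the standard dialects: VCF positions are 1-based,
every BED output is 0-based half-open.  Tract files use a 6-column BED-like
layout (chrom, start, end, sample, hap_index, ancestry); segmentations are
4-column BEDs (chrom, start, end, state), one file per cell type, named by
the cell-type id.
"""

from __future__ import annotations

import io as _stdio
from pathlib import Path

import numpy as np
import pandas as pd

TRACT_COLUMNS = ["chrom", "start", "end", "sample", "hap_index", "ancestry"]


# ---------------------------------------------------------------------------
# VCF


def vcf_text(cohort) -> str:
    """Render a cohort as a VCF v4.2 document (phased diploid GTs)."""
    buf = _stdio.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write(f"##contig=<ID={cohort.chrom},length={cohort.chrom_length}>\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
    buf.write("\t".join(cohort.samples) + "\n")
    code = {-1: ".", 0: "0", 1: "1"}
    for i, pos in enumerate(cohort.positions):
        row = cohort.geno[i]
        gts = "\t".join(
            f"{code[int(row[2 * s])]}|{code[int(row[2 * s + 1])]}"
            for s in range(len(cohort.samples))
        )
        buf.write(
            f"{cohort.chrom}\t{pos}\t.\t{cohort.ref[i]}\t{cohort.alt[i]}\t.\tPASS\t.\tGT\t{gts}\n"
        )
    return buf.getvalue()


def read_vcf(path):
    """Load a phased VCF into (chrom, samples, positions, ref, alt, geno).

    ``geno`` is (n_sites, 2 * n_samples) int8 with -1 for missing alleles.
    Multiallelic records are kept (alt = first alternative; alleles beyond
    the first alt are coded as missing) so the biallelic filter downstream
    can count and exclude them.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms, positions, refs, alts, rows = [], [], [], [], []
    multiallelic = []
    for rec in vcf:
        chroms.append(rec.CHROM)
        positions.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0] if rec.ALT else ".")
        multiallelic.append(len(rec.ALT) > 1)
        gt = np.asarray(rec.genotype.array())[:, :2].reshape(-1).astype(np.int8)
        gt[gt > 1] = -1  # second-alt alleles treated as missing
        rows.append(gt)
    geno = np.array(rows, dtype=np.int8) if rows else np.zeros((0, 2 * len(samples)), np.int8)
    return {
        "chrom": chroms[0] if chroms else None,
        "samples": samples,
        "positions": np.array(positions, dtype=np.int64),
        "ref": np.array(refs),
        "alt": np.array(alts),
        "geno": geno,
        "multiallelic": np.array(multiallelic, dtype=bool),
    }


# ---------------------------------------------------------------------------
# Tables


def write_tracts(tracts: pd.DataFrame, path) -> None:
    tracts[TRACT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_tracts(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=TRACT_COLUMNS,
        dtype={"chrom": str, "sample": str},
    )


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_ancestral(path) -> pd.DataFrame:
    """Ancestral-allele TSV (chrom, pos, allele); malformed rows raise with
    their line number."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "allele": str})
    bad = ~df["allele"].isin(list("ACGT.")) | df["pos"].isna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +header +1-based
        raise ValueError(f"{path}: malformed ancestral-allele row at line {line}")
    return df


# ---------------------------------------------------------------------------
# Segmentations / BED


def write_segmentations(segmentations: dict[str, pd.DataFrame], outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for cell_type, seg in segmentations.items():
        safe = seg.copy()
        safe["state"] = safe["state"].str.replace("/", "_")
        safe[["chrom", "start", "end", "state"]].to_csv(
            outdir / f"{cell_type}.bed", sep="\t", header=False, index=False
        )


def read_segmentations(indir) -> dict[str, pd.DataFrame]:
    from .states import normalize_state

    out = {}
    for path in sorted(Path(indir).glob("*.bed")):
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "start", "end", "state"]
        )
        df["state"] = df["state"].map(normalize_state)
        out[path.stem] = df
    return out


def write_bed(df: pd.DataFrame, path, extra_cols=()) -> None:
    cols = ["chrom", "start", "end", *extra_cols]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, extra_cols=()) -> pd.DataFrame:
    names = ["chrom", "start", "end", *extra_cols]
    return pd.read_csv(path, sep="\t", header=None, names=names)


# ---------------------------------------------------------------------------
# FASTA / motifs


def write_fasta(sequences: dict[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    seqio_write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    from Bio.SeqIO import parse

    return {rec.id: str(rec.seq) for rec in parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Cohort bundle


def write_cohort(cohort, outdir) -> None:
    """Write the full input bundle of a simulated cohort to ``outdir``."""
    outdir = Path(outdir)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)
    (outdir / "cohort.vcf").write_text(vcf_text(cohort))
    write_tracts(cohort.tracts, outdir / "tracts.bed")
    write_table(cohort.ancestral, outdir / "ancestral.tsv")
    write_table(cohort.altai, outdir / "altai.tsv")
    write_table(cohort.outgroup, outdir / "outgroup_freqs.tsv")
    write_table(cohort.truth, outdir / "truth" / "variants.tsv")
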