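"""Readers and writers for the formats the pipeline exchanges.

FASTA/FASTQ go through Biopython; the repeat and SNV VCFs are written as
plain VCF 4.2 text and read back with pysam; tables are TSV via pandas
(tolerant of CRLF and leading ``#`` comment lines carrying the config hash).
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genotype import SampleGenotype
from .simulate import REPEAT_CHROM, REPEAT_POS, AmpliconRead, HaplotypeDefinition

DEFAULT_QUAL = 40  # constant HiFi-like Phred quality for simulated reads


def config_hash(obj) -> str:
    """Short stable hash of a config's repr, stamped into every output."""
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def write_reference_fasta(refs: list[HaplotypeDefinition], path, header_note: str = "") -> None:
    records = [
        SeqRecord(Seq(r.sequence), id=r.name, description=f"length={r.length} {header_note}".strip())
        for r in refs
    ]
    SeqIO.write(records, str(path), "fasta")


def read_reference_fasta(path) -> list[HaplotypeDefinition]:
    return [HaplotypeDefinition(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fastq(reads: list[AmpliconRead], path) -> None:
    records = []
    for read in reads:
        rec = SeqRecord(Seq(read.sequence), id=read.id, description="")
        rec.letter_annotations["phred_quality"] = [DEFAULT_QUAL] * len(read.sequence)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path) -> list[AmpliconRead]:
    """Parse a FASTQ into reads; sample id recovered from the ``sample/readNNNN`` id scheme."""
    reads = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
            sample_id = rec.id.split("/")[0]
            reads.append(
                AmpliconRead(
                    id=rec.id,
                    sequence=str(rec.seq),
                    orientation="+",
                    sample_id=sample_id,
                    true_allele="unknown",
                )
            )
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ record near record {len(reads) + 1} "
                         f"(line ~{4 * len(reads) + 1}): {exc}") from exc
    return reads


def write_truth_table(reads: list[AmpliconRead], path, header_comment: str = "") -> None:
    df = pd.DataFrame(
        {
            "read_id": [r.id for r in reads],
            "sample_id": [r.sample_id for r in reads],
            "true_allele": [r.true_allele for r in reads],
            "orientation": [r.orientation for r in reads],
            "is_chimera": [r.is_chimera for r in reads],
        }
    )
    write_table(df, path, header_comment)


# ---------------------------------------------------------------------------
# TSV


def write_table(df: pd.DataFrame, path, header_comment: str = "") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_bed(coords: pd.DataFrame, path, header_comment: str = "") -> None:
    """BED (0-based half-open): chrom, start, end, name."""
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        coords[["chrom", "start", "end", "feature"]].to_csv(fh, sep="\t", index=False, header=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "feature"])
    if (df["end"] <= df["start"]).any():
        bad = int(np.argmax((df["end"] <= df["start"]).to_numpy())) + 1
        raise ValueError(f"invalid BED interval at line {bad}")
    return df


# ---------------------------------------------------------------------------
# VCF

_VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID={chrom}>
{extra}##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_repeat_vcf(genotypes: list[SampleGenotype], path, hash_note: str = "") -> None:
    """Multi-sample VCF with the repeat as symbolic ALT alleles and lengths in INFO/ALLENS.

    ALT alleles are the distinct consensus length classes across the cohort
    (<TR1>, <TR2>, ...); FORMAT carries GT plus per-sample allele lengths (AL)
    and supporting-read counts (SD). QC-failed or uncalled samples get ./. .
    """
    called = [g for g in genotypes if g.allele_calls]
    distinct = sorted({length for g in called for length in g.allele_lengths})
    alt_of = {length: i + 1 for i, length in enumerate(distinct)}
    extra = (
        '##INFO=<ID=ALLENS,Number=A,Type=Integer,Description="Repeat allele length per ALT">\n'
        '##FORMAT=<ID=AL,Number=.,Type=Integer,Description="Allele lengths">\n'
        '##FORMAT=<ID=SD,Number=.,Type=Integer,Description="Supporting reads per allele">\n'
    )
    if hash_note:
        extra = f"##config={hash_note}\n" + extra
    lines = [_VCF_HEADER.format(chrom=REPEAT_CHROM, extra=extra).rstrip()]
    sample_ids = [g.sample_id for g in genotypes]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\t" + "FORMAT\t" + "\t".join(sample_ids))
    alt_field = ",".join(f"<TR{i}>" for i in range(1, len(distinct) + 1)) or "."
    info = "ALLENS=" + ",".join(str(l) for l in distinct) if distinct else "."
    cells = []
    for g in genotypes:
        if not g.allele_calls or not g.qc_pass:
            cells.append("./.:.:.")
            continue
        lens = g.allele_lengths
        gt = "/".join(str(alt_of[l]) for l in sorted(lens))
        supports = [c.support for c in g.allele_calls]
        cells.append(f"{gt}:{','.join(str(l) for l in sorted(set(lens)))}:{','.join(map(str, supports))}")
    lines.append(
        f"{REPEAT_CHROM}\t{REPEAT_POS}\tSNCA_CTrich\tN\t{alt_field}\t.\tPASS\t{info}\tGT:AL:SD\t"
        + "\t".join(cells)
    )
    Path(path).write_text("\n".join(lines) + "\n")


def write_snv_vcf(dosages: pd.DataFrame, positions: pd.DataFrame, path) -> None:
    """Biallelic SNV VCF from a sample x SNV 0/1/2 dosage frame (NaN -> ./.)."""
    pos = positions.set_index("variant") if "variant" in positions.columns else positions
    lines = [_VCF_HEADER.format(chrom=REPEAT_CHROM, extra="").rstrip()]
    samples = list(dosages.index)
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    gt_of = {0: "0/0", 1: "0/1", 2: "1/1"}
    for snv in dosages.columns:
        chrom = pos.loc[snv, "chrom"] if snv in pos.index else REPEAT_CHROM
        p = int(pos.loc[snv, "pos"]) if snv in pos.index else REPEAT_POS
        cells = [
            "./." if pd.isna(d) else gt_of[int(d)] for d in dosages[snv]
        ]
        lines.append(f"{chrom}\t{p}\t{snv}\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf_dosages(path) -> pd.DataFrame:
    """Read ALT-allele dosages (0/1 -> 1, 1/1 -> 2, ./. -> NaN) from a VCF via pysam."""
    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    data = {}
    for rec in vcf:
        dosages = []
        for s in samples:
            gt = rec.samples[s].get("GT")
            if gt is None or any(a is None for a in gt):
                dosages.append(np.nan)
            else:
                dosages.append(float(sum(1 for a in gt if a and a > 0)))
        data[rec.id or f"{rec.chrom}:{rec.pos}"] = dosages
    return pd.DataFrame(data, index=samples)
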