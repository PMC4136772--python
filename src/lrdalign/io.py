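"""File formats: FASTA/FASTQ readers, TSV and minimal SAM writers,
manifest and truth tables.

FASTA/FASTQ parsing goes through Biopython's ``SeqIO``; sequences are
uppercased on ingest and FASTQ qualities are discarded.  Alignment
results are written primarily as TSV (read_id, ref_id, strand, 0-based
position, lrd, aligned) and optionally as a minimal SAM dialect
(FLAG 0/16/4, 1-based POS, ``<L>M`` CIGAR for aligned reads, the LRD
value in the ``rd:i`` tag).
"""

from __future__ import annotations

import csv
from pathlib import Path

from Bio import SeqIO

from .aligner import AlignmentResult
from .rankdist import Sequence, revcomp
from .simulate import GenomeRecord, SimulatedRead

ALIGNMENT_COLUMNS = ["read_id", "ref_id", "strand", "position_0based", "lrd", "aligned"]
TRUTH_COLUMNS = ["read_id", "genome_id", "start_0based", "strand"]


def read_fasta(path: str | Path) -> list[Sequence]:
    """All records of a FASTA file, uppercased; empty file -> empty list."""
    return _read_seqio(path, "fasta")


def read_fastq(path: str | Path) -> list[Sequence]:
    """All records of a FASTQ file; qualities are parsed and discarded."""
    return _read_seqio(path, "fastq")


def _read_seqio(path: str | Path, fmt: str) -> list[Sequence]:
    out = []
    try:
        for rec in SeqIO.parse(str(path), fmt):
            out.append(Sequence(rec.id, str(rec.seq)))
    except ValueError as exc:
        raise ValueError(f"malformed {fmt} record in {path}: {exc}") from exc
    return out


def write_fasta(seqs: list[Sequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.bases), width):
                fh.write(s.bases[i : i + width] + "\n")


def write_fastq(seqs: list[Sequence], path: str | Path) -> None:
    """FASTQ with a flat maximal quality string (qualities are synthetic)."""
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f"@{s.id}\n{s.bases}\n+\n{'I' * len(s.bases)}\n")


def write_alignments(
    results: list[AlignmentResult],
    path: str | Path,
    format: str = "tsv",
    reads: dict[str, Sequence] | None = None,
    references: list[Sequence] | None = None,
) -> None:
    """Write alignment results as TSV (default) or minimal SAM.

    SAM output needs the read sequences (for SEQ) and the reference
    sequences (for the @SQ header lines).
    """
    if format == "tsv":
        _write_tsv(results, path)
    elif format == "sam":
        if reads is None or references is None:
            raise ValueError("SAM output requires reads and references")
        _write_sam(results, path, reads, references)
    else:
        raise ValueError(f"unknown alignment format {format!r}")


def _write_tsv(results: list[AlignmentResult], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(ALIGNMENT_COLUMNS)
        for r in results:
            pos = "" if r.position is None else r.position
            w.writerow(
                [r.read_id, r.reference_id, r.strand, pos,
                 int(r.distance), int(r.aligned)]
            )


def read_alignments_tsv(path: str | Path) -> list[AlignmentResult]:
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            pos = int(row["position_0based"]) if row["position_0based"] else None
            out.append(
                AlignmentResult(
                    row["read_id"], row["ref_id"], pos, row["strand"],
                    float(row["lrd"]), bool(int(row["aligned"])),
                )
            )
    return out


def _write_sam(
    results: list[AlignmentResult],
    path: str | Path,
    reads: dict[str, Sequence],
    references: list[Sequence],
) -> None:
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for ref in references:
            fh.write(f"@SQ\tSN:{ref.id}\tLN:{len(ref)}\n")
        for r in results:
            seq = reads[r.read_id].bases
            if not r.aligned:
                fh.write(
                    f"{r.read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t*\trd:i:{int(r.distance)}\n"
                )
                continue
            flag = 16 if r.strand == "-" else 0
            if r.strand == "-":
                seq = revcomp(seq)  # SEQ is stored on the forward reference strand
            fh.write(
                f"{r.read_id}\t{flag}\t{r.reference_id}\t{r.position + 1}\t255\t"
                f"{len(seq)}M\t*\t0\t0\t{seq}\t*\trd:i:{int(r.distance)}\n"
            )


def write_truth(reads: list[SimulatedRead], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(TRUTH_COLUMNS)
        for r in reads:
            w.writerow([r.read.id, r.source_genome_id, r.source_start, r.strand])


def read_truth(path: str | Path) -> dict[str, dict[str, str]]:
    """Truth table keyed by read id; values keep the column names."""
    out: dict[str, dict[str, str]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out[row["read_id"]] = row
    return out


def write_manifest(records: list[GenomeRecord], directory: str | Path,
                   manifest_name: str = "manifest.tsv") -> Path:
    """Write each genome to its own FASTA under ``directory`` plus a
    manifest TSV (genome_id, order_label, group_id, fasta_path)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / manifest_name
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["genome_id", "order_label", "group_id", "fasta_path"])
        for rec in records:
            fa = directory / f"{rec.genome_id}.fa"
            write_fasta([rec.sequence], fa)
            w.writerow([rec.genome_id, rec.order, rec.group_id, str(fa)])
    return manifest


def read_manifest(path: str | Path) -> list[GenomeRecord]:
    """Load a manifest TSV; relative FASTA paths resolve against the
    manifest's directory."""
    base = Path(path).parent
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            fa = Path(row["fasta_path"])
            if not fa.is_absolute():
                fa = base / fa
            seqs = read_fasta(fa)
            if not seqs:
                raise ValueError(f"no sequence in {fa}")
            records.append(
                GenomeRecord(
                    row["genome_id"], row["order_label"],
                    seqs[0], row.get("group_id") or row["genome_id"],
                )
            )
    return records
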