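"""File formats: taxonomy-headed FASTA, paired FASTQ, manifests, tables.

Reference FASTA headers follow the convention

    >ID taxonomy=Family;Genus;Species [circular]

with semicolon-separated ranks and an optional ``[circular]`` token.
Records without a taxonomy token are readable (for pipeline input) but are
rejected wherever a reference database is required.  Gzipped FASTQ is
auto-detected by magic bytes, not by extension.  Proportion tables are TSV
with three columns per sample group (Contigs, %, Haplotypes), percent to
three decimals, totals row last.
"""

from __future__ import annotations

import gzip
import io as _io
import json
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .pipeline import ProportionTable, ReadPair, RepresentativeHaplotype
from .primers import ReferenceRecord


def parse_taxonomy_header(header: str) -> ReferenceRecord:
    """Parse a FASTA header line into an (empty-sequence) record.

    The sequence is filled in by the FASTA reader; this function only
    interprets the header.  A malformed taxonomy token (wrong rank count)
    is an error naming the header; a missing token yields a record with
    ``taxonomy=None``.
    """
    header = header.lstrip(">").strip()
    if not header:
        raise ValueError("empty FASTA header")
    tokens = header.split()
    rec_id = tokens[0]
    taxonomy = None
    circular = False
    for tok in tokens[1:]:
        if tok.startswith("taxonomy="):
            ranks = tok[len("taxonomy="):].split(";")
            if len(ranks) != 3 or not all(r.strip() for r in ranks):
                raise ValueError(
                    f"malformed taxonomy token in header {header!r}: "
                    "expected taxonomy=Family;Genus;Species"
                )
            taxonomy = tuple(r.strip() for r in ranks)
        elif tok == "[circular]":
            circular = True
    return ReferenceRecord(id=rec_id, sequence="", taxonomy=taxonomy,
                           circular=circular)


def format_taxonomy_header(rec: ReferenceRecord) -> str:
    parts = [rec.id]
    if rec.taxonomy:
        # species may contain spaces; genus/family must not
        fam, gen, sp = rec.taxonomy
        parts.append(f"taxonomy={fam};{gen};{sp.replace(' ', '_')}")
    if rec.circular:
        parts.append("[circular]")
    return " ".join(parts)


def read_reference_fasta(path: str | Path, require_taxonomy: bool = False
                         ) -> list[ReferenceRecord]:
    """Read a taxonomy-headed FASTA into reference records."""
    records = []
    seen = set()
    for seqrec in SeqIO.parse(str(path), "fasta"):
        header = seqrec.description
        parsed = parse_taxonomy_header(header)
        if parsed.taxonomy:
            fam, gen, sp = parsed.taxonomy
            parsed.taxonomy = (fam, gen, sp.replace("_", " "))
        if require_taxonomy and parsed.taxonomy is None:
            raise ValueError(
                f"record {parsed.id} lacks taxonomy and cannot join a "
                "reference database"
            )
        if parsed.id in seen:
            raise ValueError(f"duplicate record id {parsed.id}")
        seen.add(parsed.id)
        parsed.sequence = str(seqrec.seq).upper().replace("U", "T")
        records.append(parsed)
    return records


def write_reference_fasta(records: Iterable[ReferenceRecord], path: str | Path
                          ) -> None:
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.id,
                  description=format_taxonomy_header(r)[len(r.id):].strip())
        for r in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


def write_representatives_fasta(reps: Iterable[RepresentativeHaplotype],
                                path: str | Path) -> None:
    with open(path, "w") as fh:
        for rep in reps:
            fh.write(f">{rep.name.replace(' ', '_')} "
                     f"identity={rep.taxon.identity:.3f} "
                     f"category={rep.taxon.category}\n{rep.sequence}\n")


def _open_maybe_gzip(path: str | Path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_paired_fastq(path1: str | Path, path2: str | Path, group: str
                      ) -> Iterator[ReadPair]:
    """Stream read pairs from two (optionally gzipped) FASTQ files."""
    with _open_maybe_gzip(path1) as f1, _open_maybe_gzip(path2) as f2:
        it1 = SeqIO.parse(f1, "fastq")
        it2 = SeqIO.parse(f2, "fastq")
        for r1, r2 in zip(it1, it2, strict=True):
            yield ReadPair(
                id=r1.id,
                seq1=str(r1.seq).upper(),
                qual1=r1.letter_annotations["phred_quality"],
                seq2=str(r2.seq).upper(),
                qual2=r2.letter_annotations["phred_quality"],
                group=group,
            )


def write_paired_fastq(pairs: Iterable[ReadPair], path1: str | Path,
                       path2: str | Path) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for rp in pairs:
            for fh, seq, qual in ((f1, rp.seq1, rp.qual1), (f2, rp.seq2, rp.qual2)):
                rec = SeqRecord(Seq(seq), id=rp.id, description="")
                rec.letter_annotations["phred_quality"] = list(qual)
                SeqIO.write(rec, fh, "fastq")


def read_manifest(path: str | Path) -> list[tuple[str, Path, Path]]:
    """Read a (group, fastq1, fastq2) TSV manifest; paths resolve relative
    to the manifest's directory."""
    base = Path(path).parent
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3 or not fields[0]:
                raise ValueError(f"manifest line {ln}: expected group<TAB>fastq1<TAB>fastq2")
            group, f1, f2 = fields
            rows.append((group, base / f1, base / f2))
    return rows


def write_proportion_table(table: ProportionTable, path: str | Path) -> None:
    """Write the per-group Contigs / % / Haplotypes TSV, totals row last."""
    groups = table.groups
    percents = table.percents
    with open(path, "w") as fh:
        header = ["Taxon"]
        for g in groups:
            header += [f"{g}:Contigs", f"{g}:%", f"{g}:Haplotypes"]
        fh.write("\t".join(header) + "\n")
        for name in table.contigs.index:
            row = [name]
            for g in groups:
                row += [
                    str(int(table.contigs.at[name, g])),
                    f"{percents.at[name, g]:.3f}",
                    str(int(table.haplotypes.at[name, g])),
                ]
            fh.write("\t".join(row) + "\n")
        totals = ["Total"]
        for g in groups:
            total = int(table.totals[g])
            totals += [
                str(total),
                f"{100.0 if total else 0.0:.3f}",
                str(int(table.haplotypes[g].sum())),
            ]
        fh.write("\t".join(totals) + "\n")


def read_proportion_table(path: str | Path) -> ProportionTable:
    """Read back a proportion-table TSV (inverse of the writer)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = df.drop(index="Total")
    df.index.name = None
    groups = []
    for col in df.columns:
        g = col.rsplit(":", 1)[0]
        if g not in groups:
            groups.append(g)
    contigs = pd.DataFrame({g: df[f"{g}:Contigs"].astype(int) for g in groups})
    haps = pd.DataFrame({g: df[f"{g}:Haplotypes"].astype(int) for g in groups})
    return ProportionTable(contigs=contigs, haplotypes=haps)


def write_run_manifest(path: str | Path, config, stage_counts: dict,
                       inputs: dict[str, str]) -> None:
    """Machine-readable record of a run: config echo, inputs, stage counts."""
    from dataclasses import asdict

    payload = {
        "config": asdict(config),
        "inputs": inputs,
        "stage_counts": stage_counts,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
        fh.write("\n")
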