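"""File formats: FASTA, BED, TSV tables.

FASTA is read/written through Bio.SeqIO (wrapped at 60 columns).  BED is
6-column, 0-based half-open, with the feature name in column 4 and strand in
column 6 (score unused).  Matrices and tag tables are plain TSV with a
header row.  All round-trips are lossless for the alphabets used here.
"""

from __future__ import annotations

import os

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .assay import GenotypeMatrix, HaplotypeCall
from .region import AnnotatedRegion
from .tags import OligoSet, Tag


def write_fasta(path: str | os.PathLike, regions: list[AnnotatedRegion]) -> None:
    records = [
        SeqRecord(Seq(r.seq), id=r.name, description="") for r in regions
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> list[AnnotatedRegion]:
    return [
        AnnotatedRegion(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_bed(path: str | os.PathLike, region: AnnotatedRegion,
              kinds: tuple[str, ...] | None = None) -> None:
    with open(path, "w") as fh:
        for f in sorted(region.features, key=lambda f: (f.start, f.end)):
            if kinds and f.kind not in kinds:
                continue
            fh.write(
                f"{region.name}\t{f.start}\t{f.end}\t{f.name}\t0\t{f.strand}\n"
            )


def read_bed(path: str | os.PathLike) -> list[tuple[str, int, int, str, str]]:
    """(chrom, start, end, name, strand) tuples; intervals 0-based half-open."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            strand = fields[5] if len(fields) > 5 else "+"
            out.append((chrom, start, end, name, strand))
    return out


def write_matrix_tsv(path: str | os.PathLike, matrix: GenotypeMatrix) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="sperm")


def read_matrix_tsv(path: str | os.PathLike, donor: str = "donor") -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GenotypeMatrix(
        donor=donor,
        sperm_ids=[str(i) for i in df.index],
        tags=[str(c) for c in df.columns],
        detected=df.to_numpy(dtype=bool),
    )


def write_haplotype_table(
    path: str | os.PathLike, calls: list[HaplotypeCall], ordered_tags: list[str]
) -> None:
    """Tags × haplotype-column table in the field's +/ud/- notation."""
    data = {f"{c.donor}/{c.label}": [c.statuses[t] for t in ordered_tags] for c in calls}
    pd.DataFrame(data, index=pd.Index(ordered_tags, name="tag")).to_csv(path, sep="\t")


def read_haplotype_table(path: str | os.PathLike) -> list[HaplotypeCall]:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    calls = []
    for col in df.columns:
        donor, _, label = col.rpartition("/")
        calls.append(HaplotypeCall(donor, label, df[col].to_dict()))
    return calls


def write_tag_table(
    path: str | os.PathLike, tags: list[Tag], oligos: dict[str, OligoSet]
) -> None:
    """Per-tag oligo table: name, interval, the four oligos, extension base."""
    rows = []
    for t in tags:
        o = oligos.get(t.name)
        rows.append(
            {
                "tag": t.name, "from": t.start, "to": t.end,
                "forward": o.forward if o else "",
                "reverse": o.reverse if o else "",
                "nested": o.nested if o else "",
                "probe": o.probe if o else "",
                "extension_base": o.extension_base if o else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_runs_tsv(path: str | os.PathLike, runs_by_hap: dict[str, list]) -> None:
    rows = [
        {"haplotype": hap, "start_tag": r.start_tag, "end_tag": r.end_tag,
         "length": r.length}
        for hap, runs in runs_by_hap.items()
        for r in runs
    ]
    pd.DataFrame(rows, columns=["haplotype", "start_tag", "end_tag", "length"]).to_csv(
        path, sep="\t", index=False
    )


def write_blocks_tsv(path: str | os.PathLike, blocks_by_seq: dict[str, list]) -> None:
    rows = [
        {"sequence": name, "copy": k + 1, "start": s, "end": e,
         "complete": int(c), "unit_length": b.unit_length}
        for name, blocks in blocks_by_seq.items()
        for b in blocks
        for k, ((s, e), c) in enumerate(zip(b.copies, b.complete))
    ]
    pd.DataFrame(
        rows, columns=["sequence", "copy", "start", "end", "complete", "unit_length"]
    ).to_csv(path, sep="\t", index=False)
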