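"""Readers and writers for the plain-text genomic formats used here.

BED and bedGraph are 0-based half-open; GFF3 is 1-based inclusive and is
converted on read/write so the rest of the package only ever sees
0-based half-open coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

# gffutils is only needed for GFF3 parsing; imported lazily so the rest
# of the package works without it.


# ---------------------------------------------------------------------------
# chrom sizes
# ---------------------------------------------------------------------------


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected two tab-separated columns")
            sizes[parts[0]] = int(parts[1])
    if not sizes:
        raise ValueError(f"{path}: no chromosomes")
    return sizes


def write_chrom_sizes(sizes, path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


# ---------------------------------------------------------------------------
# bedGraph / wiggle / BED
# ---------------------------------------------------------------------------


def read_bedgraph(path) -> pd.DataFrame:
    """Read a bedGraph (chrom, start, end, value); track/browser/comment
    lines are skipped.  Errors carry the offending line number."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: expected 4 columns, got {len(parts)}")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed record: {exc}") from exc
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def write_bedgraph(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in zip(
            df["chrom"], df["start"], df["end"], df["value"]
        ):
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")


def values_to_bedgraph(
    chrom_order, chrom_codes, starts, ends, values
) -> pd.DataFrame:
    """Run-length collapse per-bin values into bedGraph intervals."""
    rows = []
    n = len(values)
    i = 0
    while i < n:
        j = i + 1
        while (
            j < n
            and chrom_codes[j] == chrom_codes[i]
            and values[j] == values[i]
            and starts[j] == ends[j - 1]
        ):
            j += 1
        rows.append(
            (chrom_order[chrom_codes[i]], int(starts[i]), int(ends[j - 1]), values[i])
        )
        i = j
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def read_wiggle(path) -> pd.DataFrame:
    """Read fixedStep/variableStep wiggle into interval+value records.

    Wiggle positions are 1-based; output is 0-based half-open.
    """
    rows = []
    mode = None
    chrom = None
    start = step = span = None
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                mode = "fixed"
                kv = dict(p.split("=") for p in line.split()[1:])
                chrom = kv["chrom"]
                start = int(kv["start"]) - 1
                step = int(kv.get("step", 1))
                span = int(kv.get("span", 1))
                continue
            if line.startswith("variableStep"):
                mode = "variable"
                kv = dict(p.split("=") for p in line.split()[1:])
                chrom = kv["chrom"]
                span = int(kv.get("span", 1))
                continue
            if mode is None:
                raise ValueError(f"{path}:{ln}: data before any step declaration")
            try:
                if mode == "fixed":
                    value = float(line)
                    rows.append((chrom, start, start + span, value))
                    start += step
                else:
                    pos_s, val_s = line.split()
                    pos = int(pos_s) - 1
                    rows.append((chrom, pos, pos + span, float(val_s)))
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed record: {exc}") from exc
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def read_signal(path) -> pd.DataFrame:
    """Dispatch on content: wiggle if a step declaration is present,
    otherwise bedGraph."""
    with open(path) as fh:
        for line in fh:
            if line.startswith(("fixedStep", "variableStep")):
                return read_wiggle(path)
            if line.strip() and not line.startswith(("#", "track", "browser")):
                break
    return read_bedgraph(path)


def read_bed(path) -> pd.DataFrame:
    """Read BED3+ (extra columns name/score/strand kept when present)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: expected >= 3 columns")
            try:
                row = [parts[0], int(parts[1]), int(parts[2])]
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed record: {exc}") from exc
            row.append(parts[3] if len(parts) > 3 else ".")
            row.append(float(parts[4]) if len(parts) > 4 else 0.0)
            row.append(parts[5] if len(parts) > 5 else ".")
            rows.append(row)
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )


def write_bed(df: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end"]
    extra = [c for c in ("name", "score", "strand") if c in df.columns]
    with open(path, "w") as fh:
        for _, row in df.iterrows():
            fields = [str(row[c]) for c in cols]
            for c in extra:
                v = row[c]
                fields.append(f"{v:.0f}" if c == "score" else str(v))
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# gene models / GFF3
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """A gene with TSS, exon/intron structure and UTRs (0-based half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: tuple[int, int] | None = None
    utr3: tuple[int, int] | None = None
    fpkm: float = 0.0

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    def introns(self) -> list[tuple[int, int]]:
        exons = sorted(self.exons)
        return [
            (exons[i][1], exons[i + 1][0])
            for i in range(len(exons) - 1)
            if exons[i + 1][0] > exons[i][1]
        ]

    def first_intron(self) -> tuple[int, int] | None:
        """Intron adjacent to the first exon in transcription order."""
        introns = self.introns()
        if not introns:
            return None
        return introns[0] if self.strand == "+" else introns[-1]

    def other_introns(self) -> list[tuple[int, int]]:
        first = self.first_intron()
        return [iv for iv in self.introns() if iv != first]


def write_gff3(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tenhancerxai\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for k, (s, e) in enumerate(sorted(g.exons)):
                fh.write(
                    f"{g.chrom}\tenhancerxai\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{k + 1};Parent={g.gene_id}\n"
                )
            if g.utr5 is not None:
                s, e = g.utr5
                fh.write(
                    f"{g.chrom}\tenhancerxai\tfive_prime_UTR\t{s + 1}\t{e}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}.utr5;Parent={g.gene_id}\n"
                )
            if g.utr3 is not None:
                s, e = g.utr3
                fh.write(
                    f"{g.chrom}\tenhancerxai\tthree_prime_UTR\t{s + 1}\t{e}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}.utr3;Parent={g.gene_id}\n"
                )


def read_gff3(path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gene = GeneModel(
            gene_id=feat.id,
            chrom=feat.seqid,
            start=feat.start - 1,
            end=feat.end,
            strand=feat.strand,
        )
        for child in db.children(feat, featuretype="exon", order_by="start"):
            gene.exons.append((child.start - 1, child.end))
        for child in db.children(feat, featuretype="five_prime_UTR"):
            gene.utr5 = (child.start - 1, child.end)
        for child in db.children(feat, featuretype="three_prime_UTR"):
            gene.utr3 = (child.start - 1, child.end)
        genes.append(gene)
    return genes


# ---------------------------------------------------------------------------
# contacts and expression tables
# ---------------------------------------------------------------------------

CONTACT_COLUMNS = [
    "chrom1",
    "start1",
    "end1",
    "chrom2",
    "start2",
    "end2",
    "score",
]


def read_contacts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CONTACT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: contact table lacks columns {missing}")
    return df


def write_contacts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_fpkm(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns or "fpkm" not in df.columns:
        raise ValueError(f"{path}: expression table needs gene_id and fpkm columns")
    return dict(zip(df["gene_id"], df["fpkm"].astype(float)))


def write_fpkm(fpkm: dict[str, float], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tfpkm\n")
        for gene_id, value in fpkm.items():
            fh.write(f"{gene_id}\t{value:.6g}\n")
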