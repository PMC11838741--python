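"""Gene models (single-transcript) with GFF3 round-trip.

Coordinates are 1-based inclusive internally, matching GFF3.  Each gene has
one transcript: a transcribed span, >=1 exons, and a CDS whose genomic
extent lies inside the exons and whose spliced length is divisible by 3.
Exonic sequence outside the CDS forms the 5'/3' UTRs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from cmmosaic.sbs import revcomp


class GeneModelError(ValueError):
    """Structurally invalid gene model (e.g. CDS outside exons)."""


@dataclass
class GeneModel:
    gene_id: str
    contig: str
    strand: str  # '+' or '-'
    start: int  # transcript leftmost, 1-based inclusive
    end: int  # transcript rightmost, 1-based inclusive
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_start: int = 0  # leftmost genomic CDS coordinate
    cds_end: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GeneModelError(f"{self.gene_id}: strand must be + or -")
        self.exons = sorted(self.exons)
        if not self.exons:
            raise GeneModelError(f"{self.gene_id}: gene requires >=1 exon")
        if self.cds_start and not any(
            s <= self.cds_start <= e for s, e in self.exons
        ):
            raise GeneModelError(f"{self.gene_id}: CDS start outside exons")
        if self.cds_end and not any(s <= self.cds_end <= e for s, e in self.exons):
            raise GeneModelError(f"{self.gene_id}: CDS end outside exons")

    # -- anatomy -----------------------------------------------------------

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        return self.end if self.strand == "+" else self.start

    def cds_segments(self) -> list[tuple[int, int]]:
        """Genomic CDS pieces (exon intersect [cds_start, cds_end]), left to right."""
        segs = []
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            if lo <= hi:
                segs.append((lo, hi))
        return segs

    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments())

    def utr5_segments(self) -> list[tuple[int, int]]:
        return self._utr(five_prime=True)

    def utr3_segments(self) -> list[tuple[int, int]]:
        return self._utr(five_prime=False)

    def _utr(self, five_prime: bool) -> list[tuple[int, int]]:
        left = (self.strand == "+") == five_prime
        segs = []
        for s, e in self.exons:
            if left and s < self.cds_start:
                segs.append((s, min(e, self.cds_start - 1)))
            if not left and e > self.cds_end:
                segs.append((max(s, self.cds_end + 1), e))
        return segs

    def introns(self) -> list[tuple[int, int]]:
        segs = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                segs.append((e1 + 1, s2 - 1))
        return segs

    # -- coding-coordinate arithmetic --------------------------------------

    def cds_offset(self, pos: int) -> int:
        """0-based offset of genomic ``pos`` along the spliced CDS in translation order."""
        segs = self.cds_segments()
        if self.strand == "+":
            off = 0
            for s, e in segs:
                if s <= pos <= e:
                    return off + (pos - s)
                off += e - s + 1
        else:
            off = 0
            for s, e in reversed(segs):
                if s <= pos <= e:
                    return off + (e - pos)
                off += e - s + 1
        raise GeneModelError(f"{self.gene_id}: position {pos} not in CDS")

    def coding_sequence(self, contig_seq: str) -> str:
        """Spliced CDS in translation order (reverse-complemented for - strand)."""
        parts = [contig_seq[s - 1 : e].upper() for s, e in self.cds_segments()]
        seq = "".join(parts)
        return revcomp(seq) if self.strand == "-" else seq


class GeneModelSet:
    """A collection of non-overlap-validated gene models on toy contigs."""

    def __init__(self, genes: list[GeneModel]):
        self.genes = sorted(genes, key=lambda g: (g.contig, g.start))

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def overlapping(self, contig: str, pos: int, pad: int = 0) -> list[GeneModel]:
        return [
            g
            for g in self.genes
            if g.contig == contig and g.start - pad <= pos <= g.end + pad
        ]

    # -- GFF3 round-trip ----------------------------------------------------

    def to_gff3(self, path: str) -> None:
        rows = ["##gff-version 3"]
        for g in self.genes:
            attrs = f"ID={g.gene_id}"
            rows.append(
                "\t".join(
                    [g.contig, "cmmosaic", "gene", str(g.start), str(g.end), ".", g.strand, ".", attrs]
                )
            )
            tid = f"{g.gene_id}.t1"
            rows.append(
                "\t".join(
                    [g.contig, "cmmosaic", "mRNA", str(g.start), str(g.end), ".", g.strand, ".", f"ID={tid};Parent={g.gene_id}"]
                )
            )
            for kind, segs in (
                ("exon", g.exons),
                ("five_prime_UTR", g.utr5_segments()),
                ("CDS", g.cds_segments()),
                ("three_prime_UTR", g.utr3_segments()),
            ):
                for s, e in segs:
                    rows.append(
                        "\t".join(
                            [g.contig, "cmmosaic", kind, str(s), str(e), ".", g.strand, "0" if kind == "CDS" else ".", f"Parent={tid}"]
                        )
                    )
        with open(path, "w") as fh:
            fh.write("\n".join(rows) + "\n")

    @classmethod
    def from_gff3(cls, path: str) -> "GeneModelSet":
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=["contig", "source", "type", "start", "end", "score", "strand", "phase", "attributes"],
        )

        def attr(s: str, key: str) -> str:
            for kv in s.split(";"):
                k, _, v = kv.partition("=")
                if k == key:
                    return v
            return ""

        genes: dict[str, GeneModel] = {}
        tx2gene: dict[str, str] = {}
        for _, row in df[df["type"] == "gene"].iterrows():
            gid = attr(row["attributes"], "ID")
            genes[gid] = GeneModel(
                gene_id=gid,
                contig=str(row.contig),
                strand=row.strand,
                start=int(row.start),
                end=int(row.end),
                exons=[(int(row.start), int(row.end))],  # replaced below
                cds_start=0,
                cds_end=0,
            )
            genes[gid].exons = []
        for _, row in df[df["type"] == "mRNA"].iterrows():
            tx2gene[attr(row["attributes"], "ID")] = attr(row["attributes"], "Parent")
        for _, row in df[df["type"] == "exon"].iterrows():
            gid = tx2gene[attr(row["attributes"], "Parent")]
            genes[gid].exons.append((int(row.start), int(row.end)))
        for _, row in df[df["type"] == "CDS"].iterrows():
            gid = tx2gene[attr(row["attributes"], "Parent")]
            g = genes[gid]
            g.cds_start = min(int(row.start), g.cds_start or int(row.start))
            g.cds_end = max(int(row.end), g.cds_end)
        out = []
        for g in genes.values():
            g.exons = sorted(g.exons)
            out.append(
                GeneModel(g.gene_id, g.contig, g.strand, g.start, g.end, g.exons, g.cds_start, g.cds_end)
            )
        return cls(out)
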