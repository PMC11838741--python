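"""Readers/writers for the plain-text formats the pipeline exchanges.

VCF parsing goes through pysam; FASTA reading through pyfaidx when a path
is given.  Writers emit minimal, valid, uncompressed text so fixtures stay
human-inspectable.
"""

from __future__ import annotations

import textwrap
from typing import Iterable, Mapping, Sequence

import pysam

from cmmosaic.sbs import VariantCall

VCF_HEADER = """\
##fileformat=VCFv4.2
##source=cmmosaic
{contigs}##INFO=<ID=PH,Number=0,Type=Flag,Description="Inside a phaseable interval">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_fasta(path: str, sequences: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            fh.write("\n".join(textwrap.wrap(seq, width)) + "\n")


def write_vcf(
    path: str,
    calls: Iterable[VariantCall],
    contig_lengths: Mapping[str, int],
) -> None:
    contigs = "".join(
        f"##contig=<ID={name},length={length}>\n"
        for name, length in contig_lengths.items()
    )
    with open(path, "w") as fh:
        fh.write(VCF_HEADER.format(contigs=contigs))
        ordered = sorted(calls, key=lambda c: (c.contig, c.pos))
        for c in ordered:
            info = "PH" if c.phaseable else "."
            fh.write(f"{c.contig}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t{info}\n")


def read_vcf(path: str, cell_id: str = "") -> list[VariantCall]:
    calls = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            for alt in rec.alts or ():
                calls.append(
                    VariantCall(
                        contig=rec.contig,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        cell_id=cell_id,
                        phaseable="PH" in rec.info,
                    )
                )
    return calls


def write_bed(path: str, intervals: Sequence[tuple[str, int, int]]) -> None:
    """Write 0-based half-open intervals as BED3."""
    with open(path, "w") as fh:
        for contig, start, end in intervals:
            fh.write(f"{contig}\t{start}\t{end}\n")


def read_bed(path: str) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out
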