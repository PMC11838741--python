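"""Genic-region annotation, functional classification, and selection ratios.

Region categories: intergenic, upstream (within 1 kb upstream of the TSS),
5' UTR, exonic (CDS), 3' UTR, downstream (within 1 kb of the transcription
end), splicing (within 2 bp of an intronic splice junction), intronic.
When a variant maps to several categories (overlapping transcripts, or
several features of one gene) a fixed precedence applies:

    splicing > exonic > UTR5/UTR3 > intronic > upstream/downstream > intergenic

Functional classes for CDS variants follow the standard genetic code:
synonymous, nonsynonymous, stop-gain, stop-loss.  Selection statistics
compare somatic and germline category proportions: the somatic
exonic:intronic and dN/dS ratios are normalized by the germline ratios and
tested with a two-sided Fisher exact test; a normalized ratio above 1 is
consistent with relaxed negative selection relative to the germline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from cmmosaic.genes import GeneModelSet
from cmmosaic.sbs import COMPLEMENT, VariantCall

UPSTREAM_WINDOW = 1000
DOWNSTREAM_WINDOW = 1000
SPLICE_WINDOW = 2

#: Higher value = higher precedence when a variant maps to several categories.
_PRECEDENCE = {
    "splicing": 7,
    "exonic": 6,
    "UTR5": 5,
    "UTR3": 5,
    "intronic": 4,
    "upstream": 3,
    "downstream": 3,
    "intergenic": 0,
}

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def _categories_for_gene(pos: int, gene) -> list[str]:
    cats = []
    # flanking windows (outside the transcript)
    if gene.strand == "+":
        if gene.tss - UPSTREAM_WINDOW <= pos < gene.start:
            cats.append("upstream")
        if gene.end < pos <= gene.tts + DOWNSTREAM_WINDOW:
            cats.append("downstream")
    else:
        if gene.end < pos <= gene.tss + UPSTREAM_WINDOW:
            cats.append("upstream")
        if gene.start - DOWNSTREAM_WINDOW <= pos < gene.start:
            cats.append("downstream")
    if not gene.start <= pos <= gene.end:
        return cats
    for s, e in gene.introns():
        if s <= pos <= e:
            if pos - s < SPLICE_WINDOW or e - pos < SPLICE_WINDOW:
                cats.append("splicing")
            else:
                cats.append("intronic")
            return cats
    for s, e in gene.cds_segments():
        if s <= pos <= e:
            cats.append("exonic")
            return cats
    for s, e in gene.utr5_segments():
        if s <= pos <= e:
            cats.append("UTR5")
            return cats
    for s, e in gene.utr3_segments():
        if s <= pos <= e:
            cats.append("UTR3")
            return cats
    return cats


def annotate_region(call: VariantCall, gene_models: GeneModelSet) -> str:
    """Single region category per variant under the documented precedence."""
    pad = max(UPSTREAM_WINDOW, DOWNSTREAM_WINDOW)
    cats: list[str] = []
    for gene in gene_models.overlapping(call.contig, call.pos, pad=pad):
        cats.extend(_categories_for_gene(call.pos, gene))
    if not cats:
        return "intergenic"
    return max(cats, key=lambda c: _PRECEDENCE[c])


def classify_functional(
    call: VariantCall, gene_models: GeneModelSet, sequences
) -> str:
    """synonymous / nonsynonymous / stopgain / stoploss for a CDS variant.

    The codon is read from the reference respecting strand; multi-transcript
    hits resolve to the most severe class (stopgain > stoploss >
    nonsynonymous > synonymous).
    """
    severity = {"stopgain": 3, "stoploss": 2, "nonsynonymous": 1, "synonymous": 0}
    seq = sequences[call.contig]
    contig_seq = seq if isinstance(seq, str) else str(seq[:])
    results = []
    for gene in gene_models.overlapping(call.contig, call.pos):
        if not any(s <= call.pos <= e for s, e in gene.cds_segments()):
            continue
        if gene.cds_length() % 3:
            raise ValueError(f"{gene.gene_id}: CDS length not divisible by 3")
        cds = gene.coding_sequence(contig_seq)
        off = gene.cds_offset(call.pos)
        ref_allele, alt_allele = call.ref.upper(), call.alt.upper()
        if gene.strand == "-":
            ref_allele, alt_allele = COMPLEMENT[ref_allele], COMPLEMENT[alt_allele]
        if cds[off] != ref_allele:
            raise ValueError(
                f"{gene.gene_id}: reference base mismatch at CDS offset {off}"
            )
        codon_i = off // 3
        codon = cds[codon_i * 3 : codon_i * 3 + 3]
        internal = set(
            CODON_TABLE[cds[i : i + 3]] for i in range(0, len(cds) - 3, 3)
        )
        if "*" in internal and codon_i * 3 < len(cds) - 3:
            warnings.warn(
                f"{gene.gene_id}: internal stop codon in reference frame", stacklevel=2
            )
        mutated = codon[: off % 3] + alt_allele + codon[off % 3 + 1 :]
        aa_ref, aa_alt = CODON_TABLE[codon], CODON_TABLE[mutated]
        if aa_ref == aa_alt:
            results.append("synonymous")
        elif aa_alt == "*":
            results.append("stopgain")
        elif aa_ref == "*":
            results.append("stoploss")
        else:
            results.append("nonsynonymous")
    if not results:
        raise ValueError("variant is not exonic in any transcript")
    return max(results, key=lambda r: severity[r])


def annotate_calls(
    calls: list[VariantCall], gene_models: GeneModelSet, sequences
) -> pd.DataFrame:
    """Region (and, for exonic variants, functional) annotation table."""
    rows = []
    for c in calls:
        region = annotate_region(c, gene_models)
        func = (
            classify_functional(c, gene_models, sequences) if region == "exonic" else ""
        )
        rows.append(
            {
                "contig": c.contig,
                "pos": c.pos,
                "ref": c.ref,
                "alt": c.alt,
                "cell_id": c.cell_id,
                "region": region,
                "functional": func,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SelectionTable:
    """Germline-normalized 2x2 selection contrast (category A vs B)."""

    label: str
    somatic_a: int
    somatic_b: int
    germline_a: int
    germline_b: int
    ratio: float = np.nan
    p_value: float = np.nan

    def compute(self) -> "SelectionTable":
        table = [[self.somatic_a, self.somatic_b], [self.germline_a, self.germline_b]]
        _, self.p_value = stats.fisher_exact(table, alternative="two-sided")
        if self.somatic_b > 0 and self.germline_b > 0 and self.germline_a > 0:
            self.ratio = (self.somatic_a / self.somatic_b) / (
                self.germline_a / self.germline_b
            )
        else:
            self.ratio = np.nan
        return self


def selection_ratios(
    somatic: pd.DataFrame, germline: pd.DataFrame
) -> tuple[SelectionTable, SelectionTable]:
    """Exonic:intronic and dN/dS tables from annotated somatic/germline calls.

    Both inputs are annotation tables from :func:`annotate_calls`.  Returns
    (exonic:intronic, nonsynonymous:synonymous), each with the germline-
    normalized ratio and the two-sided Fisher exact P value.
    """

    def counts(df: pd.DataFrame) -> dict[str, int]:
        return {
            "exonic": int((df["region"] == "exonic").sum()),
            "intronic": int((df["region"] == "intronic").sum()),
            "nonsyn": int(df["functional"].isin(["nonsynonymous", "stopgain", "stoploss"]).sum()),
            "syn": int((df["functional"] == "synonymous").sum()),
        }

    s, g = counts(somatic), counts(germline)
    exint = SelectionTable(
        "exonic:intronic", s["exonic"], s["intronic"], g["exonic"], g["intronic"]
    ).compute()
    dnds = SelectionTable(
        "dN/dS", s["nonsyn"], s["syn"], g["nonsyn"], g["syn"]
    ).compute()
    return exint, dnds


def locus_overlap_report(
    calls: list[VariantCall], loci: list[tuple[str, int, int]]
) -> pd.DataFrame:
    """Interval-intersection of calls against disease-associated loci (BED)."""
    rows = []
    for c in calls:
        for contig, s, e in loci:
            if c.contig == contig and s < c.pos <= e:
                rows.append(
                    {"contig": c.contig, "pos": c.pos, "cell_id": c.cell_id,
                     "locus_start": s, "locus_end": e}
                )
    return pd.DataFrame(rows, columns=["contig", "pos", "cell_id", "locus_start", "locus_end"])
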