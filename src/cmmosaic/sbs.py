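"""SBS96 trinucleotide substitution channels and spectrum construction.

Somatic single-nucleotide variants are standardized to a pyrimidine
reference base (C or T); a purine-reference substitution is reported on the
reverse-complement strand.  Each variant then falls into one of 96 channels:
6 substitution types (C>A, C>G, C>T, T>A, T>C, T>G) x 16 flanking-base
combinations, written ``A[C>A]A`` style and ordered substitution-major with
flanks alphabetical, the layout used by the COSMIC SBS catalogs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
PYRIMIDINES = ("C", "T")
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: The 96 channels, e.g. ``"A[C>A]A"``, substitution-major, flanks A<C<G<T.
CHANNELS_96: tuple[str, ...] = tuple(
    f"{up}[{sub}]{down}"
    for sub in SUBSTITUTIONS
    for up in "ACGT"
    for down in "ACGT"
)

CHANNEL_INDEX: dict[str, int] = {c: i for i, c in enumerate(CHANNELS_96)}

#: The 32 pyrimidine-centred trinucleotides ("ACA" ... "TTT" with centre C/T).
TRINUCLEOTIDES_32: tuple[str, ...] = tuple(
    f"{up}{mid}{down}" for mid in "CT" for up in "ACGT" for down in "ACGT"
)

#: Seven substitution classes: C>T split by CpG context.
SUBSTITUTION_CLASSES_7 = (
    "C>A",
    "C>G",
    "C>T at CpG",
    "C>T at non-CpG",
    "T>A",
    "T>C",
    "T>G",
)


class InvalidBaseError(ValueError):
    """A base outside {A, C, G, T} (ambiguity codes are rejected)."""


class ContextError(ValueError):
    """A call lacks a flanking base on its contig."""


def revcomp(seq: str) -> str:
    try:
        return "".join(COMPLEMENT[b] for b in reversed(seq))
    except KeyError as exc:
        raise InvalidBaseError(f"ambiguous or invalid base {exc.args[0]!r}") from None


def _check_base(b: str) -> None:
    if b not in COMPLEMENT:
        raise InvalidBaseError(f"ambiguous or invalid base {b!r}")


def classify_substitution(
    ref: str, alt: str, upstream: str, downstream: str
) -> tuple[int, str]:
    """Map a substitution with its flanks to (SBS96 channel index, 7-class label).

    Purine-reference substitutions are reverse-complemented so the reference
    base is a pyrimidine; CpG status of C>T is read from the standardized
    downstream base.

    Returns
    -------
    (channel, cls)
        ``channel`` indexes :data:`CHANNELS_96`; ``cls`` is one of
        :data:`SUBSTITUTION_CLASSES_7`.
    """
    for b in (ref, alt, upstream, downstream):
        _check_base(b)
    if ref == alt:
        raise ValueError("ref and alt alleles are identical")
    if ref not in PYRIMIDINES:
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        upstream, downstream = COMPLEMENT[downstream], COMPLEMENT[upstream]
    channel = CHANNEL_INDEX[f"{upstream}[{ref}>{alt}]{downstream}"]
    if ref == "C" and alt == "T":
        cls = "C>T at CpG" if downstream == "G" else "C>T at non-CpG"
    else:
        cls = f"{ref}>{alt}"
    return channel, cls


def channel_of_context(trinucleotide: str, alt: str) -> int:
    """SBS96 channel for a pyrimidine-standardized trinucleotide and alt base."""
    up, ref, down = trinucleotide
    return CHANNEL_INDEX[f"{up}[{ref}>{alt}]{down}"]


def standardize_context(trinucleotide: str) -> str:
    """Reverse-complement a trinucleotide if its centre base is a purine."""
    if trinucleotide[1] in PYRIMIDINES:
        return trinucleotide
    return revcomp(trinucleotide)


@dataclass(frozen=True)
class VariantCall:
    """A somatic SNV on a contig, 1-based position, with optional metadata."""

    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    cell_id: str = ""
    phaseable: bool = True


@dataclass
class Spectrum:
    """Counts over the 96 pyrimidine-standardized trinucleotide channels."""

    counts: np.ndarray = field(default_factory=lambda: np.zeros(96))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError("spectrum requires exactly 96 channels")
        if (self.counts < 0).any():
            raise ValueError("negative channel count")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def normalized(self) -> np.ndarray:
        t = self.total
        return self.counts / t if t > 0 else self.counts.copy()

    def __add__(self, other: "Spectrum") -> "Spectrum":
        return Spectrum(self.counts + other.counts)


def context_at(sequence: str, pos: int) -> str:
    """Trinucleotide around 1-based ``pos``; raises at contig edges."""
    if pos < 2 or pos > len(sequence) - 1:
        raise ContextError(f"position {pos} lacks a flanking base")
    return sequence[pos - 2 : pos + 1].upper()


def build_spectrum(calls: Iterable[VariantCall], sequences: Mapping[str, str]) -> Spectrum:
    """Aggregate calls into an SBS96 spectrum, reading contexts from the reference.

    ``sequences`` maps contig name to its sequence (a :class:`pyfaidx.Fasta`
    works directly).  The VCF-stated REF is cross-checked against the
    reference base.
    """
    counts = np.zeros(96)
    for call in calls:
        seq = sequences[call.contig]
        tri = str(seq[call.pos - 2 : call.pos + 1]).upper() if not isinstance(seq, str) else context_at(seq, call.pos)
        if len(tri) != 3:
            raise ContextError(f"{call.contig}:{call.pos} lacks a flanking base")
        if tri[1] != call.ref.upper():
            raise ValueError(
                f"REF mismatch at {call.contig}:{call.pos}: VCF says {call.ref}, reference has {tri[1]}"
            )
        ch, _ = classify_substitution(call.ref.upper(), call.alt.upper(), tri[0], tri[2])
        counts[ch] += 1
    return Spectrum(counts)


def substitution_class_table(
    calls: Iterable[VariantCall], sequences: Mapping[str, str]
) -> dict[str, int]:
    """Counts per 7-way substitution class (C>T split by CpG status)."""
    table = {cls: 0 for cls in SUBSTITUTION_CLASSES_7}
    for call in calls:
        seq = sequences[call.contig]
        tri = str(seq[call.pos - 2 : call.pos + 1]).upper() if not isinstance(seq, str) else context_at(seq, call.pos)
        if len(tri) != 3:
            raise ContextError(f"{call.contig}:{call.pos} lacks a flanking base")
        _, cls = classify_substitution(call.ref.upper(), call.alt.upper(), tri[0], tri[2])
        table[cls] += 1
    return table


def context_position_index(
    sequence: str,
    intervals: Sequence[tuple[int, int]] | None = None,
) -> dict[str, np.ndarray]:
    """Index of 1-based positions per standardized trinucleotide context.

    ``intervals`` are 0-based half-open (BED convention) restricting the
    index (e.g. to phaseable regions); ``None`` means the whole contig.
    Positions at contig edges (no flank) are skipped.
    """
    n = len(sequence)
    if intervals is None:
        intervals = [(0, n)]
    out: dict[str, list[int]] = {t: [] for t in TRINUCLEOTIDES_32}
    seq = sequence.upper()
    for start, end in intervals:
        lo = max(start, 1)  # 0-based centre index must have a left flank
        hi = min(end, n - 1)
        for i in range(lo, hi):
            tri = seq[i - 1 : i + 2]
            if any(b not in COMPLEMENT for b in tri):
                continue
            out[standardize_context(tri)].append(i + 1)  # 1-based
    return {t: np.asarray(p, dtype=np.int64) for t, p in out.items()}
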