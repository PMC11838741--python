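"""Synthetic cohort generator emulating the study's data structure.

Produces, under one seed, a complete fixture bundle: a toy reference
sequence, non-overlapping gene models, phaseable intervals, donors with ages
and disease condition, per-cell true burdens drawn from the linear
mixed-effects generative model, realized somatic mutations drawn from a
signature mixture and placed at context-matching phaseable positions,
binned depth profiles with amplification unevenness and an optional
zero-depth block, and a negative-binomial cell x gene count matrix with
donor/condition structure for the differential-expression stage.

The generative burden model is the analysis model run forward: per-cell
burden/GB = beta0 + beta1*age (+ betaI if diseased) + donor intercept
~ N(0, sigma_u^2) + residual ~ N(0, sigma_e^2).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cmmosaic import fileio
from cmmosaic.genes import GeneModel, GeneModelSet
from cmmosaic.sbs import (
    CHANNELS_96,
    COMPLEMENT,
    VariantCall,
    context_position_index,
)
from cmmosaic.signatures import SignatureCatalog


class PlacementError(RuntimeError):
    """A requested trinucleotide context has too few available positions."""


class CapacityError(ValueError):
    """Requested gene models do not fit on the reference."""


# ---------------------------------------------------------------------------
# Reference and gene models


@dataclass
class ToyReference:
    """A single-contig toy genome standing in for a real reference assembly."""

    sequence: str
    contig_name: str = "chrS"

    def __post_init__(self) -> None:
        if len(self.sequence) < 3:
            raise ValueError("reference must be >= 3 bp")
        bad = set(self.sequence.upper()) - set("ACGT")
        if bad:
            raise ValueError(f"ambiguity codes in reference: {bad}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def to_fasta(self, path: str) -> None:
        fileio.write_fasta(path, {self.contig_name: self.sequence})


def generate_reference(length: int, gc_fraction: float = 0.41, seed: int = 0) -> ToyReference:
    """Random i.i.d. sequence with the requested GC content (default 0.41,
    the human genome-wide value)."""
    if length < 1000:
        raise ValueError("reference length must be >= 1000 bp")
    if not 0 <= gc_fraction <= 1:
        raise ValueError("gc_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    bases = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=p)
    return ToyReference(bases.tobytes().decode())


def generate_gene_models(
    ref: ToyReference,
    n_genes: int,
    seed: int = 0,
    gene_length: int = 9000,
    n_exons: int = 3,
    utr_length: int = 200,
    flank: int = 2000,
) -> GeneModelSet:
    """Evenly spaced, non-overlapping single-transcript genes on both strands.

    Each gene has ``n_exons`` exons; the CDS starts after a 5' UTR in the
    first exon and ends before a 3' UTR in the last, with spliced CDS length
    divisible by 3.  Strand alternates with random perturbation so both
    strands are represented.
    """
    if n_genes == 0:
        return GeneModelSet([])
    rng = np.random.default_rng(seed)
    slot = gene_length + 2 * flank
    if n_genes * slot > ref.length:
        raise CapacityError(
            f"{n_genes} genes of footprint {slot} bp exceed reference length {ref.length}"
        )
    spacing = ref.length // n_genes
    genes = []
    exon_len = gene_length // (2 * n_exons - 1)
    for i in range(n_genes):
        start = i * spacing + flank + 1  # 1-based
        strand = "+" if (i + int(rng.integers(0, 2))) % 2 == 0 else "-"
        exons = []
        pos = start
        for e in range(n_exons):
            exons.append((pos, pos + exon_len - 1))
            pos += 2 * exon_len
        end = exons[-1][1]
        cds_start = exons[0][0] + utr_length
        cds_end = exons[-1][1] - utr_length
        g = GeneModel(f"gene{i + 1}", ref.contig_name, strand, start, end, exons, cds_start, cds_end)
        # trim 3'-most CDS boundary so spliced length % 3 == 0
        excess = g.cds_length() % 3
        if excess:
            if strand == "+":
                g.cds_end -= excess
            else:
                g.cds_start += excess
        genes.append(g)
    return GeneModelSet(genes)


# ---------------------------------------------------------------------------
# Cohort design and burden truths


@dataclass
class CohortDesign:
    """Study design plus generative-model parameters for per-cell burdens.

    Burden units are sSNVs per GB.  ``signature_exposure_by_condition`` maps
    condition -> {signature name: fraction}; fractions sum to 1 within each
    condition.  Defaults mirror a control-heavy aging cohort: ages spread
    evenly across the human lifespan (0.5-82 y).
    """

    n_control_donors: int = 10
    n_ihd_donors: int = 0
    cells_per_donor: int = 5
    ages: Sequence[float] | None = None
    beta0: float = 50.0
    beta1: float = 7.90
    beta_I: float = 686.0
    sigma_u: float = 50.0
    sigma_e: float = 100.0
    signature_exposure_by_condition: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sigma_u, self.sigma_e) < 0:
            raise ValueError("noise SDs must be >= 0")
        for cond, exp in self.signature_exposure_by_condition.items():
            vals = np.array(list(exp.values()))
            if (vals < 0).any() or (vals > 1).any() or not np.isclose(vals.sum(), 1.0):
                raise ValueError(f"exposure fractions for {cond!r} must lie in [0,1] and sum to 1")
        if self.ages is not None:
            if any(a < 0 for a in self.ages):
                raise ValueError("ages must be >= 0")
            if len(self.ages) != self.n_donors:
                raise ValueError("ages must match total donor count")

    @property
    def n_donors(self) -> int:
        return self.n_control_donors + self.n_ihd_donors

    def donor_table(self, rng: np.random.Generator) -> pd.DataFrame:
        if self.ages is not None:
            ages = np.asarray(self.ages, dtype=float)
        else:
            # controls and IHD donors each evenly spread over 0.5-82 years
            ctrl = np.linspace(0.5, 82, self.n_control_donors) if self.n_control_donors else np.array([])
            ihd = np.linspace(0.5, 82, self.n_ihd_donors + 2)[1:-1] if self.n_ihd_donors else np.array([])
            ages = np.concatenate([ctrl, ihd])
        conditions = ["control"] * self.n_control_donors + ["IHD"] * self.n_ihd_donors
        ids = [f"CTRL-{i + 1}" for i in range(self.n_control_donors)] + [
            f"IHD-{i + 1}" for i in range(self.n_ihd_donors)
        ]
        sex = rng.choice(["F", "M"], size=self.n_donors)
        return pd.DataFrame(
            {"donor_id": ids, "age": ages, "condition": conditions, "sex": sex}
        )


def simulate_burdens(
    design: CohortDesign,
    rng: np.random.Generator | None = None,
    truncate: bool = True,
) -> pd.DataFrame:
    """Draw per-cell true burdens from the mixed-effects generative model.

    Returns one row per cell: cell_id, donor_id, age, condition, sex,
    burden_per_gb.  ``truncate`` clips negative burdens at 0 (counts cannot
    be negative); parameter-recovery experiments on the pure linear model
    should pass ``truncate=False``.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    donors = design.donor_table(rng)
    rows = []
    for _, d in donors.iterrows():
        u = rng.normal(0.0, design.sigma_u)
        for i in range(design.cells_per_donor):
            eps = rng.normal(0.0, design.sigma_e)
            y = design.beta0 + design.beta1 * d.age + (design.beta_I if d.condition == "IHD" else 0.0) + u + eps
            if truncate:
                y = max(y, 0.0)
            rows.append(
                {
                    "cell_id": f"{d.donor_id}_c{i + 1}",
                    "donor_id": d.donor_id,
                    "age": d.age,
                    "condition": d.condition,
                    "sex": d.sex,
                    "burden_per_gb": y,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mutation placement and full cohort truth


def default_phaseable_intervals(
    ref: ToyReference, fraction: float = 0.6, n_intervals: int = 8, seed: int = 0
) -> list[tuple[str, int, int]]:
    """Evenly spaced phaseable intervals (BED, 0-based half-open) covering
    ``fraction`` of the reference."""
    rng = np.random.default_rng(seed)
    span = ref.length // n_intervals
    width = int(span * fraction)
    out = []
    for i in range(n_intervals):
        start = i * span + int(rng.integers(0, max(span - width, 1)))
        out.append((ref.contig_name, start, min(start + width, ref.length)))
    return out


def place_mutations(
    channel_counts: np.ndarray,
    context_index: Mapping[str, np.ndarray],
    sequence: str,
    contig: str,
    rng: np.random.Generator,
    cell_id: str = "",
) -> list[VariantCall]:
    """Place mutations with given SBS96 channel counts at context-matching
    positions, sampled uniformly without replacement within the cell.

    Emits VCF-ready calls with the actual genomic REF base (the channel's
    pyrimidine substitution is reverse-complemented at purine-centred sites).
    """
    calls: list[VariantCall] = []
    by_context: dict[str, list[tuple[str, int]]] = {}
    for ch, cnt in enumerate(channel_counts):
        if cnt == 0:
            continue
        name = CHANNELS_96[ch]
        tri = name[0] + name[2] + name[6]
        alt = name[4]
        by_context.setdefault(tri, []).extend([(alt, ch)] * int(cnt))
    for tri, wanted in by_context.items():
        pool = context_index.get(tri, np.array([], dtype=np.int64))
        if len(pool) < len(wanted):
            raise PlacementError(
                f"context {tri}: need {len(wanted)} positions, only {len(pool)} available"
            )
        pos = rng.choice(pool, size=len(wanted), replace=False)
        for (alt, _), p in zip(wanted, pos):
            ref_base = sequence[p - 1].upper()
            if ref_base in ("C", "T"):
                calls.append(VariantCall(contig, int(p), ref_base, alt, cell_id))
            else:
                calls.append(VariantCall(contig, int(p), ref_base, COMPLEMENT[alt], cell_id))
    return calls


@dataclass
class CohortTruth:
    """Complete ground truth for a simulated cohort."""

    reference: ToyReference
    donors: pd.DataFrame
    cells: pd.DataFrame  # incl. burden_per_gb, expected/realized mutation counts
    mutations: dict[str, list[VariantCall]]
    phaseable: list[tuple[str, int, int]]
    bin_profiles: dict[str, pd.DataFrame]

    def write(self, outdir: str) -> dict[str, str]:
        """Write the fixture bundle (FASTA, BEDs, per-cell VCFs, TSVs)."""
        os.makedirs(outdir, exist_ok=True)
        paths = {}
        paths["fasta"] = os.path.join(outdir, "reference.fa")
        self.reference.to_fasta(paths["fasta"])
        paths["phaseable"] = os.path.join(outdir, "phaseable.bed")
        fileio.write_bed(paths["phaseable"], self.phaseable)
        paths["cells"] = os.path.join(outdir, "cell_metadata.tsv")
        self.cells.to_csv(paths["cells"], sep="\t", index=False)
        contig_lengths = {self.reference.contig_name: self.reference.length}
        vcf_dir = os.path.join(outdir, "vcf")
        os.makedirs(vcf_dir, exist_ok=True)
        for cell_id, calls in self.mutations.items():
            p = os.path.join(vcf_dir, f"{cell_id}.vcf")
            fileio.write_vcf(p, calls, contig_lengths)
            paths[f"vcf:{cell_id}"] = p
        bin_dir = os.path.join(outdir, "bins")
        os.makedirs(bin_dir, exist_ok=True)
        for cell_id, bins in self.bin_profiles.items():
            p = os.path.join(bin_dir, f"{cell_id}.tsv")
            bins.to_csv(p, sep="\t", index=False)
            paths[f"bins:{cell_id}"] = p
        return paths


def simulate_bin_profile(
    ref: ToyReference,
    rng: np.random.Generator,
    mean_depth: float = 30.0,
    unevenness: float = 0.3,
    bin_size: int = 20_000,
    zero_block_fraction: float = 0.05,
) -> pd.DataFrame:
    """Gamma-noise binned depth with a contiguous zero-depth block.

    ``unevenness`` is the coefficient of variation of bin depths; the
    zero-depth block exercises the refined burden estimation.
    """
    n_bins = max(ref.length // bin_size, 2)
    shape = 1.0 / unevenness**2
    depths = rng.gamma(shape, mean_depth / shape, size=n_bins)
    n_zero = int(round(zero_block_fraction * n_bins))
    if n_zero:
        start = int(rng.integers(0, n_bins - n_zero + 1))
        depths[start : start + n_zero] = 0.0
    starts = np.arange(n_bins) * bin_size
    ends = np.minimum(starts + bin_size, ref.length)
    return pd.DataFrame(
        {"chrom": ref.contig_name, "start": starts, "end": ends, "depth": depths}
    )


def generate_cohort(
    design: CohortDesign,
    ref: ToyReference,
    catalog: SignatureCatalog,
    phaseable: list[tuple[str, int, int]] | None = None,
    callable_fraction: float = 0.85,
    detection_sensitivity: float = 0.9,
    mean_depth: float = 30.0,
    bin_size: int = 20_000,
) -> CohortTruth:
    """Simulate a full cohort: burdens, mutations, depth profiles.

    Per-cell realized mutation counts are Poisson with mean
    burden_per_gb x callable GB x detection sensitivity, where callable GB is
    ``callable_fraction`` of the toy reference.  Channels are drawn from the
    condition's signature mixture and placed at context-matching phaseable
    positions (uniform, without replacement within a cell, independently
    across cells).
    """
    rng = np.random.default_rng(design.seed)
    if phaseable is None:
        phaseable = default_phaseable_intervals(ref, seed=design.seed)
    intervals = [(s, e) for _, s, e in phaseable]
    ctx_index = context_position_index(ref.sequence, intervals)

    cells = simulate_burdens(design, rng)
    donors = cells[["donor_id", "age", "condition", "sex"]].drop_duplicates().reset_index(drop=True)

    callable_gb = callable_fraction * ref.length / 1e9
    mixtures = {}
    for cond in cells["condition"].unique():
        exp = design.signature_exposure_by_condition.get(cond)
        if exp is None:
            mix = catalog.matrix.mean(axis=1)
        else:
            mix = np.zeros(96)
            for name, frac in exp.items():
                mix += frac * catalog.column(name)
        mixtures[cond] = mix / mix.sum()

    mutations: dict[str, list[VariantCall]] = {}
    bin_profiles: dict[str, pd.DataFrame] = {}
    expected, realized = [], []
    for _, row in cells.iterrows():
        mu = row.burden_per_gb * callable_gb * detection_sensitivity
        n_mut = int(rng.poisson(mu))
        channel_counts = rng.multinomial(n_mut, mixtures[row.condition])
        calls = place_mutations(
            channel_counts, ctx_index, ref.sequence, ref.contig_name, rng, row.cell_id
        )
        mutations[row.cell_id] = calls
        expected.append(mu)
        realized.append(n_mut)
        bin_profiles[row.cell_id] = simulate_bin_profile(
            ref, rng, mean_depth=mean_depth, bin_size=bin_size
        )
    cells = cells.assign(expected_mutations=expected, realized_mutations=realized)
    return CohortTruth(ref, donors, cells, mutations, phaseable, bin_profiles)


def simulate_germline_variants(
    ref: ToyReference, n_sites: int, rng: np.random.Generator
) -> list[VariantCall]:
    """Uniformly placed heterozygous germline SNVs (distinct positions)."""
    pos = rng.choice(np.arange(2, ref.length), size=n_sites, replace=False)
    calls = []
    for p in np.sort(pos):
        ref_base = ref.sequence[p - 1].upper()
        alt = rng.choice([b for b in "ACGT" if b != ref_base])
        calls.append(VariantCall(ref.contig_name, int(p), ref_base, str(alt), "germline"))
    return calls


def depth_dropout_recovery(
    depth: np.ndarray, rng: np.random.Generator, half_depth: float = 5.0
) -> np.ndarray:
    """Bernoulli germline recovery with saturating depth dependence.

    Recovery probability 1 - 2^-(depth / half_depth): ~0 at zero depth,
    0.5 at ``half_depth``, saturating toward 1 - the canonical shape of
    allele-dropout curves in amplified single cells.
    """
    p = 1.0 - np.power(2.0, -np.asarray(depth, float) / half_depth)
    return rng.random(len(p)) < p


# ---------------------------------------------------------------------------
# Count matrix for the differential-expression stage


def simulate_counts_matrix(
    n_donors_per_condition: int = 3,
    cells_per_donor: int = 100,
    n_genes: int = 200,
    de_genes: Sequence[dict] = (),
    donor_effect_sd: float = 0.0,
    nb_dispersion: float = 2.0,
    base_mean: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """Negative-binomial cell x gene counts with donor/condition structure.

    ``de_genes`` entries are dicts with keys ``gene`` (index), ``lfc``
    (natural-log fold change), and either ``condition`` ("IHD"/"control") or
    ``donor`` (a donor id) limiting where the shift applies.  Donor random
    effects are per-gene log-normal multipliers with SD ``donor_effect_sd``.

    Returns (counts, cell metadata, gene names).
    """
    if n_donors_per_condition < 2:
        raise ValueError("need >= 2 donors per condition")
    for d in de_genes:
        if not 0 <= int(d["gene"]) < n_genes:
            raise ValueError(f"de_genes references unknown gene index {d['gene']}")
    rng = np.random.default_rng(seed)
    genes = [f"g{i + 1}" for i in range(n_genes)]
    base = base_mean * rng.lognormal(0.0, 1.0, size=n_genes)

    donors = [f"CTRL-{i + 1}" for i in range(n_donors_per_condition)] + [
        f"IHD-{i + 1}" for i in range(n_donors_per_condition)
    ]
    conditions = ["control"] * n_donors_per_condition + ["IHD"] * n_donors_per_condition

    meta_rows = []
    count_blocks = []
    for donor, cond in zip(donors, conditions):
        mu = base.copy()
        if donor_effect_sd > 0:
            mu = mu * rng.lognormal(0.0, donor_effect_sd, size=n_genes)
        for d in de_genes:
            applies = (
                d.get("donor") == donor
                if "donor" in d
                else d.get("condition") == cond
            )
            if applies:
                mu[int(d["gene"])] *= np.exp(float(d["lfc"]))
        r = nb_dispersion
        p = r / (r + mu)
        block = rng.negative_binomial(r, p[None, :], size=(cells_per_donor, n_genes))
        count_blocks.append(block)
        for i in range(cells_per_donor):
            meta_rows.append(
                {
                    "cell_id": f"{donor}_c{i + 1}",
                    "donor_id": donor,
                    "condition": cond,
                    "cell_type": "cardiomyocyte",
                }
            )
    counts = np.vstack(count_blocks)
    meta = pd.DataFrame(meta_rows)
    return counts, meta, genes
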