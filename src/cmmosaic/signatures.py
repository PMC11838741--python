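"""Mutational-signature analysis on SBS96 spectra.

Covers catalog handling (COSMIC-style 96 x S probability matrices),
signature attribution by non-negative least-squares refitting, de novo
signature extraction by NMF with cophenetic/RSS rank selection, mapping of
de novo signatures back onto a catalog, transcriptional strand-bias testing,
and signature-specific burden modeling.

Attribution is deterministic non-negative refitting: exposures minimize the
squared reconstruction error of the observed spectrum under the catalog,
subject to non-negativity, and are rescaled so they sum to the observed
mutation count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet
from scipy.optimize import nnls
from scipy.spatial.distance import squareform
from scipy.stats import ranksums
from sklearn.decomposition import NMF

from cmmosaic.genes import GeneModelSet
from cmmosaic.sbs import CHANNELS_96, SUBSTITUTIONS, Spectrum, VariantCall


class InsufficientDataError(ValueError):
    """Too few observations for the requested test or fit."""


class InvalidRankError(ValueError):
    """NMF rank not representable for the given matrix."""


# ---------------------------------------------------------------------------
# Catalog


@dataclass
class SignatureCatalog:
    """96 x S matrix of channel probabilities with signature names."""

    matrix: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (96, len(self.names)):
            raise ValueError("catalog must be 96 x n_signatures")
        if (self.matrix < 0).any():
            raise ValueError("catalog entries must be non-negative")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("every catalog column must sum to 1")

    @property
    def n_signatures(self) -> int:
        return len(self.names)

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def to_tsv(self, path: str) -> None:
        pd.DataFrame(self.matrix, index=list(CHANNELS_96), columns=self.names).to_csv(
            path, sep="\t", index_label="context"
        )

    @classmethod
    def from_tsv(cls, path: str) -> "SignatureCatalog":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df = df.loc[list(CHANNELS_96)]  # enforce canonical channel order
        return cls(df.to_numpy(), list(df.columns))


def synthetic_catalog(
    n_signatures: int, seed: int, concentration: float = 0.1
) -> SignatureCatalog:
    """Random sparse (peaked) signatures for simulation, Dirichlet-distributed.

    Low ``concentration`` yields distinct, peaked profiles similar in shape
    to real SBS signatures; columns are exactly normalized.
    """
    rng = np.random.default_rng(seed)
    cols = rng.dirichlet(np.full(96, concentration), size=n_signatures).T
    names = [f"S{i + 1}" for i in range(n_signatures)]
    return SignatureCatalog(cols, names)


# ---------------------------------------------------------------------------
# Refitting


@dataclass
class ExposureVector:
    """Per-signature attributed mutation counts plus reconstruction residual.

    ``exposures`` are rescaled to sum to the spectrum total (attributed
    counts); ``raw_exposures`` is the unrescaled least-squares solution whose
    reconstruction achieves ``residual`` (the NNLS residual norm).
    """

    exposures: np.ndarray
    names: list[str]
    residual: float
    raw_exposures: np.ndarray | None = None

    def fractions(self) -> np.ndarray:
        t = self.exposures.sum()
        return self.exposures / t if t > 0 else self.exposures

    def as_series(self) -> pd.Series:
        return pd.Series(self.exposures, index=self.names)


def fit_exposures(spectrum: Spectrum, catalog: SignatureCatalog) -> ExposureVector:
    """Attribute a spectrum to catalog signatures by non-negative least squares.

    Exposures are rescaled so their sum equals the spectrum total; the
    reported residual is the NNLS reconstruction norm on the raw counts.
    """
    if spectrum.total <= 0:
        raise ValueError("cannot refit an empty spectrum")
    _warn_on_duplicate_columns(catalog)
    raw, resid = nnls(catalog.matrix, spectrum.counts)
    coef = raw.copy()
    s = coef.sum()
    if s > 0:
        coef = coef * (spectrum.total / s)
    return ExposureVector(coef, list(catalog.names), float(resid), raw_exposures=raw)


def _warn_on_duplicate_columns(catalog: SignatureCatalog) -> None:
    m = catalog.matrix
    for i in range(m.shape[1]):
        for j in range(i + 1, m.shape[1]):
            if np.allclose(m[:, i], m[:, j], atol=1e-12):
                warnings.warn(
                    f"catalog columns {catalog.names[i]} and {catalog.names[j]} are "
                    "identical; the refit is ill-posed and ties resolve to the first",
                    stacklevel=3,
                )
                return


def decompose_denovo(
    denovo: np.ndarray, catalog: SignatureCatalog
) -> list[ExposureVector]:
    """Refit each de novo signature column onto the catalog (weights sum to 1)."""
    denovo = np.asarray(denovo, dtype=float)
    out = []
    for j in range(denovo.shape[1]):
        col = denovo[:, j]
        spec = Spectrum(col / col.sum() if col.sum() > 0 else col)
        out.append(fit_exposures(spec, catalog))
    return out


# ---------------------------------------------------------------------------
# De novo NMF extraction


@dataclass
class NMFResult:
    rank: int
    signatures: np.ndarray  # 96 x k, columns sum to 1
    contributions: np.ndarray  # k x n_cells
    cophenetic: dict[int, float] = field(default_factory=dict)
    rss: dict[int, float] = field(default_factory=dict)


def _consensus_cophenetic(assignments: np.ndarray) -> float:
    """Cophenetic correlation of the consensus matrix over restarts.

    ``assignments`` is restarts x cells of cluster labels.  A constant
    consensus (perfectly stable single cluster) is defined as 1.0.
    """
    n = assignments.shape[1]
    consensus = np.zeros((n, n))
    for labels in assignments:
        consensus += labels[:, None] == labels[None, :]
    consensus /= assignments.shape[0]
    dist = 1.0 - consensus
    condensed = squareform(dist, checks=False)
    if condensed.std() < 1e-12:
        return 1.0
    link = average(condensed)
    coph, _ = cophenet(link, condensed)
    return float(coph)


def extract_denovo(
    spectra: np.ndarray,
    rank_range: range | list[int] = range(1, 7),
    n_restarts: int = 50,
    seed: int = 0,
    max_iter: int = 1000,
) -> NMFResult:
    """De novo signature extraction by NMF with consensus-based rank selection.

    ``spectra`` is cells x 96 counts.  For each candidate rank, ``n_restarts``
    multiplicative-update factorizations of the 96 x cells matrix are run
    from random starts; consensus clustering of cells (by dominant
    contribution) yields a cophenetic correlation per rank, and the best
    restart's residual sum of squares is recorded.  The chosen rank is the
    largest before the cophenetic coefficient first decreases, with the RSS
    curve kept in the diagnostics for cross-checking.
    """
    spectra = np.asarray(spectra, dtype=float)
    if spectra.ndim != 2 or spectra.shape[1] != 96:
        raise ValueError("spectra must be cells x 96")
    n_cells = spectra.shape[0]
    ranks = sorted(rank_range)
    if ranks[-1] >= min(n_cells, 96):
        raise InvalidRankError(
            f"max rank {ranks[-1]} must be < min(n_cells, 96) = {min(n_cells, 96)}"
        )
    if n_cells < ranks[-1] + 1:
        raise InvalidRankError("need at least rank+1 cells")

    M = spectra.T  # 96 x cells
    rng = np.random.default_rng(seed)
    coph: dict[int, float] = {}
    rss: dict[int, float] = {}
    best_factors: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    for k in ranks:
        assignments = np.empty((n_restarts, n_cells), dtype=int)
        best = (np.inf, None, None)
        for r in range(n_restarts):
            rs = int(rng.integers(0, 2**31 - 1))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = NMF(
                    n_components=k,
                    init="random",
                    solver="mu",
                    beta_loss="frobenius",
                    max_iter=max_iter,
                    random_state=rs,
                    tol=1e-6,
                )
                W = model.fit_transform(M)
                H = model.components_
            err = float(np.linalg.norm(M - W @ H) ** 2)
            assignments[r] = H.argmax(axis=0)
            if err < best[0]:
                best = (err, W, H)
        coph[k] = _consensus_cophenetic(assignments)
        rss[k] = best[0]
        best_factors[k] = (best[1], best[2])

    chosen = _select_rank(ranks, coph, rss)

    W, H = best_factors[chosen]
    scale = W.sum(axis=0)
    scale[scale == 0] = 1.0
    W = W / scale
    H = H * scale[:, None]
    return NMFResult(chosen, W, H, coph, rss)


def _select_rank(
    ranks: list[int],
    coph: dict[int, float],
    rss: dict[int, float],
    min_gain: float = np.log(2.0),
    coph_floor: float = 0.8,
) -> int:
    """Choose the factorization rank from the RSS inflection, cophenetic-vetoed.

    The chosen rank is the largest whose incremental fit still at least
    halves the residual sum of squares relative to the previous rank - the
    operational reading of the RSS "inflection point", since past the true
    rank extra factors only soak noise and the RSS curve flattens.  If that
    rank's consensus clustering has collapsed (cophenetic correlation below
    ``coph_floor``, i.e. the clustering "begins to decrease" materially),
    the choice steps down to the largest supported rank that remains stable.
    With no rank clearing the gain threshold the data carry no structure
    beyond the smallest candidate rank.
    """
    supported = [
        k
        for prev, k in zip(ranks, ranks[1:])
        if rss[prev] > 0 and np.log(rss[prev] / max(rss[k], 1e-300)) > min_gain
    ]
    if not supported:
        return ranks[0]
    k = supported[-1]
    if coph[k] < coph_floor:
        stable = [j for j in ranks if j <= k and coph[j] >= coph_floor]
        if stable:
            k = stable[-1]
    return k


def match_signatures(estimated: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal column matching (by cosine similarity) of two 96 x k matrices.

    Returns (permutation applied to estimated columns, per-pair cosines).
    """
    from scipy.optimize import linear_sum_assignment

    est = estimated / np.maximum(np.linalg.norm(estimated, axis=0), 1e-12)
    tru = truth / np.maximum(np.linalg.norm(truth, axis=0), 1e-12)
    cos = est.T @ tru  # k_est x k_true
    row, col = linear_sum_assignment(-cos)
    order = row[np.argsort(col)]
    return order, cos[row, col][np.argsort(col)]


# ---------------------------------------------------------------------------
# Transcriptional strand bias


def assign_transcriptional_strand(call: VariantCall, gene_models: GeneModelSet) -> str:
    """Classify a call as transcribed / untranscribed / intergenic / ambiguous.

    The pyrimidine-standardized base lies on the reference (+) strand when
    REF is C or T, else on the - strand.  Same strand as the gene definition
    means the lesion sits on the untranscribed (coding) strand; opposite
    means transcribed.  Overlapping genes on both strands give conflicting
    assignments and the call is excluded as ambiguous.
    """
    genes = gene_models.overlapping(call.contig, call.pos)
    if not genes:
        return "intergenic"
    pyr_strand = "+" if call.ref.upper() in ("C", "T") else "-"
    labels = {
        "untranscribed" if g.strand == pyr_strand else "transcribed" for g in genes
    }
    if len(labels) > 1:
        return "ambiguous"
    return labels.pop()


def strand_counts(
    calls: list[VariantCall], gene_models: GeneModelSet
) -> pd.DataFrame:
    """Per-cell transcribed/untranscribed counts by 6-way substitution class.

    Ambiguous (antisense-overlap) and intergenic calls are excluded; the
    number of ambiguous exclusions is available in the frame attrs.
    """
    from cmmosaic.sbs import COMPLEMENT

    rows = []
    n_ambiguous = 0
    for c in calls:
        strand = assign_transcriptional_strand(c, gene_models)
        if strand == "ambiguous":
            n_ambiguous += 1
            continue
        if strand == "intergenic":
            continue
        ref, alt = c.ref.upper(), c.alt.upper()
        if ref not in ("C", "T"):
            ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        rows.append({"cell_id": c.cell_id, "sub_class": f"{ref}>{alt}", "strand": strand})
    df = pd.DataFrame(rows, columns=["cell_id", "sub_class", "strand"])
    counts = (
        df.groupby(["cell_id", "sub_class", "strand"]).size().unstack(fill_value=0)
        if len(df)
        else pd.DataFrame(columns=["transcribed", "untranscribed"])
    )
    for col in ("transcribed", "untranscribed"):
        if col not in counts:
            counts[col] = 0
    counts = counts.reset_index() if len(df) else counts
    counts.attrs["n_ambiguous"] = n_ambiguous
    return counts


def strand_bias_test(counts: pd.DataFrame, min_cells: int = 3) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum test of transcribed vs untranscribed counts.

    ``counts`` has columns cell_id, sub_class, transcribed, untranscribed
    (one row per cell per class, as from :func:`strand_counts`).  Returns one
    row per substitution class with the statistic, P value, and a degenerate
    flag for all-zero classes (P reported as 1).
    """
    n_cells = counts["cell_id"].nunique() if len(counts) else 0
    if n_cells < min_cells:
        raise InsufficientDataError(
            f"strand-bias test requires >= {min_cells} cells, got {n_cells}"
        )
    cells = sorted(counts["cell_id"].unique())
    out = []
    for cls in SUBSTITUTIONS:
        sub = counts[counts["sub_class"] == cls].set_index("cell_id")
        t = sub["transcribed"].reindex(cells, fill_value=0).to_numpy(float)
        u = sub["untranscribed"].reindex(cells, fill_value=0).to_numpy(float)
        if t.sum() == 0 and u.sum() == 0:
            out.append({"sub_class": cls, "statistic": 0.0, "p_value": 1.0, "degenerate": True})
            continue
        stat, p = ranksums(t, u)
        out.append({"sub_class": cls, "statistic": float(stat), "p_value": float(p), "degenerate": False})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Signature-specific burden series


def signature_burden_series(
    exposure_fractions: pd.DataFrame,
    burden: pd.DataFrame,
    model: int = 2,
    near_zero_control_threshold: float = 6.0,
) -> dict[str, object]:
    """Fit the aging/disease burden model per signature.

    ``exposure_fractions``: cells x signatures exposure fractions (rows
    indexed by cell_id, rows sum to 1).  ``burden``: per-cell table with
    columns cell_id, donor_id, age, condition, burden_per_gb.  Each cell's
    signature-specific burden is its total burden times the exposure
    fraction.  Signatures whose control-group burden is near zero (mean
    below ``near_zero_control_threshold`` sSNVs/GB) are fitted with the
    fixed-effects-only linear model, since a donor random intercept is not
    identifiable there; this mirrors the fallback used for genuinely sparse
    signatures.  All-zero signatures are skipped with a flag.
    """
    from cmmosaic.burden import MixedModelSpec, fit_burden_model

    burden = burden.set_index("cell_id")
    fits: dict[str, object] = {}
    for sig in exposure_fractions.columns:
        frac = exposure_fractions[sig].reindex(burden.index)
        data = burden.copy()
        data["burden_per_gb"] = data["burden_per_gb"] * frac
        if np.allclose(data["burden_per_gb"], 0.0):
            fits[sig] = None
            continue
        controls = data[data["condition"] != "IHD"]
        use_model = model
        if len(controls) and controls["burden_per_gb"].mean() < near_zero_control_threshold:
            use_model = 3
        # the fallback drops only the random term; fixed effects are kept
        spec = MixedModelSpec(model=use_model, include_condition=(model == 2))
        fits[sig] = fit_burden_model(data.reset_index(), spec)
    return fits
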