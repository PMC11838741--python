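"""Leave-one-out consensus differential expression and related tests.

Counts are library-size normalized to 10,000 per cell and log1p
transformed before testing.  A marker test between two groups reports, per
gene, the natural-log fold change of group means of normalized counts (with
pseudocount 1), the expressing fraction per group, and a two-sided Wilcoxon
rank-sum P value; genes are prefiltered by min.pct and by a
direction-specific log-fold-change threshold before testing.

The leave-one-out (LOO) consensus enumerates every (control donor, diseased
donor) pair, re-runs the marker test with both excluded, and keeps only
genes called in the same direction in all iterations - removing genes whose
signal is driven by a single donor.  With 3 donors per condition this is 9
iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

TARGET_LIBRARY_SIZE = 10_000
DEFAULT_UP_LFC = 0.30
DEFAULT_DOWN_LFC = 0.25
DEFAULT_MIN_PCT = 0.1


class InsufficientCellsError(ValueError):
    pass


class DesignError(ValueError):
    pass


@dataclass
class LabeledCounts:
    """Cell x gene integer counts with donor/condition/cell-type labels."""

    counts: np.ndarray
    meta: pd.DataFrame  # columns: cell_id, donor_id, condition, cell_type
    genes: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.meta), len(self.genes)):
            raise ValueError("counts shape must be (n_cells, n_genes)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        cond_per_donor = self.meta.groupby("donor_id")["condition"].nunique()
        if (cond_per_donor > 1).any():
            raise ValueError("every donor must carry a single condition")

    def normalized(self) -> np.ndarray:
        """Library-size scaled to 10,000 then log1p."""
        lib = self.counts.sum(axis=1, keepdims=True).astype(float)
        lib[lib == 0] = 1.0
        return np.log1p(self.counts / lib * TARGET_LIBRARY_SIZE)

    def subset(self, mask: np.ndarray) -> "LabeledCounts":
        return LabeledCounts(
            self.counts[mask], self.meta[mask].reset_index(drop=True), self.genes
        )


def markers(
    data: LabeledCounts,
    group_a: np.ndarray,
    group_b: np.ndarray,
    lfc_threshold: float = 0.25,
    min_pct: float = DEFAULT_MIN_PCT,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Differential genes between cell masks A and B.

    lfc is ln(mean_norm_A + 1) - ln(mean_norm_B + 1) on library-normalized
    (pre-log) counts.  Genes pass the prefilter when expressed in at least
    ``min_pct`` of cells in either group and |lfc| >= ``lfc_threshold``;
    survivors get a two-sided Wilcoxon rank-sum test on the log-normalized
    values.  Output columns: gene, lfc, pct_a, pct_b, p, direction.
    """
    if group_a.sum() < min_cells or group_b.sum() < min_cells:
        raise InsufficientCellsError(
            f"both groups need >= {min_cells} cells "
            f"(got {int(group_a.sum())} and {int(group_b.sum())})"
        )
    lib = data.counts.sum(axis=1, keepdims=True).astype(float)
    lib[lib == 0] = 1.0
    norm = data.counts / lib * TARGET_LIBRARY_SIZE
    logn = np.log1p(norm)

    mean_a = norm[group_a].mean(axis=0)
    mean_b = norm[group_b].mean(axis=0)
    lfc = np.log(mean_a + 1) - np.log(mean_b + 1)
    pct_a = (data.counts[group_a] > 0).mean(axis=0)
    pct_b = (data.counts[group_b] > 0).mean(axis=0)

    keep = (np.maximum(pct_a, pct_b) >= min_pct) & (np.abs(lfc) >= lfc_threshold)
    rows = []
    for gi in np.flatnonzero(keep):
        a, b = logn[group_a, gi], logn[group_b, gi]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            continue  # identical constant gene: no test
        _, p = stats.ranksums(a, b)
        rows.append(
            {
                "gene": data.genes[gi],
                "lfc": float(lfc[gi]),
                "pct_a": float(pct_a[gi]),
                "pct_b": float(pct_b[gi]),
                "p": float(p),
                "direction": "up" if lfc[gi] > 0 else "down",
            }
        )
    return pd.DataFrame(rows, columns=["gene", "lfc", "pct_a", "pct_b", "p", "direction"])


@dataclass
class LOOResult:
    consensus_up: list[str]
    consensus_down: list[str]
    iterations: list[dict] = field(default_factory=list)  # excluded pair + DEG sets

    @property
    def n_iterations(self) -> int:
        return len(self.iterations)


def loo_consensus(
    data: LabeledCounts,
    up_threshold: float = DEFAULT_UP_LFC,
    down_threshold: float = DEFAULT_DOWN_LFC,
    min_pct: float = DEFAULT_MIN_PCT,
    p_cutoff: float = 0.05,
    min_cells_per_donor: int = 0,
) -> LOOResult:
    """Leave-one-donor-out-per-condition consensus DEGs (diseased vs control).

    Direction-specific log-fold-change thresholds gate the up and down
    calls separately.  The consensus is the intersection over all
    (control, diseased) exclusion pairs.  ``min_cells_per_donor`` optionally
    prefilters donors with too few cells before enumerating pairs.
    """
    meta = data.meta
    if min_cells_per_donor:
        sizes = meta.groupby("donor_id").size()
        keep_donors = set(sizes[sizes >= min_cells_per_donor].index)
        data = data.subset(meta["donor_id"].isin(keep_donors).to_numpy())
        meta = data.meta
    donors = meta[["donor_id", "condition"]].drop_duplicates()
    ctrl = sorted(donors.loc[donors["condition"] != "IHD", "donor_id"])
    ihd = sorted(donors.loc[donors["condition"] == "IHD", "donor_id"])
    if len(ctrl) < 2 or len(ihd) < 2:
        raise DesignError("LOO needs >= 2 donors per condition")

    iterations = []
    up_sets, down_sets = [], []
    for c_out, i_out in product(ctrl, ihd):
        mask = ~meta["donor_id"].isin([c_out, i_out]).to_numpy()
        sub = data.subset(mask)
        if sub.meta["condition"].nunique() < 2:
            raise DesignError("an iteration removed an entire condition")
        is_ihd = (sub.meta["condition"] == "IHD").to_numpy()
        up = markers(sub, is_ihd, ~is_ihd, lfc_threshold=up_threshold, min_pct=min_pct)
        up_genes = set(up.loc[(up["direction"] == "up") & (up["p"] < p_cutoff), "gene"])
        down = markers(sub, is_ihd, ~is_ihd, lfc_threshold=down_threshold, min_pct=min_pct)
        down_genes = set(
            down.loc[(down["direction"] == "down") & (down["p"] < p_cutoff), "gene"]
        )
        iterations.append(
            {"excluded_control": c_out, "excluded_ihd": i_out, "up": up_genes, "down": down_genes}
        )
        up_sets.append(up_genes)
        down_sets.append(down_genes)

    consensus_up = sorted(set.intersection(*up_sets)) if up_sets else []
    consensus_down = sorted(set.intersection(*down_sets)) if down_sets else []
    return LOOResult(consensus_up, consensus_down, iterations)


def metagene_score(
    data: LabeledCounts, gene_sets: dict[str, list[str]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell mean normalized expression over named gene sets.

    Returns (scores, tests): per-cell score per set, and a two-sided
    rank-sum comparison of the score between conditions per set.  Genes
    absent from the matrix are dropped with a warning; an empty intersection
    raises.
    """
    import warnings

    logn = data.normalized()
    index = {g: i for i, g in enumerate(data.genes)}
    scores = pd.DataFrame({"cell_id": data.meta["cell_id"], "condition": data.meta["condition"]})
    tests = []
    for name, genes in gene_sets.items():
        present = [index[g] for g in genes if g in index]
        missing = [g for g in genes if g not in index]
        if not present:
            raise ValueError(f"gene set {name!r} has no genes in the matrix")
        if missing:
            warnings.warn(f"gene set {name!r}: dropping absent genes {missing}", stacklevel=2)
        scores[name] = logn[:, present].mean(axis=1)
        a = scores.loc[scores["condition"] == "IHD", name]
        b = scores.loc[scores["condition"] != "IHD", name]
        if len(a) and len(b):
            stat, p = stats.ranksums(a, b)
        else:
            stat, p = np.nan, np.nan
        tests.append({"set": name, "statistic": float(stat), "p": float(p)})
    return scores, pd.DataFrame(tests)


def proportion_test(
    meta: pd.DataFrame, cell_type: str
) -> tuple[pd.DataFrame, float]:
    """Per-donor fraction of a cell type, compared between conditions.

    The donor is the unit of analysis: the fraction of cells of
    ``cell_type`` is computed per donor and conditions are compared with a
    two-sided Wilcoxon rank-sum test.  Donors with zero cells are excluded
    with a warning.
    """
    import warnings

    sizes = meta.groupby("donor_id").size()
    empty = sizes[sizes == 0].index.tolist()
    if empty:
        warnings.warn(f"excluding donors with zero cells: {empty}", stacklevel=2)
    frac = (
        meta.groupby(["donor_id", "condition"])
        .apply(lambda g: (g["cell_type"] == cell_type).mean(), include_groups=False)
        .rename("fraction")
        .reset_index()
    )
    a = frac.loc[frac["condition"] == "IHD", "fraction"].to_numpy()
    b = frac.loc[frac["condition"] != "IHD", "fraction"].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise DesignError("proportion test needs >= 2 donors per condition")
    return frac, exact_rank_sum_p(a, b)


def exact_rank_sum_p(a: np.ndarray, b: np.ndarray, max_enumeration: int = 20000) -> float:
    """Two-sided rank-sum P; exact permutation null for small samples.

    Donor-level samples are tiny, so the null is enumerated exactly over all
    assignments of the pooled values (ties handled by midranks, matching the
    exact two-sided rank-sum value).  Larger samples fall back to the normal
    approximation.
    """
    from itertools import combinations
    from math import comb as _comb

    m, n = len(a), len(b)
    if _comb(m + n, m) > max_enumeration:
        _, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        return float(p)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    obs = abs(ranks[:m].sum() - m * (m + n + 1) / 2)
    hits = total = 0
    for idx in combinations(range(m + n), m):
        stat = abs(ranks[list(idx)].sum() - m * (m + n + 1) / 2)
        hits += stat >= obs - 1e-12
        total += 1
    return hits / total
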