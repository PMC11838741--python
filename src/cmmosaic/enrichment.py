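"""Context-preserving permutation test of mutation density vs genomic tracks.

Units (genes, or fixed-width accessibility bins) are ranked by their track
value and split into eight equal-count groups, group 1 lowest.  The null
model shuffles every observed sSNV to a uniformly drawn position with the
same pyrimidine-standardized trinucleotide context inside phaseable
intervals, preserving the exact context histogram per permutation and
keeping positions unique within one permutation.  Observed density per
group is compared to the permutation mean (the expected density), and the
trend of the observed/expected ratio across groups is summarized by a
least-squares correlation R and its P value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from cmmosaic.sbs import VariantCall, context_position_index, standardize_context


class PlacementError(RuntimeError):
    pass


@dataclass
class GroupTrack:
    """Units grouped 1..k by ascending track value, with genomic footprints."""

    units: pd.DataFrame  # columns: unit, value, group
    footprints: dict[int, list[tuple[str, int, int]]]  # group -> BED intervals
    degenerate: bool = False

    def group_span_mb(self, group: int) -> float:
        return sum(e - s for _, s, e in self.footprints.get(group, [])) / 1e6


def make_groups(
    values: pd.Series,
    footprints_by_unit: Mapping[str, list[tuple[str, int, int]]],
    k: int = 8,
) -> GroupTrack:
    """Split units into ``k`` equal-count groups by ascending value.

    Ties (including the all-equal case) break by stable unit order; the
    all-equal case is flagged degenerate.
    """
    values = values[np.isfinite(values)]
    if len(values) < k:
        raise ValueError(f"need >= {k} units with finite values, got {len(values)}")
    order = np.argsort(values.to_numpy(), kind="stable")
    units = values.index.to_numpy()[order]
    splits = np.array_split(np.arange(len(units)), k)
    rows = []
    footprints: dict[int, list[tuple[str, int, int]]] = {}
    for gi, idx in enumerate(splits, start=1):
        footprints[gi] = []
        for i in idx:
            u = units[i]
            rows.append({"unit": u, "value": float(values.loc[u]), "group": gi})
            footprints[gi].extend(footprints_by_unit.get(u, []))
    degenerate = bool(values.nunique() == 1)
    return GroupTrack(pd.DataFrame(rows), footprints, degenerate)


def fixed_width_bins(
    contig: str, length: int, values: np.ndarray, bin_width: int = 10_000
) -> tuple[pd.Series, dict[str, list[tuple[str, int, int]]]]:
    """Helper for accessibility tracks: per-bin values + bin footprints."""
    n = len(values)
    series = pd.Series(values, index=[f"bin{i}" for i in range(n)])
    fp = {
        f"bin{i}": [(contig, i * bin_width, min((i + 1) * bin_width, length))]
        for i in range(n)
    }
    return series, fp


def permute_calls(
    calls: Sequence[VariantCall],
    phaseable: Sequence[tuple[str, int, int]],
    sequence: str,
    n_perm: int = 1000,
    seed: int = 0,
    context_index: Mapping[str, np.ndarray] | None = None,
) -> list[np.ndarray]:
    """Shuffle calls within phaseable regions preserving trinucleotide contexts.

    Returns ``n_perm`` arrays of 1-based permuted positions (call order
    preserved); substitution identities stay with their calls.  Within one
    permutation positions are sampled without replacement per context, so no
    duplicate sites arise.
    """
    contig = calls[0].contig if calls else None
    if context_index is None:
        intervals = [(s, e) for c, s, e in phaseable if contig is None or c == contig]
        context_index = context_position_index(sequence, intervals)
    # group call indices by standardized context
    by_ctx: dict[str, list[int]] = {}
    for i, c in enumerate(calls):
        tri = sequence[c.pos - 2 : c.pos + 1].upper()
        by_ctx.setdefault(standardize_context(tri), []).append(i)
    for tri, idx in by_ctx.items():
        avail = len(context_index.get(tri, ()))
        if avail < len(idx):
            raise PlacementError(
                f"context {tri}: {len(idx)} calls but only {avail} phaseable positions"
            )
    rng = np.random.default_rng(seed)
    perms = []
    for _ in range(n_perm):
        pos = np.empty(len(calls), dtype=np.int64)
        for tri, idx in by_ctx.items():
            draw = rng.choice(context_index[tri], size=len(idx), replace=False)
            pos[idx] = draw
        perms.append(pos)
    return perms


def _density(positions: np.ndarray, footprints: list[tuple[str, int, int]]) -> float:
    """Calls per Mb inside the footprint (positions are 1-based)."""
    span = sum(e - s for _, s, e in footprints)
    if span == 0:
        return np.nan
    hits = 0
    for _, s, e in footprints:
        hits += int(((positions > s) & (positions <= e)).sum())
    return hits / (span / 1e6)


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # group, observed, expected_mean, expected_sd, ratio, ratio_sd
    r_value: float
    p_value: float
    excluded_groups: list[int] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "R": self.r_value,
            "P": self.p_value,
            "groups": self.table.to_dict(orient="records"),
        }


def enrichment_ratio(
    calls: Sequence[VariantCall],
    permuted_positions: Sequence[np.ndarray],
    groups: GroupTrack,
) -> EnrichmentResult:
    """Observed/expected density ratios per group plus the linear trend.

    Expected density is the mean over permutations; the ratio SD comes from
    the permutation spread scaled by the observed density (delta method:
    ratio x SD(perm)/mean(perm)).  Groups whose expected density is zero
    across all permutations are excluded with a warning.  R and P are the
    Pearson correlation of ratio against group index from a least-squares
    fit.
    """
    if len(permuted_positions) < 100:
        raise ValueError("need >= 100 permutations for SD reporting")
    obs_pos = np.array([c.pos for c in calls], dtype=np.int64)
    rows = []
    excluded = []
    for g in sorted(groups.footprints):
        fp = groups.footprints[g]
        obs = _density(obs_pos, fp)
        perm = np.array([_density(p, fp) for p in permuted_positions])
        mean, sd = float(np.nanmean(perm)), float(np.nanstd(perm))
        if not np.isfinite(mean) or mean == 0:
            excluded.append(g)
            continue
        ratio = obs / mean
        rows.append(
            {
                "group": g,
                "observed": obs,
                "expected_mean": mean,
                "expected_sd": sd,
                "ratio": ratio,
                "ratio_sd": ratio * sd / mean if obs > 0 else sd / mean,
            }
        )
    table = pd.DataFrame(rows)
    if len(table) >= 3:
        fit = stats.linregress(table["group"], table["ratio"])
        r, p = float(fit.rvalue), float(fit.pvalue)
    else:
        r, p = np.nan, np.nan
    return EnrichmentResult(table, r, p, excluded)
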