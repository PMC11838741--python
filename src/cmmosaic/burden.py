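"""Genome-wide sSNV burden estimation and mixed-effects burden models.

Burden estimation extrapolates raw somatic calls to a genome-wide rate using
germline-recovery sensitivity measured in central depth strata (a trimmed
approach): per-GB burden = calls / sum over trimmed strata of
(sensitivity_s x callable length_s).  When a large zero-depth block drags the
depth quantiles to zero and leaves the trimmed strata empty, a refined
variant excludes zero-depth territory before trimming, rescuing cells whose
only defect is missing coverage.

The burden models are linear mixed-effects regressions of per-cell burden on
age (model 1), age plus disease condition (model 2), with a Gaussian random
intercept per donor, fitted by maximum likelihood; model 3 drops the random
term (ordinary linear regression) and serves as the automatic fallback when
the donor variance is estimated at the boundary.  Fixed-effect tests use
Satterthwaite-approximate degrees of freedom derived from the ML variance
components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

#: Diploid genome size used to convert per-GB burden to per-cell burden.
#: Consistent with the paired study figures (686/GB ~ 4,010/cell and
#: 7.90/GB/yr ~ 46/cell/yr), i.e. ~5.845 GB of callable diploid genome.
DIPLOID_GENOME_GB = 5.845

SINGULARITY_RATIO = 1e-8  # sigma_u^2 / sigma_e^2 below this is singular


class InsufficientDataError(ValueError):
    pass


class UndefinedBurdenError(ValueError):
    """Effective callable genome is zero; burden cannot be computed."""


class CollinearityError(ValueError):
    pass


class FitFailureError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Sensitivity and burden


@dataclass
class SensitivityProfile:
    """Per-depth-stratum germline-recovery sensitivity over trimmed strata."""

    depth_lo: np.ndarray  # inclusive lower depth bound per stratum
    depth_hi: np.ndarray  # inclusive upper depth bound per stratum
    sensitivity: np.ndarray  # fraction of germline hets recovered
    length_bp: np.ndarray  # callable bp per stratum
    method: str = "standard"  # or "zero-depth-refined"

    def __post_init__(self) -> None:
        for name in ("depth_lo", "depth_hi", "sensitivity", "length_bp"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if ((self.sensitivity < 0) | (self.sensitivity > 1)).any():
            raise ValueError("sensitivities must lie in [0, 1]")

    @property
    def effective_callable_gb(self) -> float:
        return float((self.sensitivity * self.length_bp).sum() / 1e9)

    def contains_depth(self, depth: float) -> bool:
        return bool(((self.depth_lo <= depth) & (depth <= self.depth_hi)).any())


def estimate_sensitivity(
    recovered: Sequence[tuple[str, int]],
    truth: Sequence[tuple[str, int]],
    bins: pd.DataFrame,
    trim: tuple[float, float] = (0.25, 0.75),
    n_strata: int = 4,
    method: str = "standard",
    min_sites: int = 50,
) -> SensitivityProfile:
    """Estimate detection sensitivity from germline-het recovery in depth strata.

    Parameters
    ----------
    recovered, truth
        (contig, 1-based position) of germline heterozygous sites recovered
        in the single cell, and of all true germline het sites.
    bins
        Binned depth profile with columns chrom, start, end, depth (BED-style
        0-based half-open coordinates).
    trim
        Quantile pair bounding the trimmed (central) depth region.  With the
        ``standard`` method the quantiles are taken over the full bin-depth
        distribution; ``zero-depth-refined`` first removes zero-depth bins.
    n_strata
        Number of equal-count depth strata inside the trimmed region.
    """
    if method not in ("standard", "zero-depth-refined"):
        raise ValueError(f"unknown method {method!r}")
    depths = bins["depth"].to_numpy(float)
    pool = depths if method == "standard" else depths[depths > 0]
    if pool.size == 0:
        raise InsufficientDataError("no usable bins in depth profile")
    qlo, qhi = np.quantile(pool, trim)
    keep = (depths >= qlo) & (depths <= qhi)
    if method == "zero-depth-refined":
        keep &= depths > 0
    trimmed = bins[keep]
    if not len(trimmed):
        raise InsufficientDataError("trimmed depth region is empty")

    nonzero_truth = _sites_with_depth(truth, bins)
    if (nonzero_truth["depth"] > 0).sum() < min_sites:
        raise InsufficientDataError(
            f"fewer than {min_sites} germline het sites in nonzero-depth strata"
        )
    truth_df = _sites_with_depth(truth, trimmed, must_hit=False)
    truth_df = truth_df[truth_df["hit"]]
    if not len(truth_df):
        raise InsufficientDataError("no germline sites in the trimmed depth region")
    rec_set = set(recovered)
    truth_df["recovered"] = [
        (c, p) in rec_set for c, p in zip(truth_df["chrom"], truth_df["pos"])
    ]

    # equal-count depth strata over the trimmed bins
    tdepths = trimmed["depth"].to_numpy(float)
    edges = np.quantile(tdepths, np.linspace(0, 1, n_strata + 1))
    edges = np.unique(edges)
    if len(edges) < 2:
        edges = np.array([tdepths.min(), tdepths.max() + 1e-9])
    lengths = trimmed["end"].to_numpy() - trimmed["start"].to_numpy()

    lo, hi, sens, length = [], [], [], []
    overall = truth_df["recovered"].mean()
    for i in range(len(edges) - 1):
        a, b = edges[i], edges[i + 1]
        in_stratum = (tdepths >= a) & (
            (tdepths <= b) if i == len(edges) - 2 else (tdepths < b)
        )
        if not in_stratum.any():
            continue
        mask = (truth_df["depth"] >= a) & (
            (truth_df["depth"] <= b) if i == len(edges) - 2 else (truth_df["depth"] < b)
        )
        s = truth_df.loc[mask, "recovered"].mean() if mask.any() else overall
        lo.append(a)
        hi.append(b)
        sens.append(float(s))
        length.append(int(lengths[in_stratum].sum()))
    return SensitivityProfile(
        np.array(lo), np.array(hi), np.array(sens), np.array(length), method=method
    )


def _sites_with_depth(
    sites: Sequence[tuple[str, int]], bins: pd.DataFrame, must_hit: bool = True
) -> pd.DataFrame:
    """Annotate (contig, pos) sites with the depth of their containing bin."""
    rows = []
    by_chrom = {c: g.sort_values("start") for c, g in bins.groupby("chrom")}
    for chrom, pos in sites:
        g = by_chrom.get(chrom)
        depth, hit = 0.0, False
        if g is not None:
            starts = g["start"].to_numpy()
            idx = np.searchsorted(starts, pos - 1, side="right") - 1
            if idx >= 0 and pos - 1 < g["end"].iloc[idx]:
                depth, hit = float(g["depth"].iloc[idx]), True
        rows.append({"chrom": chrom, "pos": pos, "depth": depth, "hit": hit})
    df = pd.DataFrame(rows)
    return df[df["hit"]] if must_hit else df


@dataclass
class BurdenEstimate:
    raw_calls: int
    effective_callable_gb: float
    burden_per_gb: float
    burden_per_cell: float
    method: str = "standard"


def genome_burden(
    calls: int,
    sensitivity: SensitivityProfile,
    genome_size_gb: float = DIPLOID_GENOME_GB,
) -> BurdenEstimate:
    """Sensitivity-corrected genome-wide burden from calls in the trimmed strata.

    ``calls`` counts somatic SNVs lying inside the profile's trimmed depth
    strata.  Per-GB burden divides by the effective callable genome
    (sensitivity-weighted stratum length); per-cell burden scales by the
    diploid genome constant.
    """
    eff = sensitivity.effective_callable_gb
    if eff <= 0:
        raise UndefinedBurdenError(
            "effective callable genome is zero"
            + (
                " (a zero-depth-dominated profile; try the zero-depth-refined method)"
                if sensitivity.method == "standard"
                else ""
            )
        )
    per_gb = calls / eff
    return BurdenEstimate(
        raw_calls=int(calls),
        effective_callable_gb=eff,
        burden_per_gb=per_gb,
        burden_per_cell=per_gb * genome_size_gb,
        method=sensitivity.method,
    )


def calls_in_strata(
    calls: Sequence[tuple[str, int]], bins: pd.DataFrame, profile: SensitivityProfile
) -> int:
    """Count calls whose containing bin's depth falls in the profile's strata."""
    df = _sites_with_depth(calls, bins, must_hit=False)
    return int(sum(h and profile.contains_depth(d) for h, d in zip(df["hit"], df["depth"])))


# ---------------------------------------------------------------------------
# Linear mixed-effects burden models


@dataclass
class MixedModelSpec:
    """Model 1: age + donor random intercept; 2: + condition; 3: no random term.

    ``include_condition`` overrides the default fixed-effect structure (model
    2 includes the condition indicator, models 1 and 3 follow the request
    that produced them).  ``covariates`` are additional per-cell fixed
    effects by column name.
    """

    model: int = 1
    include_condition: bool | None = None
    covariates: tuple[str, ...] = ()
    response: str = "burden_per_gb"

    def wants_condition(self) -> bool:
        if self.include_condition is not None:
            return self.include_condition
        return self.model == 2


@dataclass
class MixedModelFit:
    params: pd.DataFrame  # index: term; columns: estimate, se, df, t, p
    sigma_u2: float
    sigma_e2: float
    model: int
    loglik: float
    converged: bool = True
    singular: bool = False
    fallback: bool = False
    normal_approx: bool = False

    def estimate(self, term: str) -> float:
        return float(self.params.loc[term, "estimate"])

    def p_value(self, term: str) -> float:
        return float(self.params.loc[term, "p"])


def _design(data: pd.DataFrame, spec: MixedModelSpec) -> tuple[np.ndarray, list[str]]:
    n = len(data)
    cols = [np.ones(n)]
    names = ["intercept"]
    cols.append(data["age"].to_numpy(float))
    names.append("age")
    if spec.wants_condition():
        cond = (data["condition"].astype(str) == "IHD").astype(float).to_numpy()
        cols.append(cond)
        names.append("condition")
    for cov in spec.covariates:
        x = data[cov].to_numpy(float)
        if not np.isfinite(x).all():
            raise ValueError(f"covariate {cov!r} contains non-finite values")
        if np.ptp(x) == 0:
            raise ValueError(f"covariate {cov!r} is constant")
        if spec.wants_condition():
            cond = (data["condition"].astype(str) == "IHD").astype(float).to_numpy()
            if np.ptp(cond) > 0:
                r = np.corrcoef(x, cond)[0, 1]
                if abs(r) > 1 - 1e-10:
                    raise CollinearityError(
                        f"covariate {cov!r} is collinear with the condition indicator"
                    )
        cols.append(x)
        names.append(cov)
    return np.column_stack(cols), names


def _group_blocks(data: pd.DataFrame, y: np.ndarray, X: np.ndarray):
    codes, _ = pd.factorize(data["donor_id"])
    blocks = []
    for g in range(codes.max() + 1):
        idx = np.flatnonzero(codes == g)
        blocks.append((y[idx], X[idx]))
    return blocks


def _profiled_nll(theta: np.ndarray, blocks) -> float:
    """-log ML likelihood profiled over beta, random-intercept model."""
    su2, se2 = float(theta[0]), float(theta[1])
    se2 = max(se2, 1e-12)
    su2 = max(su2, 0.0)
    XtVX = 0.0
    XtVy = 0.0
    logdet = 0.0
    # Woodbury: V_j^-1 = (1/se2) (I - su2/(se2 + n_j su2) J)
    for yj, Xj in blocks:
        nj = len(yj)
        c = su2 / (se2 + nj * su2)
        Xs, ys = Xj.sum(axis=0), yj.sum()
        XtVX = XtVX + (Xj.T @ Xj - c * np.outer(Xs, Xs)) / se2
        XtVy = XtVy + (Xj.T @ yj - c * Xs * ys) / se2
        logdet += (nj - 1) * np.log(se2) + np.log(se2 + nj * su2)
    # age varies only between donors, so X'V^-1X degenerates as su2 -> inf;
    # fall back to a least-squares solve when the optimizer probes there
    try:
        beta = np.linalg.solve(XtVX, XtVy)
    except np.linalg.LinAlgError:
        beta, *_ = np.linalg.lstsq(XtVX, XtVy, rcond=None)
    quad = 0.0
    n = 0
    for yj, Xj in blocks:
        rj = yj - Xj @ beta
        nj = len(rj)
        c = su2 / (se2 + nj * su2)
        rs = rj.sum()
        quad += (rj @ rj - c * rs * rs) / se2
        n += nj
    return 0.5 * (logdet + quad + n * np.log(2 * np.pi))


def _gls(theta: np.ndarray, blocks) -> tuple[np.ndarray, np.ndarray]:
    """GLS beta-hat and its covariance (X' V^-1 X)^-1 at given theta."""
    su2, se2 = max(float(theta[0]), 0.0), max(float(theta[1]), 1e-12)
    XtVX = 0.0
    XtVy = 0.0
    for yj, Xj in blocks:
        nj = len(yj)
        c = su2 / (se2 + nj * su2)
        Xs, ys = Xj.sum(axis=0), yj.sum()
        XtVX = XtVX + (Xj.T @ Xj - c * np.outer(Xs, Xs)) / se2
        XtVy = XtVy + (Xj.T @ yj - c * Xs * ys) / se2
    try:
        C = np.linalg.inv(XtVX)
    except np.linalg.LinAlgError:
        C = np.linalg.pinv(XtVX)
    return C @ XtVy, C


def _ols_fit(
    y: np.ndarray, X: np.ndarray, names: list[str], model: int, **flags
) -> MixedModelFit:
    import statsmodels.api as sm

    res = sm.OLS(y, X).fit()
    dfres = max(len(y) - X.shape[1], 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = res.params / res.bse
    p = 2 * stats.t.sf(np.abs(t), dfres)
    p = np.where(res.bse == 0, np.where(res.params == 0, 1.0, 0.0), p)
    params = pd.DataFrame(
        {
            "estimate": res.params,
            "se": res.bse,
            "df": float(dfres),
            "t": t,
            "p": p,
        },
        index=names,
    )
    return MixedModelFit(
        params=params,
        sigma_u2=0.0,
        sigma_e2=float(res.ssr / dfres),
        model=model,
        loglik=float(res.llf),
        **flags,
    )


def fit_burden_model(data: pd.DataFrame, spec: MixedModelSpec) -> MixedModelFit:
    """Fit a burden model by maximum likelihood.

    Models 1 and 2 include a Gaussian donor random intercept; fixed-effect
    P values use a t distribution with Satterthwaite degrees of freedom
    computed from the ML variance-component covariance.  A donor variance
    estimated at the boundary (sigma_u^2 < 1e-8 x sigma_e^2) triggers the
    documented fallback to the fixed-effects-only linear model, preserving
    the fixed-effect structure and flagged in the result.
    """
    if data["donor_id"].nunique() < 2:
        raise InsufficientDataError("need >= 2 donors")
    if spec.wants_condition() and data["condition"].astype(str).nunique() < 2:
        raise InsufficientDataError("condition model requires both conditions present")
    y = data[spec.response].to_numpy(float)
    X, names = _design(data, spec)

    if spec.model == 3:
        return _ols_fit(y, X, names, model=3)

    blocks = _group_blocks(data, y, X)

    # starting values from OLS and donor-mean dispersion
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta0
    se2_0 = max(float(resid.var()), 1e-8)
    donor_means = pd.Series(resid).groupby(data["donor_id"].to_numpy()).mean()
    su2_0 = max(float(donor_means.var()) if len(donor_means) > 1 else se2_0 / 2, 1e-8)

    if se2_0 < 1e-10 * max(1.0, float(np.var(y))) or np.allclose(resid, 0, atol=1e-10):
        # interpolating (noiseless) data: GLS = OLS = exact solution
        return _ols_fit(y, X, names, model=spec.model, singular=True, fallback=True)

    best = None
    for start in ((su2_0, se2_0), (se2_0, se2_0), (1e-6 * se2_0, se2_0)):
        res = optimize.minimize(
            _profiled_nll,
            x0=np.array(start),
            args=(blocks,),
            method="L-BFGS-B",
            bounds=[(0.0, None), (1e-10 * se2_0, None)],
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitFailureError("mixed-model likelihood optimization failed")
    su2, se2 = float(best.x[0]), float(best.x[1])

    if su2 < SINGULARITY_RATIO * se2:
        fit = _ols_fit(y, X, names, model=3, fallback=True, singular=True)
        return fit

    theta = np.array([su2, se2])
    beta, C = _gls(theta, blocks)
    se = np.sqrt(np.diag(C))

    dfs = _satterthwaite_df(theta, blocks, len(y) - X.shape[1])
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), dfs)
    params = pd.DataFrame(
        {"estimate": beta, "se": se, "df": dfs, "t": t, "p": p}, index=names
    )
    return MixedModelFit(
        params=params,
        sigma_u2=su2,
        sigma_e2=se2,
        model=spec.model,
        loglik=-float(best.fun),
        converged=bool(best.success),
        normal_approx=not np.isfinite(dfs).all(),
    )


def _satterthwaite_df(theta: np.ndarray, blocks, dfres: int) -> np.ndarray:
    """Satterthwaite degrees of freedom per fixed-effect coefficient.

    df_j = 2 f_j^2 / (g_j' A g_j) with f_j(theta) the j-th diagonal of
    (X'V^-1X)^-1, g_j its gradient in the variance components, and A the
    asymptotic covariance of theta-hat (inverse observed information of the
    profiled ML likelihood).  When the information matrix is not positive
    definite (boundary fits), the residual degrees of freedom are used.
    """
    p = blocks[0][1].shape[1]
    h = np.maximum(1e-5 * np.abs(theta), 1e-10)

    def cdiag(th):
        _, C = _gls(th, blocks)
        return np.diag(C).copy()

    grads = np.zeros((2, p))
    for k in range(2):
        up, dn = theta.copy(), theta.copy()
        up[k] += h[k]
        dn[k] = max(dn[k] - h[k], 0.0)
        grads[k] = (cdiag(up) - cdiag(dn)) / (up[k] - dn[k])

    H = np.zeros((2, 2))
    f0 = _profiled_nll(theta, blocks)
    for i in range(2):
        for j in range(2):
            ti = theta.copy()
            ti[i] += h[i]
            tj = theta.copy()
            tj[j] += h[j]
            tij = theta.copy()
            tij[i] += h[i]
            tij[j] += h[j]
            H[i, j] = (
                _profiled_nll(tij, blocks)
                - _profiled_nll(ti, blocks)
                - _profiled_nll(tj, blocks)
                + f0
            ) / (h[i] * h[j])
    H = (H + H.T) / 2
    try:
        eigvals = np.linalg.eigvalsh(H)
        if eigvals.min() <= 0:
            raise np.linalg.LinAlgError
        A = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.full(p, float(dfres))

    f = cdiag(theta)
    dfs = np.empty(p)
    for j in range(p):
        g = grads[:, j]
        denom = float(g @ A @ g)
        dfs[j] = 2 * f[j] ** 2 / denom if denom > 1e-300 else float(dfres)
        if not np.isfinite(dfs[j]) or dfs[j] <= 0:
            dfs[j] = float(dfres)
    return dfs


def adjust_covariate(
    data: pd.DataFrame, covariate: str, spec: MixedModelSpec
) -> MixedModelFit:
    """Refit the model with a technical covariate as an extra fixed effect."""
    new_spec = MixedModelSpec(
        model=spec.model,
        include_condition=spec.include_condition,
        covariates=tuple(spec.covariates) + (covariate,),
        response=spec.response,
    )
    return fit_burden_model(data, new_spec)
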