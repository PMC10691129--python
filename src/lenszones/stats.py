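"""The study's statistical battery.

Spearman rank correlations against age with Benjamini-Hochberg FDR control
and per-variable OLS rates of change; Mann-Whitney U comparisons between age
groups; multivariable linear regression with variance-inflation-factor
screening and a Breusch-Pagan homoscedasticity check; two-way-random ICC for
grader reproducibility; the minimal detectable Spearman coefficient at given
power; and the objective scatter index (OSI) of a double-pass PSF image —
the ratio of peripheral (12-20 arcmin) to central-peak (1 arcmin) intensity.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import brentq
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.outliers_influence import variance_inflation_factor
import statsmodels.api as sm

from .errors import ValidationError

#: age-group bounds (years): Group 1: 9-29, Group 2: 30-54, Group 3: 55-78
AGE_GROUPS = {1: (9, 29), 2: (30, 54), 3: (55, 78)}

#: default variable family for the main age-correlation analysis (23 tests)
DEFAULT_FAMILY = (
    "thickness_lens", "thickness_cortex", "thickness_nucleus",
    "thickness_c1a", "thickness_c1b", "thickness_c2", "thickness_c3", "thickness_c4",
    "radius_lens_ant", "radius_nucleus_ant", "radius_nucleus_post", "radius_lens_post",
    "density_lens", "density_cortex", "density_nucleus",
    "density_c1a", "density_c1b", "density_c2", "density_c3", "density_c4",
    "osi", "aulcsf", "va_logmar",
)


def assign_age_groups(ages) -> np.ndarray:
    """Group id per eye (0 = outside all groups)."""
    ages = np.asarray(ages, dtype=float)
    out = np.zeros(ages.size, dtype=int)
    for gid, (lo, hi) in AGE_GROUPS.items():
        out[(ages >= lo) & (ages <= hi)] = gid
    return out


# ---------------------------------------------------------------------------
# Spearman correlation with exact small-sample null
# ---------------------------------------------------------------------------

@lru_cache(maxsize=16)
def _exact_t_distribution(n: int) -> np.ndarray:
    """Null distribution of T = sum(i * pi(i)) over all rank permutations,
    by dynamic programming over subsets.  counts[t] = #permutations with T=t.
    Feasible through n = 12."""
    tmax = sum((i + 1) * (i + 1) for i in range(n))
    full = (1 << n) - 1
    counts = {0: np.zeros(tmax + 1)}
    counts[0][0] = 1.0
    # iterate masks in order of popcount via simple dict over masks
    by_pop: list[list[int]] = [[] for _ in range(n + 1)]
    for mask in range(full + 1):
        by_pop[bin(mask).count("1")].append(mask)
    table = np.zeros((full + 1, tmax + 1))
    table[0, 0] = 1.0
    for pop in range(n):
        pos = pop + 1  # assigning rank pi(pos) for position `pos` (1-based)
        for mask in by_pop[pop]:
            row = table[mask]
            if not row.any():
                continue
            nz = np.nonzero(row)[0]
            for j in range(n):
                if mask & (1 << j):
                    continue
                add = pos * (j + 1)
                table[mask | (1 << j)][nz + add] += row[nz]
    return table[full]


def spearman_exact_pvalue(rho: float, n: int) -> float:
    """Two-sided exact P(|rho_null| >= |rho|) for tie-free samples, n <= 12."""
    if n > 12:
        raise ValidationError("exact Spearman null limited to n <= 12")
    counts = _exact_t_distribution(n)
    t = np.arange(counts.size)
    # rho = (T - mu) / s with mu = n(n+1)^2/4, scaling n(n^2-1)/12
    mu = n * (n + 1) ** 2 / 4
    scale = n * (n**2 - 1) / 12
    rho_null = (t - mu) / scale
    total = counts.sum()
    return float(counts[np.abs(rho_null) >= abs(rho) - 1e-12].sum() / total)


def spearman_test(x, y, *, exact_max_n: int = 12) -> tuple[float, float]:
    """Spearman R_s and two-sided P (exact permutation null for tie-free
    samples up to ``exact_max_n``, t-approximation otherwise)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValidationError("need >= 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("constant variable: Spearman correlation undefined")
    rho = float(sps.spearmanr(x, y).statistic)
    n = x.size
    ties = (np.unique(x).size < n) or (np.unique(y).size < n)
    if n <= exact_max_n and not ties:
        return rho, spearman_exact_pvalue(rho, n)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    return rho, float(2.0 * sps.t.sf(abs(t), df=n - 2))


@dataclass
class CorrelationReport:
    """Per-variable Spearman/BH/OLS summary table."""

    table: pd.DataFrame
    alpha: float
    family: tuple[str, ...]

    def row(self, variable: str) -> pd.Series:
        return self.table.set_index("variable").loc[variable]


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up adjusted P values (monotone, each >= raw)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def spearman_with_bh(table: pd.DataFrame, variables=DEFAULT_FAMILY, *,
                     against: str = "age", alpha: float = 0.05) -> CorrelationReport:
    """Spearman R_s of each variable against ``against`` with BH correction
    across the family, plus the OLS rate of change per year."""
    variables = tuple(v for v in variables if v in table.columns)
    if not variables:
        raise ValidationError("no requested variables present in the table")
    x = table[against].to_numpy(dtype=float)
    rows, pvals = [], []
    for var in variables:
        y = table[var].to_numpy(dtype=float)
        try:
            rho, p = spearman_test(x, y)
            err = ""
        except ValidationError as e:
            rho, p, err = np.nan, np.nan, str(e)
        if np.isfinite(p):
            pvals.append(p)
        ols = sps.linregress(x, y) if np.ptp(y) > 0 else None
        rows.append({
            "variable": var, "n": x.size, "r_s": rho, "p": p,
            "rate_per_year": ols.slope if ols else np.nan,
            "rate_se": ols.stderr if ols else np.nan,
            "intercept": ols.intercept if ols else np.nan,
            "error": err,
        })
    out = pd.DataFrame(rows)
    adj = np.full(len(out), np.nan)
    finite = out["p"].notna().to_numpy()
    if finite.any():
        adj[finite] = benjamini_hochberg(out.loc[finite, "p"].to_numpy())
    out.insert(4, "p_bh", adj)
    out["significant"] = out["p_bh"] < alpha
    return CorrelationReport(table=out, alpha=alpha, family=variables)


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

def mann_whitney_u(group_a, group_b, *, exact_limit: int = 400) -> tuple[float, float]:
    """Mann-Whitney U (of group_a) and two-sided P.

    The exact null distribution is used when n_a * n_b <= exact_limit and
    there are no cross-group ties; otherwise the normal approximation with
    tie correction and continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValidationError("both groups need at least one observation")
    pooled = np.concatenate([a, b])
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size * b.size <= exact_limit and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def relative_zone_thickness(table: pd.DataFrame, zone_cols=None) -> pd.DataFrame:
    """Per-eye percentage contribution of each cortical zone to the cortex."""
    zone_cols = zone_cols or [f"thickness_{z}" for z in ("c1a", "c1b", "c2", "c3", "c4")]
    out = table[["eye_id", "age"]].copy() if "eye_id" in table.columns else table[["age"]].copy()
    total = table[zone_cols].sum(axis=1)
    for c in zone_cols:
        out[f"rel_{c.removeprefix('thickness_')}"] = 100.0 * table[c] / total
    out["group"] = assign_age_groups(table["age"])
    return out


def group_comparisons(table: pd.DataFrame, value_cols=None) -> pd.DataFrame:
    """Pairwise Mann-Whitney tests of relative zone thickness between the
    three age groups (Group1 vs 2, 2 vs 3, 1 vs 3)."""
    rel = relative_zone_thickness(table) if value_cols is None else table
    value_cols = value_cols or [c for c in rel.columns if c.startswith("rel_")]
    rows = []
    for col in value_cols:
        for ga, gb in ((1, 2), (2, 3), (1, 3)):
            va = rel.loc[rel["group"] == ga, col].to_numpy()
            vb = rel.loc[rel["group"] == gb, col].to_numpy()
            if va.size and vb.size:
                u, p = mann_whitney_u(va, vb)
            else:
                u, p = np.nan, np.nan
            rows.append({"variable": col, "groups": f"{ga}v{gb}", "U": u, "p": p,
                         "n_a": va.size, "n_b": vb.size})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Multivariable linear regression
# ---------------------------------------------------------------------------

@dataclass
class MvlrResult:
    coefficients: pd.Series
    pvalues: pd.Series
    adjusted_r2: float
    breusch_pagan_p: float
    vif: dict[str, float]
    excluded: list[str]

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients.to_dict(),
            "pvalues": self.pvalues.to_dict(),
            "adjusted_r2": self.adjusted_r2,
            "breusch_pagan_p": self.breusch_pagan_p,
            "vif": self.vif,
            "excluded": self.excluded,
        }


def mvlr(table: pd.DataFrame, response: str, predictors, *,
         vif_threshold: float = 10.0) -> MvlrResult:
    """OLS of ``response`` on ``predictors`` with iterative VIF screening
    (largest VIF above threshold removed first) and a Breusch-Pagan test on
    the final residuals."""
    predictors = list(predictors)
    n = len(table)
    if n <= len(predictors) + 1:
        raise ValidationError(f"n={n} too small for {len(predictors)} predictors")
    excluded: list[str] = []
    current = predictors.copy()
    while len(current) > 1:
        X = sm.add_constant(table[current].to_numpy(dtype=float))
        with np.errstate(divide="ignore", invalid="ignore"):
            vifs = np.array([variance_inflation_factor(X, i + 1) for i in range(len(current))])
        vifs = np.where(np.isfinite(vifs), vifs, np.inf)
        if np.max(vifs) <= vif_threshold:
            break
        worst = current[int(np.argmax(vifs))]
        excluded.append(worst)
        current.remove(worst)
    X = sm.add_constant(table[current].to_numpy(dtype=float))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("design matrix rank-deficient after VIF exclusion")
    y = table[response].to_numpy(dtype=float)
    fit = sm.OLS(y, X).fit()
    bp = het_breuschpagan(fit.resid, X)[1]
    names = ["const"] + current
    with np.errstate(divide="ignore", invalid="ignore"):
        final_vif = {
            p: float(variance_inflation_factor(X, i + 1)) for i, p in enumerate(current)
        } if len(current) > 1 else {current[0]: 1.0}
    return MvlrResult(
        coefficients=pd.Series(fit.params, index=names),
        pvalues=pd.Series(fit.pvalues, index=names),
        adjusted_r2=float(fit.rsquared_adj),
        breusch_pagan_p=float(bp),
        vif=final_vif,
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# Reproducibility (ICC)
# ---------------------------------------------------------------------------

def icc(ratings: np.ndarray, *, form: str = "absolute") -> float:
    """Single-measures two-way-random ICC of a subjects x raters matrix.

    ``form`` "absolute" gives ICC(2,1) (absolute agreement), "consistency"
    gives ICC(3,1).  Raises on fewer than 3 subjects / 2 raters or zero
    total variance.
    """
    r = np.asarray(ratings, dtype=float)
    if r.ndim != 2 or r.shape[0] < 3 or r.shape[1] < 2:
        raise ValidationError("ICC needs a (>=3 subjects) x (>=2 raters) matrix")
    if np.ptp(r) == 0:
        raise ValidationError("zero total variance: ICC undefined")
    n, k = r.shape
    grand = r.mean()
    row_m = r.mean(axis=1)
    col_m = r.mean(axis=0)
    ss_rows = k * np.sum((row_m - grand) ** 2)
    ss_cols = n * np.sum((col_m - grand) ** 2)
    ss_total = np.sum((r - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if form == "absolute":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif form == "consistency":
        denom = msr + (k - 1) * mse
    else:
        raise ValidationError(f"unknown ICC form {form!r}")
    if denom == 0:
        raise ValidationError("degenerate ANOVA decomposition: ICC undefined")
    return float((msr - mse) / denom)


# ---------------------------------------------------------------------------
# Power analysis
# ---------------------------------------------------------------------------

def spearman_power(rho: float, n: int, *, alpha: float = 0.05) -> float:
    """Two-sided Fisher-z power for Spearman's coefficient (variance
    1.06/(n-3))."""
    if n < 10:
        raise ValidationError("power approximation needs n >= 10")
    se = np.sqrt(1.06 / (n - 3))
    z = np.arctanh(rho) / se
    zc = sps.norm.isf(alpha / 2)
    return float(sps.norm.sf(zc - z) + sps.norm.cdf(-zc - z))


def spearman_min_detectable_rho(n: int, *, alpha: float = 0.05,
                                power: float = 0.80) -> float:
    """Smallest rho whose two-sided test at ``alpha`` reaches ``power``."""
    if n < 10:
        raise ValidationError("minimum detectable rho needs n >= 10")
    if spearman_power(0.999, n, alpha=alpha) < power:
        raise ValidationError(f"power {power} unattainable at n={n}")
    return float(brentq(lambda r: spearman_power(r, n, alpha=alpha) - power, 1e-6, 0.999))


def simulate_spearman_power(rho: float, n: int, *, alpha: float = 0.05,
                            n_reps: int = 10_000, seed=0) -> float:
    """Monte-Carlo power of the two-sided Spearman t-test at target Spearman
    rho, using bivariate normal samples (Pearson r = 2 sin(pi*rho/6))."""
    rng = np.random.default_rng(seed)
    r = 2.0 * np.sin(np.pi * rho / 6.0)
    z = rng.standard_normal((n_reps, n, 2))
    x = z[:, :, 0]
    y = r * z[:, :, 0] + np.sqrt(1 - r**2) * z[:, :, 1]
    rx = sps.rankdata(x, axis=1)
    ry = sps.rankdata(y, axis=1)
    rx -= rx.mean(axis=1, keepdims=True)
    ry -= ry.mean(axis=1, keepdims=True)
    rs = (rx * ry).sum(axis=1) / np.sqrt((rx**2).sum(axis=1) * (ry**2).sum(axis=1))
    t = rs * np.sqrt((n - 2) / np.clip(1 - rs**2, 1e-12, None))
    p = 2 * sps.t.sf(np.abs(t), df=n - 2)
    return float(np.mean(p < alpha))


# ---------------------------------------------------------------------------
# Objective scatter index
# ---------------------------------------------------------------------------

def compute_osi(psf: np.ndarray, pixel_scale_arcmin: float, *,
                calibration: float = 100.0) -> float:
    """OSI of a double-pass PSF image: mean intensity in the 12-20 arcmin
    annulus divided by the central-peak intensity (within 1 arcmin of the
    peak), times a device-like calibration constant."""
    psf = np.asarray(psf, dtype=float)
    if psf.ndim != 2:
        raise ValidationError("PSF must be a 2-D image")
    iy, ix = np.unravel_index(np.argmax(psf), psf.shape)
    yy, xx = np.mgrid[: psf.shape[0], : psf.shape[1]]
    r = np.hypot(yy - iy, xx - ix) * pixel_scale_arcmin
    edge = min(iy, ix, psf.shape[0] - 1 - iy, psf.shape[1] - 1 - ix) * pixel_scale_arcmin
    if edge < 20.0:
        raise ValidationError("12-20 arcmin annulus not fully inside the image")
    central = psf[r <= 1.0]
    peak = float(central.max())
    if peak <= 0:
        raise ValidationError("zero central peak: OSI undefined")
    annulus = psf[(r >= 12.0) & (r <= 20.0)]
    return float(calibration * annulus.mean() / peak)
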