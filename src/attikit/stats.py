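"""Method-comparison statistics for paired measurements.

Implements the full comparison battery for two measurement methods read
on the same subjects: Shapiro-Wilk normality gatekeeping, Student's
t-test (pooled or Welch, from vectors or summary statistics), Pearson
correlation with Fisher-z confidence interval, two-way consistency
intraclass correlation (single and average measures, with F-based
confidence intervals), Bland-Altman agreement, Passing-Bablok regression
with rank-based confidence intervals and the cusum linearity test, and
Cohen's kappa on binned categories.

Passing-Bablok, the cusum test, the ICC ANOVA decomposition, Bland-Altman
and kappa are implemented here from first principles; Shapiro-Wilk
delegates to scipy's implementation of the published algorithm.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass

import numpy as np
from scipy import special, stats as sps

from .cohort import PairedMeasurements

__all__ = [
    "StatError",
    "ICCResult",
    "BlandAltmanResult",
    "PassingBablokResult",
    "KappaResult",
    "PearsonResult",
    "TTestResult",
    "MethodComparisonReport",
    "shapiro_wilk",
    "ttest_two_sample",
    "pearson_ci",
    "icc_consistency",
    "spearman_brown",
    "bland_altman",
    "passing_bablok",
    "cohen_kappa",
    "bin_measurements",
    "compare_methods",
]


class StatError(ValueError):
    """Raised for invalid statistical inputs or undefined estimands."""


# -- result containers -------------------------------------------------------

@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    pooled: bool

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class PearsonResult:
    r: float
    ci: tuple[float, float]
    p: float
    n: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class ICCResult:
    icc_single: float
    icc_average: float
    ci_single: tuple[float, float]
    ci_average: tuple[float, float]
    ms_rows: float
    ms_error: float
    n: int
    k: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    slope: float
    slope_ci: tuple[float, float]
    n: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class PassingBablokResult:
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    n: int
    n_slopes: int
    k_offset: int
    cusum_stat: float
    cusum_p: float
    residual_sd: float
    residual_sd_perpendicular: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    observed_agreement: float
    expected_agreement: float
    weights: str
    scheme: str
    n: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# -- elementary statistics ----------------------------------------------------

def shapiro_wilk(x) -> tuple[float, float]:
    """Shapiro-Wilk W and p for 3 <= n <= 5000 non-constant samples."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or not (3 <= x.size <= 5000):
        raise StatError("Shapiro-Wilk requires a 1D sample with 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise StatError("Shapiro-Wilk undefined for a constant sample")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def _summarize(v) -> tuple[int, float, float]:
    if isinstance(v, tuple) and len(v) == 3:
        n, m, s = v
        return int(n), float(m), float(s)
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise StatError("each group needs n >= 2 observations or an (n, mean, sd) summary")
    return int(arr.size), float(arr.mean()), float(arr.std(ddof=1))


def ttest_two_sample(a, b, pooled: bool = True) -> TTestResult:
    """Two-sided two-sample t-test from vectors or (n, mean, sd) summaries.

    Default is the pooled-variance Student form with df = n1 + n2 - 2;
    ``pooled=False`` gives the Welch variant.
    """

    n1, m1, s1 = _summarize(a)
    n2, m2, s2 = _summarize(b)
    if n1 < 2 or n2 < 2:
        raise StatError("each group needs n >= 2")
    if s1 == 0 and s2 == 0 and m1 == m2:
        raise StatError("t undefined: zero variance in both groups with equal means")
    if pooled:
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = s1**2 / n1, s2**2 / n2
        se = np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    if se == 0:
        raise StatError("t undefined: zero standard error")
    t = (m1 - m2) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p=float(p), pooled=pooled)


def ttest_paired(x, y) -> TTestResult:
    """Paired t-test on the per-subject differences (two-sided)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise StatError("paired t-test needs two equal-length vectors, n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            raise StatError("t undefined: all differences zero")
        raise StatError("t undefined: zero variance of differences")
    t = d.mean() / (sd / np.sqrt(d.size))
    df = d.size - 1
    return TTestResult(t=float(t), df=float(df), p=float(2 * sps.t.sf(abs(t), df)), pooled=False)


def pearson_ci(
    x=None, y=None, r: float | None = None, n: int | None = None, level: float = 0.95
) -> PearsonResult:
    """Pearson correlation with Fisher-z confidence interval.

    Either two data vectors or a precomputed (r, n) pair.  The interval is
    tanh(atanh(r) +/- z / sqrt(n - 3)); the p-value comes from
    t = r sqrt((n - 2) / (1 - r^2)) on n - 2 degrees of freedom.
    """

    if r is None:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise StatError("pearson_ci needs equal-length 1D vectors")
        n = x.size
        if n < 4:
            raise StatError("confidence interval undefined for n <= 3")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise StatError("correlation undefined for a constant vector")
        r = float(np.corrcoef(x, y)[0, 1])
    else:
        if n is None or n < 4:
            raise StatError("confidence interval undefined for n <= 3")
        r = float(r)
    if abs(r) >= 1.0 - 1e-12:
        # collinear data (to numerical precision): degenerate interval, flagged
        r = float(np.sign(r))
        return PearsonResult(r=r, ci=(r, r), p=0.0, n=int(n), degenerate=True)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * sps.t.sf(abs(t), n - 2)
    zc = sps.norm.ppf(0.5 + level / 2.0)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    ci = (float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se)))
    return PearsonResult(r=r, ci=ci, p=float(p), n=int(n))


# -- intraclass correlation ---------------------------------------------------

def spearman_brown(icc_single: float, k: int = 2) -> float:
    """Average-measures reliability from single-measures reliability."""
    return k * icc_single / (1.0 + (k - 1) * icc_single)


def icc_consistency(data, level: float = 0.95) -> ICCResult:
    """Two-way consistency ICC (single and average measures).

    ``data`` is an (n subjects) x (k methods/raters) table, a
    PairedMeasurements, or two vectors stacked by the caller.  The two-way
    ANOVA decomposition removes the column (method) effect, so a constant
    offset between methods does not penalize the coefficient; confidence
    intervals use the F bounds on MSR / MSE.
    """

    if isinstance(data, PairedMeasurements):
        table = np.column_stack([data.mri, data.rx])
    else:
        table = np.asarray(data, dtype=float)
    if table.ndim != 2:
        raise StatError("icc_consistency expects an n x k table")
    n, k = table.shape
    if n < 3 or k < 2:
        raise StatError("icc_consistency needs n >= 3 subjects and k >= 2 columns")
    if not np.isfinite(table).all():
        raise StatError("missing or non-finite cells are not supported")
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((table - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    df_rows = n - 1
    df_err = (n - 1) * (k - 1)
    msr = ss_rows / df_rows
    mse = ss_err / df_err
    if msr + (k - 1) * mse == 0:
        raise StatError("ICC undefined: no variance in the table")
    icc1 = (msr - mse) / (msr + (k - 1) * mse)
    icck = (msr - mse) / msr if msr > 0 else 0.0
    alpha = 1.0 - level
    if mse == 0:
        ci1 = (icc1, icc1)
        cik = (icck, icck)
    else:
        f = msr / mse
        fl = f / sps.f.ppf(1 - alpha / 2, df_rows, df_err)
        fu = f * sps.f.ppf(1 - alpha / 2, df_err, df_rows)
        ci1 = ((fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1))
        cik = (1 - 1 / fl, 1 - 1 / fu)
    return ICCResult(
        icc_single=float(icc1),
        icc_average=float(icck),
        ci_single=(float(ci1[0]), float(ci1[1])),
        ci_average=(float(cik[0]), float(cik[1])),
        ms_rows=float(msr),
        ms_error=float(mse),
        n=n,
        k=k,
    )


# -- Bland-Altman -------------------------------------------------------------

def bland_altman(first, second, level: float = 0.95) -> BlandAltmanResult:
    """Bland-Altman agreement: bias, limits of agreement, trend of differences.

    Differences are ``second - first``; the limits of agreement are
    bias +/- 1.96 sd of the differences.  A least-squares regression of
    differences on pairwise means quantifies any proportional trend.
    """

    x = np.asarray(first, dtype=float)
    y = np.asarray(second, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise StatError("bland_altman needs two equal-length vectors with n >= 3")
    diff = y - x
    mean = (x + y) / 2.0
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    loa = (bias - 1.96 * sd, bias + 1.96 * sd)
    if np.ptp(mean) == 0 or sd == 0:
        slope, slope_ci = 0.0, (0.0, 0.0)
    else:
        reg = sps.linregress(mean, diff)
        tc = sps.t.ppf(0.5 + level / 2.0, x.size - 2)
        slope = float(reg.slope)
        slope_ci = (slope - tc * reg.stderr, slope + tc * reg.stderr)
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=float(loa[0]),
        loa_high=float(loa[1]),
        slope=slope,
        slope_ci=(float(slope_ci[0]), float(slope_ci[1])),
        n=x.size,
    )


# -- Passing-Bablok -----------------------------------------------------------

def _pairwise_slopes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    i, j = np.triu_indices(x.size, k=1)
    dx = x[j] - x[i]
    dy = y[j] - y[i]
    both_zero = (dx == 0) & (dy == 0)
    dx = dx[~both_zero]
    dy = dy[~both_zero]
    with np.errstate(divide="ignore"):
        s = np.where(dx == 0, np.sign(dy) * np.inf, dy / np.where(dx == 0, 1.0, dx))
    return s[s != -1.0]  # slopes of exactly -1 carry no direction information


def passing_bablok(x, y, level: float = 0.95) -> PassingBablokResult:
    """Passing-Bablok method-comparison regression with cusum linearity test.

    The slope is the shifted median of all pairwise slopes: with K the
    number of slopes below -1, the estimate is the order statistic at the
    median position offset by K (averaging the two central values when the
    shifted count is even), which makes the estimator invariant under
    exchange of x and y (slope -> 1/slope).  Identical points are skipped
    and slopes of exactly -1 are excluded; vertical pairs enter as signed
    infinities at the sort boundaries.  Confidence bounds are the rank
    statistics M1 = round((N - w)/2), M2 = N - M1 + 1 shifted by K, with
    w = z * sqrt(n(n-1)(2n+5)/18).  The intercept is median(y - slope x),
    its bounds computed from the slope bounds.

    The cusum test scores residual signs (+sqrt(L/l) above the line for
    the l points above, -sqrt(l/L) for the L points below), accumulates
    them in order of increasing x (ties broken by y), and refers
    max |cusum| / sqrt(l + L) to the asymptotic Kolmogorov-Smirnov tail.
    """

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatError("passing_bablok needs equal-length 1D vectors")
    n = x.size
    if n < 10:
        raise StatError("passing_bablok requires n >= 10 for a valid rank CI")
    if np.ptp(x) == 0:
        raise StatError("all x identical: slope undefined")
    slopes = _pairwise_slopes(x, y)
    slopes = np.sort(slopes)
    nn = slopes.size
    if nn == 0:
        raise StatError("no valid pairwise slopes")
    k_off = int(np.count_nonzero(slopes < -1.0))

    def _order_stat(pos: int) -> float:
        return float(slopes[int(np.clip(pos, 1, nn)) - 1])

    if nn % 2 == 1:
        slope = _order_stat((nn + 1) // 2 + k_off)
    else:
        slope = 0.5 * (_order_stat(nn // 2 + k_off) + _order_stat(nn // 2 + 1 + k_off))
    zc = sps.norm.ppf(0.5 + level / 2.0)
    w = zc * np.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    m1 = int(round((nn - w) / 2.0))
    m2 = nn - m1 + 1
    slope_lo = _order_stat(m1 + k_off)
    slope_hi = _order_stat(m2 + k_off)
    if not np.isfinite(slope):
        raise StatError("slope estimate is not finite (degenerate data)")
    intercept = float(np.median(y - slope * x))
    icept_hi = float(np.median(y - slope_lo * x)) if np.isfinite(slope_lo) else np.nan
    icept_lo = float(np.median(y - slope_hi * x)) if np.isfinite(slope_hi) else np.nan

    resid = y - (intercept + slope * x)
    above = resid > 0
    below = resid < 0
    l_cnt = int(above.sum())
    big_l = int(below.sum())
    if l_cnt + big_l == 0:
        cusum_stat, cusum_p = 0.0, 1.0
    elif l_cnt == 0 or big_l == 0:
        # all residuals on one side: maximal departure from a random walk
        cusum_stat = float(np.sqrt(l_cnt + big_l))
        cusum_p = float(special.kolmogorov(cusum_stat))
    else:
        scores = np.zeros(n)
        scores[above] = np.sqrt(big_l / l_cnt)
        scores[below] = -np.sqrt(l_cnt / big_l)
        order = np.lexsort((y, x))
        csum = np.cumsum(scores[order])
        cusum_stat = float(np.abs(csum).max() / np.sqrt(l_cnt + big_l))
        cusum_p = float(special.kolmogorov(cusum_stat))
    residual_sd = float(resid.std(ddof=1))
    residual_sd_perp = residual_sd / float(np.sqrt(1.0 + slope * slope))
    return PassingBablokResult(
        slope=float(slope),
        intercept=intercept,
        slope_ci=(float(slope_lo), float(slope_hi)),
        intercept_ci=(icept_lo, icept_hi),
        n=n,
        n_slopes=nn,
        k_offset=k_off,
        cusum_stat=cusum_stat,
        cusum_p=cusum_p,
        residual_sd=residual_sd,
        residual_sd_perpendicular=residual_sd_perp,
    )


# -- categorical agreement ----------------------------------------------------

def bin_measurements(values, scheme="terciles") -> np.ndarray:
    """Deterministic binning of continuous values into ordinal categories.

    ``scheme='terciles'`` cuts at the 1/3 and 2/3 quantiles of the input;
    a list/tuple of thresholds gives right-closed intervals
    (-inf, t1], (t1, t2], ...  Categories are 1-based integers.
    """

    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise StatError("bin_measurements expects a 1D vector")
    if isinstance(scheme, str):
        if scheme != "terciles":
            raise StatError(f"unknown binning scheme {scheme!r}")
        if values.size < 3:
            raise StatError("need at least as many values as bins")
        cuts = np.quantile(values, [1.0 / 3.0, 2.0 / 3.0])
    else:
        cuts = np.asarray(scheme, dtype=float)
        if cuts.ndim != 1 or cuts.size == 0:
            raise StatError("threshold list must be a nonempty 1D sequence")
        if (np.diff(cuts) <= 0).any():
            raise StatError("threshold list must be strictly increasing")
        if values.size < cuts.size + 1:
            raise StatError("need at least as many values as bins")
    return np.searchsorted(cuts, values, side="left") + 1


def cohen_kappa(a, b, weights: str = "none") -> KappaResult:
    """Cohen's kappa (optionally linear/quadratic weighted) for two raters."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise StatError("cohen_kappa needs two equal-length 1D vectors")
    cats = np.unique(np.concatenate([a, b]))
    if cats.size < 2:
        raise StatError("kappa undefined: a single shared category (pe = 1)")
    idx = {c: i for i, c in enumerate(cats)}
    m = cats.size
    conf = np.zeros((m, m), dtype=float)
    for ai, bi in zip(a, b):
        conf[idx[ai], idx[bi]] += 1.0
    conf /= conf.sum()
    if weights == "none":
        wmat = 1.0 - np.eye(m)
    elif weights in ("linear", "quadratic"):
        d = np.abs(np.arange(m)[:, None] - np.arange(m)[None, :]) / (m - 1)
        wmat = d if weights == "linear" else d**2
    else:
        raise StatError(f"unknown weights {weights!r}")
    row = conf.sum(axis=1)
    col = conf.sum(axis=0)
    expected = np.outer(row, col)
    do = float((wmat * conf).sum())
    de = float((wmat * expected).sum())
    if de == 0:
        raise StatError("kappa undefined: expected disagreement is zero")
    kappa = 1.0 - do / de
    po = float(np.trace(conf))
    pe = float(np.trace(expected))
    return KappaResult(
        kappa=float(kappa),
        observed_agreement=po,
        expected_agreement=pe,
        weights=weights,
        scheme="",
        n=a.size,
    )


# -- aggregate driver ---------------------------------------------------------

@dataclass
class MethodComparisonReport:
    """All comparison statistics computed on one paired-measurements snapshot."""

    n: int
    data_hash: str
    normality: dict
    ttest: TTestResult
    ttest_paired: TTestResult
    pearson: PearsonResult
    icc: ICCResult
    bland_altman: BlandAltmanResult
    passing_bablok: PassingBablokResult
    kappa: dict
    kappa_scheme: str
    schema_version: str = "1"

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "n": self.n,
            "data_hash": self.data_hash,
            "normality": self.normality,
            "ttest": self.ttest.to_dict(),
            "ttest_paired": self.ttest_paired.to_dict(),
            "pearson": self.pearson.to_dict(),
            "icc": self.icc.to_dict(),
            "bland_altman": self.bland_altman.to_dict(),
            "passing_bablok": self.passing_bablok.to_dict(),
            "kappa": {k: v.to_dict() for k, v in self.kappa.items()},
            "kappa_scheme": self.kappa_scheme,
        }


def _hash_pairs(pairs: PairedMeasurements) -> str:
    payload = pairs.df.round(12).to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def compare_methods(pairs: PairedMeasurements, kappa_scheme="terciles") -> MethodComparisonReport:
    """Run the full method-comparison battery on a paired cohort.

    Variable roles follow the method-comparison convention used
    throughout the package: x = radiograph (reference), y = MRI (index
    method); Bland-Altman differences are MRI minus radiograph.  The
    unpaired pooled t-test is reported as the headline mean comparison
    (with the paired variant alongside, which is statistically preferable
    for paired designs).  Kappa is computed on binned values — between
    observers and between sessions when replicate columns are present,
    otherwise between the two methods.
    """

    def _run(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except StatError as exc:
            raise StatError(f"{name}: {exc}") from exc

    mri, rx = pairs.mri, pairs.rx
    normality = {}
    for label, v in (("mri", mri), ("rx", rx)):
        w, p = _run(f"shapiro_wilk[{label}]", shapiro_wilk, v)
        normality[label] = {"W": w, "p": p}
    tt = _run("ttest", ttest_two_sample, mri, rx, True)
    ttp = _run("ttest_paired", ttest_paired, mri, rx)
    pr = _run("pearson", pearson_ci, rx, mri)
    icc = _run("icc", icc_consistency, np.column_stack([mri, rx]))
    ba = _run("bland_altman", bland_altman, rx, mri)
    pb = _run("passing_bablok", passing_bablok, rx, mri)

    pooled = np.concatenate([mri, rx])
    cuts = (
        np.quantile(pooled, [1 / 3, 2 / 3]) if kappa_scheme == "terciles" else np.asarray(kappa_scheme)
    )
    scheme_desc = (
        f"terciles of pooled sample at {np.round(cuts, 6).tolist()}"
        if kappa_scheme == "terciles"
        else f"thresholds {list(cuts)}"
    )
    kappas: dict[str, KappaResult] = {}

    def _kappa(tag, u, v):
        res = _run(
            f"kappa[{tag}]",
            cohen_kappa,
            bin_measurements(u, cuts),
            bin_measurements(v, cuts),
        )
        kappas[tag] = dataclasses.replace(res, scheme=scheme_desc)

    has_reps = bool(pairs.replicate_columns("mri"))
    if has_reps:
        for method in ("mri", "rx"):
            _kappa(
                f"inter_observer_{method}",
                pairs.replicate(method, 1, 1),
                pairs.replicate(method, 2, 1),
            )
            _kappa(
                f"intra_observer_{method}",
                pairs.replicate(method, 1, 1),
                pairs.replicate(method, 1, 2),
            )
    else:
        _kappa("mri_vs_rx", mri, rx)

    return MethodComparisonReport(
        n=pairs.n,
        data_hash=_hash_pairs(pairs),
        normality=normality,
        ttest=tt,
        ttest_paired=ttp,
        pearson=pr,
        icc=icc,
        bland_altman=ba,
        passing_bablok=pb,
        kappa=kappas,
        kappa_scheme=scheme_desc,
    )
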