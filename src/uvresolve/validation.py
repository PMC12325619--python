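"""OLS calibration and ICH Q2(R1)-style validation statistics.

Covers the whole statistics battery of a spectrophotometric method
validation: straight-line calibration with correlation and residual
scatter, detection/quantitation limits (3.3σ/S and 10σ/S), recovery and
precision summaries, standard addition, pooled-variance t and
variance-ratio F comparisons against a reference method, and one-way
ANOVA with eta-squared effect size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationModel",
    "fit_calibration",
    "lod_loq",
    "recovery_percent",
    "mean_sd",
    "percent_rsd",
    "StandardAdditionResult",
    "standard_addition",
    "ComparisonResult",
    "two_sample_t_f",
    "AnovaResult",
    "one_way_anova",
    "anova_from_sums",
    "t_critical",
    "f_critical",
]


@dataclass
class CalibrationModel:
    """A fitted calibration line signal = slope·conc + intercept.

    ``sigma_resid`` is the residual standard deviation on n−2 degrees of
    freedom; ``lod``/``loq`` follow the ICH 3.3σ/S and 10σ/S convention.
    Hand-built models (e.g. known unit absorptivities with zero
    intercept) may leave the fit diagnostics unset.
    """

    slope: float
    intercept: float = 0.0
    r: float | None = None
    sigma_resid: float | None = None
    n: int | None = None
    conc_range: tuple[float, float] | None = None
    lod: float | None = None
    loq: float | None = None
    label: str = ""
    analyte: str = ""

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be nonzero")
        if self.r is not None and abs(self.r) > 1 + 1e-12:
            raise ValueError(f"|r| must be <= 1, got {self.r}")

    def predict(self, conc: float | np.ndarray) -> float | np.ndarray:
        return self.slope * conc + self.intercept

    def to_concentration(self, signal: float | np.ndarray) -> float | np.ndarray:
        return (signal - self.intercept) / self.slope


def fit_calibration(
    conc: Sequence[float],
    signal: Sequence[float],
    label: str = "",
    analyte: str = "",
) -> CalibrationModel:
    """Ordinary least squares calibration of signal on concentration.

    Requires at least three points and non-degenerate concentrations;
    ``r`` is the Pearson correlation of the raw data.
    """
    x = np.asarray(conc, dtype=float)
    y = np.asarray(signal, dtype=float)
    if x.size != y.size:
        raise ValueError("concentration and signal lengths differ")
    if x.size < 3:
        raise ValueError(f"calibration needs n >= 3 points, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all concentrations equal")
    fit = stats.linregress(x, y)
    resid = y - (fit.slope * x + fit.intercept)
    sigma = float(np.sqrt(np.sum(resid**2) / (x.size - 2)))
    model = CalibrationModel(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        sigma_resid=sigma,
        n=int(x.size),
        conc_range=(float(x.min()), float(x.max())),
        label=label,
        analyte=analyte,
    )
    model.lod, model.loq = lod_loq(model)
    return model


def lod_loq(model: CalibrationModel) -> tuple[float, float]:
    """Detection and quantitation limits: 3.3σ/|S| and 10σ/|S| (µg/mL)."""
    if model.slope == 0:
        raise ValueError("zero slope: limits undefined")
    if model.sigma_resid is None:
        raise ValueError("model has no residual standard deviation")
    lod = 3.3 * model.sigma_resid / abs(model.slope)
    loq = 10.0 * model.sigma_resid / abs(model.slope)
    return lod, loq


def recovery_percent(found: float, taken: float) -> float:
    """%R = 100·found/taken."""
    if taken <= 0:
        raise ValueError(f"taken must be positive, got {taken}")
    return 100.0 * found / taken


def mean_sd(values: Sequence[float]) -> tuple[float, float]:
    """Mean and sample standard deviation (n−1 denominator); needs n >= 2."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("sample standard deviation needs n >= 2")
    return float(v.mean()), float(v.std(ddof=1))


def percent_rsd(values: Sequence[float]) -> float:
    """%RSD = 100·sd/mean of a replicate series."""
    mean, sd = mean_sd(values)
    if mean == 0:
        raise ValueError("mean is zero; %RSD undefined")
    return 100.0 * sd / mean


@dataclass
class StandardAdditionResult:
    """Recovery-of-added summary of a standard-addition series."""

    added: list[float]
    recoveries: list[float]
    mean: float
    rsd: float


def standard_addition(
    base_found: float,
    added: Sequence[float],
    total_found: Sequence[float],
) -> StandardAdditionResult:
    """Per-level recovery of the spiked amount plus mean and %RSD.

    %R_i = 100·(total_found_i − base_found)/added_i. The conventional
    recovery-of-added definition is used: the pre-analysed sample's
    content is subtracted and only the spike is scored.
    """
    added_arr = np.asarray(added, dtype=float)
    total_arr = np.asarray(total_found, dtype=float)
    if added_arr.size != total_arr.size:
        raise ValueError("added and total_found lengths differ")
    if added_arr.size == 0:
        raise ValueError("empty standard-addition series")
    if np.any(added_arr <= 0):
        raise ValueError("added amounts must be positive")
    rec = 100.0 * (total_arr - base_found) / added_arr
    mean = float(rec.mean())
    rsd = float(100.0 * rec.std(ddof=1) / mean) if rec.size >= 2 else float("nan")
    return StandardAdditionResult(
        added=list(map(float, added_arr)),
        recoveries=list(map(float, rec)),
        mean=mean,
        rsd=rsd,
    )


@dataclass
class ComparisonResult:
    """Two-sample comparison against a reference method (t and F tests)."""

    t_stat: float
    t_df: float
    t_crit: float
    f_stat: float
    f_df: tuple[int, int]
    f_crit: float
    alpha: float
    mean_a: float
    mean_b: float
    var_a: float
    var_b: float
    verdict: str


def two_sample_t_f(
    a: Sequence[float],
    b: Sequence[float],
    alpha: float = 0.05,
    welch: bool = False,
) -> ComparisonResult:
    """Student t (pooled variance by default) and variance-ratio F tests.

    The F statistic places the larger variance in the numerator so that
    F >= 1 and the upper-tail critical value applies. Verdict is
    "no significant difference" when both statistics fall below their
    critical values at ``alpha``.
    """
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if xa.size < 2 or xb.size < 2:
        raise ValueError("each sample needs n >= 2")
    va = float(xa.var(ddof=1))
    vb = float(xb.var(ddof=1))
    if va == 0 and vb == 0:
        raise ValueError("both samples have zero variance; t undefined")
    na, nb = xa.size, xb.size
    if welch:
        se2 = va / na + vb / nb
        t_stat = (xa.mean() - xb.mean()) / np.sqrt(se2)
        t_df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        t_stat = (xa.mean() - xb.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        t_df = na + nb - 2
    if va >= vb:
        f_stat, f_df = (va / vb if vb > 0 else float("inf")), (na - 1, nb - 1)
    else:
        f_stat, f_df = (vb / va if va > 0 else float("inf")), (nb - 1, na - 1)
    t_crit = t_critical(alpha, t_df)
    f_crit = f_critical(alpha, *f_df)
    ok = abs(t_stat) < t_crit and f_stat < f_crit
    return ComparisonResult(
        t_stat=float(t_stat),
        t_df=float(t_df),
        t_crit=t_crit,
        f_stat=float(f_stat),
        f_df=f_df,
        f_crit=f_crit,
        alpha=alpha,
        mean_a=float(xa.mean()),
        mean_b=float(xb.mean()),
        var_a=va,
        var_b=vb,
        verdict="no significant difference" if ok else "significant difference",
    )


@dataclass
class AnovaResult:
    """One-way ANOVA table with eta-squared effect size."""

    ss_between: float
    df_between: int
    ms_between: float | None
    ss_within: float
    df_within: int
    ms_within: float | None
    ss_total: float
    df_total: int
    f: float | None
    p: float | None
    eta_squared: float | None
    f_undefined: bool = False


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way ANOVA over >= 2 groups (each n >= 2).

    Decomposes total sum of squares into between- and within-group
    parts; F = MS_between/MS_within, p from the F distribution,
    η² = SS_between/SS_total. When every observation is identical both
    sums of squares vanish and F is reported as undefined.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least two groups")
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValueError(f"group {i} has n < 2")
    all_vals = np.concatenate(arrays)
    grand = all_vals.mean()
    ss_between = float(sum(g.size * (g.mean() - grand) ** 2 for g in arrays))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in arrays))
    ss_total = float(((all_vals - grand) ** 2).sum())
    df_between = len(arrays) - 1
    df_within = all_vals.size - len(arrays)
    if ss_within == 0 and ss_between == 0:
        return AnovaResult(
            ss_between=ss_between,
            df_between=df_between,
            ms_between=0.0,
            ss_within=ss_within,
            df_within=df_within,
            ms_within=0.0,
            ss_total=ss_total,
            df_total=all_vals.size - 1,
            f=None,
            p=None,
            eta_squared=None,
            f_undefined=True,
        )
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        f_val, p_val = None, None
        undefined = True
    else:
        f_val = ms_between / ms_within
        p_val = float(stats.f.sf(f_val, df_between, df_within))
        undefined = False
    eta = ss_between / ss_total if ss_total > 0 else None
    return AnovaResult(
        ss_between=ss_between,
        df_between=df_between,
        ms_between=ms_between,
        ss_within=ss_within,
        df_within=df_within,
        ms_within=ms_within,
        ss_total=ss_total,
        df_total=all_vals.size - 1,
        f=f_val,
        p=p_val,
        eta_squared=eta,
        f_undefined=undefined,
    )


def anova_from_sums(
    ss_between: float, df_between: float, ss_within: float, df_within: float
) -> tuple[float, float, float, float]:
    """Rebuild (MS_between, MS_within, F, η²) from printed sums of squares."""
    if df_between <= 0 or df_within <= 0:
        raise ValueError("degrees of freedom must be positive")
    if ss_between <= 0 or ss_within <= 0:
        raise ValueError("sums of squares must be positive")
    ms_b = ss_between / df_between
    ms_w = ss_within / df_within
    f = ms_b / ms_w
    eta = ss_between / (ss_between + ss_within)
    return ms_b, ms_w, f, eta


def t_critical(alpha: float, df: float) -> float:
    """Two-sided Student t critical value at significance ``alpha``."""
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return float(stats.t.ppf(1 - alpha / 2, df))


def f_critical(alpha: float, df1: float, df2: float) -> float:
    """Upper-tail F critical value at significance ``alpha``."""
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return float(stats.f.ppf(1 - alpha, df1, df2))
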