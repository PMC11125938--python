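"""Longitudinal statistics for breast tissue-volume series.

Implements the measurement-to-decision chain used to compare glandular and
ductal volume dynamics between pre- and post-menopausal groups:

* per-breast coefficient of variation (CoV = s / x-bar, n-1 denominator),
* one-tailed F comparisons of pooled within-breast variances,
* a heteroscedastic two-sample t-test for group mean CoV with an
  approximate degrees-of-freedom formula that uses (n + 1) denominators
  and a -2 correction (it reduces to 2n, not 2n - 2, when the two groups
  have equal s and n),
* Spearman rank correlation of per-breast mean ductal vs. glandular
  volume as an internal-consistency check,
* ``run_battery`` which ties these into the four-null-hypothesis battery
  and the per-group summary table.

Critical values are always computed from the continuous F and t
distributions (via scipy's inverse incomplete beta machinery), never from
printed tables.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InsufficientDataError

__all__ = [
    "CoVResult",
    "VarianceComparison",
    "MeanComparison",
    "RankCorrelation",
    "BatteryConfig",
    "BatteryResult",
    "coefficient_of_variation",
    "f_variance_ratio",
    "f_critical",
    "t_unequal_var",
    "t_critical",
    "spearman_r",
    "run_battery",
]

REJECT = "reject"
FAIL_TO_REJECT = "fail-to-reject"


# ---------------------------------------------------------------------------
# result records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoVResult:
    """Coefficient of variation of one breast's volume series."""

    n: int
    mean: float
    sd: float
    cov: float
    breast_id: str = ""
    tissue: str = ""

    @property
    def cov_percent(self) -> float:
        return 100.0 * self.cov


@dataclass(frozen=True)
class VarianceComparison:
    """One-tailed F comparison of two standard deviations."""

    name: str
    s1: float
    s2: float
    df1: int
    df2: int
    f_calc: float
    alpha: float
    f_crit: float
    reject: bool
    note: str = ""

    @property
    def decision(self) -> str:
        return REJECT if self.reject else FAIL_TO_REJECT


@dataclass(frozen=True)
class MeanComparison:
    """Heteroscedastic one-tailed t comparison of two group means."""

    name: str
    n1: int
    n2: int
    mean1: float
    mean2: float
    s1: float
    s2: float
    t_stat: float
    df_raw: float
    df: int
    alpha: float
    t_crit: float
    t_crit_unrounded_df: float
    reject: bool
    note: str = ""

    @property
    def decision(self) -> str:
        return REJECT if self.reject else FAIL_TO_REJECT


@dataclass(frozen=True)
class RankCorrelation:
    """Spearman rank correlation (rank-rank Pearson, average ranks for ties)."""

    n: int
    spearman_r: float
    method: str = "rank-rank Pearson, average ranks for ties"


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def coefficient_of_variation(
    values: Sequence[float] | np.ndarray,
    breast_id: str = "",
    tissue: str = "",
) -> CoVResult:
    """CoV of a volume series: sample SD (n-1 denominator) over the mean.

    The CoV is scale-invariant, which is what makes it comparable across
    breasts of very different size.

    Raises
    ------
    InsufficientDataError
        if fewer than two observations are supplied.
    ValueError
        if the mean is not strictly positive (CoV undefined).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if x.size < 2:
        raise InsufficientDataError(
            f"CoV needs at least 2 observations, got {x.size}"
        )
    mean = float(x.mean())
    if mean <= 0.0:
        raise ValueError(f"CoV undefined for non-positive mean ({mean:g})")
    sd = float(x.std(ddof=1))
    return CoVResult(n=x.size, mean=mean, sd=sd, cov=sd / mean,
                     breast_id=breast_id, tissue=tissue)


def f_critical(df1: int | float, df2: int | float, alpha: float) -> float:
    """Upper-tail F quantile: q with P(F(df1, df2) > q) = alpha."""
    if not (0.0 < alpha <= 0.5):
        raise ValueError(f"alpha must be in (0, 0.5], got {alpha}")
    if df1 < 1 or df2 < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got ({df1}, {df2})")
    return float(stats.f.isf(alpha, df1, df2))


def t_critical(df: int | float, alpha: float) -> float:
    """One-tailed upper t quantile: q with P(t(df) > q) = alpha."""
    if not (0.0 < alpha <= 0.5):
        raise ValueError(f"alpha must be in (0, 0.5], got {alpha}")
    if df < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got {df}")
    return float(stats.t.isf(alpha, df))


def f_variance_ratio(
    s1: float,
    s2: float,
    df1: int,
    df2: int,
    alpha: float = 0.05,
    name: str = "",
) -> VarianceComparison:
    """One-tailed variance-ratio test: F_calc = (s1 / s2)^2 vs. its critical value.

    Rejects the equal-variance null when F_calc exceeds the upper-tail
    critical value at ``alpha`` with (df1, df2) degrees of freedom.
    A zero ``s2`` (a perfectly constant comparison series) is reported as
    a degenerate outcome rather than an error: the statistic is NaN and
    the null is not rejected.
    """
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be non-negative")
    crit = f_critical(df1, df2, alpha)
    if s2 == 0.0:
        return VarianceComparison(
            name=name, s1=s1, s2=s2, df1=df1, df2=df2,
            f_calc=float("nan"), alpha=alpha, f_crit=crit, reject=False,
            note="degenerate: zero denominator variance",
        )
    f_calc = (s1 / s2) ** 2
    return VarianceComparison(
        name=name, s1=s1, s2=s2, df1=df1, df2=df2,
        f_calc=f_calc, alpha=alpha, f_crit=crit, reject=bool(f_calc > crit),
    )


def _approx_df(s1: float, n1: int, s2: float, n2: int) -> float:
    """Approximate d.f. for the unequal-variance t-test.

    Uses (n + 1) denominators and a -2 correction (not the usual
    Welch-Satterthwaite (n - 1) form).  With equal s and equal n this
    evaluates to 2n.
    """
    a = s1 ** 2 / n1
    b = s2 ** 2 / n2
    denom = a ** 2 / (n1 + 1) + b ** 2 / (n2 + 1)
    if denom == 0.0:
        return float("inf")
    return (a + b) ** 2 / denom - 2.0


def t_unequal_var(
    pre: Sequence[float] | np.ndarray,
    post: Sequence[float] | np.ndarray,
    alpha: float = 0.01,
    name: str = "",
) -> MeanComparison:
    """One-tailed two-sample t-test for means with unequal, unknown variances.

    t = (x-bar_1 - x-bar_2) / sqrt(s1^2/n1 + s2^2/n2), with the approximate
    degrees of freedom from :func:`_approx_df`.  The d.f. is rounded to the
    nearest integer for the critical-value lookup; the critical value at
    the unrounded d.f. is logged alongside as a cross-check.
    """
    x1 = np.asarray(pre, dtype=float).ravel()
    x2 = np.asarray(post, dtype=float).ravel()
    if x1.size < 2 or x2.size < 2:
        raise InsufficientDataError(
            f"both groups need n >= 2, got {x1.size} and {x2.size}"
        )
    n1, n2 = x1.size, x2.size
    m1, m2 = float(x1.mean()), float(x2.mean())
    s1, s2 = float(x1.std(ddof=1)), float(x2.std(ddof=1))
    se = math.sqrt(s1 ** 2 / n1 + s2 ** 2 / n2)
    note = ""
    if se == 0.0:
        t_stat = 0.0 if m1 == m2 else math.inf * math.copysign(1.0, m1 - m2)
        note = "degenerate: zero standard error"
    else:
        t_stat = (m1 - m2) / se
    df_raw = _approx_df(s1, n1, s2, n2)
    df_int = max(1, int(round(df_raw))) if math.isfinite(df_raw) else 10 ** 6
    crit = t_critical(df_int, alpha)
    crit_raw = t_critical(max(1.0, df_raw), alpha) if math.isfinite(df_raw) else crit
    return MeanComparison(
        name=name, n1=n1, n2=n2, mean1=m1, mean2=m2, s1=s1, s2=s2,
        t_stat=float(t_stat), df_raw=float(df_raw), df=df_int, alpha=alpha,
        t_crit=crit, t_crit_unrounded_df=crit_raw,
        reject=bool(t_stat > crit), note=note,
    )


def spearman_r(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
) -> RankCorrelation:
    """Spearman rank correlation of two paired samples.

    Computed as the Pearson correlation of the two rank vectors, with
    average ranks assigned to ties.  Any strictly monotone relation
    therefore scores exactly +/-1.
    """
    xv = np.asarray(x, dtype=float).ravel()
    yv = np.asarray(y, dtype=float).ravel()
    if xv.size != yv.size:
        raise ValueError("x and y must be the same length")
    if xv.size < 3:
        raise InsufficientDataError("Spearman r needs at least 3 pairs")
    if np.ptp(xv) == 0.0 or np.ptp(yv) == 0.0:
        raise ValueError("Spearman r undefined for a constant vector")
    rx = stats.rankdata(xv, method="average")
    ry = stats.rankdata(yv, method="average")
    r = float(np.corrcoef(rx, ry)[0, 1])
    return RankCorrelation(n=xv.size, spearman_r=r)


# ---------------------------------------------------------------------------
# the four-hypothesis battery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BatteryConfig:
    """Significance levels and column mapping for the hypothesis battery.

    Alphas follow the study's usage: variance F-tests at 0.01 (gland) and
    0.05 (duct); CoV t-tests at 0.01, with a 0.10 sensitivity note for the
    ductal test; within-group gland-vs-duct variance contrasts at 0.001.
    All tests are one-tailed.
    """

    alpha_h1: float = 0.01
    alpha_h2: float = 0.05
    alpha_h3: float = 0.01
    alpha_h4: float = 0.01
    alpha_h4_sensitivity: float = 0.10
    alpha_contrast: float = 0.001
    group_col: str = "group"
    breast_col: str = "breast_id"
    day_col: str = "day"
    gland_col: str = "gland_cc"
    duct_col: str = "duct_cc"
    excluded_col: str = "excluded"


@dataclass
class BatteryResult:
    """Statistics, critical values and decisions for the four null hypotheses.

    ``hypotheses`` maps "I".."IV" to the comparison records; ``contrasts``
    holds the within-group gland-vs-duct variance F-tests; ``spearman``
    the per-group rank correlations of per-breast mean duct vs. gland
    volume; ``summary`` the per-group/per-tissue CoV and SD table;
    ``per_breast`` one row per breast and tissue with n, mean, sd, cov.
    """

    hypotheses: dict = field(default_factory=dict)
    contrasts: dict = field(default_factory=dict)
    spearman: dict = field(default_factory=dict)
    summary: pd.DataFrame = field(default_factory=pd.DataFrame)
    per_breast: pd.DataFrame = field(default_factory=pd.DataFrame)
    notes: list = field(default_factory=list)

    @property
    def decisions(self) -> dict:
        return {k: v.decision for k, v in self.hypotheses.items()}

    def to_dict(self) -> dict:
        out = {
            "hypotheses": {k: asdict(v) for k, v in self.hypotheses.items()},
            "decisions": self.decisions,
            "contrasts": {k: asdict(v) for k, v in self.contrasts.items()},
            "spearman": {k: asdict(v) for k, v in self.spearman.items()},
            "summary": self.summary.to_dict(orient="records"),
            "notes": list(self.notes),
        }
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, default=float, **kwargs)

    def to_markdown(self) -> str:
        lines = ["# Cycle-variation hypothesis battery", ""]
        lines.append("## Group summary (per-breast series statistics)")
        lines.append("")
        if not self.summary.empty:
            lines.append(self.summary.to_markdown(index=False))
        lines.append("")
        lines.append("## Null hypotheses")
        lines.append("")
        lines.append(
            "| H | contrast | statistic | critical value | alpha | decision |"
        )
        lines.append("|---|----------|-----------|----------------|-------|----------|")
        for key, h in self.hypotheses.items():
            if isinstance(h, VarianceComparison):
                stat = f"F = {h.f_calc:.3f}"
                crit = f"{h.f_crit:.3f} (df {h.df1}, {h.df2})"
            else:
                stat = f"t = {h.t_stat:.3f}"
                crit = f"{h.t_crit:.3f} (df {h.df})"
            lines.append(
                f"| {key} | {h.name} | {stat} | {crit} | {h.alpha:g} | {h.decision} |"
            )
        lines.append("")
        if self.contrasts:
            lines.append("## Within-group gland-vs-duct variance contrasts")
            lines.append("")
            for key, c in self.contrasts.items():
                lines.append(
                    f"- {key}: F = {c.f_calc:.3f} vs. "
                    f"F({c.df1},{c.df2};{c.alpha:g}) = {c.f_crit:.3f} -> {c.decision}"
                )
            lines.append("")
        if self.spearman:
            lines.append("## Spearman validation (per-breast mean duct vs. gland volume)")
            lines.append("")
            for key, r in self.spearman.items():
                lines.append(f"- {key}: r = {r.spearman_r:.3f} (n = {r.n})")
            lines.append("")
        for note in self.notes:
            lines.append(f"> {note}")
        return "\n".join(lines) + "\n"


def _per_breast_stats(df: pd.DataFrame, cfg: BatteryConfig) -> pd.DataFrame:
    rows = []
    for (breast, group), sub in df.groupby([cfg.breast_col, cfg.group_col], sort=True):
        for tissue, col in (("gland", cfg.gland_col), ("duct", cfg.duct_col)):
            x = sub.sort_values(cfg.day_col)[col].to_numpy(dtype=float)
            if x.size < 2:
                continue
            mean = float(x.mean())
            sd = float(x.std(ddof=1))
            cov = sd / mean if mean > 0 else float("nan")
            rows.append({
                "breast_id": breast, "group": group, "tissue": tissue,
                "n": int(x.size), "mean_cc": mean, "sd_cc": sd, "cov": cov,
            })
    return pd.DataFrame(rows)


def _pooled_sd(df: pd.DataFrame, cfg: BatteryConfig, group: str, col: str) -> tuple[float, int]:
    """Pool per-scan deviations from each breast's own mean across a group.

    Returns (pooled SD in cc, degrees of freedom = total scans - breasts).
    """
    sub = df[df[cfg.group_col] == group]
    ss = 0.0
    n_obs = 0
    n_breast = 0
    for _, b in sub.groupby(cfg.breast_col):
        x = b[col].to_numpy(dtype=float)
        if x.size < 2:
            continue
        ss += float(((x - x.mean()) ** 2).sum())
        n_obs += x.size
        n_breast += 1
    dof = n_obs - n_breast
    if dof < 1:
        raise InsufficientDataError(
            f"group {group!r} has no breast with >= 2 retained observations"
        )
    return math.sqrt(ss / dof), dof


def run_battery(
    volumetrics: pd.DataFrame,
    config: BatteryConfig | None = None,
) -> BatteryResult:
    """Run the four-null-hypothesis battery on a cleaned volumetrics table.

    Expects one row per retained scan with group, breast, day, glandular
    and ductal volume columns (see :class:`BatteryConfig`).  Rows with a
    truthy ``excluded`` column are dropped.  Peri-menopausal series are
    carried through the per-breast statistics and summary but the four
    hypotheses compare the pre and post groups only.

    * H-I  : pooled glandular variance, pre vs. post (one-tailed F)
    * H-II : pooled ductal variance, pre vs. post (one-tailed F)
    * H-III: mean glandular CoV, pre vs. post (heteroscedastic t)
    * H-IV : mean ductal CoV, pre vs. post (heteroscedastic t)

    plus within-group gland-vs-duct variance contrasts and the per-group
    Spearman rank correlation of per-breast mean duct vs. gland volume.
    """
    cfg = config or BatteryConfig()
    df = volumetrics.copy()
    for col in (cfg.group_col, cfg.breast_col, cfg.day_col, cfg.gland_col, cfg.duct_col):
        if col not in df.columns:
            raise ConfigurationError(
                f"volumetrics table is missing required column {col!r}"
            )
    if cfg.excluded_col in df.columns:
        df = df[~df[cfg.excluded_col].astype(bool)]
    groups = set(df[cfg.group_col].unique())
    for required in ("pre", "post"):
        if required not in groups:
            raise ConfigurationError(
                f"battery requires both 'pre' and 'post' groups; found {sorted(groups)}"
            )

    result = BatteryResult()
    per_breast = _per_breast_stats(df, cfg)
    result.per_breast = per_breast

    # pooled within-breast variances per group and tissue
    pooled: dict[tuple[str, str], tuple[float, int]] = {}
    for group in ("pre", "post"):
        for tissue, col in (("gland", cfg.gland_col), ("duct", cfg.duct_col)):
            pooled[(group, tissue)] = _pooled_sd(df, cfg, group, col)

    (s_pre_g, df_pre_g) = pooled[("pre", "gland")]
    (s_post_g, df_post_g) = pooled[("post", "gland")]
    (s_pre_d, df_pre_d) = pooled[("pre", "duct")]
    (s_post_d, df_post_d) = pooled[("post", "duct")]

    result.hypotheses["I"] = f_variance_ratio(
        s_pre_g, s_post_g, df_pre_g, df_post_g, alpha=cfg.alpha_h1,
        name="glandular variance, pre vs. post",
    )
    result.hypotheses["II"] = f_variance_ratio(
        s_pre_d, s_post_d, df_pre_d, df_post_d, alpha=cfg.alpha_h2,
        name="ductal variance, pre vs. post",
    )

    def covs(group: str, tissue: str) -> np.ndarray:
        sel = (per_breast["group"] == group) & (per_breast["tissue"] == tissue)
        return per_breast.loc[sel, "cov"].dropna().to_numpy()

    result.hypotheses["III"] = t_unequal_var(
        covs("pre", "gland"), covs("post", "gland"), alpha=cfg.alpha_h3,
        name="mean glandular CoV, pre vs. post",
    )
    h4 = t_unequal_var(
        covs("pre", "duct"), covs("post", "duct"), alpha=cfg.alpha_h4,
        name="mean ductal CoV, pre vs. post",
    )
    result.hypotheses["IV"] = h4
    sens = t_critical(h4.df, cfg.alpha_h4_sensitivity)
    result.notes.append(
        f"H-IV sensitivity: at alpha = {cfg.alpha_h4_sensitivity:g} the critical value is "
        f"{sens:.3f}; t = {h4.t_stat:.3f} -> "
        f"{REJECT if h4.t_stat > sens else FAIL_TO_REJECT}"
    )

    result.contrasts["pre: gland vs. duct"] = f_variance_ratio(
        s_pre_g, s_pre_d, df_pre_g, df_pre_d, alpha=cfg.alpha_contrast,
        name="pre-menopausal gland vs. duct variance",
    )
    result.contrasts["post: gland vs. duct"] = f_variance_ratio(
        s_post_g, s_post_d, df_post_g, df_post_d, alpha=cfg.alpha_contrast,
        name="post-menopausal gland vs. duct variance",
    )

    # Spearman validation per group (and pooled) on per-breast mean volumes
    for label, sel_groups in (("pre", ["pre"]), ("post", ["post"]),
                              ("all", sorted(groups))):
        sel = per_breast[per_breast["group"].isin(sel_groups)]
        means = sel.pivot_table(index="breast_id", columns="tissue",
                                values="mean_cc")
        if {"gland", "duct"} <= set(means.columns) and len(means) >= 3:
            try:
                result.spearman[label] = spearman_r(
                    means["gland"].to_numpy(), means["duct"].to_numpy()
                )
            except ValueError:
                result.notes.append(f"Spearman undefined for group {label!r}")

    # Table-style summary: mean CoV with range, mean per-breast SD
    summary_rows = []
    for group in sorted(per_breast["group"].unique()):
        for tissue in ("gland", "duct"):
            sel = per_breast[(per_breast["group"] == group)
                             & (per_breast["tissue"] == tissue)]
            if sel.empty:
                continue
            summary_rows.append({
                "group": group,
                "tissue": tissue,
                "n_breasts": int(len(sel)),
                "mean_cov_pct": 100.0 * float(sel["cov"].mean()),
                "min_cov_pct": 100.0 * float(sel["cov"].min()),
                "max_cov_pct": 100.0 * float(sel["cov"].max()),
                "mean_sd_cc": float(sel["sd_cc"].mean()),
                "pooled_sd_cc": pooled[(group, tissue)][0]
                if (group, tissue) in pooled else float("nan"),
            })
    result.summary = pd.DataFrame(summary_rows)

    degenerate = [k for k, h in result.hypotheses.items() if h.note]
    if degenerate:
        result.notes.append(
            "degenerate-variance outcome for hypotheses: " + ", ".join(degenerate)
        )
    return result
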