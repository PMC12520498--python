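"""Psychometric scoring, responder classification and cohort inference.

Paired condition contrasts use the two-tailed Wilcoxon signed-rank test
(exact p for n <= 25 via the rank-sum distribution, normal approximation
with tie correction above), Benjamini-Hochberg FDR within declared
families, and Cliff's delta with a consistent-variance normal CI.
Response-magnitude regressions (delta STAI on cardiac, EEG and coupling
predictors) are ordinary least squares.  Split-half (odd/even)
reliability uses the Spearman-Brown prediction formula.  The a-priori
paired-design sample size iterates the noncentral-t power expression.

``AnxietyStudy(metrics).fit()`` bundles all of it into an
:class:`AnxietyStudyResults` with a ``summary()`` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sct
from statsmodels.api import OLS, add_constant
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "response_magnitude",
    "classify_responders",
    "wilcoxon_signed_rank",
    "fdr_adjust",
    "cliffs_delta",
    "fit_response_models",
    "split_half_reliability",
    "spearman_brown",
    "power_sample_size",
    "AnxietyStudy",
    "AnxietyStudyResults",
    "WilcoxonResult",
    "PairedComparisonResult",
    "ResponseModelResult",
    "ReliabilityResult",
]


def response_magnitude(before: float, after: float, baseline: float) -> float:
    """(before - after) / baseline; positive values mean anxiety reduction."""
    if baseline <= 0:
        raise ValueError("baseline score must be positive")
    return (before - after) / baseline


def classify_responders(cohort: pd.DataFrame) -> pd.DataFrame:
    """Label participants responsive (after < before) / unresponsive.

    Rows with missing before/after scores are excluded with a log entry.
    Expects columns ``participant``, ``stai_before``, ``stai_after``.
    """
    df = cohort.copy()
    missing = df["stai_before"].isna() | df["stai_after"].isna()
    for pid in df.loc[missing, "participant"]:
        logger.warning("participant %s excluded: missing STAI score", pid)
    df = df.loc[~missing].copy()
    df["group"] = np.where(df["stai_after"] < df["stai_before"], "responsive", "unresponsive")
    return df


@dataclass(frozen=True)
class WilcoxonResult:
    w_plus: float
    w_minus: float
    p: float
    n: int
    method: str

    @property
    def w(self) -> float:  # positive-difference rank sum, the primary statistic
        return self.w_plus


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p via the distribution of the positive rank sum.

    Mid-ranks are handled by doubling (2 * rank is integral for half-
    integer mid-ranks); the null assigns each rank to + or - with equal
    probability.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = r2.sum()
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    w2 = int(np.rint(2 * w_plus))
    p_le = dist[: w2 + 1].sum()
    p_ge = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(x, y, exact_max_n: int = 25) -> WilcoxonResult:
    """Two-tailed Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (classic Wilcoxon convention); ties are
    mid-ranked.  Reports both the positive- and negative-difference rank
    sums, since either orientation appears in common software.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero")
    if n < 5:
        raise ValueError("fewer than 5 nonzero differences")
    ranks = sct.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    if n <= exact_max_n:
        p = _exact_signed_rank_p(ranks, w_plus)
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        # tie correction on the variance of the rank sum
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = (counts**3 - counts).sum() / 48.0
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        z = (w_plus - mu) / sigma
        p = float(2.0 * sct.norm.sf(abs(z)))
        method = "normal"
    return WilcoxonResult(w_plus, w_minus, p, n, method)


def fdr_adjust(p_values, families=None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment within declared families.

    ``families`` maps a family label to the indices it contains; ``None``
    treats all p values as one family.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    out = np.empty_like(p)
    if families is None:
        families = {"all": np.arange(p.size)}
    covered = np.concatenate([np.asarray(ix) for ix in families.values()])
    if sorted(covered.tolist()) != list(range(p.size)):
        raise ValueError("families must partition the p values")
    for ix in families.values():
        ix = np.asarray(ix)
        if ix.size == 0:
            continue
        out[ix] = multipletests(p[ix], method="fdr_bh")[1]
    return out


def cliffs_delta(x, y, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Cliff's dominance delta with a consistent-variance normal CI.

    delta = (#{x_i > y_j} - #{x_i < y_j}) / (n m).  The CI uses Cliff's
    consistent variance estimate from the row/column dominance means,
    truncated to [-1, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n, m = x.size, y.size
    sign = np.sign(x[:, None] - y[None, :])
    delta = float(sign.mean())
    di = sign.mean(axis=1)  # row dominance means
    dj = sign.mean(axis=0)
    s_di = di.var(ddof=1) if n > 1 else 0.0
    s_dj = dj.var(ddof=1) if m > 1 else 0.0
    s_dij = sign.var(ddof=1)
    var = (m**2 * n * s_di + n**2 * m * s_dj - n * m * s_dij) / (n * m * (n - 1) * (m - 1)) \
        if n > 1 and m > 1 else np.nan
    var = max(var, 0.0) if np.isfinite(var) else np.nan
    z = sct.norm.ppf(1 - alpha / 2)
    if np.isfinite(var):
        half = z * np.sqrt(var)
        ci = (max(-1.0, delta - half), min(1.0, delta + half))
    else:
        ci = (-1.0, 1.0)
    return delta, ci


@dataclass
class PairedComparisonResult:
    metric: str
    group: str
    n: int
    w_plus: float
    w_minus: float
    p_raw: float
    p_adj: float
    cliffs_delta: float
    delta_ci: tuple[float, float]


@dataclass
class ResponseModelResult:
    """One OLS response-magnitude model (per-predictor slope/t/p/d)."""

    name: str
    predictors: list[str]
    coefficients: np.ndarray
    t_stats: np.ndarray
    p_values: np.ndarray
    cohens_d: np.ndarray
    d_ci: list[tuple[float, float]]
    nobs: int
    metadata: dict = field(default_factory=dict)


@dataclass
class ReliabilityResult:
    metric: str
    group: str
    spearman_r: float
    spearman_brown: float


def fit_response_models(
    metrics: pd.DataFrame,
    model_specs: dict[str, list[str]] | None = None,
    response_col: str = "delta_stai",
) -> dict[str, ResponseModelResult]:
    """OLS of the response magnitude on cardiac / EEG / coupling predictors.

    Default model blocks: cardiac (lf, hf, lf_hf), eeg (alpha, beta),
    coupling (b2hf, b2lf, hf2b, lf2b).  Cohen's d per predictor is
    2 t / sqrt(df) (convention recorded in metadata); its CI uses the
    usual large-sample variance of d.
    """
    if model_specs is None:
        model_specs = {
            "cardiac": ["lf", "hf", "lf_hf"],
            "eeg": ["alpha", "beta"],
            "coupling": ["b2hf", "b2lf", "hf2b", "lf2b"],
        }
    out = {}
    for name, preds in model_specs.items():
        cols = [c for c in preds if c in metrics.columns]
        if len(cols) != len(preds):
            missing = set(preds) - set(cols)
            raise ValueError(f"model {name!r}: missing predictor column(s) {sorted(missing)}")
        sub = metrics[[response_col] + cols].dropna()
        if len(sub) <= len(cols) + 2:
            raise ValueError(f"model {name!r}: n={len(sub)} too small for {len(cols)} predictors")
        X = add_constant(sub[cols].to_numpy())
        cond = np.linalg.cond(X)
        if cond > 1e8:
            logger.warning("model %s: collinear predictors (condition number %.2g)", name, cond)
        fit = OLS(sub[response_col].to_numpy(), X).fit()
        df_resid = fit.df_resid
        t = fit.tvalues[1:]
        d = 2 * t / np.sqrt(df_resid)
        se_d = np.sqrt(4.0 / len(sub) + d**2 / (2 * df_resid))
        z = sct.norm.ppf(0.975)
        d_ci = [(float(di - z * si), float(di + z * si)) for di, si in zip(d, se_d)]
        out[name] = ResponseModelResult(
            name=name,
            predictors=cols,
            coefficients=fit.params[1:],
            t_stats=t,
            p_values=fit.pvalues[1:],
            cohens_d=d,
            d_ci=d_ci,
            nobs=int(fit.nobs),
            metadata={"cohens_d_convention": "d = 2t/sqrt(df_resid)",
                      "condition_number": float(cond)},
        )
    return out


def split_half_reliability(
    per_participant: dict[str, np.ndarray], metric: str = "", group: str = "all"
) -> ReliabilityResult:
    """Odd-even split-half reliability across a cohort.

    For each participant the windowed metric values are split by odd/even
    index; the cohort Spearman correlation between odd means and even
    means is stepped up with the Spearman-Brown prediction formula
    2r / (1 + r).
    """
    odd, even = [], []
    for pid, vals in per_participant.items():
        v = np.asarray(vals, dtype=float)
        v = v[np.isfinite(v)]
        if v.size < 8:
            raise ValueError(f"participant {pid}: need >= 8 data points")
        odd.append(v[1::2].mean())
        even.append(v[0::2].mean())
    odd, even = np.asarray(odd), np.asarray(even)
    if np.all(odd == odd[0]) or np.all(even == even[0]):
        raise ValueError("constant split means: reliability undefined")
    r = float(sct.spearmanr(odd, even).statistic)
    sb = spearman_brown(r)
    return ReliabilityResult(metric, group, r, sb)


def spearman_brown(r: float) -> float:
    """Reliability of the full-length measure from a half-split correlation."""
    if r <= -1:
        raise ValueError("r must exceed -1")
    return 2.0 * r / (1.0 + r)


def power_sample_size(d: float, alpha: float = 0.05, power: float = 0.8,
                      n_max: int = 10000) -> int:
    """Smallest paired-design n giving the requested power for effect size d.

    Two-sided one-sample/paired t test: noncentrality d * sqrt(n),
    df = n - 1; power from the noncentral-t distribution.
    """
    if d <= 0:
        raise ValueError("effect size must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    for n in range(2, n_max + 1):
        df = n - 1
        tcrit = sct.t.ppf(1 - alpha / 2, df)
        ncp = d * np.sqrt(n)
        pw = sct.nct.sf(tcrit, df, ncp) + sct.nct.cdf(-tcrit, df, ncp)
        if pw >= power:
            return n
    raise ValueError("requested power unreachable within n_max")


class AnxietyStudy:
    """Cohort-level inference model.

    Parameters
    ----------
    metrics : DataFrame
        One row per participant x condition with columns ``participant``,
        ``condition`` ({zen, control}), ``stai_baseline``, ``stai_before``,
        ``stai_after`` and per-metric condition means (``lf``, ``hf``,
        ``lf_hf``, ``alpha``, ``beta`` and optionally the four coupling
        coefficients ``b2hf``, ``b2lf``, ``hf2b``, ``lf2b``).
    """

    PHYSIO_METRICS = ("lf", "hf", "lf_hf", "alpha", "beta")
    COUPLING_METRICS = ("b2hf", "b2lf", "hf2b", "lf2b")

    def __init__(self, metrics: pd.DataFrame):
        required = {"participant", "condition", "stai_before", "stai_after", "stai_baseline"}
        missing = required - set(metrics.columns)
        if missing:
            raise ValueError(f"metrics missing column(s): {sorted(missing)}")
        self.metrics = metrics.copy()

    def _wide(self) -> pd.DataFrame:
        value_cols = [c for c in self.metrics.columns
                      if c in self.PHYSIO_METRICS + self.COUPLING_METRICS]
        wide = self.metrics.pivot_table(
            index="participant", columns="condition", values=value_cols
        )
        stai = self.metrics.drop_duplicates("participant").set_index("participant")[
            ["stai_baseline", "stai_before", "stai_after"]
        ]
        return wide, stai

    def fit(self, alpha: float = 0.05, exclude_hf2b_outliers: bool = True) -> "AnxietyStudyResults":
        from .coupling import exclude_coupling_outliers

        wide, stai = self._wide()
        cohort = classify_responders(stai.reset_index())
        cohort["delta_stai"] = [
            response_magnitude(b, a, bl)
            for b, a, bl in zip(cohort["stai_before"], cohort["stai_after"], cohort["stai_baseline"])
        ]
        cohort = cohort.set_index("participant")

        present = [m for m in self.PHYSIO_METRICS + self.COUPLING_METRICS
                   if m in {c[0] for c in wide.columns}]
        coupling_present = [m for m in self.COUPLING_METRICS if m in present]

        # per-analysis-block FDR families
        comparisons: list[PairedComparisonResult] = []
        raw_p, fam_labels = [], []
        excluded_outliers: list[str] = []
        coupling_keep = set(cohort.index)
        if coupling_present and exclude_hf2b_outliers and "hf2b" in coupling_present:
            means = pd.DataFrame({
                "participant": wide.index,
                "group": cohort.loc[wide.index, "group"].to_numpy(),
                "hf2b": wide[("hf2b", "zen")].to_numpy(),
            }).dropna()
            filtered, excluded_outliers = exclude_coupling_outliers(means)
            coupling_keep = set(filtered["participant"])

        def add(metric, group, ids, family):
            ids = [i for i in ids if i in wide.index]
            z = wide.loc[ids, (metric, "zen")].to_numpy()
            c = wide.loc[ids, (metric, "control")].to_numpy()
            ok = np.isfinite(z) & np.isfinite(c)
            z, c = z[ok], c[ok]
            if z.size < 5:
                return
            res = wilcoxon_signed_rank(z, c)
            delta, ci = cliffs_delta(z, c)
            comparisons.append(PairedComparisonResult(
                metric, group, res.n, res.w_plus, res.w_minus, res.p, np.nan, delta, ci
            ))
            raw_p.append(res.p)
            fam_labels.append(family)

        all_ids = list(cohort.index)
        resp = list(cohort.index[cohort["group"] == "responsive"])
        unresp = list(cohort.index[cohort["group"] == "unresponsive"])
        for m in present:
            if m in self.COUPLING_METRICS:
                continue
            add(m, "all", all_ids, "all_contrasts")
            add(m, "responsive", resp, "group_contrasts")
            add(m, "unresponsive", unresp, "group_contrasts")
        for m in coupling_present:
            ids = [i for i in all_ids if i in coupling_keep]
            add(m, "responsive", [i for i in resp if i in coupling_keep], "coupling_contrasts")
            add(m, "unresponsive", [i for i in unresp if i in coupling_keep], "coupling_contrasts")

        if raw_p:
            fams: dict[str, list[int]] = {}
            for i, f in enumerate(fam_labels):
                fams.setdefault(f, []).append(i)
            adj = fdr_adjust(np.asarray(raw_p), fams)
            for comp, pa in zip(comparisons, adj):
                comp.p_adj = float(pa)

        # STAI before/after contrast (its own single-test family)
        try:
            stai_test = wilcoxon_signed_rank(
                cohort["stai_before"].to_numpy(), cohort["stai_after"].to_numpy()
            )
        except ValueError:
            stai_test = None  # too few nonzero differences at this cohort size

        # response-magnitude regressions on zen-condition means
        reg_df = pd.DataFrame({"delta_stai": cohort["delta_stai"]})
        for m in present:
            reg_df[m] = wide[(m, "zen")]
        model_specs = {}
        if all(m in present for m in ("lf", "hf", "lf_hf")):
            model_specs["cardiac"] = ["lf", "hf", "lf_hf"]
        if all(m in present for m in ("alpha", "beta")):
            model_specs["eeg"] = ["alpha", "beta"]
        if all(m in present for m in self.COUPLING_METRICS):
            model_specs["coupling"] = list(self.COUPLING_METRICS)
        models = {}
        for name, preds in model_specs.items():
            try:
                models.update(fit_response_models(reg_df.reset_index(drop=True), {name: preds}))
            except ValueError as exc:
                logger.warning("response model %s skipped: %s", name, exc)

        return AnxietyStudyResults(
            self, cohort.reset_index(), comparisons, models, stai_test, excluded_outliers
        )


class AnxietyStudyResults:
    def __init__(self, model, cohort, comparisons, regressions, stai_test, excluded_outliers):
        self.model = model
        self.cohort = cohort
        self.comparisons = comparisons
        self.regressions = regressions
        self.stai_test = stai_test
        self.excluded_outliers = excluded_outliers

    @property
    def n_responsive(self) -> int:
        return int((self.cohort["group"] == "responsive").sum())

    @property
    def n_unresponsive(self) -> int:
        return int((self.cohort["group"] == "unresponsive").sum())

    def comparisons_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"metric": c.metric, "group": c.group, "n": c.n, "W_plus": c.w_plus,
             "W_minus": c.w_minus, "p_raw": c.p_raw, "p_adj": c.p_adj,
             "delta": c.cliffs_delta, "ci_lo": c.delta_ci[0], "ci_hi": c.delta_ci[1]}
            for c in self.comparisons
        ])

    def summary(self) -> str:
        lines = [
            "Cohort inference summary",
            f"  participants: {len(self.cohort)} "
            f"({self.n_responsive} responsive / {self.n_unresponsive} unresponsive)",
        ]
        if self.stai_test is not None:
            lines.append(
                f"  STAI-Y1 before vs after: W+={self.stai_test.w_plus:.0f} "
                f"W-={self.stai_test.w_minus:.0f} p={self.stai_test.p:.4f}"
            )
        if self.excluded_outliers:
            lines.append(f"  HF2B outliers excluded from coupling stats: {self.excluded_outliers}")
        df = self.comparisons_frame()
        if len(df):
            lines.append(df.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
        for name, m in self.regressions.items():
            lines.append(f"  model {name}: n={m.nobs}")
            for pred, b, t, p, d in zip(m.predictors, m.coefficients, m.t_stats, m.p_values, m.cohens_d):
                lines.append(f"    {pred:>6}: slope {b:+.4f}  t {t:+.3f}  p {p:.4f}  d {d:+.3f}")
        return "\n".join(lines)
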