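"""Group-level statistics of per-subject defocus-curve metrics.

Two analyses:

* :class:`DofGainModel` — linear mixed-effects regression of the
  depth-of-focus gain (lens DOF minus the subject's monofocal baseline)
  on the baseline, separately sloped per lens class, with a session fixed
  effect and a per-subject random intercept (REML via statsmodels).

* :func:`omnibus_and_posthoc` — repeated-measures comparison of a metric
  across the lenses of a session: RM-ANOVA with Bonferroni-corrected
  paired t tests when residuals look normal, otherwise a Friedman test
  with Tukey–Kramer rank post hoc.

The expected input is a tidy table with one row per subject × lens:
columns ``subject``, ``lens``, ``group`` ('trifocal'|'EDOF'), ``session``
('I'|'II'), ``dof``, ``baseline_dof`` and metric columns such as ``far``,
``intermediate``, ``near``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DofGainModel",
    "DofGainResults",
    "dof_gain_regression",
    "friedman_statistic",
    "friedman_test",
    "tukey_kramer_ranks",
    "OmnibusResult",
    "omnibus_and_posthoc",
]

_REQUIRED = {"subject", "lens", "group", "session", "dof", "baseline_dof"}


def _validate(records: pd.DataFrame) -> pd.DataFrame:
    missing = _REQUIRED - set(records.columns)
    if missing:
        raise ValueError(f"records table lacks columns: {sorted(missing)}")
    if records.duplicated(["subject", "lens"]).any():
        raise ValueError("more than one record per subject × lens")
    return records.copy()


class DofGainModel:
    """Mixed-effects model of DOF gain on the monofocal baseline.

    gain ~ baseline * group + session, random intercept per subject.
    The per-group baseline slopes quantify how much less a wide
    monofocal depth of focus leaves to gain from a presbyopia-correcting
    design.
    """

    def __init__(self, records: pd.DataFrame) -> None:
        df = _validate(records)
        df["gain"] = df["dof"] - df["baseline_dof"]
        if df["subject"].nunique() < 5:
            raise ValueError("need at least 5 subjects")
        per_group = df.groupby("group")["lens"].nunique()
        if (per_group < 2).any():
            raise ValueError("need at least 2 lenses per group")
        self.data = df

    def fit(self, reml: bool = True) -> "DofGainResults":
        import statsmodels.formula.api as smf

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = smf.mixedlm("gain ~ baseline_dof * C(group) + C(session)",
                              self.data, groups=self.data["subject"]
                              ).fit(reml=reml)
        return DofGainResults(self, res)


class DofGainResults:
    """Per-group baseline slopes, interaction and session tests."""

    def __init__(self, model: DofGainModel, mixedlm_results) -> None:
        self.model = model
        self.mixedlm = mixedlm_results
        params = mixedlm_results.params
        cov = mixedlm_results.cov_params()
        groups = sorted(model.data["group"].unique())
        ref = groups[0]
        self.slopes: dict[str, dict[str, float]] = {}
        base_se = float(mixedlm_results.bse["baseline_dof"])
        self.slopes[ref] = self._slope_entry(float(params["baseline_dof"]), base_se)
        self._interaction_terms = []
        for g in groups[1:]:
            term = f"baseline_dof:C(group)[T.{g}]"
            est = float(params["baseline_dof"] + params[term])
            var = (cov.loc["baseline_dof", "baseline_dof"]
                   + cov.loc[term, term]
                   + 2.0 * cov.loc["baseline_dof", term])
            self.slopes[g] = self._slope_entry(est, float(np.sqrt(var)))
            self._interaction_terms.append(term)

    @staticmethod
    def _slope_entry(est: float, se: float) -> dict[str, float]:
        z = est / se if se > 0 else np.inf
        return {
            "estimate": est, "se": se,
            "ci_low": est - 1.96 * se, "ci_high": est + 1.96 * se,
            "pvalue": float(2.0 * stats.norm.sf(abs(z))),
        }

    @property
    def interaction_pvalue(self) -> float:
        """Wald test: do the baseline slopes differ between lens classes?"""
        ps = [float(self.mixedlm.pvalues[t]) for t in self._interaction_terms]
        return min(ps) if ps else np.nan

    @property
    def session_pvalue(self) -> float:
        terms = [t for t in self.mixedlm.params.index if t.startswith("C(session)")]
        ps = [float(self.mixedlm.pvalues[t]) for t in terms]
        return min(ps) if ps else np.nan

    def summary(self) -> str:
        lines = [
            "DOF gain ~ baseline × lens class + session (random intercept/subject)",
            "=" * 70,
            f"{'group':<12}{'slope':>10}{'se':>10}{'95% CI':>22}{'p':>12}",
        ]
        for g, s in self.slopes.items():
            lines.append(
                f"{g:<12}{s['estimate']:>10.3f}{s['se']:>10.3f}"
                f"{'[%.3f, %.3f]' % (s['ci_low'], s['ci_high']):>22}"
                f"{s['pvalue']:>12.4g}")
        lines.append("-" * 70)
        lines.append(f"slope × class interaction p = {self.interaction_pvalue:.4g}")
        lines.append(f"session fixed effect p       = {self.session_pvalue:.4g}")
        return "\n".join(lines)


def dof_gain_regression(records: pd.DataFrame) -> DofGainResults:
    """Functional wrapper: fit :class:`DofGainModel` by REML."""
    return DofGainModel(records).fit()


# ---------------------------------------------------------------------------
# repeated-measures omnibus + post hoc
# ---------------------------------------------------------------------------

def friedman_statistic(blocks: np.ndarray) -> float:
    """Friedman chi-square for an n-subjects × k-treatments block design.

    χ²_F = 12/(n·k·(k+1)) · Σ R_j² − 3·n·(k+1), with mid-ranks for ties
    (a fully tied design therefore yields exactly 0).
    """
    x = np.asarray(blocks, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("blocks must be an n × k array with k >= 2")
    n, k = x.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, x)
    rsum = ranks.sum(axis=0)
    return float(12.0 / (n * k * (k + 1)) * np.sum(rsum ** 2) - 3.0 * n * (k + 1))


def friedman_test(blocks: np.ndarray) -> tuple[float, float]:
    """Friedman statistic and its chi-square p-value (k − 1 df)."""
    x = np.asarray(blocks, dtype=float)
    chi2 = friedman_statistic(x)
    return chi2, float(stats.chi2.sf(chi2, x.shape[1] - 1))


def tukey_kramer_ranks(blocks: np.ndarray) -> pd.DataFrame:
    """Tukey–Kramer post hoc on Friedman mean ranks.

    Pairwise studentized-range test of mean-rank differences with the
    large-sample standard error sqrt(k(k+1)/(6n)).
    """
    x = np.asarray(blocks, dtype=float)
    n, k = x.shape
    mean_ranks = np.apply_along_axis(stats.rankdata, 1, x).mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            q = abs(mean_ranks[i] - mean_ranks[j]) / se * np.sqrt(2.0)
            p = float(stats.studentized_range.sf(q, k, np.inf))
            rows.append({"i": i, "j": j, "statistic": q, "pvalue": min(1.0, p)})
    return pd.DataFrame(rows)


@dataclass
class OmnibusResult:
    """Omnibus + post hoc comparison of one metric across k lenses."""

    branch: str                  # 'parametric' | 'nonparametric'
    normality_pvalue: float
    omnibus_statistic: float
    omnibus_pvalue: float
    pairwise: pd.DataFrame       # lens_a, lens_b, direction, pvalue, significant
    n_subjects: int
    lenses: list[str] = field(default_factory=list)

    def to_records(self, session: str = "", distance: str = "") -> list[dict]:
        """Table-style rows: session, distance, comparison, direction, p."""
        out = []
        for _, row in self.pairwise.iterrows():
            out.append({
                "session": session, "distance": distance,
                "comparison": f"{row['lens_a']} vs. {row['lens_b']}",
                "direction": row["direction"] if row["significant"] else "-",
                "p": float(row["pvalue"]),
            })
        return out


def _complete_blocks(records: pd.DataFrame, value: str) -> pd.DataFrame:
    wide = records.pivot(index="subject", columns="lens", values=value)
    incomplete = wide.isna().any(axis=1)
    if incomplete.any():
        warnings.warn(f"dropping {int(incomplete.sum())} subject(s) with "
                      "incomplete lens blocks", stacklevel=3)
        wide = wide.loc[~incomplete]
    if wide.shape[0] < 5:
        raise ValueError("fewer than 5 complete subject blocks")
    return wide


def omnibus_and_posthoc(records: pd.DataFrame, value: str,
                        alpha: float = 0.05,
                        higher_is_better: bool = True) -> OmnibusResult:
    """Compare one metric across all lenses in complete repeated blocks.

    Residuals (after removing subject and lens means) are tested for
    normality with Shapiro–Wilk at ``alpha``.  Normal data get a
    repeated-measures ANOVA with Bonferroni-corrected paired t tests;
    otherwise a Friedman test with Tukey–Kramer rank post hoc.  The branch
    taken is reported and is deterministic given the data.
    """
    if value not in records.columns:
        raise ValueError(f"no metric column '{value}'")
    wide = _complete_blocks(records, value)
    lenses = list(wide.columns)
    x = wide.to_numpy()
    n, k = x.shape
    resid = x - x.mean(axis=1, keepdims=True) - x.mean(axis=0) + x.mean()
    if np.allclose(resid, 0):
        norm_p = 0.0  # degenerate residuals: fall through to ranks
    else:
        norm_p = float(stats.shapiro(resid.ravel()).pvalue)
    n_pairs = k * (k - 1) // 2
    rows = []
    if norm_p >= alpha:
        branch = "parametric"
        from statsmodels.stats.anova import AnovaRM

        long = wide.reset_index().melt(id_vars="subject", var_name="lens",
                                       value_name=value)
        aov = AnovaRM(long, value, "subject", within=["lens"]).fit()
        stat = float(aov.anova_table["F Value"].iloc[0])
        omni_p = float(aov.anova_table["Pr > F"].iloc[0])
        for i in range(k):
            for j in range(i + 1, k):
                t = stats.ttest_rel(x[:, i], x[:, j])
                p = min(1.0, float(t.pvalue) * n_pairs)
                better = i if (x[:, i].mean() > x[:, j].mean()) == higher_is_better else j
                rows.append({"lens_a": lenses[i], "lens_b": lenses[j],
                             "pvalue": p, "direction": f"{lenses[better]} better",
                             "significant": p < alpha})
    else:
        branch = "nonparametric"
        stat, omni_p = friedman_test(x)
        tk = tukey_kramer_ranks(x)
        mean_vals = x.mean(axis=0)
        for _, row in tk.iterrows():
            i, j = int(row["i"]), int(row["j"])
            better = i if (mean_vals[i] > mean_vals[j]) == higher_is_better else j
            rows.append({"lens_a": lenses[i], "lens_b": lenses[j],
                         "pvalue": float(row["pvalue"]),
                         "direction": f"{lenses[better]} better",
                         "significant": float(row["pvalue"]) < alpha})
    return OmnibusResult(branch=branch, normality_pvalue=norm_p,
                         omnibus_statistic=stat, omnibus_pvalue=omni_p,
                         pairwise=pd.DataFrame(rows), n_subjects=n,
                         lenses=lenses)
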