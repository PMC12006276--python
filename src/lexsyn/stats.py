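"""Normality-gated group statistics for longitudinal discourse features.

The procedure mirrors standard clinical-speech practice:

* cross-sectional group differences at baseline — one-way ANOVA with
  Fisher LSD post hoc when every group looks normal, otherwise
  Kruskal–Wallis with Mann–Whitney U post hoc, post hocs protected by a
  significant omnibus;
* within-group longitudinal change (followup − baseline) — paired t-test
  when the differences look normal, Wilcoxon signed-rank otherwise;
* change–change correlations against clinical covariates — Pearson when
  both change vectors look normal, Spearman otherwise;
* Bonferroni control within each 3-feature family (lexical, syntactic),
  giving the adjusted threshold 0.05/3 ≈ 0.0167.

Normality is judged by a Kolmogorov–Smirnov test against a normal with
sample-estimated mean/SD using Lilliefors-corrected critical values (the
plain KS test is anticonservative when parameters are estimated); a
plain-KS mode is available by configuration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from .features import FEATURE_FAMILIES, FEATURE_NAMES, FeatureVector

__all__ = [
    "CohortDataset",
    "GateResult",
    "AnalysisConfig",
    "AnalysisReport",
    "normality_gate",
    "cross_sectional",
    "longitudinal_change",
    "correlate_changes",
    "bonferroni_alpha",
    "severity_zscores",
    "run_full_analysis",
]

REPORT_SCHEMA_VERSION = "1.0"
TIMEPOINTS = ("baseline", "followup")


# ---------------------------------------------------------------------------
# dataset container


class CohortDataset:
    """Long-format feature table: one row per subject × timepoint.

    Required columns: ``subject_id``, ``group``, ``timepoint``, plus any
    subset of the six feature columns; remaining numeric columns are
    treated as clinical covariates.  NaN in a feature cell means the
    feature was undefined on that transcript.
    """

    ID_COLS = ("subject_id", "group", "timepoint")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.ID_COLS if c not in df.columns]
        if missing:
            raise ValueError(f"dataset missing required columns: {missing}")
        self.df = df.reset_index(drop=True).copy()
        self.df["subject_id"] = self.df["subject_id"].astype(str)
        dup = self.df.duplicated(subset=["subject_id", "timepoint"])
        if dup.any():
            rows = self.df.loc[dup, ["subject_id", "timepoint"]].iloc[0]
            raise ValueError(
                f"duplicate row for subject {rows['subject_id']!r} at {rows['timepoint']!r}"
            )
        bad_tp = set(self.df["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise ValueError(f"unknown timepoints {sorted(bad_tp)}; expected {TIMEPOINTS}")
        base = set(self.df.loc[self.df.timepoint == "baseline", "subject_id"])
        fup = set(self.df.loc[self.df.timepoint == "followup", "subject_id"])
        orphans = fup - base
        if orphans:
            raise ValueError(f"followup rows without baseline: {sorted(orphans)[:5]}")

    @classmethod
    def from_features(
        cls, features: list[FeatureVector], design_rows: list[dict]
    ) -> "CohortDataset":
        """Join extracted feature vectors with a cohort design table on
        (subject_id, timepoint)."""
        feat_df = pd.DataFrame(
            [{"subject_id": f.subject_id, "timepoint": f.timepoint, **f.values} for f in features]
        )
        design_df = pd.DataFrame(design_rows)
        design_df["subject_id"] = design_df["subject_id"].astype(str)
        df = feat_df.merge(design_df, on=["subject_id", "timepoint"], how="inner")
        return cls(df)

    @property
    def groups(self) -> list[str]:
        return sorted(self.df["group"].unique())

    @property
    def feature_names(self) -> list[str]:
        return [f for f in FEATURE_NAMES if f in self.df.columns]

    @property
    def covariate_names(self) -> list[str]:
        skip = set(self.ID_COLS) | set(FEATURE_NAMES)
        return [
            c
            for c in self.df.columns
            if c not in skip and pd.api.types.is_numeric_dtype(self.df[c])
        ]

    def values(self, column: str, group: str, timepoint: str) -> np.ndarray:
        sub = self.df[(self.df.group == group) & (self.df.timepoint == timepoint)]
        return sub[column].to_numpy(dtype=float)

    def paired_changes(self, column: str, group: str) -> pd.Series:
        """followup − baseline per subject, NaN-complete pairs only,
        indexed by subject_id in sorted order."""
        sub = self.df[self.df.group == group]
        wide = sub.pivot(index="subject_id", columns="timepoint", values=column)
        if "baseline" not in wide.columns or "followup" not in wide.columns:
            return pd.Series(dtype=float)
        wide = wide.dropna()
        return (wide["followup"] - wide["baseline"]).sort_index()


# ---------------------------------------------------------------------------
# elementary operations


@dataclass(frozen=True)
class GateResult:
    normal: bool
    statistic: float | None
    p_value: float | None
    n: int
    method: str
    note: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


def normality_gate(values, alpha: float = 0.05, method: str = "lilliefors") -> GateResult:
    """Treat-as-normal decision for one sample.

    Lilliefors-corrected KS by default; ``method="ks"`` uses the plain KS
    test with sample-estimated parameters; ``method="nonparametric"``
    always fails the gate, forcing rank-based tests throughout.
    Degenerate samples (n < 4 or zero SD) route to the nonparametric
    branch.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    n = len(x)
    if method == "nonparametric":
        return GateResult(False, None, None, n, method, "forced nonparametric")
    if n < 4:
        warnings.warn(f"normality gate: n={n} < 4, using nonparametric branch")
        return GateResult(False, None, None, n, method, "n < 4")
    if np.std(x) == 0:
        return GateResult(False, None, None, n, method, "zero variance")
    if method == "lilliefors":
        stat, p = lilliefors(x, dist="norm", pvalmethod="table")
    elif method == "ks":
        stat, p = sps.kstest(x, "norm", args=(float(np.mean(x)), float(np.std(x, ddof=1))))
    else:
        raise ValueError(f"unknown normality method {method!r}")
    return GateResult(bool(p >= alpha), float(stat), float(p), n, method)


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Familywise-adjusted per-test threshold alpha/m."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


@dataclass
class PairwiseResult:
    group_a: str
    group_b: str
    test: str
    statistic: float
    p_value: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CrossSectionalResult:
    feature: str
    timepoint: str
    test: str  # "anova" | "kruskal" | "excluded"
    statistic: float | None
    p_value: float | None
    groups: dict
    gates: dict
    pairwise: list
    excluded: dict
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "timepoint": self.timepoint,
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "groups": self.groups,
            "gates": {k: v.to_dict() for k, v in self.gates.items()},
            "pairwise": [p.to_dict() for p in self.pairwise],
            "excluded": self.excluded,
            "note": self.note,
        }


def cross_sectional(
    dataset: CohortDataset,
    feature: str,
    timepoint: str = "baseline",
    alpha: float = 0.05,
    normality_method: str = "lilliefors",
) -> CrossSectionalResult:
    """Omnibus group comparison with protected post hocs.

    All groups normal → one-way ANOVA; pairwise Fisher LSD t-tests with
    the pooled within-group mean square, reported only when the omnibus
    rejects at ``alpha``.  Any group non-normal → Kruskal–Wallis with
    pairwise two-sided Mann–Whitney U under the same omnibus protection.
    Raw pairwise p-values are returned; familywise thresholds are applied
    at reporting time.
    """
    samples: dict[str, np.ndarray] = {}
    excluded: dict[str, str] = {}
    for g in dataset.groups:
        x = dataset.values(feature, g, timepoint)
        x = x[~np.isnan(x)]
        if len(x) < 2:
            excluded[g] = f"fewer than 2 observations (n={len(x)})"
        else:
            samples[g] = x
    if len(samples) < 2:
        return CrossSectionalResult(
            feature, timepoint, "excluded", None, None, {}, {}, [], excluded,
            "fewer than 2 usable groups",
        )
    labels = sorted(samples)
    gates = {g: normality_gate(samples[g], alpha, normality_method) for g in labels}
    parametric = all(gates[g].normal for g in labels)
    groups_summary = {
        g: {"n": int(len(samples[g])), "mean": float(np.mean(samples[g])),
            "median": float(np.median(samples[g]))}
        for g in labels
    }
    arrays = [samples[g] for g in labels]
    pairwise: list[PairwiseResult] = []
    if parametric:
        fstat, p = sps.f_oneway(*arrays)
        test = "anova"
        if p < alpha:
            n_tot = sum(len(a) for a in arrays)
            k = len(arrays)
            mse = sum(np.sum((a - a.mean()) ** 2) for a in arrays) / (n_tot - k)
            df = n_tot - k
            for i in range(k):
                for j in range(i + 1, k):
                    a, b = arrays[i], arrays[j]
                    se = math.sqrt(mse * (1 / len(a) + 1 / len(b)))
                    t = (a.mean() - b.mean()) / se if se > 0 else 0.0
                    pp = 2 * sps.t.sf(abs(t), df)
                    pairwise.append(
                        PairwiseResult(labels[i], labels[j], "fisher_lsd", float(t), float(pp))
                    )
        stat, pval = float(fstat), float(p)
    else:
        hstat, p = sps.kruskal(*arrays)
        test = "kruskal"
        if p < alpha:
            for i in range(len(labels)):
                for j in range(i + 1, len(labels)):
                    u, pp = sps.mannwhitneyu(
                        arrays[i], arrays[j], alternative="two-sided"
                    )
                    pairwise.append(
                        PairwiseResult(labels[i], labels[j], "mannwhitneyu", float(u), float(pp))
                    )
        stat, pval = float(hstat), float(p)
    note = "" if pairwise else "post hoc withheld (omnibus not significant)"
    return CrossSectionalResult(
        feature, timepoint, test, stat, pval, groups_summary, gates, pairwise, excluded, note
    )


@dataclass
class PairedResult:
    feature: str
    group: str
    test: str  # "paired_t" | "wilcoxon" | "no_evidence" | "excluded"
    statistic: float | None
    p_value: float | None
    n: int
    mean_change: float | None
    median_change: float | None
    gate: GateResult | None
    note: str = ""

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "gate"}
        d["gate"] = self.gate.to_dict() if self.gate is not None else None
        return d


def longitudinal_change(
    dataset: CohortDataset,
    feature: str,
    group: str,
    alpha: float = 0.05,
    normality_method: str = "lilliefors",
) -> PairedResult:
    """Paired baseline→followup change test within one group.

    Change = followup − baseline per subject.  Differences gated for
    normality: paired t when normal, Wilcoxon signed-rank otherwise
    (zero differences dropped, exact p for n ≤ 25 after dropping, normal
    approximation with continuity correction above).  All-zero
    differences are reported as explicit no-evidence, not as a test.
    """
    diffs = dataset.paired_changes(feature, group).to_numpy(dtype=float)
    n = len(diffs)
    if n < 4:
        return PairedResult(
            feature, group, "excluded", None, None, n, None, None, None,
            f"fewer than 4 complete pairs (n={n})",
        )
    mean_c = float(np.mean(diffs))
    median_c = float(np.median(diffs))
    if np.all(diffs == 0):
        return PairedResult(
            feature, group, "no_evidence", 0.0, 1.0, n, mean_c, median_c, None,
            "all paired differences are zero",
        )
    gate = normality_gate(diffs, alpha, normality_method)
    if gate.normal:
        t, p = sps.ttest_1samp(diffs, 0.0)
        return PairedResult(feature, group, "paired_t", float(t), float(p), n, mean_c, median_c, gate)
    nz = diffs[diffs != 0]
    # Exact null distribution for small n, unless tied |differences| force
    # the normal approximation (with continuity correction).
    tied = len(np.unique(np.abs(nz))) < len(nz)
    method = "exact" if (len(nz) <= 25 and not tied) else "approx"
    stat, p = sps.wilcoxon(nz, zero_method="wilcox", correction=(method == "approx"), method=method)
    return PairedResult(feature, group, "wilcoxon", float(stat), float(p), n, mean_c, median_c, gate)


@dataclass
class CorrelationResult:
    x_name: str
    y_name: str
    group: str
    test: str  # "pearson" | "spearman" | "excluded"
    r: float | None
    p_value: float | None
    n: int
    note: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


def correlate_changes(
    x_changes,
    y_changes,
    x_name: str = "x",
    y_name: str = "y",
    group: str = "",
    alpha: float = 0.05,
    normality_method: str = "lilliefors",
) -> CorrelationResult:
    """Correlation between two paired change vectors: Pearson when both
    pass the normality gate, Spearman otherwise."""
    x = np.asarray(x_changes, dtype=float)
    y = np.asarray(y_changes, dtype=float)
    if x.shape != y.shape:
        raise ValueError("change vectors must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 5:
        return CorrelationResult(x_name, y_name, group, "excluded", None, None, n,
                                 f"fewer than 5 complete pairs (n={n})")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(x_name, y_name, group, "excluded", None, None, n,
                                 "zero-variance input")
    gx = normality_gate(x, alpha, normality_method)
    gy = normality_gate(y, alpha, normality_method)
    if gx.normal and gy.normal:
        r, p = sps.pearsonr(x, y)
        test = "pearson"
    else:
        r, p = sps.spearmanr(x, y)
        test = "spearman"
    return CorrelationResult(x_name, y_name, group, test, float(r), float(p), n)


# ---------------------------------------------------------------------------
# severity profiles

#: Features where larger values mean *better* performance; their z-scores
#: are sign-flipped so that higher always indicates greater severity.
SEVERITY_FLIP = frozenset({"mlu", "clause_sentence_ratio", "mattr", "content_density"})


def severity_zscores(
    dataset: CohortDataset,
    reference_group: str,
    reference: str = "control_baseline",
    flip: frozenset[str] = SEVERITY_FLIP,
) -> pd.DataFrame:
    """Z-score each feature against a reference distribution and orient
    all axes so higher = greater severity.

    ``reference="control_baseline"`` standardizes against the reference
    group's baseline mean/SD; ``"pooled_baseline"`` uses all groups'
    baseline rows.
    """
    if reference == "control_baseline":
        ref = dataset.df[(dataset.df.group == reference_group)
                         & (dataset.df.timepoint == "baseline")]
    elif reference == "pooled_baseline":
        ref = dataset.df[dataset.df.timepoint == "baseline"]
    else:
        raise ValueError(f"unknown z-score reference {reference!r}")
    out = dataset.df[list(CohortDataset.ID_COLS)].copy()
    for feat in dataset.feature_names:
        mu = ref[feat].mean()
        sd = ref[feat].std(ddof=1)
        z = (dataset.df[feat] - mu) / sd
        out[feat] = -z if feat in flip else z
    return out


# ---------------------------------------------------------------------------
# full pipeline


@dataclass(frozen=True)
class AnalysisConfig:
    alpha: float = 0.05
    family_size: int = 3
    baseline_timepoint: str = "baseline"
    normality_method: str = "lilliefors"
    #: (feature, covariate) pairs to correlate as change–change, per group.
    correlation_pairs: tuple = ()
    correlation_groups: tuple = ()
    zscore_reference: str = "control_baseline"


@dataclass
class AnalysisReport:
    """Machine-readable results of the full procedure.

    Significance is always double-reported: the raw threshold (alpha)
    and the family-adjusted threshold (alpha / family_size), with
    separate flags, because borderline paired changes are interpreted
    differently under the two conventions.
    """

    config: AnalysisConfig
    adjusted_alpha: float
    cross_sectional: dict
    longitudinal: dict
    correlations: list
    flags: dict

    def to_dict(self) -> dict:
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "config": {
                **{k: v for k, v in asdict(self.config).items()},
                "correlation_pairs": [list(p) for p in self.config.correlation_pairs],
                "correlation_groups": list(self.config.correlation_groups),
            },
            "alpha_raw": self.config.alpha,
            "alpha_adjusted": self.adjusted_alpha,
            "cross_sectional": {f: r.to_dict() for f, r in self.cross_sectional.items()},
            "longitudinal": {
                g: {f: r.to_dict() for f, r in by_feat.items()}
                for g, by_feat in self.longitudinal.items()
            },
            "correlations": [c.to_dict() for c in self.correlations],
            "flags": self.flags,
        }

    def summary_tsv(self) -> str:
        """Human-readable flat table: one line per feature × contrast."""
        a, aa = self.config.alpha, self.adjusted_alpha
        lines = ["analysis\tfeature\tcontrast\ttest\tstatistic\tp\talpha_raw\talpha_adjusted"]

        def fmt(x):
            return "" if x is None else (f"{x:.6g}" if isinstance(x, float) else str(x))

        for feat, res in self.cross_sectional.items():
            lines.append(
                f"cross_sectional\t{feat}\tomnibus\t{res.test}\t{fmt(res.statistic)}"
                f"\t{fmt(res.p_value)}\t{a:.4g}\t{aa:.4g}"
            )
            for pw in res.pairwise:
                lines.append(
                    f"cross_sectional\t{feat}\t{pw.group_a}|{pw.group_b}\t{pw.test}"
                    f"\t{fmt(pw.statistic)}\t{fmt(pw.p_value)}\t{a:.4g}\t{aa:.4g}"
                )
        for group, by_feat in self.longitudinal.items():
            for feat, res in by_feat.items():
                lines.append(
                    f"longitudinal\t{feat}\t{group}\t{res.test}\t{fmt(res.statistic)}"
                    f"\t{fmt(res.p_value)}\t{a:.4g}\t{aa:.4g}"
                )
        for c in self.correlations:
            lines.append(
                f"correlation\t{c.x_name}\t{c.group}:{c.y_name}\t{c.test}\t{fmt(c.r)}"
                f"\t{fmt(c.p_value)}\t{a:.4g}\t{aa:.4g}"
            )
        return "\n".join(lines) + "\n"


def run_full_analysis(dataset: CohortDataset, config: AnalysisConfig = AnalysisConfig()) -> AnalysisReport:
    """Cross-sectional baseline comparisons, per-group longitudinal change
    tests, and configured change–change correlations, with Bonferroni
    flags applied within each 3-feature family."""
    adjusted = bonferroni_alpha(config.alpha, config.family_size)
    present = dataset.feature_names
    absent = [f for f in FEATURE_NAMES if f not in present]

    cross: dict[str, CrossSectionalResult] = {}
    for feat in FEATURE_NAMES:
        if feat in absent:
            cross[feat] = CrossSectionalResult(
                feat, config.baseline_timepoint, "excluded", None, None, {}, {}, [],
                {}, "feature column absent from dataset",
            )
        else:
            cross[feat] = cross_sectional(
                dataset, feat, config.baseline_timepoint, config.alpha, config.normality_method
            )

    longitudinal: dict[str, dict] = {}
    for group in dataset.groups:
        by_feat: dict[str, PairedResult] = {}
        for feat in FEATURE_NAMES:
            if feat in absent:
                by_feat[feat] = PairedResult(
                    feat, group, "excluded", None, None, 0, None, None, None,
                    "feature column absent from dataset",
                )
            else:
                by_feat[feat] = longitudinal_change(
                    dataset, feat, group, config.alpha, config.normality_method
                )
        longitudinal[group] = by_feat

    correlations: list[CorrelationResult] = []
    corr_groups = config.correlation_groups or tuple(dataset.groups)
    for feat, cov in config.correlation_pairs:
        for group in corr_groups:
            if feat not in dataset.df.columns or cov not in dataset.df.columns:
                correlations.append(
                    CorrelationResult(feat, cov, group, "excluded", None, None, 0,
                                      "column absent from dataset")
                )
                continue
            fx = dataset.paired_changes(feat, group)
            fy = dataset.paired_changes(cov, group)
            common = fx.index.intersection(fy.index)
            correlations.append(
                correlate_changes(
                    fx.loc[common], fy.loc[common], feat, cov, group,
                    config.alpha, config.normality_method,
                )
            )

    flags: dict[str, dict] = {"cross_sectional": {}, "longitudinal": {}}
    for family, feats in FEATURE_FAMILIES.items():
        for feat in feats:
            res = cross[feat]
            flags["cross_sectional"][feat] = {
                "family": family,
                "significant_raw": bool(res.p_value is not None and res.p_value < config.alpha),
                "significant_adjusted": bool(res.p_value is not None and res.p_value < adjusted),
            }
    for group, by_feat in longitudinal.items():
        flags["longitudinal"][group] = {}
        for family, feats in FEATURE_FAMILIES.items():
            for feat in feats:
                res = by_feat[feat]
                flags["longitudinal"][group][feat] = {
                    "family": family,
                    "significant_raw": bool(res.p_value is not None and res.p_value < config.alpha),
                    "significant_adjusted": bool(res.p_value is not None and res.p_value < adjusted),
                }

    return AnalysisReport(config, adjusted, cross, longitudinal, correlations, flags)
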