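"""Patient-level keratin analysis of CellSearch CTC cohorts.

The stratification rule: pool every CTC keratin value across the cohort,
take the median, call a CTC "high" when its value lies strictly above that
median, and call a patient "high keratin" (HK) when more than 50% of their
CTCs are high, otherwise "low keratin" (LK). The two strata are then compared
on tumor characteristics (two-sample t-test on pooled per-CTC keratin,
chi-squared association of HK/LK with binary covariates) and on overall
survival (Kaplan-Meier 1-year OS per stratum with a log-rank test).

A patient with exactly 50% high CTCs is LK: "high" requires a strict
majority, which makes HK/LK a partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .records import CtcemtError, PatientRecord


class CohortError(CtcemtError):
    pass


def pooled_median(patients: list[PatientRecord]) -> float:
    """Median over the pooled multiset of all patients' CTC keratin values."""
    pool = np.concatenate([p.ctc_keratin_values for p in patients]) if patients else []
    if len(pool) == 0:
        raise CohortError("no CTC keratin values in the cohort")
    return float(np.median(pool))


def label_patients(
    patients: list[PatientRecord], median: float
) -> list[PatientRecord]:
    """Assign HK/LK labels in place (and return the list).

    A CTC is high iff its keratin value is strictly above the pooled median
    (a value equal to the median is not high); a patient is HK iff more than
    half of their CTCs are high.
    """
    for p in patients:
        vals = np.asarray(p.ctc_keratin_values)
        p.fraction_high = float(np.mean(vals > median))
        p.keratin_group = "HK" if p.fraction_high > 0.5 else "LK"
    return patients


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample comparison of pooled per-CTC keratin values."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t_statistic: float
    p_value: float
    variance_f: float
    variance_p: float

    @property
    def mean_difference(self) -> float:
        return self.mean_a - self.mean_b


def compare_keratin_by_group(
    patients: list[PatientRecord], grouping: str = "triple_negative"
) -> GroupComparison:
    """t-test of pooled per-CTC keratin between two patient strata.

    ``grouping`` is a binary patient covariate: ``triple_negative`` or one of
    ``er_status`` / ``pr_status`` / ``her2_status`` (positive vs negative;
    unknowns excluded listwise). CTC values are pooled across patients within
    each stratum. An F-test of equal variances is reported alongside, and the
    t-test uses the pooled-variance form (matching the equal-variance check).
    """
    group_a, group_b = [], []
    for p in patients:
        side = _covariate_side(p, grouping)
        if side is None:
            continue
        (group_a if side else group_b).append(p)
    a = np.concatenate([p.ctc_keratin_values for p in group_a]) if group_a else np.array([])
    b = np.concatenate([p.ctc_keratin_values for p in group_b]) if group_b else np.array([])
    if a.size < 2 or b.size < 2:
        raise CohortError(f"grouping {grouping!r}: each stratum needs >=2 CTC values")
    var_a, var_b = a.var(ddof=1), b.var(ddof=1)
    if var_a == 0 and var_b == 0:
        # degenerate: no within-group variability
        same = a.mean() == b.mean()
        t_stat, t_p = (0.0, 1.0) if same else (np.inf, 0.0)
    else:
        t_res = stats.ttest_ind(a, b, equal_var=True)
        t_stat, t_p = float(t_res.statistic), float(t_res.pvalue)
    if var_b == 0 and var_a == 0:
        f_stat, f_p = 1.0, 1.0
    else:
        hi, lo = (var_a, var_b) if var_a >= var_b else (var_b, var_a)
        dfn, dfd = (a.size - 1, b.size - 1) if var_a >= var_b else (b.size - 1, a.size - 1)
        f_stat = hi / lo if lo > 0 else np.inf
        f_p = min(2.0 * stats.f.sf(f_stat, dfn, dfd), 1.0)
    names = _covariate_names(grouping)
    return GroupComparison(
        group_a=names[0],
        group_b=names[1],
        n_a=int(a.size),
        n_b=int(b.size),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        t_statistic=t_stat,
        p_value=t_p,
        variance_f=float(f_stat),
        variance_p=float(f_p),
    )


def _covariate_side(p: PatientRecord, grouping: str) -> bool | None:
    """True for the covariate-positive side, None when unknown (excluded)."""
    if grouping == "triple_negative":
        return p.triple_negative
    if grouping in ("er_status", "pr_status", "her2_status"):
        status = getattr(p, grouping)
        if status == "unknown":
            return None
        return status == "negative"  # the "-negative" stratum is the exposure
    raise CohortError(f"unknown grouping {grouping!r}")


def _covariate_names(grouping: str) -> tuple[str, str]:
    if grouping == "triple_negative":
        return "triple_negative", "other"
    marker = grouping.split("_")[0].upper()
    return f"{marker}-negative", f"{marker}-positive"


@dataclass(frozen=True)
class Association:
    """Chi-squared association of the HK/LK label with a binary covariate."""

    covariate: str
    table: tuple[tuple[int, int], tuple[int, int]]  # rows LK/HK x cols pos/neg
    chi2: float
    p_value: float
    lk_fraction_in_positive: float
    n_excluded_unknown: int


def associate_group_with_covariate(
    patients: list[PatientRecord], covariate: str = "triple_negative"
) -> Association:
    """2x2 Pearson chi-squared of keratin group vs a binary patient covariate.

    Rows are LK/HK, columns covariate-positive/-negative (for receptor
    covariates, "positive" means the marker-negative exposure stratum, e.g.
    ER-negative). Also reports the LK percentage within the exposed stratum.
    """
    if any(p.keratin_group is None for p in patients):
        raise CohortError("patients must be labeled (label_patients) first")
    lk_pos = hk_pos = lk_neg = hk_neg = 0
    excluded = 0
    for p in patients:
        side = _covariate_side(p, covariate)
        if side is None:
            excluded += 1
            continue
        if p.keratin_group == "LK":
            lk_pos, lk_neg = lk_pos + side, lk_neg + (not side)
        else:
            hk_pos, hk_neg = hk_pos + side, hk_neg + (not side)
    table = np.array([[lk_pos, lk_neg], [hk_pos, hk_neg]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise CohortError(f"degenerate 2x2 table for {covariate!r}: {table.tolist()}")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return Association(
        covariate=covariate,
        table=((lk_pos, lk_neg), (hk_pos, hk_neg)),
        chi2=float(chi2),
        p_value=float(p),
        lk_fraction_in_positive=lk_pos / (lk_pos + hk_pos),
        n_excluded_unknown=excluded,
    )


@dataclass(frozen=True)
class SurvivalSummary:
    """Per-stratum Kaplan-Meier 1-year overall survival with log-rank test."""

    horizon_months: float
    survival: dict[str, float]  # group -> S(horizon)
    std_err: dict[str, float]  # Greenwood SE of S(horizon)
    n_per_group: dict[str, int]
    logrank_p: float


def _km_at(times: np.ndarray, events: np.ndarray, horizon: float) -> tuple[float, float]:
    kmf = KaplanMeierFitter().fit(times, events)
    s = float(kmf.predict(horizon))
    # Greenwood variance from the event table
    et = kmf.event_table
    mask = et.index <= horizon
    d = et.loc[mask, "observed"].to_numpy(dtype=float)
    n = et.loc[mask, "at_risk"].to_numpy(dtype=float)
    keep = (d > 0) & (n > d)
    var = s**2 * np.sum(d[keep] / (n[keep] * (n[keep] - d[keep])))
    return s, float(np.sqrt(var))


def one_year_os(
    patients: list[PatientRecord], horizon_months: float = 12.0
) -> SurvivalSummary:
    """Kaplan-Meier S(12 months) per keratin group plus a log-rank comparison."""
    if any(p.keratin_group is None for p in patients):
        raise CohortError("patients must be labeled (label_patients) first")
    groups = {g: [p for p in patients if p.keratin_group == g] for g in ("HK", "LK")}
    if any(not members for members in groups.values()):
        raise CohortError("both HK and LK groups must be non-empty")
    surv, se, n_per = {}, {}, {}
    for g, members in groups.items():
        t = np.array([p.os_months for p in members])
        e = np.array([p.os_event for p in members])
        surv[g], se[g] = _km_at(t, e, horizon_months)
        n_per[g] = len(members)
    lr = logrank_test(
        np.array([p.os_months for p in groups["HK"]]),
        np.array([p.os_months for p in groups["LK"]]),
        event_observed_A=np.array([p.os_event for p in groups["HK"]]),
        event_observed_B=np.array([p.os_event for p in groups["LK"]]),
    )
    return SurvivalSummary(
        horizon_months=horizon_months,
        survival=surv,
        std_err=se,
        n_per_group=n_per,
        logrank_p=float(lr.p_value),
    )


@dataclass(frozen=True)
class MultiGroupComparison:
    """Kruskal-Wallis omnibus with Dunn's pairwise post test."""

    h_statistic: float
    p_value: float
    group_names: tuple[str, ...]
    dunn_z: dict[tuple[str, str], float]
    dunn_p: dict[tuple[str, str], float]  # Bonferroni-adjusted


def compare_cell_populations(
    groups: dict[str, list[float] | np.ndarray],
) -> MultiGroupComparison:
    """Compare >=3 cell populations: Kruskal-Wallis H plus Dunn's post test.

    Dunn's pairwise z statistics use mean ranks of the pooled sample with the
    tie-corrected variance ``(N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j)`` where
    ``T = sum(t^3 - t)`` over tie groups; two-sided normal p-values are
    Bonferroni-adjusted over all pairs.
    """
    if len(groups) < 3:
        raise CohortError("need >=3 groups (use the t-test path for 2)")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if any(a.size < 2 for a in arrays.values()):
        raise CohortError("each group needs >=2 values")
    h, p = stats.kruskal(*arrays.values())
    names = tuple(arrays)
    pooled = np.concatenate(list(arrays.values()))
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    mean_ranks, sizes = {}, {}
    start = 0
    for name, a in arrays.items():
        mean_ranks[name] = float(ranks[start : start + a.size].mean())
        sizes[name] = a.size
        start += a.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    n_pairs = len(names) * (len(names) - 1) // 2
    dunn_z, dunn_p = {}, {}
    for i, gi in enumerate(names):
        for gj in names[i + 1 :]:
            sd = np.sqrt(base_var * (1.0 / sizes[gi] + 1.0 / sizes[gj]))
            z = (mean_ranks[gi] - mean_ranks[gj]) / sd if sd > 0 else 0.0
            dunn_z[(gi, gj)] = float(z)
            dunn_p[(gi, gj)] = float(min(2.0 * stats.norm.sf(abs(z)) * n_pairs, 1.0))
    return MultiGroupComparison(
        h_statistic=float(h),
        p_value=float(p),
        group_names=names,
        dunn_z=dunn_z,
        dunn_p=dunn_p,
    )


@dataclass(frozen=True)
class CohortResult:
    """Bundle of the standard HK/LK cohort analysis outputs."""

    pooled_median_keratin: float
    n_hk: int
    n_lk: int
    keratin_by_tn: GroupComparison
    tn_association: Association
    survival: SurvivalSummary


def analyze_cohort(patients: list[PatientRecord]) -> CohortResult:
    """End-to-end HK/LK analysis: median split, TN comparison, survival."""
    med = pooled_median(patients)
    label_patients(patients, med)
    return CohortResult(
        pooled_median_keratin=med,
        n_hk=sum(p.keratin_group == "HK" for p in patients),
        n_lk=sum(p.keratin_group == "LK" for p in patients),
        keratin_by_tn=compare_keratin_by_group(patients, "triple_negative"),
        tn_association=associate_group_with_covariate(patients, "triple_negative"),
        survival=one_year_os(patients),
    )
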