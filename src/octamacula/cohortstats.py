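"""Cohort-level statistics for paired treated/fellow-eye designs.

Eyes are clustered within patients (typically one treated and one fellow
eye each), so naive per-eye tests are anticonservative.  Group contrasts
are therefore assessed with a patient-clustered bootstrap: patients are
resampled with replacement and both of a patient's eyes move together,
preserving the inter-eye correlation.  Rank statistics (Spearman) and
ROC/AUC for burnout prediction complete the layer.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage.morphology import closing as _closing, disk

from octamacula.types import VesselMap

logger = logging.getLogger(__name__)

METRIC_COLUMNS = [
    "vad_foveal_scp", "vad_parafoveal_scp", "vsd_foveal_scp", "vsd_parafoveal_scp",
    "vad_foveal_dcp", "vad_parafoveal_dcp", "vsd_foveal_dcp", "vsd_parafoveal_dcp",
    "faz_scp_mm2", "faz_dcp_mm2",
]


@dataclass
class GroupComparison:
    """Difference of group means with clustered-bootstrap uncertainty."""

    metric: str
    group_a: str
    group_b: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    difference: float  # mean_a - mean_b
    ci95: tuple[float, float]
    p_value: float
    n_boot: int


@dataclass
class RocResult:
    """ROC curve and AUC of one predictor for a binary outcome."""

    predictor: str
    auc: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray


def nonperfused_area_mm2(
    vessel_map: VesselMap, closing_radius_px: int = 3
) -> float:
    """Nonperfused area (mm^2) within the central 3-mm disc.

    The vessel map is morphologically closed so normal inter-capillary
    spacing does not count as nonperfusion; what remains background
    inside the 3-mm circle is ischemic area.
    """
    closed = _closing(vessel_map.pixels, disk(closing_radius_px))
    side = vessel_map.side_px
    rr, cc = np.mgrid[0:side, 0:side]
    c = (side - 1) / 2.0
    disc3 = np.hypot(rr - c, cc - c) * vessel_map.mm_per_px <= 1.5
    return float((disc3 & ~closed).sum()) * vessel_map.px_area_mm2


def classify_burnout(
    vessel_map: VesselMap,
    threshold_mm2: float = 6.0,
    closing_radius_px: int = 3,
) -> bool:
    """Burnout macula: nonperfused area in the 3-mm disc above threshold.

    The default 6 mm^2 is ~85% of the 3-mm disc area (pi * 1.5^2 ~= 7.07
    mm^2), i.e. near-total loss of capillary detail.
    """
    return nonperfused_area_mm2(vessel_map, closing_radius_px) > threshold_mm2


def _group_selector(table: pd.DataFrame, group: str) -> pd.Series:
    if group == "treated":
        return table["treated"].astype(bool)
    if group in ("fellow", "control", "fellow_control"):
        if "group" in table.columns and (table["group"] == "fellow_control").any():
            return table["group"] == "fellow_control"
        return ~table["treated"].astype(bool)
    if "group" in table.columns and (table["group"] == group).any():
        return table["group"] == group
    raise ValueError(f"unknown group {group!r}")


def compare_groups(
    table: pd.DataFrame,
    metric: str,
    group_a: str,
    group_b: str,
    n_boot: int = 2000,
    seed: int = 0,
) -> GroupComparison:
    """Patient-clustered bootstrap comparison of group means.

    Patients (not eyes) are resampled with replacement; each bootstrap
    replicate recomputes both group means from the resampled patients'
    eyes, which preserves the paired-eye correlation structure.  The CI
    is the 2.5-97.5 percentile interval and the two-sided p-value is the
    (add-one corrected) fraction of bootstrap differences on the far side
    of zero, doubled.
    """
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000 for stable tails")
    # eyes without a measurable value (e.g. FAZ not found on burnout eyes)
    # drop out of this metric's comparison
    table = table[np.isfinite(table[metric].astype(float))]
    sel_a = _group_selector(table, group_a)
    sel_b = _group_selector(table, group_b)
    va = table.loc[sel_a, metric].to_numpy(float)
    vb = table.loc[sel_b, metric].to_numpy(float)
    patients = pd.unique(table["patient_id"])
    for sel, name in ((sel_a, group_a), (sel_b, group_b)):
        if table.loc[sel, "patient_id"].nunique() < 2:
            raise ValueError(f"group {name!r} has fewer than 2 patients")
    pid_index = pd.Series(np.arange(len(patients)), index=patients)
    npat = len(patients)

    def _per_patient(sel: pd.Series) -> tuple[np.ndarray, np.ndarray]:
        sums = np.zeros(npat)
        counts = np.zeros(npat)
        sub = table.loc[sel]
        idx = pid_index[sub["patient_id"]].to_numpy()
        np.add.at(sums, idx, sub[metric].to_numpy(float))
        np.add.at(counts, idx, 1.0)
        return sums, counts

    sa, ca = _per_patient(sel_a)
    sb, cb = _per_patient(sel_b)
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, npat, size=(n_boot, npat))
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_a_star = sa[draws].sum(axis=1) / ca[draws].sum(axis=1)
        mean_b_star = sb[draws].sum(axis=1) / cb[draws].sum(axis=1)
    diff_star = mean_a_star - mean_b_star
    diff_star = diff_star[np.isfinite(diff_star)]
    diff = float(va.mean() - vb.mean())
    lo, hi = np.percentile(diff_star, [2.5, 97.5])
    b = len(diff_star)
    p = 2.0 * min(
        (1 + np.sum(diff_star <= 0)) / (b + 1),
        (1 + np.sum(diff_star >= 0)) / (b + 1),
    )
    return GroupComparison(
        metric=metric,
        group_a=group_a,
        group_b=group_b,
        mean_a=float(va.mean()),
        sd_a=float(va.std(ddof=1)),
        mean_b=float(vb.mean()),
        sd_b=float(vb.std(ddof=1)),
        difference=diff,
        ci95=(float(lo), float(hi)),
        p_value=float(min(p, 1.0)),
        n_boot=int(b),
    )


def _rank(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v, method="average")


def spearman_corr(
    x, y, n_perm: int = 10_000, seed: int = 0
) -> tuple[float, float]:
    """Spearman rank correlation with an exact/permutation/asymptotic p.

    rho is the Pearson correlation of average ranks.  The p-value is
    computed by exhaustive permutation for n <= 7, by ``n_perm`` random
    permutations for 7 < n < 30, and from the asymptotic t reference
    otherwise.  Constant inputs have undefined rho and raise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-D vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman rho undefined for a constant vector")
    rx, ry = _rank(x), _rank(y)
    n = len(x)

    def _rho(a: np.ndarray, b: np.ndarray) -> float:
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / math.sqrt((a @ a) * (b @ b)))

    rho = _rho(rx, ry)
    tol = 1e-12
    if n <= 7:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = _rho(rx, ry[list(perm)])
            count += abs(r) >= abs(rho) - tol
            total += 1
        p = count / total
    elif n < 30:
        rng = np.random.default_rng(seed)
        count = 1
        for _ in range(n_perm):
            r = _rho(rx, ry[rng.permutation(n)])
            count += abs(r) >= abs(rho) - tol
        p = count / (n_perm + 1)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1 - rho**2))
            p = 2 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(min(p, 1.0))


def roc_auc(labels, scores, predictor: str = "") -> RocResult:
    """ROC curve and AUC via the normalized Mann-Whitney U statistic.

    AUC = P(score_pos > score_neg) + 0.5 P(tie), computed from average
    ranks; the sensitivity/specificity grid uses the rule
    ``positive iff score >= threshold`` over all unique scores.
    """
    y = np.asarray(labels).astype(bool)
    s = np.asarray(scores, float)
    if y.shape != s.shape or y.ndim != 1:
        raise ValueError("labels and scores must be equal-length 1-D vectors")
    n1 = int(y.sum())
    n0 = int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present for ROC analysis")
    ranks = _rank(s)
    auc = (ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    thr = np.unique(s)[::-1]
    sens = np.array([(s[y] >= t).mean() for t in thr])
    spec = np.array([(s[~y] < t).mean() for t in thr])
    return RocResult(
        predictor=predictor,
        auc=float(auc),
        thresholds=thr,
        sensitivity=sens,
        specificity=spec,
    )


@dataclass
class CohortReport:
    """Tables produced by :func:`run_cohort_analysis`."""

    comparisons: pd.DataFrame
    spearman: pd.DataFrame
    roc: pd.DataFrame
    seed: int

    def summary(self) -> str:
        lines = ["Cohort analysis summary", "=" * 40]
        lines.append(f"bootstrap seed: {self.seed}")
        lines.append("\nGroup comparisons (clustered bootstrap):")
        for _, r in self.comparisons.iterrows():
            lines.append(
                f"  {r['metric']:>22s} {r['group_a']} vs {r['group_b']}: "
                f"diff={r['difference']:+.4f} "
                f"CI95=({r['ci_lo']:+.4f}, {r['ci_hi']:+.4f}) p={r['p_value']:.4f}"
            )
        lines.append("\nSpearman correlations:")
        for _, r in self.spearman.iterrows():
            lines.append(
                f"  {r['x']:>16s} vs {r['y']:<22s} rho={r['rho']:+.3f} p={r['p']:.4f}"
            )
        lines.append("\nROC for burnout prediction:")
        for _, r in self.roc.iterrows():
            lines.append(f"  {r['predictor']:>22s} AUC={r['auc']:.3f}")
        return "\n".join(lines)


def run_cohort_analysis(
    table: pd.DataFrame,
    n_boot: int = 2000,
    seed: int = 0,
    metrics: list[str] | None = None,
) -> CohortReport:
    """Full statistical layer on a per-eye cohort table.

    Emits treated-vs-fellow contrasts for every metric, subgroup contrasts
    (RM and no-RM treated eyes vs fellow eyes), the Spearman matrix of
    dose/FAZ/BCVA/density among treated eyes, and per-predictor ROC for
    the burnout outcome.  Deterministic given ``seed``.
    """
    metrics = metrics or [m for m in METRIC_COLUMNS if m in table.columns]
    rng = np.random.default_rng(seed)
    rows = []
    pairs = [("treated", "fellow")]
    for g in ("treated_RM", "treated_noRM"):
        if "group" in table.columns and (table["group"] == g).sum() >= 2:
            pairs.append((g, "fellow"))
    for ga, gb in pairs:
        for m in metrics:
            try:
                c = compare_groups(table, m, ga, gb, n_boot, int(rng.integers(2**31)))
            except ValueError:
                continue
            rows.append(
                dict(metric=m, group_a=ga, group_b=gb, mean_a=c.mean_a, sd_a=c.sd_a,
                     mean_b=c.mean_b, sd_b=c.sd_b, difference=c.difference,
                     ci_lo=c.ci95[0], ci_hi=c.ci95[1], p_value=c.p_value)
            )
    comparisons = pd.DataFrame(rows)

    treated = table[table["treated"].astype(bool)]
    sp_rows = []
    predictors = [c for c in ("foveal_dose_gy", "disc_dose_gy", "interval_months", "bcva_logmar") if c in treated.columns]
    for xcol in predictors:
        for ycol in metrics:
            x = treated[xcol].to_numpy(float)
            yv = treated[ycol].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(yv)
            if ok.sum() < 3 or np.all(x[ok] == x[ok][0]) or np.all(yv[ok] == yv[ok][0]):
                continue
            rho, p = spearman_corr(x[ok], yv[ok], seed=int(rng.integers(2**31)))
            sp_rows.append(dict(x=xcol, y=ycol, rho=rho, p=p, n=int(ok.sum())))
    spearman = pd.DataFrame(sp_rows)

    roc_rows = []
    if "burnout" in treated.columns and treated["burnout"].nunique() == 2:
        for pred in ("foveal_dose_gy", "disc_dose_gy", "interval_months"):
            if pred not in treated.columns:
                continue
            vals = treated[pred].to_numpy(float)
            ok = np.isfinite(vals)
            if treated.loc[ok, "burnout"].nunique() < 2:
                continue
            r = roc_auc(treated.loc[ok, "burnout"].to_numpy(), vals[ok], pred)
            roc_rows.append(dict(predictor=pred, auc=r.auc))
    roc = pd.DataFrame(roc_rows)
    return CohortReport(comparisons=comparisons, spearman=spearman, roc=roc, seed=seed)
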