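"""Inter-rater and human-vs-model agreement statistics.

Continuous TSR estimates are compared with the two-way, absolute-agreement,
single-measurement intraclass correlation coefficient (McGraw-Wong A,1;
the "mixed vs random" effects distinction changes interpretation, not the
point estimate). Categorized TSR values are compared with Cohen's kappa.
Deviation summaries and the quality-vs-deviation A-D categorization relate
segmentation-quality grades to TSR discrepancies.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class RaterTable:
    """TSR percent per ROI (rows) and observer (columns)."""
    values: pd.DataFrame                       # index roi_id, columns obs id
    groups: dict = field(default_factory=dict)  # observer -> group tag

    def __post_init__(self):
        v = self.values.to_numpy(dtype=float)
        if np.isnan(v).any():
            raise ValueError("rater table has missing cells")
        if v.size and (v.min() < 0 or v.max() > 100):
            raise ValueError("TSR estimates must lie in [0, 100]")

    @property
    def n_rois(self) -> int:
        return len(self.values.index)

    @property
    def observers(self) -> list:
        return list(self.values.columns)

    def subset(self, observers) -> "RaterTable":
        return RaterTable(self.values[list(observers)],
                          {o: self.groups.get(o, "observer")
                           for o in observers})

    def to_long(self) -> pd.DataFrame:
        long = self.values.reset_index().melt(
            id_vars=self.values.index.name or "index",
            var_name="observer_id", value_name="tsr_percent")
        long = long.rename(columns={self.values.index.name or "index":
                                    "roi_id"})
        long["group"] = long["observer_id"].map(
            lambda o: self.groups.get(o, "observer"))
        return long[["roi_id", "observer_id", "group", "tsr_percent"]]

    def to_csv(self, path) -> None:
        self.to_long().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RaterTable":
        long = pd.read_csv(path)
        wide = long.pivot(index="roi_id", columns="observer_id",
                          values="tsr_percent")
        groups = (long.drop_duplicates("observer_id")
                  .set_index("observer_id")["group"].to_dict()
                  if "group" in long.columns else {})
        return cls(wide, groups)


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    n_subjects: int
    n_raters: int


@dataclass(frozen=True)
class QualityRecord:
    roi_id: object
    quality: float                      # mean of two graders' 1-10 integers
    deviations_pp: dict                 # observer -> (AI TSR - observer TSR)

    def __post_init__(self):
        if not 1.0 <= self.quality <= 10.0:
            raise ValueError("quality must lie in [1, 10]")


def _anova_mean_squares(x: np.ndarray):
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_means - grand) ** 2).sum() / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    mse = (resid ** 2).sum() / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_a1(table: RaterTable, alpha: float = 0.05) -> ICCResult:
    """Two-way absolute-agreement single-measure ICC with a 95% CI.

    The CI uses the standard F-distribution construction with a
    Satterthwaite degrees-of-freedom approximation for the denominator.
    """
    x = table.values.to_numpy(dtype=float)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("ICC requires at least 2 subjects and 2 raters")
    msr, msc, mse = _anova_mean_squares(x)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        raise ValueError("ICC undefined: zero between-subject variance")
    icc = (msr - mse) / denom

    if np.isclose(mse, 0.0) and np.isclose(msc, 0.0):
        return ICCResult(icc, 1.0, 1.0, n, k)
    a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    if np.isinf(a) or np.isinf(b):
        return ICCResult(icc, 1.0, 1.0, n, k)
    num_v = (a * msc + b * mse) ** 2
    den_v = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num_v / den_v if den_v > 0 else 1.0
    f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
    low = n * (msr - f1 * mse) / (
        f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
    high = n * (f2 * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f2 * msr)
    low, high = float(np.clip(low, -1, 1)), float(np.clip(high, -1, 1))
    return ICCResult(float(icc), min(low, icc), max(high, icc), n, k)


def cohens_kappa(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two categorical raters.

    Degenerate case (chance agreement is 1, i.e. both raters use a single
    category): returns 1.0 under perfect agreement, else 0.0.
    """
    a = list(labels_a)
    b = list(labels_b)
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if not a:
        raise ValueError("empty label lists")
    cats = sorted(set(a) | set(b), key=str)
    idx = {c: i for i, c in enumerate(cats)}
    m = np.zeros((len(cats), len(cats)))
    for x, y in zip(a, b):
        m[idx[x], idx[y]] += 1
    n = m.sum()
    p_o = np.trace(m) / n
    p_e = float((m.sum(axis=1) / n) @ (m.sum(axis=0) / n))
    if np.isclose(p_e, 1.0):
        return 1.0 if np.isclose(p_o, 1.0) else 0.0
    return float((p_o - p_e) / (1 - p_e))


def pairwise_icc(table: RaterTable) -> pd.DataFrame:
    """ICC(A,1) for every observer pair; cells hold ICCResult objects.

    Pairs whose ICC is undefined are flagged with None.
    """
    obs = table.observers
    out = pd.DataFrame(index=obs, columns=obs, dtype=object)
    for i, oa in enumerate(obs):
        for ob in obs[i + 1:]:
            try:
                res = icc_a1(table.subset([oa, ob]))
            except ValueError:
                res = None
            out.loc[oa, ob] = res
            out.loc[ob, oa] = res
    return out


def deviation_summary(ai_tsr: dict, observers: RaterTable,
                      quality: list[QualityRecord],
                      quality_min: float = 9.0) -> dict:
    """Mean (AI - observer) TSR deviation over well-segmented ROIs.

    Only ROIs whose segmentation-quality grade is >= quality_min enter the
    averages; this isolates ROIs where the model's mask is trustworthy so
    that remaining deviations reflect observer bias.
    """
    qual = {q.roi_id: q.quality for q in quality}
    missing = [r for r in observers.values.index if r not in qual
               or r not in ai_tsr]
    if missing:
        raise ValueError(f"ROIs without aligned AI/quality data: {missing}")
    keep = [r for r in observers.values.index if qual[r] >= quality_min]
    if not keep:
        raise ValueError(f"no ROIs with quality >= {quality_min}")
    out = {}
    for obs in observers.observers:
        devs = [ai_tsr[r] - observers.values.loc[r, obs] for r in keep]
        out[obs] = float(np.mean(devs))
    return {"per_observer": out, "n_rois": len(keep),
            "quality_min": quality_min}


def assign_category(deviation_pp: float, quality: float,
                    quality_good: float = 7.0,
                    deviation_large: float = 20.0) -> str:
    """Quality-vs-deviation category for one ROI.

    A: poor segmentation and large TSR deviation (neither source trusted);
    B: good segmentation but large deviation (suggests observer bias);
    C: good segmentation and small deviation (both agree);
    D: poor segmentation yet small deviation (both error-prone).
    """
    if not 1.0 <= quality <= 10.0:
        raise ValueError("quality must lie in [1, 10]")
    big = abs(deviation_pp) >= deviation_large
    good = quality >= quality_good
    if big:
        return "B" if good else "A"
    return "C" if good else "D"
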