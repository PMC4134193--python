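"""Volume quantification and segmentation-agreement statistics.

Agreement between an automated WMH mask and a reference (semi-automated)
mask is summarized per hemisphere by

* SI (similarity index, the Dice coefficient as a percentage),
  2|A∩B| / (|A|+|B|) x 100,
* sensitivity |A∩B|/|B| x 100 and specificity TN/(TN+FP) x 100 over an
  evaluation domain (by default the whole hemisphere, whose size drives
  the near-100% specificities typical of small lesions),
* the volume error ΔVol = (auto - semi)/semi x 100.

Cohort-level agreement uses the intraclass correlation coefficient (all
six McGraw & Wong forms are computed; two-way absolute-agreement
single-measures ICC(A,1) is reported as primary), ordinary least squares
of automated on semi-automated volumes, and Bland-Altman analysis with
differences taken as semi - auto (bias = mean difference, limits of
agreement bias ± 1.96 SD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sstats

from .volumes import BinaryMask, check_same_grid, mask_and

__all__ = [
    "HemisphereRecord",
    "EvaluationReport",
    "volume_ml",
    "delta_vol",
    "overlap_metrics",
    "icc",
    "icc_all_forms",
    "regression_fit",
    "bland_altman",
    "aggregate_cohort",
]

METRIC_COLUMNS = ("semi_auto_ml", "auto_ml", "delta_vol_pct",
                  "si_pct", "sen_pct", "spe_pct")


@dataclass
class HemisphereRecord:
    """Per-hemisphere evaluation row (one line of a cohort table)."""

    patient: str
    side: str                      # "L" or "R"
    group: str                     # "wmh_only" or "wmh_infarct"
    semi_auto_ml: float
    auto_ml: float
    si_pct: float
    sen_pct: float
    spe_pct: float
    delta_vol_pct: float | None = None
    demar: float | None = None     # rater's lowest normalized intensity, 0-1 scale

    def __post_init__(self) -> None:
        if self.semi_auto_ml < 0 or self.auto_ml < 0:
            raise ValueError("volumes must be non-negative")
        if self.delta_vol_pct is None and self.semi_auto_ml > 0:
            self.delta_vol_pct = delta_vol(self.semi_auto_ml, self.auto_ml)


@dataclass
class EvaluationReport:
    """Cohort aggregates in the layout of the per-cohort summary tables."""

    records: pd.DataFrame
    group_stats: pd.DataFrame      # mean/SD per metric per group + overall
    icc_by_group: dict[str, float]
    regression_by_group: dict[str, tuple[float, float, float]]  # slope, intercept, R2
    bland_altman_by_group: dict[str, tuple[float, tuple[float, float]]]

    def to_json_dict(self) -> dict:
        stats_nested: dict = {}
        for (group, stat), row in self.group_stats.iterrows():
            stats_nested.setdefault(group, {})[stat] = row.to_dict()
        return {
            "group_stats": stats_nested,
            "icc": self.icc_by_group,
            "regression": {k: {"slope": v[0], "intercept": v[1], "r2": v[2]}
                           for k, v in self.regression_by_group.items()},
            "bland_altman": {k: {"bias_ml": v[0], "loa_ml": list(v[1])}
                             for k, v in self.bland_altman_by_group.items()},
        }


def volume_ml(m: BinaryMask) -> float:
    """Mask volume in ml: voxel count x dx*dy*dz / 1000.

    The z spacing is the slice pitch (thickness + gap), so each voxel
    accounts for its full z extent.
    """
    dx, dy, dz = m.spacing
    return float(m.n_voxels * dx * dy * dz / 1000.0)


def delta_vol(semi: float, auto: float) -> float:
    """Relative volume error (auto - semi)/semi x 100 (%); semi must be > 0."""
    if semi <= 0:
        raise ValueError("reference volume must be positive")
    return (auto - semi) / semi * 100.0


def overlap_metrics(auto: BinaryMask, ref: BinaryMask,
                    domain: BinaryMask) -> tuple[float, float, float]:
    """(SI %, sensitivity %, specificity %) of auto vs ref over a domain.

    ``domain`` is the evaluation region (typically the hemisphere); the
    true-negative count in specificity is taken over it.  Raises when the
    reference is empty within the domain.
    """
    check_same_grid(auto, ref)
    a = mask_and(auto, domain).data
    b = mask_and(ref, domain).data
    nb = int(b.sum())
    if nb == 0:
        raise ValueError("reference mask is empty within the evaluation domain")
    tp = int((a & b).sum())
    fp = int((a & ~b).sum())
    fn = nb - tp
    tn = int(domain.n_voxels) - tp - fp - fn
    si = 200.0 * tp / (2 * tp + fp + fn)
    sens = 100.0 * tp / nb
    spec = 100.0 * tn / (tn + fp) if (tn + fp) else 100.0
    return si, sens, spec


def _icc_long(pairs: np.ndarray) -> pd.DataFrame:
    n = len(pairs)
    return pd.DataFrame({
        "targets": np.repeat(np.arange(n), 2),
        "raters": ["semi", "auto"] * n,
        "ratings": np.asarray(pairs, dtype=float).ravel(),
    })


def icc_all_forms(pairs) -> pd.DataFrame:
    """All six McGraw & Wong ICC forms for (semi, auto) volume pairs."""
    pairs = np.asarray(pairs, dtype=float)
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs for ICC")
    if np.ptp(pairs.mean(axis=1)) == 0:
        raise ValueError("zero between-subject variance; ICC undefined")
    return pg.intraclass_corr(_icc_long(pairs), targets="targets",
                              raters="raters", ratings="ratings")


def icc(pairs, form: str = "ICC2") -> float:
    """Intraclass correlation; primary form ICC(A,1) (pingouin 'ICC2')."""
    table = icc_all_forms(pairs)
    row = table[table["Type"] == {"ICC1": "ICC(1,1)", "ICC2": "ICC(A,1)",
                                  "ICC3": "ICC(C,1)"}.get(form, form)]
    if row.empty:
        row = table[table["Type"] == form]
    if row.empty:
        raise ValueError(f"unknown ICC form {form!r}")
    return float(row["ICC"].iloc[0])


def regression_fit(pairs) -> tuple[float, float, float]:
    """OLS of automated on semi-automated volume: (slope, intercept, R^2)."""
    pairs = np.asarray(pairs, dtype=float)
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs for regression")
    semi, auto = pairs[:, 0], pairs[:, 1]
    if np.ptp(semi) == 0:
        raise ValueError("degenerate predictor (constant semi-automated volumes)")
    res = sstats.linregress(semi, auto)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def bland_altman(pairs) -> tuple[float, tuple[float, float]]:
    """Bland-Altman bias and 95% limits of agreement.

    Paired differences are taken as semi - auto; bias is their mean and
    the limits of agreement are bias ± 1.96 x SD(differences).
    """
    pairs = np.asarray(pairs, dtype=float)
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    diff = pairs[:, 0] - pairs[:, 1]
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return bias, (bias - 1.96 * sd, bias + 1.96 * sd)


def aggregate_cohort(records: list[HemisphereRecord] | pd.DataFrame) -> EvaluationReport:
    """Cohort summary: per-group and overall mean/SD, ICC, OLS, Bland-Altman.

    SDs are sample (n-1) standard deviations.  Groups are taken from the
    ``group`` column; an ``all`` row aggregates every record.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([r.__dict__ for r in records])
    if df.empty:
        raise ValueError("no records to aggregate")
    cols = [c for c in METRIC_COLUMNS if c in df.columns]
    groups: dict[str, pd.DataFrame] = {"all": df}
    for g, sub in df.groupby("group"):
        groups[str(g)] = sub
    stat_rows = {}
    icc_by, reg_by, ba_by = {}, {}, {}
    for name, sub in groups.items():
        if sub.empty:
            raise ValueError(f"empty group {name!r}")
        stat_rows[(name, "mean")] = sub[cols].mean()
        stat_rows[(name, "sd")] = sub[cols].std(ddof=1).fillna(0.0)
        pairs = sub[["semi_auto_ml", "auto_ml"]].to_numpy()
        if len(pairs) >= 3 and np.ptp(pairs[:, 0]) > 0:
            icc_by[name] = icc(pairs)
            reg_by[name] = regression_fit(pairs)
        if len(pairs) >= 2:
            ba_by[name] = bland_altman(pairs)
    group_stats = pd.DataFrame(stat_rows).T
    group_stats.index = pd.MultiIndex.from_tuples(group_stats.index,
                                                  names=["group", "stat"])
    return EvaluationReport(df, group_stats, icc_by, reg_by, ba_by)
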