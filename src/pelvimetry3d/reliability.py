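"""Accuracy and reliability statistics for landmark labelings and measures.

Implements the study's evaluation framework:

* leave-one-rater-out errors — each rater's landmark (or measure) against
  the mean of the remaining raters;
* errors against the all-rater consensus (used for the automatic method);
* intraclass correlation coefficients, two-way mixed, consistency form
  (Shrout-Fleiss ICC(3,1) and ICC(3,k)), with the standard error of
  measurement SEM = SD * sqrt(1 - ICC) and the usual four-level ICC
  classification;
* Wilcoxon signed-rank tests (exact null by sign-vector enumeration for
  small samples, normal approximation with tie and continuity corrections
  otherwise) and the D'Agostino K² normality pre-test.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "leave_one_out_error",
    "measure_error_loo",
    "error_vs_consensus",
    "relative_error",
    "RaterMatrix",
    "ICCResult",
    "icc",
    "sem",
    "classify_icc",
    "wilcoxon_signed_rank",
    "dagostino_k2",
    "WilcoxonResult",
]


# ------------------------------------------------------------------ errors


def leave_one_out_error(positions: np.ndarray) -> np.ndarray:
    """Per-rater distance to the mean position of the other raters.

    ``positions`` is (k, 3), one row per rater, for one landmark of one
    model.  With exactly two raters the "others' mean" is the other rater
    (supported, flagged with a warning).
    """
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    k = len(positions)
    if k < 2:
        raise ValueError("insufficient raters: need at least 2")
    if k == 2:
        warnings.warn("leave-one-out with 2 raters: error is the pairwise distance", stacklevel=2)
    total = positions.sum(axis=0)
    others_mean = (total[None, :] - positions) / (k - 1)
    return np.linalg.norm(positions - others_mean, axis=1)


def measure_error_loo(values: np.ndarray) -> np.ndarray:
    """Per-rater absolute difference to the mean of the other raters' values."""
    values = np.asarray(values, dtype=float).ravel()
    k = len(values)
    if k < 2:
        raise ValueError("insufficient raters: need at least 2")
    others_mean = (values.sum() - values) / (k - 1)
    return np.abs(values - others_mean)


def error_vs_consensus(value: np.ndarray | float, rater_values: np.ndarray) -> float:
    """Distance (3-vectors) or absolute difference (scalars) from a value to
    the all-rater mean — the comparison used for the automatic method."""
    rater_values = np.asarray(rater_values, dtype=float)
    if rater_values.size == 0:
        raise ValueError("no raters")
    consensus = rater_values.mean(axis=0)
    diff = np.asarray(value, dtype=float) - consensus
    return float(np.linalg.norm(diff)) if diff.ndim else float(abs(diff))


def relative_error(error: float, reference_mean: float) -> float:
    """Error as a percentage of the measure's reference mean."""
    if reference_mean <= 0:
        raise ValueError("reference mean must be positive")
    return 100.0 * error / reference_mean


# --------------------------------------------------------------------- ICC


@dataclasses.dataclass
class RaterMatrix:
    """n_subjects x k_raters values of one measure."""

    values: np.ndarray
    subjects: list[str] | None = None
    raters: list[str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("rater matrix must be 2D (subjects x raters)")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError("need at least 2 subjects and 2 raters")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("missing cells: apply listwise deletion upstream")


@dataclasses.dataclass
class ICCResult:
    icc: float
    form: str  # "(3,1)" | "(3,k)"
    sem: float
    category: str
    n: int
    k: int


def _two_way_mean_squares(x: np.ndarray) -> tuple[float, float]:
    """BMS (between subjects) and EMS (residual) of the two-way ANOVA."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    bms = ss_rows / (n - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    return bms, ems


def icc(m: RaterMatrix | np.ndarray, form: str = "(3,1)") -> ICCResult:
    """Two-way mixed, consistency ICC from ANOVA mean squares.

    ICC(3,1) = (BMS - EMS) / (BMS + (k-1) EMS);
    ICC(3,k) = (BMS - EMS) / BMS.
    Negative estimates are reported as computed and classified "poor".

    Raises
    ------
    ValueError
        If the total variance is zero (ICC undefined).
    """
    if not isinstance(m, RaterMatrix):
        m = RaterMatrix(m)
    x = m.values
    n, k = x.shape
    if np.allclose(x, x.flat[0]):
        raise ValueError("undefined ICC: zero total variance")
    bms, ems = _two_way_mean_squares(x)
    if form == "(3,1)":
        value = (bms - ems) / (bms + (k - 1) * ems)
    elif form == "(3,k)":
        if bms == 0:
            raise ValueError("undefined ICC: zero between-subject variance")
        value = (bms - ems) / bms
    else:
        raise ValueError(f"unknown ICC form {form!r}")
    value = float(value)
    return ICCResult(
        icc=value,
        form=form,
        sem=sem(x, value),
        category=classify_icc(value),
        n=n,
        k=k,
    )


def sem(values: np.ndarray, icc_value: float) -> float:
    """Standard error of measurement: SD * sqrt(1 - ICC).

    SD is the pooled standard deviation of all observations of the
    measure.  A negative ICC is floored at 0 inside the radical (flagged).
    """
    if icc_value > 1:
        raise ValueError("ICC cannot exceed 1")
    if icc_value < 0:
        warnings.warn("negative ICC floored at 0 for SEM", stacklevel=2)
        icc_value = 0.0
    sd = float(np.std(np.asarray(values, dtype=float).ravel(), ddof=1))
    return sd * float(np.sqrt(1.0 - icc_value))


def classify_icc(icc_value: float) -> str:
    """Excellent >= 0.9 > good >= 0.75 > moderate >= 0.5 > poor."""
    if icc_value >= 0.9:
        return "excellent"
    if icc_value >= 0.75:
        return "good"
    if icc_value >= 0.5:
        return "moderate"
    return "poor"


# ------------------------------------------------------------------- tests


@dataclasses.dataclass
class WilcoxonResult:
    statistic: float  # W+: sum of ranks of positive differences
    p_value: float
    n_nonzero: int
    method: str  # "exact" | "normal-approximation"


def wilcoxon_signed_rank(
    a: np.ndarray, b: np.ndarray, exact_limit: int = 25
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (Wilcoxon convention), ties get
    mid-ranks.  For up to ``exact_limit`` nonzero pairs the two-sided p is
    computed from the exact null distribution over all 2^n sign vectors
    (valid with ties); beyond that, a normal approximation with tie and
    continuity corrections is used.

    Raises
    ------
    ValueError
        If all differences are zero (no nonzero pairs).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("no nonzero pairs")
    ranks = sps.rankdata(np.abs(d))  # mid-ranks for ties
    w_pos = float(ranks[d > 0].sum())

    if n <= exact_limit:
        # exact null: each sign vector equally likely
        totals = np.zeros(1)
        for r in ranks:
            totals = np.concatenate([totals, totals + r])
        # two-sided: 2 * min tail, capped at 1
        w_mean = ranks.sum() / 2.0
        lo = np.minimum(w_pos, 2 * w_mean - w_pos)
        p = float(np.mean(totals <= lo + 1e-9) + np.mean(totals >= 2 * w_mean - lo - 1e-9))
        p = min(p, 1.0)
        return WilcoxonResult(w_pos, p, n, "exact")

    mean = n * (n + 1) / 4.0
    # tie correction on the variance
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = (counts**3 - counts).sum() / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w_pos - mean - 0.5 * np.sign(w_pos - mean)) / np.sqrt(var)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return WilcoxonResult(w_pos, min(p, 1.0), n, "normal-approximation")


def wilcoxon_null_pmf(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of W+ by full enumeration (oracle-sized n)."""
    ranks = np.asarray(ranks, dtype=float)
    sums = np.array(
        [np.dot(signs, ranks) for signs in itertools.product([0, 1], repeat=len(ranks))]
    )
    values, counts = np.unique(sums, return_counts=True)
    return values, counts / counts.sum()


def dagostino_k2(sample: np.ndarray) -> tuple[float, float]:
    """D'Agostino's K² omnibus normality test (skewness + kurtosis).

    Raises
    ------
    ValueError
        For n < 8 (the kurtosis transform is undefined below that).
    """
    sample = np.asarray(sample, dtype=float).ravel()
    if len(sample) < 8:
        raise ValueError("sample too small for K²: need n >= 8")
    stat, p = sps.normaltest(sample)
    return float(stat), float(p)


# --------------------------------------------------- study-level pipelines


def landmark_error_table(
    labelings_by_model: dict[tuple[str, str], list], auto_by_model: dict | None = None
) -> pd.DataFrame:
    """Leave-one-rater-out landmark errors, plus optional automatic-vs-consensus.

    ``labelings_by_model`` maps (subject, segmentation) to the per-rater
    LandmarkSet list of that model; ``auto_by_model`` maps the same keys to
    one automatic LandmarkSet.  Returns one row per (model, landmark,
    rater-or-automatic) with the error in mm.
    """
    rows = []
    for key, raters in labelings_by_model.items():
        subject, seg = key
        names = raters[0].keys()
        for name, side in names:
            pos = np.array([ls.position(name, side) for ls in raters])
            errs = leave_one_out_error(pos)
            for ls, e in zip(raters, errs):
                rows.append(
                    {
                        "subject": subject,
                        "segmentation": seg,
                        "rater": ls.rater_id,
                        "landmark": name,
                        "side": side,
                        "error_mm": float(e),
                        "error_type": "leave-one-out",
                    }
                )
            if auto_by_model and key in auto_by_model:
                auto = auto_by_model[key]
                e = error_vs_consensus(auto.position(name, side), pos)
                rows.append(
                    {
                        "subject": subject,
                        "segmentation": seg,
                        "rater": "automatic",
                        "landmark": name,
                        "side": side,
                        "error_mm": e,
                        "error_type": "vs-consensus",
                    }
                )
    return pd.DataFrame(rows)


def measure_error_table(measure_values: pd.DataFrame) -> pd.DataFrame:
    """Leave-one-rater-out measure errors from a long-format measure table.

    Expects columns subject, segmentation, rater, measure, value; rows
    with rater == "automatic" are scored against the consensus of the
    others instead of leave-one-out.
    """
    rows = []
    for (subject, seg, measure), grp in measure_values.groupby(
        ["subject", "segmentation", "measure"], sort=False
    ):
        manual = grp[grp.rater != "automatic"]
        vals = manual.value.to_numpy()
        if np.isnan(vals).any() or len(vals) < 2:
            continue
        errs = measure_error_loo(vals)
        for rater, e in zip(manual.rater, errs):
            rows.append(
                {
                    "subject": subject,
                    "segmentation": seg,
                    "rater": rater,
                    "measure": measure,
                    "error": float(e),
                    "error_type": "leave-one-out",
                }
            )
        auto = grp[grp.rater == "automatic"]
        if len(auto) == 1 and np.isfinite(auto.value.iloc[0]):
            rows.append(
                {
                    "subject": subject,
                    "segmentation": seg,
                    "rater": "automatic",
                    "measure": measure,
                    "error": error_vs_consensus(float(auto.value.iloc[0]), vals),
                    "error_type": "vs-consensus",
                }
            )
    return pd.DataFrame(rows)


def inter_rater_icc_table(measure_values: pd.DataFrame, form: str = "(3,k)") -> pd.DataFrame:
    """Per-measure ICC/SEM across raters (subjects = models)."""
    rows = []
    manual = measure_values[measure_values.rater != "automatic"]
    for measure, grp in manual.groupby("measure", sort=False):
        wide = grp.pivot_table(
            index=["subject", "segmentation"], columns="rater", values="value"
        ).dropna()
        if wide.shape[0] < 2 or wide.shape[1] < 2:
            continue
        try:
            res = icc(RaterMatrix(wide.to_numpy()), form)
        except ValueError:
            continue
        rows.append(
            {
                "measure": measure,
                "form": form,
                "icc": res.icc,
                "sem": res.sem,
                "category": res.category,
                "n": res.n,
                "k": res.k,
            }
        )
    return pd.DataFrame(rows)


def across_segmentation_icc_table(
    measure_values: pd.DataFrame, form: str = "(3,1)"
) -> pd.DataFrame:
    """Per-measure, per-rater ICC/SEM across repeated segmentations.

    Subjects are scans; the "raters" of the matrix are the repeated
    segmentations of each scan (same rater labeling each).
    """
    rows = []
    for (measure, rater), grp in measure_values.groupby(["measure", "rater"], sort=False):
        wide = grp.pivot_table(index="subject", columns="segmentation", values="value").dropna()
        if wide.shape[0] < 2 or wide.shape[1] < 2:
            continue
        try:
            res = icc(RaterMatrix(wide.to_numpy()), form)
        except ValueError:
            continue
        rows.append(
            {
                "measure": measure,
                "rater": rater,
                "form": form,
                "icc": res.icc,
                "sem": res.sem,
                "category": res.category,
                "n": res.n,
                "k": res.k,
            }
        )
    return pd.DataFrame(rows)


def manual_vs_automatic_tests(error_table: pd.DataFrame, value_col: str) -> pd.DataFrame:
    """Paired Wilcoxon tests of manual vs automatic errors.

    Pairs on (subject, segmentation, item); the manual value of a pair is
    the mean of the raters' leave-one-out errors for that item.  A
    D'Agostino K² test of the paired differences is reported alongside
    when the sample allows it.
    """
    item_col = "landmark" if "landmark" in error_table.columns else "measure"
    rows = []
    for item, grp in error_table.groupby(item_col, sort=False):
        manual = (
            grp[grp.rater != "automatic"]
            .groupby(["subject", "segmentation"])[value_col]
            .mean()
        )
        auto = grp[grp.rater == "automatic"].set_index(["subject", "segmentation"])[value_col]
        joined = pd.concat([manual.rename("manual"), auto.rename("automatic")], axis=1).dropna()
        if len(joined) < 2:
            continue
        try:
            w = wilcoxon_signed_rank(joined.manual.to_numpy(), joined.automatic.to_numpy())
            stat, p = w.statistic, w.p_value
        except ValueError:  # identical errors
            stat, p = np.nan, 1.0
        diffs = joined.manual.to_numpy() - joined.automatic.to_numpy()
        k2_p = np.nan
        if len(diffs) >= 8:
            k2_p = dagostino_k2(diffs)[1]
        rows.append(
            {
                item_col: item,
                "n_pairs": len(joined),
                "median_manual": float(joined.manual.median()),
                "median_automatic": float(joined.automatic.median()),
                "wilcoxon_w": stat,
                "p_value": p,
                "k2_normality_p": k2_p,
            }
        )
    return pd.DataFrame(rows)
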