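"""Calibration, reference normalization and group comparison statistics.

Quantification is deliberately *relative*: absolute concentrations exist
only for the two calibrated standards, while every compound's peak area is
divided by the 0.780 ng/µL reference-standard area of its replicate batch,
and groups are compared on those unitless ratios with a two-sample
Student's t-test (mean ± sem, n replicates per group).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "GroupComparison",
    "fit_calibration",
    "normalize_to_reference",
    "compare_groups",
    "summarize_study",
    "null_rejection_rate",
]

LOQ_LOD_RATIO = 10.0 / 3.0


@dataclass(frozen=True)
class CalibrationCurve:
    """Least-squares dilution-series fit with detection limits.

    LOD and LOQ are 3× and 10× the fit's residual standard deviation
    expressed in concentration units (residual SD divided by the slope);
    LOQ/LOD is exactly 10/3 by construction.
    """

    compound: str
    concentrations: tuple[float, ...]
    areas: tuple[float, ...]
    slope: float
    intercept: float
    r_squared: float
    lod: float
    loq: float
    sd_concentration: float

    def predict_area(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept


def fit_calibration(
    points: list[tuple[float, float]],
    compound: str = "",
    blank_sd: float | None = None,
) -> CalibrationCurve:
    """Ordinary least-squares calibration line of area on concentration.

    ``points`` are (concentration ng/µL, peak area) pairs, at least three
    distinct concentrations, all positive. The SD feeding the 3×/10×
    detection limits is the residual standard deviation of the fit
    converted to concentration units; pass ``blank_sd`` (an area-unit SD of
    blank injections) to use the blank-based convention instead.
    """
    if len(points) < 3:
        raise ValueError("calibration needs at least 3 points")
    conc = np.array([c for c, _ in points], dtype=float)
    area = np.array([a for _, a in points], dtype=float)
    if np.any(conc <= 0):
        raise ValueError("calibrant concentrations must be positive")
    if np.unique(conc).size < 3:
        raise ValueError("calibration needs at least 3 distinct concentrations")
    fit = stats.linregress(conc, area)
    if fit.slope == 0:
        raise ValueError("calibration slope is zero")
    residuals = area - (fit.slope * conc + fit.intercept)
    dof = conc.size - 2
    resid_sd = float(np.sqrt(np.sum(residuals**2) / dof)) if dof > 0 else 0.0
    sd_area = blank_sd if blank_sd is not None else resid_sd
    sd_conc = sd_area / abs(fit.slope)
    return CalibrationCurve(
        compound=compound,
        concentrations=tuple(conc),
        areas=tuple(area),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        lod=3.0 * sd_conc,
        loq=10.0 * sd_conc,
        sd_concentration=sd_conc,
    )


def normalize_to_reference(area: float, reference_area: float) -> float:
    """Peak area as a unitless ratio to the batch reference-standard area."""
    if reference_area <= 0:
        raise ValueError("reference area must be positive")
    return area / reference_area


@dataclass(frozen=True)
class GroupComparison:
    """Two-group summary: mean ± sem per group and a Student's t-test."""

    compound: str
    matrix: str
    mean_a: float
    sem_a: float
    n_a: int
    mean_b: float
    sem_b: float
    n_b: int
    t_statistic: float
    p_value: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    @property
    def fold_change(self) -> float:
        """mean_b / mean_a (e.g. resistant over parental)."""
        return self.mean_b / self.mean_a if self.mean_a != 0 else math.inf


def compare_groups(
    ratios_a,
    ratios_b,
    compound: str = "",
    matrix: str = "",
    equal_var: bool = True,
    alpha: float = 0.05,
) -> GroupComparison:
    """Two-sided two-sample t-test on normalized ratios.

    Equal-variance (Student's) by default; set ``equal_var=False`` for
    Welch. Two identical degenerate groups give t=0, p=1 rather than an
    error.
    """
    a = np.asarray(ratios_a, dtype=float)
    b = np.asarray(ratios_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = math.inf if b.mean() < a.mean() else -math.inf, 0.0
    else:
        t_stat, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return GroupComparison(
        compound=compound,
        matrix=matrix,
        mean_a=float(a.mean()),
        sem_a=float(a.std(ddof=1) / math.sqrt(a.size)),
        n_a=int(a.size),
        mean_b=float(b.mean()),
        sem_b=float(b.std(ddof=1) / math.sqrt(b.size)),
        n_b=int(b.size),
        t_statistic=float(t_stat),
        p_value=float(p),
        alpha=alpha,
    )


def summarize_study(
    detections: pd.DataFrame,
    measurements: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    group_a: str | None = None,
    group_b: str | None = None,
    alpha: float = 0.05,
    equal_var: bool = True,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-compound, per-matrix group comparison table.

    ``detections`` carries one row per (sample_id, compound) with a
    ``detected`` flag; ``measurements`` one row per (sample_id, compound)
    with a normalized ``ratio``. Only treated test samples enter the
    comparison; samples where the compound was not detected are excluded
    from the test (never imputed as zero) and counted in ``n_below_a/b``. A
    compound detected in neither group is reported "not detected" with no
    test. ``fdr=True`` adds Benjamini–Hochberg adjusted p-values.
    """
    sheet = sample_sheet.set_index("sample_id")
    test_ids = sheet[(sheet["role"] == "test") & (sheet["treatment"] == "treated")]
    groups = sorted(test_ids["group"].unique())
    if group_a is None or group_b is None:
        if len(groups) != 2:
            raise ValueError(f"cannot infer two groups from {groups}; pass group_a/b")
        group_a, group_b = groups

    det = detections.set_index(["sample_id", "compound"])["detected"]
    meas = measurements.set_index(["sample_id", "compound"])["ratio"]

    rows = []
    compounds = sorted(
        set(measurements["compound"]).union(detections["compound"])
    )
    for matrix in sorted(test_ids["matrix"].unique()):
        for compound in compounds:
            values: dict[str, list[float]] = {group_a: [], group_b: []}
            below: dict[str, int] = {group_a: 0, group_b: 0}
            for sample_id, row in test_ids[test_ids["matrix"] == matrix].iterrows():
                group = row["group"]
                if group not in values:
                    continue
                key = (sample_id, compound)
                detected = bool(det.get(key, False))
                if detected and key in meas.index:
                    values[group].append(float(meas.loc[key]))
                else:
                    below[group] += 1
            a, b = values[group_a], values[group_b]
            if len(a) >= 2 and len(b) >= 2:
                cmp = compare_groups(
                    a, b, compound=compound, matrix=matrix,
                    equal_var=equal_var, alpha=alpha,
                )
                status = "detected"
                rows.append(
                    {
                        "compound": compound,
                        "matrix": matrix,
                        "status": status,
                        f"mean_{group_a}": cmp.mean_a,
                        f"sem_{group_a}": cmp.sem_a,
                        f"n_{group_a}": cmp.n_a,
                        f"mean_{group_b}": cmp.mean_b,
                        f"sem_{group_b}": cmp.sem_b,
                        f"n_{group_b}": cmp.n_b,
                        "fold_change": cmp.fold_change,
                        "t_statistic": cmp.t_statistic,
                        "p_value": cmp.p_value,
                        "significant": cmp.significant,
                        "n_below_detection": below[group_a] + below[group_b],
                    }
                )
            else:
                rows.append(
                    {
                        "compound": compound,
                        "matrix": matrix,
                        "status": "not detected"
                        if not a and not b
                        else "below detection",
                        f"mean_{group_a}": np.nan,
                        f"sem_{group_a}": np.nan,
                        f"n_{group_a}": len(a),
                        f"mean_{group_b}": np.nan,
                        f"sem_{group_b}": np.nan,
                        f"n_{group_b}": len(b),
                        "fold_change": np.nan,
                        "t_statistic": np.nan,
                        "p_value": np.nan,
                        "significant": False,
                        "n_below_detection": below[group_a] + below[group_b],
                    }
                )
    table = pd.DataFrame(rows)
    if fdr and table["p_value"].notna().any():
        from statsmodels.stats.multitest import multipletests

        mask = table["p_value"].notna()
        adjusted = np.full(len(table), np.nan)
        adjusted[mask.to_numpy()] = multipletests(
            table.loc[mask, "p_value"], method="fdr_bh"
        )[1]
        table["p_adjusted"] = adjusted
        table.loc[mask, "significant"] = table.loc[mask, "p_adjusted"] < alpha
    return table


def null_rejection_rate(
    n: int = 10,
    cv: float = 0.20,
    repetitions: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    equal_var: bool = True,
) -> float:
    """Type-I error of the group comparison under the simulated null.

    Both groups are drawn from the study's biological-scatter model
    (mean-preserving log-normal at coefficient of variation ``cv``) with
    identical means; returns the fraction of ``repetitions`` in which the
    two-sided t-test rejects at ``alpha``.
    """
    from .simulate import biological_scatter

    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(repetitions):
        a = biological_scatter(rng, 1.0, cv, size=n)
        b = biological_scatter(rng, 1.0, cv, size=n)
        cmp = compare_groups(a, b, equal_var=equal_var, alpha=alpha)
        if cmp.significant:
            rejections += 1
    return rejections / repetitions
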