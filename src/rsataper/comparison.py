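"""Statistical interchangeability analysis of marker-based vs EGS migration.

Bland–Altman agreement with the RSA accuracy thresholds, one-sample t-tests
on intermethod differences, and Pearson correlation of the differences
against head-taper migration with Fisher-Z inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import InputError, UndefinedStatisticError

__all__ = [
    "TRANSLATION_THRESHOLD_MM",
    "ROTATION_THRESHOLD_DEG",
    "BlandAltmanResult",
    "CorrelationResult",
    "bland_altman",
    "one_sample_t",
    "correlate_diff_vs_slip",
    "compare_methods",
]

#: Upper limit of RSA accuracy used as the LoA acceptance threshold.
TRANSLATION_THRESHOLD_MM = 0.5
ROTATION_THRESHOLD_DEG = 1.15

LOA_FACTOR = 1.96


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_difference: float
    sd_difference: float  # sample SD, divisor n-1
    loa_lower: float
    loa_upper: float
    n: int
    threshold: float
    within_threshold: bool


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    fisher_z: float
    z_statistic: float
    p_value: float
    perfect: bool = False


def _paired(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("paired series must be 1-D and of equal length")
    return a, b


def bland_altman(a, b, threshold: float = TRANSLATION_THRESHOLD_MM
                 ) -> BlandAltmanResult:
    """Bland–Altman agreement of paired series via differences a - b.

    LoA = mean ± 1.96 · sample SD. `within_threshold` holds when both limits
    lie inside ±threshold."""
    a, b = _paired(a, b)
    if a.size < 2:
        raise InputError("Bland-Altman needs n >= 2 pairs")
    diff = a - b
    mean = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    lower = mean - LOA_FACTOR * sd
    upper = mean + LOA_FACTOR * sd
    within = max(abs(lower), abs(upper)) <= threshold
    return BlandAltmanResult(mean_difference=mean, sd_difference=sd,
                             loa_lower=lower, loa_upper=upper, n=int(a.size),
                             threshold=float(threshold),
                             within_threshold=bool(within))


def one_sample_t(differences, mu0: float = 0.0) -> tuple[float, int, float]:
    """One-sample two-sided t-test: t = (mean - mu0) / (sd_sample / sqrt(n)).

    Returns (t, dof, p)."""
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise InputError("t-test needs n >= 2")
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        raise UndefinedStatisticError("zero variance: t statistic undefined")
    t = (float(np.mean(d)) - mu0) / (sd / np.sqrt(d.size))
    dof = int(d.size - 1)
    p = float(2.0 * stats.t.sf(abs(t), dof))
    return float(t), dof, p


def correlate_diff_vs_slip(intermethod_differences, head_taper_migrations
                           ) -> CorrelationResult:
    """Pearson r between intermethod differences and head-taper migration,
    with Fisher-Z inference against r = 0 (needs n > 3)."""
    x, y = _paired(intermethod_differences, head_taper_migrations)
    if x.size < 4:
        raise InputError("Fisher-Z inference needs n >= 4")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise UndefinedStatisticError("constant input: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0 - 1e-15:
        r = float(np.sign(r))
        return CorrelationResult(r=r, n=int(x.size), fisher_z=float("inf") * r,
                                 z_statistic=float("inf") * r, p_value=0.0,
                                 perfect=True)
    z = float(np.arctanh(r))
    z_stat = z * np.sqrt(x.size - 3)
    p = float(2.0 * stats.norm.sf(abs(z_stat)))
    return CorrelationResult(r=r, n=int(x.size), fisher_z=z,
                             z_statistic=float(z_stat), p_value=p)


_AXES_T = ("tx", "ty", "tz")
_AXES_R = ("rx", "ry", "rz")
_SLIP_FOR_AXIS = {"tx": "dx", "ty": "dy", "tz": "dz"}

#: Follow-up groups used by the pooled-vs-split analysis (months).
DEFAULT_GROUPS = {"3-6": (3.0, 6.0), "12-120": (12.0, 120.0)}


def _one_comparison(marker: pd.Series, other: pd.Series, slip: pd.Series | None,
                    axis: str, group: str, threshold: float) -> dict:
    # Difference convention: EGS-route minus marker-based (model vs gold standard).
    ba = bland_altman(other.to_numpy(), marker.to_numpy(), threshold=threshold)
    diff = other.to_numpy() - marker.to_numpy()
    try:
        t, _dof, p_t = one_sample_t(diff)
    except UndefinedStatisticError:
        t, p_t = np.nan, np.nan
    r = p_fisher = np.nan
    if slip is not None:
        try:
            corr = correlate_diff_vs_slip(diff, slip.to_numpy())
            r, p_fisher = corr.r, corr.p_value
        except (InputError, UndefinedStatisticError):
            pass
    return {"axis": axis, "group": group, "n": ba.n,
            "mean_diff": ba.mean_difference, "loa_lower": ba.loa_lower,
            "loa_upper": ba.loa_upper, "t": t, "p_t": p_t,
            "r": r, "p_fisher": p_fisher,
            "within_threshold": ba.within_threshold}


def compare_methods(migration_df: pd.DataFrame,
                    headtaper_df: pd.DataFrame | None = None,
                    groups: dict[str, tuple[float, float]] | None = None,
                    translation_method: str = "egs_corrected",
                    rotation_method: str = "egs") -> pd.DataFrame:
    """Marker vs EGS interchangeability table, per axis (and follow-up group).

    Translations compare marker against the reference-point-corrected EGS
    route; rotations against the plain EGS route (rotations are reference-point
    independent). When a head-taper table is supplied, translation differences
    are additionally correlated with the same-axis head-taper migration.
    """
    required = {"patient_id", "visit_months", "method"}
    if not required <= set(migration_df.columns):
        raise InputError("migration_df lacks required columns")
    df = migration_df[~migration_df["gated_out"].astype(bool)] \
        if "gated_out" in migration_df else migration_df
    pivoted = df.pivot_table(index=["patient_id", "visit_months"],
                             columns="method",
                             values=list(_AXES_T + _AXES_R))
    slip_lookup = None
    if headtaper_df is not None:
        ht = headtaper_df[headtaper_df["valid"]] if "valid" in headtaper_df \
            else headtaper_df
        slip_lookup = ht.set_index(["patient_id", "visit_months"])[
            ["dx", "dy", "dz"]]
    group_map = {"all": None} if groups is None else groups
    rows = []
    for gname, bounds in group_map.items():
        idx = pivoted.index
        if bounds is not None:
            months = idx.get_level_values("visit_months")
            sel = (months >= bounds[0]) & (months <= bounds[1])
            sub = pivoted[sel]
        else:
            sub = pivoted
        if sub.empty:
            continue
        for axis in _AXES_T + _AXES_R:
            method = translation_method if axis in _AXES_T else rotation_method
            threshold = TRANSLATION_THRESHOLD_MM if axis in _AXES_T \
                else ROTATION_THRESHOLD_DEG
            try:
                marker = sub[(axis, "marker")].dropna()
                other = sub[(axis, method)].dropna()
            except KeyError as exc:
                raise InputError(f"method column missing: {exc}") from exc
            common = marker.index.intersection(other.index)
            if len(common) < 2:
                continue
            marker = marker.loc[common]
            other = other.loc[common]
            slip = None
            if slip_lookup is not None and axis in _SLIP_FOR_AXIS:
                slip = slip_lookup[_SLIP_FOR_AXIS[axis]].reindex(common)
                if slip.isna().any():
                    slip = None
            rows.append(_one_comparison(marker, other, slip, axis, gname,
                                        threshold))
    return pd.DataFrame(rows)
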