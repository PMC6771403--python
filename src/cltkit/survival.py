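"""Expression-tertile survival analysis: Kaplan-Meier, log-rank, Cox.

Patients are split at the 33.33rd/66.67th expression percentiles; the
bottom ("low") and top ("high") tertiles are compared by the log-rank test
and by a Cox proportional-hazards model (Efron tie handling, via
lifelines), whose exponentiated coefficient is the reported hazard ratio.

Overall survival time is days_to_death for deceased patients; for
censored patients it is reconstructed from the annotation-update reference
year as ``365 x (reference_year - year_of_birth) - age_at_diagnosis_days``.
That censoring formula mixes calendar years and day counts; it is applied
literally, as the source annotations define it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats


@dataclass
class SurvivalRecord:
    patient_id: str
    time: float  # days
    event: bool  # True = death observed

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"{self.patient_id}: non-positive survival time")


def build_survival_records(
    clinical: pd.DataFrame,
    reference_year: int = 2017,
) -> list[SurvivalRecord]:
    """Overall-survival records from a TCGA-style clinical table.

    Expected columns: ``patient_id``, ``days_to_death``, ``vital_status``
    (``deceased``/``dead`` vs anything else), ``year_of_birth``,
    ``age_at_diagnosis_days``. Patients with non-positive or missing times
    are dropped with a warning.
    """
    records: list[SurvivalRecord] = []
    dropped = 0
    for _, row in clinical.iterrows():
        pid = str(row["patient_id"])
        status = str(row.get("vital_status", "")).lower()
        dead = status in {"dead", "deceased"}
        if dead and not pd.isna(row.get("days_to_death")):
            time = float(row["days_to_death"])
            event = True
        elif not pd.isna(row.get("year_of_birth")) and not pd.isna(row.get("age_at_diagnosis_days")):
            time = 365.0 * (reference_year - float(row["year_of_birth"])) - float(
                row["age_at_diagnosis_days"]
            )
            event = False
        else:
            dropped += 1
            continue
        if time <= 0:
            dropped += 1
            continue
        records.append(SurvivalRecord(pid, time, event))
    if dropped:
        warnings.warn(f"dropped {dropped} patients with missing or non-positive times")
    if not records:
        raise ValueError("no usable survival records")
    return records


# ---------------------------------------------------------------------------
# tertiles

TERTILE_STRATA = ("low", "mid", "high")


@dataclass
class TertileAssignment:
    patient_id: str
    stratum: str
    expression: float


def tertile_stratify(expression: Mapping[str, float]) -> list[TertileAssignment]:
    """Assign patients to low/mid/high expression tertiles.

    Cuts are the 33.33rd and 66.67th percentiles (linear interpolation);
    patients exactly at a cut go to the lower stratum. Assignment is
    order-independent: patients are processed in sorted-id order.
    """
    if len(expression) < 6:
        raise ValueError("tertile stratification needs >= 6 patients")
    values = np.array([expression[p] for p in sorted(expression)])
    if np.all(values == values[0]):
        raise ValueError("constant expression: tertiles undefined")
    low_cut = float(np.percentile(values, 100.0 / 3.0))
    high_cut = float(np.percentile(values, 200.0 / 3.0))
    out = []
    for pid in sorted(expression):
        v = float(expression[pid])
        stratum = "low" if v <= low_cut else ("mid" if v <= high_cut else "high")
        out.append(TertileAssignment(pid, stratum, v))
    return out


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank

def km_curve(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    """Kaplan-Meier survival curve coordinates (via lifelines)."""
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit([r.time for r in records], [r.event for r in records])
    df = kmf.survival_function_.reset_index()
    df.columns = ["time", "survival"]
    return df


@dataclass
class LogrankResult:
    statistic: float
    p_value: float
    observed_minus_expected: float  # O - E in group A


def logrank_test(
    group_a: Sequence[SurvivalRecord],
    group_b: Sequence[SurvivalRecord],
) -> LogrankResult:
    """Two-group log-rank chi-square (1 df), deaths at equal times tied.

    With zero events in both groups the test is undefined; a warning is
    emitted and p = 1 returned.
    """
    times = np.array([r.time for r in group_a] + [r.time for r in group_b])
    events = np.array([r.event for r in group_a] + [r.event for r in group_b])
    in_a = np.array([True] * len(group_a) + [False] * len(group_b))
    if events.sum() == 0:
        warnings.warn("log-rank with zero events in both groups; p set to 1")
        return LogrankResult(0.0, 1.0, 0.0)

    o_minus_e = 0.0
    variance = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & in_a).sum())
        d = int((events & (times == t)).sum())
        d1 = int((events & (times == t) & in_a).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            variance += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if variance == 0:
        return LogrankResult(0.0, 1.0, o_minus_e)
    chi2 = o_minus_e**2 / variance
    p = float(sstats.chi2.sf(chi2, df=1))
    return LogrankResult(float(chi2), p, float(o_minus_e))


# ---------------------------------------------------------------------------
# Cox proportional hazards

@dataclass
class CoxResult:
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    coefficient: float
    n: int
    n_events: int


def cox_hazard_ratio(
    records: Sequence[SurvivalRecord],
    covariate: Mapping[str, float],
) -> CoxResult:
    """Cox partial-likelihood hazard ratio for a single covariate.

    Uses Efron tie handling (lifelines). ``covariate`` maps patient_id to a
    numeric value (e.g. 1 for the high tertile, 0 for the low). Raises on
    non-convergence; complete separation is reported as non-estimable.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    rows = [
        {"time": r.time, "event": int(r.event), "x": float(covariate[r.patient_id])}
        for r in records
        if r.patient_id in covariate
    ]
    df = pd.DataFrame(rows)
    if df.empty or df["x"].nunique() < 2:
        raise ValueError("Cox regression needs >= 2 covariate levels")
    if df["event"].sum() == 0:
        raise ValueError("Cox regression needs >= 1 event")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc
    coef = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    if abs(coef) > 15 or se > 50:  # monotone likelihood: separation
        raise RuntimeError("complete separation: hazard ratio non-estimable")
    ci = cph.confidence_intervals_
    return CoxResult(
        hazard_ratio=float(np.exp(coef)),
        ci_low=float(np.exp(ci.iloc[0, 0])),
        ci_high=float(np.exp(ci.iloc[0, 1])),
        p_value=float(cph.summary["p"].iloc[0]),
        coefficient=coef,
        n=len(df),
        n_events=int(df["event"].sum()),
    )


def cox_score_test_at_zero(
    records: Sequence[SurvivalRecord],
    covariate: Mapping[str, float],
) -> float:
    """Cox partial-likelihood score chi-square at beta = 0 (Breslow risk
    sets). On tie-free data this equals the log-rank statistic."""
    rows = sorted(
        ((r.time, r.event, float(covariate[r.patient_id])) for r in records),
        key=lambda x: x[0],
    )
    times = np.array([r[0] for r in rows])
    events = np.array([r[1] for r in rows])
    x = np.array([r[2] for r in rows])
    score = 0.0
    info = 0.0
    for t in np.unique(times[events.astype(bool)]):
        at_risk = times >= t
        xr = x[at_risk]
        d_idx = events.astype(bool) & (times == t)
        d = int(d_idx.sum())
        xbar = xr.mean()
        score += x[d_idx].sum() - d * xbar
        info += d * ((xr**2).mean() - xbar**2)
    if info == 0:
        return 0.0
    return float(score**2 / info)


# ---------------------------------------------------------------------------
# per-transcript prognostic screen

def prognostic_screen(
    expression: pd.DataFrame,  # transcripts x patients
    records: Sequence[SurvivalRecord],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tertile-stratified log-rank + Cox screen over transcripts.

    Emits raw and Benjamini-Hochberg-adjusted log-rank p-values; the
    ``significant`` flag uses the raw p at ``alpha`` (no correction), with
    the adjusted column available for stricter calls.
    """
    by_id = {r.patient_id: r for r in records}
    rows = []
    for tid in expression.index:
        expr = {p: float(expression.loc[tid, p]) for p in expression.columns if p in by_id}
        try:
            strata = tertile_stratify(expr)
        except ValueError:
            continue
        low = [by_id[a.patient_id] for a in strata if a.stratum == "low"]
        high = [by_id[a.patient_id] for a in strata if a.stratum == "high"]
        if not low or not high:
            continue
        lr = logrank_test(high, low)
        cov = {a.patient_id: 1.0 for a in strata if a.stratum == "high"}
        cov.update({a.patient_id: 0.0 for a in strata if a.stratum == "low"})
        try:
            cox = cox_hazard_ratio(low + high, cov)
            hr, ci_lo, ci_hi, cox_p = cox.hazard_ratio, cox.ci_low, cox.ci_high, cox.p_value
        except (ValueError, RuntimeError):
            hr = ci_lo = ci_hi = cox_p = np.nan
        rows.append(
            {
                "transcript_id": tid,
                "logrank_stat": lr.statistic,
                "logrank_p": lr.p_value,
                "hazard_ratio": hr,
                "hr_ci_low": ci_lo,
                "hr_ci_high": ci_hi,
                "cox_p": cox_p,
                "n_low": len(low),
                "n_high": len(high),
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["logrank_p_bh"] = _benjamini_hochberg(df["logrank_p"].values)
        df["significant"] = df["logrank_p"] < alpha
    return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]
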