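"""Patient-level aggregation and cohort statistics.

Covers the descriptive layer (prevalence of flagged patients, mentions per
flagged patient, ranked matched-phrase frequencies), association analyses
(unadjusted 2x2 odds ratios with Woolf confidence intervals, adjusted odds
ratios from a binary logistic regression), and longitudinal summaries
(yearly mention rates among flagged patients, inter-event intervals).

Conventions: odds ratio = (a*d)/(b*c) on an exposed/reference 2x2; Woolf CI
= exp(ln OR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d)); a Haldane-Anscombe 0.5
correction is applied to every cell when any cell is zero.  Quartiles use
linear interpolation (numpy default), medians/IQRs in days.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DataError
from .matcher import MentionMatch, NoteResult
from .preprocess import CleanNote

Z95 = 1.959963984540054  # scipy.stats.norm.ppf(0.975)

AGE_BANDS = ("18-<60", "60-<70", "70-<80", ">=80")

#: Reference level per demographic factor used for odds ratios.
DEFAULT_REFERENCES = {
    "age_band": "18-<60",
    "sex": "Male",
    "race": "White",
    "ethnicity": "Hispanic or Latino",
}

#: Factor levels excluded from regression (unknown exposure).
MISSING_LEVELS = {"Declined or missing", "Unknown", ""}


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    age_band: str = ""
    sex: str = ""
    race: str = ""
    ethnicity: str = ""
    first_encounter_date: date | None = None
    total_notes: int = 0
    mention_events: tuple[date, ...] = ()

    @property
    def flagged(self) -> bool:
        return len(self.mention_events) > 0


@dataclass(frozen=True)
class TwoByTwo:
    """a: exposed with outcome, b: exposed without, c: reference with,
    d: reference without."""

    a: int
    b: int
    c: int
    d: int


@dataclass(frozen=True)
class ORResult:
    estimate: float
    ci_low: float
    ci_high: float
    method: str  # "woolf", "exact-style" or "wald-logistic"
    reference_level: str
    label: str = ""
    degenerate: bool = False


@dataclass(frozen=True)
class YearRateRow:
    year: int
    total_notes: int
    need_count: int

    @property
    def rate_percent(self) -> float:
        return round(100.0 * self.need_count / self.total_notes, 1)


@dataclass(frozen=True)
class IntervalRow:
    event_count: int
    n_patients: int
    between_median: float | None
    between_iqr: tuple[float, float] | None
    from_first_median: float
    from_first_iqr: tuple[float, float]


@dataclass(frozen=True)
class Prevalence:
    proportion: float

    @property
    def percent(self) -> str:
        return f"{100.0 * self.proportion:.1f}%"


# ---------------------------------------------------------------- aggregation


def aggregate_by_patient(
    results: list[NoteResult],
    notes: list[CleanNote],
    demographics: pd.DataFrame,
) -> list[PatientRecord]:
    """One record per patient: demographics from the first visit, note
    totals, and the sorted dates of flagged notes (one event per flagged
    note)."""
    demo = demographics.set_index("patient_id") if "patient_id" in demographics else demographics
    note_patients: dict[str, int] = {}
    for n in notes:
        note_patients[n.patient_id] = note_patients.get(n.patient_id, 0) + 1
    unknown = sorted({r.patient_id for r in results} - set(note_patients))
    if unknown:
        raise DataError(
            f"results reference {len(unknown)} patient(s) absent from notes: "
            + ", ".join(unknown[:10])
        )

    events: dict[str, list[date]] = {}
    for r in results:
        if r.flagged:
            events.setdefault(r.patient_id, []).append(r.encounter_date)

    records = []
    for pid, total in note_patients.items():
        row = demo.loc[pid] if pid in demo.index else None
        get = (lambda k: str(row[k])) if row is not None else (lambda k: "")
        fed = None
        if row is not None and "first_encounter_date" in row:
            fed = row["first_encounter_date"]
            if isinstance(fed, str):
                fed = date.fromisoformat(fed)
            elif isinstance(fed, pd.Timestamp):
                fed = fed.date()
        records.append(
            PatientRecord(
                patient_id=pid,
                age_band=get("age_band") if row is not None else "",
                sex=get("sex") if row is not None else "",
                race=get("race") if row is not None else "",
                ethnicity=get("ethnicity") if row is not None else "",
                first_encounter_date=fed,
                total_notes=total,
                mention_events=tuple(sorted(events.get(pid, []))),
            )
        )
    return records


def prevalence(patients: list[PatientRecord]) -> Prevalence:
    """Fraction of patients with at least one mention."""
    if not patients:
        raise ValueError("prevalence of an empty cohort is undefined")
    flagged = sum(p.flagged for p in patients)
    return Prevalence(proportion=flagged / len(patients))


def mean_mentions_per_flagged(patients: list[PatientRecord]) -> float:
    flagged = [p for p in patients if p.flagged]
    if not flagged:
        raise ValueError("no flagged patients")
    return sum(len(p.mention_events) for p in flagged) / len(flagged)


def single_mention_share(patients: list[PatientRecord]) -> float:
    """Proportion of flagged patients with exactly one mention event."""
    flagged = [p for p in patients if p.flagged]
    if not flagged:
        raise ValueError("no flagged patients")
    return sum(len(p.mention_events) == 1 for p in flagged) / len(flagged)


def mean_notes_per_patient(patients: list[PatientRecord]) -> float:
    if not patients:
        raise ValueError("empty cohort")
    return sum(p.total_notes for p in patients) / len(patients)


def term_frequency(mentions: list[MentionMatch]) -> pd.DataFrame:
    """Ranked table of matched phrases: distinct encounter (note) hits and
    distinct patient hits, sorted by encounter hits descending, ties
    alphabetical."""
    if not mentions:
        return pd.DataFrame(
            columns=["phrase", "encounter_hits", "unique_patient_hits"]
        )
    df = pd.DataFrame(
        {
            "phrase": [m.matched_phrase for m in mentions],
            "note_id": [m.note_id for m in mentions],
            "patient_id": [m.patient_id for m in mentions],
        }
    )
    out = (
        df.groupby("phrase")
        .agg(
            encounter_hits=("note_id", "nunique"),
            unique_patient_hits=("patient_id", "nunique"),
        )
        .reset_index()
        .sort_values(
            ["encounter_hits", "phrase"], ascending=[False, True], kind="stable"
        )
        .reset_index(drop=True)
    )
    return out


# -------------------------------------------------------------- associations


def two_by_two(
    patients: list[PatientRecord], factor: str, level: str, reference: str
) -> TwoByTwo:
    """Cross-tabulate flagged status for one factor level vs its reference."""
    a = b = c = d = 0
    for p in patients:
        value = getattr(p, factor)
        if value == level:
            if p.flagged:
                a += 1
            else:
                b += 1
        elif value == reference:
            if p.flagged:
                c += 1
            else:
                d += 1
    return TwoByTwo(a=a, b=b, c=c, d=d)


def odds_ratio(
    t: TwoByTwo,
    method: str = "woolf",
    reference_level: str = "reference",
    label: str = "",
) -> ORResult:
    """Odds ratio with 95% CI.

    ``woolf``: cross-product estimate with the log-OR normal-approximation
    interval; a 0.5 correction on all cells when any cell is zero.
    ``exact-style``: conditional (hypergeometric) estimate and interval via
    scipy, for sparse tables.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if method == "exact-style":
        from scipy.stats.contingency import odds_ratio as _exact_or

        res = _exact_or([[a, b], [c, d]])
        lo, hi = res.confidence_interval(0.95)
        return ORResult(
            estimate=float(res.statistic),
            ci_low=float(lo),
            ci_high=float(hi),
            method="exact-style",
            reference_level=reference_level,
            label=label,
        )
    if method != "woolf":
        raise ValueError(f"unknown odds-ratio method {method!r}")

    degenerate = min(a, b, c, d) == 0
    if degenerate:  # Haldane-Anscombe correction
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(est)
    return ORResult(
        estimate=est,
        ci_low=math.exp(log_or - Z95 * se),
        ci_high=math.exp(log_or + Z95 * se),
        method="woolf",
        reference_level=reference_level,
        label=label,
        degenerate=degenerate,
    )


def unadjusted_odds_ratios(
    patients: list[PatientRecord],
    factors: list[str] | None = None,
    references: dict[str, str] | None = None,
) -> list[ORResult]:
    """Per-level unadjusted odds ratios vs each factor's reference level.
    Missing/declined levels are reported without an OR (skipped)."""
    factors = factors or ["age_band", "sex", "race", "ethnicity"]
    references = {**DEFAULT_REFERENCES, **(references or {})}
    out = []
    for factor in factors:
        ref = references[factor]
        levels = sorted({getattr(p, factor) for p in patients})
        for level in levels:
            if level == ref or level in MISSING_LEVELS:
                continue
            t = two_by_two(patients, factor, level, ref)
            out.append(
                odds_ratio(
                    t, reference_level=ref, label=f"{factor}={level}"
                )
            )
    return out


def _safe_exp(x: float) -> float:
    # separated fits can produce huge Wald bounds; report inf, never crash
    try:
        return math.exp(x)
    except OverflowError:
        return float("inf")


def fit_logistic_adjusted(
    patients: list[PatientRecord],
    covariates: list[str],
    references: dict[str, str] | None = None,
) -> list[ORResult]:
    """Adjusted odds ratios from a binary logistic regression.

    Dummy-coded design with declared reference levels; patients with a
    missing/declined level on any included factor are excluded.  Fit by
    iteratively reweighted least squares (GLM, binomial family, deviance
    tolerance 1e-8, max 100 iterations); Wald 95% intervals.  Coefficients
    diverging toward separation are flagged rather than clipped.
    """
    references = {**DEFAULT_REFERENCES, **(references or {})}
    rows = [
        p
        for p in patients
        if all(getattr(p, f) not in MISSING_LEVELS for f in covariates)
    ]
    if not rows:
        raise DataError("no patients left after excluding missing levels")
    df = pd.DataFrame(
        {f: [getattr(p, f) for p in rows] for f in covariates}
        | {"_y": [int(p.flagged) for p in rows]}
    )
    X_parts, labels = [], []
    for f in covariates:
        ref = references[f]
        levels = [lv for lv in sorted(df[f].unique()) if lv != ref]
        for lv in levels:
            X_parts.append((df[f] == lv).astype(float).rename(f"{f}={lv}"))
            labels.append((f"{f}={lv}", ref))
    X = sm.add_constant(pd.concat(X_parts, axis=1)) if X_parts else None
    if X is None:
        raise ValueError("no non-reference levels among covariates")
    model = sm.GLM(df["_y"], X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(maxiter=100, tol=1e-8)
    conf = fit.conf_int(alpha=0.05)
    out = []
    for (label, ref) in labels:
        beta = fit.params[label]
        lo, hi = conf.loc[label]
        separated = bool((not fit.converged) or abs(beta) > 15)
        out.append(
            ORResult(
                estimate=_safe_exp(beta),
                ci_low=_safe_exp(lo),
                ci_high=_safe_exp(hi),
                method="wald-logistic",
                reference_level=ref,
                label=label,
                degenerate=separated,
            )
        )
    return out


# ------------------------------------------------------------- longitudinal


def yearly_rates(
    patients: list[PatientRecord], results: list[NoteResult]
) -> list[YearRateRow]:
    """Per calendar year, among flagged patients only: flagged-note count
    over total note count."""
    flagged_ids = {p.patient_id for p in patients if p.flagged}
    totals: dict[int, int] = {}
    needs: dict[int, int] = {}
    for r in results:
        if r.patient_id not in flagged_ids:
            continue
        year = r.encounter_date.year
        totals[year] = totals.get(year, 0) + 1
        if r.flagged:
            needs[year] = needs.get(year, 0) + 1
    return [
        YearRateRow(year=y, total_notes=totals[y], need_count=needs.get(y, 0))
        for y in sorted(totals)
    ]


def _median_iqr(values: list[float]) -> tuple[float, tuple[float, float]]:
    arr = np.asarray(values, dtype=float)
    return (
        float(np.median(arr)),
        (float(np.percentile(arr, 25)), float(np.percentile(arr, 75))),
    )


def interevent_intervals(patients: list[PatientRecord]) -> list[IntervalRow]:
    """Patients grouped by number of mention events; for k >= 2 the pooled
    within-patient gaps between consecutive events, and for all k the days
    from first encounter to the first event."""
    groups: dict[int, list[PatientRecord]] = {}
    for p in patients:
        k = len(p.mention_events)
        if k >= 1:
            groups.setdefault(k, []).append(p)
    rows = []
    for k in sorted(groups):
        members = groups[k]
        from_first = [
            (p.mention_events[0] - p.first_encounter_date).days
            for p in members
            if p.first_encounter_date is not None
        ]
        ff_med, ff_iqr = _median_iqr(from_first) if from_first else (float("nan"), (float("nan"),) * 2)
        if k >= 2:
            gaps = [
                (p.mention_events[i + 1] - p.mention_events[i]).days
                for p in members
                for i in range(k - 1)
            ]
            b_med, b_iqr = _median_iqr(gaps)
        else:
            b_med, b_iqr = None, None
        rows.append(
            IntervalRow(
                event_count=k,
                n_patients=len(members),
                between_median=b_med,
                between_iqr=b_iqr,
                from_first_median=ff_med,
                from_first_iqr=ff_iqr,
            )
        )
    return rows
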