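"""Neuropsychological scoring against regression-based norms and cohort stratification.

The cognitive battery (BRB-N) comprises nine tests grouped into four
domains: verbal memory (SRT long-term storage, SRT consistent long-term
retrieval, SRT delayed recall), visual memory (SPART, SPART delayed
recall), information processing speed / attention (SDMT, PASAT-3, PASAT-2)
and verbal fluency (WLG).  Each raw test score is converted to a z-score
against a normative linear regression on age, sex and education; domain
z-scores average the member tests, and a global z averages the four
domains.  A test is failed at z <= -1.5 (at least 1.5 SD below the norm);
a domain is impaired when at least one of its tests is failed; a subject is
cognitively impaired when two or more domains are impaired.  Fatigue is
MFIS >= 38 and depression is MADRS > 9; either instrument may be missing,
which excludes the subject from that stratification only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .inference import RankDeficientDesignError, _find_collinear_column

__all__ = [
    "TESTS",
    "DOMAINS",
    "SubjectRecord",
    "NormativeModel",
    "CognitiveProfile",
    "StratificationReport",
    "fit_normative_model",
    "score_subject",
    "classify_subject",
    "score_and_classify",
    "stratify_cohort",
    "prevalence_pct",
]

#: cognitive domains and their member tests, in battery order
DOMAINS: dict[str, tuple[str, ...]] = {
    "verbal_memory": ("srt_lts", "srt_cltr", "srt_recall"),
    "visual_memory": ("spart", "spart_recall"),
    "processing_speed_attention": ("sdmt", "pasat3", "pasat2"),
    "verbal_fluency": ("wlg",),
}

TESTS: tuple[str, ...] = tuple(t for tests in DOMAINS.values() for t in tests)

#: a test is failed at or below this z (>= 1.5 SD below the norm)
Z_FAILURE_CUTOFF = -1.5
#: a subject is cognitively impaired with at least this many impaired domains
MIN_IMPAIRED_DOMAINS = 2
MFIS_CUTOFF = 38   # fatigued at MFIS >= 38
MADRS_CUTOFF = 9   # depressed at MADRS > 9


@dataclass
class SubjectRecord:
    """One subject's demographics, raw test scores and symptom scales."""

    subject_id: str
    age: float
    sex: int                      # 0/1 coding; any full-rank coding is equivalent
    education: float              # years
    edss: float                   # ordinal 0-10, steps of 0.5
    scanner: int                  # 1 or 2
    course: str = "RR"            # "RR" or "progressive"
    raw_scores: dict[str, float | None] = field(default_factory=dict)
    mfis: float | None = None     # 0-84, or None if not administered
    madrs: float | None = None    # >= 0, or None
    t2lv: float | None = None     # T2 lesion volume, mL

    def __post_init__(self) -> None:
        if not (0.0 <= self.edss <= 10.0):
            raise ValueError(f"EDSS {self.edss} outside 0-10")
        if self.mfis is not None and not (0 <= self.mfis <= 84):
            raise ValueError(f"MFIS {self.mfis} outside 0-84")
        if self.madrs is not None and self.madrs < 0:
            raise ValueError("MADRS must be >= 0")
        unknown = set(self.raw_scores) - set(TESTS)
        if unknown:
            raise ValueError(f"unknown tests: {sorted(unknown)}")


@dataclass(frozen=True)
class NormativeModel:
    """Per-test normative regression on age, sex and education.

    ``coefficients[test]`` is (intercept, b_age, b_sex, b_education);
    ``residual_sd[test]`` is the df-corrected residual standard deviation of
    the fit (must be positive).
    """

    coefficients: dict[str, tuple[float, float, float, float]]
    residual_sd: dict[str, float]

    def __post_init__(self) -> None:
        for test, sd in self.residual_sd.items():
            if sd <= 0:
                raise ValueError(f"residual SD for {test} must be > 0")

    def predict(self, test: str, age: float, sex: float, education: float) -> float:
        b0, b_age, b_sex, b_edu = self.coefficients[test]
        return b0 + b_age * age + b_sex * sex + b_edu * education

    def zscore(self, test: str, raw: float, age: float, sex: float, education: float) -> float:
        return (raw - self.predict(test, age, sex, education)) / self.residual_sd[test]


@dataclass
class CognitiveProfile:
    """Derived z-scores and classification flags for one subject.

    Missing tests are skipped in the domain mean; a domain with no scored
    tests is None and drops out of the global mean.  ``fatigued`` and
    ``depressed`` are None when the instrument was not administered.
    """

    subject_id: str
    z_tests: dict[str, float | None]
    z_domains: dict[str, float | None]
    global_z: float | None
    failed_tests: dict[str, bool] = field(default_factory=dict)
    impaired_domains: dict[str, bool] = field(default_factory=dict)
    cognitively_impaired: bool | None = None
    fatigued: bool | None = None
    depressed: bool | None = None


def fit_normative_model(reference_records: list[SubjectRecord]) -> NormativeModel:
    """Ordinary least squares normative fit, one regression per test.

    Requires at least 30 reference subjects with complete covariates per
    test.  Residual SD uses the n - 4 degrees-of-freedom correction.
    """
    coefficients: dict[str, tuple[float, float, float, float]] = {}
    residual_sd: dict[str, float] = {}
    names = ["intercept", "age", "sex", "education"]
    for test in TESTS:
        rows = [r for r in reference_records if r.raw_scores.get(test) is not None]
        if len(rows) < 30:
            raise ValueError(f"need >= 30 reference subjects for test {test}, got {len(rows)}")
        X = np.array([[1.0, r.age, r.sex, r.education] for r in rows])
        y = np.array([r.raw_scores[test] for r in rows], dtype=float)
        if np.linalg.matrix_rank(X) < 4:
            raise RankDeficientDesignError(
                f"normative covariates are collinear for test {test}: "
                f"column '{_find_collinear_column(X, names)}'"
            )
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sd = float(np.sqrt(resid @ resid / (len(y) - 4)))
        if sd <= 0:
            # noiseless reference: any nonzero deviation is infinitely abnormal;
            # use a tiny floor so z-scores stay finite for exact-prediction data
            sd = np.finfo(float).tiny ** 0.5
        coefficients[test] = tuple(beta)
        residual_sd[test] = sd
    return NormativeModel(coefficients, residual_sd)


def score_subject(record: SubjectRecord, model: NormativeModel) -> CognitiveProfile:
    """z = (raw - predicted) / residual SD per test; domain and global means."""
    z_tests: dict[str, float | None] = {}
    for test in TESTS:
        raw = record.raw_scores.get(test)
        if raw is None:
            z_tests[test] = None
            continue
        if test not in model.coefficients:
            raise ValueError(f"normative model does not cover test {test}")
        z_tests[test] = model.zscore(test, raw, record.age, record.sex, record.education)
    z_domains: dict[str, float | None] = {}
    for domain, tests in DOMAINS.items():
        zs = [z_tests[t] for t in tests if z_tests[t] is not None]
        z_domains[domain] = float(np.mean(zs)) if zs else None
    scored = [z for z in z_domains.values() if z is not None]
    global_z = float(np.mean(scored)) if scored else None
    return CognitiveProfile(
        subject_id=record.subject_id,
        z_tests=z_tests,
        z_domains=z_domains,
        global_z=global_z,
    )


def classify_subject(profile: CognitiveProfile, record: SubjectRecord) -> CognitiveProfile:
    """Apply the failure / impairment / fatigue / depression cut-offs.

    Idempotent: flags are pure functions of the z-scores and scale scores.
    """
    failed = {
        test: (z is not None and z <= Z_FAILURE_CUTOFF)
        for test, z in profile.z_tests.items()
    }
    impaired_domains = {
        domain: any(failed[t] for t in tests)
        for domain, tests in DOMAINS.items()
    }
    impaired = sum(impaired_domains.values()) >= MIN_IMPAIRED_DOMAINS
    fatigued = None if record.mfis is None else bool(record.mfis >= MFIS_CUTOFF)
    depressed = None if record.madrs is None else bool(record.madrs > MADRS_CUTOFF)
    return replace(
        profile,
        failed_tests=failed,
        impaired_domains=impaired_domains,
        cognitively_impaired=impaired,
        fatigued=fatigued,
        depressed=depressed,
    )


def score_and_classify(record: SubjectRecord, model: NormativeModel) -> CognitiveProfile:
    return classify_subject(score_subject(record, model), record)


def prevalence_pct(n_positive: int, n_total: int) -> float:
    """Percentage to one decimal, rounding halves up (162/596 -> 27.2)."""
    if n_total == 0:
        return float("nan")
    pct = Decimal(100 * n_positive) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class Split:
    """One binary stratification of the cohort."""

    name: str
    n_positive: int
    n_total: int
    positive_ids: tuple[str, ...]
    negative_ids: tuple[str, ...]

    @property
    def prevalence(self) -> float:
        return prevalence_pct(self.n_positive, self.n_total)


@dataclass
class StratificationReport:
    """The seven analysis splits plus per-test/domain impairment frequencies."""

    splits: dict[str, Split]
    impairment_table: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "split": s.name,
                "n_positive": s.n_positive,
                "n_total": s.n_total,
                "prevalence_pct": s.prevalence,
            }
            for s in self.splits.values()
        ]
        return pd.DataFrame(rows)


SPLITS = (
    "cognitive_impairment",
    "verbal_memory",
    "visual_memory",
    "processing_speed_attention",
    "verbal_fluency",
    "fatigue",
    "depression",
)


def _split_flag(profile: CognitiveProfile, split: str) -> bool | None:
    if split == "cognitive_impairment":
        return profile.cognitively_impaired
    if split == "fatigue":
        return profile.fatigued
    if split == "depression":
        return profile.depressed
    return profile.impaired_domains.get(split)


def stratify_cohort(profiles: list[CognitiveProfile]) -> StratificationReport:
    """Build the seven analysis group splits and the impairment frequency table.

    Subjects with a missing instrument are excluded from the fatigue /
    depression splits only.  A subject may appear in several splits.  An
    empty group raises a recorded warning; downstream comparisons skip
    that split.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    if any(p.cognitively_impaired is None for p in profiles):
        raise ValueError("profiles must be classified before stratification")
    splits: dict[str, Split] = {}
    notes: list[str] = []
    for name in SPLITS:
        pos, neg = [], []
        for p in profiles:
            flag = _split_flag(p, name)
            if flag is None:
                continue
            (pos if flag else neg).append(p.subject_id)
        split = Split(name, len(pos), len(pos) + len(neg), tuple(pos), tuple(neg))
        if not pos or not neg:
            msg = f"split '{name}' has an empty group (positive={len(pos)}, negative={len(neg)})"
            warnings.warn(msg, stacklevel=2)
            notes.append(msg)
        splits[name] = split

    # per-test and per-domain impairment frequencies by cognitive status
    impaired = [p for p in profiles if p.cognitively_impaired]
    preserved = [p for p in profiles if not p.cognitively_impaired]
    rows = []
    for domain, tests in DOMAINS.items():
        for test in tests:
            rows.append(_freq_row("test", test, domain, preserved, impaired,
                                  lambda p, t=test: p.failed_tests.get(t, False)))
        rows.append(_freq_row("domain", domain, domain, preserved, impaired,
                              lambda p, d=domain: p.impaired_domains.get(d, False)))
    table = pd.DataFrame(rows)
    return StratificationReport(splits=splits, impairment_table=table, warnings=notes)


def _freq_row(level, name, domain, preserved, impaired, flag):
    def _mean_z(group):
        if level == "test":
            zs = [p.z_tests.get(name) for p in group]
        else:
            zs = [p.z_domains.get(name) for p in group]
        zs = [z for z in zs if z is not None]
        return float(np.mean(zs)) if zs else math.nan

    return {
        "level": level,
        "name": name,
        "domain": domain,
        "preserved_mean_z": _mean_z(preserved),
        "preserved_n_impaired": sum(flag(p) for p in preserved),
        "preserved_n": len(preserved),
        "impaired_mean_z": _mean_z(impaired),
        "impaired_n_impaired": sum(flag(p) for p in impaired),
        "impaired_n": len(impaired),
    }


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_COVARIATE_COLUMNS = ["subject_id", "age", "sex", "education", "edss", "scanner", "course"]


def records_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {c: getattr(r, c) for c in _COVARIATE_COLUMNS}
        row.update({t: r.raw_scores.get(t) for t in TESTS})
        row.update({"mfis": r.mfis, "madrs": r.madrs, "t2lv": r.t2lv})
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(frame: pd.DataFrame) -> list[SubjectRecord]:
    records = []
    for _, row in frame.iterrows():
        raw = {t: (None if pd.isna(row[t]) else float(row[t])) for t in TESTS if t in row}
        records.append(SubjectRecord(
            subject_id=str(row["subject_id"]),
            age=float(row["age"]),
            sex=int(row["sex"]),
            education=float(row["education"]),
            edss=float(row["edss"]),
            scanner=int(row["scanner"]),
            course=str(row.get("course", "RR")),
            raw_scores=raw,
            mfis=None if pd.isna(row.get("mfis")) else float(row["mfis"]),
            madrs=None if pd.isna(row.get("madrs")) else float(row["madrs"]),
            t2lv=None if pd.isna(row.get("t2lv")) else float(row["t2lv"]),
        ))
    return records


def profiles_to_frame(profiles: list[CognitiveProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"subject_id": p.subject_id, "global_z": p.global_z}
        row.update({f"z_{t}": p.z_tests.get(t) for t in TESTS})
        row.update({f"z_{d}": p.z_domains.get(d) for d in DOMAINS})
        row.update({f"impaired_{d}": p.impaired_domains.get(d) for d in DOMAINS})
        row.update({
            "cognitively_impaired": p.cognitively_impaired,
            "fatigued": p.fatigued,
            "depressed": p.depressed,
        })
        rows.append(row)
    return pd.DataFrame(rows)
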