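"""PGCC detection and the PUB (PGCC/UBE2C) score.

A polyploid giant cancer cell (PGCC) is a tumor cell whose nucleus is at
least three times larger (in sectional area) than that of a regular cancer
cell; the regular-cell baseline is the median tumor nuclear area. A tumor
is PGCC-abundant when it averages one or more PGCC per 40x field. The PUB
score adds one point for PGCC abundance and one for moderate/strong UBE2C
immunostaining; a score of 2 is the histological surrogate call for
polyploidy, evaluated here against the FISH ploidy call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GradeValidationError, JoinError, UncallableTumorError
from .simulate import GRADES, HIGH_GRADES

#: a PGCC nucleus is at least this many times the baseline nuclear area
PGCC_AREA_RATIO = 3.0
#: PGCC-abundant means at least this many PGCCs per 40x field on average
ABUNDANCE_DENSITY = 1.0


@dataclass(frozen=True)
class PGCCSummary:
    tumor_id: str
    baseline_area: float  # median tumor nuclear area, um^2
    n_pgcc: int
    n_fields: int
    density: float  # PGCCs per 40x field
    abundant: bool


@dataclass(frozen=True)
class PUBResult:
    tumor_id: str
    pgcc_abundant: bool
    ube2c_grade: str
    score: int  # 0, 1 or 2


@dataclass(frozen=True)
class DiagnosticPerformance:
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def sensitivity(self) -> float:
        """Percent of true positives among condition-positives."""
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        """Percent of true negatives among condition-negatives."""
        return 100.0 * self.tn / (self.tn + self.fp)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fn": self.fn,
            "fp": self.fp,
            "tn": self.tn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "sensitivity_rounded": round(self.sensitivity),
            "specificity_rounded": round(self.specificity),
        }


def flag_pgccs(
    nuclei: pd.DataFrame,
    area_ratio: float = PGCC_AREA_RATIO,
    density_threshold: float = ABUNDANCE_DENSITY,
) -> PGCCSummary:
    """Count PGCCs in one tumor's nucleus table.

    The baseline is the median area over all tumor nuclei (robust while
    PGCCs remain a minority); a nucleus is a PGCC iff its area is at least
    ``area_ratio`` times the baseline (boundary inclusive). Density is the
    PGCC count divided by the number of distinct fields examined.
    """
    tumor_rows = nuclei[nuclei["is_tumor"].astype(bool)]
    if len(tumor_rows) == 0:
        ids = nuclei["tumor_id"].unique()
        label = str(ids[0]) if len(ids) else "<empty>"
        raise UncallableTumorError(f"tumor {label}: no tumor nuclei to assess PGCCs")
    tumor_id = str(tumor_rows["tumor_id"].iloc[0])
    areas = np.asarray(tumor_rows["area_um2"], dtype=float)
    baseline = float(np.median(areas))
    n_pgcc = int((areas >= area_ratio * baseline).sum())
    n_fields = int(tumor_rows["field_id"].nunique())
    density = n_pgcc / n_fields
    return PGCCSummary(
        tumor_id=tumor_id,
        baseline_area=baseline,
        n_pgcc=n_pgcc,
        n_fields=n_fields,
        density=density,
        abundant=bool(density >= density_threshold),
    )


def grade_ube2c(grade) -> str:
    """Normalize an ordinal IHC grade string.

    Accepted (case-insensitive, surrounding whitespace ignored):
    negative, weak, moderate, strong.
    """
    if not isinstance(grade, str):
        raise GradeValidationError(
            f"IHC grade must be a string, got {type(grade).__name__}; "
            f"allowed values: {', '.join(GRADES)}"
        )
    norm = grade.strip().lower()
    if norm not in GRADES:
        raise GradeValidationError(
            f"unrecognized IHC grade {grade!r}; allowed values: {', '.join(GRADES)}"
        )
    return norm


def pub_score(pgcc_abundant: bool, ube2c_grade: str) -> int:
    """PUB score: one point for PGCC abundance, one for UBE2C moderate/strong."""
    grade = grade_ube2c(ube2c_grade)
    return int(bool(pgcc_abundant)) + int(grade in HIGH_GRADES)


def score_cohort(nuclei: pd.DataFrame, ihc: pd.DataFrame) -> pd.DataFrame:
    """Per-tumor PUB table (pub.csv schema) from nuclei and IHC grades."""
    pgcc = {
        str(tid): flag_pgccs(group)
        for tid, group in nuclei.groupby("tumor_id", sort=True)
    }
    ihc_ids = set(ihc["tumor_id"].astype(str))
    missing = sorted(set(pgcc) ^ ihc_ids)
    if missing:
        raise JoinError(
            f"nuclei and IHC tables disagree on tumor_ids; difference: {missing}"
        )
    rows = []
    for _, row in ihc.sort_values("tumor_id").iterrows():
        tid = str(row["tumor_id"])
        s = pgcc[tid]
        grade = grade_ube2c(row["ube2c_grade"])
        rows.append(
            {
                "tumor_id": tid,
                "baseline_area_um2": s.baseline_area,
                "pgcc_density": s.density,
                "pgcc_abundant": s.abundant,
                "ube2c_grade": grade,
                "pub_score": pub_score(s.abundant, grade),
            }
        )
    return pd.DataFrame(rows)


def evaluate_pub(
    pub_results: pd.DataFrame, tumor_profiles: pd.DataFrame
) -> DiagnosticPerformance:
    """Diagnostic performance of "PUB score = 2 predicts polyploidy".

    Cross-tabulates (pub_score == 2) against (call == polyploid) over the
    shared tumor_id set and reports the 2x2 counts with sensitivity and
    specificity percentages.
    """
    pub_ids = set(pub_results["tumor_id"].astype(str))
    prof_ids = set(tumor_profiles["tumor_id"].astype(str))
    if pub_ids != prof_ids:
        raise JoinError(
            "PUB and profile tables disagree on tumor_ids; difference: "
            f"{sorted(pub_ids ^ prof_ids)}"
        )
    merged = pub_results.merge(tumor_profiles[["tumor_id", "call"]], on="tumor_id")
    predicted = merged["pub_score"].astype(int) == 2
    actual = merged["call"] == "polyploid"
    return DiagnosticPerformance(
        tp=int((predicted & actual).sum()),
        fn=int((~predicted & actual).sum()),
        fp=int((predicted & ~actual).sum()),
        tn=int((~predicted & ~actual).sum()),
    )
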