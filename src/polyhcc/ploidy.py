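"""Tumor ploidy calling from per-nucleus FISH spot counts.

For each of the three probes (pericentromeres of chromosomes 7, 11 and 16)
the predominant (modal) nonzero spot count across tumor nuclei is taken as
the tumor's copy number for that chromosome; the average of the three is
the tumor's ploidy statistic, and a tumor is called polyploid when that
average is at least 2.5 (boundary inclusive).

Zero spot counts are treated as hybridization failure and excluded
probe-wise; ties in the mode are broken toward the larger count, because
FFPE sectioning only removes signals and thus biases counts downward.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import UncallableProbeError, UncallableTumorError

#: probe short names mapped to nuclei-table columns
PROBE_COLUMNS = {"chr7": "spots_chr7", "chr11": "spots_chr11", "chr16": "spots_chr16"}
POLYPLOID_THRESHOLD = 2.5
MIN_NUCLEI_DEFAULT = 200
MIN_FIELDS_DEFAULT = 5


@dataclass(frozen=True)
class TumorProfile:
    """Per-tumor ploidy call."""

    tumor_id: str
    c7: int
    c11: int
    c16: int
    average_ploidy: float
    call: str  # "near_diploid" | "polyploid"
    n_nuclei_used: int
    n_fields: int
    qc_pass: bool

    @property
    def predominant(self) -> tuple[int, int, int]:
        return (self.c7, self.c11, self.c16)


@dataclass(frozen=True)
class CohortCallResult:
    profiles: pd.DataFrame
    n_tumors: int
    n_polyploid: int
    pct_polyploid: float
    mean_ploidy_polyploid: float  # NaN when no tumor is called polyploid


def classify_ploidy(average_ploidy: float, threshold: float = POLYPLOID_THRESHOLD) -> str:
    """Classify a tumor from its average predominant copy number.

    Polyploid when the average is at or above the threshold (an average of
    exactly 2.5 is polyploid), near-diploid below.
    """
    return "polyploid" if average_ploidy >= threshold else "near_diploid"


def predominant_copy_number(nuclei: pd.DataFrame, probe: str) -> int:
    """Modal nonzero spot count for ``probe`` over tumor nuclei.

    Parameters
    ----------
    nuclei:
        Per-nucleus table with the nuclei.csv schema. Only rows with
        ``is_tumor`` are considered.
    probe:
        One of ``"chr7"``, ``"chr11"``, ``"chr16"``.

    Raises
    ------
    UncallableProbeError
        If no tumor nucleus has a nonzero count for the probe.
    """
    if probe not in PROBE_COLUMNS:
        raise ValueError(f"unknown probe {probe!r}; expected one of {list(PROBE_COLUMNS)}")
    counts = np.asarray(
        nuclei.loc[nuclei["is_tumor"].astype(bool), PROBE_COLUMNS[probe]], dtype=int
    )
    counts = counts[counts > 0]
    if counts.size == 0:
        raise UncallableProbeError(
            f"probe {probe}: no nonzero spot counts among tumor nuclei"
        )
    freq = np.bincount(counts)
    # argmax on the reversed array finds the largest value among tied modes
    best = len(freq) - 1 - int(np.argmax(freq[::-1]))
    return best


def call_tumor(
    nuclei: pd.DataFrame,
    min_nuclei: int = MIN_NUCLEI_DEFAULT,
    min_fields: int = MIN_FIELDS_DEFAULT,
    threshold: float = POLYPLOID_THRESHOLD,
) -> TumorProfile:
    """Call one tumor's ploidy from its per-nucleus spot counts.

    All rows must share one tumor_id. Sampling below ``min_nuclei`` tumor
    nuclei or ``min_fields`` fields clears ``qc_pass`` but still yields a
    call; an empty table or an uncallable probe raises
    :class:`UncallableTumorError`.
    """
    if len(nuclei) == 0:
        raise UncallableTumorError("empty nucleus table")
    ids = nuclei["tumor_id"].unique()
    if len(ids) != 1:
        raise ValueError(f"call_tumor expects one tumor, got tumor_ids {sorted(ids)}")
    tumor_id = str(ids[0])
    tumor_rows = nuclei[nuclei["is_tumor"].astype(bool)]
    if len(tumor_rows) == 0:
        raise UncallableTumorError(f"tumor {tumor_id}: no tumor nuclei")

    triple = []
    for probe in PROBE_COLUMNS:
        try:
            triple.append(predominant_copy_number(nuclei, probe))
        except UncallableProbeError as exc:
            raise UncallableTumorError(f"tumor {tumor_id}: {exc}") from exc
    average = sum(triple) / 3.0
    n_used = int(len(tumor_rows))
    n_fields = int(tumor_rows["field_id"].nunique())
    return TumorProfile(
        tumor_id=tumor_id,
        c7=triple[0],
        c11=triple[1],
        c16=triple[2],
        average_ploidy=average,
        call=classify_ploidy(average, threshold),
        n_nuclei_used=n_used,
        n_fields=n_fields,
        qc_pass=bool(n_used >= min_nuclei and n_fields >= min_fields),
    )


def call_cohort(
    nuclei: pd.DataFrame,
    min_nuclei: int = MIN_NUCLEI_DEFAULT,
    min_fields: int = MIN_FIELDS_DEFAULT,
    threshold: float = POLYPLOID_THRESHOLD,
) -> CohortCallResult:
    """Call every tumor in a cohort nucleus table.

    Returns the per-tumor profile table plus cohort summary statistics:
    the polyploid count, percentage, and the mean average-ploidy within
    the polyploid-called group.
    """
    if len(nuclei) == 0:
        raise UncallableTumorError("empty cohort nucleus table")
    rows = []
    for tumor_id, group in nuclei.groupby("tumor_id", sort=True):
        profile = call_tumor(
            group, min_nuclei=min_nuclei, min_fields=min_fields, threshold=threshold
        )
        rows.append(asdict(profile))
    profiles = pd.DataFrame(rows)
    n_tumors = len(profiles)
    poly = profiles[profiles["call"] == "polyploid"]
    n_poly = len(poly)
    return CohortCallResult(
        profiles=profiles,
        n_tumors=n_tumors,
        n_polyploid=n_poly,
        pct_polyploid=100.0 * n_poly / n_tumors,
        mean_ploidy_polyploid=(
            float(poly["average_ploidy"].mean()) if n_poly else float("nan")
        ),
    )
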