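"""Nuclear image cytometry: DNA content from integrated DAPI intensity.

Integrated nuclear DAPI fluorescence is proportional to DNA content, but
the proportionality constant (staining gain) varies slide to slide. Each
tumor's intensities are therefore normalized against a diploid reference
population from the same section — by default the non-tumor nuclei
(stroma, lymphocytes) — whose modal intensity is anchored at 2C. Nuclei
are gated to HNF4a-positive / Ki-67-negative tumor cells so that measured
DNA reflects ploidy rather than S/G2/M replication, then binned into
doubling classes (2C / 4C / 8C / >=8C) at half-integer log2 boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyGateError, EmptyGroupError, InsufficientReferenceError
from .stats import MannWhitneyResult, mann_whitney_one_sided

#: log2 histogram bin width used to locate the reference 2C intensity mode
MODE_BIN_WIDTH_LOG2 = 0.05
MIN_REFERENCE_NUCLEI = 20
#: class bins on log2(c_value): [-inf,1.5) 2C, [1.5,2.5) 4C, [2.5,3.5) 8C, >=3.5 high
CLASS_BIN_EDGES = (1.5, 2.5, 3.5)
CLASS_NAMES = ("2c", "4c", "8c", "ge8c")


@dataclass(frozen=True)
class DnaIndexProfile:
    """Per-tumor DNA-content profile of the gated nuclei."""

    tumor_id: str
    c_value: np.ndarray  # per gated nucleus, in C units
    class_fractions: dict[str, float]
    median_area: float
    median_c: float


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    values_a: np.ndarray
    values_b: np.ndarray
    test: MannWhitneyResult


def gate_nuclei(nuclei: pd.DataFrame, tumor_id: str | None = None) -> pd.DataFrame:
    """Select tumor, HNF4a-positive, Ki-67-negative nuclei (order preserved).

    Ki-67-positive nuclei are excluded because cycling diploid cells carry
    more than 2C DNA and would inflate the apparent ploidy.
    """
    mask = (
        nuclei["is_tumor"].astype(bool)
        & nuclei["hnf4a_pos"].astype(bool)
        & ~nuclei["ki67_pos"].astype(bool)
    )
    gated = nuclei[mask]
    if len(gated) == 0:
        label = tumor_id if tumor_id is not None else "<unknown>"
        raise EmptyGateError(
            f"tumor {label}: no HNF4a-positive/Ki-67-negative tumor nuclei"
        )
    return gated


def _histogram_mode(values: np.ndarray, bin_width: float) -> float:
    """Mode of a positive-valued sample via a fixed-width log2 histogram.

    Bins are centered on the sample minimum so a degenerate (constant)
    sample returns its value exactly.
    """
    logs = np.log2(values)
    lo, hi = float(logs.min()), float(logs.max())
    n_bins = int(np.ceil((hi - lo) / bin_width)) + 1
    edges = (lo - bin_width / 2.0) + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(logs, bins=edges)
    k = int(np.argmax(counts))
    return float(2.0 ** (lo + k * bin_width))


def normalize_dna_content(
    gated: pd.DataFrame,
    reference: pd.DataFrame,
    tumor_id: str | None = None,
) -> DnaIndexProfile:
    """Convert integrated DAPI intensity to DNA content in C units.

    ``c_value = 2 * dapi / mode(reference dapi)`` where the reference is a
    diploid population from the same section and its modal intensity is
    located on a log2 histogram of width 0.05. The result is invariant to
    the per-tumor staining gain.
    """
    if len(reference) < MIN_REFERENCE_NUCLEI:
        raise InsufficientReferenceError(
            f"need >= {MIN_REFERENCE_NUCLEI} diploid reference nuclei, "
            f"got {len(reference)}"
        )
    if tumor_id is None:
        ids = gated["tumor_id"].unique()
        tumor_id = str(ids[0]) if len(ids) == 1 else "<multiple>"
    ref_mode = _histogram_mode(
        np.asarray(reference["dapi_integrated"], dtype=float), MODE_BIN_WIDTH_LOG2
    )
    c_value = 2.0 * np.asarray(gated["dapi_integrated"], dtype=float) / ref_mode
    log2c = np.log2(c_value)
    edges = np.array([-np.inf, *CLASS_BIN_EDGES, np.inf])
    counts, _ = np.histogram(log2c, bins=edges)
    fractions = {
        name: float(c) / len(c_value) for name, c in zip(CLASS_NAMES, counts)
    }
    return DnaIndexProfile(
        tumor_id=tumor_id,
        c_value=c_value,
        class_fractions=fractions,
        median_area=float(np.median(gated["area_um2"])),
        median_c=float(np.median(c_value)),
    )


def profile_tumor(nuclei: pd.DataFrame, tumor_id: str | None = None) -> DnaIndexProfile:
    """Gate and normalize one tumor's table, using its non-tumor nuclei
    as the diploid reference."""
    if tumor_id is None:
        ids = nuclei["tumor_id"].unique()
        if len(ids) != 1:
            raise ValueError("profile_tumor expects a single tumor's table")
        tumor_id = str(ids[0])
    gated = gate_nuclei(nuclei, tumor_id=tumor_id)
    reference = nuclei[~nuclei["is_tumor"].astype(bool)]
    return normalize_dna_content(gated, reference, tumor_id=tumor_id)


def profile_cohort(nuclei: pd.DataFrame) -> pd.DataFrame:
    """Per-tumor cytometry table (cytometry.csv schema) for a cohort."""
    rows = []
    for tumor_id, group in nuclei.groupby("tumor_id", sort=True):
        p = profile_tumor(group, tumor_id=str(tumor_id))
        rows.append(
            {
                "tumor_id": p.tumor_id,
                "median_c": p.median_c,
                "median_area_um2": p.median_area,
                **{f"frac_{k}": v for k, v in p.class_fractions.items()},
            }
        )
    return pd.DataFrame(rows)


def compare_groups(
    profiles_a: list[DnaIndexProfile],
    profiles_b: list[DnaIndexProfile],
    metric: str = "median_c",
) -> GroupComparison:
    """One-sided Mann-Whitney comparison of a per-tumor cytometry metric.

    Alternative: group A (polyploid) stochastically greater than group B
    (near-diploid).
    """
    if metric not in ("median_c", "median_area"):
        raise ValueError(f"metric must be 'median_c' or 'median_area', got {metric!r}")
    if len(profiles_a) == 0 or len(profiles_b) == 0:
        raise EmptyGroupError("compare_groups: both groups must be non-empty")
    a = np.array([getattr(p, metric) for p in profiles_a], dtype=float)
    b = np.array([getattr(p, metric) for p in profiles_b], dtype=float)
    test = mann_whitney_one_sided(a, b, alternative="greater")
    return GroupComparison(metric=metric, values_a=a, values_b=b, test=test)
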