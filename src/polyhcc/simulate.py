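"""Synthetic HCC cohort generator.

Generates seeded cohorts whose statistical structure mirrors a surgical
hepatocellular-carcinoma series in which roughly one third of tumors have
undergone whole-genome doubling: per-nucleus FISH spot counts for the
pericentromeres of chromosomes 7, 11 and 16 with FFPE signal dropout,
nuclear area and integrated DAPI intensity proportional to DNA content,
polyploid giant cancer cells (PGCCs) planted at a per-field rate, ordinal
UBE2C/AURKA/TOP2A immunohistochemistry grades conditional on ploidy class,
lognormal serum AFP, and exponential survival with uniform right-censoring.

Every draw comes from a NumPy generator seeded from the cohort seed;
per-tumor sub-streams are keyed by tumor index so the output is
reproducible and insensitive to generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError

GRADES = ("negative", "weak", "moderate", "strong")
#: seeds of the twenty reference replicates used for stochastic checks
DOCUMENTED_SEEDS = tuple(range(1, 21))
HIGH_GRADES = ("moderate", "strong")
CLASSES = ("near_diploid", "polyploid")
PROBES = ("chr7", "chr11", "chr16")

#: nuclear area of a diploid (2C) hepatocyte nucleus in a tissue section
AREA_DIPLOID_UM2 = 40.0
#: multiplicative noise on nuclear area (coefficient of variation)
AREA_CV = 0.15
#: multiplicative noise on integrated DAPI intensity per nucleus
DAPI_CV = 0.10
#: spread of the per-tumor DAPI staining gain (slide-to-slide variation)
GAIN_CV = 0.30
#: fraction of tumor nuclei staining HNF4a-positive
HNF4A_RATE_TUMOR = 0.95
#: fraction of cycling (Ki-67+) nuclei among tumor / non-tumor nuclei
KI67_RATE_TUMOR = 0.15
KI67_RATE_NONTUMOR = 0.02
#: DNA-content multiples (relative to the tumor clone) of planted PGCCs.
#: The PGCC rule flags nuclei with >= 3x the baseline area, i.e. >= 3^(3/2)
#: ~ 5.2x the clone DNA content under the area model, so only cells at
#: least three doublings above the clone qualify; 2x-doubled (4x DNA)
#: giants fall below the area cutoff and are not planted as PGCCs.
PGCC_PLOIDY_FACTORS = (8, 16)


def _ln_sigma(cv: float) -> float:
    """Lognormal shape parameter for a given coefficient of variation."""
    return math.sqrt(math.log1p(cv * cv))


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Median-1 multiplicative lognormal noise."""
    if cv <= 0:
        return np.ones(size)
    return rng.lognormal(mean=0.0, sigma=_ln_sigma(cv), size=size)


@dataclass(frozen=True)
class MarkerConditionals:
    """P(marker category | ploidy class) for the two PUB-score components.

    Each tuple is (both, ube2c_only, pgcc_only, neither), where "both"
    means PGCC-abundant AND UBE2C moderate/strong, the categories a tumor's
    PUB score is built from. The defaults put 15/20 polyploid and 3/36
    near-diploid tumors in the "both" cell of the default 56-tumor cohort,
    i.e. 75% sensitivity and 33/36 = 92% specificity of the PUB=2 rule.
    """

    polyploid: tuple[float, float, float, float] = (0.75, 0.20, 0.0, 0.05)
    near_diploid: tuple[float, float, float, float] = (3 / 36, 8 / 36, 0.0, 25 / 36)

    def validate(self) -> None:
        for name in CLASSES:
            probs = getattr(self, name)
            if len(probs) != 4 or any(p < 0 or p > 1 for p in probs):
                raise ConfigError(
                    f"marker_conditionals.{name}: probabilities must lie in [0, 1]"
                )
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigError(
                    f"marker_conditionals.{name}: probabilities must sum to 1"
                )

    def for_class(self, true_class: str) -> tuple[float, float, float, float]:
        return getattr(self, true_class)


@dataclass
class GeneratorConfig:
    """All parameters of the synthetic cohort.

    Defaults reproduce the study-mirror cohort: 56 tumors of which 20 are
    polyploid, 250 nuclei per tumor over 6 high-magnification fields, 10%
    per-signal FISH dropout plus 5% whole-nucleus hybridization failure.
    """

    n_tumors: int = 56
    prevalence_polyploid: float = 20 / 56
    truth_mode: str = "stratified"  # {"stratified", "stochastic"}
    nuclei_per_tumor: int = 250
    fields_per_tumor: int = 6
    nontumor_fraction: float = 0.2
    signal_dropout: float = 0.10
    hyb_failure: float = 0.05
    p_tetrasomy_polyploid: float = 0.14
    p_trisomy_neardiploid: float = 0.3
    pgcc_rate_polyploid: float = 2.0
    pgcc_rate_neardiploid: float = 0.1
    marker_conditionals: MarkerConditionals = field(default_factory=MarkerConditionals)
    afp_median_neardiploid: float = 9.8
    afp_median_polyploid: float = 193.0
    afp_log_sd: float = 2.0
    hazard_neardiploid: float = 0.08
    hazard_ratio_polyploid: float = 3.5
    censor_window: tuple[float, float] = (0.5, 5.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_tumors < 1:
            raise ConfigError("n_tumors: must be >= 1")
        for name in (
            "prevalence_polyploid",
            "nontumor_fraction",
            "signal_dropout",
            "hyb_failure",
            "p_tetrasomy_polyploid",
            "p_trisomy_neardiploid",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}: must lie in [0, 1], got {v}")
        if self.truth_mode not in ("stratified", "stochastic"):
            raise ConfigError(
                f"truth_mode: must be 'stratified' or 'stochastic', got {self.truth_mode!r}"
            )
        if self.nuclei_per_tumor < 1:
            raise ConfigError("nuclei_per_tumor: must be >= 1")
        if self.fields_per_tumor < 1:
            raise ConfigError("fields_per_tumor: must be >= 1")
        for name in ("pgcc_rate_polyploid", "pgcc_rate_neardiploid"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name}: must be >= 0")
        for name in ("afp_median_neardiploid", "afp_median_polyploid", "afp_log_sd"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name}: must be > 0")
        if self.hazard_neardiploid <= 0:
            raise ConfigError("hazard_neardiploid: must be > 0")
        if self.hazard_ratio_polyploid <= 0:
            raise ConfigError("hazard_ratio_polyploid: must be > 0")
        lo, hi = self.censor_window
        if not (0 < lo <= hi):
            raise ConfigError(f"censor_window: need 0 < lo <= hi, got {self.censor_window}")
        self.marker_conditionals.validate()


@dataclass
class TumorTruth:
    """Latent per-tumor state the downstream callers must recover."""

    tumor_id: str
    true_class: str
    true_copies: tuple[int, int, int]
    pgcc_rate: float
    pgcc_abundant_true: bool
    ube2c_grade_true: str
    afp: float
    hazard: float

    @property
    def mean_copies(self) -> float:
        return sum(self.true_copies) / 3.0

    @property
    def c_value(self) -> float:
        """DNA content of the clone in C units; (2,2,2) corresponds to 2C."""
        return 2.0 * self.mean_copies / 2.0


@dataclass
class CohortDataset:
    """One generated cohort: latent truths plus the four observable tables."""

    truths: list[TumorTruth]
    nuclei: pd.DataFrame
    ihc: pd.DataFrame
    clinical: pd.DataFrame
    survival: pd.DataFrame
    config: GeneratorConfig


def _cohort_rng(config: GeneratorConfig) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(config.seed), 0)))


def _tumor_rng(config: GeneratorConfig, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(config.seed), 1, index)))


def _largest_remainder_counts(probs: tuple[float, ...], n: int) -> list[int]:
    """Integer allocation of n items to categories, preserving sum(n)."""
    raw = [p * n for p in probs]
    counts = [int(math.floor(r)) for r in raw]
    short = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:short]:
        counts[i] += 1
    return counts


def _draw_true_copies(true_class: str, config: GeneratorConfig,
                      rng: np.random.Generator) -> tuple[int, int, int]:
    if true_class == "polyploid":
        # Duplicated genomes: each chromosome predominantly at 4 copies with
        # probability p_tetrasomy_polyploid, otherwise at 3 (post-doubling
        # loss), giving mean ploidy 3 + p_tetrasomy.
        copies = 3 + (rng.random(3) < config.p_tetrasomy_polyploid).astype(int)
        return tuple(int(c) for c in copies)
    copies = [2, 2, 2]
    if rng.random() < config.p_trisomy_neardiploid:
        copies[int(rng.integers(3))] = 3
    return tuple(copies)


def assign_marker_profile(
    truths: list[TumorTruth], config: GeneratorConfig, rng: np.random.Generator
) -> list[TumorTruth]:
    """Assign UBE2C grade and PGCC-abundance designation to each tumor.

    In stratified mode the marker categories are allocated as exact
    largest-remainder counts of the class conditionals within each ploidy
    class (randomly permuted over tumors), so the cohort-level 2x2 table of
    (PUB = 2) against true class is fixed; in stochastic mode each tumor
    samples its category independently.

    Returns new TumorTruth objects with ``pgcc_rate``, ``pgcc_abundant_true``
    and ``ube2c_grade_true`` filled in.
    """
    config.marker_conditionals.validate()
    # categories: 0 = both, 1 = ube2c only, 2 = pgcc only, 3 = neither
    category: dict[str, int] = {}
    if config.truth_mode == "stratified":
        for cls in CLASSES:
            ids = [t.tumor_id for t in truths if t.true_class == cls]
            if not ids:
                continue
            counts = _largest_remainder_counts(
                config.marker_conditionals.for_class(cls), len(ids)
            )
            cats = np.repeat(np.arange(4), counts)
            rng.shuffle(cats)
            category.update(zip(ids, (int(c) for c in cats)))
    else:
        for t in truths:
            probs = config.marker_conditionals.for_class(t.true_class)
            category[t.tumor_id] = int(rng.choice(4, p=probs))

    out: list[TumorTruth] = []
    for t in truths:
        cat = category[t.tumor_id]
        abundant = cat in (0, 2)
        ube2c_high = cat in (0, 1)
        grade = str(rng.choice(HIGH_GRADES)) if ube2c_high \
            else str(rng.choice(("negative", "weak")))
        rate = config.pgcc_rate_polyploid if abundant else config.pgcc_rate_neardiploid
        out.append(replace(
            t,
            pgcc_rate=rate,
            pgcc_abundant_true=abundant,
            ube2c_grade_true=grade,
        ))
    return out


def generate_tumor_nuclei(
    truth: TumorTruth, config: GeneratorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Generate the per-nucleus measurement table for one tumor.

    Tumor nuclei carry the clone's true copy triple; observed spot counts
    are Binomial(true copy, 1 - signal_dropout) per probe, zeroed for all
    probes with probability ``hyb_failure`` (whole-nucleus hybridization
    failure). Non-tumor nuclei (stroma/lymphocytes) are diploid and
    HNF4a-negative. PGCC nuclei are planted at ``truth.pgcc_rate`` per
    field: a Poisson count in stochastic mode, the exact rounded count in
    stratified mode. Integrated DAPI is gain * C with 10% CV noise under a
    per-tumor staining gain; nuclear area is 40 um^2 * (C/2)^(2/3) with
    15% CV noise. Cycling (Ki-67+) nuclei carry 1-2x replicating DNA.
    """
    n_total = config.nuclei_per_tumor
    n_nontumor = int(round(config.nontumor_fraction * n_total))
    n_tumor = n_total - n_nontumor
    if config.truth_mode == "stratified":
        n_pgcc = int(round(truth.pgcc_rate * config.fields_per_tumor))
    else:
        n_pgcc = int(rng.poisson(truth.pgcc_rate * config.fields_per_tumor))

    n = n_tumor + n_pgcc + n_nontumor
    is_tumor = np.zeros(n, dtype=bool)
    is_tumor[: n_tumor + n_pgcc] = True

    # true DNA content in C units and true copy triples
    clone_c = truth.c_value
    c_value = np.full(n, 2.0)
    c_value[:n_tumor] = clone_c
    copies = np.full((n, 3), 2, dtype=int)
    copies[:n_tumor] = truth.true_copies
    if n_pgcc:
        factors = rng.choice(PGCC_PLOIDY_FACTORS, size=n_pgcc)
        c_value[n_tumor : n_tumor + n_pgcc] = clone_c * factors
        copies[n_tumor : n_tumor + n_pgcc] = (
            np.asarray(truth.true_copies)[None, :] * factors[:, None]
        )

    # marker flags; Ki-67+ nuclei are in S/G2/M and carry replicating DNA
    hnf4a = np.zeros(n, dtype=bool)
    hnf4a[: n_tumor + n_pgcc] = rng.random(n_tumor + n_pgcc) < HNF4A_RATE_TUMOR
    ki67 = np.where(
        is_tumor,
        rng.random(n) < KI67_RATE_TUMOR,
        rng.random(n) < KI67_RATE_NONTUMOR,
    )
    c_eff = c_value * np.where(ki67, rng.uniform(1.0, 2.0, size=n), 1.0)

    gain = float(_lognormal_noise(rng, GAIN_CV, 1)[0])
    dapi = gain * c_eff * _lognormal_noise(rng, DAPI_CV, n)
    area = AREA_DIPLOID_UM2 * (c_eff / 2.0) ** (2.0 / 3.0) * _lognormal_noise(
        rng, AREA_CV, n
    )

    # FFPE noise on spot counts: per-signal binomial thinning + whole-nucleus
    # hybridization failure
    spots = rng.binomial(copies, 1.0 - config.signal_dropout)
    failed = rng.random(n) < config.hyb_failure
    spots[failed] = 0

    # round-robin field assignment guarantees every field is represented
    field_id = (np.arange(n) % config.fields_per_tumor) + 1
    return pd.DataFrame(
        {
            "tumor_id": truth.tumor_id,
            "field_id": field_id,
            "nucleus_id": [f"{truth.tumor_id}-N{i:04d}" for i in range(n)],
            "spots_chr7": spots[:, 0],
            "spots_chr11": spots[:, 1],
            "spots_chr16": spots[:, 2],
            "area_um2": area,
            "dapi_integrated": dapi,
            "hnf4a_pos": hnf4a,
            "ki67_pos": ki67,
            "is_tumor": is_tumor,
        }
    )


def generate_survival(
    truth: TumorTruth, config: GeneratorConfig, rng: np.random.Generator
) -> dict:
    """One survival record: exponential event time, uniform right-censoring."""
    t_event = rng.exponential(1.0 / truth.hazard)
    t_censor = rng.uniform(*config.censor_window)
    event = bool(t_event <= t_censor)
    return {
        "tumor_id": truth.tumor_id,
        "time_years": float(min(t_event, t_censor)),
        "event": event,
    }


def _sample_secondary_grades(
    truth: TumorTruth, rng: np.random.Generator
) -> tuple[str, str]:
    """AURKA (ploidy-associated) and TOP2A (ploidy-independent) IHC grades."""
    p_high_aurka = 0.8 if truth.true_class == "polyploid" else 0.25
    aurka = str(rng.choice(HIGH_GRADES)) if rng.random() < p_high_aurka \
        else str(rng.choice(("negative", "weak")))
    top2a = str(rng.choice(GRADES))
    return aurka, top2a


def generate_cohort(config: GeneratorConfig) -> CohortDataset:
    """Generate a full synthetic cohort from a validated configuration.

    Deterministic given ``config.seed``; in stratified mode exactly
    ``round(n_tumors * prevalence_polyploid)`` tumors are polyploid.
    """
    config.validate()
    rng = _cohort_rng(config)
    n = config.n_tumors

    if config.truth_mode == "stratified":
        n_poly = int(round(n * config.prevalence_polyploid))
        labels = np.array(["near_diploid"] * (n - n_poly) + ["polyploid"] * n_poly)
        rng.shuffle(labels)
    else:
        labels = np.where(
            rng.random(n) < config.prevalence_polyploid, "polyploid", "near_diploid"
        )

    truths: list[TumorTruth] = []
    for i, cls in enumerate(labels):
        cls = str(cls)
        afp_median = (
            config.afp_median_polyploid if cls == "polyploid"
            else config.afp_median_neardiploid
        )
        hazard = config.hazard_neardiploid * (
            config.hazard_ratio_polyploid if cls == "polyploid" else 1.0
        )
        truths.append(
            TumorTruth(
                tumor_id=f"T{i + 1:03d}",
                true_class=cls,
                true_copies=_draw_true_copies(cls, config, rng),
                pgcc_rate=0.0,
                pgcc_abundant_true=False,
                ube2c_grade_true="negative",
                afp=float(afp_median * rng.lognormal(0.0, config.afp_log_sd)),
                hazard=hazard,
            )
        )
    truths = assign_marker_profile(truths, config, rng)

    nuclei_parts = []
    survival_rows = []
    ihc_rows = []
    for i, truth in enumerate(truths):
        trng = _tumor_rng(config, i)
        nuclei_parts.append(generate_tumor_nuclei(truth, config, trng))
        survival_rows.append(generate_survival(truth, config, trng))
        aurka, top2a = _sample_secondary_grades(truth, trng)
        ihc_rows.append(
            {
                "tumor_id": truth.tumor_id,
                "ube2c_grade": truth.ube2c_grade_true,
                "aurka_grade": aurka,
                "top2a_grade": top2a,
                "pgcc_per_field": truth.pgcc_rate,
            }
        )

    nuclei = pd.concat(nuclei_parts, ignore_index=True)
    clinical = pd.DataFrame(
        {
            "tumor_id": [t.tumor_id for t in truths],
            "afp_ng_ml": [t.afp for t in truths],
            "true_class": [t.true_class for t in truths],
        }
    )
    return CohortDataset(
        truths=truths,
        nuclei=nuclei,
        ihc=pd.DataFrame(ihc_rows),
        clinical=clinical,
        survival=pd.DataFrame(survival_rows),
        config=config,
    )
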