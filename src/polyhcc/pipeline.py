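"""End-to-end pipeline: simulate -> call-ploidy -> cytometry -> pub -> stats.

Each stage writes its canonical CSV/JSON output into the run directory and
the run manifest records the configuration snapshot, seed, package version
and a SHA-256 hash of every output so deterministic stages can be verified
byte-for-byte across re-runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError
from .io import read_table, write_table
from .cytometry import profile_cohort
from .ploidy import call_cohort
from .pub import evaluate_pub, score_cohort
from .simulate import GeneratorConfig, MarkerConditionals, generate_cohort
from .stats import km_logrank, mann_whitney_one_sided

log = logging.getLogger("polyhcc")


def load_config(path) -> GeneratorConfig:
    """Load a GeneratorConfig from a YAML key-value file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping of GeneratorConfig fields")
    return config_from_dict(data)


def config_from_dict(data: dict) -> GeneratorConfig:
    known = {f.name for f in dataclasses.fields(GeneratorConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"unknown config field(s): {', '.join(unknown)}")
    data = dict(data)
    if "marker_conditionals" in data and isinstance(data["marker_conditionals"], dict):
        mc = data["marker_conditionals"]
        data["marker_conditionals"] = MarkerConditionals(
            polyploid=tuple(mc.get("polyploid", MarkerConditionals().polyploid)),
            near_diploid=tuple(mc.get("near_diploid", MarkerConditionals().near_diploid)),
        )
    if "censor_window" in data:
        data["censor_window"] = tuple(data["censor_window"])
    config = GeneratorConfig(**data)
    config.validate()
    return config


def config_to_dict(config: GeneratorConfig) -> dict:
    d = dataclasses.asdict(config)
    d["marker_conditionals"] = {
        "polyploid": list(config.marker_conditionals.polyploid),
        "near_diploid": list(config.marker_conditionals.near_diploid),
    }
    d["censor_window"] = list(config.censor_window)
    return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stats_stage(out: Path) -> None:
    """Cohort comparisons and survival stratification from stage outputs."""
    clinical = read_table(out / "clinical.csv", "clinical")
    survival = read_table(out / "survival.csv", "survival")
    profiles = read_table(out / "tumor_profiles.csv", "tumor_profiles")
    cyto = read_table(out / "cytometry.csv", "cytometry")
    pub = read_table(out / "pub.csv", "pub")

    call = profiles[["tumor_id", "call"]]
    report = []

    def split(df, col):
        m = df.merge(call, on="tumor_id")
        return (
            m.loc[m["call"] == "polyploid", col].to_numpy(float),
            m.loc[m["call"] == "near_diploid", col].to_numpy(float),
        )

    # one-sided rank tests, alternative: polyploid > near-diploid
    for name, df, col in (
        ("afp_polyploid_gt_neardiploid", clinical, "afp_ng_ml"),
        ("median_c_polyploid_gt_neardiploid", cyto, "median_c"),
        ("median_area_polyploid_gt_neardiploid", cyto, "median_area_um2"),
    ):
        a, b = split(df, col)
        if a.size and b.size:
            r = mann_whitney_one_sided(a, b, alternative="greater")
            report.append(
                {
                    "comparison": name,
                    "test": "mann_whitney_one_sided",
                    "direction": "polyploid > near_diploid",
                    "statistic": r.u_statistic,
                    "p_value": r.p_value,
                    "n_polyploid": r.n_x,
                    "n_near_diploid": r.n_y,
                    "method": r.method,
                }
            )

    # survival stratified by ploidy call and by PUB score
    surv = survival.merge(call, on="tumor_id").merge(
        pub[["tumor_id", "pub_score"]], on="tumor_id"
    )
    curves_frames = []
    strata = [
        ("os_by_ploidy", surv["call"], "polyploid", "near_diploid"),
        (
            "os_by_pub",
            surv["pub_score"].map(lambda s: "pub2" if s == 2 else "pub01"),
            "pub2",
            "pub01",
        ),
    ]
    for name, groups, a, b in strata:
        records = pd.DataFrame(
            {"time": surv["time_years"], "event": surv["event"], "group": groups}
        )
        if (records["group"] == a).any() and (records["group"] == b).any() and records["event"].any():
            r = km_logrank(records, a, b)
            report.append(
                {
                    "comparison": name,
                    "test": "logrank_two_sided",
                    "direction": f"{a} vs {b}",
                    "statistic": r.statistic,
                    "p_value": r.p_value,
                    "n_a": int((records["group"] == a).sum()),
                    "n_b": int((records["group"] == b).sum()),
                }
            )
            c = r.curves.copy()
            c["group"] = f"{name}:" + c["group"].astype(str)
            curves_frames.append(c)
        else:
            log.warning("stats: skipping %s (a group is empty or no events)", name)

    (out / "stats_report.json").write_text(json.dumps(report, indent=2))
    if curves_frames:
        write_table(pd.concat(curves_frames, ignore_index=True), out / "km_curves.csv", "km_curves")


def run_pipeline(config: GeneratorConfig, out_dir, seed: int | None = None) -> Path:
    """Run the full pipeline into ``out_dir`` and write run_manifest.json.

    ``seed`` overrides ``config.seed`` when given. Returns the manifest path.
    """
    if seed is not None:
        config = dataclasses.replace(config, seed=int(seed))
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = datetime.now(timezone.utc).isoformat()

    log.info("stage simulate: n_tumors=%d seed=%d", config.n_tumors, config.seed)
    cohort = generate_cohort(config)
    write_table(cohort.nuclei, out / "nuclei.csv", "nuclei")
    write_table(cohort.ihc, out / "ihc.csv", "ihc")
    write_table(cohort.clinical, out / "clinical.csv", "clinical")
    write_table(cohort.survival, out / "survival.csv", "survival")

    log.info("stage call-ploidy")
    nuclei = read_table(out / "nuclei.csv", "nuclei")
    result = call_cohort(nuclei)
    write_table(result.profiles, out / "tumor_profiles.csv", "tumor_profiles")

    log.info("stage cytometry")
    write_table(profile_cohort(nuclei), out / "cytometry.csv", "cytometry")

    log.info("stage pub")
    ihc = read_table(out / "ihc.csv", "ihc")
    pub_table = score_cohort(nuclei, ihc)
    write_table(pub_table, out / "pub.csv", "pub")
    perf = evaluate_pub(pub_table, result.profiles)
    (out / "performance.json").write_text(json.dumps(perf.as_dict(), indent=2))

    log.info("stage stats")
    _stats_stage(out)

    outputs = sorted(
        p.name for p in out.iterdir()
        if p.is_file() and p.name != "run_manifest.json"
    )
    manifest = {
        "package": "polyhcc",
        "version": __version__,
        "seed": config.seed,
        "config": config_to_dict(config),
        "started": started,
        "finished": datetime.now(timezone.utc).isoformat(),
        "outputs": {name: _sha256(out / name) for name in outputs},
        "summary": {
            "n_tumors": result.n_tumors,
            "n_polyploid": result.n_polyploid,
            "pct_polyploid": result.pct_polyploid,
            "mean_ploidy_polyploid": result.mean_ploidy_polyploid,
            "pub_performance": perf.as_dict(),
        },
    }
    manifest_path = out / "run_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    log.info(
        "done: %d/%d tumors called polyploid (%.1f%%)",
        result.n_polyploid, result.n_tumors, result.pct_polyploid,
    )
    return manifest_path
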