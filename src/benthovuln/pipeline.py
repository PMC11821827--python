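"""End-to-end orchestration: ingest -> FEs -> trait space -> volumes -> models.

A run is configured by :class:`RunConfig` (either CSV inputs or a synthetic
simulation config), executes every analysis stage deterministically under
the configured seeds, and writes its tables plus a manifest into a single
output directory. All reported numbers are produced by the stage operations;
the report holds them in one JSON-serializable structure.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .schema import TraitSchema, default_schema
from .synthetic import SyntheticConfig, generate_mortality_records, generate_trait_table
from .trait_data import (
    MortalityRecord,
    ValidationError,
    build_functional_entities,
    impacted_fe_ids,
    read_mortality_records,
    read_trait_table,
    summarize_redundancy,
    write_mortality_records,
    write_trait_table,
)
from .trait_space import gower_distance, select_dimension
from .trait_volume import (
    DEFAULT_REGION_BOUNDS,
    DriverYearCell,
    decade_summary,
    driver_year_heatmap,
    impacted_fraction,
    resample_volume,
    subset_records,
)
from .zoib import (
    SEVERITY_PLAN,
    VOLUME_PLAN,
    ChainPlan,
    SingleCategoryError,
    fit_severity_model,
    fit_volume_model,
)

__all__ = ["RunConfig", "RunReport", "run_full_analysis", "validate_inputs"]

log = logging.getLogger("benthovuln")

SEVERITY_THRESHOLDS = (10, 20, 30, 40, 50, 60, 70, 80, 90, 100)


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    traits_csv: str | None = None
    mortality_csv: str | None = None
    simulate: SyntheticConfig | None = None
    schema_path: str | None = None
    dimension_candidates: tuple[int, ...] = tuple(range(2, 11))
    region_bounds: tuple[float, float] = DEFAULT_REGION_BOUNDS
    resample_n: int = 100
    resample_repetitions: int = 1000
    severity_plan: ChainPlan = field(default_factory=lambda: SEVERITY_PLAN)
    volume_plan: ChainPlan = field(default_factory=lambda: VOLUME_PLAN)
    fit_models: bool = True
    rhat_threshold: float = 1.01
    seed: int = 0
    out_dir: str | None = None

    def schema(self) -> TraitSchema:
        if self.schema_path:
            return TraitSchema.from_yaml(self.schema_path)
        return default_schema()

    def config_hash(self) -> str:
        def sanitize(o):
            if isinstance(o, dict):
                return {str(k): sanitize(v) for k, v in sorted(o.items(), key=lambda kv: str(kv[0]))}
            if isinstance(o, (list, tuple)):
                return [sanitize(v) for v in o]
            if isinstance(o, (str, int, float, bool)) or o is None:
                return o
            return str(o)

        payload = json.dumps(sanitize(asdict(self)), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """All stage outputs of one run, JSON-serializable via ``to_dict``."""

    redundancy: dict
    unquantified_records: int
    n_records: int
    severity_mix: dict
    mad_profile: dict
    m_selected: int
    eigenvalues: list
    volume_by_threshold: list
    volume_by_severity_class: list
    heatmap_cells: list
    decade_means: dict
    five_year_means: dict
    regional_resamples: dict
    severity_by_category: list
    model_diagnostics: dict
    manifest: dict

    def to_dict(self) -> dict:
        return asdict(self)


def _load_inputs(config: RunConfig):
    schema = config.schema()
    if config.simulate is not None:
        table = generate_trait_table(config.simulate, schema)
        records, truth = generate_mortality_records(table, config.simulate)
        return table, records, 0, truth
    if not (config.traits_csv and config.mortality_csv):
        raise ValidationError("config needs either CSV inputs or a simulate config")
    table = read_trait_table(config.traits_csv, schema)
    records, unquantified = read_mortality_records(config.mortality_csv)
    return table, records, unquantified, None


def run_full_analysis(config: RunConfig) -> RunReport:
    """Execute every stage and (optionally) write the run directory."""
    t0 = time.perf_counter()
    table, records, unquantified, truth = _load_inputs(config)
    log.info("inputs: %d species, %d quantified records", table.n_species, len(records))

    fes = build_functional_entities(table)
    red = summarize_redundancy(fes)
    redundancy = {
        "n_species": red.n_species,
        "n_fes": red.n_fes,
        "n_singletons": red.n_singletons,
        "mean_species_per_fe": red.mean_species_per_fe,
        "max_species_per_fe": red.max_species_per_fe,
        "singleton_share": red.singleton_share,
    }
    n = len(records)
    severity_mix = {
        s: sum(1 for r in records if r.severity == s) / n for s in ("severe", "moderate", "low")
    }

    D = gower_distance(table, level="fe")
    space = select_dimension(D, candidates=config.dimension_candidates)
    log.info("trait space: %d FEs, m_selected=%d", D.n, space.m_selected)

    volume_by_threshold = []
    for thr in SEVERITY_THRESHOLDS:
        sub = subset_records(records, min_percent=thr)
        imp = impacted_fe_ids(sub, fes)
        res = impacted_fraction(space, fes, imp, descriptor=f">={thr}%")
        volume_by_threshold.append(
            {
                "min_percent": thr,
                "n_records": len(sub),
                "n_fes_impacted": res.n_fes_impacted,
                "fraction": res.fraction,
                "degenerate": res.degenerate,
            }
        )
    volume_by_class = []
    for sev in ("low", "moderate", "severe"):
        sub = subset_records(records, severity=sev)
        imp = impacted_fe_ids(sub, fes)
        res = impacted_fraction(space, fes, imp, descriptor=sev)
        volume_by_class.append(
            {
                "severity": sev,
                "n_records": len(sub),
                "n_fes_impacted": res.n_fes_impacted,
                "fraction": res.fraction,
            }
        )

    cells = driver_year_heatmap(records, space, fes)
    # annual totals across all drivers, for decade averages and the volume model
    years = sorted({c.year for c in cells})
    annual = []
    for year in years:
        sub = subset_records(records, year_window=(year, year))
        imp = impacted_fe_ids(sub, fes)
        if imp:
            res = impacted_fraction(space, fes, imp, descriptor=f"all:{year}")
            annual.append(DriverYearCell("all drivers", year, res.fraction, res.n_fes_impacted))
        else:
            annual.append(DriverYearCell("all drivers", year, 0.0, 0))
    start = min(years)
    decade_means = decade_summary(annual, window=10, start_year=start)
    five_year_means = decade_summary(annual, window=5, start_year=start)

    regional = {}
    rng = np.random.SeedSequence(config.seed)
    region_seeds = {reg: int(s.generate_state(1)[0] % (2**31)) for reg, s in
                    zip(("western", "central", "eastern"), rng.spawn(3))}
    for region in ("western", "central", "eastern"):
        sub = subset_records(records, region=region, region_bounds=config.region_bounds)
        if len(sub) < config.resample_n:
            regional[region] = {"skipped": f"only {len(sub)} records (< {config.resample_n})"}
            continue
        summ = resample_volume(
            sub,
            space,
            fes,
            group=region,
            n=config.resample_n,
            repetitions=config.resample_repetitions,
            seed=region_seeds[region],
        )
        regional[region] = {
            "n_records": len(sub),
            "mean_fraction": summ.mean_fraction,
            "sd_fraction": summ.sd_fraction,
            "mean_fe_count": summ.mean_fe_count,
            "sd_fe_count": summ.sd_fe_count,
            "repetitions": summ.repetitions,
            "fractions": summ.fractions.tolist(),
            "fe_counts": summ.fe_counts.tolist(),
        }

    severity_rows = []
    posterior_frames = []
    diagnostics: dict = {"severity_models": {}, "volume_model": None, "skipped_traits": []}
    if config.fit_models:
        model_seeds = np.random.SeedSequence((config.seed, 17)).spawn(len(table.schema.codes) + 1)
        for code, sseq in zip(table.schema.codes, model_seeds):
            try:
                post, rows = fit_severity_model(
                    records, table, code, plan=config.severity_plan,
                    seed=int(sseq.generate_state(1)[0] % (2**31)),
                    rhat_threshold=config.rhat_threshold,
                )
            except SingleCategoryError as exc:
                diagnostics["skipped_traits"].append(str(exc))
                continue
            severity_rows.extend(
                {
                    "trait": r.trait,
                    "category": r.category,
                    "mean_percent": r.mean_percent,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                }
                for r in rows
            )
            diagnostics["severity_models"][code] = {
                "max_rhat": max(post.rhat.values()),
                "r2_median": post.r2["median"],
                "n_retained": post.n_retained,
            }
            posterior_frames.append(post.summary().assign(model=f"severity:{code}"))
            log.info("severity model %s: max rhat %.4f", code, max(post.rhat.values()))
        counts = pd.DataFrame(
            [(c.year, c.driver_class, c.n_fes_impacted) for c in cells],
            columns=["year", "driver_class", "n"],
        ).pivot(index="year", columns="driver_class", values="n")
        fractions = np.array([c.fraction for c in annual])
        vseed = int(model_seeds[-1].generate_state(1)[0] % (2**31))
        vpost = fit_volume_model(fractions, counts, plan=config.volume_plan, seed=vseed,
                                 rhat_threshold=config.rhat_threshold)
        posterior_frames.append(vpost.summary().assign(model="volume"))
        diagnostics["volume_model"] = {
            "max_rhat": max(vpost.rhat.values()),
            "r2_median": vpost.r2["median"],
            "n_retained": vpost.n_retained,
            "coefficients": {
                nm: {
                    "mean": float(vpost.flat(nm).mean()),
                    "q2.5": vpost.credible_interval(nm)[0],
                    "q97.5": vpost.credible_interval(nm)[1],
                }
                for nm in vpost.coef_names
            },
        }

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_species": table.n_species,
        "n_fes": len(fes),
        "n_records": n,
        "ground_truth": truth.to_dict() if truth else None,
    }
    report = RunReport(
        redundancy=redundancy,
        unquantified_records=unquantified,
        n_records=n,
        severity_mix=severity_mix,
        mad_profile={str(k): v for k, v in space.mad_profile.items()},
        m_selected=space.m_selected,
        eigenvalues=space.eigenvalues.tolist(),
        volume_by_threshold=volume_by_threshold,
        volume_by_severity_class=volume_by_class,
        heatmap_cells=[
            {
                "driver_class": c.driver_class,
                "year": c.year,
                "fraction": c.fraction,
                "n_fes_impacted": c.n_fes_impacted,
            }
            for c in cells
        ],
        decade_means=decade_means,
        five_year_means=five_year_means,
        regional_resamples=regional,
        severity_by_category=severity_rows,
        model_diagnostics=diagnostics,
        manifest=manifest,
    )
    if config.out_dir:
        _write_outputs(config, report, table, records, unquantified, D, space, posterior_frames)
    log.info("run complete in %.1f s", time.perf_counter() - t0)
    return report


def _write_outputs(config, report, table, records, unquantified, D, space, posterior_frames) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    D.to_tsv(out / "gower_distances.tsv")
    space.to_tsv(out / "coordinates.tsv")
    if posterior_frames:
        pd.concat(posterior_frames, ignore_index=True).to_csv(
            out / "posterior_summaries.tsv", sep="\t", index=False
        )
    if config.simulate is not None:
        write_trait_table(table, out / "traits.csv")
        write_mortality_records(records, out / "mortality.csv", n_unquantified=unquantified)
        if report.manifest["ground_truth"] is not None:
            (out / "truth.json").write_text(
                json.dumps(report.manifest["ground_truth"], indent=2) + "\n"
            )
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2) + "\n")
    pd.DataFrame(report.severity_by_category).to_csv(
        out / "severity_by_category.tsv", sep="\t", index=False
    )
    pd.DataFrame(report.heatmap_cells).to_csv(out / "heatmap.tsv", sep="\t", index=False)
    (out / "mad_profile.json").write_text(json.dumps(report.mad_profile, indent=2) + "\n")
    (out / "resample_regions.json").write_text(
        json.dumps(report.regional_resamples, indent=2) + "\n"
    )
    (out / "manifest.json").write_text(json.dumps(report.manifest, indent=2) + "\n")


def validate_inputs(config: RunConfig) -> list[str]:
    """Report schema violations in the configured inputs without analyzing.

    Returns a list of human-readable violation messages; empty when the
    inputs are clean. Unlike :func:`run_full_analysis` this never raises on
    bad data.
    """
    violations: list[str] = []
    if config.simulate is not None:
        return violations  # generated data are valid by construction
    try:
        schema = config.schema()
    except Exception as exc:  # schema file unreadable/malformed
        return [f"schema: {exc}"]
    table = None
    try:
        table = read_trait_table(config.traits_csv, schema)
    except Exception as exc:
        violations.append(f"traits: {exc}")
    records: list[MortalityRecord] = []
    try:
        records, _ = read_mortality_records(config.mortality_csv)
    except Exception as exc:
        violations.append(f"mortality: {exc}")
    if table is not None:
        for sp in sorted({r.species for r in records}):
            if sp not in table:
                violations.append(f"mortality: species {sp!r} absent from trait table")
    return violations
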