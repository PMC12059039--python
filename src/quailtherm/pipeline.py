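"""End-to-end analysis pipeline with seeds, caching and a provenance manifest.

One configuration drives the whole chain: load (or simulate) a study,
relativise respirometry to thermoneutrality, fit the cold slope models and
their permutation null, assemble and fit the path analyses per age class and
terminal response, compute effect fields and the selective-disappearance
contrast, fit the Gompertz growth models, and write every table plus a
manifest (package version, seed, config hash, section health) sufficient to
reproduce the numbers.  Stages are cached by config hash: re-running with an
unchanged config reuses existing outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import StudyData, read_dataset, write_dataset
from .errors import ConfigurationError
from .growth import GompertzModel, default_gompertz_spec, treatment_contrast
from .paths import (
    PathModel,
    PhenotypeDistribution,
    default_path_spec,
    effect_field,
    selective_disappearance,
)
from .respirometry import relativize
from .slopes import (
    ColdSlopeModel,
    default_slope_spec,
    heat_slopes,
    null_repeatability_test,
)
from .synthetic import GeneratorConfig, generate_population

logger = logging.getLogger("quailtherm.pipeline")

JUVENILE_WEEK = 3
ADULT_WEEK = 8


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one input source must be given: ``input_dir`` (a canonical study
    directory) or ``generator`` (a synthetic-study configuration).
    """

    output_dir: str
    input_dir: str | None = None
    generator: GeneratorConfig | None = None
    age_classes: tuple[str, ...] = ("juvenile", "adult")
    responses: tuple[str, ...] = ("cold_slope", "heat_slope", "ece")
    growth_traits: tuple[str, ...] = ("mass", "tarsus", "bill")
    chains: int = 2
    draws: int = 1000
    seed: int = 0
    n_scrambles: int = 20
    apply_calibration_adjustment: bool = False
    include_batch_growth: bool = True
    column_map: str | None = None

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.generator is None):
            raise ConfigurationError(
                "exactly one of input_dir or generator must be configured"
            )

    @classmethod
    def from_json_file(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
        if raw.get("generator") is not None:
            raw["generator"] = GeneratorConfig.from_json(json.dumps(raw["generator"]))
        for key in ("age_classes", "responses", "growth_traits"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        payload = dataclasses.asdict(self)
        return payload

    def config_hash(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _package_version() -> str:
    from . import __version__

    return __version__


def _age_table(data: StudyData, age_class: str) -> pd.DataFrame:
    """Morphometry of the analysis subset for one age class."""
    week = JUVENILE_WEEK if age_class == "juvenile" else ADULT_WEEK
    morph = data.morphometry
    sub = morph.loc[morph["age_weeks"] == week, ["id", "mass_g", "tarsus_mm", "bill_mm"]]
    sub = sub.rename(columns={"mass_g": "mass", "tarsus_mm": "tarsus", "bill_mm": "bill"})
    return data.individuals.merge(sub, on="id", how="inner")


def _growth_table(data: StudyData) -> pd.DataFrame:
    return data.morphometry.merge(data.individuals[["id", "batch", "rearing"]], on="id")


class _StageCache:
    """Content-hash cache: a stage is skipped when its key is unchanged."""

    def __init__(self, outdir: Path, run_key: str) -> None:
        self.path = outdir / "cache.json"
        self.run_key = run_key
        try:
            self.entries = json.loads(self.path.read_text(encoding="utf-8"))
        except (OSError, json.JSONDecodeError):
            self.entries = {}

    def fresh(self, stage: str, outputs: Sequence[Path]) -> bool:
        return self.entries.get(stage) == self.run_key and all(p.exists() for p in outputs)

    def mark(self, stage: str) -> None:
        self.entries[stage] = self.run_key
        self.path.write_text(json.dumps(self.entries, indent=2, sort_keys=True), encoding="utf-8")


def run_pipeline(config: PipelineConfig, stages: Sequence[str] | None = None) -> dict:
    """Run the analysis chain and write a report bundle.

    Returns the manifest (also written to ``manifest.json``).  A stage whose
    fit fails its convergence gates is still written but marked degraded.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_all = stages is None
    stages = set(stages or ("slopes", "paths", "growth"))
    sections: dict[str, dict] = {}
    cache = _StageCache(outdir, config.config_hash())

    # ------------------------------------------------------------------ data
    if config.input_dir is not None:
        indir = Path(config.input_dir)
        if not indir.exists():
            raise ConfigurationError(f"input directory {indir} does not exist")
        data = read_dataset(indir, column_map=config.column_map)
        truth = None
    else:
        data, truth = generate_population(config.generator)
        write_dataset(data, outdir / "dataset")
        truth.to_json_file(outdir / "dataset" / "truth.json")
    if config.apply_calibration_adjustment:
        data = data.adjust_calibration()
    sections["data"] = {
        "status": "ok",
        "individuals": int(len(data.individuals)),
        "rejected_rows": len(data.rejects),
    }

    profiles_by_age: dict[str, list] = {}
    records = data.respirometry_records()
    for age in config.age_classes:
        profiles, excluded = relativize([r for r in records if r.age_class == age])
        profiles_by_age[age] = profiles
        if excluded:
            logger.warning("%d individuals excluded from %s profiles", len(excluded), age)

    slope_fits: dict[str, object] = {}

    # ---------------------------------------------------------------- slopes
    if "slopes" in stages:
        for age in config.age_classes:
            spec = default_slope_spec(age)
            out_params = outdir / f"slope_parameters_{age}.csv"
            out_ind = outdir / f"individual_slopes_{age}.csv"
            out_rep = outdir / f"repeatability_{age}.json"
            fit = ColdSlopeModel(profiles_by_age[age], spec).fit(
                chains=config.chains, draws=config.draws, seed=config.seed
            )
            slope_fits[age] = fit
            if not cache.fresh(f"slopes_{age}", [out_params, out_ind, out_rep]):
                fit.summary().to_csv(out_params, index=False, float_format="%.6g")
                fit.individual_slopes().to_csv(out_ind, index=False, float_format="%.6g")
                if config.n_scrambles > 0:
                    rep = null_repeatability_test(
                        ColdSlopeModel(profiles_by_age[age], spec).frame,
                        spec,
                        n_scrambles=config.n_scrambles,
                        seed=config.seed,
                        chains=config.chains,
                        draws=min(config.draws, 500),
                        fit=fit,
                    )
                else:
                    rep = fit.repeatability()
                out_rep.write_text(
                    json.dumps(rep.to_dict(), indent=2, sort_keys=True), encoding="utf-8"
                )
                cache.mark(f"slopes_{age}")
            sections[f"slopes_{age}"] = {
                "status": "ok" if fit.healthy else "degraded",
            }
        hs, _excl = heat_slopes([p for ps in profiles_by_age.values() for p in ps])
        hs.to_csv(outdir / "heat_slopes.csv", index=False, float_format="%.6g")

    # ----------------------------------------------------------------- paths
    if "paths" in stages:
        for age in config.age_classes:
            base = _age_table(data, age)
            hs, _ = heat_slopes(profiles_by_age[age])
            for response in config.responses:
                table = base.copy()
                if response == "cold_slope":
                    if age not in slope_fits:
                        spec = default_slope_spec(age)
                        slope_fits[age] = ColdSlopeModel(profiles_by_age[age], spec).fit(
                            chains=config.chains, draws=config.draws, seed=config.seed
                        )
                    ind_slopes = slope_fits[age].individual_slopes()
                    table = table.merge(
                        ind_slopes.rename(columns={"slope_median": "cold_slope"})[
                            ["id", "cold_slope"]
                        ],
                        on="id",
                    )
                elif response == "heat_slope":
                    table = table.merge(hs[["id", "heat_slope"]], on="id")
                else:
                    ece_rows = [
                        {"id": p.id, "ece": p.ece[40.0]}
                        for p in profiles_by_age[age]
                        if 40.0 in p.ece
                    ]
                    if not ece_rows:
                        sections[f"paths_{age}_{response}"] = {"status": "skipped"}
                        continue
                    table = table.merge(pd.DataFrame(ece_rows), on="id")
                spec = default_path_spec(age, response)
                out_csv = outdir / f"path_{age}_{response}.csv"
                fit = PathModel(table, spec).fit(
                    chains=config.chains, draws=config.draws, seed=config.seed
                )
                coef = fit.coefficient_table()
                pr2 = {
                    p: fit.partial_r2(p) for p in ("mass", "tarsus", "bill")
                }
                coef["partial_r2"] = coef.apply(
                    lambda r: pr2[r["coefficient"]].median
                    if r["equation"] == "response" and r["coefficient"] in pr2
                    else np.nan,
                    axis=1,
                )
                if not cache.fresh(f"paths_{age}_{response}", [out_csv]):
                    coef.to_csv(out_csv, index=False, float_format="%.6g")
                    cache.mark(f"paths_{age}_{response}")
                section = {"status": "ok" if fit.healthy else "degraded"}
                if response == "heat_slope":
                    subset = table.dropna(subset=["mass", "tarsus"])
                    dist = PhenotypeDistribution.from_data(
                        subset["mass"].to_numpy(), subset["tarsus"].to_numpy()
                    )
                    fld = effect_field(fit, dist)
                    sel = selective_disappearance(
                        table,
                        fit,
                        fld,
                        threshold=0.5,
                        chains=config.chains,
                        draws=config.draws,
                        seed=config.seed,
                    )
                    payload = {
                        "rarity": {str(k): v for k, v in fld.rarity.items()},
                        "selective_disappearance": {
                            "removed": list(sel.removed_ids),
                            "delta_slope_mean": sel.mean,
                            "delta_slope_sd": sel.sd,
                            "bf": sel.bf.display if sel.bf else None,
                        },
                    }
                    (outdir / f"effect_field_{age}.json").write_text(
                        json.dumps(payload, indent=2, sort_keys=True), encoding="utf-8"
                    )
                sections[f"paths_{age}_{response}"] = section

    # ---------------------------------------------------------------- growth
    if "growth" in stages:
        gtable = _growth_table(data)
        for trait in config.growth_traits:
            spec = default_gompertz_spec(trait, include_batch=config.include_batch_growth)
            out_csv = outdir / f"growth_{trait}.csv"
            out_curves = outdir / f"growth_curves_{trait}.csv"
            fit = GompertzModel(gtable, spec).fit(
                chains=config.chains, draws=config.draws, seed=config.seed
            )
            rows = []
            for par in ("a", "c"):
                summary, _delta = treatment_contrast(fit, par, ("warm", "cold"))
                rows.append(
                    {
                        "parameter": f"delta_{par}_warm_minus_cold",
                        "median": summary.median,
                        "q2.5": summary.ci95[0],
                        "q97.5": summary.ci95[1],
                        "bf": float(summary.bf) if summary.bf else np.nan,
                        "bf_display": summary.bf.display if summary.bf else "",
                    }
                )
            if not cache.fresh(f"growth_{trait}", [out_csv, out_curves]):
                pd.concat(
                    [fit.summary(), pd.DataFrame(rows)], ignore_index=True
                ).to_csv(out_csv, index=False, float_format="%.6g")
                fit.predicted_curves().to_csv(out_curves, index=False, float_format="%.6g")
                cache.mark(f"growth_{trait}")
            sections[f"growth_{trait}"] = {"status": "ok" if fit.healthy else "degraded"}

    manifest = {
        "package": "quailtherm",
        "version": _package_version(),
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "sections": sections,
        "stages_run": sorted(stages) if not run_all else "all",
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str), encoding="utf-8"
    )
    return manifest
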