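"""Orchestration: validated inputs → rates, PLFA products and statistics.

``run_all`` reads the tidy CSV bundle of one experiment (or takes an
in-memory :class:`~spongeflux.synth.ExperimentBundle`), computes bulk rates,
per-specimen efficiencies, PLFA profiles and tracer incorporation, runs the
permutational comparisons, and writes everything plus a manifest recording
the configuration, seed, package version and QC warnings.  No row is dropped
silently: every excluded input row is counted with a reason in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bulk import compute_bulk_rates
from .plfa import (
    ExtractionRecord,
    PLFAPeak,
    load_classification_table,
    parse_fatty_acid,
    plfa_backgrounds,
    plfa_tracer_incorporation,
    profile_summary,
)
from .stats import DesignTable, OneLevelFactorError, pairwise, permanova, permanova_table
from .synth import ExperimentBundle

__all__ = ["RunConfig", "RunResult", "run_all", "load_bundle"]

logger = logging.getLogger("spongeflux")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    input_dir: str | Path | None = None
    output_dir: str | Path | None = None
    isotope_mode: str = "exact"  # or "paper_approx"
    control_correction: bool = True
    dic_pool: str = "t_end"
    classification_table: str | Path | None = None
    detection_threshold: float = 1e-5
    default_plfa_background: float = -25.0
    permutations: int = 9999
    seed: int = 0


@dataclass
class RunResult:
    rates: pd.DataFrame
    efficiencies: pd.DataFrame
    plfa_profiles: pd.DataFrame
    plfa_class_totals: pd.DataFrame
    plfa_incorporation: pd.DataFrame
    stats_omnibus: pd.DataFrame
    stats_pairwise: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("rates", "efficiencies", "plfa_profiles", "plfa_class_totals",
                     "plfa_incorporation", "stats_omnibus", "stats_pairwise"):
            getattr(self, name).to_csv(outdir / f"{name}.csv", index=False)
        (outdir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True, default=str) + "\n"
        )


def load_bundle(input_dir) -> ExperimentBundle:
    """Read an experiment bundle from CSV files in a directory."""
    d = Path(input_dir)

    def read(name, required=True):
        path = d / f"{name}.csv"
        if not path.exists():
            if required:
                raise FileNotFoundError(f"missing input table: {path}")
            return pd.DataFrame()
        return pd.read_csv(path)

    meta = {}
    meta_path = d / "experiment.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    return ExperimentBundle(
        specimens=read("specimens"),
        bulk_isotopes=read("bulk_isotopes"),
        dic_samples=read("dic_samples", required=False),
        incubations=read("incubations"),
        plfa_peaks=read("plfa_peaks", required=False),
        extractions=read("extractions", required=False),
        source_profiles=read("source_profiles", required=False),
        truth=read("truth", required=False),
        meta=meta,
    )


def _sample_objects(peaks_df: pd.DataFrame, ext_df: pd.DataFrame, sample_id: str):
    ext_row = ext_df[ext_df["sample_id"] == sample_id]
    if len(ext_row) != 1:
        raise ValueError(f"expected one extraction record for {sample_id!r}")
    e = ext_row.iloc[0]
    ext = ExtractionRecord(
        sample_id=sample_id,
        sample_mass_mg=float(e["sample_mass_mg"]),
        dcm_fraction_recovered=float(e["f_recovered"]),
        standard_area=float(e["standard_area"]),
        standard_ug_c=float(e["standard_ug_c"]),
        delta13c_methanol=float(e["delta13c_methanol"]),
    )
    peaks = [
        PLFAPeak(sample_id, parse_fatty_acid(r.fatty_acid), float(r.area),
                 float(r.delta13c_fame))
        for r in peaks_df[peaks_df["sample_id"] == sample_id].itertuples()
    ]
    return peaks, ext


def _stats_tables(rates: pd.DataFrame, cfg: RunConfig):
    """Species comparisons of total processing (per food source × element)
    and of efficiency (per food source, C only), with pairwise tests."""
    omnibus_rows = []
    pairwise_frames = []
    rng_seed = np.random.SeedSequence([cfg.seed, 7]).generate_state(1)[0] % (2**31)
    for (food, element), sub in rates.groupby(["food_source", "element"]):
        for response, label in (
            ("total_processing", "total_processing"),
            ("efficiency_pct", "efficiency"),
        ):
            vals = sub.dropna(subset=[response])
            if vals.empty or vals["species"].nunique() < 2:
                continue
            try:
                design = DesignTable(
                    vals[response].to_numpy(), vals["species"].to_numpy()
                )
            except OneLevelFactorError:
                continue
            res = permanova(design, permutations=cfg.permutations, seed=rng_seed)
            tab = permanova_table(res)
            tab.insert(0, "response", label)
            tab.insert(0, "element", element)
            tab.insert(0, "food_source", food)
            omnibus_rows.append(tab)
            pw = pairwise(design, "factor_a", seed=rng_seed,
                          permutations=cfg.permutations)
            pw.insert(0, "response", label)
            pw.insert(0, "element", element)
            pw.insert(0, "food_source", food)
            pairwise_frames.append(pw)
    omnibus = (
        pd.concat(omnibus_rows, ignore_index=True)
        if omnibus_rows
        else pd.DataFrame()
    )
    pw_all = (
        pd.concat(pairwise_frames, ignore_index=True)
        if pairwise_frames
        else pd.DataFrame()
    )
    return omnibus, pw_all


def run_all(
    cfg: RunConfig,
    bundle: ExperimentBundle | None = None,
) -> RunResult:
    """Execute the full analysis on a bundle (from ``cfg.input_dir`` if not
    given), returning all result tables; writes them when ``cfg.output_dir``
    is set."""
    if bundle is None:
        if cfg.input_dir is None:
            raise ValueError("either bundle or cfg.input_dir is required")
        bundle = load_bundle(cfg.input_dir)

    qc_warnings: list[str] = []
    excluded: list[dict] = []

    specimens = bundle.specimens.copy()
    if "labelled" not in specimens.columns:
        specimens["labelled"] = True
    labelled = specimens[specimens["labelled"].astype(bool)]
    for sid in specimens.loc[~specimens["labelled"].astype(bool), "specimen_id"]:
        excluded.append(
            dict(table="specimens", row_id=sid,
                 reason="unlabelled background specimen (bulk rates)")
        )

    rates = compute_bulk_rates(
        labelled,
        bundle.bulk_isotopes,
        bundle.dic_samples if len(bundle.dic_samples) else None,
        bundle.incubations,
        mode=cfg.isotope_mode,
        control_correction=cfg.control_correction,
        dic_pool=cfg.dic_pool,
    )
    for row in rates.itertuples():
        if row.qc:
            qc_warnings.append(f"{row.specimen_id}/{row.element}: {row.qc}")

    eff = (
        rates[rates["element"] == "C"]
        .dropna(subset=["efficiency_pct"])
        .groupby(["species", "food_source"], as_index=False)
        .agg(
            mean_efficiency_pct=("efficiency_pct", "mean"),
            sd_efficiency_pct=("efficiency_pct", "std"),
            n=("efficiency_pct", "size"),
        )
    )

    # ----- PLFA layer -----
    table = (
        load_classification_table(cfg.classification_table)
        if cfg.classification_table
        else None
    )
    profiles_rows = []
    class_rows = []
    incorporation_frames = []
    if len(bundle.plfa_peaks):
        spec_index = specimens.set_index("specimen_id")
        sample_ids = list(bundle.plfa_peaks["sample_id"].unique())
        # backgrounds per species from unlabelled specimens
        bg_profiles: dict[str, list] = {}
        for sid in sample_ids:
            if sid in spec_index.index and not bool(spec_index.loc[sid, "labelled"]):
                species = spec_index.loc[sid, "species"]
                bg_profiles.setdefault(species, []).append(
                    _sample_objects(bundle.plfa_peaks, bundle.extractions, sid)
                )
        backgrounds = {
            species: plfa_backgrounds(profs)
            for species, profs in bg_profiles.items()
        }

        source_profiles: dict[str, set[str]] = {}
        if len(bundle.source_profiles):
            for food, sub in bundle.source_profiles.groupby("food_source"):
                source_profiles[str(food)] = {
                    parse_fatty_acid(f).name for f in sub["fatty_acid"]
                }

        for sid in sample_ids:
            peaks, ext = _sample_objects(bundle.plfa_peaks, bundle.extractions, sid)
            in_specimens = sid in spec_index.index
            biomass = float(spec_index.loc[sid, "c_org_umol"]) if in_specimens else None
            dry_mg = (
                float(spec_index.loc[sid, "dry_weight_g"]) * 1000.0
                if in_specimens
                else None
            )
            prof, summary = profile_summary(
                peaks, ext, table=table, biomass_c_umol=biomass, dry_weight_mg=dry_mg
            )
            if in_specimens:
                prof.insert(1, "species", spec_index.loc[sid, "species"])
            profiles_rows.append(prof)
            class_rows.append(dict(sample_id=sid, **summary))

            if not in_specimens or not bool(spec_index.loc[sid, "labelled"]):
                if in_specimens:
                    excluded.append(
                        dict(table="plfa_peaks", row_id=sid,
                             reason="unlabelled specimen (incorporation)")
                    )
                continue
            species = spec_index.loc[sid, "species"]
            food = str(spec_index.loc[sid, "food_source"])
            inc_row = bundle.incubations[
                bundle.incubations["incubation_id"] == sid
            ]
            if inc_row.empty:
                excluded.append(
                    dict(table="plfa_peaks", row_id=sid,
                         reason="no incubation metadata")
                )
                continue
            duration = float(
                inc_row.iloc[0]["n_pulses"] * inc_row.iloc[0]["pulse_duration_h"] / 24.0
            )
            inc = plfa_tracer_incorporation(
                peaks, ext,
                background_delta=backgrounds.get(species, {}),
                biomass_c_umol=biomass,
                duration_days=duration,
                dry_weight_mg=dry_mg,
                mode=cfg.isotope_mode,
                detection_threshold=cfg.detection_threshold,
                source_profile=source_profiles.get(food),
                default_background=cfg.default_plfa_background,
            )
            inc.insert(1, "species", species)
            inc.insert(2, "food_source", food)
            incorporation_frames.append(inc)
            for r in inc.itertuples():
                if r.qc:
                    qc_warnings.append(f"{sid}/{r.fatty_acid}: {r.qc}")

    profiles = (
        pd.concat(profiles_rows, ignore_index=True)
        if profiles_rows
        else pd.DataFrame()
    )
    class_totals = pd.DataFrame(class_rows) if class_rows else pd.DataFrame()
    incorporation = (
        pd.concat(incorporation_frames, ignore_index=True)
        if incorporation_frames
        else pd.DataFrame()
    )

    try:
        omnibus, pw = _stats_tables(rates, cfg)
    except (OneLevelFactorError, ValueError):
        omnibus, pw = pd.DataFrame(), pd.DataFrame()

    cfg_dict = {k: str(v) for k, v in asdict(cfg).items()}
    manifest = dict(
        package_version=__version__,
        config=cfg_dict,
        config_hash=hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest()[:16],
        seed=cfg.seed,
        input_rows={
            "specimens": int(len(bundle.specimens)),
            "bulk_isotopes": int(len(bundle.bulk_isotopes)),
            "dic_samples": int(len(bundle.dic_samples)),
            "plfa_peaks": int(len(bundle.plfa_peaks)),
        },
        analyzed_rows={
            "rates": int(len(rates)),
            "plfa_incorporation": int(len(incorporation)),
        },
        excluded=excluded,
        qc_warnings=qc_warnings,
    )
    result = RunResult(
        rates=rates,
        efficiencies=eff,
        plfa_profiles=profiles,
        plfa_class_totals=class_totals,
        plfa_incorporation=incorporation,
        stats_omnibus=omnibus,
        stats_pairwise=pw,
        manifest=manifest,
    )
    if cfg.output_dir is not None:
        result.write(cfg.output_dir)
    return result
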