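"""Seeded, provenance-tracked pipeline: generate -> classify -> clocks ->
harmonize -> CoMeT -> stats.

Each stage reads and writes CSV tables inside a run directory and appends a
provenance entry (stage name, parameters, input/output content hashes, seed)
to ``manifest.json``. Identical config + seed yields byte-identical run
directories.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import clocks as clocks_mod
from . import cohorts as cohorts_mod
from .comet import DEFAULT_ROI_SETS, RoiSetDefinition, compute_comet, fit_comet_models
from .errors import CometBioageError, InputError, ValidationError
from .harmonization import ComBatHarmonizer, apply_combat, fit_combat
from .stats import describe_cohorts, format_report, run_primary_analysis
from .synthetic import SyntheticConfig, SyntheticTruth, generate_clock_data, generate_cohort, write_cohort

log = logging.getLogger("comet_bioage")

MANIFEST_NAME = "manifest.json"


@dataclass
class PipelineConfig:
    """Top-level run configuration; YAML-serializable.

    All randomness flows from ``seed``; stage-specific sub-seeds are derived
    from it deterministically.
    """

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    amyloid_thresholds: dict = field(
        default_factory=lambda: dict(cohorts_mod.DEFAULT_AMYLOID_THRESHOLDS))
    sd_multiplier: float = clocks_mod.DEFAULT_SD_MULTIPLIER
    seed: int = 0
    clock_files: list = field(default_factory=list)  # optional external clock CSVs
    roi_sets_file: str | None = None
    log_level: str = "INFO"

    def __post_init__(self):
        if self.sd_multiplier <= 0:
            raise InputError("sd_multiplier k must be > 0")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["synthetic"] = self.synthetic.to_dict()
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        if "synthetic" in d:
            d["synthetic"] = SyntheticConfig.from_dict(d["synthetic"])
        return cls(**d)

    def roi_sets(self) -> RoiSetDefinition:
        if self.roi_sets_file:
            return RoiSetDefinition.from_yaml(self.roi_sets_file)
        return DEFAULT_ROI_SETS


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class RunDirectory:
    """A pipeline run directory with a provenance manifest."""

    def __init__(self, path):
        self.path = Path(path)
        self.path.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.path / MANIFEST_NAME
        self.entries = []
        if self.manifest_path.exists():
            self.entries = json.loads(self.manifest_path.read_text())["stages"]

    def record(self, stage: str, params: dict, inputs: list, outputs: list) -> None:
        self.entries.append({
            "stage": stage,
            "params": params,
            "inputs": {str(Path(p).name): _sha256(Path(p)) for p in inputs},
            "outputs": {str(Path(p).name): _sha256(Path(p)) for p in outputs},
        })
        self.manifest_path.write_text(
            json.dumps({"stages": self.entries}, indent=1, sort_keys=True))

    def file(self, name: str) -> Path:
        return self.path / name


def stage_simulate(config: PipelineConfig, run: RunDirectory) -> None:
    cfg = dataclasses.replace(config.synthetic, seed=config.seed)
    participants, roi, amyloid, truth = generate_cohort(cfg)
    betas, clocks = (None, [])
    if len(participants):
        betas, clocks = generate_clock_data(participants, truth, cfg)
    paths = write_cohort(run.path, participants, roi, amyloid, truth, betas, clocks)
    outputs = [p for k, p in paths.items() if k != "clocks"]
    if clocks:
        outputs += [paths["clocks"] / f"{c.name}.csv" for c in clocks]
    run.record("simulate", cfg.to_dict(), [], outputs)
    log.info("simulate: wrote %d participants", len(participants))


def stage_classify(config: PipelineConfig, run: RunDirectory) -> None:
    participants = pd.read_csv(run.file("participants.csv"))
    amyloid = pd.read_csv(run.file("amyloid.csv"))
    labels = cohorts_mod.build_cohort_table(participants, amyloid,
                                            config.amyloid_thresholds)
    out = run.file("cohort_labels.csv")
    labels.to_csv(out)
    run.record("classify", {"thresholds": config.amyloid_thresholds},
               [run.file("participants.csv"), run.file("amyloid.csv")], [out])
    log.info("classify: %s", labels["cohort"].value_counts().to_dict())


def _load_clocks(config: PipelineConfig, run: RunDirectory) -> list:
    files = [Path(p) for p in config.clock_files]
    if not files:
        clock_dir = run.file("clocks")
        files = sorted(clock_dir.glob("*.csv")) if clock_dir.is_dir() else []
    if not files:
        raise InputError("no clock coefficient files found (clocks/ dir or clock_files)")
    for f in files:
        if not f.exists():
            raise InputError(f"clock file does not exist: {f}")
    return [clocks_mod.read_clock(f) for f in files]


def stage_clocks(config: PipelineConfig, run: RunDirectory) -> None:
    betas = pd.read_csv(run.file("methylation.csv"),
                        index_col=["participant_id", "replicate"])
    participants = pd.read_csv(run.file("participants.csv")).set_index("id")
    clock_models = _load_clocks(config, run)
    matrix = clocks_mod.select_replicate(betas, seed=config.seed + 1)
    bag_table = clocks_mod.compute_bag_table(
        matrix, clock_models, participants["age_at_mri"], k=config.sd_multiplier)
    out = run.file("bag.csv")
    bag_table.to_csv(out)
    run.record("clocks", {"sd_multiplier": config.sd_multiplier,
                          "replicate_seed": config.seed + 1,
                          "clocks": [c.name for c in clock_models]},
               [run.file("methylation.csv"), run.file("participants.csv")], [out])
    log.info("clocks: BAG for %d participants", len(bag_table))


def stage_harmonize(config: PipelineConfig, run: RunDirectory) -> None:
    roi = pd.read_csv(run.file("roi.csv"), index_col="participant_id")
    participants = pd.read_csv(run.file("participants.csv")).set_index("id")
    labels = pd.read_csv(run.file("cohort_labels.csv"), index_col="participant_id")
    covariates = pd.DataFrame({
        "age": participants["age_at_mri"],
        "sex": (participants["sex"] == "female").astype(float),
    })
    for diag in ("MCI", "dementia"):  # one-hot with CU baseline; constant cols dropped at fit
        covariates[f"diagnosis_{diag}"] = (participants["diagnosis"] == diag).astype(float)
    batch = participants["scanner_field"]
    cu_ids = labels.index[labels["cohort"] == "CU"]
    model = fit_combat(roi.loc[cu_ids], covariates.loc[cu_ids], batch.loc[cu_ids])
    harmonized = apply_combat(model, roi, covariates.loc[roi.index], batch.loc[roi.index])
    out = run.file("roi_harmonized.csv")
    harmonized.to_csv(out)
    model.save(run.file("combat_model.json"))
    run.record("harmonize", {"batch": "scanner_field", "reference": "CU",
                             "dropped_covariates": model.dropped_covariates_},
               [run.file("roi.csv"), run.file("participants.csv"),
                run.file("cohort_labels.csv")],
               [out, run.file("combat_model.json")])
    log.info("harmonize: fitted on %d CU rows, %d batches", len(cu_ids), len(model.batches_))


def stage_comet(config: PipelineConfig, run: RunDirectory) -> None:
    roi = pd.read_csv(run.file("roi_harmonized.csv"), index_col="participant_id")
    participants = pd.read_csv(run.file("participants.csv")).set_index("id")
    labels = pd.read_csv(run.file("cohort_labels.csv"), index_col="participant_id")
    covariates = pd.DataFrame({
        "age": participants["age_at_mri"],
        "sex": (participants["sex"] == "female").astype(float),
        "icv": participants["icv"],
    })
    cu_ids = labels.index[labels["cohort"] == "CU"]
    models = fit_comet_models(roi.loc[cu_ids], covariates, config.roi_sets())
    comet = compute_comet(roi, covariates, models)
    out = run.file("comet.csv")
    comet.to_csv(out)
    run.record("comet", {"reference": "CU", "n_reference": int(len(cu_ids))},
               [run.file("roi_harmonized.csv"), run.file("participants.csv"),
                run.file("cohort_labels.csv")], [out])
    log.info("comet: scored %d participants", len(comet))


def stage_analyze(config: PipelineConfig, run: RunDirectory) -> None:
    comet = pd.read_csv(run.file("comet.csv"), index_col="participant_id")
    bag = pd.read_csv(run.file("bag.csv"), index_col="participant_id")
    labels = pd.read_csv(run.file("cohort_labels.csv"), index_col="participant_id")
    participants = pd.read_csv(run.file("participants.csv"))
    report = run_primary_analysis(comet, bag, labels, participants)
    table1 = describe_cohorts(participants, labels, bag)
    report.to_csv(run.file("analysis.csv"), index=False)
    table1.to_csv(run.file("table1.csv"))
    run.file("summary.txt").write_text(format_report(report))
    run.record("analyze", {},
               [run.file("comet.csv"), run.file("bag.csv"),
                run.file("cohort_labels.csv"), run.file("participants.csv")],
               [run.file("analysis.csv"), run.file("table1.csv"), run.file("summary.txt")])
    log.info("analyze: %d report rows", len(report))


STAGES = {
    "simulate": stage_simulate,
    "classify": stage_classify,
    "clocks": stage_clocks,
    "harmonize": stage_harmonize,
    "comet": stage_comet,
    "analyze": stage_analyze,
}


def run_pipeline(config: PipelineConfig, outdir,
                 stages: list[str] | None = None) -> RunDirectory:
    """Execute pipeline stages in order inside ``outdir``.

    A stage failure raises :class:`CometBioageError` with the stage named;
    the CLI maps that to a nonzero exit status.
    """
    run = RunDirectory(outdir)
    config.to_yaml(run.file("config.yaml"))
    for name in stages or list(STAGES):
        try:
            STAGES[name](config, run)
        except CometBioageError as exc:
            raise type(exc)(f"stage '{name}': {exc}") from exc
        except FileNotFoundError as exc:
            raise InputError(f"stage '{name}': missing input file: {exc.filename}") from exc
    return run


# ---------------------------------------------------------------------------
# Input validation


@dataclass
class ValidationReport:
    fatal: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.fatal

    def raise_if_fatal(self) -> None:
        if self.fatal:
            raise ValidationError("; ".join(self.fatal))


EXPECTED_PARTICIPANT_COLUMNS = ("id", "age_at_mri", "sex", "education", "icv",
                                "diagnosis", "scanner_field")


def validate_inputs(participants: pd.DataFrame | None = None,
                    roi: pd.DataFrame | None = None,
                    amyloid: pd.DataFrame | None = None,
                    methylation: pd.DataFrame | None = None,
                    roi_sets: RoiSetDefinition = DEFAULT_ROI_SETS) -> ValidationReport:
    """Schema, range and cross-table alignment checks.

    All fatal violations are collected and reported at once; cosmetic issues
    (extra columns) are warnings.
    """
    rep = ValidationReport()
    known_ids = None
    if participants is not None:
        missing = [c for c in EXPECTED_PARTICIPANT_COLUMNS if c not in participants.columns]
        if missing:
            rep.fatal.append(f"participants: missing columns {missing}")
        extra = [c for c in participants.columns
                 if c not in EXPECTED_PARTICIPANT_COLUMNS + ("cdrsb", "apoe4_count")]
        if extra:
            rep.warnings.append(f"participants: unused columns {extra}")
        if "id" in participants.columns:
            known_ids = set(participants["id"])
            if participants["id"].duplicated().any():
                rep.fatal.append("participants: duplicated ids")
        if "age_at_mri" in participants.columns and (participants["age_at_mri"] <= 0).any():
            rep.fatal.append("participants: non-positive age_at_mri")
        if "diagnosis" in participants.columns:
            bad = sorted(set(participants["diagnosis"]) - set(cohorts_mod.DIAGNOSES))
            if bad:
                rep.fatal.append(f"participants: unknown diagnosis labels {bad}")
    if roi is not None:
        from .comet import roi_columns
        needed = (roi_columns(roi_sets.cortical_thickness_rois, "thickness")
                  + roi_columns(roi_sets.mtl_thickness_rois, "thickness")
                  + roi_columns(roi_sets.mtl_volume_rois, "volume"))
        missing = [c for c in needed if c not in roi.columns]
        if missing:
            rep.fatal.append(f"roi: missing ROI columns {missing[:6]}"
                             f"{' ...' if len(missing) > 6 else ''}")
        present = [c for c in needed if c in roi.columns]
        if present and not (roi[present].to_numpy(float) > 0).all():
            rep.fatal.append("roi: non-positive or non-finite structural values")
        if known_ids is not None:
            orphan = sorted(set(roi.index) - known_ids)
            if orphan:
                rep.fatal.append(f"roi: participants absent from demographics: {orphan[:5]}")
    if amyloid is not None:
        missing = [c for c in cohorts_mod.AMYLOID_COLUMNS if c not in amyloid.columns]
        if missing:
            rep.fatal.append(f"amyloid: missing columns {missing}")
        elif (amyloid["value"] <= 0).any():
            rep.fatal.append("amyloid: non-positive measure values")
        if known_ids is not None and "participant_id" in amyloid.columns:
            orphan = sorted(set(amyloid["participant_id"]) - known_ids)
            if orphan:
                rep.fatal.append(f"amyloid: participants absent from demographics: {orphan[:5]}")
    if methylation is not None:
        vals = methylation.to_numpy(float)
        if vals.size and (not ((vals >= 0) & (vals <= 1)).all() or not pd.notna(vals).all()):
            rep.fatal.append("methylation: beta values outside [0, 1]")
        if methylation.index.duplicated().any():
            rep.fatal.append("methylation: duplicated (participant, replicate) rows")
        if known_ids is not None:
            pids = set(methylation.index.get_level_values(0))
            orphan = sorted(pids - known_ids)
            if orphan:
                rep.fatal.append(f"methylation: participants absent from demographics: {orphan[:5]}")
    return rep
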