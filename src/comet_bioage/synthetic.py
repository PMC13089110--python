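"""Synthetic ADNI-like cohort generator with planted, recorded ground truth.

The generator emulates the structure the downstream pipeline assumes: a
participant table with demographics and diagnosis, amyloid measures placed on
the correct side of the positivity cutoffs, a bilateral DKT ROI table with
age/sex/ICV covariate dependence plus a two-scanner batch effect, and a
methylation beta matrix constructed so that each synthetic clock predicts
chronological age + latent biological-age gap + noise.

The key planted quantity is the coupling between the latent per-participant
BAG and the cortical-minus-MTL atrophy contrast of symptomatic subjects:
subject-level compartment deviations are generated so that
corr(BAG, contrast) = ``coupling_rho`` by construction, with the contrast
expressed in reference-SD units so measured CoMeT inherits the correlation
up to small measurement-noise attenuation.

Every random draw flows from a single seed through per-table sub-streams, so
outputs are byte-identical under the same seed and adding a new table cannot
perturb earlier ones.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .clocks import ClockModel, transform_age
from .comet import CORTICAL_THICKNESS_ROIS, MTL_THICKNESS_ROIS, MTL_VOLUME_ROIS
from .errors import ConfigurationError, GenerationError

# Healthy-norm means (mm for thickness, mm^3 for volume) and between-subject
# biological SDs used as the reference scale of planted atrophy.
THICKNESS_NORMS = {
    "inferiortemporal": 2.75, "temporalpole": 3.60, "superiorparietal": 2.20,
    "precuneus": 2.40, "supramarginal": 2.55, "superiorfrontal": 2.70,
    "middlefrontal": 2.50, "fusiform": 2.70, "inferiorparietal": 2.45,
    "superiortemporal": 2.80, "posteriorcingulate": 2.50, "isthmuscingulate": 2.40,
    "lateraloccipital": 2.20, "middletemporal": 2.85, "medialorbitofrontal": 2.40,
    "cuneus": 1.90, "lingual": 2.00, "pericalcarine": 1.65,
    "entorhinal": 3.35, "parahippocampal": 2.75,
}
VOLUME_NORMS = {"hippocampus": 3700.0, "amygdala": 1650.0}
THICKNESS_SCALE = 0.12  # mm biological SD per thickness ROI
VOLUME_SCALES = {"hippocampus": 380.0, "amygdala": 180.0}

CLOCK_SPECS = (
    # (name, transform, coefficient scale) — two blood-trained identity
    # clocks and one pan-tissue log-linear clock, mirroring the
    # Hannum/Shireby/Horvath trio in shape only.
    ("syn_hannum", "identity", 8.0),
    ("syn_shireby", "identity", 8.0),
    ("syn_horvath", "log_linear_adult", 0.4),
)
N_CLOCKS = len(CLOCK_SPECS)
BETA_NOISE_SD = 0.02  # CpG-level noise orthogonal to the clock direction


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Cohort sizes default to the study's DNA-methylation subset (163 CU, 170
    MCI, 115 dementia); ages are truncated-normal around the study's pooled
    mean/SD; the planted BAG-contrast coupling defaults to the study's
    headline correlation scale.
    """

    n_cu: int = 163
    n_mci: int = 170
    n_dementia: int = 115
    age_range: tuple = (55.0, 95.0)
    age_mean: float = 75.3     # years (Table-1-scale pooled mean)
    age_sd: float = 7.3        # years
    sex_ratio: float = 0.444   # fraction female
    batch_probs: float = 0.5   # probability of 1.5T (second batch is 3T)
    batch_shift: float = 0.06  # mm additive offset for the 3T batch (thickness scale)
    batch_scale: float = 1.3   # multiplicative noise-SD factor for the 3T batch
    age_slope_thickness: float = -0.01  # mm per year
    age_slope_volume: float = -15.0     # mm^3 per year at hippocampus scale
    sex_effect: float = 0.05   # mm, female minus male thickness
    icv_mean_sd: tuple = (1.45e6, 1.4e5)  # mm^3
    icv_slope: float = 0.0015  # mm^3 ROI per mm^3 ICV at hippocampus scale
    atrophy_cortex: float = -1.2   # mean symptomatic cortical atrophy, reference-SD units
    atrophy_mtl: float = -1.8      # mean symptomatic MTL atrophy, reference-SD units
    contrast_sd: float = 1.0       # SD of the cortical-minus-MTL contrast, reference-SD units
    bag_sd: float = 4.0            # years
    coupling_rho: float = 0.15     # corr(latent BAG, contrast) in symptomatic subjects
    clock_noise_sd: float = 2.0    # years per clock
    n_cpgs: int = 200
    cpgs_per_clock: int = 60
    measurement_noise_sd: float = 0.05  # mm per thickness ROI measurement
    replicate_fraction: float = 0.0     # fraction of subjects with a technical replicate
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_cu", "n_mci", "n_dementia", "n_cpgs", "cpgs_per_clock"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ConfigurationError(f"{name} must be a non-negative integer, got {v!r}")
        for name in ("sex_ratio", "batch_probs", "replicate_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v!r}")
        if not -1.0 <= self.coupling_rho <= 1.0:
            raise ConfigurationError(f"coupling_rho must lie in [-1, 1], got {self.coupling_rho!r}")
        if self.bag_sd <= 0:
            raise ConfigurationError(f"bag_sd must be positive, got {self.bag_sd!r}")
        for name in ("age_sd", "contrast_sd", "batch_scale"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive, got {getattr(self, name)!r}")
        for name in ("clock_noise_sd", "measurement_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        lo, hi = self.age_range
        if not lo < hi or lo <= 0:
            raise ConfigurationError(f"age_range must be an increasing positive pair, got {self.age_range!r}")
        if 2.0 * self.contrast_sd > 2.0:
            # variance budget: subject deviations have unit variance split as
            # sigma_S^2 + contrast_sd^2 / 4 = 1
            if self.contrast_sd > 2.0:
                raise ConfigurationError("contrast_sd must be <= 2 (unit variance budget)")
        if self.n_cpgs < N_CLOCKS * self.cpgs_per_clock:
            raise ConfigurationError(
                f"n_cpgs must be >= {N_CLOCKS} * cpgs_per_clock "
                f"({N_CLOCKS * self.cpgs_per_clock}), got {self.n_cpgs}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["age_range"] = list(self.age_range)
        d["icv_mean_sd"] = list(self.icv_mean_sd)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        if "icv_mean_sd" in d:
            d["icv_mean_sd"] = tuple(d["icv_mean_sd"])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Everything planted by the generator, recoverable without re-running it."""

    per_participant: pd.DataFrame
    batch_shift: dict[str, float]
    batch_scale: float
    clocks: list[ClockModel] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        doc = {
            "per_participant": self.per_participant.reset_index().to_dict(orient="list"),
            "per_participant_columns": list(self.per_participant.reset_index().columns),
            "batch_shift": self.batch_shift,
            "batch_scale": self.batch_scale,
            "clocks": [{
                "name": c.name, "intercept": c.intercept, "transform": c.transform,
                "adult_age": c.adult_age, "coefficients": c.coefficients,
            } for c in self.clocks],
            "config": self.config,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        per = (pd.DataFrame(doc["per_participant"])
               .reindex(columns=doc["per_participant_columns"])
               .set_index("participant_id"))
        clocks = [ClockModel(name=c["name"], intercept=c["intercept"],
                             coefficients=c["coefficients"], transform=c["transform"],
                             adult_age=c["adult_age"]) for c in doc["clocks"]]
        return cls(per_participant=per, batch_shift=doc["batch_shift"],
                   batch_scale=doc["batch_scale"], clocks=clocks, config=doc["config"])


def _substreams(seed: int) -> list[np.random.Generator]:
    """Fixed per-table sub-streams: participants, roi, amyloid, methylation."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(4)]


def _roi_catalog() -> list[tuple[str, str, float, float]]:
    """(column, kind, healthy mean, biological scale) for every bilateral ROI."""
    cat = []
    for roi in (*CORTICAL_THICKNESS_ROIS, *MTL_THICKNESS_ROIS):
        for h in ("lh", "rh"):
            cat.append((f"{h}_{roi}_thickness", "thickness", THICKNESS_NORMS[roi],
                        THICKNESS_SCALE))
    for roi in MTL_VOLUME_ROIS:
        for h in ("lh", "rh"):
            cat.append((f"{h}_{roi}_volume", "volume", VOLUME_NORMS[roi] / 2.0,
                        VOLUME_SCALES[roi] / 2.0))
    return cat


def generate_cohort(config: SyntheticConfig):
    """Generate participants, ROI measures, amyloid measures and the truth record.

    Returns ``(participants, roi, amyloid, truth)``. CU subjects are drawn
    amyloid-negative and MCI/dementia subjects amyloid-positive, with measure
    values placed strictly on the correct side of the default cutoffs. ROI
    values are healthy norm + covariate effects + batch effect + planted
    deviation + measurement noise.
    """
    config.validate()
    rng_part, rng_roi, rng_amy, _ = _substreams(config.seed)

    n = config.n_cu + config.n_mci + config.n_dementia
    width = max(4, len(str(max(n, 1))))
    ids = [f"S{i:0{width}d}" for i in range(1, n + 1)]
    diagnosis = np.array(["CU"] * config.n_cu + ["MCI"] * config.n_mci
                         + ["dementia"] * config.n_dementia, dtype=object)
    symptomatic = diagnosis != "CU"

    lo, hi = config.age_range
    a = (lo - config.age_mean) / config.age_sd
    b = (hi - config.age_mean) / config.age_sd
    age = sps.truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd,
                            size=n, random_state=rng_part)
    sex = np.where(rng_part.random(n) < config.sex_ratio, "female", "male")
    education = np.clip(np.round(rng_part.normal(16.0, 2.5, n)), 8, 20).astype(int)
    icv = np.clip(rng_part.normal(config.icv_mean_sd[0], config.icv_mean_sd[1], n), 8e5, None)
    scanner = np.where(rng_part.random(n) < config.batch_probs, "1.5T", "3T")

    cdrsb = np.zeros(n)
    is_mci = diagnosis == "MCI"
    is_dem = diagnosis == "dementia"
    cdrsb[is_mci] = np.round(np.clip(rng_part.gamma(2.0, 0.9, is_mci.sum()), 0.0, 8.0) * 2) / 2
    cdrsb[is_dem] = np.round(np.clip(rng_part.normal(5.0, 2.0, is_dem.sum()), 0.5, 14.0) * 2) / 2

    apoe4 = np.zeros(n, dtype=int)
    cu_mask = ~symptomatic
    apoe4[cu_mask] = rng_part.choice([0, 1, 2], size=cu_mask.sum(), p=[0.79, 0.19, 0.02])
    apoe4[symptomatic] = rng_part.choice([0, 1, 2], size=symptomatic.sum(),
                                         p=[0.315, 0.50, 0.185])

    # Latent biological age gap and the planted atrophy structure. Subject
    # deviations per compartment: W = S +/- D/2 with shared severity S and
    # contrast D; in symptomatic subjects D is coupled to BAG at coupling_rho.
    latent_bag = rng_part.normal(0.0, config.bag_sd, n)
    z = latent_bag / config.bag_sd
    eps = rng_part.normal(0.0, 1.0, n)
    eta = rng_part.normal(0.0, 1.0, n)
    rho = config.coupling_rho
    d_noise = config.contrast_sd * (rho * z + np.sqrt(1.0 - rho**2) * eps)
    d_null = config.contrast_sd * eps
    contrast = np.where(symptomatic,
                        (config.atrophy_cortex - config.atrophy_mtl) + d_noise,
                        d_null)
    sigma_s = np.sqrt(max(1.0 - config.contrast_sd**2 / 4.0, 0.05))
    severity = np.where(symptomatic,
                        (config.atrophy_cortex + config.atrophy_mtl) / 2.0, 0.0) + sigma_s * eta
    w_cortex = severity + contrast / 2.0
    w_mtl = severity - contrast / 2.0

    participants = pd.DataFrame({
        "id": ids, "age_at_mri": age, "sex": sex, "education": education,
        "icv": icv, "diagnosis": diagnosis, "scanner_field": scanner,
        "cdrsb": cdrsb, "apoe4_count": apoe4,
    })

    # ROI table
    female = (sex == "female").astype(float)
    is_3t = (scanner == "3T").astype(float)
    age_c = age - config.age_mean
    icv_c = icv - config.icv_mean_sd[0]
    cols = {}
    shift_record = {}
    for col, kind, mean, scale in _roi_catalog():
        dev = w_cortex if any(col.split("_")[1] == r for r in CORTICAL_THICKNESS_ROIS) else w_mtl
        if kind == "thickness":
            fixed = (mean + config.age_slope_thickness * age_c
                     + config.sex_effect * female)
            shift = config.batch_shift
        else:
            rel = scale / (VOLUME_SCALES["hippocampus"] / 2.0)
            fixed = (mean + config.age_slope_volume * rel * age_c / 2.0
                     + config.icv_slope * rel * icv_c / 2.0)
            shift = config.batch_shift * scale / THICKNESS_SCALE
        noise_sd = config.measurement_noise_sd * scale / THICKNESS_SCALE
        noise = rng_roi.normal(0.0, 1.0, n) * noise_sd * np.where(is_3t == 1.0,
                                                                  config.batch_scale, 1.0)
        cols[col] = fixed + dev * scale + shift * is_3t + noise
        shift_record[col] = shift
    roi = pd.DataFrame(cols, index=pd.Index(ids, name="participant_id"))

    # Amyloid measures: one per participant, on the correct side of the cutoff.
    modality = rng_amy.choice(["florbetapir", "PiB", "CSF_abeta42"], size=n,
                              p=[0.7, 0.1, 0.2])
    offset = rng_amy.uniform(-1.5, 1.5, n)
    u = rng_amy.random(n)
    value = np.empty(n)
    for mod, (neg_lo, neg_hi), (pos_lo, pos_hi) in (
        ("florbetapir", (0.85, 1.08), (1.12, 1.70)),
        ("PiB", (1.00, 1.44), (1.50, 2.20)),
        ("CSF_abeta42", (1000.0, 1700.0), (400.0, 950.0)),
    ):
        m = modality == mod
        value[m & ~symptomatic] = neg_lo + u[m & ~symptomatic] * (neg_hi - neg_lo)
        value[m & symptomatic] = pos_lo + u[m & symptomatic] * (pos_hi - pos_lo)
    amyloid = pd.DataFrame({"participant_id": ids, "modality": modality,
                            "value": value, "offset_years": offset})

    per = pd.DataFrame({
        "latent_bag": latent_bag, "atrophy_contrast": contrast,
        "severity": severity, "w_cortex": w_cortex, "w_mtl": w_mtl,
        "diagnosis": diagnosis,
    }, index=pd.Index(ids, name="participant_id"))
    truth = SyntheticTruth(per_participant=per, batch_shift=shift_record,
                           batch_scale=config.batch_scale, clocks=[],
                           config=config.to_dict())
    return participants, roi, amyloid, truth


def generate_clock_data(participants: pd.DataFrame, truth: SyntheticTruth,
                        config: SyntheticConfig):
    """Construct methylation betas and three synthetic clock models.

    Betas are an affine map of the target predicted age (chronological age +
    latent BAG + per-clock noise) through each clock's coefficient direction,
    centred at beta 0.5, plus CpG-level noise orthogonal to the coefficient
    vector so the planted prediction is exact. Raises
    :class:`GenerationError` if any beta would leave [0, 1] (clipping would
    destroy the planted signal).
    """
    config.validate()
    if len(participants) == 0:
        raise GenerationError("cannot generate clock data for an empty cohort")
    rng = _substreams(config.seed)[3]
    n = len(participants)
    ids = list(participants["id"])
    age = participants["age_at_mri"].to_numpy(float)
    bag = truth.per_participant["latent_bag"].reindex(ids).to_numpy(float)

    m = config.cpgs_per_clock
    cpg_ids = [f"cg{i:06d}" for i in range(config.n_cpgs)]
    blocks = np.empty((n, config.n_cpgs))
    clocks: list[ClockModel] = []
    block_info = []  # (slice, weights, deltas) kept for replicate rows
    for k, (name, transform, w_scale) in enumerate(CLOCK_SPECS):
        sl = slice(k * m, (k + 1) * m)
        w = rng.normal(0.0, w_scale, m)
        target = age + bag + rng.normal(0.0, config.clock_noise_sd, n)
        m_target = transform_age(target) if transform == "log_linear_adult" else target
        w2 = float(w @ w)
        if w2 == 0:
            raise GenerationError(f"degenerate coefficient vector for clock '{name}'")
        center = float(np.mean(m_target))
        intercept = center - 0.5 * float(w.sum())
        deltas = m_target - center
        eps = rng.normal(0.0, BETA_NOISE_SD, (n, m))
        eps -= np.outer(eps @ w, w) / w2
        block = 0.5 + np.outer(deltas, w) / w2 + eps
        if block.min() < 0.0 or block.max() > 1.0:
            raise GenerationError(
                f"clock '{name}': planted betas leave [0, 1] "
                f"(range {block.min():.3f}..{block.max():.3f}); clipping would "
                "destroy the planted age signal — reduce age spread, bag_sd or noise")
        blocks[:, sl] = block
        clocks.append(ClockModel(name=name, intercept=intercept,
                                 coefficients=dict(zip(cpg_ids[sl], w)),
                                 transform=transform))
        block_info.append((sl, w, w2, deltas))

    n_extra = config.n_cpgs - N_CLOCKS * m
    if n_extra:
        blocks[:, N_CLOCKS * m:] = np.clip(
            rng.normal(0.5, 0.05, (n, n_extra)), 0.0, 1.0)

    index = pd.MultiIndex.from_arrays([ids, [0] * n], names=["participant_id", "replicate"])
    betas = pd.DataFrame(np.clip(blocks, 0.0, 1.0), index=index, columns=cpg_ids)

    if config.replicate_fraction > 0 and n > 0:
        k_rep = int(round(config.replicate_fraction * n))
        chosen = rng.choice(n, size=k_rep, replace=False)
        rep_rows = np.empty((k_rep, config.n_cpgs))
        for sl, w, w2, deltas in block_info:
            eps = rng.normal(0.0, BETA_NOISE_SD, (k_rep, sl.stop - sl.start))
            eps -= np.outer(eps @ w, w) / w2
            rep_rows[:, sl] = 0.5 + np.outer(deltas[chosen], w) / w2 + eps
        if n_extra:
            rep_rows[:, N_CLOCKS * m:] = np.clip(
                rng.normal(0.5, 0.05, (k_rep, n_extra)), 0.0, 1.0)
        if rep_rows.min() < 0.0 or rep_rows.max() > 1.0:
            raise GenerationError("replicate betas leave [0, 1]")
        rep_index = pd.MultiIndex.from_arrays(
            [[ids[i] for i in chosen], [1] * k_rep], names=["participant_id", "replicate"])
        betas = pd.concat([betas, pd.DataFrame(rep_rows, index=rep_index, columns=cpg_ids)])

    truth.clocks = clocks
    return betas, clocks


def write_cohort(outdir, participants: pd.DataFrame, roi: pd.DataFrame,
                 amyloid: pd.DataFrame, truth: SyntheticTruth,
                 betas: pd.DataFrame | None = None,
                 clocks: list[ClockModel] | None = None) -> dict:
    """Write the generated tables as UTF-8 CSV (+ truth JSON); returns paths."""
    from pathlib import Path

    from .clocks import write_clock

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    participants.to_csv(outdir / "participants.csv", index=False)
    paths["participants"] = outdir / "participants.csv"
    roi.to_csv(outdir / "roi.csv")
    paths["roi"] = outdir / "roi.csv"
    amyloid.to_csv(outdir / "amyloid.csv", index=False)
    paths["amyloid"] = outdir / "amyloid.csv"
    truth.to_json(outdir / "truth.json")
    paths["truth"] = outdir / "truth.json"
    if betas is not None:
        betas.to_csv(outdir / "methylation.csv")
        paths["methylation"] = outdir / "methylation.csv"
    if clocks:
        clock_dir = outdir / "clocks"
        clock_dir.mkdir(exist_ok=True)
        for c in clocks:
            write_clock(c, clock_dir / f"{c.name}.csv")
        paths["clocks"] = clock_dir
    return paths
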