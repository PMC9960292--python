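"""Synthetic study generator: design, latent bioactivity, LC-MS blocks, assay plates.

Emulates a balanced plant-extract screening design — nine individual trees
sampled at two sites (mountain, littoral) for three organs (leaf, stem bark,
fruit), i.e. 54 extracts — each profiled by LC-MS in two ionization modes and
assayed for alpha-glucosidase inhibition.  Every downstream stage of the
pipeline is testable against the ground truth planted here:

* a per-sample latent inhibition level set by organ x site cell means,
* a handful of "active" ions whose log peak area tracks the latent activity,
* organ-structured but activity-orthogonal variation in the remaining ions
  (the source of the orthogonal OPLS component),
* redundant co-eluting clone ions (r > 0.95, identical retention time) for
  the correlation-pruning stage,
* sub-threshold ions whose organ-mean peak areas stay below the intensity
  filter cutoff.

Intensities are log-normal: peak areas of a given ion vary multiplicatively
across extracts, which is the standard heteroscedastic behaviour of LC-MS
responses and keeps the correlation pruning non-trivial on the raw scale.

One master seed drives everything; stage-specific substreams are spawned from
it so that, e.g., regenerating the assay plate does not disturb the feature
blocks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

ORGANS = ("leaf", "stem_bark", "fruit")
SITES = ("littoral", "mountain")

#: substream indices spawned from the master seed
_STREAM_LATENT = 0
_STREAM_BLOCKS = 1
_STREAM_PLATE = 2


class GeneratorError(ValueError):
    """Invalid generator configuration or arguments."""


# ---------------------------------------------------------------------------
# configuration and ground truth containers
# ---------------------------------------------------------------------------

def _default_cell_means() -> dict:
    # organ x site mean inhibition (%) at the reference dose of 10 ug/mL.
    return {
        ("stem_bark", "littoral"): 84.7,
        ("stem_bark", "mountain"): 69.9,
        ("leaf", "littoral"): 49.0,
        ("leaf", "mountain"): 49.0,
        ("fruit", "littoral"): 13.6,
        ("fruit", "mountain"): 13.6,
    }


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic study.

    The defaults reproduce the emulated design: 54 samples, pre-filter ion
    counts that land near 198 (neg) / 160 (pos) after the standard filter
    chain, ten active ions split across the two modes, and a 5% triplicate
    CV on the assay.
    """

    n_trees: int = 9
    organ_site_mean_inhibition: dict = field(default_factory=_default_cell_means)
    latent_sd: float = 6.0            # tree-level spread of inhibition, % points
    n_ions_neg: int = 230
    n_ions_pos: int = 190
    n_active: int = 10
    n_clones_neg: int = 8
    n_clones_pos: int = 6
    n_subthreshold_neg: int = 12
    n_subthreshold_pos: int = 10
    effect_size_range: tuple = (2.0, 3.5)   # log-intensity units per unit activity/100
    active_baseline_log: float = math.log(8000.0)
    baseline_log_mean: float = 10.2   # inactive-ion mean log peak area (~27000)
    baseline_log_sd: float = 0.8
    organ_structure_sd: float = 0.6   # activity-orthogonal organ/site structure
    noise_sd_log_intensity: float = 0.35
    assay_cv: float = 0.05            # triplicate coefficient of variation
    a_negative_control: float = 1.0   # mean 405 nm absorbance, no inhibitor
    concentrations: tuple = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0)       # ug/mL
    acarbose_concentrations: tuple = (0.2, 0.4, 0.6, 0.8, 1.0)    # mg/mL
    acarbose_ic50: float = 0.05       # mg/mL; ~100% inhibition at the top dose
    n_replicates: int = 3
    rt_range: tuple = (0.4, 5.2)      # minutes
    active_rt_range: tuple = (0.7, 4.8)
    mz_range: tuple = (120.0, 1200.0)
    subthreshold_log_mean: float = math.log(300.0)
    subthreshold_guard: float = 2000.0    # organ means forced below this
    clone_epsilon_sd: float = 0.01
    clone_attenuation: float = 0.97   # keeps the parent the higher-median ion
    seed: int = 0

    def validate(self) -> None:
        counts = dict(
            n_trees=self.n_trees, n_ions_neg=self.n_ions_neg,
            n_ions_pos=self.n_ions_pos, n_replicates=self.n_replicates,
        )
        for name, v in counts.items():
            if v < 1:
                raise GeneratorError(f"{name} must be positive, got {v}")
        for k in ((o, s) for o in ORGANS for s in SITES):
            if k not in self.organ_site_mean_inhibition:
                raise GeneratorError(f"missing organ x site inhibition mean for {k}")
            m = self.organ_site_mean_inhibition[k]
            if not 0.0 <= m <= 100.0:
                raise GeneratorError(f"cell mean for {k} outside [0, 100]: {m}")
        if self.n_active < 0:
            raise GeneratorError("n_active must be non-negative")
        if self.assay_cv < 0:
            raise GeneratorError("assay_cv must be non-negative")
        lo, hi = self.rt_range
        if not (0.0 <= lo < hi <= 10.0):
            raise GeneratorError(f"rt_range must be increasing within [0, 10]: {self.rt_range}")

    def substream(self, index: int) -> np.random.Generator:
        children = np.random.SeedSequence(self.seed).spawn(3)
        return np.random.default_rng(children[index])


@dataclass
class GroundTruth:
    """What the generator planted; used to score downstream recovery."""

    latent_activity: pd.Series | None = None      # indexed by sample_id, %
    active_ion_ids: list = field(default_factory=list)
    effect_sizes: dict = field(default_factory=dict)       # ion_id -> slope
    redundant_pairs: list = field(default_factory=list)    # (parent, clone)
    subthreshold_ion_ids: list = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "latent_activity": {k: float(v) for k, v in self.latent_activity.items()},
            "active_ion_ids": list(self.active_ion_ids),
            "effect_sizes": {k: float(v) for k, v in self.effect_sizes.items()},
            "redundant_pairs": [list(p) for p in self.redundant_pairs],
            "subthreshold_ion_ids": list(self.subthreshold_ion_ids),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# design and latent activity
# ---------------------------------------------------------------------------

def generate_design(n_trees: int = 9, seed: int | None = None) -> pd.DataFrame:
    """Fully crossed sampling design: n_trees x 3 organs x 2 sites.

    The design is deterministic (``seed`` is accepted for interface symmetry
    but unused); records are ordered by (site, organ, tree).
    """
    if n_trees < 1:
        raise GeneratorError(f"n_trees must be >= 1, got {n_trees}")
    rows = []
    for site in SITES:
        for organ in ORGANS:
            for tree in range(1, n_trees + 1):
                rows.append({
                    "sample_id": f"{site}_{organ}_t{tree:02d}",
                    "tree_id": tree,
                    "organ": organ,
                    "site": site,
                })
    return pd.DataFrame(rows)


def generate_latent_activity(design: pd.DataFrame, config: GeneratorConfig,
                             rng: np.random.Generator | None = None) -> GroundTruth:
    """Per-sample target inhibition %: organ x site cell mean + tree noise, clipped to [0, 100]."""
    config.validate()
    if rng is None:
        rng = config.substream(_STREAM_LATENT)
    means = np.array([
        config.organ_site_mean_inhibition[(o, s)]
        for o, s in zip(design["organ"], design["site"])
    ])
    noise = rng.normal(0.0, config.latent_sd, size=len(design)) if config.latent_sd > 0 else 0.0
    activity = np.clip(means + noise, 0.0, 100.0)
    return GroundTruth(latent_activity=pd.Series(activity, index=design["sample_id"].to_numpy(),
                                                 name="latent_activity"))


# ---------------------------------------------------------------------------
# feature blocks
# ---------------------------------------------------------------------------

def _cell_index(design: pd.DataFrame) -> tuple[np.ndarray, list]:
    cells = [(o, s) for o in ORGANS for s in SITES]
    lookup = {c: i for i, c in enumerate(cells)}
    idx = np.array([lookup[(o, s)] for o, s in zip(design["organ"], design["site"])])
    return idx, cells


def _orthogonal_cell_offsets(rng, n_ions: int, activity_cell_means: np.ndarray,
                             sd: float) -> np.ndarray:
    """Cell-level offsets with zero projection on the activity contrast.

    Draw a 6-vector per ion, centre it, then remove its component along the
    centred activity cell-mean vector: the resulting between-cell structure is
    orthogonal to the bioactivity gradient, so inactive ions contribute only
    response-orthogonal variation.
    """
    a = activity_cell_means - activity_cell_means.mean()
    a_norm2 = float(a @ a)
    d = rng.normal(0.0, sd, size=(n_ions, len(a)))
    d -= d.mean(axis=1, keepdims=True)
    if a_norm2 > 0:
        d -= np.outer((d @ a) / a_norm2, a)
    return d


def generate_feature_blocks(design: pd.DataFrame, ground_truth: GroundTruth,
                            config: GeneratorConfig):
    """Two-mode feature tables with planted actives, clones and sub-threshold ions.

    Returns ``(neg_block, pos_block, ground_truth)`` with the ground truth
    completed in place (active ion ids, effect sizes, redundant pairs,
    sub-threshold ids).  Blocks are :class:`mbopls.features.FeatureBlock`.
    """
    from .features import FeatureBlock  # local import to avoid a cycle

    config.validate()
    if ground_truth.latent_activity is None:
        raise GeneratorError("ground truth latent activity must be populated first")
    rng = config.substream(_STREAM_BLOCKS)
    activity = ground_truth.latent_activity.loc[design["sample_id"]].to_numpy()
    n_samples = len(design)
    cell_idx, cells = _cell_index(design)
    # mean activity per cell (for orthogonalizing inactive-ion structure)
    act_cell = np.array([activity[cell_idx == i].mean() if (cell_idx == i).any() else 0.0
                         for i in range(len(cells))])

    n_active_by_mode = {"neg": (config.n_active + 1) // 2,
                        "pos": config.n_active // 2}
    blocks = {}
    for mode, n_total, n_clones, n_sub in (
        ("neg", config.n_ions_neg, config.n_clones_neg, config.n_subthreshold_neg),
        ("pos", config.n_ions_pos, config.n_clones_pos, config.n_subthreshold_pos),
    ):
        n_act = n_active_by_mode[mode]
        n_inactive = n_total - n_act - n_clones - n_sub
        if n_inactive < 0:
            raise GeneratorError(
                f"{mode}: n_active + clones + subthreshold exceeds total ions ({n_total})")

        ids, rts, mzs, cols = [], [], [], []
        counter = 0

        def new_id():
            nonlocal counter
            counter += 1
            return f"{mode}_ion_{counter:04d}"

        noise_sd = config.noise_sd_log_intensity

        # --- active ions: log area = baseline + effect * activity/100 + noise
        if n_act > 0:
            lo, hi = config.active_rt_range
            grid = np.linspace(lo, hi, n_act) if n_act > 1 else np.array([(lo + hi) / 2])
            jitter = rng.uniform(-0.04, 0.04, size=n_act)
            for j in range(n_act):
                ion = new_id()
                eff = rng.uniform(*config.effect_size_range)
                log_i = (config.active_baseline_log + eff * activity / 100.0
                         + rng.normal(0.0, noise_sd, n_samples))
                ids.append(ion)
                rts.append(float(np.clip(grid[j] + jitter[j], *config.rt_range)))
                mzs.append(rng.uniform(*config.mz_range))
                cols.append(np.exp(log_i))
                ground_truth.active_ion_ids.append(ion)
                ground_truth.effect_sizes[ion] = eff

        # --- inactive ions: organ/site structure orthogonal to activity
        if n_inactive > 0:
            base = rng.normal(config.baseline_log_mean, config.baseline_log_sd, n_inactive)
            offsets = _orthogonal_cell_offsets(rng, n_inactive, act_cell,
                                               config.organ_structure_sd)
            for j in range(n_inactive):
                ion = new_id()
                log_i = (base[j] + offsets[j, cell_idx]
                         + rng.normal(0.0, noise_sd, n_samples))
                ids.append(ion)
                rts.append(rng.uniform(*config.rt_range))
                mzs.append(rng.uniform(*config.mz_range))
                cols.append(np.exp(log_i))

        # --- sub-threshold ions: all organ-mean areas below the filter cutoff
        organ_codes = design["organ"].to_numpy()
        for _ in range(n_sub):
            ion = new_id()
            mu = config.subthreshold_log_mean + rng.normal(0.0, 0.3)
            x = np.exp(mu + rng.normal(0.0, noise_sd, n_samples))
            max_mean = max(x[organ_codes == o].mean() for o in ORGANS)
            guard = 0.95 * config.subthreshold_guard
            if max_mean >= guard:
                x *= guard / max_mean
            ids.append(ion)
            rts.append(rng.uniform(*config.rt_range))
            mzs.append(rng.uniform(*config.mz_range))
            cols.append(x)
            ground_truth.subthreshold_ion_ids.append(ion)

        # --- redundant clones of inactive parents eluting inside 0.5-5 min
        inactive_start = n_act
        inactive_ids = ids[inactive_start:inactive_start + n_inactive]
        eligible = [k for k, ion in enumerate(inactive_ids)
                    if 0.5 <= rts[inactive_start + k] <= 5.0]
        if n_clones > len(eligible):
            raise GeneratorError(f"{mode}: not enough in-window inactive ions to clone")
        chosen = rng.choice(len(eligible), size=n_clones, replace=False)
        for k in chosen:
            parent_pos = inactive_start + eligible[k]
            ion = new_id()
            eps = rng.normal(0.0, config.clone_epsilon_sd, n_samples)
            ids.append(ion)
            rts.append(rts[parent_pos])  # identical retention time
            mzs.append(rng.uniform(*config.mz_range))
            cols.append(cols[parent_pos] * config.clone_attenuation * (1.0 + eps))
            ground_truth.redundant_pairs.append((ids[parent_pos], ion))

        intensities = pd.DataFrame(
            np.column_stack(cols), index=design["sample_id"].to_numpy(), columns=ids)
        intensities.index.name = "sample_id"
        ions = pd.DataFrame({"mz": mzs, "rt": rts}, index=pd.Index(ids, name="ion_id"))
        blocks[mode] = FeatureBlock(intensities=intensities, ions=ions, mode=mode)

    return blocks["neg"], blocks["pos"], ground_truth


# ---------------------------------------------------------------------------
# assay plates
# ---------------------------------------------------------------------------

def generate_assay_plate(design: pd.DataFrame, ground_truth: GroundTruth,
                         config: GeneratorConfig) -> pd.DataFrame:
    """Long-format 405 nm absorbance records for every extract, the negative
    control and the acarbose positive control.

    The extract dose-response is linear in concentration, reaching the
    latent activity at the top dose (10 ug/mL): expected inhibition at dose c
    is ``latent * c / 10``.  Replicate absorbances are
    ``A_neg * (1 - inh/100) * (1 + CV * z)``.  Acarbose follows a saturating
    curve that is ~100% inhibitory at its top dose (1 mg/mL).
    """
    config.validate()
    if ground_truth.latent_activity is None:
        raise GeneratorError("ground truth latent activity must be populated first")
    rng = config.substream(_STREAM_PLATE)
    a0 = config.a_negative_control
    cv = config.assay_cv
    top = max(config.concentrations)
    rows = []

    def noisy(a_expected):
        if cv == 0:
            return a_expected
        return a_expected * (1.0 + cv * rng.standard_normal())

    for rep in range(1, config.n_replicates + 1):
        rows.append({"sample_id": "negative_control", "role": "negative_control",
                     "concentration": 0.0, "unit": "ug/mL", "replicate": rep,
                     "absorbance_405": max(noisy(a0), 0.0)})

    for sample_id in design["sample_id"]:
        act = float(ground_truth.latent_activity[sample_id])
        for c in config.concentrations:
            inh = act * (c / top)
            for rep in range(1, config.n_replicates + 1):
                rows.append({"sample_id": sample_id, "role": "extract",
                             "concentration": float(c), "unit": "ug/mL",
                             "replicate": rep,
                             "absorbance_405": max(noisy(a0 * (1.0 - inh / 100.0)), 0.0)})

    for c in config.acarbose_concentrations:
        inh = 100.0 * c ** 2 / (c ** 2 + config.acarbose_ic50 ** 2)
        for rep in range(1, config.n_replicates + 1):
            rows.append({"sample_id": "acarbose", "role": "positive_control",
                         "concentration": float(c), "unit": "mg/mL", "replicate": rep,
                         "absorbance_405": max(noisy(a0 * (1.0 - inh / 100.0)), 0.0)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# one-call dataset and serialization
# ---------------------------------------------------------------------------

def generate_dataset(config: GeneratorConfig):
    """Design + ground truth + both blocks + assay plate, from one master seed."""
    design = generate_design(config.n_trees)
    gt = generate_latent_activity(design, config)
    neg, pos, gt = generate_feature_blocks(design, gt, config)
    plate = generate_assay_plate(design, gt, config)
    return design, gt, neg, pos, plate


def write_dataset(out_dir, design, ground_truth, neg, pos, plate) -> dict:
    """Write metadata TSV, per-block CSVs, plate CSV and ground-truth JSON.

    Returns the mapping of artifact name -> path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "metadata": out / "metadata.tsv",
        "block_neg": out / "block_neg.csv",
        "block_pos": out / "block_pos.csv",
        "plate": out / "assay_plate.csv",
        "ground_truth": out / "ground_truth.json",
    }
    design.to_csv(paths["metadata"], sep="\t", index=False)
    neg.to_csv(paths["block_neg"])
    pos.to_csv(paths["block_pos"])
    plate.to_csv(paths["plate"], index=False)
    ground_truth.to_json(paths["ground_truth"])
    return {k: str(v) for k, v in paths.items()}


def config_from_dict(d: dict) -> GeneratorConfig:
    """Build a config from a plain (e.g. YAML) mapping.

    ``organ_site_mean_inhibition`` may be keyed "organ/site" or "organ,site".
    """
    d = dict(d)
    means = d.get("organ_site_mean_inhibition")
    if isinstance(means, dict):
        parsed = {}
        for k, v in means.items():
            if isinstance(k, str):
                organ, site = k.replace(",", "/").split("/")
                parsed[(organ.strip(), site.strip())] = float(v)
            else:
                parsed[tuple(k)] = float(v)
        d["organ_site_mean_inhibition"] = parsed
    for tup in ("effect_size_range", "rt_range", "active_rt_range", "mz_range",
                "concentrations", "acarbose_concentrations"):
        if tup in d and d[tup] is not None:
            d[tup] = tuple(d[tup])
    return GeneratorConfig(**d)


def config_to_dict(config: GeneratorConfig) -> dict:
    d = asdict(config)
    d["organ_site_mean_inhibition"] = {
        f"{o}/{s}": v for (o, s), v in config.organ_site_mean_inhibition.items()}
    return d
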