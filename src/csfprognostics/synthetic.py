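"""Seeded synthetic CSF-proteomics cohorts with known ground truth.

Real multiplexed TMT studies cannot ship with the package, so every
downstream stage is exercised on cohorts generated here: multi-batch
intensity matrices with per-batch multiplicative effects and
intensity-dependent missingness, planted group-differential proteins
organized into co-expressed modules, random-intercept/random-slope
longitudinal outcomes, conversion events with times, and monotone staged
biomarker trajectories. Every planted quantity is recorded in
:class:`SimTruth` so recovery can be tested exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .matrix import AbundanceMatrix, write_abundance_tsv

__all__ = [
    "SimConfig",
    "SimTruth",
    "generate_cohort",
    "generate_proteome",
    "generate_longitudinal_outcomes",
    "generate_staging_data",
    "write_cohort",
]

# stream tags keep independently callable generators decoupled under one seed
_STREAM_COHORT = 11
_STREAM_PROTEOME = 23
_STREAM_OUTCOMES = 37
_STREAM_STAGING = 53


class ConfigurationError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Scales are log2 for the proteome block (so ``batch_log2_sd=1`` means
    batch effects with sd one two-fold change) and outcome units/month for
    the longitudinal block.
    """

    n_subjects: int = 300
    n_proteins: int = 200
    n_batches: int = 10
    batch_log2_sd: float = 1.0
    sample_load_sd: float = 0.3
    noise_sd: float = 0.3
    frac_differential: float = 0.1
    effect_log2: float = 1.0
    n_modules: int = 4
    module_size: int = 20
    module_loading: float = 0.5
    missing_mcar: float = 0.05
    missing_mnar_quantile: float = 0.02
    baseline_log2_mean: float = 20.0
    baseline_log2_sd: float = 1.5
    intercept_fixed: float = 10.0
    slope_fixed: float = 0.2
    slope_sd: float = 0.1
    intercept_sd: float = 1.0
    outcome_noise_sd: float = 1.0
    visit_months: tuple = (0.0, 12.0, 25.0)
    conversion_frac: float = 0.3
    max_followup_months: float = 84.0
    ebm_n_biomarkers: int = 10
    ebm_z: float = 2.0
    ebm_sigma: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_subjects", "n_proteins", "n_batches", "n_modules",
                     "module_size", "ebm_n_biomarkers"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        for name in ("frac_differential", "missing_mcar", "missing_mnar_quantile",
                     "conversion_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        for name in ("batch_log2_sd", "sample_load_sd", "noise_sd", "slope_sd",
                     "intercept_sd", "outcome_noise_sd", "baseline_log2_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.ebm_sigma <= 0:
            raise ConfigurationError("ebm_sigma must be positive")
        if self.ebm_z == 0:
            raise ConfigurationError("ebm_z must be nonzero")
        if self.n_modules * self.module_size > self.n_proteins:
            raise ConfigurationError(
                "module_size x n_modules exceeds n_proteins")
        vm = list(self.visit_months)
        if len(vm) == 0 or any(b <= a for a, b in zip(vm, vm[1:])):
            raise ConfigurationError("visit_months must be strictly increasing")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))


@dataclass
class SimTruth:
    """Ground truth planted by the generators."""

    differential_proteins: dict = field(default_factory=dict)  # id -> signed log2 effect
    batch_factors: dict = field(default_factory=dict)          # batch id -> log2 offset
    module_membership: dict = field(default_factory=dict)      # protein id -> module id
    true_slopes: dict = field(default_factory=dict)            # outcome -> {subject -> slope}
    conversion_times: dict = field(default_factory=dict)       # subject -> months or None
    true_sequence: list = field(default_factory=list)          # ordered biomarker ids
    true_stages: dict = field(default_factory=dict)            # subject -> stage index

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True, default=str)


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Draw subjects, baseline samples, batch assignments and conversion labels.

    One baseline CSF sample per subject; TMT batches assigned round-robin;
    converter status drawn Bernoulli(``conversion_frac``) with conversion
    times uniform over [6, ``max_followup_months``] months.
    """
    config.validate()
    rng = config.rng(_STREAM_COHORT)
    n = config.n_subjects
    subjects = [f"S{i:04d}" for i in range(n)]
    samples = [f"smp{i:04d}" for i in range(n)]
    batches = [f"b{(i % config.n_batches) + 1:02d}" for i in range(n)]
    converter = rng.random(n) < config.conversion_frac
    conv_times = np.where(
        converter, rng.uniform(6.0, config.max_followup_months, size=n), np.nan)
    age = rng.normal(73.0, 7.0, size=n)
    apoe4 = rng.choice([0, 1, 2], size=n, p=[0.6, 0.3, 0.1])
    # CSF immunoassay markers: converters drawn with lower Abeta42, higher pTau
    abeta42 = np.exp(rng.normal(np.where(converter, 6.4, 6.9), 0.25, size=n))
    ptau181 = np.exp(rng.normal(np.where(converter, 3.3, 2.9), 0.3, size=n))
    meta = pd.DataFrame({
        "sample_id": samples,
        "subject_id": subjects,
        "batch_id": batches,
        "group": np.where(converter, "converter", "stable"),
        "diagnosis": np.where(converter, "MCI", "CN"),
        "abeta42": abeta42,
        "ptau181": ptau181,
        "apoe4_dose": apoe4,
        "age": age,
    })
    truth = SimTruth(
        conversion_times={s: (float(t) if np.isfinite(t) else None)
                          for s, t in zip(subjects, conv_times)})
    return meta, truth


def generate_proteome(
    meta: pd.DataFrame, truth: SimTruth, config: SimConfig
) -> tuple[AbundanceMatrix, SimTruth]:
    """Simulate the raw multi-batch intensity matrix.

    log2 intensity = protein baseline + batch offset + sample loading
    + module latent factor + group effect (differential proteins only)
    + residual noise; exponentiated to raw intensities; missingness applied
    (MCAR plus below-quantile MNAR) and encoded as zeros, matching the raw
    export convention.
    """
    config.validate()
    for col in ("batch_id", "group", "sample_id"):
        if col not in meta.columns:
            raise ConfigurationError(f"metadata lacks column {col}")
    rng = config.rng(_STREAM_PROTEOME)
    p, n = config.n_proteins, len(meta)
    protein_ids = [f"P{i:04d}" for i in range(p)]
    batch_ids = sorted(meta["batch_id"].unique())
    batch_off = rng.normal(0.0, config.batch_log2_sd, size=len(batch_ids))
    batch_map = dict(zip(batch_ids, batch_off))
    col_batch = meta["batch_id"].map(batch_map).to_numpy()
    loading = rng.normal(0.0, config.sample_load_sd, size=n)
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=p)

    # module membership: first n_modules blocks of module_size proteins
    membership: dict[str, str] = {}
    for m in range(config.n_modules):
        for j in range(m * config.module_size, (m + 1) * config.module_size):
            membership[protein_ids[j]] = f"M{m + 1}"

    # differential proteins fill whole modules first so enrichment is planted
    n_diff = int(round(config.frac_differential * p))
    module_order = [pid for pid in protein_ids if pid in membership]
    nonmodule = [pid for pid in protein_ids if pid not in membership]
    diff_ids = (module_order + nonmodule)[:n_diff]
    signs = rng.choice([-1.0, 1.0], size=n_diff)
    differential = {pid: float(s * config.effect_log2)
                    for pid, s in zip(diff_ids, signs)}

    log2 = baseline[:, None] + col_batch[None, :] + loading[None, :]
    # shared module-level latent factor induces co-expression
    latent = rng.normal(0.0, 1.0, size=(config.n_modules, n))
    for m in range(config.n_modules):
        rows = slice(m * config.module_size, (m + 1) * config.module_size)
        log2[rows] += config.module_loading * latent[m][None, :]
    is_conv = (meta["group"].to_numpy() == "converter").astype(float)
    row_of = {pid: i for i, pid in enumerate(protein_ids)}
    for pid, eff in differential.items():
        log2[row_of[pid]] += eff * is_conv
    log2 += rng.normal(0.0, config.noise_sd, size=(p, n))

    intens = np.exp2(log2)
    mask = rng.random((p, n)) < config.missing_mcar
    if config.missing_mnar_quantile > 0:
        thr = np.quantile(intens, config.missing_mnar_quantile)
        mask |= intens < thr
    values = np.where(mask, 0.0, intens)

    truth.batch_factors = {b: float(v) for b, v in batch_map.items()}
    truth.module_membership = membership
    truth.differential_proteins = differential
    m = AbundanceMatrix(values=values, mask=mask, protein_ids=protein_ids,
                        sample_ids=list(meta["sample_id"]), scale="raw")
    return m, truth


def generate_longitudinal_outcomes(
    meta: pd.DataFrame, config: SimConfig,
    truth: SimTruth | None = None, outcome_name: str = "ADAS-Cog11",
) -> tuple[pd.DataFrame, SimTruth]:
    """Random-intercept / random-slope outcome trajectories.

    y_ij = (b0 + u0_i) + (b1 + u1_i) * t_ij + eps_ij, with the per-subject
    true slope b1 + u1_i recorded in truth.
    """
    config.validate()
    if truth is None:
        truth = SimTruth()
    rng = config.rng(_STREAM_OUTCOMES)
    subjects = list(meta["subject_id"])
    t = np.asarray(config.visit_months, dtype=float)
    n, k = len(subjects), len(t)
    u0 = rng.normal(0.0, config.intercept_sd, size=n)
    u1 = rng.normal(0.0, config.slope_sd, size=n)
    eps = rng.normal(0.0, config.outcome_noise_sd, size=(n, k))
    y = (config.intercept_fixed + u0)[:, None] + \
        ((config.slope_fixed + u1)[:, None]) * t[None, :] + eps
    rows = pd.DataFrame({
        "subject_id": np.repeat(subjects, k),
        "outcome_name": outcome_name,
        "months": np.tile(t, n),
        "value": y.ravel(),
    })
    truth.true_slopes.setdefault(outcome_name, {})
    truth.true_slopes[outcome_name].update(
        {s: float(config.slope_fixed + u) for s, u in zip(subjects, u1)})
    return rows, truth


def generate_staging_data(
    config: SimConfig, truth: SimTruth | None = None
) -> tuple[pd.DataFrame, SimTruth]:
    """Cross-sectional staged biomarker z-data for ordering recovery.

    Each subject gets a stage k uniform on {0..N}; biomarker i reads
    Normal(ebm_z, ebm_sigma) once its event position is <= k, else
    Normal(0, ebm_sigma).
    """
    config.validate()
    if truth is None:
        truth = SimTruth()
    rng = config.rng(_STREAM_STAGING)
    n, nb = config.n_subjects, config.ebm_n_biomarkers
    if nb < 2:
        raise ConfigurationError("ebm_n_biomarkers must be >= 2")
    biomarkers = [f"B{i:02d}" for i in range(nb)]
    order = list(rng.permutation(biomarkers))
    position = {b: i + 1 for i, b in enumerate(order)}  # event positions 1..N
    stages = rng.integers(0, nb + 1, size=n)
    subjects = [f"S{i:04d}" for i in range(n)]
    mean = np.array([[config.ebm_z if position[b] <= k else 0.0
                      for b in biomarkers] for k in stages])
    z = mean + rng.normal(0.0, config.ebm_sigma, size=(n, nb))
    df = pd.DataFrame(z, index=subjects, columns=biomarkers)
    truth.true_sequence = order
    truth.true_stages = {s: int(k) for s, k in zip(subjects, stages)}
    return df, truth


def write_cohort(config: SimConfig, outdir) -> dict:
    """Generate a full cohort and write its TSV/JSON artifacts to ``outdir``."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    meta, truth = generate_cohort(config)
    abundance, truth = generate_proteome(meta, truth, config)
    outcomes, truth = generate_longitudinal_outcomes(meta, config, truth)
    staging, truth = generate_staging_data(config, truth)
    paths = {
        "abundance": out / "abundance.tsv",
        "metadata": out / "metadata.tsv",
        "outcomes": out / "outcomes.tsv",
        "staging": out / "staging_z.tsv",
        "truth": out / "truth.json",
    }
    write_abundance_tsv(abundance, paths["abundance"])
    meta.to_csv(paths["metadata"], sep="\t", index=False)
    outcomes.to_csv(paths["outcomes"], sep="\t", index=False)
    staging.to_csv(paths["staging"], sep="\t")
    truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
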