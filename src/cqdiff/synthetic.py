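"""Synthetic plasma-miRNA qPCR datasets with known ground truth.

The generator emulates an 84-assay serum/plasma focus panel measured on two
groups of 10 samples: three reference miRNAs, a red-blood-cell hemolysis
marker (miR-451a; the constant hemolysis marker miR-23a-3p doubles as a
reference, as in the real panel), 80 target assays, and four spike-in
channels at 100-fold concentration steps. The Cq model per miRNA cell is

    Cq(s, a) = baseline_a - delta_a * [s is case] - sample_effect(s) + noise,

where a true log2 fold change of delta in expression is one fewer cycle of
delta on the Cq scale, ``sample_effect`` is a per-sample global shift
(input/pipetting variation, absorbed exactly by reference normalization)
and noise is Gaussian technical noise. Spike-ins receive technical noise
only. Missingness arises mechanistically from limit-of-detection censoring:
after noise, any Cq above the ceiling becomes "not detected". Hemolysis is
injected by lowering the miR-451a Cq of chosen samples.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CqMatrix, SampleMetadata

DEFAULT_REFERENCE_IDS = ("hsa-miR-30c-5p", "hsa-miR-103a-3p", "hsa-miR-23a-3p")
DEFAULT_REFERENCE_BASELINES = (29.0, 30.0, 24.0)
RBC_MARKER_ID = "hsa-miR-451a"
#: ~6.64 cycles per 100-fold concentration step (log2(100))
HUNDREDFOLD_CYCLES = float(np.log2(100.0))
DEFAULT_SPIKE_BASELINES = {
    "UniSp2": 19.0,
    "UniSp4": 19.0 + HUNDREDFOLD_CYCLES,
    "UniSp5": 19.0 + 2 * HUNDREDFOLD_CYCLES,
    "UniSp6": 19.0,
}


@dataclass
class SyntheticConfig:
    """Study-scale defaults: 84 miRNA assays, 10 cases vs 10 controls."""

    n_case: int = 10
    n_control: int = 10
    n_assays: int = 84                       # miRNA assays incl. references and RBC marker
    reference_ids: tuple = DEFAULT_REFERENCE_IDS
    reference_baseline_cq: tuple = DEFAULT_REFERENCE_BASELINES
    rbc_marker_id: str = RBC_MARKER_ID
    rbc_baseline_cq: float = 20.0            # uncontaminated dCq = 24 - 20 = 4 cycles
    baseline_mean: float = 28.0              # target assay baseline Cq distribution
    baseline_sd: float = 3.0
    effects: dict = field(default_factory=dict)  # assay_id -> true log2 FC in cases
    noise_sd: float = 0.5                    # technical noise, cycles
    sample_effect_sd: float = 0.5            # per-sample global Cq shift, cycles
    lod_ceiling: float = 37.0                # Cq above this -> not detected
    hemolysis_samples: tuple = ()            # sample ids to contaminate
    hemolysis_shift: float = 4.0             # cycles removed from Cq(miR-451a)
    spike_baselines: dict = field(default_factory=lambda: dict(DEFAULT_SPIKE_BASELINES))
    confounder_strength: float = 0.0         # covariate shift between groups (SD units)
    seed: int = 123

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("need at least one sample per group")
        if len(self.reference_ids) != len(self.reference_baseline_cq):
            raise ValueError("reference_ids and reference_baseline_cq lengths differ")
        if self.n_assays < len(self.reference_ids) + 1:
            raise ValueError("n_assays must cover references plus the RBC marker")
        if self.baseline_sd < 0 or self.noise_sd < 0 or self.sample_effect_sd < 0:
            raise ValueError("dispersion parameters must be non-negative")
        if not (0 < self.lod_ceiling <= 45):
            raise ValueError("lod_ceiling must lie in (0, 45]")


@dataclass
class SyntheticTruth:
    """Ground truth injected into a simulated dataset."""

    log2_fc: dict                      # assay_id -> true log2 FC (0 if null)
    hemolysis_samples: tuple
    groups: dict                       # sample_id -> case/control
    covariates: pd.DataFrame
    sample_effects: dict
    baseline_cq: dict
    censored_fraction: dict            # assay_id -> fraction censored by LOD
    seed: int

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        d["covariates"] = self.covariates.to_dict(orient="index")
        d["hemolysis_samples"] = list(self.hemolysis_samples)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, sort_keys=True, default=float)
            fh.write("\n")


def _covariates(rng: np.random.Generator, groups: pd.Series, strength: float) -> pd.DataFrame:
    """Matching covariates: age, sex, NIHSS, OCSP subtype. ``strength`` shifts
    the case distributions (in fractions of an SD) to simulate confounding."""
    n = len(groups)
    is_case = (groups == "case").to_numpy().astype(float)
    age = rng.normal(70.0, 10.0, n) + strength * 3.0 * is_case
    sex = rng.choice(["F", "M"], n)
    nihss = np.clip(np.round(rng.normal(12.0, 5.0, n) + strength * 2.0 * is_case), 0, 42)
    ocsp = rng.choice(["PACS", "TACS", "POCS"], n, p=[0.7, 0.2, 0.1])
    return pd.DataFrame(
        {"age": np.round(age, 1), "sex": sex, "nihss": nihss.astype(int), "ocsp": ocsp},
        index=groups.index,
    )


def simulate_cq_dataset(config: SyntheticConfig | None = None, **overrides):
    """Generate (CqMatrix, SampleMetadata, SyntheticTruth) from a config.

    Deterministic given ``config.seed``. Keyword overrides are applied on
    top of the supplied (or default) config.
    """
    base = config or SyntheticConfig()
    if overrides:
        base = dataclasses.replace(base, **overrides)
    cfg = base
    rng = np.random.default_rng(cfg.seed)

    sample_ids = [f"case{i+1:02d}" for i in range(cfg.n_case)] + [
        f"ctrl{i+1:02d}" for i in range(cfg.n_control)
    ]
    groups = pd.Series(
        ["case"] * cfg.n_case + ["control"] * cfg.n_control, index=sample_ids, name="group"
    )

    n_targets = cfg.n_assays - len(cfg.reference_ids) - 1
    target_ids = [f"synthetic-miR-{i+1:03d}" for i in range(n_targets)]
    assay_ids = list(cfg.reference_ids) + [cfg.rbc_marker_id] + target_ids
    spike_ids = list(cfg.spike_baselines)

    baselines = dict(zip(cfg.reference_ids, cfg.reference_baseline_cq))
    baselines[cfg.rbc_marker_id] = cfg.rbc_baseline_cq
    target_base = np.clip(
        rng.normal(cfg.baseline_mean, cfg.baseline_sd, n_targets), 10.0, 44.0
    )
    baselines.update(zip(target_ids, target_base))

    unknown = set(cfg.effects) - set(assay_ids)
    if unknown:
        raise ValueError(f"effect map names unknown assay(s): {sorted(unknown)}")
    delta = np.array([cfg.effects.get(a, 0.0) for a in assay_ids])

    sample_effect = rng.normal(0.0, cfg.sample_effect_sd, len(sample_ids))
    is_case = (groups == "case").to_numpy().astype(float)

    base_row = np.array([baselines[a] for a in assay_ids])
    cq = (
        base_row[None, :]
        - is_case[:, None] * delta[None, :]
        - sample_effect[:, None]
        + rng.normal(0.0, cfg.noise_sd, (len(sample_ids), len(assay_ids)))
    )
    spikes = np.array([cfg.spike_baselines[s] for s in spike_ids])
    spike_cq = spikes[None, :] + rng.normal(0.0, cfg.noise_sd, (len(sample_ids), len(spike_ids)))

    # instrument range: amplification beyond 45 cycles is never read out
    values = pd.DataFrame(
        np.clip(np.hstack([cq, spike_cq]), 1.0, 45.0),
        index=sample_ids,
        columns=assay_ids + spike_ids,
    )
    roles = {a: "target" for a in target_ids}
    roles.update({a: "reference" for a in cfg.reference_ids})
    roles[cfg.rbc_marker_id] = "hemolysis_marker"
    roles.update({s: "spike_in" for s in spike_ids})
    matrix = CqMatrix(values, roles)

    if cfg.hemolysis_samples:
        matrix = inject_hemolysis(
            matrix, cfg.hemolysis_samples, cfg.hemolysis_shift, rbc_marker=cfg.rbc_marker_id
        )
    pre_censor = matrix.values.copy()
    matrix = apply_lod_censoring(matrix, cfg.lod_ceiling)
    censored = ((pre_censor > cfg.lod_ceiling).mean(axis=0)).to_dict()

    covariates = _covariates(rng, groups, cfg.confounder_strength)
    meta = covariates.copy()
    meta.insert(0, "group", groups)
    metadata = SampleMetadata(meta)

    truth = SyntheticTruth(
        log2_fc={a: float(cfg.effects.get(a, 0.0)) for a in assay_ids},
        hemolysis_samples=tuple(cfg.hemolysis_samples),
        groups=groups.to_dict(),
        covariates=covariates,
        sample_effects=dict(zip(sample_ids, map(float, sample_effect))),
        baseline_cq={a: float(baselines[a]) for a in assay_ids},
        censored_fraction={a: float(f) for a, f in censored.items()},
        seed=cfg.seed,
    )
    return matrix, metadata, truth


def inject_hemolysis(cq: CqMatrix, samples, shift, rbc_marker: str = RBC_MARKER_ID) -> CqMatrix:
    """Lower the RBC-marker Cq of the listed samples by ``shift`` cycles.

    ``shift`` may be a scalar or a per-sample mapping. Returns a new matrix;
    unknown sample ids are errors.
    """
    if rbc_marker not in cq.values.columns:
        raise KeyError(f"RBC marker {rbc_marker!r} not in matrix")
    values = cq.values.copy()
    shifts = shift if isinstance(shift, dict) else {s: shift for s in samples}
    for s in samples:
        if s not in values.index:
            raise KeyError(f"unknown sample {s!r}")
        values.loc[s, rbc_marker] = values.loc[s, rbc_marker] - shifts[s]
    return CqMatrix(values, dict(cq.assay_role))


def apply_lod_censoring(cq: CqMatrix, ceiling: float = 37.0) -> CqMatrix:
    """Censor Cq values strictly above the limit-of-detection ceiling to missing."""
    if not (0 < ceiling <= 45):
        raise ValueError("ceiling must lie in (0, 45]")
    values = cq.values.where(~(cq.values > ceiling))
    return CqMatrix(values, dict(cq.assay_role))


def simulate_matching_cohort(
    n_case: int = 10,
    n_pool: int = 40,
    confounder_strength: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Covariate table + group labels with confounded case assignment.

    Draws a candidate pool, scores each subject on a linear combination of
    age, NIHSS and sex scaled by ``confounder_strength``, and selects the
    cases by a noisy top-``n_case`` rule (Gumbel perturbation), so case
    status genuinely depends on the covariates and matching has imbalance
    to remove.
    """
    rng = np.random.default_rng(seed)
    ids = [f"s{i+1:03d}" for i in range(n_pool)]
    age = rng.normal(70.0, 10.0, n_pool)
    nihss = np.clip(np.round(rng.normal(12.0, 5.0, n_pool)), 0, 42)
    sex = rng.choice([0.0, 1.0], n_pool)
    score = confounder_strength * (0.08 * (age - 70.0) + 0.15 * (nihss - 12.0) + 0.5 * sex)
    noisy = score + rng.gumbel(0.0, 1.0, n_pool)
    case_idx = set(np.argsort(noisy)[-n_case:])
    group = pd.Series(
        ["case" if i in case_idx else "control" for i in range(n_pool)], index=ids, name="group"
    )
    cov = pd.DataFrame(
        {"age": np.round(age, 1), "nihss": nihss.astype(int), "sex": sex}, index=ids
    )
    return cov, group
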