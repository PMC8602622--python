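"""Synthetic factorial metabolomics studies with known planted effects.

The generator emulates the study design this pipeline targets: 34 animals in
four unbalanced capacity x age cells (HCR-Y n=10, LCR-Y n=10, HCR-O n=6,
LCR-O n=8), with 89 serum, 71 muscle and 71 white-adipose-tissue metabolites.
Raw abundances are log-normal: for metabolite j,

    abundance_ij = exp( mu_j + b1_j*cap_i + b2_j*age_i + b3_j*cap_i*age_i + e_ij ),
    e_ij ~ Normal(0, sigma_j),  cap, age coded 0/1 (LCR / young reference),

so the Box-Cox exponent lambda = 0 is the recoverable truth for the
transformation-selection stage.  Planted coefficients b are expressed in
units of the within-group log-scale SD sigma_j and recorded in a GroundTruth
object so every downstream stage can be recovery-tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GROUP_ORDER, MetaboliteMatrix, StudyDesign

EFFECT_TERMS = ("capacity", "age", "interaction")


def _default_tissues() -> dict:
    return {"serum": 89, "muscle": 71, "wat": 71}


def _default_speed_model() -> dict:
    # m/min; LCR-young baseline ~20, HCR advantage ~14, old-HCR decline ~25%
    return {
        "intercept": 20.0,
        "capacity": 14.0,
        "age": -1.0,
        "interaction": -8.0,
        "metabolite_coef": 2.0,
        "frac_metabolites": 0.1,
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Effect sizes are standardized (units of within-group SD on the log
    scale); ``frac_affected`` is the fraction of metabolites carrying each
    effect type, drawn independently per term.  ``speed_model`` links running
    speed to the design cells and to a subset of metabolites of the first
    tissue (serum by default).
    """

    n_per_group: tuple = (10, 10, 6, 8)  # HCR-Y, LCR-Y, HCR-O, LCR-O
    tissues: dict = field(default_factory=_default_tissues)
    effect_capacity: float = 1.0
    effect_age: float = 1.0
    effect_interaction: float = 1.0
    frac_affected: float = 0.1
    base_log_mean: tuple = (1.0, 3.0)
    base_log_sd: tuple = (0.2, 0.6)
    speed_model: dict = field(default_factory=_default_speed_model)
    noise_sd_speed: float = 2.0
    block_correlation: bool = False
    block_size: int = 5
    block_rho: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_group) != 4 or any(int(n) <= 0 for n in self.n_per_group):
            raise ValueError("n_per_group must be four positive counts")
        if not self.tissues or any(int(j) <= 0 for j in self.tissues.values()):
            raise ValueError("each tissue needs a positive metabolite count")
        if not 0.0 <= self.frac_affected <= 1.0:
            raise ValueError("frac_affected must lie in [0, 1]")
        if not 0.0 <= self.block_rho < 1.0:
            raise ValueError("block_rho must lie in [0, 1)")


@dataclass
class GroundTruth:
    """Planted per-metabolite coefficients (log scale), one table per tissue.

    Columns: metabolite, beta_capacity, beta_age, beta_interaction,
    speed_coef (0 where the metabolite does not feed the speed model).
    A metabolite with all three design coefficients zero is a true null.
    """

    tables: dict

    def affected(self, tissue: str, term: str) -> set:
        t = self.tables[tissue]
        return set(t.loc[t[f"beta_{term}"] != 0.0, "metabolite"])

    def true_nulls(self, tissue: str) -> set:
        t = self.tables[tissue]
        null = (t[[f"beta_{term}" for term in EFFECT_TERMS]] == 0.0).all(axis=1)
        return set(t.loc[null, "metabolite"])


def _correlated_noise(rng, n, J, sigma, block_size, rho) -> np.ndarray:
    """Block-equicorrelated Gaussian noise, blocks of ``block_size`` columns."""
    z = rng.standard_normal((n, J))
    out = np.empty_like(z)
    for start in range(0, J, block_size):
        block = z[:, start : start + block_size]
        shared = rng.standard_normal((n, 1))
        out[:, start : start + block.shape[1]] = (
            np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * block
        )
    return out * sigma


def simulate_study(config: SimulationConfig) -> tuple[dict, StudyDesign, GroundTruth]:
    """Generate per-tissue abundance matrices, a design and the ground truth."""
    rng = np.random.default_rng(config.seed)
    groups = [g for g, n in zip(GROUP_ORDER, config.n_per_group) for _ in range(int(n))]
    n = len(groups)
    sample_ids = [f"R{i + 1:02d}" for i in range(n)]
    capacity = [g.split("-")[0] for g in groups]
    age = [g.split("-")[1] for g in groups]
    design_table = pd.DataFrame(
        {"capacity": capacity, "age": age}, index=pd.Index(sample_ids, name="sample_id")
    )
    cap = (design_table["capacity"] == "HCR").to_numpy(float)
    old = (design_table["age"] == "O").to_numpy(float)

    effect_sizes = {
        "capacity": config.effect_capacity,
        "age": config.effect_age,
        "interaction": config.effect_interaction,
    }
    matrices: dict = {}
    truth_tables: dict = {}
    speed_contrib = np.zeros(n)
    for tissue_index, (tissue, J) in enumerate(config.tissues.items()):
        J = int(J)
        met_ids = [f"{tissue}_m{j + 1:03d}" for j in range(J)]
        mu = rng.uniform(*config.base_log_mean, size=J)
        sigma = rng.uniform(*config.base_log_sd, size=J)
        betas = {}
        n_affected = int(np.floor(config.frac_affected * J))
        for term in EFFECT_TERMS:
            b = np.zeros(J)
            if n_affected > 0 and effect_sizes[term] != 0.0:
                idx = rng.choice(J, size=n_affected, replace=False)
                signs = rng.choice([-1.0, 1.0], size=n_affected)
                b[idx] = signs * effect_sizes[term] * sigma[idx]
            betas[term] = b

        mean_log = (
            mu[None, :]
            + np.outer(cap, betas["capacity"])
            + np.outer(old, betas["age"])
            + np.outer(cap * old, betas["interaction"])
        )
        if config.block_correlation:
            noise = _correlated_noise(rng, n, J, sigma[None, :],
                                      config.block_size, config.block_rho)
        else:
            noise = rng.standard_normal((n, J)) * sigma[None, :]
        log_abund = mean_log + noise
        values = np.exp(log_abund)
        matrices[tissue] = MetaboliteMatrix(
            pd.DataFrame(values, index=pd.Index(sample_ids, name="sample_id"),
                         columns=met_ids),
            tissue=tissue,
        )

        speed_coef = np.zeros(J)
        if tissue_index == 0:
            sm = config.speed_model
            k = int(np.floor(sm.get("frac_metabolites", 0.0) * J))
            if k > 0 and sm.get("metabolite_coef", 0.0) != 0.0:
                idx = rng.choice(J, size=k, replace=False)
                speed_coef[idx] = sm["metabolite_coef"]
                z = (log_abund[:, idx] - log_abund[:, idx].mean(axis=0)) / log_abund[
                    :, idx
                ].std(axis=0, ddof=1)
                speed_contrib = z @ speed_coef[idx]
        truth_tables[tissue] = pd.DataFrame(
            {
                "metabolite": met_ids,
                "beta_capacity": betas["capacity"],
                "beta_age": betas["age"],
                "beta_interaction": betas["interaction"],
                "speed_coef": speed_coef,
            }
        )

    sm = config.speed_model
    speed = (
        sm["intercept"]
        + sm["capacity"] * cap
        + sm["age"] * old
        + sm["interaction"] * cap * old
        + speed_contrib
        + rng.standard_normal(n) * config.noise_sd_speed
    )
    design_table["speed"] = np.clip(speed, 0.0, None)
    return matrices, StudyDesign(design_table), GroundTruth(truth_tables)


def null_permutation_dataset(matrix: MetaboliteMatrix, design: StudyDesign,
                             seed: int) -> StudyDesign:
    """Jointly permute the capacity and age labels across samples.

    Group sizes are preserved while any metabolite-design association is
    severed; speed stays attached to its sample.
    """
    if matrix.sample_ids != design.sample_ids:
        raise ValueError("inputs must be aligned before permutation")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(design.n_samples)
    table = design.table.copy()
    table[["capacity", "age"]] = table[["capacity", "age"]].to_numpy()[perm]
    return StudyDesign(table)


def write_ground_truth(truth: GroundTruth, path) -> None:
    rows = []
    for tissue, table in truth.tables.items():
        t = table.copy()
        t.insert(0, "tissue", tissue)
        rows.append(t)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
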