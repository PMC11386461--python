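"""Synthetic two-species, two-study expression pairs with known truth.

The generator emulates the structure the normalization problem assumes:
two bulk RNA-seq studies, one per species, each profiling the same two
conditions.  On the log2 scale, a gene's clean value is

    value = mu_g + delta_sp[g] * [species 2] + delta_cond[g, species] * [C2]

where a small fraction of genes carries a condition effect (shared sign
across species except for a discordant minority) and another small fraction
a species effect.  Each study then distorts its values with a global affine
map, gene-wise offsets and i.i.d. noise:

    value <- a_d * value + c_d + b[g, d] + eps,   eps ~ N(0, noise_sd).

The per-study gene-wise offsets are what inflates the cross and species DEG
lists before normalization; the affine-per-cluster CSN model can in
principle undo the distortion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import ExpressionMatrix, OrthologMap

__all__ = ["SimConfig", "SyntheticTruth", "simulate_pair"]


@dataclass(frozen=True)
class SimConfig:
    """Generator settings (all effect sizes on the log2 scale)."""

    n_genes: int = 2000
    samples_per_group: int = 5
    frac_condition_de: float = 0.10
    frac_species_de: float = 0.10
    frac_discordant: float = 0.05
    effect_low: float = 1.5
    effect_high: float = 3.0
    batch_offset_sd: float = 1.0
    batch_scale_range: tuple = (0.8, 1.2)
    batch_shift_range: tuple = (-1.0, 1.0)
    noise_sd: float = 0.5
    baseline_mean: float = 6.0
    baseline_sd: float = 2.0
    condition_c1: str = "C1"
    condition_c2: str = "C2"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_condition_de", "frac_species_de", "frac_discordant"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.frac_condition_de + self.frac_species_de > 1.0:
            raise ValueError("DE fractions may not sum above 1")
        if self.baseline_sd <= 0:
            raise ValueError("baseline_sd must be positive")
        if self.noise_sd < 0 or self.batch_offset_sd < 0:
            raise ValueError("noise/batch offset sds must be nonnegative")
        if self.effect_high < self.effect_low or self.effect_low < 0:
            raise ValueError("need 0 <= effect_low <= effect_high")
        if self.n_genes < 1 or self.samples_per_group < 2:
            raise ValueError("need >= 1 gene and >= 2 samples per group")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated pair.

    ``condition_de`` maps each species key ("x", "y") to
    {gene_id: direction}, where direction +1 means higher expression in C1
    (matching the condition DEG list convention C1 - C2).
    ``species_de`` maps gene ids of each dataset to the direction of the
    species-2 effect.  ``batch`` records each study's distortion parameters.
    """

    condition_de: dict
    species_de: dict
    batch: dict
    ortholog_map: OrthologMap


def _sample_ids(prefix: str, cond: str, n: int) -> list:
    return [f"{prefix}_{cond}_{r + 1}" for r in range(n)]


def simulate_pair(config: SimConfig = SimConfig()):
    """Generate ``(X, Y, truth)``: one matrix per species/study.

    X is species 1 / study 1 (gene ids ``spA_g...``), Y species 2 / study 2
    (``spB_g...``); rows are orthologous in order and the identity pairing
    is returned inside the truth.  Deterministic given ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    r = cfg.samples_per_group

    stems = [f"g{i + 1:05d}" for i in range(n)]
    x_ids = [f"spA_{s}" for s in stems]
    y_ids = [f"spB_{s}" for s in stems]

    mu = rng.normal(cfg.baseline_mean, cfg.baseline_sd, n)

    n_cond = int(round(cfg.frac_condition_de * n))
    n_sp = int(round(cfg.frac_species_de * n))
    perm = rng.permutation(n)
    cond_idx = perm[:n_cond]
    sp_idx = perm[n_cond:n_cond + n_sp]

    # condition effect (applied to C2), shared sign across species except a
    # discordant minority whose sign flips in species 2
    cond_mag = rng.uniform(cfg.effect_low, cfg.effect_high, n_cond)
    cond_sign = rng.choice([-1.0, 1.0], n_cond)
    delta_cond_x = np.zeros(n)
    delta_cond_x[cond_idx] = cond_mag * cond_sign
    n_disc = int(round(cfg.frac_discordant * n_cond))
    disc_local = rng.permutation(n_cond)[:n_disc]
    flip = np.ones(n_cond)
    flip[disc_local] = -1.0
    delta_cond_y = np.zeros(n)
    delta_cond_y[cond_idx] = cond_mag * cond_sign * flip

    # species effect, applied to species 2 only
    sp_mag = rng.uniform(cfg.effect_low, cfg.effect_high, n_sp)
    sp_sign = rng.choice([-1.0, 1.0], n_sp)
    delta_sp = np.zeros(n)
    delta_sp[sp_idx] = sp_mag * sp_sign

    # per-study distortions
    batch = {}
    matrices = {}
    for key, prefix, cond_delta, sp_shift in (
        ("x", "spA", delta_cond_x, 0.0),
        ("y", "spB", delta_cond_y, 1.0),
    ):
        a_d = rng.uniform(*cfg.batch_scale_range)
        c_d = rng.uniform(*cfg.batch_shift_range)
        b_gd = rng.normal(0.0, cfg.batch_offset_sd, n)
        batch[key] = {"scale": a_d, "shift": c_d, "gene_offsets": b_gd}

        base = mu + sp_shift * delta_sp
        cols = {}
        col_conditions = []
        for cond_label, has_effect in (
            (cfg.condition_c1, 0.0), (cfg.condition_c2, 1.0)
        ):
            clean = base + has_effect * cond_delta
            for sid in _sample_ids(prefix, cond_label, r):
                eps = rng.normal(0.0, cfg.noise_sd, n)
                cols[sid] = a_d * clean + c_d + b_gd + eps
                col_conditions.append(cond_label)
        ids = x_ids if key == "x" else y_ids
        values = pd.DataFrame(cols, index=pd.Index(ids, name="gene_id"))
        samples = pd.DataFrame(
            {
                "study": f"study_{key}",
                "species": "species_A" if key == "x" else "species_B",
                "condition": col_conditions,
            },
            index=values.columns,
        )
        matrices[key] = ExpressionMatrix(values, samples)

    # directions in the C1 - C2 convention: +1 = higher in C1 = -sign(delta)
    def dirs(ids, delta):
        return {
            ids[i]: int(-np.sign(delta[i])) for i in cond_idx if delta[i] != 0
        }

    truth = SyntheticTruth(
        condition_de={
            "x": dirs(x_ids, delta_cond_x),
            "y": dirs(y_ids, delta_cond_y),
        },
        species_de={
            "x": {x_ids[i]: int(np.sign(delta_sp[i])) for i in sp_idx},
            "y": {y_ids[i]: int(np.sign(delta_sp[i])) for i in sp_idx},
        },
        batch=batch,
        ortholog_map=OrthologMap(tuple(zip(x_ids, y_ids))),
    )
    return matrices["x"], matrices["y"], truth
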