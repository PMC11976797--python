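"""Synthetic assay and predictor generators.

Emulates the structure of the real experiment: a pool of biological
replicates (default 17), each covering a random subset of variants across
2-3 technical replicates; WT / EV / KD controls present in every
(bio, tech) pair; each variant covered by 3-6 biological replicates; true
activity drawn from a bimodal low-activity / WT-like mixture. Raw readings
are produced by mapping R-WT-scale activity (truth plus replicate noise)
through per-replicate WT and EV baselines, so the normalization round-trips
exactly when the noise is zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from vepbench._rng import substream
from vepbench.assay import (
    CONTROL_EV,
    CONTROL_KD,
    CONTROL_WT,
    REPLICATE_COLUMNS,
)
from vepbench.predictions import ORIENT_ACTIVITY, ORIENT_PATHOGENICITY, PredictionSet


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs for the assay generator; defaults mirror the real design."""

    n_variants: int = 28
    n_bio_reps_total: int = 17
    bio_reps_per_variant: tuple[int, int] = (3, 6)
    tech_reps_per_bio: tuple[int, int] = (2, 3)
    noise_sd: float = 0.1  # replicate noise on the R-WT scale
    #: 50/50 mixture of Normal(0.2, 0.15) and Normal(1.1, 0.25), truncated
    truth_components: tuple[tuple[float, float], ...] = ((0.2, 0.15), (1.1, 0.25))
    truth_bounds: tuple[float, float] = (-0.2, 2.0)
    wt_base_range: tuple[float, float] = (2.0, 4.0)
    ev_base_range: tuple[float, float] = (0.5, 1.0)
    kd_activity: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 1 or self.n_bio_reps_total < 1:
            raise ValueError("counts must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.bio_reps_per_variant[1] > self.n_bio_reps_total:
            raise ValueError("bio_reps_per_variant max exceeds total replicates")


def sample_truth(
    config: SyntheticConfig, rng: np.random.Generator
) -> dict[str, float]:
    """Draw true activities from the truncated bimodal mixture."""
    lo, hi = config.truth_bounds
    truth = {}
    for i in range(config.n_variants):
        comp = config.truth_components[rng.integers(len(config.truth_components))]
        value = rng.normal(*comp)
        while not lo <= value <= hi:
            value = rng.normal(*comp)
        truth[f"v{i:03d}"] = float(value)
    return truth


def generate_assay(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Raw long-format replicate table plus the true activity map.

    Every (bio, tech) pair carries WT, EV and KD readings; a variant's raw
    reading is EV_base + (truth + noise) * (WT_base - EV_base).
    """
    rng = substream(config.seed, "synthetic/assay")
    truth = sample_truth(config, rng)
    variants = list(truth)
    lo, hi = config.bio_reps_per_variant
    assignment = {
        v: rng.choice(config.n_bio_reps_total, size=rng.integers(lo, hi + 1), replace=False)
        for v in variants
    }
    tlo, thi = config.tech_reps_per_bio
    rows = []
    for b in range(config.n_bio_reps_total):
        bio = f"B{b + 1:02d}"
        members = [v for v in variants if b in assignment[v]]
        for t in range(int(rng.integers(tlo, thi + 1))):
            tech = f"T{t + 1}"
            wt_base = rng.uniform(*config.wt_base_range)
            ev_base = rng.uniform(*config.ev_base_range)
            span = wt_base - ev_base

            def raw(activity: float, noisy: bool = True) -> float:
                eps = rng.normal(0.0, config.noise_sd) if noisy and config.noise_sd else 0.0
                return ev_base + (activity + eps) * span

            rows.append((CONTROL_WT, bio, tech, raw(1.0, noisy=False)))
            rows.append((CONTROL_EV, bio, tech, raw(0.0, noisy=False)))
            rows.append((CONTROL_KD, bio, tech, raw(config.kd_activity)))
            for v in members:
                rows.append((v, bio, tech, raw(truth[v])))
    table = pd.DataFrame(rows, columns=list(REPLICATE_COLUMNS))
    return table, truth


def noise_sd_for_tau(target_tau: float, truth_sd: float) -> float:
    """Gaussian noise sd so that truth + noise attains ~``target_tau``.

    Uses tau = (2/pi) arcsin(rho) for bivariate normals, with
    rho = sd_truth / sqrt(sd_truth^2 + sd_noise^2); approximate for
    non-Gaussian truth but adequate for targeting.
    """
    if not 0 < target_tau < 1:
        raise ValueError("target tau must be in (0, 1)")
    rho = math.sin(target_tau * math.pi / 2)
    return truth_sd * math.sqrt(1.0 / rho**2 - 1.0)


def generate_predictor(
    truth: dict[str, float],
    orientation: str = ORIENT_ACTIVITY,
    noise_sd: float = 0.0,
    missing_rate: float = 0.0,
    seed: int = 0,
    name: str = "synthetic",
    target_tau: float | None = None,
    **kwargs,
) -> PredictionSet:
    """Noisy view of the truth as a PredictionSet of either orientation.

    Activity orientation emits truth + noise; pathogenicity orientation
    emits 1 - (truth + noise) clipped to [0, 1]. ``target_tau`` overrides
    ``noise_sd`` via the Gaussian tau-noise relationship. Missing entries
    are injected independently at ``missing_rate``.
    """
    if not truth:
        raise ValueError("empty truth map")
    rng = substream(seed, f"synthetic/predictor/{name}")
    if target_tau is not None:
        noise_sd = noise_sd_for_tau(target_tau, float(np.std(list(truth.values()))))
    scores = {}
    for v, t in truth.items():
        if missing_rate and rng.random() < missing_rate:
            continue
        y = t + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
        if orientation == ORIENT_PATHOGENICITY:
            y = float(np.clip(1.0 - y, 0.0, 1.0))
        scores[v] = float(y)
    if not scores:
        raise ValueError("missing_rate removed every score")
    return PredictionSet(
        predictor=name, orientation=orientation, scores=scores, **kwargs
    )


def load_fixtures():
    """Packaged ground-truth and classification fixtures; see
    :mod:`vepbench.fixtures`."""
    from vepbench import fixtures

    return fixtures.load_activity_fixture(), fixtures.load_classification_fixture()
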