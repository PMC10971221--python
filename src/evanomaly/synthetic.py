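"""Synthetic three-donor abundance tables with known planted structure.

The generator emulates the structure the pipeline assumes: the same D
donors measured in every condition, a dominant cloud of consistently
quantified proteins (the analog of the density-retained primary cluster),
an optional secondary low-abundance contaminant cloud to exercise the
density filter, and a minority of planted condition-specific anomalies.

Model on the log2 scale:

    l(p, d, c) = mu_p + delta_d + beta_{p,c} + eps

with protein baselines mu_p ~ N(mu0, sigma_p), donor offsets
delta_d ~ N(0, sigma_d) shared across proteins and conditions,
measurement noise eps ~ N(0, sigma_eps) per cell, and beta = 0 except for
planted anomalies, where beta_{p, treatment} = +-Delta with random sign.
Raw peak areas are 2**l (effects multiplicative on intensities).

Default magnitudes: the main cloud models a homogeneous expression
cluster, so the between-protein baseline spread (sigma_p = 0.75) sits only
modestly above the per-measurement noise (sigma_eps = 0.5 log2 units,
about 35% CV — in line with commonly reported 20-30% technical CVs plus
donor-level biological noise); the planted shift Delta = 3 log2 units
(8-fold, 6 noise SDs) is an "extremely changing" effect.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import AbundanceTable, ProteinId

__all__ = ["SyntheticSpec", "SyntheticTruth", "generate", "expected_distance"]


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """The stated world of the generator; see the module docstring."""

    n_proteins: int = 500
    n_donors: int = 3
    conditions: tuple[str, ...] = ("plast", "ctrl", "doped")
    anomaly_condition: str = "doped"
    mu0: float = 20.0
    sigma_p: float = 0.75
    sigma_d: float = 0.5
    sigma_eps: float = 0.5
    anomaly_fraction: float = 0.02
    effect_size: float = 3.0
    contaminant_fraction: float = 0.0
    contaminant_offset: float = -8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.n_donors < 2:
            raise ValueError("need n_proteins >= 1 and n_donors >= 2")
        if min(self.sigma_p, self.sigma_d, self.sigma_eps) < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0 <= self.anomaly_fraction < 1:
            raise ValueError("anomaly_fraction must be in [0, 1)")
        if not 0 <= self.contaminant_fraction < 1:
            raise ValueError("contaminant_fraction must be in [0, 1)")
        if self.anomaly_fraction + self.contaminant_fraction >= 1:
            raise ValueError("anomaly + contaminant fractions must be < 1")
        if self.anomaly_condition not in self.conditions:
            raise ValueError("anomaly_condition must be one of conditions")


@dataclasses.dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth: signed anomaly effects and contaminant ids."""

    anomaly_effects: dict[str, float]   # accession -> signed Delta
    contaminant_accessions: frozenset[str]

    @property
    def anomaly_accessions(self) -> frozenset[str]:
        return frozenset(self.anomaly_effects)


def generate(spec: SyntheticSpec) -> tuple[AbundanceTable, SyntheticTruth]:
    """Generate an abundance table plus its planted truth, reproducibly.

    Accessions are SYN00001... (contaminants carry a CONT prefix so a
    reader of the fixture can tell the planted clouds apart; membership is
    still asserted through the returned truth object, not the names).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_proteins
    n_anom = int(round(spec.anomaly_fraction * n))
    n_cont = int(round(spec.contaminant_fraction * n))

    # Contaminants occupy the tail indices; anomalies are drawn from the
    # main cloud only (a contaminant protein is a different population).
    idx = np.arange(n)
    cont_idx = idx[n - n_cont:] if n_cont else idx[:0]
    anom_idx = rng.choice(idx[:n - n_cont], size=n_anom, replace=False) \
        if n_anom else idx[:0]
    signs = rng.choice([-1.0, 1.0], size=n_anom)

    mu = rng.normal(spec.mu0, spec.sigma_p, size=n)
    mu[cont_idx] += spec.contaminant_offset
    delta = rng.normal(0.0, spec.sigma_d, size=spec.n_donors)

    beta = np.zeros((n, len(spec.conditions)))
    c_anom = spec.conditions.index(spec.anomaly_condition)
    beta[anom_idx, c_anom] = signs * spec.effect_size

    eps = rng.normal(0.0, spec.sigma_eps,
                     size=(n, spec.n_donors, len(spec.conditions)))
    log2 = (mu[:, None, None] + delta[None, :, None]
            + beta[:, None, :] + eps)
    raw = np.power(2.0, log2)

    accs = [f"CONT{i + 1:05d}" if i in set(cont_idx.tolist())
            else f"SYN{i + 1:05d}" for i in range(n)]
    donors = [f"d{j + 1}" for j in range(spec.n_donors)]
    proteins = [ProteinId(a) for a in accs]
    columns = pd.MultiIndex.from_product([donors, list(spec.conditions)],
                                         names=["donor", "condition"])
    flat = {(d, c): raw[:, j, k]
            for j, d in enumerate(donors)
            for k, c in enumerate(spec.conditions)}
    data = pd.DataFrame(flat, index=accs)[columns]
    data.columns = columns
    table = AbundanceTable(proteins, donors, list(spec.conditions), data)
    truth = SyntheticTruth(
        anomaly_effects={accs[i]: float(s * spec.effect_size)
                         for i, s in zip(anom_idx, signs)},
        contaminant_accessions=frozenset(accs[i] for i in cont_idx),
    )
    return table, truth


def expected_distance(spec: SyntheticSpec) -> float:
    """Closed-form mean cross-condition displacement of a null protein.

    Donor offsets and baselines cancel between paired conditions, so each
    coordinate of the displacement is N(0, 2 sigma_eps^2) and the distance
    is sigma_eps * sqrt(2) times a chi-distributed variable with D degrees
    of freedom:

        E[d] = sigma_eps * sqrt(2) * sqrt(2) * Gamma((D+1)/2) / Gamma(D/2)
             = 2 sigma_eps * Gamma((D+1)/2) / Gamma(D/2).
    """
    if spec.sigma_eps <= 0:
        return 0.0
    D = spec.n_donors
    chi_mean = math.sqrt(2.0) * math.exp(
        gammaln((D + 1) / 2.0) - gammaln(D / 2.0))
    return spec.sigma_eps * math.sqrt(2.0) * chi_mean
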