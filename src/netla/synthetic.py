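"""Synthetic family-structured, two-day connectome datasets.

The generator emulates the structure that matters for family-aware
resampling and network-level enrichment benchmarks: siblings share a
family-level intercept (so their connectomes are more alike than strangers'),
each subject has a stable individual intercept, each subject-by-edge value
has a component that is stable across scan days and a day-specific noise
component, and age effects are planted block-wise — every edge in a chosen
network block gains the same linear slope per standard deviation of age.

The additive model for subject ``s``, edge ``e``, day ``d`` is::

    x[s, e, d] = mu[e] + beta[block(e)] * age_std[s]
                 + u[family(s)] + v[s] + eps[s, e] + w[s, e, d]

with ``u ~ N(0, family_sd^2)``, ``v ~ N(0, subject_sd^2)`` scalars shared
across edges and days, ``eps ~ N(0, edge_sd^2)`` per edge shared across days,
and ``w ~ N(0, day_sd^2)`` independent per day. Ages are uniform over the
configured range and shared between the two days, as are family assignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_model import (
    ConnectomeDataset,
    NetworkPartition,
    build_block_map,
    build_edge_index,
)

__all__ = [
    "EffectSpec",
    "FamilyLayout",
    "generate_partition",
    "generate_dataset",
    "beta_for_target_r",
]


@dataclass
class EffectSpec:
    """Effect sizes and variance components of the generative model.

    ``block_betas`` maps block id to the age slope (change in edge z(r) per
    SD of age); blocks not listed are null. SDs are in z(r) units. Defaults
    give per-edge, per-day noise SD ~= 0.2 with half of the subject-level
    variance shared within families, roughly matching the magnitude of
    between-subject variability seen in group Fisher-z connectivity maps.
    """

    block_betas: dict = field(default_factory=dict)
    baseline_mean: float | np.ndarray = 0.25
    family_sd: float = 0.1
    subject_sd: float = 0.1
    day_sd: float = 0.1
    edge_sd: float = 0.1
    per_block_family_effect: bool = False  # heritability experiments only

    def __post_init__(self):
        for name in ("family_sd", "subject_sd", "day_sd", "edge_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for b, beta in self.block_betas.items():
            if not np.isfinite(beta):
                raise ValueError(f"beta for block {b} is not finite")

    def betas(self, block_count: int) -> np.ndarray:
        out = np.zeros(block_count)
        for b, beta in self.block_betas.items():
            if not 0 <= b < block_count:
                raise ValueError(f"block id {b} out of range [0, {block_count})")
            out[b] = beta
        return out

    def noise_sd(self) -> float:
        """Total per-edge, per-day noise SD around the age effect."""
        return float(
            np.sqrt(
                self.family_sd**2
                + self.subject_sd**2
                + self.edge_sd**2
                + self.day_sd**2
            )
        )


def beta_for_target_r(target_r: float, effects: EffectSpec) -> float:
    """Age slope giving an expected edge-age correlation of ``target_r``.

    With standardized age and total noise SD ``s``, the population edge-age
    correlation is ``beta / sqrt(beta^2 + s^2)``; invert for ``beta``.
    """
    if not 0 < abs(target_r) < 1:
        raise ValueError("target_r must be in (0, 1) in magnitude")
    s = effects.noise_sd()
    return float(np.sign(target_r) * abs(target_r) * s / np.sqrt(1 - target_r**2))


@dataclass
class FamilyLayout:
    """Family sizes and age range of the simulated cohort.

    ``members`` is either an explicit sequence of per-family counts or a
    ``(lo, hi)`` range from which counts are drawn uniformly. Default mirrors
    a multi-member family cohort at desk scale: 100 families of 1-3 members,
    ages 22-35 years.

    Ages cluster within families: a family mean age is drawn uniformly over
    ``age_range`` and members deviate from it by ``N(0, within_family_age_sd)``
    (clipped to the range). Twins and siblings in young-adult cohorts are
    close in age, and this closeness is what lets family-ignorant resampling
    leak age information; ``within_family_age_sd = inf`` recovers fully
    independent uniform ages.
    """

    n_families: int = 100
    members: Sequence[int] | tuple[int, int] = (1, 3)
    age_range: tuple[float, float] = (22.0, 35.0)
    within_family_age_sd: float = 1.5

    def __post_init__(self):
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must be increasing")
        if self.within_family_age_sd < 0:
            raise ValueError("within_family_age_sd must be >= 0")

    def draw_ages(self, family_idx: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        lo, hi = self.age_range
        n = family_idx.shape[0]
        if not np.isfinite(self.within_family_age_sd):
            return rng.uniform(lo, hi, size=n)
        fam_mean = rng.uniform(lo, hi, size=self.n_families)
        ages = fam_mean[family_idx] + rng.normal(
            0.0, self.within_family_age_sd, size=n
        )
        return np.clip(ages, lo, hi)

    def family_sizes(self, rng: np.random.Generator) -> np.ndarray:
        if len(self.members) == 2 and not isinstance(self.members, (list, np.ndarray)):
            lo, hi = self.members
            sizes = rng.integers(lo, hi + 1, size=self.n_families)
        else:
            sizes = np.asarray(self.members, dtype=np.int64)
            if sizes.shape != (self.n_families,):
                raise ValueError(
                    f"explicit member counts ({sizes.shape[0]}) must match "
                    f"n_families ({self.n_families})"
                )
        if np.any(sizes < 1):
            raise ValueError("every family needs at least one member")
        return sizes


def generate_partition(
    parcel_count: int, network_sizes: Sequence[int], names: Sequence[str] = ()
) -> NetworkPartition:
    """Partition with networks laid out contiguously by the size list."""
    sizes = np.asarray(network_sizes, dtype=np.int64)
    if np.any(sizes <= 0):
        raise ValueError("network sizes must be positive")
    if sizes.sum() != parcel_count:
        raise ValueError(
            f"network sizes sum to {sizes.sum()}, expected {parcel_count}"
        )
    labels = np.repeat(np.arange(1, sizes.size + 1), sizes)
    return NetworkPartition(parcel_count, labels, tuple(names))


def generate_dataset(
    partition: NetworkPartition,
    layout: FamilyLayout,
    effects: EffectSpec,
    seed,
) -> tuple[ConnectomeDataset, ConnectomeDataset]:
    """Generate one cohort measured on two days.

    Returns the (day 1, day 2) datasets; both share subjects, family ids and
    ages. Generation is reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    index = build_edge_index(partition.parcel_count)
    block_map = build_block_map(partition, index)
    e_count = index.edge_count

    sizes = layout.family_sizes(rng)
    n = int(sizes.sum())
    family_idx = np.repeat(np.arange(layout.n_families), sizes)
    subject_ids = np.array([f"sub{i:05d}" for i in range(n)])
    family_ids = np.array([f"fam{f:05d}" for f in family_idx])

    ages = layout.draw_ages(family_idx, rng)
    age_sd = ages.std()
    age_std = (ages - ages.mean()) / age_sd if age_sd > 0 else np.zeros(n)

    betas = effects.betas(block_map.block_count)
    beta_edge = betas[block_map.block_of_edge]  # (E,)
    mu = np.broadcast_to(np.asarray(effects.baseline_mean, dtype=float), (e_count,))

    signal = mu[None, :] + np.outer(age_std, beta_edge)  # (n, E)

    u = rng.normal(0.0, effects.family_sd, size=layout.n_families)[family_idx]
    v = rng.normal(0.0, effects.subject_sd, size=n)
    subject_level = u + v  # (n,)
    if effects.per_block_family_effect:
        u_block = rng.normal(
            0.0, effects.family_sd, size=(layout.n_families, block_map.block_count)
        )
        subject_block = u_block[family_idx][:, block_map.block_of_edge]
    else:
        subject_block = 0.0

    eps = rng.normal(0.0, effects.edge_sd, size=(n, e_count))  # stable across days
    base = signal + subject_level[:, None] + subject_block + eps

    datasets = []
    for day in (1, 2):
        w = rng.normal(0.0, effects.day_sd, size=(n, e_count))
        datasets.append(
            ConnectomeDataset(
                subject_ids=subject_ids,
                family_ids=family_ids,
                ages=ages,
                day=day,
                edges=base + w,
                parcel_count=partition.parcel_count,
            )
        )
    return datasets[0], datasets[1]
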