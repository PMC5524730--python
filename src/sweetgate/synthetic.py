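"""Synthetic benchmark generator: planted fingerprint clusters + descriptor signal.

The generator emulates the structure the expert system exploits in real
chemical data:

* **Fingerprints** — a configurable number of planted sweet clusters, each
  sharing a common scaffold bit block (mimicking structurally homogeneous
  sweetener families) plus random private bits per molecule, so that
  within-cluster Jaccard-Tanimoto similarity exceeds between-cluster
  similarity in expectation.  Background molecules get independent random
  bit sets of comparable density and sit far from every planted cluster.

* **Descriptors** — a molecules x descriptors matrix in which a small set of
  informative descriptors carries a class-dependent mean shift (in noise-SD
  units) while the remaining nuisance descriptors are pure noise, correlated
  in blocks through a shared latent factor, to exercise correlation-based
  reduction and subset selection.

Ground-truth metadata (cluster membership, informative descriptor names)
is returned so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import (
    ConfigurationError,
    DescriptorTable,
    FingerprintMatrix,
    FingerprintParams,
    NON_SWEET,
    SWEET,
)
from .similarity import ClusterReference


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic benchmark.

    Defaults: two planted sweet clusters of 40 molecules sharing a
    200-of-2048-bit scaffold with 50 private bits each, over a 300-molecule
    background (150 sweet / 150 non-sweet) described by 100 descriptors of
    which 6 are informative at a 1.5-SD class shift; the 94 nuisance
    descriptors are block-correlated at 0.7.
    """

    cluster_sizes: tuple[int, ...] = (40, 40)
    n_background_sweet: int = 150
    n_background_nonsweet: int = 150
    n_bits: int = 2048
    scaffold_bits: int = 200
    private_bits: int = 50
    background_bits: int = 250
    n_informative: int = 6
    effect_size: float = 1.5
    n_nuisance: int = 94
    nuisance_correlation: float = 0.7
    n_blocks: int = 12

    def __post_init__(self) -> None:
        if self.scaffold_bits + self.private_bits > self.n_bits:
            raise ConfigurationError("scaffold + private bits exceed fingerprint width")
        if self.background_bits > self.n_bits:
            raise ConfigurationError("background bits exceed fingerprint width")
        if not 0.0 <= self.nuisance_correlation < 1.0:
            raise ConfigurationError("nuisance correlation must lie in [0, 1)")
        if self.n_informative < 0 or self.n_nuisance < 0:
            raise ConfigurationError("descriptor counts must be non-negative")

    @property
    def n_molecules(self) -> int:
        return sum(self.cluster_sizes) + self.n_background_sweet + self.n_background_nonsweet

    @property
    def n_descriptors(self) -> int:
        return self.n_informative + self.n_nuisance


@dataclass
class SyntheticMetadata:
    """Ground truth: planted memberships and informative descriptor names."""

    cluster_members: dict[str, list[str]]
    informative_names: list[str]
    config: SyntheticConfig = field(repr=False, default=None)


def generate_synthetic_dataset(
    config: SyntheticConfig | None = None, seed: int = 0
) -> tuple[FingerprintMatrix, DescriptorTable, np.ndarray, SyntheticMetadata]:
    """Generate (fingerprints, descriptors, labels, metadata); reproducible under seed."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    n = config.n_molecules
    ids = [f"mol{i:04d}" for i in range(n)]

    labels = np.empty(n, dtype=object)
    bits = np.zeros((n, config.n_bits), dtype=np.uint8)
    cluster_members: dict[str, list[str]] = {}

    row = 0
    for c, size in enumerate(config.cluster_sizes):
        name = f"S{c + 1}"
        scaffold = rng.choice(config.n_bits, size=config.scaffold_bits, replace=False)
        members: list[str] = []
        for _ in range(size):
            bits[row, scaffold] = 1
            remaining = np.setdiff1d(np.arange(config.n_bits), scaffold)
            private = rng.choice(remaining, size=config.private_bits, replace=False)
            bits[row, private] = 1
            labels[row] = SWEET
            members.append(ids[row])
            row += 1
        cluster_members[name] = members
    for _ in range(config.n_background_sweet):
        on = rng.choice(config.n_bits, size=config.background_bits, replace=False)
        bits[row, on] = 1
        labels[row] = SWEET
        row += 1
    for _ in range(config.n_background_nonsweet):
        on = rng.choice(config.n_bits, size=config.background_bits, replace=False)
        bits[row, on] = 1
        labels[row] = NON_SWEET
        row += 1

    # descriptors: informative mean shift +/- effect/2, nuisance block-correlated noise
    p = config.n_descriptors
    values = np.empty((n, p))
    names: list[str] = []
    block_of: dict[str, str] = {}
    sign = np.where(labels == SWEET, 0.5, -0.5)
    for j in range(config.n_informative):
        name = f"inf{j:02d}"
        names.append(name)
        block_of[name] = f"B{j % config.n_blocks:02d}"
        values[:, j] = sign * config.effect_size + rng.standard_normal(n)
    rho = config.nuisance_correlation
    nuisance_blocks = np.arange(config.n_nuisance) % config.n_blocks
    factors = rng.standard_normal((n, config.n_blocks))
    for k in range(config.n_nuisance):
        j = config.n_informative + k
        name = f"nui{k:02d}"
        names.append(name)
        g = nuisance_blocks[k]
        block_of[name] = f"B{g:02d}"
        values[:, j] = np.sqrt(rho) * factors[:, g] + np.sqrt(1 - rho) * rng.standard_normal(n)

    # interleave classes so venetian-blind folds keep both classes everywhere
    order = rng.permutation(n)
    ids = [ids[i] for i in order]
    bits = bits[order]
    labels = labels[order]
    values = values[order]

    fps = FingerprintMatrix(ids, bits, FingerprintParams(n_bits=config.n_bits))
    table = DescriptorTable(ids, names, values, block_of)
    meta = SyntheticMetadata(cluster_members=cluster_members,
                             informative_names=names[: config.n_informative],
                             config=config)
    return fps, table, labels, meta


def planted_cluster_references(
    fps: FingerprintMatrix,
    metadata: SyntheticMetadata,
    thresholds: tuple[float, ...] = (0.6, 0.8),
) -> list[ClusterReference]:
    """Build gate references from the generator's ground-truth memberships."""
    refs = []
    for k, (name, members) in enumerate(sorted(metadata.cluster_members.items())):
        idx = [fps.ids.index(m) for m in members]
        threshold = thresholds[min(k, len(thresholds) - 1)]
        refs.append(ClusterReference(name, fps.subset(idx), threshold))
    return refs
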