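"""Seeded generator of two-class expression data with planted structure.

The generator emulates the feature landscape that motivates interaction-aware
selection: a sea of Gaussian noise genes, a few marginally shifted genes, a
pure-interaction (XOR-like) gene pair whose members carry no marginal class
signal but whose sign product determines the class, and optional blocks of
equicorrelated redundant genes driven by one latent class signal.  Planted
roles are recorded so recovery can be checked gene by gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import ExpressionDataset


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic two-class dataset.

    Parameters
    ----------
    n_per_class : samples per class (labels are balanced).
    n_genes : total genes; planted genes occupy the first columns before a
        seeded column shuffle.
    n_marginal : genes whose class means differ by ``marginal_effect``
        standard deviations.
    marginal_effect : class-mean shift in units of ``noise_sd``.
    n_xor_pairs : pure-interaction pairs; each member is marginally
        class-symmetric, but the pair's sign product encodes the class with
        label noise ``xor_flip_prob``.
    n_redundant_blocks, block_size, block_rho : equicorrelated blocks
        sharing a latent class signal of ``block_effect`` sd units.
    noise_sd : standard deviation of the background noise.
    """

    n_per_class: int = 30
    n_genes: int = 200
    n_marginal: int = 2
    marginal_effect: float = 1.0
    n_xor_pairs: int = 1
    xor_flip_prob: float = 0.1
    n_redundant_blocks: int = 0
    block_size: int = 5
    block_rho: float = 0.7
    block_effect: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        planted = (
            self.n_marginal
            + 2 * self.n_xor_pairs
            + self.n_redundant_blocks * self.block_size
        )
        if planted > self.n_genes:
            raise ValueError(
                f"{planted} planted genes exceed n_genes={self.n_genes}"
            )
        if not 0 <= self.block_rho < 1:
            raise ValueError("block_rho must be in [0, 1)")
        if not 0 <= self.xor_flip_prob < 0.5:
            raise ValueError("xor_flip_prob must be in [0, 0.5)")
        if self.n_per_class < 4:
            raise ValueError("need at least 4 samples per class")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class Truth:
    """Planted role of every gene, by dataset column index."""

    marginal: list[int] = field(default_factory=list)
    xor_pairs: list[tuple[int, int]] = field(default_factory=list)
    blocks: list[list[int]] = field(default_factory=list)
    noise: list[int] = field(default_factory=list)

    @property
    def informative(self) -> list[int]:
        genes = list(self.marginal)
        for a, b in self.xor_pairs:
            genes.extend((a, b))
        for block in self.blocks:
            genes.extend(block)
        return genes


def _xor_pair(
    labels: np.ndarray, flip_prob: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Two genes whose sign product encodes the class, marginally symmetric.

    Each member is a symmetric bimodal mixture scaled to unit variance
    (modes at roughly +-0.97 sd, mode width 0.26 sd), so a member is
    marginally indistinguishable from a background noise gene: the sign of
    the first member is uniform and independent of the class, and the
    second member's sign is chosen so that sign(g1 * g2) equals the
    (noise-flipped) class.  Either member alone therefore has identical
    class-conditional distributions and the same variance as the noise.
    """
    n = len(labels)
    target = labels * np.where(rng.random(n) < flip_prob, -1, 1)
    # the first member's sign is balanced exactly within each class, so the
    # pair is purely interacting in every realization, not just on average
    sign1 = np.empty(n)
    for cls in (1, -1):
        members = np.flatnonzero(labels == cls)
        half = np.resize([1.0, -1.0], len(members))
        sign1[members] = rng.permutation(half)
    sign2 = target * sign1
    # mode 1.5, width 0.4, normalised to total variance 1 (in sd units)
    scale = sd / np.hypot(1.5, 0.4)
    mag = scale * (1.5 + rng.normal(0.0, 0.4, size=(n, 2)))
    return np.column_stack([sign1 * np.abs(mag[:, 0]), sign2 * np.abs(mag[:, 1])])


def generate(spec: SyntheticSpec) -> tuple[ExpressionDataset, Truth]:
    """Generate one dataset and the record of planted gene roles."""
    rng = np.random.default_rng(spec.seed)
    n = 2 * spec.n_per_class
    labels = np.repeat([1, -1], spec.n_per_class)
    sd = spec.noise_sd

    columns: list[np.ndarray] = []
    roles: list[str] = []
    for _ in range(spec.n_marginal):
        shift = spec.marginal_effect * sd
        col = rng.normal(0.0, sd, size=n) + np.where(labels == 1, shift / 2, -shift / 2)
        columns.append(col)
        roles.append("marginal")
    for _ in range(spec.n_xor_pairs):
        pair = _xor_pair(labels, spec.xor_flip_prob, sd, rng)
        columns.extend([pair[:, 0], pair[:, 1]])
        roles.extend(["xor_a", "xor_b"])
    for b in range(spec.n_redundant_blocks):
        latent = rng.normal(0.0, 1.0, size=n) + np.where(
            labels == 1, spec.block_effect / 2, -spec.block_effect / 2
        )
        for _ in range(spec.block_size):
            eps = rng.normal(0.0, 1.0, size=n)
            col = sd * (
                np.sqrt(spec.block_rho) * latent + np.sqrt(1 - spec.block_rho) * eps
            )
            columns.append(col)
            roles.append(f"block{b}")
    n_noise = spec.n_genes - len(columns)
    for _ in range(n_noise):
        columns.append(rng.normal(0.0, sd, size=n))
        roles.append("noise")

    matrix = np.column_stack(columns)
    # Shuffle columns so planted genes sit at arbitrary positions.
    order = rng.permutation(spec.n_genes)
    matrix = matrix[:, order]
    position = np.empty(spec.n_genes, dtype=int)
    for new_pos, old_pos in enumerate(order):
        position[old_pos] = new_pos

    truth = Truth()
    xor_buffer: list[int] = []
    block_map: dict[str, list[int]] = {}
    for old_pos, role in enumerate(roles):
        new_pos = int(position[old_pos])
        if role == "marginal":
            truth.marginal.append(new_pos)
        elif role == "xor_a":
            xor_buffer.append(new_pos)
        elif role == "xor_b":
            truth.xor_pairs.append((xor_buffer.pop(), new_pos))
        elif role.startswith("block"):
            block_map.setdefault(role, []).append(new_pos)
        else:
            truth.noise.append(new_pos)
    truth.blocks = [block_map[k] for k in sorted(block_map)]

    dataset = ExpressionDataset(
        matrix=matrix,
        sample_ids=tuple(f"s{i:04d}" for i in range(n)),
        gene_ids=tuple(f"g{j:04d}" for j in range(spec.n_genes)),
        labels=labels,
        class_names=("case", "control"),
    )
    return dataset, truth
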