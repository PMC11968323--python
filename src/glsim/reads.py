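"""Per-site read-stack simulation.

For each sample at each site: depth is Poisson with a fixed mean; each read
samples one of the two genotype alleles with probability 1/2; a true error
probability (exact or Beta-drawn) corrupts the base to one of the three other
bases uniformly; the read carries the reported (capped/binned) quality, a
fair-coin strand, a uniform tail distance, and a constant mapping quality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import ErrorModelConfig
from .truth import BASES, TruthSite

DEFAULT_MAPQ = 60
DEFAULT_TAIL_MAX = 50

__all__ = [
    "BaseObservation",
    "SiteReadData",
    "ReadSimConfig",
    "sample_depth",
    "simulate_site",
]


class BaseObservation(NamedTuple):
    """One simulated read base at one site."""

    base: str
    true_error_prob: float
    reported_quality: int
    strand: int  # 0 = forward, 1 = reverse
    tail_distance: int  # bp from the nearer read end, >= 1
    mapping_quality: int


@dataclass
class ReadSimConfig:
    """Depth and read-metadata settings.

    mean_depth is the Poisson mean (reads/site/sample); mapping_quality is a
    fixed constant; tail_distance is uniform on [1, tail_max].
    """

    mean_depth: float = 20.0
    mapping_quality: int = DEFAULT_MAPQ
    tail_max: int = DEFAULT_TAIL_MAX

    def __post_init__(self) -> None:
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be nonnegative")
        if self.tail_max < 1:
            raise ValueError("tail_max must be >= 1")


@dataclass
class SiteReadData:
    """Per-sample read stacks at one site; depth == stack length per sample."""

    observations: list[list[BaseObservation]]

    @property
    def depths(self) -> list[int]:
        return [len(stack) for stack in self.observations]


def sample_depth(mean_depth: float, rng: np.random.Generator) -> int:
    """One Poisson(mean_depth) depth draw."""
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    return int(rng.poisson(mean_depth))


# Index gymnastics for the uniform-over-3-other-bases substitution: row = true
# base index, columns = the three alternatives.
_OTHER = np.array(
    [[j for j in range(4) if j != i] for i in range(4)], dtype=np.int64
)
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def simulate_site(
    site: TruthSite,
    err_cfg: ErrorModelConfig,
    read_cfg: ReadSimConfig,
    rng: np.random.Generator,
) -> SiteReadData:
    """Simulate read stacks for every sample at one site.

    Per sample the RNG is consumed in a fixed order (depth, allele picks,
    error probabilities, substitution mask, substitution choices, strands,
    tail distances), so whole-run output is byte-reproducible given the seed.
    A missing genotype yields depth 0.
    """
    allele_idx = np.array([_BASE_INDEX[a] for a in site.alleles], dtype=np.int64)
    stacks: list[list[BaseObservation]] = []
    for gt in site.genotypes:
        if gt is None:
            stacks.append([])
            continue
        depth = int(rng.poisson(read_cfg.mean_depth))
        if depth == 0:
            stacks.append([])
            continue
        pick = rng.integers(0, 2, size=depth)
        true_base = allele_idx[np.where(pick == 0, gt[0], gt[1])]
        probs = err_cfg.draw_error_probs(depth, rng)
        is_err = rng.random(depth) < probs
        alt_choice = rng.integers(0, 3, size=depth)
        obs_base = np.where(is_err, _OTHER[true_base, alt_choice], true_base)
        strands = rng.integers(0, 2, size=depth)
        tails = rng.integers(1, read_cfg.tail_max + 1, size=depth)
        stacks.append(
            [
                BaseObservation(
                    base=BASES[obs_base[j]],
                    true_error_prob=float(probs[j]),
                    reported_quality=err_cfg.reported_quality(float(probs[j])),
                    strand=int(strands[j]),
                    tail_distance=int(tails[j]),
                    mapping_quality=read_cfg.mapping_quality,
                )
                for j in range(depth)
            ]
        )
    return SiteReadData(stacks)
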