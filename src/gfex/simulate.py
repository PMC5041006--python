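"""Synthetic genome × COG matrices with a size–paralogy trend.

The generator emulates the qualitative structure of real prokaryotic
COG count matrices:

* genome sizes are uniform over a Mbp range spanning small parasites to
  large free-living genomes;
* each COG is present in a genome with a probability that grows
  logistically with genome size, so larger genomes carry more families
  (larger K');
* a present family's size is drawn from a shifted geometric distribution
  on {1, 2, 3, ...} whose mean ``1 + e(size)`` grows linearly with genome
  size, so larger genomes are enriched for larger families — the trend all
  four GFE measures pick up;
* a configurable minority of genomes is planted as *atypical*: their mean
  family-size excess ``e`` is multiplied (above trend) or divided (below
  trend) by ``outlier_effect``, alternating so both outlier polarities
  occur.  The truth labels are stored alongside the matrix.

The shifted geometric is the simplest one-parameter family on the positive
integers whose tail weight grows with its mean; it is a modelling
convenience, not a claim about the true biological family-size law.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.special import expit

from .matrix import GeneFamilyMatrix

__all__ = ["SimulationConfig", "SyntheticDataset", "generate", "table_fixtures"]


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic matrix generator.

    Defaults describe a desk-scale analogue of a broad prokaryotic survey:
    300 genomes of 0.5–10 Mbp over 2000 COGs, family-size excess rising from
    ~0.1 copies at the smallest genomes by 0.08 per Mbp (mean family size
    ~1.1 → ~1.9, paralog index ~0.09 → ~0.46), COG presence rising
    logistically from ~0.16 to ~0.66, and 5% planted atypical genomes at a
    two-fold family-size-excess displacement.  The COG universe is kept in
    the thousands on purpose: pairs of small genomes must still share tens
    of families, as they do in real COG collections, for the pairwise
    majority comparisons of the sorting heuristic to carry information.
    """

    n_genomes: int = 300
    n_cogs: int = 2000
    size_range_mbp: tuple[float, float] = (0.5, 10.0)
    presence_intercept: float = -0.5
    presence_slope: float = 0.25
    base_mean_excess: float = 0.1
    familysize_slope: float = 0.08
    familysize_family: str = "shifted-geometric"
    outlier_fraction: float = 0.05
    outlier_effect: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 1 or self.n_cogs < 1:
            raise ValueError("n_genomes and n_cogs must be positive")
        lo, hi = self.size_range_mbp
        if not (0 < lo <= hi):
            raise ValueError("size_range_mbp must be a positive (min, max) pair")
        if not (0 <= self.outlier_fraction < 1):
            raise ValueError("outlier_fraction must lie in [0, 1)")
        if self.outlier_effect <= 0:
            raise ValueError("outlier_effect must be > 0")
        if self.base_mean_excess <= 0:
            raise ValueError("base_mean_excess must be > 0")
        if self.familysize_family != "shifted-geometric":
            raise ValueError(
                f"unsupported family-size distribution {self.familysize_family!r}"
            )


@dataclasses.dataclass
class SyntheticDataset:
    """Generated matrix plus metadata and ground-truth outlier labels."""

    matrix: GeneFamilyMatrix
    metadata: pd.DataFrame  # genome_id, size_mbp
    truth: pd.DataFrame     # genome_id, is_outlier, direction, mean_excess
    config: SimulationConfig


def generate(config: SimulationConfig) -> SyntheticDataset:
    """Draw one dataset; bit-identical for identical configs (same seed)."""
    rng = np.random.default_rng(config.seed)
    n, k = config.n_genomes, config.n_cogs
    lo, hi = config.size_range_mbp
    sizes = rng.uniform(lo, hi, size=n)

    # planted atypical genomes, alternating above/below the trend
    n_out = int(round(config.outlier_fraction * n))
    out_idx = rng.choice(n, size=n_out, replace=False) if n_out else np.array([], dtype=int)
    direction = np.zeros(n, dtype=int)
    for j, i in enumerate(out_idx):
        direction[i] = 1 if j % 2 == 0 else -1

    # latent mean family size 1 + e_i; outliers shift e multiplicatively so
    # counts stay on {1, 2, ...} and mp stays defined
    excess = config.base_mean_excess + config.familysize_slope * (sizes - lo)
    excess = np.where(direction == 1, excess * config.outlier_effect, excess)
    excess = np.where(direction == -1, excess / config.outlier_effect, excess)
    p_geom = 1.0 / (1.0 + excess)

    mid = 0.5 * (lo + hi)
    presence_prob = expit(config.presence_intercept + config.presence_slope * (sizes - mid))

    present = rng.random((n, k)) < presence_prob[:, None]
    family_sizes = rng.geometric(np.broadcast_to(p_geom[:, None], (n, k)))
    counts = np.where(present, family_sizes, 0).astype(np.int64)

    # a genome that ended up with no COG at all is resampled once
    empty = np.flatnonzero(counts.sum(axis=1) == 0)
    for i in empty:
        row_present = rng.random(k) < presence_prob[i]
        row_sizes = rng.geometric(np.full(k, p_geom[i]))
        counts[i] = np.where(row_present, row_sizes, 0)
    if np.any(counts.sum(axis=1) == 0):
        raise ValueError(
            "infeasible config: a genome drew zero COGs twice; raise "
            "presence_intercept/presence_slope or n_cogs"
        )

    width = len(str(n))
    ids = [f"G{i + 1:0{width}d}" for i in range(n)]
    matrix = GeneFamilyMatrix(ids, [f"COG{j + 1:04d}" for j in range(k)], counts)
    metadata = pd.DataFrame({"genome_id": ids, "size_mbp": sizes})
    truth = pd.DataFrame(
        {
            "genome_id": ids,
            "is_outlier": direction != 0,
            "direction": ["above" if d == 1 else "below" if d == -1 else "" for d in direction],
            "mean_excess": excess,
        }
    )
    return SyntheticDataset(matrix=matrix, metadata=metadata, truth=truth, config=config)


def table_fixtures():
    """The packaged worked-example tables (see :mod:`gfex.datasets`)."""
    from . import datasets

    matrix, metadata = datasets.load_fictional_example()
    return {
        "fictional": {"matrix": matrix, "metadata": metadata},
        "mycoplasma": datasets.load_mycoplasma_family_sizes(),
        "mycoplasma_profiles": datasets.mycoplasma_profiles(),
    }
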