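"""Plain and partial Kendall rank correlations between GFE measures.

All four measures (p.i., ave, rank, mp) trend with genome size, so their
pairwise association is summarised by the first-order partial Kendall
tau-b, which removes the shared size signal:

    tau(xy.z) = (tau_xy − tau_xz · tau_yz) / sqrt((1 − tau_xz²)(1 − tau_yz²))

with tau-b (tie-corrected) used for every pairwise term and a two-sided
normal approximation for p-values.  Rows with a missing measure (undefined
mp) are dropped pairwise.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DegenerateControlError",
    "CorrelationTable",
    "kendall_tau_b",
    "partial_kendall",
    "measure_correlation_table",
]

MEASURES = ["p_i", "ave", "rank", "mp"]


class DegenerateControlError(ValueError):
    """The control variable is perfectly rank-correlated with x or y."""


def kendall_tau_b(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Tie-corrected Kendall tau-b with an asymptotic (normal) p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    res = stats.kendalltau(x, y, variant="b", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def partial_kendall(
    x: Sequence[float], y: Sequence[float], z: Sequence[float]
) -> tuple[float, float]:
    """First-order partial Kendall tau-b of x and y controlling for z."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (x.shape == y.shape == z.shape) or x.ndim != 1:
        raise ValueError("x, y and z must be equal-length 1-D vectors")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    t_xy, _ = kendall_tau_b(x, y)
    t_xz, _ = kendall_tau_b(x, z)
    t_yz, _ = kendall_tau_b(y, z)
    denom = (1 - t_xz**2) * (1 - t_yz**2)
    if denom <= 1e-12:
        raise DegenerateControlError(
            "control variable is perfectly correlated with x or y; partial tau undefined"
        )
    pt = (t_xy - t_xz * t_yz) / math.sqrt(denom)
    pt = float(np.clip(pt, -1.0, 1.0))
    # normal approximation with the no-tie tau variance 2(2n+5)/(9n(n-1))
    z_stat = pt * math.sqrt(9 * n * (n - 1) / (2 * (2 * n + 5)))
    p_value = 2 * stats.norm.sf(abs(z_stat))
    return pt, float(p_value)


@dataclasses.dataclass
class CorrelationTable:
    """Symmetric correlation summary over the GFE measures.

    ``tau``/``p_values``/``n_used`` are symmetric DataFrames over the
    measures (diagonal 1 by convention, excluded from reporting);
    ``size_tau`` holds each measure's plain (uncontrolled) tau against
    genome size.
    """

    variables: list[str]
    tau: pd.DataFrame
    p_values: pd.DataFrame
    n_used: pd.DataFrame
    controlled_for: Optional[str]
    size_tau: pd.DataFrame  # columns: measure, tau, p_value, n_used

    def to_long(self) -> pd.DataFrame:
        rows = []
        for a, b in itertools.combinations(self.variables, 2):
            rows.append(
                {
                    "var_a": a,
                    "var_b": b,
                    "tau": self.tau.loc[a, b],
                    "p_value": self.p_values.loc[a, b],
                    "n_used": int(self.n_used.loc[a, b]),
                    "controlled_for": self.controlled_for or "",
                }
            )
        for _, r in self.size_tau.iterrows():
            rows.append(
                {
                    "var_a": r["measure"],
                    "var_b": "genome_size",
                    "tau": r["tau"],
                    "p_value": r["p_value"],
                    "n_used": int(r["n_used"]),
                    "controlled_for": "",
                }
            )
        return pd.DataFrame(rows)


def measure_correlation_table(
    profiles: pd.DataFrame,
    ranks: pd.DataFrame,
    metadata: pd.DataFrame,
    control: str = "genome_size",
) -> CorrelationTable:
    """All pairwise measure correlations plus each measure against size.

    ``profiles`` needs columns genome_id/p_i/ave/mp, ``ranks`` columns
    genome_id/mean_rank, ``metadata`` columns genome_id/size_mbp.  With
    ``control='genome_size'`` the measure pairs are partial taus given
    size; measure-vs-size taus are always plain.  Undefined mp rows are
    excluded pairwise.
    """
    if control not in {"none", "genome_size"}:
        raise ValueError("control must be 'none' or 'genome_size'")
    df = (
        profiles[["genome_id", "p_i", "ave", "mp"]]
        .merge(ranks[["genome_id", "mean_rank"]].rename(columns={"mean_rank": "rank"}),
               on="genome_id")
        .merge(metadata[["genome_id", "size_mbp"]], on="genome_id")
    )
    if len(df) < 4:
        raise ValueError(f"need at least 4 genomes shared across inputs, got {len(df)}")

    k = len(MEASURES)
    tau = pd.DataFrame(np.eye(k), index=MEASURES, columns=MEASURES)
    pvals = pd.DataFrame(np.zeros((k, k)), index=MEASURES, columns=MEASURES)
    n_used = pd.DataFrame(np.full((k, k), len(df)), index=MEASURES, columns=MEASURES)
    for a, b in itertools.combinations(MEASURES, 2):
        cols = [a, b] + (["size_mbp"] if control == "genome_size" else [])
        sub = df[cols].dropna()
        if len(sub) < 4:
            raise ValueError(f"insufficient complete observations for pair ({a}, {b})")
        if control == "genome_size":
            t, p = partial_kendall(sub[a], sub[b], sub["size_mbp"])
        else:
            t, p = kendall_tau_b(sub[a], sub[b])
        tau.loc[a, b] = tau.loc[b, a] = t
        pvals.loc[a, b] = pvals.loc[b, a] = p
        n_used.loc[a, b] = n_used.loc[b, a] = len(sub)

    size_rows = []
    for m in MEASURES:
        sub = df[[m, "size_mbp"]].dropna()
        t, p = kendall_tau_b(sub[m], sub["size_mbp"])
        size_rows.append({"measure": m, "tau": t, "p_value": p, "n_used": len(sub)})

    return CorrelationTable(
        variables=list(MEASURES),
        tau=tau,
        p_values=pvals,
        n_used=n_used,
        controlled_for="size_mbp" if control == "genome_size" else None,
        size_tau=pd.DataFrame(size_rows),
    )
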