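"""Monte-Carlo null calibration for gene-list overlap p-values.

Hypergeometric overlap p-values on real DEG lists are sometimes distrusted
because list sizes, annotation structure and the choice of universe can all
distort the nominal null. The simulation here rebuilds the null empirically:
draw many random pairs of gene lists of realistic sizes from the universe,
compute the hypergeometric upper-tail p for each pair's chance overlap, and
locate an observed p-value within that empirical distribution.

Defaults follow the published protocol this package reimplements: 100,000
random pairs with list sizes in [500, 2000] genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .gene_sets import GeneUniverse
from .overlap import hypergeom_upper_tail

DEFAULT_K = 100_000
DEFAULT_SIZE_RANGE = (500, 2000)


@dataclass(frozen=True)
class NullDistribution:
    """Empirical distribution of overlap p-values from random list pairs."""

    pvals: np.ndarray  # sorted ascending
    K: int
    universe_size: int
    size_range: tuple[int, int]
    seed: int
    bit_generator: str = "PCG64"

    def __post_init__(self) -> None:
        if len(self.pvals) != self.K:
            raise ValueError("pvals length must equal K")
        if np.any(self.pvals <= 0) or np.any(self.pvals > 1):
            raise ValueError("null p-values must lie in (0, 1]")
        if np.any(np.diff(self.pvals) < 0):
            raise ValueError("pvals must be sorted ascending")

    def fraction_below(self, alpha: float) -> float:
        return float(np.searchsorted(self.pvals, alpha, side="right")) / self.K


def simulate_null(
    u: GeneUniverse | int,
    K: int = DEFAULT_K,
    size_range: tuple[int, int] = DEFAULT_SIZE_RANGE,
    seed: int = 0,
) -> NullDistribution:
    """Simulate the null distribution of overlap p-values for random list pairs.

    Per replicate, in this fixed order: draw size_a uniformly from the
    integer range, sample list_a without replacement, draw size_b, sample
    list_b (the two lists are independent, so any overlap is chance), then
    record the hypergeometric upper-tail p of the realized overlap. Only
    membership matters, so lists are sampled as index sets over the universe.
    """
    N = u.size if isinstance(u, GeneUniverse) else int(u)
    lo, hi = size_range
    if lo > hi:
        raise ValueError(f"size_range min {lo} > max {hi}")
    if hi > N:
        raise ValueError(f"size_range max {hi} exceeds universe size {N}")
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    pvals = np.empty(K)
    mask = np.zeros(N, dtype=bool)
    for i in range(K):
        n_a = int(rng.integers(lo, hi + 1))
        list_a = rng.choice(N, n_a, replace=False)
        n_b = int(rng.integers(lo, hi + 1))
        list_b = rng.choice(N, n_b, replace=False)
        mask[list_a] = True
        k = int(np.count_nonzero(mask[list_b]))
        mask[list_a] = False
        pvals[i] = hypergeom_upper_tail(k, n_a, n_b, N)
    pvals.sort()
    return NullDistribution(
        pvals=pvals, K=K, universe_size=N, size_range=(lo, hi), seed=seed
    )


class EmpiricalPercentile(NamedTuple):
    fraction: float
    """Plain plug-in estimate: (#null p <= p_obs) / K."""
    empirical_p: float
    """Add-one estimate (#null p <= p_obs + 1) / (K + 1), never exactly zero."""


def empirical_percentile(nd: NullDistribution, p_obs: float) -> EmpiricalPercentile:
    """Locate an observed overlap p-value within the simulated null."""
    count = int(np.searchsorted(nd.pvals, p_obs, side="right"))
    return EmpiricalPercentile(count / nd.K, (count + 1) / (nd.K + 1))


def null_report(
    nd: NullDistribution, observed: Sequence[tuple[str, float]] = ()
) -> pd.DataFrame:
    """Summarise a null distribution and place observed p-values within it.

    The summary rows give the null minimum, quartiles and the fraction of
    simulated pairs reaching p < 0.05 (the sub-distribution a reader would
    inspect when judging whether an observed value is extreme). Each
    observation gets its percentile; values below the simulated minimum are
    flagged as lying outside the simulated distribution entirely.
    """
    q = np.quantile(nd.pvals, [0.25, 0.5, 0.75])
    rows = [
        {"kind": "summary", "label": "min", "value": float(nd.pvals[0]), "note": ""},
        {"kind": "summary", "label": "q25", "value": float(q[0]), "note": ""},
        {"kind": "summary", "label": "median", "value": float(q[1]), "note": ""},
        {"kind": "summary", "label": "q75", "value": float(q[2]), "note": ""},
        {"kind": "summary", "label": "max", "value": float(nd.pvals[-1]), "note": ""},
        {
            "kind": "summary",
            "label": "fraction_p_lt_0.05",
            "value": nd.fraction_below(np.nextafter(0.05, 0)),
            "note": "",
        },
    ]
    for label, p_obs in observed:
        perc = empirical_percentile(nd, p_obs)
        note = "outside simulated distribution" if p_obs < nd.pvals[0] else ""
        rows.append(
            {
                "kind": "observed",
                "label": label,
                "value": p_obs,
                "percentile": perc.fraction,
                "empirical_p": perc.empirical_p,
                "note": note,
            }
        )
    return pd.DataFrame(rows)


def write_null(nd: NullDistribution, path: str | Path) -> None:
    """Serialize as TSV: metadata header lines, then (replicate, p) rows."""
    with open(path, "w") as fh:
        fh.write(f"#K={nd.K}\n#N={nd.universe_size}\n")
        fh.write(f"#size_range={nd.size_range[0]}-{nd.size_range[1]}\n")
        fh.write(f"#seed={nd.seed}\n#bit_generator={nd.bit_generator}\n")
        fh.write("replicate\tp\n")
        for i, p in enumerate(nd.pvals):
            fh.write(f"{i}\t{p:.17g}\n")


def read_null(path: str | Path) -> NullDistribution:
    meta: dict[str, str] = {}
    pvals = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key] = val
            elif line.startswith("replicate"):
                continue
            elif line.strip():
                pvals.append(float(line.split("\t")[1]))
    lo, _, hi = meta["size_range"].partition("-")
    return NullDistribution(
        pvals=np.sort(np.asarray(pvals)),
        K=int(meta["K"]),
        universe_size=int(meta["N"]),
        size_range=(int(lo), int(hi)),
        seed=int(meta["seed"]),
        bit_generator=meta.get("bit_generator", "PCG64"),
    )


def plot_null(nd: NullDistribution, path: str | Path, bins: int = 50) -> None:
    """Histogram of log10-transformed null p-values, with the sub-0.05 tail inset."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    logs = np.log10(nd.pvals)
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(6, 6))
    ax1.hist(logs, bins=bins, color="steelblue")
    ax1.set_xlabel("log10 p (all simulated pairs)")
    ax1.set_ylabel("frequency")
    tail = logs[nd.pvals < 0.05]
    if tail.size:
        ax2.hist(tail, bins=bins, color="darkorange")
    ax2.set_xlabel("log10 p (pairs with p < 0.05)")
    ax2.set_ylabel("frequency")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
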