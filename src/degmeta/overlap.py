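"""Overlap and enrichment statistics for gene lists.

The central statistic is the hypergeometric upper-tail probability
P[X >= k] for the overlap k between two gene sets of sizes n_a and n_b
drawn from a universe of N genes. The test is one-sided for enrichment by
default; a lower-tail (depletion) variant exists behind a flag but is never
the default, since the analyses this package supports report enrichment or
"not significant", not depletion.

When both lists carry directions, the overlap is further partitioned into
four classes — concordant up/up, concordant down/down, and the two
discordant mixtures — and each class gets its own upper-tail p-value
computed against the per-direction margins over the same universe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .gene_sets import AnnotationTrack, GeneUniverse, SignedGeneSet, restrict_to_universe

# p-values are never reported as exactly 0; floor at the smallest positive
# normal double so log-space results stay representable.
_P_FLOOR = np.finfo(float).tiny

PARTITION_CLASSES = ("concordant_up", "concordant_down", "discordant_a_up", "discordant_a_down")


def _log_comb(n: float, k: float) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_upper_tail(k: int, n_a: int, n_b: int, N: int, lower: bool = False) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, n_a, n_b), in log space.

    X is the overlap of a fixed set of n_a genes with a uniformly random set
    of n_b genes from a universe of N. With ``lower=True`` returns the
    depletion tail P[X <= k] instead.

    Summation is done on log-gamma terms so probabilities are accurate down
    to ~1e-300 where naive factorials would overflow.
    """
    if not (0 <= n_a <= N and 0 <= n_b <= N):
        raise ValueError(f"need 0 <= n_a, n_b <= N; got n_a={n_a}, n_b={n_b}, N={N}")
    k_min = max(0, n_a + n_b - N)
    k_max = min(n_a, n_b)
    if not (k_min <= k <= k_max):
        raise ValueError(
            f"overlap k={k} outside feasible range [{k_min}, {k_max}] "
            f"for n_a={n_a}, n_b={n_b}, N={N}"
        )
    # the whole support is included: the event is certain, exactly
    if (not lower and k <= k_min) or (lower and k >= k_max):
        return 1.0
    if lower:
        js = np.arange(k_min, k + 1)
    else:
        js = np.arange(k, k_max + 1)
    log_terms = (
        _log_comb(n_a, js) + _log_comb(N - n_a, n_b - js) - _log_comb(N, n_b)
    )
    p = float(np.exp(logsumexp(log_terms)))
    return min(1.0, max(p, _P_FLOOR))


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b, c, d) = (query∩annotated, query∩not, rest∩annotated, rest∩not)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d


def fisher_exact_upper(t: ContingencyTable2x2) -> float:
    """One-sided (enrichment) Fisher exact p for a 2x2 table.

    With margins fixed, the enrichment tail of Fisher's exact test is the
    hypergeometric upper tail P[X >= a] with n_a = a+b, n_b = a+c, N = total.
    """
    return hypergeom_upper_tail(t.a, t.a + t.b, t.a + t.c, t.N)


def benjamini_yekutieli(pvals: Sequence[float]) -> list[float]:
    """Benjamini–Yekutieli step-up FDR adjustment, valid under arbitrary dependence.

    Adjusted p for rank i (ascending) is min over j >= i of
    p_(j) * m * c(m) / j, clipped to 1, where c(m) = sum_{i=1..m} 1/i is the
    harmonic inflation factor that distinguishes BY from Benjamini–Hochberg.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m * c_m / np.arange(1, m + 1)
    # step-up: running minimum from the largest rank downwards
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out.tolist()


@dataclass
class OverlapResult:
    """Counts, directional partition and p-values for one pairwise comparison."""

    label_a: str
    label_b: str
    N: int
    n_a: int
    n_b: int
    k: int
    p_upper: float
    partition: dict[str, int] | None = None
    class_pvalues: dict[str, float] | None = None
    overlap_genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        k_min = max(0, self.n_a + self.n_b - self.N)
        if not (k_min <= self.k <= min(self.n_a, self.n_b)):
            raise ValueError("overlap count outside feasible bounds")
        if self.partition is not None and sum(self.partition.values()) != self.k:
            raise ValueError("directional partition must sum to the overlap count")

    @property
    def percent_of_a(self) -> float:
        return 100.0 * self.k / self.n_a if self.n_a else math.nan

    @property
    def percent_of_b(self) -> float:
        return 100.0 * self.k / self.n_b if self.n_b else math.nan

    @staticmethod
    def _round(pct: float, decimals: int) -> float:
        if math.isnan(pct):
            return math.nan
        return round(pct, decimals) if decimals else int(round(pct))

    def percent_of_a_rounded(self, decimals: int = 0) -> float:
        return self._round(self.percent_of_a, decimals)

    def percent_of_b_rounded(self, decimals: int = 0) -> float:
        """Percent of list b overlapping a; nearest integer matches the '26%' reporting style."""
        return self._round(self.percent_of_b, decimals)

    def to_row(self) -> dict[str, object]:
        row: dict[str, object] = {
            "label_a": self.label_a,
            "label_b": self.label_b,
            "N": self.N,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "k": self.k,
            "p_upper": self.p_upper,
            "percent_of_a": round(self.percent_of_a, 1),
            "percent_of_b": round(self.percent_of_b, 1),
            "percent_of_a_int": self.percent_of_a_rounded(),
            "percent_of_b_int": self.percent_of_b_rounded(),
        }
        for cls in PARTITION_CLASSES:
            row[cls] = self.partition.get(cls) if self.partition else None
            row[f"p_{cls}"] = self.class_pvalues.get(cls) if self.class_pvalues else None
        return row


def _members_and_directions(x: SignedGeneSet | AnnotationTrack):
    if isinstance(x, AnnotationTrack):
        return x.members, None, x.label
    return x.members, x.directions, x.label


def overlap_test(
    a: SignedGeneSet,
    b: SignedGeneSet | AnnotationTrack,
    u: GeneUniverse,
    lower: bool = False,
) -> OverlapResult:
    """Test the overlap of two gene sets against a common universe.

    Both inputs are restricted to the universe first so the hypergeometric
    margins are well-defined. If both inputs carry directions the overlap is
    partitioned into concordant/discordant classes, each with an upper-tail
    p-value against the per-direction sublist sizes over the same N.
    """
    if u.size == 0:
        raise ValueError("empty universe")
    a = restrict_to_universe(a, u)
    b = restrict_to_universe(b, u)
    mem_a, dir_a, lab_a = _members_and_directions(a)
    mem_b, dir_b, lab_b = _members_and_directions(b)
    shared = mem_a & mem_b
    k = len(shared)
    p = hypergeom_upper_tail(k, len(mem_a), len(mem_b), u.size, lower=lower)
    partition = class_p = None
    if dir_a is not None and dir_b is not None:
        partition = {cls: 0 for cls in PARTITION_CLASSES}
        for g in shared:
            if dir_a[g] == +1:
                cls = "concordant_up" if dir_b[g] == +1 else "discordant_a_up"
            else:
                cls = "concordant_down" if dir_b[g] == -1 else "discordant_a_down"
            partition[cls] += 1
        margins = {
            "concordant_up": (a.up, b.up),
            "concordant_down": (a.down, b.down),
            "discordant_a_up": (a.up, b.down),
            "discordant_a_down": (a.down, b.up),
        }
        class_p = {}
        for cls, (ma, mb) in margins.items():
            count = partition[cls]
            lo = max(0, len(ma) + len(mb) - u.size)
            # class counts can fall below the margin-forced minimum because
            # the classes compete for the same genes; the tail is then certain
            class_p[cls] = 1.0 if count < lo else hypergeom_upper_tail(count, len(ma), len(mb), u.size)
    return OverlapResult(
        label_a=lab_a,
        label_b=lab_b,
        N=u.size,
        n_a=len(mem_a),
        n_b=len(mem_b),
        k=k,
        p_upper=p,
        partition=partition,
        class_pvalues=class_p,
        overlap_genes=frozenset(shared),
    )


def stratified_overlap(
    a: SignedGeneSet, strata: Sequence[AnnotationTrack], u: GeneUniverse
) -> list[OverlapResult]:
    """Overlap of one list against several annotation strata, all over the same N.

    Strata may overlap each other (e.g. H3K9ac ∩ high-H2A.Z next to
    H3K9ac ∩ low-H2A.Z); disjointness is not assumed.
    """
    if not strata:
        raise ValueError("stratified_overlap needs at least one stratum")
    return [overlap_test(a, s, u) for s in strata]


def enrichment_table(
    query: SignedGeneSet,
    tracks: Sequence[AnnotationTrack],
    u: GeneUniverse,
) -> pd.DataFrame:
    """Fisher-exact enrichment of a query list against annotation tracks, BY-corrected.

    One row per track with the 2x2 margins, the one-sided Fisher p and its
    Benjamini–Yekutieli adjusted value.
    """
    query = restrict_to_universe(query, u)
    rows = []
    for t in tracks:
        t = restrict_to_universe(t, u)
        a = len(query.members & t.members)
        b = len(query.members) - a
        c = len(t.members) - a
        d = u.size - a - b - c
        table = ContingencyTable2x2(a, b, c, d)
        rows.append(
            {
                "track": t.label,
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "p_fisher": fisher_exact_upper(table),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["p_by"] = benjamini_yekutieli(df["p_fisher"].tolist())
    else:
        df["p_by"] = []
    return df


def results_to_frame(results: Sequence[OverlapResult]) -> pd.DataFrame:
    """Tabulate overlap results, one row per comparison."""
    columns = list(OverlapResult("a", "b", 1, 0, 0, 0, 1.0).to_row())
    return pd.DataFrame([r.to_row() for r in results], columns=columns)
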