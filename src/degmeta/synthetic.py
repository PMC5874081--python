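"""Synthetic inputs with the statistical structure the analysis assumes.

Everything the pipeline consumes can be generated here: a gene universe of
AGI-style locus IDs, annotation tracks of configurable prevalence (defaults
match the published stratification sizes this package was built around —
4081 high-H2A.Z genes and 1984 H3K9-acetylated genes), signed DEG lists
with a planted enrichment for a chosen track and a tunable cross-list
direction concordance, and balanced two-factor phenotype tables with a
configurable interaction effect.

The enrichment model: a gene's odds of entering a DEG list are multiplied
by theta if it belongs to the target track, with the list size held exact
by weighted sampling without replacement. theta = 1 is the uniform null;
theta -> inf drives the list entirely inside the track. Directions follow a
latent per-gene sign drawn once per universe; the first list generated is
the reference and carries the latent signs exactly, while every later list
copies the latent sign with probability rho and flips it otherwise. A
non-reference list therefore agrees with the reference on a shared gene
with probability exactly rho (and two non-reference lists with probability
rho^2 + (1-rho)^2), so rho > 1/2 plants concordant-dominant overlaps
against the reference and rho < 1/2 plants discordant-dominant ones.

All generators are pure functions of (configuration, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gene_sets import AnnotationTrack, GeneUniverse, SignedGeneSet

DEFAULT_UNIVERSE_SIZE = 27_416  # stand-in: TAIR10 protein-coding gene count
DEFAULT_TRACK_SIZES = {"high_H2AZ": 4081, "H3K9ac": 1984}


@dataclass(frozen=True)
class TrackSpec:
    """One annotation track: a label, a size, and an optional forced overlap
    with a previously generated track."""

    label: str
    size: int
    overlap_with: str | None = None
    overlap: int | None = None


@dataclass(frozen=True)
class DegSpec:
    """One DEG list: size, enrichment odds ratio theta against a named track
    (theta=1 is the null), and the fraction of members that are up-regulated
    before the latent-sign concordance model is applied."""

    label: str
    size: int
    theta: float = 1.0
    track: str | None = None


@dataclass(frozen=True)
class PhenotypeSpec:
    """Balanced two-factor design, mm-scale. Cell mean is
    grand_mean + effect_a (second level of A) + effect_b (second level of B)
    + beta_interaction (the A2/B2 cell only), plus N(0, sigma^2) noise.

    Defaults emulate a warm-temperature hypocotyl-elongation experiment:
    a wild type elongating strongly at 27 vs 23 degrees C and a mutant whose
    response is attenuated (negative interaction term).
    """

    levels_a: tuple[str, ...] = ("Col-0", "pwr-2")
    levels_b: tuple[str, ...] = ("23C", "27C")
    n_per_cell: int = 15
    grand_mean: float = 2.0
    effect_a: float = -0.3
    effect_b: float = 4.0
    beta_interaction: float = -3.0
    sigma: float = 0.5


@dataclass(frozen=True)
class GeneratorConfig:
    universe_size: int = DEFAULT_UNIVERSE_SIZE
    tracks: tuple[TrackSpec, ...] = (
        TrackSpec("high_H2AZ", DEFAULT_TRACK_SIZES["high_H2AZ"]),
        TrackSpec("H3K9ac", DEFAULT_TRACK_SIZES["H3K9ac"]),
    )
    deg_lists: tuple[DegSpec, ...] = ()
    concordance: float = 0.9
    phenotypes: PhenotypeSpec = field(default_factory=PhenotypeSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.universe_size < 1:
            raise ValueError("universe_size must be >= 1")
        if not 0.0 <= self.concordance <= 1.0:
            raise ValueError("concordance must lie in [0, 1]")
        for t in self.tracks:
            if t.size > self.universe_size:
                raise ValueError(f"track {t.label!r} larger than universe")
        for d in self.deg_lists:
            if d.size > self.universe_size:
                raise ValueError(f"DEG list {d.label!r} larger than universe")
            if d.theta < 0:
                raise ValueError("theta must be >= 0")
        if self.phenotypes.sigma < 0:
            raise ValueError("sigma must be >= 0")


def generate_universe(n: int = DEFAULT_UNIVERSE_SIZE, seed: int = 0) -> GeneUniverse:
    """N unique AGI-style locus IDs (ATxGnnnnn), deterministic given seed."""
    # IDs are synthetic AGI look-alikes; chromosome digit cycles 1-5
    ids = tuple(f"AT{(i % 5) + 1}G{i:05d}" for i in range(n))
    return GeneUniverse(ids)


def generate_tracks(
    cfg: GeneratorConfig, u: GeneUniverse, rng: np.random.Generator | None = None
) -> list[AnnotationTrack]:
    """Sample annotation tracks without replacement, honouring forced overlaps.

    A spec with ``overlap_with``/``overlap`` draws exactly that many members
    from the named earlier track and the remainder from outside it, so
    pairwise dependence (e.g. H3K9ac enriched within high-H2A.Z) is exact by
    construction.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    id_arr = np.asarray(u.ids)
    done: dict[str, AnnotationTrack] = {}
    for spec in cfg.tracks:
        if spec.overlap_with is None:
            idx = rng.choice(u.size, spec.size, replace=False)
            members = frozenset(id_arr[idx])
        else:
            if spec.overlap_with not in done:
                raise ValueError(f"track {spec.label!r} references unknown track {spec.overlap_with!r}")
            if spec.overlap is None:
                raise ValueError(f"track {spec.label!r} sets overlap_with but no overlap count")
            other = done[spec.overlap_with]
            inside = np.asarray(sorted(other.members))
            outside = np.asarray(sorted(set(u.ids) - other.members))
            n_out = spec.size - spec.overlap
            if spec.overlap > len(inside) or n_out > len(outside) or n_out < 0:
                raise ValueError(
                    f"requested overlap {spec.overlap} infeasible for track "
                    f"{spec.label!r} (size {spec.size}) against {spec.overlap_with!r}"
                )
            chosen = list(rng.choice(inside, spec.overlap, replace=False))
            chosen += list(rng.choice(outside, n_out, replace=False))
            members = frozenset(chosen)
        done[spec.label] = AnnotationTrack(spec.label, members, u)
    return list(done.values())


def _weighted_sample_without_replacement(
    rng: np.random.Generator, weights: np.ndarray, size: int
) -> np.ndarray:
    """Indices of a weighted sample without replacement, exact size.

    Exponential-race keys: drawing Exp(rate=w_i) per item and keeping the
    `size` smallest is distributionally identical to sequential
    draw-and-remove with probabilities proportional to the weights.
    """
    if size > np.count_nonzero(weights):
        raise ValueError("not enough items with positive weight")
    keys = np.full(len(weights), np.inf)
    pos = weights > 0
    finite = np.isfinite(weights)
    # infinite-weight items always win the race
    keys[pos & finite] = rng.exponential(1.0, int(np.count_nonzero(pos & finite))) / weights[pos & finite]
    keys[pos & ~finite] = -1.0
    idx = np.argpartition(keys, size - 1)[:size]
    return idx


def generate_deg_lists(
    cfg: GeneratorConfig,
    u: GeneUniverse,
    tracks: list[AnnotationTrack],
    rng: np.random.Generator | None = None,
) -> list[SignedGeneSet]:
    """Signed DEG lists with planted track enrichment and direction concordance."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    id_arr = np.asarray(u.ids)
    index_of = {g: i for i, g in enumerate(u.ids)}
    track_by_label = {t.label: t for t in tracks}
    latent = rng.choice(np.array([-1, 1]), size=u.size)
    out: list[SignedGeneSet] = []
    for spec in cfg.deg_lists:
        weights = np.ones(u.size)
        if spec.track is not None:
            if spec.track not in track_by_label:
                raise ValueError(f"DEG spec {spec.label!r} references unknown track {spec.track!r}")
            track_idx = np.fromiter(
                (index_of[g] for g in track_by_label[spec.track].members),
                dtype=np.intp,
            )
            weights[track_idx] = spec.theta
        idx = _weighted_sample_without_replacement(rng, weights, spec.size)
        if not out:
            # the first list is the reference: it carries the latent signs, so
            # a later list agrees with it on a shared gene with probability rho
            signs = latent[idx]
        else:
            copy = rng.random(spec.size) < cfg.concordance
            signs = np.where(copy, latent[idx], -latent[idx])
        out.append(
            SignedGeneSet(
                label=spec.label,
                directions={id_arr[i]: int(s) for i, s in zip(idx, signs)},
            )
        )
    return out


def generate_phenotypes(
    spec: PhenotypeSpec | GeneratorConfig | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Balanced two-factor phenotype table with Gaussian noise."""
    if isinstance(spec, GeneratorConfig):
        if seed is None:
            seed = spec.seed
        spec = spec.phenotypes
    elif spec is None:
        spec = PhenotypeSpec()
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    rows = []
    for i, la in enumerate(spec.levels_a):
        for j, lb in enumerate(spec.levels_b):
            mean = spec.grand_mean
            if i == len(spec.levels_a) - 1:
                mean += spec.effect_a
            if j == len(spec.levels_b) - 1:
                mean += spec.effect_b
            if i == len(spec.levels_a) - 1 and j == len(spec.levels_b) - 1:
                mean += spec.beta_interaction
            noise = rng.normal(0.0, spec.sigma, spec.n_per_cell) if spec.sigma > 0 else np.zeros(spec.n_per_cell)
            for r in range(spec.n_per_cell):
                rows.append(
                    {
                        "factor_a": la,
                        "factor_b": lb,
                        "replicate": r + 1,
                        "value": mean + noise[r],
                    }
                )
    return pd.DataFrame(rows)


def write_synthetic_inputs(cfg: GeneratorConfig, outdir: str | Path) -> dict[str, str]:
    """Emit every generated input as the file formats the readers consume,
    plus a manifest recording the configuration and seed."""
    from .gene_sets import write_plain, write_signed_set

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    u = generate_universe(cfg.universe_size, cfg.seed)
    tracks = generate_tracks(cfg, u, rng)
    degs = generate_deg_lists(cfg, u, tracks, rng)
    phen = generate_phenotypes(cfg.phenotypes, rng)
    paths: dict[str, str] = {}
    write_plain(u.ids, outdir / "universe.txt")
    paths["universe"] = "universe.txt"
    for t in tracks:
        fname = f"track_{t.label}.txt"
        write_plain(sorted(t.members), outdir / fname)
        paths[f"track:{t.label}"] = fname
    for s in degs:
        fname = f"deg_{s.label}.tsv"
        write_signed_set(s, outdir / fname)
        paths[f"deg:{s.label}"] = fname
    phen.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
    paths["phenotypes"] = "phenotypes.tsv"
    manifest = {
        "seed": cfg.seed,
        "universe_size": cfg.universe_size,
        "tracks": [vars(t) | {} for t in cfg.tracks],
        "deg_lists": [vars(d) | {} for d in cfg.deg_lists],
        "concordance": cfg.concordance,
        "phenotypes": vars(cfg.phenotypes) | {},
        "files": paths,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=list)
    return paths
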