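"""Gene universes, signed DEG lists, and binary annotation tracks.

The containers here define the sampling frame for every overlap test in
:mod:`degmeta.overlap`: a finite gene universe of size ``N``, signed
differentially-expressed-gene (DEG) lists carrying an up/down direction per
gene, and flat annotation tracks (e.g. genes with high H2A.Z enrichment in
their gene bodies).

Gene identifiers are normalized to locus level — uppercased, with any
``.n`` transcript/model suffix stripped — so lists produced by different
labs against different annotation releases join on a common key.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

logger = logging.getLogger(__name__)

_TRANSCRIPT_SUFFIX = re.compile(r"\.\d+$")


def normalize_gene_id(gene_id: str) -> str:
    """Uppercase a gene ID and strip a trailing ``.n`` transcript suffix."""
    return _TRANSCRIPT_SUFFIX.sub("", gene_id.strip().upper())


@dataclass(frozen=True)
class GeneUniverse:
    """The finite reference set of genes defining N for overlap probabilities.

    IDs are stored normalized and deduplicated, preserving first-seen order.
    """

    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) < 1:
            raise ValueError("gene universe must contain at least one gene")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("gene universe contains duplicate IDs")

    @classmethod
    def from_iterable(cls, ids: Iterable[str]) -> "GeneUniverse":
        seen: dict[str, None] = {}
        for gid in ids:
            seen.setdefault(normalize_gene_id(gid), None)
        return cls(tuple(seen))

    @property
    def size(self) -> int:
        return len(self.ids)

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, gene_id: str) -> bool:
        return normalize_gene_id(gene_id) in self._index

    @property
    def _index(self) -> frozenset[str]:
        # cached on first use; frozen dataclass so stash via object.__setattr__
        cached = self.__dict__.get("_index_cache")
        if cached is None:
            cached = frozenset(self.ids)
            object.__setattr__(self, "_index_cache", cached)
        return cached


@dataclass
class SignedGeneSet:
    """A gene list with a per-gene direction (+1 up, -1 down).

    ``log2fc`` and ``padj`` are optional per-gene annotations carried along
    from a differential-expression table; ``padj`` is the multiple-testing
    adjusted p-value used by :func:`filter_degs`.
    """

    label: str
    directions: dict[str, int] = field(default_factory=dict)
    log2fc: dict[str, float] = field(default_factory=dict)
    padj: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [g for g, d in self.directions.items() if d not in (-1, 1)]
        if bad:
            raise ValueError(f"directions must be +1 or -1; offending genes: {bad[:5]}")

    @property
    def members(self) -> frozenset[str]:
        return frozenset(self.directions)

    def __len__(self) -> int:
        return len(self.directions)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.directions

    def genes_with_direction(self, direction: int) -> frozenset[str]:
        return frozenset(g for g, d in self.directions.items() if d == direction)

    @property
    def up(self) -> frozenset[str]:
        return self.genes_with_direction(+1)

    @property
    def down(self) -> frozenset[str]:
        return self.genes_with_direction(-1)


@dataclass
class AnnotationTrack:
    """A binary gene label (e.g. high-H2A.Z) over a universe."""

    label: str
    members: frozenset[str]
    universe: GeneUniverse

    def __post_init__(self) -> None:
        outside = self.members - self.universe._index
        if outside:
            raise ValueError(
                f"track {self.label!r} has {len(outside)} members outside its "
                f"universe (e.g. {sorted(outside)[:3]}); restrict first"
            )

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.members


def intersect_tracks(a: AnnotationTrack, b: AnnotationTrack, label: str | None = None) -> AnnotationTrack:
    """Intersection of two tracks over a shared universe (e.g. H3K9ac ∩ high-H2A.Z)."""
    if a.universe.ids != b.universe.ids:
        raise ValueError("tracks must share a universe")
    return AnnotationTrack(
        label=label or f"{a.label}&{b.label}",
        members=a.members & b.members,
        universe=a.universe,
    )


class GeneListParseError(ValueError):
    """Raised on a malformed gene-list file; message names the line."""


def _read_plain(path: Path) -> SignedGeneSet:
    directions: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if len(line.split()) > 1:
                raise GeneListParseError(
                    f"{path}:{lineno}: expected one gene ID per line, got {raw.strip()!r}"
                )
            directions[normalize_gene_id(line)] = +1
    return SignedGeneSet(label=Path(path).stem, directions=directions)


def _read_tsv(path: Path) -> SignedGeneSet:
    directions: dict[str, int] = {}
    log2fc: dict[str, float] = {}
    padj: dict[str, float] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            return SignedGeneSet(label=Path(path).stem)
        cols = {name.strip().lower(): i for i, name in enumerate(header)}
        if "gene_id" not in cols:
            raise GeneListParseError(f"{path}:1: TSV header must contain 'gene_id'")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < len(cols):
                raise GeneListParseError(f"{path}:{lineno}: expected {len(cols)} fields, got {len(row)}")
            gid = normalize_gene_id(row[cols["gene_id"]])
            fc = None
            if "log2fc" in cols and row[cols["log2fc"]].strip():
                try:
                    fc = float(row[cols["log2fc"]])
                except ValueError as exc:
                    raise GeneListParseError(f"{path}:{lineno}: bad log2fc {row[cols['log2fc']]!r}") from exc
            direction = +1 if fc is None or fc > 0 else (-1 if fc < 0 else 0)
            if gid in directions and directions[gid] != direction:
                raise GeneListParseError(
                    f"{path}:{lineno}: gene {gid} appears twice with conflicting direction"
                )
            # direction 0 (log2fc == 0) is resolved downstream by filter_degs,
            # which rejects it only if the gene survives the padj filter
            directions[gid] = direction if direction != 0 else +1
            if fc is not None:
                log2fc[gid] = fc
            if "padj" in cols and row[cols["padj"]].strip():
                try:
                    padj[gid] = float(row[cols["padj"]])
                except ValueError as exc:
                    raise GeneListParseError(f"{path}:{lineno}: bad padj {row[cols['padj']]!r}") from exc
    return SignedGeneSet(label=Path(path).stem, directions=directions, log2fc=log2fc, padj=padj)


def _read_gmt(path: Path) -> list[SignedGeneSet]:
    sets: list[SignedGeneSet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise GeneListParseError(
                    f"{path}:{lineno}: GMT record needs name, description and >=1 member"
                )
            name, _desc, *members = fields
            directions = {normalize_gene_id(m): +1 for m in members if m.strip()}
            sets.append(SignedGeneSet(label=name, directions=directions))
    return sets


def read_gene_list(
    path: str | Path, format: Literal["plain", "tsv", "gmt"] = "plain"
) -> list[SignedGeneSet]:
    """Read one or more signed gene sets from a file.

    ``plain`` is one ID per line (``#`` comments allowed, direction +1),
    ``tsv`` needs a header with ``gene_id`` and optional ``log2fc``/``padj``
    columns, and ``gmt`` yields one set per record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "plain":
        return [_read_plain(path)]
    if format == "tsv":
        return [_read_tsv(path)]
    if format == "gmt":
        return _read_gmt(path)
    raise ValueError(f"unknown format {format!r}")


def write_signed_set(s: SignedGeneSet, path: str | Path) -> None:
    """Write a signed set as a two-column TSV (gene_id, direction)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene_id", "direction"])
        for gid in sorted(s.directions):
            writer.writerow([gid, s.directions[gid]])


def write_plain(ids: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid in ids:
            fh.write(f"{gid}\n")


def filter_degs(table: SignedGeneSet, alpha: float = 0.05) -> SignedGeneSet:
    """Keep genes with adjusted p-value strictly below ``alpha``.

    This is the standard DEG definition (padj < 0.05 by default). The
    surviving gene's direction is the sign of its log2 fold change; a gene
    that passes the filter with log2fc exactly zero has no defined direction
    and is an error.
    """
    missing = [g for g in table.directions if g not in table.padj]
    if missing:
        raise ValueError(f"filter_degs requires padj for every member; missing for {missing[:5]}")
    directions: dict[str, int] = {}
    log2fc: dict[str, float] = {}
    padj: dict[str, float] = {}
    for gid in table.directions:
        if not table.padj[gid] < alpha:
            continue
        fc = table.log2fc.get(gid)
        if fc is None:
            directions[gid] = table.directions[gid]
        elif fc == 0:
            raise ValueError(f"gene {gid} passes padj filter but has log2fc == 0 (undefined direction)")
        else:
            directions[gid] = +1 if fc > 0 else -1
            log2fc[gid] = fc
        padj[gid] = table.padj[gid]
    return SignedGeneSet(label=table.label, directions=directions, log2fc=log2fc, padj=padj)


def merge_direction_consistent(
    sets: Sequence[SignedGeneSet],
    how: Literal["union", "intersection"] = "union",
    label: str | None = None,
) -> SignedGeneSet:
    """Compile DEG lists across datasets, excluding direction conflicts.

    A gene observed as up in one dataset and down in another is dropped; a
    gene absent from a dataset is treated as not measured, never as a
    conflict. ``how="union"`` keeps every direction-consistent gene seen in
    any list; ``how="intersection"`` keeps only genes seen (consistently) in
    every list.
    """
    if not sets:
        raise ValueError("merge_direction_consistent needs at least one set")
    seen: dict[str, int] = {}
    counts: dict[str, int] = {}
    conflicted: set[str] = set()
    for s in sets:
        for gid, d in s.directions.items():
            counts[gid] = counts.get(gid, 0) + 1
            if gid in seen and seen[gid] != d:
                conflicted.add(gid)
            seen.setdefault(gid, d)
    if how == "union":
        keep = {g: d for g, d in seen.items() if g not in conflicted}
    elif how == "intersection":
        keep = {g: d for g, d in seen.items() if g not in conflicted and counts[g] == len(sets)}
    else:
        raise ValueError(f"unknown merge mode {how!r}")
    return SignedGeneSet(label=label or "+".join(s.label for s in sets), directions=keep)


def restrict_to_universe(
    s: SignedGeneSet | AnnotationTrack, u: GeneUniverse
) -> SignedGeneSet | AnnotationTrack:
    """Drop members outside the universe so hypergeometric margins are well-defined."""
    idx = u._index
    if isinstance(s, AnnotationTrack):
        kept = s.members & idx
        dropped = len(s.members) - len(kept)
        result: SignedGeneSet | AnnotationTrack = AnnotationTrack(s.label, kept, u)
        n_in = len(s.members)
    else:
        directions = {g: d for g, d in s.directions.items() if g in idx}
        dropped = len(s.directions) - len(directions)
        result = SignedGeneSet(
            label=s.label,
            directions=directions,
            log2fc={g: v for g, v in s.log2fc.items() if g in directions},
            padj={g: v for g, v in s.padj.items() if g in directions},
        )
        n_in = len(s.directions)
    if dropped:
        logger.info("restrict_to_universe: dropped %d/%d IDs from %r", dropped, n_in, s.label)
    if n_in and not len(result):
        logger.warning("restrict_to_universe: no members of %r are in the universe", s.label)
    return result
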