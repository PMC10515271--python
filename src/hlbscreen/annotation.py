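"""Coordinate model of the *Drosophila* replication-dependent histone repeat unit.

The histone locus is a cluster of roughly one hundred tandemly repeated,
nearly identical ~5 kb units. Each unit carries the five canonical histone
genes (H1, H2A, H2B, H3, H4) and three promoters: two divergent
TATA-containing core promoters (one shared by H2A/H2B, one by H3/H4) and the
TATA-less H1 promoter. The H3/H4 promoter — the ~300 bp element that
nucleates the histone locus body — additionally contains GA-repeat cis
elements bound by CLAMP, which are also the source of a short-read
multimapping artifact that the classifier must recognize.

Coordinates are 0-based, half-open (BED convention) throughout. Strand is
recorded but ignored by coverage and classification: all downstream tracks
are unstranded.

No public base-pair annotation of the repeat unit's internal layout exists,
so :func:`build_default_annotation` provides a fixed synthetic stand-in with
realistic element sizes. Users holding a real annotation supply it as BED6
via :func:`read_bed`; the feature kind is carried in the BED name field as
``name|kind``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FEATURE_KINDS = frozenset(
    {"gene", "promoter", "tata_box", "ga_repeat", "tata_less_motif"}
)

GENE_NAMES = ("H1", "H2A", "H2B", "H3", "H4")
PROMOTER_NAMES = ("H1_promoter", "H2A_H2B_promoter", "H3_H4_promoter")

UNIT_NAME = "histone_unit"  # single reference sequence name used everywhere


class AnnotationError(ValueError):
    """Raised when an annotation violates the repeat-unit invariants."""


@dataclass(frozen=True)
class Feature:
    """A named interval on the repeat unit.

    ``start``/``end`` follow the 0-based half-open convention; ``strand`` is
    one of ``+``, ``-``, ``.``.
    """

    name: str
    kind: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise AnnotationError(f"unknown feature kind {self.kind!r}")
        if not 0 <= self.start < self.end:
            raise AnnotationError(
                f"feature {self.name!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise AnnotationError(f"feature {self.name!r}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class ArrayAnnotation:
    """The repeat-unit coordinate system and its named features.

    ``promoter_map`` records which genes each promoter drives (the two core
    promoters are divergent and drive a gene on each side).
    """

    unit_length: int = 5000
    features: list[Feature] = field(default_factory=list)
    promoter_map: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- queries -----------------------------------------------------------

    def feature(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def by_kind(self, *kinds: str) -> list[Feature]:
        return [f for f in self.features if f.kind in kinds]

    def mask(self, *kinds: str) -> np.ndarray:
        """Boolean per-base membership vector for the union of the given kinds."""
        m = np.zeros(self.unit_length, dtype=bool)
        for f in self.by_kind(*kinds):
            m[f.start : f.end] = True
        return m

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise AnnotationError(f"duplicate feature names: {dup}")
        for f in self.features:
            if f.end > self.unit_length:
                raise AnnotationError(
                    f"feature {f.name!r} extends past unit end "
                    f"({f.end} > {self.unit_length})"
                )
        genes = self.by_kind("gene")
        if sorted(g.name for g in genes) != sorted(GENE_NAMES):
            raise AnnotationError(
                f"genes must be exactly {GENE_NAMES}, got "
                f"{sorted(g.name for g in genes)}"
            )
        for name in PROMOTER_NAMES:
            if not any(f.name == name and f.kind == "promoter" for f in self.features):
                raise AnnotationError(f"missing promoter {name!r}")
        h1p = self.feature("H1_promoter")
        h34p = self.feature("H3_H4_promoter")
        within = lambda f, p: p.start <= f.start and f.end <= p.end  # noqa: E731
        if not any(within(f, h34p) for f in self.by_kind("ga_repeat")):
            raise AnnotationError("H3_H4_promoter must contain a ga_repeat element")
        if not any(within(f, h1p) for f in self.by_kind("tata_less_motif")):
            raise AnnotationError("H1_promoter must contain a tata_less_motif")
        if any(within(f, h1p) for f in self.by_kind("tata_box")):
            raise AnnotationError("H1_promoter must not contain a tata_box")
        for name in ("H2A_H2B_promoter", "H3_H4_promoter"):
            p = self.feature(name)
            if not any(within(f, p) for f in self.by_kind("tata_box")):
                raise AnnotationError(f"{name} must contain a tata_box")
        ordered = sorted(genes, key=lambda g: g.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start < a.end:
                raise AnnotationError(
                    f"gene bodies overlap: {a.name} [{a.start},{a.end}) and "
                    f"{b.name} [{b.start},{b.end})"
                )


def build_default_annotation() -> ArrayAnnotation:
    """The fixed default layout of the 5 kb unit.

    The layout is synthetic (the real array's internal coordinates are not
    published) but keeps realistic proportions: histone gene bodies at ORF
    scale (~310–790 bp), a ~300 bp H3/H4 promoter centered near the unit
    midpoint with two GA-repeat elements flanked by the divergent pair's two
    TATA boxes, and every gene/promoter at least 200 bp so peaks are
    unambiguous at simulated read lengths.
    """
    features = [
        Feature("H1_promoter", "promoter", 150, 450, "."),
        Feature("H1_tata_less", "tata_less_motif", 270, 300, "."),
        Feature("H1", "gene", 450, 1240, "+"),
        Feature("H3", "gene", 1940, 2350, "-"),
        Feature("H3_H4_promoter", "promoter", 2350, 2650, "."),
        Feature("H3_tata", "tata_box", 2365, 2395, "."),
        Feature("H3_H4_ga_1", "ga_repeat", 2430, 2490, "."),
        Feature("H3_H4_ga_2", "ga_repeat", 2510, 2560, "."),
        Feature("H4_tata", "tata_box", 2605, 2635, "."),
        Feature("H4", "gene", 2650, 2970, "+"),
        Feature("H2A", "gene", 3700, 4080, "-"),
        Feature("H2A_H2B_promoter", "promoter", 4080, 4330, "."),
        Feature("H2A_tata", "tata_box", 4100, 4130, "."),
        Feature("H2B_tata", "tata_box", 4280, 4310, "."),
        Feature("H2B", "gene", 4330, 4710, "+"),
    ]
    promoter_map = {
        "H1_promoter": ("H1",),
        "H2A_H2B_promoter": ("H2A", "H2B"),
        "H3_H4_promoter": ("H3", "H4"),
    }
    return ArrayAnnotation(5000, features, promoter_map)


def elements_at(annotation: ArrayAnnotation, pos: int) -> set[Feature]:
    """All features whose half-open interval contains ``pos``.

    An empty set means the position is intergenic. Out-of-range positions
    are a coordinate error.
    """
    if not 0 <= pos < annotation.unit_length:
        raise AnnotationError(
            f"position {pos} outside unit [0, {annotation.unit_length})"
        )
    return {f for f in annotation.features if f.contains(pos)}


def intergenic_intervals(annotation: ArrayAnnotation) -> list[tuple[int, int]]:
    """Sorted, disjoint complement of the union of gene and promoter features."""
    covered = annotation.mask("gene", "promoter")
    out: list[tuple[int, int]] = []
    pos = 0
    L = annotation.unit_length
    while pos < L:
        if not covered[pos]:
            start = pos
            while pos < L and not covered[pos]:
                pos += 1
            out.append((start, pos))
        else:
            pos += 1
    return out


# -- BED6 interchange ------------------------------------------------------


def write_bed(annotation: ArrayAnnotation, path) -> None:
    """Write the annotation as BED6; kind is encoded in the name as name|kind."""
    with open(path, "w") as fh:
        for f in annotation.features:
            fh.write(
                f"{UNIT_NAME}\t{f.start}\t{f.end}\t{f.name}|{f.kind}\t0\t{f.strand}\n"
            )


def read_bed(path, unit_length: int = 5000) -> ArrayAnnotation:
    """Parse a BED6 annotation written by :func:`write_bed`.

    Malformed lines raise :class:`AnnotationError` naming the line number.
    The promoter→genes map is reconstructed from promoter names (tokens that
    match gene names, e.g. ``H3_H4_promoter`` drives H3 and H4).
    """
    features: list[Feature] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise AnnotationError(
                    f"{path}: line {lineno}: expected 6 BED fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                raise AnnotationError(
                    f"{path}: line {lineno}: start {start} >= end {end}"
                )
            name_kind = fields[3]
            if "|" not in name_kind:
                raise AnnotationError(
                    f"{path}: line {lineno}: name field must be 'name|kind', "
                    f"got {name_kind!r}"
                )
            name, kind = name_kind.rsplit("|", 1)
            if name in seen:
                raise AnnotationError(f"{path}: line {lineno}: duplicate name {name!r}")
            seen.add(name)
            try:
                features.append(Feature(name, kind, start, end, fields[5]))
            except AnnotationError as exc:
                raise AnnotationError(f"{path}: line {lineno}: {exc}") from exc
    gene_names = {f.name for f in features if f.kind == "gene"}
    promoter_map = {}
    for f in features:
        if f.kind == "promoter":
            tokens = f.name.split("_")
            promoter_map[f.name] = tuple(g for g in GENE_NAMES if g in tokens and g in gene_names)
    return ArrayAnnotation(unit_length, features, promoter_map)
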