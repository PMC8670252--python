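"""Genomic feature annotation: types, strand-aware interval index, GFF3 I/O.

Transcript features (mRNA, cis-antisense RNA, trans-encoded sRNA, 5'UTR and
internal-TSS transcripts) are represented with 0-based half-open coordinates
internally.  GFF3 files use 1-based inclusive coordinates; the conversion
happens only at the I/O boundary so overlap arithmetic inside the package is
always half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Iterator, Optional

import numpy as np

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)


class FeatureType(str, Enum):
    """Transcript classes distinguished on the expression platform."""

    mRNA = "mRNA"
    asRNA = "asRNA"
    sRNA = "sRNA"
    utr5 = "utr5"
    internal = "internal"


#: GFF3 ``type`` column spellings accepted for each internal class.
_GFF_TYPE_ALIASES = {
    "mrna": FeatureType.mRNA,
    "gene": FeatureType.mRNA,
    "cds": FeatureType.mRNA,
    "asrna": FeatureType.asRNA,
    "antisense_rna": FeatureType.asRNA,
    "srna": FeatureType.sRNA,
    "ncrna": FeatureType.sRNA,
    "utr5": FeatureType.utr5,
    "five_prime_utr": FeatureType.utr5,
    "internal": FeatureType.internal,
}


@dataclass(frozen=True)
class GenomicFeature:
    """One annotated transcript feature.

    ``start``/``end`` are 0-based half-open.  ``gene_id`` carries the locus
    tag of the host gene (for an mRNA, usually its own locus tag; for an
    asRNA, the cognate gene).
    """

    feature_id: str
    feature_type: FeatureType
    replicon: str
    start: int
    end: int
    strand: str
    gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"feature {self.feature_id!r}: start ({self.start}) must be "
                f"< end ({self.end}) in half-open coordinates"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"feature {self.feature_id!r}: strand must be '+' or '-', "
                f"got {self.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicFeature") -> int:
        """Overlap in bp with *other* on the same replicon (strand ignored)."""
        if self.replicon != other.replicon:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class FeatureSet:
    """A collection of features with a strand-aware interval index.

    The index is a per-(replicon, strand) pair of sorted start/end arrays;
    an overlap query is two binary searches plus a mask, which is ample for
    annotation-scale inputs (thousands of features).
    """

    def __init__(self, features: Iterable[GenomicFeature]):
        self.features: list[GenomicFeature] = list(features)
        seen: set[str] = set()
        for f in self.features:
            if f.feature_id in seen:
                raise ValidationError(f"duplicate feature_id {f.feature_id!r}")
            seen.add(f.feature_id)
        self._by_id = {f.feature_id: f for f in self.features}
        self._index: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, list[int]]] = {}
        buckets: dict[tuple[str, str], list[int]] = {}
        for i, f in enumerate(self.features):
            buckets.setdefault((f.replicon, f.strand), []).append(i)
        for key, idx in buckets.items():
            starts = np.array([self.features[i].start for i in idx])
            ends = np.array([self.features[i].end for i in idx])
            self._index[key] = (starts, ends, idx)

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[GenomicFeature]:
        return iter(self.features)

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._by_id

    def get(self, feature_id: str) -> GenomicFeature:
        return self._by_id[feature_id]

    def by_type(self, ftype: FeatureType) -> list[GenomicFeature]:
        return [f for f in self.features if f.feature_type is ftype]

    def overlapping(
        self, replicon: str, start: int, end: int, strand: str
    ) -> list[GenomicFeature]:
        """Features on (replicon, strand) whose [start, end) intersects the query."""
        key = (replicon, strand)
        if key not in self._index:
            return []
        starts, ends, idx = self._index[key]
        mask = (starts < end) & (ends > start)
        return [self.features[idx[i]] for i in np.flatnonzero(mask)]


def read_annotation(path, default_type: Optional[FeatureType] = None) -> FeatureSet:
    """Read a GFF3 annotation into a :class:`FeatureSet`.

    The feature class is taken from the GFF3 ``type`` column (aliases such as
    ``antisense_RNA`` are accepted).  Unknown types map to *default_type* if
    given, otherwise the line is rejected.  The ``ID`` attribute becomes the
    feature id and ``gene`` (or ``locus_tag``) the gene id.
    """
    features: list[GenomicFeature] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            replicon, _source, gff_type, start_s, end_s, _score, strand, _phase, attrs = cols
            try:
                start1 = int(start_s)
                end1 = int(end_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            attributes = _parse_attributes(attrs, path, lineno)
            ftype = _GFF_TYPE_ALIASES.get(gff_type.lower())
            if ftype is None and "feature_type" in attributes:
                ftype = _GFF_TYPE_ALIASES.get(attributes["feature_type"].lower())
            if ftype is None:
                if default_type is None:
                    raise ParseError(
                        f"{path}:{lineno}: unknown feature type {gff_type!r} "
                        "and no default configured"
                    )
                ftype = default_type
            feature_id = attributes.get("ID")
            if feature_id is None:
                raise ParseError(f"{path}:{lineno}: missing ID attribute")
            # GFF3 1-based inclusive -> 0-based half-open.
            start0, end0 = start1 - 1, end1
            if start0 >= end0:
                raise ValidationError(
                    f"{path}:{lineno}: start >= end after coordinate conversion"
                )
            features.append(
                GenomicFeature(
                    feature_id=feature_id,
                    feature_type=ftype,
                    replicon=replicon,
                    start=start0,
                    end=end0,
                    strand=strand,
                    gene_id=attributes.get("gene") or attributes.get("locus_tag"),
                )
            )
    if not features:
        logger.warning("annotation %s contains no features", path)
    return FeatureSet(features)


def write_annotation(features: FeatureSet, path) -> None:
    """Write a :class:`FeatureSet` back to GFF3 (1-based inclusive)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.feature_id}"
            if f.gene_id:
                attrs += f";gene={f.gene_id}"
            fh.write(
                "\t".join(
                    [
                        f.replicon,
                        "saltomics",
                        f.feature_type.value,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def _parse_attributes(field: str, path, lineno: int) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in field.split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise ParseError(f"{path}:{lineno}: malformed attribute {item!r}")
        key, value = item.split("=", 1)
        out[key] = value
    return out
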