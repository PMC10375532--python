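"""Counting randomized-region variants in amplicon sequencing reads.

A selection library consists of a fixed upstream flank, a fully randomized
region of k nucleotides, and a fixed downstream flank.  Reads are matched
against this fixed layout (no indel alignment: amplicon reads either fit the
layout or they are discarded), the enclosed k-mer is extracted, and every one
of the 4**k possible variants is tallied — including the ones never observed,
which matter downstream for pseudocounted enrichment.
"""

from __future__ import annotations

import gzip
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO

RNA_ALPHABET = "ACGU"

_DNA_TO_RNA = str.maketrans("Tt", "Uu")
_COMPLEMENT = str.maketrans("ACGTU", "TGCAA")


def _to_rna(seq: str) -> str:
    return seq.upper().translate(_DNA_TO_RNA)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA/RNA sequence (returned as DNA letters)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class LibraryDesign:
    """Fixed-flank amplicon layout with a randomized region of length ``k``.

    Flanks are RNA sequences (A/C/G/U); ``k`` is the number of fully
    randomized positions between them.  At least one flank must be non-empty,
    otherwise the randomized region cannot be anchored in a read.
    """

    upstream_flank: str
    k: int
    downstream_flank: str
    name: str = "library"

    def __post_init__(self) -> None:
        object.__setattr__(self, "upstream_flank", _to_rna(self.upstream_flank))
        object.__setattr__(self, "downstream_flank", _to_rna(self.downstream_flank))
        if self.k < 1:
            raise ValueError(f"randomized-region length k must be >= 1, got {self.k}")
        for label, flank in (("upstream", self.upstream_flank),
                             ("downstream", self.downstream_flank)):
            if any(b not in RNA_ALPHABET for b in flank):
                raise ValueError(f"{label} flank contains non-ACGU characters: {flank!r}")
        if not self.upstream_flank and not self.downstream_flank:
            raise ValueError("at least one flank must be non-empty")

    @property
    def read_length(self) -> int:
        return len(self.upstream_flank) + self.k + len(self.downstream_flank)

    @property
    def n_variants(self) -> int:
        return 4 ** self.k

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "upstream_flank": self.upstream_flank,
            "k": self.k,
            "downstream_flank": self.downstream_flank,
            "name": self.name,
        }, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "LibraryDesign":
        d = json.loads(Path(path).read_text())
        return cls(upstream_flank=d["upstream_flank"], k=int(d["k"]),
                   downstream_flank=d["downstream_flank"],
                   name=d.get("name", "library"))


# Library layouts used in the screens: a 3'-overhang library with five
# randomized terminal bases, and a stem library with three randomized bases
# upstream of the fixed UUCCA overhang (paired with the donor 5'-pNNNGAAUC-3').
OVERHANG_LIBRARY = LibraryDesign("UCGCU", 5, "", name="overhang5")
STEM_LIBRARY = LibraryDesign("GAUUC", 3, "UUCCA", name="stem3")


def enumerate_variants(k: int) -> list[str]:
    """All 4**k RNA k-mers in lexicographic order (A < C < G < U).

    ``k`` is guarded to at most 8 (65 536 variants) — beyond that a dense
    table over the variant space stops being the right data structure.
    """
    if not 1 <= k <= 8:
        raise ValueError(f"k must be in [1, 8], got {k}")
    return ["".join(p) for p in itertools.product(RNA_ALPHABET, repeat=k)]


@dataclass
class VariantCountTable:
    """Per-condition read counts over the complete variant space.

    ``counts`` maps every one of the 4**k variants (in lexicographic order)
    to a non-negative integer; ``matched``/``unmatched`` account for every
    read processed.
    """

    design: LibraryDesign
    condition_label: str
    counts: dict[str, int]
    matched: int = 0
    unmatched: int = 0

    def __post_init__(self) -> None:
        expected = enumerate_variants(self.design.k)
        if list(self.counts.keys()) != expected:
            # tolerate arbitrary key order / missing zero entries
            filled = {v: int(self.counts.get(v, 0)) for v in expected}
            extra = set(self.counts) - set(expected)
            if extra:
                raise ValueError(f"counts contain off-design variants: {sorted(extra)[:5]}")
            self.counts = filled
        total = sum(self.counts.values())
        if total != self.matched:
            raise ValueError(f"sum(counts)={total} != matched={self.matched}")

    @property
    def total_reads(self) -> int:
        return self.matched + self.unmatched

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, name=self.condition_label)

    def to_tsv(self, path: str | Path) -> None:
        total = max(self.matched, 1)
        df = pd.DataFrame({
            "variant": list(self.counts),
            "count": list(self.counts.values()),
        })
        df["frequency"] = df["count"] / total
        df.to_csv(path, sep="\t", index=False)

    def summary(self) -> dict:
        return {"condition": self.condition_label, "matched": self.matched,
                "unmatched": self.unmatched, "total": self.total_reads}


@dataclass
class ReadSet:
    """A labelled bag of reads tied to a library design."""

    condition_label: str
    reads: list[str]
    design: LibraryDesign

    def __post_init__(self) -> None:
        if not self.condition_label:
            raise ValueError("condition_label must be non-empty")
        if any(not r for r in self.reads):
            raise ValueError("reads must be non-empty strings")

    def __len__(self) -> int:
        return len(self.reads)


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fastq(path: str | Path, design: LibraryDesign,
               condition_label: str | None = None) -> ReadSet:
    """Load a FASTQ(.gz) file into a :class:`ReadSet` (sequences as stored)."""
    label = condition_label or Path(path).name.split(".")[0]
    with _open_maybe_gzip(path) as handle:
        reads = [str(rec.seq) for rec in SeqIO.parse(handle, "fastq")]
    return ReadSet(condition_label=label, reads=reads, design=design)


def _hamming_within(a: str, b: str, limit: int) -> bool:
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > limit:
                return False
    return True


def extract_variants(reads: ReadSet | Iterable[str], design: LibraryDesign,
                     max_flank_mismatch: int = 1,
                     revcomp: bool = False,
                     condition_label: str | None = None) -> VariantCountTable:
    """Match reads against the fixed layout and count variants.

    A read matches when both flanks agree with the design at their fixed
    offsets with at most ``max_flank_mismatch`` substitutions per flank and
    the enclosed k-mer is unambiguous (A/C/G/T/U only; T is read as U).
    Reads that are too short, misaligned, or ambiguous increment
    ``unmatched`` — never an exception.  ``revcomp=True`` reverse-complements
    each read first (orientation is a property of the protocol).
    """
    if max_flank_mismatch < 0:
        raise ValueError("max_flank_mismatch must be >= 0")
    if isinstance(reads, ReadSet):
        label = condition_label or reads.condition_label
        seqs: Iterable[str] = reads.reads
    else:
        label = condition_label or "reads"
        seqs = reads

    up, down, k = design.upstream_flank, design.downstream_flank, design.k
    nup = len(up)
    counts = dict.fromkeys(enumerate_variants(k), 0)
    matched = unmatched = 0
    for raw in seqs:
        seq = reverse_complement(raw) if revcomp else raw
        seq = _to_rna(seq)
        if len(seq) < design.read_length:
            unmatched += 1
            continue
        if not _hamming_within(seq[:nup], up, max_flank_mismatch):
            unmatched += 1
            continue
        if down and not _hamming_within(seq[nup + k:nup + k + len(down)], down,
                                        max_flank_mismatch):
            unmatched += 1
            continue
        variant = seq[nup:nup + k]
        if any(b not in RNA_ALPHABET for b in variant):
            unmatched += 1
            continue
        counts[variant] += 1
        matched += 1
    return VariantCountTable(design=design, condition_label=label,
                             counts=counts, matched=matched, unmatched=unmatched)


def count_fastq(path: str | Path, design: LibraryDesign,
                max_flank_mismatch: int = 1, revcomp: bool = False,
                condition_label: str | None = None) -> VariantCountTable:
    """Convenience: :func:`read_fastq` followed by :func:`extract_variants`."""
    rs = read_fastq(path, design, condition_label=condition_label)
    return extract_variants(rs, design, max_flank_mismatch=max_flank_mismatch,
                            revcomp=revcomp)


def merge_counts(tables: Sequence[VariantCountTable]) -> VariantCountTable:
    """Elementwise sum of technical-replicate count tables."""
    if not tables:
        raise ValueError("need at least one table")
    first = tables[0]
    for t in tables[1:]:
        if t.design != first.design:
            raise ValueError("cannot merge tables with different designs")
        if t.condition_label != first.condition_label:
            raise ValueError("cannot merge tables with different condition labels")
    merged = dict.fromkeys(first.counts, 0)
    matched = unmatched = 0
    for t in tables:
        for v, c in t.counts.items():
            merged[v] += c
        matched += t.matched
        unmatched += t.unmatched
    return VariantCountTable(design=first.design,
                             condition_label=first.condition_label,
                             counts=merged, matched=matched, unmatched=unmatched)
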