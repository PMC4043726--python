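"""Recoding of raw alignments into mutational-step character vectors.

Statistical-parsimony networks count mutational steps.  Microsatellite-like
repeat tracts violate the one-column/one-step assumption: a tract expanding by
one motif copy shifts many alignment columns at once.  The fix is to recode
each annotated repeat tract as a single integer character (copy number) whose
step distance is the absolute copy-number difference — one tandem-repeat
difference, one mutational step (stepwise mutation model).  Large indels are
recoded the same way, as one binary presence/absence character.  All remaining
columns form the SNP vector, in which a gap is kept as a fifth character state
(small indels count column-by-column).

The step distance between two recoded alleles decomposes as::

    steps = #(differing SNP columns) + sum |copy-number differences|
          + #(differing indel states)

and is a metric on recoded vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import AnnotationError, SchemaError
from .seq_io import AlignedMarker, AlleleSequence

#: Gaps spanning at least this many columns are "large" indels, recoded as one
#: binary character rather than column-wise fifth-state gaps.
LARGE_INDEL_THRESHOLD = 10


@dataclass(frozen=True)
class RepeatAnnotation:
    """A tandem-repeat tract: alignment interval [start, end) plus motif."""

    marker: str
    start: int
    end: int
    motif: str

    def __post_init__(self) -> None:
        if len(self.motif) < 1:
            raise AnnotationError("repeat motif must be non-empty")
        if self.end <= self.start or self.start < 0:
            raise AnnotationError(
                f"invalid repeat interval [{self.start}, {self.end})"
            )


@dataclass(frozen=True)
class IndelAnnotation:
    """A large indel: alignment interval [start, end), presence scored per allele."""

    marker: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start or self.start < 0:
            raise AnnotationError(
                f"invalid indel interval [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RecodedVector:
    """One allele's recoded characters: SNP string + repeat copies + indel states."""

    snp: str
    repeat_copies: tuple[int, ...]
    indel_present: tuple[bool, ...]
    schema: tuple

    def key(self) -> tuple:
        """Hashable identity used to collapse alleles into haplotypes."""
        return (self.snp, self.repeat_copies, self.indel_present)


@dataclass(frozen=True)
class RecodedAlignment:
    """A whole alignment after recoding; all alleles share one character schema."""

    marker: str
    alleles: tuple[AlleleSequence, ...]
    snp_columns: tuple[int, ...]  # original alignment coordinates (0-based)
    snp: tuple[str, ...]  # one string per allele, over snp_columns
    repeats: tuple[RepeatAnnotation, ...]
    repeat_copies: tuple[tuple[int, ...], ...]  # [allele][repeat]
    indels: tuple[IndelAnnotation, ...]
    indel_present: tuple[tuple[bool, ...], ...]  # [allele][indel]

    @property
    def schema(self) -> tuple:
        return (
            self.marker,
            self.snp_columns,
            tuple((r.start, r.end, r.motif) for r in self.repeats),
            tuple((i.start, i.end) for i in self.indels),
        )

    def vector(self, i: int) -> RecodedVector:
        return RecodedVector(
            snp=self.snp[i],
            repeat_copies=self.repeat_copies[i],
            indel_present=self.indel_present[i],
            schema=self.schema,
        )

    def vectors(self) -> list[RecodedVector]:
        return [self.vector(i) for i in range(len(self.alleles))]


def _degap(s: str) -> str:
    return s.replace("-", "")


def count_repeat_copies(window_seq: str, motif: str) -> int:
    """Longest run of exact tandem motif copies in a (gapped) window.

    Gaps are removed first; partial copies do not count.
    """
    s = _degap(window_seq)
    k = len(motif)
    best = 0
    i = 0
    while i < len(s):
        run = 0
        j = i
        while s[j : j + k] == motif:
            run += 1
            j += k
        best = max(best, run)
        i += 1
    return best


def _minimal_rotation_primitive(motif: str) -> bool:
    """True if motif is not itself a repetition of a shorter unit."""
    n = len(motif)
    for k in range(1, n):
        if n % k == 0 and motif[:k] * (n // k) == motif:
            return False
    return True


def detect_repeats(
    marker: AlignedMarker,
    min_copies: int = 3,
    max_motif_len: int = 6,
) -> list[RepeatAnnotation]:
    """Auto-detect tandem repeat tracts on the alignment consensus.

    Scans the column-majority consensus for ≥``min_copies`` exact tandem
    copies of primitive motifs of length 1..``max_motif_len``.  Longest tracts
    win; overlapping weaker candidates are discarded.  Intended as a
    convenience — curated annotations should be preferred when known.
    """
    cons = []
    for col in range(marker.length):
        counts: dict[str, int] = {}
        for a in marker.alleles:
            c = a.seq[col]
            counts[c] = counts.get(c, 0) + a.n_copies
        cons.append(max(counts, key=lambda c: (counts[c], c)))
    consensus = "".join(cons)

    candidates: list[tuple[int, int, str]] = []  # (start, end, motif)
    for k in range(1, max_motif_len + 1):
        i = 0
        while i + k <= len(consensus):
            motif = consensus[i : i + k]
            if "-" in motif or "N" in motif or not _minimal_rotation_primitive(motif):
                i += 1
                continue
            run = 1
            while consensus[i + run * k : i + (run + 1) * k] == motif:
                run += 1
            if run >= min_copies:
                candidates.append((i, i + run * k, motif))
                i += run * k
            else:
                i += 1
    # prefer longer tracts; drop candidates overlapping an accepted one
    candidates.sort(key=lambda c: (c[0] - c[1], c[0]))
    accepted: list[tuple[int, int, str]] = []
    for start, end, motif in candidates:
        if all(end <= s or start >= e for s, e, _ in accepted):
            accepted.append((start, end, motif))
    accepted.sort()
    return [
        RepeatAnnotation(marker.marker, s, e, m) for s, e, m in accepted
    ]


def annotate_repeats(
    marker: AlignedMarker,
    config: Iterable[dict] | None = None,
    auto: bool = False,
    min_copies: int = 3,
    max_motif_len: int = 6,
) -> list[RepeatAnnotation]:
    """Build repeat annotations from explicit config and/or auto-detection.

    Config entries are dicts with keys ``start``, ``end``, ``motif`` (and
    optional ``marker``).  An annotation whose motif occurs in no allele is
    dropped with a warning; out-of-range intervals raise.
    """
    annots: list[RepeatAnnotation] = []
    for entry in config or []:
        ann = RepeatAnnotation(
            marker=entry.get("marker", marker.marker),
            start=int(entry["start"]),
            end=int(entry["end"]),
            motif=str(entry["motif"]).upper(),
        )
        if ann.end > marker.length:
            raise AnnotationError(
                f"repeat interval [{ann.start}, {ann.end}) exceeds alignment "
                f"length {marker.length}"
            )
        found = any(
            count_repeat_copies(a.seq[ann.start : ann.end], ann.motif) > 0
            for a in marker.alleles
        )
        if not found:
            warnings.warn(
                f"motif {ann.motif!r} not found in any allele within "
                f"[{ann.start}, {ann.end}); annotation dropped",
                stacklevel=2,
            )
            continue
        annots.append(ann)
    if auto:
        taken = [(a.start, a.end) for a in annots]
        for det in detect_repeats(marker, min_copies, max_motif_len):
            if all(det.end <= s or det.start >= e for s, e in taken):
                annots.append(det)
    annots.sort(key=lambda a: a.start)
    return annots


def _check_disjoint(
    intervals: Sequence[tuple[int, int]], length: int
) -> None:
    ordered = sorted(intervals)
    for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
        if e1 > s2:
            raise AnnotationError(
                f"annotations overlap: [{s1},{e1}) and [{s2},{e2})"
            )
    for s, e in ordered:
        if s < 0 or e > length:
            raise AnnotationError(f"annotation [{s},{e}) outside alignment 0..{length}")


def recode(
    marker: AlignedMarker,
    repeats: Sequence[RepeatAnnotation] = (),
    indels: Sequence[IndelAnnotation] = (),
) -> RecodedAlignment:
    """Recode an alignment into SNP / repeat-copy / indel characters.

    Annotated intervals are removed from the SNP vector.  Indel presence is
    scored per allele as sequence present (gap fraction < 0.5 in the window).
    Overlapping annotations raise; recoding an already recoded alignment is
    rejected.
    """
    if isinstance(marker, RecodedAlignment):
        raise TypeError("input is already recoded; recoding is not re-applicable")
    intervals = [(r.start, r.end) for r in repeats] + [
        (i.start, i.end) for i in indels
    ]
    _check_disjoint(intervals, marker.length)

    masked = np.zeros(marker.length, dtype=bool)
    for s, e in intervals:
        masked[s:e] = True
    snp_columns = tuple(int(c) for c in np.flatnonzero(~masked))

    snp = tuple(
        "".join(a.seq[c] for c in snp_columns) for a in marker.alleles
    )
    repeat_copies = tuple(
        tuple(
            count_repeat_copies(a.seq[r.start : r.end], r.motif) for r in repeats
        )
        for a in marker.alleles
    )
    indel_present = tuple(
        tuple(
            (a.seq[i.start : i.end].count("-") / i.length) < 0.5 for i in indels
        )
        for a in marker.alleles
    )
    return RecodedAlignment(
        marker=marker.marker,
        alleles=marker.alleles,
        snp_columns=snp_columns,
        snp=snp,
        repeats=tuple(repeats),
        repeat_copies=repeat_copies,
        indels=tuple(indels),
        indel_present=indel_present,
    )


def step_distance(a: RecodedVector, b: RecodedVector) -> int:
    """Mutational steps between two recoded alleles.

    SNP columns: one step per differing column, gap as a fifth state, N
    skipped as missing.  Repeats: |copy difference| steps each (stepwise
    mutation).  Indels: one step per differing presence state.
    """
    if a.schema != b.schema:
        raise SchemaError("recoded vectors come from different character schemas")
    snp_steps = sum(
        1
        for x, y in zip(a.snp, b.snp)
        if x != y and x != "N" and y != "N"
    )
    rep_steps = sum(
        abs(x - y) for x, y in zip(a.repeat_copies, b.repeat_copies)
    )
    indel_steps = sum(
        1 for x, y in zip(a.indel_present, b.indel_present) if x != y
    )
    return snp_steps + rep_steps + indel_steps
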