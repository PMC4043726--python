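"""Reading, writing and pairing of phased sex-linked marker alignments.

Input data are per-marker multiple sequence alignments in FASTA in which each
record is one allele of a diploid individual.  Headers follow the canonical
grammar ``<locality>_<sex:F|M>_<sample>_<tag:a|b|ab>`` (e.g. ``3_M_1_a``);
``ab`` marks a homozygote, where a single record stands for both copies.
Because field datasets label alleles in many dialects, :func:`read_alignment`
accepts an alternative regex with named groups as a mapping hook.

Males carry one X- and one Y-borne copy of a sex-linked marker (gametologs);
females carry two X copies.  The loader never assigns X/Y identity — that is
unknowable from a single individual — it only pairs the two copies.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentLengthError, DataError, LabelError

MALE = "M"
FEMALE = "F"
SEXES = (FEMALE, MALE)

#: The three phylogeographic region labels used throughout the package.
SE_REFUGIA = "SE_refugia"
PANNONIAN = "Pannonian"
NW_EUROPE = "NW_Europe"
REGIONS = (SE_REFUGIA, PANNONIAN, NW_EUROPE)

#: Canonical header grammar; override via ``label_pattern`` for other dialects.
DEFAULT_LABEL_PATTERN = re.compile(
    r"^(?P<locality>\d+)_(?P<sex>[FM])_(?P<sample>\d+)_(?P<tag>ab|a|b)$"
)

VALID_CHARS = frozenset("ACGTN-")


@dataclass(frozen=True)
class AlleleSequence:
    """One aligned allele of one individual at one marker."""

    marker: str
    locality: int
    sex: str
    sample_no: int
    allele_tag: str  # "a", "b" or "ab" (homozygote)
    seq: str

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise DataError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.allele_tag not in ("a", "b", "ab"):
            raise DataError(f"allele tag must be a, b or ab, got {self.allele_tag!r}")
        bad = set(self.seq.upper()) - VALID_CHARS
        if bad:
            raise DataError(
                f"allele {self.label} contains characters outside A,C,G,T,N,-: {sorted(bad)}"
            )
        object.__setattr__(self, "seq", self.seq.upper())

    @property
    def individual(self) -> tuple[int, str, int]:
        """(locality, sex, sample_no) — the individual this allele belongs to."""
        return (self.locality, self.sex, self.sample_no)

    @property
    def label(self) -> str:
        return f"{self.locality}_{self.sex}_{self.sample_no}_{self.allele_tag}"

    @property
    def n_copies(self) -> int:
        """Number of allele copies this record stands for (2 for ``ab``)."""
        return 2 if self.allele_tag == "ab" else 1


@dataclass(frozen=True)
class AlignedMarker:
    """One marker's alignment: equal-length allele sequences with parsed labels."""

    marker: str
    length: int
    alleles: tuple[AlleleSequence, ...]

    def __post_init__(self) -> None:
        for a in self.alleles:
            if len(a.seq) != self.length:
                raise AlignmentLengthError(
                    f"allele {a.label} has length {len(a.seq)}, expected {self.length}"
                )

    def __len__(self) -> int:
        return len(self.alleles)

    def individuals(self) -> list[tuple[int, str, int]]:
        seen: dict[tuple[int, str, int], None] = {}
        for a in self.alleles:
            seen.setdefault(a.individual, None)
        return list(seen)


MISSING = None  # sentinel for a missing second allele


@dataclass(frozen=True)
class IndividualGenotype:
    """An individual's two allele copies (allele2 may be missing) plus region.

    For males the two copies are an X and a Y in unknown order; for females
    both are X.  Homozygotes carry two references to the same record.
    """

    individual: tuple[int, str, int]
    allele1: AlleleSequence
    allele2: AlleleSequence | None
    region: str

    @property
    def sex(self) -> str:
        return self.individual[1]

    @property
    def locality(self) -> int:
        return self.individual[0]

    @property
    def missing(self) -> bool:
        return self.allele2 is MISSING


@dataclass(frozen=True)
class RegionMap:
    """Total mapping from locality id to phylogeographic region label."""

    mapping: Mapping[int, str]

    def region(self, locality: int) -> str:
        try:
            return self.mapping[locality]
        except KeyError:
            raise DataError(
                f"locality {locality} has no region assignment; RegionMap must be total"
            ) from None

    def __contains__(self, locality: int) -> bool:
        return locality in self.mapping

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RegionMap":
        df = pd.read_csv(path, sep="\t", dtype={"locality": int, "region": str})
        if not {"locality", "region"} <= set(df.columns):
            raise DataError("region map TSV needs columns 'locality' and 'region'")
        return cls(dict(zip(df["locality"], df["region"])))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self.mapping.items()), columns=["locality", "region"]
        ).to_csv(path, sep="\t", index=False)


def parse_label(
    header: str,
    marker: str,
    seq: str,
    label_pattern: re.Pattern[str] = DEFAULT_LABEL_PATTERN,
    sex_map: Mapping[str, str] | None = None,
) -> AlleleSequence:
    """Decompose one FASTA header into an :class:`AlleleSequence`.

    ``label_pattern`` must expose named groups ``locality``, ``sex``,
    ``sample`` and ``tag``; ``sex_map`` translates dialect sex codes to F/M.
    """
    m = label_pattern.match(header.strip())
    if m is None:
        raise LabelError(
            f"header {header!r} does not match the allele-label grammar "
            f"{label_pattern.pattern!r}"
        )
    sex = m.group("sex")
    if sex_map is not None:
        sex = sex_map.get(sex, sex)
    return AlleleSequence(
        marker=marker,
        locality=int(m.group("locality")),
        sex=sex,
        sample_no=int(m.group("sample")),
        allele_tag=m.group("tag"),
        seq=seq,
    )


def read_alignment(
    path: str | Path,
    marker: str,
    label_pattern: re.Pattern[str] = DEFAULT_LABEL_PATTERN,
    sex_map: Mapping[str, str] | None = None,
) -> AlignedMarker:
    """Read an aligned FASTA of alleles into an :class:`AlignedMarker`.

    Raises :class:`AlignmentLengthError` on ragged records, :class:`LabelError`
    on unparseable headers or duplicate (individual, tag) pairs.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise DataError(f"{path}: no FASTA records")
    alleles = [
        parse_label(r.id, marker, str(r.seq), label_pattern, sex_map) for r in records
    ]
    lengths = {len(a.seq) for a in alleles}
    if len(lengths) != 1:
        raise AlignmentLengthError(
            f"{path}: records have differing lengths {sorted(lengths)}"
        )
    seen: set[tuple[tuple[int, str, int], str]] = set()
    for a in alleles:
        key = (a.individual, a.allele_tag)
        if key in seen:
            raise LabelError(f"duplicate record for individual/tag {a.label}")
        seen.add(key)
    return AlignedMarker(marker=marker, length=lengths.pop(), alleles=tuple(alleles))


def write_alignment(marker: AlignedMarker, path: str | Path) -> None:
    """Write an :class:`AlignedMarker` back to FASTA under the canonical grammar."""
    recs = [
        SeqRecord(Seq(a.seq), id=a.label, description="") for a in marker.alleles
    ]
    SeqIO.write(recs, str(path), "fasta")


def pair_alleles(
    marker: AlignedMarker, regions: RegionMap
) -> list[IndividualGenotype]:
    """Pair each individual's alleles into a diploid genotype.

    ``ab`` records expand to a homozygote (allele1 is allele2); individuals
    with a single ``a`` or ``b`` record get a MISSING second allele and are
    later excluded from pairwise-difference analyses.
    """
    by_ind: dict[tuple[int, str, int], list[AlleleSequence]] = {}
    for a in marker.alleles:
        by_ind.setdefault(a.individual, []).append(a)

    genotypes: list[IndividualGenotype] = []
    for ind, recs in by_ind.items():
        tags = sorted(r.allele_tag for r in recs)
        region = regions.region(ind[0])
        if tags == ["ab"]:
            (r,) = recs
            genotypes.append(IndividualGenotype(ind, r, r, region))
        elif tags == ["a", "b"]:
            a, b = sorted(recs, key=lambda r: r.allele_tag)
            genotypes.append(IndividualGenotype(ind, a, b, region))
        elif tags in (["a"], ["b"]):
            (r,) = recs
            genotypes.append(IndividualGenotype(ind, r, MISSING, region))
        else:
            raise DataError(
                f"individual {ind} has invalid allele records (tags {tags})"
            )
    return genotypes


def genotype_table(genotypes: Sequence[IndividualGenotype]) -> pd.DataFrame:
    """Tabular view of paired genotypes (one row per individual)."""
    rows = []
    for g in genotypes:
        rows.append(
            {
                "locality": g.locality,
                "sex": g.sex,
                "sample_no": g.individual[2],
                "region": g.region,
                "missing_allele": g.missing,
                "homozygous": (not g.missing) and g.allele1.seq == g.allele2.seq,
            }
        )
    return pd.DataFrame(rows)


def count_variable_sites(
    marker: AlignedMarker, gap_policy: str = "exclude"
) -> tuple[int, int]:
    """Count (variable, parsimony-informative) columns of an alignment.

    A column is variable when ≥2 distinct states are observed, and
    parsimony-informative when ≥2 states are each carried by ≥2 sequences.
    Copy multiplicity of ``ab`` homozygote records is honoured (they count as
    two sequences).
    """
    if gap_policy not in ("exclude", "fifth_state"):
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    if len(marker.alleles) < 2:
        raise DataError("variable-site counts need at least 2 sequences")
    variable = informative = 0
    weights = [a.n_copies for a in marker.alleles]
    for col in range(marker.length):
        chars = [a.seq[col] for a in marker.alleles]
        counts: dict[str, int] = {}
        excluded = False
        for c, w in zip(chars, weights):
            if c == "N":
                continue
            if c == "-" and gap_policy == "exclude":
                excluded = True
                break
            counts[c] = counts.get(c, 0) + w
        if excluded or len(counts) < 2:
            continue
        variable += 1
        if sum(1 for n in counts.values() if n >= 2) >= 2:
            informative += 1
    return variable, informative
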