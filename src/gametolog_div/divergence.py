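"""Within-individual pairwise nucleotide differences (p_d).

For a sex-linked marker, the two copies of a male are necessarily one X and
one Y allele, so the pairwise nucleotide difference between them measures X–Y
gametolog divergence; in a female the same quantity measures X–X diversity.
Comparing the two distributions across sexes and regions is the core signal:
suppressed male recombination inflates male p_d relative to female p_d.

p_d is computed on the raw nucleotide alignment (never on recoded steps) as
an integer count of differing sites.  Two site policies are supported:

``pairwise``  (default) — skip a site only when gapped/N in either of the two
alleles being compared (pairwise deletion);
``complete``  — skip every site gapped/N in *any* allele of the marker
(complete deletion, the classic DnaSP convention).

Individuals whose second allele is missing are excluded, never scored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import MissingAlleleError
from .seq_io import AlignedMarker, IndividualGenotype

POLICIES = ("pairwise", "complete")


@dataclass(frozen=True)
class PdRecord:
    """One individual's within-genotype nucleotide difference count."""

    individual: tuple[int, str, int]
    sex: str
    region: str
    marker: str
    pd: int

    def __post_init__(self) -> None:
        if self.pd < 0:
            raise ValueError("p_d must be non-negative")


def complete_deletion_columns(marker: AlignedMarker) -> frozenset[int]:
    """Columns gapped or ambiguous (N) in at least one allele of the marker."""
    excluded = set()
    for col in range(marker.length):
        for a in marker.alleles:
            if a.seq[col] in "-N":
                excluded.add(col)
                break
    return frozenset(excluded)


def within_individual_pd(
    genotype: IndividualGenotype,
    policy: str = "pairwise",
    excluded_columns: frozenset[int] | None = None,
) -> int:
    """Count differing nucleotide sites between an individual's two alleles.

    Under ``complete`` policy, ``excluded_columns`` (from
    :func:`complete_deletion_columns`) must be supplied.  Raises
    :class:`MissingAlleleError` for genotypes flagged with a missing allele —
    exclusion is a signal, not a number.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown site policy {policy!r}")
    if genotype.missing:
        raise MissingAlleleError(
            f"individual {genotype.individual} has a missing allele and is "
            "excluded from pairwise-distance analyses"
        )
    s1, s2 = genotype.allele1.seq, genotype.allele2.seq
    if policy == "complete":
        if excluded_columns is None:
            raise ValueError("complete-deletion policy needs excluded_columns")
        skip = excluded_columns
    else:
        skip = frozenset()
    count = 0
    for col, (x, y) in enumerate(zip(s1, s2)):
        if col in skip:
            continue
        if x in "-N" or y in "-N":
            continue
        if x != y:
            count += 1
    return count


def compute_pd(
    genotypes: Sequence[IndividualGenotype],
    marker: AlignedMarker,
    policy: str = "pairwise",
) -> tuple[list[PdRecord], list[tuple[int, str, int]]]:
    """p_d for every complete genotype; returns (records, excluded individuals)."""
    excluded_cols = (
        complete_deletion_columns(marker) if policy == "complete" else None
    )
    records: list[PdRecord] = []
    excluded: list[tuple[int, str, int]] = []
    for g in genotypes:
        if g.missing:
            excluded.append(g.individual)
            continue
        records.append(
            PdRecord(
                individual=g.individual,
                sex=g.sex,
                region=g.region,
                marker=marker.marker,
                pd=within_individual_pd(g, policy, excluded_cols),
            )
        )
    return records, excluded


def records_frame(records: Iterable[PdRecord]) -> pd.DataFrame:
    rows = [
        {
            "locality": r.individual[0],
            "sex": r.sex,
            "sample_no": r.individual[2],
            "region": r.region,
            "marker": r.marker,
            "pd": r.pd,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows, columns=["locality", "sex", "sample_no", "region", "marker", "pd"]
    )


def summarize_pd(
    records: Sequence[PdRecord],
    by: Sequence[str] = ("region", "sex"),
    region_groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-group n and mean p_d.

    ``by`` selects grouping columns from {"region", "sex", "marker"};
    ``region_groups`` optionally collapses region labels first (e.g. the
    NW-Europe vs refugial+Pannonian dichotomy).  Requested-but-empty groups
    are simply absent (a warning is emitted when nothing groups at all).
    """
    df = records_frame(records)
    if df.empty:
        warnings.warn("no p_d records to summarise", stacklevel=2)
        return pd.DataFrame(columns=[*by, "n", "mean_pd"])
    if region_groups is not None:
        df["region"] = df["region"].map(lambda r: region_groups.get(r, r))
    bad = set(by) - {"region", "sex", "marker"}
    if bad:
        raise ValueError(f"cannot group by {sorted(bad)}")
    out = (
        df.groupby(list(by), sort=True)["pd"]
        .agg(n="count", mean_pd="mean")
        .reset_index()
    )
    return out
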