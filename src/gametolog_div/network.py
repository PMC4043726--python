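"""Statistical-parsimony haplotype networks.

Identical recoded alleles are collapsed into haplotypes; haplotypes are then
joined by edges weighted in mutational steps, but only up to a *connection
limit*: the largest number of steps at which a connection still has ≥95%
probability (by default) of being non-homoplasious, i.e. of reflecting exactly
that many mutations with no hidden parallel or reverse changes.  Pairs beyond
the limit stay in separate subnetworks.

Probability model
-----------------
For two sequences of ``m`` sites differing at ``j`` of them, the parsimony
probability is computed under the classical pair-coalescent finite-sites
model: coalescence time ``t ~ Exp(1)`` (in units of 2N generations), mutations
at each site Poisson with mean ``θ·t`` where the per-site divergence parameter
θ is estimated from the observed fraction q̂ = j/m via E[q] = θ/(1+2θ).
Parsimony holds when every differing site carries exactly one mutation and no
other site carries any.  The limit is the largest j whose conditional
parsimony probability still reaches the confidence level; with a two-state
site model this is the probability calculation behind the Templeton–Crandall–
Sing 95% criterion.  At least single-step connections are always trusted.

Network construction is a minimum-spanning network with tie retention: pairs
are connected in order of increasing step distance, an edge being added
whenever its endpoints are not already connected at a strictly smaller
distance level — all ties at a level are added, so reticulations are kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.integrate import quad

from .errors import DataError
from .recode import RecodedAlignment, RecodedVector, step_distance
from .seq_io import MALE, FEMALE, RegionMap


@dataclass(frozen=True)
class Carrier:
    """One allele copy carried by one individual, with its metadata."""

    individual: tuple[int, str, int]
    sex: str
    region: str | None
    slot: str  # allele tag of the copy ("a" or "b")


@dataclass(frozen=True)
class Haplotype:
    id: str
    vector: RecodedVector
    multiplicity: int
    carriers: tuple[Carrier, ...]

    def __post_init__(self) -> None:
        if self.multiplicity != len(self.carriers) or self.multiplicity < 1:
            raise DataError("haplotype multiplicity must equal carrier count (≥1)")


@dataclass(frozen=True)
class ParsimonyNetwork:
    haplotypes: tuple[Haplotype, ...]
    edges: tuple[tuple[str, str, int], ...]  # (hap_a, hap_b, steps)
    connection_limit: int
    components: tuple[frozenset[str], ...]

    def graph(self) -> nx.Graph:
        """NetworkX view with node attributes for plotting/export."""
        g = nx.Graph()
        for h in self.haplotypes:
            regions = [c.region for c in h.carriers if c.region is not None]
            g.add_node(
                h.id,
                multiplicity=h.multiplicity,
                n_male=sum(1 for c in h.carriers if c.sex == MALE),
                n_female=sum(1 for c in h.carriers if c.sex == FEMALE),
                region=(
                    max(set(regions), key=regions.count) if regions else "unknown"
                ),
            )
        for a, b, w in self.edges:
            g.add_edge(a, b, steps=w)
        return g


def collapse_haplotypes(
    recoded: RecodedAlignment, regions: RegionMap | None = None
) -> list[Haplotype]:
    """Collapse identical recoded alleles into haplotypes.

    Homozygote ``ab`` records contribute two copies.  Ids ``H_1, H_2, ...``
    are assigned by decreasing multiplicity, ties broken lexicographically by
    recoded vector, so labelling is deterministic.
    """
    if not recoded.alleles:
        raise DataError("cannot collapse an empty alignment")
    groups: dict[tuple, list[Carrier]] = {}
    vec_of: dict[tuple, RecodedVector] = {}
    for i, allele in enumerate(recoded.alleles):
        v = recoded.vector(i)
        key = v.key()
        vec_of.setdefault(key, v)
        region = regions.region(allele.locality) if regions is not None else None
        slots = ("a", "b") if allele.allele_tag == "ab" else (allele.allele_tag,)
        for slot in slots:
            groups.setdefault(key, []).append(
                Carrier(allele.individual, allele.sex, region, slot)
            )
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return [
        Haplotype(
            id=f"H_{i + 1}",
            vector=vec_of[key],
            multiplicity=len(carriers),
            carriers=tuple(carriers),
        )
        for i, (key, carriers) in enumerate(ordered)
    ]


def parsimony_probability(n_steps: int, seq_len: int) -> float:
    """P(connection at ``n_steps`` differences over ``seq_len`` sites is
    non-homoplasious), under the pair-coalescent finite-sites model.

    Numerator: all j differing sites carry exactly one mutation, every other
    site none.  Denominator: probability of observing j differing sites (a
    site differs when it carries an odd number of two-state changes).  Both
    are averaged over t ~ Exp(1); binomial coefficients cancel.
    """
    j, m = n_steps, seq_len
    if not (1 <= j <= m):
        raise ValueError("need 1 <= n_steps <= seq_len")
    q = j / m
    if q >= 0.5:
        return 0.0
    theta = q / (1.0 - 2.0 * q)  # per-site divergence parameter, E[q] = θ/(1+2θ)

    # numerator has closed form: ∫ e^-t (θt)^j e^{-θtm} dt = θ^j j! / (1+θm)^{j+1}
    log_num = (
        j * math.log(theta)
        + math.lgamma(j + 1)
        - (j + 1) * math.log1p(theta * m)
    )

    def log_den_integrand(t: float) -> float:
        if t <= 0.0:
            return -math.inf
        x = math.exp(-2.0 * theta * t)
        if x >= 1.0:
            return -math.inf
        return (
            -t
            + j * (math.log1p(-x) - math.log(2.0))
            + (m - j) * (math.log1p(x) - math.log(2.0))
        )

    # shift by the integrand's maximum (found on a log grid) for stability
    t_grid = np.geomspace(1e-8, 200.0, 600)
    log_vals = np.array([log_den_integrand(t) for t in t_grid])
    shift = float(log_vals.max())
    t_star = float(t_grid[int(log_vals.argmax())])
    # f(t) ≤ e^{-t}, so truncating at T leaves a tail below e^{-T}
    t_max = max(50.0, -shift + 40.0)
    val, _ = quad(
        lambda t: math.exp(log_den_integrand(t) - shift),
        0.0,
        t_max,
        points=[t_star, min(5 * t_star + 1.0, t_max / 2)],
        limit=200,
    )
    log_den = shift + math.log(val)
    p = math.exp(log_num - log_den)
    return min(p, 1.0)


def connection_limit(
    seq_len: int, confidence: float = 0.95, override: int | None = None
) -> int:
    """Largest step count whose parsimony probability still meets ``confidence``.

    Single-step connections are always trusted (limit ≥ 1).  ``override``
    bypasses the computation, e.g. to match an externally chosen limit.
    """
    if override is not None:
        if override < 1:
            raise ValueError("connection limit override must be ≥ 1")
        return override
    if seq_len < 1:
        raise ValueError("seq_len must be ≥ 1")
    if not (0.0 < confidence < 1.0):
        raise ValueError("confidence must be in (0, 1)")
    limit = 1
    j = 1
    while j <= seq_len:
        if parsimony_probability(j, seq_len) < confidence:
            break
        limit = j
        j += 1
    return limit


class _UnionFind:
    def __init__(self, items: Sequence[str]) -> None:
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def build_network(
    haplotypes: Sequence[Haplotype],
    limit: int,
    dist: Callable[[RecodedVector, RecodedVector], int] = step_distance,
) -> ParsimonyNetwork:
    """Minimum-spanning network with tie retention under a connection limit.

    Pairs are processed by increasing step distance; at each distance level,
    every pair not yet connected through strictly smaller levels gains an
    edge (so equally parsimonious alternatives are all kept).  Pairs farther
    apart than ``limit`` never connect; disconnected subnetworks remain.
    """
    ids = [h.id for h in haplotypes]
    if len(set(ids)) != len(ids):
        raise DataError("haplotype ids must be unique")
    pairs: dict[int, list[tuple[str, str]]] = {}
    for i in range(len(haplotypes)):
        for k in range(i + 1, len(haplotypes)):
            d = dist(haplotypes[i].vector, haplotypes[k].vector)
            if 1 <= d <= limit:
                pairs.setdefault(d, []).append((ids[i], ids[k]))

    uf = _UnionFind(ids)
    edges: list[tuple[str, str, int]] = []
    for level in sorted(pairs):
        connected_before = {
            (a, b): uf.find(a) == uf.find(b) for a, b in pairs[level]
        }
        added = []
        for a, b in pairs[level]:
            if not connected_before[(a, b)]:
                edges.append((a, b, level))
                added.append((a, b))
        for a, b in added:
            uf.union(a, b)

    comp: dict[str, set[str]] = {}
    for hid in ids:
        comp.setdefault(uf.find(hid), set()).add(hid)
    components = tuple(frozenset(c) for c in comp.values())
    return ParsimonyNetwork(
        haplotypes=tuple(haplotypes),
        edges=tuple(edges),
        connection_limit=limit,
        components=components,
    )


def male_specific_haplotype(
    haplotypes: Sequence[Haplotype],
    region: str,
    min_male_fraction: float = 0.5,
) -> Haplotype | None:
    """Find a dominant male-specific haplotype in one region, if any.

    Returns the first haplotype that is carried by more than
    ``min_male_fraction`` of the region's sampled males — exactly one copy
    each, as expected for a fixed Y gametolog — and by none of the region's
    females.  This is the fixed-Y signature of a postglacial expansion
    population.
    """
    males_in_region: set = set()
    for h in haplotypes:
        for c in h.carriers:
            if c.region == region and c.sex == MALE:
                males_in_region.add(c.individual)
    if not males_in_region:
        return None
    for h in haplotypes:
        per_male: dict = {}
        n_female = 0
        for c in h.carriers:
            if c.region != region:
                continue
            if c.sex == MALE:
                per_male[c.individual] = per_male.get(c.individual, 0) + 1
            else:
                n_female += 1
        if (
            n_female == 0
            and len(per_male) > min_male_fraction * len(males_in_region)
            and all(v == 1 for v in per_male.values())
        ):
            return h
    return None


def export_network(
    net: ParsimonyNetwork, path: str | Path, fmt: str = "tsv"
) -> list[Path]:
    """Write the network to disk.

    ``tsv`` writes an edge list (hap_a, hap_b, steps) at ``path`` plus a node
    attribute table next to it (``<stem>.nodes.tsv``); ``gml`` writes a GML
    graph with the same node attributes.  Returns the paths written.
    """
    path = Path(path)
    if fmt == "tsv":
        pd.DataFrame(
            list(net.edges), columns=["hap_a", "hap_b", "steps"]
        ).to_csv(path, sep="\t", index=False)
        g = net.graph()
        nodes = pd.DataFrame(
            [{"haplotype": n, **attrs} for n, attrs in g.nodes(data=True)]
        )
        nodes_path = path.with_suffix(".nodes.tsv")
        nodes.to_csv(nodes_path, sep="\t", index=False)
        return [path, nodes_path]
    if fmt == "gml":
        nx.write_gml(net.graph(), str(path))
        return [path]
    raise ValueError(f"unknown export format {fmt!r} (use 'tsv' or 'gml')")


def read_edge_list(path: str | Path) -> set[tuple[str, str, int]]:
    """Read an exported edge-list TSV back as a canonical edge set."""
    df = pd.read_csv(path, sep="\t")
    return {
        (min(a, b), max(a, b), int(s))
        for a, b, s in zip(df["hap_a"], df["hap_b"], df["steps"])
    }
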