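"""Forward simulator for sex-linked gametolog alignments.

The generator produces exactly the data structure the analysis consumes:
per-marker FASTA alignments of phased diploid alleles with the canonical
``<locality>_<sex>_<sample>_<tag>`` labels, a locality→region table, and
ground truth (which allele copy is X vs Y, and every male X–Y recombination
event).

Model
-----
An XY system with a male-heterogametic marker: females carry two X copies,
males an X and a Y.  Inheritance is forward-in-time over discrete
generations.  A daughter receives one recombinant of her mother's two X's
and her father's X; a son receives the maternal X and his father's Y.  A
male meiosis may experience a single X–Y crossover at a uniform point, in
which case the transmitted copy is a random one of the two recombinant
products (the marker's position relative to the sex-determining locus is
left unspecified).  Refugial and Pannonian demes recombine recurrently at
``refugial_recomb_prob`` per male meiosis, keeping their X and Y pools
mixed; the expansion (NW) lineage recombines at ``male_recomb_prob`` (r)
from its founding, so ``t_split`` is the time since X–Y recombination
arrest there when r = 0.  r = 0 lets X–Y divergence accumulate in NW
males; r = 0.5 mixes the gametolog pools everywhere.

Mutation has three components, matching the marker anatomy the analysis
recodes: per-site nucleotide substitution on the backbone; a
microsatellite-like repeat tract under the stepwise mutation model (±1 copy
per event, reflecting at zero); and a rare large indel segment whose
presence/absence toggles.

Demography emulates a refugium-to-expansion history: one refugial deme at
mutation–drift equilibrium-ish diversity after a burn-in, a Pannonian deme
founded from it, and a NW-European deme founded from the Pannonian one
through a ``bottleneck`` of very few individuals ``t_split`` generations
before the present, then doubling each generation to its cap.  With little
or no male recombination, the bottleneck fixes a single Y haplotype in the
NW deme while female X diversity collapses — the single-male-haplotype
pattern the analysis is designed to detect.

Sizes and rates are desk-scale (tens of individuals, hundreds of
generations, mutation rescaled accordingly), chosen so that within-individual
differences fall in the few-per-kilobase range typical of intron data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .seq_io import (
    FEMALE,
    MALE,
    NW_EUROPE,
    PANNONIAN,
    SE_REFUGIA,
    AlignedMarker,
    AlleleSequence,
    RegionMap,
    write_alignment,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Paper-flavoured locality numbering: refugia low, Pannonian middle, NW 20+.
DEFAULT_LOCALITIES: Mapping[str, tuple[int, ...]] = {
    SE_REFUGIA: (1, 3, 7, 9),
    PANNONIAN: (15, 18, 19),
    NW_EUROPE: (20, 24, 29),
}

DEFAULT_SAMPLES: Mapping[tuple[str, str], int] = {
    (SE_REFUGIA, MALE): 11,
    (SE_REFUGIA, FEMALE): 9,
    (PANNONIAN, MALE): 8,
    (PANNONIAN, FEMALE): 7,
    (NW_EUROPE, MALE): 11,
    (NW_EUROPE, FEMALE): 8,
}


@dataclass(frozen=True)
class SimParams:
    """Simulator configuration; defaults define the standard study conditions."""

    marker: str = "markerA"
    seq_len: int = 992
    sub_rate: float = 5e-6  # substitutions / site / lineage / generation
    repeat_motif: str = "AC"
    repeat_initial: int = 8
    repeat_rate: float = 1e-3  # stepwise ±1 events / lineage / generation
    indel_rate: float = 1e-4  # presence toggles / lineage / generation
    indel_size_range: tuple[int, int] = (30, 60)
    male_recomb_prob: float = 1e-3  # r: XY recombination in the NW lineage
    refugial_recomb_prob: float = 0.2  # recurrent XY recombination in refugia
    t_split: int = 100  # generations since the NW founding (= arrest, if r=0)
    t_pannonian: int | None = None  # defaults to t_split + 60
    burn_in: int = 300  # refugial-only generations before any founding
    bottleneck: int = 2  # founder count of each NW expansion step (a pair)
    serial_interval: int = 8  # generations between serial NW bottlenecks
    n_pannonian_founders: int = 8
    deme_size: Mapping[str, int] = field(
        default_factory=lambda: {SE_REFUGIA: 200, PANNONIAN: 80, NW_EUROPE: 40}
    )
    n_sample: Mapping[tuple[str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_SAMPLES)
    )
    localities: Mapping[str, tuple[int, ...]] = field(
        default_factory=lambda: dict(DEFAULT_LOCALITIES)
    )
    repeat_pos_frac: float = 0.3  # backbone position of the repeat tract
    indel_pos_frac: float = 0.7  # backbone position of the indel segment
    seed: int | None = None

    def validate(self) -> None:
        if not (0.0 <= self.male_recomb_prob <= 0.5):
            raise ValueError("male_recomb_prob must be in [0, 0.5]")
        if not (0.0 <= self.refugial_recomb_prob <= 0.5):
            raise ValueError("refugial_recomb_prob must be in [0, 0.5]")
        for name in ("sub_rate", "repeat_rate", "indel_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be ≥ 0")
        if self.bottleneck < 2 or self.n_pannonian_founders < 2:
            # a dioecious founding group needs at least one of each sex
            raise ValueError("founder counts must be ≥ 2")
        if self.seq_len < 10:
            raise ValueError("seq_len must be ≥ 10")
        if self.repeat_initial < 0:
            raise ValueError("repeat_initial must be ≥ 0")
        if self.t_split < 1 or self.burn_in < 1:
            raise ValueError("t_split and burn_in must be ≥ 1")
        if self.serial_interval < 2:
            raise ValueError("serial_interval must be ≥ 2")
        tp = self.t_pannonian if self.t_pannonian is not None else self.t_split + 60
        if tp < self.t_split:
            raise ValueError("t_pannonian must be ≥ t_split")
        for (region, sex), n in self.n_sample.items():
            cap = self.deme_size[region]
            if n > cap // 2:
                raise ValueError(
                    f"cannot sample {n} {sex} from {region} (deme size {cap}, "
                    f"{cap // 2} per sex)"
                )


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one simulated marker."""

    #: (individual, slot tag) → "X" or "Y"
    chromosome: Mapping[tuple[tuple[int, str, int], str], str]
    #: (generation index, deme, crossover column) per male X–Y exchange
    recomb_events: tuple[tuple[int, str, int], ...]
    #: (individual, slot tag) → founder haplotype id (head-segment ancestry)
    founder: Mapping[tuple[tuple[int, str, int], str], int]


class _Deme:
    """Vectorised deme state: one row per individual, slot1 = maternal X,
    slot2 = paternal X (females) or Y (males)."""

    def __init__(
        self,
        is_male: np.ndarray,
        seq: tuple[np.ndarray, np.ndarray],
        rep: tuple[np.ndarray, np.ndarray],
        ind: tuple[np.ndarray, np.ndarray],
        fdr: tuple[np.ndarray, np.ndarray],
    ) -> None:
        self.is_male = is_male
        self.seq = seq
        self.rep = rep
        self.ind = ind
        self.fdr = fdr

    @property
    def n(self) -> int:
        return len(self.is_male)


def _balanced_sexes(n: int, rng: np.random.Generator) -> np.ndarray:
    """Shuffled half/half sex assignment so tiny demes never lose one sex."""
    s = np.zeros(n, dtype=bool)
    s[: n // 2] = True
    if n % 2:
        s[n // 2] = rng.random() < 0.5
    rng.shuffle(s)
    return s


def _splice(
    head: np.ndarray, tail: np.ndarray, cuts: np.ndarray
) -> np.ndarray:
    """Row-wise single-crossover splice: head[:, :cut] + tail[:, cut:]."""
    cols = np.arange(head.shape[1])
    mask = cols[None, :] < cuts[:, None]
    return np.where(mask, head, tail)


def _char_side(cuts: np.ndarray, pos: int) -> np.ndarray:
    """True where a non-sequence character (at backbone pos) comes from head."""
    return pos < cuts


class _Simulator:
    def __init__(self, params: SimParams, rng: np.random.Generator) -> None:
        params.validate()
        self.p = params
        self.rng = rng
        L = params.seq_len
        self.repeat_pos = int(L * params.repeat_pos_frac)
        self.indel_pos = int(L * params.indel_pos_frac)
        self.indel_size = int(
            rng.integers(params.indel_size_range[0], params.indel_size_range[1] + 1)
        )
        self.indel_segment = _BASES[rng.integers(0, 4, self.indel_size)]
        self.recomb_events: list[tuple[int, str, int]] = []
        self.gen = 0
        self._next_founder = 0

    def _founder_deme(self, n: int) -> _Deme:
        """All founders share one ancestral haplotype (divergence then accrues)."""
        L = self.p.seq_len
        anc = _BASES[self.rng.integers(0, 4, L)]
        seq = (np.tile(anc, (n, 1)), np.tile(anc, (n, 1)))
        rep = tuple(
            np.full(n, self.p.repeat_initial, dtype=np.int64) for _ in range(2)
        )
        ind = tuple(np.ones(n, dtype=bool) for _ in range(2))
        ids = np.arange(self._next_founder, self._next_founder + 2 * n)
        self._next_founder += 2 * n
        fdr = (ids[:n].copy(), ids[n:].copy())
        return _Deme(_balanced_sexes(n, self.rng), seq, rep, ind, fdr)

    def _substitute(self, seq: np.ndarray) -> None:
        """Per-gamete Poisson substitutions, each to a uniformly different base."""
        p, rng = self.p, self.rng
        n, L = seq.shape
        if p.sub_rate == 0:
            return
        counts = rng.poisson(p.sub_rate * L, n)
        for i in np.flatnonzero(counts):
            sites = rng.integers(0, L, counts[i])
            old = seq[i, sites]
            # map base byte -> index, add 1..3 mod 4, map back
            idx = np.searchsorted(np.sort(_BASES), old)
            order = np.argsort(_BASES)
            base_idx = order[idx]
            new_idx = (base_idx + rng.integers(1, 4, counts[i])) % 4
            seq[i, sites] = _BASES[new_idx]

    def _offspring(self, deme: _Deme, n_next: int, deme_name: str) -> _Deme:
        p, rng = self.p, self.rng
        L = p.seq_len
        mothers_pool = np.flatnonzero(~deme.is_male)
        fathers_pool = np.flatnonzero(deme.is_male)
        mothers = rng.choice(mothers_pool, n_next)
        fathers = rng.choice(fathers_pool, n_next)
        child_male = _balanced_sexes(n_next, rng)

        # maternal gamete: free recombination between the mother's two X's
        m1, m2 = deme.seq[0][mothers], deme.seq[1][mothers]
        r1, r2 = deme.rep[0][mothers], deme.rep[1][mothers]
        i1, i2 = deme.ind[0][mothers], deme.ind[1][mothers]
        f1, f2 = deme.fdr[0][mothers], deme.fdr[1][mothers]
        swap = rng.random(n_next) < 0.5
        mh = np.where(swap[:, None], m2, m1)
        mt = np.where(swap[:, None], m1, m2)
        rh, rt = np.where(swap, r2, r1), np.where(swap, r1, r2)
        ih, it = np.where(swap, i2, i1), np.where(swap, i1, i2)
        fh, ft = np.where(swap, f2, f1), np.where(swap, f1, f2)
        cuts = rng.integers(1, L, n_next)
        egg_seq = _splice(mh, mt, cuts)
        rep_side = _char_side(cuts, self.repeat_pos)
        ind_side = _char_side(cuts, self.indel_pos)
        egg_rep = np.where(rep_side, rh, rt)
        egg_ind = np.where(ind_side, ih, it)
        egg_fdr = fh.copy()  # head-segment ancestry

        # paternal gamete: X to daughters, Y to sons; occasional X-Y crossover
        fx, fy = deme.seq[0][fathers], deme.seq[1][fathers]
        frx, fry = deme.rep[0][fathers], deme.rep[1][fathers]
        fix_, fiy = deme.ind[0][fathers], deme.ind[1][fathers]
        ffx, ffy = deme.fdr[0][fathers], deme.fdr[1][fathers]
        sperm_seq = np.where(child_male[:, None], fy, fx)
        sperm_rep = np.where(child_male, fry, frx)
        sperm_ind = np.where(child_male, fiy, fix_)
        sperm_fdr = np.where(child_male, ffy, ffx)
        recomb_prob = (
            p.male_recomb_prob
            if deme_name == NW_EUROPE
            else p.refugial_recomb_prob
        )
        if recomb_prob > 0:
            rec = rng.random(n_next) < recomb_prob
            for i in np.flatnonzero(rec):
                cut = int(rng.integers(1, L))
                # marker position relative to the sex-determining locus is
                # unspecified, so the transmitted recombinant product is
                # chosen at random between the two crossover products
                y_head = bool(rng.random() < 0.5)
                head_seq, tail_seq = (
                    (fy[i], fx[i]) if y_head else (fx[i], fy[i])
                )
                sperm_seq[i] = np.where(np.arange(L) < cut, head_seq, tail_seq)
                head = (fry[i], fiy[i]) if y_head else (frx[i], fix_[i])
                tail = (frx[i], fix_[i]) if y_head else (fry[i], fiy[i])
                sperm_rep[i] = head[0] if self.repeat_pos < cut else tail[0]
                sperm_ind[i] = head[1] if self.indel_pos < cut else tail[1]
                self.recomb_events.append((self.gen, deme_name, cut))

        self._substitute(egg_seq)
        self._substitute(sperm_seq)
        for rep_arr, ind_arr in ((egg_rep, egg_ind), (sperm_rep, sperm_ind)):
            if p.repeat_rate > 0:
                hit = rng.random(n_next) < p.repeat_rate
                step = rng.choice(np.array([-1, 1]), size=int(hit.sum()))
                rep_arr[hit] = np.abs(rep_arr[hit] + step)
            if p.indel_rate > 0:
                flip = rng.random(n_next) < p.indel_rate
                ind_arr[flip] = ~ind_arr[flip]

        return _Deme(
            child_male,
            (egg_seq, sperm_seq),
            (egg_rep, sperm_rep),
            (egg_ind, sperm_ind),
            (egg_fdr, sperm_fdr),
        )

    def _found(self, source: _Deme, n_founders: int) -> _Deme:
        # a single-sex founding group cannot found a population: resample
        while True:
            idx = self.rng.choice(source.n, n_founders, replace=False)
            sexes = source.is_male[idx].copy()
            if sexes.any() and not sexes.all():
                break
        return _Deme(
            sexes,
            tuple(s[idx].copy() for s in source.seq),
            tuple(r[idx].copy() for r in source.rep),
            tuple(i[idx].copy() for i in source.ind),
            tuple(f[idx].copy() for f in source.fdr),
        )

    def run(self) -> dict[str, _Deme]:
        p = self.p
        t_pann = p.t_pannonian if p.t_pannonian is not None else p.t_split + 60
        total = p.burn_in + t_pann
        g_pann = p.burn_in
        g_nw = total - p.t_split
        demes: dict[str, _Deme] = {
            SE_REFUGIA: self._founder_deme(p.deme_size[SE_REFUGIA])
        }
        # the NW deme is *serially* bottlenecked: the sampled deme stands for
        # the expansion front, re-founded by a few individuals every
        # serial_interval generations.  The final recovery window is only as
        # long as regrowth to the sampling size requires — range-edge
        # populations are sampled soon after their founding
        doublings = int(np.ceil(np.log2(p.deme_size[NW_EUROPE] / p.bottleneck)))
        min_recovery = doublings + 1
        for self.gen in range(1, total + 1):
            if self.gen == g_pann:
                demes[PANNONIAN] = self._found(
                    demes[SE_REFUGIA], p.n_pannonian_founders
                )
            if self.gen == g_nw:
                demes[NW_EUROPE] = self._found(demes[PANNONIAN], p.bottleneck)
            elif (
                NW_EUROPE in demes
                and (self.gen - g_nw) % p.serial_interval == 0
                and total - self.gen >= min_recovery
            ):
                demes[NW_EUROPE] = self._found(demes[NW_EUROPE], p.bottleneck)
            new = {}
            for name, deme in demes.items():
                cap = p.deme_size[name]
                n_next = min(cap, max(2, deme.n * 2))
                new[name] = self._offspring(deme, n_next, name)
            demes = new
        return demes


def _render_allele(
    sim: _Simulator, seq_row: np.ndarray, copies: int, present: bool, max_copies: int
) -> str:
    """Backbone + repeat tract + indel segment as one aligned string."""
    p = sim.p
    motif = p.repeat_motif
    backbone = seq_row.tobytes().decode("ascii")
    tract = motif * copies + "-" * (len(motif) * (max_copies - copies))
    segment = (
        sim.indel_segment.tobytes().decode("ascii")
        if present
        else "-" * sim.indel_size
    )
    a, b = sim.repeat_pos, sim.indel_pos
    return backbone[:a] + tract + backbone[a:b] + segment + backbone[b:]


def simulate_marker(
    params: SimParams, seed: int | None = None
) -> tuple[AlignedMarker, SimTruth]:
    """Run one forward simulation and emit an alignment plus ground truth.

    Deterministic for a fixed seed (``seed`` argument wins over
    ``params.seed``).  Homozygous individuals (both characters and sequence
    identical) are emitted as single ``ab`` records, as in real phased data.
    """
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    sim = _Simulator(params, rng)
    demes = sim.run()

    alleles: list[AlleleSequence] = []
    chromosome: dict[tuple[tuple[int, str, int], str], str] = {}
    founder: dict[tuple[tuple[int, str, int], str], int] = {}

    # one shared alignment schema: pad repeat tract to the sample-wide maximum
    sampled: list[tuple[str, str, int]] = []  # (region, sexcode, row index)
    for (region, sexcode), n in sorted(params.n_sample.items()):
        deme = demes[region]
        pool = np.flatnonzero(deme.is_male == (sexcode == MALE))
        if len(pool) < n:
            raise RuntimeError(
                f"deme {region} has only {len(pool)} {sexcode} individuals; "
                f"requested {n}"
            )
        for row in rng.choice(pool, n, replace=False):
            sampled.append((region, sexcode, int(row)))
    max_copies = max(
        (
            int(demes[region].rep[slot][row])
            for region, _, row in sampled
            for slot in (0, 1)
        ),
        default=params.repeat_initial,
    )

    region_cursor: dict[str, int] = {}
    sample_counter: dict[tuple[int, str], int] = {}
    for region, sexcode, row in sampled:
        deme = demes[region]
        locs = params.localities[region]
        cursor = region_cursor.get(region, 0)
        loc = locs[cursor % len(locs)]
        region_cursor[region] = cursor + 1
        sample_no = sample_counter.get((loc, sexcode), 0) + 1
        sample_counter[(loc, sexcode)] = sample_no
        individual = (loc, sexcode, sample_no)

        rendered = []
        for slot in (0, 1):
            rendered.append(
                _render_allele(
                    sim,
                    deme.seq[slot][row],
                    int(deme.rep[slot][row]),
                    bool(deme.ind[slot][row]),
                    max_copies,
                )
            )
        chroms = ("X", "Y") if sexcode == MALE else ("X", "X")
        if rendered[0] == rendered[1]:
            alleles.append(
                AlleleSequence(
                    params.marker, loc, sexcode, sample_no, "ab", rendered[0]
                )
            )
            for tag, slot in (("a", 0), ("b", 1)):
                chromosome[(individual, tag)] = chroms[slot]
                founder[(individual, tag)] = int(deme.fdr[slot][row])
        else:
            order = (0, 1) if rng.random() < 0.5 else (1, 0)
            for tag, slot in zip(("a", "b"), order):
                alleles.append(
                    AlleleSequence(
                        params.marker, loc, sexcode, sample_no, tag, rendered[slot]
                    )
                )
                chromosome[(individual, tag)] = chroms[slot]
                founder[(individual, tag)] = int(deme.fdr[slot][row])

    length = len(alleles[0].seq)
    marker = AlignedMarker(params.marker, length, tuple(alleles))
    truth = SimTruth(
        chromosome=chromosome,
        recomb_events=tuple(sim.recomb_events),
        founder=founder,
    )
    return marker, truth


def study_scale_params() -> list[SimParams]:
    """Three-marker study at the sampling scale of the motivating field study.

    markerA is long (992 bp) and sampled in every region (n = 54 individuals),
    markerB intermediate (504 bp, n = 33), markerC short (411 bp, n = 16) —
    the sample-size ladder at which the sex and sex × region tests are run.
    """
    n_b = {
        (SE_REFUGIA, MALE): 7,
        (SE_REFUGIA, FEMALE): 6,
        (PANNONIAN, MALE): 5,
        (PANNONIAN, FEMALE): 4,
        (NW_EUROPE, MALE): 6,
        (NW_EUROPE, FEMALE): 5,
    }
    n_c = {
        (SE_REFUGIA, MALE): 3,
        (SE_REFUGIA, FEMALE): 3,
        (PANNONIAN, MALE): 2,
        (PANNONIAN, FEMALE): 2,
        (NW_EUROPE, MALE): 3,
        (NW_EUROPE, FEMALE): 3,
    }
    return [
        SimParams(marker="markerA", seq_len=992),
        SimParams(marker="markerB", seq_len=504, n_sample=n_b),
        SimParams(marker="markerC", seq_len=411, n_sample=n_c),
    ]


def region_map(params: SimParams) -> RegionMap:
    return RegionMap(
        {
            loc: region
            for region, locs in params.localities.items()
            for loc in locs
        }
    )


@dataclass(frozen=True)
class StudyBundle:
    markers: Mapping[str, AlignedMarker]
    truths: Mapping[str, SimTruth]
    regions: RegionMap
    paths: tuple[Path, ...]


def simulate_study(
    params_per_marker: Sequence[SimParams],
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> StudyBundle:
    """Simulate several markers and (optionally) write a ready-to-load dataset.

    Each marker runs as an independent forward simulation (sub-seeded from
    ``seed``) over the shared locality→region scheme.  When ``out_dir`` is
    given, writes ``<marker>.fasta`` per marker, one ``regions.tsv`` and one
    ``truth_<marker>.tsv``.
    """
    names = [p.marker for p in params_per_marker]
    if len(set(names)) != len(names):
        raise ValueError(f"clashing marker names: {names}")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(params_per_marker))
    markers: dict[str, AlignedMarker] = {}
    truths: dict[str, SimTruth] = {}
    for p, child in zip(params_per_marker, children):
        sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        marker, truth = simulate_marker(p, seed=sub_seed)
        markers[p.marker] = marker
        truths[p.marker] = truth

    regions = region_map(params_per_marker[0])
    paths: list[Path] = []
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, marker in markers.items():
            fp = out / f"{name}.fasta"
            write_alignment(marker, fp)
            paths.append(fp)
            tp = out / f"truth_{name}.tsv"
            rows = [
                {
                    "locality": ind[0],
                    "sex": ind[1],
                    "sample_no": ind[2],
                    "tag": tag,
                    "chromosome": chrom,
                    "founder": truths[name].founder[(ind, tag)],
                }
                for (ind, tag), chrom in sorted(truths[name].chromosome.items())
            ]
            pd.DataFrame(rows).to_csv(tp, sep="\t", index=False)
            paths.append(tp)
        rp = out / "regions.tsv"
        regions.to_tsv(rp)
        paths.append(rp)
    return StudyBundle(
        markers=markers, truths=truths, regions=regions, paths=tuple(paths)
    )
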