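"""Permutation ANOVA of within-individual nucleotide differences.

p_d counts are non-negative, discrete and often strongly skewed, so classical
F-distribution p-values are unreliable; the F statistic is kept as the test
statistic but its null distribution is built by permutation.  Two models are
used: a one-way ANOVA on sex (X–Y vs X–X divergence pooled over regions) and
a two-way sex × region ANOVA with region collapsed to a two-level factor
(recent postglacial NW Europe vs the refugial + Pannonian rest), where the
sex × region interaction is the signature of region-specific X–Y
differentiation.

Sums of squares are sequential (Type I, default order sex → region →
interaction, the convention of R's ``aov``/``anova.lm``); Type II is
available for unbalanced designs.  The default permutation scheme shuffles
the response vector freely across observations (Manly); Freedman–Lane
residual permutation is available as an alternative.  p-values carry the +1
finite-sample correction, p = (1 + #{F* ≥ F}) / (1 + n_perm), so they are
never exactly zero.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .divergence import PdRecord
from .errors import DataError
from .seq_io import NW_EUROPE, PANNONIAN, SE_REFUGIA

#: The two-level geography factor used in the two-way model.
DEFAULT_REGION_GROUPS: Mapping[str, str] = {
    NW_EUROPE: "NW",
    SE_REFUGIA: "SE_Pann",
    PANNONIAN: "SE_Pann",
}

MODELS = ("one_way_sex", "two_way_full")
DEFAULT_SS_ORDER = ("sex", "region", "sex:region")


@dataclass(frozen=True)
class AnovaTerm:
    term: str
    df_num: int
    df_den: int
    F: float
    ss: float


@dataclass(frozen=True)
class AnovaResult:
    term: str
    df_num: int
    df_den: int
    F: float
    p_perm: float
    n_perm: int
    seed: int | None
    scheme: str


def design_table(
    records: Sequence[PdRecord],
    region_groups: Mapping[str, str] = DEFAULT_REGION_GROUPS,
) -> pd.DataFrame:
    """Observation table (pd, sex, region) with region collapsed to two levels."""
    if not records:
        raise DataError("no observations for ANOVA")
    return pd.DataFrame(
        {
            "pd": [r.pd for r in records],
            "sex": [r.sex for r in records],
            "region": [region_groups.get(r.region, r.region) for r in records],
        }
    )


def _dummies(values: pd.Series) -> np.ndarray:
    """Treatment-coded (drop-first) dummy matrix for one factor."""
    levels = sorted(values.unique())
    if len(levels) < 2:
        raise DataError(
            f"factor with a single level {levels!r}: need ≥2 observations per "
            "marginal level"
        )
    return np.column_stack(
        [(values == lev).to_numpy(float) for lev in levels[1:]]
    )


def _blocks(
    design: pd.DataFrame, model: str, ss_order: Sequence[str] = DEFAULT_SS_ORDER
) -> list[tuple[str, np.ndarray]]:
    """Ordered model term blocks (term name, design-matrix columns)."""
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    sex = _dummies(design["sex"])
    if model == "one_way_sex":
        return [("sex", sex)]
    region = _dummies(design["region"])
    # every cell of the two-way layout must be observed
    cells = design.groupby(["sex", "region"], sort=True).size()
    n_sex = design["sex"].nunique()
    n_reg = design["region"].nunique()
    if len(cells) < n_sex * n_reg:
        observed = set(cells.index)
        missing = [
            (s, r)
            for s in sorted(design["sex"].unique())
            for r in sorted(design["region"].unique())
            if (s, r) not in observed
        ]
        raise DataError(f"empty cell(s) in two-way design: {missing}")
    inter = np.column_stack(
        [
            sex[:, i] * region[:, k]
            for i in range(sex.shape[1])
            for k in range(region.shape[1])
        ]
    )
    by_name = {"sex": sex, "region": region, "sex:region": inter}
    if set(ss_order) != set(by_name):
        raise ValueError(
            f"ss_order must be a permutation of {sorted(by_name)}, got {ss_order}"
        )
    if ss_order.index("sex:region") != len(ss_order) - 1:
        raise ValueError("the interaction must come after both main effects")
    return [(name, by_name[name]) for name in ss_order]


class _SequentialSS:
    """Sequential (Type I) sum-of-squares engine over a fixed design.

    A single QR factorisation of [1 | block_1 | ... | block_k] yields an
    orthonormal basis whose leading columns span each cumulative model, so a
    term's SS is the squared projection of y onto its own Q columns — and for
    permutation tests the SS of thousands of permuted responses is one matrix
    product.
    """

    def __init__(self, blocks: list[tuple[str, np.ndarray]], n: int) -> None:
        self.n = n
        X = np.column_stack([np.ones((n, 1))] + [b for _, b in blocks])
        q, r = np.linalg.qr(X)
        if np.abs(np.diag(r)).min() < 1e-10 * max(1.0, np.abs(r).max()):
            raise DataError("design matrix is rank deficient")
        self.Q = q
        self.terms = [name for name, _ in blocks]
        self.slices: list[slice] = []
        start = 1  # column 0 is the intercept
        for _, b in blocks:
            self.slices.append(slice(start, start + b.shape[1]))
            start += b.shape[1]
        self.df_num = [s.stop - s.start for s in self.slices]
        self.df_den = n - start
        if self.df_den < 1:
            raise DataError("no residual degrees of freedom")

    def f_stats(self, Y: np.ndarray) -> np.ndarray:
        """F statistics, shape (n_terms, n_columns_of_Y)."""
        Y = np.atleast_2d(Y.T).T  # (n, k)
        Z = self.Q.T @ Y  # (p, k)
        yy = (Y * Y).sum(axis=0)
        sse = np.maximum(yy - (Z * Z).sum(axis=0), 0.0)
        mse = sse / self.df_den
        tol = 1e-12 * np.maximum(yy, 1.0)  # float-noise floor for SS
        out = np.empty((len(self.terms), Y.shape[1]))
        with np.errstate(divide="ignore", invalid="ignore"):
            for i, sl in enumerate(self.slices):
                ss = (Z[sl] * Z[sl]).sum(axis=0)
                out[i] = np.where(
                    mse > tol,
                    ss / self.df_num[i] / np.where(mse > tol, mse, 1.0),
                    np.where(ss > tol, np.inf, 0.0),
                )
        return out

    def fitted_and_residuals(
        self, y: np.ndarray, drop_term: str
    ) -> tuple[np.ndarray, np.ndarray]:
        """Reduced-model fit/residuals with one term's columns removed."""
        keep = np.r_[
            np.array([0]),
            np.concatenate(
                [
                    np.arange(sl.start, sl.stop)
                    for t, sl in zip(self.terms, self.slices)
                    if t != drop_term
                ]
            ).astype(int)
            if len(self.terms) > 1
            else np.array([], dtype=int),
        ]
        Qr = self.Q[:, keep]
        fitted = Qr @ (Qr.T @ y)
        return fitted, y - fitted


def anova_f(
    design: pd.DataFrame,
    model: str = "one_way_sex",
    ss_order: Sequence[str] = DEFAULT_SS_ORDER,
    ss_type: int = 1,
) -> list[AnovaTerm]:
    """F statistics from sums of squares for the chosen model.

    Type I (sequential, default) attributes SS in ``ss_order``; Type II gives
    each main effect its SS adjusted for the other main effect (interaction
    unchanged).  Denominators always use the full-model residual mean square.
    """
    y = design["pd"].to_numpy(float)
    blocks = _blocks(design, model, ss_order if model == "two_way_full" else DEFAULT_SS_ORDER)
    engine = _SequentialSS(blocks, len(y))
    f_seq = engine.f_stats(y)[:, 0]
    terms: list[AnovaTerm] = []
    if ss_type == 1 or model == "one_way_sex":
        Z = engine.Q.T @ y
        for i, name in enumerate(engine.terms):
            ss = float((Z[engine.slices[i]] ** 2).sum())
            terms.append(
                AnovaTerm(name, engine.df_num[i], engine.df_den, float(f_seq[i]), ss)
            )
        return terms
    if ss_type != 2:
        raise ValueError("ss_type must be 1 or 2")
    # Type II: each main effect last among main effects; interaction as in Type I
    sse = float(y @ y - (engine.Q.T @ y) @ (engine.Q.T @ y))
    mse = sse / engine.df_den
    for name in [t for t, _ in blocks]:
        if name == "sex:region":
            order = DEFAULT_SS_ORDER
        else:
            other = "region" if name == "sex" else "sex"
            order = (other, name, "sex:region")
        eng = _SequentialSS(_blocks(design, model, order), len(y))
        Z = eng.Q.T @ y
        i = eng.terms.index(name)
        ss = float((Z[eng.slices[i]] ** 2).sum())
        df = eng.df_num[i]
        terms.append(AnovaTerm(name, df, eng.df_den, ss / df / mse, ss))
    return terms


def permutation_p(
    design: pd.DataFrame,
    model: str = "one_way_sex",
    n_perm: int = 10_000,
    seed: int | None = None,
    scheme: str = "manly",
    ss_order: Sequence[str] = DEFAULT_SS_ORDER,
) -> list[AnovaResult]:
    """Permutation p-values for every term of the model.

    ``manly`` permutes the raw response across all observations and recomputes
    the full F table per replicate; ``freedman_lane`` permutes, per term, the
    residuals of the model with that term removed, added back to the reduced
    fit.  Deterministic under a fixed seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be ≥ 1")
    if scheme not in ("manly", "freedman_lane"):
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    y = design["pd"].to_numpy(float)
    n = len(y)
    blocks = _blocks(design, model, ss_order if model == "two_way_full" else DEFAULT_SS_ORDER)
    engine = _SequentialSS(blocks, n)
    f_obs = engine.f_stats(y)[:, 0]
    rng = np.random.default_rng(seed)

    exceed = np.zeros(len(engine.terms), dtype=int)
    if scheme == "manly":
        batch = 2000
        done = 0
        while done < n_perm:
            b = min(batch, n_perm - done)
            perms = rng.permuted(
                np.broadcast_to(np.arange(n), (b, n)).copy(), axis=1
            )
            F = engine.f_stats(y[perms].T)  # (terms, b)
            exceed += (F >= f_obs[:, None] - 1e-12).sum(axis=1)
            done += b
    else:
        for i, term in enumerate(engine.terms):
            fitted, resid = engine.fitted_and_residuals(y, term)
            batch = 2000
            done = 0
            while done < n_perm:
                b = min(batch, n_perm - done)
                perms = rng.permuted(
                    np.broadcast_to(np.arange(n), (b, n)).copy(), axis=1
                )
                Y = fitted[:, None] + resid[perms].T
                F = engine.f_stats(Y)
                exceed[i] += int((F[i] >= f_obs[i] - 1e-12).sum())
                done += b

    return [
        AnovaResult(
            term=name,
            df_num=engine.df_num[i],
            df_den=engine.df_den,
            F=float(f_obs[i]),
            p_perm=(1 + int(exceed[i])) / (1 + n_perm),
            n_perm=n_perm,
            seed=seed,
            scheme=scheme,
        )
        for i, name in enumerate(engine.terms)
    ]


def exhaustive_permutation_p(
    design: pd.DataFrame, model: str = "one_way_sex", max_n: int = 9
) -> dict[str, float]:
    """Exact permutation p-values by enumerating all n! response orderings.

    Only feasible for tiny designs (n ≤ ``max_n``).  The identity permutation
    is included, so p ≥ 1/n!.
    """
    y = design["pd"].to_numpy(float)
    n = len(y)
    if n > max_n:
        raise ValueError(f"exhaustive enumeration limited to n ≤ {max_n}")
    blocks = _blocks(design, model)
    engine = _SequentialSS(blocks, n)
    f_obs = engine.f_stats(y)[:, 0]
    perms = np.array(list(itertools.permutations(range(n))))
    F = engine.f_stats(y[perms].T)
    p = (F >= f_obs[:, None] - 1e-12).mean(axis=1)
    return {name: float(p[i]) for i, name in enumerate(engine.terms)}


def run_study_tests(
    records: Sequence[PdRecord],
    region_groups: Mapping[str, str] = DEFAULT_REGION_GROUPS,
    n_perm: int = 10_000,
    seed: int | None = None,
    scheme: str = "manly",
    two_way_markers: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, list[AnovaResult]]]:
    """The study's test battery over a set of p_d records.

    Per marker: a one-way sex ANOVA pooled over regions; additionally, for
    markers listed in ``two_way_markers`` (default: every marker whose
    two-level sex × region layout has no empty cell), the two-way model with
    the NW vs refugial+Pannonian dichotomy.  Returns a tidy report table and
    the raw results keyed by ``"<marker>:<model>"``.
    """
    by_marker: dict[str, list[PdRecord]] = {}
    for r in records:
        by_marker.setdefault(r.marker, []).append(r)
    rows = []
    results: dict[str, list[AnovaResult]] = {}
    for mi, (marker, recs) in enumerate(sorted(by_marker.items())):
        design = design_table(recs, region_groups)
        sub_seed = None if seed is None else seed + 1000 * mi
        run_two_way = (
            marker in two_way_markers
            if two_way_markers is not None
            else design.groupby(["sex", "region"]).size().shape[0] == 4
        )
        models = ["one_way_sex"] + (["two_way_full"] if run_two_way else [])
        for model in models:
            res = permutation_p(
                design, model=model, n_perm=n_perm, seed=sub_seed, scheme=scheme
            )
            results[f"{marker}:{model}"] = res
            for t in res:
                rows.append(
                    {
                        "marker": marker,
                        "model": model,
                        "term": t.term,
                        "df": f"{t.df_num},{t.df_den}",
                        "F": round(t.F, 3),
                        "p_perm": round(t.p_perm, 4),
                    }
                )
    report = pd.DataFrame(rows)
    return report, results


def brute_force_anova_f(
    design: pd.DataFrame, model: str = "one_way_sex"
) -> dict[str, tuple[int, int, float]]:
    """Independent group-mean sum-of-squares oracle (for testing).

    Computes sequential SS directly from cell/marginal means without any
    matrix algebra; returns {term: (df_num, df_den, F)}.  One-way: classical
    between/within decomposition.  Two-way (sex → region → interaction):
    SS(sex) from sex marginal means; SS(sex+region) − SS(sex) for region via
    explicit least squares on the additive model is avoided by using
    projection-free Gram–Schmidt on indicator columns, i.e. plain arithmetic.
    """
    y = design["pd"].to_numpy(float)
    n = len(y)
    if model == "one_way_sex":
        groups = [y[(design["sex"] == s).to_numpy()] for s in sorted(design["sex"].unique())]
        grand = y.mean()
        ss_b = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_w = sum(((g - g.mean()) ** 2).sum() for g in groups)
        df_b, df_w = len(groups) - 1, n - len(groups)
        F = math.inf if ss_w == 0 and ss_b > 0 else (
            0.0 if ss_b == 0 else (ss_b / df_b) / (ss_w / df_w)
        )
        return {"sex": (df_b, df_w, F)}
    if model != "two_way_full":
        raise ValueError(model)

    # Gram–Schmidt on raw indicator columns, sequentially per term
    def cols_for(factor: str) -> list[np.ndarray]:
        vals = design[factor]
        return [(vals == lev).to_numpy(float) for lev in sorted(vals.unique())[1:]]

    sex_cols = cols_for("sex")
    reg_cols = cols_for("region")
    int_cols = [a * b for a in sex_cols for b in reg_cols]
    basis: list[np.ndarray] = [np.ones(n) / math.sqrt(n)]
    ss: dict[str, float] = {}
    dfs: dict[str, int] = {}
    for name, cols in (
        ("sex", sex_cols),
        ("region", reg_cols),
        ("sex:region", int_cols),
    ):
        term_ss = 0.0
        added = 0
        for c in cols:
            v = c.astype(float)
            for u in basis:
                v = v - (u @ v) * u
            norm = math.sqrt(v @ v)
            if norm < 1e-10:
                continue
            u = v / norm
            basis.append(u)
            term_ss += float((u @ y) ** 2)
            added += 1
        ss[name] = term_ss
        dfs[name] = added
    fitted_ss = sum(float((u @ y) ** 2) for u in basis)
    sse = float(y @ y) - fitted_ss
    df_den = n - len(basis)
    out = {}
    for name in ("sex", "region", "sex:region"):
        if dfs[name] == 0:
            continue
        msr = ss[name] / dfs[name]
        mse = sse / df_den
        F = math.inf if mse == 0 and msr > 0 else (0.0 if msr == 0 else msr / mse)
        out[name] = (dfs[name], df_den, F)
    return out
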