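"""Distance-based linear models (DistLM) with two-stage forward selection.

A distance matrix D among samples is Gower-centred into a Gram matrix
G = (I - J/n)(-1/2 D.D)(I - J/n) (McArdle-Anderson construction); the
variance in G explained by a centred predictor matrix X with hat matrix H
is R^2 = tr(HGH)/tr(G), tested with the pseudo-F ratio

    F = [tr(HGH)/m] / [tr((I-H)G(I-H))/(n-m-1)]

whose null distribution is obtained by permutation of residuals under the
reduced model (Freedman-Lane).  For a univariate response under Euclidean
distance this reduces exactly to ordinary least squares, which the test
suite exploits as an independent oracle.

The selection protocol explains each ecosystem function in two stages:
first forward selection (adjusted-R^2 criterion) over trait-cluster
abundance predictors, then — with the significant cluster terms forced
into the model — forward selection over environmental characteristics.
Each base variable enters as up to three candidate columns (raw, squared
or square-root, log10(x+1)); under the strict admissibility rule the log
column may only be selected while no raw/square column of the same base
is in the model, and vice versa.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .tables import RunConfig, SampleMatrix, ValidationError
from .traitnet import ClusterAbundanceTable

logger = logging.getLogger("mfnet")

_RANK_TOL = 1e-10


@dataclass
class CenteredGram:
    """Gower-centred inner-product matrix of a distance matrix."""

    G: np.ndarray
    total_ss: float

    @property
    def n(self) -> int:
        return self.G.shape[0]


@dataclass
class PredictorColumn:
    """One centred candidate column: a base variable under one transform."""

    base_variable: str
    transform: str          # raw | square | sqrt | log10p1
    values: np.ndarray

    @property
    def label(self) -> str:
        return f"{self.base_variable}[{self.transform}]"


@dataclass
class SelectionStep:
    """One forward-selection step: the column added and its statistics."""

    column: PredictorColumn
    delta_r2: float
    adj_r2_after: float
    pseudo_F: float
    p_perm: float
    stage: str              # traits | environment

    def to_dict(self) -> dict:
        return {
            "base": self.column.base_variable,
            "transform": self.column.transform,
            "delta_r2": self.delta_r2,
            "adj_r2_after": self.adj_r2_after,
            "pseudo_F": self.pseudo_F,
            "p_perm": self.p_perm,
            "stage": self.stage,
        }


@dataclass
class FunctionResult:
    """Selection path and stage totals for a single ecosystem function."""

    steps: list[SelectionStep]
    r2_traits: float        # row A: all significant trait clusters
    r2_env_added: float     # row B: environment added on top of A
    r2_total: float         # row C = A + B
    n: int


@dataclass
class DistLMReport:
    """Per-function selection paths plus the A/B/C stage totals."""

    results: dict[str, FunctionResult]
    n: int
    config: dict

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "config": self.config,
            "functions": {
                f: {
                    "steps": [s.to_dict() for s in r.steps],
                    "A": r.r2_traits,
                    "B": r.r2_env_added,
                    "C": r.r2_total,
                }
                for f, r in self.results.items()
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "DistLMReport":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        results = {}
        for f, r in d["functions"].items():
            steps = [
                SelectionStep(
                    column=PredictorColumn(s["base"], s["transform"], np.empty(0)),
                    delta_r2=s["delta_r2"], adj_r2_after=s["adj_r2_after"],
                    pseudo_F=s["pseudo_F"], p_perm=s["p_perm"], stage=s["stage"],
                )
                for s in r["steps"]
            ]
            results[f] = FunctionResult(steps, r["A"], r["B"], r["C"], d["n"])
        return cls(results=results, n=d["n"], config=d["config"])

    def cell_weights(self, function: str) -> dict[str, float]:
        """Summed sequential R^2 per base variable for one function."""
        out: dict[str, float] = {}
        for s in self.results[function].steps:
            out[s.column.base_variable] = out.get(s.column.base_variable, 0.0) + s.delta_r2
        return out

    def to_table(self, aliases: Mapping[str, str] | None = None) -> pd.DataFrame:
        """Predictors x functions table of summed sequential R^2 with
        transform-set footnotes, plus the A/B/C total rows.

        Footnotes: (a) raw only; (b) log only, square only, or raw+square;
        (c) log together with raw or square.
        """
        aliases = dict(aliases or {})
        functions = list(self.results)
        bases: list[str] = []
        for f in functions:
            for s in self.results[f].steps:
                b = s.column.base_variable
                if b not in bases:
                    bases.append(b)
        rows = {}
        for b in bases:
            row = []
            for f in functions:
                steps = [s for s in self.results[f].steps if s.column.base_variable == b]
                if not steps:
                    row.append("")
                    continue
                total = sum(s.delta_r2 for s in steps)
                note = _footnote({s.column.transform for s in steps})
                row.append(f"{total:.6g}{'^' + note if note else ''}")
            rows[aliases.get(b, b)] = row
        rows["(A) R2 all significant trait clusters"] = [
            f"{self.results[f].r2_traits:.6g}" for f in functions
        ]
        rows["(B) R2 all significant environmental characteristics"] = [
            f"{self.results[f].r2_env_added:.6g}" for f in functions
        ]
        rows["(C) Total"] = [f"{self.results[f].r2_total:.6g}" for f in functions]
        return pd.DataFrame.from_dict(rows, orient="index", columns=functions)


def _footnote(transforms: set[str]) -> str:
    has_log = "log10p1" in transforms
    has_other = bool(transforms - {"log10p1"})
    if has_log and has_other:
        return "c"
    if transforms == {"raw"}:
        return "a"
    return "b"


# ---------------------------------------------------------------------------
# core linear algebra


def gower_center(D: np.ndarray) -> CenteredGram:
    """Gower-centre a distance matrix: G = (I - J/n)(-D.D/2)(I - J/n)."""
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValidationError("distance matrix must be symmetric")
    if np.any(D < 0):
        raise ValidationError("distance matrix must be non-negative")
    n = D.shape[0]
    A = -0.5 * D * D
    row_mean = A.mean(axis=1, keepdims=True)
    G = A - row_mean - row_mean.T + A.mean()
    G = 0.5 * (G + G.T)
    return CenteredGram(G=G, total_ss=float(np.trace(G)))


def response_gram(y: np.ndarray) -> CenteredGram:
    """Centred Gram of the Euclidean distance among values of one response."""
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    return gower_center(squareform(pdist(y, metric="euclidean")))


def center(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v - v.mean()


def _orth_basis(columns: Sequence[np.ndarray], labels: Sequence[str]) -> np.ndarray:
    """Orthonormal basis of the span of centred columns; raises naming the
    collinear columns on rank deficiency."""
    X = np.column_stack(columns)
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    scale = diag.max() if diag.size else 0.0
    bad = [labels[k] for k in range(len(columns)) if diag[k] <= _RANK_TOL * max(scale, 1.0)]
    if bad:
        raise ValidationError(f"rank-deficient design; collinear columns: {bad}")
    return q


def fit_r2(
    G: CenteredGram, X: Sequence[PredictorColumn | np.ndarray]
) -> tuple[float, float]:
    """Explained-variance fraction and pseudo-F of predictors X on G.

    R^2 = tr(HGH)/tr(G) with H the hat matrix of the centred design; for a
    univariate Euclidean response this equals the OLS R^2.
    """
    if G.total_ss <= 0:
        raise ValidationError("constant response: total sum of squares is zero")
    cols = [c.values if isinstance(c, PredictorColumn) else np.asarray(c, float) for c in X]
    labels = [c.label if isinstance(c, PredictorColumn) else f"x{k}" for k, c in enumerate(X)]
    if not cols:
        return 0.0, float("nan")
    n = G.n
    m = len(cols)
    if n <= m + 1:
        raise ValidationError(f"need n > m + 1 (n={n}, m={m})")
    Q = _orth_basis(cols, labels)
    explained = float(np.sum(Q * (G.G @ Q)))
    r2 = explained / G.total_ss
    residual = G.total_ss - explained
    with np.errstate(divide="ignore"):
        F = (explained / m) / (residual / (n - m - 1)) if residual > 0 else float("inf")
    return r2, F


def adjusted_r2(r2: float, n: int, v: int) -> float:
    """Adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - v - 1)."""
    if n <= v + 1:
        raise ValidationError(f"adjusted R^2 undefined for n={n}, v={v}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - v - 1)


def permutation_p(
    G: CenteredGram,
    X_test: Sequence[PredictorColumn | np.ndarray],
    X_forced: Sequence[PredictorColumn | np.ndarray] = (),
    n_perm: int = 999,
    seed: int | Sequence[int] = 0,
) -> float:
    """Sequential permutation p-value for X_test given X_forced.

    Permutation of residuals under the reduced (forced-only) model: the
    residual Gram G_r = (I-H0) G (I-H0) has rows and columns permuted
    simultaneously, and the partial pseudo-F of X_test is recomputed on
    each permuted matrix; p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    n = G.n
    test = [c.values if isinstance(c, PredictorColumn) else np.asarray(c, float) for c in X_test]
    forced = [c.values if isinstance(c, PredictorColumn) else np.asarray(c, float) for c in X_forced]
    if forced:
        Q0 = _orth_basis(forced, [f"f{k}" for k in range(len(forced))])
        R0 = np.eye(n) - Q0 @ Q0.T
    else:
        Q0 = np.empty((n, 0))
        R0 = np.eye(n)
    m0 = Q0.shape[1]
    Gr = R0 @ G.G @ R0
    Xt = [R0 @ c for c in test]
    Qt = _orth_basis(Xt, [f"t{k}" for k in range(len(Xt))])
    m1 = Qt.shape[1]
    df_res = n - m0 - m1 - 1
    if df_res < 1:
        raise ValidationError("no residual degrees of freedom for permutation test")

    def stat(Gm: np.ndarray) -> float:
        expl_t = float(np.sum(Qt * (Gm @ Qt)))
        expl_0 = float(np.sum(Q0 * (Gm @ Q0))) if m0 else 0.0
        residual = float(np.trace(Gm)) - expl_0 - expl_t
        if residual <= 0:
            return float("inf")
        return (expl_t / m1) / (residual / df_res)

    f_obs = stat(Gr)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        ix = rng.permutation(n)
        if stat(Gr[np.ix_(ix, ix)]) >= f_obs:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)


# ---------------------------------------------------------------------------
# candidate construction and forward selection


def expand_transforms(table: SampleMatrix, family: str = "square") -> list[PredictorColumn]:
    """Three centred candidate columns per base variable: raw, square (or
    sqrt under ``family='sqrt'``), and log10(x+1).

    Constant base variables are degenerate and excluded with a warning;
    negative values are an error for sqrt/log transforms.
    """
    if family not in ("square", "sqrt"):
        raise ValidationError("transform family must be 'square' or 'sqrt'")
    out: list[PredictorColumn] = []
    for var in table.variable_ids:
        v = table.column(var)
        if np.ptp(v) == 0:
            logger.warning("predictor %s is constant; its candidate columns are excluded", var)
            continue
        if np.any(v < 0):
            raise ValidationError(
                f"variable {var!r} has negative values; sqrt/log10(x+1) transforms undefined"
            )
        second = v * v if family == "square" else np.sqrt(v)
        second_name = "square" if family == "square" else "sqrt"
        for name, vals in (("raw", v), (second_name, second), ("log10p1", np.log10(v + 1))):
            if np.ptp(vals) == 0:
                logger.warning("column %s[%s] is constant; excluded", var, name)
                continue
            out.append(PredictorColumn(var, name, center(vals)))
    return out


_TRANSFORM_KIND = {"raw": "power", "square": "power", "sqrt": "power", "log10p1": "log"}


def _admissible(cand: PredictorColumn, in_model: Sequence[PredictorColumn],
                constraint: str) -> bool:
    if constraint == "lenient":
        return True
    same_base = [c for c in in_model if c.base_variable == cand.base_variable]
    if not same_base:
        return True
    if _TRANSFORM_KIND[cand.transform] == "log":
        return all(_TRANSFORM_KIND[c.transform] == "log" for c in same_base)
    return all(_TRANSFORM_KIND[c.transform] != "log" for c in same_base)


def forward_select(
    G: CenteredGram,
    candidates: Sequence[PredictorColumn],
    forced: Sequence[PredictorColumn] = (),
    constraint: str = "strict",
    n_perm: int = 0,
    seed: int | Sequence[int] = 0,
    stage: str = "traits",
) -> list[SelectionStep]:
    """Greedy forward selection maximizing adjusted R^2.

    At each step the admissible candidate giving the highest adjusted R^2
    of the enlarged model is added; selection stops when no admissible
    candidate increases adjusted R^2.  Ties are broken lexicographically
    by (base_variable, transform).  ``n_perm >= 1`` attaches a sequential
    permutation p-value to every accepted step.
    """
    n = G.n
    forced = list(forced)
    if forced:
        fit_r2(G, forced)  # raises on rank deficiency
    selected: list[SelectionStep] = []
    model_cols = list(forced)
    current_r2 = fit_r2(G, model_cols)[0] if model_cols else 0.0
    current_adj = adjusted_r2(current_r2, n, len(model_cols))
    remaining = list(candidates)
    step_idx = 0
    while remaining:
        best = None
        for cand in sorted(remaining, key=lambda c: (c.base_variable, c.transform)):
            if not _admissible(cand, model_cols, constraint):
                continue
            if n <= len(model_cols) + 2:
                break
            try:
                r2_new, _ = fit_r2(G, model_cols + [cand])
            except ValidationError:
                continue  # collinear with current model
            adj_new = adjusted_r2(r2_new, n, len(model_cols) + 1)
            if best is None or adj_new > best[0] + 1e-15:
                best = (adj_new, cand, r2_new)
        if best is None:
            break
        adj_new, cand, r2_new = best
        if adj_new <= current_adj:
            break
        delta = r2_new - current_r2
        res = 1.0 - r2_new
        df = n - len(model_cols) - 2
        F = (delta) / (res / df) if res > 0 else float("inf")
        p = float("nan")
        if n_perm >= 1:
            base_seed = list(np.atleast_1d(np.asarray(seed, dtype=np.int64)))
            p = permutation_p(G, [cand], model_cols, n_perm=n_perm,
                              seed=[int(s) for s in base_seed] + [step_idx])
        selected.append(SelectionStep(
            column=cand, delta_r2=delta, adj_r2_after=adj_new,
            pseudo_F=F, p_perm=p, stage=stage,
        ))
        model_cols.append(cand)
        remaining = [c for c in remaining if c is not cand]
        current_r2, current_adj = r2_new, adj_new
        step_idx += 1
    return selected


def _recompute_path(
    G: CenteredGram,
    steps: Sequence[SelectionStep],
    forced: Sequence[PredictorColumn],
    stage: str,
) -> list[SelectionStep]:
    """Sequential statistics for a fixed column order (used after the
    significance filter drops steps, so that sums of sequential R^2 still
    telescope exactly to the model R^2)."""
    n = G.n
    model = list(forced)
    base_r2 = fit_r2(G, model)[0] if model else 0.0
    out = []
    for s in steps:
        r2_new, _ = fit_r2(G, model + [s.column])
        delta = r2_new - base_r2
        res = 1.0 - r2_new
        df = n - len(model) - 2
        F = delta / (res / df) if res > 0 else float("inf")
        out.append(SelectionStep(
            column=s.column, delta_r2=delta,
            adj_r2_after=adjusted_r2(r2_new, n, len(model) + 1),
            pseudo_F=F, p_perm=s.p_perm, stage=stage,
        ))
        model.append(s.column)
        base_r2 = r2_new
    return out


def run_two_stage(
    functions: SampleMatrix,
    clusters: ClusterAbundanceTable | SampleMatrix,
    env: SampleMatrix,
    cfg: RunConfig | None = None,
) -> DistLMReport:
    """Two-stage DistLM for every ecosystem function.

    Stage 1 forward-selects trait-cluster abundance columns; clusters that
    prove significant (per ``cfg.significance_rule``) are forced into the
    stage-2 model, which then forward-selects environmental columns.
    Row A is the variance explained by retained cluster terms, row B the
    environmental addition, row C = A + B.
    """
    cfg = cfg or RunConfig()
    cluster_mat = clusters.matrix if isinstance(clusters, ClusterAbundanceTable) else clusters
    for other, name in ((cluster_mat, "cluster"), (env, "environment")):
        if other.sample_ids != functions.sample_ids:
            missing = set(functions.sample_ids) ^ set(other.sample_ids)
            raise ValidationError(
                f"sample ids of {name} table do not match function table "
                f"(symmetric difference: {sorted(missing) or 'same set, different order'})"
            )
    cluster_cands = expand_transforms(cluster_mat, cfg.transform_family)
    env_cands = expand_transforms(env, cfg.transform_family)
    results: dict[str, FunctionResult] = {}
    n = len(functions.sample_ids)
    for k, fname in enumerate(functions.variable_ids):
        G = response_gram(functions.column(fname))
        steps1 = forward_select(
            G, cluster_cands, forced=(), constraint=cfg.transform_constraint,
            n_perm=cfg.n_permutations, seed=[cfg.seed, k, 1], stage="traits",
        )
        retained1 = _apply_significance(steps1, cfg)
        steps1 = _recompute_path(G, retained1, forced=(), stage="traits")
        forced = [s.column for s in steps1]
        a = sum(s.delta_r2 for s in steps1)
        steps2 = forward_select(
            G, env_cands, forced=forced, constraint=cfg.transform_constraint,
            n_perm=cfg.n_permutations, seed=[cfg.seed, k, 2], stage="environment",
        )
        retained2 = _apply_significance(steps2, cfg)
        steps2 = _recompute_path(G, retained2, forced=forced, stage="environment")
        b = sum(s.delta_r2 for s in steps2)
        results[fname] = FunctionResult(
            steps=steps1 + steps2, r2_traits=a, r2_env_added=b, r2_total=a + b, n=n,
        )
    return DistLMReport(results=results, n=n, config=cfg.to_dict())


def _apply_significance(steps: list[SelectionStep], cfg: RunConfig) -> list[SelectionStep]:
    if cfg.significance_rule == "selected":
        return steps
    return [s for s in steps if s.p_perm <= cfg.alpha]
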