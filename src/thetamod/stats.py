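"""The inference battery: Pearson and partial correlations, the dependent-
correlation (Steiger) comparison, one-sample t, the 2x2x2 within-subject
ANOVA, and the group ANCOVA with Type-III tests.

Everything is computed from the explicit formulas (tail probabilities via
the regularized incomplete beta/gamma functions in scipy.special); no
model-fitting front end stands between the data and the reported
statistic. Established implementations (scipy.stats, statsmodels,
pingouin) serve as independent cross-checks in the test suite only.

Conventions: all tests are two-sided except the Steiger comparison,
whose one-sided normal upper tail matches the field's reporting style
for directional band comparisons. No multiple-testing correction is
applied anywhere. Missing data are handled by listwise deletion per
analysis, with the per-analysis n carried in every result object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

logger = logging.getLogger("thetamod")

__all__ = [
    "DegenerateInputError",
    "InsufficientDataError",
    "CorrResult",
    "AnovaTable",
    "SteigerResult",
    "p_from_statistic",
    "pearson",
    "partial_corr",
    "steiger_dependent",
    "one_sample_t",
    "rm_anova_2x2x2",
    "ancova_group",
]


class DegenerateInputError(ValueError):
    """Zero variance / exact collinearity where the formula needs spread."""


class InsufficientDataError(ValueError):
    """Fewer complete cases than the analysis requires."""


# ---------------------------------------------------------------------------
# Tail-probability kernel
# ---------------------------------------------------------------------------

def p_from_statistic(kind: str, statistic: float, df, sided: str = "two") -> float:
    """Exact tail probability for t, F or z statistics.

    t: df is a scalar; two-sided uses both tails, one-sided the upper.
    F: df is (df1, df2); the upper tail (the only side an F test uses).
    z: standard normal; one-sided upper or two-sided.

    t and F tails are regularized incomplete beta integrals; the normal
    tail is erfc. Identity used by the invariants: for df1 = 1 the
    two-sided t probability at sqrt(F) equals the upper F tail.
    """
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    if kind == "t":
        d = float(df)
        if d <= 0:
            raise ValueError(f"t requires df > 0, got {d}")
        if not np.isfinite(statistic):
            return 0.0
        two = special.betainc(d / 2.0, 0.5, d / (d + statistic**2))
        if sided == "two":
            return float(two)
        return float(two / 2.0 if statistic >= 0 else 1.0 - two / 2.0)
    if kind == "F":
        d1, d2 = float(df[0]), float(df[1])
        if d1 <= 0 or d2 <= 0:
            raise ValueError(f"F requires positive df, got {df}")
        if statistic < 0:
            raise ValueError("F statistic must be >= 0")
        if not np.isfinite(statistic):
            return 0.0
        return float(special.betainc(d2 / 2.0, d1 / 2.0, d2 / (d2 + d1 * statistic)))
    if kind == "z":
        one = 0.5 * special.erfc(statistic / np.sqrt(2.0))
        if sided == "one":
            return float(one)
        return float(2.0 * 0.5 * special.erfc(abs(statistic) / np.sqrt(2.0)))
    raise ValueError(f"unknown statistic kind '{kind}'")


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

@dataclass
class CorrResult:
    r: float
    n: int
    df: int
    t: float
    p: float
    kind: str = "pearson"
    partialled: list[str] = field(default_factory=list)

    def __str__(self) -> str:  # paper-style "r(n) = .., p = .."
        return f"{self.kind} r({self.n}) = {self.r:.2f}, p = {self.p:.3g}"


def _complete(*cols: np.ndarray) -> tuple[np.ndarray, ...]:
    """Pairwise-complete: drop rows with any NaN across the inputs."""
    cols = tuple(np.asarray(c, dtype=float).ravel() for c in cols)
    n = cols[0].size
    if any(c.size != n for c in cols):
        raise ValueError("inputs must have equal length")
    keep = np.ones(n, dtype=bool)
    for c in cols:
        keep &= np.isfinite(c)
    return tuple(c[keep] for c in cols)


def _corrcoef(x: np.ndarray, y: np.ndarray) -> float:
    xc, yc = x - x.mean(), y - y.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx == 0 or sy == 0:
        raise DegenerateInputError("zero variance in a correlation input")
    return float(np.clip((xc * yc).sum() / (sx * sy), -1.0, 1.0))


def pearson(x, y) -> CorrResult:
    """Product-moment correlation with the t-based two-sided p.

    t = r*sqrt(n-2)/sqrt(1-r^2), df = n-2. Exact collinearity (|r| = 1)
    bypasses the t path: t = inf, p = 0.
    """
    x, y = _complete(x, y)
    n = x.size
    if n < 4:
        raise InsufficientDataError(f"pearson requires n >= 4 complete pairs, got {n}")
    r = _corrcoef(x, y)
    df = n - 2
    if abs(r) >= 1.0 - 1e-15:
        return CorrResult(r=r, n=n, df=df, t=float("inf") * np.sign(r), p=0.0)
    t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    return CorrResult(r=r, n=n, df=df, t=float(t), p=p_from_statistic("t", t, df))


def partial_corr(x, y, covariates, df_convention: str = "n-2-k",
                 names: list[str] | None = None) -> CorrResult:
    """Correlation of x and y with covariates partialled out.

    One covariate uses the first-order formula
    r_xy.z = (r_xy - r_xz*r_yz)/sqrt((1-r_xz^2)(1-r_yz^2)); more use OLS
    residualization (the two agree, a test asserts it). Default
    df = n-2-k; ``df_convention="n-2"`` reproduces reports that quote
    the plain-correlation df.
    """
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != np.asarray(x).size and cov.shape[1] == np.asarray(x).size:
        cov = cov.T
    arrays = _complete(x, y, *[cov[:, j] for j in range(cov.shape[1])])
    x, y = arrays[0], arrays[1]
    cov = np.column_stack(arrays[2:])
    n, k = x.size, cov.shape[1]
    if n < k + 4:
        raise InsufficientDataError(f"partial correlation requires n >= k+4, got n={n}, k={k}")
    for j in range(k):
        if np.allclose(x, cov[:, j]) or np.allclose(y, cov[:, j]):
            logger.warning("partialling a variable out of itself; returning r = 0")
            df = n - 2 - k if df_convention == "n-2-k" else n - 2
            return CorrResult(r=0.0, n=n, df=df, t=0.0, p=1.0, kind="partial",
                              partialled=names or [f"z{j}" for j in range(k)])
    if k == 1:
        z = cov[:, 0]
        r_xy, r_xz, r_yz = _corrcoef(x, y), _corrcoef(x, z), _corrcoef(y, z)
        if abs(r_xz) >= 1.0 - 1e-12 or abs(r_yz) >= 1.0 - 1e-12:
            raise DegenerateInputError("covariate collinear with x or y")
        r = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    else:
        design = np.column_stack([np.ones(n), cov])
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            raise DegenerateInputError("covariate set is rank deficient")
        rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
        ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
        r = _corrcoef(rx, ry)
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 2 - k if df_convention == "n-2-k" else n - 2
    if abs(r) >= 1.0 - 1e-15:
        return CorrResult(r=r, n=n, df=df, t=float("inf") * np.sign(r), p=0.0,
                          kind="partial", partialled=names or [])
    t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    return CorrResult(r=r, n=n, df=df, t=float(t), p=p_from_statistic("t", t, df),
                      kind="partial", partialled=names or [])


# ---------------------------------------------------------------------------
# Steiger comparison of two dependent correlations
# ---------------------------------------------------------------------------

@dataclass
class SteigerResult:
    r13: float
    r23: float
    r12: float
    n: int
    z: float
    p_one_sided: float

    @property
    def p_two_sided(self) -> float:
        return p_from_statistic("z", self.z, None, sided="two")


def steiger_dependent(r13: float, r23: float, r12: float, n: int) -> SteigerResult:
    """Steiger's Z* for two correlations sharing variable 3.

    Fisher-transform r13 and r23; with pooled r_bar = (r13+r23)/2 the
    covariance term is
    psi = r12*(1-2*r_bar^2) - r_bar^2*(1-2*r_bar^2-r12^2)/2,
    s = psi/(1-r_bar^2)^2, and
    Z = (z13 - z23) * sqrt((n-3) / (2*(1-s))).
    p is the one-sided normal upper tail. Antisymmetric in (r13, r23).
    """
    if n < 4:
        raise InsufficientDataError(f"steiger requires n >= 4, got {n}")
    for name, r in (("r13", r13), ("r23", r23), ("r12", r12)):
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"{name} = {r} outside [-1, 1]")
    R = np.array([[1.0, r12, r13], [r12, 1.0, r23], [r13, r23, 1.0]])
    if np.linalg.eigvalsh(R).min() < -1e-10:
        raise ValueError("correlation matrix (r12, r13, r23) is not positive semidefinite")
    z13, z23 = np.arctanh(r13), np.arctanh(r23)
    rbar = (r13 + r23) / 2.0
    psi = r12 * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r12**2)
    s = psi / (1 - rbar**2) ** 2
    z = (z13 - z23) * np.sqrt((n - 3) / (2.0 * (1.0 - s)))
    return SteigerResult(r13=r13, r23=r23, r12=r12, n=n, z=float(z),
                         p_one_sided=p_from_statistic("z", float(z), None, sided="one"))


# ---------------------------------------------------------------------------
# One-sample t
# ---------------------------------------------------------------------------

def one_sample_t(x, mu0: float = 0.0) -> tuple[float, int, float]:
    """t = (mean - mu0)/(sd/sqrt(n)), df = n-1, two-sided p.

    A constant sample equal to mu0 returns t = 0, p = 1 (documented
    convention); a constant sample elsewhere is degenerate.
    """
    (x,) = _complete(x)
    n = x.size
    if n < 2:
        raise InsufficientDataError(f"one-sample t requires n >= 2, got {n}")
    sd = x.std(ddof=1)
    if sd == 0:
        if np.isclose(x.mean(), mu0):
            return 0.0, n - 1, 1.0
        raise DegenerateInputError("zero variance with mean != mu0")
    t = (x.mean() - mu0) / (sd / np.sqrt(n))
    return float(t), n - 1, p_from_statistic("t", float(t), n - 1)


# ---------------------------------------------------------------------------
# Repeated-measures 2x2x2 ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaTable:
    table: pd.DataFrame  # effect, F, df1, df2, p, partial_eta_sq
    n: int
    extra: dict = field(default_factory=dict)

    def effect(self, name: str) -> pd.Series:
        sel = self.table[self.table["effect"] == name]
        if not len(sel):
            raise KeyError(f"no effect '{name}' in table ({list(self.table['effect'])})")
        return sel.iloc[0]


_RM_FACTORS = ("condition", "half", "region")


def rm_anova_2x2x2(df: pd.DataFrame, value: str = "value",
                   subject: str = "subject") -> AnovaTable:
    """Fully within-subject 2x2x2 ANOVA via per-subject contrast scores.

    For every effect (3 mains, 3 two-way, 1 three-way) the per-subject
    contrast is the +/- coded mean over the 8 cells; each F(1, n-1) is
    the square of the paired t on that contrast, p is the upper F tail,
    and partial eta^2 = F/(F + n - 1). Subjects missing any cell are
    dropped (listwise, logged).
    """
    for col in (subject, value, *_RM_FACTORS):
        if col not in df.columns:
            raise ValueError(f"rm_anova_2x2x2: missing column '{col}'")
    wide = df.pivot_table(index=subject, columns=list(_RM_FACTORS), values=value,
                          aggfunc="mean")
    complete = wide.dropna()
    dropped = len(wide) - len(complete)
    if dropped:
        logger.info("rm_anova: dropped %d incomplete subjects (listwise)", dropped)
    n = len(complete)
    if n < 3:
        raise InsufficientDataError(f"rm_anova requires n >= 3 complete subjects, got {n}")
    levels = {f: sorted(complete.columns.get_level_values(f).unique()) for f in _RM_FACTORS}
    for f, lv in levels.items():
        if len(lv) != 2:
            raise ValueError(f"factor '{f}' must have exactly 2 levels, got {lv}")

    # +1 for the first sorted level, -1 for the second, per factor
    codes = {
        f: {lv[0]: 1.0, lv[1]: -1.0} for f, lv in levels.items()
    }
    effects = [
        ("condition",), ("half",), ("region",),
        ("condition", "half"), ("condition", "region"), ("half", "region"),
        ("condition", "half", "region"),
    ]
    rows = []
    scale = max(1.0, float(np.abs(complete.to_numpy()).max()))
    for eff in effects:
        w = np.array([
            np.prod([codes[f][col[_RM_FACTORS.index(f)]] for f in eff])
            for col in complete.columns
        ])
        scores = complete.to_numpy() @ (w / 8.0)
        if np.abs(scores).max() < 1e-12 * scale:  # exact-null contrast
            scores = np.zeros_like(scores)
        sd = scores.std(ddof=1)
        if sd == 0:
            F = 0.0 if np.isclose(scores.mean(), 0.0) else float("inf")
        else:
            t = scores.mean() / (sd / np.sqrt(n))
            F = float(t * t)
        df2 = n - 1
        rows.append(
            dict(
                effect=" x ".join(eff),
                F=F,
                df1=1,
                df2=df2,
                p=p_from_statistic("F", F, (1, df2)),
                partial_eta_sq=(F / (F + df2)) if np.isfinite(F) else 1.0,
            )
        )
    return AnovaTable(table=pd.DataFrame(rows), n=n)


# ---------------------------------------------------------------------------
# ANCOVA with a group factor (Type III, effects coding)
# ---------------------------------------------------------------------------

def _effects_code(groups: pd.Series) -> tuple[np.ndarray, list[str]]:
    levels = sorted(groups.unique())
    ref = levels[-1]
    cols, names = [], []
    for lv in levels[:-1]:
        c = np.where(groups == lv, 1.0, np.where(groups == ref, -1.0, 0.0))
        cols.append(c)
        names.append(f"group[{lv}]")
    return (np.column_stack(cols) if cols else np.empty((len(groups), 0))), names


def _ssr(design: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return float((resid**2).sum())


def ancova_group(outcome, predictor, group, covariate=None) -> AnovaTable:
    """outcome ~ predictor + group + predictor:group (+ covariate).

    Sum-to-zero (effects) coding, Type-III F tests: each effect's SS is
    the residual-SS increase when its columns are removed from the full
    model. partial eta^2 = SS_effect/(SS_effect + SS_residual). Per-group
    Pearson correlations ride along in ``extra["group_r"]``. An exact fit
    (SS_residual = 0) reports F = inf, p = 0.
    """
    data = pd.DataFrame({"y": np.asarray(outcome, float),
                         "x": np.asarray(predictor, float),
                         "g": np.asarray(group)})
    if covariate is not None:
        data["c"] = np.asarray(covariate, float)
    data = data.dropna()
    n = len(data)
    groups = sorted(data["g"].unique())
    if len(groups) < 2:
        raise InsufficientDataError("ANCOVA requires >= 2 groups")
    sizes = data.groupby("g").size()
    if (sizes < 2).any():
        raise InsufficientDataError(f"every group needs n >= 2, got {dict(sizes)}")

    G, gnames = _effects_code(data["g"])
    x = data["x"].to_numpy()
    blocks: dict[str, np.ndarray] = {
        "predictor": x[:, None],
        "group": G,
        "predictor x group": x[:, None] * G,
    }
    if covariate is not None:
        blocks["covariate"] = data["c"].to_numpy()[:, None]
    design = np.column_stack([np.ones(n)] + list(blocks.values()))
    p_full = design.shape[1]
    if np.linalg.matrix_rank(design) < p_full:
        for name, b in blocks.items():
            partial = np.column_stack(
                [np.ones(n)] + [v for k, v in blocks.items() if k != name]
            )
            if np.linalg.matrix_rank(np.column_stack([partial, b])) == \
               np.linalg.matrix_rank(partial):
                raise DegenerateInputError(f"design is rank deficient: term '{name}' aliased")
        raise DegenerateInputError("design is rank deficient")
    y = data["y"].to_numpy()
    ss_full = _ssr(design, y)
    df_res = n - p_full
    if df_res < 1:
        raise InsufficientDataError("no residual degrees of freedom")
    rows = []
    for name, b in blocks.items():
        reduced = np.column_stack(
            [np.ones(n)] + [v for k, v in blocks.items() if k != name]
        )
        ss_eff = _ssr(reduced, y) - ss_full
        df1 = b.shape[1]
        if ss_full <= 1e-12 * max(1.0, float((y - y.mean()) @ (y - y.mean()))):
            F, p, eta = float("inf"), 0.0, 1.0
        else:
            F = (ss_eff / df1) / (ss_full / df_res)
            F = max(F, 0.0)
            p = p_from_statistic("F", F, (df1, df_res))
            eta = ss_eff / (ss_eff + ss_full)
        rows.append(dict(effect=name, F=F, df1=df1, df2=df_res, p=p,
                         partial_eta_sq=eta))
    group_r = {}
    for g in groups:
        sub = data[data["g"] == g]
        if len(sub) >= 4:
            try:
                group_r[g] = pearson(sub["x"], sub["y"])
            except DegenerateInputError:
                pass
    return AnovaTable(table=pd.DataFrame(rows), n=n, extra={"group_r": group_r})
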