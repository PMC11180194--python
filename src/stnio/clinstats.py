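"""Clinical statistics: predictor-family GLMs with interaction orders,
N-way ANOVA of aperiodic parameters, Spearman correlation with a
permutation null, and pointwise rank-sum spectrum comparisons.

Predictor families (four members each):

========  =========================================
DeF       LD, Ag, DD, Gd          (demography)
ApF       LO, SO, LE, SE          (aperiodic)
PeF       LCF, SCF, LP, SP        (periodic)
LFPF      LO, LE, LCF, LP         (LFP features)
SPKF      SO, SE, SCF, SP         (SPK features)
LSF       LSCF, LSP, LSO, LSE     (LFP − SPK differences)
========  =========================================

Model orders: ``individual`` (one predictor), ``zeroth`` (the four members
additively), ``first`` (the six pairwise products only), ``higher`` (the
four triple products plus the quadruple product).  All predictors and
responses are z-normalized before fitting; models are Gaussian-identity
GLMs (ordinary least squares).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst

__all__ = ["FAMILIES", "ModelResult", "zscore", "derive_difference_columns",
           "fit_family", "anova_aperiodic", "spearman_with_shuffle",
           "pointwise_psd_test"]

FAMILIES: dict[str, tuple[str, str, str, str]] = {
    "DeF": ("LD", "Ag", "DD", "Gd"),
    "ApF": ("LO", "SO", "LE", "SE"),
    "PeF": ("LCF", "SCF", "LP", "SP"),
    "LFPF": ("LO", "LE", "LCF", "LP"),
    "SPKF": ("SO", "SE", "SCF", "SP"),
    "LSF": ("LSCF", "LSP", "LSO", "LSE"),
}

_DIFFERENCES = {"LSCF": ("LCF", "SCF"), "LSP": ("LP", "SP"),
                "LSO": ("LO", "SO"), "LSE": ("LE", "SE")}


@dataclass
class ModelResult:
    family: str
    response: str
    model_order: str
    r_squared: float
    aic: float
    model_p: float
    coefficients: pd.Series
    coefficient_p: pd.Series
    n_obs: int
    rank_deficient: bool = False


def zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, float)
    sd = x.std(ddof=0)
    if sd == 0:
        return x - x.mean()
    return (x - x.mean()) / sd


def derive_difference_columns(df: pd.DataFrame,
                              atol: float = 1e-8) -> pd.DataFrame:
    """Add (or verify) the LFP−SPK difference columns.

    If a difference column is already present it must equal the difference
    of its parents; a violation is a data error, not silently fixed.
    """
    out = df.copy()
    for diff, (a, b) in _DIFFERENCES.items():
        if a in out.columns and b in out.columns:
            expected = out[a] - out[b]
            if diff in out.columns:
                if not np.allclose(out[diff], expected, atol=atol,
                                   equal_nan=True):
                    raise ValueError(
                        f"column {diff} is inconsistent with {a} - {b}")
            else:
                out[diff] = expected
    return out


def _design(Z: pd.DataFrame, members: tuple[str, ...],
            order: str) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = []
    names: list[str] = []
    if order == "zeroth":
        for m in members:
            cols.append(Z[m].to_numpy())
            names.append(m)
    elif order == "first":
        for a, b in itertools.combinations(members, 2):
            cols.append(Z[a].to_numpy() * Z[b].to_numpy())
            names.append(f"{a}*{b}")
    elif order == "higher":
        for trip in itertools.combinations(members, 3):
            cols.append(np.prod([Z[m].to_numpy() for m in trip], axis=0))
            names.append("*".join(trip))
        cols.append(np.prod([Z[m].to_numpy() for m in members], axis=0))
        names.append("*".join(members))
    else:
        raise ValueError(f"unknown model order {order!r}")
    X = np.column_stack(cols)
    return X, names


def fit_family(table: pd.DataFrame, family: str, response: str,
               order: str = "zeroth") -> ModelResult:
    """Fit one predictor family against one response at a given order.

    ``family`` may also be a single predictor name, in which case
    ``order='individual'`` is implied (simple linear regression).
    Complete cases only; AIC is ``n·ln(RSS/n) + 2k`` with ``k`` counting
    the intercept, the slope terms and the error variance.
    """
    import statsmodels.api as sm

    if family in FAMILIES:
        members = FAMILIES[family]
        if order == "individual":
            raise ValueError("individual order needs a single predictor name")
    else:
        members = (family,)
        order = "individual"

    table = derive_difference_columns(table)
    cc = table[list(members) + [response]].dropna()
    n = len(cc)
    n_terms = {"individual": 1, "zeroth": 4, "first": 6, "higher": 5}[order]
    if n < n_terms + 2:
        raise ValueError(f"only {n} complete cases for {family}/{response}")

    Z = cc[list(members)].apply(zscore)
    y = zscore(cc[response].to_numpy())
    if order == "individual":
        X, names = Z[members[0]].to_numpy()[:, None], [members[0]]
    else:
        X, names = _design(Z, members, order)

    Xc = sm.add_constant(X, has_constant="add")
    rank_deficient = np.linalg.matrix_rank(Xc) < Xc.shape[1]
    res = sm.OLS(y, Xc).fit()

    rss = float(np.sum(res.resid ** 2))
    k = X.shape[1] + 2  # slopes + intercept + error variance
    aic = float(n * np.log(rss / n) + 2 * k) if rss > 0 else -np.inf
    if rank_deficient:
        aic = float("nan")
    model_p = float(res.f_pvalue) if np.isfinite(res.f_pvalue) else float("nan")
    coef = pd.Series(res.params[1:], index=names)
    coef_p = pd.Series(res.pvalues[1:], index=names)
    return ModelResult(family=family, response=response, model_order=order,
                       r_squared=float(res.rsquared), aic=aic,
                       model_p=model_p, coefficients=coef,
                       coefficient_p=coef_p, n_obs=n,
                       rank_deficient=rank_deficient)


def anova_aperiodic(values: np.ndarray, stream: np.ndarray,
                    subregion: np.ndarray) -> dict:
    """Two-factor ANOVA (signal × subregion, Type II sums of squares, with
    interaction) of an aperiodic parameter, plus a Bonferroni-corrected
    pairwise rank-sum table over the six (stream, subregion) cells."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = pd.DataFrame({"value": np.asarray(values, float),
                       "stream": np.asarray(stream),
                       "subregion": np.asarray(subregion)})
    counts = df.groupby(["stream", "subregion"]).size()
    if counts.empty or (counts < 2).any() or len(counts) < 4:
        raise ValueError("each (stream, subregion) cell needs >= 2 values")

    model = ols("value ~ C(stream) * C(subregion)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    ps = {
        "p_signal": float(tab.loc["C(stream)", "PR(>F)"]),
        "p_subregion": float(tab.loc["C(subregion)", "PR(>F)"]),
        "p_interaction": float(tab.loc["C(stream):C(subregion)", "PR(>F)"]),
    }

    cells = {key: g["value"].to_numpy()
             for key, g in df.groupby(["stream", "subregion"])}
    pairs = list(itertools.combinations(sorted(cells), 2))
    rows = []
    for a, b in pairs:
        stat, p = sst.ranksums(cells[a], cells[b])
        rows.append({"cell_a": "/".join(a), "cell_b": "/".join(b),
                     "statistic": float(stat), "p_raw": float(p),
                     "p_bonferroni": float(min(1.0, p * len(pairs)))})
    ps["posthoc"] = pd.DataFrame(rows)
    return ps


def spearman_with_shuffle(x: np.ndarray, y: np.ndarray, n_shuffle: int = 100,
                          rng: np.random.Generator | None = None) -> dict:
    """Spearman rho of paired values plus its permutation-null distribution
    (one member shuffled ``n_shuffle`` times)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 pairs")
    rng = rng or np.random.default_rng()
    rho, p = sst.spearmanr(x, y)
    null = np.empty(n_shuffle)
    for i in range(n_shuffle):
        null[i] = sst.spearmanr(x, rng.permutation(y))[0]
    return {"rho": float(rho), "p": float(p), "null_rho": null,
            "null_mean": float(null.mean()), "null_sd": float(null.std(ddof=1))}


def pointwise_psd_test(group_a: np.ndarray, group_b: np.ndarray,
                       correction_groups: int = 3, alpha: float = 0.05
                       ) -> dict:
    """Two-tailed Wilcoxon rank-sum per frequency bin with a Bonferroni
    threshold of ``alpha / correction_groups``.

    ``group_a`` / ``group_b`` are (n_samples, n_freqs) arrays.  Bins with
    fewer than two samples in either group are untestable (NaN p, masked).
    """
    A = np.atleast_2d(np.asarray(group_a, float))
    B = np.atleast_2d(np.asarray(group_b, float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups must share the frequency grid")
    nf = A.shape[1]
    pvals = np.full(nf, np.nan)
    for j in range(nf):
        a = A[:, j][~np.isnan(A[:, j])]
        b = B[:, j][~np.isnan(B[:, j])]
        if a.size >= 2 and b.size >= 2:
            pvals[j] = sst.ranksums(a, b)[1]
    threshold = alpha / correction_groups
    mask = np.zeros(nf, bool)
    ok = ~np.isnan(pvals)
    mask[ok] = pvals[ok] < threshold
    return {"p_values": pvals, "significant": mask,
            "untestable": ~ok, "threshold": threshold}
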