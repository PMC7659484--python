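"""Pairwise condition comparisons and factorial interaction ANOVA.

Two statistical layers sit on top of the normalized growth rates:

* all-pairs two-sided t-tests using a standard deviation pooled across *all*
  conditions (the semantics of R's ``pairwise.t.test`` with ``pool.sd=TRUE``),
  with Shapiro-Wilk / Bartlett diagnostics and a compact letter display for
  plotting, and
* a three-factor factorial ANOVA ``response ~ il2 * il7 * il15`` with each
  cytokine dose entering as a single-df numeric covariate and Type I
  (sequential) sums of squares, the behaviour of R's ``aov``.

No multiplicity adjustment is applied to the pairwise matrix by default;
Holm and Benjamini-Hochberg adjustments are available via ``adjust``.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

ANOVA_TERMS = (
    "il2",
    "il7",
    "il15",
    "il2:il7",
    "il2:il15",
    "il7:il15",
    "il2:il7:il15",
    "Residuals",
)


def _as_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    out = {}
    for name, values in groups.items():
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise ValueError(f"condition {name!r} needs >= 2 observations")
        out[str(name)] = arr
    if len(out) < 2:
        raise ValueError("need >= 2 conditions")
    return out


def groups_from_table(table: pd.DataFrame, value: str = "normalized_rate") -> dict:
    """Condition -> replicate vector (one value per dataset) from a rate table."""
    return {key: sub[value].to_numpy(dtype=float) for key, sub in table.groupby("key")}


def pooled_sd(groups: Mapping[str, Sequence[float]]) -> tuple[float, int]:
    """Pooled SD across all groups and its residual df (N - k)."""
    gs = _as_groups(groups)
    sq = sum(np.sum((g - g.mean()) ** 2) for g in gs.values())
    df = sum(g.size for g in gs.values()) - len(gs)
    sd = float(np.sqrt(sq / df))
    return sd, df


def pairwise_t_tests(
    groups: Mapping[str, Sequence[float]], adjust: str = "none"
) -> pd.DataFrame:
    """Symmetric matrix of two-sided p-values for all condition pairs.

    The t statistic for pair (i, j) uses the SD pooled over *all* conditions:
    t = (mean_i - mean_j) / (s_p * sqrt(1/n_i + 1/n_j)), df = N - k.
    ``adjust`` in {"none", "holm", "bh"} applies a multiplicity correction to
    the strictly-lower-triangle p-values.
    """
    gs = _as_groups(groups)
    sd, df = pooled_sd(gs)
    if sd == 0:
        raise ValueError("pooled SD is 0; pairwise t-tests undefined")
    names = list(gs)
    k = len(names)
    pmat = np.full((k, k), np.nan)
    pairs, raw = [], []
    for i in range(k):
        for j in range(i):
            gi, gj = gs[names[i]], gs[names[j]]
            t = (gi.mean() - gj.mean()) / (sd * np.sqrt(1 / gi.size + 1 / gj.size))
            p = 2.0 * scipy.stats.t.sf(abs(t), df)
            pairs.append((i, j))
            raw.append(p)
    if adjust != "none":
        method = {"holm": "holm", "bh": "fdr_bh"}.get(adjust)
        if method is None:
            raise ValueError(f"unknown adjustment {adjust!r}")
        raw = list(multipletests(raw, method=method)[1])
    for (i, j), p in zip(pairs, raw):
        pmat[i, j] = pmat[j, i] = min(float(p), 1.0)
    return pd.DataFrame(pmat, index=names, columns=names)


def normality_and_variance_checks(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> dict:
    """Shapiro-Wilk on pooled within-group residuals; Bartlett across groups.

    Advisory diagnostics: failures raise a warning, never an exception.
    """
    gs = _as_groups(groups)
    residuals = np.concatenate([g - g.mean() for g in gs.values()])
    if np.allclose(residuals, residuals[0]):
        raise ValueError("all residuals identical; diagnostics undefined")
    w_stat, w_p = scipy.stats.shapiro(residuals)
    b_stat, b_p = scipy.stats.bartlett(*gs.values())
    result = {
        "shapiro_w": float(w_stat),
        "shapiro_p": float(w_p),
        "shapiro_ok": bool(w_p >= alpha),
        "bartlett_k2": float(b_stat),
        "bartlett_p": float(b_p),
        "bartlett_ok": bool(b_p >= alpha),
    }
    if not result["shapiro_ok"]:
        warnings.warn(f"Shapiro-Wilk normality check failed (p={w_p:.3g})")
    if not result["bartlett_ok"]:
        warnings.warn(f"Bartlett homogeneity check failed (p={b_p:.3g})")
    return result


def factorial_anova(
    data: pd.DataFrame,
    response: str = "normalized_rate",
    categorical: bool = False,
) -> pd.DataFrame:
    """Type I (sequential) factorial ANOVA for response ~ il2 * il7 * il15.

    Doses enter as numeric covariates (1 df per term) by default, giving the
    8-row table (three mains, three 2-way interactions, the 3-way interaction,
    residuals).  ``categorical=True`` treats each dose as a factor instead.
    """
    for col in ("il2", "il7", "il15", response):
        if col not in data.columns:
            raise ValueError(f"missing column {col!r}")
    for col in ("il2", "il7", "il15"):
        if np.ptp(data[col].to_numpy(dtype=float)) == 0:
            raise ValueError(f"term {col!r} is constant; design is rank-deficient")
    if categorical:
        formula = f"{response} ~ C(il2) * C(il7) * C(il15)"
    else:
        formula = f"{response} ~ il2 * il7 * il15"
    model = smf.ols(formula, data=data).fit()
    if not categorical and model.df_resid > 0 and np.linalg.matrix_rank(
        model.model.exog
    ) < model.model.exog.shape[1]:
        raise ValueError("model matrix is rank-deficient")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-residual fits divide by 0
        table = sm.stats.anova_lm(model, typ=1)
    table = table.rename(
        index=lambda s: s.replace("C(", "").replace(")", "").replace("Residual", "Residuals")
    )
    table = table.rename(
        columns={"df": "Df", "sum_sq": "Sum Sq", "mean_sq": "Mean Sq",
                 "F": "F value", "PR(>F)": "Pr(>F)"}
    )
    if not categorical:
        table = table.loc[list(ANOVA_TERMS)]
    return table


def compact_letter_display(
    pmat: pd.DataFrame, alpha: float = 0.05, order: Sequence[str] | None = None
) -> dict[str, str]:
    """Insert-and-absorb compact letter display from a symmetric p matrix.

    Two conditions share at least one letter iff their pairwise p >= alpha.
    ``order`` fixes the letter-assignment order (e.g. descending mean rate so
    the top group reads 'a'); default is matrix order.
    """
    names = list(pmat.index)
    if order is not None:
        if set(order) != set(names):
            raise ValueError("order must be a permutation of the matrix index")
        names = list(order)
    columns: list[set[str]] = [set(names)]
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if float(pmat.loc[a, b]) < alpha:  # significant: a and b must split
                new_cols: list[set[str]] = []
                for col in columns:
                    if a in col and b in col:
                        new_cols.extend([col - {a}, col - {b}])
                    else:
                        new_cols.append(col)
                # absorb columns contained in another; drop duplicates/empties
                new_cols = [c for c in new_cols if c]
                keep: list[set[str]] = []
                for c in new_cols:
                    if not any(c < d or (c == d and c in keep) for d in new_cols):
                        if c not in keep:
                            keep.append(c)
                columns = keep
    # stable letter order: column rank = first member's position in `names`
    columns.sort(key=lambda col: min(names.index(m) for m in col))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {name: "" for name in names}
    for idx, col in enumerate(columns):
        letter = (
            alphabet[idx]
            if idx < len(alphabet)
            else alphabet[idx // 26 - 1] + alphabet[idx % 26]
        )
        for name in names:
            if name in col:
                letters[name] += letter
    return letters


def write_pvalue_matrix(pmat: pd.DataFrame, path) -> None:
    pmat.to_csv(path, sep="\t")


def write_anova_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


def write_letters(letters: Mapping[str, str], path) -> None:
    pd.Series(dict(letters), name="letters").rename_axis("key").to_csv(path, sep="\t")
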