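"""Group-level inference: factorial ANOVA, summary-statistics ANOVA, and
ANCOVA with backward elimination.

The study design is a balanced 2x2 factorial (aspirin level x breed, n
animals per cell).  Each outcome (urinary Co excretion, serum markers) is
analyzed by OLS ANOVA for the two main effects and their interaction.  The
relation of serum markers to quantified Co excretion is analyzed by ANCOVA
starting from the full factorial-by-covariate model and removing
nonsignificant terms backward, highest order first, respecting marginality.

``anova_from_summary`` reconstructs the balanced ANOVA from cell means and
the pooled SEM of a cell mean alone (MSE = n * SEM^2), which lets published
tables be re-analyzed without raw data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "LinearModelTable",
    "AncovaResult",
    "factorial_anova",
    "anova_from_summary",
    "ancova_stepwise",
]


@dataclass
class LinearModelTable:
    """Term-level ANOVA results for one response."""

    response: str
    terms: list[tuple[str, int, float, float, float]]  # (name, df, SS, F, p)
    df_error: int
    mse: float
    cell_means: dict[str, float]
    sem: float | None  # pooled SEM of a cell mean; balanced designs only

    def p_value(self, term: str) -> float:
        for name, _, _, _, p in self.terms:
            if name == term:
                return p
        raise KeyError(f"no term {term!r} in table for {self.response!r}")

    def f_value(self, term: str) -> float:
        for name, _, _, f, _ in self.terms:
            if name == term:
                return f
        raise KeyError(f"no term {term!r} in table for {self.response!r}")


@dataclass
class AncovaResult:
    response: str
    elimination_path: list[tuple[str, float]]  # (term dropped, p at drop)
    final_terms: list[tuple[str, float, float]]  # (term, F, p)
    slope: float | None  # covariate coefficient in the final model, if retained

    def retained(self, term: str) -> bool:
        return any(name == term for name, _, _ in self.final_terms)


def _check_two_by_two(data: pd.DataFrame, factor_a: str, factor_b: str) -> None:
    for f in (factor_a, factor_b):
        if data[f].nunique() != 2:
            raise ValueError(f"factor {f!r} must have exactly 2 levels")
    counts = data.groupby([factor_a, factor_b], observed=True).size()
    if len(counts) < 4:
        present = set(counts.index)
        levels_a, levels_b = sorted(data[factor_a].unique()), sorted(data[factor_b].unique())
        missing = [(a, b) for a in levels_a for b in levels_b if (a, b) not in present]
        raise ValueError(f"empty design cell(s): {missing}")


def factorial_anova(
    data: pd.DataFrame,
    response: str,
    factor_a: str = "aspirin",
    factor_b: str = "breed",
) -> LinearModelTable:
    """Two-way factorial ANOVA of ``response`` on two 2-level factors.

    OLS fit of response ~ A + B + A:B with term F-tests against the residual
    mean square (type II sums of squares, identical to type I/III in the
    balanced case).
    """
    _check_two_by_two(data, factor_a, factor_b)
    df = data[[response, factor_a, factor_b]].copy()
    formula = f"{response} ~ C({factor_a}) * C({factor_b})"
    model = smf.ols(formula, data=df).fit()
    if model.df_resid <= 0:
        raise ValueError("zero residual degrees of freedom: one observation per cell")
    if np.allclose(model.resid, 0) and np.allclose(df[response], df[response].iloc[0]):
        # all observations identical: define F = 0, p = 1 for every term
        terms = [
            (name, 1, 0.0, 0.0, 1.0)
            for name in (f"C({factor_a})", f"C({factor_b})", f"C({factor_a}):C({factor_b})")
        ]
        cm = df.groupby([factor_a, factor_b], observed=True)[response].mean()
        return LinearModelTable(
            response=response,
            terms=terms,
            df_error=int(model.df_resid),
            mse=0.0,
            cell_means={f"{a}|{b}": float(v) for (a, b), v in cm.items()},
            sem=0.0,
        )
    tab = anova_lm(model, typ=2)
    mse = float(tab.loc["Residual", "sum_sq"] / tab.loc["Residual", "df"])
    terms = []
    for name, row in tab.iterrows():
        if name == "Residual":
            continue
        terms.append(
            (name, int(row["df"]), float(row["sum_sq"]), float(row["F"]), float(row["PR(>F)"]))
        )
    cm = df.groupby([factor_a, factor_b], observed=True)[response].mean()
    sizes = df.groupby([factor_a, factor_b], observed=True).size()
    sem = float(np.sqrt(mse / sizes.iloc[0])) if sizes.nunique() == 1 else None
    return LinearModelTable(
        response=response,
        terms=terms,
        df_error=int(tab.loc["Residual", "df"]),
        mse=mse,
        cell_means={f"{a}|{b}": float(v) for (a, b), v in cm.items()},
        sem=sem,
    )


def anova_from_summary(
    cell_means: np.ndarray,
    sem: float,
    n_per_cell: int,
    response: str = "response",
    factor_a: str = "aspirin",
    factor_b: str = "breed",
) -> LinearModelTable:
    """Reconstruct the balanced 2x2 ANOVA from cell means and pooled SEM.

    ``cell_means`` is a 2x2 array with factor B (e.g. breed) on rows and
    factor A (e.g. aspirin) on columns — i.e. flat order (B0A0, B0A1, B1A0,
    B1A1), matching the usual published-table layout.  The pooled SEM of a
    cell mean yields MSE = n_per_cell * sem^2 and df_error = 4*(n-1), which
    together with the balanced sums-of-squares formulas gives exact F and p
    for both main effects and the interaction; raw data are not needed.
    """
    if n_per_cell < 2:
        raise ValueError("n_per_cell must be >= 2")
    if sem <= 0:
        raise ValueError("sem must be > 0")
    m = np.asarray(cell_means, dtype=float).reshape(2, 2)
    n = int(n_per_cell)
    mse = n * sem**2
    df_error = 4 * (n - 1)
    grand = m.mean()
    ss_a = 2 * n * float(((m.mean(axis=0) - grand) ** 2).sum())  # column margins
    ss_b = 2 * n * float(((m.mean(axis=1) - grand) ** 2).sum())  # row margins
    contrast = float(m[0, 0] - m[0, 1] - m[1, 0] + m[1, 1])
    ss_ab = n * contrast**2 / 4
    terms = []
    for name, ss in (
        (f"C({factor_a})", ss_a),
        (f"C({factor_b})", ss_b),
        (f"C({factor_a}):C({factor_b})", ss_ab),
    ):
        f_stat = ss / mse if mse > 0 else 0.0
        p = float(stats.f.sf(f_stat, 1, df_error)) if mse > 0 else 1.0
        terms.append((name, 1, ss, f_stat, p))
    labels = [f"{b}|{a}" for b in ("B0", "B1") for a in ("A0", "A1")]
    return LinearModelTable(
        response=response,
        terms=terms,
        df_error=df_error,
        mse=mse,
        cell_means=dict(zip(labels, m.ravel())),
        sem=float(sem),
    )


# --- ANCOVA with backward elimination --------------------------------------

def _term_factors(term: str) -> frozenset[str]:
    return frozenset(term.split(":"))


def _contained_in_retained(term: str, retained: list[str]) -> bool:
    tf = _term_factors(term)
    return any(tf < _term_factors(other) for other in retained if other != term)


def ancova_stepwise(
    data: pd.DataFrame,
    response: str,
    covariate: str = "co_excretion",
    factor_a: str = "aspirin",
    factor_b: str = "breed",
    alpha: float = 0.05,
) -> AncovaResult:
    """ANCOVA of ``response`` with backward elimination of nonsignificant terms.

    Starts from the full model A * B * covariate (all terms up to the 3-way
    interaction) with type II sums of squares.  At each step the droppable
    term — one not marginal to any retained higher-order term — with the
    largest p-value is removed if p > alpha; elimination stops when every
    droppable term is significant.  The reported slope is the covariate's
    coefficient in the final model (None if the covariate was eliminated).
    """
    if data[covariate].nunique() < 2:
        raise ValueError(f"covariate {covariate!r} must take at least 2 distinct values")
    _check_two_by_two(data, factor_a, factor_b)
    A, B, X = f"C({factor_a})", f"C({factor_b})", covariate
    terms = [A, B, X, f"{A}:{B}", f"{A}:{X}", f"{B}:{X}", f"{A}:{B}:{X}"]
    path: list[tuple[str, float]] = []

    while True:
        formula = f"{response} ~ " + (" + ".join(terms) if terms else "1")
        model = smf.ols(formula, data=data).fit()
        if model.df_resid <= 0 or np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
            aliased = [t for t in terms]
            raise ValueError(f"rank-deficient ANCOVA model; check terms {aliased}")
        if not terms:
            break
        tab = anova_lm(model, typ=2)
        droppable = [t for t in terms if not _contained_in_retained(t, terms)]
        p_vals = {t: float(tab.loc[t, "PR(>F)"]) for t in droppable}
        # drop the highest-order nonsignificant term with the largest p
        worst = None
        max_order = max(len(_term_factors(t)) for t in droppable)
        for order in range(max_order, 0, -1):
            cands = [t for t in droppable
                     if len(_term_factors(t)) == order and p_vals[t] > alpha]
            if cands:
                worst = max(cands, key=lambda t: p_vals[t])
                break
        if worst is None:
            break
        path.append((worst, p_vals[worst]))
        terms.remove(worst)

    final: list[tuple[str, float, float]] = []
    if terms:
        model = smf.ols(f"{response} ~ " + " + ".join(terms), data=data).fit()
        tab = anova_lm(model, typ=2)
        final = [(t, float(tab.loc[t, "F"]), float(tab.loc[t, "PR(>F)"])) for t in terms]
        slope = float(model.params[covariate]) if covariate in terms else None
    else:
        slope = None
    return AncovaResult(
        response=response, elimination_path=path, final_terms=final, slope=slope
    )
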