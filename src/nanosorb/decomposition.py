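"""Thermodynamic and per-term decomposition of adsorption free energy.

Two exact identities split the aqueous adsorption free energy:

* enthalpy/entropy: ``ΔG_aq = E_ad − TΔS`` with the DFT adsorption
  energy ``E_ad`` standing in for the enthalpy, hence
  ``TΔS = E_ad − ΔG_aq``;
* solvent: ``ΔG_aq = ΔG_H2O + ΔG_gas`` with
  ``ΔG_H2O = ΔG_aq − ΔG_gas`` the (typically positive) water-cavity
  cost of adsorption from solution.

On top of these, pp-LFER models fitted to each quantity are decomposed
term by term: the contribution of descriptor term ``j`` for a compound
is the signed fraction ``coefficient_j·descriptor_j`` over the model's
six-term sum (five descriptor terms plus intercept), averaged over
compounds and reported in percent.  For the entropic/enthalpic and
water/gaseous columns of the aggregate report, contributions are
instead referenced against a common denominator — the direct logK
model's prediction — scaled by ±1/(2.303RT), so that paired columns
approximately add up to the direct logK contribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .lfer import PPLFERModel, predict

__all__ = [
    "TERM_LABELS",
    "ContributionColumn",
    "Table1Report",
    "decompose_entropy",
    "decompose_water",
    "term_contributions",
    "aggregate_table1_report",
]

#: Field-standard labels for coefficient·descriptor products.
TERM_LABELS = {"E": "eE", "S": "sS", "A": "aA", "B": "bB", "V": "vV", "L": "lL"}

_CANONICAL_TERM_ORDER = ("eE", "sS", "aA", "bB", "vV", "lL", "intercept")


class DecompositionInputError(ValueError):
    pass


@dataclass
class ContributionColumn:
    """Mean percentage contribution of each model term for one target."""

    name: str
    fractions: pd.Series  # index: term labels (eE … intercept), values: %
    n_compounds: int
    n_excluded: int

    @property
    def explicit_sum(self) -> float:
        """Sum over the five explicit descriptor terms (intercept excluded)."""
        explicit = [t for t in self.fractions.index if t != "intercept"]
        return float(self.fractions[explicit].sum())


@dataclass
class Table1Report:
    """Aggregated contribution report with a sum row and diagnostics."""

    table: pd.DataFrame  # rows: terms (+ 'sum'), columns: targets, cells: %
    diagnostics: pd.DataFrame | None = None


def _require_pairs(df: pd.DataFrame, cols: Sequence[str]) -> None:
    missing_cols = [c for c in cols if c not in df.columns]
    if missing_cols:
        raise DecompositionInputError(f"missing column(s) {missing_cols}")
    bad = df.index[df[list(cols)].isna().any(axis=1)].tolist()
    if bad:
        raise DecompositionInputError(
            f"missing values for compounds {bad} in columns {list(cols)}"
        )


def decompose_entropy(records: pd.DataFrame) -> pd.DataFrame:
    """Add the entropic term ``t_delta_s = e_ad_aqueous − delta_g_aqueous``.

    Expects columns ``delta_g_aqueous`` and ``e_ad_aqueous`` (kcal/mol),
    one row per compound; returns a copy with ``t_delta_s`` so that the
    identity ``ΔG = E_ad − TΔS`` holds exactly.
    """
    _require_pairs(records, ("delta_g_aqueous", "e_ad_aqueous"))
    out = records.copy()
    out["t_delta_s"] = out["e_ad_aqueous"] - out["delta_g_aqueous"]
    return out


def decompose_water(records: pd.DataFrame) -> pd.DataFrame:
    """Add the solvent term ``delta_g_h2o = delta_g_aqueous − delta_g_gaseous``.

    Water impedes adsorption, so the term is typically positive.
    """
    _require_pairs(records, ("delta_g_aqueous", "delta_g_gaseous"))
    out = records.copy()
    out["delta_g_h2o"] = out["delta_g_aqueous"] - out["delta_g_gaseous"]
    return out


def term_contributions(
    model: PPLFERModel,
    table: pd.DataFrame,
    name: str | None = None,
    denominator_model: PPLFERModel | None = None,
    scale: float = 1.0,
    eps: float = 1e-6,
) -> ContributionColumn:
    """Mean signed per-term percentage contributions of a pp-LFER model.

    For each compound, term ``j`` contributes
    ``scale·(coefficient_j·descriptor_j) / D`` where ``D`` is the
    six-term sum (prediction) of ``denominator_model`` — by default the
    model itself, giving self-normalized fractions that sum to exactly
    100 % per compound.  Compounds with ``|D| < eps`` are excluded with
    a warning.  Cell values are means over compounds × 100 %.
    """
    denom_model = denominator_model or model
    denom = np.asarray(predict(denom_model, table), dtype=float)
    keep = np.abs(denom) >= eps
    n_excluded = int((~keep).sum())
    if n_excluded:
        warnings.warn(
            f"{n_excluded} compound(s) excluded from contribution averaging "
            f"(six-term sum within {eps} of zero)",
            UserWarning,
            stacklevel=2,
        )
    labels = [TERM_LABELS[d] for d in model.descriptor_set] + ["intercept"]
    terms = np.column_stack(
        [
            model.coefficients[d] * table[d].to_numpy(dtype=float)
            for d in model.descriptor_set
        ]
        + [np.full(len(table), model.intercept)]
    )
    fracs = scale * terms[keep] / denom[keep, None]
    mean_pct = pd.Series(fracs.mean(axis=0) * 100.0, index=labels)
    return ContributionColumn(
        name=name or model.endpoint,
        fractions=mean_pct,
        n_compounds=int(keep.sum()),
        n_excluded=n_excluded,
    )


def aggregate_table1_report(columns: Iterable[ContributionColumn]) -> Table1Report:
    """Assemble contribution columns into the standard report shape.

    Rows are the explicit descriptor terms (plus ``intercept`` where
    present) and a ``sum`` row over the five explicit terms only.  All
    columns must share the same explicit term set.

    When both decompositions of logK are present, per-term consistency
    diagnostics are emitted: ``(TdS + Ead_enthalpic) − logK`` and
    ``(dG_H2O + dG_gaseous) − logK`` — expected small but nonzero,
    since each column comes from its own fit.
    """
    cols = list(columns)
    if not cols:
        raise ValueError("no contribution columns given")
    explicit_sets = [
        tuple(t for t in c.fractions.index if t != "intercept") for c in cols
    ]
    if len(set(explicit_sets)) != 1:
        raise DecompositionInputError(
            f"columns have mismatched term sets: {sorted(set(explicit_sets))}"
        )
    order = [t for t in _CANONICAL_TERM_ORDER if t in cols[0].fractions.index]
    table = pd.DataFrame({c.name: c.fractions.reindex(order) for c in cols})
    explicit = [t for t in order if t != "intercept"]
    table.loc["sum"] = table.loc[explicit].sum()
    table.index.name = "term"

    diagnostics = None
    diag = {}
    if {"TdS", "Ead_enthalpic", "logK"} <= set(table.columns):
        diag["enthalpic_plus_entropic_minus_logK"] = (
            table.loc[explicit, "TdS"]
            + table.loc[explicit, "Ead_enthalpic"]
            - table.loc[explicit, "logK"]
        )
    if {"dG_H2O", "dG_gaseous", "logK"} <= set(table.columns):
        diag["water_plus_gaseous_minus_logK"] = (
            table.loc[explicit, "dG_H2O"]
            + table.loc[explicit, "dG_gaseous"]
            - table.loc[explicit, "logK"]
        )
    if diag:
        diagnostics = pd.DataFrame(diag)
        diagnostics.index.name = "term"
    return Table1Report(table=table, diagnostics=diagnostics)
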