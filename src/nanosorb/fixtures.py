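"""Packaged reference fixtures.

Three small JSON resources ship with the package:

* the four BP pp-LFER models (logK and |E_ad|, gaseous and aqueous)
  with their reported validation statistics,
* the comparison table of literature pp-LFER models for carbon
  nanomaterials and this study's BP/graphene models,
* the reference per-term contribution percentages of intermolecular
  interactions to BP adsorption in the aqueous phase.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .lfer import PPLFERModel

__all__ = [
    "reference_models",
    "literature_models",
    "table1_reference",
    "table1_reference_columns",
]


def _load(name: str):
    with resources.files("nanosorb.data").joinpath(name).open() as fh:
        return json.load(fh)


def reference_models() -> dict[str, PPLFERModel]:
    """The four packaged BP pp-LFER models keyed by endpoint name.

    The reported validation statistics are attached as ``model.stats``.
    """
    raw = _load("bp_pplfer_models.json")
    out: dict[str, PPLFERModel] = {}
    for key, entry in raw.items():
        stats = entry.pop("stats", None)
        model = PPLFERModel(source="reference", **entry)
        model.stats = stats  # reported, not recomputed
        out[key] = model
    return out


def literature_models() -> list[dict]:
    """Raw rows of the literature-comparison table (list of dicts).

    Rows with ``abraham: false`` use a non-Abraham descriptor basis and
    are stored verbatim as an equation string.
    """
    return _load("literature_models.json")


def table1_reference() -> pd.DataFrame:
    """Reference contribution table as a DataFrame (terms × columns, %).

    Includes the ``sum`` row over the five explicit descriptor terms.
    """
    raw = _load("table1_contributions.json")
    df = pd.DataFrame(raw["columns"]).reindex(raw["terms"])
    df.loc["sum"] = pd.Series(raw["sum_row"])
    df.index.name = "term"
    return df


def table1_reference_columns():
    """Reference cells as ContributionColumn objects (without the sum row)."""
    from .decomposition import ContributionColumn

    raw = _load("table1_contributions.json")
    cols = []
    for name, cells in raw["columns"].items():
        cols.append(
            ContributionColumn(
                name=name,
                fractions=pd.Series(cells, dtype=float).reindex(raw["terms"]),
                n_compounds=0,
                n_excluded=0,
            )
        )
    return cols
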