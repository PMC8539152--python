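"""Additive evaluation of the heat of combustion and formation.

The heat of combustion is the plain sum over the decomposition

    dHc = sum_i a_i * A_i  +  sum_j b_j * B_j

with `a_i`, `b_j` the tabulated contributions of the ordinary atom groups and
geometric special groups and `A_i`, `B_j` their occurrence counts.  In strict
mode a prediction is refused (``computable=False``) when any required atom
group is unknown or not valid (supported by fewer than three training
molecules); lenient mode sums what it can and reports the blockers.

The heat of formation follows by Hess's law from the combustion enthalpies
of the elements:  dHf = sum_e n_e * c_e - dHc.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from . import graph as g
from .graph import Molecule
from .groups import Decomposition, GroupDecomposer, GroupKey, decompose
from .table import ContributionTable, ElementCombustionTable, load_table

KCAL_TO_KJ = 4.1858


def kcal_to_kj(x: float) -> float:
    """Convert kcal/mol to kJ/mol (exact factor 4.1858)."""
    return x * KCAL_TO_KJ


def round_report(x: float, ndigits: int = 1) -> float:
    """Reporting precision: round-half-even at 0.1 kJ/mol by default."""
    return round(x, ndigits)


@dataclass
class Prediction:
    hc: float
    hf: Optional[float] = None
    per_group_terms: list[tuple[GroupKey, int, Optional[float], float]] = field(default_factory=list)
    computable: bool = True
    blockers: list[GroupKey] = field(default_factory=list)

    @property
    def hc_rounded(self) -> float:
        return round_report(self.hc)


def predict_hc(decomp: Decomposition, table: ContributionTable,
               strict: bool = True) -> Prediction:
    """Evaluate the group sum for one decomposition."""
    terms: list[tuple[GroupKey, int, Optional[float], float]] = []
    blockers: list[GroupKey] = []
    total = 0.0
    items = list(decomp.ordinary.items()) + list(decomp.special.items())
    for key, count in items:
        entry = table.get(key)
        if entry is None or not table.usable(key):
            blockers.append(key)
            value = None if entry is None else entry.value
            product = 0.0 if value is None else count * value
        else:
            value = entry.value
            product = count * value
        terms.append((key, count, value, product))
        if value is not None:
            total += product
    if decomp.uncovered_atoms:
        blockers.append(GroupKey("<uncovered atoms>", str(decomp.uncovered_atoms)))
    computable = not blockers and bool(items)
    if strict and blockers:
        return Prediction(hc=total, per_group_terms=terms, computable=False,
                          blockers=blockers)
    return Prediction(hc=total, per_group_terms=terms, computable=computable,
                      blockers=blockers)


def predict_hf(hc: float, formula: dict[str, int],
               constants: Optional[ElementCombustionTable] = None) -> float:
    """Heat of formation from a heat of combustion by Hess's law."""
    if constants is None:
        constants = ElementCombustionTable.load()
    total = sum(n * constants.value(el) for el, n in formula.items())
    return total - hc


class GroupAdditivityPredictor(RegressorMixin, BaseEstimator):
    """Estimator-style front end: molecules in, heats of combustion out.

    The predictor is born fitted (its parameters are the packaged
    contribution table); ``fit`` only validates and stores the table.

    Parameters
    ----------
    table : ContributionTable, optional
        Contribution set; the packaged table by default.
    strict : bool
        Refuse predictions involving unknown or invalid groups.
    geometry_policy : {"topology_only", "use_3d"}
        Special-group assignment mode.
    zwitterion_policy : {"as_drawn", "auto"}
        Structural normalization of acid/base pairs.
    with_hf : bool
        Also compute the heat of formation (requires supported elements).
    """

    def __init__(self, table: Optional[ContributionTable] = None, strict: bool = True,
                 geometry_policy: str = "topology_only",
                 zwitterion_policy: str = "as_drawn", with_hf: bool = False):
        self.table = table
        self.strict = strict
        self.geometry_policy = geometry_policy
        self.zwitterion_policy = zwitterion_policy
        self.with_hf = with_hf

    def fit(self, X=None, y=None):
        self.table_ = self.table if self.table is not None else load_table()
        self.constants_ = ElementCombustionTable.load()
        return self

    def _ensure_fitted(self):
        if not hasattr(self, "table_"):
            self.fit()

    def predict_one(self, item: Union[str, Molecule]) -> Prediction:
        self._ensure_fitted()
        mol = g.parse_smiles(item) if isinstance(item, str) else item
        mol = g.normalize_conventions(mol, self.zwitterion_policy)
        decomp = decompose(mol, table=self.table_,
                           geometry_policy=self.geometry_policy)
        pred = predict_hc(decomp, self.table_, strict=self.strict)
        if self.with_hf and pred.computable:
            heavy = {el: n for el, n in mol.formula().items()}
            pred.hf = predict_hf(pred.hc, heavy, self.constants_)
        return pred

    def predict(self, X: Sequence[Union[str, Molecule]]) -> np.ndarray:
        """Heats of combustion (kJ/mol); NaN where not computable."""
        out = np.full(len(X), np.nan)
        for k, item in enumerate(X):
            pred = self.predict_one(item)
            if pred.computable or not self.strict:
                out[k] = pred.hc
        return out
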