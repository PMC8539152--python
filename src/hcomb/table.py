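"""Packaged group-contribution table and element combustion constants.

The 390-row contribution table is shipped verbatim as TSV (iodine spelled
``J``, exactly as in the published grammar) together with a SHA-256 checksum
so a corrupted transcription fails loudly.  A contribution is *valid* when it
was supported by at least ``min_molecules`` independent training molecules;
only valid atom groups may be used for prediction.  The table's own
bookkeeping of prediction-usable groups counts ordinary atom groups only
(the geometric special groups are exempt from the validity rule) and skips
placeholder rows whose printed contribution is exactly zero, which yields
the published count of 267.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
import yaml

from .errors import DataIntegrityError, ElementNotSupported
from .groups import GroupKey

#: SHA-256 of the packaged contribution TSV
TABLE4_SHA256 = "55e73d02eaba3ae479a64270949ea32cc002159183f12a941d9f8d8cc6d7023b"
TABLE4_N_ENTRIES = 390
DEFAULT_MIN_MOLECULES = 3


@dataclass(frozen=True)
class GroupContribution:
    key: GroupKey
    value: float  # kJ/mol
    occurrences: int
    molecules: int
    valid: bool

    @property
    def is_placeholder(self) -> bool:
        """Rows printed with a contribution of exactly 0 were never fitted."""
        return self.value == 0.0


class ContributionTable:
    """Immutable mapping from :class:`GroupKey` to its fitted contribution."""

    def __init__(self, entries: Iterable[GroupContribution],
                 min_molecules: int = DEFAULT_MIN_MOLECULES,
                 checksum: Optional[str] = None):
        self._entries = {e.key: e for e in entries}
        self.min_molecules = min_molecules
        self.checksum = checksum

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, key: GroupKey) -> bool:
        return key in self._entries

    def __iter__(self):
        return iter(self._entries.values())

    def keys(self):
        return self._entries.keys()

    def get(self, key: GroupKey) -> Optional[GroupContribution]:
        return self._entries.get(key)

    def lookup(self, atom_type: str, neighbors: str = "") -> GroupContribution:
        entry = self._entries.get(GroupKey(atom_type, neighbors))
        if entry is None:
            raise KeyError(f"no contribution for {atom_type!r} / {neighbors!r}")
        return entry

    @property
    def n_valid(self) -> int:
        return sum(1 for e in self if e.valid)

    def n_prediction_groups(self) -> int:
        """Valid, fitted (non-placeholder) ordinary atom groups — the
        table's own count of groups usable for prediction."""
        return sum(
            1 for e in self
            if e.valid and not e.key.is_special and not e.is_placeholder
        )

    def usable(self, key: GroupKey) -> bool:
        """Whether a group may enter a strict prediction."""
        entry = self._entries.get(key)
        if entry is None:
            return False
        if key.is_special:
            return not entry.is_placeholder
        return entry.valid and not entry.is_placeholder

    def validity_filter(self, min_molecules: int = DEFAULT_MIN_MOLECULES) -> "ContributionTable":
        """Re-flag validity against a support threshold (new table)."""
        return ContributionTable(
            (replace(e, valid=e.molecules >= min_molecules) for e in self),
            min_molecules=min_molecules,
            checksum=self.checksum,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "atom_type": [e.key.atom_type for e in self],
                "neighbors": [e.key.neighbors for e in self],
                "contribution": [e.value for e in self],
                "occurrences": [e.occurrences for e in self],
                "molecules": [e.molecules for e in self],
                "valid": [e.valid for e in self],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   min_molecules: int = DEFAULT_MIN_MOLECULES,
                   checksum: Optional[str] = None) -> "ContributionTable":
        entries = [
            GroupContribution(
                key=GroupKey(str(row.atom_type), str(row.neighbors) if pd.notna(row.neighbors) else ""),
                value=float(row.contribution),
                occurrences=int(getattr(row, "occurrences", 0)),
                molecules=int(getattr(row, "molecules", 0)),
                valid=int(getattr(row, "molecules", 0)) >= min_molecules,
            )
            for row in frame.itertuples()
        ]
        return cls(entries, min_molecules=min_molecules, checksum=checksum)


def _packaged(name: str) -> Path:
    return Path(resources.files("hcomb") / "data" / name)


def load_table(source: Union[str, Path, None] = None,
               min_molecules: int = DEFAULT_MIN_MOLECULES,
               verify: bool = True) -> ContributionTable:
    """Load a contribution table (the packaged one by default).

    The packaged file is audited: exactly 390 entries and a matching SHA-256
    checksum, otherwise :class:`DataIntegrityError` is raised.
    """
    packaged = source is None
    path = _packaged("table4_contributions.tsv") if packaged else Path(source)
    raw = path.read_bytes()
    checksum = hashlib.sha256(raw).hexdigest()
    if packaged and verify and checksum != TABLE4_SHA256:
        raise DataIntegrityError("packaged contribution table failed its checksum")
    frame = pd.read_csv(path, sep="\t", keep_default_na=False,
                        dtype={"atom_type": str, "neighbors": str})
    table = ContributionTable.from_frame(frame, min_molecules=min_molecules,
                                         checksum=checksum)
    if packaged and verify and len(table) != TABLE4_N_ENTRIES:
        raise DataIntegrityError(
            f"packaged table has {len(table)} entries, expected {TABLE4_N_ENTRIES}"
        )
    return table


class ElementCombustionTable:
    """Per-atom standard combustion enthalpies of the elements (kJ/mol)."""

    def __init__(self, values: dict[str, float], convention: str = ""):
        self._values = dict(values)
        self.convention = convention

    def supports(self, element: str) -> bool:
        return element in self._values

    def value(self, element: str) -> float:
        if element not in self._values:
            raise ElementNotSupported(
                f"no combustion constant for element {element!r} "
                "(supply an override table to enable it)"
            )
        return self._values[element]

    @property
    def elements(self) -> list[str]:
        return sorted(self._values)

    @classmethod
    def load(cls, source: Union[str, Path, None] = None) -> "ElementCombustionTable":
        path = _packaged("element_combustion.yaml") if source is None else Path(source)
        doc = yaml.safe_load(path.read_text())
        values = {
            el: float(v)
            for el, v in doc["elements"].items()
            if not (isinstance(v, str) and v == "unsupported")
        }
        return cls(values, convention=str(doc.get("product_convention", "")))
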