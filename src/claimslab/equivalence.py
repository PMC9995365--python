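"""Dose equivalence between ingredients of one drug class.

Doses of different drugs in a class are expressed in milligrams of a single
reference ingredient via the ratio of their standard doses: a full standard
dose of any member is taken to equal a full standard dose of the reference,
so ``mg_reference = mg_own * (reference basis dose / own basis dose)``.
The basis is either the standard single dose or the maximum daily dose;
both are carried so a study can run under either definition.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

DoseBasis = Literal["single_dose", "max_daily_dose"]

_BASES = ("single_dose", "max_daily_dose")


class UnknownIngredientError(KeyError):
    """An ingredient has no entry in the dose-equivalence table."""


@dataclass(frozen=True, slots=True)
class DoseEntry:
    ingredient: str
    single_dose_mg: float
    max_daily_dose_mg: float

    def __post_init__(self) -> None:
        if not (self.single_dose_mg > 0 and self.max_daily_dose_mg > 0):
            raise ValueError(f"dose values for {self.ingredient!r} must be > 0")

    def basis_dose(self, basis: DoseBasis) -> float:
        if basis == "single_dose":
            return self.single_dose_mg
        if basis == "max_daily_dose":
            return self.max_daily_dose_mg
        raise ValueError(f"basis must be one of {_BASES}, got {basis!r}")


class DoseEquivalenceTable:
    """Per-ingredient standard doses plus a designated reference ingredient."""

    def __init__(self, entries: list[DoseEntry], reference: str):
        self._entries = {e.ingredient: e for e in entries}
        if reference not in self._entries:
            raise ValueError(f"reference ingredient {reference!r} has no entry")
        self.reference = reference

    def __contains__(self, ingredient: str) -> bool:
        return ingredient in self._entries

    @property
    def ingredients(self) -> list[str]:
        return list(self._entries)

    def entry(self, ingredient: str) -> DoseEntry:
        try:
            return self._entries[ingredient]
        except KeyError:
            raise UnknownIngredientError(
                f"ingredient {ingredient!r} not in dose-equivalence table"
            ) from None

    def reference_dose(self, basis: DoseBasis) -> float:
        return self._entries[self.reference].basis_dose(basis)

    def ratio(self, ingredient: str, basis: DoseBasis) -> float:
        """Multiplier converting mg of ``ingredient`` to reference-equivalent mg."""
        own = self.entry(ingredient).basis_dose(basis)
        return self.reference_dose(basis) / own

    @classmethod
    def from_csv(cls, path: str | Path) -> "DoseEquivalenceTable":
        """Read a table with columns ingredient, single_dose_mg, max_daily_dose_mg, reference."""
        entries: list[DoseEntry] = []
        reference = None
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            required = {"ingredient", "single_dose_mg", "max_daily_dose_mg", "reference"}
            missing = required - set(reader.fieldnames or ())
            if missing:
                raise ValueError(f"dose table missing column(s): {sorted(missing)}")
            for row in reader:
                entries.append(
                    DoseEntry(
                        ingredient=row["ingredient"],
                        single_dose_mg=float(row["single_dose_mg"]),
                        max_daily_dose_mg=float(row["max_daily_dose_mg"]),
                    )
                )
                if row["reference"].strip().lower() in ("1", "true", "yes"):
                    reference = row["ingredient"]
        if reference is None:
            raise ValueError("dose table marks no reference ingredient")
        return cls(entries, reference)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["ingredient", "single_dose_mg", "max_daily_dose_mg", "reference"])
            for e in self._entries.values():
                writer.writerow(
                    [
                        e.ingredient,
                        repr(e.single_dose_mg),
                        repr(e.max_daily_dose_mg),
                        "1" if e.ingredient == self.reference else "0",
                    ]
                )
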