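"""Vital-rate data model, CSV schema, and the packaged species fixtures.

A :class:`VitalRateSet` holds the demographic parameters of one
species-population-period combination: age of first reproduction (AFR),
fledglings per breeding pair (mean and between-year SD), age-class
survival rates (first-year, second-year, older) and an age schedule of
breeding participation.  Eleven such parameter sets ship with the
package under ``data/vital_rates.csv``.

The CSV layout is long (tidy): one row per survival or
breeding-probability entry, with the record-level fields repeated.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

from .errors import SchemaError, ValidationError

SURVIVAL_LABELS = ("first_year", "second_year", "older")

CSV_COLUMNS = (
    "species",
    "population",
    "period",
    "afr",
    "fledglings_mean",
    "fledglings_sd",
    "param_kind",
    "age_class",
    "mean",
    "sd",
)

#: Key identifying one record: (species, population, period).
Key = tuple[str, str, str]


@dataclass(frozen=True)
class SurvivalRate:
    """One age-class survival entry (annual probability, mean and SD)."""

    label: str
    mean: float
    sd: float


@dataclass(frozen=True)
class VitalRateSet:
    """Vital rates of one species-population-period combination.

    ``survival`` carries exactly three entries (first-year, second-year,
    older birds).  ``breeding_prob`` is an ordered tuple of
    ``(age, probability)`` pairs starting at the age of first
    reproduction; the last entry applies to that age *and older*.
    """

    species: str
    population: str
    period: str
    afr: int
    fledglings_mean: float
    fledglings_sd: float
    survival: tuple[SurvivalRate, ...]
    breeding_prob: tuple[tuple[int, float], ...]

    @property
    def key(self) -> Key:
        return (self.species, self.population, self.period)

    @property
    def n_classes(self) -> int:
        """Number of age classes: oldest scheduled breeding age plus one.

        Birds at the oldest breeding-schedule age and beyond share the
        terminal class, which self-loops on older-bird survival.
        """
        return max(age for age, _ in self.breeding_prob) + 1

    def breeding_prob_at(self, age: int) -> float:
        """Breeding probability at ``age``; 0 below AFR, terminal value above."""
        if age < self.afr:
            return 0.0
        prob = self.breeding_prob[-1][1]
        for a, p in self.breeding_prob:
            if a == age:
                return p
            if a > age:
                break
        return prob

    def survival_label_for_class(self, j: int) -> str:
        """Which survival rate applies to age class ``j``.

        Class 0 uses first-year survival.  Class 1 uses second-year
        survival unless it is the terminal class, in which case the
        older-bird rate applies (the terminal class always does).
        """
        n = self.n_classes
        if j == 0:
            return "first_year"
        if j == 1 and j < n - 1:
            return "second_year"
        return "older"

    def survival_for_class(self, j: int) -> SurvivalRate:
        label = self.survival_label_for_class(j)
        return self.survival[SURVIVAL_LABELS.index(label)]

    @property
    def survival_by_label(self) -> Mapping[str, SurvivalRate]:
        return {s.label: s for s in self.survival}

    def validate(self) -> "VitalRateSet":
        """Check all domain invariants; raise :class:`ValidationError` if violated."""
        ident = "/".join(self.key)
        if self.afr < 1:
            raise ValidationError(f"{ident}: afr must be >= 1, got {self.afr}")
        if self.fledglings_mean < 0:
            raise ValidationError(
                f"{ident}: fledglings_mean must be >= 0, got {self.fledglings_mean}"
            )
        if self.fledglings_sd < 0:
            raise ValidationError(
                f"{ident}: fledglings_sd must be >= 0, got {self.fledglings_sd}"
            )
        if tuple(s.label for s in self.survival) != SURVIVAL_LABELS:
            raise ValidationError(
                f"{ident}: survival labels must be {SURVIVAL_LABELS}, got "
                f"{tuple(s.label for s in self.survival)}"
            )
        for s in self.survival:
            if not 0.0 <= s.mean <= 1.0:
                raise ValidationError(
                    f"{ident}: survival[{s.label}].mean must be in [0, 1], got {s.mean}"
                )
            if s.sd < 0:
                raise ValidationError(
                    f"{ident}: survival[{s.label}].sd must be >= 0, got {s.sd}"
                )
        if not self.breeding_prob:
            raise ValidationError(f"{ident}: breeding_prob schedule is empty")
        ages = [age for age, _ in self.breeding_prob]
        if ages != sorted(set(ages)):
            raise ValidationError(f"{ident}: breeding_prob ages must be strictly increasing")
        if ages[0] != self.afr:
            raise ValidationError(
                f"{ident}: breeding_prob schedule must start at afr={self.afr}, "
                f"starts at {ages[0]}"
            )
        for age, p in self.breeding_prob:
            if not 0.0 < p <= 1.0:
                raise ValidationError(
                    f"{ident}: breeding_prob[{age}] must be in (0, 1], got {p}"
                )
        if self.n_classes < self.afr + 1:
            raise ValidationError(
                f"{ident}: n_classes={self.n_classes} must be >= afr + 1 = {self.afr + 1}"
            )
        return self

    def with_survival_means(self, means: Mapping[str, float]) -> "VitalRateSet":
        """Copy with survival means replaced (SDs and everything else kept)."""
        new = tuple(
            replace(s, mean=float(means.get(s.label, s.mean))) for s in self.survival
        )
        return replace(self, survival=new)


class FixtureCatalog:
    """Ordered collection of :class:`VitalRateSet` records, keyed uniquely."""

    def __init__(self, records: Iterator[VitalRateSet] | list[VitalRateSet] = ()):
        self._records: dict[Key, VitalRateSet] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: VitalRateSet) -> None:
        rec.validate()
        if rec.key in self._records:
            raise ValidationError(f"duplicate catalog key {rec.key}")
        self._records[rec.key] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[VitalRateSet]:
        return iter(self._records.values())

    def __getitem__(self, key: Key) -> VitalRateSet:
        return self._records[key]

    def __contains__(self, key: Key) -> bool:
        return key in self._records

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FixtureCatalog):
            return NotImplemented
        return self._records == other._records

    @property
    def keys(self) -> list[Key]:
        return list(self._records)

    def get(
        self,
        species: str,
        population: str | None = None,
        period: str | None = None,
    ) -> VitalRateSet:
        """Look up a single record by species and optional population/period.

        Raises :class:`KeyError` if zero or more than one record matches.
        """
        hits = [
            r
            for r in self
            if r.species == species
            and (population is None or r.population == population)
            and (period is None or r.period == period)
        ]
        if len(hits) != 1:
            raise KeyError(
                f"selector (species={species!r}, population={population!r}, "
                f"period={period!r}) matched {len(hits)} records"
            )
        return hits[0]


def _parse_float(value: str, row_no: int, field: str) -> float:
    try:
        return float(value)
    except ValueError as exc:
        raise SchemaError(f"row {row_no}: field {field!r} is not a number: {value!r}") from exc


def _parse_int(value: str, row_no: int, field: str) -> int:
    try:
        return int(value)
    except ValueError as exc:
        raise SchemaError(f"row {row_no}: field {field!r} is not an integer: {value!r}") from exc


def read_vital_rates(path: str | Path | io.TextIOBase) -> FixtureCatalog:
    """Read a vital-rates CSV into a validated :class:`FixtureCatalog`.

    The file must follow the documented long schema (see
    :data:`CSV_COLUMNS`).  Malformed rows raise :class:`SchemaError`
    naming the row and field; invariant violations raise
    :class:`ValidationError`.
    """
    if isinstance(path, io.TextIOBase):
        return _read_stream(path)
    with open(path, newline="", encoding="utf-8") as fh:
        return _read_stream(fh)


def _read_stream(fh) -> FixtureCatalog:
    reader = csv.DictReader(fh)
    if reader.fieldnames is None:
        raise SchemaError("file is empty (missing header)")
    if tuple(reader.fieldnames) != CSV_COLUMNS:
        raise SchemaError(
            f"header mismatch: expected {list(CSV_COLUMNS)}, got {reader.fieldnames}"
        )
    # accumulate per-record pieces preserving first-seen order
    heads: dict[Key, dict] = {}
    survs: dict[Key, dict[str, SurvivalRate]] = {}
    breeds: dict[Key, list[tuple[int, float]]] = {}
    for row_no, row in enumerate(reader, start=2):
        if any(row.get(c) is None for c in CSV_COLUMNS):
            raise SchemaError(f"row {row_no}: wrong number of fields")
        key: Key = (row["species"], row["population"], row["period"])
        head = {
            "afr": _parse_int(row["afr"], row_no, "afr"),
            "fledglings_mean": _parse_float(row["fledglings_mean"], row_no, "fledglings_mean"),
            "fledglings_sd": _parse_float(row["fledglings_sd"], row_no, "fledglings_sd"),
        }
        if key in heads and heads[key] != head:
            raise SchemaError(f"row {row_no}: record-level fields disagree for {key}")
        heads.setdefault(key, head)
        kind = row["param_kind"]
        if kind == "survival":
            label = row["age_class"]
            if label not in SURVIVAL_LABELS:
                raise SchemaError(
                    f"row {row_no}: field 'age_class' must be one of "
                    f"{SURVIVAL_LABELS} for survival rows, got {label!r}"
                )
            entry = SurvivalRate(
                label,
                _parse_float(row["mean"], row_no, "mean"),
                _parse_float(row["sd"], row_no, "sd"),
            )
            bucket = survs.setdefault(key, {})
            if label in bucket:
                raise SchemaError(f"row {row_no}: duplicate survival row {label!r} for {key}")
            bucket[label] = entry
        elif kind == "breeding_prob":
            age = _parse_int(row["age_class"], row_no, "age_class")
            breeds.setdefault(key, []).append(
                (age, _parse_float(row["mean"], row_no, "mean"))
            )
        else:
            raise SchemaError(
                f"row {row_no}: field 'param_kind' must be 'survival' or "
                f"'breeding_prob', got {kind!r}"
            )
    records = []
    for key, head in heads.items():
        missing = [lbl for lbl in SURVIVAL_LABELS if lbl not in survs.get(key, {})]
        if missing:
            raise SchemaError(f"record {key}: missing survival rows {missing}")
        records.append(
            VitalRateSet(
                species=key[0],
                population=key[1],
                period=key[2],
                survival=tuple(survs[key][lbl] for lbl in SURVIVAL_LABELS),
                breeding_prob=tuple(sorted(breeds.get(key, []))),
                **head,
            )
        )
    return FixtureCatalog(records)


def _fmt(x: float) -> str:
    # repr round-trips doubles exactly; keep integers compact
    return repr(float(x)) if float(x) != int(x) else str(int(x))


def write_vital_rates(catalog: FixtureCatalog, path: str | Path) -> None:
    """Write ``catalog`` in the long CSV schema; read-back equals input."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for rec in catalog:
            head = [
                rec.species,
                rec.population,
                rec.period,
                str(rec.afr),
                _fmt(rec.fledglings_mean),
                _fmt(rec.fledglings_sd),
            ]
            for s in rec.survival:
                writer.writerow(head + ["survival", s.label, _fmt(s.mean), _fmt(s.sd)])
            for age, p in rec.breeding_prob:
                writer.writerow(head + ["breeding_prob", str(age), _fmt(p), "0"])


def load_fixtures() -> FixtureCatalog:
    """The 11 packaged species-population-period parameter sets."""
    ref = resources.files("avipva.data").joinpath("vital_rates.csv")
    with ref.open("r", encoding="utf-8", newline="") as fh:
        return _read_stream(fh)
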