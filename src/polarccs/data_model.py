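"""Typed containers for adduct CCS datasets and delimited-table I/O.

The central object is :class:`PropertyDataset`, an ordered collection of
:class:`AdductRecord` rows.  Each record describes one measured adduct — the
charged form of an analyte actually observed in the ion-mobility mass
spectrometer — together with its experimental collision cross-section (CCS,
in squared angstroms) and the physicochemical properties computed on the
adduct geometry (polarizability, van der Waals volume/surface, ovality,
radius of gyration).

Tables are plain CSV/TSV files with a header row.  Required columns:
``compound_id, adduct_type, ion_mode, mz, ccs, polarizability``.  Optional
columns: ``polarizability_neutral, vdw_volume, vdw_surface, ovality,
radius_gyration, instrument, smiles``.  Column aliasing is supported because
published supplementary tables rarely use identical headers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AdductRecord",
    "PropertyDataset",
    "SchemaError",
    "RowParseError",
    "ValidationError",
    "read_property_table",
    "write_property_table",
    "filter_by_mz_range",
    "random_split",
]

#: canonical adduct tokens and their charge states
ADDUCT_CHARGE: dict[str, int] = {"M+H": +1, "M+Na": +1, "M-H": -1}

#: spellings accepted on input, normalised to the canonical tokens above
_ADDUCT_ALIASES: dict[str, str] = {
    "M+H": "M+H",
    "[M+H]+": "M+H",
    "M+NA": "M+Na",
    "M+Na": "M+Na",
    "[M+NA]+": "M+Na",
    "[M+Na]+": "M+Na",
    "M-H": "M-H",
    "[M-H]-": "M-H",
}

_REQUIRED_COLUMNS = ("compound_id", "adduct_type", "ion_mode", "mz", "ccs", "polarizability")
_OPTIONAL_NUMERIC = (
    "polarizability_neutral",
    "vdw_volume",
    "vdw_surface",
    "ovality",
    "radius_gyration",
)
_ALL_COLUMNS = _REQUIRED_COLUMNS + _OPTIONAL_NUMERIC + ("instrument", "smiles")


class SchemaError(ValueError):
    """A required column is missing from a property table."""


class RowParseError(ValueError):
    """A data row holds an unparseable or out-of-domain value."""


class ValidationError(ValueError):
    """Dataset-level invariant violated (e.g. duplicate record keys)."""


def normalize_adduct(token: str) -> str:
    """Map an adduct spelling (``[M+Na]+``, ``M+Na``, unicode minus) to its
    canonical token.  Raises :class:`RowParseError` for unknown adducts."""
    cleaned = str(token).strip().replace("−", "-").replace("–", "-")
    key = cleaned if cleaned in _ADDUCT_ALIASES else cleaned.upper().replace(" ", "")
    try:
        return _ADDUCT_ALIASES[key]
    except KeyError:
        raise RowParseError(f"unknown adduct type {token!r}") from None


@dataclass(frozen=True)
class AdductRecord:
    """One measured adduct and its physicochemical properties.

    Units: ``mz`` in Da per unit charge, ``ccs`` in Å², polarizabilities in
    Å³, ``vdw_volume`` in Å³, ``vdw_surface`` in Å², ``radius_gyration`` in
    Å; ``ovality`` is dimensionless (1 for a sphere).
    """

    compound_id: str
    adduct_type: str
    mz: float
    ccs: float
    polarizability: float
    ion_mode: str | None = None
    polarizability_neutral: float | None = None
    vdw_volume: float | None = None
    vdw_surface: float | None = None
    ovality: float | None = None
    radius_gyration: float | None = None
    instrument: str = "TWIM"
    smiles: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "adduct_type", normalize_adduct(self.adduct_type))
        charge = ADDUCT_CHARGE[self.adduct_type]
        expected_mode = "positive" if charge > 0 else "negative"
        if self.ion_mode is None:
            object.__setattr__(self, "ion_mode", expected_mode)
        elif str(self.ion_mode).lower() != expected_mode:
            raise RowParseError(
                f"{self.compound_id} {self.adduct_type}: ion_mode "
                f"{self.ion_mode!r} inconsistent with charge {charge:+d}"
            )
        if self.instrument not in ("TWIM", "DTIM"):
            raise RowParseError(
                f"{self.compound_id}: instrument must be TWIM or DTIM, got {self.instrument!r}"
            )
        for name in ("mz", "ccs", "polarizability") + _OPTIONAL_NUMERIC:
            value = getattr(self, name)
            if value is None:
                if name in ("mz", "ccs", "polarizability"):
                    raise RowParseError(f"{self.compound_id}: missing required field {name}")
                continue
            value = float(value)
            if not math.isfinite(value):
                raise RowParseError(f"{self.compound_id}: non-finite {name} = {value!r}")
            if name == "ovality":
                if value < 1.0:
                    raise RowParseError(f"{self.compound_id}: ovality {value} < 1")
            elif value <= 0.0:
                raise RowParseError(f"{self.compound_id}: {name} must be > 0, got {value}")
            object.__setattr__(self, name, value)

    @property
    def charge(self) -> int:
        """Charge state: +1 for M+H and M+Na, -1 for M-H."""
        return ADDUCT_CHARGE[self.adduct_type]

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.compound_id, self.adduct_type, self.instrument)


@dataclass
class PropertyDataset:
    """Ordered, key-unique collection of :class:`AdductRecord`."""

    records: list[AdductRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, str]] = set()
        for rec in self.records:
            if rec.key in seen:
                raise ValidationError(
                    f"duplicate record key {rec.key}; deduplicate or average upstream"
                )
            seen.add(rec.key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[AdductRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> AdductRecord:
        return self.records[i]

    def adduct_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.records:
            counts[rec.adduct_type] = counts.get(rec.adduct_type, 0) + 1
        return counts

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            rows.append({name: getattr(rec, name) for name in _ALL_COLUMNS})
        df = pd.DataFrame(rows, columns=list(_ALL_COLUMNS))
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, provenance: str = "") -> "PropertyDataset":
        records = []
        for idx, row in df.iterrows():
            kwargs = {}
            for name in _ALL_COLUMNS:
                if name not in df.columns:
                    continue
                value = row[name]
                if value is None or (isinstance(value, float) and math.isnan(value)):
                    continue
                kwargs[name] = value
            if "instrument" not in kwargs:
                kwargs["instrument"] = "TWIM"
            try:
                records.append(AdductRecord(**kwargs))
            except RowParseError as exc:
                raise RowParseError(f"row {idx}: {exc}") from None
            except TypeError:
                missing = [c for c in ("compound_id", "adduct_type", "mz", "ccs", "polarizability") if c not in kwargs]
                raise RowParseError(f"row {idx}: missing required fields {missing}") from None
        return cls(records=records, provenance=provenance)

    def feature_matrix(self, features: Sequence[str]) -> np.ndarray:
        """Dense (n, p) array of the named numeric fields; raises if absent."""
        cols = []
        for name in features:
            col = []
            for rec in self.records:
                value = getattr(rec, name)
                if value is None:
                    raise ValidationError(
                        f"record {rec.compound_id} ({rec.adduct_type}) lacks feature {name!r}"
                    )
                col.append(float(value))
            cols.append(col)
        return np.asarray(cols, dtype=float).T

    def ccs_values(self) -> np.ndarray:
        return np.asarray([rec.ccs for rec in self.records], dtype=float)


def read_property_table(
    path,
    delimiter: str | None = None,
    aliases: Mapping[str, str] | None = None,
) -> PropertyDataset:
    """Read a CSV/TSV property table into a :class:`PropertyDataset`.

    Parameters
    ----------
    path
        File with a header row.  Delimiter auto-detected among comma/tab
        unless ``delimiter`` is given.  Decimal point notation only.
    aliases
        Optional mapping ``{file_header: canonical_name}`` to adapt tables
        whose headers differ from the canonical snake-case tokens.
    """
    if delimiter is None:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    else:
        df = pd.read_csv(path, sep=delimiter, dtype=str)
    if aliases:
        df = df.rename(columns=dict(aliases))
    df.columns = [str(c).strip() for c in df.columns]

    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} missing from {path}")

    numeric_cols = [c for c in ("mz", "ccs", "polarizability") + _OPTIONAL_NUMERIC if c in df.columns]
    for col in numeric_cols:
        raw = df[col]
        parsed = pd.to_numeric(raw, errors="coerce")
        bad = parsed.isna() & raw.notna() & (raw.str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise RowParseError(
                f"{path}: column {col!r}, data row {row}: cannot parse {raw.iloc[row]!r}"
            )
        df[col] = parsed
    return PropertyDataset.from_dataframe(df, provenance=str(path))


def write_property_table(ds: PropertyDataset, path, delimiter: str = ",") -> None:
    """Write a dataset as delimited text; numeric cells use ``%.10g`` so a
    read-back round trip preserves values well beyond 6 significant digits."""
    df = ds.to_dataframe()
    df.to_csv(path, sep=delimiter, index=False, float_format="%.10g")


def filter_by_mz_range(ds: PropertyDataset, lo: float, hi: float) -> PropertyDataset:
    """Records with ``lo <= mz <= hi`` (inclusive both ends), order preserved."""
    if lo > hi:
        raise ValueError(f"invalid m/z window: lo={lo} > hi={hi}")
    kept = [rec for rec in ds.records if lo <= rec.mz <= hi]
    return PropertyDataset(records=kept, provenance=f"{ds.provenance}|mz[{lo},{hi}]")


def filter_by_adduct(ds: PropertyDataset, adducts: Iterable[str]) -> PropertyDataset:
    wanted = {normalize_adduct(a) for a in adducts}
    kept = [rec for rec in ds.records if rec.adduct_type in wanted]
    return PropertyDataset(records=kept, provenance=f"{ds.provenance}|adducts={sorted(wanted)}")


def filter_by_ion_mode(ds: PropertyDataset, mode: str) -> PropertyDataset:
    kept = [rec for rec in ds.records if rec.ion_mode == mode]
    return PropertyDataset(records=kept, provenance=f"{ds.provenance}|mode={mode}")


def random_split(
    ds: PropertyDataset, n_train: int, n_test: int, seed: int
) -> tuple[PropertyDataset, PropertyDataset]:
    """Disjoint train/test subsets drawn without replacement.

    The same seed always yields the same membership.  Within each subset the
    original record order is preserved so downstream numerics are stable.
    """
    n = len(ds)
    if n_train < 0 or n_test < 0 or n_train + n_test > n:
        raise ValueError(
            f"cannot draw {n_train} train + {n_test} test records from {n} available"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_idx = sorted(perm[:n_train])
    test_idx = sorted(perm[n_train : n_train + n_test])
    train = PropertyDataset(
        records=[ds.records[i] for i in train_idx], provenance=f"{ds.provenance}|train(seed={seed})"
    )
    test = PropertyDataset(
        records=[ds.records[i] for i in test_idx], provenance=f"{ds.provenance}|test(seed={seed})"
    )
    return train, test
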