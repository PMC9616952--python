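"""Effect-size data model for at-vessel mortality (AVM) meta-analysis.

One record is a study-specific effect size: the number of animals of one
species recorded dead at haulback (``n_dead``) out of the number caught
(``n_caught``) on pelagic longline gear, together with the moderators and
grouping identifiers (study, record-within-study, research group) that the
hierarchical meta-regression uses.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("elasmoavm")

OCEANS = ("Atlantic", "Pacific", "Indian", "Mediterranean", "BlackSea", "Unknown")
HOOK_SHAPES = ("circle", "J", "other", "unknown")
BAIT_TYPES = ("squid", "fish", "mixed", "unknown")
VENTILATION_MODES = ("ram_obligate", "buccal_facultative", "unknown")

#: canonical internal column names -> default CSV header
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "record_id": "record_id",
    "study_id": "study_id",
    "research_group_id": "research_group_id",
    "species": "species",
    "genus": "genus",
    "family": "family",
    "order": "order",
    "n_caught": "n_caught",
    "n_dead": "n_dead",
    "ocean": "ocean",
    "hook_shape": "hook_shape",
    "hook_type": "hook_type",
    "hooks_between_floats": "hooks_between_floats",
    "soak_duration": "soak_duration",
    "bait_type": "bait_type",
    "body_form": "body_form",
    "ventilation_mode": "ventilation_mode",
}

REQUIRED_COLUMNS = ("record_id", "study_id", "species", "n_caught", "n_dead")

CATEGORICAL_COLUMNS = (
    "ocean",
    "hook_shape",
    "hook_type",
    "bait_type",
    "body_form",
    "ventilation_mode",
)
NUMERIC_MODERATORS = ("hooks_between_floats", "soak_duration")

_CLOSED_LEVELS = {
    "ocean": OCEANS,
    "hook_shape": HOOK_SHAPES,
    "bait_type": BAIT_TYPES,
    "ventilation_mode": VENTILATION_MODES,
}


class SchemaError(ValueError):
    """A required column is missing or unparseable."""


class ValidationError(ValueError):
    """Rows violate the record invariants; carries row-level diagnostics."""

    def __init__(self, message: str, bad_records: Sequence[str] = ()):
        super().__init__(message)
        self.bad_records = list(bad_records)


class EmptySubsetError(ValueError):
    """A clade/ocean subset produced no usable records."""


def normalize_species(name: str) -> str:
    """Trim, collapse whitespace, sentence-case the genus, lower-case the epithet."""
    parts = re.sub(r"\s+", " ", str(name).strip()).split(" ")
    if not parts or parts == [""]:
        return ""
    parts[0] = parts[0].capitalize()
    rest = [p.lower() for p in parts[1:]]
    return " ".join([parts[0], *rest])


@dataclass(frozen=True)
class AVMRecord:
    record_id: str
    study_id: str
    species: str
    n_caught: int
    n_dead: int
    research_group_id: str = "unknown"
    genus: str = ""
    family: str = ""
    order: str = ""
    ocean: str = "Unknown"
    hook_shape: str = "unknown"
    hook_type: str = "unknown"
    hooks_between_floats: float | None = None
    soak_duration: float | None = None
    bait_type: str = "unknown"
    body_form: str = "unknown"
    ventilation_mode: str = "unknown"

    def __post_init__(self):
        if self.n_caught < 1:
            raise ValidationError(
                f"record {self.record_id!r}: n_caught must be >= 1", [self.record_id]
            )
        if not (0 <= self.n_dead <= self.n_caught):
            raise ValidationError(
                f"record {self.record_id!r}: need 0 <= n_dead <= n_caught "
                f"(got {self.n_dead}/{self.n_caught})",
                [self.record_id],
            )
        if not self.study_id or not self.species:
            raise ValidationError(
                f"record {self.record_id!r}: study_id and species must be non-empty",
                [self.record_id],
            )

    @property
    def raw_rate(self) -> float:
        return self.n_dead / self.n_caught


def raw_avm_rate(record: AVMRecord) -> float:
    """Study-specific proportion recorded dead at haulback: ``n_dead / n_caught``."""
    return record.raw_rate


@dataclass
class AVMDataset:
    """An ordered collection of AVM effect sizes backed by a DataFrame."""

    frame: pd.DataFrame
    provenance: str = ""

    def __post_init__(self):
        self.frame = self.frame.reset_index(drop=True)
        validate_frame(self.frame)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self):
        for row in self.frame.itertuples(index=False):
            yield AVMRecord(
                **{
                    k: (None if (k in NUMERIC_MODERATORS and pd.isna(getattr(row, k))) else getattr(row, k))
                    for k in DEFAULT_COLUMN_MAP
                }
            )

    @classmethod
    def from_records(cls, records: Iterable[AVMRecord], provenance: str = "") -> "AVMDataset":
        rows = [{k: getattr(r, k) for k in DEFAULT_COLUMN_MAP} for r in records]
        frame = pd.DataFrame(rows, columns=list(DEFAULT_COLUMN_MAP))
        return cls(frame, provenance=provenance)

    # -- summaries ----------------------------------------------------------
    @property
    def species(self) -> list[str]:
        return sorted(self.frame["species"].unique())

    def load_report(self) -> dict:
        f = self.frame
        return {
            "n_records": int(len(f)),
            "n_species": int(f["species"].nunique()),
            "n_genera": int(f.loc[f["genus"] != "", "genus"].nunique()),
            "n_families": int(f.loc[f["family"] != "", "family"].nunique()),
            "n_orders": int(f.loc[f["order"] != "", "order"].nunique()),
            "n_studies": int(f["study_id"].nunique()),
            "n_research_groups": int(f["research_group_id"].nunique()),
            "provenance": self.provenance,
        }


def _coerce_categorical(series: pd.Series, column: str) -> pd.Series:
    out = series.astype("string").str.strip()
    out = out.where(~(out.isna() | (out == "")), "unknown" if column != "ocean" else "Unknown")
    if column in _CLOSED_LEVELS:
        levels = _CLOSED_LEVELS[column]
        lookup = {lv.lower(): lv for lv in levels}
        unk = "Unknown" if column == "ocean" else "unknown"
        out = out.map(lambda s: lookup.get(str(s).lower(), unk))
    return out.astype(str)


def validate_frame(frame: pd.DataFrame) -> None:
    """Raise on invariant violations, naming the offending record_ids."""
    for col in DEFAULT_COLUMN_MAP:
        if col not in frame.columns:
            raise SchemaError(f"missing required column: {col!r}")
    rid = frame["record_id"].astype(str)
    if rid.duplicated().any():
        dups = sorted(rid[rid.duplicated()].unique())
        raise ValidationError(f"duplicate record_id values: {dups}", dups)
    bad = frame.loc[
        (frame["n_caught"] < 1)
        | (frame["n_dead"] < 0)
        | (frame["n_dead"] > frame["n_caught"]),
        "record_id",
    ]
    if len(bad):
        raise ValidationError(
            f"count invariant violated (need 0 <= n_dead <= n_caught, n_caught >= 1) "
            f"for records: {sorted(bad.astype(str))}",
            sorted(bad.astype(str)),
        )
    empty = frame.loc[
        (frame["study_id"].astype(str).str.len() == 0)
        | (frame["species"].astype(str).str.len() == 0),
        "record_id",
    ]
    if len(empty):
        raise ValidationError(
            f"empty study_id or species for records: {sorted(empty.astype(str))}",
            sorted(empty.astype(str)),
        )
    # one taxonomy per species string
    tax = frame.groupby("species")[["genus", "family", "order"]].nunique()
    inconsistent = tax[(tax > 1).any(axis=1)].index.tolist()
    if inconsistent:
        raise ValidationError(
            f"inconsistent taxonomy for species: {inconsistent}", inconsistent
        )


def read_dataset(
    path,
    schema_config: Mapping[str, str] | None = None,
    provenance: str = "",
) -> AVMDataset:
    """Read and validate an effect-size CSV.

    Parameters
    ----------
    path : str or Path
        CSV file (UTF-8, header row).
    schema_config : mapping, optional
        Canonical column name -> CSV header. Unmapped optional columns fall
        back to defaults; absent optional columns are filled with
        unknown/missing values. Required columns (record ids, study ids,
        species, counts) must resolve.
    """
    colmap = dict(DEFAULT_COLUMN_MAP)
    if schema_config:
        colmap.update(schema_config)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    frame = pd.DataFrame()
    for canon, header in colmap.items():
        if header in raw.columns:
            frame[canon] = raw[header]
        elif canon in REQUIRED_COLUMNS:
            raise SchemaError(f"missing required column: {header!r} (for {canon!r})")
        else:
            frame[canon] = pd.NA

    for col in ("record_id", "study_id", "research_group_id", "genus", "family", "order"):
        frame[col] = frame[col].astype("string").fillna("" if col not in ("research_group_id",) else "unknown")
        if col == "research_group_id":
            frame[col] = frame[col].replace("", "unknown")
        frame[col] = frame[col].astype(str).str.strip()
    frame["species"] = frame["species"].astype("string").fillna("").map(normalize_species)

    for col in ("n_caught", "n_dead"):
        try:
            frame[col] = pd.to_numeric(frame[col], errors="raise").astype(int)
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"column {colmap[col]!r} does not parse as integer counts: {exc}")
    for col in NUMERIC_MODERATORS:
        frame[col] = pd.to_numeric(frame[col], errors="coerce")
    for col in CATEGORICAL_COLUMNS:
        frame[col] = _coerce_categorical(frame[col], col)

    ds = AVMDataset(frame, provenance=provenance or str(path))
    report = ds.load_report()
    logger.info("loaded %s: %s", path, json.dumps(report))
    return ds


def write_dataset(ds: AVMDataset, path) -> None:
    """Write the canonical CSV dialect (round-trips through read_dataset)."""
    ds.frame.to_csv(path, index=False)


def write_load_report(ds: AVMDataset, path) -> None:
    with open(path, "w") as fh:
        json.dump(ds.load_report(), fh, indent=2)


def subset_clade(
    ds: AVMDataset,
    order_name: str,
    oceans_keep: Iterable[str] = ("Atlantic", "Pacific"),
) -> AVMDataset:
    """Restrict to one taxonomic order and a set of ocean basins.

    Mirrors the clade-level analysis subsets where sparsely sampled basins
    (e.g. Mediterranean, Indian) are excluded before fitting.
    """
    if order_name not in set(ds.frame["order"]):
        raise EmptySubsetError(f"order {order_name!r} not present in dataset")
    keep = set(oceans_keep)
    in_order = ds.frame[ds.frame["order"] == order_name]
    removed = in_order[~in_order["ocean"].isin(keep)]
    if len(removed):
        per_ocean = removed["ocean"].value_counts().to_dict()
        logger.info("subset_clade(%s): removed per ocean: %s", order_name, per_ocean)
    out = in_order[in_order["ocean"].isin(keep)]
    if out["species"].nunique() < 2:
        raise EmptySubsetError(
            f"subset order={order_name!r}, oceans={sorted(keep)} leaves "
            f"{out['species'].nunique()} species; downstream fits require >= 2"
        )
    return AVMDataset(out.copy(), provenance=f"{ds.provenance} | order={order_name}")


def subset_species(ds: AVMDataset, species: str) -> AVMDataset:
    sub = ds.frame[ds.frame["species"] == species]
    if sub.empty:
        raise EmptySubsetError(f"species {species!r} not present in dataset")
    return AVMDataset(sub.copy(), provenance=f"{ds.provenance} | species={species}")
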