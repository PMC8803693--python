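"""Plate-reader I/O, the EcoPlate substrate catalog and the experiment design.

The on-disk format is a single long (tidy) table, one row per well reading:

    sample_id, reactor_id, treatment, day, matrix, substrate, replicate,
    time_h, od590 [, od750, storage_flag]

CSV or TSV, autodetected by file extension, UTF-8, decimal point. Vendor 8x12
plate grids are out of scope. OD at 750 nm is read and retained when present
but never enters any computation; all analysis uses the 590 nm channel.

The substrate catalog is the five-guild partition of the 31 EcoPlate carbon
sources used throughout: amines (2), amino acids (6), carbohydrates (10),
carboxylic acids (9) and polymers (4). Blank wells carry the reserved
substrate token ``BLANK``.
"""

from __future__ import annotations

import difflib
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "BLANK",
    "GROUP_NAMES",
    "TREATMENTS",
    "MATRICES",
    "SAMPLING_DAYS",
    "READ_TIMES_H",
    "REACTORS_BY_TREATMENT",
    "SOLID_SAMPLED_TREATMENTS",
    "META_COLS",
    "PlateFormatError",
    "SampleMeta",
    "SubstrateCatalog",
    "default_catalog",
    "read_plate_table",
    "read_ri4_table",
    "write_results",
]

#: Reserved substrate token for the water blank (one per plate, triplicate).
BLANK = "BLANK"

GROUP_NAMES = ("amines", "amino_acids", "carbohydrates", "carboxylic_acids", "polymers")
TREATMENTS = ("aerobic", "mixed", "anaerobic")
MATRICES = ("solid", "leachate")

#: Sampling campaigns, days since reactor installation.
SAMPLING_DAYS = (0, 57, 114, 358, 763)

#: Plate-reader incubation read times (hours). The 144-h read informs the
#: spline but the activity integral is cut off at 96 h.
READ_TIMES_H = (24.0, 48.0, 72.0, 96.0, 144.0)

#: Canonical reactor numbering of the 9-reactor, 3-treatment design.
REACTORS_BY_TREATMENT: Mapping[str, tuple[int, ...]] = {
    "aerobic": (1, 2, 3),
    "mixed": (4, 5, 6),
    "anaerobic": (7, 8, 9),
}

#: Which treatments have solid (and leachate) samples on each campaign day.
#: The anaerobic reactors stay sealed between installation and termination,
#: so they appear only on day 0 and day 763.
SOLID_SAMPLED_TREATMENTS: Mapping[int, tuple[str, ...]] = {
    0: ("aerobic", "mixed", "anaerobic"),
    57: ("aerobic", "mixed"),
    114: ("aerobic", "mixed"),
    358: ("aerobic", "mixed"),
    763: ("aerobic", "mixed", "anaerobic"),
}

#: Metadata columns that identify a sample in every long table.
META_COLS = ["sample_id", "reactor_id", "treatment", "day", "matrix"]

_REQUIRED_COLS = META_COLS + ["substrate", "replicate", "time_h", "od590"]
_OPTIONAL_COLS = ["od750", "storage_flag"]


class PlateFormatError(ValueError):
    """Raised when an input table violates the plate-table contract."""


class Treatment(str, enum.Enum):
    aerobic = "aerobic"
    mixed = "mixed"
    anaerobic = "anaerobic"


class Matrix(str, enum.Enum):
    solid = "solid"
    leachate = "leachate"


@dataclass(frozen=True)
class SampleMeta:
    """Provenance of one sample: reactor, treatment, campaign day, matrix.

    ``storage_flag`` ('fresh', 'cooled', 'frozen') records sample handling
    (the day-114 campaign was frozen at -20 degC); it is metadata only and
    never alters any computation. ``aeration_at_sampling`` is the oxygen
    state of the reactor at the moment the sample was drawn.
    """

    sample_id: str
    reactor_id: int
    treatment: str
    day: int
    matrix: str
    aeration_at_sampling: str = "anaerobic"
    storage_flag: str = "cooled"

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.matrix not in MATRICES:
            raise ValueError(f"unknown matrix {self.matrix!r}")
        if not 1 <= int(self.reactor_id) <= 9:
            raise ValueError(f"reactor_id must be 1..9, got {self.reactor_id}")


@dataclass(frozen=True)
class SubstrateCatalog:
    """Closed mapping of the 31 EcoPlate substrates onto the five guilds."""

    entries: tuple[tuple[str, str], ...]
    _by_name: Mapping[str, str] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("substrate names must be unique")
        if len(names) != 31:
            raise ValueError(f"catalog must hold exactly 31 substrates, got {len(names)}")
        bad = {g for _, g in self.entries} - set(GROUP_NAMES)
        if bad:
            raise ValueError(f"unknown groups: {sorted(bad)}")
        object.__setattr__(self, "_by_name", dict(self.entries))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.entries)

    def group_of(self, substrate: str) -> str:
        """Guild of ``substrate``; raises KeyError with near-matches."""
        try:
            return self._by_name[substrate]
        except KeyError:
            hints = difflib.get_close_matches(substrate, self.names, n=3, cutoff=0.6)
            msg = f"unknown substrate {substrate!r}"
            if hints:
                msg += f"; did you mean {', '.join(map(repr, hints))}?"
            raise KeyError(msg) from None

    def members(self, group: str) -> tuple[str, ...]:
        return tuple(n for n, g in self.entries if g == group)

    def group_sizes(self) -> dict[str, int]:
        sizes = {g: 0 for g in GROUP_NAMES}
        for _, g in self.entries:
            sizes[g] += 1
        return sizes


_DEFAULT_ENTRIES: tuple[tuple[str, str], ...] = (
    # amines (2)
    ("Phenylethylamine", "amines"),
    ("Putrescine", "amines"),
    # amino acids (6)
    ("Glycyl-L-glutamic acid", "amino_acids"),
    ("L-Arginine", "amino_acids"),
    ("L-Asparagine", "amino_acids"),
    ("L-Phenylalanine", "amino_acids"),
    ("L-Serine", "amino_acids"),
    ("L-Threonine", "amino_acids"),
    # carbohydrates (10)
    ("alpha-D-Lactose", "carbohydrates"),
    ("D-Cellobiose", "carbohydrates"),
    ("D-Galactonic acid gamma-lactone", "carbohydrates"),
    ("D-Mannitol", "carbohydrates"),
    ("D-Xylose", "carbohydrates"),
    ("D,L-alpha-Glycerol phosphate", "carbohydrates"),
    ("Glucose-1-phosphate", "carbohydrates"),
    ("i-Erythritol", "carbohydrates"),
    ("N-Acetyl-D-glucosamine", "carbohydrates"),
    ("beta-Methyl-D-glucoside", "carbohydrates"),
    # carboxylic acids (9)
    ("2-Hydroxy benzoic acid", "carboxylic_acids"),
    ("4-Hydroxy benzoic acid", "carboxylic_acids"),
    ("D-Galacturonic acid", "carboxylic_acids"),
    ("D-Glucosaminic acid", "carboxylic_acids"),
    ("D-Malic acid", "carboxylic_acids"),
    ("gamma-Hydroxybutyric acid", "carboxylic_acids"),
    ("Itaconic acid", "carboxylic_acids"),
    ("Pyruvic acid methyl ester", "carboxylic_acids"),
    ("alpha-Ketobutyric acid", "carboxylic_acids"),
    # polymers (4)
    ("alpha-Cyclodextrin", "polymers"),
    ("Glycogen", "polymers"),
    ("Tween 40", "polymers"),
    ("Tween 80", "polymers"),
)


def default_catalog() -> SubstrateCatalog:
    """The standard 31-substrate EcoPlate catalog with the five-guild split.

    Guild sizes: amines 2, amino acids 6, carbohydrates 10, carboxylic
    acids 9, polymers 4. Note that glucose-1-phosphate and the glycerol
    phosphate are counted among the carbohydrates here; some other published
    EcoPlate groupings place the phosphorylated compounds in a guild of
    their own. This partition is the one the downstream regression uses.
    """
    return SubstrateCatalog(_DEFAULT_ENTRIES)


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    # round_trip parsing so read(write(x)) preserves every bit
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def read_plate_table(
    path: str | Path,
    catalog: SubstrateCatalog | None = None,
) -> pd.DataFrame:
    """Read and validate a long-format plate table.

    Every row is checked: metadata enums, replicate in 1..3, non-negative
    times, numeric OD590 and substrate resolution against ``catalog``
    (default catalog if None). Problems are collected and raised together as
    a :class:`PlateFormatError` whose message carries 1-based data line
    numbers (header = line 1). An unknown substrate is reported with
    near-match candidates.

    Returns a DataFrame with normalized dtypes; blank wells keep the
    ``BLANK`` token in the ``substrate`` column.
    """
    catalog = catalog or default_catalog()
    df = _read_delimited(path)

    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise PlateFormatError(f"{path}: missing required column(s): {', '.join(missing)}")

    errors: list[str] = []

    def complain(mask: pd.Series, what: str) -> None:
        for idx in df.index[mask][:20]:
            errors.append(f"line {idx + 2}: {what}")

    complain(~df["treatment"].isin(TREATMENTS), "treatment not one of " + "/".join(TREATMENTS))
    complain(~df["matrix"].isin(MATRICES), "matrix not one of " + "/".join(MATRICES))
    rep = pd.to_numeric(df["replicate"], errors="coerce")
    complain(rep.isna() | ~rep.isin([1, 2, 3]), "replicate must be 1, 2 or 3")
    t = pd.to_numeric(df["time_h"], errors="coerce")
    complain(t.isna() | (t < 0), "time_h must be a non-negative number")
    od = pd.to_numeric(df["od590"], errors="coerce")
    complain(od.isna(), "od590 must be numeric")

    known = set(catalog.names) | {BLANK}
    for name in pd.unique(df["substrate"]):
        if name not in known:
            hints = difflib.get_close_matches(str(name), catalog.names, n=3, cutoff=0.6)
            hint = f" (did you mean {', '.join(map(repr, hints))}?)" if hints else ""
            lines = df.index[df["substrate"] == name][:5]
            where = ", ".join(str(i + 2) for i in lines)
            errors.append(f"line(s) {where}: unknown substrate {name!r}{hint}")

    dup = df.groupby(["sample_id", "substrate", "time_h", "replicate"]).size()
    if (dup > 1).any():
        for key in dup[dup > 1].index[:10]:
            errors.append(f"duplicate reading for {key}")
    nrep = df.groupby(["sample_id", "substrate", "time_h"])["replicate"].nunique()
    if (nrep > 3).any():
        errors.append("more than 3 replicates for some (sample, substrate, time)")

    if errors:
        raise PlateFormatError(f"{path}: {len(errors)} problem(s):\n  " + "\n  ".join(errors))

    out = df.copy()
    out["reactor_id"] = out["reactor_id"].astype(int)
    out["day"] = out["day"].astype(int)
    out["replicate"] = rep.astype(int)
    out["time_h"] = t.astype(float)
    out["od590"] = od.astype(float)
    if "od750" in out.columns:
        out["od750"] = pd.to_numeric(out["od750"], errors="coerce")
    return out


def read_ri4_table(path: str | Path) -> pd.DataFrame:
    """Read per-sample 4-day respiration index measurements.

    Columns: sample metadata plus ``ri4`` in mg O2 per kg dry weight
    (finite, non-negative).
    """
    df = _read_delimited(path)
    need = META_COLS + ["ri4"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise PlateFormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    ri4 = pd.to_numeric(df["ri4"], errors="coerce")
    if ri4.isna().any() or (ri4 < 0).any():
        raise PlateFormatError(f"{path}: ri4 must be finite and non-negative")
    df = df.copy()
    df["ri4"] = ri4.astype(float)
    df["reactor_id"] = df["reactor_id"].astype(int)
    df["day"] = df["day"].astype(int)
    return df


def write_results(tables: Mapping[str, pd.DataFrame | str], out_dir: str | Path) -> list[Path]:
    """Write result tables as CSV (or plain text for str values) to out_dir.

    Column order is taken from each DataFrame as-is and is deterministic for
    pipeline outputs; numeric payloads are written at full precision so that
    read(write(x)) round-trips exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, table in tables.items():
        if isinstance(table, str):
            p = out_dir / (name if name.endswith(".txt") else f"{name}.txt")
            p.write_text(table)
        else:
            p = out_dir / (name if name.endswith(".csv") else f"{name}.csv")
            # shortest-repr floats; exact round trip with round_trip parsing
            table.to_csv(p, index=False)
        written.append(p)
    return written


def expected_samples(matrix: str = "solid") -> pd.DataFrame:
    """The design table: one row per expected sample of the given matrix.

    9 reactors x the campaign days their treatment is sampled on; 36 rows
    per matrix (9 at day 0, 6 on each of days 57/114/358, 9 at day 763).
    """
    rows = []
    for day, treats in SOLID_SAMPLED_TREATMENTS.items():
        for tr in treats:
            for r in REACTORS_BY_TREATMENT[tr]:
                rows.append({"reactor_id": r, "treatment": tr, "day": day, "matrix": matrix})
    return pd.DataFrame(rows)


def check_design_consistency(meta: pd.DataFrame) -> list[str]:
    """Return design violations (e.g. anaerobic solid samples on day 57)."""
    problems = []
    for _, row in meta[META_COLS].drop_duplicates().iterrows():
        allowed = SOLID_SAMPLED_TREATMENTS.get(int(row["day"]))
        if allowed is not None and row["treatment"] not in allowed:
            problems.append(
                f"sample {row['sample_id']}: treatment {row['treatment']} "
                f"has no campaign on day {row['day']}"
            )
    return problems


def readings_from_records(records: Iterable[dict]) -> pd.DataFrame:
    """Build a plate table from an iterable of per-reading dicts."""
    df = pd.DataFrame(list(records))
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise PlateFormatError(f"records missing field(s): {', '.join(missing)}")
    return df
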