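"""Data model, validation and I/O for tidy line x tester trial tables.

The canonical in-memory container is a tidy :class:`pandas.DataFrame`
with one row per plot, carrying the design coordinates
(``environment``, ``condition``, ``replicate``, ``block``, ``entry``,
``entry_role``, ``line``, ``tester``) followed by one column per trait.
Missing plot values are empty cells (NaN), never zero; every downstream
estimator skips missing cells and reports effective n.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DESIGN_COLUMNS = [
    "environment",
    "condition",
    "replicate",
    "block",
    "entry",
    "entry_role",
    "line",
    "tester",
]

#: Bounds enforced on ingest, keyed by trait name. ``None`` means unbounded.
TRAIT_BOUNDS: dict[str, tuple[float | None, float | None]] = {
    "yield": (0.0, None),
    "striga_damage": (1.0, 9.0),
    "striga_count": (0.0, None),
    "ear_aspect": (1.0, 5.0),
    "plant_aspect": (1.0, 5.0),
    "husk_cover": (1.0, 5.0),
}


class Condition(str, enum.Enum):
    """Research condition a plot was grown under."""

    INFESTED = "infested"
    NON_INFESTED = "non_infested"


class EntryRole(str, enum.Enum):
    """Role of a hybrid entry in the trial."""

    TESTCROSS = "testcross"
    TESTER_CROSS = "tester_cross"
    CHECK = "check"


class TrialSchemaError(ValueError):
    """A mandatory column is absent or mis-typed."""


class TrialValidationError(ValueError):
    """A row violates a design or trait invariant."""


@dataclass(frozen=True)
class TrialRecord:
    """One plot observation: design coordinates plus trait values."""

    environment: str
    condition: Condition
    replicate: int
    block: str
    entry: str
    entry_role: EntryRole
    line: str | None
    tester: str | None
    traits: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.entry_role is EntryRole.TESTCROSS and (
            self.line is None or self.tester is None
        ):
            raise TrialValidationError(
                f"testcross entry {self.entry!r} must carry both line and tester"
            )
        for name, value in self.traits.items():
            _check_trait_value(name, value, row=self.entry)
        if "striga_damage" in self.traits and not np.isnan(
            self.traits["striga_damage"]
        ):
            if self.condition is not Condition.INFESTED:
                raise TrialValidationError(
                    "striga_damage recorded on a non-infested plot "
                    f"(entry {self.entry!r})"
                )


@dataclass(frozen=True)
class LxTDesign:
    """A line x tester factorial plus checks, over environments.

    ``entries`` maps every testcross entry identifier to its
    ``(line, tester)`` pair.  The tester-cross hybrid (T1 x T2) and the
    checks are listed separately; they are excluded from the factorial
    ANOVA but used as yield references.
    """

    lines: tuple[str, ...]
    testers: tuple[str, ...]
    checks: tuple[str, ...] = ()
    tester_cross_entry: str | None = None
    environments: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    replicates: int = 2
    entries: Mapping[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.lines) < 2 or len(self.testers) < 2:
            raise TrialValidationError("need at least 2 lines and 2 testers")
        if not self.entries:
            object.__setattr__(
                self,
                "entries",
                {
                    testcross_name(li, te): (li, te)
                    for li in self.lines
                    for te in self.testers
                },
            )
        if self.tester_cross_entry in self.entries:
            raise TrialValidationError(
                "tester-cross entry must be distinct from all testcross entries"
            )

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def n_testers(self) -> int:
        return len(self.testers)

    def known_entries(self) -> set[str]:
        known = set(self.entries) | set(self.checks)
        if self.tester_cross_entry is not None:
            known.add(self.tester_cross_entry)
        return known


def testcross_name(line: str, tester: str) -> str:
    return f"{line}x{tester}"


def _check_trait_value(name: str, value: float, row: object = None) -> None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return
    lo, hi = TRAIT_BOUNDS.get(name, (None, None))
    where = f" (row {row!r})" if row is not None else ""
    if lo is not None and value < lo:
        raise TrialValidationError(f"{name}={value} below {lo}{where}")
    if hi is not None and value > hi:
        raise TrialValidationError(f"{name}={value} above {hi}{where}")


def trait_columns(frame: pd.DataFrame) -> list[str]:
    """Columns of *frame* that are trait values, preserving order."""
    return [c for c in frame.columns if c not in DESIGN_COLUMNS]


def validate_trial_frame(
    frame: pd.DataFrame, design: LxTDesign | None = None
) -> pd.DataFrame:
    """Validate a tidy trial table; returns the coerced frame.

    Checks mandatory columns, coerces trait columns to float (empty cell
    = missing), enforces trait bounds and design membership.
    """
    missing = [c for c in DESIGN_COLUMNS if c not in frame.columns]
    if missing:
        raise TrialSchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    traits = trait_columns(frame)
    if not traits:
        raise TrialSchemaError("no trait columns found")
    out = frame.copy()
    out["condition"] = out["condition"].map(lambda v: Condition(v).value)
    out["entry_role"] = out["entry_role"].map(lambda v: EntryRole(v).value)
    out["replicate"] = out["replicate"].astype(int)
    for col in traits:
        try:
            out[col] = pd.to_numeric(out[col])
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(frame[col], errors="coerce")
            idx = out.index[bad.isna() & frame[col].notna()].tolist()
            raise TrialSchemaError(
                f"non-numeric value in trait column {col!r} at row(s) {idx}"
            ) from exc
        lo, hi = TRAIT_BOUNDS.get(col, (None, None))
        vals = out[col]
        if lo is not None and (vals < lo).any():
            bad_rows = out.index[vals < lo].tolist()
            raise TrialValidationError(f"{col} below {lo} at row(s) {bad_rows}")
        if hi is not None and (vals > hi).any():
            bad_rows = out.index[vals > hi].tolist()
            raise TrialValidationError(f"{col} above {hi} at row(s) {bad_rows}")
    if "striga_damage" in traits:
        offside = (out["condition"] != Condition.INFESTED.value) & out[
            "striga_damage"
        ].notna()
        if offside.any():
            raise TrialValidationError(
                "striga_damage present on non-infested row(s) "
                f"{out.index[offside].tolist()}"
            )
    tc = out["entry_role"] == EntryRole.TESTCROSS.value
    if (tc & (out["line"].isna() | out["tester"].isna())).any():
        raise TrialValidationError("testcross rows must carry both line and tester")
    if design is not None:
        known = design.known_entries()
        unknown = sorted(set(out["entry"]) - known)
        if unknown:
            raise TrialValidationError(f"entries not in design: {unknown}")
    return out


def read_trial_csv(path, design: LxTDesign | None = None) -> pd.DataFrame:
    """Read and validate a tidy trial CSV (one row per plot).

    Lines starting with ``#`` are metadata comments and are skipped.
    Empty trait cells become NaN (explicit missing), never zero.
    """
    frame = pd.read_csv(path, comment="#")
    return validate_trial_frame(frame, design)


def write_trial_csv(frame: pd.DataFrame, path, metadata: str | None = None) -> None:
    """Write a trial table as CSV with an optional ``#`` metadata header."""
    with open(path, "w", encoding="utf-8") as fh:
        if metadata:
            fh.write(f"# {metadata}\n")
        frame.to_csv(fh, index=False)


def records_to_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    """Flatten TrialRecord objects into the tidy frame layout."""
    rows = []
    for r in records:
        row = {
            "environment": r.environment,
            "condition": r.condition.value,
            "replicate": r.replicate,
            "block": r.block,
            "entry": r.entry,
            "entry_role": r.entry_role.value,
            "line": r.line,
            "tester": r.tester,
        }
        row.update(r.traits)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(frame: pd.DataFrame) -> list[TrialRecord]:
    traits = trait_columns(frame)
    out = []
    for _, row in frame.iterrows():
        out.append(
            TrialRecord(
                environment=row["environment"],
                condition=Condition(row["condition"]),
                replicate=int(row["replicate"]),
                block=str(row["block"]),
                entry=row["entry"],
                entry_role=EntryRole(row["entry_role"]),
                line=None if pd.isna(row["line"]) else row["line"],
                tester=None if pd.isna(row["tester"]) else row["tester"],
                traits={t: float(row[t]) for t in traits},
            )
        )
    return out


def cell_means(
    frame: pd.DataFrame,
    trait: str,
    condition: str | Condition,
    level: str = "across_env",
) -> pd.DataFrame:
    """Per-entry arithmetic means of *trait* under *condition*.

    ``level="per_env"`` averages over replicates within each environment
    (result indexed by entry x environment); ``"across_env"`` averages
    over replicates and environments. Cells with no data get ``n=0`` and
    a missing mean rather than silently disappearing.
    """
    condition = Condition(condition).value
    if trait not in frame.columns:
        raise TrialSchemaError(f"unknown trait {trait!r}")
    sub = frame[frame["condition"] == condition]
    if level == "per_env":
        keys = ["entry", "environment"]
    elif level == "across_env":
        keys = ["entry"]
    else:
        raise ValueError(f"unknown level {level!r}")
    grouped = sub.groupby(keys)[trait].agg(mean="mean", n="count")
    grouped["n"] = grouped["n"].astype(int)
    return grouped.reset_index()
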