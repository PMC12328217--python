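"""Threat records, expected-decline scoring, and abatement scenarios.

Each IUCN threat listed for a species carries a *scope* (the fraction of the
species' range it affects), a *severity* (the rate of decline it causes) and
a *timing*.  A scope x severity lookup table converts every record into an
expected percentage population decline over 10 years or three generations;
per species, the maximum decline within each second-order threat code becomes
one pseudo-continuous covariate of the extinction-risk model.

Threat-abatement scenarios transform records before scoring:

* ``complete`` — expected decline set to zero for every preventable threat
  (timing Ongoing, Future, or Past likely to return);
* ``partial``  — scopes of Whole or Majority downgraded to Minority;
* ``minimal``  — scope Whole downgraded to Majority.

Threats whose timing is "Past, Unlikely to Return" are never altered: they
cannot be prevented but may still contribute to risk through extinction lags.
Scenarios may be restricted to the threat codes of particular drivers of
extinction (habitat loss, hunting, climate change, ...).
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SCOPES",
    "SEVERITIES",
    "TIMINGS",
    "DRIVERS",
    "PREVENTABLE_TIMINGS",
    "ThreatRecord",
    "DeclineTable",
    "ScenarioSpec",
    "load_decline_table",
    "decline_from_scope_severity",
    "score_species",
    "build_design",
    "group_rare",
    "apply_scenario",
]

SCOPES = ("Whole (>90%)", "Majority (50-90%)", "Minority (<50%)", "Unknown")
SEVERITIES = (
    "very rapid declines",
    "rapid declines",
    "slow significant declines",
    "causing/could cause fluctuations",
    "negligible declines",
    "no decline",
    "unknown",
)
TIMINGS = (
    "Ongoing",
    "Future",
    "Past, Likely to Return",
    "Past, Unlikely to Return",
)
#: Timings whose impact abatement can remove.  "Past, Unlikely to Return"
#: is always retained.
PREVENTABLE_TIMINGS = frozenset(
    {"Ongoing", "Future", "Past, Likely to Return"}
)

DRIVERS = (
    "habitat loss and degradation",
    "hunting and collection",
    "climate change and severe weather",
    "disturbance and accidental mortality",
    "invasive species and disease",
    "pollution",
    "other",
)

#: Scope order used by the monotonicity assertion (narrow to wide).
_SCOPE_ORDER = ("Minority (<50%)", "Majority (50-90%)", "Whole (>90%)")

_CODE2_RE = re.compile(r"^\d{1,2}\.\d{1,2}$")


@dataclass(frozen=True)
class ThreatRecord:
    """One species x threat row.

    ``decline_override``, when set, replaces the table lookup for this record;
    abatement scenarios use it so that the original scope/severity fields are
    preserved (which also makes every scenario transform idempotent).
    """

    species_id: str
    code2: str
    scope: str
    severity: str
    timing: str
    code3: str | None = None
    decline_override: float | None = None

    def __post_init__(self):
        if not _CODE2_RE.match(self.code2):
            raise ValueError(f"invalid second-order threat code: {self.code2!r}")
        if self.scope not in SCOPES:
            raise ValueError(f"unknown scope level: {self.scope!r}")
        if self.severity not in SEVERITIES:
            raise ValueError(f"unknown severity level: {self.severity!r}")
        if self.timing not in TIMINGS:
            raise ValueError(f"unknown timing level: {self.timing!r}")

    @property
    def level1(self) -> str:
        return self.code2.split(".", 1)[0]


@dataclass
class DeclineTable:
    """Scope x severity -> expected % population decline, plus driver grouping.

    ``decline[scope][severity]`` is a percentage in [0, 100].  ``driver_map``
    assigns each level-1 IUCN threat class to one of the seven driver labels.
    """

    decline: dict[str, dict[str, float]]
    driver_map: dict[str, str]
    rare_threshold: int = 10

    def __post_init__(self):
        for scope, row in self.decline.items():
            for severity, value in row.items():
                if not 0.0 <= value <= 100.0:
                    raise ValueError(
                        f"decline out of [0, 100] at ({scope!r}, {severity!r})"
                    )
        for lvl1, driver in self.driver_map.items():
            if driver not in DRIVERS:
                raise ValueError(f"unknown driver label {driver!r} for class {lvl1}")
        # Anchor values quoted in the source method description.
        assert self.lookup("Whole (>90%)", "rapid declines") == 24
        assert self.lookup("Majority (50-90%)", "negligible declines") == 0
        assert self.lookup("Minority (<50%)", "negligible declines") == 0
        assert self.lookup("Minority (<50%)", "no decline") == 0
        # Monotone non-decreasing in scope for every severity: the partial /
        # minimal scenario ordering depends on it.
        for severity in self.decline[_SCOPE_ORDER[0]]:
            vals = [self.decline[s][severity] for s in _SCOPE_ORDER]
            if not (vals[0] <= vals[1] <= vals[2]):
                raise ValueError(f"decline not monotone in scope for {severity!r}")

    def lookup(self, scope: str, severity: str) -> float:
        try:
            return float(self.decline[scope][severity])
        except KeyError:
            raise KeyError(
                f"no decline entry for scope={scope!r}, severity={severity!r}; "
                "unknown levels must be resolved upstream"
            ) from None

    def driver_of(self, code2: str) -> str:
        lvl1 = code2.split(".", 1)[0]
        try:
            return self.driver_map[lvl1]
        except KeyError:
            raise KeyError(f"no driver mapping for threat class {lvl1!r}") from None


def load_decline_table(path: str | None = None) -> DeclineTable:
    """Load the decline table; by default the packaged configuration."""
    if path is None:
        ref = importlib.resources.files("threatspace.data") / "decline_table.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return DeclineTable(
        decline={s: dict(row) for s, row in raw["decline"].items()},
        driver_map={str(k): v for k, v in raw["driver_map"].items()},
        rare_threshold=int(raw.get("rare_threshold", 10)),
    )


def decline_from_scope_severity(
    scope: str, severity: str, table: DeclineTable
) -> float:
    """Exact table lookup, no interpolation."""
    return table.lookup(scope, severity)


def _effective_decline(record: ThreatRecord, table: DeclineTable) -> float:
    if record.decline_override is not None:
        return float(record.decline_override)
    return table.lookup(record.scope, record.severity)


def score_species(
    records: list[ThreatRecord],
    table: DeclineTable,
    codes: list[str] | None = None,
    combine: str = "max",
) -> dict[str, float]:
    """Per second-order code, the combined expected decline over its records.

    All records must belong to one species.  When several records (for
    example several third-order threats) fall under the same second-order
    code, the maximum decline is used by default; ``combine="sum"`` adds
    them instead (capped at 100), a variant with minimal downstream impact.
    If ``codes`` is given, the map covers exactly those codes, filling
    zeros for codes without records.
    """
    if combine not in ("max", "sum"):
        raise ValueError("combine must be 'max' or 'sum'")
    if records:
        ids = {r.species_id for r in records}
        if len(ids) > 1:
            raise ValueError(f"records span multiple species: {sorted(ids)}")
    out: dict[str, float] = {c: 0.0 for c in codes} if codes is not None else {}
    for rec in records:
        d = _effective_decline(rec, table)
        prev = out.get(rec.code2, 0.0)
        if combine == "max":
            out[rec.code2] = max(prev, d)
        else:
            out[rec.code2] = min(prev + d, 100.0)
    return out


def build_design(
    records: list[ThreatRecord],
    species: list[str],
    table: DeclineTable,
    combine: str = "max",
) -> pd.DataFrame:
    """Species x threat-code matrix of expected % declines.

    One column per second-order code present in ``records`` (sorted
    numerically for a stable order); species without a record under a code
    get 0, so zero-decline threats are discarded by construction.
    """
    if len(set(species)) != len(species):
        raise ValueError("duplicate species ids")
    codes = sorted(
        {r.code2 for r in records},
        key=lambda c: tuple(int(p) for p in c.split(".")),
    )
    by_species: dict[str, list[ThreatRecord]] = {s: [] for s in species}
    for rec in records:
        if rec.species_id not in by_species:
            raise ValueError(f"record for unlisted species {rec.species_id!r}")
        by_species[rec.species_id].append(rec)
    X = np.zeros((len(species), len(codes)))
    col = {c: j for j, c in enumerate(codes)}
    for i, s in enumerate(species):
        for code, d in score_species(by_species[s], table, combine=combine).items():
            X[i, col[code]] = d
    return pd.DataFrame(X, index=pd.Index(species, name="species"), columns=codes)


def group_rare(
    design: pd.DataFrame, rare_threshold: int = 10
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Merge threat columns that affect few species.

    Columns with ``rare_threshold`` or fewer affected species (nonzero
    entries) are pooled within their level-1 threat class by elementwise
    maximum; the merged column keeps the numerically smallest member code.
    Returns the grouped design and a merge map {kept column: members}.
    """
    counts = (design.values > 0).sum(axis=0)
    rare = [c for c, n in zip(design.columns, counts) if n <= rare_threshold]
    keep = [c for c in design.columns if c not in rare]
    merges: dict[str, list[str]] = {}
    by_class: dict[str, list[str]] = {}
    for c in rare:
        by_class.setdefault(c.split(".", 1)[0], []).append(c)
    out = design[keep].copy()
    for _, members in sorted(by_class.items(), key=lambda kv: int(kv[0])):
        members = sorted(members, key=lambda c: tuple(int(p) for p in c.split(".")))
        name = members[0]
        out[name] = design[members].max(axis=1)
        merges[name] = members
    # restore numeric column order
    out = out[sorted(out.columns, key=lambda c: tuple(int(p) for p in c.split(".")))]
    return out, merges


@dataclass(frozen=True)
class ScenarioSpec:
    """An abatement scenario: level plus the drivers it applies to."""

    level: str
    drivers: str | frozenset = "all"

    _LEVELS = ("baseline", "complete", "partial", "minimal")

    def __post_init__(self):
        if self.level not in self._LEVELS:
            raise ValueError(f"unknown scenario level {self.level!r}")
        if self.drivers != "all":
            drivers = frozenset(self.drivers)
            for d in drivers:
                if d not in DRIVERS:
                    raise ValueError(f"unknown driver label {d!r}")
            object.__setattr__(self, "drivers", drivers)

    def applies_to(self, driver: str) -> bool:
        return self.drivers == "all" or driver in self.drivers


def apply_scenario(
    records: list[ThreatRecord],
    scenario: ScenarioSpec,
    table: DeclineTable,
) -> list[ThreatRecord]:
    """Transform threat records under an abatement scenario.

    Only records whose timing is preventable (Ongoing, Future, Past likely to
    return) and whose threat code belongs to one of the scenario's drivers
    are altered.  The transform writes ``decline_override`` and leaves
    scope/severity untouched, so applying the same scenario twice is a no-op.
    """
    if scenario.level == "baseline":
        return list(records)
    out: list[ThreatRecord] = []
    for rec in records:
        if rec.timing not in PREVENTABLE_TIMINGS or not scenario.applies_to(
            table.driver_of(rec.code2)
        ):
            out.append(rec)
            continue
        if scenario.level == "complete":
            out.append(replace(rec, decline_override=0.0))
        elif scenario.level == "partial":
            if rec.scope in ("Whole (>90%)", "Majority (50-90%)"):
                out.append(
                    replace(
                        rec,
                        decline_override=table.lookup(
                            "Minority (<50%)", rec.severity
                        ),
                    )
                )
            else:
                out.append(rec)
        else:  # minimal
            if rec.scope == "Whole (>90%)":
                out.append(
                    replace(
                        rec,
                        decline_override=table.lookup(
                            "Majority (50-90%)", rec.severity
                        ),
                    )
                )
            else:
                out.append(rec)
    return out


def records_to_frame(records: list[ThreatRecord]) -> pd.DataFrame:
    """Tidy CSV-ready frame (species_id, code2, code3, scope, severity, timing)."""
    return pd.DataFrame(
        {
            "species_id": [r.species_id for r in records],
            "code2": [r.code2 for r in records],
            "code3": [r.code3 for r in records],
            "scope": [r.scope for r in records],
            "severity": [r.severity for r in records],
            "timing": [r.timing for r in records],
        }
    )


def records_from_frame(df: pd.DataFrame) -> list[ThreatRecord]:
    recs = []
    for row in df.itertuples(index=False):
        code3 = getattr(row, "code3", None)
        if code3 is not None and (code3 != code3 or code3 == ""):  # NaN/empty
            code3 = None
        recs.append(
            ThreatRecord(
                species_id=str(row.species_id),
                code2=str(row.code2),
                code3=code3,
                scope=row.scope,
                severity=row.severity,
                timing=row.timing,
            )
        )
    return recs
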