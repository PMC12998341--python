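"""Childbirth-related code sets and ICD-10 category matching.

Four code sets drive the phenotyping algorithms:

* a diagnosis set of ICD-10 three-character categories covering delivery and
  its immediate complications (the obstetric O-chapter blocks plus the
  delivery-outcome/liveborn categories Z37-Z38);
* a preterm-exclusion subset (placental abruption O45, preterm labour O60,
  cord complications O69) removed for the preterm-excluded algorithm
  variants, because preterm deliveries date poorly against a term-birth
  reference;
* opaque exact-match procedure codes (labour induction, vacuum extraction,
  forceps delivery, caesarean section);
* opaque exact-match medication codes (oxytocin, dinoprostone).

Diagnosis matching is by three-character category prefix: a full code such
as ``O80.1`` or ``O801`` matches through its category ``O80``. Procedure and
medication code values are fee-schedule specific and are supplied through
configuration; the built-in defaults are synthetic placeholders used by the
simulated-claims generator.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = [
    "CodeSets",
    "DEFAULT_DIAGNOSIS_RANGES",
    "DEFAULT_PRETERM_EXCLUSION",
    "DEFAULT_PROCEDURE_CODES",
    "DEFAULT_MEDICATION_CODES",
    "default_codesets",
    "load_codesets",
    "save_codesets",
    "expand_ranges",
    "normalize_icd10",
]

#: ICD-10 category ranges defining the childbirth diagnosis set.
DEFAULT_DIAGNOSIS_RANGES: tuple[str, ...] = (
    "O14-O15",
    "O32-O34",
    "O42",
    "O45",
    "O48",
    "O60-O69",
    "O70-O72",
    "O74-O75",
    "O80-O84",
    "O86-O87",
    "O90",
    "O99",
    "Z37-Z38",
)

#: Categories dropped for the preterm-excluded variants.
DEFAULT_PRETERM_EXCLUSION: tuple[str, ...] = ("O45", "O60", "O69")

#: Synthetic placeholder procedure codes (delivery interventions).
DEFAULT_PROCEDURE_CODES: tuple[str, ...] = (
    "PROC_INDUCTION",
    "PROC_VACUUM",
    "PROC_FORCEPS",
    "PROC_CAESAREAN",
)

#: Synthetic placeholder medication codes (uterotonics).
DEFAULT_MEDICATION_CODES: tuple[str, ...] = ("MED_OXYTOCIN", "MED_DINOPROSTONE")

_CATEGORY_RE = re.compile(r"^[A-Z][0-9]{2}$")
_RANGE_RE = re.compile(r"^([A-Z][0-9]{2})\s*-\s*([A-Z][0-9]{2})$")


def normalize_icd10(code: str) -> str | None:
    """Reduce an ICD-10 code string to its three-character category.

    Dots are stripped (``'O80.1'`` and ``'O801'`` both give ``'O80'``).
    Returns ``None`` for strings that cannot be a category.
    """
    c = code.strip().upper().replace(".", "")
    if len(c) < 3:
        return None
    cat = c[:3]
    return cat if _CATEGORY_RE.match(cat) else None


def expand_ranges(entries) -> set[str]:
    """Expand range entries like ``'O60-O69'`` (or single categories) into
    an explicit category set."""
    out: set[str] = set()
    for entry in entries:
        e = str(entry).strip().upper()
        if _CATEGORY_RE.match(e):
            out.add(e)
            continue
        m = _RANGE_RE.match(e)
        if m is None:
            raise ConfigError(f"malformed ICD-10 category or range: {entry!r}")
        start, end = m.group(1), m.group(2)
        if start[0] != end[0]:
            raise ConfigError(f"range endpoints use different letters: {entry!r}")
        lo, hi = int(start[1:]), int(end[1:])
        if lo > hi:
            raise ConfigError(f"range start exceeds end: {entry!r}")
        out.update(f"{start[0]}{i:02d}" for i in range(lo, hi + 1))
    return out


@dataclass(frozen=True)
class CodeSets:
    """The four code sets used by the phenotyping algorithms."""

    diagnosis: frozenset[str]
    preterm_exclusion: frozenset[str]
    procedure: frozenset[str]
    medication: frozenset[str]
    #: Source ranges retained so a round-trip through config is lossless.
    diagnosis_ranges: tuple[str, ...] = field(default=DEFAULT_DIAGNOSIS_RANGES)

    def __post_init__(self) -> None:
        if not self.diagnosis:
            raise ConfigError("diagnosis code set is empty")
        bad = [c for c in self.diagnosis if not _CATEGORY_RE.match(c)]
        if bad:
            raise ConfigError(f"invalid ICD-10 categories in diagnosis set: {sorted(bad)}")
        stray = self.preterm_exclusion - self.diagnosis
        if stray:
            raise ConfigError(
                f"preterm exclusion categories not in diagnosis set: {sorted(stray)}"
            )
        if not self.procedure or not self.medication:
            raise ConfigError("procedure and medication code sets must be non-empty")
        if self.procedure & self.medication:
            raise ConfigError(
                "procedure and medication code sets overlap: "
                f"{sorted(self.procedure & self.medication)}"
            )

    # -- diagnosis matching -------------------------------------------------

    def matches_diagnosis(self, code: str, exclude_preterm: bool = False) -> bool:
        """True iff ``code``'s ICD-10 category is in the diagnosis set
        (minus the preterm-exclusion subset when ``exclude_preterm``)."""
        cat = normalize_icd10(code)
        if cat is None:
            return False
        if exclude_preterm and cat in self.preterm_exclusion:
            return False
        return cat in self.diagnosis

    def restrict_preterm(self) -> "CodeSets":
        """Return code sets with the preterm-exclusion categories removed
        from the diagnosis set (idempotent; procedure/medication unchanged)."""
        remaining = self.diagnosis - self.preterm_exclusion
        return CodeSets(
            diagnosis=remaining,
            preterm_exclusion=frozenset(),
            procedure=self.procedure,
            medication=self.medication,
            diagnosis_ranges=tuple(sorted(remaining)),
        )

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "diagnosis_ranges": list(self.diagnosis_ranges),
            "preterm_exclusion": sorted(self.preterm_exclusion),
            "procedure_codes": sorted(self.procedure),
            "medication_codes": sorted(self.medication),
        }


def default_codesets() -> CodeSets:
    """The built-in code sets (34 diagnosis categories)."""
    return CodeSets(
        diagnosis=frozenset(expand_ranges(DEFAULT_DIAGNOSIS_RANGES)),
        preterm_exclusion=frozenset(DEFAULT_PRETERM_EXCLUSION),
        procedure=frozenset(DEFAULT_PROCEDURE_CODES),
        medication=frozenset(DEFAULT_MEDICATION_CODES),
    )


def _from_mapping(raw: dict, source: str) -> CodeSets:
    known = {"diagnosis_ranges", "preterm_exclusion", "procedure_codes", "medication_codes"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{source}: unknown keys {sorted(unknown)}")
    ranges = tuple(str(r) for r in raw.get("diagnosis_ranges", DEFAULT_DIAGNOSIS_RANGES))
    try:
        diagnosis = expand_ranges(ranges)
        exclusion = expand_ranges(raw.get("preterm_exclusion", DEFAULT_PRETERM_EXCLUSION))
    except ConfigError as exc:
        raise ConfigError(f"{source}: {exc}") from exc
    procedure = frozenset(
        str(c) for c in raw.get("procedure_codes", DEFAULT_PROCEDURE_CODES)
    )
    medication = frozenset(
        str(c) for c in raw.get("medication_codes", DEFAULT_MEDICATION_CODES)
    )
    try:
        return CodeSets(
            diagnosis=frozenset(diagnosis),
            preterm_exclusion=frozenset(exclusion),
            procedure=procedure,
            medication=medication,
            diagnosis_ranges=ranges,
        )
    except ConfigError as exc:
        raise ConfigError(f"{source}: {exc}") from exc


def load_codesets(path: str | Path | None = None) -> CodeSets:
    """Load code sets from a YAML/JSON config file; ``None`` gives defaults.

    Omitted sections fall back to the defaults; ranges are expanded to
    explicit categories at load time.
    """
    if path is None:
        return default_codesets()
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: cannot parse config: {exc}") from exc
    if raw is None:
        return default_codesets()
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return _from_mapping(raw, str(path))


def save_codesets(cs: CodeSets, path: str | Path) -> None:
    """Write code sets as YAML; ``load_codesets`` round-trips the result."""
    Path(path).write_text(yaml.safe_dump(cs.to_dict(), sort_keys=False))
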