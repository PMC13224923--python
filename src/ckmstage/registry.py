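"""Machine-actionable ICD-10-CM code sets for CKM syndrome stages 0-4.

The registry is the authoritative description of which diagnosis codes
define or support each cardiovascular-kidney-metabolic (CKM) stage.  It is
shipped as a canonical JSON document (with a flattened CSV companion for
review and audit) and loaded into typed objects:

* :class:`CodePattern` -- one literal code, a code-family prefix (the
  machine form of hyphen shorthand such as ``I25.-``), or an explicit code
  range (``Z68.25-Z68.45``), with subtractive exclusions.
* :class:`CodeSet` -- a named group of patterns with a role
  (stage-defining core, supplementary, exclusion, or substage marker) and
  a condition acuity (chronic vs acute) that selects the encounter
  confirmation rule.
* :class:`StageDefinition` / :class:`Registry` -- the five stage rows and
  the code sets they reference.

Codes are stored dotless and uppercase internally; the dotted display form
is regenerated on demand.  Descendant inclusion is always explicit: a
family pattern includes descendants by construction, a literal never does.
"""

from __future__ import annotations

import csv
import io
import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator

from .errors import CodeValidationError, RegistryError

__all__ = [
    "CodePattern",
    "CodeSet",
    "StageDefinition",
    "Registry",
    "normalize_code",
    "dotted_code",
    "code_matches",
    "classify_code",
    "load_registry",
    "export_registry_json",
    "export_registry_csv",
    "validate_registry",
    "default_registry",
    "PATTERN_KINDS",
    "SET_ROLES",
    "ACUITIES",
]

_CODE_RE = re.compile(r"^[A-Z][A-Z0-9]{2,6}$")

PATTERN_KINDS = ("literal", "family", "range")
SET_ROLES = ("stage_core", "supplementary", "exclusion", "substage_marker")
ACUITIES = ("chronic", "acute")


def normalize_code(raw: str) -> str:
    """Normalize an ICD-10-CM code string to its canonical dotless form.

    Uppercases, strips whitespace, and removes the conventional decimal
    point after the category characters.  Idempotent.

    Raises
    ------
    CodeValidationError
        If the result is not 3-7 alphanumeric characters starting with a
        letter (the ICD-10-CM code shape).
    """
    if raw is None:
        raise CodeValidationError("ICD-10-CM code is missing")
    code = str(raw).strip().upper().replace(".", "")
    if not code:
        raise CodeValidationError("ICD-10-CM code is empty")
    if not _CODE_RE.match(code):
        raise CodeValidationError(f"malformed ICD-10-CM code: {raw!r}")
    return code


def dotted_code(code: str) -> str:
    """Render a normalized code in conventional dotted display form."""
    if len(code) > 3:
        return code[:3] + "." + code[3:]
    return code


def _stem(code: str) -> str:
    return code[:3]


@dataclass(frozen=True)
class CodePattern:
    """One matching rule over normalized ICD-10-CM codes.

    kind
        ``literal`` (exact code), ``family`` (the stem and every
        descendant), or ``range`` (an explicit span such as
        ``Z6825-Z6845``, descendants of in-span codes included).
    value
        The normalized code/stem, or ``"LO-HI"`` for a range.
    exclusions
        Patterns applied subtractively; an excluded code never matches.
    """

    kind: str
    value: str
    exclusions: tuple["CodePattern", ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in PATTERN_KINDS:
            raise RegistryError(f"unknown pattern kind: {self.kind!r}")
        if self.kind == "range":
            lo, hi = self.bounds()
            if not (_stem(lo) == _stem(hi) or (lo[0] == hi[0] and _stem(lo) <= _stem(hi))):
                raise RegistryError(
                    f"range bounds {lo}-{hi} must share a 3-character stem "
                    "or the same leading letter with ordered stems"
                )
            if lo > hi:
                raise RegistryError(f"range lower bound {lo} exceeds upper bound {hi}")
        else:
            normalize_code(self.value)  # shape check; value stored normalized
            if self.value != normalize_code(self.value):
                raise RegistryError(f"pattern value not normalized: {self.value!r}")

    def bounds(self) -> tuple[str, str]:
        """Lower/upper bounds of a range pattern (normalized)."""
        if self.kind != "range":
            raise RegistryError(f"pattern {self.value!r} is not a range")
        try:
            lo_raw, hi_raw = self.value.split("-")
        except ValueError:
            raise RegistryError(f"range value must be 'LO-HI': {self.value!r}") from None
        return normalize_code(lo_raw), normalize_code(hi_raw)

    def _base_match(self, code: str) -> bool:
        if self.kind == "literal":
            return code == self.value
        if self.kind == "family":
            return code.startswith(self.value)
        lo, hi = self.bounds()
        # A code is in-span when it sorts at or above the lower bound and
        # its prefix truncated to the upper bound's length does not exceed
        # it -- so I60-I64 captures I639, and Z6825-Z6845 captures Z6841.
        return code >= lo and code[: len(hi)] <= hi

    def matches(self, code: str) -> bool:
        """True when ``code`` (normalized) is in the pattern net exclusions."""
        if not self._base_match(code):
            return False
        return not any(exc.matches(code) for exc in self.exclusions)

    def display(self) -> str:
        if self.kind == "range":
            lo, hi = self.bounds()
            return f"{dotted_code(lo)}-{dotted_code(hi)}"
        if self.kind == "family":
            return dotted_code(self.value) + ".-" if len(self.value) == 3 else dotted_code(self.value) + "-"
        return dotted_code(self.value)


def code_matches(code: str, pattern: CodePattern) -> bool:
    """Functional form of :meth:`CodePattern.matches`."""
    return pattern.matches(code)


@dataclass(frozen=True)
class CodeSet:
    """A named collection of patterns with a role and condition acuity."""

    name: str
    role: str
    acuity: str
    patterns: tuple[CodePattern, ...]

    def __post_init__(self) -> None:
        if self.role not in SET_ROLES:
            raise RegistryError(f"code set {self.name!r}: unknown role {self.role!r}")
        if self.acuity not in ACUITIES:
            raise RegistryError(f"code set {self.name!r}: unknown acuity {self.acuity!r}")
        if not self.patterns:
            raise RegistryError(f"code set {self.name!r} has no patterns")

    def matches(self, code: str) -> bool:
        return any(p.matches(code) for p in self.patterns)


@dataclass(frozen=True)
class StageDefinition:
    """One CKM stage row: referenced code sets and its co-occurrence rule."""

    stage: int
    cooccurrence_rule: str
    core_sets: tuple[str, ...] = ()
    supplementary_sets: tuple[str, ...] = ()
    exclusion_sets: tuple[str, ...] = ()
    substage_marker_sets: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.stage not in range(5):
            raise RegistryError(f"stage must be 0-4, got {self.stage}")
        if self.stage == 0 and self.core_sets:
            raise RegistryError("stage 0 is defined by absence and has no core sets")

    def referenced_sets(self) -> Iterator[tuple[str, str]]:
        """Yield (reference-kind, set-name) over all four reference lists."""
        for kind, names in (
            ("core", self.core_sets),
            ("supplementary", self.supplementary_sets),
            ("exclusion", self.exclusion_sets),
            ("substage_marker", self.substage_marker_sets),
        ):
            for name in names:
                yield kind, name


@dataclass(frozen=True)
class Registry:
    """The full stage 0-4 code-set specification."""

    version: str
    code_sets: tuple[CodeSet, ...]
    stages: tuple[StageDefinition, ...]
    _by_name: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        names = [cs.name for cs in self.code_sets]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise RegistryError(f"duplicate code-set names: {sorted(dupes)}")
        object.__setattr__(self, "_by_name", {cs.name: cs for cs in self.code_sets})
        stage_ids = sorted(s.stage for s in self.stages)
        if stage_ids != [0, 1, 2, 3, 4]:
            raise RegistryError(f"registry must define stages 0-4 exactly once, got {stage_ids}")
        for sd in self.stages:
            for _, name in sd.referenced_sets():
                if name not in self._by_name:
                    raise RegistryError(
                        f"stage {sd.stage} references undefined code set {name!r}"
                    )

    def code_set(self, name: str) -> CodeSet:
        try:
            return self._by_name[name]
        except KeyError:
            raise RegistryError(f"no code set named {name!r}") from None

    def stage(self, k: int) -> StageDefinition:
        for sd in self.stages:
            if sd.stage == k:
                return sd
        raise RegistryError(f"no stage {k} in registry")

    def set_names(self) -> tuple[str, ...]:
        return tuple(cs.name for cs in self.code_sets)


def classify_code(code: str, registry: Registry) -> list[tuple[int, str, str]]:
    """Every (stage, role, set-name) whose patterns match a normalized code.

    Membership references only: a stage's core, supplementary, and
    substage-marker lists place a code *in* that stage's row; exclusion
    references point at other stages' sets and are not membership.
    Results are ordered by stage ascending, then set name.
    """
    hits: list[tuple[int, str, str]] = []
    for sd in sorted(registry.stages, key=lambda s: s.stage):
        names = sorted(set(sd.core_sets) | set(sd.supplementary_sets) | set(sd.substage_marker_sets))
        for name in names:
            cs = registry.code_set(name)
            if cs.matches(code):
                hits.append((sd.stage, cs.role, name))
    return hits


# ---------------------------------------------------------------------------
# JSON (authoritative) and CSV (flattened companion) serialization
# ---------------------------------------------------------------------------

def _pattern_to_json(p: CodePattern) -> dict:
    return {
        "kind": p.kind,
        "value": p.value,
        "exclusions": [_pattern_to_json(e) for e in p.exclusions],
    }


def _pattern_from_json(obj, path: str) -> CodePattern:
    if not isinstance(obj, dict):
        raise RegistryError(f"{path}: pattern must be an object")
    for key in ("kind", "value"):
        if key not in obj:
            raise RegistryError(f"{path}.{key}: required key missing")
    exclusions = tuple(
        _pattern_from_json(e, f"{path}.exclusions[{i}]")
        for i, e in enumerate(obj.get("exclusions", []))
    )
    try:
        return CodePattern(kind=obj["kind"], value=obj["value"], exclusions=exclusions)
    except (RegistryError, CodeValidationError) as err:
        raise RegistryError(f"{path}: {err}") from None


def load_registry(document: str) -> Registry:
    """Parse and validate a registry JSON document.

    Errors cite the JSON path of the offending element; dangling code-set
    references name the stage and the missing set.
    """
    try:
        doc = json.loads(document)
    except json.JSONDecodeError as err:
        raise RegistryError(f"registry document is not valid JSON: {err}") from None
    if not isinstance(doc, dict):
        raise RegistryError("$: registry document must be a JSON object")
    for key in ("version", "code_sets", "stages"):
        if key not in doc:
            raise RegistryError(f"$.{key}: required key missing")
    if not isinstance(doc["version"], str):
        raise RegistryError("$.version: must be a string")
    if not isinstance(doc["code_sets"], list):
        raise RegistryError("$.code_sets: must be an array")
    if not isinstance(doc["stages"], list):
        raise RegistryError("$.stages: must be an array")

    code_sets = []
    for i, cs in enumerate(doc["code_sets"]):
        path = f"$.code_sets[{i}]"
        if not isinstance(cs, dict):
            raise RegistryError(f"{path}: must be an object")
        for key in ("name", "role", "acuity", "patterns"):
            if key not in cs:
                raise RegistryError(f"{path}.{key}: required key missing")
        patterns = tuple(
            _pattern_from_json(p, f"{path}.patterns[{j}]")
            for j, p in enumerate(cs["patterns"])
        )
        try:
            code_sets.append(
                CodeSet(name=cs["name"], role=cs["role"], acuity=cs["acuity"], patterns=patterns)
            )
        except RegistryError as err:
            raise RegistryError(f"{path}: {err}") from None

    stages = []
    for i, sd in enumerate(doc["stages"]):
        path = f"$.stages[{i}]"
        if not isinstance(sd, dict):
            raise RegistryError(f"{path}: must be an object")
        for key in ("stage", "cooccurrence_rule"):
            if key not in sd:
                raise RegistryError(f"{path}.{key}: required key missing")
        try:
            stages.append(
                StageDefinition(
                    stage=sd["stage"],
                    cooccurrence_rule=sd["cooccurrence_rule"],
                    core_sets=tuple(sd.get("core_sets", [])),
                    supplementary_sets=tuple(sd.get("supplementary_sets", [])),
                    exclusion_sets=tuple(sd.get("exclusion_sets", [])),
                    substage_marker_sets=tuple(sd.get("substage_marker_sets", [])),
                )
            )
        except RegistryError as err:
            raise RegistryError(f"{path}: {err}") from None

    return Registry(version=doc["version"], code_sets=tuple(code_sets), stages=tuple(stages))


def export_registry_json(registry: Registry) -> str:
    """Serialize to canonical JSON text (a fixed point of load -> export)."""
    doc = {
        "version": registry.version,
        "code_sets": [
            {
                "name": cs.name,
                "role": cs.role,
                "acuity": cs.acuity,
                "patterns": [_pattern_to_json(p) for p in cs.patterns],
            }
            for cs in registry.code_sets
        ],
        "stages": [
            {
                "stage": sd.stage,
                "cooccurrence_rule": sd.cooccurrence_rule,
                "core_sets": list(sd.core_sets),
                "supplementary_sets": list(sd.supplementary_sets),
                "exclusion_sets": list(sd.exclusion_sets),
                "substage_marker_sets": list(sd.substage_marker_sets),
            }
            for sd in sorted(registry.stages, key=lambda s: s.stage)
        ],
    }
    return json.dumps(doc, indent=2, ensure_ascii=False) + "\n"


def _set_stage_map(registry: Registry) -> dict[str, int]:
    """Map each code set to the stage row it belongs to (membership refs)."""
    out: dict[str, int] = {}
    for sd in sorted(registry.stages, key=lambda s: s.stage):
        for kind, name in sd.referenced_sets():
            if kind != "exclusion" and name not in out:
                out[name] = sd.stage
    return out


def export_registry_csv(registry: Registry) -> str:
    """Flattened companion CSV: one row per (stage, set, pattern)."""
    stage_of = _set_stage_map(registry)
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(
        ["stage", "set_name", "role", "acuity", "pattern_kind", "pattern_value", "exclusions"]
    )
    for sd in sorted(registry.stages, key=lambda s: s.stage):
        seen: set[str] = set()
        for kind, name in sd.referenced_sets():
            if kind == "exclusion" or name in seen or stage_of.get(name) != sd.stage:
                continue
            seen.add(name)
            cs = registry.code_set(name)
            for p in cs.patterns:
                writer.writerow(
                    [
                        sd.stage,
                        cs.name,
                        cs.role,
                        cs.acuity,
                        p.kind,
                        p.value,
                        ";".join(e.value for e in p.exclusions),
                    ]
                )
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Registry quality checks
# ---------------------------------------------------------------------------

_VERY_HIGH_RISK_CKD = ("N184", "N185")
_KIDNEY_FAILURE = ("N186",)


def validate_registry(registry: Registry) -> list[str]:
    """Content-level findings beyond structural validity.

    Returns human-readable findings (empty for a clean registry) rather
    than raising: malformed pattern values, empty sets and duplicate names
    are caught at construction, so the checks here are semantic -- most
    importantly that the stage-2 moderate/high-risk CKD proxy does not
    swallow very high-risk CKD (N18.4-N18.5) or kidney failure (N18.6),
    which must route to stages 3 and 4B respectively.
    """
    findings: list[str] = []
    stage2 = registry.stage(2)
    for name in stage2.core_sets:
        cs = registry.code_set(name)
        if not any(p.value.startswith("N18") or p.kind == "range" and p.bounds()[0].startswith("N18") for p in cs.patterns):
            continue
        for code in _VERY_HIGH_RISK_CKD + _KIDNEY_FAILURE:
            if cs.matches(code):
                label = "kidney failure" if code in _KIDNEY_FAILURE else "very high-risk CKD"
                findings.append(
                    f"stage 2 CKD proxy set {name!r} matches {dotted_code(code)}: "
                    f"must exclude {label} (routes to stage {'4B' if code in _KIDNEY_FAILURE else '3'})"
                )
    # acute acuity is reserved for event-type sets
    event_sets = {"acute_mi", "stroke_acute"}
    for cs in registry.code_sets:
        if cs.acuity == "acute" and cs.name not in event_sets:
            findings.append(
                f"code set {cs.name!r} is marked acute but is not a recognized event-type set"
            )
    # every set should be referenced by some stage
    referenced = {name for sd in registry.stages for _, name in sd.referenced_sets()}
    for cs in registry.code_sets:
        if cs.name not in referenced:
            findings.append(f"code set {cs.name!r} is not referenced by any stage")
    return findings


def default_registry() -> Registry:
    """Load the shipped FY2026 registry."""
    text = resources.files("ckmstage.data").joinpath("registry_fy2026.json").read_text("utf-8")
    return load_registry(text)


def iter_registry_codes(registry: Registry) -> Iterable[str]:
    """All concrete codes named in the registry (literals and range bounds);
    family stems are included as codes in their own right."""
    seen: set[str] = set()

    def walk(p: CodePattern) -> Iterator[str]:
        if p.kind == "range":
            lo, hi = p.bounds()
            yield lo
            yield hi
        else:
            yield p.value
        for e in p.exclusions:
            yield from walk(e)

    for cs in registry.code_sets:
        for p in cs.patterns:
            for c in walk(p):
                if c not in seen:
                    seen.add(c)
                    yield c
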