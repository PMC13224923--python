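"""Independent explicit-expansion oracle for code-pattern matching.

Instead of the engine's lexicographic comparison with upper-bound
truncation, each pattern is expanded into an explicit list of allowed
code prefixes, and membership is a plain startswith/equality test:

* literal  -> the code itself, equality only (no descendants)
* family   -> the stem as a prefix (descendants by construction)
* range    -> enumerate every in-span code at the bounds' granularity
              (same-stem numeric suffixes counted out one by one, or
              whole 3-character stems for bare-stem ranges) and treat
              each as a prefix

Exclusions are applied subtractively after the base decision.  This is a
deliberately different algorithm from the shipped matcher; the two must
agree on every code.
"""

from ckmstage.registry import CodePattern


def _expand_prefixes(pattern: CodePattern) -> tuple[str, ...] | None:
    """Explicit prefix list for a family/range pattern; None for literal."""
    if pattern.kind == "literal":
        return None
    if pattern.kind == "family":
        return (pattern.value,)
    lo, hi = pattern.bounds()
    if len(lo) == len(hi) == 3:
        # bare-stem span like I60-I64: count the stems out
        head, lo_n, hi_n = lo[0], int(lo[1:]), int(hi[1:])
        return tuple(f"{head}{n:02d}" for n in range(lo_n, hi_n + 1))
    if lo[:3] == hi[:3] and len(lo) == len(hi):
        # same-stem numeric suffixes like Z6825-Z6845 or N1830-N1832
        stem, width = lo[:3], len(lo) - 3
        lo_n, hi_n = int(lo[3:]), int(hi[3:])
        return tuple(f"{stem}{n:0{width}d}" for n in range(lo_n, hi_n + 1))
    raise NotImplementedError(f"oracle cannot expand range {pattern.value!r}")


def oracle_matches(code: str, pattern: CodePattern) -> bool:
    if pattern.kind == "literal":
        base = code == pattern.value
    else:
        base = any(code.startswith(p) for p in _expand_prefixes(pattern))
    if not base:
        return False
    return not any(oracle_matches(code, exc) for exc in pattern.exclusions)
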