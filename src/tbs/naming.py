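"""Feature-name grammar: Condition[_Context]_Descriptor.

Condition is one of the four route-phase combinations (NoseInspiration,
NoseExpiration, MouthInspiration, MouthExpiration) or ``Average`` (mean of a
descriptor across the four conditions).  The optional Context marks where the
descriptor was evaluated: ``Range`` = inside the class-pair 1D spectral gap
band, ``BBox`` = inside the class-pair 2D bispectral gap box.  Descriptors are
single CamelCase tokens (no underscores), so every key parses back uniquely.
"""

from __future__ import annotations

CONDITIONS = ("NoseInspiration", "NoseExpiration",
              "MouthInspiration", "MouthExpiration", "Average")
CONTEXTS = ("Range", "BBox")


def make_name(condition: str, descriptor: str, context: str | None = None) -> str:
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if context is not None and context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    if "_" in descriptor or not descriptor:
        raise ValueError(f"descriptor must be a single token: {descriptor!r}")
    parts = [condition] + ([context] if context else []) + [descriptor]
    return "_".join(parts)


def parse_name(name: str) -> tuple[str, str | None, str]:
    """Return (condition, context, descriptor); raises on malformed keys."""
    parts = name.split("_")
    if len(parts) == 2:
        cond, desc = parts
        ctx = None
    elif len(parts) == 3:
        cond, ctx, desc = parts
        if ctx not in CONTEXTS:
            raise ValueError(f"unknown context in {name!r}")
    else:
        raise ValueError(f"malformed feature name {name!r}")
    if cond not in CONDITIONS:
        raise ValueError(f"unknown condition in {name!r}")
    if not desc:
        raise ValueError(f"empty descriptor in {name!r}")
    return cond, ctx, desc


def condition_of(route: str, phase: str) -> str:
    return route.capitalize() + phase.capitalize()
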