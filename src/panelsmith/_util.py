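"""Small shared helpers: half-up rounding and chromosome-name joining."""

from __future__ import annotations

import io
import os
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (school rounding, not banker's).

    Percentages and sizes in this package are reported at two decimals with
    half-up rounding (e.g. 169.169 Kb -> 169.17).
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def normalize_chrom(name: str) -> str:
    """Strip an optional 'chr' prefix so bare and prefixed names join."""
    return name[3:] if name.lower().startswith("chr") else name


def as_text(source) -> str:
    """Accept a path, os.PathLike, or text stream and return its contents.

    Strings containing a newline or tab are treated as literal text, not
    paths, so small tables can be passed inline.
    """
    if isinstance(source, io.IOBase) or hasattr(source, "read"):
        return source.read()
    if isinstance(source, os.PathLike):
        return open(os.fspath(source)).read()
    if isinstance(source, str):
        if not source or "\n" in source or "\t" in source:
            return source
        return open(source).read()
    raise TypeError(f"cannot read from {type(source).__name__}")
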