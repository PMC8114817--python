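"""Reading numeric vectors from plain-text files."""

from __future__ import annotations

from pathlib import Path
from typing import IO, Iterable, List, Union


def parse_number(token: str) -> Union[int, float]:
    """Integers stay exact; anything else parses as float."""
    try:
        return int(token)
    except ValueError:
        return float(token)


def read_values(source: Union[str, Path, IO[str], Iterable[str]]) -> List[Union[int, float]]:
    """Read one numeric value per line (single-column CSV accepted).

    Blank lines and ``#`` comments are skipped; a trailing comma on a
    line (single-column CSV) is tolerated.
    """
    if isinstance(source, (str, Path)):
        with open(source) as handle:
            lines = handle.readlines()
    else:
        lines = list(source)
    values = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip().rstrip(",").strip()
        if not line or line.startswith("#"):
            continue
        try:
            values.append(parse_number(line))
        except ValueError:
            raise ValueError(f"line {lineno}: not a number: {line!r}") from None
    return values
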