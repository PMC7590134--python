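"""Readers for delimited IMU text files and corpus assembly.

Two dialects are built in:

* ``FIXED_CSV`` — this package's constant-width baseline CSV
  (sign + 5 digits, comma separated).
* ``HUGADB`` — gait-database style text: ``#``-prefixed metadata lines,
  one whitespace-separated column-name header, then tab/space separated
  integer rows; 36 leading columns hold six body segments x six IMU
  channels, trailing columns (EMG, activity id) are ignored for corpus
  assembly. Filenames carry activity/subject/trial tags.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .predictors import INT16_MAX, INT16_MIN, SignalChannel


@dataclass(frozen=True)
class Dialect:
    """Parsing rules for a delimited integer table."""

    delimiter: str | None = None       # None = any whitespace
    comment: str = "#"
    has_header: bool = False           # one column-name line before the data
    name: str = "generic"


FIXED_CSV = Dialect(delimiter=",", comment="#", has_header=False, name="fixed-csv")
HUGADB = Dialect(delimiter=None, comment="#", has_header=True, name="hugadb")

#: HuGaDB-style naming: <prefix>_<activity>_<subject>_<trial>.txt
DEFAULT_FILENAME_RE = re.compile(
    r"^(?:[A-Za-z0-9]+_)*?(?P<activity>[a-z][a-z_]*?)_(?P<subject>\d+)_(?P<trial>\d+)\.txt$"
)

#: column grouping for six-node lower-body files: 6 consecutive columns
#: (acc xyz + gyro xyz) per segment
DEFAULT_SEGMENTS = (
    "right_foot", "right_shank", "right_thigh",
    "left_foot", "left_shank", "left_thigh",
)
CHANNELS_PER_SEGMENT = 6


@dataclass(frozen=True)
class TestCase:
    """One unit of the benchmark: six equal-length co-located channels
    tagged by subject, activity, trial and body segment."""

    subject: str
    activity: str
    trial: int
    segment: str
    channels: list[SignalChannel] = field(repr=False)

    def __post_init__(self) -> None:
        lengths = {len(c) for c in self.channels}
        if len(self.channels) != 6 or len(lengths) != 1:
            raise ValueError("a test case is exactly 6 equal-length channels")

    @property
    def case_id(self) -> str:
        return f"{self.subject}/{self.activity}/{self.trial}/{self.segment}"


def read_delimited(
    path: str | Path,
    dialect: Dialect = HUGADB,
    rate_hz: float = 60.0,
    validate_int16: bool = True,
) -> tuple[list[SignalChannel], list[str]]:
    """Parse a delimited integer table into per-column channels.

    Returns (channels, column names); names are empty strings when the
    dialect has no header line. Raises ValueError naming the offending
    row/column on non-integer cells, out-of-range values, or ragged rows.
    """
    path = Path(path)
    names: list[str] = []
    rows: list[list[int]] = []
    header_pending = dialect.has_header
    with path.open("r", encoding="ascii") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(dialect.comment):
                continue
            tokens = line.split(dialect.delimiter)
            if header_pending:
                header_pending = False
                names = [t.strip() for t in tokens]
                continue
            row = []
            for col, token in enumerate(tokens, start=1):
                try:
                    value = int(token)
                except ValueError:
                    raise ValueError(
                        f"{path.name}:{lineno}: column {col}: "
                        f"{token!r} is not an integer"
                    ) from None
                if validate_int16 and not (INT16_MIN <= value <= INT16_MAX):
                    raise ValueError(
                        f"{path.name}:{lineno}: column {col}: "
                        f"value {value} outside 16-bit signed range"
                    )
                row.append(value)
            if rows and len(row) != len(rows[0]):
                raise ValueError(
                    f"{path.name}:{lineno}: ragged row "
                    f"({len(row)} columns, expected {len(rows[0])})"
                )
            rows.append(row)
    if not rows:
        raise ValueError(f"{path.name}: no data rows")
    matrix = np.array(rows, dtype=np.int64)
    channels = [
        SignalChannel(
            matrix[:, j],
            rate_hz=rate_hz,
            label=names[j] if j < len(names) else f"col{j}",
        )
        for j in range(matrix.shape[1])
    ]
    return channels, names


def parse_case_filename(
    name: str, pattern: re.Pattern = DEFAULT_FILENAME_RE
) -> dict | None:
    match = pattern.match(name)
    if not match:
        return None
    d = match.groupdict()
    return {"activity": d["activity"], "subject": d["subject"], "trial": int(d["trial"])}


def build_corpus(
    root: str | Path,
    exclusions: list[str] | None = None,
    dialect: Dialect = HUGADB,
    segments: tuple[str, ...] = DEFAULT_SEGMENTS,
    pattern: re.Pattern = DEFAULT_FILENAME_RE,
) -> list[TestCase]:
    """Assemble test cases from a directory of recording files.

    Each file yields one case per body segment (six consecutive columns
    each). Files listed in ``exclusions`` (by filename) are skipped —
    intended for externally published corruption lists; unparseable
    filenames are skipped with a warning.
    """
    root = Path(root)
    excluded = set(exclusions or [])
    cases: list[TestCase] = []
    for path in sorted(root.glob("*.txt")):
        if path.name in excluded:
            continue
        tags = parse_case_filename(path.name, pattern)
        if tags is None:
            warnings.warn(f"cannot parse filename {path.name!r}; skipped", stacklevel=2)
            continue
        channels, _ = read_delimited(path, dialect)
        if len(channels) < CHANNELS_PER_SEGMENT * len(segments):
            raise ValueError(
                f"{path.name}: {len(channels)} columns, need at least "
                f"{CHANNELS_PER_SEGMENT * len(segments)}"
            )
        for si, segment in enumerate(segments):
            group = channels[si * CHANNELS_PER_SEGMENT : (si + 1) * CHANNELS_PER_SEGMENT]
            cases.append(
                TestCase(
                    subject=tags["subject"],
                    activity=tags["activity"],
                    trial=tags["trial"],
                    segment=segment,
                    channels=group,
                )
            )
    return cases


def load_exclusion_list(path: str | Path) -> list[str]:
    """One filename per line; blank lines and ``#`` comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out
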