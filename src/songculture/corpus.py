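"""Domain types and tabular I/O for transcribed humpback whale song.

Song has a nested structure: *units* (single sounds, labelled by type) are
sung in stereotyped order to form a *phrase*; a repeated phrase is a *theme*;
distinct themes sung in order form a *song cycle*.  Phrase types carry a
numeric label plus an optional variant letter ("1", "2A"); the numeric part
identifies the theme.

All tables are UTF-8 comma-separated text with a header row.  Ordered
unit/theme sequences are stored as single space-delimited columns, so unit
labels must not contain whitespace.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UnitObservation",
    "PhraseString",
    "SongString",
    "ThemePresence",
    "SimilarityMatrix",
    "CorpusError",
    "SchemaError",
    "RowValidationError",
    "parse_phrase_type",
    "song_string_from_theme_sequence",
    "read_phrase_table",
    "write_phrase_table",
    "read_song_table",
    "write_song_table",
    "read_presence_table",
    "write_presence_table",
    "read_unit_table",
    "theme_inventory_summary",
]


class CorpusError(ValueError):
    """Base class for corpus validation failures."""


class SchemaError(CorpusError):
    """A table is missing a required column."""


class RowValidationError(CorpusError):
    """A table row violates a domain invariant; carries the row number."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


_PHRASE_TYPE_RE = re.compile(r"^([0-9]+)([A-Z])?$")

#: relative tolerance for the bandwidth = high − low consistency check
BANDWIDTH_RTOL = 1e-3


def parse_phrase_type(label: str) -> tuple[int, str | None]:
    """Split a phrase-type label into (theme number, variant letter or None).

    >>> parse_phrase_type("2A")
    (2, 'A')
    """
    m = _PHRASE_TYPE_RE.match(str(label).strip())
    if not m:
        raise CorpusError(
            f"phrase type {label!r} is not of the form <number><optional letter>"
        )
    number = int(m.group(1))
    if number < 1:
        raise CorpusError(f"phrase type number must be >= 1, got {label!r}")
    return number, m.group(2)


@dataclass(frozen=True)
class UnitObservation:
    """One measured song unit: 11 numeric acoustic parameters + its label.

    Frequencies are Hz, duration seconds, pulse_rate per second.
    ``frequency_trend`` = start/end and ``frequency_range`` = high/low are
    derived ratios.
    """

    duration: float
    bandwidth: float
    peak_frequency: float
    high_frequency: float
    low_frequency: float
    start_frequency: float
    end_frequency: float
    frequency_trend: float
    frequency_range: float
    inflections: int
    pulse_rate: float
    qualitative_name: str

    NUMERIC_FIELDS = (
        "duration",
        "bandwidth",
        "peak_frequency",
        "high_frequency",
        "low_frequency",
        "start_frequency",
        "end_frequency",
        "frequency_trend",
        "frequency_range",
        "inflections",
        "pulse_rate",
    )

    def __post_init__(self):
        for f in (
            "peak_frequency",
            "high_frequency",
            "low_frequency",
            "start_frequency",
            "end_frequency",
        ):
            if getattr(self, f) <= 0:
                raise CorpusError(f"{f} must be > 0, got {getattr(self, f)}")
        if self.high_frequency < self.low_frequency:
            raise CorpusError(
                f"high_frequency {self.high_frequency} < low_frequency "
                f"{self.low_frequency}"
            )
        if self.frequency_range < 1:
            raise CorpusError(f"frequency_range must be >= 1, got {self.frequency_range}")
        if self.inflections < 0:
            raise CorpusError("inflections must be >= 0")
        expected_bw = self.high_frequency - self.low_frequency
        if not np.isclose(self.bandwidth, expected_bw,
                          rtol=BANDWIDTH_RTOL, atol=1e-6 + BANDWIDTH_RTOL * expected_bw):
            raise CorpusError(
                f"bandwidth {self.bandwidth} inconsistent with high−low = {expected_bw}"
            )


@dataclass(frozen=True)
class PhraseString:
    """One transcribed phrase: an ordered unit sequence plus its assignment."""

    units: tuple[str, ...]
    phrase_type: str
    location: str
    year: int
    recording_id: str
    song_type_tag: str = ""

    def __post_init__(self):
        if not self.units:
            raise CorpusError("phrase must contain at least one unit")
        for u in self.units:
            if not u or any(c.isspace() for c in u):
                raise CorpusError(f"unit label {u!r} is empty or contains whitespace")
        parse_phrase_type(self.phrase_type)  # raises on malformed labels

    @property
    def theme(self) -> int:
        """Theme ID = numeric part of the phrase-type label."""
        return parse_phrase_type(self.phrase_type)[0]

    @property
    def variant(self) -> str | None:
        return parse_phrase_type(self.phrase_type)[1]


@dataclass(frozen=True)
class SongString:
    """Ordered distinct theme IDs for one song rendition.

    Each theme appears once, in first-occurrence order, regardless of how many
    times its phrase was repeated when sung.
    """

    themes: tuple[int, ...]
    location: str = ""
    year: int = 0
    recording_id: str = ""
    song_type_tag: str = ""

    def __post_init__(self):
        if len(set(self.themes)) != len(self.themes):
            raise CorpusError(f"song string has repeated themes: {self.themes}")
        if any(t < 1 for t in self.themes):
            raise CorpusError("theme IDs must be positive integers")

    @property
    def group_key(self) -> tuple[str, int, str, str]:
        return (self.location, self.year, self.recording_id, self.song_type_tag)


@dataclass(frozen=True)
class ThemePresence:
    """Unordered theme set for one recording (order information discarded)."""

    themes: frozenset[int]
    location: str = ""
    year: int = 0
    recording_id: str = ""
    song_type_tag: str = ""

    def __post_init__(self):
        if any(t < 1 for t in self.themes):
            raise CorpusError("theme IDs must be positive integers")

    @classmethod
    def from_song(cls, song: SongString) -> "ThemePresence":
        return cls(
            themes=frozenset(song.themes),
            location=song.location,
            year=song.year,
            recording_id=song.recording_id,
            song_type_tag=song.song_type_tag,
        )

    @property
    def group_key(self) -> tuple[str, int, str, str]:
        return (self.location, self.year, self.recording_id, self.song_type_tag)


def song_string_from_theme_sequence(
    theme_sequence: Iterable[int], **provenance
) -> SongString:
    """Collapse a sung theme sequence (with repeats) into a song string.

    Keeps first-occurrence order and drops later re-occurrences; an empty
    input yields an empty song string.
    """
    seen: dict[int, None] = {}
    for t in theme_sequence:
        t = int(t)
        if t < 1:
            raise CorpusError(f"theme IDs must be positive, got {t}")
        seen.setdefault(t, None)
    return SongString(themes=tuple(seen), **provenance)


class SimilarityMatrix:
    """A labelled symmetric matrix of similarity proportions in [0, 1]."""

    def __init__(self, labels: Sequence[str], values: np.ndarray, *, validate=True):
        self.labels = list(labels)
        self.values = np.asarray(values, dtype=float)
        if validate:
            self._validate()

    def _validate(self):
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise CorpusError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if len(set(self.labels)) != n:
            raise CorpusError("similarity matrix labels must be unique")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise CorpusError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-12):
            raise CorpusError("similarity matrix diagonal must be 1")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise CorpusError("similarity values must lie in [0, 1]")

    def __len__(self):
        return len(self.labels)

    def __getitem__(self, pair):
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return self.values[i, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_long(self) -> pd.DataFrame:
        """Long-format upper-triangle pair table (item_i, item_j, similarity)."""
        rows = []
        for i in range(len(self.labels)):
            for j in range(i + 1, len(self.labels)):
                rows.append((self.labels[i], self.labels[j], self.values[i, j]))
        return pd.DataFrame(rows, columns=["item_i", "item_j", "similarity"])

    def to_distance(self) -> pd.DataFrame:
        """Dissimilarity counterpart (1 − similarity)."""
        return pd.DataFrame(1.0 - self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path):
        self.to_frame().to_csv(path, index_label="label")

    @classmethod
    def from_csv(cls, path) -> "SimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy())


# ---------------------------------------------------------------------------
# tabular readers / writers

PHRASE_COLUMNS = ["location", "year", "recording_id", "song_type_tag", "phrase_type", "units"]
SONG_COLUMNS = ["location", "year", "recording_id", "song_type_tag", "themes"]
PRESENCE_COLUMNS = ["location", "year", "recording_id", "song_type_tag", "themes"]
UNIT_COLUMNS = list(UnitObservation.NUMERIC_FIELDS) + ["qualitative_name"]


def _read_table(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    return df


def read_phrase_table(path) -> list[PhraseString]:
    """Read phrases.csv; row order is authoritative for phrase sequence."""
    df = _read_table(path, PHRASE_COLUMNS)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        units = tuple(str(row.units).split())
        if not units:
            raise RowValidationError(i, "empty unit sequence")
        try:
            out.append(
                PhraseString(
                    units=units,
                    phrase_type=str(row.phrase_type),
                    location=str(row.location),
                    year=int(row.year),
                    recording_id=str(row.recording_id),
                    song_type_tag=str(row.song_type_tag),
                )
            )
        except CorpusError as e:
            raise RowValidationError(i, str(e)) from e
    return out


def write_phrase_table(phrases: Iterable[PhraseString], path) -> None:
    rows = [
        (p.location, p.year, p.recording_id, p.song_type_tag, p.phrase_type,
         " ".join(p.units))
        for p in phrases
    ]
    pd.DataFrame(rows, columns=PHRASE_COLUMNS).to_csv(path, index=False)


def read_song_table(path) -> list[SongString]:
    df = _read_table(path, SONG_COLUMNS)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            themes = tuple(int(t) for t in str(row.themes).split())
            out.append(
                SongString(
                    themes=themes,
                    location=str(row.location),
                    year=int(row.year),
                    recording_id=str(row.recording_id),
                    song_type_tag=str(row.song_type_tag),
                )
            )
        except (ValueError, CorpusError) as e:
            raise RowValidationError(i, str(e)) from e
    return out


def write_song_table(songs: Iterable[SongString], path) -> None:
    rows = [
        (s.location, s.year, s.recording_id, s.song_type_tag,
         " ".join(str(t) for t in s.themes))
        for s in songs
    ]
    pd.DataFrame(rows, columns=SONG_COLUMNS).to_csv(path, index=False)


def read_presence_table(path) -> list[ThemePresence]:
    df = _read_table(path, PRESENCE_COLUMNS)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            themes = frozenset(int(t) for t in str(row.themes).split())
            out.append(
                ThemePresence(
                    themes=themes,
                    location=str(row.location),
                    year=int(row.year),
                    recording_id=str(row.recording_id),
                    song_type_tag=str(row.song_type_tag),
                )
            )
        except (ValueError, CorpusError) as e:
            raise RowValidationError(i, str(e)) from e
    return out


def write_presence_table(presences: Iterable[ThemePresence], path) -> None:
    rows = [
        (p.location, p.year, p.recording_id, p.song_type_tag,
         " ".join(str(t) for t in sorted(p.themes)))
        for p in presences
    ]
    pd.DataFrame(rows, columns=PRESENCE_COLUMNS).to_csv(path, index=False)


def read_unit_table(path) -> list[UnitObservation]:
    df = _read_table(path, UNIT_COLUMNS)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            kwargs = {f: float(getattr(row, f)) for f in UnitObservation.NUMERIC_FIELDS}
            kwargs["inflections"] = int(float(row.inflections))
            out.append(UnitObservation(qualitative_name=str(row.qualitative_name), **kwargs))
        except (ValueError, CorpusError) as e:
            raise RowValidationError(i, str(e)) from e
    return out


def theme_inventory_summary(phrases: Iterable[PhraseString]) -> dict:
    """Count distinct themes and themes with multiple phrase-type variants.

    Returns ``{"n_themes": ..., "n_multi_variant_themes": ..., "phrase_types":
    {theme: sorted labels}}`` computed from the phrase table alone.
    """
    types_by_theme: dict[int, set[str]] = {}
    for p in phrases:
        types_by_theme.setdefault(p.theme, set()).add(p.phrase_type)
    return {
        "n_themes": len(types_by_theme),
        "n_multi_variant_themes": sum(1 for s in types_by_theme.values() if len(s) > 1),
        "phrase_types": {k: sorted(v) for k, v in sorted(types_by_theme.items())},
    }
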