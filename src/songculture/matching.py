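"""Phrase-type verification and cross-location song matching.

Two complementary song comparisons are provided: sequence-aware LSI over
ordered theme strings, and Dice's similarity index (DSI) over unordered
theme presence, 2·|A∩B| / (|A|+|B|).  Phrase-type assignments are checked by
contrasting within-type against between-type string similarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corpus import PhraseString, SimilarityMatrix, SongString, ThemePresence
from .metrics import lsi, median_string, similarity_matrix

__all__ = [
    "PhraseTypeReport",
    "verify_phrase_types",
    "group_label",
    "song_lsi_matrix",
    "dice_similarity",
    "aggregate_presence",
    "dsi_matrix",
]


@dataclass
class PhraseTypeReport:
    """Similarity summary of a qualitative phrase-type classification.

    ``per_type`` has one row per phrase type: member count, within-type mean
    LSI, the max between-type mean LSI, the median unit string, and whether
    the type is consistent (within strictly exceeds every between).
    ``between`` is the full type-by-type mean-LSI table (diagonal = within).
    """

    per_type: pd.DataFrame
    between: pd.DataFrame
    flagged: list[str]

    @property
    def consistent(self) -> bool:
        return not self.flagged


def verify_phrase_types(phrases: list[PhraseString]) -> PhraseTypeReport:
    """Check that unit strings are more alike within phrase types than between.

    A type whose within-type mean LSI does not strictly exceed its mean LSI
    to every other type is flagged as inconsistent with the qualitative
    assignment.  Requires at least two phrase types.  Singleton types use
    within-similarity 1.0 by convention (a lone exemplar is trivially
    self-consistent); the flag then depends only on the between terms.
    """
    groups: dict[str, list[tuple]] = {}
    for p in phrases:
        groups.setdefault(p.phrase_type, []).append(p.units)
    types = sorted(groups)
    if len(types) < 2:
        raise ValueError("phrase-type verification needs at least 2 phrase types")

    k = len(types)
    between = np.empty((k, k))
    rows = []
    for i, t in enumerate(types):
        med = median_string(groups[t])
        between[i, i] = med.within_set_similarity
        rows.append(
            {
                "phrase_type": t,
                "n": len(groups[t]),
                "within_similarity": med.within_set_similarity,
                "median_string": " ".join(str(u) for u in med.string),
            }
        )
    for i in range(k):
        for j in range(i + 1, k):
            vals = [lsi(a, b) for a in groups[types[i]] for b in groups[types[j]]]
            between[i, j] = between[j, i] = float(np.mean(vals))

    per_type = pd.DataFrame(rows)
    off = between + np.diag(np.full(k, -np.inf))
    per_type["max_between_similarity"] = off.max(axis=1)
    per_type["consistent"] = per_type["within_similarity"] > per_type["max_between_similarity"]
    flagged = per_type.loc[~per_type["consistent"], "phrase_type"].tolist()
    between_df = pd.DataFrame(between, index=types, columns=types)
    return PhraseTypeReport(per_type=per_type, between=between_df, flagged=flagged)


def group_label(key: tuple[str, int, str, str]) -> str:
    """Human-readable Location_Year[_Tag]_Recording label for a group key."""
    location, year, recording_id, tag = key
    parts = [location, str(year)]
    if tag:
        parts.append(tag)
    if recording_id:
        parts.append(recording_id)
    return "_".join(parts)


def song_lsi_matrix(songs: list[SongString], mode: str = "full") -> SimilarityMatrix:
    """LSI matrix over theme-ID song strings.

    ``mode='full'`` compares every song string (one row each, labelled with a
    positional suffix when a recording contributes several).  ``mode='median'``
    first reduces each (location, year, recording, song-type) group to its
    median string, giving a point estimate per recording.
    """
    if not songs:
        raise ValueError("no song strings supplied")
    for s in songs:
        if not s.themes:
            raise ValueError(f"empty song string for {group_label(s.group_key)}")
    if mode == "full":
        counts: dict[tuple, int] = {}
        for s in songs:
            counts[s.group_key] = counts.get(s.group_key, 0) + 1
        labels = [
            f"{group_label(s.group_key)}.{i + 1}" if counts[s.group_key] > 1
            else group_label(s.group_key)
            for i, s in zip(_occurrence_index(songs), songs)
        ]
        return similarity_matrix([s.themes for s in songs], labels)
    if mode == "median":
        grouped: dict[tuple, list[tuple]] = {}
        for s in songs:
            grouped.setdefault(s.group_key, []).append(s.themes)
        labels = [group_label(k) for k in grouped]
        medians = [median_string(v).string for v in grouped.values()]
        return similarity_matrix(medians, labels)
    raise ValueError(f"mode must be 'full' or 'median', got {mode!r}")


def _occurrence_index(songs):
    seen: dict[tuple, int] = {}
    out = []
    for s in songs:
        out.append(seen.get(s.group_key, 0))
        seen[s.group_key] = out[-1] + 1
    return out


def dice_similarity(a: ThemePresence, b: ThemePresence) -> float:
    """Dice's similarity index on theme presence: 2·|A∩B| / (|A|+|B|)."""
    sa, sb = a.themes, b.themes
    if not sa or not sb:
        raise ValueError("Dice similarity is undefined for an empty theme set")
    return 2.0 * len(sa & sb) / (len(sa) + len(sb))


def aggregate_presence(presences: list[ThemePresence]) -> list[ThemePresence]:
    """Union theme sets over rows sharing a recording group key.

    Collapses per-rendition presence rows to one set per (location, year,
    recording, song-type) combination, preserving first-seen group order.
    """
    merged: dict[tuple, set] = {}
    for p in presences:
        merged.setdefault(p.group_key, set()).update(p.themes)
    return [
        ThemePresence(
            themes=frozenset(themes), location=key[0], year=key[1],
            recording_id=key[2], song_type_tag=key[3],
        )
        for key, themes in merged.items()
    ]


def dsi_matrix(presences: list[ThemePresence]) -> SimilarityMatrix:
    """Pairwise Dice similarity over recordings' theme sets."""
    if len(presences) < 2:
        raise ValueError("DSI matrix needs at least 2 recordings")
    labels = [group_label(p.group_key) for p in presences]
    n = len(presences)
    values = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = dice_similarity(presences[i], presences[j])
    return SimilarityMatrix(labels, values)
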