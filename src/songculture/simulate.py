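"""Generative model of multi-population song cultures.

The generator emulates the hierarchical structure of humpback song and its
cultural dynamics so that every analysis stage can be exercised against a
known ground truth:

* a **lineage** is a version of the song: an ordered set of themes, each
  theme realized by one or two stereotyped phrase templates (unit sequences);
* **evolution** is gradual within-lineage change between years — a theme is
  gained and another lost, always preserving shared themes year to year;
* **revolution** replaces a population's lineage with a brand-new one whose
  theme block is disjoint from everything sung before;
* **transcription noise** perturbs emitted unit sequences symbol-wise
  (substitute / delete / insert, mirroring the three edit operations, so the
  noise magnitude maps directly onto expected LSI), and individual renditions
  may omit a theme.

All randomness flows from one seed through two spawned streams: stream 0
builds the cultural structure (variant designation, templates, evolution
draws, in population/year order), stream 1 drives emission (populations, then
years, recordings, song renditions, in order).  Identical configurations and
seeds therefore yield byte-identical corpora.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .corpus import (
    CorpusError,
    PhraseString,
    SongString,
    ThemePresence,
    UnitObservation,
    song_string_from_theme_sequence,
    write_phrase_table,
    write_presence_table,
    write_song_table,
)

__all__ = [
    "YearAssignment",
    "PopulationSpec",
    "GeneratorConfig",
    "GroundTruth",
    "SimulatedCorpus",
    "generate_corpus",
    "generate_unit_features",
]


@dataclass(frozen=True)
class YearAssignment:
    """Which lineage a population sings in a given year (optionally tagged
    when two song types co-occur, e.g. early/late season)."""

    year: int
    lineage: str
    tag: str = ""


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    assignments: tuple[YearAssignment, ...]


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic song-culture model.

    Defaults reproduce a two-population, three-year scenario with one
    revolution and one evolution event over a 16-theme inventory of which
    five themes carry two phrase variants.
    """

    seed: int = 0
    populations: tuple[PopulationSpec, ...] = ()
    theme_inventory: int = 16
    themes_per_lineage: int = 5
    unit_inventory: int = 71
    units_per_phrase: tuple[int, int] = (4, 8)
    variant_prob: float = 0.3125          # fraction of themes with 2 variants
    repeats_per_theme: tuple[int, int] = (2, 4)
    evolution_rate: float = 0.0           # stochastic per year-transition
    evolution_events: tuple[tuple[str, int], ...] = ()  # forced (population, year)
    noise_sub: float = 0.025              # per-unit substitution probability
    noise_del: float = 0.0125             # per-unit deletion probability
    noise_ins: float = 0.0125             # per-unit insertion probability
    theme_drop: float = 0.05              # per-theme omission per rendition
    recordings_per_population_year: int = 3
    songs_per_recording: int = 5

    def __post_init__(self):
        for p in ("variant_prob", "evolution_rate", "noise_sub", "noise_del",
                  "noise_ins", "theme_drop"):
            v = getattr(self, p)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{p} must be a probability in [0, 1], got {v}")
        if self.themes_per_lineage > self.theme_inventory:
            raise ValueError("themes_per_lineage exceeds the theme inventory")
        if self.units_per_phrase[0] < 1 or self.units_per_phrase[0] > self.units_per_phrase[1]:
            raise ValueError("units_per_phrase must be an increasing positive range")
        if self.repeats_per_theme[0] < 1 or self.repeats_per_theme[0] > self.repeats_per_theme[1]:
            raise ValueError("repeats_per_theme must be an increasing positive range")

    @classmethod
    def default(cls, seed: int = 0) -> "GeneratorConfig":
        """Two populations, three years, one revolution, one evolution event.

        Population "west" sings lineage ``blue`` throughout 2015–2017 with an
        evolution event at the 2016 transition; population "east" sings
        lineage ``green`` in 2015 and revolves to the disjoint lineage
        ``amber`` from 2016.  All 16 inventory themes are sung somewhere.
        """
        west = PopulationSpec(
            "west",
            tuple(YearAssignment(y, "blue") for y in (2015, 2016, 2017)),
        )
        east = PopulationSpec(
            "east",
            (
                YearAssignment(2015, "green"),
                YearAssignment(2016, "amber"),
                YearAssignment(2017, "amber"),
            ),
        )
        return cls(seed=seed, populations=(west, east),
                   evolution_events=(("west", 2016),))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        raw = yaml.safe_load(Path(path).read_text())
        pops = tuple(
            PopulationSpec(
                name=p["name"],
                assignments=tuple(YearAssignment(**a) for a in p["assignments"]),
            )
            for p in raw.pop("populations", [])
        )
        for key in ("units_per_phrase", "repeats_per_theme"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "evolution_events" in raw:
            raw["evolution_events"] = tuple(tuple(e) for e in raw["evolution_events"])
        return cls(populations=pops, **raw)


@dataclass
class GroundTruth:
    """What the generator actually did, keyed for every downstream check."""

    lineage_of: dict            # (population, year, tag) -> lineage name
    theme_sets: dict            # (lineage, year) -> ordered tuple of theme IDs
    templates: dict             # theme -> {phrase_type_label: unit tuple}
    true_songs: dict            # (population, year, recording, tag) -> theme tuple

    def lineage_partition(self) -> dict:
        """Lineage -> set of group labels (population_year[_tag])."""
        out: dict[str, set] = {}
        for (pop, year, tag), lin in self.lineage_of.items():
            label = "_".join([pop, str(year)] + ([tag] if tag else []))
            out.setdefault(lin, set()).add(label)
        return out


@dataclass
class SimulatedCorpus:
    phrases: list[PhraseString]
    songs: list[SongString]
    presences: list[ThemePresence]
    ground_truth: GroundTruth
    config: GeneratorConfig

    def song_groups(self) -> dict:
        """Group label -> list of song theme strings (for clustering)."""
        from .matching import group_label

        groups: dict[str, list] = {}
        for s in self.songs:
            key = group_label((s.location, s.year, "", s.song_type_tag))
            groups.setdefault(key, []).append(s.themes)
        return groups

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_phrase_table(self.phrases, out / "phrases.csv")
        write_song_table(self.songs, out / "songs.csv")
        write_presence_table(self.presences, out / "theme_presence.csv")


def _build_structure(cfg: GeneratorConfig, rng: np.random.Generator):
    """Allocate lineage theme blocks, evolution steps and phrase templates."""
    n_variant = int(round(cfg.variant_prob * cfg.theme_inventory))
    variant_themes = set(
        (rng.choice(cfg.theme_inventory, size=n_variant, replace=False) + 1).tolist()
    ) if n_variant else set()

    next_theme = 1
    unit_names = [f"U{k + 1:02d}" for k in range(cfg.unit_inventory)]

    def allocate_block(k: int) -> list[int]:
        nonlocal next_theme
        if next_theme + k - 1 > cfg.theme_inventory:
            raise CorpusError(
                "theme inventory exhausted: revolution/evolution needs "
                f"{k} fresh theme(s) but only "
                f"{cfg.theme_inventory - next_theme + 1} remain"
            )
        block = list(range(next_theme, next_theme + k))
        next_theme += k
        return block

    templates: dict[int, dict[str, tuple]] = {}

    def make_templates(theme: int) -> None:
        lo, hi = cfg.units_per_phrase
        variants = ["A", "B"] if theme in variant_themes else [""]
        templates[theme] = {}
        for letter in variants:
            length = int(rng.integers(lo, hi + 1))
            units = tuple(unit_names[i] for i in rng.integers(0, cfg.unit_inventory, length))
            templates[theme][f"{theme}{letter}"] = units

    events = set(cfg.evolution_events)
    lineage_current: dict[str, list[int]] = {}
    theme_sets: dict[tuple, tuple] = {}
    lineage_of: dict[tuple, str] = {}

    all_years = sorted({a.year for p in cfg.populations for a in p.assignments})
    for year in all_years:
        for pop in cfg.populations:
            for a in pop.assignments:
                if a.year != year:
                    continue
                lineage_of[(pop.name, year, a.tag)] = a.lineage
                if (a.lineage, year) in theme_sets:
                    continue
                if a.lineage not in lineage_current:
                    block = allocate_block(cfg.themes_per_lineage)
                    for t in block:
                        make_templates(t)
                    lineage_current[a.lineage] = block
                else:
                    evolve = (pop.name, year) in events or (
                        cfg.evolution_rate > 0 and rng.random() < cfg.evolution_rate
                    )
                    if evolve:
                        themes = lineage_current[a.lineage]
                        gained = allocate_block(1)[0]
                        make_templates(gained)
                        if len(themes) > 1:
                            lost = int(rng.integers(0, len(themes)))
                            themes = themes[:lost] + themes[lost + 1:]
                        lineage_current[a.lineage] = themes + [gained]
                theme_sets[(a.lineage, year)] = tuple(lineage_current[a.lineage])
    return lineage_of, theme_sets, templates, unit_names


def _noisy_units(units: tuple, rng: np.random.Generator, cfg: GeneratorConfig,
                 unit_names: list[str]) -> tuple:
    out = []
    for u in units:
        x = rng.random()
        if x < cfg.noise_sub:
            out.append(unit_names[int(rng.integers(0, len(unit_names)))])
        elif x < cfg.noise_sub + cfg.noise_del:
            continue
        else:
            out.append(u)
        if rng.random() < cfg.noise_ins:
            out.append(unit_names[int(rng.integers(0, len(unit_names)))])
    if not out:  # a phrase is never transcribed as empty
        out.append(units[0])
    return tuple(out)


def generate_corpus(config: GeneratorConfig | None = None) -> SimulatedCorpus:
    """Emit phrase, song and theme-presence tables with full ground truth.

    Deterministic given ``config.seed``; see the module docstring for the
    stream-splitting order.
    """
    cfg = config or GeneratorConfig.default()
    if not cfg.populations:
        raise ValueError("config defines no populations")
    root = np.random.default_rng(cfg.seed)
    structure_rng, emission_rng = root.spawn(2)

    lineage_of, theme_sets, templates, unit_names = _build_structure(cfg, structure_rng)

    phrases: list[PhraseString] = []
    songs: list[SongString] = []
    presences: list[ThemePresence] = []
    true_songs: dict[tuple, tuple] = {}

    rec_ids = [chr(ord("X") + i) if i < 3 else f"R{i + 1}"
               for i in range(cfg.recordings_per_population_year)]
    rep_lo, rep_hi = cfg.repeats_per_theme

    for pop in cfg.populations:
        for a in pop.assignments:
            lineage = lineage_of[(pop.name, a.year, a.tag)]
            true_theme_order = theme_sets[(lineage, a.year)]
            for rec in rec_ids:
                true_songs[(pop.name, a.year, rec, a.tag)] = true_theme_order
                for _ in range(cfg.songs_per_recording):
                    sung: list[int] = []
                    for theme in true_theme_order:
                        if cfg.theme_drop > 0 and emission_rng.random() < cfg.theme_drop:
                            continue
                        sung.append(theme)
                    if not sung:  # a rendition always contains at least one theme
                        sung.append(true_theme_order[0])
                    theme_seq: list[int] = []
                    for theme in sung:
                        repeats = int(emission_rng.integers(rep_lo, rep_hi + 1))
                        labels = sorted(templates[theme])
                        for _ in range(repeats):
                            label = labels[int(emission_rng.integers(0, len(labels)))]
                            units = _noisy_units(
                                templates[theme][label], emission_rng, cfg, unit_names
                            )
                            phrases.append(
                                PhraseString(
                                    units=units,
                                    phrase_type=label,
                                    location=pop.name,
                                    year=a.year,
                                    recording_id=rec,
                                    song_type_tag=a.tag,
                                )
                            )
                            theme_seq.append(theme)
                    song = song_string_from_theme_sequence(
                        theme_seq,
                        location=pop.name,
                        year=a.year,
                        recording_id=rec,
                        song_type_tag=a.tag,
                    )
                    songs.append(song)
                    presences.append(ThemePresence.from_song(song))

    gt = GroundTruth(
        lineage_of=lineage_of,
        theme_sets=theme_sets,
        templates=templates,
        true_songs=true_songs,
    )
    return SimulatedCorpus(phrases, songs, presences, gt, cfg)


# ---------------------------------------------------------------------------
# unit-feature generator (feeds the random-forest agreement check)

_LATENT_DIM = 8
_MAX_REDRAWS = 100


def _class_means(n_classes: int, separation: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Class centroids in latent space with pairwise distance ≈ separation."""
    scale = separation / np.sqrt(2.0)
    if n_classes <= _LATENT_DIM:
        mu = np.zeros((n_classes, _LATENT_DIM))
        mu[np.arange(n_classes), np.arange(n_classes)] = scale
        return mu
    dirs = rng.standard_normal((n_classes, _LATENT_DIM))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return scale * dirs


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _latent_to_row(z: np.ndarray, rng: np.random.Generator) -> dict:
    low = 150.0 * float(np.exp(0.8 + 0.35 * z[1]))
    frange = 1.0 + float(np.exp(-0.3 + 0.5 * z[2]))
    high = low * frange
    span = high - low
    start = low + span * float(_sigmoid(0.8 * z[4]))
    end = low + span * float(_sigmoid(0.8 * z[5]))
    return {
        "duration": float(np.exp(-0.7 + 0.3 * z[0])),
        "bandwidth": span,
        "peak_frequency": low + span * float(_sigmoid(0.8 * z[3])),
        "high_frequency": high,
        "low_frequency": low,
        "start_frequency": start,
        "end_frequency": end,
        "frequency_trend": start / end,
        "frequency_range": frange,
        "inflections": int(rng.poisson(float(np.exp(-0.2 + 0.4 * z[6])))),
        "pulse_rate": float(5.0 * z[7]) if z[7] > 0 else 0.0,
    }


def generate_unit_features(
    n_classes: int = 2,
    separation: float = 5.0,
    n_per_class: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Synthetic unit-measurement table with class-separable distributions.

    Classes are multivariate normal in an 8-dimensional latent space with
    centroids ``separation`` standard deviations apart; latent draws map
    monotonically onto the 11 acoustic parameters so that the
    :class:`UnitObservation` invariants (high >= low, consistent ratios and
    bandwidth) hold by construction.  ``separation=0`` gives identically
    distributed classes (chance-level classification); large separations give
    near-perfect classification.  Rows violating an invariant (numerically
    degenerate draws) are redrawn, up to a bounded number of retries.
    """
    if separation < 0:
        raise ValueError("separation must be >= 0")
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    mu = _class_means(n_classes, separation, rng)
    rows = []
    for k in range(n_classes):
        name = f"class{k + 1}"
        for _ in range(n_per_class):
            for _attempt in range(_MAX_REDRAWS):
                z = mu[k] + rng.standard_normal(_LATENT_DIM)
                row = _latent_to_row(z, rng)
                try:
                    UnitObservation(qualitative_name=name, **row)
                except (CorpusError, OverflowError):
                    continue
                row["qualitative_name"] = name
                rows.append(row)
                break
            else:
                raise CorpusError(
                    "could not draw an invariant-satisfying unit after "
                    f"{_MAX_REDRAWS} attempts"
                )
    cols = list(UnitObservation.NUMERIC_FIELDS) + ["qualitative_name"]
    return pd.DataFrame(rows, columns=cols)
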