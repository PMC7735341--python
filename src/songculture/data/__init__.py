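"""Bundled reference tables.

``nz_recording_events.csv`` and ``breeding_recording_events.csv`` hold the
published recording-event metadata for the transcribed songs: six recording
events from two central New Zealand locations (South Taranaki Bight and Cook
Strait, 2016) and twenty-one events from the two breeding populations (New
Caledonia and East Australia, 2015–2017).

``breeding_theme_sets_reconstructed.csv`` is a SYNTHETIC reconstruction of
the per-location/year song theme sets.  The sets for New Zealand 2016, the
2015–2017 East Australia songs, New Caledonia 2015 "B", 2016 and 2017 follow
the published narrative; the five themes of the New Caledonia 2015 "A"
lineage were never enumerated publicly (only that it shared no themes with
"B") and are represented here by placeholder IDs 12–16.  Use it for method
demonstrations, not as primary data.
"""

from importlib import resources

import pandas as pd

from ..corpus import ThemePresence, read_presence_table

__all__ = [
    "load_nz_recording_events",
    "load_breeding_recording_events",
    "load_reconstructed_theme_sets",
]


def _path(name: str):
    return resources.files(__package__) / name


def load_nz_recording_events() -> pd.DataFrame:
    """Recording-event table for the six central New Zealand song sessions."""
    with resources.as_file(_path("nz_recording_events.csv")) as p:
        return pd.read_csv(p, keep_default_na=False)


def load_breeding_recording_events() -> pd.DataFrame:
    """Recording-event table for the 21 breeding-population song sessions."""
    with resources.as_file(_path("breeding_recording_events.csv")) as p:
        return pd.read_csv(p, keep_default_na=False)


def load_reconstructed_theme_sets() -> list[ThemePresence]:
    """Synthetic reconstruction of per-location/year theme presence sets."""
    with resources.as_file(_path("breeding_theme_sets_reconstructed.csv")) as p:
        return read_presence_table(p)
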