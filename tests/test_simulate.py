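"""Generator ground truth, determinism, and noise-model guarantees."""

import filecmp

import numpy as np
import pytest

from songculture import (
    GeneratorConfig,
    PopulationSpec,
    ThemePresence,
    YearAssignment,
    dice_similarity,
    generate_corpus,
    generate_unit_features,
    lsi,
    median_string,
    rf_agreement,
    theme_inventory_summary,
)
from songculture.corpus import CorpusError, UnitObservation


def two_lineage_config(seed=0, **overrides):
    cfg = GeneratorConfig.default(seed=seed)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


class TestStructure:
    def test_default_scenario_inventory(self, default_corpus):
        summary = theme_inventory_summary(default_corpus.phrases)
        assert summary["n_themes"] == 16
        assert summary["n_multi_variant_themes"] == 5

    def test_revolution_block_is_disjoint(self, default_corpus):
        ts = default_corpus.ground_truth.theme_sets
        green = set(ts[("green", 2015)])
        amber = set(ts[("amber", 2016)])
        blue_all = set().union(
            *(set(ts[("blue", y)]) for y in (2015, 2016, 2017))
        )
        assert green & amber == set()
        assert blue_all & amber == set()
        assert blue_all & green == set()

    def test_evolution_preserves_shared_themes(self, default_corpus):
        ts = default_corpus.ground_truth.theme_sets
        before, after = set(ts[("blue", 2015)]), set(ts[("blue", 2016)])
        assert before != after
        assert len(before & after) >= 1

    def test_zero_evolution_keeps_theme_sets(self):
        cfg = two_lineage_config(evolution_events=(), evolution_rate=0.0)
        ts = generate_corpus(cfg).ground_truth.theme_sets
        assert ts[("blue", 2015)] == ts[("blue", 2016)] == ts[("blue", 2017)]
        assert ts[("amber", 2016)] == ts[("amber", 2017)]

    def test_infeasible_inventory_raises(self):
        cfg = two_lineage_config()
        cfg.theme_inventory = 10  # two disjoint blocks of 5 leave no room
        with pytest.raises(CorpusError, match="inventory"):
            generate_corpus(cfg)

    def test_variant_letters_only_on_multi_form_themes(self, default_corpus):
        by_theme = {}
        for p in default_corpus.phrases:
            by_theme.setdefault(p.theme, set()).add(p.phrase_type)
        for theme, types in by_theme.items():
            if len(types) == 1:
                assert list(types)[0] == str(theme)
            else:
                assert all(t[-1] in "AB" for t in types)


class TestDeterminism:
    def test_same_seed_byte_identical_output(self, tmp_path):
        for d in ("a", "b"):
            generate_corpus(two_lineage_config(seed=11)).write(tmp_path / d)
        for name in ("phrases.csv", "songs.csv", "theme_presence.csv"):
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name,
                               shallow=False)

    def test_different_seeds_differ(self):
        a = generate_corpus(two_lineage_config(seed=1))
        b = generate_corpus(two_lineage_config(seed=2))
        assert a.phrases != b.phrases


class TestNoiseModel:
    def test_zero_noise_disjoint_lineages(self, clean_corpus):
        gt = clean_corpus.ground_truth
        groups = clean_corpus.song_groups()
        part = gt.lineage_partition()
        # within a population-year every rendition equals the true theme order
        for (pop, year, rec, tag), true in gt.true_songs.items():
            label = "_".join([pop, str(year)] + ([tag] if tag else []))
            assert all(s == true for s in groups[label])
        # across disjoint lineages the song LSI is exactly 0
        blue = next(iter(part["blue"]))
        amber = next(iter(part["amber"]))
        assert lsi(groups[blue][0], groups[amber][0]) == 0.0

    def test_median_recovers_templates_at_default_noise(self, default_corpus):
        by_type = {}
        for p in default_corpus.phrases:
            by_type.setdefault(p.phrase_type, []).append(p.units)
        templates = {
            label: units
            for tpls in default_corpus.ground_truth.templates.values()
            for label, units in tpls.items()
        }
        eligible = {t: s for t, s in by_type.items() if len(s) >= 10}
        assert eligible
        hits = sum(
            median_string(s).string == templates[t] for t, s in eligible.items()
        )
        assert hits / len(eligible) >= 0.95

    def test_dice_from_ground_truth_sets_is_exact(self, default_corpus):
        ts = default_corpus.ground_truth.theme_sets
        a = ThemePresence(frozenset(ts[("blue", 2015)]))
        b = ThemePresence(frozenset(ts[("blue", 2016)]))
        k = len(set(ts[("blue", 2015)]) & set(ts[("blue", 2016)]))
        m = len(ts[("blue", 2015)]) + len(ts[("blue", 2016)])
        assert dice_similarity(a, b) == pytest.approx(2 * k / m)

    def test_presence_matches_song_strings(self, default_corpus):
        for song, pres in zip(default_corpus.songs, default_corpus.presences):
            assert pres.themes == frozenset(song.themes)
            assert pres.group_key == song.group_key


class TestUnitFeatureGenerator:
    def test_rows_satisfy_unit_invariants(self):
        df = generate_unit_features(n_classes=3, separation=2.0,
                                    n_per_class=30, seed=0)
        for _, row in df.iterrows():
            UnitObservation(**row.to_dict())  # raises on violation

    def test_zero_separation_is_chance_level(self):
        df = generate_unit_features(n_classes=2, separation=0.0,
                                    n_per_class=100, seed=4)
        report = rf_agreement(df, trees=500, seed=4)
        assert report.oob_error == pytest.approx(0.5, abs=0.05)

    def test_large_separation_is_near_perfect(self):
        df = generate_unit_features(n_classes=2, separation=10.0,
                                    n_per_class=100, seed=4)
        assert rf_agreement(df, trees=500, seed=4).oob_error <= 0.02

    def test_one_observation_per_class_surfaces_precondition(self):
        df = generate_unit_features(n_classes=2, separation=1.0,
                                    n_per_class=1, seed=0)
        with pytest.raises(ValueError, match=">= 2"):
            rf_agreement(df, trees=50, seed=0)

    def test_seed_determinism(self):
        a = generate_unit_features(2, 1.0, 20, seed=9)
        b = generate_unit_features(2, 1.0, 20, seed=9)
        assert a.equals(b)

    def test_negative_separation_rejected(self):
        with pytest.raises(ValueError):
            generate_unit_features(2, -1.0, 10, seed=0)


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = GeneratorConfig.default(seed=3)
        path = tmp_path / "config.yaml"
        cfg.to_yaml(path)
        again = GeneratorConfig.from_yaml(path)
        assert again == cfg

    def test_probability_validation(self):
        with pytest.raises(ValueError):
            GeneratorConfig(noise_sub=1.5)

    def test_custom_population_spec(self):
        cfg = GeneratorConfig(
            seed=0,
            populations=(
                PopulationSpec("p", (YearAssignment(2015, "L1"),)),
                PopulationSpec("q", (YearAssignment(2015, "L2"),)),
            ),
            theme_inventory=10,
        )
        corpus = generate_corpus(cfg)
        assert set(corpus.ground_truth.lineage_partition()) == {"L1", "L2"}
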