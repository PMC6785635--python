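"""Screen normalization, proportions, Holm–Šidák labelling and bona fide counting."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

import npfcavity as nc
from npfcavity.errors import ClassificationError, NormalizationError


def _records(rows):
    out = []
    for transporter, compound, amounts in rows:
        for i, a in enumerate(amounts, start=1):
            out.append(
                {"transporter": transporter, "compound": compound, "batch": "b1",
                 "replicate": i, "amount": float(a)}
            )
    return pd.DataFrame(out)


class TestNormalization:
    def test_reference_level_is_one_mock_level_zero(self):
        rec = _records([
            ("NPF4.1", "GA1", [10, 10, 10]),
            ("T", "GA1", [10, 10, 10]),
            ("M", "GA1", [0, 0, 0]),
            ("Z", "GA1", [0, 0, 0]),
        ])
        norm = nc.normalize_to_reference(rec, reference="NPF4.1", mock_label="M")
        by_t = norm.set_index("transporter")["normalized"]
        assert by_t["T"] == pytest.approx(1.0)
        assert by_t["Z"] == pytest.approx(0.0)

    def test_missing_reference_names_batch(self):
        rec = _records([("T", "GA1", [1, 2]), ("M", "GA1", [0, 0])])
        with pytest.raises(NormalizationError, match="b1"):
            nc.normalize_to_reference(rec, reference="NPF4.1", mock_label="M")

    def test_scale_invariance_within_batch(self):
        rec = _records([
            ("NPF4.1", "GA1", [12, 9, 11]),
            ("T", "GA1", [4, 5, 6]),
            ("Mock", "GA1", [1, 2, 1]),
        ])
        scaled = rec.assign(amount=rec["amount"] * 37.5)
        a = nc.normalize_to_reference(rec).set_index("transporter")["normalized"]
        b = nc.normalize_to_reference(scaled).set_index("transporter")["normalized"]
        assert np.allclose(a, b)

    def test_generated_fifteen_percent_effect_recovered(self):
        # mirrors a weak transporter at ~15% of reference above mock
        spec = nc.ScreenGeneratorSpec(
            effects={"NPF4.1": {"GA1": 21.0}, "NPF4.6": {"GA1": 4.0}},
            compounds=["GA1"], mock_mean=10.0, cv=0.1, replicates=6, seed=4,
        )
        table, _ = nc.generate_screen(spec)
        norm = nc.normalize_to_reference(table).set_index("transporter")["normalized"]
        assert norm["NPF4.6"] == pytest.approx(0.15, abs=0.05)

    def test_clamped_below_at_zero(self):
        rec = _records([
            ("NPF4.1", "GA1", [10, 10]),
            ("T", "GA1", [0.5, 0.4]),
            ("Mock", "GA1", [1, 1]),
        ])
        norm = nc.normalize_to_reference(rec).set_index("transporter")["normalized"]
        assert norm["T"] == 0.0


class TestProportions:
    def test_single_compound_share_one(self):
        rec = _records([("T", "GA1", [5, 5]), ("Mock", "GA1", [1, 1])])
        shares = nc.substrate_proportions(rec)
        assert shares.loc["T", "GA1"] == pytest.approx(1.0)

    def test_equal_net_means_split_evenly(self):
        rec = _records([
            ("T", "GA1", [5, 5]), ("T", "GA3", [5, 5]),
            ("Mock", "GA1", [1, 1]), ("Mock", "GA3", [1, 1]),
        ])
        shares = nc.substrate_proportions(rec)
        assert shares.loc["T", "GA1"] == pytest.approx(0.5)

    def test_planted_shares_recovered(self):
        spec = nc.ScreenGeneratorSpec(
            effects={"T": {"GA1": 13.0, "GA3": 7.0, "GA8": 3.0}},
            compounds=["GA1", "GA3", "GA8"], mock_mean=10.0, cv=0.05,
            replicates=6, reference="T", seed=9,
        )
        table, _ = nc.generate_screen(spec)
        shares = nc.substrate_proportions(table)
        # net effects 12, 6, 2 → shares 0.6, 0.3, 0.1
        assert shares.loc["T", "GA1"] == pytest.approx(0.6, abs=0.05)
        assert shares.loc["T", "GA3"] == pytest.approx(0.3, abs=0.05)
        assert shares.loc["T", "GA8"] == pytest.approx(0.1, abs=0.05)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        rec = _records([
            (f"T{i}", c, rng.uniform(1, 10, size=4))
            for i in range(3) for c in ("GA1", "GA3", "GA4")
        ] + [("Mock", c, rng.uniform(0, 1, size=4)) for c in ("GA1", "GA3", "GA4")])
        shares = nc.substrate_proportions(rec)
        assert np.allclose(shares.sum(axis=1), 1.0, atol=1e-12)

    def test_all_zero_transporter_excluded_with_warning(self):
        rec = _records([
            ("T", "GA1", [5, 5]), ("Dead", "GA1", [0.1, 0.1]),
            ("Mock", "GA1", [1, 1]),
        ])
        with pytest.warns(UserWarning, match="Dead"):
            shares = nc.substrate_proportions(rec)
        assert "Dead" not in shares.index


class TestHolmSidak:
    def test_worked_value_three_equal_pvalues(self):
        adj = nc.holm_sidak_adjust([0.02, 0.02, 0.02])
        assert adj.min() == pytest.approx(1 - 0.98**3, abs=1e-12)

    def test_matches_statsmodels_reference(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            raw = rng.uniform(0, 1, size=8)
            ours = nc.holm_sidak_adjust(raw)
            ref = multipletests(raw, method="holm-sidak")[1]
            assert np.allclose(ours, ref, atol=1e-12)

    def test_adjusted_at_least_raw_and_monotone(self):
        raw = [0.001, 0.2, 0.04, 0.6, 0.04]
        adj = nc.holm_sidak_adjust(raw)
        assert (adj >= np.asarray(raw) - 1e-15).all()
        order = np.argsort(raw)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_transporter_identical_to_mock_not_flagged(self):
        rec = _records([
            ("T", "GA1", [5.0, 5.1, 4.9, 5.0]),
            ("Mock", "GA1", [5.0, 5.1, 4.9, 5.0]),
        ])
        out = nc.holm_sidak_label(rec)
        assert not out["significant"].any()

    def test_strong_effect_flagged_null_neighbours_not(self):
        spec = nc.ScreenGeneratorSpec(
            effects={"Hit": {"GA1": 10.0}, **{f"Null{i}": {} for i in range(5)}},
            compounds=["GA1"], replicates=6, cv=0.2, reference="Hit", seed=3,
        )
        table, _ = nc.generate_screen(spec)
        out = nc.holm_sidak_label(table).set_index("transporter")
        assert bool(out.loc["Hit", "significant"])

    def test_single_true_effect_power_over_seeds(self):
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            spec = nc.ScreenGeneratorSpec(
                effects={"Hit": {"GA1": 10.0}, **{f"N{i}": {} for i in range(5)}},
                compounds=["GA1"], replicates=6, cv=0.2, reference="Hit", seed=seed,
            )
            table, _ = nc.generate_screen(spec)
            out = nc.holm_sidak_label(table).set_index("transporter")
            hits += bool(out.loc["Hit", "significant"])
        assert hits >= 0.95 * n_seeds

    def test_group_with_single_replicate_excluded(self):
        rec = pd.concat([
            _records([("T", "GA1", [5, 6, 5]), ("Mock", "GA1", [1, 1.2, 0.9])]),
            _records([("Lone", "GA1", [9])]),
        ])
        with pytest.warns(UserWarning, match="Lone"):
            out = nc.holm_sidak_label(rec)
        assert "Lone" not in set(out["transporter"])


class TestBonaFide:
    CLASSES = {"GA1": "non-permeating", "GA3": "non-permeating",
               "GA4": "moderate", "GA24": "moderate"}

    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["transporter", "compound", "normalized", "significant"]
        )

    def test_no_flags_empty_list(self):
        table = self._table([("T", "GA1", 1.0, False)])
        names, count = nc.count_bona_fide(table, self.CLASSES)
        assert names == [] and count == 0

    def test_moderate_only_hits_excluded(self):
        table = self._table([("T", "GA4", 1.0, True), ("T", "GA1", 0.2, False)])
        names, count = nc.count_bona_fide(table, self.CLASSES)
        assert count == 0

    def test_sorted_by_activity_descending(self):
        table = self._table([
            ("Weak", "GA1", 0.1, True),
            ("Strong", "GA1", 1.0, True),
            ("Mid", "GA3", 0.4, True),
        ])
        names, count = nc.count_bona_fide(table, self.CLASSES)
        assert names == ["Strong", "Mid", "Weak"] and count == 3

    def test_unknown_compound_class_rejected(self):
        table = self._table([("T", "GA99", 1.0, True)])
        with pytest.raises(ClassificationError, match="GA99"):
            nc.count_bona_fide(table, self.CLASSES)

    def test_packaged_screen_fixture_yields_ten_transporters(self):
        fixture = nc.datasets.load_screen_fixture()
        classes = nc.datasets.compound_class_map()
        names, count = nc.count_bona_fide(fixture, classes)
        assert count == 10
        assert set(names) == {
            "NPF1.1", "NPF2.3", "NPF2.4", "NPF2.5", "NPF2.7", "NPF2.12",
            "NPF2.13", "NPF3.1", "NPF4.1", "NPF4.6",
        }
        assert names[0] == "NPF4.1"
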