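import numpy as np
import pandas as pd
import pytest

from sirscan import (
    Chromosome,
    GenomeAnnotation,
    MaskThresholds,
    OrfRecord,
    classify_sir_positive,
    expression_quartile_crosstab,
    orf_sir_score,
    score_orfs,
    sir_position_mask,
)
from sirscan.coverage import FACTORS, EnrichmentTrack, build_bundle
from sirscan.scoring import ScoringError

from conftest import make_bundle, passing_values


class TestPositionMask:
    def test_all_conditions_met(self):
        bundle = make_bundle(
            {"sir2": 2.0, "sir3": 2.0, "sir4": 2.5, "gfp": 1.0, "h4k16ac": 0.1, "h3": 1.0}
        )
        assert sir_position_mask(bundle).data["chrI"].tolist() == [True]

    def test_boundary_value_fails_strict_inequality(self):
        bundle = make_bundle(passing_values(sir2=1.75))
        assert sir_position_mask(bundle).data["chrI"].tolist() == [False]

    def test_elevated_gfp_is_excluded(self):
        bundle = make_bundle(passing_values(gfp=3.5))
        assert sir_position_mask(bundle).data["chrI"].tolist() == [False]

    def test_undefined_position_is_never_masked(self):
        bundle = make_bundle(passing_values(h3=np.nan))
        assert sir_position_mask(bundle).data["chrI"].tolist() == [False]

    def test_missing_factor_is_fatal_and_names_it(self):
        tracks = [
            EnrichmentTrack(f, {"chrI": np.ones(1)}, {"chrI": np.ones(1, dtype=bool)})
            for f in FACTORS
            if f != "h4k16ac"
        ]
        with pytest.raises(ValueError, match="h4k16ac"):
            build_bundle(tracks)

    def test_mask_bed_export_merges_adjacent_positions(self, tmp_path):
        values = passing_values()
        sir2 = np.full(10, 2.5)
        sir2[[0, 3, 4, 9]] = 1.0  # fail at these positions
        bundle = make_bundle({**values, "sir2": sir2})
        mask = sir_position_mask(bundle)
        intervals = [(iv.start, iv.end) for iv in mask.to_intervals()]
        assert intervals == [(1, 3), (5, 9)]

    def test_raising_min_thresholds_shrinks_mask(self):
        rng = np.random.default_rng(5)
        bundle = make_bundle(
            {
                "sir2": rng.uniform(0, 5, 2000),
                "sir3": rng.uniform(0, 5, 2000),
                "sir4": rng.uniform(0, 5, 2000),
                "gfp": rng.uniform(0, 5, 2000),
                "h4k16ac": rng.uniform(0, 1, 2000),
                "h3": rng.uniform(0, 2, 2000),
            }
        )
        base = sir_position_mask(bundle).data["chrI"]
        for stricter in [
            MaskThresholds(sir2_min=2.5),
            MaskThresholds(sir4_min=3.0),
            MaskThresholds(gfp_max=1.5),
            MaskThresholds(h4k16ac_max=0.15),
            MaskThresholds(h3_min=1.2),
        ]:
            tightened = sir_position_mask(bundle, stricter).data["chrI"]
            assert not np.any(tightened & ~base)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ScoringError):
            MaskThresholds(sir2_min=0)


class TestOrfScore:
    def _mask_bundle(self, mask_vector):
        sir2 = np.where(mask_vector, 2.5, 1.0)
        return make_bundle({**passing_values(), "sir2": sir2})

    def test_fraction_of_masked_positions(self):
        vec = np.zeros(1000, dtype=bool)
        vec[:250] = True
        mask = sir_position_mask(self._mask_bundle(vec))
        orf = OrfRecord("a", "chrI", 0, 1000, "+")
        assert orf_sir_score(orf, mask) == (250, 0.25)

    def test_no_masked_positions_scores_zero(self):
        mask = sir_position_mask(self._mask_bundle(np.zeros(500, dtype=bool)))
        assert orf_sir_score(OrfRecord("a", "chrI", 100, 400, "+"), mask) == (0, 0.0)

    def test_matches_position_by_position_loop(self):
        rng = np.random.default_rng(17)
        vec = rng.random(2000) < 0.3
        mask = sir_position_mask(self._mask_bundle(vec))
        for _ in range(20):
            start = int(rng.integers(0, 1800))
            orf = OrfRecord("a", "chrI", start, start + 200, "+")
            t_naive = sum(bool(mask.data["chrI"][p]) for p in range(start, start + 200))
            assert orf_sir_score(orf, mask) == (t_naive, t_naive / 200)

    def test_fully_masked_orf_scores_exactly_one(self):
        mask = sir_position_mask(self._mask_bundle(np.ones(300, dtype=bool)))
        assert orf_sir_score(OrfRecord("a", "chrI", 50, 250, "+"), mask) == (200, 1.0)

    def test_undefined_factor_genome_wide_gives_all_zero_scores(self):
        bundle = make_bundle({**passing_values(), "h4k16ac": np.full(500, np.nan)})
        mask = sir_position_mask(bundle)
        orf = OrfRecord("a", "chrI", 0, 500, "+")
        assert orf_sir_score(orf, mask) == (0, 0.0)


class TestClassification:
    def _table(self, scores):
        return pd.DataFrame(
            {
                "id": [f"o{i}" for i in range(len(scores))],
                "length": 1000,
                "T": [int(s * 1000) for s in scores],
                "score": scores,
                "location": "interior",
            }
        )

    def test_score_at_cutoff_is_not_positive(self):
        table = classify_sir_positive(self._table([0.2, 0.2001, 0.19]))
        assert table["positive"].tolist() == [False, True, False]

    def test_cutoff_must_be_a_proper_fraction(self):
        for bad in (0.0, 1.0, -0.5, 2.0):
            with pytest.raises(ScoringError):
                classify_sir_positive(self._table([0.5]), cutoff=bad)

    def test_overlapping_orfs_are_scored_independently(self):
        vec = np.zeros(1000, dtype=bool)
        vec[400:600] = True
        sir2 = np.where(vec, 2.5, 1.0)
        bundle = make_bundle({**passing_values(), "sir2": sir2})
        mask = sir_position_mask(bundle)
        ann = GenomeAnnotation(
            [Chromosome("chrI", 1000)],
            [
                OrfRecord("a", "chrI", 300, 550, "+"),
                OrfRecord("b", "chrI", 450, 700, "-"),
            ],
        )
        table = score_orfs(ann, mask)
        assert table.set_index("id")["T"].to_dict() == {"a": 150, "b": 150}

    def test_translation_invariance(self):
        rng = np.random.default_rng(23)
        vec = rng.random(600) < 0.4
        shift = 2000
        for offset in (0, shift):
            full = np.zeros(600 + shift, dtype=bool)
            full[offset:offset + 600] = vec
            sir2 = np.where(full, 2.5, 1.0)
            bundle = make_bundle({**passing_values(), "sir2": sir2})
            mask = sir_position_mask(bundle)
            orf = OrfRecord("a", "chrI", offset + 100, offset + 500, "+")
            if offset == 0:
                base = orf_sir_score(orf, mask)
            else:
                assert orf_sir_score(orf, mask) == base


class TestExpressionCrosstab:
    def _table(self, n, positive_ids=()):
        df = pd.DataFrame(
            {
                "id": [f"o{i}" for i in range(n)],
                "score": 0.0,
                "location": "interior",
            }
        )
        df["positive"] = df["id"].isin(positive_ids)
        return df

    def test_eight_orfs_split_two_per_quartile(self):
        table = self._table(8)
        expr = pd.Series({f"o{i}": float(i + 1) for i in range(8)})
        ct = expression_quartile_crosstab(table, expr).set_index("quartile")
        assert ct.loc[["I", "II", "III", "IV"], "n_orfs"].tolist() == [2, 2, 2, 2]

    def test_positives_concentrate_where_planted(self):
        table = self._table(8, positive_ids={"o6", "o7"})
        expr = pd.Series({f"o{i}": float(i + 1) for i in range(8)})
        ct = expression_quartile_crosstab(table, expr).set_index("quartile")
        assert ct.loc["IV", "n_positive"] == 2
        assert ct.loc[["I", "II", "III"], "n_positive"].sum() == 0

    def test_empty_positive_set_gives_zero_rows(self):
        table = self._table(8)
        expr = pd.Series({f"o{i}": float(i + 1) for i in range(8)})
        ct = expression_quartile_crosstab(table, expr)
        assert ct["n_positive"].sum() == 0

    def test_orfs_without_expression_reported_separately(self):
        table = self._table(6)
        expr = pd.Series({f"o{i}": float(i + 1) for i in range(4)})
        ct = expression_quartile_crosstab(table, expr).set_index("quartile")
        assert ct.loc["no_expression", "n_orfs"] == 2

    def test_disjoint_ids_are_fatal(self):
        table = self._table(4)
        with pytest.raises(ScoringError, match="overlap"):
            expression_quartile_crosstab(table, pd.Series({"x": 1.0}))
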