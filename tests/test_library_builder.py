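from collections import Counter

import numpy as np
import pandas as pd
import pytest

from hdrps.affect_core import Category, ValenceLabel
from hdrps.library_builder import (
    LibraryManifest,
    identity_ratio,
    library_stats,
    merge_rounds,
    screen_images,
)
from hdrps.synthetic_cohort import SimConfig, simulate_ratings

# -- independent brute-force oracle --------------------------------------

NEG, NEU, POS = {1, 2, 3}, {4, 5, 6}, {7, 8, 9}


def oracle_modal(scores, dimension):
    """Recount label frequencies via explicit score sets, no shared code."""
    names = ("negative", "neutral", "positive") if dimension == "valence" else ("low", "medium", "high")
    counts = Counter()
    for s in scores:
        for name, bucket in zip(names, (NEG, NEU, POS)):
            if s in bucket:
                counts[name] += 1
    top = counts.most_common()
    if len(top) > 1 and top[1][1] == top[0][1]:
        return None, top[0][1] / len(scores)
    return top[0][0], top[0][1] / len(scores)


def random_rating_table(rng, n_images=20, n_raters=6):
    rows = []
    for i in range(n_images):
        for r in range(n_raters):
            for dim in ("valence", "arousal"):
                rows.append(
                    {
                        "rater_id": f"r{r}",
                        "image_id": f"people-p{i:03d}",
                        "dimension": dim,
                        "score": int(rng.integers(1, 10)),
                        "session_id": f"s{r}",
                        "rater_affect_valid": True,
                    }
                )
    return pd.DataFrame(rows)


class TestIdentityRatio:
    def test_hand_counted_example(self):
        label, ratio = identity_ratio([2, 2, 3, 8, 5, 5, 2], "valence")
        assert label is ValenceLabel.NEGATIVE
        assert ratio == pytest.approx(4 / 7)

    def test_unanimous(self):
        label, ratio = identity_ratio([7, 7, 7], "valence")
        assert label is ValenceLabel.POSITIVE
        assert ratio == 1.0

    def test_tie_has_no_modal_label(self):
        label, ratio = identity_ratio([4, 4, 8, 8], "valence")
        assert label is None
        assert ratio == 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            identity_ratio([], "valence")

    def test_matches_bruteforce_oracle_on_random_lists(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            scores = rng.integers(1, 10, size=int(rng.integers(1, 12))).tolist()
            for dim in ("valence", "arousal"):
                label, ratio = identity_ratio(scores, dim)
                o_label, o_ratio = oracle_modal(scores, dim)
                assert (label.value if label else None) == o_label
                assert ratio == pytest.approx(o_ratio, abs=1e-12)


class TestScreening:
    def test_screening_matches_oracle_recount(self):
        """Retention decisions equal an independent recount at 1e-10."""
        rng = np.random.default_rng(21)
        table = random_rating_table(rng, n_images=20, n_raters=6)
        result = screen_images(table, 0.60).set_index("image_id")
        for image_id, g in table.groupby("image_id"):
            expected_retained = True
            for dim in ("valence", "arousal"):
                scores = g[g["dimension"] == dim]["score"].tolist()
                o_label, o_ratio = oracle_modal(scores, dim)
                row = result.loc[image_id]
                assert row[f"{dim}_ratio"] == pytest.approx(o_ratio, abs=1e-10)
                assert row[f"{dim}_label"] == o_label
                if o_label is None or o_ratio < 0.60:
                    expected_retained = False
            assert bool(result.loc[image_id, "retained"]) == expected_retained

    def test_threshold_zero_retains_everything_without_ties(self):
        rng = np.random.default_rng(3)
        # constant ratings: unanimous labels, no ties
        table = random_rating_table(rng, n_images=5, n_raters=1)
        result = screen_images(table, 0.0)
        assert result["retained"].all()

    def test_filter_monotone_in_threshold(self):
        """Raising the threshold never enlarges the retained set."""
        rng = np.random.default_rng(5)
        table = random_rating_table(rng, n_images=30, n_raters=7)
        retained_sets = []
        for thr in [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]:
            res = screen_images(table, thr)
            retained_sets.append(set(res[res["retained"]]["image_id"]))
        for smaller, larger in zip(retained_sets[1:], retained_sets[:-1]):
            assert smaller <= larger

    def test_abnormal_affect_sessions_excluded(self):
        rows = []
        # 4 valid raters say positive; 3 abnormal-session raters say negative
        for r in range(7):
            valid = r < 4
            score = 8 if valid else 2
            for dim in ("valence", "arousal"):
                rows.append(
                    dict(rater_id=f"r{r}", image_id="people-p001", dimension=dim,
                         score=score if dim == "valence" else 5,
                         session_id=f"s{r}", rater_affect_valid=valid)
                )
        result = screen_images(pd.DataFrame(rows), 0.60)
        assert result.loc[0, "valence_label"] == "positive"
        assert result.loc[0, "n_raters_valence"] == 4

    def test_image_missing_a_dimension_is_excluded_and_reported(self, caplog):
        rows = [
            dict(rater_id="r0", image_id="people-p001", dimension="valence",
                 score=8, session_id="s0", rater_affect_valid=True),
            dict(rater_id="r0", image_id="people-p002", dimension="valence",
                 score=8, session_id="s0", rater_affect_valid=True),
            dict(rater_id="r0", image_id="people-p002", dimension="arousal",
                 score=5, session_id="s0", rater_affect_valid=True),
        ]
        with caplog.at_level("WARNING", logger="hdrps.library_builder"):
            result = screen_images(pd.DataFrame(rows), 0.60)
        assert list(result["image_id"]) == ["people-p002"]
        assert result.attrs["incomplete_images"] == ["people-p001"]
        assert "missing a dimension" in caplog.text


def screening_row(image_id, v_label, a_label, retained=True, mv=5.5, ma=5.0, n=10):
    return dict(
        image_id=image_id, round_id="x", valence_label=v_label, valence_ratio=0.8,
        arousal_label=a_label, arousal_ratio=0.8, mean_valence=mv, mean_arousal=ma,
        n_raters_valence=n, n_raters_arousal=n, retained=retained,
    )


class TestMergeRounds:
    def test_consistent_labels_enter_library(self):
        r1 = pd.DataFrame([screening_row("people-p001", "positive", "low")])
        r2 = pd.DataFrame([screening_row("people-p001", "positive", "low", mv=7.1)])
        lib = merge_rounds(r1, r2)
        assert len(lib) == 1
        assert lib.images[0].mean_valence == 7.1  # round-2 means by default

    def test_label_disagreement_excluded(self):
        r1 = pd.DataFrame([screening_row("people-p001", "positive", "low")])
        r2 = pd.DataFrame([screening_row("people-p001", "negative", "low", mv=2.5)])
        assert len(merge_rounds(r1, r2)) == 0

    def test_single_round_presence_is_not_retained(self):
        r1 = pd.DataFrame([screening_row("people-p001", "positive", "low")])
        r2 = pd.DataFrame([screening_row("people-p002", "positive", "low", mv=7.0)])
        assert len(merge_rounds(r1, r2)) == 0

    def test_set_intersection_counts(self):
        """10 images, 7 valence-consistent, 6 arousal-consistent, 5 both -> 5."""
        rng = np.random.default_rng(13)
        ids = [f"people-p{i:03d}" for i in range(10)]
        v_consistent = set(ids[:7])
        a_consistent = set(ids[2:8])  # overlap with v_consistent: ids 2..6 -> 5
        r1_rows, r2_rows = [], []
        for i, image_id in enumerate(ids):
            v1 = "positive"
            v2 = v1 if image_id in v_consistent else "negative"
            a1 = "low"
            a2 = a1 if image_id in a_consistent else "high"
            mv = 7.0 + 0.01 * i
            r1_rows.append(screening_row(image_id, v1, a1))
            r2_rows.append(screening_row(image_id, v2, a2, mv=mv))
        lib = merge_rounds(pd.DataFrame(r1_rows), pd.DataFrame(r2_rows))
        expected = v_consistent & a_consistent
        assert len(lib) == len(expected) == 5
        assert {img.image_id for img in lib.images} == expected

    def test_library_subset_of_each_round(self):
        cfg = SimConfig(seed=29, n_images_per_category=8, professional_raters=9,
                        rater_noise_sd=1.5)
        ratings = simulate_ratings(cfg)
        r1 = screen_images(ratings.expert)
        r2 = screen_images(ratings.professional)
        lib = merge_rounds(r1, r2)
        kept1 = set(r1[r1["retained"]]["image_id"])
        kept2 = set(r2[r2["retained"]]["image_id"])
        lib_ids = {img.image_id for img in lib.images}
        assert lib_ids <= kept1 and lib_ids <= kept2
        assert len(lib) <= min(len(kept1), len(kept2))

    def test_pooled_means_weighted_by_panel_size(self):
        r1 = pd.DataFrame([screening_row("people-p001", "positive", "low", mv=7.0, ma=3.0, n=5)])
        r2 = pd.DataFrame([screening_row("people-p001", "positive", "low", mv=8.0, ma=2.0, n=15)])
        lib = merge_rounds(r1, r2, means="pooled")
        assert lib.images[0].mean_valence == pytest.approx((7.0 * 5 + 8.0 * 15) / 20)
        assert lib.images[0].mean_arousal == pytest.approx((3.0 * 5 + 2.0 * 15) / 20)


class TestLibraryStats:
    def test_single_image_manifest(self, minimal_library):
        lib = LibraryManifest(images=[minimal_library.images[0]])
        stats = library_stats(lib)
        cat = lib.images[0].category.value
        assert stats.loc[cat, "share_pct"] == 100.0
        assert stats.loc[cat, "n"] == 1
        others = [c.value for c in Category if c.value != cat]
        assert (stats.loc[others, "n"] == 0).all()
        assert stats.loc["all", "n"] == 1

    def test_counts_and_shares(self, minimal_library):
        stats = library_stats(minimal_library)
        assert stats.loc["all", "n"] == 20
        assert (stats.drop("all")["n"] == 4).all()
        assert (stats.drop("all")["share_pct"] == 20.0).all()

    def test_empty_manifest_rejected(self):
        with pytest.raises(ValueError):
            library_stats(LibraryManifest(images=[]))


class TestParameterRecovery:
    def test_zero_noise_recovers_all_true_labels(self):
        cfg = SimConfig(seed=17, n_images_per_category=12, rater_noise_sd=0.0,
                        professional_raters=9, expert_abnormal_session_rate=0.0)
        ratings = simulate_ratings(cfg)
        result = screen_images(ratings.professional).set_index("image_id")
        truth = ratings.truth.set_index("image_id").loc[result.index]
        assert (result["valence_ratio"] == 1.0).all()
        assert (result["arousal_ratio"] == 1.0).all()
        assert (result["valence_label"] == truth["true_valence_label"]).all()
        assert (result["arousal_label"] == truth["true_arousal_label"]).all()

    def test_recovery_degrades_monotonically_in_noise(self):
        rates = []
        for sd in (0.25, 1.5, 3.0):
            cfg = SimConfig(seed=23, n_images_per_category=20, rater_noise_sd=sd,
                            professional_raters=9, expert_abnormal_session_rate=0.0)
            ratings = simulate_ratings(cfg)
            result = screen_images(ratings.professional).set_index("image_id")
            truth = ratings.truth.set_index("image_id")
            correct = (
                (result["valence_label"] == truth.loc[result.index, "true_valence_label"])
                & result["retained"]
            )
            rates.append(correct.mean())
        assert rates[0] > rates[1] > rates[2]
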