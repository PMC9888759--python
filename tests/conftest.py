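import pytest

from hdrps.affect_core import (
    ArousalLabel,
    Category,
    ImageAffect,
    NeutralSubtype,
    ValenceLabel,
    image_name,
)
from hdrps.library_builder import LibraryManifest, merge_rounds, screen_images
from hdrps.synthetic_cohort import SimConfig, simulate_ratings

STRATUM_VALENCE = {
    ValenceLabel.POSITIVE: 7.2,
    NeutralSubtype.HIGH_NEUTRAL: 5.5,
    NeutralSubtype.LOW_NEUTRAL: 4.5,
    ValenceLabel.NEGATIVE: 2.5,
}


def make_image(category, stratum, number, valence=None, arousal=4.5):
    v = STRATUM_VALENCE[stratum] if valence is None else valence
    v_label = (
        ValenceLabel.NEUTRAL if isinstance(stratum, NeutralSubtype) else ValenceLabel(stratum)
    )
    return ImageAffect(
        image_id=image_name(category, stratum, number),
        category=category,
        mean_valence=v,
        mean_arousal=arousal,
        valence_label=v_label,
        arousal_label=ArousalLabel.MEDIUM,
        neutral_subtype=stratum if isinstance(stratum, NeutralSubtype) else None,
        valence_identity_ratio=0.9,
        arousal_identity_ratio=0.9,
        n_raters=35,
    )


@pytest.fixture(scope="session")
def minimal_library():
    """Exactly one picture per (category, valence stratum): 20 pictures."""
    images = [
        make_image(cat, stratum, 1)
        for cat in Category
        for stratum in STRATUM_VALENCE
    ]
    return LibraryManifest(images=images)


@pytest.fixture(scope="session")
def rich_library():
    """Several pictures per stratum, with within-stratum valence spread."""
    images = []
    for cat in Category:
        num = 0
        for stratum, base in STRATUM_VALENCE.items():
            for k in range(4):
                num += 1
                offset = (k - 1.5) * (0.1 if isinstance(stratum, NeutralSubtype) else 0.3)
                images.append(make_image(cat, stratum, num, valence=base + offset))
    return LibraryManifest(images=images)


@pytest.fixture(scope="session")
def small_sim_config():
    return SimConfig(
        seed=11,
        n_images_per_category=16,
        expert_raters=7,
        professional_raters=15,
        rater_noise_sd=0.5,
        n_participants=40,
        n_trials_per_participant=8,
    )


@pytest.fixture(scope="session")
def simulated_library(small_sim_config):
    ratings = simulate_ratings(small_sim_config)
    r1 = screen_images(ratings.expert, round_id="expert")
    r2 = screen_images(ratings.professional, round_id="professional")
    return merge_rounds(r1, r2)
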