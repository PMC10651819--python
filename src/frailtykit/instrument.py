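"""The clinical frailty-index instrument: deficit items and scoring levels.

The assessment starts from the 31-item mouse clinical frailty index
(Whitehead-style visual deficit rating) and drops four items — forelimb
grip strength, tail stiffening, body temperature and body weight — that
are measured elsewhere in the protocol, leaving 27 visually scored
health deficits. Each item is rated 0 (absent), 0.5 (mild) or 1
(severe), and the frailty index is the item sum divided by 27.

The source study names only example items (vestibular disturbance,
alopecia, dermatitis, coat condition, vision and hearing loss, ...), so
the default list below is a faithful reconstruction of the instrument,
not a verbatim copy; any 27-name list can be substituted via the
``items=`` argument of the readers and validators.
"""

from __future__ import annotations

# Full 31-item visual instrument, grouped roughly by body system.
FULL_INSTRUMENT_ITEMS: tuple[str, ...] = (
    # integument
    "alopecia",
    "loss_of_fur_colour",
    "dermatitis",
    "loss_of_whiskers",
    "coat_condition",
    # physical / musculoskeletal
    "tumours",
    "distended_abdomen",
    "kyphosis",
    "tail_stiffening",
    "gait_disorders",
    "tremor",
    "forelimb_grip_strength",
    "body_condition_score",
    # vestibulocochlear / auditory
    "vestibular_disturbance",
    "hearing_loss",
    # ocular / nasal
    "cataracts",
    "corneal_opacity",
    "eye_discharge_swelling",
    "microphthalmia",
    "vision_loss",
    "menace_reflex",
    "nasal_discharge",
    # digestive / urogenital
    "malocclusions",
    "rectal_prolapse",
    "genital_prolapse",
    "diarrhea",
    # respiratory
    "breathing_rate_depth",
    # discomfort
    "mouse_grimace_scale",
    "piloerection",
    # instrumented measures, excluded from the visual index here
    "body_temperature",
    "body_weight",
)

# Items scored by instruments rather than visual inspection; excluded.
EXCLUDED_ITEMS: tuple[str, ...] = (
    "forelimb_grip_strength",
    "tail_stiffening",
    "body_temperature",
    "body_weight",
)

DEFAULT_DEFICIT_ITEMS: tuple[str, ...] = tuple(
    item for item in FULL_INSTRUMENT_ITEMS if item not in EXCLUDED_ITEMS
)

N_DEFICIT_ITEMS: int = len(DEFAULT_DEFICIT_ITEMS)

#: Permitted per-item scores: absent, mild, severe.
VALID_SCORES: frozenset[float] = frozenset({0.0, 0.5, 1.0})

assert N_DEFICIT_ITEMS == 27, "instrument must reduce to 27 items"
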