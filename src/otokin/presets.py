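"""Published stage-54 species means used as synthetic ground truth.

Each preset bundles the reported group means for one species at larval
stage 54 — oculomotor gains and phases, locomotor statistics, canal radii
and duct length — so that every parameter-recovery test draws its target
from a single source of truth. Phases follow the convention used
throughout the package: degrees relative to peak stimulus position,
negative values denoting a phase lead.
"""

from __future__ import annotations

PRESETS: dict[str, dict] = {
    "xenopus_54": {
        "species": "xenopus",
        # oculomotor (gain, phase °) per condition
        "vor_dark": {"gain": 0.29, "phase": -54.3},
        "vor_light": {"gain": 0.32, "phase": -29.4},
        "okr": {"gain": 0.14, "phase": 13.4},
        # locomotion: near-continuous swimming in long bouts
        "time_swimming_per_60s": 28.8,  # s
        "mean_bout_duration": 6.98,  # s
        "glide": False,
        "swim_speed": 5.0,  # mm/s during bouts
        "tail_beat_freq": 4.0,  # Hz
        # spino-ocular coupling
        "eye_tail_ratio": 90.31,  # % of tail cycles with a matched eye cycle
        # horizontal-canal morphometry
        "circuit_radius": 634.09,  # μm
        "lumen_radius": 77.11,  # μm
        "duct_length_mm": 1.4,
    },
    "axolotl_54": {
        "species": "axolotl",
        "vor_dark": {"gain": 0.05, "phase": 47.06},
        "vor_light": {"gain": 0.14, "phase": 41.52},
        "okr": {"gain": 0.25, "phase": 6.03},
        # locomotion: short thrust-and-glide bouts
        "time_swimming_per_60s": 10.7,
        "mean_bout_duration": 0.92,
        "glide": True,
        "swim_speed": 5.0,
        "tail_beat_freq": 4.0,
        "eye_tail_ratio": 56.49,
        "circuit_radius": 582.91,
        "lumen_radius": 66.32,
        "duct_length_mm": 1.07,
    },
}


def get_preset(name: str) -> dict:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
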