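"""Recording-protocol constants: activity codes, trial counts, durations, cohorts.

The protocol comprises 19 activities of daily living (D01–D19) and 15 fall
types (F01–F15) recorded at the waist. Falls last 15 s; ADLs last 12, 25 or
100 s depending on the activity. Subject codes carry the cohort prefix:
``SA`` for young adults, ``SE`` for elderly participants.
"""

from __future__ import annotations

#: activity code -> (description, trials per subject, duration in seconds)
ACTIVITIES: dict[str, tuple[str, int, float]] = {
    "D01": ("Walking slowly", 1, 100.0),
    "D02": ("Walking quickly", 1, 100.0),
    "D03": ("Jogging slowly", 1, 100.0),
    "D04": ("Jogging quickly", 1, 100.0),
    "D05": ("Walking upstairs and downstairs slowly", 5, 25.0),
    "D06": ("Walking upstairs and downstairs quickly", 5, 25.0),
    "D07": ("Slowly sit in a half height chair, wait a moment, and up slowly", 5, 12.0),
    "D08": ("Quickly sit in a half height chair, wait a moment, and up quickly", 5, 12.0),
    "D09": ("Slowly sit in a low height chair, wait a moment, and up slowly", 5, 12.0),
    "D10": ("Quickly sit in a low height chair, wait a moment, and up quickly", 5, 12.0),
    "D11": ("Sitting a moment, trying to get up, and collapse into a chair", 5, 12.0),
    "D12": ("Sitting a moment, lying slowly, wait a moment, and sit again", 5, 12.0),
    "D13": ("Sitting a moment, lying quickly, wait a moment, and sit again", 5, 12.0),
    "D14": ("Being on one's back change to lateral position, wait a moment, and change to one's back", 5, 12.0),
    "D15": ("Standing, slowly bending at knees, and getting up", 5, 12.0),
    "D16": ("Standing, slowly bending without bending knees, and getting up", 5, 12.0),
    "D17": ("Standing, get into a car, remain seated and get out of the car", 5, 25.0),
    "D18": ("Stumble while walking", 5, 12.0),
    "D19": ("Gently jump without falling (trying to reach a high object)", 5, 12.0),
    "F01": ("Fall forward while walking caused by a slip", 5, 15.0),
    "F02": ("Fall backward while walking caused by a slip", 5, 15.0),
    "F03": ("Lateral fall while walking caused by a slip", 5, 15.0),
    "F04": ("Fall forward while walking caused by a trip", 5, 15.0),
    "F05": ("Fall forward while jogging caused by a trip", 5, 15.0),
    "F06": ("Vertical fall while walking caused by fainting", 5, 15.0),
    "F07": ("Fall while walking, with use of hands in a table to dampen fall, caused by fainting", 5, 15.0),
    "F08": ("Fall forward when trying to get up", 5, 15.0),
    "F09": ("Lateral fall when trying to get up", 5, 15.0),
    "F10": ("Fall forward when trying to sit down", 5, 15.0),
    "F11": ("Fall backward when trying to sit down", 5, 15.0),
    "F12": ("Lateral fall when trying to sit down", 5, 15.0),
    "F13": ("Fall forward while sitting, caused by fainting or falling asleep", 5, 15.0),
    "F14": ("Fall backward while sitting, caused by fainting or falling asleep", 5, 15.0),
    "F15": ("Lateral fall while sitting, caused by fainting or falling asleep", 5, 15.0),
}

ADL_CODES: tuple[str, ...] = tuple(c for c in ACTIVITIES if c.startswith("D"))
FALL_CODES: tuple[str, ...] = tuple(c for c in ACTIVITIES if c.startswith("F"))

#: cohort sizes of the recording campaign (young adults / elderly)
N_YOUNG = 23
N_ELDERLY = 15

COHORT_PREFIX = {"young": "SA", "elderly": "SE"}
PREFIX_COHORT = {v: k for k, v in COHORT_PREFIX.items()}

DEFAULT_FS = 200.0


def is_fall(activity_code: str) -> bool:
    """A trial is a fall iff its activity code starts with ``F``."""
    return activity_code.startswith("F")


def label_of(activity_code: str) -> str:
    return "fall" if is_fall(activity_code) else "adl"


def duration_of(activity_code: str) -> float:
    return ACTIVITIES[activity_code][2]
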