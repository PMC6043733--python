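"""Activity-category taxonomy and keyword-based categorizer.

Behavioral-activation (BA) diaries record one free-text activity per hour
slot.  During transcription each activity is assigned one of seven activity
categories (AC).  The taxonomy used here follows the published BA category
scheme: six substantive classes plus a residual ``Other`` class.

The :class:`CategoryLexicon` is a reproducible stand-in for manual
dual-rater coding: a longest-match keyword table mapping lower-cased
phrases to categories, with unmatched text falling through to ``Other``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "ActivityCategory",
    "CategoryLexicon",
    "DEFAULT_LEXICON",
    "categorize_entry",
]


class ActivityCategory(Enum):
    """The seven activity categories, in their canonical order.

    The integer value is the category's ordinal; it is fixed and used for
    deterministic tie-breaking (e.g. when building diurnal templates).
    """

    Movement = 0
    WorkEducation = 1
    SpareTime = 2
    DailyLiving = 3
    Practical = 4
    Social = 5
    Other = 6

    @property
    def ordinal(self) -> int:
        return self.value

    @classmethod
    def from_label(cls, label: str) -> "ActivityCategory":
        """Resolve a category from a label, tolerating common spellings.

        Accepts the enum name, the ordinal as a string, and the printed
        display forms ("Work & education", "Daily living", "Spare time",
        "Practical things").
        """
        text = str(label).strip()
        if not text:
            raise ValueError("empty category label")
        key = "".join(ch for ch in text.lower() if ch.isalnum())
        try:
            return _LABEL_ALIASES[key]
        except KeyError:
            raise ValueError(f"unknown activity category: {label!r}") from None


_LABEL_ALIASES: dict[str, ActivityCategory] = {}
for _cat in ActivityCategory:
    _LABEL_ALIASES["".join(_cat.name.lower())] = _cat
    _LABEL_ALIASES[str(_cat.value)] = _cat
_LABEL_ALIASES.update(
    {
        "workeducation": ActivityCategory.WorkEducation,
        "workandeducation": ActivityCategory.WorkEducation,
        "sparetime": ActivityCategory.SpareTime,
        "dailyliving": ActivityCategory.DailyLiving,
        "practicalthings": ActivityCategory.Practical,
        "practical": ActivityCategory.Practical,
    }
)

#: Display names matching the printed category headings.
DISPLAY_NAMES: dict[ActivityCategory, str] = {
    ActivityCategory.Movement: "Movement",
    ActivityCategory.WorkEducation: "Work & education",
    ActivityCategory.SpareTime: "Spare time",
    ActivityCategory.DailyLiving: "Daily living",
    ActivityCategory.Practical: "Practical",
    ActivityCategory.Social: "Social",
    ActivityCategory.Other: "Other",
}

# Seed phrases: every published category example, plus recurrent diary
# entries mentioned alongside them (sleep variants, resting, reading...).
_DEFAULT_PHRASES: dict[str, ActivityCategory] = {
    # Movement: activities involving physical activity
    "training": ActivityCategory.Movement,
    "go for a walk": ActivityCategory.Movement,
    "walk": ActivityCategory.Movement,
    "horse riding": ActivityCategory.Movement,
    "night run": ActivityCategory.Movement,
    "run": ActivityCategory.Movement,
    # Work & education: work, learning, or treatment
    "work": ActivityCategory.WorkEducation,
    "lecture": ActivityCategory.WorkEducation,
    "outpatient consultation": ActivityCategory.WorkEducation,
    "class": ActivityCategory.WorkEducation,
    # Spare time: time spent alone on hobbies or similar
    "relaxing": ActivityCategory.SpareTime,
    "watching a movie": ActivityCategory.SpareTime,
    "watching tv": ActivityCategory.SpareTime,
    "resting": ActivityCategory.SpareTime,
    "reading": ActivityCategory.SpareTime,
    "knitting": ActivityCategory.SpareTime,
    "computer": ActivityCategory.SpareTime,
    "home on the couch": ActivityCategory.SpareTime,
    # Daily living: basic activities of daily living
    "sleeping": ActivityCategory.DailyLiving,
    "sleep": ActivityCategory.DailyLiving,
    "half-asleep": ActivityCategory.DailyLiving,
    "went to bed": ActivityCategory.DailyLiving,
    "having breakfast": ActivityCategory.DailyLiving,
    "breakfast": ActivityCategory.DailyLiving,
    "eating dinner": ActivityCategory.DailyLiving,
    "bathing": ActivityCategory.DailyLiving,
    "shower": ActivityCategory.DailyLiving,
    "getting up": ActivityCategory.DailyLiving,
    # Practical: practical daily activities
    "cleaning": ActivityCategory.Practical,
    "pick up kids": ActivityCategory.Practical,
    "shopping": ActivityCategory.Practical,
    "laundry": ActivityCategory.Practical,
    # Social: spending time with others
    "cinema": ActivityCategory.Social,
    "concert": ActivityCategory.Social,
    "football": ActivityCategory.Social,
    "meeting with a friend": ActivityCategory.Social,
    # Other: uncategorized
    "transport": ActivityCategory.Other,
    "crying": ActivityCategory.Other,
    "migraine attack": ActivityCategory.Other,
}


@dataclass
class CategoryLexicon:
    """Keyword/phrase table mapping lower-cased text to a category.

    Matching is case- and whitespace-insensitive; the longest phrase
    contained in the input wins; text matching nothing maps to
    ``default_category``.
    """

    phrases: Mapping[str, ActivityCategory] = field(
        default_factory=lambda: dict(_DEFAULT_PHRASES)
    )
    default_category: ActivityCategory = ActivityCategory.Other

    def __post_init__(self) -> None:
        self.phrases = {
            " ".join(str(k).lower().split()): v for k, v in self.phrases.items()
        }

    def categorize(self, raw_text: str) -> ActivityCategory:
        return categorize_entry(raw_text, self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CategoryLexicon":
        """Load a lexicon from a YAML mapping of phrase -> category label."""
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError("lexicon YAML must be a mapping phrase -> category")
        return cls(
            phrases={k: ActivityCategory.from_label(v) for k, v in raw.items()}
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {k: v.name for k, v in sorted(self.phrases.items())}, fh
            )


#: Module-level default lexicon seeded with the published example phrases.
DEFAULT_LEXICON = CategoryLexicon()


def categorize_entry(
    raw_text: str, lexicon: CategoryLexicon | None = None
) -> ActivityCategory:
    """Assign an activity category to a free-text diary entry.

    The longest lexicon phrase occurring as a substring of the normalized
    text wins; ties at equal length are broken by lower category ordinal.
    Unmatched text returns the lexicon's default category (``Other``).

    Raises
    ------
    ValueError
        If ``raw_text`` is empty after trimming.
    """
    if lexicon is None:
        lexicon = DEFAULT_LEXICON
    text = " ".join(str(raw_text).lower().split())
    if not text:
        raise ValueError("cannot categorize empty activity text")
    best: tuple[int, int] | None = None  # (-len, ordinal) for min()
    best_cat: ActivityCategory | None = None
    for phrase, cat in lexicon.phrases.items():
        if phrase and phrase in text:
            key = (-len(phrase), cat.ordinal)
            if best is None or key < best:
                best = key
                best_cat = cat
    return best_cat if best_cat is not None else lexicon.default_category
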