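"""Facial-emotion feature vocabulary.

The encoding models are built on 48 continuous facial-expression scores
per video frame, each in [0, 1].  The vocabulary follows the 48-category
output of automated facial-expression models; only the labels matter to
the pipeline, plus two distinguished subsets used in the weight analysis:

* *complex* (socially grounded, late-developing) emotions:
  guilt, embarrassment, pride, envy — optionally also interest;
* *basic* emotions: joy, sadness, fear, anger, disgust, surprise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["EmotionFeatureSet", "HUME_48", "default_feature_set"]

# 48 stable labels.  The eleven named below (complex + basic + interest)
# are fixed; the remainder follow the automated-model vocabulary.
HUME_48: tuple[str, ...] = (
    "admiration", "adoration", "aesthetic_appreciation", "amusement",
    "anger", "anxiety", "awe", "awkwardness", "boredom", "calmness",
    "concentration", "confusion", "contemplation", "contempt",
    "contentment", "craving", "desire", "determination", "disappointment",
    "disgust", "distress", "doubt", "ecstasy", "embarrassment",
    "empathic_pain", "entrancement", "envy", "excitement", "fear",
    "gratitude", "guilt", "horror", "interest", "joy", "love",
    "nostalgia", "pain", "pride", "realization", "relief", "romance",
    "sadness", "satisfaction", "shame", "surprise", "sympathy",
    "tiredness", "triumph",
)

COMPLEX_4: frozenset[str] = frozenset({"guilt", "embarrassment", "pride", "envy"})
COMPLEX_5: frozenset[str] = COMPLEX_4 | {"interest"}
BASIC_6: frozenset[str] = frozenset(
    {"joy", "sadness", "fear", "anger", "disgust", "surprise"}
)


@dataclass(frozen=True)
class EmotionFeatureSet:
    """Ordered 48-feature vocabulary with the complex/basic subsets.

    Parameters
    ----------
    names
        Exactly 48 unique feature labels.
    complex_set, basic_set
        Disjoint subsets of ``names`` used for the aggregate
        weight–age correlations.
    """

    names: tuple[str, ...] = HUME_48
    complex_set: frozenset[str] = COMPLEX_4
    basic_set: frozenset[str] = BASIC_6

    def __post_init__(self) -> None:
        if len(self.names) != 48:
            raise ValueError(f"expected 48 feature names, got {len(self.names)}")
        if len(set(self.names)) != 48:
            raise ValueError("feature names must be unique")
        missing = (self.complex_set | self.basic_set) - set(self.names)
        if missing:
            raise ValueError(f"subset labels not in vocabulary: {sorted(missing)}")
        if self.complex_set & self.basic_set:
            raise ValueError("complex and basic sets must be disjoint")

    @property
    def n_features(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def indices(self, subset: frozenset[str] | set[str]) -> list[int]:
        """Vocabulary positions of ``subset``, in vocabulary order."""
        return [i for i, n in enumerate(self.names) if n in subset]

    def feature_class(self, name: str) -> str:
        if name in self.complex_set:
            return "complex"
        if name in self.basic_set:
            return "basic"
        return "other"


def default_feature_set(five_complex: bool = False) -> EmotionFeatureSet:
    """The default vocabulary; ``five_complex`` adds interest to the
    complex subset (an alternative grouping used in ranking discussions)."""
    return EmotionFeatureSet(
        names=HUME_48,
        complex_set=COMPLEX_5 if five_complex else COMPLEX_4,
        basic_set=BASIC_6,
    )
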