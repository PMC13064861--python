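"""Published topic-count tables from the Dreamachine stroboscopic-light study.

The original study analysed open reflections from two versions of the
Dreamachine immersive experience: "High Sensory" (HS; stroboscopic light plus
360-degree spatial sound; 700 sentences from 315 reports) and "Deep
Listening" (DL; the same soundtrack with non-stroboscopic wash lights; 198
sentences from 92 reports).  The per-topic sentence counts below are the
published distribution tables; the five cross-condition theme pairs are the
published greedy matches at threshold tau = 0.85.  The underlying report text
was never deposited, so these printed counts are the inputs available for
reproducing the study's contingency-table inference.
"""

from __future__ import annotations

#: High Sensory condition: topic label -> sentence count (outliers: -1)
HS_TOPIC_COUNTS: dict[str, int] = {
    "Visual perception of kaleidoscopic patterns and colours": 191,
    "Out-of-body experiences and cosmic dream-like consciousness": 125,
    "Experience of time and space distortions": 58,
    "Mindfulness and music based sensory experience for calm and peace": 54,
    "Spiritual or meditative experience with euphoric sensations": 40,
    "Subjective experience of therapeutic potential": 33,
    "Nostalgic memory recall phenomenon": 29,
    "Synesthetic sensory and emotional experience": 27,
    "Phenomenological experience of disorientation and anxiety": 24,
    "Visual sensitivity to flashing light intensity": 24,
    "Psychedelic experience and potential for trauma processing": 14,
    "Near-death experience and existential reflections": 13,
    "Outliers": 68,
}

#: Deep Listening condition: topic label -> sentence count
DL_TOPIC_COUNTS: dict[str, int] = {
    "Mindfulness and relaxation through sound experience": 50,
    "Spiritual experiences of connection and self-discovery": 41,
    "Phenomenology of visual perception in closed eyes": 27,
    "Imagery and perception of aquatic environments": 19,
    "Out-of-body experience": 16,
    "Space-time imagery and perception": 15,
    "The power of music on spatial perception": 14,
    "Outliers": 16,
}

#: Published greedy 1:1 matches at tau = 0.85: (HS topic, DL topic, similarity)
PUBLISHED_THEME_PAIRS: list[tuple[str, str, float]] = [
    (
        "Mindfulness and music based sensory experience for calm and peace",
        "Mindfulness and relaxation through sound experience",
        0.96,
    ),
    (
        "Out-of-body experiences and cosmic dream-like consciousness",
        "Out-of-body experience",
        0.94,
    ),
    (
        "Nostalgic memory recall phenomenon",
        "Spiritual experiences of connection and self-discovery",
        0.917,
    ),
    (
        "Visual sensitivity to flashing light intensity",
        "Phenomenology of visual perception in closed eyes",
        0.911,
    ),
    (
        "Experience of time and space distortions",
        "Space-time imagery and perception",
        0.869,
    ),
]

MATCH_THRESHOLD_TAU = 0.85


def merged_contingency_counts() -> tuple[list[str], list[tuple[int, int]]]:
    """Merged theme x condition sentence counts from the published tables:
    the five matched pairs, then HS-specific themes, then DL-specific themes.
    Outlier rows are excluded (they are unassigned sentences, not themes)."""
    themes: list[str] = []
    rows: list[tuple[int, int]] = []
    matched_hs = {a for a, _, _ in PUBLISHED_THEME_PAIRS}
    matched_dl = {b for _, b, _ in PUBLISHED_THEME_PAIRS}
    for hs, dl, _sim in PUBLISHED_THEME_PAIRS:
        themes.append(f"{hs} | {dl}")
        rows.append((HS_TOPIC_COUNTS[hs], DL_TOPIC_COUNTS[dl]))
    for label, count in HS_TOPIC_COUNTS.items():
        if label == "Outliers" or label in matched_hs:
            continue
        themes.append(label)
        rows.append((count, 0))
    for label, count in DL_TOPIC_COUNTS.items():
        if label == "Outliers" or label in matched_dl:
            continue
        themes.append(label)
        rows.append((0, count))
    return themes, rows
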