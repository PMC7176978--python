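"""Published summary counts from a clinical plasma-versus-stool methylated
*SEPT9* comparison.

The study behind this pipeline reported only group-level detection counts
(positive / total per diagnostic group, stage and calling algorithm) and a
paired-specimen agreement table — not the raw per-replicate Cp values.
Those printed counts are reproduced here so that every statistic derivable
from them (pooled sensitivities, specificities, concordance rates) can be
recomputed by the ``diagnostics`` machinery and compared against the
published figures.

Keys of the per-specimen tables are the calling algorithms: ``"1/3"``,
``"2/3"``, ``"3/3"`` and ``"3/3+cp40"`` (3-of-3 with censored mean Cp
< 40.0).  Values map row labels (stages, ``AA``, ``normal``) to
``(n_positive, n_total)``.
"""

from __future__ import annotations

__all__ = [
    "ALGORITHMS",
    "PLASMA_COUNTS",
    "STOOL_COUNTS",
    "CRC_STAGES",
    "PAIRED_CATEGORIES",
    "PAIRED_CRC_CATEGORIES",
]

ALGORITHMS = ("1/3", "2/3", "3/3", "3/3+cp40")

#: Detection counts for plasma specimens, per algorithm and row.
PLASMA_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "1/3": {
        "AA": (4, 13),
        "I": (14, 18), "II": (23, 27), "III": (24, 26), "IV": (8, 10),
        "unknown": (8, 9),
        "normal": (8, 81),
    },
    "2/3": {
        "AA": (1, 13),
        "I": (6, 18), "II": (19, 27), "III": (18, 26), "IV": (7, 10),
        "unknown": (8, 9),
        "normal": (5, 81),
    },
    "3/3": {
        "AA": (1, 13),
        "I": (3, 18), "II": (18, 27), "III": (13, 26), "IV": (6, 10),
        "unknown": (8, 9),
        "normal": (3, 81),
    },
    "3/3+cp40": {
        "AA": (1, 13),
        "I": (3, 18), "II": (16, 27), "III": (9, 26), "IV": (6, 10),
        "unknown": (8, 9),
        "normal": (1, 81),
    },
}

#: Detection counts for stool specimens, per algorithm and row.
STOOL_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "1/3": {
        "AA": (10, 12),
        "I": (15, 15), "II": (17, 18), "III": (23, 23), "IV": (8, 9),
        "unknown": (7, 7),
        "normal": (39, 76),
    },
    "2/3": {
        "AA": (9, 12),
        "I": (14, 15), "II": (17, 18), "III": (20, 23), "IV": (7, 9),
        "unknown": (6, 7),
        "normal": (23, 76),
    },
    "3/3": {
        "AA": (8, 12),
        "I": (13, 15), "II": (17, 18), "III": (20, 23), "IV": (7, 9),
        "unknown": (5, 7),
        "normal": (10, 76),
    },
    "3/3+cp40": {
        "AA": (8, 12),
        "I": (13, 15), "II": (17, 18), "III": (18, 23), "IV": (7, 9),
        "unknown": (5, 7),
        "normal": (6, 76),
    },
}

CRC_STAGES = ("I", "II", "III", "IV", "unknown")

#: Paired plasma/stool agreement categories over the 60 paired subjects,
#: as (stool+/plasma+, stool+/plasma-, stool-/plasma+, stool-/plasma-).
PAIRED_CATEGORIES = (39, 7, 6, 8)

#: Same categories restricted to the 52 paired CRC subjects.
PAIRED_CRC_CATEGORIES = (39, 6, 6, 1)
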