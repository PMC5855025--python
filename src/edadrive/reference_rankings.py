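"""Reference per-subject SVM-RFE rank tables from a 10-driver on-road study.

These are the published per-subject feature rankings (feature ids 1–18,
rank position 1 first) for the two binary distraction scenarios of a
10-subject on-road driving study with normal, phone-conversation and
texting conditions.  They serve as a worked example for the consensus
rule in :mod:`edadrive.rfe`: feeding either table through
:func:`edadrive.rfe.consensus_select` with k = 7 yields the same
seven-feature subset — number of peaks (6), second STFT band (9), Katz
fractal dimension (13) and four autoregressive coefficients
(14, 15, 17, 18).
"""

from __future__ import annotations

#: Normal vs phone-conversation scenario, subjects 1–10.
NORMAL_VS_PHONE: dict[str, list[int]] = {
    "subject_01": [6, 13, 15, 17, 14, 18, 16, 9, 5, 1, 12, 7, 8, 3, 11, 4, 2, 10],
    "subject_02": [16, 15, 6, 17, 14, 9, 18, 13, 1, 5, 12, 7, 11, 8, 3, 2, 4, 10],
    "subject_03": [16, 15, 6, 14, 17, 18, 9, 13, 12, 5, 1, 7, 8, 11, 3, 2, 4, 10],
    "subject_04": [15, 13, 16, 14, 6, 18, 9, 17, 1, 5, 7, 12, 11, 8, 3, 2, 4, 10],
    "subject_05": [1, 15, 6, 17, 16, 14, 18, 9, 13, 5, 12, 7, 11, 8, 3, 2, 10, 4],
    "subject_06": [15, 13, 17, 6, 14, 18, 9, 16, 5, 1, 12, 2, 4, 8, 3, 11, 7, 10],
    "subject_07": [6, 15, 14, 16, 9, 18, 17, 13, 12, 11, 7, 5, 1, 4, 2, 3, 8, 10],
    "subject_08": [6, 15, 13, 14, 9, 16, 18, 17, 12, 5, 1, 7, 11, 8, 3, 4, 2, 10],
    "subject_09": [6, 17, 1, 15, 14, 18, 13, 16, 9, 5, 12, 7, 11, 8, 3, 2, 10, 4],
    "subject_10": [15, 6, 14, 17, 18, 13, 9, 16, 5, 12, 1, 11, 7, 2, 4, 3, 8, 10],
}

#: Published "frequent feature" consensus row for the phone scenario.
NORMAL_VS_PHONE_CONSENSUS: list[int] = \
    [6, 15, 6, 17, 14, 18, 9, 13, 5, 5, 12, 7, 11, 8, 3, 2, 4, 10]

#: Normal vs texting scenario, subjects 1–10.
NORMAL_VS_TEXT: dict[str, list[int]] = {
    "subject_01": [15, 6, 17, 14, 18, 9, 16, 13, 5, 1, 12, 7, 11, 3, 8, 2, 10, 4],
    "subject_02": [15, 6, 17, 14, 18, 16, 9, 13, 12, 7, 11, 5, 1, 3, 8, 10, 2, 4],
    "subject_03": [5, 6, 15, 17, 18, 14, 16, 9, 13, 1, 12, 7, 11, 3, 4, 2, 8, 10],
    "subject_04": [17, 15, 13, 18, 14, 6, 16, 9, 1, 12, 5, 7, 11, 3, 8, 2, 10, 4],
    "subject_05": [6, 17, 15, 16, 14, 18, 9, 13, 5, 1, 12, 7, 11, 3, 8, 2, 4, 10],
    "subject_06": [17, 16, 6, 15, 18, 14, 9, 13, 1, 2, 4, 12, 5, 8, 3, 11, 7, 10],
    "subject_07": [15, 17, 9, 14, 18, 16, 13, 12, 8, 11, 10, 7, 6, 5, 4, 3, 2, 1],
    "subject_08": [5, 15, 6, 17, 14, 18, 16, 9, 13, 12, 7, 8, 11, 10, 4, 3, 2, 1],
    "subject_09": [5, 6, 17, 15, 18, 14, 9, 16, 13, 1, 12, 7, 11, 8, 3, 2, 4, 10],
    "subject_10": [15, 17, 12, 14, 18, 13, 9, 6, 16, 11, 5, 1, 8, 3, 2, 4, 7, 10],
}

#: Published "frequent feature" consensus row for the texting scenario.
NORMAL_VS_TEXT_CONSENSUS: list[int] = \
    [15, 6, 17, 14, 18, 14, 9, 13, 13, 1, 12, 7, 11, 3, 8, 2, 2, 10]

#: The unified seven-feature subset reported for both scenarios.
SELECTED_SEVEN: frozenset[int] = frozenset({6, 9, 13, 14, 15, 17, 18})
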