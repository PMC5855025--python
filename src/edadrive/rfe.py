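"""SVM recursive feature elimination and cross-subject consensus.

SVM-RFE ranks features by iteratively training a linear SVM, scoring
each remaining feature by the square of its weight ``w_i = sum_j alpha_j
y_j x_ji``, and discarding the feature with the smallest score until one
remains; reading the elimination order backwards gives a best-first
ranking.  Because it is a binary technique, distraction scenarios are
ranked pairwise (normal vs phone, normal vs text), one ranking per
subject, and a single consensus feature subset is then distilled across
subjects: the modal feature at each rank position, scanned left to
right for the first k distinct features.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .features import FEATURE_NAMES

SCENARIOS = {"normal_vs_phone": ("normal", "phone"),
             "normal_vs_text": ("normal", "text")}


def svm_rfe_rank(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> list[int]:
    """Rank feature columns best-first by linear-SVM RFE.

    Features are standardized once over the full input (weights are only
    comparable across features of equal scale); a constant column has
    zero weight and is therefore eliminated first among ties (ties break
    toward the lower column index, which ``argmin`` gives for free).

    Returns a best-first permutation of ``range(X.shape[1])``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"SVM-RFE is a binary technique, got "
                         f"{classes.size} class(es)")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd

    remaining = list(range(X.shape[1]))
    eliminated: list[int] = []
    while len(remaining) > 1:
        svc = SVC(kernel="linear", C=C)
        svc.fit(Xs[:, remaining], y)
        crit = svc.coef_.ravel() ** 2
        worst = int(np.argmin(crit))
        eliminated.append(remaining.pop(worst))
    eliminated.append(remaining[0])
    return eliminated[::-1]


@dataclass
class RankingResult:
    """Per-subject rankings for one binary scenario, plus the consensus."""

    scenario: str
    per_subject_ranks: dict[str, list[int]]
    consensus_row: list[int] = field(default_factory=list)
    selected_subset: set[int] = field(default_factory=set)

    def to_frame(self) -> pd.DataFrame:
        """Table mirroring the per-subject rank layout (rank 1 first)."""
        rows = {s: r for s, r in self.per_subject_ranks.items()}
        if self.consensus_row:
            rows["frequent_feature"] = self.consensus_row
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.columns = [f"rank_{j + 1}" for j in range(df.shape[1])]
        return df


def consensus_select(per_subject_ranks, k: int = 7):
    """Cross-subject consensus: per-position mode, then first-k-distinct.

    ``consensus_row[j]`` is the most frequent feature at rank position j
    across subjects (ties broken toward the smaller feature id);
    ``selected_subset`` collects the first ``k`` distinct features met
    while scanning the consensus row from rank 1 onward.

    Accepts a dict or list of equal-length rank lists; features may be
    any orderable labels.
    """
    ranks = list(per_subject_ranks.values()
                 if isinstance(per_subject_ranks, dict)
                 else per_subject_ranks)
    if not ranks:
        raise ValueError("need at least one ranking")
    length = len(ranks[0])
    if any(len(r) != length for r in ranks):
        raise ValueError("all rankings must have the same length")
    if k > len(set().union(*map(set, ranks))):
        raise ValueError("k exceeds the number of distinct features")

    consensus_row = []
    for j in range(length):
        counts = Counter(r[j] for r in ranks)
        top = max(counts.values())
        consensus_row.append(min(f for f, c in counts.items() if c == top))

    selected: list = []
    for f in consensus_row:
        if f not in selected:
            selected.append(f)
            if len(selected) == k:
                break
    if len(selected) < k:   # consensus row itself held < k distinct features
        pool = sorted(set().union(*map(set, ranks)) - set(selected))
        selected.extend(pool[: k - len(selected)])
    return consensus_row, set(selected)


def rank_cohort(features: pd.DataFrame, scenario: str, C: float = 1.0,
                k: int = 7) -> RankingResult:
    """Per-subject SVM-RFE rankings for one binary scenario.

    ``features`` is the table produced by
    :func:`edadrive.features.extract_table` (columns f1..f18,
    ``subject_id``, ``condition``).  Each subject is ranked on its own
    windows only; a subject missing one of the two classes is skipped
    with a warning.  Feature ids in the result are 1-based (f1..f18).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    cond_a, cond_b = SCENARIOS[scenario]
    per_subject: dict[str, list[int]] = {}
    for subject, sub in features.groupby("subject_id"):
        sub = sub[sub["condition"].isin((cond_a, cond_b))]
        if sub["condition"].nunique() < 2:
            warnings.warn(f"subject {subject} lacks a class for {scenario}; "
                          "skipped")
            continue
        X = sub.loc[:, list(FEATURE_NAMES)].to_numpy()
        y = (sub["condition"] == cond_b).to_numpy().astype(int)
        ranking = svm_rfe_rank(X, y, C=C)
        per_subject[subject] = [i + 1 for i in ranking]
    if not per_subject:
        raise ValueError("no subject had both classes")
    consensus_row, subset = consensus_select(per_subject, k=k)
    return RankingResult(scenario, per_subject, consensus_row, subset)
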