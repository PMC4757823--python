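"""Theoretical validation of screening runs: EF, maxEF, ROC AUC, hit selection.

The enrichment factor of a virtual hitlist is

    EF = (TP / n) / (A / N)

with TP true-positive hits among n hits, A actives among N library
compounds: the fold-enrichment of actives over a random selection.  Its
ceiling for a given library is maxEF = N / A (attained by a pure-TP
hitlist); for a fixed hitlist size n the ceiling is min(n, A)/n * N/A.

Displayed values are rounded half-away-from-zero to one decimal.  Because
the percent-of-maxEF convention differs between reports (rounded vs
unrounded ratio), both variants are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .errors import DomainError
from .library_io import ActivityRecord, ScreeningResult


def round_display(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, matching printed-table style."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def enrichment_factor(TP: int, n: int, A: int, N: int) -> float:
    """EF = (TP/n) / (A/N); undefined for an empty hitlist."""
    if n < 1:
        raise DomainError("EF is undefined for an empty hitlist (n = 0)")
    if N < 1 or A < 1:
        raise DomainError("need at least one active and one library compound")
    if not (0 <= TP <= min(n, A)) or A > N or n > N:
        raise DomainError(f"inconsistent counts TP={TP}, n={n}, A={A}, N={N}")
    return (TP / n) / (A / N)


def max_enrichment_factor(A: int, N: int, n: int | None = None) -> float:
    """Theoretical EF ceiling: N/A, or min(n, A)/n * N/A for fixed hitlist size."""
    if A < 1 or N < A:
        raise DomainError("need 1 <= A <= N")
    if n is None:
        return N / A
    if n < 1:
        raise DomainError("hitlist size must be positive")
    return (min(n, A) / n) * (N / A)


def roc_auc(scores: Mapping[str, float] | Sequence[float], active_flags) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie correction.

    ``scores`` may be a mapping id -> score with ``active_flags`` a set of
    active ids, or a score sequence with a parallel boolean sequence.
    """
    if isinstance(scores, Mapping):
        ids = sorted(scores)
        s = np.array([scores[i] for i in ids], dtype=float)
        y = np.array([i in set(active_flags) for i in ids], dtype=bool)
    else:
        s = np.asarray(scores, dtype=float)
        y = np.asarray(active_flags, dtype=bool)
        if len(s) != len(y):
            raise DomainError("scores and flags must have equal length")
    na = int(y.sum())
    nb = int((~y).sum())
    if na == 0 or nb == 0:
        raise DomainError("AUC needs at least one active and one non-active")
    ranks = rankdata(s)  # midranks
    return float((ranks[y].sum() - na * (na + 1) / 2.0) / (na * nb))


@dataclass
class ValidationMetrics:
    TP: int
    n: int
    A: int
    N: int
    EF: float
    EF_display: float
    maxEF: float
    maxEF_display: float
    pct_maxEF_unrounded: float
    pct_maxEF_rounded: float
    auc: float
    per_class_recovery: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "TP": self.TP, "n": self.n, "A": self.A, "N": self.N,
            "EF": self.EF, "EF_display": self.EF_display,
            "maxEF": self.maxEF, "maxEF_display": self.maxEF_display,
            "pct_maxEF_unrounded": self.pct_maxEF_unrounded,
            "pct_maxEF_rounded": self.pct_maxEF_rounded,
            "auc": self.auc,
            "per_class_recovery": dict(self.per_class_recovery),
        }


def evaluate_model_ensemble(
    result: ScreeningResult,
    annotations: Mapping[str, ActivityRecord],
    active_definition: Iterable[str] = ("agonist",),
) -> ValidationMetrics:
    """Compute EF/maxEF/AUC and per-class recovery for a screening run.

    ``active_definition`` names the classes counted as active (for example
    only antagonists, or agonists and antagonists together).  Every screened
    compound must be annotated.  For hit/non-hit (binary) score patterns the
    AUC uses the reported scores for hits and a common score below every hit
    score for non-hits, with midranks handling the tie block.
    """
    active = set(active_definition)
    ids = result.table["compound_id"].tolist()
    missing = [i for i in ids if i not in annotations]
    if missing:
        raise DomainError(f"unannotated compounds: {missing[:10]}"
                          + ("..." if len(missing) > 10 else ""))
    labels = {i: annotations[i].class_label for i in ids}
    hits = set(result.table.loc[result.table["is_hit"], "compound_id"])
    n = len(hits)
    big_n = len(ids)
    big_a = sum(1 for i in ids if labels[i] in active)
    tp = sum(1 for i in hits if labels[i] in active)
    ef = enrichment_factor(tp, n, big_a, big_n)
    maxef = max_enrichment_factor(big_a, big_n)
    ef_disp = round_display(ef)
    maxef_disp = round_display(maxef)
    scores = dict(zip(result.table["compound_id"], result.table["score"]))
    floor = (min(scores[i] for i in hits) - 1.0) if hits else 0.0
    auc_scores = {i: (scores[i] if i in hits else floor) for i in ids}
    auc = roc_auc(auc_scores, {i for i in ids if labels[i] in active})
    recovery: dict[str, float] = {}
    for cls in sorted(set(labels.values())):
        members = [i for i in ids if labels[i] == cls]
        recovery[cls] = sum(1 for i in members if i in hits) / len(members)
    return ValidationMetrics(
        TP=tp, n=n, A=big_a, N=big_n,
        EF=ef, EF_display=ef_disp,
        maxEF=maxef, maxEF_display=maxef_disp,
        pct_maxEF_unrounded=100.0 * ef / maxef,
        pct_maxEF_rounded=100.0 * ef_disp / maxef_disp,
        auc=auc,
        per_class_recovery=recovery,
    )


@dataclass(frozen=True)
class HitSelection:
    """Top-ranked hit ids per (method, screen target class)."""

    selections: tuple[tuple[str, str, tuple[str, ...], bool], ...]
    # each entry: (method, target_class, ids in rank order, shortfall flag)

    def ids(self, method: str, target_class: str) -> tuple[str, ...]:
        for m, c, ids, _ in self.selections:
            if m == method and c == target_class:
                return ids
        raise KeyError((method, target_class))

    def shortfall(self, method: str, target_class: str) -> bool:
        for m, c, _, flag in self.selections:
            if m == method and c == target_class:
                return flag
        raise KeyError((method, target_class))


def select_top_hits(
    results: Sequence[ScreeningResult],
    k_per_class: Mapping[str, int],
) -> HitSelection:
    """Select the top-k ranked hits of each screening run by its target class.

    Mirrors exemplary-hit selection: e.g. top-four from an agonist screen and
    top-two from an antagonist screen.  When fewer hits are available, all
    are returned with a shortfall flag.
    """
    entries = []
    for result in results:
        cls = result.target_class or "unknown"
        k = k_per_class.get(cls, 0)
        if k < 0:
            raise DomainError("selection size must be non-negative")
        ranked = result.hit_ids()
        selected = tuple(ranked[:k])
        entries.append((result.method, cls, selected, len(selected) < k))
    return HitSelection(selections=tuple(entries))
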