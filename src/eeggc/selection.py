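"""Electrode-pair selection from first-principal-component loadings.

The aligned group trajectory matrix (time offsets x pairs) of each category
is mean-centered by column and decomposed by SVD; PC1 loadings (the first
right singular vector, pairs as variables) rank the pairs by how strongly
they participate in the dominant mode of change around the responsiveness
transitions.  The loading sign is fixed so that loadings correlate positively
with each pair's absolute change magnitude across the event, making "large
loading = large change" well defined.

For Granger causality the four categories are delta/alpha x LOBR/ROBR (beta
changes are smaller and EMG-prone, so beta is excluded from pair selection);
pairs in the top 5% of loadings in at least three of the four categories form
the large-change set, and the bottom 5% rule gives the minimal-change set.
For coherence, pairs are first split by the sign of their change across the
event, PCA is run within each sign group per band, and a pair must be in the
top 5% for both the LOBR and ROBR transitions to be selected.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .trajectories import AlignedGroupTrajectory

__all__ = [
    "PairSelection", "pc1_loadings", "select_gc_pairs",
    "select_coherence_pairs", "GC_CATEGORIES",
]

logger = logging.getLogger(__name__)

GC_CATEGORIES = (("delta", "LOBR"), ("delta", "ROBR"),
                 ("alpha", "LOBR"), ("alpha", "ROBR"))
CHANGE_OFFSET_S = 120.0  # change scored value(+2 min) - value(-2 min)


@dataclass
class PairSelection:
    """A selected set of pairs plus the PCA bookkeeping behind it."""

    metric: str                       # "gc" | "coherence"
    rule: str                         # "top5" | "bottom5" | "coh_increase_top5" | ...
    pairs: frozenset
    variance_explained: dict = field(default_factory=dict)  # category -> fraction
    categories_used: tuple = ()
    band: str | None = None

    def __post_init__(self):
        for frac in self.variance_explained.values():
            if not 0.0 <= frac <= 1.0 + 1e-12:
                raise ValueError("variance fractions must lie in [0, 1]")


def pc1_loadings(matrix: np.ndarray, offsets: np.ndarray | None = None,
                 change_offset: float = CHANGE_OFFSET_S,
                 ) -> tuple[np.ndarray, float]:
    """PC1 loadings per pair (column) and the variance fraction it explains.

    Rows are time offsets, columns pairs; rows containing missing values are
    dropped before the decomposition.  The sign is fixed so that the largest
    loadings mark the pairs with the greatest change: each pair's change is
    scored as |value(+2 min) - value(-2 min)| across the event (offset 0) when
    ``offsets`` is given, last minus first retained row otherwise, and the
    orientation is chosen so the top-5%-loading pairs have the larger mean
    absolute change (a plain loadings/change correlation is ambiguous when
    many pairs drift slightly against few pairs changing strongly).
    """
    matrix = np.asarray(matrix, dtype=float)
    rows = np.isfinite(matrix).all(axis=1)
    m = matrix[rows]
    if m.shape[0] < 2:
        raise ValueError("need at least 2 complete time points for PCA")
    centered = m - m.mean(axis=0, keepdims=True)
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    loadings = vt[0]
    total = float((svals ** 2).sum())
    var_explained = float(svals[0] ** 2 / total) if total > 0 else 0.0
    if offsets is None:
        change = np.abs(m[-1] - m[0])
    else:
        kept = np.asarray(offsets, dtype=float)[rows]
        pre = int(np.argmin(np.abs(kept + change_offset)))
        post = int(np.argmin(np.abs(kept - change_offset)))
        change = np.abs(m[post] - m[pre])
    finite = np.isfinite(change)
    if finite.any():
        k = max(1, int(np.ceil(0.05 * loadings.size)))
        order = np.argsort(loadings)
        top_pos = np.nanmean(change[order[-k:]])
        top_neg = np.nanmean(change[order[:k]])
        if top_neg > top_pos:
            loadings = -loadings
        elif top_neg == top_pos and np.corrcoef(
                loadings[finite], change[finite])[0, 1] < 0:
            loadings = -loadings
    return loadings, var_explained


def _quantile_set(loadings: np.ndarray, quantile: float, top: bool) -> set[int]:
    """Pairs at/beyond the loading quantile; boundary ties are all included."""
    if top:
        thr = np.percentile(loadings, 100 * (1 - quantile))
        sel = np.flatnonzero(loadings >= thr)
    else:
        thr = np.percentile(loadings, 100 * quantile)
        sel = np.flatnonzero(loadings <= thr)
    if sel.size == 0:
        raise ValueError("quantile produced an empty selection")
    return set(sel.tolist())


def _category_matrix(groups: dict, band: str, event: str) -> AlignedGroupTrajectory:
    try:
        return groups[(band, event)]
    except KeyError as err:
        raise KeyError(f"missing aligned group curve for ({band}, {event})") from err


def select_gc_pairs(groups: dict[tuple[str, str], AlignedGroupTrajectory],
                    quantile: float = 0.05, min_common: int = 3,
                    categories=GC_CATEGORIES,
                    ) -> tuple[PairSelection, PairSelection]:
    """Top- and bottom-quantile GC pair sets common to >= min_common categories.

    ``groups`` maps (band, event) to the aligned group trajectory.  Returns
    (top, bottom) selections with per-category PC1 variance bookkeeping.
    """
    pairs = None
    tops: Counter = Counter()
    bots: Counter = Counter()
    var_explained = {}
    for band, event in categories:
        g = _category_matrix(groups, band, event)
        if pairs is None:
            pairs = g.pairs
        elif g.pairs != pairs:
            raise ValueError("categories must share the pair index")
        loadings, ve = pc1_loadings(g.curve, offsets=g.offsets)
        var_explained[f"{band}-{event}"] = ve
        tops.update(_quantile_set(loadings, quantile, top=True))
        bots.update(_quantile_set(loadings, quantile, top=False))
    top_idx = {i for i, c in tops.items() if c >= min_common}
    bot_idx = {i for i, c in bots.items() if c >= min_common}
    mk = lambda idx, rule: PairSelection(  # noqa: E731
        metric="gc", rule=rule,
        pairs=frozenset(pairs[i] for i in idx),
        variance_explained=dict(var_explained),
        categories_used=tuple(f"{b}-{e}" for b, e in categories),
    )
    return mk(top_idx, "top5"), mk(bot_idx, "bottom5")


def select_coherence_pairs(groups: dict[tuple[str, str], AlignedGroupTrajectory],
                           band: str, quantile: float = 0.05,
                           change_offset: float = CHANGE_OFFSET_S,
                           ) -> tuple[PairSelection, PairSelection]:
    """Coherence increase/decrease selections for one band.

    Pairs are split by the sign of value(+2 min) - value(-2 min) across LOBR;
    within each sign group, PC1 loadings are computed independently for the
    LOBR and ROBR curves and a pair must rank in the top quantile for both
    transitions.  Bands are treated independently by calling per band.
    Returns (increase, decrease); an empty sign group yields an empty
    selection (logged).
    """
    g_lobr = _category_matrix(groups, band, "LOBR")
    g_robr = _category_matrix(groups, band, "ROBR")
    if g_lobr.pairs != g_robr.pairs:
        raise ValueError("LOBR/ROBR curves must share the pair index")
    pairs = g_lobr.pairs
    delta_change = g_lobr.at_offset(change_offset) - g_lobr.at_offset(-change_offset)
    selections = []
    for rule, members in (("coh_increase_top5", delta_change > 0),
                          ("coh_decrease_top5", delta_change <= 0)):
        idx = np.flatnonzero(members & np.isfinite(delta_change))
        if idx.size == 0:
            logger.info("no pairs in sign group %s for band %s", rule, band)
            selections.append(PairSelection(
                metric="coherence", rule=rule, pairs=frozenset(), band=band,
                categories_used=(f"{band}-LOBR", f"{band}-ROBR"),
            ))
            continue
        common = None
        var_explained = {}
        for event, g in (("LOBR", g_lobr), ("ROBR", g_robr)):
            loadings, ve = pc1_loadings(g.curve[:, idx], offsets=g.offsets)
            var_explained[f"{band}-{event}"] = ve
            chosen = {int(idx[i]) for i in _quantile_set(loadings, quantile, top=True)}
            common = chosen if common is None else (common & chosen)
        selections.append(PairSelection(
            metric="coherence", rule=rule,
            pairs=frozenset(pairs[i] for i in common),
            variance_explained=var_explained, band=band,
            categories_used=(f"{band}-LOBR", f"{band}-ROBR"),
        ))
    return selections[0], selections[1]
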