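"""Target-decoy q-values and FDR filtering of PSM identifications.

The false discovery rate at a score threshold ``t`` is estimated from a
decoy database search as

    FDR(t) = #{decoys with score >= t} / #{targets with score >= t}

and the q-value of an item is the smallest FDR over all thresholds that
would still retain it, i.e. the running minimum of FDR along decreasing
score.  The estimator is the plain decoy/target ratio (no +1 correction).
Items sharing a score are handled as one threshold block, so every decoy
tied with a target counts against it — the conservative tie policy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Hashable, Sequence

from .psm_io import PsmRecord

__all__ = ["ScoredItem", "compute_qvalues", "filter_fdr", "filter_psms_fdr"]


@dataclass(frozen=True)
class ScoredItem:
    """A search hit entering FDR estimation; ``q_value`` is assigned later."""

    item_id: Hashable
    search_score: float
    is_decoy: bool
    q_value: float | None = None


def compute_qvalues(items: Sequence[ScoredItem]) -> list[ScoredItem]:
    """Assign target-decoy q-values; returns items in the input order.

    Decoy items also carry a q-value but stay flagged as decoys.  Raises on
    NaN scores or when no target item is present (the ratio would be
    undefined for every threshold).
    """
    if not any(not item.is_decoy for item in items):
        raise ValueError("compute_qvalues requires at least one target item")
    for item in items:
        if math.isnan(item.search_score) or math.isinf(item.search_score):
            raise ValueError(f"non-finite search score for item {item.item_id!r}")

    # Descending score; items sharing a score form one threshold block, so
    # FDR is only ever evaluated at complete thresholds (a tie between a
    # decoy and a target cannot split the ratio).
    order = sorted(range(len(items)), key=lambda i: -items[i].search_score)
    n_decoys = 0
    n_targets = 0
    fdr_at_position = [0.0] * len(order)
    block_start = 0
    for position, i in enumerate(order):
        if items[i].is_decoy:
            n_decoys += 1
        else:
            n_targets += 1
        last_of_block = (
            position + 1 == len(order)
            or items[order[position + 1]].search_score != items[i].search_score
        )
        if last_of_block:
            fdr = n_decoys / n_targets if n_targets else math.inf
            for p in range(block_start, position + 1):
                fdr_at_position[p] = min(fdr, 1.0)
            block_start = position + 1

    # q = running minimum of FDR over lower thresholds (later positions).
    qvalues = [0.0] * len(items)
    running = 1.0
    for position in range(len(order) - 1, -1, -1):
        running = min(running, fdr_at_position[position])
        qvalues[order[position]] = running

    return [replace(item, q_value=q) for item, q in zip(items, qvalues)]


def filter_fdr(items: Sequence[ScoredItem], alpha: float) -> list[ScoredItem]:
    """Return target items with q-value <= alpha; decoys are always removed."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    retained = []
    for item in items:
        if item.is_decoy:
            continue
        if item.q_value is None:
            raise ValueError(f"item {item.item_id!r} has no q-value assigned")
        if item.q_value <= alpha:
            retained.append(item)
    return retained


def filter_psms_fdr(
    psms: Sequence[PsmRecord], alpha: float
) -> tuple[list[PsmRecord], dict]:
    """FDR-filter a PSM table; returns retained targets and stage counts.

    Convenience wrapper applying :func:`compute_qvalues` and
    :func:`filter_fdr` to :class:`~cosecretome.psm_io.PsmRecord` lists.
    Empty input yields an empty output.
    """
    if not psms:
        return [], {"n_input": 0, "n_decoys": 0, "n_retained": 0}
    items = [
        ScoredItem(item_id=i, search_score=p.search_score, is_decoy=p.is_decoy)
        for i, p in enumerate(psms)
    ]
    retained_items = filter_fdr(compute_qvalues(items), alpha)
    retained = [psms[item.item_id] for item in retained_items]
    stats = {
        "n_input": len(psms),
        "n_decoys": sum(p.is_decoy for p in psms),
        "n_retained": len(retained),
    }
    return retained, stats
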