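"""Stability-time decision rule for molecular-dynamics-profiled triplexes.

The pipeline does not run molecular dynamics; it ingests stability-time
summaries (picoseconds a strand stayed hydrogen-bonded during a production
run) and applies the selection rule: the triplex must hold both miRNAs for
at least ``threshold_ps`` (default 100 ps) and at least one miRNA must be
held longer in the triplex than in its own duplex.

Two variants of the duplex comparison exist in the literature the rule
derives from; the per-miRNA comparison (``caption``) is the default because
it is the one consistent with the published pass/fail outcomes, while the
``equation`` variant compares against the smaller duplex time only.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping

from .io_model import StabilityRecord

DEFAULT_THRESHOLD_PS = 100.0

RULES = ("caption", "equation")


def triplex_stability_time(record: StabilityRecord) -> float:
    """Duration (ps) for which *both* miRNAs stayed attached: min(t1, t2)."""
    return min(record.t1, record.t2)


def stability_pass(
    record: StabilityRecord,
    threshold_ps: float = DEFAULT_THRESHOLD_PS,
    rule: str = "caption",
) -> bool:
    """True when the triplex holds both miRNAs for at least ``threshold_ps``
    (inclusive) and the triplex improves on the duplex stability.

    ``caption`` rule: some miRNA is held longer in the triplex than in its
    corresponding duplex (t1 > d1 or t2 > d2).  ``equation`` rule: the joint
    triplex time exceeds the smaller duplex time (min(t1,t2) > min(d1,d2)).
    """
    if rule not in RULES:
        raise ValueError(f"unknown stability rule: {rule!r}")
    st = triplex_stability_time(record)
    if st < threshold_ps:
        return False
    if rule == "caption":
        return record.t1 > record.d1 or record.t2 > record.d2
    return st > min(record.d1, record.d2)


def group_pass_counts(
    records: Iterable[StabilityRecord],
    threshold_ps: float = DEFAULT_THRESHOLD_PS,
    rule: str = "caption",
) -> dict:
    """Per-group count of records passing :func:`stability_pass`."""
    counts: Counter[str] = Counter()
    for rec in records:
        counts.setdefault(rec.group_label, 0)
        if stability_pass(rec, threshold_ps=threshold_ps, rule=rule):
            counts[rec.group_label] += 1
    return dict(counts)


def stability_verdicts(
    records: Iterable[StabilityRecord],
    threshold_ps: float = DEFAULT_THRESHOLD_PS,
    rule: str = "caption",
) -> dict:
    """(gene, miRNA1, miRNA2) -> pass/fail mapping, for pipeline joins."""
    return {
        (r.gene_id, r.mirna1_id, r.mirna2_id): stability_pass(
            r, threshold_ps=threshold_ps, rule=rule
        )
        for r in records
    }
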