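"""Target-site filtering and pairing into triplex candidates.

Two miRNAs can cooperate on a mutual target when their seed matches sit
13-35 nt apart in the 3' UTR; site pairs inside that window are promoted to
:class:`~triplexkit.io_model.TriplexCandidate` objects carrying the UTR
subsequence that encloses both sites.
"""

from __future__ import annotations

import math
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

from .io_model import (
    CoordinateError,
    OrderingError,
    TargetSite,
    TriplexCandidate,
)

#: Cooperativity window on the seed-to-seed spacing, inclusive at both ends.
DEFAULT_D_MIN = 13
DEFAULT_D_MAX = 35

#: Keep sites with mirSVR score at or below this (more negative = better).
DEFAULT_MIRSVR_MAX = -0.1

SEED_DISTANCE_METRICS = ("gap", "start_to_start")


def filter_sites(
    sites: Iterable[TargetSite],
    mirsvr_max: float = DEFAULT_MIRSVR_MAX,
    conserved_only: bool = True,
    mirna_conservation: Mapping[str, bool] | None = None,
) -> list[TargetSite]:
    """Keep sites with ``mirsvr <= mirsvr_max`` and, when ``conserved_only``,
    whose miRNA is flagged conserved.

    ``mirna_conservation`` maps miRNA id -> conserved flag; miRNAs absent from
    the mapping are treated as conserved (the upstream predictor's tables are
    typically already restricted to conserved miRNAs).
    """
    cons = mirna_conservation or {}
    kept = []
    for site in sites:
        if site.mirsvr > mirsvr_max:
            continue
        if conserved_only and not cons.get(site.mirna_id, True):
            continue
        kept.append(site)
    return kept


def seed_distance(a: TargetSite, b: TargetSite, metric: str = "gap") -> int:
    """Spacing between the seed matches of two sites on the same transcript.

    ``gap`` (default) counts the nucleotides strictly between the two seed
    matches: ``b.seed_start - a.seed_end - 1``.  ``start_to_start`` returns
    ``b.seed_start - a.seed_start``.  The caller orders the sites; overlapping
    or mis-ordered seeds raise :class:`OrderingError`.
    """
    if metric not in SEED_DISTANCE_METRICS:
        raise ValueError(f"unknown seed-distance metric: {metric!r}")
    if a.transcript_id != b.transcript_id:
        raise OrderingError(
            f"sites on different transcripts: {a.transcript_id} vs {b.transcript_id}"
        )
    if a.seed_end >= b.seed_start:
        raise OrderingError(
            f"seeds overlap or are mis-ordered: upstream ends at {a.seed_end}, "
            f"downstream starts at {b.seed_start}"
        )
    if metric == "start_to_start":
        return b.seed_start - a.seed_start
    return b.seed_start - a.seed_end - 1


def extract_window(
    utr_seq: str,
    a: TargetSite,
    b: TargetSite,
    flank: int = 0,
) -> tuple[str, int]:
    """UTR subsequence enclosing both sites, plus its 1-based UTR offset.

    The window spans ``min(site starts) - flank .. max(site ends) + flank``,
    clipped to the UTR.  A site interval outside the UTR raises
    :class:`CoordinateError`.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    lo_1 = min(a.site_start, b.site_start)
    hi_1 = max(a.site_end, b.site_end)
    if lo_1 < 1 or hi_1 > len(utr_seq):
        raise CoordinateError(
            f"site interval [{lo_1},{hi_1}] outside UTR of length {len(utr_seq)}"
        )
    lo_1 = max(1, lo_1 - flank)
    hi_1 = min(len(utr_seq), hi_1 + flank)
    return utr_seq[lo_1 - 1 : hi_1], lo_1


def pair_sites(
    sites_per_transcript: Mapping[str, Sequence[TargetSite]],
    utr_seqs: Mapping[str, str],
    d_min: int = DEFAULT_D_MIN,
    d_max: int = DEFAULT_D_MAX,
    metric: str = "gap",
    flank: int = 0,
) -> list[TriplexCandidate]:
    """Every ordered site pair whose seed distance lies in ``[d_min, d_max]``
    (both ends inclusive) becomes one candidate.

    Pairs of sites for the same miRNA (homotypic triplexes) are allowed.
    Sites whose seed matches overlap are never paired.  Output order is
    deterministic: transcripts in sorted order, pairs by (upstream seed start,
    downstream seed start).
    """
    candidates: list[TriplexCandidate] = []
    for transcript_id in sorted(sites_per_transcript):
        sites = sorted(
            sites_per_transcript[transcript_id],
            key=lambda s: (s.seed_start, s.seed_end, s.mirna_id),
        )
        utr = utr_seqs.get(transcript_id)
        if utr is None:
            raise CoordinateError(f"no UTR sequence for transcript {transcript_id}")
        for i, a in enumerate(sites):
            for b in sites[i + 1 :]:
                if a.seed_end >= b.seed_start:
                    continue  # overlapping seeds cannot cooperate
                d = seed_distance(a, b, metric=metric)
                if not d_min <= d <= d_max:
                    continue
                window, offset = extract_window(utr, a, b, flank=flank)
                candidates.append(
                    TriplexCandidate(
                        gene_id=a.gene_id,
                        transcript_id=transcript_id,
                        upstream_site=a,
                        downstream_site=b,
                        seed_distance=d,
                        window_seq=window,
                        window_offset=offset,
                    )
                )
    return candidates


def group_sites_by_transcript(
    sites: Iterable[TargetSite],
) -> dict[str, list[TargetSite]]:
    grouped: dict[str, list[TargetSite]] = defaultdict(list)
    for site in sites:
        grouped[site.transcript_id].append(site)
    return dict(grouped)
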