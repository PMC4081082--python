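"""Self-contained test inputs with known ground truth.

:func:`generate_toy_dataset` builds UTR sequences with planted triplexes —
two miRNAs whose seed complements (nucleotides 2-8, reverse-complemented
into the UTR) sit at a requested seed distance — together with the matching
target-site table and a truth table.  Background sequence is uniform over
{A, C, G, U} with rejection sampling so that no accidental seed complement
of a planted miRNA appears inside the pairing window of a planted site.

:func:`load_fixture` returns the bundled reference tables: the twelve
extreme-energy triplex candidates selected for molecular-dynamics profiling
("table1") and the stability times of their complexes plus the validated
CDKN1A control ("table2").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .io_model import (
    InputError,
    MiRNA,
    StabilityRecord,
    TargetSite,
    write_fasta,
    write_site_table,
)

_COMPLEMENT = str.maketrans("ACGU", "UGCA")

#: mirSVR score assigned to planted sites; passes the -0.1 filter.
PLANTED_MIRSVR = -0.5
PLANTED_PHASTCONS = 0.9

SEED_LEN = 7  # miRNA nucleotides 2-8
MAX_SUPPLEMENTARY = 12  # 3'-end nucleotides that complementarity_level scales


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ToyDataset:
    utrs: list  # (transcript_id, sequence)
    mirnas: list  # MiRNA
    sites: list  # TargetSite
    truth: list  # dict per planted triplex

    def utr_map(self) -> dict:
        return dict(self.utrs)

    def mirna_map(self) -> dict:
        return {m.id: m for m in self.mirnas}

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.utrs, out / "utrs.fasta")
        write_fasta([(m.id, m.sequence) for m in self.mirnas], out / "mirnas.fasta")
        write_site_table(self.sites, out / "sites.tsv")
        pd.DataFrame(self.truth).to_csv(out / "truth.tsv", sep="\t", index=False)


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))


def generate_toy_dataset(
    n_genes: int = 4,
    utr_len: int = 300,
    mirna_pool_size: int = 6,
    planted_triplexes: list | None = None,
    rng_seed: int = 0,
    mirsvr: float = PLANTED_MIRSVR,
    phastcons: float = PLANTED_PHASTCONS,
    max_resample: int = 200,
) -> ToyDataset:
    """Generate UTRs, miRNAs, a site table and a truth table.

    ``planted_triplexes`` is a list of ``(seed_distance, complementarity_level)``
    tuples, one per planted triplex, assigned to genes in order (one triplex
    per gene; genes beyond the list carry background sequence only).
    ``complementarity_level`` in [0, 1] scales how many 3'-end miRNA
    nucleotides beyond the seed are complementary to the site.

    Raises :class:`InputError` when the UTR is too short to host a planted
    pair of sites (overcrowded UTR).
    """
    if planted_triplexes is None:
        planted_triplexes = [(20, 1.0)]
    if len(planted_triplexes) > n_genes:
        raise InputError(
            f"{len(planted_triplexes)} planted triplexes need at least as many genes"
        )
    for d, level in planted_triplexes:
        if d < 0:
            raise InputError("planted seed distance must be >= 0")
        if not 0.0 <= level <= 1.0:
            raise InputError("complementarity_level must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)

    mirnas = [
        MiRNA(id=f"syn-miR-{k+1}", sequence=_random_rna(rng, 22), conserved=True)
        for k in range(mirna_pool_size)
    ]

    utrs: list[tuple[str, str]] = []
    sites: list[TargetSite] = []
    truth: list[dict] = []

    for g in range(n_genes):
        gene_id = f"GENE{g+1}"
        transcript_id = f"TX{g+1}"
        if g >= len(planted_triplexes):
            utrs.append((transcript_id, _random_rna(rng, utr_len)))
            continue
        d, level = planted_triplexes[g]
        idx = rng.choice(len(mirnas), size=2, replace=False)
        mir1, mir2 = mirnas[int(idx[0])], mirnas[int(idx[1])]

        extra = int(round(level * MAX_SUPPLEMENTARY))
        # upstream miRNA: 3' supplementary pairing extends 5'-ward on the UTR
        len1 = SEED_LEN + extra
        # downstream miRNA: the extension reaches into the inter-site gap
        len2 = SEED_LEN + min(extra, d)
        site1_seq = revcomp(mir1.sequence[1 : 1 + len1])
        site2_seq = revcomp(mir2.sequence[1 : 1 + len2])

        needed = len1 + d + len2
        margin = 10
        if needed + 2 * margin > utr_len:
            raise InputError(
                f"UTR of length {utr_len} too short for planted sites "
                f"needing {needed + 2 * margin} nt (overcrowded UTR)"
            )
        a1_0 = int(rng.integers(margin, utr_len - needed - margin + 1))
        b1_0 = a1_0 + len1 - 1  # seed match of miR1 ends here (0-based)
        a2_0 = b1_0 + 1 + d - (len2 - SEED_LEN)
        b2_0 = a2_0 + len2 - 1

        for attempt in range(max_resample):
            seq = list(_random_rna(rng, utr_len))
            seq[a1_0 : b1_0 + 1] = site1_seq
            seq[a2_0 : b2_0 + 1] = site2_seq
            utr = "".join(seq)
            if not _accidental_seed_match(
                utr, (mir1, mir2), window=(a1_0, b2_0), planted=((a1_0, b1_0), (a2_0, b2_0))
            ):
                break
        else:
            raise InputError(
                "could not place planted sites without accidental seed matches"
            )
        utrs.append((transcript_id, utr))

        site1 = TargetSite(
            gene_id=gene_id,
            transcript_id=transcript_id,
            mirna_id=mir1.id,
            site_start=a1_0 + 1,
            site_end=b1_0 + 1,
            seed_start=b1_0 + 1 - SEED_LEN + 1,
            seed_end=b1_0 + 1,
            mirsvr=mirsvr,
            phastcons=phastcons,
        )
        site2 = TargetSite(
            gene_id=gene_id,
            transcript_id=transcript_id,
            mirna_id=mir2.id,
            site_start=a2_0 + 1,
            site_end=b2_0 + 1,
            seed_start=b2_0 + 1 - SEED_LEN + 1,
            seed_end=b2_0 + 1,
            mirsvr=mirsvr,
            phastcons=phastcons,
        )
        sites.extend([site1, site2])
        truth.append(
            {
                "gene_id": gene_id,
                "transcript_id": transcript_id,
                "mirna1_id": mir1.id,
                "mirna2_id": mir2.id,
                "seed_distance": d,
                "complementarity_level": level,
                "site1_start": site1.site_start,
                "site1_end": site1.site_end,
                "site2_start": site2.site_start,
                "site2_end": site2.site_end,
            }
        )
    return ToyDataset(utrs=utrs, mirnas=mirnas, sites=sites, truth=truth)


def _accidental_seed_match(
    utr: str,
    mirnas,
    window: tuple[int, int],
    planted,
    margin: int = 25,
) -> bool:
    """True when a planted miRNA's seed complement occurs in the pairing
    window at a position other than its planted seed match."""
    lo = max(0, window[0] - margin)
    hi = min(len(utr), window[1] + 1 + margin)
    region = utr[lo:hi]
    planted_seed_starts = {
        (m.id, b - SEED_LEN + 1) for m, (a, b) in zip(mirnas, planted)
    }
    for m in mirnas:
        seed_rc = revcomp(m.sequence[1 : 1 + SEED_LEN])
        start = 0
        while True:
            k = region.find(seed_rc, start)
            if k < 0:
                break
            pos0 = lo + k
            if (m.id, pos0) not in planted_seed_starts:
                return True
            start = k + 1
    return False


# ---------------------------------------------------------------------------
# Bundled reference tables
# ---------------------------------------------------------------------------

FIXTURE_ALIASES = {
    "table1": "table1_mds_candidates.tsv",
    "mds_candidates": "table1_mds_candidates.tsv",
    "table2": "table2_stability_times.tsv",
    "stability_times": "table2_stability_times.tsv",
}


def load_fixture(name: str):
    """Return a bundled reference table.

    ``"table1"`` / ``"mds_candidates"``: the twelve extreme-energy triplex
    candidates (3x low and 3x high triplex free energy, 3x strong and 3x weak
    free-energy gain) as dicts with gene, miRNA pair, ``dG_triplex``, ``ddG``,
    the back-computed ``dG_duplex_min`` and a ``group_label``.

    ``"table2"`` / ``"stability_times"``: molecular-dynamics stability times
    (ps) of those candidates' duplexes and triplexes plus the validated
    CDKN1A control, as :class:`StabilityRecord` objects.
    """
    if name not in FIXTURE_ALIASES:
        raise KeyError(f"unknown fixture {name!r}; options: {sorted(FIXTURE_ALIASES)}")
    fname = FIXTURE_ALIASES[name]
    path = resources.files("triplexkit") / "data" / fname
    with path.open() as fh:
        df = pd.read_csv(fh, sep="\t")
    if fname.startswith("table2"):
        return [
            StabilityRecord(
                gene_id=r.gene_id,
                mirna1_id=r.mirna1_id,
                mirna2_id=r.mirna2_id,
                d1=float(r.d1_ps),
                d2=float(r.d2_ps),
                t1=float(r.t1_ps),
                t2=float(r.t2_ps),
                group_label=r.group_label,
            )
            for r in df.itertuples(index=False)
        ]
    records = df.to_dict(orient="records")
    for rec in records:
        rec["dG_duplex_min"] = round(rec["dG_triplex"] - rec["ddG"], 6)
    return records
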