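"""Multi-strand RNA secondary-structure MFE prediction and triplex filters.

The engine is a reduced nearest-neighbor model: Watson-Crick plus G.U wobble
pairs, a helix stacking table, and affine + logarithmic loop penalties
(parameters packaged under ``triplexkit/data/``).  Up to three strands are
folded over their concatenation with nick-aware loop rules: a loop that
contains a strand nick is exterior-like — it carries no penalty and is exempt
from the minimum hairpin size.  Pseudoknots are excluded.  Unstructured
single strands are the zero point of the energy scale, so the free energy of
a complex never exceeds 0 and adding a strand never raises the MFE.

Two independent routes compute energies: :func:`mfe_complex` (dynamic
program) and :func:`enumerate_structures` (exhaustive listing scored by
:func:`score_structure`, the definition of the model).  Their agreement on
random instances is the engine's correctness test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from statistics import mean, stdev
from typing import Iterable, Iterator, Sequence

from .io_model import (
    CoordinateError,
    InputError,
    MiRNA,
    ParseError,
    TriplexCandidate,
    normalize_rna,
)

#: Gas constant, kcal/(mol K).
R_KCAL = 1.9872e-3

INF = float("inf")

WC_AND_WOBBLE = frozenset(
    [("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")]
)


# ---------------------------------------------------------------------------
# Energy model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnergyModel:
    """Thermodynamic parameters of the reduced nearest-neighbor model."""

    stacks: dict  # (pair1, pair2) -> kcal/mol, keys like ("GC", "GC")
    hairpin_base: float
    hairpin_log: float
    bulge_base: float
    bulge_log: float
    internal_base: float
    internal_log: float
    internal_asym: float
    asym_max: float
    ml_base: float
    ml_branch: float
    ml_unpaired: float
    max_loop: int
    hairpin_min: int
    temperature: float = 310.15

    @staticmethod
    def load(temperature: float = 310.15) -> "EnergyModel":
        """Load the packaged parameter tables."""
        data = resources.files("triplexkit") / "data"
        stacks: dict[tuple[str, str], float] = {}
        with (data / "stack_energies.tsv").open() as fh:
            header_seen = False
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if not header_seen:
                    header_seen = True  # column header row
                    continue
                p1, p2, dg = line.split("\t")
                for key in ((p1, p2), (p2[::-1], p1[::-1])):
                    val = float(dg)
                    if key in stacks and abs(stacks[key] - val) > 1e-9:
                        raise ParseError(
                            f"stack table symmetry conflict for {key}"
                        )
                    stacks[key] = val
        params: dict[str, float] = {}
        with (data / "loop_params.tsv").open() as fh:
            header_seen = False
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if not header_seen:
                    header_seen = True
                    continue
                name, value = line.split("\t")
                params[name] = float(value)
        return EnergyModel(
            stacks=stacks,
            hairpin_base=params["hairpin_base"],
            hairpin_log=params["hairpin_log"],
            bulge_base=params["bulge_base"],
            bulge_log=params["bulge_log"],
            internal_base=params["internal_base"],
            internal_log=params["internal_log"],
            internal_asym=params["internal_asym"],
            asym_max=params["asym_max"],
            ml_base=params["ml_base"],
            ml_branch=params["ml_branch"],
            ml_unpaired=params["ml_unpaired"],
            max_loop=int(params["max_loop"]),
            hairpin_min=int(params["hairpin_min"]),
            temperature=temperature,
        )

    def pairable(self, x: str, y: str) -> bool:
        return (x, y) in WC_AND_WOBBLE

    def stack_energy(self, outer: str, inner: str) -> float:
        """Stack of inner pair on outer pair; pairs as 2-character strings."""
        return self.stacks[(outer, inner)]

    def hairpin_energy(self, n: int) -> float:
        if n < self.hairpin_min:
            return INF
        return self.hairpin_base + self.hairpin_log * math.log(n / self.hairpin_min)

    def bulge_energy(self, n: int) -> float:
        if n > self.max_loop:
            return INF
        return self.bulge_base + self.bulge_log * math.log(n)

    def internal_energy(self, n1: int, n2: int) -> float:
        if n1 + n2 > self.max_loop:
            return INF
        return (
            self.internal_base
            + self.internal_log * math.log((n1 + n2) / 2)
            + min(self.asym_max, self.internal_asym * abs(n1 - n2))
        )

    def loop_energy(self, n1: int, n2: int) -> float:
        """Energy of the 1-child loop with gap sizes n1, n2 (no nick)."""
        if n1 == 0 and n2 == 0:
            raise ValueError("stacks are scored from the stack table")
        if n1 == 0 or n2 == 0:
            return self.bulge_energy(n1 + n2)
        return self.internal_energy(n1, n2)


_DEFAULT_MODEL: EnergyModel | None = None


def default_model() -> EnergyModel:
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        _DEFAULT_MODEL = EnergyModel.load()
    return _DEFAULT_MODEL


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

class Conformation(str, Enum):
    CANONICAL_TRIPLEX = "canonical_triplex"
    DUPLEX_PLUS_FREE_MIRNA = "duplex_plus_free_mirna"
    MIRNA_MIRNA_HYBRID = "mirna_mirna_hybrid"
    OTHER = "other"


@dataclass(frozen=True)
class ComplexStructure:
    """A multi-strand secondary structure: strand order, pair map over the
    concatenation, dot-bracket with ``&`` strand separators, and its free
    energy ``dG`` (kcal/mol)."""

    strand_ids: tuple[str, ...]
    strands: tuple[str, ...]
    pairs: frozenset
    dG: float

    @property
    def strand_offsets(self) -> tuple[int, ...]:
        offs, total = [], 0
        for s in self.strands:
            offs.append(total)
            total += len(s)
        return tuple(offs)

    def strand_of(self, pos: int) -> int:
        offs = self.strand_offsets
        for k in range(len(offs) - 1, -1, -1):
            if pos >= offs[k]:
                return k
        raise IndexError(pos)

    @property
    def dot_bracket(self) -> str:
        return pairs_to_dotbracket(self.pairs, [len(s) for s in self.strands])

    def partner(self) -> dict:
        out = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out


def pairs_to_dotbracket(pairs: Iterable[tuple[int, int]], strand_lengths: Sequence[int]) -> str:
    n = sum(strand_lengths)
    chars = ["."] * n
    for i, j in pairs:
        chars[i], chars[j] = "(", ")"
    parts, pos = [], 0
    for L in strand_lengths:
        parts.append("".join(chars[pos : pos + L]))
        pos += L
    return "&".join(parts)


def dotbracket_to_pairs(db: str) -> tuple[frozenset, list[int]]:
    """Parse an ``&``-separated dot-bracket string into (pairs, strand lengths)."""
    strand_lengths = [len(p) for p in db.split("&")]
    stack: list[int] = []
    pairs = set()
    pos = 0
    for ch in db:
        if ch == "&":
            continue
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise ParseError("unbalanced dot-bracket string")
            pairs.add((stack.pop(), pos))
        elif ch != ".":
            raise ParseError(f"invalid dot-bracket symbol {ch!r}")
        pos += 1
    if stack:
        raise ParseError("unbalanced dot-bracket string")
    return frozenset(pairs), strand_lengths


# ---------------------------------------------------------------------------
# Scoring (the definition of the model)
# ---------------------------------------------------------------------------

def _concat(strands: Sequence[str]) -> tuple[str, list[bool], list[int]]:
    """Concatenate strands; return (sequence, nick_after flags, nick cumsum).

    ``nick_after[p]`` is True when a strand boundary lies between positions
    p and p+1.  ``nickcum[t]`` counts nick boundaries with index < t, so the
    boundary range [a, b-1] is nick-free iff nickcum[b] == nickcum[a].
    """
    seq = "".join(strands)
    n = len(seq)
    nick_after = [False] * max(n - 1, 0)
    pos = 0
    for s in strands[:-1]:
        pos += len(s)
        nick_after[pos - 1] = True
    nickcum = [0] * (n + 1)
    for p in range(n - 1):
        nickcum[p + 1] = nickcum[p] + (1 if nick_after[p] else 0)
    if n >= 1:
        nickcum[n] = nickcum[n - 1]
    return seq, nick_after, nickcum


def score_structure(
    strands: Sequence[str],
    pairs: Iterable[tuple[int, int]],
    model: EnergyModel | None = None,
) -> float:
    """Free energy of a given structure under the loop decomposition rules.

    Returns ``inf`` for structures the model disallows (hairpin loop smaller
    than the minimum without a nick, internal/bulge loop above ``max_loop``).
    Raises :class:`InputError` for structures that are not a valid
    non-pseudoknotted matching of pairable bases.
    """
    model = model or default_model()
    seq, nick_after, _ = _concat(strands)
    n = len(seq)
    plist = sorted((min(i, j), max(i, j)) for (i, j) in pairs)
    seen: set[int] = set()
    for i, j in plist:
        if i == j or not (0 <= i < j < n):
            raise InputError(f"invalid pair ({i},{j})")
        if i in seen or j in seen:
            raise InputError("position in more than one pair")
        seen.update((i, j))
        if not model.pairable(seq[i], seq[j]):
            raise InputError(f"bases {seq[i]}{seq[j]} at ({i},{j}) cannot pair")
    for a in range(len(plist)):
        i, j = plist[a]
        for b in range(a + 1, len(plist)):
            k, l = plist[b]
            if k > j:
                break
            if k < j < l:  # i < k by sort order
                raise InputError(f"pseudoknot: ({i},{j}) crosses ({k},{l})")

    # parent/children via a stack over the sorted pair list
    children: dict[tuple[int, int] | None, list[tuple[int, int]]] = {None: []}
    stack: list[tuple[int, int]] = []
    for p in plist:
        children[p] = []
        while stack and stack[-1][1] < p[0]:
            stack.pop()
        parent = stack[-1] if stack else None
        children[parent].append(p)
        stack.append(p)

    total = 0.0
    for (i, j) in plist:
        kids = children[(i, j)]
        inside = set(range(i, j))  # boundary indices within [i, j-1]
        for (a, b) in kids:
            inside -= set(range(a, b))
        nick_in_loop = any(nick_after[q] for q in inside)
        if nick_in_loop:
            continue  # exterior-like loop: no penalty
        if not kids:
            e = model.hairpin_energy(j - i - 1)
        elif len(kids) == 1:
            (a, b) = kids[0]
            n1, n2 = a - i - 1, j - b - 1
            if n1 == 0 and n2 == 0:
                e = model.stack_energy(seq[i] + seq[j], seq[a] + seq[b])
            else:
                e = model.loop_energy(n1, n2)
        else:
            covered = set()
            for (a, b) in kids:
                covered.update(range(a, b + 1))
            unpaired = sum(
                1 for q in range(i + 1, j) if q not in covered
            )
            e = (
                model.ml_base
                + model.ml_branch * (len(kids) + 1)
                + model.ml_unpaired * unpaired
            )
        if e == INF:
            return INF
        total += e
    return total


# ---------------------------------------------------------------------------
# Enumeration oracle
# ---------------------------------------------------------------------------

def enumerate_structures(
    strands: Sequence[str],
    model: EnergyModel | None = None,
    max_total_len: int = 30,
) -> Iterator[tuple[frozenset, float]]:
    """Yield every valid non-pseudoknotted matching with its energy.

    Structures the model disallows (infinite energy) are not yielded.
    Refuses inputs with total length above ``max_total_len``.
    """
    model = model or default_model()
    strands = tuple(normalize_rna(s) for s in strands)
    seq, nick_after, nickcum = _concat(strands)
    n = len(seq)
    if n > max_total_len:
        raise InputError(
            f"total length {n} exceeds the enumeration cap {max_total_len}"
        )

    def gen(i: int, j: int) -> Iterator[frozenset]:
        if i > j:
            yield frozenset()
            return
        for rest in gen(i + 1, j):
            yield rest
        for k in range(i + 1, j + 1):
            if not model.pairable(seq[i], seq[k]):
                continue
            has_nick = nickcum[k] > nickcum[i]
            if k - i - 1 < model.hairpin_min and not has_nick:
                continue  # cannot close any legal loop
            for inner in gen(i + 1, k - 1):
                for outer in gen(k + 1, j):
                    yield frozenset({(i, k)}) | inner | outer

    for pairs in gen(0, n - 1):
        e = score_structure(strands, pairs, model)
        if e < INF:
            yield pairs, e


# ---------------------------------------------------------------------------
# MFE dynamic program
# ---------------------------------------------------------------------------

class _Folder:
    """Nick-aware MFE over the strand concatenation.

    Tables:
      V[i][j]   best energy with (i, j) paired
      WX[i][j]  exterior-like region (no loop charges)
      M0[i][j]  multiloop interior filling, >= 0 branches
      M1[i][j]  multiloop interior filling, >= 1 branch
    A loop containing a strand nick is handled by the ``nick loop`` case of V,
    whose contents are exterior-like.
    """

    def __init__(self, strands: Sequence[str], model: EnergyModel):
        self.model = model
        self.strands = tuple(strands)
        self.seq, self.nick_after, self.nickcum = _concat(strands)
        self.n = len(self.seq)
        self.nicks = [p for p in range(self.n - 1) if self.nick_after[p]]

    def nickfree(self, a: int, b: int) -> bool:
        """No nick in boundary range [a, b-1]."""
        if b <= a:
            return True
        return self.nickcum[b] == self.nickcum[a]

    def fold(self) -> tuple[float, frozenset]:
        n, seq, m = self.n, self.seq, self.model
        if n == 0:
            return 0.0, frozenset()
        pairable = [[False] * n for _ in range(n)]
        for i in range(n):
            for j in range(i + 1, n):
                pairable[i][j] = m.pairable(seq[i], seq[j])
        V = [[INF] * n for _ in range(n)]
        WX = [[0.0] * n for _ in range(n)]
        M0 = [[INF] * n for _ in range(n)]
        M1 = [[INF] * n for _ in range(n)]
        maxloop = m.max_loop
        mlb, mlc = m.ml_branch, m.ml_unpaired
        for i in range(n):
            M0[i][i] = mlc  # single unpaired base inside a multiloop

        for span in range(1, n):
            for i in range(0, n - span):
                j = i + span
                # ---- V ----
                if pairable[i][j]:
                    best = INF
                    # hairpin
                    if self.nickfree(i, j):
                        best = m.hairpin_energy(j - i - 1)
                    # stack
                    if (
                        j - i >= 2
                        and pairable[i + 1][j - 1]
                        and not self.nick_after[i]
                        and not self.nick_after[j - 1]
                    ):
                        e = (
                            m.stack_energy(seq[i] + seq[j], seq[i + 1] + seq[j - 1])
                            + V[i + 1][j - 1]
                        )
                        if e < best:
                            best = e
                    # internal / bulge
                    for k in range(i + 1, min(i + 2 + maxloop, j)):
                        n1 = k - i - 1
                        if not self.nickfree(i, k):
                            break
                        lmin = max(k + 1, j - 1 - (maxloop - n1))
                        for l in range(j - 1, lmin - 1, -1):
                            n2 = j - l - 1
                            if n1 == 0 and n2 == 0:
                                continue
                            if not pairable[k][l] or V[k][l] == INF:
                                continue
                            if not self.nickfree(l, j):
                                continue
                            e = m.loop_energy(n1, n2) + V[k][l]
                            if e < best:
                                best = e
                    # multiloop
                    if (
                        j - i >= 4
                        and not self.nick_after[i]
                        and not self.nick_after[j - 1]
                    ):
                        base = m.ml_base + mlb
                        for k in range(i + 1, j - 1):
                            if self.nick_after[k]:
                                continue
                            left, right = M1[i + 1][k], M1[k + 1][j - 1]
                            if left == INF or right == INF:
                                continue
                            e = base + left + right
                            if e < best:
                                best = e
                    # nick loop
                    for p in self.nicks:
                        if p < i or p >= j:
                            continue
                        left = WX[i + 1][p] if i + 1 <= p else 0.0
                        right = WX[p + 1][j - 1] if p + 1 <= j - 1 else 0.0
                        e = left + right
                        if e < best:
                            best = e
                    V[i][j] = best

                # ---- M0 / M1 ----
                best0 = best1 = INF
                if not self.nick_after[i]:
                    t = M0[i + 1][j] if i + 1 <= j else 0.0
                    if t < INF:
                        best0 = min(best0, mlc + t)
                    t1 = M1[i + 1][j] if i + 1 <= j else INF
                    if t1 < INF:
                        best1 = min(best1, mlc + t1)
                for k in range(i + 1, j + 1):
                    if V[i][k] == INF:
                        continue
                    if k == j:
                        tail = 0.0
                    elif self.nick_after[k]:
                        continue
                    else:
                        tail = M0[k + 1][j]
                        if tail == INF:
                            continue
                    e = V[i][k] + mlb + tail
                    if e < best0:
                        best0 = e
                    if e < best1:
                        best1 = e
                M0[i][j] = best0
                M1[i][j] = best1

                # ---- WX ----
                best = WX[i + 1][j] if i + 1 <= j else 0.0
                for k in range(i + 1, j + 1):
                    if V[i][k] == INF:
                        continue
                    tail = WX[k + 1][j] if k + 1 <= j else 0.0
                    e = V[i][k] + tail
                    if e < best:
                        best = e
                WX[i][j] = best

        self.V, self.WX, self.M0, self.M1 = V, WX, M0, M1
        mfe = WX[0][n - 1] if n >= 1 else 0.0
        pairs = self._traceback()
        return mfe, frozenset(pairs)

    # -- traceback ---------------------------------------------------------

    def _traceback(self) -> set:
        n = self.n
        pairs: set[tuple[int, int]] = set()
        if n == 0:
            return pairs
        agenda = [("WX", 0, n - 1)]
        while agenda:
            tag, i, j = agenda.pop()
            if i > j:
                continue
            if tag == "WX":
                self._trace_wx(i, j, pairs, agenda)
            elif tag == "V":
                self._trace_v(i, j, pairs, agenda)
            elif tag == "M0":
                self._trace_m(i, j, pairs, agenda, require_branch=False)
            elif tag == "M1":
                self._trace_m(i, j, pairs, agenda, require_branch=True)
        return pairs

    @staticmethod
    def _close(a: float, b: float) -> bool:
        return a == b or abs(a - b) <= 1e-9

    def _trace_wx(self, i, j, pairs, agenda):
        target = self.WX[i][j]
        skip = self.WX[i + 1][j] if i + 1 <= j else 0.0
        if self._close(target, skip):
            agenda.append(("WX", i + 1, j))
            return
        for k in range(i + 1, j + 1):
            if self.V[i][k] == INF:
                continue
            tail = self.WX[k + 1][j] if k + 1 <= j else 0.0
            if self._close(target, self.V[i][k] + tail):
                pairs.add((i, k))
                agenda.append(("V", i, k))
                agenda.append(("WX", k + 1, j))
                return
        raise AssertionError("WX traceback failed")

    def _trace_v(self, i, j, pairs, agenda):
        m, seq = self.model, self.seq
        target = self.V[i][j]
        if self.nickfree(i, j) and self._close(target, m.hairpin_energy(j - i - 1)):
            return
        if (
            j - i >= 2
            and m.pairable(seq[i + 1], seq[j - 1])
            and not self.nick_after[i]
            and not self.nick_after[j - 1]
            and self.V[i + 1][j - 1] < INF
            and self._close(
                target,
                m.stack_energy(seq[i] + seq[j], seq[i + 1] + seq[j - 1])
                + self.V[i + 1][j - 1],
            )
        ):
            pairs.add((i + 1, j - 1))
            agenda.append(("V", i + 1, j - 1))
            return
        for k in range(i + 1, j):
            n1 = k - i - 1
            if n1 > m.max_loop or not self.nickfree(i, k):
                break
            for l in range(j - 1, k, -1):
                n2 = j - l - 1
                if n1 == 0 and n2 == 0:
                    continue
                if n1 + n2 > m.max_loop:
                    break
                if self.V[k][l] == INF or not self.nickfree(l, j):
                    continue
                if self._close(target, m.loop_energy(n1, n2) + self.V[k][l]):
                    pairs.add((k, l))
                    agenda.append(("V", k, l))
                    return
        if j - i >= 4 and not self.nick_after[i] and not self.nick_after[j - 1]:
            base = m.ml_base + m.ml_branch
            for k in range(i + 1, j - 1):
                if self.nick_after[k]:
                    continue
                left, right = self.M1[i + 1][k], self.M1[k + 1][j - 1]
                if left == INF or right == INF:
                    continue
                if self._close(target, base + left + right):
                    agenda.append(("M1", i + 1, k))
                    agenda.append(("M1", k + 1, j - 1))
                    return
        for p in self.nicks:
            if p < i or p >= j:
                continue
            left = self.WX[i + 1][p] if i + 1 <= p else 0.0
            right = self.WX[p + 1][j - 1] if p + 1 <= j - 1 else 0.0
            if self._close(target, left + right):
                if i + 1 <= p:
                    agenda.append(("WX", i + 1, p))
                if p + 1 <= j - 1:
                    agenda.append(("WX", p + 1, j - 1))
                return
        raise AssertionError("V traceback failed")

    def _trace_m(self, i, j, pairs, agenda, require_branch: bool):
        m = self.model
        table = self.M1 if require_branch else self.M0
        target = table[i][j]
        if i == j and not require_branch and self._close(target, m.ml_unpaired):
            return
        if i < j and not self.nick_after[i]:
            t = table[i + 1][j]
            if t < INF and self._close(target, m.ml_unpaired + t):
                agenda.append(("M1" if require_branch else "M0", i + 1, j))
                return
        for k in range(i + 1, j + 1):
            if self.V[i][k] == INF:
                continue
            if k == j:
                tail = 0.0
            elif self.nick_after[k]:
                continue
            else:
                tail = self.M0[k + 1][j]
                if tail == INF:
                    continue
            if self._close(target, self.V[i][k] + m.ml_branch + tail):
                pairs.add((i, k))
                agenda.append(("V", i, k))
                if k < j:
                    agenda.append(("M0", k + 1, j))
                return
        raise AssertionError("M traceback failed")


def mfe_complex(
    strands: Sequence[str],
    model: EnergyModel | None = None,
    strand_ids: Sequence[str] | None = None,
) -> ComplexStructure:
    """Minimum-free-energy structure of an ordered 1-3 strand complex.

    Pairs are allowed within and between strands; the structure is
    non-pseudoknotted over the given concatenation order; loops containing a
    strand nick carry no penalty.  Ties between co-optimal structures are
    broken by a fixed deterministic traceback order (unpaired-first, then
    smallest split position).
    """
    model = model or default_model()
    if not 1 <= len(strands) <= 3:
        raise InputError(f"{len(strands)} strands unsupported (need 1-3)")
    norm = []
    for s in strands:
        if not s:
            raise InputError("empty strand")
        norm.append(normalize_rna(s))
    total = sum(len(s) for s in norm)
    if total > 2000:
        raise InputError(f"total length {total} exceeds 2000")
    if strand_ids is None:
        strand_ids = tuple(f"strand{k+1}" for k in range(len(norm)))
    folder = _Folder(norm, model)
    dG, pairs = folder.fold()
    if not pairs:
        dG = 0.0
    return ComplexStructure(
        strand_ids=tuple(strand_ids),
        strands=tuple(norm),
        pairs=pairs,
        dG=dG,
    )


# ---------------------------------------------------------------------------
# Conformation classification and seed preservation
# ---------------------------------------------------------------------------

def classify_conformation(structure: ComplexStructure) -> Conformation:
    """Classify a 3-strand structure (strand 0 = mRNA window).

    ``duplex_plus_free_mirna``: one miRNA strand has no inter-strand pairs.
    ``mirna_mirna_hybrid``: the two miRNA strands share at least one pair.
    ``canonical_triplex``: both miRNAs pair exclusively with the mRNA, each
    with at least one pair.  Anything else is ``other``.
    """
    if len(structure.strands) != 3:
        raise InputError("conformation classification requires 3 strands")
    offs = structure.strand_offsets
    ends = offs[1:] + (sum(len(s) for s in structure.strands),)

    def strand_of(pos: int) -> int:
        for k in (2, 1, 0):
            if pos >= offs[k]:
                return k
        raise IndexError(pos)

    inter = {1: 0, 2: 0}
    mir_mir = 0
    intra = {1: 0, 2: 0}
    for (a, b) in structure.pairs:
        sa, sb = strand_of(a), strand_of(b)
        if sa == sb:
            if sa in intra:
                intra[sa] += 1
            continue
        touched = {sa, sb}
        if touched == {1, 2}:
            mir_mir += 1
        for s in touched & {1, 2}:
            inter[s] += 1
    if inter[1] == 0 or inter[2] == 0:
        return Conformation.DUPLEX_PLUS_FREE_MIRNA
    if mir_mir > 0:
        return Conformation.MIRNA_MIRNA_HYBRID
    if intra[1] == 0 and intra[2] == 0:
        return Conformation.CANONICAL_TRIPLEX
    return Conformation.OTHER


def seed_preserved(
    structure: ComplexStructure,
    candidate: TriplexCandidate,
    which_mirna: int,
    mirna_strand: int | None = None,
    seed_positions: Sequence[int] = tuple(range(2, 9)),
    min_paired: int = 7,
) -> bool:
    """True when at least ``min_paired`` of the miRNA's seed nucleotides
    (positions 2-8 from the 5' end by convention) are paired to positions
    inside that miRNA's designated seed-match interval on the window.

    ``which_mirna`` is 1 (upstream site) or 2 (downstream site);
    ``mirna_strand`` gives the strand index carrying that miRNA in
    ``structure`` (default: strand ``which_mirna``).
    """
    if which_mirna not in (1, 2):
        raise ValueError("which_mirna must be 1 or 2")
    strand = mirna_strand if mirna_strand is not None else which_mirna
    offs = structure.strand_offsets
    mir_off = offs[strand]
    mir_len = len(structure.strands[strand])
    lo, hi = candidate.seed_window_interval0(which_mirna)
    win_len = len(structure.strands[0])
    if lo < 0 or hi > win_len:
        raise CoordinateError(
            f"seed interval [{lo},{hi}) outside window of length {win_len}"
        )
    partner = structure.partner()
    count = 0
    for p in seed_positions:
        idx = mir_off + (p - 1)
        if p - 1 >= mir_len:
            continue
        mate = partner.get(idx)
        if mate is not None and offs[0] + lo <= mate < offs[0] + hi:
            count += 1
    return count >= min_paired


# ---------------------------------------------------------------------------
# Triplex energetics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TriplexEnergetics:
    """Free energies of a triplex and its inherent duplexes.

    ``ddG = dG_triplex - min(dG_duplex1, dG_duplex2)``: the free energy
    gained (when negative) by forming the triplex rather than the best
    single-miRNA duplex.
    """

    dG_triplex: float
    dG_duplex1: float
    dG_duplex2: float
    conformation_class: Conformation = Conformation.CANONICAL_TRIPLEX
    seed_preserved_1: bool = True
    seed_preserved_2: bool = True
    gene_id: str = ""
    mirna1_id: str = ""
    mirna2_id: str = ""
    triplex_structure: ComplexStructure | None = None

    @property
    def ddG(self) -> float:
        return self.dG_triplex - min(self.dG_duplex1, self.dG_duplex2)

    @property
    def dG_duplex_min(self) -> float:
        return min(self.dG_duplex1, self.dG_duplex2)


def triplex_energetics(
    candidate: TriplexCandidate,
    mir1: MiRNA,
    mir2: MiRNA,
    model: EnergyModel | None = None,
    seed_min_paired: int = 7,
) -> TriplexEnergetics:
    """Fold the triplex and its two duplexes, classify the conformation and
    check seed preservation.

    ``dG_triplex`` is the minimum over the two distinct strand orders
    (window, miR1, miR2) and (window, miR2, miR1); conformation and seed
    checks are evaluated on the winning structure.
    """
    model = model or default_model()
    window = candidate.window_seq
    t12 = mfe_complex(
        (window, mir1.sequence, mir2.sequence),
        model,
        strand_ids=(candidate.transcript_id, mir1.id, mir2.id),
    )
    t21 = mfe_complex(
        (window, mir2.sequence, mir1.sequence),
        model,
        strand_ids=(candidate.transcript_id, mir2.id, mir1.id),
    )
    if t21.dG < t12.dG:
        winner, strand_for = t21, {1: 2, 2: 1}
    else:
        winner, strand_for = t12, {1: 1, 2: 2}
    d1 = mfe_complex(
        (window, mir1.sequence), model, strand_ids=(candidate.transcript_id, mir1.id)
    )
    d2 = mfe_complex(
        (window, mir2.sequence), model, strand_ids=(candidate.transcript_id, mir2.id)
    )
    return TriplexEnergetics(
        dG_triplex=winner.dG,
        dG_duplex1=d1.dG,
        dG_duplex2=d2.dG,
        conformation_class=classify_conformation(winner),
        seed_preserved_1=seed_preserved(
            winner, candidate, 1, mirna_strand=strand_for[1], min_paired=seed_min_paired
        ),
        seed_preserved_2=seed_preserved(
            winner, candidate, 2, mirna_strand=strand_for[2], min_paired=seed_min_paired
        ),
        gene_id=candidate.gene_id,
        mirna1_id=mir1.id,
        mirna2_id=mir2.id,
        triplex_structure=winner,
    )


# ---------------------------------------------------------------------------
# Population cutoff and filters
# ---------------------------------------------------------------------------

def tfe_cutoff(dG_population: Sequence[float], z: float = 3.0) -> float:
    """Population cutoff ``mean(dG) - z * sd(dG)`` (sample standard
    deviation); triplexes with free energy above the cutoff are discarded."""
    vals = list(dG_population)
    if not vals:
        raise InputError("empty free-energy population")
    if z < 0:
        raise ValueError("z must be >= 0")
    if z == 0 or len(vals) == 1:
        if z > 0 and len(vals) < 2:
            raise InputError("population size must be >= 2 for z > 0")
        return mean(vals)
    return mean(vals) - z * stdev(vals)


DEFAULT_DROP_CLASSES = frozenset(
    {Conformation.DUPLEX_PLUS_FREE_MIRNA, Conformation.MIRNA_MIRNA_HYBRID}
)


def apply_structure_filters(
    records: Sequence[TriplexEnergetics],
    cutoff: float,
    require_seed: bool = True,
    drop_classes: frozenset = DEFAULT_DROP_CLASSES,
) -> tuple[list[TriplexEnergetics], dict]:
    """Keep records with ``dG_triplex <= cutoff`` (inclusive), an accepted
    conformation, and (when required) both seeds preserved.

    Returns ``(kept, funnel)`` where funnel counts removals per filter, in
    the order conformation -> seed -> tfe.
    """
    kept: list[TriplexEnergetics] = []
    funnel = {"input": len(records), "conformation": 0, "seed": 0, "tfe": 0}
    for rec in records:
        if rec.conformation_class in drop_classes:
            funnel["conformation"] += 1
            continue
        if require_seed and not (rec.seed_preserved_1 and rec.seed_preserved_2):
            funnel["seed"] += 1
            continue
        if rec.dG_triplex > cutoff:
            funnel["tfe"] += 1
            continue
        kept.append(rec)
    funnel["kept"] = len(kept)
    return kept, funnel
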