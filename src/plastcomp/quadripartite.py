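"""Quadripartite structure: inverted-repeat detection and LSC/IRa/SSC/IRb partition.

Plastomes carry two large inverted repeats (IRa/IRb) separating a large and a
small single-copy region.  Detection here is exact: the reported IR pair is the
longest pair of disjoint intervals on the circle whose sequences are exact
reverse complements of each other.  In *Amaranthus*-like genomes the two IR
copies are identical, so the exact-match definition recovers the annotated
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .plastome_io import AnnotatedGenome, revcomp

SUBGENERA = ("Amaranthus", "Acnida", "Albersia", "outgroup")


class NoQuadripartiteStructure(ValueError):
    """Raised when no inverted repeat of the required length exists."""


@dataclass
class QuadripartiteStructure:
    """Circular partition into LSC, IRa, SSC, IRb.

    Each region is ``(start, length)`` on the original coordinate system;
    regions may wrap the origin.  Genome order is LSC -> IRa -> SSC -> IRb.
    """

    lsc: tuple[int, int]
    ira: tuple[int, int]
    ssc: tuple[int, int]
    irb: tuple[int, int]
    total_length: int
    gc_percent: float

    @property
    def lsc_length(self) -> int:
        return self.lsc[1]

    @property
    def ssc_length(self) -> int:
        return self.ssc[1]

    @property
    def ir_length(self) -> int:
        return self.ira[1]

    def region_of(self, pos: int) -> str:
        pos %= self.total_length
        for name, (s, ln) in (("LSC", self.lsc), ("IRa", self.ira),
                              ("SSC", self.ssc), ("IRb", self.irb)):
            if ln == 0:
                continue
            e = s + ln
            if e <= self.total_length:
                if s <= pos < e:
                    return name
            elif pos >= s or pos < e - self.total_length:
                return name
        raise AssertionError("partition does not tile the circle")

    def as_row(self) -> dict:
        return {
            "total_bp": self.total_length,
            "lsc_bp": self.lsc_length,
            "ssc_bp": self.ssc_length,
            "ir_bp": self.ir_length,
            "gc_percent": self.gc_percent,
        }


def _round_half_up(x, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


def gc_content(genome_or_seq) -> float:
    """GC percentage, rounded half-up to one decimal; N bases are excluded."""
    seq = genome_or_seq.sequence if isinstance(genome_or_seq, AnnotatedGenome) else genome_or_seq
    if not seq:
        raise ValueError("empty sequence")
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    if acgt == 0:
        raise ValueError("sequence contains no A/C/G/T bases")
    # exact decimal arithmetic so that e.g. 729/2000 -> 36.45 -> 36.5
    pct = Decimal(gc) * 100 / Decimal(acgt)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _circular_kmer(seq: str, k: int) -> str:
    return seq + seq[: k - 1]


def detect_inverted_repeat(
    genome_or_seq, min_ir_len: int = 1000, k: int = 25
) -> QuadripartiteStructure:
    """Find the longest exact inverted-repeat pair and partition the circle.

    Seeds are shared ``k``-mers between the sequence and its reverse complement,
    grouped by the match diagonal (which is invariant under extension) and each
    diagonal is extended to its maximal exact run.  The two single-copy arcs
    between the winning arms become LSC (longer) and SSC (shorter); IRa is the
    repeat copy that follows the LSC in genome order.

    Raises :class:`NoQuadripartiteStructure` if no disjoint pair of exact
    reverse-complement intervals of length >= ``min_ir_len`` exists.
    """
    if isinstance(genome_or_seq, AnnotatedGenome):
        seq = genome_or_seq.sequence
    else:
        seq = genome_or_seq.upper()
    L = len(seq)
    if L < 4 * min_ir_len:
        raise ValueError(f"genome length {L} < 4 x min_ir_len ({4 * min_ir_len})")
    rc = revcomp(seq)
    ext_s = _circular_kmer(seq, k)
    ext_r = _circular_kmer(rc, k)

    index: dict[str, list[int]] = {}
    for i in range(L):
        index.setdefault(ext_s[i:i + k], []).append(i)

    # f(p) == True iff seq[(p + d) % L] pairs with rc[p % L] on diagonal d
    seq_arr = np.frombuffer(seq.encode(), dtype="S1")
    rc_arr = np.frombuffer(rc.encode(), dtype="S1")

    best: tuple[int, int, int] | None = None  # (length, arm1_start, arm2_start)
    done_diagonals: set[int] = set()
    for u in range(L):
        kmer = ext_r[u:u + k]
        for i in index.get(kmer, ()):
            d = (i - u) % L
            if d in done_diagonals:
                continue
            done_diagonals.add(d)
            match = seq_arr[(np.arange(L) + d) % L] == rc_arr
            if match.all():
                continue  # whole-circle palindrome: no disjoint arms
            # maximal circular runs of True: rotate so index 0 is a mismatch
            shift = int(np.argmin(match))
            rot = np.roll(match, -shift)
            edges = np.flatnonzero(np.diff(rot.astype(np.int8)))
            starts = edges[::2] + 1      # False->True transitions
            ends = edges[1::2] + 1       # True->False transitions
            if len(ends) < len(starts):  # trailing run touching the array end
                ends = np.append(ends, L)
            for r0, r1 in zip(starts, ends):
                m = int(r1 - r0)
                if m < min_ir_len:
                    continue
                p0 = (int(r0) + shift) % L
                arm2 = (p0 + d) % L            # start of arm in seq coords
                arm1 = (L - p0 - m) % L        # rc window maps back to seq
                if not _disjoint_on_circle(arm1, arm2, m, L):
                    continue
                a1, a2 = sorted((arm1, arm2))
                cand = (m, -a1, -a2)           # larger IR, then smaller start
                if best is None or cand > (best[0], -best[1], -best[2]):
                    best = (m, a1, a2)
    if best is None:
        raise NoQuadripartiteStructure(
            f"no inverted repeat >= {min_ir_len} bp: single-copy genome"
        )
    m, a, b = best
    # arcs between the two arms
    gap1 = (b - (a + m)) % L        # from end of arm A to start of arm B
    gap2 = (a - (b + m)) % L        # from end of arm B to start of arm A
    if gap1 >= gap2:
        lsc = ((a + m) % L, gap1)
        ira = (b, m)
        ssc = ((b + m) % L, gap2)
        irb = (a, m)
    else:
        lsc = ((b + m) % L, gap2)
        ira = (a, m)
        ssc = ((a + m) % L, gap1)
        irb = (b, m)
    gc = gc_content(seq)
    assert lsc[1] + ssc[1] + 2 * m == L
    return QuadripartiteStructure(lsc=lsc, ira=ira, ssc=ssc, irb=irb,
                                  total_length=L, gc_percent=gc)


def _disjoint_on_circle(a: int, b: int, m: int, L: int) -> bool:
    """True if circular intervals [a, a+m) and [b, b+m) do not overlap."""
    if a == b:
        return False
    gap_ab = (b - a) % L
    gap_ba = (a - b) % L
    return gap_ab >= m and gap_ba >= m


def region_sequence(seq: str, region: tuple[int, int]) -> str:
    s, ln = region
    L = len(seq)
    if s + ln <= L:
        return seq[s:s + ln]
    return seq[s:] + seq[: (s + ln) % L]


def ssc_summary_by_subgenus(
    ssc_lengths: dict[str, int] | pd.Series,
    subgenus_of: dict[str, str],
    include_outgroup: bool = False,
) -> pd.DataFrame:
    """Mean and population SD of SSC lengths per subgenus and pooled pairs.

    Mirrors the familiar half-matrix layout: the diagonal holds within-subgenus
    summaries, off-diagonal cells pool the two subgenera.  Population SD
    (divide by n) is used; values are rounded half-up to 2 decimals.
    """
    if isinstance(ssc_lengths, pd.Series):
        ssc_lengths = ssc_lengths.to_dict()
    groups: dict[str, list[int]] = {}
    for sid, ln in ssc_lengths.items():
        try:
            sg = subgenus_of[sid]
        except KeyError:
            raise ValueError(f"sample {sid!r} missing from subgenus metadata") from None
        if sg not in SUBGENERA:
            raise ValueError(f"unknown subgenus label {sg!r} for sample {sid!r}")
        if sg == "outgroup" and not include_outgroup:
            continue
        groups.setdefault(sg, []).append(int(ln))
    order = [g for g in SUBGENERA if g in groups]
    rows = []
    for i, ga in enumerate(order):
        for gb in order[: i + 1]:
            vals = groups[ga] if ga == gb else groups[ga] + groups[gb]
            arr = np.asarray(vals, dtype=float)
            rows.append({
                "group_a": ga,
                "group_b": gb,
                "n": len(vals),
                "mean_bp": _round_half_up(arr.mean(), 2),
                "sd_bp": _round_half_up(arr.std(ddof=0), 2),
            })
    return pd.DataFrame(rows)


def partition_table(genomes, min_ir_len: int = 1000) -> pd.DataFrame:
    """Per-genome summary table: total/LSC/SSC/IR lengths and GC percentage."""
    rows = []
    for g in genomes:
        try:
            st = detect_inverted_repeat(g, min_ir_len=min_ir_len)
            row = st.as_row()
        except NoQuadripartiteStructure:
            row = {"total_bp": len(g), "lsc_bp": len(g), "ssc_bp": 0, "ir_bp": 0,
                   "gc_percent": gc_content(g)}
        rows.append({"sample_id": g.sample_id, "species": g.species, **row})
    return pd.DataFrame(rows)
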