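"""Dispersed-repeat detection (forward / palindromic / reverse / complement),
cross-sample locus clustering, and the circular-symmetry report.

A repeat pair is two intervals whose sequences agree under the kind's
transform — identical (forward), reverse complement (palindromic), reversed
(reverse) or base-complemented (complement) — at >= ``min_identity`` under a
Hamming (substitution-only) model, each arm >= ``min_len`` bp.  Seeds are exact
k-mer matches under the transform, extended along the diagonal with an X-drop
rule and trimmed back to matching ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .plastome_io import AnnotatedGenome, Msa, complement, revcomp
from .quadripartite import QuadripartiteStructure

KINDS = ("forward", "palindromic", "reverse", "complement")


@dataclass
class RepeatRecord:
    kind: str
    arm1: tuple[int, int]           # 0-based half-open, arm1.start <= arm2.start
    arm2: tuple[int, int]
    length: int
    identity: float
    regions: tuple[str, str] = ("", "")

    def validates(self, seq: str) -> bool:
        """Re-check the identity fraction by direct comparison."""
        return abs(self.identity - arm_identity(seq, self.kind, self.arm1, self.arm2)) < 1e-9


def _transform_arm2(seq: str, kind: str, interval: tuple[int, int]) -> str:
    s = seq[interval[0]:interval[1]]
    if kind == "forward":
        return s
    if kind == "palindromic":
        return revcomp(s)
    if kind == "reverse":
        return s[::-1]
    if kind == "complement":
        return complement(s)
    raise ValueError(f"unknown repeat kind {kind!r}")


def arm_identity(seq: str, kind: str, arm1: tuple[int, int], arm2: tuple[int, int]) -> float:
    a = seq[arm1[0]:arm1[1]]
    b = _transform_arm2(seq, kind, arm2)
    if len(a) != len(b) or not a:
        return 0.0
    m = sum(x == y for x, y in zip(a, b))
    return m / len(a)


def _extend(sa: np.ndarray, ta: np.ndarray, i: int, u: int, k: int,
            min_identity: float, xdrop: int = 12):
    """Extend an exact seed sa[i:i+k] == ta[u:u+u+k] along its diagonal.

    Returns (i0, u0, length, matches) of the best-scoring extension whose ends
    are matches, or None.  Score: match +1, mismatch -3 (tuned to a 90%
    identity floor); extension stops when the score drops ``xdrop`` below the
    running maximum.
    """
    L = len(sa)
    # right extension
    best_r, score, best_score = k - 1, 0, 0
    p, q = i + k, u + k
    off_r = 0
    while p + off_r < L and q + off_r < L:
        score += 1 if sa[p + off_r] == ta[q + off_r] else -3
        if score >= best_score:          # ties go to the longer extent
            best_score, best_r = score, k - 1 + off_r + 1
        if score < best_score - xdrop:
            break
        off_r += 1
    # left extension
    score, best_score = 0, 0
    best_l = 0
    off_l = 1
    while i - off_l >= 0 and u - off_l >= 0:
        score += 1 if sa[i - off_l] == ta[u - off_l] else -3
        if score >= best_score:          # ties go to the longer extent
            best_score, best_l = score, off_l
        if score < best_score - xdrop:
            break
        off_l += 1
    i0, u0 = i - best_l, u - best_l
    length = best_l + best_r + 1
    seg_a = sa[i0:i0 + length]
    seg_b = ta[u0:u0 + length]
    matches = int((seg_a == seg_b).sum())
    # trim ends to matches (they are, by construction of best_l / best_r)
    if length == 0 or matches / length < min_identity:
        # fall back to the bare seed region
        return None
    return i0, u0, length, matches


def find_repeats(
    genome_or_seq,
    min_len: int = 30,
    min_identity: float = 0.90,
    k: int = 12,
    kinds: tuple[str, ...] = KINDS,
    structure: QuadripartiteStructure | None = None,
) -> list[RepeatRecord]:
    """REPuter-style dispersed repeats on a linear view of the sequence.

    The structural IRa-vs-IRb hit (the quadripartite structure itself) is
    suppressed when ``structure`` is given; contained duplicates and a hit's
    own mirror image are always suppressed.
    """
    if not (0 < min_identity <= 1):
        raise ValueError("min_identity must lie in (0, 1]")
    seq = genome_or_seq.sequence if isinstance(genome_or_seq, AnnotatedGenome) else genome_or_seq.upper()
    L = len(seq)
    if L < 2 * min_len:
        raise ValueError(f"sequence length {L} < 2 x min_len")
    sa = np.frombuffer(seq.encode(), dtype="S1")
    records: list[RepeatRecord] = []
    for kind in kinds:
        t = {"forward": seq, "palindromic": revcomp(seq),
             "reverse": seq[::-1], "complement": complement(seq)}[kind]
        ta = np.frombuffer(t.encode(), dtype="S1")
        index: dict[bytes, list[int]] = {}
        raw = t.encode()
        for u in range(L - k + 1):
            index.setdefault(raw[u:u + k], []).append(u)
        sraw = seq.encode()
        covered: dict[int, list[tuple[int, int]]] = {}
        hits: list[tuple[int, int, int, int]] = []
        for i in range(L - k + 1):
            for u in index.get(sraw[i:i + k], ()):
                d = u - i
                if kind == "forward" and d == 0:
                    continue
                spans = covered.setdefault(d, [])
                if any(s <= i and i + k <= e for s, e in spans):
                    continue
                ext = _extend(sa, ta, i, u, k, min_identity)
                if ext is None:
                    spans.append((i, i + k))
                    continue
                i0, u0, length, matches = ext
                spans.append((i0, i0 + length))
                if length >= min_len:
                    hits.append((i0, u0, length, matches))
        for i0, u0, length, matches in hits:
            arm1 = (i0, i0 + length)
            if kind in ("forward", "complement"):
                arm2 = (u0, u0 + length)
            else:  # reverse / palindromic: t coordinates run backwards
                arm2 = (L - (u0 + length), L - u0)
            if arm1 == arm2:
                continue
            if arm2 < arm1:
                arm1, arm2 = arm2, arm1
            records.append(RepeatRecord(kind=kind, arm1=arm1, arm2=arm2,
                                        length=length, identity=matches / length))
    records = _dedupe(records)
    if structure is not None:
        records = [r for r in records if not _is_structural_ir_hit(r, structure)]
        for r in records:
            r.regions = (structure.region_of(r.arm1[0]), structure.region_of(r.arm2[0]))
    return sorted(records, key=lambda r: (r.arm1, r.arm2, r.kind))


def _contained(inner: tuple[int, int], outer: tuple[int, int]) -> bool:
    return outer[0] <= inner[0] and inner[1] <= outer[1]


def _dedupe(records: list[RepeatRecord]) -> list[RepeatRecord]:
    """Remove exact duplicates / mirrors and same-kind contained records."""
    seen = set()
    uniq = []
    for r in records:
        key = (r.kind, r.arm1, r.arm2)
        if key in seen:
            continue
        seen.add(key)
        uniq.append(r)
    keep = []
    by_kind: dict[str, list[RepeatRecord]] = {}
    for r in uniq:
        by_kind.setdefault(r.kind, []).append(r)
    for kind, recs in by_kind.items():
        recs = sorted(recs, key=lambda r: -r.length)
        taken: list[RepeatRecord] = []
        for r in recs:
            if any(
                (_contained(r.arm1, t.arm1) and _contained(r.arm2, t.arm2))
                or (_contained(r.arm1, t.arm2) and _contained(r.arm2, t.arm1))
                for t in taken
            ):
                continue
            taken.append(r)
            keep.append(r)
    return keep


def _within(interval: tuple[int, int], region: tuple[int, int], L: int) -> bool:
    s, ln = region
    e = s + ln
    if e <= L:
        return s <= interval[0] and interval[1] <= e
    return interval[0] >= s or interval[1] <= e - L


def _is_structural_ir_hit(r: RepeatRecord, st: QuadripartiteStructure) -> bool:
    if r.kind != "palindromic":
        return False
    L = st.total_length
    in_a1 = _within(r.arm1, st.ira, L) and _within(r.arm2, st.irb, L)
    in_a2 = _within(r.arm1, st.irb, L) and _within(r.arm2, st.ira, L)
    return in_a1 or in_a2


# ---------------------------------------------------------------------------
# Cross-sample loci
# ---------------------------------------------------------------------------

@dataclass
class RepeatLocus:
    locus_id: str                         # R1..Rn in reference order
    anchor: tuple[int, int]               # interval on the reference genome
    members: dict[str, list[RepeatRecord]] = field(default_factory=dict)
    common: bool = False
    variable_length: bool = False


def _sample_to_ref_map(msa: Msa, sample_id: str, reference_id: str) -> np.ndarray:
    """For each ungapped position of ``sample_id``, the reference coordinate
    (index of the last reference base at or before that column)."""
    row = np.frombuffer(msa.row(sample_id).encode(), dtype="S1")
    ref = np.frombuffer(msa.row(reference_id).encode(), dtype="S1")
    ref_pos = np.cumsum(ref != b"-") - 1
    return np.maximum(ref_pos[row != b"-"], 0)


def cluster_repeat_loci(
    per_sample: dict[str, list[RepeatRecord]],
    msa: Msa,
    reference_id: str,
    link_dist: int = 2000,
) -> list[RepeatLocus]:
    """Single-linkage clustering of arm1 intervals projected onto the reference.

    Intervals closer than ``link_dist`` bp on the reference join one locus.
    A locus is ``common`` when every sample contributes a member and
    ``variable_length`` when member lengths differ.
    """
    if reference_id not in msa.sample_ids:
        raise ValueError(f"reference {reference_id!r} has no alignment row")
    if len(per_sample) < 2:
        raise ValueError("need records from at least two samples")
    projected: list[tuple[int, int, str, RepeatRecord]] = []
    for sid, recs in per_sample.items():
        m = _sample_to_ref_map(msa, sid, reference_id)
        for r in recs:
            s = int(m[min(r.arm1[0], len(m) - 1)])
            e = int(m[min(r.arm1[1] - 1, len(m) - 1)]) + 1
            projected.append((s, e, sid, r))
    projected.sort(key=lambda t: t[:2])
    loci: list[RepeatLocus] = []
    cluster: list[tuple[int, int, str, RepeatRecord]] = []

    def _flush():
        if not cluster:
            return
        s = min(c[0] for c in cluster)
        e = max(c[1] for c in cluster)
        locus = RepeatLocus(locus_id=f"R{len(loci) + 1}", anchor=(s, e))
        for _, _, sid, r in cluster:
            locus.members.setdefault(sid, []).append(r)
        locus.common = set(locus.members) == set(per_sample)
        lengths = {r.length for recs in locus.members.values() for r in recs}
        locus.variable_length = len(lengths) > 1
        loci.append(locus)

    for item in projected:
        if cluster and item[0] - max(c[1] for c in cluster) >= link_dist:
            _flush()
            cluster = []
        cluster.append(item)
    _flush()
    return loci


# ---------------------------------------------------------------------------
# Circular symmetry (R12-style report)
# ---------------------------------------------------------------------------

def symmetry_report(records: list[RepeatRecord], total_length: int) -> pd.DataFrame:
    """Angular positions of each record's arms on the circular genome and an
    antipodality score: |180 deg - angular separation|, 0 for perfectly
    opposite arms, 180 for coincident arms."""
    rows = []
    for r in records:
        mids = [sum(r.arm1) / 2, sum(r.arm2) / 2]
        angles = [360.0 * (m % total_length) / total_length for m in mids]
        sep = abs(angles[0] - angles[1])
        sep = min(sep, 360.0 - sep)
        rows.append({
            "kind": r.kind,
            "arm1_angle_deg": angles[0],
            "arm2_angle_deg": angles[1],
            "separation_deg": sep,
            "antipodality_deg": abs(180.0 - sep),
        })
    return pd.DataFrame(rows)


def repeat_table(records: list[RepeatRecord], sample_id: str) -> pd.DataFrame:
    """TSV-ready table; coordinates 1-based inclusive."""
    return pd.DataFrame([
        {
            "sample": sample_id,
            "kind": r.kind,
            "length": r.length,
            "identity": round(r.identity, 4),
            "arm1_start": r.arm1[0] + 1,
            "arm1_end": r.arm1[1],
            "arm2_start": r.arm2[0] + 1,
            "arm2_end": r.arm2[1],
            "region1": r.regions[0],
            "region2": r.regions[1],
        }
        for r in records
    ])
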