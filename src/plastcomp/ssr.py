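"""Microsatellite (SSR) detection and the species-discriminating marker search.

Detection follows the MISA conventions for perfect repeats: maximal tandem runs
of a 1-6 bp unit, with minimum unit counts of 10/5/4/3/3/3 for periods 1-6, the
reported motif primitive (not itself a tandem of a shorter unit), and the
interval truncated to whole copies.  Imperfect or compound SSRs are not merged.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plastome_io import AnnotatedGenome, revcomp
from .quadripartite import QuadripartiteStructure, _round_half_up

DEFAULT_THRESHOLDS = {1: 10, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}


@dataclass
class SSRRecord:
    motif: str
    period: int
    copy_number: int
    start: int                      # 0-based; end may wrap on circular genomes
    region: str = ""                # LSC / IRa / SSC / IRb
    context: str = ""               # gene name or IGS name

    @property
    def end(self) -> int:
        return self.start + self.period * self.copy_number

    @property
    def length(self) -> int:
        return self.period * self.copy_number

    @property
    def at_only(self) -> bool:
        return set(self.motif) <= {"A", "T"}

    @property
    def canonical_motif(self) -> str:
        return canonical_motif(self.motif)


def is_primitive(motif: str) -> bool:
    """True unless the motif is a whole-number tandem of a shorter unit."""
    p = len(motif)
    for d in range(1, p):
        if p % d == 0 and motif == motif[:d] * (p // d):
            return False
    return True


def canonical_motif(motif: str) -> str:
    """Lexicographic minimum over rotations and reverse-complement rotations.

    This is the grouping convention used when SSR loci from different genomes
    are keyed into one marker matrix (e.g. TA, AT and their complements all
    map to "AT").
    """
    rc = revcomp(motif)
    variants = [motif[i:] + motif[:i] for i in range(len(motif))]
    variants += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(variants)


def _runs_for_period(seq: str, p: int, min_copies: int):
    """Maximal tandem runs of period p as (start, copies) on a linear string."""
    n = len(seq)
    if n < p * 2:
        return
    a = np.frombuffer(seq.encode(), dtype="S1")
    eq = a[p:] == a[:-p]           # eq[i]: seq[i+p] == seq[i]
    if not eq.any():
        return
    ints = eq.astype(np.int8)
    edges = np.flatnonzero(np.diff(ints))
    starts = list(edges[np.where(ints[edges + 1] == 1)] + 1) if len(edges) else []
    ends = list(edges[np.where(ints[edges + 1] == 0)] + 1) if len(edges) else []
    if ints[0] == 1:
        starts = [0] + starts
    if ints[-1] == 1:
        ends = ends + [len(ints)]
    for s, e in zip(starts, ends):
        run_len = (e - s) + p      # bases covered by the tandem run
        copies = run_len // p
        if copies >= min_copies:
            yield s, copies


def find_ssrs(
    genome_or_seq,
    thresholds: dict[int, int] | None = None,
    circular: bool | None = None,
) -> list[SSRRecord]:
    """All maximal perfect SSRs meeting the per-period unit-count thresholds.

    Circular genomes are scanned on a doubled sequence; calls are reported once
    with start in ``[0, L)`` and wrapped duplicates or contained sub-calls
    removed.
    """
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    if isinstance(genome_or_seq, AnnotatedGenome):
        seq = genome_or_seq.sequence
        if circular is None:
            circular = genome_or_seq.circular
    else:
        seq = genome_or_seq.upper()
        circular = bool(circular)
    L = len(seq)
    scan = seq + seq if circular else seq
    records: list[SSRRecord] = []
    for p, min_copies in sorted(thresholds.items()):
        for s, copies in _runs_for_period(scan, p, min_copies):
            if s >= L:
                continue
            motif = scan[s:s + p]
            if not is_primitive(motif):
                continue
            copies = min(copies, L // p)  # a run cannot exceed the circle
            if copies < min_copies:
                continue
            records.append(SSRRecord(motif=motif, period=p, copy_number=copies, start=s))
    return _dedupe_contained(records, L, circular)


def _dedupe_contained(records: list[SSRRecord], L: int, circular: bool) -> list[SSRRecord]:
    """Drop calls whose interval is contained in another call of the same period."""
    def covered(r: SSRRecord) -> set[int]:
        return {(r.start + i) % L if circular else r.start + i for i in range(r.length)}

    keep: list[SSRRecord] = []
    by_period: dict[int, list[SSRRecord]] = {}
    for r in records:
        by_period.setdefault(r.period, []).append(r)
    for p, recs in sorted(by_period.items()):
        recs = sorted(recs, key=lambda r: (-r.length, r.start))
        taken: list[set[int]] = []
        for r in recs:
            cov = covered(r)
            if any(cov <= t for t in taken):
                continue
            taken.append(cov)
            keep.append(r)
    return sorted(keep, key=lambda r: (r.start, r.period))


def annotate_ssrs(
    records: list[SSRRecord],
    genome: AnnotatedGenome,
    structure: QuadripartiteStructure | None = None,
) -> list[SSRRecord]:
    """Fill region (quadripartite) and context (gene or IGS name) in place."""
    gene_feats = [f for f in genome.features if f.kind in ("gene", "CDS", "tRNA", "rRNA")]
    igs_feats = [f for f in genome.features if f.kind == "IGS"]
    for r in records:
        mid = (r.start + r.length // 2) % len(genome)
        if structure is not None:
            r.region = structure.region_of(mid)
        for f in gene_feats:
            if any(s <= mid < e for s, e in f.parts):
                r.context = f.name
                break
        else:
            for f in igs_feats:
                if any(s <= mid < e for s, e in f.parts):
                    r.context = f.name
                    break
    return records


def ssr_composition_stats(records: list[SSRRecord]) -> dict:
    """Summary fractions mirroring the usual SSR report.

    Percentages are rounded half-up to 2 decimals; the period histogram is
    ordered by descending count.
    """
    if not records:
        raise ValueError("no SSR records to summarize")
    n = len(records)
    at = sum(r.at_only for r in records)
    lsc = sum(r.region == "LSC" for r in records)
    igs = sum("-" in r.context for r in records)
    hist = Counter(r.period for r in records)
    return {
        "n": n,
        "pct_at_only": _round_half_up(100 * at / n, 2),
        "pct_in_lsc": _round_half_up(100 * lsc / n, 2),
        "pct_in_igs": _round_half_up(100 * igs / n, 2),
        "period_counts": dict(sorted(hist.items(), key=lambda kv: (-kv[1], kv[0]))),
    }


def ssr_table(records: list[SSRRecord], sample_id: str) -> pd.DataFrame:
    """TSV-ready table; coordinates are 1-based inclusive."""
    return pd.DataFrame([
        {
            "sample": sample_id,
            "motif": r.motif,
            "canonical_motif": r.canonical_motif,
            "period": r.period,
            "copies": r.copy_number,
            "start": r.start + 1,
            "end": r.end,
            "region": r.region,
            "context": r.context,
        }
        for r in records
    ])


def marker_matrix(per_sample: dict[str, list[SSRRecord]]) -> pd.DataFrame:
    """Samples x loci matrix of copy numbers; loci keyed (context, motif).

    Absent loci are NaN.  When a sample has several SSRs at the same key the
    copy numbers are summed (keeps every cell traceable to records).
    """
    cells: dict[str, dict[tuple, int]] = {}
    for sid, recs in per_sample.items():
        row: dict[tuple, int] = {}
        for r in recs:
            key = (r.context or f"pos{r.start}", r.canonical_motif)
            row[key] = row.get(key, 0) + r.copy_number
        cells[sid] = row
    df = pd.DataFrame.from_dict(cells, orient="index")
    df = df[sorted(df.columns)]
    df.columns = [f"{c}:{m}" for c, m in df.columns]
    return df


def _pair_separable(row_a: pd.Series, row_b: pd.Series, cols) -> bool:
    for c in cols:
        va, vb = row_a[c], row_b[c]
        if (pd.isna(va) != pd.isna(vb)) or (pd.notna(va) and va != vb):
            return True
    return False


def discriminating_combinations(matrix: pd.DataFrame, max_size: int = 4):
    """Smallest marker set separating each sample pair, plus inseparable pairs.

    For every unordered pair the minimum-cardinality column subset (searched by
    increasing cardinality, lexicographic tie-break) whose value vectors differ
    is reported; pairs with identical full rows are inseparable.  Absence of a
    locus is itself an informative state.
    """
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    if len(matrix) < 2:
        raise ValueError("need at least two samples")
    cols = list(matrix.columns)
    per_pair: dict[tuple[str, str], tuple[str, ...]] = {}
    inseparable: list[tuple[str, str]] = []
    for a, b in itertools.combinations(matrix.index, 2):
        ra, rb = matrix.loc[a], matrix.loc[b]
        found = None
        for size in range(1, max_size + 1):
            for combo in itertools.combinations(cols, size):
                if _pair_separable(ra, rb, combo):
                    found = combo
                    break
            if found:
                break
        if found is None and not _pair_separable(ra, rb, cols):
            inseparable.append((a, b))
        elif found is not None:
            per_pair[(a, b)] = found
    return per_pair, inseparable


def minimal_universal_marker_set(matrix: pd.DataFrame, max_size: int = 4):
    """Smallest column set separating every separable pair simultaneously.

    Exhaustive over increasing cardinality with lexicographic tie-break;
    returns None if no subset of size <= max_size works.
    """
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    pairs = [
        (a, b) for a, b in itertools.combinations(matrix.index, 2)
        if _pair_separable(matrix.loc[a], matrix.loc[b], matrix.columns)
    ]
    cols = list(matrix.columns)
    for size in range(1, max_size + 1):
        for combo in itertools.combinations(cols, size):
            if all(_pair_separable(matrix.loc[a], matrix.loc[b], combo) for a, b in pairs):
                return combo
    return None
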