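"""Consensus building, SNP/InDel site calling, annotation-class stratification
and pairwise sample differences, all on a whole-genome multiple alignment.

Definitions: a SNP site is an alignment column with >= 2 distinct non-gap
bases among the ingroup rows (multi-allelic columns count once); an InDel site
is a column where at least one ingroup row has a gap and at least one has a
base.  An InDel *event* is a maximal run of columns sharing one fixed set of
gap-bearing samples.  Site counts feed region-class frequency tables; event
counts feed pairwise species comparisons — the two scales are reported
separately and labelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plastome_io import AnnotatedGenome, Msa, derive_igs

GAP = b"-"
#: class precedence used when projecting reference features onto columns
CLASS_ORDER = ("CDS", "tRNA", "rRNA", "intron", "IGS")
_CLASS_CODE = {c: i for i, c in enumerate(CLASS_ORDER)}


@dataclass
class Consensus:
    sequence: str
    col_to_cons: np.ndarray     # alignment column -> consensus index (-1 dropped)
    cons_to_col: np.ndarray     # consensus index -> alignment column


def build_consensus(msa: Msa, sample_ids: list[str] | None = None) -> Consensus:
    """Per-column majority base, gaps ignored in the vote.

    Ties break alphabetically (A < C < G < T); N wins only when a column holds
    nothing but N.  Columns that are gap in every (selected) row are dropped
    from the consensus coordinate system.
    """
    if len(msa.rows) < 2:
        raise ValueError("need at least two rows")
    mat = msa.matrix(sample_ids)
    counts = np.stack([(mat == b).sum(axis=0) for b in (b"A", b"C", b"G", b"T")])
    n_counts = (mat == b"N").sum(axis=0)
    has_base = counts.sum(axis=0) > 0
    has_n = n_counts > 0
    keep = has_base | has_n
    if not keep.any():
        raise ValueError("alignment is all gaps")
    winner = np.array(list("ACGT"))[counts.argmax(axis=0)]
    winner[~has_base & has_n] = "N"
    col_to_cons = np.full(mat.shape[1], -1, dtype=np.int64)
    col_to_cons[keep] = np.arange(int(keep.sum()))
    cons_to_col = np.flatnonzero(keep)
    return Consensus("".join(winner[keep]), col_to_cons, cons_to_col)


def classify_columns(msa: Msa, annotation: AnnotatedGenome):
    """Assign every alignment column a region class and a feature name.

    The reference row's features are painted onto reference coordinates with
    precedence CDS > tRNA > rRNA > intron > IGS, then each column inherits the
    class of the reference base at or before it (so insertions relative to the
    reference stay inside the surrounding feature).  Returns (class_codes,
    feature_names) arrays over columns.
    """
    if not any(f.kind == "IGS" for f in annotation.features):
        annotation = derive_igs(annotation)
    L = len(annotation)
    ref_class = np.full(L, _CLASS_CODE["IGS"], dtype=np.int8)
    ref_name = np.empty(L, dtype=object)
    ref_name[:] = ""
    for kind in reversed(CLASS_ORDER):        # paint lowest precedence first
        for f in annotation.features:
            if f.kind != kind:
                continue
            for s, e in f.parts:
                ref_class[s:e] = _CLASS_CODE[kind]
                ref_name[s:e] = f.name
    ref_row = np.frombuffer(msa.row(msa.reference_id).encode(), dtype="S1")
    n_ref = int((ref_row != GAP).sum())
    if n_ref != L:
        raise ValueError(
            f"reference row has {n_ref} bases but annotation covers {L} bp"
        )
    ref_pos = np.cumsum(ref_row != GAP) - 1
    ref_pos = np.clip(ref_pos, 0, L - 1)
    return ref_class[ref_pos], ref_name[ref_pos]


@dataclass
class VariantTable:
    """Per-column variant calls plus region-class tallies."""

    msa: Msa
    ingroup: list[str]
    snp_sites: np.ndarray           # bool per column
    indel_sites: np.ndarray         # bool per column
    class_codes: np.ndarray         # int8 per column
    feature_names: np.ndarray       # object per column
    consensus: Consensus

    @property
    def n_snps(self) -> int:
        return int(self.snp_sites.sum())

    @property
    def n_indel_sites(self) -> int:
        return int(self.indel_sites.sum())

    def snp_positions_on_consensus(self) -> np.ndarray:
        pos = self.consensus.col_to_cons[np.flatnonzero(self.snp_sites)]
        return pos[pos >= 0]

    def summary(self) -> pd.DataFrame:
        """Region-class tally table (lengths measured on the consensus).

        The "Gene" row aggregates CDS + tRNA + rRNA + intron; frequencies are
        true percentages (count / class length x 100).
        """
        keep = self.consensus.col_to_cons >= 0
        cls = self.class_codes[keep]
        snp = self.snp_sites[keep]
        ind = self.indel_sites[keep]
        rows = []

        def add(name, mask):
            ln = int(mask.sum())
            ns, ni = int(snp[mask].sum()), int(ind[mask].sum())
            rows.append({
                "region": name, "length_bp": ln,
                "snp_count": ns,
                "snp_freq_pct": round(100 * ns / ln, 2) if ln else 0.0,
                "indel_count": ni,
                "indel_freq_pct": round(100 * ni / ln, 2) if ln else 0.0,
            })

        add("Consensus", np.ones_like(snp, dtype=bool))
        genic = np.isin(cls, [_CLASS_CODE[c] for c in ("CDS", "tRNA", "rRNA", "intron")])
        add("Gene", genic)
        for c in CLASS_ORDER:
            add(c if c != "intron" else "Intron", cls == _CLASS_CODE[c])
        return pd.DataFrame(rows)


def call_variants(
    msa: Msa,
    annotation: AnnotatedGenome,
    ingroup: list[str] | None = None,
) -> VariantTable:
    """Call SNP and InDel sites and stratify them by annotation class.

    ``ingroup`` restricts both the variant calls and the consensus (outgroups
    are excluded from genus-level tallies); the reference row must belong to
    the alignment regardless.
    """
    ingroup = list(ingroup) if ingroup is not None else list(msa.sample_ids)
    for sid in ingroup:
        if sid not in msa.sample_ids:
            raise KeyError(f"ingroup sample {sid!r} not in alignment")
    mat = msa.matrix(ingroup)
    is_gap = mat == GAP
    distinct = np.zeros(mat.shape[1], dtype=np.int8)
    for b in (b"A", b"C", b"G", b"T"):
        distinct += (mat == b).any(axis=0)
    snp_sites = (distinct >= 2)
    indel_sites = is_gap.any(axis=0) & ~is_gap.all(axis=0)
    class_codes, feature_names = classify_columns(msa, annotation)
    consensus = build_consensus(msa, ingroup)
    return VariantTable(
        msa=msa, ingroup=ingroup, snp_sites=snp_sites, indel_sites=indel_sites,
        class_codes=class_codes, feature_names=feature_names, consensus=consensus,
    )


@dataclass
class IndelEvent:
    start_col: int
    end_col: int                 # half-open on alignment columns
    length: int
    gapped_samples: frozenset
    feature: str = ""

    def __repr__(self) -> str:  # compact, useful in reports
        who = ",".join(sorted(self.gapped_samples))
        return f"IndelEvent([{self.start_col},{self.end_col}) {self.length} bp gap:{who} {self.feature})"


def indel_events(
    msa: Msa,
    sample_ids: list[str] | None = None,
    feature_names: np.ndarray | None = None,
) -> list[IndelEvent]:
    """Maximal runs of columns with one fixed, non-empty, proper set of
    gap-bearing samples."""
    ids = sample_ids if sample_ids is not None else list(msa.sample_ids)
    mat = msa.matrix(ids)
    is_gap = mat == GAP
    active = is_gap.any(axis=0) & ~is_gap.all(axis=0)
    idx = np.flatnonzero(active)
    if len(idx) == 0:
        return []
    # one integer label per distinct per-column gap pattern
    _, labels = np.unique(is_gap.T, axis=0, return_inverse=True)
    labels = labels.ravel()
    brk = np.flatnonzero((np.diff(idx) != 1) | (labels[idx[1:]] != labels[idx[:-1]]))
    seg_starts = np.concatenate([[0], brk + 1])
    seg_ends = np.concatenate([brk, [len(idx) - 1]])
    events: list[IndelEvent] = []
    for a, b in zip(seg_starts, seg_ends):
        c, e = int(idx[a]), int(idx[b]) + 1
        pattern = is_gap[:, c]
        events.append(IndelEvent(
            start_col=c, end_col=e, length=e - c,
            gapped_samples=frozenset(ids[i] for i in np.flatnonzero(pattern)),
            feature="" if feature_names is None else str(feature_names[c]),
        ))
    return events


def longest_indels(events: list[IndelEvent], k: int) -> list[IndelEvent]:
    """Top-k events by length (descending), ties by coordinate."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not events:
        raise ValueError("no indel events")
    return sorted(events, key=lambda ev: (-ev.length, ev.start_col))[:k]


def pairwise_differences(
    msa: Msa,
    sample_a: str,
    sample_b: str,
    annotation: AnnotatedGenome | None = None,
):
    """SNPs and InDel events between two samples.

    SNPs: columns where both carry (different) bases.  InDel events: maximal
    runs of columns where exactly one of the two has a gap; columns where both
    samples are gapped (material neither carries) are ignored entirely, so an
    unrelated third sample's insertion does not split an event.  Returns
    ``(snp_count, indel_event_count, events)``; event coordinates refer to the
    original alignment columns.
    """
    sub = msa.subset([sample_a, sample_b])
    a = np.frombuffer(sub.rows[0].encode(), dtype="S1")
    b = np.frombuffer(sub.rows[1].encode(), dtype="S1")
    base_a = (a != GAP) & (a != b"N")
    base_b = (b != GAP) & (b != b"N")
    snp_count = int(((a != b) & base_a & base_b).sum())
    feature_names = None
    if annotation is not None:
        _, feature_names = classify_columns(msa, annotation)
    keep = ~((a == GAP) & (b == GAP))
    col_of = np.flatnonzero(keep)
    stripped = Msa(
        [sample_a, sample_b],
        [a[keep].tobytes().decode(), b[keep].tobytes().decode()],
        sample_a,
    )
    fn = feature_names[keep] if feature_names is not None else None
    events = indel_events(stripped, feature_names=fn)
    for ev in events:
        ev.start_col = int(col_of[ev.start_col])
        ev.end_col = int(col_of[ev.end_col - 1]) + 1
    return snp_count, len(events), events
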