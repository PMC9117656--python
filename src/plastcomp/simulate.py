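"""Synthetic plastome generator with full ground truth.

The simulator emulates the statistical structure comparative plastome analyses
assume: a circular genome LSC + IRa + SSC + IRb (defaults 84,000 / 24,300 /
18,000 / 24,300 bp) with gene/tRNA/rRNA/intron/IGS annotation, per-class
substitution and indel rates concentrated in non-coding sequence, planted
SSRs and dispersed repeats, and a three-clade ingroup topology plus outgroups.

Internally only the "reduced" genome LSC + IRa + SSC evolves; the second
inverted-repeat copy is emitted as the reverse complement of the current IRa,
so every leaf keeps an exact IR pair and IR mutations are automatically
mirrored between the two copies (both copies still count in downstream
tallies, as in real data).  The emitted alignment is the true homology
alignment: every column is identified by a persistent site key, so no
external aligner is involved and ground truth is exact.

Branch lengths are per-site substitution probabilities (not rates); the preset
tree's branches sum to 1.0 over the ingroup, so a class's substitution
parameter is, to first order, the expected fraction of polymorphic columns of
that class — the scale on which published variability tables report.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from .plastome_io import AnnotatedGenome, Feature, Msa, complement, derive_igs, revcomp
from .variants import CLASS_ORDER, _CLASS_CODE

CLADES = ("Acnida", "Amaranthus", "Albersia")

#: per-class substitution probability per unit tree length (fraction of
#: polymorphic sites of that class across the whole ingroup)
DEFAULT_SUBST_RATES = {
    "CDS": 0.0129, "tRNA": 0.0032, "rRNA": 0.0007, "intron": 0.0168, "IGS": 0.0326,
}
#: per-class gap-column frequency targets; the per-site indel *event* rate is
#: half of this (background event lengths are geometric with mean 2)
DEFAULT_INDEL_FREQS = {
    "CDS": 0.0107, "tRNA": 0.0, "rRNA": 0.0, "intron": 0.0219, "IGS": 0.0732,
}

# (motif, copies) pairs planted in the ancestor; composition chosen so that
# roughly 56% of loci are A/T-only and the period histogram runs
# mono > tetra > di > tri > penta > hexa
DEFAULT_SSR_PLANTS = [
    ("A", 12), ("T", 12), ("A", 11), ("T", 11), ("A", 10), ("T", 10),
    ("A", 13), ("T", 13), ("A", 10), ("T", 10), ("A", 14), ("T", 11),
    ("G", 10), ("C", 10), ("G", 11),
    ("AT", 6), ("AT", 5), ("AG", 5), ("CT", 5),
    ("AAT", 4), ("ATC", 4), ("CTT", 4),
    ("AAAT", 3), ("TTTA", 3), ("GATA", 3), ("TCTA", 3), ("ACGT", 3), ("TTCG", 3),
    ("AATAT", 3),
    ("AATCGT", 3),
]

# (kind, length) planted dispersed-repeat pairs; the antipodal forward pair is
# handled separately (see plant_antipodal_pair)
DEFAULT_REPEAT_PLANTS = [
    ("forward", 40), ("palindromic", 35), ("reverse", 32), ("complement", 30),
    ("palindromic", 34),
]


@dataclass
class SimulationConfig:
    seed: int = 0
    taxa: dict = field(default_factory=lambda: {"Acnida": 6, "Amaranthus": 6, "Albersia": 10})
    n_outgroup: int = 3
    lsc_len: int = 84_000
    ir_len: int = 24_300
    ssc_len: int = 18_000
    gc_target: float = 0.366
    subst_rates: dict = field(default_factory=lambda: dict(DEFAULT_SUBST_RATES))
    indel_freqs: dict = field(default_factory=lambda: dict(DEFAULT_INDEL_FREQS))
    indel_geom_p: float = 0.5
    #: (target feature name, deletion length, branch label) long planted indels
    planted_indels: list = field(default_factory=lambda: [
        ("ycf2-like", 387, "stem_Acnida"),
        ("psbM-like-trnD-like", 384, "stem_Albersia"),
    ])
    #: (start, end, multiplier) substitution-rate windows in ancestral
    #: reduced-genome coordinates (hotspot planting)
    rate_windows: list = field(default_factory=list)
    ssr_plants: list = field(default_factory=lambda: list(DEFAULT_SSR_PLANTS))
    repeat_plants: list = field(default_factory=lambda: list(DEFAULT_REPEAT_PLANTS))
    plant_antipodal_pair: bool = True
    tree_newick: str = ""           # optional override of the preset topology
    outgroup_branch: float = 0.12

    @property
    def reduced_len(self) -> int:
        return self.lsc_len + self.ir_len + self.ssc_len

    @property
    def total_len(self) -> int:
        return self.reduced_len + self.ir_len


@dataclass
class GroundTruth:
    ancestor_reduced: str
    ancestor_features: list
    ssr_plants: list            # (motif, copies, start) reduced coords
    repeat_plants: list         # (kind, length, arm1_start, arm2_start) full-genome coords
    planted_indels: list        # (feature, length, branch, start_key, end_key)
    rate_windows: list
    branch_ops: dict            # branch label -> {"sub": [...], "indel": [...]}
    tree_newick: str
    class_site_counts: dict     # reduced-genome site count per class


@dataclass
class SimulationResult:
    config: SimulationConfig
    genomes: dict               # sample_id -> AnnotatedGenome (full circle)
    msa: Msa                    # true full-genome alignment
    metadata: pd.DataFrame      # sample_id, species, subgenus
    truth: GroundTruth
    tree: dendropy.Tree

    @property
    def ingroup(self) -> list[str]:
        return list(self.metadata.loc[self.metadata.subgenus != "outgroup", "sample_id"])

    @property
    def reference_id(self) -> str:
        return self.msa.reference_id


# ---------------------------------------------------------------------------
# Ancestor construction
# ---------------------------------------------------------------------------

def _scaled(n: int, factor: float, floor: int = 60) -> int:
    return max(floor, int(round(n * factor)))


def _region_specs(config: SimulationConfig):
    """Gene specs per region as (name, kind, [segment lengths], intron flags).

    Segments alternate exon/intron when a gene has introns.  Lengths scale
    down proportionally for miniature test genomes.
    """
    fl = min(1.0, config.lsc_len / 84_000)
    fi = min(1.0, config.ir_len / 24_300)
    fs = min(1.0, config.ssc_len / 18_000)

    def cds(name, *segs, factor=1.0):
        return (name, "CDS", [_scaled(x, factor) for x in segs])

    def rna(name, kind, ln, factor=1.0):
        return (name, kind, [_scaled(ln, factor, floor=40)])

    lsc_special = [
        cds("rbcL", 1500, factor=fl),
        cds("rpoC2-like", 4100, factor=fl),
        cds("ycf2-like", 2400, factor=fl),
        cds("psbM-like", 1000, factor=fl),
        # wide pre-gap: the psbM-like--trnD-like spacer hosts a planted long indel
        rna("trnD-like", "tRNA", 80, factor=fl) + (max(120, _scaled(600, fl)),),
    ]
    ir_special = [
        rna("rrn16-like", "rRNA", 1491, factor=fi),
        rna("trnI-like", "tRNA", 75, factor=fi),
        rna("rrn23-like", "rRNA", 2810, factor=fi),
        rna("rrn4.5-like", "rRNA", 95, factor=fi),
        rna("rrn5-like", "rRNA", 120, factor=fi),
        rna("trnN-like", "tRNA", 75, factor=fi),
        cds("ycf2b-like", 3000, 800, 2200, factor=fi),   # exon/intron/exon
    ]
    ssc_special = [
        cds("ndhF-like", 2200, factor=fs),
        cds("ndhA-like", 550, 1000, 550, factor=fs),     # exon/intron/exon
        cds("ycf1-like", 5600, factor=fs),
    ]
    # repeating filler unit for single-copy regions
    filler = [
        ("CDS", [1000]),
        ("CDS", [650, 800, 650]),
        ("tRNA", [80]),
    ]
    return lsc_special, ir_special, ssc_special, filler


def _layout_region(offset, length, specials, filler, prefix, gap=250):
    """Place special genes then cycle filler genes; remainder stays IGS.

    Returns the feature list (gene containers, CDS/tRNA/rRNA parts and derived
    introns) for the region ``[offset, offset + length)``.
    """
    feats: list[Feature] = []
    cur = offset
    end = offset + length
    idx = 0

    def place(name, kind, segs, pre_gap=None):
        nonlocal cur
        g = gap if pre_gap is None else pre_gap
        total = sum(segs)
        if cur + g + total > end:
            return False
        cur += g
        start = cur
        if len(segs) == 1:
            feats.append(Feature(kind, name, ((cur, cur + segs[0]),)))
            cur += segs[0]
        else:
            exon_parts = []
            for si, seg in enumerate(segs):
                if si % 2 == 0:
                    exon_parts.append((cur, cur + seg))
                else:
                    feats.append(Feature("intron", name, ((cur, cur + seg),)))
                cur += seg
            feats.append(Feature(kind, name, tuple(exon_parts)))
        feats.append(Feature("gene", name, ((start, cur),)))
        return True

    for spec in specials:
        place(*spec)
    if filler:
        while True:
            kind, segs = filler[idx % len(filler)]
            name = f"{prefix}{idx + 1:03d}"
            if not place(name, kind, segs):
                break
            idx += 1
    return feats


def build_ancestor(config: SimulationConfig, rng: np.random.Generator):
    """Random reduced ancestor (LSC + IRa + SSC) with annotation and plants.

    Returns (sequence, features, class_codes, ssr_plants, repeat_plants).
    Raises if planted elements do not fit the intergenic space available.
    """
    n = config.reduced_len
    gc = config.gc_target
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=probs)
    # pin the bases flanking the IR junctions so the exact inverted repeat is
    # maximal at the configured boundaries (A never pairs with complement(A))
    for pos in (0, config.lsc_len - 1, config.lsc_len + config.ir_len, n - 1):
        seq[pos] = b"A"

    lsc_sp, ir_sp, ssc_sp, filler = _region_specs(config)
    feats = []
    feats += _layout_region(0, config.lsc_len, lsc_sp, filler, "lg",
                            gap=max(60, _scaled(250, config.lsc_len / 84_000)))
    feats += _layout_region(config.lsc_len, config.ir_len, ir_sp, None, "ig",
                            gap=max(60, _scaled(1600, config.ir_len / 24_300)))
    feats += _layout_region(config.lsc_len + config.ir_len, config.ssc_len,
                            ssc_sp, filler, "sg",
                            gap=max(60, _scaled(250, config.ssc_len / 18_000)))

    class_codes = np.full(n, _CLASS_CODE["IGS"], dtype=np.int8)
    for kind in ("intron", "rRNA", "tRNA", "CDS"):   # painted low to high precedence
        for f in feats:
            if f.kind == kind:
                for s, e in f.parts:
                    class_codes[s:e] = _CLASS_CODE[kind]

    igs_gaps = _igs_gaps(feats, n)
    # keep planted-indel target spacers free of planted SSRs/repeats
    reserved = []
    tmp = derive_igs(AnnotatedGenome("anc", "A" * n, circular=False, features=list(feats)))
    for name, *_ in config.planted_indels:
        iv = _feature_interval(tmp.features, name, n)
        if iv is not None:
            reserved.append(iv)
    igs_gaps = [
        g for g in igs_gaps
        if not any(g[0] < e and s < g[1] for s, e in reserved)
    ]
    ssr_plants, repeat_plants = _plant_elements(seq, config, igs_gaps, rng)
    return seq.tobytes().decode(), feats, class_codes, ssr_plants, repeat_plants


def _igs_gaps(feats, n):
    """Intervals not covered by any gene container, in order."""
    spans = sorted(p for f in feats if f.kind == "gene" for p in f.parts)
    gaps = []
    cur = 0
    for s, e in spans:
        if s > cur:
            gaps.append((cur, s))
        cur = max(cur, e)
    if cur < n:
        gaps.append((cur, n))
    return gaps


def _plant_elements(seq: np.ndarray, config: SimulationConfig, igs_gaps, rng):
    """Overwrite intergenic stretches with SSR runs and repeat-pair arms."""
    n = len(seq)
    lsc_end = config.lsc_len
    ssc_start = config.lsc_len + config.ir_len
    lsc_gaps = [g for g in igs_gaps if g[1] <= lsc_end and g[1] - g[0] >= 44]
    ir_gaps = [g for g in igs_gaps if g[0] >= lsc_end and g[1] <= ssc_start and g[1] - g[0] >= 44]
    ssc_gaps = [g for g in igs_gaps if g[0] >= ssc_start and g[1] - g[0] >= 44]
    used: list[tuple[int, int]] = []

    def alloc(length, pools):
        """A free sub-interval of `length` from the first pool that fits."""
        for pool in pools:
            for (gs, ge) in pool:
                lo, hi = gs + 4, ge - 4 - length
                if hi <= lo:
                    continue
                for _ in range(30):
                    s = int(rng.integers(lo, hi))
                    if all(e2 <= s or s + length <= s2 for s2, e2 in used):
                        used.append((s, s + length))
                        return s
        raise ValueError("planted elements exceed intergenic capacity")

    ssr_plants = []
    for i, (motif, copies) in enumerate(config.ssr_plants):
        run = motif * copies
        # ~75% of loci in the LSC, a few in SSC and IR, as in real plastomes
        pool_order = [lsc_gaps] if i % 8 < 6 else ([ssc_gaps, lsc_gaps] if i % 8 == 6
                                                  else [ir_gaps, lsc_gaps])
        s = alloc(len(run) + 2, pool_order)
        s += 1
        seq[s:s + len(run)] = np.frombuffer(run.encode(), dtype="S1")
        # break accidental run extension at the flanks
        for flank, adjacent in ((s - 1, motif[-1]), (s + len(run), motif[0])):
            if 0 <= flank < n and seq[flank] == adjacent.encode():
                choices = [b for b in b"ACGT" if bytes([b]) != adjacent.encode()]
                seq[flank] = bytes([choices[int(rng.integers(len(choices)))]])
        ssr_plants.append((motif, copies, s))

    repeat_plants = []
    for kind, length in config.repeat_plants:
        a1 = alloc(length, [lsc_gaps])
        a2 = alloc(length, [lsc_gaps] if kind != "palindromic" else [ssc_gaps, lsc_gaps])
        _copy_arm(seq, kind, a1, a2, length)
        repeat_plants.append((kind, length, min(a1, a2), max(a1, a2)))
    if config.plant_antipodal_pair:
        # forward pair with arms at nearly opposite positions on the circle
        length = 42
        a2 = alloc(length, [ssc_gaps])
        # choose the LSC arm as close to the antipode as the gaps allow
        best = None
        antipode = (a2 + config.total_len // 2) % config.total_len
        for gs, ge in lsc_gaps:
            lo, hi = gs + 20, ge - 20 - length
            if hi <= lo:
                continue
            cand = int(np.clip(antipode, lo, hi - 1))
            if all(e2 <= cand or cand + length <= s2 for s2, e2 in used):
                if best is None or abs(cand - antipode) < abs(best - antipode):
                    best = cand
        if best is None:
            raise ValueError("no LSC gap available for the antipodal repeat pair")
        used.append((best, best + length))
        _copy_arm(seq, "forward", best, a2, length)
        repeat_plants.append(("forward-antipodal", length, best, a2))
    return ssr_plants, repeat_plants


def _copy_arm(seq: np.ndarray, kind: str, a1: int, a2: int, length: int):
    src = seq[a1:a1 + length].tobytes().decode()
    kind = kind.split("-")[0]
    if kind == "forward":
        out = src
    elif kind == "palindromic":
        out = revcomp(src)
    elif kind == "reverse":
        out = src[::-1]
    elif kind == "complement":
        out = complement(src)
    else:
        raise ValueError(kind)
    seq[a2:a2 + length] = np.frombuffer(out.encode(), dtype="S1")


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------

def preset_tree(config: SimulationConfig) -> dendropy.Tree:
    """Three-clade ingroup topology ((Acnida, Amaranthus), Albersia) with the
    outgroup tips at the root; ingroup branch lengths sum to 1.0."""
    if config.tree_newick:
        return dendropy.Tree.get(data=config.tree_newick, schema="newick",
                                 preserve_underscores=True)
    n_in = sum(config.taxa.values())
    if n_in < 2:
        raise ValueError("need at least two ingroup taxa")
    stems = {"Acnida": 0.08, "Amaranthus": 0.08, "Albersia": 0.08, "join": 0.06}
    tip_len = (1.0 - sum(stems.values())) / n_in
    parts = {}
    for clade in CLADES:
        count = config.taxa.get(clade, 0)
        if count < 1:
            raise ValueError(f"preset tree needs >= 1 taxon per clade ({clade})")
        tips = ",".join(f"{clade}_{i + 1}:{tip_len:.6f}" for i in range(count))
        parts[clade] = f"({tips}){'stem_' + clade}:{stems[clade]:.6f}"
    og = ",".join(
        f"outgroup_{i + 1}:{config.outgroup_branch:.6f}" for i in range(config.n_outgroup)
    )
    newick = (f"(({parts['Acnida']},{parts['Amaranthus']})stem_join:{stems['join']:.6f},"
              f"{parts['Albersia']}" + (f",{og}" if og else "") + ")root;")
    return dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=False,
                             preserve_underscores=True)


# ---------------------------------------------------------------------------
# Evolution along the tree
# ---------------------------------------------------------------------------

class _NodeState:
    __slots__ = ("keys", "bases", "classes")

    def __init__(self, keys, bases, classes):
        self.keys = keys
        self.bases = bases
        self.classes = classes

    def copy(self):
        return _NodeState(list(self.keys), list(self.bases), list(self.classes))


def _site_rates(state: _NodeState, rates_by_code: np.ndarray, rate_windows) -> np.ndarray:
    cls = np.fromiter(state.classes, dtype=np.int8, count=len(state.classes))
    r = rates_by_code[cls]
    if rate_windows:
        anc = np.fromiter((k[0] for k in state.keys), dtype=np.int64, count=len(state.keys))
        for ws, we, mult in rate_windows:
            r = np.where((anc >= ws) & (anc < we), r * mult, r)
    return r


def _apply_branch(state, ops, gc_probs, rng=None):
    """Apply recorded operations to a node state (used both for simulation and
    for ground-truth replay)."""
    key_index = {k: i for i, k in enumerate(state.keys)}
    for key, new_base in ops["sub"]:
        idx = key_index.get(key)
        if idx is not None:
            state.bases[idx] = new_base
    # indels: rebuild the three lists in one pass
    if ops["indel"]:
        removed = set()
        inserts: dict[tuple, tuple[list, list, int]] = {}
        for ev in ops["indel"]:
            if ev[0] == "del":
                removed.update(ev[1])
        for ev in ops["indel"]:
            if ev[0] == "ins":
                _, anchor, keys, bases = ev
                if anchor in removed:   # same-branch deletion swallowed the anchor
                    continue
                inserts[anchor] = (keys, bases)
        new_keys, new_bases, new_classes = [], [], []
        for k, b, c in zip(state.keys, state.bases, state.classes):
            if k not in removed:
                new_keys.append(k)
                new_bases.append(b)
                new_classes.append(c)
            if k in inserts:
                ik, ib = inserts[k]
                new_keys.extend(ik)
                new_bases.extend(ib)
                new_classes.extend([c] * len(ik))
        state.keys, state.bases, state.classes = new_keys, new_bases, new_classes
    return state


def _sample_branch_ops(
    state: _NodeState,
    bl: float,
    config: SimulationConfig,
    branch_label: str,
    rng: np.random.Generator,
    branch_no: int,
    anc_features,
):
    sub_rates = np.array([config.subst_rates[c] for c in CLASS_ORDER])
    if bl * sub_rates.max() * max(
        [m for *_, m in config.rate_windows] or [1.0]
    ) > 0.5:
        raise ValueError("per-branch substitution probability exceeds 0.5 (saturation)")
    n = len(state.keys)
    p = _site_rates(state, sub_rates, config.rate_windows) * bl
    hit = np.flatnonzero(rng.random(n) < p)
    subs = []
    for i in hit:
        old = state.bases[i]
        alt = [b for b in "ACGT" if b != old]
        subs.append((state.keys[i], alt[int(rng.integers(3))]))

    indel_rates = np.array([config.indel_freqs[c] / 2 for c in CLASS_ORDER])
    q = _site_rates(state, indel_rates, []) * bl
    starts = np.flatnonzero(rng.random(n) < q)
    events = []
    gc = config.gc_target
    gc_probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    for i in starts[::-1]:
        ln = int(rng.geometric(config.indel_geom_p))
        if rng.random() < 0.5:
            keys = tuple(state.keys[i:i + ln])
            if keys:
                events.append(("del", keys))
        else:
            anchor = state.keys[i]
            new_keys = [anchor + (branch_no, j) for j in range(ln)]
            new_bases = ["ACGT"[int(rng.choice(4, p=gc_probs))] for _ in range(ln)]
            events.append(("ins", anchor, new_keys, new_bases))
    # planted long deletions targeted at this branch
    for feat_name, ln, branch in config.planted_indels:
        if branch != branch_label:
            continue
        interval = _feature_interval(anc_features, feat_name,
                                     config.reduced_len)
        if interval is None:
            raise ValueError(f"planted indel target {feat_name!r} not found")
        s, e = interval
        i0 = bisect_left(state.keys, (s,))
        i1 = bisect_left(state.keys, (e,))
        if i1 - i0 < ln + 2:
            raise ValueError(f"feature {feat_name!r} too short for a {ln} bp deletion")
        mid = (i0 + i1) // 2
        a = max(i0 + 1, mid - ln // 2)
        keys = tuple(state.keys[a:a + ln])
        events.append(("del", keys))
    return {"sub": subs, "indel": events}


def _feature_interval(features, name, n):
    for f in features:
        if f.name == name and f.kind in ("gene", "IGS"):
            return f.start, f.end
    for f in features:
        if f.name == name:
            return f.start, f.end
    return None


# ---------------------------------------------------------------------------
# Top level
# ---------------------------------------------------------------------------

def simulate(config: SimulationConfig) -> SimulationResult:
    """Run the full generator: ancestor, evolution, leaves, true alignment.

    Identical config (including seed) gives byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    anc_seq, anc_feats, class_codes, ssr_plants, repeat_plants = build_ancestor(config, rng)
    # IGS intervals on the ancestor, for planted-indel targeting by IGS name
    anc_genome = AnnotatedGenome("ancestor", anc_seq, circular=False,
                                 features=list(anc_feats))
    anc_with_igs = derive_igs(anc_genome)
    tree = preset_tree(config)

    root_state = _NodeState(
        [(i,) for i in range(len(anc_seq))], list(anc_seq), list(class_codes)
    )
    branch_ops: dict[str, dict] = {}
    leaf_states: dict[str, _NodeState] = {}
    counter = [0]

    def walk(node, state):
        for child in node.child_nodes():
            counter[0] += 1
            label = _node_label(child)
            bl = child.edge.length or 0.0
            child_state = state.copy()
            ops = _sample_branch_ops(child_state, bl, config, label, rng,
                                     counter[0], anc_with_igs.features)
            _apply_branch(child_state, ops, None)
            branch_ops[label] = ops
            if child.is_leaf():
                leaf_states[label] = child_state
            else:
                walk(child, child_state)

    walk(tree.seed_node, root_state)

    genomes, msa, metadata = _emit(config, leaf_states, anc_feats)
    truth = GroundTruth(
        ancestor_reduced=anc_seq,
        ancestor_features=list(anc_with_igs.features),
        ssr_plants=ssr_plants,
        repeat_plants=repeat_plants,
        planted_indels=list(config.planted_indels),
        rate_windows=list(config.rate_windows),
        branch_ops=branch_ops,
        tree_newick=tree.as_string(schema="newick",
                                   unquoted_underscores=True).strip(),
        class_site_counts={
            c: int((class_codes == _CLASS_CODE[c]).sum()) for c in CLASS_ORDER
        },
    )
    return SimulationResult(config=config, genomes=genomes, msa=msa,
                            metadata=metadata, truth=truth, tree=tree)


def _node_label(node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return node.label or f"node{id(node)}"


def _emit(config, leaf_states, anc_feats):
    lsc, ir = config.lsc_len, config.ir_len
    leaf_order = sorted(
        leaf_states,
        key=lambda s: (["Acnida", "Amaranthus", "Albersia", "outgroup"].index(s.split("_")[0]),
                       int(s.split("_")[1])),
    )
    genomes = {}
    rows_reduced = {}
    key_sets = []
    for sid in leaf_order:
        st = leaf_states[sid]
        reduced = "".join(st.bases)
        ira_s = bisect_left(st.keys, (lsc,))
        ira_e = bisect_left(st.keys, (lsc + ir,))
        full_seq = reduced + revcomp(reduced[ira_s:ira_e])
        feats = _project_features(anc_feats, st.keys, ira_s, ira_e, len(reduced), lsc, ir)
        subgenus = sid.split("_")[0]
        genomes[sid] = AnnotatedGenome(
            sample_id=sid, sequence=full_seq, species=f"A. sim-{sid.lower()}",
            subgenus=subgenus, circular=True, features=feats,
        )
        rows_reduced[sid] = st
        key_sets.append(st.keys)

    union = sorted(set().union(*[set(k) for k in key_sets]))
    pos = {k: i for i, k in enumerate(union)}
    n_cols = len(union)
    ira_lo = bisect_left(union, (lsc,))
    ira_hi = bisect_left(union, (lsc + ir,))
    rows = []
    for sid in leaf_order:
        st = rows_reduced[sid]
        row = np.full(n_cols, b"-", dtype="S1")
        idx = np.fromiter((pos[k] for k in st.keys), dtype=np.int64, count=len(st.keys))
        row[idx] = np.frombuffer("".join(st.bases).encode(), dtype="S1")
        reduced_row = row.tobytes().decode()
        rows.append(reduced_row + revcomp(reduced_row[ira_lo:ira_hi]))
    reference_id = leaf_order[0]
    msa = Msa(leaf_order, rows, reference_id=reference_id)
    metadata = pd.DataFrame({
        "sample_id": leaf_order,
        "species": [genomes[s].species for s in leaf_order],
        "subgenus": [genomes[s].subgenus for s in leaf_order],
    })
    return genomes, msa, metadata


def _project_features(anc_feats, keys, ira_s, ira_e, n_reduced, lsc, ir):
    def pos(x):
        return bisect_left(keys, (x,))

    feats = []
    ir_feats = []
    for f in anc_feats:
        parts = []
        for s, e in f.parts:
            a, b = pos(s), pos(e)
            if b > a:
                parts.append((a, b))
        if not parts:
            continue
        nf = Feature(f.kind, f.name, tuple(parts), f.strand)
        feats.append(nf)
        if f.start >= lsc and f.end <= lsc + ir:
            ir_feats.append(nf)
    # mirrored copies of IR features on the second (appended) IR copy
    for f in ir_feats:
        parts = tuple(sorted(
            (n_reduced + (ira_e - e), n_reduced + (ira_e - s)) for s, e in f.parts
        ))
        feats.append(Feature(f.kind, f.name, parts, -f.strand))
    return feats


# ---------------------------------------------------------------------------
# Ground-truth replay
# ---------------------------------------------------------------------------

def replay(config: SimulationConfig, truth: GroundTruth) -> dict[str, str]:
    """Re-apply the recorded per-branch operations to the recorded ancestor;
    returns reduced leaf sequences.  Must reproduce the simulation's leaves
    exactly (the ground-truth integrity property)."""
    tree = dendropy.Tree.get(data=truth.tree_newick, schema="newick",
                             suppress_internal_node_taxa=False,
                             preserve_underscores=True)
    root = _NodeState([(i,) for i in range(len(truth.ancestor_reduced))],
                      list(truth.ancestor_reduced), [0] * len(truth.ancestor_reduced))
    out = {}

    def walk(node, state):
        for child in node.child_nodes():
            label = _node_label(child)
            st = state.copy()
            _apply_branch(st, truth.branch_ops[label], None)
            if child.is_leaf():
                out[label] = "".join(st.bases)
            else:
                walk(child, st)

    walk(tree.seed_node, root)
    return out


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def hotspot_demo_config(seed: int = 0) -> SimulationConfig:
    """Low-background preset with two planted high-substitution segments
    10 kb apart, for hotspot-recovery demonstrations."""
    base = SimulationConfig(seed=seed)
    cfg = replace(
        base,
        taxa={"Acnida": 2, "Amaranthus": 2, "Albersia": 3},
        n_outgroup=1,
        lsc_len=20_000, ir_len=4_000, ssc_len=6_000,
        subst_rates={k: v / 10 for k, v in DEFAULT_SUBST_RATES.items()},
        indel_freqs={k: v / 10 for k, v in DEFAULT_INDEL_FREQS.items()},
        planted_indels=[],
        rate_windows=[(3_000, 4_500, 30.0), (14_500, 16_000, 30.0)],
        ssr_plants=[("A", 12), ("AT", 6)],
        repeat_plants=[("forward", 40)],
        plant_antipodal_pair=False,
    )
    return cfg


def mini_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Miniature genome preset for replicate-heavy tests."""
    cfg = SimulationConfig(
        seed=seed,
        taxa={"Acnida": 2, "Amaranthus": 2, "Albersia": 3},
        n_outgroup=1,
        lsc_len=7_000, ir_len=2_000, ssc_len=2_500,
        planted_indels=[],
        ssr_plants=[("A", 12), ("AT", 6), ("AAT", 4)],
        repeat_plants=[("forward", 40)],
        plant_antipodal_pair=False,
    )
    return replace(cfg, **overrides)
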