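"""Reading, writing and the shared coordinate model for annotated plastomes.

Internally every interval is 0-based half-open, ``[start, end)``.  Features that
wrap the circular origin are stored as an ordered list of non-wrapping parts;
their length is the sum of part lengths.  Report files written by the CLI use
1-based inclusive coordinates (the GenBank convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

FEATURE_KINDS = ("gene", "CDS", "tRNA", "rRNA", "intron", "IGS", "repeat_region", "misc")

#: annotation classes that count as "gene span" when deriving intergenic spacers
GENIC_KINDS = frozenset({"gene", "CDS", "tRNA", "rRNA"})

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


@dataclass
class Feature:
    """A located annotation.

    ``parts`` is an ordered tuple of 0-based half-open ``(start, end)`` intervals;
    more than one part means either a multi-exon feature or a feature wrapping
    the circular origin.
    """

    kind: str
    name: str
    parts: tuple[tuple[int, int], ...]
    strand: int = 1

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        self.parts = tuple((int(s), int(e)) for s, e in self.parts)
        for s, e in self.parts:
            if s == e:
                raise ValueError(f"zero-length part in feature {self.name!r}")

    @property
    def start(self) -> int:
        return self.parts[0][0]

    @property
    def end(self) -> int:
        return self.parts[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.parts)

    def shifted(self, offset: int) -> "Feature":
        return replace(self, parts=tuple((s + offset, e + offset) for s, e in self.parts))


@dataclass
class AnnotatedGenome:
    """A (typically circular, ~150 kb) plastid genome with its feature list."""

    sample_id: str
    sequence: str
    species: str = ""
    subgenus: str = ""
    circular: bool = True
    features: list[Feature] = field(default_factory=list)
    source_accession: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) == 0:
            raise ValueError(f"{self.sample_id}: empty sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"{self.sample_id}: non-DNA characters {sorted(bad)}")
        L = len(self.sequence)
        for f in self.features:
            for s, e in f.parts:
                if not (0 <= s < e <= L):
                    raise ValueError(
                        f"{self.sample_id}: feature {f.name!r} part [{s},{e}) "
                        f"outside genome of length {L}"
                    )

    def __len__(self) -> int:
        return len(self.sequence)

    def feature_seq(self, feat: Feature) -> str:
        s = "".join(self.sequence[a:b] for a, b in feat.parts)
        return revcomp(s) if feat.strand < 0 else s

    def features_of_kind(self, *kinds: str) -> list[Feature]:
        return [f for f in self.features if f.kind in kinds]


@dataclass
class Msa:
    """A whole-genome multiple alignment over {A,C,G,T,N,-}."""

    sample_ids: list[str]
    rows: list[str]
    reference_id: str = ""

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.rows):
            raise ValueError("sample_ids and rows differ in count")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            offenders = [
                sid for sid, r in zip(self.sample_ids, self.rows)
                if len(r) != len(self.rows[0])
            ]
            raise ValueError(f"ragged alignment rows for ids: {offenders}")
        self.rows = [r.upper() for r in self.rows]
        if not self.reference_id:
            self.reference_id = self.sample_ids[0]
        if self.reference_id not in self.sample_ids:
            raise ValueError(f"reference_id {self.reference_id!r} not among sample ids")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def row(self, sample_id: str) -> str:
        try:
            return self.rows[self.sample_ids.index(sample_id)]
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in alignment") from None

    def matrix(self, sample_ids: list[str] | None = None) -> np.ndarray:
        """Rows as a 2-D byte matrix (dtype S1), optionally row-subset."""
        ids = sample_ids if sample_ids is not None else self.sample_ids
        rows = [self.row(i) for i in ids]
        return np.frombuffer("".join(rows).encode(), dtype="S1").reshape(len(rows), -1)

    def subset(self, sample_ids: list[str]) -> "Msa":
        ref = self.reference_id if self.reference_id in sample_ids else sample_ids[0]
        return Msa(list(sample_ids), [self.row(i) for i in sample_ids], ref)


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------

def _location_parts(loc) -> tuple[tuple[int, int], ...]:
    if isinstance(loc, CompoundLocation):
        return tuple((int(p.start), int(p.end)) for p in loc.parts)
    return ((int(loc.start), int(loc.end)),)


def read_genbank(path) -> AnnotatedGenome:
    """Parse a GenBank flat file into an :class:`AnnotatedGenome`.

    Compound (``join``) locations are split into exon parts and the gaps
    between consecutive exons of one CDS/tRNA/rRNA become derived ``intron``
    features.  The circular flag is taken from the LOCUS line topology.
    """
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # Biopython raises assorted types on bad input
        raise ValueError(f"malformed GenBank record in {path}: {exc}") from exc
    seq = str(record.seq).upper()
    if not seq:
        raise ValueError(f"{path}: GenBank record has an empty sequence")
    circular = record.annotations.get("topology", "circular") == "circular"
    features: list[Feature] = []
    for bf in record.features:
        if bf.type not in ("gene", "CDS", "tRNA", "rRNA", "intron", "misc_feature",
                           "repeat_region"):
            continue
        kind = {"misc_feature": "misc"}.get(bf.type, bf.type)
        quals = bf.qualifiers
        name = (quals.get("gene") or quals.get("label") or quals.get("note") or [""])[0]
        parts = _location_parts(bf.location)
        strand = bf.location.strand or 1
        if strand < 0:
            parts = tuple(sorted(parts))
        features.append(Feature(kind=kind, name=name, parts=parts, strand=strand))
        # derive introns between consecutive exon parts
        if kind in ("CDS", "tRNA", "rRNA") and len(parts) > 1:
            ordered = sorted(parts)
            for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
                if e1 < s2:
                    features.append(
                        Feature(kind="intron", name=name, parts=((e1, s2),), strand=strand)
                    )
    meta = {}
    for bf in record.features:
        if bf.type == "source":
            q = bf.qualifiers
            meta["species"] = (q.get("organism") or [""])[0]
            meta["subgenus"] = (q.get("sub_species") or q.get("note") or [""])[0]
    return AnnotatedGenome(
        sample_id=record.id or record.name,
        sequence=seq,
        species=meta.get("species", record.annotations.get("organism", "")),
        subgenus=meta.get("subgenus", ""),
        circular=circular,
        features=features,
        source_accession=record.id or "",
    )


def write_genbank(genome: AnnotatedGenome, path) -> None:
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.sample_id,
        name=genome.sample_id[:16].replace(" ", "_") or "plastome",
        description=genome.species,
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if genome.circular else "linear",
            "organism": genome.species,
        },
    )
    record.features.append(
        SeqFeature(
            SimpleLocation(0, len(genome.sequence), strand=1),
            type="source",
            qualifiers={"organism": [genome.species], "note": [genome.subgenus]},
        )
    )
    for f in genome.features:
        if f.kind in ("intron", "IGS"):
            continue  # derived on read; GenBank records carry the primary kinds
        locs = [SimpleLocation(s, e, strand=f.strand) for s, e in f.parts]
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        bio_type = {"misc": "misc_feature"}.get(f.kind, f.kind)
        record.features.append(
            SeqFeature(loc, type=bio_type, qualifiers={"gene": [f.name]})
        )
    with open(path, "w") as fh:
        SeqIO.write(record, fh, "genbank")


# ---------------------------------------------------------------------------
# Intergenic spacers
# ---------------------------------------------------------------------------

def merged_gene_spans(genome: AnnotatedGenome) -> list[tuple[int, int, str]]:
    """Union of genic extents in genome order, as (start, end, name) triples.

    Overlapping or touching genic features are merged; the merged span keeps
    the name of its first (left-most) member.  `gene` container features are
    used when present, otherwise CDS/tRNA/rRNA extents.
    """
    feats = genome.features_of_kind("gene")
    if not feats:
        feats = genome.features_of_kind("CDS", "tRNA", "rRNA")
    if not feats:
        raise ValueError(f"{genome.sample_id}: no gene features to derive IGS from")
    ivals = sorted(
        (s, e, f.name) for f in feats for s, e in f.parts
    )
    merged: list[list] = []
    for s, e, name in ivals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e, name])
    return [(s, e, n) for s, e, n in merged]


def derive_igs(genome: AnnotatedGenome) -> AnnotatedGenome:
    """Return a copy of ``genome`` with IGS features filling inter-gene gaps.

    IGS features are named ``"geneA-geneB"`` after the flanking genes in
    circular genome order; on a circular genome the gap spanning the origin is
    emitted as a single wrapping feature.  Conservation holds by construction:
    total genic span + total IGS length == genome length.
    """
    L = len(genome)
    spans = merged_gene_spans(genome)
    feats = [f for f in genome.features if f.kind != "IGS"]
    for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
        if e1 < s2:
            feats.append(Feature("IGS", f"{n1}-{n2}", ((e1, s2),)))
    # gap around the origin (or trailing gap on a linear genome)
    last_s, last_e, last_n = spans[-1]
    first_s, first_e, first_n = spans[0]
    if genome.circular:
        if last_e < L and first_s > 0:
            feats.append(
                Feature("IGS", f"{last_n}-{first_n}", ((last_e, L), (0, first_s)))
            )
        elif last_e < L:
            feats.append(Feature("IGS", f"{last_n}-{first_n}", ((last_e, L),)))
        elif first_s > 0:
            feats.append(Feature("IGS", f"{last_n}-{first_n}", ((0, first_s),)))
    else:
        if first_s > 0:
            feats.append(Feature("IGS", f"start-{first_n}", ((0, first_s),)))
        if last_e < L:
            feats.append(Feature("IGS", f"{last_n}-end", ((last_e, L),)))
    return replace(genome, features=feats)


# ---------------------------------------------------------------------------
# FASTA / aligned FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_msa(path, reference_id: str = "") -> Msa:
    """Read an aligned FASTA; raises with the offending ids on ragged rows."""
    seqs = read_fasta(path)
    if not seqs:
        raise ValueError(f"{path}: no sequences found")
    return Msa(list(seqs), list(seqs.values()), reference_id or next(iter(seqs)))


def write_msa(msa: Msa, path) -> None:
    write_fasta(dict(zip(msa.sample_ids, msa.rows)), path)
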