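"""SNP-density hotspot discovery on the consensus coordinate system.

An exhaustive scan slides a window (default 1000 bp) at step 1 over the
consensus; windows containing strictly more than 10 SNP sites (>= ``min_snps``
= 11) qualify, and overlapping or adjacent qualifying windows are merged into
maximal hotspot regions whose counts and frequencies are recomputed on the
merged interval.  Merged regions may fall below the per-window density floor:
that is a property of merging, not an error.  Candidate regions are then
screened for tree concordance with seeded site-resampling replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plastome_io import Msa
from .variants import VariantTable
from . import phylo


@dataclass
class Window:
    start: int          # on consensus coordinates; may wrap the circle
    snp_count: int


@dataclass
class HotspotRegion:
    start: int
    end: int            # half-open; end > consensus length means wrap-around
    snp_count: int
    n_windows: int
    features: tuple[str, ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def snp_freq_pct(self) -> float:
        return round(100 * self.snp_count / self.length, 2)


def _snp_indicator(variants) -> np.ndarray:
    if isinstance(variants, VariantTable):
        n = len(variants.consensus.sequence)
        ind = np.zeros(n, dtype=np.int64)
        ind[variants.snp_positions_on_consensus()] = 1
        return ind
    return np.asarray(variants, dtype=np.int64)


def scan_windows(
    variants,
    window: int = 1000,
    step: int = 1,
    min_snps: int = 11,
    circular: bool = True,
) -> list[Window]:
    """Every window start whose window holds >= ``min_snps`` SNP sites.

    ``variants`` is a :class:`VariantTable` or a 0/1 SNP indicator array on
    consensus coordinates.  ``step=1`` is the exhaustive scan; wrap-around
    windows are included for circular genomes.
    """
    if window < 1 or min_snps < 1 or step < 1:
        raise ValueError("window, step and min_snps must all be >= 1")
    ind = _snp_indicator(variants)
    n = len(ind)
    if n < window:
        raise ValueError(f"window ({window}) larger than consensus ({n})")
    ext = np.concatenate([ind, ind[: window - 1]]) if circular else ind
    csum = np.concatenate([[0], np.cumsum(ext)])
    starts = np.arange(0, n if circular else n - window + 1, step)
    counts = csum[starts + window] - csum[starts]
    return [Window(int(s), int(c)) for s, c in zip(starts, counts) if c >= min_snps]


def merge_hotspots(
    windows: list[Window],
    window: int = 1000,
    variants=None,
    feature_names_on_consensus: np.ndarray | None = None,
    genome_length: int | None = None,
) -> list[HotspotRegion]:
    """Union overlapping/adjacent qualifying windows into maximal regions.

    SNP counts are recomputed on each merged interval.  On circular genomes a
    trailing wrap-around region is merged with a region starting at 0 when
    they touch.
    """
    if not windows:
        return []
    ind = _snp_indicator(variants) if variants is not None else None
    n = genome_length or (len(ind) if ind is not None else None)
    ivals = sorted((w.start, w.start + window) for w in windows)
    merged: list[list[int]] = []
    counts: list[int] = []
    for s, e in ivals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
            counts[-1] += 1
        else:
            merged.append([s, e])
            counts.append(1)
    # circular wrap: last region may extend past n and touch the first
    if n is not None and len(merged) > 1 and merged[-1][1] > n:
        overhang = merged[-1][1] - n
        if overhang >= merged[0][0]:
            merged[-1][1] = max(merged[-1][1], merged[0][1] + n)
            counts[-1] += counts[0]
            merged.pop(0)
            counts.pop(0)
    regions = []
    for (s, e), nw in zip(merged, counts):
        if ind is not None:
            ext = np.concatenate([ind, ind]) if e > len(ind) else ind
            count = int(ext[s:e].sum())
        else:
            count = -1
        feats: tuple[str, ...] = ()
        if feature_names_on_consensus is not None:
            fn = feature_names_on_consensus
            ext_f = np.concatenate([fn, fn]) if e > len(fn) else fn
            seen = []
            for name in ext_f[s:e]:
                if name and name not in seen:
                    seen.append(name)
            feats = tuple(seen)
        regions.append(HotspotRegion(start=int(s), end=int(e), snp_count=count,
                                     n_windows=int(nw), features=feats))
    return regions


def screen_markers(
    msa: Msa,
    regions: list[HotspotRegion],
    clade_map: dict[str, list[str]],
    variants: VariantTable,
    outgroup: str | None = None,
    n_replicates: int = 100,
    seed: int = 0,
    min_region_len: int = 100,
) -> pd.DataFrame:
    """Per-region tree concordance of labeled clades.

    For each region an NJ tree is built from the region's sub-alignment and
    the region is "concordant" when every clade in ``clade_map`` is
    monophyletic; ``n_replicates`` site-resampling replicates (sampling region
    columns with replacement, seeded) report the clade-recovery fraction, a
    stand-in for bootstrap support.
    """
    if len(msa.sample_ids) < 3 or len(clade_map) < 2:
        raise ValueError("need >= 3 samples and >= 2 clades")
    rng = np.random.default_rng(seed)
    cons_to_col = variants.consensus.cons_to_col
    n_cons = len(cons_to_col)
    mat = msa.matrix()
    rows = []
    for reg in regions:
        if reg.length < min_region_len:
            warnings.warn(f"hotspot region [{reg.start},{reg.end}) shorter than "
                          f"{min_region_len} bp: skipped")
            continue
        pos = np.arange(reg.start, reg.end) % n_cons
        cols = cons_to_col[pos]
        sub = mat[:, cols]
        concordant = _clades_monophyletic(sub, msa.sample_ids, clade_map, outgroup)
        hits = 0
        for _ in range(n_replicates):
            resampled = sub[:, rng.integers(0, sub.shape[1], sub.shape[1])]
            hits += _clades_monophyletic(resampled, msa.sample_ids, clade_map, outgroup)
        rows.append({
            "start": reg.start, "end": reg.end, "length_bp": reg.length,
            "snp_count": reg.snp_count,
            "features": ";".join(reg.features),
            "concordant": bool(concordant),
            "recovery_fraction": hits / n_replicates,
        })
    return pd.DataFrame(rows)


def _clades_monophyletic(sub: np.ndarray, ids, clade_map, outgroup) -> bool:
    try:
        dm = phylo.p_distance_matrix(sub)
    except ValueError:
        return False
    if not np.any(dm > 0):
        return False                    # zero variation: star tree, no signal
    tree = phylo.neighbor_joining(list(ids), dm)
    return all(
        phylo.is_monophyletic(tree, members, outgroup=outgroup)
        for members in clade_map.values()
    )
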