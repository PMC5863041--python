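"""V-plots, fragment-length profiles, K-means promoter classification.

A V-plot is the 2-D histogram of (oriented fragment-midpoint offset,
fragment length) around aligned anchors: protected particles produce
V-shaped densities whose apex height reads out the protected size.  At
single-site resolution coverage is sparse, so each site is summarized as a
21-bin fragment-length histogram (40-250 bp at 10 bp) and sites are
clustered with K-means into promoter configuration classes.

Midpoint convention: ``floor((start + end - 1) / 2)`` — the floor of the
mean of the two inclusive end coordinates; one fixed rule for even-length
fragments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .fragio import FragmentSet
from .footprint import _orientation_signs
from .peaks import Peak

LENGTH_BIN_MIN, LENGTH_BIN_MAX, LENGTH_BIN_WIDTH = 40, 250, 10
N_LENGTH_BINS = (LENGTH_BIN_MAX - LENGTH_BIN_MIN) // LENGTH_BIN_WIDTH  # 21


def fragment_midpoints(fs: FragmentSet) -> np.ndarray:
    s = fs.frags["start"].to_numpy()
    e = fs.frags["end"].to_numpy()
    return (s + e - 1) // 2


@dataclass
class VMatrix:
    """Counts indexed (length, offset) over [-W, W] x [Lmin, Lmax]."""

    W: int
    Lmin: int
    Lmax: int
    counts: np.ndarray            # shape (Lmax - Lmin + 1, 2W + 1)
    n_dropped: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts,
                            index=np.arange(self.Lmin, self.Lmax + 1),
                            columns=np.arange(-self.W, self.W + 1))


def vplot(fs: FragmentSet, anchors: pd.DataFrame, W: int = 500,
          Lmin: int = 1, Lmax: int = 250) -> VMatrix:
    """Accumulate (oriented midpoint offset, length) counts around anchors.

    Fragments with out-of-range midpoint or length are dropped and counted
    in ``n_dropped`` (per anchor; a fragment near two anchors contributes
    to both, which cannot happen at the simulator's >= 2 kb site spacing).
    """
    if Lmin >= Lmax:
        raise ValueError("Lmin must be < Lmax")
    signs = _orientation_signs(anchors)
    counts = np.zeros((Lmax - Lmin + 1, 2 * W + 1), dtype=np.int64)
    mids_all = fragment_midpoints(fs)
    lengths_all = fs.lengths
    chroms = fs.frags["chrom"].to_numpy()
    n_dropped = 0
    for (_, a), sign in zip(anchors.iterrows(), signs):
        near = (chroms == a["chrom"]) & (np.abs(mids_all - a["pos"]) <= W + Lmax)
        off = (mids_all[near] - a["pos"]) * sign
        ln = lengths_all[near]
        ok = (np.abs(off) <= W) & (ln >= Lmin) & (ln <= Lmax)
        n_dropped += int((~ok).sum())
        np.add.at(counts, (ln[ok] - Lmin, off[ok] + W), 1)
    return VMatrix(W, Lmin, Lmax, counts, n_dropped)


@dataclass
class LengthProfile:
    """Per-site fraction vector over the 21 length bins [40,250] @ 10 bp."""

    peak_id: str
    fractions: np.ndarray
    n_fragments: int

    @property
    def empty(self) -> bool:
        return self.n_fragments == 0

    @property
    def long_fraction(self) -> float:
        """Mass in bins >= 160 bp (the co-bound length class)."""
        return float(self.fractions[(160 - LENGTH_BIN_MIN) // LENGTH_BIN_WIDTH:].sum())


def _bin_lengths(lengths: np.ndarray) -> np.ndarray:
    """Histogram lengths into the 21 bins; 250 goes in the top bin."""
    keep = (lengths >= LENGTH_BIN_MIN) & (lengths <= LENGTH_BIN_MAX)
    idx = np.minimum((lengths[keep] - LENGTH_BIN_MIN) // LENGTH_BIN_WIDTH,
                     N_LENGTH_BINS - 1)
    return np.bincount(idx, minlength=N_LENGTH_BINS).astype(float)


def length_profile(peak: Peak, fs: FragmentSet, halfwidth: int = 100) -> LengthProfile:
    """Length histogram of fragments whose midpoint lies in the peak region.

    The peak region is summit +- ``halfwidth``; fragments with length in
    [40, 250] are binned at 10 bp (left-closed bins, top bin right-closed)
    and normalized to fractions.  A region with no in-range fragments
    yields an empty profile, excluded from clustering.
    """
    mids = fragment_midpoints(fs)
    near = ((fs.frags["chrom"].to_numpy() == peak.chrom)
            & (np.abs(mids - peak.center) <= halfwidth))
    counts = _bin_lengths(fs.lengths[near])
    n = int(counts.sum())
    fractions = counts / n if n else counts
    return LengthProfile(peak.name, fractions, n)


def profiles_for_sites(fs: FragmentSet, anchors: pd.DataFrame,
                       halfwidth: int = 100) -> list[LengthProfile]:
    """One length profile per anchor row (peak_id = anchor name)."""
    out = []
    for _, a in anchors.iterrows():
        pk = Peak(a["chrom"], a["pos"] - halfwidth, a["pos"] + halfwidth + 1,
                  summit=a["pos"], name=a["name"])
        out.append(length_profile(pk, fs, halfwidth))
    return out


@dataclass
class ClusterResult:
    labels: np.ndarray            # canonical 1..K per profile
    centroids: np.ndarray         # (K, 21), row k-1 = canonical cluster k
    long_fractions: np.ndarray    # per canonical cluster
    seed: int
    restarts: int

    def sizes(self) -> dict[int, int]:
        return {int(k): int((self.labels == k).sum())
                for k in range(1, len(self.centroids) + 1)}


def cluster_profiles(profiles: list[LengthProfile], K: int = 4, seed: int = 0,
                     restarts: int = 25) -> ClusterResult:
    """K-means on 21-dim fraction vectors, canonically relabeled.

    The best of ``restarts`` seeded k-means++ initializations (by
    within-cluster sum of squares) is relabeled by ascending centroid
    long-fraction (mass in bins >= 160 bp): label 1 is the
    shortest-dominated cluster, label K the long-fragment-dominated one.
    Empty profiles must be excluded by the caller.
    """
    if any(p.empty for p in profiles):
        raise ValueError("empty profiles must be excluded before clustering")
    X = np.stack([p.fractions for p in profiles])
    if len(X) < K:
        raise ValueError(f"need >= {K} profiles, got {len(X)}")
    km = KMeans(n_clusters=K, n_init=restarts, random_state=seed).fit(X)
    long_idx = (160 - LENGTH_BIN_MIN) // LENGTH_BIN_WIDTH
    longfrac = km.cluster_centers_[:, long_idx:].sum(axis=1)
    order = np.argsort(longfrac, kind="stable")        # raw label -> rank
    relabel = np.empty(K, dtype=np.int64)
    relabel[order] = np.arange(1, K + 1)
    return ClusterResult(
        labels=relabel[km.labels_],
        centroids=km.cluster_centers_[order],
        long_fractions=longfrac[order],
        seed=seed, restarts=restarts,
    )


def long_fragment_asymmetry(fs: FragmentSet, anchors: pd.DataFrame,
                            long_range: tuple[int, int] = (160, 220)) -> pd.Series:
    """TSS-distal asymmetry of long (co-bound) fragments per anchor.

    Among fragments with length in ``long_range`` (inclusive) overlapping
    the anchor position, the score is
    ``(upstream midpoints - downstream midpoints) / total`` in TSS-oriented
    coordinates, where upstream (negative offsets) is the TSS-distal side.
    +1 means every long fragment's midpoint is TSS-distal; anchors with no
    long fragments get NaN.
    """
    signs = _orientation_signs(anchors)
    lengths = fs.lengths
    mids = fragment_midpoints(fs)
    starts = fs.frags["start"].to_numpy()
    ends = fs.frags["end"].to_numpy()
    chroms = fs.frags["chrom"].to_numpy()
    lo, hi = long_range
    scores = {}
    for (_, a), sign in zip(anchors.iterrows(), signs):
        sel = ((chroms == a["chrom"]) & (lengths >= lo) & (lengths <= hi)
               & (starts <= a["pos"]) & (ends > a["pos"]))
        if not sel.any():
            scores[a["name"]] = np.nan
            continue
        off = (mids[sel] - a["pos"]) * sign
        up = int((off < 0).sum())
        down = int((off > 0).sum())
        scores[a["name"]] = (up - down) / sel.sum()
    return pd.Series(scores, name="asymmetry")
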