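"""A/B compartments, compartment switching, SAHF and LVS scores.

Compartment structure is read off the first principal component of the
Pearson correlation matrix of the observed/expected contact map: bins whose
contact profiles correlate form the euchromatic A and heterochromatic B
checkerboard. Scores are oriented so that gene-dense bins are positive (A).
Per-bin scores from two conditions are combined into transition categories
(AA, BB, BA, AB; BAB across three conditions), strongly negative scores mark
senescence-associated heterochromatic foci (SAHF), and the long-versus-short
(LVS) score measures the fraction of a bin's cis contacts reaching beyond a
distance cutoff (default 2 Mb).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from senhic.bins import GenomeBins
from senhic.matrix import ContactMatrix, observed_over_expected

logger = logging.getLogger(__name__)

SAHF_THRESHOLD_DEFAULT = -20.0
LVS_CUTOFF_DEFAULT = 2_000_000
MIN_COMPARTMENT_BINS = 5
MIN_PCA_BINS = 10

CATEGORIES = ("AA", "BB", "BA", "AB", "NA")


@dataclass
class PCATrack:
    """Per-bin compartment score derived from PC1.

    ``score`` is NaN at masked bins; the sign is fixed so that the track
    correlates positively with gene density. ``eigenvalue_fraction`` is the
    share of total variance carried by PC1.
    """

    bins: GenomeBins
    score: np.ndarray
    eigenvalue_fraction: float

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=float)
        if self.score.shape != (self.bins.n_bins,):
            raise ValueError("score length does not match bins")

    def defined(self) -> np.ndarray:
        return np.isfinite(self.score)


@dataclass(frozen=True)
class CompartmentSet:
    """Sorted, non-overlapping A/B intervals in bin coordinates.

    ``intervals`` is a list of ``(start_bin, end_bin_inclusive, label)``; each
    interval spans at least ``min_bins`` consecutive bins of one sign.
    """

    bins: GenomeBins
    intervals: tuple

    def labels(self) -> np.ndarray:
        """Per-bin label array: 'A', 'B', or '' where unassigned."""
        out = np.full(self.bins.n_bins, "", dtype=object)
        for s, e, lab in self.intervals:
            out[s:e + 1] = lab
        return out

    def sizes_bp(self, label: str | None = None) -> np.ndarray:
        """Interval sizes in bp, optionally restricted to one label."""
        return np.array([
            (e - s + 1) * self.bins.bin_size
            for s, e, lab in self.intervals
            if label is None or lab == label
        ])


@dataclass
class TransitionMap:
    """Per-bin compartment transition categories between two conditions."""

    bins: GenomeBins
    category: np.ndarray  # array of strings among CATEGORIES

    def __post_init__(self) -> None:
        self.category = np.asarray(self.category, dtype=object)
        if self.category.shape != (self.bins.n_bins,):
            raise ValueError("category length does not match bins")

    def bins_in(self, category: str) -> np.ndarray:
        return np.flatnonzero(self.category == category)

    def runs(self, categories=("BA", "AB")) -> list[tuple[int, int, str]]:
        """Maximal runs of identical category, for the given categories.

        Returned as ``(start_bin, end_bin_inclusive, category)``; these are
        the switch regions, typically small (100-500 kb).
        """
        out = []
        cat = self.category
        n = len(cat)
        i = 0
        while i < n:
            c = cat[i]
            j = i
            while j + 1 < n and cat[j + 1] == c:
                j += 1
            if c in categories:
                out.append((i, j, c))
            i = j + 1
        return out


@dataclass
class SAHFRegions:
    """Bins flagged as SAHF (score below threshold) plus contiguous regions."""

    bins: GenomeBins
    flagged: np.ndarray  # boolean per bin
    threshold: float

    def __post_init__(self) -> None:
        self.flagged = np.asarray(self.flagged, dtype=bool)

    def bin_indices(self) -> np.ndarray:
        return np.flatnonzero(self.flagged)

    def regions(self) -> list[tuple[int, int]]:
        """Maximal contiguous flagged runs as (start, end_inclusive)."""
        idx = self.bin_indices()
        if idx.size == 0:
            return []
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([idx[0]], idx[breaks + 1]))
        ends = np.concatenate((idx[breaks], [idx[-1]]))
        return list(zip(starts.tolist(), ends.tolist()))

    def region_sizes_bp(self) -> np.ndarray:
        return np.array([(e - s + 1) * self.bins.bin_size
                         for s, e in self.regions()])


@dataclass
class LVSTrack:
    """Per-bin fraction of cis contact mass beyond ``distance_cutoff``."""

    bins: GenomeBins
    lvs: np.ndarray
    distance_cutoff: int = LVS_CUTOFF_DEFAULT

    def __post_init__(self) -> None:
        self.lvs = np.asarray(self.lvs, dtype=float)
        finite = self.lvs[np.isfinite(self.lvs)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
            raise ValueError("LVS values outside [0, 1]")


def pca_scores(
    m: ContactMatrix,
    gene_density: np.ndarray,
    use_oe: bool = True,
    eigenvalue_floor: float = 0.05,
) -> PCATrack:
    """PC1 compartment scores of an ICE-normalized matrix.

    The Pearson correlation matrix of the observed/expected map (columns
    restricted to unmasked bins) is eigendecomposed; the per-bin score is the
    unit PC1 eigenvector entry scaled by ``sqrt(eigenvalue) * 100``. The
    global sign is flipped if the score correlates negatively with
    ``gene_density``, so gene-dense (A) bins come out positive. Zero-variance
    columns are moved into the mask. Masked bins are NaN.
    """
    gene_density = np.asarray(gene_density, dtype=float)
    if gene_density.shape != (m.n_bins,):
        raise ValueError("gene_density does not cover bins")
    if not m.normalized:
        logger.warning("pca_scores on unnormalized matrix")
    work = observed_over_expected(m) if use_oe else m

    keep = ~m.mask_array()
    sub = work.counts[np.ix_(keep, keep)]
    # drop zero-variance columns into the mask
    var = sub.var(axis=0)
    nzv = var > 0
    if not nzv.all():
        keep_idx = np.flatnonzero(keep)[~nzv]
        keep2 = keep.copy()
        keep2[keep_idx] = False
        keep = keep2
        sub = work.counts[np.ix_(keep, keep)]
    n_ok = keep.sum()
    if n_ok < MIN_PCA_BINS:
        raise ValueError(
            f"chromosome too short: {n_ok} unmasked bins (< {MIN_PCA_BINS})"
        )

    corr = np.corrcoef(sub)
    evals, evecs = np.linalg.eigh(corr)
    top = np.argmax(evals)
    lam = max(evals[top], 0.0)
    vec = evecs[:, top]
    frac = float(lam / np.clip(evals[evals > 0].sum(), 1e-300, None))
    if frac < eigenvalue_floor:
        warnings.warn(
            f"PC1 explains only {frac:.1%} of variance; "
            "compartment separation may be unreliable"
        )

    score = np.full(m.n_bins, np.nan)
    score[keep] = vec * np.sqrt(lam) * 100.0

    gd = gene_density[keep]
    if np.std(gd) > 0 and np.std(score[keep]) > 0:
        r = np.corrcoef(score[keep], gd)[0, 1]
        if r < 0:
            score = -score
    return PCATrack(m.bins, score, frac)


def call_compartments(t: PCATrack, min_bins: int = MIN_COMPARTMENT_BINS) -> CompartmentSet:
    """Call A/B compartments as maximal same-sign runs of at least ``min_bins``.

    A compartments are runs of positive score, B of negative score (five
    consecutive 40 kb bins by default). Shorter runs, zero scores and missing
    bins are left unassigned.
    """
    if min_bins < 1:
        raise ValueError("min_bins must be >= 1")
    sign = np.zeros(t.bins.n_bins, dtype=int)
    ok = t.defined()
    sign[ok & (t.score > 0)] = 1
    sign[ok & (t.score < 0)] = -1
    intervals = []
    n = len(sign)
    i = 0
    while i < n:
        s = sign[i]
        j = i
        while j + 1 < n and sign[j + 1] == s:
            j += 1
        if s != 0 and (j - i + 1) >= min_bins:
            intervals.append((i, j, "A" if s > 0 else "B"))
        i = j + 1
    return CompartmentSet(t.bins, tuple(intervals))


def classify_transitions(t1: PCATrack, t2: PCATrack) -> TransitionMap:
    """Per-bin compartment category between two conditions.

    The first letter encodes the sign in ``t1`` (+ -> A, - -> B), the second
    the sign in ``t2``; a missing or exactly-zero score in either condition
    gives NA. Swapping the conditions maps BA to AB and vice versa.
    """
    if t1.bins != t2.bins:
        raise ValueError("bin grids differ between conditions")
    n = t1.bins.n_bins
    cat = np.full(n, "NA", dtype=object)
    ok = t1.defined() & t2.defined() & (t1.score != 0) & (t2.score != 0)
    l1 = np.where(t1.score > 0, "A", "B")
    l2 = np.where(t2.score > 0, "A", "B")
    combined = np.char.add(l1.astype(str), l2.astype(str))
    cat[ok] = combined[ok]
    return TransitionMap(t1.bins, cat)


def classify_bab(trans_g_to_s: TransitionMap, trans_s_to_kd: TransitionMap) -> np.ndarray:
    """Flag bins that switch B->A upon senescence and back A->B upon KD.

    Returns a boolean array: True where the bin is BA in the first map and AB
    in the second.
    """
    if trans_g_to_s.bins != trans_s_to_kd.bins:
        raise ValueError("bin grids differ between transition maps")
    return (np.asarray(trans_g_to_s.category == "BA")
            & np.asarray(trans_s_to_kd.category == "AB"))


def detect_sahf(t: PCATrack, threshold: float = SAHF_THRESHOLD_DEFAULT) -> SAHFRegions:
    """Flag bins with compartment score strictly below ``threshold``.

    The default threshold of -20 follows the convention for 40 kb scores
    scaled as eigenvector x sqrt(eigenvalue) x 100; because the absolute
    scale depends on map size and depth, the threshold is a parameter (see
    :func:`sahf_threshold_from_scores` for a scale-free choice).
    """
    flagged = t.defined() & (t.score < threshold)
    return SAHFRegions(t.bins, flagged, threshold)


def sahf_threshold_from_scores(scores: np.ndarray) -> float:
    """Scale-free SAHF cutoff: Otsu split of the negative-score tail.

    SAHF bins form the strongly negative mode of the score distribution. The
    negative scores are split into two groups at the threshold minimizing
    within-group variance (Otsu's criterion, evaluated at every candidate
    split of the sorted values); the returned cutoff is the midpoint between
    the groups. Falls back to the median of negative scores when fewer than
    four negative bins exist.
    """
    scores = np.asarray(scores, dtype=float)
    neg = np.sort(scores[np.isfinite(scores) & (scores < 0)])
    if neg.size < 4:
        return float(np.median(neg)) if neg.size else 0.0
    best, best_cut = np.inf, neg[0]
    csum = np.cumsum(neg)
    csq = np.cumsum(neg ** 2)
    n = neg.size
    for k in range(1, n):  # lower group = neg[:k]
        n1, n2 = k, n - k
        s1, s2 = csum[k - 1], csum[-1] - csum[k - 1]
        q1, q2 = csq[k - 1], csq[-1] - csq[k - 1]
        w = (q1 - s1 ** 2 / n1) + (q2 - s2 ** 2 / n2)
        if w < best:
            best = w
            best_cut = 0.5 * (neg[k - 1] + neg[k])
    return float(best_cut)


def lvs_scores(m: ContactMatrix, distance_cutoff: int = LVS_CUTOFF_DEFAULT) -> LVSTrack:
    """Long-versus-short score: fraction of cis contacts beyond the cutoff.

    For each bin, ``lvs = (contact mass with partners > distance_cutoff away)
    / (total cis contact mass of the bin)``, with the diagonal excluded from
    both sums. Bins with zero total mass (incl. masked bins) are NaN.
    """
    n = m.n_bins
    counts = m.counts
    offdiag = counts - np.diag(np.diag(counts))
    total = offdiag.sum(axis=1)
    sep = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    long_mass = np.where(sep * m.bins.bin_size > distance_cutoff, counts, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        lvs = np.where(total > 0, long_mass / total, np.nan)
    masked = m.mask_array()
    lvs[masked] = np.nan
    return LVSTrack(m.bins, lvs, distance_cutoff)


def occupancy_stats(c1: CompartmentSet, c2: CompartmentSet,
                    tmap: TransitionMap) -> dict:
    """Compartment occupancy and size statistics for two conditions.

    Returns a dict with, per condition, the percent of assigned genome in
    A/B, compartment counts and size lists (bp), the percent of bins in each
    transition category, and two-sided Mann-Whitney p-values comparing A and
    B size distributions between conditions.
    """
    out: dict = {}
    for name, cs in (("condition1", c1), ("condition2", c2)):
        labels = cs.labels()
        assigned = int((labels != "").sum())
        entry = {"n_assigned_bins": assigned}
        for lab in "AB":
            sizes = cs.sizes_bp(lab)
            n_lab = int((labels == lab).sum())
            entry[f"{lab}_occupancy_pct"] = (
                100.0 * n_lab / assigned if assigned else float("nan"))
            entry[f"{lab}_count"] = int(sizes.size)
            entry[f"{lab}_sizes_bp"] = sizes
        out[name] = entry
    n = tmap.bins.n_bins
    out["transition_pct"] = {
        c: 100.0 * float((tmap.category == c).sum()) / n for c in CATEGORIES
    }
    for lab in "AB":
        s1, s2 = c1.sizes_bp(lab), c2.sizes_bp(lab)
        if s1.size and s2.size:
            out[f"{lab}_size_mannwhitney_p"] = float(
                stats.mannwhitneyu(s1, s2, alternative="two-sided",
                                   method="auto").pvalue)
        else:
            out[f"{lab}_size_mannwhitney_p"] = float("nan")
    return out


def chromosome_occupancy(flagged_by_chrom: dict[str, np.ndarray],
                         n_bins_by_chrom: dict[str, int]) -> dict[str, float]:
    """Percent of each chromosome's bins carrying a flag (e.g. SAHF)."""
    out = {}
    for chrom, n in n_bins_by_chrom.items():
        flags = np.asarray(flagged_by_chrom.get(chrom, np.zeros(0)))
        n_flag = int(flags.sum()) if flags.size else 0
        out[chrom] = 100.0 * n_flag / n if n else float("nan")
    return out


def occupancy_group_comparison(occupancy: dict[str, float],
                               group1: list[str], group2: list[str]):
    """Mann-Whitney two-sided comparison of per-chromosome occupancy groups.

    Mirrors the long-vs-short chromosome comparison (e.g. chromosomes 1-14
    vs 15-22). Returns ``(U, p)``.
    """
    a = [occupancy[c] for c in group1]
    b = [occupancy[c] for c in group2]
    if not a or not b:
        raise ValueError("both chromosome groups must be nonempty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)
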