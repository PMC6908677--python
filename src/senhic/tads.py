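"""TAD border-strength scores and border calling.

The border-strength score of a 40 kb bin compares contacts *within* the 13
bins on either side of it against contacts *between* the two flanks:

    R = (sum of contacts within upstream window
         + sum of contacts within downstream window)
        / (sum of contacts between the upstream and downstream windows)

Within-window sums run over unordered bin pairs (i < j), excluding the
diagonal; the between sum runs over all upstream x downstream pairs. R is
standardized genome-wide (mean subtracted, divided by SD) and TAD borders
are called as thresholded local maxima of the z-score. Borders are further
classified by replicate/condition specificity and compared against
compartment borders.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from senhic.bins import GenomeBins
from senhic.compartments import CompartmentSet
from senhic.enrichment import hypergeometric_overlap
from senhic.matrix import ContactMatrix

logger = logging.getLogger(__name__)

WINDOW_BINS_DEFAULT = 13
Z_MIN_DEFAULT = 1.0
TOLERANCE_BINS_DEFAULT = 1


@dataclass
class BorderStrengthTrack:
    """Raw R and z-scored border-strength profile of one chromosome.

    Bins within ``window_bins`` of either chromosome edge are NaN. z-scores
    are standardized over defined bins (pooled genome-wide when several
    chromosomes are standardized together via :func:`zscore_tracks`).
    """

    bins: GenomeBins
    raw_R: np.ndarray
    z_score: np.ndarray
    window_bins: int = WINDOW_BINS_DEFAULT

    def __post_init__(self) -> None:
        self.raw_R = np.asarray(self.raw_R, dtype=float)
        self.z_score = np.asarray(self.z_score, dtype=float)

    def defined(self) -> np.ndarray:
        return np.isfinite(self.raw_R)


@dataclass
class TADBorderSet:
    """Called border bins of one chromosome, with optional specificity labels."""

    bins: GenomeBins
    border_bins: np.ndarray
    labels: dict = field(default_factory=dict)  # border bin -> specificity

    def __post_init__(self) -> None:
        self.border_bins = np.asarray(sorted(np.asarray(self.border_bins, dtype=int)))

    def tad_segments(self) -> list[tuple[int, int]]:
        """TADs as (start_bin, end_bin_inclusive) between consecutive borders."""
        b = self.border_bins
        if b.size < 2:
            return []
        return [(int(b[k]), int(b[k + 1]) - 1) for k in range(b.size - 1)]

    def tad_sizes_bp(self) -> np.ndarray:
        return np.array([(e - s + 1) * self.bins.bin_size
                         for s, e in self.tad_segments()])


def _raw_border_strength(counts: np.ndarray, w: int,
                         masked: np.ndarray | None = None) -> np.ndarray:
    """Eq.-style R profile via a summed-area table; edges NaN.

    For bin b, upstream window is bins [b-w, b-1], downstream [b+1, b+w];
    within sums count each unordered pair once, diagonal excluded. When a
    mask is given, each window sum is rescaled by the ratio of the expected
    (distance-decay) mass of the full window to that of its unmasked pairs —
    identical to the plain ratio on mask-free input, but immune to the
    spurious insulation a zeroed bin would otherwise create. Bins whose
    windows retain no unmasked expected mass are NaN.
    """
    n = counts.shape[0]
    R = np.full(n, np.nan)
    if masked is None:
        masked = np.zeros(n, dtype=bool)

    def sat(mat):
        S = np.zeros((n + 1, n + 1))
        S[1:, 1:] = mat.cumsum(axis=0).cumsum(axis=1)
        return S

    def block(S, r0, r1, c0, c1):
        # sum of mat[r0:r1, c0:c1]
        return S[r1, c1] - S[r0, c1] - S[r1, c0] + S[r0, c0]

    S = sat(counts)
    csum_diag = np.concatenate(([0.0], np.cumsum(np.diag(counts))))

    any_masked = bool(masked.any())
    if any_masked:
        # expected contact by separation, from unmasked pairs
        ok = ~masked
        exp = np.zeros(n)
        for d in range(1, 2 * w + 1):
            i = np.arange(n - d)
            keep = ok[i] & ok[i + d]
            exp[d] = counts[i[keep], i[keep] + d].mean() if keep.any() else 0.0
        sep = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        emat_full = exp[np.clip(sep, 0, n - 1)]
        emat_ok = emat_full * np.outer(ok, ok)
        Ef, Eo = sat(emat_full), sat(emat_ok)

    genome_mean = counts.mean()
    eps = 1e-6 * genome_mean if genome_mean > 0 else 1e-12
    for b in range(w, n - w):
        u0, u1 = b - w, b          # upstream bins [u0, u1)
        d0, d1 = b + 1, b + 1 + w  # downstream bins [d0, d1)
        within_up = 0.5 * (block(S, u0, u1, u0, u1) - (csum_diag[u1] - csum_diag[u0]))
        within_down = 0.5 * (block(S, d0, d1, d0, d1) - (csum_diag[d1] - csum_diag[d0]))
        between = block(S, u0, u1, d0, d1)
        if any_masked:
            scales = []
            for (r0, r1, c0, c1) in ((u0, u1, u0, u1), (d0, d1, d0, d1),
                                     (u0, u1, d0, d1)):
                full = block(Ef, r0, r1, c0, c1)
                have = block(Eo, r0, r1, c0, c1)
                if have <= 0:
                    scales = None
                    break
                scales.append(full / have)
            if scales is None:
                continue
            within_up *= scales[0]
            within_down *= scales[1]
            between *= scales[2]
        R[b] = (within_up + within_down) / max(between, eps)
    return R


def raw_border_strength(counts: np.ndarray, window_bins: int = WINDOW_BINS_DEFAULT,
                        masked: np.ndarray | None = None) -> np.ndarray:
    """Un-standardized R profile for a raw counts array (edges NaN)."""
    if window_bins < 1:
        raise ValueError(f"window must be >= 1, got {window_bins}")
    return _raw_border_strength(np.asarray(counts, dtype=float), window_bins, masked)


def border_strength(m: ContactMatrix, window_bins: int = WINDOW_BINS_DEFAULT) -> BorderStrengthTrack:
    """Compute the border-strength profile of one chromosome and z-score it.

    For genome-wide (pooled) standardization across chromosomes compute the
    raw profiles first and use :func:`zscore_tracks`; this convenience
    function standardizes over the single chromosome's defined bins.
    """
    if window_bins < 1:
        raise ValueError(f"window must be >= 1, got {window_bins}")
    if not m.normalized:
        logger.warning("border_strength on unnormalized matrix")
    R = _raw_border_strength(m.counts, window_bins, m.mask_array())
    track = BorderStrengthTrack(m.bins, R, np.full_like(R, np.nan), window_bins)
    zscore_tracks([track])
    return track


def zscore_tracks(tracks: list[BorderStrengthTrack]) -> None:
    """Standardize raw R in place, pooled across the given tracks.

    The mean over all defined bins is subtracted and the result divided by
    the pooled SD. If the SD is zero every z is set to 0 with a warning.
    """
    pooled = np.concatenate([t.raw_R[t.defined()] for t in tracks])
    if pooled.size == 0:
        return
    mu = pooled.mean()
    sd = pooled.std()
    degenerate = sd <= 1e-12 * max(abs(mu), 1.0)
    for t in tracks:
        ok = t.defined()
        z = np.full_like(t.raw_R, np.nan)
        if degenerate:
            logger.warning("border-strength SD is zero; all z set to 0")
            z[ok] = 0.0
        else:
            z[ok] = (t.raw_R[ok] - mu) / sd
        t.z_score = z


def call_tad_borders(t: BorderStrengthTrack, z_min: float = Z_MIN_DEFAULT) -> TADBorderSet:
    """Call borders as local maxima of the z profile with ``z >= z_min``.

    A border bin is strictly greater than both neighbors; a flat plateau of
    equal values flanked by lower values yields its leftmost bin. NaN edges
    never qualify.
    """
    z = t.z_score
    n = len(z)
    borders = []
    i = 0
    while i < n:
        if not np.isfinite(z[i]) or z[i] < z_min:
            i += 1
            continue
        # extend plateau
        j = i
        while j + 1 < n and np.isfinite(z[j + 1]) and z[j + 1] == z[i]:
            j += 1
        left_ok = i == 0 or not np.isfinite(z[i - 1]) or z[i - 1] < z[i]
        right_ok = j == n - 1 or not np.isfinite(z[j + 1]) or z[j + 1] < z[i]
        # chromosome-edge NaNs do not count as lower neighbors for maxima:
        # require at least one finite lower neighbor on each defined side
        if i > 0 and not np.isfinite(z[i - 1]):
            left_ok = False
        if j < n - 1 and not np.isfinite(z[j + 1]):
            right_ok = False
        if left_ok and right_ok and 0 < i and j < n - 1:
            borders.append(i)
        i = j + 1
    return TADBorderSet(t.bins, np.array(borders, dtype=int))


def _present_within(border: int, border_set: np.ndarray, tol: int) -> bool:
    if border_set.size == 0:
        return False
    return bool(np.min(np.abs(border_set - border)) <= tol)


def classify_border_specificity(
    growing_reps: list[TADBorderSet],
    ois_reps: list[TADBorderSet],
    tolerance_bins: int = TOLERANCE_BINS_DEFAULT,
) -> TADBorderSet:
    """Label borders by replicate/condition presence.

    With presence matching allowing a shift of ``tolerance_bins``:
    G-specific borders are present in *all* growing replicates and in no
    senescent (OIS) replicate; OIS-specific borders in at least two OIS
    replicates and no growing replicate; remaining borders present in at
    least two datasets are non-specific; anything else is unclassified.
    """
    if len(growing_reps) < 2 or len(ois_reps) < 2:
        raise ValueError("need >= 2 replicates per condition")
    bins = growing_reps[0].bins
    all_sets = [r.border_bins for r in growing_reps] + [r.border_bins for r in ois_reps]
    n_g = len(growing_reps)

    # cluster candidate borders: union, grouped within tolerance
    union = np.unique(np.concatenate([s for s in all_sets if s.size] or [np.zeros(0, int)]))
    labels: dict[int, str] = {}
    k = 0
    while k < union.size:
        j = k
        while j + 1 < union.size and union[j + 1] - union[j] <= tolerance_bins:
            j += 1
        center = int(round(union[k:j + 1].mean()))
        in_g = [_present_within(center, s, tolerance_bins)
                for s in all_sets[:n_g]]
        in_o = [_present_within(center, s, tolerance_bins)
                for s in all_sets[n_g:]]
        n_total = sum(in_g) + sum(in_o)
        if all(in_g) and not any(in_o):
            lab = "G-specific"
        elif sum(in_o) >= 2 and not any(in_g):
            lab = "OIS-specific"
        elif n_total >= 2:
            lab = "non-specific"
        else:
            lab = "unclassified"
        labels[center] = lab
        k = j + 1
    borders = np.array(sorted(labels), dtype=int)
    return TADBorderSet(bins, borders, labels)


def compartment_borders(c: CompartmentSet) -> np.ndarray:
    """Bins where the compartment label changes.

    A border is the first bin of a compartment whose label differs from the
    nearest preceding compartment's label; a chromosome with a single
    compartment has no borders.
    """
    borders = []
    prev_label = None
    for s, e, lab in c.intervals:
        if prev_label is not None and lab != prev_label:
            borders.append(s)
        prev_label = lab
    return np.array(borders, dtype=int)


def condition_specific_borders(b1: np.ndarray, b2: np.ndarray,
                               tolerance_bins: int = TOLERANCE_BINS_DEFAULT) -> np.ndarray:
    """Borders in ``b1`` with no counterpart in ``b2`` within tolerance."""
    b1 = np.asarray(b1, dtype=int)
    b2 = np.asarray(b2, dtype=int)
    return np.array([b for b in b1 if not _present_within(b, b2, tolerance_bins)],
                    dtype=int)


def border_overlap_fraction(
    tad_borders: TADBorderSet,
    comp_borders: np.ndarray,
    tolerance_bins: int = TOLERANCE_BINS_DEFAULT,
) -> tuple[float, float, int]:
    """Fraction of TAD borders within tolerance of a compartment border.

    Returns ``(fraction, hypergeometric_p, overlap_count)``. The enrichment
    p-value treats bins within ``tolerance_bins`` of a compartment border as
    successes in the population of all bins, and the TAD borders as the
    draw. With an empty TAD border set the fraction and p are NaN.
    """
    tb = tad_borders.border_bins
    comp_borders = np.asarray(comp_borders, dtype=int)
    if tb.size == 0:
        return float("nan"), float("nan"), 0
    hits = np.array([_present_within(b, comp_borders, tolerance_bins) for b in tb])
    overlap = int(hits.sum())
    frac = overlap / tb.size
    n_bins = tad_borders.bins.n_bins
    near = np.zeros(n_bins, dtype=bool)
    for b in comp_borders:
        near[max(0, b - tolerance_bins):min(n_bins, b + tolerance_bins + 1)] = True
    res = hypergeometric_overlap(set(tb.tolist()),
                                 set(np.flatnonzero(near).tolist()),
                                 n_bins)
    return frac, res.p_value, overlap
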