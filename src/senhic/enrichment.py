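"""Enrichment and association statistics linking genome reorganization to
gene regulation.

The module holds the statistical layer of the pipeline: hypergeometric /
Fisher overlap tests computed in log space (replicate overlaps of switching
regions can reach p ~ 1e-4000), Benjamini-Hochberg correction, pre-ranked
gene-set enrichment analysis (GSEA) with a gene-label permutation null,
gene-to-SAHF distance-window analysis, per-category signal-track summaries,
metagene profiles, compartment-level contact-change ranking, Mann-Whitney
comparisons, ordinary R^2, and background-corrected immunofluorescence
quantification.

Gene tables are plain pandas DataFrames with columns ``gene_id, chrom,
start, end, strand`` plus expression / fold-change columns named by the
caller (fold changes are condition ratios, e.g. senescent / growing).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# overlap tests

@dataclass(frozen=True)
class OverlapResult:
    """Upper-tail hypergeometric overlap between two bin/gene sets."""

    overlap: int
    size1: int
    size2: int
    population: int
    p_value: float
    log10_p: float


def hypergeometric_overlap(set1: Iterable, set2: Iterable, population: int) -> OverlapResult:
    """Upper-tail P(X >= observed overlap) for two sets drawn from a population.

    Computed in log space so that extremely small tails (down to ~1e-5000)
    remain representable in ``log10_p`` even when ``p_value`` underflows to
    zero. Equivalent to a one-sided Fisher exact test on the 2x2 table.
    """
    s1, s2 = set(set1), set(set2)
    if population <= 0:
        raise ValueError("population must be positive")
    if len(s1) > population or len(s2) > population:
        raise ValueError("set larger than population")
    k = len(s1 & s2)
    if k == 0:
        return OverlapResult(0, len(s1), len(s2), population, 1.0, 0.0)
    logp = stats.hypergeom.logsf(k - 1, population, len(s1), len(s2))
    logp = min(logp, 0.0)
    return OverlapResult(k, len(s1), len(s2), population,
                         float(np.exp(logp)), float(logp / np.log(10)))


def benjamini_hochberg(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment of a vector of p-values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# pre-ranked GSEA

@dataclass(frozen=True)
class GSEAResult:
    """Pre-ranked GSEA outcome.

    ``es`` is the weighted Kolmogorov-Smirnov enrichment score, ``nes`` the
    score normalized by the mean |null ES| of the same sign, and ``p_value``
    the permutation p among same-sign null scores (floor 1/(n_same_sign+1)).
    """

    es: float
    nes: float
    p_value: float
    n_perm: int
    seed: int
    set_size: int
    n_genes: int


def _running_es(positions: np.ndarray, weights: np.ndarray, n_genes: int) -> np.ndarray:
    """Signed extreme of the GSEA running sum for each row of hit positions.

    ``positions`` are sorted 0-based ranks of the set members, one row per
    permutation; ``weights`` the matching |score|^w values. Hits step the sum
    up by weight/sum(weights); misses step it down by 1/(N-k).
    """
    n_rows, k = positions.shape
    nr = weights.sum(axis=1, keepdims=True)
    flat = nr[:, 0] == 0
    if np.any(flat):  # all-zero scores in the set: fall back to equal weights
        weights = weights.copy()
        weights[flat] = 1.0
        nr = weights.sum(axis=1, keepdims=True)
    miss_step = 1.0 / (n_genes - k)
    j = np.arange(k)
    cum = np.cumsum(weights, axis=1)
    misses_before = positions - j  # misses strictly before each hit
    after = cum / nr - misses_before * miss_step
    before = (cum - weights) / nr - misses_before * miss_step
    max_dev = after.max(axis=1)
    min_dev = np.minimum(before.min(axis=1), 0.0)
    return np.where(max_dev >= -min_dev, max_dev, min_dev)


def preranked_gsea(
    ranked: Mapping[str, float] | pd.Series,
    gene_set: Iterable[str],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> GSEAResult:
    """Pre-ranked GSEA with a gene-label permutation null.

    ``ranked`` maps gene ids to ranking scores (e.g. log fold changes); genes
    are ordered by decreasing score. The enrichment score is the signed
    extreme of the weighted KS running sum (weights ``|score|**weight``); the
    null redraws the set's positions uniformly without replacement,
    preserving set size. NES divides ES by the mean |null ES| of the same
    sign; the p-value counts same-sign null scores at least as extreme, with
    the usual +1 guard.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    s = pd.Series(ranked, dtype=float) if not isinstance(ranked, pd.Series) else ranked.astype(float)
    order = np.argsort(-s.to_numpy(), kind="stable")
    genes = s.index.to_numpy()[order]
    scores = s.to_numpy()[order]
    n_genes = len(genes)
    members = set(gene_set)
    hit = np.isin(genes, list(members))
    k = int(hit.sum())
    if k == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if k == n_genes:
        raise ValueError("degenerate set: contains every ranked gene")

    w = np.abs(scores) ** weight
    obs_pos = np.flatnonzero(hit)
    es = float(_running_es(obs_pos[None, :], w[obs_pos][None, :], n_genes)[0])

    rng = np.random.default_rng(seed)
    # k positions without replacement per permutation, vectorized
    r = rng.random((n_perm, n_genes))
    null_pos = np.sort(np.argpartition(r, k - 1, axis=1)[:, :k], axis=1)
    null_es = _running_es(null_pos, w[null_pos], n_genes)

    same = null_es > 0 if es >= 0 else null_es < 0
    n_same = int(same.sum())
    if n_same:
        nes = es / float(np.abs(null_es[same]).mean())
        n_extreme = int((np.abs(null_es[same]) >= abs(es)).sum())
        p = (1 + n_extreme) / (1 + n_same)
    else:
        nes = float("nan")
        p = 1.0 / (1 + n_perm)
    return GSEAResult(es, float(nes), float(p), n_perm, seed, k, n_genes)


# ---------------------------------------------------------------------------
# SAHF distance windows

def gene_sahf_distances(genes: pd.DataFrame, sahf_regions_bp: Mapping[str, list]) -> pd.Series:
    """Distance (bp) from each gene body to the nearest SAHF edge.

    ``sahf_regions_bp`` maps chromosome names to lists of 0-based half-open
    ``(start, end)`` intervals. Distance is the gap between the gene interval
    and the closest interval on the same chromosome, 0 on overlap, NaN on
    chromosomes without SAHF.
    """
    out = np.full(len(genes), np.nan)
    for chrom, sub in genes.groupby("chrom"):
        regions = sahf_regions_bp.get(chrom, [])
        if not regions:
            continue
        rs = np.array([r[0] for r in regions])
        re_ = np.array([r[1] for r in regions])
        gs = sub["start"].to_numpy()
        ge = sub["end"].to_numpy()
        # gap between [gs,ge) and [rs,re): max(0, rs-ge, gs-re)
        gap = np.maximum.reduce([
            np.zeros((len(sub), len(regions))),
            rs[None, :] - ge[:, None],
            gs[:, None] - re_[None, :],
        ])
        out[genes.index.get_indexer(sub.index)] = gap.min(axis=1)
    return pd.Series(out, index=genes.index, name="sahf_distance")


def genes_in_distance_windows(
    genes: pd.DataFrame,
    sahf_regions_bp: Mapping[str, list],
    window_start: int,
    window_end: int,
) -> list[str]:
    """Gene ids whose distance to the nearest SAHF lies in [start, end)."""
    if window_start >= window_end:
        raise ValueError("window_start must be < window_end")
    d = gene_sahf_distances(genes, sahf_regions_bp)
    sel = (d >= window_start) & (d < window_end)
    return genes.loc[sel.fillna(False), "gene_id"].tolist()


def window_sweep(
    genes: pd.DataFrame,
    sahf_regions_bp: Mapping[str, list],
    contrast: str,
    window_size: int = 200_000,
    max_distance: int = 1_400_000,
    cumulative: bool = False,
) -> pd.DataFrame:
    """Fraction of downregulated genes per distance window from SAHF.

    Sliding windows of ``window_size`` (or cumulative windows [0, end)) up
    to ``max_distance``; each row reports the window, the number of genes
    and the percent with fold change < 1 in ``contrast``.
    """
    rows = []
    starts = range(0, max_distance, window_size)
    for ws in starts:
        lo = 0 if cumulative else ws
        hi = ws + window_size
        ids = genes_in_distance_windows(genes, sahf_regions_bp, lo, hi)
        pct = fraction_downregulated(ids, genes, contrast)
        rows.append({"window_start": lo, "window_end": hi,
                     "n_genes": len(ids), "pct_downregulated": pct})
    return pd.DataFrame(rows)


def fraction_downregulated(gene_ids: Iterable[str], genes: pd.DataFrame,
                           contrast: str) -> float:
    """Percent of the given genes with fold change strictly below 1."""
    ids = list(gene_ids)
    if not ids:
        return float("nan")
    sub = genes.set_index("gene_id").loc[ids, contrast]
    return 100.0 * float((sub < 1).mean())


def mann_whitney(a: Iterable[float], b: Iterable[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; exact for small tie-free samples.

    Returns ``(U, p)``. The exact null distribution is used when both
    samples are small (min n <= 8) and tie-free; otherwise the normal
    approximation with tie correction applies.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# per-category track summaries and metagene profiles

def summarize_track_by_category(
    track: np.ndarray,
    tmap,
    n_sample: int = 500,
    seed: int = 0,
    categories: tuple = ("AA", "BB", "BA", "AB"),
) -> dict:
    """Sample bins per compartmental category and summarize a signal track.

    For each category, ``n_sample`` bins are drawn without replacement (all
    bins if fewer are available, with a warning); returns the sampled value
    distributions and pairwise two-sided Mann-Whitney p-values.
    """
    track = np.asarray(track, dtype=float)
    rng = np.random.default_rng(seed)
    samples: dict[str, np.ndarray] = {}
    for cat in categories:
        idx = tmap.bins_in(cat)
        idx = idx[np.isfinite(track[idx])]
        if idx.size == 0:
            warnings.warn(f"category {cat} empty; skipped")
            continue
        if idx.size < n_sample:
            warnings.warn(
                f"category {cat} has only {idx.size} bins (< {n_sample}); using all")
            chosen = idx
        else:
            chosen = rng.choice(idx, size=n_sample, replace=False)
        samples[cat] = track[np.sort(chosen)]
    pairwise = {}
    cats = list(samples)
    for i, c1 in enumerate(cats):
        for c2 in cats[i + 1:]:
            pairwise[(c1, c2)] = mann_whitney(samples[c1], samples[c2])[1]
    return {"samples": samples, "pairwise_p": pairwise}


def metagene_profile(
    track: Mapping[str, np.ndarray],
    bin_size: int,
    genes: pd.DataFrame,
    expression: str,
    n_groups: int = 10,
    n_points: int = 50,
    flank_bp: int = 100_000,
    n_flank_points: int = 25,
) -> pd.DataFrame:
    """Average signal over length-normalized gene bodies, by expression group.

    Genes are split into ``n_groups`` quantile groups of the ``expression``
    column (group 0 lowest). Each gene body is rescaled to ``n_points``
    positions running TSS to TES (strand-aware), with ``flank_bp`` flanks
    sampled at ``n_flank_points`` points on each side. Returns a DataFrame
    indexed by group with one column per profile position; genes shorter
    than one bin are skipped (count logged).
    """
    ranks = genes[expression].rank(method="first")
    group = np.minimum((ranks - 1) * n_groups // len(genes), n_groups - 1).astype(int)
    total = n_points + 2 * n_flank_points
    sums = np.zeros((n_groups, total))
    counts = np.zeros(n_groups)
    skipped = 0
    for (_, g), grp in zip(genes.iterrows(), group):
        chrom = g["chrom"]
        if chrom not in track:
            continue
        values = track[chrom]
        length = g["end"] - g["start"]
        if length < bin_size:
            skipped += 1
            continue
        body = g["start"] + (np.arange(n_points) + 0.5) / n_points * length
        up = g["start"] - flank_bp + (np.arange(n_flank_points) + 0.5) / n_flank_points * flank_bp
        down = g["end"] + (np.arange(n_flank_points) + 0.5) / n_flank_points * flank_bp
        pos = np.concatenate([up, body, down])
        idx = np.clip((pos // bin_size).astype(int), 0, len(values) - 1)
        prof = values[idx]
        if g.get("strand", "+") == "-":
            prof = prof[::-1]
        sums[grp] += prof
        counts[grp] += 1
    if skipped:
        logger.info("metagene_profile skipped %d sub-bin genes", skipped)
    with np.errstate(invalid="ignore"):
        mean = sums / counts[:, None]
    return pd.DataFrame(mean, index=pd.RangeIndex(n_groups, name="group"))


# ---------------------------------------------------------------------------
# compartment-level contact change

def rank_compartment_contact_change(
    m_cond1,
    m_cond2,
    comps,
    bottom_fraction: float = 0.10,
    label: str = "A",
    fine_bin_size: int | None = None,
) -> pd.DataFrame:
    """Rank compartments by the ratio of within-compartment O/E contact.

    Both matrices must share one (coarse, e.g. 200 kb) grid; ``comps`` may be
    called on a finer grid (pass its bin size as ``fine_bin_size``). For each
    compartment with the requested label the mean within-compartment O/E is
    computed in each condition; the relative score is cond1/cond2 and
    compartments are ranked ascending (ties broken by start coordinate). The
    bottom ``bottom_fraction`` are marked selected — these are the
    compartments losing the most internal contact in condition 1.
    """
    from senhic.matrix import observed_over_expected

    if m_cond1.bins != m_cond2.bins:
        raise ValueError("matrices must share a bin grid")
    if not 0 < bottom_fraction <= 1:
        raise ValueError("bottom_fraction must be in (0, 1]")
    factor = 1
    if fine_bin_size is not None:
        if m_cond1.bins.bin_size % fine_bin_size:
            raise ValueError("coarse bin size must be a multiple of fine")
        factor = m_cond1.bins.bin_size // fine_bin_size
    oe1 = observed_over_expected(m_cond1).counts
    oe2 = observed_over_expected(m_cond2).counts
    masked = m_cond1.mask_array() | m_cond2.mask_array()
    rows = []
    for s, e, lab in comps.intervals:
        if lab != label:
            continue
        cs, ce = s // factor, e // factor  # inclusive coarse range
        idx = np.arange(cs, min(ce + 1, m_cond1.n_bins))
        idx = idx[~masked[idx]]
        if idx.size == 0:
            continue
        ii, jj = np.triu_indices(idx.size)
        v1 = oe1[idx[ii], idx[jj]].mean()
        v2 = oe2[idx[ii], idx[jj]].mean()
        rel = v1 / v2 if v2 > 0 else np.nan
        rows.append({"start_bin": s, "end_bin": e, "label": lab,
                     "mean_oe_cond1": v1, "mean_oe_cond2": v2,
                     "relative": rel})
    df = pd.DataFrame(rows)
    if df.empty:
        df["selected"] = []
        return df
    df = df.sort_values(["relative", "start_bin"], kind="stable").reset_index(drop=True)
    n_sel = int(np.ceil(bottom_fraction * len(df)))
    df["selected"] = np.arange(len(df)) < n_sel
    return df


def genes_in_intervals(genes: pd.DataFrame, chrom: str,
                       intervals_bp: list) -> list[str]:
    """Gene ids overlapping any of the given (start, end) bp intervals."""
    sub = genes[genes["chrom"] == chrom]
    ids: list[str] = []
    for start, end in intervals_bp:
        hit = sub[(sub["end"] > start) & (sub["start"] < end)]
        ids.extend(hit["gene_id"].tolist())
    return sorted(set(ids))


# ---------------------------------------------------------------------------
# small helpers

def linear_r2(x: Iterable[float], y: Iterable[float]) -> float:
    """Coefficient of determination of an ordinary least-squares line fit."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance; R^2 undefined")
        return float("nan")
    res = stats.linregress(x, y)
    return float(res.rvalue ** 2)


class NuclearSignal(NamedTuple):
    signal: float
    negative: bool


def quantify_nuclear_signal(total_nuclear: float, nuclear_area_px: float,
                            background_density: float) -> NuclearSignal:
    """Background-corrected total immunofluorescence signal per nucleus.

    ``total - area * density``; a negative corrected value is reported
    as-is but flagged.
    """
    if total_nuclear < 0 or nuclear_area_px < 0 or background_density < 0:
        raise ValueError("inputs must be non-negative")
    v = total_nuclear - nuclear_area_px * background_density
    return NuclearSignal(float(v), v < 0)
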