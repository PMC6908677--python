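"""Synthetic Hi-C data with planted, exported ground truth.

The generator emulates the statistical structure the analysis assumes:

* alternating multi-megabase A/B compartment blocks producing a checkerboard
  in the contact map;
* small (100-500 kb) B-to-A transitions in the "senescent" condition, fewer
  A-to-B transitions, and a subset of BA regions flipped back to B in the
  condensin-depleted "kd" condition (BAB);
* TAD blocks (~400 kb) nested within compartment blocks;
* SAHF-like blocks inside persistent-B compartments whose mutual contacts
  beyond 2 Mb are boosted in senescent conditions;
* power-law distance decay P(s) ~ s^-alpha, ICE-correctable multiplicative
  per-bin biases, and Poisson-sampled counts;
* gene expression fold changes coupled to transitions (BA up, AB down, a
  downshift ring near SAHF) plus heterochromatin/condensin-like signal
  tracks and a gene-density track for compartment-sign orientation.

Everything is deterministic under a fixed seed; the exported truth suffices
to score recovery in every downstream module without re-running the
generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from senhic.bins import GenomeBins
from senhic.matrix import ContactMatrix

CONDITIONS = ("growing", "senescent", "kd")
_COND_INDEX = {c: i + 1 for i, c in enumerate(CONDITIONS)}


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults define the package's study conditions.

    Lengths are bp, effects log2 units, multipliers dimensionless (> 0).
    """

    chromosomes: tuple = (("chr1", 40_000_000), ("chr2", 40_000_000))
    bin_size: int = 40_000
    # compartment architecture
    mean_block_bp: int = 2_000_000       # mean A/B block length
    min_block_bp: int = 600_000          # floor so transitions fit inside
    transition_fraction: float = 0.10    # fraction of bins switching G->S
    ba_ab_ratio: float = 2.0             # BA transitions outnumber AB
    transition_min_bp: int = 100_000
    transition_max_bp: int = 500_000
    bab_fraction: float = 0.5            # BA regions reverting upon KD
    # TADs
    tad_min_bp: int = 320_000            # 8 bins
    tad_max_bp: int = 480_000            # 12 bins; mean ~400 kb
    # contact model
    decay_exponent: float = 1.0
    checkerboard: float = 1.6            # same-compartment multiplier
    tad_strength: float = 3.0            # same-TAD multiplier
    sahf_boost: float = 3.0              # SAHF-SAHF pairs beyond the cutoff
    sahf_long_range_bp: int = 2_000_000
    sahf_block_fraction: float = 0.3     # persistent-B blocks becoming SAHF
    bias_sd: float = 0.5                 # log-normal per-bin bias sigma
    depth: float = 60.0                  # mean expected counts per pair
    # expression coupling
    expr_ba_effect: float = 1.0
    expr_ab_effect: float = -1.0
    expr_bab_kd_effect: float = -1.0     # KD-vs-senescent shift at BAB bins
    expr_noise_sd: float = 0.5
    sahf_ring_shift: float = -0.75
    sahf_ring_window: tuple = (500_000, 700_000)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("checkerboard", "tad_strength", "sahf_boost", "depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.transition_fraction <= 1:
            raise ValueError("transition_fraction must be in [0, 1]")
        if not 0 <= self.bab_fraction <= 1:
            raise ValueError("bab_fraction must be in [0, 1]")
        if self.transition_min_bp < self.bin_size:
            raise ValueError("transitions must span at least one bin")

    def bins_for(self, chrom: str) -> GenomeBins:
        for name, length in self.chromosomes:
            if name == chrom:
                return GenomeBins(name, self.bin_size, length // self.bin_size)
        raise KeyError(chrom)


@dataclass
class SyntheticTruth:
    """Planted architecture: everything recovery tests need.

    ``labels[chrom][condition]`` is the per-bin 'A'/'B' array;
    ``tad_boundaries[chrom]`` the sorted TAD start bins;
    ``sahf_blocks[chrom]`` (start, end_inclusive) bin intervals;
    ``biases[chrom]`` the per-bin multiplicative bias.
    """

    config: SyntheticConfig
    labels: dict = field(default_factory=dict)
    tad_boundaries: dict = field(default_factory=dict)
    sahf_blocks: dict = field(default_factory=dict)
    biases: dict = field(default_factory=dict)

    def chroms(self) -> list[str]:
        return [name for name, _ in self.config.chromosomes]

    def transition_bins(self, chrom: str, cond1: str = "growing",
                        cond2: str = "senescent") -> dict[str, np.ndarray]:
        """Planted transition bin indices by category between two conditions."""
        l1 = np.asarray(self.labels[chrom][cond1])
        l2 = np.asarray(self.labels[chrom][cond2])
        return {
            "BA": np.flatnonzero((l1 == "B") & (l2 == "A")),
            "AB": np.flatnonzero((l1 == "A") & (l2 == "B")),
            "AA": np.flatnonzero((l1 == "A") & (l2 == "A")),
            "BB": np.flatnonzero((l1 == "B") & (l2 == "B")),
        }

    def bab_bins(self, chrom: str) -> np.ndarray:
        """Bins that are BA growing->senescent and AB senescent->kd."""
        ba = set(self.transition_bins(chrom, "growing", "senescent")["BA"].tolist())
        ab = set(self.transition_bins(chrom, "senescent", "kd")["AB"].tolist())
        return np.array(sorted(ba & ab), dtype=int)

    def sahf_bin_mask(self, chrom: str) -> np.ndarray:
        n = self.config.bins_for(chrom).n_bins
        m = np.zeros(n, dtype=bool)
        for s, e in self.sahf_blocks[chrom]:
            m[s:e + 1] = True
        return m

    def sahf_regions_bp(self) -> dict[str, list]:
        """SAHF blocks as (start, end) bp intervals per chromosome."""
        bs = self.config.bin_size
        return {
            chrom: [(s * bs, (e + 1) * bs) for s, e in self.sahf_blocks[chrom]]
            for chrom in self.chroms()
        }

    # -- serialization ------------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "config": asdict(self.config),
            "labels": {c: {k: "".join(v) for k, v in d.items()}
                       for c, d in self.labels.items()},
            "tad_boundaries": {c: np.asarray(v).tolist()
                               for c, v in self.tad_boundaries.items()},
            "sahf_blocks": {c: [list(b) for b in v]
                            for c, v in self.sahf_blocks.items()},
            "biases": {c: np.asarray(v).tolist() for c, v in self.biases.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        cfg = payload["config"]
        cfg["chromosomes"] = tuple(tuple(c) for c in cfg["chromosomes"])
        cfg["sahf_ring_window"] = tuple(cfg["sahf_ring_window"])
        config = SyntheticConfig(**cfg)
        truth = cls(config)
        truth.labels = {c: {k: np.array(list(v), dtype=object)
                            for k, v in d.items()}
                        for c, d in payload["labels"].items()}
        truth.tad_boundaries = {c: np.array(v, dtype=int)
                                for c, v in payload["tad_boundaries"].items()}
        truth.sahf_blocks = {c: [tuple(b) for b in v]
                             for c, v in payload["sahf_blocks"].items()}
        truth.biases = {c: np.array(v) for c, v in payload["biases"].items()}
        return truth


def _draw_segments(rng, n_bins: int, cfg: SyntheticConfig) -> list[tuple[int, int, str]]:
    """Alternating A/B blocks covering [0, n_bins)."""
    mean_bins = max(cfg.mean_block_bp // cfg.bin_size, 1)
    min_bins = max(cfg.min_block_bp // cfg.bin_size, 5)
    blocks = []
    pos = 0
    label = "A" if rng.random() < 0.5 else "B"
    while pos < n_bins:
        length = int(np.clip(round(rng.exponential(mean_bins)),
                             min_bins, 3 * mean_bins))
        end = min(pos + length, n_bins)
        blocks.append((pos, end - 1, label))
        label = "B" if label == "A" else "A"
        pos = end
    return blocks


def _plant_switches(rng, blocks, labels_from, target_bins: int,
                    from_label: str, cfg: SyntheticConfig) -> list[tuple[int, int]]:
    """Flip 100-500 kb segments inside blocks of ``from_label``; return them."""
    lo = max(-(-cfg.transition_min_bp // cfg.bin_size), 1)   # ceil
    hi = max(cfg.transition_max_bp // cfg.bin_size, lo)      # floor
    candidates = [(s, e) for s, e, lab in blocks if lab == from_label]
    planted: list[tuple[int, int]] = []
    placed = np.zeros(len(labels_from), dtype=bool)
    n_planted = 0
    attempts = 0
    while n_planted < target_bins and attempts < 10_000 and candidates:
        attempts += 1
        s, e = candidates[rng.integers(len(candidates))]
        block_len = e - s + 1
        seg_len = int(rng.integers(lo, hi + 1))
        if seg_len + 2 > block_len:  # keep one flanking bin on each side
            continue
        start = int(rng.integers(s + 1, e - seg_len + 1))
        if placed[start - 1:start + seg_len + 1].any():
            continue
        placed[start:start + seg_len] = True
        planted.append((start, start + seg_len - 1))
        n_planted += seg_len
    return planted


def plant_architecture(config: SyntheticConfig) -> SyntheticTruth:
    """Draw the planted genome architecture for all conditions.

    Growing-condition A/B blocks are drawn first; BA segments (B blocks
    flipped to A in the senescent condition) outnumber AB segments by
    ``ba_ab_ratio``; a ``bab_fraction`` subset of BA segments reverts to B in
    the kd condition. SAHF blocks are chosen among persistent B blocks and
    TAD boundaries tile every compartment block.
    """
    truth = SyntheticTruth(config)
    for ci, (chrom, length) in enumerate(config.chromosomes):
        n_bins = length // config.bin_size
        rng = np.random.default_rng([config.seed, 101, ci])
        blocks = _draw_segments(rng, n_bins, config)
        growing = np.empty(n_bins, dtype=object)
        for s, e, lab in blocks:
            growing[s:e + 1] = lab

        total = config.transition_fraction * n_bins
        r = config.ba_ab_ratio
        ba_target = int(round(total * r / (1 + r)))
        ab_target = int(round(total / (1 + r)))
        ba_segs = _plant_switches(rng, blocks, growing, ba_target, "B", config)
        ab_segs = _plant_switches(rng, blocks, growing, ab_target, "A", config)
        if config.transition_fraction > 0 and not ba_segs and ba_target > 0:
            raise ValueError(
                "infeasible config: no B block can hold a transition segment")

        senescent = growing.copy()
        for s, e in ba_segs:
            senescent[s:e + 1] = "A"
        for s, e in ab_segs:
            senescent[s:e + 1] = "B"

        kd = senescent.copy()
        n_bab = int(round(config.bab_fraction * len(ba_segs)))
        bab_idx = rng.choice(len(ba_segs), size=n_bab, replace=False) if n_bab else []
        for k in sorted(bab_idx):
            s, e = ba_segs[k]
            kd[s:e + 1] = "B"

        # SAHF: maximal runs of persistent-B bins (B in every condition) long
        # enough to act as heterochromatic blocks; several per chromosome so
        # that SAHF-SAHF pairs beyond the long-range cutoff exist
        persistent = (growing == "B") & (senescent == "B")
        min_run = max(config.min_block_bp // (2 * config.bin_size), 5)
        persistent_b = []
        i = 0
        while i < n_bins:
            if persistent[i]:
                j = i
                while j + 1 < n_bins and persistent[j + 1]:
                    j += 1
                if j - i + 1 >= min_run:
                    persistent_b.append((i, j))
                i = j + 1
            else:
                i += 1
        n_sahf = int(round(config.sahf_block_fraction * len(persistent_b)))
        sahf_idx = (rng.choice(len(persistent_b), size=n_sahf, replace=False)
                    if n_sahf else [])
        sahf_blocks = [persistent_b[k] for k in sorted(sahf_idx)]

        # TADs tile each compartment block
        tad_lo = max(config.tad_min_bp // config.bin_size, 2)
        tad_hi = max(config.tad_max_bp // config.bin_size, tad_lo)
        boundaries = []
        for s, e, _lab in blocks:
            pos = s
            while pos <= e:
                boundaries.append(pos)
                pos += int(rng.integers(tad_lo, tad_hi + 1))
        truth.labels[chrom] = {
            "growing": growing, "senescent": senescent, "kd": kd,
        }
        truth.tad_boundaries[chrom] = np.unique(np.array(boundaries, dtype=int))
        truth.sahf_blocks[chrom] = sahf_blocks
        truth.biases[chrom] = rng.lognormal(0.0, config.bias_sd, size=n_bins)
    return truth


def _tad_ids(boundaries: np.ndarray, n_bins: int) -> np.ndarray:
    ids = np.zeros(n_bins, dtype=int)
    for b in boundaries:
        ids[b:] += 1
    return ids


def expected_contacts(truth: SyntheticTruth, condition: str, chrom: str,
                      with_biases: bool = True) -> np.ndarray:
    """Expected (Poisson-mean) contact matrix lambda for one chromosome."""
    cfg = truth.config
    if condition not in CONDITIONS:
        raise KeyError(f"unknown condition {condition!r}")
    bins = cfg.bins_for(chrom)
    n = bins.n_bins
    labels = np.asarray(truth.labels[chrom][condition])
    idx = np.arange(n)
    sep = np.abs(np.subtract.outer(idx, idx))
    sep_safe = np.where(sep > 0, sep, 1).astype(float)
    base = np.where(sep > 0, sep_safe ** -cfg.decay_exponent, 0.0)
    same_comp = labels[:, None] == labels[None, :]
    base *= np.where(same_comp, cfg.checkerboard, 1.0)
    tids = _tad_ids(truth.tad_boundaries[chrom], n)
    base *= np.where(tids[:, None] == tids[None, :], cfg.tad_strength, 1.0)
    if condition in ("senescent", "kd"):
        sahf = truth.sahf_bin_mask(chrom)
        long_pair = sep * cfg.bin_size > cfg.sahf_long_range_bp
        base *= np.where(sahf[:, None] & sahf[None, :] & long_pair,
                         cfg.sahf_boost, 1.0)
    off = sep > 0
    scale = cfg.depth / base[off].mean()
    lam = base * scale
    if with_biases:
        b = np.asarray(truth.biases[chrom])
        lam = lam * np.outer(b, b)
    return lam


def simulate_contacts(truth: SyntheticTruth, condition: str,
                      chrom: str, with_biases: bool = True) -> ContactMatrix:
    """Poisson-sample a raw contact matrix for one chromosome and condition.

    The expected contact between bins i and j is
    ``depth-scaled |i-j|^-alpha x checkerboard x TAD x SAHF x b_i b_j``;
    counts are drawn independently per unordered pair and symmetrized.
    """
    cfg = truth.config
    lam = expected_contacts(truth, condition, chrom, with_biases)
    bins = cfg.bins_for(chrom)
    ci = truth.chroms().index(chrom)
    rng = np.random.default_rng(
        [cfg.seed, 202, _COND_INDEX[condition], ci, int(with_biases)])
    iu, ju = np.triu_indices(bins.n_bins, k=1)
    draws = rng.poisson(lam[iu, ju])
    counts = np.zeros_like(lam)
    counts[iu, ju] = draws
    counts[ju, iu] = draws
    return ContactMatrix(bins, counts)


def simulate_expression_and_tracks(truth: SyntheticTruth):
    """Gene table and per-bin signal tracks coupled to the planted truth.

    One gene is tiled per 40 kb bin. Log2 fold changes senescent-vs-growing
    are Normal(effect, noise) with +effect at BA bins, -effect at AB bins, a
    ``sahf_ring_shift`` added in the configured distance ring around SAHF and
    0 elsewhere; the kd-vs-senescent contrast shifts BAB-bin genes down.
    Tracks: ``gene_density`` (elevated in growing-A blocks, used to orient
    compartment scores), ``h3k9me3`` (elevated on B and SAHF bins) and
    ``caph2`` (elevated on senescent-A and BA bins).

    Returns ``(genes, tracks)`` where ``genes`` is a DataFrame and ``tracks``
    maps track name -> {chrom: per-bin array}.
    """
    cfg = truth.config
    ring_lo, ring_hi = cfg.sahf_ring_window
    rows = []
    tracks: dict[str, dict[str, np.ndarray]] = {
        "gene_density": {}, "h3k9me3": {}, "caph2": {},
    }
    for ci, chrom in enumerate(truth.chroms()):
        bins = cfg.bins_for(chrom)
        n = bins.n_bins
        rng = np.random.default_rng([cfg.seed, 303, ci])
        lab_g = np.asarray(truth.labels[chrom]["growing"])
        lab_s = np.asarray(truth.labels[chrom]["senescent"])
        tcat = truth.transition_bins(chrom)
        ba = np.zeros(n, dtype=bool); ba[tcat["BA"]] = True
        ab = np.zeros(n, dtype=bool); ab[tcat["AB"]] = True
        bab = np.zeros(n, dtype=bool); bab[truth.bab_bins(chrom)] = True
        sahf = truth.sahf_bin_mask(chrom)

        # distance (bp) from each bin to the nearest SAHF block edge
        dist = np.full(n, np.inf)
        for s, e in truth.sahf_blocks[chrom]:
            i = np.arange(n)
            d = np.where(i < s, (s - i) * cfg.bin_size,
                         np.where(i > e, (i - e) * cfg.bin_size, 0))
            dist = np.minimum(dist, d)
        ring = (dist >= ring_lo) & (dist < ring_hi)

        shift = np.zeros(n)
        shift[ba] += cfg.expr_ba_effect
        shift[ab] += cfg.expr_ab_effect
        shift[ring] += cfg.sahf_ring_shift
        noise = rng.normal(0.0, cfg.expr_noise_sd, size=n)
        log2fc = shift + noise
        shift_kd = np.zeros(n)
        shift_kd[bab] += cfg.expr_bab_kd_effect
        log2fc_kd = shift_kd + rng.normal(0.0, cfg.expr_noise_sd, size=n)
        base_expr = rng.normal(5.0, 2.0, size=n)

        for i in range(n):
            start = i * cfg.bin_size + 5_000
            rows.append({
                "gene_id": f"{chrom}_g{i:04d}",
                "chrom": chrom,
                "start": start,
                "end": start + 30_000,
                "strand": "+" if i % 2 == 0 else "-",
                "bin": i,
                "expr_growing": float(2.0 ** base_expr[i]),
                "expr_senescent": float(2.0 ** (base_expr[i] + log2fc[i])),
                "fc_senescent_vs_growing": float(2.0 ** log2fc[i]),
                "fc_kd_vs_senescent": float(2.0 ** log2fc_kd[i]),
                "true_log2fc": float(shift[i]),
                "true_log2fc_kd": float(shift_kd[i]),
            })

        tracks["gene_density"][chrom] = np.clip(
            np.where(lab_g == "A", 3.0, 1.0) + rng.normal(0, 0.2, n), 0.05, None)
        tracks["h3k9me3"][chrom] = np.clip(
            np.where(sahf, 3.0, np.where(lab_s == "B", 2.0, 0.5))
            + rng.normal(0, 0.2, n), 0.0, None)
        tracks["caph2"][chrom] = np.clip(
            np.where(ba, 2.5, np.where(lab_s == "A", 1.5, 0.5))
            + rng.normal(0, 0.2, n), 0.0, None)
    genes = pd.DataFrame(rows)
    return genes, tracks
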