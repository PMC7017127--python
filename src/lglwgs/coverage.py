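"""Read-depth copy-number mapping for a paired tumor/normal genome.

The procedure: bin aligned fragments into intervals of a fixed number of
mappable bases (default 10 kb), model expected coverage as a function of GC
content with a robust locally weighted linear regression (LOWESS), scale
each bin by the fitted expectation, segment the normalized log2 ratios with
circular binary segmentation (CBS), and genotype segment levels with a 1-D
Gaussian mixture whose components map to integer copy states at c/2 on the
diploid-relative ratio scale.

`CopyNumberModel` / `CopyNumberResults` bundle the steps statsmodels-style;
the individual operations are public functions usable on their own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .errors import InputError

log = logging.getLogger(__name__)

BIN_COLUMNS = ["chrom", "start", "end", "mappable_bases", "gc"]


# ---------------------------------------------------------------------------
# binning

def _mappability_masks(mappability, lengths: dict) -> dict:
    """Build per-chromosome boolean masks from BED-like intervals."""
    masks = {c: np.zeros(n, dtype=bool) for c, n in lengths.items()}
    for row in mappability:
        chrom, start, end = row[0], int(row[1]), int(row[2])
        if chrom not in masks:
            raise InputError(f"mappability references unknown chromosome {chrom!r}")
        masks[chrom][start:end] = True
    return masks


def read_mappability_bed(path):
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    return list(df.itertuples(index=False, name=None))


def build_bins(reference, mappability=None, target_mappable: int = 10_000) -> pd.DataFrame:
    """Cut each chromosome into bins of ``target_mappable`` mappable bases.

    ``reference`` maps chromosome name to sequence string (GC computed from
    G/C/g/c) or to a per-position 0/1 GC indicator array.  ``mappability``
    is either None (all positions mappable), a dict of boolean arrays, or an
    iterable of (chrom, start, end) intervals.  Bin genomic widths vary so
    that every bin except the last per chromosome holds exactly the target
    number of mappable positions; GC fractions are computed over mappable
    positions only.
    """
    lengths = {c: len(s) for c, s in reference.items()}
    if mappability is None:
        masks = None
    elif isinstance(mappability, dict):
        for c in mappability:
            if c not in lengths:
                raise InputError(f"mappability references unknown chromosome {c!r}")
        masks = {c: np.asarray(m, dtype=bool) for c, m in mappability.items()}
    else:
        masks = _mappability_masks(mappability, lengths)

    rows = []
    for chrom, seq in reference.items():
        n = lengths[chrom]
        if n == 0:
            continue
        if isinstance(seq, (str, bytes)):
            arr = np.frombuffer(seq.encode() if isinstance(seq, str) else seq,
                                dtype="S1")
            gc_ind = np.isin(arr, [b"G", b"C", b"g", b"c"]).astype(np.int64)
        else:
            gc_ind = np.asarray(seq, dtype=np.int64)
        mask = np.ones(n, dtype=bool) if masks is None else masks.get(chrom, np.ones(n, dtype=bool))
        cum_map = np.concatenate([[0], np.cumsum(mask.astype(np.int64))])
        cum_gc = np.concatenate([[0], np.cumsum(gc_ind * mask)])
        total = cum_map[-1]
        if total == 0:
            rows.append({"chrom": chrom, "start": 0, "end": n,
                         "mappable_bases": 0, "gc": np.nan})
            continue
        targets = np.arange(target_mappable, total + 1, target_mappable)
        ends = np.searchsorted(cum_map, targets, side="left")
        if total % target_mappable != 0 or len(ends) == 0:
            ends = np.append(ends, n)
        else:
            ends[-1] = n  # absorb trailing unmappable tail into the last bin
        start = 0
        for end in ends:
            end = int(end)
            mappable = int(cum_map[end] - cum_map[start])
            gc_count = int(cum_gc[end] - cum_gc[start])
            rows.append({
                "chrom": chrom, "start": start, "end": end,
                "mappable_bases": mappable,
                "gc": gc_count / mappable if mappable else np.nan,
            })
            start = end
    return pd.DataFrame(rows, columns=BIN_COLUMNS)


def count_fragments(fragments, bins: pd.DataFrame, column: str = "count"):
    """Assign each fragment to the bin containing its midpoint.

    ``fragments`` is an iterable of (chrom, midpoint_bp) pairs or a
    DataFrame with columns chrom, midpoint.  Bins are half-open, so a
    midpoint exactly on a bin start counts in that bin.  Returns
    ``(bins_with_counts, n_discarded)``; fragments on unknown chromosomes
    or outside every bin are discarded (and logged), never fatal.
    """
    if not isinstance(fragments, pd.DataFrame):
        fragments = pd.DataFrame(list(fragments), columns=["chrom", "midpoint"])
    bins = bins.reset_index(drop=True).copy()
    counts = np.zeros(len(bins), dtype=np.int64)
    discarded = 0
    by_chrom = {c: g for c, g in bins.groupby("chrom", sort=False)}
    if len(fragments):
        for chrom, grp in fragments.groupby("chrom", sort=False):
            sub = by_chrom.get(chrom)
            if sub is None:
                log.warning("discarding %d fragments on unknown chromosome %s",
                            len(grp), chrom)
                discarded += len(grp)
                continue
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            mids = grp["midpoint"].to_numpy()
            idx = np.searchsorted(starts, mids, side="right") - 1
            ok = (idx >= 0) & (mids < ends[np.clip(idx, 0, len(ends) - 1)])
            discarded += int((~ok).sum())
            np.add.at(counts, sub.index.to_numpy()[idx[ok]], 1)
    bins[column] = counts
    return bins, discarded


# ---------------------------------------------------------------------------
# GC correction

@dataclass
class GcCorrectionCurve:
    """LOWESS fit of per-bin fragment count against GC fraction, evaluated
    on a fixed grid; callable on arbitrary GC values (clamped to the grid)."""

    grid: np.ndarray
    values: np.ndarray
    smoothing_fraction: float

    def __call__(self, gc):
        return np.interp(np.asarray(gc, dtype=float), self.grid, self.values)


def _count_column(bins: pd.DataFrame, sample: str) -> str:
    for cand in (f"count_{sample}", sample, "count"):
        if cand in bins.columns:
            return cand
    raise InputError(f"no count column for sample {sample!r} in bins table")


def fit_gc_curve(bins: pd.DataFrame, smoothing_fraction: float = 0.3,
                 sample: str = "tumor", n_grid: int = 101) -> GcCorrectionCurve:
    """Robust LOWESS of raw fragment count on GC fraction (3 robustifying
    iterations), evaluated on an even grid over the observed GC range.
    Degenerate GC support (a single value) yields a constant curve at the
    mean count."""
    col = _count_column(bins, sample)
    ok = (bins["mappable_bases"] > 0) & np.isfinite(bins[col]) & np.isfinite(bins["gc"])
    gc = bins.loc[ok, "gc"].to_numpy(dtype=float)
    y = bins.loc[ok, col].to_numpy(dtype=float)
    if len(y) == 0:
        raise InputError("no usable bins to fit a GC curve")
    if len(y) < 50:
        log.warning("fitting GC curve on only %d bins", len(y))
    lo, hi = float(gc.min()), float(gc.max())
    if hi - lo < 1e-9 or len(np.unique(gc)) < 3:
        grid = np.array([lo - 1e-6, hi + 1e-6])
        return GcCorrectionCurve(grid, np.full(2, y.mean()), smoothing_fraction)
    grid = np.linspace(lo, hi, n_grid)
    values = sm_lowess(y, gc, frac=smoothing_fraction, it=3, xvals=grid)
    return GcCorrectionCurve(grid, values, smoothing_fraction)


def normalize_coverage(bins: pd.DataFrame, curve: GcCorrectionCurve,
                       sample: str = "tumor") -> pd.DataFrame:
    """Scale each bin by the expected coverage of bins with the same GC:
    ratio = raw_count / curve(gc).  Bins with no mappable bases, missing
    counts, or non-positive fitted expectation get a missing ratio."""
    col = _count_column(bins, sample)
    bins = bins.copy()
    expected = curve(bins["gc"].to_numpy(dtype=float))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = bins[col].to_numpy(dtype=float) / expected
    bad = (expected <= 0) | (bins["mappable_bases"].to_numpy() == 0)
    ratio[bad] = np.nan
    bins[f"ratio_{sample}"] = ratio
    return bins


def gc_bias_diagnostic(bins: pd.DataFrame, sample: str = "tumor") -> pd.DataFrame:
    """Decile table of mean raw count (and normalized ratio, if present) by
    GC content — flat normalized means indicate the correction worked."""
    if len(bins) == 0:
        return pd.DataFrame(columns=["gc_decile", "gc_mean", "mean_raw_count",
                                     "mean_normalized_ratio"])
    col = _count_column(bins, sample)
    ok = bins["mappable_bases"] > 0
    sub = bins.loc[ok].copy()
    sub["gc_decile"] = pd.qcut(sub["gc"], 10, labels=False, duplicates="drop") + 1
    ratio_col = f"ratio_{sample}"
    agg = sub.groupby("gc_decile").agg(
        gc_mean=("gc", "mean"),
        mean_raw_count=(col, "mean"),
        mean_normalized_ratio=(ratio_col, "mean") if ratio_col in sub.columns else (col, lambda s: np.nan),
    ).reset_index()
    return agg


# ---------------------------------------------------------------------------
# circular binary segmentation

@lru_cache(maxsize=256)
def _arc_index(n: int, min_width: int):
    """Candidate arcs (i, j], 0 <= i < j <= n, such that every resulting
    segment piece has at least ``min_width`` bins.  Because the two-sample
    t-statistic is symmetric in arc/complement, interior arcs cover the
    circular (wrap-around) case."""
    i_list, j_list = [], []
    for i in range(0, n):
        for j in range(i + 1, n + 1):
            if i == 0 and j == n:
                continue
            pieces = [p for p in (i, j - i, n - j) if p > 0]
            if min(pieces) < min_width:
                continue
            i_list.append(i)
            j_list.append(j)
    return np.asarray(i_list, dtype=np.int64), np.asarray(j_list, dtype=np.int64)


def _arc_tstats(x: np.ndarray, i_idx: np.ndarray, j_idx: np.ndarray) -> np.ndarray:
    """|t| of arc-vs-complement mean difference (pooled variance) for every
    candidate arc; zero-variance series give t=0 when means agree and a
    large finite t when they do not."""
    n = len(x)
    s = np.concatenate([[0.0], np.cumsum(x)])
    q = np.concatenate([[0.0], np.cumsum(x * x)])
    n1 = (j_idx - i_idx).astype(float)
    n2 = n - n1
    sum1 = s[j_idx] - s[i_idx]
    sum2 = s[n] - sum1
    m1 = sum1 / n1
    m2 = sum2 / n2
    ss1 = (q[j_idx] - q[i_idx]) - n1 * m1 * m1
    ss2 = (q[n] - (q[j_idx] - q[i_idx])) - n2 * m2 * m2
    dof = max(n - 2, 1)
    sp2 = np.maximum(ss1 + ss2, 0.0) / dof
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    diff = np.abs(m1 - m2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    t[(se == 0) & (diff <= 1e-12)] = 0.0
    t[(se == 0) & (diff > 1e-12)] = 1e12
    return t


def max_t_split(x: np.ndarray, min_width: int = 2):
    """Best arc split of a series: returns (t_max, i, j) over all candidate
    arcs, ties broken by the lexicographically first (i, j); (0, None, None)
    when no candidate arc exists."""
    n = len(x)
    i_idx, j_idx = _arc_index(n, min_width)
    if len(i_idx) == 0:
        return 0.0, None, None
    t = _arc_tstats(np.asarray(x, dtype=float), i_idx, j_idx)
    k = int(np.argmax(t))
    return float(t[k]), int(i_idx[k]), int(j_idx[k])


def _permutation_pvalue(x, t_obs, min_width, alpha, n_permutations, rng):
    """Permutation p-value of the max-|t| statistic with early rejection:
    once enough permutations exceed the observed statistic to guarantee
    p >= alpha, stop.  Returns (p_value_bound, accepted)."""
    n = len(x)
    i_idx, j_idx = _arc_index(n, min_width)
    reject_at = int(np.ceil(alpha * (n_permutations + 1)))
    exceed = 0
    x = np.asarray(x, dtype=float)
    for b in range(n_permutations):
        perm = rng.permutation(x)
        if _arc_tstats(perm, i_idx, j_idx).max() >= t_obs:
            exceed += 1
            if exceed >= reject_at:
                return (1 + exceed) / (2 + b), False
    p = (1 + exceed) / (1 + n_permutations)
    return p, p < alpha


def first_split(x, alpha: float = 0.01, n_permutations: int = 1000,
                min_width: int = 2, seed=None):
    """The single top-level CBS decision on an (already transformed) series.

    Returns ``(boundaries, t_obs)`` where ``boundaries`` is the tuple of
    accepted change-points (empty when the permutation test rejects the
    split): one boundary for an edge arc, two for an interior arc.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    t_obs, i, j = max_t_split(x, min_width)
    if i is None or t_obs <= 0:
        return (), t_obs
    rng = np.random.default_rng(seed)
    _, accept = _permutation_pvalue(x, t_obs, min_width, alpha,
                                    n_permutations, rng)
    if not accept:
        return (), t_obs
    return tuple(sorted({i, j} - {0, n})), t_obs


def segment_cbs(ratios, alpha: float = 0.01, n_permutations: int = 1000,
                min_width: int = 2, seed=None, pseudocount: float = 1e-3,
                prune_delta: float = 0.05, log_transform: bool = True) -> pd.DataFrame:
    """Circular binary segmentation of a (finite) normalized-ratio series.

    Operates on log2(ratio + pseudocount).  Recursively finds the arc
    maximizing the arc-vs-complement two-sample t statistic and accepts the
    split when its permutation p-value is below ``alpha``; accepted interior
    arcs contribute two change-points.  After recursion, adjacent segments
    whose (log-scale) means differ by less than ``prune_delta`` are merged.

    Returns a DataFrame with columns start_bin, end_bin (half-open, local
    indices), n_bins, mean_ratio (arithmetic mean on the ratio scale).
    """
    r = np.asarray(ratios, dtype=float)
    if len(r) == 0:
        return pd.DataFrame(columns=["start_bin", "end_bin", "n_bins", "mean_ratio"])
    if not np.all(np.isfinite(r)):
        raise InputError("segment_cbs requires finite ratios; drop missing bins first")
    x = np.log2(r + pseudocount) if log_transform else r
    rng = np.random.default_rng(seed)

    boundaries = [0, len(x)]
    stack = [(0, len(x))]
    while stack:
        lo, hi = stack.pop()
        seg = x[lo:hi]
        if hi - lo < 2 * min_width:
            continue
        t_obs, i, j = max_t_split(seg, min_width)
        if i is None or t_obs <= 0:
            continue
        _, accept = _permutation_pvalue(seg, t_obs, min_width, alpha,
                                        n_permutations, rng)
        if not accept:
            continue
        cuts = sorted({lo + i, lo + j} - {lo, hi})
        if not cuts:
            continue
        boundaries.extend(cuts)
        pieces = [lo] + cuts + [hi]
        for a, b in zip(pieces, pieces[1:]):
            stack.append((a, b))

    edges = sorted(set(boundaries))
    # prune: merge adjacent segments with nearly equal means
    merged = True
    while merged and len(edges) > 2:
        merged = False
        for k in range(1, len(edges) - 1):
            a, b, c = edges[k - 1], edges[k], edges[k + 1]
            if abs(x[a:b].mean() - x[b:c].mean()) < prune_delta:
                edges.pop(k)
                merged = True
                break
    rows = [
        {"start_bin": a, "end_bin": b, "n_bins": b - a,
         "mean_ratio": float(r[a:b].mean())}
        for a, b in zip(edges, edges[1:])
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GMM copy-state genotyping

@dataclass
class CnvMap:
    """Segments with integer copy states for the tumor sample."""

    segments: pd.DataFrame
    baseline_ploidy: int = 2
    component_means: np.ndarray = field(default_factory=lambda: np.array([]))
    component_states: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    n_components: int = 0


def _state_for_mean(mean: float, max_copy: int) -> int:
    """Integer copy state minimizing |mean - c/2| on the diploid-relative
    ratio scale."""
    return int(np.clip(np.round(2.0 * mean), 0, max_copy))


def genotype_segments(segments: pd.DataFrame, max_copy: int = 6, seed=None,
                      baseline_ploidy: int = 2, min_fit_bins: int = 5) -> CnvMap:
    """Genotype segment mean ratios with a 1-D Gaussian mixture.

    Mixtures with k = 1..max_copy+1 components are fitted by EM (k-means
    init, 5 restarts) to segment means replicated n_bins times each — exact
    integer length-weighting — and the component count is chosen by BIC.
    Segments shorter than ``min_fit_bins`` do not inform the fit (their
    mean levels are too noisy to define a copy-state component) but are
    still genotyped under the fitted model.  Each component maps to the
    copy state nearest 2*mean; components sharing a state are merged by
    summing posteriors.  Each segment gets the state of its
    maximum-posterior component and that posterior.
    """
    from sklearn.mixture import GaussianMixture

    if len(segments) == 0:
        raise InputError("no segments to genotype")
    segments = segments.reset_index(drop=True).copy()
    all_means = segments["mean_ratio"].to_numpy(dtype=float)
    all_weights = segments["n_bins"].to_numpy(dtype=int)
    fit_mask = all_weights >= min_fit_bins
    if not fit_mask.any():
        fit_mask = np.ones(len(segments), dtype=bool)
    means = all_means[fit_mask]
    weights = all_weights[fit_mask]
    expanded = np.repeat(means, weights).reshape(-1, 1)
    n_distinct = len(np.unique(np.round(means, 10)))

    if len(means) == 1 or n_distinct == 1 or expanded.std() < 1e-9:
        # degenerate support: one level informs the fit; genotype every
        # segment by direct nearest-c/2 mapping of its own mean
        level = float(np.average(means, weights=weights))
        segments["copy_state"] = [_state_for_mean(m, max_copy) for m in all_means]
        segments["posterior"] = 1.0
        return CnvMap(segments, baseline_ploidy, np.array([level]),
                      np.array([_state_for_mean(level, max_copy)]), 1)

    rng = np.random.default_rng(seed)
    best = None
    best_bic = np.inf
    kmax = min(max_copy + 1, n_distinct, len(expanded))
    for k in range(1, kmax + 1):
        # reg_covar floors component variance at the within-state scale
        # (states are 0.5 apart) so BIC does not split one copy state into
        # several near-degenerate components.
        gm = GaussianMixture(
            n_components=k, covariance_type="full", n_init=5,
            init_params="k-means++", reg_covar=1e-3, max_iter=500,
            random_state=int(rng.integers(2 ** 31 - 1)),
        ).fit(expanded)
        if not gm.converged_:
            log.warning("GMM with k=%d did not converge; best restart used", k)
        bic = gm.bic(expanded)
        if bic < best_bic:
            best_bic, best = bic, gm
    comp_means = best.means_.ravel()
    comp_states = np.array([_state_for_mean(m, max_copy) for m in comp_means])
    resp = best.predict_proba(all_means.reshape(-1, 1))
    states_unique = np.unique(comp_states)
    # merge components mapping to the same copy state
    state_post = np.column_stack(
        [resp[:, comp_states == s].sum(axis=1) for s in states_unique]
    )
    assign = np.argmax(state_post, axis=1)
    segments["copy_state"] = states_unique[assign]
    segments["posterior"] = state_post[np.arange(len(all_means)), assign]
    return CnvMap(segments, baseline_ploidy, comp_means, comp_states,
                  best.n_components)


# ---------------------------------------------------------------------------
# Model / Results

class CopyNumberModel:
    """Read-depth copy-number model for one sample of a binned genome.

    Parameters
    ----------
    bins : DataFrame
        Columns chrom, start, end, mappable_bases, gc and a fragment-count
        column (``count_<sample>``, ``<sample>`` or ``count``).
    sample : str
        Which sample's counts to model (default ``"tumor"``).
    baseline_ploidy : int
        Copy number of the unaltered genome (default 2).
    """

    def __init__(self, bins: pd.DataFrame, sample: str = "tumor",
                 baseline_ploidy: int = 2):
        missing = [c for c in BIN_COLUMNS if c not in bins.columns]
        if missing:
            raise InputError(f"bins table lacks columns {missing}")
        _count_column(bins, sample)  # validates
        self.bins = bins.reset_index(drop=True).copy()
        self.sample = sample
        self.baseline_ploidy = baseline_ploidy

    @classmethod
    def from_counts_tsv(cls, path, sample: str = "tumor",
                        baseline_ploidy: int = 2) -> "CopyNumberModel":
        return cls(pd.read_csv(path, sep="\t"), sample=sample,
                   baseline_ploidy=baseline_ploidy)

    def fit(self, smoothing_fraction: float = 0.3, alpha: float = 0.01,
            n_permutations: int = 1000, min_width: int = 2,
            max_copy: int = 6, prune_delta: float = 0.05,
            recenter: bool = True, two_pass: bool = True,
            seed: int = 0) -> "CopyNumberResults":
        """GC-correct, recenter, segment and genotype; returns results.

        ``two_pass`` refits the GC curve on bins whose first-pass ratio
        lies near the genome-wide median (the copy-neutral majority), so
        copy-number segments cannot distort the correction at the GC
        values they happen to occupy.  ``recenter`` divides all normalized
        ratios by their genome-wide median so the modal (diploid-majority)
        level sits at 1.0, which the component -> c/2 state mapping
        assumes.
        """
        curve = fit_gc_curve(self.bins, smoothing_fraction, self.sample)
        bins = normalize_coverage(self.bins, curve, self.sample)
        rcol = f"ratio_{self.sample}"
        if two_pass:
            ratio = bins[rcol].to_numpy()
            med = float(np.nanmedian(ratio))
            neutral = np.isfinite(ratio) & (np.abs(ratio - med) < 0.25 * med)
            if neutral.sum() >= 50:
                curve = fit_gc_curve(bins.loc[neutral], smoothing_fraction,
                                     self.sample)
                bins = normalize_coverage(self.bins, curve, self.sample)
        scale = 1.0
        if recenter:
            # median of the copy-neutral subset, not of all bins: ranks of
            # gained/lost bins would otherwise pull the genome-wide median
            # off the diploid-majority centre and deflate every level.
            ratio = bins[rcol].to_numpy()
            med = float(np.nanmedian(ratio))
            neutral = np.isfinite(ratio) & (np.abs(ratio - med) < 0.25 * med)
            if neutral.any():
                med = float(np.median(ratio[neutral]))
            if med > 0:
                scale = med
                bins[rcol] = bins[rcol] / med

        ss = np.random.SeedSequence(entropy=seed)
        seg_rows = []
        chroms = bins["chrom"].drop_duplicates().tolist()
        chrom_seeds = ss.spawn(len(chroms) + 1)
        for ci, chrom in enumerate(chroms):
            sub = bins[bins["chrom"] == chrom]
            kept = sub.index.to_numpy()[np.isfinite(sub[rcol].to_numpy())]
            if len(kept) == 0:
                continue
            series = bins.loc[kept, rcol].to_numpy()
            segs = segment_cbs(series, alpha=alpha,
                               n_permutations=n_permutations,
                               min_width=min_width,
                               seed=chrom_seeds[ci],
                               prune_delta=prune_delta)
            base = bins.index.get_indexer(kept)
            for row in segs.itertuples(index=False):
                b0 = int(kept[row.start_bin])
                b1 = int(kept[row.end_bin - 1]) + 1
                seg_rows.append({
                    "chrom": chrom,
                    "start_bin": b0, "end_bin": b1,
                    "start": int(bins.loc[b0, "start"]),
                    "end": int(bins.loc[b1 - 1, "end"]),
                    "n_bins": b1 - b0,
                    "mean_ratio": row.mean_ratio,
                })
        segments = pd.DataFrame(seg_rows)
        cnv_map = genotype_segments(segments, max_copy=max_copy,
                                    seed=chrom_seeds[-1],
                                    baseline_ploidy=self.baseline_ploidy)
        return CopyNumberResults(self, bins, curve, cnv_map, scale,
                                 params=dict(
                                     smoothing_fraction=smoothing_fraction,
                                     alpha=alpha, n_permutations=n_permutations,
                                     min_width=min_width, max_copy=max_copy,
                                     prune_delta=prune_delta,
                                     recenter=recenter, seed=seed))


class CopyNumberResults:
    """Fitted copy-number map: normalized bins, segments with copy states,
    the GC-correction curve and the mixture genotyping summary."""

    def __init__(self, model, bins, gc_curve, cnv_map, recenter_scale, params):
        self.model = model
        self.bins = bins
        self.gc_curve = gc_curve
        self.cnv_map = cnv_map
        self.recenter_scale = recenter_scale
        self.params = params

    @property
    def segments(self) -> pd.DataFrame:
        return self.cnv_map.segments

    @property
    def bin_states(self) -> np.ndarray:
        """Per-bin integer copy state (-1 where unassigned/missing)."""
        states = np.full(len(self.bins), -1, dtype=int)
        for row in self.segments.itertuples(index=False):
            states[row.start_bin:row.end_bin] = row.copy_state
        ratio = self.bins[f"ratio_{self.model.sample}"].to_numpy()
        states[~np.isfinite(ratio)] = -1
        return states

    def gc_diagnostic(self) -> pd.DataFrame:
        return gc_bias_diagnostic(self.bins, self.model.sample)

    def to_bed(self, path) -> None:
        """BED: chrom, start, end, name=copy_state, score=1000*posterior."""
        with open(path, "w") as fh:
            for row in self.segments.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t"
                         f"{row.copy_state}\t{int(round(1000 * row.posterior))}\n")

    def to_tsv(self, path) -> None:
        self.segments.to_csv(path, sep="\t", index=False,
                             float_format="%.6g", lineterminator="\n")

    def summary(self) -> str:
        seg = self.segments
        lines = [
            "Copy-number model results",
            "=" * 60,
            f"sample:            {self.model.sample}",
            f"bins:              {len(self.bins)}"
            f" ({int(np.isfinite(self.bins[f'ratio_{self.model.sample}']).sum())} usable)",
            f"segments:          {len(seg)}",
            f"mixture components:{self.cnv_map.n_components}",
            f"recenter scale:    {self.recenter_scale:.4g}",
            "",
            "component mean -> copy state",
        ]
        for m, s in sorted(zip(self.cnv_map.component_means,
                               self.cnv_map.component_states)):
            lines.append(f"  {m:8.4f} -> {s}")
        lines.append("")
        lines.append("copy state   n_segments   n_bins   mean ratio")
        for state, grp in seg.groupby("copy_state"):
            lines.append(f"  {state:>8}   {len(grp):>10}   {grp['n_bins'].sum():>6}"
                         f"   {np.average(grp['mean_ratio'], weights=grp['n_bins']):.4f}")
        return "\n".join(lines)

    def plot(self, path=None):
        """Scatter of normalized ratios with segment means (matplotlib)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        rcol = f"ratio_{self.model.sample}"
        fig, ax = plt.subplots(figsize=(10, 3))
        ax.plot(self.bins[rcol].to_numpy(), ".", ms=2, alpha=0.5)
        for row in self.segments.itertuples(index=False):
            ax.hlines(row.mean_ratio, row.start_bin, row.end_bin,
                      colors="red", lw=2)
        ax.set_xlabel("bin index")
        ax.set_ylabel("normalized ratio")
        if path is not None:
            fig.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(fig)
        return fig
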