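"""Nonoverlapping windowed genome-scan statistics.

Implements the per-window differentiation/divergence/diversity/linkage
measurements used to screen a genome for barrier regions:

* Weir & Cockerham (1984) FST, windowed as ratio of sums of the per-site
  variance components (sum a / sum (a+b+c)),
* absolute divergence dxy per bp (all unreported sites assumed invariant,
  so the window length in bp is the denominator),
* proportion of fixed differences df among variant sites,
* nucleotide diversity pi per bp with the n/(n-1) small-sample correction,
* mean pairwise genotype-dosage r² within the window.

Windows are half-open [start, end) in 0-based coordinates internally; the
output table also carries 1-based inclusive coordinates for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, _pairwise_r2

#: minimum called chromosomes per population for a site to enter a
#: between-population statistic
MIN_CALLED_CHROMS = 4


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    partial: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


def make_windows(chrom_lengths: dict[str, int], size_bp: int) -> list[Window]:
    """Tile each chromosome with nonoverlapping windows of ``size_bp``.

    The last window of a chromosome may be shorter; it is kept and flagged
    ``partial``.
    """
    if size_bp <= 0:
        raise ValueError("window size must be positive")
    windows: list[Window] = []
    for chrom, length in chrom_lengths.items():
        start = 0
        while start < length:
            end = min(start + size_bp, length)
            windows.append(Window(chrom, start, end, partial=(end - start) < size_bp))
            start = end
    return windows


def _window_site_idx(g: GenotypeMatrix, window: Window) -> np.ndarray:
    # window is 0-based half-open; positions are 1-based
    return np.flatnonzero(
        (g.chrom == window.chrom) & (g.pos > window.start) & (g.pos <= window.end)
    )


def _pop_counts(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (n called individuals, alt-allele freq, observed het freq)."""
    called = calls != MISSING
    n = called.sum(axis=0)
    alt = np.where(called, calls, 0).sum(axis=0)
    het = np.where(called, calls == 1, False).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
        h = np.where(n > 0, het / n, np.nan)
    return n, p, h


def wc_fst_components(
    callsA: np.ndarray, callsB: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Weir-Cockerham variance components (a, b, c) and usable mask.

    Two-population diploid estimator with the observed-heterozygosity term.
    Sites with < MIN_CALLED_CHROMS called chromosomes in either population
    or zero total variance are flagged unusable.
    """
    n1, p1, h1 = _pop_counts(callsA)
    n2, p2, h2 = _pop_counts(callsB)
    r = 2.0
    usable = (2 * n1 >= MIN_CALLED_CHROMS) & (2 * n2 >= MIN_CALLED_CHROMS)

    with np.errstate(invalid="ignore", divide="ignore"):
        n_bar = (n1 + n2) / r
        n_c = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)

        a = (n_bar / n_c) * (
            s2
            - 1.0 / (n_bar - 1.0)
            * (p_bar * (1.0 - p_bar) - ((r - 1.0) / r) * s2 - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1.0 - p_bar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * n_bar - 1.0) / (4.0 * n_bar)) * h_bar
        )
        c = h_bar / 2.0

    tot = a + b + c
    usable &= np.isfinite(tot) & (tot != 0.0)
    return a, b, c, usable


def wc_fst_window(g: GenotypeMatrix, popA: str, popB: str, window: Window) -> float:
    """Windowed WC-FST as ratio of sums; NaN if no usable site."""
    idx = _window_site_idx(g, window)
    if len(idx) == 0:
        return np.nan
    callsA = g.calls[g.sample_indices(popA)][:, idx]
    callsB = g.calls[g.sample_indices(popB)][:, idx]
    a, b, c, usable = wc_fst_components(callsA, callsB)
    if not usable.any():
        return np.nan
    denom = (a + b + c)[usable].sum()
    if denom == 0:
        return np.nan
    return float(a[usable].sum() / denom)


def dxy_window(g: GenotypeMatrix, popA: str, popB: str, window: Window) -> float:
    """Between-population divergence per bp over the window length."""
    if window.length <= 0:
        raise ValueError("zero-length window")
    idx = _window_site_idx(g, window)
    if len(idx) == 0:
        return 0.0
    nA, pA, _ = _pop_counts(g.calls[g.sample_indices(popA)][:, idx])
    nB, pB, _ = _pop_counts(g.calls[g.sample_indices(popB)][:, idx])
    ok = (2 * nA >= MIN_CALLED_CHROMS) & (2 * nB >= MIN_CALLED_CHROMS)
    contrib = pA[ok] * (1.0 - pB[ok]) + pB[ok] * (1.0 - pA[ok])
    return float(contrib.sum() / window.length)


def df_window(g: GenotypeMatrix, popA: str, popB: str, window: Window) -> float:
    """Proportion of fixed differences among variant sites in the window."""
    idx = _window_site_idx(g, window)
    if len(idx) == 0:
        return np.nan
    nA, pA, _ = _pop_counts(g.calls[g.sample_indices(popA)][:, idx])
    nB, pB, _ = _pop_counts(g.calls[g.sample_indices(popB)][:, idx])
    ok = (2 * nA >= MIN_CALLED_CHROMS) & (2 * nB >= MIN_CALLED_CHROMS)
    pA, pB = pA[ok], pB[ok]
    variant = ~((pA == pB) & ((pA == 0.0) | (pA == 1.0)))
    if not variant.any():
        return np.nan
    fixed = np.abs(pA[variant] - pB[variant]) == 1.0
    return float(fixed.sum() / variant.sum())


def pi_window(g: GenotypeMatrix, pop: str, window: Window) -> float:
    """Nucleotide diversity per bp: sum over sites of 2p(1-p) n/(n-1) / L."""
    if window.length <= 0:
        raise ValueError("zero-length window")
    idx = _window_site_idx(g, window)
    if len(idx) == 0:
        return 0.0
    calls = g.calls[g.sample_indices(pop)][:, idx]
    called = calls != MISSING
    n_chr = 2 * called.sum(axis=0)
    alt = np.where(called, calls, 0).sum(axis=0)
    ok = n_chr >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_chr > 0, alt / n_chr, 0.0)
        contrib = np.where(ok, (n_chr / np.maximum(n_chr - 1.0, 1.0)) * 2.0 * p * (1.0 - p), 0.0)
    return float(contrib.sum() / window.length)


def ld_window(g: GenotypeMatrix, window: Window) -> float:
    """Mean pairwise squared dosage correlation over SNP pairs in the window."""
    idx = _window_site_idx(g, window)
    if len(idx) < 2:
        return np.nan
    vals = []
    for i in range(len(idx)):
        for j in range(i + 1, len(idx)):
            r2 = _pairwise_r2(g.calls[:, idx[i]], g.calls[:, idx[j]])
            if np.isfinite(r2):
                vals.append(r2)
    return float(np.mean(vals)) if vals else np.nan


def mean_r2_matrix(calls: np.ndarray, max_pairs: int | None = None, seed: int = 0) -> float:
    """Mean pairwise r² among the columns of a dosage matrix.

    Vectorised over mean-imputed dosages; optional random subsample of
    column pairs keeps large regions tractable.
    """
    n, m = calls.shape
    if m < 2:
        return np.nan
    x = calls.astype(float)
    x[calls == MISSING] = np.nan
    mu = np.nanmean(x, axis=0)
    x = np.where(np.isnan(x), mu, x)
    sd = x.std(axis=0)
    keep = sd > 0
    x = (x[:, keep] - mu[keep]) / sd[keep]
    m = x.shape[1]
    if m < 2:
        return np.nan
    if max_pairs is not None and m * (m - 1) // 2 > max_pairs:
        rng = np.random.default_rng(seed)
        ii = rng.integers(0, m, size=max_pairs)
        jj = rng.integers(0, m, size=max_pairs)
        ok = ii != jj
        r = (x[:, ii[ok]] * x[:, jj[ok]]).mean(axis=0)
        return float((r**2).mean())
    corr = (x.T @ x) / n
    iu = np.triu_indices(m, k=1)
    return float((corr[iu] ** 2).mean())


def scan(
    g: GenotypeMatrix,
    pops: list[str],
    size_bp: int,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Windowed scan: one row per window with pairwise and per-population stats.

    Columns: chrom, start0, end, start1, end1, partial, n_sites,
    ``fst_<A>_<B>``, ``dxy_<A>_<B>``, ``df_<A>_<B>`` for each population
    pair, ``pi_<P>`` per population, and mean_r2.
    """
    if chrom_lengths is None:
        chrom_lengths = {
            str(c): int(g.pos[g.chrom == c].max()) for c in dict.fromkeys(g.chrom)
        }
    windows = make_windows(chrom_lengths, size_bp)
    pairs = [(pops[i], pops[j]) for i in range(len(pops)) for j in range(i + 1, len(pops))]
    rows = []
    for w in windows:
        idx = _window_site_idx(g, w)
        row: dict = {
            "chrom": w.chrom,
            "start0": w.start,
            "end": w.end,
            "start1": w.start + 1,
            "end1": w.end,
            "partial": w.partial,
            "n_sites": len(idx),
        }
        for a, b in pairs:
            row[f"fst_{a}_{b}"] = wc_fst_window(g, a, b, w)
            row[f"dxy_{a}_{b}"] = dxy_window(g, a, b, w)
            row[f"df_{a}_{b}"] = df_window(g, a, b, w)
        for p in pops:
            row[f"pi_{p}"] = pi_window(g, p, w)
        row["mean_r2"] = (
            mean_r2_matrix(g.calls[:, idx], max_pairs=2000) if len(idx) >= 2 else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)
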