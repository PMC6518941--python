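"""Genotype matrix container, VCF I/O and the site/genotype filter chain.

The central substrate is :class:`GenotypeMatrix`: diploid biallelic calls
coded as alternate-allele dosage {0, 1, 2} with -1 for missing, one row per
individual and one column per site, with optional per-genotype read depth
(DP) and genotype quality (GQ) annotations and a population label per sample.

The filter chain mirrors common practice for low-coverage whole-genome
resequencing panels: genotype-level DP/GQ masking first, then site-level
missingness / minor-allele / heterozygote-excess / mean-depth filters, then
LD pruning.  Genotype masking always precedes site filters so that site
summaries are computed on the surviving calls.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import binom

logger = logging.getLogger(__name__)

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes: individuals x sites.

    Attributes
    ----------
    calls : int8 array (n_samples, n_sites)
        Alternate-allele dosage 0/1/2, or -1 for missing.
    chrom : object array (n_sites,)
        Chromosome / linkage-group name per site.
    pos : int64 array (n_sites,)
        1-based position per site; strictly increasing within chromosome.
    samples : list of str
    populations : list of str
        One label per sample.
    dp, gq : int32 arrays (n_samples, n_sites) or None
        Per-genotype read depth and phred genotype quality.
    """

    calls: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    samples: list[str]
    populations: list[str]
    dp: np.ndarray | None = None
    gq: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (samples x sites)")
        n, m = self.calls.shape
        if len(self.samples) != n:
            raise ValueError("sample count does not match calls rows")
        if len(self.populations) != n:
            raise ValueError("population-label count does not match sample count")
        if len(self.chrom) != m or len(self.pos) != m:
            raise ValueError("site annotation length does not match calls columns")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls must be in {0,1,2,-1}")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_sites(self) -> int:
        return self.calls.shape[1]

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the site columns in ``idx`` (order kept)."""
        return GenotypeMatrix(
            calls=self.calls[:, idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            samples=list(self.samples),
            populations=list(self.populations),
            dp=None if self.dp is None else self.dp[:, idx],
            gq=None if self.gq is None else self.gq[:, idx],
        )

    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            calls=self.calls[idx, :],
            chrom=self.chrom,
            pos=self.pos,
            samples=[self.samples[i] for i in idx],
            populations=[self.populations[i] for i in idx],
            dp=None if self.dp is None else self.dp[idx, :],
            gq=None if self.gq is None else self.gq[idx, :],
        )

    def sample_indices(self, population: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.populations, dtype=object) == population)

    def region_site_mask(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Boolean site mask for a 1-based inclusive [start, end] interval."""
        return (self.chrom == chrom) & (self.pos >= start) & (self.pos <= end)

    def allele_freq(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        """Alternate-allele frequency per site from called genotypes only."""
        calls = self.calls if sample_idx is None else self.calls[sample_idx, :]
        called = calls != MISSING
        alt = np.where(called, calls, 0).sum(axis=0)
        n_chr = 2 * called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_chr > 0, alt / n_chr, np.nan)


@dataclass
class FilterReport:
    """Accounting of a site-filter pass. A site may fail several rules."""

    sites_in: int
    sites_out: int
    removed_by_rule: dict[str, int] = field(default_factory=dict)
    genotypes_masked: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "sites_in": self.sites_in,
                "sites_out": self.sites_out,
                "removed_by_rule": self.removed_by_rule,
                "genotypes_masked": self.genotypes_masked,
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# popmap + VCF I/O


def load_popmap(path) -> dict[str, str]:
    """Read a 2-column sample<TAB>population table."""
    popmap: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise ValueError(f"malformed popmap line: {line!r}")
            popmap[parts[0]] = parts[1]
    return popmap


def load_genotypes(vcf_path, popmap_path) -> GenotypeMatrix:
    """Load biallelic SNPs from a VCF with a sample->population map.

    Multiallelic and indel records are dropped (count logged).  Half-missing
    diploid calls are treated as missing.
    """
    from cyvcf2 import VCF

    popmap = load_popmap(popmap_path)
    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)
    for s in samples:
        if s not in popmap:
            raise ValueError(f"sample {s!r} absent from population map")

    calls_cols, dp_cols, gq_cols, chroms, poss = [], [], [], [], []
    n_dropped = 0
    for rec in vcf:
        if not rec.is_snp or len(rec.ALT) != 1:
            n_dropped += 1
            continue
        gt = np.asarray(rec.gt_types, dtype=np.int8)  # 0,1,2 and 3=unknown
        gt[gt == 3] = MISSING
        calls_cols.append(gt)
        try:
            dp = rec.format("DP")
            dp_cols.append(
                np.full(len(samples), -1, dtype=np.int32)
                if dp is None
                else np.where(np.isfinite(dp[:, 0].astype(float)), dp[:, 0], -1).astype(np.int32)
            )
        except KeyError:
            dp_cols.append(np.full(len(samples), -1, dtype=np.int32))
        try:
            gq = rec.format("GQ")
            gq_cols.append(
                np.full(len(samples), -1, dtype=np.int32)
                if gq is None
                else np.where(np.isfinite(gq[:, 0].astype(float)), gq[:, 0], -1).astype(np.int32)
            )
        except KeyError:
            gq_cols.append(np.full(len(samples), -1, dtype=np.int32))
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
    if n_dropped:
        logger.info("dropped %d non-biallelic-SNP records", n_dropped)
    if not calls_cols:
        raise ValueError("no biallelic SNP records in VCF")

    calls = np.stack(calls_cols, axis=1)
    dp = np.stack(dp_cols, axis=1)
    gq = np.stack(gq_cols, axis=1)
    has_dp = (dp >= 0).any()
    has_gq = (gq >= 0).any()
    return GenotypeMatrix(
        calls=calls,
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(poss, dtype=np.int64),
        samples=samples,
        populations=[popmap[s] for s in samples],
        dp=dp if has_dp else None,
        gq=gq if has_gq else None,
    )


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write a minimal VCF v4.2 with GT:DP:GQ per genotype."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##source=fjordflow\n')
        for c in dict.fromkeys(g.chrom):  # preserve order
            end = int(g.pos[g.chrom == c].max()) + 1000
            fh.write(f"##contig=<ID={c},length={end}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(g.samples) + "\n")
        for j in range(g.n_sites):
            fields = [str(g.chrom[j]), str(int(g.pos[j])), ".", "A", "G", ".", "PASS", ".", "GT:DP:GQ"]
            for i in range(g.n_samples):
                dp = g.dp[i, j] if g.dp is not None else 20
                gq = g.gq[i, j] if g.gq is not None else 99
                fields.append(f"{gt_str[int(g.calls[i, j])]}:{int(dp)}:{int(gq)}")
            fh.write("\t".join(fields) + "\n")


def write_popmap(g: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        for s, p in zip(g.samples, g.populations):
            fh.write(f"{s}\t{p}\n")


# ---------------------------------------------------------------------------
# filters


def apply_genotype_filters(
    g: GenotypeMatrix,
    min_dp: int | None = 3,
    min_gq: int | None = 20,
    mask_dp_below: int | None = None,
) -> GenotypeMatrix:
    """Mask genotypes failing per-genotype depth/quality thresholds.

    ``min_dp``/``min_gq`` are strict lower bounds (a call needs DP > min_dp
    and GQ > min_gq to survive).  ``mask_dp_below`` additionally masks calls
    with DP < that value; with the default landscape setting of 7, a DP=7
    call is retained.
    """
    calls = g.calls.copy()
    if min_dp is not None or mask_dp_below is not None:
        if g.dp is None:
            raise ValueError("DP annotations absent but a DP threshold was requested")
    if min_gq is not None and g.gq is None:
        raise ValueError("GQ annotations absent but a GQ threshold was requested")
    mask = np.zeros_like(calls, dtype=bool)
    if min_dp is not None:
        mask |= g.dp <= min_dp
    if mask_dp_below is not None:
        mask |= g.dp < mask_dp_below
    if min_gq is not None:
        mask |= g.gq <= min_gq
    calls[mask] = MISSING
    return replace(g, calls=calls)


def _het_excess_pvalue(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """One-sided exact heterozygote-excess p-value (Levene conditional law).

    P(het count >= observed | allele counts), summed over heterozygote
    counts of matching parity.
    """
    from .inversions import _levene_het_distribution

    n = n_hom_ref + n_het + n_hom_alt
    n_alt = n_het + 2 * n_hom_alt
    if n == 0 or n_alt == 0 or n_alt == 2 * n:
        return 1.0
    hets, probs = _levene_het_distribution(n, n_alt)
    return float(probs[hets >= n_het].sum())


def apply_site_filters(
    g: GenotypeMatrix,
    max_missing: float = 0.20,
    min_mac: int = 3,
    min_maf: float = 0.03,
    het_excess_p: float = 0.001,
    max_mean_dp: float = 30.0,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Site-level filter chain.

    A site is kept iff missing fraction < ``max_missing`` AND minor-allele
    count >= ``min_mac`` (i.e. > min_mac - 1) AND MAF > ``min_maf`` AND the
    one-sided heterozygote-excess exact p >= ``het_excess_p`` AND mean DP
    over called genotypes < ``max_mean_dp``.  MAF/MAC use called genotypes
    only.
    """
    if g.n_sites == 0:
        raise ValueError("empty genotype matrix")
    called = g.calls != MISSING
    n_called = called.sum(axis=0)
    miss_frac = (g.n_samples - n_called) / g.n_samples

    alt = np.where(called, g.calls, 0).sum(axis=0)
    n_chr = 2 * n_called
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(n_chr > 0, alt / n_chr, 0.0)
    mac = np.minimum(alt, n_chr - alt)
    maf = np.minimum(p_alt, 1.0 - p_alt)

    fail_missing = miss_frac >= max_missing
    fail_mac = mac < min_mac
    fail_maf = maf <= min_maf

    fail_het = np.zeros(g.n_sites, dtype=bool)
    for j in range(g.n_sites):
        col = g.calls[:, j]
        n_het = int((col == 1).sum())
        if n_het == 0:
            continue
        p = _het_excess_pvalue(int((col == 0).sum()), n_het, int((col == 2).sum()))
        fail_het[j] = p < het_excess_p

    if g.dp is not None:
        dp = np.where(called & (g.dp >= 0), g.dp, 0).astype(float)
        n_dp = (called & (g.dp >= 0)).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_dp = np.where(n_dp > 0, dp.sum(axis=0) / n_dp, 0.0)
        fail_dp = mean_dp >= max_mean_dp
    else:
        fail_dp = np.zeros(g.n_sites, dtype=bool)

    fail_any = fail_missing | fail_mac | fail_maf | fail_het | fail_dp
    keep = np.flatnonzero(~fail_any)
    report = FilterReport(
        sites_in=g.n_sites,
        sites_out=len(keep),
        removed_by_rule={
            "missingness": int(fail_missing.sum()),
            "minor_allele_count": int(fail_mac.sum()),
            "minor_allele_frequency": int(fail_maf.sum()),
            "heterozygote_excess": int(fail_het.sum()),
            "mean_depth": int(fail_dp.sum()),
        },
    )
    return g.take_sites(keep), report


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors, pairwise-complete."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return np.nan
    xv = x[ok].astype(float)
    yv = y[ok].astype(float)
    sx = xv.std()
    sy = yv.std()
    if sx == 0 or sy == 0:
        return np.nan
    r = np.corrcoef(xv, yv)[0, 1]
    return float(r * r)


def ld_prune(g: GenotypeMatrix, window_bp: int = 10_000, r2_max: float = 0.8) -> GenotypeMatrix:
    """Greedy left-to-right LD pruning within sliding physical windows.

    For each kept site, later sites within ``window_bp`` with pairwise
    r² > ``r2_max`` are dropped.  Idempotent by construction.
    """
    keep = np.ones(g.n_sites, dtype=bool)
    for c in np.unique(g.chrom):
        idx = np.flatnonzero(g.chrom == c)
        pos = g.pos[idx]
        for a_i, a in enumerate(idx):
            if not keep[a]:
                continue
            for b_i in range(a_i + 1, len(idx)):
                b = idx[b_i]
                if pos[b_i] - pos[a_i] > window_bp:
                    break
                if not keep[b]:
                    continue
                r2 = _pairwise_r2(g.calls[:, a], g.calls[:, b])
                if np.isfinite(r2) and r2 > r2_max:
                    keep[b] = False
    return g.take_sites(np.flatnonzero(keep))


def downsample_individuals(g: GenotypeMatrix, per_pop_n: int = 20, seed: int = 0,
                           populations: list[str] | None = None) -> GenotypeMatrix:
    """Seeded uniform sample of ``per_pop_n`` individuals per population."""
    rng = np.random.default_rng(seed)
    pops = populations if populations is not None else list(dict.fromkeys(g.populations))
    chosen: list[int] = []
    for p in pops:
        idx = g.sample_indices(p)
        if len(idx) < per_pop_n:
            raise ValueError(f"population {p!r} has only {len(idx)} samples (< {per_pop_n})")
        chosen.extend(sorted(rng.choice(idx, size=per_pop_n, replace=False)))
    return g.take_samples(np.asarray(chosen))
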