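"""Inversion karyotyping and arrangement-frequency inference.

A large chromosomal inversion suppresses recombination in heterozygotes, so
each orientation (ancestral vs inverted) is inherited as a single
"arrangement" allele.  Restricting a PCA to SNPs inside the inverted region
separates individuals into three clusters on PC1 — the two homozygote
classes at the extremes and heterozygotes in between.  This module calls
those karyotype states, tabulates arrangement frequencies per population,
tests arrangement over-representation against the pooled frequency by a
seeded parametric bootstrap, tests Hardy-Weinberg equilibrium exactly, and
computes the combination census across regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

STATES = ("anc", "het", "inv")

#: inversion regions of the Atlantic cod GadMor2 assembly (1-based inclusive)
COD_INVERSION_REGIONS = {
    "LG01": (9_114_741, 26_192_386),
    "LG02": (18_609_260, 23_660_985),
    "LG07": (13_622_710, 23_019_113),
    "LG12": (426_531, 13_445_150),
}


@dataclass(frozen=True)
class InversionRegion:
    chrom: str
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("region start must be < end")

    @property
    def name(self) -> str:
        return self.chrom


@dataclass
class KaryotypeCall:
    individual: str
    region: str
    state: str  # anc | het | inv
    pc1_score: float
    confidence: float
    low_confidence_flag: bool = False


@dataclass
class BootstrapResult:
    population: str
    region: str
    arrangement: str  # anc | inv
    observed: int
    n_chromosomes: int
    pooled_freq: float
    B: int
    p_raw: float
    p_bonferroni: float
    family_size: int


# ---------------------------------------------------------------------------
# PCA and karyotype calling


def region_pca(g: GenotypeMatrix, region: InversionRegion, n_components: int = 2):
    """PCA of dosages restricted to an inversion region.

    smartPCA-style normalisation: per-SNP mean centring and scaling by
    sqrt(p(1-p)) with the shrunk frequency p = (1 + sum g)/(2 + 2n);
    missing dosages imputed to the column mean before scaling.  PC1 sign is
    fixed downstream by the heterozygosity-orientation rule in
    :func:`call_karyotypes`; here the raw SVD orientation is made
    deterministic by forcing a nonnegative largest-magnitude loading.

    Returns (scores (n x k), explained_variance (k,)).
    """
    mask = g.region_site_mask(region.chrom, region.start, region.end)
    calls = g.calls[:, mask]
    if calls.shape[1] < 2:
        raise ValueError("need >= 2 SNPs in region")
    if calls.shape[0] < 3:
        raise ValueError("need >= 3 individuals")

    x = calls.astype(float)
    x[calls == MISSING] = np.nan
    n_called = np.sum(~np.isnan(x), axis=0)
    alt = np.nansum(x, axis=0)
    p_shrunk = (1.0 + alt) / (2.0 + 2.0 * n_called)
    mu = np.where(n_called > 0, alt / np.maximum(n_called, 1), 0.0)
    x = np.where(np.isnan(x), mu, x)
    x -= mu
    denom = np.sqrt(p_shrunk * (1.0 - p_shrunk))
    poly = denom > 0
    x = x[:, poly] / denom[poly]
    if x.shape[1] < 2 or not np.any(x.std(axis=0) > 0):
        raise ValueError("degenerate region: no variance among individuals")

    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, len(s))
    scores = u[:, :k] * s[:k]
    # deterministic sign: largest-|loading| entry of each PC made positive
    for j in range(k):
        i_max = np.argmax(np.abs(vt[j]))
        if vt[j, i_max] < 0:
            scores[:, j] = -scores[:, j]
    explained = (s[:k] ** 2) / (x.shape[0] - 1)
    return scores, explained


def _silhouette_1d(x: np.ndarray, labels: np.ndarray) -> float:
    from sklearn.metrics import silhouette_score

    return float(silhouette_score(x.reshape(-1, 1), labels))


def call_karyotypes(
    pc_scores: np.ndarray,
    region_calls: np.ndarray,
    samples: list[str],
    region_name: str,
    k1_silhouette_floor: float = 0.7,
    seed: int = 0,
) -> list[KaryotypeCall]:
    """Assign anc/het/inv states by 1-D k-means on PC1.

    k is chosen from {1, 2, 3} by silhouette on PC1 (k=1 selected when the
    best silhouette over k in {2,3} is below ``k1_silhouette_floor``; the
    floor sits above the ~0.6 silhouette that k-means attains on
    unstructured one-dimensional scores, so an unclustered region yields a
    single class).
    Clusters are ordered by centroid; with k=3 the middle cluster is het.
    Orientation check: the het cluster must show the highest mean observed
    heterozygosity across region SNPs; if violated, calls are flagged
    low-confidence.  Which homozygote cluster is "anc" cannot be decided
    from genotypes alone (the two arrangements are symmetric); the package
    follows the convention that the ancestral arrangement is the more
    common one, so the larger homozygote cluster is labelled anc (ties go
    to the lower-PC1 cluster).  Supply reference individuals downstream
    when the inverted arrangement is locally in the majority.

    ``region_calls`` is the (n individuals x region SNPs) dosage matrix used
    for the heterozygosity orientation rule.
    """
    from sklearn.cluster import KMeans

    pc1 = np.asarray(pc_scores)[:, 0].astype(float)
    n = len(pc1)
    best_k, best_sil, best_labels = 1, -np.inf, np.zeros(n, dtype=int)
    for k in (2, 3):
        if n <= k:
            continue
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(pc1.reshape(-1, 1))
        if len(np.unique(labels)) < k:
            continue
        sil = _silhouette_1d(pc1, labels)
        if sil > best_sil:
            best_k, best_sil, best_labels = k, sil, labels
    if best_sil < k1_silhouette_floor:
        best_k, best_labels = 1, np.zeros(n, dtype=int)
        best_sil = 0.0

    # order clusters by PC1 centroid
    centroids = np.array([pc1[best_labels == c].mean() for c in range(best_k)])
    order = np.argsort(centroids)
    rank = {c: r for r, c in enumerate(order)}
    ranks = np.array([rank[c] for c in best_labels])

    het_frac = np.mean(region_calls == 1, axis=1)

    if best_k == 3:
        state_by_rank = {0: "anc", 1: "het", 2: "inv"}
        # majority convention: the larger homozygote cluster is ancestral
        if (ranks == 2).sum() > (ranks == 0).sum():
            ranks = 2 - ranks
        het_ok = (
            het_frac[ranks == 1].mean() > het_frac[ranks == 0].mean()
            and het_frac[ranks == 1].mean() > het_frac[ranks == 2].mean()
        )
    elif best_k == 2:
        # two clusters: decide whether the pair is (anc, het) or (anc, inv)
        # by heterozygosity: if the upper cluster is markedly more
        # heterozygous it is "het", otherwise it is the other homozygote
        hi_het = het_frac[ranks == 1].mean()
        lo_het = het_frac[ranks == 0].mean()
        if hi_het > 1.5 * max(lo_het, 1e-9):
            state_by_rank = {0: "anc", 1: "het"}
        else:
            # majority convention as in the k=3 case
            if (ranks == 1).sum() > (ranks == 0).sum():
                ranks = 1 - ranks
            state_by_rank = {0: "anc", 1: "inv"}
        het_ok = True
    else:
        state_by_rank = {0: "anc"}
        het_ok = True

    calls: list[KaryotypeCall] = []
    for i, s in enumerate(samples):
        calls.append(
            KaryotypeCall(
                individual=s,
                region=region_name,
                state=state_by_rank[int(ranks[i])],
                pc1_score=float(pc1[i]),
                confidence=float(best_sil),
                low_confidence_flag=not het_ok,
            )
        )
    return calls


def call_region(
    g: GenotypeMatrix, region: InversionRegion, seed: int = 0
) -> list[KaryotypeCall]:
    """Convenience: region PCA followed by karyotype calling."""
    scores, _ = region_pca(g, region)
    mask = g.region_site_mask(region.chrom, region.start, region.end)
    return call_karyotypes(scores, g.calls[:, mask], g.samples, region.name, seed=seed)


# ---------------------------------------------------------------------------
# arrangement frequencies and bootstrap test


def arrangement_frequencies(
    calls: list[KaryotypeCall],
    popmap: dict[str, str],
    extra_groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Counts of anc/het/inv individuals and chromosome-level arrangements.

    One row per (population, region).  ``extra_groups`` maps individual ->
    derived group label (e.g. genotype classes within one sampling site);
    those rows are appended in addition to the sampling-site rows.
    """
    rows: dict[tuple[str, str], dict] = {}

    def add(pop: str, call: KaryotypeCall) -> None:
        key = (pop, call.region)
        if key not in rows:
            rows[key] = {"population": pop, "region": call.region, "anc": 0, "het": 0, "inv": 0}
        rows[key][call.state] += 1

    for call in calls:
        if call.individual not in popmap:
            raise ValueError(f"unknown individual {call.individual!r}")
        add(popmap[call.individual], call)
        if extra_groups and call.individual in extra_groups:
            add(extra_groups[call.individual], call)

    df = pd.DataFrame(list(rows.values()))
    df["n"] = df["anc"] + df["het"] + df["inv"]
    df["anc_chroms"] = 2 * df["anc"] + df["het"]
    df["inv_chroms"] = 2 * df["inv"] + df["het"]
    return df


def bootstrap_overrep_test(
    table: pd.DataFrame,
    B: int = 1_000_000,
    seed: int = 0,
    populations: list[str] | None = None,
) -> list[BootstrapResult]:
    """Bootstrap test of arrangement over-representation per population.

    Null: the arrangement frequency within a population equals the pooled
    frequency across all populations.  For each population x region x
    arrangement, B seeded replicates draw Binomial(2 n_pop, q_pooled)
    arrangement counts; one-sided p = (1 + #{replicate >= observed})/(B+1).
    Bonferroni family = number of tests performed in this invocation.

    Pooling uses the sampling-site rows only (``populations`` restricts
    which rows are tested AND pooled; by default all rows are used).
    """
    if B < 1_000:
        raise ValueError("B < 1000 is unstable; increase the replicate count")
    rng = np.random.default_rng(seed)
    tab = table if populations is None else table[table["population"].isin(populations)]
    results: list[BootstrapResult] = []
    tests: list[tuple] = []
    for region, sub in tab.groupby("region", sort=False):
        total_chroms = int(2 * sub["n"].sum())
        if total_chroms == 0:
            continue
        pooled = {
            "anc": int(sub["anc_chroms"].sum()) / total_chroms,
            "inv": int(sub["inv_chroms"].sum()) / total_chroms,
        }
        for _, row in sub.iterrows():
            n2 = int(2 * row["n"])
            if n2 == 0:
                continue
            for arr in ("anc", "inv"):
                obs = int(row[f"{arr}_chroms"])
                tests.append((str(row["population"]), str(region), arr, obs, n2, pooled[arr]))
    family = len(tests)
    for pop, region, arr, obs, n2, q in tests:
        draws = rng.binomial(n2, q, size=B)
        p_raw = (1.0 + np.count_nonzero(draws >= obs)) / (B + 1.0)
        results.append(
            BootstrapResult(
                population=pop,
                region=region,
                arrangement=arr,
                observed=obs,
                n_chromosomes=n2,
                pooled_freq=q,
                B=B,
                p_raw=float(p_raw),
                p_bonferroni=float(min(1.0, p_raw * family)),
                family_size=family,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (Levene conditional distribution)


def _levene_het_distribution(n: int, n_alt: int) -> tuple[np.ndarray, np.ndarray]:
    """Heterozygote-count distribution given allele counts (n diploids).

    Returns (het counts of matching parity, probabilities).  The
    conditional probability of n_het heterozygotes given n individuals and
    n_alt minor-allele copies is

        P(n_het) = C * 2^n_het * n! / (n_hom_ref! n_het! n_hom_alt!)

    normalised over all feasible n_het with n_het = n_alt (mod 2).
    """
    n_alt = min(n_alt, 2 * n - n_alt)
    hets = np.arange(n_alt % 2, n_alt + 1, 2)
    logs = np.empty(len(hets))
    for i, h in enumerate(hets):
        hom_alt = (n_alt - h) // 2
        hom_ref = n - h - hom_alt
        if hom_ref < 0:
            logs[i] = -np.inf
            continue
        logs[i] = (
            h * np.log(2.0)
            + lgamma(n + 1)
            - lgamma(hom_ref + 1)
            - lgamma(h + 1)
            - lgamma(hom_alt + 1)
        )
    ok = np.isfinite(logs)
    hets, logs = hets[ok], logs[ok]
    logs -= logs.max()
    probs = np.exp(logs)
    probs /= probs.sum()
    return hets, probs


def hwe_exact(n_anc: int, n_het: int, n_inv: int) -> float:
    """Two-sided exact Hardy-Weinberg p for anc/het/inv counts.

    Sums Levene-conditional probabilities of all heterozygote counts whose
    probability does not exceed that of the observed configuration.
    """
    if min(n_anc, n_het, n_inv) < 0:
        raise ValueError("negative count")
    n = n_anc + n_het + n_inv
    if n == 0:
        raise ValueError("all counts zero")
    n_alt = n_het + 2 * n_inv
    if n_alt == 0 or n_alt == 2 * n:
        return 1.0
    hets, probs = _levene_het_distribution(n, n_alt)
    p_obs = probs[hets == n_het]
    if len(p_obs) == 0:
        raise ValueError("heterozygote count incompatible with allele counts")
    return float(min(1.0, probs[probs <= p_obs[0] * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# combination census and coverage probability


def combination_census(
    calls: list[KaryotypeCall], regions: list[str]
) -> tuple[set[tuple[str, ...]], int, int]:
    """Observed karyotype-state triples across regions.

    Returns (observed combination set, observed count, total possible =
    3^len(regions)).  Individuals missing a call at any region are excluded.
    """
    by_ind: dict[str, dict[str, str]] = {}
    for c in calls:
        by_ind.setdefault(c.individual, {})[c.region] = c.state
    observed: set[tuple[str, ...]] = set()
    n_excluded = 0
    for ind, states in by_ind.items():
        if not all(r in states for r in regions):
            n_excluded += 1
            continue
        observed.add(tuple(states[r] for r in regions))
    if n_excluded:
        import logging

        logging.getLogger(__name__).info(
            "combination_census: excluded %d individuals lacking calls", n_excluded
        )
    return observed, len(observed), 3 ** len(regions)


def combo_coverage_probability(
    genotype_freqs: list[np.ndarray],
    N: int,
    B: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """P(all state combinations appear in an iid sample of N individuals).

    ``genotype_freqs`` holds one length-3 (anc, het, inv) frequency vector
    per region; regions combine independently, so the probability of a
    state triple is the product of its per-region genotype frequencies.
    Monte-Carlo estimate with standard error.  Returns exact 0 when N is
    below the number of combinations or any combination has probability 0.
    """
    freqs = [np.asarray(f, dtype=float) for f in genotype_freqs]
    for f in freqs:
        if abs(f.sum() - 1.0) > 1e-8:
            raise ValueError("genotype frequencies must sum to 1")
    n_combo = 3 ** len(freqs)
    p_combo = freqs[0]
    for f in freqs[1:]:
        p_combo = np.outer(p_combo, f).ravel()
    if N < n_combo or np.any(p_combo <= 0.0):
        return 0.0, 0.0
    rng = np.random.default_rng(seed)
    hits = 0
    chunk = max(1, min(B, int(2e7) // max(N, 1)))
    done = 0
    while done < B:
        b = min(chunk, B - done)
        draws = rng.choice(n_combo, size=(b, N), p=p_combo)
        counts = np.zeros((b, n_combo), dtype=np.int32)
        for k in range(n_combo):
            counts[:, k] = (draws == k).sum(axis=1)
        hits += int(np.all(counts > 0, axis=1).sum())
        done += b
    p_hat = hits / B
    se = float(np.sqrt(max(p_hat * (1 - p_hat), 1.0 / B / B) / B))
    return float(p_hat), se


# ---------------------------------------------------------------------------
# whole-genome genotype-class assignment


def assign_genotype_class(
    pc_scores: np.ndarray,
    samples: list[str],
    reference_labels: dict[str, str],
    tau: float = 0.5,
) -> dict[str, str]:
    """Assign individuals to genotype classes from whole-genome PC1-PC2.

    Class centroids are the mean PC1-PC2 positions of the reference-labelled
    individuals.  An individual gets its nearest centroid's class iff the
    nearest distance is < tau x the distance to the second-nearest centroid;
    otherwise "intermediate".  The PCA feeding this should exclude the
    inversion-carrying chromosomes.
    """
    xy = np.asarray(pc_scores)[:, :2]
    classes = sorted(set(reference_labels.values()))
    if len(classes) < 2:
        raise ValueError("need at least 2 reference classes")
    idx_by_class = {
        c: [i for i, s in enumerate(samples) if reference_labels.get(s) == c] for c in classes
    }
    for c, idx in idx_by_class.items():
        if len(idx) == 0:
            raise ValueError(f"no reference individuals for class {c!r}")
    centroids = np.stack([xy[idx_by_class[c]].mean(axis=0) for c in classes])
    out: dict[str, str] = {}
    for i, s in enumerate(samples):
        d = np.linalg.norm(centroids - xy[i], axis=1)
        order = np.argsort(d)
        if d[order[0]] < tau * d[order[1]]:
            out[s] = classes[order[0]]
        else:
            out[s] = "intermediate"
    return out
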