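"""SNP-panel QC, diversity statistics, distances, clustering and PCA.

Genotypes are biallelic dosages (0 = homozygous A, 1 = heterozygous,
2 = homozygous B, NaN = missing) in a samples x markers matrix with a
marker map (chromosome, position). QC mirrors the standard inbred-panel
filters: drop markers with too much missing data, a near-monomorphic
major-allele frequency, or excess heterozygosity. Diversity statistics
are the classical per-marker quantities: major-allele frequency, gene
diversity (expected heterozygosity 1 - p^2 - q^2), Botstein's PIC, and
observed heterozygosity.

Distances are computed pairwise-complete: Jaccard dissimilarity on an
allele-presence bit expansion (each call becomes two presence bits), or
identity-by-state (1 - shared alleles / 2 x co-called markers). Ward
clustering uses the Lance-Williams update on the supplied
dissimilarities (the ward.D2 convention); PCA is an eigendecomposition
of the column-centered dosage matrix with marker-mean imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score


class EmptyPanelError(ValueError):
    """All markers were removed by QC."""


@dataclass
class GenotypeMatrix:
    """Dosage-coded biallelic SNP calls with a marker map."""

    samples: list[str]
    calls: np.ndarray  # n_samples x n_markers float, NaN = missing
    marker_map: pd.DataFrame  # columns: marker, chromosome, position

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.samples), len(self.marker_map)):
            raise ValueError("calls shape does not match samples x markers")
        ok = np.isnan(self.calls) | np.isin(self.calls, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("calls must be 0, 1, 2 or missing")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.marker_map)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.calls, index=self.samples, columns=self.marker_map["marker"]
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, marker_map: pd.DataFrame | None = None
    ) -> "GenotypeMatrix":
        """Build from a samples x markers dosage table (index = samples)."""
        if marker_map is None:
            marker_map = pd.DataFrame(
                {
                    "marker": list(frame.columns),
                    "chromosome": "1",
                    "position": np.arange(1, frame.shape[1] + 1),
                }
            )
        return cls(
            samples=list(frame.index),
            calls=frame.to_numpy(dtype=float),
            marker_map=marker_map.reset_index(drop=True),
        )

    @classmethod
    def read_csv(cls, genotype_path, map_path=None, sep=",") -> "GenotypeMatrix":
        """Read a dosage matrix CSV/TSV (rows = samples) plus a map sidecar."""
        frame = pd.read_csv(genotype_path, sep=sep, index_col=0, comment="#")
        marker_map = None
        if map_path is not None:
            marker_map = pd.read_csv(map_path, sep=sep, comment="#")
        return cls.from_frame(frame, marker_map)

    @classmethod
    def read_vcf(cls, path) -> tuple["GenotypeMatrix", int]:
        """Read biallelic SNPs from a VCF; returns (panel, n_multiallelic).

        Multiallelic sites are rejected and counted. Genotypes are
        collapsed to alt-allele dosage; missing calls become NaN.
        """
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        rows, markers, chroms, positions = [], [], [], []
        n_multi = 0
        for var in vcf:
            if len(var.ALT) != 1 or var.ALT[0] not in "ACGT" or len(var.REF) != 1:
                n_multi += 1
                continue
            dosages = []
            for gt in var.genotypes:
                alleles = [a for a in gt[:-1] if a >= 0]
                dosages.append(float(sum(alleles)) if alleles else np.nan)
            rows.append(dosages)
            markers.append(var.ID or f"{var.CHROM}_{var.POS}")
            chroms.append(str(var.CHROM))
            positions.append(int(var.POS))
        calls = np.array(rows, dtype=float).T if rows else np.empty((len(samples), 0))
        marker_map = pd.DataFrame(
            {"marker": markers, "chromosome": chroms, "position": positions}
        )
        return cls(samples=samples, calls=calls, marker_map=marker_map), n_multi

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=list(self.samples),
            calls=self.calls[:, keep],
            marker_map=self.marker_map.iloc[keep].reset_index(drop=True),
        )


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities in [0, 1] with co-call counts."""

    metric: str
    samples: list[str]
    values: np.ndarray  # n x n
    pair_counts: np.ndarray  # co-called markers per pair

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.samples)

    def condensed(self) -> np.ndarray:
        if np.isnan(self.values).any():
            raise ValueError(
                "distance matrix has missing entries; impute or drop the pair"
            )
        return squareform(self.values, checks=False)


def _marker_stats_arrays(calls: np.ndarray):
    n_called = np.sum(~np.isnan(calls), axis=0)
    with np.errstate(invalid="ignore"):
        alt = np.nansum(calls, axis=0)
        p_alt = np.where(n_called > 0, alt / (2 * np.maximum(n_called, 1)), np.nan)
        het = np.where(
            n_called > 0,
            np.sum(calls == 1.0, axis=0) / np.maximum(n_called, 1),
            np.nan,
        )
    p_major = np.maximum(p_alt, 1 - p_alt)
    call_rate = n_called / calls.shape[0]
    return p_major, het, call_rate, n_called


def filter_markers(
    g: GenotypeMatrix,
    max_missing: float = 0.10,
    max_major_af: float = 0.95,
    max_het: float = 0.20,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop markers failing the missingness, MAF or heterozygosity filters.

    Retains markers with missing fraction <= max_missing AND major
    allele frequency <= max_major_af AND observed heterozygosity
    <= max_het (criteria are conjunctive, so filtering is
    order-independent). Returns the filtered panel and a QC report with
    per-criterion failure tallies and the first-failing criterion
    attributed per removed marker.
    """
    p_major, het, call_rate, n_called = _marker_stats_arrays(g.calls)
    missing_frac = 1 - call_rate
    fail_missing = missing_frac > max_missing
    fail_maf = np.where(np.isnan(p_major), True, p_major > max_major_af)
    fail_het = np.where(np.isnan(het), True, het > max_het)
    keep = ~(fail_missing | fail_maf | fail_het)
    if not keep.any():
        raise EmptyPanelError("QC removed every marker")

    first_fail = np.full(g.n_markers, "", dtype=object)
    first_fail[fail_het] = "heterozygosity"
    first_fail[fail_maf] = "major_allele_frequency"
    first_fail[fail_missing] = "missing_data"  # attribution order: missing, MAF, het

    report = pd.DataFrame(
        {
            "criterion": [
                "input_markers",
                "fail_missing_data",
                "fail_major_allele_frequency",
                "fail_heterozygosity",
                "removed_total",
                "retained",
            ],
            "count": [
                g.n_markers,
                int(fail_missing.sum()),
                int(fail_maf.sum()),
                int(fail_het.sum()),
                int((~keep).sum()),
                int(keep.sum()),
            ],
        }
    )
    report.attrs["first_failing"] = pd.Series(
        first_fail[~keep], index=g.marker_map["marker"][~keep]
    )
    report.attrs["thresholds"] = {
        "max_missing": max_missing,
        "max_major_allele_frequency": max_major_af,
        "max_heterozygosity": max_het,
    }
    return g.subset_markers(np.flatnonzero(keep)), report


def marker_summary(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker MAF, gene diversity, PIC, observed het and call rate.

    For a biallelic marker with allele frequencies p and q = 1 - p:
    gene diversity = 1 - p^2 - q^2 = 2pq, and
    PIC = 1 - (p^2 + q^2) - 2 p^2 q^2 (Botstein's measure, max 0.375).
    Chromosome and global summaries are unweighted means over markers
    with at least one call; use ``.attrs["by_chromosome"]`` and
    ``.attrs["global"]``.
    """
    if g.n_markers == 0:
        raise EmptyPanelError("no markers to summarize")
    p_major, het, call_rate, n_called = _marker_stats_arrays(g.calls)
    p, q = p_major, 1 - p_major
    gene_div = 1 - p**2 - q**2
    pic = 1 - (p**2 + q**2) - 2 * p**2 * q**2
    stats = pd.DataFrame(
        {
            "marker": g.marker_map["marker"],
            "chromosome": g.marker_map["chromosome"],
            "position": g.marker_map["position"],
            "major_allele_frequency": p_major,
            "gene_diversity": gene_div,
            "pic": pic,
            "observed_heterozygosity": het,
            "call_rate": call_rate,
        }
    )
    called = stats[n_called > 0]
    cols = [
        "major_allele_frequency",
        "gene_diversity",
        "pic",
        "observed_heterozygosity",
        "call_rate",
    ]
    stats.attrs["by_chromosome"] = called.groupby("chromosome")[cols].mean()
    stats.attrs["global"] = called[cols].mean()
    return stats


def _pairwise(calls: np.ndarray, kernel) -> tuple[np.ndarray, np.ndarray]:
    n = calls.shape[0]
    values = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(calls[i]) & ~np.isnan(calls[j])
            counts[i, j] = counts[j, i] = int(both.sum())
            if counts[i, j] == 0:
                values[i, j] = values[j, i] = np.nan
                continue
            d = kernel(calls[i, both], calls[j, both])
            values[i, j] = values[j, i] = d
    return values, counts


def jaccard_distance(
    g: GenotypeMatrix, shared_genotype: bool = False
) -> DistanceMatrix:
    """Pairwise Jaccard dissimilarity over co-called markers.

    Each dosage expands to two allele-presence bits (0 -> A only,
    1 -> both, 2 -> B only); the dissimilarity is 1 - |intersection| /
    |union| over those bits. With ``shared_genotype=True`` the
    alternative convention treats each marker as one item shared iff
    the dosages are identical.
    """
    if g.n_samples < 2:
        raise ValueError("need at least 2 samples")

    def bits_kernel(a: np.ndarray, b: np.ndarray) -> float:
        a_hasA, a_hasB = a <= 1, a >= 1
        b_hasA, b_hasB = b <= 1, b >= 1
        inter = np.sum(a_hasA & b_hasA) + np.sum(a_hasB & b_hasB)
        union = np.sum(a_hasA | b_hasA) + np.sum(a_hasB | b_hasB)
        return 1.0 - inter / union if union else np.nan

    def shared_kernel(a: np.ndarray, b: np.ndarray) -> float:
        return 1.0 - np.mean(a == b)

    kernel = shared_kernel if shared_genotype else bits_kernel
    values, counts = _pairwise(g.calls, kernel)
    return DistanceMatrix("jaccard", list(g.samples), values, counts)


def ibs_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """Identity-by-state distance: 1 - shared alleles / (2 co-called).

    Shared alleles per marker = 2 - |dosage difference|, so identical
    co-called dosages give distance 0 and opposite homozygotes give 1.
    """
    if g.n_samples < 2:
        raise ValueError("need at least 2 samples")

    def kernel(a: np.ndarray, b: np.ndarray) -> float:
        shared = np.sum(2.0 - np.abs(a - b))
        return 1.0 - shared / (2.0 * len(a))

    values, counts = _pairwise(g.calls, kernel)
    return DistanceMatrix("ibs", list(g.samples), values, counts)


@dataclass
class WardClustering:
    linkage: np.ndarray
    samples: list[str]
    convention: str = "ward.D2"

    def cut(self, k: int) -> pd.Series:
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.samples, name="cluster")

    def newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node):
            if node.is_leaf():
                return self.samples[node.id]
            left, right = walk(node.get_left()), walk(node.get_right())
            dl = node.dist - node.get_left().dist
            dr = node.dist - node.get_right().dist
            return f"({left}:{dl:.6g},{right}:{dr:.6g})"

        return walk(tree) + ";"


def ward_cluster(d: DistanceMatrix) -> WardClustering:
    """Ward minimum-variance hierarchical clustering of a distance matrix.

    Uses the Lance-Williams Ward update on the supplied dissimilarities
    (ward.D2 convention: the input distances are treated as Euclidean
    analogues). Merge heights are non-decreasing.
    """
    z = hierarchy.linkage(d.condensed(), method="ward")
    return WardClustering(linkage=z, samples=list(d.samples))


def pca_genotypes(g: GenotypeMatrix, scale: bool = False):
    """PCA of the dosage matrix: scores and percent variance per axis.

    Dosages are column-centered with marker-mean imputation of missing
    calls; components come from the singular value decomposition of the
    centered matrix, so percent variance = eigenvalue / trace x 100 and
    the percentages sum to 100 over all axes. ``scale=True`` divides
    each column by its standard deviation first.
    """
    if g.n_samples < 2 or g.n_markers < 2:
        raise ValueError("need at least 2 samples and 2 markers")
    x = g.calls.copy()
    col_mean = np.nanmean(x, axis=0)
    idx = np.where(np.isnan(x))
    x[idx] = np.take(col_mean, idx[1])
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        x = x / np.where(sd > 0, sd, 1.0)
    if not np.any(x):
        raise ValueError("constant genotype matrix: no variance to decompose")
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    eig = s**2 / (g.n_samples - 1)
    pct = 100.0 * eig / eig.sum()
    scores = pd.DataFrame(
        u * s,
        index=g.samples,
        columns=[f"PC{i + 1}" for i in range(len(s))],
    )
    return scores, pct


def silhouette_k(
    d: DistanceMatrix, k_range=range(2, 11)
) -> tuple[int, pd.DataFrame]:
    """Pick the cluster number maximizing the mean silhouette width.

    Clusters are Ward cuts of *d* at each k in *k_range* (k >= n is
    skipped with a note); ties break to the smallest k. Returns the
    selected k and the full score table.
    """
    n = len(d.samples)
    if n < 3:
        raise ValueError("need at least 3 samples for silhouette selection")
    clust = ward_cluster(d)
    rows = []
    for k in k_range:
        if k >= n:
            rows.append({"k": k, "silhouette": np.nan, "note": "k >= n, skipped"})
            continue
        labels = clust.cut(k).to_numpy()
        score = silhouette_score(d.values, labels, metric="precomputed")
        rows.append({"k": k, "silhouette": float(score), "note": ""})
    scores = pd.DataFrame(rows)
    valid = scores.dropna(subset=["silhouette"])
    if valid.empty:
        raise ValueError("no feasible k in range")
    best = int(valid.loc[valid["silhouette"].idxmax(), "k"])
    return best, scores
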