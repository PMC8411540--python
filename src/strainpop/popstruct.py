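"""Population structure: clonal pruning, chromosome painting, clustering, Fst.

The painting model is a deliberate simplification of the ChromoPainter /
fineSTRUCTURE machinery: the SNP matrix is cut into consecutive windows and,
for each recipient and window, the non-self donor(s) at minimal Hamming
distance receive equal shares of one "chunk".  Under a uniform recombination
rate the window-local nearest donor carries the dominant copying signal, and
unlike an HMM + MCMC chain the procedure is deterministic and exactly
testable.  Population assignment replaces the fineSTRUCTURE MCMC with
average-linkage hierarchical clustering of row-normalized co-ancestry
profiles, choosing K by maximal mean silhouette.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.metrics import silhouette_score

from .coresnp import DistanceMatrix, SnpMatrix
from .errors import ParameterError

log = logging.getLogger("strainpop")

#: silhouette below which the clustering is flagged as weak structure
WEAK_SILHOUETTE = 0.25


@dataclass
class CoancestryMatrix:
    """Recipient x donor chunk counts; every row sums to the window count."""

    ids: list[str]
    matrix: np.ndarray
    n_windows: int
    window_snps: int

    def row_profiles(self) -> np.ndarray:
        return self.matrix / self.n_windows

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)


@dataclass
class PopulationAssignment:
    labels: dict[str, str]

    @property
    def k(self) -> int:
        return len(set(self.labels.values()))

    def members(self, pop: str) -> list[str]:
        return [s for s, p in self.labels.items() if p == pop]


def single_linkage_clusters(d: DistanceMatrix, threshold: float) -> list[list[str]]:
    """Connected components of the graph {d < threshold} (single linkage)."""
    adj = (d.values < threshold).astype(np.int8)
    np.fill_diagonal(adj, 0)
    _, comp = connected_components(csr_matrix(adj), directed=False)
    out: dict[int, list[str]] = {}
    for sid, c in zip(d.ids, comp):
        out.setdefault(int(c), []).append(sid)
    return [out[c] for c in sorted(out)]


def prune_clonal(
    d: DistanceMatrix, threshold: int = 300, seed: int | None = None
) -> tuple[list[str], list[list[str]]]:
    """Collapse clonal clusters (single-linkage components at d < threshold)
    to one representative each, chosen uniformly at random under ``seed``.

    Among the returned representatives all pairwise distances are >= threshold.
    """
    rng = np.random.default_rng(seed)
    clusters = single_linkage_clusters(d, threshold)
    reps = []
    for members in clusters:
        reps.append(members[int(rng.integers(len(members)))] if len(members) > 1
                    else members[0])
    reps = [s for s in d.ids if s in set(reps)]  # preserve input order
    return reps, clusters


def _window_bounds(n_sites: int, window_snps: int) -> list[tuple[int, int]]:
    """Consecutive windows of ``window_snps`` columns; a trailing partial
    window is kept if >= half size, else merged into the previous one."""
    bounds = []
    start = 0
    while start < n_sites:
        end = min(start + window_snps, n_sites)
        bounds.append((start, end))
        start = end
    if len(bounds) > 1 and (bounds[-1][1] - bounds[-1][0]) < window_snps / 2:
        last = bounds.pop()
        bounds[-1] = (bounds[-1][0], last[1])
    return bounds


def paint_chromosomes(
    snps: SnpMatrix, window_snps: int = 100
) -> tuple[CoancestryMatrix, list[list[np.ndarray]]]:
    """Per-window nearest-donor chromosome painting.

    Returns the co-ancestry matrix and the per-window donor record: for each
    window, a list over recipients of the donor index arrays that tied for
    minimal Hamming distance (each sharing 1/n_ties of one chunk).
    """
    n = snps.n_strains
    if n < 3:
        raise ParameterError("painting requires at least 3 strains")
    if snps.n_sites < window_snps:
        raise ParameterError("fewer SNP columns than one full window")
    bounds = _window_bounds(snps.n_sites, window_snps)
    ca = np.zeros((n, n), dtype=np.float64)
    window_donors: list[list[np.ndarray]] = []
    X = snps.alleles
    for lo, hi in bounds:
        W = X[:, lo:hi]
        valid = W >= 0
        # mismatches over sites where both calls are non-missing
        diff = (W[:, None, :] != W[None, :, :]) & valid[:, None, :] & valid[None, :, :]
        ham = diff.sum(axis=2).astype(np.float64)
        np.fill_diagonal(ham, np.inf)
        donors_this_window = []
        for i in range(n):
            best = ham[i].min()
            winners = np.flatnonzero(ham[i] == best)
            ca[i, winners] += 1.0 / winners.size
            donors_this_window.append(winners)
        window_donors.append(donors_this_window)
    return CoancestryMatrix(list(snps.strain_ids), ca, len(bounds), window_snps), window_donors


def cluster_populations(
    ca: CoancestryMatrix, k_range: range = range(2, 11)
) -> tuple[PopulationAssignment, dict]:
    """Assign strains to populations from their co-ancestry profiles.

    Average-linkage hierarchical clustering of row-normalized profiles
    (Euclidean metric); K maximizes the mean silhouette over ``k_range``
    (smallest K on ties).  Deterministic given the input.  The info dict
    carries the silhouette curve and a ``weak_structure`` flag.
    """
    n = len(ca.ids)
    ks = [k for k in k_range if 2 <= k <= n - 1]
    if not ks:
        raise ParameterError(f"k_range {k_range} outside [2, {n - 1}]")
    profiles = ca.row_profiles()
    with warnings.catch_warnings():
        # profiles are observations; an n x n observation matrix trips
        # scipy's uncondensed-distance-matrix heuristic
        warnings.simplefilter("ignore")
        Z = linkage(profiles, method="average", metric="euclidean")
    sil: dict[int, float] = {}
    labelings: dict[int, np.ndarray] = {}
    for k in ks:
        lab = fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(lab)) < 2:
            sil[k] = -1.0
        else:
            sil[k] = float(silhouette_score(profiles, lab, metric="euclidean"))
        labelings[k] = lab
    best_k = max(ks, key=lambda k: (sil[k], -k))
    lab = labelings[best_k]
    # stable population names: pop1 = cluster of the first strain, etc.
    order: dict[int, str] = {}
    labels: dict[str, str] = {}
    for sid, c in zip(ca.ids, lab):
        if int(c) not in order:
            order[int(c)] = f"pop{len(order) + 1}"
        labels[sid] = order[int(c)]
    info = {"silhouette": sil, "k": best_k,
            "weak_structure": sil[best_k] < WEAK_SILHOUETTE}
    if info["weak_structure"]:
        log.warning("weak population structure: best silhouette %.3f", sil[best_k])
    return PopulationAssignment(labels), info


def small_cluster_rerun(
    assignment: PopulationAssignment,
    snps: SnpMatrix,
    min_size: int = 4,
    window_snps: int = 100,
    k_range: range = range(2, 11),
    seed: int | None = None,
) -> tuple[PopulationAssignment, dict]:
    """Collapse residual clonal signal and re-cluster.

    Clusters smaller than ``min_size`` are treated as undetected clonal
    groups: all but one randomly chosen member are dropped, then painting and
    clustering are repeated on the reduced strain set.  With no small
    cluster, the assignment is returned unchanged (no rerun).
    """
    rng = np.random.default_rng(seed)
    small = [p for p in sorted(set(assignment.labels.values()))
             if len(assignment.members(p)) < min_size]
    if not small:
        return assignment, {"rerun": False, "dropped": []}
    dropped: list[str] = []
    keep = list(assignment.labels)
    for p in small:
        members = assignment.members(p)
        rep = members[int(rng.integers(len(members)))]
        for s in members:
            if s != rep:
                dropped.append(s)
    keep = [s for s in keep if s not in set(dropped)]
    sub = snps.subset_strains(keep)
    ca, _ = paint_chromosomes(sub, window_snps=window_snps)
    new_assignment, info = cluster_populations(ca, k_range=k_range)
    info.update({"rerun": True, "dropped": dropped})
    return new_assignment, info


def compute_palettes(
    ca: CoancestryMatrix, assignment: PopulationAssignment
) -> pd.DataFrame:
    """Per-strain fraction of painted chunk mass received from each population.

    Rows sum to 1 (chunk mass is conserved by tie-splitting).
    """
    pops = sorted(set(assignment.labels.values()))
    indicator = np.array([[1.0 if assignment.labels.get(d) == p else 0.0
                           for p in pops] for d in ca.ids])
    mass = ca.matrix @ indicator
    frac = mass / mass.sum(axis=1, keepdims=True)
    return pd.DataFrame(frac, index=ca.ids, columns=pops)


def _theta_components(
    alleles: np.ndarray, pop_index: list[np.ndarray]
) -> tuple[float, float]:
    """Sum of haploid Weir-Cockerham variance components (a, a+b) over loci.

    One-way ANOVA on haploid allele indicators: per locus with r populations,
    sizes n_i and alt frequencies p_i,

        MSP = sum n_i (p_i - pbar)^2 / (r - 1)
        MSG = sum n_i p_i (1 - p_i) / (N - r)
        n_c = (N - sum n_i^2 / N) / (r - 1)
        a = (MSP - MSG) / n_c,   b = MSG

    Monomorphic loci contribute 0/0 and are skipped.
    """
    sum_a = 0.0
    sum_ab = 0.0
    for j in range(alleles.shape[1]):
        ns, ps = [], []
        for idx in pop_index:
            col = alleles[idx, j]
            col = col[col >= 0]
            if col.size == 0:
                continue
            ns.append(col.size)
            ps.append(col.mean())
        r = len(ns)
        if r < 2:
            continue
        ns_arr = np.asarray(ns, dtype=float)
        ps_arr = np.asarray(ps, dtype=float)
        N = ns_arr.sum()
        if N <= r:
            continue
        pbar = (ns_arr * ps_arr).sum() / N
        if pbar <= 0.0 or pbar >= 1.0:
            continue
        msp = (ns_arr * (ps_arr - pbar) ** 2).sum() / (r - 1)
        msg = (ns_arr * ps_arr * (1.0 - ps_arr)).sum() / (N - r)
        n_c = (N - (ns_arr ** 2).sum() / N) / (r - 1)
        a = (msp - msg) / n_c
        sum_a += a
        sum_ab += a + msg
    return sum_a, sum_ab


def weir_cockerham_fst(
    snps: SnpMatrix, assignment: PopulationAssignment
) -> pd.DataFrame:
    """Multi-locus haploid Weir-Cockerham theta, per population pair and overall.

    theta = sum_l a_l / sum_l (a_l + b_l); populations with fewer than 2
    members are excluded with a warning.  The estimator is invariant to a
    global 0<->1 allele-label swap and equals 1 for fixed differences.
    """
    pops = sorted(set(assignment.labels.values()))
    usable = []
    for p in pops:
        members = [s for s in assignment.members(p) if s in snps.strain_ids]
        if len(members) < 2:
            log.warning("population %s has < 2 members; excluded from Fst", p)
            continue
        usable.append((p, np.array([snps.strain_ids.index(s) for s in members])))
    if len(usable) < 2:
        raise ParameterError("need at least 2 populations with >= 2 members")

    rows = []
    for i in range(len(usable)):
        for j in range(i + 1, len(usable)):
            (pa, ia), (pb, ib) = usable[i], usable[j]
            sa, sab = _theta_components(snps.alleles, [ia, ib])
            rows.append({"pop1": pa, "pop2": pb,
                         "theta": sa / sab if sab > 0 else np.nan})
    sa, sab = _theta_components(snps.alleles, [idx for _, idx in usable])
    rows.append({"pop1": "overall", "pop2": "overall",
                 "theta": sa / sab if sab > 0 else np.nan})
    return pd.DataFrame(rows)
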