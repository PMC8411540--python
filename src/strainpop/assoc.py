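"""Variant-phenotype association: population scans, enrichment, sketch
distances, MDS structure covariates, and fixed-effect GWAS.

Two scan flavours mirror the two questions asked of the cohort:

* ``population_scan`` — one-vs-rest Fisher exact tests per variant with *no*
  structure correction (deliberate: the scan looks for the markers that
  define the populations themselves), 5-95% carriage filter, Bonferroni
  0.05/m.
* ``phenotype_gwas`` — fixed-effect association of variants with a host
  phenotype (continuous OLS / binary logistic with Firth fallback), with
  classical-MDS axes of a MinHash sketch distance matrix as population
  structure covariates, 1-99% carriage filter, Bonferroni 0.05/m.

Fisher p-values are computed by exact integer hypergeometric enumeration,
so they agree with a brute-force oracle to floating-point rounding.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .coresnp import AlignedGenomeSet, DistanceMatrix
from .errors import ParameterError
from .popstruct import PopulationAssignment

log = logging.getLogger("strainpop")


# ---------------------------------------------------------------------------
# Exact Fisher tests (integer hypergeometric enumeration)

def _hypergeom_weights(row1: int, row2: int, col1: int) -> tuple[int, int, list[int]]:
    """Integer weights N_k = C(row1, k) C(row2, col1-k) over the support."""
    lo = max(0, col1 - row2)
    hi = min(row1, col1)
    w = [math.comb(row1, lo) * math.comb(row2, col1 - lo)]
    for k in range(lo, hi):
        # N_{k+1} = N_k (row1-k)(col1-k) / ((k+1)(row2-col1+k+1))
        w.append(w[-1] * (row1 - k) * (col1 - k)
                 // ((k + 1) * (row2 - col1 + k + 1)))
    return lo, hi, w


def fisher_exact_twosided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for table [[a, b], [c, d]].

    Sums hypergeometric probabilities <= P(observed); ties are resolved by
    exact integer comparison, so there is no float tie tolerance.
    """
    lo, _, w = _hypergeom_weights(a + b, c + d, a + c)
    obs = w[a - lo]
    total = sum(w)
    return sum(x for x in w if x <= obs) / total


def fisher_exact_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater) Fisher exact p: P(X >= a) under the null."""
    lo, _, w = _hypergeom_weights(a + b, c + d, a + c)
    total = sum(w)
    return sum(w[a - lo:]) / total


def _log_odds(a: int, b: int, c: int, d: int) -> float:
    """Log odds ratio with Haldane-Anscombe 0.5 correction on zero cells."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return math.log(a * d / (b * c))


# ---------------------------------------------------------------------------
# Variant filtering and population scans

def filter_variants(matrix: pd.DataFrame, min_frac: float, max_frac: float) -> pd.DataFrame:
    """Keep variants with carriage fraction strictly inside (min_frac, max_frac).

    ``matrix`` is strains x variants, boolean/0-1.
    """
    if min_frac >= max_frac:
        raise ParameterError(f"min_frac {min_frac} must be < max_frac {max_frac}")
    frac = matrix.astype(float).mean(axis=0)
    keep = (frac > min_frac) & (frac < max_frac)
    return matrix.loc[:, keep]


def population_scan(
    variants: pd.DataFrame,
    assignment: PopulationAssignment,
    target_pop: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-vs-rest scan for variants over/under-represented in ``target_pop``.

    Two-sided Fisher exact per variant, no structure covariates, Bonferroni
    threshold alpha/m with m = number of variants tested.
    """
    pops = set(assignment.labels.values())
    if len(pops) < 2:
        raise ParameterError("need at least 2 populations")
    if target_pop not in pops:
        raise ParameterError(f"population {target_pop!r} not in assignment")
    strains = [s for s in variants.index if s in assignment.labels]
    V = variants.loc[strains].to_numpy().astype(bool)
    in_pop = np.array([assignment.labels[s] == target_pop for s in strains])
    n1, n2 = int(in_pop.sum()), int((~in_pop).sum())
    m = V.shape[1]
    threshold = alpha / m if m else np.nan

    rows = []
    for j, vid in enumerate(variants.columns):
        a = int(V[in_pop, j].sum())       # carriers in target
        c = int(V[~in_pop, j].sum())      # carriers in rest
        b, d = n1 - a, n2 - c
        p = fisher_exact_twosided(a, b, c, d)
        rows.append({
            "variant": vid, "population": target_pop,
            "carriers_target": a, "n_target": n1,
            "carriers_rest": c, "n_rest": n2,
            "log_odds": _log_odds(a, b, c, d),
            "p": p, "threshold": threshold, "significant": p < threshold,
        })
    return pd.DataFrame(rows)


def merge_hits(results: list[pd.DataFrame]) -> pd.DataFrame:
    """Union of significant variants across scans, tagged with the
    population(s) whose scan flagged each variant."""
    tags: dict[str, list[str]] = {}
    best: dict[str, float] = {}
    for res in results:
        if res.empty:
            continue
        for _, row in res[res["significant"]].iterrows():
            tags.setdefault(row["variant"], []).append(row["population"])
            best[row["variant"]] = min(best.get(row["variant"], 1.0), row["p"])
    rows = [{"variant": v, "populations": ",".join(t), "min_p": best[v]}
            for v, t in tags.items()]
    return pd.DataFrame(rows, columns=["variant", "populations", "min_p"])


def enrichment_test(
    hits: list[str],
    annotation: pd.DataFrame,
    background: list[str],
    alpha: float = 0.01,
    n_terms: int = 220,
) -> pd.DataFrame:
    """COG/KEGG enrichment of hit genes against a reference background.

    One-sided (greater) Fisher exact per term on the hypergeometric model
    "draw len(hits) genes from the background"; a term is significant iff
    p < alpha / n_terms (default 0.01/220 = 4.55e-5).  Hits absent from the
    background are dropped; terms absent from the background are skipped.
    """
    bg = [g for g in background if g in annotation.index]
    bg_set = set(bg)
    used_hits = [g for g in hits if g in bg_set]
    if len(used_hits) < len(hits):
        log.warning("%d hit gene(s) not in the reference background; dropped",
                    len(hits) - len(used_hits))
    threshold = alpha / n_terms

    term_members: dict[tuple[str, str], set[str]] = {}
    ann = annotation.loc[[g for g in bg]]
    for gid, row in ann.iterrows():
        if isinstance(row.get("cog"), str):
            for letter in row["cog"]:
                term_members.setdefault(("COG", letter), set()).add(gid)
        if isinstance(row.get("kegg"), str):
            for kid in row["kegg"].split(";"):
                term_members.setdefault(("KEGG", kid), set()).add(gid)

    N, n = len(bg), len(used_hits)
    rows = []
    for (kind, term), members in sorted(term_members.items()):
        K = len(members)
        a = len(members & set(used_hits))
        p = fisher_exact_greater(a, n - a, K - a, N - K - (n - a))
        rows.append({"kind": kind, "term": term, "hits_in_term": a,
                     "term_size": K, "n_hits": n, "background": N,
                     "p": p, "threshold": threshold, "significant": p < threshold})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# MinHash sketch distances

@dataclass
class SketchConfig:
    """MinHash sketch parameters (tool-style defaults: k=21, s=1000)."""

    k: int = 21
    sketch_size: int = 1000
    hash_seed: int = 42

    def validate(self) -> None:
        if not 1 <= self.k <= 31:
            raise ParameterError(f"k-mer length {self.k} outside [1, 31]")
        if self.sketch_size < 1:
            raise ParameterError("sketch_size must be >= 1")
        if self.k % 2 == 0 or self.k < 11:
            warnings.warn(
                f"k={self.k} is outside the recommended odd 11-31 range",
                stacklevel=2)


def _splitmix64(x: np.ndarray) -> np.ndarray:
    x = (x + np.uint64(0x9E3779B97F4A7C15)).astype(np.uint64)
    x ^= x >> np.uint64(30)
    x = (x * np.uint64(0xBF58476D1CE4E5B9)).astype(np.uint64)
    x ^= x >> np.uint64(27)
    x = (x * np.uint64(0x94D049BB133111EB)).astype(np.uint64)
    x ^= x >> np.uint64(31)
    return x


def _sketch(codes: np.ndarray, cfg: SketchConfig, name: str) -> np.ndarray:
    """Bottom-s sketch of canonical k-mer hashes; gaps/Ns are stripped first."""
    codes = codes[codes >= 0].astype(np.uint64)
    k = cfg.k
    if codes.size < k:
        raise ParameterError(f"sequence of strain {name!r} shorter than k={k}")
    m = codes.size - k + 1
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    for t in range(k):
        fwd = (fwd << np.uint64(2)) | codes[t:t + m]
        rev = (rev << np.uint64(2)) | (np.uint64(3) - codes[k - 1 - t:k - 1 - t + m])
    canon = np.minimum(fwd, rev)
    hashes = _splitmix64(np.unique(canon) ^ np.uint64(cfg.hash_seed))
    hashes = np.unique(hashes)
    return hashes[:cfg.sketch_size]


def sketch_jaccard(h1: np.ndarray, h2: np.ndarray, sketch_size: int) -> float:
    """Mash's merged bottom-s Jaccard estimate from two bottom-s sketches."""
    union = np.union1d(h1, h2)[:sketch_size]
    shared = np.intersect1d(np.intersect1d(union, h1), h2).size
    return shared / union.size if union.size else 0.0


def mash_distance(genomes: AlignedGenomeSet, cfg: SketchConfig | None = None) -> DistanceMatrix:
    """Pairwise MinHash distances d = -(1/k) ln(2j/(1+j)) between strains.

    Gaps and ambiguous bases are stripped before k-merization; with a sketch
    at least as large as the number of distinct k-mers the estimate equals
    the exact Jaccard.  j = 0 (and any d > 1) is capped at 1.
    """
    cfg = cfg or SketchConfig()
    cfg.validate()
    ids = genomes.strain_ids
    sketches = [_sketch(genomes.codes[genomes.ids.index(s)], cfg, s) for s in ids]
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            jac = sketch_jaccard(sketches[i], sketches[j], cfg.sketch_size)
            if jac <= 0.0:
                dist = 1.0
            else:
                dist = min(1.0, -math.log(2.0 * jac / (1.0 + jac)) / cfg.k)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(list(ids), d)


# ---------------------------------------------------------------------------
# Classical MDS covariates

def mds_covariates(d: DistanceMatrix, max_dims: int = 10, var_frac: float = 0.8) -> pd.DataFrame:
    """Classical (Torgerson) MDS axes as population-structure covariates.

    Retains the smallest number of positive-eigenvalue axes whose eigenvalue
    mass reaches ``var_frac`` of the total positive mass, capped at
    ``max_dims``; each axis is sign-fixed so its largest-magnitude loading
    is positive.
    """
    D = d.values.astype(float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = 1e-9 * max(abs(vals[0]), 1.0)
    pos = vals > tol
    if not pos.any():
        raise ParameterError("degenerate distances: no positive MDS eigenvalue")
    pvals = vals[pos]
    cum = np.cumsum(pvals) / pvals.sum()
    ndim = min(int(np.searchsorted(cum, var_frac) + 1), max_dims, pvals.size)
    coords = vecs[:, pos][:, :ndim] * np.sqrt(pvals[:ndim])
    for a in range(ndim):
        if coords[np.abs(coords[:, a]).argmax(), a] < 0:
            coords[:, a] = -coords[:, a]
    out = pd.DataFrame(coords, index=d.ids,
                       columns=[f"MDS{i + 1}" for i in range(ndim)])
    out.attrs["eigenvalues"] = vals
    return out


# ---------------------------------------------------------------------------
# Fixed-effect phenotype GWAS

def _design_with_intercept(covariates: pd.DataFrame | np.ndarray | None,
                           n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    Z = np.column_stack([np.ones(n), C])
    # drop rank-deficient covariate columns (keep leftmost independent set)
    rank = np.linalg.matrix_rank(Z)
    if rank < Z.shape[1]:
        keep = [0]
        for j in range(1, Z.shape[1]):
            trial = Z[:, keep + [j]]
            if np.linalg.matrix_rank(trial) > len(keep):
                keep.append(j)
        log.warning("dropped %d rank-deficient covariate column(s)",
                    Z.shape[1] - len(keep))
        Z = Z[:, keep]
    return Z


def _firth_logistic(X: np.ndarray, y: np.ndarray,
                    max_iter: int = 100, tol: float = 1e-8):
    """Firth-penalized logistic regression (Jeffreys prior score correction)."""
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        mu = expit(X @ beta)
        w = mu * (1.0 - mu)
        F = (X * w[:, None]).T @ X
        Finv = np.linalg.pinv(F)
        h = w * np.einsum("ij,jk,ik->i", X, Finv, X)
        U = X.T @ (y - mu + h * (0.5 - mu))
        step = Finv @ U
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    mu = expit(X @ beta)
    w = mu * (1.0 - mu)
    Finv = np.linalg.pinv((X * w[:, None]).T @ X)
    se = np.sqrt(np.diag(Finv))
    return beta, se


def phenotype_gwas(
    variants: pd.DataFrame,
    phenotype: pd.Series,
    covariates: pd.DataFrame | None = None,
    binary: bool | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fixed-effect GWAS: phenotype ~ variant + MDS covariates, Bonferroni 0.05/m.

    Continuous phenotypes use OLS with a Wald test on the variant term
    (vectorized over variants via Frisch-Waugh residualization; identical to
    a per-variant least-squares fit).  Binary phenotypes use logistic
    regression, falling back to a Firth-penalized fit on separation.
    Strains with missing phenotype are dropped casewise.
    """
    keep = phenotype.dropna().index.intersection(variants.index)
    y = phenotype.loc[keep].to_numpy(dtype=float)
    V = variants.loc[keep].to_numpy(dtype=float)
    C = covariates.loc[keep] if covariates is not None else None
    n = len(keep)
    m = V.shape[1]
    if m == 0 or n < 3:
        raise ParameterError("need at least one variant and 3 strains")
    threshold = alpha / m
    if binary is None:
        binary = set(np.unique(y)) <= {0.0, 1.0}
    Z = _design_with_intercept(C, n)
    c = Z.shape[1]

    if not binary:
        Q, _ = np.linalg.qr(Z)
        yr = y - Q @ (Q.T @ y)
        Vr = V - Q @ (Q.T @ V)
        sxx = (Vr ** 2).sum(axis=0)
        ok = sxx > 1e-12
        beta = np.full(m, np.nan)
        se = np.full(m, np.nan)
        p = np.full(m, np.nan)
        df = n - c - 1
        sxy = Vr.T @ yr
        syy = yr @ yr
        beta[ok] = sxy[ok] / sxx[ok]
        rss = syy - beta[ok] ** 2 * sxx[ok]
        sigma2 = np.maximum(rss, 0.0) / df
        se[ok] = np.sqrt(sigma2 / sxx[ok])
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = beta[ok] / se[ok]
        p[ok] = 2.0 * stats.t.sf(np.abs(tstat), df)
        if (~ok).any():
            log.warning("%d constant variant(s) skipped", int((~ok).sum()))
    else:
        import statsmodels.api as sm
        beta = np.full(m, np.nan)
        se = np.full(m, np.nan)
        p = np.full(m, np.nan)
        for j in range(m):
            x = V[:, j]
            if np.ptp(x) == 0:
                continue
            X = np.column_stack([x, Z])
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
                if not fit.mle_retvals.get("converged", True) or \
                        np.abs(fit.params).max() > 15:
                    raise ValueError("separation suspected")
                beta[j], se[j], p[j] = fit.params[0], fit.bse[0], fit.pvalues[0]
            except Exception:
                b, s = _firth_logistic(X, y)
                beta[j], se[j] = b[0], s[0]
                p[j] = 2.0 * stats.norm.sf(abs(b[0] / s[0])) if s[0] > 0 else np.nan

    out = pd.DataFrame({
        "variant": variants.columns, "beta": beta, "se": se, "p": p,
        "threshold": threshold,
    })
    out["significant"] = out["p"] < threshold
    return out


def genotype_effectsizes(
    variants: pd.DataFrame,
    covariates: pd.DataFrame,
    permutations: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-covariate effect sizes (R^2, permutation p) on the genotype matrix.

    Validates GWAS hits at the whole-genotype level: the binary variant
    matrix is the multivariate response; RDA reports marginal per-covariate
    tests and PERMANOVA (Euclidean distance) sequential ones.  Strains with
    any missing covariate are dropped (count logged); zero-variance
    covariates are excluded.
    """
    from . import community

    cov = covariates.copy()
    complete = cov.dropna().index.intersection(variants.index)
    dropped = len(variants.index) - len(complete)
    if dropped:
        log.warning("%d strain(s) dropped for missing covariates", dropped)
    cov = cov.loc[complete]
    keep_cols = [c for c in cov.columns if cov[c].nunique() > 1]
    for c in cov.columns:
        if c not in keep_cols:
            log.warning("covariate %r has zero variance; excluded", c)
    cov = cov[keep_cols]
    Y = variants.loc[complete].to_numpy(dtype=float)

    rda = community.rda_effects(Y, cov, permutations=permutations, seed=seed)
    rda["method"] = "RDA"
    dist = community.euclidean_distances(Y, list(complete))
    perm = community.permanova(dist, cov, permutations=permutations, seed=seed)
    perm["method"] = "PERMANOVA"
    return pd.concat([rda, perm], ignore_index=True)


def plot_manhattan(results: pd.DataFrame, positions: dict[str, int] | None,
                   path: str) -> None:
    """Manhattan plot (position vs -log10 p) with the Bonferroni line in red."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = results.dropna(subset=["p"])
    x = (np.array([positions.get(v, i) for i, v in enumerate(res["variant"])])
         if positions else np.arange(len(res)))
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.scatter(x, -np.log10(res["p"]), s=6, c="steelblue")
    thr = res["threshold"].iloc[0] if len(res) else np.nan
    if np.isfinite(thr):
        ax.axhline(-np.log10(thr), color="red", lw=1)
    ax.set_xlabel("position")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
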