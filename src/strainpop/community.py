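"""Microbiota composition statistics.

Abundance filtering, the Hellinger transformation, transformation-based
redundancy analysis (tb-RDA), PERMANOVA on Euclidean distances, and
per-taxon group comparisons (Kruskal-Wallis omnibus + pairwise Mann-Whitney
U with a compact letter display).

RDA is performed on Hellinger-transformed abundances and PERMANOVA on the
Euclidean distances of the same matrix; by the Gower identity their R^2
partitions agree when the distance is Euclidean on the same response.
PERMANOVA terms are partitioned sequentially (Type I) in the order given;
RDA reports marginal (unique-contribution) per-term tests.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .coresnp import DistanceMatrix
from .errors import FormatError, ParameterError

log = logging.getLogger("strainpop")

AGE_BIN_EDGES = [0, 18, 46, 66, np.inf]
AGE_BIN_LABELS = ["0-17", "18-45", "46-65", ">65"]


def age_bins(ages: pd.Series) -> pd.Series:
    """Bin ages into the standard cohort categories 0-17 / 18-45 / 46-65 / >65."""
    return pd.cut(ages, bins=AGE_BIN_EDGES, labels=AGE_BIN_LABELS,
                  right=False, include_lowest=True)


def to_relative(table: pd.DataFrame) -> pd.DataFrame:
    """Row-normalize counts to relative abundances."""
    totals = table.sum(axis=1)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise FormatError(f"sample {bad!r} has zero total abundance")
    return table.div(totals, axis=0)


def filter_low_abundance(table: pd.DataFrame, min_frac: float = 0.00005) -> pd.DataFrame:
    """Remove taxa whose dataset-wide relative abundance is below ``min_frac``.

    The fraction is taxon total over grand total (default 0.005%).
    """
    if (table.to_numpy() < 0).any():
        raise FormatError("negative abundance values")
    frac = table.sum(axis=0) / table.to_numpy().sum()
    return table.loc[:, frac >= min_frac]


def hellinger(table: pd.DataFrame) -> pd.DataFrame:
    """Hellinger transform: y' = sqrt(y / row_total); rows get unit sum of squares."""
    totals = table.sum(axis=1)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise FormatError(f"sample {bad!r} has an all-zero abundance row")
    return np.sqrt(table.div(totals, axis=0))


# ---------------------------------------------------------------------------
# Design-matrix plumbing shared by RDA and PERMANOVA

def _dummy_code(covariates: pd.DataFrame) -> tuple[np.ndarray, list[tuple[str, slice]]]:
    """Dummy-code each covariate; returns the design (no intercept) and
    per-term column slices."""
    blocks, spans = [], []
    start = 0
    for name in covariates.columns:
        col = covariates[name]
        if pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col):
            X = col.to_numpy(dtype=float)[:, None]
        else:
            X = pd.get_dummies(col.astype("category"), drop_first=True).to_numpy(dtype=float)
        blocks.append(X)
        spans.append((name, slice(start, start + X.shape[1])))
        start += X.shape[1]
    return np.column_stack(blocks), spans


def _drop_collinear(X: np.ndarray, spans: list[tuple[str, slice]], n: int):
    """Drop columns that add no rank beyond the intercept + earlier columns."""
    cols = [np.ones(n)]
    keep_idx: list[int] = []
    rank = 1
    for j in range(X.shape[1]):
        trial = np.column_stack(cols + [X[:, j]])
        r = np.linalg.matrix_rank(trial)
        if r > rank:
            cols.append(X[:, j])
            keep_idx.append(j)
            rank = r
    if len(keep_idx) < X.shape[1]:
        log.warning("dropped %d collinear design column(s)", X.shape[1] - len(keep_idx))
    new_spans = []
    pos = 0
    for name, sl in spans:
        cnt = sum(1 for j in keep_idx if sl.start <= j < sl.stop)
        new_spans.append((name, slice(pos, pos + cnt)))
        pos += cnt
    return X[:, keep_idx], new_spans


def _projector(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis Q of [1 | X]; projection is QQ^T."""
    n = X.shape[0] if X.ndim == 2 else len(X)
    M = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    Q, R = np.linalg.qr(M)
    keep = np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(R).max())
    return Q[:, keep]


# ---------------------------------------------------------------------------
# tb-RDA


def _safe_f(ss_term: float, df_term: int, ss_resid: float, df_resid: int) -> float:
    """Pseudo-F; +inf for a saturated (zero-residual) design."""
    num = ss_term / max(df_term, 1)
    den = ss_resid / max(df_resid, 1)
    if den <= 0:
        return np.inf if num > 0 else np.nan
    return num / den


def rda_effects(
    response: pd.DataFrame | np.ndarray,
    covariates: pd.DataFrame,
    permutations: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Redundancy analysis of a (Hellinger-transformed) response on host covariates.

    Constrained ordination by least squares on dummy-coded covariates.
    Reports the full-model R^2 (SS_fitted / SS_total, with adjusted R^2) and,
    per covariate, the marginal R^2 (unique contribution: full minus the
    model without that term) with a permutation p-value
    (count(F_perm >= F_obs) + 1) / (permutations + 1) from row permutations
    of the response.
    """
    Y = np.asarray(response, dtype=float)
    n = Y.shape[0]
    if covariates.shape[0] != n:
        raise ParameterError("response and covariates disagree in sample count")
    rng = np.random.default_rng(seed)
    X, spans = _dummy_code(covariates)
    X, spans = _drop_collinear(X, spans, n)
    Yc = Y - Y.mean(axis=0)
    ss_tot = float((Yc ** 2).sum())
    if ss_tot <= 0:
        raise ParameterError("response has zero total variance")

    Q_full = _projector(X)
    df_model = Q_full.shape[1] - 1
    df_resid = n - 1 - df_model
    reduced = {name: _projector(np.delete(X, np.r_[sl], axis=1))
               for name, sl in spans}

    def fit_ss(Q: np.ndarray, Ymat: np.ndarray) -> float:
        return float(((Q.T @ Ymat) ** 2).sum())

    ss_full = fit_ss(Q_full, Yc)
    ss_resid = ss_tot - ss_full
    rows = [{
        "term": "full_model", "df": df_model,
        "R2": ss_full / ss_tot,
        "adj_R2": 1.0 - (1.0 - ss_full / ss_tot) * (n - 1) / max(df_resid, 1),
        "F": _safe_f(ss_full, df_model, ss_resid, df_resid),
        "p": np.nan,
    }]

    stats_obs = {}
    for name, sl in spans:
        df_term = sl.stop - sl.start
        ss_term = ss_full - fit_ss(reduced[name], Yc)
        F = _safe_f(ss_term, df_term, ss_resid, df_resid)
        stats_obs[name] = F
        rows.append({"term": name, "df": df_term, "R2": ss_term / ss_tot,
                     "adj_R2": np.nan, "F": F, "p": 1.0})

    counts = {name: 0 for name, _ in spans}
    count_full = 0
    for _ in range(permutations):
        Yp = Yc[rng.permutation(n)]
        ssf = fit_ss(Q_full, Yp)
        ssr = ss_tot - ssf
        if _safe_f(ssf, df_model, ssr, df_resid) >= rows[0]["F"] - 1e-12:
            count_full += 1
        for name, sl in spans:
            df_term = sl.stop - sl.start
            ss_term = ssf - fit_ss(reduced[name], Yp)
            F = _safe_f(ss_term, df_term, ssr, df_resid)
            if F >= stats_obs[name] - 1e-12:
                counts[name] += 1
    rows[0]["p"] = (count_full + 1) / (permutations + 1)
    for row in rows[1:]:
        row["p"] = (counts[row["term"]] + 1) / (permutations + 1)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PERMANOVA

def euclidean_distances(Y: np.ndarray, ids: list[str]) -> DistanceMatrix:
    from scipy.spatial.distance import pdist, squareform
    return DistanceMatrix(ids, squareform(pdist(np.asarray(Y, dtype=float))))


def gower_center(d: DistanceMatrix) -> np.ndarray:
    """Gower-centered inner-product matrix G = -1/2 J D^2 J."""
    D2 = d.values.astype(float) ** 2
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ D2 @ J


def permanova(
    d: DistanceMatrix,
    covariates: pd.DataFrame,
    permutations: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Sequential (Type I) PERMANOVA in the covariate order given.

    Per-term pseudo-F from Gower-centered inner products, p by row
    permutation ((count >= obs) + 1) / (permutations + 1), R^2 per term =
    SS_term / SS_total; term and residual R^2 sum to 1.  On a 1-dimensional
    Euclidean response with one factor this reduces to the one-way ANOVA F.
    """
    n = len(d.ids)
    if n < 3:
        raise ParameterError("PERMANOVA needs at least 3 samples")
    if covariates.shape[0] != n:
        raise ParameterError("distance matrix and covariates disagree in size")
    rng = np.random.default_rng(seed)
    G = gower_center(d)
    ss_tot = float(np.trace(G))
    X, spans = _dummy_code(covariates)
    X, spans = _drop_collinear(X, spans, n)

    # cumulative projectors: intercept, then adding one term at a time
    Qs = [_projector(np.zeros((n, 0)))]
    for _, sl in spans:
        Qs.append(_projector(X[:, :sl.stop]))
    df_terms = [sl.stop - sl.start for _, sl in spans]
    df_model = sum(df_terms)
    df_resid = n - 1 - df_model
    if df_resid <= 0:
        raise ParameterError("saturated design: no residual degrees of freedom")

    def seq_ss(Gm: np.ndarray) -> tuple[list[float], float]:
        traces = [float(np.einsum("ij,ij->", Q, Gm @ Q)) for Q in Qs]
        terms = [traces[i + 1] - traces[i] for i in range(len(spans))]
        resid = ss_tot_m(Gm) - traces[-1]
        return terms, resid

    def ss_tot_m(Gm: np.ndarray) -> float:
        return float(np.trace(Gm))

    ss_terms, ss_resid = seq_ss(G)
    F_obs = [_safe_f(ss_terms[i], df_terms[i], ss_resid, df_resid)
             for i in range(len(spans))]

    counts = [0] * len(spans)
    for _ in range(permutations):
        p = rng.permutation(n)
        Gp = G[np.ix_(p, p)]
        terms_p, resid_p = seq_ss(Gp)
        for i in range(len(spans)):
            Fp = _safe_f(terms_p[i], df_terms[i], resid_p, df_resid)
            if Fp >= F_obs[i] - 1e-12:
                counts[i] += 1

    rows = []
    for i, (name, _) in enumerate(spans):
        rows.append({"term": name, "df": df_terms[i], "SS": ss_terms[i],
                     "R2": ss_terms[i] / ss_tot, "F": F_obs[i],
                     "p": (counts[i] + 1) / (permutations + 1)})
    rows.append({"term": "residual", "df": df_resid, "SS": ss_resid,
                 "R2": ss_resid / ss_tot, "F": np.nan, "p": np.nan})
    rows.append({"term": "total", "df": n - 1, "SS": ss_tot, "R2": 1.0,
                 "F": np.nan, "p": np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Per-taxon group tests with compact letter display

def _pairwise_mwu(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney U: exact enumeration for small tie-free groups,
    otherwise the normal approximation with tie and continuity correction."""
    exact = len(x) <= 8 and len(y) <= 8 and np.unique(np.r_[x, y]).size == len(x) + len(y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="exact" if exact else "asymptotic",
                             use_continuity=True)
    return float(res.pvalue)


def _letter_display(groups: list[str], sig: dict[tuple[str, str], bool]) -> dict[str, str]:
    """Compact letter display: groups share a letter iff no pairwise test
    separates them (maximal cliques of the non-significance graph)."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(groups)
    for a, b in itertools.combinations(groups, 2):
        if not sig[(a, b)]:
            g.add_edge(a, b)
    cliques = sorted(nx.find_cliques(g),
                     key=lambda c: min(groups.index(m) for m in c))
    letters = {grp: "" for grp in groups}
    for i, clique in enumerate(cliques):
        ch = chr(ord("a") + i)
        for member in clique:
            letters[member] += ch
    return {g_: "".join(sorted(v)) for g_, v in letters.items()}


def taxon_group_tests(
    table: pd.DataFrame,
    taxon: str,
    grouping: pd.Series,
    alpha: float = 0.05,
) -> dict:
    """Compare one taxon's relative abundance across groups (e.g. age bins).

    Kruskal-Wallis omnibus (tie-corrected) plus all pairwise Mann-Whitney U
    tests; returns omnibus p, the pairwise table, and a compact letter
    display (groups share a letter iff no pairwise p < alpha separates them).
    Empty or singleton groups are excluded with a warning.
    """
    if taxon not in table.columns:
        raise ParameterError(f"taxon {taxon!r} not in table")
    vals = table[taxon]
    grouping = grouping.loc[vals.index]
    labels = [str(g) for g in
              (grouping.cat.categories if hasattr(grouping, "cat") else
               pd.unique(grouping.dropna()))]
    samples = {}
    for lab in labels:
        x = vals[grouping.astype(str) == lab].to_numpy(dtype=float)
        if x.size < 2:
            log.warning("group %r has < 2 samples; excluded", lab)
            continue
        samples[lab] = x
    if len(samples) < 2:
        raise ParameterError("need at least 2 groups with >= 2 samples")
    used = [lab for lab in labels if lab in samples]

    omnibus_p = float(stats.kruskal(*[samples[g] for g in used]).pvalue)
    rows = []
    sig = {}
    for a, b in itertools.combinations(used, 2):
        p = _pairwise_mwu(samples[a], samples[b])
        rows.append({"group1": a, "group2": b, "p": p, "significant": p < alpha})
        sig[(a, b)] = sig[(b, a)] = p < alpha
    letters = _letter_display(used, sig)
    return {
        "taxon": taxon,
        "omnibus_p": omnibus_p,
        "pairwise": pd.DataFrame(rows),
        "letters": letters,
        "group_medians": {g: float(np.median(samples[g])) for g in used},
    }
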