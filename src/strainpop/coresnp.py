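"""Core-genome SNP calling, pairwise SNP distances, and neighbor-joining trees.

Genomes are consumed as reference-coordinate alignments (one equal-length
record per strain plus the reference), i.e. the whole-genome alignment step
is upstream of this package.  Every downstream stage — clonal pruning,
chromosome painting, Fst, GWAS, transmission — runs off the bi-allelic core
SNP matrix produced here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio.tree import TreeNode

from .errors import FormatError, ParameterError

# ASCII codes for the four unambiguous bases; anything else (N, -, IUPAC
# ambiguity) is treated as missing.
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase

MISSING = np.int8(-1)


def encode_bases(seq: str | bytes) -> np.ndarray:
    """Encode a sequence as int8 codes: A,C,G,T -> 0..3; other -> -1."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _CODE[np.frombuffer(seq, dtype=np.uint8)]


def decode_bases(codes: np.ndarray) -> str:
    out = np.full(codes.shape, ord("N"), dtype=np.uint8)
    ok = codes >= 0
    out[ok] = _BASES[codes[ok]]
    return out.tobytes().decode("ascii")


@dataclass
class AlignedGenomeSet:
    """Equal-length genomes in reference coordinates.

    ``codes`` is an (n_records x L) int8 matrix over {0..3, -1}; the row at
    ``ids.index(reference_id)`` is the reference and must contain no missing
    calls.
    """

    ids: list[str]
    reference_id: str
    codes: np.ndarray

    def __post_init__(self) -> None:
        if len(self.ids) != self.codes.shape[0]:
            raise FormatError("id list and sequence matrix disagree in length")
        if len(set(self.ids)) != len(self.ids):
            raise FormatError("duplicate record ids in alignment")
        if self.reference_id not in self.ids:
            raise FormatError(f"reference record {self.reference_id!r} not in alignment")
        ref = self.codes[self.ids.index(self.reference_id)]
        if (ref < 0).any():
            raise FormatError("reference sequence contains N or gap characters")

    @property
    def length(self) -> int:
        return self.codes.shape[1]

    @property
    def strain_ids(self) -> list[str]:
        """All record ids except the reference."""
        return [i for i in self.ids if i != self.reference_id]

    @property
    def reference_codes(self) -> np.ndarray:
        return self.codes[self.ids.index(self.reference_id)]

    @property
    def strain_codes(self) -> np.ndarray:
        keep = [i for i, name in enumerate(self.ids) if name != self.reference_id]
        return self.codes[keep]

    def sequence(self, record_id: str) -> str:
        return decode_bases(self.codes[self.ids.index(record_id)])

    def subset(self, keep_ids: list[str]) -> "AlignedGenomeSet":
        """Restrict to ``keep_ids`` (reference always retained)."""
        names = list(keep_ids)
        if self.reference_id not in names:
            names = [self.reference_id] + names
        idx = [self.ids.index(n) for n in names]
        return AlignedGenomeSet(names, self.reference_id, self.codes[idx])


@dataclass
class SnpMatrix:
    """Bi-allelic core SNP calls in reference coordinates.

    ``alleles`` is (n_strains x n_sites) over {0 (ref), 1 (alt), -1 (missing)};
    positions are 1-based and strictly increasing.
    """

    strain_ids: list[str]
    reference_id: str
    positions: np.ndarray  # int64, 1-based
    ref_alleles: np.ndarray  # int8 base codes
    alt_alleles: np.ndarray  # int8 base codes
    alleles: np.ndarray  # int8 (n x m)
    genome_length: int = 0

    def __post_init__(self) -> None:
        if self.positions.size and not (np.diff(self.positions) > 0).all():
            raise FormatError("SNP positions must be strictly increasing")

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)

    def subset_strains(self, keep_ids: list[str]) -> "SnpMatrix":
        idx = [self.strain_ids.index(s) for s in keep_ids]
        sub = self.alleles[idx]
        variable = ((sub == 0).any(axis=0)) & ((sub == 1).any(axis=0))
        return SnpMatrix(
            list(keep_ids),
            self.reference_id,
            self.positions[variable],
            self.ref_alleles[variable],
            self.alt_alleles[variable],
            sub[:, variable],
            self.genome_length,
        )


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances (integer SNP counts or real sketch distances)."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.shape != (len(self.ids), len(self.ids)):
            raise FormatError("distance matrix shape does not match id list")
        if not np.allclose(v, v.T):
            raise FormatError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise FormatError("distance matrix has nonzero diagonal")
        if np.any(v < 0):
            raise FormatError("negative distances")
        self.values = v

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def subset(self, keep_ids: list[str]) -> "DistanceMatrix":
        idx = [self.ids.index(s) for s in keep_ids]
        return DistanceMatrix(list(keep_ids), self.values[np.ix_(idx, idx)])


def call_core_snps(genomes: AlignedGenomeSet, core_fraction: float = 1.0) -> SnpMatrix:
    """Call bi-allelic SNPs on the core genome.

    A column is *core* when the fraction of strains (reference excluded) with
    an unambiguous base is >= ``core_fraction``.  Among core columns, those
    where exactly two bases are observed (reference included) become sites;
    columns with three or more bases are dropped as non-bi-allelic.  N/gap
    calls at retained sites become missing.
    """
    if not 0.0 < core_fraction <= 1.0:
        raise ParameterError(f"core_fraction must be in (0, 1], got {core_fraction}")
    strains = genomes.strain_ids
    if len(strains) < 2:
        raise ParameterError("need at least 2 non-reference strains to call SNPs")
    X = genomes.strain_codes  # (n, L)
    ref = genomes.reference_codes
    ok = X >= 0
    core = ok.mean(axis=0) >= core_fraction

    present = np.zeros((4, genomes.length), dtype=bool)
    for b in range(4):
        present[b] = (X == b).any(axis=0)
        present[b] |= ref == b
    n_bases = present.sum(axis=0)
    site = core & (n_bases == 2)

    pos = np.flatnonzero(site)
    ref_al = ref[pos]
    # the alt allele is the observed base that is not the reference base
    alt_al = np.empty_like(ref_al)
    sub_present = present[:, pos]
    for b in range(4):
        is_alt = sub_present[b] & (ref_al != b)
        alt_al[is_alt] = b

    sub = X[:, pos]
    alleles = np.full(sub.shape, MISSING, dtype=np.int8)
    alleles[sub == ref_al[None, :]] = 0
    alleles[sub == alt_al[None, :]] = 1
    return SnpMatrix(
        list(strains),
        genomes.reference_id,
        (pos + 1).astype(np.int64),
        ref_al.astype(np.int8),
        alt_al.astype(np.int8),
        alleles,
        genome_length=genomes.length,
    )


def pairwise_snp_distances(snps: SnpMatrix) -> DistanceMatrix:
    """Pairwise SNP counts with pairwise deletion of missing calls.

    d(i, j) counts sites where both strains have a non-missing call and the
    calls differ.  All downstream thresholds (300 / 2500 / 10) are absolute
    counts, so no normalization to a rate is applied.
    """
    if snps.n_strains < 2:
        raise ParameterError("need at least 2 strains")
    A = (snps.alleles == 1).astype(np.float64)
    B = (snps.alleles == 0).astype(np.float64)
    d = A @ B.T + B @ A.T
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(snps.strain_ids), np.rint(d).astype(np.int64))


def diversity_by_group(d: DistanceMatrix, groups: dict[str, str]) -> pd.DataFrame:
    """Within-group pairwise distance summaries (n, median, IQR).

    Groups of size < 2 are reported with their size and NaN statistics.
    """
    rows = []
    labels = sorted({groups[s] for s in d.ids if s in groups})
    for lab in labels:
        members = [s for s in d.ids if groups.get(s) == lab]
        idx = [d.ids.index(s) for s in members]
        if len(idx) < 2:
            rows.append({"group": lab, "n": len(idx), "n_pairs": 0,
                         "median": np.nan, "q1": np.nan, "q3": np.nan})
            continue
        sub = d.values[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        vals = sub[iu]
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append({"group": lab, "n": len(idx), "n_pairs": vals.size,
                     "median": med, "q1": q1, "q3": q3})
    return pd.DataFrame(rows)


def neighbor_joining(d: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with the Studier-Keppler Q criterion.

    Ties in Q are broken by lexicographic pair order over the current node
    creation order; negative branch-length estimates are clamped to zero with
    the deficit shifted onto the sibling branch.  Additive matrices are
    recovered exactly (all leaf-to-leaf path lengths reproduced).
    """
    n = len(d.ids)
    if n < 3:
        raise ParameterError("neighbor joining requires at least 3 strains")
    D = d.values.astype(np.float64).copy()
    nodes: list[TreeNode] = [TreeNode(name=s) for s in d.ids]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lexicographic tie-break: first minimal (i, j) in row-major order
        flat = np.argmin(Q)
        qmin = Q.flat[flat]
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        ai, aj = min((int(i), int(j)) for i, j in ties if i < j)
        i, j = active[ai], active[aj]

        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = TreeNode()
        ci, cj = nodes[i], nodes[j]
        ci.length = float(li)
        cj.length = float(lj)
        parent.extend([ci, cj])

        new = D.shape[0]
        D = np.pad(D, ((0, 1), (0, 1)))
        for ak in active:
            if ak in (i, j):
                continue
            D[new, ak] = D[ak, new] = 0.5 * (D[i, ak] + D[j, ak] - dij)
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [new]

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = TreeNode()
    for k, lk in zip((a, b, c), (la, lb, lc)):
        nodes[k].length = float(max(lk, 0.0))
        root.append(nodes[k])
    return root
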